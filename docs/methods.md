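# Methods

This note records the models, defaults and numerical choices behind
`bindsite`, and what the synthetic fixtures do and do not establish.

## Binding-site definition

Each relevant ligand instance contributes the set of protein residues it
contacts (reference-sequence numbering). Ligands are nodes of an overlap
graph; an edge joins two ligands when the Jaccard index of their residue
sets reaches a threshold `tau` (default 0.5; `overlap-coefficient` and
`share-one` statistics are available). Binding sites are the connected
components. Any positive `tau` additionally requires a strictly positive
intersection, so `tau = 0` degenerates to "share at least one residue".
The exact overlap criterion used by production site-definition pipelines
is not published in a reusable form, hence statistic and threshold are
configuration, not constants.

Site numbering is deterministic and input-order independent: descending
member count, then smallest minimum residue index, then smallest member
key. Identical interfaces (same structure, component and residue set)
appearing in several assemblies of one structure are counted once,
*before* graph construction.

Only homomeric complexes are supported: residue identity across chains
is by author residue number, and a custom batch must present the same
number of protein chains per structure (validated up front).

## Contact model

Every protein-atom/ligand-atom pair within 5.0 Å is recorded with a
distance class — *clash* (d < r_i + r_j, van der Waals radii), *vdw*
(within the envelope plus a 0.1 Å compensation factor), *proximal*
(otherwise) — and interaction types: *hbond* (donor/acceptor heavy-atom
pair ≤ 3.5 Å), *polar* (donor/acceptor 3.5–4.0 Å), *ionic* (opposite
formal charges ≤ 4.0 Å), *hydrophobic* (two apolar carbons ≤ 4.5 Å).
Hydrogens are ignored throughout; with no hydrogen positions there is no
angular term, which over-calls hydrogen bonds relative to
geometry-aware tools. Protein atoms are typed from residue/atom-name
templates for the 20 standard amino acids; ligand atoms by element
heuristics (N/O treated as both donor and acceptor, C as hydrophobe,
formal charge read from the coordinate file). Component-dictionary
chemistry perception is deliberately out of scope.

A residue joins a ligand's binding set if it has at least one contact
that is typed or inside the vdW envelope; untyped proximal contacts are
excluded by default. Which categories "count" is configurable
(`ContactPolicy`) because upstream practice varies.

Detection uses a k-d tree but is tested for exact equality against an
all-pairs distance scan.

## Divergence, missense enrichment

Shenkin divergence per alignment column: `V = 6·2^H` with `H` the
base-2 Shannon entropy of amino-acid frequencies over non-gap symbols;
`V` spans [6, 120] and is normalised to DS in [0, 100]. Default
normalisation is over the theoretical range; per-alignment min–max
("empirical") is available since the normalisation convention in the
literature is ambiguous. Gaps are excluded from frequencies; columns
with under 50% occupancy are flagged low-coverage but scored;
non-standard symbols (B, Z, U, O, J, X) count toward occupancy but not
entropy.

MES per column uses a 2×2 table of (variant, residue-without-variant) ×
(column, rest-of-alignment), where "residues" are non-gap occupancies of
the human records. OR = ad/bc with Haldane–Anscombe +0.5 on all cells
when any cell is zero; 95% CI from the log-OR normal approximation;
p from the two-sided Fisher exact test on the uncorrected table; raw
p-values, no multiple-testing correction. By default a position with a
variant counts once (`cap_variants=True`); allele-level counts can be
supplied with the cap off. Alignments without human records yield
MES-undefined columns (flagged, not an error).

## Accessibility and secondary structure

ASA uses Shrake–Rupley sphere sampling (960 points/atom by default,
probe 1.4 Å) via biotite's implementation, driven with this package's
element radii (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å …). Residue ASA
is the exact sum of member-atom ASAs. RSA = 100·ASA/max_ASA with a
published theoretical-maximum scale (ALA 129.0 Ų …), capped at 100 by
default and replaceable via configuration. Sampled ASA is exactly
translation invariant but rotation invariant only to quadrature
tolerance (≈1%); tests reflect that. By default ligands/waters do not
occlude (apo-style RSA comparable across assemblies).

Secondary structure follows Kabsch–Sander: amide H reconstructed 1.01 Å
from N along the direction opposing the bisector of C(prev)–N and CA–N;
H-bond energy `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)`
kcal/mol, bond iff E < −0.5; chain breaks detected by peptide-bond
distance. Pattern rules give the 8 states with priority
H > E > G/I > B > T > S > C. This is a faithful re-implementation, not a
bit-exact replica of the original program; residues missing backbone
atoms become coil with a warning, and a precomputed SS table can be
imported instead.

## Cluster probabilities and functional score

The production accessibility-cluster classifier (a trained MLP) is not
redistributable, so the default model is a transparent stand-in: softmax
over negative squared distances of (mean RSA, RSA interquartile range)
to four centroids at 15/40/65/90 % RSA (IQR component 15 each),
temperature 50 %². C1 is the most buried cluster; a site's
buried-cluster probability is monotone decreasing in mean RSA. The model
serialises to versioned JSON, and any object with the same
`predict_proba` contract can be plugged in. Cluster probabilities from
this stand-in are *not* the production MLP's — only the FS arithmetic
downstream of P is exact.

`FS = P·F` with `F = [0.52, 0.18, 0.05, 0.04]` (proportion of annotated
functional sites per cluster, a published constant here treated as
config-overridable data). FS is linear in P and bounded by min/max of F.

## Superposition

Batches are superposed by Kabsch least squares on CA atoms paired by
author residue number onto the representative (most resolved CA in the
first chain; ties by structure id). Reflections are excluded via the SVD
determinant correction. This replaces a sequence-independent structural
aligner deliberately: the batch contract already requires a shared
numbering scheme, making pairing trivial at desk scale. Assemblies
sharing fewer than 3 CA positions with the representative are skipped
with a warning.

## Synthetic fixtures: what a green test establishes

The structure generator plants 1–6 disjoint pockets on a rigid two-helix
backbone-only poly-alanine scaffold (ideal φ/ψ = −57°/−47°, built by
internal-coordinate chaining). Each ligand is three N/O atoms placed
~3 Å radially outward from two pocket carbonyl oxygens one helix turn
apart, so each forms hydrogen-bond-typed contacts to exactly the planted
residues. Ground truth is verified at build time with the generator's
own distance arithmetic, and jitter beyond 0.25 Å (or any jitter that
shifts an admitted residue set) is refused. The alignment generator
produces ungapped sequences with designed conserved/divergent/depleted
columns and Binomial missense variants.

These fixtures validate the pipeline's bookkeeping and statistics, not
physics: there are no side chains, no waters, no ionic or hydrophobic
site chemistry, no alternate locations, no gapped alignments, and pocket
geometry is idealised. Recovery of planted sites therefore demonstrates
correctness of contact typing, interface mapping, deduplication and
clustering — it says nothing about performance on real, noisy
structures. Defaults (2 structures, 3 sites, 2 ligands/site, 10-sequence
alignments, 20% missense rate, tenfold depletion) were chosen once as a
small but non-degenerate regime and are not tuned to test outcomes.

## Numerical conventions

CSV exports are comma-separated, UTF-8, LF, '.' decimal, floats to 6
significant digits — fixed so identical inputs/config/seed give
byte-identical outputs. Undefined values (MES without human homologues,
DS without an MSA) export as empty fields. All randomness in fixtures is
driven by explicit integer seeds; the analysis pipeline itself is
deterministic.

## Known limitations

- Heteromeric interfaces, nucleic-acid entities, symmetry expansion and
  assembly generation are out of scope (assemblies are consumed as
  files, one per file).
- Ligand chemistry is element-level; tautomers, aromaticity, halogen
  bonds, ring stacking and water bridges are not modelled.
- Hydrogen-bond calls lack angular screening.
- The C1–C4 probabilities come from the documented stand-in model unless
  a trained classifier is supplied; cross-study comparability of FS
  depends on that choice.
- MSA quality is the caller's responsibility; the homology search that
  produces it is not run here.
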