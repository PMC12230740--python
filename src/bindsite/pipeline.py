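"""End-to-end orchestration and export of binding-site analyses.

``run_pipeline`` executes the full analysis on a batch of structure
files: read -> ligand relevance filter -> contact detection -> interface
clustering into sites -> (conservation, missense enrichment and
accessibility, when an MSA/variant table is supplied) -> cluster
probabilities and functional scores -> CSV / viewer-script exports.
Identical inputs, configuration and seed produce byte-identical CSVs.

Two modes mirror the server's entry points: *reference* (a reference
accession names the sequence whose numbering and MSA record anchor the
residue mapping) and *custom* (no accession; the structures' own
numbering is the reference, so the batch must share a numbering scheme).
"""

from __future__ import annotations

import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .accessibility import assemble_accessibility, assign_secondary_structure
from .chem import AA3_TO_1
from .conservation import (Alignment, column_mapping, column_profiles,
                           read_alignment, write_stockholm)
from .contacts import (CONTACT_CSV_HEADER, ContactParams, ContactPolicy,
                       binding_residues_per_ligand, contacts_to_rows,
                       detect_contacts)
from .scoring import (CentroidSoftmaxModel, ClusterModel, FunctionalProportions,
                      ResidueFeatures, SiteFeatures, score_sites)
from .sites import (BindingSite, deduplicate_interfaces, define_sites,
                    map_residues_to_reference, read_mapping_table)
from .structure import (Assembly, default_exclusion_list, filter_relevant_ligands,
                        load_exclusion_list, read_structures, validate_batch,
                        write_assembly_pdb)
from .superpose import SuperpositionResult, superpose_batch
from .variation import column_mes, read_variant_table

__all__ = [
    "RunConfig",
    "PipelineResult",
    "PipelineError",
    "run_pipeline",
    "write_binding_sites_csv",
    "write_binding_residues_csv",
    "write_contacts_exports",
    "write_viewer_scripts",
]

logger = logging.getLogger("bindsite")

SITE_CSV_HEADER = ["site_id", "size", "mean_RSA", "mean_DS", "mean_MES",
                   "cluster_label", "FS", "n_ligands"]
RESIDUE_CSV_HEADER = ["UPResNum", "MSACol", "DS", "MES", "p", "AA", "RSA", "SS"]

#: ChimeraX/PyMOL site colour cycle (name usable in both dialects)
_SITE_COLORS = ["red", "orange", "yellow", "green", "cyan", "blue",
                "purple", "magenta", "salmon", "olive", "teal", "pink"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; mirrors the per-flag configuration."""

    structures: Sequence[str | Path]
    mode: str = "custom"  # {"reference", "custom"}
    format_hint: str = "auto"
    reference_id: str | None = None  # accession; also the MSA record id
    msa_path: str | Path | None = None
    variants_path: str | Path | None = None
    mapping_path: str | Path | None = None
    exclusion_path: str | Path | None = None
    tau: float = 0.5
    similarity: str = "jaccard"
    contact_params: ContactParams = field(default_factory=ContactParams)
    contact_policy: ContactPolicy = field(default_factory=ContactPolicy)
    cluster_model_path: str | Path | None = None
    functional_proportions: FunctionalProportions = field(
        default_factory=FunctionalProportions)
    out_dir: str | Path = "bindsite_out"
    seed: int = 0
    sasa_points: int = 960

    def __post_init__(self) -> None:
        if self.mode not in ("reference", "custom"):
            raise ValueError("mode must be 'reference' or 'custom'")
        if self.mode == "reference" and not self.reference_id:
            raise ValueError("reference mode requires a reference accession")


@dataclass
class PipelineResult:
    sites: list[BindingSite]
    site_features: list[SiteFeatures]
    residue_features: dict[int, ResidueFeatures]
    superposition: SuperpositionResult
    contacts_by_assembly: dict[tuple[str, str], list]
    outputs: dict[str, Path]
    log_counts: dict[str, int]


def _fmt(value, digits: int = 6) -> str:
    """Float to <= 6 significant digits, '.' decimal; blank for undefined."""
    if value is None:
        return ""
    if isinstance(value, (int,)) and not isinstance(value, bool):
        return str(value)
    return f"{value:.{digits}g}"


def write_binding_sites_csv(site_features: Sequence[SiteFeatures],
                            path: str | Path) -> Path:
    """One row per scored site, ordered by site id."""
    path = Path(path)
    lines = [",".join(SITE_CSV_HEADER)]
    for f in sorted(site_features, key=lambda s: s.site_id):
        lines.append(",".join([
            str(f.site_id), str(f.size), _fmt(f.mean_RSA), _fmt(f.mean_DS),
            _fmt(f.mean_MES), f.cluster_label or "", _fmt(f.FS),
            str(getattr(f, "n_ligands", "")),
        ]))
    path.write_text("\n".join(lines) + "\n", newline="\n")
    return path


def write_binding_residues_csv(sites: Sequence[BindingSite],
                               residue_features: Mapping[int, ResidueFeatures],
                               path: str | Path) -> Path:
    """One row per (site, residue) with the canonical residue columns."""
    path = Path(path)
    lines = [",".join(RESIDUE_CSV_HEADER)]
    for site in sorted(sites, key=lambda s: s.site_id):
        for idx in sorted(site.residues):
            f = residue_features.get(idx) or ResidueFeatures(idx)
            lines.append(",".join([
                str(f.reference_index),
                str(f.msa_column) if f.msa_column is not None else "",
                _fmt(f.DS), _fmt(f.MES), _fmt(f.p), f.aa,
                _fmt(f.RSA), f.SS or "",
            ]))
    path.write_text("\n".join(lines) + "\n", newline="\n")
    return path


def write_contacts_exports(contacts_by_assembly: Mapping[tuple[str, str], list],
                           out_dir: str | Path,
                           scope: str = "all") -> list[Path]:
    """Per-assembly contact CSVs; scope='all' additionally zips them.

    Zip entries are named ``<structure_id>_<assembly_id>.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for (structure_id, assembly_id), contacts in sorted(contacts_by_assembly.items()):
        rows = contacts_to_rows(contacts)
        name = f"{structure_id}_{assembly_id}.csv"
        lines = [CONTACT_CSV_HEADER]
        for row in rows:
            lines.append(",".join([
                str(row["structure_id"]), str(row["assembly_id"]),
                row["ligand_comp_id"], row["ligand_chain"],
                str(row["ligand_resnum"]), row["ligand_atom"],
                row["protein_chain"], str(row["protein_resnum"]),
                row["protein_resname"], row["protein_atom"],
                _fmt(row["distance"]), row["distance_class"],
                row["interaction_types"],
            ]))
        p = out_dir / name
        p.write_text("\n".join(lines) + "\n", newline="\n")
        written.append(p)
    if scope == "all" and written:
        zip_path = out_dir / "contacts_all_assemblies.zip"
        with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
            for p in written:
                zf.write(p, arcname=p.name)
        written.append(zip_path)
    return written


def write_viewer_scripts(superposition: SuperpositionResult,
                         sites: Sequence[BindingSite],
                         out_dir: str | Path,
                         flavor: str = "cxc") -> Path:
    """ChimeraX (.cxc) or PyMOL (.pml) script loading the superposed view.

    Writes the representative assembly and one PDB per site ligand, then
    a script that loads the representative chain in white cartoon and
    each transformed ligand coloured by its binding site.
    """
    if flavor not in ("cxc", "pml"):
        raise ValueError("flavor must be 'cxc' or 'pml'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {a.structure_id: a for a in superposition.assemblies}
    rep = by_id[superposition.representative_id]
    rep_path = out_dir / f"{rep.structure_id}_representative.pdb"
    rep_only = Assembly(rep.assembly_id, rep.structure_id,
                        protein_chains=rep.protein_chains)
    write_assembly_pdb(rep_only, rep_path)
    site_of = {}
    for site in sites:
        for member in site.members:
            site_of[member] = site.site_id
    ligand_files: list[tuple[Path, int]] = []
    for assembly in superposition.assemblies:
        for lig in assembly.ligands:
            if lig.key not in site_of:
                continue
            site_id = site_of[lig.key]
            lig_path = out_dir / (f"ligand_site{site_id}_{lig.structure_id}_"
                                  f"{lig.chain_id}{lig.residue_number}.pdb")
            shell = Assembly(assembly.assembly_id, lig.structure_id, ligands=[lig])
            write_assembly_pdb(shell, lig_path)
            ligand_files.append((lig_path, site_id))
    lines = []
    if flavor == "cxc":
        lines.append(f"open {rep_path.name}")
        lines.append("color #1 white")
        lines.append("cartoon")
        for k, (path, site_id) in enumerate(ligand_files, start=2):
            color = _SITE_COLORS[site_id % len(_SITE_COLORS)]
            lines.append(f"open {path.name}")
            lines.append(f"color #{k} {color}")
            lines.append(f"style #{k} stick")
    else:
        lines.append(f"load {rep_path.name}, representative")
        lines.append("color white, representative")
        lines.append("show cartoon, representative")
        for path, site_id in ligand_files:
            color = _SITE_COLORS[site_id % len(_SITE_COLORS)]
            obj = path.stem
            lines.append(f"load {path.name}, {obj}")
            lines.append(f"color {color}, {obj}")
            lines.append(f"show sticks, {obj}")
    script = out_dir / f"superposition.{flavor}"
    script.write_text("\n".join(lines) + "\n", newline="\n")
    return script


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis; every stage is logged with counts.

    Stage failures raise :class:`PipelineError` naming the stage, and
    files written so far in this run's output directory are removed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {}
    current_stage = "setup"
    try:
        current_stage = "read"
        assemblies = read_structures(config.structures, config.format_hint)
        counts["structures"] = len(assemblies)
        logger.info("read %d assemblies", len(assemblies))

        current_stage = "validate"
        report = validate_batch(assemblies, config.reference_id)
        if not report.passed:
            raise ValueError(
                "chain-count mismatch across batch: "
                + ", ".join(f"{sid}={report.chain_counts[sid]}"
                            for sid in report.offenders))

        current_stage = "ligand-filter"
        exclusion = (load_exclusion_list(config.exclusion_path)
                     if config.exclusion_path else default_exclusion_list())
        filtered: dict[str, list] = {}
        n_pre = n_post = 0
        for assembly in assemblies:
            kept = filter_relevant_ligands(assembly.ligands, exclusion)
            n_pre += len(assembly.ligands)
            n_post += len(kept)
            for lig in assembly.ligands:
                if lig not in kept:
                    logger.info("dropped ligand %r (excluded or partial occupancy)",
                                lig)
            filtered[assembly.structure_id] = kept
        counts["ligands_pre_filter"] = n_pre
        counts["ligands_post_filter"] = n_post

        current_stage = "contacts"
        contacts_by_assembly: dict[tuple[str, str], list] = {}
        ligand_residue_sets: dict[tuple, set[int]] = {}
        comp_of: dict[tuple, str] = {}
        structure_of: dict[tuple, str] = {}
        mapping = (read_mapping_table(config.mapping_path)
                   if config.mapping_path else None)
        for assembly in assemblies:
            contacts = detect_contacts(assembly, config.contact_params,
                                       ligands=filtered[assembly.structure_id])
            contacts_by_assembly[(assembly.structure_id,
                                  assembly.assembly_id)] = contacts
            per_ligand = binding_residues_per_ligand(contacts, config.contact_policy)
            for key, residues in per_ligand.items():
                mapped, unmapped = map_residues_to_reference(
                    residues, assembly.structure_id, mapping)
                if unmapped:
                    logger.info("%s: %d residues unmapped to reference",
                                assembly.structure_id, len(unmapped))
                if mapped:
                    ligand_residue_sets[key] = mapped
                    comp_of[key] = key[4]
                    structure_of[key] = key[0]
        counts["contacts"] = sum(len(v) for v in contacts_by_assembly.values())

        current_stage = "site-definition"
        deduped = deduplicate_interfaces(ligand_residue_sets, comp_of, structure_of)
        if len(deduped) < len(ligand_residue_sets):
            logger.info("deduplicated %d duplicate interfaces",
                        len(ligand_residue_sets) - len(deduped))
        sites = define_sites(deduped, tau=config.tau, statistic=config.similarity)
        counts["sites"] = len(sites)
        logger.info("defined %d binding sites from %d interfaces",
                    len(sites), len(deduped))

        current_stage = "superposition"
        superposition = superpose_batch(assemblies)

        current_stage = "residue-features"
        residue_features = _residue_features(config, assemblies, superposition,
                                             sites, mapping)

        current_stage = "scoring"
        model = (CentroidSoftmaxModel.from_json(config.cluster_model_path)
                 if config.cluster_model_path else CentroidSoftmaxModel())
        site_features = score_sites(sites, residue_features, model,
                                    config.functional_proportions)
        for sf, site in zip(site_features, sites):
            sf.n_ligands = site.n_ligands

        current_stage = "export"
        outputs["binding_sites"] = write_binding_sites_csv(
            site_features, out_dir / "binding_sites.csv")
        outputs["binding_residues"] = write_binding_residues_csv(
            sites, residue_features, out_dir / "binding_residues.csv")
        contact_files = write_contacts_exports(
            contacts_by_assembly, out_dir / "contacts", scope="all")
        if contact_files:
            outputs["contacts_zip"] = contact_files[-1]
        outputs["viewer_cxc"] = write_viewer_scripts(
            superposition, sites, out_dir / "superposition", flavor="cxc")
        outputs["viewer_pml"] = write_viewer_scripts(
            superposition, sites, out_dir / "superposition", flavor="pml")
        if config.msa_path:
            msa = read_alignment(config.msa_path)
            outputs["msa_sto"] = write_stockholm(msa, out_dir / "alignment.sto")
        return PipelineResult(sites, site_features, residue_features,
                              superposition, contacts_by_assembly, outputs,
                              counts)
    except PipelineError:
        raise
    except Exception as exc:
        for path in outputs.values():
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage '{current_stage}' failed: {exc}") from exc


def _residue_features(config: RunConfig, assemblies: list[Assembly],
                      superposition: SuperpositionResult,
                      sites: Sequence[BindingSite],
                      mapping) -> dict[int, ResidueFeatures]:
    """Per-reference-residue features from the representative assembly.

    RSA and secondary structure come from the representative assembly of
    the superposed batch; divergence and missense enrichment come from
    the MSA record named by the reference accession when an MSA is
    supplied (reference index k maps to the record's k-th non-gap
    column). Without an MSA those columns stay undefined.
    """
    wanted = sorted(set().union(*(s.residues for s in sites)) if sites else set())
    rep = next(a for a in assemblies
               if a.structure_id == superposition.representative_id)
    access = assemble_accessibility(rep, n_points=config.sasa_points)
    ss: dict[tuple[str, int], str] = {}
    for chain in rep.protein_chains:
        ss.update(assign_secondary_structure(chain))
    # invert the residue mapping for the representative so reference
    # indices can be traced back to its author numbering
    back: dict[int, tuple[str, int]] = {}
    for chain in rep.protein_chains:
        for res in chain.residues:
            if mapping is None:
                back.setdefault(res.number, (chain.chain_id, res.number))
            else:
                key = (rep.structure_id, chain.chain_id, res.number)
                if key in mapping:
                    back.setdefault(mapping[key], (chain.chain_id, res.number))
    aa_of: dict[tuple[str, int], str] = {}
    for chain in rep.protein_chains:
        for res in chain.residues:
            aa_of[(chain.chain_id, res.number)] = AA3_TO_1.get(res.name.upper(), "X")
    ds_by_col = mes_by_col = pos_to_col = None
    if config.msa_path:
        msa = read_alignment(config.msa_path)
        profiles = column_profiles(msa)
        ds_by_col = {p.column_index: p.DS for p in profiles}
        if config.reference_id and config.reference_id in msa.ids:
            pos_to_col = column_mapping(msa, config.reference_id)
        elif msa.ids:
            pos_to_col = column_mapping(msa, msa.ids[0])
        if config.variants_path:
            variants = read_variant_table(config.variants_path)
            human_ids = {rid for rid in msa.ids if rid.upper().startswith("HUMAN")}
            if human_ids:
                mes_by_col = column_mes(msa, variants, human_ids)
            else:
                logger.info("no human records in MSA; MES undefined")
    features: dict[int, ResidueFeatures] = {}
    for idx in wanted:
        feat = ResidueFeatures(reference_index=idx)
        if idx in back:
            chain_res = back[idx]
            feat.aa = aa_of.get(chain_res, "X")
            acc = access.get(chain_res)
            if acc is not None:
                feat.RSA = acc.RSA
            feat.SS = ss.get(chain_res)
        if pos_to_col and idx in pos_to_col:
            col = pos_to_col[idx]
            feat.msa_column = col
            if ds_by_col:
                feat.DS = ds_by_col.get(col)
            if mes_by_col and col in mes_by_col and mes_by_col[col].defined:
                feat.MES = mes_by_col[col].OR
                feat.p = mes_by_col[col].p
        features[idx] = feat
    return features
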