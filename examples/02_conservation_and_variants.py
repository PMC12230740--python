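"""Column divergence (Shenkin DS) and missense enrichment (MES) on a toy MSA.

Builds an alignment with designed conserved, divergent and
missense-depleted columns, scores every column, and prints the three
designed ones.
"""

from bindsite import column_mes, column_profiles, make_toy_alignment_and_variants

alignment, variants, human_ids = make_toy_alignment_and_variants(
    n_seqs=20, length=30, conserved_cols={5}, divergent_cols={12},
    depleted_cols={20}, base_rate=0.25, seed=4)

profiles = {p.column_index: p for p in column_profiles(alignment)}
mes = column_mes(alignment, variants, human_ids)

print("col  role        DS      MES     p")
for col, role in [(5, "conserved"), (12, "divergent"), (20, "depleted")]:
    p = profiles[col]
    m = mes[col]
    print(f"{col:>3}  {role:<10} {p.DS:6.1f}  {m.OR:6.2f}  {m.p:.3f}")
# DS runs 0 (fully conserved) to 100 (all 20 amino acids equally likely).
# MES is an odds ratio: < 1 means the column carries fewer human missense
# variants than the alignment background (constraint), > 1 enrichment.
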