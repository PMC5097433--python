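"""GO enrichment of the defined set and conservation versus peak stage.

Annotations are propagated up the is_a DAG, each term is tested with the
upper-tail hypergeometric distribution against all annotated DD genes, and
DD-DF global-alignment identity is compared between late-peaking (t3/t4)
and early-peaking (t1) genes with a one-sided Mann-Whitney U test.
"""

import dictycore as dc

res = dc.run_pipeline(dc.SimulationConfig(seed=42))

print("top enriched GO terms in the defined developmental set:")
for r in res.enrichment[:5]:
    print(f"  {r.term_id}  {r.k_study}/{r.n_study} study vs "
          f"{r.k_pop}/{r.n_pop} background  p={r.p_value:.3g} q={r.q_value:.3g}")

print(f"\nDD-DF conservation records: {len(res.conservation_records)}")
t = res.conservation
if t is not None:
    print(f"late (t3/t4) median identity:  {t.median_late:.3f} (n={t.n_late})")
    print(f"early (t1) median identity:    {t.median_early:.3f} (n={t.n_early})")
    print(f"one-sided Mann-Whitney U={t.u_statistic:.0f}, p={t.p_value:.4f} "
          f"({'exact' if t.exact else 'asymptotic'})")
# A small p supports the planted property: genes peaking in the
# fruiting-body stages evolve more slowly than early aggregation genes.
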