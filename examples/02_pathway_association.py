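"""Kernel machine SNP-set test of pathways with one planted risk pathway.

Twenty disjoint 10-gene pathways, one carrying a per-SNP log-odds of 0.35;
the score test should put the planted pathway far ahead of the rest.
"""

from padnet import assoc
from padnet.assoc import KernelSpec, PathwaySnpSet
from padnet.simulate import SimulationConfig, simulate

cfg = SimulationConfig(
    n_cases=1000, n_controls=1000, n_genes=200, snps_per_gene=(1, 1),
    n_pathways=20, pathway_size_range=(10, 10), disjoint_pathways=True,
    risk_pathways={"PW01": 0.35}, missing_rate=0.0, seed=7,
)
bundle = simulate(cfg)
snp_of_gene = {s.rsplit("_", 1)[0]: s for s in bundle.data.snps["snp_id"]}
sets = [
    PathwaySnpSet(pid, sorted(snp_of_gene[g] for g in genes))
    for pid, genes in bundle.pathways.items()
]

# flat weights: matched to equal per-SNP effects on common variants
results = assoc.test_pathways(bundle.data, sets, spec=KernelSpec(weight_scheme="flat"))
print(f"{'pathway':8s} {'n_snps':>6s} {'Q':>12s} {'p_raw':>10s} {'p_adj':>10s} sig")
for r in results[:5]:
    print(f"{r.pathway_id:8s} {r.n_snps:6d} {r.q_stat:12.1f} "
          f"{r.p_raw:10.2e} {r.p_adjusted:10.2e} {r.significant}")
print("\nThe planted risk pathway (PW01) should rank first with an adjusted")
print("p-value many orders of magnitude below the 19 null pathways, whose")
print("raw p-values are roughly uniform.")
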