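"""Robustness of ARSI rankings to sequencing-error-level mutation.

Because the score aggregates many substring matches per element, uniform
substitution errors at realistic rates (1 per 1000 nt) barely perturb the
ranking: the Spearman correlation between scores computed before and
after mutating the whole reference stays above 0.99.
"""

from arsi import analysis
from arsi.synthetic import SyntheticSpec, synthesize_genome

ds = synthesize_genome(SyntheticSpec(n_genes=300, seed=42))
total = sum(len(p.orf) for p in ds.parts)
rhos = analysis.error_robustness(ds.parts, "orf", error_rate=1e-3,
                                 n_replicates=5, seed=42)
print(f"reference: {len(ds.parts)} ORFs, {total} nt total")
print("Spearman(before, after) per error replicate:")
for i, r in enumerate(rhos):
    print(f"  replicate {i}: rho = {r:.4f}")
print(f"minimum: {min(rhos):.4f}")
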