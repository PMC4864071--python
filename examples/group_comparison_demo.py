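"""Group-level cross-prediction of trial measures with a planted coupling.

Builds 15 subjects of null measures in which the per-trial SSE is driven by
the DTW-spectrum SD (beta = 0.5), runs per-subject GLMs, the group t-test,
BH-FDR over the 30-cell matrix and a permutation test, then prints the cells
that survive.
"""

from dtwspec import StatsConfig, generate_null_measures, run_comparison

measures = generate_null_measures(15, 112, seed=5, coupling=[("sse", "dtw_sd", 0.5)])
result = run_comparison(measures, cfg=StatsConfig(n_perm=999, seed=5))

sig = result.table[result.table.p_fdr < 0.05]
print("cells with FDR p < 0.05 (planted: sse <- dtw_sd, beta 0.5):")
for r in sig.itertuples():
    print(f"  {r.target:9s} <- {r.predictor:9s} beta {r.mean_beta:+.3f} "
          f"t {r.t:6.2f}  FDR p {r.p_fdr:.2e}  perm p {r.p_perm:.4f}")
n_null = (result.table.p_fdr >= 0.05).sum()
print(f"{n_null} of {len(result.table)} cells correctly stay null "
      "(the reverse cell flags too: association is symmetric)")
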