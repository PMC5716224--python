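"""Flag an injected low-quality cell and keep over-dispersed genes.

One cell is scaled down 5-fold (a degraded library).  After per-gene
standardization its norm z-score is extreme and the two-sided z rule
flags it.  Gene filtering then keeps genes more variable than the
negative-binomial mean-dispersion trend predicts.
"""

import numpy as np

import cellpipe as cp

dataset, truth = cp.simulate_dataset(
    cp.SimulationParams(n_genes=500, n_cells=100, seed=3)
)
damaged, truth = cp.inject_outliers(dataset, truth, n=1, scale=5.0, seed=3)

log = cp.log_transform(damaged.matrix)
report = cp.detect_outliers(cp.cell_norms(log), log.sample_ids,
                            z_threshold=2, value_space="log")
hit = report.flagged
print(f"injected outlier: {truth.outlier_cells}; flagged: {hit}")
idx = log.sample_ids.index(truth.outlier_cells[0])
print(f"its norm z-score: {report.zscores[idx]:.2f} (|z| > 2 flags it)")

clean = cp.remove_samples(damaged, report.flagged)
table = cp.dispersion_table(clean.matrix)
trend = cp.fit_dispersion_trend(table)
table = cp.filter_genes(table, trend, mean_threshold=0.5, dispersion_ratio=1.0)
print(f"dispersion trend phi(mu) = {trend.a0:.3f} + {trend.a1:.3f}/mu; "
      f"kept {table.summary['n_kept']} of {table.summary['n_total']} genes")
# kept genes sit above both the mean threshold and the fitted trend, i.e.
# they carry more variation than depth + counting noise explain.
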