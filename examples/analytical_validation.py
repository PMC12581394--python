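"""Analytical-validation statistics: LoD, LoB, precision and Deming.

Each block builds a small input (simulated or typed in), runs one
estimator and prints the result with a line on what it means.
"""

import numpy as np
import pandas as pd

from cdxval import (
    BlankPanel,
    deming_regression,
    estimate_lob,
    estimate_lod,
    simulate_dilution_series,
    simulate_precision_panel,
    variance_components,
)

# --- limit of detection: 20 replicates per VF level, logistic detection ----
series = simulate_dilution_series(
    true_lod_level=7.5, slope=1.2, levels=[2.5, 5.0, 7.5, 10.0, 15.0],
    replicates=20, analyte_id="BRAF V600E (VF %)", seed=3,
)
res = estimate_lod(series)
print(f"{series.analyte_id}: hit rates {res.per_level_hit_rates}")
print(f"LoD = {res.lod_level}% VF (lowest level with >= 95% detection and a qualifying tail)\n")

# --- limit of blank: wild-type samples, zero-event exact upper bound -------
panel = BlankPanel(pd.DataFrame({
    "sample_id": ["wt1", "wt2", "wt3"],
    "variant_class": ["SNV", "SNV", "INDEL"],
    "false_positive_calls": [1, 0, 0],
    "opportunities": [40_000, 60_000, 30_000],
}))
for cls, r in estimate_lob(panel).items():
    print(f"LoB {cls}: rate {100 * r.rate:.4f}%  upper bound {100 * r.ci_high:.4f}% ({r.ci_method})")
print()

# --- precision: 36-replicate crossed design, variance components and %CV ---
p = simulate_precision_panel(
    mean=12.0, sigma_operator=0.2, sigma_lot=0.5, sigma_run=0.3, sigma_resid=0.4,
    panel_member="TMB panel member", seed=5,
)
d = variance_components(p)
print(f"variance components: { {k: round(v, 4) for k, v in d.components.items()} }")
print(f"total within-lab SD {d.total_sd:.3f} at mean {d.mean:.2f} -> %CV {d.cv_percent:.1f}%\n")

# --- Deming regression: TMB method comparison with errors in both assays ---
rng = np.random.default_rng(8)
truth = rng.uniform(2, 30, 60)
x = truth + rng.normal(0, 1.0, 60)  # comparator WES assay
y = 0.9 * truth - 0.5 + rng.normal(0, 1.0, 60)  # new assay
fit = deming_regression(x, y, variance_ratio=1.0)
print(
    f"Deming fit: slope {fit['slope']:.3f}, intercept {fit['intercept']:.3f}, "
    f"Pearson r {fit['pearson_r']:.3f}"
)
print("(slope near 1 and intercept near 0 would indicate interchangeable TMB scales)")
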