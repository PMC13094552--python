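#!/usr/bin/env python
"""Evaluate individual and combined predictors of suction feeding.

One stratified 75/25 split; logistic models for each character, the
composite indices (CharSum, CharMean, adjusted SSI), and two
multivariate models; accuracy with Clopper-Pearson 95% CI and the exact
binomial p against the no-information rate. Writes results/battery.json.
"""

from suctionmorph.classify import run_predictor_battery
from suctionmorph.data_io import (
    AnalysisConfig,
    read_label_table,
    read_suction_matrix,
    write_report,
)
from suctionmorph.ssi import compute_ssi

matrix = read_suction_matrix("results/synthetic/suction_scores.csv")
labels = read_label_table("results/synthetic/labels.csv")
table = compute_ssi(matrix)

bat = run_predictor_battery(matrix, labels, table, AnalysisConfig(seed=1))
write_report(bat, "results/battery.json", "classify")

part = bat["partition"]
nir = next(iter(bat["reports"].values())).nir
print(f"split: {len(part.train)} train / {len(part.test)} test "
      f"({part.class_counts}); NIR = {nir:.4f}")
print(f"{'predictor':28s} {'acc':>7s} {'95% CI':>18s} {'p vs NIR':>10s}")
for name, r in bat["reports"].items():
    flag = " *" if r.p_vs_nir < 0.05 else ""
    print(f"{name:28s} {r.accuracy:7.4f} "
          f"({r.ci_low:7.4f},{r.ci_high:7.4f}) {r.p_vs_nir:10.4g}{flag}")
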