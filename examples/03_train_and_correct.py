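"""Train the correction network on a small cohort and benchmark it.

Simulates 600 samples, trains on 450 and evaluates on the 150 held out,
printing the MAE of raw vs corrected counts per purity bin. A smaller
model and fewer epochs than the package defaults keep this example quick;
expect the corrected counts to beat the raw counts most clearly at low
purity, where the caller bias is largest.
"""

import numpy as np

from snvpurify import SimulationConfig, simulate_cohort
from snvpurify import evaluate as ev
from snvpurify.features import build_feature_groups, intra_group_correlation
from snvpurify.model import ModelConfig
from snvpurify.train import TrainConfig, fit_new

cohort = simulate_cohort(SimulationConfig(n_samples=600, seed=5))
fsets = {sid: build_feature_groups(recs, cohort.tracks)
         for sid, recs in cohort.samples.items()}
truth = {t.sample_id: t for t in cohort.truths}
ids = sorted(fsets)
rng = np.random.default_rng(5)
order = rng.permutation(len(ids))
hold = sorted(ids[i] for i in order[:150])
train_ids = sorted(ids[i] for i in order[150:])

model, history = fit_new(
    [fsets[i] for i in train_ids],
    [truth[i].true_snv_count for i in train_ids],
    [truth[i].true_purity for i in train_ids],
    ModelConfig(d_model=32, n_heads=4, n_blocks=2, seed=5),
    TrainConfig(max_epochs=150, patience=150, seed=5),
)
print(f"trained for {len(history.train_loss)} epochs "
      f"(best validation epoch {history.best_epoch})\n")

report = ev.build_report(
    sample_ids=hold,
    purity=[truth[i].true_purity for i in hold],
    actual=[truth[i].true_snv_count for i in hold],
    raw=[truth[i].raw_snv_count for i in hold],
    corrected=model.predict([fsets[i] for i in hold]),
    correlations=intra_group_correlation([fsets[i] for i in hold]),
)
print(report.per_bin[["bin", "n", "MAE_raw", "MAE_corrected"]].to_string(index=False))
res = report.residual
print(f"\nresiduals (actual - corrected): mean {res.mean:.2f}, std {res.std:.2f}, "
      f"skewness {res.skewness:.2f}")
r = report.correlations["depth_vaf_stats"].loc["vaf_mean", "vaf_median"]
print(f"Pearson r(vaf_mean, vaf_median) across held-out samples: {r:.3f}")
print("\nA zero-centred, symmetric residual distribution means the correction"
      "\nis unbiased; the per-bin table shows the gain grows as purity falls.")
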