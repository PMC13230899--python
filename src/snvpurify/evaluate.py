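"""Evaluation of correction quality against ground truth.

Produces the standard benchmark views for a corrected cohort:

* per-sample trajectory table (raw vs corrected vs actual counts),
* per-purity-bin accuracy (MAE/RMSE of raw and corrected counts over the
  five bins 0.2-0.3, 0.3-0.5, 0.5-0.7, 0.7-0.8, 0.8-1.0; bins are
  left-open/right-closed so the printed labels partition (0.2, 1.0]),
* residual analysis (residual = actual - corrected; an unbiased corrector
  gives a zero-centred, symmetric residual distribution),
* purity-trend curves (mean count per purity interval for each series),
* optional figure output mirroring those views.

MAE is the primary error metric (robust and on the count scale); RMSE is
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PURITY_BIN_EDGES = (0.2, 0.3, 0.5, 0.7, 0.8, 1.0)
PURITY_BIN_LABELS = ("0.2-0.3", "0.3-0.5", "0.5-0.7", "0.7-0.8", "0.8-1.0")


@dataclass
class ResidualSummary:
    n: int
    mean: float
    std: float
    skewness: float
    frac_within_1std: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


@dataclass
class EvaluationReport:
    per_sample: pd.DataFrame      # sample_id, purity, actual, raw, corrected, residual
    per_bin: pd.DataFrame         # bin, n, MAE/RMSE raw+corrected, means
    residual: ResidualSummary
    correlations: Mapping[str, pd.DataFrame] | None = None


def compute_residuals(actual: Sequence[float], corrected: Sequence[float]) -> np.ndarray:
    """Residual = actual count - corrected count, elementwise."""
    actual = np.asarray(actual, dtype=np.float64)
    corrected = np.asarray(corrected, dtype=np.float64)
    if actual.shape != corrected.shape:
        raise ValueError(f"length mismatch: {actual.shape} vs {corrected.shape}")
    return actual - corrected


def residual_summary(residuals: Sequence[float], n_bins: int = 30) -> ResidualSummary:
    """Mean, standard deviation, adjusted Fisher-Pearson sample skewness and
    a histogram of the residuals."""
    r = np.asarray(residuals, dtype=np.float64)
    if r.size < 3:
        raise ValueError("residual summary requires at least 3 values")
    std = float(r.std(ddof=1))
    counts, edges = np.histogram(r, bins=n_bins)
    within = float(np.mean(np.abs(r - r.mean()) <= std)) if std > 0 else 1.0
    return ResidualSummary(
        n=r.size,
        mean=float(r.mean()),
        std=std,
        skewness=float(stats.skew(r, bias=False)) if std > 0 else 0.0,
        frac_within_1std=within,
        hist_counts=counts,
        hist_edges=edges,
    )


def assign_purity_bins(purity: Sequence[float]) -> pd.Categorical:
    """Left-open/right-closed binning over PURITY_BIN_EDGES; out-of-range
    purities get NaN (reported separately by binned_benchmark)."""
    return pd.cut(np.asarray(purity, dtype=np.float64),
                  bins=list(PURITY_BIN_EDGES), labels=list(PURITY_BIN_LABELS),
                  right=True, include_lowest=False)


def binned_benchmark(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Per-purity-bin error table.

    Requires columns purity, actual, raw, corrected. Empty bins keep their
    row with n=0 and NaN metrics (flagged via the ``defined`` column);
    samples outside (0.2, 1.0] are counted in ``n_out_of_range`` attrs.
    """
    df = per_sample.copy()
    df["bin"] = assign_purity_bins(df["purity"])
    rows = []
    for label in PURITY_BIN_LABELS:
        sub = df[df["bin"] == label]
        n = len(sub)
        if n:
            err_raw = np.abs(sub["raw"] - sub["actual"])
            err_cor = np.abs(sub["corrected"] - sub["actual"])
            rows.append({
                "bin": label, "n": n, "defined": True,
                "MAE_raw": float(err_raw.mean()),
                "MAE_corrected": float(err_cor.mean()),
                "RMSE_raw": float(np.sqrt((err_raw ** 2).mean())),
                "RMSE_corrected": float(np.sqrt((err_cor ** 2).mean())),
                "mean_actual": float(sub["actual"].mean()),
                "mean_raw": float(sub["raw"].mean()),
                "mean_corrected": float(sub["corrected"].mean()),
            })
        else:
            rows.append({"bin": label, "n": 0, "defined": False,
                         "MAE_raw": np.nan, "MAE_corrected": np.nan,
                         "RMSE_raw": np.nan, "RMSE_corrected": np.nan,
                         "mean_actual": np.nan, "mean_raw": np.nan,
                         "mean_corrected": np.nan})
    out = pd.DataFrame(rows)
    out.attrs["n_out_of_range"] = int(df["bin"].isna().sum())
    return out


def purity_trend(per_sample: pd.DataFrame, interval_width: float = 0.1,
                 purity_range: tuple[float, float] = (0.2, 1.0)) -> pd.DataFrame:
    """Mean raw/corrected/actual count per purity interval.

    Intervals tile ``purity_range`` with width ``interval_width``
    (left-open, right-closed); empty intervals are skipped and flagged in
    ``attrs['skipped_intervals']``.
    """
    if interval_width <= 0:
        raise ValueError("interval width must be positive")
    lo, hi = purity_range
    edges = np.arange(lo, hi + 1e-12, interval_width)
    if edges[-1] < hi:
        edges = np.append(edges, hi)
    mids, rows, skipped = [], [], []
    p = per_sample["purity"].to_numpy()
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (p > a) & (p <= b)
        mid = (a + b) / 2.0
        if not mask.any():
            skipped.append(mid)
            continue
        sub = per_sample[mask]
        rows.append({
            "midpoint": mid, "n": int(mask.sum()),
            "mean_raw": float(sub["raw"].mean()),
            "mean_corrected": float(sub["corrected"].mean()),
            "mean_actual": float(sub["actual"].mean()),
        })
    out = pd.DataFrame(rows)
    out.attrs["skipped_intervals"] = skipped
    return out


def trajectory_table(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Per-sample (raw, corrected, actual) in stable sample-id order."""
    cols = ["sample_id", "raw", "corrected", "actual"]
    return per_sample[cols].sort_values("sample_id").reset_index(drop=True)


def build_report(
    sample_ids: Sequence[str],
    purity: Sequence[float],
    actual: Sequence[float],
    raw: Sequence[float],
    corrected: Sequence[float],
    correlations: Mapping[str, pd.DataFrame] | None = None,
) -> EvaluationReport:
    """Assemble the full evaluation report from aligned per-sample vectors."""
    per_sample = pd.DataFrame({
        "sample_id": list(sample_ids),
        "purity": np.asarray(purity, dtype=np.float64),
        "actual": np.asarray(actual, dtype=np.float64),
        "raw": np.asarray(raw, dtype=np.float64),
        "corrected": np.asarray(corrected, dtype=np.float64),
    })
    per_sample["residual"] = compute_residuals(per_sample["actual"], per_sample["corrected"])
    return EvaluationReport(
        per_sample=per_sample,
        per_bin=binned_benchmark(per_sample),
        residual=residual_summary(per_sample["residual"]),
        correlations=correlations,
    )


def overall_mae(per_sample: pd.DataFrame) -> dict[str, float]:
    return {
        "MAE_raw": float(np.abs(per_sample["raw"] - per_sample["actual"]).mean()),
        "MAE_corrected": float(np.abs(per_sample["corrected"] - per_sample["actual"]).mean()),
    }


def write_report(report: EvaluationReport, out_dir: str | Path,
                 figures: bool = True) -> dict:
    """Write report tables as TSV (and figures as SVG) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    report.per_sample.to_csv(out / "per_sample.tsv", sep="\t", index=False)
    manifest["per_sample"] = str(out / "per_sample.tsv")
    report.per_bin.to_csv(out / "per_bin.tsv", sep="\t", index=False)
    manifest["per_bin"] = str(out / "per_bin.tsv")
    res = report.residual
    pd.DataFrame([{
        "n": res.n, "mean": res.mean, "std": res.std,
        "skewness": res.skewness, "frac_within_1std": res.frac_within_1std,
    }]).to_csv(out / "residual_summary.tsv", sep="\t", index=False)
    manifest["residual_summary"] = str(out / "residual_summary.tsv")
    if report.correlations:
        for g, mat in report.correlations.items():
            p = out / f"correlation_{g}.tsv"
            mat.to_csv(p, sep="\t")
            manifest[f"correlation_{g}"] = str(p)
    if figures:
        manifest.update(plot_report(report, out))
    return manifest


def plot_report(report: EvaluationReport, out_dir: str | Path) -> dict:
    """Figures: trajectories, per-bin bars, residual histogram, purity
    trend, and per-group correlation heatmaps (SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    manifest = {}

    traj = trajectory_table(report.per_sample)
    fig, ax = plt.subplots(figsize=(9, 4))
    x = np.arange(len(traj))
    ax.plot(x, traj["raw"], label="Raw", color="tab:blue", lw=0.8)
    ax.plot(x, traj["actual"], label="Actual", color="tab:green", lw=0.8)
    ax.plot(x, traj["corrected"], label="Corrected", color="tab:orange", lw=0.8)
    ax.set_xlabel("sample (id order)")
    ax.set_ylabel("SNV count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "trajectories.svg")
    plt.close(fig)
    manifest["fig_trajectories"] = str(out / "trajectories.svg")

    pb = report.per_bin[report.per_bin["defined"]]
    fig, ax = plt.subplots(figsize=(6, 4))
    pos = np.arange(len(pb))
    ax.bar(pos - 0.2, pb["MAE_raw"], width=0.4, label="Raw", color="tab:blue")
    ax.bar(pos + 0.2, pb["MAE_corrected"], width=0.4, label="Corrected", color="tab:orange")
    ax.set_xticks(pos, pb["bin"])
    ax.set_xlabel("host purity bin")
    ax.set_ylabel("MAE (counts)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "per_bin_mae.svg")
    plt.close(fig)
    manifest["fig_per_bin"] = str(out / "per_bin_mae.svg")

    res = report.residual
    fig, ax = plt.subplots(figsize=(5, 4))
    centers = (res.hist_edges[:-1] + res.hist_edges[1:]) / 2
    ax.bar(centers, res.hist_counts, width=np.diff(res.hist_edges), color="tab:gray")
    ax.axvline(0.0, color="red", ls="--")
    ax.set_xlabel("residual (actual - corrected)")
    ax.set_ylabel("frequency")
    fig.tight_layout()
    fig.savefig(out / "residual_hist.svg")
    plt.close(fig)
    manifest["fig_residuals"] = str(out / "residual_hist.svg")

    trend = purity_trend(report.per_sample)
    if len(trend):
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(trend["midpoint"], trend["mean_raw"], "-o", label="Raw", color="tab:blue")
        ax.plot(trend["midpoint"], trend["mean_corrected"], "--s",
                label="Corrected", color="tab:orange")
        ax.plot(trend["midpoint"], trend["mean_actual"], "-^", label="Actual",
                color="tab:green")
        ax.set_xlabel("host purity interval midpoint")
        ax.set_ylabel("mean SNV count")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "purity_trend.svg")
        plt.close(fig)
        manifest["fig_trend"] = str(out / "purity_trend.svg")

    if report.correlations:
        n = len(report.correlations)
        fig, axes = plt.subplots(1, n, figsize=(4 * n, 4))
        for ax, (g, mat) in zip(np.atleast_1d(axes), report.correlations.items()):
            im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="coolwarm")
            ax.set_title(g, fontsize=8)
            ax.set_xticks(range(len(mat)), mat.columns, rotation=90, fontsize=6)
            ax.set_yticks(range(len(mat)), mat.index, fontsize=6)
            fig.colorbar(im, ax=ax, shrink=0.7)
        fig.tight_layout()
        fig.savefig(out / "feature_correlations.svg")
        plt.close(fig)
        manifest["fig_correlations"] = str(out / "feature_correlations.svg")
    return manifest
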