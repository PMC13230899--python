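"""Per-sample feature extraction from variant call sets and annotation tracks.

A sample's call set (one VCF of biallelic SNVs) is summarised into five
fixed-length feature groups that feed the correction network:

* ``depth_vaf_stats`` — moments and quantiles of the VAF distribution plus
  depth statistics. VAF is highly informative about host purity: a diploid
  heterozygous host variant in a mixture of host fraction *p* has expected
  VAF of about *p*/2.
* ``purity_basic`` — a deterministic baseline purity estimate (2 x median
  VAF of heterozygous candidates) plus the raw call count.
* ``repeat_region`` / ``dnase_region`` / ``blacklist_region`` — genomic
  context: the fraction of calls falling in the corresponding annotation
  track and mean VAF inside vs. outside it, capturing mapping-artifact and
  accessibility effects on calling.

Statistics over an empty subset (e.g. no calls inside the repeat track) are
encoded as 0 together with a paired binary "subset was empty" indicator, so
the model input is always dense with a fixed width.

Coordinate conventions: VCF positions are 1-based inclusive; BED intervals
are 0-based half-open. Track membership of a variant uses its single base
position (pos - 1 in 0-based space).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
TRACK_NAMES = ("repeat", "dnase", "blacklist")

#: group name -> ordered feature names (the fixed model-input layout)
GROUP_FEATURES: dict[str, tuple[str, ...]] = {
    "depth_vaf_stats": (
        "vaf_mean", "vaf_median", "vaf_std", "vaf_q10", "vaf_q90",
        "depth_mean", "depth_median", "depth_std", "empty_indicator",
    ),
    "purity_basic": (
        "purity_estimate", "raw_snv_count", "log1p_raw_count", "fallback_indicator",
    ),
    "repeat_region": (
        "fraction_in_repeat", "mean_vaf_in_repeat", "mean_vaf_outside_repeat",
        "inside_empty_indicator", "outside_empty_indicator",
    ),
    "dnase_region": (
        "fraction_in_dnase", "mean_vaf_in_dnase", "mean_vaf_outside_dnase",
        "inside_empty_indicator", "outside_empty_indicator",
    ),
    "blacklist_region": (
        "fraction_in_blacklist", "mean_vaf_in_blacklist", "mean_vaf_outside_blacklist",
        "inside_empty_indicator", "outside_empty_indicator",
    ),
}

GROUP_NAMES: tuple[str, ...] = tuple(GROUP_FEATURES)
GROUP_DIMS: dict[str, int] = {g: len(f) for g, f in GROUP_FEATURES.items()}

#: default heterozygous-candidate VAF window for the purity estimator
HET_VAF_WINDOW = (0.02, 0.6)


@dataclass(frozen=True)
class VariantRecord:
    """One called biallelic SNV."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_count: int

    def __post_init__(self):
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.depth < 1 or not (0 <= self.alt_count <= self.depth):
            raise ValueError(
                f"invalid depth/alt_count ({self.depth}/{self.alt_count}) "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth


@dataclass
class AnnotationTrack:
    """A named set of sorted, merged, half-open genomic intervals."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.intervals = merge_intervals(self.intervals)
        # pre-build per-chromosome arrays for O(log n) membership
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in {c for c, _, _ in self.intervals}:
            ivs = [(s, e) for c, s, e in self.intervals if c == chrom]
            starts = np.array([s for s, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e in ivs], dtype=np.int64)
            self._index[chrom] = (starts, ends)

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised membership of 0-based positions; returns a bool array."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._index:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = self._index[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(positions.shape, dtype=bool)
        hit[ok] = positions[ok] < ends[idx[ok]]
        return hit

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


def merge_intervals(intervals: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals per chromosome."""
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if start >= end:
            raise ValueError(f"degenerate interval {chrom}:{start}-{end}")
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out.pop()
            out.append((chrom, prev[1], max(prev[2], end)))
        else:
            out.append((chrom, start, end))
    return out


@dataclass
class FeatureGroupSet:
    """The five named fixed-length feature vectors for one sample."""

    depth_vaf_stats: np.ndarray
    purity_basic: np.ndarray
    repeat_region: np.ndarray
    dnase_region: np.ndarray
    blacklist_region: np.ndarray

    def __post_init__(self):
        for name in GROUP_NAMES:
            vec = np.asarray(getattr(self, name), dtype=np.float64)
            if vec.shape != (GROUP_DIMS[name],):
                raise ValueError(
                    f"group {name!r} has shape {vec.shape}, expected ({GROUP_DIMS[name]},)"
                )
            setattr(self, name, vec)

    def group(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def as_flat_dict(self) -> dict[str, float]:
        """Columns namespaced ``group__feature`` in the fixed layout order."""
        out: dict[str, float] = {}
        for g in GROUP_NAMES:
            for fname, val in zip(GROUP_FEATURES[g], self.group(g)):
                out[f"{g}__{fname}"] = float(val)
        return out


# ---------------------------------------------------------------------------
# readers


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read biallelic SNVs from a VCF.

    Multiallelic lines are split into one record per alternate allele;
    non-SNV alleles are skipped (a count is logged). Depth comes from the
    per-sample ``DP`` field and alt support from ``AD``.
    """
    from cyvcf2 import VCF  # deferred: import cost and optional at pkg import

    records: list[VariantRecord] = []
    skipped = 0
    vcf = VCF(str(path))
    try:
        for v in vcf:
            try:
                dp_arr = v.format("DP")
                ad_arr = v.format("AD")
            except Exception:
                dp_arr = ad_arr = None
            if dp_arr is None or ad_arr is None:
                raise ValueError(
                    f"record {v.CHROM}:{v.POS} lacks per-sample DP/AD fields"
                )
            depth = int(dp_arr[0][0])
            ads = np.atleast_1d(ad_arr[0])
            for j, alt in enumerate(v.ALT):
                if len(v.REF) != 1 or len(alt) != 1 or v.REF not in BASES or alt not in BASES:
                    skipped += 1
                    continue
                alt_count = int(ads[j + 1]) if len(ads) > j + 1 else int(ads[0])
                records.append(
                    VariantRecord(
                        chrom=v.CHROM, pos=int(v.POS), ref=v.REF, alt=alt,
                        depth=depth, alt_count=alt_count,
                    )
                )
    finally:
        vcf.close()
    if skipped:
        logger.info("read_vcf(%s): skipped %d non-SNV allele(s)", path, skipped)
    return records


def read_bed(path: str | Path, name: str) -> AnnotationTrack:
    """Read a 3+ column BED file into a merged, sorted annotation track."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append((chrom, start, end))
    return AnnotationTrack(name=name, intervals=intervals)


# ---------------------------------------------------------------------------
# per-sample statistics


def _vafs(records: Sequence[VariantRecord]) -> np.ndarray:
    return np.array([r.alt_count / r.depth for r in records], dtype=np.float64)


def overlap_fraction(records: Sequence[VariantRecord], track: AnnotationTrack) -> float:
    """Fraction of records whose base position falls inside the track.

    Empty record lists yield 0.0 (the paired empty indicator in the feature
    group carries that information).
    """
    if not records:
        return 0.0
    hits = _track_membership(records, track)
    return float(hits.mean())


def _track_membership(records: Sequence[VariantRecord], track: AnnotationTrack) -> np.ndarray:
    hits = np.zeros(len(records), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_chrom.setdefault(r.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        pos0 = np.array([records[i].pos - 1 for i in idx], dtype=np.int64)
        hits[np.array(idx)] = track.contains(chrom, pos0)
    return hits


def vaf_depth_stats(records: Sequence[VariantRecord]) -> np.ndarray:
    """The ``depth_vaf_stats`` group vector.

    Quantiles use linear interpolation; standard deviations are the
    population form (divide by n). Empty input gives the zero vector with
    the trailing empty indicator set.
    """
    if not records:
        out = np.zeros(GROUP_DIMS["depth_vaf_stats"])
        out[-1] = 1.0
        return out
    vafs = _vafs(records)
    depths = np.array([r.depth for r in records], dtype=np.float64)
    return np.array([
        vafs.mean(),
        np.median(vafs),
        vafs.std(),
        np.quantile(vafs, 0.1),
        np.quantile(vafs, 0.9),
        depths.mean(),
        np.median(depths),
        depths.std(),
        0.0,
    ])


def estimate_purity(
    records: Sequence[VariantRecord],
    het_window: tuple[float, float] = HET_VAF_WINDOW,
) -> float:
    """Baseline host-purity estimate: 2 x median VAF of heterozygous
    candidates (VAF inside ``het_window``), clipped to [0, 1].

    With no candidates in the window the estimate falls back to 2 x median
    of all VAFs (see :func:`estimate_purity_flagged` for the fallback flag).
    """
    est, _ = estimate_purity_flagged(records, het_window)
    return est


def estimate_purity_flagged(
    records: Sequence[VariantRecord],
    het_window: tuple[float, float] = HET_VAF_WINDOW,
) -> tuple[float, bool]:
    """As :func:`estimate_purity`, also returning the fallback flag."""
    if not records:
        return 0.0, True
    vafs = _vafs(records)
    lo, hi = het_window
    in_window = vafs[(vafs >= lo) & (vafs <= hi)]
    if in_window.size:
        return float(np.clip(2.0 * np.median(in_window), 0.0, 1.0)), False
    return float(np.clip(2.0 * np.median(vafs), 0.0, 1.0)), True


def _context_group(records: Sequence[VariantRecord], track: AnnotationTrack) -> np.ndarray:
    """[fraction_in, mean_vaf_in, mean_vaf_out, in_empty, out_empty]."""
    if not records:
        return np.array([0.0, 0.0, 0.0, 1.0, 1.0])
    hits = _track_membership(records, track)
    vafs = _vafs(records)
    inside, outside = vafs[hits], vafs[~hits]
    return np.array([
        hits.mean(),
        inside.mean() if inside.size else 0.0,
        outside.mean() if outside.size else 0.0,
        0.0 if inside.size else 1.0,
        0.0 if outside.size else 1.0,
    ])


def build_feature_groups(
    records: Sequence[VariantRecord],
    tracks: Mapping[str, AnnotationTrack],
    raw_count: int | None = None,
) -> FeatureGroupSet:
    """Assemble the five feature-group vectors for one sample.

    ``raw_count`` defaults to ``len(records)``; it is exposed so a caller
    holding a caller-reported count that differs from the parsed record list
    (e.g. after multiallelic splitting) can pass it through.
    """
    missing = [t for t in TRACK_NAMES if t not in tracks]
    if missing:
        raise KeyError(f"missing annotation track(s): {missing}")
    n = len(records) if raw_count is None else int(raw_count)
    purity, fallback = estimate_purity_flagged(records)
    return FeatureGroupSet(
        depth_vaf_stats=vaf_depth_stats(records),
        purity_basic=np.array([purity, float(n), np.log1p(float(n)), float(fallback)]),
        repeat_region=_context_group(records, tracks["repeat"]),
        dnase_region=_context_group(records, tracks["dnase"]),
        blacklist_region=_context_group(records, tracks["blacklist"]),
    )


# ---------------------------------------------------------------------------
# cohort-level


def feature_table(feature_sets: Mapping[str, FeatureGroupSet]) -> pd.DataFrame:
    """One row per sample, columns namespaced ``group__feature``."""
    rows = {sid: fgs.as_flat_dict() for sid, fgs in feature_sets.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df.sort_index()


def feature_sets_from_table(df: pd.DataFrame) -> dict[str, FeatureGroupSet]:
    """Inverse of :func:`feature_table`."""
    out: dict[str, FeatureGroupSet] = {}
    for sid, row in df.iterrows():
        groups = {
            g: np.array([row[f"{g}__{f}"] for f in GROUP_FEATURES[g]])
            for g in GROUP_NAMES
        }
        out[str(sid)] = FeatureGroupSet(**groups)
    return out


def intra_group_correlation(
    feature_sets: Sequence[FeatureGroupSet] | Mapping[str, FeatureGroupSet],
) -> dict[str, pd.DataFrame]:
    """Per-group Pearson correlation matrices across a cohort.

    Matrices are exactly symmetric with unit diagonal. Constant columns make
    their correlations undefined; those entries are NaN (flagged, never
    silently zeroed), with the diagonal kept at 1.
    """
    if isinstance(feature_sets, Mapping):
        feature_sets = list(feature_sets.values())
    if len(feature_sets) < 3:
        raise ValueError("intra-group correlation requires at least 3 samples")
    out: dict[str, pd.DataFrame] = {}
    for g in GROUP_NAMES:
        mat = np.stack([fs.group(g) for fs in feature_sets])  # (n_samples, d)
        names = list(GROUP_FEATURES[g])
        constant = mat.std(axis=0) == 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(mat, rowvar=False)
        corr = np.atleast_2d(corr)
        corr[constant, :] = np.nan
        corr[:, constant] = np.nan
        corr = (corr + corr.T) / 2.0  # enforce exact symmetry
        np.fill_diagonal(corr, 1.0)
        out[g] = pd.DataFrame(corr, index=names, columns=names)
    return out
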