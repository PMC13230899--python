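"""Synthetic mixed-sample cohorts with controlled ground truth.

Each simulated sample is a host-microbiome mixture characterised by its host
purity p (fraction of sequencing material of host origin) and a strictly
controlled true SNV count. The emitted call set stands in for the output of
a conventional variant caller run on the mixture, with the purity-dependent
failure modes such callers exhibit:

* every true variant is a diploid heterozygous host SNV, so its expected VAF
  is p/2; observed VAFs are Beta-distributed around p/2 with a configurable
  concentration, then resampled binomially at the site's depth;
* sequencing depth per site follows a negative binomial (mean ``mean_depth``,
  dispersion ``depth_dispersion``), the standard overdispersed coverage model;
* false negatives: each true variant is dropped with probability interpolated
  linearly from 0 at purity 1.0 to ``fn_rate_at_min_purity`` at the low end
  of ``purity_range`` (diluted alleles fall below caller detection limits);
* false positives: spurious low-VAF records (microbial reads mis-mapped to
  the host reference, sequencing artifacts) are injected at a rate
  interpolated the same way, as a fraction of the true count.

The raw count therefore drifts away from the true count as purity falls,
with expectation  E[raw - true] = true_count * (fp(p) - fn(p)).

Everything is reproducible from ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import BASES, TRACK_NAMES, AnnotationTrack, VariantRecord

CHROM = "chrS"  # single simulated chromosome; readers accept any


class ConfigurationError(ValueError):
    """Raised for invalid simulation settings."""


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings.

    Defaults reflect the benchmark conditions: purity uniform on (0.2, 1.0),
    true counts uniform on [200, 2000], mean depth 100x, and caller noise
    reaching 40% spurious / 30% dropped calls at the lowest purity.
    """

    n_samples: int = 100
    purity_range: tuple[float, float] = (0.2, 1.0)
    true_count_range: tuple[int, int] = (200, 2000)
    mean_depth: float = 100.0
    depth_dispersion: float = 3.0
    fp_rate_at_min_purity: float = 0.4
    fn_rate_at_min_purity: float = 0.3
    vaf_concentration: float = 50.0
    fp_vaf_mean: float = 0.05
    fp_vaf_concentration: float = 20.0
    genome_length: int = 1_000_000
    annotation_density: dict[str, float] = field(
        default_factory=lambda: {"repeat": 0.15, "dnase": 0.10, "blacklist": 0.05}
    )
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(f"invalid purity_range {self.purity_range}")
        clo, chi = self.true_count_range
        if clo > chi or clo < 0:
            raise ConfigurationError(f"invalid true_count_range {self.true_count_range}")
        for nm, r in (("fp_rate_at_min_purity", self.fp_rate_at_min_purity),
                      ("fn_rate_at_min_purity", self.fn_rate_at_min_purity)):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"{nm} must lie in [0,1], got {r}")
        for nm, d in self.annotation_density.items():
            if not 0.0 <= d <= 1.0:
                raise ConfigurationError(f"annotation_density[{nm!r}] must lie in [0,1]")
        if self.n_samples < 1 or self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ConfigurationError("n_samples, mean_depth, depth_dispersion must be positive")
        # worst case every true variant kept plus as many spurious ones
        max_records = chi * 2
        if self.genome_length < max_records:
            raise ConfigurationError(
                f"genome_length {self.genome_length} smaller than maximum "
                f"plausible record count {max_records}"
            )


@dataclass(frozen=True)
class SampleTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    true_snv_count: int
    true_purity: float
    raw_snv_count: int


@dataclass
class SimulatedCohort:
    """In-memory cohort: call sets, annotation tracks and truth table."""

    samples: dict[str, list[VariantRecord]]
    tracks: dict[str, AnnotationTrack]
    truths: list[SampleTruth]
    config: SimulationConfig


def _noise_rate(purity: float, rate_at_min: float, purity_low: float) -> float:
    """Linear interpolation: 0 at purity 1.0, ``rate_at_min`` at ``purity_low``."""
    if purity_low >= 1.0:
        return 0.0
    frac = (1.0 - purity) / (1.0 - purity_low)
    return rate_at_min * float(np.clip(frac, 0.0, 1.0))


def _draw_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    # NB with mean m and size k: variance m + m^2/k
    p = dispersion / (dispersion + mean)
    return np.maximum(rng.negative_binomial(dispersion, p, size=n), 1)


def _draw_alt_counts(rng: np.random.Generator, depths: np.ndarray, vafs: np.ndarray) -> np.ndarray:
    # a reported call always has at least one supporting read
    return np.maximum(rng.binomial(depths, vafs), 1)


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def _sample_records(
    rng: np.random.Generator, config: SimulationConfig, purity: float, true_count: int
) -> tuple[list[VariantRecord], int]:
    """Emit one sample's call set; returns (records, raw_count)."""
    p_low = config.purity_range[0]
    fn = _noise_rate(purity, config.fn_rate_at_min_purity, p_low)
    fp = _noise_rate(purity, config.fp_rate_at_min_purity, p_low)

    n_dropped = rng.binomial(true_count, fn) if true_count else 0
    n_kept = true_count - n_dropped
    n_fp = rng.binomial(true_count, fp) if true_count else 0
    n_total = n_kept + n_fp

    positions = np.sort(rng.choice(config.genome_length, size=n_total, replace=False))
    order = rng.permutation(n_total)  # which sorted positions host the spurious calls
    fp_slots = np.zeros(n_total, dtype=bool)
    fp_slots[order[:n_fp]] = True

    depths = _draw_depths(rng, n_total, config.mean_depth, config.depth_dispersion)
    vafs = np.empty(n_total)
    a, b = _beta_params(max(purity / 2.0, 1e-6), config.vaf_concentration)
    vafs[~fp_slots] = rng.beta(a, b, size=n_kept)
    a_fp, b_fp = _beta_params(config.fp_vaf_mean, config.fp_vaf_concentration)
    vafs[fp_slots] = rng.beta(a_fp, b_fp, size=n_fp)
    alts = _draw_alt_counts(rng, depths, vafs)

    ref_idx = rng.integers(0, 4, size=n_total)
    alt_shift = rng.integers(1, 4, size=n_total)  # guarantees alt != ref

    records = [
        VariantRecord(
            chrom=CHROM,
            pos=int(pos) + 1,
            ref=BASES[ref_idx[i]],
            alt=BASES[(ref_idx[i] + alt_shift[i]) % 4],
            depth=int(depths[i]),
            alt_count=int(alts[i]),
        )
        for i, pos in enumerate(positions)
    ]
    return records, n_total


def simulate_annotations(config: SimulationConfig) -> dict[str, AnnotationTrack]:
    """Generate the repeat / DNase / blacklist tracks.

    Each track covers approximately its requested fraction of the genome
    with non-overlapping intervals; deterministic under the config seed.
    """
    tracks: dict[str, AnnotationTrack] = {}
    mean_len = 2000
    for k, name in enumerate(TRACK_NAMES):
        density = config.annotation_density.get(name, 0.0)
        if not 0.0 <= density <= 1.0:
            raise ConfigurationError(f"annotation density for {name!r} outside [0,1]")
        rng = np.random.default_rng([config.seed, 7001 + k])
        G = config.genome_length
        if density == 0.0:
            tracks[name] = AnnotationTrack(name=name, intervals=[])
            continue
        if density == 1.0:
            tracks[name] = AnnotationTrack(name=name, intervals=[(CHROM, 0, G)])
            continue
        covered = int(round(G * density))
        n_iv = max(1, covered // mean_len)
        # split covered bases into n_iv pieces (each >= 1) and the gap budget
        # into n_iv + 1 pieces, then interleave gap/interval/gap/...
        lengths = rng.multinomial(covered - n_iv, np.full(n_iv, 1.0 / n_iv)) + 1
        gaps = rng.multinomial(G - covered, np.full(n_iv + 1, 1.0 / (n_iv + 1)))
        intervals = []
        cursor = 0
        for i in range(n_iv):
            cursor += int(gaps[i])
            start = cursor
            cursor += int(lengths[i])
            intervals.append((CHROM, start, cursor))
        tracks[name] = AnnotationTrack(name=name, intervals=intervals)
    return tracks


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate a full cohort of call sets with ground truth.

    Per sample: purity ~ U(purity_range); true count ~ U(true_count_range);
    records generated as described in the module docstring. Purity and count
    draws are consumed before the per-sample record stream, so the truth
    table depends only on (seed, n_samples, ranges, noise rates).
    """
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.purity_range
    purities = rng.uniform(lo, hi, size=config.n_samples) if hi > lo else np.full(config.n_samples, lo)
    clo, chi = config.true_count_range
    true_counts = rng.integers(clo, chi + 1, size=config.n_samples)

    samples: dict[str, list[VariantRecord]] = {}
    truths: list[SampleTruth] = []
    width = max(4, len(str(config.n_samples - 1)))
    for i in range(config.n_samples):
        sid = f"S{i:0{width}d}"
        records, raw = _sample_records(rng, config, float(purities[i]), int(true_counts[i]))
        samples[sid] = records
        truths.append(
            SampleTruth(
                sample_id=sid,
                true_snv_count=int(true_counts[i]),
                true_purity=float(purities[i]),
                raw_snv_count=raw,
            )
        )
    tracks = simulate_annotations(config)
    return SimulatedCohort(samples=samples, tracks=tracks, truths=truths, config=config)


# ---------------------------------------------------------------------------
# serialization

VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##source=snvpurify-simulate
##contig=<ID={chrom},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""

TRUTH_COLUMNS = ("sample_id", "true_snv_count", "true_purity", "raw_snv_count")


def write_vcf(records: Sequence[VariantRecord], path: str | Path,
              sample_name: str = "SAMPLE", contig_length: int | None = None) -> None:
    """Write records as a minimal valid VCF 4.2 with GT:DP:AD per record."""
    recs = sorted(records, key=lambda r: (r.chrom, r.pos))
    length = contig_length or (max((r.pos for r in recs), default=0) + 1)
    chrom = recs[0].chrom if recs else CHROM
    with open(path, "w") as fh:
        fh.write(VCF_HEADER_TEMPLATE.format(chrom=chrom, length=length, sample=sample_name))
        for r in recs:
            ref_reads = r.depth - r.alt_count
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"GT:DP:AD\t0/1:{r.depth}:{ref_reads},{r.alt_count}\n"
            )


def write_bed(track: AnnotationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_truth_table(truths: Sequence[SampleTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            fh.write(
                f"{t.sample_id}\t{t.true_snv_count}\t{t.true_purity:.10g}\t{t.raw_snv_count}\n"
            )


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict:
    """Write one VCF per sample, one BED per track and the truth table.

    Returns a manifest dict of the written paths.
    """
    out = Path(out_dir)
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"vcf": {}, "bed": {}, "truth": str(out / "truth.tsv")}
    for sid, records in cohort.samples.items():
        path = vcf_dir / f"{sid}.vcf"
        write_vcf(records, path, sample_name=sid,
                  contig_length=cohort.config.genome_length)
        manifest["vcf"][sid] = str(path)
    for name, track in cohort.tracks.items():
        path = out / f"{name}.bed"
        write_bed(track, path)
        manifest["bed"][name] = str(path)
    write_truth_table(cohort.truths, manifest["truth"])
    return manifest


def read_truth_table(path: str | Path) -> list[SampleTruth]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth table missing column(s): {sorted(missing)}")
    return [
        SampleTruth(
            sample_id=str(r.sample_id),
            true_snv_count=int(r.true_snv_count),
            true_purity=float(r.true_purity),
            raw_snv_count=int(r.raw_snv_count),
        )
        for r in df.itertuples()
    ]


def expected_raw_minus_true(true_count: int, purity: float, config: SimulationConfig) -> float:
    """Closed-form E[raw - true] = true_count * (fp(p) - fn(p)).

    The analytic counterpart of the simulator's noise process, used as an
    independent oracle for Monte-Carlo checks.
    """
    p_low = config.purity_range[0]
    fp = _noise_rate(purity, config.fp_rate_at_min_purity, p_low)
    fn = _noise_rate(purity, config.fn_rate_at_min_purity, p_low)
    return true_count * (fp - fn)
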