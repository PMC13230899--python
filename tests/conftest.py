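import numpy as np
import pytest

from snvpurify.features import AnnotationTrack, VariantRecord
from snvpurify.simulate import SimulationConfig, simulate_cohort


def make_record(pos: int, vaf: float = 0.5, depth: int = 100,
                chrom: str = "chrS") -> VariantRecord:
    alt = max(1, int(round(vaf * depth)))
    return VariantRecord(chrom=chrom, pos=pos, ref="A", alt="C",
                         depth=depth, alt_count=alt)


@pytest.fixture
def records_factory():
    return make_record


@pytest.fixture
def empty_tracks():
    return {name: AnnotationTrack(name=name) for name in ("repeat", "dnase", "blacklist")}


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample cohort with default noise, reused by read-only tests."""
    cfg = SimulationConfig(n_samples=60, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def random_record_sets():
    """100 random (records, intervals) instances for oracle-equivalence tests."""
    rng = np.random.default_rng(2024)
    instances = []
    for _ in range(100):
        n = rng.integers(5, 60)
        recs = []
        for _ in range(n):
            depth = int(rng.integers(10, 200))
            alt = int(rng.integers(1, depth + 1))
            recs.append(VariantRecord(chrom="chrS", pos=int(rng.integers(1, 10_000)),
                                      ref="A", alt="G", depth=depth, alt_count=alt))
        n_iv = int(rng.integers(1, 30))
        ivs = []
        for _ in range(n_iv):
            s = int(rng.integers(0, 9_900))
            ivs.append(("chrS", s, s + int(rng.integers(1, 300))))
        instances.append((recs, ivs))
    return instances
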