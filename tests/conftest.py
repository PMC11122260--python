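import numpy as np
import pytest
from hypothesis import settings

from caricature import ArmDefinition, CopyNumberSegment

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def toy_arm():
    """A 10 kb q arm, small enough for per-base brute forcing."""
    return ArmDefinition("1", "q", 0, 10_000)


@pytest.fixture
def two_arm_chrom():
    return [
        ArmDefinition("1", "p", 0, 4_000),
        ArmDefinition("1", "q", 4_000, 10_000),
    ]


def random_segmentation(rng, arm, sample_id="s1", max_segments=8):
    """Non-overlapping random segments with random CN states on one arm.

    Returns internal (0-based half-open) segments; some carry minor_cn so
    CN-LOH states occur.
    """
    n = rng.integers(0, max_segments + 1)
    cuts = np.sort(rng.choice(np.arange(arm.start + 1, arm.end), size=2 * n, replace=False)) if n else []
    segments = []
    for i in range(n):
        start, end = int(cuts[2 * i]), int(cuts[2 * i + 1])
        if end <= start:
            continue
        cn = int(rng.integers(-2, 3))
        minor = int(rng.integers(0, 2)) if cn == 0 and rng.random() < 0.5 else None
        segments.append(
            CopyNumberSegment(sample_id, arm.chromosome, start, end, cn, minor)
        )
    return segments


def per_base_fractions(segments, arm):
    """Brute-force oracle: paint every base of the arm and count states."""
    gain = np.zeros(arm.length_bp, dtype=bool)
    loss = np.zeros(arm.length_bp, dtype=bool)
    cnloh = np.zeros(arm.length_bp, dtype=bool)
    for seg in segments:
        if seg.chromosome != arm.chromosome:
            continue
        lo = max(seg.start, arm.start) - arm.start
        hi = min(seg.end, arm.end) - arm.start
        if hi <= lo:
            continue
        if seg.cn_state > 0:
            gain[lo:hi] = True
        elif seg.cn_state < 0:
            loss[lo:hi] = True
        elif seg.cn_state == 0 and seg.minor_cn == 0:
            cnloh[lo:hi] = True
    n = arm.length_bp
    return gain.sum() / n, loss.sum() / n, cnloh.sum() / n
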