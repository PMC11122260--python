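"""Chromosome arms, copy-number segments, and broad-aberration calling.

Arm-level ("broad") copy-number aberrations — BCNAs — are gains or losses
covering more than 25% of a chromosome arm, or a whole chromosome; their
per-sample inventory is a *virtual karyotype*, and the count of broadly
gained/lost arms is the sample's *aneuploidy index*.

Coordinates are 0-based half-open throughout this module.  Copy-number
states are integers relative to diploid: −2, −1 (loss), 0 (neutral),
+1, +2 (gain).  Copy-neutral LOH is a cn_state-0 segment whose minor
allele copy number is 0.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

ALLOWED_CN_STATES = frozenset({-2, -1, 0, 1, 2})

#: Default fraction of an arm a gain/loss must exceed to count as broad.
DEFAULT_BROAD_THRESHOLD = 0.25

# Arm-call statuses.
BROAD_GAIN = "broad_gain"
BROAD_LOSS = "broad_loss"
BROAD_CNLOH = "broad_cnloh"
FOCAL_ONLY = "focal_only"
NEUTRAL = "neutral"


def normalize_chrom(name: str) -> str:
    """Strip a ``chr`` prefix so 'chr20' and '20' compare equal."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    return name


@dataclass(frozen=True)
class ArmDefinition:
    """One chromosome arm as a half-open genomic interval."""

    chromosome: str
    arm: str  # 'p' or 'q'
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if self.end <= self.start:
            raise ValueError(
                f"arm {self.chromosome}{self.arm}: end ({self.end}) must "
                f"exceed start ({self.start})"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chromosome}{self.arm}"


@dataclass(frozen=True)
class CopyNumberSegment:
    """A copy-number call on one genomic interval of one sample.

    ``minor_cn`` is the minor-allele copy number where allele-specific
    estimates exist; segments with ``cn_state == 0`` and ``minor_cn == 0``
    are copy-neutral LOH.
    """

    sample_id: str
    chromosome: str
    start: int
    end: int
    cn_state: int
    minor_cn: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment {self.sample_id} {self.chromosome}:"
                f"{self.start}-{self.end}: end must exceed start"
            )
        if self.cn_state not in ALLOWED_CN_STATES:
            raise ValueError(
                f"cn_state must be in {sorted(ALLOWED_CN_STATES)}, "
                f"got {self.cn_state}"
            )
        if self.minor_cn is not None and self.minor_cn < 0:
            raise ValueError(f"minor_cn must be >= 0, got {self.minor_cn}")
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))

    @property
    def is_cnloh(self) -> bool:
        return self.cn_state == 0 and self.minor_cn == 0


@dataclass(frozen=True)
class ArmCall:
    """Altered fractions and broad/focal/neutral status of one sample arm."""

    sample_id: str
    chromosome: str
    arm: str
    frac_gain: float
    frac_loss: float
    frac_cnloh: float
    status: str


@dataclass
class VirtualKaryotype:
    """Per-sample inventory of broad aberrations.

    ``entries`` are (chromosome, scope, direction) with scope 'p', 'q' or
    'w' (whole chromosome) and direction 'gain', 'loss' or 'cnloh'.  The
    aneuploidy index counts broadly gained/lost *arms* (CN-LOH excluded),
    so a whole-chromosome event on a two-arm chromosome contributes 2.
    """

    sample_id: str
    entries: list[tuple[str, str, str]] = field(default_factory=list)
    aneuploidy_index: int = 0


# ---------------------------------------------------------------------------
# Arm definitions from cytobands
# ---------------------------------------------------------------------------

def load_arm_definitions(
    cytoband_rows: Iterable[Sequence],
) -> list[ArmDefinition]:
    """Build p/q arm intervals from UCSC-style cytoband records.

    Each record carries (chrom, start, end, band_name, stain); band names
    begin with 'p' or 'q'.  Arms are contiguous unions of their bands.
    Chromosomes with only q bands (acrocentric-style input) yield a single
    q arm.  Row order in the input does not matter.

    Raises ``ValueError`` with the offending line number on malformed rows.
    """
    bands: dict[str, dict[str, list[tuple[int, int]]]] = defaultdict(
        lambda: {"p": [], "q": []}
    )
    order: list[str] = []
    for lineno, row in enumerate(cytoband_rows, start=1):
        try:
            chrom, start, end, name = row[0], int(row[1]), int(row[2]), str(row[3])
        except (IndexError, TypeError, ValueError) as exc:
            raise ValueError(f"cytoband line {lineno}: malformed row {row!r}") from exc
        if end <= start:
            raise ValueError(
                f"cytoband line {lineno}: end ({end}) must exceed start ({start})"
            )
        arm = name[:1]
        if arm not in ("p", "q"):
            raise ValueError(
                f"cytoband line {lineno}: band name {name!r} must start with p or q"
            )
        chrom = normalize_chrom(chrom)
        if chrom not in bands:
            order.append(chrom)
        bands[chrom][arm].append((start, end))

    arms: list[ArmDefinition] = []
    for chrom in order:
        chrom_arms: list[ArmDefinition] = []
        for arm in ("p", "q"):
            ivals = sorted(bands[chrom][arm])
            if not ivals:
                continue
            start, end = ivals[0][0], ivals[-1][1]
            # bands of one arm must tile it without holes
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 != e1:
                    raise ValueError(
                        f"{chrom}{arm}: bands not contiguous at {e1}..{s2}"
                    )
            chrom_arms.append(ArmDefinition(chrom, arm, start, end))
        if not chrom_arms:
            logger.warning("chromosome %s has no bands; skipped", chrom)
            continue
        if len(chrom_arms) == 2 and chrom_arms[0].end != chrom_arms[1].start:
            raise ValueError(
                f"{chrom}: p arm ends at {chrom_arms[0].end} but q arm "
                f"starts at {chrom_arms[1].start}"
            )
        arms.extend(chrom_arms)
    return arms


def arms_by_chromosome(
    arms: Iterable[ArmDefinition],
) -> dict[str, list[ArmDefinition]]:
    """Group arm definitions by chromosome, p before q."""
    out: dict[str, list[ArmDefinition]] = defaultdict(list)
    for a in arms:
        out[a.chromosome].append(a)
    for chrom in out:
        out[chrom].sort(key=lambda a: a.arm)
    return dict(out)


# ---------------------------------------------------------------------------
# Altered fractions and status calling
# ---------------------------------------------------------------------------

def _validate_sample_segments(
    segments: Sequence[CopyNumberSegment], chrom_ends: Mapping[str, int]
) -> None:
    by_chrom: dict[tuple[str, str], list[CopyNumberSegment]] = defaultdict(list)
    for seg in segments:
        if seg.chromosome in chrom_ends and seg.end > chrom_ends[seg.chromosome]:
            raise ValueError(
                f"segment {seg.sample_id} {seg.chromosome}:{seg.start}-{seg.end} "
                f"extends beyond chromosome end {chrom_ends[seg.chromosome]}"
            )
        by_chrom[(seg.sample_id, seg.chromosome)].append(seg)
    for (sample, chrom), segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping segments for sample {sample} on "
                    f"chromosome {chrom}: [{a.start},{a.end}) and "
                    f"[{b.start},{b.end})"
                )


def arm_altered_fractions(
    segments: Iterable[CopyNumberSegment], arm: ArmDefinition
) -> tuple[float, float, float]:
    """Fractions of an arm's bases that are gained, lost, or CN-LOH.

    Segments are clipped to the arm interval; arithmetic is exact per-base
    integer counting divided by the arm length.  Segments must not overlap
    within the sample (validated by the callers that see whole samples).
    """
    gain = loss = cnloh = 0
    for seg in segments:
        if normalize_chrom(seg.chromosome) != arm.chromosome:
            continue
        lo = max(seg.start, arm.start)
        hi = min(seg.end, arm.end)
        if hi <= lo:
            continue
        span = hi - lo
        if seg.cn_state > 0:
            gain += span
        elif seg.cn_state < 0:
            loss += span
        elif seg.is_cnloh:
            cnloh += span
    n = arm.length_bp
    return gain / n, loss / n, cnloh / n


def call_arm_status(
    frac_gain: float,
    frac_loss: float,
    frac_cnloh: float,
    broad_threshold: float = DEFAULT_BROAD_THRESHOLD,
) -> str:
    """Classify one arm from its altered fractions.

    The broad comparison is strict (fraction must *exceed* the threshold;
    exactly 25% altered is focal).  Should more than one fraction exceed
    the threshold, precedence is gain > loss > cnloh and the conflict is
    logged.
    """
    if not 0.0 < broad_threshold < 1.0:
        raise ValueError(
            f"broad_threshold must be in (0, 1), got {broad_threshold}"
        )
    for name, frac in (
        ("frac_gain", frac_gain),
        ("frac_loss", frac_loss),
        ("frac_cnloh", frac_cnloh),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")

    broad = [
        status
        for status, frac in (
            (BROAD_GAIN, frac_gain),
            (BROAD_LOSS, frac_loss),
            (BROAD_CNLOH, frac_cnloh),
        )
        if frac > broad_threshold
    ]
    if len(broad) > 1:
        logger.warning(
            "multiple broad statuses on one arm (%s); keeping %s by precedence",
            ", ".join(broad),
            broad[0],
        )
    if broad:
        return broad[0]
    if frac_gain > 0 or frac_loss > 0 or frac_cnloh > 0:
        return FOCAL_ONLY
    return NEUTRAL


def call_sample_arms(
    segments: Sequence[CopyNumberSegment],
    arms: Sequence[ArmDefinition],
    broad_threshold: float = DEFAULT_BROAD_THRESHOLD,
    sample_id: str | None = None,
) -> list[ArmCall]:
    """Per-arm fractions and status for one sample's segments."""
    seen = {s.sample_id for s in segments}
    if len(seen) > 1:
        raise ValueError(
            f"call_sample_arms expects one sample, got {sorted(seen)}"
        )
    if sample_id is None:
        sample_id = next(iter(seen)) if seen else ""
    elif seen and sample_id not in seen:
        raise ValueError(
            f"segments belong to {next(iter(seen))!r}, not {sample_id!r}"
        )
    chrom_ends = {
        chrom: max(a.end for a in chrom_arms)
        for chrom, chrom_arms in arms_by_chromosome(arms).items()
    }
    _validate_sample_segments(segments, chrom_ends)
    calls = []
    for arm in arms:
        fg, fl, fc = arm_altered_fractions(segments, arm)
        status = call_arm_status(fg, fl, fc, broad_threshold)
        calls.append(ArmCall(sample_id, arm.chromosome, arm.arm, fg, fl, fc, status))
    return calls


_STATUS_DIRECTION = {
    BROAD_GAIN: "gain",
    BROAD_LOSS: "loss",
    BROAD_CNLOH: "cnloh",
}


def build_virtual_karyotype(arm_calls: Sequence[ArmCall]) -> VirtualKaryotype:
    """Collapse one sample's arm calls into a virtual karyotype.

    Two arms of one chromosome broad in the same direction merge into a
    single whole-chromosome ('w') entry; a chromosome whose definition has
    only a q arm reports scope 'q' as the whole-chromosome equivalent.
    The aneuploidy index counts broadly gained/lost arms; CN-LOH entries
    are listed but not counted.
    """
    sample_ids = {c.sample_id for c in arm_calls}
    if len(sample_ids) > 1:
        raise ValueError(
            f"arm calls span multiple samples: {sorted(sample_ids)}"
        )
    sample_id = next(iter(sample_ids)) if sample_ids else ""

    by_chrom: dict[str, dict[str, ArmCall]] = defaultdict(dict)
    for call in arm_calls:
        if call.arm in by_chrom[call.chromosome]:
            raise ValueError(
                f"duplicate arm call for {call.chromosome}{call.arm}"
            )
        by_chrom[call.chromosome][call.arm] = call

    entries: list[tuple[str, str, str]] = []
    index = 0
    for chrom in by_chrom:
        directions = {
            arm: _STATUS_DIRECTION.get(call.status)
            for arm, call in by_chrom[chrom].items()
        }
        broad_arms = {a: d for a, d in directions.items() if d is not None}
        if not broad_arms:
            continue
        if (
            len(by_chrom[chrom]) == 2
            and len(broad_arms) == 2
            and len(set(broad_arms.values())) == 1
        ):
            entries.append((chrom, "w", broad_arms["p"]))
        else:
            for arm in sorted(broad_arms):
                entries.append((chrom, arm, broad_arms[arm]))
        index += sum(1 for d in broad_arms.values() if d in ("gain", "loss"))
    return VirtualKaryotype(sample_id, entries, index)


def call_karyotypes(
    segments: Sequence[CopyNumberSegment],
    arms: Sequence[ArmDefinition],
    broad_threshold: float = DEFAULT_BROAD_THRESHOLD,
    sample_ids: Sequence[str] | None = None,
) -> tuple[list[ArmCall], list[VirtualKaryotype]]:
    """Arm calls and virtual karyotypes for every sample in ``segments``.

    ``sample_ids``, when given, forces output for each listed sample even
    if it has no segments (an all-diploid genome).  Sample order of the
    output follows ``sample_ids`` or first appearance in the input;
    within a sample the calls follow the arm-definition order.
    """
    by_sample: dict[str, list[CopyNumberSegment]] = defaultdict(list)
    if sample_ids is not None:
        for sid in sample_ids:
            by_sample[sid] = []
    for seg in segments:
        if sample_ids is not None and seg.sample_id not in by_sample:
            raise ValueError(
                f"segment sample {seg.sample_id!r} not in sample_ids"
            )
        by_sample[seg.sample_id].append(seg)
    all_calls: list[ArmCall] = []
    karyotypes: list[VirtualKaryotype] = []
    for sample_id, segs in by_sample.items():
        calls = call_sample_arms(segs, arms, broad_threshold, sample_id=sample_id)
        all_calls.extend(calls)
        kt = build_virtual_karyotype(calls)
        kt.sample_id = sample_id
        karyotypes.append(kt)
    return all_calls, karyotypes
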