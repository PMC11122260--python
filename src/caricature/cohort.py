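"""Aneuploidy-stratified group design.

For a chosen target aberration (e.g. chromosome-20 gain), tumors split
into a *Selected* group bearing a matching broad aberration and a
*Control* group free of any broad aberration on that chromosome; tumors
with a non-matching broad event there are excluded from both.  Normal
mucosae form their own group and the tumor universe is the All-CRC group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genome import VirtualKaryotype, normalize_chrom

logger = logging.getLogger(__name__)

VALID_SCOPES = frozenset({"p", "q", "w"})
VALID_DIRECTIONS = frozenset({"gain", "loss", "cnloh"})


@dataclass(frozen=True)
class Target:
    """A target aberration: chromosome, accepted scopes, and direction."""

    chromosome: str
    scopes: frozenset[str]
    direction: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        object.__setattr__(self, "scopes", frozenset(self.scopes))
        if not self.scopes or not self.scopes <= VALID_SCOPES:
            raise ValueError(f"scopes must be a non-empty subset of p/q/w, got {set(self.scopes)}")
        if self.direction not in VALID_DIRECTIONS:
            raise ValueError(f"direction must be one of {sorted(VALID_DIRECTIONS)}")

    @classmethod
    def parse(cls, text: str) -> "Target":
        """Parse a ``chrom:scopes:direction`` spec, e.g. ``20:q,w:gain``."""
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(
                f"target must look like '20:q,w:gain', got {text!r}"
            )
        chrom, scopes, direction = parts
        return cls(chrom, frozenset(s.strip() for s in scopes.split(",")), direction)

    @property
    def label(self) -> str:
        return f"{self.chromosome}:{','.join(sorted(self.scopes))}:{self.direction}"


@dataclass
class CohortDesign:
    """The four analysis groups for one target aberration.

    Selected, Control and excluded partition the tumor set; normals are
    disjoint from all of them.  ``flagged`` marks a degenerate design
    (an empty Selected or Control group, which leaves FC2 undefined).
    """

    target: Target
    normal_ids: frozenset[str]
    all_crc_ids: frozenset[str]
    selected_ids: frozenset[str]
    control_ids: frozenset[str]
    excluded_ids: frozenset[str] = field(default_factory=frozenset)
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.selected_ids | self.control_ids | self.excluded_ids != self.all_crc_ids:
            raise ValueError("selected ∪ control ∪ excluded must equal all_crc")
        if self.selected_ids & self.control_ids:
            raise ValueError("selected and control must be disjoint")
        if self.normal_ids & self.all_crc_ids:
            raise ValueError("normal and tumor sample sets must be disjoint")


def assign_groups(
    karyotypes: Iterable[VirtualKaryotype],
    sample_tissue: Mapping[str, str],
    target: Target,
) -> CohortDesign:
    """Assign samples to Normal / All-CRC / Selected / Control / excluded.

    ``sample_tissue`` maps sample id to ``normal`` or ``tumor``.  A tumor
    enters Selected when its karyotype has a broad entry on the target
    chromosome with the target direction and a scope in the target's
    scope set; it enters Control when it has *no* broad entry of any
    direction (gain, loss or CN-LOH) on that chromosome; otherwise it is
    excluded.  Focal events never disqualify a Control: grouping operates
    at the broad-aberration level.  Normals never enter Selected/Control.
    """
    kt_by_sample: dict[str, VirtualKaryotype] = {}
    for kt in karyotypes:
        if kt.sample_id in kt_by_sample:
            raise ValueError(f"duplicate karyotype for sample {kt.sample_id!r}")
        kt_by_sample[kt.sample_id] = kt

    for sid in kt_by_sample:
        if sid not in sample_tissue:
            raise ValueError(f"karyotype sample {sid!r} not in sample sheet")

    normals, tumors = set(), set()
    for sid, tissue in sample_tissue.items():
        if tissue == "normal":
            normals.add(sid)
        elif tissue == "tumor":
            tumors.add(sid)
        else:
            raise ValueError(
                f"sample {sid!r}: tissue must be 'normal' or 'tumor', got {tissue!r}"
            )

    missing = sorted(t for t in tumors if t not in kt_by_sample)
    if missing:
        raise ValueError(f"tumor samples without karyotypes: {missing}")

    selected, control, excluded = set(), set(), set()
    for sid in tumors:
        on_target = [
            (scope, direction)
            for chrom, scope, direction in kt_by_sample[sid].entries
            if chrom == target.chromosome
        ]
        if any(
            direction == target.direction and scope in target.scopes
            for scope, direction in on_target
        ):
            selected.add(sid)
        elif not on_target:
            control.add(sid)
        else:
            excluded.add(sid)

    flagged = not selected or not control
    if flagged:
        logger.warning(
            "degenerate design for target %s: %d Selected, %d Control "
            "(FC2 undefined)",
            target.label,
            len(selected),
            len(control),
        )
    return CohortDesign(
        target=target,
        normal_ids=frozenset(normals),
        all_crc_ids=frozenset(tumors),
        selected_ids=frozenset(selected),
        control_ids=frozenset(control),
        excluded_ids=frozenset(excluded),
        flagged=flagged,
    )


def groups_table(design: CohortDesign) -> "list[tuple[str, str]]":
    """(sample_id, group) rows in a stable order, for the groups TSV."""
    rows = []
    for name, ids in (
        ("normal", design.normal_ids),
        ("selected", design.selected_ids),
        ("control", design.control_ids),
        ("excluded", design.excluded_ids),
    ):
        rows.extend((sid, name) for sid in sorted(ids))
    return rows
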