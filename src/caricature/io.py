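"""Readers and writers for the pipeline's tab-separated dialects.

All readers validate eagerly and raise located errors instead of
silently coercing.  Chromosome names are normalized at read time
("chr20" and "20" compare equal).  Segment files are declared 1-based
inclusive and converted to the internal 0-based half-open convention on
read; every other coordinate format is already 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .cerna import InteractionPair
from .foldchange import ThresholdConfig
from .genome import ArmDefinition, CopyNumberSegment, load_arm_definitions, normalize_chrom

logger = logging.getLogger(__name__)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a transcripts × samples log2 expression TSV.

    First column is the transcript id; remaining columns are samples.
    Duplicate transcript ids and non-numeric cells are rejected with
    their location.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: expression file has no sample columns")
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate transcript ids: {dupes}")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row {bad!r}"
            ) from None
    if out.isna().any().any():
        raise ValueError(f"{path}: missing values in expression matrix")
    return out


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="transcript_id")


def read_segments(path: str | Path) -> list[CopyNumberSegment]:
    """Read a 1-based-inclusive segment TSV into internal segments.

    Expected header: ``sample_id  chrom  start  end  cn_state[  minor_cn]``.
    Per-sample overlaps and inverted intervals are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "chrom", "start", "end", "cn_state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing segment columns: {missing}")
    if df.empty:
        logger.warning("%s: empty segment file", path)
        return []
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start1, end1 = int(row.start), int(row.end)
            cn = int(row.cn_state)
            minor = None
            if "minor_cn" in df.columns:
                raw = getattr(row, "minor_cn")
                if raw is not None and not pd.isna(raw) and str(raw).strip() != "":
                    minor = int(raw)
            seg = CopyNumberSegment(
                str(row.sample_id), str(row.chrom), start1 - 1, end1, cn, minor
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {i}: {exc}") from None
        segments.append(seg)
    _check_overlaps(segments, path)
    return segments


def _check_overlaps(segments: Sequence[CopyNumberSegment], path) -> None:
    by_key: dict[tuple[str, str], list[CopyNumberSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chromosome), []).append(seg)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{path}: overlapping segments for sample {sample} "
                    f"on chromosome {chrom} at {b.start}"
                )


def read_cytobands(path: str | Path) -> list[ArmDefinition]:
    """Read a UCSC cytoBand.txt-style file into arm definitions."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    return load_arm_definitions(rows)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet TSV (sample_id, tissue[, matched_pair_id])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "tissue"):
        if col not in df.columns:
            raise ValueError(f"{path}: sample sheet missing column {col!r}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sample ids: {dupes}")
    bad = sorted(set(df["tissue"]) - {"normal", "tumor"})
    if bad:
        raise ValueError(f"{path}: tissue must be normal/tumor, got {bad}")
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED-like transcript annotation keyed by transcript_id.

    Columns: transcript_id, chrom, start, end, strand, biotype (0-based
    half-open coordinates).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["transcript_id", "chrom", "start", "end", "biotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns: {missing}")
    dupes = df["transcript_id"][df["transcript_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate transcript ids: {dupes}")
    df = df.set_index("transcript_id")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["end"] <= df["start"]).any():
        bad = df.index[df["end"] <= df["start"]][0]
        raise ValueError(f"{path}: transcript {bad!r} has end <= start")
    return df


def read_pairs(path: str | Path) -> list[InteractionPair]:
    """Read the lncRNA–partner pair TSV (lncrna_id, partner_id, partner_kind)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["lncrna_id", "partner_id", "partner_kind"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pair columns: {missing}")
    pairs = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = (row.lncrna_id, row.partner_id)
        if key in seen:
            raise ValueError(f"{path} line {i}: duplicate pair {key}")
        seen.add(key)
        try:
            pairs.append(InteractionPair(row.lncrna_id, row.partner_id, row.partner_kind))
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from None
    return pairs


def write_arm_calls(calls, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "chrom": c.chromosome,
                "arm": c.arm,
                "frac_gain": c.frac_gain,
                "frac_loss": c.frac_loss,
                "frac_cnloh": c.frac_cnloh,
                "status": c.status,
            }
            for c in calls
        ],
        columns=[
            "sample_id", "chrom", "arm", "frac_gain", "frac_loss",
            "frac_cnloh", "status",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_karyotypes(karyotypes, path: str | Path) -> None:
    rows = []
    for kt in karyotypes:
        if not kt.entries:
            rows.append(
                {
                    "sample_id": kt.sample_id,
                    "chrom": "",
                    "scope": "",
                    "direction": "",
                    "aneuploidy_index": kt.aneuploidy_index,
                }
            )
        for chrom, scope, direction in kt.entries:
            rows.append(
                {
                    "sample_id": kt.sample_id,
                    "chrom": chrom,
                    "scope": scope,
                    "direction": direction,
                    "aneuploidy_index": kt.aneuploidy_index,
                }
            )
    pd.DataFrame(
        rows, columns=["sample_id", "chrom", "scope", "direction", "aneuploidy_index"]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Paths, thresholds and flags for one pipeline run.

    ``targets`` holds one or more ``chrom:scopes:direction`` strings; the
    pipeline runs the stratification + classification once per target.
    """

    expression: str
    segments: str
    samples: str
    cytobands: str
    targets: list[str]
    outdir: str
    annotation: str | None = None
    pairs: str | None = None
    biotype_allowlist: list[str] | None = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    broad_threshold: float = 0.25
    fdr_filter: bool = False
    include_normals_in_correlation: bool = False
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("at least one target region is required")
        for name in ("expression", "segments", "samples", "cytobands"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML config; keyword overrides win over file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = ThresholdConfig(**thr)
        return cfg
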