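"""Signed linear fold-change indices and caricature-effect classification.

Expression values are log2-scale normalized intensities (RMA-like).
Group means are taken on the log2 scale and only then exponentiated.
The signed linear fold change between a study and a control group is

    +2^(study − control)   if study > control
    −2^(control − study)   if study < control
    +1                     if equal

so |FC| ≥ 1 always and the sign carries the direction.  Four indices are
computed per transcript:

    FC1  all tumors        vs  normal mucosae
    FC2  Selected tumors   vs  Control tumors
    FC3  Control tumors    vs  normal mucosae
    FC4  Selected tumors   vs  normal mucosae

Because all four derive from the same log-scale means, the unsigned
ratios satisfy ratio4 = ratio2 · ratio3 exactly.

Classification (strict inequalities; boundary values fail):

    UpT      — up in cancer independent of the aberration:
               FC3 > 1.5 and FC4 > 1.5
    OverT    — overexpressed in aberration-bearing tumors: FC2 > 1.3
    Over-UpT — up in cancer and further potentiated by the copy-number
               gain (the "caricature" effect): FC2 > 1.3 and FC3 > 1.5

Label precedence is Over-UpT > UpT > OverT > none.  One-way ANOVA
p-values and Benjamini–Hochberg FDR are annotations, not filters, unless
FDR filtering is explicitly enabled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortDesign

logger = logging.getLogger(__name__)

CLASS_NONE = "none"
CLASS_UPT = "UpT"
CLASS_OVERT = "OverT"
CLASS_OVER_UPT = "Over-UpT"


@dataclass(frozen=True)
class ThresholdConfig:
    """Fold-change cut-offs for transcript classification.

    All fold-change thresholds are strict lower bounds on signed linear
    FCs.  ``fdr_alpha`` only annotates significance unless the caller
    enables FDR filtering.  ``require_upt`` additionally demands
    FC4 > ``upt_fc4`` for the Over-UpT label (the reading under which
    Over-UpT is a strict subset of UpT).
    """

    upt_fc3: float = 1.5
    upt_fc4: float = 1.5
    over_fc2: float = 1.3
    over_fc3: float = 1.5
    fdr_alpha: float = 0.05
    require_upt: bool = False

    def __post_init__(self) -> None:
        for name in ("upt_fc3", "upt_fc4", "over_fc2", "over_fc3"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be > 1, got {getattr(self, name)}")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError(f"fdr_alpha must be in (0, 1), got {self.fdr_alpha}")


GROUP_MEAN_COLUMNS = ("avg_normal", "avg_all_crc", "avg_selected", "avg_control")


def group_means(matrix: pd.DataFrame, design: CohortDesign) -> pd.DataFrame:
    """Arithmetic per-transcript log2 means of the four design groups.

    Returns a frame indexed like ``matrix`` with columns ``avg_normal``,
    ``avg_all_crc``, ``avg_selected``, ``avg_control``.  An empty group
    yields NaN means (flagged downstream, never silently zero).
    """
    missing = sorted(
        (design.normal_ids | design.all_crc_ids) - set(matrix.columns)
    )
    if missing:
        raise KeyError(f"design samples absent from expression matrix: {missing}")
    out = {}
    for col, ids in zip(
        GROUP_MEAN_COLUMNS,
        (design.normal_ids, design.all_crc_ids, design.selected_ids, design.control_ids),
    ):
        if ids:
            out[col] = matrix[sorted(ids)].mean(axis=1)
        else:
            logger.warning("empty group for %s; means undefined", col)
            out[col] = pd.Series(np.nan, index=matrix.index)
    return pd.DataFrame(out, index=matrix.index)


def linear_fold_change(avg_study, avg_control):
    """Signed linear fold change from two log2-scale means.

    Accepts scalars or aligned arrays; equal means return +1.0.
    Non-finite inputs raise ``ValueError``.
    """
    study = np.asarray(avg_study, dtype=float)
    control = np.asarray(avg_control, dtype=float)
    if not (np.all(np.isfinite(study)) and np.all(np.isfinite(control))):
        raise ValueError("linear_fold_change requires finite log2 means")
    delta = study - control
    fc = np.where(delta >= 0, 2.0 ** delta, -(2.0 ** (-delta)))
    if fc.ndim == 0:
        return float(fc)
    return fc


def compute_fc_indices(means: pd.DataFrame) -> pd.DataFrame:
    """FC1–FC4 and unsigned ratios from the four group means.

    Rows with any undefined (NaN) mean are flagged ``incomputable`` and
    carry NaN fold changes.
    """
    required = set(GROUP_MEAN_COLUMNS)
    if not required <= set(means.columns):
        raise KeyError(f"means must have columns {sorted(required)}")
    ok = means[list(GROUP_MEAN_COLUMNS)].notna().all(axis=1)

    out = pd.DataFrame(index=means.index)
    pairs = {
        "fc1": ("avg_all_crc", "avg_normal"),
        "fc2": ("avg_selected", "avg_control"),
        "fc3": ("avg_control", "avg_normal"),
        "fc4": ("avg_selected", "avg_normal"),
    }
    for name, (study, control) in pairs.items():
        vals = np.full(len(means), np.nan)
        if ok.any():
            vals[ok.to_numpy()] = linear_fold_change(
                means.loc[ok, study].to_numpy(), means.loc[ok, control].to_numpy()
            )
        out[name] = vals
    for name in ("fc2", "fc3", "fc4"):
        study, control = pairs[name]
        out["ratio" + name[-1]] = 2.0 ** (means[study] - means[control])
    out["incomputable"] = ~ok
    return out


def classify_transcript(
    fc2: float, fc3: float, fc4: float, thresholds: ThresholdConfig | None = None
) -> str:
    """Class label from the signed fold-change indices.

    Comparisons are strict and on signed values, so negative fold changes
    never pass.  Incomputable (NaN) records label ``none``.
    """
    t = thresholds or ThresholdConfig()
    if any(not np.isfinite(v) for v in (fc2, fc3, fc4)):
        return CLASS_NONE
    over_upt = fc2 > t.over_fc2 and fc3 > t.over_fc3
    if over_upt and t.require_upt:
        over_upt = fc3 > t.upt_fc3 and fc4 > t.upt_fc4
    if over_upt:
        return CLASS_OVER_UPT
    if fc3 > t.upt_fc3 and fc4 > t.upt_fc4:
        return CLASS_UPT
    if fc2 > t.over_fc2:
        return CLASS_OVERT
    return CLASS_NONE


def anova_pvalue(groups: Sequence[Sequence[float]]) -> float:
    """One-way fixed-effects ANOVA p-value across ≥2 groups.

    Degenerate input in which every value is identical (zero between- and
    within-group variance) reports p = 1.0 with a log flag rather than
    NaN.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("anova_pvalue needs at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs >= 2 members for a within-group variance")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        logger.debug("degenerate ANOVA input (all values identical); p := 1.0")
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.f_oneway(*arrays)
    if not np.isfinite(p):  # zero within-group variance but distinct means
        return 0.0
    return float(p)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def qpcr_relative_expression(ct_target: float, ct_ref: float) -> float:
    """Relative expression from qPCR cycle thresholds, reported as 1/ΔCt.

    ΔCt is the target Ct minus the reference-gene (e.g. ACTB) Ct.  A zero
    ΔCt is undefined; a negative ΔCt (target more abundant than the
    reference) is returned with a warning.
    """
    if ct_target <= 0 or ct_ref <= 0:
        raise ValueError("Ct values must be positive")
    delta = ct_target - ct_ref
    if delta == 0:
        raise ZeroDivisionError("ΔCt is zero; 1/ΔCt undefined")
    if delta < 0:
        logger.warning(
            "negative ΔCt (%.3f): target amplifies before the reference", delta
        )
    return 1.0 / delta


def classify_matrix(
    matrix: pd.DataFrame,
    design: CohortDesign,
    thresholds: ThresholdConfig | None = None,
    annotation: pd.DataFrame | None = None,
    biotype_allowlist: Sequence[str] | None = None,
    fdr_filter: bool = False,
) -> pd.DataFrame:
    """Full per-transcript fold-change and classification table.

    ``annotation``, when given, is indexed by transcript id with at least
    ``chrom``/``start``/``end``/``biotype`` columns; a biotype allow-list
    (e.g. ``["lncRNA"]``) restricts classification to those transcripts
    before anything else.  The ANOVA compares the normal, Control and
    Selected groups.  With ``fdr_filter`` enabled, transcripts whose BH
    FDR exceeds ``thresholds.fdr_alpha`` are demoted to ``none``.
    """
    t = thresholds or ThresholdConfig()
    if annotation is not None and biotype_allowlist is not None:
        keep = annotation.index[annotation["biotype"].isin(biotype_allowlist)]
        matrix = matrix.loc[matrix.index.intersection(keep)]

    means = group_means(matrix, design)
    fc = compute_fc_indices(means)
    result = pd.concat([means, fc], axis=1)

    groups = [
        sorted(ids)
        for ids in (design.normal_ids, design.control_ids, design.selected_ids)
        if len(ids) >= 2
    ]
    if len(groups) >= 2:
        values = [matrix[g].to_numpy() for g in groups]
        result["p_value"] = [
            anova_pvalue([v[i] for v in values]) for i in range(len(matrix))
        ]
        result["fdr"] = bh_adjust(result["p_value"])
    else:
        logger.warning("fewer than two groups with >= 2 samples; no ANOVA annotation")
        result["p_value"] = np.nan
        result["fdr"] = np.nan

    result["class_label"] = [
        classify_transcript(r.fc2, r.fc3, r.fc4, t) for r in result.itertuples()
    ]
    if fdr_filter:
        demote = result["fdr"].isna() | (result["fdr"] > t.fdr_alpha)
        result.loc[demote, "class_label"] = CLASS_NONE

    if annotation is not None:
        for col in ("chrom", "arm", "start", "end", "biotype"):
            if col in annotation.columns:
                result[col] = annotation[col].reindex(result.index)
    result.index.name = "transcript_id"
    return result
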