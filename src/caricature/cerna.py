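"""Sponge-consistency correlation screen.

A lncRNA acting as a competing endogenous RNA (ceRNA) sequesters miRNAs
through shared response elements, which predicts a *negative* Pearson
correlation between the lncRNA and its pri-miRNA partners across tumor
samples.  A proliferation-linked lncRNA instead predicts a *positive*
correlation with proliferation marker transcripts (e.g. CCND1, PCNA).
The screen evaluates pre-computed interaction pairs — target prediction
itself happens upstream and is consumed as an input file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .foldchange import anova_pvalue, linear_fold_change

logger = logging.getLogger(__name__)

PARTNER_KINDS = frozenset({"pri_mirna", "marker"})

SPONGE_CONSISTENT = "sponge_consistent"
PROLIFERATION_CONSISTENT = "proliferation_consistent"
INCONSISTENT = "inconsistent"
INDETERMINATE = "indeterminate"
ERROR = "error"


@dataclass(frozen=True)
class InteractionPair:
    """A candidate lncRNA–partner pair with the partner's role."""

    lncrna_id: str
    partner_id: str
    partner_kind: str

    def __post_init__(self) -> None:
        if self.partner_kind not in PARTNER_KINDS:
            raise ValueError(
                f"partner_kind must be one of {sorted(PARTNER_KINDS)}, "
                f"got {self.partner_kind!r}"
            )


@dataclass(frozen=True)
class CorrelationResult:
    pair: InteractionPair
    r: float
    p_value: float
    n: int
    consistency: str


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value.

    The p-value comes from the t transform of r with n − 2 degrees of
    freedom.  Series must have equal length ≥ 3 and non-zero variance;
    violations raise ``ValueError`` rather than propagating NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def label_consistency(partner_kind: str, r: float, p: float, alpha: float) -> str:
    """Consistency label from the partner role, sign of r, and significance.

    pri-miRNA partners: significant negative r is sponge-consistent.
    Marker partners: significant positive r is proliferation-consistent.
    A significant wrong-sign correlation is inconsistent; anything
    non-significant is indeterminate.
    """
    if partner_kind not in PARTNER_KINDS:
        raise ValueError(f"unknown partner_kind {partner_kind!r}")
    if p >= alpha:
        return INDETERMINATE
    if partner_kind == "pri_mirna":
        return SPONGE_CONSISTENT if r < 0 else INCONSISTENT
    return PROLIFERATION_CONSISTENT if r > 0 else INCONSISTENT


def sponge_screen(
    matrix: pd.DataFrame,
    pairs: Iterable[InteractionPair],
    tumor_ids: Sequence[str],
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Correlate every pair across tumor samples and label consistency.

    An unresolvable transcript id (or a degenerate, zero-variance series)
    yields a result with status ``error``/``indeterminate`` and the run
    continues.  Correlations default to tumor samples only; pass a wider
    id list to include normals.
    """
    cols = sorted(set(tumor_ids))
    missing = sorted(set(cols) - set(matrix.columns))
    if missing:
        raise KeyError(f"tumor samples absent from expression matrix: {missing}")
    if len(cols) < 3:
        raise ValueError("need at least 3 samples for the correlation screen")

    results = []
    for pair in pairs:
        if pair.lncrna_id not in matrix.index or pair.partner_id not in matrix.index:
            logger.warning(
                "pair (%s, %s): id not in expression matrix; skipped",
                pair.lncrna_id,
                pair.partner_id,
            )
            results.append(CorrelationResult(pair, np.nan, np.nan, len(cols), ERROR))
            continue
        x = matrix.loc[pair.lncrna_id, cols].to_numpy(dtype=float)
        y = matrix.loc[pair.partner_id, cols].to_numpy(dtype=float)
        try:
            r, p = pearson(x, y)
        except ValueError:
            results.append(
                CorrelationResult(pair, np.nan, np.nan, len(cols), INDETERMINATE)
            )
            continue
        results.append(
            CorrelationResult(
                pair, r, p, len(cols), label_consistency(pair.partner_kind, r, p, alpha)
            )
        )
    return results


def correlation_table(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    """Flatten screen results for the output TSV."""
    rows = [
        {
            "lncrna_id": res.pair.lncrna_id,
            "partner_id": res.pair.partner_id,
            "partner_kind": res.pair.partner_kind,
            "r": res.r,
            "p_value": res.p_value,
            "n": res.n,
            "consistency": res.consistency,
        }
        for res in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "lncrna_id", "partner_id", "partner_kind", "r", "p_value", "n",
            "consistency",
        ],
    )


def group_difference_report(
    matrix: pd.DataFrame,
    partner_ids: Sequence[str],
    normal_ids: Sequence[str],
    tumor_ids: Sequence[str],
) -> pd.DataFrame:
    """Tumor-vs-normal fold change and ANOVA p for partner transcripts.

    Reuses the signed linear fold-change and one-way ANOVA machinery to
    report whether each partner (e.g. a pri-miRNA) is under- or
    over-expressed in tumors relative to normal mucosae.
    """
    normals = sorted(set(normal_ids))
    tumors = sorted(set(tumor_ids))
    if not normals or not tumors:
        raise ValueError("both normal and tumor sets must be non-empty")
    rows = []
    for tid in partner_ids:
        if tid not in matrix.index:
            raise KeyError(f"transcript {tid!r} not in expression matrix")
        nvals = matrix.loc[tid, normals].to_numpy(dtype=float)
        tvals = matrix.loc[tid, tumors].to_numpy(dtype=float)
        fc = linear_fold_change(tvals.mean(), nvals.mean())
        p = (
            anova_pvalue([tvals, nvals])
            if len(nvals) >= 2 and len(tvals) >= 2
            else np.nan
        )
        rows.append({"transcript_id": tid, "fc_tumor_vs_normal": fc, "p_value": p})
    return pd.DataFrame(rows).set_index("transcript_id")
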