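"""Group comparison and classification performance.

Welch's unequal-variance two-sample t-test (two-sided), Benjamini–
Hochberg step-up adjustment across the family of contrasts emitted by one
:func:`compare_groups` call, and ROC-AUC as the Mann–Whitney probability
that a positive sample out-scores a negative one (ties count 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, ValidationError
from .io import NA_TOKEN, CompositeScoreSet


def welch_t(a, b) -> tuple[float, float]:
    """Welch's two-sample t (unpaired, unequal variance); returns (t, p) two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise DegenerateDataError("both groups have zero variance; p undefined")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def roc_auc(
    scores,
    labels,
    positive_label=None,
    orientation_free: bool = False,
) -> float:
    """ROC-AUC of score-based separation of two classes.

    Equals the probability that a random positive sample has a higher score
    than a random negative one, ties counted 1/2.  With
    ``orientation_free=True`` the reported value is ``max(auc, 1 − auc)``
    (separation quality regardless of score direction).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes.size}")
    if positive_label is None:
        positive_label = classes[1]
    y = (labels == positive_label).astype(int)
    if y.sum() in (0, y.size):
        raise ValidationError(f"positive label {positive_label!r} not among the classes")
    auc = float(roc_auc_score(y, scores))
    return max(auc, 1.0 - auc) if orientation_free else auc


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group contrast on composite scores."""

    contrast_id: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    p_adjusted: float
    auc: float

    def to_dict(self) -> dict:
        return asdict(self)


def _apply_stratum(annotations: pd.DataFrame, strata: Mapping[str, str] | None) -> pd.DataFrame:
    if not strata:
        return annotations
    out = annotations
    for col, val in strata.items():
        if col not in out.columns:
            raise ValidationError(f"unknown stratum field {col!r}")
        out = out[out[col].astype(str) == str(val)]
        if out.empty:
            raise ValidationError(f"stratum {col}={val} leaves no samples")
    return out


def compare_groups(
    scores: CompositeScoreSet | pd.Series,
    annotations: pd.DataFrame,
    grouping_field: str,
    contrasts: Sequence[tuple[str, str]],
    strata: Mapping[str, str] | None = None,
    orientation_free: bool = False,
) -> list[ComparisonResult]:
    """Welch test + ROC-AUC for each (group_a, group_b) contrast.

    ``annotations`` is indexed by sample id; ``strata`` optionally restricts
    all contrasts to samples matching ``{field: value}``.  BH adjustment is
    applied across the family of contrasts emitted by this one call.  The
    AUC's positive class is ``group_b`` (so AUC > 0.5 means group_b scores
    higher, i.e. more tolerant).
    """
    s = scores.scores if isinstance(scores, CompositeScoreSet) else scores
    if grouping_field not in annotations.columns:
        raise ValidationError(f"unknown grouping field {grouping_field!r}")
    ann = _apply_stratum(annotations, strata)
    ann = ann[ann.index.isin(s.index)]
    results: list[ComparisonResult] = []
    for ga, gb in contrasts:
        ids_a = ann.index[ann[grouping_field].astype(str) == str(ga)]
        ids_b = ann.index[ann[grouping_field].astype(str) == str(gb)]
        if len(ids_a) == 0 or len(ids_b) == 0:
            raise ValidationError(
                f"contrast {ga}:{gb} on {grouping_field!r}: empty group after filtering"
            )
        a = s.loc[ids_a].to_numpy(dtype=float)
        b = s.loc[ids_b].to_numpy(dtype=float)
        t, p = welch_t(a, b)
        auc = roc_auc(
            np.concatenate([a, b]),
            np.array([ga] * len(a) + [gb] * len(b)),
            positive_label=gb,
            orientation_free=orientation_free,
        )
        stratum_tag = (
            "|" + ",".join(f"{k}={v}" for k, v in strata.items()) if strata else ""
        )
        results.append(
            ComparisonResult(
                contrast_id=f"{ga}_vs_{gb}{stratum_tag}",
                group_a=str(ga),
                group_b=str(gb),
                n_a=len(a),
                n_b=len(b),
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                t_statistic=t,
                p_value=p,
                p_adjusted=np.nan,
                auc=auc,
            )
        )
    adj = bh_adjust([r.p_value for r in results])
    return [
        ComparisonResult(**{**r.to_dict(), "p_adjusted": float(q)})
        for r, q in zip(results, adj)
    ]
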