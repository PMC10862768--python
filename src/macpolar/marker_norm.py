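"""Marker-gene abundance normalization of composite scores.

Bulk samples contain varying numbers of macrophages, and every
macrophage-programme gene — hence the composite score — rises and falls
with that abundance.  A universal macrophage marker (FCER1G by default)
tracks abundance directly, so regressing it out of the score removes the
confound while leaving the polarization signal.

The procedure, per sample with marker expression ``x`` and composite
score ``y``:

1. within each sample-type group compute the bounding-box statistics
   ``S1`` (range of scores), ``S2`` (range of marker expression),
   ``S3`` (mean score), ``S4`` (mean marker expression);
2. shift each sample,

       ``x′ = x − S3·(S2 + 1)/(S1 + 1)``
       ``y′ = y + S4·(S1 + 1)/(S2 + 1)``

   (the ``+1`` guards keep the ratios finite when a group's range
   degenerates to zero);
3. fit one ordinary-least-squares trend ``y′ = m·x′ + c`` pooled over all
   samples and take the residual ``y′ − (m·x′ + c)`` as the final
   normalized score; samples are then re-ranked.

Which group's statistics feed step 2 is controlled by ``stats_mode``:

* ``"reference"`` (default) — one bounding box, from the reference group
  (lexicographically first unless ``reference_group`` is given), is used
  for every sample.  The shifts are then global constants, so the final
  scores equal the plain OLS residuals of score on marker: the
  abundance-mediated component of any group difference is removed exactly,
  while marker-independent (true polarization) differences survive.
* ``"own"`` — each sample is shifted by its own group's statistics.  This
  injects group-level offsets proportional to the group's mean marker
  expression into ``y′``; when abundance differs between groups those
  offsets re-introduce (and can amplify) the very confound the procedure
  is meant to remove, so this mode is provided for comparison only.

Because the final scores are OLS residuals they have mean zero and zero
sample covariance with ``x′`` exactly (to floating point).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateDataError, ValidationError
from .io import CompositeScoreSet, gene_index, rank_scores

DEFAULT_MARKER = "FCER1G"


@dataclass(frozen=True)
class GroupStats:
    """Bounding-box statistics of one sample-type group."""

    s1: float  # range of composite scores
    s2: float  # range of marker expression
    s3: float  # mean composite score
    s4: float  # mean marker expression


@dataclass(frozen=True)
class NormalizationResult:
    marker_gene: str
    x: pd.Series  # raw marker expression per sample
    y: pd.Series  # raw composite score per sample
    group_stats: Mapping[str, GroupStats]
    groups: pd.Series
    x_prime: pd.Series
    y_prime: pd.Series
    slope: float
    intercept: float
    final_scores: pd.Series
    ranks: pd.Series = field(repr=False, default=None)


def group_stats(
    scores: pd.Series, marker_values: pd.Series, groups: pd.Series
) -> dict[str, GroupStats]:
    """Per-group (S1, S2, S3, S4); every sample must belong to a ≥2-sample group."""
    missing = [s for s in scores.index if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without a group assignment: {missing[:5]}")
    out: dict[str, GroupStats] = {}
    for grp, members in groups.loc[scores.index].groupby(groups.loc[scores.index]):
        ids = members.index
        if len(ids) < 2:
            raise DegenerateDataError(
                f"group {grp!r} has a single sample; its range is degenerate"
            )
        y = scores.loc[ids].to_numpy(dtype=float)
        x = marker_values.loc[ids].to_numpy(dtype=float)
        out[str(grp)] = GroupStats(
            s1=float(y.max() - y.min()),
            s2=float(x.max() - x.min()),
            s3=float(y.mean()),
            s4=float(x.mean()),
        )
    return out


def _minmax(v: pd.Series) -> pd.Series:
    span = float(v.max() - v.min())
    if span == 0:
        return v * 0.0
    return (v - float(v.min())) / span


def normalize_marker(
    scores: CompositeScoreSet | pd.Series,
    matrix: pd.DataFrame,
    groups: pd.Series,
    marker_gene: str = DEFAULT_MARKER,
    prescale: bool = False,
    stats_mode: str = "reference",
    reference_group: str | None = None,
) -> NormalizationResult:
    """Detrend composite scores against a macrophage marker gene.

    Parameters
    ----------
    scores : CompositeScoreSet or Series
        Raw composite scores per sample (``y``).
    matrix : DataFrame
        Genes × samples log-expression matrix containing ``marker_gene``.
    groups : Series
        Sample → sample-type group label (e.g. BPD vs noBPD); the
        bounding-box statistics are computed within each group.
    marker_gene : str
        Marker symbol, matched case-insensitively.
    prescale : bool
        Min–max scale marker and score to [0, 1] over all samples before
        the group transform (alternative reading of the procedure; off by
        default — the transform is applied to the raw values).
    stats_mode : {"reference", "own"}
        Whose bounding-box statistics shift each sample (see module
        docstring); "reference" is the mode that actually removes the
        abundance confound.
    reference_group : str, optional
        Reference group for ``stats_mode="reference"``; defaults to the
        lexicographically first group label.
    """
    y = scores.scores if isinstance(scores, CompositeScoreSet) else scores
    y = y.astype(float)
    idx = gene_index(matrix)
    key = marker_gene.strip().upper()
    if key not in idx:
        raise ValidationError(f"marker gene {marker_gene!r} not in the expression matrix")
    x = matrix.loc[idx[key], y.index].astype(float)
    if x.isna().any():
        raise ValidationError(f"marker gene {marker_gene!r} has missing values")

    x_used, y_used = (_minmax(x), _minmax(y)) if prescale else (x, y)
    stats = group_stats(y_used, x_used, groups)

    g = groups.loc[y.index].astype(str)
    if stats_mode == "reference":
        ref = reference_group if reference_group is not None else sorted(stats)[0]
        if ref not in stats:
            raise ValidationError(f"reference group {ref!r} not among {sorted(stats)}")
        stats_of = {k: stats[ref] for k in stats}
    elif stats_mode == "own":
        stats_of = dict(stats)
    else:
        raise ValidationError(f"stats_mode must be 'reference' or 'own', got {stats_mode!r}")
    offset_x = g.map(lambda k: stats_of[k].s3 * (stats_of[k].s2 + 1) / (stats_of[k].s1 + 1))
    offset_y = g.map(lambda k: stats_of[k].s4 * (stats_of[k].s1 + 1) / (stats_of[k].s2 + 1))
    x_prime = x_used - offset_x
    y_prime = y_used + offset_y

    xp = x_prime.to_numpy(dtype=float)
    yp = y_prime.to_numpy(dtype=float)
    if float(np.ptp(xp)) < 1e-12:
        raise DegenerateDataError(
            "transformed marker values are constant; the trend y' = m·x' + c is "
            "undefined — check that the marker gene varies across samples"
        )
    m, c = np.polyfit(xp, yp, 1)
    final = y_prime - (m * x_prime + c)
    final.name = "score"
    return NormalizationResult(
        marker_gene=marker_gene,
        x=x,
        y=y,
        group_stats=stats,
        groups=g,
        x_prime=x_prime,
        y_prime=y_prime,
        slope=float(m),
        intercept=float(c),
        final_scores=final,
        ranks=rank_scores(final),
    )


def rank_after_normalization(result: NormalizationResult) -> list[str]:
    """Sample ids ordered by ascending final score, ties by sample id."""
    return sorted(result.final_scores.index, key=lambda s: (result.final_scores[s], str(s)))


def as_score_set(result: NormalizationResult, path_id: str) -> CompositeScoreSet:
    return CompositeScoreSet(
        path_id=f"{path_id}|{result.marker_gene}-normalized",
        scores=result.final_scores,
        ranks=result.ranks,
    )


class MarkerDetrendNormalizer(BaseEstimator):
    """Estimator wrapper around :func:`normalize_marker`.

    ``fit(scores, marker=matrix, groups=groups)`` computes the group
    statistics and the pooled OLS trend; ``transform`` (argument-free on the
    fitted data) returns the final normalized scores.
    """

    def __init__(
        self,
        marker_gene: str = DEFAULT_MARKER,
        prescale: bool = False,
        stats_mode: str = "reference",
        reference_group: str | None = None,
    ):
        self.marker_gene = marker_gene
        self.prescale = prescale
        self.stats_mode = stats_mode
        self.reference_group = reference_group

    def fit(self, scores, matrix: pd.DataFrame, groups: pd.Series):
        self.result_ = normalize_marker(
            scores,
            matrix,
            groups,
            marker_gene=self.marker_gene,
            prescale=self.prescale,
            stats_mode=self.stats_mode,
            reference_group=self.reference_group,
        )
        self.slope_ = self.result_.slope
        self.intercept_ = self.result_.intercept
        self.group_stats_ = dict(self.result_.group_stats)
        return self

    def transform(self, X=None) -> pd.Series:
        check_is_fitted(self, "result_")
        return self.result_.final_scores

    def fit_transform(self, scores, matrix, groups) -> pd.Series:
        return self.fit(scores, matrix, groups).transform()
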