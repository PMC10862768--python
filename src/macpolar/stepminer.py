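"""StepMiner one-step threshold fitting.

Each gene's expression values, sorted ascending, are fit with a one-step
function: a split into a low and a high segment, each summarised by its
mean, chosen to minimise the total within-segment sum of squared errors.
The threshold SThr is the midpoint of the two segment means and is the
centring constant of the modified Z-score used throughout scoring.

Conventions fixed here (the step-fit itself is classical, but details
matter for reproducibility):

* exhaustive scan over every admissible split ``s ∈ {1..n−1}``;
* among splits whose SSE ties within 1e−12 relative, the smallest split
  index wins;
* ``stddev`` is the population (ddof=0) standard deviation of all values;
* genes with ``stddev < 1e−12`` are flagged degenerate and excluded from
  scoring rather than dividing by zero;
* genes with ≥20% missing values are excluded from fitting entirely;
  remaining NAs are dropped pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEGENERATE_TOL = 1e-12
#: genes missing at least this fraction of samples are not fit
MAX_MISSING_FRACTION = 0.2


@dataclass(frozen=True)
class StepThreshold:
    """Result of the one-step least-squares fit for a single gene."""

    gene_id: str
    sthr: float
    low_mean: float
    high_mean: float
    split_index: int  # number of values in the low segment
    sse: float
    stddev: float
    degenerate: bool = False


def fit_step_threshold(values, gene_id: str = "") -> StepThreshold:
    """Fit the one-step function to ``values`` and return its threshold.

    Values are sorted ascending; for every split ``s`` the SSE is the sum of
    squared deviations of each segment from its own mean; the minimising
    split defines ``low_mean``/``high_mean`` and ``sthr`` is their midpoint.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValidationError(f"need at least 2 finite values, got {v.size}")
    if not np.isfinite(v).all():
        raise ValidationError("values must be finite")
    v = np.sort(v)
    n = v.size
    stddev = float(v.std(ddof=0))

    # SSE(s) = Σv² − s·mean_low² − (n−s)·mean_high², via prefix sums
    csum = np.cumsum(v)
    csq = np.cumsum(v * v)
    total, total_sq = csum[-1], csq[-1]
    s = np.arange(1, n)
    low_sum = csum[:-1]
    high_sum = total - low_sum
    sse = (total_sq - low_sum**2 / s - high_sum**2 / (n - s))
    sse = np.maximum(sse, 0.0)  # clamp tiny negative round-off

    best = float(sse.min())
    scale = max(best, 1.0)
    split = int(s[np.nonzero(sse <= best + DEGENERATE_TOL * scale)[0][0]])

    low_mean = float(csum[split - 1] / split)
    high_mean = float((total - csum[split - 1]) / (n - split))
    return StepThreshold(
        gene_id=gene_id,
        sthr=(low_mean + high_mean) / 2.0,
        low_mean=low_mean,
        high_mean=high_mean,
        split_index=split,
        sse=float(sse[split - 1]),
        stddev=stddev,
        degenerate=stddev < DEGENERATE_TOL,
    )


def thresholds_for_matrix(
    matrix: pd.DataFrame,
) -> tuple[dict[str, StepThreshold], list[tuple[str, str]]]:
    """Fit a :class:`StepThreshold` per gene of a genes × samples matrix.

    Returns ``(thresholds, exclusions)`` where ``exclusions`` lists
    ``(gene_id, reason)`` pairs, reason ∈ {constant, too_missing, too_few}.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValidationError("empty expression matrix")
    thresholds: dict[str, StepThreshold] = {}
    exclusions: list[tuple[str, str]] = []
    values = matrix.to_numpy(dtype=float)
    for i, gene in enumerate(matrix.index):
        row = values[i]
        n_missing = int(np.isnan(row).sum())
        if n_missing / row.size >= MAX_MISSING_FRACTION:
            exclusions.append((str(gene), "too_missing"))
            continue
        finite = row[~np.isnan(row)]
        if finite.size < 2:
            exclusions.append((str(gene), "too_few"))
            continue
        fit = fit_step_threshold(finite, gene_id=str(gene))
        if fit.degenerate:
            exclusions.append((str(gene), "constant"))
            continue
        thresholds[str(gene)] = fit
    if exclusions:
        logger.warning("excluded %d genes from threshold fitting", len(exclusions))
    return thresholds, exclusions


def write_exclusion_report(exclusions: list[tuple[str, str]], path) -> None:
    pd.DataFrame(exclusions, columns=["gene_id", "reason"]).to_csv(
        path, sep="\t", index=False
    )


class StepMinerNormalizer(TransformerMixin, BaseEstimator):
    """Modified Z-score transformer centred on per-gene StepMiner thresholds.

    Follows the scikit-learn transformer contract with ``X`` of shape
    ``(n_samples, n_genes)``.  ``fit`` learns one :class:`StepThreshold` per
    gene; ``transform`` maps each cell to

        ``z = (expr − SThr − 0.5) / (3 · stddev)``

    so that a value half a unit above the step is 0 and each further
    3-standard-deviation excursion adds 1.  Degenerate or too-missing genes
    are dropped from the transformed output and listed in ``exclusions_``.
    """

    def __init__(self, max_missing_fraction: float = MAX_MISSING_FRACTION):
        self.max_missing_fraction = max_missing_fraction

    def fit(self, X, y=None):
        X = self._as_frame(X)
        thr, excl = thresholds_for_matrix(X.T)
        self.thresholds_ = thr
        self.exclusions_ = excl
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.retained_genes_ = [g for g in X.columns if str(g) in thr]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "thresholds_")
        X = self._as_frame(X)
        missing = [g for g in self.retained_genes_ if g not in X.columns]
        if missing:
            raise ValidationError(f"matrix lacks fitted genes: {missing[:5]}")
        out = {}
        for g in self.retained_genes_:
            t = self.thresholds_[str(g)]
            out[g] = (X[g].to_numpy(dtype=float) - t.sthr - 0.5) / (3.0 * t.stddev)
        return pd.DataFrame(out, index=X.index)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "thresholds_")
        return np.asarray(self.retained_genes_, dtype=object)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-dimensional (n_samples, n_genes)")
        return pd.DataFrame(X, columns=[f"g{i}" for i in range(X.shape[1])])
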