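"""Boolean-path composite polarization scores.

The score places each sample on the reactive ↔ tolerant macrophage axis:
expression is mapped to a modified Z-score centred on the per-gene
StepMiner threshold, the normalized values are averaged within each gene
cluster of the Boolean path, and the cluster averages are linearly
combined with the path's monotone weights.  For the full path
C13 → C14 → C3 the weights are (−1, 1, 2): reactive-programme (C13)
genes pull the score down, tolerance-programme genes (C14, and more
strongly C3) pull it up, so low scores mean reactive, high scores mean
tolerant.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError
from .io import BooleanPath, CompositeScoreSet, GeneCluster, gene_index, rank_scores
from .stepminer import StepMinerNormalizer, StepThreshold

#: weights of the named paths, induced from the full-path triple
#: (−1 for C13, 1 for C14, 2 for C3).
PATH_SPECS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "C13": (("C13",), (-1.0,)),
    "C14-3": (("C14", "C3"), (1.0, 2.0)),
    "C13-14-3": (("C13", "C14", "C3"), (-1.0, 1.0, 2.0)),
}


def normalize_modified_z(
    matrix: pd.DataFrame, thresholds: Mapping[str, StepThreshold]
) -> pd.DataFrame:
    """Apply ``(expr − SThr − 0.5)/(3·stddev)`` per gene of a genes × samples frame.

    Only genes with a threshold appear in the output; a retained gene missing
    from ``thresholds`` raises.  NA cells propagate.
    """
    rows = {}
    for gene in matrix.index:
        key = str(gene)
        if key not in thresholds:
            raise ValidationError(f"no StepMiner threshold for gene {key!r}")
        t = thresholds[key]
        if t.stddev <= 0:
            raise ValidationError(f"gene {key!r} has zero dispersion; exclude it instead")
        rows[gene] = (matrix.loc[gene].to_numpy(dtype=float) - t.sthr - 0.5) / (
            3.0 * t.stddev
        )
    return pd.DataFrame(rows, index=matrix.columns).T


def cluster_average(norm: pd.DataFrame, cluster: GeneCluster) -> pd.Series:
    """Per-sample mean of the cluster's genes present in the normalized matrix.

    Gene symbols match case-insensitively after trimming; NA cells are
    dropped per sample (pairwise deletion).
    """
    idx = gene_index(norm)
    present = [idx[g.strip().upper()] for g in cluster.genes if g.strip().upper() in idx]
    if not present:
        raise ValidationError(
            f"cluster {cluster.cluster_id!r}: none of its {len(cluster.genes)} genes "
            f"are in the matrix (missing e.g. {list(cluster.genes)[:5]})"
        )
    sub = norm.loc[present]
    avg = pd.Series(np.nanmean(sub.to_numpy(dtype=float), axis=0), index=norm.columns)
    return avg


def composite_score(norm: pd.DataFrame, path: BooleanPath) -> CompositeScoreSet:
    """Weighted linear combination of the path's cluster averages.

    ``score_s = Σ_k weight_k · mean(normalized values of cluster k in sample s)``;
    samples are ranked ascending (1 = lowest = most reactive), ties broken by
    sample id.
    """
    comps = pd.DataFrame(
        {c.cluster_id: cluster_average(norm, c) for c in path.clusters}
    ).T  # clusters × samples
    scores = pd.Series(0.0, index=norm.columns, name="score")
    for w, c in zip(path.weights, path.clusters):
        scores = scores + w * comps.loc[c.cluster_id]
    scores.name = "score"
    return CompositeScoreSet(
        path_id=path.path_id,
        scores=scores,
        ranks=rank_scores(scores),
        component_averages=comps,
    )


def resolve_path(
    clusters: Sequence[GeneCluster],
    path_spec: str,
    weights: Sequence[float] | None = None,
) -> BooleanPath:
    """Build a :class:`BooleanPath` from a named spec over the given clusters.

    Cluster ids are matched ignoring case and an optional ``#`` (so C13,
    c13 and C#13 are the same cluster).
    """
    if path_spec not in PATH_SPECS:
        raise ValidationError(
            f"unknown path spec {path_spec!r}; known: {sorted(PATH_SPECS)}"
        )
    wanted_ids, default_w = PATH_SPECS[path_spec]
    by_id = {c.cluster_id.upper().replace("#", ""): c for c in clusters}
    missing = [cid for cid in wanted_ids if cid.upper() not in by_id]
    if missing:
        raise ValidationError(f"path {path_spec!r} needs clusters {missing} not provided")
    w = tuple(float(x) for x in weights) if weights is not None else default_w
    return BooleanPath(
        path_id=path_spec,
        clusters=tuple(by_id[cid.upper()] for cid in wanted_ids),
        weights=w,
    )


def score_matrix(
    matrix: pd.DataFrame,
    clusters: Sequence[GeneCluster],
    path_spec: str = "C13-14-3",
    weights: Sequence[float] | None = None,
) -> CompositeScoreSet:
    """Convenience composition: thresholds → modified Z → composite score."""
    path = resolve_path(clusters, path_spec, weights)
    scorer = BooleanPathScorer(clusters=list(clusters), path_spec=path_spec, weights=weights)
    scores = scorer.fit(matrix.T).score_samples(matrix.T)
    comps = scorer.component_averages(matrix.T)
    return CompositeScoreSet(
        path_id=path.path_id,
        scores=scores,
        ranks=rank_scores(scores),
        component_averages=comps,
    )


class BooleanPathScorer(BaseEstimator):
    """Scikit-learn style estimator producing Boolean-path composite scores.

    Parameters
    ----------
    clusters : list of GeneCluster
        The gene clusters referenced by ``path_spec``.
    path_spec : {"C13", "C14-3", "C13-14-3"}
        Which composite to compute.
    weights : sequence of float, optional
        Override the path's default monotone weights.

    ``X`` is ``(n_samples, n_genes)`` with gene names as columns (a
    DataFrame).  ``fit`` learns the per-gene StepMiner thresholds;
    ``score_samples``/``transform`` return the per-sample composite score.
    """

    def __init__(self, clusters=None, path_spec: str = "C13-14-3", weights=None):
        self.clusters = clusters
        self.path_spec = path_spec
        self.weights = weights

    def fit(self, X, y=None):
        if self.clusters is None:
            raise ValidationError("BooleanPathScorer requires cluster definitions")
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("X must be a DataFrame with gene-name columns")
        self.path_ = resolve_path(self.clusters, self.path_spec, self.weights)
        self.normalizer_ = StepMinerNormalizer().fit(X)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def score_samples(self, X) -> pd.Series:
        check_is_fitted(self, "path_")
        norm = self.normalizer_.transform(X).T  # genes × samples
        return composite_score(norm, self.path_).scores

    def component_averages(self, X) -> pd.DataFrame:
        check_is_fitted(self, "path_")
        norm = self.normalizer_.transform(X).T
        return composite_score(norm, self.path_).component_averages

    def transform(self, X):
        return self.score_samples(X).to_numpy(dtype=float).reshape(-1, 1)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
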