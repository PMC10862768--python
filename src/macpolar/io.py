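"""Readers and writers for every on-disk artifact.

Dialects are fixed and small:

* expression matrix — TSV, first header cell ``gene_id`` then sample ids,
  one row per gene, cells numeric or the literal ``NA``;
* gene clusters — JSON object ``{cluster_id: [gene, ...]}``;
* sample annotations — TSV with the fixed header
  ``sample_id  placental_domain  preterm_labor  monocyte_subset  timepoint
  bpd  treatment``;
* composite scores — TSV ``sample_id  score  rank``.

All floats are written with ``repr`` so a write→read round trip is
bit-exact.  Parsing is total: malformed input raises :class:`ParseError`
naming the line, never a partial object.  Gene symbols are matched
case-insensitively after trimming whitespace (no alias mapping).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

#: fixed annotation header and the vocabulary of each categorical field.
ANNOTATION_COLUMNS = (
    "sample_id",
    "placental_domain",
    "preterm_labor",
    "monocyte_subset",
    "timepoint",
    "bpd",
    "treatment",
)

ANNOTATION_VOCAB: dict[str, frozenset[str]] = {
    "placental_domain": frozenset({"PID", "PVD", "none"}),
    "preterm_labor": frozenset({"yes", "no"}),
    "monocyte_subset": frozenset({"classical", "intermediate", "nonclassical"}),
    "timepoint": frozenset("ABCDEFGHIJ"),
    "bpd": frozenset({"BPD", "noBPD"}),
    "treatment": frozenset({"control", "LPS"}),
}


@dataclass(frozen=True)
class GeneCluster:
    """A named set of gene symbols (one node of the Boolean-implication path)."""

    cluster_id: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"cluster {self.cluster_id!r} has an empty gene list")
        keys = [g.strip().upper() for g in self.genes]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(
                f"cluster {self.cluster_id!r} lists duplicate genes: {', '.join(dupes)}"
            )


@dataclass(frozen=True)
class BooleanPath:
    """Ordered clusters with strictly monotone weights.

    The weight sequence encodes the logical order of the Boolean-implication
    path (e.g. the reactive→tolerant axis C13 → C14 → C3 with weights
    −1, 1, 2); a non-monotone sequence would scramble the sample ordering the
    score is meant to induce.
    """

    path_id: str
    clusters: tuple[GeneCluster, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ValidationError("a Boolean path needs at least one cluster")
        if len(self.clusters) != len(self.weights):
            raise ValidationError(
                f"path {self.path_id!r}: {len(self.clusters)} clusters but "
                f"{len(self.weights)} weights"
            )
        w = self.weights
        if len(w) > 1:
            diffs = [b - a for a, b in zip(w, w[1:])]
            if not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
                raise ValidationError(
                    f"path {self.path_id!r}: weights {w} are not strictly monotone"
                )


@dataclass(frozen=True)
class CompositeScoreSet:
    """Per-sample composite polarization scores with their rank order.

    ``ranks`` assigns 1 to the lowest (most reactive) score; ties are broken
    by sample id.  ``component_averages`` holds the per-cluster mean of
    normalized values (clusters × samples) that the weighted score combines.
    """

    path_id: str
    scores: pd.Series
    ranks: pd.Series
    component_averages: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if len(self.scores) == 0:
            raise ValidationError("empty score set")
        if sorted(self.ranks.tolist()) != list(range(1, len(self.scores) + 1)):
            raise ValidationError("ranks must be a permutation of 1..n_samples")


def rank_scores(scores: pd.Series) -> pd.Series:
    """Ascending ranks (1 = lowest score); ties broken lexicographically by sample id."""
    order = sorted(scores.index, key=lambda s: (scores[s], str(s)))
    return pd.Series({s: i + 1 for i, s in enumerate(order)}, name="rank").reindex(
        scores.index
    )


# ---------------------------------------------------------------------------
# expression matrices


def validate_expression_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Check the ExpressionMatrix invariants on a genes × samples frame."""
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError("expression matrix must have at least one gene and one sample")
    genes = [str(g).strip() for g in df.index]
    keys = [g.upper() for g in genes]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate gene symbols: {', '.join(dupes)}")
    samples = [str(s) for s in df.columns]
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicate sample ids in expression matrix")
    values = df.to_numpy(dtype=float)
    if np.isinf(values).any():
        raise ValidationError("expression matrix contains non-finite (inf) values")
    out = pd.DataFrame(values, index=genes, columns=samples)
    return out


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples TSV into a float DataFrame (NaN for ``NA``)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 2 or header[0].strip().lower() not in {"gene_id", "gene", "symbol"}:
            raise ParseError(
                f"{path}:1: malformed header — expected 'gene_id' then sample ids, "
                f"got {header[:3]!r}"
            )
        samples = [s.strip() for s in header[1:]]
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: ragged row — {len(row)} cells, expected {len(header)}"
                )
            genes.append(row[0].strip())
            vals = []
            for col, cell in enumerate(row[1:], start=2):
                cell = cell.strip()
                if cell == NA_TOKEN:
                    vals.append(math.nan)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in column {col}"
                    ) from None
            rows.append(vals)
    if not genes:
        raise ParseError(f"{path}: no gene rows")
    try:
        return validate_expression_matrix(pd.DataFrame(rows, index=genes, columns=samples))
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from None


def _fmt(v: float) -> str:
    return NA_TOKEN if (isinstance(v, float) and math.isnan(v)) else repr(float(v))


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a genes × samples frame in the TSV dialect ``read_expression_matrix`` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(str(s) for s in df.columns) + "\n")
        for gene, row in df.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# clusters


def read_clusters(path: str | Path) -> list[GeneCluster]:
    """Read a JSON ``{cluster_id: [gene, ...]}`` object, preserving file order."""
    path = Path(path)
    try:
        with path.open(encoding="utf-8") as fh:
            raw = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}:{exc.lineno}: invalid JSON — {exc.msg}") from None
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: top level must be an object mapping cluster_id → genes")
    clusters = []
    for cid, genes in raw.items():
        if not isinstance(genes, list) or not all(isinstance(g, str) for g in genes):
            raise ValidationError(f"cluster {cid!r}: genes must be a list of strings")
        clusters.append(GeneCluster(str(cid), tuple(genes)))
    if not clusters:
        raise ValidationError(f"{path}: no clusters defined")
    return clusters


def write_clusters(clusters: Sequence[GeneCluster], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump({c.cluster_id: list(c.genes) for c in clusters}, fh, indent=1)
        fh.write("\n")


def default_clusters() -> list[GeneCluster]:
    """The packaged cluster definition (synthetic stand-in gene lists whose
    symbols match the synthetic cohort generator's vocabulary)."""
    return read_clusters(Path(__file__).parent / "data" / "smart_clusters_synthetic.json")


# ---------------------------------------------------------------------------
# annotations


def validate_annotation(df: pd.DataFrame, where: str = "<annotation>") -> pd.DataFrame:
    if list(df.columns) != list(ANNOTATION_COLUMNS):
        raise ParseError(
            f"{where}: header must be exactly {list(ANNOTATION_COLUMNS)}, got {list(df.columns)}"
        )
    ids = df["sample_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValidationError(f"{where}: duplicate sample ids: {', '.join(dupes)}")
    for rowno, (_, row) in enumerate(df.iterrows(), start=2):
        for col, vocab in ANNOTATION_VOCAB.items():
            tok = str(row[col])
            if tok != NA_TOKEN and tok not in vocab:
                raise ValidationError(
                    f"{where}:{rowno}: unknown token {tok!r} in column {col!r} "
                    f"(allowed: {sorted(vocab)} or {NA_TOKEN})"
                )
    return df.astype(str).set_index(df["sample_id"].astype(str)).drop(columns=["sample_id"])


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read sample annotations; returns a frame indexed by sample_id."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return validate_annotation(df, where=str(path))


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    out = df.reset_index(names="sample_id")[list(ANNOTATION_COLUMNS)]
    out.to_csv(path, sep="\t", index=False)


def align_annotation(df: pd.DataFrame, sample_ids: Iterable[str]) -> pd.DataFrame:
    """Reindex annotations onto the matrix's samples; unannotated samples get
    all-NA labels with a logged warning."""
    sample_ids = [str(s) for s in sample_ids]
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        logger.warning(
            "%d samples lack annotations and were assigned all-NA labels: %s",
            len(missing), ", ".join(missing[:10]),
        )
    return df.reindex(sample_ids, fill_value=NA_TOKEN)


# ---------------------------------------------------------------------------
# score tables


def write_scores(scores: CompositeScoreSet, path: str | Path) -> None:
    """Write a TSV with columns sample_id, score, rank (repr floats round-trip)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tscore\trank\n")
        for sid in scores.scores.index:
            fh.write(f"{sid}\t{_fmt(scores.scores[sid])}\t{int(scores.ranks[sid])}\n")


def read_scores(path: str | Path, path_id: str = "unknown") -> CompositeScoreSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
    if list(df.columns) != ["sample_id", "score", "rank"]:
        raise ParseError(f"{path}: expected header sample_id/score/rank, got {list(df.columns)}")
    if df.empty:
        raise ValidationError(f"{path}: empty score table")
    scores = pd.Series(df["score"].to_numpy(float), index=df["sample_id"], name="score")
    ranks = pd.Series(df["rank"].to_numpy(int), index=df["sample_id"], name="rank")
    return CompositeScoreSet(path_id=path_id, scores=scores, ranks=ranks)


def gene_index(df: pd.DataFrame) -> Mapping[str, str]:
    """Case-insensitive lookup from trimmed upper-case symbol to matrix row label."""
    return {str(g).strip().upper(): g for g in df.index}
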