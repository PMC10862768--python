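"""Configuration-driven end-to-end runs.

``run_analysis`` wires the stages together — read → StepMiner thresholds →
composite score → optional marker detrend → stratified contrasts — and
writes every artifact (score tables, normalization sidecar, plots with
their underlying data, a machine-readable report).  Data artifacts are
byte-identical across reruns on identical inputs: the report carries no
timestamps and all JSON is written with sorted keys.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns

from . import __version__, io, marker_norm, scoring, stats, stepminer
from .errors import MacpolarError, ValidationError

logger = logging.getLogger(__name__)

MAX_PLOT_GROUPS = 12


@dataclass(frozen=True)
class ContrastSpec:
    field: str
    group_a: str
    group_b: str
    strata: Mapping[str, str] | None = None


@dataclass(frozen=True)
class RunConfig:
    expression: Path
    annotation: Path
    clusters: Path | None  # None → packaged default
    out_dir: Path
    path_spec: str = "C13-14-3"
    weights: Sequence[float] | None = None
    marker_normalize: bool = False
    marker_gene: str = marker_norm.DEFAULT_MARKER
    marker_grouping_field: str = "bpd"
    contrasts: Sequence[ContrastSpec] = ()
    plot_grouping_field: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = json.load(fh)
        contrasts = tuple(
            ContrastSpec(
                field=c["field"],
                group_a=c["a"],
                group_b=c["b"],
                strata=c.get("where"),
            )
            for c in raw.get("contrasts", [])
        )
        cfg = cls(
            expression=Path(raw["expression"]),
            annotation=Path(raw["annotation"]),
            clusters=Path(raw["clusters"]) if raw.get("clusters") else None,
            out_dir=Path(raw["out_dir"]),
            path_spec=raw.get("path_spec", "C13-14-3"),
            weights=raw.get("weights"),
            marker_normalize=bool(raw.get("marker_normalize", False)),
            marker_gene=raw.get("marker_gene", marker_norm.DEFAULT_MARKER),
            marker_grouping_field=raw.get("marker_grouping_field", "bpd"),
            contrasts=contrasts,
            plot_grouping_field=raw.get("plot_grouping_field"),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
        )
        for p in (cfg.expression, cfg.annotation, cfg.clusters):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"configured input does not exist: {p}")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def render_ranked_barplot(
    scores: io.CompositeScoreSet,
    annotations: pd.DataFrame,
    grouping_field: str,
    out_path: str | Path,
) -> dict[str, str]:
    """Rank-ordered color-coded bar plot plus a violin+swarm panel.

    Writes vector (SVG) and raster (PNG) renderings and a sidecar JSON with
    the exact data behind the figure (tests assert on the data, not pixels).
    Returns the artifact paths.
    """
    out_path = Path(out_path)
    if grouping_field not in annotations.columns:
        raise ValidationError(f"unknown grouping field {grouping_field!r}")
    ann = io.align_annotation(annotations, scores.scores.index)
    groups = ann[grouping_field].astype(str)
    levels = sorted(groups.unique())
    if len(levels) > MAX_PLOT_GROUPS:
        raise ValidationError(f"{len(levels)} groups exceed the palette limit of {MAX_PLOT_GROUPS}")
    if any((groups == lv).sum() == 0 for lv in levels):
        raise ValidationError("empty group after filtering")

    order = sorted(scores.scores.index, key=lambda s: scores.ranks[s])
    data = pd.DataFrame(
        {
            "sample_id": order,
            "rank": [int(scores.ranks[s]) for s in order],
            "score": [float(scores.scores[s]) for s in order],
            "group": [groups[s] for s in order],
        }
    )
    palette = dict(zip(levels, sns.color_palette("colorblind", n_colors=len(levels))))

    fig, (ax_bar, ax_violin) = plt.subplots(
        2, 1, figsize=(max(6, len(order) * 0.12), 6), height_ratios=[1, 1.4]
    )
    ax_bar.bar(
        data["rank"], data["score"], color=[palette[g] for g in data["group"]], width=0.9
    )
    ax_bar.set_xlabel(f"rank (composite score, {scores.path_id})")
    ax_bar.set_ylabel("score")
    handles = [plt.Rectangle((0, 0), 1, 1, color=palette[lv]) for lv in levels]
    ax_bar.legend(handles, levels, fontsize=8)
    sns.violinplot(
        data=data, x="group", y="score", hue="group", order=levels, palette=palette,
        inner=None, cut=0, ax=ax_violin, legend=False,
    )
    sns.swarmplot(data=data, x="group", y="score", order=levels, color="k", size=2.5, ax=ax_violin)
    fig.tight_layout()

    png = out_path.with_suffix(".png")
    svg = out_path.with_suffix(".svg")
    sidecar = out_path.with_suffix(".json")
    fig.savefig(png, dpi=150)
    fig.savefig(svg)
    plt.close(fig)
    with sidecar.open("w", encoding="utf-8") as fh:
        json.dump(
            {
                "grouping_field": grouping_field,
                "path_id": scores.path_id,
                "groups": levels,
                "samples": data.to_dict(orient="records"),
            },
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    return {"png": str(png), "svg": str(svg), "data": str(sidecar)}


def run_analysis(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns (and writes) the run report."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "io"
    try:
        matrix = io.read_expression_matrix(config.expression)
        annotations = io.read_annotation(config.annotation)
        annotations = io.align_annotation(annotations, matrix.columns)
        clusters = (
            io.read_clusters(config.clusters) if config.clusters else io.default_clusters()
        )
        logger.info("io: %d genes × %d samples", *matrix.shape)

        stage = "stepminer"
        thresholds, exclusions = stepminer.thresholds_for_matrix(matrix)
        excl_path = out / "threshold_exclusions.tsv"
        stepminer.write_exclusion_report(exclusions, excl_path)

        stage = "scoring"
        retained = matrix.loc[[g for g in matrix.index if str(g) in thresholds]]
        norm = scoring.normalize_modified_z(retained, thresholds)
        path = scoring.resolve_path(clusters, config.path_spec, config.weights)
        score_set = scoring.composite_score(norm, path)
        scores_path = out / "scores.tsv"
        io.write_scores(score_set, scores_path)

        norm_stats: dict[str, Any] | None = None
        final_scores = score_set
        if config.marker_normalize:
            stage = "marker_norm"
            groups = annotations[config.marker_grouping_field].astype(str)
            result = marker_norm.normalize_marker(
                score_set, matrix, groups, marker_gene=config.marker_gene
            )
            final_scores = marker_norm.as_score_set(result, score_set.path_id)
            io.write_scores(final_scores, out / "scores_normalized.tsv")
            norm_stats = {
                "marker_gene": result.marker_gene,
                "grouping_field": config.marker_grouping_field,
                "slope": result.slope,
                "intercept": result.intercept,
                "group_stats": {
                    g: {"S1": s.s1, "S2": s.s2, "S3": s.s3, "S4": s.s4}
                    for g, s in result.group_stats.items()
                },
            }
            with (out / "normalization.json").open("w", encoding="utf-8") as fh:
                json.dump(norm_stats, fh, indent=1, sort_keys=True)
                fh.write("\n")

        stage = "stats_eval"
        comparisons: list[stats.ComparisonResult] = []
        for spec in config.contrasts:
            comparisons.extend(
                stats.compare_groups(
                    final_scores,
                    annotations,
                    spec.field,
                    [(spec.group_a, spec.group_b)],
                    strata=spec.strata,
                )
            )

        stage = "plots"
        plots: dict[str, str] = {}
        plot_field = config.plot_grouping_field or (
            config.contrasts[0].field if config.contrasts else None
        )
        if plot_field:
            plots = render_ranked_barplot(
                final_scores, annotations, plot_field, out / "ranked_scores"
            )

        stage = "report"
        report: dict[str, Any] = {
            "version": __version__,
            "config": {
                "expression": str(config.expression),
                "annotation": str(config.annotation),
                "clusters": str(config.clusters) if config.clusters else "packaged-default",
                "path_spec": config.path_spec,
                "weights": list(path.weights),
                "marker_normalize": config.marker_normalize,
                "marker_gene": config.marker_gene if config.marker_normalize else None,
                "seed": config.seed,
            },
            "input_checksums": {
                "expression": _sha256(config.expression),
                "annotation": _sha256(config.annotation),
            },
            "artifacts": {
                "exclusions": str(excl_path),
                "scores": str(scores_path),
                "scores_normalized": str(out / "scores_normalized.tsv")
                if config.marker_normalize
                else None,
                **plots,
            },
            "n_genes": int(matrix.shape[0]),
            "n_samples": int(matrix.shape[1]),
            "n_excluded_genes": len(exclusions),
            "normalization": norm_stats,
            "comparisons": [c.to_dict() for c in comparisons],
            "bh_family": {"m": len(comparisons), "method": "fdr_bh"},
        }
        for key, p in list(report["artifacts"].items()):
            if p is not None and not Path(p).exists():
                raise MacpolarError(f"claimed artifact missing on disk: {p}")
        report_path = out / "report.json"
        with report_path.open("w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
        return report
    except MacpolarError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
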