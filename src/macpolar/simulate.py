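"""Synthetic cohort generator.

Emulates the statistical structure of the bulk cohorts the scoring
pipeline targets: three gene clusters (C13 reactive-programme; C14 and C3
tolerance-programme) whose means shift monotonically along the
polarization axis, background genes, and a macrophage-abundance nuisance
variable — each sample has a macrophage fraction ``f`` drawn log-uniform,
and ``log f`` shifts every macrophage-programme gene plus the marker gene
FCER1G, which tracks it with low noise.  Values are additive Gaussian on
a log-expression scale (the scoring math is threshold/Z-score based, so
count-level realism would add nothing testable).

Generative model for gene g in sample s with planted state z_s and
fraction f_s:

* C13:        baseline + δ·[z_s = reactive]      + κ·log f_s + ε
* C14:        baseline + δ·[z_s = tolerant]      + κ·log f_s + ε
* C3:         baseline + 1.5·δ·[z_s = tolerant]  + κ·log f_s + ε
* background: baseline + ε
* FCER1G:     baseline + κ·log f_s + ε_marker   (ε_marker low-noise)

with ε ~ N(0, noise_sd²).  The ×1.5 scaling of the C3 shift encodes the
path ordering (C3 sits after C14 with the larger weight) so that planted
monotonicity along the Boolean path is meaningful.

Everything is deterministic under ``seed`` (numpy PCG64 via
``default_rng``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ANNOTATION_COLUMNS, NA_TOKEN

REACTIVE = "reactive"
TOLERANT = "tolerant"

#: how a planted state shows up in the categorical annotation fields
#: (reactive ↔ preterm labor / inflammatory placenta; tolerant ↔ BPD /
#: vascular placenta — the direction of the associations the score is
#: designed to detect).
_STATE_LABELS = {
    REACTIVE: {"placental_domain": "PID", "preterm_labor": "yes", "bpd": "noBPD"},
    TOLERANT: {"placental_domain": "PVD", "preterm_labor": "no", "bpd": "BPD"},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the simulated cohort.

    Defaults are the conditions the pipeline's evaluation experiments use:
    two 30-sample groups, 20-gene clusters, a planted polarization shift of
    two noise standard deviations, and a macrophage fraction between 5% and
    50% whose logarithm couples into every macrophage-programme gene with
    unit slope.
    """

    seed: int = 0
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {REACTIVE: 30, TOLERANT: 30}
    )
    cluster_sizes: tuple[int, int, int] = (20, 20, 20)
    n_background: int = 100
    polarization_effect: float = 1.0  # δ, log-expression units
    macrophage_fraction: tuple[float, float] = (0.05, 0.5)  # log-uniform bounds on f
    marker_coupling: float = 1.0  # κ, slope of log f into programme genes
    noise_sd: float = 0.5
    marker_noise_sd: float = 0.05
    baseline_mean: float = 6.0

    def __post_init__(self) -> None:
        if not self.n_per_group:
            raise ValidationError("n_per_group must name at least one group")
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValidationError("group sizes must be positive")
        if any(k <= 0 for k in self.cluster_sizes) or len(self.cluster_sizes) != 3:
            raise ValidationError("cluster_sizes must be three positive integers")
        if self.n_background < 0:
            raise ValidationError("n_background must be ≥ 0")
        if self.polarization_effect < 0:
            raise ValidationError("polarization_effect must be ≥ 0")
        if self.noise_sd <= 0 or self.marker_noise_sd <= 0:
            raise ValidationError("noise standard deviations must be > 0")
        lo, hi = self.macrophage_fraction
        if not (0 < lo <= hi):
            raise ValidationError("macrophage_fraction bounds must satisfy 0 < lo ≤ hi")

    def gene_names(self) -> dict[str, list[str]]:
        n13, n14, n3 = self.cluster_sizes
        return {
            "C13": [f"C13_{i:03d}" for i in range(1, n13 + 1)],
            "C14": [f"C14_{i:03d}" for i in range(1, n14 + 1)],
            "C3": [f"C3_{i:03d}" for i in range(1, n3 + 1)],
        }


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for parameter-recovery experiments."""

    states: Mapping[str, str]  # sample → reactive/tolerant
    fractions: Mapping[str, float]  # sample → macrophage fraction f
    group: Mapping[str, str]  # sample → group label
    config: SyntheticConfig
    confound_strength: float = 0.0


def _state_of_group(label: str) -> str:
    if label in (REACTIVE, TOLERANT):
        return label
    # clinical-style labels map through the planted associations
    for state, fields in _STATE_LABELS.items():
        if label in fields.values():
            return state
    raise ValidationError(
        f"cannot infer a planted state for group label {label!r}; "
        f"use 'reactive'/'tolerant' or one of the clinical labels"
    )


def _annotation_rows(sample_ids, states) -> pd.DataFrame:
    rows = []
    for sid in sample_ids:
        lab = _STATE_LABELS[states[sid]]
        rows.append(
            {
                "sample_id": sid,
                "placental_domain": lab["placental_domain"],
                "preterm_labor": lab["preterm_labor"],
                "monocyte_subset": "classical",
                "timepoint": "A",
                "bpd": lab["bpd"],
                "treatment": "control",
            }
        )
    df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    return df.set_index("sample_id")


def _simulate(
    config: SyntheticConfig, logf_shift_per_group: Mapping[str, float]
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    rng = np.random.default_rng(config.seed)
    groups = list(config.n_per_group)
    sample_ids, group_of, state_of = [], {}, {}
    for grp in groups:
        for _ in range(config.n_per_group[grp]):
            sid = f"S{len(sample_ids) + 1:03d}"
            sample_ids.append(sid)
            group_of[sid] = grp
            state_of[sid] = _state_of_group(grp)

    lo, hi = config.macrophage_fraction
    logf = rng.uniform(math.log(lo), math.log(hi), size=len(sample_ids))
    logf = logf + np.array([logf_shift_per_group.get(group_of[s], 0.0) for s in sample_ids])
    fractions = {s: float(math.exp(v)) for s, v in zip(sample_ids, logf)}

    names = config.gene_names()
    delta = config.polarization_effect
    kappa = config.marker_coupling
    reactive_mask = np.array([state_of[s] == REACTIVE for s in sample_ids], dtype=float)
    tolerant_mask = 1.0 - reactive_mask

    blocks, index = [], []
    for cid, shift in (("C13", delta * reactive_mask),
                       ("C14", delta * tolerant_mask),
                       ("C3", 1.5 * delta * tolerant_mask)):
        genes = names[cid]
        mean = config.baseline_mean + shift + kappa * logf
        noise = rng.normal(0.0, config.noise_sd, size=(len(genes), len(sample_ids)))
        blocks.append(mean[None, :] + noise)
        index.extend(genes)
    bg_genes = [f"BG_{i:03d}" for i in range(1, config.n_background + 1)]
    if bg_genes:
        blocks.append(
            config.baseline_mean
            + rng.normal(0.0, config.noise_sd, size=(len(bg_genes), len(sample_ids)))
        )
        index.extend(bg_genes)
    marker = (
        config.baseline_mean
        + kappa * logf
        + rng.normal(0.0, config.marker_noise_sd, size=len(sample_ids))
    )
    blocks.append(marker[None, :])
    index.append("FCER1G")

    matrix = pd.DataFrame(np.vstack(blocks), index=index, columns=sample_ids)
    annotations = _annotation_rows(sample_ids, state_of)
    truth = GroundTruth(
        states=state_of,
        fractions=fractions,
        group=group_of,
        config=config,
        confound_strength=max(abs(v) for v in logf_shift_per_group.values())
        if logf_shift_per_group
        else 0.0,
    )
    return matrix, annotations, truth


def simulate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a cohort with a planted reactive/tolerant split and a shared
    (non-confounded) macrophage-fraction distribution."""
    return _simulate(config, {})


def simulate_confounded_cohort(
    config: SyntheticConfig, confound_strength: float
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a cohort whose macrophage fraction differs between groups.

    The second group's ``log f`` is shifted up by ``confound_strength``
    (log-units), inducing a spurious score–group association of controllable
    size; the planted polarization effect is whatever ``config`` says (set
    ``polarization_effect=0`` for a pure-confound experiment).
    """
    if confound_strength < 0:
        raise ValidationError("confound_strength must be ≥ 0")
    groups = list(config.n_per_group)
    if len(groups) != 2:
        raise ValidationError("confounded cohorts need exactly 2 groups")
    return _simulate(config, {groups[1]: confound_strength})


def make_longitudinal_labels(
    annotations: pd.DataFrame, subject_of: Mapping[str, str]
) -> pd.DataFrame:
    """Assign each subject's samples consecutive timepoints A, B, C, … .

    Samples of a subject are ordered by sample id; the first gets A (day 1),
    the second B (day 7), then C… weekly.  A subject with more than 10
    samples exceeds the A–J vocabulary and raises.
    """
    letters = "ABCDEFGHIJ"
    missing = [s for s in annotations.index if s not in subject_of]
    if missing:
        raise ValidationError(f"samples without a subject: {missing[:5]}")
    out = annotations.copy()
    by_subject: dict[str, list[str]] = {}
    for sid in annotations.index:
        by_subject.setdefault(str(subject_of[sid]), []).append(sid)
    for subj, sids in by_subject.items():
        if len(sids) > len(letters):
            raise ValidationError(
                f"subject {subj!r} has {len(sids)} samples; timepoint vocabulary is A–J"
            )
        for tp, sid in zip(letters, sorted(sids)):
            out.loc[sid, "timepoint"] = tp
    return out


def filter_timepoint_at_least(annotations: pd.DataFrame, timepoint: str) -> pd.DataFrame:
    """Samples at or after the given timepoint (C ≈ day 14 onwards)."""
    letters = "ABCDEFGHIJ"
    if timepoint not in letters:
        raise ValidationError(f"unknown timepoint token {timepoint!r}")
    keep = annotations["timepoint"].isin(list(letters[letters.index(timepoint):]))
    return annotations[keep]


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["n_per_group"] = dict(d["n_per_group"])
    d["cluster_sizes"] = list(d["cluster_sizes"])
    d["macrophage_fraction"] = list(d["macrophage_fraction"])
    return d
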