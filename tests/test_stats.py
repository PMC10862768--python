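"""Welch t, Benjamini–Hochberg, ROC-AUC — each checked against a hand-rolled
independent oracle — plus the compare_groups contrast machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import macpolar as mp
from macpolar.errors import DegenerateDataError, ValidationError
from macpolar.io import CompositeScoreSet, rank_scores

from conftest import derive_seeds, MASTER_SEED


def welch_oracle(a, b):
    """Textbook Welch formula with Welch–Satterthwaite degrees of freedom."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, p


def bh_oracle(pvals):
    """Step-up BH: sort, scale by m/i, enforce monotonicity from the top, cap at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_pos in range(m - 1, -1, -1):
        i = order[rank_pos]
        running = min(running, pvals[i] * m / (rank_pos + 1))
        adj[i] = running
    return adj


def auc_oracle(scores, labels, positive):
    """O(n²) Mann–Whitney pair counting, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestWelch:
    def test_identical_groups(self):
        t, p = mp.welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        a, b = [1, 2, 3], [1, 2, 3, 4, 5, 6]
        t, p = mp.welch_t(a, b)
        t0, p0 = welch_oracle(a, b)
        assert t == pytest.approx(t0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)

    @pytest.mark.parametrize("seed", derive_seeds(MASTER_SEED, 3))
    def test_matches_oracle_on_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(3, 20))
        b = rng.normal(0.5, 2, rng.integers(3, 20))
        t, p = mp.welch_t(a, b)
        t0, p0 = welch_oracle(a, b)
        assert t == pytest.approx(t0, abs=1e-12) and p == pytest.approx(p0, abs=1e-12)

    @given(st.floats(-1e3, 1e3))
    def test_location_invariance(self, c):
        a, b = [1.0, 2.0, 4.0], [0.0, 3.0, 5.0, 9.0]
        t1, p1 = mp.welch_t(a, b)
        t2, p2 = mp.welch_t([x + c for x in a], [x + c for x in b])
        assert t2 == pytest.approx(t1, abs=1e-6) and p2 == pytest.approx(p1, abs=1e-6)

    def test_symmetry_up_to_sign(self):
        a, b = [1.0, 2.0, 4.0], [0.0, 3.0, 5.0, 9.0]
        t1, p1 = mp.welch_t(a, b)
        t2, p2 = mp.welch_t(b, a)
        assert t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)

    def test_degenerate_variances_rejected(self):
        with pytest.raises(DegenerateDataError):
            mp.welch_t([1.0, 1.0], [2.0, 2.0])

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            mp.welch_t([1.0], [1.0, 2.0])


class TestBH:
    def test_single_p_unchanged(self):
        assert mp.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_step_up_case(self):
        # 0.01·4/1 = 0.02·4/2 = 0.03·4/3 (→ monotone cap) = 0.04·4/4 = 0.04
        out = mp.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("seed", derive_seeds(MASTER_SEED, 3))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 25).tolist()
        assert np.allclose(mp.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_output_bounds_and_dominance(self):
        p = [0.001, 0.5, 0.9, 0.04, 1.0]
        out = mp.bh_adjust(p)
        assert (out <= 1).all() and (out >= np.asarray(p)).all()

    def test_monotone_in_inputs(self):
        p = [0.01, 0.2, 0.6]
        q = [0.02, 0.3, 0.7]
        assert (mp.bh_adjust(p) <= mp.bh_adjust(q)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            mp.bh_adjust([0.5, 1.5])


class TestRocAuc:
    def test_perfect_separation(self):
        assert mp.roc_auc([1, 2, 3, 10, 11], ["a"] * 3 + ["b"] * 2, positive_label="b") == 1.0

    def test_all_ties(self):
        assert mp.roc_auc([1, 1, 1, 1], ["a", "a", "b", "b"], positive_label="b") == 0.5

    def test_label_flip_complements(self):
        scores = [0.1, 0.7, 0.3, 0.9]
        labels = ["a", "b", "a", "b"]
        auc = mp.roc_auc(scores, labels, positive_label="b")
        assert mp.roc_auc(scores, labels, positive_label="a") == pytest.approx(1 - auc)

    @pytest.mark.parametrize("seed", derive_seeds(MASTER_SEED, 5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=40), 1)  # rounding forces ties
        labels = rng.choice(["neg", "pos"], size=40)
        if len(set(labels)) < 2:
            labels[0] = "neg"; labels[1] = "pos"
        auc = mp.roc_auc(scores, labels, positive_label="pos")
        assert auc == pytest.approx(auc_oracle(scores, labels, "pos"), abs=1e-12)

    def test_orientation_free_mode(self):
        scores = [3, 2, 1, 0]
        labels = ["a", "a", "b", "b"]
        assert mp.roc_auc(scores, labels, positive_label="b") == 0.0
        assert mp.roc_auc(scores, labels, positive_label="b", orientation_free=True) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            mp.roc_auc([1, 2], ["a", "a"])


def make_score_set(values, ids):
    s = pd.Series(values, index=ids, name="score", dtype=float)
    return CompositeScoreSet("C13-14-3", s, rank_scores(s))


class TestCompareGroups:
    def annotations(self, rows):
        df = pd.DataFrame(rows)
        return df.set_index("sample_id")

    def cohort_frames(self, seed, delta):
        rng = np.random.default_rng(seed)
        n = 20
        ids = [f"s{i}" for i in range(2 * n)]
        scores = np.concatenate([rng.normal(0, 1, n), rng.normal(delta, 1, n)])
        ann = self.annotations(
            [
                {
                    "sample_id": sid,
                    "placental_domain": "PID" if i < n else "PVD",
                    "preterm_labor": "no",
                }
                for i, sid in enumerate(ids)
            ]
        )
        return make_score_set(scores, ids), ann

    def test_planted_separation_detected(self):
        detected = 0
        for seed in derive_seeds(MASTER_SEED, 20):
            ss, ann = self.cohort_frames(seed, delta=2.0)
            (res,) = mp.compare_groups(ss, ann, "placental_domain", [("PID", "PVD")])
            detected += res.p_value < 0.01
        assert detected >= 18

    def test_null_auc_near_half(self):
        aucs = []
        for seed in derive_seeds(MASTER_SEED + 1, 20):
            rng = np.random.default_rng(seed)
            ids = [f"s{i}" for i in range(100)]
            ss = make_score_set(rng.normal(size=100), ids)
            ann = self.annotations(
                [{"sample_id": s, "placental_domain": "PID" if i < 50 else "PVD"}
                 for i, s in enumerate(ids)]
            )
            (res,) = mp.compare_groups(ss, ann, "placental_domain", [("PID", "PVD")])
            aucs.append(res.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_stratum_filter_excludes_other_samples(self):
        ids = ["a", "b", "c", "d", "e", "f", "g", "h"]
        ss = make_score_set([0, 1, 2, 3, 10, 11, 12, 13], ids)
        ann = self.annotations(
            [
                {"sample_id": s, "placental_domain": "PID" if i % 2 == 0 else "PVD",
                 "preterm_labor": "no" if i < 4 else "yes"}
                for i, s in enumerate(ids)
            ]
        )
        (res,) = mp.compare_groups(
            ss, ann, "placental_domain", [("PID", "PVD")], strata={"preterm_labor": "no"}
        )
        assert res.n_a == 2 and res.n_b == 2
        assert res.mean_a == pytest.approx(1.0) and res.mean_b == pytest.approx(2.0)

    def test_empty_stratum_named_in_error(self):
        ss, ann = self.cohort_frames(0, delta=0.0)
        with pytest.raises(ValidationError, match="preterm_labor=yes"):
            mp.compare_groups(
                ss, ann, "placental_domain", [("PID", "PVD")],
                strata={"preterm_labor": "yes"},
            )

    def test_bh_family_is_the_emitted_contrasts(self):
        ss, ann = self.cohort_frames(1, delta=1.0)
        results = mp.compare_groups(
            ss, ann, "placental_domain", [("PID", "PVD"), ("PVD", "PID")]
        )
        adj = mp.bh_adjust([r.p_value for r in results])
        for r, q in zip(results, adj):
            assert r.p_adjusted == pytest.approx(q)
            assert r.p_adjusted >= r.p_value


def test_null_type_one_error_rate():
    """Empirical type-I error of the pipeline's contrast test at α = 0.05
    stays in [0.02, 0.08] over 2,000 null replicates."""
    rng = np.random.default_rng(derive_seeds(MASTER_SEED + 2, 1)[0])
    rejections = 0
    n_rep = 2000
    for _ in range(n_rep):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 1, 10)
        _, p = mp.welch_t(a, b)
        rejections += p < 0.05
    assert 0.02 <= rejections / n_rep <= 0.08
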