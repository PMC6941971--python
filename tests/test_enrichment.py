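"""R+/R- splitting, one-sided KS test, FDR control, MST and ROC reporting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ttrans.datamodel import MatchScoreTable, TargetLinkTable, ValidationError
from ttrans.enrichment import (
    bh_qvalues,
    enrich_all,
    ks_one_sided,
    mst_of_targets,
    roc_predictions,
    split_by_target,
    storey_qvalues,
)


def _links(rows):
    return TargetLinkTable(records=pd.DataFrame(
        rows, columns=["chemical", "protein", "combined_score"]
    ))


class TestSplitByTarget:
    DRUGS = [f"d{i}" for i in range(10)]

    def test_strict_score_boundary(self):
        links = _links([("d0", "P1", 901), ("d1", "P1", 900),
                        ("d2", "P1", 950), ("d3", "P1", 950),
                        ("d4", "P1", 999)])
        r_plus, r_minus = split_by_target("P1", links, self.DRUGS,
                                          min_group_size=4)
        assert r_plus == {"d0", "d2", "d3", "d4"}
        assert "d1" in r_minus  # score exactly 900 is not a link

    def test_small_group_skipped(self):
        links = _links([("d0", "P1", 950), ("d1", "P1", 950),
                        ("d2", "P1", 950)])
        assert split_by_target("P1", links, self.DRUGS) is None

    def test_absent_target_skipped(self):
        assert split_by_target("PX", _links([("d0", "P1", 950)]),
                               self.DRUGS) is None


def _brute_force_ks(plus, minus):
    """Pure-python enumeration oracle: D and exact permutation p."""
    def one_sided_d(a, b):
        grid = sorted(set(a) | set(b))
        d = 0.0
        for x in grid:
            ecdf_a = sum(v <= x for v in a) / len(a)
            ecdf_b = sum(v <= x for v in b) / len(b)
            d = max(d, ecdf_b - ecdf_a)
        return d

    d_obs = one_sided_d(plus, minus)
    pooled = list(plus) + list(minus)
    m = len(plus)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), m):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if one_sided_d(a, b) >= d_obs - 1e-12:
            count += 1
        total += 1
    return d_obs, count / total


class TestKsOneSided:
    def test_identical_samples(self):
        d, p = ks_one_sided([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert d == 0.0 and p == 1.0

    def test_complete_separation(self):
        d, p = ks_one_sided([0.7, 0.8, 0.9], [0.1, 0.2, 0.3])
        assert d == 1.0
        assert p == pytest.approx(1 / 20)  # 1 of C(6,3) splits ties the max

    def test_exhaustive_enumeration_oracle_three_four_split(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
        for idx in itertools.combinations(range(7), 3):
            plus = [vals[i] for i in idx]
            minus = [vals[i] for i in range(7) if i not in idx]
            d, p = ks_one_sided(plus, minus)
            d_o, p_o = _brute_force_ks(plus, minus)
            assert d == d_o
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_oracle_agreement_with_ties(self, rng):
        for _ in range(20):
            pooled = rng.choice([0.1, 0.2, 0.3, 0.4], size=8)
            plus, minus = pooled[:3].tolist(), pooled[3:].tolist()
            d, p = ks_one_sided(plus, minus)
            d_o, p_o = _brute_force_ks(plus, minus)
            assert d == pytest.approx(d_o, abs=1e-12)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_statistic_agrees_with_scipy_one_sided(self, rng):
        for _ in range(20):
            plus = rng.normal(size=12)
            minus = rng.normal(size=30)
            d, _ = ks_one_sided(plus, minus)
            ref = stats.ks_2samp(minus, plus, alternative="greater").statistic
            assert d == pytest.approx(float(ref), abs=1e-12)

    def test_asymptotic_bound_above_switchover(self, rng):
        plus = rng.normal(size=20) + 1.0
        minus = rng.normal(size=40)
        d, p = ks_one_sided(plus, minus)
        en = 20 * 40 / 60
        assert p == pytest.approx(min(1.0, np.exp(-2 * d * d * en)))

    def test_empty_sample_errors(self):
        with pytest.raises(ValidationError, match="non-empty"):
            ks_one_sided([], [0.1])


class TestFdr:
    def test_bh_matches_step_up_formula(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 200))
            p = rng.uniform(size=m)
            q = bh_qvalues(p)
            order = np.argsort(p)
            q_oracle = np.empty(m)
            running = 1.0
            for rank in range(m - 1, -1, -1):
                i = order[rank]
                running = min(running, p[i] * m / (rank + 1))
                q_oracle[i] = running
            np.testing.assert_allclose(q, q_oracle, atol=1e-12)

    def test_textbook_bh_vector(self):
        np.testing.assert_allclose(bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04])),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_test_q_equals_p(self):
        np.testing.assert_allclose(bh_qvalues(np.array([0.031])), [0.031])

    def test_storey_shrinks_by_pi0(self, rng):
        p = np.concatenate([rng.uniform(0, 0.001, size=20),
                            rng.uniform(size=80)])
        q_bh = bh_qvalues(p)
        q_st = storey_qvalues(p)
        assert (q_st <= q_bh + 1e-12).all()


def _score_table(scores: dict, feature="f1", direction="-"):
    rows = [(d, feature, direction, s, 1.0, 1) for d, s in scores.items()]
    return MatchScoreTable(table=pd.DataFrame(
        rows, columns=["drug", "feature", "direction", "score", "sigma_bar",
                       "n_cell_lines"]
    ))


class TestEnrichAll:
    def test_shifted_target_detected(self, rng):
        scores = {f"d{i}": float(v) for i, v in
                  enumerate(rng.uniform(0, 0.4, size=50))}
        for i in range(5):
            scores[f"hit{i}"] = float(rng.uniform(0.8, 1.0))
        links = _links([(f"hit{i}", "P1", 950) for i in range(5)]
                       + [(f"d{i}", "P2", 950) for i in range(5)])
        table = enrich_all(_score_table(scores), links, alpha_q=0.01).table
        p1 = table[table["target"] == "P1"].iloc[0]
        p2 = table[table["target"] == "P2"].iloc[0]
        assert p1["significant"] and p1["D"] == 1.0
        assert not p2["significant"]

    def test_families_corrected_separately(self, rng):
        scores = {f"d{i}": float(v) for i, v in
                  enumerate(rng.uniform(size=30))}
        t_minus = _score_table(scores, direction="-").table
        t_plus = _score_table(scores, direction="+").table
        both = MatchScoreTable(table=pd.concat([t_minus, t_plus]))
        links = _links([(f"d{i}", f"P{j}", 950)
                        for j in range(3) for i in range(j * 5, j * 5 + 5)])
        table = enrich_all(both, links).table
        # one BH family per (feature, direction): 3 targets each
        for _, fam in table.groupby(["feature", "direction"]):
            assert len(fam) == 3

    def test_no_eligible_targets_returns_empty(self, rng):
        scores = {f"d{i}": 0.5 for i in range(10)}
        links = _links([("d0", "P1", 950)])  # only 1 linked drug < 4
        table = enrich_all(_score_table(scores), links).table
        assert table.empty


class TestMst:
    def test_triangle_keeps_two_cheapest_edges(self):
        links = pd.DataFrame(
            {"protein1": ["A", "A", "B"], "protein2": ["B", "C", "C"],
             "combined_score": [999, 998, 997]}  # distances 1, 2, 3
        )
        edges = mst_of_targets(["A", "B", "C"], links)
        assert len(edges) == 2
        assert set(edges["distance"]) == {1, 2}

    def test_complete_graph_yields_n_minus_one_edges(self, rng):
        nodes = [f"P{i}" for i in range(6)]
        rows = [(a, b, int(rng.integers(100, 900)))
                for a, b in itertools.combinations(nodes, 2)]
        links = pd.DataFrame(rows, columns=["protein1", "protein2",
                                            "combined_score"])
        edges = mst_of_targets(nodes, links)
        assert len(edges) == 5

    def test_disconnected_pairs_form_forest(self):
        links = pd.DataFrame(
            {"protein1": ["A", "C"], "protein2": ["B", "D"],
             "combined_score": [900, 800]}
        )
        edges = mst_of_targets(["A", "B", "C", "D"], links)
        assert len(edges) == 2  # 4 nodes, 2 components

    def test_tie_break_is_deterministic(self):
        links = pd.DataFrame(
            {"protein1": ["A", "A", "B"], "protein2": ["B", "C", "C"],
             "combined_score": [900, 900, 900]}
        )
        e1 = mst_of_targets(["A", "B", "C"], links)
        e2 = mst_of_targets(["A", "B", "C"], links.iloc[::-1])
        pd.testing.assert_frame_equal(e1, e2)


class TestRoc:
    def _frames(self, scores, values, direction="-"):
        pred = pd.DataFrame({
            "drug": list(scores), "feature": "f1", "direction": direction,
            "score": list(scores.values()),
        })
        obs = pd.DataFrame({
            "drug": list(values), "feature": "f1",
            "value": list(values.values()),
        })
        return pred, obs

    def test_perfect_separation_auc_one(self):
        scores = {f"d{i}": i / 10 for i in range(10)}
        values = {f"d{i}": (-1.0 if i >= 5 else 1.0) for i in range(10)}
        pred, obs = self._frames(scores, values)
        assert roc_predictions(pred, obs).auc["-"] == 1.0

    def test_random_scores_auc_near_half(self):
        inside = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            scores = {f"d{i}": float(g.uniform()) for i in range(500)}
            values = {f"d{i}": float(g.choice([-1.0, 1.0]))
                      for i in range(500)}
            pred, obs = self._frames(scores, values)
            if 0.4 < roc_predictions(pred, obs).auc["-"] < 0.6:
                inside += 1
        assert inside >= 19  # >= 95% of seeds

    def test_negated_scores_mirror_auc(self, rng):
        scores = {f"d{i}": float(rng.uniform()) for i in range(100)}
        values = {f"d{i}": float(rng.choice([-1.0, 1.0])) for i in range(100)}
        pred, obs = self._frames(scores, values)
        auc = roc_predictions(pred, obs).auc["-"]
        pred_neg = pred.assign(score=-pred["score"])
        auc_neg = roc_predictions(pred_neg, obs).auc["-"]
        assert auc + auc_neg == pytest.approx(1.0, abs=1e-12)

    def test_single_class_labels_error(self):
        scores = {f"d{i}": i / 5 for i in range(5)}
        values = {f"d{i}": -1.0 for i in range(5)}
        pred, obs = self._frames(scores, values)
        with pytest.raises(ValidationError, match="single-class"):
            roc_predictions(pred, obs)
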