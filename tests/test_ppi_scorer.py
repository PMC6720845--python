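import math

import numpy as np
import pytest

from domppi.ppi_scorer import (
    DEFAULT_LATTICE,
    DEFAULT_THRESHOLD_GRID,
    FusionConfig,
    InteractionScoreTable,
    ProteinRecord,
    counts_at_threshold,
    enumerate_domain_pairs,
    fuse,
    lattice_search,
    normalize_score,
    predict_ppi,
    predicted_ratio,
    protein_pair_dscore,
    select_threshold,
    twentieth_percentile_background,
)
from domppi.metrics import fn_fp_rates


class StubModel:
    """Predicts 1 exactly for feature rows whose first value is >= 0."""

    def predict(self, X):
        return (np.asarray(X)[:, 0] >= 0).astype(int)


class ConstantModel:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label, dtype=int)


def prot(pid, *doms):
    return ProteinRecord(protein_id=pid, domain_ids=tuple(doms))


@pytest.fixture()
def table():
    return InteractionScoreTable(
        scores={("a", "b"): 100.0, ("c", "d"): 4.0, ("e", "e"): 25.0},
        background_score=2.0,
    )


class TestScoreTable:
    def test_orientation_insensitive(self, table):
        assert table.lookup("b", "a") == 100.0
        assert table.lookup("a", "b") == 100.0

    def test_fallback_to_background(self, table):
        assert table.lookup("a", "zzz") == 2.0

    def test_s_max(self, table):
        assert table.s_max == 100.0

    def test_rejects_nonpositive_lambda(self):
        with pytest.raises(ValueError):
            InteractionScoreTable(scores={("a", "b"): 0.0}, background_score=2.0)

    def test_rejects_small_s_max(self):
        with pytest.raises(ValueError, match="s_max"):
            InteractionScoreTable(scores={("a", "b"): 0.9}, background_score=2.0)

    def test_rejects_background_at_most_one(self):
        with pytest.raises(ValueError, match="background"):
            InteractionScoreTable(scores={("a", "b"): 5.0}, background_score=1.0)

    def test_percentile_background_rule(self):
        # ascending [1.6, 1.7, 1.8, 1.9, 2.0]; ceil(0.2*5) = 1 -> first value
        lams = [2.0, 1.6, 1.9, 1.7, 1.8]
        assert twentieth_percentile_background(lams) == 1.6
        # sub-cutoff values are excluded before taking the percentile
        assert twentieth_percentile_background([0.5, 1.0] + lams) == 1.6
        # ten values: ceil(2) = 2 -> second smallest
        ten = [float(v) for v in range(2, 12)]
        assert twentieth_percentile_background(ten) == 3.0

    def test_from_scores_derives_background(self):
        rows = [("a", "b", 10.0), ("c", "d", 2.0), ("e", "f", 5.0)]
        t = InteractionScoreTable.from_scores(rows)
        assert t.background_score == 2.0
        assert t.s_max == 10.0


class TestEnumerateDomainPairs:
    def test_one_by_one(self):
        assert enumerate_domain_pairs(prot("p", "a"), prot("q", "b")) == [("a", "b")]

    def test_cross_product(self):
        pairs = enumerate_domain_pairs(prot("p", "a", "b"), prot("q", "x", "y", "z"))
        assert len(pairs) == 6
        assert pairs[0] == ("a", "x")

    def test_duplicates_kept(self):
        pairs = enumerate_domain_pairs(prot("p", "a", "a"), prot("q", "b"))
        assert pairs == [("a", "b"), ("a", "b")]

    def test_length_is_product(self, rng):
        for _ in range(20):
            na, nb = rng.integers(1, 5, size=2)
            pa = prot("p", *[f"d{i}" for i in range(na)])
            pb = prot("q", *[f"e{i}" for i in range(nb)])
            assert len(enumerate_domain_pairs(pa, pb)) == na * nb

    def test_empty_architecture_rejected(self):
        with pytest.raises(ValueError):
            prot("p")


class TestNormalizeScore:
    def test_endpoints(self):
        assert normalize_score(50.0, 50.0) == 1.0
        assert normalize_score(1.0, 50.0) == 0.0

    def test_sqrt_gives_half(self):
        for s_max in (2.0, 10.0, 402.5):
            assert normalize_score(math.sqrt(s_max), s_max) == pytest.approx(0.5)

    def test_below_one_clamped_to_zero(self):
        assert normalize_score(0.5, 10.0) == 0.0

    def test_monotone_on_unit_to_smax(self, rng):
        s_max = 123.0
        lams = np.sort(rng.uniform(1.0, s_max, size=50))
        vals = [normalize_score(l, s_max) for l in lams]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("lam,s_max", [(0.0, 10.0), (-1.0, 10.0)])
    def test_nonpositive_lambda_rejected(self, lam, s_max):
        with pytest.raises(ValueError):
            normalize_score(lam, s_max)

    def test_small_s_max_rejected(self):
        with pytest.raises(ValueError):
            normalize_score(5.0, 1.0)


class TestProteinPairDscore:
    def test_single_domain_at_s_max(self, table):
        assert protein_pair_dscore(prot("p", "a"), prot("q", "b"), table) == 1.0

    def test_fallback_contract(self, table):
        d = protein_pair_dscore(prot("p", "u"), prot("q", "v"), table)
        assert d == pytest.approx(normalize_score(2.0, 100.0))

    def test_matches_exhaustive_enumeration(self, rng, table):
        ids = ["a", "b", "c", "d", "e", "u", "v"]
        for _ in range(30):
            pa = prot("p", *rng.choice(ids, size=rng.integers(1, 5)))
            pb = prot("q", *rng.choice(ids, size=rng.integers(1, 5)))
            expected = max(
                normalize_score(table.lookup(x, ycol), table.s_max)
                for x in pa.domain_ids
                for ycol in pb.domain_ids
            )
            assert protein_pair_dscore(pa, pb, table) == pytest.approx(expected)

    def test_mean_aggregation(self, table):
        pa, pb = prot("p", "a", "u"), prot("q", "b")
        vals = [
            normalize_score(table.lookup("a", "b"), table.s_max),
            normalize_score(table.lookup("u", "b"), table.s_max),
        ]
        assert protein_pair_dscore(pa, pb, table, agg="mean") == pytest.approx(
            np.mean(vals)
        )

    def test_unknown_aggregation(self, table):
        with pytest.raises(ValueError, match="aggregation"):
            protein_pair_dscore(prot("p", "a"), prot("q", "b"), table, agg="median")


class TestPredictedRatio:
    @pytest.fixture()
    def featurizer(self):
        return {
            d: np.full(10, v)
            for d, v in [("a", 1.0), ("b", 2.0), ("c", -1.0), ("d", -2.0), ("e", 3.0)]
        }

    def test_all_predicted(self, featurizer):
        r = predicted_ratio(prot("p", "a"), prot("q", "b"), ConstantModel(1), featurizer)
        assert r == 1.0

    def test_none_predicted(self, featurizer):
        r = predicted_ratio(prot("p", "a"), prot("q", "b"), ConstantModel(0), featurizer)
        assert r == 0.0

    def test_three_of_six(self, featurizer):
        # 2x3 cross product; stub labels exactly the rows whose first
        # domain has positive features -> domains {a} x all 3 = 3 of 6
        pa = prot("p", "a", "c")
        pb = prot("q", "b", "d", "e")
        r = predicted_ratio(pa, pb, StubModel(), featurizer)
        assert r == pytest.approx(0.5)

    def test_missing_domain_named(self, featurizer):
        with pytest.raises(KeyError, match="zz"):
            predicted_ratio(prot("p", "zz"), prot("q", "a"), StubModel(), featurizer)


class TestFuse:
    @pytest.mark.parametrize(
        "d,p,a,b,expected",
        [
            (1.0, 1.0, 0.5, 0.5, 1.0),
            (0.7, 0.2, 1.0, 0.0, 0.7),
            (0.4, 0.8, 0.5, 0.5, 0.6),
        ],
    )
    def test_examples(self, d, p, a, b, expected):
        assert fuse(d, p, a, b) == pytest.approx(expected)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            fuse(0.5, 0.5, -0.1, 0.5)

    def test_convex_blend_stays_in_unit_interval(self, rng):
        for _ in range(100):
            d, p = rng.uniform(0, 1, size=2)
            assert 0.0 <= fuse(d, p, 0.5, 0.5) <= 1.0


class TestLatticeSearch:
    def test_exactly_49_points(self, rng):
        d = rng.uniform(0, 1, size=40)
        p = rng.uniform(0, 1, size=40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        a, b, diag = lattice_search(d, p, y)
        assert len(diag) == 49
        assert len(DEFAULT_LATTICE) == 7

    def test_d_channel_separates(self, rng):
        y = np.array([1] * 30 + [0] * 30)
        d = np.concatenate([rng.uniform(0.7, 1.0, 30), rng.uniform(0.0, 0.3, 30)])
        p = rng.uniform(0, 1, size=60)  # noise channel
        a, b, diag = lattice_search(d, p, y)
        assert a > 0
        best = diag[(diag.a == a) & (diag.b == b)].iloc[0]
        assert best.acc == pytest.approx(100.0)

    def test_weight_scaling_preserves_ranking(self, rng):
        d = rng.uniform(0, 1, size=50)
        p = rng.uniform(0, 1, size=50)
        s1 = 0.2 * d + 0.3 * p
        s2 = 0.4 * d + 0.6 * p
        assert np.array_equal(np.argsort(s1), np.argsort(s2))

    def test_single_class_rejected(self, rng):
        d = rng.uniform(0, 1, size=10)
        with pytest.raises(ValueError):
            lattice_search(d, d, np.ones(10, dtype=int))

    def test_tie_break_prefers_smaller_a(self):
        # perfectly separable by either channel: many points tie at 100%
        # accuracy and AUC 1; the tie-break walks to the smallest (A, B)
        # scores at (0, 0.1) all sit below the smallest grid threshold, so
        # (0, 0.2) is the first point reaching 100% accuracy
        y = np.array([1] * 10 + [0] * 10)
        d = np.array([0.9] * 10 + [0.1] * 10)
        a, b, _ = lattice_search(d, d.copy(), y)
        assert (a, b) == (0.0, 0.2)


class TestSelectThreshold:
    def test_grid_structure(self):
        assert len(DEFAULT_THRESHOLD_GRID) == 10
        assert DEFAULT_THRESHOLD_GRID[0] == 0.10
        assert DEFAULT_THRESHOLD_GRID[-1] == 0.55
        steps = np.diff(DEFAULT_THRESHOLD_GRID)
        assert np.allclose(steps, 0.05)

    def test_degenerate_perfect_scores(self):
        y = np.array([1, 1, 0, 0])
        chosen, table = select_threshold(y.astype(float), y)
        assert chosen == 0.10  # full tie; refinement keeps the coarse pick
        coarse = table[table.stage == "coarse"]
        assert len(coarse) == 10

    def test_unique_zero_imbalance_at_030(self):
        y = np.array([1, 1, 0, 0])
        scores = np.array([0.32, 0.34, 0.28, 0.26])
        chosen, _ = select_threshold(scores, y)
        assert chosen == pytest.approx(0.30)

    def test_refinement_can_move_off_grid(self):
        y = np.array([1, 1, 0, 0])
        scores = np.array([0.095, 0.5, 0.04, 0.085])
        chosen, table = select_threshold(scores, y)
        assert chosen == pytest.approx(0.09)
        refine = table[table.stage == "refine"]
        assert sorted(refine.threshold) == [pytest.approx(0.09), pytest.approx(0.11)]

    def test_table_consistent_with_counts(self, rng):
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        scores = rng.uniform(0, 1, size=80)
        chosen, table = select_threshold(scores, y)
        for _, row in table.iterrows():
            c = counts_at_threshold(scores, y, row.threshold)
            assert (c.tp, c.tn, c.fp, c.fn) == (row.tp, row.tn, row.fp, row.fn)
            fnr, fpr = fn_fp_rates(c)
            assert row.fn_rate == pytest.approx(fnr)
            assert row.fp_rate == pytest.approx(fpr)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            scores = np.round(rng.uniform(0, 0.7, size=n), 2)
            chosen, _ = select_threshold(scores, y)

            def key2(t):
                c = counts_at_threshold(scores, y, t)
                fnr, fpr = fn_fp_rates(c)
                return (abs(fnr - fpr), fnr + fpr)

            coarse = min(
                DEFAULT_THRESHOLD_GRID, key=lambda t: (*key2(t), t)
            )
            best, best_k = coarse, key2(coarse)
            for t in (round(coarse - 0.01, 10), round(coarse + 0.01, 10)):
                k = key2(t)
                if k < best_k:
                    best, best_k = t, k
            assert chosen == pytest.approx(best)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([0.1, 0.9], [1, 1])


class TestPredictPpi:
    @pytest.fixture()
    def setup(self, rng):
        featurizer = {
            "a": np.full(10, 1.0),
            "b": np.full(10, 2.0),
            "c": np.full(10, -1.0),
            "d": np.full(10, -2.0),
        }
        proteins = {
            "P1": prot("P1", "a", "b"),
            "P2": prot("P2", "b"),
            "P3": prot("P3", "c", "d"),
        }
        table = InteractionScoreTable(
            scores={("a", "b"): 100.0, ("b", "b"): 50.0}, background_score=2.0
        )
        pairs = [("P1", "P2"), ("P1", "P3"), ("P2", "P3")]
        return featurizer, proteins, table, pairs

    def test_threshold_zero_labels_all_positive(self, setup):
        featurizer, proteins, table, pairs = setup
        out = predict_ppi(
            pairs, proteins, StubModel(), featurizer, table,
            FusionConfig(threshold=0.0),
        )
        assert [r.predicted_label for r in out] == [1, 1, 1]

    def test_threshold_above_one_labels_all_negative(self, setup):
        featurizer, proteins, table, pairs = setup
        out = predict_ppi(
            pairs, proteins, StubModel(), featurizer, table,
            FusionConfig(threshold=1.01),
        )
        assert [r.predicted_label for r in out] == [0, 0, 0]

    def test_provenance_fields(self, setup):
        featurizer, proteins, table, pairs = setup
        out = predict_ppi(pairs, proteins, StubModel(), featurizer, table)
        for r in out:
            assert r.p_mn == pytest.approx(0.5 * r.d_mn + 0.5 * r.p_ij)
            assert 0.0 <= r.d_mn <= 1.0 and 0.0 <= r.p_ij <= 1.0

    def test_raising_lambda_never_decreases_pmn(self, rng):
        featurizer = {f"d{i}": rng.normal(size=10) for i in range(6)}
        proteins = {
            "P1": prot("P1", "d0", "d1"),
            "P2": prot("P2", "d2", "d3"),
            "P3": prot("P3", "d4", "d5"),
        }
        pairs = [("P1", "P2"), ("P1", "P3")]
        base_scores = {("d0", "d2"): 20.0, ("d1", "d5"): 30.0, ("d9", "d8"): 100.0}
        for bumped in (25.0, 40.0, 99.0):
            t1 = InteractionScoreTable(scores=dict(base_scores), background_score=2.0)
            scores2 = dict(base_scores)
            scores2[("d0", "d2")] = bumped
            t2 = InteractionScoreTable(scores=scores2, background_score=2.0)
            out1 = predict_ppi(pairs, proteins, StubModel(), featurizer, t1)
            out2 = predict_ppi(pairs, proteins, StubModel(), featurizer, t2)
            for r1, r2 in zip(out1, out2):
                assert r2.p_mn >= r1.p_mn - 1e-12
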