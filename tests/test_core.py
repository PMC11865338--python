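import math

import numpy as np
import pytest

from bhwa.core import (
    DegenerateRankError,
    RankSimilarity,
    aggregate_weighted,
    apply_min_disturbance_filter,
    bh_fdr,
    pairwise_similarity,
    quantify_disturbance,
    rank_similarity,
)

from conftest import make_counts, make_evidence, random_instance
from _oracle import oracle_weighted_similarity


class TestMinDisturbanceFilter:
    ROWS = [
        ("s1", "fiber", "Keep3", "M1", "genus", 1),
        ("s2", "fiber", "Keep3", "M2", "genus", 1),
        ("s3", "fiber", "Keep3", "M3", "genus", -1),
        ("s4", "fiber", "Drop2", "M1", "genus", 1),
        ("s5", "fiber", "Drop2", "OrphanTaxon", "genus", 1),
    ]

    def test_boundary_three_taxa_retained(self):
        out = apply_min_disturbance_filter(make_evidence(self.ROWS), threshold=3)
        assert out.entities() == ["Keep3"]

    def test_fewer_than_three_removed(self):
        out = apply_min_disturbance_filter(make_evidence(self.ROWS))
        assert "Drop2" not in out.entities()

    def test_orphan_taxon_absent_after_filter(self):
        out = apply_min_disturbance_filter(make_evidence(self.ROWS))
        assert "OrphanTaxon" not in set(out.records["microbe_name"])

    def test_filter_emptying_table_raises(self):
        with pytest.raises(ValueError, match="removed every entity"):
            apply_min_disturbance_filter(make_evidence(self.ROWS), threshold=10)

    def test_distinct_taxa_not_rows_counted(self):
        rows = [("s%d" % k, "fiber", "Rep", "M1", "genus", 1) for k in range(5)]
        with pytest.raises(ValueError):
            apply_min_disturbance_filter(make_evidence(rows), threshold=3)


class TestQuantifyDisturbance:
    def test_hand_evaluated_strength(self):
        # entity A: 3 net increases of taxon m; 4 entities, taxon m seen in 2
        counts = make_counts(
            {
                "genus": {
                    ("A", "m"): (3, 0),
                    ("B", "m"): (1, 0),
                    ("B", "x"): (1, 0),
                    ("C", "y"): (1, 0),
                    ("D", "z"): (1, 0),
                }
            }
        )
        dm = quantify_disturbance(counts, "genus")
        assert dm.N == 4
        i, j = dm.entities.index("A"), dm.taxa.index("m")
        assert dm.D[i, j] == pytest.approx(3 * math.log(2), abs=1e-12)

    def test_globally_associated_taxon_scores_zero(self):
        counts = make_counts(
            {"genus": {("A", "m"): (1, 0), ("B", "m"): (2, 0), ("C", "m"): (1, 0)}}
        )
        dm = quantify_disturbance(counts, "genus")
        assert np.all(dm.D == 0)  # n == N -> ln(1) = 0

    def test_tied_directions_zero_out(self):
        counts = make_counts(
            {"genus": {("A", "m"): (2, 2), ("B", "x"): (1, 0)}}
        )
        dm = quantify_disturbance(counts, "genus")
        i, j = dm.entities.index("A"), dm.taxa.index("m")
        assert dm.alpha[i, j] == 0
        assert dm.D[i, j] == 0

    def test_single_entity_rank_degenerate(self):
        counts = make_counts({"genus": {("A", "m"): (1, 0)}})
        with pytest.raises(DegenerateRankError):
            quantify_disturbance(counts, "genus")

    def test_matrix_invariant_holds(self):
        rng = np.random.default_rng(7)
        _, tallies = random_instance(rng)
        counts = make_counts(tallies)
        for rank in tallies:
            try:
                dm = quantify_disturbance(counts, rank)
            except DegenerateRankError:
                continue
            with np.errstate(divide="ignore"):
                idf = np.where(dm.n > 0, np.log(dm.N / dm.n), 0.0)
            np.testing.assert_allclose(dm.D, dm.alpha * dm.C * idf, atol=1e-12)


class TestRankSimilarity:
    def test_identical_vectors(self):
        r = rank_similarity([1.0, 2.0, 0, 3.0], [1.0, 2.0, 0, 3.0])
        assert r.sim == pytest.approx(1.0)
        assert r.contributing
        assert np.isfinite(r.weight)

    def test_orthogonal_support_six(self):
        r = rank_similarity([1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1])
        assert r.sim == pytest.approx(0.0)
        assert r.m_shared == 6
        assert r.sigma == pytest.approx(0.5)  # sqrt((1-0)/4)
        assert r.weight == pytest.approx(2.0)

    def test_antiparallel_vectors(self):
        r = rank_similarity([1.0, -2.0, 3.0], [-1.0, 2.0, -3.0])
        assert r.sim == pytest.approx(-1.0)

    def test_zero_vector_not_contributing(self):
        r = rank_similarity([0, 0, 0], [1, 2, 3])
        assert not r.contributing

    def test_small_support_not_contributing(self):
        r = rank_similarity([1, 0, 0], [1, 0, 0])  # support 1 -> df -1
        assert not r.contributing

    def test_sigma_equals_sim_over_t(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            v = rng.normal(size=8)
            w = rng.normal(size=8)
            r = rank_similarity(v, w)
            if r.contributing and r.sim != 0:
                assert r.sigma == pytest.approx(r.sim / r.t, rel=1e-9)


def _rank(sim, weight, m, rank="genus"):
    sigma = 1.0 / weight
    return RankSimilarity(rank, sim, m, sim / sigma, sigma, weight, True)


class TestAggregateWeighted:
    def test_single_rank_degenerate_mean(self):
        agg = aggregate_weighted([_rank(0.37, 2.0, 5)])
        assert agg.sim_weighted == pytest.approx(0.37)

    def test_equal_weights_average(self):
        agg = aggregate_weighted([_rank(0.2, 1.0, 5), _rank(0.4, 1.0, 6, "phylum")])
        assert agg.sim_weighted == pytest.approx(0.3)

    def test_hand_evaluated_weighted_mean(self):
        agg = aggregate_weighted([_rank(0.0, 1.0, 5), _rank(0.4, 3.0, 6, "phylum")])
        assert agg.sim_weighted == pytest.approx(0.3)
        assert agg.sigma_bar == pytest.approx(0.5)  # sqrt(1/4)
        assert agg.df == 5 + 6 - 2

    def test_noncontributing_ranks_excluded(self):
        off = RankSimilarity("species", float("nan"), 1, float("nan"),
                             float("nan"), float("nan"), False)
        agg = aggregate_weighted([off, _rank(0.25, 2.0, 7)])
        assert agg.sim_weighted == pytest.approx(0.25)

    def test_no_contributing_rank_raises(self):
        off = RankSimilarity("species", float("nan"), 0, float("nan"),
                             float("nan"), float("nan"), False)
        with pytest.raises(ValueError, match="no contributing rank"):
            aggregate_weighted([off])

    def test_p_in_unit_interval(self):
        agg = aggregate_weighted([_rank(0.9, 5.0, 10)])
        assert 0.0 <= agg.p <= 1.0


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_ties_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_adjusted_at_least_raw_and_order_preserving(self):
        rng = np.random.default_rng(3)
        p = rng.random(40)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        assert ((p[:, None] <= p[None, :]) | (q[:, None] >= q[None, :] - 1e-15)).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestPairwiseSimilarity:
    @pytest.fixture
    def counts(self):
        rng = np.random.default_rng(42)
        _, tallies = random_instance(rng, max_entities=5, max_taxa=8)
        return make_counts(tallies)

    def test_within_mode_symmetric_matrix(self, counts):
        st = pairwise_similarity(counts)
        mat = st.matrix()
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T, atol=1e-12)

    def test_self_similarity_is_one(self, counts):
        st = pairwise_similarity(counts)
        df = st.table
        selfs = df[df.entity_i == df.entity_j]
        assert (selfs["sim_weighted"] == 1.0).all()
        assert selfs["fdr"].isna().all()  # excluded from the FDR family

    def test_cross_mode_pair_count(self):
        rng = np.random.default_rng(5)
        _, ta = random_instance(rng, max_entities=4)
        _, tb = random_instance(rng, max_entities=3)
        a, b = make_counts(ta), make_counts(tb)
        st = pairwise_similarity(a, b)
        assert len(st.table) == len(a.entities()) * len(b.entities())

    def test_weighted_sim_in_convex_hull_of_rank_sims(self, counts):
        st = pairwise_similarity(counts)
        df = st.table[st.table.entity_i != st.table.entity_j]
        sim_cols = [c for c in df.columns if c.startswith("sim_") and c != "sim_weighted"]
        for _, row in df.iterrows():
            sims = row[sim_cols].dropna().astype(float)
            if len(sims) and not np.isnan(row["sim_weighted"]):
                assert sims.min() - 1e-9 <= row["sim_weighted"] <= sims.max() + 1e-9

    def test_similarity_bounded(self, counts):
        st = pairwise_similarity(counts)
        vals = st.table["sim_weighted"].dropna()
        assert ((vals >= -1 - 1e-9) & (vals <= 1 + 1e-9)).all()

    def test_fdr_at_least_p(self, counts):
        df = pairwise_similarity(counts).table
        mask = df["fdr"].notna()
        assert (df.loc[mask, "fdr"] >= df.loc[mask, "p"] - 1e-15).all()

    def test_scale_invariance_of_rank_cosines(self):
        rng = np.random.default_rng(9)
        _, tallies = random_instance(rng)
        scaled = {
            rank: {k: (3 * ci, 3 * cd) for k, (ci, cd) in tally.items()}
            for rank, tally in tallies.items()
        }
        st1 = pairwise_similarity(make_counts(tallies))
        st2 = pairwise_similarity(make_counts(scaled))
        sim_cols = [c for c in st1.table.columns if c.startswith("sim_") and c != "sim_weighted"]
        for col in sim_cols:
            np.testing.assert_allclose(
                st1.table[col].to_numpy(dtype=float),
                st2.table[col].to_numpy(dtype=float),
                atol=1e-12, equal_nan=True,
            )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        _, tallies = random_instance(rng)
        renamed = {
            rank: {(e.replace("E", "Z"), t): v for (e, t), v in tally.items()}
            for rank, tally in tallies.items()
        }
        m1 = pairwise_similarity(make_counts(tallies)).matrix()
        m2 = pairwise_similarity(make_counts(renamed)).matrix()
        m2.index = [e.replace("Z", "E") for e in m2.index]
        m2.columns = [e.replace("Z", "E") for e in m2.columns]
        np.testing.assert_allclose(
            m1.to_numpy(), m2.loc[m1.index, m1.columns].to_numpy(), atol=1e-12
        )

    def test_matches_brute_force_oracle(self):
        """Vectorized pipeline == loop-and-dict re-derivation (50 instances)."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(50):
            entities, tallies = random_instance(rng)
            if not tallies:
                continue
            st = pairwise_similarity(make_counts(tallies))
            df = st.table[st.table.entity_i != st.table.entity_j]
            for row in df.itertuples():
                expected = oracle_weighted_similarity(tallies, row.entity_i, row.entity_j)
                if expected is None:
                    assert np.isnan(row.sim_weighted)
                else:
                    assert row.sim_weighted == pytest.approx(expected, abs=1e-10)
                    checked += 1
        assert checked > 100
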