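import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pitmud import CommunityTable, to_relative
from pitmud._errors import DataError
from pitmud import diversity as dv
from pitmud.phylo import parse_newick

from conftest import sparse_table


def table_of(columns: dict, taxa, relative=False):
    return CommunityTable(pd.DataFrame(columns, index=list(taxa)),
                          is_relative=relative)


class TestAlpha:
    def test_chao1_bias_corrected_formula(self):
        # 10 observed taxa: 5 singletons, 2 doubletons, 3 heavier
        counts = [1] * 5 + [2] * 2 + [5, 7, 9]
        t = table_of({"s": counts}, [f"t{i}" for i in range(10)])
        rec = dv.alpha_indices(t)
        assert rec.loc["s", "chao1"] == pytest.approx(10 + 5 * 4 / (2 * 3))
        assert rec.loc["s", "observed_richness"] == 10

    def test_chao1_reduces_to_richness_without_singletons(self):
        t = table_of({"s": [4, 5, 6]}, list("abc"))
        assert dv.alpha_indices(t).loc["s", "chao1"] == 3

    def test_uniform_sample_maximal_evenness(self):
        t = table_of({"s": [10] * 8}, [f"t{i}" for i in range(8)])
        rec = dv.alpha_indices(t)
        assert rec.loc["s", "shannon"] == pytest.approx(np.log(8))
        assert rec.loc["s", "pielou"] == pytest.approx(1.0)

    def test_single_taxon_zero_entropy(self):
        t = table_of({"s": [42]}, ["a"])
        assert dv.alpha_indices(t).loc["s", "shannon"] == 0.0

    def test_pielou_identity(self, small_counts):
        rec = dv.alpha_indices(small_counts)
        expect = rec["shannon"] / np.log(rec["observed_richness"])
        assert np.allclose(rec["pielou"].dropna(), expect.dropna())

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            dv.alpha_indices(table_of({"s": [0, 0]}, ["a", "b"]))


class TestTrend:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = dv.trend_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(1)
        hits = sum(
            dv.trend_regression(rng.normal(size=200), rng.normal(size=200)).p_value < 0.05
            for _ in range(1000))
        assert 0.03 < hits / 1000 < 0.07

    def test_degenerate_x_rejected(self):
        with pytest.raises(DataError):
            dv.trend_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = table_of({"a": [0.5, 0.5], "b": [0.5, 0.5]}, ["x", "y"], relative=True)
        assert dv.bray_curtis(t).values[0, 1] == 0.0

    def test_disjoint_samples_one(self):
        t = table_of({"a": [1.0, 0.0], "b": [0.0, 1.0]}, ["x", "y"], relative=True)
        assert dv.bray_curtis(t).values[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        t = table_of({"a": [0.75, 0.25], "b": [0.25, 0.75]}, ["x", "y"],
                     relative=True)
        assert dv.bray_curtis(t).values[0, 1] == pytest.approx(0.5)


class TestWeightedUnifrac:
    def test_identical_samples_zero(self, balanced_tree4):
        t = table_of({"a": [0.25] * 4, "b": [0.25] * 4}, list("ABCD"),
                     relative=True)
        assert dv.weighted_unifrac(t, balanced_tree4).values[0, 1] == pytest.approx(0.0)

    def test_star_tree_equals_bray_curtis(self, rng):
        taxa = [f"O{i}" for i in range(20)]
        star = parse_newick("(" + ",".join(f"{t}:1" for t in taxa) + ");")
        rel = to_relative(CommunityTable(pd.DataFrame(
            rng.integers(0, 50, (20, 8)) + 1, index=taxa,
            columns=[f"s{j}" for j in range(8)])))
        wu = dv.weighted_unifrac(rel, star)
        bc = dv.bray_curtis(rel)
        assert np.allclose(wu.values, bc.values, atol=1e-9)

    def test_four_tip_hand_enumeration(self, balanced_tree4):
        # k on {A,B}, m on {C,D}: every branch is fully unshared, so the
        # numerator equals the denominator: sum l_b |A_b - B_b| = 0.5+0.5
        # +1 (left clade) + 0.5+0.5+1 (right clade) = 4 = sum l_b(A_b+B_b)
        t = table_of({"k": [0.5, 0.5, 0, 0], "m": [0, 0, 0.5, 0.5]},
                     list("ABCD"), relative=True)
        assert dv.weighted_unifrac(t, balanced_tree4).values[0, 1] == pytest.approx(1.0)

    def test_partial_overlap_hand_enumeration(self, balanced_tree4):
        # k = {A: 1}, m = {A: .5, C: .5}: per-branch terms
        #   A(1): |1-.5| = .5   num; 1+.5 = 1.5 den
        #   B(1): 0 ; 0         AB(1): |1-.5|=.5 ; 1.5
        #   C(1): .5 ; .5       D(1): 0 ; 0     CD(1): .5 ; .5
        # num = 2.0, den = 4.0 -> 0.5
        t = table_of({"k": [1.0, 0, 0, 0], "m": [0.5, 0, 0.5, 0]},
                     list("ABCD"), relative=True)
        assert dv.weighted_unifrac(t, balanced_tree4).values[0, 1] == pytest.approx(0.5)

    def test_taxon_off_tree_is_hard_error(self, balanced_tree4):
        t = table_of({"a": [0.5, 0.5], "b": [0.5, 0.5]}, ["A", "Z"],
                     relative=True)
        with pytest.raises(Exception, match="Z"):
            dv.weighted_unifrac(t, balanced_tree4)


class TestNmds:
    def test_embeddable_input_low_stress(self, rng):
        pts = rng.normal(size=(12, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dist = dv.PairwiseMatrix([f"s{i}" for i in range(12)], d, "euclid")
        res = dv.nmds(dist, seed=0)
        assert res.stress <= 0.01

    def test_seed_determinism(self, small_counts):
        bc = dv.bray_curtis(to_relative(small_counts))
        a = dv.nmds(bc, seed=5)
        b = dv.nmds(bc, seed=5)
        assert np.allclose(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_cluster_separation_recovered(self, rng):
        pts = np.vstack([rng.normal(0, 0.3, (8, 4)), rng.normal(5, 0.3, (8, 4))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dist = dv.PairwiseMatrix([f"s{i}" for i in range(16)], d, "euclid")
        coords = dv.nmds(dist, seed=1).coordinates.to_numpy()
        within = np.linalg.norm(coords[:8] - coords[:8].mean(0), axis=1).mean()
        between = np.linalg.norm(coords[:8].mean(0) - coords[8:].mean(0))
        assert between > within

    def test_small_n_rejected(self):
        dist = dv.PairwiseMatrix(["a", "b"], np.zeros((2, 2)), "m")
        with pytest.raises(DataError):
            dv.nmds(dist, seed=0)


class TestPermanova:
    def _dist_frame(self, rng, n=12):
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(n)]
        return dv.PairwiseMatrix(ids, d, "euclid"), ids

    def test_one_way_pseudo_f_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova
        dist, ids = self._dist_frame(rng)
        frame = pd.DataFrame({"g": ["A"] * 6 + ["B"] * 6}, index=ids)
        mine = dv.permanova(dist, frame, ["g"], n_perm=99, seed=0)
        ref = sk_permanova(DistanceMatrix(dist.values, ids),
                           frame["g"].tolist(), permutations=99)
        assert mine.terms["g"]["pseudo_F"] == pytest.approx(
            ref["test statistic"], rel=1e-10)

    def test_r2_partition_sums_to_one(self, rng):
        dist, ids = self._dist_frame(rng)
        frame = pd.DataFrame({"g": ["A", "B"] * 6, "h": ["X"] * 4 + ["Y"] * 8},
                             index=ids)
        res = dv.permanova(dist, frame, ["g", "h"], n_perm=99, seed=0)
        total = sum(t["r2_fraction"] for t in res.terms.values())
        assert total + res.residual["r2_fraction"] == pytest.approx(1.0, abs=1e-9)

    def test_perfect_separation(self):
        # two tight groups far apart: group explains ~everything
        pts = np.vstack([np.zeros((6, 2)), np.full((6, 2), 10.0)])
        pts += np.random.default_rng(0).normal(0, 1e-3, pts.shape)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(12)]
        frame = pd.DataFrame({"g": ["A"] * 6 + ["B"] * 6}, index=ids)
        res = dv.permanova(dv.PairwiseMatrix(ids, d, "m"), frame, ["g"],
                           n_perm=199, seed=1)
        assert res.terms["g"]["r2_fraction"] > 0.999
        assert res.terms["g"]["p_value"] <= 1 / 200 + 1e-12

    def test_single_level_term_rejected(self, rng):
        dist, ids = self._dist_frame(rng)
        frame = pd.DataFrame({"g": ["A"] * 12}, index=ids)
        with pytest.raises(DataError):
            dv.permanova(dist, frame, ["g"], n_perm=99, seed=0)


class TestGroupSummaries:
    def test_identical_samples_degenerate_at_zero(self):
        ids = [f"s{i}" for i in range(6)]
        dist = dv.PairwiseMatrix(ids, np.zeros((6, 6)), "m")
        frame = pd.DataFrame({"age_group": ["Aa"] * 3 + ["Ab"] * 3}, index=ids)
        out = dv.group_dissimilarity(dist, frame)
        assert all((v == 0).all() for v in out["within"].values())

    def test_single_sample_group_error_names_group(self, rng):
        pts = rng.normal(size=(5, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(5)]
        frame = pd.DataFrame({"age_group": ["Aa", "Aa", "Ab", "Ab", "Ac"]},
                             index=ids)
        with pytest.raises(DataError, match="Ac"):
            dv.group_dissimilarity(dv.PairwiseMatrix(ids, d, "m"), frame)

    def test_designed_dispersion_decrease_recovered(self, rng):
        # groups with shrinking within-group spread -> shrinking medians
        frames, mats = [], []
        ids, groups, pts = [], [], []
        for gi, (g, scale) in enumerate(zip(["Aa", "Ab", "Ac", "Ad"],
                                            [4.0, 2.0, 1.0, 0.5])):
            for k in range(6):
                ids.append(f"{g}_{k}")
                groups.append(g)
                pts.append(rng.normal(0, scale, 3))
        pts = np.array(pts)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        frame = pd.DataFrame({"age_group": groups}, index=ids)
        out = dv.group_dissimilarity(dv.PairwiseMatrix(ids, d, "m"), frame)
        med = [out["medians"][g] for g in ["Aa", "Ab", "Ac", "Ad"]]
        assert med == sorted(med, reverse=True)
        assert out["median_trend"].slope < 0


class TestTaxonOverlap:
    def _tax(self, taxa):
        from pitmud.table import RANKS
        return pd.DataFrame({r: list(taxa) for r in RANKS}, index=list(taxa))

    def test_identical_groups_no_unique(self):
        t = sparse_table("abcdef", 6, seed=1, density=1.0)
        frame = pd.DataFrame({"g": ["X"] * 3 + ["Y"] * 3}, index=t.sample_ids)
        out = dv.taxon_overlap(t, self._tax("abcdef"), "genus", frame, "g")
        assert out["unique"] == {"X": set(), "Y": set()}

    def test_disjoint_groups_all_unique(self):
        df = pd.DataFrame({"s1": [5, 0], "s2": [0, 7]}, index=["a", "b"])
        t = CommunityTable(df)
        frame = pd.DataFrame({"g": ["X", "Y"]}, index=["s1", "s2"])
        out = dv.taxon_overlap(t, self._tax("ab"), "genus", frame, "g")
        assert out["unique"]["X"] == {"a"} and out["unique"]["Y"] == {"b"}

    def test_partition_sizes_sum_to_total(self, rng):
        t = sparse_table("abcdefghij", 9, seed=2, density=0.4)
        frame = pd.DataFrame({"g": ["X"] * 3 + ["Y"] * 3 + ["Z"] * 3},
                             index=t.sample_ids)
        out = dv.taxon_overlap(t, self._tax("abcdefghij"), "genus", frame, "g")
        total = set().union(*out["present"].values())
        assert sum(len(s) for s in out["partition"].values()) == len(total)


class TestGroupAlphaTest:
    def test_shifted_group_detected(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(10, 1, 10)])
        alpha = pd.DataFrame({"shannon": vals},
                             index=[f"s{i}" for i in range(20)])
        frame = pd.DataFrame({"g": ["A"] * 10 + ["B"] * 10}, index=alpha.index)
        anova, pairwise = dv.group_alpha_test(alpha, frame, "g")
        assert anova["p_value"] < 1e-6
        assert (pairwise["p-adj"] < 0.05).all()

    def test_two_group_tukey_equals_t_test(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)])
        alpha = pd.DataFrame({"shannon": vals},
                             index=[f"s{i}" for i in range(24)])
        frame = pd.DataFrame({"g": ["A"] * 12 + ["B"] * 12}, index=alpha.index)
        _, pairwise = dv.group_alpha_test(alpha, frame, "g")
        t_p = sps.ttest_ind(vals[:12], vals[12:]).pvalue
        assert pairwise["p-adj"].iloc[0] == pytest.approx(t_p, abs=1e-3)
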