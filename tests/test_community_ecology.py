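import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from gutweb.community_ecology import (
    DistanceMatrix,
    betadisper,
    bray_curtis,
    patristic_matrix,
    pcoa,
    permanova,
)
from gutweb.synthetic_data import make_truth, simulate_counts, simulate_tree
from gutweb.tabular_io import tree_from_newick
from tests.conftest import make_table


def euclidean_dm(points, labels=None):
    points = np.asarray(points, float)
    labels = labels or [f"S{i}" for i in range(len(points))]
    return DistanceMatrix(labels=labels, values=squareform(pdist(points)))


class TestBrayCurtis:
    def test_identical_rows_have_zero_distance(self):
        d = bray_curtis(make_table([[1, 2, 3], [1, 2, 3]]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_supports_have_distance_one(self):
        d = bray_curtis(make_table([[5, 0, 0], [0, 3, 2]]))
        assert d.values[0, 1] == 1.0

    def test_worked_example(self):
        d = bray_curtis(make_table([[1, 2, 3], [3, 2, 1]]))
        assert d.values[0, 1] == pytest.approx(4 / 12)

    def test_zero_total_sample_errors(self):
        with pytest.raises(ValueError, match="zero-total"):
            bray_curtis(make_table([[1, 2], [0, 0]]))

    def test_values_within_unit_interval(self, rng):
        d = bray_curtis(make_table(rng.integers(0, 50, (15, 20)) + 1))
        assert np.all(d.values >= 0) and np.all(d.values <= 1)


class TestPcoa:
    def test_planar_points_are_reconstructed(self):
        pts = np.array([[0, 0], [3, 0], [0, 4], [3, 4]], float)
        d = euclidean_dm(pts)
        res = pcoa(d, k=2)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(rec, d.values, atol=1e-8)

    def test_two_points_sit_symmetric_on_one_axis(self):
        d = DistanceMatrix(labels=["a", "b"],
                           values=np.array([[0.0, 2.0], [2.0, 0.0]]))
        with pytest.warns(UserWarning):
            res = pcoa(d, k=2)  # only one positive eigenvalue exists
        coords = np.sort(res.coordinates.to_numpy().ravel())
        np.testing.assert_allclose(coords, [-1.0, 1.0], atol=1e-10)

    def test_euclidean_input_has_no_negative_eigenvalues(self, rng):
        d = euclidean_dm(rng.standard_normal((10, 3)))
        res = pcoa(d, k=3)
        assert res.negative_eigenvalues.size == 0

    def test_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.standard_normal((12, 4))
        d = euclidean_dm(pts)
        mine = pcoa(d, k=3).coordinates.to_numpy()
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=d.labels)
        ).samples.to_numpy()[:, :3]
        # eigenvector sign is arbitrary: compare column-by-column up to sign
        for k in range(3):
            assert np.allclose(mine[:, k], ref[:, k], atol=1e-6) or \
                np.allclose(mine[:, k], -ref[:, k], atol=1e-6)


class TestBetadisper:
    def test_translated_clouds_have_equal_dispersion(self, rng):
        cloud = rng.standard_normal((10, 3))
        pts = np.vstack([cloud, cloud + 50.0])
        d = euclidean_dm(pts)
        groups = ["g1"] * 10 + ["g2"] * 10
        res = betadisper(d, groups, n_perm=99, seed=0)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-9)

    def test_identical_distances_give_p_one(self):
        # perfectly symmetric square: all points equidistant from centers
        pts = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], float)
        d = euclidean_dm(pts)
        res = betadisper(d, ["a", "a", "b", "b"], n_perm=199, seed=1)
        assert res.p_value == 1.0

    def test_detects_dispersion_difference(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tight = rng.standard_normal((20, 3)) * 1.0
            wide = rng.standard_normal((20, 3)) * 5.0
            d = euclidean_dm(np.vstack([tight, wide]))
            res = betadisper(d, ["t"] * 20 + ["w"] * 20, n_perm=199, seed=seed)
            hits += res.p_value <= 0.05
        assert hits >= 95

    def test_singleton_group_rejected(self, rng):
        d = euclidean_dm(rng.standard_normal((5, 2)))
        with pytest.raises(ValueError, match="size 1"):
            betadisper(d, ["a", "a", "a", "a", "b"])

    def test_matches_vegan_on_euclidean_toy(self, rng, tmp_path):
        pts = rng.standard_normal((15, 4))
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        d = euclidean_dm(pts)
        res = betadisper(d, groups, n_perm=9, seed=0)
        pd.DataFrame(d.values, index=d.labels, columns=d.labels).to_csv(
            tmp_path / "d.tsv", sep="\t")
        pd.DataFrame({"g": groups}, index=d.labels).to_csv(
            tmp_path / "g.tsv", sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            d <- as.dist(as.matrix(read.table("{tmp_path}/d.tsv", header=TRUE,
                                              row.names=1, check.names=FALSE)))
            g <- read.table("{tmp_path}/g.tsv", header=TRUE, row.names=1)$g
            mod <- betadisper(d, g)
            f <- anova(mod)$`F value`[1]
            cat(sprintf("%.10f", f))
        """)
        try:
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, timeout=120)
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        assert out.returncode == 0, out.stderr
        assert res.f_statistic == pytest.approx(float(out.stdout), rel=1e-4)


class TestPermanova:
    def two_group_toy(self):
        pts = np.array([[0, 0], [1, 0], [0, 1],
                        [5, 5], [6, 5], [5, 6]], float)
        d = euclidean_dm(pts)
        factors = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3}, index=d.labels)
        return d, factors

    def test_identical_group_profiles_give_null_result(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [1, 1], [2, 2]], float)
        d = euclidean_dm(pts)
        factors = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3}, index=d.labels)
        res = permanova(d, factors, ["g"], n_perm=99, seed=0)
        assert res.table.loc["g", "F"] == pytest.approx(0.0, abs=1e-9)
        assert res.table.loc["g", "p"] == 1.0

    def test_f_matches_hand_sum_of_squares(self):
        d, factors = self.two_group_toy()
        res = permanova(d, factors, ["g"], n_perm=9, seed=0)
        sq = d.values ** 2
        ss_total = sq[np.triu_indices(6, 1)].sum() / 6
        ss_within = (sq[:3, :3][np.triu_indices(3, 1)].sum() / 3
                     + sq[3:, 3:][np.triu_indices(3, 1)].sum() / 3)
        ss_between = ss_total - ss_within
        f_hand = (ss_between / 1) / (ss_within / 4)
        assert res.table.loc["g", "SS"] == pytest.approx(ss_between)
        assert res.table.loc["g", "F"] == pytest.approx(f_hand)

    def test_monte_carlo_p_matches_full_enumeration(self):
        d, factors = self.two_group_toy()
        res = permanova(d, factors, ["g"], n_perm=719, seed=3)
        # exact reference distribution over all 720 relabelings
        f_obs = res.table.loc["g", "F"]
        fs = []
        for perm in itertools.permutations(range(6)):
            dp = d.values[np.ix_(perm, perm)]
            r = permanova(DistanceMatrix(labels=d.labels, values=dp),
                          factors, ["g"], n_perm=1, seed=0)
            fs.append(r.table.loc["g", "F"])
        p_exact = np.mean(np.asarray(fs) >= f_obs - 1e-9 * max(1.0, abs(f_obs)))
        se = np.sqrt(p_exact * (1 - p_exact) / 719)
        assert abs(res.table.loc["g", "p"] - p_exact) <= 2 * se + 1 / 720

    def test_r2_components_sum_to_one(self, rng):
        d = euclidean_dm(rng.standard_normal((18, 4)))
        factors = pd.DataFrame({
            "host": rng.choice(["f", "l", "s"], 18),
            "geo": rng.choice(["x", "y"], 18),
        }, index=d.labels)
        res = permanova(d, factors, ["host", "geo", "host:geo"],
                        n_perm=49, seed=0)
        non_total = res.table.loc[res.table.index != "Total", "R2"]
        assert non_total.sum() == pytest.approx(1.0, abs=1e-9)

    def test_f_invariant_to_sample_reordering(self, rng):
        d = euclidean_dm(rng.standard_normal((12, 3)))
        factors = pd.DataFrame({"g": rng.choice(["a", "b", "c"], 12)},
                               index=d.labels)
        res1 = permanova(d, factors, ["g"], n_perm=9, seed=0)
        order = list(rng.permutation(d.labels))
        d2 = DistanceMatrix(
            labels=order,
            values=pd.DataFrame(d.values, index=d.labels,
                                columns=d.labels).loc[order, order].to_numpy())
        res2 = permanova(d2, factors, ["g"], n_perm=9, seed=0)
        assert res1.table.loc["g", "F"] == pytest.approx(
            res2.table.loc["g", "F"])

    def test_saturated_model_rejected(self):
        d, factors = self.two_group_toy()
        factors["id"] = [f"u{k}" for k in range(6)]
        with pytest.raises(ValueError, match="residual"):
            permanova(d, factors, ["id"], n_perm=9, seed=0)

    def test_planted_group_effect_is_detected_with_power(self):
        hits = 0
        n_rep = 25
        for seed in range(n_rep):
            truth = make_truth(p=60, density=0.02, n_modules=6, seed=seed,
                               group_effect_fraction=0.10,
                               group_effect_multiplier=3.0)
            table, meta = simulate_counts(truth, 30, depth_mean=5000,
                                          balanced_groups=True)
            d = bray_curtis(table)
            factors = meta.data.loc[d.labels, ["host_group"]]
            res = permanova(d, factors, ["host_group"], n_perm=199, seed=seed)
            hits += res.table.loc["host_group", "p"] <= 0.05
        assert hits / n_rep >= 0.8

    def test_matches_vegan_adonis_sequential_terms(self, rng, tmp_path):
        d = euclidean_dm(rng.standard_normal((16, 5)))
        factors = pd.DataFrame({
            "host": rng.choice(["f", "l"], 16),
            "geo": rng.choice(["x", "y"], 16),
        }, index=d.labels)
        res = permanova(d, factors, ["host", "geo", "host:geo"],
                        n_perm=9, seed=0)
        pd.DataFrame(d.values, index=d.labels, columns=d.labels).to_csv(
            tmp_path / "d.tsv", sep="\t")
        factors.to_csv(tmp_path / "m.tsv", sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            d <- as.dist(as.matrix(read.table("{tmp_path}/d.tsv", header=TRUE,
                                              row.names=1, check.names=FALSE)))
            m <- read.table("{tmp_path}/m.tsv", header=TRUE, row.names=1)
            res <- adonis2(d ~ host + geo + host:geo, data=m,
                           permutations=2, by="terms")
            cat(sprintf("%.10f %.10f %.10f %.10f %.10f %.10f",
                res$SumOfSqs[1], res$SumOfSqs[2], res$SumOfSqs[3],
                res$F[1], res$F[2], res$F[3]))
        """)
        try:
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, timeout=120)
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        assert out.returncode == 0, out.stderr
        ss1, ss2, ss3, f1, f2, f3 = map(float, out.stdout.split())
        assert res.table.loc["host", "SS"] == pytest.approx(ss1, rel=1e-6)
        assert res.table.loc["geo", "SS"] == pytest.approx(ss2, rel=1e-6)
        assert res.table.loc["host:geo", "SS"] == pytest.approx(ss3, rel=1e-6)
        assert res.table.loc["host", "F"] == pytest.approx(f1, rel=1e-6)
        assert res.table.loc["geo", "F"] == pytest.approx(f2, rel=1e-6)
        assert res.table.loc["host:geo", "F"] == pytest.approx(f3, rel=1e-6)


class TestPatristic:
    def test_sibling_tips(self):
        d = patristic_matrix(tree_from_newick("(A:1,B:2);"))
        df = d.to_frame()
        assert df.loc["A", "B"] == pytest.approx(3.0)

    def test_path_summation_by_hand(self):
        d = patristic_matrix(tree_from_newick("((A:1,B:1):2,C:4);")).to_frame()
        assert d.loc["A", "C"] == pytest.approx(7.0)
        assert d.loc["A", "B"] == pytest.approx(2.0)

    def test_four_point_condition_on_random_trees(self):
        for seed in range(5):
            tree = simulate_tree(8, seed=seed)
            d = patristic_matrix(tree).values
            for q in itertools.combinations(range(8), 4):
                i, j, k, l = q
                sums = sorted([d[i, j] + d[k, l], d[i, k] + d[j, l],
                               d[i, l] + d[j, k]])
                assert sums[2] - sums[1] <= 1e-9
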