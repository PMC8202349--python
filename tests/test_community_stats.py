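"""Thresholding, log normalization, partial RDA, IndVal and Kruskal-Wallis."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest

from peatmob.community_stats import (
    StatsParams,
    design_matrices,
    indval,
    kruskal_wallis,
    log_normalize,
    partial_rda,
    permutation_test,
    threshold_relative_abundance,
    to_relative_abundance,
)
from peatmob.synthetic_data import CommunityDesign, PlantedIndicator, simulate_community_counts


def df(values, prefix="otu"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values,
                        index=[f"s{i}" for i in range(values.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(values.shape[1])])


class TestThreshold:
    def test_below_threshold_zeroed_boundary_kept(self):
        M = df([[0.0009, 0.001, 0.5]])
        out = threshold_relative_abundance(M)
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == 0.001  # strict inequality
        assert out.iloc[0, 2] == 0.5

    def test_all_zero_columns_counted_by_scan(self, rng):
        M = df(rng.uniform(0, 0.01, size=(10, 30)))
        out = threshold_relative_abundance(M)
        brute = sum((M.values[:, j] < 0.001).all() for j in range(30))
        assert (out.sum(axis=0) == 0).sum() == brute


class TestLogNormalize:
    def test_zero_stays_zero_and_log2(self):
        M = df([[0.0, 8.0, 1.0]])
        out = log_normalize(M)
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == pytest.approx(4.0)  # log2(8) + 1
        assert out.iloc[0, 2] == pytest.approx(1.0)

    def test_non_integer_matrix_prediv_maps_min_to_one(self):
        M = df([[0.001, 0.01, 0.0]])
        out = log_normalize(M)
        assert out.iloc[0, 0] == pytest.approx(1.0)
        assert out.iloc[0, 1] == pytest.approx(np.log2(10) + 1)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            log_normalize(df([[-1.0, 2.0]]))


class TestPartialRDA:
    def test_constant_x_gives_zero_constrained(self, rng):
        Y = df(rng.normal(size=(10, 4)))
        fit = partial_rda(Y, {"const": np.ones((10, 1))})
        assert fit.constrained_inertia == pytest.approx(0.0, abs=1e-12)

    def test_group_mean_response_fully_constrained(self):
        groups = np.array([0] * 5 + [1] * 5)
        v = np.array([1.0, -2.0, 0.5])
        Y = df(np.outer(groups, v))
        X = {"g": groups[:, None].astype(float)}
        fit = partial_rda(Y, X)
        assert fit.unconstrained_inertia == pytest.approx(0.0, abs=1e-12)
        assert fit.eigenvalues[0] == pytest.approx(fit.constrained_inertia)

    def test_inertia_decomposition_sums_to_total(self, rng):
        Y = df(rng.normal(size=(16, 8)))
        X = {"a": rng.normal(size=(16, 2)), "b": rng.normal(size=(16, 1))}
        Z = rng.integers(0, 2, size=(16, 1)).astype(float)
        fit = partial_rda(Y, X, Z)
        total = fit.conditioned_inertia + fit.constrained_inertia + fit.unconstrained_inertia
        assert total == pytest.approx(fit.total_inertia, rel=1e-9)
        eig = fit.eigenvalues
        assert (np.diff(eig) <= 1e-12).all() and (eig >= 0).all()

    def test_aliased_term_raises(self, rng):
        Y = df(rng.normal(size=(10, 3)))
        x = rng.normal(size=(10, 1))
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            partial_rda(Y, {"x": x, "dup": x.copy()})

    def test_matches_vegan_reference_implementation(self, tmp_path, rng):
        """Independent cross-check of the whole RDA decomposition against
        the R vegan package on a small random dataset."""
        n = 12
        Y = df(np.round(rng.normal(10, 2, size=(n, 5)), 4))
        meta = pd.DataFrame({
            "treatment": ["grazed", "exclosed"] * 6,
            "site": ["SV1"] * 6 + ["SV2"] * 6,
        }, index=Y.index)
        Y.to_csv(tmp_path / "Y.csv")
        meta.to_csv(tmp_path / "meta.csv")
        rscript = f"""
        suppressMessages(library(vegan))
        Y <- read.csv("{tmp_path}/Y.csv", row.names=1)
        meta <- read.csv("{tmp_path}/meta.csv", row.names=1)
        fit <- rda(Y ~ treatment + Condition(site), data=meta)
        cat(fit$tot.chi, fit$pCCA$tot.chi, fit$CCA$tot.chi, fit$CA$tot.chi,
            fit$CCA$eig, sep="\\n")
        """
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, check=True)
        vals = [float(x) for x in out.stdout.split()]
        blocks, Z = design_matrices(meta, terms=("treatment",), condition="site")
        fit = partial_rda(Y, blocks, Z)
        assert fit.total_inertia == pytest.approx(vals[0], rel=1e-6)
        assert fit.conditioned_inertia == pytest.approx(vals[1], rel=1e-6)
        assert fit.constrained_inertia == pytest.approx(vals[2], rel=1e-6)
        assert fit.unconstrained_inertia == pytest.approx(vals[3], rel=1e-6)
        assert fit.eigenvalues[0] == pytest.approx(vals[4], rel=1e-6)


class TestPermutationTest:
    def test_saturated_effect_reaches_p_floor(self, rng):
        # a continuous driver, so no non-identity permutation reproduces F
        x = rng.normal(size=12)
        Y = df(np.outer(x, [3.0, -1.0, 2.0]) + rng.normal(0, 0.01, (12, 3)))
        fit = partial_rda(Y, {"x": x[:, None]})
        res = permutation_test(fit, StatsParams(n_permutations=999), seed=0)
        assert res.loc["x", "p"] == pytest.approx(1 / 1000)

    def test_pvalues_bounded_below_by_grid(self, rng):
        Y = df(rng.normal(size=(10, 4)))
        fit = partial_rda(Y, {"x": rng.normal(size=(10, 1))})
        res = permutation_test(fit, StatsParams(n_permutations=99), seed=1)
        assert (res["p"] >= 1 / 100).all()

    def test_zero_permutations_disallowed(self):
        with pytest.raises(ValueError):
            StatsParams(n_permutations=0)

    def test_model_and_axis_scopes_run(self, rng):
        Y = df(rng.normal(size=(12, 5)))
        X = {"x": rng.normal(size=(12, 2))}
        fit = partial_rda(Y, X)
        model = permutation_test(fit, StatsParams(n_permutations=49), "model", seed=2)
        axes = permutation_test(fit, StatsParams(n_permutations=49), "axes", seed=2)
        assert set(model.index) == {"model"}
        assert list(axes.index)[0] == "RDA1"
        assert ((axes["p"] > 0) & (axes["p"] <= 1)).all()


class TestIndval:
    def test_perfect_indicator(self):
        M = df([[4.0], [4.0], [0.0], [0.0]])
        out = indval(M, ["G1", "G1", "G2", "G2"],
                     StatsParams(n_permutations=99), seed=0)
        row = out.iloc[0]
        assert row["A"] == 1.0 and row["B"] == 1.0 and row["indval"] == 1.0
        assert row["group"] == "G1"

    def test_half_occupancy_hand_computation(self):
        # abundances (4,0 | 4,0): A = 0.5, B = 0.5, indval = 0.25 in each group
        M = df([[4.0], [0.0], [4.0], [0.0]])
        out = indval(M, ["G1", "G1", "G2", "G2"],
                     StatsParams(n_permutations=99), seed=0)
        assert out.iloc[0]["indval"] == pytest.approx(0.25)

    def test_exact_p_equals_exhaustive_enumeration(self, rng):
        M = df(rng.uniform(0, 1, size=(4, 3)))
        labels = ["G1", "G1", "G2", "G2"]
        out = indval(M, labels, method="exact")

        # oracle: recompute statistic naively for all 4! sample orderings
        X = M.to_numpy()
        def naive_stat(order):
            Xp = X[list(order)]
            stats = []
            for j in range(X.shape[1]):
                ivs = []
                for g in ("G1", "G2"):
                    idx = [i for i, l in enumerate(labels) if l == g]
                    mean_in = np.mean([Xp[i, j] for i in idx])
                    means = [np.mean([Xp[i, j] for i, l in enumerate(labels) if l == gg])
                             for gg in ("G1", "G2")]
                    A = mean_in / sum(means) if sum(means) > 0 else 0.0
                    B = np.mean([Xp[i, j] > 0 for i in idx])
                    ivs.append(A * B)
                stats.append(max(ivs))
            return np.array(stats)

        obs = naive_stat(range(4))
        exceed = np.zeros(3)
        count = 0
        for perm in itertools.permutations(range(4)):
            exceed += naive_stat(perm) > obs
            count += 1
        expected_p = (1 + exceed) / (1 + count)
        assert np.allclose(out["p"].to_numpy(), expected_p)

    def test_invariant_to_single_sample_depth(self, rng):
        counts = df(rng.integers(0, 50, size=(6, 5)).astype(float))
        counts.iloc[0] += 1  # avoid zero rows
        labels = ["G1"] * 3 + ["G2"] * 3
        rel1 = to_relative_abundance(counts)
        scaled = counts.copy()
        scaled.iloc[2] *= 10  # one sample sequenced 10x deeper
        rel2 = to_relative_abundance(scaled)
        out1 = indval(rel1, labels, StatsParams(n_permutations=49), seed=3)
        out2 = indval(rel2, labels, StatsParams(n_permutations=49), seed=3)
        assert np.allclose(out1["indval"], out2["indval"])

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            indval(df([[1.0], [2.0]]), ["G1", "G1"])


class TestKruskalWallis:
    def test_complete_separation_hand_ranked(self):
        H, p = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert H == pytest.approx(3.857, abs=1e-3)

    def test_identical_constant_groups(self):
        H, p = kruskal_wallis([2.0, 2.0], [2.0, 2.0])
        assert H == 0.0 and p == 1.0

    def test_matches_direct_rank_formula(self, rng):
        g1 = rng.normal(size=9).tolist()
        g2 = rng.normal(size=7).tolist()
        g3 = rng.normal(size=8).tolist()
        H, _ = kruskal_wallis(g1, g2, g3)
        allv = np.array(g1 + g2 + g3)
        ranks = allv.argsort().argsort() + 1.0  # no ties with continuous draws
        n = len(allv)
        sizes = [9, 7, 8]
        splits = np.split(ranks, np.cumsum(sizes)[:-1])
        brute = 12.0 / (n * (n + 1)) * sum(
            len(g) * (g.mean() - (n + 1) / 2) ** 2 for g in splits)
        assert H == pytest.approx(brute)


class TestPipelineRecovery:
    def test_planted_bioindicators_recovered(self):
        design = CommunityDesign(
            dates=("summer2015",), replicates_per_cell=5, n_background_otus=30,
            planted_bioindicators=(PlantedIndicator(0, "grazed", 8.0),
                                   PlantedIndicator(1, "exclosed", 8.0)),
            seed=7)
        counts, meta = simulate_community_counts(design)
        thr = threshold_relative_abundance(to_relative_abundance(counts))
        out = indval(thr, meta["treatment"].tolist(),
                     StatsParams(n_permutations=2999), seed=7)
        flagged = set(out[out["p"] < 0.001].index)
        assert flagged == {"planted_0", "planted_1"}
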