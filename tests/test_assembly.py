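import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

from ecoassembly.assembly import (
    beta_nti,
    bmntd,
    classify_process,
    mntd,
    nti,
    summarize_processes,
)
from ecoassembly.phylo import cophenetic, write_newick
from ecoassembly.synthetic import simulate_tree

from conftest import make_table


def star_dm(ids, r=1.0):
    n = len(ids)
    d = np.full((n, n), 2 * r)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(ids))


class TestMntd:
    def test_two_taxon_community(self):
        d = DistanceMatrix([[0, 2], [2, 0]], ids=["A", "B"])
        assert mntd([1, 1], d) == pytest.approx(2.0)

    def test_three_taxon_hand_enumeration(self):
        d = DistanceMatrix(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=["A", "B", "C"]
        )
        # nearest neighbours: A->B (2), B->A (2), C->A or B (4)
        assert mntd([1, 1, 1], d) == pytest.approx(8 / 3)

    def test_weighted_limit_concentrates_on_pair(self):
        d = DistanceMatrix(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=["A", "B", "C"]
        )
        v = mntd([1000, 1000, 1], d, weighted=True)
        assert v == pytest.approx(2.0, abs=0.01)

    def test_single_taxon_rejected(self):
        d = DistanceMatrix([[0, 2], [2, 0]], ids=["A", "B"])
        with pytest.raises(ValueError, match="<2 taxa"):
            mntd([1, 0], d)


class TestBmntd:
    def test_identical_communities_are_zero(self, six_tip_dm):
        c = [1, 2, 0, 3, 0, 0]
        assert bmntd(c, c, six_tip_dm) == pytest.approx(0.0)

    def test_singleton_pair(self):
        d = DistanceMatrix([[0, 2], [2, 0]], ids=["A", "B"])
        assert bmntd([1, 0], [0, 1], d) == pytest.approx(2.0)

    def test_matches_brute_force_double_loop(self, six_tip_dm):
        rng = np.random.default_rng(0)
        m = six_tip_dm.data
        for _ in range(10):
            x = rng.integers(0, 5, 6)
            y = rng.integers(0, 5, 6)
            if x.sum() == 0 or y.sum() == 0:
                continue
            px, py = np.flatnonzero(x), np.flatnonzero(y)
            wx, wy = x[px] / x[px].sum(), y[py] / y[py].sum()
            expected = 0.5 * (
                sum(w * min(m[i, j] for j in py) for w, i in zip(wx, px))
                + sum(w * min(m[i, j] for i in px) for w, j in zip(wy, py))
            )
            assert bmntd(x, y, six_tip_dm) == pytest.approx(expected)

    @given(
        st.lists(st.integers(min_value=0, max_value=9), min_size=6, max_size=6),
        st.lists(st.integers(min_value=0, max_value=9), min_size=6, max_size=6),
        st.booleans(),
    )
    @settings(max_examples=40, deadline=None)
    def test_symmetry(self, x, y, weighted):
        if sum(x) == 0 or sum(y) == 0:
            return
        tree = simulate_tree(6, seed=13)
        d = cophenetic(tree)
        assert bmntd(x, y, d, weighted) == pytest.approx(
            bmntd(y, x, d, weighted)
        )


def exhaustive_null_mntd(dmat, present_idx, pool_positions, weights=None):
    """Independent oracle: MNTD under every permutation of pool labels."""
    vals = []
    k = len(pool_positions)
    for perm in itertools.permutations(range(k)):
        pos = pool_positions[np.array(perm)][present_idx]
        sub = dmat[np.ix_(pos, pos)].copy()
        np.fill_diagonal(sub, np.inf)
        mins = sub.min(axis=1)
        vals.append(
            float(mins.mean()) if weights is None else float(weights @ mins)
        )
    return np.array(vals)


class TestNti:
    def test_closest_pair_on_ladder_is_clustered(self, six_tip_ladder):
        d = cophenetic(six_tip_ladder)
        t = make_table({"s": [int(i in ("A", "B")) for i in d.ids]}, list(d.ids))
        res = nti(t, d, runs="exhaustive", null_pool=list(d.ids))
        assert res.loc["s", "nti"] > 0

    def test_most_distant_pair_is_overdispersed(self, six_tip_ladder):
        d = cophenetic(six_tip_ladder)
        t = make_table({"s": [int(i in ("A", "F")) for i in d.ids]}, list(d.ids))
        res = nti(t, d, runs="exhaustive", null_pool=list(d.ids))
        assert res.loc["s", "nti"] < 0

    def test_exhaustive_matches_independent_enumeration(self, six_tip_dm):
        d = six_tip_dm
        counts = pd.Series([3, 1, 0, 2, 0, 0], index=list(d.ids))
        t = make_table({"s": counts.values}, list(d.ids))
        res = nti(t, d, runs="exhaustive", null_pool=list(d.ids))
        vals = exhaustive_null_mntd(d.data, np.flatnonzero(counts.values),
                                    np.arange(6))
        assert res.loc["s", "null_mean"] == pytest.approx(vals.mean())
        assert res.loc["s", "null_sd"] == pytest.approx(vals.std(ddof=0))

    def test_saturated_community_has_undefined_nti(self, six_tip_dm):
        t = make_table({"s": [1] * 6}, list(six_tip_dm.ids))
        res = nti(t, six_tip_dm, runs=25, seed=0)
        assert np.isnan(res.loc["s", "nti"])
        assert "undefined" in res.loc["s", "note"]

    def test_seeded_determinism(self, six_tip_dm):
        t = make_table({"s": [1, 1, 0, 1, 0, 0]}, list(six_tip_dm.ids))
        r1 = nti(t, six_tip_dm, runs=99, seed=5)
        r2 = nti(t, six_tip_dm, runs=99, seed=5)
        pd.testing.assert_frame_equal(r1, r2)


class TestBetaNti:
    def test_identical_pair_has_degenerate_null(self, six_tip_dm):
        # a tip relabeling maps both communities identically, so every null
        # betaMNTD of an identical pair is 0 and betaNTI is undefined
        t = make_table(
            {"x": [1, 1, 1, 0, 0, 0], "y": [1, 1, 1, 0, 0, 0]},
            list(six_tip_dm.ids),
        )
        res = beta_nti(t, six_tip_dm, runs="exhaustive")
        assert res.loc[0, "bmntd_obs"] == pytest.approx(0.0)
        assert np.isnan(res.loc[0, "bnti"])
        assert res.loc[0, "process"] == "undefined"

    def test_nearly_identical_clustered_pair_is_homogeneous(self, six_tip_ladder):
        # samples share the closest pair and differ in one close taxon each:
        # observed turnover far below the tip-shuffle null
        d = cophenetic(six_tip_ladder)
        ids = list(d.ids)
        x = [int(i in ("A", "B", "C")) for i in ids]
        y = [int(i in ("A", "B", "D")) for i in ids]
        t = make_table({"x": x, "y": y}, ids)
        res = beta_nti(t, d, runs="exhaustive", null_pool=ids)
        assert res.loc[0, "bnti"] < 0

    def test_exhaustive_equals_enumeration_oracle(self, six_tip_dm):
        d = six_tip_dm
        ids = list(d.ids)
        x = pd.Series([2, 1, 0, 0, 1, 0], index=ids)
        y = pd.Series([0, 1, 3, 0, 0, 1], index=ids)
        t = make_table({"x": x.values, "y": y.values}, ids)
        res = beta_nti(t, d, runs="exhaustive", null_pool=ids, weighted=True)
        m = d.data
        px, py = np.flatnonzero(x.values), np.flatnonzero(y.values)
        wx = x.values[px] / x.values[px].sum()
        wy = y.values[py] / y.values[py].sum()
        vals = []
        for perm in itertools.permutations(range(6)):
            perm = np.array(perm)
            qx, qy = perm[px], perm[py]
            sub = m[np.ix_(qx, qy)]
            vals.append(0.5 * (wx @ sub.min(1) + wy @ sub.min(0)))
        vals = np.array(vals)
        assert res.loc[0, "null_mean"] == pytest.approx(vals.mean())
        assert res.loc[0, "null_sd"] == pytest.approx(vals.std(ddof=0))

    def test_sampled_null_within_monte_carlo_error_of_exhaustive(self, six_tip_dm):
        d = six_tip_dm
        ids = list(d.ids)
        t = make_table({"x": [2, 1, 0, 0, 1, 0], "y": [0, 1, 3, 0, 0, 1]}, ids)
        exact = beta_nti(t, d, runs="exhaustive", null_pool=ids)
        runs = 999
        sampled = beta_nti(t, d, runs=runs, seed=7, null_pool=ids)
        se = exact.loc[0, "null_sd"] / np.sqrt(runs)
        assert abs(sampled.loc[0, "null_mean"] - exact.loc[0, "null_mean"]) < 3 * se

    def test_random_subsets_of_pool_are_mostly_stochastic(self):
        tree = simulate_tree(40, seed=21)
        d = cophenetic(tree)
        ids = list(d.ids)
        rng = np.random.default_rng(1)
        cols = {
            f"s{i}": (rng.random(40) < 0.4).astype(int) for i in range(12)
        }
        t = make_table(cols, ids)
        res = beta_nti(t, d, runs=199, seed=3, null_pool=ids)
        frac_within = (res["bnti"].abs() <= 2).mean()
        assert frac_within >= 0.9

    def test_seeded_reproducibility(self, six_tip_dm):
        ids = list(six_tip_dm.ids)
        t = make_table({"x": [2, 1, 0, 0, 1, 0], "y": [0, 1, 3, 0, 0, 1]}, ids)
        r1 = beta_nti(t, six_tip_dm, runs=99, seed=11)
        r2 = beta_nti(t, six_tip_dm, runs=99, seed=11)
        pd.testing.assert_frame_equal(r1, r2)


class TestClassifyProcess:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (2.5, "heterogeneous_selection"),
            (-3.0, "homogeneous_selection"),
            (0.0, "stochastic"),
            (2.0, "stochastic"),
            (-2.0, "stochastic"),
            (float("nan"), "undefined"),
        ],
    )
    def test_thresholds(self, value, expected):
        assert classify_process(value) == expected


class TestSummarizeProcesses:
    def test_fractions_and_pair_counts(self):
        df = pd.DataFrame(
            {
                "process": ["homogeneous_selection"] * 3 + ["stochastic"],
                "group": ["g1"] * 4,
            }
        )
        out = summarize_processes(df, "group")
        assert out.loc["g1", "homogeneous_selection"] == pytest.approx(0.75)
        assert out.loc["g1", "stochastic"] == pytest.approx(0.25)
        assert out.loc["g1", "n_pairs"] == 4

    def test_group_pair_counts_follow_binomial_rule(self, six_tip_dm):
        ids = list(six_tip_dm.ids)
        rng = np.random.default_rng(0)
        cols = {f"s{i}": rng.integers(0, 3, 6) + (rng.random(6) < 0.5)
                for i in range(5)}
        cols = {k: np.maximum(v, 1) for k, v in cols.items()}  # non-empty
        t = make_table({k: v.astype(int) for k, v in cols.items()}, ids)
        res = beta_nti(t, six_tip_dm, runs=19, seed=0)
        out = summarize_processes(res)
        assert out.loc["all", "n_pairs"] == 5 * 4 // 2


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestPicanteOracle:
    """Cross-check MNTD/betaMNTD/ses.mntd semantics against R picante."""

    def run_r(self, script: str) -> str:
        res = subprocess.run(
            ["Rscript", "--vanilla", "-e", script],
            capture_output=True, text=True, timeout=300,
        )
        assert res.returncode == 0, res.stderr
        return res.stdout

    def test_observed_statistics_match_picante(self, six_tip_ladder, tmp_path):
        d = cophenetic(six_tip_ladder)
        ids = list(d.ids)
        x = pd.Series([3, 1, 0, 2, 0, 1], index=ids)
        y = pd.Series([0, 2, 4, 0, 1, 0], index=ids)
        t = make_table({"x": x.values, "y": y.values}, ids)
        nwk = tmp_path / "tree.nwk"
        nwk.write_text(write_newick(six_tip_ladder) + "\n")
        comm = tmp_path / "comm.tsv"
        t.counts.T.to_csv(comm, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(picante))
            tree <- read.tree("{nwk}")
            comm <- as.matrix(read.table("{comm}", sep="\\t", header=TRUE,
                                         row.names=1, check.names=FALSE))
            dis <- cophenetic(tree)[colnames(comm), colnames(comm)]
            cat(mntd(comm, dis, abundance.weighted=FALSE), "\\n")
            cat(mntd(comm, dis, abundance.weighted=TRUE), "\\n")
            cat(as.matrix(comdistnt(comm, dis, abundance.weighted=TRUE))[1,2], "\\n")
        """)
        out = [line.split() for line in self.run_r(script).strip().splitlines()]
        r_mntd_uw = [float(v) for v in out[0]]
        r_mntd_w = [float(v) for v in out[1]]
        r_bmntd = float(out[2][0])
        assert mntd(x, d) == pytest.approx(r_mntd_uw[0])
        assert mntd(y, d) == pytest.approx(r_mntd_uw[1])
        assert mntd(x, d, weighted=True) == pytest.approx(r_mntd_w[0])
        assert bmntd(x, y, d, weighted=True) == pytest.approx(r_bmntd)

    def test_nti_sign_and_null_match_ses_mntd(self, six_tip_ladder, tmp_path):
        d = cophenetic(six_tip_ladder)
        ids = list(d.ids)
        x = pd.Series([1, 1, 0, 1, 0, 0], index=ids)
        y = pd.Series([0, 1, 1, 0, 1, 1], index=ids)
        t = make_table({"x": x.values, "y": y.values}, ids)
        ours = nti(t, d, runs="exhaustive", null_pool=ids)
        nwk = tmp_path / "tree.nwk"
        nwk.write_text(write_newick(six_tip_ladder) + "\n")
        comm = tmp_path / "comm.tsv"
        t.counts.T.to_csv(comm, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(picante))
            set.seed(1)
            tree <- read.tree("{nwk}")
            comm <- as.matrix(read.table("{comm}", sep="\\t", header=TRUE,
                                         row.names=1, check.names=FALSE))
            dis <- cophenetic(tree)[colnames(comm), colnames(comm)]
            r <- ses.mntd(comm, dis, null.model="taxa.labels", runs=2000,
                          abundance.weighted=FALSE)
            cat(r$mntd.obs[1], r$mntd.rand.mean[1], r$mntd.obs.z[1], "\\n")
        """)
        obs_r, null_mean_r, z_r = map(float, self.run_r(script).split())
        assert ours.loc["x", "mntd_obs"] == pytest.approx(obs_r)
        assert ours.loc["x", "null_mean"] == pytest.approx(null_mean_r, rel=0.05)
        # NTI is the negative of picante's z-score
        assert ours.loc["x", "nti"] == pytest.approx(-z_r, abs=0.25)
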