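"""Patristic distances, environmental optima, Mantel correlograms, NRI/NTI."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sludgenet import (CountMatrix, cophenetic_distances, environmental_optima,
                       mantel_correlogram, mntd, mpd, ses_dispersion,
                       simulate_tree)
from sludgenet.phylo import DistanceMatrix, optima_distance_matrix


def brute_force_patristic(phylogeny):
    """Independent oracle: root-to-tip paths summed via common prefix."""
    tree = phylogeny.tree
    paths = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append((id(node), node.edge.length))
            node = node.parent_node
        paths[leaf.taxon.label] = path[::-1]
    labels = sorted(paths)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = paths[labels[i]], paths[labels[j]]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k][0] == pb[k][0]:
                k += 1
            d[i, j] = d[j, i] = sum(e for _, e in pa[k:]) + sum(e for _, e in pb[k:])
    return labels, d


def brute_mpd(f, d):
    num = den = 0.0
    for i in range(len(f)):
        for j in range(len(f)):
            if i != j and f[i] > 0 and f[j] > 0:
                num += f[i] * f[j] * d[i, j]
                den += f[i] * f[j]
    return num / den


def brute_mntd(f, d):
    out = tot = 0.0
    present = [i for i in range(len(f)) if f[i] > 0]
    for i in present:
        nearest = min(d[i, j] for j in present if j != i)
        out += f[i] * nearest
        tot += f[i]
    return out / tot


class TestCopheneticDistances:
    def test_hand_values(self, toy_tree):
        dm = cophenetic_distances(toy_tree)
        assert dm.ids == ["A", "B", "C"]
        assert dm.values[0, 1] == pytest.approx(2.0)
        assert dm.values[0, 2] == pytest.approx(4.0)
        assert dm.values[1, 2] == pytest.approx(4.0)

    def test_ultrametric_max_is_twice_depth(self):
        phy = simulate_tree(30, seed=4)
        dm = cophenetic_distances(phy)
        assert dm.values.max() == pytest.approx(2.0, abs=1e-9)

    def test_matches_path_walking_oracle(self):
        phy = simulate_tree(50, seed=8)
        dm = cophenetic_distances(phy)
        labels, d = brute_force_patristic(phy)
        assert labels == dm.ids
        assert np.allclose(dm.values, d, atol=1e-10)


class TestEnvironmentalOptima:
    def test_single_condition(self, tiny_metadata):
        cm = CountMatrix(["x"], ["s1", "s2"], np.array([[3, 0]]),
                         {"s1": (1, 1), "s2": (1, 2)})
        opt = environmental_optima(cm, tiny_metadata, ["temperature"])
        assert opt.loc["x", "temperature"] == pytest.approx(20.0)

    def test_balanced_counts_average(self, tiny_metadata):
        cm = CountMatrix(["x"], ["s1", "s3"], np.array([[2, 2]]),
                         {"s1": (1, 1), "s3": (2, 1)})
        opt = environmental_optima(cm, tiny_metadata, ["temperature"])
        assert opt.loc["x", "temperature"] == pytest.approx(25.0)

    def test_zero_total_count_undefined(self, tiny_metadata):
        cm = CountMatrix(["x", "y"], ["s1", "s2"], np.array([[1, 2], [0, 0]]),
                         {"s1": (1, 1), "s2": (1, 2)})
        opt = environmental_optima(cm, tiny_metadata, ["temperature"])
        assert np.isnan(opt.loc["y", "temperature"])

    def test_recovers_planted_optima(self, seasonal_run):
        res = seasonal_run
        opt = environmental_optima(res.counts, res.metadata, ["temperature"])
        planted = {a: v for a, v in res.truth["optima"].items() if v is not None}
        ids = [a for a in planted if np.isfinite(opt.loc[a, "temperature"])]
        rho, _ = stats.spearmanr([planted[a] for a in ids],
                                 opt.loc[ids, "temperature"])
        assert rho >= 0.7


class TestMantelCorrelogram:
    def test_self_signal_in_shortest_class(self):
        phy = simulate_tree(25, seed=2)
        dm = cophenetic_distances(phy)
        out = mantel_correlogram(dm, dm, n_permutations=199, seed=0)
        first = out.iloc[0]
        assert first["r"] > 0
        assert first["p"] <= 0.05

    def test_type_one_error_on_shuffled_traits(self):
        phy = simulate_tree(20, seed=3)
        dm = cophenetic_distances(phy)
        rng = np.random.default_rng(0)
        n_sig = n_tot = 0
        for _ in range(50):
            perm = rng.permutation(len(dm.ids))
            shuffled = DistanceMatrix(dm.ids, dm.values[np.ix_(perm, perm)])
            out = mantel_correlogram(shuffled, dm, n_permutations=99,
                                     seed=int(rng.integers(2 ** 31)))
            ok = out[~out["skipped"]]
            n_sig += (ok["p"] <= 0.05).sum()
            n_tot += len(ok)
        assert n_sig / n_tot <= 0.10  # ~5% plus Monte-Carlo error

    def test_zero_permutations_rejected(self):
        phy = simulate_tree(6, seed=1)
        dm = cophenetic_distances(phy)
        with pytest.raises(ValueError):
            mantel_correlogram(dm, dm, n_permutations=0)


class TestMPDMNTD:
    def test_two_taxa_equal_distance(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        assert mpd([1, 9], d) == pytest.approx(3.0)
        assert mntd([1, 9], d) == pytest.approx(3.0)

    def test_equal_abundance_reduces_to_mean(self):
        rng = np.random.default_rng(1)
        x = rng.random((6, 6))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        iu = np.triu_indices(6, 1)
        assert mpd(np.ones(6), d) == pytest.approx(d[iu].mean())

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        x = rng.random((5, 5))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        f = np.array([0.4, 0.1, 0.0, 0.3, 0.2])
        assert mpd(f, d) == pytest.approx(brute_mpd(f, d))
        assert mntd(f, d) == pytest.approx(brute_mntd(f, d))

    def test_single_taxon_undefined(self):
        d = np.zeros((2, 2))
        assert np.isnan(mpd([1, 0], d))


def pool_counts(abund_rows, ids=None):
    rows = np.asarray(abund_rows).T
    ids = ids or [f"t{i}" for i in range(rows.shape[0])]
    return CountMatrix(ids, [f"s{j}" for j in range(rows.shape[1])], rows,
                       {f"s{j}": (j + 1, 1) for j in range(rows.shape[1])})


class TestSESDispersion:
    def test_matches_exhaustive_enumeration(self):
        """4-taxon pool: SES equals the value from all 4! label shuffles."""
        rng = np.random.default_rng(3)
        x = rng.random((4, 4))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        ids = ["t0", "t1", "t2", "t3"]
        dm = DistanceMatrix(ids, d)
        ab = np.array([5, 2, 1, 0])
        cm = pool_counts([ab], ids)

        out = ses_dispersion(cm, dm, seed=0, exhaustive=True)

        null_mpd, null_mntd = [], []
        for perm in permutations(range(4)):
            dp = d[np.ix_(perm, perm)]
            null_mpd.append(brute_mpd(ab, dp))
            null_mntd.append(brute_mntd(ab, dp))
        ses_mpd = (brute_mpd(ab, d) - np.mean(null_mpd)) / np.std(null_mpd)
        ses_mntd = (brute_mntd(ab, d) - np.mean(null_mntd)) / np.std(null_mntd)
        assert out.loc["s0", "ses_mpd"] == pytest.approx(ses_mpd, abs=1e-10)
        assert out.loc["s0", "ses_mntd"] == pytest.approx(ses_mntd, abs=1e-10)
        assert out.loc["s0", "nri"] == pytest.approx(-ses_mpd, abs=1e-10)

    def test_sampled_null_converges_to_exhaustive(self):
        rng = np.random.default_rng(4)
        x = rng.random((5, 5))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"t{i}" for i in range(5)]
        dm = DistanceMatrix(ids, d)
        cm = pool_counts([[3, 1, 2, 0, 1]], ids)
        exact = ses_dispersion(cm, dm, seed=0, exhaustive=True)
        approx = ses_dispersion(cm, dm, n_null=4000, seed=5)
        assert approx.loc["s0", "ses_mntd"] == pytest.approx(
            exact.loc["s0", "ses_mntd"], abs=0.15)

    def test_star_phylogeny_undefined(self):
        # all pairwise distances equal -> label shuffles change nothing
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix([f"t{i}" for i in range(4)], d)
        cm = pool_counts([[1, 1, 1, 0]])
        out = ses_dispersion(cm, dm, n_null=50, seed=0)
        assert np.isnan(out.loc["s0", "nri"]) and np.isnan(out.loc["s0", "nti"])

    def test_branch_length_scale_invariance(self):
        phy = simulate_tree(12, seed=6)
        dm = cophenetic_distances(phy)
        rng = np.random.default_rng(7)
        ab = (rng.random((3, 12)) < 0.5) * rng.integers(1, 9, (3, 12))
        cm = pool_counts(ab, dm.ids)
        a = ses_dispersion(cm, dm, n_null=99, seed=8)
        dm5 = DistanceMatrix(dm.ids, dm.values * 5.0)
        b = ses_dispersion(cm, dm5, n_null=99, seed=8)
        assert np.allclose(a["nri"], b["nri"], atol=1e-9, equal_nan=True)
        assert np.allclose(a["nti"], b["nti"], atol=1e-9, equal_nan=True)

    def test_clustered_vs_overdispersed_sign(self):
        """Taxa from one clade give NTI > 0; one taxon per deep clade < 0."""
        signs_c, signs_o = [], []
        for seed in range(10):
            phy = simulate_tree(24, seed=100 + seed)
            dm = cophenetic_distances(phy)
            d = dm.values
            # clustered: the 8 taxa closest to taxon 0
            order = np.argsort(d[0])
            clustered = np.zeros(24)
            clustered[order[:8]] = 1
            # overdispersed: greedy max-min spread
            chosen = [int(np.argmax(d.sum(0)))]
            while len(chosen) < 8:
                rest = [i for i in range(24) if i not in chosen]
                chosen.append(rest[int(np.argmax([min(d[i, c] for c in chosen)
                                                  for i in rest]))])
            over = np.zeros(24)
            over[chosen] = 1
            cm = pool_counts([clustered, over], dm.ids)
            out = ses_dispersion(cm, dm, n_null=199, seed=seed)
            signs_c.append(out["nti"].iloc[0])
            signs_o.append(out["nti"].iloc[1])
        assert np.mean(signs_c) > 0.5
        assert np.mean(signs_o) < -0.5

    def test_random_assembly_calibration(self):
        """Random draws from the pool give NRI/NTI centred on zero."""
        phy = simulate_tree(20, seed=9)
        dm = cophenetic_distances(phy)
        rng = np.random.default_rng(10)
        ab = (rng.random((100, 20)) < 0.4) * rng.integers(1, 20, (100, 20))
        ab[ab.sum(1) == 0, 0] = 1
        cm = pool_counts(ab, dm.ids)
        out = ses_dispersion(cm, dm, n_null=399, seed=11)
        assert abs(out["nri"].mean()) < 0.25
        assert abs(out["nti"].mean()) < 0.25
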