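import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster

import oracles
from damscan.patterns import (
    IpdRatioMatrix,
    build_ratio_matrix,
    cut_to_patterns,
    ipd_ratio,
    label_patterns,
    linkage_to_newick,
    ward_cluster,
)
from damscan.synthetic import DEFAULT_TIMEPOINTS, PATTERN_LABELS, pattern_fraction


def ratio_trajectories(labels, noise_sd, seed, sites_per_label=10):
    """Positive ratio rows generated from the pattern templates + noise."""
    rng = np.random.default_rng(seed)
    t = np.asarray(DEFAULT_TIMEPOINTS, dtype=float)
    rows, truth, sites = [], [], []
    pos = 100
    for lab in labels:
        base = 1.0 + 1.7 * pattern_fraction(lab, t)
        for _ in range(sites_per_label):
            rows.append(base + rng.normal(0, noise_sd, t.size))
            truth.append(lab)
            sites.append((pos, "+"))
            pos += 10
    m = IpdRatioMatrix(sites=sites, timepoints_h=list(t), ratios=np.clip(rows, 0.05, None))
    return m, np.array(truth)


class TestRatio:
    def test_equal_means_give_one(self):
        assert ipd_ratio([2.0, 4.0], [1.0, 5.0]) == pytest.approx(1.0)

    def test_worked_example(self):
        assert ipd_ratio([2.4], [1.2]) == pytest.approx(2.0)

    def test_scale_invariance(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.5])
        assert ipd_ratio(7.3 * x, 7.3 * y) == pytest.approx(ipd_ratio(x, y))

    def test_zero_control_mean_guards_corrupt_input(self):
        with pytest.raises(ValueError, match="control mean"):
            ipd_ratio([1.0], [0.0])


class TestRatioMatrix:
    def build_maps(self, n_sites=10, missing=()):
        rng = np.random.default_rng(0)
        samples = [(t, f"t{t:03g}h") for t in DEFAULT_TIMEPOINTS]
        raw = {}
        for i in range(n_sites):
            key = (50 + i, "+")
            per = {sid: rng.lognormal(0, 0.5, 20) for _, sid in samples}
            per["dam"] = rng.lognormal(0, 0.5, 20)
            if key in missing:
                del per["t072h"]
            raw[key] = per
        return raw, samples

    def test_dense_shape_and_column_order(self):
        raw, samples = self.build_maps()
        matrix, dropped = build_ratio_matrix(raw, list(raw), samples, "dam")
        assert matrix.ratios.shape == (10, 7)
        assert matrix.timepoints_h == [8, 16, 24, 48, 72, 96, 120]
        assert dropped == []
        assert matrix.sites == sorted(matrix.sites)

    def test_missing_cell_drops_site_with_warning(self):
        raw, samples = self.build_maps(missing=[(52, "+")])
        with pytest.warns(UserWarning, match="dropped"):
            matrix, dropped = build_ratio_matrix(raw, list(raw), samples, "dam")
        assert (52, "+") in dropped
        assert matrix.ratios.shape == (9, 7)


class TestWard:
    def one_d_matrix(self, values):
        n = len(values)
        return IpdRatioMatrix(
            sites=[(10 * (i + 1), "+") for i in range(n)],
            timepoints_h=[8.0],
            ratios=np.asarray(values, dtype=float).reshape(n, 1),
        )

    def test_two_cluster_cut_matches_exhaustive_variance_minimizer(self):
        m = self.one_d_matrix([0.1, 1.0, 10.0, 11.0])
        labels = cut_to_patterns(ward_cluster(m), k=2)
        got = {frozenset(np.flatnonzero(labels == c)) for c in set(labels)}
        assert got == oracles.best_two_partition_1d([0.1, 1.0, 10.0, 11.0])

    def test_duplicate_rows_merge_first_at_height_zero(self):
        m = self.one_d_matrix([5.0, 5.0, 1.0, 9.0])
        link = ward_cluster(m)
        assert link[0, 2] == 0.0
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}

    def test_merge_sequence_matches_bruteforce_ward_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.lognormal(0, 0.4, size=(6, 7))
        m = IpdRatioMatrix(
            sites=[(i, "+") for i in range(6)], timepoints_h=list(DEFAULT_TIMEPOINTS), ratios=X
        )
        link = ward_cluster(m)
        merges = oracles.brute_ward(X)
        # reconstruct scipy merge membership bottom-up
        members = [frozenset([i]) for i in range(6)]
        for row, (oa, ob, oh) in zip(link, merges):
            a, b = int(row[0]), int(row[1])
            members.append(members[a] | members[b])
            assert {members[a], members[b]} == {oa, ob}
            assert row[2] == pytest.approx(oh, rel=1e-9)

    def test_heights_monotone_nondecreasing(self):
        m, _ = ratio_trajectories(PATTERN_LABELS, noise_sd=0.2, seed=5)
        link = ward_cluster(m)
        assert (np.diff(link[:, 2]) >= -1e-12).all()

    def test_site_reordering_invariance_up_to_relabeling(self):
        m, truth = ratio_trajectories(PATTERN_LABELS, noise_sd=0.1, seed=8)
        perm = np.random.default_rng(0).permutation(len(m.sites))
        m2 = IpdRatioMatrix(
            sites=[m.sites[i] for i in perm],
            timepoints_h=m.timepoints_h,
            ratios=m.ratios[perm],
        )
        l1 = cut_to_patterns(ward_cluster(m), 4)
        l2 = cut_to_patterns(ward_cluster(m2), 4)
        part1 = {frozenset(np.flatnonzero(l1 == c)) for c in set(l1)}
        part2 = {frozenset(perm[np.flatnonzero(l2 == c)]) for c in set(l2)}
        assert part1 == part2

    def test_single_site_rejected(self):
        m = self.one_d_matrix([1.0])
        with pytest.raises(ValueError):
            ward_cluster(m)


class TestCut:
    def test_extreme_k_values(self):
        m, _ = ratio_trajectories(["A", "C"], noise_sd=0.05, seed=2, sites_per_label=3)
        link = ward_cluster(m)
        assert len(set(cut_to_patterns(link, k=6))) == 6  # singletons
        assert len(set(cut_to_patterns(link, k=1))) == 1
        with pytest.raises(ValueError):
            cut_to_patterns(link, k=0)


class TestLabels:
    def test_clean_template_centroids_get_their_own_labels(self):
        m, truth = ratio_trajectories(PATTERN_LABELS, noise_sd=0.0, seed=1, sites_per_label=2)
        link = ward_cluster(m)
        out = label_patterns(cut_to_patterns(link, 4), m, link)
        assert (out["pattern_label"].to_numpy() == truth).all()

    def test_monotone_rise_after_flat_start_is_pattern_a(self):
        m, truth = ratio_trajectories(["A"], noise_sd=0.0, seed=1, sites_per_label=4)
        with pytest.warns(UserWarning, match="subset"):
            out = label_patterns(np.ones(4, dtype=int), m)
        assert (out["pattern_label"] == "A").all()

    def test_peak_at_72h_is_pattern_c(self):
        m, _ = ratio_trajectories(["C"], noise_sd=0.0, seed=1, sites_per_label=4)
        with pytest.warns(UserWarning, match="subset"):
            out = label_patterns(np.ones(4, dtype=int), m)
        assert (out["pattern_label"] == "C").all()

    def test_recovery_from_noisy_templates(self):
        m, truth = ratio_trajectories(PATTERN_LABELS, noise_sd=0.1, seed=3, sites_per_label=8)
        link = ward_cluster(m)
        out = label_patterns(cut_to_patterns(link, 4), m, link)
        accuracy = (out["pattern_label"].to_numpy() == truth).mean()
        assert accuracy >= 0.9
        assert set(out.loc[out["cluster_index"] == out["cluster_index"].iloc[0], "linkage_height"]).issubset(
            set(out["linkage_height"])
        )


def test_newick_export_contains_all_leaves():
    m, _ = ratio_trajectories(["A", "B"], noise_sd=0.05, seed=4, sites_per_label=3)
    link = ward_cluster(m)
    leaves = [f"{p}{s}" for p, s in m.sites]
    nwk = linkage_to_newick(link, leaves)
    assert nwk.endswith(";")
    for leaf in leaves:
        assert leaf in nwk
    import dendropy

    tree = dendropy.Tree.get(data=nwk.replace("+", "p"), schema="newick")
    assert len(tree.leaf_nodes()) == len(leaves)
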