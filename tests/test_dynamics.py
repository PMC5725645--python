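import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutphase.dynamics import (
    consecutive_dissimilarity,
    mean_dissimilarity_by_phase_pair,
    toy_class_tree,
    weighted_unifrac,
    within_vs_cross_test,
)
from gutphase.io import parse_tree_newick
from gutphase.phases import PhaseLabel


def brute_force_unifrac(newick, taxa, a, b, normalized=False):
    """Explicit branch enumeration: for every branch collect its leaf set
    and sum length x |difference of descendant fractions|."""
    from skbio import TreeNode
    import io as sio

    tree = TreeNode.read(sio.StringIO(newick))
    pa = np.asarray(a, float) / np.sum(a)
    pb = np.asarray(b, float) / np.sum(b)
    frac = {t: (pa[i], pb[i]) for i, t in enumerate(taxa)}
    total = 0.0
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips(include_self=True)}
        fa = sum(frac[t][0] for t in leaves if t in frac)
        fb = sum(frac[t][1] for t in leaves if t in frac)
        total += (node.length or 0.0) * abs(fa - fb)
    if not normalized:
        return total
    denom = 0.0
    for tip in tree.tips():
        depth = 0.0
        node = tip
        while node.parent is not None:
            depth += node.length or 0.0
            node = node.parent
        fa, fb = frac[tip.name]
        denom += depth * (fa + fb)
    return total / denom if denom else 0.0


def random_newick(rng, n_leaves):
    nodes = [f"L{i}" for i in range(n_leaves)]
    trees = [f"{n}:{rng.uniform(0.1, 3):.3f}" for n in nodes]
    while len(trees) > 1:
        i, j = sorted(rng.choice(len(trees), 2, replace=False))
        merged = f"({trees[i]},{trees[j]}):{rng.uniform(0.1, 3):.3f}"
        trees = [t for k, t in enumerate(trees) if k not in (i, j)] + [merged]
    # strip the root's branch length: a rooted tree's root has no branch
    return trees[0].rsplit(":", 1)[0] + ";", nodes


class TestWeightedUnifrac:
    def test_identical_profiles_have_zero_distance(self):
        tree = toy_class_tree()
        taxa = sorted(tree.leaf_names())
        a = np.arange(1, len(taxa) + 1)
        assert weighted_unifrac(a, a, taxa, tree) == pytest.approx(0.0, abs=1e-15)

    def test_two_leaf_star_tree_disjoint_profiles(self):
        tree = parse_tree_newick("(A:1,B:1):0;")
        d = weighted_unifrac([1, 0], [0, 1], ["A", "B"], tree, normalized=False)
        assert d == pytest.approx(2.0)

    def test_matches_brute_force_on_random_trees(self, rng):
        """Branch-enumeration oracle agreement to 1e-12 on trees <= 8 leaves."""
        for n_leaves in range(2, 9):
            for rep in range(5):
                newick, taxa = random_newick(rng, n_leaves)
                tree = parse_tree_newick(newick)
                a = rng.integers(0, 50, n_leaves) + (rng.random(n_leaves) < 0.5)
                b = rng.integers(0, 50, n_leaves) + 1
                if a.sum() == 0:
                    a[0] = 1
                for norm in (False, True):
                    got = weighted_unifrac(a, b, taxa, tree, normalized=norm)
                    want = brute_force_unifrac(newick, taxa, a, b, normalized=norm)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_matches_reference_library(self, rng):
        """Independent cross-check against scikit-bio's implementation."""
        from skbio.diversity.beta import weighted_unifrac as skbio_wu
        from skbio import TreeNode
        import io as sio

        newick, taxa = random_newick(rng, 6)
        a = rng.integers(1, 40, 6)
        b = rng.integers(1, 40, 6)
        sk_tree = TreeNode.read(sio.StringIO(newick))
        for norm in (False, True):
            got = weighted_unifrac(a, b, taxa, parse_tree_newick(newick), normalized=norm)
            want = skbio_wu(a, b, taxa=taxa, tree=sk_tree, normalized=norm)
            assert got == pytest.approx(float(want), abs=1e-10)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, derandomize=True)
    def test_symmetry_and_normalized_range(self, seed):
        rng = np.random.default_rng(seed)
        tree = toy_class_tree()
        taxa = sorted(tree.leaf_names())
        a = rng.integers(0, 100, len(taxa)) + 1
        b = rng.integers(0, 100, len(taxa)) + 1
        assert weighted_unifrac(a, b, taxa, tree) == pytest.approx(
            weighted_unifrac(b, a, taxa, tree), abs=1e-14
        )
        dn = weighted_unifrac(a, b, taxa, tree, normalized=True)
        assert 0.0 <= dn <= 1.0

    def test_taxon_absent_from_tree_is_error(self):
        tree = parse_tree_newick("(A:1,B:1):0;")
        with pytest.raises(KeyError, match="C"):
            weighted_unifrac([1, 1], [1, 1], ["A", "C"], tree)

    def test_zero_total_abundance_is_error(self):
        tree = parse_tree_newick("(A:1,B:1):0;")
        with pytest.raises(ValueError, match="positive totals"):
            weighted_unifrac([0, 0], [1, 1], ["A", "B"], tree)


def _pair_setup(phases_by_subject):
    """Build labels/metadata/table for hand-specified per-subject phases."""
    rows, meta, labels = {}, [], {}
    rng = np.random.default_rng(0)
    tree = toy_class_tree()
    taxa = sorted(tree.leaf_names())
    profile = {
        PhaseLabel.P1: [80, 0, 5, 10, 5],
        PhaseLabel.P2: [5, 0, 5, 80, 10],
        PhaseLabel.P3: [5, 20, 60, 10, 5],
    }
    for subj, phases in phases_by_subject.items():
        for k, ph in enumerate(phases):
            sid = f"{subj}_{k}"
            noise = rng.integers(0, 3, len(taxa))
            rows[sid] = np.array(profile[ph]) + noise
            meta.append(
                {"sample_id": sid, "subject_id": subj, "dol": 7 * (k + 1),
                 "pma": 26 + k}
            )
            labels[sid] = ph
    table = pd.DataFrame.from_dict(rows, orient="index", columns=taxa)
    return (
        pd.Series(labels),
        pd.DataFrame(meta),
        table,
        tree,
    )


class TestConsecutivePairs:
    def test_single_sample_subject_contributes_no_pairs(self):
        labels, meta, table, tree = _pair_setup({"a": [PhaseLabel.P1]})
        pairs = consecutive_dissimilarity(labels, meta, table, tree)
        assert len(pairs) == 0

    def test_n_samples_give_n_minus_one_pairs(self):
        labels, meta, table, tree = _pair_setup(
            {"a": [PhaseLabel.P1] * 5, "b": [PhaseLabel.P2] * 3}
        )
        pairs = consecutive_dissimilarity(labels, meta, table, tree)
        assert len(pairs) == 4 + 2
        assert set(pairs["subject_id"]) == {"a", "b"}

    def test_phase_change_pairs_are_farther(self, default_cohort):
        """On the synthetic cohort, pairs straddling a true phase change
        have a larger mean distance than same-phase pairs."""
        from gutphase.preprocess import filter_min_depth, rarefy

        table = rarefy(filter_min_depth(default_cohort.abundance), seed=0)
        cls = table.rollup(3).terminal_names()
        labels = default_cohort.true_phases.loc[
            default_cohort.true_phases.index.intersection(cls.data.index)
        ]
        pairs = consecutive_dissimilarity(
            labels, default_cohort.metadata, cls, toy_class_tree()
        )
        same = pairs[pairs["phase_i"] == pairs["phase_j"]]["distance"]
        cross = pairs[pairs["phase_i"] != pairs["phase_j"]]["distance"]
        assert cross.mean() > same.mean()


class TestMeanMatrix:
    def test_hand_mean_of_two_cross_pairs(self):
        pairs = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "phase_i": [PhaseLabel.P1, PhaseLabel.P1],
                "phase_j": [PhaseLabel.P2, PhaseLabel.P2],
                "distance": [0.2, 0.4],
            }
        )
        means, counts = mean_dissimilarity_by_phase_pair(pairs)
        assert means.loc["P1", "P2"] == pytest.approx(0.3)
        assert counts.loc["P1", "P2"] == 2

    def test_same_phase_equal_distances_fill_diagonal_only(self):
        pairs = pd.DataFrame(
            {
                "subject_id": ["a"] * 3,
                "phase_i": [PhaseLabel.P2] * 3,
                "phase_j": [PhaseLabel.P2] * 3,
                "distance": [0.1, 0.1, 0.1],
            }
        )
        means, counts = mean_dissimilarity_by_phase_pair(pairs)
        assert means.loc["P2", "P2"] == pytest.approx(0.1)
        assert counts.to_numpy().sum() == 3
        off = means.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.isnan(off[~np.isnan(off)]).all() or np.isnan(off).all()

    def test_counts_conserve_pair_total(self, rng):
        n = 40
        pairs = pd.DataFrame(
            {
                "subject_id": rng.choice(["a", "b", "c"], n),
                "phase_i": [PhaseLabel(p) for p in rng.integers(1, 4, n)],
                "phase_j": [PhaseLabel(p) for p in rng.integers(1, 4, n)],
                "distance": rng.random(n),
            }
        )
        _, counts = mean_dissimilarity_by_phase_pair(pairs)
        assert counts.to_numpy().sum() == n

    def test_per_subject_vs_pooled_averaging(self):
        pairs = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b"],
                "phase_i": [PhaseLabel.P1] * 3,
                "phase_j": [PhaseLabel.P1] * 3,
                "distance": [0.0, 0.2, 0.4],
            }
        )
        per_subj, _ = mean_dissimilarity_by_phase_pair(pairs, average="per_subject")
        pooled, _ = mean_dissimilarity_by_phase_pair(pairs, average="pooled")
        assert per_subj.loc["P1", "P1"] == pytest.approx((0.1 + 0.4) / 2)
        assert pooled.loc["P1", "P1"] == pytest.approx(0.2)


def _pairs_from(within, cross):
    rows = []
    for i, d in enumerate(within):
        rows.append(("s%d" % i, PhaseLabel.P1, PhaseLabel.P1, d))
    for i, d in enumerate(cross):
        rows.append(("t%d" % i, PhaseLabel.P1, PhaseLabel.P2, d))
    return pd.DataFrame(rows, columns=["subject_id", "phase_i", "phase_j", "distance"])


class TestRankSum:
    def test_fully_separated_groups_are_significant(self, rng):
        within = rng.uniform(0.0, 0.3, 25)
        cross = rng.uniform(0.5, 1.0, 25)
        res = within_vs_cross_test(_pairs_from(within, cross))
        assert res.pvalue < 0.001
        assert res.median_cross > res.median_within

    def test_empty_group_is_error(self, rng):
        with pytest.raises(ValueError, match="nonempty"):
            within_vs_cross_test(_pairs_from(rng.random(5), []))

    def test_tie_heavy_input_uses_midranks(self):
        res = within_vs_cross_test(
            _pairs_from([0.1, 0.1, 0.1, 0.2], [0.1, 0.2, 0.2, 0.2])
        )
        assert res.method == "normal-approximation"
        assert 0.0 <= res.pvalue <= 1.0

    def test_small_untied_input_uses_exact_enumeration(self):
        res = within_vs_cross_test(
            _pairs_from([0.11, 0.12, 0.13], [0.21, 0.22, 0.23])
        )
        assert res.method == "exact"
        # exact two-sided p for complete separation with n = m = 3
        assert res.pvalue == pytest.approx(0.1, abs=1e-9)

    def test_type_i_error_calibrated_under_null(self, rng):
        """Permuted labels -> rejection rate close to alpha."""
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            d = rng.normal(size=40)
            res = within_vs_cross_test(_pairs_from(d[:20], d[20:]))
            rejections += res.pvalue < 0.05
        assert 0.03 <= rejections / n_sims <= 0.07
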