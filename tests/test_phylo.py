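import numpy as np
import pytest

from gpcrminer import hmm
from gpcrminer.phylo import (AnchoredMSA, PhyloError, bootstrap_support,
                             hmm_anchored_msa, is_monophyletic, nj_tree,
                             pdistance_matrix, poisson_correct)
from gpcrminer.seqio import AMINO_ACIDS, SequenceRecord

from oracle import random_additive_tree


def leaf_path_lengths(tree):
    """Sum of branch lengths between every leaf pair (for additivity)."""
    # collect root-to-leaf paths
    paths = {}

    def walk(node, acc):
        acc = acc + [(node, node.length)]
        if node.is_leaf():
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    for c in tree.root.children:
        walk(c, [])
    names = sorted(paths)
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = paths[names[i]]
            pj = paths[names[j]]
            nodes_i = [id(x[0]) for x in pi]
            shared = 0
            for k, (node, _) in enumerate(pj):
                if k < len(pi) and id(pi[k][0]) == id(node):
                    shared = k + 1
                else:
                    break
            total = sum(w for _, w in pi[shared:]) + \
                sum(w for _, w in pj[shared:])
            d[i, j] = d[j, i] = total
    return names, d


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        tree = nj_tree(d, ["a", "b", "c"])
        names, dd = leaf_path_lengths(tree)
        idx = {n: i for i, n in enumerate(names)}
        assert dd[idx["a"], idx["b"]] == pytest.approx(0.3, abs=1e-9)
        assert dd[idx["a"], idx["c"]] == pytest.approx(0.5, abs=1e-9)
        assert dd[idx["b"], idx["c"]] == pytest.approx(0.6, abs=1e-9)

    def test_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(101)
        for trial in range(20):
            n = int(rng.integers(4, 13))
            labels, d, true_biparts = random_additive_tree(rng, n)
            tree = nj_tree(d, labels)
            assert set(tree.bipartitions()) == true_biparts
            names, dd = leaf_path_lengths(tree)
            order = [labels.index(x) for x in names]
            assert np.allclose(dd, d[np.ix_(order, order)], atol=1e-8)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0, 2.0],
                      [1.5, 0.0, 1.0],
                      [2.0, 1.0, 0.0]])
        with pytest.raises(PhyloError, match="symmetric"):
            nj_tree(d, list("abc"))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(PhyloError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_agrees_with_skbio_on_noisy_matrices(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 8
            labels, d, _ = random_additive_tree(rng, n)
            noise = rng.uniform(0, 0.01, size=d.shape)
            d2 = d + noise + noise.T
            d2 = (d2 + d2.T) / 2.0  # exact float symmetry
            np.fill_diagonal(d2, 0.0)
            ours = nj_tree(d2, labels)
            theirs = skbio.tree.nj(
                skbio.DistanceMatrix(d2, ids=labels))
            ref = min(labels)
            their_biparts = set()
            all_names = set(labels)
            for node in theirs.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= n - 2:
                    if ref in side:
                        side = frozenset(all_names - side)
                    their_biparts.add(side)
            assert set(ours.bipartitions()) == their_biparts


class TestDistances:
    def test_identical_rows_zero(self):
        msa = AnchoredMSA(ids=["a", "b"], rows=["ACDE", "ACDE"])
        assert pdistance_matrix(msa)[0, 1] == 0.0

    def test_quarter_difference(self):
        msa = AnchoredMSA(ids=["a", "b"], rows=["ACDE", "ACDF"])
        assert pdistance_matrix(msa)[0, 1] == 0.25

    def test_gapped_columns_excluded(self):
        msa = AnchoredMSA(ids=["a", "b"], rows=["AC-E", "ACDF"])
        # 3 shared columns, 1 differs
        assert pdistance_matrix(msa)[0, 1] == pytest.approx(1 / 3)

    def test_no_shared_columns_is_error(self):
        msa = AnchoredMSA(ids=["a", "b"], rows=["A--", "--C"])
        with pytest.raises(PhyloError, match="share"):
            pdistance_matrix(msa)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        rows = ["".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 30))
                for _ in range(5)]
        msa = AnchoredMSA(ids=list("abcde"), rows=rows)
        d = pdistance_matrix(msa)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_poisson_correction_expands_distances(self):
        d = np.array([[0.0, 0.2], [0.2, 0.0]])
        out = poisson_correct(d)
        assert out[0, 1] == pytest.approx(-np.log(0.8))


def two_family_msa(rng, n_per=6, ncol=60, divergence=0.45,
                   within=0.08):
    """Alignment with two clearly separated planted clusters."""
    anc_a = rng.integers(0, 20, size=ncol)
    anc_b = anc_a.copy()
    flip = rng.random(ncol) < divergence
    anc_b[flip] = rng.integers(0, 20, size=int(flip.sum()))
    ids, rows = [], []
    for fam, anc in (("A", anc_a), ("B", anc_b)):
        for k in range(n_per):
            member = anc.copy()
            mut = rng.random(ncol) < within
            member[mut] = rng.integers(0, 20, size=int(mut.sum()))
            ids.append(f"{fam}{k}")
            rows.append("".join(AMINO_ACIDS[i] for i in member))
    return AnchoredMSA(ids=ids, rows=rows)


class TestBootstrap:
    def test_family_split_strongly_supported(self):
        rng = np.random.default_rng(11)
        msa = two_family_msa(rng)
        tree = bootstrap_support(msa, n_reps=100, seed=5)
        ids_a = {i for i in msa.ids if i.startswith("A")}
        mono, support = is_monophyletic(tree, ids_a)
        assert mono and support >= 0.9

    def test_single_replicate_gives_binary_support(self):
        rng = np.random.default_rng(13)
        msa = two_family_msa(rng)
        tree = bootstrap_support(msa, n_reps=1, seed=5)
        sups = {n.support for n in tree.root.postorder()
                if n.support is not None}
        assert sups <= {0.0, 1.0}

    def test_seed_reproducible(self):
        rng = np.random.default_rng(17)
        msa = two_family_msa(rng)
        t1 = bootstrap_support(msa, n_reps=50, seed=9)
        t2 = bootstrap_support(msa, n_reps=50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_input_order_invariance(self):
        rng = np.random.default_rng(19)
        msa = two_family_msa(rng)
        rev = AnchoredMSA(ids=list(reversed(msa.ids)),
                          rows=list(reversed(msa.rows)))
        t1 = bootstrap_support(msa, n_reps=50, seed=9)
        t2 = bootstrap_support(rev, n_reps=50, seed=9)
        assert t1.to_newick() == t2.to_newick()


class TestMonophyly:
    def test_singleton_trivially_monophyletic(self):
        rng = np.random.default_rng(23)
        msa = two_family_msa(rng)
        tree = bootstrap_support(msa, n_reps=10, seed=1)
        mono, support = is_monophyletic(tree, {"A0"})
        assert mono and support is None

    def test_full_leaf_set_rejected(self):
        rng = np.random.default_rng(29)
        msa = two_family_msa(rng)
        tree = bootstrap_support(msa, n_reps=10, seed=1)
        with pytest.raises(PhyloError):
            is_monophyletic(tree, set(msa.ids))

    def test_non_subset_rejected(self):
        rng = np.random.default_rng(31)
        msa = two_family_msa(rng)
        tree = bootstrap_support(msa, n_reps=10, seed=1)
        with pytest.raises(PhyloError):
            is_monophyletic(tree, {"zzz"})

    def test_mixed_set_not_monophyletic(self):
        rng = np.random.default_rng(37)
        msa = two_family_msa(rng)
        tree = bootstrap_support(msa, n_reps=10, seed=1)
        mono, _ = is_monophyletic(tree, {"A0", "B0"})
        assert not mono


@pytest.fixture(scope="module")
def profile():
    rng = np.random.default_rng(41)
    cons = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 40))
    return hmm.build_profile([cons] * 8, name="anchor")


class TestAnchoredMSA:

    def test_consensus_rows_are_gapless_and_identical(self, profile):
        cons = hmm.emit_consensus(profile)
        recs = [SequenceRecord(id=f"s{i}", sequence=cons)
                for i in range(3)]
        msa = hmm_anchored_msa(profile, recs)
        assert msa.rows == [cons] * 3

    def test_column_count_equals_n_match(self, profile):
        rng = np.random.default_rng(43)
        recs = [SequenceRecord(
            id=f"s{i}",
            sequence="".join(AMINO_ACIDS[j]
                             for j in rng.integers(0, 20, 60)))
            for i in range(3)]
        msa = hmm_anchored_msa(profile, recs)
        assert msa.n_col == profile.n_match

    def test_projection_identity_tracks_direct_identity(self, profile):
        from gpcrminer.redundancy import pairwise_identity
        rng = np.random.default_rng(47)
        cons = hmm.emit_consensus(profile)
        pair = []
        for _ in range(2):
            pair.append("".join(
                c if rng.random() > 0.15 else AMINO_ACIDS[rng.integers(20)]
                for c in cons))
        msa = hmm_anchored_msa(
            profile, [SequenceRecord(id=f"p{i}", sequence=s)
                      for i, s in enumerate(pair)])
        d = pdistance_matrix(msa)
        proj_ident = 1 - d[0, 1]
        direct = pairwise_identity(pair[0], pair[1])
        assert abs(proj_ident - direct) <= 0.05

    def test_low_scoring_sequence_reported(self, profile):
        recs = [SequenceRecord(id="junk", sequence="G" * 30)]
        with pytest.raises(PhyloError, match="junk"):
            hmm_anchored_msa(profile, recs, min_score=10.0)
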