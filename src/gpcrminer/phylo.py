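"""HMM-anchored alignments, neighbor-joining trees and monophyly checks.

The multiple alignment is the match-state projection of each sequence's
Viterbi alignment to an anchoring profile: insert-state residues are
dropped and unmatched match states gapped, so every row has exactly
n_match columns and the alignment is restricted to the modelled (7TM)
region by construction. Trees are canonical Saitou-Nei neighbor joining
on p-distances, with bootstrap support from column resampling; family
claims reduce to bipartition (monophyly) statements on the unrooted tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import ProfileHMM, viterbi_align
from .seqio import SequenceRecord


class PhyloError(ValueError):
    pass


@dataclass
class AnchoredMSA:
    """Fixed-column alignment projected onto a profile's match states."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise PhyloError("ids and rows must correspond")
        if len({len(r) for r in self.rows}) > 1:
            raise PhyloError("rows must have equal length")

    @property
    def n_col(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f" {len(self.ids)} {self.n_col}\n")
            for sid, row in zip(self.ids, self.rows):
                fh.write(f"{sid}  {row}\n")


def hmm_anchored_msa(profile: ProfileHMM,
                     seqs: list[SequenceRecord],
                     min_score: float | None = None) -> AnchoredMSA:
    """Project each sequence's Viterbi path to the profile's columns."""
    ids, rows = [], []
    failed = []
    for rec in seqs:
        hit = viterbi_align(profile, rec)
        if min_score is not None and hit.bit_score < min_score:
            failed.append(rec.id)
            continue
        row = ["-"] * profile.n_match
        for pos, state in hit.state_path:
            if state is not None:
                row[state - 1] = rec.sequence[pos - 1]
        ids.append(rec.id)
        rows.append("".join(row))
    if failed:
        raise PhyloError(
            "no acceptable alignment for: " + ", ".join(failed))
    return AnchoredMSA(ids=ids, rows=rows)


# -- distances --------------------------------------------------------------


def _encode_msa(msa: AnchoredMSA) -> np.ndarray:
    arr = np.frombuffer("".join(msa.rows).encode(), dtype=np.uint8)
    return arr.reshape(len(msa.rows), msa.n_col)


def _pdist_from_matrix(arr: np.ndarray, strict: bool = True) -> np.ndarray:
    gap = np.uint8(ord("-"))
    n = arr.shape[0]
    d = np.zeros((n, n))
    valid = arr != gap
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            shared = int(both.sum())
            if shared == 0:
                if strict:
                    raise PhyloError(
                        f"rows {i} and {j} share no ungapped columns")
                d[i, j] = d[j, i] = 1.0
                continue
            diff = int((arr[i, both] != arr[j, both]).sum())
            d[i, j] = d[j, i] = diff / shared
    return d


def pdistance_matrix(msa: AnchoredMSA) -> np.ndarray:
    """d(i,j) = 1 - identity over columns ungapped in both rows."""
    if len(msa.rows) < 2:
        raise PhyloError("need at least two rows")
    return _pdist_from_matrix(_encode_msa(msa), strict=True)


def poisson_correct(d: np.ndarray) -> np.ndarray:
    """Poisson-corrected distances -ln(1 - p), capped below saturation."""
    capped = np.minimum(d, 0.95)
    out = -np.log(1.0 - capped)
    np.fill_diagonal(out, 0.0)
    return out


# -- trees ------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> set[str]:
        return {l.name for l in self.leaves()}

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ("" if node.support is None
                     else f"{node.support:.3f}")
            return f"({inner}){label}:{node.length:.6g}"
        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


@dataclass
class SupportTree:
    """Unrooted tree over sequence ids with optional bootstrap supports.

    Bipartitions are canonicalised as the side not containing the
    lexicographically smallest leaf, so trees over the same leaf set are
    directly comparable.
    """

    root: TreeNode

    @property
    def leaf_set(self) -> set[str]:
        return self.root.leaf_names()

    def _ref_leaf(self) -> str:
        return min(self.leaf_set)

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial bipartitions -> the node under the defining edge."""
        all_leaves = self.leaf_set
        ref = self._ref_leaf()
        out: dict[frozenset, TreeNode] = {}
        for node in self.root.postorder():
            if node is self.root or node.is_leaf():
                continue
            side = frozenset(node.leaf_names())
            if len(side) < 2 or len(side) > len(all_leaves) - 2:
                continue
            if ref in side:
                side = frozenset(all_leaves - side)
            out[side] = node
        return out

    def to_newick(self) -> str:
        return self.root.to_newick()


def nj_tree(d: np.ndarray, labels: list[str]) -> SupportTree:
    """Canonical Saitou-Nei neighbor joining.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch. Exact on additive matrices.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise PhyloError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise PhyloError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 3:
        raise PhyloError("need at least three taxa")
    if len(labels) != n:
        raise PhyloError("labels must match the matrix")
    nodes = [TreeNode(name=lab) for lab in labels]
    active = list(range(n))
    D = d.copy()
    while len(active) > 2:
        r = len(active)
        sub = D[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        q = (r - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (sums[ai] - sums[aj]) / (2.0 * (r - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li = max(li, 0.0)
        lj = max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.children = [nodes[i], nodes[j]]
        # distances from the new node
        newrow = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D[i, :] = newrow
        D[:, i] = newrow
        nodes[i] = parent
        active.remove(j)
    # join the last two
    i, j = active
    root = TreeNode()
    half = max(D[i, j], 0.0)
    nodes[i].length = half / 2.0
    nodes[j].length = half / 2.0
    root.children = [nodes[i], nodes[j]]
    return SupportTree(root=root)


def bootstrap_support(msa: AnchoredMSA, n_reps: int = 500,
                      seed: int = 0) -> SupportTree:
    """NJ tree with per-edge support from column resampling.

    Support of an internal edge is the fraction of replicates whose NJ
    tree contains the same bipartition. Taxa are processed in canonical
    (id-sorted) order so supports do not depend on input order.
    """
    order = np.argsort(np.array(msa.ids))
    ids = [msa.ids[k] for k in order]
    rows = [msa.rows[k] for k in order]
    msa_c = AnchoredMSA(ids=ids, rows=rows)
    arr = _encode_msa(msa_c)
    main = nj_tree(_pdist_from_matrix(arr, strict=True), ids)
    biparts = main.bipartitions()
    counts = {bp: 0 for bp in biparts}
    rng = np.random.default_rng(seed)
    ncol = arr.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_d = _pdist_from_matrix(arr[:, cols], strict=False)
        rep_tree = nj_tree(rep_d, ids)
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    for bp, node in biparts.items():
        node.support = counts[bp] / n_reps
    return main


def is_monophyletic(tree: SupportTree, ids: set[str],
                    ) -> tuple[bool, float | None]:
    """Whether some edge separates exactly ``ids`` from the rest.

    Returns (verdict, support of the defining edge when annotated).
    Singletons are trivially monophyletic (leaf edge, no support value);
    the full leaf set or a non-subset is an error.
    """
    ids = set(ids)
    leaves = tree.leaf_set
    if not ids or not ids.issubset(leaves):
        raise PhyloError("ids must be a non-empty subset of the leaves")
    if ids == leaves:
        raise PhyloError("the full leaf set is not a proper subset")
    if len(ids) == 1 or len(ids) == len(leaves) - 1:
        return True, None
    ref = tree._ref_leaf()
    side = frozenset(ids if ref not in ids else leaves - ids)
    biparts = tree.bipartitions()
    if side in biparts:
        return True, biparts[side].support
    return False, None
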