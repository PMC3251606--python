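"""Within-proteome redundancy collapse and pairwise identity statistics.

Two identity conventions coexist deliberately: greedy clustering uses the
CD-HIT convention (identical aligned positions / length of the shorter
sequence) while reported identity statistics use the alignment-column
convention (identical pairs / total alignment columns, gap columns
included). Both ride on one global aligner (BLOSUM62, gap open -11,
extend -1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_aligner.open_gap_score = -11.0
_aligner.extend_gap_score = -1.0


def _aligned_pair(a: str, b: str) -> tuple[str, str]:
    aln = _aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _seq(x) -> str:
    return x.sequence if isinstance(x, SequenceRecord) else str(x)


def pairwise_identity(a, b, mode: str = "full") -> float:
    """Global-alignment identity between two sequences.

    mode="full": identical aligned pairs over all alignment columns
    (gapped columns count in the denominator). mode="region" is the same
    computation; callers pass pre-extracted 7TM-region strings.
    """
    if mode not in ("full", "region"):
        raise ValueError(f"unknown identity mode {mode!r}")
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        raise ValueError("cannot compute identity of an empty sequence")
    ra, rb = _aligned_pair(sa, sb)
    same = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    return same / len(ra)


def clustering_identity(a, b) -> float:
    """CD-HIT convention: identical positions / shorter sequence length."""
    sa, sb = _seq(a), _seq(b)
    ra, rb = _aligned_pair(sa, sb)
    same = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    return same / min(len(sa), len(sb))


@dataclass
class ClusterSet:
    """Partition of one proteome's sequences into identity clusters."""

    clusters: list[tuple[str, list[str]]]
    threshold: float

    def members(self) -> set[str]:
        out: set[str] = set()
        for rep, mem in self.clusters:
            out.update(mem)
        return out

    def representatives(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    def representative_of(self, seq_id: str) -> str:
        for rep, mem in self.clusters:
            if seq_id in mem:
                return rep
        raise KeyError(seq_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for idx, (rep, mem) in enumerate(self.clusters):
            for m in mem:
                rows.append({"cluster_index": idx, "representative": rep,
                             "member": m})
        return pd.DataFrame(rows,
                            columns=["cluster_index", "representative",
                                     "member"])


def cluster_at_threshold(seqs: list[SequenceRecord],
                         threshold: float = 0.90) -> ClusterSet:
    """Greedy incremental clustering within one proteome.

    Sequences are canonically ordered (length descending, id ascending);
    each joins the first cluster whose representative it matches at >=
    threshold under the shorter-length identity convention, else founds a
    new cluster. Representatives are therefore the longest members.
    """
    ordered = sorted(seqs, key=lambda r: (-len(r.sequence), r.id))
    clusters: list[tuple[SequenceRecord, list[str]]] = []
    for rec in ordered:
        placed = False
        for rep, members in clusters:
            if clustering_identity(rep, rec) >= threshold:
                members.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append((rec, [rec.id]))
    return ClusterSet(
        clusters=[(rep.id, members) for rep, members in clusters],
        threshold=threshold,
    )


def identity_matrix(seqs: list[str] | list[SequenceRecord],
                    ids: list[str] | None = None,
                    mode: str = "full") -> pd.DataFrame:
    """Symmetric all-pairs identity table (alignment-column convention)."""
    strs = [_seq(s) for s in seqs]
    if ids is None:
        ids = [s.id if isinstance(s, SequenceRecord) else f"s{i}"
               for i, s in enumerate(seqs)]
    n = len(strs)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(strs[i], strs[j],
                                                      mode=mode)
    return pd.DataFrame(mat, index=ids, columns=ids)


def mean_pairwise_identity(seqs, mode: str = "full") -> float:
    """Mean over all unordered pairs; the reported identity statistic."""
    strs = [_seq(s) for s in seqs]
    n = len(strs)
    if n < 2:
        raise ValueError("need at least two sequences")
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += pairwise_identity(strs[i], strs[j], mode=mode)
            count += 1
    return total / count
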