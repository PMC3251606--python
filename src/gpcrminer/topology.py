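"""Transmembrane topology prediction and the 6-9 segment filter.

A sliding-window Kyte-Doolittle hydropathy predictor stands in for a full
topology model: maximal runs of high average hydropathy become TM
segments, nearby runs are merged, and short runs discarded. Loop labels
assume an extracellular N-terminus (universal for this receptor class),
so the loop after TM1 is ICL1, after TM2 is ECL1, and so on. Externally
predicted topologies can be imported from TSV and used bit-for-bit in all
downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .config import RunConfig
from .seqio import SequenceRecord

#: per-residue hydropathy; ambiguity code X is neutral
_KD = dict(KYTE_DOOLITTLE)
_KD["X"] = 0.0


class TopologyError(ValueError):
    pass


@dataclass
class TMTopology:
    """Ordered TM segments plus per-residue region labels.

    ``segments`` are 1-based inclusive (start, end) spans, sorted and
    non-overlapping. ``region_map`` assigns each residue one label from
    {Nterm, TM1..TM9, ICL1..ICL4, ECL1..ECL4, Cterm} and tiles the
    sequence exactly. ``seven_tm_span`` covers TM1 start through the last
    TM end (None when no segment was found).
    """

    segments: list[tuple[int, int]]
    region_map: list[str]
    seq_length: int

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in self.segments:
            if s <= prev_end or e < s:
                raise TopologyError("segments must be sorted, disjoint")
            prev_end = e
        if len(self.region_map) != self.seq_length:
            raise TopologyError("region map must tile the sequence")

    @property
    def n_tm(self) -> int:
        return len(self.segments)

    @property
    def seven_tm_span(self) -> tuple[int, int] | None:
        if not self.segments:
            return None
        return (self.segments[0][0], self.segments[-1][1])

    def region_span(self, label: str) -> tuple[int, int] | None:
        """1-based inclusive span of a region label, or None if absent."""
        pos = [i + 1 for i, lab in enumerate(self.region_map)
               if lab == label]
        if not pos:
            return None
        return (pos[0], pos[-1])


def _loop_label(k: int) -> str:
    """Label of the loop following TM k (extracellular N-terminus)."""
    return f"ICL{(k + 1) // 2}" if k % 2 == 1 else f"ECL{k // 2}"


def hydropathy_profile(seq, window: int = 19) -> np.ndarray:
    """Centered moving-average Kyte-Doolittle hydropathy.

    Ends are padded by shrinking the window to the available residues.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else str(seq)
    if len(s) < 5:
        raise TopologyError("sequence shorter than 5 residues")
    if window < 5 or window % 2 == 0:
        raise TopologyError("window must be odd and >= 5")
    vals = np.array([_KD[c] for c in s])
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    n = len(vals)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def predict_tm_segments(seq, threshold: float = 1.5, min_len: int = 15,
                        merge_gap: int = 3, window: int = 19) -> TMTopology:
    """Hydropathy TM prediction with merge and length rules.

    Maximal runs with windowed hydropathy >= threshold are taken, runs
    separated by <= merge_gap residues are merged, and runs shorter than
    min_len discarded.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else str(seq)
    prof = hydropathy_profile(s, window=window)
    above = prof >= threshold
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start + 1, i))
            start = None
    if start is not None:
        runs.append((start + 1, len(s)))
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    segments = [r for r in merged if r[1] - r[0] + 1 >= min_len]
    return build_topology(segments, len(s))


def build_topology(segments: list[tuple[int, int]],
                   seq_length: int) -> TMTopology:
    """Region labelling for a given segment list (shared with TSV import)."""
    region = ["Nterm"] * seq_length
    for k, (s, e) in enumerate(segments, start=1):
        for i in range(s - 1, e):
            region[i] = f"TM{k}"
        if k < len(segments):
            nxt = segments[k][0]
            for i in range(e, nxt - 1):
                region[i] = _loop_label(k)
        else:
            for i in range(e, seq_length):
                region[i] = "Cterm"
    return TMTopology(segments=list(segments), region_map=region,
                      seq_length=seq_length)


def passes_tm_filter(top: TMTopology, cfg: RunConfig) -> bool:
    """True iff tm_min <= n_tm <= tm_max (both bounds inclusive)."""
    return cfg.tm_min <= top.n_tm <= cfg.tm_max


def extract_regions(seq, top: TMTopology) -> dict[str, str]:
    """Subsequence per region label, plus the concatenated 7TM-region.

    The special key ``seven_tm_region`` holds the span from TM1 start
    through the last TM end (loops included), the unit used for
    alignments and identity statistics.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else str(seq)
    if top.n_tm < 1:
        raise TopologyError("no TM segments; nothing to extract")
    out: dict[str, str] = {}
    for label in dict.fromkeys(top.region_map):
        span = top.region_span(label)
        out[label] = s[span[0] - 1:span[1]]
    a, b = top.seven_tm_span
    out["seven_tm_region"] = s[a - 1:b]
    return out


def read_topology_tsv(path: str | Path,
                      seq_lengths: dict[str, int]) -> dict[str, TMTopology]:
    """Import externally predicted topologies (id, start, end per row)."""
    rows: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise TopologyError(f"{path}: expected header 'id\\tstart\\tend'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise TopologyError(f"{path}:{lineno}: expected 3 columns")
            rows.setdefault(parts[0], []).append(
                (int(parts[1]), int(parts[2])))
    out = {}
    for sid, segs in rows.items():
        if sid not in seq_lengths:
            raise TopologyError(f"{path}: unknown sequence id {sid!r}")
        out[sid] = build_topology(sorted(segs), seq_lengths[sid])
    return out
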