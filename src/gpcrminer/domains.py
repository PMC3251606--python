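"""N-terminal domain-architecture annotation.

The extracellular N-terminus (everything before TM1) is scanned with
per-domain profile HMMs; hits below the E-value cutoff are kept
best-first with the same >50%-of-shorter-envelope overlap rule used in
family scanning. The domain vocabulary is data, not code: a manifest
maps domain names to seed-alignment files from which profiles are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .hmm import ProfileHMM, scan_best_domains
from .seqio import SequenceRecord
from .topology import TMTopology


@dataclass
class DomainArchitecture:
    """Ordered N-terminal domains of one receptor."""

    target_id: str
    nterm_length: int
    domains: list[tuple[str, int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, start, end, _ in self.domains:
            if not (1 <= start <= end <= max(self.nterm_length, 1)):
                raise ValueError(
                    f"{self.target_id}: domain {name} outside the N-terminus")
        self.domains.sort(key=lambda d: d[1])

    @property
    def architecture_string(self) -> str:
        return "-".join(name for name, *_ in self.domains)


def annotate_nterm(seq: SequenceRecord, top: TMTopology,
                   domain_profiles: list[ProfileHMM],
                   cutoff: float = 0.01,
                   db_size: int = 1) -> DomainArchitecture:
    """Scan the region before TM1 for functional domains.

    nterm_length = TM1 start - 1; no kept domain crosses TM1. With no
    N-terminal residues (or no hits at the cutoff) the architecture is
    empty.
    """
    if top.n_tm < 1:
        raise ValueError(f"{seq.id}: no TM segments; N-terminus undefined")
    nterm_length = top.segments[0][0] - 1
    if nterm_length == 0 or not domain_profiles:
        return DomainArchitecture(target_id=seq.id,
                                  nterm_length=nterm_length)
    nterm = SequenceRecord(id=seq.id, sequence=seq.sequence[:nterm_length])
    hits = scan_best_domains(domain_profiles, nterm,
                             report_cutoff=cutoff, db_size=db_size)
    return DomainArchitecture(
        target_id=seq.id, nterm_length=nterm_length,
        domains=[(h.model_name, h.env_start, h.env_end, h.evalue)
                 for h in hits],
    )


def architecture_summary(archs: list[DomainArchitecture],
                         grouping: dict[str, str],
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group N-terminus length stats and domain-name frequencies.

    Returns (length_stats, domain_frequencies); sequences missing from
    ``grouping`` fall into group 'ungrouped'.
    """
    rows = []
    freq_rows = []
    by_group: dict[str, list[DomainArchitecture]] = {}
    for a in archs:
        by_group.setdefault(grouping.get(a.target_id, "ungrouped"),
                            []).append(a)
    for group in sorted(by_group):
        items = by_group[group]
        lengths = [a.nterm_length for a in items]
        rows.append({
            "group": group, "n": len(items),
            "min_nterm": min(lengths), "max_nterm": max(lengths),
            "mean_nterm": sum(lengths) / len(lengths),
        })
        counts: dict[str, int] = {}
        for a in items:
            for name, *_ in a.domains:
                counts[name] = counts.get(name, 0) + 1
        for name in sorted(counts):
            freq_rows.append({"group": group, "domain": name,
                              "count": counts[name]})
    stats = pd.DataFrame(rows, columns=["group", "n", "min_nterm",
                                        "max_nterm", "mean_nterm"])
    freqs = pd.DataFrame(freq_rows, columns=["group", "domain", "count"])
    return stats, freqs


def load_domain_manifest(path: str | Path) -> list[tuple[str, Path]]:
    """Manifest TSV (name, seed-alignment path[, note]) -> pairs."""
    path = Path(path)
    out = []
    with open(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected name\\tpath")
            out.append((parts[0], (path.parent / parts[1]).resolve()))
    return out
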