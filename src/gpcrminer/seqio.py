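"""Sequence and metadata I/O.

Every downstream stage of the pipeline consumes :class:`SequenceRecord`
objects produced here (plus a :class:`~gpcrminer.config.RunConfig`); no
stage re-reads files. Proteomes arrive as one multi-FASTA per species and
a tab-separated species table maps accession prefixes to species, phylum
and a coarse lineage tag (fungi, choanoflagellata, ..., other).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

log = logging.getLogger("gpcrminer")

#: Canonical residue alphabet in alphabetical order; index 20 is reserved
#: for the ambiguity code X (scored with background frequencies downstream).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
AA_INDEX["X"] = 20

LINEAGE_TAGS = frozenset(
    {"fungi", "choanoflagellata", "filasterea", "alveolata",
     "porifera", "metazoa", "amoebozoa", "other"}
)


class SeqIOError(ValueError):
    """Raised on malformed sequence or metadata input."""


@dataclass
class SequenceRecord:
    """A protein sequence with identifier and lineage metadata.

    The sequence is uppercase, restricted to the 20 canonical residues
    plus X, with no gap or stop characters.
    """

    id: str
    sequence: str
    species: str = ""
    phylum: str = ""
    lineage_tag: str = "other"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record requires a non-empty id")
        if not self.sequence:
            raise SeqIOError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise SeqIOError(
                f"{self.id}: non-canonical residues {sorted(bad)}; "
                "normalise with read_fasta/normalise_sequence first"
            )
        if self.lineage_tag not in LINEAGE_TAGS:
            raise SeqIOError(
                f"{self.id}: unknown lineage tag {self.lineage_tag!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def encoded(self) -> np.ndarray:
        """Residues as uint8 indices into AMINO_ACIDS, with X -> 20."""
        return np.fromiter(
            (AA_INDEX[c] for c in self.sequence), dtype=np.uint8,
            count=len(self.sequence),
        )

    def with_metadata(self, species: str, phylum: str,
                      lineage_tag: str) -> "SequenceRecord":
        return replace(self, species=species, phylum=phylum,
                       lineage_tag=lineage_tag)


def normalise_sequence(raw: str, seq_id: str = "?") -> str:
    """Normalise a raw FASTA sequence string.

    Uppercases, strips a single terminal stop codon ``*`` (a common
    proteome artifact), rejects internal stops, and maps any other
    non-canonical letter to X with a logged warning.
    """
    seq = raw.strip().upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if "*" in seq:
        raise SeqIOError(f"{seq_id}: internal stop codon '*'")
    cleaned = []
    replaced = set()
    for c in seq:
        if c in AA_INDEX:
            cleaned.append(c)
        elif c.isalpha():
            cleaned.append("X")
            replaced.add(c)
        else:
            raise SeqIOError(f"{seq_id}: illegal character {c!r}")
    if replaced:
        log.warning("%s: replaced non-canonical residues %s with X",
                    seq_id, sorted(replaced))
    return "".join(cleaned)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-FASTA proteome into normalised records.

    The id is the first whitespace-delimited header token; the remainder is
    kept as a free-text description. Duplicate ids and empty files are
    errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise SeqIOError(f"{path}: duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        seq = normalise_sequence(str(entry.seq), entry.id)
        desc = entry.description[len(entry.id):].strip()
        records.append(SequenceRecord(id=entry.id, sequence=seq,
                                      description=desc))
    if not records:
        raise SeqIOError(f"{path}: no FASTA entries found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA; round-trips ids and sequences exactly."""
    out = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(out, str(Path(path)), "fasta")


def load_species_table(path: str | Path) -> dict[str, tuple[str, str, str]]:
    """Load the id-prefix -> (species, phylum, lineage_tag) lookup.

    Expects a tab-separated table with a header row and four columns:
    id_prefix, species, phylum, lineage. An empty table (header only)
    yields an empty map.
    """
    path = Path(path)
    table: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise SeqIOError(f"{path}: empty species table (missing header)")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise SeqIOError(
                f"{path}:{lineno}: expected 4 tab-separated columns, "
                f"got {len(parts)}"
            )
        prefix, species, phylum, lineage = (p.strip() for p in parts)
        if lineage not in LINEAGE_TAGS:
            raise SeqIOError(
                f"{path}:{lineno}: unknown lineage tag {lineage!r} "
                f"(expected one of {sorted(LINEAGE_TAGS)})"
            )
        table[prefix] = (species, phylum, lineage)
    return table


def tag_records(records: Iterable[SequenceRecord],
                table: dict[str, tuple[str, str, str]],
                ) -> list[SequenceRecord]:
    """Attach species metadata by longest matching id prefix."""
    prefixes = sorted(table, key=len, reverse=True)
    tagged = []
    for r in records:
        for p in prefixes:
            if r.id.startswith(p):
                tagged.append(r.with_metadata(*table[p]))
                break
        else:
            tagged.append(r)
    return tagged
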