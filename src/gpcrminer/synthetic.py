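"""Seeded synthetic proteomes with planted ground truth.

The generator emulates the statistical structure the pipeline assumes:
seven-transmembrane receptors (hydrophobic TM stretches separated by
hydrophilic loops), family-diagnostic motifs planted at their canonical
region-anchored positions, N-terminal cassettes of family-typical length
(short domain-free fungal Adhesion N-termini vs long domain-bearing
Glutamate N-termini), hydrophilic globular decoys, 5-TM fragments and
near-duplicate copies. Each family derives from a seeded consensus core;
members are region-aware mutations of it. The cAMP core is itself a
diverged copy of the Rhodopsin-like core, reflecting the close kinship of
those two families that makes the dual-model E-value scatter informative.

TM residue composition and loop hydropathy are co-calibrated with the
default hydropathy predictor thresholds (the constants live here, beside
the predictor defaults in :mod:`gpcrminer.topology`); truth labels never
leak into pipeline inputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, SequenceRecord
from .topology import _loop_label

# -- residue pools (probability over the 20 canonical residues) -------------


def _pool(weights: dict[str, float]) -> np.ndarray:
    p = np.zeros(20)
    for aa, w in weights.items():
        p[AMINO_ACIDS.index(aa)] = w
    return p / p.sum()


#: strongly hydrophobic; windowed Kyte-Doolittle stays well above the
#: predictor threshold inside a TM stretch
TM_POOL = _pool({"I": 0.30, "L": 0.25, "V": 0.20, "F": 0.15, "A": 0.10})

#: mildly hydrophilic loops: low enough to break TM runs, high enough not
#: to erode segment ends below the minimum-length rule
LOOP_POOL = _pool({"S": 0.25, "T": 0.20, "G": 0.20, "P": 0.10, "N": 0.08,
                   "Q": 0.07, "D": 0.05, "K": 0.05})

#: globular decoys: hydrophilic residues plus 20% general background
_hydrophilic = {aa: 0.8 / 11 for aa in "DEKRNQSTGPH"}
DECOY_POOL = 0.8 * _pool(_hydrophilic) / _pool(_hydrophilic).sum() \
    + 0.2 * np.full(20, 0.05)
DECOY_POOL = DECOY_POOL / DECOY_POOL.sum()


def _draw(rng: np.random.Generator, pool: np.ndarray, n: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=n, p=pool))


@dataclass(frozen=True)
class MotifPlant:
    """One motif planted into a region of the TM-core template.

    ``position`` places the literal at the region start, middle or end
    (with up to 2 residues of seeded jitter) or uniformly anywhere.
    """

    motif_name: str
    region: str
    choices: tuple[str, ...]
    position: str = "mid"  # start | mid | end | any


@dataclass(frozen=True)
class CoreTemplate:
    """Family consensus TM core: TM stretches and the loops between."""

    tm: tuple[str, ...]
    loops: tuple[str, ...]

    @property
    def n_tm(self) -> int:
        return len(self.tm)


@dataclass(frozen=True)
class FamilySpec:
    """Generative description of one receptor family."""

    family: str             # truth label (e.g. Rhodopsin, cAMP)
    model_name: str         # profile model the family answers to
    prefix: str             # accession prefix for emitted ids
    core: CoreTemplate
    motif_plants: tuple[MotifPlant, ...] = ()
    nterm_range: tuple[int, int] = (2, 66)
    cterm_len: int = 25
    domain_cassette: tuple[str, ...] = ()
    copy_number: int = 36
    n_duplicates: int = 4
    mutation_rate: float = 0.20      # member divergence from the core
    duplicate_rate: float = 0.05     # near-duplicate point mutations
    kind: str = "receptor"           # receptor | chimera | fragment
    master_seed: int = 0             # ties domain consensi to the run

    def __post_init__(self) -> None:
        if not (5 <= self.core.n_tm <= 10) and self.kind != "fragment":
            raise ValueError("receptor specs need 5..10 TM stretches")
        if self.kind == "fragment" and self.core.n_tm >= 6:
            raise ValueError("fragment specs must carry < 6 TM stretches")
        if not (0.0 <= self.duplicate_rate <= 0.5):
            raise ValueError("duplicate mutation rate must be in [0, 0.5]")


TM_LEN = 25
LOOP_LEN = 15


def _stable_seed(master: int, tag: str) -> int:
    h = hashlib.sha256(f"{master}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _make_core(rng: np.random.Generator, n_tm: int = 7,
               tm_len: int = TM_LEN, loop_len: int = LOOP_LEN,
               ) -> CoreTemplate:
    tm = tuple(_draw(rng, TM_POOL, tm_len) for _ in range(n_tm))
    loops = tuple(_draw(rng, LOOP_POOL, loop_len) for _ in range(n_tm - 1))
    return CoreTemplate(tm=tm, loops=loops)


def _mutate(s: str, rate: float, pool: np.ndarray,
            rng: np.random.Generator) -> str:
    out = list(s)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[rng.choice(20, p=pool)]
    return "".join(out)


def _diverge_core(core: CoreTemplate, rate: float,
                  rng: np.random.Generator) -> CoreTemplate:
    return CoreTemplate(
        tm=tuple(_mutate(t, rate, TM_POOL, rng) for t in core.tm),
        loops=tuple(_mutate(l, rate, LOOP_POOL, rng) for l in core.loops),
    )


# -- family catalogue -------------------------------------------------------

_RHODOPSIN_PLANTS = (
    MotifPlant("icl1_basic", "ICL1", ("R", "K"), "mid"),
    MotifPlant("tm2_asp", "TM2", ("D",), "mid"),
    MotifPlant("rhodopsin_tm3_dry", "TM3", ("DRY", "ERY"), "end"),
    MotifPlant("rhodopsin_tm7_npxxy", "TM7", ("NPLIY", "NPIIY"), "end"),
    MotifPlant("ecl1_cys", "ECL1", ("C",), "mid"),
    MotifPlant("ecl2_cys", "ECL2", ("C",), "mid"),
)

_CAMP_PLANTS = (
    MotifPlant("icl1_basic", "ICL1", ("R", "K"), "mid"),
    MotifPlant("tm2_asp", "TM2", ("D",), "mid"),
    MotifPlant("camp_tm3_nxy", "TM3", ("NSY", "NTY"), "end"),
    MotifPlant("camp_tm7_nsaxxy", "TM7", ("NSLIY", "NALIY"), "end"),
    MotifPlant("ecl1_cys", "ECL1", ("C",), "mid"),
    MotifPlant("ecl2_cys", "ECL2", ("C",), "mid"),
)

_ADHESION_PLANTS = (
    MotifPlant("ecl1_cys", "ECL1", ("C",), "mid"),
    MotifPlant("ecl2_cys", "ECL2", ("C",), "mid"),
    MotifPlant("adhesion_tm3_trp", "TM3", ("W",), "mid"),
    MotifPlant("adhesion_tm4_pro", "TM4", ("P",), "mid"),
    MotifPlant("adhesion_tm5_pro", "TM5", ("P",), "mid"),
    MotifPlant("adhesion_tm7_gly", "TM7", ("G",), "end"),
)

_SHARED_CYS = (
    MotifPlant("ecl1_cys", "ECL1", ("C",), "mid"),
    MotifPlant("ecl2_cys", "ECL2", ("C",), "mid"),
)


def default_family_specs(seed: int) -> dict[str, FamilySpec]:
    """The five GRAFS/cAMP family specs plus the cAMP-motif chimera.

    All cores are seeded deterministically from ``seed``; the cAMP core is
    the Rhodopsin core diverged at rate 0.3, and the chimera spec reuses
    the Rhodopsin core with the cAMP motif set and no D/ERY.
    """
    rho_core = _make_core(np.random.default_rng(
        _stable_seed(seed, "core:Rhodopsin")))
    camp_core = _diverge_core(rho_core, 0.30, np.random.default_rng(
        _stable_seed(seed, "core:cAMP")))
    adh_core = _make_core(np.random.default_rng(
        _stable_seed(seed, "core:Adhesion")))
    glu_core = _make_core(np.random.default_rng(
        _stable_seed(seed, "core:Glutamate")))
    fzd_core = _make_core(np.random.default_rng(
        _stable_seed(seed, "core:Frizzled")))
    specs = {
        "Rhodopsin": FamilySpec(
            family="Rhodopsin", model_name="7tm_1", prefix="SYRHO_",
            core=rho_core, motif_plants=_RHODOPSIN_PLANTS,
            nterm_range=(10, 50), master_seed=seed),
        "Adhesion": FamilySpec(
            family="Adhesion", model_name="7tm_2", prefix="SYADH_",
            core=adh_core, motif_plants=_ADHESION_PLANTS,
            nterm_range=(2, 66), master_seed=seed),
        "Glutamate": FamilySpec(
            family="Glutamate", model_name="7tm_3", prefix="SYGLU_",
            core=glu_core, motif_plants=_SHARED_CYS,
            nterm_range=(160, 400),
            domain_cassette=("ANF_receptor",), master_seed=seed),
        "Frizzled": FamilySpec(
            family="Frizzled", model_name="Frizzled", prefix="SYFZD_",
            core=fzd_core, motif_plants=_SHARED_CYS,
            nterm_range=(80, 160), master_seed=seed),
        "cAMP": FamilySpec(
            family="cAMP", model_name="Dicty_CAR", prefix="SYCAM_",
            core=camp_core, motif_plants=_CAMP_PLANTS,
            nterm_range=(10, 50), copy_number=29, n_duplicates=3,
            master_seed=seed),
        "chimera": FamilySpec(
            family="cAMP", model_name="7tm_1", prefix="SYCHI_",
            core=rho_core, motif_plants=_CAMP_PLANTS,
            nterm_range=(10, 50), copy_number=8, n_duplicates=0,
            kind="chimera", master_seed=seed),
    }
    return specs


def fungal_family_specs(seed: int) -> dict[str, FamilySpec]:
    """Fungal-specific receptor specs (pheromone, glucose and nutrient
    sensors); independent cores, shared ECL cysteines only."""
    out = {}
    for family, model, prefix in (("Ste2", "STE2", "SYST2_"),
                                  ("Ste3", "STE3", "SYST3_"),
                                  ("Git3", "Git3", "SYGIT_"),
                                  ("Nutrient", "Nutrient", "SYNUT_")):
        core = _make_core(np.random.default_rng(
            _stable_seed(seed, f"core:{family}")))
        out[family] = FamilySpec(
            family=family, model_name=model, prefix=prefix, core=core,
            motif_plants=_SHARED_CYS, nterm_range=(10, 60),
            copy_number=8, n_duplicates=0, master_seed=seed)
    return out


def fragment_spec(seed: int) -> FamilySpec:
    """A 5-TM fragment decoy spec (truncated Rhodopsin-like core)."""
    full = default_family_specs(seed)["Rhodopsin"].core
    core = CoreTemplate(tm=full.tm[:5], loops=full.loops[:4])
    return FamilySpec(family="Rhodopsin", model_name="7tm_1",
                      prefix="SYFRG_", core=core, motif_plants=(),
                      nterm_range=(5, 30), copy_number=10, n_duplicates=0,
                      kind="fragment")


# -- synthetic functional domains ------------------------------------------


def synthetic_domain_seed(name: str, seed: int, length: int = 80,
                          n_members: int = 20,
                          mutation_rate: float = 0.15) -> list[str]:
    """Ungapped seed alignment for a synthetic N-terminal domain family.

    The consensus is drawn deterministically from the domain name and the
    master seed, using the hydrophilic-biased background so planted
    domains never masquerade as TM stretches.
    """
    rng = np.random.default_rng(_stable_seed(seed, f"domain:{name}"))
    consensus = _draw(rng, DECOY_POOL, length)
    return [_mutate(consensus, mutation_rate, DECOY_POOL, rng)
            for _ in range(n_members)]


def domain_instance(name: str, seed: int, rng: np.random.Generator,
                    length: int = 80,
                    mutation_rate: float = 0.15) -> str:
    """One mutated copy of a synthetic domain's consensus."""
    crng = np.random.default_rng(_stable_seed(seed, f"domain:{name}"))
    consensus = _draw(crng, DECOY_POOL, length)
    return _mutate(consensus, mutation_rate, DECOY_POOL, rng)


# -- family seed alignments -------------------------------------------------


def family_seed_alignment(spec: FamilySpec, seed: int,
                          n_members: int = 25) -> list[str]:
    """Ungapped alignment of TM-core members used to train the profile.

    Members share the template geometry exactly (no indels), carry the
    family motif plants at fixed canonical offsets, and diverge from the
    core at the spec's mutation rate.
    """
    rng = np.random.default_rng(
        _stable_seed(seed, f"seedaln:{spec.model_name}"))
    rows = []
    for _ in range(n_members):
        pieces, spans = _assemble_core(spec.core, rng, spec.mutation_rate,
                                       loop_jitter=0)
        seq = _plant_motifs(pieces, spans, spec.motif_plants, rng,
                            jitter=0)[0]
        rows.append(seq)
    return rows


# -- receptor assembly ------------------------------------------------------


def _assemble_core(core: CoreTemplate, rng: np.random.Generator,
                   rate: float, loop_jitter: int = 2):
    """Mutated TM/loop pieces with per-receptor loop-length variation."""
    pieces: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    for k, tm in enumerate(core.tm, start=1):
        piece = _mutate(tm, rate, TM_POOL, rng)
        pieces.append(piece)
        spans[f"TM{k}"] = (pos + 1, pos + len(piece))
        pos += len(piece)
        if k <= len(core.loops):
            loop = _mutate(core.loops[k - 1], rate, LOOP_POOL, rng)
            if loop_jitter:
                delta = int(rng.integers(-loop_jitter, loop_jitter + 1))
                if delta > 0:
                    loop = loop + _draw(rng, LOOP_POOL, delta)
                elif delta < 0:
                    loop = loop[:delta]
            pieces.append(loop)
            spans[_loop_label(k)] = (pos + 1, pos + len(loop))
            pos += len(loop)
    return pieces, spans


def _plant_motifs(pieces: list[str], spans: dict[str, tuple[int, int]],
                  plants: tuple[MotifPlant, ...],
                  rng: np.random.Generator, jitter: int = 2):
    """Overwrite motif literals inside their regions; returns (seq, truth)."""
    seq = list("".join(pieces))
    planted = []
    for plant in plants:
        if plant.region not in spans:
            raise ValueError(
                f"motif {plant.motif_name} anchors to absent region "
                f"{plant.region}")
        lo, hi = spans[plant.region]
        literal = plant.choices[int(rng.integers(len(plant.choices)))]
        k = len(literal)
        width = hi - lo + 1
        if k > width:
            raise ValueError(
                f"motif {plant.motif_name} longer than region "
                f"{plant.region}")
        off = int(rng.integers(0, jitter + 1)) if jitter else 0
        # keep start/end plants a few residues inside the region so a
        # hydropathy predictor's slightly shrunken segment still covers
        # them within its search window
        margin = 5
        if plant.position == "start":
            start = lo + min(margin + off, width - k)
        elif plant.position == "end":
            start = max(hi - k + 1 - margin - off, lo)
        elif plant.position == "mid":
            start = lo + (width - k) // 2
            start = min(max(start + int(rng.integers(-jitter, jitter + 1))
                            if jitter else start, lo), hi - k + 1)
        elif plant.position == "any":
            start = lo + int(rng.integers(0, width - k + 1))
        else:
            raise ValueError(f"unknown position {plant.position!r}")
        seq[start - 1:start - 1 + k] = literal
        planted.append((plant.motif_name, plant.region, start,
                        start + k - 1))
    return "".join(seq), planted


def generate_receptor(spec: FamilySpec, seed: int,
                      record_id: str = "receptor",
                      ) -> tuple[SequenceRecord, dict]:
    """One synthetic receptor plus its truth row.

    The N-terminus is hydrophilic background with any domain-cassette
    instances spliced in; the TM core is a mutated copy of the family
    consensus with the family motifs planted region-anchored; a
    hydrophilic C-terminus closes the sequence. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.nterm_range
    nterm_len = int(rng.integers(lo, hi + 1))
    dom_instances = [(name,
                      domain_instance(name, seed=spec.master_seed, rng=rng))
                     for name in spec.domain_cassette]
    dom_total = sum(len(s) for _, s in dom_instances)
    if dom_instances:
        nterm_len = max(nterm_len,
                        dom_total + 10 * (len(dom_instances) + 1))
    filler = nterm_len - dom_total
    # spread filler around the cassette
    n_gaps = len(dom_instances) + 1
    cuts = sorted(rng.integers(0, filler + 1, size=n_gaps - 1).tolist()) \
        if n_gaps > 1 else []
    gap_lens = np.diff([0] + cuts + [filler]).tolist()
    nterm_parts = []
    dom_truth = []
    pos = 0
    for g, dom in zip(gap_lens, dom_instances + [None]):
        pad = _draw(rng, DECOY_POOL, int(g))
        nterm_parts.append(pad)
        pos += len(pad)
        if dom is not None:
            name, text = dom
            nterm_parts.append(text)
            dom_truth.append((name, pos + 1, pos + len(text)))
            pos += len(text)
    nterm = "".join(nterm_parts)

    pieces, spans = _assemble_core(spec.core, rng, spec.mutation_rate)
    core_seq, motif_truth = _plant_motifs(pieces, spans, spec.motif_plants,
                                          rng)
    cterm = _draw(rng, LOOP_POOL, spec.cterm_len)
    sequence = nterm + core_seq + cterm
    offset = len(nterm)
    segments = [(spans[f"TM{k}"][0] + offset, spans[f"TM{k}"][1] + offset)
                for k in range(1, spec.core.n_tm + 1)]
    truth = {
        "id": record_id,
        "kind": spec.kind,
        "family": spec.family,
        "n_tm": spec.core.n_tm,
        "nterm_length": len(nterm),
        "segments": ";".join(f"{s}-{e}" for s, e in segments),
        "motifs": ";".join(
            f"{name}@{region}:{s + offset}-{e + offset}"
            for name, region, s, e in motif_truth),
        "domains": ";".join(f"{name}:{s}-{e}"
                            for name, s, e in dom_truth),
        "duplicate_of": "",
    }
    return SequenceRecord(id=record_id, sequence=sequence), truth


def make_duplicate(parent: SequenceRecord, truth: dict, rate: float,
                   seed: int, record_id: str,
                   ) -> tuple[SequenceRecord, dict]:
    """Region-aware near-duplicate of a generated receptor."""
    rng = np.random.default_rng(seed)
    tm_mask = np.zeros(len(parent.sequence), dtype=bool)
    if truth["segments"]:
        for part in truth["segments"].split(";"):
            s, e = part.split("-")
            tm_mask[int(s) - 1:int(e)] = True
    out = list(parent.sequence)
    for i in range(len(out)):
        if rng.random() < rate:
            pool = TM_POOL if tm_mask[i] else LOOP_POOL
            out[i] = AMINO_ACIDS[rng.choice(20, p=pool)]
    new_truth = dict(truth)
    new_truth.update(id=record_id, duplicate_of=parent.id)
    return SequenceRecord(id=record_id, sequence="".join(out)), new_truth


def generate_decoy(seed: int, record_id: str,
                   length_range: tuple[int, int] = (250, 400),
                   ) -> tuple[SequenceRecord, dict]:
    """Globular (hydrophilic) non-receptor decoy."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    truth = {"id": record_id, "kind": "decoy", "family": "none",
             "n_tm": 0, "nterm_length": 0, "segments": "", "motifs": "",
             "domains": "", "duplicate_of": ""}
    return SequenceRecord(id=record_id, sequence=_draw(rng, DECOY_POOL, n)), \
        truth


def generate_proteome(specs: list[FamilySpec], n_decoys: int,
                      n_fragments: int, seed: int,
                      ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Full synthetic proteome with a truth table (one row per sequence).

    Emits ``copy_number`` receptors plus ``n_duplicates`` near-duplicates
    per spec, ``n_fragments`` 5-TM fragments and ``n_decoys`` hydrophilic
    decoys, in a seeded shuffled order. Truth stays in the returned table
    only.
    """
    records: list[SequenceRecord] = []
    rows: list[dict] = []
    for spec in specs:
        parents: list[tuple[SequenceRecord, dict]] = []
        for c in range(spec.copy_number):
            rid = f"{spec.prefix}{c + 1:04d}"
            rec, truth = generate_receptor(
                spec, seed=_stable_seed(seed, f"rec:{rid}"), record_id=rid)
            parents.append((rec, truth))
            records.append(rec)
            rows.append(truth)
        drng = np.random.default_rng(
            _stable_seed(seed, f"dups:{spec.prefix}"))
        for d in range(spec.n_duplicates):
            parent, ptruth = parents[int(drng.integers(len(parents)))]
            rid = f"{spec.prefix}D{d + 1:03d}"
            rec, truth = make_duplicate(
                parent, ptruth, spec.duplicate_rate,
                seed=_stable_seed(seed, f"dup:{rid}"), record_id=rid)
            records.append(rec)
            rows.append(truth)
    frag = fragment_spec(seed)
    for c in range(n_fragments):
        rid = f"{frag.prefix}{c + 1:04d}"
        rec, truth = generate_receptor(
            frag, seed=_stable_seed(seed, f"frag:{rid}"), record_id=rid)
        records.append(rec)
        rows.append(truth)
    for c in range(n_decoys):
        rid = f"SYDEC_{c + 1:04d}"
        rec, truth = generate_decoy(
            _stable_seed(seed, f"decoy:{rid}"), rid)
        records.append(rec)
        rows.append(truth)
    order = np.random.default_rng(
        _stable_seed(seed, "shuffle")).permutation(len(records))
    records = [records[i] for i in order]
    rows = [rows[i] for i in order]
    return records, pd.DataFrame(rows)
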