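"""GRAFS / cAMP / fungal-specific family classification.

Families are assigned from the best (minimum-E) hit among the family
profile models; the Rhodopsin vs cAMP boundary — where the two profile
models score nearly alike — is refined by region-anchored diagnostic
motifs: Rhodopsin carries D/ERY at the cytoplasmic end of TM3 and NPxxY
in TM7, while cAMP receptors carry the variant N(S)xY / NS(A)xxY motifs.
A 7tm_1-best sequence lacking the D/ERY class but carrying a cAMP TM3
motif is reclassified to cAMP (and symmetrically back), with motif
evidence taking precedence over the E-value margin.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import RunConfig
from .hmm import DomainHit, ProfileHMM, log10_evalue, viterbi_align
from .seqio import SequenceRecord
from .topology import TMTopology

FAMILIES = ("Rhodopsin", "Adhesion", "Glutamate", "Frizzled", "cAMP",
            "Ste2", "Ste3", "Git3", "Nutrient", "unclassified")

#: profile model name -> family; Git3 and Git3_c collapse to one family
MODEL_FAMILY = {
    "7tm_1": "Rhodopsin",
    "7tm_2": "Adhesion",
    "7tm_3": "Glutamate",
    "Frizzled": "Frizzled",
    "Dicty_CAR": "cAMP",
    "STE2": "Ste2",
    "STE3": "Ste3",
    "Git3": "Git3",
    "Git3_c": "Git3",
    "Nutrient": "Nutrient",
}


@dataclass(frozen=True)
class MotifDef:
    """A residue-class pattern searched inside one topological region.

    The pattern is an ordinary regular expression over residue letters;
    the search window extends the anchored region by ``search_window``
    residues on each side to absorb small boundary error in the TM
    predictor.
    """

    name: str
    pattern: str
    anchor_region: str
    search_window: int = 5

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        re.compile(self.pattern)


#: Parenthetical notation like N(S)xY is encoded as both readings
#: (optional residue and any residue), neither privileged.
DEFAULT_MOTIFS: tuple[MotifDef, ...] = (
    MotifDef("rhodopsin_tm3_dry", "[DE]RY", "TM3"),
    MotifDef("rhodopsin_tm3_dr_relaxed", "[DE]R.", "TM3"),
    MotifDef("rhodopsin_tm7_npxxy", "NP..", "TM7"),
    MotifDef("camp_tm3_nxy", "N.Y", "TM3"),
    MotifDef("camp_tm3_nsxy", "NS.Y", "TM3"),
    MotifDef("camp_tm7_nsaxxy", "N[SA]..Y", "TM7"),
    MotifDef("icl1_basic", "[RK]", "ICL1"),
    MotifDef("tm2_asp", "D", "TM2"),
    MotifDef("ecl1_cys", "C", "ECL1"),
    MotifDef("ecl2_cys", "C", "ECL2"),
    MotifDef("adhesion_tm3_trp", "W", "TM3"),
    MotifDef("adhesion_tm4_pro", "P", "TM4"),
    MotifDef("adhesion_tm5_pro", "P", "TM5"),
    MotifDef("adhesion_tm7_gly", "G", "TM7"),
)

DRY_CLASS = frozenset({"rhodopsin_tm3_dry"})
CAMP_TM3_CLASS = frozenset({"camp_tm3_nxy", "camp_tm3_nsxy"})
CAMP_CLASS = CAMP_TM3_CLASS | {"camp_tm7_nsaxxy"}


def load_motif_defs(path) -> tuple[MotifDef, ...]:
    """Motif table from TSV (name, pattern, region, window) or YAML.

    YAML files hold a list of mappings with the same keys; the window
    column is optional and defaults to 5.
    """
    import yaml
    from pathlib import Path as _Path
    path = _Path(path)
    defs = []
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            for item in yaml.safe_load(fh) or []:
                defs.append(MotifDef(
                    name=item["name"], pattern=item["pattern"],
                    anchor_region=item["region"],
                    search_window=int(item.get("window", 5))))
        return tuple(defs)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            try:
                defs.append(MotifDef(
                    name=row["name"], pattern=row["pattern"],
                    anchor_region=row["region"],
                    search_window=int(row.get("window", 5) or 5)))
            except KeyError as exc:
                raise ValueError(
                    f"{path}:{lineno}: missing column {exc}") from exc
    return tuple(defs)


@dataclass
class MotifHit:
    name: str
    start: int  # 1-based position in the full sequence
    matched: str


@dataclass
class FamilyCall:
    """Per-sequence classification record."""

    target_id: str
    family: str = "unclassified"
    best_model: str | None = None
    evalues: dict[str, float] = field(default_factory=dict)
    scatter: tuple[float, float] | None = None
    motif_hits: list[str] = field(default_factory=list)
    reclassified: bool = False
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


def assign_family(hits: list[DomainHit],
                  cfg: RunConfig | None = None) -> FamilyCall:
    """Family of the minimum-E family-model hit.

    Nutrient-profile hits are honoured only at the strict cutoff
    (default 1e-25); with no qualifying hit the call is unclassified.
    """
    cfg = cfg or RunConfig()
    if hits:
        target = hits[0].target_id
        if any(h.target_id != target for h in hits):
            raise ValueError("hits must all concern one target")
    else:
        target = "?"
    evalues = {h.model_name: h.evalue for h in hits}
    qualifying = []
    for h in hits:
        if h.model_name not in MODEL_FAMILY:
            continue
        if (MODEL_FAMILY[h.model_name] == "Nutrient"
                and h.evalue > cfg.nutrient_evalue_cutoff):
            continue
        qualifying.append(h)
    if not qualifying:
        return FamilyCall(target_id=target, evalues=evalues)

    def rank(h: DomainHit):
        le = h.log10_evalue
        if math.isnan(le):
            le = math.log10(h.evalue) if h.evalue > 0 else -math.inf
        return (le, -h.bit_score, h.model_name)

    best = min(qualifying, key=rank)
    return FamilyCall(target_id=target,
                      family=MODEL_FAMILY[best.model_name],
                      best_model=best.model_name, evalues=evalues)


def scatter_coordinates(seq, model_a: ProfileHMM, model_b: ProfileHMM,
                        db_size: int,
                        cfg: RunConfig | None = None,
                        ) -> tuple[tuple[float, float], bool]:
    """(log10 E_a, log10 E_b) and the ambiguity flag.

    Ambiguous when |log10 E_a - log10 E_b| < scatter_ambiguity_delta;
    symmetric in the two models.
    """
    cfg = cfg or RunConfig()
    la = log10_evalue(model_a, viterbi_align(model_a, seq).bit_score,
                      db_size)
    lb = log10_evalue(model_b, viterbi_align(model_b, seq).bit_score,
                      db_size)
    return (la, lb), abs(la - lb) < cfg.scatter_ambiguity_delta


def find_motifs(seq, top: TMTopology,
                defs: tuple[MotifDef, ...] = DEFAULT_MOTIFS,
                ) -> list[MotifHit]:
    """Scan each motif inside its anchored region +/- its window."""
    s = seq.sequence if isinstance(seq, SequenceRecord) else str(seq)
    hits: list[MotifHit] = []
    for d in defs:
        span = top.region_span(d.anchor_region)
        if span is None:
            continue
        lo = max(1, span[0] - d.search_window)
        hi = min(len(s), span[1] + d.search_window)
        for m in re.finditer(d.pattern, s[lo - 1:hi]):
            hits.append(MotifHit(name=d.name, start=lo + m.start(),
                                 matched=m.group(0)))
    return hits


def reclassify(call: FamilyCall, motifs: list[MotifHit] | list[str],
               cfg: RunConfig | None = None) -> FamilyCall:
    """Motif-evidence override on the Rhodopsin/cAMP boundary.

    7tm_1-best with no D/ERY but a cAMP TM3 motif -> cAMP; Dicty_CAR-best
    with D/ERY and no cAMP motifs -> Rhodopsin; anything else is
    unchanged. Motif precedence applies regardless of the E-value margin;
    a motif-free ambiguous call keeps the E-value winner and stays
    flagged for tree-based review. Idempotent.
    """
    names = {m if isinstance(m, str) else m.name for m in motifs}
    out = replace(call, motif_hits=sorted(names))
    has_dry = bool(names & DRY_CLASS)
    has_camp_tm3 = bool(names & CAMP_TM3_CLASS)
    has_camp_any = bool(names & CAMP_CLASS)
    if call.best_model == "7tm_1" and not has_dry and has_camp_tm3:
        if call.family != "cAMP":
            out = replace(out, family="cAMP", reclassified=True)
    elif call.best_model == "Dicty_CAR" and has_dry and not has_camp_any:
        if call.family != "Rhodopsin":
            out = replace(out, family="Rhodopsin", reclassified=True)
    return out


def conservation_profile(msa: list[str],
                         ) -> list[tuple[str, float]]:
    """Per-column (modal residue, conservation fraction), gaps excluded.

    The fraction is the modal count over non-gap residues; ties break
    alphabetically. All-gap columns report ('-', 0.0).
    """
    if len(msa) < 2:
        raise ValueError("need at least two aligned sequences")
    if len({len(r) for r in msa}) != 1:
        raise ValueError("aligned sequences must have equal length")
    out = []
    for col in zip(*msa):
        counts: dict[str, int] = {}
        for c in col:
            if c in "-.":
                continue
            counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append(("-", 0.0))
            continue
        best = min(counts, key=lambda c: (-counts[c], c))
        out.append((best, counts[best] / sum(counts.values())))
    return out


def conserved_columns(msa: list[str], threshold: float = 0.90,
                      ) -> list[tuple[int, str, float]]:
    """Columns conserved at >= threshold: (1-based column, residue, frac)."""
    return [(i + 1, res, frac)
            for i, (res, frac) in enumerate(conservation_profile(msa))
            if frac >= threshold and res != "-"]


def calls_to_frame(calls: list[FamilyCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "id": c.target_id, "family": c.family,
            "best_model": c.best_model,
            "reclassified": c.reclassified, "ambiguous": c.ambiguous,
            "motifs": ";".join(c.motif_hits),
        }
        if c.scatter is not None:
            row["log10_E_7tm_1"], row["log10_E_Dicty_CAR"] = c.scatter
        else:
            row["log10_E_7tm_1"] = row["log10_E_Dicty_CAR"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", "family", "best_model",
                                       "log10_E_7tm_1",
                                       "log10_E_Dicty_CAR",
                                       "reclassified", "ambiguous",
                                       "motifs"])
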