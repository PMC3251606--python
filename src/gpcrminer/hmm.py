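"""Profile hidden Markov models for protein family search.

This module is the scoring engine of the pipeline: it builds profile HMMs
from seed alignments, aligns sequences to them (Viterbi and forward, in a
Plan-7-like local mode with uniform entry into any match state and free
exit from any match state), calibrates E-values on a Gumbel null fitted to
scores of random background sequences, emits per-family consensus
sequences by match-state plurality, samples synthetic members, and
resolves best-domain-per-region over a set of profiles.

Scores are bit scores: log2 odds of the model path against a background
model emitting every residue independently. The background is flat (1/20)
by default and overridable. The ambiguity code X scores zero (background)
at every state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import _kernels
from .seqio import AMINO_ACIDS, AA_INDEX, SequenceRecord

GAP_CHARS = set("-.")
_NEG = _kernels.NEG


class ProfileError(ValueError):
    """Raised on invalid profile construction or use."""


@dataclass(frozen=True)
class ProfileHMM:
    """A profile HMM over the 20 canonical amino acids.

    Transition arrays are indexed by source state (1-based; index 0 and
    the final match state hold no outgoing transitions and are ignored).
    ``gumbel_lambda``/``gumbel_mu`` are absent until :func:`calibrate_evalue`
    has been run.
    """

    name: str
    match_emissions: np.ndarray      # (m, 20)
    insert_emissions: np.ndarray     # (20,)
    t_mm: np.ndarray                 # (m+1,) M_j -> M_{j+1}
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    begin_match: float = 1.0         # P(first column occupied), for sampling
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 0.05))
    gumbel_lambda: float | None = None
    gumbel_mu: float | None = None

    def __post_init__(self) -> None:
        m = self.n_match
        if m < 1:
            raise ProfileError("profile needs at least one match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ProfileError("match emission rows must sum to 1")
        if not math.isclose(self.insert_emissions.sum(), 1.0, abs_tol=1e-9):
            raise ProfileError("insert emissions must sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ProfileError("background must sum to 1")
        for j in range(1, m):
            if not math.isclose(
                    self.t_mm[j] + self.t_mi[j] + self.t_md[j], 1.0,
                    abs_tol=1e-9):
                raise ProfileError(f"M{j} transitions must sum to 1")
            if not math.isclose(self.t_im[j] + self.t_ii[j], 1.0,
                                abs_tol=1e-9):
                raise ProfileError(f"I{j} transitions must sum to 1")
            if j >= 2 and not math.isclose(
                    self.t_dm[j] + self.t_dd[j], 1.0, abs_tol=1e-9):
                raise ProfileError(f"D{j} transitions must sum to 1")

    @property
    def n_match(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.gumbel_lambda is not None

    # -- score parameterisation ------------------------------------------

    def _score_arrays(self):
        """Log2 emission odds (incl. X column = 0) and transition scores."""
        m = self.n_match
        esc = np.empty((m, 21))
        esc[:, :20] = np.log2(self.match_emissions / self.background)
        esc[:, 20] = 0.0
        def logs(t, lo, hi):
            out = np.full(m + 1, _NEG)
            for j in range(lo, hi):
                if t[j] > 0:
                    out[j] = math.log2(t[j])
            return out
        sMM = logs(self.t_mm, 1, m)
        sMI = logs(self.t_mi, 1, m)
        sMD = logs(self.t_md, 1, m)
        sIM = logs(self.t_im, 1, m)
        sII = logs(self.t_ii, 1, m)
        sDM = logs(self.t_dm, 2, m)
        sDD = logs(self.t_dd, 2, m)
        entry = math.log2(1.0 / m)
        return esc, (sMM, sMI, sMD, sIM, sII, sDM, sDD), entry


@dataclass
class DomainHit:
    """A local alignment of one profile to one target sequence.

    ``state_path`` maps 1-based target positions inside the envelope to
    the match-state index they align to, or None for insert-state
    positions.
    """

    model_name: str
    target_id: str
    env_start: int
    env_end: int
    bit_score: float
    evalue: float = math.nan
    log10_evalue: float = math.nan
    state_path: list[tuple[int, int | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.env_start > self.env_end:
            raise ProfileError("envelope start must be <= end")

    @property
    def length(self) -> int:
        return self.env_end - self.env_start + 1


def _as_rows(msa) -> list[str]:
    rows = []
    for entry in msa:
        if isinstance(entry, SequenceRecord):
            rows.append(entry.sequence)
        elif isinstance(entry, (tuple, list)):
            rows.append(str(entry[1]))
        else:
            rows.append(str(entry))
    rows = [r.upper() for r in rows]
    if not rows:
        raise ProfileError("empty alignment")
    if len({len(r) for r in rows}) != 1:
        raise ProfileError("aligned sequences must have equal length")
    return rows


def build_profile(msa, match_gap_fraction: float = 0.5,
                  pseudocount: float = 1.0, name: str = "profile",
                  background: np.ndarray | None = None) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Columns whose gap fraction is <= ``match_gap_fraction`` become match
    states (a column at exactly the threshold IS a match state). Emissions
    get additive Laplace pseudocounts (weight ``pseudocount`` per residue);
    X residues are treated as missing observations. Transitions are
    counted from each row's path through the match columns, also with
    +1-per-allowed-transition smoothing; insertions adjacent to deletions
    are folded into the direct delete transition (the local model has no
    D<->I moves).
    """
    rows = _as_rows(msa)
    ncol = len(rows[0])
    nseq = len(rows)
    if background is None:
        background = np.full(20, 0.05)
    is_match = []
    for c in range(ncol):
        gaps = sum(1 for r in rows if r[c] in GAP_CHARS)
        is_match.append(gaps / nseq <= match_gap_fraction)
    match_cols = [c for c, flag in enumerate(is_match) if flag]
    m = len(match_cols)
    if m == 0:
        raise ProfileError("alignment yields zero match columns")

    emis = np.full((m, 20), pseudocount, dtype=float)
    for k, c in enumerate(match_cols):
        for r in rows:
            ch = r[c]
            if ch in GAP_CHARS or ch == "X":
                continue
            emis[k, AA_INDEX[ch]] += 1.0
    emis /= emis.sum(axis=1, keepdims=True)

    # transition counts, indexed by source state
    cMM = np.zeros(m + 1); cMI = np.zeros(m + 1); cMD = np.zeros(m + 1)
    cIM = np.zeros(m + 1); cII = np.zeros(m + 1)
    cDM = np.zeros(m + 1); cDD = np.zeros(m + 1)
    begin_occupied = 0
    for r in rows:
        states = ["M" if r[c] not in GAP_CHARS else "D" for c in match_cols]
        if states[0] == "M":
            begin_occupied += 1
        # inserted residues between match columns j and j+1
        for j in range(1, m):
            lo, hi = match_cols[j - 1] + 1, match_cols[j]
            nins = sum(1 for c in range(lo, hi) if r[c] not in GAP_CHARS)
            src, dst = states[j - 1], states[j]
            if src == "M" and dst == "M" and nins > 0:
                cMI[j] += 1
                cII[j] += nins - 1
                cIM[j] += 1
            elif src == "M" and dst == "M":
                cMM[j] += 1
            elif src == "M":
                cMD[j] += 1  # inserts adjacent to a deletion are folded
            elif dst == "M":
                cDM[j] += 1
            else:
                cDD[j] += 1

    def norm(parts):
        tot = sum(parts) + len(parts)  # +1 pseudocount each
        return [(p + 1.0) / tot for p in parts]

    t_mm = np.zeros(m + 1); t_mi = np.zeros(m + 1); t_md = np.zeros(m + 1)
    t_im = np.zeros(m + 1); t_ii = np.zeros(m + 1)
    t_dm = np.zeros(m + 1); t_dd = np.zeros(m + 1)
    for j in range(1, m):
        t_mm[j], t_mi[j], t_md[j] = norm([cMM[j], cMI[j], cMD[j]])
        t_im[j], t_ii[j] = norm([cIM[j], cII[j]])
        if j >= 2:
            t_dm[j], t_dd[j] = norm([cDM[j], cDD[j]])

    return ProfileHMM(
        name=name,
        match_emissions=emis,
        insert_emissions=background.copy(),
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii, t_dm=t_dm, t_dd=t_dd,
        begin_match=(begin_occupied + 1.0) / (nseq + 2.0),
        background=background,
    )


# -- alignment --------------------------------------------------------------


def _encode(seq) -> np.ndarray:
    if isinstance(seq, SequenceRecord):
        return seq.encoded()
    return np.fromiter((AA_INDEX[c] for c in seq.upper()), dtype=np.uint8,
                       count=len(seq))


def _seq_id(seq) -> str:
    return seq.id if isinstance(seq, SequenceRecord) else "seq"


def viterbi_align(profile: ProfileHMM, seq) -> DomainHit:
    """Maximum-log-odds local alignment of ``seq`` to ``profile``.

    Returns the single best-scoring domain with its envelope and
    match-state path; the score may be <= 0 for unrelated sequences but a
    (possibly single-residue) alignment always exists.
    """
    obs = _encode(seq)
    if obs.size < 1:
        raise ProfileError("cannot align an empty sequence")
    esc, trans, entry = profile._score_arrays()
    VM, VI, VD, pM, pI, pD = _kernels.viterbi_matrices(
        obs, esc, *trans, entry)
    flat = np.argmax(VM)
    i, j = divmod(int(flat), VM.shape[1])
    score = float(VM[i, j])
    # traceback
    path: list[tuple[int, int | None]] = []
    state = "M"
    while True:
        if state == "M":
            path.append((i, j))
            code = pM[i, j]
            if code == 0:
                break
            i, j = i - 1, j - 1
            state = {1: "M", 2: "I", 3: "D"}[int(code)]
        elif state == "I":
            path.append((i, None))
            code = pI[i, j]
            i = i - 1
            state = "M" if code == 1 else "I"
        else:  # D consumes no residue
            code = pD[i, j]
            j = j - 1
            state = "M" if code == 1 else "D"
    path.reverse()
    env_start = path[0][0]
    env_end = path[-1][0]
    return DomainHit(model_name=profile.name, target_id=_seq_id(seq),
                     env_start=env_start, env_end=env_end,
                     bit_score=score, state_path=path)


def viterbi_bits(profile: ProfileHMM, seq) -> float:
    """Viterbi bit score without traceback (fast path for calibration)."""
    obs = _encode(seq)
    esc, trans, entry = profile._score_arrays()
    return float(_kernels.viterbi_score(obs, esc, *trans, entry))


def forward_score(profile: ProfileHMM, seq) -> float:
    """Log2-sum of odds over all local alignments; always >= Viterbi."""
    obs = _encode(seq)
    esc, trans, entry = profile._score_arrays()
    return float(_kernels.forward_score(obs, esc, *trans, entry))


# -- E-value calibration ----------------------------------------------------


def calibrate_evalue(profile: ProfileHMM, n_random: int = 1000,
                     length: int = 350, seed: int = 0) -> ProfileHMM:
    """Fit a Gumbel null to Viterbi scores of random background sequences.

    Returns a new profile carrying (lambda, mu); emissions and transitions
    are untouched. Requires n_random >= 100; a degenerate (zero-variance)
    score distribution is an error.
    """
    if n_random < 100:
        raise ProfileError("calibration needs n_random >= 100")
    rng = np.random.default_rng(seed)
    obs_all = rng.choice(20, size=(n_random, length),
                         p=profile.background).astype(np.uint8)
    esc, trans, entry = profile._score_arrays()
    scores = np.empty(n_random)
    for k in range(n_random):
        scores[k] = _kernels.viterbi_score(obs_all[k], esc, *trans, entry)
    if np.var(scores) == 0:
        raise ProfileError("degenerate null score distribution")
    loc, scale = stats.gumbel_r.fit(scores)
    return replace(profile, gumbel_lambda=1.0 / scale, gumbel_mu=loc)


def fit_gumbel(scores: Sequence[float]) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (lambda, mu)."""
    loc, scale = stats.gumbel_r.fit(np.asarray(scores, dtype=float))
    return 1.0 / scale, loc


def evalue(profile: ProfileHMM, bit_score: float, db_size: int) -> float:
    """Expected chance hits >= bit_score in a database of db_size sequences.

    E = db_size * (1 - exp(-exp(-lambda (s - mu)))): monotone decreasing in
    the score, linear in db_size.
    """
    if not profile.calibrated:
        raise ProfileError(f"profile {profile.name!r} is not calibrated")
    lam, mu = profile.gumbel_lambda, profile.gumbel_mu
    x = -lam * (bit_score - mu)
    # tail prob of one draw; stable for both large and small x
    if x > 40.0:
        p = 1.0
    else:
        p = -math.expm1(-math.exp(x))
    return db_size * p


def log10_evalue(profile: ProfileHMM, bit_score: float,
                 db_size: int) -> float:
    """log10 of the E-value, stable far into the significant tail.

    For strong scores the E-value underflows double precision; on that
    branch the Gumbel tail is ~exp(-lambda (s - mu)) and the log is
    computed analytically.
    """
    if not profile.calibrated:
        raise ProfileError(f"profile {profile.name!r} is not calibrated")
    x = -profile.gumbel_lambda * (bit_score - profile.gumbel_mu)
    if x < -30.0:  # p ~ exp(x), exact to double precision here
        return math.log10(db_size) + x / math.log(10.0)
    e = evalue(profile, bit_score, db_size)
    return math.log10(e) if e > 0 else -math.inf


# -- multi-profile scan -----------------------------------------------------


def scan_best_domains(profiles: Iterable[ProfileHMM], seq,
                      report_cutoff: float = 10.0,
                      db_size: int = 1) -> list[DomainHit]:
    """Scan one sequence against many profiles, best domain per region.

    Hits at E <= report_cutoff are sorted by E and kept greedily unless
    they overlap an already-kept hit over more than half of the shorter
    envelope. Output is ordered by envelope start.
    """
    hits = []
    for p in profiles:
        hit = viterbi_align(p, seq)
        hit.evalue = evalue(p, hit.bit_score, db_size)
        hit.log10_evalue = log10_evalue(p, hit.bit_score, db_size)
        if hit.evalue <= report_cutoff:
            hits.append(hit)
    hits.sort(key=lambda h: (h.log10_evalue, -h.bit_score, h.model_name))
    kept: list[DomainHit] = []
    for h in hits:
        clash = False
        for k in kept:
            ov = min(h.env_end, k.env_end) - max(h.env_start, k.env_start) + 1
            if ov > 0.5 * min(h.length, k.length):
                clash = True
                break
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: h.env_start)
    return kept


# -- generative operations --------------------------------------------------


def emit_consensus(profile: ProfileHMM) -> str:
    """Plurality consensus: the max-probability residue per match state.

    Ties break alphabetically (argmax over the alphabetically ordered
    residue axis).
    """
    idx = np.argmax(profile.match_emissions, axis=1)
    return "".join(AMINO_ACIDS[i] for i in idx)


def sample_sequence(profile: ProfileHMM, seed: int,
                    record_id: str = "sample") -> SequenceRecord:
    """Stochastic traversal of the state machine; deterministic per seed."""
    rng = np.random.default_rng(seed)
    m = profile.n_match
    out: list[str] = []

    def emit_match(j):
        out.append(AMINO_ACIDS[rng.choice(20,
                   p=profile.match_emissions[j - 1])])

    def emit_insert():
        out.append(AMINO_ACIDS[rng.choice(20, p=profile.insert_emissions)])

    state = "M" if rng.random() < profile.begin_match else "D"
    j = 1
    if state == "M":
        emit_match(1)
    while j < m:
        if state == "M":
            u = rng.random()
            if u < profile.t_mm[j]:
                nxt = "M"
            elif u < profile.t_mm[j] + profile.t_mi[j]:
                nxt = "I"
            else:
                nxt = "D"
        elif state == "I":
            nxt = "M" if rng.random() < profile.t_im[j] else "I"
        else:
            if j >= 2:
                nxt = "M" if rng.random() < profile.t_dm[j] else "D"
            else:  # D_1 exits into column 2 directly
                nxt = "M" if rng.random() < 0.5 else "D"
        if nxt == "I":
            emit_insert()
            state = "I"
            continue
        j += 1
        state = nxt
        if state == "M":
            emit_match(j)
    if not out:  # all-delete path; emit the consensus head instead
        out.append(emit_consensus(profile)[0])
    return SequenceRecord(id=record_id, sequence="".join(out))


# -- plain-text serialization ----------------------------------------------


def write_profile(profile: ProfileHMM, path: str | Path) -> None:
    """Serialise a profile to a documented plain-text format."""
    with open(Path(path), "w") as fh:
        fh.write("GPCRMINER_PROFILE 1\n")
        fh.write(f"NAME {profile.name}\n")
        fh.write(f"NMATCH {profile.n_match}\n")
        fh.write(f"BEGIN_MATCH {float(profile.begin_match)!r}\n")
        if profile.calibrated:
            fh.write(f"GUMBEL {float(profile.gumbel_lambda)!r} "
                     f"{float(profile.gumbel_mu)!r}\n")
        fh.write("BACKGROUND " +
                 " ".join(repr(float(x)) for x in profile.background) + "\n")
        fh.write("INSERT " +
                 " ".join(repr(float(x)) for x in profile.insert_emissions) + "\n")
        for k in range(profile.n_match):
            fh.write(f"MATCH {k + 1} " +
                     " ".join(repr(float(x)) for x in profile.match_emissions[k]) +
                     "\n")
        for tag, arr in (("TMM", profile.t_mm), ("TMI", profile.t_mi),
                         ("TMD", profile.t_md), ("TIM", profile.t_im),
                         ("TII", profile.t_ii), ("TDM", profile.t_dm),
                         ("TDD", profile.t_dd)):
            fh.write(f"{tag} " + " ".join(repr(float(x)) for x in arr) + "\n")


def read_profile(path: str | Path) -> ProfileHMM:
    with open(Path(path)) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines or not lines[0].startswith("GPCRMINER_PROFILE"):
        raise ProfileError(f"{path}: not a gpcrminer profile file")
    fields: dict = {"gumbel": None}
    match_rows = {}
    trans = {}
    for line in lines[1:]:
        tag, rest = line.split(" ", 1)
        if tag == "NAME":
            fields["name"] = rest
        elif tag == "NMATCH":
            fields["n_match"] = int(rest)
        elif tag == "BEGIN_MATCH":
            fields["begin_match"] = float(rest)
        elif tag == "GUMBEL":
            lam, mu = rest.split()
            fields["gumbel"] = (float(lam), float(mu))
        elif tag == "BACKGROUND":
            fields["background"] = np.array([float(x) for x in rest.split()])
        elif tag == "INSERT":
            fields["insert"] = np.array([float(x) for x in rest.split()])
        elif tag == "MATCH":
            k, vals = rest.split(" ", 1)
            match_rows[int(k)] = [float(x) for x in vals.split()]
        elif tag in ("TMM", "TMI", "TMD", "TIM", "TII", "TDM", "TDD"):
            trans[tag] = np.array([float(x) for x in rest.split()])
        else:
            raise ProfileError(f"{path}: unknown record {tag!r}")
    m = fields["n_match"]
    emis = np.array([match_rows[k + 1] for k in range(m)])
    lam_mu = fields["gumbel"]
    return ProfileHMM(
        name=fields["name"], match_emissions=emis,
        insert_emissions=fields["insert"],
        t_mm=trans["TMM"], t_mi=trans["TMI"], t_md=trans["TMD"],
        t_im=trans["TIM"], t_ii=trans["TII"],
        t_dm=trans["TDM"], t_dd=trans["TDD"],
        begin_match=fields["begin_match"], background=fields["background"],
        gumbel_lambda=None if lam_mu is None else lam_mu[0],
        gumbel_mu=None if lam_mu is None else lam_mu[1],
    )
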