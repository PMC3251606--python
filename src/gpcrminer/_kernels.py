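"""Numba DP kernels for profile-HMM alignment.

Scores are log2-odds against the background (null) model, so flanking
residues outside the local alignment contribute zero and cancel from the
recurrences. State layout (Plan-7-like local mode):

- match states M_1..M_m; insert state I_j between M_j and M_{j+1};
  delete states D_2..D_m (entry is into match states only, so D_1 is
  unreachable and inserts cannot open or close an alignment).
- uniform entry log2(1/m) into any match state; free exit from any match
  state.

Transition score arrays are indexed by the *source* state j and hold
-inf where a transition does not exist, which keeps the recurrences
branch-free.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=False)
def _log2addexp(a, b):
    if a < b:
        a, b = b, a
    d = a - b
    if d > 60.0:
        return a
    return a + math.log2(1.0 + 2.0 ** (-d))


@njit(cache=False)
def viterbi_matrices(obs, esc, sMM, sMI, sMD, sIM, sII, sDM, sDD, entry):
    """Fill Viterbi matrices and traceback pointers.

    obs: (L,) uint8 residue indices (X = 20); esc: (m, 21) emission
    log-odds with the X column zero. Returns (VM, VI, VD, pM, pI, pD).
    Pointer codes: 0 entry/none, 1 from M, 2 from I, 3 from D.
    """
    L = obs.shape[0]
    m = esc.shape[0]
    VM = np.full((L + 1, m + 1), NEG)
    VI = np.full((L + 1, m + 1), NEG)
    VD = np.full((L + 1, m + 1), NEG)
    pM = np.zeros((L + 1, m + 1), dtype=np.int8)
    pI = np.zeros((L + 1, m + 1), dtype=np.int8)
    pD = np.zeros((L + 1, m + 1), dtype=np.int8)
    for i in range(1, L + 1):
        a = obs[i - 1]
        for j in range(1, m + 1):
            best = entry
            code = 0
            v = VM[i - 1, j - 1] + sMM[j - 1]
            if v > best:
                best = v
                code = 1
            v = VI[i - 1, j - 1] + sIM[j - 1]
            if v > best:
                best = v
                code = 2
            v = VD[i - 1, j - 1] + sDM[j - 1]
            if v > best:
                best = v
                code = 3
            VM[i, j] = esc[j - 1, a] + best
            pM[i, j] = code
            if j < m:
                vi_m = VM[i - 1, j] + sMI[j]
                vi_i = VI[i - 1, j] + sII[j]
                if vi_m >= vi_i:
                    VI[i, j] = vi_m
                    pI[i, j] = 1
                else:
                    VI[i, j] = vi_i
                    pI[i, j] = 2
            if j >= 2:
                vd_m = VM[i, j - 1] + sMD[j - 1]
                vd_d = VD[i, j - 1] + sDD[j - 1]
                if vd_m >= vd_d:
                    VD[i, j] = vd_m
                    pD[i, j] = 1
                else:
                    VD[i, j] = vd_d
                    pD[i, j] = 3
    return VM, VI, VD, pM, pI, pD


@njit(cache=False)
def viterbi_score(obs, esc, sMM, sMI, sMD, sIM, sII, sDM, sDD, entry):
    """Best local-alignment log2-odds score only (no traceback)."""
    L = obs.shape[0]
    m = esc.shape[0]
    vm_prev = np.full(m + 1, NEG)  # VM row i-1
    vi_prev = np.full(m + 1, NEG)  # VI row i-1
    vd_prev = np.full(m + 1, NEG)  # VD row i-1
    vm = np.full(m + 1, NEG)
    vi = np.full(m + 1, NEG)
    vd = np.full(m + 1, NEG)
    best_all = NEG
    for i in range(1, L + 1):
        a = obs[i - 1]
        vd_left = NEG  # VD[i, j-1]
        vm_left = NEG  # VM[i, j-1]
        for j in range(1, m + 1):
            best = entry
            v = vm_prev[j - 1] + sMM[j - 1]
            if v > best:
                best = v
            v = vi_prev[j - 1] + sIM[j - 1]
            if v > best:
                best = v
            v = vd_prev[j - 1] + sDM[j - 1]
            if v > best:
                best = v
            cur = esc[j - 1, a] + best
            vm[j] = cur
            if cur > best_all:
                best_all = cur
            if j < m:
                vi_m = vm_prev[j] + sMI[j]
                vi_i = vi_prev[j] + sII[j]
                vi[j] = vi_m if vi_m >= vi_i else vi_i
            if j >= 2:
                vd_m = vm_left + sMD[j - 1]
                vd_d = vd_left + sDD[j - 1]
                vd_cur = vd_m if vd_m >= vd_d else vd_d
            else:
                vd_cur = NEG
            vm_left = cur
            vd_left = vd_cur
            vd[j] = vd_cur
        tmp = vm_prev
        vm_prev = vm
        vm = tmp
        tmp = vi_prev
        vi_prev = vi
        vi = tmp
        tmp = vd_prev
        vd_prev = vd
        vd = tmp
    return best_all


@njit(cache=False)
def forward_score(obs, esc, sMM, sMI, sMD, sIM, sII, sDM, sDD, entry):
    """Log2-sum of odds over all local paths (free exit from any match)."""
    L = obs.shape[0]
    m = esc.shape[0]
    FM = np.full((L + 1, m + 1), NEG)
    FI = np.full((L + 1, m + 1), NEG)
    FD = np.full((L + 1, m + 1), NEG)
    total = NEG
    for i in range(1, L + 1):
        a = obs[i - 1]
        for j in range(1, m + 1):
            s = entry
            s = _log2addexp(s, FM[i - 1, j - 1] + sMM[j - 1])
            s = _log2addexp(s, FI[i - 1, j - 1] + sIM[j - 1])
            s = _log2addexp(s, FD[i - 1, j - 1] + sDM[j - 1])
            FM[i, j] = esc[j - 1, a] + s
            total = _log2addexp(total, FM[i, j])
            if j < m:
                FI[i, j] = _log2addexp(FM[i - 1, j] + sMI[j],
                                       FI[i - 1, j] + sII[j])
            if j >= 2:
                FD[i, j] = _log2addexp(FM[i, j - 1] + sMD[j - 1],
                                       FD[i, j - 1] + sDD[j - 1])
    return total
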