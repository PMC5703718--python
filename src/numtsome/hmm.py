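"""Profile-HMM scoring for NumtS insertion dating.

A NumtS that inserted recently still looks mitochondrial; an old one has
compositionally homogenized with its nuclear neighbourhood.  Each NumtS is
therefore scored against two position-specific profiles — one derived from
its mitochondrial counterpart region and one from its own flanking regions
— and dated by the difference of the two log-odds scores (positive delta =
recent, negative = old).

Architecture: a simplified single-hit glocal profile HMM.  The full profile
(match/insert/delete columns) must be traversed; free sequence endpoints
are provided by flanking background-emitting states N (before) and C
(after) with self-loop probability 0.9.  Scores are log-odds in NATS
against a null model defined as the same state machine with every match
emission replaced by the background distribution, so a profile equal to
the background scores exactly zero and transition costs cancel.

Default transitions: t(M->M)=0.9, t(M->I)=t(M->D)=0.05, t(I->I)=t(D->D)=0.3
with the remainder to M; entry N->M1=0.95, N->D1=0.05 of the (1-0.9) mass
leaving N; M_k and D_k exit to C with probability 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

# state-machine constants (probabilities; see module docstring)
T_MM, T_MI, T_MD = 0.9, 0.05, 0.05
T_II, T_IM = 0.3, 0.7
T_DD, T_DM = 0.3, 0.7
FLANK_LOOP = 0.9
ENTRY_M, ENTRY_D = 0.95, 0.05

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
NEG_INF = float("-inf")


@dataclass
class ProfileHMM:
    match_emissions: np.ndarray        # (length, 4), rows sum to 1
    insert_emissions: np.ndarray       # (4,)
    background: np.ndarray             # (4,)
    pseudocount: float = 1.0

    def __post_init__(self):
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.match_emissions.ndim != 2 or self.match_emissions.shape[1] != 4:
            raise ValueError("match_emissions must be (length, 4)")
        if self.length < 1:
            raise ValueError("profile needs >= 1 match column")
        for name, arr in (("match", self.match_emissions),
                          ("insert", self.insert_emissions[None, :]),
                          ("background", self.background[None, :])):
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} emission rows must sum to 1")

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    def null(self) -> "ProfileHMM":
        """Same transitions and length, background emissions everywhere."""
        bg = np.tile(self.background, (self.length, 1))
        return ProfileHMM(bg, self.insert_emissions.copy(),
                          self.background.copy(), self.pseudocount)


@dataclass(frozen=True)
class DatingResult:
    numts_id: str
    score_mt: float        # nats
    score_flank: float     # nats
    delta: float           # score_mt - score_flank
    call: str              # recent / old / ambiguous


def build_profile(seqs: str | Sequence[str], pseudocount: float = 1.0,
                  background: Sequence[float] | None = None) -> ProfileHMM:
    """Profile from aligned sequences (or one unaligned sequence).

    Alignment columns with >= 50% residues become match columns; emissions
    are pseudocount-smoothed column frequencies, (count + pc) / (n + 4 pc)
    with n the residues in the column.  A single sequence gives a sharply
    informative but heavily smoothed profile (n = 1).
    """
    if isinstance(seqs, str):
        seqs = [seqs]
    seqs = [s.upper() for s in seqs]
    if not seqs or not seqs[0]:
        raise ValueError("empty input")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("aligned sequences must share one length")
    bg = (np.full(4, 0.25) if background is None
          else np.asarray(background, dtype=float))
    cols = []
    for j in range(width):
        residues = [s[j] for s in seqs if s[j] not in "-."]
        if len(residues) * 2 < len(seqs):
            continue                   # insert-like column
        counts = np.zeros(4)
        for r in residues:
            idx = _BASE_IDX.get(r)
            if idx is not None and idx < 4:
                counts[idx] += 1
        n = counts.sum()
        cols.append((counts + pseudocount) / (n + 4 * pseudocount))
    if not cols:
        raise ValueError("no match columns (all-gap alignment)")
    return ProfileHMM(np.array(cols), bg.copy(), bg.copy(), pseudocount)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_IDX[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc}") from None


def forward_logprob(profile: ProfileHMM, seq: str) -> float:
    """log P(seq | profile HMM) by the forward algorithm in log space.

    N bases emit with probability 0.25 from every emitting state.
    """
    if not seq:
        raise ValueError("empty sequence")
    x = _encode(seq)
    k = profile.length
    lem = np.log(np.hstack([profile.match_emissions,
                            np.full((k, 1), 0.25)]))
    lbg = np.log(np.append(profile.insert_emissions, 0.25))
    lmm, lmi, lmd = math.log(T_MM), math.log(T_MI), math.log(T_MD)
    lii, lim = math.log(T_II), math.log(T_IM)
    ldd, ldm = math.log(T_DD), math.log(T_DM)
    leta = math.log(FLANK_LOOP)
    lexit = math.log(1 - FLANK_LOOP)
    lem1 = math.log(ENTRY_M)
    led1 = math.log(ENTRY_D)

    idx = np.arange(1, k + 1, dtype=float)

    def delete_chain(d1: float, m_row: np.ndarray) -> np.ndarray:
        """D_1 = d1; D_j = logaddexp(M_{j-1} + lmd, D_{j-1} + ldd), solved
        as a prefix log-sum-exp scan (no per-column Python loop)."""
        seed = np.empty(k)
        seed[0] = d1 - ldd
        if k > 1:
            seed[1:] = m_row[:-1] + lmd - idx[1:] * ldd
        return np.logaddexp.accumulate(seed) + idx * ldd

    M = np.full(k, NEG_INF)
    I = np.full(max(k - 1, 0), NEG_INF)
    N = 0.0
    D = (N + lexit + led1) + ldd * np.arange(k, dtype=float)
    C = D[k - 1]

    for xi in x:
        newN = N + leta + lbg[xi]
        newM = np.full(k, NEG_INF)
        newM[0] = lem[0, xi] + N + lexit + lem1
        if k > 1:
            inner = np.logaddexp(M[:-1] + lmm, D[:-1] + ldm)
            if I.size:
                inner = np.logaddexp(inner, I + lim)
            newM[1:] = lem[1:, xi] + inner
        newI = (lbg[xi] + np.logaddexp(M[: k - 1] + lmi, I + lii)
                if I.size else I)
        newD = delete_chain(newN + lexit + led1, newM)
        newC = np.logaddexp(C + leta + lbg[xi],
                            np.logaddexp(newM[k - 1], newD[k - 1]))
        N, M, I, D, C = newN, newM, newI, newD, newC
    return float(C + lexit)


def forward_score(profile: ProfileHMM, seq: str) -> float:
    """Log-odds (nats): forward log-probability under the profile minus the
    same under its background null.  Zero for a background-equal profile."""
    return forward_logprob(profile, seq) - forward_logprob(profile.null(), seq)


def delta_score(numts_seq: str, mt_profile: ProfileHMM,
                flank_profile: ProfileHMM, numts_id: str = "",
                tolerance: float = 0.0) -> DatingResult:
    """Date one NumtS: mt-profile score minus flank-profile score."""
    s_mt = forward_score(mt_profile, numts_seq)
    s_fl = forward_score(flank_profile, numts_seq)
    delta = s_mt - s_fl
    if delta > tolerance:
        call = "recent"
    elif delta < -tolerance:
        call = "old"
    else:
        call = "ambiguous"
    return DatingResult(numts_id, s_mt, s_fl, delta, call)


def _stack_pseudoalignment(seqs: Sequence[str]) -> list[str]:
    """End-truncate unaligned sequences to the shortest so they can be
    stacked as a compositional pseudo-alignment."""
    w = min(len(s) for s in seqs)
    if w == 0:
        raise ValueError("empty flank sequence")
    return [s[:w] for s in seqs]


def flank_profile_for(numts_id: str,
                      flank_seqs: Mapping[str, Sequence[str]],
                      gap_fraction_max: float = 0.3,
                      pseudocount: float = 1.0) -> ProfileHMM:
    """Profile of a NumtS's own (repeat-subtracted) flanks, with a consensus
    fallback over all other NumtS flanks when the own flanks carry too many
    assembly gaps (N fraction above gap_fraction_max)."""
    own = [s for s in flank_seqs.get(numts_id, []) if s]
    joined = "".join(own)
    n_frac = (joined.upper().count("N") / len(joined)) if joined else 1.0
    if joined and n_frac <= gap_fraction_max:
        return build_profile(joined, pseudocount=pseudocount)
    pooled = ["".join(v) for key, v in sorted(flank_seqs.items())
              if key != numts_id and "".join(v)]
    pooled = [s for s in pooled
              if s.upper().count("N") / len(s) <= gap_fraction_max]
    if not pooled:
        raise ValueError("no usable flanks anywhere")
    return build_profile(_stack_pseudoalignment(pooled),
                         pseudocount=pseudocount)
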