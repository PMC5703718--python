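"""HSP detection: BLAST tabular I/O and a built-in seed-and-extend aligner.

The canonical input for large genomes is BlastN 12-column tabular output
(``read_blast_tab``).  For self-contained runs ``find_hsps`` provides a
stand-in local aligner: exact k-mer seeding on both strands, seed chaining,
ungapped X-drop boundary extension, then a gapped realignment of the
candidate region trimmed to its maximum-scoring contiguous stretch.  The
mitochondrial query is treated as circular by scanning its doubled
sequence and normalizing rotation-duplicate hits.

E-values use Karlin-Altschul statistics with the ungapped lambda solved
for the configured match/mismatch scores and K fixed at 0.21; they are
approximate and serve only for thresholding, as with any heuristic local
aligner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from scipy.optimize import brentq

from .simulate import revcomp

KARLIN_K = 0.21


@dataclass(frozen=True)
class HSP:
    """One local alignment between the mt query (plus strand) and a nuclear
    subject.  All coordinates 0-based half-open; mt_end may exceed the mt
    length for hits spanning the circular origin (unwrapped coordinates)."""

    mt_start: int
    mt_end: int
    chrom: str
    g_start: int
    g_end: int
    strand: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    bitscore: float
    evalue: float

    def __post_init__(self):
        if not self.mt_start < self.mt_end:
            raise ValueError("mt interval must be non-empty")
        if not self.g_start < self.g_end:
            raise ValueError("genomic interval must be non-empty")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("pct_identity out of range")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def g_interval(self) -> tuple[int, int]:
        return (self.g_start, self.g_end)

    def mt_intervals(self, mt_length: int | None = None):
        """mt interval(s), split at the origin when the hit wraps."""
        if mt_length is not None and self.mt_end > mt_length:
            return [(self.mt_start, mt_length), (0, self.mt_end - mt_length)]
        return [(self.mt_start, self.mt_end)]


@dataclass(frozen=True)
class DetectionParams:
    evalue_max: float = 1e-3
    word_size: int = 11
    xdrop: int = 20            # score units, ungapped boundary extension
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    max_hits: int = 200_000
    seed_gap: int = 200        # max bp between chained seeds
    diag_band: int = 50        # max diagonal drift within a chain
    extend_pad: int = 200      # bp of context realigned past the ungapped stop

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.word_size < 8:
            raise ValueError("word_size must be >= 8")
        if self.gap_open > 0 or self.gap_extend > 0 or self.mismatch > 0:
            raise ValueError("penalties must be <= 0")

    def karlin_lambda(self) -> float:
        """Ungapped lambda for uniform base composition: the positive root of
        sum_ij p_i p_j exp(lambda * s_ij) = 1."""
        f = lambda lam: (0.25 * math.exp(lam * self.match)
                         + 0.75 * math.exp(lam * self.mismatch) - 1.0)
        return brentq(f, 1e-6, 10.0)


# ---------------------------------------------------------------------------
# BLAST outfmt-6 tabular I/O

_BLAST_COLS = 12


def read_blast_tab(path) -> list[HSP]:
    """Parse 12-column BLAST tabular (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore), mt genome as query.

    BLAST 1-based inclusive coordinates become 0-based half-open; rows with
    send < sstart are minus-strand hits and get ordered coordinates.
    """
    hsps: list[HSP] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < _BLAST_COLS:
                raise ValueError(f"{path}: line {lineno}: expected "
                                 f"{_BLAST_COLS} columns, got {len(f)}")
            try:
                pident = float(f[2])
                length = int(f[3])
                mism = int(f[4])
                gapo = int(f[5])
                qs, qe = int(f[6]), int(f[7])
                ss, se = int(f[8]), int(f[9])
                ev = float(f[10])
                bits = float(f[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if ss <= se:
                strand, g_start, g_end = "+", ss - 1, se
            else:
                strand, g_start, g_end = "-", se - 1, ss
            hsps.append(HSP(mt_start=qs - 1, mt_end=qe, chrom=f[1],
                            g_start=g_start, g_end=g_end, strand=strand,
                            pct_identity=pident, aln_len=length,
                            mismatches=mism, gap_opens=gapo,
                            bitscore=bits, evalue=ev))
    hsps.sort(key=lambda h: (h.chrom, h.g_start, h.g_end))
    return hsps


def write_hsp_tab(hsps: Iterable[HSP], path, mt_name: str = "chrM") -> None:
    """Write the 12-column BLAST tabular dialect (1-based inclusive; minus
    strand encoded by sstart > send)."""
    with open(path, "w") as fh:
        for h in hsps:
            if h.strand == "+":
                ss, se = h.g_start + 1, h.g_end
            else:
                ss, se = h.g_end, h.g_start + 1
            fh.write("\t".join(map(str, (
                mt_name, h.chrom, f"{h.pct_identity:.2f}", h.aln_len,
                h.mismatches, h.gap_opens, h.mt_start + 1, h.mt_end,
                ss, se, f"{h.evalue:.2g}", f"{h.bitscore:.1f}",
            ))) + "\n")


# ---------------------------------------------------------------------------
# built-in seed-and-extend detection

def _kmer_index(mt_doubled: str, k: int, mt_len: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(min(len(mt_doubled) - k + 1, mt_len)):
        kmer = mt_doubled[i:i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _chain_seeds(matches: list[tuple[int, int]], params: DetectionParams):
    """Greedy chaining of (g_pos, mt_pos) seed matches by proximity and
    diagonal drift.  Returns chains as lists of matches."""
    matches.sort()
    finished: list[list[tuple[int, int]]] = []
    active: list[list[tuple[int, int]]] = []
    tails: list[tuple[int, int]] = []      # (g, diag) of each active chain tail
    horizon = params.seed_gap + params.word_size
    for g, m in matches:
        while tails and g - tails[0][0] > horizon:
            finished.append(active.pop(0))
            tails.pop(0)
        d = g - m
        best = -1
        for idx in range(len(active) - 1, -1, -1):
            tg, td = tails[idx]
            if abs(d - td) <= params.diag_band and g >= tg:
                best = idx
                break
        if best >= 0:
            active[best].append((g, m))
            tails[best] = (g, d)
        else:
            active.append([(g, m)])
            tails.append((g, d))
    return finished + active


def _ungapped_extend(sub: str, mt: str, g: int, m: int, step: int,
                     params: DetectionParams) -> tuple[int, int]:
    """Extend an ungapped alignment from (g, m) in direction step, returning
    the best-scoring endpoint (exclusive in the direction of travel)."""
    best = 0
    best_g, best_m = g, m
    score = 0
    while True:
        g += step
        m += step
        if not (0 <= g < len(sub) and 0 <= m < len(mt)):
            break
        score += params.match if sub[g] == mt[m] else params.mismatch
        if score > best:
            best, best_g, best_m = score, g, m
        elif best - score > params.xdrop:
            break
    return best_g, best_m


def _align_region(mt_sub: str, g_sub: str, params: DetectionParams):
    """Globally align the candidate region and trim to the maximum-scoring
    contiguous alignment stretch.  Returns per-alignment statistics plus the
    kept offsets into both substrings, or None when empty."""
    if not mt_sub or not g_sub:
        return None
    res = edlib.align(mt_sub, g_sub, mode="NW", task="path")
    cigar = res["cigar"]
    # expand to per-column (op) list with affine gap scoring
    col_scores: list[int] = []
    col_ops: list[str] = []
    num = ""
    mt_i = g_i = 0
    cols_mt: list[int] = []
    cols_g: list[int] = []
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        for j in range(n):
            cols_mt.append(mt_i)
            cols_g.append(g_i)
            if ch == "=":
                col_scores.append(params.match)
                mt_i += 1
                g_i += 1
            elif ch == "X":
                col_scores.append(params.mismatch)
                mt_i += 1
                g_i += 1
            elif ch == "I":                      # mt-only column (gap in subject)
                col_scores.append(params.gap_extend + (params.gap_open if j == 0 else 0))
                mt_i += 1
            else:                                # 'D': subject-only column
                col_scores.append(params.gap_extend + (params.gap_open if j == 0 else 0))
                g_i += 1
            col_ops.append(ch)
    cols_mt.append(mt_i)
    cols_g.append(g_i)
    # Kadane: max-scoring contiguous run of columns
    best_sum = cur = 0
    best_lo = best_hi = cur_lo = 0
    for i, s in enumerate(col_scores):
        if cur <= 0:
            cur = 0
            cur_lo = i
        cur += s
        if cur > best_sum:
            best_sum, best_lo, best_hi = cur, cur_lo, i + 1
    if best_hi <= best_lo:
        return None
    ops = col_ops[best_lo:best_hi]
    matches = ops.count("=")
    mismatches = ops.count("X")
    gap_opens = sum(1 for i, o in enumerate(ops)
                    if o in "ID" and (i == 0 or ops[i - 1] != o))
    return {
        "score": best_sum,
        "aln_len": best_hi - best_lo,
        "matches": matches,
        "mismatches": mismatches,
        "gap_opens": gap_opens,
        "mt_lo": cols_mt[best_lo], "mt_hi": cols_mt[best_hi],
        "g_lo": cols_g[best_lo], "g_hi": cols_g[best_hi],
    }


def find_hsps(nuclear: Mapping[str, str], mt: str,
              params: DetectionParams | None = None) -> list[HSP]:
    """Detect mtDNA-derived HSPs in nuclear sequences.

    Sequences are over {A,C,G,T,N}; N never seeds and mismatches everything.
    Hits with e-value above params.evalue_max are dropped; output is sorted
    by (chrom, g_start).
    """
    if params is None:
        params = DetectionParams()
    mt = mt.upper()
    L = len(mt)
    doubled = mt + mt
    index = _kmer_index(doubled, params.word_size, L)
    if not index:
        return []
    lam = params.karlin_lambda()
    total_n = sum(len(s) for s in nuclear.values())
    search_space = float(L) * max(total_n, 1)

    hsps: list[HSP] = []
    for chrom in sorted(nuclear):
        seq = nuclear[chrom].upper()
        n = len(seq)
        for strand in "+-":
            sub = seq if strand == "+" else revcomp(seq)
            matches: list[tuple[int, int]] = []
            k = params.word_size
            for g in range(0, n - k + 1):
                hitlist = index.get(sub[g:g + k])
                if hitlist:
                    for m in hitlist:
                        matches.append((g, m))
            if not matches:
                continue
            covered: list[tuple[int, int, int]] = []   # (g_lo, g_hi, diag)
            for chain in _chain_seeds(matches, params):
                g0, m0 = chain[0]
                g1, m1 = chain[-1]
                g1 += k - 1
                m1 += k - 1
                diag = g0 - m0
                if any(lo <= g0 and g1 <= hi and abs(diag - d) <= params.diag_band
                       for lo, hi, d in covered):
                    continue
                eg0, em0 = _ungapped_extend(sub, doubled, g0, m0, -1, params)
                eg1, em1 = _ungapped_extend(sub, doubled, g1, m1, +1, params)
                # pad past the ungapped stop so indel-interrupted terminal
                # segments are still realigned; the score trim removes junk
                pad = params.extend_pad
                lo_pad = min(pad, em0, eg0)
                hi_pad = min(pad, len(doubled) - em1 - 1, len(sub) - eg1 - 1)
                em0, eg0 = em0 - lo_pad, eg0 - lo_pad
                em1, eg1 = em1 + hi_pad, eg1 + hi_pad
                stats = _align_region(doubled[em0:em1 + 1], sub[eg0:eg1 + 1], params)
                if stats is None or stats["aln_len"] < params.word_size:
                    continue
                bits = (lam * stats["score"] - math.log(KARLIN_K)) / math.log(2)
                evalue = search_space * 2.0 ** (-bits)
                if evalue > params.evalue_max:
                    continue
                ms = em0 + stats["mt_lo"]
                me = em0 + stats["mt_hi"]
                gs = eg0 + stats["g_lo"]
                ge = eg0 + stats["g_hi"]
                covered.append((gs, ge, gs - ms))
                if ms >= L:                        # rotation duplicate
                    ms, me = ms - L, me - L
                if strand == "-":
                    gs, ge = n - ge, n - gs
                ident = 100.0 * stats["matches"] / stats["aln_len"]
                hsps.append(HSP(mt_start=ms, mt_end=me, chrom=chrom,
                                g_start=gs, g_end=ge, strand=strand,
                                pct_identity=round(ident, 2),
                                aln_len=stats["aln_len"],
                                mismatches=stats["mismatches"],
                                gap_opens=stats["gap_opens"],
                                bitscore=round(bits, 1), evalue=evalue))
                if len(hsps) >= params.max_hits:
                    break

    # drop near-duplicate hits (same strand, >=90% contained in a better
    # one); partially overlapping hits survive — assembly merges them
    hsps.sort(key=lambda h: -h.bitscore)
    kept: list[HSP] = []
    for h in hsps:
        dup = False
        for kpt in kept:
            if kpt.chrom == h.chrom and kpt.strand == h.strand:
                ov = min(kpt.g_end, h.g_end) - max(kpt.g_start, h.g_start)
                if ov >= 0.9 * (h.g_end - h.g_start):
                    dup = True
                    break
        if not dup:
            kept.append(h)
    kept.sort(key=lambda h: (h.chrom, h.g_start, h.g_end))
    return kept
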