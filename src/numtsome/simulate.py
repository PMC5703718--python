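"""Synthetic nuclear + mitochondrial genome pairs with planted NumtS.

The simulator emulates the situation a NumtS annotation pipeline faces on a
real assembly: a nuclear background containing mtDNA-derived fragments of
varying age, repeat elements crowding their flanks, and contamination
contigs that are wholly or mostly mitochondrial.  Every planted feature is
recorded as machine-readable ground truth so detection, purging, assembly,
coverage, dating and phylogeny can all be scored without downloads.

Fragment decay model: each planted fragment is evolved under a Kimura
2-parameter (K2P) substitution process to a chosen per-site substitution
load ("age", substitutions/site), plus single-base indels at a fixed
per-site rate.  The K2P stationary distribution is uniform, so old
fragments drift compositionally toward the (uniform) nuclear background —
the homogenization signal the profile-HMM dating stage relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .bedio import BedRow

BASES = "ACGT"
_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Mitochondrial protein-coding loci plus the control region (CR), with
# weights proportional to their typical vertebrate lengths; the tiling is
# rescaled to mt_length.
MT_LOCI: tuple[tuple[str, int], ...] = (
    ("ND1", 956), ("ND2", 1042), ("COX1", 1545), ("COX2", 684),
    ("ATP8", 207), ("ATP6", 681), ("COX3", 784), ("ND3", 346),
    ("ND4", 1675), ("ND5", 1812), ("ND6", 525), ("CYTB", 1141),
    ("CR", 1122),
)

# human-like mtDNA L-strand base composition (A, C, G, T): skewed away from
# the uniform nuclear background so composition carries an age signal
MT_COMPOSITION = (0.31, 0.31, 0.13, 0.25)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _LUT[codes].tobytes().decode()


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; identical config => identical bytes."""

    seed: int = 0
    mt_length: int = 17000
    n_chromosomes: int = 5
    chromosome_lengths: tuple[int, ...] | None = None
    n_insertions: int = 50
    age_grid: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15)
    kappa: float = 4.0          # transition/transversion rate ratio
    # single-base indel events per site per unit substitution load, so indels
    # accrue with age and an age-0 insertion is an exact copy
    indel_rate: float = 0.05
    re_density: float = 1.0     # expected repeats per 2-kb flank
    n_pure_mt_contigs: int = 3
    n_partial_mt_contigs: int = 4
    partial_occupancy: tuple[float, ...] = (0.85, 0.85, 0.5, 0.5)
    frag_min: int = 300
    frag_max: int = 5000
    background_composition: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    mt_composition: tuple[float, ...] = MT_COMPOSITION
    hotspot_locus: str = "CR"   # mt locus over-sampled as insertion source
    hotspot_fraction: float = 0.4
    min_spacing: int = 6000     # background bp kept between insertions
    flank_len: int = 2000
    n_bridge_pairs: int = 0     # repeat-bridged truth pairs (off by default)

    def __post_init__(self):
        if self.mt_length < 1000:
            raise ValueError("mt_length must be >= 1000")
        if self.chromosome_lengths is not None:
            object.__setattr__(
                self, "chromosome_lengths", tuple(self.chromosome_lengths)
            )
            if len(self.chromosome_lengths) != self.n_chromosomes:
                raise ValueError("chromosome_lengths/n_chromosomes mismatch")
        if any(a < 0 for a in self.age_grid):
            raise ValueError("age_grid values must be >= 0")
        occ = self.partial_occupancy
        if isinstance(occ, (int, float)):
            object.__setattr__(self, "partial_occupancy", (float(occ),))
        if any(not 0 < o <= 1 for o in self.partial_occupancy):
            raise ValueError("partial_occupancy must lie in (0, 1]")
        if not 0 < self.frag_min <= self.frag_max < self.mt_length // 2:
            raise ValueError("fragment lengths must fit within half of mt")

    def chrom_lengths(self) -> tuple[int, ...]:
        if self.chromosome_lengths is not None:
            return self.chromosome_lengths
        return (400_000,) * self.n_chromosomes


@dataclass(frozen=True)
class TruthRecord:
    """One planted NumtS; mt_start > mt_end flags an origin-spanning source."""

    chrom: str
    start: int
    end: int
    strand: str
    mt_start: int
    mt_end: int
    age: float

    def to_bed(self) -> BedRow:
        name = f"truth_mt_{self.mt_start}_{self.mt_end}_age{self.age:g}"
        return (self.chrom, self.start, self.end, name, 0, self.strand)


@dataclass
class SimulatedGenome:
    nuclear: dict[str, str]          # chromosomes plus contamination contigs
    mt: str
    loci: list[tuple[str, int, int]]
    truth: list[TruthRecord]
    repeats: list[BedRow]
    contig_labels: list[tuple[str, float]]  # (contig name, true mt occupancy)
    config: SimulationConfig


def random_sequence(length: int, composition: Sequence[float], rng) -> str:
    codes = rng.choice(4, size=length, p=np.asarray(composition) / np.sum(composition))
    return decode(codes.astype(np.uint8))


def k2p_event_probs(age: float, kappa: float) -> tuple[float, float]:
    """Expected transition (P) and transversion (Q) proportions at a given
    substitution load under K2P with ts/tv rate ratio kappa."""
    bt = age / (kappa + 2.0)
    at = kappa * bt
    p = 0.25 + 0.25 * math.exp(-4 * bt) - 0.5 * math.exp(-2 * (at + bt))
    q = 0.5 - 0.5 * math.exp(-4 * bt)
    return p, q


def mutate_k2p(seq: str, age: float, kappa: float, rng) -> str:
    """Apply K2P substitutions only (no indels) at the given age."""
    if age == 0:
        return seq
    codes = encode(seq).astype(np.uint8)
    p, q = k2p_event_probs(age, kappa)
    u = rng.random(codes.size)
    transition = codes ^ 2            # A<->G, C<->T
    coin = rng.integers(0, 2, codes.size).astype(np.uint8)
    transversion = np.where(coin == 0, codes ^ 1, codes ^ 3).astype(np.uint8)
    out = np.where(u < p, transition, np.where(u < p + q, transversion, codes))
    return decode(out.astype(np.uint8))


def apply_indels(seq: str, indel_rate: float, rng) -> str:
    if indel_rate <= 0:
        return seq
    u = rng.random(len(seq))
    hits = np.nonzero(u < indel_rate)[0]
    if hits.size == 0:
        return seq
    kind = rng.integers(0, 2, hits.size)          # 0 = deletion, 1 = insertion
    ins_base = rng.integers(0, 4, hits.size)
    parts: list[str] = []
    prev = 0
    for h, k, b in zip(hits, kind, ins_base):
        parts.append(seq[prev:h])
        if k == 0:                                 # drop the base
            prev = h + 1
        else:                                      # keep base, insert before it
            parts.append(BASES[b])
            prev = h
    parts.append(seq[prev:])
    return "".join(parts)


def decayed_fragment(mt: str, mt_start: int, length: int, strand: str,
                     age: float, config: SimulationConfig, rng) -> str:
    """Extract a (possibly origin-spanning) mt fragment and age it."""
    doubled = mt + mt
    frag = doubled[mt_start:mt_start + length]
    frag = mutate_k2p(frag, age, config.kappa, rng)
    frag = apply_indels(frag, config.indel_rate * age, rng)
    if strand == "-":
        frag = revcomp(frag)
    return frag


def generate_mt(config: SimulationConfig, rng=None):
    """Random circular mt genome plus a named locus tiling of [0, mt_length)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.mt_length < len(MT_LOCI):
        raise ValueError("mt_length too small to host the locus tiling")
    seq = random_sequence(config.mt_length, config.mt_composition, rng)
    weights = np.array([w for _, w in MT_LOCI], dtype=float)
    bounds = np.round(np.cumsum(weights) / weights.sum() * config.mt_length)
    bounds = bounds.astype(int)
    loci = []
    prev = 0
    for (name, _), b in zip(MT_LOCI, bounds):
        loci.append((name, prev, int(b)))
        prev = int(b)
    return seq, loci


def plant_numts(nuclear: Mapping[str, str], mt: str, config: SimulationConfig,
                loci=None, rng=None):
    """Splice aged mt fragments into background chromosomes.

    Returns the mutated chromosome dict and truth records in genomic order.
    Insertion points keep >= min_spacing background bases between fragments
    so each truth record maps 1:1 to one assembled NumtS downstream.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = len(mt)
    chroms = list(nuclear)
    lengths = np.array([len(nuclear[c]) for c in chroms], dtype=float)
    hotspot = None
    if loci is not None:
        for name, s, e in loci:
            if name == config.hotspot_locus:
                hotspot = (s, e)

    plan: dict[str, list[tuple[int, str, int, int, str, float]]] = {c: [] for c in chroms}
    used: dict[str, list[int]] = {c: [] for c in chroms}
    margin = config.flank_len + 500
    for i in range(config.n_insertions):
        age = config.age_grid[i % len(config.age_grid)]
        frag_len = int(rng.integers(config.frag_min, config.frag_max + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if hotspot is not None and rng.random() < config.hotspot_fraction:
            # hotspot fragments are wholly contained in the source locus
            width = hotspot[1] - hotspot[0]
            frag_len = min(frag_len, width)
            mt_start = int(rng.integers(hotspot[0],
                                        hotspot[1] - frag_len + 1))
        else:
            mt_start = int(rng.integers(0, L))
        chrom = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
        placed = False
        for _ in range(500):
            pos = int(rng.integers(margin, len(nuclear[chrom]) - margin))
            if all(abs(pos - p) >= config.min_spacing + config.frag_max
                   for p in used[chrom]):
                placed = True
                break
        if not placed:
            raise ValueError("requested insertions exceed available background space")
        used[chrom].append(pos)
        frag = decayed_fragment(mt, mt_start, frag_len, strand, age, config, rng)
        mt_end = mt_start + frag_len
        if mt_end > L:
            mt_end -= L      # wrap: mt_start > mt_end flags the origin span
        plan[chrom].append((pos, frag, mt_start, mt_end, strand, age))

    out: dict[str, str] = {}
    truth: list[TruthRecord] = []
    for chrom in chroms:
        background = nuclear[chrom]
        pieces: list[str] = []
        prev = 0
        shift = 0
        for pos, frag, mt_s, mt_e, strand, age in sorted(plan[chrom]):
            pieces.append(background[prev:pos])
            start = pos + shift
            truth.append(TruthRecord(chrom, start, start + len(frag), strand,
                                     mt_s, mt_e, age))
            pieces.append(frag)
            shift += len(frag)
            prev = pos
        pieces.append(background[prev:])
        out[chrom] = "".join(pieces)
    truth.sort(key=lambda t: (t.chrom, t.start))
    return out, truth


def plant_contamination(mt: str, config: SimulationConfig, rng=None):
    """Extra contigs that are wholly or partially mitochondrial."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    doubled = mt + mt
    contigs: dict[str, str] = {}
    labels: list[tuple[str, float]] = []
    for i in range(config.n_pure_mt_contigs):
        length = int(rng.integers(2000, 8001))
        start = int(rng.integers(0, len(mt)))
        name = f"contig_mt_pure_{i + 1}"
        contigs[name] = doubled[start:start + length]
        labels.append((name, 1.0))
    occs = config.partial_occupancy
    for i in range(config.n_partial_mt_contigs):
        occ = occs[i % len(occs)]
        length = int(rng.integers(4000, 10001))
        block = int(round(occ * length))
        start = int(rng.integers(0, len(mt)))
        offset = int(rng.integers(0, length - block + 1))
        bg = random_sequence(length - block, config.background_composition, rng)
        seq = bg[:offset] + doubled[start:start + block] + bg[offset:]
        name = f"contig_mt_part_{i + 1}"
        contigs[name] = seq
        labels.append((name, block / length))
    return contigs, labels


REPEAT_CLASSES = ("SINE_Alu", "LINE_L1", "LTR_ERVL", "DNA_hAT")


def plant_repeats(nuclear: Mapping[str, str], truth: Sequence[TruthRecord],
                  config: SimulationConfig, rng=None) -> list[BedRow]:
    """Repeat intervals placed inside the flanks of planted NumtS.

    With n_bridge_pairs > 0, consecutive same-strand truth pairs further than
    the merge distance apart get a single repeat spanning their whole gap, to
    exercise the unique-repeat merge rule.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows: list[BedRow] = []
    k = 0
    for t in truth:
        clen = len(nuclear[t.chrom])
        for side in (0, 1):
            n = int(rng.poisson(config.re_density))
            for _ in range(n):
                rlen = int(rng.integers(150, 801))
                if side == 0:
                    lo, hi = t.start - config.flank_len, t.start - rlen
                else:
                    lo, hi = t.end, t.end + config.flank_len - rlen
                if hi <= lo:
                    continue
                s = int(rng.integers(lo, hi))
                s2, e2 = max(0, s), min(clen, s + rlen)
                if e2 <= s2:
                    continue
                k += 1
                cls = REPEAT_CLASSES[int(rng.integers(0, len(REPEAT_CLASSES)))]
                rows.append((t.chrom, s2, e2, f"{cls}_{k}", 0, "+"))
    bridged = 0
    by_chrom: dict[str, list[TruthRecord]] = {}
    for t in truth:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, recs in sorted(by_chrom.items()):
        recs.sort(key=lambda t: t.start)
        for a, b in zip(recs, recs[1:]):
            if bridged >= config.n_bridge_pairs:
                break
            if a.strand == b.strand and 2000 < b.start - a.end <= 10000:
                bridged += 1
                rows.append((chrom, a.end, b.start, f"LTR_bridge_{bridged}", 0, "+"))
    rows.sort(key=lambda r: (r[0], r[1]))
    return rows


def simulate(config: SimulationConfig) -> SimulatedGenome:
    """Run the full generator with one seeded RNG stream."""
    rng = np.random.default_rng(config.seed)
    mt, loci = generate_mt(config, rng)
    background = {
        f"chr{i + 1}": random_sequence(l, config.background_composition, rng)
        for i, l in enumerate(config.chrom_lengths())
    }
    nuclear, truth = plant_numts(background, mt, config, loci=loci, rng=rng)
    contigs, labels = plant_contamination(mt, config, rng)
    nuclear.update(contigs)
    repeats = plant_repeats(nuclear, truth, config, rng)
    return SimulatedGenome(nuclear, mt, loci, truth, repeats, labels, config)


def e2e_config(seed: int = 0) -> SimulationConfig:
    """The documented end-to-end demo scenario: 5 x 400-kb chromosomes,
    50 insertions at ages up to 0.15 subst/site, 3 pure-mt contigs and
    partial contigs at 0.85 / 0.5 occupancy."""
    return SimulationConfig(seed=seed)
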