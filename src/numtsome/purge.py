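"""Purging of artefact contigs and assembly of HSPs into NumtS.

Purging removes (i) contigs whose mtDNA occupancy — the fraction of the
contig covered by the union of HSP subject intervals — is strictly greater
than 80%, and (ii) hits on random/unknown chromosome-style sequence names.
Surviving HSPs on the same chromosome and strand are merged into assembled
NumtS when they overlap, lie at most 2 kb apart, or when the gap between
them is covered (>= 90% of its length) by exactly one repeat element.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import intervals
from .bedio import BedRow
from .hsp import HSP


@dataclass(frozen=True)
class PurgeConfig:
    occupancy_max: float = 0.80
    excluded_chrom_patterns: tuple[str, ...] = ("random", "chrun", "unknown")

    def __post_init__(self):
        if not 0 < self.occupancy_max <= 1:
            raise ValueError("occupancy_max must be in (0, 1]")


@dataclass(frozen=True)
class AssembleConfig:
    max_gap: int = 2000            # inclusive: a 2000-bp gap still merges
    repeat_bridge: bool = True
    bridge_cover: float = 0.90     # fraction of the gap one repeat must span

    def __post_init__(self):
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass
class NumtS:
    """A merged run of same-chromosome, same-strand HSPs."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    members: list[HSP]
    mt_intervals: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_bed(self) -> BedRow:
        return (self.chrom, self.start, self.end, self.id, 0, self.strand)


@dataclass
class ContigReport:
    contig: str
    occupancy: float
    n_hsps_dropped: int


def occupancy_filter(hsps: Sequence[HSP], contig_lengths: Mapping[str, int],
                     config: PurgeConfig | None = None):
    """Drop whole contigs whose mt occupancy exceeds the threshold.

    Occupancy is |union of HSP subject intervals| / contig length, so
    overlapping hits cannot inflate it past 1.  "higher than 80%" is strict:
    a contig at exactly the threshold is kept.
    """
    if config is None:
        config = PurgeConfig()
    by_contig: dict[str, list[HSP]] = {}
    for h in hsps:
        if h.chrom not in contig_lengths:
            raise ValueError(f"no length known for contig {h.chrom!r}")
        by_contig.setdefault(h.chrom, []).append(h)
    removed: list[ContigReport] = []
    bad: set[str] = set()
    for contig, hits in sorted(by_contig.items()):
        occ = intervals.union_length([h.g_interval for h in hits]) / contig_lengths[contig]
        if occ > config.occupancy_max:
            bad.add(contig)
            removed.append(ContigReport(contig, occ, len(hits)))
    kept = [h for h in hsps if h.chrom not in bad]
    return kept, removed


def chrom_filter(hsps: Sequence[HSP], config: PurgeConfig | None = None):
    """Drop HSPs on random/unknown chromosomes by case-insensitive substring
    match against the configured name patterns."""
    if config is None:
        config = PurgeConfig()
    patterns = [p.lower() for p in config.excluded_chrom_patterns]
    kept = [h for h in hsps
            if not any(p in h.chrom.lower() for p in patterns)]
    return kept


def _merge_mt_intervals(members: Sequence[HSP]) -> list[tuple[int, int]]:
    return intervals.merge([(h.mt_start, h.mt_end) for h in members])


def _bridged(a: HSP, b: HSP, repeats_on_chrom: Sequence[tuple[int, int]],
             config: AssembleConfig) -> bool:
    gap_lo = min(a.g_end, b.g_end)
    gap_hi = max(a.g_start, b.g_start)
    if gap_hi <= gap_lo:
        return False
    gap_len = gap_hi - gap_lo
    touching = [r for r in repeats_on_chrom
                if intervals.overlap_length(r, (gap_lo, gap_hi)) > 0]
    if len(touching) != 1:
        return False
    cover = intervals.overlap_length(touching[0], (gap_lo, gap_hi))
    return cover >= config.bridge_cover * gap_len


def mergeable(a: HSP, b: HSP, repeats_on_chrom: Sequence[tuple[int, int]],
              config: AssembleConfig) -> bool:
    """Pairwise merge predicate: same chrom+strand and (overlap, gap <=
    max_gap, or unique-repeat bridge)."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    g = intervals.gap(a.g_interval, b.g_interval)
    if g <= config.max_gap:
        return True
    return config.repeat_bridge and _bridged(a, b, repeats_on_chrom, config)


def assemble_numts(hsps: Sequence[HSP],
                   repeats: Sequence[BedRow] | None = None,
                   config: AssembleConfig | None = None) -> list[NumtS]:
    """Transitive closure of the pairwise merge predicate (union-find),
    yielding one NumtS per merge class, sorted, with stable ids."""
    if config is None:
        config = AssembleConfig()
    rep_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if repeats:
        for r in repeats:
            rep_by_chrom.setdefault(r[0], []).append((int(r[1]), int(r[2])))
    hsps = sorted(hsps, key=lambda h: (h.chrom, h.g_start, h.g_end))
    parent = list(range(len(hsps)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    groups: dict[tuple[str, str], list[int]] = {}
    for i, h in enumerate(hsps):
        groups.setdefault((h.chrom, h.strand), []).append(i)
    for (chrom, _), idxs in groups.items():
        reps = rep_by_chrom.get(chrom, [])
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                i, j = idxs[ai], idxs[bi]
                if mergeable(hsps[i], hsps[j], reps, config):
                    parent[find(i)] = find(j)

    clusters: dict[int, list[HSP]] = {}
    for i, h in enumerate(hsps):
        clusters.setdefault(find(i), []).append(h)
    numts = []
    for members in clusters.values():
        members.sort(key=lambda h: (h.g_start, h.g_end))
        numts.append(NumtS(
            id="", chrom=members[0].chrom,
            start=min(h.g_start for h in members),
            end=max(h.g_end for h in members),
            strand=members[0].strand, members=members,
            mt_intervals=_merge_mt_intervals(members),
        ))
    numts.sort(key=lambda x: (x.chrom, x.start, x.end, x.strand))
    counters: dict[str, int] = {}
    for x in numts:
        counters[x.chrom] = counters.get(x.chrom, 0) + 1
        x.id = f"NumtS_{x.chrom}_{counters[x.chrom]}"
    return numts


def purge_and_assemble(hsps: Sequence[HSP], contig_lengths: Mapping[str, int],
                       repeats: Sequence[BedRow] | None = None,
                       purge_config: PurgeConfig | None = None,
                       assemble_config: AssembleConfig | None = None):
    """Convenience: occupancy filter, chrom filter, then assembly."""
    kept, removed = occupancy_filter(hsps, contig_lengths, purge_config)
    kept = chrom_filter(kept, purge_config)
    return assemble_numts(kept, repeats, assemble_config), kept, removed
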