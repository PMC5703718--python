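"""Repeat-element co-occurrence in NumtS loci and flanks, plus the
rank-correlation analyses (repeats vs NumtS, NumtS vs assembly statistics).

Overlap counting follows the bedtools-intersect default: a repeat interval
counts in every region class it touches by at least 1 bp.  Counts are
normalized by the number of NumtS so genomes of different NumtS load are
comparable.  Spearman correlations use average ranks for ties with the
two-sided t-approximation p-value, and significance is judged against a
Bonferroni-adjusted alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals
from .bedio import BedRow
from .purge import NumtS

Region = tuple[str, int, int]      # (chrom, start, end)


@dataclass(frozen=True)
class FlankSpec:
    flank_len: int = 2000          # 1000 for the dating subset
    clip_at_contig_ends: bool = True

    def __post_init__(self):
        if self.flank_len < 0:
            raise ValueError("flank_len must be >= 0")


@dataclass
class CorrelationReport:
    pairs: list[tuple[str, str]]
    rho: dict[tuple[str, str], float]
    p: dict[tuple[str, str], float]
    alpha: float
    alpha_adj: float
    significant: list[tuple[str, str]]


def flanks(numts: Sequence[NumtS], chrom_lengths: Mapping[str, int],
           spec: FlankSpec | None = None):
    """5' and 3' flanking intervals, strand-aware, clipped to the
    chromosome.  Returns two parallel lists of (chrom, start, end)."""
    if spec is None:
        spec = FlankSpec()
    five: list[Region] = []
    three: list[Region] = []
    for x in numts:
        clen = chrom_lengths[x.chrom]
        left = (x.chrom, max(0, x.start - spec.flank_len), x.start)
        right = (x.chrom, x.end, min(clen, x.end + spec.flank_len))
        if x.strand == "+":
            five.append(left)
            three.append(right)
        else:
            five.append(right)
            three.append(left)
    return five, three


def _count_overlapping(regions: Sequence[Region],
                       repeats: Sequence[BedRow]) -> int:
    """Number of repeat intervals overlapping >= 1 bp of any region."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in regions:
        by_chrom.setdefault(chrom, []).append((s, e))
    n = 0
    for r in repeats:
        ivs = by_chrom.get(r[0])
        if ivs and any(intervals.overlap_length((int(r[1]), int(r[2])), iv) > 0
                       for iv in ivs):
            n += 1
    return n


def count_re(numts: Sequence[NumtS], repeats: Sequence[BedRow],
             chrom_lengths: Mapping[str, int],
             spec: FlankSpec | None = None) -> pd.DataFrame:
    """Repeat counts per region class (5' flank, NumtS locus, 3' flank),
    raw and normalized by the NumtS count.  A repeat straddling a class
    boundary is counted in every class it touches."""
    five, three = flanks(numts, chrom_lengths, spec)
    loci = [(x.chrom, x.start, x.end) for x in numts]
    classes = {"flank_5p": five, "numts_locus": loci, "flank_3p": three}
    n_numts = max(len(numts), 1)
    rows = []
    for name, regions in classes.items():
        c = _count_overlapping(regions, repeats)
        rows.append({"region_class": name, "count": c,
                     "per_numts": c / n_numts})
    return pd.DataFrame(rows).set_index("region_class")


def interval_subtract(a: Sequence[tuple[int, int]],
                      b: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set-difference a \\ b as maximal disjoint intervals (both lists on the
    same sequence and coordinate convention)."""
    return intervals.subtract(a, b)


def re_free_subset(numts: Sequence[NumtS], repeats: Sequence[BedRow],
                   chrom_lengths: Mapping[str, int],
                   spec: FlankSpec | None = None) -> list[NumtS]:
    """NumtS with zero repeat overlap in their own locus and both flanks —
    the clean subset used for insertion dating (default flank 1000 bp)."""
    if spec is None:
        spec = FlankSpec(flank_len=1000)
    five, three = flanks(numts, chrom_lengths, spec)
    out = []
    for x, f5, f3 in zip(numts, five, three):
        regions = [f5, (x.chrom, x.start, x.end), f3]
        if _count_overlapping(regions, repeats) == 0:
            out.append(x)
    return out


def spearman_matrix(table: pd.DataFrame, alpha: float = 0.05) -> CorrelationReport:
    """All-pairs Spearman rho with p-values and a Bonferroni-adjusted
    threshold.  Constant variables yield undefined rho, reported as NaN."""
    cols = list(table.columns)
    pairs = list(itertools.combinations(cols, 2))
    if not pairs:
        raise ValueError("need at least two variables")
    rho: dict[tuple[str, str], float] = {}
    pval: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"pair ({a}, {b}): need >= 3 paired observations")
        if sub[a].nunique() == 1 or sub[b].nunique() == 1:
            rho[(a, b)] = float("nan")
            pval[(a, b)] = float("nan")
            continue
        r, p = stats.spearmanr(sub[a], sub[b])
        rho[(a, b)] = float(r)
        pval[(a, b)] = float(p)
    alpha_adj = alpha / len(pairs)
    significant = [pr for pr in pairs
                   if not np.isnan(pval[pr]) and pval[pr] < alpha_adj]
    return CorrelationReport(pairs, rho, pval, alpha, alpha_adj, significant)


def assembly_stats_correlation(path_or_df, alpha: float = 0.05) -> CorrelationReport:
    """Correlate NumtS counts with assembly contiguity statistics from a
    user-supplied TSV (species, numts_count, contig_n50, scaffold_n50,
    contig_l50, scaffold_l50, gap_size ... any numeric columns)."""
    df = (path_or_df if isinstance(path_or_df, pd.DataFrame)
          else pd.read_csv(path_or_df, sep="\t"))
    numeric = df.select_dtypes("number")
    return spearman_matrix(numeric, alpha=alpha)


def report_tsv(report: CorrelationReport, path) -> None:
    rows = [{"var_a": a, "var_b": b, "rho": report.rho[(a, b)],
             "p": report.p[(a, b)],
             "significant": (a, b) in report.significant}
            for a, b in report.pairs]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
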