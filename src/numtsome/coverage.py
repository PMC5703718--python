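"""Per-base occurrence of mtDNA positions across nuclear genomes.

The mitochondrial genome is held fixed and each HSP (or each member mt
interval of an assembled NumtS) increments the count at every mt position
it covers; the mt molecule is circular, so intervals may wrap across the
origin.  Profiles from several nuclear genomes can be layered, and maximal
runs above a threshold are called as hotspots annotated with the mt loci
they overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hsp import HSP
from .purge import NumtS


@dataclass
class CoverageProfile:
    mt_length: int
    counts: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.mt_length,):
            raise ValueError("counts length must equal mt_length")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class Hotspot:
    mt_start: int
    mt_end: int        # may exceed mt_length for an origin-spanning run
    peak: int
    loci: tuple[str, ...] = ()


def _normalize_interval(s: int, e: int, L: int) -> list[tuple[int, int]]:
    """Split a possibly wrapping mt interval into linear pieces in [0, L)."""
    if s > e:                      # wrap flagged by start > end
        e = e + L
    length = e - s
    if length > L:
        raise ValueError(f"mt interval ({s}, {e}) exceeds mt length {L}")
    if length <= 0:
        raise ValueError(f"empty mt interval ({s}, {e})")
    s %= L
    e = s + length
    if e <= L:
        return [(s, e)]
    return [(s, L), (0, e - L)]


def iter_mt_intervals(records: Iterable[HSP | NumtS | tuple[int, int]]):
    for rec in records:
        if isinstance(rec, HSP):
            yield (rec.mt_start, rec.mt_end)
        elif isinstance(rec, NumtS):
            yield from rec.mt_intervals
        else:
            yield rec


def mt_coverage(records: Iterable, mt_length: int, label: str = "") -> CoverageProfile:
    """Difference-array per-base counting; each record's mt interval
    increments every position it covers, wrapping across the origin."""
    diff = np.zeros(mt_length + 1, dtype=np.int64)
    for s, e in iter_mt_intervals(records):
        for ps, pe in _normalize_interval(int(s), int(e), mt_length):
            diff[ps] += 1
            diff[pe] -= 1
    counts = np.cumsum(diff[:-1])
    return CoverageProfile(mt_length, counts, label)


def layer_profiles(profiles: Mapping[str, CoverageProfile]):
    """Stack profiles into a position x label table plus mean/max summaries."""
    if not profiles:
        raise ValueError("no profiles given")
    lengths = {p.mt_length for p in profiles.values()}
    if len(lengths) != 1:
        raise ValueError("profiles have mixed mt_length")
    table = pd.DataFrame({label: p.counts for label, p in profiles.items()})
    table.index.name = "position"
    summary = pd.DataFrame({
        "mean": table.mean(axis=1),
        "max": table.max(axis=1),
    })
    return table, summary


def plot_layers(table: pd.DataFrame, loci=None, path=None):
    """Optional transparent area plot of layered profiles with locus
    boundaries as vertical lines.  Writes to ``path``; no interactive use."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.5))
    x = table.index.to_numpy()
    for label in table.columns:
        ax.fill_between(x, table[label].to_numpy(), alpha=0.25, label=label)
    if loci:
        for _, s, e in loci:
            ax.axvline(s, color="k", lw=0.4)
        ax.axvline(loci[-1][2], color="k", lw=0.4)
    ax.set_xlabel("mt position (bp)")
    ax.set_ylabel("per-base occurrence")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    plt.close(fig)


def call_hotspots(profile: CoverageProfile, threshold: float | None = None,
                  locus_map: Sequence[tuple[str, int, int]] | None = None
                  ) -> list[Hotspot]:
    """Maximal circular runs of positions with count >= threshold.

    A threshold in (0, 1) is read as a quantile of the nonzero counts
    (default: the 0.99 quantile); otherwise it is an absolute count.
    """
    counts = profile.counts
    L = profile.mt_length
    if threshold is None:
        threshold = 0.99
    if 0 < threshold < 1:
        nz = counts[counts > 0]
        if nz.size == 0:
            return []
        threshold = float(np.quantile(nz, threshold))
    mask = counts >= threshold
    if not mask.any():
        return []
    if mask.all():
        runs = [(0, L)]
    else:
        idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
        runs = [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]
        # join a run touching the end with one starting at 0 (circular)
        if len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == L:
            s, _ = runs[-1]
            _, e = runs[0]
            runs = runs[1:-1] + [(s, L + e)]
    out = []
    for s, e in runs:
        if e <= L:
            peak = int(counts[s:e].max())
            span = [(s, e)]
        else:
            peak = int(max(counts[s:L].max(), counts[: e - L].max()))
            span = [(s, L), (0, e - L)]
        loci: list[str] = []
        if locus_map:
            for name, ls, le in locus_map:
                if any(min(le, b) > max(ls, a) for a, b in span):
                    loci.append(name)
        out.append(Hotspot(s, e, peak, tuple(loci)))
    out.sort(key=lambda h: h.mt_start)
    return out


def genome_summary(numts: Sequence[NumtS], genome_size: int) -> dict:
    """Headline per-genome statistics: counts, density per Mb, genomic
    fraction, mean NumtS length and mean HSP identity."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    n_hsps = sum(len(x.members) for x in numts)
    total_bp = sum(x.length for x in numts)
    idents = [h.pct_identity for x in numts for h in x.members]
    return {
        "n_hsps": n_hsps,
        "n_numts": len(numts),
        "numts_per_Mb": len(numts) / (genome_size / 1e6),
        "total_numts_bp": total_bp,
        "percent_of_genome": 100.0 * total_bp / genome_size,
        "mean_length": (total_bp / len(numts)) if numts else math.nan,
        "mean_identity": (sum(idents) / len(idents)) if idents else math.nan,
    }


def write_profile_tsv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t")


def read_profile_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
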