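"""High-level pipeline stages: wiring between detection, purging, assembly,
dating and scoring against simulator ground truth.

Each function is a pure mapping from (inputs, config) to results; the CLI
is a thin shell around these.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import hmm, repeats as repeats_mod
from .hsp import HSP, DetectionParams, find_hsps
from .purge import AssembleConfig, NumtS, PurgeConfig, purge_and_assemble
from .simulate import SimulatedGenome, TruthRecord, revcomp


def detect(genome: SimulatedGenome,
           params: DetectionParams | None = None) -> list[HSP]:
    return find_hsps(genome.nuclear, genome.mt, params)


def purge_assemble(genome: SimulatedGenome, hsps: Sequence[HSP],
                   purge_config: PurgeConfig | None = None,
                   assemble_config: AssembleConfig | None = None):
    contig_lengths = {c: len(s) for c, s in genome.nuclear.items()}
    return purge_and_assemble(hsps, contig_lengths, genome.repeats,
                              purge_config, assemble_config)


# ---------------------------------------------------------------------------
# truth matching (recovery scoring on synthetic genomes)

@dataclass(frozen=True)
class TruthMatch:
    truth: TruthRecord
    numts_id: str | None
    boundary_error: int | None     # max endpoint deviation, bp
    exclusive: bool                # 1:1 - its NumtS matches no other truth


def match_truth(numts: Sequence[NumtS], truth: Sequence[TruthRecord]):
    """Assign each truth record the assembled NumtS with the largest
    genomic overlap; report boundary error and 1:1 exclusivity."""
    assigned: dict[str, list[int]] = {}
    picks: list[tuple[int, NumtS | None]] = []
    for ti, t in enumerate(truth):
        best = None
        best_ov = 0
        for x in numts:
            if x.chrom != t.chrom:
                continue
            ov = min(x.end, t.end) - max(x.start, t.start)
            if ov > best_ov:
                best_ov, best = ov, x
        picks.append((ti, best))
        if best is not None:
            assigned.setdefault(best.id, []).append(ti)
    out = []
    for ti, best in picks:
        t = truth[ti]
        if best is None:
            out.append(TruthMatch(t, None, None, False))
        else:
            err = max(abs(best.start - t.start), abs(best.end - t.end))
            out.append(TruthMatch(t, best.id, err,
                                  len(assigned[best.id]) == 1))
    return out


def recovery_rate(matches: Sequence[TruthMatch], max_boundary_error: int = 20,
                  min_age: float = 0.0, max_age: float = 0.15,
                  min_length: int = 300) -> float:
    """Fraction of eligible truth records recovered 1:1 within tolerance."""
    eligible = [m for m in matches
                if min_age <= m.truth.age <= max_age
                and (m.truth.end - m.truth.start) >= min_length]
    if not eligible:
        return float("nan")
    good = [m for m in eligible
            if m.numts_id is not None and m.exclusive
            and m.boundary_error is not None
            and m.boundary_error <= max_boundary_error]
    return len(good) / len(eligible)


# ---------------------------------------------------------------------------
# insertion dating

def numts_sequence(numts: NumtS, nuclear: Mapping[str, str]) -> str:
    """NumtS genomic sequence, reverse-complemented to mt orientation for
    minus-strand loci."""
    seq = nuclear[numts.chrom][numts.start:numts.end]
    return revcomp(seq) if numts.strand == "-" else seq


def mt_counterpart(numts: NumtS, mt: str) -> str:
    """Concatenated mt sequence over the NumtS's mt interval union
    (unwrapped across the circular origin where needed)."""
    doubled = mt + mt
    return "".join(doubled[s:e] for s, e in numts.mt_intervals)


def repeat_free_flank_seqs(numts: Sequence[NumtS], nuclear: Mapping[str, str],
                           repeat_rows, flank_len: int = 1000):
    """Per-NumtS [5', 3'] flank sequences with repeat intervals excised."""
    chrom_lengths = {c: len(s) for c, s in nuclear.items()}
    spec = repeats_mod.FlankSpec(flank_len=flank_len)
    five, three = repeats_mod.flanks(numts, chrom_lengths, spec)
    rep_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in repeat_rows:
        rep_by_chrom.setdefault(r[0], []).append((int(r[1]), int(r[2])))

    def extract(region):
        chrom, s, e = region
        if e <= s:
            return ""
        pieces = repeats_mod.interval_subtract(
            [(s, e)], rep_by_chrom.get(chrom, []))
        return "".join(nuclear[chrom][a:b] for a, b in pieces)

    return {x.id: [extract(f5), extract(f3)]
            for x, f5, f3 in zip(numts, five, three)}


def date_numts(numts: Sequence[NumtS], nuclear: Mapping[str, str], mt: str,
               repeat_rows, flank_len: int = 1000, pseudocount: float = 1.0,
               gap_fraction_max: float = 0.3, restrict_re_free: bool = True,
               tolerance: float = 0.0) -> list[hmm.DatingResult]:
    """Profile-score dating of a NumtS set.

    Scores each NumtS against a profile of its mt counterpart and one of
    its own repeat-subtracted flanks; by default only the repeat-free
    subset (no repeat overlap in locus or flanks) is dated.
    """
    chrom_lengths = {c: len(s) for c, s in nuclear.items()}
    subset = list(numts)
    if restrict_re_free:
        subset = repeats_mod.re_free_subset(
            subset, repeat_rows, chrom_lengths,
            repeats_mod.FlankSpec(flank_len=flank_len))
    if not subset:
        return []
    flank_seqs = repeat_free_flank_seqs(subset, nuclear, repeat_rows, flank_len)
    results = []
    for x in subset:
        seq = numts_sequence(x, nuclear)
        mt_prof = hmm.build_profile(mt_counterpart(x, mt),
                                    pseudocount=pseudocount)
        fl_prof = hmm.flank_profile_for(x.id, flank_seqs,
                                        gap_fraction_max=gap_fraction_max,
                                        pseudocount=pseudocount)
        results.append(hmm.delta_score(seq, mt_prof, fl_prof, numts_id=x.id,
                                       tolerance=tolerance))
    return results


def dating_table(results: Sequence[hmm.DatingResult]):
    import pandas as pd

    return pd.DataFrame(
        [{"numts_id": r.numts_id, "score_mt": r.score_mt,
          "score_flank": r.score_flank, "delta": r.delta, "call": r.call}
         for r in results])
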