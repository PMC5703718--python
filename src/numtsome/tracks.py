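"""UCSC-style annotation tracks and NumtS/mt mismatch calling.

Four track files are emitted per compilation: purged HSPs on nuclear
coordinates ("NumtS"), merged NumtS ("Assembled NumtS"), their
mitochondrial mapping ("NumtS on mitochondrion"), and a per-NumtS
substitution/indel record set ("NumtS on mitochondrion with mismatches").
Nuclear and mitochondrial items cross-reference each other by name.  BED
output is BED6, 0-based half-open, with a ``track`` header line; mismatch
records are TSV (mt coordinates, 0-based) with optional SAM output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import global_affine
from .bedio import write_bed
from .hsp import HSP
from .purge import NumtS


@dataclass
class TrackSet:
    numts_track: str
    assembled_track: str
    mt_track: str
    mismatch_track: str | None = None


@dataclass(frozen=True)
class MismatchRecord:
    mt_pos: int        # 0-based on the mt plus strand
    mt_base: str       # '-' for an insertion in the nuclear copy
    nuc_base: str      # '-' for a deletion in the nuclear copy
    kind: str          # 'sub' | 'ins' | 'del'


def write_tracks(numts: Sequence[NumtS], hsps: Sequence[HSP],
                 mt_length: int, outdir, label: str = "numtsome",
                 mt_name: str = "chrM") -> TrackSet:
    """Write the BED track files; assembled and mt items share names."""
    os.makedirs(outdir, exist_ok=True)
    member_of: dict[int, str] = {}
    for x in numts:
        for h in x.members:
            member_of[id(h)] = x.id

    hsp_rows = []
    counters: dict[str, int] = {}
    for h in sorted(hsps, key=lambda h: (h.chrom, h.g_start, h.g_end)):
        owner = member_of.get(id(h), "unassembled")
        counters[owner] = counters.get(owner, 0) + 1
        hsp_rows.append((h.chrom, h.g_start, h.g_end,
                         f"{owner}_hsp{counters[owner]}",
                         min(1000, int(round(h.bitscore))), h.strand))
    numts_path = os.path.join(outdir, f"{label}_numts.bed")
    write_bed(numts_path, hsp_rows,
              track_line=f'track name="NumtS ({label})" description="purged HSPs"')

    assembled_path = os.path.join(outdir, f"{label}_assembled.bed")
    write_bed(assembled_path, [x.to_bed() for x in numts],
              track_line=f'track name="Assembled NumtS ({label})"')

    mt_rows = []
    for x in numts:
        for s, e in x.mt_intervals:
            for ps, pe in (((s, e),) if e <= mt_length
                           else ((s, mt_length), (0, e - mt_length))):
                mt_rows.append((mt_name, ps, pe, x.id, 0, x.strand))
    mt_rows.sort(key=lambda r: (r[1], r[2], r[3]))
    mt_path = os.path.join(outdir, f"{label}_on_mt.bed")
    write_bed(mt_path, mt_rows,
              track_line=f'track name="NumtS on mitochondrion ({label})"')
    return TrackSet(numts_path, assembled_path, mt_path)


def mismatch_records(numts_seq: str, mt_counterpart_seq: str,
                     mt_offset: int = 0):
    """Globally align a NumtS to its mt counterpart (score-based affine
    Needleman-Wunsch) and report every substitution and indel in mt
    coordinates, plus the extended CIGAR.

    Positions are 0-based on the mt plus strand; minus-strand NumtS should
    be reverse-complemented by the caller first.
    """
    if not numts_seq or not mt_counterpart_seq:
        raise ValueError("both sequences must be nonempty")
    _, cigar = global_affine(numts_seq.upper(), mt_counterpart_seq.upper())
    records: list[MismatchRecord] = []
    qi = 0                      # nuclear (query) offset
    ti = 0                      # mt (target) offset
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            qi += n
            ti += n
        elif ch == "X":
            for _ in range(n):
                records.append(MismatchRecord(
                    mt_offset + ti, mt_counterpart_seq[ti].upper(),
                    numts_seq[qi].upper(), "sub"))
                qi += 1
                ti += 1
        elif ch == "I":         # extra base in the nuclear copy
            for _ in range(n):
                records.append(MismatchRecord(
                    mt_offset + ti, "-", numts_seq[qi].upper(), "ins"))
                qi += 1
        else:                   # 'D': base deleted from the nuclear copy
            for _ in range(n):
                records.append(MismatchRecord(
                    mt_offset + ti, mt_counterpart_seq[ti].upper(), "-", "del"))
                ti += 1
    return records, cigar


def write_mismatch_tsv(path, per_numts: Mapping[str, Sequence[MismatchRecord]]) -> None:
    with open(path, "w") as fh:
        fh.write("numts_id\tmt_pos\tmt_base\tnuc_base\tkind\n")
        for numts_id in sorted(per_numts):
            for r in per_numts[numts_id]:
                fh.write(f"{numts_id}\t{r.mt_pos}\t{r.mt_base}\t"
                         f"{r.nuc_base}\t{r.kind}\n")


def write_mismatch_sam(path, alignments: Sequence[tuple[str, int, str, str]],
                       mt_name: str = "chrM", mt_length: int = 0) -> None:
    """Minimal SAM with one line per NumtS: (id, mt_pos, cigar, seq).

    The extended CIGAR (=/X/I/D) is converted to standard M/I/D operations.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{mt_name}\tLN:{mt_length}\n")
        for name, pos, cigar, seq in sorted(alignments, key=lambda a: a[1]):
            sam_cigar = cigar.replace("=", "M").replace("X", "M")
            fh.write(f"{name}\t0\t{mt_name}\t{pos + 1}\t255\t{sam_cigar}"
                     f"\t*\t0\t0\t{seq}\t*\n")


# ---------------------------------------------------------------------------
# cross-compilation scheduling

@dataclass(frozen=True)
class CompilationJob:
    mt_species: str
    nuclear_species: str

    @property
    def kind(self) -> str:
        return "intra" if self.mt_species == self.nuclear_species else "inter"

    @property
    def name(self) -> str:
        if self.kind == "intra":
            return self.mt_species
        return f"{self.mt_species}__on__{self.nuclear_species}"


def cross_compilation_jobs(labels: Sequence[str]) -> list[CompilationJob]:
    """All intra- plus interspecies compilations: n + n*(n-1) jobs for n
    genome labels (23 labels -> 23 intra and 506 inter)."""
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate genome labels")
    return [CompilationJob(mt, nuc) for mt in labels for nuc in labels]
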