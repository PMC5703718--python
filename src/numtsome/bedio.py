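"""BED and FASTA file helpers.

BED records are ``(chrom, start, end, name, score, strand)`` with 0-based
half-open coordinates, the UCSC convention.  Writers accept 3-6 columns;
the reader always returns 6-tuples padded with defaults.  Optional UCSC
``track`` header lines are skipped on read and emitted on request.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BedRow = tuple[str, int, int, str, int, str]


def write_bed(path, rows: Iterable[Sequence], track_line: str | None = None) -> None:
    with open(path, "w") as fh:
        if track_line:
            fh.write(track_line.rstrip("\n") + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[BedRow]:
    rows: list[BedRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            score = int(float(f[4])) if len(f) > 4 and f[4] != "." else 0
            strand = f[5] if len(f) > 5 else "+"
            rows.append((chrom, start, end, name, score, strand))
    return rows


def write_fasta(path, seqs: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def fasta_str(seqs: Mapping[str, str]) -> str:
    buf = io.StringIO()
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()
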