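"""Artificial paired-end reads from the ends of long reads.

Slicing a fixed-length mate off each end of a long read turns it into a
large-insert "paired-end" read whose mapped mates probe assembly continuity
across regions that defeat full-length alignment.  Mate 1 is the 5' prefix;
mate 2 is the reverse complement of the 3' suffix (standard FR orientation),
toggleable for pipelines expecting both mates on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class ReadPair:
    name: str
    mate1: str
    mate2: str
    qual1: str | None = None
    qual2: str | None = None


@dataclass
class SkipReport:
    n_input: int = 0
    n_pairs: int = 0
    n_skipped_short: int = 0


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def make_end_pairs(
    records: Iterable[SeqRecord],
    end_len: int = 300,
    revcomp_mate2: bool = True,
    report: SkipReport | None = None,
) -> Iterator[ReadPair]:
    """Yield one end pair per read of length ≥ 2·``end_len``.

    Shorter reads are skipped (overlapping mates would misrepresent the
    insert) and counted in ``report``.  FASTQ qualities are sliced in
    register with the bases; mate-2 qualities are reversed when the sequence
    is reverse-complemented.
    """
    if end_len < 1:
        raise ValueError("end_len must be >= 1")
    for rec in records:
        if report is not None:
            report.n_input += 1
        seq = str(rec.seq)
        if len(seq) < 2 * end_len:
            if report is not None:
                report.n_skipped_short += 1
            continue
        mate1 = seq[:end_len]
        suffix = seq[-end_len:]
        mate2 = _revcomp(suffix) if revcomp_mate2 else suffix
        quals = rec.letter_annotations.get("phred_quality")
        qual1 = qual2 = None
        if quals is not None:
            qual1 = "".join(chr(q + 33) for q in quals[:end_len])
            tail = quals[-end_len:]
            qual2 = "".join(chr(q + 33) for q in (tail[::-1] if revcomp_mate2 else tail))
        if report is not None:
            report.n_pairs += 1
        yield ReadPair(name=rec.id, mate1=mate1, mate2=mate2, qual1=qual1, qual2=qual2)


def write_end_pairs(
    in_path,
    out1,
    out2,
    end_len: int = 300,
    revcomp_mate2: bool = True,
) -> SkipReport:
    """Stream a FASTA/FASTQ file into two mate files; returns the skip report.

    Output format follows the input: FASTQ in → FASTQ out, FASTA in → FASTA
    out (no fabricated qualities).
    """
    in_path = Path(in_path)
    fmt = "fastq" if in_path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    try:
        records = SeqIO.parse(str(in_path), fmt)
        report = SkipReport()
        with open(out1, "w") as fh1, open(out2, "w") as fh2:
            for pair in make_end_pairs(records, end_len, revcomp_mate2, report):
                if fmt == "fastq":
                    fh1.write(f"@{pair.name}/1\n{pair.mate1}\n+\n{pair.qual1}\n")
                    fh2.write(f"@{pair.name}/2\n{pair.mate2}\n+\n{pair.qual2}\n")
                else:
                    fh1.write(f">{pair.name}/1\n{pair.mate1}\n")
                    fh2.write(f">{pair.name}/2\n{pair.mate2}\n")
    except ValueError as exc:
        raise ValueError(f"malformed {fmt} input {in_path}: {exc}") from exc
    return report
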