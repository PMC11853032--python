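"""GC-corrected telomere content from raw sequencing reads.

A simplified estimator of per-sample telomere content: reads carrying at least
``t`` (non-overlapping, not necessarily consecutive) copies of the telomeric
hexamer TTAGGG — on either strand — count as intratelomeric, and the content is

    tel_content = intratel_reads * 1_000_000 / total_reads_with_tel_gc

where the denominator is the number of reads whose GC fraction falls in the
telomere-like window [0.48, 0.52] (inclusive; a pure-repeat read has GC 0.50).
Dividing by GC-matched rather than total reads corrects for GC bias in library
coverage.

Deliberate simplifications relative to full alignment-based telomere callers:
all repeat-passing reads count as intratelomeric (no alignment-coordinate or
mapping-quality stratification into telomeric regions), and only the canonical
motif is used (no variant repeats).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "ReadRecord",
    "TelomereContentResult",
    "count_repeats",
    "classify_telomeric",
    "default_threshold",
    "gc_fraction",
    "telomere_content",
    "read_records",
    "write_content_tsv",
]

CANONICAL_MOTIF = "TTAGGG"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: an ID and an uppercase A/C/G/T/N sequence."""

    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"read {self.read_id!r} has non-ACGTN characters: {bad}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TelomereContentResult:
    sample_id: str
    intratel_reads: int
    total_reads_with_tel_gc: int
    tel_content: float

    def __post_init__(self) -> None:
        if self.intratel_reads < 0 or self.total_reads_with_tel_gc < 0:
            raise ValueError("read counts must be non-negative")


def count_repeats(sequence: str, motif: str = CANONICAL_MOTIF) -> int:
    """Non-overlapping occurrences of the motif, counted on the better strand.

    The forward motif and its reverse complement are counted separately (a
    read is wholly from one strand) and the larger count is returned.
    Occurrences need not be consecutive.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not motif:
        raise ValueError("motif must be non-empty")
    seq = sequence.upper()
    fwd = seq.count(motif.upper())
    rev = seq.count(reverse_complement(motif.upper()))
    return max(fwd, rev)


def default_threshold(read_length: int, per_100bp: int = 6) -> int:
    """Length-proportional repeat threshold: floor(length × per_100bp / 100), at least 1."""
    return max(1, (read_length * per_100bp) // 100)


def classify_telomeric(read: ReadRecord, threshold: int | None = None, motif: str = CANONICAL_MOTIF) -> bool:
    """True iff the read carries at least ``threshold`` motif copies.

    With ``threshold=None`` the length-proportional default is used
    (6 repeats per 100 bp, minimum 1).
    """
    t = default_threshold(read.length) if threshold is None else threshold
    if t < 1:
        raise ValueError("repeat threshold must be >= 1")
    return count_repeats(read.sequence, motif) >= t


def gc_fraction(sequence: str) -> float | None:
    """(G+C)/(A+C+G+T); N bases are excluded entirely.  All-N reads return None."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        return None
    return gc / acgt


def telomere_content(
    reads: Iterable[ReadRecord],
    threshold: int | None = None,
    gc_window: tuple[float, float] = (0.48, 0.52),
    motif: str = CANONICAL_MOTIF,
    sample_id: str = "sample",
) -> TelomereContentResult:
    """Compute GC-corrected telomere content for one sample's reads.

    Raises when no read falls in the GC window (the content is undefined, not
    zero) or when the read collection is empty.
    """
    lo, hi = gc_window
    if not (0 <= lo <= hi <= 1):
        raise ValueError("GC window must satisfy 0 <= low <= high <= 1")
    intratel = 0
    in_window = 0
    n = 0
    for read in reads:
        n += 1
        if classify_telomeric(read, threshold, motif):
            intratel += 1
        gc = gc_fraction(read.sequence)
        if gc is not None and lo <= gc <= hi:  # inclusive bounds
            in_window += 1
    if n == 0:
        raise ValueError("read collection is empty")
    if in_window == 0:
        raise ValueError(
            f"sample {sample_id!r}: no reads with GC in [{lo}, {hi}]; telomere content undefined"
        )
    return TelomereContentResult(
        sample_id=sample_id,
        intratel_reads=intratel,
        total_reads_with_tel_gc=in_window,
        tel_content=intratel * 1_000_000 / in_window,
    )


def read_records(path: str | Path, fmt: str | None = None) -> Iterator[ReadRecord]:
    """Stream reads from FASTA/FASTQ (by extension) or SAM/BAM (sequence only).

    Alignment coordinates in SAM/BAM are ignored; only read sequences are used.
    """
    p = Path(path)
    if fmt is None:
        suffix = p.suffix.lower()
        fmt = {
            ".fa": "fasta",
            ".fasta": "fasta",
            ".fna": "fasta",
            ".fq": "fastq",
            ".fastq": "fastq",
            ".sam": "sam",
            ".bam": "bam",
        }.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer read format from {p.name!r}; pass fmt explicitly")
    if fmt in ("fasta", "fastq"):
        for rec in SeqIO.parse(str(p), fmt):
            yield ReadRecord(rec.id, str(rec.seq))
    elif fmt in ("sam", "bam"):
        import pysam

        mode = "rb" if fmt == "bam" else "r"
        with pysam.AlignmentFile(str(p), mode, check_sq=False) as fh:
            for aln in fh.fetch(until_eof=True):
                if aln.query_sequence:
                    yield ReadRecord(aln.query_name, aln.query_sequence)
    else:
        raise ValueError(f"unsupported read format {fmt!r}")


def write_content_tsv(results: Iterable[TelomereContentResult], path: str | Path) -> None:
    """Write results in the telomere.tsv layout consumed by the cohort readers."""
    with open(path, "w") as fh:
        fh.write("sample_id\tintratel_reads\ttotal_reads_with_tel_gc\ttel_content\n")
        for r in results:
            fh.write(f"{r.sample_id}\t{r.intratel_reads}\t{r.total_reads_with_tel_gc}\t{r.tel_content:.17g}\n")
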