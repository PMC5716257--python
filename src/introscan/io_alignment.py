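"""Reference and alignment input: FASTA lengths, MD-tag parsing, read streaming.

The per-base homology signal is built entirely in reference space from the
``MD:Z:`` optional tag of each alignment record.  The MD tag encodes, walking
along the reference, the run-lengths of matching bases, the reference base at
each mismatch, and any deleted reference bases (``^``-prefixed).  Insertions
in the read consume no reference bases and never appear in MD, so they
contribute nothing to the match vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pysam
from Bio import SeqIO

__all__ = [
    "AlignedReadView",
    "ReferenceMatchVector",
    "ReferenceIndex",
    "FilterPolicy",
    "AlignmentStream",
    "FastaFormatError",
    "MDParseError",
    "read_reference_lengths",
    "parse_md",
    "stream_alignments",
]


class FastaFormatError(ValueError):
    """Raised when a reference FASTA is empty or malformed."""


class MDParseError(ValueError):
    """Raised when an MD tag violates the SAM MD grammar.

    Carries the offending tag and the 0-based offset of the first bad
    character.
    """

    def __init__(self, md_tag: str, offset: int, reason: str):
        self.md_tag = md_tag
        self.offset = offset
        super().__init__(f"bad MD tag {md_tag!r} at offset {offset}: {reason}")


@dataclass(frozen=True)
class AlignedReadView:
    """The fields of one alignment record needed for homology scoring."""

    reference_name: str
    start_pos: int  # 1-based leftmost aligned reference coordinate
    md_tag: str
    is_unmapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if not self.is_unmapped and self.start_pos < 1:
            raise ValueError(f"start_pos must be >= 1, got {self.start_pos}")


@dataclass(frozen=True)
class ReferenceMatchVector:
    """Binary reference-space vector: 1 = match, 0 = mismatch or deletion.

    ``ref_span`` is the number of reference bases the alignment consumes,
    which by construction equals ``len(values)``.
    """

    values: np.ndarray
    ref_span: int

    def __post_init__(self) -> None:
        if len(self.values) != self.ref_span:
            raise ValueError("match vector length must equal ref_span")


@dataclass
class ReferenceIndex:
    """Ordered map of chromosome id -> length in bp, as read from FASTA."""

    lengths: dict[str, int]

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __iter__(self) -> Iterator[str]:
        return iter(self.lengths)

    def __len__(self) -> int:
        return len(self.lengths)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())


@dataclass(frozen=True)
class FilterPolicy:
    """Which alignment records to drop before scoring.

    Defaults mirror a de-duplicated alignment workflow: unmapped, secondary,
    supplementary and duplicate-flagged records are all excluded.
    """

    drop_unmapped: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_duplicates: bool = True

    def passes(self, read: AlignedReadView) -> bool:
        if self.drop_unmapped and read.is_unmapped:
            return False
        if self.drop_secondary and read.is_secondary:
            return False
        if self.drop_supplementary and read.is_supplementary:
            return False
        if self.drop_duplicates and read.is_duplicate:
            return False
        return True


def read_reference_lengths(fasta_path: str | Path) -> ReferenceIndex:
    """Read chromosome lengths from a (possibly wrapped) multi-record FASTA.

    Every sequence character counts toward the length, including lowercase
    and IUPAC ambiguity codes; line breaks are ignored.  Record order is
    preserved.

    Raises
    ------
    FastaFormatError
        If the file is empty or the first non-blank line is not a header,
        naming the offending line number.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    with open(fasta_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{fasta_path}: line {lineno} is not a FASTA header: "
                        f"{line.strip()[:60]!r}"
                    )
                break
        else:
            raise FastaFormatError(f"{fasta_path}: empty FASTA file")
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        lengths[record.id] = len(record.seq)
    if not lengths:
        raise FastaFormatError(f"{fasta_path}: no sequence records found")
    return ReferenceIndex(lengths)


def parse_md(md_tag: str) -> ReferenceMatchVector:
    """Expand an MD tag into its binary reference-space match vector.

    Grammar (SAM spec): ``[0-9]+(([A-Z]|\\^[A-Z]+)[0-9]+)*``.  Each digit
    group *n* contributes *n* ones; each mismatch letter one zero; each
    deleted reference base (after ``^``) one zero.  Insertions never appear.

    >>> parse_md("75").ref_span
    75
    >>> parse_md("10A5^AC20").values.sum()
    35
    """
    n = len(md_tag)
    if n == 0:
        raise MDParseError(md_tag, 0, "empty tag")
    chunks: list[np.ndarray] = []
    i = 0
    expect_number = True
    while i < n:
        ch = md_tag[i]
        if ch.isdigit():
            j = i
            while j < n and md_tag[j].isdigit():
                j += 1
            run = int(md_tag[i:j])
            if run:
                chunks.append(np.ones(run, dtype=np.uint8))
            i = j
            expect_number = False
        elif expect_number:
            raise MDParseError(md_tag, i, "expected a match-run number")
        elif ch == "^":
            j = i + 1
            while j < n and md_tag[j].isalpha() and md_tag[j].isupper():
                j += 1
            if j == i + 1:
                raise MDParseError(md_tag, i + 1, "deletion with no bases")
            chunks.append(np.zeros(j - i - 1, dtype=np.uint8))
            i = j
            expect_number = True
        elif ch.isalpha() and ch.isupper():
            chunks.append(np.zeros(1, dtype=np.uint8))
            i += 1
            expect_number = True
        else:
            raise MDParseError(md_tag, i, f"unexpected character {ch!r}")
    if expect_number:
        raise MDParseError(md_tag, n, "tag must end with a match-run number")
    values = (
        np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.uint8)
    )
    return ReferenceMatchVector(values=values, ref_span=len(values))


@dataclass
class AlignmentStream:
    """Iterable over scoring-eligible records of a SAM/BAM file.

    Applies ``filter_policy`` (flag-based) and skips records with no MD tag,
    keeping counts.  After exhaustion, a warning is raised if more than half
    of the mapped records lacked an MD tag.
    """

    path: str | Path
    chromosome: str | None = None
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    yielded: int = 0
    skipped_no_md: int = 0
    skipped_filtered: int = 0

    def __iter__(self) -> Iterator[AlignedReadView]:
        path = Path(self.path)
        if not path.exists():
            raise FileNotFoundError(path)
        mode = "rb" if path.suffix == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
            for rec in af:
                view = AlignedReadView(
                    reference_name=rec.reference_name or "",
                    start_pos=(rec.reference_start + 1)
                    if not rec.is_unmapped
                    else 1,
                    md_tag=rec.get_tag("MD") if rec.has_tag("MD") else "",
                    is_unmapped=rec.is_unmapped,
                    is_secondary=rec.is_secondary,
                    is_supplementary=rec.is_supplementary,
                    is_duplicate=rec.is_duplicate,
                )
                if not self.filter_policy.passes(view):
                    self.skipped_filtered += 1
                    continue
                if (
                    self.chromosome is not None
                    and view.reference_name != self.chromosome
                ):
                    continue
                if not view.md_tag:
                    self.skipped_no_md += 1
                    continue
                self.yielded += 1
                yield view
        mapped = self.yielded + self.skipped_no_md
        if mapped and self.skipped_no_md / mapped > 0.5:
            warnings.warn(
                f"{self.skipped_no_md}/{mapped} mapped records "
                f"({self.skipped_no_md / mapped:.0%}) lack an MD tag and were "
                "skipped; regenerate the alignment with MD tags "
                "(e.g. samtools calmd)",
                stacklevel=2,
            )


def stream_alignments(
    bam_path: str | Path,
    chromosome: str | None = None,
    filter_policy: FilterPolicy | None = None,
) -> AlignmentStream:
    """Stream scoring-eligible alignment records for one chromosome.

    Returns an :class:`AlignmentStream`; iterate it to consume records and
    then inspect its ``yielded`` / ``skipped_no_md`` counters.
    """
    return AlignmentStream(
        path=bam_path,
        chromosome=chromosome,
        filter_policy=filter_policy or FilterPolicy(),
    )
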