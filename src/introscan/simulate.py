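"""Simulated hybrid genomes, paired-end reads, and truth alignments.

A simulated hybrid is a maternal (recurrent-parent) genome in which randomly
selected syntenic blocks have been replaced by the homologous paternal
sequence — the backcross-introgression scenario the detector is built for.
Everything is driven by a seeded RNG and audit-logged so a run is repeatable
byte-for-byte.

The read simulator draws fragments uniformly over the genome and reports
paired 75 bp reads (500 bp fragments by default) with their true placements.
``emit_truth_alignments`` then writes those reads as a SAM file with MD tags
against any reference — when the reference is the maternal genome but the
reads came from a hybrid, the mismatch pattern inside introgressed blocks is
exactly the homology signal the detector consumes, with no external aligner
in the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evaluation import TruthRegion

__all__ = [
    "SyntenyBlock",
    "HybridTruthLog",
    "ReadPlacement",
    "ToyParents",
    "ReadSet",
    "generate_toy_parents",
    "make_simulated_hybrids",
    "apply_truth_log",
    "simulate_reads",
    "subsample_placements",
    "emit_truth_alignments",
    "pairs_for_depth",
    "read_fasta_arrays",
    "write_fasta",
    "read_blocks_tsv",
    "write_blocks_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_a] = _b

# wgsim-like defaults: 75 bp reads on 500 bp fragments, 2% base error
DEFAULT_READ_LENGTH = 75
DEFAULT_FRAGMENT_LENGTH = 500
DEFAULT_BASE_ERROR_RATE = 0.02


@dataclass(frozen=True)
class SyntenyBlock:
    """A pair of homologous intervals, one per parental genome (1-based
    inclusive)."""

    maternal_chrom: str
    maternal_start: int
    maternal_end: int
    paternal_chrom: str
    paternal_start: int
    paternal_end: int

    def __post_init__(self) -> None:
        if self.maternal_start > self.maternal_end or self.maternal_start < 1:
            raise ValueError(f"bad maternal interval in {self}")
        if self.paternal_start > self.paternal_end or self.paternal_start < 1:
            raise ValueError(f"bad paternal interval in {self}")

    @property
    def maternal_length(self) -> int:
        return self.maternal_end - self.maternal_start + 1

    @property
    def paternal_length(self) -> int:
        return self.paternal_end - self.paternal_start + 1

    def maternal_region(self) -> TruthRegion:
        return TruthRegion(
            self.maternal_chrom, self.maternal_start, self.maternal_end
        )


@dataclass
class HybridTruthLog:
    """Audit log of one hybrid-construction run.

    Records the run arguments (paths, seed, selection policy), the blocks
    chosen for replacement, the resulting truth regions in hybrid
    coordinates, and per-chromosome length deltas.  Reapplying the log to
    the maternal genome (:func:`apply_truth_log`) reproduces the hybrid
    byte-for-byte.
    """

    args: dict
    selected_blocks: list[SyntenyBlock]
    truth_regions: list[TruthRegion]
    length_deltas: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "args": self.args,
                "selected_blocks": [asdict(b) for b in self.selected_blocks],
                "truth_regions": [asdict(t) for t in self.truth_regions],
                "length_deltas": self.length_deltas,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "HybridTruthLog":
        d = json.loads(text)
        return cls(
            args=d["args"],
            selected_blocks=[SyntenyBlock(**b) for b in d["selected_blocks"]],
            truth_regions=[TruthRegion(**t) for t in d["truth_regions"]],
            length_deltas=d["length_deltas"],
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json() + "\n")
        return path


@dataclass
class ReadPlacement:
    """Ground truth for one simulated read pair.

    Mate sequences and substitution offsets are stored in reference-forward
    orientation (R2 is reverse-complemented only when written to FASTQ).
    """

    read_id: str
    chromosome: str
    fragment_start: int  # 1-based
    fragment_length: int
    r1_seq: str
    r2_seq: str
    r1_subs: tuple[int, ...] = ()
    r2_subs: tuple[int, ...] = ()

    @property
    def r2_start(self) -> int:
        return self.fragment_start + self.fragment_length - len(self.r2_seq)


# ---------------------------------------------------------------------------
# FASTA / table helpers


def read_fasta_arrays(path: str | Path) -> dict[str, np.ndarray]:
    """Read FASTA records as uint8 byte arrays (uppercased)."""
    seqs: dict[str, np.ndarray] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = np.frombuffer(
            str(rec.seq).upper().encode("ascii"), dtype=np.uint8
        )
    return seqs


def write_fasta(seqs: dict[str, np.ndarray], path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(arr.tobytes().decode("ascii")), id=name, description="")
        for name, arr in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


def write_blocks_tsv(blocks: Sequence[SyntenyBlock], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        out.write(
            "maternal_chrom\tmaternal_start\tmaternal_end\t"
            "paternal_chrom\tpaternal_start\tpaternal_end\n"
        )
        for b in blocks:
            out.write(
                f"{b.maternal_chrom}\t{b.maternal_start}\t{b.maternal_end}\t"
                f"{b.paternal_chrom}\t{b.paternal_start}\t{b.paternal_end}\n"
            )
    return path


def read_blocks_tsv(path: str | Path) -> list[SyntenyBlock]:
    blocks = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("maternal_chrom"):
            raise ValueError(f"{path}: missing synteny-block header")
        for line in handle:
            if not line.strip():
                continue
            mc, ms, me, pc, ps, pe = line.rstrip("\n").split("\t")
            blocks.append(
                SyntenyBlock(mc, int(ms), int(me), pc, int(ps), int(pe))
            )
    return blocks


# ---------------------------------------------------------------------------
# Toy parental genomes


@dataclass
class ToyParents:
    maternal_fasta: Path
    paternal_fasta: Path
    blocks: list[SyntenyBlock]
    blocks_tsv: Path


def _apply_indels(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Apply small (1-3 bp) indels at ``rate`` events/bp.

    Returns the mutated sequence and a coordinate map ``offset[i]`` giving
    the cumulative length change at or before original position i (0-based),
    so original coordinate i maps to ``i + offset[i]``.
    """
    n = len(seq)
    n_events = rng.binomial(n, rate)
    offset = np.zeros(n + 1, dtype=np.int64)
    if n_events == 0:
        return seq.copy(), offset
    pos = np.sort(rng.choice(n, size=n_events, replace=False))
    sizes = rng.integers(1, 4, size=n_events)
    is_del = rng.random(n_events) < 0.5
    parts = []
    cur = 0
    shift = 0
    for p, size, deletion in zip(pos, sizes, is_del):
        if p < cur:
            continue
        parts.append(seq[cur:p])
        if deletion:
            size = min(size, n - p)
            cur = p + size
            shift -= size
        else:
            parts.append(_BASES[rng.integers(0, 4, size=size)])
            cur = p
            shift += size
            # avoid a second event at the same base
            cur += 1
            parts.append(seq[p : p + 1])
        offset[cur:] = shift
    parts.append(seq[cur:])
    return np.concatenate(parts), offset


def generate_toy_parents(
    outdir: str | Path,
    n_chrom: int = 1,
    chrom_length: int = 1_000_000,
    divergence_rate: float = 0.10,
    n_blocks: int = 8,
    block_length_range: tuple[int, int] = (50_000, 70_000),
    indel_rate: float = 0.0,
    seed: int = 0,
    edge_margin: int | None = None,
) -> ToyParents:
    """Generate a desk-scale pair of diverged parental genomes plus a
    synteny-block table.

    The maternal genome is uniform random A/C/G/T; the paternal genome is
    the maternal one with i.i.d. substitutions at ``divergence_rate`` (and
    optional small indels).  ``n_blocks`` disjoint syntenic blocks per
    chromosome are placed one per equal-width slot (keeping them separated
    and away from the chromosome ends) with identity coordinate mapping
    when ``indel_rate == 0``.
    """
    if not 0 <= divergence_rate < 0.5:
        raise ValueError(f"divergence_rate must be in [0, 0.5), got {divergence_rate}")
    lo, hi = block_length_range
    if lo > hi or lo < 1:
        raise ValueError(f"bad block length range {block_length_range}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    if edge_margin is None:
        edge_margin = min(50_000, chrom_length // 20)
    usable = chrom_length - 2 * edge_margin
    slot = usable // n_blocks if n_blocks else 0
    if n_blocks and slot < hi:
        raise ValueError(
            f"{n_blocks} blocks of up to {hi} bp do not fit in a "
            f"{chrom_length} bp chromosome (usable span {usable} bp)"
        )

    maternal: dict[str, np.ndarray] = {}
    paternal: dict[str, np.ndarray] = {}
    blocks: list[SyntenyBlock] = []
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        m_seq = _BASES[rng.integers(0, 4, size=chrom_length)]
        p_seq = m_seq.copy()
        sub_mask = rng.random(chrom_length) < divergence_rate
        idx = np.flatnonzero(sub_mask)
        # substitute with a uniformly different base
        cur = np.searchsorted(_BASES, p_seq[idx])
        p_seq[idx] = _BASES[(cur + rng.integers(1, 4, size=len(idx))) % 4]
        if indel_rate > 0:
            p_seq, offset = _apply_indels(p_seq, indel_rate, rng)
        else:
            offset = np.zeros(chrom_length + 1, dtype=np.int64)
        maternal[chrom] = m_seq
        paternal[chrom] = p_seq
        for bi in range(n_blocks):
            blen = int(rng.integers(lo, hi + 1))
            start0 = edge_margin + bi * slot + int(
                rng.integers(0, slot - blen + 1)
            )
            m_start, m_end = start0 + 1, start0 + blen
            p_start = m_start + int(offset[m_start - 1])
            p_end = m_end + int(offset[m_end - 1])
            p_end = min(p_end, len(p_seq))
            blocks.append(
                SyntenyBlock(chrom, m_start, m_end, chrom, p_start, p_end)
            )

    maternal_fa = write_fasta(maternal, outdir / "maternal.fasta")
    paternal_fa = write_fasta(paternal, outdir / "paternal.fasta")
    blocks_tsv = write_blocks_tsv(blocks, outdir / "blocks.tsv")
    return ToyParents(maternal_fa, paternal_fa, blocks, blocks_tsv)


# ---------------------------------------------------------------------------
# Hybrid construction


def make_simulated_hybrids(
    maternal_fasta: str | Path,
    paternal_fasta: str | Path,
    blocks: Sequence[SyntenyBlock],
    seed: int = 0,
    inclusion_prob: float = 0.5,
    n_select: int | None = None,
    out_fasta: str | Path | None = None,
    log_path: str | Path | None = None,
) -> tuple[Path, HybridTruthLog]:
    """Splice randomly selected paternal syntenic blocks into the maternal
    genome.

    Selection is either Bernoulli per block (``inclusion_prob``) or a fixed
    count ``n_select`` drawn without replacement.  Selected blocks' maternal
    intervals are excised and the homologous paternal sequence spliced in
    (lengths may differ); the truth log reports the introgressed intervals
    in hybrid coordinates.  The same inputs and seed reproduce the outputs
    byte-for-byte.
    """
    maternal_fasta = Path(maternal_fasta)
    paternal_fasta = Path(paternal_fasta)
    maternal = read_fasta_arrays(maternal_fasta)
    paternal = read_fasta_arrays(paternal_fasta)
    for b in blocks:
        if b.maternal_chrom not in maternal:
            raise ValueError(f"block chromosome {b.maternal_chrom!r} not in maternal genome")
        if b.paternal_chrom not in paternal:
            raise ValueError(f"block chromosome {b.paternal_chrom!r} not in paternal genome")
        if b.maternal_end > len(maternal[b.maternal_chrom]):
            raise ValueError(f"block {b} exceeds maternal chromosome length")
        if b.paternal_end > len(paternal[b.paternal_chrom]):
            raise ValueError(f"block {b} exceeds paternal chromosome length")

    rng = np.random.default_rng(seed)
    if n_select is not None:
        if n_select > len(blocks):
            raise ValueError(
                f"cannot select {n_select} of {len(blocks)} blocks"
            )
        chosen_idx = sorted(
            rng.choice(len(blocks), size=n_select, replace=False).tolist()
        )
    else:
        chosen_idx = [
            i for i in range(len(blocks)) if rng.random() < inclusion_prob
        ]
    selected = [blocks[i] for i in chosen_idx]

    # overlapping selected blocks on one maternal chromosome are an error
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in selected:
        by_chrom.setdefault(b.maternal_chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        bs.sort(key=lambda b: b.maternal_start)
        for a, b in zip(bs, bs[1:]):
            if a.maternal_end >= b.maternal_start:
                raise ValueError(
                    f"selected blocks overlap on {chrom}: "
                    f"[{a.maternal_start},{a.maternal_end}] and "
                    f"[{b.maternal_start},{b.maternal_end}]"
                )

    hybrid: dict[str, np.ndarray] = {}
    truth_regions: list[TruthRegion] = []
    length_deltas: dict[str, int] = {}
    for chrom, m_seq in maternal.items():
        bs = sorted(by_chrom.get(chrom, []), key=lambda b: b.maternal_start)
        parts: list[np.ndarray] = []
        cur = 0  # 0-based cursor on maternal
        offset = 0  # hybrid minus maternal coordinate shift so far
        for b in bs:
            parts.append(m_seq[cur : b.maternal_start - 1])
            p_seq = paternal[b.paternal_chrom][
                b.paternal_start - 1 : b.paternal_end
            ]
            parts.append(p_seq)
            truth_regions.append(
                TruthRegion(
                    chrom,
                    b.maternal_start + offset,
                    b.maternal_start + offset + len(p_seq) - 1,
                )
            )
            offset += len(p_seq) - b.maternal_length
            cur = b.maternal_end
        parts.append(m_seq[cur:])
        hybrid[chrom] = np.concatenate(parts) if parts else m_seq.copy()
        length_deltas[chrom] = len(hybrid[chrom]) - len(m_seq)

    if out_fasta is None:
        out_fasta = maternal_fasta.with_name("hybrid.fasta")
    out_fasta = write_fasta(hybrid, out_fasta)
    log = HybridTruthLog(
        args={
            "maternal_fasta": str(maternal_fasta),
            "paternal_fasta": str(paternal_fasta),
            "seed": seed,
            "inclusion_prob": inclusion_prob,
            "n_select": n_select,
            "n_blocks_supplied": len(blocks),
        },
        selected_blocks=selected,
        truth_regions=truth_regions,
        length_deltas=length_deltas,
    )
    if log_path is None:
        log_path = Path(out_fasta).with_suffix(".log.json")
    log.write(log_path)
    return out_fasta, log


def apply_truth_log(
    log: HybridTruthLog,
    maternal_fasta: str | Path | None = None,
    paternal_fasta: str | Path | None = None,
) -> dict[str, np.ndarray]:
    """Reconstruct the hybrid genome from the maternal genome plus the log.

    Paths default to those recorded in the log's run arguments.
    """
    maternal = read_fasta_arrays(maternal_fasta or log.args["maternal_fasta"])
    paternal = read_fasta_arrays(paternal_fasta or log.args["paternal_fasta"])
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in log.selected_blocks:
        by_chrom.setdefault(b.maternal_chrom, []).append(b)
    hybrid: dict[str, np.ndarray] = {}
    for chrom, m_seq in maternal.items():
        bs = sorted(by_chrom.get(chrom, []), key=lambda b: b.maternal_start)
        parts = []
        cur = 0
        for b in bs:
            parts.append(m_seq[cur : b.maternal_start - 1])
            parts.append(
                paternal[b.paternal_chrom][b.paternal_start - 1 : b.paternal_end]
            )
            cur = b.maternal_end
        parts.append(m_seq[cur:])
        hybrid[chrom] = np.concatenate(parts)
    return hybrid


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class ReadSet:
    r1_fastq: Path
    r2_fastq: Path
    placements: list[ReadPlacement]


def pairs_for_depth(
    depth: float, genome_length: int, read_length: int = DEFAULT_READ_LENGTH
) -> int:
    """Number of read pairs giving a target mean depth of coverage."""
    return int(round(depth * genome_length / (2 * read_length)))


def _revcomp(seq: str) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _COMPLEMENT[arr][::-1].tobytes().decode("ascii")


def simulate_reads(
    genome_fasta: str | Path,
    n_pairs: int,
    read_length: int = DEFAULT_READ_LENGTH,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    base_error_rate: float = DEFAULT_BASE_ERROR_RATE,
    seed: int = 0,
    out_prefix: str | Path | None = None,
) -> ReadSet:
    """Simulate paired-end reads with uniformly placed fragments.

    Fragments are drawn uniformly over valid positions, weighted by
    chromosome length; R1 is the fragment's left end, R2 the right end
    reverse-complemented in FASTQ.  Substitution errors are i.i.d. per base
    at ``base_error_rate``.  Placements (reference-forward sequences and the
    error offsets) are the ground truth for truth-alignment emission.
    """
    if n_pairs <= 0:
        raise ValueError(f"n_pairs must be positive, got {n_pairs}")
    if fragment_length < read_length:
        raise ValueError(
            f"fragment_length {fragment_length} < read_length {read_length}"
        )
    genome_fasta = Path(genome_fasta)
    genome = read_fasta_arrays(genome_fasta)
    chroms = [c for c, s in genome.items() if len(s) >= fragment_length]
    if not chroms:
        raise ValueError("no chromosome long enough for one fragment")
    rng = np.random.default_rng(seed)
    valid = np.array(
        [len(genome[c]) - fragment_length + 1 for c in chroms], dtype=float
    )
    chrom_choice = rng.choice(len(chroms), size=n_pairs, p=valid / valid.sum())

    placements: list[ReadPlacement] = []
    r1_chunks: list[str] = []
    r2_chunks: list[str] = []
    qual = "I" * read_length
    pair_index = 0
    for ci, chrom in enumerate(chroms):
        n_here = int((chrom_choice == ci).sum())
        if n_here == 0:
            continue
        seq = genome[chrom]
        starts0 = np.sort(
            rng.integers(0, len(seq) - fragment_length + 1, size=n_here)
        )
        col = np.arange(read_length)
        r1 = seq[starts0[:, None] + col].copy()
        r2 = seq[(starts0 + fragment_length - read_length)[:, None] + col].copy()
        subs_list = []
        for mate in (r1, r2):
            err = rng.random(mate.shape) < base_error_rate
            idx = np.flatnonzero(err)
            cur = np.searchsorted(_BASES, mate.reshape(-1)[idx])
            mate.reshape(-1)[idx] = _BASES[
                (cur + rng.integers(1, 4, size=len(idx))) % 4
            ]
            subs_list.append(err)
        r1_err, r2_err = subs_list
        for k in range(n_here):
            rid = f"sim_{pair_index:08d}"
            pair_index += 1
            r1_seq = r1[k].tobytes().decode("ascii")
            r2_seq = r2[k].tobytes().decode("ascii")
            placements.append(
                ReadPlacement(
                    read_id=rid,
                    chromosome=chrom,
                    fragment_start=int(starts0[k]) + 1,
                    fragment_length=fragment_length,
                    r1_seq=r1_seq,
                    r2_seq=r2_seq,
                    r1_subs=tuple(np.flatnonzero(r1_err[k]).tolist()),
                    r2_subs=tuple(np.flatnonzero(r2_err[k]).tolist()),
                )
            )
            r1_chunks.append(f"@{rid}/1\n{r1_seq}\n+\n{qual}\n")
            r2_chunks.append(f"@{rid}/2\n{_revcomp(r2_seq)}\n+\n{qual}\n")

    if out_prefix is None:
        out_prefix = genome_fasta.with_suffix("")
    out_prefix = Path(out_prefix)
    r1_path = out_prefix.parent / (out_prefix.name + "_R1.fastq")
    r2_path = out_prefix.parent / (out_prefix.name + "_R2.fastq")
    r1_path.write_text("".join(r1_chunks))
    r2_path.write_text("".join(r2_chunks))
    return ReadSet(r1_fastq=r1_path, r2_fastq=r2_path, placements=placements)


def subsample_placements(
    placements: Sequence[ReadPlacement], fraction: float, seed: int = 0
) -> list[ReadPlacement]:
    """Seeded uniform subsample of read pairs (for coverage-degradation
    studies)."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    n_keep = int(round(fraction * len(placements)))
    keep = np.sort(rng.choice(len(placements), size=n_keep, replace=False))
    return [placements[i] for i in keep]


# ---------------------------------------------------------------------------
# Truth alignments


def _md_string(read: np.ndarray, ref: np.ndarray) -> str:
    mism = np.flatnonzero(read != ref)
    if len(mism) == 0:
        return str(len(read))
    parts = []
    prev = -1
    for m in mism:
        parts.append(str(m - prev - 1))
        parts.append(chr(ref[m]))
        prev = m
    parts.append(str(len(read) - prev - 1))
    return "".join(parts)


def emit_truth_alignments(
    placements: Sequence[ReadPlacement],
    reference_fasta: str | Path,
    out_sam: str | Path,
) -> tuple[Path, int]:
    """Write each read pair at its true position as a coordinate-sorted SAM
    record with an MD tag computed against ``reference_fasta``.

    The reference may differ from the genome the reads were simulated from;
    the resulting mismatches are the homology signal.  Pairs extending past
    the reference end (possible when splicing changed chromosome lengths)
    are dropped and counted.

    Returns the SAM path and the number of dropped pairs.
    """
    reference = read_fasta_arrays(reference_fasta)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": len(seq)}
                for name, seq in reference.items()
            ],
        }
    )
    tid = {name: i for i, name in enumerate(reference)}
    dropped = 0
    records: list[tuple[int, int, pysam.AlignedSegment]] = []
    for p in placements:
        if p.chromosome not in reference:
            dropped += 1
            continue
        ref_seq = reference[p.chromosome]
        rl1, rl2 = len(p.r1_seq), len(p.r2_seq)
        start1 = p.fragment_start - 1  # 0-based
        start2 = p.fragment_start + p.fragment_length - rl2 - 1
        if start2 + rl2 > len(ref_seq) or start1 < 0:
            dropped += 1
            continue
        for mate_i, (seq, start, rl) in enumerate(
            ((p.r1_seq, start1, rl1), (p.r2_seq, start2, rl2))
        ):
            a = pysam.AlignedSegment(header)
            a.query_name = p.read_id
            a.query_sequence = seq
            a.reference_id = tid[p.chromosome]
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{rl}M"
            a.flag = 99 if mate_i == 0 else 147
            a.next_reference_id = tid[p.chromosome]
            a.next_reference_start = start2 if mate_i == 0 else start1
            a.template_length = (
                p.fragment_length if mate_i == 0 else -p.fragment_length
            )
            a.query_qualities = pysam.qualitystring_to_array("I" * rl)
            read_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            a.set_tag("MD", _md_string(read_arr, ref_seq[start : start + rl]))
            records.append((tid[p.chromosome], start, a))
    records.sort(key=lambda r: (r[0], r[1]))
    out_sam = Path(out_sam)
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        for _, _, a in records:
            out.write(a)
    return out_sam, dropped
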