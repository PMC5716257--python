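"""Scoring of introgression calls against truth, and ROC parameter tuning.

Region-level confusion counts need a negative class: here the negatives are
the syntenic blocks that were *not* introgressed in the simulated genome —
the natural units a simulated hybrid is assembled from.  A truth region is a
true positive when at least one call overlaps it by >= 1 bp; a call touching
no truth is a false positive; a clean negative block is a true negative.

Loci accuracy asks whether the predicted center of a recovered region lies
within +/- 5% of the true-center nucleotide coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import IntrogressionCall, call_regions
from .signal import HomologySignal, SignalParams, lowess_fit

__all__ = [
    "TruthRegion",
    "ConfusionSummary",
    "loci_accurate",
    "match_calls",
    "roc_scan",
    "read_regions",
    "write_regions_tsv",
]

#: Loci-accuracy tolerance: fraction of the true-center coordinate.
LOCI_TOLERANCE = 0.05


@dataclass(frozen=True)
class TruthRegion:
    """A known introgressed (or negative syntenic) interval, 1-based
    inclusive."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"bad truth interval [{self.start}, {self.end}]")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other) -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and self.end >= other.start
        )


def read_regions(path) -> list[TruthRegion]:
    """Read truth/negative regions from TSV (1-based inclusive, header
    ``chromosome  start  end``) or BED (0-based half-open, by extension)."""
    from pathlib import Path as _Path

    path = _Path(path)
    is_bed = path.suffix.lower() == ".bed"
    regions: list[TruthRegion] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if fields[0] in ("chromosome", "chrom"):
                continue
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if is_bed:
                start += 1  # 0-based half-open -> 1-based inclusive
            regions.append(TruthRegion(chrom, start, end))
    return regions


def write_regions_tsv(regions: Sequence[TruthRegion], path) -> None:
    with open(path, "w") as out:
        out.write("chromosome\tstart\tend\n")
        for r in regions:
            out.write(f"{r.chromosome}\t{r.start}\t{r.end}\n")


@dataclass
class ConfusionSummary:
    """Region-level confusion counts and derived rates.

    Rates with an undefined denominator are ``None`` (reported as missing,
    never coerced to 0).
    """

    TP: int
    FP: int
    FN: int
    TN: int
    mean_loci_accuracy: float | None

    @staticmethod
    def _rate(num: int, den: int) -> float | None:
        return num / den if den else None

    @property
    def TPR(self) -> float | None:
        return self._rate(self.TP, self.TP + self.FN)

    @property
    def FPR(self) -> float | None:
        return self._rate(self.FP, self.FP + self.TN)

    @property
    def PPV(self) -> float | None:
        return self._rate(self.TP, self.TP + self.FP)

    @property
    def NPV(self) -> float | None:
        return self._rate(self.TN, self.TN + self.FN)

    def as_dict(self) -> dict:
        return {
            "TP": self.TP,
            "FP": self.FP,
            "FN": self.FN,
            "TN": self.TN,
            "TPR": self.TPR,
            "FPR": self.FPR,
            "PPV": self.PPV,
            "NPV": self.NPV,
            "mean_loci_accuracy": self.mean_loci_accuracy,
        }


def loci_accurate(
    call: IntrogressionCall,
    truth: TruthRegion,
    tolerance: float = LOCI_TOLERANCE,
) -> bool:
    """True iff the call center is within ``tolerance`` (default 5%) of the
    true-center nucleotide coordinate."""
    if call.chromosome != truth.chromosome:
        raise ValueError(
            f"call on {call.chromosome} vs truth on {truth.chromosome}"
        )
    return abs(call.center - truth.center) <= tolerance * truth.center


def _overlap_len(call: IntrogressionCall, region: TruthRegion) -> int:
    if call.chromosome != region.chromosome:
        return 0
    return max(0, min(call.end, region.end) - max(call.start, region.start) + 1)


def _check_disjoint(truths: Sequence[TruthRegion]) -> None:
    by_chrom: dict[str, list[TruthRegion]] = {}
    for tr in truths:
        by_chrom.setdefault(tr.chromosome, []).append(tr)
    for chrom, regs in by_chrom.items():
        regs = sorted(regs, key=lambda r: r.start)
        for a, b in zip(regs, regs[1:]):
            if a.end >= b.start:
                raise ValueError(
                    f"overlapping truth regions on {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def _match(
    calls: Sequence[IntrogressionCall],
    truths: Sequence[TruthRegion],
    negatives: Sequence[TruthRegion],
    tolerance: float,
) -> tuple[int, int, int, int, list[bool]]:
    """Raw counts plus per-recovered-truth loci-accuracy flags."""
    _check_disjoint(truths)
    loci_flags: list[bool] = []
    tp = fn = 0
    for truth in truths:
        overlapping = [c for c in calls if _overlap_len(c, truth) > 0]
        if overlapping:
            tp += 1
            # best call: largest overlap, ties -> leftmost
            best = max(
                overlapping, key=lambda c: (_overlap_len(c, truth), -c.start)
            )
            loci_flags.append(loci_accurate(best, truth, tolerance))
        else:
            fn += 1
    fp = sum(
        1
        for c in calls
        if all(_overlap_len(c, truth) == 0 for truth in truths)
    )
    tn = sum(
        1
        for neg in negatives
        if all(_overlap_len(c, neg) == 0 for c in calls)
    )
    return tp, fp, fn, tn, loci_flags


def match_calls(
    calls: Sequence[IntrogressionCall],
    truths: Sequence[TruthRegion],
    negatives: Sequence[TruthRegion],
    tolerance: float = LOCI_TOLERANCE,
) -> ConfusionSummary:
    """Region-level confusion summary of calls against disjoint truths.

    TP: truths overlapped (>= 1 bp) by at least one call; FN: truths missed;
    FP: calls overlapping no truth; TN: negative blocks overlapped by no
    call.  Mean loci accuracy is averaged over recovered truths using each
    truth's best-overlapping call.
    """
    tp, fp, fn, tn, flags = _match(calls, truths, negatives, tolerance)
    return ConfusionSummary(
        TP=tp,
        FP=fp,
        FN=fn,
        TN=tn,
        mean_loci_accuracy=float(np.mean(flags)) if flags else None,
    )


@dataclass
class GenomeSignalInput:
    """Low-passed score vectors for one simulated genome, with its truth.

    ``filtered`` maps chromosome id -> the moving-average-filtered score
    vector (LOWESS is recomputed per ``frac`` during the scan, the low-pass
    stage is reused across the grid).
    """

    filtered: Mapping[str, np.ndarray]
    truths: Sequence[TruthRegion]
    negatives: Sequence[TruthRegion]
    origin_offset: int = 1


def roc_scan(
    signal_inputs: Sequence[GenomeSignalInput],
    frac_grid: Sequence[float] = (0.05, 0.01),
    t_grid: Sequence[float] = (0.85, 0.90, 0.95),
    *,
    delta: float | None = None,
    robust_iters: int = 3,
    tolerance: float = LOCI_TOLERANCE,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Grid scan over (frac, t): pooled confusion per pair + selection.

    Metrics are pooled across genomes and chromosomes.  The selected pair is
    the one with the greatest TPR among rows with FPR == 0 (the greatest
    sensitivity before the onset of false positives); if no row is
    false-positive-free, the row maximising TPR - FPR is selected with a
    warning.

    Returns a DataFrame with one row per (frac, t) and the selected pair.
    """
    if not signal_inputs:
        raise ValueError("at least one genome input is required")
    if not any(g.truths for g in signal_inputs):
        raise ValueError("empty truth: nothing to scan against")
    if not frac_grid or not t_grid:
        raise ValueError("frac and t grids must be non-empty")

    rows = []
    for frac in frac_grid:
        # LOWESS once per (genome, chromosome, frac); threshold is cheap
        fitted: list[dict[str, HomologySignal]] = []
        for genome in signal_inputs:
            sigs = {}
            for chrom, filt in genome.filtered.items():
                values = lowess_fit(
                    filt, frac=frac, delta=delta, robust_iters=robust_iters
                )
                sigs[chrom] = HomologySignal(
                    chromosome=chrom,
                    values=values,
                    origin_offset=genome.origin_offset,
                    params=SignalParams(
                        window=0, frac=frac, delta=delta,
                        robust_iters=robust_iters,
                    ),
                )
            fitted.append(sigs)
        for t in t_grid:
            tp = fp = fn = tn = 0
            flags: list[bool] = []
            for genome, sigs in zip(signal_inputs, fitted):
                calls: list[IntrogressionCall] = []
                for sig in sigs.values():
                    calls.extend(call_regions(sig, t))
                g_tp, g_fp, g_fn, g_tn, g_flags = _match(
                    calls, genome.truths, genome.negatives, tolerance
                )
                tp += g_tp
                fp += g_fp
                fn += g_fn
                tn += g_tn
                flags.extend(g_flags)
            summary = ConfusionSummary(
                TP=tp,
                FP=fp,
                FN=fn,
                TN=tn,
                mean_loci_accuracy=float(np.mean(flags)) if flags else None,
            )
            rows.append({"frac": frac, "t": t, **summary.as_dict()})
    table = pd.DataFrame(rows)

    usable = table.dropna(subset=["TPR", "FPR"])
    zero_fp = usable[usable["FPR"] == 0.0]
    if len(zero_fp):
        best = zero_fp.loc[zero_fp["TPR"].idxmax()]
    else:
        warnings.warn(
            "no (frac, t) pair is false-positive-free; selecting the pair "
            "maximising TPR - FPR",
            stacklevel=2,
        )
        best = usable.loc[(usable["TPR"] - usable["FPR"]).idxmax()]
    selected = (float(best["frac"]), float(best["t"]))
    return table, selected
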