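"""End-to-end simulation harnesses: detect on simulated hybrids, coverage
sweeps.

These compose the simulator with the scan model so that the whole pipeline
— hybrid construction, read simulation, truth alignment, homology signal,
region calling, evaluation — runs with no external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .evaluation import ConfusionSummary, TruthRegion
from .model import IntrogressionScan, IntrogressionScanResults
from .simulate import (
    ReadPlacement,
    emit_truth_alignments,
    subsample_placements,
)

__all__ = ["SimulatedRun", "detect_from_placements", "coverage_sweep"]


@dataclass
class SimulatedRun:
    """Results of one simulated detect run scored against truth."""

    results: IntrogressionScanResults
    confusion: ConfusionSummary
    depth: float
    breadth: float


def detect_from_placements(
    placements: Sequence[ReadPlacement],
    reference_fasta: str | Path,
    truths: Sequence[TruthRegion],
    negatives: Sequence[TruthRegion],
    workdir: str | Path,
    *,
    window: int = 1000,
    frac: float = 0.05,
    threshold: float = 0.90,
    delta: float | None = None,
    robust_iters: int = 3,
    tag: str = "run",
) -> SimulatedRun:
    """Emit truth alignments for ``placements`` and run the scan against
    ``reference_fasta``, scoring calls against the truth regions."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    sam_path, _ = emit_truth_alignments(
        placements, reference_fasta, workdir / f"{tag}.sam"
    )
    scan = IntrogressionScan(
        reference_fasta,
        sam_path,
        window=window,
        frac=frac,
        delta=delta,
        robust_iters=robust_iters,
    )
    results = scan.fit(threshold=threshold)
    confusion = results.evaluate(list(truths), list(negatives))
    depth = sum(c.depth * scan.ref_index[ch] for ch, c in results.coverage.items())
    total = scan.ref_index.total_length
    breadth = sum(
        c.breadth * scan.ref_index[ch] for ch, c in results.coverage.items()
    )
    return SimulatedRun(
        results=results,
        confusion=confusion,
        depth=depth / total,
        breadth=breadth / total,
    )


def coverage_sweep(
    placements: Sequence[ReadPlacement],
    reference_fasta: str | Path,
    truths: Sequence[TruthRegion],
    negatives: Sequence[TruthRegion],
    fractions: Sequence[float] = (1.0, 0.8, 0.6, 0.4, 0.2),
    workdir: str | Path = ".",
    seed: int = 0,
    **detect_kwargs,
) -> pd.DataFrame:
    """Rerun detection on subsampled read sets of decreasing size.

    Emulates sequencing the same hybrid at decreasing depth; returns a table
    with depth, breadth, TPR, FPR, PPV, NPV and mean loci accuracy per
    retained fraction.
    """
    rows = []
    for i, fraction in enumerate(fractions):
        subset = (
            list(placements)
            if fraction >= 1.0
            else subsample_placements(placements, fraction, seed=seed + i)
        )
        run = detect_from_placements(
            subset,
            reference_fasta,
            truths,
            negatives,
            workdir,
            tag=f"sweep_{int(round(fraction * 100))}",
            **detect_kwargs,
        )
        rows.append(
            {
                "fraction": fraction,
                "n_pairs": len(subset),
                "depth": run.depth,
                "breadth": run.breadth,
                **run.confusion.as_dict(),
            }
        )
    return pd.DataFrame(rows)
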