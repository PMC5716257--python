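"""Model/results interface for a whole-genome introgression scan.

:class:`IntrogressionScan` is configured from a reference FASTA and a
SAM/BAM alignment (the data); :meth:`IntrogressionScan.fit` runs the
pipeline — per-base scoring from MD tags, moving-average low-pass filter,
LOWESS fit, threshold classification — and returns an
:class:`IntrogressionScanResults` carrying the homology signals, the calls,
coverage diagnostics and a summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .evaluation import ConfusionSummary, TruthRegion, match_calls
from .io_alignment import (
    FilterPolicy,
    ReferenceIndex,
    read_reference_lengths,
    stream_alignments,
)
from .regions import IntrogressionCall, call_regions, plot_signal, write_bed
from .signal import (
    CoverageStats,
    DEFAULT_ROBUST_ITERS,
    DEFAULT_WINDOW,
    HomologySignal,
    accumulate_scores,
    build_signal,
    coverage_stats,
    lowpass,
)

__all__ = ["IntrogressionScan", "IntrogressionScanResults"]


class IntrogressionScan:
    """Homology-signal introgression scan of an alignment against a
    reference.

    Parameters
    ----------
    reference : path
        Reference genome FASTA (the recurrent parent's reference).
    alignments : path
        Coordinate-sorted SAM/BAM with MD tags, aligned to ``reference``.
    window : int
        Moving-average low-pass window w in bp (default 1000).  For toy
        chromosomes shorter than ``10 * window`` the window is scaled down
        with a warning.
    frac : float
        LOWESS fraction; the fit window is ``frac * L_c`` bp.
    delta : float or None
        LOWESS interpolation skip in bp (default 0.1% of the signal).
    robust_iters : int
        LOWESS robustifying iterations.
    chromosomes : sequence of str, optional
        Restrict the scan to these chromosomes.
    filter_policy : FilterPolicy, optional
        Which alignment records to exclude (default drops unmapped,
        secondary, supplementary, duplicate).
    """

    def __init__(
        self,
        reference: str | Path,
        alignments: str | Path,
        *,
        window: int = DEFAULT_WINDOW,
        frac: float = 0.05,
        delta: float | None = None,
        robust_iters: int = DEFAULT_ROBUST_ITERS,
        chromosomes: list[str] | None = None,
        filter_policy: FilterPolicy | None = None,
    ):
        self.reference = Path(reference)
        self.alignments = Path(alignments)
        self.window = window
        self.frac = frac
        self.delta = delta
        self.robust_iters = robust_iters
        self.filter_policy = filter_policy or FilterPolicy()
        self.ref_index: ReferenceIndex = read_reference_lengths(reference)
        if chromosomes:
            missing = [c for c in chromosomes if c not in self.ref_index]
            if missing:
                raise ValueError(
                    f"chromosome(s) {missing} not in reference "
                    f"{sorted(self.ref_index.chromosomes)}"
                )
            self.chromosomes = list(chromosomes)
        else:
            self.chromosomes = self.ref_index.chromosomes

    @classmethod
    def from_files(cls, reference, alignments, **kwargs) -> "IntrogressionScan":
        return cls(reference, alignments, **kwargs)

    def _window_for(self, length: int) -> int:
        w = self.window
        if w > length // 10:
            w_new = max(1, length // 10)
            warnings.warn(
                f"window {w} exceeds a tenth of the chromosome length "
                f"{length}; scaled down to {w_new}",
                stacklevel=2,
            )
            return w_new
        return w

    def fit(
        self,
        threshold: float = 0.90,
        min_length: int = 0,
        keep_tracks: bool = False,
    ) -> "IntrogressionScanResults":
        """Run the scan and classify at ``threshold``.

        ``min_length`` optionally screens out calls shorter than that many
        bp (off by default; the classifier itself imposes no minimum).
        """
        signals: dict[str, HomologySignal] = {}
        coverage: dict[str, CoverageStats] = {}
        filtered: dict[str, "object"] = {}
        tracks: dict[str, object] = {}
        calls: list[IntrogressionCall] = []
        read_counts: dict[str, int] = {}
        skipped_no_md = 0
        for chrom in self.chromosomes:
            length = self.ref_index[chrom]
            stream = stream_alignments(
                self.alignments, chrom, self.filter_policy
            )
            track = accumulate_scores(stream, chrom, length)
            read_counts[chrom] = stream.yielded
            skipped_no_md += stream.skipped_no_md
            coverage[chrom] = coverage_stats(track)
            w = self._window_for(length)
            sig = build_signal(
                track,
                w=w,
                frac=self.frac,
                delta=self.delta,
                robust_iters=self.robust_iters,
            )
            signals[chrom] = sig
            filtered[chrom] = lowpass(track.score, w)
            if keep_tracks:
                tracks[chrom] = track
            chrom_calls = call_regions(sig, threshold)
            if min_length:
                chrom_calls = [c for c in chrom_calls if c.length >= min_length]
            calls.extend(chrom_calls)
        return IntrogressionScanResults(
            model=self,
            threshold=threshold,
            min_length=min_length,
            calls=calls,
            signals=signals,
            filtered=filtered,
            coverage=coverage,
            read_counts=read_counts,
            skipped_no_md=skipped_no_md,
            tracks=tracks or None,
        )


@dataclass
class IntrogressionScanResults:
    """Fitted homology signals and the regions called below threshold."""

    model: IntrogressionScan
    threshold: float
    min_length: int
    calls: list[IntrogressionCall]
    signals: dict[str, HomologySignal]
    filtered: dict
    coverage: dict[str, CoverageStats]
    read_counts: dict[str, int]
    skipped_no_md: int = 0
    tracks: dict | None = field(default=None, repr=False)

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chromosome": c.chromosome,
                    "start": c.start,
                    "end": c.end,
                    "length": c.length,
                    "min_signal": c.min_signal,
                    "mean_signal": c.mean_signal,
                }
                for c in self.calls
            ],
            columns=[
                "chromosome",
                "start",
                "end",
                "length",
                "min_signal",
                "mean_signal",
            ],
        )

    def to_bed(self, path: str | Path) -> Path:
        return write_bed(self.calls, path)

    def plot(self, out_dir: str | Path, fmt: str = "png") -> list[Path]:
        """One signal panel per chromosome; returns the written paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for chrom, sig in self.signals.items():
            paths.append(
                plot_signal(
                    sig,
                    self.threshold,
                    [c for c in self.calls if c.chromosome == chrom],
                    out_dir / f"{chrom}.{fmt}",
                )
            )
        return paths

    def evaluate(
        self,
        truths: list[TruthRegion],
        negatives: list[TruthRegion],
    ) -> ConfusionSummary:
        return match_calls(self.calls, truths, negatives)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Introgression scan results",
            "=" * 60,
            f"reference:     {m.reference}",
            f"alignments:    {m.alignments}",
            f"window w:      {m.window} bp    frac: {m.frac}    "
            f"threshold t: {self.threshold}",
            f"robust iters:  {m.robust_iters}    "
            f"delta: {'auto' if m.delta is None else m.delta}",
            "",
            f"{'chromosome':<14}{'length':>12}{'reads':>10}"
            f"{'depth':>9}{'breadth':>9}{'calls':>7}",
        ]
        for chrom in m.chromosomes:
            cov = self.coverage[chrom]
            n_calls = sum(1 for c in self.calls if c.chromosome == chrom)
            lines.append(
                f"{chrom:<14}{m.ref_index[chrom]:>12}"
                f"{self.read_counts[chrom]:>10}"
                f"{cov.depth:>9.2f}{cov.breadth:>9.2%}{n_calls:>7}"
            )
        lines.append("")
        if self.calls:
            lines.append(
                f"{'chromosome':<14}{'start':>12}{'end':>12}"
                f"{'length':>10}{'min_h':>8}{'mean_h':>8}"
            )
            for c in sorted(self.calls, key=lambda c: (c.chromosome, c.start)):
                lines.append(
                    f"{c.chromosome:<14}{c.start:>12}{c.end:>12}"
                    f"{c.length:>10}{c.min_signal:>8.3f}{c.mean_signal:>8.3f}"
                )
        else:
            lines.append("no regions called below threshold")
        return "\n".join(lines)
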