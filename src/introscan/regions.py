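"""Threshold classification of the homology signal into introgression calls.

A region opens at the first signal position with ``h < t`` and closes at the
last position before the signal rises back to ``h >= t``; ties (``h == t``)
are outside.  A region still open at the end of the signal closes at the
final signal coordinate (not the chromosome end — trailing bases lost to the
filter truncation were never examined).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .signal import HomologySignal

__all__ = [
    "IntrogressionCall",
    "call_regions",
    "write_bed",
    "read_bed_calls",
    "plot_signal",
]


@dataclass(frozen=True)
class IntrogressionCall:
    """A called region, 1-based inclusive reference coordinates."""

    chromosome: str
    start: int
    end: int
    min_signal: float
    mean_signal: float

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad call interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def call_regions(signal: HomologySignal, t: float) -> list[IntrogressionCall]:
    """Call introgressed regions as maximal runs of ``h < t``.

    Calls are disjoint, sorted, and mapped to reference coordinates through
    the signal's origin offset.
    """
    if not 0 < t < 1:
        raise ValueError(f"threshold t must be in (0, 1), got {t}")
    h = signal.values
    below = h < t
    if not below.any():
        return []
    # run boundaries of the below-threshold mask
    step = np.diff(below.astype(np.int8))
    starts = list(np.flatnonzero(step == 1) + 1)
    ends = list(np.flatnonzero(step == -1))
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(len(h) - 1)
    calls = []
    for i0, i1 in zip(starts, ends):
        seg = h[i0 : i1 + 1]
        calls.append(
            IntrogressionCall(
                chromosome=signal.chromosome,
                start=signal.position(i0),
                end=signal.position(i1),
                min_signal=float(seg.min()),
                mean_signal=float(seg.mean()),
            )
        )
    return calls


def write_bed(calls: list[IntrogressionCall], path: str | Path) -> Path:
    """Write calls as BED3+ (0-based half-open) with signal summary columns."""
    path = Path(path)
    with open(path, "w") as out:
        out.write(
            "#chrom\tstart\tend\tlength\tmin_signal\tmean_signal\n"
        )
        for call in sorted(calls, key=lambda c: (c.chromosome, c.start)):
            out.write(
                f"{call.chromosome}\t{call.start - 1}\t{call.end}\t"
                f"{call.length}\t{call.min_signal:.6f}\t"
                f"{call.mean_signal:.6f}\n"
            )
    return path


def read_bed_calls(path: str | Path) -> list[IntrogressionCall]:
    """Read calls back from a BED3+ file written by :func:`write_bed`.

    Missing signal-summary columns default to NaN.
    """
    calls = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
            min_sig = float(fields[4]) if len(fields) > 4 else float("nan")
            mean_sig = float(fields[5]) if len(fields) > 5 else float("nan")
            calls.append(
                IntrogressionCall(
                    chromosome=chrom,
                    start=start0 + 1,
                    end=end,
                    min_signal=min_sig,
                    mean_signal=mean_sig,
                )
            )
    return calls


def plot_signal(
    signal: HomologySignal,
    t: float,
    calls: list[IntrogressionCall],
    path: str | Path,
) -> Path:
    """Plot h_c with the threshold line and shaded call boxes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.2))
    x = np.arange(len(signal)) + signal.origin_offset
    ax.plot(x, signal.values, color="tab:green", lw=0.8, label="homology $h_c$")
    ax.axhline(t, color="tab:purple", lw=1.0, label=f"threshold t = {t:g}")
    for call in calls:
        if call.chromosome == signal.chromosome:
            ax.axvspan(call.start, call.end, color="tab:orange", alpha=0.3)
    ax.set_xlabel("reference position (bp)")
    ax.set_ylabel("homology score")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(signal.chromosome)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
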