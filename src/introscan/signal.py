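"""Per-base homology scoring and smoothing.

The score at reference position *l* is the fraction of covering reads whose
aligned base matches the reference there (positions with no coverage score
0).  The raw score vector is denoised in two stages: a moving-average
low-pass filter of window *w* (fully-overlapping windows, so the output is
``L - w + 1`` points), then a LOWESS fit whose ``frac`` parameter sets the
fit window as a fraction of the chromosome length.  The result is the
homology signal h_c with values in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io_alignment import AlignedReadView, parse_md

__all__ = [
    "PerBaseScoreTrack",
    "HomologySignal",
    "SignalParams",
    "CoverageStats",
    "accumulate_scores",
    "lowpass",
    "lowess_fit",
    "build_signal",
    "coverage_stats",
]

#: Default low-pass window in bp (1 kbp suits chromosome-scale references).
DEFAULT_WINDOW = 1000
#: Default LOWESS robustifying iterations.
DEFAULT_ROBUST_ITERS = 3
#: Default LOWESS interpolation skip, as a fraction of the signal length.
DEFAULT_DELTA_FRAC = 0.001


@dataclass
class PerBaseScoreTrack:
    """Match/coverage accumulators and the derived per-base score for one
    chromosome.

    Invariants: all arrays have length ``L_c``; ``0 <= match_count <=
    cover_count`` everywhere; ``score = match_count / cover_count`` where
    covered, else 0.
    """

    chromosome: str
    match_count: np.ndarray
    cover_count: np.ndarray
    skipped_out_of_range: int = 0
    clipped_overhangs: int = 0

    @property
    def length(self) -> int:
        return len(self.cover_count)

    @property
    def score(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(
                self.cover_count > 0,
                self.match_count / np.maximum(self.cover_count, 1),
                0.0,
            )
        return s


@dataclass(frozen=True)
class SignalParams:
    window: int = DEFAULT_WINDOW
    frac: float = 0.05
    delta: float | None = None  # bp; None -> DEFAULT_DELTA_FRAC * length
    robust_iters: int = DEFAULT_ROBUST_ITERS


@dataclass
class HomologySignal:
    """Smoothed homology signal h_c for one chromosome.

    ``values[i]`` is anchored at reference position ``origin_offset + i``
    (1-based).  Length is ``L_c - w + 1`` by the fully-overlapping
    convolution convention.
    """

    chromosome: str
    values: np.ndarray
    origin_offset: int
    params: SignalParams

    def __len__(self) -> int:
        return len(self.values)

    def position(self, index: int) -> int:
        """Reference coordinate (1-based) of signal index ``index``."""
        return self.origin_offset + index


@dataclass(frozen=True)
class CoverageStats:
    depth: float  # mean reads per position
    breadth: float  # fraction of positions with >= 1 covering read


def accumulate_scores(
    read_stream,
    chromosome: str,
    length: int,
) -> PerBaseScoreTrack:
    """Fold a stream of alignment records into per-base match/coverage counts.

    Each record's MD tag is expanded into its binary match vector and added
    at its (1-based) start coordinate.  Records starting beyond the
    chromosome end are skipped and counted; vectors overhanging the end are
    clipped with a warning.
    """
    match = np.zeros(length, dtype=np.int32)
    cover = np.zeros(length, dtype=np.int32)
    skipped = 0
    clipped = 0
    for read in read_stream:
        if isinstance(read, AlignedReadView):
            if read.reference_name != chromosome:
                continue
            start0 = read.start_pos - 1
            vec = parse_md(read.md_tag).values
        else:  # (start_pos, match_vector) pair, for direct use in tests
            start0 = read[0] - 1
            vec = np.asarray(read[1], dtype=np.uint8)
        if start0 >= length:
            skipped += 1
            continue
        span = len(vec)
        end0 = start0 + span
        if end0 > length:
            clipped += 1
            vec = vec[: length - start0]
            end0 = length
        cover[start0:end0] += 1
        match[start0:end0] += vec
    if clipped:
        warnings.warn(
            f"{chromosome}: {clipped} record(s) overhung the chromosome end "
            "and were clipped",
            stacklevel=2,
        )
    return PerBaseScoreTrack(
        chromosome=chromosome,
        match_count=match,
        cover_count=cover,
        skipped_out_of_range=skipped,
        clipped_overhangs=clipped,
    )


def lowpass(score_vector: np.ndarray, w: int) -> np.ndarray:
    """Moving-average low-pass filter with fully-overlapping windows.

    ``out[i] = mean(score[i : i + w])``; the output has ``L - w + 1``
    points (a 10,000-point signal at w = 300 yields 9,701).
    """
    x = np.asarray(score_vector, dtype=np.float64)
    n = len(x)
    if w < 1:
        raise ValueError(f"window must be >= 1, got {w}")
    if w > n:
        raise ValueError(
            f"window w={w} exceeds signal length {n}; shrink the window "
            "(e.g. below a tenth of the chromosome length)"
        )
    cs = np.concatenate(([0.0], np.cumsum(x)))
    out = (cs[w:] - cs[:-w]) / w
    # cumulative sums can leak tiny float error outside [0, 1]
    return np.clip(out, 0.0, 1.0)


def lowess_fit(
    filtered_vector: np.ndarray,
    frac: float,
    delta: float | None = None,
    robust_iters: int = DEFAULT_ROBUST_ITERS,
) -> np.ndarray:
    """Locally weighted linear regression over the filtered signal.

    Classical LOWESS: each point is fitted by tricube-weighted linear
    regression over its nearest ``frac * N`` neighbours, with
    ``robust_iters`` robustifying passes; points within ``delta`` bp of a
    fitted anchor are linearly interpolated.  Output clipped into [0, 1].
    """
    y = np.asarray(filtered_vector, dtype=np.float64)
    n = len(y)
    if not 0 < frac <= 1:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    if int(frac * n) < 3:
        raise ValueError(
            f"frac={frac} gives a local window of {int(frac * n)} < 3 points "
            f"on a signal of {n}; increase frac"
        )
    if delta is None:
        delta = DEFAULT_DELTA_FRAC * n
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    x = np.arange(n, dtype=np.float64)
    fitted = _sm_lowess(
        y, x, frac=frac, it=robust_iters, delta=delta, return_sorted=False
    )
    return np.clip(fitted, 0.0, 1.0)


def build_signal(
    track: PerBaseScoreTrack,
    w: int = DEFAULT_WINDOW,
    frac: float = 0.05,
    delta: float | None = None,
    robust_iters: int = DEFAULT_ROBUST_ITERS,
) -> HomologySignal:
    """Compose low-pass filtering and LOWESS fitting into h_c.

    Signal index 0 is anchored at reference position 1 (left-aligned
    windows); the ``<= w`` coordinate slack is negligible when ``w`` is
    small against the chromosome.
    """
    filtered = lowpass(track.score, w)
    values = lowess_fit(filtered, frac=frac, delta=delta, robust_iters=robust_iters)
    return HomologySignal(
        chromosome=track.chromosome,
        values=values,
        origin_offset=1,
        params=SignalParams(
            window=w, frac=frac, delta=delta, robust_iters=robust_iters
        ),
    )


def coverage_stats(track: PerBaseScoreTrack) -> CoverageStats:
    """Depth (mean reads/position) and breadth (fraction covered >= 1x)."""
    n = track.length
    if n == 0:
        return CoverageStats(0.0, 0.0)
    depth = float(track.cover_count.sum()) / n
    breadth = float(np.count_nonzero(track.cover_count)) / n
    return CoverageStats(depth=depth, breadth=breadth)
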