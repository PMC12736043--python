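"""Plateau segmentation of RMSD (or any) time series.

A plateau is a contiguous stretch of frames whose values all stay within a
tolerance band (default +/- 0.2 nm) of the stretch's own mean.  The reference
procedure for picking such windows was visual; here it is operationalized as
a deterministic greedy scan: grow the current window frame by frame as long
as every member stays within the band around the running window mean, close
the window on the first violation, and restart at the violating frame.  Ties
between overlapping candidate windows therefore always resolve in favor of
the earlier start.  Segments shorter than a minimum duration are discarded,
and adjacent segments separated by less than ``merge_gap_ns`` are merged when
the merged window (gap frames included) still satisfies the criterion.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SeriesResult


class PlateauError(ValueError):
    pass


@dataclass(frozen=True)
class PlateauSegment:
    """A maximal stable interval of a series."""

    start_ns: float
    end_ns: float
    start_idx: int
    end_idx: int  # inclusive
    mean_value: float
    max_abs_deviation: float
    n_frames: int

    def as_dict(self) -> dict:
        return {
            "start_ns": self.start_ns, "end_ns": self.end_ns,
            "mean": self.mean_value, "max_abs_deviation": self.max_abs_deviation,
            "n_frames": self.n_frames,
        }


def _segment(times: np.ndarray, values: np.ndarray, i: int, j: int) -> PlateauSegment:
    window = values[i:j + 1]
    mean = float(window.mean())
    return PlateauSegment(
        start_ns=float(times[i]), end_ns=float(times[j]),
        start_idx=i, end_idx=j,
        mean_value=mean,
        max_abs_deviation=float(np.max(np.abs(window - mean))),
        n_frames=j - i + 1,
    )


def _window_ok(values: np.ndarray, i: int, j: int, tol: float) -> bool:
    w = values[i:j + 1]
    m = w.mean()
    return w.max() - m <= tol and m - w.min() <= tol


def detect_plateaus(series: SeriesResult, tolerance: float = 0.2,
                    min_length_ns: float | None = None,
                    merge_gap_ns: float = 0.0) -> list[PlateauSegment]:
    """Segment a series into plateaus under the +/- tolerance criterion.

    Parameters
    ----------
    series
        Any per-frame series; tolerance shares its units (nm for RMSD).
    tolerance
        Half-width of the allowed band about the segment mean (> 0).
    min_length_ns
        Minimum segment duration; default 5% of the series time span.
    merge_gap_ns
        Merge adjacent segments separated by less than this gap when the
        merged window still satisfies the criterion.  0 disables merging.
    """
    if tolerance <= 0:
        raise PlateauError("tolerance must be positive")
    values = np.asarray(series.values, dtype=float)
    times = np.asarray(series.times_ns, dtype=float)
    if values.size < 2:
        raise PlateauError("series must have at least 2 points")
    if min_length_ns is None:
        min_length_ns = 0.05 * (times[-1] - times[0])

    # greedy scan with running sum/min/max (window only ever grows)
    raw: list[tuple[int, int]] = []
    i = 0
    s = values[0]
    lo = hi = values[0]
    for j in range(1, values.size):
        x = values[j]
        s2, lo2, hi2 = s + x, min(lo, x), max(hi, x)
        m = s2 / (j - i + 1)
        if hi2 - m <= tolerance and m - lo2 <= tolerance:
            s, lo, hi = s2, lo2, hi2
        else:
            raw.append((i, j - 1))
            i = j
            s, lo, hi = x, x, x
    raw.append((i, values.size - 1))

    # merge across short gaps when the merged window still qualifies
    if merge_gap_ns > 0:
        merged: list[tuple[int, int]] = []
        for seg in raw:
            if merged:
                a0, a1 = merged[-1]
                gap = times[seg[0]] - times[a1]
                if gap < merge_gap_ns and _window_ok(values, a0, seg[1], tolerance):
                    merged[-1] = (a0, seg[1])
                    continue
            merged.append(seg)
        raw = merged

    out = [_segment(times, values, i, j) for i, j in raw
           if times[j] - times[i] >= min_length_ns]
    return out
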