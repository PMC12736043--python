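"""Statistics of per-frame MM/GBSA-style system energies.

The upstream producer (an MM/GBSA post-processor) leaves one interaction
energy per trajectory frame, in kcal/mol with more negative meaning more
favorable.  This module computes window statistics (mean, sample SD, most
negative value), distribution histograms, and the intrinsic specificity
ratio

    ISR = deltaE / DeltaE = (mu - E_min) / sigma,

where ``deltaE`` is the gap between the strongest (most negative) energy of
the distribution and its mean, and ``DeltaE`` is one standard deviation.  ISR
measures how far the best-bound state separates from the bulk of the
distribution; it is shift- and positive-scale-invariant and undefined for a
constant series.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .structio import StructIOError, read_table, write_table


class EnergyError(ValueError):
    pass


class IsrUndefinedError(EnergyError):
    """ISR is undefined: the energy distribution has zero standard deviation."""


@dataclass
class EnergySeries:
    """Per-frame system energy (kcal/mol) along a trajectory."""

    times_ns: np.ndarray
    energies_kcal: np.ndarray

    def __post_init__(self):
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.energies_kcal = np.asarray(self.energies_kcal, dtype=float)
        if self.times_ns.shape != self.energies_kcal.shape or self.times_ns.ndim != 1:
            raise EnergyError("times and energies must be aligned 1-D arrays")
        if not np.all(np.isfinite(self.energies_kcal)):
            raise EnergyError("non-finite energies")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnergySeries":
        df = read_table(path, {"time_ns": float, "energy_kcal": float})
        return cls(df["time_ns"].to_numpy(), df["energy_kcal"].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        write_table(pd.DataFrame({"time_ns": self.times_ns,
                                  "energy_kcal": self.energies_kcal}), path)

    def window(self, start_ns: float | None, end_ns: float | None) -> np.ndarray:
        lo = -np.inf if start_ns is None else start_ns
        hi = np.inf if end_ns is None else end_ns
        return self.energies_kcal[(self.times_ns >= lo) & (self.times_ns <= hi)]


@dataclass(frozen=True)
class EnergyStats:
    """Window statistics of an energy distribution."""

    start_ns: float | None
    end_ns: float | None
    n: int
    mu: float
    sigma: float
    e_min: float
    isr: float | None = None

    def as_dict(self) -> dict:
        return {
            "window_ns": [self.start_ns, self.end_ns],
            "n": self.n, "mu": self.mu, "sigma": self.sigma,
            "e_min": self.e_min, "isr": self.isr,
        }


def window_stats(series: EnergySeries, start_ns: float | None = None,
                 end_ns: float | None = None, with_isr: bool = False) -> EnergyStats:
    """Mean, sample SD (n-1) and most negative energy over a time window.

    The window is inclusive on both ends; omitted bounds span the full series.
    Requires at least two frames in the window.
    """
    e = series.window(start_ns, end_ns)
    if e.size < 2:
        raise EnergyError(f"window [{start_ns}, {end_ns}] has {e.size} frame(s); need >= 2")
    mu = float(np.mean(e))
    sigma = float(np.std(e, ddof=1))
    e_min = float(np.min(e))
    val = None
    if with_isr:
        if sigma == 0:
            raise IsrUndefinedError("ISR undefined (sigma = 0): constant energy series")
        val = (mu - e_min) / sigma
    return EnergyStats(start_ns=start_ns, end_ns=end_ns, n=int(e.size),
                       mu=mu, sigma=sigma, e_min=e_min, isr=val)


def isr(series: EnergySeries, start_ns: float | None = None,
        end_ns: float | None = None) -> float:
    """Intrinsic specificity ratio (mu - E_min) / sigma over a window.

    Strictly positive unless every value equals the minimum; raises
    :class:`IsrUndefinedError` for a constant distribution (sigma = 0).
    """
    return window_stats(series, start_ns, end_ns, with_isr=True).isr


def implied_min_energy(mu: float, sigma: float, isr_value: float) -> float:
    """Invert the ISR definition: the strongest energy E_min = mu - ISR * sigma.

    Useful for checking printed (mu, sigma, ISR) triples against the reported
    extremes of an energy distribution.
    """
    return mu - isr_value * sigma


def energy_histogram(series: EnergySeries, bin_width_kcal: float,
                     start_ns: float | None = None,
                     end_ns: float | None = None) -> pd.DataFrame:
    """Histogram of the energy distribution with fixed-width centered bins.

    The first bin is centered on the window minimum, so bins cover
    [e_min, e_max]; counts sum to the number of frames.  Returns
    (bin_center, count).
    """
    if bin_width_kcal <= 0:
        raise EnergyError("bin width must be positive")
    e = series.window(start_ns, end_ns)
    if e.size == 0:
        raise EnergyError("empty window")
    w = float(bin_width_kcal)
    lo = float(e.min()) - w / 2.0
    hi = float(e.max())
    nbins = max(1, int(np.ceil((hi - lo) / w)))
    edges = lo + w * np.arange(nbins + 1)
    edges[-1] = max(edges[-1], hi)  # guard against fp shortfall on the top edge
    counts, _ = np.histogram(e, bins=edges)
    return pd.DataFrame({
        "bin_center": lo + w / 2.0 + w * np.arange(nbins),
        "count": counts,
    })
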