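"""Model-free phasor representation of fluorescence decays.

A decay histogram maps to Fourier coordinates at the laser repetition
frequency:

    g = sum(counts * cos(w t)) / sum(counts)
    s = sum(counts * sin(w t)) / sum(counts)

with t at bin centres and w = 2*pi*harmonic*rep_rate. Mono-exponential
decays lie on the universal semicircle (g - 1/2)^2 + s^2 = 1/4; any
mixture is the photon-weighted convex combination of its component
phasors. Decays are summarised by their orthogonal projection onto the
chord joining the 0.4 ns (free NAD(P)H) and 3.4 ns (protein-bound
NAD(P)H) reference phasors, reported as the normalised position toward
the long-lifetime end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AcquisitionParams
from .decay_fitting import DecayHistogram
from .errors import DomainError

TAU_LONG_REF_NS = 3.4
TAU_SHORT_REF_NS = 0.4


@dataclass(frozen=True)
class PhasorPoint:
    g: float
    s: float
    harmonic: int = 1
    omega: float = 0.0  # rad/ns


def angular_frequency(acq: AcquisitionParams, harmonic: int = 1) -> float:
    """Angular frequency in rad/ns for a given harmonic."""
    return 2.0 * np.pi * harmonic * acq.rep_rate * 1e-9


def phasor_transform(
    hist: DecayHistogram, acq: AcquisitionParams, harmonic: int = 1
) -> PhasorPoint:
    """Phasor (g, s) of a decay histogram at the given harmonic."""
    counts = hist.counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise DomainError("cannot transform an empty histogram")
    omega = angular_frequency(acq, harmonic)
    t = hist.bin_centers()
    g = float(np.sum(counts * np.cos(omega * t)) / total)
    s = float(np.sum(counts * np.sin(omega * t)) / total)
    return PhasorPoint(g=g, s=s, harmonic=harmonic, omega=omega)


def mono_exp_phasor(
    tau_ns: float, acq: AcquisitionParams, harmonic: int = 1
) -> PhasorPoint:
    """Closed-form phasor of an ideal (continuous) mono-exponential decay:
    g = 1/(1 + (w tau)^2), s = w tau/(1 + (w tau)^2)."""
    if tau_ns <= 0:
        raise DomainError("tau must be positive")
    omega = angular_frequency(acq, harmonic)
    wt = omega * tau_ns
    denom = 1.0 + wt * wt
    return PhasorPoint(g=1.0 / denom, s=wt / denom, harmonic=harmonic, omega=omega)


def chord_fraction(
    p: PhasorPoint,
    acq: AcquisitionParams,
    tau_long: float = TAU_LONG_REF_NS,
    tau_short: float = TAU_SHORT_REF_NS,
    harmonic: int = 1,
) -> float:
    """Normalised position of a phasor along the fixed reference chord.

    The phasor is orthogonally projected onto the segment joining the
    mono-exponential phasors of tau_short and tau_long; 0 is the short
    end, 1 the long end, values clipped to [0, 1].
    """
    if tau_long <= 0 or tau_short <= 0 or np.isclose(tau_long, tau_short):
        raise DomainError("reference lifetimes must be distinct and positive")
    a = mono_exp_phasor(tau_short, acq, harmonic)
    b = mono_exp_phasor(tau_long, acq, harmonic)
    ab = np.array([b.g - a.g, b.s - a.s])
    denom = float(ab @ ab)
    if denom < 1e-15:
        raise DomainError("reference phasors coincide")
    ap = np.array([p.g - a.g, p.s - a.s])
    frac = float(ap @ ab) / denom
    return float(np.clip(frac, 0.0, 1.0))


def phasor_histogram(
    points,
    acq: AcquisitionParams,
    n_bins_2d: int = 64,
    n_bins_chord: int = 50,
    tau_long: float = TAU_LONG_REF_NS,
    tau_short: float = TAU_SHORT_REF_NS,
):
    """2-D phasor density grid plus 1-D chord-fraction histogram.

    Returns (grid, g_edges, s_edges, chord_counts, chord_edges); the grid
    conserves counts (sums to the number of points).
    """
    points = list(points)
    if not points:
        raise DomainError("empty phasor point list")
    g = np.array([p.g for p in points])
    s = np.array([p.s for p in points])
    grid, g_edges, s_edges = np.histogram2d(
        g, s, bins=n_bins_2d, range=[[-0.05, 1.05], [-0.05, 0.75]]
    )
    fracs = np.array(
        [chord_fraction(p, acq, tau_long, tau_short) for p in points]
    )
    chord_counts, chord_edges = np.histogram(fracs, bins=n_bins_chord, range=(0, 1))
    return grid, g_edges, s_edges, chord_counts, chord_edges
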