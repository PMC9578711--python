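"""Shared acquisition and ground-truth parameter types.

The acquisition geometry mirrors a standard TCSPC two-photon setup: an
80 MHz pulsed laser gives a 12.5 ns measurement window, digitised into
256 time bins per pixel on 512 x 512 images (reducible for tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class AcquisitionParams:
    """TCSPC acquisition geometry.

    Parameters
    ----------
    rep_rate : float
        Laser pulse repetition frequency in Hz (default 80 MHz).
    n_bins : int
        Time bins per pixel (default 256).
    image_size : int
        Pixels per image side (default 512; tests use smaller fields).
    """

    rep_rate: float = 8.0e7
    n_bins: int = 256
    image_size: int = 512

    def __post_init__(self):
        if self.rep_rate <= 0:
            raise ParameterError("rep_rate must be positive")
        if self.n_bins < 2:
            raise ParameterError("n_bins must be at least 2")
        if self.image_size < 1:
            raise ParameterError("image_size must be at least 1")

    @property
    def window_ns(self) -> float:
        """Measurement window in ns (one laser period)."""
        return 1e9 / self.rep_rate

    @property
    def bin_width_ns(self) -> float:
        return self.window_ns / self.n_bins

    def bin_centers_ns(self) -> np.ndarray:
        w = self.bin_width_ns
        return (np.arange(self.n_bins) + 0.5) * w

    def bin_edges_ns(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width_ns


@dataclass(frozen=True)
class GroundTruthParams:
    """Parameters of the bi-exponential fluorescence decay model

        I(t) = I0 * [alpha1 * exp(-t/tau1) + alpha2 * exp(-t/tau2)] + C

    with tau1 the long (protein-bound NAD(P)H) and tau2 the short (free
    NAD(P)H) lifetime; alpha_i is the fractional amplitude paired with
    tau_i, and C a constant background in photons per bin.
    """

    I0: float
    alpha1: float
    alpha2: float
    tau1: float
    tau2: float
    C: float = 0.0

    def __post_init__(self):
        if self.I0 <= 0:
            raise ParameterError("I0 must be positive")
        if not np.isclose(self.alpha1 + self.alpha2, 1.0, atol=1e-9):
            raise ParameterError("alpha1 + alpha2 must equal 1")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ParameterError("amplitude fractions must be non-negative")
        if not (self.tau1 >= self.tau2 > 0):
            raise ParameterError("lifetimes must satisfy tau1 >= tau2 > 0")
        if self.C < 0:
            raise ParameterError("background C must be non-negative")

    @property
    def tau_avg(self) -> float:
        """Amplitude-weighted mean lifetime in ns."""
        return (self.tau1 * self.alpha1 + self.tau2 * self.alpha2) / (
            self.alpha1 + self.alpha2
        )
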