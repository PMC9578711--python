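"""Extracellular-flux (Seahorse-style) summary metrics.

A flux series holds ECAR and OCR measurements over time with a
four-injection schedule (oligomycin, FCCP, rotenone + antimycin A,
2-DG) splitting the run into five phases. Summary rates follow the
manufacturer-convention arithmetic:

    basal glycolysis  = mean ECAR before oligomycin - non-glycolytic ECAR
    max glycolysis    = mean ECAR between oligomycin and FCCP
    basal respiration = mean OCR before oligomycin - non-mitochondrial OCR
    max respiration   = mean OCR between FCCP and Rot+AA

with non-glycolytic ECAR taken as the post-2-DG phase mean and
non-mitochondrial OCR as the post-Rot+AA phase mean. Per-phase areas
under the curve are trapezoidal integrals over each phase's time span.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError, PhaseCoverageError, ScheduleError

PHASE_NAMES = ("basal", "post_oligomycin", "post_FCCP", "post_RotAA", "post_2DG")


@dataclass(frozen=True)
class FluxSeries:
    """One replicate's ECAR/OCR time series with its injection schedule."""

    times: np.ndarray  # minutes, strictly increasing
    ecar: np.ndarray
    ocr: np.ndarray
    schedule: tuple  # four injection times (min)
    replicate: int = 0
    group: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        ecar = np.asarray(self.ecar, dtype=float)
        ocr = np.asarray(self.ocr, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ScheduleError("measurement times must be strictly increasing")
        if len(self.schedule) != 4 or np.any(np.diff(self.schedule) <= 0):
            raise ScheduleError("schedule must be four strictly increasing times")
        if not (np.all(np.isfinite(ecar)) and np.all(np.isfinite(ocr))):
            raise DomainError("ECAR/OCR values must be finite")
        if ecar.shape != times.shape or ocr.shape != times.shape:
            raise DomainError("ecar/ocr must match times in length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ecar", ecar)
        object.__setattr__(self, "ocr", ocr)

    def phase_index(self) -> np.ndarray:
        """Phase number (0..4) of each timepoint; measurements exactly at
        an injection time belong to the preceding phase."""
        return np.searchsorted(np.asarray(self.schedule), self.times, side="left")


@dataclass(frozen=True)
class FluxRates:
    basal_glycolysis: float
    max_glycolysis: float
    basal_respiration: float
    max_respiration: float
    ecar_auc: dict  # phase name -> assay units x minutes
    ocr_auc: dict


def phase_means(series: FluxSeries):
    """Arithmetic mean (ECAR, OCR) per phase. Raises if a phase is empty."""
    idx = series.phase_index()
    means = {}
    for k, name in enumerate(PHASE_NAMES):
        sel = idx == k
        if not np.any(sel):
            raise PhaseCoverageError(f"no measurements in phase {name!r}")
        means[name] = (float(series.ecar[sel].mean()), float(series.ocr[sel].mean()))
    return means


def compute_flux_rates(series: FluxSeries) -> FluxRates:
    """Summary rates plus per-phase trapezoidal AUCs for one series."""
    pm = phase_means(series)
    non_glycolytic = pm["post_2DG"][0]
    non_mito = pm["post_RotAA"][1]
    ecar_auc, ocr_auc = {}, {}
    for name in PHASE_NAMES:
        try:
            ecar_auc[name] = auc_between_treatments(series, name, signal="ecar")
            ocr_auc[name] = auc_between_treatments(series, name, signal="ocr")
        except DomainError:
            ecar_auc[name] = np.nan
            ocr_auc[name] = np.nan
    return FluxRates(
        basal_glycolysis=pm["basal"][0] - non_glycolytic,
        max_glycolysis=pm["post_oligomycin"][0],
        basal_respiration=pm["basal"][1] - non_mito,
        max_respiration=pm["post_FCCP"][1],
        ecar_auc=ecar_auc,
        ocr_auc=ocr_auc,
    )


def auc_between_treatments(
    series: FluxSeries, phase: str | int, signal: str = "ecar"
) -> float:
    """Trapezoidal integral of ECAR or OCR over one phase's time span."""
    k = PHASE_NAMES.index(phase) if isinstance(phase, str) else int(phase)
    if not 0 <= k < 5:
        raise DomainError(f"unknown phase {phase!r}")
    sel = series.phase_index() == k
    if sel.sum() < 2:
        raise DomainError("AUC needs at least two timepoints in the phase")
    y = getattr(series, signal)[sel]
    t = series.times[sel]
    return float(np.trapezoid(y, t))


def subtract_blank(series: FluxSeries, blank: FluxSeries) -> FluxSeries:
    """Background correction against a paired cell-free blank series
    measured on the same time grid."""
    if not np.array_equal(series.times, blank.times):
        raise DomainError("blank series must share the measurement time grid")
    return replace(
        series, ecar=series.ecar - blank.ecar, ocr=series.ocr - blank.ocr
    )
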