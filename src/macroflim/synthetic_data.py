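"""Seeded synthetic 2P-FLIM cohorts, fields and flux series.

The generator emulates the statistical structure the downstream analysis
assumes: per-pixel NAD(P)H photon-arrival histograms following the
bi-exponential decay model, a matched FAD+ intensity image realising a
per-cell optical redox ratio target, disk-shaped non-overlapping cells
whose positions are held fixed across the sequential-inhibitor time
course, donor-level additive random effects, and the established
phenotype effect directions: IL-4-M2 macrophages have higher tau1, tau2
and tau_avg and lower ORR than IFNgamma-M1 macrophages, most pronounced
under FCCP.

Every generator is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AcquisitionParams, GroundTruthParams
from .errors import DomainError, ParameterError, PlacementError, ScheduleError
from .flux_metrics import FluxSeries

PHENOTYPES = ("M1", "M2")
TREATMENTS = ("baseline", "oligomycin", "FCCP", "Rot+AA", "2-DG")
VARIABLES = ("tau1", "tau2", "alpha2", "orr")

# Per-treatment population means (phenotype midpoint) for
# (tau1 [ns], tau2 [ns], alpha2 [unitless], ORR [unitless]), and the
# full M2 - M1 phenotype contrast at FCCP scaled down for the other
# treatments. Values sit in the physiological NAD(P)H range; effect
# directions and their FCCP dominance follow the polarised-macrophage
# redox biology the pipeline is built to detect.
_TREATMENT_BASE = {
    "baseline": dict(tau1=2.30, tau2=0.40, alpha2=0.76, orr=1.00),
    "oligomycin": dict(tau1=2.40, tau2=0.42, alpha2=0.75, orr=0.95),
    "FCCP": dict(tau1=2.45, tau2=0.41, alpha2=0.76, orr=0.98),
    "Rot+AA": dict(tau1=2.50, tau2=0.42, alpha2=0.75, orr=0.97),
    "2-DG": dict(tau1=2.20, tau2=0.38, alpha2=0.78, orr=1.05),
}
# M2 minus M1, full-strength (applied at FCCP)
_PHENOTYPE_CONTRAST = dict(tau1=0.50, tau2=0.10, alpha2=-0.04, orr=-0.15)
_TREATMENT_EFFECT_SCALE = {
    "baseline": 0.3,
    "oligomycin": 0.4,
    "FCCP": 1.0,
    "Rot+AA": 0.5,
    "2-DG": 0.3,
}


def default_condition_means() -> dict:
    """Mean (tau1, tau2, alpha2, orr) per (phenotype, treatment)."""
    means = {}
    for treatment, base in _TREATMENT_BASE.items():
        scale = _TREATMENT_EFFECT_SCALE[treatment]
        for phenotype, sign in (("M1", -0.5), ("M2", +0.5)):
            means[(phenotype, treatment)] = {
                var: base[var] + sign * scale * _PHENOTYPE_CONTRAST[var]
                for var in VARIABLES
            }
    return means


# field-to-field, cell-to-cell and donor-level standard deviations
DEFAULT_FIELD_SD = dict(tau1=0.15, tau2=0.04, alpha2=0.03, orr=0.10)
DEFAULT_CELL_SD = dict(tau1=0.08, tau2=0.02, alpha2=0.015, orr=0.05)
DEFAULT_DONOR_SD = dict(tau1=0.10, tau2=0.025, alpha2=0.015, orr=0.06)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic imaging cohort.

    Defaults give 6 donors x 2 phenotypes x 3 fields per condition with
    24 cells per field on 128 x 128 pixel test-scale images.
    """

    seed: int
    n_donors: int = 6
    phenotypes: Sequence[str] = PHENOTYPES
    treatments: Sequence[str] = TREATMENTS
    fields_per_condition: int = 3
    cells_per_field: int = 24
    cell_radius: int = 6
    photons_per_cell: float = 20000.0
    background_c: float = 0.005  # photons per bin per pixel
    fad_background: float = 0.2  # photons per off-cell pixel
    condition_means: Mapping | None = None
    field_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FIELD_SD))
    cell_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CELL_SD))
    donor_effect_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DONOR_SD)
    )
    acq: AcquisitionParams = AcquisitionParams(image_size=128)

    def __post_init__(self):
        if self.n_donors < 1 or self.cells_per_field < 1:
            raise ParameterError("n_donors and cells_per_field must be >= 1")
        if self.fields_per_condition < 1:
            raise ParameterError("fields_per_condition must be >= 1")
        for sd_map in (self.field_sd, self.cell_sd, self.donor_effect_sd):
            if any(v < 0 for v in sd_map.values()):
                raise ParameterError("standard deviations must be non-negative")
        if self.condition_means is None:
            object.__setattr__(self, "condition_means", default_condition_means())

    @property
    def donors(self) -> list:
        return [chr(ord("A") + i) for i in range(self.n_donors)]

    def means_for(self, phenotype: str, treatment: str) -> dict:
        key = (phenotype, treatment)
        if key not in self.condition_means:
            raise ParameterError(f"no condition means for {key}")
        return self.condition_means[key]

    def fccp_ordering_ok(self) -> bool:
        """True when the FCCP-condition means put M2 above M1 in tau1,
        tau2 and tau_avg and below M1 in ORR."""
        m1 = self.means_for("M1", "FCCP")
        m2 = self.means_for("M2", "FCCP")

        def t_avg(m):
            return (1 - m["alpha2"]) * m["tau1"] + m["alpha2"] * m["tau2"]

        return (
            m2["tau1"] > m1["tau1"]
            and m2["tau2"] > m1["tau2"]
            and t_avg(m2) > t_avg(m1)
            and m2["orr"] < m1["orr"]
        )


@dataclass(frozen=True)
class Condition:
    donor: str
    phenotype: str
    treatment: str
    field: int = 0


@dataclass
class FieldStack:
    """One synthetic imaging field: NAD(P)H histogram stack, FAD+ image,
    truth labels and per-cell ground-truth parameters."""

    nadh_histograms: np.ndarray  # (H, W, n_bins) uint16
    fad_intensity: np.ndarray  # (H, W)
    labels: np.ndarray  # (H, W) int32, 0 = background
    condition: Condition
    acq: AcquisitionParams
    truth: pd.DataFrame  # one row per cell: ids + ground-truth params


def _rng_from(*entropy) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def sample_truncated_biexp(
    params: GroundTruthParams,
    window_ns: float,
    n_photons: int,
    rng: np.random.Generator,
    return_components: bool = False,
):
    """Draw photon arrival times from the bi-exponential decay, truncated
    to the measurement window.

    Component i is chosen with probability proportional to alpha_i*tau_i
    (its share of the integrated intensity); arrival times within a
    component follow a window-truncated exponential drawn by inverse CDF.
    """
    w1 = params.alpha1 * params.tau1
    w2 = params.alpha2 * params.tau2
    p1 = w1 / (w1 + w2)
    comp1 = rng.random(n_photons) < p1
    taus = np.where(comp1, params.tau1, params.tau2)
    u = rng.random(n_photons)
    times = -taus * np.log1p(-u * (1.0 - np.exp(-window_ns / taus)))
    if return_components:
        return times, comp1
    return times


def generate_decay_histogram(
    params: GroundTruthParams,
    acq: AcquisitionParams,
    n_photons: int,
    seed,
    return_parts: bool = False,
):
    """Simulate one TCSPC histogram: n_photons signal draws from the
    truncated bi-exponential plus Poisson background with mean C per bin.

    Returns the counts array (length acq.n_bins); with return_parts=True
    also a dict with per-component signal counts and the background total.
    """
    if n_photons < 0:
        raise DomainError("n_photons must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.zeros(acq.n_bins, dtype=np.int64)
    n_comp1 = 0
    if n_photons > 0:
        times, comp1 = sample_truncated_biexp(
            params, acq.window_ns, n_photons, rng, return_components=True
        )
        bins = np.minimum(
            (times / acq.bin_width_ns).astype(np.int64), acq.n_bins - 1
        )
        np.add.at(counts, bins, 1)
        n_comp1 = int(comp1.sum())
    background = rng.poisson(params.C, size=acq.n_bins) if params.C > 0 else np.zeros(
        acq.n_bins, dtype=np.int64
    )
    counts = counts + background
    if return_parts:
        return counts, dict(
            n_signal=n_photons,
            n_component1=n_comp1,
            n_component2=n_photons - n_comp1,
            n_background=int(background.sum()),
        )
    return counts


def _place_cells(rng, image_size, n_cells, radius, max_tries=20000):
    """Non-overlapping disk centres with a margin keeping cells in-frame."""
    # cells must stay resolvable as separate connected components after
    # the segmenter's Gaussian smoothing, hence the 6 px clearance
    margin = radius + 2
    min_sep = 2 * radius + 6
    centers = []
    tries = 0
    while len(centers) < n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"placed {len(centers)}/{n_cells} cells after {max_tries} tries"
            )
        tries += 1
        y = rng.uniform(margin, image_size - margin)
        x = rng.uniform(margin, image_size - margin)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep**2 for cy, cx in centers):
            centers.append((y, x))
    return centers


def _draw_cell_params(cfg: CohortConfig, means, donor_shift, rng):
    """One cell's (tau1, tau2, alpha2, orr) around the condition means."""
    out = {}
    for var in VARIABLES:
        val = (
            means[var]
            + donor_shift[var]
            + rng.normal(0.0, cfg.cell_sd[var])
        )
        out[var] = val
    out["tau2"] = float(np.clip(out["tau2"], 0.1, 1.5))
    out["tau1"] = float(np.clip(out["tau1"], out["tau2"] + 0.1, 8.0))
    out["alpha2"] = float(np.clip(out["alpha2"], 0.05, 0.95))
    out["orr"] = float(max(out["orr"], 0.05))
    return out


def donor_shifts(cfg: CohortConfig, donor: str) -> dict:
    """Additive per-donor random effect for each variable (deterministic
    in (config seed, donor))."""
    idx = cfg.donors.index(donor)
    rng = _rng_from(cfg.seed, 1000 + idx)
    return {
        var: rng.normal(0.0, cfg.donor_effect_sd[var]) for var in VARIABLES
    }


def generate_field(cfg: CohortConfig, condition: Condition, seed=None) -> FieldStack:
    """Generate one imaging field for a (donor, phenotype, treatment).

    Cell positions depend only on (seed, donor, phenotype, field) so the
    same field keeps its cell layout across the treatment sequence, as in
    a maintained field of view; photon noise and per-cell metabolic state
    are re-drawn per treatment.
    """
    if condition.phenotype not in cfg.phenotypes:
        raise ParameterError(f"unknown phenotype {condition.phenotype!r}")
    if condition.treatment not in cfg.treatments:
        raise ParameterError(f"unknown treatment {condition.treatment!r}")
    seed = cfg.seed if seed is None else seed
    d = cfg.donors.index(condition.donor)
    p = list(cfg.phenotypes).index(condition.phenotype)
    t = list(cfg.treatments).index(condition.treatment)
    rng_place = _rng_from(seed, 2, d, p, condition.field)
    rng_noise = _rng_from(seed, 3, d, p, t, condition.field)

    size = cfg.acq.image_size
    n_bins = cfg.acq.n_bins
    centers = _place_cells(rng_place, size, cfg.cells_per_field, cfg.cell_radius)

    yy, xx = np.mgrid[0:size, 0:size]
    labels = np.zeros((size, size), dtype=np.int32)
    for i, (cy, cx) in enumerate(centers, start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= cfg.cell_radius**2
        labels[disk] = i

    hists = np.zeros((size * size, n_bins), dtype=np.uint16)
    means = cfg.means_for(condition.phenotype, condition.treatment)
    shift = donor_shifts(cfg, condition.donor)
    # field-level wobble shared by all cells in the field
    field_shift = {
        var: rng_noise.normal(0.0, cfg.field_sd[var]) for var in VARIABLES
    }
    means = {var: means[var] + field_shift[var] for var in VARIABLES}

    flat_labels = labels.ravel()
    truth_rows = []
    cell_truth_params = []
    for i in range(1, cfg.cells_per_field + 1):
        cell_pix = np.flatnonzero(flat_labels == i)
        drawn = _draw_cell_params(cfg, means, shift, rng_noise)
        gt = GroundTruthParams(
            I0=1.0,
            alpha1=1.0 - drawn["alpha2"],
            alpha2=drawn["alpha2"],
            tau1=drawn["tau1"],
            tau2=drawn["tau2"],
            C=0.0,
        )
        n_phot = int(rng_noise.poisson(cfg.photons_per_cell))
        times = sample_truncated_biexp(gt, cfg.acq.window_ns, n_phot, rng_noise)
        bins = np.minimum(
            (times / cfg.acq.bin_width_ns).astype(np.int64), n_bins - 1
        )
        pix = rng_noise.choice(cell_pix, size=n_phot, replace=True)
        np.add.at(hists, (pix, bins), 1)
        cell_truth_params.append((i, gt, drawn["orr"], cell_pix))
        truth_rows.append(
            dict(
                donor=condition.donor,
                phenotype=condition.phenotype,
                treatment=condition.treatment,
                field_id=condition.field,
                cell_id=i,
                tau1=gt.tau1,
                tau2=gt.tau2,
                alpha1=gt.alpha1,
                alpha2=gt.alpha2,
                tau_avg=gt.tau_avg,
                orr=drawn["orr"],
                n_photons=n_phot,
            )
        )

    if cfg.background_c > 0:
        hists = hists + rng_noise.poisson(
            cfg.background_c, size=hists.shape
        ).astype(np.uint16)

    nadh_total = hists.sum(axis=1).astype(np.float64)
    fad = np.zeros(size * size, dtype=np.float64)
    if cfg.fad_background > 0:
        fad[flat_labels == 0] = rng_noise.poisson(
            cfg.fad_background, size=int((flat_labels == 0).sum())
        )
    for i, gt, orr_target, cell_pix in cell_truth_params:
        cell_nadh = nadh_total[cell_pix].sum()
        lam = orr_target * cell_nadh / cell_pix.size
        fad[cell_pix] = rng_noise.poisson(lam, size=cell_pix.size)

    return FieldStack(
        nadh_histograms=hists.reshape(size, size, n_bins),
        fad_intensity=fad.reshape(size, size),
        labels=labels,
        condition=condition,
        acq=cfg.acq,
        truth=pd.DataFrame(truth_rows),
    )


def iter_conditions(cfg: CohortConfig):
    for donor in cfg.donors:
        for phenotype in cfg.phenotypes:
            for treatment in cfg.treatments:
                for f in range(cfg.fields_per_condition):
                    yield Condition(donor, phenotype, treatment, f)


def iter_cohort(cfg: CohortConfig):
    """Yield FieldStacks for every condition of the cohort (memory-light)."""
    for cond in iter_conditions(cfg):
        yield generate_field(cfg, cond)


def generate_cohort(cfg: CohortConfig):
    """All FieldStacks of a cohort plus the ground-truth cell table."""
    stacks = list(iter_cohort(cfg))
    truth = pd.concat([s.truth for s in stacks], ignore_index=True)
    return stacks, truth


def generate_flux_timeseries(
    phase_means,
    schedule,
    noise_sd=0.0,
    n_replicates: int = 1,
    seed=0,
    timepoints_per_phase: int = 3,
    group: str = "",
):
    """Synthetic extracellular-flux (ECAR, OCR) series.

    phase_means: five (ecar, ocr) pairs — basal plus the four phases after
    oligomycin, FCCP, Rot+AA and 2-DG injections given in `schedule`
    (minutes, strictly increasing). Measurements are piecewise-constant
    phase means plus Gaussian noise; returns one FluxSeries per replicate.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size != 4 or np.any(np.diff(schedule) <= 0) or schedule[0] <= 0:
        raise ScheduleError("schedule must be four strictly increasing times > 0")
    phase_means = np.asarray(phase_means, dtype=float)
    if phase_means.shape != (5, 2):
        raise ScheduleError("phase_means must be five (ecar, ocr) pairs")
    rng = np.random.default_rng(seed)
    gaps = np.diff(np.concatenate([[0.0], schedule]))
    bounds = np.concatenate([[0.0], schedule, [schedule[-1] + gaps.mean()]])
    times, phase_of = [], []
    for k in range(5):
        lo, hi = bounds[k], bounds[k + 1]
        pts = lo + (np.arange(timepoints_per_phase) + 0.5) * (hi - lo) / timepoints_per_phase
        times.extend(pts)
        phase_of.extend([k] * timepoints_per_phase)
    times = np.array(times)
    phase_of = np.array(phase_of)
    ecar_sd, ocr_sd = (
        (noise_sd, noise_sd) if np.isscalar(noise_sd) else tuple(noise_sd)
    )
    out = []
    for r in range(n_replicates):
        ecar = phase_means[phase_of, 0] + rng.normal(0, ecar_sd, times.size)
        ocr = phase_means[phase_of, 1] + rng.normal(0, ocr_sd, times.size)
        out.append(
            FluxSeries(
                times=times.copy(),
                ecar=ecar,
                ocr=ocr,
                schedule=tuple(schedule),
                replicate=r,
                group=group,
            )
        )
    return out
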