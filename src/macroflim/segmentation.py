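"""Single-cell segmentation, per-cell feature aggregation and tracking.

Cells are segmented from the NAD(P)H total-intensity image by Gaussian
smoothing, automatic (Otsu) or absolute thresholding and
connected-component labelling; small and border-touching components are
dropped. Per-cell features come from the cell's aggregate-decay fit,
with the per-cell optical redox ratio computed as mean FAD+ over mean
NAD(P)H intensity inside the mask. Cells are matched across the
sequential-treatment time course by greedy nearest-centroid matching
within a displacement radius (the field of view is held fixed during
the inhibitor sequence, so matched centroids move little).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, segmentation as sk_seg
from skimage.filters import gaussian, threshold_otsu

from .decay_fitting import FitOptions, fit_field, optical_redox_ratio
from .errors import DomainError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationOptions:
    sigma: float = 1.0
    method: str = "otsu"  # or 'absolute'
    threshold: float | None = None
    min_area: int = 20
    clear_border: bool = True
    watershed: bool = False  # distance-transform splitting for touching cells


@dataclass(frozen=True)
class LabelMap:
    """Connected-component cell labels (0 = background)."""

    labels: np.ndarray
    n_cells: int
    centroids: np.ndarray  # (n_cells, 2) as (y, x)
    areas: np.ndarray  # (n_cells,)


def _as_label_map(labels: np.ndarray) -> LabelMap:
    props = measure.regionprops(labels)
    # relabel consecutively 1..n
    out = np.zeros_like(labels)
    centroids, areas = [], []
    for new_id, p in enumerate(sorted(props, key=lambda p: p.label), start=1):
        out[labels == p.label] = new_id
        centroids.append(p.centroid)
        areas.append(p.area)
    return LabelMap(
        labels=out,
        n_cells=len(props),
        centroids=np.array(centroids, dtype=float).reshape(-1, 2),
        areas=np.array(areas, dtype=int),
    )


def segment_cells(
    intensity_image: np.ndarray, options: SegmentationOptions | None = None
) -> LabelMap:
    """Segment cells from a total-intensity image; an empty result is a
    valid LabelMap with zero cells, not an error."""
    options = options or SegmentationOptions()
    img = np.asarray(intensity_image, dtype=float)
    if np.any(img < 0):
        raise DomainError("intensity image must be non-negative")
    smooth = gaussian(img, sigma=options.sigma, preserve_range=True)
    if options.method == "absolute":
        if options.threshold is None:
            raise DomainError("absolute thresholding requires a threshold")
        fg = smooth >= options.threshold
    elif options.method == "otsu":
        logs = np.log1p(smooth)
        if np.allclose(logs, logs.flat[0]):
            fg = np.zeros_like(logs, dtype=bool)
        else:
            fg = logs >= threshold_otsu(logs)
    else:
        raise DomainError(f"unknown segmentation method {options.method!r}")

    if options.clear_border:
        fg = sk_seg.clear_border(fg)
    if options.watershed:
        dist = ndimage.distance_transform_edt(fg)
        peaks = measure.label(dist >= 0.6 * dist.max()) if dist.max() > 0 else None
        labels = (
            sk_seg.watershed(-dist, peaks, mask=fg) if peaks is not None else
            measure.label(fg)
        )
    else:
        labels = measure.label(fg)
    # drop undersized components
    for p in measure.regionprops(labels):
        if p.area < options.min_area:
            labels[labels == p.label] = 0
    lm = _as_label_map(labels)
    if lm.n_cells == 0:
        logger.info("segmentation found no cells")
    return lm


def aggregate_cell_features(
    label_map: LabelMap,
    stack,
    fit_options: FitOptions | None = None,
) -> pd.DataFrame:
    """One feature row per segmented cell: bi-exponential fit of the
    cell's aggregate decay plus its optical redox ratio and identifiers.

    Cells whose fit fails are emitted with good=False so downstream
    stages can exclude them without losing the audit trail.
    """
    fits = fit_field(
        stack, mode="per_cell", options=fit_options, labels=label_map.labels
    )
    nadh_total = stack.nadh_histograms.sum(axis=2).astype(float)
    rows = []
    for _, r in fits.iterrows():
        m = label_map.labels == r.unit_id
        mean_nadh = float(nadh_total[m].mean())
        mean_fad = float(stack.fad_intensity[m].mean())
        orr = optical_redox_ratio(mean_fad, mean_nadh) if mean_nadh > 0 else np.nan
        rows.append(
            dict(
                donor=stack.condition.donor,
                phenotype=stack.condition.phenotype,
                treatment=stack.condition.treatment,
                field_id=stack.condition.field,
                cell_id=int(r.unit_id),
                tau1_ns=r.tau1_ns,
                tau2_ns=r.tau2_ns,
                alpha1=r.alpha1,
                alpha2=r.alpha2,
                tau_avg_ns=r.tau_avg_ns,
                orr=orr,
                chi2_nu=r.chi2_nu,
                n_photons=r.n_photons,
                good=bool(r.good),
            )
        )
    return pd.DataFrame(rows)


def match_cells_across_treatments(
    maps: list, max_displacement: float = 10.0
) -> pd.DataFrame:
    """Greedy nearest-centroid matching of cells across an ordered list of
    label maps from the same field.

    Returns a track table with one row per (map index, cell) and a track
    id; cells with no counterpart within the radius are flagged as
    appearing/disappearing.
    """
    if not maps:
        raise DomainError("empty label-map list")
    rows = []
    next_track = 1
    prev_tracks = {}
    for lab in range(1, maps[0].n_cells + 1):
        prev_tracks[lab] = next_track
        rows.append(
            dict(map_index=0, cell_id=lab, track_id=next_track, status="present")
        )
        next_track += 1
    for k in range(1, len(maps)):
        prev, cur = maps[k - 1], maps[k]
        pairs = []
        for i in range(cur.n_cells):
            for j in range(prev.n_cells):
                d = float(np.hypot(*(cur.centroids[i] - prev.centroids[j])))
                if d <= max_displacement:
                    pairs.append((d, i, j))
        pairs.sort()
        used_cur, used_prev = set(), set()
        assign = {}
        for d, i, j in pairs:
            if i in used_cur or j in used_prev:
                continue
            used_cur.add(i)
            used_prev.add(j)
            assign[i + 1] = j + 1  # labels are 1-based
        cur_tracks = {}
        for i in range(1, cur.n_cells + 1):
            if i in assign:
                cur_tracks[i] = prev_tracks[assign[i]]
                rows.append(
                    dict(map_index=k, cell_id=i, track_id=cur_tracks[i], status="present")
                )
            else:
                cur_tracks[i] = next_track
                rows.append(
                    dict(map_index=k, cell_id=i, track_id=next_track, status="appeared")
                )
                next_track += 1
        for j in range(1, prev.n_cells + 1):
            if j not in assign.values():
                rows.append(
                    dict(
                        map_index=k,
                        cell_id=j,
                        track_id=prev_tracks[j],
                        status="lost",
                    )
                )
        prev_tracks = cur_tracks
    return pd.DataFrame(rows)
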