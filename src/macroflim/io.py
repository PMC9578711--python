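"""On-disk formats: multi-page TIFF field stacks with JSON sidecars,
CSV feature/fit tables and cohort manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import AcquisitionParams
from .synthetic_data import Condition, FieldStack


def field_stem(condition: Condition) -> str:
    treat = condition.treatment.replace("+", "").replace("-", "")
    return f"{condition.donor}_{condition.phenotype}_{treat}_f{condition.field}"


def save_field(stack: FieldStack, out_dir) -> dict:
    """Write one field as NAD(P)H multi-page TIFF (time bins as pages),
    FAD+ single-page TIFF, truth-label TIFF and a JSON sidecar. Returns
    the file manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = field_stem(stack.condition)
    paths = {
        "nadh": out_dir / f"{stem}_nadh.tif",
        "fad": out_dir / f"{stem}_fad.tif",
        "labels": out_dir / f"{stem}_labels.tif",
        "sidecar": out_dir / f"{stem}.json",
    }
    # pages = time bins
    tifffile.imwrite(paths["nadh"], np.moveaxis(stack.nadh_histograms, 2, 0))
    tifffile.imwrite(paths["fad"], stack.fad_intensity.astype(np.float32))
    tifffile.imwrite(paths["labels"], stack.labels.astype(np.uint16))
    sidecar = dict(
        condition=dict(
            donor=stack.condition.donor,
            phenotype=stack.condition.phenotype,
            treatment=stack.condition.treatment,
            field=stack.condition.field,
        ),
        acq=dict(
            rep_rate=stack.acq.rep_rate,
            n_bins=stack.acq.n_bins,
            image_size=stack.acq.image_size,
        ),
        truth=stack.truth.to_dict(orient="records"),
    )
    paths["sidecar"].write_text(json.dumps(sidecar, indent=1))
    return {k: str(v) for k, v in paths.items()}


def load_field(sidecar_path) -> FieldStack:
    """Read back a field written by :func:`save_field`."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    stem = sidecar_path.stem
    d = sidecar_path.parent
    nadh = np.moveaxis(tifffile.imread(d / f"{stem}_nadh.tif"), 0, 2)
    fad = tifffile.imread(d / f"{stem}_fad.tif").astype(float)
    labels = tifffile.imread(d / f"{stem}_labels.tif").astype(np.int32)
    cond = Condition(**meta["condition"])
    acq = AcquisitionParams(**meta["acq"])
    return FieldStack(
        nadh_histograms=nadh,
        fad_intensity=fad,
        labels=labels,
        condition=cond,
        acq=acq,
        truth=pd.DataFrame(meta["truth"]),
    )


def write_manifest(entries: list, path) -> None:
    pd.DataFrame(entries).to_csv(path, index=False)
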