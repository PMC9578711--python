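"""Run the whole pipeline from a configuration document.

Uses a scaled-down synthetic cohort so the example finishes in ~20 s;
artefacts (TIFF fields, feature CSVs, phasor table, model reports) land
in ./pipeline_demo. The same document works via the CLI:

    macroflim run --config config.yaml --seed 5 --out pipeline_demo
"""

from macroflim.pipeline import run_pipeline, validate_config

config = validate_config({
    "seed": 5,
    "out_dir": "pipeline_demo",
    "cohort": {
        "n_donors": 2,
        "fields_per_condition": 2,
        "cells_per_field": 8,
        "cell_radius": 5,
        "photons_per_cell": 8000.0,
        "treatments": ["FCCP"],
        "image_size": 96,
    },
    "grid": {"ntree_candidates": [50, 100]},
})
report = run_pipeline(config)

print("stage counts:", report.counts)
fov = report.reports["full_fov"]
print(f"full-FoV model: ntree={fov['ntree']} mtry={fov['mtry']} "
      f"OOB={fov['oob_error']:.2f}% AUC={fov['roc_auc']:.3f}")
for donor, rep in report.reports.get("donors", {}).items():
    print(f"donor {donor}: AUC={rep['roc_auc']:.3f} OOB={rep['oob_error']:.1f}%")
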