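"""End-to-end pipeline: simulate -> fit -> template -> tract -> parcellate
-> overlap, driven by one YAML config and one master seed.

Every stage derives its randomness from the master seed, so two runs with
the same config produce byte-identical reports. The config schema (all
keys optional, defaults shown in :func:`default_config`) mirrors the CLI
subcommands.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as tio
from .dti import compute_fa, fit_tensor_lls
from .lesions import (
    compute_overlap_report,
    format_report_tsv,
    reports_to_json_dict,
)
from .parcellation import classify_winner_take_all, parcellation_dice
from .phantom import (
    CohortSpec,
    LesionSpec,
    default_phantom_spec,
    generate_cohort,
    generate_lesion_mask,
    make_protocol,
)
from .template import average_tensor_volumes, warp_tensor_volume_ppd
from .tracking import TrackingConfig, estimate_connection_probabilities
from .volumes import ScalarVolume


def default_config() -> dict[str, Any]:
    """Baseline run-all configuration (the default three-bundle study)."""
    return {
        "seed": 0,
        "phantom": {"dims": [40, 60, 40], "voxel_mm": 2.3, "targets": ["BA6", "BA9", "BA32"]},
        "protocol": {"n_weighted": 81, "n_b0": 9, "bval": 1000.0},
        "cohort": {
            "n_subjects": 19,
            "snr_b0": 20.0,
            "rotation_max_deg": 2.0,
            "translation_max_mm": 2.0,
        },
        "tracking": {},
        "parcellation": {"min_probability": 0.5},
        "lesions": [],
    }


def load_config(path: str | Path) -> dict[str, Any]:
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_all(config: dict[str, Any] | str | Path, out_dir: str | Path) -> dict[str, Any]:
    """Run the whole analysis on the synthetic study described by ``config``.

    Writes the template tensor/FA, connection-probability TSV, parcellation
    label and max-probability volumes, overlap ``report.tsv`` and a
    full-precision ``report.json`` into ``out_dir``; returns the report
    dict. Deterministic given the config (including its master ``seed``).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(config["seed"]) % (2**31)

    # --- synthetic study -------------------------------------------------
    ph = config["phantom"]
    spec = default_phantom_spec(
        dims=tuple(ph["dims"]), voxel_mm=float(ph["voxel_mm"]), target_names=ph["targets"]
    )
    from .phantom import build_tensor_phantom

    truth_tensors, truth_labels = build_tensor_phantom(spec)
    pr = config["protocol"]
    protocol = make_protocol(int(pr["n_weighted"]), int(pr["n_b0"]), float(pr["bval"]))
    cohort = CohortSpec(rng_seed=master, **config["cohort"])
    subjects = generate_cohort(spec, cohort, protocol)

    # --- per-subject fit, warp to template, average ----------------------
    warped = []
    for dwi, to_template in subjects:
        tensors = fit_tensor_lls(dwi, protocol)
        warped.append(warp_tensor_volume_ppd(tensors, to_template, spec.grid))
    template, coverage = average_tensor_volumes(warped)
    fa = compute_fa(template)
    tio.write_tensor_volume(template, out / "template")
    tio.write_volume(fa, out / "template_fa.nii.gz")
    tio.write_volume(ScalarVolume(spec.grid, coverage.values), out / "template_coverage.nii.gz")

    # --- seed mask from a probabilistic atlas -----------------------------
    # synthetic percent-scale atlas whose 25% binarisation recovers the
    # phantom's seed region: 90% inside, 10% on a one-voxel boundary shell
    from scipy.ndimage import binary_dilation

    from .parcellation import build_seed_mask

    region = spec.seed_region.values
    shell = binary_dilation(region) & ~region
    atlas = ScalarVolume(spec.grid, np.where(region, 90.0, np.where(shell, 10.0, 0.0)))
    seed_mask = build_seed_mask(atlas, threshold=0.25)
    tio.write_volume(seed_mask, out / "seed_mask.nii.gz")

    # --- tractography + parcellation -------------------------------------
    tracking = TrackingConfig(rng_seed=master, **config["tracking"])
    cpm = estimate_connection_probabilities(
        seed_mask, spec.targets, template, fa, tracking
    )
    cpm.to_dataframe().to_csv(out / "connection_probabilities.tsv", sep="\t", index=False)
    parc = classify_winner_take_all(
        cpm, min_probability=float(config["parcellation"]["min_probability"])
    )
    tio.write_volume(parc.labels, out / "parcellation.nii.gz")
    tio.write_volume(parc.max_probability, out / "max_probability.nii.gz")
    dice = parcellation_dice(parc, truth_labels)

    # --- lesions ----------------------------------------------------------
    reports = []
    for les in config["lesions"]:
        mask = generate_lesion_mask(
            LesionSpec(
                center_mm=tuple(les["center_mm"]),
                semi_axes_mm=tuple(les["semi_axes_mm"]),
                side_label=str(les.get("id", "")),
            ),
            spec.grid,
        )
        tio.write_volume(mask, out / f"lesion_{_slug(les['id'])}.nii.gz")
        reports.append(compute_overlap_report(mask, parc, str(les["id"])))
    if reports:
        (out / "report.tsv").write_text(format_report_tsv(reports))

    report: dict[str, Any] = {
        "seed": master,
        "config": _jsonable(config),
        "n_seed_voxels": int(cpm.seed_voxels.shape[0]),
        "n_flagged_seed_voxels": int(cpm.flagged.sum()),
        "targets": cpm.target_names,
        "dice_vs_truth": {cpm.target_names[cpm.targets.index(k)]: v for k, v in dice.items()},
        "tie_count": parc.tie_count,
        "labeled_voxels": int(np.sum(parc.labels.values > 0)),
        "overlap": reports_to_json_dict(reports)["lesions"],
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in str(text))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
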