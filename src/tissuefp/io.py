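"""Disk formats: PNG rasters, CSV labels, JSON manifests, TSV logs."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthgen import BUILTIN_STYLES, SyntheticCohort, WsiCohort, render_style

__all__ = [
    "write_cohort",
    "write_wsi_cohort",
    "read_manifest",
    "write_fingerprints",
    "load_image",
]


def load_image(path: str | Path) -> np.ndarray:
    return iio.imread(path)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path,
                 styles: list[str] | None = None) -> Path:
    """Write rendered cores (one PNG per style) plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    style_ids = styles or [s.style_id for s in cohort.styles]
    registry = {s.style_id: s for s in cohort.styles} | BUILTIN_STYLES
    entries = []
    for core_index, pid, morph in cohort.cores:
        for sid in style_ids:
            img = render_style(morph, registry[sid], seed=core_index)
            name = f"core{core_index:04d}_{sid}.png"
            iio.imwrite(out / name, img)
            entries.append({"file": name, "core_index": core_index,
                            "patient_id": pid, "style_id": sid,
                            "mpp": cohort.config.microns_per_pixel})
    manifest = {
        "seed": cohort.seed,
        "layout": {str(k): v for k, v in cohort.layout.items()},
        "phenotypes": [vars(p) for p in cohort.phenotypes],
        "images": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def write_wsi_cohort(cohort: WsiCohort, out_dir: str | Path) -> Path:
    """Write slides and masks as PNG, labels as CSV, sidecar JSON with mpp."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for phen, slide, mask in zip(cohort.phenotypes, cohort.slides, cohort.masks):
        iio.imwrite(out / f"slide{phen.patient_id:04d}.png", slide)
        iio.imwrite(out / f"mask{phen.patient_id:04d}.png", mask)
        (out / f"slide{phen.patient_id:04d}.json").write_text(
            json.dumps({"microns_per_pixel": cohort.microns_per_pixel}))
    cohort.labels.to_csv(out / "labels.csv", index=False)
    return out


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_fingerprints(path: str | Path, matrix: np.ndarray,
                       sources: pd.DataFrame) -> None:
    """Fingerprints as TSV next to a sources CSV of the same stem."""
    path = Path(path)
    pd.DataFrame(matrix).to_csv(path, sep="\t", header=False, index=False)
    sources.to_csv(path.with_suffix(".sources.csv"), index=False)
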