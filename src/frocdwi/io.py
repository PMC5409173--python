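"""Readers and writers for the on-disk formats.

NIfTI-1 images (nibabel) carry the 4-D DWI volume, the integer ROI
label image and the fitted parameter maps; the acquisition scheme is an
FSL-style one-line ``.bval`` table (whitespace-separated, s/mm^2) plus a
small JSON sidecar with the gradient timing (``delta_ms``, ``Delta_ms``,
``gamma_rad_per_ms_mT``) that a .bval file cannot express; lesion and
results tables are CSV.  All validation errors name the offending file
or field; nothing is silently coerced.

Coordinate convention: voxel indices are 0-based; world coordinates come
from the NIfTI affine; lesion diameters are world mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .cohort import BENIGN, MALIGNANT, CohortAnalysis, LesionRecord
from .errors import DataValidationError
from .fitting import ParameterMaps
from .signal_models import GYROMAGNETIC_RATIO_PROTON, AcquisitionScheme

__all__ = [
    "DWIDataset",
    "read_bval",
    "write_bval",
    "read_scheme",
    "write_scheme",
    "read_dwi_dataset",
    "write_dwi_dataset",
    "read_lesion_csv",
    "write_lesion_csv",
    "write_parameter_maps",
    "write_results",
]


@dataclass
class DWIDataset:
    """A validated in-memory dataset: 4-D signal volume (x, y, z, b) with
    b-values sorted ascending, ROI label image on the same grid, and the
    lesion table (lesion_id, label, size_mm)."""

    volume: np.ndarray
    scheme: AcquisitionScheme
    roi_labels: np.ndarray
    lesion_table: pd.DataFrame
    affine: np.ndarray


def read_bval(path: str | Path) -> np.ndarray:
    """Read an FSL-style .bval file (one whitespace-separated line)."""
    text = Path(path).read_text().split()
    if not text:
        raise DataValidationError(f"{path}: empty .bval file")
    try:
        return np.array([float(t) for t in text])
    except ValueError as exc:
        raise DataValidationError(f"{path}: non-numeric b-value: {exc}") from exc


def write_bval(path: str | Path, b_values) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in np.asarray(b_values)) + "\n")


def read_scheme(bval_path: str | Path, sidecar_path: str | Path) -> AcquisitionScheme:
    """Assemble an AcquisitionScheme from a .bval table plus its JSON
    timing sidecar.  The b-values are sorted ascending here; callers
    that hold a matching 4-D volume must reorder it with the returned
    permutation from :func:`read_dwi_dataset`."""
    b = np.sort(read_bval(bval_path))
    meta = json.loads(Path(sidecar_path).read_text())
    for key in ("delta_ms", "Delta_ms"):
        if key not in meta:
            raise DataValidationError(f"{sidecar_path}: missing field {key!r}")
    return AcquisitionScheme(
        b_values=tuple(b),
        delta=float(meta["delta_ms"]),
        Delta=float(meta["Delta_ms"]),
        gamma=float(meta.get("gamma_rad_per_ms_mT", GYROMAGNETIC_RATIO_PROTON)),
    )


def write_scheme(
    bval_path: str | Path, sidecar_path: str | Path, scheme: AcquisitionScheme
) -> None:
    write_bval(bval_path, scheme.b_values)
    Path(sidecar_path).write_text(
        json.dumps(
            {
                "delta_ms": scheme.delta,
                "Delta_ms": scheme.Delta,
                "gamma_rad_per_ms_mT": scheme.gamma,
            },
            indent=2,
        )
        + "\n"
    )


def read_lesion_csv(path: str | Path) -> pd.DataFrame:
    """Lesion table CSV with at least lesion_id, label, size_mm columns
    (additional per-parameter columns are preserved)."""
    table = pd.read_csv(path)
    for col in ("lesion_id", "label", "size_mm"):
        if col not in table.columns:
            raise DataValidationError(f"{path}: missing column {col!r}")
    bad = set(table["label"]) - {MALIGNANT, BENIGN}
    if bad:
        raise DataValidationError(
            f"{path}: labels must be '{MALIGNANT}' or '{BENIGN}', found {sorted(bad)}"
        )
    if table["lesion_id"].duplicated().any():
        dupes = table.loc[table["lesion_id"].duplicated(), "lesion_id"].tolist()
        raise DataValidationError(f"{path}: duplicate lesion_id values {dupes}")
    return table


def write_lesion_csv(path: str | Path, records: list[LesionRecord]) -> None:
    rows = [
        {"lesion_id": r.lesion_id, "label": r.label, "size_mm": r.size_mm,
         **r.summaries}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def records_from_lesion_csv(path: str | Path) -> list[LesionRecord]:
    """LesionRecords from a summary CSV (one column per parameter)."""
    table = read_lesion_csv(path)
    meta = {"lesion_id", "label", "size_mm"}
    params = [c for c in table.columns if c not in meta]
    if not params:
        raise DataValidationError(f"{path}: no parameter columns beside {sorted(meta)}")
    return [
        LesionRecord(
            lesion_id=int(row["lesion_id"]),
            label=str(row["label"]),
            size_mm=float(row["size_mm"]),
            summaries={p: float(row[p]) for p in params},
        )
        for _, row in table.iterrows()
    ]


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def read_dwi_dataset(
    dwi_path: str | Path,
    bval_path: str | Path,
    sidecar_path: str | Path,
    roi_path: str | Path,
    lesion_csv_path: str | Path,
) -> DWIDataset:
    """Load and cross-validate a full dataset.

    Checks: 4th-axis length equals the b-count; a b = 0 channel exists;
    ROI and DWI grids/affines agree; every ROI label has a lesion-table
    row and vice versa.  The signal axis is reordered so b-values are
    ascending regardless of on-disk order.
    """
    volume, affine = _load_nifti(dwi_path)
    if volume.ndim != 4:
        raise DataValidationError(f"{dwi_path}: expected a 4-D volume, got {volume.ndim}-D")
    b_raw = read_bval(bval_path)
    if volume.shape[3] != b_raw.size:
        raise DataValidationError(
            f"{dwi_path}: 4th axis has {volume.shape[3]} channels but "
            f"{bval_path} lists {b_raw.size} b-values"
        )
    if not np.any(b_raw == 0):
        raise DataValidationError(f"{bval_path}: missing the b = 0 channel")
    order = np.argsort(b_raw, kind="stable")
    volume = volume[..., order]
    scheme = read_scheme(bval_path, sidecar_path)

    roi, roi_affine = _load_nifti(roi_path)
    if roi.shape != volume.shape[:3]:
        raise DataValidationError(
            f"{roi_path}: grid {roi.shape} does not match DWI grid {volume.shape[:3]}"
        )
    if not np.allclose(roi_affine, affine, atol=1e-4):
        raise DataValidationError(f"{roi_path}: affine disagrees with {dwi_path}")
    roi = roi.astype(np.int32)

    lesion_table = read_lesion_csv(lesion_csv_path)
    roi_ids = set(int(v) for v in np.unique(roi)) - {0}
    csv_ids = set(int(v) for v in lesion_table["lesion_id"])
    orphans = roi_ids - csv_ids
    if orphans:
        raise DataValidationError(
            f"{roi_path}: ROI labels {sorted(orphans)} absent from {lesion_csv_path}"
        )
    missing = csv_ids - roi_ids
    if missing:
        raise DataValidationError(
            f"{lesion_csv_path}: lesion_id {sorted(missing)} absent from {roi_path}"
        )
    return DWIDataset(
        volume=volume,
        scheme=scheme,
        roi_labels=roi,
        lesion_table=lesion_table,
        affine=affine,
    )


def _affine_from_voxel_size(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_dwi_dataset(
    outdir: str | Path,
    volume: np.ndarray,
    scheme: AcquisitionScheme,
    roi_labels: np.ndarray,
    lesion_table: pd.DataFrame,
    voxel_size=(2.5, 2.5, 3.0),
) -> dict[str, Path]:
    """Write the formats the fitting pipeline consumes; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine_from_voxel_size(voxel_size)
    paths = {
        "dwi": outdir / "dwi.nii.gz",
        "bval": outdir / "dwi.bval",
        "sidecar": outdir / "scheme.json",
        "roi": outdir / "roi_labels.nii.gz",
        "lesions": outdir / "lesions.csv",
    }
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), aff), paths["dwi"])
    nib.save(
        nib.Nifti1Image(np.asarray(roi_labels, dtype=np.int32), aff), paths["roi"]
    )
    write_scheme(paths["bval"], paths["sidecar"], scheme)
    lesion_table.to_csv(paths["lesions"], index=False, float_format="%.10g")
    return paths


def write_parameter_maps(
    outdir: str | Path,
    maps: ParameterMaps,
    affine: np.ndarray | None = None,
    prefix: str = "",
) -> dict[str, Path]:
    """One NIfTI per fitted parameter plus a JSON diagnostics summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    paths: dict[str, Path] = {}
    for name, arr in maps.maps.items():
        p = outdir / f"{prefix}{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), p)
        paths[name] = p
    n_valid = int(maps.valid.sum())
    diag = {
        "model": maps.model,
        "n_valid": n_valid,
        "n_converged": int(maps.diagnostics.get("converged", maps.valid).sum()),
        "mean_residual_norm": (
            float(np.nanmean(maps.diagnostics["residual_norm"][maps.valid]))
            if n_valid and "residual_norm" in maps.diagnostics
            else None
        ),
    }
    diag_path = outdir / f"{prefix}{maps.model}_diagnostics.json"
    diag_path.write_text(json.dumps(diag, indent=2, sort_keys=True) + "\n")
    paths["diagnostics"] = diag_path
    return paths


def analysis_to_json(analysis: CohortAnalysis) -> dict:
    """Full test detail as a JSON-serialisable dict."""
    out: dict = {
        "size_threshold_mm": analysis.size_threshold_mm,
        "reference": analysis.reference,
        "not_computable": dict(analysis.not_computable),
        "subgroups": {},
    }
    for sub in analysis.comparisons:
        entry: dict = {}
        for param, gc in analysis.comparisons[sub].items():
            roc = analysis.rocs[sub][param]
            cmp_ = analysis.auc_vs_reference[sub].get(param)
            entry[param] = {
                "mannwhitney": {
                    "U": gc.U, "p": gc.p, "method": gc.method,
                    "n_malignant": gc.n_malignant, "n_benign": gc.n_benign,
                    "malignant": [gc.q25_malignant, gc.median_malignant,
                                  gc.q75_malignant],
                    "benign": [gc.q25_benign, gc.median_benign, gc.q75_benign],
                },
                "roc": {
                    "auc": roc.auc, "ci": [roc.ci_low, roc.ci_high],
                    "orientation": roc.orientation,
                },
                "auc_vs_reference": (
                    None if cmp_ is None else
                    {"area_difference": cmp_.area_difference, "p": cmp_.p,
                     "method": cmp_.method}
                ),
            }
        out["subgroups"][sub] = entry
    return out


def write_results(
    outdir: str | Path,
    analysis: CohortAnalysis,
    records: list[LesionRecord] | None = None,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write the results table (CSV), full detail (JSON), optional lesion
    summary CSV and a run manifest.

    Re-running with identical inputs produces byte-identical CSV/JSON;
    anything time- or host-dependent belongs in ``manifest`` only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["results_csv"] = outdir / "results.csv"
    analysis.to_frame().to_csv(paths["results_csv"], index=False,
                               float_format="%.10g")
    paths["results_json"] = outdir / "results.json"
    paths["results_json"].write_text(
        json.dumps(analysis_to_json(analysis), indent=2, sort_keys=True) + "\n"
    )
    if records is not None:
        paths["lesions_csv"] = outdir / "lesion_summaries.csv"
        write_lesion_csv(paths["lesions_csv"], records)
    manifest = dict(manifest or {})
    manifest.setdefault("package", "frocdwi")
    manifest.setdefault("version", __version__)
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
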