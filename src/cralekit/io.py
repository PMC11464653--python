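"""File formats: NIfTI/DICOM volumes, CSV traces and panels, histology images.

Conventions:

- CT volumes and masks travel as NIfTI (``.nii``/``.nii.gz``) on a shared
  grid; voxel spacing comes from the affine, axis roles from the caller
  (array axes default to cranio-caudal, ventro-dorsal, left-right).
  A DICOM series folder is accepted and converted on read.
- Pressure traces are CSV with columns ``time_s, paw_cmh2o, pes_cmh2o``
  and optional ``pao_mmhg, pra_mmhg``; epoch annotations are a second CSV
  with ``label, start_s, end_s, kind``.
- Blood-gas panels are CSV, one row per timepoint, columns named after
  the standard symbols plus ``cardiac_output_l_min``.
- Histology label images are single-channel PNG/TIFF with a JSON legend
  mapping integer codes to class names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cralekit import ct as ctmod
from cralekit.mechanics import Epoch, PressureTrace
from cralekit.oxygen import BloodGasPanel
from cralekit.stereology import HistologyLabelImage
from cralekit.synthetic import CohortBundle

__all__ = [
    "export_cohort",
    "load_config",
    "load_dicom_series",
    "load_histology",
    "load_mask_nifti",
    "load_nifti",
    "load_panels_csv",
    "load_trace_csv",
    "save_histology",
    "save_nifti",
    "save_panels_csv",
    "save_trace_csv",
]


# ---------------------------------------------------------------- volumes

def save_nifti(ct: ctmod.CTVolume, path: str | Path) -> Path:
    """Write a CT volume (or any 3-D field) as NIfTI with spacing in the affine."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(ct.spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(ct.data, dtype=np.float32), affine)
    img.header.set_zooms(ct.spacing_mm)
    nib.save(img, path)
    return path


def load_nifti(
    path: str | Path, axis_roles: tuple[str, str, str] = ctmod.AXIS_ROLES
) -> ctmod.CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ctmod.CTVolume(data=data, spacing_mm=zooms, axis_roles=axis_roles)


def load_mask_nifti(path: str | Path, provenance: str = "file") -> ctmod.LungMask:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj) > 0.5
    return ctmod.LungMask(data=data, provenance=provenance)


def load_dicom_series(
    folder: str | Path, axis_roles: tuple[str, str, str] = ctmod.AXIS_ROLES
) -> ctmod.CTVolume:
    """Read a single-series DICOM folder into a CT volume.

    Slices are ordered by ImagePositionPatient (fallback InstanceNumber)
    and rescaled to HU with RescaleSlope/Intercept.  The slice-stacking
    axis becomes array axis 0.
    """
    import pydicom

    folder = Path(folder)
    files = sorted(p for p in folder.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM slices in {folder}")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    arrays = []
    for ds in slices:
        a = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(a * slope + intercept)
    vol = np.stack(arrays, axis=0)
    ps = getattr(slices[0], "PixelSpacing", [1.0, 1.0])
    if len(slices) > 1:
        z0, z1 = sort_key(slices[0]), sort_key(slices[1])
        dz = abs(z1 - z0) or float(getattr(slices[0], "SliceThickness", 1.0))
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    return ctmod.CTVolume(
        data=vol, spacing_mm=(dz, float(ps[0]), float(ps[1])), axis_roles=axis_roles
    )


# ----------------------------------------------------------------- traces

def save_trace_csv(
    trace: PressureTrace, path: str | Path, annotations_path: str | Path
) -> tuple[Path, Path]:
    path, apath = Path(path), Path(annotations_path)
    cols = {
        "time_s": trace.time_s,
        "paw_cmh2o": trace.paw,
        "pes_cmh2o": trace.pes,
    }
    if trace.pao is not None:
        cols["pao_mmhg"] = trace.pao
    if trace.pra is not None:
        cols["pra_mmhg"] = trace.pra
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")
    pd.DataFrame(
        [
            {"label": e.label, "start_s": e.start_s, "end_s": e.end_s, "kind": e.kind}
            for e in trace.epochs
        ]
    ).to_csv(apath, index=False)
    return path, apath


def load_trace_csv(path: str | Path, annotations_path: str | Path | None = None) -> PressureTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("trace needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace sampling is not uniform")
    epochs: tuple[Epoch, ...] = ()
    if annotations_path is not None:
        adf = pd.read_csv(annotations_path)
        epochs = tuple(
            Epoch(str(r.label), float(r.start_s), float(r.end_s), str(r.kind))
            for r in adf.itertuples()
        )
    return PressureTrace(
        fs_hz=1.0 / float(dt[0]),
        paw=df["paw_cmh2o"].to_numpy(),
        pes=df["pes_cmh2o"].to_numpy(),
        pao=df["pao_mmhg"].to_numpy() if "pao_mmhg" in df else None,
        pra=df["pra_mmhg"].to_numpy() if "pra_mmhg" in df else None,
        epochs=epochs,
    )


# ----------------------------------------------------------------- panels

_PANEL_COLUMNS = {
    "pao2_mmhg": "pao2_mmhg",
    "paco2_mmhg": "paco2_mmhg",
    "pvo2_mmhg": "pvo2_mmhg",
    "pvco2_mmhg": "pvco2_mmhg",
    "sao2": "sao2",
    "svo2": "svo2",
    "hb_g_dl": "hb_g_dl",
    "fio2": "fio2",
}


def save_panels_csv(
    panels: list[tuple[str, BloodGasPanel, float]], path: str | Path
) -> Path:
    path = Path(path)
    rows = []
    for label, p, co in panels:
        row = {"timepoint": label, "cardiac_output_l_min": co}
        for col in _PANEL_COLUMNS:
            row[col] = getattr(p, col)
        row["lactate_mmol_l"] = p.lactate_mmol_l
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def load_panels_csv(path: str | Path) -> list[tuple[str, BloodGasPanel, float]]:
    df = pd.read_csv(path)
    out = []
    for r in df.to_dict("records"):
        lact = r.get("lactate_mmol_l")
        panel = BloodGasPanel(
            **{col: float(r[col]) for col in _PANEL_COLUMNS},
            lactate_mmol_l=None if lact is None or pd.isna(lact) else float(lact),
            timepoint=str(r.get("timepoint", "")),
        )
        out.append((panel.timepoint, panel, float(r["cardiac_output_l_min"])))
    return out


# -------------------------------------------------------------- histology

def save_histology(
    image: HistologyLabelImage, path: str | Path, legend_path: str | Path
) -> tuple[Path, Path]:
    """Write a class map as single-channel PNG/TIFF plus a JSON legend."""
    path, lpath = Path(path), Path(legend_path)
    data = image.data.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)
    legend = {str(k): v for k, v in image.legend.items()}
    if image.pixel_size_um is not None:
        legend["_pixel_size_um"] = image.pixel_size_um
    lpath.write_text(json.dumps(legend, indent=1, sort_keys=True))
    return path, lpath


def load_histology(path: str | Path, legend_path: str | Path) -> HistologyLabelImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
    raw = json.loads(Path(legend_path).read_text())
    pixel_size = raw.pop("_pixel_size_um", None)
    legend = {int(k): str(v) for k, v in raw.items()}
    return HistologyLabelImage(
        data=np.asarray(data), legend=legend, pixel_size_um=pixel_size
    )


# ----------------------------------------------------------------- config

def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON pipeline config."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def export_cohort(bundle: CohortBundle, out_dir: str | Path) -> Path:
    """Write a synthetic cohort to disk in the pipeline's file formats.

    Produces per-animal NIfTI volumes/masks, trace + annotation CSVs,
    blood-gas panel CSVs, histology PNG + legend, truth JSON sidecars,
    and a ``config.json`` that :func:`cralekit.pipeline.run_pipeline`
    consumes directly.  Returns the config path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = []
    for a in bundle.animals:
        d = out / a.subject_id
        d.mkdir(exist_ok=True)
        sub = {"id": a.subject_id, "vt_ml": a.vt_ml}
        for tp, ctv, msk, truth in (
            ("baseline", a.baseline_ct, a.baseline_mask, a.baseline_truth),
            ("post", a.post_ct, a.post_mask, a.post_truth),
        ):
            save_nifti(ctv, d / f"ct_{tp}.nii.gz")
            mask_vol = ctmod.CTVolume(
                data=msk.data.astype(np.float32), spacing_mm=ctv.spacing_mm
            )
            save_nifti(mask_vol, d / f"mask_{tp}.nii.gz")
            (d / f"truth_{tp}.json").write_text(json.dumps(truth.as_dict(), indent=1))
            sub[f"ct_{tp}"] = f"{a.subject_id}/ct_{tp}.nii.gz"
            sub[f"mask_{tp}"] = f"{a.subject_id}/mask_{tp}.nii.gz"
        save_trace_csv(a.cc_trace, d / "cc_trace.csv", d / "cc_annotations.csv")
        sub["cc_trace"] = f"{a.subject_id}/cc_trace.csv"
        sub["cc_annotations"] = f"{a.subject_id}/cc_annotations.csv"
        for tp, tr in (
            ("baseline", a.baseline_occl_trace),
            ("post", a.post_occl_trace),
        ):
            save_trace_csv(
                tr, d / f"occl_{tp}.csv", d / f"occl_{tp}_annotations.csv"
            )
            sub[f"occlusion_trace_{tp}"] = f"{a.subject_id}/occl_{tp}.csv"
            sub[f"occlusion_annotations_{tp}"] = (
                f"{a.subject_id}/occl_{tp}_annotations.csv"
            )
        save_panels_csv(
            [(label, p, co) for label, p, co, _t in a.gas_panels],
            d / "gas_panels.csv",
        )
        sub["gas_panels"] = f"{a.subject_id}/gas_panels.csv"
        save_histology(a.histology, d / "histology.png", d / "histology_legend.json")
        sub["histology"] = f"{a.subject_id}/histology.png"
        sub["histology_legend"] = f"{a.subject_id}/histology_legend.json"
        sub["ex_vivo_weight_g"] = a.ex_vivo_weight_g
        sub["body_weight_kg"] = a.body_weight_kg
        sub["wet_mass_g"] = a.wet_mass_g
        sub["dry_mass_g"] = a.dry_mass_g
        subjects.append(sub)
    config = {"root": str(out), "subjects": subjects, "seed": bundle.seed}
    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps(config, indent=1, sort_keys=True))
    return cfg_path
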