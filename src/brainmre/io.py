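"""File I/O: NIfTI volumes for image-like data, CSV for tables.

Conventions: image-like arrays travel as uncompressed NIfTI (spatial
units mm in the affine) with a JSON sidecar carrying exact metadata
(period, frequencies, spacing in meters, demodulation convention), so
write-then-read round-trips are lossless.  Cohort tables are CSV with a
fixed schema; units in tables are the printed clinical units (kPa,
dm^3), while all in-memory computation uses SI (Pa, m, s).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from brainmre.inversion import ComplexModulusMap, DispersionSample
from brainmre.springpot import SpringpotFit
from brainmre.synthetic import WaveFieldSeries
from brainmre.wave_processing import ComplexWaveField

COHORT_COLUMNS = (
    "subject_id",
    "group",
    "sex",
    "age",
    "edss",
    "duration_y",
    "volume_dm3",
    "bpf",
    "mu_kpa",
    "alpha",
)


def _affine(spacing_m: float) -> np.ndarray:
    mm = spacing_m * 1000.0
    return np.diag([mm, mm, 1.0, 1.0])


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json") if path.suffix == ".nii" else Path(
        str(path) + ".json"
    )


def write_wavefield(series: WaveFieldSeries, path: str | Path) -> Path:
    """Write a wave series as NIfTI (x, y, t) plus mask NIfTI and JSON sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(series.data.astype(np.float64), _affine(series.spacing)), path)
    mask_path = path.with_name(path.stem + "_mask.nii")
    nib.save(nib.Nifti1Image(series.mask.astype(np.uint8), _affine(series.spacing)), mask_path)
    meta = {
        "spacing_m": series.spacing,
        "period_s": series.period,
        "frequencies_hz": list(series.frequencies),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_wavefield(path: str | Path) -> WaveFieldSeries:
    """Read a wave series written by :func:`write_wavefield`.

    Rejects volumes with non-uniform in-plane pixel spacing (the
    inversion stencil assumes an isotropic in-plane grid).
    """
    path = Path(path)
    img = nib.load(path)
    zooms = img.header.get_zooms()[:2]
    if abs(zooms[0] - zooms[1]) > 1e-9 * max(zooms):
        raise ValueError(
            f"non-uniform in-plane pixel spacing {zooms}; an isotropic grid is required"
        )
    mask_img = nib.load(path.with_name(path.stem + "_mask.nii"))
    meta = json.loads(_sidecar_path(path).read_text())
    return WaveFieldSeries(
        data=np.asarray(img.dataobj, dtype=np.float64),
        mask=np.asarray(mask_img.dataobj).astype(bool),
        spacing=float(meta["spacing_m"]),
        period=float(meta["period_s"]),
        frequencies=tuple(meta["frequencies_hz"]),
    )


def write_complex_field(field: ComplexWaveField, stem: str | Path) -> tuple[Path, Path]:
    """Write a complex wave image as paired real/imaginary NIfTI + sidecar."""
    stem = Path(stem)
    real_path = stem.with_name(stem.name + "_real.nii")
    imag_path = stem.with_name(stem.name + "_imag.nii")
    aff = _affine(field.spacing)
    nib.save(nib.Nifti1Image(field.data.real.astype(np.float64), aff), real_path)
    nib.save(nib.Nifti1Image(field.data.imag.astype(np.float64), aff), imag_path)
    mask_path = stem.with_name(stem.name + "_mask.nii")
    nib.save(nib.Nifti1Image(field.mask.astype(np.uint8), aff), mask_path)
    meta = {
        "frequency_hz": field.frequency,
        "spacing_m": field.spacing,
        "convention": field.convention,
    }
    stem.with_name(stem.name + ".json").write_text(json.dumps(meta, indent=2))
    return real_path, imag_path


def read_complex_field(stem: str | Path) -> ComplexWaveField:
    stem = Path(stem)
    real = np.asarray(nib.load(stem.with_name(stem.name + "_real.nii")).dataobj)
    imag = np.asarray(nib.load(stem.with_name(stem.name + "_imag.nii")).dataobj)
    mask = np.asarray(nib.load(stem.with_name(stem.name + "_mask.nii")).dataobj).astype(bool)
    meta = json.loads(stem.with_name(stem.name + ".json").read_text())
    return ComplexWaveField(
        data=real + 1j * imag,
        frequency=float(meta["frequency_hz"]),
        spacing=float(meta["spacing_m"]),
        mask=mask,
        convention=str(meta["convention"]),
    )


def write_modulus_map(mmap: ComplexModulusMap, stem: str | Path, spacing: float) -> None:
    """Persist a modulus map as paired real/imaginary NIfTI plus validity mask."""
    stem = Path(stem)
    aff = _affine(spacing)
    nib.save(nib.Nifti1Image(mmap.data.real.astype(np.float64), aff), stem.with_name(stem.name + "_real.nii"))
    nib.save(nib.Nifti1Image(mmap.data.imag.astype(np.float64), aff), stem.with_name(stem.name + "_imag.nii"))
    nib.save(nib.Nifti1Image(mmap.valid.astype(np.uint8), aff), stem.with_name(stem.name + "_valid.nii"))
    stem.with_name(stem.name + ".json").write_text(
        json.dumps({"frequency_hz": mmap.frequency, "spacing_m": spacing}, indent=2)
    )


def write_dispersion(samples: list[DispersionSample], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "frequency_hz": [s.frequency for s in samples],
            "g_real_pa": [s.g_star.real for s in samples],
            "g_imag_pa": [s.g_star.imag for s in samples],
            "n_pixels": [s.n_pixels for s in samples],
        }
    ).to_csv(path, index=False)
    return path


def read_dispersion(path: str | Path) -> list[DispersionSample]:
    df = pd.read_csv(path)
    return [
        DispersionSample(
            frequency=float(r.frequency_hz),
            g_star=complex(r.g_real_pa, r.g_imag_pa),
            n_pixels=int(r.n_pixels),
        )
        for r in df.itertuples()
    ]


def write_fit(fit: SpringpotFit, path: str | Path, subject_id: str = "S000") -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "subject_id": subject_id,
                "mu_pa": fit.mu,
                "alpha": fit.alpha,
                "kappa": fit.kappa,
                "eta": fit.eta,
                "residual": fit.residual,
                "n_freqs": fit.n_freqs,
            }
        ]
    ).to_csv(path, index=False)
    return path


def write_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {missing}")
    table.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; schema violations are named per field."""
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort CSV missing column(s): {missing}")
    problems = []
    if not table["group"].isin(["patient", "control"]).all():
        problems.append("group: labels must be 'patient' or 'control'")
    if not ((table["bpf"] > 0) & (table["bpf"] <= 1)).all():
        problems.append("bpf: must lie in (0, 1]")
    if not (table["volume_dm3"] > 0).all():
        problems.append("volume_dm3: must be positive")
    edss = table["edss"].dropna()
    if not ((edss >= 0) & (edss <= 10)).all():
        problems.append("edss: must lie in [0, 10]")
    if problems:
        raise ValueError("cohort CSV schema violations: " + "; ".join(problems))
    return table
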