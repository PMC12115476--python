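"""Spectrum and dataset I/O: two-column CSV, sidecar JSON metadata,
dataset directories with a YAML manifest, and stable numeric JSON.

Numbers are serialized with 12 significant digits for cross-platform
byte stability.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .absorber import Spectrum
from .pca import SpectraDataset
from .permittivity import MixtureSpec

__all__ = [
    "write_spectrum_csv", "read_spectrum_csv",
    "write_dataset", "read_dataset",
    "round_sig", "dump_json",
]

_SIG = 12


def round_sig(obj):
    """Recursively round floats to 12 significant digits for stable output."""
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.{_SIG}g}")
    if isinstance(obj, (int, np.integer, str)) or obj is None:
        return obj if not isinstance(obj, np.integer) else int(obj)
    if isinstance(obj, np.ndarray):
        return [round_sig(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): round_sig(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_sig(v) for v in obj]
    return obj


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(round_sig(obj), indent=2) + "\n")


def _meta_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.json")


def write_spectrum_csv(spectrum: Spectrum, path) -> Path:
    """Write a spectrum as `wavelength_nm,absorption` CSV + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"wavelength_nm": spectrum.wavelength_nm,
                       "absorption": spectrum.absorption})
    df.to_csv(path, index=False, float_format=f"%.{_SIG}g")
    if spectrum.metadata:
        dump_json(spectrum.metadata, _meta_path(path))
    return path


def read_spectrum_csv(path) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["wavelength_nm", "absorption"]:
        raise ValueError(
            f"{path}: expected columns 'wavelength_nm,absorption', got {list(df.columns)}")
    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
    return Spectrum(df["wavelength_nm"].to_numpy(),
                    df["absorption"].to_numpy(), meta)


def write_dataset(dataset: SpectraDataset, directory) -> Path:
    """Write each condition as a CSV plus a manifest.yaml tying them together."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (label, mix) in enumerate(zip(dataset.labels, dataset.mixtures)):
        fname = f"spectrum_{i:02d}_{label.replace(':', '-')}.csv"
        sp = (dataset.spectra[i] if dataset.spectra
              else Spectrum(dataset.grid_nm, dataset.X[i], {"label": label}))
        write_spectrum_csv(sp, directory / fname)
        entries.append({
            "file": fname, "label": label,
            "lipid_fraction": round_sig(mix.lipid_fraction),
            "total_amount": round_sig(mix.total_amount),
        })
    manifest = {
        "grid": {"start_nm": round_sig(float(dataset.grid_nm[0])),
                 "stop_nm": round_sig(float(dataset.grid_nm[-1])),
                 "points": int(dataset.grid_nm.size)},
        "spectra": entries,
    }
    (directory / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=False))
    return directory


def read_dataset(directory) -> SpectraDataset:
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    labels, mixtures, spectra, rows = [], [], [], []
    grid = None
    for entry in manifest["spectra"]:
        sp = read_spectrum_csv(directory / entry["file"])
        labels.append(entry["label"])
        mixtures.append(MixtureSpec(entry["lipid_fraction"], entry["total_amount"]))
        spectra.append(sp)
        rows.append(sp.absorption)
        grid = sp.wavelength_nm
    return SpectraDataset(np.array(rows), labels, mixtures, grid, spectra)
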