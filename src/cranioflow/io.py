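"""File formats: NIfTI cine series and masks, JSON sidecars, YAML configs.

A cine series is stored as a 4-D NIfTI volume with the cardiac phase on
the 4th axis and a JSON sidecar carrying the acquisition parameters
(keys: venc_cm_s, n_phases, pixel_area_cm2, cycle_duration_s,
noise_sd). Masks are integer-labelled NIfTI volumes whose label-to-
vessel-class mapping lives in their sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple

import nibabel as nib
import numpy as np
import yaml

from .core import AcquisitionParams, LumenMask, VelocityCine
from .errors import ConfigurationError


def _affine(params: AcquisitionParams) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = params.pixel_spacing * 10.0  # cm -> mm
    return aff


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_cine(cine: VelocityCine, path) -> Path:
    """Write velocity (and magnitude) cine as NIfTI + JSON sidecar."""
    path = Path(path)
    # nibabel expects spatial axes first: (x, y, t, component)
    data = np.stack([cine.velocity, cine.magnitude], axis=-1)
    data = np.moveaxis(data, 0, 2)  # (row, col, phase, component)
    nib.save(nib.Nifti1Image(data.astype(np.float64), _affine(cine.params)), path)
    sidecar = cine.params.to_sidecar()
    sidecar["name"] = cine.name
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_cine(path) -> VelocityCine:
    """Read a cine series written by :func:`write_cine`."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"cine file not found: {path}")
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise ConfigurationError(f"sidecar not found: {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    params = AcquisitionParams.from_sidecar(sidecar)
    data = np.asarray(nib.load(path).dataobj, dtype=float)
    data = np.moveaxis(data, 2, 0)  # back to (phase, row, col, component)
    return VelocityCine(velocity=data[..., 0], magnitude=data[..., 1],
                        params=params, name=sidecar.get("name", path.stem))


def write_masks(masks: Dict[str, LumenMask], params: AcquisitionParams,
                path) -> Path:
    """Write labelled masks as one integer NIfTI + label mapping sidecar."""
    path = Path(path)
    labels = sorted(masks)
    first = masks[labels[0]].mask
    arr = np.zeros(first.shape, dtype=np.int16)
    mapping = {}
    for i, label in enumerate(labels, start=1):
        arr[masks[label].mask] = i
        mapping[str(i)] = label
    nib.save(nib.Nifti1Image(arr, _affine(params)), path)
    _sidecar_path(path).write_text(json.dumps({"labels": mapping}, indent=2))
    return path


def read_masks(path) -> Dict[str, LumenMask]:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"mask file not found: {path}")
    mapping = json.loads(_sidecar_path(path).read_text())["labels"]
    arr = np.asarray(nib.load(path).dataobj)
    return {label: LumenMask(label, arr == int(i), source_cine=str(path))
            for i, label in mapping.items()}


def load_yaml_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh)
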