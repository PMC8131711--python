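"""Volume and table I/O.

Volumes are written as NIfTI with an identity-orientation affine at 2 mm
isotropic spacing (the functional resolution; purely for viewer
compatibility — the pipeline works in 0-based voxel indices).  Tables are
TSV; a leading ``#``-comment line carries the seed and config digest so
outputs are self-identifying while remaining byte-reproducible.  The string
"none" (a missing recognition report) is preserved as a level, never parsed
as missing data.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

_AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])


def save_nifti(data: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _AFFINE)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_tsv(
    df: pd.DataFrame, path: str | Path, *, seed: int | None = None, digest: str | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None or digest is not None:
            fh.write(f"# seed={seed} digest={digest}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline TSV; 'none' stays a string level, not NaN."""
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, na_values=[""])


def save_masks(masks: dict[str, np.ndarray], classes: dict[str, str], dirpath: str | Path) -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    for name, mask in masks.items():
        save_nifti(mask.astype(np.float64), dirpath / f"{name}.nii")
    with open(dirpath / "classes.json", "w") as fh:
        json.dump(classes, fh, indent=1, sort_keys=True)


def load_masks(dirpath: str | Path) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    dirpath = Path(dirpath)
    with open(dirpath / "classes.json") as fh:
        classes = json.load(fh)
    masks = {}
    for name in classes:
        p = dirpath / f"{name}.nii"
        if not p.exists():
            raise FileNotFoundError(f"mask/label mismatch: no volume for ROI {name!r}")
        masks[name] = load_nifti(p) > 0.5
    return masks, classes
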