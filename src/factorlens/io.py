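"""Format plumbing: NIfTI volumes, factor-matrix TSVs, model JSON."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


def save_volume(array: np.ndarray, path) -> None:
    import nibabel as nib
    nib.Nifti1Image(np.asarray(array, dtype=np.float64), np.eye(4)).to_filename(str(path))


def load_volume(path) -> np.ndarray:
    import nibabel as nib
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_matrix(matrix: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(matrix)).to_csv(path, sep="\t", index=False, header=False)


def load_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)


def save_model(network, path) -> None:
    with open(path, "w") as fh:
        json.dump(network.to_dict(), fh)


def load_model(path):
    from .network import EqlNetwork
    with open(path) as fh:
        return EqlNetwork.from_dict(json.load(fh))


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
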