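"""HDF5 persistence for trained models, labelings and configs."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np

from .core import CRBAConfig
from .inference import NeuronLabeling

__all__ = ["save_model", "load_model", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def save_model(path: str | Path, W: np.ndarray, theta: np.ndarray,
               config: CRBAConfig, labeling: NeuronLabeling | None = None) -> None:
    """Write model state to an HDF5 container (bitwise round-trippable)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["config_json"] = json.dumps(config.to_dict())
        f.create_dataset("W", data=np.asarray(W, dtype=float))
        f.create_dataset("theta", data=np.asarray(theta, dtype=float))
        if labeling is not None:
            g = f.create_group("labeling")
            g.create_dataset("labels", data=labeling.labels)
            g.create_dataset("activity", data=labeling.activity)
            g.create_dataset("classes", data=labeling.classes)


def load_model(path: str | Path):
    """Load (W, theta, config, labeling-or-None) from an HDF5 container.

    A missing labeling group is allowed (model trained but not yet
    labeled) and flagged with a warning.
    """
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version} "
                             f"(expected {FORMAT_VERSION})")
        config = CRBAConfig.from_dict(json.loads(f.attrs["config_json"]))
        W = f["W"][()]
        theta = f["theta"][()]
        labeling = None
        if "labeling" in f:
            g = f["labeling"]
            labeling = NeuronLabeling(labels=g["labels"][()],
                                      activity=g["activity"][()],
                                      classes=g["classes"][()])
        else:
            warnings.warn("model file has no labeling; label before predicting")
    return W, theta, config, labeling
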