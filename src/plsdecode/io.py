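"""Serialization: fitted models (JSON + npz), NIfTI volumes/masks, events TSV."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .decoding import FeatureMask, PLSTaskClassifier, TrainedClassifier
from .pls import PLSRegressor
from .sparse import SparsePLSRegressor

__all__ = [
    "save_pls_model",
    "load_pls_model",
    "save_classifier",
    "load_classifier",
    "mask_to_tsv",
    "mask_from_tsv",
    "run_to_nifti",
    "run_from_nifti",
    "mask_to_nifti",
    "write_events",
    "read_events",
]

_ARRAY_FIELDS = (
    "x_weights_", "directions_", "scores_", "x_loadings_", "y_loadings_",
    "coef_", "x_mean_", "y_mean_", "_Xc_T_T", "_Yc_T_T", "_tt",
)


def save_pls_model(model: PLSRegressor, path):
    """Write a fitted PLS(/sparse) model as ``<path>.json`` + ``<path>.npz``."""
    path = Path(path)
    meta = {
        "class": type(model).__name__,
        "params": {k: v for k, v in model.get_params().items()},
        "n_components_": int(model.n_components_),
    }
    arrays = {f: getattr(model, f) for f in _ARRAY_FIELDS}
    if isinstance(model, SparsePLSRegressor):
        meta["support_"] = [s.tolist() for s in model.support_]
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    np.savez(path.with_suffix(".npz"), **arrays)


def load_pls_model(path) -> PLSRegressor:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cls = {"PLSRegressor": PLSRegressor, "SparsePLSRegressor": SparsePLSRegressor}[
        meta["class"]
    ]
    model = cls(**meta["params"])
    with np.load(path.with_suffix(".npz")) as z:
        for f in _ARRAY_FIELDS:
            setattr(model, f, z[f])
    model.n_components_ = meta["n_components_"]
    if "support_" in meta:
        model.support_ = [np.asarray(s, dtype=int) for s in meta["support_"]]
    return model


def save_classifier(clf: TrainedClassifier, path):
    """Write a trained masked classifier: JSON metadata + npz arrays."""
    path = Path(path)
    save_pls_model(clf.model.pls_, path.parent / (path.stem + "_pls"))
    meta = {
        "task_names": clf.task_names,
        "classes": clf.model.classes_.tolist(),
        "clf_params": clf.model.get_params(),
        "n_components_": int(clf.model.n_components_),
        "mask": {
            "voxel_indices": clf.mask.voxel_indices.tolist(),
            "per_task_sources": {
                str(k): v.tolist() for k, v in clf.mask.per_task_sources.items()
            },
            "selector_name": clf.mask.selector_name,
            "threshold_used": clf.mask.threshold_used,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_classifier(path) -> TrainedClassifier:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    pls = load_pls_model(path.parent / (path.stem + "_pls"))
    clf = PLSTaskClassifier(**meta["clf_params"])
    clf.classes_ = np.asarray(meta["classes"])
    clf.pls_ = pls
    clf.n_components_ = meta["n_components_"]
    clf.tie_count_ = 0
    m = meta["mask"]
    mask = FeatureMask(
        voxel_indices=np.asarray(m["voxel_indices"], dtype=int),
        per_task_sources={
            int(k): np.asarray(v, dtype=int)
            for k, v in m["per_task_sources"].items()
        },
        selector_name=m["selector_name"],
        threshold_used=m["threshold_used"],
    )
    return TrainedClassifier(model=clf, mask=mask, task_names=meta["task_names"])


def mask_to_tsv(mask: FeatureMask, path):
    rows = []
    for task, idx in mask.per_task_sources.items():
        for i in idx:
            rows.append({"voxel_index": int(i), "task": task})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def mask_from_tsv(path, selector_name: str = "", threshold: float = float("nan")):
    df = pd.read_csv(path, sep="\t")
    per_task = {
        int(t): g["voxel_index"].to_numpy()
        for t, g in df.groupby("task")
    }
    union = np.unique(df["voxel_index"].to_numpy())
    return FeatureMask(
        voxel_indices=union, per_task_sources=per_task,
        selector_name=selector_name, threshold_used=threshold,
    )


def run_to_nifti(data: np.ndarray, path, tr: float = 2.0):
    """(n, H, W) run -> 4-D NIfTI with shape (H, W, 1, n)."""
    data = np.asarray(data)
    img_data = np.transpose(data, (1, 2, 0))[:, :, None, :]
    img = nib.Nifti1Image(img_data.astype(np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, tr))
    nib.save(img, str(path))


def run_from_nifti(path) -> np.ndarray:
    """4-D NIfTI -> (n, H*W...) compatible (n, H, W) array (single slice)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI time series")
    h, w, d, n = data.shape
    if d == 1:
        return np.transpose(data[:, :, 0, :], (2, 0, 1))
    return np.transpose(data.reshape(h, w * d, n), (2, 0, 1))


def mask_to_nifti(mask_2d: np.ndarray, path):
    img = nib.Nifti1Image(
        np.asarray(mask_2d, dtype=np.uint8)[:, :, None], affine=np.eye(4)
    )
    nib.save(img, str(path))


def write_events(paradigm, path):
    paradigm.to_events().to_csv(path, sep="\t", index=False)


def read_events(path, tr: float = 2.0):
    from .simulator import REST, Paradigm

    df = pd.read_csv(path, sep="\t").sort_values("onset")
    blocks = []
    for _, row in df.iterrows():
        tt = str(row["trial_type"])
        label = REST if tt == "rest" else int(tt.removeprefix("task"))
        blocks.append((label, float(row["duration"])))
    return Paradigm(tr=tr, blocks=blocks)
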