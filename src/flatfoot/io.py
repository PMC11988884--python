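"""Readers and writers: image datasets, feature tables, model archives.

Dataset layout (one directory per class, filenames encoding the patient):

    root/
      pes_planus/P0001_0.png  P0001_1.png ...
      not_pes_planus/P0040_0.png ...
      manifest.csv            # optional: path,patient_id,angle,label

Patient ids are parsed from the ``<patientID>_<index>.<ext>`` filename
pattern; a ``manifest.csv`` at the root takes precedence. Files that
match neither fall back to one patient per file with a warning.

Model archives are single ``.npz`` files holding every array plus a JSON
metadata entry (format version, class order, configs, content checksum);
loading verifies the checksum and the version tag, and round-trips are
exact.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from . import backbone as bb
from . import elm
from .exceptions import (ChecksumError, InvalidDatasetError,
                         UnsupportedVersionError)
from .samples import CLASSES, ImageSample

log = logging.getLogger("flatfoot")

FILENAME_RE = re.compile(r"^(?P<pid>.+)_(?P<idx>\d+)\.(?:jpg|jpeg|png)$",
                         re.IGNORECASE)
MODEL_FORMAT_VERSION = "flatfoot-model-1"


# ---------------------------------------------------------------------------
# image datasets


def write_image_dataset(samples, root) -> Path:
    """Write class-per-folder PNGs plus a ``manifest.csv``."""
    root = Path(root)
    rows = []
    counters: dict[str, int] = {}
    for s in samples:
        idx = s.meta.get("image_index")
        if idx is None:
            idx = counters.get(s.patient_id, 0)
            counters[s.patient_id] = idx + 1
        rel = Path(s.label) / f"{s.patient_id}_{idx}.png"
        path = root / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        pix = np.asarray(s.pixels)
        if pix.ndim == 3 and pix.shape[2] == 1:
            pix = pix[:, :, 0]
        Image.fromarray(np.round(pix * 255).astype(np.uint8)).save(path)
        rows.append({"path": str(rel), "patient_id": s.patient_id,
                     "angle": s.meta.get("angle", ""), "label": s.label})
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)
    return root


def read_image_dataset(root) -> list[ImageSample]:
    """Read every decodable JPG/PNG under class subdirectories.

    Labels come from the directory names; patient ids from the manifest
    when present, else from the filename pattern, else one patient per
    file (with a warning). Undecodable files are skipped with a warning.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir()) \
        if root.is_dir() else []
    if not class_dirs:
        raise InvalidDatasetError(f"no class directories under {root}")
    manifest = {}
    mpath = root / "manifest.csv"
    if mpath.exists():
        df = pd.read_csv(mpath, dtype={"patient_id": str})
        manifest = {str(Path(r["path"])): r for _, r in df.iterrows()}
    samples = []
    for cdir in class_dirs:
        label = cdir.name
        for f in sorted(cdir.iterdir()):
            if f.suffix.lower() not in (".jpg", ".jpeg", ".png"):
                continue
            try:
                with Image.open(f) as im:
                    arr = np.asarray(im.convert("L") if im.mode not in
                                     ("RGB", "L") else im)
            except (UnidentifiedImageError, OSError):
                warnings.warn(f"skipping undecodable image {f}")
                continue
            rel = str(Path(label) / f.name)
            meta: dict = {"path": str(f)}
            if rel in manifest:
                pid = str(manifest[rel]["patient_id"])
                if "angle" in manifest[rel] and manifest[rel]["angle"] != "":
                    meta["angle"] = float(manifest[rel]["angle"])
            else:
                m = FILENAME_RE.match(f.name)
                if m:
                    pid = m.group("pid")
                else:
                    warnings.warn(
                        f"{f.name} does not match <patient>_<index>; "
                        "treating as its own patient")
                    pid = f.stem
            samples.append(ImageSample(pixels=arr.astype(np.float64) / 255.0,
                                       label=label, patient_id=pid, meta=meta))
    if not samples:
        raise InvalidDatasetError(f"no readable images under {root}")
    return samples


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(path, features: np.ndarray, labels, patients) -> None:
    """CSV with columns ``f0..f{d-1}, label, patient_id``."""
    df = pd.DataFrame(features,
                      columns=[f"f{i}" for i in range(features.shape[1])])
    df["label"] = list(labels)
    df["patient_id"] = list(patients)
    df.to_csv(path, index=False)


def read_feature_table(path):
    """Inverse of :func:`write_feature_table`; returns (X, labels, patients)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    fcols.sort(key=lambda c: int(c[1:]))
    return (df[fcols].to_numpy(dtype=np.float64), list(df["label"]),
            list(df["patient_id"]))


# ---------------------------------------------------------------------------
# model archive


@dataclasses.dataclass
class ModelBundle:
    """Everything needed to score new inputs: head, and optionally backbone."""

    hidden: elm.HiddenLayer
    beta: np.ndarray
    classes: tuple[str, ...] = CLASSES
    oelm_config: elm.OELMConfig | None = None
    backbone_config: bb.BackboneConfig | None = None
    backbone_weights: bb.BackboneWeights | None = None
    #: per-feature standardization fitted on the training set
    feat_mean: np.ndarray | None = None
    feat_std: np.ndarray | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.feat_mean is None:
            return X
        return (X - self.feat_mean) / self.feat_std

    def predict_features(self, X: np.ndarray):
        return elm.predict(self.transform(np.atleast_2d(X)), self.hidden,
                           self.beta, self.classes)

    def predict_images(self, samples):
        if self.backbone_weights is None:
            raise InvalidDatasetError("bundle has no backbone; expects features")
        cfg = self.backbone_config
        prepped = [bb.preprocess(s.pixels, cfg) for s in samples]
        X = bb.extract_features(prepped, self.backbone_weights, cfg)
        return self.predict_features(X)


def _content_hash(arrays: dict[str, np.ndarray], meta: dict) -> str:
    h = hashlib.sha256()
    for name in sorted(arrays):
        h.update(name.encode())
        a = np.ascontiguousarray(arrays[name])
        h.update(str(a.dtype).encode())
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    h.update(json.dumps(meta, sort_keys=True).encode())
    return h.hexdigest()


def save_model(path, bundle: ModelBundle) -> str:
    """Write the bundle as one ``.npz``; returns the content hash."""
    arrays: dict[str, np.ndarray] = {"beta": np.asarray(bundle.beta)}
    if bundle.hidden.W is not None:
        arrays["hidden/W"] = np.asarray(bundle.hidden.W)
        arrays["hidden/b"] = np.asarray(bundle.hidden.b)
    if bundle.feat_mean is not None:
        arrays["feat/mean"] = np.asarray(bundle.feat_mean)
        arrays["feat/std"] = np.asarray(bundle.feat_std)
    if bundle.backbone_weights is not None:
        for k, v in bb.weights_to_named_arrays(bundle.backbone_weights).items():
            arrays[f"backbone/{k}"] = v
    meta = {
        "format": MODEL_FORMAT_VERSION,
        "classes": list(bundle.classes),
        "hidden": {"activation": bundle.hidden.activation,
                   "seed": bundle.hidden.seed,
                   "input_dim": bundle.hidden.input_dim,
                   "L": bundle.hidden.L},
        "oelm_config": dataclasses.asdict(bundle.oelm_config)
        if bundle.oelm_config else None,
        "backbone_config": dataclasses.asdict(bundle.backbone_config)
        if bundle.backbone_config else None,
    }
    meta["checksum"] = _content_hash(arrays, {k: v for k, v in meta.items()
                                              if k != "checksum"})
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8), **arrays)
    return meta["checksum"]


def load_model(path) -> ModelBundle:
    """Inverse of :func:`save_model`; verifies version tag and checksum."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    if meta.get("format") != MODEL_FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"unsupported model format {meta.get('format')!r}")
    expect = meta.pop("checksum", None)
    if _content_hash(arrays, meta) != expect:
        raise ChecksumError(f"model archive {path} failed its checksum")
    hmeta = meta["hidden"]
    W = arrays.get("hidden/W")
    b = arrays.get("hidden/b")
    if W is not None:
        W.setflags(write=False)
        b.setflags(write=False)
    hidden = elm.HiddenLayer(W=W, b=b, activation=hmeta["activation"],
                             seed=hmeta["seed"], input_dim=hmeta["input_dim"])
    oelm_cfg = (elm.OELMConfig(**meta["oelm_config"])
                if meta["oelm_config"] else None)
    bb_cfg = bb_weights = None
    if meta["backbone_config"]:
        cfgdict = dict(meta["backbone_config"])
        cfgdict["normalize_mean"] = float(cfgdict["normalize_mean"])
        bb_cfg = bb.BackboneConfig(**cfgdict)
        named = {k[len("backbone/"):]: v for k, v in arrays.items()
                 if k.startswith("backbone/")}
        bb_weights = bb.weights_from_named_arrays(named, bb_cfg)
    return ModelBundle(
        hidden=hidden, beta=arrays["beta"],
        classes=tuple(meta["classes"]), oelm_config=oelm_cfg,
        backbone_config=bb_cfg, backbone_weights=bb_weights,
        feat_mean=arrays.get("feat/mean"), feat_std=arrays.get("feat/std"))


def model_content_hash(path) -> str:
    """Recompute the canonical content hash of a saved archive."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    meta.pop("checksum", None)
    return _content_hash(arrays, meta)
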