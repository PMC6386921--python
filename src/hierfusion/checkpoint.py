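"""Single-file model checkpoints and recognizer-bundle directories.

A checkpoint is one ``.npz`` archive holding the layer parameters,
normalization statistics, training config, and (for recognizer bundles)
the hierarchy fingerprint, so a trained model round-trips exactly. A bundle
directory holds ``motion.npz``, one ``group_<i>.npz`` per multi-activity
group, the hierarchy config, and a ``bundle.json`` manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .classifiers import (
    ConvExtractor,
    GroupFrameClassifier,
    GroupSequenceClassifier,
    MotionStateClassifier,
    PassthroughExtractor,
    TrainConfig,
)
from .fusion import RecognizerBundle
from .hierarchy import Correspondence, load_hierarchy_file

__all__ = ["save_model", "load_model", "save_bundle", "load_bundle"]


def _extractor_meta(extractor) -> dict:
    if isinstance(extractor, PassthroughExtractor):
        return {"type": "passthrough", "dim": extractor.n_channels}
    if isinstance(extractor, ConvExtractor):
        return {"type": "conv", "n_channels": extractor.n_channels}
    raise TypeError(f"cannot serialize extractor {type(extractor).__name__}")


def _rebuild_extractor(meta: dict, arrays: dict):
    if meta["type"] == "passthrough":
        return PassthroughExtractor(meta["dim"])
    ext = ConvExtractor(
        in_channels=arrays["ext_filters1"].shape[3],
        n_channels=meta["n_channels"],
    )
    ext.filters1 = arrays["ext_filters1"]
    ext.filters2 = arrays["ext_filters2"]
    return ext


def save_model(model, path) -> None:
    arrays: dict[str, np.ndarray] = {}
    meta: dict = {"config": model.config.to_dict(), "metadata": model.metadata}
    if isinstance(model, MotionStateClassifier):
        meta["kind"] = "motion"
        meta["classes"] = list(model.classes)
        meta["input_length"] = model.input_length
        layers = {"lstm": model.lstm, "head": model.head}
    elif isinstance(model, GroupFrameClassifier):
        meta["kind"] = "frame"
        meta["classes"] = list(model.group)
        meta["extractor"] = _extractor_meta(model.extractor)
        layers = {"head": model.head}
    elif isinstance(model, GroupSequenceClassifier):
        meta["kind"] = "sequence"
        meta["classes"] = list(model.group)
        meta["extractor"] = _extractor_meta(model.extractor)
        layers = {"lstm": model.lstm, "fc": model.fc, "head": model.head}
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    for lname, layer in layers.items():
        for pname, arr in layer.params.items():
            arrays[f"{lname}__{pname}"] = arr
    if isinstance(getattr(model, "extractor", None), ConvExtractor):
        arrays["ext_filters1"] = model.extractor.filters1
        arrays["ext_filters2"] = model.extractor.filters2
    arrays["norm_mean"] = model.norm_mean
    arrays["norm_sd"] = model.norm_sd
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_model(path):
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(bytes(arrays.pop("meta")).decode())
    config = TrainConfig(**meta["config"])
    kind = meta["kind"]
    if kind == "motion":
        model = MotionStateClassifier(meta["classes"], config)
        model.input_length = meta["input_length"]
        layers = {"lstm": model.lstm, "head": model.head}
    else:
        extractor = _rebuild_extractor(meta["extractor"], arrays)
        if kind == "frame":
            model = GroupFrameClassifier(meta["classes"], extractor, config)
            layers = {"head": model.head}
        else:
            model = GroupSequenceClassifier(meta["classes"], extractor, config)
            layers = {"lstm": model.lstm, "fc": model.fc, "head": model.head}
    for lname, layer in layers.items():
        for pname in layer.params:
            layer.params[pname][...] = arrays[f"{lname}__{pname}"]
    model.norm_mean = arrays["norm_mean"]
    model.norm_sd = arrays["norm_sd"]
    model.metadata = meta["metadata"]
    return model


def save_bundle(bundle: RecognizerBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    C = bundle.correspondence
    hierarchy = {
        "activities": list(C.activity_set.labels),
        "motion_states": list(C.state_set.labels),
        "correspondence": {s: list(C.invert(s)) for s in C.state_set},
    }
    with open(outdir / "hierarchy.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(hierarchy, fh, sort_keys=False)
    manifest = {
        "ips": bundle.ips,
        "hierarchy_fingerprint": C.fingerprint(),
        "groups": {},
    }
    if bundle.motion_model is not None:
        save_model(bundle.motion_model, outdir / "motion.npz")
        manifest["motion"] = "motion.npz"
    for i, state in enumerate(C.state_set):
        if state in bundle.group_models:
            fname = f"group_{i}.npz"
            save_model(bundle.group_models[state], outdir / fname)
            manifest["groups"][state] = fname
    with open(outdir / "bundle.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)


def load_bundle(outdir) -> RecognizerBundle:
    outdir = Path(outdir)
    with open(outdir / "bundle.json", "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    C = load_hierarchy_file(outdir / "hierarchy.yaml")
    if C.fingerprint() != manifest["hierarchy_fingerprint"]:
        raise ValueError("bundle hierarchy fingerprint mismatch")
    motion = load_model(outdir / manifest["motion"]) if "motion" in manifest else None
    groups = {s: load_model(outdir / f) for s, f in manifest["groups"].items()}
    return RecognizerBundle(
        correspondence=C, motion_model=motion, group_models=groups,
        ips=manifest["ips"],
    )
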