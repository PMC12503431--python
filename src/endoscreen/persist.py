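"""Checkpointing: one ``.npz`` file per model (weights + spec header)."""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from . import nn
from .nn.layers import BatchNorm2d, iter_layers
from .architectures import ArchSpec, build_classifier
from .dcm import DiseaseModel
from .iqm import QualityModel
from .weaklabel import SegmentationModel, UNetSpec


def _gather(net: nn.Layer) -> dict:
    out = {f"p{i}": p.data for i, p in enumerate(net.params())}
    bns = [l for l in iter_layers(net) if isinstance(l, BatchNorm2d)]
    for i, bn in enumerate(bns):  # running statistics are not parameters
        out[f"bn{i}_mean"] = bn.running_mean
        out[f"bn{i}_var"] = bn.running_var
    return out


def _restore(net: nn.Layer, blobs) -> None:
    for i, p in enumerate(net.params()):
        stored = blobs[f"p{i}"]
        if stored.shape != p.data.shape:
            raise ValueError(f"checkpoint shape mismatch at parameter {i}")
        p.data[...] = stored
    bns = [l for l in iter_layers(net) if isinstance(l, BatchNorm2d)]
    for i, bn in enumerate(bns):
        bn.running_mean[...] = blobs[f"bn{i}_mean"]
        bn.running_var[...] = blobs[f"bn{i}_var"]


def save_classifier(path, model: QualityModel | DiseaseModel, kind: str) -> None:
    header = json.dumps({"kind": kind, "spec": asdict(model.spec)})
    np.savez(path, __header__=np.array(header), **_gather(model.net))


def load_classifier(path, kind: str):
    blobs = np.load(path, allow_pickle=False)
    header = json.loads(str(blobs["__header__"]))
    if header["kind"] != kind:
        raise ValueError(f"checkpoint is a {header['kind']!r} model, not {kind!r}")
    spec_d = header["spec"]
    spec_d["input_size"] = tuple(spec_d["input_size"])
    spec = ArchSpec(**spec_d)
    net = build_classifier(spec, seed=0)
    _restore(net, blobs)
    cls = QualityModel if kind == "iqm" else DiseaseModel
    model = cls(net, spec)
    model.trained = True
    return model


def save_segmenter(path, model: SegmentationModel) -> None:
    header = json.dumps({"kind": "unet", "spec": asdict(model.spec)})
    np.savez(path, __header__=np.array(header), **_gather(model.net))


def load_segmenter(path) -> SegmentationModel:
    blobs = np.load(path, allow_pickle=False)
    header = json.loads(str(blobs["__header__"]))
    if header["kind"] != "unet":
        raise ValueError("checkpoint is not a segmentation model")
    spec_d = header["spec"]
    spec_d["input_size"] = tuple(spec_d["input_size"])
    spec = UNetSpec(**spec_d)
    net = nn.UNet(in_channels=3, base_channels=spec.base_channels,
                  depth=spec.depth, rng=np.random.default_rng(0))
    _restore(net, blobs)
    model = SegmentationModel(net, spec)
    model.trained = True
    return model
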