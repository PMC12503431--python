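"""Analytic FLOP accounting and informational inference timing.

Convention: one multiply-accumulate = one FLOP. Convolutions cost
``C_in/groups x C_out x k_h x k_w x H_out x W_out`` MACs, linear layers
``in x out``; normalisation, activations and pooling are counted as zero.
Under this convention a ResNet50 inference pass on one 224x224 image costs
about 3.8 GFLOPs. Totals scale linearly with batch size.

Wall-clock timing is provided for relative comparisons only — it depends
on the host and is never a reproducible architecture property.
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass, field

import numpy as np

from .architectures import ArchSpec, build_classifier
from . import nn


class ProfilingError(RuntimeError):
    pass


@dataclass
class FlopReport:
    arch: str
    input_size: tuple[int, int]
    batch: int
    total_macs: int
    per_layer: list = field(default_factory=list)  # (name, macs) per sample

    @property
    def gflops(self) -> float:
        return self.total_macs / 1e9

    def as_dict(self) -> dict:
        return {
            "arch": self.arch, "input_size": list(self.input_size),
            "batch": self.batch, "total_macs": self.total_macs,
            "gflops": self.gflops,
            "per_layer": [{"name": n, "macs": m} for n, m in self.per_layer],
        }


def count_flops(spec: ArchSpec, input_size: tuple[int, int] | None = None,
                batch: int = 64) -> FlopReport:
    """Analytic layer walk over the built architecture."""
    size = tuple(input_size or spec.input_size)
    model = build_classifier(spec, seed=0)
    entries, out_shape = model.flop_walk((3, size[0], size[1]))
    if out_shape != (spec.n_classes,):
        raise ProfilingError(
            f"layer walk ended at shape {out_shape}, expected ({spec.n_classes},)")
    per_sample = sum(m for _, m in entries)
    return FlopReport(arch=spec.name, input_size=size, batch=batch,
                      total_macs=per_sample * batch, per_layer=entries)


def time_inference(model: nn.Layer, batch_shape=(8, 3, 64, 64), repeats=5,
                   warmup=2, seed=0) -> dict:
    """Median wall-clock seconds per forward batch after warm-up runs."""
    rng = np.random.default_rng(seed)
    x = rng.random(batch_shape, dtype=np.float32)
    for _ in range(warmup):
        model.forward(x, train=False)
    timings = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        model.forward(x, train=False)
        timings.append(time.perf_counter() - t0)
    return {
        "timings_s": timings,
        "median_s": float(np.median(timings)),
        "batch_shape": list(batch_shape),
        "repeats": repeats,
        "warmup": warmup,
        "hardware": platform.processor() or platform.machine(),
    }
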