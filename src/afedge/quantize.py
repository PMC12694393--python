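"""Post-training INT8 quantization of the trained 1D CNN.

Weights of the convolutional and dense layers are quantized per tensor to
symmetric int8 (scale = max|w| / 127, zero point 0); activations are
quantized per tensor to asymmetric int8 using min/max ranges calibrated on
a seeded representative set of training windows (200 by default).
Quantized inference replays the layer graph on the int8 grid: every weight
is the dequantized int8 value and every intermediate activation is snapped
to its calibrated 256-level grid, which reproduces the numerical behavior
of integer kernels up to accumulator rounding.  BatchNorm is kept as a
separate per-channel affine in float32 (it is not folded into the
preceding convolution); its parameter count is negligible, so the
serialized INT8 container is still several times smaller than the float32
one, mirroring the flash-footprint reduction that motivates deployment.

Softmax probabilities are computed in float from the dequantized logits,
so ranking metrics (AUC) remain well defined for the quantized model.
"""

from __future__ import annotations

import json
import struct
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from afedge.cnn import (
    _MAGIC,
    BatchNorm,
    CNN1D,
    Conv1D,
    Dense,
    ModelConfig,
    TrainedModel,
    _read_container,
    _softmax,
    _write_container,
)

REPRESENTATIVE_SET_SIZE = 200
_QMIN, _QMAX = -128, 127


@dataclass(frozen=True)
class ActQuant:
    """Asymmetric per-tensor activation quantization parameters."""

    scale: float
    zero_point: int

    def apply(self, x: np.ndarray) -> np.ndarray:
        q = np.clip(np.round(x / self.scale) + self.zero_point, _QMIN, _QMAX)
        return (q - self.zero_point) * self.scale

    @classmethod
    def from_range(cls, lo: float, hi: float) -> "ActQuant":
        lo = min(0.0, float(lo))
        hi = max(0.0, float(hi))
        scale = (hi - lo) / (_QMAX - _QMIN)
        if scale == 0.0:
            return cls(1.0, 0)
        zp = int(np.clip(round(_QMIN - lo / scale), _QMIN, _QMAX))
        return cls(scale, zp)


def _quantize_weight(w: np.ndarray) -> tuple[np.ndarray, float]:
    """Symmetric per-tensor int8 quantization of one weight tensor."""
    amax = float(np.max(np.abs(w)))
    scale = amax / _QMAX if amax > 0 else 1.0
    q = np.clip(np.round(w / scale), -_QMAX, _QMAX).astype(np.int8)
    return q, scale


class QuantizedModel:
    """INT8 counterpart of a trained model with the same prediction contract."""

    def __init__(
        self,
        model_config: ModelConfig,
        weight_payload: list[dict],
        act_qparams: list[ActQuant],
        rep_descriptor: dict,
    ):
        self.model_config = model_config
        self.weight_payload = weight_payload
        self.act_qparams = act_qparams
        self.rep_descriptor = rep_descriptor
        self._graph = self._build_graph()

    def _build_graph(self) -> CNN1D:
        """A layer graph carrying the dequantized int8 weights."""
        graph = CNN1D(self.model_config, seed=0)
        it = iter(self.weight_payload)
        for layer in graph.layers:
            if isinstance(layer, (Conv1D, Dense)):
                payload = next(it)
                layer.w[...] = payload["q_w"].astype(float) * payload["w_scale"]
                layer.b[...] = payload["b"]
            elif isinstance(layer, BatchNorm):
                payload = next(it)
                layer.gamma[...] = payload["gamma"]
                layer.beta[...] = payload["beta"]
                layer.moving_mean[...] = payload["moving_mean"]
                layer.moving_var[...] = payload["moving_var"]
        return graph

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        x = self._graph._as_input(windows)
        x = self.act_qparams[0].apply(x)
        for layer, qp in zip(self._graph.layers, self.act_qparams[1:]):
            x = layer.forward(x, training=False, rng=None)
            x = qp.apply(x)
        return _softmax(x)

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(windows), axis=1)


def quantize_int8(
    tm: TrainedModel,
    representative_windows: np.ndarray,
    seed: int = 0,
    rep_size: int = REPRESENTATIVE_SET_SIZE,
) -> QuantizedModel:
    """Convert a trained float32 model to its INT8 representation.

    ``representative_windows`` should come from the training distribution;
    ``rep_size`` windows are drawn from it (seeded, without replacement)
    and pushed through the float model to calibrate per-tensor activation
    ranges.
    """
    representative_windows = np.asarray(representative_windows, dtype=float)
    if len(representative_windows) == 0:
        raise ValueError("representative set must be non-empty")
    rng = np.random.default_rng(seed)
    take = min(rep_size, len(representative_windows))
    idx = np.sort(rng.choice(len(representative_windows), size=take, replace=False))
    rep = representative_windows[idx]

    model = tm.model
    x = model._as_input(rep)
    ranges: list[tuple[float, float]] = [(float(x.min()), float(x.max()))]
    for layer in model.layers:
        x = layer.forward(x, training=False, rng=None)
        ranges.append((float(x.min()), float(x.max())))
    act_qparams = [ActQuant.from_range(lo, hi) for lo, hi in ranges]

    weight_payload: list[dict] = []
    for layer in model.layers:
        if isinstance(layer, (Conv1D, Dense)):
            q_w, w_scale = _quantize_weight(layer.w)
            weight_payload.append(
                {"q_w": q_w, "w_scale": w_scale, "b": layer.b.astype(np.float32)}
            )
        elif isinstance(layer, BatchNorm):
            weight_payload.append(
                {
                    "gamma": layer.gamma.astype(np.float32),
                    "beta": layer.beta.astype(np.float32),
                    "moving_mean": layer.moving_mean.astype(np.float32),
                    "moving_var": layer.moving_var.astype(np.float32),
                }
            )

    rep_descriptor = {"source": "training-windows", "size": int(take), "seed": int(seed)}
    return QuantizedModel(tm.model_config, weight_payload, act_qparams, rep_descriptor)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_quantized(qm: QuantizedModel, path: str | Path) -> None:
    """Serialize the INT8 model (int8 weight bytes, float32 side data)."""
    arrays: list[np.ndarray] = []
    payload_meta = []
    for payload in qm.weight_payload:
        keys = sorted(payload)
        meta = {"keys": [], "scalars": {}}
        for key in keys:
            value = payload[key]
            if isinstance(value, np.ndarray):
                arrays.append(value)
                meta["keys"].append(key)
            else:
                meta["scalars"][key] = float(value)
        payload_meta.append(meta)
    header = {
        "format": "afedge-model",
        "kind": "int8",
        "model_config": asdict(qm.model_config),
        "payload_meta": payload_meta,
        "act_qparams": [[qp.scale, qp.zero_point] for qp in qm.act_qparams],
        "representative_set": qm.rep_descriptor,
    }
    _write_container(path, header, arrays)


def load_quantized(path: str | Path) -> QuantizedModel:
    header, arrays = _read_container(path)
    if header.get("kind") != "int8":
        raise ValueError(f"{path}: container holds a {header.get('kind')} model")
    cfg = ModelConfig(**header["model_config"])
    weight_payload = []
    it = iter(arrays)
    for meta in header["payload_meta"]:
        payload: dict = {k: next(it) for k in meta["keys"]}
        payload.update(meta["scalars"])
        weight_payload.append(payload)
    act_qparams = [ActQuant(s, int(z)) for s, z in header["act_qparams"]]
    return QuantizedModel(cfg, weight_payload, act_qparams, header["representative_set"])
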