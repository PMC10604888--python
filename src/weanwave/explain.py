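"""Grad-CAM saliency over each branch's final convolutional layer.

For a chosen branch, the class-discriminative map is

    alpha_k = spatial mean of  d(failure logit) / d(A_k)
    L       = ReLU( sum_k alpha_k * A_k )

where ``A_k`` is channel k of the branch extractor's final 720-channel
convolutional output on the full-length (uncropped) input.  The coarse
map is bilinearly upsampled to the folded image grid, unfolded row-major
back to the time axis, truncated to the recording length and
max-normalized to [0, 1] — yielding one brightness weight per original
time step, renderable as background bands behind the waveform channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .preprocess import FoldLayout, PreprocessConfig, prepare_inputs
from .vent_data import SBTRecord, ValidationError
from .wean_net import AssembledModel

__all__ = [
    "SaliencyMap",
    "gradcam",
    "unfold_to_time",
    "render_overlay",
    "saliency_bands",
]


@dataclass(frozen=True)
class SaliencyMap:
    """Per-branch Grad-CAM result aligned to the recording's time axis."""

    branch: str                  # "waveform" | "numeric"
    raw_cam: np.ndarray          # (h, w) >= 0 over the final conv grid
    time_weights: np.ndarray     # (T,) in [0, 1]
    channel_weights: np.ndarray  # alpha_k, (720,)
    layout: FoldLayout

    def __post_init__(self):
        if np.any(self.raw_cam < 0):
            raise ValidationError("raw_cam must be non-negative")
        if self.time_weights.ndim != 1:
            raise ValidationError("time_weights must be 1-D")


def cam_from_activations(activations: np.ndarray,
                         grads: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Core Grad-CAM algebra on one sample.

    ``activations`` is the target layer's (C, h, w) map A, ``grads`` is
    d(logit)/dA of the same shape.  Returns (alpha, cam): the
    gradient-pooled channel weights alpha_k and the class-discriminative
    map ReLU(sum_k alpha_k A_k).
    """
    if activations.shape != grads.shape or activations.ndim != 3:
        raise ValidationError("activations and grads must share a (C, h, w) shape")
    alpha = grads.mean(axis=(1, 2))
    cam = np.maximum(np.tensordot(alpha, activations, axes=1), 0.0)
    return alpha, cam


def gradcam(assembled: AssembledModel, record: SBTRecord, branch: str,
            config: Optional[PreprocessConfig] = None) -> SaliencyMap:
    """Grad-CAM for the failure logit on a full-length record."""
    if branch not in ("waveform", "numeric"):
        raise ValidationError(f"branch must be 'waveform' or 'numeric', got {branch!r}")
    config = config or PreprocessConfig()
    xw, xn = prepare_inputs(record, config, crop=False)
    model = assembled.model
    model.forward(xw[None], xn[None], training=False)
    gAw, gAn = model.backward(np.ones(1), into_extractors=False)
    Aw, An = model.feature_maps
    A, gA = (Aw, gAw) if branch == "waveform" else (An, gAn)
    alpha, cam = cam_from_activations(A[0], gA[0])
    layout = (config.waveform_layout if branch == "waveform"
              else config.numeric_layout)
    T = len(record.waveform) if branch == "waveform" else len(record.numeric)
    tw = unfold_to_time(cam, layout, T)
    return SaliencyMap(branch=branch, raw_cam=cam, time_weights=tw,
                       channel_weights=alpha, layout=layout)


def _interp_axis(arr: np.ndarray, n_out: int, axis: int) -> np.ndarray:
    """Linear interpolation along one axis between cell centers."""
    n_in = arr.shape[axis]
    if n_in == 1:
        reps = [1] * arr.ndim
        reps[axis] = n_out
        return np.tile(arr, reps)
    # cell-center coordinates of in/out grids on a common [0, 1] axis
    x_in = (np.arange(n_in) + 0.5) / n_in
    x_out = (np.arange(n_out) + 0.5) / n_out
    arr = np.moveaxis(arr, axis, 0)
    out = np.empty((n_out,) + arr.shape[1:])
    flat = arr.reshape(n_in, -1)
    oflat = out.reshape(n_out, -1)
    for j in range(flat.shape[1]):
        oflat[:, j] = np.interp(x_out, x_in, flat[:, j])
    return np.moveaxis(out, 0, axis)


def unfold_to_time(cam: np.ndarray, layout: FoldLayout, T: int) -> np.ndarray:
    """Upsample a coarse (h, w) map to the folded image grid, unfold
    row-major, truncate to T and max-normalize to [0, 1].

    An all-zero map stays all-zero; otherwise the maximum weight is
    exactly 1 and the argmax of the map is preserved.
    """
    cam = np.asarray(cam, dtype=np.float64)
    if cam.ndim != 2:
        raise ValidationError("cam must be 2-D")
    rows = layout.height_for(T)
    if cam.shape[0] > max(rows, 1) * 64 or T < 1:
        raise ValidationError("cam shape inconsistent with layout/T")
    up = _interp_axis(_interp_axis(cam, rows, 0), layout.width, 1)
    tw = up.reshape(-1)[:T]
    m = tw.max()
    if m > 0:
        tw = tw / m
    return tw


def saliency_bands(sal: SaliencyMap, sample_period_s: float,
                   threshold: float = 0.5) -> list[dict]:
    """Contiguous high-saliency intervals: [{start_s, end_s, weight}, ...].

    ``weight`` is the mean time weight inside the band.
    """
    mask = sal.time_weights >= threshold
    bands = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            seg = sal.time_weights[start:i]
            bands.append({
                "start_s": start * sample_period_s,
                "end_s": i * sample_period_s,
                "weight": float(seg.mean()),
            })
            start = None
    if start is not None:
        seg = sal.time_weights[start:]
        bands.append({
            "start_s": start * sample_period_s,
            "end_s": len(mask) * sample_period_s,
            "weight": float(seg.mean()),
        })
    return bands


def render_overlay(record: SBTRecord, maps: dict[str, SaliencyMap],
                   path, band_threshold: float = 0.5) -> Path:
    """Waveform plot with brightness-coded saliency background.

    Writes a PNG at ``path`` and a machine-readable JSON band list at
    ``path`` + ``.bands.json`` so downstream checks never parse pixels.
    Output bytes are deterministic for fixed inputs.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    wf = record.waveform
    dt = wf.sample_period_ms / 1000.0
    t = np.arange(len(wf)) * dt
    channels = [("Paw (cmH2O)", wf.paw), ("Flow (L/min)", wf.flow),
                ("Volume (mL)", wf.volume)]
    sal = maps.get("waveform")
    fig, axes = plt.subplots(len(channels), 1, figsize=(10, 6), sharex=True)
    for ax, (name, y) in zip(axes, channels):
        if sal is not None:
            ax.imshow(sal.time_weights[None, :], aspect="auto",
                      extent=(0, t[-1] if len(t) > 1 else dt,
                              float(np.min(y)), float(np.max(y))),
                      origin="lower", cmap="inferno", alpha=0.45,
                      vmin=0.0, vmax=1.0, interpolation="nearest")
        ax.plot(t, y, lw=0.6, color="tab:blue")
        ax.set_ylabel(name, fontsize=8)
    axes[-1].set_xlabel("time (s)")
    fig.suptitle(f"{record.patient_id}: Grad-CAM saliency overlay", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": "weanwave"})
    plt.close(fig)

    bands_payload = {}
    for branch, m in maps.items():
        period = (dt if branch == "waveform"
                  else record.numeric.step_period_s)
        bands_payload[branch] = saliency_bands(m, period, band_threshold)
    band_path = path.with_name(path.name + ".bands.json")
    band_path.write_text(json.dumps(bands_payload, indent=2, sort_keys=True))
    return path
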