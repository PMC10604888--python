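"""Normalization, cropping and 1-D -> 2-D folding of SBT series.

Model inputs are produced in three steps, always in this order:

1. per-channel min-max normalization over the *full* recording,
2. (training only) a random contiguous crop of fixed length
   (13,000 waveform steps / 3,500 numeric steps),
3. row-major folding of each channel into a 2-D image
   (width 130 -> 100x130 waveform, width 70 -> 50x70 numeric; the
   training lengths factor exactly, so training images carry no padding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vent_data import ValidationError

__all__ = [
    "FoldLayout",
    "PreprocessConfig",
    "minmax_normalize",
    "random_crop",
    "fold_to_image",
    "unfold_from_image",
    "prepare_inputs",
]


class LengthError(ValueError):
    """A crop length exceeds the series length."""


@dataclass(frozen=True)
class FoldLayout:
    """Row-major fold layout: ``width`` time steps per image row."""

    width: int
    pad_value: float = 0.0

    def __post_init__(self):
        if self.width < 1:
            raise ValidationError("fold width must be >= 1")

    def height_for(self, T: int) -> int:
        return -(-T // self.width)


@dataclass(frozen=True)
class PreprocessConfig:
    """Crop lengths and fold widths for the two branches."""

    crop_len_waveform: int = 13_000
    crop_len_numeric: int = 3_500
    fold_width_waveform: int = 130
    fold_width_numeric: int = 70
    pad_value: float = 0.0

    @property
    def waveform_layout(self) -> FoldLayout:
        return FoldLayout(self.fold_width_waveform, self.pad_value)

    @property
    def numeric_layout(self) -> FoldLayout:
        return FoldLayout(self.fold_width_numeric, self.pad_value)


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Scale each channel of a (C, T) series to [0, 1] independently.

    A constant channel maps to all zeros (it carries no information and
    this avoids a divide-by-zero).  Non-finite input raises.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if not np.all(np.isfinite(x)):
        raise ValidationError("minmax_normalize: input contains non-finite values")
    lo = x.min(axis=-1, keepdims=True)
    hi = x.max(axis=-1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(x)
    nz = span[:, 0] > 0
    out[nz] = (x[nz] - lo[nz]) / span[nz]
    return out


def random_crop(x: np.ndarray, L: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous window of length ``L`` with start uniform on {0..T-L}.

    All channels share the same start, so cross-channel alignment is
    preserved.
    """
    x = np.asarray(x)
    T = x.shape[-1]
    if L < 1:
        raise LengthError("crop length must be >= 1")
    if L > T:
        raise LengthError(f"crop length {L} exceeds series length {T}")
    start = int(rng.integers(0, T - L + 1))
    return x[..., start:start + L]


def fold_to_image(x: np.ndarray, layout: FoldLayout) -> np.ndarray:
    """Fold a (C, T) series row-major into a (C, ceil(T/width), width) image,
    padding the tail with ``layout.pad_value``."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    C, T = x.shape
    if T < 1:
        raise ValidationError("cannot fold an empty series")
    H = layout.height_for(T)
    padded = np.full((C, H * layout.width), layout.pad_value, dtype=np.float64)
    padded[:, :T] = x
    return padded.reshape(C, H, layout.width)


def unfold_from_image(img: np.ndarray, T: int) -> np.ndarray:
    """Inverse of :func:`fold_to_image`: row-major unfold truncated to T."""
    img = np.asarray(img)
    C, H, W = img.shape
    if not (1 <= T <= H * W):
        raise ValidationError(f"T={T} incompatible with image of {H * W} slots")
    return img.reshape(C, H * W)[:, :T]


def prepare_inputs(
    record,
    config: PreprocessConfig,
    rng: np.random.Generator | None = None,
    crop: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Record -> (waveform image, numeric image), each (C, H, W).

    With ``crop=True`` (training) both series are normalized over their
    full length first, then randomly cropped to the configured lengths;
    otherwise the entire sequences are used (inference contract), except
    that the tail is truncated to a whole number of fold rows (less than
    one row, i.e. <=129 waveform / <=69 numeric steps) so the model never
    sees artificial pad values.
    """
    xw = minmax_normalize(record.waveform.as_array())
    xn = minmax_normalize(record.numeric.as_array())
    if crop:
        if rng is None:
            raise ValidationError("crop=True requires an rng")
        xw = random_crop(xw, config.crop_len_waveform, rng)
        xn = random_crop(xn, config.crop_len_numeric, rng)
    else:
        xw = _truncate_to_rows(xw, config.fold_width_waveform)
        xn = _truncate_to_rows(xn, config.fold_width_numeric)
    return (
        fold_to_image(xw, config.waveform_layout),
        fold_to_image(xn, config.numeric_layout),
    )


def _truncate_to_rows(x: np.ndarray, width: int) -> np.ndarray:
    """Drop the trailing partial fold row (keeps at least one row)."""
    T = x.shape[-1]
    keep = (T // width) * width
    return x[..., :keep] if keep >= width else x
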