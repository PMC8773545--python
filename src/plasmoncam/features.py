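"""Image features fed to the refractive-index regressor.

Per VIS/NIR frame pair, four scalars are extracted:

* ``gm_vis``, ``gm_nir`` — grayscale means, proxies for band-integrated
  transmitted power (hence SPR absorption);
* ``es_vis``, ``es_nir`` — totals of the Prewitt edge-gradient magnitude
  over all pixels and channels ("RGB summation of the edge image"),
  proxies for spot size and rim sharpness, which respond to saturation
  blooming.

Grayscale conversion uses the luminance weights 0.3 R + 0.59 G + 0.11 B in
floating point (no rounding).  Edge detection is the 3x3 Prewitt operator,
per channel, Euclidean gradient magnitude ``sqrt(Gx**2 + Gy**2)`` with
replicate-padded borders and no thresholding or binarization: continuous
magnitudes preserve the spot-perimeter signal that a hard threshold would
quantize away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import FormatError
from .imaging import FramePair, ImageFrame

__all__ = [
    "GRAY_WEIGHTS",
    "PREWITT_X",
    "PREWITT_Y",
    "GrayFrame",
    "EdgeFrame",
    "FeatureVector",
    "FEATURE_NAMES",
    "to_grayscale",
    "grayscale_mean",
    "prewitt_edges",
    "edge_summation",
    "extract_features",
    "features_table",
]

#: Luminance weights for R, G, B.
GRAY_WEIGHTS = np.array([0.3, 0.59, 0.11])

#: 3x3 Prewitt kernels (correlation convention): horizontal and vertical
#: derivative estimates.
PREWITT_X = np.array([[-1.0, 0.0, 1.0]] * 3)
PREWITT_Y = PREWITT_X.T.copy()

FEATURE_NAMES = ("gm_vis", "gm_nir", "es_vis", "es_nir")


@dataclass(frozen=True)
class GrayFrame:
    """Floating-point luminance image plus the band it came from."""

    pixels: np.ndarray  # H x W float
    provenance: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=float))


@dataclass(frozen=True)
class EdgeFrame:
    """Per-channel gradient-magnitude image; operator is always Prewitt."""

    pixels: np.ndarray  # H x W x C float, >= 0
    operator: str = "prewitt"


@dataclass(frozen=True)
class FeatureVector:
    """The four network inputs, in fixed order (gm_vis, gm_nir, es_vis, es_nir)."""

    gm_vis: float
    gm_nir: float
    es_vis: float
    es_nir: float

    def as_array(self) -> np.ndarray:
        return np.array([self.gm_vis, self.gm_nir, self.es_vis, self.es_nir])


def to_grayscale(frame: ImageFrame) -> GrayFrame:
    """Luminance conversion: 0.3 R + 0.59 G + 0.11 B, floating point.

    Single-channel (NIR) frames pass through unchanged; any other channel
    count raises :class:`FormatError`.
    """
    px = frame.pixels.astype(float)
    if frame.channels == 1:
        return GrayFrame(px[:, :, 0], frame.band)
    if frame.channels == 3:
        return GrayFrame(px @ GRAY_WEIGHTS, frame.band)
    raise FormatError(f"expected 1 or 3 channels, got {frame.channels}")


def grayscale_mean(gray: GrayFrame) -> float:
    """Arithmetic mean luminance over all pixels (DN)."""
    if gray.pixels.size == 0:
        raise FormatError("empty frame")
    return float(gray.pixels.mean())


def prewitt_edges(frame: ImageFrame) -> EdgeFrame:
    """Prewitt gradient magnitude per channel, replicate-padded, unthresholded."""
    h, w = frame.shape
    if h < 3 or w < 3:
        raise FormatError(f"frame {h}x{w} smaller than the 3x3 Prewitt kernel")
    px = frame.pixels.astype(float)
    mags = np.empty_like(px)
    # The Prewitt kernels are separable: [-1 0 1] x [1 1 1] and its transpose.
    for c in range(frame.channels):
        chan = px[:, :, c]
        gx = ndimage.correlate1d(chan, [-1.0, 0.0, 1.0], axis=1, mode="nearest")
        gx = ndimage.correlate1d(gx, [1.0, 1.0, 1.0], axis=0, mode="nearest")
        gy = ndimage.correlate1d(chan, [-1.0, 0.0, 1.0], axis=0, mode="nearest")
        gy = ndimage.correlate1d(gy, [1.0, 1.0, 1.0], axis=1, mode="nearest")
        mags[:, :, c] = np.hypot(gx, gy)
    return EdgeFrame(mags)


def edge_summation(edges: EdgeFrame) -> float:
    """Sum of gradient magnitudes over all pixels and channels (DN)."""
    return float(edges.pixels.sum())


def extract_features(vis: ImageFrame, nir: ImageFrame) -> FeatureVector:
    """Assemble the four-element feature vector from one frame pair."""
    if vis.band != "VIS" or nir.band != "NIR":
        raise FormatError(f"band mismatch: got ({vis.band}, {nir.band}), expected (VIS, NIR)")
    return FeatureVector(
        gm_vis=grayscale_mean(to_grayscale(vis)),
        gm_nir=grayscale_mean(to_grayscale(nir)),
        es_vis=edge_summation(prewitt_edges(vis)),
        es_nir=edge_summation(prewitt_edges(nir)),
    )


def features_table(pairs: list[FramePair]):
    """Feature DataFrame for a simulated campaign.

    Columns: frame_id, time, true_ri, gm_vis, gm_nir, es_vis, es_nir.
    """
    import pandas as pd

    rows = []
    for i, pair in enumerate(pairs):
        fv = extract_features(pair.vis, pair.nir)
        rows.append(
            {
                "frame_id": i,
                "time": pair.time_s,
                "true_ri": pair.true_ri,
                "gm_vis": fv.gm_vis,
                "gm_nir": fv.gm_nir,
                "es_vis": fv.es_vis,
                "es_nir": fv.es_nir,
            }
        )
    return pd.DataFrame(rows)
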