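"""Maximum-entropy (Kapur) thresholding and overall percent density.

The masked grey-level histogram is split at the intensity t that
maximizes the summed Shannon entropies of the two classes,

    psi(t) = H_low(t) + H_high(t),

with p_i the histogram probabilities, P_t = sum_{i<=t} p_i,
H_low(t)  = -sum_{i<=t}  (p_i/P_t)     ln(p_i/P_t)      and
H_high(t) = -sum_{i>t}   (p_i/(1-P_t)) ln(p_i/(1-P_t)),

zero-probability bins skipped (0 ln 0 := 0).  Pixels strictly above the
threshold are radiodense; overall percent density is

    PD = 100 * (# dense pixels) / (# breast-mask pixels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Histogram256",
    "DenseMap",
    "SegmentationError",
    "masked_histogram",
    "kapur_threshold",
    "segment",
    "overall_pd",
]

N_LEVELS = 256


class SegmentationError(ValueError):
    """Raised for empty masks or histograms with no valid split."""


@dataclass(frozen=True)
class Histogram256:
    """256-bin intensity histogram of the in-mask pixels."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_LEVELS,):
            raise SegmentationError("histogram must have 256 bins")
        if (c < 0).any():
            raise SegmentationError("histogram counts must be nonnegative")
        if c.sum() <= 0:
            raise SegmentationError("histogram is empty")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DenseMap:
    """Boolean raster of radiodense pixels with the threshold that made it."""

    pixels: np.ndarray
    threshold_used: int


def masked_histogram(image: np.ndarray, mask: np.ndarray) -> Histogram256:
    """Histogram of in-mask intensities only; total equals the mask size."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise SegmentationError("image and mask shapes differ")
    if not mask.any():
        raise SegmentationError("mask is empty")
    counts = np.bincount(image[mask].ravel().astype(np.int64), minlength=N_LEVELS)
    return Histogram256(counts=counts)


def kapur_entropy_curve(hist: Histogram256) -> np.ndarray:
    """psi(t) for every candidate threshold t in [0, 254].

    Invalid candidates (one class empty) get -inf.  Natural log; the base
    only rescales psi and leaves the argmax unchanged.
    """
    p = hist.counts / hist.total
    P = np.cumsum(p)
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    C = np.cumsum(plogp)
    Ctot = C[-1]
    psi = np.full(N_LEVELS - 1, -np.inf)
    Pt = P[:-1]
    valid = (Pt > 0) & (Pt < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_low = np.log(Pt) - C[:-1] / Pt
        h_high = np.log1p(-Pt) - (Ctot - C[:-1]) / (1 - Pt)
    psi[valid] = h_low[valid] + h_high[valid]
    return psi


def kapur_threshold(hist: Histogram256) -> int:
    """Maximum-entropy threshold: smallest t maximizing psi(t).

    Requires at least two distinct nonzero bins (otherwise there is no
    valid two-class split).  Ties in psi break toward the smallest level.
    """
    if np.count_nonzero(hist.counts) < 2:
        raise SegmentationError(
            "histogram has a single occupied bin: no valid two-class split"
        )
    psi = kapur_entropy_curve(hist)
    # np.argmax returns the first (= smallest) maximizer
    return int(np.argmax(psi))


def segment(image: np.ndarray, mask: np.ndarray, t: int) -> DenseMap:
    """Mark in-mask pixels with intensity strictly above t as radiodense."""
    if not 0 <= t <= 254:
        raise SegmentationError("threshold must be in [0, 254]")
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise SegmentationError("image and mask shapes differ")
    return DenseMap(pixels=mask & (image > t), threshold_used=int(t))


def overall_pd(dense: DenseMap, mask: np.ndarray) -> float:
    """Overall percent density: 100 * dense pixels / breast-mask pixels."""
    mask = np.asarray(mask, dtype=bool)
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise SegmentationError("mask is empty")
    n_dense = int((dense.pixels & mask).sum())
    return 100.0 * n_dense / n_mask
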