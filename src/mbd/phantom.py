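"""Synthetic MLO-view mammogram phantoms and cohorts with known ground truth.

A phantom emulates the geometry a density pipeline actually consumes: a
half-ellipse breast contour attached to the chest-wall image edge, a
triangular pectoral cut-out at the top corner, a radiolucent (adipose)
background inside the contour, radiodense fibroglandular "blobs" whose
total area is driven to a target fraction of the breast area, and
additive Gaussian noise inside the breast only.  The ground-truth dense
and breast masks are exported, so downstream percent-density and
spatial-pattern measurements can be validated by pixel counting.

Placement modes plant spatial patterns on the same 8x6 tile grid the
regional module measures on: ``posterior``/``middle``/``anterior``
concentrate blob centers in one zone's column band (a clustered,
positive-autocorrelation pattern), ``uniform`` scatters centers anywhere
in the breast, and ``checkerboard`` fills alternating grid tiles to plant
a negative-autocorrelation (scattered) pattern.

The target dense fraction is hit by scaling all blob radii with a
monotone bisection on the achieved pixel fraction; generation fails with
an explicit shortfall if the requested fraction is unreachable (e.g. a
checkerboard cannot exceed the alternating tiles' share of the breast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regional import default_zones, make_grid

__all__ = [
    "PhantomSpec",
    "Phantom",
    "PhantomError",
    "CohortSubject",
    "generate_phantom",
    "generate_cohort",
    "cohort_metadata",
    "PLACEMENTS",
    "DEFAULT_CLUSTERED_SHARE",
]

PLACEMENTS = ("posterior", "middle", "anterior", "uniform", "checkerboard")

FRACTION_TOL = 0.02  # contract: achieved dense fraction within this of target
_SEARCH_TOL = 0.004  # bisection stops inside this band (tighter than contract)


class PhantomError(ValueError):
    """Raised for invalid specs or unreachable dense fractions."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic mammogram.

    ``dense_fraction`` is the target share of breast-mask pixels that are
    radiodense; ``dense_level``/``adipose_level`` are the mean intensities
    of the two tissue classes (8-bit scale); ``noise_sd`` is the standard
    deviation of the Gaussian intensity noise added inside the breast.
    """

    image_height: int = 192
    image_width: int = 144
    dense_fraction: float = 0.25
    blob_count: int = 6
    placement: str = "uniform"
    dense_level: int = 200
    adipose_level: int = 80
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 48 or self.image_width < 48:
            raise PhantomError("image must be at least 48x48 pixels")
        if not 0.0 <= self.dense_fraction <= 1.0:
            raise PhantomError("dense_fraction must be in [0, 1]")
        if self.blob_count < 1:
            raise PhantomError("blob_count must be positive")
        if self.placement not in PLACEMENTS:
            raise PhantomError(f"placement must be one of {PLACEMENTS}")
        if not 0 <= self.adipose_level < self.dense_level <= 255:
            raise PhantomError("need 0 <= adipose_level < dense_level <= 255")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class Phantom:
    image: np.ndarray
    breast_mask: np.ndarray
    true_dense_mask: np.ndarray
    spec: PhantomSpec

    @property
    def true_dense_fraction(self) -> float:
        """Ground-truth dense share of the breast, by pixel counting."""
        return float(self.true_dense_mask.sum()) / float(self.breast_mask.sum())


def _breast_mask(h: int, w: int) -> np.ndarray:
    """Half-ellipse breast attached to the left edge minus a pectoral corner."""
    rr = np.arange(h)[:, None].astype(float)
    cc = np.arange(w)[None, :].astype(float)
    cy = (h - 1) / 2.0
    a = 0.48 * h  # vertical semi-axis
    b = 0.92 * w  # horizontal semi-axis (chest wall at column 0)
    mask = ((rr - cy) / a) ** 2 + (cc / b) ** 2 <= 1.0
    # pectoral muscle: top-left corner triangle, well under 15% of the mask
    mask &= rr / (0.35 * h) + cc / (0.30 * w) >= 1.0
    return mask


def _mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def _disc_union(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii: np.ndarray,
) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    h, w = shape
    for (r0, c0), rad in zip(centers, radii):
        ri0, ri1 = max(0, int(r0 - rad)), min(h, int(r0 + rad) + 2)
        ci0, ci1 = max(0, int(c0 - rad)), min(w, int(c0 + rad) + 2)
        rr = np.arange(ri0, ri1)[:, None] - r0
        cc = np.arange(ci0, ci1)[None, :] - c0
        out[ri0:ri1, ci0:ci1] |= rr**2 + cc**2 <= rad**2
    return out


def _bisect_scale(frac_of, target: float, context: str) -> np.ndarray:
    """Find a radius scale whose achieved fraction lies within tolerance.

    ``frac_of(s)`` must be nondecreasing in s.  Returns the dense raster at
    the accepted scale; raises :class:`PhantomError` with the shortfall when
    even the maximal scale cannot reach the target.
    """
    lo, hi = 0.0, 1.0
    dense_hi = frac_of(hi)
    f_hi = dense_hi[1]
    while f_hi < target and hi < 64.0:
        hi *= 2.0
        dense_hi = frac_of(hi)
        f_hi = dense_hi[1]
    if f_hi < target - _SEARCH_TOL:
        raise PhantomError(
            f"dense_fraction {target:.3f} unreachable with {context}: "
            f"maximum achievable fraction is {f_hi:.3f} "
            f"(shortfall {target - f_hi:.3f})"
        )
    best = dense_hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        dense_mid = frac_of(mid)
        best = dense_mid
        if abs(dense_mid[1] - target) <= _SEARCH_TOL:
            break
        if dense_mid[1] < target:
            lo = mid
        else:
            hi = mid
    else:
        # pixel granularity: accept the closer endpoint
        dense_lo = frac_of(lo)
        best = min((dense_lo, frac_of(hi)), key=lambda d: abs(d[1] - target))
    if abs(best[1] - target) > FRACTION_TOL:
        raise PhantomError(
            f"could not place dense tissue within {FRACTION_TOL} of "
            f"dense_fraction {target:.3f} with {context} "
            f"(achieved {best[1]:.3f})"
        )
    return best[0]


def _blob_dense(
    spec: PhantomSpec, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    h, w = mask.shape
    if spec.placement == "uniform":
        region = mask
    else:
        # restrict blob centers to the placement zone's column band of the
        # grid over the mask bounding box, so planted and measured zones
        # coincide by construction
        r0, r1, c0, c1 = _mask_bbox(mask)
        grid = make_grid(r1 - r0, c1 - c0)
        zones = default_zones("left")
        band_cols = zones.zone_columns(spec.placement)
        lo = c0 + grid.col_edges[band_cols[0]]
        hi = c0 + grid.col_edges[band_cols[-1] + 1]
        in_band = np.zeros_like(mask)
        in_band[:, lo:hi] = True
        region = mask & in_band
    idx = np.flatnonzero(region)
    pick = rng.choice(idx, size=spec.blob_count, replace=True)
    centers = np.column_stack(np.unravel_index(pick, mask.shape)).astype(float)
    base_radii = rng.uniform(0.05, 0.14, size=spec.blob_count) * min(h, w)
    n_mask = mask.sum()

    def frac_of(s: float) -> tuple[np.ndarray, float]:
        dense = _disc_union(mask.shape, centers, base_radii * s) & mask
        return dense, float(dense.sum()) / n_mask

    return _bisect_scale(
        frac_of, spec.dense_fraction, f"{spec.blob_count} blobs ({spec.placement})"
    )


def _checkerboard_dense(spec: PhantomSpec, mask: np.ndarray) -> np.ndarray:
    """Alternating grid tiles filled from their centers outward."""
    r0, r1, c0, c1 = _mask_bbox(mask)
    grid = make_grid(r1 - r0, c1 - c0)
    tiles = []
    for i in range(grid.rows):
        for j in range(grid.cols):
            if (i + j) % 2 == 0:
                tiles.append(
                    (
                        r0 + grid.row_edges[i],
                        r0 + grid.row_edges[i + 1],
                        c0 + grid.col_edges[j],
                        c0 + grid.col_edges[j + 1],
                    )
                )
    n_mask = mask.sum()

    def frac_of(s: float) -> tuple[np.ndarray, float]:
        dense = np.zeros_like(mask)
        for tr0, tr1, tc0, tc1 in tiles:
            mr = (tr0 + tr1 - 1) / 2.0
            mc = (tc0 + tc1 - 1) / 2.0
            rad = s * 0.5 * np.hypot(tr1 - tr0, tc1 - tc0)
            rr = np.arange(tr0, tr1)[:, None] - mr
            cc = np.arange(tc0, tc1)[None, :] - mc
            dense[tr0:tr1, tc0:tc1] |= rr**2 + cc**2 <= rad**2
        dense &= mask
        return dense, float(dense.sum()) / n_mask

    return _bisect_scale(frac_of, spec.dense_fraction, "checkerboard tiles")


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render one phantom; identical spec (incl. seed) gives identical output.

    The image is ``adipose_level`` inside the breast, ``dense_level`` on the
    dense mask, exactly 0 off the breast, with Gaussian noise (sd
    ``noise_sd``) added inside the breast only, then rounded and clipped to
    8-bit.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _breast_mask(spec.image_height, spec.image_width)
    if spec.dense_fraction == 0.0:
        dense = np.zeros_like(mask)
    elif spec.placement == "checkerboard":
        dense = _checkerboard_dense(spec, mask)
    else:
        dense = _blob_dense(spec, mask, rng)

    img = np.zeros(mask.shape, dtype=float)
    img[mask] = spec.adipose_level
    img[dense] = spec.dense_level
    if spec.noise_sd > 0:
        img[mask] += rng.normal(0.0, spec.noise_sd, size=int(mask.sum()))
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    img[~mask] = 0
    return Phantom(image=img, breast_mask=mask, true_dense_mask=dense, spec=spec)


# ---------------------------------------------------------------------------
# cohorts

# planted share of blob-clustered (vs checkerboard) subjects per BI-RADS
# group: the less-dense groups cluster more
DEFAULT_CLUSTERED_SHARE = {"A": 0.75, "B": 0.75, "C": 0.45, "D": 0.45}

# clustered subjects' zone preference by age group: mature women
# concentrate in the middle zone, older women in posterior and middle
_ZONE_PREF = {
    "mature": (("middle", 0.70), ("posterior", 0.25), ("anterior", 0.05)),
    "older": (("posterior", 0.50), ("middle", 0.40), ("anterior", 0.10)),
}

_AGE_RANGE = (35.0, 90.0)
_MEAN_AGE = 62.5  # midpoint of the study age range
_CHECKERBOARD_CAP = 0.42  # alternating tiles cover about half the breast

# BI-RADS density category from the planted dense fraction
_BIRADS_CUTOFFS = ((0.12, "A"), (0.25, "B"), (0.40, "C"), (1.01, "D"))


@dataclass(frozen=True)
class CohortSubject:
    subject_id: str
    phantom: Phantom
    age: float
    birads: str
    planted_fraction: float
    placement: str


def _birads_of(fraction: float) -> str:
    for cut, label in _BIRADS_CUTOFFS:
        if fraction < cut:
            return label
    return "D"


def generate_cohort(
    n: int,
    age_slope: float = -0.004,
    clustered_share_by_group: dict[str, float] | None = None,
    seed: int = 0,
    *,
    base_fraction: float = 0.25,
    fraction_noise_sd: float = 0.08,
    image_height: int = 96,
    image_width: int = 72,
    noise_sd: float = 10.0,
    dense_level: int = 200,
    adipose_level: int = 80,
    blob_count: int = 6,
) -> list[CohortSubject]:
    """Generate a synthetic screening cohort with planted effects.

    Ages are uniform over 35-90 years.  Each subject's planted dense
    fraction is ``base_fraction + age_slope * (age - 62.5) + noise``
    (Gaussian, sd ``fraction_noise_sd``), clipped to [0.02, 0.90]; the
    default negative slope plants the denser-breasts-in-younger-women
    trend.  The BI-RADS label is assigned from the planted fraction.
    Each subject is blob-clustered with the probability given for their
    BI-RADS group (default: 0.75 in groups A/B vs 0.45 in C/D) and a
    checkerboard (scattered pattern) otherwise; clustered mature subjects
    favor the middle zone while older subjects split between posterior
    and middle, planting the middle-zone excess in mature women.
    Fixed arguments and seed give a bit-reproducible cohort.
    """
    if n < 2:
        raise PhantomError("cohort needs at least 2 subjects")
    shares = dict(DEFAULT_CLUSTERED_SHARE)
    if clustered_share_by_group:
        shares.update(clustered_share_by_group)
    rng = np.random.default_rng(seed)
    subjects = []
    for k in range(n):
        age = float(rng.uniform(*_AGE_RANGE))
        frac = base_fraction + age_slope * (age - _MEAN_AGE)
        frac += float(rng.normal(0.0, fraction_noise_sd))
        frac = float(np.clip(frac, 0.02, 0.90))
        birads = _birads_of(frac)
        clustered = rng.random() < shares[birads]
        if clustered:
            group = "mature" if age < 65 else "older"
            names, probs = zip(*_ZONE_PREF[group])
            placement = str(rng.choice(names, p=probs))
        else:
            placement = "checkerboard"
            frac = min(frac, _CHECKERBOARD_CAP)
        spec = PhantomSpec(
            image_height=image_height,
            image_width=image_width,
            dense_fraction=frac,
            blob_count=blob_count,
            placement=placement,
            dense_level=dense_level,
            adipose_level=adipose_level,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        subjects.append(
            CohortSubject(
                subject_id=f"S{k:04d}",
                phantom=generate_phantom(spec),
                age=age,
                birads=birads,
                planted_fraction=frac,
                placement=placement,
            )
        )
    return subjects


def cohort_metadata(subjects: list[CohortSubject]) -> pd.DataFrame:
    """Per-subject metadata table (id, age, birads, planted fraction, ...)."""
    return pd.DataFrame(
        {
            "id": [s.subject_id for s in subjects],
            "age": [s.age for s in subjects],
            "birads": [s.birads for s in subjects],
            "planted_fraction": [s.planted_fraction for s in subjects],
            "true_dense_fraction": [s.phantom.true_dense_fraction for s in subjects],
            "placement": [s.placement for s in subjects],
            "seed": [s.phantom.spec.seed for s in subjects],
        }
    )
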