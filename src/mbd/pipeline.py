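"""End-to-end analysis of one masked mammogram and of whole cohorts.

Per image: maximum-entropy threshold on the in-breast histogram,
radiodense segmentation, overall PD, crop to the breast bounding box,
8x6 regional PD grid, zonal PDs, Moran's I and its pattern label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import SubjectRecord
from .phantom import CohortSubject
from .preprocess import enhance_contrast
from .regional import (
    DensityGrid,
    ZonalPD,
    default_zones,
    make_grid,
    regional_pd,
    zonal_pd,
)
from .segmentation import kapur_threshold, masked_histogram, overall_pd, segment
from .spatial import MoranError, MoranResult, morans_i, weight_matrix

__all__ = ["ImageAnalysis", "analyze_image", "analyze_cohort"]


@dataclass(frozen=True)
class ImageAnalysis:
    threshold: int
    overall_pd: float
    density_grid: DensityGrid
    zonal: ZonalPD
    moran: MoranResult
    crop: tuple[int, int, int, int]


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def analyze_image(
    image: np.ndarray,
    mask: np.ndarray,
    *,
    rows: int = 8,
    cols: int = 6,
    enhance: bool = False,
    hist_scope: str = "mask",
    denominator: str = "tile",
    scheme: str = "inverse_distance_squared",
    chest_wall: str = "left",
    eps: float = 0.0,
    crop_to_mask: bool = True,
) -> ImageAnalysis:
    """Run threshold -> segment -> grid -> zones -> Moran on one image.

    ``hist_scope`` chooses whether the threshold histogram is built from
    in-mask pixels only (default) or the whole frame including the cropped
    black background.  The grid is laid over the breast bounding box
    (``crop_to_mask=True``) so the 48 sub-regions tile the cropped image.
    A constant regional-PD field (e.g. a fully non-dense breast) has no
    spatial structure and is reported as pattern ``random`` with I = 0.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if enhance:
        image = enhance_contrast(image, mask)
    hist_mask = mask if hist_scope == "mask" else np.ones_like(mask)
    if hist_scope not in ("mask", "frame"):
        raise ValueError("hist_scope must be 'mask' or 'frame'")
    t = kapur_threshold(masked_histogram(image, hist_mask))
    dense = segment(image, mask, t)
    pd_overall = overall_pd(dense, mask)

    if crop_to_mask:
        r0, r1, c0, c1 = _bbox(mask)
    else:
        r0, r1, c0, c1 = 0, mask.shape[0], 0, mask.shape[1]
    dense_c = dense.pixels[r0:r1, c0:c1]
    mask_c = mask[r0:r1, c0:c1]
    grid = make_grid(r1 - r0, c1 - c0, rows, cols)
    dgrid = regional_pd(dense_c, mask_c, grid, denominator=denominator)
    zones = default_zones(chest_wall, cols=cols)
    zpd = zonal_pd(dgrid, zones)
    W = weight_matrix(grid, scheme)
    try:
        moran = morans_i(dgrid.pd, W, eps=eps)
    except MoranError:
        moran = MoranResult(
            I=0.0, N=grid.n_tiles, pattern="random", x_bar=float(dgrid.pd.mean()),
            scheme=scheme,
        )
    return ImageAnalysis(
        threshold=t,
        overall_pd=pd_overall,
        density_grid=dgrid,
        zonal=zpd,
        moran=moran,
        crop=(r0, r1, c0, c1),
    )


def analyze_cohort(subjects: list[CohortSubject], **kwargs) -> list[SubjectRecord]:
    """Analyze every phantom of a synthetic cohort into SubjectRecords."""
    records = []
    for s in subjects:
        a = analyze_image(s.phantom.image, s.phantom.breast_mask, **kwargs)
        records.append(
            SubjectRecord(
                subject_id=s.subject_id,
                age=s.age,
                birads=s.birads,
                overall_pd=a.overall_pd,
                zonal_pd=a.zonal,
                moran_i=a.moran.I,
                pattern=a.moran.pattern,
                regional=a.density_grid.pd,
            )
        )
    return records
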