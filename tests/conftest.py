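"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mbd.cohort import SubjectRecord
from mbd.phantom import PhantomSpec, generate_phantom
from mbd.regional import TileGrid, ZonalPD, make_grid


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; no shared code with the package)


def brute_force_kapur(counts: np.ndarray) -> int:
    """Exhaustive two-class entropy maximization over all 255 candidate splits."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    best_t, best_psi = None, -math.inf
    for t in range(255):
        low = counts[: t + 1]
        high = counts[t + 1 :]
        pl, ph = low.sum() / total, high.sum() / total
        if pl <= 0 or ph <= 0:
            continue
        psi = 0.0
        for c in low:
            if c > 0:
                q = (c / total) / pl
                psi -= q * math.log(q)
        for c in high:
            if c > 0:
                q = (c / total) / ph
                psi -= q * math.log(q)
        if psi > best_psi + 1e-12:
            best_psi, best_t = psi, t
    return best_t


def brute_force_moran(values: np.ndarray, w: np.ndarray) -> float:
    """Triple-loop Moran's I over ordered pairs, straight from the formula."""
    x = np.asarray(values, dtype=float).ravel()
    n = len(x)
    xbar = sum(x) / n
    num = 0.0
    sw = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
            sw += w[i, j]
    den = sum((xi - xbar) ** 2 for xi in x)
    return n / sw * num / den


def brute_force_weights(grid: TileGrid, scheme: str) -> np.ndarray:
    """Pairwise tile weights from first principles (midpoint geometry)."""
    n = grid.rows * grid.cols
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ri, ci = divmod(i, grid.cols)
            rj, cj = divmod(j, grid.cols)
            d2 = (ri - rj) ** 2 + (ci - cj) ** 2
            if scheme == "inverse_distance_squared":
                w[i, j] = 1.0 / d2
            elif scheme == "rook":
                w[i, j] = 1.0 if d2 == 1 else 0.0
            elif scheme == "queen":
                w[i, j] = 1.0 if d2 == 1 else (0.5 if d2 == 2 else 0.0)
    return w


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(
        PhantomSpec(dense_fraction=0.25, noise_sd=0.0, seed=7, placement="uniform")
    )


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(
        PhantomSpec(dense_fraction=0.25, noise_sd=10.0, seed=7, placement="middle")
    )


@pytest.fixture(scope="session")
def small_grid():
    return make_grid(96, 72)


def make_null_records(n: int, seed: int) -> list[SubjectRecord]:
    """Subject records with no planted effects: every variable independent."""
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n):
        zon = rng.uniform(0.0, 60.0, 3)
        records.append(
            SubjectRecord(
                subject_id=f"N{k:04d}",
                age=float(rng.uniform(35, 90)),
                birads=str(rng.choice(list("ABCD"))),
                overall_pd=float(rng.uniform(0, 60)),
                zonal_pd=ZonalPD(posterior=zon[0], middle=zon[1], anterior=zon[2]),
                moran_i=float(rng.normal(0, 0.2)),
                pattern="clustered" if rng.random() < 0.5 else "scattered",
            )
        )
    return records
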