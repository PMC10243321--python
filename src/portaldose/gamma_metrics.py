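"""Global 2D gamma-index analysis and dose-error statistics.

The gamma index (Low et al.) combines a dose-difference criterion (percent
of the maximum reference dose, "global" normalization) with a
distance-to-agreement (DTA) criterion:

    gamma(r) = min over displacements d of
               sqrt( (|d| / dta)^2
                     + ((D_eval(r + d) - D_ref(r)) / (tol% x max D_ref))^2 )

evaluated on every reference pixel above a low-dose threshold, with the
evaluated distribution bilinearly interpolated at sub-pixel displacements.
A pixel passes when gamma <= 1.

Two implementations are provided: :func:`gamma_map`, vectorized over pixels
with an early-exit over the displacement lattice, and
:func:`brute_force_gamma`, a definitionally transparent per-pixel search
used as the reference oracle on small grids.  At matched lattice settings
they agree to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DoseDistribution, GridSpec

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "gamma_map",
    "brute_force_gamma",
    "dose_errors",
    "profile_extract",
]


@dataclass(frozen=True)
class GammaCriteria:
    """Acceptance criteria for the gamma analysis (global normalization)."""

    dose_tol: float = 2.0  # percent of max reference dose
    dta: float = 2.0  # mm
    low_dose_threshold: float = 10.0  # percent of max reference dose

    def __post_init__(self) -> None:
        if self.dose_tol <= 0 or self.dta <= 0 or self.low_dose_threshold <= 0:
            raise ValueError("all gamma criteria must be > 0")


@dataclass
class GammaResult:
    """Per-pixel gamma map (NaN where unanalyzed) plus summary statistics."""

    gamma_map: np.ndarray
    mean_gamma: float
    passing_rate: float  # percent of analyzed pixels with gamma <= 1
    n_analyzed: int
    criteria: GammaCriteria


def _displacement_lattice(
    dta: float, pitch: float, subsample: int, search_radius_factor: float
) -> np.ndarray:
    """Sub-pixel displacement lattice (mm), sorted by |d| then lexically."""
    spacing = pitch / subsample
    radius = search_radius_factor * dta
    kmax = int(np.floor(radius / spacing))
    ks = np.arange(-kmax, kmax + 1) * spacing
    dy, dx = np.meshgrid(ks, ks, indexing="ij")
    d = np.column_stack([dy.ravel(), dx.ravel()])
    norm = np.hypot(d[:, 0], d[:, 1])
    keep = norm <= radius
    d, norm = d[keep], norm[keep]
    order = np.lexsort((d[:, 1], d[:, 0], norm))
    return d[order]


def _check_pair(reference: DoseDistribution, evaluated: DoseDistribution) -> None:
    if reference.grid != evaluated.grid:
        raise ValueError("reference and evaluated must share one grid")
    if reference.values.max() <= 0:
        raise ValueError("max(reference) must be > 0")


def _summarize(gmap: np.ndarray, criteria: GammaCriteria) -> GammaResult:
    analyzed = ~np.isnan(gmap)
    vals = gmap[analyzed]
    return GammaResult(
        gamma_map=gmap,
        mean_gamma=float(vals.mean()),
        passing_rate=float((vals <= 1.0).mean() * 100.0),
        n_analyzed=int(analyzed.sum()),
        criteria=criteria,
    )


def gamma_map(
    reference: DoseDistribution,
    evaluated: DoseDistribution,
    criteria: GammaCriteria = GammaCriteria(),
    subsample: int = 10,
    search_radius_factor: float = 3.0,
) -> GammaResult:
    """Global gamma analysis of ``evaluated`` against ``reference``.

    Vectorized over pixels; the displacement lattice is walked outward and
    abandoned as soon as its pure-distance term can no longer lower any
    pixel's gamma.
    """
    _check_pair(reference, evaluated)
    ref = reference.values
    ev = evaluated.values
    pitch = reference.grid.pixel_pitch
    dmax = ref.max()
    analyzed = ref >= criteria.low_dose_threshold / 100.0 * dmax
    if not analyzed.any():
        raise ValueError("empty analysis region: all pixels below threshold")
    dose_denom = criteria.dose_tol / 100.0 * dmax

    n = ref.shape[0]
    ii, jj = np.nonzero(analyzed)
    ref_a = ref[ii, jj]
    best = np.full(ref_a.shape, np.inf)

    for dy, dx in _displacement_lattice(
        criteria.dta, pitch, subsample, search_radius_factor
    ):
        dist2 = (dy * dy + dx * dx) / (criteria.dta**2)
        if dist2 >= best.max():
            break  # sorted lattice: no later displacement can improve any pixel
        py = ii + dy / pitch
        px = jj + dx / pitch
        valid = (py >= 0) & (py <= n - 1) & (px >= 0) & (px <= n - 1)
        if not valid.any():
            continue
        ev_d = _bilinear(ev, py[valid], px[valid])
        dd = (ev_d - ref_a[valid]) / dose_denom
        cand = dist2 + dd * dd
        sub = best[valid]
        best[valid] = np.where(cand < sub, cand, sub)

    gmap = np.full(ref.shape, np.nan)
    gmap[ii, jj] = np.sqrt(best)
    return _summarize(gmap, criteria)


def _bilinear(arr: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at fractional index positions inside the grid."""
    n_rows, n_cols = arr.shape
    f_y = np.minimum(np.floor(y).astype(int), n_rows - 2)
    f_x = np.minimum(np.floor(x).astype(int), n_cols - 2)
    t_y = y - f_y
    t_x = x - f_x
    return (
        arr[f_y, f_x] * (1 - t_y) * (1 - t_x)
        + arr[f_y + 1, f_x] * t_y * (1 - t_x)
        + arr[f_y, f_x + 1] * (1 - t_y) * t_x
        + arr[f_y + 1, f_x + 1] * t_y * t_x
    )


def brute_force_gamma(
    reference: DoseDistribution,
    evaluated: DoseDistribution,
    criteria: GammaCriteria = GammaCriteria(),
    subsample: int = 10,
    search_radius_factor: float = 3.0,
    max_side: int = 64,
) -> GammaResult:
    """Exhaustive per-pixel gamma search; reference oracle for small grids.

    Walks every lattice displacement for every analyzed pixel with scalar
    bookkeeping and its own inline interpolation — deliberately simple.
    """
    _check_pair(reference, evaluated)
    ref = reference.values
    ev = evaluated.values
    n = ref.shape[0]
    if n > max_side:
        raise ValueError(f"brute force refuses grids larger than {max_side}^2")
    pitch = reference.grid.pixel_pitch
    dmax = ref.max()
    threshold = criteria.low_dose_threshold / 100.0 * dmax
    dose_denom = criteria.dose_tol / 100.0 * dmax
    lattice = _displacement_lattice(criteria.dta, pitch, subsample, search_radius_factor)

    gmap = np.full(ref.shape, np.nan)
    any_analyzed = False
    for i in range(n):
        for j in range(n):
            if ref[i, j] < threshold:
                continue
            any_analyzed = True
            best = np.inf
            for dy, dx in lattice:
                dist2 = (dy * dy + dx * dx) / (criteria.dta**2)
                if dist2 >= best:
                    continue
                py = i + dy / pitch
                px = j + dx / pitch
                if py < 0 or py > n - 1 or px < 0 or px > n - 1:
                    continue
                fy = min(int(np.floor(py)), n - 2)
                fx = min(int(np.floor(px)), n - 2)
                ty = py - fy
                tx = px - fx
                val = (
                    ev[fy, fx] * (1 - ty) * (1 - tx)
                    + ev[fy + 1, fx] * ty * (1 - tx)
                    + ev[fy, fx + 1] * (1 - ty) * tx
                    + ev[fy + 1, fx + 1] * ty * tx
                )
                dd = (val - ref[i, j]) / dose_denom
                cand = dist2 + dd * dd
                if cand < best:
                    best = cand
            gmap[i, j] = np.sqrt(best)
    if not any_analyzed:
        raise ValueError("empty analysis region: all pixels below threshold")
    return _summarize(gmap, criteria)


def dose_errors(
    reference: DoseDistribution,
    evaluated: DoseDistribution,
    threshold_pct: float = 10.0,
) -> tuple[float, float]:
    """(mean absolute error in Gy, mean relative error in percent of max).

    Computed over reference pixels at or above ``threshold_pct`` percent of
    the maximum reference dose; the relative error is "global", i.e.
    normalized by the maximum reference dose.
    """
    _check_pair(reference, evaluated)
    ref = reference.values
    dmax = ref.max()
    region = ref >= threshold_pct / 100.0 * dmax
    if not region.any():
        raise ValueError("empty analysis region: all pixels below threshold")
    abs_err = float(np.abs(evaluated.values[region] - ref[region]).mean())
    rel_err = abs_err / dmax * 100.0
    return abs_err, rel_err


def profile_extract(
    values: np.ndarray, grid: GridSpec, axis: str = "left-right"
) -> tuple[np.ndarray, np.ndarray]:
    """1D profile through the beam-axis pixel.

    ``axis='left-right'`` returns the central row (varying x);
    ``axis='up-down'`` the central column.  Returns (coords_mm, values).
    """
    c = grid.center_index
    if axis == "left-right":
        prof = np.asarray(values)[c, :]
    elif axis == "up-down":
        prof = np.asarray(values)[:, c]
    else:
        raise ValueError(f"axis must be 'left-right' or 'up-down', got {axis!r}")
    return grid.coords(), prof.copy()
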