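"""Phenotypic space of stomatal traits: 2-D KDE, overlap, iso-conductance.

Species position themselves in the (log a_max, log D) plane — large
sparse stomata versus small dense ones — and the anatomical maximum
conductance they can reach is a function of that position. To compare
whole plant communities, each community's specimen cloud is smoothed
into a probability distribution on a shared 100×100 grid with a
product-Gaussian kernel using axis-wise normal-reference bandwidths
(the convention of the classical kde2d estimator: kernel SD =
1.06·min(s, IQR/1.34)·n^(−1/5) per axis), cell-normalised to sum to 1.
Overlap between two such grids is the Jensen–Shannon divergence

    JSD(p, q) = ½ KL(p‖m) + ½ KL(q‖m),   m = (p+q)/2,

with base-2 logarithms, so 0 means identical distributions and 1
disjoint support. Iso-g_smax contours — the (a_max, D) loci of constant
anatomical conductance — follow in closed form because the conductance
equation is linear in D.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core_data import SpecimenRecord
from .stomatal_morphology import D_W, V_AIR

__all__ = [
    "GridSpec", "DensityGrid",
    "normal_reference_bandwidth",
    "density_grid", "jsd", "iso_gsmax_contours", "community_overlap",
]


@dataclass(frozen=True)
class GridSpec:
    """Axis ranges (in log10 trait units) and resolution of a density grid."""

    x_range: tuple[float, float]  # log10 a_max (um^2)
    y_range: tuple[float, float]  # log10 D (mm^-2)
    gridsize: int = 100


@dataclass
class DensityGrid:
    """Normalised cell probabilities over (log a_max, log D).

    ``x``/``y`` are the cell-centre coordinates; ``prob[i, j]`` is the
    probability of cell (x=i, y=j); probabilities sum to one.
    """

    x: np.ndarray
    y: np.ndarray
    prob: np.ndarray
    bandwidths: tuple[float, float]

    def same_axes(self, other: "DensityGrid", rtol: float = 1e-9) -> bool:
        return (self.prob.shape == other.prob.shape
                and np.allclose(self.x, other.x, rtol=rtol)
                and np.allclose(self.y, other.y, rtol=rtol))


def normal_reference_bandwidth(values: np.ndarray) -> float:
    """Kernel SD by the per-axis normal reference rule.

    1.06·min(s, IQR/1.34)·n^(−1/5); degenerate spreads fall back to a
    tiny positive width so a point mass still lands in its nearest cell.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    s = float(np.std(v, ddof=1)) if n > 1 else 0.0
    q1, q3 = np.percentile(v, [25, 75])
    iqr_est = (q3 - q1) / 1.34
    spread = min(x for x in (s, iqr_est) if x > 0) if max(s, iqr_est) > 0 else 0.0
    if spread == 0.0:
        scale = max(abs(float(np.mean(v))), 1.0)
        return 1e-9 * scale
    return 1.06 * spread * n ** (-0.2)


def density_grid(points: Sequence[tuple[float, float]],
                 grid_spec: GridSpec | None = None,
                 gridsize: int = 100,
                 pad: float = 0.1,
                 bandwidth_scale: float = 1.0) -> DensityGrid:
    """Smoothed probability grid from (a_max, D) points.

    Points are log10-transformed; the grid spans the data range padded by
    ``pad`` of the span unless an explicit ``grid_spec`` fixes the axes
    (required when two grids will be compared). Points outside a declared
    grid range trigger a mass-leakage warning, not an error.
    ``bandwidth_scale`` multiplies both normal-reference bandwidths.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two (a_max, D) points")
    if np.any(pts <= 0):
        raise ValueError("trait values must be positive")
    lx = np.log10(pts[:, 0])
    ly = np.log10(pts[:, 1])
    if grid_spec is None:
        grid_spec = _auto_spec([lx], [ly], gridsize, pad)
    else:
        gridsize = grid_spec.gridsize
        if (lx.min() < grid_spec.x_range[0] or lx.max() > grid_spec.x_range[1]
                or ly.min() < grid_spec.y_range[0]
                or ly.max() > grid_spec.y_range[1]):
            warnings.warn("points outside the declared grid range: some "
                          "probability mass will leak", UserWarning,
                          stacklevel=2)
    gx = np.linspace(*grid_spec.x_range, gridsize)
    gy = np.linspace(*grid_spec.y_range, gridsize)
    # floor bandwidths at half a cell so degenerate clouds still land in
    # their nearest cells instead of vanishing between grid nodes
    hx = max(normal_reference_bandwidth(lx) * bandwidth_scale,
             0.5 * (gx[1] - gx[0]))
    hy = max(normal_reference_bandwidth(ly) * bandwidth_scale,
             0.5 * (gy[1] - gy[0]))
    # product-Gaussian kernel evaluated on the grid, one outer product per axis
    kx = np.exp(-0.5 * ((gx[:, None] - lx[None, :]) / hx) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None] - ly[None, :]) / hy) ** 2)
    dens = kx @ ky.T  # (gridsize, gridsize): sum over points
    total = dens.sum()
    if total <= 0:
        raise ValueError("density vanished on the grid")
    return DensityGrid(x=gx, y=gy, prob=dens / total, bandwidths=(hx, hy))


def _auto_spec(lx_groups: list[np.ndarray], ly_groups: list[np.ndarray],
               gridsize: int, pad: float) -> GridSpec:
    lx = np.concatenate(lx_groups)
    ly = np.concatenate(ly_groups)

    def padded(lo: float, hi: float) -> tuple[float, float]:
        span = hi - lo
        if span == 0:
            span = max(abs(hi), 1.0) * 0.1
        return lo - pad * span, hi + pad * span

    return GridSpec(x_range=padded(lx.min(), lx.max()),
                    y_range=padded(ly.min(), ly.max()),
                    gridsize=gridsize)


def jsd(p: DensityGrid, q: DensityGrid) -> float:
    """Jensen–Shannon divergence between two grids, base 2, in [0, 1].

    Requires identical axes. Zero cells contribute zero to their own KL
    term; a cell empty in one distribution but not the other contributes
    finitely through the mixture.
    """
    if not p.same_axes(q):
        raise ValueError("grids have mismatched axes")
    return _jsd_arrays(p.prob, q.prob)


def _jsd_arrays(p: np.ndarray, q: np.ndarray) -> float:
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    m = 0.5 * (p + q)
    m_safe = np.where(m > 0, m, 1.0)  # cells empty in both contribute 0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        kl_p = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / m_safe), 0.0)
        kl_q = np.where(q > 0, q * np.log2(np.where(q > 0, q, 1.0) / m_safe), 0.0)
    return float(0.5 * kl_p.sum() + 0.5 * kl_q.sum())


def iso_gsmax_contours(levels_mmol: Sequence[float],
                       amax_range: tuple[float, float],
                       pore_depth_rule: Callable[[np.ndarray], np.ndarray] | float,
                       n_points: int = 200) -> list[pd.DataFrame]:
    """Iso-conductance lines in the (a_max, D) plane.

    The anatomical conductance equation is linear in D, so for a target
    level g (mmol m⁻² s⁻¹) the locus is closed-form::

        D(a_max) = g · (p + (π/2)·sqrt(a_max/π)) / ((d_w/v) · a_max)

    ``pore_depth_rule`` maps a_max (µm²) to pore depth p (µm), or is a
    constant depth. Returns one DataFrame (level, amax_um2, d_per_mm2)
    per level, with a_max log-spaced over ``amax_range`` (µm²).
    """
    lo, hi = amax_range
    if lo <= 0 or hi <= lo:
        raise ValueError("amax_range must be positive and increasing")
    amax = np.logspace(math.log10(lo), math.log10(hi), n_points)
    if callable(pore_depth_rule):
        p_um = np.asarray(pore_depth_rule(amax), dtype=float)
    else:
        p_um = np.full_like(amax, float(pore_depth_rule))
    amax_m2 = amax * 1e-12
    p_m = p_um * 1e-6
    depth_term = p_m + (math.pi / 2.0) * np.sqrt(amax_m2 / math.pi)
    out = []
    for level in levels_mmol:
        g_mol = level * 1e-3
        d_m2 = g_mol * depth_term / ((D_W / V_AIR) * amax_m2)
        out.append(pd.DataFrame({
            "level_mmol": level,
            "amax_um2": amax,
            "d_per_mm2": d_m2 / 1e6,
        }))
    return out


def _trait_points(records: Iterable[SpecimenRecord]
                  ) -> list[tuple[float, float]]:
    from .stomatal_morphology import leaf_gsmax
    pts = []
    for rec in records:
        res = leaf_gsmax(rec)
        if res is not None:
            pts.append((res.amax, rec.stomatal_density))
    return pts


def community_overlap(community_a: Iterable[SpecimenRecord],
                      community_b: Iterable[SpecimenRecord],
                      gridsize: int = 100,
                      pad: float = 0.1,
                      ) -> tuple[float, DensityGrid, DensityGrid]:
    """JSD between two communities' stomatal-trait distributions.

    Builds one shared grid spanning the joint (log a_max, log D) range of
    both communities, padded by ``pad`` of the span per axis, and returns
    (JSD, grid_a, grid_b).
    """
    pts_a = _trait_points(community_a)
    pts_b = _trait_points(community_b)
    if len(pts_a) < 2 or len(pts_b) < 2:
        raise ValueError("each community needs at least two specimens with "
                         "complete anatomy")
    la = np.log10(np.asarray(pts_a))
    lb = np.log10(np.asarray(pts_b))
    spec = _auto_spec([la[:, 0], lb[:, 0]], [la[:, 1], lb[:, 1]],
                      gridsize, pad)
    grid_a = density_grid(pts_a, grid_spec=spec)
    grid_b = density_grid(pts_b, grid_spec=spec)
    return jsd(grid_a, grid_b), grid_a, grid_b
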