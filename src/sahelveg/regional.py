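"""Regional aggregation: petagram totals, shares, significant-trend areas
and rainfall-slope comparison masks.

Pixel-level biomass maps (kg/ha) on an equal-area grid (default 25 km,
625 km² per pixel) are summed to regional totals in petagrams; per-pixel
trend maps are reduced to significant-area statistics at raw P < 0.05
(no multiple-testing correction, matching common practice for trend maps);
and the core versus early/late rainfall slope maps are compared pixel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "aggregate_totals", "wpf_share_pct",
           "significant_area", "rainfall_slope_mask"]

KG_PER_PG = 1.0e12
HA_PER_KM2 = 100.0


@dataclass
class GridSpec:
    """Equal-area pixel grid with a boolean region mask (e.g. the
    150-600 mm mean-annual-rainfall belt)."""

    pixel_area_km2: float = 625.0
    region_mask: np.ndarray = field(default_factory=lambda: np.ones((1, 1), bool))

    def __post_init__(self) -> None:
        if self.pixel_area_km2 <= 0:
            raise ValueError("pixel_area_km2 must be positive")
        self.region_mask = np.asarray(self.region_mask, dtype=bool)

    @property
    def n_region_pixels(self) -> int:
        return int(self.region_mask.sum())

    @property
    def region_area_km2(self) -> float:
        return self.n_region_pixels * self.pixel_area_km2


def aggregate_totals(mass_map: np.ndarray, grid: GridSpec) -> float:
    """Regional total in Pg of a kg/ha mass map (NaN pixels contribute 0)."""
    mass = np.asarray(mass_map, dtype=float)
    if mass.shape != grid.region_mask.shape:
        raise ValueError("mass map and region mask shapes differ")
    kg = np.nansum(mass[grid.region_mask]) * grid.pixel_area_km2 * HA_PER_KM2
    return float(kg / KG_PER_PG)


def wpf_share_pct(agh_pg: float, wpf_pg: float) -> float:
    """Woody-foliage share of total green mass, percent."""
    total = agh_pg + wpf_pg
    if total <= 0:
        return float("nan")
    return 100.0 * wpf_pg / total


def significant_area(slope_map: np.ndarray, p_map: np.ndarray, grid: GridSpec,
                     alpha: float = 0.05) -> dict:
    """Area (km²) and share (%) of the region with significant trends,
    separately for increases and decreases."""
    slope = np.asarray(slope_map, dtype=float)
    p = np.asarray(p_map, dtype=float)
    m = grid.region_mask
    sig = (p < alpha) & m & np.isfinite(slope) & np.isfinite(p)
    out = {}
    for name, sign_mask in (("increase", slope > 0), ("decrease", slope < 0)):
        n = int((sig & sign_mask).sum())
        area = n * grid.pixel_area_km2
        pct = 100.0 * n / grid.n_region_pixels if grid.n_region_pixels else float("nan")
        out[name] = {"n_pixels": n, "area_km2": area, "pct_of_region": pct}
    return out


def rainfall_slope_mask(slope_c_map: np.ndarray, slope_el_map: np.ndarray,
                        grid: GridSpec) -> tuple[np.ndarray, float]:
    """Pixels where the early/late-rain slope strictly exceeds the
    core-rain slope, and the share (%) of the region where that holds."""
    sc = np.asarray(slope_c_map, dtype=float)
    sel = np.asarray(slope_el_map, dtype=float)
    if sc.shape != sel.shape or sc.shape != grid.region_mask.shape:
        raise ValueError("slope maps and region mask shapes differ")
    mask = (sel > sc) & grid.region_mask
    pct = (100.0 * int(mask.sum()) / grid.n_region_pixels
           if grid.n_region_pixels else float("nan"))
    return mask, pct
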