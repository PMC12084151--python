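"""Land-cover fusion and PFT / LAI assignment.

A coarse (~1 km) raster carries plant-functional-type (PFT) fractional
coverages χ_j for 16 PFTs plus an urban class, emulating a MODIS-style
product; a fine (~10 m) raster inside urban areas resolves street trees,
parks and other greenspace in four vegetation classes (tree, shrub, grass,
crop), emulating a FROM-GLC10-style product. Fusion keeps the coarse χ
outside the urban mask and, inside it, replaces χ by the areal fraction of
each fine vegetation class within the coarse cell, reclassified to PFTs:
urban trees are assumed broadleaf, evergreen or deciduous by latitude;
shrub, grass and crop map to a single PFT each.

Per-cell leaf area index then follows an empirical per-PFT reference,
LAI = Σ_j χ_j · LAI_ref(j). The reference table, the urban class→PFT map
and the coarse-product class map ship as editable CSVs under
``greenozone/data``.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .grid import Grid

N_PFT = 16
CLASS_CODES = {"non-vegetated": 0, "tree": 1, "shrub": 2, "grass": 3, "crop": 4}
CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}

# urban tree phenology rule: broadleaf evergreen equatorward of the cutoff
# (subtropical, e.g. Guangzhou ~23°N), deciduous poleward (e.g. Beijing ~40°N)
PHENOLOGY_LAT_CUTOFF = 30.0
_BROADLEAF_EVERGREEN = 5     # broadleaf evergreen temperate tree
_BROADLEAF_DECIDUOUS = 7     # broadleaf deciduous temperate tree
_URBAN_PFT = {"shrub": 9, "grass": 13, "crop": 15}


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("greenozone.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_lai_table(path: str | None = None) -> pd.Series:
    """Per-PFT reference LAI (m² m⁻²), indexed by PFT index 1–16."""
    df = pd.read_csv(path) if path else _load_table("lai_reference.csv")
    s = df.set_index("pft_index")["lai_ref"]
    missing = set(range(1, N_PFT + 1)) - set(s.index)
    if missing:
        raise ValueError(f"LAI table missing PFT entries: {sorted(missing)}")
    return s


def load_pft_names() -> pd.DataFrame:
    return _load_table("pft_classes.csv")


@dataclass
class LandCoverFusion:
    """One study domain's land cover: fine classes, coarse χ, urban mask."""

    coarse_grid: Grid
    fine_grid: Grid
    fine_classes: np.ndarray      # (ny_f, nx_f) int codes per CLASS_CODES
    coarse_chi: np.ndarray        # (16, ny, nx) fractions, Σ_j χ_j <= 1
    urban_mask: np.ndarray        # (ny, nx) bool

    def __post_init__(self) -> None:
        self.validate()

    @property
    def refine_factor(self) -> int:
        f = self.coarse_grid.res_km / self.fine_grid.res_km
        return int(round(f))

    def validate(self) -> None:
        f = self.coarse_grid.res_km / self.fine_grid.res_km
        if abs(f - round(f)) > 1e-9:
            raise ValueError("fine resolution must divide coarse resolution")
        if self.fine_classes.shape != self.fine_grid.shape:
            raise ValueError("fine raster shape mismatch")
        if self.coarse_chi.shape != (N_PFT,) + self.coarse_grid.shape:
            raise ValueError("coarse χ raster must be (16, ny, nx)")
        if self.urban_mask.shape != self.coarse_grid.shape:
            raise ValueError("urban mask shape mismatch")
        if np.min(self.coarse_chi) < -1e-12:
            raise ValueError("χ fractions must be nonnegative")
        if np.max(self.coarse_chi.sum(axis=0)) > 1.0 + 1e-9:
            raise ValueError("Σ_j χ_j must not exceed 1")


@dataclass
class PFTMap:
    """Fused per-cell PFT fractional coverage χ_j on the coarse grid."""

    grid: Grid
    chi: np.ndarray               # (16, ny, nx)
    source_mask: np.ndarray       # bool: True = fine-urban, False = coarse

    def __post_init__(self) -> None:
        if self.chi.shape != (N_PFT,) + self.grid.shape:
            raise ValueError("χ must be (16, ny, nx)")
        if np.min(self.chi) < -1e-12:
            raise ValueError("χ fractions must be nonnegative")
        if np.max(self.chi.sum(axis=0)) > 1.0 + 1e-9:
            raise ValueError("Σ_j χ_j must not exceed 1")

    def total_vegetated(self) -> np.ndarray:
        return self.chi.sum(axis=0)


@dataclass
class LAIMap:
    """Per-cell leaf area index (m² m⁻²) on the coarse grid."""

    grid: Grid
    lai: np.ndarray               # (ny, nx), >= 0
    epoch: int = 0                # 8-day composite index

    def __post_init__(self) -> None:
        if self.lai.shape != self.grid.shape:
            raise ValueError("LAI raster shape mismatch")
        if np.min(self.lai) < -1e-12:
            raise ValueError("LAI must be nonnegative")


def classify_urban_pft(veg_class: str, latitude: float,
                       phenology_lat_cutoff: float = PHENOLOGY_LAT_CUTOFF) -> int:
    """Map an urban fine-raster vegetation class to a PFT index (1–16).

    Urban trees are all broadleaf; evergreen when ``|latitude|`` is below
    the phenology cutoff (subtropical), deciduous otherwise. Shrub, grass
    and crop are latitude-independent.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude out of range")
    if veg_class == "tree":
        if abs(latitude) < phenology_lat_cutoff:
            return _BROADLEAF_EVERGREEN
        return _BROADLEAF_DECIDUOUS
    try:
        return _URBAN_PFT[veg_class]
    except KeyError:
        raise ValueError(f"unknown vegetation class: {veg_class!r}") from None


def fuse_landcover(fine: np.ndarray, coarse_chi: np.ndarray,
                   mask: np.ndarray, coarse_grid: Grid,
                   phenology_lat_cutoff: float = PHENOLOGY_LAT_CUTOFF) -> PFTMap:
    """Fuse the fine urban vegetation raster into the coarse PFT raster.

    Outside the urban mask χ is copied from the coarse input; inside, χ_j
    is the areal fraction of fine cells of each vegetation class within
    the coarse cell, reclassified to PFTs by :func:`classify_urban_pft`
    using each row's latitude. Exact area bookkeeping: the vegetated χ
    total of an urban cell equals the fine-raster vegetated fraction.
    """
    coarse_chi = np.asarray(coarse_chi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    ny, nx = coarse_grid.shape
    fy, fx = np.asarray(fine).shape
    if fy % ny or fx % nx or (fy // ny) != (fx // nx):
        raise ValueError("fine raster is not an integer refinement of the grid")
    f = fy // ny
    if coarse_chi.shape != (N_PFT, ny, nx) or mask.shape != (ny, nx):
        raise ValueError("misaligned coarse rasters")

    chi = coarse_chi.copy()
    chi[:, mask] = 0.0
    lat = coarse_grid.latitudes()
    blocks = np.asarray(fine).reshape(ny, f, nx, f)
    for cls, code in CLASS_CODES.items():
        if code == 0:
            continue
        frac = (blocks == code).mean(axis=(1, 3))       # areal fraction
        if cls == "tree":
            pft_row = np.array([classify_urban_pft("tree", la,
                                                   phenology_lat_cutoff)
                                for la in lat])
            for j in np.unique(pft_row):
                rows = pft_row == j
                sel = mask & rows[:, None]
                chi[j - 1][sel] += frac[sel]
        else:
            j = classify_urban_pft(cls, 0.0)
            chi[j - 1][mask] += frac[mask]
    return PFTMap(coarse_grid, chi, mask.copy())


def fuse(lc: LandCoverFusion,
         phenology_lat_cutoff: float = PHENOLOGY_LAT_CUTOFF) -> PFTMap:
    """Convenience wrapper fusing a :class:`LandCoverFusion` bundle."""
    return fuse_landcover(lc.fine_classes, lc.coarse_chi, lc.urban_mask,
                          lc.coarse_grid, phenology_lat_cutoff)


def lai_from_pft(pft_map: PFTMap, lai_table: pd.Series | None = None,
                 epoch: int = 0) -> LAIMap:
    """Cell LAI = Σ_j χ_j · LAI_ref(j); zero where unvegetated."""
    table = load_lai_table() if lai_table is None else lai_table
    missing = set(range(1, N_PFT + 1)) - set(table.index)
    if missing:
        raise ValueError(f"LAI table missing PFT entries: {sorted(missing)}")
    ref = table.reindex(range(1, N_PFT + 1)).to_numpy(dtype=float)
    lai = np.tensordot(ref, pft_map.chi, axes=(0, 0))
    return LAIMap(pft_map.grid, lai, epoch)
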