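"""Two-species community structure from drop plates and confocal stacks.

The fluorescent species (GFP-tagged *S. oneidensis*) is counted directly
from fluorescent colonies; the fermenter is the remainder (total minus
fluorescent).  On the electrode, the GFP channel marks the metal reducer
and the DAPI channel marks all biomass, so the thresholded GFP/DAPI
voxel-volume ratio estimates the reducer's biovolume share of the biofilm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .config import InputError

SPECIES_FLUORESCENT = "S_oneidensis"
SPECIES_NONFLUORESCENT = "E_coli"


@dataclass
class PlateCount:
    """One drop-plate observation at a given dilution."""

    compartment: str            # "planktonic" or "biofilm"
    time_h: float
    dilution: float             # unitless factor <= 1
    plated_volume_mL: float
    total_colonies: int
    fluorescent_colonies: int

    def __post_init__(self) -> None:
        if self.compartment not in ("planktonic", "biofilm"):
            raise InputError("compartment must be 'planktonic' or 'biofilm'")
        if not 0 < self.dilution <= 1:
            raise InputError("dilution must lie in (0, 1]")
        if self.plated_volume_mL <= 0:
            raise InputError("plated volume must be > 0")
        if self.total_colonies < 0 or self.fluorescent_colonies < 0:
            raise InputError("colony counts must be >= 0")
        if self.fluorescent_colonies > self.total_colonies:
            raise InputError("fluorescent colonies cannot exceed total")


@dataclass
class CommunityProfile:
    """Per-species CFU/mL and proportions, long format.

    ``table`` columns: compartment, time_h, species, cfu_per_ml,
    proportion, n_countable_plates.  Time points with no countable plate
    carry NaN estimates.
    """

    table: pd.DataFrame


@dataclass
class ImageStack:
    """Two-channel 3-D voxel stack of an electrode biofilm."""

    gfp_voxels: np.ndarray
    dapi_voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    threshold_method: str = "otsu"
    truth_gfp_mask: np.ndarray | None = field(default=None, repr=False)
    truth_dapi_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.gfp_voxels = np.asarray(self.gfp_voxels, dtype=float)
        self.dapi_voxels = np.asarray(self.dapi_voxels, dtype=float)
        if self.gfp_voxels.shape != self.dapi_voxels.shape:
            raise InputError("GFP and DAPI stacks must have the same shape")
        if (self.gfp_voxels < 0).any() or (self.dapi_voxels < 0).any():
            raise InputError("intensities must be >= 0")
        if any(s <= 0 for s in self.voxel_size_um):
            raise InputError("voxel size must be positive")


@dataclass
class BiovolumeResult:
    """Biovolume per channel (um^3) and the labeled fraction GFP/DAPI."""

    fraction: float
    gfp_biovolume_um3: float
    dapi_biovolume_um3: float
    clipped: bool = False


def plate_counts_to_cfu(counts: list[PlateCount],
                        countable_range: tuple[int, int] = (3, 300)) -> CommunityProfile:
    """Estimate per-species CFU/mL from drop-plate counts.

    Within each compartment/time group only countable plates (total
    colonies inside ``countable_range``) contribute.  Dilutions and
    replicates are pooled: CFU/mL = sum(colonies) / sum(dilution x
    plated volume), the weighted mean over plates with weights
    proportional to their effective plated volume (the minimum-variance
    combination under Poisson counting).  The fluorescent species is
    counted from fluorescent colonies, the other from the remainder.
    """
    if not counts:
        return CommunityProfile(pd.DataFrame(columns=[
            "compartment", "time_h", "species", "cfu_per_ml",
            "proportion", "n_countable_plates"]))
    lo, hi = countable_range
    rows = []
    df = pd.DataFrame([vars(c) for c in counts])
    for (comp, t), grp in df.groupby(["compartment", "time_h"], sort=True):
        ok = grp[(grp.total_colonies >= lo) & (grp.total_colonies <= hi)]
        if len(ok) == 0:
            for sp in (SPECIES_FLUORESCENT, SPECIES_NONFLUORESCENT):
                rows.append((comp, t, sp, np.nan, np.nan, 0))
            continue
        eff_vol = (ok.dilution * ok.plated_volume_mL).sum()
        cfu_fluor = ok.fluorescent_colonies.sum() / eff_vol
        cfu_other = (ok.total_colonies - ok.fluorescent_colonies).sum() / eff_vol
        total = cfu_fluor + cfu_other
        p_fluor = cfu_fluor / total if total > 0 else np.nan
        rows.append((comp, t, SPECIES_FLUORESCENT, cfu_fluor, p_fluor, len(ok)))
        rows.append((comp, t, SPECIES_NONFLUORESCENT, cfu_other,
                     1 - p_fluor if total > 0 else np.nan, len(ok)))
    return CommunityProfile(pd.DataFrame(
        rows, columns=["compartment", "time_h", "species", "cfu_per_ml",
                       "proportion", "n_countable_plates"]))


def _segment(channel: np.ndarray, method: str,
             fixed_threshold: float | None) -> np.ndarray:
    if fixed_threshold is not None or method == "fixed":
        if fixed_threshold is None:
            raise InputError("fixed threshold requested but no value given")
        return channel > fixed_threshold
    if method != "otsu":
        raise InputError(f"unknown threshold method {method!r}")
    if np.ptp(channel) == 0:       # constant channel: no separable foreground
        return np.zeros(channel.shape, dtype=bool)
    return channel > threshold_otsu(channel)


def biovolume_fraction(stack: ImageStack, method: str | None = None,
                       fixed_threshold: float | None = None) -> BiovolumeResult:
    """Thresholded two-channel biovolume ratio GFP/DAPI.

    Each channel is segmented on the whole stack (Otsu by default, or a
    fixed grey value); biovolume is the above-threshold voxel count times
    the voxel volume.  The fraction is clipped to [0, 1] with a warning
    if GFP segments larger than DAPI.
    """
    method = method or stack.threshold_method
    gfp_mask = _segment(stack.gfp_voxels, method, fixed_threshold)
    dapi_mask = _segment(stack.dapi_voxels, method, fixed_threshold)
    vox_um3 = float(np.prod(stack.voxel_size_um))
    gfp_bv = gfp_mask.sum() * vox_um3
    dapi_bv = dapi_mask.sum() * vox_um3
    if dapi_bv == 0:
        raise InputError("empty DAPI segmentation; biovolume fraction undefined")
    frac = gfp_bv / dapi_bv
    clipped = False
    if frac > 1.0:
        warnings.warn("GFP biovolume exceeds DAPI; clipping fraction to 1",
                      stacklevel=2)
        frac, clipped = 1.0, True
    return BiovolumeResult(fraction=float(frac), gfp_biovolume_um3=float(gfp_bv),
                           dapi_biovolume_um3=float(dapi_bv), clipped=clipped)


def community_timecourse(profiles: list[CommunityProfile]) -> pd.DataFrame:
    """Concatenate profiles into one tidy proportions-vs-time table."""
    tables = [p.table for p in profiles if len(p.table)]
    if not tables:
        return pd.DataFrame(columns=["compartment", "time_h", "species",
                                     "cfu_per_ml", "proportion",
                                     "n_countable_plates"])
    out = pd.concat(tables, ignore_index=True)
    return out.sort_values(["compartment", "time_h", "species"],
                           ignore_index=True)
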