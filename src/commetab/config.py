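"""Generator configuration: presets, parameter blocks and validation.

All calibration constants of the study system live here: a two-chamber
microbial fuel cell (MFC) run on 20 mM glucose, inoculated with a
fermenter (*E. coli*) and a dissimilatory metal reducer (*S. oneidensis*),
with a 1 kOhm external resistor and a 2 cm x 5 cm carbon-felt anode in a
20 mL chamber.  Presets encode the wild-type co-culture and the
hydrogenase-mutant co-culture conditions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence


class ConfigurationError(ValueError):
    """Raised when a generator configuration is physically inconsistent."""


class InputError(ValueError):
    """Raised when an analysis operation receives invalid input."""


@dataclass
class TraceParams:
    """Shape of the current-density curve and the measurement chain.

    The noiseless profile is piecewise linear: a rise from 0 to ``peak_j``
    at ``rise_rate``, a plateau until ``plateau_end_h``, then a linear
    decay reaching zero at ``zero_time_h``.  Voltage is recorded across
    ``resistor_ohm`` and normalised by ``electrode_area_cm2``.
    """

    peak_j: float = 2.0                # uA/cm^2
    rise_rate: float = 0.17            # uA/cm^2/h
    plateau_end_h: float = 48.0
    zero_time_h: float = 108.0
    noise_sd_j: float = 0.05           # uA/cm^2, additive Gaussian
    sample_interval_min: float = 5.0
    resistor_ohm: float = 1000.0
    electrode_area_cm2: float = 10.0   # projected single face of 2 x 5 cm felt

    def validate(self) -> None:
        if self.peak_j < 0:
            raise ConfigurationError("peak_j must be >= 0")
        if self.peak_j > 0 and self.rise_rate <= 0:
            raise ConfigurationError("rise_rate must be > 0 for a nonzero peak")
        if self.plateau_end_h >= self.zero_time_h:
            raise ConfigurationError("plateau_end_h must precede zero_time_h")
        if self.sample_interval_min <= 0:
            raise ConfigurationError("sample_interval_min must be > 0")
        if self.resistor_ohm <= 0 or self.electrode_area_cm2 <= 0:
            raise ConfigurationError("resistor and electrode area must be > 0")
        if self.noise_sd_j < 0:
            raise ConfigurationError("noise_sd_j must be >= 0")


@dataclass
class MetaboliteParams:
    """Mixed-acid fermentation time courses in the anolyte.

    Formate rises to ``formate_peak_mM`` at ``formate_peak_time_h`` and is
    depleted (consumed at the anode) by ``formate_depletion_time_h``;
    acetate sits near-constant; lactate stays below 1 mM.  With
    ``stoichiometric_mode`` on, production is capped at 2 mol of formate
    and 2 mol of acetate per mol of glucose consumed and the series is
    generated noise-free so the mol balance closes exactly.
    """

    glucose0_mM: float = 20.0
    formate_peak_mM: float = 45.0
    formate_peak_time_h: float = 48.0
    formate_depletion_time_h: float = 100.0
    acetate_level_mM: float = 10.0
    lactate_level_mM: float = 0.5
    noise_sd_mM: float = 0.5
    volume_L: float = 0.02
    stoichiometric_mode: bool = False
    duration_h: float = 120.0
    sample_interval_h: float = 2.0

    def validate(self) -> None:
        for name in ("glucose0_mM", "formate_peak_mM", "acetate_level_mM",
                     "lactate_level_mM", "noise_sd_mM"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.formate_peak_time_h >= self.formate_depletion_time_h:
            raise ConfigurationError(
                "formate_peak_time_h must precede formate_depletion_time_h")
        if self.volume_L <= 0:
            raise ConfigurationError("volume_L must be > 0")
        if self.sample_interval_h <= 0 or self.duration_h <= 0:
            raise ConfigurationError("sampling grid must be positive")


@dataclass
class CommunityParams:
    """Two-compartment community composition and its measurement.

    ``planktonic_ecoli_fraction`` is the true E. coli share of suspended
    cells; ``biofilm_so_biovolume_fraction`` the true S. oneidensis share
    of electrode-biofilm volume (the GFP-tagged species).  Plate-count and
    confocal-stack simulation parameters follow.
    """

    planktonic_ecoli_fraction: float = 0.98
    biofilm_so_biovolume_fraction: float = 0.60
    total_cfu_per_ml: float = 1e10
    dilutions: Sequence[float] = (1e-5, 1e-6, 1e-7)
    plated_volume_ml: float = 0.01
    n_replicates: int = 3
    stack_shape: tuple[int, int, int] = (16, 128, 128)
    voxel_size_um: tuple[float, float, float] = (2.0, 0.5, 0.5)
    signal_level: float = 100.0        # grey value of biomass voxels
    image_noise_sd: float = 5.0        # 5% of signal

    def validate(self) -> None:
        for name in ("planktonic_ecoli_fraction", "biofilm_so_biovolume_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.total_cfu_per_ml < 0:
            raise ConfigurationError("total_cfu_per_ml must be >= 0")
        if len(self.dilutions) == 0:
            raise ConfigurationError("dilutions must be non-empty")
        if any(d <= 0 or d > 1 for d in self.dilutions):
            raise ConfigurationError("dilutions must lie in (0, 1]")
        if self.plated_volume_ml <= 0:
            raise ConfigurationError("plated_volume_ml must be > 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if any(s <= 0 for s in self.stack_shape):
            raise ConfigurationError("stack dimensions must be positive")
        if any(s <= 0 for s in self.voxel_size_um):
            raise ConfigurationError("voxel size must be positive")
        if self.signal_level <= 0 or self.image_noise_sd < 0:
            raise ConfigurationError("invalid image intensity parameters")


@dataclass
class FlavinParams:
    """Fluorometric flavin quantification (440 nm ex / 525 nm em).

    Readings follow reading = intercept + blank + slope * conc + noise.
    True concentrations per culture reflect the co-culture maximum
    (~25 nM) and the two monocultures (~8 nM each).
    """

    true_conc_nM: Mapping[str, float] = field(default_factory=lambda: {
        "co_culture": 25.0, "ecoli_mono": 8.0, "so_mono": 8.2})
    curve_slope_rfu_per_nM: float = 12.0
    curve_intercept_rfu: float = 0.0
    blank_rfu: float = 50.0
    noise_sd_rfu: float = 0.0
    n_wells: int = 3

    def validate(self) -> None:
        if self.curve_slope_rfu_per_nM <= 0:
            raise ConfigurationError("standard-curve slope must be > 0")
        if any(c < 0 for c in self.true_conc_nM.values()):
            raise ConfigurationError("flavin concentrations must be >= 0")
        if self.noise_sd_rfu < 0:
            raise ConfigurationError("noise_sd_rfu must be >= 0")
        if self.n_wells < 1:
            raise ConfigurationError("n_wells must be >= 1")


@dataclass
class ExpressionParams:
    """Negative-binomial gene count tables for RPKM/fold-change testing."""

    n_genes: int = 2000
    gene_length_bp: tuple[int, int] = (300, 3000)
    base_mean: tuple[float, float] = (20.0, 500.0)
    base_mean_vector: Sequence[float] | None = None  # overrides the range draw
    log2fc: Sequence[float] | None = None   # None -> all zeros (null table)
    dispersion: float = 0.1
    n_replicates: int = 3
    libsize_sd: float = 0.05                # lognormal sd of size factors

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ConfigurationError("need >= 2 replicates per condition")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.gene_length_bp[0] < 1 or self.gene_length_bp[1] < self.gene_length_bp[0]:
            raise ConfigurationError("invalid gene length range")
        if self.base_mean[0] <= 0 or self.base_mean[1] < self.base_mean[0]:
            raise ConfigurationError("invalid base mean range")
        if self.log2fc is not None and len(self.log2fc) != self.n_genes:
            raise ConfigurationError("log2fc vector length must equal n_genes")
        if self.base_mean_vector is not None:
            if len(self.base_mean_vector) != self.n_genes:
                raise ConfigurationError(
                    "base_mean_vector length must equal n_genes")
            if any(b <= 0 for b in self.base_mean_vector):
                raise ConfigurationError("base means must be > 0")


@dataclass
class GeneratorConfig:
    """Full ground-truth parameterisation of one simulated MFC experiment."""

    preset_name: str = "co_culture"
    seed: int = 0
    trace: TraceParams = field(default_factory=TraceParams)
    metabolite: MetaboliteParams = field(default_factory=MetaboliteParams)
    community: CommunityParams = field(default_factory=CommunityParams)
    flavin: FlavinParams = field(default_factory=FlavinParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)

    def validate(self) -> "GeneratorConfig":
        self.trace.validate()
        self.metabolite.validate()
        self.community.validate()
        self.flavin.validate()
        self.expression.validate()
        return self


_PRESETS = {
    # wild-type co-culture: peak ~2.0 uA/cm2, onset ~0.17 uA/cm2/h
    "co_culture": {},
    # hydrogenase-deletion co-culture: peak ~3.0 uA/cm2, same onset shape
    "hydrogenase_mutant": {"trace": {"peak_j": 3.0}},
}


def preset(name: str = "co_culture", seed: int = 0, **overrides) -> GeneratorConfig:
    """Build a validated :class:`GeneratorConfig` for a named study condition.

    ``overrides`` maps block names (``trace``, ``metabolite``, ...) to dicts
    of field overrides, applied on top of the preset.
    """
    if name not in _PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    cfg = GeneratorConfig(preset_name=name, seed=seed)
    merged: dict[str, dict] = {}
    for source in (_PRESETS[name], overrides):
        for block, fields in source.items():
            merged.setdefault(block, {}).update(fields)
    for block, fields in merged.items():
        if not hasattr(cfg, block) or block in ("preset_name", "seed"):
            raise ConfigurationError(f"unknown config block {block!r}")
        setattr(cfg, block, dataclasses.replace(getattr(cfg, block), **fields))
    return cfg.validate()
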