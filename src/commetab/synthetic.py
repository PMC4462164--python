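"""Synthetic-data generators with known ground truth for every pipeline input.

Each generator is a pure function of its :class:`~commetab.config.GeneratorConfig`:
the same config and seed produce bit-identical output.  Independent RNG
streams are derived per generator from the config seed, so changing e.g.
the number of plate replicates never perturbs the voltage trace.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import ImageStack, PlateCount
from .config import ConfigurationError, GeneratorConfig
from .electrochemistry import CurrentTrace
from .metabolism import MetaboliteSeries
from .transcriptomics import CONTROL, TREATED, ExpressionTable

# fixed per-generator stream ids keep the streams independent of call order
_STREAMS = {"trace": 1, "metabolite": 2, "plates": 3, "stack": 4,
            "fluor": 5, "expr": 6}


def _rng(config: GeneratorConfig, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream], extra])


def current_density_profile(config: GeneratorConfig, time_h: np.ndarray) -> np.ndarray:
    """Noiseless piecewise-linear rise/plateau/decay profile (uA/cm^2)."""
    p = config.trace
    if p.peak_j == 0:
        return np.zeros_like(time_h)
    rise_end = p.peak_j / p.rise_rate
    knots_t = [0.0, rise_end, p.plateau_end_h, p.zero_time_h]
    knots_j = [0.0, p.peak_j, p.peak_j, 0.0]
    return np.interp(time_h, knots_t, knots_j)


def generate_current_trace(config: GeneratorConfig, replicate: int = 0,
                           label: str | None = None) -> CurrentTrace:
    """Voltage trace of one MFC run: V = J * A * R at each sample.

    Gaussian noise of sd ``noise_sd_j`` is added in current-density
    space, negatives clipped to 0, then converted to voltage.
    """
    p = config.trace
    p.validate()
    if p.resistor_ohm <= 0 or p.electrode_area_cm2 <= 0:
        raise ConfigurationError("resistor and area must be > 0")
    n = int(np.floor(p.zero_time_h * 60.0 / p.sample_interval_min)) + 1
    time_h = np.arange(n) * p.sample_interval_min / 60.0
    j = current_density_profile(config, time_h)
    if p.noise_sd_j > 0:
        j = j + _rng(config, "trace", replicate).normal(0.0, p.noise_sd_j, j.shape)
        j = np.clip(j, 0.0, None)
    voltage = j * 1e-6 * p.electrode_area_cm2 * p.resistor_ohm
    return CurrentTrace(time_s=time_h * 3600.0, voltage_V=voltage,
                        resistor_ohm=p.resistor_ohm,
                        electrode_area_cm2=p.electrode_area_cm2,
                        label=label or f"{config.preset_name}_rep{replicate}")


def generate_metabolite_series(config: GeneratorConfig) -> MetaboliteSeries:
    """Anolyte metabolite time courses (mM).

    Formate rises linearly to its peak and declines to 0 at depletion;
    acetate and lactate are constant; glucose falls from its initial
    value as the mol-equivalent of the products formed.  In
    ``stoichiometric_mode`` the formate peak is capped so that at every
    time cumulative formate and acetate each stay within 2 mol per mol
    of glucose consumed, and no noise is added so the balance closes
    exactly.
    """
    m = config.metabolite
    m.validate()
    n = int(np.floor(m.duration_h / m.sample_interval_h)) + 1
    t = np.arange(n) * m.sample_interval_h

    acetate = np.full(n, m.acetate_level_mM)
    lactate = np.full(n, min(m.lactate_level_mM, 0.99))
    peak = m.formate_peak_mM
    if m.stoichiometric_mode:
        # 1 glucose -> 2 pyruvate -> up to 2 formate + 2 acetyl-CoA, so each
        # product is capped at 2 mol per mol glucose independently; acetate
        # ramps in over the first 12 h so no product precedes consumption
        peak = min(peak, 2.0 * m.glucose0_mM)
        acetate = np.minimum(t / 12.0, 1.0) * m.acetate_level_mM
    formate = np.interp(t, [0.0, m.formate_peak_time_h, m.formate_depletion_time_h],
                        [0.0, peak, 0.0])
    formate[t > m.formate_depletion_time_h] = 0.0
    # cumulative formate *produced* keeps rising until the peak, then holds
    cum_formate = np.minimum(
        np.interp(t, [0.0, m.formate_peak_time_h], [0.0, peak]), peak)
    # consumption tracks product *increase* since t0 (pre-existing levels,
    # e.g. the constant acetate background, are not charged to glucose)
    cum_acetate = np.maximum.accumulate(acetate) - acetate[0]
    consumed = np.minimum(np.maximum(cum_formate, cum_acetate) / 2.0,
                          m.glucose0_mM)
    glucose = m.glucose0_mM - consumed

    conc = pd.DataFrame({"glucose": glucose, "formate": formate,
                         "acetate": acetate, "lactate": lactate})
    if m.noise_sd_mM > 0 and not m.stoichiometric_mode:
        noise = _rng(config, "metabolite").normal(0.0, m.noise_sd_mM, conc.shape)
        conc = (conc + noise).clip(lower=0.0)
    return MetaboliteSeries(time_h=t, conc_mM=conc, volume_L=m.volume_L)


def generate_plate_counts(config: GeneratorConfig,
                          times_h=(24.0, 48.0, 72.0),
                          compartments=("planktonic", "biofilm")) -> list[PlateCount]:
    """Simulated drop-plate counts for both compartments.

    Plate totals are Poisson with mean CFU/mL x dilution x plated
    volume; each total is split binomially into fluorescent
    (*S. oneidensis*) and non-fluorescent (*E. coli*) colonies at the
    compartment's true fluorescent fraction.
    """
    c = config.community
    c.validate()
    rng = _rng(config, "plates")
    fluor_fraction = {"planktonic": 1.0 - c.planktonic_ecoli_fraction,
                      "biofilm": c.biofilm_so_biovolume_fraction}
    out: list[PlateCount] = []
    for comp in compartments:
        for t in times_h:
            for dil in c.dilutions:
                for _ in range(c.n_replicates):
                    mean = c.total_cfu_per_ml * dil * c.plated_volume_ml
                    total = int(rng.poisson(mean))
                    fluor = int(rng.binomial(total, fluor_fraction[comp])) if total else 0
                    out.append(PlateCount(
                        compartment=comp, time_h=float(t), dilution=float(dil),
                        plated_volume_mL=c.plated_volume_ml,
                        total_colonies=total, fluorescent_colonies=fluor))
    return out


def generate_image_stack(config: GeneratorConfig, seed_offset: int = 0) -> ImageStack:
    """Two-channel confocal-like stack of an electrode biofilm.

    The DAPI channel marks a connected ellipsoidal blob of biomass
    voxels at ``signal_level``; the GFP channel marks a uniformly random
    subset of those voxels covering the configured labeled-volume
    fraction (rounded to a whole voxel).  Gaussian background noise of
    sd ``image_noise_sd`` is added to both channels and clipped at 0.
    Ground-truth masks are attached for parameter-recovery tests.
    """
    c = config.community
    c.validate()
    rng = _rng(config, "stack", seed_offset)
    nz, ny, nx = c.stack_shape
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    az, ay, ax = max(nz * 0.38, 1), max(ny * 0.38, 1), max(nx * 0.38, 1)
    blob = (((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2
            + ((xx - cx) / ax) ** 2) <= 1.0

    n_blob = int(blob.sum())
    n_gfp = int(round(c.biofilm_so_biovolume_fraction * n_blob))
    gfp_mask = np.zeros(c.stack_shape, dtype=bool)
    if n_gfp > 0:
        idx = np.flatnonzero(blob)
        chosen = rng.choice(idx, size=n_gfp, replace=False)
        gfp_mask.flat[chosen] = True

    dapi = np.where(blob, c.signal_level, 0.0)
    gfp = np.where(gfp_mask, c.signal_level, 0.0)
    if c.image_noise_sd > 0:
        dapi = dapi + rng.normal(0.0, c.image_noise_sd, dapi.shape)
        gfp = gfp + rng.normal(0.0, c.image_noise_sd, gfp.shape)
    return ImageStack(gfp_voxels=np.clip(gfp, 0.0, None),
                      dapi_voxels=np.clip(dapi, 0.0, None),
                      voxel_size_um=c.voxel_size_um,
                      truth_gfp_mask=gfp_mask, truth_dapi_mask=blob)


def generate_fluorescence(config: GeneratorConfig) -> pd.DataFrame:
    """Plate-reader flavin fluorescence per culture, with blank wells.

    reading = intercept + blank + slope * true_conc + Gaussian noise;
    blank wells (media only) read intercept + blank + noise.
    """
    f = config.flavin
    f.validate()
    rng = _rng(config, "fluor")
    rows = []
    for culture, conc in f.true_conc_nM.items():
        for well in range(f.n_wells):
            reading = (f.curve_intercept_rfu + f.blank_rfu
                       + f.curve_slope_rfu_per_nM * conc)
            if f.noise_sd_rfu > 0:
                reading += rng.normal(0.0, f.noise_sd_rfu)
            rows.append((culture, well, max(reading, 0.0), False))
    for well in range(f.n_wells):
        reading = f.curve_intercept_rfu + f.blank_rfu
        if f.noise_sd_rfu > 0:
            reading += rng.normal(0.0, f.noise_sd_rfu)
        rows.append(("blank", well, max(reading, 0.0), True))
    return pd.DataFrame(rows, columns=["culture", "well", "reading_rfu",
                                       "is_blank"])


def generate_expression(config: GeneratorConfig) -> ExpressionTable:
    """Negative-binomial gene count table, two conditions.

    Counts for gene g, replicate r are NB with mean
    base_mean[g] * 2^(log2fc[g] * [treated]) * size_factor[r] and
    dispersion alpha (variance mu + alpha mu^2); alpha = 0 degenerates
    to Poisson.  Size factors are lognormal around 1.
    """
    e = config.expression
    e.validate()
    rng = _rng(config, "expr")
    genes = [f"g{i:05d}" for i in range(e.n_genes)]
    lengths = pd.Series(rng.integers(e.gene_length_bp[0], e.gene_length_bp[1] + 1,
                                     e.n_genes), index=genes, name="length_bp")
    if e.base_mean_vector is not None:
        base = np.asarray(e.base_mean_vector, dtype=float)
    else:
        base = rng.uniform(e.base_mean[0], e.base_mean[1], e.n_genes)
    lfc = np.zeros(e.n_genes) if e.log2fc is None else np.asarray(e.log2fc, float)

    cols, cond = [], {}
    for c_name, tag in ((CONTROL, "c"), (TREATED, "t")):
        for r in range(e.n_replicates):
            col = f"{tag}{r + 1}"
            cols.append(col)
            cond[col] = c_name
    sf = np.exp(rng.normal(0.0, e.libsize_sd, len(cols))) if e.libsize_sd > 0 \
        else np.ones(len(cols))

    counts = np.empty((e.n_genes, len(cols)), dtype=np.int64)
    for k, col in enumerate(cols):
        mu = base * (2.0 ** (lfc * (cond[col] == TREATED))) * sf[k]
        if e.dispersion == 0:
            counts[:, k] = rng.poisson(mu)
        else:
            n_param = 1.0 / e.dispersion
            counts[:, k] = rng.negative_binomial(n_param, n_param / (n_param + mu))
    return ExpressionTable(counts=pd.DataFrame(counts, index=genes, columns=cols),
                           length_bp=lengths,
                           conditions=pd.Series(cond, name="condition"))
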