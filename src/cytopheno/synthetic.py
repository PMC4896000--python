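"""Synthetic imaging-cytometry data with known subpopulation structure.

The generator emulates the measured structure of a TFEB translocation
time-course experiment: a mixture of three activity phenotypes that differ in
their nuclear/cytoplasmic concentration ratio, a positive within- and
between-phenotype association between total TFEB concentration and nuclear
localization, a negative association between lysosomal radial position
(Max Contour Position) and nuclear localization, and treatment-specific,
time-evolving mixture weights with replicate-to-replicate jitter.

Every cell carries its generating phenotype label, so downstream clustering,
classification and time-course recovery can be scored against ground truth.
Optionally, single cells are rendered as multichannel images (brightfield,
nuclear stain, TFEB, LAMP1) whose pixel statistics realize the sampled
feature values, providing inputs for the mask/feature pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

PHENOTYPE_ORDER = ("Inactive", "Medium", "Active")

#: columns that identify an event rather than describe it
METADATA_COLUMNS = ("cell_id", "treatment", "time_h", "replicate", "true_label")


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generative description of one activity phenotype.

    The nuclear/cytoplasmic TFEB ratio is lognormal within a phenotype
    (ratios are positive and right-skewed in cytometry data), jointly normal
    with total TFEB concentration on the (log ratio, concentration) scale.
    LAMP1 concentration and Max Contour Position are independent marginals;
    MCP is truncated to [0, 1].
    """

    label: str
    log_nc_mean: float  # mean of ln(nuclear/cytoplasmic ratio)
    log_nc_sd: float
    conc_mean: float  # total TFEB concentration, intensity / um^2
    conc_sd: float
    conc_nc_corr: float  # corr(log ratio, concentration) within phenotype
    lamp1_conc_mean: float
    lamp1_conc_sd: float
    mcp_mean: float  # Max Contour Position target, in [0, 1]
    mcp_sd: float

    def __post_init__(self) -> None:
        if self.log_nc_sd <= 0:
            raise ValueError(f"{self.label}: log_nc_sd must be > 0")
        if self.conc_sd <= 0:
            raise ValueError(f"{self.label}: conc_sd must be > 0")
        if not -1.0 <= self.conc_nc_corr <= 1.0:
            raise ValueError(f"{self.label}: conc_nc_corr must be in [-1, 1]")
        if not 0.0 <= self.mcp_mean <= 1.0:
            raise ValueError(f"{self.label}: mcp_mean must be in [0, 1]")
        if self.lamp1_conc_sd < 0 or self.mcp_sd < 0:
            raise ValueError(f"{self.label}: marginal SDs must be >= 0")


@dataclass(frozen=True)
class MixtureTrajectory:
    """Phenotype mixture weights over time for one treatment."""

    treatment: str
    times: tuple[float, ...]
    weights: tuple[tuple[float, ...], ...]  # one row per time point

    def __post_init__(self) -> None:
        if len(self.times) != len(self.weights):
            raise ValueError(
                f"{self.treatment}: {len(self.times)} times but "
                f"{len(self.weights)} weight rows"
            )
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError(f"{self.treatment}: times must be strictly increasing")
        for t, row in zip(self.times, self.weights):
            if any(w < 0 for w in row):
                raise ValueError(f"{self.treatment} t={t}: negative weight")
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.treatment} t={t}: weights sum to {sum(row)!r}, not 1"
                )

    def weights_at(self, time_h: float) -> np.ndarray:
        try:
            idx = self.times.index(time_h)
        except ValueError:
            raise KeyError(
                f"time {time_h} h not in trajectory for treatment "
                f"{self.treatment!r}; available: {list(self.times)}"
            ) from None
        return np.asarray(self.weights[idx], dtype=float)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative specification of a synthetic experiment."""

    phenotypes: tuple[PhenotypeSpec, ...]
    trajectories: tuple[MixtureTrajectory, ...]
    n_cells_per_timepoint: int = 10000
    n_replicates: int = 3
    replicate_jitter_sd: float = 0.05  # logit-scale SD of weight perturbation
    image_mode: bool = False
    image_size: int = 64
    pixel_size_um: float = 0.5
    pixel_noise_sd: float = 2.0
    tfeb_background: float = 5.0
    n_lamp1_spots: int = 12
    cell_area_um2_mean: float = 160.0
    cell_area_um2_sd: float = 25.0
    nuclear_area_fraction_mean: float = 0.30
    nuclear_area_fraction_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_timepoint < 1:
            raise ValueError("n_cells_per_timepoint must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.image_mode and self.image_size < 32:
            raise ValueError("image_size must be >= 32 when image_mode is set")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.replicate_jitter_sd < 0:
            raise ValueError("replicate_jitter_sd must be >= 0")
        k = len(self.phenotypes)
        labels = [p.label for p in self.phenotypes]
        if len(set(labels)) != k:
            raise ValueError("phenotype labels must be unique")
        for traj in self.trajectories:
            if any(len(row) != k for row in traj.weights):
                raise ValueError(
                    f"{traj.treatment}: weight rows must have {k} entries "
                    f"(one per phenotype)"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.phenotypes)

    def trajectory(self, treatment: str) -> MixtureTrajectory:
        for traj in self.trajectories:
            if traj.treatment == treatment:
                return traj
        raise KeyError(
            f"unknown treatment {treatment!r}; available: "
            f"{[t.treatment for t in self.trajectories]}"
        )


# ---------------------------------------------------------------------------
# Shipped defaults.
#
# Per-cluster numeric means are a calibration choice: the three ratio modes
# (0.8 / 1.5 / 2.8) are well separated on the arcsinh scale used for
# clustering, and the concentration means/correlation are set so that the
# pooled single-cell correlation between log ratio and concentration at
# baseline weights is ~0.53 and the pooled MCP-vs-log-ratio correlation is
# ~ -0.25 (see pooled_moments for the closed form).
# ---------------------------------------------------------------------------

DEFAULT_PHENOTYPES = (
    PhenotypeSpec(
        label="Inactive",
        log_nc_mean=math.log(0.8),
        log_nc_sd=0.10,
        conc_mean=85.0,
        conc_sd=20.0,
        conc_nc_corr=0.4,
        lamp1_conc_mean=100.0,
        lamp1_conc_sd=25.0,
        mcp_mean=0.72,
        mcp_sd=0.20,
    ),
    PhenotypeSpec(
        label="Medium",
        log_nc_mean=math.log(1.5),
        log_nc_sd=0.10,
        conc_mean=100.0,
        conc_sd=25.0,
        conc_nc_corr=0.4,
        lamp1_conc_mean=100.0,
        lamp1_conc_sd=25.0,
        mcp_mean=0.65,
        mcp_sd=0.20,
    ),
    PhenotypeSpec(
        label="Active",
        log_nc_mean=math.log(2.8),
        log_nc_sd=0.10,
        conc_mean=130.0,
        conc_sd=35.0,
        conc_nc_corr=0.4,
        lamp1_conc_mean=117.0,  # lysosomal content is highest in Active cells
        lamp1_conc_sd=25.0,
        mcp_mean=0.52,  # most perinuclear lysosomes
        mcp_sd=0.20,
    ),
)

#: baseline composition (t = 0) shared by all default treatments
HELA_BASELINE_WEIGHTS = (0.45, 0.46, 0.09)

_DEFAULT_TIMES = (0.0, 0.5, 1.0, 1.5, 3.0, 5.0, 15.0)

DEFAULT_TRAJECTORIES = (
    # Fresh full medium: rapid inactivation, slow partial recovery.
    MixtureTrajectory(
        treatment="FM",
        times=_DEFAULT_TIMES,
        weights=(
            (0.45, 0.46, 0.09),
            (0.93, 0.06, 0.01),
            (0.85, 0.13, 0.02),
            (0.75, 0.22, 0.03),
            (0.55, 0.41, 0.04),
            (0.35, 0.61, 0.04),
            (0.21, 0.76, 0.03),
        ),
    ),
    # mTOR inhibition: Active fraction rises 9% -> 57% by 1.5 h, then the
    # population re-inactivates toward baseline by 15 h.
    MixtureTrajectory(
        treatment="Torin1",
        times=_DEFAULT_TIMES,
        weights=(
            (0.45, 0.46, 0.09),
            (0.15, 0.45, 0.40),
            (0.05, 0.43, 0.52),
            (0.02, 0.41, 0.57),
            (0.10, 0.48, 0.42),
            (0.25, 0.50, 0.25),
            (0.47, 0.45, 0.08),
        ),
    ),
    # Nutrient deprivation: first activation wave, re-inactivation, second wave.
    MixtureTrajectory(
        treatment="Deprivation",
        times=_DEFAULT_TIMES,
        weights=(
            (0.45, 0.46, 0.09),
            (0.25, 0.45, 0.30),
            (0.12, 0.43, 0.45),
            (0.15, 0.45, 0.40),
            (0.30, 0.45, 0.25),
            (0.42, 0.43, 0.15),
            (0.20, 0.45, 0.35),
        ),
    ),
)


def default_config(**overrides) -> SyntheticConfig:
    """The shipped default experiment: 3 phenotypes, 3 treatments, 3 replicates,
    10000 cells per (treatment, time, replicate) - the acquisition target of the
    emulated protocol."""
    base = dict(
        phenotypes=DEFAULT_PHENOTYPES,
        trajectories=DEFAULT_TRAJECTORIES,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def fast_config(**overrides) -> SyntheticConfig:
    """Reduced profile (2000 cells per condition, the post-gating floor of the
    emulated protocol) for quick runs."""
    overrides.setdefault("n_cells_per_timepoint", 2000)
    return default_config(**overrides)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _condition_rng(config: SyntheticConfig, treatment: str, time_h: float,
                   replicate: int) -> np.random.Generator:
    """Deterministic per-condition stream derived from the config seed."""
    traj = config.trajectory(treatment)
    t_idx = [t.treatment for t in config.trajectories].index(treatment)
    time_idx = traj.times.index(time_h)
    ss = np.random.SeedSequence([int(config.seed), t_idx, time_idx, int(replicate)])
    return np.random.default_rng(ss)


def jitter_weights(weights: np.ndarray, sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Logit-scale Gaussian perturbation of a weight vector.

    Log-weights of the nonzero components are perturbed by N(0, sd) and
    renormalized through a softmax, which keeps the vector on the simplex;
    exact zeros stay zero.
    """
    w = np.asarray(weights, dtype=float)
    if sd == 0:
        return w.copy()
    out = np.zeros_like(w)
    pos = w > 0
    logw = np.log(w[pos]) + rng.normal(0.0, sd, size=pos.sum())
    logw -= logw.max()
    e = np.exp(logw)
    out[pos] = e / e.sum()
    return out


def _sample_cells(config: SyntheticConfig, label_idx: np.ndarray,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-cell feature values for cells with the given phenotype indices."""
    n = label_idx.size
    k = len(config.phenotypes)

    log_nc = np.empty(n)
    conc = np.empty(n)
    lamp1 = np.empty(n)
    mcp = np.empty(n)
    for i in range(k):
        mask = label_idx == i
        m = int(mask.sum())
        if m == 0:
            continue
        p = config.phenotypes[i]
        z1 = rng.standard_normal(m)
        z2 = rng.standard_normal(m)
        log_nc[mask] = p.log_nc_mean + p.log_nc_sd * z1
        rho = p.conc_nc_corr
        conc[mask] = p.conc_mean + p.conc_sd * (rho * z1 + math.sqrt(1 - rho**2) * z2)
        lamp1[mask] = p.lamp1_conc_mean + p.lamp1_conc_sd * rng.standard_normal(m)
        mcp[mask] = p.mcp_mean + p.mcp_sd * rng.standard_normal(m)

    conc = np.clip(conc, 1e-6, None)
    lamp1 = np.clip(lamp1, 1e-6, None)
    mcp = np.clip(mcp, 0.0, 1.0)

    ratio = np.exp(log_nc)
    area_cell = np.clip(
        rng.normal(config.cell_area_um2_mean, config.cell_area_um2_sd, n), 40.0, None
    )
    nuc_frac = np.clip(
        rng.normal(config.nuclear_area_fraction_mean,
                   config.nuclear_area_fraction_sd, n),
        0.10, 0.60,
    )
    area_nucleus = nuc_frac * area_cell
    area_cytoplasm = area_cell - area_nucleus

    # nuclear percentage implied by the per-pixel ratio and the area split:
    # I_nuc / I_cyto = ratio * A_nuc / A_cyto
    odds = ratio * nuc_frac / (1.0 - nuc_frac)
    nuclear_percentage = 100.0 * odds / (1.0 + odds)

    intensity_cell = conc * area_cell
    intensity_nucleus = nuclear_percentage / 100.0 * intensity_cell
    intensity_cytoplasm = intensity_cell - intensity_nucleus

    return pd.DataFrame(
        {
            "intensity_cell": intensity_cell,
            "intensity_nucleus": intensity_nucleus,
            "intensity_cytoplasm": intensity_cytoplasm,
            "area_cell": area_cell,
            "area_nucleus": area_nucleus,
            "area_cytoplasm": area_cytoplasm,
            "concentration_cell": conc,
            "concentration_nucleus": intensity_nucleus / area_nucleus,
            "concentration_cytoplasm": intensity_cytoplasm / area_cytoplasm,
            "nuclear_percentage": nuclear_percentage,
            "mean_pixel_nuc_cyto": ratio,
            "lamp1_concentration": lamp1,
            "lamp1_max_contour_position": mcp,
            "bf_area": area_cell,
            "bf_aspect_ratio": np.clip(rng.normal(0.85, 0.07, n), 0.30, 1.0),
            "bf_gradient_rms": np.clip(rng.normal(30.0, 5.0, n), 1.0, None),
        }
    )


def generate_features(config: SyntheticConfig, treatment: str, time_h: float,
                      replicate: int) -> pd.DataFrame:
    """Feature table for one (treatment, time, replicate) condition.

    Each cell is drawn by sampling a phenotype from the replicate-jittered
    mixture weights, then sampling its features from the phenotype's
    distributions.  The generating label is retained in ``true_label``.
    """
    traj = config.trajectory(treatment)
    weights = traj.weights_at(time_h)
    if not 0 <= replicate < config.n_replicates:
        raise KeyError(
            f"replicate {replicate} out of range [0, {config.n_replicates})"
        )
    rng = _condition_rng(config, treatment, time_h, replicate)
    w = jitter_weights(weights, config.replicate_jitter_sd, rng)

    n = config.n_cells_per_timepoint
    label_idx = rng.choice(len(w), size=n, p=w)
    df = _sample_cells(config, label_idx, rng)
    df.insert(0, "cell_id",
              [f"{treatment}_t{time_h:g}_r{replicate}_{i:05d}" for i in range(n)])
    df["treatment"] = treatment
    df["time_h"] = float(time_h)
    df["replicate"] = int(replicate)
    df["true_label"] = [config.phenotypes[i].label for i in label_idx]
    return df


def generate_timecourse(config: SyntheticConfig) -> pd.DataFrame:
    """Full multi-treatment, multi-replicate event table (deterministic given seed)."""
    parts = []
    for traj in config.trajectories:
        for t in traj.times:
            for rep in range(config.n_replicates):
                parts.append(generate_features(config, traj.treatment, t, rep))
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Analytic pooled moments (used by tests as the generator-level oracle)
# ---------------------------------------------------------------------------


def pooled_moments(config: SyntheticConfig, weights) -> dict:
    """Closed-form pooled correlations implied by the mixture at given weights.

    Pooled covariance = E[within-phenotype covariance] + covariance of the
    phenotype means.  Returned correlations are between (ln ratio,
    concentration) and between (MCP, ln ratio); MCP truncation to [0, 1] is
    ignored (mild at the default SDs).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(config.phenotypes),) or abs(w.sum() - 1) > 1e-9:
        raise ValueError("weights must be one probability per phenotype")
    m = np.array([p.log_nc_mean for p in config.phenotypes])
    s = np.array([p.log_nc_sd for p in config.phenotypes])
    c = np.array([p.conc_mean for p in config.phenotypes])
    t = np.array([p.conc_sd for p in config.phenotypes])
    rho = np.array([p.conc_nc_corr for p in config.phenotypes])
    mc = np.array([p.mcp_mean for p in config.phenotypes])
    ms = np.array([p.mcp_sd for p in config.phenotypes])

    mean_x, mean_y, mean_m = (w * m).sum(), (w * c).sum(), (w * mc).sum()
    var_x = (w * s**2).sum() + (w * (m - mean_x) ** 2).sum()
    var_y = (w * t**2).sum() + (w * (c - mean_y) ** 2).sum()
    var_m = (w * ms**2).sum() + (w * (mc - mean_m) ** 2).sum()
    cov_xy = (w * rho * s * t).sum() + (w * (m - mean_x) * (c - mean_y)).sum()
    cov_mx = (w * (mc - mean_m) * (m - mean_x)).sum()  # MCP independent within
    return {
        "r_logratio_concentration": cov_xy / math.sqrt(var_x * var_y),
        "r_mcp_logratio": cov_mx / math.sqrt(var_m * var_x),
    }


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


def generate_cell_image(phenotype: PhenotypeSpec, config: SyntheticConfig,
                        rng: np.random.Generator):
    """Render one synthetic cell as a multichannel image.

    Returns ``(CellImage, truth)`` where ``truth`` records the sampled feature
    values the rendering realizes.  The cell is a filled ellipse (dark interior
    on a bright brightfield background), the nucleus a centered disk on the
    nuclear-stain channel, the TFEB channel a two-level field whose
    nucleus/cytoplasm mean-pixel ratio equals the sampled ratio plus constant
    background and optional Gaussian noise, and the LAMP1 channel a set of
    punctate spots placed at the cell depth that realizes the sampled
    Max Contour Position target.
    """
    from scipy import ndimage

    from .features import CellImage

    if not config.image_mode:
        raise ValueError("generate_cell_image requires image_mode=True")

    cfg_one = replace(config, phenotypes=(phenotype,),
                      trajectories=(MixtureTrajectory("_", (0.0,), ((1.0,),)),))
    sample = _sample_cells(cfg_one, np.zeros(1, dtype=int), rng)
    row = sample.iloc[0]

    size = config.image_size
    px_area = config.pixel_size_um**2
    area_px = row["area_cell"] / px_area
    q = row["bf_aspect_ratio"]
    a = math.sqrt(area_px / (math.pi * q))  # semi-major, pixels
    b = a * q
    margin = 8
    if 2 * a + 2 * margin > size:
        need = int(math.ceil(2 * a + 2 * margin))
        raise ValueError(
            f"cell (semi-major {a:.1f} px) exceeds frame; image_size must be "
            f">= {need}"
        )
    cy = cx = size / 2.0 - 0.5
    yy, xx = np.mgrid[0:size, 0:size]
    cell = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    rn = math.sqrt(row["area_nucleus"] / px_area / math.pi)
    nucleus = (xx - cx) ** 2 + (yy - cy) ** 2 <= rn**2
    nucleus &= cell
    n_cell = int(cell.sum())
    n_nuc = int(nucleus.sum())
    n_cyt = n_cell - n_nuc

    noise = config.pixel_noise_sd

    bf = np.full((size, size), 220.0)
    bf[cell] = 80.0

    hoechst = np.zeros((size, size))
    hoechst[nucleus] = 150.0

    ratio = row["mean_pixel_nuc_cyto"]
    mean_px = row["concentration_cell"] * px_area  # mean TFEB pixel over cell
    i_cyto = mean_px * n_cell / (ratio * n_nuc + n_cyt)
    tfeb = np.full((size, size), config.tfeb_background)
    tfeb[cell] = config.tfeb_background + i_cyto
    tfeb[nucleus] = config.tfeb_background + ratio * i_cyto

    # LAMP1 spots at the normalized depth realizing the MCP target
    lamp1 = np.zeros((size, size))
    depth = ndimage.distance_transform_edt(cell)
    dmax = depth.max()
    norm_depth = np.where(cell, depth / dmax, np.nan)
    target_depth = 1.0 - row["lamp1_max_contour_position"]
    inside = np.argwhere(cell)
    d_in = norm_depth[cell]
    order = np.argsort(np.abs(d_in - target_depth))
    n_band = max(config.n_lamp1_spots * 2, 8)
    band = inside[order[:n_band]]
    pick = rng.choice(len(band), size=min(config.n_lamp1_spots, len(band)),
                      replace=False)
    total_lamp1 = row["lamp1_concentration"] * row["area_cell"]
    per_spot = total_lamp1 / len(pick)
    for (py, px) in band[pick]:
        lamp1[py, px] += per_spot

    if noise > 0:
        for ch in (bf, hoechst, tfeb, lamp1):
            ch += rng.normal(0.0, noise, ch.shape)
            np.clip(ch, 0.0, None, out=ch)

    image = CellImage(
        channels={"brightfield": bf, "nuclear_stain": hoechst,
                  "tfeb": tfeb, "lamp1": lamp1},
        pixel_size_um=config.pixel_size_um,
        cell_id="synthetic",
        treatment="synthetic",
        time_h=0.0,
        replicate=0,
    )
    truth = {
        "true_label": phenotype.label,
        "mean_pixel_nuc_cyto": float(ratio),
        "concentration_cell": float(row["concentration_cell"]),
        "lamp1_concentration": float(row["lamp1_concentration"]),
        "lamp1_max_contour_position": float(row["lamp1_max_contour_position"]),
        "nuclear_percentage": 100.0 * ratio * n_nuc / (ratio * n_nuc + n_cyt),
        "area_cell_um2": n_cell * px_area,
        "area_nucleus_um2": n_nuc * px_area,
    }
    return image, truth


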