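"""Shared fixtures and independent brute-force oracles.

The oracle functions deliberately use explicit Python loops / fsum over pixel
sets so they share no code path with the vectorized implementations they
check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cytopheno import clustering, framework, synthetic
from cytopheno.features import CellImage, compute_masks

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def fast_cfg():
    """Reduced-size default experiment (2000 cells per condition)."""
    return synthetic.fast_config(seed=7)


@pytest.fixture(scope="session")
def fast_events(fast_cfg):
    return synthetic.generate_timecourse(fast_cfg)


@pytest.fixture(scope="session")
def fast_model(fast_cfg, fast_events):
    """Selected-model analogue fitted on the fast-profile training treatments."""
    train = fast_events[fast_events["treatment"].isin(["FM", "Torin1"])]
    merged = framework.merge_experiments([train], seed=7)
    params = clustering.ClusterParams(features=("mean_pixel_nuc_cyto",), k=3, seed=7)
    model = clustering.fit_cluster_model(merged, params)
    return clustering.label_clusters(model)


@pytest.fixture(scope="session")
def image_cfg():
    """Image-mode generator config with default pixel noise."""
    return synthetic.default_config(
        n_cells_per_timepoint=10, image_mode=True, seed=3
    )


def render_random_images(config, n, seed=0, noise=None):
    """n rendered cells cycling through the phenotypes."""
    import dataclasses

    if noise is not None:
        config = dataclasses.replace(config, pixel_noise_sd=noise)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        phen = config.phenotypes[i % len(config.phenotypes)]
        img, truth = synthetic.generate_cell_image(phen, config, rng)
        out.append((img, truth))
    return out


@pytest.fixture(scope="session")
def random_images(image_cfg):
    """30+ random noisy 64x64 events with their pipeline masks."""
    rendered = render_random_images(image_cfg, 32, seed=11)
    return [(img, compute_masks(img), truth) for img, truth in rendered]


# ---------------------------------------------------------------------------
# Brute-force oracles (loops, no shared code with the implementation)
# ---------------------------------------------------------------------------


def oracle_background(channel, cell_mask, dilation_px=3):
    from skimage.morphology import dilation, disk

    outside = ~dilation(cell_mask, footprint=disk(dilation_px))
    vals = [channel[y, x] for y, x in np.argwhere(outside)]
    return math.fsum(vals) / len(vals) if vals else 0.0


def oracle_masked_sum(channel, mask, background):
    total = 0.0
    for y, x in np.argwhere(mask):
        v = channel[y, x] - background
        total += v if v > 0 else 0.0
    return total


def oracle_masked_mean_clipped(channel, mask, background):
    vals = [max(channel[y, x] - background, 0.0) for y, x in np.argwhere(mask)]
    return math.fsum(vals) / len(vals) if vals else float("nan")


def oracle_max_contour_position(channel, cell_mask, n_rings, background):
    from scipy.ndimage import distance_transform_edt

    depth = distance_transform_edt(cell_mask)
    dmax = depth.max()
    ring_vals = {i: [] for i in range(n_rings)}
    for y, x in np.argwhere(cell_mask):
        norm = depth[y, x] / dmax
        ring = min(int(norm * n_rings), n_rings - 1)
        ring_vals[ring].append(max(channel[y, x] - background, 0.0))
    if math.fsum(v for vals in ring_vals.values() for v in vals) <= 0:
        return float("nan")
    means = {}
    for i, vals in ring_vals.items():
        if vals:
            means[i] = math.fsum(vals) / len(vals)
    best_mean = max(means.values())
    best_ring = max(i for i, m in means.items() if m == best_mean)
    return 1.0 - (best_ring + 0.5) / n_rings


def oracle_aspect_ratio(mask):
    """Minor/major axis ratio from the second central moments of the pixel set."""
    pts = np.argwhere(mask).astype(float)
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d / len(pts)
    # regionprops uses +1/12 per-pixel variance correction... it does not for
    # axis lengths; eigenvalues of the (raw) central moment matrix
    eig = np.linalg.eigvalsh(cov)
    if eig[1] <= 0:
        return 1.0
    return math.sqrt(max(eig[0], 0.0) / eig[1])


def oracle_gradient_rms(channel):
    """Finite-difference gradient RMS: central differences in the interior,
    one-sided at the borders (the standard stencil)."""
    ch = np.asarray(channel, dtype=float)
    H, W = ch.shape
    sq = []
    for y in range(H):
        for x in range(W):
            if 0 < y < H - 1:
                gy = (ch[y + 1, x] - ch[y - 1, x]) / 2.0
            elif y == 0:
                gy = ch[1, x] - ch[0, x]
            else:
                gy = ch[H - 1, x] - ch[H - 2, x]
            if 0 < x < W - 1:
                gx = (ch[y, x + 1] - ch[y, x - 1]) / 2.0
            elif x == 0:
                gx = ch[y, 1] - ch[y, 0]
            else:
                gx = ch[y, W - 1] - ch[y, W - 2]
            sq.append(gx * gx + gy * gy)
    return math.sqrt(math.fsum(sq) / len(sq))


def oracle_features(image: CellImage, masks, n_rings=8):
    """Independent per-pixel recomputation of the whole feature vector."""
    px_area = image.pixel_size_um**2
    tfeb = image.channel("tfeb")
    lamp1 = image.channel("lamp1")
    bg_t = oracle_background(tfeb, masks.cell)
    bg_l = oracle_background(lamp1, masks.cell)

    i_cell = oracle_masked_sum(tfeb, masks.cell, bg_t)
    i_nuc = oracle_masked_sum(tfeb, masks.nucleus, bg_t)
    i_cyt = oracle_masked_sum(tfeb, masks.cytoplasm, bg_t)
    a_cell = int(masks.cell.sum()) * px_area
    a_nuc = int(masks.nucleus.sum()) * px_area
    a_cyt = int(masks.cytoplasm.sum()) * px_area

    mpnc = float("nan")
    if masks.nucleus_eroded.any() and masks.cytoplasm_eroded.any():
        num = oracle_masked_mean_clipped(tfeb, masks.nucleus_eroded, bg_t)
        den = oracle_masked_mean_clipped(tfeb, masks.cytoplasm_eroded, bg_t)
        if den > 0:
            mpnc = num / den

    bf = image.channel("brightfield")
    from cytopheno.features import default_mask

    bf_mask = default_mask(bf.max() - bf)
    return {
        "intensity_cell": i_cell,
        "intensity_nucleus": i_nuc,
        "intensity_cytoplasm": i_cyt,
        "area_cell": a_cell,
        "area_nucleus": a_nuc,
        "area_cytoplasm": a_cyt,
        "concentration_cell": i_cell / a_cell if a_cell else 0.0,
        "concentration_nucleus": i_nuc / a_nuc if a_nuc else 0.0,
        "concentration_cytoplasm": i_cyt / a_cyt if a_cyt else 0.0,
        "nuclear_percentage": 100.0 * i_nuc / i_cell if i_cell else 0.0,
        "mean_pixel_nuc_cyto": mpnc,
        "lamp1_concentration": (
            oracle_masked_sum(lamp1, masks.cell, bg_l) / a_cell if a_cell else 0.0
        ),
        "lamp1_max_contour_position": oracle_max_contour_position(
            lamp1, masks.cell, n_rings, bg_l
        ),
        "bf_area": int(bf_mask.sum()) * px_area,
        "bf_aspect_ratio": oracle_aspect_ratio(bf_mask),
        "bf_gradient_rms": oracle_gradient_rms(bf),
    }


def ring_image(size=64, radius=24, ring_lo=0.0, ring_hi=1.0, value=100.0):
    """Disk cell mask plus an intensity band at normalized depth [ring_lo, ring_hi]."""
    from scipy.ndimage import distance_transform_edt

    yy, xx = np.mgrid[0:size, 0:size]
    c = size / 2.0 - 0.5
    cell = (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    depth = distance_transform_edt(cell)
    norm = np.where(cell, depth / depth.max(), np.nan)
    channel = np.zeros((size, size))
    band = cell & (norm >= ring_lo) & (norm <= ring_hi)
    channel[band] = value
    return channel, cell
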