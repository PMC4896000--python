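"""Masks, gating, and per-cell feature extraction from multichannel images.

One event is one segmented cell recorded on four channels (brightfield,
nuclear stain, TFEB immunostain, LAMP1 immunostain).  The mask chain is

    cell      = default_mask(TFEB)  OR  erode(default_mask(brightfield), 5 px)
    nucleus   = 70%-of-total-intensity threshold mask (nuclear stain) AND cell
    cytoplasm = cell AND NOT nucleus

with additional eroded ("underestimated") nucleus/cytoplasm masks used for the
Mean Pixel Nuc/Cyto ratio, so that boundary pixels cannot mix the nuclear and
cytoplasmic signals.  All intensity features are background subtracted, with
the background estimated per channel outside a dilation of the cell mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

log = logging.getLogger(__name__)


@dataclass
class CellImage:
    """One event's multichannel pixel grid plus acquisition metadata."""

    channels: dict  # name -> 2-D float array, all same shape
    pixel_size_um: float
    cell_id: str = ""
    treatment: str = ""
    time_h: float = 0.0
    replicate: int = 0

    def __post_init__(self) -> None:
        shapes = {np.asarray(ch).shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels must share one shape, got {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        for name, ch in self.channels.items():
            arr = np.asarray(ch, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} has non-finite pixels")
            if (arr < 0).any():
                raise ValueError(f"channel {name!r} has negative pixels")
            self.channels[name] = arr

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"no channel {name!r}; available: {sorted(self.channels)}"
            ) from None

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape


@dataclass
class MaskSet:
    """Boolean compartment masks for one event (cytoplasm = cell AND NOT nucleus)."""

    cell: np.ndarray
    nucleus: np.ndarray
    cytoplasm: np.ndarray
    nucleus_eroded: np.ndarray
    cytoplasm_eroded: np.ndarray

    @property
    def analyzable(self) -> bool:
        """False when the cell mask is empty (gating failure, not an exception)."""
        return bool(self.cell.any())


@dataclass
class CellFeatures:
    """The per-cell feature vector (intensities background subtracted)."""

    intensity_cell: float
    intensity_nucleus: float
    intensity_cytoplasm: float
    area_cell: float  # um^2
    area_nucleus: float
    area_cytoplasm: float
    concentration_cell: float  # intensity / um^2
    concentration_nucleus: float
    concentration_cytoplasm: float
    nuclear_percentage: float  # in [0, 100]
    mean_pixel_nuc_cyto: float
    lamp1_concentration: float
    lamp1_max_contour_position: float
    bf_area: float
    bf_aspect_ratio: float
    bf_gradient_rms: float
    mpnc_degenerate: bool = False  # empty eroded compartment
    mcp_undefined: bool = False  # no LAMP1 signal inside the cell

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class GateConfig:
    """Single-cell / in-focus gates on brightfield morphology.

    ``gradient_rms_min`` is an absolute focus floor; alternatively
    ``gradient_rms_percentile`` discards the blurriest percentile of the batch.
    """

    area_min_um2: float = 50.0
    area_max_um2: float = 400.0
    aspect_min: float = 0.6
    gradient_rms_min: float | None = None
    gradient_rms_percentile: float | None = None


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------


def default_mask(channel: np.ndarray) -> np.ndarray:
    """Foreground mask: global Otsu threshold, 3x3 binary closing, largest
    connected component.  A constant channel yields an empty mask."""
    ch = np.asarray(channel, dtype=float)
    if ch.max() == ch.min():
        return np.zeros(ch.shape, dtype=bool)
    fg = ch > threshold_otsu(ch)
    fg = morphology.closing(fg, footprint=np.ones((3, 3), dtype=bool))
    if not fg.any():
        return fg
    labeled = measure.label(fg, connectivity=2)
    counts = np.bincount(labeled.ravel())
    counts[0] = 0
    return labeled == counts.argmax()


def threshold_mask(channel: np.ndarray, fraction: float) -> np.ndarray:
    """Smallest set of brightest pixels capturing ``fraction`` of total intensity.

    Pixels are admitted in descending intensity order until the admitted sum
    reaches ``fraction`` x total; all pixels tied with the cutoff intensity are
    included.  An all-zero channel yields an empty mask.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ch = np.asarray(channel, dtype=float)
    total = ch.sum()
    if total <= 0:
        return np.zeros(ch.shape, dtype=bool)
    flat = np.sort(ch.ravel())[::-1]
    csum = np.cumsum(flat)
    idx = int(np.searchsorted(csum, fraction * total - 1e-12))
    cutoff = flat[idx]
    return ch >= cutoff if cutoff > 0 else ch > 0


def _erode(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return mask.copy()
    return morphology.erosion(mask, footprint=morphology.disk(radius))


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return mask.copy()
    return morphology.dilation(mask, footprint=morphology.disk(radius))


def compute_masks(image: CellImage, erosion_px: int = 2) -> MaskSet:
    """Compartment masks for one event.

    The brightfield default mask is taken on the inverted channel (cells are
    dark on a bright background) and eroded by 5 px before the OR with the
    TFEB default mask.  Eroded nucleus/cytoplasm masks use a disk structuring
    element of radius ``erosion_px``.
    """
    tfeb_mask = default_mask(image.channel("tfeb"))
    bf = image.channel("brightfield")
    bf_mask = default_mask(bf.max() - bf)
    cell = tfeb_mask | _erode(bf_mask, 5)
    nucleus = threshold_mask(image.channel("nuclear_stain"), 0.70) & cell
    cytoplasm = cell & ~nucleus
    nucleus_eroded = _erode(nucleus, erosion_px)
    cytoplasm_eroded = _erode(cell, erosion_px) & ~_dilate(nucleus, erosion_px)
    return MaskSet(cell, nucleus, cytoplasm, nucleus_eroded, cytoplasm_eroded)


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------


def gradient_rms(channel: np.ndarray) -> float:
    """Root-mean-square finite-difference gradient magnitude (focus score)."""
    ch = np.asarray(channel, dtype=float)
    if ch.shape[0] < 3 or ch.shape[1] < 3:
        raise ValueError("channel must be at least 3x3")
    gy, gx = np.gradient(ch)
    return float(np.sqrt(np.mean(gx**2 + gy**2)))


def brightfield_morphology(image: CellImage) -> dict:
    """Area (um^2), best-fit-ellipse aspect ratio (minor/major) and gradient RMS
    of the brightfield mask/channel."""
    bf = image.channel("brightfield")
    mask = default_mask(bf.max() - bf)
    px_area = image.pixel_size_um**2
    if not mask.any():
        return {"bf_area": 0.0, "bf_aspect_ratio": 0.0,
                "bf_gradient_rms": gradient_rms(bf)}
    props = measure.regionprops(mask.astype(np.uint8))[0]
    major = props.axis_major_length
    aspect = props.axis_minor_length / major if major > 0 else 1.0
    return {
        "bf_area": float(mask.sum() * px_area),
        "bf_aspect_ratio": float(aspect),
        "bf_gradient_rms": gradient_rms(bf),
    }


def gate_events(events: list, gate_config: GateConfig | None = None):
    """Retain single, in-focus events.

    Returns ``(retained_events, report)`` where the report records each
    event's brightfield area, aspect ratio, gradient RMS and per-gate pass
    flags.
    """
    gate_config = gate_config or GateConfig()
    if not events:
        log.warning("gate_events called with no events")
        return [], pd.DataFrame(
            columns=["cell_id", "bf_area", "bf_aspect_ratio", "bf_gradient_rms",
                     "pass_area", "pass_aspect", "pass_focus", "retained"]
        )

    rows = []
    for ev in events:
        m = brightfield_morphology(ev)
        m["cell_id"] = ev.cell_id
        rows.append(m)
    report = pd.DataFrame(rows)

    grms_min = gate_config.gradient_rms_min
    if gate_config.gradient_rms_percentile is not None:
        pct_floor = float(
            np.percentile(report["bf_gradient_rms"],
                          gate_config.gradient_rms_percentile)
        )
        grms_min = pct_floor if grms_min is None else max(grms_min, pct_floor)

    report["pass_area"] = report["bf_area"].between(
        gate_config.area_min_um2, gate_config.area_max_um2
    )
    report["pass_aspect"] = report["bf_aspect_ratio"] >= gate_config.aspect_min
    report["pass_focus"] = (
        True if grms_min is None else report["bf_gradient_rms"] >= grms_min
    )
    report["retained"] = (
        report["pass_area"] & report["pass_aspect"] & report["pass_focus"]
    )
    retained = [ev for ev, ok in zip(events, report["retained"]) if ok]
    return retained, report


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def estimate_background(channel: np.ndarray, cell_mask: np.ndarray,
                        dilation_px: int = 3) -> float:
    """Mean intensity outside a dilation of the cell mask (0 if nothing is outside)."""
    outside = ~_dilate(cell_mask, dilation_px)
    if not outside.any():
        return 0.0
    return float(np.asarray(channel, dtype=float)[outside].mean())


def _masked_sum(channel: np.ndarray, mask: np.ndarray, background: float) -> float:
    if not mask.any():
        return 0.0
    vals = np.clip(channel[mask] - background, 0.0, None)
    return float(vals.sum())


def max_contour_position(channel: np.ndarray, cell_mask: np.ndarray,
                         n_rings: int = 8, background: float = 0.0) -> float:
    """Normalized radial position of the ring with the highest mean intensity.

    The mask is partitioned into ``n_rings`` equal-width rings of the
    boundary-distance transform (depth 0 at the mask boundary, 1 at the
    deepest point).  The returned value is ``1 - center depth`` of the
    highest-mean ring: near 1 for peripheral signal, near 0 for central
    (perinuclear) signal.  Ties go to the more central (smaller) value.
    Returns NaN when the channel carries no signal inside the mask.
    """
    if n_rings < 2:
        raise ValueError("n_rings must be >= 2")
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    ch = np.asarray(channel, dtype=float)
    vals = np.clip(ch[cell_mask] - background, 0.0, None)
    if vals.sum() <= 0:
        return float("nan")
    depth = ndimage.distance_transform_edt(cell_mask)
    norm = depth[cell_mask] / depth.max()
    ring = np.minimum((norm * n_rings).astype(int), n_rings - 1)
    means = np.full(n_rings, -np.inf)
    for i in range(n_rings):
        sel = ring == i
        if sel.any():
            means[i] = vals[sel].mean()
    best = int(np.flatnonzero(means == means.max()).max())  # ties -> more central
    return 1.0 - (best + 0.5) / n_rings


def extract_features(image: CellImage, masks: MaskSet,
                     n_rings: int = 8) -> CellFeatures:
    """Compute the full feature vector from an event and its masks."""
    if not masks.analyzable:
        raise ValueError("cell mask is empty; event should have been gated out")

    px_area = image.pixel_size_um**2
    tfeb = image.channel("tfeb")
    lamp1 = image.channel("lamp1")
    bg_tfeb = estimate_background(tfeb, masks.cell)
    bg_lamp1 = estimate_background(lamp1, masks.cell)

    i_cell = _masked_sum(tfeb, masks.cell, bg_tfeb)
    i_nuc = _masked_sum(tfeb, masks.nucleus, bg_tfeb)
    i_cyt = _masked_sum(tfeb, masks.cytoplasm, bg_tfeb)

    a_cell = float(masks.cell.sum()) * px_area
    a_nuc = float(masks.nucleus.sum()) * px_area
    a_cyt = float(masks.cytoplasm.sum()) * px_area

    def conc(intensity: float, area: float) -> float:
        return intensity / area if area > 0 else 0.0

    nuclear_pct = 100.0 * i_nuc / i_cell if i_cell > 0 else 0.0

    mpnc = float("nan")
    degenerate = False
    if masks.nucleus_eroded.any() and masks.cytoplasm_eroded.any():
        nuc_mean = np.clip(tfeb[masks.nucleus_eroded] - bg_tfeb, 0, None).mean()
        cyt_mean = np.clip(tfeb[masks.cytoplasm_eroded] - bg_tfeb, 0, None).mean()
        if cyt_mean > 0:
            mpnc = float(nuc_mean / cyt_mean)
        else:
            degenerate = True
    else:
        degenerate = True

    mcp = max_contour_position(lamp1, masks.cell, n_rings=n_rings,
                               background=bg_lamp1)

    bf = brightfield_morphology(image)
    return CellFeatures(
        intensity_cell=i_cell,
        intensity_nucleus=i_nuc,
        intensity_cytoplasm=i_cyt,
        area_cell=a_cell,
        area_nucleus=a_nuc,
        area_cytoplasm=a_cyt,
        concentration_cell=conc(i_cell, a_cell),
        concentration_nucleus=conc(i_nuc, a_nuc),
        concentration_cytoplasm=conc(i_cyt, a_cyt),
        nuclear_percentage=nuclear_pct,
        mean_pixel_nuc_cyto=mpnc,
        lamp1_concentration=conc(_masked_sum(lamp1, masks.cell, bg_lamp1), a_cell),
        lamp1_max_contour_position=mcp,
        bf_area=bf["bf_area"],
        bf_aspect_ratio=bf["bf_aspect_ratio"],
        bf_gradient_rms=bf["bf_gradient_rms"],
        mpnc_degenerate=degenerate,
        mcp_undefined=bool(np.isnan(mcp)),
    )


def extract_table(events: list, erosion_px: int = 2, n_rings: int = 8,
                  gate_config: GateConfig | None = None) -> pd.DataFrame:
    """Gate a batch of events, extract features, and assemble the event table.

    Events whose cell mask comes out empty are dropped (flagged in the log)
    rather than raising.
    """
    retained, _report = gate_events(events, gate_config)
    rows = []
    for ev in retained:
        masks = compute_masks(ev, erosion_px=erosion_px)
        if not masks.analyzable:
            log.warning("event %s: empty cell mask, skipped", ev.cell_id)
            continue
        feats = extract_features(ev, masks, n_rings=n_rings).to_dict()
        feats["cell_id"] = ev.cell_id
        feats["treatment"] = ev.treatment
        feats["time_h"] = ev.time_h
        feats["replicate"] = ev.replicate
        rows.append(feats)
    return pd.DataFrame(rows)
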