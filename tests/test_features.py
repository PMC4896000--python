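"""Masks, gating, and feature extraction against brute-force pixel oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import (
    oracle_gradient_rms,
    oracle_max_contour_position,
    ring_image,
)
from cytopheno.features import (
    CellImage,
    GateConfig,
    compute_masks,
    default_mask,
    extract_features,
    gate_events,
    gradient_rms,
    max_contour_position,
    threshold_mask,
)


def disk_mask(size, radius, cy=None, cx=None):
    cy = size / 2.0 - 0.5 if cy is None else cy
    cx = size / 2.0 - 0.5 if cx is None else cx
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def simple_image(tfeb, nuclear=None, lamp1=None, brightfield=None,
                 pixel_size_um=0.5):
    shape = tfeb.shape
    if brightfield is None:
        brightfield = np.full(shape, 200.0)
        brightfield[tfeb > tfeb.min()] = 80.0
    return CellImage(
        channels={
            "brightfield": brightfield,
            "nuclear_stain": np.zeros(shape) if nuclear is None else nuclear,
            "tfeb": tfeb,
            "lamp1": np.zeros(shape) if lamp1 is None else lamp1,
        },
        pixel_size_um=pixel_size_um,
    )


class TestDefaultMask:
    def test_constant_channel_empty(self):
        assert not default_mask(np.zeros((16, 16))).any()
        assert not default_mask(np.full((16, 16), 7.0)).any()

    def test_clean_disk_within_one_pixel_band(self):
        """Otsu recovers a bright disk up to a 1-pixel boundary band."""
        from skimage.morphology import dilation, disk as disk_fp, erosion

        truth = disk_mask(64, 20)
        channel = np.where(truth, 100.0, 2.0)
        mask = default_mask(channel)
        assert mask[erosion(truth, footprint=disk_fp(1))].all()
        assert not mask[~dilation(truth, footprint=disk_fp(1))].any()

    def test_largest_component_wins(self):
        channel = np.zeros((64, 64))
        channel[disk_mask(64, 16, 30, 20)] = 100.0
        small = disk_mask(64, 4, 10, 52)
        channel[small] = 100.0
        mask = default_mask(channel)
        assert not mask[small].any()
        assert mask.sum() > 500


class TestThresholdMask:
    def test_worked_example(self):
        """Pixels (10, 5, 3, 2) at fraction 0.7 -> {10, 5} (sum 15 >= 14)."""
        channel = np.array([[10.0, 5.0], [3.0, 2.0]])
        mask = threshold_mask(channel, 0.7)
        assert mask.tolist() == [[True, True], [False, False]]

    def test_full_fraction_selects_nonzero(self):
        channel = np.array([[0.0, 1.0], [2.0, 0.0]])
        assert threshold_mask(channel, 1.0).tolist() == [[False, True],
                                                         [True, False]]

    def test_uniform_ties_select_all(self):
        channel = np.full((5, 5), 3.0)
        assert threshold_mask(channel, 0.7).all()

    def test_all_zero_gives_empty(self):
        assert not threshold_mask(np.zeros((4, 4)), 0.5).any()

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            threshold_mask(np.ones((2, 2)), 0.0)

    @staticmethod
    def brute_force(channel, fraction):
        """Walk the sorted pixel list, then include cutoff ties."""
        flat = sorted(channel.ravel(), reverse=True)
        total = math.fsum(flat)
        acc, cutoff = 0.0, None
        for v in flat:
            acc += v
            if acc >= fraction * total - 1e-12:
                cutoff = v
                break
        if total <= 0:
            return np.zeros_like(channel, dtype=bool)
        return channel >= cutoff if cutoff > 0 else channel > 0

    def test_matches_bruteforce_on_random_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            channel = rng.integers(0, 12, size=(6, 6)).astype(float)
            frac = rng.uniform(0.05, 1.0)
            got = threshold_mask(channel, frac)
            want = self.brute_force(channel, frac)
            np.testing.assert_array_equal(got, want)

    @given(arrays(np.float64, (5, 5), elements=st.floats(0, 50)),
           st.floats(0.05, 1.0))
    def test_energy_and_downward_closure(self, channel, fraction):
        """The mask always captures >= fraction of total intensity and is
        downward closed in intensity (no excluded pixel brighter than an
        included one)."""
        mask = threshold_mask(channel, fraction)
        total = channel.sum()
        if total == 0:
            assert not mask.any()
            return
        assert channel[mask].sum() >= fraction * total - 1e-9
        if mask.any() and (~mask).any():
            assert channel[mask].min() > channel[~mask].max() or np.isclose(
                channel[mask].min(), channel[~mask].max()
            ) or channel[~mask].max() == 0


class TestComputeMasks:
    def test_zero_nuclear_stain(self):
        tfeb = np.where(disk_mask(48, 15), 50.0, 1.0)
        image = simple_image(tfeb)
        masks = compute_masks(image)
        assert not masks.nucleus.any()
        np.testing.assert_array_equal(masks.cytoplasm, masks.cell)

    def test_mask_algebra_on_rendered_events(self, random_images):
        """cytoplasm = cell AND NOT nucleus; nucleus inside cell; eroded masks
        inside their parents - exact pixel-set identities on every fixture."""
        for _img, masks, _truth in random_images:
            np.testing.assert_array_equal(masks.cytoplasm,
                                          masks.cell & ~masks.nucleus)
            assert not (masks.nucleus & ~masks.cell).any()
            assert not (masks.nucleus_eroded & ~masks.nucleus).any()
            assert not (masks.cytoplasm_eroded & ~masks.cytoplasm).any()
            assert not (masks.cytoplasm & masks.nucleus).any()
            np.testing.assert_array_equal(masks.cytoplasm | masks.nucleus,
                                          masks.cell)

    def test_known_pixel_counts(self):
        """Cell disk of known rasterized area with a nuclear disk: cytoplasm
        pixel count = cell - nucleus."""
        cell_truth = disk_mask(48, 15)
        nuc_truth = disk_mask(48, 6)
        tfeb = np.where(cell_truth, 50.0, 0.5)
        nuclear = np.where(nuc_truth, 80.0, 0.0)
        image = simple_image(tfeb, nuclear=nuclear)
        masks = compute_masks(image)
        assert masks.cytoplasm.sum() == masks.cell.sum() - masks.nucleus.sum()
        assert masks.nucleus.sum() == nuc_truth.sum()  # uniform disk: tie rule


class TestGradientRMS:
    def test_constant_zero(self):
        assert gradient_rms(np.full((8, 8), 5.0)) == 0.0

    def test_blur_reduces_score(self):
        from scipy.ndimage import gaussian_filter

        sharp = np.where(disk_mask(32, 10), 100.0, 0.0)
        assert gradient_rms(sharp) > gradient_rms(gaussian_filter(sharp, 3))

    def test_matches_hand_stencil_on_step_edge(self):
        rng = np.random.default_rng(3)
        channel = rng.uniform(0, 10, (5, 5))
        channel[:, 3:] += 50.0  # step edge
        assert gradient_rms(channel) == pytest.approx(
            oracle_gradient_rms(channel), rel=1e-12
        )

    def test_requires_3x3(self):
        with pytest.raises(ValueError):
            gradient_rms(np.ones((2, 5)))


class TestGating:
    def _single(self, seed=0):
        rng = np.random.default_rng(seed)
        bf = np.full((64, 64), 200.0)
        bf[disk_mask(64, 14)] = 80.0
        bf += rng.normal(0, 2, bf.shape).clip(-50, 50)
        tfeb = np.where(disk_mask(64, 14), 50.0, 2.0)
        return simple_image(tfeb.clip(0), brightfield=bf.clip(0))

    def _doublet(self):
        bf = np.full((64, 64), 200.0)
        yy, xx = np.mgrid[0:64, 0:64]
        e1 = ((xx - 22) / 11.0) ** 2 + ((yy - 32) / 11.0) ** 2 <= 1
        e2 = ((xx - 43) / 11.0) ** 2 + ((yy - 32) / 11.0) ** 2 <= 1
        bf[e1 | e2] = 80.0
        tfeb = np.where(e1 | e2, 50.0, 2.0)
        return simple_image(tfeb, brightfield=bf)

    def test_permissive_gates_keep_all(self):
        events = [self._single(i) for i in range(5)]
        gates = GateConfig(area_min_um2=0, area_max_um2=1e9, aspect_min=0.0)
        retained, report = gate_events(events, gates)
        assert len(retained) == 5
        assert report["retained"].all()

    def test_doublet_excluded_by_aspect(self):
        """A touching cell pair forms one elongated brightfield mask whose
        ellipse aspect ratio falls below the 0.6 default."""
        events = [self._single(0), self._doublet()]
        retained, report = gate_events(events, GateConfig(area_max_um2=1e9))
        assert report.loc[1, "bf_aspect_ratio"] < 0.6
        assert not report.loc[1, "retained"]
        assert report.loc[0, "retained"]
        assert len(retained) == 1

    def test_percentile_focus_gate(self):
        from scipy.ndimage import gaussian_filter

        singles = [self._single(i) for i in range(18)]
        blurred = []
        for i in range(2):
            img = self._single(100 + i)
            img.channels["brightfield"] = gaussian_filter(
                img.channels["brightfield"], 4
            )
            blurred.append(img)
        gates = GateConfig(area_min_um2=0, area_max_um2=1e9, aspect_min=0.0,
                           gradient_rms_percentile=10.0)
        retained, report = gate_events(singles + blurred, gates)
        assert len(retained) == 18
        assert not report["retained"].iloc[18:].any()

    def test_empty_input(self):
        retained, report = gate_events([])
        assert retained == [] and report.empty


class TestExtractFeatures:
    def test_uniform_signal(self):
        """Uniform TFEB over the cell: ratio 1, nuclear % = area share."""
        cell_truth = disk_mask(48, 15)
        nuc_truth = disk_mask(48, 6)
        tfeb = np.where(cell_truth, 50.0, 0.0)
        nuclear = np.where(nuc_truth, 80.0, 0.0)
        image = simple_image(tfeb, nuclear=nuclear)
        masks = compute_masks(image)
        feats = extract_features(image, masks)
        assert feats.mean_pixel_nuc_cyto == pytest.approx(1.0)
        assert feats.nuclear_percentage == pytest.approx(
            100.0 * feats.area_nucleus / feats.area_cell
        )

    def test_all_signal_in_nucleus(self):
        cell_truth = disk_mask(48, 15)
        nuc_truth = disk_mask(48, 6)
        tfeb = np.where(nuc_truth, 50.0, 0.0)
        # TFEB default mask alone would shrink to the nucleus; give the
        # brightfield a full-cell footprint so the OR restores the cell.
        bf = np.full((48, 48), 200.0)
        bf[disk_mask(48, 21)] = 80.0
        nuclear = np.where(nuc_truth, 80.0, 0.0)
        image = simple_image(tfeb, nuclear=nuclear, brightfield=bf)
        masks = compute_masks(image)
        feats = extract_features(image, masks)
        assert feats.nuclear_percentage == pytest.approx(100.0)

    def test_scale_equivariance_zero_background(self):
        """Scaling the TFEB channel by c scales intensities/concentrations by c
        and leaves the ratios unchanged."""
        cell_truth = disk_mask(64, 18)
        nuc_truth = disk_mask(64, 8)
        rng = np.random.default_rng(5)
        tfeb = np.where(cell_truth, 40.0 + rng.uniform(0, 5, (64, 64)), 0.0)
        tfeb[nuc_truth] *= 2.0
        nuclear = np.where(nuc_truth, 80.0, 0.0)
        img1 = simple_image(tfeb)
        img1.channels["nuclear_stain"] = nuclear
        img2 = simple_image(3.0 * tfeb)
        img2.channels["nuclear_stain"] = nuclear
        m1, m2 = compute_masks(img1), compute_masks(img2)
        f1, f2 = extract_features(img1, m1), extract_features(img2, m2)
        assert f2.intensity_cell == pytest.approx(3.0 * f1.intensity_cell)
        assert f2.concentration_nucleus == pytest.approx(
            3.0 * f1.concentration_nucleus
        )
        assert f2.nuclear_percentage == pytest.approx(f1.nuclear_percentage)
        assert f2.mean_pixel_nuc_cyto == pytest.approx(f1.mean_pixel_nuc_cyto)

    def test_translation_invariance(self, image_cfg):
        from conftest import render_random_images

        # zero pixel noise so integer rolling cannot create wrap-around seams
        img, _ = render_random_images(image_cfg, 1, seed=13, noise=0.0)[0]
        shifted = CellImage(
            channels={k: np.roll(v, (3, -2), axis=(0, 1))
                      for k, v in img.channels.items()},
            pixel_size_um=img.pixel_size_um,
        )
        f1 = extract_features(img, compute_masks(img))
        f2 = extract_features(shifted, compute_masks(shifted))
        for key, val in f1.to_dict().items():
            if isinstance(val, float):
                assert f2.to_dict()[key] == pytest.approx(val, rel=1e-9), key

    def test_degenerate_eroded_compartment_flagged(self):
        """A nucleus too small to survive erosion yields NaN + flag, not a
        fabricated ratio."""
        cell_truth = disk_mask(48, 15)
        nuc_truth = disk_mask(48, 1.2)
        tfeb = np.where(cell_truth, 50.0, 0.0)
        nuclear = np.where(nuc_truth, 80.0, 0.0)
        image = simple_image(tfeb, nuclear=nuclear)
        masks = compute_masks(image, erosion_px=3)
        feats = extract_features(image, masks)
        assert feats.mpnc_degenerate
        assert math.isnan(feats.mean_pixel_nuc_cyto)


class TestMaxContourPosition:
    def test_innermost_ring(self):
        channel, cell = ring_image(ring_lo=0.9, ring_hi=1.0)
        assert max_contour_position(channel, cell, n_rings=8) <= 1.0 / 8

    def test_boundary_ring(self):
        channel, cell = ring_image(ring_lo=0.0, ring_hi=0.1)
        assert max_contour_position(channel, cell, n_rings=8) >= 1.0 - 1.0 / 8

    def test_monotone_in_ring_position(self):
        """Moving the signal band outward never decreases the value."""
        values = []
        for j in range(8):
            lo, hi = 1.0 - (j + 1) / 8.0, 1.0 - j / 8.0
            channel, cell = ring_image(ring_lo=lo + 1e-9, ring_hi=hi)
            values.append(max_contour_position(channel, cell, n_rings=8))
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] > values[0]

    def test_tie_breaks_toward_center(self):
        """Two rings with identical means resolve to the more central value."""
        # bands aligned to exact 1/8-depth ring boundaries so the means tie
        inner, cell = ring_image(ring_lo=0.875, ring_hi=1.0, value=100.0)
        outer, _ = ring_image(ring_lo=0.0, ring_hi=0.125 - 1e-9, value=100.0)
        both = inner + outer
        v = max_contour_position(both, cell, n_rings=8)
        v_inner = max_contour_position(inner, cell, n_rings=8)
        assert v == v_inner

    def test_no_signal_returns_nan(self):
        _, cell = ring_image()
        assert math.isnan(max_contour_position(np.zeros(cell.shape), cell, 8))

    def test_matches_bruteforce(self, random_images):
        for img, masks, _ in random_images[:8]:
            from cytopheno.features import estimate_background

            lamp1 = img.channel("lamp1")
            bg = estimate_background(lamp1, masks.cell)
            got = max_contour_position(lamp1, masks.cell, 8, bg)
            want = oracle_max_contour_position(lamp1, masks.cell, 8, bg)
            assert got == pytest.approx(want, abs=1e-12)
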