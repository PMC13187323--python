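"""Conditional PDFs, intersection, energy-domain tests, corrections."""

import numpy as np
import pytest

from bccxai.agreement import (
    cohort_agreement_report,
    conditional_pdfs,
    dice_jaccard,
    energy_cohens_d,
    energy_ztest,
    fg_bg_moments,
    multiple_correction,
    normalize_map,
    pdf_intersection,
)
from bccxai.synthetic import generate_activation_map


def _half_mask(n=20):
    mask = np.zeros((n, n), dtype=bool)
    mask[:, : n // 2] = True
    return mask


class TestConditionalPdfs:
    def test_densities_integrate_to_one(self, rng):
        z = rng.random((40, 40))
        fg, bg, edges = conditional_pdfs(z, _half_mask(40), n_bins=50)
        w = np.diff(edges)
        assert np.sum(fg * w) == pytest.approx(1.0, abs=1e-9)
        assert np.sum(bg * w) == pytest.approx(1.0, abs=1e-9)

    def test_constant_map_is_a_point_mass(self):
        z = np.full((10, 10), 0.5)
        fg, bg, edges = conditional_pdfs(z, _half_mask(10), n_bins=10)
        assert (fg > 0).sum() == 1 and (bg > 0).sum() == 1
        assert np.argmax(fg) == np.argmax(bg)

    def test_map_equal_to_mask_separates_supports(self):
        mask = _half_mask()
        fg, bg, edges = conditional_pdfs(mask.astype(float), mask, n_bins=10)
        assert np.argmax(fg) == 9 and np.argmax(bg) == 0

    def test_uniform_map_is_flat(self, rng):
        z = rng.random((1000, 1000))
        fg, bg, _ = conditional_pdfs(z, _half_mask(1000), n_bins=20)
        assert np.abs(fg - 1).max() < 0.05
        assert np.abs(bg - 1).max() < 0.05

    def test_empty_side_raises(self):
        z = np.random.rand(5, 5)
        with pytest.raises(ValueError, match="Fg"):
            conditional_pdfs(z, np.zeros((5, 5), dtype=bool))
        with pytest.raises(ValueError, match="Bg"):
            conditional_pdfs(z, np.ones((5, 5), dtype=bool))


class TestPdfIntersection:
    def test_identical_densities_intersect_fully(self, rng):
        z = rng.random((30, 30))
        fg, _, edges = conditional_pdfs(z, _half_mask(30), n_bins=25)
        assert pdf_intersection(fg, fg, edges) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_supports_intersect_nowhere(self):
        mask = _half_mask()
        fg, bg, edges = conditional_pdfs(mask.astype(float), mask, n_bins=4)
        assert pdf_intersection(fg, bg, edges) == 0.0

    def test_bin_aligned_half_overlap_is_one_half(self):
        """Fg uniform on [0, .5), Bg uniform on [.25, .75) with 4 bins of
        width .25: min-density overlap covers exactly one bin -> 0.5."""
        fg_vals = np.linspace(0.0, 0.4999, 200)
        bg_vals = np.linspace(0.25, 0.7499, 200)
        edges = np.linspace(0, 1, 5)
        fg, _ = np.histogram(fg_vals, bins=edges, density=True)
        bg, _ = np.histogram(bg_vals, bins=edges, density=True)
        assert pdf_intersection(fg, bg, edges) == pytest.approx(0.5, abs=1e-9)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(10):
            a = rng.random(20)
            b = rng.random(20)
            a /= a.sum() * (1 / 20)
            b /= b.sum() * (1 / 20)
            ab = pdf_intersection(a, b)
            assert ab == pytest.approx(pdf_intersection(b, a))
            assert 0 <= ab <= 1 + 1e-12

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError):
            pdf_intersection(np.ones(4), np.ones(5))


class TestMoments:
    def test_map_equal_to_mask(self):
        mask = _half_mask()
        mfg, mbg, sfg, sbg = fg_bg_moments(mask.astype(float), mask)
        assert (mfg, mbg, sfg, sbg) == (1.0, 0.0, 0.0, 0.0)

    def test_hand_computed_two_pixel_foreground(self):
        z = np.array([[0.4, 0.6], [0.1, 0.3]])
        mask = np.array([[True, True], [False, False]])
        mfg, mbg, sfg, sbg = fg_bg_moments(z, mask)
        assert mfg == pytest.approx(0.5)
        assert sfg == pytest.approx(np.sqrt(0.02), abs=1e-9)  # ~0.1414

    def test_single_pixel_region_warns_sd_zero(self):
        z = np.array([[0.4, 0.6], [0.1, 0.3]])
        mask = np.array([[True, False], [False, False]])
        with pytest.warns(UserWarning):
            _, _, sfg, _ = fg_bg_moments(z, mask)
        assert sfg == 0.0


class TestEnergyTest:
    def test_hand_computed_z_statistic(self):
        """Fg z^2 = {0.9, 1.1}, Bg z^2 = {0.1, 0.3}:
        z = (1.0 - 0.2) / sqrt(0.02/2 + 0.02/2) = 0.8 / 0.141 = 5.657."""
        z = np.sqrt(np.array([[0.9, 1.1], [0.1, 0.3]]))
        mask = np.array([[True, True], [False, False]])
        zs, p = energy_ztest(z, mask)
        assert zs == pytest.approx(0.8 / np.sqrt(0.02), abs=1e-9)
        d = energy_cohens_d(z, mask)
        assert d == pytest.approx(0.8 / np.sqrt(0.02), abs=1e-9)

    def test_map_equal_to_mask_rejects_under_fg_greater(self):
        mask = _half_mask(40)
        _, p = energy_ztest(mask.astype(float), mask, alternative="fg_greater")
        assert p < 1e-10

    def test_degenerate_conventions(self):
        const = np.full((4, 4), 0.3)
        mask = _half_mask(4)
        with pytest.warns(UserWarning):
            zs, p = energy_ztest(const, mask)
        assert (zs, p) == (0.0, 1.0)
        two_level = np.where(mask, 0.8, 0.2)
        with pytest.warns(UserWarning):
            zs, p = energy_ztest(two_level, mask)
        assert p == 0.0 and np.isinf(zs)
        with pytest.warns(UserWarning):
            assert np.isnan(energy_cohens_d(const, mask))

    def test_cohens_d_zero_without_contrast(self):
        # equal fg/bg multisets of energies
        z = np.array([[0.2, 0.4, 0.2, 0.4]] * 4)
        mask = np.array([[True, True, False, False]] * 4)
        assert energy_cohens_d(z, mask) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_of_cohens_d(self, rng):
        z = rng.random((16, 16)) * 0.5
        mask = _half_mask(16)
        d1 = energy_cohens_d(z, mask)
        d2 = energy_cohens_d(2.0 * z, mask)
        assert d1 == pytest.approx(d2, rel=1e-9)


class TestMultipleCorrection:
    def test_single_small_p_rejected_by_both(self):
        for method in ("bonferroni", "bh"):
            reject, adj = multiple_correction([0.01], 0.05, method)
            assert reject[0]

    def test_bonferroni_multiplies(self):
        reject, adj = multiple_correction([0.004] + [1.0] * 9, 0.05,
                                          "bonferroni")
        assert adj[0] == pytest.approx(0.04)
        assert reject[0] and not reject[1:].any()

    def test_bh_step_up_hand_case(self):
        """m=4, alpha=.05: thresholds i*alpha/m = .0125/.025/.0375/.05.
        p_(2)=.02 <= .025 but p_(3)=.04 > .0375, so step-up rejects the
        first two; Bonferroni (alpha/m = .0125) only the first."""
        p = [0.01, 0.02, 0.04, 0.50]
        rej_bh, _ = multiple_correction(p, 0.05, "bh")
        rej_bf, _ = multiple_correction(p, 0.05, "bonferroni")
        assert rej_bh.tolist() == [True, True, False, False]
        assert rej_bf.tolist() == [True, False, False, False]
        # a true three-rejection step-up case for contrast
        rej_bh2, _ = multiple_correction([0.01, 0.02, 0.037, 0.50], 0.05, "bh")
        assert rej_bh2.tolist() == [True, True, True, False]

    def test_rejection_monotonicity_on_random_pvalues(self, rng):
        for _ in range(20):
            p = rng.random(15)
            unc = p <= 0.05
            bf, _ = multiple_correction(p, 0.05, "bonferroni")
            bh, _ = multiple_correction(p, 0.05, "bh")
            assert (bf <= bh).all() and (bh <= unc).all()

    def test_empty_input(self):
        reject, adj = multiple_correction([], 0.05)
        assert reject.size == 0 and adj.size == 0


class TestCohortReport:
    def _mask(self, n=32):
        yy, xx = np.mgrid[:n, :n]
        return (yy - n / 2) ** 2 + (xx - n / 2) ** 2 < (n / 4) ** 2

    def test_single_image_cohort(self):
        mask = self._mask()
        z = generate_activation_map(mask, 0.7, 0.1, 0.1, 0.1, seed=0)
        rep = cohort_agreement_report([z], [mask])
        assert rep.n_analyzed == 1
        img = rep.images[0]
        assert img.mean_fg > img.mean_bg
        assert rep.group_summaries["all"]["n"] == 1

    def test_unanalyzable_images_excluded_with_reason(self):
        mask = self._mask()
        good = generate_activation_map(mask, 0.7, 0.1, 0.1, 0.1, seed=1)
        rep = cohort_agreement_report(
            [good, np.random.rand(32, 32)],
            [mask, np.zeros((32, 32), dtype=bool)],
        )
        assert rep.n_analyzed == 1
        assert len(rep.excluded) == 1

    def test_all_unanalyzable_raises(self):
        with pytest.raises(ValueError):
            cohort_agreement_report([np.random.rand(8, 8)],
                                    [np.zeros((8, 8), dtype=bool)])

    def test_correctness_split(self):
        mask = self._mask()
        maps = [generate_activation_map(mask, 0.6, 0.1, 0.1, 0.1, seed=s)
                for s in range(6)]
        rep = cohort_agreement_report(maps, [mask] * 6,
                                      correctness_flags=[True] * 4 + [False] * 2)
        assert rep.group_summaries["correct"]["n"] == 4
        assert rep.group_summaries["incorrect"]["n"] == 2


def test_normalize_map_and_constant_warning():
    z = np.array([[1.0, 3.0], [2.0, 5.0]])
    out = normalize_map(z)
    assert out.min() == 0 and out.max() == 1
    with pytest.warns(UserWarning):
        out = normalize_map(np.full((3, 3), 2.0))
    assert (out == 0).all()


def test_dice_jaccard_diagnostics():
    a = np.zeros((4, 4), dtype=bool)
    b = np.zeros((4, 4), dtype=bool)
    a[:2] = True
    b[1:3] = True
    dice, jac = dice_jaccard(a, b)
    assert dice == pytest.approx(0.5)
    assert jac == pytest.approx(1 / 3)
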