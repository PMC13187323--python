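"""Quantitative agreement between activation maps and expert segmentations.

Given a normalized saliency map z(x, y) in [0, 1] and a binary mask marking
the expert-segmented region of clinical interest (Fg; the complement is
Bg), this module estimates the conditional densities P(z | Fg) and
P(z | Bg), their intersection area, foreground/background moments, and an
image-wise two-sample z-test in the energy domain z²(x, y) with Cohen's d,
then aggregates a cohort with Bonferroni and Benjamini–Hochberg
multiplicity control.

Interpretation choices: "mean over Fg" means the mean of z over foreground
pixels (not a mean of density values); densities are equal-width histograms
on [0, 1] (50 bins by default), which make the intersection area exactly
computable; the z-test treats pixels as independent observations — spatial
autocorrelation inflates its effective sample size and is documented, not
corrected.  Overlap coefficients of the DICE/Jaccard family are offered
only as optional diagnostics; they are not part of the agreement report
because saliency maps are systematically coarser than expert contours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_BINS = 50


def _check_pair(z, mask):
    z = np.asarray(z, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if z.ndim != 2:
        raise ValueError("activation map must be a 2-D grid")
    if z.shape != mask.shape:
        raise ValueError(
            f"map shape {z.shape} does not match mask shape {mask.shape}"
        )
    return z, mask


def normalize_map(z) -> np.ndarray:
    """Min-max normalize a map to [0, 1]; constant maps become all-zero."""
    z = np.asarray(z, dtype=float)
    lo, hi = float(z.min()), float(z.max())
    if hi - lo == 0:
        warnings.warn("constant activation map normalized to all-zeros")
        return np.zeros_like(z)
    return (z - lo) / (hi - lo)


def conditional_pdfs(z, mask, n_bins: int = DEFAULT_BINS):
    """Histogram densities of z over Fg and Bg on fixed [0, 1] bins.

    Returns ``(fg_density, bg_density, bin_edges)``; each density integrates
    to 1 (sum of bin density x width).
    """
    z, mask = _check_pair(z, mask)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not mask.any():
        raise ValueError("foreground (Fg) is empty")
    if mask.all():
        raise ValueError("background (Bg) is empty")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    fg, _ = np.histogram(z[mask], bins=edges, density=True)
    bg, _ = np.histogram(z[~mask], bins=edges, density=True)
    return fg, bg, edges


def pdf_intersection(fg_density, bg_density, bin_edges=None) -> float:
    """Intersection area of two histogram densities on a shared binning.

    ``sum_b min(fg_b, bg_b) * width_b``; 1 for identical histograms, 0 for
    disjoint supports.  Symmetric in its arguments.
    """
    fg = np.asarray(fg_density, dtype=float)
    bg = np.asarray(bg_density, dtype=float)
    if fg.shape != bg.shape:
        raise ValueError("densities must share their binning")
    if bin_edges is None:
        widths = np.full(fg.shape, 1.0 / fg.size)
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
        if bin_edges.size != fg.size + 1:
            raise ValueError("bin_edges inconsistent with densities")
        widths = np.diff(bin_edges)
    return float(np.sum(np.minimum(fg, bg) * widths))


def fg_bg_moments(z, mask):
    """Sample mean and sd (n-1 denominator) of z over Fg and Bg.

    Returns ``(mean_fg, mean_bg, sd_fg, sd_bg)``.  A single-pixel region
    gets sd 0 with a warning.
    """
    z, mask = _check_pair(z, mask)
    if not mask.any() or mask.all():
        raise ValueError("both Fg and Bg must be non-empty")

    def _sd(vals):
        if vals.size == 1:
            warnings.warn("single-pixel region: sd reported as 0")
            return 0.0
        return float(vals.std(ddof=1))

    fg, bg = z[mask], z[~mask]
    return float(fg.mean()), float(bg.mean()), _sd(fg), _sd(bg)


def energy_ztest(z, mask, alternative: str = "two_sided"):
    """Welch-style two-sample z-test on the energy z² of Fg vs Bg pixels.

    z = (mean_fg(z²) - mean_bg(z²)) / sqrt(var_fg/n_fg + var_bg/n_bg)
    with the sample variances of z².  ``alternative`` is ``two_sided`` or
    ``fg_greater``.  Conventions for degenerate inputs (both regions
    constant): equal means -> (0, 1); different means -> (±inf, 0).

    Returns ``(z_stat, p_value)``.
    """
    z, mask = _check_pair(z, mask)
    if alternative not in ("two_sided", "fg_greater"):
        raise ValueError("alternative must be 'two_sided' or 'fg_greater'")
    fg = z[mask] ** 2
    bg = z[~mask] ** 2
    if fg.size < 2 or bg.size < 2:
        raise ValueError("Fg and Bg each need >= 2 pixels")
    diff = float(fg.mean() - bg.mean())
    se = float(np.sqrt(fg.var(ddof=1) / fg.size + bg.var(ddof=1) / bg.size))
    if se == 0:
        if diff == 0:
            warnings.warn("both regions constant with equal means: p = 1")
            return 0.0, 1.0
        warnings.warn("both regions constant with different means: p = 0")
        return float(np.sign(diff) * np.inf), 0.0
    zs = diff / se
    if alternative == "two_sided":
        p = float(2.0 * stats.norm.sf(abs(zs)))
    else:
        p = float(stats.norm.sf(zs))
    return float(zs), p


def energy_cohens_d(z, mask) -> float:
    """Cohen's d of the foreground-background energy contrast.

    d = (mean_fg(z²) - mean_bg(z²)) / s_pooled with the usual pooled sd.
    Zero pooled variance yields NaN (undefined) with a warning.
    """
    z, mask = _check_pair(z, mask)
    fg = z[mask] ** 2
    bg = z[~mask] ** 2
    if fg.size < 2 or bg.size < 2:
        raise ValueError("Fg and Bg each need >= 2 pixels")
    pooled = np.sqrt(
        ((fg.size - 1) * fg.var(ddof=1) + (bg.size - 1) * bg.var(ddof=1))
        / (fg.size + bg.size - 2)
    )
    if pooled == 0:
        warnings.warn("zero pooled variance: Cohen's d undefined")
        return float("nan")
    return float((fg.mean() - bg.mean()) / pooled)


def multiple_correction(p_values, alpha: float = 0.05, method: str = "bonferroni"):
    """Familywise/FDR correction: reject flags and adjusted p-values.

    ``method`` is ``bonferroni`` or ``bh`` (Benjamini–Hochberg step-up).
    Empty input yields empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if sm_method is None:
        raise ValueError("method must be 'bonferroni' or 'bh'")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method=sm_method)
    return reject, p_adj


def dice_jaccard(binary_map, mask):
    """Optional overlap diagnostics (not used in the agreement report).

    Saliency maps are coarser than expert contours, so these coefficients
    under-represent agreement; they are provided for exploration only.
    """
    a = np.asarray(binary_map).astype(bool)
    b = np.asarray(mask).astype(bool)
    inter = float((a & b).sum())
    union = float((a | b).sum())
    denom = float(a.sum() + b.sum())
    dice = 2 * inter / denom if denom else float("nan")
    jac = inter / union if union else float("nan")
    return dice, jac


@dataclass
class ImageAgreement:
    """Per-image foreground/background agreement statistics."""

    image_id: str
    mean_fg: float
    mean_bg: float
    sd_fg: float
    sd_bg: float
    intersection: float
    energy_z_stat: float
    p_value: float
    cohens_d: float
    n_fg: int
    n_bg: int
    correct: bool | None = None


@dataclass
class AgreementReport:
    """Cohort-level agreement: per-image records and summary statistics."""

    images: list[ImageAgreement]
    excluded: list[tuple[str, str]]          # (image_id, reason)
    group_summaries: dict                     # keyed by group label
    prop_significant_uncorrected: float
    prop_significant_bonferroni: float
    prop_significant_bh: float
    mean_cohens_d: float
    alpha: float
    n_analyzed: int
    per_image_extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_analyzed": self.n_analyzed,
            "n_excluded": len(self.excluded),
            "excluded": [list(e) for e in self.excluded],
            "group_summaries": self.group_summaries,
            "prop_significant_uncorrected": self.prop_significant_uncorrected,
            "prop_significant_bonferroni": self.prop_significant_bonferroni,
            "prop_significant_bh": self.prop_significant_bh,
            "mean_cohens_d": self.mean_cohens_d,
        }


def _group_summary(records: list[ImageAgreement]) -> dict:
    if not records:
        return {"n": 0}
    arr = {
        k: float(np.mean([getattr(r, k) for r in records]))
        for k in ("mean_fg", "mean_bg", "sd_fg", "sd_bg", "intersection")
    }
    arr["n"] = len(records)
    return arr


def cohort_agreement_report(
    maps,
    masks,
    image_ids=None,
    correctness_flags=None,
    alpha: float = 0.05,
    n_bins: int = DEFAULT_BINS,
    alternative: str = "two_sided",
) -> AgreementReport:
    """Aggregate per-image agreement over a cohort.

    Images failing per-image preconditions (empty Fg or Bg, too few pixels)
    are excluded with a recorded reason.  Multiplicity corrections are
    applied across the analyzable images (m = number analyzed).
    """
    if len(maps) != len(masks):
        raise ValueError("maps and masks must be aligned")
    if image_ids is None:
        image_ids = [f"img_{i:05d}" for i in range(len(maps))]
    if correctness_flags is not None and len(correctness_flags) != len(maps):
        raise ValueError("correctness_flags must be aligned with maps")

    records: list[ImageAgreement] = []
    excluded: list[tuple[str, str]] = []
    for i, (z, mask) in enumerate(zip(maps, masks)):
        flag = None if correctness_flags is None else bool(correctness_flags[i])
        try:
            z_arr, m_arr = _check_pair(z, mask)
            n_fg, n_bg = int(m_arr.sum()), int((~m_arr).sum())
            if n_fg < 2 or n_bg < 2:
                raise ValueError("Fg and Bg each need >= 2 pixels")
            mean_fg, mean_bg, sd_fg, sd_bg = fg_bg_moments(z_arr, m_arr)
            fg_d, bg_d, edges = conditional_pdfs(z_arr, m_arr, n_bins=n_bins)
            inter = pdf_intersection(fg_d, bg_d, edges)
            zs, p = energy_ztest(z_arr, m_arr, alternative=alternative)
            d = energy_cohens_d(z_arr, m_arr)
        except ValueError as exc:
            excluded.append((str(image_ids[i]), str(exc)))
            continue
        records.append(
            ImageAgreement(
                image_id=str(image_ids[i]),
                mean_fg=mean_fg, mean_bg=mean_bg,
                sd_fg=sd_fg, sd_bg=sd_bg,
                intersection=inter,
                energy_z_stat=zs, p_value=p, cohens_d=d,
                n_fg=n_fg, n_bg=n_bg, correct=flag,
            )
        )
    if not records:
        raise ValueError("no analyzable images in the cohort")

    p_values = np.array([r.p_value for r in records])
    rej_unc = p_values <= alpha
    rej_bonf, _ = multiple_correction(p_values, alpha=alpha, method="bonferroni")
    rej_bh, _ = multiple_correction(p_values, alpha=alpha, method="bh")

    groups = {"all": _group_summary(records)}
    if correctness_flags is not None:
        groups["correct"] = _group_summary([r for r in records if r.correct])
        groups["incorrect"] = _group_summary([r for r in records if not r.correct])

    d_vals = np.array([r.cohens_d for r in records])
    return AgreementReport(
        images=records,
        excluded=excluded,
        group_summaries=groups,
        prop_significant_uncorrected=float(rej_unc.mean()),
        prop_significant_bonferroni=float(rej_bonf.mean()),
        prop_significant_bh=float(rej_bh.mean()),
        mean_cohens_d=float(np.nanmean(d_vals)),
        alpha=alpha,
        n_analyzed=len(records),
    )
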