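"""Seeded synthetic dermoscopy-like data: lesion images, per-pattern masks,
multi-rater annotations and activation maps with controlled statistics.

The generator stands in for a clinical dermoscopy archive that cannot be
shipped.  It emulates exactly the structural features downstream modules
need — a 7-pattern multilabel with configurable imbalance, per-pattern
spatial masks, raters with imperfect per-pattern sensitivity/specificity,
and saliency-like maps whose foreground/background laws are controllable —
without attempting photorealism.  Pattern textures are stylized procedural
shapes (reticular lines for pigment network, bright blobs for ovoid nests,
radial spokes for spoke wheel, ...), each drawn from a distinct intensity
range so that the multilabel task is learnable by a small model.

Reproducibility contract: every public generator takes one integer seed and
is bit-reproducible given (seed, parameters).  Independent components derive
their streams with ``numpy.random.SeedSequence(seed, spawn_key=(k,))`` where
``k`` is a fixed documented component index (see ``_COMPONENT_KEYS``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .patterns import N_PATTERNS, PATTERN_NAMES, validate_pattern_matrix

# Fixed spawn keys of the per-component random streams.
_COMPONENT_KEYS = {
    "lesion_dataset": 0,
    "raters": 1,
    "activation_map": 2,
    "augment": 3,
    "training": 4,
    "pipeline": 5,
}

# Characteristic paint intensity per pattern; background skin sits at 0.42.
# The eight bands (7 patterns + background) are evenly spaced over [0, 1]
# with gaps of ~0.13, an order of magnitude above the pixel noise, so every
# pattern occupies its own disjoint intensity band.
_PATTERN_VALUES = {
    "U": 0.03,
    "PN": 0.16,
    "AT": 0.29,
    "SW": 0.55,
    "ML": 0.68,
    "MG": 0.81,
    "ON": 0.94,
}
_BACKGROUND_VALUE = 0.42
_PATTERN_NOISE_SD = 0.015


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Return the documented independent random stream for a component."""
    if component not in _COMPONENT_KEYS:
        raise ValueError(f"unknown component {component!r}")
    ss = np.random.SeedSequence(int(seed), spawn_key=(_COMPONENT_KEYS[component],))
    return np.random.default_rng(ss)


@dataclass
class RaterSpec:
    """Per-pattern annotation skill of one simulated rater.

    ``sensitivity[j]`` is P(vote=1 | truth=1) and ``specificity[j]`` is
    P(vote=0 | truth=0) for pattern ``j`` in canonical order.
    """

    sensitivity: np.ndarray
    specificity: np.ndarray

    def __post_init__(self):
        self.sensitivity = np.broadcast_to(
            np.asarray(self.sensitivity, dtype=float), (N_PATTERNS,)
        ).copy()
        self.specificity = np.broadcast_to(
            np.asarray(self.specificity, dtype=float), (N_PATTERNS,)
        ).copy()
        for name, arr in (("sensitivity", self.sensitivity),
                          ("specificity", self.specificity)):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    """A generated cohort: images, truth labels, per-pattern masks, metadata.

    Invariants: a mask exists for pattern ``j`` of image ``i`` exactly when
    ``true_labels[i, j] == 1``; every mask is non-empty and has the image's
    spatial shape.
    """

    images: list[np.ndarray]
    true_labels: np.ndarray
    masks: list[dict[str, np.ndarray]]
    image_ids: list[str]
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def n_images(self) -> int:
        return len(self.images)

    def union_mask(self, i: int) -> np.ndarray:
        """Union of the image's per-pattern masks (the integrated foreground).

        Returns an all-False grid when the image carries no pattern.
        """
        out = np.zeros(self.images[i].shape, dtype=bool)
        for m in self.masks[i].values():
            out |= m
        return out


def _disk(shape, center, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _render_pattern(name: str, shape, center, radius, rng) -> np.ndarray:
    """Return the boolean footprint of one stylized pattern instance."""
    cy, cx = center
    if name == "PN":  # reticular grid of lines inside a disk
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        pitch = max(4, int(radius / 3))
        lines = ((yy + xx) % pitch < 2.5) | ((yy - xx) % pitch < 2.5)
        fp = lines & _disk(shape, center, radius)
    elif name == "U":  # one compact dark patch
        fp = _disk(shape, center, radius * 0.85)
    elif name == "ON":  # a few large bright blobs
        fp = np.zeros(shape, dtype=bool)
        for _ in range(3):
            off = rng.uniform(-radius * 0.6, radius * 0.6, size=2)
            fp |= _disk(shape, (cy + off[0], cx + off[1]), radius * 0.55)
    elif name == "MG":  # many small globules scattered in the region
        fp = np.zeros(shape, dtype=bool)
        for _ in range(12):
            off = rng.uniform(-radius, radius, size=2)
            fp |= _disk(shape, (cy + off[0], cx + off[1]), max(2.0, radius * 0.22))
    elif name == "ML":  # lobulated structure: overlapping disks along an arc
        fp = np.zeros(shape, dtype=bool)
        theta0 = rng.uniform(0, 2 * np.pi)
        for k in range(5):
            th = theta0 + k * 0.5
            fp |= _disk(
                shape,
                (cy + 0.6 * radius * np.sin(th), cx + 0.6 * radius * np.cos(th)),
                radius * 0.42,
            )
    elif name == "SW":  # radial spokes around a hub
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        dy, dx = yy - cy, xx - cx
        rr = np.hypot(dy, dx)
        ang = np.arctan2(dy, dx)
        spokes = (np.mod(ang * 8 / (2 * np.pi), 1.0) < 0.35) & (rr <= radius)
        fp = spokes | _disk(shape, center, radius * 0.2)
    elif name == "AT":  # branching vessel-like polylines
        fp = np.zeros(shape, dtype=bool)
        for _ in range(6):
            y, x = float(cy), float(cx)
            th = rng.uniform(0, 2 * np.pi)
            for _ in range(int(radius * 2)):
                th += rng.normal(0, 0.35)
                y += np.sin(th)
                x += np.cos(th)
                iy, ix = int(round(y)), int(round(x))
                if 0 <= iy < shape[0] and 0 <= ix < shape[1]:
                    fp[max(0, iy - 1) : iy + 2, max(0, ix - 1) : ix + 2] = True
    else:  # pragma: no cover - guarded by canonical pattern list
        raise ValueError(f"unknown pattern {name!r}")
    if not fp.any():
        fp[int(cy) % shape[0], int(cx) % shape[1]] = True
    return fp


def generate_lesion_dataset(
    n_images: int,
    prevalence=None,
    image_size: int = 64,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a seeded cohort of stylized lesion images with masks.

    Each of the 7 patterns is drawn independently per image from its
    prevalence; every present pattern is rendered as a distinct textured
    region and its footprint recorded as that pattern's mask.

    Parameters
    ----------
    n_images : int
        Cohort size, >= 1.
    prevalence : array-like of shape (7,), optional
        Per-pattern presence probability in canonical order.  The default
        (0.35, 0.30, 0.25, 0.15, 0.15, 0.12, 0.30) mimics a BCC-screening
        cohort with under-represented multiglobules / maple-leaf / spoke
        wheel patterns.
    image_size : int
        Side length in pixels, >= 32.
    seed : int
        Global seed; the ``lesion_dataset`` component stream is derived
        from it.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if image_size < 32:
        raise ValueError("image_size must be >= 32")
    if prevalence is None:
        prevalence = (0.35, 0.30, 0.25, 0.15, 0.15, 0.12, 0.30)
    prevalence = np.asarray(prevalence, dtype=float)
    if prevalence.shape != (N_PATTERNS,):
        raise ValueError(f"prevalence must have shape ({N_PATTERNS},)")
    if ((prevalence < 0) | (prevalence > 1)).any():
        raise ValueError("prevalence entries must lie in [0, 1]")

    rng = component_rng(seed, "lesion_dataset")
    shape = (image_size, image_size)
    images, masks_all = [], []
    labels = np.zeros((n_images, N_PATTERNS), dtype=int)
    half = image_size / 2.0
    for i in range(n_images):
        img = _BACKGROUND_VALUE + 0.02 * ndimage.gaussian_filter(
            rng.standard_normal(shape), sigma=3.0
        )
        flags = (rng.random(N_PATTERNS) < prevalence).astype(int)
        labels[i] = flags
        masks: dict[str, np.ndarray] = {}
        # Present patterns are dealt to distinct angular sectors around the
        # image centre so their textured regions rarely overwrite each other
        # (lesions show their patterns in distinct areas).
        present = [j for j in range(N_PATTERNS) if flags[j]]
        sectors = rng.permutation(8)[: len(present)]
        occupied = np.zeros(shape, dtype=bool)
        for j, sector in zip(present, sectors):
            name = PATTERN_NAMES[j]
            theta = 2 * np.pi * (sector + rng.uniform(0.25, 0.75)) / 8
            dist = rng.uniform(0.18, 0.30) * image_size
            center = (half + dist * np.sin(theta), half + dist * np.cos(theta))
            radius = rng.uniform(0.12, 0.18) * image_size
            fp = _render_pattern(name, shape, center, radius, rng)
            # a pattern's mask is the region where it is actually visible:
            # pixels already claimed by another pattern are not repainted
            fp_vis = fp & ~occupied
            if fp_vis.any():
                fp = fp_vis
            occupied |= fp
            img[fp] = _PATTERN_VALUES[name] + _PATTERN_NOISE_SD * (
                rng.standard_normal(int(fp.sum()))
            )
            masks[name] = fp
        images.append(np.clip(img, 0.0, 1.0))
        masks_all.append(masks)
    return SyntheticDataset(
        images=images,
        true_labels=labels,
        masks=masks_all,
        image_ids=[f"img_{i:05d}" for i in range(n_images)],
        seed=int(seed),
        params={
            "n_images": int(n_images),
            "prevalence": prevalence.tolist(),
            "image_size": int(image_size),
        },
    )


def simulate_raters(
    true_labels,
    rater_specs: list[RaterSpec],
    seed: int = 0,
) -> np.ndarray:
    """Simulate noisy multi-rater annotations of the truth labels.

    Every vote is an independent Bernoulli draw:
    P(vote=1 | truth=1) = sensitivity, P(vote=0 | truth=0) = specificity.

    Returns
    -------
    numpy.ndarray of shape (n_raters, n_images, 7)
        Binary vote tensor.
    """
    labels = validate_pattern_matrix(true_labels)
    if labels.shape[0] == 0:
        raise ValueError("true_labels must contain at least one image")
    if len(rater_specs) < 1:
        raise ValueError("at least one rater is required")
    rng = component_rng(seed, "raters")
    n = labels.shape[0]
    votes = np.zeros((len(rater_specs), n, N_PATTERNS), dtype=float)
    for r, spec in enumerate(rater_specs):
        p_one = np.where(labels == 1, spec.sensitivity, 1.0 - spec.specificity)
        votes[r] = (rng.random((n, N_PATTERNS)) < p_one).astype(float)
    return votes


def clipped_normal_mean(mu: float, sd: float) -> float:
    """Expectation of a N(mu, sd) draw clipped to [0, 1] (closed form)."""
    if sd == 0:
        return float(np.clip(mu, 0.0, 1.0))
    from scipy.stats import norm

    a = (0.0 - mu) / sd
    b = (1.0 - mu) / sd
    interior = mu * (norm.cdf(b) - norm.cdf(a)) - sd * (norm.pdf(b) - norm.pdf(a))
    return float(interior + 1.0 * norm.sf(b))


def generate_activation_map(
    mask,
    fg_mean: float,
    fg_sd: float,
    bg_mean: float,
    bg_sd: float,
    smooth_radius: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Generate a saliency-like map with separate foreground/background laws.

    Pixels inside the mask are drawn from N(fg_mean, fg_sd), outside from
    N(bg_mean, bg_sd); all draws are clipped to [0, 1] (so empirical means
    match the requested means only up to the clipped-normal transform — see
    :func:`clipped_normal_mean`), then optionally Gaussian-smoothed with
    ``sigma = smooth_radius``.  Smoothing preserves the [0, 1] range.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D grid")
    if fg_sd < 0 or bg_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = component_rng(seed, "activation_map")
    z = np.where(
        mask,
        fg_mean + fg_sd * rng.standard_normal(mask.shape),
        bg_mean + bg_sd * rng.standard_normal(mask.shape),
    )
    z = np.clip(z, 0.0, 1.0)
    if smooth_radius > 0:
        z = ndimage.gaussian_filter(z, sigma=smooth_radius)
    return z


# ---------------------------------------------------------------------------
# On-disk layout: PNG images (8-bit grayscale), PNG masks (0/255), CSV labels
# and annotations, JSON parameter sidecar.  PNG quantizes intensities to 256
# levels; in-memory regeneration from (seed, params) remains bit-exact.
# ---------------------------------------------------------------------------

def _annotation_frame(votes, image_ids) -> pd.DataFrame:
    rows = []
    for r in range(votes.shape[0]):
        for i, img_id in enumerate(image_ids):
            rows.append(
                [img_id, f"rater_{r}", *votes[r, i].astype(int).tolist()]
            )
    return pd.DataFrame(
        rows, columns=["image_id", "rater_id", *PATTERN_NAMES]
    )


def save_dataset(dataset: SyntheticDataset, out_dir, votes=None) -> None:
    """Write the dataset (and optional annotations) to a directory."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for i, img_id in enumerate(dataset.image_ids):
        arr = (np.clip(dataset.images[i], 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / "images" / f"{img_id}.png")
        for name, m in dataset.masks[i].items():
            Image.fromarray((m.astype(np.uint8)) * 255, mode="L").save(
                out / "masks" / f"{img_id}_{name}.png"
            )
    frame = pd.DataFrame(dataset.true_labels, columns=list(PATTERN_NAMES))
    frame.insert(0, "image_id", dataset.image_ids)
    frame.to_csv(out / "labels.csv", index=False)
    if votes is not None:
        _annotation_frame(votes, dataset.image_ids).to_csv(
            out / "annotations.csv", index=False
        )
    with open(out / "params.json", "w") as fh:
        json.dump({"seed": dataset.seed, **dataset.params}, fh, indent=2)


def load_dataset(in_dir) -> SyntheticDataset:
    """Load a dataset previously written by :func:`save_dataset`."""
    src = Path(in_dir)
    frame = pd.read_csv(src / "labels.csv")
    image_ids = frame["image_id"].astype(str).tolist()
    labels = validate_pattern_matrix(frame[list(PATTERN_NAMES)].to_numpy())
    with open(src / "params.json") as fh:
        params = json.load(fh)
    seed = int(params.pop("seed", 0))
    images, masks_all = [], []
    for i, img_id in enumerate(image_ids):
        img = np.asarray(Image.open(src / "images" / f"{img_id}.png"), float) / 255.0
        images.append(img)
        masks = {}
        for j, name in enumerate(PATTERN_NAMES):
            if labels[i, j]:
                m = np.asarray(Image.open(src / "masks" / f"{img_id}_{name}.png"))
                masks[name] = m > 127
        masks_all.append(masks)
    return SyntheticDataset(
        images=images,
        true_labels=labels,
        masks=masks_all,
        image_ids=image_ids,
        seed=seed,
        params=params,
    )


def load_annotations(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an annotation CSV into a (raters, images, 7) vote tensor.

    Missing (image, rater) rows become NaN votes.
    """
    frame = pd.read_csv(path)
    image_ids = list(dict.fromkeys(frame["image_id"].astype(str)))
    rater_ids = list(dict.fromkeys(frame["rater_id"].astype(str)))
    img_ix = {v: i for i, v in enumerate(image_ids)}
    rat_ix = {v: r for r, v in enumerate(rater_ids)}
    votes = np.full((len(rater_ids), len(image_ids), N_PATTERNS), np.nan)
    for _, row in frame.iterrows():
        votes[rat_ix[str(row["rater_id"])], img_ix[str(row["image_id"])]] = (
            row[list(PATTERN_NAMES)].to_numpy(dtype=float)
        )
    return votes, image_ids, rater_ids
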