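"""Synthetic multi-class segmentation phantoms.

Each phantom is a grayscale image + integer label mask containing structures
at several spatial scales — a large ellipse (long-range context), a handful
of small disks (finer than the attention sampling grid), and a thin annulus
(boundary accuracy) — with per-class intensity means close enough, relative
to the additive Gaussian noise, that pixels are not separable without
spatial context.  Phantoms stand in for CT/MR slices in tests and smoke
training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import draw

__all__ = ["PhantomSpec", "generate_phantom", "make_dataset", "Dataset"]

_FAMILIES = ("ellipse", "disks", "annulus", "disk")


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one phantom.

    ``families`` assigns a shape family to each foreground class 1..K-1 in
    order.  ``disk`` is an exactly rasterized centered circle of radius
    ``disk_radius`` (useful for geometric oracles).  Intensity means default
    to an even spread over [0.2, 0.95]; noise_std 0.15 leaves adjacent
    classes ~1.7σ apart, so labels are recoverable from context, not from
    single pixels.
    """

    side: int = 64
    num_classes: int = 4
    families: tuple = ("ellipse", "disks", "annulus")
    intensity_means: tuple | None = None
    noise_std: float = 0.15
    seed: int = 0
    disk_radius: float | None = None

    def __post_init__(self):
        if self.side < 32:
            raise ValueError(f"side must be >= 32, got {self.side}")
        if self.num_classes < 2:
            raise ValueError(f"need >= 2 classes, got {self.num_classes}")
        if self.num_classes - 1 > len(self.families):
            raise ValueError(
                f"{self.num_classes - 1} foreground classes but only "
                f"{len(self.families)} shape families"
            )
        for f in self.families:
            if f not in _FAMILIES:
                raise ValueError(f"unknown family {f!r}; valid: {_FAMILIES}")

    @property
    def means(self) -> np.ndarray:
        if self.intensity_means is not None:
            m = np.asarray(self.intensity_means, dtype=float)
            if m.shape != (self.num_classes,):
                raise ValueError(
                    f"intensity_means shape {m.shape} != ({self.num_classes},)"
                )
            return m
        return np.linspace(0.2, 0.95, self.num_classes)


def _free(mask: np.ndarray, rr, cc, side: int) -> bool:
    ok = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
    if not ok.all():
        return False
    return not mask[rr, cc].any()


def _place_ellipse(mask, k, side, rng):
    for _ in range(200):
        r0 = side / 2 + rng.uniform(-0.03, 0.03) * side
        c0 = side / 2 + rng.uniform(-0.03, 0.03) * side
        a = rng.uniform(0.25, 0.30) * side
        b = rng.uniform(0.18, 0.24) * side
        rot = rng.uniform(0, np.pi)
        rr, cc = draw.ellipse(r0, c0, a, b, rotation=rot)
        if _free(mask, rr, cc, side) and len(rr) >= 4:
            mask[rr, cc] = k
            return (r0, c0), max(a, b)
    raise RuntimeError(f"could not place ellipse for class {k}")


def _place_disks(mask, k, side, rng):
    n = int(rng.integers(2, 5))
    placed = 0
    for _ in range(400):
        if placed == n:
            return
        r = rng.uniform(1.6, 2.8)  # diameter < the 7-point sampling grid
        r0 = rng.uniform(r + 2, side - r - 2)
        c0 = rng.uniform(r + 2, side - r - 2)
        rr, cc = draw.disk((r0, c0), r + 1.0)  # +1: enforce a 1 px margin
        if _free(mask, rr, cc, side):
            rr, cc = draw.disk((r0, c0), r)
            if len(rr) >= 4:
                mask[rr, cc] = k
                placed += 1
    if placed == 0:
        raise RuntimeError(f"could not place any disk for class {k}")


def _place_annulus(mask, k, side, rng, around=None):
    """Thin ring; if ``around`` gives a placed ellipse, the ring encircles it
    (the concentric layout of cardiac structures), otherwise free placement."""
    yy, xx = np.mgrid[0:side, 0:side]
    for _ in range(200):
        t = rng.uniform(2.0, 3.0)
        if around is not None:
            (r0, c0), max_semi = around
            ro = max_semi + rng.uniform(2.0, 3.5) + t
        else:
            ro = rng.uniform(0.15, 0.20) * side
            r0 = rng.uniform(ro + 2, side - ro - 2)
            c0 = rng.uniform(ro + 2, side - ro - 2)
        if not (2 <= r0 - ro and r0 + ro < side - 2 and 2 <= c0 - ro and c0 + ro < side - 2):
            continue
        d = np.hypot(yy - r0, xx - c0)
        ring = (d <= ro) & (d > ro - t)
        if not (ring & (mask > 0)).any() and ring.sum() >= 4:
            mask[ring] = k
            return
    raise RuntimeError(f"could not place annulus for class {k}")


def _place_centered_disk(mask, k, side, radius):
    yy, xx = np.mgrid[0:side, 0:side]
    c = (side - 1) / 2.0
    disk = (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    mask[disk] = k


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic phantom for ``spec``: returns ``(image, mask)`` with a
    float image and an integer label mask of shape ``(side, side)``."""
    rng = np.random.default_rng(spec.seed)
    side = spec.side
    mask = np.zeros((side, side), dtype=np.int64)
    # big structures claim space first (the ring encircles the ellipse, so it
    # must go down before small disks can block its band)
    priority = {"ellipse": 0, "disk": 0, "annulus": 1, "disks": 2}
    order = sorted(
        range(1, spec.num_classes), key=lambda k: priority[spec.families[k - 1]]
    )
    ellipse_info = None
    for k in order:
        family = spec.families[k - 1]
        if family == "ellipse":
            ellipse_info = _place_ellipse(mask, k, side, rng)
        elif family == "disks":
            _place_disks(mask, k, side, rng)
        elif family == "annulus":
            _place_annulus(mask, k, side, rng, around=ellipse_info)
        else:  # centered disk with exact radius
            radius = spec.disk_radius if spec.disk_radius is not None else 0.25 * side
            _place_centered_disk(mask, k, side, radius)
    image = spec.means[mask]
    if spec.noise_std > 0:
        image = image + rng.normal(0.0, spec.noise_std, size=image.shape)
    return image.astype(np.float64), mask


@dataclass
class Dataset:
    train: list
    val: list

    def __iter__(self):
        return iter(self.train + self.val)


def make_dataset(
    n: int, spec: PhantomSpec, split: float = 0.8, seed: int | None = None
) -> Dataset:
    """Generate ``n`` phantoms and split them into disjoint train/val sets.

    The split is deterministic given the seed; a new seed reshuffles the
    membership but keeps the split sizes.
    """
    if n < 2:
        raise ValueError(f"need at least 2 cases for a train/val split, got {n}")
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=n)
    cases = [
        generate_phantom(
            PhantomSpec(
                side=spec.side,
                num_classes=spec.num_classes,
                families=spec.families,
                intensity_means=spec.intensity_means,
                noise_std=spec.noise_std,
                seed=int(s),
                disk_radius=spec.disk_radius,
            )
        )
        for s in case_seeds
    ]
    perm = rng.permutation(n)
    n_train = max(1, min(n - 1, int(round(n * split))))
    train_idx = set(perm[:n_train].tolist())
    train = [cases[i] for i in range(n) if i in train_idx]
    val = [cases[i] for i in range(n) if i not in train_idx]
    return Dataset(train=train, val=val)
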