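"""Synthetic colony generator.

Produces ground-truthed nucleus point patterns and rendered fluorescence-like
images whose spatial clustering and nuclear morphology vary with a virtual
irradiation dose.  Two point processes span the observed contrast:

* ``uniform`` — a hard-core (minimum-separation) binomial process, emulating
  the homogeneous cell layout of unirradiated colonies;
* ``clustered`` — a Thomas process (Gaussian-dispersed offspring around
  uniformly placed parents), emulating the irregular, locally dense packing
  seen at high dose.

Nuclei are rendered as filled ellipses on a dark background at a configurable
bit depth (14-bit by default, stored in 16-bit TIFF containers), with additive
Gaussian read-out noise.  Every generator is a pure function of its arguments
and a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ColonyConfig",
    "GroundTruth",
    "FieldTooCrowdedError",
    "sample_centers_uniform",
    "sample_centers_clustered",
    "sample_shapes",
    "render_colony",
    "emulate_dose_series",
]


class FieldTooCrowdedError(RuntimeError):
    """Raised when a hard-core pattern cannot be placed in the field."""


@dataclass(frozen=True)
class ColonyConfig:
    """Parameters of one synthetic colony image.

    ``layout`` selects the point process.  ``min_separation_px`` applies to the
    uniform layout only; ``cluster_parent_count`` / ``cluster_sigma_px`` to the
    clustered layout only.  Intensities are in camera counts; values are
    clipped to ``[0, 2**bit_depth - 1]`` at render time.
    """

    field_width_px: int = 1400
    field_height_px: int = 1400
    n_cells: int = 300
    layout: str = "uniform"
    min_separation_px: float = 12.0
    cluster_parent_count: int = 12
    cluster_sigma_px: float = 18.0
    nucleus_mean_radius_px: float = 4.0
    nucleus_radius_cv: float = 0.08
    nucleus_axis_ratio: float = 1.4
    intensity_foreground: int = 8000
    intensity_background: int = 200
    noise_sigma: float = 50.0
    bit_depth: int = 14
    pixel_size_um: float = 0.7373
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in ("uniform", "clustered"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.field_width_px < 1 or self.field_height_px < 1 or self.n_cells < 1:
            raise ValueError("field dimensions and n_cells must be positive")
        top = 2**self.bit_depth - 1
        if not (0 <= self.intensity_background < self.intensity_foreground <= top):
            raise ValueError(
                "need 0 <= background < foreground <= 2**bit_depth - 1, got "
                f"{self.intensity_background}, {self.intensity_foreground}, {top}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.nucleus_mean_radius_px < 2:
            # nuclei smaller than this would be clipped by the 8-px area filter
            raise ValueError("nucleus_mean_radius_px must be >= 2")
        if self.nucleus_axis_ratio < 1:
            raise ValueError("nucleus_axis_ratio must be >= 1 (major/minor)")
        if self.layout == "clustered":
            if self.cluster_parent_count < 1:
                raise ValueError("cluster_parent_count must be >= 1")
            if self.cluster_sigma_px <= 0:
                raise ValueError("cluster_sigma_px must be > 0")

    def replace(self, **kw) -> "ColonyConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """True nucleus centers, shapes and the label partition of one image.

    ``label_mask`` assigns every rendered foreground pixel to exactly one
    nucleus (1-based labels; 0 is background); overlaps are resolved to the
    nearest center so the truth remains a partition.
    """

    centers: np.ndarray  # (n, 2) float, (x, y) pixel coordinates
    label_mask: np.ndarray  # (H, W) int32
    shapes: np.ndarray  # (n, 3): semi_major_px, semi_minor_px, orientation_rad

    @property
    def n_cells(self) -> int:
        return len(self.centers)


def sample_centers_uniform(
    n: int,
    width: float,
    height: float,
    min_separation: float = 0.0,
    seed: int = 0,
    max_attempts: int | None = None,
) -> np.ndarray:
    """Hard-core binomial point pattern: n points, pairwise distance >= min_separation.

    Sequential rejection sampling with a bounded attempt budget (default
    ``max(10_000, 500 * n)`` candidate draws).  Raises
    :class:`FieldTooCrowdedError` when the budget is exhausted, which also
    covers geometrically infeasible requests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    rng = np.random.default_rng(seed)
    if max_attempts is None:
        max_attempts = max(10_000, 500 * n)
    pts = np.empty((n, 2), dtype=float)
    k = 0
    attempts = 0
    sep2 = min_separation * min_separation
    while k < n:
        if attempts >= max_attempts:
            raise FieldTooCrowdedError(
                f"placed {k}/{n} points at separation {min_separation} in a "
                f"{width}x{height} field after {attempts} attempts: field too crowded"
            )
        cand = rng.uniform((0.0, 0.0), (width, height))
        attempts += 1
        if k == 0 or min_separation == 0:
            pts[k] = cand
            k += 1
            continue
        d2 = np.sum((pts[:k] - cand) ** 2, axis=1)
        if d2.min() >= sep2:
            pts[k] = cand
            k += 1
    return pts


def sample_centers_clustered(
    n: int,
    width: float,
    height: float,
    parents: int,
    sigma: float,
    seed: int = 0,
) -> np.ndarray:
    """Thomas-process point pattern with exactly ``n`` offspring.

    Parent locations are uniform in the field; each offspring picks a parent
    uniformly at random and is displaced by an isotropic Gaussian of scale
    ``sigma``.  Offspring falling outside the field are resampled (fresh
    displacement) so exactly ``n`` in-field points are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if parents < 1:
        raise ValueError("parents must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    parent_xy = rng.uniform((0.0, 0.0), (width, height), size=(parents, 2))
    assignment = rng.integers(0, parents, size=n)
    pts = np.empty((n, 2), dtype=float)
    for i, pa in enumerate(assignment):
        # resample the Gaussian displacement until the point lands in-field
        for _ in range(10_000):
            cand = parent_xy[pa] + rng.normal(0.0, sigma, size=2)
            if 0.0 <= cand[0] < width and 0.0 <= cand[1] < height:
                pts[i] = cand
                break
        else:  # pragma: no cover - only reachable with absurd sigma/field ratios
            pts[i] = np.clip(parent_xy[pa], (0, 0), (width - 1e-9, height - 1e-9))
    return pts


def sample_shapes(n: int, config: ColonyConfig, seed: int = 0) -> np.ndarray:
    """Draw per-nucleus ellipse parameters (semi-major, semi-minor, orientation).

    Equivalent radius varies log-normally around ``nucleus_mean_radius_px``
    with coefficient of variation ``nucleus_radius_cv``; the axis ratio is
    fixed at ``nucleus_axis_ratio`` (area-preserving split a = r*sqrt(q),
    b = r/sqrt(q)); orientation is uniform on [0, pi).  Semi-minor axes are
    floored at 2 px so no true nucleus falls under the small-object filter.
    """
    rng = np.random.default_rng(seed)
    cv = config.nucleus_radius_cv
    if cv > 0:
        s2 = np.log1p(cv * cv)
        radii = rng.lognormal(np.log(config.nucleus_mean_radius_px) - s2 / 2, np.sqrt(s2), n)
    else:
        radii = np.full(n, float(config.nucleus_mean_radius_px))
    q = np.sqrt(config.nucleus_axis_ratio)
    semi_minor = np.maximum(radii / q, 2.0)
    semi_major = np.maximum(radii * q, semi_minor)
    theta = rng.uniform(0.0, np.pi, n)
    return np.column_stack([semi_major, semi_minor, theta])


def _paint_ellipses(centers, shapes, height, width):
    """Label raster for a set of ellipses; overlap goes to the nearest center."""
    label = np.zeros((height, width), dtype=np.int32)
    best_d2 = np.full((height, width), np.inf)
    for idx, ((cx, cy), (a, b, th)) in enumerate(zip(centers, shapes), start=1):
        r_lo = max(int(np.floor(cy - a)) - 1, 0)
        r_hi = min(int(np.ceil(cy + a)) + 2, height)
        c_lo = max(int(np.floor(cx - a)) - 1, 0)
        c_hi = min(int(np.ceil(cx + a)) + 2, width)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        dx = cc - cx
        dy = rr - cy
        ct, st = np.cos(th), np.sin(th)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        d2 = dx * dx + dy * dy
        patch_best = best_d2[r_lo:r_hi, c_lo:c_hi]
        claim = inside & (d2 < patch_best)
        patch_lab = label[r_lo:r_hi, c_lo:c_hi]
        patch_lab[claim] = idx
        patch_best[claim] = d2[claim]
    return label


def render_colony(
    centers: np.ndarray,
    shapes: np.ndarray,
    config: ColonyConfig,
    seed: int | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render nuclei as filled ellipses and return (image, ground truth).

    The image is ``uint16`` with values clipped to ``[0, 2**bit_depth - 1]``;
    noise is additive Gaussian with scale ``config.noise_sigma``.
    """
    centers = np.asarray(centers, dtype=float)
    shapes = np.asarray(shapes, dtype=float)
    if len(centers) == 0:
        raise ValueError("centers must be nonempty")
    if np.any(shapes[:, 1] < 2):
        raise ValueError("semi-minor axes must be >= 2 px")
    h, w = config.field_height_px, config.field_width_px
    label = _paint_ellipses(centers, shapes, h, w)
    img = np.full((h, w), float(config.intensity_background))
    img[label > 0] = float(config.intensity_foreground)
    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        img += rng.normal(0.0, config.noise_sigma, size=img.shape)
    top = 2**config.bit_depth - 1
    img = np.clip(np.rint(img), 0, top).astype(np.uint16)
    return img, GroundTruth(centers=centers, label_mask=label, shapes=shapes)


def simulate_colony(config: ColonyConfig, seed: int | None = None):
    """Sample a point pattern per ``config.layout``, draw shapes and render.

    Returns ``(image, GroundTruth)``.  Convenience wrapper combining the
    sampling and rendering stages with seeds derived from one master seed.
    """
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    s_pts, s_shape, s_noise = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
    if config.layout == "uniform":
        centers = sample_centers_uniform(
            config.n_cells,
            config.field_width_px,
            config.field_height_px,
            config.min_separation_px,
            seed=s_pts,
        )
    else:
        centers = sample_centers_clustered(
            config.n_cells,
            config.field_width_px,
            config.field_height_px,
            config.cluster_parent_count,
            config.cluster_sigma_px,
            seed=s_pts,
        )
    shapes = sample_shapes(config.n_cells, config, seed=s_shape)
    return render_colony(centers, shapes, config, seed=s_noise)


def emulate_dose_series(
    per_dose_configs: dict[float, ColonyConfig],
    images_per_dose: int,
    seed: int,
    out_dir: str | Path,
    line: str = "SYN",
) -> pd.DataFrame:
    """Write a full synthetic dose series to ``out_dir``.

    One 16-bit grayscale TIFF per image, named ``<line>_<dose>Gy_<rep>.tif``,
    plus ``ground_truth.csv`` with columns
    ``image,nucleus_id,x,y,semi_major,semi_minor,orientation``.
    Returns the ground-truth table.  Per-image seeds are derived
    deterministically from ``seed`` and the (dose, replicate) index, so the
    CSV is byte-identical across reruns.
    """
    if not per_dose_configs:
        raise ValueError("per_dose_configs must be nonempty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for d_idx, dose in enumerate(sorted(per_dose_configs)):
        cfg = per_dose_configs[dose]
        for rep in range(images_per_dose):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(d_idx, rep))
            img_seed = int(child.generate_state(1)[0] % (2**31))
            img, truth = simulate_colony(cfg, seed=img_seed)
            dose_str = f"{dose:g}"
            name = f"{line}_{dose_str}Gy_{rep}.tif"
            tifffile.imwrite(out_dir / name, img)
            for i, ((x, y), (a, b, th)) in enumerate(
                zip(truth.centers, truth.shapes), start=1
            ):
                rows.append(
                    {
                        "image": name,
                        "nucleus_id": i,
                        "x": round(float(x), 4),
                        "y": round(float(y), 4),
                        "semi_major": round(float(a), 4),
                        "semi_minor": round(float(b), 4),
                        "orientation": round(float(th), 6),
                    }
                )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "ground_truth.csv", index=False)
    return table
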