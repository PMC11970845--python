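"""Synthetic desk-scale data with the statistical structure of the tasks.

Two generators:

* :func:`gen_mixture_sets` — variable-size sets of vectors drawn from a
  Gaussian mixture with controllable cluster separation, plus the true
  assignments, for exercising the clustering view of the attention update.

* :func:`gen_lesion_image_sets` — sets of small "glomerulus" images: a
  noisy ellipse on a light background, where a positive instance
  additionally carries a crescent-shaped arc hugging the ellipse boundary.
  Cases come from simulated institutions ("cohorts") that differ by a
  global brightness offset and a mild channel tint, emulating stain and
  scanner variation. The ``one_positive`` task plants exactly one lesion
  instance per set with a one-hot target; the ``binary`` task labels cases,
  with positive cases drawing lesion instances at an elevated rate.

Neither generator aims at photo-realism; they provide separable, shiftable
signal so every pipeline stage is testable without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .sets import BuiltSet, InstanceRecord, SetMember

__all__ = [
    "MixtureSetSpec",
    "LesionImageSpec",
    "gen_mixture_sets",
    "gen_lesion_image_sets",
    "write_image_dataset",
    "read_image_dataset",
]


@dataclass
class MixtureSetSpec:
    """Mixture-of-Gaussians set generator parameters.

    ``separation`` is the radius of the sphere the cluster means sit on, in
    units of the within-cluster standard deviation.
    """

    k: int = 2
    dims: int = 2
    separation: float = 10.0
    points_range: tuple[int, int] = (20, 40)
    n_sets: int = 10
    within_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.separation <= 0:
            raise ValueError("separation must be positive")


def gen_mixture_sets(spec: MixtureSetSpec):
    """Generate sets of mixture draws; returns list of (X, assignments)."""
    rng = np.random.default_rng(spec.seed)
    radius = spec.separation * spec.within_sd
    out = []
    for _ in range(spec.n_sets):
        # means on a sphere of the stated radius, resampled so every pair is
        # at least `separation` apart (the radius alone does not guarantee it)
        best, best_gap = None, -np.inf
        for _try in range(200):
            dirs = rng.standard_normal((spec.k, spec.dims))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            cand = dirs * radius
            if spec.k == 1:
                best = cand
                break
            gap = min(np.linalg.norm(cand[i] - cand[j])
                      for i in range(spec.k) for j in range(i + 1, spec.k))
            if gap > best_gap:
                best, best_gap = cand, gap
            if gap >= radius:
                break
        means = best
        m = int(rng.integers(spec.points_range[0], spec.points_range[1] + 1))
        labels = rng.integers(0, spec.k, size=m)
        x = means[labels] + spec.within_sd * rng.standard_normal((m, spec.dims))
        out.append((x.astype(np.float32), labels))
    return out


@dataclass
class LesionImageSpec:
    """Planted-crescent image-set generator parameters.

    ``contrast`` is the darkening the crescent arc applies on the unit
    intensity scale; ``contrast=0`` is the no-signal null (positives and
    negatives identically distributed). ``institution_shifts`` are additive
    brightness offsets per cohort; ``institution_tints`` mild per-channel
    additions. Defaults are the package's separable study conditions.
    """

    image_size: int = 64
    contrast: float = 0.55
    noise_sd: float = 0.08
    institution_shifts: tuple[float, ...] = (0.0, 0.06, -0.06)
    institution_tints: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.0, 0.0), (0.02, -0.01, 0.0), (-0.01, 0.0, 0.02))
    n_cases: int = 200
    m_neg_range: tuple[int, int] = (3, 7)     # one-positive task
    m_range: tuple[int, int] = (4, 8)         # binary task
    p_pos: float = 0.7                        # lesion rate inside positive cases
    p_neg: float = 0.05                       # lesion rate inside negative cases
    seed: int = 0

    def __post_init__(self):
        if self.contrast < 0:
            raise ValueError("contrast must be nonnegative")
        if len(self.institution_shifts) < 2:
            raise ValueError("need >= 2 cohorts to emulate institution shifts")


def _draw_glomerulus(rng: np.random.Generator, spec: LesionImageSpec,
                     lesion: bool) -> np.ndarray:
    """One instance image: noisy ellipse, optional boundary crescent."""
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
    cy = s / 2 + rng.uniform(-s * 0.06, s * 0.06)
    cx = s / 2 + rng.uniform(-s * 0.06, s * 0.06)
    ry = rng.uniform(0.28, 0.4) * s
    rx = rng.uniform(0.28, 0.4) * s
    r = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)

    img = np.full((s, s, 3), 0.92, dtype=np.float32)
    tuft = np.array([0.80, 0.66, 0.72], dtype=np.float32)   # PAS-pink-ish
    inside = r <= 1.0
    img[inside] = tuft

    if lesion and spec.contrast > 0:
        theta = np.arctan2(yy - cy, xx - cx)
        theta0 = rng.uniform(-np.pi, np.pi)
        span = np.deg2rad(rng.uniform(90.0, 180.0))
        dtheta = np.mod(theta - theta0, 2 * np.pi)
        ring = (r > 0.72) & (r <= 1.0) & (dtheta <= span)
        img[ring] -= spec.contrast
    img += spec.noise_sd * rng.standard_normal(img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0)


def _apply_cohort(img: np.ndarray, spec: LesionImageSpec, cohort: int) -> np.ndarray:
    out = img + spec.institution_shifts[cohort]
    out = out + np.asarray(spec.institution_tints[cohort], dtype=np.float32)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def gen_lesion_image_sets(spec: LesionImageSpec, task: str = "one_positive"):
    """Generate cases of instance images plus built sets and a manifest.

    Returns ``(pool, built_sets, manifest)``: a dict instance_id ->
    :class:`~picaso.sets.InstanceRecord`, one :class:`~picaso.sets.BuiltSet`
    per case, and a tidy manifest DataFrame (instance_id, group_id, cohort,
    label, set_id).
    """
    if task not in ("one_positive", "binary"):
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng(spec.seed)
    n_cohorts = len(spec.institution_shifts)
    pool: dict[str, InstanceRecord] = {}
    built: list[BuiltSet] = []
    rows = []
    for c in range(spec.n_cases):
        cohort = c % n_cohorts
        gid = f"case{c:05d}"
        if task == "one_positive":
            m_neg = int(rng.integers(spec.m_neg_range[0], spec.m_neg_range[1] + 1))
            lesions = [False] * m_neg + [True]
            label = None
        else:
            m = int(rng.integers(spec.m_range[0], spec.m_range[1] + 1))
            label = int(rng.random() < 0.5)
            p = spec.p_pos if label else spec.p_neg
            lesions = list(rng.random(m) < p)
        order = rng.permutation(len(lesions))
        lesions = [lesions[j] for j in order]
        members = []
        target = np.zeros(len(lesions), dtype=np.float32)
        for i, lesion in enumerate(lesions):
            iid = f"{gid}_g{i:02d}"
            img = _apply_cohort(_draw_glomerulus(rng, spec, lesion), spec, cohort)
            rec_label = int(lesion) if task == "one_positive" else label
            pool[iid] = InstanceRecord(instance_id=iid, group_id=gid,
                                       label=rec_label, image=img,
                                       cohort=f"inst{cohort}")
            members.append(SetMember(iid))
            if lesion:
                target[i] = 1.0
            rows.append(dict(instance_id=iid, group_id=gid,
                             cohort=f"inst{cohort}", label=int(lesion),
                             set_id=f"set{c:05d}"))
        tgt = target if task == "one_positive" else np.float32(label)
        built.append(BuiltSet(set_id=f"set{c:05d}", members=members,
                              target=tgt, group_id=gid, seed=spec.seed))
    return pool, built, pd.DataFrame(rows)


def write_image_dataset(path, pool, manifest: pd.DataFrame) -> None:
    """Persist instances as PNGs plus a CSV manifest (adds a 'path' column)."""
    path = Path(path)
    (path / "images").mkdir(parents=True, exist_ok=True)
    paths = []
    for iid in manifest["instance_id"]:
        rec = pool[iid]
        rel = f"images/{iid}.png"
        iio.imwrite(path / rel, (rec.image * 255).astype(np.uint8))
        paths.append(rel)
    manifest = manifest.assign(path=paths)
    manifest.to_csv(path / "manifest.csv", index=False)


def read_image_dataset(path):
    """Inverse of :func:`write_image_dataset` (intensities on [0, 1])."""
    path = Path(path)
    manifest = pd.read_csv(path / "manifest.csv")
    pool: dict[str, InstanceRecord] = {}
    for row in manifest.itertuples():
        img = iio.imread(path / row.path).astype(np.float32) / 255.0
        pool[row.instance_id] = InstanceRecord(
            instance_id=row.instance_id, group_id=row.group_id,
            label=int(row.label), image=img, cohort=row.cohort)
    return pool, manifest
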