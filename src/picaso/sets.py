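"""Monte Carlo construction of instance sets from a labelled pool.

Mirrors the experimental design used for the two clinical tasks: for lesion
detection, each training set holds m in [3, 7] lesion-free instances plus
exactly one lesion instance (total size in [4, 8]) with a one-hot target
marking the lesion; for case-level classification, each set holds m in
[4, 8] instances drawn from one case and inherits the case label. Negatives
default to being drawn from the positive's own group (whole-slide image);
when a group has too few distinct instances, online augmentation fills the
set with perturbed copies, which are flagged so evaluation can exclude them.

Cross-validation folds are group-aware: instances from one group never
straddle the train/validation boundary of a fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize, rotate
from sklearn.model_selection import GroupKFold

__all__ = [
    "InstanceRecord",
    "SetMember",
    "BuiltSet",
    "build_one_positive_sets",
    "build_binary_sets",
    "augment_instance",
    "group_kfold_split",
    "preprocess_crop",
    "materialize",
]


@dataclass
class InstanceRecord:
    """One instance in the pool: an image (or vector) with its provenance."""

    instance_id: str
    group_id: str
    label: int                      # lesion flag (instance task) or case label
    image: np.ndarray | None = None
    vector: np.ndarray | None = None
    cohort: str = ""

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.image is None and self.vector is None:
            raise ValueError("record needs an image or a vector")


@dataclass
class SetMember:
    instance_id: str
    augmented: bool = False
    aug_seed: int | None = None


@dataclass
class BuiltSet:
    """One sampled set: ordered members (order is semantically irrelevant),
    a one-hot or scalar target, and the seed it was drawn under."""

    set_id: str
    members: list[SetMember]
    target: np.ndarray              # one-hot over members, or shape-() scalar
    group_id: str
    seed: int

    @property
    def size(self) -> int:
        return len(self.members)


def _pool_by_group(pool: list[InstanceRecord]) -> dict[str, list[InstanceRecord]]:
    groups: dict[str, list[InstanceRecord]] = {}
    for rec in pool:
        groups.setdefault(rec.group_id, []).append(rec)
    return groups


def build_one_positive_sets(pool: list[InstanceRecord], n_sets: int,
                            m_range: tuple[int, int] = (3, 7), seed: int = 0,
                            same_group: bool = True) -> list[BuiltSet]:
    """Sample sets of (m in ``m_range``) negatives plus exactly one positive.

    The number of negatives is drawn uniformly from ``m_range`` per set, so
    total sizes are uniform on [m_range[0]+1, m_range[1]+1]. With
    ``same_group`` the negatives come from the positive's group; groups with
    fewer distinct negatives than drawn are completed with augmented copies.
    """
    rng = np.random.default_rng(seed)
    positives = [r for r in pool if r.label == 1]
    negatives = [r for r in pool if r.label == 0]
    if not positives:
        raise ValueError("pool holds no positive instances")
    if len(negatives) < m_range[0]:
        raise ValueError("pool holds too few negatives to fill any set")
    by_group = _pool_by_group(pool)

    built: list[BuiltSet] = []
    for i in range(n_sets):
        pos = positives[rng.integers(len(positives))]
        m = int(rng.integers(m_range[0], m_range[1] + 1))
        if same_group:
            candidates = [r for r in by_group[pos.group_id] if r.label == 0]
            if not candidates:
                raise ValueError(
                    f"group {pos.group_id!r} has no negatives and "
                    "same_group sampling is on"
                )
        else:
            candidates = negatives
        take = min(m, len(candidates))
        idx = rng.choice(len(candidates), size=take, replace=False)
        members = [SetMember(candidates[j].instance_id) for j in idx]
        # online augmentation completes short groups with perturbed copies
        while len(members) < m:
            src = candidates[int(rng.integers(len(candidates)))]
            members.append(SetMember(src.instance_id, augmented=True,
                                     aug_seed=int(rng.integers(2**31))))
        members.append(SetMember(pos.instance_id))
        order = rng.permutation(len(members))
        members = [members[j] for j in order]
        target = np.zeros(len(members), dtype=np.float32)
        target[[members[j].instance_id == pos.instance_id and not members[j].augmented
                for j in range(len(members))].index(True)] = 1.0
        built.append(BuiltSet(set_id=f"set{i:06d}", members=members,
                              target=target, group_id=pos.group_id, seed=seed))
    return built


def build_binary_sets(pool: list[InstanceRecord], n_sets: int,
                      m_range: tuple[int, int] = (4, 8),
                      seed: int = 0) -> list[BuiltSet]:
    """Sample per-case sets of m in ``m_range`` instances with the case label.

    All members of one set share a group (case); the scalar target is the
    group's label (records of one group must agree on it).
    """
    rng = np.random.default_rng(seed)
    by_group = _pool_by_group(pool)
    group_ids = sorted(by_group)
    built: list[BuiltSet] = []
    for i in range(n_sets):
        gid = group_ids[int(rng.integers(len(group_ids)))]
        recs = by_group[gid]
        labels = {r.label for r in recs}
        if len(labels) != 1:
            raise ValueError(f"group {gid!r} mixes case labels {labels}")
        m = int(rng.integers(m_range[0], m_range[1] + 1))
        take = min(m, len(recs))
        idx = rng.choice(len(recs), size=take, replace=False)
        members = [SetMember(recs[j].instance_id) for j in idx]
        while len(members) < m:
            src = recs[int(rng.integers(len(recs)))]
            members.append(SetMember(src.instance_id, augmented=True,
                                     aug_seed=int(rng.integers(2**31))))
        built.append(BuiltSet(set_id=f"set{i:06d}", members=members,
                              target=np.float32(labels.pop()),
                              group_id=gid, seed=seed))
    return built


def augment_instance(image: np.ndarray, seed: int,
                     crop_scale: tuple[float, float] = (0.7, 1.0),
                     max_rotation: float = 30.0) -> np.ndarray:
    """Random resized crop + vertical flip (p=0.5) + rotation, seeded.

    Output spatial size equals the input's. Parameter ranges (crop area
    fraction, rotation degrees) are package defaults.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.size == 0:
        raise ValueError("empty image")
    rng = np.random.default_rng(seed)
    h, w = img.shape[:2]
    # random resized crop
    scale = rng.uniform(*crop_scale)
    ch, cw = max(1, int(round(h * np.sqrt(scale)))), max(1, int(round(w * np.sqrt(scale))))
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    crop = img[top:top + ch, left:left + cw]
    out_shape = (h, w) + img.shape[2:]
    out = resize(crop, out_shape, anti_aliasing=True, preserve_range=True)
    # vertical flip
    if rng.random() < 0.5:
        out = out[::-1]
    # rotation about the centre
    angle = float(rng.uniform(-max_rotation, max_rotation))
    out = rotate(out, angle, mode="edge", preserve_range=True)
    return out.astype(np.float32)


def group_kfold_split(records: list[InstanceRecord], k: int = 5,
                      seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group-aware K folds: (train_idx, val_idx) pairs over ``records``.

    Every group appears in validation in exactly one fold and never
    straddles the boundary within a fold. Group order is shuffled by
    ``seed`` before assignment so repeated splits differ.
    """
    groups = np.array([r.group_id for r in records])
    unique = np.unique(groups)
    if len(unique) < k:
        raise ValueError(f"{len(unique)} groups < k={k}")
    rng = np.random.default_rng(seed)
    remap = {g: i for i, g in enumerate(rng.permutation(unique))}
    shuffled_groups = np.array([remap[g] for g in groups])
    splitter = GroupKFold(n_splits=k)
    return [(tr, va) for tr, va in
            splitter.split(np.zeros(len(records)), groups=shuffled_groups)]


def preprocess_crop(image: np.ndarray, mask: np.ndarray,
                    out_size: int = 256) -> np.ndarray:
    """Mask out background, zero-pad to square (centred), resize isotropically.

    The foreground keeps its aspect ratio ("no stretch"): padding happens on
    the shorter axis before the square is resized to ``out_size``.
    """
    img = np.asarray(image, dtype=np.float32)
    msk = np.asarray(mask)
    if msk.shape[:2] != img.shape[:2]:
        raise ValueError(
            f"mask shape {msk.shape[:2]} != image shape {img.shape[:2]}"
        )
    if img.ndim == 3 and msk.ndim == 2:
        msk = msk[..., None]
    img = img * (msk > 0)
    h, w = img.shape[:2]
    side = max(h, w)
    pad_h, pad_w = side - h, side - w
    widths = [(pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2)]
    if img.ndim == 3:
        widths.append((0, 0))
    img = np.pad(img, widths)
    out_shape = (out_size, out_size) + img.shape[2:]
    return resize(img, out_shape, anti_aliasing=True,
                  preserve_range=True).astype(np.float32)


def materialize(built: BuiltSet, pool: dict[str, InstanceRecord]):
    """Resolve a built set's members to data arrays (applying augmentation).

    Returns ``(data, target)`` where data is a list of images or an M x d
    matrix of vectors, aligned with ``built.target``.
    """
    first = pool[built.members[0].instance_id]
    if first.image is not None:
        out = []
        for mem in built.members:
            rec = pool[mem.instance_id]
            img = rec.image
            if mem.augmented:
                img = augment_instance(img, mem.aug_seed)
            out.append(img)
        return out, built.target
    vecs = []
    for mem in built.members:
        rec = pool[mem.instance_id]
        if mem.augmented:
            rng = np.random.default_rng(mem.aug_seed)
            vecs.append(rec.vector + 0.01 * rng.standard_normal(rec.vector.shape))
        else:
            vecs.append(rec.vector)
    return np.asarray(vecs, dtype=np.float32), built.target
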