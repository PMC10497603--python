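"""Model-ready samples: ROI crops, mean spectra, °Brix groups, splits.

One fruit-slice image yields one sample: a 20×20-pixel region of
interest (the CNN input) and its per-band spatial mean spectrum (the FNN
input), labeled with the slice's refractometer °Brix value.  Samples are
stratified into five °Brix groups and split 60/20/20 into train /
validation / test sets within each group.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

#: half-open °Brix group boundaries [a, b); group 5 is unbounded above
GROUP_EDGES = (10.0, 11.0, 12.0, 13.0)


@dataclass
class Sample:
    """One labeled ROI: 3-D band values plus its 1-D mean spectrum."""

    cube_3d: np.ndarray          # (roi, roi, C)
    spectrum_1d: np.ndarray      # (C,)
    brix: float
    group_id: int
    sample_id: str
    centers_nm: np.ndarray | None = None

    def __post_init__(self):
        if self.brix <= 0 or not math.isfinite(self.brix):
            raise ValueError(f"brix must be finite and positive: {self.brix}")


@dataclass
class DatasetSplit:
    """Disjoint train/valid/test id sets with their generating recipe."""

    train_ids: list
    valid_ids: list
    test_ids: list
    seed: int
    ratios: tuple[float, float, float]

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.valid_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split id sets are not pairwise disjoint")

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed, "ratios": list(self.ratios),
            "train_ids": list(self.train_ids),
            "valid_ids": list(self.valid_ids),
            "test_ids": list(self.test_ids),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DatasetSplit":
        d = json.loads(text)
        return cls(d["train_ids"], d["valid_ids"], d["test_ids"],
                   d["seed"], tuple(d["ratios"]))


def extract_roi(image: np.ndarray, roi_size: int = 20,
                valid: np.ndarray | None = None) -> np.ndarray:
    """Crop a roi_size² window centered on the valid-pixel centroid.

    ``image`` is (H, W, C); ``valid`` an optional boolean mask (2-D
    per-pixel or 3-D per-entry) marking usable pixels — the crop centers
    on their centroid so the ROI sits on the fruit, not the background.
    """
    if image.ndim != 3:
        raise ValueError("image must be 3-D (H, W, bands)")
    h, w, _ = image.shape
    if h < roi_size or w < roi_size:
        raise ValueError(
            f"image {h}x{w} smaller than ROI {roi_size}x{roi_size}"
        )
    if valid is None:
        mask2d = np.ones((h, w), dtype=bool)
    else:
        mask2d = valid.all(axis=2) if valid.ndim == 3 else valid
    if not mask2d.any():
        mask2d = np.ones((h, w), dtype=bool)
    rows, cols = np.nonzero(mask2d)
    cy, cx = rows.mean(), cols.mean()
    half = roi_size / 2.0
    top = int(round(cy - half + 0.5))
    left = int(round(cx - half + 0.5))
    top = min(max(top, 0), h - roi_size)
    left = min(max(left, 0), w - roi_size)
    return image[top:top + roi_size, left:left + roi_size, :]


def to_mean_spectrum(cube: np.ndarray,
                     valid: np.ndarray | None = None) -> np.ndarray:
    """Per-band spatial mean over unflagged pixels; shape (C,)."""
    if cube.ndim != 3:
        raise ValueError("cube must be 3-D (H, W, bands)")
    if valid is None:
        return cube.mean(axis=(0, 1))
    counts = valid.sum(axis=(0, 1))
    if np.any(counts == 0):
        bad = np.nonzero(counts == 0)[0]
        raise ValueError(f"all pixels flagged invalid in band(s) {bad.tolist()}")
    return np.where(valid, cube, 0.0).sum(axis=(0, 1)) / counts


def assign_brix_group(brix: float) -> int:
    """Map a °Brix value to its group id 1–5 (half-open intervals)."""
    if not math.isfinite(brix) or brix <= 0:
        raise ValueError(f"brix must be finite and positive: {brix}")
    for gid, edge in enumerate(GROUP_EDGES, start=1):
        if brix < edge:
            return gid
    return 5


def _split_counts(n: int, ratios: tuple[float, float, float]
                  ) -> tuple[int, int, int]:
    """train = n − valid − test with test = floor(r_test·n), valid =
    ceil(r_valid·n); reproduces the published 218→(131,44,43) and
    162→(97,33,32) splits."""
    r_train, r_valid, r_test = ratios
    n_test = math.floor(r_test * n)
    n_valid = math.ceil(r_valid * n)
    n_train = n - n_valid - n_test
    if n_train < 0:
        raise ValueError(f"ratios {ratios} infeasible for group size {n}")
    return n_train, n_valid, n_test


def split_dataset(group_ids: dict[int, list],
                  ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> DatasetSplit:
    """Stratified split: shuffle each °Brix group, cut by the rounding
    rule, concatenate across groups."""
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    train, valid, test = [], [], []
    for gid in sorted(group_ids):
        ids = list(group_ids[gid])
        if not ids:
            import warnings
            warnings.warn(f"group {gid} is empty; skipped", stacklevel=2)
            continue
        n_train, n_valid, n_test = _split_counts(len(ids), ratios)
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        train.extend(shuffled[:n_train])
        valid.extend(shuffled[n_train:n_train + n_valid])
        test.extend(shuffled[n_train + n_valid:])
    return DatasetSplit(train, valid, test, seed=seed, ratios=tuple(ratios))


def group_samples(samples: list[Sample]) -> dict[int, list[str]]:
    """Bucket sample ids by group for split_dataset."""
    groups: dict[int, list[str]] = {}
    for s in samples:
        groups.setdefault(s.group_id, []).append(s.sample_id)
    return groups
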