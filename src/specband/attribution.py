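"""Band attribution: mean integrated gradients, scores, greedy selection.

The contribution of each input band to a trained regressor is measured
with the mean of integrated gradients (MIG): gradients of the scalar
output are evaluated at M points along the straight path from a baseline
R′ (all-zero reflectance by default) to each input R, averaged over the
path and over samples.  Two modes exist:

* ``literal`` (default) — the path-and-sample-averaged gradient itself.
* ``full_ig`` — the path-averaged gradient multiplied elementwise by
  (R − R′) per sample before sample-averaging; this is the standard
  integrated-gradients estimator and satisfies the completeness
  identity Σ attributions ≈ F(R) − F(R′) as M grows.

A band's Score is the absolute value of the spatial mean of its MIG
(3-D CNN inputs) or simply |MIG| (1-D FNN inputs).  Signature bands are
chosen greedily by descending Score subject to a ±20 nm exclusion
radius around already-selected centers; a spacing of exactly 20 nm is
admissible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .bandgrid import BandGrid


@dataclass
class IGConfig:
    baseline: np.ndarray | float = 0.0
    path_steps: int = 50
    mode: str = "literal"            # literal | full_ig
    batch_rows: int = 4096           # max gradient evaluations per batch
    batch_elements: int = 2_000_000  # max input elements per batch

    def __post_init__(self):
        if self.path_steps < 1:
            raise ValueError("path_steps must be >= 1")
        if self.mode not in ("literal", "full_ig"):
            raise ValueError(f"unknown IG mode {self.mode!r}")


@dataclass
class AttributionResult:
    mig: np.ndarray                  # (C,) for FNN, (H, W, C) for CNN
    score: np.ndarray                # (C,), nonnegative
    sample_count: int
    mode: str = "literal"
    model_family: str = ""


@dataclass
class SignatureSet:
    """The selected signature-band centers with their provenance."""

    centers: np.ndarray              # nm, in selection order
    scores: np.ndarray               # Score at selection time
    exclusion_radius: float = 20.0
    model_family: str = ""
    range_label: str = ""
    half_bandwidth: float = float("nan")
    ig_mode: str = "literal"
    seed: int | None = None

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        c = self.centers
        for i in range(len(c)):
            for j in range(i + 1, len(c)):
                if abs(c[i] - c[j]) < self.exclusion_radius - 1e-9:
                    raise ValueError(
                        f"centers {c[i]:g} and {c[j]:g} nm violate the "
                        f"±{self.exclusion_radius:g} nm exclusion rule"
                    )

    def to_json(self) -> str:
        return json.dumps({
            "centers_nm": self.centers.tolist(),
            "scores": self.scores.tolist(),
            "model_family": self.model_family,
            "range": self.range_label,
            "half_bandwidth_nm": self.half_bandwidth,
            "exclusion_nm": self.exclusion_radius,
            "ig_mode": self.ig_mode,
            "seed": self.seed,
        }, indent=1)


def integrated_gradients(model, samples: np.ndarray,
                         cfg: IGConfig | None = None) -> AttributionResult:
    """Mean integrated gradients of a model over a sample batch.

    ``samples`` is (S, C) for FNN models or (S, H, W, C) for CNN models;
    the baseline broadcasts against one sample.  Gradient evaluations at
    all S·M path points are batched through the model in eval mode.
    """
    cfg = cfg or IGConfig()
    x = np.asarray(samples, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("need at least one sample")
    base = np.broadcast_to(np.asarray(cfg.baseline, dtype=float),
                           x.shape[1:])
    s, m = x.shape[0], cfg.path_steps
    delta = x - base                                 # (S, ...)
    alphas = np.arange(1, m + 1) / m                 # k/M, k = 1..M
    alphas = alphas.reshape((-1,) + (1,) * (x.ndim - 1))
    # process a few samples' worth of path points per model call to keep
    # peak memory flat regardless of S and of the per-sample input size
    row_elements = int(np.prod(x.shape[1:]))
    rows_cap = min(cfg.batch_rows, max(1, cfg.batch_elements // row_elements))
    samples_per_batch = max(1, rows_cap // m)
    avg_grad = np.empty_like(x)
    for start in range(0, s, samples_per_batch):
        block = delta[start:start + samples_per_batch]
        nb = len(block)
        points = (base + alphas[None] * block[:, None]).reshape(
            (nb * m,) + x.shape[1:])
        grads = model.input_gradient(points)
        avg_grad[start:start + nb] = grads.reshape(
            (nb, m) + x.shape[1:]).mean(axis=1)
    if cfg.mode == "full_ig":
        mig = (avg_grad * delta).mean(axis=0)
    else:
        mig = avg_grad.mean(axis=0)
    return AttributionResult(mig=mig, score=score_bands(mig),
                             sample_count=s, mode=cfg.mode)


def score_bands(mig: np.ndarray) -> np.ndarray:
    """Per-band contribution Score.

    For 3-D MIG (H × W × C) the spatial mean is taken first and its
    absolute value returned — bands whose positive and negative pixel
    attributions cancel score low by construction.  For 1-D MIG the
    Score is simply the absolute value.
    """
    mig = np.asarray(mig, dtype=float)
    if mig.ndim == 1:
        return np.abs(mig)
    if mig.ndim == 3:
        return np.abs(mig.mean(axis=(0, 1)))
    raise ValueError(f"mig must be 1-D or 3-D, got {mig.ndim}-D")


def select_signature_bands(score: np.ndarray, grid: BandGrid,
                           n_bands: int = 6,
                           exclusion_radius: float = 20.0,
                           mig: np.ndarray | None = None,
                           positive_only: bool = False,
                           **provenance) -> SignatureSet:
    """Greedy top-Score selection under the exclusion radius.

    Repeatedly picks the highest-Score band whose center is at least
    ``exclusion_radius`` nm (boundary equality allowed) from every
    selected center; score ties break toward the lower wavelength.
    With ``positive_only=True`` only bands with positive MIG are
    candidates (requires ``mig``).
    """
    score = np.asarray(score, dtype=float)
    centers = grid.centers
    if len(score) != len(centers):
        raise ValueError("score length does not match grid length")
    admissible = np.ones(len(centers), dtype=bool)
    if positive_only:
        if mig is None:
            raise ValueError("positive_only selection needs the signed MIG")
        band_mig = (np.asarray(mig).mean(axis=(0, 1))
                    if np.asarray(mig).ndim == 3 else np.asarray(mig))
        admissible &= band_mig > 0

    # stable order: descending score, ascending wavelength on ties
    order = np.lexsort((centers, -score))
    chosen: list[int] = []
    for idx in order:
        if not admissible[idx]:
            continue
        if all(abs(centers[idx] - centers[j]) >= exclusion_radius - 1e-9
               for j in chosen):
            chosen.append(idx)
            if len(chosen) == n_bands:
                break
    if len(chosen) < n_bands:
        raise ValueError(
            f"only {len(chosen)} admissible bands found; {n_bands} requested"
        )
    return SignatureSet(centers=centers[chosen], scores=score[chosen],
                        exclusion_radius=exclusion_radius, **provenance)
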