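"""Fingerprint-network training.

Training samples 224x224 patches from the *left* halves of prepared cores
and minimizes identity cross-entropy against the core index. In
``style_paired`` mode each step also draws the same patch region from a
restyled twin and adds the style-invariance term
``gamma * d2_FP(fp_1, fp_2)``. Progress is monitored as core-index accuracy
on patches from the *right* halves, which the network never trains on;
training stops when that accuracy plateaus and the best weights are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import PATCH, AugmentConfig, augment_patch
from .losses import (
    batch_cross_entropy,
    fingerprint_distance,
    fingerprint_distance_grad,
    softmax,
)
from .nn import Adam
from .nn.models import FingerprintNetwork
from .synthgen import SyntheticCohort, render_style

__all__ = [
    "TrainConfig",
    "StyleCohortData",
    "build_training_data",
    "train_fingerprint_network",
    "monitor_right_half_accuracy",
    "extract_fingerprints",
    "preprocess_batch",
]


@dataclass
class TrainConfig:
    """Optimization and early-stopping settings.

    ``mode`` is ``plain`` (identity cross-entropy only) or ``style_paired``
    (adds the fingerprint-distance term between restyled twins).
    """

    mode: str = "style_paired"
    steps: int = 400
    batch_size: int = 16
    lr: float = 1e-3
    #: optional step decay: after `lr_decay_at * steps` steps the learning
    #: rate drops to `lr * lr_decay_to` (None disables; useful because the
    #: monitored accuracy oscillates strongly late in training otherwise)
    lr_decay_at: float | None = None
    lr_decay_to: float = 1 / 3
    gamma: float = 0.5
    epsilon: float = 1e-6
    monitor_interval: int = 50
    patience: int = 10
    min_delta: float = 0.002
    monitor_patches: int = 8
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.mode not in ("plain", "style_paired"):
            raise ValueError("mode must be 'plain' or 'style_paired'")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class StyleCohortData:
    """Rendered left/right halves of every core in every style.

    ``halves[side][style_id]`` is a list of (H, W/2, 3) uint8 rasters in
    core-index order; labels are 0-based positions into that order.
    """

    core_indices: list[int]
    layout: dict[int, int]
    style_ids: list[str]
    halves: dict[str, dict[str, list[np.ndarray]]]
    #: precomputed uint8 luminance of each half, same indexing; used as a
    #: fast path when the model takes grayscale input
    halves_gray: dict[str, dict[str, list[np.ndarray]]] = field(default_factory=dict)

    @property
    def n_cores(self) -> int:
        return len(self.core_indices)


_LUMA = np.array([0.2126, 0.7152, 0.0722], dtype=np.float32)


def build_training_data(cohort: SyntheticCohort) -> StyleCohortData:
    """Render every core in every cohort style and split halves."""
    style_ids = [s.style_id for s in cohort.styles]
    halves: dict[str, dict[str, list[np.ndarray]]] = {
        "left": {s: [] for s in style_ids},
        "right": {s: [] for s in style_ids},
    }
    gray = {"left": {s: [] for s in style_ids}, "right": {s: [] for s in style_ids}}
    core_indices = []
    for core_index, _pid, morph in cohort.cores:
        core_indices.append(core_index)
        for style in cohort.styles:
            img = render_style(morph, style, seed=core_index)
            mid = img.shape[1] // 2
            for side, half in (("left", img[:, :mid]), ("right", img[:, mid:])):
                halves[side][style.style_id].append(half)
                lum = (half.astype(np.float32) @ _LUMA).round().astype(np.uint8)
                gray[side][style.style_id].append(lum)
    return StyleCohortData(core_indices, dict(cohort.layout), style_ids, halves, gray)


def preprocess_batch(patches: np.ndarray, grayscale: bool) -> np.ndarray:
    """(N,H,W,3) uint8 -> (N,3,H,W) float32 in [0,1]; eval-time preprocessing."""
    x = patches.astype(np.float32) / 255.0
    if grayscale:
        lum = x @ _LUMA
        x = np.repeat(lum[..., None], 3, axis=-1)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _crop(half: np.ndarray, r: int, c: int) -> np.ndarray:
    return half[r : r + PATCH, c : c + PATCH]


def _augment_gray(patch: np.ndarray, rng, cfg: AugmentConfig, rotation_k: int) -> np.ndarray:
    """Augment a (224,224) uint8 luminance patch; same jitter semantics as
    ``augment_patch`` but on one channel (fast path for grayscale models)."""
    x = patch.astype(np.float32) / 255.0
    x = np.rot90(x, k=rotation_k)
    if cfg.flip and rng.integers(0, 2):
        x = x[:, ::-1]
    if cfg.brightness:
        x = x * rng.uniform(1 - cfg.brightness, 1 + cfg.brightness)
    if cfg.contrast:
        x = x + rng.uniform(-cfg.contrast, cfg.contrast)
    return np.clip(x, 0.0, 1.0)


def _to_nchw(batch: np.ndarray) -> np.ndarray:
    """(B,H,W,3) -> (B,3,H,W); (B,H,W) luminance -> replicated 3 channels."""
    if batch.ndim == 3:
        return np.ascontiguousarray(
            np.broadcast_to(batch[:, None], (batch.shape[0], 3) + batch.shape[1:]))
    return np.ascontiguousarray(batch.transpose(0, 3, 1, 2))


def _sample_origins(shape, n, rng):
    rows = rng.integers(0, shape[0] - PATCH + 1, size=n)
    cols = rng.integers(0, shape[1] - PATCH + 1, size=n)
    return rows, cols


def train_fingerprint_network(data: StyleCohortData, model: FingerprintNetwork,
                              config: TrainConfig) -> pd.DataFrame:
    """Train in place; returns the log (step, ce1, ce2, d2_fp, monitor_acc).

    In ``style_paired`` mode every core must be available in at least two
    styles; twin styles are cycled across steps. Early stopping keeps the
    weights of the best monitoring round.
    """
    if config.mode == "style_paired" and len(data.style_ids) < 2:
        raise ValueError("style_paired mode needs every core in >= 2 styles")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    opt = Adam(model.parameters(), lr=config.lr)
    aug = config.augment
    base_style = data.style_ids[0]
    twin_styles = data.style_ids[1:]
    n = data.n_cores
    rows = []
    best_acc, best_state, stale = -np.inf, None, 0

    for step in range(1, config.steps + 1):
        if (config.lr_decay_at is not None
                and step == int(config.lr_decay_at * config.steps) + 1):
            opt.lr = config.lr * config.lr_decay_to
        idx = rng.integers(0, n, size=config.batch_size)
        styles1 = (rng.choice(data.style_ids, size=config.batch_size)
                   if config.mode == "plain"
                   else np.full(config.batch_size, base_style))
        twin = twin_styles[(step - 1) % len(twin_styles)] if twin_styles else base_style

        use_gray = model.grayscale_input and bool(data.halves_gray)
        pool = data.halves_gray if use_gray else data.halves
        x1, x2 = [], []
        for j, i in enumerate(idx):
            h1 = pool["left"][styles1[j]][i]
            r, c = _sample_origins(h1.shape, 1, rng)
            rot = int(rng.integers(0, 4)) if aug.rotate else 0
            if use_gray:
                x1.append(_augment_gray(_crop(h1, int(r[0]), int(c[0])), rng, aug, rot))
            else:
                x1.append(augment_patch(_crop(h1, int(r[0]), int(c[0])), rng, aug,
                                        rotation_k=rot))
            if config.mode == "style_paired":
                h2 = pool["left"][twin][i]
                crop2 = _crop(h2, int(r[0]), int(c[0]))
                if use_gray:
                    x2.append(_augment_gray(crop2, rng, aug, rot))
                else:
                    x2.append(augment_patch(crop2, rng, aug, rotation_k=rot))
        labels = idx.astype(np.int64)

        opt.zero_grad()
        if config.mode == "plain":
            xb = _to_nchw(np.stack(x1))
            logits, _, cache = model.forward(xb, train=True)
            ce1, dlog = batch_cross_entropy(logits, labels)
            model.backward(dlog, None, cache)
            ce2 = d2 = np.nan
        else:
            # both styles share one forward pass so batch-normalization
            # statistics are computed jointly; per-branch statistics would
            # absorb the style difference during training and the distance
            # term would never see it
            b = config.batch_size
            xb = _to_nchw(np.stack(x1 + x2))
            both_labels = np.concatenate([labels, labels])
            logits, fps, cache = model.forward(xb, train=True)
            _, dlog = batch_cross_entropy(logits, both_labels)
            p = softmax(logits.astype(np.float64), axis=1)
            ll = -np.log(np.clip(p[np.arange(2 * b), both_labels], 1e-300, None))
            ce1, ce2 = float(ll[:b].mean()), float(ll[b:].mean())
            fp1, fp2 = fps[:b], fps[b:]
            d2_each = np.array([
                fingerprint_distance(a, c, config.epsilon) for a, c in zip(fp1, fp2)
            ])
            d2 = float(d2_each.mean())
            g1, g2 = fingerprint_distance_grad(fp1, fp2, config.epsilon)
            scale = config.gamma / b
            dfp = (scale * np.concatenate([g1, g2], axis=0)).astype(np.float32)
            # dlog is the gradient of the mean over 2B rows; the loss sums
            # the two per-style means, so rescale by 2
            model.backward((2.0 * dlog).astype(np.float32), dfp, cache)
        opt.step()

        monitor_acc = np.nan
        if step % config.monitor_interval == 0 or step == config.steps:
            monitor_acc = monitor_right_half_accuracy(
                model, data, k=config.monitor_patches, seed=config.seed)
            if monitor_acc > best_acc + config.min_delta:
                best_acc, best_state, stale = monitor_acc, model.state_dict(), 0
            else:
                stale += 1
        rows.append({"step": step, "ce1": ce1, "ce2": ce2, "d2_fp": d2,
                     "monitor_acc": monitor_acc})
        if stale >= config.patience:
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    return pd.DataFrame(rows)


def monitor_right_half_accuracy(model: FingerprintNetwork, data: StyleCohortData,
                                k: int = 8, seed: int = 0, style_id: str | None = None,
                                batch: int = 64) -> float:
    """Core-index accuracy from K patches per unseen right half.

    Softmax outputs are averaged over the K patches of each core; a core
    counts as correct when the argmax equals its own index. By default the
    evaluated style alternates across cores, so the monitored quantity (and
    hence early stopping) rewards style-robust identity features; pass a
    ``style_id`` to monitor a single style. Deterministic for a fixed
    patch-sampling seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    patches, owners = [], []
    for i in range(data.n_cores):
        sid = style_id or data.style_ids[i % len(data.style_ids)]
        half = data.halves["right"][sid][i]
        rs, cs = _sample_origins(half.shape, k, rng)
        for r, c in zip(rs, cs):
            patches.append(_crop(half, int(r), int(c)))
            owners.append(i)
    probs = _forward_probs(model, np.stack(patches), batch)
    owners = np.asarray(owners)
    n = data.n_cores
    mean_probs = np.zeros((n, probs.shape[1]))
    for i in range(n):
        mean_probs[i] = probs[owners == i].mean(axis=0)
    return float((mean_probs.argmax(axis=1) == np.arange(n)).mean())


def _forward_probs(model, patches_u8, batch=64):
    out = []
    for s in range(0, len(patches_u8), batch):
        x = preprocess_batch(patches_u8[s : s + batch], model.grayscale_input)
        logits, _, _ = model.forward(x, train=False)
        out.append(softmax(logits, axis=1))
    return np.concatenate(out, axis=0)


def extract_fingerprints(model: FingerprintNetwork, patches,
                         sources: pd.DataFrame | None = None,
                         batch: int = 64) -> tuple[np.ndarray, pd.DataFrame]:
    """Fingerprints for a stack of patches; one row per patch.

    ``patches`` is an (N,224,224,3) uint8 array (or an empty list). Returns
    the (N,D) float32 fingerprint matrix and a source table (an empty/default
    one if none is supplied).
    """
    n = len(patches)
    if n == 0:
        empty = pd.DataFrame(columns=["patch"])
        return np.zeros((0, model.fingerprint_dim), dtype=np.float32), empty
    arr = np.asarray(patches)
    fps = []
    for s in range(0, n, batch):
        x = preprocess_batch(arr[s : s + batch], model.grayscale_input)
        _, fp, _ = model.forward(x, train=False)
        fps.append(fp)
    mat = np.concatenate(fps, axis=0).astype(np.float32)
    if sources is None:
        sources = pd.DataFrame({"patch": np.arange(n)})
    return mat, sources.reset_index(drop=True)
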