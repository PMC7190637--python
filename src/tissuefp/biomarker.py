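"""Fingerprint-based molecular marker classification (ER/PR/Her2-style).

Whole-slide-like images are tiled into non-overlapping 112 um squares
(224x224 px at 0.5 um/px), a per-patient bag of patch fingerprints is
sampled (default 120 patches), and a small head — 512x8 linear, ReLU,
8x1 linear, tanh — is trained multiple-instance style: the bag score is
the mean of per-patch tanh outputs, regressed onto the +/-1 patient label
with squared error. Early stopping maximizes patient-level AUC on a held
"overfitting" group; evaluation is 5-fold cross-validation with rotating
train/overfit/test roles, plus external-cohort application of a trained
head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .nn.models import FingerprintNetwork
from .trainfp import extract_fingerprints

__all__ = [
    "SlideRecord",
    "PatchBag",
    "MarkerHead",
    "HeadTrainConfig",
    "CVSplit",
    "tile_slide",
    "make_bags",
    "train_marker_head",
    "predict_patient",
    "evaluate",
    "rank_auc",
    "run_cross_validation",
    "make_cv_split",
]

PATCH_MICRONS = 112.0
PATCH_PX = 224


@dataclass
class SlideRecord:
    slide_id: str
    patient_id: int
    pixels: np.ndarray               # (H,W,3) uint8
    microns_per_pixel: float
    labels: dict[str, int]           # marker -> {+1,-1}; missing markers absent
    tissue_mask: np.ndarray | None = None  # (H,W) uint8 label map, optional


@dataclass
class TilePatch:
    pixels: np.ndarray               # (224,224,3) uint8
    origin: tuple[int, int]          # top-left pixel (row, col) at native scale
    tissue_class: int | None = None  # majority label under the patch, if known


@dataclass
class PatchBag:
    patient_id: int
    fingerprints: np.ndarray         # (K,D) float32
    sources: pd.DataFrame            # origin rows
    tissue_classes: np.ndarray | None = None  # (K,) int


@dataclass
class CVSplit:
    """Patient partition into n groups with rotating fold roles."""

    groups: list[np.ndarray]         # patient ids per group

    def fold(self, f: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(train_ids, overfit_ids, test_ids) for fold f; roles rotate."""
        n = len(self.groups)
        test = self.groups[f % n]
        overfit = self.groups[(f + 1) % n]
        train = np.concatenate([self.groups[(f + j) % n] for j in range(2, n)])
        return train, overfit, test


def tile_slide(slide: SlideRecord, min_foreground: float = 0.5,
               downsample: int = 8) -> list[TilePatch]:
    """Non-overlapping 112 um foreground squares, resampled to 224x224 px.

    Foreground is an Otsu threshold on HSV saturation at 8x downsample; a
    square is kept when at least ``min_foreground`` of its area is
    foreground. Returns an empty list (with a warning) for all-background
    slides.
    """
    if slide.microns_per_pixel is None or slide.microns_per_pixel <= 0:
        raise ValueError(f"slide {slide.slide_id}: microns_per_pixel missing")
    side = PATCH_MICRONS / slide.microns_per_pixel  # native px per square
    side = int(round(side))
    h, w = slide.pixels.shape[:2]

    small = slide.pixels[::downsample, ::downsample]
    sat = rgb2hsv(small)[..., 1]
    try:
        thr = threshold_otsu(sat)
    except ValueError:  # constant image
        thr = np.inf
    fg = sat > thr

    patches = []
    for r in range(0, h - side + 1, side):
        for c in range(0, w - side + 1, side):
            sub = fg[r // downsample : (r + side) // downsample,
                     c // downsample : (c + side) // downsample]
            if sub.size == 0 or sub.mean() < min_foreground:
                continue
            px = slide.pixels[r : r + side, c : c + side]
            if side != PATCH_PX:
                px = np.clip(resize(px.astype(np.float32), (PATCH_PX, PATCH_PX),
                                    order=1, anti_aliasing=side > PATCH_PX,
                                    preserve_range=True), 0, 255).round().astype(np.uint8)
            tclass = None
            if slide.tissue_mask is not None:
                sub_m = slide.tissue_mask[r : r + side, c : c + side]
                tclass = int(np.bincount(sub_m.ravel()).argmax())
            patches.append(TilePatch(px, (r, c), tclass))
    if not patches:
        warnings.warn(f"slide {slide.slide_id}: no foreground patches")
    return patches


def make_bags(slides: list[SlideRecord], model: FingerprintNetwork, k: int = 120,
              rng: np.random.Generator | None = None) -> dict[int, PatchBag]:
    """One K-patch fingerprint bag per patient.

    Patches are sampled uniformly without replacement; when fewer than K
    foreground patches exist the sample is drawn with replacement (warned).
    """
    rng = rng or np.random.default_rng()
    bags: dict[int, PatchBag] = {}
    for slide in slides:
        tiles = tile_slide(slide)
        if not tiles:
            raise ValueError(f"slide {slide.slide_id}: zero foreground patches")
        replace = len(tiles) < k
        if replace:
            warnings.warn(f"slide {slide.slide_id}: only {len(tiles)} patches; "
                          f"sampling {k} with replacement")
        idx = rng.choice(len(tiles), size=k, replace=replace)
        chosen = [tiles[i] for i in idx]
        fps, _ = extract_fingerprints(model, np.stack([t.pixels for t in chosen]))
        sources = pd.DataFrame({
            "patient_id": slide.patient_id,
            "slide_id": slide.slide_id,
            "row": [t.origin[0] for t in chosen],
            "col": [t.origin[1] for t in chosen],
        })
        classes = (np.array([t.tissue_class for t in chosen])
                   if chosen[0].tissue_class is not None else None)
        bags[slide.patient_id] = PatchBag(slide.patient_id, fps, sources, classes)
    return bags


class MarkerHead:
    """512x8 linear -> ReLU -> 8x1 linear -> tanh, scoring patches in (-1,1)."""

    def __init__(self, in_dim: int = 512, hidden: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W1 = (rng.standard_normal((in_dim, hidden)) * np.sqrt(2.0 / in_dim)).astype(np.float32)
        self.b1 = np.zeros(hidden, dtype=np.float32)
        self.W2 = (rng.standard_normal((hidden, 1)) * np.sqrt(1.0 / hidden)).astype(np.float32)
        self.b2 = np.zeros(1, dtype=np.float32)

    def forward(self, fps: np.ndarray):
        h = fps @ self.W1 + self.b1
        hr = np.maximum(h, 0.0)
        z = hr @ self.W2 + self.b2
        s = np.tanh(z)[:, 0]
        return s, (fps, h, hr, z)

    def scores(self, fps: np.ndarray) -> np.ndarray:
        return self.forward(fps.astype(np.float32))[0]

    def backward(self, ds: np.ndarray, cache):
        fps, h, hr, z = cache
        dz = (ds * (1.0 - np.tanh(z[:, 0]) ** 2))[:, None]
        gW2 = hr.T @ dz
        gb2 = dz.sum(axis=0)
        dh = (dz @ self.W2.T) * (h > 0)
        gW1 = fps.T @ dh
        gb1 = dh.sum(axis=0)
        return [gW1, gb1, gW2, gb2]

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def state_dict(self):
        return [p.copy() for p in self.params()]

    def load_state_dict(self, state):
        for p, s in zip(self.params(), state):
            p[...] = s


@dataclass
class HeadTrainConfig:
    steps: int = 2000
    bags_per_batch: int = 8
    lr: float = 1e-3
    eval_interval: int = 50
    patience: int = 10
    seed: int = 0


def predict_patient(head: MarkerHead, bag: PatchBag) -> float:
    """Patient score: mean of per-patch tanh outputs, in [-1, 1]."""
    if bag.fingerprints.shape[0] == 0:
        raise ValueError(f"patient {bag.patient_id}: empty bag")
    return float(head.scores(bag.fingerprints).mean())


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: need both classes")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(scores: dict[int, float], labels: dict[int, int],
             bags: dict[int, PatchBag] | None = None,
             head: MarkerHead | None = None,
             tissue_class: int | None = None):
    """ROC points and AUC of patient scores against +/-1 labels.

    With a tissue-class filter, each patient's score is recomputed as the
    mean head output over patches of that class only; patients with no such
    patches are excluded (their count is reported).
    """
    excluded = 0
    if tissue_class is not None:
        if bags is None or head is None:
            raise ValueError("tissue-restricted evaluation needs bags and head")
        scores = {}
        for pid, bag in bags.items():
            if pid not in labels or bag.tissue_classes is None:
                continue
            sel = bag.tissue_classes == tissue_class
            if not sel.any():
                excluded += 1
                continue
            scores[pid] = float(head.scores(bag.fingerprints[sel]).mean())
    pids = [p for p in scores if p in labels]
    y = np.array([labels[p] for p in pids])
    s = np.array([scores[p] for p in pids])
    auc = rank_auc(y, s)
    # ROC by sweeping unique thresholds (descending)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order] == 1
    tps = np.cumsum(y_sorted)
    fps_ = np.cumsum(~y_sorted)
    tpr = np.concatenate([[0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0], fps_ / max(fps_[-1], 1)])
    return {"auc": auc, "fpr": fpr, "tpr": tpr, "n": len(pids), "excluded": excluded}


def train_marker_head(bags: dict[int, PatchBag], labels: dict[int, int],
                      train_ids, overfit_ids, config: HeadTrainConfig | None = None,
                      in_dim: int | None = None) -> tuple[MarkerHead, pd.DataFrame]:
    """Train the head MIL-style on ``train_ids``; early-stop on overfit AUC.

    Loss per batch of B bags: mean over bags of (bag score - label)^2, where
    a bag score is the mean patch tanh output. Every ``eval_interval`` steps
    the overfitting group's patient-level AUC (from averaged patch
    predictions) is measured; the best-AUC weights are kept and training
    stops after ``patience`` evaluations without improvement.
    """
    config = config or HeadTrainConfig()
    train_ids = [p for p in train_ids if p in labels and p in bags]
    over_ids = [p for p in overfit_ids if p in labels and p in bags]
    over_labels = np.array([labels[p] for p in over_ids])
    if len(set(over_labels.tolist())) < 2:
        raise ValueError("overfitting group has a single class; AUC undefined")

    dim = in_dim or next(iter(bags.values())).fingerprints.shape[1]
    head = MarkerHead(in_dim=dim, seed=config.seed)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    ms = [np.zeros_like(p) for p in head.params()]
    vs = [np.zeros_like(p) for p in head.params()]
    t_adam = 0
    rows = []
    best_auc, best_state, stale = -np.inf, None, 0

    for step in range(1, config.steps + 1):
        batch = rng.choice(train_ids, size=min(config.bags_per_batch, len(train_ids)),
                           replace=False)
        grads = [np.zeros_like(p) for p in head.params()]
        loss = 0.0
        for pid in batch:
            fps = bags[pid].fingerprints.astype(np.float32)
            s, cache = head.forward(fps)
            bag_score = s.mean()
            err = bag_score - labels[pid]
            loss += err * err
            ds = np.full(s.shape, 2.0 * err / (s.size * len(batch)), dtype=np.float64)
            for g, gn in zip(grads, head.backward(ds, cache)):
                g += gn
        loss /= len(batch)

        t_adam += 1
        for p, g, m_, v_ in zip(head.params(), grads, ms, vs):
            m_ += 0.1 * (g - m_)
            v_ += 0.001 * (g * g - v_)
            mhat = m_ / (1 - 0.9 ** t_adam)
            vhat = v_ / (1 - 0.999 ** t_adam)
            p -= config.lr * mhat / (np.sqrt(vhat) + 1e-8)

        auc = np.nan
        if step % config.eval_interval == 0 or step == config.steps:
            over_scores = np.array([predict_patient(head, bags[p]) for p in over_ids])
            auc = rank_auc(over_labels, over_scores)
            if auc > best_auc:
                best_auc, best_state, stale = auc, head.state_dict(), 0
            else:
                stale += 1
        rows.append({"step": step, "mse": loss, "overfit_auc": auc})
        if stale >= config.patience:
            break

    if best_state is not None:
        head.load_state_dict(best_state)
    return head, pd.DataFrame(rows)


def make_cv_split(labels: dict[int, int], n_folds: int = 5,
                  seed: int = 0) -> CVSplit:
    """Label-stratified patient partition into n_folds groups."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    pids = np.array(sorted(labels))
    groups: list[list[int]] = [[] for _ in range(n_folds)]
    offset = 0
    for cls in (1, -1):
        members = pids[np.array([labels[p] for p in pids]) == cls]
        members = members[rng.permutation(len(members))]
        for j, p in enumerate(members):
            groups[(j + offset) % n_folds].append(int(p))
        offset += len(members)
    return CVSplit([np.array(g) for g in groups])


def run_cross_validation(bags: dict[int, PatchBag], labels: dict[int, int],
                         n_folds: int = 5, seed: int = 0,
                         config: HeadTrainConfig | None = None) -> dict:
    """Rotating-role n-fold CV; returns per-fold test AUCs and their mean."""
    labels = {p: y for p, y in labels.items() if y in (-1, 1) and p in bags}
    if len(labels) < 10:
        raise ValueError("need >= 10 labeled patients for cross-validation")
    split = make_cv_split(labels, n_folds, seed)
    fold_aucs, heads = [], []
    for f in range(n_folds):
        train_ids, over_ids, test_ids = split.fold(f)
        try:
            cfg = config or HeadTrainConfig()
            head, _log = train_marker_head(bags, labels, train_ids, over_ids,
                                           HeadTrainConfig(**{**cfg.__dict__,
                                                              "seed": cfg.seed + f}))
            test_scores = {p: predict_patient(head, bags[p]) for p in test_ids
                           if p in labels}
            res = evaluate(test_scores, labels)
        except ValueError as e:
            warnings.warn(f"fold {f} skipped: {e}")
            continue
        fold_aucs.append(res["auc"])
        heads.append(head)
    return {"fold_aucs": fold_aucs, "mean_auc": float(np.mean(fold_aucs)),
            "heads": heads, "split": split}
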