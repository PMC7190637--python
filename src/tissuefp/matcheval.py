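"""The tissue half-matching game.

Left halves of cores (one staining style) are matched to right halves
(another style) by nearest neighbor in fingerprint space. Accuracy is
scored per core (matched to its own index) and, when patients contribute
multiple cores, per patient after pooling each patient's half fingerprints
into a single centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .imaging import PATCH
from .nn.models import FingerprintNetwork
from .trainfp import StyleCohortData, extract_fingerprints

__all__ = [
    "HalfFingerprint",
    "MatchResult",
    "half_fingerprint",
    "match_nearest",
    "score_matching",
    "chance_accuracy",
    "cohort_half_fingerprints",
    "mean_interstyle_distance",
]

STRIDE = 112  # 50% patch overlap when tiling a half


@dataclass
class HalfFingerprint:
    core_index: int
    patient_id: int
    side: str
    style_id: str
    fp: np.ndarray  # unit-norm aggregate over patch fingerprints


@dataclass
class MatchResult:
    assignment: dict[int, int]  # left core_index -> matched right core_index
    core_accuracy: float
    patient_accuracy: float | None
    n_cores: int
    n_patients: int | None


def tile_origins(shape, patch: int = PATCH, stride: int = STRIDE):
    """0-based (row, col) origins of a stride-tiled grid fully inside shape."""
    rows = range(0, shape[0] - patch + 1, stride)
    cols = range(0, shape[1] - patch + 1, stride)
    return [(r, c) for r in rows for c in cols]


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def half_fingerprint(model: FingerprintNetwork, half: np.ndarray, core_index: int,
                     patient_id: int, side: str, style_id: str,
                     stride: int = STRIDE) -> HalfFingerprint:
    """Aggregate fingerprint of a core half.

    The half is tiled with 224x224 patches at the given stride; each patch
    fingerprint is L2-normalized, the mean is taken, and the mean is
    re-normalized, giving a unit vector.
    """
    origins = tile_origins(half.shape[:2], stride=stride)
    if not origins:
        raise ValueError(f"half of shape {half.shape[:2]} smaller than one patch")
    patches = np.stack([half[r : r + PATCH, c : c + PATCH] for r, c in origins])
    fps, _ = extract_fingerprints(model, patches)
    norms = np.linalg.norm(fps, axis=1, keepdims=True)
    unit = fps / np.clip(norms, 1e-12, None)
    return HalfFingerprint(core_index, patient_id, side, style_id,
                           _normalize(unit.mean(axis=0)))


def match_nearest(left: list[HalfFingerprint], right: list[HalfFingerprint],
                  bijective: bool = False) -> dict[int, int]:
    """Nearest right fingerprint for each left fingerprint (Euclidean).

    Each left item is matched independently (several left cores may map to
    one right core); ties break to the lowest right core_index. With
    ``bijective=True`` a Hungarian one-to-one assignment is used instead.
    """
    if not left or not right:
        raise ValueError("both fingerprint lists must be non-empty")
    lmat = np.stack([h.fp for h in left])
    rmat = np.stack([h.fp for h in right])
    if lmat.shape[1] != rmat.shape[1]:
        raise ValueError("fingerprint dimensionality mismatch")
    order = np.argsort([h.core_index for h in right], kind="stable")
    rmat = rmat[order]
    right_sorted = [right[i] for i in order]
    dist = cdist(lmat, rmat)
    if bijective:
        li, ri = linear_sum_assignment(dist)
        return {left[i].core_index: right_sorted[j].core_index for i, j in zip(li, ri)}
    picks = dist.argmin(axis=1)  # argmin takes the first minimum: lowest index
    return {h.core_index: right_sorted[j].core_index for h, j in zip(left, picks)}


def score_matching(left: list[HalfFingerprint], right: list[HalfFingerprint],
                   layout: dict[int, int], assignment: dict[int, int] | None = None,
                   bijective: bool = False) -> MatchResult:
    """Core-level and patient-pooled matching accuracies.

    Core accuracy is the fraction of left cores matched to their own index.
    Patient accuracy pools each patient's left half fingerprints into one
    normalized centroid (likewise right), matches nearest-neighbor at the
    patient level, and scores over patients; it is reported only when some
    patient has multiple cores.
    """
    for h in left + right:
        if h.core_index not in layout:
            raise KeyError(f"core_index {h.core_index} missing from layout")
    if assignment is None:
        assignment = match_nearest(left, right, bijective=bijective)
    correct = sum(1 for li, ri in assignment.items() if li == ri)
    core_acc = correct / len(assignment)

    patients = sorted({layout[h.core_index] for h in left})
    patient_acc = None
    if len(patients) < len(left):
        def pooled(items):
            out = {}
            for pid in patients:
                fps = [h.fp for h in items if layout[h.core_index] == pid]
                out[pid] = _normalize(np.mean(fps, axis=0))
            return out

        lp, rp = pooled(left), pooled(right)
        lmat = np.stack([lp[p] for p in patients])
        rmat = np.stack([rp[p] for p in patients])
        picks = cdist(lmat, rmat).argmin(axis=1)
        patient_acc = float(np.mean([patients[j] == p for p, j in zip(patients, picks)]))
    return MatchResult(assignment, core_acc, patient_acc, len(assignment),
                       len(patients) if patient_acc is not None else None)


def chance_accuracy(n_cores: int) -> float:
    """Null matching accuracy: 1/n (0.48% for a 208-core array)."""
    if n_cores < 1:
        raise ValueError("n_cores must be >= 1")
    return 1.0 / n_cores


def cohort_half_fingerprints(model: FingerprintNetwork, data: StyleCohortData,
                             side: str, style_id: str,
                             stride: int = STRIDE) -> list[HalfFingerprint]:
    """Half fingerprints for every core of a rendered cohort."""
    out = []
    for i, core_index in enumerate(data.core_indices):
        half = data.halves[side][style_id][i]
        out.append(half_fingerprint(model, half, core_index,
                                    data.layout[core_index], side, style_id, stride))
    return out


def mean_interstyle_distance(model: FingerprintNetwork, data: StyleCohortData,
                             side: str = "right", stride: int = STRIDE) -> float:
    """Mean squared unit-fingerprint distance between the first two styles.

    Measures style invariance: how far apart the same core half lands in
    fingerprint space when rendered in two different site styles.
    """
    a, b = data.style_ids[:2]
    fa = cohort_half_fingerprints(model, data, side, a, stride)
    fb = cohort_half_fingerprints(model, data, side, b, stride)
    d = [float(np.sum((x.fp - y.fp) ** 2)) for x, y in zip(fa, fb)]
    return float(np.mean(d))
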