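"""Heatmaps and low-dimensional embeddings of fingerprints.

Three heatmap kinds share one tiling geometry (grid dimension
``floor((L - 224)/stride) + 1`` per axis):

* identity — per-patch probability mass on the correct *patient* after
  summing core softmax probabilities over each patient's cores
  (e.g. 207 cores -> 104 patients); shaded blue (0) to red (1);
* similarity — 1 - d/2 between each query-patch unit fingerprint and the
  reference half's aggregate fingerprint, in [0, 1];
* marker — per-patch tanh scores in [-1, 1], rendered black (-1) to
  white (+1) with background mid-gray and masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.manifold import TSNE

from .biomarker import MarkerHead, SlideRecord, tile_slide
from .imaging import PATCH, CoreImage
from .losses import softmax
from .matcheval import half_fingerprint
from .nn.models import FingerprintNetwork
from .trainfp import extract_fingerprints, preprocess_batch

__all__ = [
    "HeatMap",
    "identity_heatmap",
    "aggregate_identity_probs",
    "similarity_heatmap",
    "marker_heatmap",
    "embed_and_cluster",
    "IDENTITY_STRIDE",
]

#: "80% linear overlap" between neighbouring 224-px patches -> stride
#: round(0.2 * 224) = 45 px.
IDENTITY_STRIDE = 45

KINDS = {"identity_prob": (0.0, 1.0), "similarity": (0.0, 1.0), "marker_score": (-1.0, 1.0)}


@dataclass
class HeatMap:
    values: np.ndarray          # (rows, cols) float grid
    kind: str                   # identity_prob | similarity | marker_score
    patch_size: int
    stride: int
    provenance: dict

    def __post_init__(self):
        lo, hi = KINDS[self.kind]
        v = self.values[np.isfinite(self.values)]
        if v.size and (v.min() < lo - 1e-9 or v.max() > hi + 1e-9):
            raise ValueError(f"{self.kind} values outside [{lo}, {hi}]")


def _grid_origins(shape, stride):
    rows = range(0, shape[0] - PATCH + 1, stride)
    cols = range(0, shape[1] - PATCH + 1, stride)
    return list(rows), list(cols)


def aggregate_identity_probs(core_probs: np.ndarray, layout: dict[int, int]) -> np.ndarray:
    """Sum per-core probabilities over each patient's cores.

    ``core_probs[..., i]`` is the probability of core index i+1; the result
    has one column per patient (sorted patient id order) and conserves
    probability mass row-wise.
    """
    core_probs = np.asarray(core_probs)
    n_cores = core_probs.shape[-1]
    if set(layout) != set(range(1, n_cores + 1)):
        raise ValueError(f"layout must cover core indices 1..{n_cores}")
    patients = sorted(set(layout.values()))
    out = np.zeros(core_probs.shape[:-1] + (len(patients),))
    for j, pid in enumerate(patients):
        cols = [i - 1 for i, p in layout.items() if p == pid]
        out[..., j] = core_probs[..., cols].sum(axis=-1)
    return out


def identity_heatmap(model: FingerprintNetwork, core: CoreImage,
                     layout: dict[int, int], stride: int = IDENTITY_STRIDE,
                     batch: int = 64) -> HeatMap:
    """Probability of the correct patient per overlapping patch."""
    if model.n_identities != len(layout):
        raise ValueError(f"model predicts {model.n_identities} identities, "
                         f"layout has {len(layout)} cores")
    patients = sorted(set(layout.values()))
    target_col = patients.index(layout[core.core_index])
    rows, cols = _grid_origins(core.pixels.shape[:2], stride)
    patches = np.stack([core.pixels[r : r + PATCH, c : c + PATCH]
                        for r in rows for c in cols])
    probs = []
    for s in range(0, len(patches), batch):
        x = preprocess_batch(patches[s : s + batch], model.grayscale_input)
        logits, _, _ = model.forward(x, train=False)
        probs.append(softmax(logits, axis=1))
    core_probs = np.concatenate(probs, axis=0)
    patient_probs = aggregate_identity_probs(core_probs, layout)
    grid = patient_probs[:, target_col].reshape(len(rows), len(cols))
    return HeatMap(grid, "identity_prob", PATCH, stride,
                   {"core_index": core.core_index, "profile": model.profile})


def similarity_heatmap(model: FingerprintNetwork, query_half: np.ndarray,
                       reference_half: np.ndarray, stride: int = IDENTITY_STRIDE) -> HeatMap:
    """1 - d/2 from each query patch to the reference half's mean fingerprint.

    Both fingerprints are unit-normalized, so the Euclidean distance d lies
    in [0, 2] and the similarity in [0, 1]; 1 means identical direction,
    0 antipodal.
    """
    ref = half_fingerprint(model, reference_half, 0, 0, "right", "")
    rows, cols = _grid_origins(query_half.shape[:2], stride)
    if not rows or not cols:
        raise ValueError("query half smaller than one patch")
    patches = np.stack([query_half[r : r + PATCH, c : c + PATCH]
                        for r in rows for c in cols])
    fps, _ = extract_fingerprints(model, patches)
    unit = fps / np.clip(np.linalg.norm(fps, axis=1, keepdims=True), 1e-12, None)
    d = np.linalg.norm(unit - ref.fp[None, :], axis=1)
    sim = np.clip(1.0 - d / 2.0, 0.0, 1.0)
    return HeatMap(sim.reshape(len(rows), len(cols)), "similarity", PATCH, stride, {})


def marker_heatmap(head: MarkerHead, model: FingerprintNetwork,
                   slide: SlideRecord) -> tuple[HeatMap, np.ndarray, np.ndarray]:
    """Per-patch marker scores over every non-overlapping foreground patch.

    Returns the heatmap, an 8-bit grayscale raster (score -1 -> 0 black,
    +1 -> 255 white, linear) with background at mid-gray, and a boolean
    foreground mask for the grid.
    """
    tiles = tile_slide(slide)
    side = int(round(112.0 / slide.microns_per_pixel))
    h, w = slide.pixels.shape[:2]
    nrows, ncols = h // side, w // side
    grid = np.full((nrows, ncols), np.nan)
    if tiles:
        fps, _ = extract_fingerprints(model, np.stack([t.pixels for t in tiles]))
        scores = head.scores(fps)
        for t, s in zip(tiles, scores):
            grid[t.origin[0] // side, t.origin[1] // side] = s
    fg = np.isfinite(grid)
    raster = np.full(grid.shape, 127, dtype=np.uint8)
    raster[fg] = np.clip((grid[fg] + 1.0) * 127.5, 0, 255).round().astype(np.uint8)
    heat = HeatMap(np.where(fg, grid, 0.0), "marker_score", PATCH, side,
                   {"slide_id": slide.slide_id})
    heat.values = np.where(fg, heat.values, np.nan)
    return heat, raster, fg


def _blue_green_red(scores: np.ndarray) -> np.ndarray:
    """Map [-1,1] scores onto a blue (-1) -> green (0) -> red (+1) ramp."""
    s = np.clip(np.asarray(scores, dtype=np.float64), -1, 1)
    t = (s + 1) / 2
    rgb = np.zeros(s.shape + (3,))
    lower = t <= 0.5
    rgb[..., 2] = np.where(lower, 1 - 2 * t, 0)          # blue fades out
    rgb[..., 1] = np.where(lower, 2 * t, 2 * (1 - t))    # green peaks at 0
    rgb[..., 0] = np.where(lower, 0, 2 * t - 1)          # red fades in
    return rgb


def embed_and_cluster(fingerprints: np.ndarray, scores: np.ndarray, seed: int = 0,
                      centers: np.ndarray | None = None, k_patches: int = 5,
                      perplexity: float = 30.0, sources=None) -> dict:
    """Seeded tSNE of a fingerprint matrix plus cluster patch retrieval.

    Returns 2-D coordinates, a blue-green-red shade per point from its
    score, and — for user-supplied center coordinates — the ``k_patches``
    nearest points (Euclidean in embedding space) with their provenance.
    """
    fingerprints = np.asarray(fingerprints, dtype=np.float64)
    if fingerprints.shape[0] < 10:
        raise ValueError("need >= 10 fingerprints to embed")
    if fingerprints.shape[0] <= perplexity:
        raise ValueError(f"perplexity {perplexity} too large for "
                         f"{fingerprints.shape[0]} rows; lower it below n")
    # exact gradients below a size cutoff: the Barnes-Hut approximation can
    # scatter exact-duplicate rows, breaking the locality contract
    method = "exact" if fingerprints.shape[0] <= 2000 else "barnes_hut"
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
              init="pca", method=method)
    coords = ts.fit_transform(fingerprints)
    shades = _blue_green_red(np.asarray(scores))
    retrieval = []
    if centers is not None:
        d = cdist(np.atleast_2d(centers), coords)
        for row in d:
            nearest = np.argsort(row, kind="stable")[:k_patches]
            items = nearest.tolist()
            if sources is not None:
                items = [sources[i] for i in nearest]
            retrieval.append(items)
    return {"coords": coords, "shades": shades, "retrieval": retrieval}
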