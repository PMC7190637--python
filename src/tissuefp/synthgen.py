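"""Synthetic H&E-like cohort generator.

Emulates the statistical structure the fingerprinting method assumes, at a
nominal 0.5 um/px scale:

* each patient has a morphological phenotype (gland fraction, nuclear
  density/radius, stroma wavelength/anisotropy) shared by all of their
  tissue cores, which otherwise have independent pixels;
* the same morphology can be rendered in multiple "site styles" (stain
  colors, gamma, brightness) that change color statistics only;
* a binary molecular marker label is statistically coupled to the gland
  fraction, so marker status is recoverable from morphology but not
  deterministic;
* whole-slide-like mosaics carry background/epithelium/stroma/fat label
  maps, with the marker-informative texture confined to epithelium.

All randomness flows from ``numpy.random.SeedSequence`` spawns of a single
seed, so identical arguments yield bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize

__all__ = [
    "PatientPhenotype",
    "StyleParams",
    "SyntheticCohort",
    "WsiCohort",
    "CohortConfig",
    "BUILTIN_STYLES",
    "make_cohort",
    "make_wsi_cohort",
    "render_style",
    "render_morphology",
]

# Label codes for whole-slide tissue maps.
LABEL_BACKGROUND, LABEL_EPITHELIUM, LABEL_STROMA, LABEL_FAT = 0, 1, 2, 3


@dataclass(frozen=True)
class PatientPhenotype:
    """Patient-level texture parameters and marker label.

    gland_fraction  g in [0.05, 0.95] — area fraction of glandular structure
    nuclear_density d in [0.3, 0.9]   — nuclei per 100 px^2-scale unit
    nucleus_radius  r in [3, 7] px
    stroma_wavelength w in [8, 32] px — dominant collagen band spacing
    anisotropy      a in [0, 1]       — orientation concentration of stroma
    marker_label    m in {+1, -1}     — coupled to g through a sigmoid
    """

    patient_id: int
    gland_fraction: float
    nuclear_density: float
    nucleus_radius: float
    stroma_wavelength: float
    anisotropy: float
    marker_label: int

    def __post_init__(self):
        if self.patient_id < 1:
            raise ValueError("patient_id must be >= 1")
        checks = [
            (self.gland_fraction, 0.05, 0.95, "gland_fraction"),
            (self.nuclear_density, 0.3, 0.9, "nuclear_density"),
            (self.nucleus_radius, 3.0, 7.0, "nucleus_radius"),
            (self.stroma_wavelength, 8.0, 32.0, "stroma_wavelength"),
            (self.anisotropy, 0.0, 1.0, "anisotropy"),
        ]
        for v, lo, hi, name in checks:
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.marker_label not in (-1, 1):
            raise ValueError("marker_label must be +1 or -1")


@dataclass(frozen=True)
class StyleParams:
    """A parametric site style: stain colors plus global photometric knobs."""

    style_id: str
    hematoxylin_rgb: tuple[int, int, int]
    eosin_rgb: tuple[int, int, int]
    background_rgb: tuple[int, int, int]
    gamma: float = 1.0
    hue_jitter_deg: float = 0.0
    brightness: float = 0.0

    def __post_init__(self):
        for name in ("hematoxylin_rgb", "eosin_rgb", "background_rgb"):
            col = getattr(self, name)
            if len(col) != 3 or any(not 0 <= c <= 255 for c in col):
                raise ValueError(f"{name} must be an RGB triplet in 0..255")
        if not 0.5 <= self.gamma <= 2.0:
            raise ValueError("gamma must lie in [0.5, 2.0]")


#: Two built-in site styles; same morphology rendered with each differs in
#: color statistics only (different stain hues, gamma and brightness).
BUILTIN_STYLES: dict[str, StyleParams] = {
    "siteA": StyleParams("siteA", hematoxylin_rgb=(85, 55, 150), eosin_rgb=(235, 130, 175),
                         background_rgb=(246, 243, 246), gamma=0.85, brightness=0.04),
    "siteB": StyleParams("siteB", hematoxylin_rgb=(50, 45, 115), eosin_rgb=(205, 95, 135),
                         background_rgb=(252, 250, 247), gamma=1.40, brightness=-0.05),
}


@dataclass
class CohortConfig:
    """Generator condition knobs (defaults are the study conditions)."""

    marker_coupling_k: float = 24.0   # steepness of P(m=+1 | g)
    label_noise: float = 0.01         # independent label-flip probability
    microns_per_pixel: float = 0.5
    gland_scale_px: float = 36.0      # gland blob correlation length
    epithelium_band: tuple[float, float] = (0.2, 0.6)  # slide-level epi fraction


@dataclass
class SyntheticCohort:
    phenotypes: list[PatientPhenotype]
    #: (core_index, patient_id, morphology) with morphology an (2,H,W) float32
    #: array of [nuclear, cytoplasm] channels in [0,1].
    cores: list[tuple[int, int, np.ndarray]]
    styles: list[StyleParams]
    layout: dict[int, int]  # core_index -> patient_id
    seed: int
    config: CohortConfig = field(default_factory=CohortConfig)

    @property
    def n_cores(self) -> int:
        return len(self.cores)

    def morphology(self, core_index: int) -> np.ndarray:
        for idx, _, morph in self.cores:
            if idx == core_index:
                return morph
        raise KeyError(f"unknown core_index {core_index}")


@dataclass
class WsiCohort:
    phenotypes: list[PatientPhenotype]
    slides: list[np.ndarray]       # (H,W,3) uint8 per patient
    masks: list[np.ndarray]        # (H,W) uint8 tissue-type label maps
    labels: pd.DataFrame           # patient_id, ER, PR, Her2 in {1,-1}
    microns_per_pixel: float
    seed: int


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_phenotype(patient_id: int, rng: np.random.Generator,
                    config: CohortConfig) -> PatientPhenotype:
    g = rng.uniform(0.05, 0.95)
    d = rng.uniform(0.3, 0.9)
    r = rng.uniform(3.0, 7.0)
    w = rng.uniform(8.0, 32.0)
    a = rng.uniform(0.0, 1.0)
    u = rng.uniform(0.0, 1.0)
    m = 1 if _sigmoid(config.marker_coupling_k * (g - 0.5)) > u else -1
    if rng.uniform(0.0, 1.0) < config.label_noise:
        m = -m
    return PatientPhenotype(patient_id, g, d, r, w, a, m)


def _smooth_noise(shape, sigma, rng) -> np.ndarray:
    """Unit-variance Gaussian-correlated noise; large scales are synthesized
    on a coarse grid and bilinearly upsampled for speed."""
    ds = max(1, int(sigma // 4))
    coarse = (max(8, shape[0] // ds), max(8, shape[1] // ds))
    f = gaussian_filter(rng.standard_normal(coarse).astype(np.float32),
                        sigma / ds, mode="wrap")
    if coarse != tuple(shape):
        f = resize(f, shape, order=1, anti_aliasing=False)
    f -= f.mean()
    s = f.std()
    return f / s if s > 0 else f


def _threshold_at_fraction(field_: np.ndarray, frac: float,
                           within: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask covering ~frac of `within` (or of all pixels)."""
    if within is None:
        thr = np.quantile(field_, 1.0 - frac)
        return field_ > thr
    vals = field_[within]
    if vals.size == 0 or frac <= 0:
        return np.zeros_like(field_, dtype=bool)
    thr = np.quantile(vals, max(0.0, 1.0 - frac))
    return (field_ > thr) & within


def _stamp_nuclei(nuclear: np.ndarray, centers: np.ndarray, radii: np.ndarray,
                  elong: np.ndarray, theta: np.ndarray) -> None:
    """Draw soft elliptical nuclei into the nuclear channel (in place)."""
    h, w = nuclear.shape
    for (cy, cx), r, e, th in zip(centers, radii, elong, theta):
        rr = int(np.ceil(r * max(1.0, e))) + 1
        y0, y1 = max(0, int(cy) - rr), min(h, int(cy) + rr + 1)
        x0, x1 = max(0, int(cx) - rr), min(w, int(cx) + rr + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        ct, st = np.cos(th), np.sin(th)
        u = (ct * dx + st * dy) / (r * e)
        v = (-st * dx + ct * dy) / r
        dist = np.sqrt(u * u + v * v)
        blob = np.clip(1.2 - dist, 0.0, 1.0)
        np.maximum(nuclear[y0:y1, x0:x1], np.minimum(blob, 1.0), out=nuclear[y0:y1, x0:x1])


def _stroma_texture(shape, wavelength: float, anisotropy: float,
                    orientation: float, rng) -> np.ndarray:
    """Oriented band-pass noise in [0,1] with dominant spatial wavelength."""
    h, w = shape
    noise = rng.standard_normal(shape).astype(np.float32)
    fy = np.fft.fftfreq(h).astype(np.float32)[:, None]
    fx = np.fft.rfftfreq(w).astype(np.float32)[None, :]
    rho = np.sqrt(fx * fx + fy * fy)
    theta = np.arctan2(fy, fx)
    f0 = 1.0 / wavelength
    radial = np.exp(-((rho - f0) ** 2) / (2 * (0.4 * f0) ** 2))
    # orientation selectivity grows with anisotropy; cos(2*) gives pi-periodicity
    kappa = 8.0 * anisotropy
    angular = np.exp(kappa * (np.cos(2 * (theta - orientation)) - 1.0))
    tex = sfft.irfft2(sfft.rfft2(noise) * radial * angular, s=shape)
    tex -= tex.mean()
    s = tex.std()
    if s > 0:
        tex /= 3.0 * s
    return np.clip(tex + 0.5, 0.0, 1.0)


def render_morphology(phenotype: PatientPhenotype, size: int,
                      rng: np.random.Generator,
                      config: CohortConfig | None = None) -> np.ndarray:
    """Render one core's morphology as (2,H,W) [nuclear, cytoplasm] channels.

    Gland blobs occupy ~gland_fraction of the area; nuclei are soft ellipses
    placed preferentially in glands at the phenotype's density and radius;
    non-gland area carries the oriented stroma texture.
    """
    config = config or CohortConfig()
    g = phenotype.gland_fraction
    gland_field = _smooth_noise((size, size), config.gland_scale_px / 2.0, rng)
    gland = _threshold_at_fraction(gland_field, g)
    # glandular lumina: the bright central third of each gland blob, ringed
    # by epithelial nuclei — the structural signature of gland-rich tissue
    lumen = _threshold_at_fraction(gland_field, g * 0.35)

    # nuclei: density d per 100 px^2-scale unit -> d/100 * area * 0.5 total,
    # two thirds of them inside glands (epithelial), one third in stroma
    n_total = int(phenotype.nuclear_density / 100.0 * size * size * 0.5)
    centers = rng.uniform(0, size, size=(max(n_total * 3, 1), 2))
    ci = np.minimum(centers[:, 0].astype(int), size - 1)
    cj = np.minimum(centers[:, 1].astype(int), size - 1)
    in_gland = gland[ci, cj]
    in_lumen = lumen[ci, cj]
    keep = np.where(in_gland & ~in_lumen,
                    rng.uniform(size=centers.shape[0]) < 0.8,
                    rng.uniform(size=centers.shape[0]) < 0.8 * (1 - g) / max(g, 0.05) * 0.5)
    keep &= ~in_lumen  # lumina are clear
    centers = centers[keep][:n_total]
    radii = np.clip(rng.normal(phenotype.nucleus_radius, 0.15 * phenotype.nucleus_radius,
                               centers.shape[0]), 1.5, 10.0)
    elong = rng.uniform(1.0, 1.0 + 0.8 * phenotype.anisotropy, centers.shape[0])
    theta = rng.uniform(0, np.pi, centers.shape[0])
    nuclear = np.zeros((size, size), dtype=np.float64)
    _stamp_nuclei(nuclear, centers, radii, elong, theta)

    stroma = _stroma_texture((size, size), phenotype.stroma_wavelength,
                             phenotype.anisotropy, rng.uniform(0, np.pi), rng)
    gland_soft = gaussian_filter(gland.astype(np.float64), 1.5)
    lumen_soft = gaussian_filter(lumen.astype(np.float64), 1.5)
    cyto = gland_soft * 0.65 + (1.0 - gland_soft) * (0.25 + 0.5 * stroma)
    cyto = cyto * (1.0 - 0.92 * lumen_soft)  # lumina are nearly clear
    cyto = np.clip(cyto * (1.0 - 0.7 * nuclear), 0.0, 1.0)  # nuclei displace cytoplasm
    return np.stack([nuclear, cyto]).astype(np.float32)


def render_style(morphology: np.ndarray, style: StyleParams, seed: int = 0) -> np.ndarray:
    """Composite (nuclear, cytoplasm) channels into an RGB image of one style.

    Uses a multiplicative stain model: each channel attenuates the background
    toward its stain color, then style gamma / brightness / hue jitter are
    applied. Morphology (channel supports and edges) is unchanged between
    styles; only color statistics differ.
    """
    morphology = np.asarray(morphology, dtype=np.float64)
    if morphology.ndim != 3 or morphology.shape[0] != 2:
        raise ValueError("morphology must be (2,H,W) [nuclear, cytoplasm]")
    nuclear, cyto = morphology
    if nuclear.shape != cyto.shape:
        raise ValueError("nuclear and cytoplasm channels must share a shape")
    if morphology.min() < 0 or morphology.max() > 1:
        raise ValueError("morphology channels must lie in [0,1]")

    bg = np.array(style.background_rgb, dtype=np.float32) / 255.0
    h_col = np.clip(np.array(style.hematoxylin_rgb, dtype=np.float32) / 255.0, 1e-3, 1.0)
    e_col = np.clip(np.array(style.eosin_rgb, dtype=np.float32) / 255.0, 1e-3, 1.0)
    # per-channel transmission: bg * H^n * E^c (Beer-Lambert-like composite),
    # evaluated as a single exp of stacked optical densities
    nuc32 = nuclear.astype(np.float32)[..., None]
    cyt32 = cyto.astype(np.float32)[..., None]
    log_rgb = np.log(bg) + nuc32 * np.log(h_col) + cyt32 * np.log(e_col)
    # gamma folds into the exponent: (bg * H^n * E^c) ^ gamma, all terms <= 1
    rgb = np.exp(np.float32(style.gamma) * log_rgb)
    rgb = np.clip(rgb + style.brightness, 0.0, 1.0)
    if style.hue_jitter_deg:
        rng = np.random.default_rng(seed)
        shift = rng.uniform(-style.hue_jitter_deg, style.hue_jitter_deg) / 360.0
        hsv = rgb2hsv(rgb)
        hsv[..., 0] = (hsv[..., 0] + shift) % 1.0
        rgb = hsv2rgb(hsv)
    return (np.clip(rgb, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def make_cohort(n_patients: int, cores_per_patient: int = 2, core_px: int = 1600,
                seed: int = 0, config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a multi-core cohort with per-patient shared texture statistics.

    Core indices are contiguous 1..N in patient order; cores of one patient
    share the phenotype (hence texture statistics) but use independent RNG
    substreams, so their pixels differ.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    if cores_per_patient < 1:
        raise ValueError("cores_per_patient must be >= 1")
    if core_px < 256:
        raise ValueError("core_px must be >= 256")
    config = config or CohortConfig()

    root = np.random.SeedSequence(seed)
    patient_seeds = root.spawn(n_patients)
    phenotypes: list[PatientPhenotype] = []
    cores: list[tuple[int, int, np.ndarray]] = []
    layout: dict[int, int] = {}
    core_index = 1
    for pid, pseq in enumerate(patient_seeds, start=1):
        streams = pseq.spawn(cores_per_patient + 1)
        phen = _draw_phenotype(pid, np.random.default_rng(streams[0]), config)
        phenotypes.append(phen)
        for c in range(cores_per_patient):
            morph = render_morphology(phen, core_px, np.random.default_rng(streams[c + 1]), config)
            cores.append((core_index, pid, morph))
            layout[core_index] = pid
            core_index += 1
    return SyntheticCohort(phenotypes, cores, list(BUILTIN_STYLES.values()), layout,
                           seed, config)


def _draw_markers(phen: PatientPhenotype, rng: np.random.Generator,
                  config: CohortConfig) -> dict[str, int]:
    """ER from the phenotype's marker label; PR and Her2 from weaker couplings."""
    k = config.marker_coupling_k
    pr = 1 if _sigmoid(0.5 * k * (phen.gland_fraction - 0.5)) > rng.uniform() else -1
    d01 = (phen.nuclear_density - 0.3) / 0.6
    her2 = 1 if _sigmoid(0.5 * k * (d01 - 0.5)) > rng.uniform() else -1
    return {"ER": phen.marker_label, "PR": pr, "Her2": her2}


def make_wsi_cohort(n_patients: int, slide_px: int = 2048, seed: int = 0,
                    config: CohortConfig | None = None) -> WsiCohort:
    """Generate whole-slide-like mosaics with tissue-type masks and labels.

    Each slide is one patient's mosaic of epithelium (rendered with the
    patient's phenotype, hence marker-informative), stroma (patient's
    band-pass texture, marker-independent), fat (circular vacuoles,
    patient-independent) and background. Label maps use
    {0: background, 1: epithelium, 2: stroma, 3: fat}.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if slide_px < 1024:
        raise ValueError("slide_px must be >= 1024")
    config = config or CohortConfig()

    root = np.random.SeedSequence([seed, 2])
    patient_seeds = root.spawn(n_patients)
    phenotypes, slides, masks, rows = [], [], [], []
    for pid, pseq in enumerate(patient_seeds, start=1):
        s_phen, s_mark, s_geom, s_tex = (np.random.default_rng(s) for s in pseq.spawn(4))
        phen = _draw_phenotype(pid, s_phen, config)
        phenotypes.append(phen)
        markers = _draw_markers(phen, s_mark, config)

        size = slide_px
        yy, xx = np.mgrid[0:size, 0:size]
        radial = 1.0 - ((yy - size / 2) ** 2 + (xx - size / 2) ** 2) / ((0.62 * size) ** 2)
        tissue_field = _smooth_noise((size, size), size / 10.0, s_geom) + 2.2 * radial
        tissue = _threshold_at_fraction(tissue_field, 0.82)

        lo, hi = config.epithelium_band
        epi_target = s_geom.uniform(lo + 0.05, hi - 0.05)  # fraction of slide pixels
        epi_field = _smooth_noise((size, size), size / 14.0, s_geom)
        tissue_frac = tissue.mean()
        epi = _threshold_at_fraction(epi_field, min(0.95, epi_target / tissue_frac), within=tissue)

        fat_field = _smooth_noise((size, size), size / 12.0, s_geom)
        stroma_region = tissue & ~epi
        fat = _threshold_at_fraction(fat_field, 0.3, within=stroma_region)

        mask = np.zeros((size, size), dtype=np.uint8)
        mask[tissue] = LABEL_STROMA
        mask[epi] = LABEL_EPITHELIUM
        mask[fat] = LABEL_FAT

        # epithelium morphology carries the marker-informative texture (g, d, r)
        epi_morph = render_morphology(phen, size, s_tex, config)
        # stroma texture from the patient's (w, a) — independent of the marker
        stroma_tex = _stroma_texture((size, size), phen.stroma_wavelength,
                                     phen.anisotropy, s_tex.uniform(0, np.pi), s_tex)
        n_str = int(0.002 * size * size)
        str_nuclear = np.zeros((size, size))
        centers = s_tex.uniform(0, size, size=(n_str, 2))
        _stamp_nuclei(str_nuclear, centers,
                      np.full(n_str, 4.0), np.full(n_str, 2.2),
                      s_tex.uniform(0, np.pi, n_str))
        # fat: pale circular vacuoles with thin septa (patient-independent)
        fat_nuclear = np.zeros((size, size))
        n_fat = int(0.0002 * size * size)
        fcenters = s_tex.uniform(0, size, size=(n_fat, 2))
        fradii = s_tex.uniform(12, 26, n_fat)
        fat_cyto = np.full((size, size), 0.35)
        for (cy, cx), r in zip(fcenters, fradii):
            y0, y1 = max(0, int(cy - r) - 2), min(size, int(cy + r) + 3)
            x0, x1 = max(0, int(cx - r) - 2), min(size, int(cx + r) + 3)
            if y0 >= y1 or x0 >= x1:
                continue
            dy, dx = np.mgrid[y0:y1, x0:x1]
            dist = np.sqrt((dy - cy) ** 2 + (dx - cx) ** 2)
            fat_cyto[y0:y1, x0:x1] = np.where(dist < r, 0.14, fat_cyto[y0:y1, x0:x1])
            ring = np.abs(dist - r) < 1.5
            fat_nuclear[y0:y1, x0:x1] = np.maximum(fat_nuclear[y0:y1, x0:x1],
                                                   0.5 * ring)

        nuclear = np.where(mask == LABEL_EPITHELIUM, epi_morph[0],
                           np.where(mask == LABEL_STROMA, str_nuclear,
                                    np.where(mask == LABEL_FAT, fat_nuclear, 0.0)))
        cyto = np.where(mask == LABEL_EPITHELIUM, epi_morph[1],
                        np.where(mask == LABEL_STROMA, 0.25 + 0.5 * stroma_tex,
                                 np.where(mask == LABEL_FAT, fat_cyto, 0.0)))
        morph = np.stack([nuclear, cyto]).astype(np.float32)
        slides.append(render_style(morph, BUILTIN_STYLES["siteA"]))
        masks.append(mask)
        rows.append({"patient_id": pid, **markers})

    labels = pd.DataFrame(rows, columns=["patient_id", "ER", "PR", "Her2"])
    return WsiCohort(phenotypes, slides, masks, labels, config.microns_per_pixel, seed)
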