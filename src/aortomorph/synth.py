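"""Seeded synthetic stain fields, ring cross-sections, and subject cohorts.

Everything downstream is validated against these generators: they render
label masks with exactly known geometry and composition, record that truth
pre-noise, and only then colorize and jitter. Fields are flat Cartesian
strips (lamellae as horizontal wavy bands) emulating a high-power medial
field; rings are a separate generator for layer-thickness measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .aortometry import NomogramModel, expected_diameter
from .palettes import StainPalette, default_palette
from .segmentation import StainImage

#: internal label codes for rendered component masks
COMPONENTS = ("elastin", "cytoplasm", "collagen", "gag", "nucleus", "background")
LBL = {name: i for i, name in enumerate(COMPONENTS)}

#: color fallbacks when a stain has no dedicated class for a component
#: (e.g. monochromatic Verhoeff renders everything non-elastin as tissue)
_ROLE_FALLBACK = {
    "elastin": ("elastin", "cytoplasm"),  # H&E: elastin is eosinophilic pink
    "cytoplasm": ("cytoplasm",),
    "collagen": ("collagen", "cytoplasm"),
    "gag": ("gag", "cytoplasm"),
    "nucleus": ("nucleus", "cytoplasm"),
    "background": ("background",),
}


class InfeasibleSpecError(ValueError):
    """Requested geometry or composition cannot be rendered."""


# ---------------------------------------------------------------------------
# stain fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldSpec:
    """Parameters for one synthetic high-power medial field.

    Lengths are µm; ``target_fractions`` are fractions of the whole field
    (components: elastin, cytoplasm, collagen, gag) and must sum to ≤ 1.
    The elastin fraction is realized by the lamellar geometry; the target
    value, if supplied, is informational and should be consistent with
    ``n_lamellae × lamella_thickness / field height``.
    """

    stain_kind: str = "movat"
    image_size: tuple[int, int] = (240, 320)
    pixel_size: float = 1.25
    n_lamellae: int = 8
    lamella_thickness: float = 6.0
    interlamellar_distance: float = 14.0
    target_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"cytoplasm": 0.30, "collagen": 0.30, "gag": 0.15}
    )
    nuclei_density: float = 0.0
    nucleus_axes: tuple[float, float] = (9.0, 4.0)
    waviness_amplitude: float = 0.0
    waviness_wavelength: float = 160.0
    fragmentation_prob: float = 0.0
    color_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_lamellae < 0:
            raise ValueError("n_lamellae must be >= 0")
        for name in ("lamella_thickness", "interlamellar_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.fragmentation_prob <= 1.0:
            raise ValueError("fragmentation_prob must be in [0, 1]")
        fr = dict(self.target_fractions)
        if any(not (0.0 <= v <= 1.0) for v in fr.values()):
            raise ValueError("target fractions must lie in [0, 1]")
        if sum(fr.values()) > 1.0 + 1e-9:
            raise ValueError(f"target fractions sum to {sum(fr.values())} > 1")
        unknown = set(fr) - {"elastin", "cytoplasm", "collagen", "gag"}
        if unknown:
            raise ValueError(f"unknown components in target_fractions: {unknown}")
        if self.nuclei_density < 0:
            raise ValueError("nuclei_density must be >= 0")


@dataclass(frozen=True)
class FieldTruth:
    """Ground truth recorded from the pre-noise label mask."""

    realized_fractions: dict[str, float]
    nuclei_count: int
    n_lamellae: int
    mean_lamella_thickness: float
    mean_interlamellar_distance: float
    field_area: float  # mm^2
    seed: int

    def __post_init__(self) -> None:
        if sum(self.realized_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("realized fractions sum > 1")
        if self.nuclei_count < 0 or self.field_area <= 0:
            raise ValueError("invalid truth values")


def _rng(seed: int, stream: int) -> np.random.Generator:
    # deterministic per-purpose streams so one knob never reshuffles another
    return np.random.default_rng([seed, stream])


def _band_centers(spec: FieldSpec) -> np.ndarray:
    """µm row coordinates of band centers, centered vertically in the field."""
    h_um = spec.image_size[0] * spec.pixel_size
    t, d, n = spec.lamella_thickness, spec.interlamellar_distance, spec.n_lamellae
    extent = n * t + (n - 1) * d if n else 0.0
    if extent > h_um - t:
        raise InfeasibleSpecError(
            f"image height {h_um} µm too small for {n} lamellae "
            f"(need {extent + t} µm)"
        )
    start = (h_um - extent) / 2.0
    return start + t / 2.0 + np.arange(n) * (t + d)


def _render_band_masks(spec: FieldSpec) -> np.ndarray:
    """(n_lamellae, H, W) boolean masks, one per wavy band, pre-fragmentation."""
    h, w = spec.image_size
    ps = spec.pixel_size
    rows_um = (np.arange(h) + 0.5) * ps
    cols_um = (np.arange(w) + 0.5) * ps
    phases = _rng(spec.seed, 5).uniform(0, 2 * np.pi, size=spec.n_lamellae)
    masks = np.zeros((spec.n_lamellae, h, w), dtype=bool)
    for i, c0 in enumerate(_band_centers(spec)):
        center = c0 + spec.waviness_amplitude * np.sin(
            2 * np.pi * cols_um / spec.waviness_wavelength + phases[i]
        )
        # half-open radial interval: mean rendered width equals t exactly
        half = spec.lamella_thickness / 2.0
        masks[i] = (rows_um[:, None] >= center[None, :] - half) & (
            rows_um[:, None] < center[None, :] + half
        )
    return masks


def _fragment(
    masks: np.ndarray, spec: FieldSpec, seg_px: int = 32, gap_px: int = 4
) -> np.ndarray:
    """Cut short breaks into lamellae with probability ``fragmentation_prob``.

    Each band is divided into ``seg_px``-wide segments; a hit erases a
    ``gap_px``-wide break at a seeded position inside the segment. Coupled
    sampling: the uniform draws depend only on the seed, so raising the
    probability cuts a superset of breaks (monotone elastin loss).
    """
    if spec.fragmentation_prob == 0 or masks.shape[0] == 0:
        return masks
    n, _, w = masks.shape
    n_segs = math.ceil(w / seg_px)
    rng = _rng(spec.seed, 1)
    u = rng.random((n, n_segs))
    pos = rng.random((n, n_segs))
    out = masks.copy()
    for i in range(n):
        for s in range(n_segs):
            if u[i, s] < spec.fragmentation_prob:
                lo = s * seg_px + int(pos[i, s] * (seg_px - gap_px))
                out[i, :, lo : lo + gap_px] = False
    return out


def _place_nuclei(
    spec: FieldSpec, n_nuclei: int, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """Dart-throwing Poisson-disk placement; returns (row, col, angle) in px.

    Falls back to unconstrained placement for nuclei that cannot be fit
    after a bounded number of attempts (overlaps allowed at high density).
    """
    h, w = spec.image_size
    min_dist_px = spec.nucleus_axes[0] / spec.pixel_size
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    max_attempts = 60 * max(n_nuclei, 1)
    while len(placed) < n_nuclei and attempts < max_attempts:
        attempts += 1
        r, c = rng.uniform(0, h), rng.uniform(0, w)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_dist_px**2 for pr, pc, _ in placed):
            placed.append((r, c, rng.uniform(0, np.pi)))
    while len(placed) < n_nuclei:  # density too high for the disk constraint
        placed.append((rng.uniform(0, h), rng.uniform(0, w), rng.uniform(0, np.pi)))
    return placed


def _rasterize_ellipse(
    labels: np.ndarray, row: float, col: float, angle: float, axes_px: tuple[float, float]
) -> None:
    a, b = axes_px[0] / 2.0, axes_px[1] / 2.0
    r0 = max(int(row - a - 1), 0)
    r1 = min(int(row + a + 2), labels.shape[0])
    c0 = max(int(col - a - 1), 0)
    c1 = min(int(col + a + 2), labels.shape[1])
    if r1 <= r0 or c1 <= c0:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr, dc = rr + 0.5 - row, cc + 0.5 - col
    u = dc * np.cos(angle) + dr * np.sin(angle)
    v = -dc * np.sin(angle) + dr * np.cos(angle)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    labels[r0:r1, c0:c1][inside] = LBL["nucleus"]


def _colorize(
    labels: np.ndarray, palette: StainPalette, jitter_sd: float, rng: np.random.Generator
) -> np.ndarray:
    lut = np.zeros((len(COMPONENTS), 3), dtype=np.float64)
    for comp in COMPONENTS:
        color = None
        for role in _ROLE_FALLBACK[comp]:
            try:
                color = palette.color_for_role(role)
                break
            except KeyError:
                continue
        if color is None:
            raise KeyError(f"palette {palette.stain_kind!r} cannot render {comp!r}")
        lut[LBL[comp]] = color
    img = lut[labels]
    if jitter_sd > 0:
        img = img + rng.normal(0.0, jitter_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _column_runs(col: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of maximal True runs; simple diff-based scan."""
    padded = np.concatenate(([False], col, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def _lamellar_truth(band_mask: np.ndarray, pixel_size: float) -> tuple[float, float]:
    """Mean band thickness and edge-to-edge gap (µm) from per-column runs."""
    thick, gaps = [], []
    for x in range(band_mask.shape[1]):
        runs = _column_runs(band_mask[:, x])
        thick.extend(length for _, length in runs)
        for (s0, l0), (s1, _) in zip(runs, runs[1:]):
            gaps.append(s1 - (s0 + l0))
    t = float(np.mean(thick)) * pixel_size if thick else float("nan")
    g = float(np.mean(gaps)) * pixel_size if gaps else float("nan")
    return t, g


def generate_stain_field(spec: FieldSpec) -> tuple[StainImage, FieldTruth]:
    """Render one synthetic stain field and its ground truth.

    Rendering order: elastin lamellae (wavy bands, optional fragmentation),
    then a smooth random partition of the remaining pixels into cytoplasm /
    collagen / gag hitting the target counts exactly, then nuclei ellipses,
    then colorization and additive Gaussian jitter. Truth is measured from
    the label mask before any color noise; lamellar thickness/spacing truth
    comes from the pre-fragmentation band geometry.
    """
    palette = default_palette(spec.stain_kind)
    h, w = spec.image_size
    total_px = h * w

    band_masks = _render_band_masks(spec)
    pre_frag = band_masks.any(axis=0) if spec.n_lamellae else np.zeros((h, w), bool)
    band_masks = _fragment(band_masks, spec)
    elastin = band_masks.any(axis=0) if spec.n_lamellae else np.zeros((h, w), bool)

    labels = np.full((h, w), LBL["background"], dtype=np.uint8)
    labels[elastin] = LBL["elastin"]

    targets = dict(spec.target_fractions)
    want = {
        c: int(round(targets.get(c, 0.0) * total_px))
        for c in ("cytoplasm", "collagen", "gag")
    }
    n_free = total_px - int(elastin.sum())
    if sum(want.values()) > n_free:
        raise InfeasibleSpecError(
            f"component fractions need {sum(want.values())} px but only "
            f"{n_free} px remain after lamella placement"
        )
    if n_free:
        smooth = gaussian_filter(
            _rng(spec.seed, 4).standard_normal((h, w)), sigma=8.0, mode="wrap"
        )
        free_idx = np.flatnonzero(~elastin.ravel())
        order = free_idx[np.argsort(smooth.ravel()[free_idx], kind="stable")]
        pos = 0
        flat = labels.ravel()
        for comp in ("cytoplasm", "collagen", "gag"):
            flat[order[pos : pos + want[comp]]] = LBL[comp]
            pos += want[comp]

    field_area = (h * spec.pixel_size) * (w * spec.pixel_size) / 1e6  # mm^2
    n_nuclei = int(round(spec.nuclei_density * field_area))
    for r, c, ang in _place_nuclei(spec, n_nuclei, _rng(spec.seed, 3)):
        _rasterize_ellipse(
            labels, r, c, ang,
            (spec.nucleus_axes[0] / spec.pixel_size,
             spec.nucleus_axes[1] / spec.pixel_size),
        )

    counts = np.bincount(labels.ravel(), minlength=len(COMPONENTS))
    realized = {
        "elastin": counts[LBL["elastin"]] / total_px,
        # nucleus pixels sit inside cells: counted with cytoplasm
        "cytoplasm": (counts[LBL["cytoplasm"]] + counts[LBL["nucleus"]]) / total_px,
        "collagen": counts[LBL["collagen"]] / total_px,
        "gag": counts[LBL["gag"]] / total_px,
    }
    mean_t, mean_g = _lamellar_truth(pre_frag, spec.pixel_size)
    n_rendered = int(sum(1 for m in band_masks if m.any()))

    truth = FieldTruth(
        realized_fractions=realized,
        nuclei_count=n_nuclei,
        n_lamellae=n_rendered,
        mean_lamella_thickness=mean_t,
        mean_interlamellar_distance=mean_g,
        field_area=field_area,
        seed=spec.seed,
    )
    pixels = _colorize(labels, palette, spec.color_jitter_sd, _rng(spec.seed, 2))
    image = StainImage(pixels=pixels, stain_kind=spec.stain_kind,
                       pixel_size=spec.pixel_size)
    return image, truth


def field_label_mask(spec: FieldSpec) -> np.ndarray:
    """Re-render only the pre-noise label mask (codes per :data:`LBL`).

    Deterministic companion to :func:`generate_stain_field` for
    pixel-agreement tests.
    """
    img, _ = generate_stain_field(replace(spec, color_jitter_sd=0.0))
    palette = default_palette(spec.stain_kind)
    # exact prototype colors at zero jitter -> invert the LUT
    lut = {}
    for comp in COMPONENTS:
        for role in _ROLE_FALLBACK[comp]:
            try:
                lut[comp] = palette.color_for_role(role)
                break
            except KeyError:
                continue
    out = np.full(spec.image_size, -1, dtype=np.int16)
    for comp, color in lut.items():
        out[(img.pixels == np.array(color, dtype=np.uint8)).all(axis=2)] = LBL[comp]
    return out


# ---------------------------------------------------------------------------
# ring cross-sections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RingSpec:
    """Axisymmetric whole-vessel cross-section (annulus) image."""

    external_diameter: float  # cm
    intima_thickness: float  # µm
    media_thickness: float  # µm
    adventitia_thickness: float  # µm
    pixel_size: float  # µm/px
    stain_kind: str = "ring_vvg"
    color_jitter_sd: float = 0.0
    seed: int = 0
    margin_px: int = 8

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.external_diameter <= 0:
            raise ValueError("external_diameter must be > 0")
        for name in ("intima_thickness", "media_thickness", "adventitia_thickness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        radius_um = self.external_diameter * 1e4 / 2.0
        wall = self.intima_thickness + self.media_thickness + self.adventitia_thickness
        if wall >= radius_um:
            raise ValueError(
                f"wall thickness {wall} µm must be < external radius {radius_um} µm"
            )
        for name in ("intima_thickness", "media_thickness", "adventitia_thickness"):
            t = getattr(self, name)
            if 0 < t < self.pixel_size:
                raise ValueError(
                    f"{name}={t} µm is below one pixel at {self.pixel_size} µm/px"
                )


@dataclass(frozen=True)
class RingTruth:
    """Exact layer radii (µm) of the rendered annuli."""

    lumen_radius: float
    media_inner_radius: float
    media_outer_radius: float
    external_radius: float
    media_area_px: int  # media label pixels, for pixel-count oracles
    seed: int


def generate_ring_image(spec: RingSpec) -> tuple[StainImage, RingTruth]:
    """Render concentric lumen/intima/media/adventitia annuli.

    A pixel belongs to a layer when its center radius falls in the layer's
    half-open radial interval. Zero-thickness layers are simply absent.
    """
    palette = default_palette(spec.stain_kind)
    radius_um = spec.external_diameter * 1e4 / 2.0
    a = radius_um - (
        spec.intima_thickness + spec.media_thickness + spec.adventitia_thickness
    )
    r_media_in = a + spec.intima_thickness
    r_media_out = r_media_in + spec.media_thickness

    side = int(math.ceil(spec.external_diameter * 1e4 / spec.pixel_size)) + 2 * spec.margin_px
    center = side / 2.0
    coord = (np.arange(side) + 0.5 - center) * spec.pixel_size
    rr = np.hypot(coord[:, None], coord[None, :])

    name_lbl = {"intima": 1, "media": 2, "adventitia": 3}
    labels = np.zeros((side, side), dtype=np.uint8)  # 0 = lumen/outside
    labels[(rr >= a) & (rr < r_media_in)] = name_lbl["intima"]
    labels[(rr >= r_media_in) & (rr < r_media_out)] = name_lbl["media"]
    labels[(rr >= r_media_out) & (rr < radius_um)] = name_lbl["adventitia"]

    lut = np.zeros((4, 3), dtype=np.float64)
    lut[0] = palette.color_for_role("background")
    for nm, i in name_lbl.items():
        lut[i] = dict((c.name, c.rgb) for c in palette.classes)[nm]
    img = lut[labels]
    if spec.color_jitter_sd > 0:
        img = img + _rng(spec.seed, 2).normal(0, spec.color_jitter_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = RingTruth(
        lumen_radius=a,
        media_inner_radius=r_media_in,
        media_outer_radius=r_media_out,
        external_radius=radius_um,
        media_area_px=int((labels == name_lbl["media"]).sum()),
        seed=spec.seed,
    )
    image = StainImage(pixels=pixels, stain_kind=spec.stain_kind,
                       pixel_size=spec.pixel_size)
    return image, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: nondilated-group baseline for every generated metric
BASELINE_METRICS: dict[str, float] = {
    "elastin_fraction": 0.32,
    "cytoplasm_fraction": 0.30,
    "collagen_fraction": 0.24,
    "gag_fraction": 0.14,
    "smc_density": 1500.0,  # nuclei/mm^2
    "media_thickness": 1500.0,  # µm
    "intima_thickness": 80.0,
    "adventitia_thickness": 500.0,
    "n_lamellae": 60.0,
    "lamella_thickness": 3.0,  # µm
    "interlamellar_distance": 20.0,  # µm
    "diameter_zscore": 0.0,
}

_FRACTION_METRICS = (
    "elastin_fraction", "cytoplasm_fraction", "collagen_fraction", "gag_fraction",
)


@dataclass(frozen=True)
class CohortSpec:
    """Two-group subject cohort with configurable group effects.

    ``group_effects`` maps a metric name to the additive delta applied to
    the aneurysm group; the special key ``diameter_fold`` is multiplicative
    on the observed diameter (1.0 = no effect). ``metric_noise_sd`` maps a
    metric to its between-subject Gaussian SD.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"nondilated": 17, "aneurysm": 18}
    )
    group_effects: Mapping[str, float] = field(default_factory=dict)
    metric_noise_sd: Mapping[str, float] = field(default_factory=dict)
    nomogram: NomogramModel = field(default_factory=NomogramModel)
    age_range: tuple[float, float] = (30.0, 78.0)
    bsa_range: tuple[float, float] = (1.6, 2.3)
    p_male: float = 0.7
    race_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "caucasian": 0.7, "african_american": 0.15, "hispanic": 0.15,
        }
    )
    valve_bicuspid_prob: Mapping[str, float] = field(
        default_factory=lambda: {"nondilated": 0.06, "aneurysm": 0.50}
    )
    comorbidity_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.5, "hyperlipidemia": 0.4, "diabetes": 0.15,
            "smoking": 0.5, "lipid_lowering_agents": 0.4,
        }
    )
    rater_noise_sd: float = 0.35
    n_raters: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_group:
            raise ValueError("n_per_group must not be empty")
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"n_per_group[{g!r}] must be >= 1")
        if any(sd < 0 for sd in self.metric_noise_sd.values()):
            raise ValueError("metric noise SDs must be >= 0")
        unknown = set(self.group_effects) - set(BASELINE_METRICS) - {"diameter_fold"}
        if unknown:
            raise ValueError(f"unknown metrics in group_effects: {unknown}")


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a subject table and a matching per-subject truth table.

    Returns ``(subjects, truth)``; both carry ``id`` and ``group``. Truth
    holds the exact per-metric values after group deltas and noise; the
    four composition fractions are renormalized to sum to 1 (a field is
    fully occupied by its components). The observed diameter is built from
    the nomogram's expected diameter, the subject's diameter z-score, and
    the optional ``diameter_fold`` effect.
    """
    rng = _rng(spec.seed, 7)
    rows, truths = [], []
    sid = 0
    for group in spec.n_per_group:
        is_aneurysm = group == "aneurysm"
        for _ in range(spec.n_per_group[group]):
            sid += 1
            age = rng.uniform(*spec.age_range)
            sex = "male" if rng.random() < spec.p_male else "female"
            races = list(spec.race_probs)
            race = races[
                rng.choice(len(races), p=np.array(list(spec.race_probs.values())))
            ]
            bsa = rng.uniform(*spec.bsa_range)

            metrics = {}
            for name, base in BASELINE_METRICS.items():
                delta = spec.group_effects.get(name, 0.0) if is_aneurysm else 0.0
                sd = spec.metric_noise_sd.get(name, 0.0)
                noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                metrics[name] = base + delta + noise
            frac_sum = sum(max(metrics[m], 1e-6) for m in _FRACTION_METRICS)
            for m in _FRACTION_METRICS:
                metrics[m] = max(metrics[m], 1e-6) / frac_sum
            for m in ("smc_density", "media_thickness", "intima_thickness",
                      "adventitia_thickness", "lamella_thickness",
                      "interlamellar_distance"):
                metrics[m] = max(metrics[m], 0.0)
            metrics["n_lamellae"] = max(round(metrics["n_lamellae"]), 1)

            subj = {
                "id": f"S{sid:03d}", "group": group, "age": age, "sex": sex,
                "race": race, "bsa": bsa,
            }
            exp_d = expected_diameter(subj, spec.nomogram)
            fold = (
                spec.group_effects.get("diameter_fold", 1.0) if is_aneurysm else 1.0
            )
            observed = (
                exp_d + metrics["diameter_zscore"] * spec.nomogram.residual_sd
            ) * fold

            valve_p = spec.valve_bicuspid_prob.get(group, 0.0)
            row = dict(subj)
            row["observed_diameter"] = observed
            row["valve"] = "bicuspid" if rng.random() < valve_p else "tricuspid"
            for name, p in spec.comorbidity_probs.items():
                row[name] = bool(rng.random() < p)
            latent = rng.normal(0.0, 1.0)
            for r in range(spec.n_raters):
                noisy = latent + rng.normal(0.0, spec.rater_noise_sd)
                row[f"score_rater{r + 1}"] = int(
                    np.clip(np.digitize(noisy, [-0.6, 0.6]) + 1, 1, 3)
                )
            rows.append(row)

            truth = {"id": row["id"], "group": group,
                     "expected_diameter": exp_d,
                     "observed_diameter": observed}
            truth.update(metrics)
            truths.append(truth)

    return pd.DataFrame(rows), pd.DataFrame(truths)
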