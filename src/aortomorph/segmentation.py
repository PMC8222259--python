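"""Stain-image color segmentation and medial area fractions.

Pixels are classified by nearest prototype color in CIELAB space, with an
absolute ΔE cutoff for unclassifiable colors and a luminance cutoff for
white lumen/background. Fractions are reported over classified,
non-background pixels of the medial region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.color import rgb2lab

from .palettes import StainPalette

#: label value for ROI pixels farther than ``max_distance`` from every prototype
UNCLASSIFIED = -1
#: label value for pixels excluded by the luminance (white/lumen) rule
BACKGROUND_LUM = -2
#: label value for pixels outside the ROI (untouched by classification)
OUTSIDE_ROI = -3


@dataclass
class StainImage:
    """An RGB stain raster with physical scale and stain metadata.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
    stain_kind : str
    pixel_size : float
        Microns per pixel; must be positive.
    roi_mask : (H, W) bool array, optional
        Medial region of interest. ``None`` means the whole image.
    """

    pixels: np.ndarray
    stain_kind: str
    pixel_size: float
    roi_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {self.pixels.dtype}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != self.pixels.shape[:2]:
                raise ValueError("roi_mask shape must match image")
            if not self.roi_mask.any():
                raise ValueError("roi_mask is empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def roi(self) -> np.ndarray:
        """Boolean ROI, materializing an all-true mask when none was given."""
        if self.roi_mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.roi_mask


@dataclass
class LabelMask:
    """Per-pixel class labels for a palette.

    ``labels`` holds class indices into ``palette.classes`` or one of the
    sentinel values :data:`UNCLASSIFIED`, :data:`BACKGROUND_LUM`,
    :data:`OUTSIDE_ROI`.
    """

    labels: np.ndarray
    palette: StainPalette

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        valid = (self.labels >= OUTSIDE_ROI) & (self.labels < len(self.palette.classes))
        if not valid.all():
            bad = np.unique(self.labels[~valid])
            raise ValueError(f"labels {bad} invalid for palette")

    def role_mask(self, role: str) -> np.ndarray:
        """Boolean mask of pixels whose class has the given role."""
        idx = [i for i, c in enumerate(self.palette.classes) if c.role == role]
        return np.isin(self.labels, idx)


@dataclass
class FractionSet:
    """Per-component area fractions of the classified medial region.

    ``fractions`` sum to 1 over components; background and unclassified
    pixels are excluded from the denominator and the latter reported
    separately as ``unclassified_fraction`` (share of non-background ROI
    pixels left unassigned).
    """

    fractions: dict[str, float]
    unclassified_fraction: float = 0.0
    n_pixels_roi: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"component fractions must sum to 1, got {total!r}")
        for k, v in self.fractions.items():
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"fraction {k}={v} outside [0, 1]")

    def __getitem__(self, component: str) -> float:
        return self.fractions[component]


def classify_pixels(image: StainImage, palette: StainPalette) -> LabelMask:
    """Assign each ROI pixel to the nearest palette prototype in CIELAB.

    A pixel is labeled :data:`UNCLASSIFIED` when no prototype lies within
    ``palette.max_distance`` ΔE, and :data:`BACKGROUND_LUM` when its L*
    exceeds ``palette.background_luminance`` (lumen/white exclusion, which
    takes precedence). Pixels outside the ROI get :data:`OUTSIDE_ROI`.

    Raises
    ------
    ValueError
        If the palette stain kind does not match the image.
    """
    if palette.stain_kind != image.stain_kind:
        raise ValueError(
            f"stain kind mismatch: image={image.stain_kind!r} "
            f"palette={palette.stain_kind!r}"
        )
    roi = image.roi()

    lab = rgb2lab(image.pixels)
    protos = rgb2lab(palette.prototypes_rgb()[None, :, :])[0]  # (K, 3)

    flat = lab[roi]  # (n, 3)
    # squared ΔE to each prototype
    d2 = ((flat[:, None, :] - protos[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1).astype(np.int16)
    nearest[d2.min(axis=1) > palette.max_distance**2] = UNCLASSIFIED
    nearest[flat[:, 0] > palette.background_luminance] = BACKGROUND_LUM

    labels = np.full(image.shape, OUTSIDE_ROI, dtype=np.int16)
    labels[roi] = nearest
    return LabelMask(labels=labels, palette=palette)


def medial_fractions(
    mask: LabelMask,
    roles: Mapping[str, str] | None = None,
    nucleus_policy: str = "cytoplasm",
) -> FractionSet:
    """Compute component area fractions from a label mask.

    Parameters
    ----------
    mask : LabelMask
    roles : mapping, optional
        name -> component role override; defaults to the palette's own
        class roles.
    nucleus_policy : {"cytoplasm", "separate", "exclude"}
        How nucleus-class pixels enter the fractions. The default merges
        them into cytoplasm so that exactly the four matrix/cell
        components are reported.

    Raises
    ------
    ValueError
        If no ROI pixel was classified into a component.
    """
    if nucleus_policy not in ("cytoplasm", "separate", "exclude"):
        raise ValueError(f"unknown nucleus_policy {nucleus_policy!r}")
    roles = dict(roles) if roles is not None else mask.palette.roles

    labels = mask.labels
    in_roi = labels > OUTSIDE_ROI
    if not in_roi.any():
        raise ValueError("label mask empty within ROI")

    counts: dict[str, int] = {}
    n_background = int((labels == BACKGROUND_LUM).sum())
    n_unclassified = int((labels == UNCLASSIFIED).sum())
    for i, cls in enumerate(mask.palette.classes):
        role = roles.get(cls.name, cls.role)
        n = int((labels == i).sum())
        if role == "background":
            n_background += n
            continue
        if role == "nucleus":
            if nucleus_policy == "cytoplasm":
                role = "cytoplasm"
            elif nucleus_policy == "exclude":
                n_background += n
                continue
        if n > 0:
            counts[role] = counts.get(role, 0) + n

    n_classified = sum(counts.values())
    if n_classified == 0:
        raise ValueError("zero classified component pixels in ROI")

    n_roi = int(in_roi.sum())
    non_bg = n_roi - n_background
    return FractionSet(
        fractions={k: v / n_classified for k, v in counts.items()},
        unclassified_fraction=n_unclassified / non_bg if non_bg else 0.0,
        n_pixels_roi=n_roi,
        meta={
            "denominator": "classified_non_background",
            "nucleus_policy": nucleus_policy,
            "n_classified": n_classified,
            "n_background": n_background,
            "n_unclassified": n_unclassified,
        },
    )


def aggregate_fields(per_field: Sequence[FractionSet] | Iterable[float]):
    """Unweighted mean across replicate fields.

    Accepts either ``FractionSet`` objects (component-wise mean, returning
    a new ``FractionSet`` with ``n_fields`` in its metadata) or plain
    scalars (returning their mean as a float).
    """
    items = list(per_field)
    if not items:
        raise ValueError("need at least one field")

    if not isinstance(items[0], FractionSet):
        return float(np.mean([float(x) for x in items]))

    keys = set(items[0].fractions)
    for fs in items[1:]:
        if set(fs.fractions) != keys:
            raise ValueError(
                f"inconsistent component sets: {sorted(keys)} vs "
                f"{sorted(fs.fractions)}"
            )
    mean_fracs = {k: float(np.mean([fs.fractions[k] for fs in items])) for k in keys}
    # renormalize away accumulated floating error (sums of means of sums-to-1)
    total = sum(mean_fracs.values())
    mean_fracs = {k: v / total for k, v in mean_fracs.items()}
    return FractionSet(
        fractions=mean_fracs,
        unclassified_fraction=float(
            np.mean([fs.unclassified_fraction for fs in items])
        ),
        n_pixels_roi=int(np.sum([fs.n_pixels_roi for fs in items])),
        meta={"n_fields": len(items)},
    )
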