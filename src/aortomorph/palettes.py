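"""Stain palettes: named prototype colors with tissue-component roles.

A palette maps pixel colors to medial components for one stain kind.
Defaults live here as plain data so tests can stress palette mismatch;
palettes can also be loaded from / dumped to YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

STAIN_KINDS = ("movat", "verhoeff", "vvg", "he", "ring_vvg")

#: valid roles a palette class may play
ROLES = ("elastin", "cytoplasm", "collagen", "gag", "nucleus", "background")


@dataclass(frozen=True)
class PaletteClass:
    """One color class: display name, sRGB prototype, and component role."""

    name: str
    rgb: tuple[int, int, int]
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if len(self.rgb) != 3 or any(not (0 <= v <= 255) for v in self.rgb):
            raise ValueError(f"rgb must be three values in 0..255, got {self.rgb}")


@dataclass(frozen=True)
class StainPalette:
    """Prototype-color palette for one stain kind.

    Parameters
    ----------
    stain_kind : str
        One of :data:`STAIN_KINDS`.
    classes : tuple of PaletteClass
        At least two classes with unique names and pairwise-distinct
        prototype colors.
    max_distance : float
        CIELAB distance beyond which a pixel is left unclassified
        (default 25 ΔE).
    background_luminance : float
        Pixels with L* above this are background regardless of prototype
        distance (lumen/white exclusion).
    """

    stain_kind: str
    classes: tuple[PaletteClass, ...] = field(default_factory=tuple)
    max_distance: float = 25.0
    background_luminance: float = 92.0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("palette needs at least 2 classes")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        protos = {c.rgb for c in self.classes}
        if len(protos) != len(self.classes):
            raise ValueError("prototype colors must be pairwise distinct")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.classes]

    @property
    def roles(self) -> dict[str, str]:
        """name -> role mapping."""
        return {c.name: c.role for c in self.classes}

    def prototypes_rgb(self) -> np.ndarray:
        """(K, 3) uint8 array of prototype colors, class order."""
        return np.array([c.rgb for c in self.classes], dtype=np.uint8)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def color_for_role(self, role: str) -> tuple[int, int, int]:
        for c in self.classes:
            if c.role == role:
                return c.rgb
        raise KeyError(f"palette {self.stain_kind!r} has no class with role {role!r}")

    def to_dict(self) -> dict:
        return {
            "stain_kind": self.stain_kind,
            "max_distance": self.max_distance,
            "background_luminance": self.background_luminance,
            "classes": [
                {"name": c.name, "rgb": list(c.rgb), "role": c.role}
                for c in self.classes
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "StainPalette":
        classes = tuple(
            PaletteClass(c["name"], tuple(int(v) for v in c["rgb"]), c["role"])
            for c in d["classes"]
        )
        return cls(
            stain_kind=d["stain_kind"],
            classes=classes,
            max_distance=float(d.get("max_distance", 25.0)),
            background_luminance=float(d.get("background_luminance", 92.0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "StainPalette":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _p(stain, classes, **kw) -> StainPalette:
    return StainPalette(stain, tuple(PaletteClass(*c) for c in classes), **kw)


#: pentachrome: five tissue colors plus off-white background
MOVAT = _p(
    "movat",
    [
        ("elastin", (30, 25, 30), "elastin"),
        ("cytoplasm", (170, 40, 60), "cytoplasm"),
        ("collagen", (225, 200, 60), "collagen"),
        ("gag", (70, 165, 160), "gag"),
        ("nucleus", (70, 40, 110), "nucleus"),
        ("background", (248, 246, 242), "background"),
    ],
)

#: monochromatic elastin stain, no counterstain
VERHOEFF = _p(
    "verhoeff",
    [
        ("elastin", (25, 22, 25), "elastin"),
        ("tissue", (190, 185, 182), "cytoplasm"),
        ("background", (250, 249, 247), "background"),
    ],
)

#: Verhoeff-Van Gieson: black elastin, red collagen
VVG = _p(
    "vvg",
    [
        ("elastin", (25, 20, 25), "elastin"),
        ("collagen", (200, 70, 90), "collagen"),
        ("tissue", (215, 190, 175), "cytoplasm"),
        ("background", (250, 248, 246), "background"),
    ],
)

#: hematoxylin-eosin: blue-violet nuclei on pink matrix
HE = _p(
    "he",
    [
        ("nucleus", (75, 60, 150), "nucleus"),
        ("matrix", (235, 150, 170), "cytoplasm"),
        ("background", (250, 247, 246), "background"),
    ],
)

#: cartoon ring palette for whole-cross-section layer measurement (VVG-like:
#: dark elastic media between a pale intima and a red collagenous adventitia)
RING_VVG = _p(
    "ring_vvg",
    [
        ("intima", (235, 190, 200), "cytoplasm"),
        ("media", (40, 32, 45), "elastin"),
        ("adventitia", (200, 45, 55), "collagen"),
        ("background", (252, 250, 248), "background"),
    ],
)

DEFAULT_PALETTES: dict[str, StainPalette] = {
    "movat": MOVAT,
    "verhoeff": VERHOEFF,
    "vvg": VVG,
    "he": HE,
    "ring_vvg": RING_VVG,
}


def default_palette(stain_kind: str) -> StainPalette:
    """Return the built-in palette for ``stain_kind``.

    Raises ``KeyError`` with the known kinds if no palette exists.
    """
    try:
        return DEFAULT_PALETTES[stain_kind]
    except KeyError:
        raise KeyError(
            f"no palette for stain kind {stain_kind!r}; "
            f"known: {sorted(DEFAULT_PALETTES)}"
        ) from None
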