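import numpy as np
import pytest

from aortomorph.synth import FieldSpec, RingSpec


@pytest.fixture
def movat_spec():
    """Noiseless Movat field: 8 straight bands, fractions .25/.30/.30/.15.

    240 rows at 1 µm/px with 7.5 µm bands gives exactly 25% elastin
    (integer-pixel widths via the half-open rasterization rule average out,
    but 7.5 µm at 1 µm/px renders 7 or 8 px per band -> 0.25 ± raster).
    """
    return FieldSpec(
        stain_kind="movat",
        image_size=(240, 320),
        pixel_size=1.0,
        n_lamellae=8,
        lamella_thickness=7.5,
        interlamellar_distance=22.0,
        target_fractions={"cytoplasm": 0.30, "collagen": 0.30, "gag": 0.15},
        nuclei_density=0.0,
        seed=11,
    )


@pytest.fixture
def vvg_spec():
    """Noiseless VVG strip: 8 bands, 6 µm thick, 14 µm apart, 1 µm/px."""
    return FieldSpec(
        stain_kind="vvg",
        image_size=(200, 320),
        pixel_size=1.0,
        n_lamellae=8,
        lamella_thickness=6.0,
        interlamellar_distance=14.0,
        target_fractions={"cytoplasm": 0.45, "collagen": 0.30},
        seed=5,
    )


@pytest.fixture
def he_spec():
    """H&E field of exactly 0.12 mm² (300x400 µm) with 500 nuclei/mm²."""
    return FieldSpec(
        stain_kind="he",
        image_size=(300, 400),
        pixel_size=1.0,
        n_lamellae=0,
        target_fractions={"cytoplasm": 1.0},
        nuclei_density=500.0,
        seed=23,
    )


@pytest.fixture
def ring_spec():
    return RingSpec(
        external_diameter=0.5,
        intima_thickness=40.0,
        media_thickness=300.0,
        adventitia_thickness=120.0,
        pixel_size=4.0,
        seed=2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
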