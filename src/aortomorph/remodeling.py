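"""Area-conservation model of medial thinning under lumen dilatation.

A media of thickness ``b`` on a lumen of radius ``a`` occupies an annulus
of area π((a+b)² − a²) = π(2ab + b²). If the lumen dilates with the wall
material inert, the annulus area is conserved, so the thinned thickness at
a new lumen radius ``a'`` is the unique positive root of
``2a'b' + b'² = 2ab + b²``:

    b' = sqrt(a'² + 2ab + b²) − a'

The model is unit-agnostic; unit conversions (cm ↔ µm) happen at the
boundary in :func:`predict_preaneurysmal`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .aortometry import CM_TO_UM, WallGeometry
from .morphometry import LamellarMetrics


@dataclass(frozen=True)
class AnnulusState:
    """Lumen radius ``a`` and media thickness ``b`` in one consistent unit."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("a and b must be > 0")

    @property
    def conserved_area(self) -> float:
        """Annulus area over π: Q = 2ab + b²."""
        return 2 * self.a * self.b + self.b**2

    @property
    def index(self) -> float:
        """Radius-to-thickness index a/b (≈10 nondilated, ≈20 aneurysmal)."""
        return self.a / self.b


@dataclass(frozen=True)
class RemodelingPrediction:
    """Pre-dilatation geometry inferred from observed aneurysmal geometry."""

    predicted_media_thickness: float  # µm
    predicted_lamella_thickness: float  # µm
    predicted_interlamellar_distance: float  # µm
    scaling_factor: float  # predicted / observed media thickness
    area_residual: float  # relative conservation error, must be ~0

    def __post_init__(self) -> None:
        if self.area_residual > 1e-9:
            raise ValueError(
                f"area not conserved: relative residual {self.area_residual}"
            )


def thinned_thickness(state: AnnulusState, a_new: float) -> float:
    """Media thickness after the lumen moves to radius ``a_new``.

    Works in both directions: ``a_new > a`` thins, ``a_new < a`` thickens,
    and the map is an involution (forward then inverse returns ``b``).
    """
    if not a_new > 0:
        raise ValueError("a_new must be > 0")
    return math.sqrt(a_new**2 + state.conserved_area) - a_new


def thinning_curve(
    index: float, a_new_over_a: np.ndarray | list[float]
) -> np.ndarray:
    """Relative thinning b'/b over a sweep of relative dilatation a'/a.

    ``index`` is a/b. Scale-free: computed at a = index, b = 1.
    """
    state = AnnulusState(a=float(index), b=1.0)
    ratios = np.asarray(a_new_over_a, dtype=float)
    return np.array([thinned_thickness(state, r * state.a) for r in ratios])


def fold_dilatation(observed_diameter: float, expected_diameter: float) -> float:
    """Observed-to-expected diameter ratio (> 1.5 defines an aneurysm)."""
    if not expected_diameter > 0:
        raise ValueError("expected_diameter must be > 0")
    return observed_diameter / expected_diameter


def predict_preaneurysmal(
    observed_geom: WallGeometry,
    observed_lamellae: LamellarMetrics,
    expected_diameter: float,
) -> RemodelingPrediction:
    """Reverse the passive-dilatation map to the expected (pre-aneurysmal)
    lumen size.

    The observed media annulus (lumen radius from the geometry's
    wall-subtraction convention, intima treated as part of the lumen
    boundary) is mapped back to the expected external diameter assuming
    intima and adventitia thicknesses inert. With the media's outer radius
    pinned at ``r = R_expected − adventitia`` and area conserved, the
    predicted state has inner radius ``a_pred = sqrt(r² − Q)`` and
    thickness ``b_pred = r − a_pred``. Lamella thickness and interlamellar distance scale uniformly
    by ``b_pred / b_obs``.
    """
    if not expected_diameter > 0:
        raise ValueError("expected_diameter must be > 0")
    obs = AnnulusState(
        a=observed_geom.lumen_radius + observed_geom.intima_thickness,
        b=observed_geom.media_thickness,
    )
    q = obs.conserved_area
    r_media_out_pred = (
        expected_diameter * CM_TO_UM / 2.0
        - observed_geom.adventitia_thickness
    )
    if r_media_out_pred**2 <= q:
        raise ValueError(
            f"expected diameter {expected_diameter} cm leaves no room for the "
            "conserved media area (infeasible expected radius)"
        )
    a_pred = math.sqrt(r_media_out_pred**2 - q)
    b_pred = r_media_out_pred - a_pred

    pred_state = AnnulusState(a=a_pred, b=b_pred)
    residual = abs(pred_state.conserved_area - q) / q
    scale = b_pred / obs.b
    return RemodelingPrediction(
        predicted_media_thickness=b_pred,
        predicted_lamella_thickness=observed_lamellae.lamella_thickness * scale,
        predicted_interlamellar_distance=(
            observed_lamellae.interlamellar_distance * scale
        ),
        scaling_factor=scale,
        area_residual=residual,
    )
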