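"""Nomogram-based expected diameter, z-scores, and derived cross-sectional
quantities.

Diameters are external; the lumen radius subtracts all three layer
thicknesses (the convention is explicit in :class:`WallGeometry` and can be
revisited by constructing the geometry differently). All areas are 2-D
cross-sections, no length/volume correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import yaml

CM_TO_UM = 1e4
UM2_TO_MM2 = 1e-6


@dataclass(frozen=True)
class NomogramModel:
    """Linear expected-diameter model: intercept + age, sex, BSA terms.

    The default coefficients are synthetic placeholders chosen to give
    plausible adult ascending-aorta diameters; supply published regression
    coefficients via config for real use.
    """

    intercept: float = 1.2  # cm
    coef_age: float = 0.008  # cm / year
    coef_sex: float = 0.12  # cm, indicator(male)
    coef_bsa: float = 0.85  # cm / m^2
    residual_sd: float = 0.35  # cm

    def __post_init__(self) -> None:
        if not self.residual_sd > 0:
            raise ValueError("residual_sd must be > 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "intercept": self.intercept,
                    "coef_age": self.coef_age,
                    "coef_sex": self.coef_sex,
                    "coef_bsa": self.coef_bsa,
                    "residual_sd": self.residual_sd,
                },
                fh, sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "NomogramModel":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


VALVES = ("tricuspid", "bicuspid")
GROUPS = ("nondilated", "aneurysm")


@dataclass
class SubjectRecord:
    """One subject's clinical covariates and ordinal pathology scores."""

    id: str
    group: str
    age: float
    sex: str
    race: str
    bsa: float
    observed_diameter: float
    valve: str = "tricuspid"
    hypertension: bool = False
    hyperlipidemia: bool = False
    diabetes: bool = False
    smoking: bool = False
    lipid_lowering_agents: bool = False
    scores: dict[str, int] = field(default_factory=dict)  # rater -> 1..3

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.valve not in VALVES:
            raise ValueError(f"valve must be one of {VALVES}")
        if not self.age > 0:
            raise ValueError("age must be > 0")
        if not self.bsa > 0:
            raise ValueError("bsa must be > 0")
        if not self.observed_diameter > 0:
            raise ValueError("observed_diameter must be > 0")
        for rater, s in self.scores.items():
            if s not in (1, 2, 3):
                raise ValueError(f"score for {rater} must be 1..3, got {s}")


@dataclass(frozen=True)
class WallGeometry:
    """Axisymmetric wall geometry: external diameter (cm) + layer
    thicknesses (µm).

    Derived radii (µm): external ``R``, media outer ``r_out = R −
    adventitia``, media inner ``r_in = r_out − media``, lumen
    ``a = r_in − intima``.
    """

    external_diameter: float  # cm
    intima_thickness: float  # µm
    media_thickness: float  # µm
    adventitia_thickness: float  # µm

    def __post_init__(self) -> None:
        if self.external_diameter <= 0:
            raise ValueError("external_diameter must be > 0")
        for name in ("intima_thickness", "media_thickness", "adventitia_thickness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lumen_radius <= 0:
            raise ValueError("wall thicker than external radius: lumen radius <= 0")

    @property
    def external_radius(self) -> float:
        return self.external_diameter * CM_TO_UM / 2.0

    @property
    def media_outer_radius(self) -> float:
        return self.external_radius - self.adventitia_thickness

    @property
    def media_inner_radius(self) -> float:
        return self.media_outer_radius - self.media_thickness

    @property
    def lumen_radius(self) -> float:
        return self.media_inner_radius - self.intima_thickness


@dataclass(frozen=True)
class DerivedMetrics:
    """Per-subject derived quantities; see the factory functions below."""

    expected_diameter: float  # cm
    z_score: float
    size_class: str
    fold_dilatation: float
    media_xsec_area: float  # mm^2
    smc_density: float  # nuclei/mm^2
    smc_per_xsec: float
    component_xsec: dict[str, float]  # component -> mm^2


def expected_diameter(subject: "SubjectRecord | Mapping", model: NomogramModel) -> float:
    """Expected external diameter (cm) from the linear nomogram."""
    if isinstance(subject, SubjectRecord):
        age, sex, bsa = subject.age, subject.sex, subject.bsa
    else:
        try:
            age, sex, bsa = subject["age"], subject["sex"], subject["bsa"]
        except KeyError as exc:
            raise ValueError(f"missing covariate {exc.args[0]!r}") from None
    if age is None or bsa is None or sex is None:
        raise ValueError("age, sex, and bsa are all required")
    return (
        model.intercept
        + model.coef_age * float(age)
        + model.coef_sex * (1.0 if sex == "male" else 0.0)
        + model.coef_bsa * float(bsa)
    )


def z_score_and_class(
    observed: float, expected: float, model: NomogramModel
) -> tuple[float, str]:
    """Diameter z-score and size class.

    Aneurysm when observed exceeds 1.5× expected; normal when the z-score
    lies within ±2 SD; otherwise indeterminate-dilated.
    """
    if not expected > 0:
        raise ValueError("expected diameter must be > 0")
    z = (observed - expected) / model.residual_sd
    if observed > 1.5 * expected:
        cls = "aneurysm"
    elif abs(z) <= 2.0:
        cls = "normal"
    else:
        cls = "indeterminate-dilated"
    return z, cls


def media_xsec_area(geom: WallGeometry) -> float:
    """Medial annulus area π(r_out² − r_in²), in mm²."""
    if geom.media_thickness <= 0:
        warnings.warn("media_thickness <= 0; area is 0", stacklevel=2)
        return 0.0
    r_out, r_in = geom.media_outer_radius, geom.media_inner_radius
    return math.pi * (r_out**2 - r_in**2) * UM2_TO_MM2


def per_cross_section(
    fractions: Mapping[str, float], density: float, area: float
) -> tuple[float, dict[str, float]]:
    """SMC count per cross-section and per-component cross-sectional areas.

    ``smc_per_xsec = density × area`` and ``component_xsec[c] =
    fractions[c] × area``; both are linear in every factor, which is what
    separates dilution (fraction down, amount kept) from true loss.
    """
    if not area > 0:
        raise ValueError("area must be > 0")
    return density * area, {c: f * area for c, f in fractions.items()}


def derive_metrics(
    subject: "SubjectRecord | Mapping",
    geom: WallGeometry,
    fractions: Mapping[str, float],
    smc_density: float,
    model: NomogramModel,
) -> DerivedMetrics:
    """Convenience bundle of all per-subject derived quantities."""
    exp_d = expected_diameter(subject, model)
    observed = (
        subject.observed_diameter
        if isinstance(subject, SubjectRecord)
        else subject["observed_diameter"]
    )
    z, cls = z_score_and_class(observed, exp_d, model)
    area = media_xsec_area(geom)
    if area > 0:
        smc, comp = per_cross_section(fractions, smc_density, area)
    else:
        smc, comp = 0.0, {c: 0.0 for c in fractions}
    return DerivedMetrics(
        expected_diameter=exp_d,
        z_score=z,
        size_class=cls,
        fold_dilatation=observed / exp_d,
        media_xsec_area=area,
        smc_density=smc_density,
        smc_per_xsec=smc,
        component_xsec=comp,
    )
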