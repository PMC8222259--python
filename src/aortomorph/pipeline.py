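"""End-to-end orchestration: synth → segment → morph → derive → stats.

The measurement stages are blinded by construction: field generation,
segmentation, and morphometry receive per-subject truth with the group
label stripped; clinical labels are joined back only when derived metrics
and statistics are computed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, aortometry, morphometry, remodeling, segmentation, synth
from .aortometry import NomogramModel, WallGeometry
from .io import write_table
from .palettes import default_palette
from .stats import (
    ContingencyTable,
    correlation_matrix,
    fisher_exact_rxc,
    format_p,
    interrater_agreement,
    mann_whitney,
)

_CATEGORICAL = ("sex", "race", "valve", "hypertension", "hyperlipidemia",
                "diabetes", "smoking", "lipid_lowering_agents")

_STAGE = {"cohort": 0, "movat": 1, "verhoeff": 2, "he": 3, "lamellae": 4, "ring": 5}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible synthetic study run."""

    seed: int = 0
    cohort: dict = dc_field(default_factory=dict)
    nomogram: dict = dc_field(default_factory=dict)
    # stratified field sampling: strata x fields-per-stratum (3 x 3 emulates
    # nine arbitrary fields across inner/mid/outer media)
    n_strata: int = 3
    fields_per_stratum: int = 3
    field_size: tuple[int, int] = (200, 280)
    field_pixel_size: float = 1.25
    color_jitter_sd: float = 4.0
    lamella_field_width: int = 160
    measure_layers: bool = True
    ring_n_sites: int = 3
    ring_target_px: int = 900  # ring image side length target, sets µm/px
    subjects_csv: str | None = None
    morph_csv: str | None = None
    out_dir: str | None = None

    def validate(self) -> None:
        if self.n_strata < 1 or self.fields_per_stratum < 1:
            raise ValueError("field sampling needs >= 1 stratum and field")
        for path in (self.subjects_csv, self.morph_csv):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input missing: {path}")
        if self.subjects_csv is None and self.morph_csv is not None:
            raise ValueError("morph_csv without subjects_csv is not meaningful")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "field_size" in d:
            d["field_size"] = tuple(d["field_size"])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StudyReport:
    """All output tables of one run plus a provenance block."""

    tables: dict[str, pd.DataFrame]
    provenance: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            write_table(out / f"{name}.csv", df)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=1, sort_keys=True)
        )


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sub_seed(seed: int, stage: str, *indices: int) -> int:
    ss = np.random.SeedSequence([seed, _STAGE[stage], *indices])
    return int(ss.generate_state(1)[0])


def _nomogram(config: RunConfig) -> NomogramModel:
    return NomogramModel(**config.nomogram) if config.nomogram else NomogramModel()


def _cohort_spec(config: RunConfig) -> synth.CohortSpec:
    kwargs = dict(config.cohort)
    kwargs.setdefault("seed", config.seed)
    kwargs["nomogram"] = _nomogram(config)
    return synth.CohortSpec(**kwargs)


def _movat_field_spec(truth: dict, config: RunConfig, seed: int) -> synth.FieldSpec:
    """Movat field whose composition matches the subject's true fractions."""
    ps = config.field_pixel_size
    h_px = config.field_size[0]
    n_bands = 8
    f_el = truth["elastin_fraction"]
    # integer-pixel band thickness renders exactly (a half-open interval of
    # length k*ps always covers k pixel centers), so elastin coverage is known
    t_px = max(int(round(f_el * h_px / n_bands)), 1)
    f_exact = n_bands * t_px / h_px
    d = (0.92 * h_px - n_bands * t_px) * ps / (n_bands - 1)
    if d <= 0:  # very elastin-rich subject: fewer, thicker bands
        n_bands = 5
        t_px = max(int(round(f_el * h_px / n_bands)), 1)
        f_exact = n_bands * t_px / h_px
        d = (0.92 * h_px - n_bands * t_px) * ps / (n_bands - 1)
    other = truth["cytoplasm_fraction"] + truth["collagen_fraction"] + truth["gag_fraction"]
    scale = (1.0 - f_exact - 0.001) / other
    return synth.FieldSpec(
        stain_kind="movat",
        image_size=config.field_size,
        pixel_size=ps,
        n_lamellae=n_bands,
        lamella_thickness=t_px * ps,
        interlamellar_distance=d,
        # remaining pixels split in the subject's true proportions; the
        # scaling cancels in the fractions (denominator = classified pixels)
        target_fractions={
            "cytoplasm": scale * truth["cytoplasm_fraction"],
            "collagen": scale * truth["collagen_fraction"],
            "gag": scale * truth["gag_fraction"],
        },
        nuclei_density=truth["smc_density"],
        color_jitter_sd=config.color_jitter_sd,
        seed=seed,
    )


def _lamella_field_spec(truth: dict, config: RunConfig, seed: int) -> synth.FieldSpec:
    """Tall narrow VVG strip spanning the full lamellar stack."""
    ps = config.field_pixel_size
    # integer-pixel thickness renders exactly; see _movat_field_spec
    t = max(int(round(truth["lamella_thickness"] / ps)), 2) * ps
    d = max(truth["interlamellar_distance"], ps)
    n = int(truth["n_lamellae"])
    rows = int(np.ceil((n * t + (n - 1) * d + 4 * t) / ps))
    f_el = (n * t / ps) / rows
    free = max(1.0 - f_el - 0.005, 0.0)
    return synth.FieldSpec(
        stain_kind="vvg",
        image_size=(rows, config.lamella_field_width),
        pixel_size=config.field_pixel_size,
        n_lamellae=n,
        lamella_thickness=t,
        interlamellar_distance=d,
        target_fractions={"cytoplasm": 0.6 * free, "collagen": 0.4 * free},
        color_jitter_sd=config.color_jitter_sd,
        seed=seed,
    )


def _he_field_spec(truth: dict, config: RunConfig, seed: int) -> synth.FieldSpec:
    return synth.FieldSpec(
        stain_kind="he",
        image_size=config.field_size,
        pixel_size=config.field_pixel_size,
        n_lamellae=0,
        target_fractions={"cytoplasm": 1.0},
        nuclei_density=truth["smc_density"],
        color_jitter_sd=config.color_jitter_sd,
        seed=seed,
    )


def _measure_subject(truth: dict, config: RunConfig, idx: int) -> dict:
    """Blinded measurement of one subject from rendered synthetic material.

    ``truth`` must not contain the group label; only metric ground truth
    and the observed diameter (needed for ring geometry) are used.
    """
    assert "group" not in truth, "measurement stage must stay blinded"
    n_fields = config.n_strata * config.fields_per_stratum

    frac_sets, nuclei = [], []
    for f in range(n_fields):
        img, _ = synth.generate_stain_field(
            _movat_field_spec(truth, config, _sub_seed(config.seed, "movat", idx, f))
        )
        mask = segmentation.classify_pixels(img, default_palette("movat"))
        frac_sets.append(segmentation.medial_fractions(mask))

        he_img, _ = synth.generate_stain_field(
            _he_field_spec(truth, config, _sub_seed(config.seed, "he", idx, f))
        )
        nuclei.append(morphometry.count_nuclei(he_img))

    fractions = segmentation.aggregate_fields(frac_sets)
    density = float(np.mean([n.density for n in nuclei]))

    lam_img, _ = synth.generate_stain_field(
        _lamella_field_spec(truth, config, _sub_seed(config.seed, "lamellae", idx))
    )
    elastin = morphometry.elastin_mask_from_image(lam_img)
    tspec = morphometry.TransectSpec(n_transects=9)
    lam = morphometry.measure_lamellae(
        elastin, tspec, lam_img.pixel_size, exclusion_radius=10.0
    )
    n_lam = morphometry.count_lamellae(elastin, tspec, lam_img.pixel_size)

    row = {
        "elastin_fraction": fractions["elastin"],
        "cytoplasm_fraction": fractions["cytoplasm"],
        "collagen_fraction": fractions["collagen"],
        "gag_fraction": fractions["gag"],
        "unclassified_fraction": fractions.unclassified_fraction,
        "smc_density": density,
        "n_lamellae": n_lam,
        "lamella_thickness": lam.lamella_thickness,
        "interlamellar_distance": lam.interlamellar_distance,
        "n_excluded": lam.n_excluded,
        "n_fields": n_fields,
    }

    if config.measure_layers:
        d_um = truth["observed_diameter"] * 1e4
        thinnest = min(
            t for t in (truth["intima_thickness"], truth["media_thickness"],
                        truth["adventitia_thickness"]) if t > 0
        )
        ps = max(min(d_um / config.ring_target_px, thinnest), 2.0)
        ring_spec = synth.RingSpec(
            external_diameter=truth["observed_diameter"],
            intima_thickness=truth["intima_thickness"],
            media_thickness=truth["media_thickness"],
            adventitia_thickness=truth["adventitia_thickness"],
            pixel_size=ps,
            seed=_sub_seed(config.seed, "ring", idx),
        )
        ring_img, _ = synth.generate_ring_image(ring_spec)
        wall = morphometry.measure_layer_thickness(ring_img, config.ring_n_sites)
        row.update(
            intima_thickness=wall.intima,
            media_thickness=wall.media,
            adventitia_thickness=wall.adventitia,
        )
    else:
        row.update(
            intima_thickness=truth["intima_thickness"],
            media_thickness=truth["media_thickness"],
            adventitia_thickness=truth["adventitia_thickness"],
        )
    return row


def _derive_table(
    subjects: pd.DataFrame, morph: pd.DataFrame, model: NomogramModel
) -> pd.DataFrame:
    rows = []
    merged = subjects.merge(morph, on="id", validate="one_to_one")
    for _, s in merged.iterrows():
        geom = WallGeometry(
            external_diameter=s["observed_diameter"],
            intima_thickness=s["intima_thickness"],
            media_thickness=s["media_thickness"],
            adventitia_thickness=s["adventitia_thickness"],
        )
        fractions = {
            c: s[f"{c}_fraction"]
            for c in ("elastin", "cytoplasm", "collagen", "gag")
        }
        dm = aortometry.derive_metrics(
            dict(s), geom, fractions, s["smc_density"], model
        )
        row = {
            "id": s["id"], "group": s["group"],
            "observed_diameter": s["observed_diameter"],
            "expected_diameter": dm.expected_diameter,
            "z_score": dm.z_score, "size_class": dm.size_class,
            "fold_dilatation": dm.fold_dilatation,
            "media_xsec_area": dm.media_xsec_area,
            "smc_per_xsec": dm.smc_per_xsec,
        }
        row.update({f"{c}_xsec": v for c, v in dm.component_xsec.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _group_comparison(
    subjects: pd.DataFrame, morph: pd.DataFrame, derived: pd.DataFrame
) -> pd.DataFrame:
    """Table-style two-group report: Mann–Whitney for continuous variables,
    Fisher/Freeman–Halton for categorical ones."""
    df = subjects.merge(morph, on="id").merge(
        derived.drop(columns=["group", "observed_diameter"]), on="id"
    )
    groups = [g for g in ("nondilated", "aneurysm") if (df["group"] == g).any()]
    rows = []
    numeric = [
        c for c in df.columns
        if c not in ("id", "group") and pd.api.types.is_numeric_dtype(df[c])
        and not pd.api.types.is_bool_dtype(df[c])
        and not c.startswith("score_rater")
        and c not in ("n_fields", "n_excluded")
    ]
    for col in numeric:
        samples = [df.loc[df["group"] == g, col].dropna().to_numpy() for g in groups]
        if len(groups) == 2 and all(s.size > 0 for s in samples):
            res = mann_whitney(samples[0], samples[1])
            p, method = res.p_value, res.method
        else:
            p, method = float("nan"), "NA"
        rows.append(
            {
                "variable": col, "kind": "continuous", "method": method,
                **{f"mean_{g}": float(np.mean(s)) for g, s in zip(groups, samples)},
                "p_value": p, "p_formatted": format_p(p),
            }
        )
    for col in [c for c in _CATEGORICAL if c in df.columns]:
        sub = df[[col, "group"]].dropna()
        tab = pd.crosstab(sub[col], sub["group"])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            p, method = float("nan"), "NA"  # a constant variable has no test
        else:
            res = fisher_exact_rxc(
                ContingencyTable.from_array(
                    tab.to_numpy(),
                    row_labels=[str(i) for i in tab.index],
                    col_labels=[str(c) for c in tab.columns],
                )
            )
            p, method = res.p_value, res.method
        rows.append(
            {"variable": col, "kind": "categorical", "method": method,
             "p_value": p, "p_formatted": format_p(p)}
        )
    return pd.DataFrame(rows)


def _remodeling_table(
    morph: pd.DataFrame, derived: pd.DataFrame
) -> pd.DataFrame:
    rows = []
    df = morph.merge(derived, on="id")
    for _, s in df.iterrows():
        if s["size_class"] != "aneurysm":
            continue
        geom = WallGeometry(
            external_diameter=s["observed_diameter"],
            intima_thickness=s["intima_thickness"],
            media_thickness=s["media_thickness"],
            adventitia_thickness=s["adventitia_thickness"],
        )
        lam = morphometry.LamellarMetrics(
            n_lamellae=s["n_lamellae"],
            lamella_thickness=s["lamella_thickness"],
            interlamellar_distance=s["interlamellar_distance"],
        )
        pred = remodeling.predict_preaneurysmal(geom, lam, s["expected_diameter"])
        rows.append(
            {
                "id": s["id"],
                "observed_media_thickness": s["media_thickness"],
                "predicted_media_thickness": pred.predicted_media_thickness,
                "observed_lamella_thickness": s["lamella_thickness"],
                "predicted_lamella_thickness": pred.predicted_lamella_thickness,
                "observed_interlamellar_distance": s["interlamellar_distance"],
                "predicted_interlamellar_distance": (
                    pred.predicted_interlamellar_distance
                ),
                "scaling_factor": pred.scaling_factor,
                "fold_dilatation": s["fold_dilatation"],
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute the full synthetic study and return its report.

    Stages run in dependency order; any failure aborts with a stage tag.
    Rerunning with the same config regenerates the report bit-identically.
    """
    config.validate()
    model = _nomogram(config)

    stage = "synth"
    try:
        if config.subjects_csv is not None:
            subjects = pd.read_csv(config.subjects_csv)
            truth = None
        else:
            subjects, truth = synth.generate_cohort(_cohort_spec(config))

        stage = "measure"
        if config.morph_csv is not None:
            morph = pd.read_csv(config.morph_csv)
        else:
            if truth is None:
                raise ValueError(
                    "external subjects require a morph_csv (no truth to render)"
                )
            blinded = truth.drop(columns=["group", "expected_diameter",
                                          "diameter_zscore"])
            rows = []
            for idx, (_, t) in enumerate(blinded.iterrows()):
                row = _measure_subject(dict(t), config, idx)
                row["id"] = t["id"]
                rows.append(row)
            morph = pd.DataFrame(rows)

        stage = "derive"
        derived = _derive_table(subjects, morph, model)

        stage = "stats"
        comparison = _group_comparison(subjects, morph, derived)
        quant = morph.merge(
            derived[["id", "media_xsec_area", "smc_per_xsec", "elastin_xsec",
                     "z_score", "observed_diameter"]],
            on="id",
        ).drop(columns=["id", "n_fields", "n_excluded"])
        corr = correlation_matrix(quant)
        corr_df = corr.to_frame().reset_index(names="variable")
        score_cols = [c for c in subjects.columns if c.startswith("score_rater")]
        irr = (
            interrater_agreement(subjects[score_cols])
            if len(score_cols) >= 2 else pd.DataFrame()
        )

        stage = "remodel"
        remodel_df = _remodeling_table(morph, derived)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = StudyReport(
        tables={
            "subjects": subjects,
            "morphometry": morph,
            "derived": derived,
            "group_comparison": comparison,
            "correlation_matrix": corr_df,
            "interrater": irr,
            "remodeling": remodel_df,
        },
        provenance={
            "version": __version__,
            "seed": config.seed,
            "config_hash": config_hash(config),
            "config": config.to_dict(),
        },
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report
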