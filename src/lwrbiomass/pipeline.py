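"""Study orchestration: paired points, dataset variants, concordance reports.

The full analysis mirrors a habitat-stratified validation design: survey
records are joined with species profiles and pooled LWR coefficients to
form (estimated, measured) weight pairs; the pairs are stratified into
three habitat scopes (freshwater-only, seawater/mudflat-only, and their
union "whole"); each scope is evaluated raw and after the Q > 6 outlier
filter, giving six dataset variants. Every variant is scored four ways:
OLS R-squared and identity-line R-squared, each before and after removing
Cook's-distance influential points (influential points are re-identified
per variant, since Cook's distances depend on the point set).

``run_full_analysis`` is a pure function of (input tables, config): it
writes ``reports.csv`` (+ ``reports.json``), a per-point ``audit_points.csv``
(Q score, Cook's distance, kept flags) and a ``manifest.json`` carrying the
config hash, thresholds and drop counts — with no timestamps, so reruns
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import diagnostics, estimation, synthetic
from .data_io import (
    GROUP_ONLY_FRESHWATER,
    GROUP_ONLY_SEAWATER_MUD,
    FieldSurveyRecord,
    LWRCoefficientRecord,
    PairedBiomassPoint,
    ReadResult,
    SpeciesProfile,
    classify_habitat_groups,
    read_coefficient_table,
    read_field_survey_table,
    read_species_profile_table,
    write_report,
)

logger = logging.getLogger(__name__)

SCOPE_WHOLE = "whole"
SCOPES = (GROUP_ONLY_FRESHWATER, GROUP_ONLY_SEAWATER_MUD, SCOPE_WHOLE)


@dataclass(frozen=True)
class DatasetVariant:
    """One of the six analysis datasets: a habitat scope, raw or Q-filtered."""

    habitat_scope: str
    q_filtered: bool
    points: tuple[PairedBiomassPoint, ...]

    @property
    def label(self) -> str:
        return f"{self.habitat_scope}|{'q_filtered' if self.q_filtered else 'raw'}"


@dataclass(frozen=True)
class ConcordanceReport:
    """All agreement statistics for one dataset variant.

    ``slope``/``intercept``/``r2_regression``/``r2_identity`` describe the
    full point set; the ``*_post`` fields describe the set after removing
    Cook's-distance influential points. ``rmse``/``mae`` are reported for
    the identity model (estimate as-is) and the fitted regression.
    """

    dataset_label: str
    habitat_scope: str
    q_filtered: bool
    n_points: int
    n_removed_q: int
    n_removed_influential: int
    slope: float
    intercept: float
    r2_regression: float
    r2_identity: float
    slope_post: float
    intercept_post: float
    r2_regression_post: float
    r2_identity_post: float
    rmse_identity: float
    mae_identity: float
    rmse_regression: float
    mae_regression: float
    degenerate: bool


@dataclass
class RunConfig:
    """Everything a full run depends on.

    Either the three input table paths (with optional column-map dialects)
    or a named simulation scenario; plus thresholds and the seed feeding
    any synthetic randomness.
    """

    survey_path: str | None = None
    coefficients_path: str | None = None
    profiles_path: str | None = None
    dialects: dict = field(default_factory=dict)
    scenario: str | None = None
    n_species: int = 40
    seed: int = 0
    q_threshold: float = diagnostics.Q_THRESHOLD_DEFAULT
    cooks_cutoff: float | str = "4/n"
    min_range_sample_n: int = estimation.MIN_RANGE_SAMPLE_N
    out_dir: str = "results/run"

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["cooks_cutoff"], tuple):
            d["cooks_cutoff"] = list(d["cooks_cutoff"])
        return d


# ---------------------------------------------------------------------------
# pairing


def build_paired_points(
    survey: Iterable[FieldSurveyRecord],
    coefficients: Iterable[LWRCoefficientRecord],
    profiles: Sequence[SpeciesProfile],
    min_range_sample_n: int = estimation.MIN_RANGE_SAMPLE_N,
) -> tuple[list[PairedBiomassPoint], Counter]:
    """Join the three tables into (estimated, measured) pairs.

    One point per usable survey record: measured weight from the record's
    densities (or its direct individual biomass), estimated weight from the
    species' pooled coefficients at its GTL. Records whose species lacks a
    profile, an eligible GTL, or any coefficient record — or whose measured
    weight is non-positive — are dropped and tallied by cause.

    Returns the points and a Counter of drop reasons. Raises if the join
    is empty.
    """
    profile_by_key = {p.key: p for p in profiles}
    groups = classify_habitat_groups(profiles)
    pooled = estimation.pool_coefficients(coefficients)

    gtl_by_key: dict[str, float] = {}
    for key, prof in profile_by_key.items():
        try:
            gtl_by_key[key] = estimation.compute_gtl(prof, min_range_sample_n)
        except ValueError as exc:
            logger.info("species dropped (no eligible GTL): %s", exc)

    points: list[PairedBiomassPoint] = []
    drops: Counter = Counter()
    for rec in survey:
        key = rec.key
        if key not in profile_by_key:
            drops["missing_profile"] += 1
            logger.info("%s/%s dropped: no species profile", rec.species_name, rec.period)
            continue
        if key not in pooled:
            drops["missing_coefficients"] += 1
            logger.info("%s/%s dropped: no LWR coefficients", rec.species_name, rec.period)
            continue
        if key not in gtl_by_key:
            drops["no_eligible_gtl"] += 1
            continue
        measured = (
            rec.individual_biomass_g
            if rec.individual_biomass_g is not None
            else estimation.individual_biomass(rec.biomass_density, rec.number_density)
        )
        if not (measured > 0 and math.isfinite(measured)):
            drops["nonpositive_measured"] += 1
            logger.info(
                "%s/%s dropped: measured biomass %s not positive",
                rec.species_name,
                rec.period,
                measured,
            )
            continue
        estimated = estimation.estimate_weight(pooled[key], gtl_by_key[key])
        points.append(
            PairedBiomassPoint(
                species_name=rec.species_name,
                habitat_group=groups[key],
                measured_g=measured,
                estimated_g=estimated,
                period=rec.period,
            )
        )
    if not points:
        raise ValueError(f"empty join: no usable points (drops: {dict(drops)})")
    return points, drops


def build_variants(
    points: Sequence[PairedBiomassPoint],
    q_threshold: float = diagnostics.Q_THRESHOLD_DEFAULT,
) -> tuple[list[DatasetVariant], pd.DataFrame]:
    """Build the six dataset variants and a per-point Q audit table.

    The whole-species scope is the union of the two habitat scopes (mixed
    and unrecorded species never enter any variant). Q scores for each
    scope's filtered variant are computed on that scope's own raw points.
    """
    by_scope: dict[str, list[PairedBiomassPoint]] = {s: [] for s in SCOPES}
    for pt in points:
        if pt.habitat_group in (GROUP_ONLY_FRESHWATER, GROUP_ONLY_SEAWATER_MUD):
            by_scope[pt.habitat_group].append(pt)
            by_scope[SCOPE_WHOLE].append(pt)

    variants: list[DatasetVariant] = []
    audit_rows = []
    for scope in SCOPES:
        pts = by_scope[scope]
        variants.append(DatasetVariant(scope, False, tuple(pts)))
        if pts:
            qres = diagnostics.filter_q(
                [p.measured_g for p in pts], [p.estimated_g for p in pts], q_threshold
            )
            kept = tuple(p for p, k in zip(pts, qres.keep_mask) if k)
            for p, q, k in zip(pts, qres.q, qres.keep_mask):
                audit_rows.append(
                    {
                        "habitat_scope": scope,
                        "species": p.species_name,
                        "period": p.period,
                        "measured_g": p.measured_g,
                        "estimated_g": p.estimated_g,
                        "q_score": q,
                        "q_kept": bool(k),
                    }
                )
        else:
            kept = ()
        variants.append(DatasetVariant(scope, True, kept))
    return variants, pd.DataFrame(audit_rows)


# ---------------------------------------------------------------------------
# evaluation

_NAN_REPORT_FIELDS = dict(
    slope=math.nan,
    intercept=math.nan,
    r2_regression=math.nan,
    r2_identity=math.nan,
    slope_post=math.nan,
    intercept_post=math.nan,
    r2_regression_post=math.nan,
    r2_identity_post=math.nan,
    rmse_identity=math.nan,
    mae_identity=math.nan,
    rmse_regression=math.nan,
    mae_regression=math.nan,
)


def evaluate_variant(
    variant: DatasetVariant,
    n_removed_q: int = 0,
    cooks_cutoff: float | str = "4/n",
) -> tuple[ConcordanceReport, pd.DataFrame]:
    """Score one dataset variant.

    Computes the regression and identity-line R-squared on all points, then
    re-identifies Cook's-distance influential points within this variant,
    removes them (single pass) and recomputes both R-squared values and the
    refit line. Variants with fewer than 4 points, or otherwise degenerate
    geometry (constant estimates, zero variance in measured weights), yield
    a report flagged ``degenerate`` with NaN statistics instead of raising.

    Returns the report plus a per-point frame of Cook's distances and
    influential flags.
    """
    pts = variant.points
    n = len(pts)
    base = dict(
        dataset_label=variant.label,
        habitat_scope=variant.habitat_scope,
        q_filtered=variant.q_filtered,
        n_points=n,
        n_removed_q=n_removed_q,
        n_removed_influential=0,
        degenerate=True,
        **_NAN_REPORT_FIELDS,
    )
    empty_audit = pd.DataFrame(
        columns=["species", "period", "cooks_d", "influential"]
    )
    if n < 4:
        return ConcordanceReport(**base), empty_audit

    x = np.array([p.estimated_g for p in pts])
    y = np.array([p.measured_g for p in pts])
    try:
        fit = diagnostics.ols_fit(x, y)
        r2_id = diagnostics.yx_r2(y, x)
        cooks = diagnostics.cooks_distance(x, y, cooks_cutoff)
    except ValueError as exc:
        logger.warning("%s degenerate: %s", variant.label, exc)
        return ConcordanceReport(**base), empty_audit

    keep = ~cooks.influential_mask
    base.update(
        degenerate=False,
        n_removed_influential=int(cooks.influential_mask.sum()),
        slope=fit.slope,
        intercept=fit.intercept,
        r2_regression=fit.r2,
        r2_identity=r2_id,
        rmse_identity=diagnostics.rmse(y, x),
        mae_identity=diagnostics.mae(y, x),
        rmse_regression=diagnostics.rmse(y, fit.fitted),
        mae_regression=diagnostics.mae(y, fit.fitted),
    )
    if keep.sum() >= 4:
        try:
            fit_post = diagnostics.ols_fit(x[keep], y[keep])
            base.update(
                slope_post=fit_post.slope,
                intercept_post=fit_post.intercept,
                r2_regression_post=fit_post.r2,
                r2_identity_post=diagnostics.yx_r2(y[keep], x[keep]),
            )
        except ValueError as exc:
            logger.warning("%s post-removal degenerate: %s", variant.label, exc)
            base["degenerate"] = True
    else:
        base["degenerate"] = True

    audit = pd.DataFrame(
        {
            "species": [p.species_name for p in pts],
            "period": [p.period for p in pts],
            "cooks_d": cooks.d,
            "influential": cooks.influential_mask,
        }
    )
    return ConcordanceReport(**base), audit


# ---------------------------------------------------------------------------
# full run


def _load_inputs(
    config: RunConfig,
) -> tuple[list[FieldSurveyRecord], list[LWRCoefficientRecord], list[SpeciesProfile], dict]:
    if config.scenario is not None:
        scenarios = synthetic.generate_benchmark_scenarios(
            seed=config.seed, n_species=config.n_species
        )
        if config.scenario not in scenarios:
            raise ValueError(
                f"unknown scenario {config.scenario!r}; choose from {sorted(scenarios)}"
            )
        survey, coeffs, profiles, _truth = synthetic.simulate_community(
            scenarios[config.scenario]
        )
        ingest = {"source": f"scenario:{config.scenario}", "rejected_rows": 0}
        return survey, coeffs, profiles, ingest

    if not (config.survey_path and config.coefficients_path and config.profiles_path):
        raise ValueError("need either a scenario or all three input table paths")
    d = config.dialects
    survey_r: ReadResult = read_field_survey_table(config.survey_path, d.get("survey"))
    coeff_r: ReadResult = read_coefficient_table(config.coefficients_path, d.get("coefficients"))
    prof_r: ReadResult = read_species_profile_table(config.profiles_path, d.get("profiles"))
    ingest = {
        "source": "files",
        "rejected_rows": len(survey_r.rejected) + len(coeff_r.rejected) + len(prof_r.rejected),
        "survey_rows": survey_r.n_input,
        "survey_rejected": survey_r.rejected,
        "coefficient_rejected": coeff_r.rejected,
        "profile_rejected": prof_r.rejected,
    }
    return survey_r.records, coeff_r.records, prof_r.records, ingest


def run_full_analysis(config: RunConfig) -> tuple[list[ConcordanceReport], Path]:
    """Execute the whole study and write reports, audit table and manifest.

    Deterministic given (inputs, config): the manifest carries a SHA-256
    hash of the config and all drop counts, and no timestamps, so two runs
    with the same config and seed produce byte-identical outputs.
    """
    survey, coeffs, profiles, ingest = _load_inputs(config)
    points, drops = build_paired_points(
        survey, coeffs, profiles, config.min_range_sample_n
    )
    variants, q_audit = build_variants(points, config.q_threshold)

    raw_counts = {v.habitat_scope: len(v.points) for v in variants if not v.q_filtered}
    reports: list[ConcordanceReport] = []
    cook_audits = []
    for v in variants:
        n_removed_q = raw_counts[v.habitat_scope] - len(v.points) if v.q_filtered else 0
        rep, cook_audit = evaluate_variant(v, n_removed_q, config.cooks_cutoff)
        reports.append(rep)
        cook_audit = cook_audit.assign(dataset_label=v.label)
        cook_audits.append(cook_audit)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_report(reports, out_dir / "reports.csv")

    # Q scores are per scope, Cook's distances per variant; keeping the two
    # audits in separate tables avoids row duplication in a merged view.
    cook_df = pd.concat(cook_audits, ignore_index=True) if cook_audits else pd.DataFrame()
    q_audit.to_csv(out_dir / "audit_points.csv", index=False)
    if not cook_df.empty:
        cook_df.to_csv(out_dir / "audit_influential.csv", index=False)

    manifest = {
        "config": config.to_jsonable(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_jsonable(), sort_keys=True).encode()
        ).hexdigest(),
        "ingest": {k: v for k, v in ingest.items() if not k.endswith("_rejected")},
        "drop_counts": dict(sorted(drops.items())),
        "n_points_by_variant": {r.dataset_label: r.n_points for r in reports},
        "q_removed_by_scope": {
            r.habitat_scope: r.n_removed_q for r in reports if r.q_filtered
        },
        "influential_removed_by_variant": {
            r.dataset_label: r.n_removed_influential for r in reports
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return reports, out_dir


def reports_by_label(reports: Iterable[ConcordanceReport]) -> Mapping[str, ConcordanceReport]:
    return {r.dataset_label: r for r in reports}
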