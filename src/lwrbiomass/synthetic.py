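"""Synthetic fish-community generator.

Emulates the statistical structure the estimation pipeline assumes: a pool
of species with true allometric parameters (W = a L^b), a representative
length (GTL) per species, habitat-dependent dispersion of individual
lengths about that GTL, several noisy published coefficient reports per
species, and monthly survey aggregation into (number density, biomass
density) pairs from which the pipeline's individual-biomass step recovers
the realized mean mass exactly.

Two failure modes of literature-based estimation are built in:

* seawater-like populations get a wider length distribution and a reported
  GTL that can overstate the sampled population's typical length (a
  multiplicative offset), so a single representative length is a poor
  stand-in for the realized mean mass;
* juvenile contamination: with probability ``juvenile_fraction`` a
  species-month record is a recruitment pulse in which individuals are
  juveniles at ``juvenile_length_ratio`` times the adult length draw,
  producing the heavy low-measured-mass outlier points that the Q filter
  targets. Contamination acts at the record level because monthly
  averaging would dilute individual-level mixing into a near-constant
  bias with no outliers.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` children, so every table is reproducible
from the config alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    GROUP_MIXED,
    GROUP_NO_RECORD,
    GROUP_ONLY_FRESHWATER,
    GROUP_ONLY_SEAWATER_MUD,
    FieldSurveyRecord,
    LWRCoefficientRecord,
    SpeciesProfile,
)

MONTHS = [f"{m:02d}" for m in range(1, 13)]


@dataclass(frozen=True)
class CommunitySimConfig:
    """Generative parameters for one synthetic survey.

    Defaults describe a mixed Korean-style community at roughly the scale
    of a multi-source literature compilation: a few dozen species followed
    monthly for a year (~500 records), allometric exponents near isometry
    (b ~ N(3.0, 0.15)), scale coefficients lognormal around 0.01 g cm^-3,
    species lengths spanning ~5-40 cm. Freshwater populations are tightly
    distributed about their GTL (log-sd 0.1); seawater populations are
    wider (log-sd 0.5) with reported GTL overstating the sampled median by
    ~30%. A tenth of species-month records are juvenile pulses.
    """

    n_species: int = 40
    seed: int = 0
    # true parameter distributions
    a_median: float = 0.01  # g cm^-b, lognormal median
    a_log_sd: float = 0.4
    b_mean: float = 3.0
    b_sd: float = 0.15
    gtl_min_cm: float = 5.0  # log-uniform range for species GTL
    gtl_max_cm: float = 40.0
    # habitat composition (freshwater, seawater/mud, mixed, unrecorded)
    habitat_fractions: tuple[float, float, float, float] = (0.40, 0.40, 0.16, 0.04)
    # per-habitat log-sd of individual length about the population GTL
    length_dispersion_freshwater: float = 0.1
    length_dispersion_seawater: float = 0.5
    # reported GTL = population GTL * this factor, for seawater-type species
    gtl_offset_seawater: float = 1.3
    # juvenile recruitment pulses
    juvenile_fraction: float = 0.1
    juvenile_length_ratio: float = 0.3
    # published coefficient reports
    coeff_reports_per_species: int = 3
    coeff_a_noise_log_sd: float = 0.15
    coeff_b_noise_sd: float = 0.05
    # survey aggregation
    months: int = 12
    individuals_per_record: int = 30
    area_m2: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0.0 <= self.juvenile_fraction <= 1.0:
            raise ValueError("juvenile_fraction must be in [0, 1]")
        if not 0.0 < self.juvenile_length_ratio < 1.0:
            raise ValueError("juvenile_length_ratio must be in (0, 1)")
        for name in (
            "a_median",
            "gtl_min_cm",
            "gtl_max_cm",
            "area_m2",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.habitat_fractions) - 1.0) > 1e-9:
            raise ValueError("habitat_fractions must sum to 1")


@dataclass
class SimulatedTruth:
    """Ground truth behind one synthetic community.

    ``species`` has one row per species (true a, b, population GTL,
    reported GTL, habitat group, length dispersion); ``survey`` is filled
    by :func:`simulate_survey` with one row per species-month record
    (realized mean individual mass, juvenile-pulse flag).
    """

    species: pd.DataFrame
    survey: pd.DataFrame = field(default_factory=pd.DataFrame)


def _habitat_assignment(i: int, n: int, fractions) -> tuple[frozenset[str], bool, str]:
    """Deterministic round-robin-by-quota habitat assignment."""
    bounds = np.cumsum(np.asarray(fractions) * n).round().astype(int)
    if i < bounds[0]:
        return frozenset({"freshwater"}), False, GROUP_ONLY_FRESHWATER
    if i < bounds[1]:
        habitats = frozenset({"seawater"}) if i % 2 else frozenset({"seawater", "mudflat"})
        return habitats, False, GROUP_ONLY_SEAWATER_MUD
    if i < bounds[2]:
        return frozenset({"freshwater", "estuary"}), False, GROUP_MIXED
    return frozenset(), True, GROUP_NO_RECORD


def simulate_species_pool(
    config: CommunitySimConfig,
) -> tuple[list[SpeciesProfile], SimulatedTruth]:
    """Draw the species pool: true allometry, GTL, habitats, profiles.

    Species profiles alternate between an explicit stated-average GTL and a
    min-max range whose midpoint equals the reported GTL, exercising both
    representative-length sources downstream.
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=(0,))
    rng = np.random.default_rng(ss)
    n = config.n_species
    true_a = config.a_median * np.exp(rng.normal(0.0, config.a_log_sd, size=n))
    true_b = rng.normal(config.b_mean, config.b_sd, size=n)
    log_lo, log_hi = np.log(config.gtl_min_cm), np.log(config.gtl_max_cm)
    gtl_pop = np.exp(rng.uniform(log_lo, log_hi, size=n))

    profiles: list[SpeciesProfile] = []
    rows = []
    for i in range(n):
        name = f"species_{i:03d}"
        habitats, unrecorded, group = _habitat_assignment(i, n, config.habitat_fractions)
        seawaterish = group == GROUP_ONLY_SEAWATER_MUD
        dispersion = (
            config.length_dispersion_seawater
            if seawaterish
            else config.length_dispersion_freshwater
        )
        gtl_reported = gtl_pop[i] * (config.gtl_offset_seawater if seawaterish else 1.0)
        if i % 2 == 0:
            profile = SpeciesProfile(
                species_name=name,
                habitats=habitats,
                unrecorded=unrecorded,
                gtl_cm=gtl_reported,
                gtl_source="field-guide",
            )
        else:
            half_width = 0.4 * gtl_reported
            profile = SpeciesProfile(
                species_name=name,
                habitats=habitats,
                unrecorded=unrecorded,
                length_min_cm=gtl_reported - half_width,
                length_max_cm=gtl_reported + half_width,
                sample_n=50,
                gtl_source="meta-database",
            )
        profiles.append(profile)
        rows.append(
            {
                "species": name,
                "habitat_group": group,
                "true_a": true_a[i],
                "true_b": true_b[i],
                "gtl_pop_cm": gtl_pop[i],
                "gtl_reported_cm": gtl_reported,
                "length_dispersion": dispersion,
            }
        )
    return profiles, SimulatedTruth(species=pd.DataFrame(rows))


def simulate_coefficient_reports(
    truth: SimulatedTruth, config: CommunitySimConfig
) -> list[LWRCoefficientRecord]:
    """Emulate k literature LWR studies per species.

    Multiplicative lognormal noise on ``a`` and additive normal noise on
    ``b``; with both noise scales zero the geometric/arithmetic-mean
    pooling recovers the true coefficients exactly.
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=(1,))
    rng = np.random.default_rng(ss)
    records: list[LWRCoefficientRecord] = []
    k = config.coeff_reports_per_species
    for row in truth.species.itertuples():
        for j in range(k):
            a = row.true_a * np.exp(rng.normal(0.0, config.coeff_a_noise_log_sd))
            b = row.true_b + rng.normal(0.0, config.coeff_b_noise_sd)
            records.append(
                LWRCoefficientRecord(
                    species_name=row.species, a=float(a), b=float(b), source_id=f"sim_{j}"
                )
            )
    return records


def simulate_survey(
    truth: SimulatedTruth, config: CommunitySimConfig
) -> list[FieldSurveyRecord]:
    """Generate monthly survey records per species.

    Each species-month draws ``individuals_per_record`` adult lengths
    lognormal about the population GTL; a juvenile-pulse month (probability
    ``juvenile_fraction``) scales every length by ``juvenile_length_ratio``.
    Individual masses follow the true allometry, then aggregate to number
    density and biomass density over ``area_m2`` — so biomass density
    equals number density times realized mean mass by construction.

    Fills ``truth.survey`` with the realized per-record ground truth.
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=(2,))
    rng = np.random.default_rng(ss)
    records: list[FieldSurveyRecord] = []
    survey_rows = []
    n_ind = config.individuals_per_record
    for row in truth.species.itertuples():
        for m in range(config.months):
            period = MONTHS[m % 12]
            pulse = rng.random() < config.juvenile_fraction
            lengths = row.gtl_pop_cm * np.exp(
                rng.normal(0.0, row.length_dispersion, size=n_ind)
            )
            if pulse:
                lengths = lengths * config.juvenile_length_ratio
            masses = row.true_a * lengths**row.true_b
            mean_mass = float(masses.mean())
            number_density = n_ind / config.area_m2
            biomass_density = float(masses.sum()) / config.area_m2
            records.append(
                FieldSurveyRecord(
                    species_name=row.species,
                    period=period,
                    biomass_density=biomass_density,
                    number_density=number_density,
                )
            )
            survey_rows.append(
                {
                    "species": row.species,
                    "period": period,
                    "juvenile_pulse": pulse,
                    "mean_mass_g": mean_mass,
                }
            )
    truth.survey = pd.DataFrame(survey_rows)
    return records


def simulate_community(
    config: CommunitySimConfig,
) -> tuple[list[FieldSurveyRecord], list[LWRCoefficientRecord], list[SpeciesProfile], SimulatedTruth]:
    """Full generator: (survey, coefficients, profiles, truth)."""
    profiles, truth = simulate_species_pool(config)
    coeffs = simulate_coefficient_reports(truth, config)
    survey = simulate_survey(truth, config)
    return survey, coeffs, profiles, truth


def generate_benchmark_scenarios(
    seed: int = 0, n_species: int = 40
) -> dict[str, CommunitySimConfig]:
    """Named scenario configs encoding the study's qualitative contrasts.

    * ``noiseless`` — zero dispersion, zero coefficient noise, no juveniles,
      no GTL offset: the pipeline must reproduce true weights exactly.
    * ``freshwater_like`` — tight length dispersion, little juvenile
      contamination, faithful GTL: the regime where a single representative
      length works.
    * ``seawater_like`` — wide dispersion and an overstated reported GTL
      for every species: the regime where it fails.
    * ``contaminated`` — freshwater-like conditions plus a ~25% juvenile
      recruitment-pulse rate: the regime the Q > 6 filter rescues.
    """
    base = CommunitySimConfig(n_species=n_species, seed=seed)
    return {
        "noiseless": replace(
            base,
            length_dispersion_freshwater=0.0,
            length_dispersion_seawater=0.0,
            gtl_offset_seawater=1.0,
            juvenile_fraction=0.0,
            coeff_a_noise_log_sd=0.0,
            coeff_b_noise_sd=0.0,
        ),
        "freshwater_like": replace(
            base,
            length_dispersion_freshwater=0.1,
            length_dispersion_seawater=0.1,
            gtl_offset_seawater=1.0,
            juvenile_fraction=0.02,
        ),
        "seawater_like": replace(
            base,
            length_dispersion_freshwater=0.5,
            length_dispersion_seawater=0.5,
            gtl_offset_seawater=1.5,
            juvenile_fraction=0.02,
        ),
        "contaminated": replace(
            base,
            length_dispersion_freshwater=0.1,
            length_dispersion_seawater=0.1,
            gtl_offset_seawater=1.0,
            juvenile_fraction=0.25,
        ),
    }


# ---------------------------------------------------------------------------
# table export (the exact dialects data_io reads by default)


def write_tables(
    out_dir: str | Path,
    survey: list[FieldSurveyRecord],
    coeffs: list[LWRCoefficientRecord],
    profiles: list[SpeciesProfile],
    truth: SimulatedTruth | None = None,
) -> dict[str, Path]:
    """Write survey/coefficient/profile tables (and truth) as CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    survey_df = pd.DataFrame(
        {
            "species": [r.species_name for r in survey],
            "period": [r.period for r in survey],
            "biomass_density_g_m2": [r.biomass_density for r in survey],
            "number_density_ind_m2": [r.number_density for r in survey],
            "individual_biomass_g": [r.individual_biomass_g for r in survey],
        }
    )
    paths["survey"] = out / "survey.csv"
    survey_df.to_csv(paths["survey"], index=False)

    coeff_df = pd.DataFrame(
        {
            "species": [r.species_name for r in coeffs],
            "a": [r.a for r in coeffs],
            "b": [r.b for r in coeffs],
            "source_id": [r.source_id for r in coeffs],
        }
    )
    paths["coefficients"] = out / "coefficients.csv"
    coeff_df.to_csv(paths["coefficients"], index=False)

    profile_df = pd.DataFrame(
        {
            "species": [p.species_name for p in profiles],
            "habitats": [
                ";".join(sorted(p.habitats)) if p.habitats else "unrecorded"
                for p in profiles
            ],
            "gtl_cm": [p.gtl_cm for p in profiles],
            "length_min_cm": [p.length_min_cm for p in profiles],
            "length_max_cm": [p.length_max_cm for p in profiles],
            "sample_n": [p.sample_n for p in profiles],
            "gtl_source": [p.gtl_source for p in profiles],
        }
    )
    paths["profiles"] = out / "species_profiles.csv"
    profile_df.to_csv(paths["profiles"], index=False)

    if truth is not None:
        paths["truth"] = out / "truth.csv"
        truth.species.to_csv(paths["truth"], index=False)
        if not truth.survey.empty:
            paths["truth_survey"] = out / "truth_survey.csv"
            truth.survey.to_csv(paths["truth_survey"], index=False)
    return paths
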