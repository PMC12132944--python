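"""Length-weight-relationship (LWR) biomass estimation core.

The allometric model is the field's standard form

    W = a * TL**b

with total length TL in cm and weight W in g (the convention of the
coefficient source databases). When several published (a, b) pairs exist
for a species, the representative coefficients pool them as the geometric
mean of ``a`` and the arithmetic mean of ``b``; the geometric mean is
computed in log space since typical ``a`` values sit around 1e-3 to 1e-2.

Field-side individual biomass is the surveyed biomass density divided by
the number density, computed separately for each species x month record.

The representative body length per species is the General Total Length
(GTL): an explicitly stated average when a source gives one, otherwise the
midpoint of a reported min-max range — but a range backed by fewer than 20
measurements is considered unreliable and ineligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_io import LWRCoefficientRecord, SpeciesProfile

#: minimum sample size for a min-max length range to be a usable GTL source
MIN_RANGE_SAMPLE_N = 20


@dataclass(frozen=True)
class RepresentativeCoefficients:
    """Pooled LWR coefficients for one species.

    ``a_rep`` is the geometric mean of the published scale coefficients
    (g cm^-b), ``b_rep`` the arithmetic mean of the allometric exponents.
    """

    species_name: str
    a_rep: float
    b_rep: float
    n_sources: int

    def __post_init__(self) -> None:
        if not (self.a_rep > 0 and math.isfinite(self.a_rep)):
            raise ValueError("a_rep must be positive and finite")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")


def individual_biomass(biomass_density: float, number_density: float) -> float:
    """Per-individual biomass (g) from density measurements.

    Parameters
    ----------
    biomass_density : float
        Surveyed biomass density in g/m2; must be >= 0.
    number_density : float
        Surveyed number density in ind/m2; must be > 0.
    """
    if not number_density > 0:
        raise ValueError(f"number_density must be > 0, got {number_density}")
    if biomass_density < 0:
        raise ValueError(f"biomass_density must be >= 0, got {biomass_density}")
    return biomass_density / number_density


def representative_a(a_values: Sequence[float]) -> float:
    """Geometric mean of published ``a`` coefficients, in log space."""
    a = np.asarray(a_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one a value")
    if np.any(a <= 0) or not np.all(np.isfinite(a)):
        raise ValueError("all a values must be positive and finite")
    return float(np.exp(np.mean(np.log(a))))


def representative_b(b_values: Sequence[float]) -> float:
    """Arithmetic mean of published ``b`` exponents."""
    b = np.asarray(b_values, dtype=float)
    if b.size == 0:
        raise ValueError("need at least one b value")
    if not np.all(np.isfinite(b)):
        raise ValueError("all b values must be finite")
    return float(np.mean(b))


def pool_coefficients(
    records: Iterable[LWRCoefficientRecord],
) -> dict[str, RepresentativeCoefficients]:
    """Group coefficient records by species and pool each group."""
    by_species: dict[str, list[LWRCoefficientRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.key, []).append(rec)
    out = {}
    for key, recs in by_species.items():
        out[key] = RepresentativeCoefficients(
            species_name=recs[0].species_name,
            a_rep=representative_a([r.a for r in recs]),
            b_rep=representative_b([r.b for r in recs]),
            n_sources=len(recs),
        )
    return out


def compute_gtl(profile: SpeciesProfile, min_sample_n: int = MIN_RANGE_SAMPLE_N) -> float:
    """Representative length (cm) for one species, or raise if none is eligible.

    Source precedence: an explicitly stated average (``gtl_cm``, typically
    from a field guide) wins over a min-max midpoint; a min-max range whose
    backing sample size is known and below ``min_sample_n`` is ineligible.

    Raises
    ------
    ValueError
        If the profile has no eligible length source; callers drop the
        species with a logged reason.
    """
    if profile.gtl_cm is not None:
        return profile.gtl_cm
    if profile.sample_n is not None and profile.sample_n < min_sample_n:
        raise ValueError(
            f"{profile.species_name}: length range backed by n={profile.sample_n} "
            f"< {min_sample_n}, no fallback source"
        )
    return (profile.length_min_cm + profile.length_max_cm) / 2.0


def estimate_weight(coeffs: RepresentativeCoefficients, gtl_cm: float) -> float:
    """Allometric weight estimate W = a_rep * GTL**b_rep in grams."""
    if not gtl_cm > 0:
        raise ValueError(f"gtl_cm must be > 0, got {gtl_cm}")
    return coeffs.a_rep * gtl_cm ** coeffs.b_rep
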