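import numpy as np
import pytest

from lwrbiomass.data_io import (
    FieldSurveyRecord,
    LWRCoefficientRecord,
    SpeciesProfile,
)


@pytest.fixture
def three_species_tables():
    """A tiny complete community: 3 species, 1 month, hand-checkable."""
    profiles = [
        SpeciesProfile("Carp", frozenset({"freshwater"}), gtl_cm=20.0,
                       gtl_source="field-guide"),
        SpeciesProfile("Goby", frozenset({"seawater", "mudflat"}),
                       length_min_cm=5.0, length_max_cm=15.0, sample_n=40),
        SpeciesProfile("Smelt", frozenset({"freshwater"}),
                       length_min_cm=8.0, length_max_cm=12.0, sample_n=25),
    ]
    coeffs = [
        LWRCoefficientRecord("Carp", a=0.01, b=3.0),
        LWRCoefficientRecord("Goby", a=0.01, b=3.0, source_id="s1"),
        LWRCoefficientRecord("Goby", a=0.04, b=3.2, source_id="s2"),
        LWRCoefficientRecord("Smelt", a=0.02, b=2.9),
    ]
    survey = [
        FieldSurveyRecord("Carp", "06", biomass_density=160.0, number_density=2.0),
        FieldSurveyRecord("Goby", "06", biomass_density=30.0, number_density=3.0),
        FieldSurveyRecord("Smelt", "06", individual_biomass_g=16.0),
    ]
    return survey, coeffs, profiles


@pytest.fixture
def rng():
    return np.random.default_rng(20250603)
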