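"""Domain types, habitat taxonomy, and table readers/writers.

Three tabular inputs drive the pipeline:

1. a field-survey table (species x month) carrying biomass density (g/m2)
   and number density (ind/m2), or a pre-computed individual biomass;
2. a table of published length-weight-relationship (LWR) coefficient pairs
   (a, b), possibly several rows per species;
3. a species table with habitat labels and either an explicit General Total
   Length (GTL) or a (min-length, max-length, n) range.

Column layouts differ between sources, so every reader takes a *dialect*: a
mapping from logical field names to physical column headers, loadable from a
YAML/JSON config. Rows violating invariants are rejected with a logged
reason and counted, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: the four habitat labels a species may carry
HABITAT_LABELS = frozenset({"freshwater", "seawater", "mudflat", "estuary"})

#: marker for species whose habitat is not recorded in any source
UNRECORDED = "unrecorded"

#: analysis groups derived from the habitat set
GROUP_ONLY_FRESHWATER = "only_freshwater"
GROUP_ONLY_SEAWATER_MUD = "only_seawater_mud"
GROUP_MIXED = "mixed"
GROUP_NO_RECORD = "no_record"


def normalize_species(name: str) -> str:
    """Canonical species key: trimmed, case-folded. No fuzzy matching."""
    return name.strip().casefold()


@dataclass(frozen=True)
class SpeciesProfile:
    """One species with its habitat labels and representative-length sources.

    ``habitats`` is a frozenset of labels from :data:`HABITAT_LABELS`, or
    empty with ``unrecorded=True``. Either an explicit ``gtl_cm`` (a stated
    average from a field guide) or a (``length_min_cm``, ``length_max_cm``)
    range backed by ``sample_n`` measurements must be present.
    """

    species_name: str
    habitats: frozenset[str] = frozenset()
    unrecorded: bool = False
    gtl_cm: float | None = None
    length_min_cm: float | None = None
    length_max_cm: float | None = None
    sample_n: int | None = None
    gtl_source: str = "meta-database"

    def __post_init__(self) -> None:
        if not self.species_name.strip():
            raise ValueError("species_name must be non-empty")
        bad = self.habitats - HABITAT_LABELS
        if bad:
            raise ValueError(f"unknown habitat labels: {sorted(bad)}")
        if not self.habitats and not self.unrecorded:
            raise ValueError("habitat set empty but not marked unrecorded")
        if self.gtl_cm is None:
            if self.length_min_cm is None or self.length_max_cm is None:
                raise ValueError(
                    f"{self.species_name}: need gtl_cm or a min/max length range"
                )
            if self.length_min_cm > self.length_max_cm:
                raise ValueError(f"{self.species_name}: min length > max length")
        for v in (self.gtl_cm, self.length_min_cm, self.length_max_cm):
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{self.species_name}: lengths must be positive")

    @property
    def key(self) -> str:
        return normalize_species(self.species_name)


@dataclass(frozen=True)
class LWRCoefficientRecord:
    """One published (a, b) coefficient pair for a species.

    ``a`` (g cm^-b) must be positive — the geometric-mean pooling requires
    it. ``b`` outside the plausible allometric range [2, 4] is warned about
    but kept: the literature does contain such fits.
    """

    species_name: str
    a: float
    b: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.species_name.strip():
            raise ValueError("species_name must be non-empty")
        if not (self.a > 0 and math.isfinite(self.a)):
            raise ValueError(f"{self.species_name}: a must be positive, got {self.a}")
        if not math.isfinite(self.b):
            raise ValueError(f"{self.species_name}: b must be finite")
        if not 2.0 <= self.b <= 4.0:
            logger.warning(
                "%s: allometric exponent b=%.3g outside [2, 4]", self.species_name, self.b
            )

    @property
    def key(self) -> str:
        return normalize_species(self.species_name)


@dataclass(frozen=True)
class FieldSurveyRecord:
    """One survey observation of a species in one month/period.

    Carries either a direct per-individual biomass, or the density pair
    (biomass density / number density) from which it is derived.
    """

    species_name: str
    period: str
    biomass_density: float | None = None
    number_density: float | None = None
    individual_biomass_g: float | None = None

    def __post_init__(self) -> None:
        if not self.species_name.strip():
            raise ValueError("species_name must be non-empty")
        if self.individual_biomass_g is None:
            if self.biomass_density is None or self.number_density is None:
                raise ValueError(
                    f"{self.species_name}/{self.period}: need individual biomass "
                    "or both densities"
                )
            if not self.number_density > 0:
                raise ValueError(
                    f"{self.species_name}/{self.period}: number density must be > 0"
                )
            if self.biomass_density < 0:
                raise ValueError(
                    f"{self.species_name}/{self.period}: biomass density must be >= 0"
                )

    @property
    def key(self) -> str:
        return normalize_species(self.species_name)


@dataclass(frozen=True)
class PairedBiomassPoint:
    """One (estimated, measured) weight pair — the unit of all regressions.

    ``measured_g`` is the field individual biomass (the regression y);
    ``estimated_g`` the LWR-based estimate (the x axis of the scatter, and
    the y-hat of the identity-line R-squared).
    """

    species_name: str
    habitat_group: str
    measured_g: float
    estimated_g: float
    period: str = ""

    def __post_init__(self) -> None:
        for label, v in (("measured_g", self.measured_g), ("estimated_g", self.estimated_g)):
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{self.species_name}: {label} must be positive/finite")


@dataclass
class ReadResult:
    """Records that passed validation plus an audit of rejected rows."""

    records: list
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.records) + len(self.rejected)


# ---------------------------------------------------------------------------
# dialects

DEFAULT_SURVEY_DIALECT: dict[str, str] = {
    "species_name": "species",
    "period": "period",
    "biomass_density": "biomass_density_g_m2",
    "number_density": "number_density_ind_m2",
    "individual_biomass_g": "individual_biomass_g",
}

DEFAULT_COEFF_DIALECT: dict[str, str] = {
    "species_name": "species",
    "a": "a",
    "b": "b",
    "source_id": "source_id",
}

DEFAULT_PROFILE_DIALECT: dict[str, str] = {
    "species_name": "species",
    "habitats": "habitats",
    "gtl_cm": "gtl_cm",
    "length_min_cm": "length_min_cm",
    "length_max_cm": "length_max_cm",
    "sample_n": "sample_n",
    "gtl_source": "gtl_source",
}


def load_dialect(path: str | Path) -> dict[str, dict[str, str]]:
    """Load a column-map config (YAML or JSON): table name -> field -> header."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


def _read_table(path: str | Path, sheet: str | int | None = None) -> pd.DataFrame:
    """Read a delimited-text or spreadsheet table into a DataFrame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        return pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
    sep = "\t" if suffix in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def _opt_float(row: Mapping, col: str | None) -> float | None:
    if col is None or col not in row:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _check_columns(df: pd.DataFrame, dialect: Mapping[str, str], mandatory: Sequence[str]) -> None:
    missing = [dialect[f] for f in mandatory if dialect.get(f) not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")


def read_field_survey_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sheet: str | int | None = None,
) -> ReadResult:
    """Read and validate a field-survey table.

    Returns a :class:`ReadResult`; each invalid row is recorded as
    ``(row_index, reason)`` and logged, so accepted + rejected always sum to
    the input row count.
    """
    d = dict(DEFAULT_SURVEY_DIALECT, **(dialect or {}))
    df = _read_table(path, sheet)
    _check_columns(df, d, ["species_name", "period"])
    out = ReadResult(records=[])
    for idx, row in df.iterrows():
        try:
            rec = FieldSurveyRecord(
                species_name=str(row[d["species_name"]]),
                period=str(row[d["period"]]),
                biomass_density=_opt_float(row, d.get("biomass_density")),
                number_density=_opt_float(row, d.get("number_density")),
                individual_biomass_g=_opt_float(row, d.get("individual_biomass_g")),
            )
        except (ValueError, TypeError) as exc:
            logger.warning("survey row %s rejected: %s", idx, exc)
            out.rejected.append((int(idx), str(exc)))
            continue
        out.records.append(rec)
    return out


def read_coefficient_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sheet: str | int | None = None,
) -> ReadResult:
    """Read and validate a published-LWR-coefficient table."""
    d = dict(DEFAULT_COEFF_DIALECT, **(dialect or {}))
    df = _read_table(path, sheet)
    _check_columns(df, d, ["species_name", "a", "b"])
    out = ReadResult(records=[])
    for idx, row in df.iterrows():
        try:
            rec = LWRCoefficientRecord(
                species_name=str(row[d["species_name"]]),
                a=float(row[d["a"]]),
                b=float(row[d["b"]]),
                source_id=str(row.get(d.get("source_id"), "") or ""),
            )
        except (ValueError, TypeError) as exc:
            logger.warning("coefficient row %s rejected: %s", idx, exc)
            out.rejected.append((int(idx), str(exc)))
            continue
        out.records.append(rec)
    return out


def _parse_habitats(raw: object) -> tuple[frozenset[str], bool]:
    """Parse a habitat cell: labels separated by ``;``/``,``/``|``, or 'unrecorded'."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return frozenset(), True
    text = str(raw).strip().casefold()
    if not text or text == UNRECORDED:
        return frozenset(), True
    for sep in (";", "|"):
        text = text.replace(sep, ",")
    labels = frozenset(t.strip() for t in text.split(",") if t.strip())
    return labels, False


def read_species_profile_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sheet: str | int | None = None,
) -> ReadResult:
    """Read and validate a species-profile (habitat + length) table."""
    d = dict(DEFAULT_PROFILE_DIALECT, **(dialect or {}))
    df = _read_table(path, sheet)
    _check_columns(df, d, ["species_name"])
    out = ReadResult(records=[])
    for idx, row in df.iterrows():
        try:
            habitats, unrec = _parse_habitats(row.get(d.get("habitats")))
            sample_n = _opt_float(row, d.get("sample_n"))
            rec = SpeciesProfile(
                species_name=str(row[d["species_name"]]),
                habitats=habitats,
                unrecorded=unrec,
                gtl_cm=_opt_float(row, d.get("gtl_cm")),
                length_min_cm=_opt_float(row, d.get("length_min_cm")),
                length_max_cm=_opt_float(row, d.get("length_max_cm")),
                sample_n=int(sample_n) if sample_n is not None else None,
                gtl_source=str(row.get(d.get("gtl_source"), "") or "meta-database"),
            )
        except (ValueError, TypeError) as exc:
            logger.warning("profile row %s rejected: %s", idx, exc)
            out.rejected.append((int(idx), str(exc)))
            continue
        out.records.append(rec)
    return out


# ---------------------------------------------------------------------------
# habitat grouping


def classify_habitat_group(profile: SpeciesProfile) -> str:
    """Assign one species to its analysis group.

    Rules (the four groups partition any valid input):

    * no habitat record -> ``no_record``
    * habitat set == {freshwater} -> ``only_freshwater``
    * habitat set a non-empty subset of {seawater, mudflat} -> ``only_seawater_mud``
    * anything else (straddles fresh and salt, or touches an estuary,
      including estuary-only species) -> ``mixed``
    """
    if profile.unrecorded or not profile.habitats:
        return GROUP_NO_RECORD
    h = profile.habitats
    if h == {"freshwater"}:
        return GROUP_ONLY_FRESHWATER
    if h <= {"seawater", "mudflat"}:
        return GROUP_ONLY_SEAWATER_MUD
    if "estuary" in h and h == {"estuary"}:
        logger.info("%s: estuary-only species classified as mixed", profile.species_name)
    return GROUP_MIXED


def classify_habitat_groups(profiles: Iterable[SpeciesProfile]) -> dict[str, str]:
    """Map each species key to its analysis group (a partition of the input)."""
    return {p.key: classify_habitat_group(p) for p in profiles}


# ---------------------------------------------------------------------------
# report output

REPORT_COLUMNS = [
    "dataset_label",
    "habitat_scope",
    "q_filtered",
    "n_points",
    "n_removed_q",
    "n_removed_influential",
    "slope",
    "intercept",
    "r2_regression",
    "r2_identity",
    "slope_post",
    "intercept_post",
    "r2_regression_post",
    "r2_identity_post",
    "rmse_identity",
    "mae_identity",
    "rmse_regression",
    "mae_regression",
    "degenerate",
]


def reports_to_frame(reports: Sequence) -> pd.DataFrame:
    """Tidy one-row-per-variant table from ConcordanceReport dataclasses."""
    rows = [dataclasses.asdict(r) for r in reports]
    df = pd.DataFrame(rows)
    return df.reindex(columns=REPORT_COLUMNS)


def write_report(reports: Sequence, path: str | Path) -> Path:
    """Write concordance reports as CSV plus a JSON summary alongside.

    Floats are serialized with ``repr`` round-trip precision so a
    write-then-read cycle is lossless.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = reports_to_frame(reports)
    df.to_csv(path, index=False, float_format=None)
    json_path = path.with_suffix(".json")
    with open(json_path, "w") as fh:
        json.dump(df.to_dict(orient="records"), fh, indent=2, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o):
    if isinstance(o, (bool,)):
        return o
    if o is None or (isinstance(o, float) and math.isnan(o)):
        return None
    return str(o)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report table written by :func:`write_report`."""
    return pd.read_csv(path)
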