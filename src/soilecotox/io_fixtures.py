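"""Tidy experiment tables and packaged transcriptions of the published tables.

The experiment layout is a single fungicide (azoxystrobin) applied to sandy
loam at five doses (a control plus 0.075 -- the manufacturer's recommended
rate -- 2.25, 11.25 and 22.50 mg per kg soil dry matter) and sampled after
30, 60 and 90 days of incubation.  All tabular data move through one tidy
long format: one measurement per row, keyed by (dose, time, replicate,
variable).

The module also serves frozen transcriptions of the printed summary tables
(PEC grid, microbial counts, enzyme activities, resistance and resilience
indices, soil characterisation).  Transcriptions are stored as CSV resources
exactly as printed and are checksum-locked; the raw decimal strings are kept
alongside the parsed floats so that downstream reports can reproduce printed
roundings exactly.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DOSES",
    "TREATED_DOSES",
    "TIMES",
    "ENZYMES",
    "MICROBIAL_GROUPS",
    "LONG_COLUMNS",
    "SchemaError",
    "ParseError",
    "IntegrityError",
    "CatalogError",
    "LongObservation",
    "Fixture",
    "read_long_table",
    "write_long_table",
    "observations_to_frame",
    "frame_to_observations",
    "fixture_names",
    "load_fixture",
    "verify_fixture_checksums",
]

#: Treatment doses, mg a.i. per kg soil DM (control first).
DOSES: tuple[float, ...] = (0.0, 0.075, 2.25, 11.25, 22.5)
#: Non-zero doses (the resistance/resilience tables have no control column).
TREATED_DOSES: tuple[float, ...] = DOSES[1:]
#: Sampling times, days after treatment.
TIMES: tuple[int, ...] = (30, 60, 90)

ENZYMES: tuple[str, ...] = (
    "dehydrogenases",
    "catalase",
    "urease",
    "acid_phosphatase",
    "alkaline_phosphatase",
)
MICROBIAL_GROUPS: tuple[str, ...] = (
    "organotrophic_bacteria",
    "actinomycetes",
    "fungi",
)

ENZYME_UNITS: dict[str, str] = {
    "dehydrogenases": "umol TPF kg-1 DM h-1",
    "catalase": "mol O2 kg-1 DM h-1",
    "urease": "mmol N-NH4 kg-1 DM h-1",
    "acid_phosphatase": "mmol PNP kg-1 DM h-1",
    "alkaline_phosphatase": "mmol PNP kg-1 DM h-1",
}
COUNT_UNIT = "log10 CFU kg-1 DM"

LONG_COLUMNS: tuple[str, ...] = ("dose", "time", "replicate", "variable", "value")


class SchemaError(ValueError):
    """A table does not declare the expected columns/variables."""


class ParseError(ValueError):
    """A cell cannot be parsed or violates a row invariant."""


class IntegrityError(ValueError):
    """Duplicate keys or corrupted packaged data."""


class CatalogError(KeyError):
    """Unknown fixture name."""


@dataclass(frozen=True)
class LongObservation:
    """One measurement at (dose, time, replicate, variable).

    ``dose`` is in mg a.i. per kg soil DM, ``time`` in days since treatment.
    ``value`` is in the variable's unit (log10 CFU kg-1 DM for counts,
    per-enzyme activity units otherwise).
    """

    dose: float
    time: int
    replicate: str
    variable: str
    value: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not (self.dose >= 0):
            raise ParseError(f"dose must be non-negative, got {self.dose!r}")
        if not (self.time > 0):
            raise ParseError(f"time must be a positive number of days, got {self.time!r}")
        if not math.isfinite(self.value):
            raise ParseError(f"value must be finite, got {self.value!r}")
        if not self.variable:
            raise ParseError("variable identifier must be non-empty")

    @property
    def key(self) -> tuple[float, int, str, str]:
        return (self.dose, self.time, self.replicate, self.variable)


# ---------------------------------------------------------------------------
# Tidy CSV reader / writer
# ---------------------------------------------------------------------------

def _parse_number(text: str, caster, column: str, row_index: int):
    try:
        return caster(text)
    except (TypeError, ValueError) as exc:
        raise ParseError(
            f"row {row_index}: cannot parse {column}={text!r} as a number"
        ) from exc


def read_long_table(
    path, schema: Mapping[str, str] | None = None
) -> list[LongObservation]:
    """Read a tidy long-format CSV into validated observations.

    Parameters
    ----------
    path:
        CSV file with one header row and columns
        ``dose,time,replicate,variable,value`` (UTF-8, "." decimal point).
    schema:
        Optional variable -> unit declaration.  When given, every variable in
        the file must be declared and its unit is attached to the
        observations.

    Row order is preserved.  Raises :class:`SchemaError` for a missing
    column or undeclared variable, :class:`ParseError` for non-numeric or
    invariant-violating cells (with the offending row index), and
    :class:`IntegrityError` when two rows share the same
    (dose, time, replicate, variable) key.
    """
    observations: list[LongObservation] = []
    seen: set[tuple] = set()
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        for column in LONG_COLUMNS:
            if column not in header:
                raise SchemaError(f"missing required column {column!r} in {path}")
        for index, row in enumerate(reader, start=1):
            variable = (row["variable"] or "").strip()
            if schema is not None and variable not in schema:
                raise SchemaError(
                    f"row {index}: variable {variable!r} not declared in schema "
                    f"(declared: {sorted(schema)})"
                )
            time_raw = _parse_number(row["time"], float, "time", index)
            if not float(time_raw).is_integer():
                raise ParseError(f"row {index}: time must be a whole number of days")
            obs = LongObservation(
                dose=_parse_number(row["dose"], float, "dose", index),
                time=int(time_raw),
                replicate=(row["replicate"] or "").strip(),
                variable=variable,
                value=_parse_number(row["value"], float, "value", index),
                unit=schema[variable] if schema is not None else "",
            )
            if obs.key in seen:
                raise IntegrityError(
                    f"row {index}: duplicate observation key {obs.key}"
                )
            seen.add(obs.key)
            observations.append(obs)
    return observations


def _format_value(value: float) -> str:
    """Shortest decimal representation that round-trips the float."""
    if float(value).is_integer() and abs(value) < 1e16:
        return str(int(value))
    return repr(float(value))


def write_long_table(observations: Iterable[LongObservation] | pd.DataFrame, path) -> None:
    """Write observations as a tidy CSV (inverse of :func:`read_long_table`)."""
    if isinstance(observations, pd.DataFrame):
        observations = frame_to_observations(observations)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(LONG_COLUMNS)
        for obs in observations:
            writer.writerow(
                [
                    _format_value(obs.dose),
                    str(int(obs.time)),
                    obs.replicate,
                    obs.variable,
                    _format_value(obs.value),
                ]
            )


def observations_to_frame(observations: Sequence[LongObservation]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [(o.dose, o.time, o.replicate, o.variable, o.value) for o in observations],
        columns=list(LONG_COLUMNS),
    )
    frame.attrs["units"] = {o.variable: o.unit for o in observations if o.unit}
    return frame


def frame_to_observations(frame: pd.DataFrame) -> list[LongObservation]:
    units = frame.attrs.get("units", {})
    return [
        LongObservation(
            dose=float(row.dose),
            time=int(row.time),
            replicate=str(row.replicate),
            variable=str(row.variable),
            value=float(row.value),
            unit=units.get(row.variable, ""),
        )
        for row in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    """An immutable transcription of one printed table.

    ``table`` holds the body cells with numeric dtypes; ``raw`` holds the
    same rows with every cell as the exact printed string (used for
    decimal-exact recomputation of printed summary rows).  ``summary`` holds
    the printed mean and correlation rows, when the table has them.
    """

    name: str
    table: pd.DataFrame
    raw: pd.DataFrame
    summary: pd.DataFrame | None
    units: Mapping[str, str]
    notes: tuple[str, ...] = ()


_NOTE_11_50 = (
    "the printed label of the 11.25 mg kg-1 dose row is '11.50'; the row is "
    "stored under 11.25, consistent with the other tables and with the "
    "dose-proportional PEC values (0.7330 = 1.4660 / 2)"
)
_NOTE_AS_PRINTED = (
    "summary rows are stored as printed; the published means/correlations "
    "derive from replicate-level data that the table body does not contain"
)

_CATALOG: dict[str, dict] = {
    "pec": {
        "file": "pec.csv",
        "units": {"pec": "mg kg-1"},
        "notes": (_NOTE_11_50,),
        "shape": (4, 3, None),
    },
    "microbial_counts": {
        "file": "microbial_counts.csv",
        "summary": "microbial_counts_summary.csv",
        "units": {g: COUNT_UNIT for g in MICROBIAL_GROUPS},
        "notes": (_NOTE_AS_PRINTED,),
        "shape": (5, 3, 3),
    },
    "enzyme_activity": {
        "file": "enzyme_activity.csv",
        "summary": "enzyme_activity_summary.csv",
        "units": dict(ENZYME_UNITS),
        "notes": (_NOTE_AS_PRINTED,),
        "shape": (5, 3, 5),
    },
    "resistance": {
        "file": "resistance.csv",
        "summary": "resistance_summary.csv",
        "units": {e: "RS (dimensionless)" for e in ENZYMES},
        "notes": (_NOTE_AS_PRINTED,),
        "shape": (4, 3, 5),
    },
    "resilience": {
        "file": "resilience.csv",
        "summary": "resilience_summary.csv",
        "units": {e: "RL (dimensionless)" for e in ENZYMES},
        "notes": (_NOTE_AS_PRINTED,),
        "shape": (4, None, 5),
    },
    "soil_metadata": {
        "file": "soil_metadata.csv",
        "units": {},
        "notes": (),
        "shape": None,
    },
}


def fixture_names() -> tuple[str, ...]:
    return tuple(_CATALOG)


def _data_root():
    return resources.files("soilecotox.data")


def _read_resource(filename: str) -> pd.DataFrame:
    resource = _data_root().joinpath(filename)
    with resources.as_file(resource) as path:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        expected = _expected_checksums().get(filename)
        if expected is not None and digest != expected:
            raise IntegrityError(
                f"packaged fixture {filename} fails its checksum; "
                "the transcription has been modified"
            )
        return pd.read_csv(path, dtype=str, keep_default_na=False)


def _expected_checksums() -> dict[str, str]:
    with _data_root().joinpath("checksums.json").open() as handle:
        return json.load(handle)


def verify_fixture_checksums() -> dict[str, str]:
    """Recompute SHA-256 digests of all packaged CSVs against the frozen set.

    Returns the digests; raises :class:`IntegrityError` on any mismatch.
    """
    expected = _expected_checksums()
    actual: dict[str, str] = {}
    for filename in expected:
        with resources.as_file(_data_root().joinpath(filename)) as path:
            actual[filename] = hashlib.sha256(path.read_bytes()).hexdigest()
    bad = {k for k in expected if expected[k] != actual.get(k)}
    if bad:
        raise IntegrityError(f"fixture checksum mismatch for: {sorted(bad)}")
    return actual


def _validate_shape(name: str, table: pd.DataFrame, shape) -> None:
    if shape is None:
        return
    n_doses, n_times, n_vars = shape
    if table["dose"].nunique() != n_doses:
        raise IntegrityError(f"fixture {name}: expected {n_doses} dose levels")
    if n_times is not None and table["time"].nunique() != n_times:
        raise IntegrityError(f"fixture {name}: expected {n_times} time levels")
    if n_vars is not None and table["variable"].nunique() != n_vars:
        raise IntegrityError(f"fixture {name}: expected {n_vars} variables")
    expected_rows = n_doses * (n_times or 1) * (n_vars or 1)
    if len(table) != expected_rows:
        raise IntegrityError(
            f"fixture {name}: expected {expected_rows} body cells, got {len(table)}"
        )


def load_fixture(name: str) -> Fixture:
    """Load one packaged table transcription by name.

    Valid names are given by :func:`fixture_names`.  The returned frames are
    fresh copies; mutating them cannot corrupt the catalog.
    """
    try:
        entry = _CATALOG[name]
    except KeyError:
        raise CatalogError(
            f"unknown fixture {name!r}; valid names: {', '.join(_CATALOG)}"
        ) from None

    raw = _read_resource(entry["file"])
    table = raw.copy()
    for column in table.columns:
        if column in ("dose", "time", "value"):
            table[column] = pd.to_numeric(table[column])
    if "time" in table.columns:
        table["time"] = table["time"].astype(int)
    if name != "soil_metadata":
        _validate_shape(name, table, entry["shape"])

    summary = None
    if "summary" in entry:
        summary = _read_resource(entry["summary"])
        summary["value"] = pd.to_numeric(summary["value"])
        if "time" in summary.columns:
            summary["time"] = summary["time"].astype(int)
        summary["significant"] = summary["significant"].map({"1": True, "0": False, "": None})

    table.attrs["units"] = dict(entry["units"])
    return Fixture(
        name=name,
        table=table,
        raw=raw,
        summary=summary,
        units=dict(entry["units"]),
        notes=tuple(entry["notes"]),
    )
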