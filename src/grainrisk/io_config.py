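"""Sample table I/O, parameter configuration and the central data model.

The survey unit is one grain sample: a crop (rice, corn or wheat), its
sampling coordinates in decimal degrees, and the measured fluorine and
cadmium concentrations in mg/kg dry weight.  Exposure arithmetic is driven
by a :class:`ParameterSet` holding, per population, body weight, per-crop
ingestion rate, exposure frequency and duration, and per element the oral
reference dose, carcinogenic slope factor (Cd only) and the Chinese
regulatory maximum level (GB 2762-2017; Cd only — the F food limit has
been abolished).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    EmptyGroupError,
    ParameterError,
    SchemaError,
    ValidationError,
)

CROPS = ("rice", "corn", "wheat")
ELEMENTS = ("F", "Cd")
POPULATIONS = ("adult", "child")

#: averaging-time conventions for the ADI denominator
AT_RULES = ("ed_times_365", "lifetime_70y")

SAMPLE_COLUMNS = ("sample_id", "crop", "lon", "lat", "f_mgkg", "cd_mgkg")


@dataclass(frozen=True)
class SampleRecord:
    """One grain sample: crop, location, and F/Cd concentrations (mg/kg dw)."""

    sample_id: str
    crop: str
    lon: float
    lat: float
    f_mgkg: float
    cd_mgkg: float

    def __post_init__(self) -> None:
        if self.crop not in CROPS:
            raise ValidationError(
                f"unknown crop {self.crop!r} for sample {self.sample_id!r}; "
                f"expected one of {CROPS}"
            )
        for name, value in (("lon", self.lon), ("lat", self.lat),
                            ("f_mgkg", self.f_mgkg), ("cd_mgkg", self.cd_mgkg)):
            if not math.isfinite(value):
                raise ValidationError(
                    f"non-finite {name}={value!r} for sample {self.sample_id!r}"
                )
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"lon {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"lat {self.lat} outside [-90, 90]")
        if self.f_mgkg < 0 or self.cd_mgkg < 0:
            raise ValidationError(
                f"negative concentration for sample {self.sample_id!r}: "
                f"F={self.f_mgkg}, Cd={self.cd_mgkg}"
            )

    def concentration(self, element: str) -> float:
        if element == "F":
            return self.f_mgkg
        if element == "Cd":
            return self.cd_mgkg
        raise ParameterError(f"unknown element {element!r}")


@dataclass(frozen=True)
class PopulationParams:
    """Exposure parameters for one population group.

    ``ir_kgday`` maps crop name to daily grain intake (kg/d); ``ef_dpera``
    is exposure frequency in days per year; ``ed_years`` exposure duration.
    """

    name: str
    bw_kg: float
    ir_kgday: Mapping[str, float]
    ef_dpera: float = 365.0
    ed_years: float = 70.0

    def __post_init__(self) -> None:
        if self.bw_kg <= 0:
            raise ConfigError(f"populations.{self.name}.bw_kg must be positive")
        if self.ef_dpera <= 0 or self.ed_years <= 0:
            raise ConfigError(f"populations.{self.name}: EF and ED must be positive")
        for crop, ir in self.ir_kgday.items():
            if ir <= 0:
                raise ConfigError(
                    f"populations.{self.name}.ir_kgday.{crop} must be positive"
                )

    def ir_for(self, crop: str) -> float:
        try:
            return self.ir_kgday[crop]
        except KeyError:
            raise ParameterError(
                f"population {self.name!r} has no ingestion rate for crop {crop!r}"
            ) from None


@dataclass(frozen=True)
class ElementParams:
    """Toxicological constants for one element.

    ``sf_permgkgday`` (carcinogenic slope factor) and ``si_limit`` (per-crop
    regulatory maximum, mg/kg) are present for Cd only.
    """

    element: str
    rfd_mgkgday: float
    sf_permgkgday: float | None = None
    si_limit: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.rfd_mgkgday <= 0:
            raise ConfigError(f"elements.{self.element}.rfd_mgkgday must be positive")
        if self.sf_permgkgday is not None and self.sf_permgkgday <= 0:
            raise ConfigError(f"elements.{self.element}.sf_permgkgday must be positive")
        if self.si_limit is not None:
            for crop, si in self.si_limit.items():
                if si <= 0:
                    raise ConfigError(
                        f"elements.{self.element}.si_limit.{crop} must be positive"
                    )

    def si_for(self, crop: str) -> float:
        if self.si_limit is None or crop not in self.si_limit:
            raise ParameterError(
                f"element {self.element!r} has no regulatory limit for crop {crop!r}"
            )
        return self.si_limit[crop]


@dataclass(frozen=True)
class ParameterSet:
    """All exposure constants: populations, elements and the AT convention."""

    populations: Mapping[str, PopulationParams]
    elements: Mapping[str, ElementParams]
    at_rule: str = "ed_times_365"

    def __post_init__(self) -> None:
        if self.at_rule not in AT_RULES:
            raise ConfigError(f"at_rule must be one of {AT_RULES}, got {self.at_rule!r}")
        for name, pop in self.populations.items():
            if pop.name != name:
                raise ConfigError(f"populations.{name}: inconsistent name {pop.name!r}")
        for sym, el in self.elements.items():
            if el.element != sym:
                raise ConfigError(f"elements.{sym}: inconsistent element {el.element!r}")

    def population(self, name: str) -> PopulationParams:
        try:
            return self.populations[name]
        except KeyError:
            raise ParameterError(f"unknown population {name!r}") from None

    def element(self, symbol: str) -> ElementParams:
        try:
            return self.elements[symbol]
        except KeyError:
            raise ParameterError(f"unknown element {symbol!r}") from None


def default_parameters() -> ParameterSet:
    """Packaged default exposure constants.

    Adults: BW 59.10 kg, ED 70 y; children: BW 24.90 kg, ED 9 y; EF 365 d/a.
    Daily intakes (kg/d, adult/child): rice 0.389/0.198, corn 0.10/0.15,
    wheat 0.15/0.10.  RfD: Cd 0.001, F 0.06 mg/kg/d; Cd slope factor 0.64
    (mg/kg/d)^-1; Cd limits: rice 0.2, corn 0.1, wheat 0.1 mg/kg.
    """
    return ParameterSet(
        populations={
            "adult": PopulationParams(
                name="adult",
                bw_kg=59.10,
                ir_kgday={"rice": 0.389, "corn": 0.10, "wheat": 0.15},
                ef_dpera=365.0,
                ed_years=70.0,
            ),
            "child": PopulationParams(
                name="child",
                bw_kg=24.90,
                ir_kgday={"rice": 0.198, "corn": 0.15, "wheat": 0.10},
                ef_dpera=365.0,
                ed_years=9.0,
            ),
        },
        elements={
            "F": ElementParams(element="F", rfd_mgkgday=0.06),
            "Cd": ElementParams(
                element="Cd",
                rfd_mgkgday=0.001,
                sf_permgkgday=0.64,
                si_limit={"rice": 0.2, "corn": 0.1, "wheat": 0.1},
            ),
        },
        at_rule="ed_times_365",
    )


def _merge_population(base: PopulationParams, cfg: Mapping, path: str) -> PopulationParams:
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"{path}: expected a mapping, got {type(cfg).__name__}")
    kwargs: dict = {}
    for key in cfg:
        if key == "bw_kg":
            kwargs["bw_kg"] = _as_number(cfg[key], f"{path}.bw_kg")
        elif key == "ef_dpera":
            kwargs["ef_dpera"] = _as_number(cfg[key], f"{path}.ef_dpera")
        elif key == "ed_years":
            kwargs["ed_years"] = _as_number(cfg[key], f"{path}.ed_years")
        elif key == "ir_kgday":
            sub = cfg[key]
            if not isinstance(sub, Mapping):
                raise ConfigError(f"{path}.ir_kgday: expected a mapping")
            ir = dict(base.ir_kgday)
            for crop, val in sub.items():
                ir[str(crop)] = _as_number(val, f"{path}.ir_kgday.{crop}")
            kwargs["ir_kgday"] = ir
        else:
            raise ConfigError(f"{path}.{key}: unknown key")
    return replace(base, **kwargs)


def _merge_element(base: ElementParams, cfg: Mapping, path: str) -> ElementParams:
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"{path}: expected a mapping, got {type(cfg).__name__}")
    kwargs: dict = {}
    for key in cfg:
        if key == "rfd_mgkgday":
            kwargs["rfd_mgkgday"] = _as_number(cfg[key], f"{path}.rfd_mgkgday")
        elif key == "sf_permgkgday":
            kwargs["sf_permgkgday"] = _as_number(cfg[key], f"{path}.sf_permgkgday")
        elif key == "si_limit":
            sub = cfg[key]
            if not isinstance(sub, Mapping):
                raise ConfigError(f"{path}.si_limit: expected a mapping")
            si = dict(base.si_limit or {})
            for crop, val in sub.items():
                si[str(crop)] = _as_number(val, f"{path}.si_limit.{crop}")
            kwargs["si_limit"] = si
        else:
            raise ConfigError(f"{path}.{key}: unknown key")
    return replace(base, **kwargs)


def _as_number(value, path: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{path}: expected a number, got {value!r}")
    return float(value)


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load a ParameterSet from a YAML config, merged over packaged defaults.

    An absent path (or missing file) yields the defaults.  The config may
    carry ``populations:``, ``elements:`` and ``at_rule:`` blocks; any key
    present overrides the default, everything else is inherited.
    """
    base = default_parameters()
    if path is None:
        return base
    path = Path(path)
    if not path.exists():
        return base
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError("config root: expected a mapping")

    populations = dict(base.populations)
    elements = dict(base.elements)
    at_rule = base.at_rule
    for key, block in raw.items():
        if key == "populations":
            if not isinstance(block, Mapping):
                raise ConfigError("populations: expected a mapping")
            for name, cfg in block.items():
                name = str(name)
                base_pop = populations.get(name)
                if base_pop is None:
                    raise ConfigError(f"populations.{name}: unknown population")
                populations[name] = _merge_population(base_pop, cfg, f"populations.{name}")
        elif key == "elements":
            if not isinstance(block, Mapping):
                raise ConfigError("elements: expected a mapping")
            for sym, cfg in block.items():
                sym = str(sym)
                base_el = elements.get(sym)
                if base_el is None:
                    raise ConfigError(f"elements.{sym}: unknown element")
                elements[sym] = _merge_element(base_el, cfg, f"elements.{sym}")
        elif key == "at_rule":
            if block not in AT_RULES:
                raise ConfigError(f"at_rule: must be one of {AT_RULES}, got {block!r}")
            at_rule = str(block)
        else:
            raise ConfigError(f"{key}: unknown top-level config block")
    return ParameterSet(populations=populations, elements=elements, at_rule=at_rule)


# ---------------------------------------------------------------------------
# sample table I/O


def read_samples(path: str | Path, delimiter: str | None = None) -> list[SampleRecord]:
    """Read a sample table (CSV by default, TSV accepted) into records.

    The header must name all of ``sample_id,crop,lon,lat,f_mgkg,cd_mgkg``.
    Row order is preserved; each row is validated and errors carry the
    offending row index (0-based data row).
    """
    path = Path(path)
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=delimiter, dtype={"sample_id": str},
                        float_precision="round_trip")
    return frame_to_records(frame)


def frame_to_records(frame: pd.DataFrame) -> list[SampleRecord]:
    missing = [c for c in SAMPLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records: list[SampleRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            records.append(
                SampleRecord(
                    sample_id=str(row.sample_id),
                    crop=str(row.crop),
                    lon=float(row.lon),
                    lat=float(row.lat),
                    f_mgkg=float(row.f_mgkg),
                    cd_mgkg=float(row.cd_mgkg),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {i}: non-numeric field ({exc})") from exc
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return records


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.sample_id, r.crop, r.lon, r.lat, r.f_mgkg, r.cd_mgkg)
            for r in records
        ],
        columns=list(SAMPLE_COLUMNS),
    )


def write_samples(records: Sequence[SampleRecord], path: str | Path,
                  delimiter: str = ",") -> None:
    """Write records as a delimited table; floats at full repr precision."""
    buf = io.StringIO()
    buf.write(delimiter.join(SAMPLE_COLUMNS) + "\n")
    for r in records:
        buf.write(
            delimiter.join(
                (r.sample_id, r.crop, repr(r.lon), repr(r.lat),
                 repr(r.f_mgkg), repr(r.cd_mgkg))
            )
            + "\n"
        )
    Path(path).write_text(buf.getvalue())


def subset(records: Iterable[SampleRecord], crop: str) -> list[SampleRecord]:
    return [r for r in records if r.crop == crop]


def summarize(records: Iterable[SampleRecord], crop: str, element: str) -> dict:
    """Range/median/mean summary for one crop and element.

    Mean is the arithmetic mean over all samples of the crop (zeros
    included — no detection-limit substitution); median uses the midpoint
    convention for even n.
    """
    values = np.array([r.concentration(element) for r in subset(records, crop)])
    if values.size == 0:
        raise EmptyGroupError(f"no records for crop {crop!r}")
    return {
        "n": int(values.size),
        "min": float(values.min()),
        "max": float(values.max()),
        "median": float(np.median(values)),
        "mean": float(values.mean()),
    }
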