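"""Domain data model for biotest observations and tidy-table I/O.

The pipeline's unit of work is the :class:`AssaySeries`: one
compound x organism x endpoint x exposure-time dose-response series with
replicate observations.  Series are read from a tidy CSV with one
observation per row and written back as flat result tables.

CSV dialect: UTF-8, comma separator, dot decimal, one header row.
Input columns::

    compound, organism, endpoint, exposure_time, time_unit,
    concentration, conc_unit, replicate, response_kind, value

Concentrations of exactly 0 are controls; they are kept on the series
(``control_rows``) but excluded from any log-concentration fit.
"""

from __future__ import annotations

import logging
import math
from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from uvtox.errors import SchemaError, ValidationError

log = logging.getLogger(__name__)

ORGANISMS = frozenset(
    {"aliivibrio_fischeri", "artemia_franciscana", "daphnia_magna", "lemna_minor"}
)
ENDPOINTS = frozenset(
    {"luminescence_inhibition", "mortality", "immobilization", "behavior",
     "growth_inhibition"}
)
RESPONSE_KINDS = frozenset(
    {"inhibition_pct", "affected_count", "total_count", "frond_area_day1",
     "frond_area_day7", "luminescence_t0", "luminescence_t"}
)
CONC_UNITS = frozenset({"mg_per_L", "percent_of_stock"})
TIME_UNITS = {"min": 1.0, "h": 60.0, "d": 1440.0}

REQUIRED_COLUMNS = (
    "compound", "organism", "endpoint", "exposure_time", "time_unit",
    "concentration", "conc_unit", "replicate", "response_kind", "value",
)


@dataclass(frozen=True)
class Compound:
    """A tested substance; metadata fields are optional and never fitted."""

    code: str
    full_name: str = ""
    log_kow: float | None = None
    stock_conc: float | None = None  # mg/L

    def __post_init__(self) -> None:
        if not self.code:
            raise ValidationError("compound code must be non-empty")
        if self.log_kow is not None and not math.isfinite(self.log_kow):
            raise ValidationError(f"log_kow must be finite, got {self.log_kow}")


@dataclass(frozen=True)
class Observation:
    """One raw measurement at one concentration in one replicate well."""

    concentration: float
    conc_unit: str
    replicate: int
    response_kind: str
    value: float

    def __post_init__(self) -> None:
        if self.conc_unit not in CONC_UNITS:
            raise ValidationError(f"unknown conc_unit {self.conc_unit!r}")
        if self.response_kind not in RESPONSE_KINDS:
            raise ValidationError(f"unknown response_kind {self.response_kind!r}")
        if not math.isfinite(self.value):
            raise ValidationError("observation value must be finite")
        if self.concentration < 0:
            raise ValidationError("concentration must be non-negative")
        if self.replicate < 1:
            raise ValidationError("replicate index must be positive")
        if self.response_kind.startswith("frond_area") and self.value <= 0:
            raise ValidationError("frond areas must be positive")
        if self.response_kind == "inhibition_pct" and self.value > 100:
            raise ValidationError("inhibition cannot exceed 100%")


@dataclass
class AssaySeries:
    """One dose-response series with replicate observations.

    ``exposure_time`` is stored in the input unit; ``exposure_time_minutes``
    normalises it for internal comparisons.
    """

    compound: Compound
    organism: str
    endpoint: str
    exposure_time: float
    time_unit: str
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.organism not in ORGANISMS:
            raise ValidationError(f"unknown organism {self.organism!r}")
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if self.time_unit not in TIME_UNITS:
            raise ValidationError(f"unknown time unit {self.time_unit!r}")
        if self.exposure_time <= 0:
            raise ValidationError("exposure_time must be positive")
        units = {o.conc_unit for o in self.observations}
        if len(units) > 1:
            raise ValidationError(
                f"mixed concentration units within a series: {sorted(units)}"
            )

    @property
    def conc_unit(self) -> str | None:
        return self.observations[0].conc_unit if self.observations else None

    @property
    def exposure_time_minutes(self) -> float:
        return self.exposure_time * TIME_UNITS[self.time_unit]

    @property
    def control_rows(self) -> list[Observation]:
        return [o for o in self.observations if o.concentration == 0]

    @property
    def treated_rows(self) -> list[Observation]:
        return [o for o in self.observations if o.concentration > 0]

    @property
    def key(self) -> tuple:
        return (self.compound.code, self.organism, self.endpoint,
                self.exposure_time, self.time_unit)

    def concentrations(self) -> list[float]:
        """Distinct positive concentrations, ascending."""
        return sorted({o.concentration for o in self.treated_rows})


Finding = namedtuple("Finding", ["code", "severity", "message"])

LoadReport = namedtuple("LoadReport", ["series", "rejected"])


def _check_count_pairs(rows: pd.DataFrame) -> list[str]:
    """Return messages for affected_count rows exceeding their paired total."""
    msgs = []
    counts = rows[rows["response_kind"].isin(["affected_count", "total_count"])]
    if counts.empty:
        return msgs
    for (conc, rep), grp in counts.groupby(["concentration", "replicate"]):
        kinds = grp.set_index("response_kind")["value"]
        if "affected_count" in kinds.index and "total_count" in kinds.index:
            aff, tot = float(kinds["affected_count"]), float(kinds["total_count"])
            if aff > tot:
                msgs.append(
                    f"affected_count {aff:g} > total_count {tot:g} "
                    f"at concentration {conc:g}, replicate {rep}"
                )
    return msgs


def load_assay_table(
    path: str | Path,
    compounds: Mapping[str, Compound] | None = None,
    errors: str = "raise",
) -> list[AssaySeries] | LoadReport:
    """Read a tidy observation CSV and group rows into :class:`AssaySeries`.

    Parameters
    ----------
    path
        CSV file with the documented column set.
    compounds
        Optional code -> :class:`Compound` metadata map; codes absent from
        the map get a bare ``Compound(code)``.
    errors
        ``"raise"`` (default) raises :class:`ValidationError` on any invalid
        group; ``"collect"`` returns a :class:`LoadReport` whose ``rejected``
        frame holds the offending rows with a ``reason`` column, so that
        every input row lands either in a series or in the report.
    """
    if errors not in {"raise", "collect"}:
        raise ValueError("errors must be 'raise' or 'collect'")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        log.warning("assay table %s has a header but no data rows", path)
        return [] if errors == "raise" else LoadReport([], df.assign(reason=[]))

    compounds = compounds or {}
    series_out: list[AssaySeries] = []
    rejected: list[pd.DataFrame] = []
    group_cols = ["compound", "organism", "endpoint", "exposure_time", "time_unit"]
    for key, grp in df.groupby(group_cols, sort=False):
        code, organism, endpoint, etime, tunit = key
        problems = []
        units = set(grp["conc_unit"])
        if len(units) > 1:
            bad = grp.index[grp["conc_unit"] != grp["conc_unit"].iloc[0]].tolist()
            problems.append(
                f"mixed conc_unit {sorted(units)} within series {key} "
                f"(rows {bad})"
            )
        problems.extend(_check_count_pairs(grp))
        if not problems:
            try:
                obs = [
                    Observation(
                        concentration=float(r.concentration),
                        conc_unit=str(r.conc_unit),
                        replicate=int(r.replicate),
                        response_kind=str(r.response_kind),
                        value=float(r.value),
                    )
                    for r in grp.itertuples()
                ]
                series_out.append(
                    AssaySeries(
                        compound=compounds.get(str(code), Compound(str(code))),
                        organism=str(organism),
                        endpoint=str(endpoint),
                        exposure_time=float(etime),
                        time_unit=str(tunit),
                        observations=obs,
                    )
                )
                continue
            except ValidationError as exc:
                problems.append(str(exc))
        if errors == "raise":
            raise ValidationError("; ".join(problems))
        rejected.append(grp.assign(reason="; ".join(problems)))

    if errors == "collect":
        rej = (pd.concat(rejected) if rejected
               else df.iloc[0:0].assign(reason=pd.Series(dtype=str)))
        return LoadReport(series_out, rej)
    return series_out


def validate_series(series: AssaySeries) -> list[Finding]:
    """Non-mutating sanity checks; returns machine-readable findings."""
    findings: list[Finding] = []
    n_conc = len(series.concentrations())
    if n_conc < 2:
        findings.append(Finding(
            "too_few_concentrations", "error",
            f"{n_conc} distinct positive concentration(s); >=2 required for a fit",
        ))
    kinds = {o.response_kind for o in series.observations}
    if "luminescence_t" in kinds and not series.control_rows:
        findings.append(Finding(
            "missing_control", "error",
            "raw luminescence series requires zero-concentration control rows",
        ))
    if {"affected_count", "total_count"} & kinds and not (
            {"affected_count", "total_count"} <= kinds):
        findings.append(Finding(
            "unpaired_counts", "error",
            "affected_count and total_count rows must come in pairs",
        ))
    return findings


# ---------------------------------------------------------------------------
# result tables

POTENCY_COLUMNS = (
    "compound", "organism", "endpoint", "time", "time_unit", "model",
    "a", "b", "r2", "r2_crit", "significant", "kind", "x", "value", "censored",
)
TU_COLUMNS = ("mixture_id", "components", "tu_mix", "interaction")


def _round(v, dp):
    return round(float(v), dp) if v is not None and pd.notna(v) else v


def write_results_table(results: Sequence, path: str | Path,
                        decimals: int = 2, kind: str | None = None) -> None:
    """Write potency or toxic-unit results as a flat CSV.

    ``results`` must be homogeneous; ``kind`` ("potency" | "tu") is only
    needed to pick a header for an empty list.  Numbers are rendered with
    ``decimals`` places (default 2, the precision used in reporting).
    """
    from uvtox.mixtures import ToxicUnitResult

    if results:
        types = {type(r) for r in results}
        if len(types) > 1:
            raise ValidationError(f"results not homogeneous: {types}")
        kind = "tu" if isinstance(results[0], ToxicUnitResult) else "potency"
    elif kind is None:
        kind = "potency"

    rows = []
    if kind == "potency":
        for r in results:
            fit = r.fit
            rows.append({
                "compound": r.compound or "", "organism": r.organism or "",
                "endpoint": r.endpoint or "",
                "time": r.exposure_time, "time_unit": r.time_unit,
                "model": fit.model if fit else "",
                "a": _round(fit.intercept, decimals) if fit else None,
                "b": _round(fit.slope, decimals) if fit else None,
                "r2": _round(fit.r_squared, decimals) if fit else None,
                "r2_crit": _round(fit.critical_r_squared, decimals) if fit else None,
                "significant": fit.significant if fit else None,
                "kind": r.kind, "x": r.level,
                "value": _round(r.value, decimals),
                "censored": r.censored,
            })
        df = pd.DataFrame(rows, columns=POTENCY_COLUMNS)
    else:
        for r in results:
            rows.append({
                "mixture_id": r.mixture_id,
                "components": "+".join(c.code for c in r.components),
                "tu_mix": _round(r.tu_mix, decimals),
                "interaction": r.interaction,
            })
        df = pd.DataFrame(rows, columns=TU_COLUMNS)
    df.to_csv(path, index=False)


def series_to_frame(series_list: Iterable[AssaySeries]) -> pd.DataFrame:
    """Flatten series back to the tidy input schema (inverse of loading)."""
    rows = []
    for s in series_list:
        for o in s.observations:
            rows.append({
                "compound": s.compound.code, "organism": s.organism,
                "endpoint": s.endpoint, "exposure_time": s.exposure_time,
                "time_unit": s.time_unit, "concentration": o.concentration,
                "conc_unit": o.conc_unit, "replicate": o.replicate,
                "response_kind": o.response_kind, "value": o.value,
            })
    return pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
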