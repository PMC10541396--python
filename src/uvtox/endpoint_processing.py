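"""Convert raw biotest measurements to a common percent-effect scale.

Each of the four assay protocols produces its own raw quantity — light
units (Aliivibrio fischeri), affected/total organism counts (Artemia
franciscana, Daphnia magna), frond areas on day 1 and day 7 (Lemna
minor).  The functions here reduce them to :class:`EffectPoint` values
(percent effect per concentration, with the across-replicate SD), which is
the input scale of the dose-response stage.

Negative inhibition (stimulation, e.g. luminescence increasing under
exposure) is preserved in effect tables; it is clipped to zero only inside
the gamma transform, where Γ = I/(100 − I) requires a non-negative loss.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Sequence

from uvtox.assay_core import AssaySeries
from uvtox.errors import DomainError, ValidationError

LEMNA_INTERVAL_DAYS = 6.0  # day 1 -> day 7


@dataclass(frozen=True)
class EffectPoint:
    """Percent effect at one concentration, averaged over replicates."""

    concentration: float
    effect_pct: float
    sd_pct: float | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.sd_pct is not None and self.sd_pct < 0:
            raise ValidationError("sd_pct must be non-negative")


@dataclass(frozen=True)
class GammaPoint:
    """Γ = I/(100 − I): ratio of lost to remaining luminescence."""

    concentration: float
    gamma: float
    stimulated: bool = False

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValidationError("gamma must be non-negative")


GammaResult = namedtuple("GammaResult", ["gamma", "stimulated"])
GateResult = namedtuple("GateResult", ["qualifies", "max_effect", "borderline"])


def luminescence_inhibition(control_t0: float, control_t: float,
                            sample_t0: float, sample_t: float) -> float:
    """Drift-corrected percent luminescence inhibition.

    The control correction factor f = control_t / control_t0 rescales the
    initial sample reading for the natural drift of the bacterial light
    output over the exposure window; inhibition is the relative loss
    against that corrected baseline:

        I = 100 * (f * sample_t0 - sample_t) / (f * sample_t0)

    May be negative when the sample brightens relative to the control
    (stimulation).  Invariant to rescaling all four readings by a common
    positive factor.
    """
    if control_t0 <= 0 or sample_t0 <= 0 or control_t <= 0:
        raise DomainError("control and initial readings must be positive")
    if sample_t < 0:
        raise DomainError("sample reading cannot be negative")
    f = control_t / control_t0
    corrected = f * sample_t0
    return 100.0 * (corrected - sample_t) / corrected


def gamma_transform(effect_pct: float) -> GammaResult:
    """Γ = I/(100 − I); Γ(50) = 1 marks the EC50.

    Stimulation (negative effect) is reported as Γ = 0 with the
    ``stimulated`` flag set; total quench (I >= 100) is outside the domain.
    """
    if effect_pct >= 100:
        raise DomainError("gamma undefined for effect >= 100%")
    if effect_pct < 0:
        return GammaResult(0.0, True)
    return GammaResult(effect_pct / (100.0 - effect_pct), False)


def gamma_to_effect(gamma: float) -> float:
    """Inverse of :func:`gamma_transform`: I = 100 Γ / (1 + Γ)."""
    if gamma < 0:
        raise DomainError("gamma must be non-negative")
    return 100.0 * gamma / (1.0 + gamma)


def effect_fraction_from_counts(
    wells: Sequence[tuple[float, float]],
    concentration: float = math.nan,
) -> EffectPoint:
    """Mean and SD of per-well percent affected.

    ``wells`` holds (affected, total) pairs, one per replicate well.  The
    per-well percentages are averaged and their sample (n − 1) standard
    deviation reported, matching the replicate design of the crustacean
    tests (three wells per concentration).
    """
    if not wells:
        raise DomainError("at least one well is required")
    for affected, total in wells:
        if total <= 0:
            raise DomainError("total organisms per well must be positive")
        if affected > total or affected < 0:
            raise DomainError(f"affected {affected} outside [0, total={total}]")
    pcts = [100.0 * a / t for a, t in wells]
    sd = stdev(pcts) if len(pcts) > 1 else None
    return EffectPoint(concentration, mean(pcts), sd, len(pcts))


def lemna_growth_inhibition(
    treated: Sequence[tuple[float, float]],
    control: Sequence[tuple[float, float]],
    basis: str = "yield",
    concentration: float = math.nan,
) -> EffectPoint:
    """Duckweed growth inhibition from day-1 / day-7 frond areas.

    yield basis (default): I = 100 (1 − mean(A7 − A1)_treated / mean(A7 − A1)_control)
    rate basis:            I = 100 (1 − mean(μ)_treated / mean(μ)_control),
                           μ = (ln A7 − ln A1) / 6 d

    Inhibition can exceed 100% when fronds shrink.  The yield basis follows
    the area-increase reading of the protocol; the specific-growth-rate
    basis is the standard alternative.
    """
    if basis not in {"yield", "growth_rate"}:
        raise DomainError(f"unknown basis {basis!r}")
    if not treated or not control:
        raise DomainError("treated and control replicate lists must be non-empty")
    for a1, a7 in (*treated, *control):
        if a1 <= 0 or a7 <= 0:
            raise DomainError("frond areas must be positive")
    if basis == "yield":
        t = mean(a7 - a1 for a1, a7 in treated)
        c = mean(a7 - a1 for a1, a7 in control)
    else:
        t = mean((math.log(a7) - math.log(a1)) / LEMNA_INTERVAL_DAYS
                 for a1, a7 in treated)
        c = mean((math.log(a7) - math.log(a1)) / LEMNA_INTERVAL_DAYS
                 for a1, a7 in control)
    if c <= 0:
        raise DomainError("invalid control: non-positive control growth")
    return EffectPoint(concentration, 100.0 * (1.0 - t / c),
                       None, len(treated))


def _inhibition_points(series: AssaySeries) -> list[EffectPoint]:
    by_conc: dict[float, list[float]] = {}
    for o in series.treated_rows:
        if o.response_kind == "inhibition_pct":
            by_conc.setdefault(o.concentration, []).append(o.value)
    pts = []
    for conc in sorted(by_conc):
        vals = by_conc[conc]
        sd = stdev(vals) if len(vals) > 1 else None
        pts.append(EffectPoint(conc, mean(vals), sd, len(vals)))
    return pts


def _count_points(series: AssaySeries) -> list[EffectPoint]:
    by_conc: dict[float, dict[int, dict[str, float]]] = {}
    for o in series.treated_rows:
        if o.response_kind in {"affected_count", "total_count"}:
            by_conc.setdefault(o.concentration, {}).setdefault(
                o.replicate, {})[o.response_kind] = o.value
    pts = []
    for conc in sorted(by_conc):
        wells = []
        for rep in sorted(by_conc[conc]):
            pair = by_conc[conc][rep]
            if {"affected_count", "total_count"} <= set(pair):
                wells.append((pair["affected_count"], pair["total_count"]))
        if wells:
            pts.append(effect_fraction_from_counts(wells, conc))
    return pts


def _lemna_points(series: AssaySeries, basis: str) -> list[EffectPoint]:
    def area_pairs(obs):
        by_rep: dict[int, dict[str, float]] = {}
        for o in obs:
            if o.response_kind in {"frond_area_day1", "frond_area_day7"}:
                by_rep.setdefault(o.replicate, {})[o.response_kind] = o.value
        return [(p["frond_area_day1"], p["frond_area_day7"])
                for p in by_rep.values()
                if {"frond_area_day1", "frond_area_day7"} <= set(p)]

    control = area_pairs(series.control_rows)
    if not control:
        raise DomainError("Lemna series requires zero-concentration control wells")
    by_conc: dict[float, list] = {}
    for o in series.treated_rows:
        by_conc.setdefault(o.concentration, []).append(o)
    pts = []
    for conc in sorted(by_conc):
        treated = area_pairs(by_conc[conc])
        if treated:
            pts.append(lemna_growth_inhibition(treated, control, basis, conc))
    return pts


def effect_table(series: AssaySeries, lemna_basis: str = "yield") -> list[EffectPoint]:
    """Reduce a series to percent-effect points, dispatching on response kind.

    Raw luminescence series are not reduced here (they need explicit
    control pairing through :func:`luminescence_inhibition`); the generator
    and the shared schema carry Microtox data as ``inhibition_pct``.
    """
    kinds = {o.response_kind for o in series.observations}
    if "inhibition_pct" in kinds:
        return _inhibition_points(series)
    if {"affected_count", "total_count"} & kinds:
        return _count_points(series)
    if {"frond_area_day1", "frond_area_day7"} & kinds:
        return _lemna_points(series, lemna_basis)
    raise DomainError(f"no reducible response kind in series (kinds: {sorted(kinds)})")


def screening_gate(series: AssaySeries, threshold: float = 50.0,
                   tolerance: float = 2.0, lemna_basis: str = "yield") -> GateResult:
    """Admission rule for the dilution (potency-estimation) stage.

    A compound qualifies when its maximum observed effect across
    concentrations reaches ``threshold`` minus ``tolerance`` percentage
    points; results within the tolerance below the threshold are flagged
    borderline.  The default two-point tolerance admits compounds whose
    screening response sits just under 50%.
    """
    points = effect_table(series, lemna_basis=lemna_basis)
    if not points:
        raise DomainError("series has no effect points")
    max_effect = max(p.effect_pct for p in points)
    qualifies = max_effect >= threshold - tolerance
    borderline = qualifies and max_effect < threshold
    return GateResult(qualifies, max_effect, borderline)


def gamma_points(points: Sequence[EffectPoint]) -> list[GammaPoint]:
    """Map effect points to Γ space, dropping nothing (stimulation -> Γ=0)."""
    out = []
    for p in points:
        g = gamma_transform(p.effect_pct)
        out.append(GammaPoint(p.concentration, g.gamma, g.stimulated))
    return out
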