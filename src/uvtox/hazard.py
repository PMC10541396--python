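"""Persoone acute-hazard classification of potency estimates.

Single-compound potencies (mg/L) and mixture dilution potencies (% of the
undiluted sample) map onto the ordinal acute-hazard classes

    very_high_acute > high_acute > acute > low_acute > non_toxic

through monotone concentration bands.  On the mg/L scale the bands are
left-closed, right-open:

    [0, 0.1)  very_high_acute
    [0.1, 1)  high_acute
    [1, 10)   acute
    [10, 100) low_acute
    >= 100 (or EC50 not reached below 100) non_toxic

On the percent scale (a 50% effect must occur within the dilution series,
so "very high" is not assignable):

    (0, 25)   high_acute
    [25, 75)  acute
    [75, 100] low_acute
    EC50 not reached at full strength (censored) -> non_toxic

The published band edges carry internally inconsistent inequality signs;
the monotone scheme above reproduces every class assignment the source
tables actually make (see docs/methods.md).
"""

from __future__ import annotations

import enum
from typing import Sequence

import pandas as pd

from uvtox.dose_response import PotencyEstimate
from uvtox.errors import DomainError, ValidationError


class ToxicityClass(enum.IntEnum):
    """Ordinal hazard classes; larger value = more hazardous."""

    NON_TOXIC = 0
    LOW_ACUTE = 1
    ACUTE = 2
    HIGH_ACUTE = 3
    VERY_HIGH_ACUTE = 4

    @property
    def label(self) -> str:
        return {
            ToxicityClass.VERY_HIGH_ACUTE: "very high acute toxicity",
            ToxicityClass.HIGH_ACUTE: "high acute toxicity",
            ToxicityClass.ACUTE: "acute toxicity",
            ToxicityClass.LOW_ACUTE: "low acute toxicity",
            ToxicityClass.NON_TOXIC: "non-toxic",
        }[self]


def _value_and_censoring(ec) -> tuple[float, str]:
    if isinstance(ec, PotencyEstimate):
        return ec.value, ec.censored
    return float(ec), "none"


def classify_mg_per_l(ec: PotencyEstimate | float) -> ToxicityClass:
    """Band a single-compound potency on the mg/L scale.

    Accepts a plain number or a :class:`PotencyEstimate`; estimates
    censored above the tested maximum classify as non-toxic when the bound
    is at or beyond 100 mg/L (the true potency can only be larger).
    """
    value, censored = _value_and_censoring(ec)
    if censored == "below_min_tested":
        raise DomainError("potency censored below the tested range cannot be banded")
    if value <= 0:
        raise DomainError(f"potency must be positive, got {value:g}")
    if censored == "above_max_tested":
        if value >= 100:
            return ToxicityClass.NON_TOXIC
        raise DomainError(
            f"censored above {value:g} mg/L: band undetermined below 100 mg/L")
    if value < 0.1:
        return ToxicityClass.VERY_HIGH_ACUTE
    if value < 1:
        return ToxicityClass.HIGH_ACUTE
    if value < 10:
        return ToxicityClass.ACUTE
    if value < 100:
        return ToxicityClass.LOW_ACUTE
    return ToxicityClass.NON_TOXIC


def classify_percent(ec: PotencyEstimate | float) -> ToxicityClass:
    """Band a mixture dilution potency on the percent-of-sample scale.

    A censored estimate (no 50% effect at full strength) is non-toxic;
    a nominal value beyond 100% is treated the same way.
    """
    value, censored = _value_and_censoring(ec)
    if censored == "below_min_tested":
        raise DomainError("potency censored below the tested range cannot be banded")
    if censored == "above_max_tested":
        return ToxicityClass.NON_TOXIC
    if value <= 0:
        raise DomainError(f"potency must be positive, got {value:g}")
    if value > 100:
        # beyond the undiluted sample: effect never reaches 50%
        return ToxicityClass.NON_TOXIC
    if value < 25:
        return ToxicityClass.HIGH_ACUTE
    if value < 75:
        return ToxicityClass.ACUTE
    return ToxicityClass.LOW_ACUTE


def class_summary(estimates: Sequence[PotencyEstimate]) -> pd.DataFrame:
    """Compound x organism hazard-class matrix ("n.e." = not estimated).

    Censored estimates (potency not reached in the tested range) render as
    "n.e."; row and column order follow first appearance in the input.
    Conflicting duplicate estimates for one cell raise.
    """
    compounds: list[str] = []
    organisms: list[str] = []
    cells: dict[tuple[str, str], str] = {}
    for est in estimates:
        if est.compound is None or est.organism is None:
            raise ValidationError(
                "class_summary requires compound and organism on each estimate")
        if est.compound not in compounds:
            compounds.append(est.compound)
        if est.organism not in organisms:
            organisms.append(est.organism)
        if est.censored != "none":
            label = "n.e."
        elif est.conc_unit == "percent_of_stock":
            label = classify_percent(est).label
        else:
            label = classify_mg_per_l(est).label
        key = (est.compound, est.organism)
        if key in cells and cells[key] != label:
            raise ValidationError(
                f"conflicting duplicate estimates for {key}: "
                f"{cells[key]!r} vs {label!r}")
        cells[key] = label
    matrix = pd.DataFrame("n.e.", index=compounds, columns=organisms)
    for (comp, org), label in cells.items():
        matrix.loc[comp, org] = label
    matrix.index.name = "compound"
    return matrix
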