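"""Mixture toxic units and interaction typing.

For a mixture of n components at concentrations C_i with single-compound
potencies EC50_i (same organism, same exposure time), the toxic-unit sum

    TU_mix = sum_{i=1..n} C_i / EC50_i

predicts the interaction type: TU_mix < 1 synergism, TU_mix = 1 additive,
TU_mix > 1 antagonism (the degenerate additive band {1} is the default;
a practical band such as (0.8, 1.2) can be configured).  Ratios are
accumulated at full precision; rounding to the reporting precision
happens once, at write time.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from uvtox.errors import ConfigError, DomainError

INTERACTIONS = ("synergism", "additive", "antagonism", "not_estimable")


@dataclass(frozen=True)
class MixtureComponent:
    """One constituent of a tested mixture.

    ``ec50`` is the component's single-compound EC50 at the matching
    exposure time, or ``None`` when it could not be estimated (effect
    never reached 50% in the single-compound test).
    """

    code: str
    concentration: float  # C_i, mg/L
    ec50: float | None = None  # EC50_i, mg/L

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise DomainError(f"component concentration must be positive "
                              f"({self.code}: {self.concentration:g})")
        if self.ec50 is not None and self.ec50 <= 0:
            raise DomainError(f"component EC50 must be positive "
                              f"({self.code}: {self.ec50:g})")


@dataclass(frozen=True)
class ToxicUnitResult:
    """TU_mix for one mixture with its predicted interaction type."""

    mixture_id: str
    components: tuple[MixtureComponent, ...]
    ratios: tuple[float, ...]
    tu_mix: float | None
    interaction: str
    missing: tuple[str, ...] = field(default_factory=tuple)
    exposure_time: float | None = None
    time_unit: str | None = None


def classify_interaction(tu_mix: float,
                         additive_band: tuple[float, float] = (1.0, 1.0)) -> str:
    """Map a TU_mix value to synergism / additive / antagonism."""
    lo, hi = additive_band
    if lo > hi:
        raise ConfigError(f"additive band inverted: ({lo}, {hi})")
    if tu_mix <= 0:
        raise DomainError("tu_mix must be positive")
    if tu_mix < lo:
        return "synergism"
    if tu_mix <= hi:
        return "additive"
    return "antagonism"


def compute_tu_mix(components: Sequence[MixtureComponent],
                   additive_band: tuple[float, float] = (1.0, 1.0),
                   mixture_id: str | None = None,
                   **meta) -> ToxicUnitResult:
    """Sum the component toxic units C_i/EC50_i at full precision.

    Any component without an EC50 makes the whole mixture not estimable
    (its contribution to the sum is unknown); the offending codes are
    listed on the result.
    """
    if not components:
        raise DomainError("mixture must have at least one component")
    if len(components) == 1:
        warnings.warn("single-component 'mixture': TU is just C/EC50",
                      stacklevel=2)
    mixture_id = mixture_id or " + ".join(c.code for c in components)
    missing = tuple(c.code for c in components if c.ec50 is None)
    if missing:
        return ToxicUnitResult(mixture_id, tuple(components), (), None,
                               "not_estimable", missing, **meta)
    ratios = tuple(c.concentration / c.ec50 for c in components)
    tu = sum(ratios)
    return ToxicUnitResult(mixture_id, tuple(components), ratios, tu,
                           classify_interaction(tu, additive_band), (), **meta)


def tu_table(mixtures: Sequence[tuple[str, Sequence[tuple[str, float]]]],
             ec50_lookup: Mapping[str, float | None],
             additive_band: tuple[float, float] = (1.0, 1.0),
             **meta) -> list[ToxicUnitResult]:
    """Batch TU computation over a mixture design.

    ``mixtures`` holds (mixture_id, [(compound code, C_i mg/L), ...]) in
    report order; ``ec50_lookup`` maps every compound code to its EC50 or
    ``None`` when not estimable.  A code absent from the lookup entirely
    is an error (distinct from a known compound without an estimate).
    """
    results = []
    for mixture_id, comps in mixtures:
        for code, _ in comps:
            if code not in ec50_lookup:
                raise KeyError(f"no EC50 entry (not even 'absent') for "
                               f"compound {code!r}")
        components = [MixtureComponent(code, c_i, ec50_lookup[code])
                      for code, c_i in comps]
        results.append(compute_tu_mix(components, additive_band,
                                      mixture_id, **meta))
    return results


def summarize_interactions(results: Sequence[ToxicUnitResult]) -> Counter:
    """Counts of each interaction type over a TU table."""
    return Counter(r.interaction for r in results)
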