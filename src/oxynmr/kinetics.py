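"""Stage-wise kinetics of degradation and formation on concentration time courses.

The oxidation course is described by per-stage linear rates rather than by
mechanistic rate constants: the observation window is partitioned by a
:class:`StageScheme` (default breakpoints day 0, 8, 11, 14, 16 — slow
initiation, accelerating propagation, fastest degradation, terminal stage) and
an ordinary least-squares slope is fitted inside each stage.  A shared
breakpoint day belongs to both adjacent stages.  Event detection (appearance
above the detection limit, maximum, disappearance) uses sampled days only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .synth import ACYL_TOTAL_MMOL, ConcentrationTable

__all__ = [
    "StageScheme",
    "CompoundEvents",
    "KineticsSummary",
    "stage_rates",
    "detect_events",
    "formation_fraction",
    "percent_to_mmol",
    "summarize_timecourse",
    "DEFAULT_SCHEME",
    "TOCOPHEROL_SCHEME",
]

Series = Sequence[tuple[float, float]]


@dataclass(frozen=True)
class StageScheme:
    """Ordered day breakpoints partitioning the time course into stages."""

    breakpoints: tuple[float, ...] = (0.0, 8.0, 11.0, 14.0, 16.0)

    def __post_init__(self) -> None:
        bp = self.breakpoints
        if len(bp) < 2 or any(a >= b for a, b in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing, >= 2 of them")

    @property
    def stages(self) -> list[tuple[float, float]]:
        return list(zip(self.breakpoints, self.breakpoints[1:]))


DEFAULT_SCHEME = StageScheme()
# the main antioxidant degrades in two stages: a lag up to day 2, then a
# near-constant decline until it is gone around day 11
TOCOPHEROL_SCHEME = StageScheme((0.0, 2.0, 11.0))


@dataclass(frozen=True)
class CompoundEvents:
    appearance_day: float | None
    max_day: float
    max_value: float
    disappeared_day: float | None


@dataclass
class KineticsSummary:
    """Per-compound events and per-stage OLS rates (mmol/mol TG per day)."""

    scheme: StageScheme
    lod: float
    events: dict[str, CompoundEvents] = field(default_factory=dict)
    stage_rates: dict[str, list[float | None]] = field(default_factory=dict)


def stage_rates(series: Series, scheme: StageScheme) -> list[float | None]:
    """OLS slope of concentration vs day inside each stage.

    Stage intervals are inclusive at both ends, so a sampled day equal to a
    shared breakpoint enters both adjacent fits.  Stages with fewer than two
    sampled days yield ``None`` (rate undefined), not an error.  Rates are
    signed: negative means degradation.
    """
    pts = sorted((float(d), float(c)) for d, c in series)
    out: list[float | None] = []
    for lo, hi in scheme.stages:
        sub = [(d, c) for d, c in pts if lo <= d <= hi]
        if len(sub) < 2:
            out.append(None)
            continue
        x = np.array([d for d, _ in sub])
        y = np.array([c for _, c in sub])
        if np.allclose(y, y[0]):
            out.append(0.0)  # linregress is exact here too; keep -0.0 tidy
            continue
        out.append(float(stats.linregress(x, y).slope))
    return out


def detect_events(series: Series, lod: float) -> CompoundEvents:
    """Appearance / maximum / disappearance on the sampled days.

    appearance: first sampled day with concentration > lod (None if never);
    maximum: ties broken to the earliest day; disappearance: first sampled
    day after appearance with concentration <= lod (None if not observed).
    """
    pts = sorted((float(d), float(c)) for d, c in series)
    if not pts:
        raise ValueError("series is empty")
    days = [d for d, _ in pts]
    concs = [c for _, c in pts]
    appearance = next((d for d, c in pts if c > lod), None)
    imax = int(np.argmax(concs))
    disappeared = None
    if appearance is not None:
        disappeared = next((d for d, c in pts if d > appearance and c <= lod), None)
    return CompoundEvents(
        appearance_day=appearance,
        max_day=days[imax],
        max_value=concs[imax],
        disappeared_day=disappeared,
    )


def formation_fraction(
    product_series: Series,
    substrate_series: Series,
    stage: tuple[float, float],
    scheme: StageScheme | None = None,
) -> float | None:
    """Percentage of the substrate's loss rate accounted for by the product.

    100 x (product stage rate) / |substrate stage rate| over one stage; the
    complement is the share of the substrate routed to other products.
    Returns None when the substrate rate is zero (undefined).
    """
    one = StageScheme(tuple(stage))
    (p_rate,) = stage_rates(product_series, one)
    (s_rate,) = stage_rates(substrate_series, one)
    if p_rate is None or s_rate is None or s_rate == 0:
        return None
    return 100.0 * p_rate / abs(s_rate)


def percent_to_mmol(pct: float) -> float:
    """Molar % of total acyl groups -> mmol/mol TG (three chains per TG)."""
    if not 0 <= pct <= 100:
        raise ValueError("percentage must be within [0, 100]")
    return pct * ACYL_TOTAL_MMOL / 100.0


def summarize_timecourse(
    table: ConcentrationTable,
    lod: float = 0.5,
    scheme: StageScheme = DEFAULT_SCHEME,
    per_compound_schemes: Mapping[str, StageScheme] | None = None,
) -> KineticsSummary:
    """Events and stage rates for every compound column of a time course.

    ``per_compound_schemes`` overrides the stage breakpoints for individual
    compounds (by default gamma-tocopherol uses its two-stage scheme)."""
    if len(table.days) < 2:
        raise ValueError("need at least two sampled days")
    overrides = dict(per_compound_schemes or {"gamma_tocopherol": TOCOPHEROL_SCHEME})
    summary = KineticsSummary(scheme=scheme, lod=lod)
    for cid in table.data.columns:
        series = table.series(cid)
        summary.events[cid] = detect_events(series, lod)
        summary.stage_rates[cid] = stage_rates(series, overrides.get(cid, scheme))
    return summary
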