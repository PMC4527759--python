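"""Build cohort life tables and schedule-level fecundity/survival summaries.

The central object is the age-classified life table of a synchronized
cohort: for each checkpoint interval ending at age ``x``,

* ``l_x`` — fraction of the initial cohort (n0) alive at ``x``;
* ``m_x`` — hatched juveniles produced in the interval per individual
  alive at ``x`` (juveniles are credited to the interval in which their
  egg was laid, matching the leave-in-drop scoring protocol).

Deaths are counted at the first checkpoint at or after the death time, so
``l_x`` is the end-of-interval convention; the same population normalizes
``m_x`` by default (``denominator="interval_end"``), which makes
``sum(l_x * m_x)`` equal to total juveniles / n0 exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import (
    DEAD,
    AlignmentError,
    IndividualRecord,
    LifeTable,
    LifeTableRow,
    ObservationSchedule,
    ValidationError,
)

__all__ = [
    "CohortSummary",
    "FecundityPoint",
    "build_life_table",
    "net_reproductive_rate",
    "total_fertility_rate",
    "fecundity_schedule",
    "cohort_summary",
]


@dataclass(frozen=True)
class CohortSummary:
    """Per-cohort trait summary (means with SDs where defined).

    Lifespan (days), first-egg and peak-laying-rate ages (hours) and
    lifetime egg totals are computed over individuals that reached sexual
    maturity (laid at least one egg); juvenile losses appear as
    ``juvenile_mortality`` = died-before-first-egg / n0.
    """

    n0: int
    n_mature: int
    mean_lifespan_d: float | None
    sd_lifespan_d: float | None
    age_min_h: float | None
    sd_age_min_h: float | None
    age_max_h: float | None
    sd_age_max_h: float | None
    total_eggs: float | None
    sd_total_eggs: float | None
    juvenile_mortality: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.juvenile_mortality <= 1.0):
            raise ValidationError("juvenile_mortality outside [0, 1]")
        if (
            self.age_min_h is not None
            and self.age_max_h is not None
            and self.age_min_h > self.age_max_h + 1e-9
        ):
            raise ValidationError("age at first egg exceeds age at peak laying rate")


@dataclass(frozen=True)
class FecundityPoint:
    """Cohort fecundity at one checkpoint: the arithmetic mean over alive,
    mature individuals of their per-interval hatch fraction (as a percent;
    ``None`` when no individual laid eggs in the interval), plus the mean
    number of eggs laid per such individual."""

    time_x: float
    fecundity_pct: float | None
    eggs_per_interval: float

    def __post_init__(self) -> None:
        if self.fecundity_pct is not None and not (
            -1e-9 <= self.fecundity_pct <= 100.0 + 1e-9
        ):
            raise ValidationError("fecundity percentage outside [0, 100]")


def _death_checkpoint(ind: IndividualRecord) -> float | None:
    iv = ind.death_interval
    return None if iv is None else iv[1]


def build_life_table(
    cohort: Sequence[IndividualRecord],
    schedule: ObservationSchedule,
    n0: int | None = None,
    denominator: str = "interval_end",
    trim: bool = True,
) -> LifeTable:
    """Aggregate per-individual records into a cohort life table.

    Every record interval must coincide with a schedule interval
    (:class:`~nemalife.records.AlignmentError` otherwise).  Individuals with
    no record in an interval contribute zero eggs and keep their current
    vital status.  With ``trim=True`` the table is cut to the reproductive
    window (first to last interval with any juveniles), retaining interior
    zero-production rows; a cohort with no reproduction is returned whole.

    ``denominator`` selects the population normalizing ``m_x``:
    ``"interval_end"`` (default — individuals alive at the closing
    checkpoint, the same count as ``l_x``) or ``"interval_start"``.
    """
    if denominator not in ("interval_end", "interval_start"):
        raise ValueError(f"unknown m_x denominator {denominator!r}")
    cohort = list(cohort)
    if n0 is None:
        n0 = len(cohort)
    if n0 < 1:
        raise ValidationError("cohort must contain at least one individual")

    ncp = len(schedule)
    eggs = np.zeros(ncp, dtype=np.int64)
    juv = np.zeros(ncp, dtype=np.int64)
    death_cp = []  # checkpoint index at which each individual is first dead
    censor_cp = []
    for ind in cohort:
        for r in ind.records:
            i = schedule.index_of_checkpoint(r.interval_end, r.interval_start)
            eggs[i] += r.eggs_laid
            juv[i] += r.juveniles_hatched
        dcp = _death_checkpoint(ind)
        death_cp.append(None if dcp is None else schedule.index_of_checkpoint(dcp))
        censor_cp.append(
            None
            if ind.censored_at is None
            else schedule.interval_index(ind.censored_at)
        )

    alive_end = np.empty(ncp, dtype=np.int64)  # risk set at each checkpoint
    at_risk = np.empty(ncp, dtype=np.int64)  # excludes censored individuals
    for i in range(ncp):
        alive = sum(1 for d in death_cp if d is None or d > i)
        censored = sum(
            1
            for d, c in zip(death_cp, censor_cp)
            if c is not None and c <= i and (d is None or d > i)
        )
        alive_end[i] = alive
        at_risk[i] = alive - censored

    rows = []
    for i in range(ncp):
        lx = at_risk[i] / n0
        if denominator == "interval_end":
            denom = at_risk[i]
        else:
            denom = at_risk[i - 1] if i > 0 else n0
        mx = (juv[i] / denom) if denom > 0 else 0.0
        rows.append(
            LifeTableRow(
                time_x=schedule.checkpoints[i],
                width_d=schedule.widths[i],
                lx=float(lx),
                mx=float(mx),
            )
        )

    if trim and juv.any():
        nz = np.flatnonzero(juv)
        rows = rows[nz[0] : nz[-1] + 1]
    return LifeTable(rows=tuple(rows), n0=n0)


def net_reproductive_rate(lt: LifeTable) -> float:
    """R0 = sum over age classes of l_x * m_x (offspring per newborn)."""
    return float(np.sum(lt.lxmx)) if len(lt) else 0.0


def total_fertility_rate(lt: LifeTable) -> float:
    """TFR = sum of m_x (offspring of an individual surviving to the last age)."""
    return float(np.sum(lt.mx)) if len(lt) else 0.0


def fecundity_schedule(
    cohort: Sequence[IndividualRecord],
) -> list[FecundityPoint]:
    """Per-interval cohort fecundity, following the individual-mean protocol.

    For each observation interval, every individual that is sexually mature
    (has laid an egg at or before this interval) and alive at the interval's
    end contributes its hatch fraction ``juveniles/eggs`` (individuals with
    zero eggs in the interval are excluded from that mean, as the fraction
    is undefined); the mean is reported as a percentage.  ``eggs_per_interval``
    is the mean egg count over the same mature, alive individuals.
    Checkpoints with no mature, alive individual are omitted.
    """
    # collect the union of observed intervals
    seen: dict[tuple[float, float], None] = {}
    for ind in cohort:
        for r in ind.records:
            seen.setdefault((r.interval_end, r.interval_start), None)
    intervals = sorted(seen.keys())

    points: list[FecundityPoint] = []
    for end, start in intervals:
        ratios: list[float] = []
        egg_counts: list[int] = []
        for ind in cohort:
            rec = next(
                (
                    r
                    for r in ind.records
                    if abs(r.interval_end - end) < 1e-9
                    and abs(r.interval_start - start) < 1e-9
                ),
                None,
            )
            if rec is None or rec.status_at_end == DEAD:
                continue
            first = ind.first_egg_interval
            if first is None or first[1] > end + 1e-9:
                continue  # not yet mature
            egg_counts.append(rec.eggs_laid)
            if rec.eggs_laid > 0:
                ratios.append(rec.juveniles_hatched / rec.eggs_laid)
        if not egg_counts:
            continue
        pct = 100.0 * float(np.mean(ratios)) if ratios else None
        points.append(
            FecundityPoint(
                time_x=end,
                fecundity_pct=pct,
                eggs_per_interval=float(np.mean(egg_counts)),
            )
        )
    return points


def _mean_sd(values: Iterable[float]) -> tuple[float | None, float | None]:
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        return None, None
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd


def cohort_summary(cohort: Sequence[IndividualRecord]) -> CohortSummary:
    """Trait means (± SD) for a cohort: lifespan, first-egg age, age at the
    individual peak egg-laying rate, lifetime egg totals, and juvenile
    mortality.  Interval-censored event times are taken at interval
    midpoints."""
    cohort = list(cohort)
    n0 = len(cohort)
    mature = [ind for ind in cohort if ind.matured]
    juvenile_deaths = sum(
        1 for ind in cohort if not ind.matured and ind.death_interval is not None
    )

    lifespans = [
        ind.death_estimate() / 24.0 for ind in mature if ind.death_estimate() is not None
    ]
    first_eggs = [ind.maturity_estimate() for ind in mature]

    peak_ages = []
    for ind in mature:
        best_rate, best_age = -math.inf, None
        for r in ind.records:
            rate = r.eggs_laid / (r.interval_end - r.interval_start)
            if rate > best_rate + 1e-12:
                best_rate = rate
                best_age = 0.5 * (r.interval_start + r.interval_end)
        peak_ages.append(best_age)

    eggs = [float(ind.total_eggs) for ind in mature]

    mean_ls, sd_ls = _mean_sd(lifespans)
    mean_am, sd_am = _mean_sd(a for a in first_eggs if a is not None)
    mean_ax, sd_ax = _mean_sd(a for a in peak_ages if a is not None)
    mean_te, sd_te = _mean_sd(eggs)
    return CohortSummary(
        n0=n0,
        n_mature=len(mature),
        mean_lifespan_d=mean_ls,
        sd_lifespan_d=sd_ls,
        age_min_h=mean_am,
        sd_age_min_h=sd_am,
        age_max_h=mean_ax,
        sd_age_max_h=sd_ax,
        total_eggs=mean_te,
        sd_total_eggs=sd_te,
        juvenile_mortality=juvenile_deaths / n0 if n0 else 0.0,
    )
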