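"""Rate-based demography on a cohort life table.

All quantities derive from the discrete Euler-Lotka identity

    sum_x  exp(-r_m * x) * l_x * m_x  =  1,

with ages ``x`` taken from the life-table rows under a selectable
*age convention* (``interval_end`` — the printed checkpoint times, the
default — ``interval_midpoint`` or ``interval_start``).  Ages are stored in
hours; the intrinsic rate of natural increase ``r_m`` is expressed per day,
so every exponent converts hours to days explicitly.

The left-hand side is strictly decreasing in ``r_m`` whenever any
reproduction occurs at a positive age, so the root is unique, bracketed and
refined to |LHS - 1| < 1e-10.  An independent cross-check builds the Leslie
projection matrix on a uniform age grid and takes the log of its dominant
eigenvalue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .records import LifeTable, ValidationError
from .lifetable import net_reproductive_rate, total_fertility_rate

__all__ = [
    "CONVENTIONS",
    "DemographyError",
    "NoRootError",
    "UndefinedMetricError",
    "DemographyResult",
    "HatchingEstimate",
    "euler_lotka_lhs",
    "solve_rm",
    "doubling_time",
    "generation_time_g0",
    "generation_time_g1",
    "generation_time_gh",
    "hatching_time",
    "leslie_growth_oracle",
    "full_demography",
]

CONVENTIONS = ("interval_end", "interval_midpoint", "interval_start")

_ROOT_TOL = 1e-10


class DemographyError(ValueError):
    """A demographic quantity is undefined for the given inputs."""


class NoRootError(DemographyError):
    """The Euler-Lotka equation has no root (no reproduction)."""


class UndefinedMetricError(DemographyError):
    """Requested metric is undefined (e.g. doubling time at r_m <= 0)."""


@dataclass(frozen=True)
class DemographyResult:
    """Bundle of life-table metrics under one age convention.

    Units: ``r0``/``tfr`` offspring per individual; ``rm`` per day; ``pdt``,
    ``g0``, ``g1``, ``gh`` hours.  Fields are ``None`` where undefined
    (``rm`` and the generation times when R0 = 0; ``pdt`` and ``g1`` when
    r_m <= 0 / r_m = 0).
    """

    r0: float
    tfr: float
    rm: float | None
    pdt: float | None
    g0: float | None
    g1: float | None
    gh: float | None
    convention: str

    def to_dict(self) -> dict:
        return {
            "R0": self.r0,
            "TFR": self.tfr,
            "rm_per_day": self.rm,
            "PDT_h": self.pdt,
            "G0_h": self.g0,
            "G1_h": self.g1,
            "Gh_h": self.gh,
            "convention": self.convention,
        }


@dataclass(frozen=True)
class HatchingEstimate:
    """Egg-to-hatch duration estimated from a fixed-and-stained snapshot:
    after leaving worms to lay for ``t_h`` hours, the still-unhatched egg
    fraction scales the experiment duration."""

    h_t: float
    n_eggs: int
    n_juv: int
    t_h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.h_t <= self.t_h + 1e-12):
            raise ValidationError("hatching-time estimate outside [0, t_h]")


def _check_convention(convention: str) -> None:
    if convention not in CONVENTIONS:
        raise ValueError(
            f"unknown age convention {convention!r}; expected one of {CONVENTIONS}"
        )


def euler_lotka_lhs(
    rm: float, lt: LifeTable, convention: str = "interval_end"
) -> float:
    """Discounted lifetime reproduction sum(exp(-rm * x) * l_x * m_x).

    ``rm`` is per day, ages per the convention in hours.  At ``rm = 0`` the
    value equals R0 exactly.
    """
    _check_convention(convention)
    if len(lt) == 0:
        return 0.0
    x_days = lt.ages(convention) / 24.0
    with np.errstate(over="ignore"):
        return float(np.sum(np.exp(-rm * x_days) * lt.lx * lt.mx))


def solve_rm(lt: LifeTable, convention: str = "interval_end") -> float:
    """Intrinsic rate of natural increase (per day): the unique root of the
    Euler-Lotka equation, positive iff R0 > 1, zero iff R0 = 1."""
    _check_convention(convention)
    r0 = net_reproductive_rate(lt)
    if r0 <= 0.0:
        raise NoRootError("R0 = 0: the Euler-Lotka equation has no root")
    x_days = lt.ages(convention) / 24.0
    if not np.any((lt.lxmx > 0) & (x_days > 0)):
        raise NoRootError("all reproduction occurs at age <= 0; growth rate undefined")

    def f(r: float) -> float:
        return euler_lotka_lhs(r, lt, convention) - 1.0

    lo, hi = -5.0, 10.0
    for _ in range(60):
        if f(hi) <= 0.0:
            break
        hi *= 2.0
    for _ in range(60):
        if f(lo) >= 0.0:
            break
        lo *= 2.0
    root = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    # polish with Newton steps until the discounted sum is 1 to 1e-10
    for _ in range(8):
        err = f(root)
        if abs(err) < _ROOT_TOL:
            break
        deriv = -float(np.sum(x_days * np.exp(-root * x_days) * lt.lxmx))
        if deriv == 0.0:
            break
        root -= err / deriv
    return float(root)


def doubling_time(rm: float) -> float:
    """Population doubling time ln(2)/r_m, in hours (r_m per day)."""
    if rm <= 0.0:
        raise UndefinedMetricError(
            f"doubling time undefined for non-growing population (rm = {rm})"
        )
    return math.log(2.0) / rm * 24.0


def generation_time_g0(lt: LifeTable, convention: str = "interval_end") -> float:
    """Cohort generation time: the l_x*m_x-weighted mean reproductive age (h)."""
    r0 = net_reproductive_rate(lt)
    if r0 <= 0.0:
        raise UndefinedMetricError("G0 undefined when R0 = 0")
    x = lt.ages(convention)
    return float(np.sum(x * lt.lxmx) / r0)


def generation_time_g1(r0: float, rm: float) -> float:
    """Time (h) for a population growing at r_m (per day) to grow by R0."""
    if r0 <= 0.0:
        raise UndefinedMetricError("G1 undefined when R0 = 0")
    if rm == 0.0:
        raise UndefinedMetricError("G1 undefined at rm = 0")
    return math.log(r0) / rm * 24.0


def generation_time_gh(
    lt: LifeTable, rm: float, convention: str = "interval_end"
) -> float:
    """Mean parental age (h) in the growth-discounted reproductive schedule,
    sum(x * exp(-rm*x) * l_x * m_x).

    The closed form presupposes that ``rm`` is the Euler-Lotka root of this
    table, where the discounted sum is 1; for any other ``rm`` the result is
    normalized by the discounted sum so it remains a weighted mean age.
    """
    _check_convention(convention)
    x = lt.ages(convention)
    w = np.exp(-rm * x / 24.0) * lt.lxmx
    denom = float(np.sum(w))
    if denom <= 0.0:
        raise UndefinedMetricError("Gh undefined when R0 = 0")
    return float(np.sum(x * w) / denom)


def hatching_time(n_eggs: int, n_juv: int, t_h: float) -> HatchingEstimate:
    """Estimate the egg-to-hatch time from snapshot counts.

    ``n_eggs`` unhatched eggs and ``n_juv`` hatched juveniles scored after
    ``t_h`` hours of laying give H_t = n_eggs / (n_juv + n_eggs) * t_h.
    """
    if n_eggs < 0 or n_juv < 0:
        raise ValidationError("egg and juvenile counts must be nonnegative")
    if n_eggs + n_juv == 0:
        raise UndefinedMetricError("hatching time undefined with no eggs scored")
    if t_h <= 0:
        raise ValidationError("experiment duration must be positive")
    h_t = n_eggs / (n_juv + n_eggs) * t_h
    return HatchingEstimate(h_t=h_t, n_eggs=n_eggs, n_juv=n_juv, t_h=t_h)


def leslie_growth_oracle(
    lt: LifeTable, step: float = 1.0, convention: str = "interval_end"
) -> float:
    """Population growth rate (per day) from a Leslie projection matrix.

    The life table is resampled onto a uniform age grid of ``step`` hours:
    each reproductive mass l_x*m_x acts at the end of the age class
    containing its convention age, survival entries are ratios of the
    survivorship step function at class boundaries, and the returned rate is
    ln(dominant eigenvalue)/step.  Independent of the root-finder in
    :func:`solve_rm`.
    """
    _check_convention(convention)
    if len(lt) == 0:
        raise NoRootError("empty life table")
    if step > float(np.min(lt.width_d)) + 1e-9:
        raise ValidationError(
            f"step {step} h exceeds the finest life-table interval; "
            "growth cannot be resolved"
        )
    x = lt.ages(convention)
    mass = lt.lxmx
    keep = mass > 0
    if not np.any(keep):
        raise NoRootError("R0 = 0: no reproduction to project")
    if np.any(x[keep] <= 0):
        raise ValidationError("reproductive mass at age <= 0 cannot be projected")

    # class j covers ages (j*step, (j+1)*step]; mass at age a -> class ceil(a/step)-1
    cls = np.ceil(x / step - 1e-9).astype(int) - 1
    n_classes = int(cls[keep].max()) + 1
    fert_mass = np.zeros(n_classes)
    np.add.at(fert_mass, cls[keep], mass[keep])

    # survivorship step function from the table's checkpoint times
    times = lt.time_x
    lx = lt.lx

    def surv(t: float) -> float:
        i = np.searchsorted(times, t + 1e-9) - 1
        return 1.0 if i < 0 else float(lx[i])

    l_start = np.array([surv(j * step) for j in range(n_classes + 1)])
    last = int(cls[keep].max())
    if np.any(l_start[: last + 1] <= 0):
        raise ValidationError("survivorship reaches 0 before the last reproductive age")

    A = np.zeros((n_classes, n_classes))
    A[0, :] = fert_mass / l_start[:n_classes]
    for j in range(n_classes - 1):
        A[j + 1, j] = l_start[j + 1] / l_start[j]
    lam = float(np.max(np.abs(np.linalg.eigvals(A))))
    return math.log(lam) / (step / 24.0)


def full_demography(
    lt: LifeTable, convention: str = "interval_end"
) -> DemographyResult:
    """All Table-style metrics for one life table under one age convention."""
    _check_convention(convention)
    r0 = net_reproductive_rate(lt)
    tfr = total_fertility_rate(lt)
    if r0 <= 0.0:
        return DemographyResult(
            r0=r0, tfr=tfr, rm=None, pdt=None, g0=None, g1=None, gh=None,
            convention=convention,
        )
    rm = solve_rm(lt, convention)
    pdt = doubling_time(rm) if rm > 0 else None
    g0 = generation_time_g0(lt, convention)
    g1 = generation_time_g1(r0, rm) if rm != 0 else None
    gh = generation_time_gh(lt, rm, convention)
    return DemographyResult(
        r0=r0, tfr=tfr, rm=rm, pdt=pdt, g0=g0, g1=g1, gh=gh, convention=convention
    )
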