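"""Data model and TSV I/O for individually observed nematode cohorts.

The experimental design this schema mirrors is the hanging-drop method:
synchronized individuals are kept one-per-drop and checked at scheduled
times, when eggs laid since the previous checkpoint are counted, the drop
is left for 48 h so fertile eggs hatch and can be scored, and vital status
is recorded.  Everything is therefore interval-censored to the resolution
of the observation schedule.

Two delimited-text formats are supported, both tab-separated, UTF-8,
"." decimal, header required:

* cohort log — one row per individual per checkpoint interval with columns
  ``individual_id  interval_start  interval_end  eggs_laid
  juveniles_hatched  status``;
* life table — columns ``time  D  lx  mx  [lxmx]`` (the product column is
  recomputed on read; a discrepancy beyond 0.01 is logged as a warning).
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "AlignmentError",
    "ObservationSchedule",
    "ObservationRecord",
    "IndividualRecord",
    "LifeTableRow",
    "LifeTable",
    "read_cohort",
    "write_cohort",
    "read_life_table",
    "write_life_table",
    "infer_n0",
    "load_pacificus_life_table",
]

logger = logging.getLogger(__name__)

ALIVE = "alive"
DEAD = "dead"

#: maximum tolerated gap between a printed two-decimal l_x and a cohort
#: fraction k/n0 — strictly below the half-ulp of two-decimal rounding.
_LX_ROUNDING_TOL = 0.005

COHORT_COLUMNS = (
    "individual_id",
    "interval_start",
    "interval_end",
    "eggs_laid",
    "juveniles_hatched",
    "status",
)


class FormatError(ValueError):
    """A file does not follow the expected delimited-text layout."""


class ValidationError(ValueError):
    """A record or table violates a domain invariant."""


class AlignmentError(ValidationError):
    """Observation records do not align with the observation schedule."""


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObservationSchedule:
    """Ordered checkpoint times (hours since cohort hatch) with interval widths.

    Checkpoint ``i`` closes the half-open age interval
    ``(checkpoints[i] - widths[i], checkpoints[i]]``.  A schedule is
    *contiguous* when consecutive intervals tile the age axis; the published
    schedule for *P. pacificus* is contiguous except at the printed 6 h to
    12 h transition, so contiguity is checkable but not enforced.
    """

    checkpoints: tuple[float, ...]
    widths: tuple[float, ...]

    def __post_init__(self) -> None:
        cps = tuple(float(c) for c in self.checkpoints)
        wds = tuple(float(w) for w in self.widths)
        object.__setattr__(self, "checkpoints", cps)
        object.__setattr__(self, "widths", wds)
        if len(cps) != len(wds):
            raise ValidationError("checkpoints and widths differ in length")
        if any(w <= 0 for w in wds):
            raise ValidationError("interval widths must be strictly positive")
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValidationError("checkpoints must be strictly increasing")
        for i in range(1, len(cps)):
            if cps[i] - wds[i] < cps[i - 1] - 1e-9:
                raise ValidationError(
                    f"interval ending at {cps[i]} h overlaps the previous checkpoint"
                )

    @classmethod
    def from_breaks(cls, breaks: Sequence[float]) -> "ObservationSchedule":
        """Contiguous schedule from interval boundaries ``[t0, t1, ..., tn]``."""
        breaks = [float(b) for b in breaks]
        if len(breaks) < 2:
            raise ValidationError("need at least two break points")
        return cls(
            checkpoints=tuple(breaks[1:]),
            widths=tuple(b - a for a, b in zip(breaks, breaks[1:])),
        )

    @classmethod
    def uniform(cls, width: float, horizon: float, start: float = 0.0) -> "ObservationSchedule":
        n = math.ceil((horizon - start) / width - 1e-9)
        breaks = [start + i * width for i in range(n + 1)]
        return cls.from_breaks(breaks)

    @property
    def horizon(self) -> float:
        return self.checkpoints[-1]

    def __len__(self) -> int:
        return len(self.checkpoints)

    def is_contiguous(self) -> bool:
        return all(
            abs((b - a) - w) < 1e-9
            for a, b, w in zip(self.checkpoints, self.checkpoints[1:], self.widths[1:])
        )

    def intervals(self) -> Iterator[tuple[float, float]]:
        for c, w in zip(self.checkpoints, self.widths):
            yield (c - w, c)

    def interval_index(self, t: float) -> int:
        """Index of the interval containing time ``t`` (start-exclusive)."""
        i = bisect_left(self.checkpoints, t - 1e-9)
        if i >= len(self.checkpoints):
            raise AlignmentError(f"time {t} h lies beyond the schedule horizon")
        if t <= self.checkpoints[i] - self.widths[i] + 1e-9:
            raise AlignmentError(f"time {t} h falls in a gap of the schedule")
        return i

    def index_of_checkpoint(self, end: float, start: float | None = None) -> int:
        """Index of the interval whose end equals ``end`` (and start, if given)."""
        i = bisect_left(self.checkpoints, end - 1e-9)
        if i >= len(self.checkpoints) or abs(self.checkpoints[i] - end) > 1e-9:
            raise AlignmentError(f"no checkpoint at {end} h in the schedule")
        if start is not None and abs((self.checkpoints[i] - self.widths[i]) - start) > 1e-9:
            raise AlignmentError(
                f"interval ({start}, {end}] does not match the schedule interval "
                f"ending at {end} h"
            )
        return i


# ---------------------------------------------------------------------------
# per-individual observations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObservationRecord:
    """One individual's counts over one checkpoint interval."""

    individual_id: str
    interval_start: float
    interval_end: float
    eggs_laid: int
    juveniles_hatched: int
    status_at_end: str

    def __post_init__(self) -> None:
        if self.interval_end <= self.interval_start:
            raise ValidationError(
                f"{self.individual_id}: interval_end ({self.interval_end}) must exceed "
                f"interval_start ({self.interval_start})"
            )
        if self.eggs_laid < 0 or self.juveniles_hatched < 0:
            raise ValidationError(f"{self.individual_id}: counts must be nonnegative")
        if self.juveniles_hatched > self.eggs_laid:
            raise ValidationError(
                f"{self.individual_id}, interval ({self.interval_start}, "
                f"{self.interval_end}]: juveniles_hatched ({self.juveniles_hatched}) "
                f"exceeds eggs_laid ({self.eggs_laid})"
            )
        if self.status_at_end not in (ALIVE, DEAD):
            raise ValidationError(
                f"{self.individual_id}: status must be '{ALIVE}' or '{DEAD}', "
                f"got {self.status_at_end!r}"
            )


@dataclass(frozen=True)
class IndividualRecord:
    """All observations of one individual, ordered by interval start.

    ``death_time`` is a point estimate inside the censoring interval (the
    midpoint of the first interval reported dead, unless the caller knows
    better); ``censored_at`` marks individuals still alive when observation
    stopped.  ``maturity_time`` may be supplied or derived as the midpoint
    of the first interval with eggs.
    """

    individual_id: str
    records: tuple[ObservationRecord, ...]
    hatch_offset: float = 0.0
    death_time: float | None = None
    censored_at: float | None = None
    maturity_time: float | None = None

    def __post_init__(self) -> None:
        recs = tuple(self.records)
        object.__setattr__(self, "records", recs)
        if self.hatch_offset < 0:
            raise ValidationError(f"{self.individual_id}: negative hatch_offset")
        seen_dead = False
        prev_start = -math.inf
        for r in recs:
            if r.individual_id != self.individual_id:
                raise ValidationError(
                    f"record for {r.individual_id!r} attached to {self.individual_id!r}"
                )
            if seen_dead:
                raise ValidationError(
                    f"{self.individual_id}: observation after death "
                    f"(interval starting {r.interval_start} h)"
                )
            if r.interval_start < prev_start:
                raise ValidationError(f"{self.individual_id}: records out of order")
            prev_start = r.interval_start
            seen_dead = r.status_at_end == DEAD
        if self.death_time is not None:
            last_dead = self.death_interval
            if last_dead is None:
                raise ValidationError(
                    f"{self.individual_id}: death_time given but no interval "
                    "has status dead"
                )
            lo, hi = last_dead
            if not (lo < self.death_time <= hi + 1e-9):
                raise ValidationError(
                    f"{self.individual_id}: death_time {self.death_time} h outside "
                    f"the dead interval ({lo}, {hi}]"
                )

    @property
    def death_interval(self) -> tuple[float, float] | None:
        for r in self.records:
            if r.status_at_end == DEAD:
                return (r.interval_start, r.interval_end)
        return None

    @property
    def first_egg_interval(self) -> tuple[float, float] | None:
        for r in self.records:
            if r.eggs_laid > 0:
                return (r.interval_start, r.interval_end)
        return None

    @property
    def matured(self) -> bool:
        return self.first_egg_interval is not None

    def maturity_estimate(self) -> float | None:
        """First-egg age: supplied maturity_time, else censoring-interval midpoint."""
        if self.maturity_time is not None:
            return self.maturity_time
        iv = self.first_egg_interval
        return None if iv is None else 0.5 * (iv[0] + iv[1])

    def death_estimate(self) -> float | None:
        if self.death_time is not None:
            return self.death_time
        iv = self.death_interval
        return None if iv is None else 0.5 * (iv[0] + iv[1])

    @property
    def total_eggs(self) -> int:
        return sum(r.eggs_laid for r in self.records)

    @property
    def total_juveniles(self) -> int:
        return sum(r.juveniles_hatched for r in self.records)


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeTableRow:
    """One age class: interval end ``time_x`` (h), width ``width_d`` (h),
    survival probability ``lx`` and per-capita fecundity ``mx`` (hatched
    juveniles per surviving individual)."""

    time_x: float
    width_d: float
    lx: float
    mx: float

    def __post_init__(self) -> None:
        if self.width_d <= 0:
            raise ValidationError(f"row at {self.time_x} h: nonpositive width")
        if not (0.0 <= self.lx <= 1.0 + 1e-12):
            raise ValidationError(f"row at {self.time_x} h: lx={self.lx} outside [0, 1]")
        if self.mx < 0:
            raise ValidationError(f"row at {self.time_x} h: negative mx")

    @property
    def lxmx(self) -> float:
        return self.lx * self.mx


@dataclass(frozen=True)
class LifeTable:
    """Ordered life-table rows plus the initial cohort size ``n0``.

    Every ``lx`` must be (a rounding of) a cohort fraction ``k/n0``; the
    survival column is non-increasing.
    """

    rows: tuple[LifeTableRow, ...]
    n0: int

    def __post_init__(self) -> None:
        rows = tuple(self.rows)
        object.__setattr__(self, "rows", rows)
        if self.n0 < 1:
            raise ValidationError("n0 must be at least 1")
        prev_t = -math.inf
        prev_lx = 1.0 + 1e-12
        for r in rows:
            if r.time_x <= prev_t:
                raise ValidationError(
                    f"life-table times not strictly increasing at {r.time_x} h"
                )
            if r.lx > prev_lx + 1e-12:
                raise ValidationError(f"lx increases at {r.time_x} h")
            k = round(r.lx * self.n0)
            if abs(r.lx - k / self.n0) >= _LX_ROUNDING_TOL:
                raise ValidationError(
                    f"lx={r.lx} at {r.time_x} h is not a multiple of 1/{self.n0} "
                    "within rounding tolerance"
                )
            prev_t, prev_lx = r.time_x, r.lx

    def __len__(self) -> int:
        return len(self.rows)

    # -- array views -------------------------------------------------------

    @property
    def time_x(self) -> np.ndarray:
        return np.array([r.time_x for r in self.rows], dtype=float)

    @property
    def width_d(self) -> np.ndarray:
        return np.array([r.width_d for r in self.rows], dtype=float)

    @property
    def lx(self) -> np.ndarray:
        return np.array([r.lx for r in self.rows], dtype=float)

    @property
    def mx(self) -> np.ndarray:
        return np.array([r.mx for r in self.rows], dtype=float)

    @property
    def lxmx(self) -> np.ndarray:
        return self.lx * self.mx

    def ages(self, convention: str = "interval_end") -> np.ndarray:
        """Age assigned to each interval under the chosen convention (hours)."""
        if convention == "interval_end":
            return self.time_x
        if convention == "interval_midpoint":
            return self.time_x - self.width_d / 2.0
        if convention == "interval_start":
            return self.time_x - self.width_d
        raise ValueError(f"unknown age convention {convention!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time_x,
                "D": self.width_d,
                "lx": self.lx,
                "mx": self.mx,
                "lxmx": self.lxmx,
            }
        )


def infer_n0(lx_values: Iterable[float], max_n0: int = 1000) -> int:
    """Smallest cohort size whose fractions round to every printed ``lx``.

    Printed survival values are two-decimal roundings of counts/n0, so a
    candidate n0 is feasible when every ``lx`` sits strictly within half an
    ulp (0.005) of some ``k/n0``.
    """
    vals = [float(v) for v in lx_values]
    if not vals:
        raise ValidationError("cannot infer n0 from an empty table")
    for n0 in range(1, max_n0 + 1):
        if all(abs(v - round(v * n0) / n0) < _LX_ROUNDING_TOL - 1e-12 for v in vals):
            return n0
    raise ValidationError(
        f"no cohort size up to {max_n0} is consistent with the lx column; "
        "pass n0 explicitly"
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (no header row)") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_cohort(path: str | Path) -> list[IndividualRecord]:
    """Read a per-individual observation log (TSV) into IndividualRecords.

    Records are grouped by ``individual_id`` (first-appearance order) and
    sorted by ``interval_start``; all schema invariants are enforced.
    """
    df = _read_tsv(path, COHORT_COLUMNS)
    individuals: list[IndividualRecord] = []
    for ind_id, group in df.groupby("individual_id", sort=False):
        group = group.sort_values("interval_start")
        recs = []
        for row in group.itertuples(index=False):
            try:
                recs.append(
                    ObservationRecord(
                        individual_id=str(ind_id),
                        interval_start=float(row.interval_start),
                        interval_end=float(row.interval_end),
                        eggs_laid=int(row.eggs_laid),
                        juveniles_hatched=int(row.juveniles_hatched),
                        status_at_end=str(row.status).strip().lower(),
                    )
                )
            except (TypeError, ValueError) as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise FormatError(
                    f"{path}: malformed row for individual {ind_id!r}: {exc}"
                ) from exc
        ind = IndividualRecord(individual_id=str(ind_id), records=tuple(recs))
        individuals.append(replace(ind, death_time=ind.death_estimate()))
    return individuals


def write_cohort(individuals: Iterable[IndividualRecord], path: str | Path) -> None:
    rows = []
    for ind in individuals:
        for r in ind.records:
            rows.append(
                {
                    "individual_id": r.individual_id,
                    "interval_start": r.interval_start,
                    "interval_end": r.interval_end,
                    "eggs_laid": r.eggs_laid,
                    "juveniles_hatched": r.juveniles_hatched,
                    "status": r.status_at_end,
                }
            )
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def _scan_n0_comment(path: Path) -> int | None:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip().replace(" ", "")
            if body.lower().startswith("n0="):
                try:
                    return int(body[3:])
                except ValueError:
                    return None
    return None


def read_life_table(path: str | Path, n0: int | None = None) -> LifeTable:
    """Read a life table TSV (columns ``time  D  lx  mx  [lxmx]``).

    The ``lxmx`` column, if present, is checked against the recomputed
    product; a discrepancy beyond 0.01 is logged as a warning and the
    recomputed value used (published tables round to two decimals).  The
    cohort size comes from the ``n0`` argument, an ``# n0 = N`` header
    comment, or — as a last resort — the smallest cohort size consistent
    with the survival column.
    """
    path = Path(path)
    df = _read_tsv(path, ("time", "D", "lx", "mx"))
    if n0 is None:
        n0 = _scan_n0_comment(path)
    if n0 is None and len(df):
        n0 = infer_n0(df["lx"])
    if "lxmx" in df.columns and len(df):
        bad = np.abs(df["lxmx"].to_numpy(float) - df["lx"].to_numpy(float) * df["mx"].to_numpy(float))
        if np.any(bad > 0.01):
            worst = df["time"].to_numpy(float)[int(np.argmax(bad))]
            logger.warning(
                "%s: printed lxmx deviates from lx*mx by up to %.3f (row at %g h); "
                "using the recomputed product",
                path,
                float(bad.max()),
                worst,
            )
    rows = tuple(
        LifeTableRow(
            time_x=float(r.time), width_d=float(r.D), lx=float(r.lx), mx=float(r.mx)
        )
        for r in df.itertuples(index=False)
    )
    return LifeTable(rows=rows, n0=int(n0) if n0 else 1)


def write_life_table(lt: LifeTable, path: str | Path) -> None:
    """Write a life table TSV that round-trips through :func:`read_life_table`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# n0 = {lt.n0}\n")
        fh.write("time\tD\tlx\tmx\tlxmx\n")
        for r in lt.rows:
            fh.write(
                f"{r.time_x!r}\t{r.width_d!r}\t{r.lx!r}\t{r.mx!r}\t{r.lxmx!r}\n"
            )


def load_pacificus_life_table() -> LifeTable:
    """The published *P. pacificus* (PS312) cohort life table (N = 33)."""
    ref = resources.files("nemalife.data").joinpath("pacificus_life_table.tsv")
    with resources.as_file(ref) as p:
        return read_life_table(p)
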