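"""Individual-based simulator of a synchronized hanging-drop cohort.

The generator produces per-individual event logs — maturation, death and
egg events (lay time, fertility, hatch time) — for a cohort of
self-fertilizing hermaphrodites on a shared age clock, and an observer
that censors those events to an arbitrary checkpoint schedule, yielding
exactly the record schema the life-table pipeline consumes.

Model structure (defaults parameterized to the published *P. pacificus*
PS312 trait values):

* maturation age = age at first egg deposition, truncated normal
  (65.1 ± 8.4 h, > 24 h);
* adult lifespan truncated normal (22.5 ± 7.3 d, > maturation age);
  a small fraction of individuals (2/33 by default) die as juveniles,
  uniformly between 24 h and their would-be maturation age;
* lifetime egg number truncated normal (269.6 ± 73.4, >= 1); the first
  egg is laid at maturation, the rest at ages drawn from a gamma-shaped
  laying-intensity curve (mode 140.8 h) restricted to
  [maturation, min(death, 14 d)] — reproductive effort is compressed
  into the realized life rather than truncated by early death, so the
  configured egg mean is the realized lifetime mean;
* each egg is fertile with probability given by an age-dependent fertility
  curve (two logistic ramps through 97.4 % at 6.1 d and 0.21 % at 12.8 d,
  0 after 13 d); fertile eggs hatch after a truncated-normal delay
  (25.3 ± 1.6 h).

Randomness: a single integer seed spawns one independent substream per
individual, so enlarging the cohort leaves earlier individuals unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .records import (
    ALIVE,
    DEAD,
    IndividualRecord,
    ObservationRecord,
    ObservationSchedule,
    ValidationError,
)

__all__ = [
    "TruncatedNormal",
    "GammaIntensity",
    "FertilityCurve",
    "ConstantFertility",
    "fertility_from_anchors",
    "SimulationConfig",
    "EggEvent",
    "IndividualEvents",
    "EventLog",
    "pacificus_config",
    "pacificus_schedule",
    "simulate_cohort",
    "observe",
    "expected_r0",
]


class ConfigError(ValueError):
    """Simulation configuration is infeasible or inconsistent."""


class HorizonError(ValueError):
    """Events extend beyond the observation schedule."""


# ---------------------------------------------------------------------------
# distribution / curve building blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) truncated to [lower, upper]; sd = 0 degenerates to a
    point mass at the (clipped) mean."""

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("sd must be nonnegative")
        if self.lower >= self.upper:
            raise ConfigError("empty truncation interval")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.sd == 0.0:
            val = min(max(self.mean, self.lower), self.upper)
            return val if size is None else np.full(size, val)
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=size, random_state=rng)

    def with_lower(self, lower: float) -> "TruncatedNormal":
        return replace(self, lower=max(self.lower, lower))


@dataclass(frozen=True)
class GammaIntensity:
    """Gamma-shaped egg-laying intensity over cohort age (hours), with the
    support cut at ``cutoff_h``.  ``mode = (shape - 1) * scale``."""

    shape: float
    scale: float
    cutoff_h: float

    def __post_init__(self) -> None:
        if self.shape <= 1 or self.scale <= 0 or self.cutoff_h <= 0:
            raise ConfigError("gamma intensity needs shape > 1, scale > 0, cutoff > 0")

    @property
    def mode_h(self) -> float:
        return (self.shape - 1.0) * self.scale

    def _gamma(self):
        from scipy.stats import gamma

        return gamma(self.shape, scale=self.scale)

    def pdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = self._gamma().pdf(t)
        return np.where(t > self.cutoff_h, 0.0, out)

    def sample_window(
        self, rng: np.random.Generator, lo: float, hi: float, size: int
    ) -> np.ndarray:
        """Draw lay ages from the intensity restricted to [lo, hi]."""
        hi = min(hi, self.cutoff_h)
        g = self._gamma()
        c_lo, c_hi = g.cdf(lo), g.cdf(hi)
        if size <= 0:
            return np.empty(0)
        if c_hi - c_lo <= 1e-12 or hi <= lo:
            # degenerate window: all remaining eggs at the window start
            return np.full(size, lo)
        u = rng.uniform(c_lo, c_hi, size=size)
        return np.asarray(g.ppf(u), dtype=float)


@dataclass(frozen=True)
class FertilityCurve:
    """Age-dependent probability that a laid egg is fertile: the product of a
    rising and a falling logistic ramp, clamped to 0 past ``zero_after_h``."""

    amplitude: float
    rise_mid_h: float
    rise_scale_h: float
    fall_mid_h: float
    fall_scale_h: float
    zero_after_h: float

    def __post_init__(self) -> None:
        if not (0.0 < self.amplitude <= 1.0):
            raise ConfigError("fertility amplitude must be in (0, 1]")
        if self.rise_scale_h <= 0 or self.fall_scale_h <= 0:
            raise ConfigError("logistic scales must be positive")

    def __call__(self, age_h) -> np.ndarray:
        t = np.asarray(age_h, dtype=float)
        p = (
            self.amplitude
            * expit((t - self.rise_mid_h) / self.rise_scale_h)
            * expit((self.fall_mid_h - t) / self.fall_scale_h)
        )
        return np.where(t > self.zero_after_h, 0.0, p)


@dataclass(frozen=True)
class ConstantFertility:
    """Age-independent egg fertility (for degenerate/test configurations)."""

    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ConfigError("fertility probability outside [0, 1]")

    def __call__(self, age_h) -> np.ndarray:
        return np.full_like(np.asarray(age_h, dtype=float), self.p)


def fertility_from_anchors(
    peak_age_h: float,
    peak_fertility: float,
    tail_age_h: float,
    tail_fertility: float,
    rise_mid_h: float = 60.0,
    rise_scale_h: float = 12.0,
    amplitude: float = 0.975,
    zero_after_h: float = 312.0,
) -> FertilityCurve:
    """Solve the falling ramp so the curve passes through two anchor points.

    With the rising ramp essentially saturated at both anchor ages, the two
    conditions amplitude*fall(t) = fertility determine the fall midpoint and
    scale in closed form via the logit.
    """
    y1 = peak_fertility / (amplitude * expit((peak_age_h - rise_mid_h) / rise_scale_h))
    y2 = tail_fertility / (amplitude * expit((tail_age_h - rise_mid_h) / rise_scale_h))
    if not (0 < y2 < y1 < 1):
        raise ConfigError("anchor fertilities are not realizable by a falling ramp")
    fall_scale = (tail_age_h - peak_age_h) / (logit(y1) - logit(y2))
    fall_mid = peak_age_h + fall_scale * logit(y1)
    return FertilityCurve(
        amplitude=amplitude,
        rise_mid_h=rise_mid_h,
        rise_scale_h=rise_scale_h,
        fall_mid_h=float(fall_mid),
        fall_scale_h=float(fall_scale),
        zero_after_h=zero_after_h,
    )


# ---------------------------------------------------------------------------
# configuration and event log
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one synchronized-cohort simulation."""

    n: int
    seed: int
    maturation_age: TruncatedNormal
    lifespan_h: TruncatedNormal
    juvenile_death_prob: float
    juvenile_death_min_h: float
    lifetime_eggs: TruncatedNormal
    laying_intensity: GammaIntensity
    fertility: Callable[[np.ndarray], np.ndarray]
    hatch_delay: TruncatedNormal
    sync_window_h: float = 4.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("cohort size n must be at least 1")
        if not (0.0 <= self.juvenile_death_prob <= 1.0):
            raise ConfigError("juvenile_death_prob outside [0, 1]")
        if self.sync_window_h < 0:
            raise ConfigError("sync_window_h must be nonnegative")
        if self.laying_intensity.cutoff_h <= self.maturation_age.lower:
            raise ConfigError(
                "laying support ends before any individual can mature; "
                "no reproduction is possible"
            )
        # fertility must be evaluable over the laying support
        probe = np.linspace(0.0, self.laying_intensity.cutoff_h, 7)
        p = np.asarray(self.fertility(probe), dtype=float)
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ConfigError("fertility curve leaves [0, 1] on the laying support")


@dataclass(frozen=True)
class EggEvent:
    lay_time: float
    fertile: bool
    hatch_time: float | None

    def __post_init__(self) -> None:
        if self.fertile and (self.hatch_time is None or self.hatch_time <= self.lay_time):
            raise ValidationError("fertile egg must hatch after it is laid")
        if not self.fertile and self.hatch_time is not None:
            raise ValidationError("unfertile egg cannot have a hatch time")


@dataclass(frozen=True)
class IndividualEvents:
    individual_id: str
    hatch_offset: float
    maturation_time: float | None  # None for juvenile deaths
    death_time: float
    eggs: tuple[EggEvent, ...]

    def __post_init__(self) -> None:
        for e in self.eggs:
            if self.maturation_time is None:
                raise ValidationError(f"{self.individual_id}: eggs without maturation")
            if e.lay_time < self.maturation_time - 1e-9 or e.lay_time > self.death_time + 1e-9:
                raise ValidationError(
                    f"{self.individual_id}: egg at {e.lay_time} h outside "
                    "the maturation-death window"
                )

    @property
    def n_eggs(self) -> int:
        return len(self.eggs)

    @property
    def n_fertile(self) -> int:
        return sum(1 for e in self.eggs if e.fertile)


@dataclass(frozen=True)
class EventLog:
    individuals: tuple[IndividualEvents, ...]
    config: SimulationConfig

    @property
    def max_event_time(self) -> float:
        return max(ind.death_time for ind in self.individuals)

    @property
    def total_eggs(self) -> int:
        return sum(ind.n_eggs for ind in self.individuals)

    @property
    def total_fertile(self) -> int:
        return sum(ind.n_fertile for ind in self.individuals)


# ---------------------------------------------------------------------------
# defaults: the P. pacificus study conditions
# ---------------------------------------------------------------------------


def pacificus_config(seed: int, n: int = 33) -> SimulationConfig:
    """Simulation config parameterized to the published *P. pacificus*
    (PS312, 20 degC, 5e9 E. coli cells/ml) trait values."""
    return SimulationConfig(
        n=n,
        seed=seed,
        maturation_age=TruncatedNormal(65.1, 8.4, lower=24.0),
        lifespan_h=TruncatedNormal(22.5 * 24.0, 7.3 * 24.0, lower=0.0),
        juvenile_death_prob=2.0 / 33.0,
        juvenile_death_min_h=24.0,
        lifetime_eggs=TruncatedNormal(269.6, 73.4, lower=1.0),
        laying_intensity=GammaIntensity(shape=6.0, scale=140.8 / 5.0, cutoff_h=336.0),
        fertility=fertility_from_anchors(
            peak_age_h=6.1 * 24.0,
            peak_fertility=0.974,
            tail_age_h=12.8 * 24.0,
            tail_fertility=0.0021,
        ),
        hatch_delay=TruncatedNormal(25.3, 1.6, lower=0.0),
    )


def pacificus_schedule(horizon_h: float) -> ObservationSchedule:
    """The study's checkpoint cadence, made contiguous: daily juvenile checks,
    6 h intervals through 123 h, 12 h through 291 h, 24 h thereafter."""
    breaks = [0.0, 21.0, 45.0]
    breaks += [float(t) for t in range(51, 124, 6)]
    breaks += [float(t) for t in range(135, 292, 12)]
    t = 315.0
    while True:
        breaks.append(t)
        if t >= horizon_h:
            break
        t += 24.0
    return ObservationSchedule.from_breaks(breaks)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> EventLog:
    """Generate the ground-truth event log for one synchronized cohort.

    Reproducible for a fixed config (including seed); per-individual
    substreams are spawned from the seed so the first k individuals are
    identical across cohort sizes >= k.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n)
    individuals = []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        ind_id = f"worm{i + 1:03d}"
        hatch_offset = rng.uniform(0.0, config.sync_window_h)
        mat = float(config.maturation_age.sample(rng))
        if rng.random() < config.juvenile_death_prob:
            lo = min(config.juvenile_death_min_h, mat)
            death = float(rng.uniform(lo, mat))
            individuals.append(
                IndividualEvents(
                    individual_id=ind_id,
                    hatch_offset=hatch_offset,
                    maturation_time=None,
                    death_time=death,
                    eggs=(),
                )
            )
            continue
        death = float(config.lifespan_h.with_lower(mat + 1e-6).sample(rng))
        n_eggs = max(1, int(round(float(config.lifetime_eggs.sample(rng)))))
        window_hi = min(death, config.laying_intensity.cutoff_h)
        rest = config.laying_intensity.sample_window(rng, mat, window_hi, n_eggs - 1)
        lay_times = np.sort(np.concatenate(([mat], rest)))
        fertile = rng.random(n_eggs) < np.asarray(config.fertility(lay_times), dtype=float)
        delays = np.asarray(config.hatch_delay.sample(rng, size=n_eggs), dtype=float)
        eggs = tuple(
            EggEvent(
                lay_time=float(t),
                fertile=bool(f),
                hatch_time=float(t + max(d, 1e-6)) if f else None,
            )
            for t, f, d in zip(lay_times, fertile, delays)
        )
        individuals.append(
            IndividualEvents(
                individual_id=ind_id,
                hatch_offset=hatch_offset,
                maturation_time=mat,
                death_time=death,
                eggs=eggs,
            )
        )
    return EventLog(individuals=tuple(individuals), config=config)


def observe(
    events: EventLog, schedule: ObservationSchedule | None = None
) -> list[IndividualRecord]:
    """Censor an event log to a checkpoint schedule.

    Eggs are binned to the interval containing their lay time, and hatched
    juveniles are credited to the same interval (the 48 h leave-in-drop
    scoring rule).  Death is reported at the first checkpoint at or after
    the death time.  Total egg counts are conserved exactly for any
    schedule covering the events.
    """
    if schedule is None:
        schedule = pacificus_schedule(events.max_event_time + 24.0)
    horizon = schedule.horizon
    records: list[IndividualRecord] = []
    for ind in events.individuals:
        if ind.death_time > horizon + 1e-9:
            raise HorizonError(
                f"{ind.individual_id}: death at {ind.death_time} h beyond the "
                f"schedule horizon {horizon} h"
            )
        death_idx = schedule.interval_index(ind.death_time)
        eggs = np.zeros(death_idx + 1, dtype=np.int64)
        juv = np.zeros(death_idx + 1, dtype=np.int64)
        for e in ind.eggs:
            j = schedule.interval_index(e.lay_time)
            if j > death_idx:
                raise HorizonError(
                    f"{ind.individual_id}: egg laid after the death interval"
                )
            eggs[j] += 1
            if e.fertile:
                juv[j] += 1
        recs = []
        for j in range(death_idx + 1):
            start = schedule.checkpoints[j] - schedule.widths[j]
            recs.append(
                ObservationRecord(
                    individual_id=ind.individual_id,
                    interval_start=start,
                    interval_end=schedule.checkpoints[j],
                    eggs_laid=int(eggs[j]),
                    juveniles_hatched=int(juv[j]),
                    status_at_end=DEAD if j == death_idx else ALIVE,
                )
            )
        records.append(
            IndividualRecord(
                individual_id=ind.individual_id,
                records=tuple(recs),
                hatch_offset=ind.hatch_offset,
                death_time=ind.death_time,
            )
        )
    return records


# ---------------------------------------------------------------------------
# analytic expectation (independent of the simulation path)
# ---------------------------------------------------------------------------


def expected_r0(config: SimulationConfig, n_nodes: int = 48, n_t: int = 400) -> float:
    """Expected fertile eggs per initial individual, by numerical integration.

    Integrates the model directly — over the maturation-age and lifespan
    distributions and the within-life lay-age density — rather than
    simulating, so it serves as an independent oracle for the Monte-Carlo
    estimate R0 = total juveniles / n0 produced by the pipeline.
    """
    mat_d = config.maturation_age
    life_d = config.lifespan_h
    if mat_d.sd == 0.0:
        mats = np.array([mat_d.mean])
        w_mat = np.array([1.0])
    else:
        qs = (np.arange(n_nodes) + 0.5) / n_nodes
        a = (mat_d.lower - mat_d.mean) / mat_d.sd
        b = (mat_d.upper - mat_d.mean) / mat_d.sd
        mats = truncnorm.ppf(qs, a, b, loc=mat_d.mean, scale=mat_d.sd)
        w_mat = np.full(n_nodes, 1.0 / n_nodes)

    mean_n = _truncnorm_mean(config.lifetime_eggs)
    cutoff = config.laying_intensity.cutoff_h
    g = config.laying_intensity._gamma()

    total = 0.0
    for mat, wm in zip(mats, w_mat):
        f_mat = float(np.asarray(config.fertility(np.array([mat]))).ravel()[0])
        # lifespan conditional on exceeding the maturation age
        if life_d.sd == 0.0:
            deaths = np.array([max(life_d.mean, mat + 1e-6)])
            w_d = np.array([1.0])
        else:
            lo = max(life_d.lower, mat + 1e-6)
            a = (lo - life_d.mean) / life_d.sd
            b = (life_d.upper - life_d.mean) / life_d.sd
            qs = (np.arange(n_nodes) + 0.5) / n_nodes
            deaths = truncnorm.ppf(qs, a, b, loc=life_d.mean, scale=life_d.sd)
            w_d = np.full(n_nodes, 1.0 / n_nodes)
        for death, wd in zip(deaths, w_d):
            hi = min(death, cutoff)
            if hi <= mat or g.cdf(hi) - g.cdf(mat) <= 1e-12:
                fbar = f_mat  # degenerate window: remaining eggs at maturation
            else:
                t = np.linspace(mat, hi, n_t)
                dens = g.pdf(t)
                z = np.trapezoid(dens, t)
                fbar = float(
                    np.trapezoid(np.asarray(config.fertility(t)) * dens, t) / z
                )
            total += wm * wd * (f_mat + (mean_n - 1.0) * fbar)
    return (1.0 - config.juvenile_death_prob) * total


def _truncnorm_mean(d: TruncatedNormal) -> float:
    if d.sd == 0.0:
        return min(max(d.mean, d.lower), d.upper)
    a = (d.lower - d.mean) / d.sd
    b = (d.upper - d.mean) / d.sd
    return float(truncnorm.mean(a, b, loc=d.mean, scale=d.sd))


# ---------------------------------------------------------------------------
# config (de)serialization — YAML/JSON-friendly plain dicts
# ---------------------------------------------------------------------------


def _tn_to_dict(d: TruncatedNormal) -> dict:
    out = {"mean": d.mean, "sd": d.sd}
    if math.isfinite(d.lower):
        out["lower"] = d.lower
    if math.isfinite(d.upper):
        out["upper"] = d.upper
    return out


def _tn_from_dict(d: dict) -> TruncatedNormal:
    return TruncatedNormal(
        mean=float(d["mean"]),
        sd=float(d["sd"]),
        lower=float(d.get("lower", -math.inf)),
        upper=float(d.get("upper", math.inf)),
    )


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-dict form of a config, suitable for YAML or JSON."""
    if isinstance(config.fertility, FertilityCurve):
        fert = {"kind": "logistic_ramps", **{
            k: getattr(config.fertility, k)
            for k in (
                "amplitude", "rise_mid_h", "rise_scale_h",
                "fall_mid_h", "fall_scale_h", "zero_after_h",
            )
        }}
    elif isinstance(config.fertility, ConstantFertility):
        fert = {"kind": "constant", "p": config.fertility.p}
    else:
        raise ConfigError("only built-in fertility curves can be serialized")
    return {
        "n": config.n,
        "seed": config.seed,
        "maturation_age_h": _tn_to_dict(config.maturation_age),
        "lifespan_h": _tn_to_dict(config.lifespan_h),
        "juvenile_death_prob": config.juvenile_death_prob,
        "juvenile_death_min_h": config.juvenile_death_min_h,
        "lifetime_eggs": _tn_to_dict(config.lifetime_eggs),
        "laying_intensity": {
            "shape": config.laying_intensity.shape,
            "scale_h": config.laying_intensity.scale,
            "cutoff_h": config.laying_intensity.cutoff_h,
        },
        "fertility": fert,
        "hatch_delay_h": _tn_to_dict(config.hatch_delay),
        "sync_window_h": config.sync_window_h,
    }


def config_from_dict(d: dict) -> SimulationConfig:
    fert_d = d["fertility"]
    kind = fert_d.get("kind", "logistic_ramps")
    if kind == "constant":
        fertility: Callable = ConstantFertility(p=float(fert_d["p"]))
    elif kind == "logistic_ramps":
        fertility = FertilityCurve(
            amplitude=float(fert_d["amplitude"]),
            rise_mid_h=float(fert_d["rise_mid_h"]),
            rise_scale_h=float(fert_d["rise_scale_h"]),
            fall_mid_h=float(fert_d["fall_mid_h"]),
            fall_scale_h=float(fert_d["fall_scale_h"]),
            zero_after_h=float(fert_d["zero_after_h"]),
        )
    else:
        raise ConfigError(f"unknown fertility curve kind {kind!r}")
    li = d["laying_intensity"]
    return SimulationConfig(
        n=int(d["n"]),
        seed=int(d["seed"]),
        maturation_age=_tn_from_dict(d["maturation_age_h"]),
        lifespan_h=_tn_from_dict(d["lifespan_h"]),
        juvenile_death_prob=float(d["juvenile_death_prob"]),
        juvenile_death_min_h=float(d.get("juvenile_death_min_h", 24.0)),
        lifetime_eggs=_tn_from_dict(d["lifetime_eggs"]),
        laying_intensity=GammaIntensity(
            shape=float(li["shape"]),
            scale=float(li["scale_h"]),
            cutoff_h=float(li["cutoff_h"]),
        ),
        fertility=fertility,
        hatch_delay=_tn_from_dict(d["hatch_delay_h"]),
        sync_window_h=float(d.get("sync_window_h", 4.0)),
    )
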