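"""Life-table construction, R0/TFR, fecundity schedule and cohort summaries."""

import numpy as np
import pytest
from conftest import random_life_table

from nemalife.lifetable import (
    build_life_table,
    cohort_summary,
    fecundity_schedule,
    net_reproductive_rate,
    total_fertility_rate,
)
from nemalife.records import (
    ALIVE,
    DEAD,
    AlignmentError,
    IndividualRecord,
    LifeTable,
    ObservationRecord,
    ObservationSchedule,
)
from nemalife.simulate import observe, pacificus_config, pacificus_schedule, simulate_cohort


def make_individual(ind_id, schedule, eggs_by_end=None, juv_by_end=None, death_end=None):
    """Records for one individual on a schedule; counts keyed by interval end."""
    eggs_by_end = eggs_by_end or {}
    juv_by_end = juv_by_end or {}
    recs = []
    for start, end in schedule.intervals():
        status = DEAD if death_end is not None and end == death_end else ALIVE
        recs.append(
            ObservationRecord(
                individual_id=ind_id,
                interval_start=start,
                interval_end=end,
                eggs_laid=eggs_by_end.get(end, 0),
                juveniles_hatched=juv_by_end.get(end, 0),
                status_at_end=status,
            )
        )
        if status == DEAD:
            break
    return IndividualRecord(individual_id=ind_id, records=tuple(recs))


class TestBuildLifeTable:
    def test_juvenile_deaths_drop_lx_at_following_checkpoint(self):
        """Deaths at 62 h and 89 h reproduce the published survival pattern:
        l_x = 0.97 through 87 h and 0.94 from the 93 h checkpoint on."""
        schedule = pacificus_schedule(360.0)
        cohort = [
            make_individual(
                f"w{i}", schedule, eggs_by_end={75.0: 5, 81.0: 5}, juv_by_end={75.0: 4, 81.0: 4}
            )
            for i in range(31)
        ]
        cohort.append(make_individual("j1", schedule, death_end=63.0))
        cohort.append(make_individual("j2", schedule, death_end=93.0))
        # j1 died at 62 h -> first checkpoint >= 62 is 63; j2 at 89 h -> 93
        lt = build_life_table(cohort, schedule, trim=False)
        by_time = {r.time_x: r.lx for r in lt.rows}
        for t in (75.0, 81.0, 87.0):
            assert round(by_time[t], 2) == 0.97
        for t in (93.0, 99.0, 105.0):
            assert round(by_time[t], 2) == 0.94

    def test_single_survivor(self):
        schedule = ObservationSchedule.from_breaks([0, 6, 12])
        ind = make_individual("w1", schedule, eggs_by_end={12.0: 5}, juv_by_end={12.0: 5})
        lt = build_life_table([ind], schedule)
        assert len(lt) == 1
        assert lt.rows[0].lx == 1.0
        assert lt.rows[0].mx == 5.0

    def test_no_reproduction_gives_zero_r0_untrimmed(self):
        schedule = ObservationSchedule.from_breaks([0, 6, 12])
        cohort = [make_individual(f"w{i}", schedule) for i in range(4)]
        lt = build_life_table(cohort, schedule)
        assert len(lt) == 2
        assert net_reproductive_rate(lt) == 0.0

    def test_trim_keeps_interior_zero_rows(self):
        schedule = ObservationSchedule.from_breaks([0, 6, 12, 18, 24, 30])
        ind = make_individual(
            "w1", schedule,
            eggs_by_end={12.0: 3, 24.0: 2}, juv_by_end={12.0: 2, 24.0: 1},
        )
        lt = build_life_table([ind], schedule)
        assert [r.time_x for r in lt.rows] == [12.0, 18.0, 24.0]
        assert lt.rows[1].mx == 0.0

    def test_misaligned_records_raise(self):
        fine = ObservationSchedule.from_breaks([0, 6, 12])
        coarse = ObservationSchedule.from_breaks([0, 12])
        ind = make_individual("w1", fine, eggs_by_end={6.0: 1}, juv_by_end={6.0: 1})
        with pytest.raises(AlignmentError):
            build_life_table([ind], coarse)

    def test_rebinning_conserves_juvenile_totals(self, rng):
        """Aggregating the same events to a coarser schedule leaves the
        cohort's total juvenile count (sum over rows of m_x * alive) exact."""
        events = simulate_cohort(pacificus_config(seed=11, n=20))
        horizon = (np.ceil(events.max_event_time / 48) + 1) * 48
        for width in (6.0, 12.0, 24.0, 48.0):
            sched = ObservationSchedule.uniform(width, horizon)
            lt = build_life_table(observe(events, sched), sched, trim=False)
            total = np.sum(lt.mx * np.round(lt.lx * lt.n0))
            assert total == pytest.approx(events.total_fertile, abs=1e-9)

    def test_denominator_conventions_differ_after_deaths(self):
        schedule = ObservationSchedule.from_breaks([0, 6, 12])
        laying = make_individual("w1", schedule, eggs_by_end={12.0: 4}, juv_by_end={12.0: 4})
        dying = make_individual("w2", schedule, death_end=12.0)
        lt_end = build_life_table([laying, dying], schedule, denominator="interval_end")
        lt_start = build_life_table([laying, dying], schedule, denominator="interval_start")
        assert lt_end.rows[-1].mx == 4.0  # one alive at the closing checkpoint
        assert lt_start.rows[-1].mx == 2.0  # two alive when the interval opened


class TestRates:
    def test_published_r0_and_tfr(self, pacificus_table):
        assert net_reproductive_rate(pacificus_table) == pytest.approx(108.95, abs=0.1)
        assert total_fertility_rate(pacificus_table) == pytest.approx(115.35, abs=0.1)

    def test_empty_table(self):
        lt = LifeTable(rows=(), n0=1)
        assert net_reproductive_rate(lt) == 0.0
        assert total_fertility_rate(lt) == 0.0

    def test_r0_matches_loop_oracle_on_random_tables(self, rng):
        for _ in range(10):
            lt = random_life_table(rng)
            brute = sum(r.lx * r.mx for r in lt.rows)
            assert net_reproductive_rate(lt) == pytest.approx(brute, rel=1e-12)
            assert total_fertility_rate(lt) >= net_reproductive_rate(lt)


class TestFecunditySchedule:
    def test_mean_of_individual_hatch_fractions(self):
        schedule = ObservationSchedule.from_breaks([0, 6])
        a = make_individual("a", schedule, eggs_by_end={6.0: 10}, juv_by_end={6.0: 10})
        b = make_individual("b", schedule, eggs_by_end={6.0: 10}, juv_by_end={6.0: 9})
        (pt,) = fecundity_schedule([a, b])
        assert pt.fecundity_pct == pytest.approx(95.0)
        assert pt.eggs_per_interval == pytest.approx(10.0)

    def test_all_unfertile_is_zero_percent(self):
        schedule = ObservationSchedule.from_breaks([0, 6])
        a = make_individual("a", schedule, eggs_by_end={6.0: 7})
        (pt,) = fecundity_schedule([a])
        assert pt.fecundity_pct == 0.0

    def test_immature_and_dead_individuals_excluded(self):
        schedule = ObservationSchedule.from_breaks([0, 6, 12])
        mature = make_individual(
            "a", schedule, eggs_by_end={6.0: 4, 12.0: 4}, juv_by_end={6.0: 4, 12.0: 2}
        )
        late = make_individual("b", schedule, eggs_by_end={12.0: 2}, juv_by_end={12.0: 0})
        dead = make_individual("c", schedule, death_end=12.0)
        pts = fecundity_schedule([mature, late, dead])
        assert [p.time_x for p in pts] == [6.0, 12.0]
        assert pts[0].fecundity_pct == pytest.approx(100.0)  # only `a` is mature
        assert pts[1].fecundity_pct == pytest.approx((0.5 + 0.0) / 2 * 100)

    def test_simulated_peak_fecundity_recovers_configured_peak(self):
        """At the study's cohort size the estimated maximum fecundity lands
        within 3 percentage points of the configured 97.4 % peak."""
        events = simulate_cohort(pacificus_config(seed=5, n=33))
        pts = fecundity_schedule(observe(events))
        peak = max(p.fecundity_pct for p in pts if p.fecundity_pct is not None)
        assert peak == pytest.approx(97.4, abs=3.0)


class TestCohortSummary:
    def test_exact_first_egg_age(self):
        schedule = ObservationSchedule.from_breaks([0, 60, 70, 80])
        cohort = [
            make_individual(f"w{i}", schedule, eggs_by_end={70.0: 3}, juv_by_end={70.0: 3})
            for i in range(5)
        ]
        cs = cohort_summary(cohort)
        assert cs.age_min_h == pytest.approx(65.0)  # interval (60, 70] midpoint
        assert cs.sd_age_min_h == 0.0
        assert cs.juvenile_mortality == 0.0

    def test_mean_lifespan_of_two_deaths(self):
        schedule = ObservationSchedule.uniform(24.0, 26 * 24.0)
        a = make_individual("a", schedule, eggs_by_end={48.0: 1, 72.0: 1},
                            juv_by_end={48.0: 1}, death_end=20 * 24.0)
        b = make_individual("b", schedule, eggs_by_end={48.0: 1},
                            juv_by_end={48.0: 1}, death_end=25 * 24.0)
        cs = cohort_summary([a, b])
        # midpoints of the (456, 480] and (576, 600] intervals
        assert cs.mean_lifespan_d == pytest.approx((19.5 + 24.5) / 2)
        assert cs.total_eggs == pytest.approx(1.5)

    def test_juvenile_mortality_counts_deaths_before_first_egg(self):
        schedule = ObservationSchedule.from_breaks([0, 24, 48, 72])
        adult = make_individual("a", schedule, eggs_by_end={72.0: 2}, juv_by_end={72.0: 2})
        juv = make_individual("j", schedule, death_end=48.0)
        cs = cohort_summary([adult, juv])
        assert cs.juvenile_mortality == pytest.approx(0.5)
        assert cs.n_mature == 1

    def test_simulated_cohort_recovers_config_means_within_2sd(self):
        cfg = pacificus_config(seed=21, n=33)
        cs = cohort_summary(observe(simulate_cohort(cfg)))
        n = cs.n_mature
        assert cs.mean_lifespan_d == pytest.approx(22.5, abs=2 * 7.3 / np.sqrt(n) + 0.5)
        assert cs.age_min_h == pytest.approx(65.1, abs=2 * 8.4 / np.sqrt(n) + 3.0)
        assert cs.total_eggs == pytest.approx(269.6, abs=2 * 73.4 / np.sqrt(n))
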