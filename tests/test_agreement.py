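"""Kappa machinery: exact values, invariances, pooled SE, summaries."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from concord.agreement import (ContingencyTable, KappaResult, analyze,
                               bootstrap_pooled_se, cohen_kappa, contingency,
                               pair_days, per_participant_kappas,
                               pooled_kappa, summarize_kappas,
                               sweep_agreement)
from concord.io_formats import EmaRecord
from concord.synthetic_data import analytic_kappa, day_level_generator


class TestCohenKappa:
    def test_hand_computed_example(self):
        r = cohen_kappa(ContingencyTable(50, 10, 10, 30))
        assert r.p_o == pytest.approx(0.8)
        assert r.p_e == pytest.approx(0.52)
        assert r.kappa == pytest.approx(0.5833333333333334, abs=1e-12)

    def test_perfect_agreement(self):
        r = cohen_kappa(ContingencyTable(7, 0, 0, 13))
        assert r.kappa == pytest.approx(1.0)

    def test_independent_marginals_zero(self):
        r = cohen_kappa(ContingencyTable(9, 21, 21, 49))
        assert r.p_o == pytest.approx(r.p_e) == pytest.approx(0.58)
        assert r.kappa == pytest.approx(0.0, abs=1e-12)

    def test_empty_table_undefined(self):
        r = cohen_kappa(ContingencyTable())
        assert r.undefined and "no included days" in r.reason

    def test_constant_measure_undefined(self):
        # all EMA yes: uninformative, excluded rather than imputed
        r = cohen_kappa(ContingencyTable(5, 3, 0, 0))
        assert r.undefined and "constant" in r.reason

    def test_symmetric_under_transpose(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 50, size=4)
            k1 = cohen_kappa(ContingencyTable(a, b, c, d)).kappa
            k2 = cohen_kappa(ContingencyTable(a, c, b, d)).kappa
            assert k1 == pytest.approx(k2, abs=1e-12)

    def test_invariant_to_count_scaling(self):
        base = ContingencyTable(8, 3, 5, 11)
        k = cohen_kappa(base).kappa
        for s in (2, 7, 100):
            scaled = ContingencyTable(8 * s, 3 * s, 5 * s, 11 * s)
            assert cohen_kappa(scaled).kappa == pytest.approx(k, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = ContingencyTable(*rng.integers(1, 30, size=4))
            r = cohen_kappa(t)
            assert -1.0 - 1e-12 <= r.kappa <= 1.0 + 1e-12


class TestPooledKappa:
    def test_single_table_equals_own_kappa(self):
        t = ContingencyTable(50, 10, 10, 30)
        assert pooled_kappa([t]).kappa == pytest.approx(cohen_kappa(t).kappa)

    def test_two_identical_tables(self):
        t = ContingencyTable(50, 10, 10, 30)
        one, two = pooled_kappa([t]), pooled_kappa([t, t])
        assert two.kappa == pytest.approx(one.kappa, abs=1e-12)
        assert two.se == pytest.approx(one.se / np.sqrt(2), rel=1e-9)

    def test_counts_conserved(self):
        rng = np.random.default_rng(3)
        tables = [ContingencyTable(*rng.integers(0, 20, size=4))
                  for _ in range(10)]
        pooled = pooled_kappa(tables)
        assert pooled.n == sum(t.n for t in tables)

    def test_se_scaling_exact(self):
        t = ContingencyTable(5000, 1000, 1000, 3000)
        se1 = pooled_kappa([t]).se
        for k in (2, 4, 9):
            sek = pooled_kappa([t] * k).se
            assert sek * np.sqrt(k) == pytest.approx(se1, rel=1e-9)

    def test_asymptotic_se_close_to_bootstrap(self):
        t = ContingencyTable(5000, 1000, 1000, 3000)
        asym = pooled_kappa([t]).se
        boot = bootstrap_pooled_se(t, n_boot=2000, seed=17)
        assert abs(asym - boot) / boot < 0.10


class TestPairing:
    def _classifications(self):
        return pd.DataFrame({
            "participant_id": ["P1"] * 3,
            "day_date": [date(2020, 1, d) for d in (1, 2, 3)],
            "exercise": [True, True, False],
            "valid": [True, False, True],   # day 2: only 400 min of wear
        })

    def _ema(self):
        return [EmaRecord("P1", date(2020, 1, 1), "yes"),
                EmaRecord("P1", date(2020, 1, 2), "yes"),
                EmaRecord("P1", date(2020, 1, 3), "missing")]

    def test_inclusion_rules(self):
        out = pair_days(self._classifications(), self._ema())
        out = out.set_index("day_date")
        assert out.loc[date(2020, 1, 1), "included"]          # valid + yes
        assert not out.loc[date(2020, 1, 2), "included"]      # invalid day
        assert not out.loc[date(2020, 1, 3), "included"]      # missing EMA
        assert np.isnan(out.loc[date(2020, 1, 2), "accel_exercise"])

    def test_contingency_matches_brute_force(self):
        rng = np.random.default_rng(8)
        n = 300
        out = pd.DataFrame({
            "participant_id": "P1",
            "day_date": [date(2020, 1, 1) + timedelta(days=i) for i in range(n)],
            "accel_exercise": rng.choice([0.0, 1.0, np.nan], size=n),
            "ema_exercise": rng.choice([0.0, 1.0, np.nan], size=n),
        })
        out["included"] = out.accel_exercise.notna() & out.ema_exercise.notna()
        t = contingency(out)
        tally = {"a": 0, "b": 0, "c": 0, "d": 0}
        for _, row in out.iterrows():
            if not row.included:
                continue
            key = {(1, 1): "a", (1, 0): "b", (0, 1): "c", (0, 0): "d"}[
                (int(row.ema_exercise), int(row.accel_exercise))]
            tally[key] += 1
        assert (t.a, t.b, t.c, t.d) == tuple(tally.values())
        assert t.n == int(out.included.sum())


class TestSummaries:
    def test_two_values(self):
        results = [KappaResult(kappa=0.2, n=10), KappaResult(kappa=0.4, n=10)]
        s = summarize_kappas(results)
        assert s.mean == pytest.approx(0.3)
        assert s.median == pytest.approx(0.3)
        assert (s.min, s.max) == (pytest.approx(0.2), pytest.approx(0.4))

    def test_undefined_excluded_and_counted(self):
        results = [KappaResult(kappa=0.2, n=10), KappaResult(kappa=0.4, n=10),
                   KappaResult(undefined=True, reason="constant")]
        s = summarize_kappas(results)
        assert s.n_participants == 2 and s.n_undefined == 1
        assert s.mean == pytest.approx(0.3)

    def test_bootstrap_ci_seed_reproducible(self):
        rng = np.random.default_rng(4)
        results = [KappaResult(kappa=float(k), n=50)
                   for k in rng.normal(0.3, 0.2, size=30)]
        s1 = summarize_kappas(results, seed=123)
        s2 = summarize_kappas(results, seed=123)
        assert (s1.ci_low, s1.ci_high) == (s2.ci_low, s2.ci_high)
        s3 = summarize_kappas(results, seed=124)
        assert (s1.ci_low, s1.ci_high) != (s3.ci_low, s3.ci_high)

    def test_empty_summary_flagged(self):
        s = summarize_kappas([KappaResult(undefined=True)])
        assert s.n_participants == 0 and s.n_undefined == 1
        assert np.isnan(s.mean)


class TestMonteCarloConsistency:
    def test_empirical_matches_analytic(self):
        """Empirical pooled kappa on i.i.d. day-level draws converges to the
        closed-form kappa of the generating joint distribution."""
        pi, se_a, sp_a, se_e, sp_e = 0.3, 0.9, 0.95, 0.7, 0.8
        target = analytic_kappa(pi, se_a, sp_a, se_e, sp_e)
        out = day_level_generator(pi, se_a, sp_a, se_e, sp_e,
                                  n_days=12807, seed=5)
        pooled = pooled_kappa([contingency(out)])
        assert abs(pooled.kappa - target) < 3 * pooled.se


class TestAnalyzeAndSweep:
    def test_analyze_report_shape(self, small_cohort):
        from concord import pipeline
        from concord.config import RunConfig
        out = pipeline.daily_outcomes(small_cohort.minutes, small_cohort.ema,
                                      RunConfig())
        rep = analyze(out, seed=0)
        assert set(rep) == {"per_participant", "pooled", "summary"}
        assert rep["pooled"]["n"] == sum(p["n"] for p in rep["per_participant"])
        for p in rep["per_participant"]:
            assert p["a"] + p["b"] + p["c"] + p["d"] == p["n"]

    def test_sweep_pooled_n_constant_and_perfect_agreement(self):
        """EMA copied from a 24-min-bout classification gives kappa 1 at
        every m <= 24 under MVPA, and constant included-day counts."""
        from concord.bout_detection import sweep_definitions
        from concord.day_processing import SLOTS_PER_DAY
        from helpers import make_day

        rng = np.random.default_rng(6)
        days, ema = [], []
        for p in range(3):
            for d in range(15):
                intensity = np.zeros(SLOTS_PER_DAY, dtype=np.int8)
                truth = rng.random() < 0.4
                if truth:
                    s = rng.integers(300, 1000)
                    intensity[s:s + 24] = 2
                day = make_day(intensity, pid=f"P{p}")
                day.day_date = date(2020, 1, 1) + timedelta(days=int(d))
                days.append(day)
                ema.append(EmaRecord(f"P{p}", day.day_date,
                                     "yes" if truth else "no"))
        sweep_cls = sweep_definitions(days)
        table = sweep_agreement(sweep_cls, ema)
        assert len(table) == 3 * 16
        assert table["n_days"].nunique() == 1
        mv = table[(table.intensity_set == "moderate+vigorous") &
                   (table.m <= 24)]
        assert np.allclose(mv["mean_kappa"], 1.0)
        assert np.allclose(mv["pooled_kappa"], 1.0)
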