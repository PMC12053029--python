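"""Box-Cox screening, mixed ANCOVA, speed grids, EMMs, Tukey contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from suspendkin.errors import EmptyOverlapError
from suspendkin.simulate import simulate_summary_table
from suspendkin.stats import (
    CHOLOEPUS_EMM,
    ModelSpec,
    compare_species_descriptive,
    fit_mixed_ancova,
    overlapping_speed_grid,
    screen_and_transform,
    stride_table_to_long,
    tukey_emm,
)


class TestScreenAndTransform:
    def test_symmetric_sample_untouched(self, rng):
        x = rng.normal(10, 2, size=200)
        out, lam, shift = screen_and_transform(x)
        assert lam is None and shift == 0.0
        assert np.array_equal(out, x)

    def test_lognormal_transformed_and_skew_reduced(self, rng):
        x = rng.lognormal(0, 1, size=300)
        out, lam, shift = screen_and_transform(x)
        assert lam is not None
        assert abs(sps.skew(out)) < abs(sps.skew(x))

    def test_nonpositive_values_shifted(self, rng):
        x = rng.lognormal(0, 1, size=300) - 2.0
        out, lam, shift = screen_and_transform(x)
        assert lam is not None
        assert shift == pytest.approx(1.0 - x.min())

    def test_constant_input_warns(self):
        with pytest.warns(UserWarning):
            out, lam, shift = screen_and_transform(np.full(20, 3.0))
        assert lam is None

    def test_residual_basis_overrides_raw_skew(self, rng):
        # two well-separated symmetric groups: raw values look skewed,
        # within-group residuals do not -> no transform
        x = np.concatenate([rng.normal(0, 1, 150), rng.normal(30, 1, 50)])
        resid = np.concatenate([rng.normal(0, 1, 150), rng.normal(0, 1, 50)])
        out, lam, _ = screen_and_transform(x, residuals=resid)
        assert lam is None

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            screen_and_transform(np.arange(5, dtype=float))


class TestFit:
    def test_recovers_known_event_effect_and_slope(self):
        rng = np.random.default_rng(3)
        df = simulate_summary_table(
            n_strides=80, event_effect=20.0, speed_slope=15.0, rng=rng
        )
        spec = ModelSpec("value", ("event",), include_interaction=False,
                         transform="none")
        fit = fit_mixed_ancova(df, spec)
        fe = fit.result.fe_params
        cov = np.asarray(fit.result.cov_params())[: fit.result.k_fe, : fit.result.k_fe]
        names = list(fe.index)
        tcrit = sps.t.ppf(0.975, fit.df_resid)
        i = names.index("C(event)[T.td]")
        assert abs(fe.iloc[i] - 20.0) <= tcrit * np.sqrt(cov[i, i])
        j = names.index("speed")
        assert abs(fe.iloc[j] - 15.0) <= tcrit * np.sqrt(cov[j, j])

    def test_needs_two_individuals(self):
        df = simulate_summary_table(n_individuals=1, n_strides=20)
        with pytest.raises(ValueError):
            fit_mixed_ancova(df, ModelSpec("value", ("event",)))

    def test_interaction_term_testable(self):
        df = simulate_summary_table(n_strides=60, rng=np.random.default_rng(5))
        fit = fit_mixed_ancova(df, ModelSpec("value", ("event",), transform="none"))
        res = fit.interaction_test("event")
        assert res["df_num"] == 2
        assert 0.0 <= res["p"] <= 1.0


class TestSpeedGrid:
    def test_partial_overlap(self):
        df = pd.DataFrame(
            {"g": ["a"] * 3 + ["b"] * 3, "speed": [0.1, 0.3, 0.5, 0.2, 0.4, 0.6]}
        )
        lo, mean, hi = overlapping_speed_grid(df, "g")
        assert (lo, hi) == (0.2, 0.5)
        assert mean == pytest.approx(np.mean([0.3, 0.5, 0.2, 0.4]))

    def test_identical_ranges(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"], "speed": [0.1, 0.5, 0.1, 0.5]})
        lo, mean, hi = overlapping_speed_grid(df, "g")
        assert (lo, mean, hi) == (0.1, 0.3, 0.5)

    def test_matches_brute_force_scan(self, rng):
        for _ in range(20):
            df = pd.DataFrame(
                {
                    "g": rng.choice(["a", "b", "c"], size=30),
                    "speed": rng.uniform(0, 1, size=30),
                }
            )
            if df.groupby("g")["speed"].count().min() < 2 or df["g"].nunique() < 2:
                continue
            per_level = {g: (s.min(), s.max()) for g, s in df.groupby("g")["speed"]}
            lo_o = max(v[0] for v in per_level.values())
            hi_o = min(v[1] for v in per_level.values())
            if lo_o > hi_o:
                with pytest.raises(EmptyOverlapError):
                    overlapping_speed_grid(df, "g")
                continue
            lo, mean, hi = overlapping_speed_grid(df, "g")
            assert (lo, hi) == (lo_o, hi_o)

    def test_disjoint_levels_named(self):
        df = pd.DataFrame(
            {"g": ["a", "a", "b", "b"], "speed": [0.1, 0.2, 0.5, 0.6]}
        )
        with pytest.raises(EmptyOverlapError, match="a.*b"):
            overlapping_speed_grid(df, "g")


class TestEmmTukey:
    def _balanced(self, rng, slope=0.0):
        # every stride contributes one row per event at its own speed, so
        # per-event speed distributions are identical (balanced design)
        rows = []
        for ind in range(4):
            for k in range(5):
                speed = rng.uniform(0.1, 0.5)
                for ev, mu in (("td", 130.0), ("ms", 110.0), ("lo", 115.0)):
                    rows.append(
                        {
                            "individual": f"I{ind}", "trial": f"I{ind}_t{k}",
                            "speed": speed, "event": ev,
                            "value": mu + slope * speed + rng.normal(0, 0.5),
                        }
                    )
        return pd.DataFrame(rows)

    def test_balanced_design_emms_equal_group_means(self, rng):
        df = self._balanced(rng)
        fit = fit_mixed_ancova(
            df, ModelSpec("value", ("event",), include_interaction=False,
                          transform="none")
        )
        emm, _ = tukey_emm(fit, "event")
        means = df.groupby("event")["value"].mean()
        for _, row in emm.iterrows():
            assert row["emmean"] == pytest.approx(means[row["event"]], abs=1e-6)
        assert (emm["lower_cl"] <= emm["emmean"]).all()
        assert (emm["emmean"] <= emm["upper_cl"]).all()

    def test_two_level_factor_tukey_equals_t_test(self):
        rng = np.random.default_rng(8)
        df = simulate_summary_table(n_strides=40, rng=rng)
        df = df[df["event"].isin(["td", "ms"])].copy()
        fit = fit_mixed_ancova(
            df, ModelSpec("value", ("event",), include_interaction=False,
                          transform="none")
        )
        _, con = tukey_emm(fit, "event")
        est, se = con.loc[0, "estimate"], con.loc[0, "se"]
        p_t = 2 * sps.t.sf(abs(est) / se, fit.df_resid)
        assert con.loc[0, "p_tukey"] == pytest.approx(p_t, abs=1e-6)

    def test_contrasts_invariant_to_level_relabeling(self):
        rng = np.random.default_rng(9)
        df = simulate_summary_table(n_strides=60, event_effect=10.0, rng=rng)
        fit_a = fit_mixed_ancova(
            df, ModelSpec("value", ("event",), include_interaction=False,
                          transform="none")
        )
        relab = df.copy()
        # force a different patsy reference level by renaming
        relab["event"] = relab["event"].map({"td": "z_td", "ms": "a_ms", "lo": "lo"})
        fit_b = fit_mixed_ancova(
            relab, ModelSpec("value", ("event",), include_interaction=False,
                             transform="none")
        )
        _, con_a = tukey_emm(fit_a, "event", at_speeds=[0.3])
        _, con_b = tukey_emm(fit_b, "event", at_speeds=[0.3])
        est_a = {frozenset(c.split(" - ")): abs(e)
                 for c, e in zip(con_a["contrast"], con_a["estimate"])}
        rename = {"z_td": "td", "a_ms": "ms", "lo": "lo"}
        for c, e in zip(con_b["contrast"], con_b["estimate"]):
            key = frozenset(rename[x] for x in c.split(" - "))
            assert abs(e) == pytest.approx(est_a[key], abs=1e-6)


class TestTidyHelpers:
    def test_long_format_melt(self):
        wide = pd.DataFrame(
            {
                "individual": ["a"], "trial": ["t1"], "stride_id": ["s1"],
                "limb": ["fore"], "side": ["left"], "speed": [0.3],
                "midjoint_angle_td": [130.0], "midjoint_angle_ms": [100.0],
                "midjoint_angle_lo": [110.0],
            }
        )
        long = stride_table_to_long(wide, "midjoint_angle", girdle="fore")
        assert len(long) == 3
        assert set(long["event"]) == {"td", "ms", "lo"}
        assert long.loc[long["event"] == "ms", "midjoint_angle"].iloc[0] == 100.0

    def test_species_comparison_reports_differences(self):
        emm = pd.DataFrame(
            {
                "event": ["td", "ms", "lo"],
                "emmean": [136.9, 102.1, 105.1],
                "lower_cl": [127.0, 95.1, 98.3],
                "upper_cl": [146.9, 109.0, 111.8],
            }
        )
        cmp = compare_species_descriptive(emm, "fore")
        assert len(cmp) == 3
        td = cmp[cmp["event"] == "td"].iloc[0]
        ref = CHOLOEPUS_EMM.query("girdle == 'fore' and event == 'td'")["emmean"].iloc[0]
        assert td["difference"] == pytest.approx(136.9 - ref)
        assert not td["ci_overlap"]
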