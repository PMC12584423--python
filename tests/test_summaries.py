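import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from behavar import (
    ModelSpec,
    VarianceSummary,
    contrast_table,
    fit_mcmc,
    fixed_effect_summary,
    format_contrast_grid,
    group_mean_contrasts,
    repeatability,
    variance_components,
)
from behavar.exceptions import AlignmentError

from helpers import fake_samples, make_table


class TestRepeatability:
    @pytest.mark.parametrize("va,vw,expected", [(1.0, 1.0, 0.5), (0.0, 7.0, 0.0),
                                                (3.0, 1.0, 0.75)])
    def test_ratio_arithmetic(self, va, vw, expected):
        assert repeatability(va, vw) == expected

    def test_undefined_at_zero_total(self):
        with pytest.raises(ZeroDivisionError):
            repeatability(0.0, 0.0)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            repeatability(-1.0, 2.0)

    @given(va=st.floats(0.0, 1e6), vw=st.floats(1e-6, 1e6),
           c=st.floats(1e-3, 1e3))
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, va, vw, c):
        r1 = repeatability(va, vw)
        r2 = repeatability(c * va, c * vw)
        assert 0.0 <= r1 <= 1.0
        assert abs(r1 - r2) < 1e-9


class TestFixedEffectSummary:
    def _samples(self, beta):
        names = ["intercept", "population[PM]", "sex[M]", "population[PM]:sex[M]"]
        return fake_samples(beta, coef_names=names)

    def test_degenerate_draws(self):
        s = self._samples(np.full((1, 50, 4), 0.5))
        out = fixed_effect_summary(s)
        assert set(out["term"]) == {"population", "sex", "population:sex"}
        assert (out["mean"] == 0.5).all()
        assert (out["lower95"] == 0.5).all() and (out["upper95"] == 0.5).all()

    def test_normal_quantile_oracle(self, rng):
        s = self._samples(rng.normal(size=(1, 100_000, 4)))
        out = fixed_effect_summary(s)
        assert np.all(np.abs(out["lower95"] + 1.96) < 0.05)
        assert np.all(np.abs(out["upper95"] - 1.96) < 0.05)

    def test_negating_draws_negates_summary(self, rng):
        beta = rng.normal(size=(1, 2000, 4))
        a = fixed_effect_summary(self._samples(beta))
        b = fixed_effect_summary(self._samples(-beta))
        np.testing.assert_allclose(a["mean"], -b["mean"], rtol=1e-12)
        np.testing.assert_allclose(a["lower95"], -b["upper95"], rtol=1e-12)

    def test_absent_term_errors(self):
        s = fake_samples(np.zeros((1, 10, 1)), coef_names=["intercept"])
        from behavar.exceptions import ConfigurationError

        with pytest.raises(ConfigurationError):
            fixed_effect_summary(s)


class TestVarianceComponents:
    def test_draw_wise_identities(self, rng):
        sa = rng.gamma(2.0, size=(1, 500, 4))
        sw = rng.gamma(2.0, size=(1, 500, 4))
        s = fake_samples(np.zeros((1, 500, 1)), sigma_a=sa, sigma_w=sw,
                         spec=ModelSpec.from_id("M4"))
        out = variance_components(s)
        for g, v in enumerate(out):
            np.testing.assert_array_equal(v.va_draws, sa[0, :, g] ** 2)
            np.testing.assert_array_equal(
                v.r_draws, v.va_draws / (v.va_draws + v.vw_draws)
            )
            assert np.all((v.r_draws >= 0) & (v.r_draws <= 1))

    def test_shared_components_identical_across_groups(self, fast_mcmc):
        table = make_table(group_sizes=(3, 3, 3, 3), seed=1)
        spec = ModelSpec.from_id("M1")
        from behavar import build_design

        s = fit_mcmc(None, build_design(table, spec), spec, config=fast_mcmc)
        out = variance_components(s)
        for v in out[1:]:
            np.testing.assert_array_equal(v.va_draws, out[0].va_draws)
            np.testing.assert_array_equal(v.vw_draws, out[0].vw_draws)


def _summaries_from(rng, n_draws=5000, groups=("PKF", "PKM", "PMF", "PMM"), scale=1.0):
    out = []
    for k, g in enumerate(groups):
        out.append(VarianceSummary(
            group=g,
            va_draws=rng.gamma(3.0, scale, size=n_draws),
            vw_draws=rng.gamma(3.0, scale, size=n_draws),
        ))
    return out


class TestContrastTable:
    def test_identical_groups_give_zero_nonsubstantial(self, rng):
        draws = rng.gamma(2.0, size=3000)
        vws = rng.gamma(2.0, size=3000)
        summaries = [VarianceSummary(g, draws.copy(), vws.copy())
                     for g in ("PKF", "PKM")]
        t = contrast_table(summaries, "delta_vw")
        assert t.mean.loc["PKF", "PKM"] == 0.0
        assert not t.substantial.loc["PKF", "PKM"]

    def test_constant_draws(self):
        a = VarianceSummary("PKF", np.full(100, 0.5), np.full(100, 1.0))
        b = VarianceSummary("PKM", np.full(100, 0.5), np.full(100, 0.8))
        t = contrast_table([a, b], "delta_vw")
        e = t.entry("PKF", "PKM")
        assert e["mean"] == pytest.approx(0.2, abs=1e-12)
        assert e["lower95"] == pytest.approx(0.2) and e["upper95"] == pytest.approx(0.2)
        assert e["substantial"]

    def test_brute_force_oracle(self, rng):
        summaries = _summaries_from(rng)
        t = contrast_table(summaries, "delta_r")
        for i, a in enumerate(summaries):
            for b in summaries[i + 1:]:
                d = a.r_draws - b.r_draws
                np.testing.assert_allclose(t.mean.loc[a.group, b.group], d.mean(),
                                           rtol=1e-12)
                np.testing.assert_allclose(
                    [t.lower.loc[a.group, b.group], t.upper.loc[a.group, b.group]],
                    np.quantile(d, (0.025, 0.975)), rtol=1e-12,
                )

    def test_antisymmetry_and_zero_diagonal_exact(self, rng):
        t = contrast_table(_summaries_from(rng), "delta_vw")
        M = t.mean.to_numpy()
        np.testing.assert_array_equal(M, -M.T)
        assert np.all(np.diag(M) == 0.0)
        assert not np.any(np.diag(t.substantial.to_numpy()))
        np.testing.assert_array_equal(t.lower.to_numpy(), -t.upper.to_numpy().T)

    def test_mean_separates_but_interval_does_not(self, rng):
        """Draw-wise contract: the contrast mean equals the difference of
        means exactly, but the CI is narrower than naive endpoint
        differencing when draws are positively correlated."""
        base = rng.gamma(3.0, size=4000)
        a = VarianceSummary("PKF", np.full(4000, 1.0), base + 0.3)
        b = VarianceSummary("PKM", np.full(4000, 1.0), base)
        t = contrast_table([a, b], "delta_vw")
        np.testing.assert_allclose(
            t.mean.loc["PKF", "PKM"], a.vw_draws.mean() - b.vw_draws.mean(), rtol=1e-12
        )
        naive_width = (np.quantile(a.vw_draws, 0.975) - np.quantile(b.vw_draws, 0.025)) - (
            np.quantile(a.vw_draws, 0.025) - np.quantile(b.vw_draws, 0.975)
        )
        width = t.upper.loc["PKF", "PKM"] - t.lower.loc["PKF", "PKM"]
        assert width < naive_width

    def test_na_flag_when_va_indistinguishable_from_zero(self, rng):
        lowva = VarianceSummary("PKF", np.concatenate([np.zeros(200), rng.gamma(0.2, size=800)]),
                                rng.gamma(3.0, size=1000))
        ok = VarianceSummary("PKM", rng.gamma(3.0, 1.0, size=1000) + 0.5,
                             rng.gamma(3.0, size=1000))
        t = contrast_table([lowva, ok], "delta_r")
        assert t.na_flag.loc["PKF", "PKM"] and t.na_flag.loc["PKM", "PKF"]
        # raw value retained alongside the flag
        assert np.isfinite(t.mean.loc["PKF", "PKM"])
        t_vw = contrast_table([lowva, ok], "delta_vw")
        assert not t_vw.na_flag.to_numpy().any()

    def test_misaligned_draws_rejected(self, rng):
        a = VarianceSummary("PKF", rng.gamma(2, size=100), rng.gamma(2, size=100))
        b = VarianceSummary("PKM", rng.gamma(2, size=101), rng.gamma(2, size=101))
        with pytest.raises(AlignmentError):
            contrast_table([a, b], "delta_vw")


def test_format_grid_layout(rng):
    summaries = _summaries_from(rng)
    vw = contrast_table(summaries, "delta_vw")
    r = contrast_table(summaries, "delta_r")
    grid = format_contrast_grid(vw, r)
    assert grid.loc["PKF", "PKF"] == "-"
    assert "(" in grid.loc["PKF", "PKM"]  # upper triangle: Delta Vw
    assert "(" in grid.loc["PKM", "PKF"] or grid.loc["PKM", "PKF"] == "NA"


def test_group_mean_contrasts_detects_shift(fast_mcmc):
    from behavar import build_design

    table = make_table(group_sizes=(6, 6, 6, 6), seed=2)
    # shift PMF group strongly upward
    df = table.df.drop(columns="group").copy()
    df.loc[df["population"] + df["sex"] == "PMF", "value"] += 3.0
    table = type(table)(df)
    spec = ModelSpec.from_id("M1")
    design = build_design(table, spec)
    s = fit_mcmc(None, design, spec, config=fast_mcmc)
    t = group_mean_contrasts(s, design)
    assert t.mean.loc["PMF", "PKF"] > 1.0
    assert t.substantial.loc["PMF", "PKF"]
    np.testing.assert_array_equal(t.mean.to_numpy(), -t.mean.to_numpy().T)
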