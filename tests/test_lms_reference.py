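import numpy as np
import pytest

from bivakit.cohort_io import Sex
from bivakit.errors import DomainError, ExtrapolationError, ParseError
from bivakit.lms_reference import (
    LMSReference,
    centile_curve,
    centile_table,
    fit_lms,
    read_reference,
    to_sds,
    write_reference,
)


def simulate_lms_sample(n, seed, l0=0.3, l_slope=-0.01):
    """Draw (values, ages) from known smooth L*, M*, S* curves over 4-20 y."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(4.0, 20.0, n)
    L = l0 + l_slope * (ages - 12.0)
    M = 600.0 * np.exp(-0.05 * (ages - 4.0)) + 250.0
    S = 0.10 + 0.002 * (ages - 12.0)
    z = rng.standard_normal(n)
    values = M * np.power(1.0 + L * S * z, 1.0 / L)
    return values, ages


def true_m(ages):
    return 600.0 * np.exp(-0.05 * (np.asarray(ages) - 4.0)) + 250.0


@pytest.fixture(scope="module")
def fitted_ref():
    values, ages = simulate_lms_sample(5000, seed=42)
    return fit_lms(values, ages, Sex.MALE, "rh"), values, ages


class TestFit:
    def test_recovers_generating_median_and_calibrates(self, fitted_ref):
        ref, values, ages = fitted_ref
        interior = (ref.age_grid > 5.0) & (ref.age_grid < 19.0)
        rel_err = np.abs(ref.M - true_m(ref.age_grid)) / true_m(ref.age_grid)
        assert rel_err[interior].max() < 0.02
        assert abs(ref.fit_meta["sample_z_mean"]) < 0.05
        assert abs(ref.fit_meta["sample_z_sd"] - 1.0) < 0.05
        z = to_sds(values, ages, ref)
        assert abs(np.mean(z < 0.0) - 0.5) < 0.03  # half the sample below the median

    def test_median_recovery_over_replicates(self):
        """Median absolute relative error of M at interior ages stays < 2%."""
        probe = np.linspace(6.0, 18.0, 25)
        errs = []
        for rep in range(20):
            values, ages = simulate_lms_sample(2000, seed=100 + rep)
            ref = fit_lms(values, ages, Sex.MALE, "rh")
            _, M, _ = ref.curves_at(probe)
            errs.append(np.median(np.abs(M - true_m(probe)) / true_m(probe)))
        assert np.median(errs) < 0.02

    def test_constant_data_settles_on_flat_minimal_model(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(4.0, 20.0, 500)
        values = 50.0 * (1.0 + 0.01 * rng.standard_normal(500))
        ref = fit_lms(values, ages, Sex.FEMALE, "flat")
        assert np.allclose(ref.M, 50.0, rtol=0.01)
        assert ref.fit_meta["edf"]["M"] == 1
        assert np.allclose(ref.S, 0.01, rtol=0.2)  # sample CV recovered

    def test_single_entry_complexity_grid_is_forced(self):
        values, ages = simulate_lms_sample(500, seed=1)
        ref = fit_lms(values, ages, Sex.MALE, "rh", complexity_grid=[(1, 3, 1)])
        assert ref.fit_meta["edf"] == {"L": 1, "M": 3, "S": 1}
        assert len(ref.fit_meta["trace"]) == 1

    def test_selection_trace_is_recorded(self, fitted_ref):
        ref, _, _ = fitted_ref
        trace = ref.fit_meta["trace"]
        assert trace[0]["accepted"]
        assert all({"edf", "deviance", "accepted", "reason"} <= set(row) for row in trace)

    def test_domain_errors(self):
        values, ages = simulate_lms_sample(200, seed=2)
        values[0] = -1.0
        with pytest.raises(DomainError):
            fit_lms(values, ages, Sex.MALE, "rh")
        with pytest.raises(DomainError):
            fit_lms(values[:10], ages[:10], Sex.MALE, "rh")  # below minimum n


class TestSDS:
    def test_value_at_median_maps_to_zero(self, fitted_ref):
        ref, _, _ = fitted_ref
        ages = np.array([6.0, 12.0, 18.0])
        _, M, _ = ref.curves_at(ages)
        assert to_sds(M, ages, ref) == pytest.approx(np.zeros(3), abs=1e-10)

    def test_linear_case_matches_closed_form(self):
        ref = LMSReference(
            "t", Sex.MALE, age_grid=[4.0, 20.0], L=[1.0, 1.0], M=[50.0, 50.0], S=[0.10, 0.10]
        )
        assert to_sds(55.0, 10.0, ref) == pytest.approx(1.0)

    def test_continuity_at_l_equal_zero(self):
        mk = lambda l: LMSReference("t", Sex.MALE, [4.0, 20.0], [l, l], [50.0, 50.0], [0.1, 0.1])
        z_plus = to_sds(57.0, 10.0, mk(1e-3))
        z_minus = to_sds(57.0, 10.0, mk(-1e-3))
        z_zero = to_sds(57.0, 10.0, mk(0.0))
        assert z_plus == pytest.approx(z_zero, abs=1e-4)
        assert z_minus == pytest.approx(z_zero, abs=1e-4)

    def test_extrapolation_and_domain_refusals(self, fitted_ref):
        ref, _, _ = fitted_ref
        lo, hi = ref.support
        with pytest.raises(ExtrapolationError):
            to_sds(400.0, hi + 1.0, ref)
        with pytest.raises(DomainError):
            to_sds(-5.0, 12.0, ref)


class TestCentiles:
    def test_p50_is_the_median_curve(self, fitted_ref):
        ref, _, _ = fitted_ref
        assert centile_curve(ref, 50.0, ref.age_grid) == pytest.approx(ref.M, rel=1e-10)

    def test_round_trip_with_to_sds(self, fitted_ref):
        from scipy.stats import norm

        ref, _, _ = fitted_ref
        for p in (3.0, 25.0, 91.0, 97.0):
            vals = centile_curve(ref, p, ref.age_grid)
            z = to_sds(vals, ref.age_grid, ref)
            assert np.max(np.abs(z - norm.ppf(p / 100.0))) < 1e-8
        assert to_sds(centile_curve(ref, 91.0, ref.age_grid), ref.age_grid, ref) == pytest.approx(
            np.full(ref.age_grid.size, 1.341), abs=1e-3
        )

    def test_centiles_never_cross(self, fitted_ref):
        ref, _, _ = fitted_ref
        tbl = centile_table(ref)
        curves = tbl[[c for c in tbl.columns if c.startswith("p")]].to_numpy()
        assert np.all(np.diff(curves, axis=1) > 0)

    def test_undefined_region_is_gap_not_crash(self):
        # L*S*z_p <= -1 for a low centile with strongly negative L and big S
        ref = LMSReference("t", Sex.MALE, [4.0, 20.0], [-3.0, -3.0], [50.0, 50.0], [0.5, 0.5])
        vals = centile_curve(ref, 97.0, [8.0, 16.0])  # high centile -> 1 + LSz < 0
        assert np.all(np.isnan(vals))

    def test_percentile_domain(self, fitted_ref):
        ref, _, _ = fitted_ref
        with pytest.raises(DomainError):
            centile_curve(ref, 0.0, ref.age_grid)


class TestSerialisation:
    def test_write_read_round_trip(self, fitted_ref, tmp_path):
        ref, _, _ = fitted_ref
        path = tmp_path / "ref.csv"
        write_reference(ref, path)
        (back,) = read_reference(path)
        assert back.trait == ref.trait and back.sex == ref.sex
        np.testing.assert_allclose(back.age_grid, ref.age_grid, rtol=1e-9)
        np.testing.assert_allclose(back.M, ref.M, rtol=1e-9)
        np.testing.assert_allclose(back.L, ref.L, atol=1e-9)
        np.testing.assert_allclose(back.S, ref.S, rtol=1e-9)

    @pytest.mark.parametrize(
        "mutation",
        ["non_monotone_age", "nonpositive_s"],
    )
    def test_malformed_tables_raise_parse_error(self, tmp_path, mutation):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "trait": "rh",
                "sex": "male",
                "age_y": [4.0, 5.0, 6.0],
                "L": 0.0,
                "M": [500.0, 480.0, 460.0],
                "S": 0.1,
            }
        )
        if mutation == "non_monotone_age":
            frame.loc[2, "age_y"] = 4.5
        else:
            frame.loc[1, "S"] = -0.1
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ParseError):
            read_reference(path)
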