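import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldhsim import sorption as so
from ldhsim import synthetic as syn


class TestDatasets:
    def test_kinetic_validation(self):
        with pytest.raises(ValueError):
            so.KineticDataset([5, 3, 10], [1, 2, 3])  # not increasing
        with pytest.raises(ValueError):
            so.KineticDataset([1, 2, 3], [1, -2, 3])  # negative uptake

    def test_release_monotonicity_tolerance(self):
        so.ReleaseDataset([1, 2, 3], [0.1, 0.09, 0.2])  # within noise
        with pytest.raises(ValueError):
            so.ReleaseDataset([1, 2, 3], [0.5, 0.1, 0.6])

    def test_csv_roundtrip(self, tmp_path):
        d = so.IsothermDataset([120.0, 500.0, 3500.0], [1.0, 2.0, 3.0])
        p = tmp_path / "iso.csv"
        d.to_csv(p)
        assert p.read_text().splitlines()[0] == "Ceq_ppm,Q_mg_per_g"
        back = so.IsothermDataset.from_csv(p)
        assert np.allclose(back.C_eq, d.C_eq) and np.allclose(back.Q, d.Q)


NOISELESS_CASES = [
    ("kinetics", "pfo", {"Qe": 90.0, "k1": 0.01}),
    ("kinetics", "pso", {"Qe": 490.0, "k2": 2.5e-5}),
    ("kinetics", "elovich", {"alpha": 5.0, "beta": 0.05}),
    ("isotherm", "freundlich", {"k": 0.455, "n": 2.35}),
    ("isotherm", "sips", {"Qm": 300.0, "Ks": 0.002, "m": 1.6}),
    ("release", "zero", {"k": 0.002}),
    ("release", "first", {"k": 0.01}),
    ("release", "higuchi", {"k": 0.03}),
    ("release", "hixson_crowell", {"k": 0.001}),
    ("release", "korsmeyer_peppas", {"k": 0.15, "n": 0.23}),
]


@pytest.mark.parametrize("family,model,params", NOISELESS_CASES)
def test_noiseless_exact_recovery(family, model, params):
    """Every fitter recovers its generating parameters on noiseless data."""
    if family == "kinetics":
        d = syn.gen_kinetic_dataset(model, params)
        fit = so.fit_kinetics(d, model)
    elif family == "isotherm":
        if model == "freundlich":
            d = syn.gen_isotherm_dataset(model, params)
            fit = so.fit_freundlich(d)
        else:
            d = syn.gen_isotherm_dataset(model, params, c_range=(10, 5000), n_points=20)
            fit = so.fit_sips(d)
    else:
        t = np.linspace(5, 180, 15)
        F = so.release_model(model)(t, **params)
        d = so.ReleaseDataset(t, np.clip(F, 0, 1))
        fit = so.fit_release(d, model)
    for key, val in params.items():
        assert fit.params[key] == pytest.approx(val, rel=1e-6), (model, key)
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)


class TestKinetics:
    def test_pso_data_prefers_pso_over_pfo(self):
        d = syn.gen_kinetic_dataset(
            "pso", syn.STUDY["powder_pso"], noise=syn.NoiseModel(sigma=0.02, seed=8)
        )
        r2_pso = so.fit_kinetics(d, "pso").r2
        r2_pfo = so.fit_kinetics(d, "pfo").r2
        assert r2_pso > r2_pfo

    def test_pso_matches_linearised_regression(self):
        # t/Q vs t is linear for PSO: slope 1/Qe, intercept 1/(k2 Qe^2)
        d = syn.gen_kinetic_dataset("pso", {"Qe": 90.0, "k2": 1.4e-4})
        slope, intercept = np.polyfit(d.t, d.t / d.Q, 1)
        fit = so.fit_kinetics(d, "pso")
        assert fit.params["Qe"] == pytest.approx(1 / slope, rel=1e-6)
        assert fit.params["k2"] == pytest.approx(slope**2 / intercept, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4"):
            so.fit_kinetics(so.KineticDataset([1, 2, 3], [1, 2, 3]), "pso")


class TestFreundlich:
    def test_n_equal_one_reduces_to_proportionality(self):
        d = syn.gen_isotherm_dataset("freundlich", {"k": 0.06, "n": 1.0})
        fit = so.fit_freundlich(d)
        slope = np.sum(d.C_eq * d.Q) / np.sum(d.C_eq**2)  # no-intercept line
        assert fit.params["n"] == pytest.approx(1.0, abs=1e-6)
        assert fit.params["k"] == pytest.approx(slope, rel=1e-6)

    def test_optimum_beats_grid_search(self):
        d = syn.gen_isotherm_dataset(
            "freundlich", {"k": 0.455, "n": 2.35}, noise=syn.NoiseModel(sigma=0.02, seed=17)
        )
        fit = so.fit_freundlich(d)
        w = so._weights(d.Q)
        sse_fit = float(np.sum((fit.residuals / w) ** 2))
        ks = np.geomspace(0.05, 5, 40)
        ns = np.linspace(1.0, 4.0, 40)
        grid = min(
            float(np.sum(((so.freundlich(d.C_eq, k, n) - d.Q) / w) ** 2))
            for k in ks
            for n in ns
        )
        assert sse_fit <= grid + 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_unit_rescaling_covariance(self, scale):
        # C -> c C rescales k by c^(-1/n), leaves n unchanged
        base = syn.gen_isotherm_dataset(
            "freundlich", {"k": 0.455, "n": 2.35}, noise=syn.NoiseModel(sigma=0.02, seed=5)
        )
        f0 = so.fit_freundlich(base)
        f1 = so.fit_freundlich(so.IsothermDataset(base.C_eq * scale, base.Q))
        assert f1.params["n"] == pytest.approx(f0.params["n"], rel=1e-4)
        assert f1.params["k"] == pytest.approx(
            f0.params["k"] * scale ** (-1.0 / f0.params["n"]), rel=1e-3
        )


class TestSips:
    def test_langmuir_data_gives_m_near_one(self):
        d = syn.gen_isotherm_dataset(
            "sips", {"Qm": 200.0, "Ks": 0.003, "m": 1.0},
            c_range=(10, 5000), n_points=20, noise=syn.NoiseModel(sigma=0.01, seed=9),
        )
        fit = so.fit_sips(d)
        assert abs(fit.params["m"] - 1.0) <= 2 * fit.se["m"] + 0.05

    def test_optimum_beats_grid(self):
        d = syn.gen_isotherm_dataset(
            "sips", syn.STUDY["tc_sips"], c_range=(5, 40), n_points=8,
            noise=syn.NoiseModel(sigma=0.02, seed=4),
        )
        fit = so.fit_sips(d)
        w = so._weights(d.Q)
        sse_fit = float(np.sum((fit.residuals / w) ** 2))
        best = np.inf
        for qm in np.geomspace(200, 5000, 12):
            for ks in np.geomspace(1e-7, 1e-2, 12):
                for m in np.linspace(0.5, 4, 12):
                    best = min(
                        best,
                        float(np.sum(((so.sips(d.C_eq, qm, ks, m) - d.Q) / w) ** 2)),
                    )
        assert sse_fit <= best + 1e-12

    def test_no_plateau_flag(self):
        d = syn.gen_isotherm_dataset(
            "sips", syn.STUDY["tc_sips"], c_range=(5, 40), n_points=8
        )
        fit = so.fit_sips(d)
        assert fit.flags["plateau"] is False
        assert fit.flags["cooperative"] is True


class TestRelease:
    def test_linear_release_gives_exponent_one(self):
        t = np.linspace(5, 180, 12)
        d = so.ReleaseDataset(t, 0.003 * t)
        fit = so.fit_release(d, "korsmeyer_peppas")
        assert fit.params["n"] == pytest.approx(1.0, rel=1e-6)

    def test_kp_matches_loglog_regression_on_noiseless(self):
        d = syn.gen_release_dataset({"k": 0.15, "n": 0.23})
        n_ll, logk = np.polyfit(np.log(d.t), np.log(d.F), 1)
        fit = so.fit_release(d, "korsmeyer_peppas")
        assert fit.params["n"] == pytest.approx(n_ll, rel=1e-6)
        assert fit.params["k"] == pytest.approx(np.exp(logk), rel=1e-6)

    def test_sixty_percent_filter(self):
        t = np.linspace(5, 180, 12)
        F = np.minimum(0.008 * t, 0.95)
        d = so.ReleaseDataset(t, F)
        fit = so.fit_release(d, "korsmeyer_peppas")
        assert len(fit.residuals) == int((F <= 0.6).sum())

    def test_too_few_valid_points_rejected(self):
        d = so.ReleaseDataset([1.0, 10, 100], [0.7, 0.8, 0.9], noise_tolerance=1)
        with pytest.raises(ValueError, match="0.6"):
            so.fit_release(d, "korsmeyer_peppas")

    def test_fickian_label(self):
        d = syn.gen_release_dataset({"k": 0.15, "n": 0.23})
        assert so.fit_release(d).flags["mechanism"] == "fickian_diffusion"


class TestCompareModels:
    def test_single_fit_is_its_own_best(self):
        d = syn.gen_release_dataset({"k": 0.15, "n": 0.23})
        fit = so.fit_release(d, "higuchi")
        assert so.compare_models([fit])[0] is fit

    def test_ranking_matches_pairwise_r2(self):
        d = syn.gen_release_dataset(
            {"k": 0.15, "n": 0.23}, noise=syn.NoiseModel(sigma=0.02, seed=2)
        )
        fits = [so.fit_release(d, m) for m in so.RELEASE_MODELS]
        # restrict to fits on the same filtered point set
        fits = [f for f in fits if len(f.residuals) == len(fits[0].residuals)]
        ranked = so.compare_models(fits)
        r2s = [f.r2 for f in ranked]
        assert r2s == sorted(r2s, reverse=True)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            so.compare_models([])


class TestLoadingArithmetic:
    def test_no_uptake(self):
        assert so.loading_from_concentration(500, 500, 1e-3, 1e-3) == 0.0

    def test_hand_value(self):
        # 2291 ppm start, 1000 ppm left, 1 mL on 1.3 mg
        q = so.loading_from_concentration(2291, 1000, 1e-3, 1.3e-3)
        assert q == pytest.approx(993.1, abs=0.05)

    def test_mass_linearity(self):
        q1 = so.loading_from_concentration(2291, 1000, 1e-3, 1.3e-3)
        q2 = so.loading_from_concentration(2291, 1000, 1e-3, 2.6e-3)
        assert q1 == pytest.approx(2 * q2)

    def test_negative_requires_flag(self):
        with pytest.raises(ValueError):
            so.loading_from_concentration(100, 200, 1e-3, 1e-3)
        assert so.loading_from_concentration(100, 200, 1e-3, 1e-3, allow_negative=True) < 0


class TestCalibration:
    def test_zero_at_intercept(self):
        cal = so.CalibrationLine(slope=0.01, intercept=0.05)
        assert so.concentration_from_absorbance(0.05, cal) == 0.0

    def test_round_trip_identity(self):
        cal = so.CalibrationLine(slope=0.0123, intercept=0.02)
        c0 = 321.0
        a = cal.slope * c0 + cal.intercept
        assert so.concentration_from_absorbance(a, cal) == pytest.approx(c0, rel=1e-12)

    def test_two_point_hand_solution(self):
        cal = so.CalibrationLine.from_standards([100, 300], [0.2, 0.5])
        # line through the two points: slope 0.0015, intercept 0.05
        assert cal.slope == pytest.approx(0.0015)
        assert so.concentration_from_absorbance(0.35, cal) == pytest.approx(200.0)

    def test_dilution_factor(self):
        cal = so.CalibrationLine(slope=0.01)
        assert so.concentration_from_absorbance(1.0, cal, dilution=10) == pytest.approx(1000.0)

    def test_extrapolation_warns(self):
        cal = so.CalibrationLine(slope=0.01)
        with pytest.warns(UserWarning, match="extrapolat"):
            so.concentration_from_absorbance(5.0, cal, A_max=2.0)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            so.CalibrationLine(slope=0.0)


@pytest.mark.parametrize(
    "generator,truth",
    [("pso", syn.STUDY["powder_pso"]), ("pfo", {"Qe": 200.0, "k1": 0.008})],
)
def test_generating_model_wins_in_expectation(generator, truth):
    """Over replicates, the generating kinetic law out-fits the other."""
    wins = 0
    n_rep = 40
    for rep in range(n_rep):
        d = syn.gen_kinetic_dataset(
            generator, truth, noise=syn.NoiseModel(sigma=0.02, seed=1000 + rep)
        )
        other = "pfo" if generator == "pso" else "pso"
        if so.fit_kinetics(d, generator).r2 >= so.fit_kinetics(d, other).r2:
            wins += 1
    assert wins >= 0.9 * n_rep
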