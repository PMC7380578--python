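"""SSR, chi-square acceptance, flux fitting, profile confidence bounds."""

import numpy as np
import pytest

from conftest import emp_fluxes, make_fluxstate, noiseless_dataset
from fluxtherm import fixtures as fx
from fluxtherm.emu import MIDVector, TracerSpec, metabolite_emu, simulate_mids
from fluxtherm.fluxfit import (Dataset, FitError, FluxState, TracerData,
                               chi2_acceptance, compute_ssr,
                               confidence_intervals, fit_fluxes, residuals)
from fluxtherm.network import parse_model

RATE_TOY = parse_model(
    "@met A 1 0 0 0\n@met B 1 0 0 1\n"
    "inflow\tA (a)\tB (a)\t0\t0\t1000\ttransport\n"
    "outflow\tB (a)\t-\t0\t0\t1000\ttransport", name="rate-toy")


def test_fluxstate_net_and_exchange():
    fs = FluxState(("a", "b"), np.array([10.0, 5.0]), np.array([3.0, 8.0]))
    assert fs.net.tolist() == [7.0, -3.0]
    assert fs.exchange.tolist() == [3.0, 5.0]
    with pytest.raises(ValueError):
        FluxState(("a",), np.array([-1.0]), np.array([0.0]))


def test_ssr_zero_on_noiseless_data(emp_model):
    truth = emp_fluxes(emp_model, {"fba": 20, "tpi": 50})
    ds = noiseless_dataset(emp_model, truth, ["1-13C1"], ["3PG", "FBP"],
                           ["pyr_out"], rate_sd=1.0)
    assert compute_ssr(emp_model, truth, ds) == pytest.approx(0.0, abs=1e-18)


def test_single_two_sigma_residual_gives_ssr_four(emp_model):
    truth = emp_fluxes(emp_model)
    ds = noiseless_dataset(emp_model, truth, ["1-13C1"], ["3PG"],
                           ["pyr_out"], mid_sd=0.003, rate_sd=1.0)
    mid = ds.tracers["1-13C1"].mids["3PG"]
    mid.fractions = mid.fractions.copy()
    mid.fractions[1] += 2 * 0.003          # one residual of exactly 2 SDs
    assert compute_ssr(emp_model, truth, ds) == pytest.approx(4.0)


def test_missing_sd_is_an_error(emp_model):
    truth = emp_fluxes(emp_model)
    tracer = fx.glucose_tracer(emp_model, "1-13C1")
    emu = metabolite_emu(emp_model, "3PG")
    sim = simulate_mids(emp_model, truth, tracer, [emu])[emu]
    ds = Dataset({"t": TracerData(tracer,
                                  {"3PG": MIDVector("3PG", sim.fractions)})})
    with pytest.raises(FitError, match="SD"):
        compute_ssr(emp_model, truth, ds)


def test_mean_ssr_matches_residual_count(emp_model):
    """At the true fluxes, with independent Gaussian measurement errors,
    the weighted SSR is chi-square distributed: its mean equals the number
    of residuals."""
    truth = emp_fluxes(emp_model, {"pgi": 10, "fba": 40, "tpi": 150,
                                   "gly": 30, "eno": 20})
    rng = np.random.default_rng(7)
    ssrs, counts = [], []
    for _ in range(200):
        ds = noiseless_dataset(emp_model, truth,
                               ["1-13C1", "U-13C6/unlabeled"],
                               ["G6P", "FBP", "3PG", "PYR"], ["pyr_out"],
                               mid_sd=0.003, rate_sd=2.0)
        cnt = 0
        for td in ds.tracers.values():
            for mid in td.mids.values():
                mid.fractions = mid.fractions + rng.normal(
                    0, 0.003, mid.fractions.shape)
                cnt += int(np.count_nonzero(mid.fractions))
        ds.rates = {r: (v + rng.normal(0, s), s)
                    for r, (v, s) in ds.rates.items()}
        cnt += len(ds.rates)
        ssrs.append(compute_ssr(emp_model, truth, ds))
        counts.append(cnt)
    ratio = np.mean(ssrs) / np.mean(counts)
    assert 0.9 < ratio < 1.1


# ---------------------------------------------------------------------------
# chi-square acceptance

def test_chi2_band_and_verdict_at_large_dof():
    """An SSR of 499.2 against the band (422.1, 543.7) is accepted; the
    band is the central 95% chi-square range at 481 degrees of freedom."""
    lo, hi, ok = chi2_acceptance(499.2, 482, 1)
    assert lo == pytest.approx(422.1, abs=0.05)
    assert hi == pytest.approx(543.7, abs=0.05)
    assert ok
    assert chi2_acceptance(600.0, 482, 1)[2] is False


def test_single_dof_range():
    lo, hi, _ = chi2_acceptance(1.0, 2, 1)
    assert lo == pytest.approx(0.000982, rel=1e-3)
    assert hi == pytest.approx(5.0239, rel=1e-4)


def test_degenerate_dof_rejected():
    with pytest.raises(FitError):
        chi2_acceptance(1.0, 3, 3)


# ---------------------------------------------------------------------------
# fitting

def test_noiseless_fit_recovers_net_fluxes(tsac_core):
    """Self-consistency: fitting exact five-tracer data returns the
    generating net fluxes to 0.1% and an SSR indistinguishable from 0."""
    from fluxtherm.synth import CORE_MEASURED, CORE_RATES, reference_truth
    truth = reference_truth(tsac_core)
    ds = noiseless_dataset(tsac_core, truth, fx.FIVE_TRACER_PANEL,
                           list(CORE_MEASURED), list(CORE_RATES),
                           mid_sd=0.003, rate_sd=2.0)
    fit = fit_fluxes(tsac_core, ds, restarts=3, seed=11)
    assert fit.ssr < 1e-6
    # the carbon/energy backbone is identifiable; dilution and cofactor
    # exchange pools have flat directions at SSR = 0 and are excluded
    backbone = ["glk", "pgi", "pfk", "fba", "tpi", "gapdh", "pgk", "eno",
                "pyk", "pfor", "adh", "ack"]
    for rid in backbone:
        i = tsac_core.reaction_index(rid)
        assert fit.fluxes.net[i] == pytest.approx(truth.net[i], rel=1e-3)


def test_fit_deterministic_given_seed():
    model = fx.emp_ed_mixture()
    truth = make_fluxstate(model,
                           {"glk": 100, "pgi": 100, "pfk": 60, "fba": 60,
                            "tpi": 60, "ed": 40, "gly": 160, "eno": 160,
                            "pyk": 160, "pyr_out": 200},
                           {"tpi": 100})
    ds = noiseless_dataset(model, truth, ["1-13C1"], ["3PG", "FBP"],
                           ["pyr_out"], rate_sd=2.0)
    fit1 = fit_fluxes(model, ds, restarts=2, seed=5)
    fit2 = fit_fluxes(model, ds, restarts=2, seed=5)
    assert np.array_equal(fit1.theta, fit2.theta)
    assert fit1.ssr == fit2.ssr
    assert fit1.restart_ssrs == fit2.restart_ssrs


def test_more_restarts_never_worse():
    """The best of a restart superset is at least as good (same seed, so
    the first start coincides)."""
    model = fx.emp_ed_mixture()
    truth = make_fluxstate(model,
                           {"glk": 100, "pgi": 100, "pfk": 60, "fba": 60,
                            "tpi": 60, "ed": 40, "gly": 160, "eno": 160,
                            "pyk": 160, "pyr_out": 200},
                           {"tpi": 100, "fba": 20})
    ds = noiseless_dataset(model, truth, ["1-13C1"], ["3PG"],
                           ["pyr_out"], rate_sd=2.0)
    ssr1 = fit_fluxes(model, ds, restarts=1, seed=2).ssr
    ssr4 = fit_fluxes(model, ds, restarts=4, seed=2).ssr
    assert ssr4 <= ssr1 + 1e-12


def test_descent_from_perturbed_truth(tsac_core):
    """The optimizer strictly improves the SSR from a perturbed start —
    the weighted least-squares objective is locally well-behaved."""
    from fluxtherm.fluxfit import FluxParameterization, _objective
    from fluxtherm.synth import CORE_MEASURED, CORE_RATES, reference_truth
    truth = reference_truth(tsac_core)
    ds = noiseless_dataset(tsac_core, truth, ["1-13C1"],
                           list(CORE_MEASURED), list(CORE_RATES),
                           rate_sd=2.0)
    par = FluxParameterization(tsac_core)
    fun = _objective(par, ds, 0.0)
    theta0 = par.project_fluxes(truth)
    rng = np.random.default_rng(0)
    theta = theta0 + rng.normal(0, 0.02, theta0.shape)
    theta = np.clip(theta, *par.theta_bounds())
    from scipy.optimize import least_squares
    sol = least_squares(fun, theta, bounds=par.theta_bounds(),
                        max_nfev=200)
    assert 2 * sol.cost < np.sum(fun(theta) ** 2)


# ---------------------------------------------------------------------------
# confidence intervals

def test_quadratic_profile_closed_form():
    """Two direct rate measurements of one flux make the SSR exactly
    quadratic: the continuation bound sits at sqrt(3.8415/curvature)."""
    ds = Dataset({}, {"inflow": (50.0, 2.0), "outflow": (50.0, 2.0)})
    fit = fit_fluxes(RATE_TOY, ds, restarts=2, seed=0)
    iv = confidence_intervals(RATE_TOY, ds, fit,
                              which=[("inflow", "net")])[("inflow", "net")]
    half = 1.96 * 2.0 / np.sqrt(2.0)       # = sqrt(3.8415 * sd^2 / 2)
    assert iv.lb == pytest.approx(50.0 - half, abs=0.1)
    assert iv.ub == pytest.approx(50.0 + half, abs=0.1)


def test_unidentifiable_branch_spans_bounds():
    """A branch flux that reaches no measured fragment is unconstrained:
    its confidence interval is the full bound range."""
    toy = parse_model(
        "@met A 2 0 0 0\n@met B 2 0 0 1\n@met C 2 0 0 1\n@met D 2 0 0 1\n"
        "upt\tA (ab)\tB (ab)\t0\t100\t100\ttransport\n"
        "bc\tB (ab)\tC (ab)\t0\t0\t1000\tinternal\n"
        "bd\tB (ab)\tD (ab)\t0\t0\t50\tinternal\n"
        "outc\tC (ab)\t-\t0\t0\t1000\ttransport\n"
        "outd\tD (ab)\t-\t0\t0\t1000\ttransport", name="branch-toy")
    fs0 = make_fluxstate(toy, {"upt": 100, "bc": 70, "bd": 30,
                               "outc": 70, "outd": 30})
    tracers = {"a": TracerSpec("A", (((0,), 1.0),)),
               "b": TracerSpec("A", (((0, 1), 0.5), ((), 0.5)))}
    tds = {}
    for tid, tr in tracers.items():
        emu = metabolite_emu(toy, "C")
        sim = simulate_mids(toy, fs0, tr, [emu])[emu]
        tds[tid] = TracerData(tr, {"C": MIDVector(
            "C", sim.fractions, sd=np.full(3, 0.003))})
    fit = fit_fluxes(toy, Dataset(tds, {}), restarts=2, seed=0)
    iv = confidence_intervals(toy, Dataset(tds, {}), fit,
                              which=[("bd", "net")])[("bd", "net")]
    assert iv.lb == 0.0 and iv.ub == 50.0
    assert iv.at_lower_bound and iv.at_upper_bound
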