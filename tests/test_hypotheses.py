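"""Route-discrimination predictions and scoring."""

import numpy as np
import pytest

from conftest import make_fluxstate
from fluxtherm import fixtures as fx
from fluxtherm.emu import EMUNode, MIDVector
from fluxtherm.hypotheses import (PathwayHypothesis, emp_ed_hypothesis,
                                  emp_route_3pg, ed_route_3pg,
                                  estimate_route_weight, ftkt_pentose,
                                  isoleucine_citramalate_route,
                                  isoleucine_threonine_route,
                                  leucine_from_c2_units,
                                  phosphoketolase_xu5p,
                                  predict_hypothesis_mids, score_hypotheses,
                                  simulate_route)


def test_equal_emp_ed_mixture_quarter_and_three_quarter_rule():
    """Equal pool contributions give 25% M+1 lower-glycolytic label on
    [1-13C1] glucose and 75% on [6-13C1] glucose."""
    h1 = emp_ed_hypothesis(0.5, "1-13C1")
    assert predict_hypothesis_mids(h1)["3PG"].fractions[1] == pytest.approx(0.25)
    h6 = emp_ed_hypothesis(0.5, "6-13C1")
    assert predict_hypothesis_mids(h6)["3PG"].fractions[1] == pytest.approx(0.75)


def test_pure_route_weights_reproduce_route_predictions():
    for w, route in [(0.0, emp_route_3pg("1-13C1")),
                     (1.0, ed_route_3pg("1-13C1"))]:
        pred = predict_hypothesis_mids(emp_ed_hypothesis(w, "1-13C1"))
        assert np.allclose(pred["3PG"].fractions, route.mids["3PG"].fractions)


def test_predictions_are_valid_mids():
    for h in [emp_ed_hypothesis(0.3, "6-13C1")]:
        for mid in predict_hypothesis_mids(h).values():
            assert mid.fractions.sum() == pytest.approx(1.0)
            assert (mid.fractions >= 0).all()


def test_invalid_weights_rejected():
    r = emp_route_3pg("1-13C1")
    with pytest.raises(ValueError, match="sum"):
        PathwayHypothesis("bad", ((0.6, r), (0.6, r)))


def test_pyruvate_carbon_order_discriminates_routes():
    """[1,2-13C2] glucose labels pyruvate C2+C3 via hexose-bisphosphate
    cleavage but C1+C2 via the KDPG route — opposite carbon order, same
    mass shift, distinguished positionally."""
    from fluxtherm.emu import simulate_mids

    def positional(model, net):
        fs = make_fluxstate(model, net)
        tracer = fx.glucose_tracer(model, "1,2-13C2")
        emus = [EMUNode("PYR", (0,)), EMUNode("PYR", (2,))]
        mids = simulate_mids(model, fs, tracer, emus)
        return mids[emus[0]].fractions[1], mids[emus[1]].fractions[1]

    ed = fx.ed_only()
    c1_ed, c3_ed = positional(ed, {"glk": 100, "ed": 100, "gly": 100,
                                   "eno": 100, "pyk": 100, "pyr_out": 200})
    # ED: half the pyruvate pool is C1-C3 of glucose -> C1 labeled, C3 not
    assert c1_ed == pytest.approx(0.5, abs=1e-9)
    assert c3_ed == pytest.approx(0.0, abs=1e-9)

    emp = fx.emp_only()
    c1_emp, c3_emp = positional(
        emp, {"glk": 100, "pgi": 100, "pfk": 100, "fba": 100, "tpi": 100,
              "gly": 200, "eno": 200, "pyk": 200, "pyr_out": 200})
    # EMP: glucose C1/C2 end at pyruvate C3/C2 — the reverse order
    assert c1_emp == pytest.approx(0.0, abs=1e-9)
    assert c3_emp == pytest.approx(0.5, abs=1e-9)


def test_threonine_route_isoleucine_m3_independent_of_co2():
    for f in (0.0, 0.3, 1.0):
        mids = isoleucine_threonine_route(co2_labeled_fraction=f).mids
        assert mids["Ile"].fractions[3] == pytest.approx(0.25)


def test_citramalate_route_produces_no_m3():
    assert isoleucine_citramalate_route().mids["Ile"].fractions[3] == 0.0


def test_observed_low_m3_bounds_threonine_contribution():
    """1.5% observed M+3 against a 25% threonine-route prediction bounds
    that route at 6% of isoleucine synthesis."""
    obs = {"Ile": MIDVector("Ile", [0.3, 0.0, 0.35, 0.015, 0.235, 0.0, 0.1])}
    w = estimate_route_weight(obs, isoleucine_threonine_route(),
                              isoleucine_citramalate_route(),
                              mass_shifts={"Ile": [3]})
    assert w == pytest.approx(0.06, abs=1e-9)


def test_exact_match_ranks_first_with_zero_sse():
    h25 = emp_ed_hypothesis(0.5, "1-13C1")
    obs = predict_hypothesis_mids(h25)
    ranked = score_hypotheses(obs, [emp_ed_hypothesis(w, "1-13C1")
                                    for w in (0.0, 0.25, 0.5, 0.75, 1.0)])
    assert ranked[0][0] == h25.name
    assert ranked[0][1] == pytest.approx(0.0, abs=1e-15)


def test_linear_unmixing_recovers_half_weight():
    a, b = emp_route_3pg("6-13C1"), ed_route_3pg("6-13C1")
    obs = {"3PG": MIDVector("3PG",
                            0.5 * a.mids["3PG"].fractions
                            + 0.5 * b.mids["3PG"].fractions)}
    assert estimate_route_weight(obs, a, b) == pytest.approx(0.5, abs=1e-6)


def test_phosphoketolase_and_leucine_registry_patterns():
    xu5p = phosphoketolase_xu5p().mids["Xu5P"].fractions
    assert np.allclose(xu5p[:3], [0.25, 0.5, 0.25])
    leu = leucine_from_c2_units().mids["Leu"].fractions
    assert np.allclose(leu[[0, 2, 4, 6]], [0.125, 0.375, 0.375, 0.125])


def test_ftkt_prediction_fills_odd_masses():
    """The formaldehyde-transketolase route populates M+1/M+3, unlike the
    canonical non-oxidative pentose route (reconstructed prediction)."""
    xu5p = ftkt_pentose().mids["Xu5P"].fractions
    assert xu5p[1] > 0.05 and xu5p[3] > 0.05 and xu5p[2] == max(xu5p)


def test_simulated_route_prediction_matches_analytic_rule(emp_model):
    from conftest import emp_fluxes
    route = simulate_route(
        "EMP", emp_model, emp_fluxes(emp_model),
        fx.glucose_tracer(emp_model, "1-13C1"),
        {"3PG": EMUNode("3PG", (0, 1, 2))})
    assert np.allclose(route.mids["3PG"].fractions,
                       emp_route_3pg("1-13C1").mids["3PG"].fractions,
                       atol=1e-9)


def test_registry_file_round_trip():
    """The shipped hypothesis registry serializes to the data dialect and
    parses back with identical predictions."""
    from fluxtherm.hypotheses import (parse_hypotheses, standard_registry,
                                      write_hypotheses)
    reg = standard_registry()
    text = write_hypotheses(reg)
    back = parse_hypotheses(text)
    assert [h.name for h in back] == [h.name for h in reg]
    for h0, h1 in zip(reg, back):
        p0, p1 = predict_hypothesis_mids(h0), predict_hypothesis_mids(h1)
        for f in p0:
            assert np.allclose(p0[f].fractions, p1[f].fractions, atol=1e-9)
    # the registry reproduces the analytic claims
    by_name = {(h.name, h.tracer): h for h in back}
    m1 = predict_hypothesis_mids(by_name[("EMP0.5-ED0.5", "1-13C1")])
    assert m1["3PG"].fractions[1] == pytest.approx(0.25)
    pkt = predict_hypothesis_mids(by_name[("pentose-phosphoketolase",
                                           "6-13C1")])
    assert np.allclose(pkt["Xu5P"].fractions[:3], [0.25, 0.5, 0.25])


def test_score_requires_overlapping_fragments():
    with pytest.raises(ValueError, match="overlap"):
        score_hypotheses({"PEP": MIDVector("PEP", [1.0])},
                         [emp_ed_hypothesis(0.5, "1-13C1")])
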