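"""EMU decomposition, steady-state MID simulation, convolution."""

import numpy as np
import pytest

from conftest import emp_fluxes, make_fluxstate
from fluxtherm import fixtures as fx
from fluxtherm.emu import (EMUNode, MIDVector, SimulationError, TracerSpec,
                           convolve_mids, decompose_emus, metabolite_emu,
                           simulate_mids)
from fluxtherm.network import parse_model

LINEAR = parse_model(
    "@met A 2 0 0 0\n@met B 2 0 0 1\n@met C 2 0 0 1\n"
    "v1\tA (ab)\tB (ab)\t0\t0\t100\tinternal\n"
    "v2\tB (ab)\tC (ab)\t0\t0\t100\tinternal\n"
    "out\tC (ab)\t-\t0\t0\t100\ttransport", name="linear")

CONDENSE = parse_model(
    "@met A 2 0 0 0\n@met X 1 0 0 0\n@met C 3 0 0 1\n"
    "v\tA (ab) + X (c)\tC (abc)\t0\t0\t100\tinternal\n"
    "out\tC (abc)\t-\t0\t0\t100\ttransport", name="condense")


def test_linear_chain_decomposition():
    cascade = decompose_emus(LINEAR, [EMUNode("C", (0, 1))])
    assert cascade.n_emus == 3
    assert all(e.size == 2 for e in list(cascade.terms) + list(cascade.inputs))
    assert all(len(t.sources) == 1
               for ts in cascade.terms.values() for t in ts)


def test_linear_chain_size1_target():
    cascade = decompose_emus(LINEAR, [EMUNode("C", (0,))])
    assert cascade.n_emus == 3
    assert all(e.size == 1 for e in list(cascade.terms) + list(cascade.inputs))


def test_condensation_decomposition():
    cascade = decompose_emus(CONDENSE, [EMUNode("C", (0, 1, 2))])
    sizes = sorted(e.size for e in list(cascade.terms) + list(cascade.inputs))
    assert sizes == [1, 2, 3]
    (term,) = cascade.terms[EMUNode("C", (0, 1, 2))]
    assert len(term.sources) == 2          # convolution edge


def test_out_of_range_target_raises():
    with pytest.raises(SimulationError, match="out of range"):
        decompose_emus(LINEAR, [EMUNode("C", (0, 5))])


def test_label_passthrough_linear_chain():
    fs = make_fluxstate(LINEAR, {"v1": 100, "v2": 100, "out": 100})
    tracer = TracerSpec("A", (((0,), 1.0),))
    emu = EMUNode("C", (0,))
    mid = simulate_mids(LINEAR, fs, tracer, [emu])[emu]
    assert np.allclose(mid.fractions, [0.0, 1.0], atol=1e-12)


def test_disconnected_emu_raises():
    fs = make_fluxstate(LINEAR, {"v1": 100, "v2": 0, "out": 0})
    tracer = TracerSpec("A", (((0,), 1.0),))
    with pytest.raises(SimulationError, match="no inflow"):
        simulate_mids(LINEAR, fs, tracer, [metabolite_emu(LINEAR, "C")])


def test_emp_3pg_half_labeled(emp_model):
    """Single-position glucose labels reach half the triose pool via the
    hexose-bisphosphate route."""
    fs = emp_fluxes(emp_model)
    for tracer in ("1-13C1", "6-13C1"):
        emu = metabolite_emu(emp_model, "3PG")
        mid = simulate_mids(emp_model, fs,
                            fx.glucose_tracer(emp_model, tracer), [emu])[emu]
        assert np.allclose(mid.fractions[:2], [0.5, 0.5], atol=1e-9)


def test_ed_3pg_unlabeled_with_c1_tracer():
    model = fx.ed_only()
    fs = make_fluxstate(model, {"glk": 100, "ed": 100, "gly": 100,
                                "eno": 100, "pyk": 100, "pyr_out": 200})
    emu = metabolite_emu(model, "3PG")
    mid = simulate_mids(model, fs, fx.glucose_tracer(model, "1-13C1"),
                        [emu])[emu]
    assert mid.fractions[0] == pytest.approx(1.0, abs=1e-9)


def test_fbp_full_exchange_limit():
    """With aldolase exchange far above net flux, hexose-bisphosphate
    reassembles from two independent triose pools: 25:50:25 of M+0/M+3/M+6
    on equimolar fully-labeled/unlabeled glucose."""
    model = fx.fba_tpi_toy()
    fs = make_fluxstate(model, {"upt": 100, "fba": 100, "tpi": 100,
                                "gap_out": 200},
                        {"fba": 1e7, "tpi": 1e7})
    emu = metabolite_emu(model, "FBP")
    mid = simulate_mids(model, fs,
                        fx.glucose_tracer(model, "U-13C6/unlabeled"),
                        [emu])[emu]
    expect = np.zeros(7)
    expect[[0, 3, 6]] = [0.25, 0.5, 0.25]
    assert np.allclose(mid.fractions, expect, atol=1e-4)


def test_m3_fbp_monotone_in_exchange():
    """The M+3 fraction of FBP grows with aldolase exchange, saturating at
    50% — the reverse-flux readout of upper-glycolysis reversibility."""
    model = fx.fba_tpi_toy()
    tracer = fx.glucose_tracer(model, "U-13C6/unlabeled")
    emu = metabolite_emu(model, "FBP")
    last = -1.0
    for exch in [0.0, 1.0, 10.0, 100.0, 1e4, 1e7]:
        fs = make_fluxstate(model, {"upt": 100, "fba": 100, "tpi": 100,
                                    "gap_out": 200},
                            {"fba": exch, "tpi": 1e6})
        m3 = simulate_mids(model, fs, tracer, [emu])[emu].fractions[3]
        assert m3 >= last - 1e-12
        last = m3
    assert last == pytest.approx(0.5, abs=1e-3)


def test_uniform_tracer_fully_labels_network(emp_model):
    fs = emp_fluxes(emp_model, {"pgi": 5, "fba": 7, "tpi": 13, "gly": 3,
                                "eno": 2})
    tracer = fx.glucose_tracer(emp_model, "U-13C6")
    for met in ["G6P", "FBP", "GAP", "PYR"]:
        emu = metabolite_emu(emp_model, met)
        mid = simulate_mids(emp_model, fs, tracer, [emu])[emu]
        assert mid.fractions[-1] == pytest.approx(1.0, abs=1e-9)


def test_mids_normalized_across_targets(tsac_core):
    from fluxtherm.synth import reference_truth
    fs = reference_truth(tsac_core)
    for name in fx.FIVE_TRACER_PANEL:
        tracer = fx.glucose_tracer(tsac_core, name)
        targets = [metabolite_emu(tsac_core, m)
                   for m in ("G6P", "FBP", "DHAP", "3PG", "PYR")]
        mids = simulate_mids(tsac_core, fs, tracer, targets)
        for emu, mid in mids.items():
            assert mid.fractions.sum() == pytest.approx(1.0, abs=1e-9)
            assert (mid.fractions >= 0).all()


def test_symmetric_metabolite_invariant_under_map_reversal():
    """Succinate-like symmetric pools give identical MIDs whichever atom
    orientation the producing reaction writes."""
    base = ("@met A 4 0 0 0\n@met S 4 0 1 1\n"
            "in\tA (abcd)\tS ({})\t0\t0\t100\tinternal\n"
            "out\tS (abcd)\t-\t0\t0\t100\ttransport")
    tracer = TracerSpec("A", (((0,), 1.0),))
    mids = []
    for orient in ("abcd", "dcba"):
        m = parse_model(base.format(orient), name=orient)
        fs = make_fluxstate(m, {"in": 100, "out": 100})
        emu = EMUNode("S", (0, 1))
        mids.append(simulate_mids(m, fs, tracer, [emu])[emu].fractions)
    assert np.allclose(mids[0], mids[1], atol=1e-12)


def test_inactive_route_variant_still_simulates():
    """A model variant carrying a dead alternative route (zero flux
    through the ED branch) simulates its active backbone unperturbed —
    the fate of every route-comparison fit near a zero branch flux."""
    model = fx.emp_ed_mixture()
    fs = make_fluxstate(model, {"glk": 100, "pgi": 100, "pfk": 100,
                                "fba": 100, "tpi": 100, "ed": 0,
                                "gly": 200, "eno": 200, "pyk": 200,
                                "pyr_out": 200})
    emu = metabolite_emu(model, "3PG")
    mid = simulate_mids(model, fs, fx.glucose_tracer(model, "1-13C1"),
                        [emu])[emu]
    assert np.allclose(mid.fractions[:2], [0.5, 0.5], atol=1e-9)


# ---------------------------------------------------------------------------
# convolution

def test_convolve_identity():
    delta = MIDVector("d", [1.0, 0.0])
    x = MIDVector("x", [0.2, 0.5, 0.3])
    out = convolve_mids(delta, x)
    assert np.allclose(out.fractions[:3], x.fractions)
    assert out.fractions.sum() == pytest.approx(1.0)


def test_triple_two_carbon_convolution():
    """Three independent C2 units, each half doubly-labeled: the leucine
    pattern 12.5/37.5/37.5/12.5 over M+0/M+2/M+4/M+6."""
    c2 = MIDVector("c2", [0.5, 0.0, 0.5])
    leu = convolve_mids(convolve_mids(c2, c2), c2)
    assert np.allclose(leu.fractions,
                       [0.125, 0, 0.375, 0, 0.375, 0, 0.125])


def test_phosphoketolase_condensation():
    """GAP and acetyl-phosphate units each 50% M+0/50% M+1 give a
    25/50/25 pentose."""
    out = convolve_mids(MIDVector("a", [0.5, 0.5]),
                        MIDVector("b", [0.5, 0.5]))
    assert np.allclose(out.fractions, [0.25, 0.5, 0.25])
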