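import numpy as np
import pytest

from fluxtherm import fixtures as fx
from fluxtherm.emu import metabolite_emu, simulate_mids
from fluxtherm.fluxfit import Dataset, FluxState, TracerData
from fluxtherm.emu import MIDVector


def make_fluxstate(model, net: dict, exch: dict | None = None) -> FluxState:
    """FluxState from sparse net/exchange dicts (absent reactions -> 0)."""
    exch = exch or {}
    netv = np.array([net.get(r.id, 0.0) for r in model.reactions])
    exchv = np.array([exch.get(r.id, 0.0) if r.reversible else 0.0
                      for r in model.reactions])
    return FluxState.from_net_exchange(model, netv, exchv)


def emp_fluxes(model, exch=None):
    """Reference steady state of the carbon-only EMP fixture."""
    net = {"glk": 100, "pgi": 100, "pfk": 100, "fba": 100, "tpi": 100,
           "gly": 200, "eno": 200, "pyk": 200, "pyr_out": 200}
    return make_fluxstate(model, net, exch)


def noiseless_dataset(model, truth, tracer_names, measured, rates,
                      mid_sd=0.003, rate_sd=2.0) -> Dataset:
    """Exact simulated MIDs with SD columns attached (no noise applied)."""
    tracers = {}
    for name in tracer_names:
        spec = fx.glucose_tracer(model, name)
        targets = [metabolite_emu(model, m) for m in measured]
        sim = simulate_mids(model, truth, spec, targets)
        mids = {m: MIDVector(m, sim[metabolite_emu(model, m)].fractions,
                             sd=np.full(len(sim[metabolite_emu(model, m)].fractions),
                                        mid_sd))
                for m in measured}
        tracers[name] = TracerData(spec, mids)
    net = truth.net
    ridx = {r.id: i for i, r in enumerate(model.reactions)}
    return Dataset(tracers, {r: (float(net[ridx[r]]), rate_sd) for r in rates})


@pytest.fixture(scope="session")
def emp_model():
    return fx.emp_only()


@pytest.fixture(scope="session")
def tsac_core():
    return fx.glycolysis_core("tsac")


@pytest.fixture(scope="session")
def cthe_core():
    return fx.glycolysis_core("cthe", malic_enzyme=True)
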