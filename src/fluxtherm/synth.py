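"""Synthetic ground truths and noisy multi-tracer datasets.

Every downstream stage (simulation, fitting, thermodynamics) is exercised
against data generated here: a ground-truth flux state satisfying steady
state, simulated MIDs for a tracer panel with sum-preserving Gaussian
measurement noise (a composition must sum to 1, so per-bin errors are
zero-sum projected and rescaled to the declared marginal SD), perturbed
extracellular rates, and concentration tables constructed to hit
prescribed reaction free energies.  Defaults: absolute MID-fraction SD
0.003 (resembling replicate scatter of well-measured LC-MS fractions),
5% relative SD on rates, exchange fluxes log-uniform in [0.1, 1000] mol
per 100 mol glucose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .emu import EMUNode, MIDVector, TracerSpec, metabolite_emu, simulate_mids
from .fluxfit import Dataset, FluxState, TracerData
from .network import NetworkModel, build_stoichiometry, parse_model
from .thermo import ConcentrationSet, ThermoContext


@dataclass(frozen=True)
class NoiseModel:
    mid_sd: float = 0.003          # absolute SD per MID fraction
    rate_rel_sd: float = 0.05      # relative SD on extracellular rates
    detection_floor: float = 1e-3  # true fractions below this report as 0
    seed: int | None = None

    def __post_init__(self):
        if self.mid_sd <= 0 or self.rate_rel_sd <= 0:
            raise ValueError("noise SDs must be positive")


class SynthError(RuntimeError):
    pass


def sample_flux_state(model: NetworkModel,
                      constraints: dict[str, float] | None = None,
                      seed: int | None = None,
                      exch_range: tuple[float, float] = (0.1, 1000.0),
                      n_vertices: int = 4) -> FluxState:
    """Random feasible flux state.

    Net fluxes are a random convex combination of random-objective vertices
    of {S v = 0, lb <= v <= ub, constraints}; exchange fluxes of reversible
    reactions are drawn log-uniform from ``exch_range``.  Deterministic per
    seed; a fully determined network returns the same net fluxes for every
    seed.
    """
    constraints = constraints or {}
    rng = np.random.default_rng(seed)
    S, _ = build_stoichiometry(model)
    n = len(model.reactions)
    lb = np.array([r.lb for r in model.reactions])
    ub = np.array([r.ub for r in model.reactions])
    for rid, val in constraints.items():
        j = model.reaction_index(rid)
        lb[j] = ub[j] = val
    verts = []
    for _ in range(n_vertices):
        c = rng.normal(size=n)
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=list(zip(lb, ub)), method="highs")
        if not res.success:
            raise SynthError(f"infeasible constraints for model {model.name}")
        verts.append(res.x)
    w = rng.dirichlet(np.ones(len(verts)))
    net = np.asarray(verts).T @ w
    lo, hi = exch_range
    exch = np.zeros(n)
    for j, r in enumerate(model.reactions):
        if r.reversible:
            exch[j] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    return FluxState.from_net_exchange(model, net, exch)


def generate_tracer_dataset(model: NetworkModel, truth: FluxState,
                            tracers: dict[str, TracerSpec],
                            noise: NoiseModel,
                            measured: list[str],
                            rate_reactions: list[str] = (),
                            p13: float = 0.0) -> Dataset:
    """Noisy steady-state dataset from a ground-truth flux state.

    Detectable fractions (those above ``noise.detection_floor``) get
    Gaussian noise with marginal SD ``noise.mid_sd``, drawn sum-preserving
    (projected onto the zero-sum subspace and rescaled) so the reported
    vector remains a composition with exactly the per-bin scatter the SD
    column declares — the statistical structure the variance-weighted fit
    assumes.  Fractions below the floor are reported as exact zeros, the
    way undetected isotopomers appear in measured MID tables (and what
    makes the fitted-measurement rule "all non-zero MIDs" meaningful).
    A metabolite with fewer than two detectable bins under a tracer is a
    deterministic composition (identically 100% one mass) and is omitted
    for that tracer: it carries no residual.  Any negative value left by
    the noise is clipped at 0 and the vector renormalized.  Rates are the
    truth's net fluxes perturbed by relative Gaussian noise.
    """
    rng = np.random.default_rng(noise.seed)
    tracer_data: dict[str, TracerData] = {}
    for name, spec in tracers.items():
        targets = [metabolite_emu(model, m) for m in measured]
        sim = simulate_mids(model, truth, spec, targets, p13=p13)
        mids = {}
        for m in measured:
            frac = sim[metabolite_emu(model, m)].fractions.copy()
            detected = frac >= noise.detection_floor
            k = int(detected.sum())
            if k < 2:
                continue
            z = rng.normal(0.0, 1.0, size=k)
            z = (z - z.mean()) * np.sqrt(k / (k - 1.0))
            frac[detected] += noise.mid_sd * z
            frac[~detected] = 0.0
            frac = np.clip(frac, 0.0, None)
            frac = frac / frac.sum()
            mids[m] = MIDVector(m, frac, sd=np.full(frac.shape, noise.mid_sd))
        tracer_data[name] = TracerData(spec, mids)
    rates = {}
    net = truth.net
    for rid in rate_reactions:
        j = model.reaction_index(rid)
        val = net[j]
        sd = abs(val) * noise.rate_rel_sd
        rates[rid] = (val + rng.normal(0.0, sd), sd)
    return Dataset(tracer_data, rates)


def generate_concentration_table(model: NetworkModel, ctx: ThermoContext,
                                 target_dgs: dict[str, float],
                                 seed: int | None = None,
                                 rel_sd: float = 0.05,
                                 skip=("WATER", "H2O", "H"),
                                 ) -> ConcentrationSet:
    """Concentrations (mM) hitting prescribed reaction free energies.

    Starts from log-normal concentrations around 1 mM and applies the
    minimum-norm log-space adjustment so every target reaction satisfies
    dG0' + RT ln Q = target dG within 1e-6.  Raises if the targets are
    mutually inconsistent.
    """
    rng = np.random.default_rng(seed)
    mets = sorted({p.met
                   for rid in target_dgs
                   for p in (model.reaction(rid).reactants
                             + model.reaction(rid).products)
                   if p.met not in skip})
    idx = {m: i for i, m in enumerate(mets)}
    A = np.zeros((len(target_dgs), len(mets)))
    b = np.zeros(len(target_dgs))
    rt = ctx.rt_kj
    for k, (rid, dg) in enumerate(sorted(target_dgs.items())):
        if rid not in ctx.dg0:
            raise SynthError(f"no standard free energy for reaction {rid}")
        rxn = model.reaction(rid)
        for p in rxn.products:
            if p.met not in skip:
                A[k, idx[p.met]] += 1
        for p in rxn.reactants:
            if p.met not in skip:
                A[k, idx[p.met]] -= 1
        b[k] = (dg - ctx.dg0[rid]) / rt            # = ln Q required
    x0 = rng.normal(0.0, 0.5, size=len(mets))      # log-normal around 1 mM
    # minimum-norm correction onto the constraint manifold
    resid = b - A @ x0
    corr, *_ = np.linalg.lstsq(A, resid, rcond=None)
    x = x0 + corr
    if np.max(np.abs(A @ x - b)) > 1e-9:
        raise SynthError("inconsistent simultaneous free-energy targets")
    conc = {m: (float(np.exp(x[idx[m]])),
                float(np.exp(x[idx[m]])) * rel_sd) for m in mets}
    return ConcentrationSet(conc)


# ---------------------------------------------------------------------------
# reference study conditions for the glycolysis cores

#: measured metabolite panel for the core fixtures
CORE_MEASURED = ("G6P", "F6P", "FBP", "DHAP", "3PG", "PEP", "PYR")
CORE_RATES = ("glk", "adh", "ack")


def reference_truth(model: NetworkModel) -> FluxState:
    """Ground-truth flux state for a glycolysis-core fixture.

    The two presets contrast a thermodynamically favorable (ATP-Pfk style,
    near-zero Pfk exchange) pathway with a near-equilibrium (PPi-Pfk style)
    one whose Pfk forward/backward ratio is ~1.7; glucose uptake is
    normalized to 100.
    """
    variant = model.variant
    if variant.startswith("tsac"):
        net = {"glk": 100, "pgi": 100, "pfk": 100, "fba": 100, "tpi": -100,
               "gapdh": 200, "pgk": 200, "eno": 200, "pyk": 200,
               "pyr_dil": 5, "pfor": 205, "adh": 170, "ack": 35,
               "co2_dil": 10, "co2_out": 215, "nadh_in": 140, "nadh_ox": 0}
        exch = {"pgi": 30, "pfk": 0.05, "fba": 60, "tpi": 600, "gapdh": 50,
                "pgk": 100, "eno": 60, "pfor": 17, "co2_dil": 5}
    elif variant.startswith("cthe"):
        has_me = variant.endswith("+me")
        net = {"glk": 100, "pgi": 100, "pfk": 100, "fba": 100, "tpi": -100,
               "gapdh": 200, "pgk": 200, "eno": 200, "pyr_dil": 5,
               "pfor": 205, "adh": 170, "ack": 35,
               "co2_dil": 10, "co2_out": 215, "nadh_in": 140, "nadh_ox": 0}
        if has_me:
            net.update({"ppdk": 170, "pepck": 30, "mdh": 30, "me": 30})
        else:
            net.update({"ppdk": 190, "pepck": 10, "mdh": 10, "mal_sink": 10,
                        "pfor": 195, "adh": 160, "co2_out": 195,
                        "nadh_in": 120})
        # pfk J+/J- = 1.701 -> exchange = 100 / (1.701 - 1)
        exch = {"pgi": 60, "pfk": 100.0 / 0.701, "fba": 120, "tpi": 800,
                "gapdh": 120, "pgk": 150, "eno": 100, "ppdk": 30,
                "pepck": 10, "mdh": 20, "me": 10, "pfor": 40, "co2_dil": 10}
    else:
        raise SynthError(f"no reference truth for variant {variant!r}")
    netv = np.array([net.get(r.id, 0.0) for r in model.reactions])
    exchv = np.array([exch.get(r.id, 0.0) if r.reversible else 0.0
                      for r in model.reactions])
    S, _ = build_stoichiometry(model)
    assert np.abs(S @ netv).max() < 1e-9, "reference truth violates S v = 0"
    return FluxState.from_net_exchange(model, netv, exchv)


def core_dataset(model: NetworkModel, seed: int | None = None,
                 noise: NoiseModel | None = None,
                 truth: FluxState | None = None,
                 tracer_names=None, purity: float = 1.0,
                 p13: float = 0.0) -> Dataset:
    """Five-tracer noisy dataset under the reference study conditions."""
    from .fixtures import FIVE_TRACER_PANEL, glucose_tracer
    if truth is None:
        truth = reference_truth(model)
    if noise is None:
        noise = NoiseModel(seed=seed)
    elif noise.seed is None and seed is not None:
        noise = NoiseModel(noise.mid_sd, noise.rate_rel_sd, seed)
    names = tracer_names or FIVE_TRACER_PANEL
    tracers = {n: glucose_tracer(model, n, purity=purity) for n in names}
    return generate_tracer_dataset(model, truth, tracers, noise,
                                   list(CORE_MEASURED), list(CORE_RATES),
                                   p13=p13)


# ---------------------------------------------------------------------------
# randomized small networks for oracle cross-checks

def random_toy_model(seed: int) -> tuple[NetworkModel, FluxState, TracerSpec]:
    """Random <=16-atom network with feasible fluxes and a random tracer.

    Topology: substrate -> A <-> B, cleavage B -> C + D, condensation
    C + D <-> E, optional recycle E <-> A; atom maps are random
    permutations, one metabolite may be symmetric.  Exchange fluxes are
    kept moderate so the brute-force isotopomer iteration converges
    quickly.
    """
    rng = np.random.default_rng(seed)

    def perm(letters: str) -> str:
        arr = list(letters)
        rng.shuffle(arr)
        return "".join(arr)

    b_sym = int(rng.random() < 0.3)
    recycle = rng.random() < 0.5
    lines = [
        f"@met SRC 3 0 0 0",
        f"@met A 3 0 0 1",
        f"@met B 3 0 {b_sym} 1",
        f"@met C 2 0 0 1",
        f"@met D 1 0 0 1",
        f"@met E 3 0 0 1",
    ]
    split = perm("abc")
    cond = perm("abc")
    lines += [
        _line("upt", "SRC (abc)", f"A ({perm('abc')})", 0, 100, 100,
              "transport"),
        _line("iso", f"A (abc)", f"B ({perm('abc')})", 1, -1000, 1000,
              "internal"),
        _line("split", "B (abc)", f"C ({split[:2]}) + D ({split[2]})", 1,
              -1000, 1000, "internal"),
        _line("cond", "C (ab) + D (c)", f"E ({cond})", 1, -1000, 1000,
              "internal"),
        _line("out", "E (abc)", "-", 0, 0, 1000, "transport"),
    ]
    if recycle:
        lines.append(_line("rec", "E (abc)", f"A ({perm('abc')})", 1,
                           -1000, 1000, "internal"))
    model = parse_model("\n".join(lines), name=f"toy-{seed}")
    r = float(rng.uniform(0.0, 30.0)) if recycle else 0.0
    net = {"upt": 100.0, "iso": 100.0 + r, "split": 100.0 + r,
           "cond": 100.0 + r, "out": 100.0, "rec": r}
    netv = np.array([net.get(x.id, 0.0) for x in model.reactions])
    exch = np.array([
        math.exp(rng.uniform(math.log(0.1), math.log(20.0)))
        if x.reversible else 0.0 for x in model.reactions])
    fluxes = FluxState.from_net_exchange(model, netv, exch)
    # random tracer: mixture of two random labeling patterns
    pat1 = tuple(sorted(rng.choice(3, size=rng.integers(1, 3),
                                   replace=False).tolist()))
    frac = float(rng.uniform(0.3, 0.9))
    tracer = TracerSpec("SRC", ((pat1, frac), ((), 1.0 - frac)),
                        purity=float(rng.uniform(0.9, 1.0)))
    return model, fluxes, tracer


def _line(rid, reac, prod, rev, lb, ub, role):
    return f"{rid}\t{reac}\t{prod}\t{rev}\t{lb}\t{ub}\t{role}"
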