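"""Gibbs free energies from flux ratios and metabolite concentrations.

At metabolic steady state the free energy of a reaction is tied to its
forward/backward flux ratio by the flux-force relation

    dG = -R T ln(J+ / J-),

so a reaction running close to equilibrium (J+ ~ J-) has dG ~ 0 and a
reaction whose reverse flux vanishes is unbounded in the negative
direction.  Where the reverse-flux confidence bound reaches zero the
flux-based estimate degenerates, and the concentration route

    dG = dG0' + R T ln(Q)

(with Q the product/reactant concentration ratio and dG0' the transformed
standard free energy at stated pH and ionic strength) supplies the bound
instead.  Defaults target thermophilic anaerobes grown at 55 C
(T = 328.15 K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .fluxfit import FitResult, FluxInterval
from .network import NetworkModel

R_GAS = 8.314  # J / (mol K)


@dataclass(frozen=True)
class ThermoContext:
    temperature: float = 328.15          # kelvin
    gas_constant: float = R_GAS
    dg0: dict[str, float] = field(default_factory=dict)   # kJ/mol per reaction

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def rt_kj(self) -> float:
        return self.gas_constant * self.temperature / 1000.0


@dataclass
class DeltaGEstimate:
    reaction: str
    best: float                          # kJ/mol
    lb: float = math.nan                 # most negative bound
    ub: float = math.nan                 # least negative bound
    method: str = "flux_ratio"
    unbounded_low: bool = False
    unbounded_high: bool = False


@dataclass
class ConcentrationSet:
    """Intracellular concentrations (mM) with SDs."""

    conc: dict[str, tuple[float, float]]

    def __post_init__(self):
        for met, (c, _) in self.conc.items():
            if c <= 0:
                raise ValueError(f"non-positive concentration for {met}")

    def value(self, met: str) -> float:
        return self.conc[met][0]

    def bounds(self, met: str) -> tuple[float, float]:
        c, sd = self.conc[met]
        return max(c - 1.96 * sd, 1e-12), c + 1.96 * sd


def delta_g_from_flux_ratio(j_plus: float, j_minus: float,
                            ctx: ThermoContext) -> float:
    """dG = -RT ln(J+/J-) in kJ/mol; -inf when the reverse flux is zero."""
    if j_plus <= 0:
        raise ValueError("j_plus must be positive; orient the reaction first")
    if j_minus < 0:
        raise ValueError("j_minus must be non-negative")
    if j_minus == 0:
        return -math.inf
    return -ctx.rt_kj * math.log(j_plus / j_minus)


def _reaction_quotient(model: NetworkModel, rid: str, conc,
                       skip=("WATER", "H2O", "H")) -> float:
    rxn = model.reaction(rid)
    q = 1.0
    for p in rxn.products:
        if p.met in skip:
            continue
        q *= conc(p.met)
    for p in rxn.reactants:
        if p.met in skip:
            continue
        q /= conc(p.met)
    return q


def delta_g_from_concentrations(model: NetworkModel, rid: str,
                                conc: ConcentrationSet, dg0: float,
                                ctx: ThermoContext) -> DeltaGEstimate:
    """dG = dG0' + RT ln Q, with interval propagation over concentration SDs."""
    rxn = model.reaction(rid)
    for p in rxn.reactants + rxn.products:
        if p.met in ("WATER", "H2O", "H"):
            continue
        if p.met not in conc.conc:
            raise KeyError(f"reaction {rid}: missing concentration for {p.met}")
    rt = ctx.rt_kj
    best = dg0 + rt * math.log(_reaction_quotient(model, rid, conc.value))

    def q_extreme(low_products: bool) -> float:
        def c(met):
            lo, hi = conc.bounds(met)
            is_product = any(p.met == met for p in rxn.products)
            if low_products:
                return lo if is_product else hi
            return hi if is_product else lo
        return _reaction_quotient(model, rid, c)

    lb = dg0 + rt * math.log(q_extreme(True))
    ub = dg0 + rt * math.log(q_extreme(False))
    return DeltaGEstimate(rid, best, lb=lb, ub=ub, method="concentration")


def pathway_delta_g(estimates: list[DeltaGEstimate],
                    name: str = "pathway") -> DeltaGEstimate:
    """Interval sum of sequential reaction free energies."""
    best = sum(e.best for e in estimates)
    lb = sum(e.lb for e in estimates) if estimates else 0.0
    ub = sum(e.ub for e in estimates) if estimates else 0.0
    return DeltaGEstimate(
        name, best if estimates else 0.0, lb=lb, ub=ub, method="pathway",
        unbounded_low=any(e.unbounded_low or math.isinf(e.lb) for e in estimates),
        unbounded_high=any(e.unbounded_high for e in estimates))


def flux_ratio_estimate(rid: str, j_plus: float, j_minus: float,
                        ctx: ThermoContext,
                        interval_net: FluxInterval | None = None,
                        interval_exch: FluxInterval | None = None,
                        ) -> DeltaGEstimate:
    """dG with 95% bounds mapped from net/exchange flux intervals.

    The mapping is the conservative rectangle: dG_LB uses the largest J+
    with the smallest J-, dG_UB the reverse.  An exchange lower bound of 0
    makes the estimate unbounded in the negative direction.
    """
    best = delta_g_from_flux_ratio(j_plus, j_minus, ctx)
    est = DeltaGEstimate(rid, best)
    if math.isinf(best):
        est.unbounded_low = True
        est.lb = -math.inf
    if interval_net is None or interval_exch is None:
        return est
    jp_hi = max(interval_net.ub, 0.0) + interval_exch.ub
    jp_lo = max(interval_net.lb, 0.0) + interval_exch.lb
    jm_hi = max(-interval_net.lb, 0.0) + interval_exch.ub
    jm_lo = max(-interval_net.ub, 0.0) + interval_exch.lb
    rt = ctx.rt_kj
    if jm_lo <= 0 or not interval_exch.lb_determined:
        est.unbounded_low = True
        est.lb = -math.inf
    else:
        est.lb = -rt * math.log(jp_hi / jm_lo)
    if jp_lo <= 0:
        est.unbounded_high = True
        est.ub = math.inf
    else:
        est.ub = -rt * math.log(jp_lo / jm_hi)
    return est


def thermo_report(model: NetworkModel, fit: FitResult, ctx: ThermoContext,
                  conc: ConcentrationSet | None = None,
                  reactions: list[str] | None = None) -> list[DeltaGEstimate]:
    """Per-reaction free energies from a converged fit.

    Reactions whose flux-ratio estimate is unbounded switch to the
    concentration method when a dG0' and concentrations are available;
    otherwise they are reported with their unbounded flags set.
    """
    if reactions is None:
        reactions = [r.id for r in model.reactions if r.reversible]
    out = []
    for rid in reactions:
        jp, jm = fit.fluxes[rid]
        if jp < jm:
            # report in the direction the net flux runs
            jp, jm = jm, jp
        iv_net = fit.intervals.get((rid, "net"))
        iv_exch = fit.intervals.get((rid, "exch"))
        est = flux_ratio_estimate(rid, max(jp, 1e-12), jm, ctx,
                                  iv_net, iv_exch)
        if est.unbounded_low and conc is not None and rid in ctx.dg0:
            est = delta_g_from_concentrations(model, rid, conc,
                                              ctx.dg0[rid], ctx)
        out.append(est)
    return out
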