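"""Executable pathway-discrimination hypotheses.

Competing route topologies predict distinct steady-state labeling patterns
under a given tracer; comparing predictions with observed MIDs identifies
the active route or bounds the contribution of a minor one.  A hypothesis
is either a closed-form mixing rule over route-specific MIDs (weights =
fractional contributions to the observed pool) or a full network variant
simulated with the EMU machinery.  Scoring is sum-of-squared-error ranking
plus least-squares estimation of two-route mixture weights; the registry
ships the standard discriminations for fermentative thermophiles
(EMP vs ED glycolysis, phosphoketolase and formaldehyde-transketolase
pentose routes, ketoisovalerate-derived leucine, citramalate- vs
threonine-derived isoleucine).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emu import EMUNode, MIDVector, TracerSpec, convolve_mids, simulate_mids


@dataclass
class RoutePrediction:
    """Predicted fragment MIDs of one pure route."""

    name: str
    mids: dict[str, MIDVector]


@dataclass
class PathwayHypothesis:
    """Weighted mixture of route predictions for one tracer condition."""

    name: str
    routes: tuple[tuple[float, RoutePrediction], ...]
    tracer: str = ""
    note: str = ""

    def __post_init__(self):
        total = sum(w for w, _ in self.routes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"route weights sum to {total}, expected 1")
        if any(w < 0 or w > 1 for w, _ in self.routes):
            raise ValueError("route weights must lie in [0, 1]")


def _aligned(mids: list[np.ndarray]) -> np.ndarray:
    n = max(len(m) for m in mids)
    out = np.zeros((len(mids), n))
    for i, m in enumerate(mids):
        out[i, :len(m)] = m
    return out


def predict_hypothesis_mids(h: PathwayHypothesis) -> dict[str, MIDVector]:
    """Weighted-mixture MIDs per fragment (valid MIDs by construction)."""
    fragments = sorted({f for _, r in h.routes for f in r.mids})
    out = {}
    for f in fragments:
        stacks = []
        weights = []
        for w, r in h.routes:
            if f not in r.mids:
                raise KeyError(f"route {r.name} lacks fragment {f}")
            stacks.append(r.mids[f].fractions)
            weights.append(w)
        M = _aligned(stacks)
        mix = np.asarray(weights) @ M
        out[f] = MIDVector(f, mix / mix.sum())
    return out


def simulate_route(name: str, model, fluxes, tracer: TracerSpec,
                   fragments: dict[str, EMUNode], p13: float = 0.0
                   ) -> RoutePrediction:
    """Route prediction computed from a network variant via EMU simulation."""
    sim = simulate_mids(model, fluxes, tracer, list(fragments.values()),
                        p13=p13)
    return RoutePrediction(name, {f: MIDVector(f, sim[emu].fractions)
                                  for f, emu in fragments.items()})


def score_hypotheses(observed: dict[str, MIDVector],
                     hypotheses: list[PathwayHypothesis]
                     ) -> list[tuple[str, float]]:
    """Rank hypotheses by summed squared error against observed MIDs."""
    ranked = []
    for h in hypotheses:
        pred = predict_hypothesis_mids(h)
        common = set(observed) & set(pred)
        if not common:
            raise ValueError(f"hypothesis {h.name}: no fragments overlap "
                             "with the observations")
        sse = 0.0
        for f in sorted(common):
            M = _aligned([observed[f].fractions, pred[f].fractions])
            sse += float(np.sum((M[0] - M[1]) ** 2))
        ranked.append((h.name, sse))
    return sorted(ranked, key=lambda t: t[1])


def estimate_route_weight(observed: dict[str, MIDVector],
                          route_a: RoutePrediction,
                          route_b: RoutePrediction,
                          fragments: list[str] | None = None,
                          mass_shifts: dict[str, list[int]] | None = None
                          ) -> float:
    """Least-squares weight of route A in a two-route mixture, in [0, 1].

    ``mass_shifts`` optionally restricts each fragment to its diagnostic
    mass bins (e.g. only the M+3 fraction separates threonine-derived from
    citramalate-derived isoleucine).
    """
    fragments = fragments or sorted(set(observed) & set(route_a.mids)
                                    & set(route_b.mids))
    if not fragments:
        raise ValueError("no overlapping fragments")
    num = 0.0
    den = 0.0
    for f in fragments:
        M = _aligned([observed[f].fractions, route_a.mids[f].fractions,
                      route_b.mids[f].fractions])
        obs, a, b = M
        idx = (mass_shifts or {}).get(f)
        if idx is not None:
            obs, a, b = obs[idx], a[idx], b[idx]
        d = a - b
        num += float(d @ (obs - b))
        den += float(d @ d)
    if den == 0:
        raise ValueError("routes predict identical MIDs on these fragments")
    return float(np.clip(num / den, 0.0, 1.0))


# ---------------------------------------------------------------------------
# shipped registry (closed-form route predictions)

def _mid(f, v):
    v = np.asarray(v, float)
    return MIDVector(f, v / v.sum())


def emp_route_3pg(tracer: str) -> RoutePrediction:
    """Lower-glycolysis pool from hexose-bisphosphate cleavage: both triose
    halves contribute, so single-position glucose labels appear in half the
    pool under either [1-13C1] or [6-13C1] glucose."""
    if tracer not in ("1-13C1", "6-13C1"):
        raise ValueError(tracer)
    return RoutePrediction(f"EMP[{tracer}]",
                           {"3PG": _mid("3PG", [0.5, 0.5, 0, 0])})


def ed_route_3pg(tracer: str) -> RoutePrediction:
    """KDPG cleavage sends glucose C1-C3 directly to pyruvate; the 3PG pool
    sees only C4-C6, so it is unlabeled under [1-13C1] and fully M+1 under
    [6-13C1] glucose."""
    if tracer == "1-13C1":
        return RoutePrediction(f"ED[{tracer}]",
                               {"3PG": _mid("3PG", [1, 0, 0, 0])})
    if tracer == "6-13C1":
        return RoutePrediction(f"ED[{tracer}]",
                               {"3PG": _mid("3PG", [0, 1, 0, 0])})
    raise ValueError(tracer)


def emp_ed_hypothesis(weight_ed: float, tracer: str) -> PathwayHypothesis:
    """Mixture of EMP- and ED-derived contributions to the 3PG pool."""
    return PathwayHypothesis(
        f"EMP{1 - weight_ed:g}-ED{weight_ed:g}",
        ((1.0 - weight_ed, emp_route_3pg(tracer)),
         (weight_ed, ed_route_3pg(tracer))), tracer=tracer)


def phosphoketolase_xu5p() -> RoutePrediction:
    """Xu5P assembled by phosphoketolase from a GAP unit and an
    acetyl-phosphate unit, each 50% M+0 / 50% M+1 under [6-13C1] glucose."""
    gap = _mid("GAP", [0.5, 0.5, 0, 0])
    acp = _mid("AcP", [0.5, 0.5, 0])
    xu5p = convolve_mids(gap, acp)
    return RoutePrediction("phosphoketolase",
                           {"Xu5P": _mid("Xu5P", xu5p.fractions)})


def leucine_from_c2_units() -> RoutePrediction:
    """Leucine inherits three independent two-carbon units, each 50%
    unlabeled / 50% doubly labeled under [1,2-13C2] glucose."""
    c2 = _mid("C2", [0.5, 0, 0.5])
    leu = convolve_mids(convolve_mids(c2, c2), c2)
    return RoutePrediction("leucine-C2x3", {"Leu": _mid("Leu", leu.fractions)})


def isoleucine_threonine_route(co2_labeled_fraction: float = 0.0
                               ) -> RoutePrediction:
    """Isoleucine via threonine under equimolar [U-13C6]/unlabeled glucose.

    The 2-oxobutanoate skeleton is PEP (50% M+0 / 50% M+3) plus a CO2
    carbon (labeled with fraction f); condensation with a pyruvate-derived
    two-carbon unit (50% M+0 / 50% M+2) gives the isoleucine pattern.  The
    M+3 fraction is 25% independent of f.
    """
    pep = _mid("PEP", [0.5, 0, 0, 0.5])
    co2 = _mid("CO2", [1 - co2_labeled_fraction, co2_labeled_fraction])
    ob2 = convolve_mids(pep, co2)
    c2 = _mid("C2", [0.5, 0, 0.5])
    ile = convolve_mids(ob2, c2)
    return RoutePrediction("ile-threonine", {"Ile": _mid("Ile", ile.fractions)})


def isoleucine_citramalate_route() -> RoutePrediction:
    """Isoleucine via citramalate under equimolar [U-13C6]/unlabeled
    glucose: pyruvate C2-C3 (50% M+0 / 50% M+2) + acetyl unit (50%/50%)
    + pyruvate-derived C2 unit; no M+3 forms (labels come in pairs)."""
    c2 = _mid("C2", [0.5, 0, 0.5])
    ile = convolve_mids(convolve_mids(c2, c2), c2)
    return RoutePrediction("ile-citramalate",
                           {"Ile": _mid("Ile", ile.fractions)})


# ---------------------------------------------------------------------------
# registry file dialect: hypotheses as data, not code branches

REGISTRY_HEADER = "#fluxtherm-hypothesis v1"


def parse_hypotheses(text: str) -> list[PathwayHypothesis]:
    """Parse a hypothesis registry file.

    Dialect::

        #fluxtherm-hypothesis v1
        @hypothesis <name> <tracer>
        @mix <weight> <route-name>          # one per route, weights sum to 1
        @route <route-name> <fragment> <f0> <f1> ...

    ``@route`` lines are shared across hypotheses in the same file.
    """
    routes: dict[str, RoutePrediction] = {}
    pending: list[tuple[str, str, list[tuple[float, str]]]] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if toks[0] == "@hypothesis":
            pending.append((toks[1], toks[2] if len(toks) > 2 else "", []))
        elif toks[0] == "@mix":
            if not pending:
                raise ValueError(f"line {lineno}: @mix before @hypothesis")
            pending[-1][2].append((float(toks[1]), toks[2]))
        elif toks[0] == "@route":
            name, fragment = toks[1], toks[2]
            frac = np.asarray([float(t) for t in toks[3:]])
            route = routes.setdefault(name, RoutePrediction(name, {}))
            route.mids[fragment] = MIDVector(fragment, frac / frac.sum())
        else:
            raise ValueError(f"line {lineno}: unknown directive {toks[0]!r}")
    out = []
    for name, tracer, mixes in pending:
        missing = [rn for _, rn in mixes if rn not in routes]
        if missing:
            raise ValueError(f"hypothesis {name}: undefined routes {missing}")
        out.append(PathwayHypothesis(
            name, tuple((w, routes[rn]) for w, rn in mixes), tracer=tracer))
    return out


def write_hypotheses(hypotheses: list[PathwayHypothesis]) -> str:
    lines = [REGISTRY_HEADER]
    seen: dict[str, RoutePrediction] = {}
    for h in hypotheses:
        for _, r in h.routes:
            seen.setdefault(r.name, r)
    for r in seen.values():
        for fragment, mid in sorted(r.mids.items()):
            vals = " ".join(f"{f:.10g}" for f in mid.fractions)
            lines.append(f"@route {r.name} {fragment} {vals}")
    for h in hypotheses:
        lines.append(f"@hypothesis {h.name} {h.tracer}")
        for w, r in h.routes:
            lines.append(f"@mix {w:.10g} {r.name}")
    return "\n".join(lines) + "\n"


def standard_registry() -> list[PathwayHypothesis]:
    """The shipped discriminations as registry entries."""
    out = []
    for tracer in ("1-13C1", "6-13C1"):
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            out.append(emp_ed_hypothesis(w, tracer))
    out.append(PathwayHypothesis("pentose-phosphoketolase",
                                 ((1.0, phosphoketolase_xu5p()),),
                                 tracer="6-13C1"))
    out.append(PathwayHypothesis("pentose-ftkt", ((1.0, ftkt_pentose()),),
                                 tracer="1,2-13C2",
                                 note="reconstructed, assumption-dependent"))
    out.append(PathwayHypothesis("leucine-c2-assembly",
                                 ((1.0, leucine_from_c2_units()),),
                                 tracer="1,2-13C2"))
    out.append(PathwayHypothesis("ile-threonine",
                                 ((1.0, isoleucine_threonine_route()),),
                                 tracer="U-13C6/unlabeled"))
    out.append(PathwayHypothesis("ile-citramalate",
                                 ((1.0, isoleucine_citramalate_route()),),
                                 tracer="U-13C6/unlabeled"))
    return out


def ftkt_pentose() -> RoutePrediction:
    """Formaldehyde-transketolase pentose route under [1,2-13C2] glucose.

    Reconstructed, assumption-dependent: DHA (from DHAP, 50% M+0 / 50%
    M+2) is symmetric, so the transferred two-carbon unit from an M+2 DHA
    carries both labels or just one with equal odds; condensation with GAP
    (50% M+0 / 50% M+2) populates every mass from M+0 to M+4 with M+2
    enriched — qualitatively distinct from the canonical non-oxidative
    pentose phosphate route, which leaves M+1/M+3 nearly empty.
    """
    dha_c2 = _mid("DHA-C2", [0.5, 0.25, 0.25])
    gap = _mid("GAP", [0.5, 0, 0.5, 0])
    xu5p = convolve_mids(dha_c2, gap)
    return RoutePrediction("ftkt", {"Xu5P": _mid("Xu5P", xu5p.fractions)})
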