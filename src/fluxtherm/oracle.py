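"""Exact positional-isotopomer oracle for verifying the EMU simulator.

Solves the full isotopomer balance by fixed-point iteration: each balanced
metabolite's distribution over 2^n positional isotopomers is repeatedly
replaced by its inflow-weighted production, with condensation reactions
taking the outer product of their reactants' current distributions.  The
map is a contraction at isotopic steady state, with convergence rate set by
the largest recycle fraction, so iteration counts grow with exchange flux;
the implementation iterates until the residual falls below tolerance.

Intended for small networks only (<= 16 tracked atoms across balanced
metabolites); the EMU simulator is the production path.
"""

from __future__ import annotations

import itertools

import numpy as np

from .emu import EMUNode, MIDVector, SimulationError, TracerSpec, flux_modes, input_mid
from .network import NetworkModel

MAX_TRACKED_ATOMS = 16


def _boundary_isotopomers(model: NetworkModel, met: str,
                          tracer: TracerSpec | None, p13: float) -> np.ndarray:
    """Joint positional distribution of an unbalanced pool (atoms independent
    except for tracer mixture structure)."""
    m = model.metabolites[met]
    n = m.n_atoms
    dist = np.zeros(2 ** n)
    if tracer is not None and met == tracer.substrate:
        for labeled, frac in tracer.patterns:
            probs = []
            for a in range(n):
                if a in labeled:
                    probs.append(tracer.purity)
                elif a < m.n_carbons:
                    probs.append(p13)
                else:
                    probs.append(0.0)
            dist += frac * _independent_joint(probs)
    else:
        probs = [p13 if a < m.n_carbons else 0.0 for a in range(n)]
        dist = _independent_joint(probs)
    if m.symmetric and n > 0:
        dist = 0.5 * (dist + _reversed_joint(dist, m.n_carbons, m.n_hydrogens))
    return dist


def _independent_joint(probs: list[float]) -> np.ndarray:
    dist = np.array([1.0])
    for p in probs:
        dist = np.concatenate([(1 - p) * dist, p * dist])
    return dist


def _reversed_joint(dist: np.ndarray, nc: int, nh: int) -> np.ndarray:
    n = nc + nh
    perm = list(range(nc))[::-1] + [nc + i for i in range(nh)][::-1]
    out = np.empty_like(dist)
    for state in range(2 ** n):
        bits = [(state >> a) & 1 for a in range(n)]
        new = sum(bits[perm[a]] << a for a in range(n))
        out[new] = dist[state]
    return out


def enumerate_isotopomers_oracle(model: NetworkModel, fluxes,
                                 tracer: TracerSpec, target: EMUNode,
                                 p13: float = 0.0, tol: float = 1e-13,
                                 max_iter: int = 200_000) -> MIDVector:
    """Exact steady-state MID of ``target`` by full isotopomer balancing."""
    balanced = model.balanced_metabolites()
    total_atoms = sum(model.metabolites[m].n_atoms for m in balanced)
    if total_atoms > MAX_TRACKED_ATOMS:
        raise SimulationError(
            f"oracle size cap exceeded: {total_atoms} tracked atoms "
            f"(limit {MAX_TRACKED_ATOMS})")

    jp = np.asarray(fluxes.j_plus, dtype=float)
    jm = np.asarray(fluxes.j_minus, dtype=float)
    modes = flux_modes(model)

    # initial state: everything unlabeled
    state: dict[str, np.ndarray] = {}
    for met in balanced:
        n = model.metabolites[met].n_atoms
        d = np.zeros(2 ** n)
        d[0] = 1.0
        state[met] = d
    boundary = {m.id: _boundary_isotopomers(model, m.id, tracer, p13)
                for m in model.metabolites.values() if not m.balanced}

    # production recipes: (met, flux_ref, atom sources)
    recipes: dict[str, list] = {met: [] for met in balanced}
    for mode in modes:
        for p in mode.products:
            if p.met not in recipes:
                continue
            srcs = []     # per product atom: (reactant_index, reactant_atom)
            for ch in p.atoms:
                for ri, rp in enumerate(mode.reactants):
                    pos = rp.atoms.find(ch)
                    if pos >= 0:
                        srcs.append((ri, pos))
                        break
            recipes[p.met].append((mode, p, srcs))

    def produced_dist(mode, part, srcs) -> np.ndarray:
        n = len(part.atoms)
        # marginalize each reactant onto the atoms it contributes
        react_dists = []
        for ri, rp in enumerate(mode.reactants):
            d = state.get(rp.met)
            if d is None:
                d = boundary[rp.met]
            react_dists.append(d)
        out = np.zeros(2 ** n)
        # enumerate joint source states reactant by reactant
        contrib = {}    # reactant -> list of product-atom positions & src atoms
        for pa, (ri, ra) in enumerate(srcs):
            contrib.setdefault(ri, []).append((pa, ra))
        # marginal over used atoms per reactant
        marg = {}
        for ri, pairs in contrib.items():
            d = react_dists[ri]
            natoms = int(np.log2(len(d)) + 0.5)
            m = np.zeros(2 ** len(pairs))
            for s in range(len(d)):
                key = 0
                for k, (_, ra) in enumerate(pairs):
                    key |= ((s >> ra) & 1) << k
                m[key] += d[s]
            marg[ri] = (m, pairs)
        for combo in itertools.product(*[range(len(marg[ri][0]))
                                         for ri in marg]):
            prob = 1.0
            pstate = 0
            for (ri, c) in zip(marg, combo):
                m, pairs = marg[ri]
                prob *= m[c]
                for k, (pa, _) in enumerate(pairs):
                    pstate |= ((c >> k) & 1) << pa
            out[pstate] += prob
        return out

    for it in range(max_iter):
        max_delta = 0.0
        for met in balanced:
            total = 0.0
            acc = np.zeros_like(state[met])
            for mode, part, srcs in recipes[met]:
                w = mode.weight * (jp[mode.rxn_index] if mode.direction > 0
                                   else jm[mode.rxn_index])
                if w == 0.0:
                    continue
                total += w
                acc += w * produced_dist(mode, part, srcs)
            if total == 0.0:
                raise SimulationError(f"metabolite {met} has no inflow")
            new = acc / total
            max_delta = max(max_delta, float(np.abs(new - state[met]).max()))
            state[met] = new
        if max_delta < tol:
            break
    else:
        raise SimulationError("isotopomer iteration did not converge")

    m = model.metabolites[target.met]
    dist = state[target.met] if m.balanced else boundary[target.met]
    n = m.n_atoms
    mid = np.zeros(target.size + 1)
    for s in range(2 ** n):
        k = sum((s >> a) & 1 for a in target.atoms)
        mid[k] += dist[s]
    return MIDVector(target.label(), mid / mid.sum())
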