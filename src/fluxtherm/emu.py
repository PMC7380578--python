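"""Steady-state isotopomer simulation via elementary metabolite units.

An EMU is a subset of one metabolite's tracked atoms.  At isotopic steady
state the mass-isotopomer distribution (MID) of every EMU of size *s*
satisfies a linear balance once all EMUs of size < *s* are known, because a
condensation reaction assembles an EMU from independent smaller EMUs whose
MIDs convolve.  The simulator decomposes the network backward from the
requested target EMUs, groups the cascade by size, and solves one dense
linear system per size.

Reversible reactions contribute two flux modes: the forward mode weighted by
J+ and the backward mode (atom map inverted) weighted by J-.  Exchange flux
therefore enters the balances directly, not as net flux.  A metabolite
flagged symmetric is indistinguishable under reversal of its atom order, so
every mode producing it is split into two half-weight variants, one with the
produced atom string reversed (carbons and tracked hydrogens reversed
separately).

Unbalanced metabolites are isotopic boundary conditions: the tracer
substrate takes its MID from the :class:`TracerSpec`; every other unbalanced
pool is at natural abundance (``p13`` per carbon, hydrogens unlabeled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .network import Metabolite, NetworkModel, Participant, Reaction

C13_NATURAL_ABUNDANCE = 0.0107


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class EMUNode:
    """A metabolite together with a subset of its tracked-atom indices."""

    met: str
    atoms: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(sorted(self.atoms)))
        if not self.atoms:
            raise ValueError("EMU needs a non-empty atom subset")

    @property
    def size(self) -> int:
        return len(self.atoms)

    def label(self) -> str:
        return f"{self.met}:{','.join(str(i + 1) for i in self.atoms)}"


@dataclass
class MIDVector:
    """Fractional abundances M+0..M+n of a fragment, optionally with SDs."""

    fragment: str
    fractions: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)

    def normalized(self) -> "MIDVector":
        s = self.fractions.sum()
        if s <= 0:
            raise ValueError(f"{self.fragment}: non-positive MID mass")
        return MIDVector(self.fragment, self.fractions / s, self.sd)

    def __len__(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class TracerSpec:
    """Isotopic composition of the feed substrate.

    ``patterns`` maps each molecular species in the feed to its molar
    fraction; a pattern is the tuple of labeled tracked-atom indices
    (0-based).  ``purity`` is the atom fraction of heavy isotope at the
    positions a pattern declares labeled; unlabeled positions sit at the
    natural abundance passed to the simulator.
    """

    substrate: str
    patterns: tuple[tuple[tuple[int, ...], float], ...]
    purity: float = 1.0

    def __post_init__(self):
        total = sum(f for _, f in self.patterns)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tracer fractions sum to {total}, expected 1")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0, 1]")


def convolve_mids(a: MIDVector, b: MIDVector) -> MIDVector:
    """Cauchy product of two independent fragments' MIDs."""
    frac = np.convolve(a.fractions, b.fractions)
    return MIDVector(f"{a.fragment}*{b.fragment}", frac)


def natural_mid(n_carbons: int, n_hydrogens: int = 0,
                p13: float = C13_NATURAL_ABUNDANCE) -> np.ndarray:
    """Binomial natural-abundance MID over tracked atoms (2H treated as 0)."""
    mid = np.array([1.0])
    atom = np.array([1.0 - p13, p13])
    for _ in range(n_carbons):
        mid = np.convolve(mid, atom)
    mid = np.concatenate([mid, np.zeros(n_hydrogens)])
    return mid


# ---------------------------------------------------------------------------
# flux modes

@dataclass(frozen=True)
class FluxMode:
    """One directed, symmetry-resolved variant of a reaction."""

    rxn_index: int
    direction: int          # +1 forward (J+), -1 backward (J-)
    weight: float           # symmetry weight (1, 1/2, 1/4 ...)
    reactants: tuple[Participant, ...]
    products: tuple[Participant, ...]


def _reverse_atoms(atoms: str, met: Metabolite) -> str:
    nc = met.n_carbons
    return atoms[:nc][::-1] + atoms[nc:][::-1]


def _symmetric_variants(products: tuple[Participant, ...],
                        mets: dict[str, Metabolite]):
    """Split product sides on symmetric metabolites (half weight each)."""
    variants = [(1.0, list(products))]
    for i, p in enumerate(products):
        m = mets[p.met]
        if m.symmetric and p.atoms:
            new = []
            for w, side in variants:
                flipped = list(side)
                flipped[i] = Participant(p.met, _reverse_atoms(p.atoms, m))
                new.append((w / 2, side))
                new.append((w / 2, flipped))
            variants = new
    return [(w, tuple(side)) for w, side in variants]


def flux_modes(model: NetworkModel) -> list[FluxMode]:
    key = "flux_modes"
    if key in model._cache:
        return model._cache[key]
    modes: list[FluxMode] = []
    for j, r in enumerate(model.reactions):
        for w, prods in _symmetric_variants(r.products, model.metabolites):
            modes.append(FluxMode(j, +1, w, r.reactants, prods))
        if r.reversible:
            for w, prods in _symmetric_variants(r.reactants, model.metabolites):
                modes.append(FluxMode(j, -1, w, r.products, prods))
    model._cache[key] = modes
    return modes


# ---------------------------------------------------------------------------
# decomposition

@dataclass(frozen=True)
class EMUTerm:
    """One production route of an EMU: flux reference and source EMUs."""

    rxn_index: int
    direction: int
    weight: float
    sources: tuple[EMUNode, ...]   # >1 means convolution (condensation)


@dataclass
class EMUCascade:
    """Backward-reachable EMU set grouped by size, with balance terms."""

    targets: tuple[EMUNode, ...]
    terms: dict[EMUNode, tuple[EMUTerm, ...]]
    inputs: set[EMUNode]

    def sizes(self) -> list[int]:
        return sorted({e.size for e in self.terms} | {e.size for e in self.inputs})

    def by_size(self, s: int) -> list[EMUNode]:
        return sorted((e for e in self.terms if e.size == s),
                      key=lambda e: (e.met, e.atoms))

    @property
    def n_emus(self) -> int:
        return len(self.terms) + len(self.inputs)


def _producing_occurrences(model: NetworkModel):
    """met -> list of (mode, product participant index)."""
    key = "producing_occ"
    if key in model._cache:
        return model._cache[key]
    occ: dict[str, list[tuple[FluxMode, int]]] = {}
    for mode in flux_modes(model):
        for i, p in enumerate(mode.products):
            occ.setdefault(p.met, []).append((mode, i))
    model._cache[key] = occ
    return occ


def decompose_emus(model: NetworkModel,
                   targets: list[EMUNode]) -> EMUCascade:
    """Build the EMU cascade reachable backward from the targets."""
    cache = model._cache.setdefault("cascades", {})
    ckey = tuple(sorted(targets, key=lambda e: (e.met, e.atoms)))
    if ckey in cache:
        return cache[ckey]

    for t in targets:
        m = model.metabolites.get(t.met)
        if m is None:
            raise SimulationError(f"target metabolite {t.met} not in model")
        if any(a < 0 or a >= m.n_atoms for a in t.atoms):
            raise SimulationError(f"target {t.label()}: atom index out of range")

    occ = _producing_occurrences(model)
    terms: dict[EMUNode, tuple[EMUTerm, ...]] = {}
    inputs: set[EMUNode] = set()
    stack = list(targets)
    seen: set[EMUNode] = set()
    while stack:
        emu = stack.pop()
        if emu in seen:
            continue
        seen.add(emu)
        if not model.metabolites[emu.met].balanced:
            inputs.add(emu)
            continue
        emu_terms: list[EMUTerm] = []
        for mode, pidx in occ.get(emu.met, ()):
            prod = mode.products[pidx]
            letters = [prod.atoms[a] for a in emu.atoms]
            per_reactant: dict[int, list[int]] = {}
            for ch in letters:
                found = False
                for ri, rp in enumerate(mode.reactants):
                    pos = rp.atoms.find(ch)
                    if pos >= 0:
                        per_reactant.setdefault(ri, []).append(pos)
                        found = True
                        break
                if not found:   # pragma: no cover - excluded by parse invariant
                    raise SimulationError(
                        f"reaction {model.reactions[mode.rxn_index].id}: "
                        f"product atom {ch!r} has no source")
            sources = tuple(sorted(
                (EMUNode(mode.reactants[ri].met, tuple(pos))
                 for ri, pos in per_reactant.items()),
                key=lambda e: (e.met, e.atoms)))
            emu_terms.append(EMUTerm(mode.rxn_index, mode.direction,
                                     mode.weight, sources))
            stack.extend(sources)
        terms[emu] = tuple(emu_terms)
    cascade = EMUCascade(tuple(ckey), terms, inputs)
    cache[ckey] = cascade
    return cascade


# ---------------------------------------------------------------------------
# simulation

def _pattern_mid(emu: EMUNode, met: Metabolite,
                 labeled: tuple[int, ...], purity: float,
                 p13: float) -> np.ndarray:
    mid = np.array([1.0])
    for a in emu.atoms:
        if a in labeled:
            p = purity
        elif a < met.n_carbons:
            p = p13
        else:
            p = 0.0
        mid = np.convolve(mid, np.array([1.0 - p, p]))
    return mid


def input_mid(emu: EMUNode, model: NetworkModel, tracer: TracerSpec | None,
              p13: float = 0.0) -> np.ndarray:
    """Boundary MID of an unbalanced-pool EMU."""
    met = model.metabolites[emu.met]
    if tracer is not None and emu.met == tracer.substrate:
        mid = np.zeros(emu.size + 1)
        for labeled, frac in tracer.patterns:
            mid += frac * _pattern_mid(emu, met, labeled, tracer.purity, p13)
        return mid
    nc = sum(1 for a in emu.atoms if a < met.n_carbons)
    nh = emu.size - nc
    mid = natural_mid(nc, nh, p13)
    if met.symmetric:
        # orientation-averaged pool: binomial MIDs are already symmetric
        pass
    return mid


def simulate_mids(model: NetworkModel, fluxes, tracer: TracerSpec,
                  targets: list[EMUNode], p13: float = 0.0,
                  ) -> dict[EMUNode, MIDVector]:
    """Steady-state MIDs of the target EMUs.

    ``fluxes`` is a :class:`fluxtherm.fluxfit.FluxState` (or anything with
    ``j_plus``/``j_minus`` arrays aligned with ``model.reactions``).
    """
    cascade = decompose_emus(model, targets)
    jp = np.asarray(fluxes.j_plus, dtype=float)
    jm = np.asarray(fluxes.j_minus, dtype=float)

    solved: dict[EMUNode, np.ndarray] = {}

    def mode_flux(term: EMUTerm) -> float:
        base = jp[term.rxn_index] if term.direction > 0 else jm[term.rxn_index]
        return term.weight * base

    def source_mid(e: EMUNode) -> np.ndarray:
        if e in solved:
            return solved[e]
        mid = input_mid(e, model, tracer, p13)
        solved[e] = mid
        return mid

    # prune EMUs only reachable through zero-flux modes (inactive branch
    # variants, optimizer iterates with a dead route): they feed nothing
    needed: set[EMUNode] = set()
    stack = list(cascade.targets)
    while stack:
        e = stack.pop()
        if e in needed or e not in cascade.terms:
            continue
        needed.add(e)
        for term in cascade.terms[e]:
            if mode_flux(term) != 0.0:
                stack.extend(term.sources)

    for size in cascade.sizes():
        unknowns = [e for e in cascade.by_size(size) if e in needed]
        if not unknowns:
            continue
        index = {e: i for i, e in enumerate(unknowns)}
        n = len(unknowns)
        A = np.zeros((n, n))
        B = np.zeros((n, size + 1))
        for e in unknowns:
            i = index[e]
            w_tot = 0.0
            for term in cascade.terms[e]:
                w = mode_flux(term)
                if w == 0.0:
                    continue
                w_tot += w
                if len(term.sources) == 1 and term.sources[0] in index:
                    A[i, index[term.sources[0]]] += w
                else:
                    mid = source_mid(term.sources[0])
                    for s in term.sources[1:]:
                        mid = np.convolve(mid, source_mid(s))
                    B[i] -= w * mid
            A[i, i] -= w_tot
            if w_tot == 0.0:
                raise SimulationError(
                    f"EMU {e.label()} has no inflow (disconnected pool)")
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as err:
            raise SimulationError(f"singular EMU system at size {size}: {err}")
        for e, row in zip(unknowns, X):
            solved[e] = row

    out: dict[EMUNode, MIDVector] = {}
    for t in cascade.targets:
        frac = solved[t] if t in solved else input_mid(t, model, tracer, p13)
        s = frac.sum()
        if not np.isfinite(s) or abs(s - 1.0) > 1e-6:
            raise SimulationError(
                f"EMU {t.label()}: simulated MID sums to {s:.6g}")
        if frac.min() < -1e-6:
            raise SimulationError(
                f"EMU {t.label()}: negative MID fraction {frac.min():.3g}")
        out[t] = MIDVector(t.label(), np.clip(frac, 0.0, None) / s)
    return out


def metabolite_emu(model: NetworkModel, met: str,
                   carbons_only: bool = False) -> EMUNode:
    """The full-fragment EMU of a metabolite (all tracked atoms)."""
    m = model.metabolites[met]
    n = m.n_carbons if carbons_only else m.n_atoms
    return EMUNode(met, tuple(range(n)))
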