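"""Atom-mapped metabolic network models.

A model is a set of metabolites (each with a number of tracked carbons and,
optionally, tracked non-exchangeable hydrogens) and a list of reactions whose
participants carry atom-transition strings: one lowercase letter per tracked
atom, carbons first (C1..Cn by conventional numbering), then tracked
hydrogens.  Letters name atoms, so a letter appearing in a reactant and a
product means "this atom moves there".  Atoms whose letter does not reappear
on the product side are lost to untracked sinks (off-model CO2, water,
formaldehyde).

Pools that are not balanced at steady state (extracellular substrates,
excreted products, the unlabeled-CO2 dilution twin, water, the generic
hydride donor) are flagged ``balanced=False``; they act as isotopic boundary
conditions and are excluded from the stoichiometric matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

MODEL_HEADER = "#fluxtherm-model v1"

ROLES = ("internal", "transport", "dilution", "biomass")


class ModelError(ValueError):
    """Raised for malformed model files or atom-map violations."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    n_carbons: int
    n_hydrogens: int = 0
    symmetric: bool = False
    balanced: bool = True

    @property
    def n_atoms(self) -> int:
        return self.n_carbons + self.n_hydrogens

    def __post_init__(self):
        if self.n_carbons < 0 or self.n_hydrogens < 0:
            raise ModelError(f"metabolite {self.id}: negative atom count")


@dataclass(frozen=True)
class Participant:
    """One occurrence of a metabolite on one side of a reaction.

    ``atoms`` has one letter per tracked atom of the metabolite.  A
    metabolite taking part with stoichiometry 2 appears as two participants
    with distinct letters.
    """

    met: str
    atoms: str


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: tuple[Participant, ...]
    products: tuple[Participant, ...]
    reversible: bool = False
    lb: float = 0.0
    ub: float = 1000.0
    role: str = "internal"


@dataclass
class NetworkModel:
    name: str
    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    variant: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def reaction_index(self, rid: str) -> int:
        for i, r in enumerate(self.reactions):
            if r.id == rid:
                return i
        raise KeyError(rid)

    def balanced_metabolites(self) -> list[str]:
        return [m for m, spec in self.metabolites.items() if spec.balanced]


# ---------------------------------------------------------------------------
# parsing / writing

_PART_RE = re.compile(r"^\s*([A-Za-z0-9_.]+)\s*(?:\(([A-Za-z]*)\))?\s*$")


def _parse_side(expr: str, rid: str) -> tuple[Participant, ...]:
    expr = expr.strip()
    if expr in ("", "-"):
        return ()
    parts = []
    for chunk in expr.split("+"):
        m = _PART_RE.match(chunk)
        if not m:
            raise ModelError(f"reaction {rid}: cannot parse participant {chunk!r}")
        parts.append(Participant(m.group(1), m.group(2) or ""))
    return tuple(parts)


def parse_model(text: str, name: str = "model", variant: str = "") -> NetworkModel:
    """Parse the tab-separated model dialect.

    Metabolite declarations (``@met id carbons hydrogens symmetric balanced``)
    precede reactions; each reaction line is
    ``id<TAB>reactants<TAB>products<TAB>reversible<TAB>lb<TAB>ub<TAB>role``.
    """
    mets: dict[str, Metabolite] = {}
    rxns: list[Reaction] = []
    seen_ids: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@met"):
            toks = line.split()
            if len(toks) != 6:
                raise ModelError(f"line {lineno}: @met needs 5 fields")
            _, mid, nc, nh, sym, bal = toks
            if mid in mets:
                raise ModelError(f"line {lineno}: duplicate metabolite {mid}")
            mets[mid] = Metabolite(mid, int(nc), int(nh),
                                   symmetric=bool(int(sym)), balanced=bool(int(bal)))
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != 7:
            raise ModelError(f"line {lineno}: expected 7 tab-separated fields, got {len(fields)}")
        rid, rexpr, pexpr, rev, lb, ub, role = (f.strip() for f in fields)
        if rid in seen_ids:
            raise ModelError(f"duplicate reaction id {rid}")
        seen_ids.add(rid)
        if role not in ROLES:
            raise ModelError(f"reaction {rid}: unknown role {role!r}")
        rxn = Reaction(rid, _parse_side(rexpr, rid), _parse_side(pexpr, rid),
                       reversible=bool(int(rev)), lb=float(lb), ub=float(ub), role=role)
        _check_reaction_atoms(rxn, mets)
        rxns.append(rxn)
    return NetworkModel(name=name, metabolites=mets, reactions=rxns, variant=variant)


def _fmt_side(parts: tuple[Participant, ...]) -> str:
    if not parts:
        return "-"
    return " + ".join(f"{p.met} ({p.atoms})" if p.atoms else p.met for p in parts)


def write_model(model: NetworkModel) -> str:
    lines = [MODEL_HEADER]
    for m in model.metabolites.values():
        lines.append(f"@met {m.id} {m.n_carbons} {m.n_hydrogens} "
                     f"{int(m.symmetric)} {int(m.balanced)}")
    for r in model.reactions:
        lines.append("\t".join([
            r.id, _fmt_side(r.reactants), _fmt_side(r.products),
            str(int(r.reversible)), repr(r.lb), repr(r.ub), r.role,
        ]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# validation

def _check_reaction_atoms(rxn: Reaction, mets: dict[str, Metabolite]) -> None:
    """Hard invariants enforced at parse time (raise ModelError)."""
    seen: set[str] = set()
    for side, parts in (("reactant", rxn.reactants), ("product", rxn.products)):
        for p in parts:
            if p.met not in mets:
                raise ModelError(f"reaction {rxn.id}: undeclared metabolite {p.met}")
            n = mets[p.met].n_atoms
            if len(p.atoms) != n:
                raise ModelError(
                    f"reaction {rxn.id}, metabolite {p.met}: atom string "
                    f"{p.atoms!r} has {len(p.atoms)} letters, expected {n}")
    for p in rxn.reactants:
        for ch in p.atoms:
            if ch in seen:
                raise ModelError(f"reaction {rxn.id}: reactant letter {ch!r} reused")
            seen.add(ch)
    prod_seen: set[str] = set()
    for p in rxn.products:
        for ch in p.atoms:
            if ch in prod_seen:
                raise ModelError(f"reaction {rxn.id}: product letter {ch!r} reused")
            prod_seen.add(ch)
            if ch not in seen:
                raise ModelError(
                    f"reaction {rxn.id}: product atom {ch!r} has no reactant source")
    if rxn.reversible:
        # the reversed reaction must itself be a valid atom map: every
        # reactant atom must reappear so the backward direction has sources
        missing = seen - prod_seen
        if missing:
            raise ModelError(
                f"reaction {rxn.id}: reversible but atoms {sorted(missing)} "
                "are lost (backward direction would create atoms)")


def build_stoichiometry(model: NetworkModel):
    """Stoichiometric matrix over balanced metabolites.

    Returns ``(S, met_order)`` with S of shape (n_balanced, n_reactions);
    coefficients count participant occurrences (products minus reactants).
    """
    mets = model.balanced_metabolites()
    idx = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for p in r.reactants:
            if p.met in idx:
                S[idx[p.met], j] -= 1
        for p in r.products:
            if p.met in idx:
                S[idx[p.met], j] += 1
    return S, mets


def validate_model(model: NetworkModel) -> list[str]:
    """Soft diagnostics: empty list means the model is usable end to end."""
    diags: list[str] = []
    for m in model.metabolites.values():
        if m.symmetric and m.n_atoms == 0:
            diags.append(f"symmetric metabolite {m.id} has no tracked atoms")
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in model.reactions:
        for p in r.reactants:
            consumed.add(p.met)
            if r.reversible:
                produced.add(p.met)
        for p in r.products:
            produced.add(p.met)
            if r.reversible:
                consumed.add(p.met)
    for m in model.balanced_metabolites():
        if m not in produced:
            diags.append(f"dead-end metabolite {m}: never produced")
        if m not in consumed:
            diags.append(f"dead-end metabolite {m}: never consumed")
    S, _ = build_stoichiometry(model)
    lb = np.array([r.lb if not r.reversible else r.lb for r in model.reactions])
    ub = np.array([r.ub for r in model.reactions])
    # feasibility of {S v = 0, lb <= v <= ub}
    n = len(model.reactions)
    res = linprog(np.zeros(n), A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        diags.append("infeasible steady state: no flux vector satisfies "
                     "S*v = 0 within the given bounds")
    else:
        # require a nonzero solution if any reaction admits positive flux
        c = -np.ones(n)
        res2 = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                       bounds=[(l, min(u, 1e3)) for l, u in zip(lb, ub)],
                       method="highs")
        if res2.success and abs(res2.fun) < 1e-9 and np.all(lb <= 0):
            diags.append("network admits only the zero steady-state flux")
    return diags
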