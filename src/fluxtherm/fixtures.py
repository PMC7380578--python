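"""Reconstructed fixture networks.

The shipped networks are *reconstructed* reduced models of central carbon
metabolism in two thermophilic anaerobes — a Clostridium thermocellum-style
glycolysis (PPi-linked Pfk, no pyruvate kinase, PEP converted to pyruvate
by Ppdk and/or the malate shunt) and a Thermoanaerobacterium
saccharolyticum-style network (ATP-Pfk, Pyk, bifurcated TCA cycle,
sedoheptulose-bisphosphate bypass in the PPP, citramalate route to
isoleucine) — not transcriptions of any published supplementary table.

Atom conventions: carbons 1..n numbered carbonyl-proximal; the glycolytic
segment additionally tracks the two glucose hydrogens (H4, H5, atom indices
6 and 7 on hexoses) whose fate reports on GAPDH, Tpi and enolase
reversibility in deuterated-glucose experiments.  The NAD(H) hydride is a
one-atom balanced pool so the GAPDH-mediated transfer of deuterium to NADH
(and its return on reverse flux) is representable; water is an infinite
unlabeled pool that absorbs or donates tracked hydrogens.  Lumped PPP/TCA
reactions outside the glycolytic segment are carbon-only and shed tracked
hydrogens to water.
"""

from __future__ import annotations

from .emu import TracerSpec
from .network import NetworkModel, parse_model

GLUCOSE = "GLC.ext"


def _met(mid, nc, nh=0, sym=0, bal=1):
    return f"@met {mid} {nc} {nh} {sym} {bal}"


def _rx(rid, reac, prod, rev=0, lb=None, ub=1000.0, role="internal"):
    if lb is None:
        lb = -1000.0 if rev else 0.0
    return f"{rid}\t{reac}\t{prod}\t{rev}\t{lb}\t{ub}\t{role}"


# ---------------------------------------------------------------------------
# glycolysis cores (used for fitting / synthetic-data studies)

def _core_lines(variant: str, malic_enzyme: bool) -> list[str]:
    mets = [
        _met(GLUCOSE, 6, 2, bal=0),
        _met("G6P", 6, 2), _met("F6P", 6, 2), _met("FBP", 6, 2),
        _met("DHAP", 3, 1), _met("GAP", 3, 2),
        _met("NADH", 0, 1),
        _met("BPG", 3, 1), _met("3PG", 3, 1),
        _met("PEP", 3), _met("PYR", 3), _met("ACA", 2), _met("CO2", 1),
        _met("WATER", 0, 1, bal=0), _met("HX", 0, 1, bal=0),
        _met("CO2.unl", 1, bal=0), _met("PYR.unl", 3, bal=0),
    ]
    rxns = [
        _rx("glk", f"{GLUCOSE} (abcdefgh)", "G6P (abcdefgh)",
            role="transport"),
        _rx("pgi", "G6P (abcdefgh)", "F6P (abcdefgh)", rev=1),
        _rx("pfk", "F6P (abcdefgh)", "FBP (abcdefgh)", rev=1),
        _rx("fba", "FBP (abcdefgh) + WATER (i)", "DHAP (cbai) + GAP (defgh)",
            rev=1),
        _rx("tpi", "GAP (abcde)", "DHAP (abcd) + WATER (e)", rev=1),
        _rx("gapdh", "GAP (abcde)", "BPG (abce) + NADH (d)", rev=1),
        _rx("pgk", "BPG (abcd)", "3PG (abcd)", rev=1),
        _rx("eno", "3PG (abcd)", "PEP (abc) + WATER (d)", rev=1),
        _rx("pfor", "PYR (abc)", "ACA (bc) + CO2 (a)", rev=1),
        _rx("adh", "ACA (ab) + NADH (c) + NADH (d)", "-", role="transport"),
        _rx("ack", "ACA (ab)", "-", role="transport"),
        _rx("co2_out", "CO2 (a)", "-", role="transport"),
        _rx("co2_dil", "CO2.unl (a)", "CO2 (a)", rev=1, role="dilution"),
        _rx("pyr_dil", "PYR.unl (abc)", "PYR (abc)", ub=50.0,
            role="dilution"),
        _rx("nadh_in", "HX (a)", "NADH (a)"),
        _rx("nadh_ox", "NADH (a)", "-"),
    ]
    if variant == "tsac":
        rxns.append(_rx("pyk", "PEP (abc)", "PYR (abc)"))
    elif variant == "cthe":
        rxns.append(_rx("ppdk", "PEP (abc)", "PYR (abc)", rev=1))
        mets += [_met("OAA", 4), _met("MAL", 4)]
        rxns += [
            _rx("pepck", "PEP (abc) + CO2 (d)", "OAA (abcd)", rev=1),
            _rx("mdh", "OAA (abcd)", "MAL (abcd)", rev=1),
        ]
        if malic_enzyme:
            rxns.append(_rx("me", "MAL (abcd)", "PYR (abc) + CO2 (d)", rev=1))
        else:
            # without malic enzyme the shunt ends in a biomass drain
            rxns.append(_rx("mal_sink", "MAL (abcd)", "-", ub=20.0,
                            role="biomass"))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return mets + rxns


def glycolysis_core(variant: str = "tsac",
                    malic_enzyme: bool = True) -> NetworkModel:
    """~20-reaction glycolysis-to-ethanol core with 13C + 2H atom maps."""
    text = "\n".join(_core_lines(variant, malic_enzyme))
    return parse_model(text, name=f"glycolysis-core-{variant}",
                       variant=variant if variant != "cthe"
                       else ("cthe+me" if malic_enzyme else "cthe-me"))


# ---------------------------------------------------------------------------
# full-size fixtures (validation / forward predictions)

def _ppp_tca_lines(ile_route: str) -> list[str]:
    mets = [
        _met("X5P", 5), _met("RU5P", 5), _met("R5P", 5), _met("E4P", 4),
        _met("S7P", 7), _met("SBP", 7),
        _met("OAA", 4), _met("MAL", 4),
        _met("FUM", 4, sym=1), _met("SUCC", 4, sym=1), _met("AKG", 5),
        _met("THR", 4), _met("OB2", 4), _met("ILE", 6),
    ]
    rxns = [
        # non-oxidative PPP; hydrogens of F6P/GAP ride to GAP where the
        # carbon skeleton allows and fall into water otherwise
        _rx("tkt1", "F6P (abcdefgh) + GAP (ijklm)",
            "X5P (abijk) + E4P (cdef) + WATER (g) + WATER (h)"
            " + WATER (l) + WATER (m)", rev=1),
        _rx("tal", "F6P (abcdefgh) + E4P (ijkl)",
            "S7P (abcijkl) + GAP (defgh)", rev=1),
        _rx("tkt2", "S7P (abcdefg) + GAP (hijkl)",
            "R5P (cdefg) + X5P (abhij) + WATER (k) + WATER (l)", rev=1),
        _rx("rpe", "X5P (abcde)", "RU5P (abcde)", rev=1),
        _rx("rpi", "RU5P (abcde)", "R5P (abcde)", rev=1),
        _rx("sba", "DHAP (abcd) + E4P (efgh)",
            "SBP (cbaefgh) + WATER (d)", rev=1),
        _rx("sbpase", "SBP (abcdefg)", "S7P (abcdefg)"),
        _rx("r5p_sink", "R5P (abcde)", "-", ub=20.0, role="biomass"),
        # bifurcated TCA: oxidative arm to AKG, reductive arm to succinate
        _rx("pepck", "PEP (abc) + CO2 (d)", "OAA (abcd)", rev=1),
        _rx("mdh", "OAA (abcd)", "MAL (abcd)", rev=1),
        _rx("fumh", "MAL (abcd)", "FUM (abcd)", rev=1),
        _rx("fumr", "FUM (abcd)", "SUCC (abcd)"),
        _rx("succ_sink", "SUCC (abcd)", "-", ub=20.0, role="biomass"),
        _rx("csakg", "OAA (abcd) + ACA (ef)", "AKG (bcdef) + CO2 (a)"),
        _rx("akg_sink", "AKG (abcde)", "-", ub=20.0, role="biomass"),
        # oxaloacetate-family amino acids (lumped to threonine)
        _rx("thrs", "OAA (abcd)", "THR (abcd)"),
        _rx("thr_sink", "THR (abcd)", "-", ub=20.0, role="biomass"),
        _rx("ils", "OB2 (abcd) + PYR (efg)", "ILE (abcdfg) + CO2 (e)"),
        _rx("ile_sink", "ILE (abcdef)", "-", ub=20.0, role="biomass"),
    ]
    if ile_route == "citramalate":
        rxns.append(_rx("cms", "PYR (abc) + ACA (de)",
                        "OB2 (debc) + CO2 (a)"))
    elif ile_route == "threonine":
        rxns.append(_rx("tda", "THR (abcd)", "OB2 (abcd)"))
    else:
        raise ValueError(f"unknown isoleucine route {ile_route!r}")
    return mets + rxns


def t_saccharolyticum_like(ed: bool = False, oxppp: bool = False,
                           sbp_bypass: bool = True,
                           ile_route: str = "citramalate") -> NetworkModel:
    """T. saccharolyticum-style network: ATP-Pfk, Pyk, bifurcated TCA."""
    lines = _core_lines("tsac", malic_enzyme=False)
    lines += _ppp_tca_lines(ile_route)
    if ed:
        lines.append(_rx("ed", "G6P (abcdefgh)",
                         "PYR (abc) + GAP (defgh)"))
    if oxppp:
        lines.append(_rx("oxppp", "G6P (abcdefgh)",
                         "RU5P (bcdef) + CO2 (a)"))
    if not sbp_bypass:
        lines = [ln for ln in lines
                 if not ln.startswith(("sba\t", "sbpase\t"))
                 and "@met SBP " not in ln]
    variant = "+".join(["tsac"] + (["ed"] if ed else [])
                       + (["oxppp"] if oxppp else [])
                       + ([] if sbp_bypass else ["nosbp"]) + [ile_route])
    return parse_model("\n".join(lines), name="t-saccharolyticum-like",
                       variant=variant)


def c_thermocellum_like(malic_enzyme: bool = False,
                        ile_route: str = "citramalate") -> NetworkModel:
    """C. thermocellum-style network: PPi-Pfk, Ppdk + malate shunt, no Pyk."""
    lines = _core_lines("cthe", malic_enzyme=malic_enzyme)
    # the core's cthe branch already carries pepck/mdh(/me); the PPP/TCA
    # block re-declares them, so drop duplicates from the block
    block = [ln for ln in _ppp_tca_lines(ile_route)
             if not ln.startswith(("pepck\t", "mdh\t"))
             and "@met OAA " not in ln and "@met MAL " not in ln]
    lines += block
    return parse_model("\n".join(lines), name="c-thermocellum-like",
                       variant="cthe" + ("+me" if malic_enzyme else "-me"))


# ---------------------------------------------------------------------------
# small teaching/verification models (13C only)

def emp_only() -> NetworkModel:
    """Hexose-bisphosphate (EMP) glycolysis, carbons only."""
    text = "\n".join([
        _met(GLUCOSE, 6, bal=0),
        _met("G6P", 6), _met("F6P", 6), _met("FBP", 6),
        _met("DHAP", 3), _met("GAP", 3), _met("3PG", 3), _met("PEP", 3),
        _met("PYR", 3),
        _rx("glk", f"{GLUCOSE} (abcdef)", "G6P (abcdef)", lb=100.0,
            ub=100.0, role="transport"),
        _rx("pgi", "G6P (abcdef)", "F6P (abcdef)", rev=1),
        _rx("pfk", "F6P (abcdef)", "FBP (abcdef)", rev=1),
        _rx("fba", "FBP (abcdef)", "DHAP (cba) + GAP (def)", rev=1),
        _rx("tpi", "DHAP (abc)", "GAP (abc)", rev=1),
        _rx("gly", "GAP (abc)", "3PG (abc)", rev=1),
        _rx("eno", "3PG (abc)", "PEP (abc)", rev=1),
        _rx("pyk", "PEP (abc)", "PYR (abc)"),
        _rx("pyr_out", "PYR (abc)", "-", role="transport"),
    ])
    return parse_model(text, name="emp-only", variant="emp")


def ed_only() -> NetworkModel:
    """2-keto-3-deoxy-6-phosphogluconate (ED) glycolysis, carbons only.

    Glucose C1-C3 leave as pyruvate directly (C1 becomes the carboxyl),
    C4-C6 pass through GAP and lower glycolysis.
    """
    text = "\n".join([
        _met(GLUCOSE, 6, bal=0),
        _met("G6P", 6), _met("GAP", 3), _met("3PG", 3), _met("PEP", 3),
        _met("PYR", 3),
        _rx("glk", f"{GLUCOSE} (abcdef)", "G6P (abcdef)", lb=100.0,
            ub=100.0, role="transport"),
        _rx("ed", "G6P (abcdef)", "PYR (abc) + GAP (def)"),
        _rx("gly", "GAP (abc)", "3PG (abc)", rev=1),
        _rx("eno", "3PG (abc)", "PEP (abc)", rev=1),
        _rx("pyk", "PEP (abc)", "PYR (abc)"),
        _rx("pyr_out", "PYR (abc)", "-", role="transport"),
    ])
    return parse_model(text, name="ed-only", variant="ed")


def emp_ed_mixture() -> NetworkModel:
    """Both glycolytic routes; route fluxes set the 3PG pool contributions."""
    text = "\n".join([
        _met(GLUCOSE, 6, bal=0),
        _met("G6P", 6), _met("F6P", 6), _met("FBP", 6),
        _met("DHAP", 3), _met("GAP", 3), _met("3PG", 3), _met("PEP", 3),
        _met("PYR", 3),
        _rx("glk", f"{GLUCOSE} (abcdef)", "G6P (abcdef)", lb=100.0,
            ub=100.0, role="transport"),
        _rx("pgi", "G6P (abcdef)", "F6P (abcdef)", rev=1),
        _rx("pfk", "F6P (abcdef)", "FBP (abcdef)", rev=1),
        _rx("fba", "FBP (abcdef)", "DHAP (cba) + GAP (def)", rev=1),
        _rx("tpi", "DHAP (abc)", "GAP (abc)", rev=1),
        _rx("ed", "G6P (abcdef)", "PYR (abc) + GAP (def)"),
        _rx("gly", "GAP (abc)", "3PG (abc)", rev=1),
        _rx("eno", "3PG (abc)", "PEP (abc)", rev=1),
        _rx("pyk", "PEP (abc)", "PYR (abc)"),
        _rx("pyr_out", "PYR (abc)", "-", role="transport"),
    ])
    return parse_model(text, name="emp-ed-mixture", variant="emp+ed")


def fba_tpi_toy() -> NetworkModel:
    """Hexose cleavage toy: FBP aldolase + triose isomerase exchange."""
    text = "\n".join([
        _met(GLUCOSE, 6, bal=0),
        _met("FBP", 6), _met("DHAP", 3), _met("GAP", 3),
        _rx("upt", f"{GLUCOSE} (abcdef)", "FBP (abcdef)", lb=100.0,
            ub=100.0, role="transport"),
        _rx("fba", "FBP (abcdef)", "DHAP (cba) + GAP (def)", rev=1),
        _rx("tpi", "DHAP (abc)", "GAP (abc)", rev=1),
        _rx("gap_out", "GAP (abc)", "-", role="transport"),
    ])
    return parse_model(text, name="fba-tpi-toy", variant="toy")


ALL_VARIANTS = {
    "emp-only": emp_only,
    "ed-only": ed_only,
    "emp+ed": emp_ed_mixture,
    "tsac-core": lambda: glycolysis_core("tsac"),
    "cthe-core+me": lambda: glycolysis_core("cthe", malic_enzyme=True),
    "cthe-core-me": lambda: glycolysis_core("cthe", malic_enzyme=False),
    "tsac-full": t_saccharolyticum_like,
    "tsac-full+ed": lambda: t_saccharolyticum_like(ed=True),
    "tsac-full+oxppp": lambda: t_saccharolyticum_like(oxppp=True),
    "tsac-full-nosbp": lambda: t_saccharolyticum_like(sbp_bypass=False),
    "tsac-full-thr": lambda: t_saccharolyticum_like(ile_route="threonine"),
    "cthe-full-me": c_thermocellum_like,
    "cthe-full+me": lambda: c_thermocellum_like(malic_enzyme=True),
    "fba-tpi-toy": fba_tpi_toy,
}


# ---------------------------------------------------------------------------
# tracers

TRACER_NAMES = ("1-13C1", "6-13C1", "1,2-13C2", "U-13C6", "U-13C6/unlabeled",
                "4-2H1", "5-2H1")


def glucose_tracer(model: NetworkModel, name: str,
                   purity: float = 1.0) -> TracerSpec:
    """Tracer spec for the fixtures' glucose atom layout (C1..C6, H4, H5)."""
    glc = model.metabolites[GLUCOSE]
    carbons = tuple(range(glc.n_carbons))
    if name == "1-13C1":
        patterns = (((0,), 1.0),)
    elif name == "6-13C1":
        patterns = (((5,), 1.0),)
    elif name == "1,2-13C2":
        patterns = (((0, 1), 1.0),)
    elif name == "U-13C6":
        patterns = ((carbons, 1.0),)
    elif name == "U-13C6/unlabeled":
        patterns = ((carbons, 0.5), ((), 0.5))
    elif name in ("4-2H1", "5-2H1"):
        if glc.n_hydrogens < 2:
            raise ValueError(f"model {model.name} does not track glucose "
                             "hydrogens; 2H tracers unavailable")
        patterns = (((6 if name == "4-2H1" else 7,), 1.0),)
    else:
        raise ValueError(f"unknown tracer {name!r}; choose from {TRACER_NAMES}")
    return TracerSpec(GLUCOSE, patterns, purity=purity)


#: the five-tracer panel used throughout for integrated 13C/2H fitting
FIVE_TRACER_PANEL = ("1-13C1", "6-13C1", "4-2H1", "5-2H1", "U-13C6/unlabeled")
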