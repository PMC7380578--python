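"""Plain-text file formats: MID tables, flux/thermo reports, run configs.

Everything is TSV/CSV/JSON/YAML; the model-file dialect lives in
:mod:`fluxtherm.network`.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emu import EMUNode, MIDVector, TracerSpec
from .fluxfit import Dataset, FitResult, FluxState, TracerData
from .network import NetworkModel
from .thermo import DeltaGEstimate

MID_COLUMNS = ["metabolite", "fragment_formula", "mass_shift", "fraction",
               "sd", "tracer_id", "replicate"]


# ---------------------------------------------------------------------------
# MID tables (measured-data shape)

def write_mid_table(path, data: Dataset) -> None:
    rows = []
    for tid, td in data.tracers.items():
        for met, mid in td.mids.items():
            for k, f in enumerate(mid.fractions):
                rows.append({
                    "metabolite": met, "fragment_formula": "",
                    "mass_shift": k, "fraction": f,
                    "sd": (mid.sd[k] if mid.sd is not None else math.nan),
                    "tracer_id": tid, "replicate": 1,
                })
    pd.DataFrame(rows, columns=MID_COLUMNS).to_csv(path, index=False)


def read_mid_table(path, tracers: dict[str, TracerSpec]) -> Dataset:
    """Load a MID CSV; ``tracers`` maps tracer_id to its TracerSpec."""
    df = pd.read_csv(path)
    missing = set(df["tracer_id"].unique()) - set(tracers)
    if missing:
        raise ValueError(f"no tracer spec for tracer_id(s) {sorted(missing)}")
    out: dict[str, TracerData] = {}
    for tid, sub in df.groupby("tracer_id"):
        mids = {}
        for met, grp in sub.groupby("metabolite"):
            grp = grp.sort_values("mass_shift")
            mids[met] = MIDVector(met, grp["fraction"].to_numpy(),
                                  sd=grp["sd"].to_numpy())
        out[tid] = TracerData(tracers[tid], mids)
    return Dataset(out)


def write_rates(path, rates: dict[str, tuple[float, float]]) -> None:
    pd.DataFrame([{"reaction": r, "value": v, "sd": s}
                  for r, (v, s) in rates.items()]).to_csv(
        path, sep="\t", index=False)


def read_rates(path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path, sep="\t")
    return {row.reaction: (float(row.value), float(row.sd))
            for row in df.itertuples()}


# ---------------------------------------------------------------------------
# simulated-MID long form

def write_mids_long(path, mids: dict[EMUNode, MIDVector]) -> None:
    lines = ["fragment\tmass_shift\tfraction"]
    for emu in sorted(mids, key=lambda e: (e.met, e.atoms)):
        for k, f in enumerate(mids[emu].fractions):
            lines.append(f"{emu.label()}\t{k}\t{f:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fit / thermo reports

def write_flux_table(path, model: NetworkModel, fit: FitResult) -> None:
    rows = []
    for i, r in enumerate(model.reactions):
        iv_net = fit.intervals.get((r.id, "net"))
        iv_exch = fit.intervals.get((r.id, "exch"))
        rows.append({
            "reaction": r.id,
            "net": fit.fluxes.net[i],
            "exch": fit.fluxes.exchange[i],
            "net_lb": iv_net.lb if iv_net else math.nan,
            "net_ub": iv_net.ub if iv_net else math.nan,
            "exch_lb": iv_exch.lb if iv_exch else math.nan,
            "exch_ub": iv_exch.ub if iv_exch else math.nan,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def write_fit_summary(path, fit: FitResult, seed=None) -> None:
    payload = {
        "ssr": fit.ssr, "n": fit.n, "p": fit.p,
        "chi2_lower": fit.chi2_range[0], "chi2_upper": fit.chi2_range[1],
        "accepted": fit.accepted,
        "restart_ssrs": fit.restart_ssrs,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_thermo_table(path, estimates: list[DeltaGEstimate]) -> None:
    rows = []
    for e in estimates:
        flags = ";".join(f for f, on in
                         [("unbounded_low", e.unbounded_low),
                          ("unbounded_high", e.unbounded_high)] if on)
        rows.append({"reaction": e.reaction, "best": e.best,
                     "lb": e.lb, "ub": e.ub, "method": e.method,
                     "flags": flags})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.4f")


# ---------------------------------------------------------------------------
# run configuration

def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path}: expected a mapping")
    return cfg
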