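"""Flux estimation from multi-tracer MID data.

Fluxes are estimated by variance-weighted nonlinear least squares against
the measured mass-isotopomer fractions of all tracer experiments plus the
measured extracellular rates, with the steady-state constraint S*v = 0
eliminated analytically:

* net fluxes live in an affine space ``v = v_p + N u`` where N spans the
  null space of the stoichiometric matrix after pinning reactions whose
  bounds force a single value;
* each reversible reaction carries one exchange parameter x in [0, 1)
  mapped through ``J_exch = c x / (1 - x)`` (c = 100 flux units), which
  compresses the physically unbounded exchange axis into a box;
* inequality bounds on net fluxes enter as hinge penalty residuals.

The optimum of the weighted SSR is chi-square distributed with n - p
degrees of freedom when the model is correct (n fitted measurements, p free
parameters), which gives the acceptance test; per-flux confidence bounds
come from parameter continuation: a flux is stepped away from its optimum,
the remaining parameters re-optimized, until the SSR exceeds the optimum by
the chi-square(1 df) critical value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import null_space
from scipy.optimize import least_squares

from .emu import EMUNode, MIDVector, TracerSpec, metabolite_emu, simulate_mids
from .network import NetworkModel, build_stoichiometry

EXCHANGE_SCALE = 100.0
X_MAX = 1.0 - 1e-4      # caps J_exch at ~1e6 flux units for conditioning
PENALTY_SCALE = 1e-2


class FitError(RuntimeError):
    pass


@dataclass
class FluxState:
    """Forward/backward fluxes per reaction, in mol per 100 mol glucose."""

    reactions: tuple[str, ...]
    j_plus: np.ndarray
    j_minus: np.ndarray

    def __post_init__(self):
        self.j_plus = np.asarray(self.j_plus, dtype=float)
        self.j_minus = np.asarray(self.j_minus, dtype=float)
        if np.any(self.j_plus < -1e-9) or np.any(self.j_minus < -1e-9):
            raise ValueError("directional fluxes must be non-negative")

    @property
    def net(self) -> np.ndarray:
        return self.j_plus - self.j_minus

    @property
    def exchange(self) -> np.ndarray:
        return np.minimum(self.j_plus, self.j_minus)

    def __getitem__(self, rid: str) -> tuple[float, float]:
        i = self.reactions.index(rid)
        return float(self.j_plus[i]), float(self.j_minus[i])

    @classmethod
    def from_net_exchange(cls, model: NetworkModel, net, exchange) -> "FluxState":
        net = np.asarray(net, dtype=float)
        exch = np.asarray(exchange, dtype=float)
        jp = np.maximum(net, 0.0) + exch
        jm = np.maximum(-net, 0.0) + exch
        return cls(tuple(model.reaction_ids), jp, jm)


@dataclass
class TracerData:
    tracer: TracerSpec
    mids: dict[str, MIDVector]          # metabolite id -> measured MID (+sd)


@dataclass
class Dataset:
    tracers: dict[str, TracerData]
    rates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def n_measurements(self) -> int:
        n = sum(int(np.count_nonzero(td.mids[m].fractions))
                for td in self.tracers.values() for m in td.mids)
        return n + len(self.rates)


@dataclass
class FitResult:
    fluxes: FluxState
    ssr: float
    n: int
    p: int
    chi2_range: tuple[float, float]
    accepted: bool
    restart_ssrs: list[float]
    theta: np.ndarray = field(repr=False, default=None)
    intervals: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# parameterization

class FluxParameterization:
    """Maps a free-parameter vector theta to a FluxState.

    theta = [u (net null-space coordinates), x (exchange transforms)].
    """

    def __init__(self, model: NetworkModel):
        self.model = model
        S, self.met_order = build_stoichiometry(model)
        nrxn = len(model.reactions)
        lb = np.array([r.lb for r in model.reactions])
        ub = np.array([r.ub for r in model.reactions])
        pinned = np.isclose(lb, ub)
        free = ~pinned
        v_pin = np.where(pinned, lb, 0.0)
        S_free = S[:, free]
        rhs = -S @ v_pin
        # particular solution on the free columns
        v_free, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
        if np.linalg.norm(S_free @ v_free - rhs) > 1e-6:
            raise FitError("pinned bounds are inconsistent with steady state")
        N_free = null_space(S_free)
        self.v_particular = v_pin.copy()
        self.v_particular[free] = v_free
        self.N = np.zeros((nrxn, N_free.shape[1]))
        self.N[free] = N_free
        self.n_net = N_free.shape[1]
        self.exch_idx = [i for i, r in enumerate(model.reactions) if r.reversible]
        self.n_exch = len(self.exch_idx)
        self.n_params = self.n_net + self.n_exch
        self.lb, self.ub, self.pinned = lb, ub, pinned

    def net_fluxes(self, theta: np.ndarray) -> np.ndarray:
        return self.v_particular + self.N @ theta[:self.n_net]

    def flux_state(self, theta: np.ndarray) -> FluxState:
        net = self.net_fluxes(theta)
        exch = np.zeros(len(self.model.reactions))
        x = np.clip(theta[self.n_net:], 0.0, X_MAX)
        exch[self.exch_idx] = EXCHANGE_SCALE * x / (1.0 - x)
        return FluxState.from_net_exchange(self.model, net, exch)

    def bound_violations(self, theta: np.ndarray) -> np.ndarray:
        net = self.net_fluxes(theta)
        return np.concatenate([np.maximum(self.lb - net, 0.0),
                               np.maximum(net - self.ub, 0.0)])

    def theta_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.concatenate([np.full(self.n_net, -np.inf),
                             np.zeros(self.n_exch)])
        hi = np.concatenate([np.full(self.n_net, np.inf),
                             np.full(self.n_exch, X_MAX)])
        return lo, hi

    def project_fluxes(self, fluxes: FluxState) -> np.ndarray:
        """theta whose FluxState best reproduces the given fluxes."""
        u, *_ = np.linalg.lstsq(self.N, fluxes.net - self.v_particular,
                                rcond=None)
        e = fluxes.exchange[self.exch_idx]
        x = e / (EXCHANGE_SCALE + e)
        return np.concatenate([u, x])


# ---------------------------------------------------------------------------
# residuals and SSR

def residuals(model: NetworkModel, fluxes: FluxState, data: Dataset,
              p13: float = 0.0) -> np.ndarray:
    """Variance-weighted residuals over non-zero MID fractions and rates."""
    res: list[float] = []
    for td in data.tracers.values():
        targets = [metabolite_emu(model, m) for m in td.mids]
        sim = simulate_mids(model, fluxes, td.tracer, targets, p13=p13)
        for met, meas in td.mids.items():
            if meas.sd is None:
                raise FitError(f"measured MID for {met} lacks SDs")
            simv = sim[metabolite_emu(model, met)].fractions
            for k, (y, s) in enumerate(zip(meas.fractions, meas.sd)):
                if y == 0.0:
                    continue
                if s <= 0:
                    raise FitError(f"non-positive SD for {met} M+{k}")
                res.append((simv[k] - y) / s)
    net = fluxes.net
    rindex = {r: i for i, r in enumerate(fluxes.reactions)}
    for rid, (val, sd) in data.rates.items():
        if sd <= 0:
            raise FitError(f"non-positive SD for rate {rid}")
        res.append((net[rindex[rid]] - val) / sd)
    return np.asarray(res)


def compute_ssr(model: NetworkModel, fluxes: FluxState, data: Dataset,
                p13: float = 0.0) -> float:
    """Variance-weighted sum of squared residuals."""
    r = residuals(model, fluxes, data, p13=p13)
    return float(r @ r)


def chi2_acceptance(ssr: float, n: int, p: int, alpha: float = 0.05
                    ) -> tuple[float, float, bool]:
    """Acceptance range [chi2_{a/2}(n-p), chi2_{1-a/2}(n-p)] and verdict."""
    if n <= p:
        raise FitError(f"degrees of freedom n - p = {n - p} <= 0")
    df = n - p
    lo = float(stats.chi2.ppf(alpha / 2, df))
    hi = float(stats.chi2.ppf(1 - alpha / 2, df))
    return lo, hi, bool(lo <= ssr <= hi)


# ---------------------------------------------------------------------------
# fitting

def _objective(par: FluxParameterization, data: Dataset, p13: float):
    model = par.model

    def fun(theta: np.ndarray) -> np.ndarray:
        fs = par.flux_state(theta)
        try:
            r = residuals(model, fs, data, p13=p13)
        except Exception:
            # infeasible EMU system (e.g. zero total inflow): large residual
            r = np.full(data.n_measurements(), 1e3)
        pen = par.bound_violations(theta) / PENALTY_SCALE
        return np.concatenate([r, pen])

    return fun


def fit_fluxes(model: NetworkModel, data: Dataset, restarts: int = 25,
               seed: int | None = None, p13: float = 0.0,
               alpha: float = 0.05, u_range: float = 100.0,
               x_max: float = 0.95, max_nfev: int | None = None) -> FitResult:
    """Best-of-restarts weighted least-squares flux fit.

    Deterministic given ``seed``: restart initial points are drawn from a
    seeded generator, uniformly in the transformed parameter box.
    """
    par = FluxParameterization(model)
    fun = _objective(par, data, p13)
    lo, hi = par.theta_bounds()
    if max_nfev is None:
        # trf's nfev excludes finite-difference Jacobian columns, so this
        # effectively caps the iteration count; flat-direction wanderers
        # are cut off (best-of-restarts keeps the converged ones)
        max_nfev = max(100, 12 * par.n_params)
    rng = np.random.default_rng(seed)
    best = None
    restart_ssrs: list[float] = []
    for k in range(restarts):
        u0 = rng.uniform(-u_range, u_range, par.n_net)
        x0 = rng.uniform(0.0, x_max, par.n_exch)
        theta0 = np.concatenate([u0, x0])
        try:
            sol = least_squares(fun, theta0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-10,
                                max_nfev=max_nfev)
        except Exception:
            restart_ssrs.append(float("inf"))
            continue
        fs = par.flux_state(sol.x)
        try:
            ssr = compute_ssr(model, fs, data, p13=p13)
        except Exception:
            restart_ssrs.append(float("inf"))
            continue
        if np.any(par.bound_violations(sol.x) > 1e-4):
            ssr += float(np.sum((par.bound_violations(sol.x) / PENALTY_SCALE) ** 2))
        restart_ssrs.append(ssr)
        if best is None or ssr < best[0]:
            best = (ssr, sol.x)
    if best is None:
        raise FitError("no restart produced a feasible solution")
    ssr, theta = best
    n = data.n_measurements()
    p = par.n_params
    if n > p:
        lo_c, hi_c, ok = chi2_acceptance(ssr, n, p, alpha)
    else:       # under-determined problem: no goodness-of-fit statement
        lo_c, hi_c, ok = float("nan"), float("nan"), False
    return FitResult(par.flux_state(theta), ssr, n, p, (lo_c, hi_c), ok,
                     restart_ssrs, theta=theta)


# ---------------------------------------------------------------------------
# confidence intervals by parameter continuation

@dataclass
class FluxInterval:
    lb: float
    ub: float
    lb_determined: bool = True
    ub_determined: bool = True
    at_lower_bound: bool = False
    at_upper_bound: bool = False


def _profile_ssr(par, data, p13, fix):
    """SSR re-optimized with one quantity fixed.

    ``fix`` = ("net", rxn_index, value) or ("exch", rxn_index, value).
    Returns (ssr, warm-start vector for the reduced problem).
    """
    kind, ridx, value = fix
    model = par.model
    if kind == "exch":
        xpos = par.n_net + par.exch_idx.index(ridx)
        keep = [i for i in range(par.n_params) if i != xpos]
        xval = min(value / (EXCHANGE_SCALE + value), X_MAX)

        def expand(red):
            theta = np.empty(par.n_params)
            theta[keep] = red
            theta[xpos] = xval
            return theta
    else:
        # net flux of reaction ridx is v_p[ridx] + N[ridx] @ u = value:
        # reparameterize u = u0 + K w on the constraint hyperplane
        row = par.N[ridx]
        if np.linalg.norm(row) < 1e-12:
            return None, None            # flux not free: cannot continue
        u0 = row * (value - par.v_particular[ridx]) / (row @ row)
        K = null_space(row.reshape(1, -1))

        def expand(red):
            w, x = red[:K.shape[1]], red[K.shape[1]:]
            return np.concatenate([u0 + K @ w, x])

    base = _objective(par, data, p13)

    def fun(red):
        return base(expand(red))

    def solve(red0):
        if kind == "exch":
            lo = np.array([0.0 if i >= par.n_net else -np.inf for i in keep])
            hi = np.array([X_MAX if i >= par.n_net else np.inf for i in keep])
        else:
            nb = par.n_params - par.n_net
            lo = np.concatenate([np.full(len(red0) - nb, -np.inf), np.zeros(nb)])
            hi = np.concatenate([np.full(len(red0) - nb, np.inf),
                                 np.full(nb, X_MAX)])
        if len(red0) == 0:
            fs = par.flux_state(expand(np.empty(0)))
            return compute_ssr(par.model, fs, data, p13=p13), red0
        sol = least_squares(fun, np.clip(red0, lo, hi), bounds=(lo, hi),
                            method="trf", xtol=1e-10, ftol=1e-9,
                            max_nfev=600)
        fs = par.flux_state(expand(sol.x))
        try:
            ssr = compute_ssr(par.model, fs, data, p13=p13)
        except Exception:
            return float("inf"), sol.x
        if np.any(par.bound_violations(expand(sol.x)) > 1e-4):
            ssr += float(np.sum(
                (par.bound_violations(expand(sol.x)) / PENALTY_SCALE) ** 2))
        return ssr, sol.x

    def reduce(theta):
        if kind == "exch":
            return theta[keep]
        u, x = theta[:par.n_net], theta[par.n_net:]
        w, *_ = np.linalg.lstsq(K, u - u0, rcond=None)
        return np.concatenate([w, x])

    return solve, reduce


def confidence_intervals(model: NetworkModel, data: Dataset, fit: FitResult,
                         alpha: float = 0.05, p13: float = 0.0,
                         which: list[tuple[str, str]] | None = None,
                         max_hi: float = 1e4) -> dict[tuple[str, str], FluxInterval]:
    """95% (by default) profile-likelihood bounds per flux.

    ``which`` lists (reaction id, "net"|"exch") pairs; default every
    reaction's net flux plus every reversible reaction's exchange flux.
    Bounds where the continuation hits the search limit without crossing the
    SSR threshold are flagged undetermined/unbounded rather than clipped.
    """
    par = FluxParameterization(model)
    crit = fit.ssr + float(stats.chi2.ppf(1 - alpha, 1))
    theta_best = fit.theta
    fs_best = par.flux_state(theta_best)
    if which is None:
        which = [(r.id, "net") for r in model.reactions]
        which += [(r.id, "exch") for r in model.reactions if r.reversible]

    out: dict[tuple[str, str], FluxInterval] = {}
    for rid, kind in which:
        ridx = model.reaction_index(rid)
        best_val = (fs_best.net[ridx] if kind == "net"
                    else fs_best.exchange[ridx])
        lo_lim = (model.reactions[ridx].lb if kind == "net" else 0.0)
        hi_lim = (model.reactions[ridx].ub if kind == "net" else max_hi)
        lo_lim = max(lo_lim, -max_hi)
        hi_lim = min(hi_lim, max_hi)

        made = _profile_ssr(par, data, p13, (kind, ridx, best_val))
        if made[0] is None:
            out[(rid, kind)] = FluxInterval(lo_lim, hi_lim, False, False)
            continue

        def profile_at(value, warm):
            s, _ = _profile_ssr(par, data, p13, (kind, ridx, value))
            return s(warm)

        warm0 = made[1](theta_best)
        delta = float(stats.chi2.ppf(1 - alpha, 1))

        def search(direction):
            """Return (bound, determined, at_limit)."""
            limit = hi_lim if direction > 0 else lo_lim
            span = abs(limit - best_val)
            if span < 1e-9:
                return best_val, True, True
            # first step from a local curvature estimate of the profile
            d0 = min(max(0.02 * abs(best_val), 0.1), 0.5 * span)
            ssr_d, warm = profile_at(best_val + direction * d0, warm0)
            curv = max(ssr_d - fit.ssr, 1e-12) / d0 ** 2
            step = min(max(1.2 * np.sqrt(delta / curv), d0), span)
            inside, t = best_val, best_val
            for _ in range(14):
                t = t + direction * step
                if (direction > 0 and t >= limit) or (direction < 0 and t <= limit):
                    ssr_lim, warm = profile_at(limit, warm)
                    if ssr_lim <= crit:
                        return limit, True, True
                    t = limit
                    break
                ssr_t, warm = profile_at(t, warm)
                if ssr_t > crit:
                    break
                inside = t
                step *= 2.0
            else:
                return t, False, False
            # bisect between `inside` (SSR below) and `t` (SSR above)
            a, b = inside, t
            for _ in range(12):
                if abs(b - a) < max(1e-2, 5e-3 * abs(0.5 * (a + b))):
                    break
                mid = 0.5 * (a + b)
                ssr_m, warm = profile_at(mid, warm)
                if ssr_m > crit:
                    b = mid
                else:
                    a = mid
            return 0.5 * (a + b), True, False

        ub, ub_det, ub_at = search(+1)
        lb, lb_det, lb_at = search(-1)
        out[(rid, kind)] = FluxInterval(lb, ub, lb_det, ub_det,
                                        at_lower_bound=lb_at,
                                        at_upper_bound=ub_at)
    return out
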