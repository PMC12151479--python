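"""Pathway-controlled optimization (PCO) of growth.

PCO maximizes the summed thermodynamic odds differences of the growth
reactions over metabolite log concentrations and per-reaction enzyme
activity coefficients alpha in [0, 1], subject to steady state of every
variable metabolite, concentration bounds, and fixed boundary species:

    max   sum_{g in G} alpha_g (K_g/Q_g - Q_g/K_g)
    s.t.  dn_i/dt = 0            (variable i)
          0 <= n_i <= n_max_i    (variable i)
          n_i = n_bar_i          (fixed i)
          0 <= alpha_j <= 1      (all j)

The reaction flux entering the steady-state constraint is the activity-
scaled difference of forward and reverse transition probabilities,
``xi_j = alpha_j * 2 sinh(log(Kj/Qj) / Mb)``; the conditioning
hyperparameter Mb scales the reaction free energies inside the solver so
that the exponentials stay in a numerically benign, near-linear regime,
and is removed from all reported quantities.  The problem is non-convex;
the solver is a trust-region interior method (scipy ``trust-constr``)
initialized from the maximum-entropy state, which is the exact optimum
whenever no concentration bound is active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .maxent import InfeasibleSteadyStateError, maxent_state, steady_state_fluxes
from .model_core import MetabolicModel
from .thermo import DEFAULT_CONTEXT, RedoxCondition, ThermoContext, ratio_to_odds

__all__ = [
    "PcoHyperparams",
    "PcoSolution",
    "optimize",
    "retry_with_perturbed_redox",
    "objective_value",
    "apply_redox_condition",
]

_ALPHA_REG = 1e-6  # tie-break toward alpha = 1 (minimal regulation)


@dataclass
class PcoHyperparams:
    """Solver hyperparameters.

    ``var_m_lbound`` is the lower bound on natural-log concentrations
    (molar); ``mb_scale`` the free-energy conditioning factor; ``n_max``
    the default molar cap for variable metabolites without their own
    ``upper_bound``.
    """

    var_m_lbound: float = -300.0
    mb_scale: float = 1000.0
    n_max: float = 1.0
    feas_tol: float = 1e-8
    opt_tol: float = 1e-10
    max_iter: int = 2000
    seed: int = 0
    multistarts: int = 1
    retry_delta: float = 0.025  # relative NADP+/NADPH perturbation per retry
    max_retries: int = 4

    def __post_init__(self) -> None:
        if self.mb_scale <= 0:
            raise ValueError("mb_scale must be > 0")
        if self.var_m_lbound >= math.log(self.n_max):
            raise ValueError("var_m_lbound must be < log(n_max)")


@dataclass
class PcoSolution:
    concentrations: dict[str, float]  # variable metabolites, molar
    activities: dict[str, float]
    fluxes: dict[str, float]  # normalized to the carbon-uptake scale
    raw_fluxes: dict[str, float]  # alpha * 2 sinh(a/Mb), solver units
    objective: float  # sum over growth reactions of delta_pr
    success: bool
    status: str
    condition: RedoxCondition | None = None
    steady_state_residual: float = float("nan")
    bound_violation: float = 0.0
    message: str = ""
    model: MetabolicModel | None = field(default=None, repr=False)

    @property
    def failed(self) -> bool:
        return not self.success


def apply_redox_condition(
    model: MetabolicModel, condition: RedoxCondition
) -> MetabolicModel:
    """Return a model copy with the NADP+/NADPH boundary set to the condition.

    The metabolite ids of the redox pair are read from the model config
    (``nadp_id`` / ``nadph_id``); the reduced species keeps its configured
    concentration and the oxidized species is set to ratio * [NADPH].
    """
    try:
        nadp = model.config["nadp_id"]
        nadph = model.config["nadph_id"]
    except KeyError:
        raise KeyError(
            "model config must declare 'nadp_id' and 'nadph_id' to set a redox condition"
        ) from None
    new = model.copy()
    red = new.metabolite(nadph)
    ox = new.metabolite(nadp)
    if not (red.is_fixed and ox.is_fixed):
        raise ValueError("the NADP+/NADPH pair must be fixed boundary species")
    ox.fixed_concentration = condition.nadp_ratio * red.fixed_concentration
    return new


def _problem_arrays(model: MetabolicModel, ctx: ThermoContext):
    """Variable-row stoichiometry and fixed-part log-odds constants."""
    S_var, var_ids, rids = model.stoichiometric_matrix(rows="variable")
    fixed = model.fixed_concentrations()
    rxns = [model.reaction(rid) for rid in rids]
    c = np.empty(len(rids))
    for j, rxn in enumerate(rxns):
        val = math.log(rxn.effective_keq(ctx.rt))
        for mid, coef in rxn.stoichiometry.items():
            if mid in fixed:
                val -= coef * math.log(fixed[mid])
        c[j] = val
    growth = np.array([rxn.is_growth for rxn in rxns], dtype=bool)
    return S_var, var_ids, rids, c, growth


def _upper_log_bounds(model: MetabolicModel, var_ids: list[str], hp: PcoHyperparams):
    ub = np.empty(len(var_ids))
    for i, mid in enumerate(var_ids):
        met = model.metabolite(mid)
        ub[i] = math.log(met.upper_bound if met.upper_bound is not None else hp.n_max)
    return ub


def _clipped_exp(a: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(a, -500.0, 500.0))


def optimize(
    model: MetabolicModel,
    condition: RedoxCondition | None = None,
    init: "object | None" = None,
    hp: PcoHyperparams | None = None,
    ctx: ThermoContext = DEFAULT_CONTEXT,
) -> PcoSolution:
    """Solve the PCO problem for one redox condition.

    Returns a :class:`PcoSolution`; on non-convergence the solution object
    carries the best iterate with ``success=False`` rather than raising.
    Feasibility of a successful solution is asserted post hoc,
    independently of the solver's own bookkeeping.
    """
    from scipy.optimize import Bounds, NonlinearConstraint, minimize

    hp = hp or PcoHyperparams()
    work = apply_redox_condition(model, condition) if condition is not None else model

    # structural feasibility first: a steady state must exist at all
    try:
        base_fluxes = steady_state_fluxes(work)
    except (InfeasibleSteadyStateError, ValueError) as exc:
        return PcoSolution(
            concentrations={},
            activities={},
            fluxes={},
            raw_fluxes={},
            objective=float("nan"),
            success=False,
            status="infeasible",
            condition=condition,
            message=str(exc),
            model=work,
        )

    S_var, var_ids, rids, c_vec, growth = _problem_arrays(work, ctx)
    nv, nr = len(var_ids), len(rids)
    mb = hp.mb_scale
    ub = _upper_log_bounds(work, var_ids, hp)
    lb = np.full(nv, hp.var_m_lbound)

    def log_odds(x: np.ndarray) -> np.ndarray:
        return c_vec - S_var.T @ x

    def split(z: np.ndarray):
        return z[:nv], z[nv:]

    def raw_flux(x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        return alpha * 2.0 * np.sinh(np.clip(log_odds(x) / mb, -500, 500))

    def constraint_fun(z: np.ndarray) -> np.ndarray:
        x, alpha = split(z)
        return S_var @ raw_flux(x, alpha)

    def constraint_jac(z: np.ndarray) -> np.ndarray:
        x, alpha = split(z)
        a = np.clip(log_odds(x) / mb, -500, 500)
        s = 2.0 * np.sinh(a)
        dsdx = (2.0 * np.cosh(a) / mb)[:, None] * (-S_var.T)  # (nr, nv)
        J = np.empty((S_var.shape[0], nv + nr))
        J[:, :nv] = S_var @ (alpha[:, None] * dsdx)
        J[:, nv:] = S_var * s[None, :]
        return J

    # the solver maximizes the growth odds-difference under the same Mb
    # conditioning as the flux law (so objective == growth flux in solver
    # units); the reported objective is the unscaled Eq-17 sum at the optimum
    def neg_objective(z: np.ndarray) -> float:
        x, alpha = split(z)
        a = np.clip(log_odds(x) / mb, -500, 500)
        e = np.exp(a[growth])
        obj = float(np.sum(alpha[growth] * (e - 1.0 / e)))
        reg = _ALPHA_REG * float(np.sum((1.0 - alpha) ** 2))
        return -(obj - reg)

    def neg_objective_grad(z: np.ndarray) -> np.ndarray:
        x, alpha = split(z)
        a = np.clip(log_odds(x) / mb, -500, 500)
        e = np.exp(a[growth])
        g = np.zeros(nv + nr)
        # d/dalpha
        dalpha = np.zeros(nr)
        dalpha[growth] = e - 1.0 / e
        dalpha += 2.0 * _ALPHA_REG * (1.0 - alpha)
        g[nv:] = -dalpha
        # d/dx through the growth odds (cosh factor / Mb)
        w = alpha[growth] * (e + 1.0 / e) / mb
        g[:nv] = -((-S_var[:, growth]) @ w)
        return g

    # initial point: maximum-entropy state (paper workflow), alpha = 1
    if init is None:
        try:
            init = maxent_state(work, base_fluxes, ctx=ctx)
        except Exception:
            init = None
    x0 = np.zeros(nv)
    if init is not None:
        conc = getattr(init, "concentrations", init)
        for i, mid in enumerate(var_ids):
            v = conc.get(mid)
            if v is not None and v > 0:
                x0[i] = math.log(v)
    eps = 1e-9
    x0 = np.clip(x0, lb + eps, ub - eps)
    z0 = np.concatenate([x0, np.full(nr, 1.0 - eps)])

    bounds = Bounds(
        np.concatenate([lb, np.zeros(nr)]), np.concatenate([ub, np.ones(nr)])
    )
    nlc = NonlinearConstraint(constraint_fun, 0.0, 0.0, jac=constraint_jac)

    rng = np.random.default_rng(hp.seed)
    best = None
    for attempt in range(max(1, hp.multistarts)):
        z_start = z0.copy()
        if attempt > 0:
            z_start[:nv] = np.clip(
                z_start[:nv] + rng.normal(0, 1.0, nv), lb + eps, ub - eps
            )
        res = minimize(
            neg_objective,
            z_start,
            jac=neg_objective_grad,
            method="trust-constr",
            bounds=bounds,
            constraints=[nlc],
            options={
                "gtol": hp.opt_tol,
                "xtol": hp.opt_tol,
                "maxiter": hp.max_iter,
                "verbose": 0,
            },
        )
        if best is None or (-res.fun > -best.fun and res.constr_violation <= max(
            hp.feas_tol, best.constr_violation
        )):
            best = res
    res = best

    x_opt, alpha_opt = split(res.x)
    a = log_odds(x_opt)
    raw = raw_flux(x_opt, alpha_opt)

    # independent post-hoc feasibility check
    ss_residual = float(np.max(np.abs(S_var @ raw))) if nv else 0.0
    raw_scale = float(np.max(np.abs(raw))) if nr else 0.0
    feas_limit = hp.feas_tol * max(1.0, raw_scale)
    bound_violation = float(
        max(
            np.max(np.maximum(lb - x_opt, 0.0), initial=0.0),
            np.max(np.maximum(x_opt - ub, 0.0), initial=0.0),
            np.max(np.maximum(-alpha_opt, 0.0), initial=0.0),
            np.max(np.maximum(alpha_opt - 1.0, 0.0), initial=0.0),
        )
    )
    feasible = ss_residual <= feas_limit and bound_violation <= 1e-8
    converged = res.status in (1, 2) or (res.status == 0 and feasible)
    success = bool(feasible and converged)

    # unscaled objective, per the control law
    e = _clipped_exp(a[growth])
    objective = float(np.sum(alpha_opt[growth] * (e - 1.0 / e)))

    # normalize fluxes to the carbon-uptake scale
    S_all, mids, _ = work.stoichiometric_matrix(rows="all")
    fluxes = dict(zip(rids, raw))
    if work.carbon_source_id is not None:
        i_cs = mids.index(work.carbon_source_id)
        uptake = float(-(S_all[i_cs, :] @ raw))
        if abs(uptake) > 1e-300:
            # |uptake| preserves flux directions when the net carbon-source
            # exchange reverses (net production under strongly reductive
            # boundaries)
            factor = work.uptake_rate_scale / abs(uptake)
            fluxes = {rid: float(v * factor) for rid, v in zip(rids, raw)}

    return PcoSolution(
        concentrations={m: float(math.exp(v)) for m, v in zip(var_ids, x_opt)},
        activities={rid: float(v) for rid, v in zip(rids, alpha_opt)},
        fluxes=fluxes,
        raw_fluxes={rid: float(v) for rid, v in zip(rids, raw)},
        objective=objective,
        success=success,
        status="converged" if success else f"solver status {res.status}",
        condition=condition,
        steady_state_residual=ss_residual,
        bound_violation=bound_violation,
        message=str(res.message),
        model=work,
    )


def retry_with_perturbed_redox(
    model: MetabolicModel,
    condition: RedoxCondition,
    hp: PcoHyperparams | None = None,
    ctx: ThermoContext = DEFAULT_CONTEXT,
) -> PcoSolution:
    """Optimize, minimally perturbing the redox boundary on failure.

    On non-convergence the NADP+/NADPH boundary ratio is scaled by
    alternating factors (1 +/- k*delta); the first converging attempt is
    returned with its requested-versus-actual odds recorded in the
    condition.  If all retries fail, the last failure is propagated as a
    failure object.
    """
    hp = hp or PcoHyperparams()
    sol = optimize(model, condition, hp=hp, ctx=ctx)
    if sol.success:
        return sol
    last = sol
    for k in range(1, hp.max_retries + 1):
        step = (k + 1) // 2
        sign = 1 if k % 2 == 1 else -1
        ratio = condition.nadp_ratio * (1.0 + sign * step * hp.retry_delta)
        perturbed = RedoxCondition(
            target_odds=condition.target_odds,
            nadp_ratio=ratio,
            actual_odds=ratio_to_odds(ratio, ctx),
            ctx=ctx,
        )
        sol = optimize(model, perturbed, hp=hp, ctx=ctx)
        if sol.success:
            return sol
        last = sol
    return last


def objective_value(
    model: MetabolicModel,
    concentrations: dict[str, float],
    activities: dict[str, float] | None = None,
    ctx: ThermoContext = DEFAULT_CONTEXT,
) -> float:
    """Sum of delta_pr over the growth reactions at a given state.

    ``concentrations`` must cover the variable metabolites; fixed species
    default to their boundary values.  Activities default to 1.
    """
    from .maxent import delta_pr

    all_conc = {**model.fixed_concentrations(), **concentrations}
    total = 0.0
    for rxn in model.growth_reactions:
        alpha = 1.0 if activities is None else activities.get(rxn.id, 1.0)
        total += delta_pr(rxn, all_conc, activity=alpha, ctx=ctx)
    return total
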