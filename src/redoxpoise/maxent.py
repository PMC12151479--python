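"""Maximum-entropy steady states of mass-action networks.

Given a steady-state flux pattern (a null-space vector of the variable
rows of the stoichiometric matrix, scaled so the carbon-source uptake
equals the configured rate), the most likely concentrations are those at
which every net-flux-carrying reaction has the same log thermodynamic
odds in its flux direction,

    sign(xi_j) * log(Kj / Qj) = lambda        (xi_j != 0),

while zero-flux reactions sit at equilibrium.  This is the stationary-
action condition of the maximum-entropy steady state: the derivative of
the system entropy along any flux-carrying reaction's extent equals the
shared multiplier lambda.  Because log Q is linear in log
concentrations, the conditions form a linear system that is solved by
least squares, simultaneously yielding lambda.  Mass-action rate
parameters consistent with the state are back-computed afterwards (the
per-reaction timescale is fixed by the steady flux itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import MetabolicModel, Reaction
from .thermo import DEFAULT_CONTEXT, ThermoContext

__all__ = [
    "FluxPattern",
    "MaxEntSolution",
    "InfeasibleSteadyStateError",
    "steady_state_fluxes",
    "solve_lambda",
    "maxent_state",
    "delta_pr",
]

#: fluxes with |xi|/scale below this are treated as zero (Eq-12 branch)
ZERO_FLUX_TOL = 1e-12


class InfeasibleSteadyStateError(RuntimeError):
    """The variable-row stoichiometric matrix has a trivial null space."""


@dataclass
class FluxPattern:
    """A steady-state flux vector, normalized to the carbon-uptake scale."""

    fluxes: dict[str, float]
    scale: float = 1000.0

    def normalized(self) -> dict[str, float]:
        """Fluxes per unit uptake scale (dimensionless)."""
        return {rid: v / self.scale for rid, v in self.fluxes.items()}

    def nonzero(self, tol: float = ZERO_FLUX_TOL) -> dict[str, float]:
        return {rid: v for rid, v in self.fluxes.items() if abs(v) > tol * self.scale}


@dataclass
class MaxEntSolution:
    concentrations: dict[str, float]  # variable metabolites, molar
    lam: float
    odds: dict[str, float]  # K/Q per enabled reaction
    fluxes: FluxPattern
    rate_parameters: dict[str, tuple[float, float]]  # (k_plus, k_minus)
    lambda_residuals: dict[str, float]  # xi~_j * log odds_j - lambda
    undetermined: list[str] = field(default_factory=list)

    def entropy_production(self) -> float:
        """Total entropy production rate sum_j xi_j log(Kj/Qj) (units of kB)."""
        return sum(
            self.fluxes.fluxes[rid] * math.log(o) for rid, o in self.odds.items()
        )


def _uptake_row(model: MetabolicModel) -> np.ndarray:
    S, mids, _ = model.stoichiometric_matrix(rows="all")
    if model.carbon_source_id is None:
        raise ValueError("model has no carbon_source_id; cannot scale uptake")
    i = mids.index(model.carbon_source_id)
    # uptake = net consumption of the carbon source
    return -S[i, :]


def steady_state_fluxes(
    model: MetabolicModel, basis_weights: np.ndarray | None = None
) -> FluxPattern:
    """A flux vector in the null space of the variable rows of S.

    The result is scaled so that the net carbon-source uptake equals
    ``model.uptake_rate_scale``.  With nullity > 1 and no explicit
    ``basis_weights``, the minimum-norm flux achieving the required uptake
    is returned.
    """
    from scipy.linalg import null_space

    S_var, _, rids = model.stoichiometric_matrix(rows="variable")
    if not rids:
        raise InfeasibleSteadyStateError("model has no enabled reactions")
    N = null_space(S_var) if S_var.size else np.eye(len(rids))
    if N.shape[1] == 0:
        raise InfeasibleSteadyStateError(
            "variable-row stoichiometric matrix has a trivial null space"
        )
    u = _uptake_row(model)
    uN = u @ N  # uptake per basis vector
    if basis_weights is not None:
        w = np.asarray(basis_weights, dtype=float)
        if w.shape != (N.shape[1],):
            raise ValueError(f"basis_weights must have shape ({N.shape[1]},)")
        xi = N @ w
        uptake = float(u @ xi)
        if abs(uptake) < 1e-12:
            raise InfeasibleSteadyStateError(
                "selected null-space combination has zero carbon uptake"
            )
    else:
        norm2 = float(uN @ uN)
        if norm2 < 1e-24:
            raise InfeasibleSteadyStateError(
                "no null-space direction engages the carbon source"
            )
        # min-norm xi subject to u.xi = scale (N is orthonormal)
        xi = N @ (uN / norm2)
        uptake = float(u @ xi)
    xi = xi * (model.uptake_rate_scale / uptake)
    return FluxPattern(
        fluxes={rid: float(v) for rid, v in zip(rids, xi)},
        scale=model.uptake_rate_scale,
    )


def solve_lambda(odds: dict[str, float], fluxes: FluxPattern) -> float:
    """Least-squares lambda from the stationary-action conditions.

    Each nonzero-flux reaction contributes one equation
    ``sign(xi_j) log(odds_j) = lambda``; the least-squares solution is
    their unweighted mean.  With no net-flux reactions the system is
    empty and lambda = 0 (every reaction may sit at equilibrium).
    """
    terms = [
        math.copysign(1.0, xi) * math.log(odds[rid])
        for rid, xi in fluxes.nonzero().items()
        if rid in odds
    ]
    if not terms:
        return 0.0
    return float(np.mean(terms))


def maxent_state(
    model: MetabolicModel,
    fluxes: FluxPattern | None = None,
    boundary: dict[str, float] | None = None,
    ctx: ThermoContext = DEFAULT_CONTEXT,
) -> MaxEntSolution:
    """Most likely concentrations and lambda for a steady-state flux pattern.

    Solved in log-concentration space: the conditions
    ``sign(xi_j) (log Kj - sum_i nu_ij x_i) = lambda`` over nonzero-flux
    reactions are linear in the unknown log concentrations ``x`` and in
    lambda, and are solved jointly by least squares.  Variable metabolites
    that only touch zero-flux reactions are then placed at equilibrium
    (the zero-flux branch of the stationary-action principle); metabolites
    constrained by neither are reported as undetermined at 1 M.
    """
    if fluxes is None:
        fluxes = steady_state_fluxes(model)
    fixed = dict(model.fixed_concentrations())
    if boundary:
        fixed.update(boundary)
    var_ids = model.variable_ids
    col = {m: i for i, m in enumerate(var_ids)}
    nv = len(var_ids)
    rxns = {r.id: r for r in model.enabled_reactions}

    def rhs_const(rxn: Reaction) -> float:
        # log Keq minus the fixed-species part of log Q
        val = math.log(rxn.effective_keq(ctx.rt))
        for mid, coef in rxn.stoichiometry.items():
            if mid not in col:
                val -= coef * math.log(fixed[mid])
        return val

    active = fluxes.nonzero()
    rows, b = [], []
    for rid, xi in active.items():
        rxn = rxns[rid]
        s = math.copysign(1.0, xi)
        row = np.zeros(nv + 1)
        for mid, coef in rxn.stoichiometry.items():
            if mid in col:
                row[col[mid]] = s * coef
        row[nv] = 1.0  # lambda
        rows.append(row)
        b.append(s * rhs_const(rxn))
    if rows:
        A = np.vstack(rows)
        sol, *_ = np.linalg.lstsq(A, np.array(b), rcond=None)
        x = sol[:nv]
        lam = float(sol[nv])
        determined = {
            var_ids[i] for i in range(nv) if np.any(np.abs(A[:, i]) > 0)
        }
    else:
        x = np.zeros(nv)
        lam = 0.0
        determined = set()

    # second stage: equilibrium placement of zero-flux-only metabolites
    zero_rxns = [r for rid, r in rxns.items() if rid not in active]
    free = [m for m in var_ids if m not in determined]
    if free and zero_rxns:
        fcol = {m: i for i, m in enumerate(free)}
        rows2, b2 = [], []
        for rxn in zero_rxns:
            row = np.zeros(len(free))
            val = rhs_const(rxn)
            touches_free = False
            for mid, coef in rxn.stoichiometry.items():
                if mid in fcol:
                    row[fcol[mid]] = coef
                    touches_free = True
                elif mid in col:
                    val -= coef * x[col[mid]]
            if touches_free:
                rows2.append(row)
                b2.append(val)
        if rows2:
            A2 = np.vstack(rows2)
            sol2, *_ = np.linalg.lstsq(A2, np.array(b2), rcond=None)
            for m, i in fcol.items():
                if np.any(np.abs(A2[:, i]) > 0):
                    x[col[m]] = sol2[i]
                    determined.add(m)
    undetermined = [m for m in var_ids if m not in determined]

    conc = {m: float(math.exp(x[col[m]])) for m in var_ids}
    all_conc = {**fixed, **conc}
    from .thermo import thermodynamic_odds

    odds = {rid: thermodynamic_odds(r, all_conc, ctx) for rid, r in rxns.items()}
    residuals = {
        rid: math.copysign(1.0, xi) * math.log(odds[rid]) - lam
        for rid, xi in active.items()
    }
    rate_params = _back_compute_rates(model, fluxes, all_conc, ctx)
    return MaxEntSolution(
        concentrations=conc,
        lam=lam,
        odds=odds,
        fluxes=fluxes,
        rate_parameters=rate_params,
        lambda_residuals=residuals,
        undetermined=undetermined,
    )


def _back_compute_rates(
    model: MetabolicModel,
    fluxes: FluxPattern,
    concentrations: dict[str, float],
    ctx: ThermoContext,
) -> dict[str, tuple[float, float]]:
    """Mass-action (k+, k-) reproducing each steady flux at the state.

    The ratio k+/k- is pinned to the effective Keq; the remaining
    per-reaction timescale is fixed by requiring
    ``k+ prod(react) - k- prod(prod) = xi_j``.  Zero-flux reactions keep
    the unit-timescale convention k- = 1.
    """
    out: dict[str, tuple[float, float]] = {}
    for rxn in model.enabled_reactions:
        keq = rxn.effective_keq(ctx.rt)
        prod_react = 1.0
        prod_prod = 1.0
        for mid, coef in rxn.stoichiometry.items():
            c = concentrations[mid]
            if coef < 0:
                prod_react *= c ** (-coef)
            else:
                prod_prod *= c**coef
        xi = fluxes.fluxes.get(rxn.id, 0.0)
        denom = keq * prod_react - prod_prod
        if abs(xi) <= ZERO_FLUX_TOL * fluxes.scale or abs(denom) < 1e-300:
            k_minus = 1.0
        else:
            k_minus = xi / denom
        out[rxn.id] = (keq * k_minus, k_minus)
    return out


def delta_pr(
    reaction: Reaction,
    concentrations: dict[str, float],
    activity: float = 1.0,
    extent: float = 1.0,
    ctx: ThermoContext = DEFAULT_CONTEXT,
) -> float:
    """Signed odds difference alpha * ((K/Q)^xi - (Q/K)^xi).

    The difference of forward and reverse reaction probabilities, scaled
    by the enzyme activity coefficient alpha in [0, 1]; positive when the
    forward direction is favored, antisymmetric under reversal.  ``extent``
    is the (normalized) steady-state extent exponent; the control law uses
    extent = 1.
    """
    if not 0.0 <= activity <= 1.0:
        raise ValueError("activity must be within [0, 1]")
    from .thermo import thermodynamic_odds

    a = extent * math.log(thermodynamic_odds(reaction, concentrations, ctx))
    a = min(max(a, -700.0), 700.0)
    return activity * (math.exp(a) - math.exp(-a))
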