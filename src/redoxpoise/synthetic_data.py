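"""Toy thermo-kinetic model generators and a mass-action ODE oracle.

The generators emit small, exactly element-balanced networks with the
structural features the analysis relies on — fixed boundary species, a
nontrivial steady-state null space, an NADP+/NADPH-like redox pair and a
growth pseudo-reaction — so every solver stage can be exercised and
cross-checked against closed forms and direct ODE integration without a
genome-scale curated model.  Generation is a pure, seeded function of the
spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ElementFormula, MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToySpec",
    "make_toy_chain",
    "make_toy_redox_cell",
    "simulate_mass_action",
    "MassActionTrajectory",
]


@dataclass
class ToySpec:
    """Parameters of a generated toy model.

    ``keqs`` pins equilibrium constants explicitly; otherwise they are
    sampled log-uniformly over ``keq_decades`` with the given seed.
    """

    length: int = 3  # reactions in a chain
    boundary_concentration: float = 1.0  # molar, chain end species
    keqs: tuple[float, ...] | None = None
    keq_decades: tuple[float, float] = (1e-3, 1e3)
    include_redox_pair: bool = False
    include_growth: bool = False
    seed: int = 0
    boundary: dict[str, float] = field(default_factory=dict)  # redox-cell overrides


def _sample_keqs(spec: ToySpec, n: int) -> list[float]:
    if spec.keqs is not None:
        if len(spec.keqs) != n:
            raise ValueError(f"need {n} equilibrium constants, got {len(spec.keqs)}")
        return list(spec.keqs)
    rng = np.random.default_rng(spec.seed)
    lo, hi = np.log10(spec.keq_decades[0]), np.log10(spec.keq_decades[1])
    return list(10.0 ** rng.uniform(lo, hi, size=n))


def make_toy_chain(spec: ToySpec) -> MetabolicModel:
    """A linear isomerization chain M0 = M1 = ... = ML with fixed ends.

    All species share one formula (C6H12O6 homologue), so every step is
    exactly balanced; the null space of the variable rows is the single
    uniform flux vector.  With ``length=2`` and Keq = (10, 1) this is the
    closed-form maxent fixture ([M1] = sqrt(10), lambda = ln sqrt(10)).
    """
    if spec.length < 2:
        raise ValueError("chain length must be >= 2")
    keqs = _sample_keqs(spec, spec.length)
    formula = ElementFormula.parse("C6H12O6")
    n = spec.length
    mets = []
    for i in range(n + 1):
        end = i in (0, n)
        mets.append(
            Metabolite(
                id=f"M{i}",
                name=f"chain species {i}",
                formula=formula,
                is_fixed=end,
                fixed_concentration=spec.boundary_concentration if end else None,
            )
        )
    rxns = [
        Reaction(
            id=f"r{i}",
            stoichiometry={f"M{i}": -1.0, f"M{i+1}": 1.0},
            keq=keqs[i],
            # with include_growth the terminal step doubles as the growth
            # reaction, so the chain exercises the PCO objective as well
            is_growth=spec.include_growth and i == n - 1,
        )
        for i in range(n)
    ]
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        carbon_source_id="M0",
        config={"co2_id": None},
    )


#: default boundary concentrations (M) of the toy redox cell
REDOX_CELL_BOUNDARY = {
    "subst": 1e-2,
    "co2": 1e-2,
    "nh3": 1e-2,
    "nadph": 1e-3,
    "nadp": 1e-3,
    "h2o": 1.0,
    "biomass": 1e-3,
}

#: default equilibrium constants of the toy redox cell
REDOX_CELL_KEQS = {
    "r_condense": 10.0,
    "r_reduce": 100.0,
    "r_growth": 100.0,
    "r_oxidize": 1.0,
    "r_rubisco": 1.0,
}


def make_toy_redox_cell(spec: ToySpec | None = None) -> MetabolicModel:
    """A minimal dissipative cell: substrate + NH3 + reductant -> biomass.

    Five exactly balanced reactions around a fixed NADP+/NADPH-like pair:

    - ``r_condense``:  2 subst = X                (carbon backbone)
    - ``r_reduce``:    X + NADPH = Y + NADP+ + H2O (reductive step)
    - ``r_growth``:    Y + NH3 = biomass + H2O     (growth reaction, in G)
    - ``r_oxidize``:   subst + 4 NADP+ + 2 H2O = 2 CO2 + 4 NADPH
    - ``r_rubisco``:   X = X2                      (dead end: zero flux)

    The growth pathway's total driving force telescopes to a constant plus
    log([NADPH]/[NADP+]), so the optimal growth objective is monotone in
    the boundary redox poise by construction; the oxidative branch
    ``r_oxidize`` couples only boundary species, making the net CO2
    exchange flip sign between reductive and oxidative conditions; and
    steady state forces exactly zero flux through the dead-end
    carboxylation analogue ``r_rubisco``.
    """
    spec = spec or ToySpec(include_redox_pair=True, include_growth=True)
    if not (spec.include_redox_pair and spec.include_growth):
        raise ValueError("the redox cell requires include_redox_pair and include_growth")
    bnd = {**REDOX_CELL_BOUNDARY, **spec.boundary}
    F = ElementFormula.parse
    mets = [
        Metabolite("subst", "acetate-like substrate", F("C2H4O2"), True, bnd["subst"]),
        Metabolite("co2", "carbon dioxide", F("CO2"), True, bnd["co2"]),
        Metabolite("nh3", "ammonia", F("NH3"), True, bnd["nh3"]),
        Metabolite("nadph", "reduced carrier", F("C5H7N5"), True, bnd["nadph"]),
        Metabolite("nadp", "oxidized carrier", F("C5H5N5"), True, bnd["nadp"]),
        Metabolite("h2o", "water", F("H2O"), True, bnd["h2o"]),
        Metabolite("biomass", "cell monomer", F("C4H9O2N"), True, bnd["biomass"]),
        Metabolite("X", "condensed intermediate", F("C4H8O4")),
        Metabolite("Y", "reduced intermediate", F("C4H8O3")),
        Metabolite("X2", "dead-end isomer", F("C4H8O4")),
    ]
    K = REDOX_CELL_KEQS
    rxns = [
        Reaction("r_condense", {"subst": -2.0, "X": 1.0}, K["r_condense"]),
        Reaction(
            "r_reduce",
            {"X": -1.0, "nadph": -1.0, "Y": 1.0, "nadp": 1.0, "h2o": 1.0},
            K["r_reduce"],
        ),
        Reaction(
            "r_growth",
            {"Y": -1.0, "nh3": -1.0, "biomass": 1.0, "h2o": 1.0},
            K["r_growth"],
            is_growth=True,
        ),
        Reaction(
            "r_oxidize",
            {"subst": -1.0, "nadp": -4.0, "h2o": -2.0, "co2": 2.0, "nadph": 4.0},
            K["r_oxidize"],
        ),
        Reaction("r_rubisco", {"X": -1.0, "X2": 1.0}, K["r_rubisco"]),
    ]
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        carbon_source_id="subst",
        config={
            "nadp_id": "nadp",
            "nadph_id": "nadph",
            "co2_id": "co2",
            "markers": {"rubisco": "r_rubisco", "oxidation": "r_oxidize"},
            "redox_pairs": {"NADP+/NADPH": ["nadp", "nadph"]},
        },
    )


@dataclass
class MassActionTrajectory:
    times: np.ndarray
    concentrations: np.ndarray  # (n_species, n_times)
    species: list[str]
    success: bool
    message: str = ""

    def final(self) -> dict[str, float]:
        return {s: float(self.concentrations[i, -1]) for i, s in enumerate(self.species)}

    def max_relative_drift(self, reference: dict[str, float]) -> float:
        drift = 0.0
        for i, s in enumerate(self.species):
            ref = reference[s]
            drift = max(drift, float(np.max(np.abs(self.concentrations[i] - ref)) / ref))
        return drift


def simulate_mass_action(
    model: MetabolicModel,
    rate_parameters: dict[str, tuple[float, float]],
    initial: dict[str, float],
    horizon: float,
    rtol: float = 1e-10,
    atol: float = 1e-14,
    n_report: int = 50,
) -> MassActionTrajectory:
    """Integrate the mass-action ODEs with fixed species clamped.

    The independent dynamical oracle: a maxent/PCO steady state must be a
    fixed point of these equations under the back-computed rate
    parameters.  Rates use |nu|-power kinetics on each side of every
    enabled reaction.
    """
    from scipy.integrate import solve_ivp

    var_ids = model.variable_ids
    fixed = model.fixed_concentrations()
    idx = {m: i for i, m in enumerate(var_ids)}
    rxns = model.enabled_reactions
    y0 = np.array([initial[m] for m in var_ids], dtype=float)

    def rhs(_t, y):
        conc = dict(fixed)
        conc.update({m: max(y[i], 0.0) for m, i in idx.items()})
        dy = np.zeros_like(y)
        for rxn in rxns:
            kp, km = rate_parameters[rxn.id]
            fwd, rev = kp, km
            for mid, coef in rxn.stoichiometry.items():
                if coef < 0:
                    fwd *= conc[mid] ** (-coef)
                else:
                    rev *= conc[mid] ** coef
            xi = fwd - rev
            for mid, coef in rxn.stoichiometry.items():
                i = idx.get(mid)
                if i is not None:
                    dy[i] += coef * xi
        return dy

    t_eval = np.linspace(0.0, horizon, n_report)
    res = solve_ivp(rhs, (0.0, horizon), y0, method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval)
    if not res.success:  # pragma: no cover - stiff fallback advice
        return MassActionTrajectory(
            times=res.t,
            concentrations=res.y,
            species=var_ids,
            success=False,
            message=f"{res.message}; consider loosening rtol/atol or shortening the horizon",
        )
    return MassActionTrajectory(times=res.t, concentrations=res.y, species=var_ids, success=True)
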