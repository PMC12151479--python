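"""Reaction quotients, thermodynamic odds, and redox-condition bookkeeping.

The central quantity is the thermodynamic odds K/Q of a reaction: 1 at
equilibrium, > 1 when the forward direction is favored.  Redox boundary
conditions are parameterized by the odds of substrate (H2) oxidation in
the reference half-reaction

    NADP+ + H2 = NADPH,   dG0 = -35.0 kJ/mol,

at the standard-hydrogen-electrode reference concentration [H2] = 1 M, so
that a target odds maps one-to-one onto a boundary [NADP+]/[NADPH] ratio:
ratio = odds * exp(dG0/RT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model_core import Reaction

__all__ = [
    "ThermoContext",
    "RedoxCondition",
    "REFERENCE_H2_CONC",
    "reaction_quotient",
    "thermodynamic_odds",
    "odds_to_ratio",
    "ratio_to_odds",
    "adjust_proton_gradient",
]

#: reference [H2] (M); fixed by the standard-hydrogen-electrode convention
REFERENCE_H2_CONC = 1.0


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and constants for all free-energy arithmetic.

    ``reference_deltaG0`` is the standard free energy (kJ/mol) of the
    NADP+ reduction by H2 used to parameterize redox conditions.
    """

    temperature: float = 298.15  # K
    gas_constant: float = 8.314e-3  # kJ / (mol K)
    reference_deltaG0: float = -35.0  # kJ/mol

    @property
    def rt(self) -> float:
        """R*T in kJ/mol."""
        return self.gas_constant * self.temperature

    @property
    def beta(self) -> float:
        """1/(R*T) in mol/kJ (per-mole convention for beta*mu terms)."""
        return 1.0 / self.rt

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


DEFAULT_CONTEXT = ThermoContext()


def reaction_quotient(reaction: Reaction, concentrations: dict[str, float]) -> float:
    """Mass-action reaction quotient Q = prod(products) / prod(reactants).

    Computed in log space from the signed stoichiometry; every
    participating concentration must be strictly positive.
    """
    log_q = 0.0
    for mid, coef in reaction.stoichiometry.items():
        try:
            c = concentrations[mid]
        except KeyError:
            raise KeyError(
                f"no concentration for metabolite {mid!r} in reaction {reaction.id!r}"
            ) from None
        if c <= 0:
            raise ValueError(
                f"non-positive concentration for {mid!r}: {c} (reaction {reaction.id!r})"
            )
        log_q += coef * math.log(c)
    return math.exp(log_q)


def thermodynamic_odds(
    reaction: Reaction,
    concentrations: dict[str, float],
    ctx: ThermoContext = DEFAULT_CONTEXT,
) -> float:
    """K/Q for the reaction: 1 at equilibrium, > 1 forward-favored.

    Uses the effective equilibrium constant, i.e. including any declared
    standard free-energy offset (proton-gradient adjustments).
    """
    return reaction.effective_keq(ctx.rt) / reaction_quotient(reaction, concentrations)


def odds_to_ratio(odds: float, ctx: ThermoContext = DEFAULT_CONTEXT) -> float:
    """[NADP+]/[NADPH] implied by a substrate-oxidation odds at [H2] = 1 M."""
    if odds <= 0:
        raise ValueError("odds must be > 0")
    return odds * math.exp(ctx.reference_deltaG0 / ctx.rt) / REFERENCE_H2_CONC


def ratio_to_odds(ratio: float, ctx: ThermoContext = DEFAULT_CONTEXT) -> float:
    """Inverse of :func:`odds_to_ratio`; exact round-trip identity."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    return ratio * math.exp(-ctx.reference_deltaG0 / ctx.rt) * REFERENCE_H2_CONC


@dataclass
class RedoxCondition:
    """A swept redox boundary condition.

    ``target_odds`` is the requested oxidation odds; ``nadp_ratio`` the
    implied [NADP+]/[NADPH] boundary ratio; ``actual_odds`` may differ from
    the target when the ratio was minimally perturbed to rescue a
    non-converged optimization.
    """

    target_odds: float
    nadp_ratio: float
    actual_odds: float
    ctx: ThermoContext = field(default=DEFAULT_CONTEXT, repr=False)

    @classmethod
    def from_odds(
        cls, odds: float, ctx: ThermoContext = DEFAULT_CONTEXT
    ) -> "RedoxCondition":
        return cls(
            target_odds=odds, nadp_ratio=odds_to_ratio(odds, ctx), actual_odds=odds, ctx=ctx
        )

    @classmethod
    def from_ratio(
        cls, ratio: float, target_odds: float | None = None, ctx: ThermoContext = DEFAULT_CONTEXT
    ) -> "RedoxCondition":
        odds = ratio_to_odds(ratio, ctx)
        return cls(
            target_odds=odds if target_odds is None else target_odds,
            nadp_ratio=ratio,
            actual_odds=odds,
            ctx=ctx,
        )

    @property
    def perturbed(self) -> bool:
        return not math.isclose(self.actual_odds, self.target_odds, rel_tol=1e-9)


def adjust_proton_gradient(
    deltaG0: float,
    protons: float,
    fold_change: float,
    ctx: ThermoContext = DEFAULT_CONTEXT,
) -> float:
    """Shift a standard free energy for a transmembrane proton gradient.

    Returns ``deltaG0 - protons * RT * ln(fold_change)``: each translocated
    proton contributes the free energy of a ``fold_change``-fold
    concentration difference, favoring synthesis (negative increment).  The
    stronger-gradient experiment is expressed as (protons=4, fold=50)
    versus the default (4, 10).
    """
    if protons < 0:
        raise ValueError("protons must be >= 0")
    if fold_change < 1:
        raise ValueError("fold_change must be >= 1")
    return deltaG0 - protons * ctx.rt * math.log(fold_change)
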