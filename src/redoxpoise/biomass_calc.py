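"""Elemental bookkeeping: overall growth reactions and biomass composition.

The link between the simulated metabolism and measurable cell composition
runs through the net exchange of boundary species.  The overall growth
reaction is extracted from a steady-state solution, simplified (small
terms thresholded, redundant redox carriers merged), and the biomass
elemental composition C4HuO_fNz is solved from the element balances after
substituting the carrier pair by H2 and a variable amount of water.  The
carbon oxidation state

    Z_C = (-n_H + 2 n_O + 3 n_N) / n_C

summarizes how reduced the biomass (or any CHON compound) is; phosphorus
and sulfur are excluded from Z_C by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model_core import ElementFormula, MetabolicModel, Reaction

__all__ = [
    "OverallReaction",
    "ElementalComposition",
    "MacromoleculeRatios",
    "BiomassEstimate",
    "CellCycleBalance",
    "carbon_oxidation_state",
    "extract_overall_reaction",
    "merge_redox_carriers",
    "solve_biomass_formula",
    "balance_cell_cycle",
    "lipid_mass_fraction",
    "biomass_pseudo_reaction",
]


def carbon_oxidation_state(formula: ElementFormula | str) -> float:
    """Average carbon oxidation state of a CHON formula.

    Hydrogen counts -1, oxygen +2, nitrogen +3 per atom against carbon;
    phosphorus and sulfur are ignored.  Raises on zero carbon.
    """
    if isinstance(formula, str):
        formula = ElementFormula.parse(formula)
    n_c = formula.get("C")
    if n_c <= 0:
        raise ValueError("carbon oxidation state undefined for a carbon-free formula")
    return (-formula.get("H") + 2.0 * formula.get("O") + 3.0 * formula.get("N")) / n_c


@dataclass
class ElementalComposition:
    """A biomass formula normalized to 4 carbons, C4HuO_fNz."""

    formula: ElementFormula

    @classmethod
    def from_subscripts(cls, u: float, o: float, z: float) -> "ElementalComposition":
        return cls(ElementFormula({"C": 4.0, "H": u, "O": o, "N": z}))

    @property
    def u(self) -> float:
        return self.formula.get("H")

    @property
    def o(self) -> float:
        return self.formula.get("O")

    @property
    def z(self) -> float:
        return self.formula.get("N")

    @property
    def z_c(self) -> float:
        return carbon_oxidation_state(self.formula)

    def formatted(self, decimals: int = 2) -> str:
        """C/H/O/N-ordered formula string with rounded subscripts."""
        parts = []
        for el in ("C", "H", "O", "N"):
            n = self.formula.get(el)
            if n == 0:
                continue
            sub = f"{n:.{decimals}f}".rstrip("0").rstrip(".")
            parts.append(f"{el}{'' if sub == '1' else sub}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.formatted()


@dataclass
class OverallReaction:
    """Net boundary-exchange stoichiometry (negative = consumed).

    ``formulas`` maps species ids to compositions; a species id that is
    itself a parseable formula string (``"CO2"``, ``"C4H6O5"``) needs no
    entry.  ``provenance`` records thresholding/merging applied.
    """

    coefficients: dict[str, float]
    formulas: dict[str, ElementFormula] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def formula_of(self, species: str) -> ElementFormula | None:
        if species in self.formulas:
            return self.formulas[species]
        try:
            return ElementFormula.parse(species)
        except ValueError:
            return None

    def element_totals(self) -> dict[str, float]:
        """Net input per element: consumed positive, produced negative."""
        totals: dict[str, float] = {}
        for sp, coef in self.coefficients.items():
            f = self.formula_of(sp)
            if f is None:
                raise ValueError(f"species {sp!r} has no elemental formula")
            for el, n in f.counts.items():
                totals[el] = totals.get(el, 0.0) - coef * n
        return totals

    def scaled(self, factor: float) -> "OverallReaction":
        return OverallReaction(
            coefficients={s: c * factor for s, c in self.coefficients.items()},
            formulas=dict(self.formulas),
            provenance={**self.provenance, "scaled_by": factor},
        )


def extract_overall_reaction(
    solution,
    model: MetabolicModel,
    threshold: float = 0.01,
    internal: set[str] | None = None,
    keep: set[str] | None = None,
    normalize_substrate_to: float | None = None,
) -> OverallReaction:
    """Overall growth reaction from a steady-state solution.

    Boundary-species net rates (S_fixed @ flux, uptake-normalized) become
    signed coefficients; species whose |rate| is below ``threshold`` times
    the carbon-source rate are dropped, as are species declared internal
    (boundary cofactors without exchange with the environment) except for
    a keep-list defaulting to the phosphates.  With
    ``normalize_substrate_to`` the reaction is rescaled so the carbon
    source is consumed in that many units (the worked-example convention
    is 10).
    """
    from .pipeline import net_boundary_exchange

    internal = internal if internal is not None else set(
        model.config.get("internal_species", [])
    )
    keep = keep if keep is not None else set(
        model.config.get("phosphate_species", ["pi", "ppi"])
    )
    rates = net_boundary_exchange(solution, model)
    cs = model.carbon_source_id
    ref = abs(rates.get(cs, 0.0))
    if ref == 0:
        raise ValueError("carbon source carries no net exchange; cannot threshold")
    coeffs, dropped = {}, []
    for sp, rate in rates.items():
        if abs(rate) < threshold * ref:
            dropped.append(sp)
            continue
        if sp in internal and sp not in keep:
            dropped.append(sp)
            continue
        coeffs[sp] = rate
    formulas = {
        m.id: m.formula for m in model.metabolites if m.formula is not None
    }
    rxn = OverallReaction(
        coefficients=coeffs,
        formulas=formulas,
        provenance={"threshold": threshold, "dropped": dropped},
    )
    if normalize_substrate_to is not None:
        rxn = rxn.scaled(normalize_substrate_to / abs(coeffs[cs]))
    return rxn


def merge_redox_carriers(
    rxn: OverallReaction, carrier_map: dict[str, dict[str, float]]
) -> OverallReaction:
    """Fold redundant redox carriers into a single pair.

    ``carrier_map`` maps each species to eliminate onto the stoichiometry
    of a substitution reaction *producing one unit of it* (e.g. the
    NAD+ -> NADP+ redundancy is removed with
    ``{"nad": {"nadp": -1, "nad": 1, "pi": 1}}``).  The right multiple of
    each substitution is added and like terms cancelled; when formulas are
    available the substitution must itself be elementally balanced.
    """
    coeffs = dict(rxn.coefficients)
    applied = {}
    for species, sub in carrier_map.items():
        if species not in coeffs or coeffs[species] == 0:
            continue
        if sub.get(species, 0.0) == 0:
            raise ValueError(
                f"substitution for carrier {species!r} must produce that species"
            )
        # elemental neutrality of the substitution, if formulas known
        residual: dict[str, float] = {}
        known = True
        for sp, c in sub.items():
            f = rxn.formula_of(sp)
            if f is None:
                known = False
                break
            for el, n in f.counts.items():
                residual[el] = residual.get(el, 0.0) + c * n
        if known and any(abs(v) > 1e-9 for v in residual.values()):
            raise ValueError(
                f"substitution for carrier {species!r} is not elementally balanced: {residual}"
            )
        t = -coeffs[species] / sub[species]
        for sp, c in sub.items():
            coeffs[sp] = coeffs.get(sp, 0.0) + t * c
        applied[species] = t
    coeffs = {s: c for s, c in coeffs.items() if abs(c) > 1e-12}
    return OverallReaction(
        coefficients=coeffs,
        formulas=dict(rxn.formulas),
        provenance={**rxn.provenance, "carriers_merged": applied},
    )


@dataclass
class BiomassEstimate:
    x: float  # biomass units (per 4 carbons)
    water: float  # H2O coefficient on the product side
    composition: ElementalComposition

    @property
    def z_c(self) -> float:
        return self.composition.z_c


def solve_biomass_formula(rxn: OverallReaction, o_per_4c: float) -> BiomassEstimate:
    """Solve x C4HuO_fNz + y H2O from the overall-reaction element balances.

    The reaction should already have its redox carrier replaced by H2 (one
    H2 per NADPH, the oxidized partner by water).  Carbon fixes x,
    nitrogen fixes z, oxygen fixes y given the measured O subscript
    ``o_per_4c``, and hydrogen closes u; all four balances hold exactly by
    construction.  A negative solved coefficient raises, naming the
    balance that failed.
    """
    if o_per_4c <= 0:
        raise ValueError("o_per_4c must be > 0")
    totals = rxn.element_totals()
    t_c = totals.get("C", 0.0)
    if t_c <= 0:
        raise ValueError("carbon balance failed: no net carbon input")
    x = t_c / 4.0
    z = totals.get("N", 0.0) / x
    if z < 0:
        raise ValueError(f"nitrogen balance failed: z = {z:.4g} < 0")
    y = totals.get("O", 0.0) - o_per_4c * x
    if y < 0:
        raise ValueError(f"oxygen balance failed: water coefficient y = {y:.4g} < 0")
    u = (totals.get("H", 0.0) - 2.0 * y) / x
    if u < 0:
        raise ValueError(f"hydrogen balance failed: u = {u:.4g} < 0")
    return BiomassEstimate(
        x=x, water=y, composition=ElementalComposition.from_subscripts(u, o_per_4c, z)
    )


@dataclass
class CellCycleBalance:
    """Balanced coefficients of an idealized cell-cycle reaction.

    Sign convention: positive = consumed (appears on the left), negative =
    produced.  ``h2o_produced``/``h2_produced`` are sign-flipped
    conveniences.
    """

    nh3: float
    h2o: float
    h2: float

    @property
    def nh3_consumed(self) -> float:
        return self.nh3

    @property
    def h2o_produced(self) -> float:
        return -self.h2o

    @property
    def h2_produced(self) -> float:
        return -self.h2


def balance_cell_cycle(
    substrate: ElementFormula | str,
    substrate_units: float,
    biomass: ElementFormula | str,
    biomass_units: float,
    co2_units: float,
) -> CellCycleBalance:
    """Element-balance substrate -> biomass with CO2, NH3, H2O and H2.

    ``co2_units`` is signed: positive = produced, negative = consumed.
    Nitrogen fixes NH3, oxygen fixes H2O, hydrogen fixes H2, in that
    order; carbon must already balance (raises otherwise).
    """
    if isinstance(substrate, str):
        substrate = ElementFormula.parse(substrate)
    if isinstance(biomass, str):
        biomass = ElementFormula.parse(biomass)
    c_resid = substrate_units * substrate.get("C") - biomass_units * biomass.get("C") - co2_units
    if abs(c_resid) > 1e-9:
        raise ValueError(
            f"inconsistent carbon totals: residual {c_resid:.4g} "
            "(substrate vs biomass + CO2)"
        )
    nh3 = biomass_units * biomass.get("N") - substrate_units * substrate.get("N")
    # oxygen: substrate + 2 CO2(consumed side) = biomass + h2o(produced)
    h2o_produced = (
        substrate_units * substrate.get("O")
        - biomass_units * biomass.get("O")
        - 2.0 * co2_units
    )
    h2_consumed = (
        biomass_units * biomass.get("H")
        + 2.0 * h2o_produced
        - substrate_units * substrate.get("H")
        - 3.0 * nh3
    ) / 2.0
    return CellCycleBalance(nh3=nh3, h2o=-h2o_produced, h2=h2_consumed)


def lipid_mass_fraction(target_fraction: float, known_masses: list[float]) -> float:
    """Lipid mass x such that x / (sum(known) + x) equals the target fraction."""
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie strictly between 0 and 1")
    return target_fraction * math.fsum(known_masses) / (1.0 - target_fraction)


@dataclass
class MacromoleculeRatios:
    """Mass ratios relative to DNA = 1."""

    dna: float = 1.0
    rna: float = 2.9
    protein: float = 44.1
    lipid: float = 8.5
    extras: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        d = {"DNA": self.dna, "RNA": self.rna, "protein": self.protein, "lipid": self.lipid}
        d.update(self.extras)
        if any(v < 0 for v in d.values()):
            raise ValueError("macromolecule ratios must be non-negative")
        return d


def biomass_pseudo_reaction(
    ratios: MacromoleculeRatios,
    monomers: dict[str, tuple[ElementFormula | str | None, float]] | None = None,
    product_id: str = "cell_monomer",
    keq: float = 1.0,
    reaction_id: str = "growth",
) -> Reaction:
    """Growth pseudo-reaction consuming macromolecules in given mass ratios.

    ``monomers`` maps each macromolecule to (formula, molar mass in the
    model's mass unit); the stoichiometric coefficient is mass ratio over
    molar mass.  With unit masses (the default) the coefficients are the
    mass ratios themselves, the macromolecule-pool convention in which
    each pool species carries unit mass.
    """
    d = ratios.as_dict()
    stoich: dict[str, float] = {}
    for name, ratio in d.items():
        if ratio == 0:
            continue
        mass = 1.0
        if monomers and name in monomers:
            mass = monomers[name][1]
        stoich[name] = -ratio / mass
    stoich[product_id] = 1.0
    return Reaction(
        id=reaction_id,
        name="biomass pseudo-reaction",
        stoichiometry=stoich,
        keq=keq,
        is_growth=True,
    )
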