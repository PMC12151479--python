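"""Data model for thermo-kinetic metabolic networks.

A :class:`MetabolicModel` is a mass-action reaction network in which every
metabolite carries an elemental formula and every reaction carries a
transformed equilibrium constant (pH 7.0, I = 0.15 M conventions, so
explicit protons are absorbed into the constant).  Metabolites are
partitioned into *fixed* boundary species, held at constant concentration
as environmental or cofactor boundary conditions, and *variable* internal
species whose steady-state concentrations the solvers determine.

Models are serialized to a small JSON schema (top-level keys
``metabolites``, ``reactions``, ``config``; reactant coefficients
negative) and can also be imported from two delimited tables (one of
reactions with equation strings and Keq, one of metabolites with
formulas), mirroring the layout in which curated models are commonly
distributed.
"""

from __future__ import annotations

import copy as _copy
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ElementFormula",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "BalanceReport",
    "ModelValidationError",
    "load_model",
    "write_model",
    "loads_model",
    "dumps_model",
    "import_tables",
    "validate_mass_balance",
    "stoichiometric_rank",
    "set_reaction_enabled",
]

#: elements checked during mass balance, in reporting order
BALANCED_ELEMENTS = ("C", "H", "O", "N", "P", "S")

#: |residual| above this value flags a reaction as unbalanced
BALANCE_TOL = 1e-6

#: singular values below RANK_RTOL * sigma_max are treated as zero
RANK_RTOL = 1e-9


class ModelValidationError(ValueError):
    """Raised when a model file or model structure violates the schema."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


@dataclass(frozen=True)
class ElementFormula:
    """Elemental composition with non-negative, possibly fractional counts.

    Fractional subscripts are required for average biomass formulas such as
    C4H7.07O2.04N0.63.
    """

    counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
        # drop zero entries for a canonical representation
        object.__setattr__(
            self, "counts", {el: float(n) for el, n in self.counts.items() if n != 0}
        )

    @classmethod
    def parse(cls, text: str) -> "ElementFormula":
        """Parse a Hill-like formula string, e.g. ``C4H7.07O2.04N0.63``."""
        text = text.strip()
        if not text:
            return cls({})
        counts: dict[str, float] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0.0) + (float(num) if num else 1.0)
            pos = m.end()
            if pos == len(text):
                break
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def get(self, element: str) -> float:
        return self.counts.get(element, 0.0)

    def __getitem__(self, element: str) -> float:
        return self.counts.get(element, 0.0)

    def __mul__(self, factor: float) -> "ElementFormula":
        return ElementFormula({el: n * factor for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __add__(self, other: "ElementFormula") -> "ElementFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0.0) + n
        return ElementFormula(counts)

    def is_empty(self) -> bool:
        return not self.counts

    def to_string(self) -> str:
        """Hill-like string: C, H first, then remaining elements sorted."""
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))

        def fmt(n: float) -> str:
            if n == int(n):
                return "" if n == 1 else str(int(n))
            return f"{n:g}"

        return "".join(f"{el}{fmt(self.counts[el])}" for el in order)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: ElementFormula | None = None
    is_fixed: bool = False
    fixed_concentration: float | None = None  # molar, required iff fixed
    upper_bound: float | None = None  # molar cap for variable species

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = ElementFormula.parse(self.formula)
        if self.is_fixed:
            if self.fixed_concentration is None or self.fixed_concentration <= 0:
                raise ModelValidationError(
                    f"fixed metabolite {self.id!r} needs fixed_concentration > 0"
                )
        if self.upper_bound is not None and self.upper_bound <= 0:
            raise ModelValidationError(f"metabolite {self.id!r}: upper_bound must be > 0")


@dataclass
class Reaction:
    """A mass-action reaction with signed stoichiometry (reactants < 0).

    ``keq`` is the dimensionless transformed equilibrium constant at pH 7,
    I = 0.15 M.  ``deltaG0_offset`` (kJ/mol) shifts the standard free
    energy, e.g. the ATP-synthase proton-gradient adjustment; the effective
    constant is ``keq * exp(-offset / RT)``.  ``proton_exchange`` declares
    protons exchanged with the solvent so that the hydrogen balance can be
    checked under the transformed-thermodynamics convention.
    """

    id: str
    stoichiometry: dict[str, float]
    keq: float
    name: str = ""
    is_growth: bool = False
    enabled: bool = True
    deltaG0_offset: float = 0.0
    proton_exchange: float = 0.0

    def __post_init__(self) -> None:
        if self.keq <= 0:
            raise ModelValidationError(f"reaction {self.id!r}: Keq must be > 0")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")

    def effective_keq(self, rt: float) -> float:
        """Equilibrium constant including the free-energy offset (RT in kJ/mol)."""
        if self.deltaG0_offset == 0.0:
            return self.keq
        return self.keq * math.exp(-self.deltaG0_offset / rt)

    def reactants(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    carbon_source_id: str | None = None
    uptake_rate_scale: float = 1000.0  # molecules / s
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # ---- structural accessors -------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        try:
            return self._met_index[mid]
        except KeyError:
            raise KeyError(f"unknown metabolite {mid!r}") from None

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise KeyError(f"unknown reaction {rid!r}") from None

    @property
    def fixed_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.is_fixed]

    @property
    def variable_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.is_fixed]

    @property
    def enabled_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.enabled]

    @property
    def growth_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_growth and r.enabled]

    def fixed_concentrations(self) -> dict[str, float]:
        return {m.id: m.fixed_concentration for m in self.metabolites if m.is_fixed}

    def net_particle_change(self, reaction: Reaction) -> float:
        """Sum of signed coefficients over non-fixed (variable) species."""
        fixed = set(self.fixed_ids)
        return sum(c for m, c in reaction.stoichiometry.items() if m not in fixed)

    # ---- matrices -------------------------------------------------------------

    def stoichiometric_matrix(
        self, rows: str = "all", enabled_only: bool = True
    ) -> tuple[np.ndarray, list[str], list[str]]:
        """Return (S, metabolite row ids, reaction column ids).

        ``rows`` selects ``"all"``, ``"variable"`` or ``"fixed"`` metabolite
        rows; disabled reactions are excluded by default.
        """
        if rows == "all":
            mids = self.metabolite_ids
        elif rows == "variable":
            mids = self.variable_ids
        elif rows == "fixed":
            mids = self.fixed_ids
        else:  # pragma: no cover - defensive
            raise ValueError(f"rows must be all/variable/fixed, got {rows!r}")
        rxns = self.enabled_reactions if enabled_only else self.reactions
        rids = [r.id for r in rxns]
        row_of = {m: i for i, m in enumerate(mids)}
        S = np.zeros((len(mids), len(rids)))
        for j, rxn in enumerate(rxns):
            for m, c in rxn.stoichiometry.items():
                i = row_of.get(m)
                if i is not None:
                    S[i, j] = c
        return S, mids, rids

    # ---- validation -----------------------------------------------------------

    def validate(self) -> None:
        seen_m: set[str] = set()
        for m in self.metabolites:
            if m.id in seen_m:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
        seen_r: set[str] = set()
        for r in self.reactions:
            if r.id in seen_r:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            for mid in r.stoichiometry:
                if mid not in seen_m:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references unknown metabolite {mid!r}"
                    )
        if self.carbon_source_id is not None and self.carbon_source_id not in seen_m:
            raise ModelValidationError(
                f"carbon source {self.carbon_source_id!r} is not a metabolite"
            )
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)


# ---- balance report ----------------------------------------------------------


@dataclass
class BalanceReport:
    """Per-reaction, per-element residuals of sum_i nu_ij * formula_i."""

    residuals: dict[str, dict[str, float]]
    missing_formula: list[tuple[str, str]]  # (reaction id, metabolite id)
    tolerance: float = BALANCE_TOL

    @property
    def violations(self) -> list[tuple[str, str, float]]:
        out = []
        for rid, per_el in self.residuals.items():
            for el, res in per_el.items():
                if abs(res) > self.tolerance:
                    out.append((rid, el, res))
        return out

    @property
    def is_balanced(self) -> bool:
        return not self.violations and not self.missing_formula

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction_id\telement\tresidual\n")
            for rid, per_el in self.residuals.items():
                for el, res in per_el.items():
                    fh.write(f"{rid}\t{el}\t{res:.9g}\n")


def validate_mass_balance(
    model: MetabolicModel, elements: tuple[str, ...] = BALANCED_ELEMENTS
) -> BalanceReport:
    """Check elemental balance of every enabled reaction.

    The hydrogen residual is corrected by each reaction's declared
    ``proton_exchange`` (transformed-thermodynamics convention in which
    explicit H+ is absorbed into Keq).  A metabolite without a formula in
    an enabled reaction is flagged, not fatal.
    """
    residuals: dict[str, dict[str, float]] = {}
    missing: list[tuple[str, str]] = []
    for rxn in model.enabled_reactions:
        per_el = {el: 0.0 for el in elements}
        for mid, coef in rxn.stoichiometry.items():
            met = model.metabolite(mid)
            if met.formula is None or met.formula.is_empty():
                missing.append((rxn.id, mid))
                continue
            for el in elements:
                per_el[el] += coef * met.formula.get(el)
        per_el["H"] = per_el.get("H", 0.0) - rxn.proton_exchange
        residuals[rxn.id] = per_el
    return BalanceReport(residuals=residuals, missing_formula=missing)


def stoichiometric_rank(model: MetabolicModel, rtol: float = RANK_RTOL) -> int:
    """Numerical rank of the (enabled-column) stoichiometric matrix.

    Singular values below ``rtol * sigma_max`` are treated as zero.
    """
    S, _, rids = model.stoichiometric_matrix(rows="all")
    if S.size == 0 or not rids:
        return 0
    sv = np.linalg.svd(S, compute_uv=False)
    if sv.size == 0 or sv[0] == 0:
        return 0
    return int(np.sum(sv > rtol * sv[0]))


def set_reaction_enabled(
    model: MetabolicModel, reaction_id: str, enabled: bool
) -> MetabolicModel:
    """Return a copy of the model with one reaction switched on or off.

    Disabled reactions are retained but excluded from the stoichiometric
    matrix, fluxes and optimization.
    """
    new = model.copy()
    new.reaction(reaction_id).enabled = enabled  # KeyError if unknown
    new.validate()
    return new


# ---- JSON I/O ----------------------------------------------------------------


def _metabolite_to_json(m: Metabolite) -> dict:
    d: dict = {"id": m.id}
    if m.name:
        d["name"] = m.name
    if m.formula is not None and not m.formula.is_empty():
        d["formula"] = m.formula.to_string()
    if m.is_fixed:
        d["is_fixed"] = True
        d["fixed_concentration"] = m.fixed_concentration
    if m.upper_bound is not None:
        d["upper_bound"] = m.upper_bound
    return d


def _reaction_to_json(r: Reaction) -> dict:
    d: dict = {"id": r.id, "stoichiometry": dict(r.stoichiometry), "keq": r.keq}
    if r.name:
        d["name"] = r.name
    if r.is_growth:
        d["is_growth"] = True
    if not r.enabled:
        d["enabled"] = False
    if r.deltaG0_offset:
        d["deltaG0_offset"] = r.deltaG0_offset
    if r.proton_exchange:
        d["proton_exchange"] = r.proton_exchange
    return d


def dumps_model(model: MetabolicModel) -> str:
    config = dict(model.config)
    if model.carbon_source_id is not None:
        config["carbon_source"] = model.carbon_source_id
    config["uptake_rate_scale"] = model.uptake_rate_scale
    doc = {
        "metabolites": [_metabolite_to_json(m) for m in model.metabolites],
        "reactions": [_reaction_to_json(r) for r in model.reactions],
        "config": config,
    }
    return json.dumps(doc, indent=1, sort_keys=False)


def write_model(model: MetabolicModel, path: str | Path) -> None:
    Path(path).write_text(dumps_model(model))


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ModelValidationError(f"{where}: missing required field {key!r}")
    return d[key]


def loads_model(text: str) -> MetabolicModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelValidationError("top level must be a JSON object")
    mets = []
    for d in _require(doc, "metabolites", "model"):
        mets.append(
            Metabolite(
                id=_require(d, "id", "metabolite"),
                name=d.get("name", ""),
                formula=ElementFormula.parse(d["formula"]) if d.get("formula") else None,
                is_fixed=bool(d.get("is_fixed", False)),
                fixed_concentration=d.get("fixed_concentration"),
                upper_bound=d.get("upper_bound"),
            )
        )
    rxns = []
    for d in _require(doc, "reactions", "model"):
        rid = _require(d, "id", "reaction")
        rxns.append(
            Reaction(
                id=rid,
                stoichiometry={
                    str(k): float(v)
                    for k, v in _require(d, "stoichiometry", f"reaction {rid!r}").items()
                },
                keq=float(_require(d, "keq", f"reaction {rid!r}")),
                name=d.get("name", ""),
                is_growth=bool(d.get("is_growth", False)),
                enabled=bool(d.get("enabled", True)),
                deltaG0_offset=float(d.get("deltaG0_offset", 0.0)),
                proton_exchange=float(d.get("proton_exchange", 0.0)),
            )
        )
    config = dict(doc.get("config", {}))
    carbon_source = config.pop("carbon_source", None)
    uptake = float(config.pop("uptake_rate_scale", 1000.0))
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        carbon_source_id=carbon_source,
        uptake_rate_scale=uptake,
        config=config,
    )


def load_model(path: str | Path) -> MetabolicModel:
    """Load and validate a model from the JSON schema documented above."""
    return loads_model(Path(path).read_text())


# ---- delimited-table importer -------------------------------------------------

_ARROWS = ("<=>", "<->", "->", "=", "⇌", "→")


def _parse_side(side: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for term in side.split("+"):
        term = term.strip()
        if not term:
            continue
        m = re.match(r"^(\d+\.?\d*|\.\d+)\s+(.*)$", term)
        if m:
            coef, species = float(m.group(1)), m.group(2).strip()
        else:
            coef, species = 1.0, term
        out[species] = out.get(species, 0.0) + coef
    return out


def parse_equation(equation: str) -> dict[str, float]:
    """Parse ``"2 A + B <=> C"`` into signed stoichiometry (reactants < 0)."""
    for arrow in _ARROWS:
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            break
    else:
        raise ModelValidationError(f"no reaction arrow found in {equation!r}")
    stoich: dict[str, float] = {}
    for mid, c in _parse_side(left).items():
        stoich[mid] = stoich.get(mid, 0.0) - c
    for mid, c in _parse_side(right).items():
        stoich[mid] = stoich.get(mid, 0.0) + c
    return {m: c for m, c in stoich.items() if c != 0}


def import_tables(
    reactions_path: str | Path,
    metabolites_path: str | Path,
    sep: str = "\t",
    carbon_source: str | None = None,
) -> MetabolicModel:
    """Build a model from two delimited tables.

    The reactions table needs columns ``id``, ``equation``, ``keq``
    (optional ``is_growth``, ``enabled``, ``deltaG0_offset``); the
    metabolites table needs ``id`` (optional ``name``, ``formula``,
    ``is_fixed``, ``fixed_concentration``, ``upper_bound``).
    """
    import pandas as pd

    rxn_df = pd.read_csv(reactions_path, sep=sep)
    met_df = pd.read_csv(metabolites_path, sep=sep)
    for col in ("id", "equation", "keq"):
        if col not in rxn_df.columns:
            raise ModelValidationError(f"reactions table: missing column {col!r}")
    if "id" not in met_df.columns:
        raise ModelValidationError("metabolites table: missing column 'id'")

    def _truthy(v) -> bool:
        if isinstance(v, str):
            return v.strip().lower() in ("1", "true", "yes", "y")
        return bool(v) and not (isinstance(v, float) and math.isnan(v))

    def _num(v):
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    mets = []
    for _, row in met_df.iterrows():
        fx = _truthy(row.get("is_fixed", False))
        mets.append(
            Metabolite(
                id=str(row["id"]),
                name=str(row.get("name", "") or ""),
                formula=ElementFormula.parse(str(row["formula"]))
                if isinstance(row.get("formula"), str) and str(row.get("formula")).strip()
                else None,
                is_fixed=fx,
                fixed_concentration=_num(row.get("fixed_concentration")) if fx else None,
                upper_bound=_num(row.get("upper_bound")),
            )
        )
    rxns = []
    for _, row in rxn_df.iterrows():
        rxns.append(
            Reaction(
                id=str(row["id"]),
                stoichiometry=parse_equation(str(row["equation"])),
                keq=float(row["keq"]),
                name=str(row.get("name", "") or ""),
                is_growth=_truthy(row.get("is_growth", False)),
                enabled=not _truthy(row.get("disabled", False))
                if "disabled" in rxn_df.columns
                else (_truthy(row["enabled"]) if "enabled" in rxn_df.columns else True),
                deltaG0_offset=float(row.get("deltaG0_offset", 0.0) or 0.0),
            )
        )
    return MetabolicModel(metabolites=mets, reactions=rxns, carbon_source_id=carbon_source)
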