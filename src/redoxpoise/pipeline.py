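"""End-to-end redox sweep: PCO per condition plus the standard readouts.

For each target thermodynamic odds, the NADP+/NADPH boundary is set via
the reference-reaction parameterization, the pathway-controlled
optimization is run (with minimal redox perturbation on convergence
failure), and the study's readouts are collected: growth objective and
rate, marker-reaction fluxes (CO2 assimilation routes), observed redox
pair ratios of the free species, and the net exchange of every boundary
metabolite normalized to a carbon uptake of 1000.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import MetabolicModel
from .pco import PcoHyperparams, PcoSolution, retry_with_perturbed_redox
from .thermo import DEFAULT_CONTEXT, RedoxCondition, ThermoContext

__all__ = [
    "SweepRecord",
    "SweepResult",
    "run_sweep",
    "observed_redox_ratios",
    "net_boundary_exchange",
    "growth_rate",
]


@dataclass
class SweepRecord:
    target_odds: float
    actual_odds: float
    nadp_ratio: float
    failed: bool
    objective: float
    growth_rate: float
    marker_fluxes: dict[str, float] = field(default_factory=dict)
    redox_ratios: dict[str, float] = field(default_factory=dict)
    boundary_exchange: dict[str, float] = field(default_factory=dict)
    net_co2: float = float("nan")
    status: str = ""
    solution: PcoSolution | None = field(default=None, repr=False)


@dataclass
class SweepResult:
    records: list[SweepRecord]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {
                "target_odds": rec.target_odds,
                "actual_odds": rec.actual_odds,
                "nadp_ratio": rec.nadp_ratio,
                "failed": rec.failed,
                "objective": rec.objective,
                "growth_rate": rec.growth_rate,
                "net_co2": rec.net_co2,
                "status": rec.status,
            }
            row.update({f"flux_{k}": v for k, v in rec.marker_fluxes.items()})
            row.update({f"ratio_{k}": v for k, v in rec.redox_ratios.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(outdir / "sweep.tsv", sep="\t", index=False)
        manifest = [
            {
                "target_odds": r.target_odds,
                "actual_odds": r.actual_odds,
                "failed": r.failed,
                "status": r.status,
            }
            for r in self.records
        ]
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def growth_rate(solution: PcoSolution, model: MetabolicModel) -> float:
    """Summed normalized flux through the growth reactions."""
    return float(
        sum(solution.fluxes.get(r.id, 0.0) for r in model.growth_reactions)
    )


def net_boundary_exchange(
    solution: PcoSolution, model: MetabolicModel
) -> dict[str, float]:
    """Net production rate of every fixed (boundary) metabolite.

    ``S_fixed_rows @ flux`` on the uptake-normalized fluxes; negative
    values mean consumption.
    """
    S_fix, fixed_ids, rids = model.stoichiometric_matrix(rows="fixed")
    xi = np.array([solution.fluxes.get(rid, 0.0) for rid in rids])
    rates = S_fix @ xi
    return {mid: float(v) for mid, v in zip(fixed_ids, rates)}


def observed_redox_ratios(
    solution: PcoSolution,
    pairs: dict[str, tuple[str, str]] | list[tuple[str, str]],
    model: MetabolicModel | None = None,
) -> dict[str, float]:
    """Concentration ratios [ox]/[red] of the free (unbound) species.

    These are thermodynamic, unbound-species ratios and deliberately not
    whole-cell assay values.  Pairs with a missing or non-positive species
    are skipped with a warning.
    """
    if isinstance(pairs, list):
        pairs = {f"{ox}/{red}": (ox, red) for ox, red in pairs}
    conc = dict(solution.concentrations)
    if model is not None:
        conc.update(model.fixed_concentrations())
    elif solution.model is not None:
        conc.update(solution.model.fixed_concentrations())
    out: dict[str, float] = {}
    for label, (ox, red) in pairs.items():
        c_ox, c_red = conc.get(ox), conc.get(red)
        if not c_ox or not c_red or c_ox <= 0 or c_red <= 0:
            warnings.warn(f"redox pair {label}: species missing or non-positive; skipped")
            continue
        out[label] = c_ox / c_red
    return out


def run_sweep(
    model: MetabolicModel,
    odds_values: list[float],
    hp: PcoHyperparams | None = None,
    ctx: ThermoContext = DEFAULT_CONTEXT,
    markers: dict[str, str] | None = None,
    redox_pairs: dict[str, tuple[str, str]] | None = None,
) -> SweepResult:
    """Run PCO across a list of target oxidation odds.

    Marker-reaction ids and redox pairs default to the model config
    (``markers`` / ``redox_pairs`` sections).  Failed conditions keep
    their slot in the result, flagged, never silently dropped.
    """
    hp = hp or PcoHyperparams()
    if markers is None:
        markers = dict(model.config.get("markers", {}))
    if redox_pairs is None:
        redox_pairs = {
            k: tuple(v) for k, v in model.config.get("redox_pairs", {}).items()
        }
    co2_id = model.config.get("co2_id")
    records = []
    for odds in odds_values:
        condition = RedoxCondition.from_odds(odds, ctx)
        sol = retry_with_perturbed_redox(model, condition, hp=hp, ctx=ctx)
        used = sol.condition or condition
        if sol.failed:
            records.append(
                SweepRecord(
                    target_odds=odds,
                    actual_odds=used.actual_odds,
                    nadp_ratio=used.nadp_ratio,
                    failed=True,
                    objective=float("nan"),
                    growth_rate=float("nan"),
                    status=sol.status,
                    solution=sol,
                )
            )
            continue
        work = sol.model or model
        exchange = net_boundary_exchange(sol, work)
        records.append(
            SweepRecord(
                target_odds=odds,
                actual_odds=used.actual_odds,
                nadp_ratio=used.nadp_ratio,
                failed=False,
                objective=sol.objective,
                growth_rate=growth_rate(sol, work),
                marker_fluxes={
                    name: sol.fluxes.get(rid, float("nan"))
                    for name, rid in markers.items()
                },
                redox_ratios=observed_redox_ratios(sol, redox_pairs, work)
                if redox_pairs
                else {},
                boundary_exchange=exchange,
                net_co2=exchange.get(co2_id, float("nan")) if co2_id else float("nan"),
                status=sol.status,
                solution=sol,
            )
        )
    return SweepResult(records=records)
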