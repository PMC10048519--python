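"""Static in vitro oral-gastric-intestinal digestion bookkeeping.

The protocol is the standardized static simulation: three electrolyte fluids
(SSF pH 7, SGF pH 3, SIF pH 7) are prepared by diluting salt stocks to a
500 mL final volume, and a sample is pushed through three phases:

* oral       — sample + alpha-amylase + SSF + CaCl2 + water, 2 min, 37 C, 55 rpm
* gastric    — digesta + SGF (1:1 v/v by default) + pepsin to 2000 U/mL, pH 3, 2 h
* intestinal — digesta + SIF (1:1 v/v) + pancreatin to 2000 U/mL + bile to
               0.16 mol/L, pH 7, 2 h

This module is pure bookkeeping: dilution algebra, volume conservation, and
enzyme/bile targets.  Enzymes are treated as dry additions (no volume) with
opaque activity units; bile is dosed from a liquid stock by closed-form
dilution.  No proteolysis kinetics are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "StockComponent",
    "FluidRecipe",
    "PhasePlan",
    "Addition",
    "component_final_conc",
    "dilution_volume_for_target",
    "validate_recipe",
    "builtin_recipes",
    "plan_oral",
    "plan_gastric",
    "plan_intestinal",
    "full_plan",
    "simulate_tracer",
    "load_protocol",
]

FLUID_PH = {"SSF": 7.0, "SGF": 3.0, "SIF": 7.0}

#: Reference oral-phase recipe per 10 mL of sample (volumes in mL).
_ORAL_PER_10ML = {
    "alpha-amylase (1500 U/mL)": 1.0,
    "SSF electrolyte": 8.0,
    "CaCl2 (0.3 mol/L)": 0.05,
    "water": 1.95,
}


@dataclass(frozen=True)
class StockComponent:
    name: str
    stock_conc: float  # mol/L
    volume_ml: float
    declared_final: str  # declared final concentration, mmol/L, as printed

    def __post_init__(self):
        if self.volume_ml < 0:
            raise ValueError("component volume must be non-negative")


@dataclass(frozen=True)
class FluidRecipe:
    fluid: str  # SSF | SGF | SIF
    ph: float
    components: tuple[StockComponent, ...]
    final_volume_ml: float = 500.0


@dataclass(frozen=True)
class Addition:
    name: str
    volume_ml: float
    note: str = ""


@dataclass(frozen=True)
class PhasePlan:
    phase: str  # oral | gastric | intestinal
    input_volume_ml: float
    additions: tuple[Addition, ...]
    target_ph: float
    incubation: tuple[float, float, float]  # (rpm, deg C, minutes)
    resulting_volume_ml: float
    final_concentrations: dict = field(default_factory=dict)
    assumptions: tuple[str, ...] = ()


def component_final_conc(
    stock_conc: float, volume_ml: float, final_volume_ml: float
) -> float:
    """Final concentration in mmol/L of a stock aliquot diluted to volume."""
    if final_volume_ml <= 0:
        raise ValueError("final volume must be positive")
    if volume_ml < 0:
        raise ValueError("volume must be non-negative")
    return stock_conc * volume_ml / final_volume_ml * 1000.0


def dilution_volume_for_target(
    stock_conc: float, target_conc: float, volume_ml: float
) -> float:
    """Stock volume v so that stock*v / (V + v) == target (c1v1 = c2v2).

    Raises if the stock is not strictly stronger than the target.
    """
    if stock_conc <= target_conc:
        raise ValueError(
            f"stock concentration {stock_conc} cannot reach target {target_conc}"
        )
    if target_conc < 0 or volume_ml < 0:
        raise ValueError("target and volume must be non-negative")
    return target_conc * volume_ml / (stock_conc - target_conc)


def _declared_decimals(declared: str) -> int:
    return len(declared.split(".")[1]) if "." in declared else 0


def validate_recipe(recipe: FluidRecipe) -> list[dict]:
    """Check every component's computed vs declared final concentration.

    The comparison rounds the computed value to the precision the declared
    value is printed at (e.g. 6 M x 0.09 mL / 500 mL = 1.08 -> declared 1.1).
    """
    total = sum(c.volume_ml for c in recipe.components)
    if total > recipe.final_volume_ml:
        raise ValueError(
            f"component volumes ({total} mL) exceed the final volume "
            f"({recipe.final_volume_ml} mL)"
        )
    report = []
    for c in recipe.components:
        computed = component_final_conc(c.stock_conc, c.volume_ml, recipe.final_volume_ml)
        declared = float(c.declared_final)
        ok = round(computed, _declared_decimals(c.declared_final)) == declared
        report.append(
            {
                "fluid": recipe.fluid,
                "component": c.name,
                "computed_mmol_per_l": computed,
                "declared_mmol_per_l": declared,
                "match": ok,
            }
        )
    return report


def builtin_recipes() -> dict[str, FluidRecipe]:
    """The three electrolyte recipes (500 mL final volume, water to volume)."""
    rows = {
        # name, stock mol/L, (SSF vol, declared), (SGF vol, declared), (SIF vol, declared)
        "KCl": (0.5, (15.1, "15.1"), (6.9, "6.9"), (6.8, "6.8")),
        "KH2PO4": (0.5, (3.7, "3.7"), (0.9, "0.9"), (0.8, "0.8")),
        "NaHCO3": (1.0, (6.8, "13.6"), (12.5, "25"), (42.5, "85")),
        "NaCl": (2.0, None, (11.8, "47.2"), (9.6, "38.4")),
        "MgCl2(H2O)6": (0.15, (0.5, "0.15"), (0.4, "0.1"), (1.1, "0.33")),
        "(NH4)2CO3": (0.5, (0.06, "0.06"), (0.5, "0.5"), None),
        "HCl": (6.0, (0.09, "1.1"), (1.3, "15.6"), (0.7, "8.4")),
    }
    recipes = {}
    for i, fluid in enumerate(("SSF", "SGF", "SIF")):
        comps = []
        for name, spec in rows.items():
            stock, entries = spec[0], spec[1:]
            entry = entries[i]
            if entry is None:
                continue
            vol, declared = entry
            comps.append(StockComponent(name, stock, vol, declared))
        recipes[fluid] = FluidRecipe(fluid=fluid, ph=FLUID_PH[fluid], components=tuple(comps))
    return recipes


def plan_oral(sample_volume_ml: float = 10.0) -> PhasePlan:
    """Oral phase: additions scale proportionally with the sample volume.

    The 10 mL reference uses 1 mL amylase (1500 U/mL), 8 mL SSF, 0.05 mL
    CaCl2 (0.3 mol/L) and 1.95 mL water -> 21 mL total, amylase ~71.4 U/mL
    and CaCl2 ~0.714 mmol/L in the mixture.
    """
    if sample_volume_ml <= 0:
        raise ValueError("sample volume must be positive")
    scale = sample_volume_ml / 10.0
    additions = tuple(
        Addition(name, vol * scale) for name, vol in _ORAL_PER_10ML.items()
    )
    resulting = sample_volume_ml + sum(a.volume_ml for a in additions)
    amylase_vol = additions[0].volume_ml
    cacl2_vol = additions[2].volume_ml
    return PhasePlan(
        phase="oral",
        input_volume_ml=sample_volume_ml,
        additions=additions,
        target_ph=FLUID_PH["SSF"],
        incubation=(55.0, 37.0, 2.0),
        resulting_volume_ml=resulting,
        final_concentrations={
            "amylase_u_per_ml": 1500.0 * amylase_vol / resulting,
            "cacl2_mmol_per_l": 0.3 * cacl2_vol / resulting * 1000.0,
        },
    )


def _enzyme_phase(
    phase: str,
    plan_in: PhasePlan,
    fluid: str,
    ratio: float,
    enzyme: str,
    enzyme_target_u_per_ml: float,
    target_ph: float,
    bile_target_mol_per_l: float = 0.0,
    bile_stock_mol_per_l: float = 1.0,
    ph_adjust_volume_ml: float = 0.0,
    cacl2_ml_per_ml: float = 0.05 / 21.0,
) -> PhasePlan:
    if ratio < 0:
        raise ValueError("mixing ratio must be non-negative")
    v_in = plan_in.resulting_volume_ml
    additions = [Addition(f"{fluid} electrolyte", ratio * v_in)]
    assumptions = [
        f"digesta:{fluid} mixing ratio 1:{ratio:g} v/v assumed (protocol states "
        "only 'a certain proportion')",
    ]
    v = v_in + ratio * v_in
    cacl2_vol = cacl2_ml_per_ml * v
    if cacl2_vol > 0:
        additions.append(Addition("CaCl2 (0.3 mol/L)", cacl2_vol))
        v += cacl2_vol
        assumptions.append(
            "CaCl2 dose extrapolated from the oral-phase pattern scaled by volume"
        )
    if bile_target_mol_per_l > 0:
        bile_vol = dilution_volume_for_target(bile_stock_mol_per_l, bile_target_mol_per_l, v)
        additions.append(
            Addition(
                f"bile ({bile_stock_mol_per_l:g} mol/L stock)",
                bile_vol,
                note=f"to {bile_target_mol_per_l:g} mol/L final",
            )
        )
        v += bile_vol
    additions.append(
        Addition(
            enzyme,
            0.0,
            note=f"dry, to {enzyme_target_u_per_ml:g} U/mL final in {v:g} mL",
        )
    )
    if ph_adjust_volume_ml > 0:
        additions.append(Addition("HCl/NaOH (1 M) to target pH", ph_adjust_volume_ml))
        v += ph_adjust_volume_ml
    concs = {f"{enzyme}_u_per_ml": enzyme_target_u_per_ml}
    if bile_target_mol_per_l > 0:
        concs["bile_mol_per_l"] = bile_target_mol_per_l
    return PhasePlan(
        phase=phase,
        input_volume_ml=v_in,
        additions=tuple(additions),
        target_ph=target_ph,
        incubation=(55.0, 37.0, 120.0),
        resulting_volume_ml=v,
        final_concentrations=concs,
        assumptions=tuple(assumptions),
    )


def plan_gastric(plan_in: PhasePlan, ratio: float = 1.0, **kw) -> PhasePlan:
    """Gastric phase: digesta + SGF at ratio v/v, pepsin to 2000 U/mL, pH 3."""
    return _enzyme_phase(
        "gastric", plan_in, "SGF", ratio, "pepsin", 2000.0, FLUID_PH["SGF"], **kw
    )


def plan_intestinal(plan_in: PhasePlan, ratio: float = 1.0, **kw) -> PhasePlan:
    """Intestinal phase: digesta + SIF at ratio v/v, pancreatin to 2000 U/mL,
    bile to 0.16 mol/L, pH 7."""
    kw.setdefault("bile_target_mol_per_l", 0.16)
    return _enzyme_phase(
        "intestinal", plan_in, "SIF", ratio, "pancreatin", 2000.0, FLUID_PH["SIF"], **kw
    )


def full_plan(
    sample_volume_ml: float = 10.0,
    gastric_ratio: float = 1.0,
    intestinal_ratio: float = 1.0,
    **kw,
) -> list[PhasePlan]:
    oral = plan_oral(sample_volume_ml)
    gastric = plan_gastric(oral, ratio=gastric_ratio, **kw)
    intestinal = plan_intestinal(gastric, ratio=intestinal_ratio, **kw)
    return [oral, gastric, intestinal]


def simulate_tracer(
    plans: list[PhasePlan], tracer_conc: float, sample_volume_ml: float
) -> list[dict]:
    """Push a conserved, non-interacting tracer through the plan.

    The tracer amount never changes; only the volume grows, so the free
    concentration is amount / volume and the release rate of each phase is
    exactly 100% — the null test of the volume bookkeeping.
    """
    amount = tracer_conc * sample_volume_ml
    out = []
    for plan in plans:
        v = plan.resulting_volume_ml
        conc = amount / v
        out.append(
            {
                "phase": plan.phase,
                "volume_ml": v,
                "tracer_conc": conc,
                "free_amount": conc * v,
                "total_amount": amount,
                "release_pct": 100.0 * (conc * v) / amount,
            }
        )
    return out


def load_protocol(path) -> list[PhasePlan]:
    """Build a plan from a YAML protocol config.

    Recognised keys: sample_volume_ml, gastric_ratio, intestinal_ratio,
    ph_adjust_volume_ml.  Missing keys fall back to the built-in defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return full_plan(
        sample_volume_ml=cfg.get("sample_volume_ml", 10.0),
        gastric_ratio=cfg.get("gastric_ratio", 1.0),
        intestinal_ratio=cfg.get("intestinal_ratio", 1.0),
        ph_adjust_volume_ml=cfg.get("ph_adjust_volume_ml", 0.0),
    )
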