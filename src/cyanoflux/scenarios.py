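"""Named analysis conditions for phototrophic and dark metabolism.

Each scenario is a :class:`ScenarioConfig` — a complete, serializable set
of constraint parameters and topology toggles — applied to a compatible
model through a functional *role map* (role name -> reaction id), so the
suite works with any network that exposes the required roles.

Conditions encoded here:

* the phototrophic reference — light-limited growth at a 24 h doubling
  time, carbon as bicarbonate only, nitrate nitrogen, maintenance ATP, and
  residual light-phase respiratory activity (terminal oxidase and the
  Mehler-like reaction each coupled to 10% of PSII oxygen evolution,
  superoxide formation to 0.5% of PSII/PSI electron flow);
* dark metabolism — biomass maximization under a glycogen budget that only
  slightly exceeds the maintenance requirement, with transhydrogenase /
  NDH-1 substrate variants;
* the four TCA-cycle closure variants;
* photorespiration scenarios 1-3 (phosphoserine pathway absent / present /
  present with the oxygenase forced to 3% of carboxylase flux);
* the acetate + DCMU photoheterotrophy test for the glyoxylate shunt.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

from .fba import (
    LinearConstraint,
    ObjectiveSpec,
    SolverError,
    add_ratio_constraint,
    flux_variability,
    solve_fba,
)
from .model import MetabolicModel
from .synth import TCA_CLOSURE_REACTIONS, TCA_CYCLE_SETS, core_model_roles

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "ConfigurationError",
    "apply_scenario",
    "phototrophic_reference",
    "dark_metabolism",
    "compare_tca_variants",
    "photorespiration_analysis",
    "acetate_dcmu_test",
    "calibrate_light_limit",
]

GROWTH_RATE_24H = math.log(2) / 24.0  # h^-1, 24 h doubling time

CARBON_SOURCES = ("bicarbonate", "acetate", "none")
TH_MODES = ("reversible", "NADPH_to_NADH_only", "absent")
NDH1_MODES = ("NADPH_only", "both")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioConfig:
    """All tunable constraint parameters and topology toggles for one
    analysis condition.  Flux units are mmol gDW^-1 h^-1."""

    growth_rate_target: float = GROWTH_RATE_24H
    carbon_source: str = "bicarbonate"
    nitrogen_nitrate: bool = True
    maintenance_atp: float = 0.13
    oxidase_fraction: float = 0.10        # of PSII O2 evolution
    mehler_like_fraction: float = 0.10    # of PSII O2 evolution
    ros_fraction: float = 0.005           # of PSII and PSI electron flow
    oxygenase_min_ratio: float = 0.03     # lower bound on v_oxy / v_carb
    storage_flux: float = 0.01            # glycogen accumulation in light
    phosphoserine_present: bool = True
    glyoxylate_shunt_present: bool = False
    tca_variant: str = "bypass"
    transhydrogenase_mode: str = "reversible"
    ndh1_substrate: str = "NADPH_only"
    gdh_irreversible: bool = True
    glycogen_cap: float | None = None     # dark scenarios; None = derived
    glycogen_cap_epsilon: float = 0.1
    dcmu: bool = False
    light_limit: float | None = None      # None = calibrated to growth target

    def __post_init__(self) -> None:
        if self.carbon_source not in CARBON_SOURCES:
            raise ConfigurationError(f"unknown carbon source {self.carbon_source!r}")
        if self.transhydrogenase_mode not in TH_MODES:
            raise ConfigurationError(
                f"unknown transhydrogenase mode {self.transhydrogenase_mode!r}")
        if self.ndh1_substrate not in NDH1_MODES:
            raise ConfigurationError(
                f"unknown NDH-1 substrate mode {self.ndh1_substrate!r}")
        for name in ("oxidase_fraction", "mehler_like_fraction", "ros_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.storage_flux < 0 or self.maintenance_atp < 0:
            raise ConfigurationError("caps and maintenance must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        return cls(**data)

    @classmethod
    def from_file(cls, path: str) -> "ScenarioConfig":
        import json

        import yaml

        with open(path) as fh:
            text = fh.read()
        data = json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    solution: "FluxSolution"
    indicators: dict[str, float] = field(default_factory=dict)
    fva: dict[str, tuple[float, float]] | None = None

    @property
    def growth_rate(self) -> float:
        return self.indicators.get("growth_rate", float("nan"))


# ---------------------------------------------------------------------------


def _role(roles: dict[str, str], name: str, model: MetabolicModel) -> str:
    try:
        rid = roles[name]
    except KeyError:
        raise ConfigurationError(f"role map has no entry for role {name!r}") from None
    if not model.has_reaction(rid):
        raise ConfigurationError(
            f"role {name!r} maps to reaction {rid!r}, which is absent from "
            f"model {model.id!r}"
        )
    return rid


def _species_coeff(model: MetabolicModel, rxn_id: str, species: str) -> float:
    return model.reaction(rxn_id).stoichiometry.get(species, 0.0)


def apply_scenario(
    model: MetabolicModel,
    config: ScenarioConfig,
    roles: dict[str, str] | None = None,
):
    """Return ``(model', constraints, objective)`` for one condition.

    The input model is not modified.  Topology toggles remove reactions;
    exchange and process bounds are set; flux-ratio couplings are emitted
    as extra constraint rows.  Respiratory/ROS couplings are tied to PSII
    activity and are only added when PSII can run (light available, no
    DCMU).
    """
    roles = roles or core_model_roles()
    m = model.copy()

    # --- topology toggles ---------------------------------------------
    drop: list[str] = []
    if not config.phosphoserine_present:
        drop += [r for r in ("PGDH", "PSAT", "PSP") if m.has_reaction(r)]
    keep_variant = config.tca_variant
    keep: set[str] = set(TCA_CLOSURE_REACTIONS.get(keep_variant, ()))
    if keep_variant == "all":
        keep = {r for rxns in TCA_CLOSURE_REACTIONS.values() for r in rxns}
    if keep_variant in ("bypass", "GABA"):
        keep.add("SSADH")  # the NADP-dependent dehydrogenase both routes share
    if config.glyoxylate_shunt_present:
        keep |= set(TCA_CLOSURE_REACTIONS["glyoxylate"])
    closure_all = {r for rxns in TCA_CLOSURE_REACTIONS.values() for r in rxns}
    drop += [r for r in closure_all - keep if m.has_reaction(r)]
    if keep_variant in ("bypass", "GABA") and not m.has_reaction("SSADH"):
        raise ConfigurationError(
            f"model lacks the SSADH step required by variant {keep_variant!r}")
    m.remove_reactions(drop)

    # --- redox machinery modes ----------------------------------------
    th = m.reaction(_role(roles, "transhydrogenase", m))
    if config.transhydrogenase_mode == "absent":
        th.lower_bound = th.upper_bound = 0.0
    elif config.transhydrogenase_mode == "NADPH_to_NADH_only":
        th.lower_bound = 0.0
    if config.ndh1_substrate != "both":
        ndh = m.reaction(_role(roles, "ndh1_nadh", m))
        ndh.lower_bound = ndh.upper_bound = 0.0
    if config.gdh_irreversible:
        m.reaction(_role(roles, "gdh", m)).lower_bound = 0.0

    # --- exchanges ----------------------------------------------------
    hco3 = m.reaction(_role(roles, "bicarbonate_exchange", m))
    ace = m.reaction(_role(roles, "acetate_exchange", m))
    hco3.lower_bound = 0.0
    ace.lower_bound = ace.upper_bound = 0.0
    if config.carbon_source == "bicarbonate":
        hco3.lower_bound = -1000.0
    elif config.carbon_source == "acetate":
        ace.lower_bound, ace.upper_bound = -1000.0, 0.0
    if not config.nitrogen_nitrate:
        m.reaction("EX_no3").lower_bound = 0.0

    light = config.light_limit if config.light_limit is not None else 1000.0
    photon = m.reaction(_role(roles, "photon_exchange", m))
    photon.lower_bound = -abs(light)

    psii = _role(roles, "psii", m)
    if config.dcmu:
        r = m.reaction(psii)
        r.lower_bound = r.upper_bound = 0.0

    # --- maintenance and storage --------------------------------------
    m.reaction(_role(roles, "atp_maintenance", m)).lower_bound = config.maintenance_atp
    dark = light == 0
    sink = m.reaction(_role(roles, "glycogen_sink", m))
    source = m.reaction(_role(roles, "glycogen_source", m))
    sink.lower_bound = sink.upper_bound = 0.0
    source.lower_bound = source.upper_bound = 0.0
    if dark:
        cap = config.glycogen_cap
        if cap is None:
            cap = derive_glycogen_cap(m, config, roles)
        source.upper_bound = cap
    else:
        sink.lower_bound = sink.upper_bound = config.storage_flux

    # --- coupling rows ------------------------------------------------
    constraints: list[LinearConstraint] = []
    psii_active = not dark and not config.dcmu
    if psii_active:
        o2_psii = _species_coeff(m, psii, "o2")  # O2 evolved per unit flux
        for frac, role in ((config.oxidase_fraction, "oxidase"),
                           (config.mehler_like_fraction, "mehler_like")):
            if frac == 0:
                continue
            rid = _role(roles, role, m)
            uptake = -_species_coeff(m, rid, "o2")  # O2 consumed per unit flux
            # O2 uptake of the process equals frac x PSII O2 evolution
            constraints.append(LinearConstraint(
                {rid: uptake, psii: -frac * o2_psii}, "=", 0.0))
        if config.ros_fraction > 0:
            # electron flow: 4 e- per O2 evolved at PSII, 1 e- per PSI
            # turnover, 1 e- per superoxide formed
            ros2 = _role(roles, "ros_psii", m)
            el = _species_coeff(m, ros2, "ho2")
            constraints.append(LinearConstraint(
                {ros2: el, psii: -config.ros_fraction * 4 * o2_psii}, "=", 0.0))
            ros1 = _role(roles, "ros_psi", m)
            psi = _role(roles, "psi", m)
            el1 = _species_coeff(m, ros1, "ho2")
            constraints.append(LinearConstraint(
                {ros1: el1, psi: -config.ros_fraction}, "=", 0.0))

    if config.oxygenase_min_ratio > 0 and psii_active:
        constraints.append(add_ratio_constraint(
            _role(roles, "oxygenase", m), _role(roles, "carboxylase", m),
            config.oxygenase_min_ratio, ">="))

    objective = ObjectiveSpec.maximize(_role(roles, "biomass", m))
    return m, constraints, objective


def derive_glycogen_cap(
    model: MetabolicModel, config: ScenarioConfig, roles: dict[str, str]
) -> float:
    """Glycogen budget for dark metabolism: (1 + eps) times the minimal
    glycogen mobilization that covers maintenance ATP alone (growth off)."""
    m = model.copy()
    m.reaction(_role(roles, "biomass", m)).upper_bound = 0.0
    source = _role(roles, "glycogen_source", m)
    m.reaction(source).upper_bound = 1000.0
    m.reaction(_role(roles, "atp_maintenance", m)).lower_bound = config.maintenance_atp
    sol = solve_fba(m, ObjectiveSpec.minimize(source))
    if not sol.optimal:
        raise SolverError(
            "cannot satisfy maintenance from glycogen (maintenance-equivalent "
            f"problem is {sol.status})")
    return (1.0 + config.glycogen_cap_epsilon) * sol.objective_value


def calibrate_light_limit(
    model: MetabolicModel,
    config: ScenarioConfig,
    roles: dict[str, str] | None = None,
    probe: float = 100.0,
) -> float:
    """Photon-uptake bound at which optimal growth hits the target rate.

    Growth is proportional to the light bound in the light-limited regime,
    so a single probe solve fixes the scale; the result is verified with a
    second solve.
    """
    roles = roles or core_model_roles()
    limit = probe
    growth = None
    for _ in range(3):  # proportional updates; exact once truly light-limited
        cfg = replace(config, light_limit=limit)
        m, cons, obj = apply_scenario(model, cfg, roles)
        sol = solve_fba(m, obj, cons)
        if not sol.optimal or sol.objective_value <= 0:
            raise SolverError("probe problem for light calibration failed")
        growth = sol.objective_value
        if abs(growth - config.growth_rate_target) < 1e-9:
            break
        limit *= config.growth_rate_target / growth
    if abs(growth - config.growth_rate_target) > 1e-6:
        raise SolverError(
            "light calibration failed: growth is not light-limited at the "
            "requested rate")
    return limit


def _indicators(model, config, roles, sol) -> dict[str, float]:
    out = {"growth_rate": sol.objective_value if sol.optimal else float("nan")}
    if not sol.optimal:
        return out
    carb = sol.fluxes.get(roles.get("carboxylase", ""), 0.0)
    oxy = sol.fluxes.get(roles.get("oxygenase", ""), 0.0)
    out["photorespiration_rate"] = 100.0 * oxy / carb if carb > 1e-12 else 0.0
    pgk = sol.fluxes.get(roles.get("pgk", ""), float("nan"))
    pgam = sol.fluxes.get(roles.get("pgam", ""), float("nan"))
    out["pgk_pgm_ratio"] = abs(pgk) / abs(pgam) if abs(pgam) > 1e-12 else float("inf")
    cycle = TCA_CYCLE_SETS.get(config.tca_variant)
    if cycle and all(model.has_reaction(r) for r in cycle):
        out["tca_cyclic_flux"] = min(abs(sol.fluxes[r]) for r in cycle)
    else:
        out["tca_cyclic_flux"] = 0.0
    out["opp_flux"] = abs(sol.fluxes.get(roles.get("opp", ""), 0.0))
    return out


def _run(model, config, roles, fva_reactions=None) -> ScenarioResult:
    m, cons, obj = apply_scenario(model, config, roles)
    sol = solve_fba(m, obj, cons)
    result = ScenarioResult(config=config, solution=sol,
                            indicators=_indicators(m, config, roles, sol))
    if fva_reactions and sol.optimal:
        present = [r for r in fva_reactions if m.has_reaction(r)]
        if present:
            result.fva = flux_variability(m, obj, 1.0, cons, present).ranges
    return result


def phototrophic_reference(
    model: MetabolicModel,
    config: ScenarioConfig | None = None,
    roles: dict[str, str] | None = None,
    with_fva: bool = True,
) -> ScenarioResult:
    """Light-limited reference condition under constant light.

    Because the optimum is degenerate, the result carries fraction-1.0 FVA
    ranges for the fluxes whose values are known to be non-unique (the TCA
    closure steps and the oxygenase), so that zero/non-zero statements are
    made against ranges rather than one arbitrary vertex.
    """
    roles = roles or core_model_roles()
    config = config or ScenarioConfig()
    if config.light_limit is None:
        config = replace(config,
                         light_limit=calibrate_light_limit(model, config, roles))
    fva_set = None
    if with_fva:
        fva_set = [rid for rxns in TCA_CLOSURE_REACTIONS.values() for rid in rxns]
        fva_set.append(roles.get("oxygenase", ""))
    return _run(model, config, roles, fva_set)


def dark_metabolism(
    model: MetabolicModel,
    config: ScenarioConfig | None = None,
    roles: dict[str, str] | None = None,
) -> ScenarioResult:
    """Dark condition: biomass maximization under the glycogen budget."""
    roles = roles or core_model_roles()
    config = config or ScenarioConfig()
    config = replace(config, light_limit=0.0)
    return _run(model, config, roles)


def compare_tca_variants(
    model: MetabolicModel,
    base_config: ScenarioConfig | None = None,
    scenario: str = "dark",
    roles: dict[str, str] | None = None,
) -> dict[str, float]:
    """Optimal objective per TCA-closure variant under identical remaining
    constraints.

    The model must contain all closure variants (build it with
    ``tca_variant="all"``).  For the dark comparison the glycogen budget is
    derived once, from the base configuration, and shared across variants;
    for the phototrophic comparison the calibrated light bound is shared.
    """
    roles = roles or core_model_roles()
    config = base_config or ScenarioConfig()
    if scenario == "dark":
        config = replace(config, light_limit=0.0)
        if config.glycogen_cap is None:
            m0, _, _ = apply_scenario(model, config, roles)
            config = replace(config,
                             glycogen_cap=derive_glycogen_cap(m0, config, roles))
    elif scenario == "phototrophic":
        if config.light_limit is None:
            config = replace(config, light_limit=calibrate_light_limit(
                model, config, roles))
    else:
        raise ConfigurationError(f"unknown comparison scenario {scenario!r}")

    out: dict[str, float] = {}
    for variant in ("OGDH", "bypass", "GABA", "glyoxylate"):
        cfg = replace(config, tca_variant=variant)
        sol = _run(model, cfg, roles).solution
        out[variant] = sol.objective_value if sol.optimal else float("nan")
    return out


def photorespiration_analysis(
    model: MetabolicModel,
    config: ScenarioConfig | None = None,
    scenario_id: int = 1,
    roles: dict[str, str] | None = None,
) -> ScenarioResult:
    """The three serine/glycine provenance scenarios.

    1. no phosphoserine pathway, oxygenase unconstrained — photorespiration
       emerges from the optimization;
    2. phosphoserine pathway present, oxygenase unconstrained —
       photorespiration ceases;
    3. phosphoserine pathway present, oxygenase forced to >= 3% of
       carboxylase flux — the bound binds, and the result carries FVA
       ranges for the two glyoxylate fates (glycine route vs glycerate
       re-entry).
    """
    roles = roles or core_model_roles()
    config = config or ScenarioConfig()
    if scenario_id == 1:
        config = replace(config, phosphoserine_present=False,
                         oxygenase_min_ratio=0.0)
    elif scenario_id == 2:
        config = replace(config, phosphoserine_present=True,
                         oxygenase_min_ratio=0.0)
    elif scenario_id == 3:
        config = replace(config, phosphoserine_present=True,
                         oxygenase_min_ratio=config.oxygenase_min_ratio or 0.03)
    else:
        raise ConfigurationError("scenario_id must be 1, 2 or 3")
    if config.light_limit is None:
        config = replace(config,
                         light_limit=calibrate_light_limit(model, config, roles))
    fva_set = [roles.get("oxygenase", "")]
    if scenario_id == 3:
        fva_set += [roles.get("glycine_route", ""), roles.get("glycerate_route", "")]
    return _run(model, config, roles, fva_set)


def acetate_dcmu_test(
    model: MetabolicModel,
    glyoxylate_shunt_present: bool,
    config: ScenarioConfig | None = None,
    roles: dict[str, str] | None = None,
) -> float:
    """Maximal growth on acetate with PSII blocked by DCMU.

    The photoheterotrophic configuration: acetate as sole carbon source,
    bicarbonate closed to net uptake, PSII off (PSI cyclic electron flow
    and hence light-driven ATP still available).  Returns the optimal
    biomass objective value.
    """
    roles = roles or core_model_roles()
    config = config or ScenarioConfig()
    config = replace(
        config,
        carbon_source="acetate",
        dcmu=True,
        storage_flux=0.0,
        oxygenase_min_ratio=0.0,
        glyoxylate_shunt_present=glyoxylate_shunt_present,
        light_limit=config.light_limit if config.light_limit is not None else 100.0,
    )
    sol = _run(model, config, roles).solution
    return sol.objective_value if sol.optimal else 0.0
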