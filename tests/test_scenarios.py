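"""Scenario suite: reference condition, dark variants, photorespiration,
TCA-closure comparisons and the glyoxylate-shunt growth test."""

import math
from dataclasses import replace

import numpy as np
import pytest

from cyanoflux.fba import LinearConstraint, ObjectiveSpec, solve_fba
from cyanoflux.scenarios import (
    GROWTH_RATE_24H,
    ConfigurationError,
    ScenarioConfig,
    acetate_dcmu_test,
    apply_scenario,
    calibrate_light_limit,
    compare_tca_variants,
    dark_metabolism,
    phototrophic_reference,
    photorespiration_analysis,
)
from cyanoflux.synth import CoreModelToggles, build_core_model, core_model_roles


@pytest.fixture(scope="module")
def reference(core_model_all):
    # keep every closure variant in the model so their FVA ranges exist
    return phototrophic_reference(core_model_all,
                                  ScenarioConfig(tca_variant="all"))


def test_reference_hits_24h_doubling(reference):
    assert reference.growth_rate == pytest.approx(GROWTH_RATE_24H, rel=1e-4)
    assert reference.config.light_limit > 0


def test_reference_satisfies_couplings_exactly(core_model_all, reference):
    sol = reference.solution
    cfg = reference.config
    # oxidase and Mehler-like each take up 10% of PSII O2 evolution
    assert 0.5 * sol["COX"] == pytest.approx(0.1 * sol["PSII"], abs=1e-8)
    assert 0.5 * sol["FLV"] == pytest.approx(0.1 * sol["PSII"], abs=1e-8)
    # superoxide at 0.5% of PSII / PSI electron flow
    assert 2 * sol["ROS_PSII"] == pytest.approx(
        cfg.ros_fraction * 4 * sol["PSII"], abs=1e-8)
    assert sol["MEHLER_PSI"] == pytest.approx(
        cfg.ros_fraction * sol["PSI"], abs=1e-8)


def test_reference_tca_is_noncyclic(reference):
    """The closure shortcuts carry no flux at the phototrophic optimum —
    asserted through FVA ranges, not the returned vertex."""
    for rid in ("OGDC", "SSADH", "OGDH", "GAD"):
        lo, hi = reference.fva[rid]
        assert hi == pytest.approx(0.0, abs=1e-6)
        assert lo == pytest.approx(0.0, abs=1e-6)
    assert reference.indicators["tca_cyclic_flux"] == pytest.approx(0.0, abs=1e-6)


def test_reference_uses_phosphoketolase(reference):
    assert reference.solution["PHK"] > 1e-6


def test_flux_direction_invariant_under_light_intensity(core_model):
    """Scaling the light bound rescales the solution without changing its
    direction (pairwise cosine similarity 1)."""
    roles = core_model_roles()
    cfg = ScenarioConfig(light_limit=None)
    base_light = calibrate_light_limit(core_model, cfg, roles)
    sols = []
    for factor in (1.0, 3.0, 10.0):
        # scale the fixed demands along with the light so the comparison is
        # a pure change of light intensity
        c = replace(cfg, light_limit=base_light * factor,
                    storage_flux=cfg.storage_flux * factor,
                    maintenance_atp=cfg.maintenance_atp * factor)
        m, cons, obj = apply_scenario(core_model, c, roles)
        sols.append(solve_fba(m, obj, cons))
    vecs = [np.array([s.fluxes[r] for r in sorted(sols[0].fluxes)]) for s in sols]
    for v in vecs[1:]:
        cos = v @ vecs[0] / (np.linalg.norm(v) * np.linalg.norm(vecs[0]))
        assert cos == pytest.approx(1.0, abs=1e-6)


# --- dark metabolism -------------------------------------------------------

@pytest.mark.parametrize("th,ndh1,expect_cyclic", [
    ("reversible", "NADPH_only", True),
    ("absent", "NADPH_only", False),
    ("NADPH_to_NADH_only", "NADPH_only", False),
    ("absent", "both", True),
])
def test_dark_redox_routing(core_model, th, ndh1, expect_cyclic):
    """Transhydrogenase / NDH-1 assumptions flip respiration between cyclic
    TCA flux and the oxidative pentose phosphate pathway."""
    cfg = ScenarioConfig(transhydrogenase_mode=th, ndh1_substrate=ndh1)
    res = dark_metabolism(core_model, cfg)
    assert res.solution.optimal
    if expect_cyclic:
        assert res.indicators["tca_cyclic_flux"] > 1e-6
        assert res.indicators["opp_flux"] == pytest.approx(0.0, abs=1e-6)
    else:
        assert res.indicators["tca_cyclic_flux"] == pytest.approx(0.0, abs=1e-6)
        assert res.indicators["opp_flux"] > 1e-6


def test_dark_requires_feasible_glycogen_budget(core_model):
    cfg = ScenarioConfig(glycogen_cap=1e-9)  # far below maintenance needs
    res = dark_metabolism(core_model, cfg)
    assert res.solution.status == "infeasible"


# --- TCA closure comparison ------------------------------------------------

@pytest.fixture(scope="module")
def dark_yields(core_model_all):
    return compare_tca_variants(core_model_all, scenario="dark")


def test_gaba_shunt_equals_decarboxylase_bypass(dark_yields):
    """The GABA shunt and the decarboxylase/SSADH bypass are
    stoichiometrically identical, so their dark yields coincide."""
    assert dark_yields["GABA"] == pytest.approx(dark_yields["bypass"], abs=1e-6)


def test_conventional_ogdh_cycle_outyields_bypass(dark_yields):
    assert dark_yields["OGDH"] > dark_yields["bypass"] * (1 + 1e-3)


def test_glyoxylate_closure_slightly_outyields_bypass(dark_yields):
    assert dark_yields["glyoxylate"] > dark_yields["bypass"]


def test_phototrophic_yields_identical_across_closures(core_model_all):
    """With no cyclic flux needed in the light, closure topology is moot."""
    yields = compare_tca_variants(core_model_all, scenario="phototrophic")
    values = list(yields.values())
    assert max(values) - min(values) <= 1e-6


# --- photorespiration scenarios -------------------------------------------

@pytest.fixture(scope="module")
def photoresp(core_model_all):
    return {i: photorespiration_analysis(core_model_all, scenario_id=i)
            for i in (1, 2, 3)}


def test_scenario1_photorespiration_emerges(photoresp):
    """Without a phosphoserine pathway, serine/glycine synthesis forces a
    nonzero oxygenase flux of a few percent of carboxylation."""
    rate = photoresp[1].indicators["photorespiration_rate"]
    assert 1.0 < rate < 15.0
    assert photoresp[1].solution["RBC_OXY"] > 1e-6


def test_scenario2_photorespiration_ceases(photoresp):
    assert photoresp[2].indicators["photorespiration_rate"] == pytest.approx(
        0.0, abs=1e-6)
    lo, hi = photoresp[2].fva["RBC_OXY"]
    assert hi == pytest.approx(0.0, abs=1e-6)


def test_scenario3_bound_binds_exactly(photoresp):
    assert photoresp[3].indicators["photorespiration_rate"] == pytest.approx(
        3.0, abs=1e-6)


def test_extra_pathway_never_hurts(photoresp):
    """Scenario 2 adds a pathway relative to scenario 1: objective can only
    improve.  Scenario 3 adds a constraint relative to 2: only worsen."""
    assert photoresp[2].growth_rate >= photoresp[1].growth_rate - 1e-9
    assert photoresp[3].growth_rate <= photoresp[2].growth_rate + 1e-9


# --- glyoxylate shunt ------------------------------------------------------

def test_acetate_dcmu_growth_requires_glyoxylate_shunt(core_model_all):
    without = acetate_dcmu_test(core_model_all, glyoxylate_shunt_present=False)
    with_shunt = acetate_dcmu_test(core_model_all, glyoxylate_shunt_present=True)
    assert abs(without) <= 1e-9
    assert with_shunt > 1e-6


@pytest.mark.parametrize("shunt", [False, True])
def test_photomixotrophic_control_grows_regardless(core_model_all, shunt):
    """Acetate + light + bicarbonate without DCMU supports growth with or
    without the shunt."""
    cfg = ScenarioConfig(carbon_source="bicarbonate", dcmu=False,
                         glyoxylate_shunt_present=shunt, light_limit=100.0)
    m, cons, obj = apply_scenario(build_core_model(
        CoreModelToggles(tca_variant="all", glyoxylate_shunt_present=True)),
        cfg, core_model_roles())
    m.reaction("EX_ace").lower_bound = -1000.0
    sol = solve_fba(m, obj, cons)
    assert sol.objective_value > 1e-6


# --- configuration plumbing ------------------------------------------------

def test_apply_scenario_dcmu_blocks_psii(core_model):
    cfg = ScenarioConfig(dcmu=True, light_limit=50.0)
    m, _, _ = apply_scenario(core_model, cfg)
    r = m.reaction("PSII")
    assert r.lower_bound == r.upper_bound == 0.0


def test_apply_scenario_open_variant_removes_all_closures(core_model_all):
    cfg = ScenarioConfig(tca_variant="open", light_limit=50.0)
    m, _, _ = apply_scenario(core_model_all, cfg)
    for rid in ("OGDH", "SCS", "OGDC", "SSADH", "GAD", "GABAAT", "ICL", "MS"):
        assert not m.has_reaction(rid)


def test_apply_scenario_zero_fractions_add_no_rows(core_model):
    cfg = ScenarioConfig(oxidase_fraction=0.0, mehler_like_fraction=0.0,
                         ros_fraction=0.0, oxygenase_min_ratio=0.0,
                         light_limit=50.0)
    _, cons, _ = apply_scenario(core_model, cfg)
    assert cons == []


def test_monotone_burden(core_model):
    """Any added ratio lower bound can only reduce the optimum."""
    cfg = ScenarioConfig(light_limit=100.0, oxygenase_min_ratio=0.0)
    m, cons, obj = apply_scenario(core_model, cfg)
    base = solve_fba(m, obj, cons).objective_value
    for ratio in (0.03, 0.10, 0.25):
        cfg2 = ScenarioConfig(light_limit=100.0, oxygenase_min_ratio=ratio)
        m2, cons2, obj2 = apply_scenario(core_model, cfg2)
        constrained = solve_fba(m2, obj2, cons2).objective_value
        assert constrained <= base + 1e-9
        base = constrained


def test_missing_role_is_configuration_error(core_model):
    roles = core_model_roles()
    roles["psii"] = "NOT_A_REACTION"
    with pytest.raises(ConfigurationError, match="psii"):
        apply_scenario(core_model, ScenarioConfig(light_limit=10.0), roles)


def test_config_validates_fields():
    with pytest.raises(ConfigurationError):
        ScenarioConfig(carbon_source="glucose")
    with pytest.raises(ConfigurationError):
        ScenarioConfig(ros_fraction=1.5)


def test_config_yaml_roundtrip(tmp_path):
    cfg = ScenarioConfig(light_limit=42.0, tca_variant="GABA",
                         maintenance_atp=0.2)
    import yaml
    path = tmp_path / "scenario.yaml"
    path.write_text(yaml.safe_dump(cfg.to_dict()))
    assert ScenarioConfig.from_file(str(path)) == cfg


def test_cobra_agrees_with_engine(core_model, tmp_path):
    """Independent cross-check: cobrapy reads the emitted SBML and finds the
    same light-limited optimum."""
    cobra = pytest.importorskip("cobra")
    from cyanoflux.model import write_sbml

    path = tmp_path / "core.xml"
    write_sbml(core_model, str(path))
    cm = cobra.io.read_sbml_model(str(path))
    cm.reactions.EX_photon.lower_bound = -100.0
    cm.objective = "BOF"
    expected = cm.optimize().objective_value
    sol = solve_fba(core_model, ObjectiveSpec.maximize("BOF"),
                    [LinearConstraint({"EX_photon": 1.0}, ">=", -100.0)])
    assert sol.objective_value == pytest.approx(expected, abs=1e-6)
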