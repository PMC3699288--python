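"""Synthetic test-data generators.

Three generators live here:

* :func:`build_core_model` — a mass-balanced cyanobacterial core network
  (~100 reactions) with the photosynthetic electron transport chain, CBB
  cycle, photorespiratory salvage, the four alternative TCA-cycle closures,
  glycogen storage and a modular biomass objective.  It stands in for a
  genome-scale reconstruction in every scenario and diurnal analysis.
* :func:`make_lp_fixture` — tiny LP fixtures (<= 8 reactions) whose optima
  and flux-variability ranges are computed by exhaustive vertex enumeration.
* :func:`generate_expression` — diurnal transcript profiles on the uneven
  six-point circadian design, with known ground truth.

The core network uses lumped, balanced pseudo-reactions for the light
reactions with an explicit photon pseudo-metabolite and a massless
proton-motive-force token (``pmf``); quantum yields are therefore nominal
and only relative/qualitative flux statements should be read off it.
Hydrogen is deliberately not tracked through the pmf token — elemental
checks on C, N, O, P, S and charge are exact, H is reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    MetabolicModel,
    Metabolite,
    ModelSummary,
    Reaction,
    parse_formula,
)

__all__ = [
    "CoreModelToggles",
    "ExpressionSimConfig",
    "build_core_model",
    "core_model_roles",
    "make_lp_fixture",
    "generate_expression",
    "SIX_POINT_DESIGN",
]

TCA_VARIANTS = ("OGDH", "bypass", "GABA", "glyoxylate", "open", "all")


@dataclass(frozen=True)
class CoreModelToggles:
    """Topology switches of the synthetic core network."""

    phosphoserine_present: bool = True
    glyoxylate_shunt_present: bool = False
    tca_variant: str = "bypass"
    include_phk: bool = True
    include_me: bool = True
    include_opp: bool = True

    def __post_init__(self) -> None:
        if self.tca_variant not in TCA_VARIANTS:
            raise ValueError(f"unknown tca_variant {self.tca_variant!r}")


# ---------------------------------------------------------------------------
# metabolite table (neutral-form formulas; "" = massless pseudo-species)
# ---------------------------------------------------------------------------

_METS: dict[str, tuple[str, str, str]] = {
    # id: (name, compartment, formula)
    "photon_e": ("photon (external)", "e", ""),
    "photon": ("photon", "c", ""),
    "pmf": ("proton-motive-force token", "c", ""),
    "h2o": ("water", "c", "H2O"),
    "h2o_e": ("water (external)", "e", "H2O"),
    "o2": ("oxygen", "c", "O2"),
    "o2_e": ("oxygen (external)", "e", "O2"),
    "co2": ("carbon dioxide (cytosolic, respiratory)", "c", "CO2"),
    "co2x": ("carbon dioxide (carboxysomal)", "c", "CO2"),
    "co2_e": ("carbon dioxide (external)", "e", "CO2"),
    "hco3": ("bicarbonate", "c", "CH2O3"),
    "hco3_e": ("bicarbonate (external)", "e", "CH2O3"),
    "no3": ("nitrate", "c", "HNO3"),
    "no3_e": ("nitrate (external)", "e", "HNO3"),
    "pi": ("orthophosphate", "c", "H3PO4"),
    "pi_e": ("orthophosphate (external)", "e", "H3PO4"),
    "so4": ("sulfate", "c", "H2SO4"),
    "so4_e": ("sulfate (external)", "e", "H2SO4"),
    "nh3": ("ammonia", "c", "NH3"),
    "h2s": ("hydrogen sulfide", "c", "H2S"),
    "ho2": ("superoxide (protonated form)", "c", "HO2"),
    "h2o2": ("hydrogen peroxide", "c", "H2O2"),
    "ace": ("acetate", "c", "C2H4O2"),
    "ace_e": ("acetate (external)", "e", "C2H4O2"),
    # energy & redox carriers
    "atp": ("ATP", "c", "C10H16N5O13P3"),
    "adp": ("ADP", "c", "C10H15N5O10P2"),
    "nad": ("NAD", "c", "C21H27N7O14P2"),
    "nadh": ("NADH", "c", "C21H29N7O14P2"),
    "nadp": ("NADP", "c", "C21H28N7O17P3"),
    "nadph": ("NADPH", "c", "C21H30N7O17P3"),
    "pq": ("plastoquinone", "c", "C13H18O2"),
    "pqh2": ("plastoquinol", "c", "C13H20O2"),
    "pc_ox": ("plastocyanin (oxidized)", "c", ""),
    "pc_red": ("plastocyanin (reduced)", "c", "H"),
    "fd_ox": ("ferredoxin (oxidized)", "c", ""),
    "fd_red": ("ferredoxin (reduced)", "c", "H"),
    "coa": ("coenzyme A", "c", "C21H36N7O16P3S"),
    "accoa": ("acetyl-CoA", "c", "C23H38N7O17P3S"),
    "succoa": ("succinyl-CoA", "c", "C25H40N7O19P3S"),
    # CBB / sugar phosphates
    "rubp": ("ribulose 1,5-bisphosphate", "c", "C5H12O11P2"),
    "pg3": ("glycerate 3-phosphate", "c", "C3H7O7P"),
    "bpg": ("glycerate 1,3-bisphosphate", "c", "C3H8O10P2"),
    "gap": ("glyceraldehyde 3-phosphate", "c", "C3H7O6P"),
    "f6p": ("fructose 6-phosphate", "c", "C6H13O9P"),
    "g6p": ("glucose 6-phosphate", "c", "C6H13O9P"),
    "g1p": ("glucose 1-phosphate", "c", "C6H13O9P"),
    "ru5p": ("ribulose 5-phosphate", "c", "C5H11O8P"),
    "x5p": ("xylulose 5-phosphate", "c", "C5H11O8P"),
    "acep": ("acetyl phosphate", "c", "C2H5O5P"),
    "glyg": ("glycogen (glucosyl unit)", "c", "C6H10O5"),
    # lower glycolysis / TCA
    "pg2": ("glycerate 2-phosphate", "c", "C3H7O7P"),
    "pep": ("phosphoenolpyruvate", "c", "C3H5O6P"),
    "pyr": ("pyruvate", "c", "C3H4O3"),
    "oaa": ("oxaloacetate", "c", "C4H4O5"),
    "mal": ("malate", "c", "C4H6O5"),
    "fum": ("fumarate", "c", "C4H4O4"),
    "suc": ("succinate", "c", "C4H6O4"),
    "cit": ("citrate", "c", "C6H8O7"),
    "icit": ("isocitrate", "c", "C6H8O7"),
    "akg": ("2-oxoglutarate", "c", "C5H6O5"),
    "ssa": ("succinate semialdehyde", "c", "C4H6O3"),
    "gaba": ("4-aminobutanoate", "c", "C4H9NO2"),
    # photorespiration & serine family
    "pgc2": ("2-phosphoglycolate", "c", "C2H5O6P"),
    "glyc": ("glycolate", "c", "C2H4O3"),
    "glx": ("glyoxylate", "c", "C2H2O3"),
    "glya": ("glycerate", "c", "C3H6O4"),
    "php": ("3-phosphohydroxypyruvate", "c", "C3H5O7P"),
    "pser": ("phosphoserine", "c", "C3H8NO6P"),
    "c1u": ("bound one-carbon unit (methylene-THF equivalent)", "c", "CH2O"),
    "glu": ("glutamate", "c", "C5H9NO4"),
    "ala": ("alanine", "c", "C3H7NO2"),
    "gly": ("glycine", "c", "C2H5NO2"),
    "ser": ("serine", "c", "C3H7NO3"),
    "cys": ("cysteine", "c", "C3H7NO2S"),
    "pro": ("proline", "c", "C5H9NO2"),
}

#: biomass precursor components; formulas are derived below so that each
#: synthesis reaction is exactly balanced by construction
_COMPONENTS = ("protein", "dna", "rna", "cellwall", "lipid", "pigment", "ion")

#: biomass objective stoichiometry (mmol of component per unit growth flux)
#: and growth-associated ATP; protein-dominant split
BOF_WEIGHTS = {
    "protein": 1.0,   # ~71-residue unit; dominates biomass by mass
    "rna": 3.0,
    "dna": 0.6,
    "cellwall": 3.0,
    "lipid": 2.5,
    "pigment": 0.4,
    "ion": 1.0,
}
GROWTH_ATP = 60.0


def _reaction_rows(tg: CoreModelToggles):
    """(id, name, category, stoich, lb, ub, gpr) rows of the core network."""
    inf = 1000.0
    rows = [
        # --- exchanges (positive flux = export) --------------------------
        ("EX_photon", "photon exchange", "exchange", {"photon_e": -1}, -inf, 0, ""),
        ("EX_hco3", "bicarbonate exchange", "exchange", {"hco3_e": -1}, -inf, 0, ""),
        ("EX_co2", "CO2 exchange", "exchange", {"co2_e": -1}, 0, inf, ""),
        ("EX_o2", "O2 exchange", "exchange", {"o2_e": -1}, -inf, inf, ""),
        ("EX_no3", "nitrate exchange", "exchange", {"no3_e": -1}, -inf, 0, ""),
        ("EX_pi", "phosphate exchange", "exchange", {"pi_e": -1}, -inf, 0, ""),
        ("EX_so4", "sulfate exchange", "exchange", {"so4_e": -1}, -inf, 0, ""),
        ("EX_h2o", "water exchange", "exchange", {"h2o_e": -1}, -inf, inf, ""),
        ("EX_ace", "acetate exchange", "exchange", {"ace_e": -1}, 0, 0, ""),
        # --- transport ---------------------------------------------------
        ("T_photon", "photon capture", "transport",
         {"photon_e": -1, "photon": 1}, 0, inf, "syn_apcE"),
        ("T_hco3", "bicarbonate transporter", "transport",
         {"hco3_e": -1, "hco3": 1}, 0, inf, "syn_sbtA or syn_bicA"),
        ("T_co2", "CO2 outward diffusion", "transport",
         {"co2": -1, "co2_e": 1}, 0, inf, "syn_chpX"),
        ("T_o2", "O2 diffusion", "transport",
         {"o2": -1, "o2_e": 1}, -inf, inf, "syn_porin1"),
        ("T_no3", "nitrate ABC transporter", "transport",
         {"no3_e": -1, "atp": -1, "h2o": -1, "no3": 1, "adp": 1, "pi": 1},
         0, inf, "syn_nrtA and syn_nrtB and syn_nrtC"),
        ("T_pi", "phosphate transporter", "transport",
         {"pi_e": -1, "pi": 1}, 0, inf, "syn_pstS"),
        ("T_so4", "sulfate transporter", "transport",
         {"so4_e": -1, "so4": 1}, 0, inf, "syn_cysT"),
        ("T_h2o", "water diffusion", "transport",
         {"h2o": -1, "h2o_e": 1}, -inf, inf, "syn_aqpZ"),
        ("T_ace", "acetate uptake", "transport",
         {"ace_e": -1, "ace": 1}, 0, inf, "syn_actP"),
        # --- photosynthetic / respiratory electron transport -------------
        ("PSII", "photosystem II (water splitting)", "metabolic",
         {"h2o": -2, "pq": -2, "photon": -4, "o2": 1, "pqh2": 2, "pmf": 4},
         0, inf, "syn_psbA and syn_psbD"),
        ("B6F", "cytochrome b6f complex", "metabolic",
         {"pqh2": -1, "pc_ox": -2, "pq": 1, "pc_red": 2, "pmf": 2},
         0, inf, "syn_petB and syn_petD"),
        ("PSI", "photosystem I", "metabolic",
         {"pc_red": -1, "fd_ox": -1, "photon": -1, "pc_ox": 1, "fd_red": 1},
         0, inf, "syn_psaA and syn_psaB"),
        ("FNR", "ferredoxin-NADP reductase", "metabolic",
         {"fd_red": -2, "nadp": -1, "fd_ox": 2, "nadph": 1}, 0, inf, "syn_petH"),
        ("FQR", "ferredoxin-plastoquinone reductase (cyclic flow)", "metabolic",
         {"fd_red": -2, "pq": -1, "fd_ox": 2, "pqh2": 1}, 0, inf, "syn_pgr5"),
        ("NDH1", "NDH-1 complex (NADPH)", "metabolic",
         {"nadph": -1, "pq": -1, "nadp": 1, "pqh2": 1, "pmf": 2},
         0, inf, "syn_ndhA and syn_ndhB"),
        ("NDH1_NADH", "NDH-1 complex (NADH)", "metabolic",
         {"nadh": -1, "pq": -1, "nad": 1, "pqh2": 1, "pmf": 2},
         0, inf, "syn_ndhA and syn_ndhB"),
        ("TH", "pyridine-nucleotide transhydrogenase", "metabolic",
         {"nadph": -1, "nad": -1, "nadp": 1, "nadh": 1}, -inf, inf,
         "syn_pntA and syn_pntB"),
        ("COX", "cytochrome c oxidase (terminal oxidase)", "metabolic",
         {"pqh2": -1, "o2": -0.5, "pq": 1, "h2o": 1, "pmf": 2},
         0, inf, "syn_ctaC and syn_ctaD"),
        ("FLV", "Mehler-like reaction (flavodiiron, no ROS)", "metabolic",
         {"nadph": -1, "o2": -0.5, "nadp": 1, "h2o": 1}, 0, inf,
         "syn_flv1 and syn_flv3"),
        ("MEHLER_PSI", "PSI Mehler reaction (superoxide producing)", "metabolic",
         {"fd_red": -1, "o2": -1, "fd_ox": 1, "ho2": 1}, 0, inf, "syn_psaA and syn_psaB"),
        ("ROS_PSII", "PSII superoxide production", "metabolic",
         {"pqh2": -1, "o2": -2, "pq": 1, "ho2": 2}, 0, inf, "syn_psbA and syn_psbD"),
        ("SOD", "superoxide dismutase", "metabolic",
         {"ho2": -2, "h2o2": 1, "o2": 1}, 0, inf, "syn_sodB"),
        ("SPONT_ROS", "spontaneous superoxide dismutation", "spontaneous",
         {"ho2": -2, "h2o2": 1, "o2": 1}, 0, inf, ""),
        ("PEROX", "NADPH-dependent peroxidase", "metabolic",
         {"h2o2": -1, "nadph": -1, "h2o": 2, "nadp": 1}, 0, inf, "syn_tpx"),
        ("ATPSYN", "ATP synthase", "metabolic",
         {"pmf": -3, "adp": -1, "pi": -1, "atp": 1, "h2o": 1}, 0, inf,
         "syn_atpA and syn_atpB"),
        ("ATPM", "maintenance ATP hydrolysis", "pseudo",
         {"atp": -1, "h2o": -1, "adp": 1, "pi": 1}, 0, inf, ""),
        # --- inorganic carbon --------------------------------------------
        # inorganic carbon is taken up as bicarbonate only and dehydrated
        # inside the carboxysome; respiratory CO2 is not recycled (net
        # exchange fluxes only), so it can only diffuse out
        ("CA", "carboxysomal carbonic anhydrase", "metabolic",
         {"hco3": -1, "co2x": 1, "h2o": 1}, 0, inf, "syn_ccaA"),
        ("SPONT_CO2", "spontaneous bicarbonate dehydration (leak)", "spontaneous",
         {"hco3": -1, "co2": 1, "h2o": 1}, 0, inf, ""),
        # --- CBB cycle and sugar phosphates ------------------------------
        ("RBC_CARB", "RuBisCO carboxylase", "metabolic",
         {"rubp": -1, "co2x": -1, "h2o": -1, "pg3": 2}, 0, inf,
         "syn_rbcL and syn_rbcS"),
        ("RBC_OXY", "RuBisCO oxygenase", "metabolic",
         {"rubp": -1, "o2": -1, "pg3": 1, "pgc2": 1}, 0, inf,
         "syn_rbcL and syn_rbcS"),
        ("PGK", "phosphoglycerate kinase", "metabolic",
         {"pg3": -1, "atp": -1, "bpg": 1, "adp": 1}, -inf, inf, "syn_pgk"),
        ("GAPDH", "glyceraldehyde-3-phosphate dehydrogenase (NADP)", "metabolic",
         {"bpg": -1, "nadph": -1, "gap": 1, "nadp": 1, "pi": 1}, -inf, inf,
         "syn_gap2"),
        ("FBPL", "aldolase/FBPase lump", "metabolic",
         {"gap": -2, "h2o": -1, "f6p": 1, "pi": 1}, 0, inf,
         "syn_fda and syn_fbpI"),
        ("PFKL", "phosphofructokinase/aldolase lump", "metabolic",
         {"f6p": -1, "atp": -1, "gap": 2, "adp": 1}, 0, inf, "syn_pfkA"),
        ("TKTL", "transketolase/transaldolase lump", "metabolic",
         {"ru5p": -3, "f6p": 2, "gap": 1}, -inf, inf, "syn_tktA and syn_talB"),
        ("RPE", "ribulose-phosphate epimerase", "metabolic",
         {"ru5p": -1, "x5p": 1}, -inf, inf, "syn_cfxE"),
        ("PRK", "phosphoribulokinase", "metabolic",
         {"ru5p": -1, "atp": -1, "rubp": 1, "adp": 1}, 0, inf, "syn_prk"),
        ("PTA", "phosphotransacetylase", "metabolic",
         {"acep": -1, "coa": -1, "accoa": 1, "pi": 1}, -inf, inf, "syn_pta"),
        ("ACS", "acetate activation (acetate kinase/PTA lump)", "metabolic",
         {"ace": -1, "atp": -1, "coa": -1, "accoa": 1, "adp": 1, "pi": 1},
         0, inf, "syn_ackA"),
        # --- glycolysis / gluconeogenesis --------------------------------
        ("PGI", "phosphoglucose isomerase", "metabolic",
         {"f6p": -1, "g6p": 1}, -inf, inf, "syn_pgi"),
        ("PGM", "phosphoglucomutase", "metabolic",
         {"g1p": -1, "g6p": 1}, -inf, inf, "syn_pgm"),
        ("PGAM", "phosphoglycerate mutase", "metabolic",
         {"pg3": -1, "pg2": 1}, -inf, inf, "syn_gpmB"),
        ("ENO", "enolase", "metabolic",
         {"pg2": -1, "pep": 1, "h2o": 1}, -inf, inf, "syn_eno"),
        ("PYK", "pyruvate kinase", "metabolic",
         {"pep": -1, "adp": -1, "pyr": 1, "atp": 1}, 0, inf, "syn_pyk"),
        ("PDH", "pyruvate dehydrogenase complex", "metabolic",
         {"pyr": -1, "coa": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1},
         0, inf, "syn_pdhA and syn_pdhB and syn_pdhC"),
        ("PEPC", "PEP carboxylase (bicarbonate-utilizing)", "metabolic",
         {"pep": -1, "hco3": -1, "oaa": 1, "pi": 1}, 0, inf, "syn_ppc"),
        ("PEPCK", "PEP carboxykinase", "metabolic",
         {"oaa": -1, "atp": -1, "pep": 1, "co2": 1, "adp": 1}, 0, inf, "syn_pckA"),
        # --- nitrogen / sulfur / amino acids -----------------------------
        ("NR", "nitrate/nitrite reductase lump", "metabolic",
         {"no3": -1, "nadph": -4, "nh3": 1, "h2o": 3, "nadp": 4}, 0, inf,
         "syn_narB and syn_nirA"),
        ("SR", "sulfate reduction lump", "metabolic",
         {"so4": -1, "nadph": -4, "h2s": 1, "h2o": 4, "nadp": 4}, 0, inf,
         "syn_cysH and syn_sir"),
        ("GDH", "glutamate dehydrogenase", "metabolic",
         {"akg": -1, "nh3": -1, "nadph": -1, "glu": 1, "nadp": 1, "h2o": 1},
         0, inf, "syn_gdhA"),
        ("ALATA", "alanine transaminase", "metabolic",
         {"pyr": -1, "glu": -1, "ala": 1, "akg": 1}, -inf, inf, "syn_alaT"),
        ("CYSS", "cysteine synthesis lump", "metabolic",
         {"ser": -1, "h2s": -1, "cys": 1, "h2o": 1}, 0, inf, "syn_cysK"),
        ("PROS", "proline synthesis lump", "metabolic",
         {"glu": -1, "atp": -1, "nadph": -2, "pro": 1, "adp": 1, "pi": 1,
          "nadp": 2, "h2o": 1}, 0, inf, "syn_proB and syn_proC"),
        ("PROD", "proline degradation lump", "metabolic",
         {"pro": -1, "pq": -1, "nad": -1, "h2o": -2, "glu": 1, "pqh2": 1,
          "nadh": 1}, 0, inf, "syn_putA"),
        # --- photorespiration and serine family --------------------------
        ("PGP", "phosphoglycolate phosphatase", "metabolic",
         {"pgc2": -1, "h2o": -1, "glyc": 1, "pi": 1}, 0, inf, "syn_pgpA"),
        ("GLCD", "glycolate dehydrogenase", "metabolic",
         {"glyc": -1, "pq": -1, "glx": 1, "pqh2": 1}, 0, inf, "syn_glcD"),
        ("GGT", "glyoxylate-glutamate aminotransferase", "metabolic",
         {"glx": -1, "glu": -1, "gly": 1, "akg": 1}, 0, inf, "syn_ggt"),
        ("GLYSER", "glycine decarboxylase / SHMT lump", "metabolic",
         {"gly": -2, "nad": -1, "h2o": -1, "ser": 1, "co2": 1, "nh3": 1,
          "nadh": 1}, 0, inf, "syn_gcvP and syn_glyA"),
        ("SHMT", "serine hydroxymethyltransferase (serine to glycine)", "metabolic",
         {"ser": -1, "gly": 1, "c1u": 1}, 0, inf, "syn_glyA"),
        ("C1DH", "one-carbon unit oxidation lump", "metabolic",
         {"c1u": -1, "h2o": -1, "nad": -2, "co2": 1, "nadh": 2}, 0, inf,
         "syn_fdh"),
        ("TSAL", "glyoxylate carboligase / TSA reductase lump", "metabolic",
         {"glx": -2, "nadh": -1, "glya": 1, "co2": 1, "nad": 1}, 0, inf,
         "syn_gcl"),
        ("GLYK", "glycerate kinase", "metabolic",
         {"glya": -1, "atp": -1, "pg3": 1, "adp": 1}, 0, inf, "syn_glxK"),
        # --- TCA cycle and closures --------------------------------------
        ("CS", "citrate synthase", "metabolic",
         {"accoa": -1, "oaa": -1, "h2o": -1, "cit": 1, "coa": 1}, 0, inf,
         "syn_gltA"),
        ("ACO", "aconitase", "metabolic",
         {"cit": -1, "icit": 1}, -inf, inf, "syn_acnB"),
        ("IDH", "isocitrate dehydrogenase (NADP)", "metabolic",
         {"icit": -1, "nadp": -1, "akg": 1, "co2": 1, "nadph": 1}, 0, inf,
         "syn_icd"),
        ("SDH", "succinate dehydrogenase", "metabolic",
         {"suc": -1, "pq": -1, "fum": 1, "pqh2": 1}, 0, inf,
         "syn_sdhA and syn_sdhB"),
        ("FUM", "fumarase", "metabolic",
         {"fum": -1, "h2o": -1, "mal": 1}, -inf, inf, "syn_fumC"),
        ("MDH", "malate dehydrogenase", "metabolic",
         {"mal": -1, "nad": -1, "oaa": 1, "nadh": 1}, -inf, inf, "syn_mdh"),
        # --- glycogen ----------------------------------------------------
        ("GLGS", "glycogen synthesis lump (ADP-glucose)", "metabolic",
         {"g1p": -1, "atp": -1, "h2o": -1, "glyg": 1, "adp": 1, "pi": 2},
         0, inf, "syn_glgC and syn_glgA"),
        ("GLGP", "glycogen phosphorylase", "metabolic",
         {"glyg": -1, "pi": -1, "g1p": 1}, 0, inf, "syn_glgP"),
        ("DM_glycogen", "glycogen accumulation (pool sink)", "pseudo",
         {"glyg": -1}, 0, 0, ""),
        ("SRC_glycogen", "glycogen mobilization (pool source)", "pseudo",
         {"glyg": 1}, 0, 0, ""),
    ]

    if tg.include_phk:
        rows.append(("PHK", "phosphoketolase", "metabolic",
                     {"x5p": -1, "pi": -1, "acep": 1, "gap": 1, "h2o": 1},
                     0, inf, "syn_xfpA"))
    if tg.include_opp:
        rows.append(("OPP", "oxidative pentose phosphate lump", "metabolic",
                     {"g6p": -1, "nadp": -2, "h2o": -1, "ru5p": 1, "co2": 1,
                      "nadph": 2}, 0, inf, "syn_zwf and syn_gnd"))
    if tg.include_me:
        rows.append(("ME", "malic enzyme", "metabolic",
                     {"mal": -1, "nadp": -1, "pyr": 1, "co2": 1, "nadph": 1},
                     0, inf, "syn_me"))
    if tg.phosphoserine_present:
        rows += [
            ("PGDH", "3-phosphoglycerate dehydrogenase", "metabolic",
             {"pg3": -1, "nad": -1, "php": 1, "nadh": 1}, 0, inf, "syn_serA"),
            ("PSAT", "phosphoserine transaminase", "metabolic",
             {"php": -1, "glu": -1, "pser": 1, "akg": 1}, 0, inf, "syn_serC"),
            ("PSP", "phosphoserine phosphatase", "metabolic",
             {"pser": -1, "h2o": -1, "ser": 1, "pi": 1}, 0, inf, "syn_serB"),
        ]

    variant = tg.tca_variant
    if variant in ("OGDH", "all"):
        rows += [
            ("OGDH", "2-oxoglutarate dehydrogenase complex", "metabolic",
             {"akg": -1, "coa": -1, "nad": -1, "succoa": 1, "co2": 1,
              "nadh": 1}, 0, inf, "syn_sucA and syn_sucB and syn_lpd"),
            ("SCS", "succinyl-CoA synthetase", "metabolic",
             {"succoa": -1, "adp": -1, "pi": -1, "suc": 1, "coa": 1, "atp": 1},
             0, inf, "syn_sucC and syn_sucD"),
        ]
    if variant in ("bypass", "all"):
        rows.append(("OGDC", "2-oxoglutarate decarboxylase", "metabolic",
                     {"akg": -1, "ssa": 1, "co2": 1}, 0, inf, "syn_ogdc"))
    if variant in ("GABA", "all"):
        rows += [
            ("GAD", "glutamate decarboxylase", "metabolic",
             {"glu": -1, "gaba": 1, "co2": 1}, 0, inf, "syn_gad"),
            ("GABAAT", "GABA aminotransferase", "metabolic",
             {"gaba": -1, "akg": -1, "ssa": 1, "glu": 1}, 0, inf, "syn_gabT"),
        ]
    if variant in ("bypass", "GABA", "all"):
        rows.append(("SSADH", "succinate semialdehyde dehydrogenase (NADP)",
                     "metabolic",
                     {"ssa": -1, "nadp": -1, "h2o": -1, "suc": 1, "nadph": 1},
                     0, inf, "syn_ssadh"))
    if tg.glyoxylate_shunt_present or variant in ("glyoxylate", "all"):
        rows += [
            ("ICL", "isocitrate lyase", "metabolic",
             {"icit": -1, "suc": 1, "glx": 1}, 0, inf, "syn_aceA"),
            ("MS", "malate synthase", "metabolic",
             {"glx": -1, "accoa": -1, "h2o": -1, "mal": 1, "coa": 1},
             0, inf, "syn_aceB"),
        ]

    # --- biomass component synthesis (products balanced by construction) --
    comp_rows = [
        # 71-residue protein equivalent with a realistic serine-family share
        # (~7% Gly, ~7% Ser, ~1.4% Cys); 4 ATP per residue for synthesis
        ("PROT_S", "protein-equivalent synthesis", "protein",
         {"ala": -50, "glu": -10, "ser": -5, "gly": -5, "cys": -1,
          "atp": -284, "h2o": -214, "adp": 284, "pi": 284},
         "syn_rpsA and syn_rplB"),
        ("DNA_S", "DNA-equivalent synthesis", "dna",
         {"ru5p": -1, "glu": -1, "atp": -2, "adp": 2, "pi": 2}, "syn_purF"),
        ("RNA_S", "RNA-equivalent synthesis", "rna",
         {"ru5p": -1, "glu": -1, "nh3": -1, "atp": -2, "adp": 2, "pi": 2},
         "syn_pyrB"),
        ("CW_S", "cell-wall synthesis", "cellwall",
         {"f6p": -1, "pep": -1, "nh3": -1, "atp": -1, "adp": 1, "pi": 1},
         "syn_murA"),
        ("LIP_S", "lipid synthesis", "lipid",
         {"gap": -1, "accoa": -4, "nadph": -6, "atp": -1, "coa": 4,
          "nadp": 6, "adp": 1, "pi": 1, "h2o": 3}, "syn_fabD and syn_fabH"),
        ("PIG_S", "pigment synthesis (chlorophyll-like)", "pigment",
         {"glu": -2, "accoa": -1, "nadph": -2, "atp": -2, "coa": 1,
          "nadp": 2, "adp": 2, "pi": 2}, "syn_hemA and syn_chlG"),
        ("ION_S", "inorganic-ion assimilation", "ion",
         {"no3": -1, "so4": -1, "atp": -1, "adp": 1}, "syn_mgtE"),
    ]
    for rid, name, comp, stoich, gpr in comp_rows:
        stoich = dict(stoich)
        stoich[comp] = 1
        rows.append((rid, name, "metabolic", stoich, 0, inf, gpr))
        rows.append((f"DM_{comp}", f"{comp} demand (diurnal mode)", "pseudo",
                     {comp: -1}, 0, 0, ""))

    bof = {c: -w for c, w in BOF_WEIGHTS.items()}
    bof.update({"atp": -GROWTH_ATP, "h2o": -GROWTH_ATP,
                "adp": GROWTH_ATP, "pi": GROWTH_ATP})
    rows.append(("BOF", "biomass objective function", "biomass", bof, 0, inf, ""))
    return rows


def _component_formulas(rows) -> dict[str, dict[str, int]]:
    """Formula of each biomass component = exact residual of its synthesis
    reaction, so the network balances by construction."""
    base = {mid: parse_formula(f) for mid, (_, _, f) in _METS.items()}
    out: dict[str, dict[str, int]] = {}
    for rid, _, _, stoich, *_ in rows:
        comps = [m for m in stoich if m in _COMPONENTS]
        if not comps or stoich[comps[0]] < 0:
            continue
        comp = comps[0]
        residual: dict[str, float] = {}
        for mid, coef in stoich.items():
            if mid == comp:
                continue
            for el, n in base[mid].items():
                residual[el] = residual.get(el, 0.0) - coef * n
        formula = {}
        for el, n in residual.items():
            n_round = round(n)
            if abs(n - n_round) > 1e-9 or n_round < 0:
                raise AssertionError(
                    f"synthesis of {comp!r} leaves a non-integral or negative "
                    f"residual for element {el}: {n}"
                )
            if n_round:
                formula[el] = int(n_round)
        out[comp] = formula
    return out


def build_core_model(toggles: CoreModelToggles | None = None) -> MetabolicModel:
    """Construct the synthetic cyanobacterial core network."""
    tg = toggles or CoreModelToggles()
    rows = _reaction_rows(tg)
    comp_formulas = _component_formulas(rows)

    model = MetabolicModel(
        id="cyano_core",
        compartments={"c": "cytosol", "e": "extracellular"},
    )
    for mid, (name, comp, formula) in _METS.items():
        model.metabolites.append(
            Metabolite(mid, name=name, compartment=comp,
                       formula=parse_formula(formula), charge=0)
        )
    for comp in _COMPONENTS:
        model.metabolites.append(
            Metabolite(comp, name=f"biomass component: {comp}", compartment="c",
                       formula=comp_formulas[comp], charge=0)
        )
    for rid, name, cat, stoich, lb, ub, gpr in rows:
        model.reactions.append(
            Reaction(rid, name=name, stoichiometry=dict(stoich),
                     lower_bound=lb, upper_bound=ub,
                     gene_association=gpr, category=cat)
        )
    model.objective_id = "BOF"
    model.validate()
    return model


def core_model_manifest(toggles: CoreModelToggles | None = None) -> ModelSummary:
    """Counts the generator commits to, computed from its own tables."""
    tg = toggles or CoreModelToggles()
    rows = _reaction_rows(tg)
    genes: set[str] = set()
    enzymes: set[str] = set()
    counts = {"metabolic": 0, "transport": 0, "spontaneous": 0}
    for rid, _, cat, _, _, _, gpr in rows:
        if cat in counts:
            counts[cat] += 1
        if gpr:
            import re

            genes |= {t for t in re.findall(r"[A-Za-z0-9_.-]+", gpr)
                      if t not in ("and", "or")}
            if cat in ("metabolic", "transport"):
                enzymes.add(" ".join(gpr.lower().split()))
    return ModelSummary(
        n_genes=len(genes),
        n_enzymes=len(enzymes),
        n_metabolic_reactions=counts["metabolic"],
        n_metabolites=len(_METS) + len(_COMPONENTS),
        n_spontaneous=counts["spontaneous"],
        n_transport=counts["transport"],
        n_compartments=2,
    )


#: functional-role table for the synthetic core network; the scenario layer
#: is model-agnostic and looks reactions up only through such a table
CORE_ROLES: dict[str, str] = {
    "photon_exchange": "EX_photon",
    "bicarbonate_exchange": "EX_hco3",
    "co2_exchange": "EX_co2",
    "o2_exchange": "EX_o2",
    "acetate_exchange": "EX_ace",
    "psii": "PSII",
    "psi": "PSI",
    "oxidase": "COX",
    "mehler_like": "FLV",
    "ros_psii": "ROS_PSII",
    "ros_psi": "MEHLER_PSI",
    "carboxylase": "RBC_CARB",
    "oxygenase": "RBC_OXY",
    "biomass": "BOF",
    "atp_maintenance": "ATPM",
    "glycogen_sink": "DM_glycogen",
    "glycogen_source": "SRC_glycogen",
    "glycogen_synthesis": "GLGS",
    "glycogen_degradation": "GLGP",
    "transhydrogenase": "TH",
    "ndh1_nadh": "NDH1_NADH",
    "opp": "OPP",
    "gdh": "GDH",
    "pgk": "PGK",
    "pgam": "PGAM",
    "pgm": "PGM",
    "glycine_route": "GGT",
    "glycerate_route": "TSAL",
    "proline_degradation": "PROD",
    # per-component sinks used by the diurnal mode
    **{f"sink_{c}": f"DM_{c}" for c in
       ("protein", "dna", "rna", "cellwall", "lipid", "pigment", "ion")},
}


def core_model_roles() -> dict[str, str]:
    return dict(CORE_ROLES)


#: reactions whose joint activity constitutes cyclic TCA flux, per closure
TCA_CYCLE_SETS: dict[str, tuple[str, ...]] = {
    "OGDH": ("CS", "ACO", "IDH", "OGDH", "SCS", "SDH", "FUM", "MDH"),
    "bypass": ("CS", "ACO", "IDH", "OGDC", "SSADH", "SDH", "FUM", "MDH"),
    "GABA": ("CS", "ACO", "IDH", "GAD", "GABAAT", "SSADH", "SDH", "FUM", "MDH"),
    "glyoxylate": ("CS", "ACO", "ICL", "SDH", "FUM", "MDH"),
}

#: the closure steps themselves (the "shortcut" reactions)
TCA_CLOSURE_REACTIONS: dict[str, tuple[str, ...]] = {
    "OGDH": ("OGDH", "SCS"),
    "bypass": ("OGDC", "SSADH"),
    "GABA": ("GAD", "GABAAT"),
    "glyoxylate": ("ICL", "MS"),
}


# ---------------------------------------------------------------------------
# tiny LP fixtures
# ---------------------------------------------------------------------------

def make_lp_fixture(name: str):
    """Return (model, optimum, fva_ranges) for a named tiny fixture.

    The optimum and the fraction-1.0 FVA ranges are produced by the
    exhaustive vertex-enumeration oracle, not by the LP engine.
    """
    from .fba import ObjectiveSpec
    from .oracle import brute_force_fva, brute_force_optimum

    def _mk(rxns, objective_id):
        mets = sorted({m for _, st, *_ in rxns for m in st})
        model = MetabolicModel(id=f"fixture_{name}",
                               compartments={"c": "cytosol"})
        model.metabolites = [Metabolite(m, compartment="c", formula={}, charge=0)
                             for m in mets]
        for rid, st, lb, ub in rxns:
            cat = "exchange" if len(st) == 1 else "metabolic"
            model.reactions.append(Reaction(rid, stoichiometry=st,
                                            lower_bound=lb, upper_bound=ub,
                                            category=cat))
        model.objective_id = objective_id
        model.validate()
        return model

    if name == "chain":
        model = _mk([
            ("SRC_A", {"a": 1}, 0, 10),
            ("R_AB", {"a": -1, "b": 1}, 0, 1000),
            ("SINK_B", {"b": -1}, 0, 1000),
        ], "SINK_B")
    elif name == "branch":
        # two routes: yield 1.0 and yield 0.5 per unit uptake
        model = _mk([
            ("SRC_A", {"a": 1}, 0, 10),
            ("R_HI", {"a": -1, "b": 1}, 0, 1000),
            ("R_LO", {"a": -2, "b": 1}, 0, 1000),
            ("SINK_B", {"b": -1}, 0, 1000),
        ], "SINK_B")
    elif name == "parallel":
        # twin routes, each capped at 10, demand capped at 10
        model = _mk([
            ("SRC_A", {"a": 1}, 0, 1000),
            ("R_1", {"a": -1, "b": 1}, 0, 10),
            ("R_2", {"a": -1, "b": 1}, 0, 10),
            ("SINK_B", {"b": -1}, 0, 10),
        ], "SINK_B")
    elif name == "wasteful_cycle":
        # WASTE diverts substrate 1:1 away from the objective
        model = _mk([
            ("SRC_A", {"a": 1}, 0, 10),
            ("R_AB", {"a": -1, "b": 1}, 0, 1000),
            ("WASTE", {"a": -1}, 0, 1000),
            ("SINK_B", {"b": -1}, 0, 1000),
        ], "SINK_B")
    else:
        raise ValueError(f"unknown fixture {name!r}")

    objective = ObjectiveSpec.maximize(model.objective_id)
    optimum = brute_force_optimum(model, objective)
    fva = brute_force_fva(model, objective)
    return model, optimum, fva


# ---------------------------------------------------------------------------
# diurnal expression profiles
# ---------------------------------------------------------------------------

#: the six unevenly spaced circadian sampling times (CT h): 30 min around
#: lights-off (CT 12), before midnight, around lights-on (CT 0/24), before noon
SIX_POINT_DESIGN: tuple[float, ...] = (0.5, 5.5, 11.5, 12.5, 17.5, 23.5)


@dataclass(frozen=True)
class ExpressionSimConfig:
    n_genes: int = 1000
    fraction_oscillating: float = 0.2
    amplitude_mean: float = 0.75   # log2 units; ~3x the default noise sd
    amplitude_sd: float = 0.25
    noise_sd: float = 0.25
    array_trend_amplitude: float = 0.3
    #: smooth intensity-dependent distortion strength (0 disables)
    distortion: float = 0.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    sample_times: tuple[float, ...] = SIX_POINT_DESIGN
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_oscillating <= 1):
            raise ValueError("fraction_oscillating must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")


def generate_expression(config: ExpressionSimConfig):
    """Simulate a diurnal expression matrix with known ground truth.

    Oscillators follow ``baseline + A cos(2 pi (t - phase)/24)``; every gene
    receives Gaussian noise and an additive array-level trend that rises
    over the subjective day (plus an optional smooth intensity-dependent
    distortion).  Returns ``(ExpressionMatrix, truth_table)``.
    """
    from .rhythm import ExpressionMatrix

    rng = np.random.default_rng(config.seed)
    times = np.tile(np.asarray(config.sample_times, dtype=float),
                    config.n_replicates)
    replicates = np.repeat(np.arange(config.n_replicates),
                           len(config.sample_times))
    n_arr = times.size

    n_osc = int(round(config.n_genes * config.fraction_oscillating))
    is_osc = np.zeros(config.n_genes, dtype=bool)
    is_osc[:n_osc] = True

    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          config.n_genes)
    amplitude = np.where(
        is_osc,
        np.abs(rng.normal(config.amplitude_mean, config.amplitude_sd,
                          config.n_genes)),
        0.0,
    )
    phase = np.where(is_osc, rng.uniform(0, 24, config.n_genes), np.nan)

    x = baseline[:, None] + np.where(
        is_osc[:, None],
        amplitude[:, None] * np.cos(2 * np.pi * (times[None, :]
                                                 - np.nan_to_num(phase)[:, None]) / 24.0),
        0.0,
    )
    # array-level technical trend: higher apparent expression over the day
    trend = config.array_trend_amplitude * (times / 24.0)
    x = x + trend[None, :]
    if config.distortion:
        x = x + config.distortion * np.sin(x)
    x = x + rng.normal(0.0, config.noise_sd, x.shape)

    genes = [f"gene{i:04d}" for i in range(config.n_genes)]
    arrays = [f"array_t{t:04.1f}_r{r}" for t, r in zip(times, replicates)]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(x, index=genes, columns=arrays),
        sample_times=times.copy(),
        replicates=replicates.copy(),
    )
    truth = pd.DataFrame(
        {"is_oscillating": is_osc, "amplitude": amplitude, "phase": phase},
        index=genes,
    )
    return matrix, truth
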