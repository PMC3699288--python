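"""Network data model: formulas, SBML round-trips, balance checks, summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyanoflux.model import (
    BalanceFinding,
    MetabolicModel,
    Metabolite,
    ModelIntegrityError,
    Reaction,
    check_balance,
    format_formula,
    parse_formula,
    read_sbml,
    stoichiometric_matrix,
    summarize,
    write_sbml,
)
from cyanoflux.synth import core_model_manifest


# --- formulas --------------------------------------------------------------

@pytest.mark.parametrize("text,expected", [
    ("H2O", {"H": 2, "O": 1}),
    ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
    ("C21H36N7O16P3S", {"C": 21, "H": 36, "N": 7, "O": 16, "P": 3, "S": 1}),
    ("", {}),
    ("Fe2O3", {"Fe": 2, "O": 3}),
])
def test_parse_formula(text, expected):
    assert parse_formula(text) == expected


@pytest.mark.parametrize("bad", ["1H2", "C6(H2O)6", "c6h12", "C-2"])
def test_parse_formula_rejects_nonsense(bad):
    with pytest.raises(ValueError):
        parse_formula(bad)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.dictionaries(
    st.sampled_from(["C", "H", "N", "O", "P", "S", "Fe", "Mg"]),
    st.integers(min_value=1, max_value=99), max_size=6))
def test_formula_roundtrip(counts):
    assert parse_formula(format_formula(counts)) == counts


# --- small hand-built models ----------------------------------------------

def toy_model():
    m = MetabolicModel(id="toy", compartments={"c": "cytosol"})
    m.metabolites = [
        Metabolite("glc", compartment="c", formula=parse_formula("C6H12O6"), charge=0),
        Metabolite("o2", compartment="c", formula=parse_formula("O2"), charge=0),
        Metabolite("co2", compartment="c", formula=parse_formula("CO2"), charge=0),
        Metabolite("h2o", compartment="c", formula=parse_formula("H2O"), charge=0),
    ]
    m.reactions = [
        Reaction("resp", stoichiometry={"glc": -1, "o2": -6, "co2": 6, "h2o": 6},
                 lower_bound=0, upper_bound=10),
    ]
    return m


def test_stoichiometric_matrix_columns():
    m = toy_model()
    m.reactions.append(Reaction("dimer", stoichiometry={"glc": -2, "co2": 1},
                                lower_bound=0, upper_bound=1))
    S = stoichiometric_matrix(m).toarray()
    assert S.shape == (4, 2)
    assert S[0, 0] == -1 and S[1, 0] == -6 and S[2, 0] == 6
    assert S[0, 1] == -2 and S[2, 1] == 1


def test_check_balance_clean_and_seeded_imbalance():
    m = toy_model()
    assert check_balance(m, elements=("C", "H", "O")) == []
    # delete one water: H short by 2, O short by 1 on the product side
    m.reaction("resp").stoichiometry["h2o"] = 5
    findings = {(f.quantity, f.imbalance) for f in
                check_balance(m, elements=("C", "H", "O"))}
    assert ("H", -2.0) in findings and ("O", -1.0) in findings


def test_check_balance_charge_and_unknown():
    m = toy_model()
    m.metabolites.append(Metabolite("anion", compartment="c",
                                    formula={}, charge=-1))
    m.metabolites.append(Metabolite("neutral", compartment="c",
                                    formula={}, charge=0))
    m.reactions.append(Reaction("chg", stoichiometry={"anion": -1, "neutral": 1},
                                lower_bound=0, upper_bound=1))
    findings = check_balance(m, elements=())
    assert BalanceFinding("chg", "charge", 1.0) in findings
    # unknown composition is reported, not raised
    m.metabolites.append(Metabolite("mystery", compartment="c", formula=None))
    m.reactions.append(Reaction("mys", stoichiometry={"mystery": -1, "neutral": 1},
                                lower_bound=0, upper_bound=1))
    quantities = {f.quantity for f in check_balance(m, elements=())
                  if f.reaction_id == "mys"}
    assert quantities == {"unknown"}


def test_exchange_and_biomass_reactions_skipped_by_balance():
    m = toy_model()
    m.reactions.append(Reaction("EX_glc", stoichiometry={"glc": -1},
                                lower_bound=-10, upper_bound=0,
                                category="exchange"))
    assert check_balance(m, elements=("C", "H", "O")) == []


def test_summarize_empty_model():
    m = MetabolicModel(id="empty")
    s = summarize(m)
    assert all(v == 0 for v in vars(s).values())


def test_summarize_counts_distinct_enzymes():
    m = toy_model()
    m.reaction("resp").gene_association = "gA and gB"
    m.reactions.append(Reaction("iso", stoichiometry={"glc": -1, "co2": 6},
                                gene_association="gA  AND gB",
                                lower_bound=0, upper_bound=1))
    m.reactions.append(Reaction("other", stoichiometry={"glc": -1, "h2o": 6},
                                gene_association="gC",
                                lower_bound=0, upper_bound=1))
    s = summarize(m)
    assert s.n_enzymes == 2  # whitespace/case variants collapse
    assert s.n_genes == 3


def test_summary_categories_partition(core_model):
    s = summarize(core_model)
    by_cat = {}
    for r in core_model.reactions:
        by_cat[r.category] = by_cat.get(r.category, 0) + 1
    assert sum(by_cat.values()) == len(core_model.reactions)
    assert s.n_metabolic_reactions == by_cat["metabolic"]
    assert s.n_transport == by_cat["transport"]
    assert s.n_spontaneous == by_cat["spontaneous"]


def test_generator_manifest_matches_summary(core_model):
    assert summarize(core_model) == core_model_manifest()


# --- SBML I/O --------------------------------------------------------------

def test_sbml_roundtrip_core_model(core_model, tmp_path):
    path = tmp_path / "core.xml"
    write_sbml(core_model, str(path))
    m2 = read_sbml(str(path))
    assert summarize(m2) == summarize(core_model)
    r1 = {r.id: r for r in core_model.reactions}
    r2 = {r.id: r for r in m2.reactions}
    assert set(r1) == set(r2)
    for rid in r1:
        assert r1[rid].stoichiometry == r2[rid].stoichiometry
        assert r1[rid].lower_bound == r2[rid].lower_bound
        assert r1[rid].upper_bound == r2[rid].upper_bound
        assert r1[rid].category == r2[rid].category
        assert r1[rid].genes() == r2[rid].genes()
    m1m = {x.id: x for x in core_model.metabolites}
    m2m = {x.id: x for x in m2.metabolites}
    for mid in m1m:
        assert m1m[mid].formula == m2m[mid].formula
        assert m1m[mid].charge == m2m[mid].charge
    assert check_balance(m2) == []


def test_sbml_roundtrip_empty_and_unset_annotations(tmp_path):
    m = MetabolicModel(id="bare", compartments={"c": "c"})
    path = tmp_path / "bare.xml"
    write_sbml(m, str(path))
    assert summarize(read_sbml(str(path))) == summarize(m)

    m.metabolites = [Metabolite("x", compartment="c", formula=None, charge=None)]
    m.reactions = [Reaction("sink", stoichiometry={"x": -1},
                            lower_bound=0, upper_bound=5, category="exchange")]
    write_sbml(m, str(path))
    m2 = read_sbml(str(path))
    assert m2.metabolite("x").formula is None
    assert m2.metabolite("x").charge is None
    assert m2.reaction("sink").upper_bound == 5


def test_read_sbml_dangling_species_is_integrity_error(tmp_path):
    bad = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="bad">
    <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
    <listOfSpecies>
      <species id="a" compartment="c" constant="false"
               boundaryCondition="false" hasOnlySubstanceUnits="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="r" reversible="false" fast="false">
        <listOfReactants><speciesReference species="ghost"
          stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="a"
          stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>"""
    path = tmp_path / "bad.xml"
    path.write_text(bad)
    with pytest.raises(ModelIntegrityError, match="ghost"):
        read_sbml(str(path))


def test_read_sbml_malformed_xml_names_problem(tmp_path):
    path = tmp_path / "broken.xml"
    path.write_text("<sbml><model>")
    with pytest.raises(ValueError):
        read_sbml(str(path))
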