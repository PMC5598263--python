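"""Substructure prevalence, co-occurrence and the multi-parameter search."""

import numpy as np
import pytest

from toxmine.chemquery import (
    DEFAULT_BENZOIC_ACID_SMARTS,
    CriterionError,
    FindingCriterion,
    PatternError,
    cooccurrence,
    multi_parameter_search,
    parse_criterion,
    substructure_prevalence,
)
from toxmine.synthetic_data import SyntheticConfig, generate, generate_case_study

from conftest import build_db

BENZOIC = "OC(=O)c1ccccc1"
TRIPLE = [
    FindingCriterion("haematology", "Haemoglobin", "decrease"),
    FindingCriterion("haematology", "Platelets", "increase"),
    FindingCriterion("haematology", "Reticulocytes", "increase"),
]


def test_prevalence_counts_matching_structures():
    specs = [{"id": f"B{k}", "smiles": BENZOIC} for k in range(3)]
    specs += [{"id": f"N{k}", "smiles": "CCO"} for k in range(7)]
    db = build_db(specs)
    assert substructure_prevalence(db, DEFAULT_BENZOIC_ACID_SMARTS) == pytest.approx(0.30)


def test_free_acid_pattern_excludes_esters_and_aliphatic_acids():
    db = build_db(
        [
            {"id": "A", "smiles": BENZOIC},
            {"id": "B", "smiles": "CC(C)Cc1ccc(cc1)C(C)C(=O)OC"},  # aromatic ester
            {"id": "C", "smiles": "CCCC(=O)O"},  # aliphatic free acid
        ]
    )
    assert substructure_prevalence(db, DEFAULT_BENZOIC_ACID_SMARTS) == pytest.approx(1 / 3)


def test_pattern_matching_nothing_gives_zero():
    db = build_db([{"id": "A", "smiles": "CCO"}])
    assert substructure_prevalence(db, "c1ccccc1C(=O)[OX2H1]") == 0.0


def test_unparseable_pattern_raises():
    db = build_db([{"id": "A", "smiles": "CCO"}])
    with pytest.raises(PatternError):
        substructure_prevalence(db, "not a smarts ((")


def test_flag_column_path_matches_smiles_path():
    db = generate(SyntheticConfig(n_compounds=400, p_substructure=0.1, seed=8))
    by_flag = substructure_prevalence(db, None)
    by_smiles = substructure_prevalence(db, DEFAULT_BENZOIC_ACID_SMARTS)
    # the generator writes benzoic-acid SMILES exactly for flagged compounds,
    # but confidential compounds lack structures, so only the denominators differ
    assert abs(by_flag - 0.1) <= 3 * np.sqrt(0.1 * 0.9 / 400)
    assert abs(by_smiles - by_flag) < 0.1


def test_prevalence_invariant_to_compound_order_and_duplicate_findings():
    specs = [{"id": f"B{k}", "smiles": BENZOIC, "alt": "pos"} for k in range(2)]
    specs += [{"id": f"N{k}", "smiles": "CCO"} for k in range(8)]
    db = build_db(specs)
    reordered = build_db(list(reversed(specs)))
    assert substructure_prevalence(db, DEFAULT_BENZOIC_ACID_SMARTS) == substructure_prevalence(
        reordered, DEFAULT_BENZOIC_ACID_SMARTS
    )


def test_planted_prevalence_recovered_within_three_se():
    n = 3000
    db = generate(SyntheticConfig(n_compounds=n, seed=12))
    prev = substructure_prevalence(db, None)
    se = np.sqrt(0.011 * 0.989 / n)
    assert abs(prev - 0.011) <= 3 * se


def test_cooccurrence_reports_both_proportions(ontology):
    # 18% of pattern compounds vs 26% overall -> not over-represented
    specs = []
    for k in range(50):
        specs.append(
            {"id": f"B{k}", "smiles": BENZOIC, "haemoglobin": ("pos" if k < 9 else "neg", "decrease" if k < 9 else None)}
        )
    for k in range(150):
        flagged = k < 43  # (9+43)/200 = 26% overall
        specs.append({"id": f"N{k}", "smiles": "CCO", "haemoglobin": ("pos" if flagged else "neg")})
    db = build_db(specs)
    result = cooccurrence(db, DEFAULT_BENZOIC_ACID_SMARTS, "haematology", ontology)
    assert result.prop_with_pattern == pytest.approx(0.18)
    assert result.prop_overall == pytest.approx(0.26)
    assert result.conclusion == "no evidence of over-representation"


def test_cooccurrence_pattern_everywhere_equalises_proportions(ontology):
    specs = [{"id": f"B{k}", "smiles": BENZOIC, "haemoglobin": "pos" if k % 2 else "neg"} for k in range(20)]
    result = cooccurrence(build_db(specs), DEFAULT_BENZOIC_ACID_SMARTS, "haematology", ontology)
    assert result.prop_with_pattern == pytest.approx(result.prop_overall)
    assert result.n_with_pattern == result.n_total


def test_cooccurrence_detects_planted_association(ontology):
    specs = []
    for k in range(60):
        specs.append({"id": f"B{k}", "smiles": BENZOIC, "haemoglobin": "pos" if k < 50 else "neg"})
    for k in range(200):
        specs.append({"id": f"N{k}", "smiles": "CCO", "haemoglobin": "pos" if k < 20 else "neg"})
    result = cooccurrence(build_db(specs), DEFAULT_BENZOIC_ACID_SMARTS, "haematology", ontology)
    assert result.prop_with_pattern > result.prop_overall
    assert result.fisher_p < 0.05
    assert result.conclusion == "over-represented"


def test_cooccurrence_table_margins(ontology):
    db = generate(SyntheticConfig(n_compounds=300, seed=13))
    result = cooccurrence(db, None, "haematology", ontology)
    m = result.table
    assert m.tp + m.fp == result.n_with_pattern
    assert m.fn + m.tn == result.n_total - result.n_with_pattern


def test_search_returns_exactly_planted_hits(ontology):
    case = generate_case_study(SyntheticConfig(n_compounds=400, n_case_hits=12, seed=21))
    hits = multi_parameter_search(case.database, TRIPLE, ontology)
    assert sorted(h.compound_id for h in hits) == case.planted_hits


def test_search_zero_planted_hits(ontology):
    case = generate_case_study(SyntheticConfig(n_compounds=120, n_case_hits=0, seed=22))
    assert multi_parameter_search(case.database, TRIPLE, ontology) == []


def test_search_hits_span_species(ontology):
    case = generate_case_study(SyntheticConfig(n_compounds=400, n_case_hits=10, seed=23))
    hits = multi_parameter_search(case.database, TRIPLE, ontology)
    species = {s for h in hits for s in h.species}
    assert "dog" in species and "rat" in species
    actions = {h.pharmacological_action for h in hits}
    assert "EP1 receptor antagonist" in actions


def test_empty_criteria_is_vacuous_conjunction(ontology):
    db = build_db([{"id": "A", "alt": "pos"}, {"id": "B"}])
    hits = multi_parameter_search(db, [], ontology)
    assert sorted(h.compound_id for h in hits) == ["A", "B"]


def test_search_anti_monotone_in_criteria(ontology):
    db = generate(SyntheticConfig(n_compounds=300, seed=24))
    one = {h.compound_id for h in multi_parameter_search(db, TRIPLE[:1], ontology)}
    both = {h.compound_id for h in multi_parameter_search(db, TRIPLE[:2], ontology)}
    assert both <= one


def test_per_study_mode_is_stricter(ontology):
    db = generate(SyntheticConfig(n_compounds=300, seed=25))
    loose = {h.compound_id for h in multi_parameter_search(db, TRIPLE, ontology)}
    strict = {h.compound_id for h in multi_parameter_search(db, TRIPLE, ontology, per_study=True)}
    assert strict <= loose


def test_unresolvable_criterion_term_raises(ontology):
    db = build_db([{"id": "A", "alt": "pos"}])
    with pytest.raises(CriterionError):
        multi_parameter_search(
            db, [FindingCriterion("clinical_chemistry", "unobtainium level")], ontology
        )


def test_criterion_spec_grammar():
    c = parse_criterion("haematology:Haemoglobin:decrease:tr")
    assert c == FindingCriterion("haematology", "Haemoglobin", "decrease", True)
    c = parse_criterion("histopathology:Necrosis:any-flag")
    assert c == FindingCriterion("histopathology", "Necrosis", "any", False)
    with pytest.raises(CriterionError):
        parse_criterion("histopathology:Necrosis:increase")
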