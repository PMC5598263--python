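"""Confusion matrices, MCC, exact Fisher test and parameter combinations."""

import math
import random
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from toxmine.biomarkers import (
    ConfusionMatrix,
    combine_calls,
    confusion_matrix,
    evaluate_combination,
    fisher_two_tailed,
    mcc,
    rank_biomarkers,
    sensitivity_specificity,
)
from toxmine.classification import NEGATIVE, POSITIVE

from conftest import build_db
from reference_values import SINGLE_PARAMETER_ROWS


def fisher_oracle(tp, fp, fn, tn):
    """Exact two-tailed Fisher p by Fraction enumeration (sum of small p)."""
    r1, r2, c1 = tp + fp, fn + tn, tp + fn
    N = r1 + r2
    denom = math.comb(N, c1)
    p_obs = Fraction(math.comb(r1, tp) * math.comb(r2, fn), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_x = Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
        if p_x <= p_obs:
            total += p_x
    return total


def test_mcc_matches_reference_rows():
    for _name, (tp, fp, fn, tn, ref_mcc, _s, _p) in SINGLE_PARAMETER_ROWS.items():
        assert round(mcc(ConfusionMatrix(tp, fp, fn, tn)), 4) == ref_mcc


def test_mcc_boundary_conventions():
    assert mcc(ConfusionMatrix(7, 0, 0, 7)) == 1.0
    assert mcc(ConfusionMatrix(0, 7, 7, 0)) == -1.0
    assert mcc(ConfusionMatrix(0, 0, 0, 9)) == 0.0  # zero-marginal convention


def test_sensitivity_specificity_reference_rows():
    for _name, (tp, fp, fn, tn, _m, ref_sens, ref_spec) in SINGLE_PARAMETER_ROWS.items():
        sens, spec = sensitivity_specificity(ConfusionMatrix(tp, fp, fn, tn))
        assert round(sens, 1) == ref_sens
        assert round(spec, 1) == ref_spec


def test_sensitivity_undefined_reported_as_missing():
    sens, spec = sensitivity_specificity(ConfusionMatrix(0, 3, 0, 5))
    assert sens is None and spec == pytest.approx(62.5)
    assert sensitivity_specificity(ConfusionMatrix(1, 0, 0, 1)) == (100.0, 100.0)


def test_fisher_small_table_closed_form():
    # margins (4,4 / 4,4): 5 possible tables, p = 34/70
    assert fisher_two_tailed(ConfusionMatrix(3, 1, 1, 3)) == pytest.approx(34 / 70, abs=1e-15)


def test_fisher_zero_margin_is_one():
    assert fisher_two_tailed(ConfusionMatrix(0, 0, 3, 5)) == 1.0
    assert fisher_two_tailed(ConfusionMatrix(2, 4, 0, 0)) == 1.0


def test_fisher_exhaustive_small_totals_match_fraction_oracle():
    for total in range(0, 21):
        for tp in range(total + 1):
            for fp in range(total - tp + 1):
                for fn in range(total - tp - fp + 1):
                    tn = total - tp - fp - fn
                    got = fisher_two_tailed(ConfusionMatrix(tp, fp, fn, tn))
                    want = float(fisher_oracle(tp, fp, fn, tn))
                    assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


def test_fisher_random_tables_up_to_total_200_match_oracle():
    rng = random.Random(20140401)
    for _ in range(400):
        total = rng.randrange(1, 201)
        cuts = sorted(rng.randrange(total + 1) for _ in range(3))
        tp, fp, fn = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
        tn = total - cuts[2]
        got = fisher_two_tailed(ConfusionMatrix(tp, fp, fn, tn))
        want = float(fisher_oracle(tp, fp, fn, tn))
        assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


@given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
def test_fisher_agrees_with_scipy(tp, fp, fn, tn):
    got = fisher_two_tailed(ConfusionMatrix(tp, fp, fn, tn))
    _odds, want = stats.fisher_exact([[tp, fp], [fn, tn]], alternative="two-sided")
    assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
def test_mcc_symmetries(tp, fp, fn, tn):
    m = ConfusionMatrix(tp, fp, fn, tn)
    value = mcc(m)
    assert -1.0 <= value <= 1.0
    # simultaneously swapping tp<->tn and fp<->fn leaves MCC unchanged
    assert mcc(ConfusionMatrix(tn, fn, fp, tp)) == pytest.approx(value, abs=1e-12)
    # flipping the predicted labels negates MCC
    assert mcc(ConfusionMatrix(fp, tp, tn, fn)) == pytest.approx(-value, abs=1e-12)


def _quadrant_db(tp, fp, fn, tn, param="alt"):
    specs = []
    for k in range(tp):
        specs.append({"id": f"TP{k:04d}", param: "pos", "liver": "pos"})
    for k in range(fp):
        specs.append({"id": f"FP{k:04d}", param: "pos", "liver": "neg"})
    for k in range(fn):
        specs.append({"id": f"FN{k:04d}", param: "neg", "liver": "pos"})
    for k in range(tn):
        specs.append({"id": f"TN{k:04d}", param: "neg", "liver": "neg"})
    return build_db(specs)


def test_confusion_matrix_from_constructed_calls(ontology):
    db = _quadrant_db(135, 64, 206, 392)
    m = confusion_matrix(db, "ALT", "Liver", ontology)
    assert (m.tp, m.fp, m.fn, m.tn) == (135, 64, 206, 392)
    assert round(mcc(m), 4) == 0.2921


def test_confusion_matrix_each_quadrant_once(ontology):
    m = confusion_matrix(_quadrant_db(1, 1, 1, 1), "ALT", "Liver", ontology)
    assert (m.tp, m.fp, m.fn, m.tn) == (1, 1, 1, 1)


def test_unmeasured_parameter_yields_zero_matrix(ontology):
    db = build_db([{"id": "A", "liver": "pos"}])
    with pytest.warns(UserWarning, match="empty base set"):
        m = confusion_matrix(db, "ALT", "Liver", ontology)
    assert m.total == 0


def test_not_examined_compounds_excluded_from_base_set(ontology):
    db = build_db(
        [
            {"id": "A", "alt": "pos", "liver": "pos"},
            {"id": "B", "alt": "pos"},  # liver never examined
            {"id": "C", "liver": "pos"},  # parameter never measured
        ]
    )
    m = confusion_matrix(db, "ALT", "Liver", ontology)
    assert m.total == 1 and m.tp == 1


@pytest.mark.parametrize(
    "a,b,mode,expected",
    [
        (POSITIVE, POSITIVE, "negative_emphasis", POSITIVE),
        (POSITIVE, POSITIVE, "positive_emphasis", POSITIVE),
        (NEGATIVE, NEGATIVE, "negative_emphasis", NEGATIVE),
        (POSITIVE, NEGATIVE, "negative_emphasis", NEGATIVE),
        (NEGATIVE, POSITIVE, "negative_emphasis", NEGATIVE),
        (POSITIVE, NEGATIVE, "positive_emphasis", POSITIVE),
        (NEGATIVE, POSITIVE, "positive_emphasis", POSITIVE),
    ],
)
def test_combine_calls_truth_table(a, b, mode, expected):
    assert combine_calls(a, b, mode) == expected


def test_combine_rejects_not_examined():
    with pytest.raises(ValueError):
        combine_calls(POSITIVE, "not_examined", "positive_emphasis")


def _pair_db(quads):
    """quads: list of (a_call, b_call, organ_call) strings 'pos'/'neg'."""
    specs = []
    for k, (a, b, organ) in enumerate(quads):
        specs.append({"id": f"P{k:04d}", "alt": a, "alp": b, "liver": organ})
    return build_db(specs)


def test_combination_reproduces_constructed_counts(ontology):
    # construct per-compound calls so that the combined (positive-emphasis)
    # table is exactly (fp, tp, tn, fn) = (53, 168, 379, 180)
    quads = []
    quads += [("pos", "neg", "pos")] * 168
    quads += [("pos", "neg", "neg")] * 53
    quads += [("neg", "neg", "neg")] * 379
    quads += [("neg", "neg", "pos")] * 180
    db = _pair_db(quads)
    result = evaluate_combination(db, "ALT", "ALP", "Liver", "positive_emphasis", ontology)
    m = result.matrix
    assert (m.fp, m.tp, m.tn, m.fn) == (53, 168, 379, 180)
    assert round(result.mcc, 4) == 0.3972
    assert round(result.sensitivity, 1) == 48.3
    assert round(result.specificity, 1) == 87.7


def test_combination_with_itself_equals_single(ontology):
    db = _quadrant_db(9, 4, 6, 11)
    single = confusion_matrix(db, "ALT", "Liver", ontology)
    for mode in ("negative_emphasis", "positive_emphasis"):
        combo = evaluate_combination(db, "ALT", "ALT", "Liver", mode, ontology)
        assert (combo.matrix.tp, combo.matrix.fp, combo.matrix.fn, combo.matrix.tn) == (
            single.tp, single.fp, single.fn, single.tn,
        )


def test_combination_emphasis_monotonicity(ontology):
    # second parameter is independent noise; positive emphasis can only add
    # true positives, negative emphasis can only remove false positives
    rng = random.Random(7)
    quads = []
    for _ in range(300):
        a = "pos" if rng.random() < 0.4 else "neg"
        b = "pos" if rng.random() < 0.3 else "neg"
        organ = "pos" if rng.random() < 0.5 else "neg"
        quads.append((a, b, organ))
    db = _pair_db(quads)
    single = confusion_matrix(db, "ALT", "Liver", ontology)
    pos = evaluate_combination(db, "ALT", "ALP", "Liver", "positive_emphasis", ontology)
    neg = evaluate_combination(db, "ALT", "ALP", "Liver", "negative_emphasis", ontology)
    assert pos.matrix.tp >= single.tp
    assert neg.matrix.fp <= single.fp
    assert neg.matrix.tp <= single.tp


def test_rank_biomarkers_filters_and_sorts(ontology):
    # ALT strongly associated, ALP pure noise on the same compounds
    rng = random.Random(3)
    specs = []
    for k in range(400):
        organ = "pos" if rng.random() < 0.5 else "neg"
        alt = "pos" if (organ == "pos") == (rng.random() < 0.9) else "neg"
        alp = "pos" if rng.random() < 0.3 else "neg"
        specs.append({"id": f"Q{k:04d}", "alt": alt, "alp": alp, "liver": organ})
    db = build_db(specs)
    ranked = rank_biomarkers(db, ["ALT", "ALP"], "Liver", ontology, alpha=0.001)
    assert [r.parameter for r in ranked] == ["Alanine aminotransferase (ALT)"]
    unfiltered = rank_biomarkers(db, ["ALT", "ALP"], "Liver", ontology, alpha=1.1)
    assert len(unfiltered) == 2
    assert unfiltered[0].mcc >= unfiltered[1].mcc


def test_identical_parameters_tie_broken_lexicographically(ontology):
    db = _quadrant_db(30, 5, 5, 30, param="alt")
    # give ALP identical calls by duplicating the quantitative rows under ALP
    dup = db.quantitative_findings.copy()
    dup["parameter_verbatim"] = "ALP"
    import pandas as pd

    db.quantitative_findings = pd.concat([db.quantitative_findings, dup], ignore_index=True)
    ranked = rank_biomarkers(db, ["ALT", "ALP"], "Liver", ontology, alpha=1.1)
    assert [r.parameter for r in ranked] == [
        "Alanine aminotransferase (ALT)",
        "Alkaline phosphatase (ALP)",
    ]
    assert ranked[0].mcc == ranked[1].mcc
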