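"""Distributions, rankings and the secondary-target dose filter."""

import numpy as np
import pandas as pd
import pytest

from toxmine.descriptive import (
    DEFAULT_DURATION_BINS,
    DurationBinning,
    cooccurring_organs,
    distribution,
    rank_by_duration,
    rank_endpoints,
    secondary_target_filter,
)
from toxmine.synthetic_data import (
    SyntheticConfig,
    generate,
    generate_secondary_target_scenario,
)

from conftest import build_db


def test_duration_bins_partition_positive_integers():
    bins = DEFAULT_DURATION_BINS
    for d, expected in [
        (1, "<20 days"), (19, "<20 days"), (20, "20-35 days"), (35, "20-35 days"),
        (36, "36-81 days"), (81, "36-81 days"), (82, "82-101 days"), (101, "82-101 days"),
        (102, "102-364 days"), (364, "102-364 days"), (365, ">=365 days"), (3650, ">=365 days"),
    ]:
        assert bins.bin_label(d) == expected


def test_species_distribution_counts_studies():
    specs = [{"id": f"R{i}", "species": "rat", "liver": "neg"} for i in range(10)]
    specs += [{"id": f"D{i}", "species": "dog", "liver": "neg"} for i in range(5)]
    db = build_db(specs)
    counts = distribution(db, "species")
    assert counts.to_dict() == {"dog": 5, "rat": 10}
    assert counts.sum() == len(db.studies)


def test_single_duration_all_in_one_bin():
    db = build_db([{"id": "A", "liver": "neg"}], duration_days=28)
    counts = distribution(db, "duration_bin")
    assert counts.to_dict() == {"20-35 days": 1}


def test_every_distribution_sums_to_study_count():
    db = generate(SyntheticConfig(n_compounds=100, seed=5))
    for axis in ("species", "route", "duration_bin", "glp_status"):
        assert distribution(db, axis).sum() == len(db.studies)


def test_planted_glp_share_recovered_within_three_se():
    db = generate(SyntheticConfig(n_compounds=600, seed=9))
    short = distribution(db, "glp_status", within_duration_bin="<20 days")
    n = short.sum()
    not_full_glp = short.drop("glp", errors="ignore").sum() / n
    se = np.sqrt(0.66 * 0.34 / n)
    assert abs(not_full_glp - 0.66) <= 3 * se
    sub = distribution(db, "glp_status", within_duration_bin="20-35 days")
    share_glp = sub.get("glp", 0) / sub.sum()
    assert abs(share_glp - 0.77) <= 3 * np.sqrt(0.77 * 0.23 / sub.sum())


def test_only_flagged_organ_ranks_first(ontology):
    db = build_db(
        [
            {"id": "A", "liver": "pos", "spleen": "neg"},
            {"id": "B", "liver": "pos", "kidney": "neg"},
            {"id": "C", "liver": "neg"},
        ]
    )
    ranking = rank_endpoints(db, ontology, kind="organ")
    assert ranking.iloc[0]["label"] == "Liver"
    assert ranking.iloc[0]["positives"] == 2
    assert ranking.iloc[0]["rank"] == 1


def test_planted_order_recovered_exactly(ontology):
    specs = []
    for i in range(6):
        specs.append({"id": f"L{i}", "liver": "pos"})
    for i in range(4):
        specs.append({"id": f"S{i}", "spleen": "pos"})
    for i in range(2):
        specs.append({"id": f"K{i}", "kidney": "pos"})
    ranking = rank_endpoints(build_db(specs), ontology, kind="organ")
    assert ranking["label"].tolist()[:3] == ["Liver", "Spleen", "Kidney"]
    assert ranking["positives"].tolist()[:3] == [6, 4, 2]


def test_top_n_larger_than_endpoints_returns_all(ontology):
    db = build_db([{"id": "A", "liver": "pos"}])
    ranking = rank_endpoints(db, ontology, kind="organ", top_n=50)
    assert len(ranking) == 1


def test_ranking_invariant_to_row_order(ontology):
    db = generate(SyntheticConfig(n_compounds=50, seed=2))
    shuffled = db.copy()
    shuffled.qualitative_findings = (
        shuffled.qualitative_findings.sample(frac=1, random_state=0).reset_index(drop=True)
    )
    a = rank_endpoints(db, ontology, kind="organ")
    b = rank_endpoints(shuffled, ontology, kind="organ")
    pd.testing.assert_frame_equal(a, b)


def test_rank_ties_broken_lexicographically(ontology):
    db = build_db([{"id": "A", "spleen": "pos", "kidney": "pos"}])
    ranking = rank_endpoints(db, ontology, kind="organ")
    assert ranking["label"].tolist() == ["Kidney", "Spleen"]


def test_single_bin_ranking_equals_whole_db_ranking(ontology):
    db = build_db([{"id": "A", "liver": "pos"}, {"id": "B", "spleen": "pos"}], duration_days=14)
    per_bin = rank_by_duration(db, ontology)
    assert list(per_bin.keys()) == ["<20 days"]
    pd.testing.assert_frame_equal(per_bin["<20 days"], rank_endpoints(db, ontology))


def test_liver_first_in_every_bin_when_planted(ontology):
    db = generate(SyntheticConfig(n_compounds=400, seed=4))
    per_bin = rank_by_duration(db, ontology)
    assert per_bin  # at least one non-empty bin
    for label, ranking in per_bin.items():
        assert ranking.iloc[0]["label"] == "Liver", label


def test_secondary_rows_dropped_primary_kept(ontology):
    # thymus flagged only at 100 mg/kg while liver is flagged at 10 -> removed
    db = generate_secondary_target_scenario(n_primary=1, n_secondary=1, n_other=0,
                                            n_coliver=0, n_cospleen=0, seed=0)
    result = secondary_target_filter(db, "thymus", ontology)
    assert result.positives_before == 2
    assert result.positives_after == 1
    assert (result.removed["organ_verbatim"].str.lower().str.contains("thym")).all()


def test_organ_at_lowest_flagged_dose_retained(ontology):
    # thymus flagged at the study's overall lowest flagged dose -> strict inequality keeps it
    db = build_db([{"id": "A", "thymus": "pos", "liver": "pos"}])
    result = secondary_target_filter(db, "thymus", ontology)
    assert result.positives_before == result.positives_after == 1
    assert len(result.removed) == 0


def test_filter_never_removes_the_minimum_dose_organ(ontology):
    db = generate(SyntheticConfig(n_compounds=150, seed=6))
    result = secondary_target_filter(db, "liver", ontology)
    # surviving is a subset of the input rows; only flagged rows are ever removed
    assert set(result.surviving.index).issubset(set(db.qualitative_findings.index))
    if len(result.removed):
        assert result.removed["treatment_related"].all()


def test_planted_236_to_136_reduction(ontology):
    db = generate_secondary_target_scenario(seed=1)
    result = secondary_target_filter(db, "Thymus", ontology)
    assert result.positives_before == 236
    assert result.positives_after == 136


def test_cooccurrence_counts_planted_intersections(ontology):
    db = generate_secondary_target_scenario(
        n_primary=50, n_secondary=10, n_other=5, n_coliver=30, n_cospleen=20, seed=3
    )
    table = cooccurring_organs(db, "thymus", ontology)
    counts = dict(zip(table["label"], table["co_positives"]))
    assert counts["Thymus"] == 50  # self co-count equals its surviving positive count
    assert counts["Liver"] == 30
    assert counts["Spleen"] == 20


def test_cooccurrence_empty_when_no_positives(ontology):
    db = build_db([{"id": "A", "thymus": "neg", "liver": "pos"}])
    table = cooccurring_organs(db, "thymus", ontology)
    assert len(table) == 0
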