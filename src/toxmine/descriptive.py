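"""Distribution summaries, frequency rankings and the secondary-target filter.

Covers the descriptive layer of the analysis: how the study collection is
split by species, exposure duration, administration route and GLP status;
which organs, histopathology findings and clinical-chemistry parameters
most often carry treatment-related calls; and the dose-based filter that
separates primary from secondary target organs (an organ whose findings
appear only above the lowest dose producing histopathology elsewhere in
the same study is suspected to be a secondary, indirect target).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import NEGATIVE, POSITIVE, EndpointKey, call_table
from .datamodel import ToxDatabase
from .ontology import OntologyMapping

__all__ = [
    "DurationBinning",
    "DEFAULT_DURATION_BINS",
    "distribution",
    "rank_endpoints",
    "rank_by_duration",
    "secondary_target_filter",
    "SecondaryTargetResult",
    "cooccurring_organs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DurationBinning:
    """Closed integer duration bins partitioning the positive integers.

    ``edges`` are the lower bounds of every bin after the first; the
    defaults give [1,19], [20,35], [36,81], [82,101], [102,364], [365,inf).
    """

    edges: tuple[int, ...] = (20, 36, 82, 102, 365)
    labels: tuple[str, ...] = (
        "<20 days",
        "20-35 days",
        "36-81 days",
        "82-101 days",
        "102-364 days",
        ">=365 days",
    )

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) + 1:
            raise ValueError("need exactly one more label than edges")
        if list(self.edges) != sorted(set(self.edges)):
            raise ValueError("edges must be strictly increasing")

    def bin_label(self, duration_days: int) -> str:
        idx = int(np.searchsorted(self.edges, duration_days, side="right"))
        return self.labels[idx]

    def assign(self, durations: pd.Series) -> pd.Series:
        idx = np.searchsorted(self.edges, durations.to_numpy(), side="right")
        return pd.Series([self.labels[i] for i in idx], index=durations.index)


DEFAULT_DURATION_BINS = DurationBinning()

_AXES = ("species", "route", "duration_bin", "glp_status")


def distribution(
    db: ToxDatabase,
    axis: str,
    binning: DurationBinning = DEFAULT_DURATION_BINS,
    within_duration_bin: str | None = None,
) -> pd.Series:
    """Study counts per category along one axis.

    ``within_duration_bin`` restricts to studies in one duration bin first
    (used e.g. for the GLP-status split of the short-term studies).  Counts
    always sum to the number of (restricted) studies.
    """
    if axis not in _AXES:
        raise ValueError(f"unknown distribution axis: {axis!r}; expected one of {_AXES}")
    studies = db.studies
    if within_duration_bin is not None:
        bins = binning.assign(studies["duration_days"])
        studies = studies[bins == within_duration_bin]
    if axis == "duration_bin":
        values = binning.assign(studies["duration_days"])
        counts = values.value_counts()
        # keep bin order, drop empty bins
        return counts.reindex([l for l in binning.labels if l in counts.index]).astype(int)
    return studies[axis].value_counts().sort_index()


def _ranking_frame(per_term: dict[str, tuple[int, int]], mapping, top_n: int | None) -> pd.DataFrame:
    rows = [
        {"label": mapping.label(t), "positives": p, "negatives": n}
        for t, (p, n) in per_term.items()
    ]
    df = pd.DataFrame(rows, columns=["label", "positives", "negatives"])
    df = df.sort_values(["positives", "label"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if top_n is not None:
        df = df.head(top_n)
    return df


_KIND_TO_ENDPOINT = {
    "organ": ("organ_histopathology", "organ"),
    "histopath_finding": ("named_finding", "histopathology_finding"),
    "cc_parameter": ("clinical_chemistry_parameter", "clinical_chemistry_parameter"),
}


def rank_endpoints(
    db: ToxDatabase,
    mapping: OntologyMapping,
    kind: str = "organ",
    top_n: int | None = 10,
) -> pd.DataFrame:
    """Endpoints ranked by the number of positive compounds.

    ``kind`` is ``organ`` (treatment-related histopathology per organ,
    rolled up through the ontology), ``histopath_finding`` (named
    microscopic findings) or ``cc_parameter`` (treatment-related
    clinical-chemistry changes).  Rows are sorted by positives descending,
    ties broken lexicographically by label; ``negatives`` counts compounds
    examined for the endpoint but never flagged.
    """
    if kind not in _KIND_TO_ENDPOINT:
        raise ValueError(f"unknown ranking kind: {kind!r}")
    endpoint_kind, domain = _KIND_TO_ENDPOINT[kind]
    per_term: dict[str, tuple[int, int]] = {}
    for term in mapping.domain_terms(domain):
        calls = call_table(db, EndpointKey(kind=endpoint_kind, selector=term), mapping)
        pos = int((calls["status"] == POSITIVE).sum())
        neg = int((calls["status"] == NEGATIVE).sum())
        if pos or neg:
            per_term[term] = (pos, neg)
    return _ranking_frame(per_term, mapping, top_n)


def rank_by_duration(
    db: ToxDatabase,
    mapping: OntologyMapping,
    binning: DurationBinning = DEFAULT_DURATION_BINS,
    kind: str = "organ",
    top_n: int | None = 10,
) -> dict[str, pd.DataFrame]:
    """Per-duration-bin endpoint ranking; empty bins are omitted."""
    bins = binning.assign(db.studies["duration_days"])
    out: dict[str, pd.DataFrame] = {}
    for label in binning.labels:
        study_ids = db.studies.loc[(bins == label).to_numpy(), "study_id"]
        if not len(study_ids):
            continue
        sub = db.restrict_to_studies(study_ids)
        out[label] = rank_endpoints(sub, mapping, kind=kind, top_n=top_n)
    return out


@dataclass
class SecondaryTargetResult:
    """Outcome of the secondary-target dose filter for one organ."""

    organ: str
    surviving: pd.DataFrame  # qualitative finding rows retained
    removed: pd.DataFrame  # flagged organ rows dropped as secondary
    positives_before: int  # compounds with >=1 flagged organ finding
    positives_after: int  # ... after the filter
    excluded_studies: list[str] = field(default_factory=list)


def secondary_target_filter(
    db: ToxDatabase, organ: str, mapping: OntologyMapping
) -> SecondaryTargetResult:
    """Drop an organ's flagged findings that occur only above the study's
    lowest histopathology-effect dose.

    Within each study, the organ's treatment-related histopathology rows
    are removed iff the lowest dose carrying a flagged finding in that
    organ is strictly greater than the lowest dose carrying any flagged
    histopathology finding in the study.  Doses are the normalized
    mg/kg/day values of the dose groups; studies with missing doses are
    excluded from the comparison (retained unfiltered) with a warning.
    """
    target = mapping.resolve("organ", organ)
    qf = db.qualitative_findings
    histo = qf[qf["finding_type"] == "histopathology"].copy()
    dg = db.dose_groups.set_index(["study_id", "group_id"])
    idx = pd.MultiIndex.from_arrays([histo["study_id"], histo["group_id"]])
    histo["dose"] = dg["dose"].reindex(idx).to_numpy()
    histo["is_control"] = dg["is_control"].reindex(idx).fillna(False).to_numpy()
    histo["flagged"] = histo["treatment_related"] & ~histo["is_control"].astype(bool)
    is_organ = histo["organ_verbatim"].map(
        lambda v: (t := mapping.map_term("organ", v)) is not None
        and mapping.is_ancestor_or_self(target, t)
    )
    histo["is_target_organ"] = is_organ

    excluded: list[str] = []
    drop_index: list = []
    flagged = histo[histo["flagged"]]
    for study_id, grp in flagged.groupby("study_id"):
        if grp["dose"].isna().any():
            excluded.append(str(study_id))
            continue
        organ_rows = grp[grp["is_target_organ"]]
        if not len(organ_rows):
            continue
        min_all = grp["dose"].min()
        min_organ = organ_rows["dose"].min()
        if min_organ > min_all:
            drop_index.extend(organ_rows.index)
    if excluded:
        logger.warning(
            "secondary-target filter: %d studies with missing doses excluded "
            "from the dose comparison: %s",
            len(excluded),
            excluded[:10],
        )

    compound_of = db.studies.set_index("study_id")["compound_id"]
    organ_flagged = histo[histo["flagged"] & histo["is_target_organ"]]
    before = organ_flagged["study_id"].map(compound_of).nunique()
    surviving_organ = organ_flagged.drop(index=drop_index)
    after = surviving_organ["study_id"].map(compound_of).nunique()

    surviving = qf.drop(index=drop_index)
    removed = qf.loc[drop_index]
    return SecondaryTargetResult(
        organ=target,
        surviving=surviving,
        removed=removed,
        positives_before=int(before),
        positives_after=int(after),
        excluded_studies=excluded,
    )


def cooccurring_organs(
    db: ToxDatabase,
    organ: str,
    mapping: OntologyMapping,
    apply_filter: bool = True,
    top_n: int | None = 10,
) -> pd.DataFrame:
    """Organs ranked by co-positive compounds among ``organ``'s positives.

    The reference set is the organ's positive compounds after the
    secondary-target filter (``apply_filter=False`` uses the unfiltered
    positives).  Counts are compound-level intersections of positive
    calls; the organ's co-count with itself equals its positive count.
    """
    target = mapping.resolve("organ", organ)
    result = secondary_target_filter(db, target, mapping)
    if apply_filter:
        base_db = db.copy()
        base_db.qualitative_findings = result.surviving.reset_index(drop=True)
    else:
        base_db = db
    compound_of = db.studies.set_index("study_id")["compound_id"]
    organ_calls = call_table(
        base_db, EndpointKey(kind="organ_histopathology", selector=target), mapping
    )
    reference = set(organ_calls.loc[organ_calls["status"] == POSITIVE, "compound_id"])
    per_term: dict[str, tuple[int, int]] = {}
    for term in mapping.domain_terms("organ"):
        calls = call_table(
            base_db, EndpointKey(kind="organ_histopathology", selector=term), mapping
        )
        pos = set(calls.loc[calls["status"] == POSITIVE, "compound_id"])
        co = len(pos & reference)
        if co:
            per_term[term] = (co, 0)
    ranked = _ranking_frame(per_term, mapping, top_n)
    return ranked.rename(columns={"positives": "co_positives"}).drop(columns=["negatives"])
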