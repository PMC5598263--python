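"""Per-compound binary classification of treatment-related findings.

A compound typically has several studies in different species, durations
and routes, each with multiple dose groups and timepoints.  For analysis
the findings are condensed to a single call per compound per endpoint:

* ``positive`` — at least one matching finding row is flagged
  treatment-related in the original study report (any study, any dose
  group, any timepoint);
* ``negative`` — matching rows exist but none is flagged;
* ``not_examined`` — no matching row exists at all.

The flag is the expert judgement captured from the report; it is never
re-derived from group means or incidences here.  Control-group rows never
contribute positive calls.  Organ endpoints match through the ontology
roll-up, so a finding recorded at "colon" counts toward "gastrointestinal
tract".
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datamodel import (
    QUALITATIVE_FINDING_TYPES,
    QUANTITATIVE_FINDING_TYPES,
    ToxDatabase,
)
from .ontology import OntologyMapping

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "NOT_EXAMINED",
    "EndpointError",
    "EndpointKey",
    "CompoundCall",
    "derive_call",
    "call_table",
    "parse_endpoint",
]

POSITIVE = "positive"
NEGATIVE = "negative"
NOT_EXAMINED = "not_examined"

_KINDS = ("finding_type", "organ_histopathology", "clinical_chemistry_parameter", "named_finding")


class EndpointError(KeyError):
    """The endpoint selector cannot be resolved."""


@dataclass(frozen=True)
class EndpointKey:
    """What to classify a compound against.

    kind ``finding_type``: selector is a finding-type value (e.g.
    ``histopathology``).  ``organ_histopathology``: selector is a preferred
    organ term (matches descendants via roll-up).
    ``clinical_chemistry_parameter``: selector is a preferred parameter
    term; ``direction`` restricts which flagged rows count as positive.
    ``named_finding``: selector is a preferred histopathology-finding term.
    """

    kind: str
    selector: str
    direction: str = "any"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise EndpointError(f"unknown endpoint kind: {self.kind!r}")
        quantitative = self.kind == "clinical_chemistry_parameter" or (
            self.kind == "finding_type" and self.selector in QUANTITATIVE_FINDING_TYPES
        )
        if self.direction != "any" and not quantitative:
            raise EndpointError("direction is only meaningful for quantitative endpoints")


@dataclass(frozen=True)
class CompoundCall:
    compound_id: str
    endpoint: EndpointKey
    status: str


def _matching_rows(
    db: ToxDatabase, endpoint: EndpointKey, mapping: OntologyMapping | None
) -> pd.DataFrame:
    """Finding rows matching the endpoint selector (direction ignored),
    annotated with compound_id, is_control and an ``effective_flag`` column
    (treatment_related, direction-checked, control rows voided)."""
    kind, sel = endpoint.kind, endpoint.selector
    if kind == "finding_type":
        if sel in QUALITATIVE_FINDING_TYPES:
            rows = db.qualitative_findings
        elif sel in QUANTITATIVE_FINDING_TYPES:
            rows = db.quantitative_findings
        else:
            raise EndpointError(f"unknown finding type: {sel!r}")
        rows = rows[rows["finding_type"] == sel]
    elif kind in ("organ_histopathology", "named_finding"):
        if mapping is None:
            raise EndpointError(f"endpoint kind {kind!r} needs an ontology mapping")
        domain = "organ" if kind == "organ_histopathology" else "histopathology_finding"
        column = "organ_verbatim" if kind == "organ_histopathology" else "finding_verbatim"
        target = _resolve(mapping, domain, sel)
        rows = db.qualitative_findings
        rows = rows[rows["finding_type"] == "histopathology"]
        mapped = rows[column].map(lambda v: mapping.map_term(domain, v))
        keep = mapped.map(
            lambda t: t is not None and mapping.is_ancestor_or_self(target, t)
        )
        rows = rows.loc[keep.astype(bool)]
    elif kind == "clinical_chemistry_parameter":
        if mapping is None:
            raise EndpointError("clinical chemistry endpoints need an ontology mapping")
        target = _resolve(mapping, "clinical_chemistry_parameter", sel)
        rows = db.quantitative_findings
        mapped = rows["parameter_verbatim"].map(
            lambda v: mapping.map_term("clinical_chemistry_parameter", v)
        )
        keep = mapped.map(
            lambda t: t is not None and mapping.is_ancestor_or_self(target, t)
        )
        rows = rows.loc[keep.astype(bool)]
    else:  # pragma: no cover - guarded by EndpointKey
        raise EndpointError(kind)

    rows = rows.copy()
    compound_of = db.studies.set_index("study_id")["compound_id"]
    rows["compound_id"] = rows["study_id"].map(compound_of)
    ctrl = db.dose_groups.set_index(["study_id", "group_id"])["is_control"]
    idx = pd.MultiIndex.from_arrays([rows["study_id"], rows["group_id"]])
    rows["is_control"] = (
        pd.Series(ctrl.reindex(idx).to_numpy(), index=rows.index).fillna(False).astype(bool)
    )

    flag = rows["treatment_related"] & ~rows["is_control"]
    if endpoint.direction != "any" and "direction" in rows.columns:
        flag = flag & (rows["direction"] == endpoint.direction)
    rows["effective_flag"] = flag
    return rows


def _resolve(mapping: OntologyMapping, domain: str, selector: str) -> str:
    try:
        return mapping.resolve(domain, selector)
    except KeyError as exc:
        raise EndpointError(str(exc)) from exc


def call_table(
    db: ToxDatabase, endpoint: EndpointKey, mapping: OntologyMapping | None = None
) -> pd.DataFrame:
    """One call per compound: columns ``compound_id``, ``status``.

    The three statuses partition the compound set of the database.
    """
    rows = _matching_rows(db, endpoint, mapping)
    examined = set(rows["compound_id"])
    positive = set(rows.loc[rows["effective_flag"], "compound_id"])
    status = db.compounds["compound_id"].map(
        lambda c: POSITIVE if c in positive else NEGATIVE if c in examined else NOT_EXAMINED
    )
    return pd.DataFrame({"compound_id": db.compounds["compound_id"], "status": status})


def derive_call(
    db: ToxDatabase,
    compound_id: str,
    endpoint: EndpointKey,
    mapping: OntologyMapping | None = None,
) -> CompoundCall:
    """The single condensed call for one compound (see module docstring)."""
    table = call_table(db, endpoint, mapping)
    hit = table.loc[table["compound_id"] == compound_id, "status"]
    status = hit.iloc[0] if len(hit) else NOT_EXAMINED
    return CompoundCall(compound_id=compound_id, endpoint=endpoint, status=status)


def parse_endpoint(spec: str) -> EndpointKey:
    """Parse the CLI endpoint grammar.

    ``type:<finding_type>[:direction]``, ``organ:<term>``,
    ``cc:<parameter>[:direction]``, ``finding:<term>``.
    """
    parts = spec.split(":")
    if len(parts) < 2:
        raise EndpointError(f"bad endpoint spec: {spec!r}")
    head, sel = parts[0], parts[1]
    direction = parts[2] if len(parts) > 2 else "any"
    kind = {
        "type": "finding_type",
        "organ": "organ_histopathology",
        "cc": "clinical_chemistry_parameter",
        "finding": "named_finding",
    }.get(head)
    if kind is None:
        raise EndpointError(f"bad endpoint kind prefix: {head!r}")
    return EndpointKey(kind=kind, selector=sel, direction=direction)
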