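"""Structure- and finding-based case-study queries.

Three operations support early-development questions of the kind "is this
substructure associated with these findings?":

* prevalence of a substructure (SMARTS pattern over compound SMILES, or a
  precomputed boolean column when structures are unavailable);
* co-occurrence of the substructure with a treatment-related finding
  category, reported as two proportions plus a two-tailed Fisher exact
  p-value on the 2x2 compound table (the exact test is an extension over
  eyeballing the two percentages and is labelled as such in the output);
* a multi-parameter search for compounds whose data satisfy a conjunction
  of treatment-related finding criteria (e.g. decreased haemoglobin with
  concomitantly increased platelets and reticulocytes), where
  "concomitant" is read at the compound level across studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .biomarkers import ConfusionMatrix, fisher_two_tailed
from .classification import POSITIVE, EndpointKey, call_table
from .datamodel import (
    QUALITATIVE_FINDING_TYPES,
    QUANTITATIVE_FINDING_TYPES,
    ToxDatabase,
)
from .ontology import OntologyMapping

__all__ = [
    "PatternError",
    "CriterionError",
    "FindingCriterion",
    "QueryHit",
    "CooccurrenceResult",
    "DEFAULT_BENZOIC_ACID_SMARTS",
    "match_substructure",
    "substructure_prevalence",
    "cooccurrence",
    "multi_parameter_search",
    "parse_criterion",
]

logger = logging.getLogger(__name__)

# free (protonatable) carboxylic acid attached to a benzene ring
DEFAULT_BENZOIC_ACID_SMARTS = "c1ccccc1C(=O)[OX2H1]"


class PatternError(ValueError):
    """The substructure pattern cannot be parsed."""


class CriterionError(KeyError):
    """A finding criterion references an unresolvable term or type."""


def match_substructure(db: ToxDatabase, pattern: str | None) -> pd.Series:
    """Boolean per-compound series: does the compound contain the pattern?

    ``pattern=None`` uses the precomputed ``has_substructure`` column (the
    chemistry-free path); otherwise the SMARTS pattern is matched against
    the ``smiles`` column with RDKit.  Compounds without a resolvable
    structure are NA (excluded from prevalence denominators) and their
    count is logged.
    """
    comp = db.compounds
    if pattern is None:
        if "has_substructure" not in comp.columns:
            raise PatternError(
                "no pattern given and the compounds table has no 'has_substructure' column"
            )
        return pd.Series(comp["has_substructure"].astype(bool).to_numpy(), index=comp["compound_id"])

    try:
        from rdkit import Chem, RDLogger
    except ImportError as exc:  # pragma: no cover - rdkit is an optional extra
        raise PatternError(
            "SMARTS matching requires rdkit; pass pattern=None to use the "
            "precomputed substructure column"
        ) from exc
    RDLogger.DisableLog("rdApp.*")
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise PatternError(f"unparseable SMARTS pattern: {pattern!r}")
    out = {}
    n_missing = 0
    for cid, smi in zip(comp["compound_id"], comp["smiles"]):
        if not smi:
            out[cid] = pd.NA
            n_missing += 1
            continue
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            out[cid] = pd.NA
            n_missing += 1
            continue
        out[cid] = mol.HasSubstructMatch(query)
    if n_missing:
        logger.info("substructure match: %d compounds without resolvable structures excluded", n_missing)
    return pd.Series(out, dtype="boolean")


def substructure_prevalence(db: ToxDatabase, pattern: str | None = DEFAULT_BENZOIC_ACID_SMARTS) -> float:
    """Fraction of structure-resolvable compounds containing the pattern."""
    matches = match_substructure(db, pattern)
    known = matches.dropna()
    if not len(known):
        return 0.0
    return float(known.astype(bool).mean())


@dataclass
class CooccurrenceResult:
    """Substructure-by-finding co-occurrence summary."""

    pattern: str
    finding_category: str
    n_with_pattern: int
    n_total: int
    prop_with_pattern: float | None  # finding rate among pattern-bearing compounds
    prop_overall: float  # finding rate among all queried compounds
    table: ConfusionMatrix  # pattern x finding 2x2
    fisher_p: float
    conclusion: str
    note: str = (
        "the Fisher exact test is an extension beyond the direct comparison "
        "of the two proportions"
    )


def cooccurrence(
    db: ToxDatabase,
    pattern: str | None,
    finding_category: str | EndpointKey,
    mapping: OntologyMapping | None = None,
    alpha: float = 0.05,
) -> CooccurrenceResult:
    """Is a treatment-related finding category over-represented among the
    compounds carrying a substructure?

    Compares the finding rate in the pattern-bearing subset with the rate
    over all queried compounds and tests the pattern-by-finding 2x2 table
    with the two-tailed Fisher exact test.  The conclusion is "no evidence
    of over-representation" when the subset rate does not exceed the
    overall rate or the test is not significant at ``alpha``.
    """
    endpoint = (
        finding_category
        if isinstance(finding_category, EndpointKey)
        else EndpointKey(kind="finding_type", selector=str(finding_category))
    )
    calls = call_table(db, endpoint, mapping)
    positive = calls["status"] == POSITIVE
    matches = match_substructure(db, pattern).reindex(calls["compound_id"])
    known = matches.notna().to_numpy()
    has = matches.fillna(False).astype(bool).to_numpy()

    n_total = int(known.sum())
    n_with = int((known & has).sum())
    pos = positive.to_numpy()
    a = int((known & has & pos).sum())  # pattern & finding
    b = n_with - a
    c = int((known & ~has & pos).sum())
    d = (n_total - n_with) - c
    table = ConfusionMatrix(tp=a, fp=b, fn=c, tn=d)
    p = fisher_two_tailed(table)
    prop_with = a / n_with if n_with else None
    prop_overall = int((known & pos).sum()) / n_total if n_total else 0.0
    if prop_with is None or prop_with <= prop_overall or p >= alpha:
        conclusion = "no evidence of over-representation"
    else:
        conclusion = "over-represented"
    return CooccurrenceResult(
        pattern=str(pattern),
        finding_category=endpoint.selector,
        n_with_pattern=n_with,
        n_total=n_total,
        prop_with_pattern=prop_with,
        prop_overall=prop_overall,
        table=table,
        fisher_p=p,
        conclusion=conclusion,
    )


@dataclass(frozen=True)
class FindingCriterion:
    """One conjunct of a multi-parameter query.

    ``parameter_or_finding`` is resolved through the ontology: the
    quantitative-parameter domain for quantitative finding types, the
    histopathology-finding domain otherwise.  ``direction`` applies only
    to quantitative types.
    """

    finding_type: str
    parameter_or_finding: str
    direction: str = "any"
    require_treatment_related: bool = True

    def __post_init__(self) -> None:
        if self.finding_type not in QUALITATIVE_FINDING_TYPES + QUANTITATIVE_FINDING_TYPES:
            raise CriterionError(f"unknown finding type: {self.finding_type!r}")
        if self.direction != "any" and self.finding_type not in QUANTITATIVE_FINDING_TYPES:
            raise CriterionError("direction applies only to quantitative finding types")


@dataclass
class QueryHit:
    """One compound satisfying every criterion, with its study metadata."""

    compound_id: str
    pharmacological_action: str
    species: list[str]
    studies: pd.DataFrame  # study_id, species, strain, route, duration_days, vehicle, sexes


def _criterion_rows(
    db: ToxDatabase, criterion: FindingCriterion, mapping: OntologyMapping
) -> pd.DataFrame:
    quantitative = criterion.finding_type in QUANTITATIVE_FINDING_TYPES
    if quantitative:
        rows = db.quantitative_findings
        rows = rows[rows["finding_type"] == criterion.finding_type]
        domain, column = "clinical_chemistry_parameter", "parameter_verbatim"
    else:
        rows = db.qualitative_findings
        rows = rows[rows["finding_type"] == criterion.finding_type]
        domain, column = "histopathology_finding", "finding_verbatim"
    try:
        target = mapping.resolve(domain, criterion.parameter_or_finding)
    except KeyError as exc:
        raise CriterionError(str(exc)) from exc
    mapped = rows[column].map(lambda v: mapping.map_term(domain, v))
    rows = rows.loc[mapped.map(lambda t: t is not None and mapping.is_ancestor_or_self(target, t)).astype(bool)]
    if quantitative and criterion.direction != "any":
        rows = rows.loc[(rows["direction"] == criterion.direction).astype(bool)]
    if criterion.require_treatment_related:
        ctrl = db.dose_groups.set_index(["study_id", "group_id"])["is_control"]
        idx = pd.MultiIndex.from_arrays([rows["study_id"], rows["group_id"]])
        is_control = pd.Series(ctrl.reindex(idx).to_numpy(), index=rows.index).fillna(False)
        rows = rows[rows["treatment_related"] & ~is_control.astype(bool)]
    return rows


def multi_parameter_search(
    db: ToxDatabase,
    criteria: list[FindingCriterion],
    mapping: OntologyMapping,
    per_study: bool = False,
) -> list[QueryHit]:
    """Compounds whose findings satisfy every criterion.

    By default the conjunction is evaluated at the compound level (each
    criterion met by >=1 finding in any of the compound's studies);
    ``per_study=True`` requires a single study to satisfy all criteria.
    An empty criteria list is the vacuous conjunction and returns every
    compound.  Hits carry the metadata of the studies contributing
    matching findings and the set of species involved.
    """
    compound_of = db.studies.set_index("study_id")["compound_id"]
    if not criteria:
        satisfying = list(db.compounds["compound_id"])
        study_sets: dict[str, set] = {
            c: set(db.studies.loc[db.studies["compound_id"] == c, "study_id"])
            for c in satisfying
        }
    else:
        per_criterion: list[dict[str, set]] = []
        for criterion in criteria:
            rows = _criterion_rows(db, criterion, mapping)
            found: dict[str, set] = {}
            for sid in rows["study_id"]:
                found.setdefault(compound_of[sid], set()).add(sid)
            per_criterion.append(found)
        if per_study:
            satisfying = []
            study_sets = {}
            for c in db.compounds["compound_id"]:
                joint = None
                for found in per_criterion:
                    s = found.get(c, set())
                    joint = s if joint is None else joint & s
                if joint:
                    satisfying.append(c)
                    study_sets[c] = joint
        else:
            common = set(per_criterion[0])
            for found in per_criterion[1:]:
                common &= set(found)
            satisfying = [c for c in db.compounds["compound_id"] if c in common]
            study_sets = {
                c: set().union(*(found.get(c, set()) for found in per_criterion))
                for c in satisfying
            }

    action = db.compounds.set_index("compound_id")["pharmacological_action"]
    sexes_of = (
        db.dose_groups.groupby("study_id")["sex"].agg(lambda s: ", ".join(sorted(set(s))))
        if len(db.dose_groups)
        else pd.Series(dtype=str)
    )
    hits = []
    for c in satisfying:
        st = db.studies[db.studies["study_id"].isin(study_sets[c])].copy()
        st = st.sort_values("study_id").reset_index(drop=True)
        st["sexes"] = st["study_id"].map(sexes_of).fillna("")
        hits.append(
            QueryHit(
                compound_id=c,
                pharmacological_action=str(action.get(c, "")),
                species=sorted(set(st["species"])),
                studies=st[
                    ["study_id", "species", "strain", "route", "duration_days", "vehicle", "sexes"]
                ],
            )
        )
    return hits


def parse_criterion(spec: str) -> FindingCriterion:
    """Parse the CLI criterion grammar
    ``<finding_type>:<term>[:increase|decrease|any][:tr|any-flag]``."""
    parts = spec.split(":")
    if len(parts) < 2:
        raise CriterionError(f"bad criterion spec: {spec!r}")
    finding_type, term = parts[0], parts[1]
    direction = "any"
    require_tr = True
    for extra in parts[2:]:
        if extra in ("increase", "decrease", "any"):
            direction = extra
        elif extra == "tr":
            require_tr = True
        elif extra == "any-flag":
            require_tr = False
        else:
            raise CriterionError(f"bad criterion qualifier: {extra!r}")
    return FindingCriterion(
        finding_type=finding_type,
        parameter_or_finding=term,
        direction=direction,
        require_treatment_related=require_tr,
    )
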