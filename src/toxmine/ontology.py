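"""Verbatim-to-preferred-term mapping, hierarchy roll-up and coverage.

Legacy study reports use wildly heterogeneous terms for the same organ,
lesion or laboratory parameter ("hepar", "LIVER", "liver"), so findings are
stored verbatim and mapped retrospectively to a curated ontology of
preferred terms.  Terms form a forest (each term has at most one parent),
which lets findings recorded at different granularity ("colon" versus
"gastrointestinal tract") be analysed together by rolling counts up to a
common ancestor level.

Matching is case-insensitive after whitespace normalization; an unmapped
verbatim is a value (``None``), never a guess.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .datamodel import LoadError, ToxDatabase, ValidationError

__all__ = [
    "DOMAINS",
    "OntologyMapping",
    "normalize_verbatim",
    "read_ontology",
    "write_ontology",
    "rollup_counts",
    "coverage",
    "filter_mapped",
]

DOMAINS = ("organ", "histopathology_finding", "clinical_chemistry_parameter")

# which database table/column each ontology domain annotates
_DOMAIN_SOURCES = {
    "organ": ("qualitative_findings", "organ_verbatim", {"histopathology", "gross_necropsy"}),
    "histopathology_finding": ("qualitative_findings", "finding_verbatim", {"histopathology"}),
    "clinical_chemistry_parameter": ("quantitative_findings", "parameter_verbatim", None),
}


def normalize_verbatim(text: str) -> str:
    """Collapse internal whitespace and casefold; the documented, reversible
    normalization applied before synonym lookup."""
    return " ".join(str(text).split()).casefold()


@dataclass
class OntologyMapping:
    """A preferred-term table plus a synonym (verbatim) table.

    ``terms``: columns term_id, label, parent_id (empty string for roots),
    domain.  ``synonyms``: columns domain, verbatim, term_id.
    """

    terms: pd.DataFrame
    synonyms: pd.DataFrame

    def __post_init__(self) -> None:
        self.terms = self.terms.reset_index(drop=True).astype(str)
        self.synonyms = self.synonyms.reset_index(drop=True).astype(str)
        self.validate()
        self._parent = dict(zip(self.terms["term_id"], self.terms["parent_id"]))
        self._label = dict(zip(self.terms["term_id"], self.terms["label"]))
        self._domain = dict(zip(self.terms["term_id"], self.terms["domain"]))
        self._lookup: dict[tuple[str, str], str] = {}
        for domain, verbatim, term_id in self.synonyms.itertuples(index=False):
            self._lookup[(domain, normalize_verbatim(verbatim))] = term_id
        # labels resolve as synonyms of their own term
        for term_id, label, _parent, domain in self.terms.itertuples(index=False):
            self._lookup.setdefault((domain, normalize_verbatim(label)), term_id)

    def validate(self) -> None:
        problems = []
        dup = self.terms["term_id"][self.terms["term_id"].duplicated()]
        if len(dup):
            problems.append(f"ontology terms: duplicate term_id {sorted(set(dup))}")
        known = set(self.terms["term_id"])
        bad_parent = self.terms.index[
            (self.terms["parent_id"] != "") & ~self.terms["parent_id"].isin(known)
        ]
        if len(bad_parent):
            problems.append(f"ontology terms: unknown parent_id at rows {list(bad_parent)}")
        orphan = self.synonyms.index[~self.synonyms["term_id"].isin(known)]
        if len(orphan):
            problems.append(f"ontology synonyms: unknown term_id at rows {list(orphan)}")
        key = self.synonyms["domain"] + "\x00" + self.synonyms["verbatim"].map(normalize_verbatim)
        amb = self.synonyms[key.duplicated(keep=False)]
        if len(amb):
            conflicting = amb.groupby(
                amb["domain"] + "\x00" + amb["verbatim"].map(normalize_verbatim)
            )["term_id"].nunique()
            if (conflicting > 1).any():
                problems.append("ontology synonyms: a (domain, verbatim) maps to several terms")
        # cycle check: follow parents with a visited set
        parent = dict(zip(self.terms["term_id"], self.terms["parent_id"]))
        for start in parent:
            seen = set()
            node = start
            while node:
                if node in seen:
                    problems.append(f"ontology terms: parent cycle through '{start}'")
                    break
                seen.add(node)
                node = parent.get(node, "")
        if problems:
            raise ValidationError(problems)

    # -- lookups ---------------------------------------------------------
    def map_term(self, domain: str, verbatim: str) -> str | None:
        """Preferred term id for a verbatim, or ``None`` when unmapped."""
        return self._lookup.get((domain, normalize_verbatim(verbatim)))

    def label(self, term_id: str) -> str:
        return self._label.get(term_id, term_id)

    def resolve(self, domain: str, selector: str) -> str:
        """Resolve a user-supplied selector (term id, label or synonym) to a
        term id; raises ``KeyError`` when nothing matches."""
        if selector in self._domain and self._domain[selector] == domain:
            return selector
        hit = self.map_term(domain, selector)
        if hit is None:
            raise KeyError(f"unresolvable {domain} selector: {selector!r}")
        return hit

    def ancestors(self, term_id: str) -> list[str]:
        """Chain [term, parent, ..., root]; a term absent from the term table
        is its own root."""
        chain = [term_id]
        node = self._parent.get(term_id, "")
        while node:
            chain.append(node)
            node = self._parent.get(node, "")
        return chain

    def ancestor_at_level(self, term_id: str, level: int | None) -> str:
        """Ancestor at ``level`` steps below the root (0 = root); ``None``
        keeps the term itself (leaf level); terms shallower than ``level``
        stay themselves."""
        if level is None:
            return term_id
        chain = self.ancestors(term_id)[::-1]  # root ... term
        return chain[min(level, len(chain) - 1)]

    def is_ancestor_or_self(self, ancestor: str, term_id: str) -> bool:
        return ancestor in self.ancestors(term_id)

    def domain_terms(self, domain: str) -> list[str]:
        return list(self.terms.loc[self.terms["domain"] == domain, "term_id"])


def rollup_counts(
    compound_terms: Mapping[str, Iterable[str]],
    mapping: OntologyMapping,
    level: int | None = None,
) -> dict[str, int]:
    """Compound counts per term rolled up to an ancestor level.

    ``compound_terms`` maps each compound to the preferred terms it hit; a
    compound is counted once per ancestor even when several of its terms
    roll up to the same ancestor.  ``level=None`` is the leaf level
    (identity on the input terms).
    """
    counts: dict[str, int] = {}
    for _compound, terms in compound_terms.items():
        ancestors = {mapping.ancestor_at_level(t, level) for t in terms}
        for anc in ancestors:
            counts[anc] = counts.get(anc, 0) + 1
    return counts


def coverage(
    db: ToxDatabase,
    mapping: OntologyMapping,
    domain: str,
    basis: str = "distinct_terms",
) -> float:
    """Percentage of verbatim terms (or finding records) with a mapping.

    ``basis='distinct_terms'`` counts unique normalized verbatims (the
    default); ``basis='records'`` counts finding rows.  0.0 when there is
    nothing to map.
    """
    table, column, type_filter = _DOMAIN_SOURCES[domain]
    df = getattr(db, table)
    if type_filter is not None:
        df = df[df["finding_type"].isin(type_filter)]
    verbatims = df[column][df[column] != ""]
    if basis == "distinct_terms":
        distinct = {normalize_verbatim(v) for v in verbatims}
        if not distinct:
            return 0.0
        mapped = sum(1 for v in distinct if (domain, v) in mapping._lookup)
        return 100.0 * mapped / len(distinct)
    if basis == "records":
        if not len(verbatims):
            return 0.0
        mapped = sum(1 for v in verbatims if mapping.map_term(domain, v) is not None)
        return 100.0 * mapped / len(verbatims)
    raise ValueError(f"unknown coverage basis: {basis!r}")


def filter_mapped(findings: pd.DataFrame, mapping: OntologyMapping, domain: str) -> pd.DataFrame:
    """Restrict finding rows to those whose verbatim maps in ``domain``.

    Unmapped terms pending curation are excluded from term-level analyses.
    """
    _table, column, _types = _DOMAIN_SOURCES[domain]
    keep = findings[column].map(lambda v: mapping.map_term(domain, v) is not None)
    return findings[keep]


def write_ontology(mapping: OntologyMapping, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mapping.terms.to_csv(path / "ontology_terms.csv", index=False, encoding="utf-8", lineterminator="\n")
    mapping.synonyms.to_csv(
        path / "ontology_synonyms.csv", index=False, encoding="utf-8", lineterminator="\n"
    )


def read_ontology(path: str | Path) -> OntologyMapping:
    path = Path(path)
    frames = {}
    for name in ("ontology_terms", "ontology_synonyms"):
        fp = path / f"{name}.csv"
        if not fp.exists():
            raise LoadError(f"missing ontology file '{name}.csv' in {path}")
        frames[name] = pd.read_csv(fp, dtype=str, keep_default_na=False, encoding="utf-8")
    return OntologyMapping(terms=frames["ontology_terms"], synonyms=frames["ontology_synonyms"])
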