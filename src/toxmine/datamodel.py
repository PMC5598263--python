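"""Domain types and tabular I/O for the harmonized repeat-dose toxicity database.

The database is a small relational schema of five tables mirroring how
systemic-toxicity study reports are captured: compounds (test articles),
studies, dose/sex groups, qualitative findings (histopathology, clinical
signs, gross necropsy; incidence and severity per group) and quantitative
findings (clinical chemistry, haematology, haemostasis, urinalysis, organ
weights; group mean, SD, units, fold change and direction).  Every finding
row carries the expert ``treatment_related`` judgement call copied from the
original study report — downstream classification uses that flag and never
re-derives it from the raw numbers.

Tables are exchanged as UTF-8, comma-delimited, RFC-4180-quoted CSV files
with a header row; verbatim report terms are preserved byte-exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LoadError",
    "ValidationError",
    "ToxDatabase",
    "DatabaseCounts",
    "read_database",
    "write_database",
    "summarize_counts",
    "concat_databases",
    "SENSITIVITY_LABELS",
    "GLP_STATUSES",
    "SEXES",
    "QUALITATIVE_FINDING_TYPES",
    "QUANTITATIVE_FINDING_TYPES",
    "DIRECTIONS",
]


class LoadError(RuntimeError):
    """A table file is missing or unreadable."""


class ValidationError(ValueError):
    """One or more rows violate a schema invariant.

    ``problems`` lists one human-readable message per violated invariant,
    including the offending row indices.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("database validation failed:\n" + "\n".join(self.problems))


SENSITIVITY_LABELS = ("non_confidential", "confidential")
GLP_STATUSES = ("glp", "non_glp", "glp_in_part", "unknown")
SEXES = ("male", "female", "both")
QUALITATIVE_FINDING_TYPES = ("histopathology", "clinical_signs", "gross_necropsy")
QUANTITATIVE_FINDING_TYPES = (
    "clinical_chemistry",
    "haematology",
    "haemostasis",
    "urinalysis",
    "organ_weights",
)
DIRECTIONS = ("increase", "decrease", "unchanged")

# canonical column order per table; extra columns are preserved on read/write
SCHEMA: dict[str, list[str]] = {
    "compounds": ["compound_id", "smiles", "sensitivity_label", "pharmacological_action"],
    "studies": [
        "study_id",
        "compound_id",
        "species",
        "strain",
        "route",
        "duration_days",
        "glp_status",
        "vehicle",
    ],
    "dose_groups": ["study_id", "group_id", "dose", "sex", "is_control"],
    "qualitative_findings": [
        "study_id",
        "group_id",
        "finding_type",
        "organ_verbatim",
        "finding_verbatim",
        "affected",
        "examined",
        "severity",
        "timepoint_days",
        "treatment_related",
    ],
    "quantitative_findings": [
        "study_id",
        "group_id",
        "finding_type",
        "parameter_verbatim",
        "mean",
        "sd",
        "units",
        "fold_change",
        "direction",
        "timepoint_days",
        "treatment_related",
    ],
}

_BOOL_COLUMNS = {"treatment_related", "is_control", "has_substructure"}
_INT_COLUMNS = {"duration_days", "affected", "examined", "timepoint_days"}
_NULLABLE_INT_COLUMNS = {"severity"}
_FLOAT_COLUMNS = {"dose", "mean", "sd", "fold_change"}


def _empty_table(name: str) -> pd.DataFrame:
    return _coerce_types(pd.DataFrame({c: [] for c in SCHEMA[name]}))


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the canonical dtype to each known column; leave text as str."""
    out = df.copy()
    for col in out.columns:
        if col in _BOOL_COLUMNS:
            if out[col].dtype != bool:
                out[col] = (
                    out[col]
                    .map(lambda v: str(v).strip().lower() in ("true", "1", "yes"))
                    .astype(bool)
                )
        elif col in _INT_COLUMNS:
            out[col] = pd.to_numeric(out[col], errors="coerce").astype("int64" if len(out) else "int64")
        elif col in _NULLABLE_INT_COLUMNS:
            out[col] = pd.to_numeric(out[col], errors="coerce").astype("Int64")
        elif col in _FLOAT_COLUMNS:
            out[col] = pd.to_numeric(out[col], errors="coerce").astype(float)
        else:
            out[col] = out[col].astype(object).where(pd.notna(out[col]), "").astype(str)
    return out


@dataclass
class ToxDatabase:
    """In-memory container for the five relational tables.

    Construct directly from DataFrames (columns per :data:`SCHEMA`) or via
    :func:`read_database`.  :meth:`validate` enforces referential integrity
    and the per-table invariants and is called by the readers/writers.
    """

    compounds: pd.DataFrame = field(default_factory=lambda: _empty_table("compounds"))
    studies: pd.DataFrame = field(default_factory=lambda: _empty_table("studies"))
    dose_groups: pd.DataFrame = field(default_factory=lambda: _empty_table("dose_groups"))
    qualitative_findings: pd.DataFrame = field(
        default_factory=lambda: _empty_table("qualitative_findings")
    )
    quantitative_findings: pd.DataFrame = field(
        default_factory=lambda: _empty_table("quantitative_findings")
    )

    def __post_init__(self) -> None:
        for f in fields(self):
            df = getattr(self, f.name)
            missing = [c for c in SCHEMA[f.name] if c not in df.columns]
            if missing:
                raise ValidationError([f"table '{f.name}' lacks columns {missing}"])
            ordered = SCHEMA[f.name] + [c for c in df.columns if c not in SCHEMA[f.name]]
            setattr(self, f.name, _coerce_types(df[ordered]).reset_index(drop=True))

    # -- convenience -----------------------------------------------------
    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def equals(self, other: "ToxDatabase") -> bool:
        return all(
            getattr(self, name).equals(getattr(other, name)) for name in self.tables()
        )

    def copy(self) -> "ToxDatabase":
        return ToxDatabase(**{k: v.copy() for k, v in self.tables().items()})

    def restrict_to_studies(self, study_ids) -> "ToxDatabase":
        """Sub-database containing only the given studies (and their groups,
        findings and referenced compounds)."""
        keep = set(study_ids)
        studies = self.studies[self.studies["study_id"].isin(keep)]
        compounds = self.compounds[
            self.compounds["compound_id"].isin(set(studies["compound_id"]))
        ]
        return ToxDatabase(
            compounds=compounds,
            studies=studies,
            dose_groups=self.dose_groups[self.dose_groups["study_id"].isin(keep)],
            qualitative_findings=self.qualitative_findings[
                self.qualitative_findings["study_id"].isin(keep)
            ],
            quantitative_findings=self.quantitative_findings[
                self.quantitative_findings["study_id"].isin(keep)
            ],
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> "ToxDatabase":
        problems: list[str] = []

        comp = self.compounds
        dup = comp["compound_id"][comp["compound_id"].duplicated()]
        if len(dup):
            problems.append(f"compounds: duplicate compound_id {sorted(set(dup))}")
        bad = comp.index[~comp["sensitivity_label"].isin(SENSITIVITY_LABELS)]
        if len(bad):
            problems.append(f"compounds: invalid sensitivity_label at rows {list(bad)}")
        leak = comp.index[
            (comp["sensitivity_label"] == "confidential") & (comp["smiles"] != "")
        ]
        if len(leak):
            problems.append(
                f"compounds: confidential compounds carry a structure at rows {list(leak)}"
            )

        st = self.studies
        dup = st["study_id"][st["study_id"].duplicated()]
        if len(dup):
            problems.append(f"studies: duplicate study_id {sorted(set(dup))}")
        known_compounds = set(comp["compound_id"])
        orphan = st.index[~st["compound_id"].isin(known_compounds)]
        if len(orphan):
            problems.append(f"studies: unresolvable compound_id at rows {list(orphan)}")
        bad = st.index[st["duration_days"] < 1] if len(st) else []
        if len(bad):
            problems.append(f"studies: duration_days < 1 at rows {list(bad)}")
        bad = st.index[~st["glp_status"].isin(GLP_STATUSES)]
        if len(bad):
            problems.append(f"studies: invalid glp_status at rows {list(bad)}")

        dg = self.dose_groups
        key = dg["study_id"] + "\x00" + dg["group_id"]
        dup = key[key.duplicated()]
        if len(dup):
            problems.append(
                f"dose_groups: duplicate (study_id, group_id) at rows {list(dup.index)}"
            )
        known_studies = set(st["study_id"])
        orphan = dg.index[~dg["study_id"].isin(known_studies)]
        if len(orphan):
            problems.append(f"dose_groups: unresolvable study_id at rows {list(orphan)}")
        if len(dg):
            bad = dg.index[dg["dose"] < 0]
            if len(bad):
                problems.append(f"dose_groups: negative dose at rows {list(bad)}")
            mismatch = dg.index[dg["is_control"] != (dg["dose"] == 0)]
            if len(mismatch):
                problems.append(
                    f"dose_groups: is_control inconsistent with dose=0 at rows {list(mismatch)}"
                )
        bad = dg.index[~dg["sex"].isin(SEXES)]
        if len(bad):
            problems.append(f"dose_groups: invalid sex at rows {list(bad)}")

        group_keys = set(key)
        for name, df, types in (
            ("qualitative_findings", self.qualitative_findings, QUALITATIVE_FINDING_TYPES),
            ("quantitative_findings", self.quantitative_findings, QUANTITATIVE_FINDING_TYPES),
        ):
            orphan = df.index[~df["study_id"].isin(known_studies)]
            if len(orphan):
                problems.append(f"{name}: unresolvable study_id at rows {list(orphan)}")
            fkey = df["study_id"] + "\x00" + df["group_id"]
            orphan = df.index[~fkey.isin(group_keys)]
            if len(orphan):
                problems.append(
                    f"{name}: unresolvable (study_id, group_id) at rows {list(orphan)}"
                )
            bad = df.index[~df["finding_type"].isin(types)]
            if len(bad):
                problems.append(f"{name}: invalid finding_type at rows {list(bad)}")

        qf = self.qualitative_findings
        if len(qf):
            bad = qf.index[qf["examined"] < 1]
            if len(bad):
                problems.append(f"qualitative_findings: examined < 1 at rows {list(bad)}")
            bad = qf.index[(qf["affected"] < 0) | (qf["affected"] > qf["examined"])]
            if len(bad):
                problems.append(
                    f"qualitative_findings: affected outside [0, examined] at rows {list(bad)}"
                )

        qt = self.quantitative_findings
        bad = qt.index[~qt["direction"].isin(DIRECTIONS)]
        if len(bad):
            problems.append(f"quantitative_findings: invalid direction at rows {list(bad)}")
        if len(qt):
            bad = qt.index[qt["sd"] < 0]
            if len(bad):
                problems.append(f"quantitative_findings: negative sd at rows {list(bad)}")
            bad = qt.index[qt["treatment_related"] & (qt["direction"] == "unchanged")]
            if len(bad):
                problems.append(
                    "quantitative_findings: treatment_related rows with direction="
                    f"'unchanged' at rows {list(bad)}"
                )

        if problems:
            raise ValidationError(problems)

        # contradictory but tolerated: a treatment-related call on a control group
        control_keys = set(key[dg["is_control"]]) if len(dg) else set()
        for name, df in (("qualitative_findings", qf), ("quantitative_findings", qt)):
            if not len(df):
                continue
            fkey = df["study_id"] + "\x00" + df["group_id"]
            n_ctrl = int((df["treatment_related"] & fkey.isin(control_keys)).sum())
            if n_ctrl:
                warnings.warn(
                    f"{name}: {n_ctrl} control-group rows are flagged treatment-related; "
                    "they never contribute positive calls",
                    stacklevel=2,
                )
        return self


@dataclass
class DatabaseCounts:
    """Record counts per table plus a per-compound breakdown."""

    tables: dict[str, int]
    per_compound: pd.DataFrame  # compound_id, n_studies, n_qualitative, n_quantitative

    def __getitem__(self, table: str) -> int:
        return self.tables[table]


def summarize_counts(db: ToxDatabase) -> DatabaseCounts:
    """Row counts for every table and per-compound study/finding counts."""
    tables = {name: len(df) for name, df in db.tables().items()}
    study_compound = db.studies.set_index("study_id")["compound_id"]
    per = pd.DataFrame({"compound_id": db.compounds["compound_id"]})
    n_studies = db.studies.groupby("compound_id").size()
    per["n_studies"] = per["compound_id"].map(n_studies).fillna(0).astype(int)
    for label, findings in (
        ("n_qualitative", db.qualitative_findings),
        ("n_quantitative", db.quantitative_findings),
    ):
        counts = (
            findings["study_id"].map(study_compound).value_counts()
            if len(findings)
            else pd.Series(dtype=int)
        )
        per[label] = per["compound_id"].map(counts).fillna(0).astype(int)
    return DatabaseCounts(tables=tables, per_compound=per)


def concat_databases(a: ToxDatabase, b: ToxDatabase) -> ToxDatabase:
    """Union of two databases with disjoint identifier spaces."""
    merged = ToxDatabase(
        **{
            name: pd.concat([ta, tb], ignore_index=True)
            for (name, ta), tb in zip(a.tables().items(), b.tables().values())
        }
    )
    return merged.validate()


def write_database(db: ToxDatabase, path: str | Path) -> None:
    """Write the five CSV tables under ``path`` (created if absent).

    UTF-8, comma-delimited, RFC-4180 quoting, LF line endings.  Booleans are
    serialized as ``true``/``false``; missing optional numerics as empty
    fields.  Output is byte-deterministic for equal databases.
    """
    db.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in db.tables().items():
        out = df.copy()
        for col in out.columns:
            if col in _BOOL_COLUMNS and len(out):
                out[col] = out[col].map({True: "true", False: "false"})
        out.to_csv(path / f"{name}.csv", index=False, encoding="utf-8", lineterminator="\n")


def read_database(path: str | Path, validate: bool = True) -> ToxDatabase:
    """Read a database directory written by :func:`write_database`.

    Raises :class:`LoadError` naming the first missing table file and
    :class:`ValidationError` listing every violated invariant.
    """
    path = Path(path)
    frames = {}
    for name in SCHEMA:
        fp = path / f"{name}.csv"
        if not fp.exists():
            raise LoadError(f"missing table file '{name}.csv' in {path}")
        df = pd.read_csv(fp, dtype=str, keep_default_na=False, encoding="utf-8")
        frames[name] = df if len(df.columns) else _empty_table(name)
    db = ToxDatabase(**frames)
    if validate:
        db.validate()
    return db
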