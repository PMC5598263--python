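"""Concordance of clinical-chemistry biomarkers with liver histopathology.

Compound-level confusion matrices: the evaluation base set is the set of
compounds for which both the clinical-chemistry parameter and the target
organ's histopathology were examined.  A true positive is a compound
flagged treatment-related on both; a false negative is parameter-negative
but organ-positive; a false positive parameter-positive but
organ-negative; a true negative unflagged on both.

From the matrix: Matthews correlation coefficient (0 by convention when a
marginal is empty), sensitivity/specificity as percentages, and a
two-tailed Fisher exact p-value computed by exact integer enumeration of
the hypergeometric distribution (sum of the probabilities of all tables
with the observed margins whose probability does not exceed that of the
observed table — the conventional "sum of small p" two-sided definition;
ties are resolved exactly on integer numerators).

Parameter pairs can be combined with either a negative or a positive
emphasis: agreement passes through, disagreement becomes negative or
positive respectively.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .classification import NEGATIVE, NOT_EXAMINED, POSITIVE, EndpointKey, call_table
from .datamodel import ToxDatabase
from .ontology import OntologyMapping

__all__ = [
    "ConfusionMatrix",
    "BiomarkerResult",
    "COMBINATION_MODES",
    "mcc",
    "sensitivity_specificity",
    "fisher_two_tailed",
    "confusion_matrix",
    "biomarker_result",
    "rank_biomarkers",
    "combine_calls",
    "evaluate_combination",
]

COMBINATION_MODES = ("negative_emphasis", "positive_emphasis")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Compound-level 2x2 table: tp, fp, fn, tn (all non-negative)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            iv = int(v)
            if iv != v or iv < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, iv)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def mcc(matrix: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0.0 when any marginal
    (row or column sum) is zero."""
    tp, fp, fn, tn = matrix.tp, matrix.fp, matrix.fn, matrix.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def sensitivity_specificity(matrix: ConfusionMatrix) -> tuple[float | None, float | None]:
    """(sensitivity, specificity) as percentages; ``None`` when the
    respective marginal is empty (undefined, not zero)."""
    tp, fp, fn, tn = matrix.tp, matrix.fp, matrix.fn, matrix.tn
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    return sens, spec


def fisher_two_tailed(matrix: ConfusionMatrix) -> float:
    """Two-tailed Fisher exact p-value by exhaustive enumeration.

    With fixed margins the table is determined by one cell x (the tp
    cell); P(x) = C(r1, x) C(r2, c1-x) / C(N, c1).  The p-value sums P
    over the support where the integer numerator C(r1,x)C(r2,c1-x) is
    <= the observed one (exact tie handling).  A zero margin admits a
    single table, hence p = 1.
    """
    tp, fp, fn, tn = matrix.tp, matrix.fp, matrix.fn, matrix.tn
    r1, r2 = tp + fp, fn + tn
    c1 = tp + fn
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    observed = math.comb(r1, tp) * math.comb(r2, fn)
    numerator = sum(w for w in weights if w <= observed)
    return float(Fraction(numerator, sum(weights)))


def confusion_matrix(
    db: ToxDatabase,
    parameter: str,
    target_organ: str,
    mapping: OntologyMapping,
    direction: str = "any",
) -> ConfusionMatrix:
    """Confusion matrix of a clinical-chemistry parameter against
    treatment-related histopathology in the target organ.

    Base set: compounds with both endpoints examined.  Emits a warning and
    returns the zero matrix when the base set is empty.
    """
    param_calls = call_table(
        db,
        EndpointKey(kind="clinical_chemistry_parameter", selector=parameter, direction=direction),
        mapping,
    )
    organ_calls = call_table(
        db, EndpointKey(kind="organ_histopathology", selector=target_organ), mapping
    )
    merged = param_calls.merge(organ_calls, on="compound_id", suffixes=("_param", "_organ"))
    base = merged[
        (merged["status_param"] != NOT_EXAMINED) & (merged["status_organ"] != NOT_EXAMINED)
    ]
    if not len(base):
        warnings.warn(
            f"empty base set for parameter {parameter!r} vs organ {target_organ!r}",
            stacklevel=2,
        )
        return ConfusionMatrix(0, 0, 0, 0)
    p = base["status_param"] == POSITIVE
    o = base["status_organ"] == POSITIVE
    return ConfusionMatrix(
        tp=int((p & o).sum()),
        fp=int((p & ~o).sum()),
        fn=int((~p & o).sum()),
        tn=int((~p & ~o).sum()),
    )


@dataclass
class BiomarkerResult:
    """One parameter's (or parameter pair's) concordance metrics."""

    parameter: str
    matrix: ConfusionMatrix
    mcc: float
    sensitivity: float | None
    specificity: float | None
    fisher_p: float

    @classmethod
    def from_matrix(cls, parameter: str, matrix: ConfusionMatrix) -> "BiomarkerResult":
        sens, spec = sensitivity_specificity(matrix)
        return cls(
            parameter=parameter,
            matrix=matrix,
            mcc=mcc(matrix),
            sensitivity=sens,
            specificity=spec,
            fisher_p=fisher_two_tailed(matrix),
        )

    def as_row(self) -> dict:
        m = self.matrix
        return {
            "parameter": self.parameter,
            "tp": m.tp,
            "fp": m.fp,
            "fn": m.fn,
            "tn": m.tn,
            "mcc": round(self.mcc, 4),
            "sensitivity": None if self.sensitivity is None else round(self.sensitivity, 1),
            "specificity": None if self.specificity is None else round(self.specificity, 1),
            "fisher_p": self.fisher_p,
        }


def biomarker_result(
    db: ToxDatabase, parameter: str, target_organ: str, mapping: OntologyMapping
) -> BiomarkerResult:
    matrix = confusion_matrix(db, parameter, target_organ, mapping)
    return BiomarkerResult.from_matrix(mapping.label(mapping.resolve("clinical_chemistry_parameter", parameter)), matrix)


def rank_biomarkers(
    db: ToxDatabase,
    parameters: list[str],
    target_organ: str,
    mapping: OntologyMapping,
    alpha: float = 0.001,
) -> list[BiomarkerResult]:
    """Significant parameters ranked by MCC.

    Keeps parameters whose two-tailed Fisher p is below ``alpha`` (default
    0.001), sorted by MCC descending with lexicographic tie-break.
    """
    results = [biomarker_result(db, p, target_organ, mapping) for p in parameters]
    kept = [r for r in results if r.fisher_p < alpha]
    return sorted(kept, key=lambda r: (-r.mcc, r.parameter))


def combine_calls(call_a: str, call_b: str, mode: str) -> str:
    """Combine two compound calls; agreement passes through, disagreement
    resolves by the chosen emphasis.  Inputs must be positive/negative
    (not-examined compounds are excluded from the base set upstream)."""
    if mode not in COMBINATION_MODES:
        raise ValueError(f"unknown combination mode: {mode!r}")
    for c in (call_a, call_b):
        if c not in (POSITIVE, NEGATIVE):
            raise ValueError(f"combine_calls expects positive/negative, got {c!r}")
    if call_a == call_b:
        return call_a
    return NEGATIVE if mode == "negative_emphasis" else POSITIVE


def evaluate_combination(
    db: ToxDatabase,
    param_a: str,
    param_b: str,
    target_organ: str,
    mode: str,
    mapping: OntologyMapping,
) -> BiomarkerResult:
    """Concordance of a combined parameter pair against organ histopathology.

    Base set: compounds with both parameters AND the organ's histopathology
    examined (hence totals can differ from the single-parameter analyses).
    """
    calls_a = call_table(
        db, EndpointKey(kind="clinical_chemistry_parameter", selector=param_a), mapping
    )
    calls_b = call_table(
        db, EndpointKey(kind="clinical_chemistry_parameter", selector=param_b), mapping
    )
    organ_calls = call_table(
        db, EndpointKey(kind="organ_histopathology", selector=target_organ), mapping
    )
    merged = (
        calls_a.rename(columns={"status": "a"})
        .merge(calls_b.rename(columns={"status": "b"}), on="compound_id")
        .merge(organ_calls.rename(columns={"status": "organ"}), on="compound_id")
    )
    base = merged[(merged[["a", "b", "organ"]] != NOT_EXAMINED).all(axis=1)]
    if not len(base):
        warnings.warn(
            f"empty base set for combination {param_a!r}+{param_b!r} vs {target_organ!r}",
            stacklevel=2,
        )
        matrix = ConfusionMatrix(0, 0, 0, 0)
    else:
        combined = [combine_calls(a, b, mode) for a, b in zip(base["a"], base["b"])]
        p = pd.Series(combined, index=base.index) == POSITIVE
        o = base["organ"] == POSITIVE
        matrix = ConfusionMatrix(
            tp=int((p & o).sum()),
            fp=int((p & ~o).sum()),
            fn=int((~p & o).sum()),
            tn=int((~p & ~o).sum()),
        )
    label_a = mapping.label(mapping.resolve("clinical_chemistry_parameter", param_a))
    label_b = mapping.label(mapping.resolve("clinical_chemistry_parameter", param_b))
    return BiomarkerResult.from_matrix(f"{label_a} + {label_b}", matrix)
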