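"""Seeded generator of synthetic toxicity databases.

The real shared repeat-dose databases are confidential, so every analysis
stage here is exercised on synthetic databases with *planted* ground
truth.  The generator emulates the capture structure of systemic-toxicity
study reports (studies per compound, dose/sex groups, qualitative
incidence/severity rows, quantitative group-mean rows with direction and
an expert treatment-related flag) and plants the published marginal rates
as defaults:

* 99% of compounds with histopathology data, 61% of those flagged
  positive, 79% with liver examined, 42.5% of those liver-positive;
* per-biomarker flag probabilities conditional on liver status taken from
  the published single-parameter concordance table (e.g. ALT sensitivity
  0.396, false-positive rate 0.140);
* 66% of short-term (<20-day) studies non-GLP / GLP-in-part / unknown and
  77% of subacute (20-35-day) studies GLP;
* a benzoic-acid substructure in 1.1% of compounds, with
  treatment-related haematological findings in 18% of those versus 26%
  of all compounds.

Each table draws from its own pseudo-random stream derived from the
master seed, so output is byte-deterministic and adding a table leaves
earlier tables unchanged.  Compound-level states (liver status, biomarker
flags) are drawn once per compound and propagated to every study, because
the downstream analysis unit is the compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import ToxDatabase
from .ontology import OntologyMapping

__all__ = [
    "ConfigError",
    "BiomarkerSpec",
    "SyntheticConfig",
    "CaseStudy",
    "build_default_ontology",
    "generate",
    "generate_case_study",
    "generate_secondary_target_scenario",
    "config_from_yaml",
]


class ConfigError(ValueError):
    """A generator configuration value is out of range."""


@dataclass(frozen=True)
class BiomarkerSpec:
    """Planted behaviour of one quantitative parameter.

    ``sensitivity`` is P(flagged | liver-positive), ``false_positive_rate``
    P(flagged | liver-negative); ``p_measured`` is the probability the
    parameter was measured at all for a clinical-chemistry-examined
    compound.  Defaults across the ten standard parameters reproduce the
    published single-parameter concordance counts.
    """

    name: str
    sensitivity: float
    false_positive_rate: float
    direction: str = "increase"
    p_measured: float = 0.8


# sensitivities / false-positive rates derived from the published
# single-parameter confusion matrices (tp/(tp+fn), fp/(fp+tn)); p_measured
# approximates each parameter's base-set share among liver-examined compounds
DEFAULT_BIOMARKERS: tuple[BiomarkerSpec, ...] = (
    BiomarkerSpec("alt", 0.396, 0.140, "increase", 0.84),
    BiomarkerSpec("alp", 0.328, 0.104, "increase", 0.78),
    BiomarkerSpec("cholesterol", 0.416, 0.168, "increase", 0.70),
    BiomarkerSpec("ast", 0.292, 0.116, "increase", 0.78),
    BiomarkerSpec("bilirubin", 0.211, 0.077, "increase", 0.63),
    BiomarkerSpec("triglycerides", 0.328, 0.171, "increase", 0.60),
    BiomarkerSpec("albumin", 0.307, 0.166, "decrease", 0.73),
    BiomarkerSpec("creatinine", 0.193, 0.081, "increase", 0.75),
    BiomarkerSpec("urea", 0.235, 0.125, "increase", 0.64),
    BiomarkerSpec("protein", 0.289, 0.175, "decrease", 0.73),
)

# non-liver organ panel: (term_id, p_examined, weight for extra positivity)
ORGAN_PANEL: tuple[tuple[str, float, float], ...] = (
    ("spleen", 0.85, 0.30),
    ("kidney", 0.90, 0.20),
    ("thymus", 0.85, 0.18),
    ("lung", 0.80, 0.10),
    ("stomach", 0.70, 0.06),
    ("adrenal_gland", 0.70, 0.06),
    ("mesenteric_lymph_node", 0.50, 0.04),
    ("heart", 0.70, 0.03),
    ("colon", 0.50, 0.03),
)

# haematology parameters with canonical direction of a flagged change
HAEM_PARAMS: tuple[tuple[str, str], ...] = (
    ("haemoglobin", "decrease"),
    ("erythrocytes", "decrease"),
    ("platelets", "increase"),
    ("reticulocytes", "increase"),
    ("leucocytes", "increase"),
)

_BENZOIC_SMILES = (
    "OC(=O)c1ccccc1",
    "OC(=O)c1ccccc1C",
    "OC(=O)c1ccc(Cl)cc1",
    "OC(=O)c1ccc(N)cc1",
    "CCOc1ccccc1C(O)=O",
)
_PLAIN_SMILES = (
    "CCO",
    "CCN(CC)CC",
    "c1ccncc1",
    "CC(=O)NC1CCCCC1",
    "COc1ccccc1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)OC",  # aromatic ester, not a free acid
    "CCCC(=O)O",  # aliphatic acid, not on a ring
    "c1ccc2[nH]ccc2c1",
    "CN1CCC(CC1)c1ccccc1",
    "O=C1NC(=O)c2ccccc12",
)


def _default_studies_per_compound() -> dict[int, float]:
    return {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.10, 5: 0.05}


def _default_species_mix() -> dict[str, float]:
    return {"rat": 0.62, "dog": 0.15, "monkey": 0.10, "mouse": 0.08, "rabbit": 0.05}


def _default_route_mix() -> dict[str, float]:
    return {
        "oral gavage": 0.55,
        "oral diet": 0.15,
        "intravenous": 0.15,
        "subcutaneous": 0.08,
        "inhalation": 0.07,
    }


def _default_duration_mix() -> dict[int, float]:
    return {14: 0.45, 28: 0.28, 56: 0.10, 91: 0.05, 180: 0.08, 365: 0.04}


def _default_glp_mix() -> dict[str, dict[str, float]]:
    # per duration bin; "<20 days" plants 66% non-GLP/in-part/unknown,
    # "20-35 days" plants 77% GLP
    return {
        "<20 days": {"glp": 0.34, "non_glp": 0.33, "glp_in_part": 0.13, "unknown": 0.20},
        "20-35 days": {"glp": 0.77, "non_glp": 0.10, "glp_in_part": 0.05, "unknown": 0.08},
        "default": {"glp": 0.60, "non_glp": 0.15, "glp_in_part": 0.10, "unknown": 0.15},
    }


@dataclass
class SyntheticConfig:
    """All planted rates and mixes; the defaults are the study conditions."""

    n_compounds: int = 1214
    studies_per_compound: dict[int, float] = field(default_factory=_default_studies_per_compound)
    species_mix: dict[str, float] = field(default_factory=_default_species_mix)
    route_mix: dict[str, float] = field(default_factory=_default_route_mix)
    duration_mix: dict[int, float] = field(default_factory=_default_duration_mix)
    glp_mix: dict[str, dict[str, float]] = field(default_factory=_default_glp_mix)
    p_confidential: float = 0.39
    p_histopath_examined: float = 0.99
    p_histopath_positive: float = 0.61
    p_liver_examined: float = 0.79
    p_liver_positive: float = 0.425
    p_multiorgan: float = 0.5
    p_cc_examined: float = 0.89
    biomarker_specs: tuple[BiomarkerSpec, ...] = DEFAULT_BIOMARKERS
    p_substructure: float = 0.011
    p_haem_given_substructure: float = 0.18
    p_haem_overall: float = 0.26
    p_finding_mapped: float = 0.67
    n_case_hits: int = 20
    seed: int = 0

    def validate(self) -> None:
        probs = {
            k: getattr(self, k)
            for k in vars(self)
            if k.startswith("p_")
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.n_compounds < 0:
            raise ConfigError("n_compounds must be non-negative")
        if self.n_case_hits < 0:
            raise ConfigError("n_case_hits must be non-negative")
        for name in ("studies_per_compound", "species_mix", "route_mix", "duration_mix"):
            weights = list(getattr(self, name).values())
            if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
                raise ConfigError(f"{name} weights must be non-negative and not all zero")
        for spec in self.biomarker_specs:
            for attr in ("sensitivity", "false_positive_rate", "p_measured"):
                v = getattr(spec, attr)
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"biomarker {spec.name}: {attr} must be in [0, 1]")


# --------------------------------------------------------------------------
# default ontology
# --------------------------------------------------------------------------

_ORGAN_TERMS: dict[str, tuple[str, str, list[str]]] = {
    # term_id: (label, parent_id, synonyms)
    "liver": ("Liver", "", ["hepar", "hepatic", "LIVER"]),
    "spleen": ("Spleen", "", ["lien", "splenic"]),
    "kidney": ("Kidney", "", ["kidneys", "renal"]),
    "thymus": ("Thymus", "", ["thymic"]),
    "lung": ("Lung", "", ["lungs", "pulmonary"]),
    "adrenal_gland": ("Adrenal gland", "", ["adrenal", "adrenals"]),
    "heart": ("Heart", "", ["cardiac"]),
    "brain": ("Brain", "", ["cerebrum"]),
    "mesenteric_lymph_node": ("Mesenteric lymph node", "", ["lymph node, mesenteric"]),
    "bone_marrow": ("Bone marrow", "", ["marrow"]),
    "thyroid_gland": ("Thyroid gland", "", ["thyroid"]),
    "testis": ("Testis", "", ["testes"]),
    "ovary": ("Ovary", "", ["ovaries"]),
    "skin": ("Skin", "", []),
    "gastrointestinal_tract": ("Gastrointestinal tract", "", ["GI tract"]),
    "stomach": ("Stomach", "gastrointestinal_tract", ["gastric", "ventriculus"]),
    "colon": ("Colon", "gastrointestinal_tract", ["large intestine - colon"]),
    "duodenum": ("Duodenum", "gastrointestinal_tract", []),
}

_FINDING_TERMS: dict[str, tuple[str, str, list[str]]] = {
    "hypertrophy": ("Hypertrophy", "", []),
    "hepatocyte_hypertrophy": (
        "Hepatocyte hypertrophy",
        "hypertrophy",
        ["hepatocellular hypertrophy", "hypertrophy, hepatocellular"],
    ),
    "haematopoiesis_increased": (
        "Increased haematopoiesis",
        "",
        ["extramedullary haematopoiesis increased", "haematopoiesis, increased"],
    ),
    "necrosis": ("Necrosis", "", ["necrotic foci"]),
    "inflammation": ("Inflammation", "", ["inflammatory cell infiltration"]),
    "congestion": ("Congestion", "", ["vascular congestion"]),
    "atrophy": ("Atrophy", "", []),
    "lymphoid_atrophy": ("Lymphoid atrophy", "atrophy", ["atrophy, lymphoid", "thymic atrophy"]),
    "vacuolation": ("Vacuolation", "", ["vacuolar degeneration", "vacuolisation"]),
    "fibrosis": ("Fibrosis", "", []),
}

_PARAMETER_TERMS: dict[str, tuple[str, list[str]]] = {
    "alt": ("Alanine aminotransferase (ALT)", ["ALT", "alanine aminotransferase", "ALAT", "SGPT"]),
    "alp": ("Alkaline phosphatase (ALP)", ["ALP", "alkaline phosphatase"]),
    "ast": ("Aspartate aminotransferase (AST)", ["AST", "aspartate aminotransferase", "ASAT"]),
    "bilirubin": ("Bilirubin", ["total bilirubin", "TBIL"]),
    "cholesterol": ("Cholesterol", ["total cholesterol", "CHOL"]),
    "triglycerides": ("Triglycerides", ["TRIG"]),
    "albumin": ("Albumin", ["ALB"]),
    "creatinine": ("Creatinine", ["CREA"]),
    "urea": ("Urea", ["BUN", "urea nitrogen"]),
    "protein": ("Protein", ["total protein"]),
    "potassium": ("Potassium", ["K"]),
    "haemoglobin": ("Haemoglobin", ["hemoglobin", "Hgb", "Hb"]),
    "erythrocytes": ("Erythrocytes", ["RBC", "red blood cells"]),
    "platelets": ("Platelets", ["thrombocytes", "PLT", "platelet count"]),
    "reticulocytes": ("Reticulocytes", ["RET"]),
    "leucocytes": ("Leucocytes", ["WBC", "leukocytes", "white blood cells"]),
    "liver_weight": ("Liver weight", ["weight, liver"]),
}

# organ -> typical mapped finding term for a flagged row
_ORGAN_FINDING: dict[str, str] = {
    "liver": "hepatocyte_hypertrophy",
    "spleen": "haematopoiesis_increased",
    "thymus": "lymphoid_atrophy",
    "kidney": "vacuolation",
    "lung": "inflammation",
    "stomach": "inflammation",
    "adrenal_gland": "hypertrophy",
    "mesenteric_lymph_node": "congestion",
    "heart": "fibrosis",
    "colon": "inflammation",
}

_PARAM_UNITS: dict[str, str] = {
    "alt": "U/L",
    "alp": "U/L",
    "ast": "U/L",
    "bilirubin": "µmol/L",
    "cholesterol": "mmol/L",
    "triglycerides": "mmol/L",
    "albumin": "g/L",
    "creatinine": "µmol/L",
    "urea": "mmol/L",
    "protein": "g/L",
    "haemoglobin": "g/dL",
    "erythrocytes": "10^12/L",
    "platelets": "10^9/L",
    "reticulocytes": "10^9/L",
    "leucocytes": "10^9/L",
    "liver_weight": "g",
}


def build_default_ontology() -> OntologyMapping:
    """The bundled three-domain ontology the generator writes terms from."""
    terms = []
    synonyms = []
    for term_id, (label, parent, syns) in _ORGAN_TERMS.items():
        terms.append((term_id, label, parent, "organ"))
        for s in syns:
            synonyms.append(("organ", s, term_id))
    for term_id, (label, parent, syns) in _FINDING_TERMS.items():
        terms.append((term_id, label, parent, "histopathology_finding"))
        for s in syns:
            synonyms.append(("histopathology_finding", s, term_id))
    for term_id, (label, syns) in _PARAMETER_TERMS.items():
        terms.append((term_id, label, "", "clinical_chemistry_parameter"))
        for s in syns:
            synonyms.append(("clinical_chemistry_parameter", s, term_id))
    return OntologyMapping(
        terms=pd.DataFrame(terms, columns=["term_id", "label", "parent_id", "domain"]),
        synonyms=pd.DataFrame(synonyms, columns=["domain", "verbatim", "term_id"]),
    )


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def _weighted_choice(rng: np.random.Generator, mix: dict, size: int) -> np.ndarray:
    keys = list(mix.keys())
    w = np.asarray([mix[k] for k in keys], dtype=float)
    return rng.choice(np.asarray(keys, dtype=object), size=size, p=w / w.sum())


def _verbatim(rng: np.random.Generator, label: str, synonyms: list[str]) -> str:
    pool = [label] + synonyms
    return pool[int(rng.integers(len(pool)))]


def _duration_bin(duration: int) -> str:
    if duration < 20:
        return "<20 days"
    if duration <= 35:
        return "20-35 days"
    return "default"


def generate(config: SyntheticConfig | None = None) -> ToxDatabase:
    """Generate a validated synthetic database under the planted rates."""
    config = config or SyntheticConfig()
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(5)
    r_comp, r_latent, r_study, r_qual, r_quant = (np.random.default_rng(s) for s in streams)
    n = config.n_compounds

    # ---- compounds -----------------------------------------------------
    compound_ids = [f"C{i:05d}" for i in range(1, n + 1)]
    confidential = r_comp.random(n) < config.p_confidential
    has_sub = r_comp.random(n) < config.p_substructure
    smiles = []
    for i in range(n):
        if confidential[i]:
            smiles.append("")
        elif has_sub[i]:
            smiles.append(_BENZOIC_SMILES[int(r_comp.integers(len(_BENZOIC_SMILES)))])
        else:
            smiles.append(_PLAIN_SMILES[int(r_comp.integers(len(_PLAIN_SMILES)))])
    compounds = pd.DataFrame(
        {
            "compound_id": compound_ids,
            "smiles": smiles,
            "sensitivity_label": np.where(confidential, "confidential", "non_confidential"),
            "pharmacological_action": ["" for _ in range(n)],
            "has_substructure": has_sub,
        }
    )

    # ---- latent compound-level states ---------------------------------
    histo_exam = r_latent.random(n) < config.p_histopath_examined
    liver_exam = histo_exam & (r_latent.random(n) < config.p_liver_examined)
    liver_pos = liver_exam & (r_latent.random(n) < config.p_liver_positive)
    p_lp_eff = config.p_liver_examined * config.p_liver_positive
    q_extra = (
        (config.p_histopath_positive - p_lp_eff) / (1.0 - p_lp_eff) if p_lp_eff < 1.0 else 0.0
    )
    q_extra = min(max(q_extra, 0.0), 1.0)
    extra_pos = histo_exam & ~liver_pos & (r_latent.random(n) < q_extra)
    multi = liver_pos & (r_latent.random(n) < config.p_multiorgan)

    panel_terms = [t for t, _p, _w in ORGAN_PANEL]
    panel_p = np.asarray([p for _t, p, _w in ORGAN_PANEL])
    panel_w = np.asarray([w for _t, _p, w in ORGAN_PANEL])
    panel_w = panel_w / panel_w.sum()
    panel_exam = r_latent.random((n, len(panel_terms))) < panel_p[None, :]
    positive_organs: list[set[str]] = [set() for _ in range(n)]
    for i in range(n):
        if liver_pos[i]:
            positive_organs[i].add("liver")
        if extra_pos[i] or multi[i]:
            k = 1 + int(r_latent.poisson(0.7))
            k = min(k, len(panel_terms))
            chosen = r_latent.choice(len(panel_terms), size=k, replace=False, p=panel_w)
            for j in chosen:
                positive_organs[i].add(panel_terms[j])
                panel_exam[i, j] = True

    # clinical chemistry flags per biomarker
    cc_exam = r_latent.random(n) < config.p_cc_examined
    cc_measured: dict[str, np.ndarray] = {}
    cc_flag: dict[str, np.ndarray] = {}
    for spec in config.biomarker_specs:
        measured = cc_exam & (r_latent.random(n) < spec.p_measured)
        p_flag = np.where(liver_pos, spec.sensitivity, spec.false_positive_rate)
        cc_measured[spec.name] = measured
        cc_flag[spec.name] = measured & (r_latent.random(n) < p_flag)

    # haematology: overall positive rate planted unconditionally
    p_haem_nosub = config.p_haem_overall
    if config.p_substructure < 1.0:
        p_haem_nosub = (
            config.p_haem_overall - config.p_substructure * config.p_haem_given_substructure
        ) / (1.0 - config.p_substructure)
    p_haem_nosub = min(max(p_haem_nosub, 0.0), 1.0)
    p_haem = np.where(has_sub, config.p_haem_given_substructure, p_haem_nosub)
    haem_pos = r_latent.random(n) < p_haem
    haem_exam = haem_pos | (r_latent.random(n) < 0.85)
    haem_flags = np.zeros((n, len(HAEM_PARAMS)), dtype=bool)
    for i in range(n):
        if haem_pos[i]:
            row = r_latent.random(len(HAEM_PARAMS)) < 0.55
            if not row.any():
                row[0] = True
            haem_flags[i] = row
    ow_pos = histo_exam & (r_latent.random(n) < 0.45)
    cs_pos = r_latent.random(n) < 0.48

    # ---- studies and dose groups --------------------------------------
    n_studies = _weighted_choice(r_study, config.studies_per_compound, n).astype(int)
    study_rows = []
    group_rows = []
    study_ids_of: list[list[str]] = []
    for i in range(n):
        ids = []
        for j in range(n_studies[i]):
            sid = f"{compound_ids[i]}-S{j + 1}"
            species = str(_weighted_choice(r_study, config.species_mix, 1)[0])
            route = str(_weighted_choice(r_study, config.route_mix, 1)[0])
            duration = int(_weighted_choice(r_study, config.duration_mix, 1)[0])
            glp_weights = config.glp_mix.get(_duration_bin(duration), config.glp_mix["default"])
            glp = str(_weighted_choice(r_study, glp_weights, 1)[0])
            strain = {"rat": "Wistar", "dog": "Beagle", "mouse": "CD-1"}.get(species, "")
            study_rows.append(
                (sid, compound_ids[i], species, strain, route, duration, glp, "0.5% HPMC")
            )
            group_rows.append((sid, "G0", 0.0, "both", True))
            for g, dose in enumerate((10.0, 30.0, 100.0), start=1):
                group_rows.append((sid, f"G{g}", dose, "both", False))
            ids.append(sid)
        study_ids_of.append(ids)
    studies = pd.DataFrame(
        study_rows,
        columns=[
            "study_id",
            "compound_id",
            "species",
            "strain",
            "route",
            "duration_days",
            "glp_status",
            "vehicle",
        ],
    )
    dose_groups = pd.DataFrame(
        group_rows, columns=["study_id", "group_id", "dose", "sex", "is_control"]
    )
    duration_of = dict(zip(studies["study_id"], studies["duration_days"])) if len(studies) else {}

    # ---- qualitative findings -----------------------------------------
    organ_info = {t: _ORGAN_TERMS[t] for t in ["liver"] + panel_terms}
    qual_rows = []
    for i in range(n):
        examined = []
        if liver_exam[i]:
            examined.append("liver")
        for j, term in enumerate(panel_terms):
            if panel_exam[i, j]:
                examined.append(term)
        if histo_exam[i]:
            for sid in study_ids_of[i]:
                tp_days = duration_of[sid]
                for term in examined:
                    label, _parent, syns = organ_info[term]
                    organ_verbatim = _verbatim(r_qual, label, syns)
                    flagged = term in positive_organs[i]
                    if flagged:
                        group = f"G{int(r_qual.integers(1, 4))}"
                        fterm = _ORGAN_FINDING.get(term, "inflammation")
                        flabel, _fp, fsyns = _FINDING_TERMS[fterm]
                        if r_qual.random() < config.p_finding_mapped:
                            finding_verbatim = _verbatim(r_qual, flabel, fsyns)
                        else:
                            finding_verbatim = f"unclassified change {int(r_qual.integers(1000))}"
                        affected = int(r_qual.integers(3, 11))
                        severity = int(r_qual.integers(2, 5))
                    else:
                        group = "G3"
                        finding_verbatim = (
                            "no abnormality detected"
                            if r_qual.random() < 0.6
                            else f"incidental change {int(r_qual.integers(1000))}"
                        )
                        affected = int(r_qual.integers(0, 3))
                        severity = 1
                    qual_rows.append(
                        (
                            sid,
                            group,
                            "histopathology",
                            organ_verbatim,
                            finding_verbatim,
                            affected,
                            10,
                            severity,
                            tp_days,
                            flagged,
                        )
                    )
        # clinical signs: one row per study
        for sid in study_ids_of[i]:
            if r_qual.random() < 0.9:
                sign = ("salivation", "piloerection", "hunched posture")[int(r_qual.integers(3))]
                qual_rows.append(
                    (
                        sid,
                        f"G{int(r_qual.integers(1, 4))}",
                        "clinical_signs",
                        "",
                        sign,
                        int(r_qual.integers(1, 6)),
                        10,
                        None,
                        min(7, duration_of[sid]),
                        bool(cs_pos[i]) and r_qual.random() < 0.8,
                    )
                )
    qualitative = pd.DataFrame(
        qual_rows,
        columns=[
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
    )

    # ---- quantitative findings ----------------------------------------
    base_means = {
        "alt": 45.0,
        "alp": 120.0,
        "ast": 80.0,
        "bilirubin": 2.5,
        "cholesterol": 1.9,
        "triglycerides": 0.8,
        "albumin": 38.0,
        "creatinine": 35.0,
        "urea": 6.5,
        "protein": 62.0,
        "haemoglobin": 15.0,
        "erythrocytes": 8.0,
        "platelets": 900.0,
        "reticulocytes": 200.0,
        "leucocytes": 9.0,
        "liver_weight": 11.0,
    }
    quant_rows = []

    def _quant_row(sid, param, flagged, direction_flagged, rng):
        label, syns = _PARAMETER_TERMS[param]
        base = base_means[param]
        direction = direction_flagged if flagged else "unchanged"
        if flagged:
            fold = (
                round(1.5 + 2.5 * rng.random(), 2)
                if direction == "increase"
                else round(0.3 + 0.4 * rng.random(), 2)
            )
            mean = round(base * fold, 2)
        else:
            fold = np.nan
            mean = round(base * (0.9 + 0.2 * rng.random()), 2)
        return (
            sid,
            f"G{int(rng.integers(1, 4))}" if flagged else "G3",
            None,  # finding_type filled by caller
            _verbatim(rng, label, syns),
            mean,
            round(abs(mean) * 0.15, 2),
            _PARAM_UNITS[param],
            fold,
            direction,
            duration_of[sid],
            flagged,
        )

    for i in range(n):
        for sid in study_ids_of[i]:
            for spec in config.biomarker_specs:
                if cc_measured[spec.name][i]:
                    row = list(
                        _quant_row(sid, spec.name, bool(cc_flag[spec.name][i]), spec.direction, r_quant)
                    )
                    row[2] = "clinical_chemistry"
                    quant_rows.append(tuple(row))
            if haem_exam[i]:
                for k, (param, direction) in enumerate(HAEM_PARAMS):
                    flagged = bool(haem_flags[i, k])
                    if flagged or r_quant.random() < 0.9:
                        row = list(_quant_row(sid, param, flagged, direction, r_quant))
                        row[2] = "haematology"
                        quant_rows.append(tuple(row))
            if histo_exam[i]:
                row = list(_quant_row(sid, "liver_weight", bool(ow_pos[i]), "increase", r_quant))
                row[2] = "organ_weights"
                quant_rows.append(tuple(row))
    quantitative = pd.DataFrame(
        quant_rows,
        columns=[
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
    )

    db = ToxDatabase(
        compounds=compounds,
        studies=studies,
        dose_groups=dose_groups,
        qualitative_findings=qualitative,
        quantitative_findings=quantitative,
    )
    return db.validate()


@dataclass
class CaseStudy:
    """A generated database plus the compounds planted to satisfy the
    triple haematology query (haemoglobin down, platelets and
    reticulocytes up, all treatment-related)."""

    database: ToxDatabase
    planted_hits: list[str]


def generate_case_study(config: SyntheticConfig | None = None) -> CaseStudy:
    """Database with a known hit list for the multi-parameter search.

    Exactly ``config.n_case_hits`` compounds satisfy the triple criterion;
    every other compound fails at least one criterion.  The first planted
    hit is given a dog study and the first two an "EP1 receptor
    antagonist" pharmacological action, so hits span species and carry
    target annotations.
    """
    config = config or SyntheticConfig(n_compounds=1000)
    config.validate()
    db = generate(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    n = len(db.compounds)
    if config.n_case_hits > n:
        raise ConfigError("n_case_hits exceeds n_compounds")
    if config.n_case_hits:
        hit_idx = sorted(rng.choice(n, size=config.n_case_hits, replace=False).tolist())
    else:
        hit_idx = []
    hits = [db.compounds["compound_id"].iloc[i] for i in hit_idx]
    hit_set = set(hits)

    triple = {"haemoglobin": "decrease", "platelets": "increase", "reticulocytes": "increase"}
    ontology = build_default_ontology()
    qt = db.quantitative_findings.copy()
    compound_of = db.studies.set_index("study_id")["compound_id"]
    param_term = qt["parameter_verbatim"].map(
        lambda v: ontology.map_term("clinical_chemistry_parameter", v)
    )
    row_compound = qt["study_id"].map(compound_of)

    # non-hits must fail >=1 criterion: unflag reticulocyte rows of any
    # compound that happens to satisfy all three
    satisfied = {}
    for param in triple:
        flagged_rows = qt["treatment_related"] & (param_term == param)
        satisfied[param] = set(row_compound[flagged_rows])
    accidental = (
        satisfied["haemoglobin"] & satisfied["platelets"] & satisfied["reticulocytes"]
    ) - hit_set
    if accidental:
        kill = (
            (param_term == "reticulocytes")
            & qt["treatment_related"]
            & row_compound.isin(accidental)
        )
        qt.loc[kill, "treatment_related"] = False
        qt.loc[kill, "direction"] = "unchanged"
        qt.loc[kill, "fold_change"] = np.nan

    # hits get fresh flagged rows for all three parameters in their first study
    first_study = db.studies.groupby("compound_id")["study_id"].first()
    new_rows = []
    for cid in hits:
        sid = first_study[cid]
        tp_days = int(db.studies.set_index("study_id")["duration_days"][sid])
        for param, direction in triple.items():
            label, syns = _PARAMETER_TERMS[param]
            base = {"haemoglobin": 15.0, "platelets": 900.0, "reticulocytes": 200.0}[param]
            fold = 0.7 if direction == "decrease" else 1.8
            new_rows.append(
                (
                    sid,
                    "G3",
                    "haematology",
                    label,
                    round(base * fold, 2),
                    round(base * 0.1, 2),
                    _PARAM_UNITS[param],
                    fold,
                    direction,
                    tp_days,
                    True,
                )
            )
    if new_rows:
        qt = pd.concat([qt, pd.DataFrame(new_rows, columns=qt.columns)], ignore_index=True)

    studies = db.studies.copy()
    compounds = db.compounds.copy()
    if hits:
        studies.loc[studies["study_id"] == first_study[hits[0]], ["species", "strain"]] = [
            "dog",
            "Beagle",
        ]
        for cid in hits[:2]:
            compounds.loc[
                compounds["compound_id"] == cid, "pharmacological_action"
            ] = "EP1 receptor antagonist"

    out = ToxDatabase(
        compounds=compounds,
        studies=studies,
        dose_groups=db.dose_groups,
        qualitative_findings=db.qualitative_findings,
        quantitative_findings=qt,
    ).validate()
    return CaseStudy(database=out, planted_hits=sorted(hits))


def generate_secondary_target_scenario(
    n_primary: int = 136,
    n_secondary: int = 100,
    n_other: int = 64,
    n_coliver: int = 74,
    n_cospleen: int = 73,
    seed: int = 0,
) -> ToxDatabase:
    """Database where the thymus is a planted secondary target.

    ``n_secondary`` compounds have their thymus findings flagged only at a
    dose above the study's lowest flagged histopathology dose (liver
    flagged at the low dose) — the dose filter removes exactly these.
    ``n_primary`` compounds carry thymus findings at the study's lowest
    flagged dose and survive; among them the first ``n_coliver`` are also
    liver-positive and the last ``n_cospleen`` spleen-positive.
    ``n_other`` compounds are liver-only background.
    """
    if min(n_primary, n_secondary, n_other, n_coliver, n_cospleen) < 0:
        raise ConfigError("scenario counts must be non-negative")
    if max(n_coliver, n_cospleen) > n_primary:
        raise ConfigError("co-occurrence counts cannot exceed n_primary")
    rng = np.random.default_rng(seed)
    n = n_secondary + n_primary + n_other
    comp_rows, study_rows, group_rows, qual_rows = [], [], [], []

    def _organ_row(sid, group, organ, flagged):
        label, _p, syns = _ORGAN_TERMS[organ]
        fterm = _ORGAN_FINDING.get(organ, "inflammation")
        flabel, _fp, fsyns = _FINDING_TERMS[fterm]
        return (
            sid,
            group,
            "histopathology",
            _verbatim(rng, label, syns),
            _verbatim(rng, flabel, fsyns) if flagged else "no abnormality detected",
            int(rng.integers(3, 11)) if flagged else 0,
            10,
            int(rng.integers(2, 5)) if flagged else 1,
            28,
            flagged,
        )

    for i in range(n):
        cid = f"T{i + 1:05d}"
        sid = f"{cid}-S1"
        comp_rows.append((cid, "", "non_confidential", ""))
        study_rows.append((sid, cid, "rat", "Wistar", "oral gavage", 28, "glp", "0.5% HPMC"))
        group_rows.append((sid, "G0", 0.0, "both", True))
        group_rows.append((sid, "G1", 10.0, "both", False))
        group_rows.append((sid, "G2", 100.0, "both", False))
        if i < n_secondary:
            # liver at the low dose, thymus only at the high dose -> secondary
            qual_rows.append(_organ_row(sid, "G1", "liver", True))
            qual_rows.append(_organ_row(sid, "G2", "thymus", True))
        elif i < n_secondary + n_primary:
            j = i - n_secondary
            qual_rows.append(_organ_row(sid, "G1", "thymus", True))
            if j < n_coliver:
                qual_rows.append(_organ_row(sid, "G2", "liver", True))
            if j >= n_primary - n_cospleen:
                qual_rows.append(_organ_row(sid, "G2", "spleen", True))
        else:
            qual_rows.append(_organ_row(sid, "G1", "liver", True))

    db = ToxDatabase(
        compounds=pd.DataFrame(
            comp_rows,
            columns=["compound_id", "smiles", "sensitivity_label", "pharmacological_action"],
        ),
        studies=pd.DataFrame(
            study_rows,
            columns=[
                "study_id",
                "compound_id",
                "species",
                "strain",
                "route",
                "duration_days",
                "glp_status",
                "vehicle",
            ],
        ),
        dose_groups=pd.DataFrame(
            group_rows, columns=["study_id", "group_id", "dose", "sex", "is_control"]
        ),
        qualitative_findings=pd.DataFrame(
            qual_rows,
            columns=[
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
        ),
    )
    return db.validate()


def config_from_yaml(path: str | Path) -> SyntheticConfig:
    """Load a generator configuration from a YAML file; unspecified keys
    keep their defaults, ``biomarker_specs`` entries are mappings."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "biomarker_specs" in raw:
        raw["biomarker_specs"] = tuple(BiomarkerSpec(**b) for b in raw["biomarker_specs"])
    for key in ("studies_per_compound", "duration_mix"):
        if key in raw:
            raw[key] = {int(k): float(v) for k, v in raw[key].items()}
    known = set(SyntheticConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    return SyntheticConfig(**raw)
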