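"""Shared fixtures: the bundled ontology and a compact hand-built database
builder used to construct databases with exactly known per-compound calls."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from toxmine.datamodel import ToxDatabase
from toxmine.synthetic_data import build_default_ontology

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_HAEM_PARAMS = {"haemoglobin", "erythrocytes", "platelets", "reticulocytes", "leucocytes"}


@pytest.fixture(scope="session")
def ontology():
    return build_default_ontology()


def build_db(specs, species="rat", duration_days=28):
    """Build a database with one study per compound and explicit calls.

    ``specs`` is a list of per-compound dicts mapping endpoint names to:

    * organ term (e.g. ``"liver"``): ``"pos"`` / ``"neg"`` (histopathology
      row flagged / unflagged) or ``("pos"|"neg", finding_verbatim)``;
    * parameter term (e.g. ``"alt"``): ``"pos"`` / ``"neg"`` or
      ``("pos"|"neg", direction)`` — quantitative row, flagged rows
      default to direction ``increase``;
    * ``None`` / absent key: endpoint not examined.

    Optional special keys: ``id`` (compound id), ``smiles``, ``species``.
    """
    ontology = build_default_ontology()
    organ_terms = set(ontology.domain_terms("organ"))
    comp_rows, study_rows, group_rows, qual_rows, quant_rows = [], [], [], [], []
    for i, spec in enumerate(specs):
        spec = dict(spec)
        cid = spec.pop("id", f"X{i + 1:04d}")
        smiles = spec.pop("smiles", "")
        sp = spec.pop("species", species)
        sid = f"{cid}-S1"
        comp_rows.append((cid, smiles, "non_confidential", ""))
        study_rows.append((sid, cid, sp, "Wistar", "oral gavage", duration_days, "glp", ""))
        group_rows.append((sid, "G0", 0.0, "both", True))
        group_rows.append((sid, "G1", 10.0, "both", False))
        for key, value in spec.items():
            if value is None:
                continue
            detail = None
            if isinstance(value, tuple):
                value, detail = value
            flagged = value == "pos"
            if key in organ_terms:
                finding = detail if detail is not None else ("necrosis" if flagged else "no abnormality detected")
                qual_rows.append(
                    (sid, "G1", "histopathology", ontology.label(key), finding,
                     5 if flagged else 0, 10, 2 if flagged else 1, duration_days, flagged)
                )
            else:
                direction = detail if detail is not None else ("increase" if flagged else "unchanged")
                if not flagged and detail is None:
                    direction = "unchanged"
                ftype = (
                    "haematology"
                    if key in _HAEM_PARAMS
                    else "organ_weights"
                    if key == "liver_weight"
                    else "clinical_chemistry"
                )
                quant_rows.append(
                    (sid, "G1", ftype, ontology.label(key), 10.0, 1.0, "U/L",
                     2.0 if flagged else float("nan"), direction, duration_days, flagged)
                )
    return ToxDatabase(
        compounds=pd.DataFrame(
            comp_rows, columns=["compound_id", "smiles", "sensitivity_label", "pharmacological_action"]
        ),
        studies=pd.DataFrame(
            study_rows,
            columns=["study_id", "compound_id", "species", "strain", "route",
                     "duration_days", "glp_status", "vehicle"],
        ),
        dose_groups=pd.DataFrame(
            group_rows, columns=["study_id", "group_id", "dose", "sex", "is_control"]
        ),
        qualitative_findings=pd.DataFrame(
            qual_rows,
            columns=["study_id", "group_id", "finding_type", "organ_verbatim",
                     "finding_verbatim", "affected", "examined", "severity",
                     "timepoint_days", "treatment_related"],
        ),
        quantitative_findings=pd.DataFrame(
            quant_rows,
            columns=["study_id", "group_id", "finding_type", "parameter_verbatim",
                     "mean", "sd", "units", "fold_change", "direction",
                     "timepoint_days", "treatment_related"],
        ),
    ).validate()
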