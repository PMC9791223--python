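"""Clinical classification and lipid-matrix preprocessing.

Implements the updated NCEP ATPIII metabolic-syndrome definition (>=3 of 5
abnormal components, each satisfiable by medication use), the impaired
glucoregulation flag, the CRP median split, the <20%-missing species filter,
log + z-score transformation, and the two ceramide/glycosphingolipid ratio
biomarkers (computed on raw, untransformed class totals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lipid_matrix import LipidMatrix


class MissingDataError(ValueError):
    """A required clinical field is missing for a subject."""


@dataclass(frozen=True)
class MetSCriteria:
    """ATPIII component cut-offs (raw clinical units)."""

    waist_cm_male: float = 102.0  # abdominal obesity: waist > cut-off
    waist_cm_female: float = 88.0
    triglycerides_mg_dl: float = 150.0  # >= cut-off, or lipid-lowering medication
    hdl_mg_dl_male: float = 40.0  # < cut-off, or HDL-raising medication
    hdl_mg_dl_female: float = 50.0
    systolic_mmhg: float = 130.0  # >= cut-off (either pressure), or treated hypertension
    diastolic_mmhg: float = 85.0
    glucose_mg_dl: float = 100.0  # >= cut-off, or glucose-lowering medication
    required_count: int = 3

    components: tuple[str, ...] = field(
        default=("abdominal_obesity", "high_triglycerides", "low_hdl", "high_bp", "high_glucose"),
        repr=False,
    )


@dataclass(frozen=True)
class MetSStatus:
    component_flags: dict[str, bool]
    diagnosis: bool
    impaired_glucoregulation: bool | None = None
    crp_stratum: str | None = None  # "low" | "high" | None when CRP missing

    @property
    def n_components(self) -> int:
        return sum(self.component_flags.values())


_REQUIRED = {
    "abdominal_obesity": ["sex", "waist_cm"],
    "high_triglycerides": ["triglycerides_mg_dl"],
    "low_hdl": ["sex", "hdl_mg_dl"],
    "high_bp": ["systolic_mmhg", "diastolic_mmhg"],
    "high_glucose": ["glucose_mg_dl"],
}

_MED_FLAGS = {
    "high_triglycerides": "tg_medication",
    "low_hdl": "hdl_medication",
    "high_bp": "htn_medication_with_history",
    "high_glucose": "glycemia_medication",
}


def _get(record, name):
    try:
        v = record[name]
    except (KeyError, IndexError):
        return None
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return v


def classify_mets(record, criteria: MetSCriteria = MetSCriteria()) -> MetSStatus:
    """Classify one subject against the ATPIII criteria.

    ``record`` is any mapping (dict, pandas row) with the clinical fields in
    raw units; medication flags (``tg_medication``, ``hdl_medication``,
    ``htn_medication_with_history``, ``glycemia_medication``) force the
    corresponding component abnormal. A component whose value is missing and
    whose medication flag is not set raises :class:`MissingDataError`.
    """
    flags: dict[str, bool] = {}
    for comp in criteria.components:
        med = _MED_FLAGS.get(comp)
        if med is not None and bool(_get(record, med)):
            flags[comp] = True
            continue
        for fieldname in _REQUIRED[comp]:
            if _get(record, fieldname) is None:
                raise MissingDataError(f"missing required field {fieldname!r} for component {comp!r}")
        if comp == "abdominal_obesity":
            cut = criteria.waist_cm_male if _is_male(record["sex"]) else criteria.waist_cm_female
            flags[comp] = record["waist_cm"] > cut
        elif comp == "high_triglycerides":
            flags[comp] = record["triglycerides_mg_dl"] >= criteria.triglycerides_mg_dl
        elif comp == "low_hdl":
            cut = criteria.hdl_mg_dl_male if _is_male(record["sex"]) else criteria.hdl_mg_dl_female
            flags[comp] = record["hdl_mg_dl"] < cut
        elif comp == "high_bp":
            flags[comp] = (
                record["systolic_mmhg"] >= criteria.systolic_mmhg
                or record["diastolic_mmhg"] >= criteria.diastolic_mmhg
            )
        elif comp == "high_glucose":
            flags[comp] = record["glucose_mg_dl"] >= criteria.glucose_mg_dl
    diagnosis = sum(flags.values()) >= criteria.required_count

    glu, ins = _get(record, "glucose_mg_dl"), _get(record, "insulin_uiu_ml")
    impaired = None if ins is None or glu is None else bool(glu > 100 and ins >= 25)
    return MetSStatus(component_flags=flags, diagnosis=diagnosis, impaired_glucoregulation=impaired)


def _is_male(sex) -> bool:
    s = str(sex).strip().lower()
    if s in {"m", "male", "man", "men", "1"}:
        return True
    if s in {"f", "female", "woman", "women", "0"}:
        return False
    raise MissingDataError(f"unrecognized sex value {sex!r}")


def classify_mets_table(clinical: pd.DataFrame, criteria: MetSCriteria = MetSCriteria()) -> pd.DataFrame:
    """Vectorized per-subject classification for a clinical table.

    Returns a DataFrame indexed like ``clinical`` with one boolean column per
    component plus ``mets`` (diagnosis), ``impaired_glucoregulation``, and
    ``crp_stratum`` (median split on ``crp_ug_ml``, if present).
    """
    rows = {}
    for sid, rec in clinical.iterrows():
        st = classify_mets(rec, criteria)
        rows[sid] = {
            **st.component_flags,
            "mets": st.diagnosis,
            "impaired_glucoregulation": st.impaired_glucoregulation,
        }
    out = pd.DataFrame.from_dict(rows, orient="index").loc[clinical.index]
    if "crp_ug_ml" in clinical.columns:
        out["crp_stratum"] = crp_stratify(clinical["crp_ug_ml"])
    return out


def crp_stratify(crp_values: pd.Series) -> pd.Series:
    """Median split: ``high`` iff value > sample median, ``low`` iff <= median.

    Missing CRP leaves the stratum undefined (NaN); those subjects are
    excluded from CRP-stratified analyses.
    """
    crp = pd.Series(crp_values, dtype=float)
    if crp.notna().sum() < 1:
        raise ValueError("need at least one non-missing CRP value")
    med = crp.median(skipna=True)
    out = pd.Series(pd.NA, index=crp.index, dtype="object")
    out[crp.notna()] = np.where(crp[crp.notna()] > med, "high", "low")
    return out


def filter_species(matrix: LipidMatrix, max_missing: float = 0.20) -> tuple[LipidMatrix, pd.Series]:
    """Retain species with missing fraction strictly below ``max_missing``.

    Returns the filtered matrix and the missing fractions of the species that
    were dropped (the dropped-species report). A species missing exactly 20%
    of its values is dropped.
    """
    if matrix.abundances.empty:
        raise ValueError("empty lipid matrix")
    frac = matrix.missing_fraction()
    keep = frac.index[frac < max_missing].tolist()
    if not keep:
        raise ValueError(f"all species exceed the {max_missing:.0%} missingness threshold")
    dropped = frac[frac >= max_missing]
    return matrix.select_species(keep), dropped


def log_zscore(matrix: LipidMatrix) -> pd.DataFrame:
    """Per-species standardized natural-log abundances.

    Each species column becomes (log x - mean)/SD over its non-missing
    entries; missing stays missing. Strictly positive abundances are required
    and constant species raise an error naming the species.
    """
    return matrix.zscore


def compute_ratios(matrix: LipidMatrix) -> pd.DataFrame:
    """Per-subject ratio biomarkers on raw (untransformed) class totals.

    ``ratio_cer_lcer``   = total CER / total LCER
    ``ratio_integrative`` = (total DCER + total CER) / (total HCER + total LCER)

    Class totals sum the non-missing species of each class.
    """
    totals = matrix.class_totals(["DCER", "CER", "HCER", "LCER"])
    return pd.DataFrame(
        {
            "ratio_cer_lcer": totals["CER"] / totals["LCER"],
            "ratio_integrative": (totals["DCER"] + totals["CER"]) / (totals["HCER"] + totals["LCER"]),
        },
        index=matrix.subjects,
    )


def category_percentages(counts: dict[str, int], decimals: int = 1) -> dict[str, float]:
    """Percent occurrence of each category, denominated by the summed counts.

    The standard 'n (%)' descriptive summary for a categorical variable:
    each category's share of the observed total, rounded to ``decimals``.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return {k: round(100.0 * v / total, decimals) for k, v in counts.items()}


def stratum_labels(status: pd.DataFrame, scheme: str = "mets_crp") -> pd.Series:
    """Combine MetS diagnosis with CRP stratum or glucoregulation status.

    ``mets_crp`` yields labels like ``mets-_crp_low`` … ``mets+_crp_high``;
    ``mets_gluco`` yields ``mets-_gluco-`` … ``mets+_gluco+``. Subjects with
    an undefined second axis get NaN.
    """
    mets = status["mets"].map({True: "mets+", False: "mets-"})
    if scheme == "mets_crp":
        second = status["crp_stratum"].map({"low": "crp_low", "high": "crp_high"})
    elif scheme == "mets_gluco":
        second = status["impaired_glucoregulation"].map({True: "gluco+", False: "gluco-"})
    else:
        raise ValueError(f"unknown stratification scheme {scheme!r}")
    out = mets.str.cat(second, sep="_")
    out[second.isna() | status["mets"].isna()] = pd.NA
    return out
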