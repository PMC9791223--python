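"""Seeded synthetic cohort generator.

Emulates the statistical structure the downstream analyses assume: a
middle-aged cohort with ATPIII metabolic-syndrome components generated from
correlated latent Gaussians thresholded at the clinical cut-offs (so the
classifier, not the generator, decides the diagnosis), inflammatory
biomarkers shifted upward in MetS, and class-blocked lognormal sphingolipid
abundances whose interclass rank correlations differ across the four
MetS x CRP strata, with ceramide classes shifted up and glycosphingolipid
classes shifted down in MetS. Missingness is injected missing-completely-
at-random.

Correlation targets are specified on the Spearman scale and converted to the
latent Pearson scale via rho_P = 2*sin(pi*rho_S/6); exponentiation of the
latent normals then preserves the planted rank correlations exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .lipid_matrix import LipidMatrix
from .panel import SpeciesPanel, default_species_panel
from .preprocessing import MetSCriteria, classify_mets_table, crp_stratify

STRATA = ("mets-_crp_low", "mets-_crp_high", "mets+_crp_low", "mets+_crp_high")

_COMPONENTS = ("abdominal_obesity", "high_triglycerides", "low_hdl", "high_bp", "high_glucose")


def spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson correlation reproducing a target Spearman under normality."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def pearson_to_spearman(rho_p: float) -> float:
    return (6.0 / np.pi) * np.arcsin(rho_p / 2.0)


class ConfigurationError(ValueError):
    """Invalid cohort configuration (e.g. non-PSD correlation targets)."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Correlations (``within_class_rho``, interclass targets) are Spearman
    rank correlations; ``class_mean_shift`` and ``biomarker_effects`` are
    additive shifts on the natural-log scale for MetS subjects.
    """

    n_subjects: int = 2063
    mets_target_prevalence: float = 0.374
    class_mean_shift: dict = field(
        default_factory=lambda: {"DCER": 0.20, "CER": 0.20, "HCER": -0.15, "LCER": -0.25, "SM": 0.0}
    )
    within_class_rho: float = 0.5
    interclass_rho_default: float = 0.2
    # overrides: {stratum: {frozenset-like sorted class pair tuple: spearman}}
    stratum_interclass_rho: dict = field(
        default_factory=lambda: {
            "mets+_crp_high": {
                ("CER", "DCER"): 0.35, ("CER", "HCER"): 0.35, ("CER", "LCER"): 0.35,
                ("DCER", "HCER"): 0.35, ("DCER", "LCER"): 0.35, ("HCER", "LCER"): 0.35,
            },
            "mets-_crp_high": {("CER", "HCER"): 0.35, ("HCER", "LCER"): 0.10},
        }
    )
    missing_rate: float = 0.05
    component_rho: float = 0.4  # latent correlation among the 5 MetS components
    medication_rate: float = 0.0
    sex_probs: dict = field(default_factory=lambda: {"female": 0.549, "male": 0.451})
    race_probs: dict = field(
        default_factory=lambda: {
            "White": 0.748, "African American": 0.177, "Native American": 0.066,
            "Asian": 0.007, "Other": 0.002,
        }
    )
    education_probs: dict = field(
        default_factory=lambda: {"high school or less": 0.236, "some college": 0.522, "postgraduate": 0.242}
    )
    age_range: tuple = (34.0, 78.0)
    biomarker_effects: dict = field(
        default_factory=lambda: {
            "crp_ug_ml": 0.6, "il6_pg_ml": 0.4, "fibrinogen_mg_dl": 0.15,
            "sicam_ng_ml": 0.10, "seselectin_ng_ml": 0.15,
        }
    )
    lipid_log_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        if not 0.0 < self.mets_target_prevalence < 1.0:
            raise ConfigurationError("mets_target_prevalence must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.within_class_rho < 1.0:
            raise ConfigurationError("within_class_rho must lie in [0, 1)")
        self.stratum_interclass_rho = {
            stratum: {tuple(sorted(pair)): float(r) for pair, r in pairs.items()}
            for stratum, pairs in self.stratum_interclass_rho.items()
        }
        for probs, name in ((self.sex_probs, "sex"), (self.race_probs, "race"), (self.education_probs, "education")):
            if abs(sum(probs.values()) - 1.0) > 1e-8:
                raise ConfigurationError(f"{name} probabilities must sum to 1")
        # PSD validation of every stratum's latent correlation matrix, done
        # once at construction on the default panel's class structure.
        panel = default_species_panel()
        for stratum in STRATA:
            latent_correlation(panel, self, stratum)

    def interclass_rho(self, stratum: str, class_a: str, class_b: str) -> float:
        pair = tuple(sorted((class_a, class_b)))
        return self.stratum_interclass_rho.get(stratum, {}).get(pair, self.interclass_rho_default)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["age_range"] = list(self.age_range)
        data["stratum_interclass_rho"] = {
            s: {"|".join(p): r for p, r in pairs.items()}
            for s, pairs in self.stratum_interclass_rho.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "age_range" in data:
            data["age_range"] = tuple(data["age_range"])
        if "stratum_interclass_rho" in data:
            data["stratum_interclass_rho"] = {
                s: {tuple(p.split("|")): r for p, r in pairs.items()}
                for s, pairs in data["stratum_interclass_rho"].items()
            }
        return cls(**data)


def block_correlation(
    panel: SpeciesPanel,
    within_class_rho: float,
    interclass_rho,
    context: str = "panel",
) -> np.ndarray:
    """Latent Pearson correlation matrix with class-block structure.

    Within-class blocks sit at ``within_class_rho`` and class-pair blocks at
    the pair's interclass target (``interclass_rho``: scalar, or a mapping
    from sorted class-pair tuples to values), all given on the Spearman
    scale and converted to the latent Pearson scale. Raises
    :class:`ConfigurationError` naming the first class pair whose two-class
    submatrix is not positive semidefinite, or a generic error if only the
    full matrix fails.
    """
    classes = panel.classes
    idx = {c: [i for i, s in enumerate(panel.entries) if s.class_id == c] for c in classes}
    k = len(panel)
    corr = np.eye(k)
    rho_w = spearman_to_pearson(within_class_rho)
    for c in classes:
        for i in idx[c]:
            for j in idx[c]:
                if i != j:
                    corr[i, j] = rho_w

    def pair_rho(a: str, b: str) -> float:
        if np.isscalar(interclass_rho):
            return float(interclass_rho)
        return float(interclass_rho[tuple(sorted((a, b)))])

    for a, b in combinations(classes, 2):
        rho_b = spearman_to_pearson(pair_rho(a, b))
        for i in idx[a]:
            for j in idx[b]:
                corr[i, j] = corr[j, i] = rho_b
    for a, b in combinations(classes, 2):
        sub = corr[np.ix_(idx[a] + idx[b], idx[a] + idx[b])]
        if np.linalg.eigvalsh(sub).min() < -1e-8:
            raise ConfigurationError(
                f"correlation targets for class pair ({a}, {b}) in {context} "
                f"are not positive semidefinite (within={within_class_rho}, "
                f"interclass={pair_rho(a, b)})"
            )
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ConfigurationError(f"joint correlation matrix for {context} is not positive semidefinite")
    return corr


def latent_correlation(panel: SpeciesPanel, config: CohortConfig, stratum: str) -> np.ndarray:
    """Latent Pearson correlation matrix for one stratum's lipid panel."""
    classes = panel.classes
    inter = {
        tuple(sorted((a, b))): config.interclass_rho(stratum, a, b)
        for a, b in combinations(classes, 2)
    }
    return block_correlation(panel, config.within_class_rho, inter, context=f"stratum {stratum!r}")


def sample_lipid_matrix(
    panel: SpeciesPanel,
    within_class_rho: float,
    interclass_rho,
    n: int,
    seed=None,
    log_mean: float = 0.0,
    log_sd: float = 0.4,
) -> LipidMatrix:
    """Draw one group's lognormal abundance matrix with block rank correlations.

    Convenience sampler for calibration and power studies: a single stratum,
    no clinical table, no missingness. ``seed`` may be an int or an existing
    numpy Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    corr = block_correlation(panel, within_class_rho, interclass_rho)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(panel)))
    latent = rng.standard_normal((n, len(panel))) @ chol.T
    abund = pd.DataFrame(
        np.exp(log_mean + log_sd * latent),
        index=pd.RangeIndex(n, name="subject_id"),
        columns=panel.species_ids,
    )
    return LipidMatrix(abund, pd.Series(panel.class_map, name="class_id"))


def _component_threshold(target: float, rho: float) -> float:
    """Latent cut-off tau so that P(>=3 of 5 exchangeable components abnormal) = target.

    Components share a standard-normal factor f with loading sqrt(rho);
    conditional on f each component is independently abnormal with
    probability Phi((sqrt(rho)*f - tau)/sqrt(1-rho)). The 3-of-5 probability
    is integrated over f with Gauss-Hermite quadrature and inverted for tau.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    w = weights / np.sqrt(2.0 * np.pi)

    def prevalence(tau: float) -> float:
        p = stats.norm.sf((tau - np.sqrt(rho) * nodes) / np.sqrt(1.0 - rho))
        p_ge3 = sum(
            stats.binom.pmf(kk, 5, p) for kk in range(3, 6)
        )
        return float(np.sum(w * p_ge3))

    return optimize.brentq(lambda t: prevalence(t) - target, -6.0, 6.0, xtol=1e-10)


def generate_cohort(
    config: CohortConfig, panel: SpeciesPanel | None = None
) -> tuple[pd.DataFrame, LipidMatrix, pd.Series]:
    """Generate one cohort: clinical table, lipid matrix, true stratum labels.

    Clinical values are constructed so that a component is ATPIII-abnormal
    exactly when its latent Gaussian exceeds the calibrated threshold, which
    makes the classified MetS prevalence match ``mets_target_prevalence`` in
    expectation. Lipid log-abundances are multivariate normal with the
    stratum's block correlation and class mean shifts for MetS subjects,
    then exponentiated; MCAR missingness is injected last. Fully
    reproducible given ``config.seed``.
    """
    panel = panel or default_species_panel()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    crit = MetSCriteria()

    sex = rng.choice(list(config.sex_probs), size=n, p=list(config.sex_probs.values()))
    race = rng.choice(list(config.race_probs), size=n, p=list(config.race_probs.values()))
    education = rng.choice(
        list(config.education_probs), size=n, p=list(config.education_probs.values())
    )
    age = rng.uniform(*config.age_range, size=n)
    male = sex == "male"

    # latent MetS components: shared factor + idiosyncratic noise
    r = config.component_rho
    tau = _component_threshold(config.mets_target_prevalence, r)
    f = rng.standard_normal(n)
    z = np.sqrt(r) * f[:, None] + np.sqrt(1.0 - r) * rng.standard_normal((n, 5))
    z_waist, z_tg, z_hdl, z_bp, z_glu = (z[:, i] for i in range(5))

    waist_cut = np.where(male, crit.waist_cm_male, crit.waist_cm_female)
    hdl_cut = np.where(male, crit.hdl_mg_dl_male, crit.hdl_mg_dl_female)
    waist = waist_cut + 12.0 * (z_waist - tau)
    tg = crit.triglycerides_mg_dl * np.exp(0.45 * (z_tg - tau))
    hdl = np.maximum(hdl_cut - 11.0 * (z_hdl - tau), 15.0)
    systolic = crit.systolic_mmhg + 14.0 * (z_bp - tau)
    # diastolic tied to systolic so a diastolic flag never fires without the
    # systolic one (keeps the latent threshold equivalent to the BP criterion)
    diastolic = 50.0 + 0.25 * systolic + rng.uniform(-2.0, 2.0, size=n)
    glucose = crit.glucose_mg_dl * np.exp(0.30 * (z_glu - tau))
    insulin = np.exp(np.log(9.0) + 0.6 * (z_glu - tau) + 0.5 * rng.standard_normal(n))

    meds = {}
    for flag in ("tg_medication", "hdl_medication", "htn_medication_with_history", "glycemia_medication"):
        meds[flag] = rng.random(n) < config.medication_rate

    clinical = pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "race": race,
            "education": education,
            "waist_cm": waist,
            "bmi": waist / 3.1 + rng.normal(0.0, 1.2, size=n),
            "triglycerides_mg_dl": tg,
            "hdl_mg_dl": hdl,
            "ldl_mg_dl": rng.normal(115.0, 30.0, size=n).clip(40.0),
            "systolic_mmhg": systolic,
            "diastolic_mmhg": diastolic,
            "glucose_mg_dl": glucose,
            "insulin_uiu_ml": insulin,
            "hba1c_pct": 5.4 + 0.35 * (z_glu - tau) + rng.normal(0.0, 0.25, size=n),
            **meds,
        },
        index=pd.RangeIndex(n, name="subject_id"),
    )
    clinical["homa_ir"] = clinical["glucose_mg_dl"] * clinical["insulin_uiu_ml"] / 405.0

    status = classify_mets_table(clinical, crit)
    mets = status["mets"].to_numpy(dtype=bool)

    # inflammatory / endothelial biomarkers, lognormal with MetS shifts
    base_log = {
        "crp_ug_ml": np.log(1.3), "il6_pg_ml": np.log(2.2), "fibrinogen_mg_dl": np.log(330.0),
        "sicam_ng_ml": np.log(270.0), "seselectin_ng_ml": np.log(38.0),
    }
    base_sd = {
        "crp_ug_ml": 0.9, "il6_pg_ml": 0.6, "fibrinogen_mg_dl": 0.2,
        "sicam_ng_ml": 0.3, "seselectin_ng_ml": 0.4,
    }
    for name, mu in base_log.items():
        shift = config.biomarker_effects.get(name, 0.0)
        clinical[name] = np.exp(mu + shift * mets + base_sd[name] * rng.standard_normal(n))

    crp_stratum = crp_stratify(clinical["crp_ug_ml"])
    labels = pd.Series(
        np.where(mets, "mets+", "mets-"), index=clinical.index, dtype="object"
    ) + "_" + np.where(crp_stratum == "high", "crp_high", "crp_low")
    labels.name = "stratum"

    # lipid abundances per stratum
    base_class_log = {"DCER": np.log(0.3), "CER": np.log(2.0), "SM": np.log(5.0),
                      "HCER": np.log(0.8), "LCER": np.log(0.5)}
    mu_species = np.array([base_class_log[s.class_id] for s in panel.entries])
    shift_species = np.array([config.class_mean_shift.get(s.class_id, 0.0) for s in panel.entries])
    k = len(panel)
    log_abund = np.empty((n, k))
    for stratum in STRATA:
        mask = (labels == stratum).to_numpy()
        if not mask.any():
            continue
        corr = latent_correlation(panel, config, stratum)
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(k))
        latent = rng.standard_normal((int(mask.sum()), k)) @ chol.T
        mu = mu_species + (shift_species if stratum.startswith("mets+") else 0.0)
        log_abund[mask] = mu + config.lipid_log_sd * latent
    abund = pd.DataFrame(np.exp(log_abund), index=clinical.index, columns=panel.species_ids)
    matrix = LipidMatrix(abund, pd.Series(panel.class_map, name="class_id"))
    if config.missing_rate > 0:
        matrix = inject_missingness(matrix, config.missing_rate, int(rng.integers(2**31)))
    return clinical, matrix, labels


def inject_missingness(matrix: LipidMatrix, rate: float, seed: int) -> LipidMatrix:
    """Set each cell missing independently with probability ``rate`` (MCAR)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    if rate == 0.0:
        return matrix
    rng = np.random.default_rng(seed)
    mask = rng.random(matrix.abundances.shape) < rate
    abund = matrix.abundances.copy()
    abund[mask] = np.nan
    return LipidMatrix(abund, matrix.class_map)


def write_cohort(outdir, clinical: pd.DataFrame, matrix: LipidMatrix,
                 labels: pd.Series, config: CohortConfig) -> None:
    """Write the cohort as plain TSV + YAML config + JSON provenance sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index_label="subject_id")
    matrix.to_tsv(outdir / "lipids.tsv", outdir / "species_classes.tsv")
    labels.to_csv(outdir / "strata.tsv", sep="\t", index_label="subject_id")
    config.to_yaml(outdir / "cohort_config.yaml")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump({"seed": config.seed, "n_subjects": config.n_subjects}, fh, indent=2)
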