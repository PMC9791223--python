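"""End-to-end orchestration: preprocessing -> volcano -> association
matrices -> per-stratum networks -> interclass permutation tests -> pairwise
Steiger comparisons, from a single config, with a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .lipid_matrix import LipidMatrix
from .panel import CERAMIDE_CLASSES
from .preprocessing import (
    classify_mets_table,
    compute_ratios,
    filter_species,
    log_zscore,
    stratum_labels,
)
from .volcano import volcano_table
from .associations import association_matrix, zscore
from .network import (
    interclass_distance,
    permutation_interclass_test,
    steiger_compare,
    stratum_network,
)
from .synthetic import CohortConfig, generate_cohort, write_cohort

log = logging.getLogger("sphingonet")

MIN_STRATUM_SIZE = 20

BIOMARKER_OUTCOMES = [
    "bmi", "waist_cm", "systolic_mmhg", "diastolic_mmhg", "ldl_mg_dl", "hdl_mg_dl",
    "triglycerides_mg_dl", "glucose_mg_dl", "insulin_uiu_ml", "hba1c_pct", "homa_ir",
    "crp_ug_ml", "il6_pg_ml", "fibrinogen_mg_dl", "sicam_ng_ml", "seselectin_ng_ml",
]


@dataclass
class PipelineConfig:
    """Run-level parameters (defaults are the analysis' canonical values)."""

    cohort: CohortConfig | None = None  # synthetic mode when set
    clinical_path: str | None = None  # real-data mode otherwise
    lipid_path: str | None = None
    class_map_path: str | None = None
    alpha: float = 0.05
    fc_threshold: float = 1.15
    max_missing: float = 0.20
    n_perm: int = 1000
    covariates: tuple = ("sex", "age", "race", "education")
    stratification: str = "mets_crp"  # or "mets_gluco"
    outdir: str = "sphingonet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm <= 0:
            raise ValueError("n_perm must be positive")
        if self.fc_threshold <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")
        if self.stratification not in ("mets_crp", "mets_gluco"):
            raise ValueError(f"unknown stratification scheme {self.stratification!r}")
        if self.cohort is None and not (self.clinical_path and self.lipid_path and self.class_map_path):
            raise ValueError("provide either a synthetic cohort config or input paths")


@dataclass
class PipelineResult:
    status: pd.DataFrame
    strata: pd.Series
    volcano: pd.DataFrame
    ratios: pd.DataFrame
    linear_long: pd.DataFrame
    linear_matrix: pd.DataFrame
    logistic_long: pd.DataFrame
    logistic_matrix: pd.DataFrame
    networks: dict = field(default_factory=dict)  # stratum -> (corr, net, partition)
    interclass: pd.DataFrame | None = None
    permutation_tests: pd.DataFrame | None = None
    steiger: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def load_inputs(config: PipelineConfig):
    if config.cohort is not None:
        clinical, matrix, _ = generate_cohort(config.cohort)
        return clinical, matrix
    clinical = pd.read_csv(config.clinical_path, sep="\t", index_col="subject_id")
    matrix = LipidMatrix.from_tsv(config.lipid_path, config.class_map_path)
    return clinical, matrix


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute every stage; write TSV/GraphML/JSON artifacts under outdir."""
    outdir = Path(config.outdir)
    clinical, matrix = _stage("load_inputs")(load_inputs)(config)

    status = _stage("classify_mets")(classify_mets_table)(clinical)
    strata = _stage("stratify")(stratum_labels)(status, config.stratification)

    matrix, dropped = _stage("filter_species")(filter_species)(matrix, config.max_missing)
    volcano = _stage("volcano")(volcano_table)(
        matrix, status["mets"], config.fc_threshold, config.alpha
    )
    ratios = _stage("ratios")(compute_ratios)(matrix)

    # association surfaces on z-scored exposures (class totals + ratios)
    zmat = _stage("log_zscore")(log_zscore)(matrix)
    totals = matrix.class_totals([c for c in CERAMIDE_CLASSES if c in set(matrix.class_map)])
    exposures = pd.concat([np.log(totals), np.log(ratios)], axis=1).apply(zscore)
    biomarkers = clinical[[c for c in BIOMARKER_OUTCOMES if c in clinical.columns]]
    outcomes_lin = np.log(biomarkers.clip(lower=1e-9)).apply(zscore)
    covs = clinical[list(config.covariates)]
    linear_long, linear_matrix = _stage("linear_models")(association_matrix)(
        exposures, outcomes_lin, covs, config.covariates, "linear"
    )
    logistic_long, logistic_matrix = _stage("logistic_models")(association_matrix)(
        exposures,
        status[["abdominal_obesity", "high_triglycerides", "low_hdl", "high_bp", "high_glucose", "mets"]].astype(float),
        covs,
        config.covariates,
        "logistic",
    )

    # per-stratum networks on the ceramide/glycosphingolipid species
    net_species = [s for s in matrix.species if matrix.class_map[s] in CERAMIDE_CLASSES]
    net_matrix = matrix.select_species(net_species)
    networks = {}
    for stratum in sorted(strata.dropna().unique()):
        subjects = strata.index[strata == stratum]
        if len(subjects) < MIN_STRATUM_SIZE:
            log.warning("stratum %s has %d subjects (<%d); skipped", stratum, len(subjects), MIN_STRATUM_SIZE)
            continue
        networks[stratum] = _stage(f"network[{stratum}]")(stratum_network)(
            net_matrix, subjects, config.alpha
        )

    class_pairs = list(combinations([c for c in CERAMIDE_CLASSES if c in set(net_matrix.class_map)], 2))
    inter_rows = []
    for stratum, (_, net, _) in networks.items():
        for a, b in class_pairs:
            inter_rows.append(
                {"stratum": stratum, "class_a": a, "class_b": b,
                 "mean_distance": interclass_distance(net, net_matrix.class_map, a, b)}
            )
    interclass = pd.DataFrame(inter_rows)

    rng = np.random.default_rng(config.seed)
    perm_rows, steiger_rows = [], []
    for (sa, na), (sb, nb) in combinations(networks.items(), 2):
        steig = _stage(f"steiger[{sa}|{sb}]")(steiger_compare)(na[0], nb[0])
        steiger_rows.append(
            {"stratum_a": sa, "stratum_b": sb, "chi_square": steig.chi_square,
             "df": steig.df, "p_value": steig.p_value, "n_a": steig.n1, "n_b": steig.n2}
        )
        for a, b in class_pairs:
            res = _stage(f"permutation[{sa}|{sb}|{a}-{b}]")(permutation_interclass_test)(
                net_matrix,
                strata.index[strata == sa],
                strata.index[strata == sb],
                (a, b),
                n_perm=config.n_perm,
                seed=int(rng.integers(2**31)),
                alpha=config.alpha,
            )
            perm_rows.append(
                {"stratum_a": sa, "stratum_b": sb, "class_a": a, "class_b": b,
                 "distance_a": res.mean_distance_a, "distance_b": res.mean_distance_b,
                 "delta": res.delta, "p_value": res.p_value, "n_perm": res.n_perm, "seed": res.seed}
            )
    permutation_tests = pd.DataFrame(perm_rows)
    steiger = pd.DataFrame(steiger_rows)

    manifest = {
        "sphingonet_version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "fc_threshold": config.fc_threshold,
        "fc_stat": volcano.attrs.get("fc_stat", "mean"),
        "max_missing": config.max_missing,
        "n_perm": config.n_perm,
        "stratification": config.stratification,
        "covariates": list(config.covariates),
        "reference_levels": {"sex": "female", "race": "White", "education": "high school or less"},
        "n_subjects": int(len(clinical)),
        "n_species_retained": int(len(matrix.species)),
        "species_dropped": {k: float(v) for k, v in dropped.items()},
        "strata_sizes": {k: int(v) for k, v in strata.value_counts().items()},
        "input_checksums": _checksums(config),
    }

    result = PipelineResult(
        status=status, strata=strata, volcano=volcano, ratios=ratios,
        linear_long=linear_long, linear_matrix=linear_matrix,
        logistic_long=logistic_long, logistic_matrix=logistic_matrix,
        networks=networks, interclass=interclass,
        permutation_tests=permutation_tests, steiger=steiger, manifest=manifest,
    )
    if write:
        _write_outputs(outdir, result, config, clinical, matrix)
    return result


def _checksums(config: PipelineConfig) -> dict:
    out = {}
    for attr in ("clinical_path", "lipid_path", "class_map_path"):
        path = getattr(config, attr)
        if path and Path(path).exists():
            out[attr] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    if config.cohort is not None:
        out["cohort_seed"] = config.cohort.seed
    return out


def _write_outputs(outdir: Path, result: PipelineResult, config: PipelineConfig,
                   clinical: pd.DataFrame, matrix: LipidMatrix) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.status.join(result.strata.rename("stratum")).to_csv(
        outdir / "mets_status.tsv", sep="\t", index_label="subject_id"
    )
    result.ratios.to_csv(outdir / "ratios.tsv", sep="\t", index_label="subject_id")
    result.volcano.to_csv(outdir / "volcano.tsv", sep="\t")
    result.linear_long.to_csv(outdir / "linear_associations.tsv", sep="\t", index=False)
    result.linear_matrix.to_csv(outdir / "linear_matrix_masked.tsv", sep="\t")
    result.logistic_long.to_csv(outdir / "logistic_associations.tsv", sep="\t", index=False)
    result.logistic_matrix.to_csv(outdir / "logistic_matrix_masked.tsv", sep="\t")
    netdir = outdir / "networks"
    netdir.mkdir(exist_ok=True)
    for stratum, (corr, net, part) in result.networks.items():
        safe = stratum.replace("+", "pos").replace("-", "neg")
        net.to_edge_list().to_csv(netdir / f"{safe}_edges.tsv", sep="\t", index=False)
        net.write_graphml(netdir / f"{safe}.graphml")
        part.to_frame().to_csv(netdir / f"{safe}_clusters.tsv", sep="\t")
    if result.interclass is not None:
        result.interclass.to_csv(outdir / "interclass_distances.tsv", sep="\t", index=False)
    if result.permutation_tests is not None:
        result.permutation_tests.to_csv(outdir / "permutation_tests.tsv", sep="\t", index=False)
    if result.steiger is not None:
        result.steiger.to_csv(outdir / "steiger_comparisons.tsv", sep="\t", index=False)
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)


def simulate(config: CohortConfig, outdir) -> None:
    """Generate a synthetic cohort and write it as TSV + provenance."""
    clinical, matrix, labels = generate_cohort(config)
    write_cohort(outdir, clinical, matrix, labels, config)
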