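"""End-to-end orchestration: simulate/load -> assemble -> subtype ->
associate -> train (all seven feature-type combinations) -> evaluate.

Each stage reads and writes plain-text artifacts under the configured
output directory; a manifest records the config hash, seed and per-stage
counts so runs are reproducible and filter attrition is debuggable.
"""

from __future__ import annotations

import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .coxnet import TuningGrid, risk_score, train_prognostic_model
from .evaluate import evaluate_model
from .features import (
    FeatureMatrix,
    assemble_features,
    binarize_mutations,
    collapse_segments,
    score_signatures,
)
from .io import read_clinical, read_gene_catalog, read_maf, read_matrix, read_segments, \
    read_signatures
from .subtyping import CentroidSet, assign_subtype, subgroup_center
from .stats import adjust_family, binomial_glm_univariate, cox_univariate, results_to_frame
from .synthetic import CohortConfig, generate_cohort, write_cohort

__all__ = ["run_pipeline", "MODEL_COMBOS"]

log = logging.getLogger("tnbcprog")

#: the seven feature-type combinations trained as separate models
MODEL_COMBOS = {
    "clinical": ("clinical",),
    "rna": ("rna",),
    "dna": ("dna",),
    "clinical_rna": ("clinical", "rna"),
    "clinical_dna": ("clinical", "dna"),
    "rna_dna": ("rna", "dna"),
    "clinical_rna_dna": ("clinical", "rna", "dna"),
}


def _stage(manifest, name):
    class _Timer:
        def __enter__(self):
            self.t0 = _time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = _time.perf_counter() - self.t0
            manifest["stages"][name] = {"seconds": round(dt, 3)}
            if exc is not None:
                manifest["stages"][name]["failed"] = repr(exc)
                log.error("stage %s failed after %.1fs: %r", name, dt, exc)
            else:
                log.info("stage %s: done in %.1fs", name, dt)
            return False

    return _Timer()


def simulate_inputs(config: PipelineConfig, data_dir: Path):
    cohort_cfg = CohortConfig(**{"seed": config.seed, **config.cohort})
    cohort = generate_cohort(cohort_cfg)
    write_cohort(cohort, data_dir, overwrite=True)
    return cohort


def load_inputs(config: PipelineConfig, data_dir: Path):
    clinical = read_clinical(data_dir / "clinical.tsv")
    patients = clinical.index
    mutations = read_maf(data_dir / "mutations.maf")
    cn = read_matrix(data_dir / "cn_genes.tsv", patients=patients).T  # -> patients x genes
    expression = read_matrix(data_dir / "expression.tsv", patients=patients)  # genes x patients
    segments = read_segments(data_dir / "segments.json")
    signatures = read_signatures(data_dir / "signatures.json")
    catalog = read_gene_catalog(data_dir / "gene_catalog.json")
    return clinical, mutations, cn, expression, segments, signatures, catalog


def assemble_stage(config, clinical, mutations, cn, expression, segments, signatures, catalog):
    mut_matrix = binarize_mutations(
        mutations,
        catalog["mutation_genes"],
        catalog.get("exclusion_list", ()),
        patients=clinical.index,
        tp53_variant_catalog=catalog.get("tp53_variants"),
    )
    seg_calls = collapse_segments(
        cn, segments, gain=config.gain_threshold, loss=config.loss_threshold
    )
    sig_scores = score_signatures(expression, signatures)
    return assemble_features(clinical, mut_matrix, seg_calls, sig_scores), mut_matrix, seg_calls


def subtype_stage(clinical, expression, data_dir: Path):
    centroid_path = data_dir / "centroids.tsv"
    if not centroid_path.exists():
        log.info("no centroid file at %s; skipping subtype stage", centroid_path)
        return None
    centroids = pd.read_csv(centroid_path, sep="\t", index_col=0)
    shared = centroids.index.intersection(expression.index)
    expr = expression.loc[shared]
    # cohort-median centering stands in for subgroup-specific reference columns
    centering = expr.median(axis=1)
    centered = subgroup_center(expr, centering)
    labels, corr, flags = assign_subtype(centered, CentroidSet(centroids.loc[shared]))
    return labels


def associate_stage(config, features: FeatureMatrix, clinical, subtype_labels):
    """Univariate scans on the training dataset, BH-adjusted per family."""
    train_ids = clinical.index[clinical["dataset"] == config.training_dataset]
    X = features.values.loc[features.values.index.intersection(train_ids)]
    clin = clinical.loc[X.index]
    time_, event_ = clin["time"].to_numpy(), clin["event"].to_numpy()
    binary = features.category.isin(["gene_mutation", "tp53_variant", "cn_gain", "cn_loss"])
    eligible = [
        c
        for c in X.columns
        if (not binary[c] and X[c].std() > 0)
        or (binary[c] and X[c].sum() >= config.eligibility_min)
    ]
    surv = []
    for c in eligible:
        if X[c].std() == 0:
            continue
        try:
            surv.append(cox_univariate(time_, event_, X[c].to_numpy(), name=c))
        except (ValueError, np.linalg.LinAlgError):
            continue
    adjust_family(surv, "survival_scan")

    glm = []
    if subtype_labels is not None:
        sub = subtype_labels.reindex(X.index)
        outcome = (sub == "basal").astype(float)
        if outcome.nunique() == 2:
            mut_cols = [c for c in eligible if binary[c]]
            for c in mut_cols:
                try:
                    glm.append(
                        binomial_glm_univariate(outcome.to_numpy(), X[c].to_numpy(), name=c)
                    )
                except ValueError:
                    continue
            ok = [r for r in glm if np.isfinite(r.p)]
            adjust_family(ok, "subtype_scan")
    return results_to_frame(surv), results_to_frame(glm)


def landscape_stage(features: FeatureMatrix, surv_results: pd.DataFrame):
    """Per-segment gain/loss frequencies with survival-association class."""
    gains = features.category[features.category == "cn_gain"].index
    rows = []
    surv = surv_results.set_index("feature") if len(surv_results) else pd.DataFrame()
    for g in gains:
        seg = g[len("gain:"):]
        loss_col = f"loss:{seg}"
        row = {"segment": seg, "gain_freq": features.values[g].mean()}
        row["loss_freq"] = (
            features.values[loss_col].mean() if loss_col in features.values.columns else np.nan
        )
        for kind, col in (("gain", g), ("loss", loss_col)):
            if col in surv.index:
                hr, p, q = surv.loc[col, ["estimate", "p", "fdr_p"]]
                direction = "worse" if hr > 1 else "better"
                sig = "fdr" if q < 0.05 else ("nominal" if p < 0.05 else "ns")
            else:
                direction, sig = "", "untested"
            row[f"{kind}_direction"] = direction
            row[f"{kind}_significance"] = sig
        rows.append(row)
    return pd.DataFrame(rows)


def train_stage(config, features: FeatureMatrix, clinical):
    train_ids = clinical.index[clinical["dataset"] == config.training_dataset]
    X = features.values.loc[features.values.index.intersection(train_ids)]
    clin = clinical.loc[X.index]
    sub = FeatureMatrix(values=X, category=features.category)
    grid = TuningGrid(alphas=tuple(config.alphas), lambdas=tuple(config.lambdas))
    combos = MODEL_COMBOS
    if config.model_combos is not None:
        unknown = set(config.model_combos) - set(MODEL_COMBOS)
        if unknown:
            raise ValueError(f"unknown model combinations: {sorted(unknown)}")
        combos = {k: MODEL_COMBOS[k] for k in config.model_combos}
    models = {}
    for name, combo in combos.items():
        models[name] = train_prognostic_model(
            sub,
            clin["time"].to_numpy(),
            clin["event"].to_numpy(),
            combo,
            grid=grid,
            B=config.n_bootstrap,
            seed=config.seed,
            sparse_threshold=config.sparse_threshold,
            per_event=config.normalize_oob,
            training_cohort=config.training_dataset,
        )
        log.info(
            "model %s: %d/%d features selected",
            name,
            len(models[name].selected_features),
            models[name].n_features_after_filter,
        )
    return models


def evaluate_stage(config, features: FeatureMatrix, clinical, models):
    test_mask = clinical["dataset"] != config.training_dataset
    test_ids = features.values.index.intersection(clinical.index[test_mask])
    X = features.values.loc[test_ids]
    clin = clinical.loc[test_ids]
    reports = {}
    for name, model in models.items():
        scores = risk_score(model, X)
        reports[name] = evaluate_model(
            scores,
            clin["time"].to_numpy(),
            clin["event"].to_numpy(),
            clin["dataset"],
            stage=(clin["stage"] == "III").astype(float) if "stage" in clin else None,
            group_mode=config.risk_group_mode,
        )
    return reports


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_dir = Path(config.data_dir) if config.data_dir else out / "cohort"
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    with _stage(manifest, "inputs"):
        if config.simulate:
            simulate_inputs(config, data_dir)
        clinical, mutations, cn, expression, segments, signatures, catalog = load_inputs(
            config, data_dir
        )
        manifest["n_patients"] = int(len(clinical))

    with _stage(manifest, "assemble"):
        features, mut_matrix, seg_calls = assemble_stage(
            config, clinical, mutations, cn, expression, segments, signatures, catalog
        )
        features.values.to_csv(out / "features.tsv", sep="\t", float_format="%.10g")
        features.category.rename("category").to_csv(out / "feature_categories.tsv", sep="\t")
        manifest["n_features"] = int(features.values.shape[1])
        manifest["n_excluded_patients"] = int(features.n_excluded_patients)

    with _stage(manifest, "subtype"):
        subtype_labels = subtype_stage(clinical, expression, data_dir)
        if subtype_labels is not None:
            clinical = clinical.assign(subtype=subtype_labels.reindex(clinical.index))
            clinical.to_csv(out / "clinical_with_subtype.tsv", sep="\t")

    with _stage(manifest, "associate"):
        surv_results, glm_results = associate_stage(config, features, clinical, subtype_labels)
        surv_results.to_csv(out / "associations_survival.tsv", sep="\t", index=False)
        glm_results.to_csv(out / "associations_subtype.tsv", sep="\t", index=False)
        landscape = landscape_stage(features, surv_results)
        landscape.to_csv(out / "cn_landscape.tsv", sep="\t", index=False)

    with _stage(manifest, "train"):
        models = train_stage(config, features, clinical)
        for name, model in models.items():
            model.to_json(out / f"model_{name}.json")
            if model.tuning is not None:
                model.tuning.deviance_table.to_csv(
                    out / f"deviance_{name}.tsv", sep="\t", float_format="%.8g"
                )

    with _stage(manifest, "evaluate"):
        reports = evaluate_stage(config, features, clinical, models)
        with open(out / "evaluation.json", "w") as fh:
            json.dump({k: r.to_dict() for k, r in reports.items()}, fh, indent=1)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {
        "features": features,
        "models": models,
        "evaluations": reports,
        "manifest": manifest,
        "clinical": clinical,
    }
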