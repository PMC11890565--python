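"""Synthetic multi-dataset TNBC-like cohorts with known ground truth.

No public generative model exists for the study data this pipeline targets
(controlled-access clinical-trial and consortium cohorts), so this module
defines one explicitly: a four-dataset cohort of stage II/III patients with

* right-censored overall survival from a proportional-hazards model with
  dataset-specific Weibull baselines and a known coefficient vector,
* a dominant highly mutated gene (TP53-like, default frequency 0.85) plus a
  tail of rarer genes, with hotspot TP53 protein changes of typed classes,
* gene-level copy number built from latent segment-level gains/losses plus
  gene noise, and
* an expression matrix whose signature member genes track latent signature
  scores, with planted survival effects, plus subtype-marker genes drawn
  around per-subtype centroids.

Every distributional choice is a configurable stand-in, not a claim about
the real data; the point is that each downstream stage has a known truth to
recover.  One integer seed drives a named sub-stream per platform, so
regenerating one platform never perturbs the others.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .features import SegmentDefinition, SignatureDefinition

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "simulate_survival",
    "write_cohort",
]

#: default per-dataset sample sizes (discovery + three test sets)
DEFAULT_DATASETS = {"train": 238, "testA": 224, "testB": 91, "testC": 133}

#: default Weibull (shape, scale-in-years) baselines per dataset; chosen so
#: the four baseline survival trajectories differ visibly
DEFAULT_BASELINES = {
    "train": (1.1, 18.0),
    "testA": (0.9, 14.0),
    "testB": (1.3, 25.0),
    "testC": (0.8, 10.0),
}

#: recurrent TP53 protein changes planted with elevated frequency
HOTSPOT_WEIGHTS = {
    "R175H": 27,
    "R273H": 17,
    "R213*": 17,
    "Y220C": 14,
    "R273C": 13,
    "R306*": 13,
    "R248Q": 12,
}

_CLASS_TO_MAF = {
    "missense": "Missense_Mutation",
    "nonsense": "Nonsense_Mutation",
    "frameshift": "Frame_Shift_Del",
    "in-frame": "In_Frame_Del",
    "splice site": "Splice_Site",
}

SUBTYPES = ("basal", "her2_enriched", "luminal_a", "luminal_b", "normal_like")
#: rough cohort-level subtype mix (basal-dominant, as in TNBC)
SUBTYPE_PROBS = (0.735, 0.128, 0.036, 0.010, 0.091)


@dataclass
class CohortConfig:
    """Generator settings; the defaults are the package's study conditions."""

    datasets: dict = field(default_factory=lambda: dict(DEFAULT_DATASETS))
    stage_iii_fraction: float = 0.236
    n_mutation_genes: int = 700
    n_tp53_variants: int = 134
    n_segments: int = 534
    genes_per_segment: int = 3
    n_signatures: int = 759
    signature_genes: int = 5
    n_subtype_genes: int = 50
    dominant_gene_freq: float = 0.85
    mutation_freq_range: tuple = (0.01, 0.15)  # log-uniform for non-dominant genes
    segment_event_prob_range: tuple = (0.02, 0.40)  # log-uniform per-segment gain & loss
    gain_magnitude: float = 0.6
    segment_noise_sd: float = 0.08
    gene_noise_sd: float = 0.15
    signature_noise_sd: float = 0.5
    subtype_noise_sd: float = 0.5
    hrd_germline_prob: float = 0.05
    hrd_somatic_prob: float = 0.01
    beta_true: dict | None = None  # None -> default planted effects
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    censor_window: float = 10.0
    mutation_freqs: np.ndarray | None = None  # overrides the drawn frequencies
    hotspot_classes: dict | None = None  # protein change -> class, overrides catalog
    seed: int = 0

    def __post_init__(self):
        if not self.datasets or any(n < 1 for n in self.datasets.values()):
            raise ValueError("every dataset must have at least one patient")
        if not (0.0 <= self.stage_iii_fraction <= 1.0):
            raise ValueError("stage_iii_fraction must be a probability")
        for name in (
            "n_mutation_genes",
            "n_tp53_variants",
            "n_segments",
            "genes_per_segment",
            "n_signatures",
            "signature_genes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.dominant_gene_freq <= 1.0):
            raise ValueError("dominant_gene_freq must be a probability")
        if self.censor_window <= 0:
            raise ValueError("censor_window must be positive (otherwise every subject "
                             "would be censored at time zero)")
        for ds, (shape, scale) in self.baselines.items():
            if shape <= 0 or scale <= 0:
                raise ValueError(f"baseline shape/scale for {ds!r} must be positive")
        missing = [d for d in self.datasets if d not in self.baselines]
        if missing:
            raise ValueError(f"datasets without baseline parameters: {missing}")

    def default_beta(self) -> dict:
        """Planted survival effects: stage is harmful; two immune-like
        signatures are protective; one segment loss is harmful."""
        return {
            "stage": 0.5,
            "sig:SIG0001": -0.5,
            "sig:SIG0002": -0.4,
            "loss:SEG0001": 0.4,
        }


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated cohort (the oracle for tests)."""

    beta_true: pd.Series
    baselines: dict
    features: pd.DataFrame = field(repr=False, default=None)  # true design matrix
    linear_predictor: pd.Series = field(repr=False, default=None)
    subtype: pd.Series = field(repr=False, default=None)
    subtype_centroids: pd.DataFrame = field(repr=False, default=None)
    signature_latent: pd.DataFrame = field(repr=False, default=None)


@dataclass
class SyntheticCohort:
    clinical: pd.DataFrame
    mutations: pd.DataFrame
    cn_genes: pd.DataFrame  # patients x genes
    expression: pd.DataFrame  # genes x patients
    segment_catalog: list
    signature_catalog: list
    truth: SyntheticTruth
    mutation_genes: list = field(default_factory=list)
    tp53_variants: list = field(default_factory=list)
    tp53_classes: dict = field(default_factory=dict)


def simulate_survival(linear_predictor, shape, scale, censor_window, rng_or_seed=0):
    """Draw right-censored Weibull proportional-hazards survival times.

    The hazard is the Weibull baseline multiplied by exp(linear predictor);
    censoring is uniform administrative censoring on (0, censor_window],
    independent of the covariates.
    """
    eta = np.asarray(linear_predictor, dtype=float)
    if np.any(~np.isfinite(eta)):
        raise ValueError("linear predictor must be finite")
    if shape <= 0 or scale <= 0:
        raise ValueError("baseline shape and scale must be positive")
    if censor_window <= 0:
        raise ValueError("censor_window must be positive")
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else substream(int(rng_or_seed), "survival")
    )
    u = rng.uniform(size=eta.size)
    # S(t) = exp(-(t/scale)^shape * e^eta)  =>  invert at u
    t_event = scale * (-np.log(u) / np.exp(eta)) ** (1.0 / shape)
    c = rng.uniform(0.0, censor_window, size=eta.size)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(np.int8)
    return time, event


def _catalog_names(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _tp53_catalog(config: CohortConfig, rng: np.random.Generator):
    """(protein change, class, sampling weight) for n_tp53_variants changes."""
    if config.hotspot_classes is not None:
        items = list(config.hotspot_classes.items())
        weights = np.ones(len(items))
        for i, (chg, _) in enumerate(items):
            weights[i] = HOTSPOT_WEIGHTS.get(chg, 1.0)
        return [c for c, _ in items], [k for _, k in items], weights
    changes, classes, weights = [], [], []
    for chg in HOTSPOT_WEIGHTS:
        changes.append(chg)
        classes.append("nonsense" if chg.endswith("*") else "missense")
        weights.append(float(HOTSPOT_WEIGHTS[chg]))
    aa = "ACDEFGHIKLMNPQRSTVWY"
    class_pool = ["missense"] * 60 + ["nonsense"] * 15 + ["frameshift"] * 15 + [
        "splice site"
    ] * 5 + ["in-frame"] * 5
    while len(changes) < config.n_tp53_variants:
        pos = int(rng.integers(1, 394))
        kind = class_pool[int(rng.integers(0, len(class_pool)))]
        ref = aa[int(rng.integers(0, 20))]
        if kind == "missense":
            alt = aa[int(rng.integers(0, 20))]
            chg = f"{ref}{pos}{alt}"
        elif kind == "nonsense":
            chg = f"{ref}{pos}*"
        elif kind == "frameshift":
            chg = f"{ref}{pos}fs"
        elif kind == "in-frame":
            chg = f"{ref}{pos}del"
        else:
            chg = f"X{pos}_splice"  # vcf2maf-style splice notation
        if chg in changes:
            continue
        changes.append(chg)
        classes.append(kind)
        weights.append(1.0)
    return (
        changes[: config.n_tp53_variants],
        classes[: config.n_tp53_variants],
        np.asarray(weights[: config.n_tp53_variants]),
    )


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate one multi-dataset cohort; the seed fixes every value."""
    config = config or CohortConfig()
    seed = config.seed
    ds_names = list(config.datasets)
    patients = []
    ds_labels = []
    for ds in ds_names:
        n = config.datasets[ds]
        patients.extend(f"{ds}_P{i + 1:04d}" for i in range(n))
        ds_labels.extend([ds] * n)
    patients = pd.Index(patients, name="patient")
    n_total = len(patients)

    # --- clinical: stage ---------------------------------------------------
    rng_cl = substream(seed, "clinical")
    stage_iii = rng_cl.uniform(size=n_total) < config.stage_iii_fraction
    clinical = pd.DataFrame(
        {"dataset": ds_labels, "stage": np.where(stage_iii, "III", "II")}, index=patients
    )

    # --- catalogs (their own stream so sizes can change independently) -----
    rng_cat = substream(seed, "catalog")
    mut_genes = ["TP53"] + _catalog_names("G", config.n_mutation_genes - 1)
    if config.mutation_freqs is not None:
        freqs = np.asarray(config.mutation_freqs, dtype=float)
        if freqs.size != config.n_mutation_genes:
            raise ValueError("mutation_freqs must have one entry per catalog gene")
    else:
        lo, hi = config.mutation_freq_range
        freqs = np.exp(rng_cat.uniform(np.log(lo), np.log(hi), size=config.n_mutation_genes))
        freqs[0] = config.dominant_gene_freq
    tp53_changes, tp53_classes, tp53_weights = _tp53_catalog(config, rng_cat)
    seg_ids = _catalog_names("SEG", config.n_segments)
    segment_catalog = [
        SegmentDefinition(
            sid, tuple(f"{sid}_CG{g + 1}" for g in range(config.genes_per_segment))
        )
        for sid in seg_ids
    ]
    lo, hi = config.segment_event_prob_range
    p_gain = np.exp(rng_cat.uniform(np.log(lo), np.log(hi), size=config.n_segments))
    p_loss = np.exp(rng_cat.uniform(np.log(lo), np.log(hi), size=config.n_segments))
    sig_ids = _catalog_names("SIG", config.n_signatures)
    signature_catalog = [
        SignatureDefinition(s, tuple(f"{s}_EG{g + 1}" for g in range(config.signature_genes)))
        for s in sig_ids
    ]

    # --- mutations ---------------------------------------------------------
    rng_mut = substream(seed, "mutation")
    mut_ind = (rng_mut.uniform(size=(n_total, config.n_mutation_genes)) < freqs).astype(np.int8)
    records = []
    tp53_idx = 0  # TP53 is the first catalog gene
    rng_tp53 = substream(seed, "tp53")
    tp53_p = tp53_weights / tp53_weights.sum()
    var_class_pool = np.array(
        ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Splice_Site", "In_Frame_Del"]
    )
    var_class_w = np.array([0.70, 0.10, 0.10, 0.05, 0.05])
    aa = "ACDEFGHIKLMNPQRSTVWY"
    for pi, patient in enumerate(patients):
        hit = np.flatnonzero(mut_ind[pi])
        for gi in hit:
            gene = mut_genes[gi]
            if gi == tp53_idx:
                vi = int(rng_tp53.choice(len(tp53_changes), p=tp53_p))
                chg, kind = tp53_changes[vi], tp53_classes[vi]
                records.append(
                    (
                        patient,
                        gene,
                        _CLASS_TO_MAF[kind],
                        f"p.{chg}" if chg else "",
                        "somatic",
                        "",
                    )
                )
            else:
                vc = str(rng_mut.choice(var_class_pool, p=var_class_w))
                if vc == "Missense_Mutation":
                    chg = (
                        f"p.{aa[int(rng_mut.integers(0, 20))]}"
                        f"{int(rng_mut.integers(1, 900))}{aa[int(rng_mut.integers(0, 20))]}"
                    )
                else:
                    chg = ""
                records.append((patient, gene, vc, chg, "somatic", ""))

    # classified germline/somatic HRD-gene calls
    rng_hrd = substream(seed, "hrd")
    hrd_genes = np.array(["BRCA1", "BRCA2", "PALB2"])
    hrd_w = np.array([27.0, 5.0, 3.0])
    hrd_w /= hrd_w.sum()
    for patient in patients:
        u = rng_hrd.uniform()
        if u < config.hrd_germline_prob:
            g = str(rng_hrd.choice(hrd_genes, p=hrd_w))
            records.append((patient, g, "Missense_Mutation", "", "germline", "pathogenic"))
        elif u < config.hrd_germline_prob + config.hrd_somatic_prob:
            g = str(rng_hrd.choice(hrd_genes, p=hrd_w))
            records.append((patient, g, "Missense_Mutation", "", "somatic", "oncogenic"))
        elif u < config.hrd_germline_prob + config.hrd_somatic_prob + 0.02:
            g = str(rng_hrd.choice(hrd_genes, p=hrd_w))
            records.append(
                (patient, g, "Missense_Mutation", "", "germline", "uncertain_significance")
            )
    mutations = pd.DataFrame(
        records,
        columns=["patient", "gene", "variant_classification", "protein_change", "origin",
                 "pathogenicity"],
    )

    # --- copy number: latent segment scores + gene noise --------------------
    rng_cn = substream(seed, "copynumber")
    u = rng_cn.uniform(size=(n_total, config.n_segments))
    latent = rng_cn.normal(0.0, config.segment_noise_sd, size=(n_total, config.n_segments))
    gain_mag = np.abs(rng_cn.normal(config.gain_magnitude, 0.2, size=(n_total, config.n_segments)))
    loss_mag = np.abs(rng_cn.normal(config.gain_magnitude, 0.2, size=(n_total, config.n_segments)))
    is_gain = u < p_gain
    is_loss = (u >= p_gain) & (u < p_gain + p_loss)
    latent = np.where(is_gain, gain_mag, np.where(is_loss, -loss_mag, latent))
    cn_cols = [g for seg in segment_catalog for g in seg.genes]
    gene_noise = rng_cn.normal(
        0.0, config.gene_noise_sd, size=(n_total, config.n_segments * config.genes_per_segment)
    )
    cn_vals = np.repeat(latent, config.genes_per_segment, axis=1) + gene_noise
    cn_genes = pd.DataFrame(cn_vals, index=patients, columns=cn_cols)

    # --- expression: signature latents + subtype centroids ------------------
    rng_ex = substream(seed, "expression")
    sig_latent = rng_ex.normal(0.0, 1.0, size=(n_total, config.n_signatures))
    expr_blocks = []
    expr_genes = []
    for k, sigdef in enumerate(signature_catalog):
        base = rng_ex.normal(6.0, 1.0)
        noise = rng_ex.normal(0.0, config.signature_noise_sd,
                              size=(config.signature_genes, n_total))
        expr_blocks.append(base + sig_latent[:, k][None, :] + noise)
        expr_genes.extend(sigdef.genes)

    rng_sub = substream(seed, "subtype")
    subtype_genes = _catalog_names("PAMG", config.n_subtype_genes)
    centroids = rng_sub.normal(0.0, 1.0, size=(config.n_subtype_genes, len(SUBTYPES)))
    sub_idx = rng_sub.choice(len(SUBTYPES), size=n_total, p=SUBTYPE_PROBS)
    sub_noise = rng_sub.normal(0.0, config.subtype_noise_sd, size=(config.n_subtype_genes, n_total))
    expr_blocks.append(6.0 + centroids[:, sub_idx] + sub_noise)
    expr_genes.extend(subtype_genes)
    expression = pd.DataFrame(
        np.vstack(expr_blocks), index=pd.Index(expr_genes, name="gene"), columns=patients
    )

    # --- true feature matrix and survival -----------------------------------
    stage_num = (clinical["stage"] == "III").astype(float)
    feat_blocks = {
        "stage": stage_num.to_numpy(),
    }
    features = pd.DataFrame(feat_blocks, index=patients)
    sig_df = pd.DataFrame(sig_latent, index=patients, columns=[f"sig:{s}" for s in sig_ids])
    mut_df = pd.DataFrame(mut_ind, index=patients, columns=[f"mut:{g}" for g in mut_genes])
    gain_df = pd.DataFrame(
        (latent > 0.3).astype(float), index=patients, columns=[f"gain:{s}" for s in seg_ids]
    )
    loss_df = pd.DataFrame(
        (latent < -0.3).astype(float), index=patients, columns=[f"loss:{s}" for s in seg_ids]
    )
    features = pd.concat([features, sig_df, mut_df, gain_df, loss_df], axis=1)

    beta_dict = config.beta_true if config.beta_true is not None else config.default_beta()
    unknown = [f for f in beta_dict if f not in features.columns]
    if unknown:
        raise ValueError(f"beta_true names unknown features: {unknown[:5]}")
    beta_true = pd.Series(0.0, index=features.columns)
    for f, b in beta_dict.items():
        beta_true[f] = float(b)
    eta = features.to_numpy() @ beta_true.to_numpy()
    time = np.empty(n_total)
    event = np.empty(n_total, dtype=np.int8)
    for ds in ds_names:
        mask = np.asarray(clinical["dataset"] == ds)
        shape, scale = config.baselines[ds]
        t, e = simulate_survival(
            eta[mask], shape, scale, config.censor_window, substream(seed, "survival", ds)
        )
        time[mask], event[mask] = t, e
    clinical["time"] = time
    clinical["event"] = event
    if clinical["event"].sum() == 0:
        warnings.warn("generated cohort has no events; survival models will be degenerate")

    truth = SyntheticTruth(
        beta_true=beta_true,
        baselines=dict(config.baselines),
        features=features,
        linear_predictor=pd.Series(eta, index=patients),
        subtype=pd.Series([SUBTYPES[i] for i in sub_idx], index=patients, name="subtype"),
        subtype_centroids=pd.DataFrame(centroids, index=subtype_genes, columns=SUBTYPES),
        signature_latent=pd.DataFrame(sig_latent, index=patients, columns=sig_ids),
    )
    return SyntheticCohort(
        clinical=clinical,
        mutations=mutations,
        cn_genes=cn_genes,
        expression=expression,
        segment_catalog=segment_catalog,
        signature_catalog=signature_catalog,
        truth=truth,
        mutation_genes=mut_genes,
        tp53_variants=[c for c in tp53_changes if c],
        tp53_classes={c: k for c, k in zip(tp53_changes, tp53_classes) if c},
    )


def write_cohort(cohort: SyntheticCohort, directory, *, overwrite: bool = False) -> dict:
    """Write a cohort as plain-text files readable by the pipeline.

    Emits a MAF-dialect mutation table, TSV matrices (patients as columns),
    a clinical TSV, JSON catalogs, and a JSON truth file.  Returns the path
    map.  Refuses to overwrite existing files unless ``overwrite`` is set.
    """
    directory = Path(directory)
    if not directory.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {directory.parent}")
    directory.mkdir(exist_ok=True)
    paths = {
        "clinical": directory / "clinical.tsv",
        "mutations": directory / "mutations.maf",
        "cn_genes": directory / "cn_genes.tsv",
        "expression": directory / "expression.tsv",
        "segments": directory / "segments.json",
        "signatures": directory / "signatures.json",
        "gene_catalog": directory / "gene_catalog.json",
        "centroids": directory / "centroids.tsv",
        "truth": directory / "truth.json",
    }
    if not overwrite:
        clashes = [str(p) for p in paths.values() if p.exists()]
        if clashes:
            raise FileExistsError(f"refusing to overwrite without overwrite=True: {clashes[:3]}")

    cohort.clinical.to_csv(paths["clinical"], sep="\t", float_format="%.10g")
    maf = pd.DataFrame(
        {
            "Hugo_Symbol": cohort.mutations["gene"],
            "Tumor_Sample_Barcode": cohort.mutations["patient"],
            "Variant_Classification": cohort.mutations["variant_classification"],
            "HGVSp_Short": cohort.mutations["protein_change"],
            "Mutation_Status": cohort.mutations["origin"].str.capitalize(),
            "Pathogenicity": cohort.mutations["pathogenicity"],
        }
    )
    maf.to_csv(paths["mutations"], sep="\t", index=False)
    # matrices with patients as columns
    cohort.cn_genes.T.to_csv(paths["cn_genes"], sep="\t", float_format="%.10g")
    cohort.expression.to_csv(paths["expression"], sep="\t", float_format="%.10g")
    with open(paths["segments"], "w") as fh:
        json.dump({s.segment_id: list(s.genes) for s in cohort.segment_catalog}, fh)
    with open(paths["signatures"], "w") as fh:
        json.dump({s.signature_id: list(s.genes) for s in cohort.signature_catalog}, fh)
    with open(paths["gene_catalog"], "w") as fh:
        json.dump(
            {
                "mutation_genes": list(cohort.mutation_genes),
                "tp53_variants": list(cohort.tp53_variants),
                "tp53_classes": dict(cohort.tp53_classes),
            },
            fh,
        )
    truth = cohort.truth
    if truth.subtype_centroids is not None:
        truth.subtype_centroids.to_csv(paths["centroids"], sep="\t", float_format="%.10g")
    nz = truth.beta_true[truth.beta_true != 0]
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "beta_true_nonzero": nz.to_dict(),
                "baselines": {k: list(v) for k, v in truth.baselines.items()},
                "subtype": truth.subtype.to_dict(),
            },
            fh,
            indent=1,
        )
    return paths
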