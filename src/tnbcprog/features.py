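"""Assembly of the candidate feature space from mutation, copy-number and
expression inputs.

The candidate space mirrors a multi-platform tumor-profiling study: one
clinical feature (tumor stage), RNA expression-signature scores, gene-level
somatic mutation indicators, variant-level TP53 indicators, and segment-level
copy-number gain/loss indicators.  All indicator features are binary; the
signature scores are continuous and median-centered within the analysis
cohort.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MutationMatrix",
    "SegmentDefinition",
    "SegmentCalls",
    "SignatureDefinition",
    "FeatureMatrix",
    "MUTATION_COLUMNS",
    "binarize_mutations",
    "classify_tp53_variant",
    "hrd_status",
    "log2_ratio",
    "collapse_segments",
    "call_gain_loss",
    "normalize_expression",
    "score_signatures",
    "zscale_gene",
    "assemble_features",
    "filter_sparse",
    "dedup_perfect_correlation",
]

#: canonical internal columns of a mutation record table
MUTATION_COLUMNS = [
    "patient",
    "gene",
    "variant_classification",
    "protein_change",
    "origin",
    "pathogenicity",
]

HRD_GENES = ("BRCA1", "BRCA2", "PALB2")

GAIN_THRESHOLD = 0.3
LOSS_THRESHOLD = -0.3

# feature categories and the coarse groups used to define model combinations
CATEGORY_GROUPS = {
    "clinical": ("clinical",),
    "rna": ("rna_signature",),
    "dna": ("gene_mutation", "tp53_variant", "cn_gain", "cn_loss"),
}


@dataclass
class SegmentDefinition:
    segment_id: str
    genes: tuple
    region: str = ""

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"segment {self.segment_id} has an empty gene list")


@dataclass
class SignatureDefinition:
    signature_id: str
    genes: tuple
    method: str = "median"  # median | weighted-mean | centroid-correlation
    weights: tuple | None = None
    centroid: tuple | None = None

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.signature_id} has an empty gene list")
        if self.method not in ("median", "weighted-mean", "centroid-correlation"):
            raise ValueError(f"unknown scoring method {self.method!r}")
        if self.method == "weighted-mean" and (
            self.weights is None or len(self.weights) != len(self.genes)
        ):
            raise ValueError("weighted-mean signatures need one weight per gene")
        if self.method == "centroid-correlation" and (
            self.centroid is None or len(self.centroid) != len(self.genes)
        ):
            raise ValueError("centroid-correlation signatures need a centroid value per gene")


@dataclass
class MutationMatrix:
    """Patient x gene binary matrix plus variant-level TP53 columns."""

    gene: pd.DataFrame
    tp53_variant: pd.DataFrame


@dataclass
class SegmentCalls:
    """Patient x segment scores and the derived gain/loss indicators."""

    scores: pd.DataFrame
    gain: pd.DataFrame
    loss: pd.DataFrame
    coverage: pd.DataFrame = field(repr=False, default=None)
    missing_segments: tuple = ()


@dataclass
class FeatureMatrix:
    """Patient x feature values with per-feature category metadata."""

    values: pd.DataFrame
    category: pd.Series
    n_excluded_patients: int = 0

    def select_categories(self, which) -> pd.DataFrame:
        """Subset columns by coarse group name ('clinical', 'rna', 'dna') or
        by fine category name."""
        cats: list[str] = []
        for w in which:
            cats.extend(CATEGORY_GROUPS.get(w, (w,)))
        keep = self.category.isin(cats)
        return self.values.loc[:, keep[keep].index]


# ---------------------------------------------------------------------------
# mutations


def _check_mutation_frame(mutations: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("patient", "gene") if c not in mutations.columns]
    if missing:
        raise ValueError(f"mutation table lacks required columns: {missing}")
    out = mutations.copy()
    for c in MUTATION_COLUMNS:
        if c not in out.columns:
            out[c] = "" if c != "origin" else "somatic"
    return out


def binarize_mutations(
    mutations: pd.DataFrame,
    gene_catalog,
    exclusion_list=(),
    *,
    patients,
    tp53_variant_catalog=None,
) -> MutationMatrix:
    """Binarize somatic mutation records at the gene level.

    A cell is 1 iff the patient carries at least one retained somatic record
    for the gene.  Records in genes outside ``gene_catalog`` or inside
    ``exclusion_list`` (known passenger genes) contribute nothing.  TP53
    variant-level indicator columns, keyed by protein change, are built from
    ``tp53_variant_catalog`` (or from all observed somatic TP53 changes when
    the catalog is None).
    """
    gene_catalog = list(gene_catalog)
    if not gene_catalog:
        raise ValueError("gene catalog is empty")
    excl = set(exclusion_list)
    catalog = [g for g in gene_catalog if g not in excl]
    if not catalog:
        raise ValueError("every catalog gene is excluded; empty post-filter catalog")
    patients = pd.Index(patients)
    mut = _check_mutation_frame(mutations)
    unknown = set(mut["patient"]) - set(patients)
    if unknown:
        raise ValueError(f"mutation records for unknown patient ids: {sorted(unknown)[:5]}")
    somatic = mut[mut["origin"].str.lower().eq("somatic") | mut["origin"].eq("")]
    retained = somatic[somatic["gene"].isin(set(catalog))]

    gene_mat = pd.DataFrame(0, index=patients, columns=pd.Index(catalog, name="gene"), dtype=np.int8)
    if len(retained):
        hit = retained[["patient", "gene"]].drop_duplicates()
        gene_mat.values[
            patients.get_indexer(hit["patient"]), gene_mat.columns.get_indexer(hit["gene"])
        ] = 1

    tp53 = somatic[somatic["gene"].eq("TP53") & somatic["protein_change"].ne("")]
    changes = [
        _strip_p(c) for c in (tp53_variant_catalog if tp53_variant_catalog is not None
                              else sorted(tp53["protein_change"].map(_strip_p).unique()))
    ]
    var_mat = pd.DataFrame(
        0, index=patients, columns=pd.Index(changes, name="tp53_variant"), dtype=np.int8
    )
    if len(tp53) and changes:
        obs = tp53.assign(change=tp53["protein_change"].map(_strip_p))
        obs = obs[obs["change"].isin(set(changes))][["patient", "change"]].drop_duplicates()
        var_mat.values[
            patients.get_indexer(obs["patient"]), var_mat.columns.get_indexer(obs["change"])
        ] = 1
    return MutationMatrix(gene=gene_mat, tp53_variant=var_mat)


def _strip_p(change: str) -> str:
    return change[2:] if change.startswith("p.") else change


_MISSENSE_RE = re.compile(r"^[A-Z]\d+[A-Z]$")
_SPLICE_CLASSES = {"splice_site", "splice_region"}
_CLASSIFICATION_MAP = {
    "missense_mutation": "missense",
    "nonsense_mutation": "nonsense",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "in_frame_del": "in-frame",
    "in_frame_ins": "in-frame",
    "splice_site": "splice site",
    "splice_region": "splice site",
}


def classify_tp53_variant(protein_change: str, variant_classification: str = "") -> str:
    """Assign a TP53 variant to one of six functional classes.

    Rules, in order: splice calls come from the classification field (splice
    variants rarely carry a protein notation); a trailing ``*`` (stop gain)
    is nonsense; ``fs`` is frameshift; in-frame insertions/deletions/
    duplications are in-frame; a simple substitution is missense.  Anything
    unparseable falls back to the classification field, else to ``other``
    with a warning (never a silent drop).
    """
    cls = (variant_classification or "").strip().lower()
    if cls in _SPLICE_CLASSES:
        return "splice site"
    change = _strip_p((protein_change or "").strip())
    if change:
        if "splice" in change.lower():
            return "splice site"
        if change.endswith("*"):
            return "nonsense"
        if "fs" in change:
            return "frameshift"
        if any(tag in change for tag in ("del", "ins", "dup")):
            return "in-frame"
        if _MISSENSE_RE.match(change):
            return "missense"
    if cls in _CLASSIFICATION_MAP:
        return _CLASSIFICATION_MAP[cls]
    warnings.warn(
        f"unclassifiable TP53 variant (protein_change={protein_change!r}, "
        f"classification={variant_classification!r}); assigned 'other'"
    )
    return "other"


_GERMLINE_QUALIFYING = {"pathogenic", "likely_pathogenic", "likely pathogenic"}
_SOMATIC_QUALIFYING = {"oncogenic", "likely_oncogenic", "likely oncogenic"}


def hrd_status(calls: pd.DataFrame, *, patients) -> pd.Series:
    """Composite homologous-recombination-deficiency flag.

    1 iff the patient carries at least one germline pathogenic / likely
    pathogenic or somatic oncogenic / likely oncogenic call in BRCA1, BRCA2
    or PALB2.  Calls in other genes are ignored with a warning.
    """
    patients = pd.Index(patients)
    calls = _check_mutation_frame(calls)
    other = set(calls["gene"]) - set(HRD_GENES)
    if other:
        warnings.warn(f"ignoring HRD calls in non-HRD genes: {sorted(other)[:5]}")
    calls = calls[calls["gene"].isin(HRD_GENES)]
    label = calls["pathogenicity"].str.lower().str.strip()
    origin = calls["origin"].str.lower().str.strip()
    qualifies = (origin.eq("germline") & label.isin(_GERMLINE_QUALIFYING)) | (
        origin.eq("somatic") & label.isin(_SOMATIC_QUALIFYING)
    )
    flagged = set(calls.loc[qualifies, "patient"])
    return pd.Series(
        [1 if p in flagged else 0 for p in patients], index=patients, dtype=np.int8, name="hrd"
    )


# ---------------------------------------------------------------------------
# copy number


def log2_ratio(nAraw, nBraw, ploidy):
    """Ploidy-corrected log2 copy-number ratio: log2((nA + nB) / ploidy)."""
    nAraw = np.asarray(nAraw, dtype=float)
    nBraw = np.asarray(nBraw, dtype=float)
    ploidy = np.asarray(ploidy, dtype=float)
    total = nAraw + nBraw
    if np.any(total <= 0):
        raise ValueError("total copy number must be positive (log undefined at 0)")
    if np.any(ploidy <= 0):
        raise ValueError("ploidy must be positive")
    out = np.log2(total / ploidy)
    return float(out) if out.ndim == 0 else out


def call_gain_loss(score, *, gain: float = GAIN_THRESHOLD, loss: float = LOSS_THRESHOLD) -> str:
    """Call one segment score: gain iff score > 0.3, loss iff score < -0.3
    (strict inequalities; a score exactly at the threshold is neutral)."""
    if not np.isfinite(score):
        raise ValueError("segment score must be finite")
    if score > gain:
        return "gain"
    if score < loss:
        return "loss"
    return "neutral"


def collapse_segments(
    gene_scores: pd.DataFrame,
    segments,
    *,
    gain: float = GAIN_THRESHOLD,
    loss: float = LOSS_THRESHOLD,
) -> SegmentCalls:
    """Collapse gene-level copy-number scores to segment-level calls.

    ``gene_scores`` is patients x genes.  Each segment score is the
    arithmetic mean of its member genes' scores; genes absent from the
    matrix are skipped and reported in the coverage table, and a segment
    with no present genes is dropped and flagged.
    """
    if isinstance(segments, dict):
        segments = [SegmentDefinition(k, tuple(v)) for k, v in segments.items()]
    ids = [s.segment_id for s in segments]
    if len(set(ids)) != len(ids):
        raise ValueError("segment ids are not unique")
    present_cols = set(gene_scores.columns)
    scores = {}
    cov_rows = []
    missing = []
    for seg in segments:
        members = [g for g in seg.genes if g in present_cols]
        cov_rows.append((seg.segment_id, len(members), len(seg.genes)))
        if not members:
            missing.append(seg.segment_id)
            continue
        scores[seg.segment_id] = gene_scores[members].mean(axis=1)
    if missing:
        warnings.warn(f"{len(missing)} segments had no genes in the matrix and were dropped")
    score_df = pd.DataFrame(scores, index=gene_scores.index)
    coverage = pd.DataFrame(cov_rows, columns=["segment", "genes_present", "genes_total"])
    gain_df = (score_df > gain).astype(np.int8)
    loss_df = (score_df < loss).astype(np.int8)
    return SegmentCalls(
        scores=score_df,
        gain=gain_df,
        loss=loss_df,
        coverage=coverage,
        missing_segments=tuple(missing),
    )


# ---------------------------------------------------------------------------
# expression


def normalize_expression(raw: pd.DataFrame, *, target_quartile: float = 1000.0) -> pd.DataFrame:
    """Upper-quartile normalize raw counts, then log2(x + 1).

    ``raw`` is genes x samples.  Each sample is scaled so that the 75th
    percentile of its non-zero entries equals ``target_quartile`` (the fixed
    constant is a configuration value), after which the log2 pseudo-count
    transform is applied.  Zero entries stay exactly zero.
    """
    if (raw.to_numpy() < 0).any():
        raise ValueError("raw counts must be non-negative")
    out = {}
    for col in raw.columns:
        x = raw[col].to_numpy(dtype=float)
        nz = x[x > 0]
        if nz.size == 0:
            raise ValueError(f"sample {col!r} is all zeros; cannot normalize")
        uq = np.percentile(nz, 75)
        out[col] = np.log2(x * (target_quartile / uq) + 1.0)
    return pd.DataFrame(out, index=raw.index)


def score_signatures(
    expr: pd.DataFrame,
    signatures,
    *,
    center: bool = True,
) -> pd.DataFrame:
    """Score expression signatures and median-center them across the cohort.

    ``expr`` is genes x samples; the result is patients x signatures.  Each
    signature is scored by its declared method (default: median over member
    genes); signatures with no genes present are dropped with a warning.
    After scoring, each signature is median-centered across the analysis
    cohort (disable with ``center=False``).
    """
    if isinstance(signatures, dict):
        signatures = [
            s if isinstance(s, SignatureDefinition) else SignatureDefinition(k, tuple(s))
            for k, s in signatures.items()
        ]
    present = set(expr.index)
    cols = {}
    dropped = []
    for sig in signatures:
        keep = [i for i, g in enumerate(sig.genes) if g in present]
        if not keep:
            dropped.append(sig.signature_id)
            continue
        sub = expr.loc[[sig.genes[i] for i in keep]]
        if sig.method == "median":
            vals = sub.median(axis=0)
        elif sig.method == "weighted-mean":
            w = np.asarray([sig.weights[i] for i in keep], dtype=float)
            vals = pd.Series(
                (sub.to_numpy() * w[:, None]).sum(axis=0) / w.sum(), index=sub.columns
            )
        else:  # centroid-correlation
            c = np.asarray([sig.centroid[i] for i in keep], dtype=float)
            m = sub.to_numpy()
            mc = m - m.mean(axis=0)
            cc = c - c.mean()
            denom = np.sqrt((mc**2).sum(axis=0) * (cc**2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = pd.Series(
                    np.where(denom > 0, (mc * cc[:, None]).sum(axis=0) / denom, 0.0),
                    index=sub.columns,
                )
        cols[sig.signature_id] = vals
    if dropped:
        warnings.warn(f"{len(dropped)} signatures had no genes present and were dropped")
    mat = pd.DataFrame(cols)  # patients x signatures
    if center:
        mat = mat - mat.median(axis=0)
    return mat


def zscale_gene(values_by_dataset) -> pd.Series:
    """Z-scale one gene's expression within each dataset, then concatenate.

    Removes dataset-level location/scale (a crude batch correction) before
    expression values from different platforms are pooled.
    """
    pieces = []
    for name, vals in dict(values_by_dataset).items():
        v = pd.Series(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"dataset {name!r} has fewer than 2 values")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"dataset {name!r} has zero variance; cannot z-scale")
        pieces.append((v - v.mean()) / sd)
    return pd.concat(pieces)


# ---------------------------------------------------------------------------
# assembly and filters


def assemble_features(
    clinical: pd.DataFrame,
    mutation_matrix: MutationMatrix,
    segment_calls: SegmentCalls,
    signatures: pd.DataFrame,
) -> FeatureMatrix:
    """Assemble the candidate feature matrix from all platforms.

    Patients are restricted to the intersection with complete data on every
    platform (the number excluded is reported on the result).  Columns are
    namespaced by category:  ``stage``, ``sig:*``, ``mut:*``, ``tp53:*``,
    ``gain:*``, ``loss:*`` — so the total column count is
    1 + |signatures| + |mutation genes| + |TP53 variants| + 2 |segments|.
    """
    if "stage" not in clinical.columns:
        raise ValueError("clinical table must have a 'stage' column")
    sets = [
        set(clinical.index),
        set(mutation_matrix.gene.index),
        set(segment_calls.gain.index),
        set(signatures.index),
    ]
    common = set.intersection(*sets)
    if not common:
        raise ValueError("no patients with complete data on every platform")
    n_excluded = len(set.union(*sets)) - len(common)
    patients = pd.Index([p for p in clinical.index if p in common])

    stage = clinical.loc[patients, "stage"]
    if stage.dtype == object:
        stage = stage.map({"II": 0, "III": 1})
        if stage.isna().any():
            raise ValueError("stage column must be II/III or 0/1")
    blocks = [
        (pd.DataFrame({"stage": stage.astype(float)}), "clinical"),
        (signatures.loc[patients].add_prefix("sig:"), "rna_signature"),
        (mutation_matrix.gene.loc[patients].add_prefix("mut:").astype(float), "gene_mutation"),
        (
            mutation_matrix.tp53_variant.loc[patients].add_prefix("tp53:").astype(float),
            "tp53_variant",
        ),
        (segment_calls.gain.loc[patients].add_prefix("gain:").astype(float), "cn_gain"),
        (segment_calls.loss.loc[patients].add_prefix("loss:").astype(float), "cn_loss"),
    ]
    values = pd.concat([b for b, _ in blocks], axis=1)
    if values.columns.duplicated().any():
        raise ValueError("duplicate feature names after namespacing")
    if values.isna().any().any():
        raise ValueError("assembled features contain missing values")
    category = pd.Series(
        np.concatenate([[cat] * b.shape[1] for b, cat in blocks]), index=values.columns
    )
    return FeatureMatrix(values=values, category=category, n_excluded_patients=n_excluded)


def filter_sparse(
    matrix: pd.DataFrame, training_ids=None, threshold: float = 0.05
) -> pd.DataFrame:
    """Drop features that are non-zero in <= ``threshold`` of training samples.

    The boundary is inclusive: at n=100 a feature with exactly 5 non-zero
    training values is removed, one with 6 is kept.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    train = matrix if training_ids is None else matrix.loc[training_ids]
    frac = (train != 0).mean(axis=0)
    keep = frac > threshold
    if not keep.any():
        raise ValueError("sparse filter removed every feature")
    return matrix.loc[:, keep[keep].index]


def dedup_perfect_correlation(matrix: pd.DataFrame, training_ids=None) -> pd.DataFrame:
    """Keep one representative of each perfectly correlated feature group.

    Zero-variance features are removed first; then, among features with
    |Pearson r| = 1 on the training samples (within 1e-12), only the first
    in column order survives.  Anti-correlated duplicates (r = -1) carry the
    same information for a linear model and are deduplicated too.
    """
    train = matrix if training_ids is None else matrix.loc[training_ids]
    X = train.to_numpy(dtype=float)
    sd = X.std(axis=0)
    varying = sd > 0
    cols = matrix.columns[varying]
    X = X[:, varying]
    if X.shape[1] == 0:
        return matrix.loc[:, cols]
    U = (X - X.mean(axis=0)) / (X.std(axis=0) * np.sqrt(X.shape[0]))
    C = np.abs(U.T @ U)
    p = C.shape[0]
    keep = np.ones(p, dtype=bool)
    for j in range(1, p):
        if np.any(C[j, :j][keep[:j]] >= 1.0 - 1e-12):
            keep[j] = False
    return matrix.loc[:, cols[keep]]
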