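"""Readers and writers for the pipeline's plain-text formats.

Matrices are TSV with patients as columns by convention; orientation is
auto-detected against the clinical table's patient ids when possible.
Mutations use a MAF dialect (tab-separated; only gene symbol, sample
barcode, variant classification and protein change are consumed).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_maf",
    "read_matrix",
    "read_clinical",
    "read_segments",
    "read_signatures",
    "read_gene_catalog",
]

_MAF_REQUIRED = ["Hugo_Symbol", "Tumor_Sample_Barcode"]
_MAF_OPTIONAL = {
    "Variant_Classification": "variant_classification",
    "HGVSp_Short": "protein_change",
    "Mutation_Status": "origin",
    "Pathogenicity": "pathogenicity",
}


def read_maf(path) -> pd.DataFrame:
    """Read a MAF-dialect mutation table into the internal record format.

    Unknown Variant_Classification strings are preserved verbatim; a
    header-only file yields an empty record set.
    """
    maf = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in _MAF_REQUIRED if c not in maf.columns]
    if missing:
        raise ValueError(f"MAF file {path} lacks required column(s): {missing}")
    out = pd.DataFrame(
        {"patient": maf["Tumor_Sample_Barcode"], "gene": maf["Hugo_Symbol"]}
    )
    for src, dst in _MAF_OPTIONAL.items():
        out[dst] = maf[src] if src in maf.columns else ""
    out["origin"] = out["origin"].str.lower().replace("", "somatic")
    return out


def read_matrix(path, patients=None, orientation: str | None = None) -> pd.DataFrame:
    """Read a rectangular TSV matrix, returned with patients as columns.

    ``orientation`` may be 'patients_cols' or 'patients_rows'; when omitted
    it is auto-detected from the overlap of the header / index with
    ``patients``.  Ambiguity (or no patient ids to compare against) raises
    an error demanding the hint.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.isna().any().any():
        raise ValueError(f"matrix {path} has missing values (ragged rows?)")
    if orientation is None:
        if patients is None:
            raise ValueError("orientation hint required when no patient ids are given")
        pset = set(patients)
        col_hits = len(pset & set(mat.columns))
        row_hits = len(pset & set(mat.index))
        if col_hits > row_hits:
            orientation = "patients_cols"
        elif row_hits > col_hits:
            orientation = "patients_rows"
        else:
            raise ValueError(
                f"cannot auto-detect orientation of {path}; pass orientation="
                "'patients_cols' or 'patients_rows'"
            )
    if orientation == "patients_rows":
        mat = mat.T
    elif orientation != "patients_cols":
        raise ValueError(f"unknown orientation {orientation!r}")
    return mat


def read_clinical(path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("dataset", "stage"):
        if col not in clin.columns:
            raise ValueError(f"clinical table lacks required column {col!r}")
    return clin


def read_segments(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_signatures(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_gene_catalog(path) -> dict:
    with open(path) as fh:
        cat = json.load(fh)
    if "mutation_genes" not in cat:
        raise ValueError(f"gene catalog {path} lacks 'mutation_genes'")
    cat.setdefault("tp53_variants", None)
    cat.setdefault("tp53_classes", {})
    return cat


def exists_or_error(path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p
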