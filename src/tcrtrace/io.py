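"""Readers and writers for the external formats the pipeline consumes.

Expression matrices travel as the Cell Ranger filtered-matrix triplet
(``matrix.mtx`` in Matrix Market coordinate form, genes x cells on disk, with
``barcodes.tsv`` / ``features.tsv`` sidecars); in memory everything is an
:class:`anndata.AnnData` with cells as rows. V(D)J chains use the 10x
``filtered_contig_annotations.csv`` dialect, and the epitope reference is a
VDJdb-style TSV.
"""

from __future__ import annotations

import logging
import os

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

log = logging.getLogger(__name__)

CHAIN_LOCI = ("TRA", "TRB", "TRG", "TRD")


class FormatError(ValueError):
    """A file did not match the expected dialect; the message names it."""


def read_matrix(path: str, integer: bool = True) -> ad.AnnData:
    """Read a matrix triplet directory into an AnnData (cells x genes).

    ``path`` contains ``matrix.mtx``, ``barcodes.tsv`` and ``features.tsv``.
    The Matrix Market file is genes x cells (10x convention) and is transposed
    on load. With ``integer=True`` fractional entries are a format error.
    """
    mtx = os.path.join(path, "matrix.mtx")
    bpath = os.path.join(path, "barcodes.tsv")
    fpath = os.path.join(path, "features.tsv")
    mat = spio.mmread(mtx)
    barcodes = pd.read_csv(bpath, sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(fpath, sep="\t", header=None)
    if mat.shape[0] != len(features):
        raise FormatError(
            f"{fpath}: {len(features)} features but matrix declares {mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{bpath}: {len(barcodes)} barcodes but matrix declares {mat.shape[1]} columns"
        )
    if not barcodes.is_unique:
        raise FormatError(f"{bpath}: duplicate barcodes")
    data = np.asarray(mat.data)
    if integer and data.size and not np.array_equal(data, np.round(data)):
        raise FormatError(f"{mtx}: non-integer entries in an integer count matrix")
    X = sparse.csr_matrix(mat.T)
    if integer:
        X = X.astype(np.int64)
    var = pd.DataFrame(index=pd.Index(features[0].astype(str), name="gene"))
    if features.shape[1] > 1:
        var["gene_name"] = features[1].astype(str).to_numpy()
    adata = ad.AnnData(X=X, obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")), var=var)
    log.info("read matrix %s: %d cells x %d genes", path, adata.n_obs, adata.n_vars)
    return adata


def write_matrix(adata: ad.AnnData, path: str) -> None:
    """Write the triplet; inverse of :func:`read_matrix` (lossless round-trip)."""
    os.makedirs(path, exist_ok=True)
    X = sparse.csc_matrix(adata.X.T)  # genes x cells on disk
    integer = np.issubdtype(X.dtype, np.integer)
    spio.mmwrite(
        os.path.join(path, "matrix.mtx"),
        X,
        field="integer" if integer else "real",
        precision=None if integer else 10,
    )
    with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
        fh.write("".join(f"{b}\n" for b in adata.obs_names))
    with open(os.path.join(path, "features.tsv"), "w") as fh:
        names = (
            adata.var["gene_name"]
            if "gene_name" in adata.var
            else pd.Series(adata.var_names, index=adata.var_names)
        )
        for g in adata.var_names:
            fh.write(f"{g}\t{names[g]}\tGene Expression\n")


_CONTIG_REQUIRED = ("barcode", "chain", "cdr3", "productive")


def read_contigs(path: str) -> pd.DataFrame:
    """Parse a 10x ``filtered_contig_annotations.csv`` into chain records.

    Keeps one record per productive contig with a non-empty CDR3 on a TR
    locus; columns of the result: barcode, locus, cdr3_aa (uppercase),
    cdr3_nt, v_gene, j_gene.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _CONTIG_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    productive = df["productive"].str.lower().isin(("true", "t", "1"))
    locus_ok = df["chain"].isin(CHAIN_LOCI)
    cdr3 = df["cdr3"].str.strip().str.upper()
    keep = productive & locus_ok & (cdr3 != "") & (cdr3.str.lower() != "none")
    out = pd.DataFrame(
        {
            "barcode": df.loc[keep, "barcode"],
            "locus": df.loc[keep, "chain"],
            "cdr3_aa": cdr3[keep],
            "cdr3_nt": df.loc[keep, "cdr3_nt"] if "cdr3_nt" in df else "",
            "v_gene": df.loc[keep, "v_gene"] if "v_gene" in df else "",
            "j_gene": df.loc[keep, "j_gene"] if "j_gene" in df else "",
        }
    ).reset_index(drop=True)
    log.info("read contigs %s: %d/%d rows kept", path, len(out), len(df))
    return out


def write_contigs(chains: pd.DataFrame, path: str) -> None:
    """Write a chain table in the 10x contig CSV dialect."""
    df = pd.DataFrame(
        {
            "barcode": chains["barcode"],
            "is_cell": "True",
            "contig_id": chains.get("contig_id", chains["barcode"] + "_contig_1"),
            "high_confidence": "True",
            "chain": chains["locus"] if "locus" in chains else chains["chain"],
            "v_gene": chains.get("v_gene", ""),
            "d_gene": "",
            "j_gene": chains.get("j_gene", ""),
            "c_gene": "",
            "full_length": "True",
            "productive": chains.get("productive", "True"),
            "cdr3": chains["cdr3_aa"] if "cdr3_aa" in chains else chains["cdr3"],
            "cdr3_nt": chains.get("cdr3_nt", ""),
            "umis": chains.get("umis", 1),
        }
    )
    df.to_csv(path, index=False)


def read_vdjdb(path: str) -> pd.DataFrame:
    """Load a VDJdb-style TSV of CDR3 <-> epitope records.

    Column names are matched case-insensitively (``cdr3``/``CDR3``,
    ``gene``/``Gene``, ``epitope``/``Epitope``, optional species/MHC columns).
    CDR3 strings are canonicalized to uppercase; duplicate CDR3s with
    different epitopes are all retained (multimap).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    lower = {c.lower(): c for c in df.columns}
    if "cdr3" not in lower:
        raise FormatError(f"{path}: missing CDR3 column")
    gene_col = lower.get("gene")
    epi_col = lower.get("epitope")
    if epi_col is None:
        raise FormatError(f"{path}: missing epitope column")
    out = pd.DataFrame(
        {
            "cdr3_aa": df[lower["cdr3"]].str.strip().str.upper(),
            "locus": df[gene_col].str.strip().str.upper() if gene_col else "",
            "epitope": df[epi_col].str.strip(),
            "species": df[lower["species"]].str.strip() if "species" in lower else "",
        }
    )
    out = out[out["cdr3_aa"] != ""].reset_index(drop=True)
    return out


def write_cohort(
    adata: ad.AnnData, chains: pd.DataFrame, outdir: str, truth: "pd.DataFrame | None" = None
) -> dict:
    """Write one directory per sample (matrix triplet + contig CSV).

    Barcodes are emitted in the raw per-sample form (sample suffix stripped);
    :func:`read_cohort` re-suffixes them, so a write/read cycle round-trips.
    Returns a manifest mapping sample -> paths/labels; the truth table, when
    given, is written as TSV alongside.
    """
    os.makedirs(outdir, exist_ok=True)
    manifest = {}
    for s, sub in adata.obs.groupby("sample", observed=True, sort=True):
        sdir = os.path.join(outdir, str(s))
        sample_cells = adata[sub.index]
        raw = sample_cells.copy()
        raw.obs_names = [b.rsplit("-", 1)[0] for b in raw.obs_names]
        write_matrix(raw, sdir)
        cpath = os.path.join(sdir, "filtered_contig_annotations.csv")
        ch = chains[chains["barcode"].isin(sub.index)].copy()
        ch["barcode"] = ch["barcode"].str.rsplit("-", n=1).str[0]
        write_contigs(ch, cpath)
        manifest[str(s)] = {
            "matrix": sdir,
            "contigs": cpath,
            "tissue": str(sub["tissue"].iloc[0]),
            "disease": str(sub["disease"].iloc[0]),
        }
    if truth is not None:
        truth.to_csv(os.path.join(outdir, "truth_cells.tsv"), sep="\t")
    return manifest


def read_cohort(manifest: dict) -> tuple[ad.AnnData, pd.DataFrame]:
    """Pool per-sample matrices and contig tables into one cohort.

    Barcodes are suffixed with the sample identifier (``{barcode}-{sample}``)
    to disambiguate collisions across pooled libraries; tissue and disease
    labels from the manifest are attached to ``obs``.
    """
    adatas, chain_frames = [], []
    for s in sorted(manifest):
        entry = manifest[s]
        a = read_matrix(entry["matrix"])
        a.obs_names = [f"{b}-{s}" for b in a.obs_names]
        a.obs["sample"] = s
        a.obs["tissue"] = entry["tissue"]
        a.obs["disease"] = entry["disease"]
        adatas.append(a)
        ch = read_contigs(entry["contigs"])
        ch["barcode"] = ch["barcode"] + f"-{s}"
        chain_frames.append(ch)
    if not adatas:
        raise FormatError("empty sample manifest")
    pooled = ad.concat(adatas, join="outer", merge="same") if len(adatas) > 1 else adatas[0]
    pooled.obs_names.name = "barcode"
    chains = pd.concat(chain_frames, ignore_index=True) if chain_frames else pd.DataFrame()
    log.info("pooled cohort: %d cells x %d genes, %d chains", pooled.n_obs, pooled.n_vars, len(chains))
    return pooled, chains
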