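"""Clonotype assignment, expansion statistics, blood<->islet matching,
clone-fate calls, within-clone transition graphs, and epitope annotation.

A clonotype is the equivalence class of cells sharing identical alpha- and
beta-chain CDR3 amino-acid *sets*: cells need at least one productive alpha
and one beta chain to enter the analysis, and cells carrying multiple chains
match only on full set equality. Two cells in different tissues "match" (are
an infiltrating pair) if they share at least one identical alpha OR beta
CDR3; a blood cell matching any islet cell is islet-matching, and vice versa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MATURATION_ORDER = ("naive", "effector", "memory", "SLEC", "Pexh", "Texh")


def _norm_chains(chains: pd.DataFrame) -> pd.DataFrame:
    """Accept either parsed records (locus/cdr3_aa) or the raw 10x contig
    dialect (chain/cdr3/productive); non-productive rows are dropped."""
    df = chains.rename(columns={"chain": "locus", "cdr3": "cdr3_aa"}).copy()
    if "productive" in df.columns:
        prod = df["productive"].astype(str).str.lower().isin(("true", "t", "1"))
        df = df[prod]
    df["cdr3_aa"] = df["cdr3_aa"].astype(str).str.upper()
    return df[df["cdr3_aa"] != ""]


def assign_clonotypes(chains: pd.DataFrame, strict_vj: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group cells into clonotypes by their (alpha-set, beta-set) CDR3 key.

    Parameters
    ----------
    chains : productive chain table with columns barcode, locus, cdr3_aa
        (gamma/delta chains are ignored for the key).
    strict_vj : additionally require identical V/J gene sets per locus.

    Returns
    -------
    clonotypes : one row per clonotype (clonotype_id, alpha, beta as
        ';'-joined sorted sets, size), ordered by decreasing size then key.
    cell_map : one row per included cell (barcode, clonotype_id); cells
        lacking an alpha or a beta chain are excluded.
    """
    chains = _norm_chains(chains)
    ab = chains[chains["locus"].isin(("TRA", "TRB"))]
    keys: dict[str, tuple] = {}
    for bc, grp in ab.groupby("barcode", sort=True):
        alpha = grp.loc[grp["locus"] == "TRA", "cdr3_aa"]
        beta = grp.loc[grp["locus"] == "TRB", "cdr3_aa"]
        if alpha.empty or beta.empty:
            continue  # at least one alpha and one beta chain required
        a_key = tuple(sorted(set(alpha.str.upper())))
        b_key = tuple(sorted(set(beta.str.upper())))
        if strict_vj:
            av = tuple(sorted(set(zip(grp.loc[grp["locus"] == "TRA", "v_gene"],
                                      grp.loc[grp["locus"] == "TRA", "j_gene"]))))
            bv = tuple(sorted(set(zip(grp.loc[grp["locus"] == "TRB", "v_gene"],
                                      grp.loc[grp["locus"] == "TRB", "j_gene"]))))
            keys[bc] = (a_key, b_key, av, bv)
        else:
            keys[bc] = (a_key, b_key)

    groups: dict[tuple, list] = {}
    for bc, key in keys.items():
        groups.setdefault(key, []).append(bc)

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    clono_rows, map_rows = [], []
    for i, (key, members) in enumerate(ordered):
        cid = f"ct{i + 1:05d}"
        clono_rows.append(
            dict(clonotype_id=cid, alpha=";".join(key[0]), beta=";".join(key[1]), size=len(members))
        )
        for bc in members:
            map_rows.append(dict(barcode=bc, clonotype_id=cid))
    clonotypes = pd.DataFrame(clono_rows, columns=["clonotype_id", "alpha", "beta", "size"])
    cell_map = pd.DataFrame(map_rows, columns=["barcode", "clonotype_id"])
    log.info("clonotypes: %d cells -> %d clonotypes", len(cell_map), len(clonotypes))
    return clonotypes, cell_map


def expansion_summary(clonotypes: pd.DataFrame, cell_map: pd.DataFrame | None = None,
                      meta: pd.DataFrame | None = None) -> dict:
    """Expansion statistics over clonotype sizes.

    Reports counts of clonotypes of size 1 (singletons), size >= 3, size > 10,
    the maximum size, and — when per-cell ``meta`` with sample/disease labels
    is given — clones observed in >= 2 samples and clones spanning diabetic
    and non-diabetic samples (restricted to clones of size > 3 for the
    multi-sample tallies, matching how expanded clones are summarised).
    """
    sizes = clonotypes["size"] if len(clonotypes) else pd.Series([], dtype=int)
    out = {
        "n_clonotypes": int(len(sizes)),
        "n_cells": int(sizes.sum()),
        "singletons": int((sizes == 1).sum()),
        "size_ge3": int((sizes >= 3).sum()),
        "size_gt10": int((sizes > 10).sum()),
        "max_size": int(sizes.max()) if len(sizes) else 0,
        "multi_sample_clones": 0,
        "cross_disease_clones": 0,
    }
    if cell_map is not None and meta is not None and len(cell_map):
        df = cell_map.merge(meta[["sample", "disease"]], left_on="barcode", right_index=True)
        expanded = set(clonotypes.loc[clonotypes["size"] > 3, "clonotype_id"])
        grp = df[df["clonotype_id"].isin(expanded)].groupby("clonotype_id")
        out["multi_sample_clones"] = int((grp["sample"].nunique() >= 2).sum())
        out["cross_disease_clones"] = int((grp["disease"].nunique() >= 2).sum())
    return out


def match_tissues(clonotypes: pd.DataFrame, cell_map: pd.DataFrame,
                  tissues: pd.Series) -> tuple[pd.Series, pd.DataFrame]:
    """Flag infiltrating cells by shared alpha OR beta CDR3 across tissues.

    Parameters
    ----------
    tissues : per-barcode tissue label (``blood`` / ``islet``), covering every
        cell in ``cell_map``.

    Returns
    -------
    flags : boolean Series over the barcodes of ``cell_map``; True for a blood
        cell matching >= 1 islet cell or an islet cell matching >= 1 blood
        cell.
    matched : one row per cross-tissue-shared chain (locus, cdr3_aa,
        clonotype ids carrying it, per-tissue cell counts).
    """
    df = cell_map.merge(clonotypes, on="clonotype_id")
    df["tissue"] = tissues.reindex(df["barcode"]).to_numpy()
    if df["tissue"].isna().any():
        missing = df.loc[df["tissue"].isna(), "barcode"].head().tolist()
        raise KeyError(f"cells without tissue labels, e.g. {missing}")

    # chain -> tissues and cell counts, via clonotype membership
    chain_cells: dict[tuple, dict] = {}
    chain_clonos: dict[tuple, set] = {}
    for _, row in df.iterrows():
        for locus, col in (("TRA", "alpha"), ("TRB", "beta")):
            for aa in str(row[col]).split(";"):
                if not aa:
                    continue
                key = (locus, aa)
                chain_cells.setdefault(key, {}).setdefault(row["tissue"], 0)
                chain_cells[key][row["tissue"]] += 1
                chain_clonos.setdefault(key, set()).add(row["clonotype_id"])

    shared = {k for k, t in chain_cells.items() if len(t) > 1}

    flags = pd.Series(False, index=pd.Index(df["barcode"], name="barcode"))
    for i, row in df.iterrows():
        own = row["tissue"]
        for locus, col in (("TRA", "alpha"), ("TRB", "beta")):
            for aa in str(row[col]).split(";"):
                key = (locus, aa)
                if not aa or key not in shared:
                    continue
                others = sum(n for t, n in chain_cells[key].items() if t != own)
                if others > 0:
                    flags.iloc[df.index.get_loc(i)] = True
    matched_rows = [
        dict(
            locus=locus, cdr3_aa=aa,
            clonotypes=";".join(sorted(chain_clonos[(locus, aa)])),
            **{f"n_{t}": n for t, n in sorted(chain_cells[(locus, aa)].items())},
        )
        for locus, aa in sorted(shared)
    ]
    matched = pd.DataFrame(matched_rows, columns=["locus", "cdr3_aa", "clonotypes", "n_blood", "n_islet"])
    log.info("matching: %d infiltrating cells, %d shared chains", int(flags.sum()), len(matched))
    return flags, matched


def match_tissues_bruteforce(clonotypes: pd.DataFrame, cell_map: pd.DataFrame,
                             tissues: pd.Series) -> pd.Series:
    """O(n^2) all-pairs comparison; the independent oracle for
    :func:`match_tissues` on small cohorts."""
    df = cell_map.merge(clonotypes, on="clonotype_id")
    df["tissue"] = tissues.reindex(df["barcode"]).to_numpy()
    chain_sets = [
        {("TRA", aa) for aa in str(r.alpha).split(";") if aa}
        | {("TRB", aa) for aa in str(r.beta).split(";") if aa}
        for r in df.itertuples()
    ]
    t = df["tissue"].to_numpy()
    n = len(df)
    flags = np.zeros(n, bool)
    for i in range(n):
        for j in range(i + 1, n):
            if t[i] != t[j] and chain_sets[i] & chain_sets[j]:
                flags[i] = flags[j] = True
    return pd.Series(flags, index=pd.Index(df["barcode"], name="barcode"))


def classify_clone_fate(clonotypes: pd.DataFrame, cell_map: pd.DataFrame, states: pd.Series,
                        slec_states=("SLEC",), texh_states=("Texh",)) -> pd.Series:
    """Fate of each clonotype from its members' states.

    ``SLEC_only`` if >= 1 member sits in a SLEC state and none in a Texh
    state, ``Texh_only`` symmetrically, ``mixed`` when both occur, ``other``
    when neither. Raises on unlabeled member cells.
    """
    st = states.reindex(cell_map["barcode"])
    if st.isna().any():
        missing = cell_map.loc[st.isna().to_numpy(), "barcode"].head().tolist()
        raise ValueError(f"unlabeled member cells, e.g. {missing}")
    df = pd.DataFrame({"clonotype_id": cell_map["clonotype_id"].to_numpy(), "state": st.to_numpy()})
    slec = df.groupby("clonotype_id")["state"].agg(lambda s: s.isin(slec_states).any())
    texh = df.groupby("clonotype_id")["state"].agg(lambda s: s.isin(texh_states).any())
    fate = pd.Series("other", index=slec.index, name="fate")
    fate[slec & ~texh] = "SLEC_only"
    fate[texh & ~slec] = "Texh_only"
    fate[slec & texh] = "mixed"
    return fate.reindex(clonotypes["clonotype_id"]).fillna("other")


@dataclass
class TransitionGraph:
    """State-pair transition likelihoods averaged over eligible clones.

    ``edges`` has one row per unordered state pair observed in any eligible
    clone: state_a, state_b (state_a <= state_b in maturation order),
    likelihood (mean over clones of the per-clone pair fraction, in [0, 1])
    and same_compartment. Per-clone likelihoods over all pairs sum to 1.
    """

    nodes: list
    edges: pd.DataFrame
    n_clones: int
    per_clone: dict = field(default_factory=dict, repr=False)


def _aggregate(per_clone: dict, nodes: list, compartment_of) -> TransitionGraph:
    node_rank = {s: i for i, s in enumerate(nodes)}
    all_pairs = sorted({p for d in per_clone.values() for p in d},
                       key=lambda p: (node_rank.get(p[0], 99), node_rank.get(p[1], 99)))
    rows = []
    n = len(per_clone)
    for a, b in all_pairs:
        mean_l = float(np.mean([d.get((a, b), 0.0) for d in per_clone.values()])) if n else 0.0
        same = (compartment_of.get(a, a) == compartment_of.get(b, b)) if compartment_of else True
        rows.append(dict(state_a=a, state_b=b, likelihood=mean_l, same_compartment=same))
    edges = pd.DataFrame(rows, columns=["state_a", "state_b", "likelihood", "same_compartment"])
    return TransitionGraph(nodes=list(nodes), edges=edges, n_clones=n, per_clone=per_clone)


def _clone_states(cell_map: pd.DataFrame, states: pd.Series, min_size_exclusive: int):
    st = states.reindex(cell_map["barcode"])
    if st.isna().any():
        raise ValueError("unlabeled member cells in transition analysis")
    df = pd.DataFrame({"clonotype_id": cell_map["clonotype_id"].to_numpy(), "state": st.to_numpy()})
    for cid, grp in df.groupby("clonotype_id"):
        if len(grp) > min_size_exclusive:
            yield cid, grp["state"].to_numpy()


def _pair_key(a: str, b: str, rank: dict) -> tuple:
    return (a, b) if rank.get(a, 99) <= rank.get(b, 99) else (b, a)


def exact_transitions(cell_map: pd.DataFrame, states: pd.Series,
                      min_clone_size_exclusive: int = 3,
                      nodes=MATURATION_ORDER, compartment_of: dict | None = None) -> TransitionGraph:
    """Per-clone state-pair likelihoods by enumerating all C(n,2) unordered
    cell pairs; enumeration oracle for :func:`bootstrap_transitions`."""
    rank = {s: i for i, s in enumerate(nodes)}
    per_clone = {}
    for cid, st in _clone_states(cell_map, states, min_clone_size_exclusive):
        n = len(st)
        total = n * (n - 1) // 2
        counts: dict[tuple, int] = {}
        for i, j in combinations(range(n), 2):
            key = _pair_key(st[i], st[j], rank)
            counts[key] = counts.get(key, 0) + 1
        per_clone[cid] = {k: v / total for k, v in counts.items()}
    if not per_clone:
        warnings.warn("no clone exceeds the minimum size; empty transition graph")
    return _aggregate(per_clone, list(nodes), compartment_of or {})


def bootstrap_transitions(cell_map: pd.DataFrame, states: pd.Series, n_reps: int = 100,
                          min_clone_size_exclusive: int = 3, seed: int = 0,
                          nodes=MATURATION_ORDER, compartment_of: dict | None = None) -> TransitionGraph:
    """Monte-Carlo version: per eligible clone (size > 3 by default), draw
    ``n_reps`` unordered pairs of distinct cells uniformly; the per-clone
    likelihood of a state pair is the fraction of draws selecting it."""
    rng = np.random.default_rng(seed)
    rank = {s: i for i, s in enumerate(nodes)}
    per_clone = {}
    for cid, st in _clone_states(cell_map, states, min_clone_size_exclusive):
        n = len(st)
        counts: dict[tuple, int] = {}
        for _ in range(n_reps):
            i, j = rng.choice(n, size=2, replace=False)
            key = _pair_key(st[i], st[j], rank)
            counts[key] = counts.get(key, 0) + 1
        per_clone[cid] = {k: v / n_reps for k, v in counts.items()}
    if not per_clone:
        warnings.warn("no clone exceeds the minimum size; empty transition graph")
    return _aggregate(per_clone, list(nodes), compartment_of or {})


def annotate_epitopes(clonotypes: pd.DataFrame, vdjdb: pd.DataFrame,
                      cell_map: pd.DataFrame | None = None,
                      tissues: pd.Series | None = None) -> pd.DataFrame:
    """Exact-match CDR3 annotation against a VDJdb-style reference.

    A clonotype is annotated with every epitope whose reference CDR3 equals
    (string equality after uppercase canonicalization) any of its alpha CDR3s
    (reference gene TRA) or beta CDR3s (TRB). With ``cell_map``/``tissues``
    given, per-epitope per-tissue cell counts are included.
    """
    ref: dict[tuple, set] = {}
    for r in vdjdb.itertuples():
        locus = (r.locus or "").upper()
        if locus not in ("TRA", "TRB"):
            continue
        ref.setdefault((locus, r.cdr3_aa.upper()), set()).add(r.epitope)

    sizes = dict(zip(clonotypes["clonotype_id"], clonotypes["size"]))
    tissue_counts = None
    if cell_map is not None and tissues is not None:
        df = cell_map.copy()
        df["tissue"] = tissues.reindex(df["barcode"]).to_numpy()
        tissue_counts = df.groupby(["clonotype_id", "tissue"]).size()

    rows = []
    for r in clonotypes.itertuples():
        hits: dict[str, list] = {}
        for locus, col in (("TRA", r.alpha), ("TRB", r.beta)):
            for aa in str(col).split(";"):
                for epi in ref.get((locus, aa.upper()), ()):  # honour the chain
                    hits.setdefault(epi, []).append(f"{locus}:{aa}")
        for epi, via in sorted(hits.items()):
            row = dict(clonotype_id=r.clonotype_id, epitope=epi, via=";".join(sorted(set(via))),
                       n_cells=sizes[r.clonotype_id])
            if tissue_counts is not None:
                for t in sorted(tissues.dropna().unique()):
                    row[f"n_{t}"] = int(tissue_counts.get((r.clonotype_id, t), 0))
            rows.append(row)
    return pd.DataFrame(rows, columns=None if rows else ["clonotype_id", "epitope", "via", "n_cells"])
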