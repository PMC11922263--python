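"""Synthetic paired expression + TCR-repertoire cohorts with planted ground truth.

The generator emulates the statistical structure of a pooled multi-sample
T-cell study in the NOD mouse: blood and islet samples from diabetic and
non-diabetic animals, a compartment structure (CD4 / CD8 / DN / DP / gamma-delta)
driven by a small marker panel, maturation states (naive -> effector ->
memory / SLEC-like / pre-exhausted / exhausted), a heavy-tailed clone-size
distribution with a controlled number of clones planted in both tissues, and
dropout-prone negative-binomial counts.

Every cell's compartment, state, clone identity and infiltration status are
recorded in a :class:`SimulationTruth` so each downstream stage of the
pipeline can be checked against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

COMPARTMENTS = ("CD4", "CD8", "DN", "DP", "GD")
STATES = ("naive", "effector", "memory", "SLEC", "Pexh", "Texh")

# the 20 proteinogenic amino acids; CDR3s are framed C...F as in productive
# rearrangements
_AA = "ACDEFGHIKLMNPQRSTVWY"

_TRAV = [f"TRAV{i}" for i in (1, 3, 6, 7, 9, 12, 14)] + ["Trav16n", "Trav15d-1", "Trav8d-2", "Trav7-3"]
_TRAJ = [f"TRAJ{i}" for i in (12, 15, 21, 23, 31, 40, 52)]
_TRBV = [f"TRBV{i}" for i in (1, 2, 5, 13, 16, 19)] + ["Trbv29"]
_TRBJ = [f"TRBJ{i}-{j}" for i in (1, 2) for j in (1, 2, 4)]
_TRGV = ["Trgv2"]
_TRGJ = ["TRGJ1"]
_TRDV = ["TRDV2", "TRDV5"]
_TRDJ = ["TRDJ1"]


@dataclass
class MarkerEffect:
    """A gene expressed above background in cells carrying a target label.

    ``targets`` may contain compartment names, state names, the special label
    ``"infiltrating"`` (cells of clones spanning both tissues) or ``"all"``.
    The gene's negative-binomial mean is ``on_scale * fold`` in target cells
    and ``off_mean`` (ambient background) elsewhere; ``off_mean=None`` falls
    back to the config-wide ambient mean.
    """

    gene: str
    targets: frozenset
    fold: float = 2.0
    off_mean: float | None = None
    on_scale: float | None = None

    def __post_init__(self):
        self.targets = frozenset(self.targets)


def default_marker_panel(fold: float = 2.0) -> list[MarkerEffect]:
    """Marker panel mirroring the genes the pipeline gates and classifies on.

    ``fold`` scales the on-state mean of the compartment/state markers; it is
    the knob the gating-recovery experiments turn (1.5x / 2x / 4x).
    """
    m = MarkerEffect
    panel = [
        # pan-T and housekeeping: always on
        m("Cd3e", {"all"}, fold=4.0),
        m("Actb", {"all"}, fold=6.0),
        m("B2m", {"all"}, fold=5.0),
        m("Gapdh", {"all"}, fold=4.0),
        # mitochondrial genome: always on, low -> mito fraction ~2-3%
        m("mt-Nd1", {"all"}, fold=1.0),
        m("mt-Nd2", {"all"}, fold=1.0),
        m("mt-Co1", {"all"}, fold=1.0),
        m("mt-Co2", {"all"}, fold=1.0),
        m("mt-Cytb", {"all"}, fold=1.0),
        # compartment co-receptors
        m("Cd4", {"CD4", "DP"}, fold=fold),
        m("Cd8a", {"CD8", "DP"}, fold=fold),
        m("Cd8b1", {"CD8", "DP"}, fold=fold),
        m("Trgv2", {"GD"}, fold=fold),
        # maturation-state markers
        m("Sell", {"naive"}, fold=fold),
        m("Ccr7", {"naive", "memory"}, fold=fold),
        m("Il7r", {"naive", "memory", "effector"}, fold=fold),
        m("Ifng", {"effector"}, fold=fold),
        m("Tnf", {"effector"}, fold=fold),
        m("Klrg1", {"SLEC"}, fold=fold),
        m("Gzma", {"SLEC"}, fold=fold),
        m("Pdcd1", {"Pexh", "Texh"}, fold=fold),
        m("Tigit", {"Pexh", "Texh"}, fold=fold),
        m("Ctla4", {"Texh"}, fold=fold),
        m("Lag3", {"Texh"}, fold=fold),
        m("Havcr2", {"Texh"}, fold=fold),
        # Th-subset cytokines not planted by default (background only)
        m("Il4", set(), fold=1.0),
        m("Il10", set(), fold=1.0),
        m("Il17a", set(), fold=1.0),
        m("Il22", set(), fold=1.0),
        m("Foxp3", set(), fold=1.0),
    ]
    # moderate transcriptional program of tissue-crossing (infiltrating)
    # clones: a 2-fold bump on genes expressed by every T cell, giving the
    # classifier real but imperfect signal
    for g in ("Ccl5", "Nkg7", "Klrd1", "Lgals1", "S100a6", "Crip1", "Vim", "Id2", "Ly6c2", "Cxcr6"):
        panel.append(m(g, {"infiltrating"}, fold=2.0, off_mean=1.0, on_scale=1.0))
    return panel


def _default_states() -> dict:
    return {
        "CD4": {"naive": 0.30, "effector": 0.30, "memory": 0.20, "SLEC": 0.0, "Pexh": 0.10, "Texh": 0.10},
        "CD8": {"naive": 0.25, "effector": 0.25, "memory": 0.15, "SLEC": 0.15, "Pexh": 0.10, "Texh": 0.10},
        "DN": {"naive": 0.30, "effector": 0.30, "memory": 0.20, "SLEC": 0.0, "Pexh": 0.10, "Texh": 0.10},
        "DP": {"naive": 0.80, "effector": 0.20, "memory": 0.0, "SLEC": 0.0, "Pexh": 0.0, "Texh": 0.0},
        "GD": {"naive": 0.40, "effector": 0.40, "memory": 0.20, "SLEC": 0.0, "Pexh": 0.0, "Texh": 0.0},
    }


def _default_samples(n: int) -> tuple[dict, dict]:
    """Alternate blood/islet samples; islets only from diabetic mice, as in a
    cohort where non-diabetic islets yield too few T cells to sequence."""
    tissue, disease = {}, {}
    for i in range(n):
        name = f"S{i + 1}"
        if i % 2 == 0:
            tissue[name] = "blood"
            disease[name] = "diabetic" if (i // 2) % 2 == 0 else "nondiabetic"
        else:
            tissue[name] = "islet"
            disease[name] = "diabetic"
    return tissue, disease


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the study conditions the pipeline is exercised under:
    six pooled samples, ~33% DN T cells, negative-binomial counts
    (dispersion theta=4) with 3% independent dropout, a discrete power-law
    clone-size tail (exponent 2.5, truncated at 75 cells) and 50 clones
    planted in both blood and islets.
    """

    n_samples: int = 6
    cells_per_sample: int = 400
    tissue_of_sample: dict = None
    disease_of_sample: dict = None
    compartment_fractions: dict = field(
        default_factory=lambda: {"CD4": 0.30, "CD8": 0.25, "DN": 0.33, "DP": 0.04, "GD": 0.08}
    )
    state_fractions_per_compartment: dict = field(default_factory=_default_states)
    marker_panel: list = None
    marker_fold: float = 2.0
    baseline_mean: float = 0.3
    ambient_mean: float = 0.03
    marker_on_scale: float = 2.0
    dispersion: float = 4.0
    dropout_rate: float = 0.03
    n_genes: int = 1200
    clone_size_alpha: float = 2.5
    max_clone_size: int = 75
    shared_clone_count: int = 50
    paired_chain_rate: float = 0.92
    chain_capture_rate: float = 0.95
    multi_alpha_rate: float = 0.12
    seed: int = 0

    def __post_init__(self):
        if self.tissue_of_sample is None or self.disease_of_sample is None:
            t, d = _default_samples(self.n_samples)
            self.tissue_of_sample = self.tissue_of_sample or t
            self.disease_of_sample = self.disease_of_sample or d
        if self.marker_panel is None:
            self.marker_panel = default_marker_panel(self.marker_fold)
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 1 or self.cells_per_sample < 1:
            raise ValueError("n_samples and cells_per_sample must be positive")
        _check_simplex(self.compartment_fractions, COMPARTMENTS, "compartment_fractions")
        for comp, fr in self.state_fractions_per_compartment.items():
            _check_simplex(fr, STATES, f"state_fractions[{comp}]")
        for p, name in [
            (self.dropout_rate, "dropout_rate"),
            (self.paired_chain_rate, "paired_chain_rate"),
            (self.chain_capture_rate, "chain_capture_rate"),
            (self.multi_alpha_rate, "multi_alpha_rate"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        for v, name in [
            (self.baseline_mean, "baseline_mean"),
            (self.dispersion, "dispersion"),
            (self.clone_size_alpha, "clone_size_alpha"),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_genes < len(self.marker_panel):
            raise ValueError("n_genes smaller than marker panel")
        tissues = set(self.tissue_of_sample.values())
        if self.shared_clone_count > 0 and not {"blood", "islet"} <= tissues:
            raise ValueError("shared clones require both blood and islet samples")


def _check_simplex(fractions: dict, keys, name: str) -> None:
    extra = set(fractions) - set(keys)
    if extra:
        raise ValueError(f"{name}: unknown labels {sorted(extra)}")
    vals = np.array([fractions.get(k, 0.0) for k in keys], float)
    if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a simplex summing to 1, got sum {vals.sum()}")


@dataclass
class SimulationTruth:
    """Planted per-cell and per-clone ground truth.

    ``cells`` is indexed by barcode with columns sample, tissue, disease,
    compartment, state, clone_id (empty string when no chains were captured)
    and infiltrating (True iff the cell's clone spans blood and islet).
    ``clones`` is indexed by clone_id with member counts per tissue and the
    clone's chain sets.
    """

    cells: pd.DataFrame
    clones: pd.DataFrame


def _rand_cdr3(rng: np.random.Generator, used: set) -> str:
    while True:
        n = int(rng.integers(8, 13))
        s = "C" + "".join(_AA[i] for i in rng.integers(0, len(_AA), n)) + "F"
        if s not in used:
            used.add(s)
            return s


def _rand_nt(rng: np.random.Generator, aa: str) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, 3 * len(aa)))


def _power_law_sizes(rng: np.random.Generator, alpha: float, smax: int, total: int) -> list[int]:
    """Draw clone sizes from P(s) ~ s^-alpha on {1..smax} until `total` cells
    are used; the last clone is truncated to fit exactly."""
    support = np.arange(1, smax + 1)
    p = support.astype(float) ** -alpha
    p /= p.sum()
    sizes, used = [], 0
    while used < total:
        s = int(rng.choice(support, p=p))
        s = min(s, total - used)
        sizes.append(s)
        used += s
    return sizes


def generate_cohort(config: SimulationConfig) -> tuple[ad.AnnData, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate one cohort.

    Returns
    -------
    adata : AnnData (cells x genes, raw integer counts in ``X``) with sample,
        tissue and disease in ``obs``.
    meta : the per-cell metadata frame (``adata.obs``, for convenience).
    chains : productive-chain table in the 10x contig dialect (one row per
        chain) for cells whose TCR was captured.
    truth : :class:`SimulationTruth` with planted labels.

    Deterministic given ``config.seed``: the same config yields byte-identical
    outputs.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    samples = list(cfg.tissue_of_sample)

    # ---- per-cell sample / barcode scaffold -------------------------------
    rows = []
    for s in samples:
        for _ in range(cfg.cells_per_sample):
            bc = "".join("ACGT"[i] for i in rng.integers(0, 4, 16))
            rows.append((f"{bc}-{s}", s, cfg.tissue_of_sample[s], cfg.disease_of_sample[s]))
    cells = pd.DataFrame(rows, columns=["barcode", "sample", "tissue", "disease"]).set_index("barcode")
    if not cells.index.is_unique:  # pragma: no cover - 4^16 space
        raise RuntimeError("barcode collision in simulation")
    n_cells = len(cells)

    # ---- clone structure ---------------------------------------------------
    # Chains are captured for a subset of cells; clone identifiers partition
    # exactly the captured cells. GD cells carry gamma/delta chains and can
    # never match across tissues, so shared clones are planted among
    # alpha/beta cells only.
    captured = rng.random(n_cells) < cfg.chain_capture_rate
    cells["captured"] = captured

    comp_names = list(COMPARTMENTS)
    comp_p = np.array([cfg.compartment_fractions.get(c, 0.0) for c in comp_names])

    clone_id = np.full(n_cells, "", dtype=object)
    compartment = np.full(n_cells, "", dtype=object)
    order = np.arange(n_cells)

    pools = {}  # sample -> list of captured cell indices not yet in a clone
    for si, s in enumerate(samples):
        lo, hi = si * cfg.cells_per_sample, (si + 1) * cfg.cells_per_sample
        pools[s] = [int(i) for i in order[lo:hi] if captured[i]]

    clones = []  # dicts: id, compartment, cdr3 sets, member idx
    used_cdr3: set = set()
    next_id = 1

    def new_clone(comp: str, members: list[int], shared: bool) -> None:
        nonlocal next_id
        cid = f"clone_{next_id:05d}"
        next_id += 1
        if comp == "GD":
            alpha = beta = ()
            gamma = (_rand_cdr3(rng, used_cdr3),)
            delta = (_rand_cdr3(rng, used_cdr3),)
        else:
            n_a = 2 if rng.random() < cfg.multi_alpha_rate else 1
            alpha = tuple(sorted(_rand_cdr3(rng, used_cdr3) for _ in range(n_a)))
            beta = (_rand_cdr3(rng, used_cdr3),)
            gamma = delta = ()
        clones.append(
            dict(id=cid, compartment=comp, alpha=alpha, beta=beta, gamma=gamma,
                 delta=delta, members=members, shared=shared)
        )
        for i in members:
            clone_id[i] = cid
            compartment[i] = comp

    # planted cross-tissue clones: alternate over (blood sample, islet sample)
    # pairs, >=1 cell on each side, both chains always captured so the planted
    # flag is recoverable from the data
    blood_s = [s for s in samples if cfg.tissue_of_sample[s] == "blood"]
    islet_s = [s for s in samples if cfg.tissue_of_sample[s] == "islet"]
    ab_comps = [c for c in ("CD4", "CD8", "DN", "DP") if cfg.compartment_fractions.get(c, 0)]
    if cfg.shared_clone_count > 0 and not ab_comps:
        raise ValueError("shared clones need a nonzero alpha/beta compartment fraction")
    support = np.arange(2, cfg.max_clone_size + 1)
    p_shared = support.astype(float) ** -cfg.clone_size_alpha
    p_shared /= p_shared.sum()
    for k in range(cfg.shared_clone_count):
        bs = blood_s[k % len(blood_s)]
        is_ = islet_s[k % len(islet_s)]
        size = int(rng.choice(support, p=p_shared))
        n_blood = int(rng.integers(1, size))
        take_b = min(n_blood, len(pools[bs]), size - 1)
        take_i = min(size - take_b, len(pools[is_]))
        if take_b < 1 or take_i < 1:
            raise ValueError("not enough captured cells to plant shared clones")
        members = [pools[bs].pop() for _ in range(take_b)] + [pools[is_].pop() for _ in range(take_i)]
        comp = ab_comps[int(rng.integers(len(ab_comps)))]
        new_clone(comp, members, shared=True)

    # tissue-private clones fill the remaining captured cells of each sample
    for s in samples:
        pool = pools[s]
        rng.shuffle(pool)
        for size in _power_law_sizes(rng, cfg.clone_size_alpha, cfg.max_clone_size, len(pool)):
            members = [pool.pop() for _ in range(size)]
            comp = comp_names[int(rng.choice(len(comp_names), p=comp_p))]
            new_clone(comp, members, shared=False)

    # cells without captured chains get an independent compartment draw
    free = compartment == ""
    compartment[free] = rng.choice(comp_names, size=int(free.sum()), p=comp_p)

    # ---- states ------------------------------------------------------------
    state = np.empty(n_cells, dtype=object)
    for comp in comp_names:
        mask = compartment == comp
        fr = cfg.state_fractions_per_compartment[comp]
        p = np.array([fr.get(st, 0.0) for st in STATES])
        state[mask] = rng.choice(STATES, size=int(mask.sum()), p=p)

    cells["compartment"] = compartment
    cells["state"] = state
    cells["clone_id"] = clone_id

    shared_ids = {c["id"] for c in clones if c["shared"]}
    cells["infiltrating"] = cells["clone_id"].isin(shared_ids)

    # ---- chain table -------------------------------------------------------
    chain_rows = []
    for c in clones:
        loci = (
            [("TRG", c["gamma"]), ("TRD", c["delta"])]
            if c["compartment"] == "GD"
            else [("TRA", c["alpha"]), ("TRB", c["beta"])]
        )
        for i in c["members"]:
            bc = cells.index[i]
            if c["shared"] or rng.random() < cfg.paired_chain_rate:
                keep = {"TRA", "TRB", "TRG", "TRD"}
            else:  # single-chain cell: exercises the exclusion rule
                keep = {("TRA" if rng.random() < 0.5 else "TRB")}
                if c["compartment"] == "GD":
                    keep = {("TRG" if "TRA" in keep else "TRD")}
            for locus, cdr3s in loci:
                if locus not in keep:
                    continue
                for j, aa in enumerate(cdr3s):
                    v, jj = _vj_genes(rng, locus)
                    chain_rows.append(
                        (bc, f"{bc}_contig_{locus}_{j}", locus, v, jj, aa, _rand_nt(rng, aa), "True", int(rng.integers(2, 60)))
                    )
    chains = pd.DataFrame(
        chain_rows,
        columns=["barcode", "contig_id", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt", "productive", "umis"],
    )

    # ---- expression --------------------------------------------------------
    panel_genes = [m.gene for m in cfg.marker_panel]
    if len(set(panel_genes)) != len(panel_genes):
        raise ValueError("duplicate genes in marker panel")
    n_bg = cfg.n_genes - len(panel_genes)
    genes = panel_genes + [f"Gene{j:04d}" for j in range(n_bg)]

    mean = np.full((n_cells, cfg.n_genes), cfg.baseline_mean)
    infiltrating = cells["infiltrating"].to_numpy()
    for gi, m in enumerate(cfg.marker_panel):
        off = cfg.ambient_mean if m.off_mean is None else m.off_mean
        scale = cfg.marker_on_scale if m.on_scale is None else m.on_scale
        on = scale * m.fold
        if "all" in m.targets:
            mask = np.ones(n_cells, bool)
        else:
            mask = np.zeros(n_cells, bool)
            for t in m.targets:
                if t == "infiltrating":
                    mask |= infiltrating
                elif t in COMPARTMENTS:
                    mask |= compartment == t
                elif t in STATES:
                    mask |= state == t
                else:
                    raise ValueError(f"unknown marker target {t!r}")
        mean[:, gi] = np.where(mask, on, off)

    theta = cfg.dispersion
    lam = rng.gamma(shape=theta, scale=mean / theta)
    counts = rng.poisson(lam)
    if cfg.dropout_rate > 0:
        counts[rng.random(counts.shape) < cfg.dropout_rate] = 0

    adata = ad.AnnData(
        X=sparse.csr_matrix(counts.astype(np.int64)),
        obs=cells[["sample", "tissue", "disease"]].copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )

    clone_rows = []
    for c in clones:
        member_bc = [cells.index[i] for i in c["members"]]
        tissues = sorted(set(cells["tissue"].iloc[c["members"]]))
        clone_rows.append(
            dict(
                clone_id=c["id"],
                compartment=c["compartment"],
                size=len(c["members"]),
                alpha=";".join(c["alpha"]),
                beta=";".join(c["beta"]),
                gamma=";".join(c["gamma"]),
                delta=";".join(c["delta"]),
                tissues=";".join(tissues),
                spans_tissues=len(tissues) > 1,
                barcodes=";".join(member_bc),
            )
        )
    clones_df = pd.DataFrame(clone_rows).set_index("clone_id") if clone_rows else pd.DataFrame(
        columns=["compartment", "size", "alpha", "beta", "gamma", "delta", "tissues", "spans_tissues", "barcodes"]
    )

    truth = SimulationTruth(cells=cells.drop(columns=["captured"]), clones=clones_df)
    return adata, truth.cells, chains, truth


def _vj_genes(rng: np.random.Generator, locus: str) -> tuple[str, str]:
    pools = {"TRA": (_TRAV, _TRAJ), "TRB": (_TRBV, _TRBJ), "TRG": (_TRGV, _TRGJ), "TRD": (_TRDV, _TRDJ)}
    v, j = pools[locus]
    return str(rng.choice(v)), str(rng.choice(j))


def truth_report(truth: SimulationTruth) -> dict[str, pd.DataFrame]:
    """Tally the planted labels for recovery comparisons.

    Returns per-sample compartment counts, per-sample state counts, and the
    clone-size histogram (size -> number of clones).
    """
    cells, clones = truth.cells, truth.clones
    if len(cells) == 0:
        empty = pd.DataFrame()
        return {"compartments": empty, "states": empty, "clone_sizes": pd.DataFrame(columns=["size", "n_clones"])}
    comp = cells.groupby(["sample", "compartment"], observed=True).size().unstack(fill_value=0)
    states = cells.groupby(["sample", "state"], observed=True).size().unstack(fill_value=0)
    if len(clones):
        hist = clones["size"].value_counts().sort_index()
        sizes = pd.DataFrame({"size": hist.index.to_numpy(), "n_clones": hist.to_numpy()})
    else:
        sizes = pd.DataFrame(columns=["size", "n_clones"])
    return {"compartments": comp, "states": states, "clone_sizes": sizes}


def planted_logistic(
    n_cells: int = 1500,
    n_genes: int = 500,
    n_informative: int = 20,
    effect: float = 1.0,
    seed: int = 0,
    intercept: float = 0.0,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Expression-like features with a planted sparse logistic signal.

    ``n_informative`` genes carry log-odds coefficients of magnitude
    ``effect`` (alternating sign); labels are Bernoulli draws from the
    resulting logistic model. Used to characterise the infiltration
    classifier's discrimination and feature recovery.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_cells, n_genes))
    beta = np.zeros(n_genes)
    beta[:n_informative] = effect * np.where(np.arange(n_informative) % 2 == 0, 1.0, -1.0)
    logits = intercept + X @ beta
    y = (rng.random(n_cells) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    genes = [f"Gene{j:04d}" for j in range(n_genes)]
    perm = rng.permutation(n_genes)  # informative genes not all first
    X = X[:, perm]
    names = [genes[i] for i in perm]
    informative = [genes[i] for i in range(n_informative)]
    return pd.DataFrame(X, columns=names), y, informative
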