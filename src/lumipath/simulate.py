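"""Synthetic Smart-seq2-like lineage-conversion datasets with full ground truth.

The generator emulates a basal-to-luminal cell-fate conversion: index-sorted
mammary cells placed along a latent conversion time ``t`` in [0, 1], with
basal genes switching off and luminal genes switching on at heterogeneous
per-gene switch times, a transient "intermediate" gene program peaking
mid-conversion, a proliferative (cell-cycle-high) subpopulation concentrated
at intermediate ``t``, and a minority hormone-receptor-positive (HRpos)
terminal branch that forks the trajectory near its end.  Counts are
negative-binomial with log-normal library sizes and per-gene multiplicative
batch effects; FACS gate labels (basal / intermediate / luminal) are derived
from two surrogate surface-marker genes (Epcam, Itga6) the way an
EpCAM/CD49f sort would assign them.

Every downstream stage of the package is testable against the returned
ground truth: true conversion time, branch, cycling flag, per-gene temporal
program and true regulon activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimConfigError",
    "program_mean",
    "simulate_dataset",
    "assign_facs_gate",
    "TREND_PROGRAMS",
    "PROGRAMS",
]

#: the six temporal expression patterns of the conversion, plus the
#: branch-restricted, cycling and constant programs
TREND_PROGRAMS = (
    "bas_early",
    "bas_late",
    "int_early",
    "int_late",
    "lum_early",
    "lum_late",
)
PROGRAMS = TREND_PROGRAMS + ("hr_pos", "cc", "housekeeping")

STAGES = ("BAS", "INT1", "INT2", "HRneg", "HRpos")

# windows of the latent conversion time each truth stage occupies; the gaps
# between windows make the stages resolvable as clusters, as discrete chase
# timepoints do in the real experiment
STAGE_T_WINDOWS = {
    "BAS": (0.00, 0.22),
    "INT1": (0.30, 0.50),
    "INT2": (0.52, 0.74),
    "LUM": (0.80, 1.00),
}
STAGE_TIMEPOINT_WEEKS = {"BAS": 1, "INT1": 3, "INT2": 4, "HRneg": 6, "HRpos": 6}

_MITO_GENES = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
]

# canonical marker symbols seeded into each program so that marker-based
# cluster naming and FACS surrogates work on simulated data
_CANONICAL = {
    "bas_early": ["Acta2", "Myh11", "Mylk", "Cnn1", "Trp63", "Oxtr", "Myl9"],
    "bas_late": ["Krt5", "Krt14", "Trp73", "Itga6", "Tagln", "Sparc"],
    "int_early": ["Hes1", "Sox4"],
    "int_late": ["Sox9", "Mdk"],
    "lum_early": ["Epcam", "Jun", "Krt8", "Cldn3", "Cldn4", "Wfdc18"],
    "lum_late": ["Krt18", "Krt19", "Stat6", "Elf5", "Kit", "Aldh1a3", "Cd14", "Foxc1"],
    "hr_pos": ["Esr1", "Pgr", "Prlr", "Cited1", "Foxa1", "Areg"],
    "cc_s": ["E2f1", "Brca1", "E2f8", "Mcm2", "Mcm3", "Mcm4", "Mcm5", "Mcm6", "Pcna", "Rrm1"],
    "cc_g2m": ["Mki67", "Top2a", "Ccnb1", "Cdk1", "Aurka", "Plk1", "Cenpa", "Bub1", "Ccna2", "Cdc20"],
    "housekeeping": ["Actb", "Gapdh", "B2m", "Rplp0", "Eef1a1", "Tuba1b"],
}

_SYNTH_PREFIX = {
    "bas_early": "Basge", "bas_late": "Basgl",
    "int_early": "Intge", "int_late": "Intgl",
    "lum_early": "Lumge", "lum_late": "Lumgl",
    "hr_pos": "Hrg", "cc_s": "Ccsg", "cc_g2m": "Ccgg",
    "housekeeping": "Hkg",
}

# regulon sizes drawn from the leading genes of each program; the TF itself
# is a member of its own regulon by convention
_TRUE_REGULON_SPEC = [
    ("Trp63", "bas_early", 25),
    ("Trp73", "bas_late", 25),
    ("Jun", "lum_early", 25),
    ("Stat6", "lum_late", 25),
    ("Foxc1", "lum_late", 15),
    ("Esr1", "hr_pos", 15),
    ("Pgr", "hr_pos", 20),
    ("E2f1", "cc", 25),
    ("Brca1", "cc", 20),
]


class SimConfigError(ValueError):
    """Raised for an infeasible or inconsistent simulator configuration."""


@dataclass
class SimConfig:
    """Configuration of the lineage-conversion simulator.

    Defaults describe the study conditions the package is exercised under:
    ~500 index-sorted cells in 3 batches at Smart-seq2 depth, six temporal
    gene programs with heterogeneous switch times, a proliferative
    mid-conversion subpopulation and a minority HRpos terminal branch.
    """

    n_cells: int = 500
    n_batches: int = 3
    n_bas: int = 120          # split evenly into bas_early / bas_late
    n_lum: int = 120          # split evenly into lum_early / lum_late
    n_int: int = 60           # transient genes, split early / late
    n_hr: int = 60
    n_cc: int = 60            # split evenly into S-phase / G2M halves
    n_housekeeping: int = 2100
    switch_sharpness: float = 12.0
    #: per-program windows from which each gene's switch / peak time τ is drawn
    tau_windows: dict = field(default_factory=lambda: {
        "bas_early": (0.16, 0.28), "bas_late": (0.60, 0.74),
        "lum_early": (0.24, 0.38), "lum_late": (0.68, 0.82),
        "int_early": (0.30, 0.40), "int_late": (0.56, 0.66),
        "hr_pos": (0.60, 0.75),
    })
    nb_dispersion: float = 10.0
    library_size_lognormal: tuple = (math.log(3.0e5), 0.4)
    cycling_fraction_at_mid_t: float = 0.4
    cycling_base_rate: float = 0.02
    batch_effect_sd: float = 0.2
    hr_branch_fraction: float = 0.30
    gfp_neg_fraction: float = 0.25
    mito_level: float = 50.0          # per-mito-gene mean, relative units
    mito_cell_sd: float = 0.35        # per-cell log-normal spread of mito load
    bump_width: float = 0.12          # temporal width of transient programs
    facs_thresholds: tuple | None = None  # (Epcam, Itga6) gate cuts; None = medians
    discrete_timepoints: bool = False  # quantize t to the four chase timepoints
    seed: int = 7

    def validate(self) -> None:
        counts = dict(n_cells=self.n_cells, n_batches=self.n_batches,
                      n_bas=self.n_bas, n_lum=self.n_lum, n_int=self.n_int,
                      n_hr=self.n_hr, n_cc=self.n_cc,
                      n_housekeeping=self.n_housekeeping)
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise SimConfigError(f"{name} must be a count >= 1, got {v!r}")
        for name in ("cycling_fraction_at_mid_t", "cycling_base_rate",
                     "hr_branch_fraction", "gfp_neg_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if not self.nb_dispersion > 0:
            raise SimConfigError("nb_dispersion must be > 0")
        if not self.switch_sharpness > 0:
            raise SimConfigError("switch_sharpness must be > 0")
        if self.batch_effect_sd < 0:
            raise SimConfigError("batch_effect_sd must be >= 0")
        for prog, (lo, hi) in self.tau_windows.items():
            if not (0.0 <= lo <= hi <= 1.0):
                raise SimConfigError(f"tau window for {prog} must satisfy 0<=lo<=hi<=1")
        sizes = {"bas_early": self.n_bas // 2, "bas_late": self.n_bas - self.n_bas // 2,
                 "lum_early": self.n_lum // 2, "lum_late": self.n_lum - self.n_lum // 2,
                 "int_early": self.n_int // 2, "int_late": self.n_int - self.n_int // 2}
        for prog, size in sizes.items():
            if size < 1:
                raise SimConfigError(f"program {prog} has size 0; increase its budget")
        for key, prog, n in _TRUE_REGULON_SPEC:
            avail = {"cc": self.n_cc}.get(prog, sizes.get(prog, self.n_hr))
            if n > avail:
                raise SimConfigError(
                    f"regulon {key} needs {n} genes from program {prog}, "
                    f"but only {avail} are simulated")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


def program_mean(program: str, tau: float, mu_low: float, mu_high: float,
                 k: float, t, *, bump_width: float = 0.12,
                 cycling=False, hr_branch=False):
    """Mean expression (relative units, before library scaling) of one gene.

    Basal programs are decreasing sigmoids centered at ``tau`` with sharpness
    ``k``; luminal programs increasing; intermediate programs Gaussian bumps
    peaking at ``tau``; housekeeping genes are constant at ``mu_high``;
    cell-cycle genes sit at ``mu_low`` plus a bonus to ``mu_high`` in cycling
    cells; hr_pos genes follow an increasing sigmoid only on the HRpos branch.

    Continuous and monotone in ``t`` for basal/luminal programs.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError("conversion time t must lie in [0, 1]")
    if mu_low > mu_high:
        raise ValueError("mu_low must be <= mu_high")
    span = mu_high - mu_low
    if program == "housekeeping":
        return np.broadcast_to(np.asarray(mu_high, dtype=float), t.shape).copy()
    if program == "cc":
        cyc = np.asarray(cycling, dtype=float)
        return mu_low + span * cyc * np.ones_like(t)
    if program in ("bas_early", "bas_late"):
        if np.isinf(k):
            act = (t <= tau).astype(float)
        else:
            act = _sigmoid(-k * (t - tau))
        return mu_low + span * act
    if program in ("lum_early", "lum_late"):
        if np.isinf(k):
            act = (t >= tau).astype(float)
        else:
            act = _sigmoid(k * (t - tau))
        return mu_low + span * act
    if program in ("int_early", "int_late"):
        act = np.exp(-((t - tau) / bump_width) ** 2)
        return mu_low + span * act
    if program == "hr_pos":
        if np.isinf(k):
            act = (t >= tau).astype(float)
        else:
            act = _sigmoid(k * (t - tau))
        branch = np.asarray(hr_branch, dtype=float)
        return mu_low + span * act * branch
    raise ValueError(f"unknown program {program!r}")


def assign_facs_gate(levels: np.ndarray, thresholds) -> np.ndarray:
    """Rectangular 2-D FACS gating on (EpCAM-like, CD49f-like) levels.

    ``levels`` is (n_cells, 2): column 0 the EpCAM surrogate, column 1 the
    CD49f surrogate (normalized expression).  EpCAM-low/CD49f-high cells gate
    basal, EpCAM-high/CD49f-low luminal, everything else intermediate — the
    gates partition the plane, so every cell receives exactly one label.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.ndim != 2 or levels.shape[1] != 2:
        raise ValueError("levels must be an (n_cells, 2) array")
    th_e, th_c = thresholds
    epcam, cd49f = levels[:, 0], levels[:, 1]
    gate = np.full(len(levels), "intermediate", dtype=object)
    gate[(epcam < th_e) & (cd49f >= th_c)] = "basal"
    gate[(epcam >= th_e) & (cd49f < th_c)] = "luminal"
    return gate.astype(str)


def _build_gene_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []

    def add_program(prog_key, program_label, n, mu_exp_range=(0.8, 1.8),
                    fold_exp_range=(1.0, 1.6), cc_class=""):
        names = list(_CANONICAL.get(prog_key, []))[:n]
        prefix = _SYNTH_PREFIX[prog_key]
        names += [f"{prefix}{i:04d}" for i in range(n - len(names))]
        window = cfg.tau_windows.get(program_label, (0.0, 1.0))
        for name in names:
            tau = rng.uniform(*window)
            mu_high = 10.0 ** rng.uniform(*mu_exp_range)
            mu_low = mu_high / 10.0 ** rng.uniform(*fold_exp_range)
            rows.append((name, program_label, tau, mu_low, mu_high, False, cc_class))
        return names

    add_program("bas_early", "bas_early", cfg.n_bas // 2)
    add_program("bas_late", "bas_late", cfg.n_bas - cfg.n_bas // 2)
    add_program("int_early", "int_early", cfg.n_int // 2)
    add_program("int_late", "int_late", cfg.n_int - cfg.n_int // 2)
    add_program("lum_early", "lum_early", cfg.n_lum // 2)
    lum_late_names = add_program("lum_late", "lum_late",
                                 cfg.n_lum - cfg.n_lum // 2)
    add_program("hr_pos", "hr_pos", cfg.n_hr)
    # moderate cycling fold: the proliferative subpopulation should show up
    # as a high-score region, not as its own cluster
    add_program("cc_s", "cc", cfg.n_cc // 2, mu_exp_range=(0.9, 1.5),
                fold_exp_range=(0.32, 0.55), cc_class="S")
    add_program("cc_g2m", "cc", cfg.n_cc - cfg.n_cc // 2, mu_exp_range=(0.9, 1.5),
                fold_exp_range=(0.32, 0.55), cc_class="G2M")

    # housekeeping genes span four orders of magnitude so that per-cell
    # detected-gene counts co-vary with sequencing depth (the complexity
    # confound the adjusted proportion score corrects for)
    n_hk = cfg.n_housekeeping
    hk_names = list(_CANONICAL["housekeeping"])[: n_hk - 1]
    hk_names += [f"Hkg{i:05d}" for i in range(n_hk - 1 - len(hk_names))]
    for name in hk_names:
        mu = 10.0 ** rng.uniform(-2.0, 1.6)
        rows.append((name, "housekeeping", 0.5, mu, mu, False, ""))
    # Dcpp1: salivary marker, essentially absent from mammary epithelium
    rows.append(("Dcpp1", "housekeeping", 0.5, 0.002, 0.002, False, ""))
    for name in _MITO_GENES:
        rows.append((name, "housekeeping", 0.5, cfg.mito_level, cfg.mito_level,
                     True, ""))

    var = pd.DataFrame(rows, columns=["gene", "program", "tau", "mu_low",
                                      "mu_high", "is_mito", "cc_class"])
    # the two luminal identities: progenitor (HRneg) markers among the late
    # luminal genes are never switched on along the HRpos branch
    hrneg_only_canon = {"Elf5", "Kit", "Aldh1a3", "Cd14", "Foxc1"}
    shared_canon = {"Krt18", "Krt19", "Stat6"}
    var["hrneg_only"] = False
    flags = []
    for i, name in enumerate(lum_late_names):
        if name in hrneg_only_canon:
            flags.append(True)
        elif name in shared_canon:
            flags.append(False)
        else:
            flags.append(True)
    var.loc[var["gene"].isin(lum_late_names), "hrneg_only"] = flags
    # fixed, well-detected FACS surrogates with switch times at mid-conversion
    for gene, tau, lo, hi in [("Epcam", 0.50, 6.0, 50.0), ("Itga6", 0.50, 6.0, 50.0)]:
        i = var.index[var["gene"] == gene][0]
        var.loc[i, ["tau", "mu_low", "mu_high"]] = (tau, lo, hi)
    var = var.set_index("gene", drop=False)
    if var.index.duplicated().any():
        raise SimConfigError("duplicate gene names in simulated panel")
    return var


def _true_regulons(var: pd.DataFrame) -> dict:
    regulons = {}
    for tf, prog, n in _TRUE_REGULON_SPEC:
        members = list(var.index[var["program"] == prog])
        targets = [tf] + [g for g in members if g != tf][: n - 1]
        regulons[tf] = sorted(set(targets))
    return regulons


def _mean_matrix(cfg: SimConfig, var: pd.DataFrame, t: np.ndarray,
                 cc_intensity: np.ndarray, hr_branch: np.ndarray) -> np.ndarray:
    """Per-cell per-gene mean expression in relative units (vectorized).

    ``cc_intensity`` is the graded cell-cycle activation in [0, 1];
    HRneg-only luminal genes are suppressed on the HRpos branch.
    """
    n_cells, n_genes = len(t), len(var)
    M = np.empty((n_cells, n_genes))
    prog = var["program"].to_numpy()
    tau = var["tau"].to_numpy()
    lo = var["mu_low"].to_numpy()
    hi = var["mu_high"].to_numpy()
    hrneg_only = var["hrneg_only"].to_numpy()
    span = hi - lo
    k = cfg.switch_sharpness
    tcol = t[:, None]
    not_hrpos = (~hr_branch)[:, None].astype(float)
    for p in np.unique(prog):
        cols = np.flatnonzero(prog == p)
        if p == "housekeeping":
            M[:, cols] = np.broadcast_to(hi[cols], (n_cells, len(cols)))
        elif p == "cc":
            M[:, cols] = lo[cols] + span[cols] * cc_intensity[:, None]
        elif p in ("bas_early", "bas_late"):
            act = _sigmoid(-k * (tcol - tau[cols]))
            M[:, cols] = lo[cols] + span[cols] * act
        elif p in ("lum_early", "lum_late"):
            act = _sigmoid(k * (tcol - tau[cols]))
            act = np.where(hrneg_only[cols][None, :], act * not_hrpos, act)
            M[:, cols] = lo[cols] + span[cols] * act
        elif p in ("int_early", "int_late"):
            act = np.exp(-((tcol - tau[cols]) / cfg.bump_width) ** 2)
            M[:, cols] = lo[cols] + span[cols] * act
        elif p == "hr_pos":
            act = _sigmoid(k * (tcol - tau[cols]))
            M[:, cols] = lo[cols] + span[cols] * act * hr_branch[:, None].astype(float)
        else:  # pragma: no cover
            raise SimConfigError(f"unknown program {p!r}")
    return M


def simulate_dataset(config: SimConfig | None = None) -> ad.AnnData:
    """Simulate one lineage-conversion dataset; deterministic given the seed.

    Returns an :class:`anndata.AnnData` with raw integer counts in ``.X``
    (and ``.layers["counts"]``), per-cell metadata and ground truth in
    ``.obs`` (``batch``, ``plate``, ``facs_gate``, ``gfp``, ``timepoint_weeks``,
    ``t_true``, ``branch``, ``cycling``, ``stage``), per-gene truth in
    ``.var`` (``program``, ``tau``, ``is_mito``, ``cc_class``), true regulons
    in ``.uns["regulons"]`` and true per-cell regulon activity in
    ``.obsm["true_regulon_activity"]``.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    var = _build_gene_table(cfg, rng)
    n = cfg.n_cells

    # --- cells: GFP status, stage, conversion time, branch -----------------
    gfp_neg = rng.random(n) < cfg.gfp_neg_fraction
    stage = np.empty(n, dtype=object)
    # wild-type (GFPneg) cells occupy only the endpoints of the conversion
    neg_idx = np.flatnonzero(gfp_neg)
    stage[neg_idx] = np.where(rng.random(len(neg_idx)) < 0.5, "BAS", "LUM")
    pos_idx = np.flatnonzero(~gfp_neg)
    stage[pos_idx] = rng.choice(["BAS", "INT1", "INT2", "LUM"], size=len(pos_idx))

    t = np.empty(n)
    for s, (lo, hi) in STAGE_T_WINDOWS.items():
        mask = stage == s
        t[mask] = rng.uniform(lo, hi, size=mask.sum())
    t[neg_idx] = np.where(stage[neg_idx] == "BAS",
                          rng.uniform(0.0, 0.08, size=len(neg_idx)),
                          rng.uniform(0.92, 1.0, size=len(neg_idx)))
    if cfg.discrete_timepoints:
        centers = {"BAS": 0.08, "INT1": 0.40, "INT2": 0.63, "LUM": 0.92}
        t = np.array([centers[s] for s in stage])

    hr_branch = np.zeros(n, dtype=bool)
    lum_mask = stage == "LUM"
    hr_branch[lum_mask] = rng.random(lum_mask.sum()) < cfg.hr_branch_fraction
    branch = np.where(hr_branch, "HRpos", "HRneg")
    # the HRpos identity diverges around the late-intermediate stage and
    # matures in parallel, slightly earlier in conversion time than HRneg
    t[hr_branch] = rng.uniform(0.74, 0.94, size=int(hr_branch.sum()))
    # terminal LUM cells split into the two luminal identities
    stage = np.asarray(stage, dtype=object)
    stage[lum_mask & hr_branch] = "HRpos"
    stage[lum_mask & ~hr_branch] = "HRneg"

    # proliferative subpopulation concentrated at intermediate t
    p_cyc = cfg.cycling_base_rate + cfg.cycling_fraction_at_mid_t * np.exp(
        -((t - 0.55) / 0.15) ** 2)
    cycling = rng.random(n) < np.clip(p_cyc, 0.0, 1.0)
    # graded cycle activation: cells traverse the cycle continuously, so the
    # proliferative subpopulation is a score gradient, not a discrete bloc
    cc_intensity = np.where(cycling,
                            rng.beta(6.0, 1.5, size=n),
                            rng.beta(1.2, 10.0, size=n))

    batch = rng.integers(1, cfg.n_batches + 1, size=n)
    plate = np.array([f"b{b}_p{i}" for b, i in
                      zip(batch, np.zeros(n, dtype=int))], dtype=object)
    # assign plates of 96 within each batch, in cell order
    for b in range(1, cfg.n_batches + 1):
        idx = np.flatnonzero(batch == b)
        plate[idx] = [f"b{b}_p{j // 96 + 1}" for j in range(len(idx))]

    libsize = rng.lognormal(*cfg.library_size_lognormal, size=n)

    # --- means, batch effects, counts --------------------------------------
    M = _mean_matrix(cfg, var, t, cc_intensity, hr_branch)
    mito_cols = var["is_mito"].to_numpy()
    mito_factor = rng.lognormal(0.0, cfg.mito_cell_sd, size=n)
    M[:, mito_cols] *= mito_factor[:, None]
    # batch 1 is the reference; other batches get per-gene log-normal factors
    for b in range(2, cfg.n_batches + 1):
        factors = rng.lognormal(0.0, cfg.batch_effect_sd, size=len(var))
        M[batch == b] *= factors[None, :]

    P = M / M.sum(axis=1, keepdims=True)
    mu = P * libsize[:, None]
    if np.isinf(cfg.nb_dispersion):
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(cfg.nb_dispersion, mu / cfg.nb_dispersion)
        counts = rng.poisson(lam)
    counts = counts.astype(np.int64)

    # --- FACS gate from surrogate surface markers ---------------------------
    totals = counts.sum(axis=1)
    e_idx = var.index.get_loc("Epcam")
    c_idx = var.index.get_loc("Itga6")
    lognorm = np.log1p(counts[:, [e_idx, c_idx]] / totals[:, None] * 1e4)
    thresholds = cfg.facs_thresholds or tuple(np.median(lognorm, axis=0))
    facs_gate = assign_facs_gate(lognorm, thresholds)

    obs = pd.DataFrame({
        "batch": pd.Categorical([f"batch{b}" for b in batch]),
        "plate": plate.astype(str),
        "facs_gate": pd.Categorical(facs_gate,
                                    categories=["basal", "intermediate", "luminal"]),
        "gfp": pd.Categorical(np.where(gfp_neg, "GFPneg", "GFPpos")),
        "timepoint_weeks": [STAGE_TIMEPOINT_WEEKS[s] for s in stage],
        "t_true": t,
        "branch": pd.Categorical(branch, categories=["HRneg", "HRpos"]),
        "cycling": cycling,
        "cc_intensity": cc_intensity,
        "stage": pd.Categorical(stage, categories=list(STAGES)),
    }, index=[f"cell_{i:04d}" for i in range(n)])

    adata = ad.AnnData(X=counts, obs=obs, var=var.drop(columns=["gene"]))
    adata.layers["counts"] = counts.copy()
    regulons = _true_regulons(var)
    adata.uns["regulons"] = {tf: list(targets) for tf, targets in regulons.items()}
    adata.uns["facs_thresholds"] = list(thresholds)
    adata.uns["sim_config"] = {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(cfg).items()
                               if k != "tau_windows"}

    # true regulon activity: mean normalized activation of the target genes
    span = (var["mu_high"] - var["mu_low"]).to_numpy()
    span[span == 0] = 1.0
    # undo the per-cell mito scaling so activity reflects the program, not load
    M_prog = M.copy()
    M_prog[:, mito_cols] /= mito_factor[:, None]
    act_norm = np.clip((M_prog - var["mu_low"].to_numpy()) / span, 0.0, None)
    activity = pd.DataFrame(
        {tf: act_norm[:, [var.index.get_loc(g) for g in targets]].mean(axis=1)
         for tf, targets in regulons.items()},
        index=adata.obs_names)
    adata.obsm["true_regulon_activity"] = activity
    return adata
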