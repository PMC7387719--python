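"""Penetrance-table GWAS simulator for epistasis benchmarks.

Disease models are penetrance tables f(g): the probability of being a case
given the functional genotype combination g, with genotype frequencies
following Hardy-Weinberg proportions at the model's minor allele frequency.
Heritability is measured on the penetrance scale,

    h2 = sum_g p(g) (f(g) - K)^2 / (K (1 - K)),

with K = sum_g p(g) f(g) the baseline prevalence.  Pure-epistasis tables
additionally have every single-locus marginal penetrance equal to K, so no
functional variant carries a main effect.

Case-control data are drawn retrospectively: subjects are generated from
the population model and kept until the case/control quotas fill.
Background variants are i.i.d. Binomial(2, MAF) independent of status.
Benchmark designs (sample sizes, h2, MAF, dimensionality) are registered in
:data:`DESIGNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import GenotypeMatrix, PhenotypeVector

__all__ = [
    "PenetranceModel",
    "SimConfig",
    "TruthInfo",
    "DESIGNS",
    "hwe_frequencies",
    "make_epistasis_penetrance",
    "make_main_effect_model",
    "nearest_neighbor_signal",
    "realized_heritability",
    "simulate_case_control",
    "simulate_continuous",
    "simulate_main_effects",
    "simulate_heterogeneous_pairs",
    "simulate_design",
]

DEFAULT_PREVALENCE = 0.3
DEFAULT_MAF = 0.2


class FeasibilityError(ValueError):
    """Requested (h2, K, MAF) combination admits no valid penetrance table."""


def hwe_frequencies(maf: float) -> np.ndarray:
    """Genotype (dosage 0/1/2) frequencies under Hardy-Weinberg equilibrium."""
    if not 0 < maf < 1:
        raise ValueError("maf must be in (0, 1)")
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])


@dataclass
class PenetranceModel:
    """1- or 2-locus penetrance table with prevalence K and realized h2."""

    table: np.ndarray  # shape (3,) or (3, 3)
    maf: float
    prevalence: float
    realized_h2: float
    kind: str  # "epistasis" | "main"

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.min() < 0 or self.table.max() > 1:
            raise ValueError("penetrances must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.table.ndim

    def genotype_weights(self) -> np.ndarray:
        w = hwe_frequencies(self.maf)
        if self.n_loci == 1:
            return w
        return np.outer(w, w)

    def marginal_penetrance(self, locus: int) -> np.ndarray:
        """Single-locus penetrance, averaging the other locus over HWE."""
        if self.n_loci == 1:
            return self.table
        w = hwe_frequencies(self.maf)
        return self.table @ w if locus == 0 else w @ self.table


def realized_heritability(table: np.ndarray, maf: float) -> tuple[float, float]:
    """(h2, K) of a penetrance table by enumeration over genotype cells."""
    table = np.asarray(table, dtype=float)
    w = hwe_frequencies(maf)
    W = w if table.ndim == 1 else np.outer(w, w)
    K = float((W * table).sum())
    if K <= 0 or K >= 1:
        return 0.0, K
    h2 = float((W * (table - K) ** 2).sum() / (K * (1 - K)))
    return h2, K


def _double_center(d: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Remove weighted row/column means so both marginals vanish under HWE."""
    rm = d @ w
    cm = w @ d
    gm = w @ d @ w
    return d - rm[:, None] - cm[None, :] + gm


def nearest_neighbor_signal(table: np.ndarray, maf: float) -> float:
    """Population-level projected-distance signal of a two-locus model.

    For balanced case-control sampling from the model, this is the smaller
    (over the two loci) covariance-to-variance ratio between the per-locus
    allele-mismatch diff and the pair miss indicator over subject pairs that
    MATCH at the partner locus.  A pure-epistasis model has exactly zero
    marginal diff-miss association over unconditioned random pairs; its
    Relief-style signal emerges when neighbors agree at the partner locus,
    which this conditional slope captures.  Models of equal heritability
    differ widely on this measure, which drives how easily nearest-neighbor
    methods detect them; it plays the role of GAMETES' ease-of-detection
    ranking for model selection.
    """
    table = np.asarray(table, dtype=float)
    w = hwe_frequencies(maf)
    W = np.outer(w, w)
    K = float((W * table).sum())
    p_case = (W * table / K).ravel()
    p_ctrl = (W * (1 - table) / (1 - K)).ravel()
    probs = np.concatenate([0.5 * p_case, 0.5 * p_ctrl])  # balanced design
    y = np.r_[np.ones(9), np.zeros(9)]
    g1 = np.repeat(np.arange(3), 3).astype(float)
    g2 = np.tile(np.arange(3), 3).astype(float)
    G1, G2 = np.r_[g1, g1], np.r_[g2, g2]
    miss = (y[:, None] != y[None, :]).astype(float)
    slopes = []
    for Gl, Gother in ((G1, G2), (G2, G1)):
        # condition on the partner locus agreeing, as in a tight neighborhood
        P = np.outer(probs, probs) * (Gother[:, None] == Gother[None, :])
        P = P / P.sum()
        d = np.abs(Gl[:, None] - Gl[None, :]) / 2.0
        Ed = (P * d).sum()
        Em = (P * miss).sum()
        cov = (P * d * miss).sum() - Ed * Em
        var = (P * d * d).sum() - Ed**2
        slopes.append(cov / var if var > 0 else 0.0)
    return float(min(slopes))


def make_epistasis_penetrance(maf: float = DEFAULT_MAF, h2: float = 0.4,
                              K: float = DEFAULT_PREVALENCE,
                              rng=None, max_tries: int = 200_000,
                              select_best_of: int = 1) -> PenetranceModel:
    """Pure-epistasis 3x3 penetrance table with exact target heritability.

    Random tables are double-centered under HWE weights (zeroing both
    single-locus marginals), scaled to the target variance, and rejected
    until all nine penetrances are valid probabilities.  With
    ``select_best_of`` > 1, that many valid tables are generated and the one
    with the highest :func:`nearest_neighbor_signal` is returned, emulating
    the ease-of-detection model selection of penetrance-table simulators.
    """
    if not 0 < K < 1:
        raise ValueError("prevalence K must be in (0, 1)")
    if h2 < 0 or h2 >= 1:
        raise ValueError("h2 must be in [0, 1)")
    if h2 == 0:
        table = np.full((3, 3), K)
        return PenetranceModel(table, maf, K, 0.0, "epistasis")
    rng = np.random.default_rng(rng)
    w = hwe_frequencies(maf)
    W = np.outer(w, w)
    target_var = h2 * K * (1 - K)
    valid: list[np.ndarray] = []
    for _ in range(max_tries):
        d = _double_center(rng.standard_normal((3, 3)), w)
        v = float((W * d**2).sum())
        if v < 1e-12:
            continue
        f = K + np.sqrt(target_var / v) * d
        if f.min() >= 0.0 and f.max() <= 1.0:
            valid.append(f)
            if len(valid) >= select_best_of:
                break
    if not valid:
        raise FeasibilityError(
            f"no valid pure-epistasis table after {max_tries} proposals for "
            f"h2={h2}, K={K}, maf={maf}; the scaled deviations exceed [0,1] — "
            f"lower h2 or move K toward the feasible range"
        )
    best = max(valid, key=lambda f: nearest_neighbor_signal(f, maf))
    h2_chk, K_chk = realized_heritability(best, maf)
    return PenetranceModel(best, maf, K_chk, h2_chk, "epistasis")


def make_main_effect_model(maf: float = DEFAULT_MAF, h2: float = 0.4,
                           K: float = DEFAULT_PREVALENCE,
                           rng=None, max_tries: int = 50_000) -> PenetranceModel:
    """Single-locus penetrance table with the target heritability."""
    if h2 == 0:
        return PenetranceModel(np.full(3, K), maf, K, 0.0, "main")
    rng = np.random.default_rng(rng)
    w = hwe_frequencies(maf)
    target_var = h2 * K * (1 - K)
    for _ in range(max_tries):
        e = rng.standard_normal(3)
        e = e - w @ e
        v = float((w * e**2).sum())
        if v < 1e-12:
            continue
        f = K + np.sqrt(target_var / v) * e
        if f.min() >= 0.0 and f.max() <= 1.0:
            h2_chk, K_chk = realized_heritability(f, maf)
            return PenetranceModel(f, maf, K_chk, h2_chk, "main")
    raise FeasibilityError(
        f"no valid single-locus table after {max_tries} proposals for "
        f"h2={h2}, K={K}, maf={maf}"
    )


@dataclass
class TruthInfo:
    """Ground truth of a simulated dataset: which SNPs are functional and how."""

    functional_snps: list[str]
    functional_indices: list[int]
    models: list[PenetranceModel]
    h2: float
    extra: dict = field(default_factory=dict)


@dataclass
class SimConfig:
    """One benchmark scenario; defaults mirror the registered designs."""

    design: str = "interact-pair"
    n_cases: int = 800
    n_controls: int = 800
    n: int = 1600  # continuous designs
    p_total: int = 20
    h2: float = 0.4
    maf: float = DEFAULT_MAF
    background_maf: float = DEFAULT_MAF
    prevalence: float = DEFAULT_PREVALENCE
    model_candidates: int = 50  # tables generated per model; best-signal kept
    seed: int | None = None


#: Benchmark design registry: name -> SimConfig defaults.
DESIGNS: dict[str, SimConfig] = {
    "main-pair": SimConfig(design="main-pair", h2=0.4, p_total=20),
    "main-4": SimConfig(design="main-4", h2=0.4, p_total=20),
    "interact-4": SimConfig(design="interact-4", h2=0.4, p_total=20),
    "interact-pair": SimConfig(design="interact-pair", h2=0.05, p_total=20),
    "continuous-pair": SimConfig(design="continuous-pair", h2=0.4, p_total=20, n=1600),
    "imbalanced-pair": SimConfig(design="imbalanced-pair", h2=0.4, p_total=20,
                                 n_cases=960, n_controls=640),
    "highdim-pair": SimConfig(design="highdim-pair", h2=0.4, p_total=10_000),
}


def _draw_functional(rng, model_list, assign, n):
    """Functional genotypes and per-subject penetrance for possibly
    heterogeneous models (``assign`` maps subject -> governing model)."""
    n_loci_total = sum(m.n_loci for m in model_list)
    geno = np.empty((n, n_loci_total), dtype=np.int8)
    pen = np.empty(n)
    col = 0
    for mi, model in enumerate(model_list):
        w = hwe_frequencies(model.maf)
        L = model.n_loci
        g = rng.choice(3, size=(n, L), p=w).astype(np.int8)
        geno[:, col:col + L] = g
        sel = assign == mi
        if L == 1:
            pen_m = model.table[g[:, 0]]
        else:
            pen_m = model.table[g[:, 0], g[:, 1]]
        pen[sel] = pen_m[sel]
        col += L
    return geno, pen


def _assemble(rng, func_geno, y_values, kind, p_total, background_maf,
              models, h2, extra=None):
    """Place functional columns at random positions among i.i.d. background."""
    n, L = func_geno.shape
    if p_total < L:
        raise ValueError(f"p_total={p_total} smaller than {L} functional loci")
    n_bg = p_total - L
    bg = rng.binomial(2, background_maf, size=(n, n_bg)).astype(np.int8)
    positions = rng.permutation(p_total)
    func_pos = np.sort(positions[:L])
    dosage = np.empty((n, p_total), dtype=np.int8)
    snps = []
    bg_iter = iter(range(n_bg))
    func_iter = iter(range(L))
    func_names = []
    for j in range(p_total):
        if j in func_pos:
            fi = next(func_iter)
            dosage[:, j] = func_geno[:, fi]
            name = f"M{fi + 1}"
            func_names.append(name)
        else:
            name = f"N{next(bg_iter) + 1}"
            dosage[:, j] = bg[:, int(name[1:]) - 1]
        snps.append(name)
    samples = [f"S{i + 1}" for i in range(n)]
    G = GenotypeMatrix(samples=samples, snps=snps, dosage=dosage)
    y = PhenotypeVector(np.asarray(y_values, dtype=float), kind)
    truth = TruthInfo(functional_snps=func_names,
                      functional_indices=[snps.index(s) for s in func_names],
                      models=list(models), h2=h2, extra=extra or {})
    return G, y, truth


def _retrospective_sample(rng, model_list, assign_prob, n_cases, n_controls,
                          max_batches: int = 2000):
    """Draw subjects until case/control quotas are met."""
    need_cases, need_controls = n_cases, n_controls
    batch = max(2048, 4 * (n_cases + n_controls))
    kept_geno, kept_y, kept_assign = [], [], []
    for _ in range(max_batches):
        assign = rng.choice(len(model_list), size=batch, p=assign_prob)
        geno, pen = _draw_functional(rng, model_list, assign, batch)
        status = rng.random(batch) < pen
        for is_case, need in ((True, need_cases), (False, need_controls)):
            take = np.flatnonzero(status == is_case)[:need]
            kept_geno.append(geno[take])
            kept_y.append(np.full(len(take), float(is_case)))
            kept_assign.append(assign[take])
            if is_case:
                need_cases -= len(take)
            else:
                need_controls -= len(take)
        if need_cases == 0 and need_controls == 0:
            geno_all = np.concatenate(kept_geno)
            y_all = np.concatenate(kept_y)
            assign_all = np.concatenate(kept_assign)
            perm = rng.permutation(len(y_all))
            return geno_all[perm], y_all[perm], assign_all[perm]
    raise FeasibilityError(
        "case/control quotas not met; prevalence too extreme for the "
        "requested sample sizes"
    )


def simulate_case_control(model: PenetranceModel, n_cases: int = 800,
                          n_controls: int = 800, p_total: int = 20,
                          background_maf: float = DEFAULT_MAF, seed=None):
    """Case-control dataset from one penetrance model.

    Returns (GenotypeMatrix, PhenotypeVector, TruthInfo).
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    rng = np.random.default_rng(seed)
    geno, y, _ = _retrospective_sample(rng, [model], [1.0], n_cases, n_controls)
    return _assemble(rng, geno, y, "binary", p_total, background_maf,
                     [model], model.realized_h2)


def simulate_heterogeneous_pairs(h2: float = 0.4, maf: float = DEFAULT_MAF,
                                 K: float = DEFAULT_PREVALENCE,
                                 n_cases: int = 800, n_controls: int = 800,
                                 p_total: int = 20,
                                 background_maf: float = DEFAULT_MAF,
                                 assign_prob: float = 0.5, seed=None,
                                 select_best_of: int = 1):
    """Two independent pure-epistasis pairs; each subject's disease status is
    governed by pair 1 with probability ``assign_prob``, else pair 2."""
    rng = np.random.default_rng(seed)
    m1 = make_epistasis_penetrance(maf, h2, K, rng, select_best_of=select_best_of)
    m2 = make_epistasis_penetrance(maf, h2, K, rng, select_best_of=select_best_of)
    models = [m1, m2]
    probs = [assign_prob, 1.0 - assign_prob]
    geno, y, assign = _retrospective_sample(rng, models, probs, n_cases, n_controls)
    return _assemble(rng, geno, y, "binary", p_total, background_maf, models,
                     h2, extra={"assign_prob": assign_prob})


def simulate_main_effects(n_functional: int = 2, h2: float = 0.4,
                          maf: float = DEFAULT_MAF, K: float = DEFAULT_PREVALENCE,
                          n_cases: int = 800, n_controls: int = 800,
                          p_total: int = 20, background_maf: float = DEFAULT_MAF,
                          mode: str | None = None, seed=None):
    """Multi-locus main-effect dataset with h2 split equally across loci.

    ``mode='additive'`` (default for 2 loci) builds a joint penetrance
    f(g) = K + sum_l c_l e_l(g_l) with zero-mean per-locus deviations, each
    contributing h2/L; every locus's marginal table then carries exactly
    h2/L.  ``mode='heterogeneous'`` (default for 4 loci, where the additive
    construction has no valid penetrance solution at benchmark settings)
    instead assigns each subject to one locus's single-locus model at full
    h2, giving influence ratios 25:25:...
    """
    if n_functional not in (2, 4):
        raise ValueError("n_functional must be 2 or 4")
    if mode is None:
        mode = "additive" if n_functional == 2 else "heterogeneous"
    rng = np.random.default_rng(seed)
    if mode == "heterogeneous":
        models = [make_main_effect_model(maf, h2, K, rng) for _ in range(n_functional)]
        probs = [1.0 / n_functional] * n_functional
        geno, y, _ = _retrospective_sample(rng, models, probs, n_cases, n_controls)
        return _assemble(rng, geno, y, "binary", p_total, background_maf,
                         models, h2, extra={"mode": mode})
    if mode != "additive":
        raise ValueError(f"unknown main-effect mode {mode!r}")
    L = n_functional
    w = hwe_frequencies(maf)
    target_var = (h2 / L) * K * (1 - K)
    for _ in range(50_000):
        devs = []
        for _ in range(L):
            e = rng.standard_normal(3)
            e = e - w @ e
            v = float((w * e**2).sum())
            if v < 1e-12:
                break
            devs.append(np.sqrt(target_var / v) * e)
        if len(devs) < L:
            continue
        lo = K + sum(d.min() for d in devs)
        hi = K + sum(d.max() for d in devs)
        if lo >= 0.0 and hi <= 1.0:
            break
    else:
        raise FeasibilityError(
            f"no valid additive {L}-locus model for h2={h2}, K={K}, maf={maf}; "
            f"try mode='heterogeneous'"
        )

    # draw directly: additive penetrance over L loci
    n_target = n_cases + n_controls
    need_cases, need_controls = n_cases, n_controls
    kept_g, kept_y = [], []
    for _ in range(2000):
        batch = max(2048, 4 * n_target)
        g = rng.choice(3, size=(batch, L), p=w).astype(np.int8)
        pen = K + sum(devs[l][g[:, l]] for l in range(L))
        status = rng.random(batch) < pen
        for is_case, need in ((True, need_cases), (False, need_controls)):
            take = np.flatnonzero(status == is_case)[:need]
            kept_g.append(g[take])
            kept_y.append(np.full(len(take), float(is_case)))
            if is_case:
                need_cases -= len(take)
            else:
                need_controls -= len(take)
        if need_cases == 0 and need_controls == 0:
            break
    else:
        raise FeasibilityError("case/control quotas not met for additive model")
    geno = np.concatenate(kept_g)
    yv = np.concatenate(kept_y)
    perm = rng.permutation(len(yv))
    geno, yv = geno[perm], yv[perm]
    # marginal single-locus models for truth metadata
    models = []
    for l in range(L):
        tab = K + devs[l]
        h2_l, K_l = realized_heritability(tab, maf)
        models.append(PenetranceModel(tab, maf, K_l, h2_l, "main"))
    return _assemble(rng, geno, yv, "binary", p_total, background_maf, models,
                     h2, extra={"mode": mode})


def simulate_continuous(model: PenetranceModel, n: int = 1600,
                        p_total: int = 20, h2: float | None = None,
                        background_maf: float = DEFAULT_MAF, seed=None):
    """Continuous outcome y = genetic score + Gaussian noise at heritability h2.

    The genetic score is the penetrance-table deviation f(g) - K; noise
    variance is set so Var_genetic / (Var_genetic + sigma^2) = h2.
    """
    rng = np.random.default_rng(seed)
    if h2 is None:
        h2 = model.realized_h2
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1) for a continuous outcome")
    W = model.genotype_weights()
    dev = model.table - model.prevalence
    var_g = float((W * dev**2).sum())
    if var_g <= 0:
        raise ValueError("degenerate model: no genetic variance")
    sigma = np.sqrt(var_g * (1 - h2) / h2)
    w = hwe_frequencies(model.maf)
    g = rng.choice(3, size=(n, model.n_loci), p=w).astype(np.int8)
    score = dev[g[:, 0]] if model.n_loci == 1 else dev[g[:, 0], g[:, 1]]
    yv = score + rng.normal(0.0, sigma, size=n)
    return _assemble(rng, g, yv, "continuous", p_total, background_maf,
                     [model], h2, extra={"sigma": sigma})


def simulate_design(name: str, seed=None, **overrides):
    """Generate a registered benchmark design by name.

    Returns (GenotypeMatrix, PhenotypeVector, TruthInfo).
    """
    if name not in DESIGNS:
        raise ValueError(f"unknown design {name!r}; choose from {sorted(DESIGNS)}")
    cfg = replace(DESIGNS[name], seed=seed, **overrides)
    rng = np.random.default_rng(cfg.seed)
    model_seed = rng.integers(2**31)
    data_seed = rng.integers(2**31)
    if name in ("interact-pair", "imbalanced-pair", "highdim-pair"):
        model = make_epistasis_penetrance(cfg.maf, cfg.h2, cfg.prevalence, model_seed,
                                          select_best_of=cfg.model_candidates)
        return simulate_case_control(model, cfg.n_cases, cfg.n_controls,
                                     cfg.p_total, cfg.background_maf, data_seed)
    if name == "continuous-pair":
        # the table only shapes the genetic score here (its c-scale cancels
        # against the noise calibration), so build it at a feasible h2
        model = make_epistasis_penetrance(cfg.maf, min(cfg.h2, 0.4), cfg.prevalence,
                                          model_seed,
                                          select_best_of=cfg.model_candidates)
        return simulate_continuous(model, cfg.n, cfg.p_total, cfg.h2,
                                   cfg.background_maf, data_seed)
    if name == "main-pair":
        return simulate_main_effects(2, cfg.h2, cfg.maf, cfg.prevalence,
                                     cfg.n_cases, cfg.n_controls, cfg.p_total,
                                     cfg.background_maf, seed=data_seed)
    if name == "main-4":
        return simulate_main_effects(4, cfg.h2, cfg.maf, cfg.prevalence,
                                     cfg.n_cases, cfg.n_controls, cfg.p_total,
                                     cfg.background_maf, seed=data_seed)
    if name == "interact-4":
        return simulate_heterogeneous_pairs(cfg.h2, cfg.maf, cfg.prevalence,
                                            cfg.n_cases, cfg.n_controls,
                                            cfg.p_total, cfg.background_maf,
                                            seed=data_seed,
                                            select_best_of=cfg.model_candidates)
    raise AssertionError(name)
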