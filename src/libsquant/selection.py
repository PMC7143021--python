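"""Variable selection on top of PLS1: VIP, selectivity ratio, and a GA.

Three schemes, each producing a per-variable importance score, a threshold
and a boolean selection mask:

* VIP (variable importance in projection) accumulates the squared,
  normalised PLS weights over factors, weighted by each factor's explained
  y-variance, and normalised so that the squared scores average to one;
  the conventional "greater than one" rule selects variables.
* SR (selectivity ratio) projects X onto the normalised regression vector
  (target projection) and scores each variable by the ratio of its
  explained to residual sum of squares; the threshold is the upper 5 %
  F-quantile with (n−2, n−3) degrees of freedom.
* GA evolves binary variable subsets with cross-validated PLSR error as
  fitness, repeats over independent runs, and keeps variables that appear
  in the best subset of enough runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chemometrics import PLSModel, kfold_cv, simpls_fit
from .synthetic import child_seed

__all__ = [
    "SelectionResult",
    "GAConfig",
    "vip_scores",
    "selectivity_ratio_scores",
    "sr_critical_value",
    "vip_select",
    "sr_select",
    "ga_select",
]


@dataclass(frozen=True)
class SelectionResult:
    """Scores, threshold and boolean mask produced by one selection method."""

    method: str  # "GA", "VIP" or "SR"
    scores: np.ndarray
    threshold: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.scores.shape != self.mask.shape:
            raise ValueError("scores and mask must align")

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def vip_scores(model: PLSModel, X_scaled: np.ndarray, y_centered: np.ndarray) -> np.ndarray:
    """VIP_j = sqrt(p · Σ_a SS_a (w_aj/‖w_a‖)² / Σ_a SS_a), SS_a = q_a²·t_aᵀt_a.

    Satisfies Σ_j VIP_j² = p exactly.
    """
    W = model.R
    p = W.shape[0]
    ss = model.q**2 * np.einsum("ia,ia->a", model.T, model.T)
    total = ss.sum()
    if total <= 0:
        raise ValueError("model explains zero y-variance; VIP undefined")
    Wn2 = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(p * (Wn2 @ ss) / total)


def selectivity_ratio_scores(
    model: PLSModel, X_scaled: np.ndarray, y_centered: np.ndarray
) -> np.ndarray:
    """Target-projection selectivity ratio for each variable.

    X is projected onto the unit regression vector; SR_j is the explained
    over residual sum of squares of column j under that rank-one model.
    A variable with zero residual gets +inf (sorts above any threshold).
    """
    Xs = np.asarray(X_scaled, dtype=float)
    b = model.b
    b_norm = np.linalg.norm(b)
    if b_norm == 0:
        raise ValueError("zero regression vector; selectivity ratio undefined")
    t_tp = Xs @ (b / b_norm)
    p_tp = Xs.T @ t_tp / (t_tp @ t_tp)
    X_tp = np.outer(t_tp, p_tp)
    explained = np.sum(X_tp**2, axis=0)
    residual = np.sum((Xs - X_tp) ** 2, axis=0)
    with np.errstate(divide="ignore"):
        sr = explained / residual
    if np.any(residual == 0):
        warnings.warn("variable(s) with zero residual variance: SR = +inf", stacklevel=2)
    return sr


def sr_critical_value(n_cal: int, alpha: float = 0.05) -> float:
    """Upper-α F quantile with (n_cal−2, n_cal−3) degrees of freedom."""
    if n_cal < 5:
        raise ValueError("need at least 5 calibration samples for the SR F-test")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(stats.f.ppf(1.0 - alpha, n_cal - 2, n_cal - 3))


def vip_select(model: PLSModel, X_scaled: np.ndarray, y_centered: np.ndarray) -> SelectionResult:
    """Greater-than-one rule on VIP scores."""
    scores = vip_scores(model, X_scaled, y_centered)
    return SelectionResult(method="VIP", scores=scores, threshold=1.0, mask=scores > 1.0)


def sr_select(
    model: PLSModel, X_scaled: np.ndarray, y_centered: np.ndarray, alpha: float = 0.05
) -> SelectionResult:
    """F-test (1−alpha) criterion on selectivity-ratio scores."""
    scores = selectivity_ratio_scores(model, X_scaled, y_centered)
    thr = sr_critical_value(X_scaled.shape[0], alpha)
    return SelectionResult(method="SR", scores=scores, threshold=thr, mask=scores > thr)


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters (standard small-p GA-PLS practice)."""

    population_size: int = 30
    n_generations: int = 100
    crossover_prob: float = 0.5
    mutation_prob: float = 0.01
    fitness_cv_folds: int = 5
    fitness_max_lv: int = 10
    n_runs: int = 5
    inclusion_frequency_cutoff: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for prob in (self.crossover_prob, self.mutation_prob, self.inclusion_frequency_cutoff):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.population_size, self.n_generations, self.n_runs, self.fitness_cv_folds) < 1:
            raise ValueError("sizes must be positive")


def _ga_fitness(X: np.ndarray, y: np.ndarray, chrom: np.ndarray, cfg: GAConfig, seed: int) -> float:
    """Fitness = −RMSECV of PLSR on the chromosome's variables (LV by inner CV)."""
    if not chrom.any():
        return -np.inf
    Xc = X[:, chrom]
    a_max = min(cfg.fitness_max_lv, Xc.shape[1], X.shape[0] - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = kfold_cv(Xc, y, A_max=a_max, k=cfg.fitness_cv_folds, seed=seed)
    return -float(cv.rmsecv_by_A[cv.chosen_A - 1])


def _ga_single_run(
    X: np.ndarray,
    y: np.ndarray,
    cfg: GAConfig,
    run_seed: int,
    initial_population: np.ndarray | None = None,
) -> np.ndarray:
    """One seeded GA run; returns the best chromosome found (elitist search)."""
    rng = np.random.default_rng(run_seed)
    n, p = X.shape
    cv_seed = child_seed(run_seed, 9)
    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = np.packbits(chrom).tobytes()
        if key not in cache:
            cache[key] = _ga_fitness(X, y, chrom, cfg, cv_seed)
        return cache[key]

    if initial_population is not None:
        pop = np.array(initial_population, dtype=bool)
        if pop.shape != (cfg.population_size, p):
            raise ValueError("initial population must be population_size × p")
    else:
        pop = rng.random((cfg.population_size, p)) < 0.5
        for i in range(cfg.population_size):  # no all-zero chromosomes at init
            if not pop[i].any():
                pop[i, rng.integers(p)] = True
    fits = np.array([fitness(c) for c in pop])

    for _ in range(cfg.n_generations):
        elite = pop[np.argmax(fits)].copy()
        children = np.empty_like(pop)
        for i in range(0, cfg.population_size, 2):
            # tournament selection, size 2
            a, b = rng.integers(cfg.population_size, size=2)
            pa = pop[a] if fits[a] >= fits[b] else pop[b]
            a, b = rng.integers(cfg.population_size, size=2)
            pb = pop[a] if fits[a] >= fits[b] else pop[b]
            c1, c2 = pa.copy(), pb.copy()
            if rng.random() < cfg.crossover_prob and p > 1:
                cut = int(rng.integers(1, p))
                c1[cut:], c2[cut:] = pb[cut:].copy(), pa[cut:].copy()
            children[i] = c1
            if i + 1 < cfg.population_size:
                children[i + 1] = c2
        flips = rng.random(children.shape) < cfg.mutation_prob
        children ^= flips
        children[0] = elite  # elitism of 1: best fitness never decreases
        pop = children
        fits = np.array([fitness(c) for c in pop])

    return pop[np.argmax(fits)].copy()


def ga_select(
    X: np.ndarray,
    y: np.ndarray,
    cfg: GAConfig | None = None,
    initial_population: np.ndarray | None = None,
) -> SelectionResult:
    """Run-frequency GA selection.

    ``cfg.n_runs`` independent seeded GA replicates each contribute their
    best chromosome; the final mask keeps variables whose inclusion
    frequency across runs reaches the cutoff. Scores are the frequencies.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cfg = cfg or GAConfig()
    if X.shape[1] < 2:
        raise ValueError("GA selection needs at least 2 variables")
    best = np.vstack(
        [
            _ga_single_run(X, y, cfg, child_seed(cfg.seed, 7, run), initial_population)
            for run in range(cfg.n_runs)
        ]
    )
    freq = best.mean(axis=0)
    mask = freq >= cfg.inclusion_frequency_cutoff
    return SelectionResult(
        method="GA", scores=freq, threshold=cfg.inclusion_frequency_cutoff, mask=mask
    )
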