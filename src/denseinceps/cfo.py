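"""Catch Fish Optimization (CFO): a bound-constrained population minimizer.

The population of M "fishermen" searches a w-dimensional box.  The run
is split evenly by evaluation count: while EFs/MaxEFs < 0.5 agents
explore, each choosing per generation between an *independent search*
(a move toward/away from a random reference agent scaled by the
empirical fitness gap, plus isotropic noise) and a *group capture*
(groups of 3-4 agents contract toward their centroid); once
EFs/MaxEFs >= 0.5 all agents are resampled from a Gaussian centered on
the best-ever position with a spread that shrinks to zero as the budget
is consumed.

Conventions (fixed here, the published description is silent or
ambiguous): minimization throughout; positions are clamped to the
bounds after every move; the degenerate fitness gap (fit_max ==
fit_min) is treated as 0; the exploitation spread factor eta is clamped
to [0, 1]; group partners are read from the pre-update snapshot
(synchronous generations).

``select_features`` wraps the optimizer into a feature selector:
continuous positions in [0,1]^d thresholded at 0.5 give a binary mask,
scored by the holdout error of a small fixed classifier plus a sparsity
penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CFOParams",
    "FisherPopulation",
    "SelectionMask",
    "OBJECTIVES",
    "capture_rate",
    "init_population",
    "independent_search",
    "group_capture",
    "exploitation_step",
    "optimize",
    "select_features",
]


@dataclass
class CFOParams:
    M: int = 20                 # population size (>= 4: group capture needs 3-4)
    MaxEFs: int = 2000          # objective-evaluation budget
    group_sizes: tuple = (3, 4)
    phase_split: float = 0.5    # exploration/exploitation budget ratio
    seed: int = 0

    def __post_init__(self):
        if self.M < 4:
            raise ValueError("population size must be >= 4")
        if self.MaxEFs < self.M:
            raise ValueError("evaluation budget must cover one generation")


@dataclass
class FisherPopulation:
    positions: np.ndarray       # M x w
    fitness: np.ndarray         # length M
    lb: np.ndarray
    ub: np.ndarray
    EFs: int
    MaxEFs: int
    Gbest: np.ndarray | None = None
    Gbest_fitness: float = np.inf
    rng_seed: int = 0
    trace: list = field(default_factory=list)

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.minimum(np.maximum(x, self.lb), self.ub)

    def record(self, j: int, fit: float):
        self.fitness[j] = fit
        self.EFs += 1
        if fit < self.Gbest_fitness:
            self.Gbest_fitness = float(fit)
            self.Gbest = self.positions[j].copy()
        self.trace.append(self.Gbest_fitness)


@dataclass
class SelectionMask:
    mask: np.ndarray
    fitness: float
    selected_count: int

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


def capture_rate(EFs: int, MaxEFs: int) -> float:
    """Probability-like schedule deciding independent search vs group capture.

    a-hat = (1 - 3*EFs/(2*MaxEFs)) ** (3*EFs/(2*MaxEFs)); defined for
    EFs/MaxEFs < 2/3 (the base must stay positive), and only used in the
    exploration half of the run.
    """
    r = 3.0 * EFs / (2.0 * MaxEFs)
    if r >= 1.0:
        raise ValueError("capture rate undefined for EFs/MaxEFs >= 2/3 "
                         "(negative base under fractional exponent)")
    return float((1.0 - r) ** r)


def init_population(params: CFOParams, lb, ub) -> FisherPopulation:
    """Uniform positions within the box: x = (ub-lb)*n + lb, n ~ U(0,1)."""
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if lb.shape != ub.shape:
        raise ValueError("bound vectors must have equal length")
    if np.any(lb > ub):
        raise ValueError("lower bound exceeds upper bound")
    rng = np.random.default_rng(params.seed)
    n = rng.random((params.M, lb.size))
    return FisherPopulation(
        positions=(ub - lb) * n + lb,
        fitness=np.full(params.M, np.inf),
        lb=lb, ub=ub, EFs=0, MaxEFs=params.MaxEFs, rng_seed=params.seed)


def independent_search(pop: FisherPopulation, j: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Move agent j relative to a random reference agent.

    Exp = (fit_j - fit_ref) / (fit_max - fit_min) (0 when degenerate);
    the drift is (x_ref - x_j) * Exp, and the noise is n_s * e * S with
    S = D * |Exp| * (1 - EFs/MaxEFs), D the distance to the reference,
    e a random unit vector and n_s ~ U(0,1).
    """
    m = len(pop.positions)
    if m < 2:
        raise ValueError("independent search needs at least two agents")
    pos = int(rng.integers(m - 1))
    if pos >= j:
        pos += 1
    fmax, fmin = float(pop.fitness.max()), float(pop.fitness.min())
    exp = 0.0 if fmax == fmin else (pop.fitness[j] - pop.fitness[pos]) / (fmax - fmin)
    diff = pop.positions[pos] - pop.positions[j]
    d = float(np.linalg.norm(diff))
    s = d * abs(exp) * (1.0 - pop.EFs / pop.MaxEFs)
    e = rng.standard_normal(diff.size)
    nrm = np.linalg.norm(e)
    e = e / nrm if nrm > 0 else e
    ns = rng.random()
    return pop.clamp(pop.positions[j] + diff * exp + ns * e * s)


def group_capture(pop: FisherPopulation, group, rng: np.random.Generator,
                  snapshot: np.ndarray | None = None) -> np.ndarray:
    """Contract a group of 3-4 agents toward its centroid.

    x_new = x + n2*(Center - x) + (1 - 2*EFs/MaxEFs)^2 * n3, with
    n2 ~ U(0,1) per agent and n3 ~ U(-1,1) per dimension.
    """
    group = list(group)
    if len(group) not in (3, 4):
        raise ValueError("group capture needs 3 or 4 agents")
    base = pop.positions if snapshot is None else snapshot
    center = base[group].mean(axis=0)
    decay = (1.0 - 2.0 * pop.EFs / pop.MaxEFs) ** 2
    out = np.empty((len(group), base.shape[1]))
    for i, j in enumerate(group):
        n2 = rng.random()
        n3 = rng.uniform(-1.0, 1.0, size=base.shape[1])
        out[i] = pop.clamp(base[j] + n2 * (center - base[j]) + decay * n3)
    return out


def _eta(EFs: int, MaxEFs: int) -> float:
    r = EFs / MaxEFs
    denom = (1.0 - 2.0 * r) ** 2
    if denom == 0.0:
        return 1.0
    return float(np.clip(2.0 * (1.0 - r) / denom, 0.0, 1.0))


def exploitation_step(pop: FisherPopulation,
                      rng: np.random.Generator) -> np.ndarray:
    """Redraw every agent from a Gaussian centered on the global best.

    The per-dimension *variance* is n4 * eta * |mean(Fisher) - Gbest| / 3
    with n4 in {1,2,3} per agent and eta shrinking from 1 to 0 over the
    exploitation half (clamped to [0,1]).  Treating the spread parameter
    as a variance (its square root is the standard deviation) keeps the
    sampling radius from collapsing geometrically with the population
    and lets the focal region be refined down to the budget's end.
    """
    eta = _eta(pop.EFs, pop.MaxEFs)
    spread = np.abs(pop.positions.mean(axis=0) - pop.Gbest) / 3.0
    out = np.empty_like(pop.positions)
    for i in range(len(out)):
        n4 = int(rng.integers(1, 4))
        out[i] = pop.clamp(pop.Gbest + rng.normal(
            0.0, 1.0, size=spread.size) * np.sqrt(n4 * eta * spread))
    return out


def _partition_groups(pool: list, rng: np.random.Generator):
    """Split indices into random groups of 3-4; leftovers of 1-2 search alone."""
    pool = list(pool)
    rng.shuffle(pool)
    groups, singles = [], []
    while pool:
        r = len(pool)
        if r < 3:
            singles.extend(pool)
            break
        if r in (3, 4):
            size = r
        elif r == 5 or r == 6:
            size = 3
        elif r == 7:
            size = 3
        else:
            size = int(rng.choice((3, 4)))
        groups.append(pool[:size])
        pool = pool[size:]
    return groups, singles


def optimize(fobj, lb, ub, params: CFOParams):
    """Run CFO; returns (Gbest, Gbest_fitness, trace of best-so-far fitness)."""
    pop = init_population(params, lb, ub)
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 1)))
    for j in range(params.M):
        pop.record(j, float(fobj(pop.positions[j])))
    while pop.EFs < pop.MaxEFs:
        n_eval = min(params.M, pop.MaxEFs - pop.EFs)
        snapshot = pop.positions.copy()
        proposals = snapshot.copy()
        if pop.EFs / pop.MaxEFs < params.phase_split:
            a_hat = capture_rate(pop.EFs, pop.MaxEFs)
            rho = rng.random(params.M)
            indep = [j for j in range(params.M) if rho[j] < a_hat]
            grouped = [j for j in range(params.M) if rho[j] >= a_hat]
            groups, singles = _partition_groups(grouped, rng)
            for j in indep + singles:
                proposals[j] = independent_search(pop, j, rng)
            for grp in groups:
                proposals[grp] = group_capture(pop, grp, rng, snapshot=snapshot)
        else:
            proposals = exploitation_step(pop, rng)
        for j in range(n_eval):
            pop.positions[j] = proposals[j]
            pop.record(j, float(fobj(pop.positions[j])))
    return pop.Gbest, pop.Gbest_fitness, pop.trace


# ---------------------------------------------------------------------------
# wrapper feature selection

def _inner_classifier_error(X, y, mask, seed, hidden=25, epochs=30,
                            repeats=1):
    """Stratified 80/20 holdout error of a small fixed network on masked features.

    With ``repeats`` > 1 the error is averaged over that many distinct
    (but seed-derived, hence deterministic) holdout splits, which makes
    the estimate finer-grained on small samples.
    """
    from .shallow_nets import MLP, stratified_split

    Xm = X[:, mask]
    total = 0.0
    for r in range(repeats):
        tr, te = stratified_split(y, test_fraction=0.2, seed=seed + 101 * r)
        clf = MLP([Xm.shape[1], hidden, int(y.max()) + 1], seed=seed)
        clf.fit(Xm[tr], y[tr], epochs=epochs, lr=0.05, momentum=0.9,
                batch_size=len(tr), seed=seed)
        total += float(np.mean(clf.predict(Xm[te]) != y[te]))
    return total / repeats


def select_features(X, y, lam: float = 0.05,
                    params: CFOParams | None = None,
                    repeats: int = 1) -> SelectionMask:
    """CFO wrapper feature selection over binary masks.

    Agents live in [0,1]^d; a position thresholded at 0.5 is the mask
    (an empty mask is repaired by activating the largest coordinate).
    Fitness = holdout error of the fixed inner classifier + lam *
    (selected/d), minimized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs at least two classes")
    if params is None:
        params = CFOParams()
    d = X.shape[1]
    cache: dict[bytes, float] = {}

    def fobj(pos):
        mask = pos > 0.5
        if not mask.any():
            mask = np.zeros(d, bool)
            mask[int(np.argmax(pos))] = True
        key = np.packbits(mask).tobytes()
        if key not in cache:
            err = _inner_classifier_error(X, y, mask, seed=params.seed,
                                          repeats=repeats)
            cache[key] = err + lam * mask.sum() / d
        return cache[key]

    gbest, gfit, trace = optimize(fobj, np.zeros(d), np.ones(d), params)
    mask = gbest > 0.5
    if not mask.any():
        mask = np.zeros(d, bool)
        mask[int(np.argmax(gbest))] = True
    return SelectionMask(mask=mask, fitness=float(gfit),
                         selected_count=int(mask.sum()))


def selection_objective(X, y, lam: float, seed: int, repeats: int = 1):
    """The exact mask-level objective used by ``select_features``.

    Exposed so an exhaustive search over all masks can serve as an
    independent optimum reference for small d.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    d = X.shape[1]

    def score(mask: np.ndarray) -> float:
        mask = np.asarray(mask, bool)
        return _inner_classifier_error(X, y, mask, seed=seed, repeats=repeats) \
            + lam * mask.sum() / d

    return score


# small registry of analytic test objectives
OBJECTIVES = {
    "sphere": lambda x: float(np.sum(np.square(x))),
    "quadratic": lambda x: float(np.sum((np.asarray(x) - 3.0) ** 2)),
    "rastrigin": lambda x: float(10 * len(np.atleast_1d(x)) + np.sum(
        np.square(x) - 10 * np.cos(2 * np.pi * np.asarray(x)))),
}
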