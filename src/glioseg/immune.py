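"""Artificial-immune-system optimizer with a quantum-inspired schedule.

Detectors are bit-string antibodies with a concentration, a tolerance
counter, an age and a match count, partitioned into immature, mature and
memory sets. The operators are the classic negative/clonal-selection
cycle: immature detectors that match a "self" pattern die (tolerance),
survivors mature; mature and memory detectors clone in proportion to
their affinity rank; clones mutate only on bits that disagree with the
guiding antigen; detectors that keep matching are promoted to memory
with reinforced concentration; concentrations decay with age.

Continuous variables use a swarm-style global-best attraction with a
linearly annealed inertial weight (0.9 -> 0.1 over the run) and an
exploration coefficient C_best = 2 (1 - J/MI) that scales a
bound-relative random step. Both encodings are combined to tune the
segmentation decision layer: a bit mask over hidden units plus
per-class additive score offsets, scored by validation Dice of the
whole-tumor region.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Detector",
    "Population",
    "affinity",
    "f_match",
    "tolerance_step",
    "clone_count",
    "clonal_selection",
    "immune_mutation",
    "expose_antigens",
    "promote_and_reinforce",
    "concentration_decay",
    "inertial_weight",
    "cbest",
    "position_update",
    "optimize",
    "OptimizeResult",
    "tune_decision_layer",
]


@dataclass(eq=False)
class Detector:
    """An antibody record: bit string + immune bookkeeping."""

    ab: np.ndarray          # uint8 bits
    p: float = 1.0          # concentration
    t: int = 0              # tolerance counter
    age: int = 0
    cnt: int = 0            # match count

    def __post_init__(self):
        self.ab = np.asarray(self.ab, dtype=np.uint8)

    def copy(self) -> "Detector":
        return Detector(self.ab.copy(), self.p, self.t, self.age, self.cnt)


@dataclass(eq=False)
class Population:
    """Immature / mature / memory detector sets plus thresholds.

    ``alpha`` is the tolerance threshold (steps an immature detector
    must survive), ``beta_act`` the activation (match-count) threshold
    for promotion to memory, ``gamma`` the affinity threshold of a
    match, ``lam_life`` the detector life cycle, ``eta1``/``eta2`` the
    memory reinforcement constants, ``theta_decay`` the decay horizon
    and ``xi`` the clone constant.
    """

    immature: list[Detector] = field(default_factory=list)
    mature: list[Detector] = field(default_factory=list)
    memory: list[Detector] = field(default_factory=list)
    self_set: list[np.ndarray] = field(default_factory=list)
    nonself_set: list[np.ndarray] = field(default_factory=list)
    alpha: int = 3
    lam_life: int = 30
    beta_act: int = 5
    gamma: float = 0.7
    eta1: float = 1.0
    eta2: float = 0.5
    theta_decay: int = 20
    xi: float = 8.0

    def all_detectors(self) -> list[Detector]:
        return self.immature + self.mature + self.memory

    def check_invariants(self) -> None:
        groups = [self.immature, self.mature, self.memory]
        ids = [id(d) for g in groups for d in g]
        if len(ids) != len(set(ids)):
            raise AssertionError("detector sets are not disjoint")


def affinity(ab: np.ndarray, ag: np.ndarray) -> float:
    """Fraction of matching bits (1 - normalized Hamming distance)."""
    ab = np.asarray(ab)
    ag = np.asarray(ag)
    if ab.shape != ag.shape:
        raise ValueError("bit strings must have equal length")
    return float(np.mean(ab == ag))


def f_match(ag: np.ndarray, detector: Detector | np.ndarray,
            gamma: float) -> int:
    """1 iff affinity strictly exceeds the threshold gamma."""
    ab = detector.ab if isinstance(detector, Detector) else detector
    return int(affinity(ab, ag) > gamma)


def tolerance_step(population: Population) -> Population:
    """Negative selection on the immature set.

    Immature detectors matching any self pattern are deleted; survivors
    age their tolerance counter and graduate to the mature set once it
    reaches ``alpha``. After this step no surviving detector in the
    mature or memory set matches self at threshold gamma.
    """
    pop = population
    survivors: list[Detector] = []
    for d in pop.immature:
        if any(f_match(s, d, pop.gamma) for s in pop.self_set):
            continue  # clonal deletion
        d.t += 1
        if d.t >= pop.alpha:
            pop.mature.append(d)
        else:
            survivors.append(d)
    pop.immature = survivors
    return pop


def clone_count(rank_nd: int, total_nd: int, xi: float) -> int:
    """Clone budget round(xi * (1 - rank/N)) for the rank-th detector."""
    if total_nd < 1 or not 0 <= rank_nd <= total_nd:
        raise ValueError("invalid rank or population size")
    return max(0, int(round(xi * (1.0 - rank_nd / total_nd))))


def _best_affinity(d: Detector, antigens: Sequence[np.ndarray]) -> float:
    return max((affinity(d.ab, ag) for ag in antigens), default=0.0)


def clonal_selection(
    population: Population, antigens: Sequence[np.ndarray]
) -> tuple[Population, list[Detector]]:
    """Affinity-proportional cloning of mature and memory detectors.

    Detectors in N_d = mature ∪ memory are ranked by best affinity to
    the antigen batch (rank 0 = highest); each receives
    ``clone_count(rank, |N_d|, xi)`` clones. Clones join the mature set
    while cloned mature parents are removed, matching the bookkeeping
    of the clonal-selection update. Returns the population and the list
    of fresh clones (so callers can mutate them).
    """
    pop = population
    nd = pop.mature + pop.memory
    if not nd or not antigens or pop.xi <= 0:
        return pop, []
    order = sorted(range(len(nd)),
                   key=lambda i: -_best_affinity(nd[i], antigens))
    clones: list[Detector] = []
    cloned_mature: set[int] = set()
    for rank, i in enumerate(order):
        c = clone_count(rank, len(nd), pop.xi)
        if c == 0:
            continue
        parent = nd[i]
        for _ in range(c):
            clones.append(parent.copy())
        if i < len(pop.mature):
            cloned_mature.add(id(parent))
    pop.mature = [d for d in pop.mature if id(d) not in cloned_mature]
    pop.mature.extend(clones)
    return pop, clones


def immune_mutation(
    detector: Detector,
    ag: np.ndarray,
    rng: np.random.Generator,
    p_mut: float = 0.1,
) -> Detector:
    """Directed mutation: only bits disagreeing with the antigen may
    flip, each independently with probability ``p_mut`` (flipping a
    mismatched bit makes it match). Returns a new detector."""
    if not 0.0 <= p_mut <= 1.0:
        raise ValueError("p_mut must lie in [0, 1]")
    ag = np.asarray(ag, dtype=np.uint8)
    out = detector.copy()
    eligible = out.ab != ag
    flips = eligible & (rng.random(out.ab.shape) < p_mut)
    out.ab[flips] = ag[flips]
    return out


def expose_antigens(population: Population,
                    antigens: Sequence[np.ndarray]) -> Population:
    """Increment match counts of mature/memory detectors that recognize
    any antigen in the batch."""
    for d in population.mature + population.memory:
        if any(f_match(ag, d, population.gamma) for ag in antigens):
            d.cnt += 1
    return population


def promote_and_reinforce(population: Population) -> Population:
    """Memory promotion and reinforcement.

    Mature detectors whose match count strictly exceeds the activation
    threshold move to memory with concentration eta1 and age reset.
    Memory detectors re-matched by the current nonself batch are
    reinforced: p <- eta1 + eta2 * p, age reset.
    """
    pop = population
    promoted = [d for d in pop.mature if d.cnt > pop.beta_act]
    pop.mature = [d for d in pop.mature if d.cnt <= pop.beta_act]
    for d in promoted:
        d.p = pop.eta1
        d.age = 0
        pop.memory.append(d)
    promoted_ids = {id(d) for d in promoted}
    for d in pop.memory:
        if id(d) in promoted_ids:
            continue
        if any(f_match(ag, d, pop.gamma) for ag in pop.nonself_set):
            d.p = pop.eta1 + pop.eta2 * d.p
            d.age = 0
    return pop


def concentration_decay(detector: Detector, theta_decay: int) -> Detector:
    """Age the detector and decay its concentration.

    p <- p * (1 - 1/(theta - age_old)) while the incremented age stays
    below theta; otherwise the concentration collapses to zero (the
    detector dies of old age).
    """
    if theta_decay <= 0:
        raise ValueError("theta_decay must be positive")
    age_old = detector.age
    detector.age += 1
    if detector.age < theta_decay:
        detector.p *= 1.0 - 1.0 / (theta_decay - age_old)
    else:
        detector.p = 0.0
    return detector


# --- continuous schedule -------------------------------------------------

def inertial_weight(J: int, MI: int) -> float:
    """Linearly annealed inertial weight, 0.9 at J=0 down to 0.1 at J=MI."""
    if MI < 1:
        raise ValueError("MI must be >= 1")
    if not 0 <= J <= MI:
        raise ValueError("J must lie in [0, MI]")
    return 0.9 - (0.9 - 0.1) / MI * J


def cbest(J: int, MI: int) -> float:
    """Exploration coefficient 2 (1 - J/MI), decreasing from 2 to 0."""
    if MI < 1:
        raise ValueError("MI must be >= 1")
    if not 0 <= J <= MI:
        raise ValueError("J must lie in [0, MI]")
    return 2.0 * (1.0 - J / MI)


def position_update(
    X: np.ndarray,
    X_gbest: np.ndarray,
    J: int,
    MI: int,
    bounds: tuple[np.ndarray, np.ndarray],
    alpha_rand: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Global-best attraction plus annealed bound-relative random step.

    X' = X + w(J) (X_gbest - X) + alpha_rand * Delta * (u - 1/2) with
    Delta = cbest(J, MI) * mean(UB - LB); the result is clipped to the
    bounds. At alpha_rand = 0 and X = X_gbest the update is a fixed
    point.
    """
    lb, ub = (np.asarray(b, dtype=float) for b in bounds)
    X = np.asarray(X, dtype=float)
    nv = lb.size
    delta = cbest(J, MI) * float(np.sum(ub - lb)) / nv
    w = inertial_weight(J, MI)
    step = alpha_rand * delta * (rng.random(X.shape) - 0.5)
    return np.clip(X + w * (np.asarray(X_gbest) - X) + step, lb, ub)


# --- optimizer -----------------------------------------------------------

@dataclass
class OptimizeResult:
    """Best solution found plus the per-cycle best-fitness trace."""

    x: np.ndarray
    fun: float
    trace: list[float]
    n_evals: int


def _optimize_continuous(objective, bounds, pop_size, n_iters, seed,
                         alpha_rand) -> OptimizeResult:
    lb, ub = (np.asarray(b, dtype=float) for b in bounds)
    rng = np.random.default_rng(seed)
    X = rng.uniform(lb, ub, size=(pop_size, lb.size))
    f = np.array([objective(x) for x in X])
    n_evals = pop_size
    ibest = int(np.argmin(f))
    gbest, gbest_f = X[ibest].copy(), float(f[ibest])
    trace = [gbest_f]
    for j in range(1, n_iters + 1):
        X = position_update(X, gbest, j, n_iters, (lb, ub), alpha_rand, rng)
        f = np.array([objective(x) for x in X])
        n_evals += pop_size
        ibest = int(np.argmin(f))
        if f[ibest] < gbest_f:
            gbest, gbest_f = X[ibest].copy(), float(f[ibest])
        trace.append(gbest_f)
    return OptimizeResult(gbest, gbest_f, trace, n_evals)


def _optimize_bits(objective, length, pop_size, clone_rate, n_iters, seed,
                   p_mut, n_random_antigens=3,
                   self_set=()) -> OptimizeResult:
    rng = np.random.default_rng(seed)
    xi = max(1.0, round(clone_rate * pop_size))
    pop = Population(xi=xi, alpha=1, self_set=list(self_set))
    pop.mature = [Detector(rng.integers(0, 2, size=length))
                  for _ in range(pop_size)]

    def evaluate(dets):
        return np.array([objective(d.ab.copy()) for d in dets])

    f = evaluate(pop.mature)
    n_evals = len(pop.mature)
    ibest = int(np.argmin(f))
    gbest = pop.mature[ibest].ab.copy()
    gbest_f = float(f[ibest])
    trace = [gbest_f]
    for _ in range(n_iters):
        antigens = [gbest.copy()] + [rng.integers(0, 2, size=length)
                                     for _ in range(n_random_antigens)]
        pop.nonself_set = antigens
        pop = tolerance_step(pop)
        pop = expose_antigens(pop, antigens)
        pop, clones = clonal_selection(pop, antigens)
        for i, c in enumerate(clones):
            mutated = immune_mutation(
                c, antigens[rng.integers(0, len(antigens))], rng, p_mut)
            c.ab = mutated.ab
        pop = promote_and_reinforce(pop)
        for d in pop.all_detectors():
            concentration_decay(d, pop.theta_decay)
        pop.mature = [d for d in pop.mature if d.p > 0]
        pop.memory = [d for d in pop.memory if d.p > 0]
        # fresh immature immigrants keep the repertoire diverse
        pop.immature.extend(
            Detector(rng.integers(0, 2, size=length))
            for _ in range(max(2, pop_size // 20))
        )
        candidates = pop.mature + pop.memory
        if not candidates:
            pop.mature = [Detector(rng.integers(0, 2, size=length))
                          for _ in range(pop_size)]
            candidates = pop.mature
        f = evaluate(candidates)
        n_evals += len(candidates)
        order = np.argsort(f)
        ibest = int(order[0])
        if f[ibest] < gbest_f:
            gbest = candidates[ibest].ab.copy()
            gbest_f = float(f[ibest])
        trace.append(gbest_f)
        # trim the mature set back to the population budget, best first
        keep = {id(candidates[i]) for i in order[:pop_size]}
        pop.mature = [d for d in pop.mature if id(d) in keep]
        pop.memory = [d for d in pop.memory if id(d) in keep]
    return OptimizeResult(gbest, gbest_f, trace, n_evals)


def optimize(
    objective: Callable[[np.ndarray], float],
    bounds: tuple | None = None,
    length: int | None = None,
    pop_size: int = 200,
    clone_rate: float = 0.04,
    n_iters: int = 10,
    seed: int | None = None,
    alpha_rand: float = 1.0,
    p_mut: float = 0.1,
) -> OptimizeResult:
    """Minimize a real-vector or bit-string objective.

    Continuous problems (``bounds`` given as (LB, UB) arrays) use the
    annealed global-best update; discrete problems (``length`` given)
    use the immune detector cycle. The best-so-far is elitist: the
    returned trace is non-increasing and the final solution never
    scores worse than the best of the initial population.
    """
    if (bounds is None) == (length is None):
        raise ValueError("give exactly one of bounds or length")
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    if bounds is not None:
        return _optimize_continuous(objective, bounds, pop_size, n_iters,
                                    seed, alpha_rand)
    return _optimize_bits(objective, length, pop_size, clone_rate, n_iters,
                          seed, p_mut)


# --- decision-layer tuning ----------------------------------------------

def tune_decision_layer(
    model,
    val_images: Sequence[np.ndarray],
    val_labels: Sequence[np.ndarray],
    seed: int | None = None,
    pop_size: int = 200,
    clone_rate: float = 0.04,
    n_iters: int = 10,
    p_mut: float = 0.1,
    offset_bound: float = 1.0,
):
    """Tune the segmentation decision layer by immune search.

    The search space is a bit mask over hidden units (the readout is
    re-solved on the masked units from the cached normal equations)
    plus per-class additive score offsets in [-offset_bound,
    offset_bound]. Fitness is the mean validation Dice of the whole-
    tumor region, maximized. The identity candidate (all units on, zero
    offsets) is seeded into the population, so the tuned model never
    scores below the untuned one on the validation set.

    Returns ``(tuned_model, result)`` where ``result.fun`` is the
    negative best validation Dice.
    """
    from . import metrics, network
    from .phantom import region_masks

    if len(val_images) == 0:
        raise ValueError("validation set is empty")
    if model.gram is None:
        raise ValueError("model carries no cached normal equations")
    rng = np.random.default_rng(seed)
    n_hidden = model.W.shape[1]
    n_classes = model.n_classes
    tumor_cols = np.isin(model.classes, [2, 3, 4])

    # hidden activations of the validation pixels, computed once
    H_val = [network._hidden_for_image(im, model) for im in val_images]
    shapes = [np.asarray(lb).shape for lb in val_labels]
    wt_true = [region_masks(lb).wt for lb in val_labels]

    def score(mask: np.ndarray, offsets: np.ndarray) -> float:
        mask = mask.astype(bool)
        if not mask.any():
            return 0.0
        beta = network.resolve_with_mask(model, mask)
        dices = []
        for Hv, shape, wt in zip(H_val, shapes, wt_true):
            s = Hv[:, mask] @ beta + offsets
            pred = model.classes[np.argmax(s, axis=1)].reshape(shape)
            dices.append(metrics.dice(region_masks(pred).wt, wt))
        return float(np.mean(dices))

    if n_iters == 0:
        return model, OptimizeResult(
            np.ones(n_hidden, dtype=np.uint8), -score(
                np.ones(n_hidden, dtype=bool), np.zeros(n_classes)),
            [], 0)

    lb = -offset_bound * np.ones(n_classes)
    ub = offset_bound * np.ones(n_classes)
    masks = rng.integers(0, 2, size=(pop_size, n_hidden)).astype(np.uint8)
    offsets = rng.uniform(lb, ub, size=(pop_size, n_classes))
    masks[0] = 1          # identity candidate
    offsets[0] = 0.0
    fitness = np.array([-score(masks[i], offsets[i])
                        for i in range(pop_size)])
    ib = int(np.argmin(fitness))
    g_mask, g_off = masks[ib].copy(), offsets[ib].copy()
    g_fit = float(fitness[ib])
    trace = [g_fit]
    n_evals = pop_size
    xi = max(1, int(round(clone_rate * pop_size)))
    for j in range(1, n_iters + 1):
        # clone the best-ranked candidates; mutate masks toward the
        # global best or a random antigen; move offsets by the schedule
        order = np.argsort(fitness)
        new_masks, new_offsets = [], []
        clone_budget = pop_size // 2
        for rank, i in enumerate(order):
            n_clones = min(clone_count(rank, pop_size, xi),
                           clone_budget - len(new_masks))
            for _ in range(n_clones):
                ag = (g_mask if rng.random() < 0.7
                      else rng.integers(0, 2, size=n_hidden).astype(np.uint8))
                mutated = immune_mutation(Detector(masks[i].copy()), ag, rng,
                                          p_mut)
                new_masks.append(mutated.ab)
                new_offsets.append(position_update(
                    offsets[i], g_off, j, n_iters, (lb, ub), 1.0, rng))
        keep = order[:max(1, pop_size - len(new_masks))]
        new_fit = np.array([-score(m, o)
                            for m, o in zip(new_masks, new_offsets)])
        masks = np.vstack([masks[keep]] + [m[None] for m in new_masks])
        offsets = np.vstack([offsets[keep]] + [o[None] for o in new_offsets])
        fitness = np.concatenate([fitness[keep], new_fit])
        n_evals += len(new_masks)
        ib = int(np.argmin(fitness))
        if fitness[ib] < g_fit:
            g_mask, g_off = masks[ib].copy(), offsets[ib].copy()
            g_fit = float(fitness[ib])
        trace.append(g_fit)

    tuned = copy.deepcopy(model)
    tuned.feature_mask = g_mask.astype(bool)
    tuned.logit_offsets = g_off
    tuned.beta_out = network.resolve_with_mask(model, tuned.feature_mask)
    return tuned, OptimizeResult(
        np.concatenate([g_mask, g_off]), g_fit, trace, n_evals)
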