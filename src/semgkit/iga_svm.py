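"""GA-tuned RBF-SVM with tiered championship selection (IGA-SVM).

An RBF support vector machine's penalty ``c`` and kernel width ``g``
are searched by a real-coded genetic algorithm operating on
``(log2 c, log2 g)``. Fitness of an individual is its stratified
k-fold cross-validated accuracy on the training set (fold split fixed
within a run so fitness comparisons are fair, and memoised per
``(c, g)``).

Plain tournament selection picks local winners and erodes population
diversity. The improved selection sorts the population by fitness into
four tiers — bad, medium, well, good — and retains each tier with
probability ``P, P+sigma, P+2*sigma, P+3*sigma`` respectively, then
refills the population elitistically from the good (and if needed
well) tiers. Strong individuals are kept with certainty at the default
``P=0.4, sigma=0.2`` while a fixed fraction of every tier survives,
preserving diversity. A plain tournament-selection GA with identical
operators is included as the comparison baseline.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ConfigError, DegenerateDataError
from .features import FeatureScaler

_TIERS = ("bad", "mid", "well", "good")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults follow the reference operating point: population ``C=2000``,
    crossover probability 0.7, mutation probability 0.1, base selection
    probability ``P=0.4`` with tier increment ``sigma=0.2`` (so the four
    tiers survive at rates 0.4/0.6/0.8/1.0), 50 generations, 5-fold CV
    fitness. Search ranges are in log2: ``c in [2^-5, 2^15]``,
    ``g in [2^-15, 2^3]``.
    """

    pop_size: int = 2000
    pc: float = 0.7
    pm: float = 0.1
    P: float = 0.4
    sigma: float = 0.2
    max_generations: int = 50
    target_fitness: float | None = None
    c_range: tuple[float, float] = (-5.0, 15.0)  # log2 bounds
    g_range: tuple[float, float] = (-15.0, 3.0)  # log2 bounds
    cv_folds: int = 5
    seed: int = 0
    selection: str = "tiered"  # or "tournament" (plain-GA baseline)
    tournament_size: int = 2
    mutation_scale: float = 0.1  # Gaussian sigma as a fraction of each range

    def __post_init__(self) -> None:
        if self.pop_size < 8:
            raise ConfigError(f"pop_size must be >= 8, got {self.pop_size}")
        if not (0 < self.P < 1 and 0 < self.sigma < 1):
            raise ConfigError("need 0 < P < 1 and 0 < sigma < 1")
        if self.P + 3 * self.sigma > 1 + 1e-12:
            raise ConfigError("need P + 3*sigma <= 1")
        if not (0 <= self.pc <= 1 and 0 <= self.pm <= 1):
            raise ConfigError("pc, pm must lie in [0, 1]")
        if self.c_range[0] >= self.c_range[1] or self.g_range[0] >= self.g_range[1]:
            raise ConfigError("empty search range")
        if self.max_generations < 0 or self.cv_folds < 2:
            raise ConfigError("max_generations >= 0 and cv_folds >= 2 required")
        if self.selection not in ("tiered", "tournament"):
            raise ConfigError(f"unknown selection scheme {self.selection!r}")


@dataclass
class Individual:
    """One candidate ``(c, g)`` pair with its CV-accuracy fitness."""

    c: float
    g: float
    fitness: float | None = None

    def __post_init__(self) -> None:
        if self.c <= 0 or self.g <= 0:
            raise ConfigError("c and g must be positive")
        if self.fitness is not None and not 0 <= self.fitness <= 1:
            raise ConfigError("fitness must lie in [0, 1]")


@dataclass
class Population:
    """GA population state. After :func:`sort_and_tier`, ``members`` is
    in ascending fitness order and ``tier_counts`` records the sizes of
    the (bad, mid, well, good) tiers."""

    members: list[Individual]
    generation: int = 0
    tier_counts: tuple[int, int, int, int] | None = None
    selected_count: int | None = None

    def __len__(self) -> int:
        return len(self.members)

    def tier(self, name: str) -> list[Individual]:
        if self.tier_counts is None:
            raise ConfigError("population is not tiered; call sort_and_tier first")
        k = _TIERS.index(name)
        start = sum(self.tier_counts[:k])
        return self.members[start : start + self.tier_counts[k]]


def init_population(config: GAConfig, rng: np.random.Generator | None = None) -> Population:
    """Seeded uniform initialisation of ``(log2 c, log2 g)`` in range."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lc = rng.uniform(*config.c_range, size=config.pop_size)
    lg = rng.uniform(*config.g_range, size=config.pop_size)
    return Population([Individual(c=float(2.0**a), g=float(2.0**b)) for a, b in zip(lc, lg)])


def make_cv_splits(y: np.ndarray, cv_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """One stratified, shuffled fold split reused for every individual in
    a run so fitness values are comparable."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DegenerateDataError("need >= 2 classes to evaluate fitness")
    if counts.min() < cv_folds:
        raise DegenerateDataError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} samples; "
            f"need >= cv_folds={cv_folds}"
        )
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    c: float,
    g: float,
    splits: list[tuple[np.ndarray, np.ndarray]],
) -> float:
    """Mean held-out accuracy of ``SVC(C=c, gamma=g)`` over given folds."""
    accs = []
    for tr, te in splits:
        clf = SVC(C=c, gamma=g, kernel="rbf")
        clf.fit(X[tr], y[tr])
        accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def evaluate_fitness(
    ind: Individual, Xp: np.ndarray, Yp: np.ndarray, cv_folds: int = 5, seed: int = 0
) -> float:
    """Stratified ``cv_folds``-fold CV accuracy of one individual."""
    splits = make_cv_splits(np.asarray(Yp), cv_folds, seed)
    return cv_accuracy(np.asarray(Xp, dtype=float), np.asarray(Yp), ind.c, ind.g, splits)


def sort_and_tier(pop: Population) -> Population:
    """Sort ascending by fitness (ties broken by ``(c, g,`` insertion
    index) for determinism) and split into bad/mid/well/good quarters,
    the remainder going to the good tier."""
    if any(m.fitness is None for m in pop.members):
        raise ConfigError("all individuals must be evaluated before tiering")
    order = sorted(range(len(pop)), key=lambda i: (pop.members[i].fitness,
                                                   pop.members[i].c, pop.members[i].g, i))
    members = [pop.members[i] for i in order]
    q = len(members) // 4
    tiers = (q, q, q, len(members) - 3 * q)
    return Population(members, generation=pop.generation, tier_counts=tiers)


def tiered_select(
    pop: Population, P: float, sigma: float, rng: np.random.Generator
) -> list[Individual]:
    """From each tier draw ``floor(tier_size * tier_probability)``
    members uniformly without replacement; tier probabilities are
    ``P, P+sigma, P+2*sigma, P+3*sigma`` from bad to good."""
    selected: list[Individual] = []
    for k, name in enumerate(_TIERS):
        tier = pop.tier(name)
        # tiny epsilon so exact-integer products are not floored down by fp error
        take = int(len(tier) * (P + k * sigma) + 1e-9)
        if take > 0:
            idx = rng.choice(len(tier), size=take, replace=False)
            selected.extend(tier[i] for i in sorted(idx))
    return selected


def refill_population(
    selected: list[Individual], pop: Population, rng: np.random.Generator
) -> list[Individual]:
    """Top the selection back up to the full population size.

    The ``C - Cnew`` vacancies are filled from the good tier when it
    suffices, else the whole good tier plus random members of the well
    tier (survival of the fittest; duplicates with the selection are
    permitted). Returns a list of exactly ``C`` individuals.
    """
    C = len(pop)
    need = C - len(selected)
    if need < 0:
        raise ConfigError("selection larger than population")
    good, well = pop.tier("good"), pop.tier("well")
    refill: list[Individual] = []
    if need <= len(good):
        idx = rng.choice(len(good), size=need, replace=False)
        refill.extend(good[i] for i in sorted(idx))
    else:
        refill.extend(good)
        extra = need - len(good)
        if extra > len(well):
            raise ConfigError("refill exceeds the well tier; selection probabilities too low")
        idx = rng.choice(len(well), size=extra, replace=False)
        refill.extend(well[i] for i in sorted(idx))
    return selected + refill


def crossover(
    parent_a: Individual,
    parent_b: Individual,
    pc: float,
    rng: np.random.Generator,
    config: GAConfig,
) -> tuple[Individual, Individual]:
    """Arithmetic-blend crossover in ``(log2 c, log2 g)`` space.

    With probability ``pc`` the children are ``alpha*a + (1-alpha)*b``
    and the mirror blend (``alpha`` uniform per gene), clipped to range;
    otherwise copies of the parents.
    """
    if rng.random() >= pc:
        return copy.copy(parent_a), copy.copy(parent_b)
    a = np.array([np.log2(parent_a.c), np.log2(parent_a.g)])
    b = np.array([np.log2(parent_b.c), np.log2(parent_b.g)])
    alpha = rng.random(2)
    ca = _clip_genes(alpha * a + (1 - alpha) * b, config)
    cb = _clip_genes(alpha * b + (1 - alpha) * a, config)
    return (
        Individual(c=float(2.0 ** ca[0]), g=float(2.0 ** ca[1])),
        Individual(c=float(2.0 ** cb[0]), g=float(2.0 ** cb[1])),
    )


def mutate(
    ind: Individual, pm: float, rng: np.random.Generator, config: GAConfig
) -> Individual:
    """Per-gene Gaussian perturbation in log2 space (scale
    ``mutation_scale`` of each range), clipped; fitness is reset when a
    gene changes."""
    genes = np.array([np.log2(ind.c), np.log2(ind.g)])
    spans = np.array(
        [config.c_range[1] - config.c_range[0], config.g_range[1] - config.g_range[0]]
    )
    hit = rng.random(2) < pm
    noise = rng.standard_normal(2) * config.mutation_scale * spans
    if not hit.any():
        return copy.copy(ind)
    genes = _clip_genes(genes + hit * noise, config)
    return Individual(c=float(2.0 ** genes[0]), g=float(2.0 ** genes[1]))


def _clip_genes(genes: np.ndarray, config: GAConfig) -> np.ndarray:
    return np.array(
        [
            np.clip(genes[0], *config.c_range),
            np.clip(genes[1], *config.g_range),
        ]
    )


@dataclass
class EvolutionResult:
    """Outcome of a GA run: the best-ever ``(c, g)``, its fitness, and a
    per-generation history of best / mean / best-so-far fitness."""

    best_c: float
    best_g: float
    best_fitness: float
    history: list[dict]


def evolve(Xp: np.ndarray, Yp: np.ndarray, config: GAConfig) -> EvolutionResult:
    """Run the GA loop: evaluate, (tiered or tournament) select, refill,
    crossover, mutate; until ``target_fitness`` or ``max_generations``.

    Deterministic under a fixed ``config.seed``; best-so-far fitness is
    non-decreasing across generations.
    """
    Xp = np.asarray(Xp, dtype=float)
    Yp = np.asarray(Yp)
    rng = np.random.default_rng(config.seed)
    cv_seed = int(rng.integers(0, 2**31 - 1))
    splits = make_cv_splits(Yp, config.cv_folds, cv_seed)
    cache: dict[tuple[float, float], float] = {}

    def fitness_of(ind: Individual) -> float:
        key = (ind.c, ind.g)
        if key not in cache:
            cache[key] = cv_accuracy(Xp, Yp, ind.c, ind.g, splits)
        return cache[key]

    pop = init_population(config, rng)
    best: Individual | None = None
    history: list[dict] = []
    for gen in range(config.max_generations + 1):
        for ind in pop.members:
            if ind.fitness is None:
                ind.fitness = fitness_of(ind)
        fits = np.array([m.fitness for m in pop.members])
        gen_best = pop.members[int(fits.argmax())]
        if best is None or gen_best.fitness > best.fitness:
            best = copy.copy(gen_best)
        history.append(
            {
                "generation": gen,
                "best_fitness": float(fits.max()),
                "mean_fitness": float(fits.mean()),
                "best_so_far": float(best.fitness),
            }
        )
        done = gen == config.max_generations or (
            config.target_fitness is not None and best.fitness >= config.target_fitness
        )
        if done:
            break
        if config.selection == "tiered":
            tiered = sort_and_tier(pop)
            selected = tiered_select(tiered, config.P, config.sigma, rng)
            members = refill_population(selected, tiered, rng)
            assert len(members) == config.pop_size
        else:  # plain tournament baseline
            members = []
            for _ in range(config.pop_size):
                idx = rng.integers(0, config.pop_size, size=config.tournament_size)
                winner = max((pop.members[i] for i in idx), key=lambda m: m.fitness)
                members.append(copy.copy(winner))
        order = rng.permutation(len(members))
        paired: list[Individual] = [None] * len(members)  # type: ignore[list-item]
        for k in range(0, len(order) - 1, 2):
            i, j = order[k], order[k + 1]
            paired[i], paired[j] = crossover(members[i], members[j], config.pc, rng, config)
        if len(order) % 2:
            i = order[-1]
            paired[i] = copy.copy(members[i])
        members = [mutate(ind, config.pm, rng, config) for ind in paired]
        # keep known fitness for individuals that survived variation unchanged
        for new, old in zip(members, paired):
            if new.c == old.c and new.g == old.g and old.fitness is not None:
                new.fitness = old.fitness
        pop = Population(members, generation=gen + 1)
    return EvolutionResult(best.c, best.g, float(best.fitness), history)


@dataclass
class TrainedModel:
    """A fitted multiclass (one-vs-one) RBF-SVM with its tuned
    hyperparameters and, optionally, the feature scaler and GA history."""

    best_c: float
    best_g: float
    classifier: SVC
    classes: np.ndarray
    fitness_history: list[dict] = field(default_factory=list)
    scaler: FeatureScaler | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.classifier.predict(X)


def train(
    Xp: np.ndarray,
    Yp: np.ndarray,
    best_c: float,
    best_g: float,
    fitness_history: list[dict] | None = None,
    scaler: FeatureScaler | None = None,
) -> TrainedModel:
    """Fit the final multiclass RBF-SVM at the tuned ``(c, g)``."""
    Xp = np.asarray(Xp, dtype=float)
    Yp = np.asarray(Yp)
    if len(np.unique(Yp)) < 2:
        raise DegenerateDataError("need >= 2 classes to train")
    clf = SVC(C=best_c, gamma=best_g, kernel="rbf")
    clf.fit(Xp, Yp)
    return TrainedModel(
        best_c=best_c,
        best_g=best_g,
        classifier=clf,
        classes=clf.classes_,
        fitness_history=fitness_history or [],
        scaler=scaler,
    )


def evaluate(
    model: TrainedModel, XT: np.ndarray, YT: np.ndarray
) -> tuple[float, dict[str, float], np.ndarray]:
    """Test-set accuracy, per-class accuracy, and the confusion matrix
    (rows = actual, columns = predicted, in ``model.classes`` order)."""
    XT = np.asarray(XT, dtype=float)
    YT = np.asarray(YT)
    unknown = set(YT) - set(model.classes)
    if unknown:
        raise DegenerateDataError(f"test labels outside training classes: {sorted(unknown)}")
    pred = model.predict(XT)
    classes = list(model.classes)
    k = len(classes)
    cm = np.zeros((k, k), dtype=int)
    idx = {c: i for i, c in enumerate(classes)}
    for a, p in zip(YT, pred):
        cm[idx[a], idx[p]] += 1
    acc = float(np.trace(cm) / cm.sum())
    per_class = {
        c: (float(cm[i, i] / cm[i].sum()) if cm[i].sum() else float("nan"))
        for i, c in enumerate(classes)
    }
    return acc, per_class, cm


def save_model(model: TrainedModel, Xp: np.ndarray, Yp: np.ndarray, path: str | Path) -> None:
    """Persist a model as JSON: tuned ``(c, g)``, classes, scaler
    parameters and the training matrix. Loading refits the SVM, which
    is deterministic, so the JSON fully reproduces the model without
    serialising solver internals."""
    doc = {
        "best_c": model.best_c,
        "best_g": model.best_g,
        "classes": [str(c) for c in model.classes],
        "scaler": None
        if model.scaler is None
        else {
            "center": model.scaler.center.tolist(),
            "half_range": model.scaler.half_range.tolist(),
        },
        "X_train": np.asarray(Xp, dtype=float).tolist(),
        "y_train": [str(v) for v in np.asarray(Yp)],
        "fitness_history": model.fitness_history,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str | Path) -> TrainedModel:
    """Reconstruct a model saved by :func:`save_model` by refitting."""
    with open(path) as fh:
        doc = json.load(fh)
    scaler = None
    if doc["scaler"] is not None:
        scaler = FeatureScaler(
            center=np.asarray(doc["scaler"]["center"]),
            half_range=np.asarray(doc["scaler"]["half_range"]),
        )
    model = train(
        np.asarray(doc["X_train"], dtype=float),
        np.asarray(doc["y_train"]),
        doc["best_c"],
        doc["best_g"],
        fitness_history=doc.get("fitness_history"),
        scaler=scaler,
    )
    return model
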