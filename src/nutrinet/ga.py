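"""Genetic-algorithm search over factor subsets and network hyperparameters.

Each individual is a fixed-length binary chromosome whose leading segment
is a factor-inclusion mask and whose trailing segments encode four
training hyperparameters.  At the study's 63 factors the layout is
76 = 63 (mask) + 4 (hidden neurons) + 3 (initial-weight range) +
4 (momentum) + 2 (learning rate); the mask segment adapts to the
cohort's factor count in general.

Each chromosome is scored by the same 3-CV fitness the backward
elimination uses (three networks trained per chromosome); scores are
cached by bit pattern, and per-chromosome training seeds derive from
(global seed, bits), making fitness a pure function of the chromosome.

One generation applies, in order: fitness evaluation, the dimensionality
penalty (chromosomes whose mask selects more than T factors — or none —
are reassigned 50% of the average fitness of the unpenalized members),
elitist fitness-proportionate selection (the single best chromosome is
copied unchanged into the next generation), two-point crossover with
probability Pc, per-bit mutation with probability Pm, and the election
operator, which keeps the two fittest members of each
parents+offspring family so offspring worse than both parents never
enter the population.  Defaults: M=100 chromosomes, 50 generations,
Pc=0.7, Pm=0.01.

The hyperparameter value tables are configuration (the defaults below
include the backward-elimination settings lr=0.01, mc=0.9 so that
configuration is reachable).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .ann import NetworkConfig
from .encoding import Cohort, EncodedMatrix, encode
from .evaluation import CVPlan, FoldResult, cross_validate, fitness, make_3cv

__all__ = [
    "Codec",
    "GAConfig",
    "EvolutionTrace",
    "decode",
    "encode_chromosome",
    "evaluate_chromosome",
    "apply_penalty",
    "roulette_select",
    "two_point_crossover",
    "mutate",
    "election",
    "evolve",
]


def _bits_to_int(bits: np.ndarray) -> int:
    return int("".join(map(str, bits.astype(int))), 2)


def _int_to_bits(value: int, width: int) -> np.ndarray:
    return np.array([int(b) for b in format(value, f"0{width}b")], dtype=np.uint8)


@dataclass(frozen=True)
class Codec:
    """Segment layout and hyperparameter lookup tables of the chromosome.

    Hidden-neuron count decodes as 1 + binary value of its segment
    (range 1..16); the other three segments index their value tables.
    """

    n_factors: int = 63
    hidden_bits: int = 4
    weight_bits: int = 3
    momentum_bits: int = 4
    lr_bits: int = 2
    weight_table: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0, 2.0)
    momentum_table: tuple[float, ...] = tuple(
        round(v, 6) for v in np.linspace(0.0, 0.9, 16)
    )
    lr_table: tuple[float, ...] = (0.001, 0.005, 0.01, 0.05)

    def __post_init__(self) -> None:
        if len(self.weight_table) != 2**self.weight_bits:
            raise ValueError("weight_table must have 2**weight_bits entries")
        if len(self.momentum_table) != 2**self.momentum_bits:
            raise ValueError("momentum_table must have 2**momentum_bits entries")
        if len(self.lr_table) != 2**self.lr_bits:
            raise ValueError("lr_table must have 2**lr_bits entries")

    @property
    def length(self) -> int:
        return (
            self.n_factors
            + self.hidden_bits
            + self.weight_bits
            + self.momentum_bits
            + self.lr_bits
        )

    def segments(self, bits: np.ndarray) -> dict[str, np.ndarray]:
        if bits.shape != (self.length,):
            raise ValueError(
                f"chromosome length {bits.shape} != codec length {self.length}"
            )
        cuts = np.cumsum(
            [self.n_factors, self.hidden_bits, self.weight_bits, self.momentum_bits]
        )
        mask, h, w, m, l = np.split(bits, cuts)
        return {"mask": mask, "hidden": h, "weight": w, "momentum": m, "lr": l}


def decode(
    bits: np.ndarray, codec: Codec
) -> tuple[np.ndarray, dict[str, float | int]]:
    """Chromosome -> (selected factor indices, decoded hyperparameters)."""
    seg = codec.segments(np.asarray(bits, dtype=np.uint8))
    factors = np.flatnonzero(seg["mask"])
    hyper = {
        "n_hidden": 1 + _bits_to_int(seg["hidden"]),
        "init_weight_range": codec.weight_table[_bits_to_int(seg["weight"])],
        "mc": codec.momentum_table[_bits_to_int(seg["momentum"])],
        "lr0": codec.lr_table[_bits_to_int(seg["lr"])],
    }
    return factors, hyper


def encode_chromosome(
    factors: Sequence[int],
    n_hidden: int,
    init_weight_range: float,
    mc: float,
    lr0: float,
    codec: Codec,
) -> np.ndarray:
    """Inverse of :func:`decode`; values must be entries of the codec tables."""
    bits = np.zeros(codec.length, dtype=np.uint8)
    bits[np.asarray(factors, dtype=int)] = 1
    off = codec.n_factors
    if not 1 <= n_hidden <= 2**codec.hidden_bits:
        raise ValueError(f"n_hidden {n_hidden} outside codec range")
    bits[off : off + codec.hidden_bits] = _int_to_bits(n_hidden - 1, codec.hidden_bits)
    off += codec.hidden_bits
    bits[off : off + codec.weight_bits] = _int_to_bits(
        codec.weight_table.index(init_weight_range), codec.weight_bits
    )
    off += codec.weight_bits
    idx = int(np.argmin(np.abs(np.asarray(codec.momentum_table) - mc)))
    if not np.isclose(codec.momentum_table[idx], mc, atol=1e-9):
        raise ValueError(f"momentum {mc} not in codec table")
    bits[off : off + codec.momentum_bits] = _int_to_bits(idx, codec.momentum_bits)
    off += codec.momentum_bits
    bits[off : off + codec.lr_bits] = _int_to_bits(
        codec.lr_table.index(lr0), codec.lr_bits
    )
    return bits


@dataclass(frozen=True)
class GAConfig:
    """Evolution-loop parameters (defaults match the study settings)."""

    population_size: int = 100
    n_generations: int = 50
    pc: float = 0.7  # crossover probability per pair
    pm: float = 0.01  # mutation probability per bit
    T: int | None = None  # dimensionality threshold; None = unbounded
    n_elite: int = 1
    seed: int = 0
    selection: Literal["roulette", "tournament"] = "roulette"
    election_mode: Literal["family", "offspring_parent"] = "family"
    codec: Codec = field(default_factory=Codec)
    max_epochs: int = 300
    tournament_size: int = 3

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be an even integer >= 2")
        if not (0 <= self.pc <= 1 and 0 <= self.pm <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.T is not None and self.T < 1:
            raise ValueError("T must be >= 1 or None")


@dataclass
class GenerationStats:
    generation: int
    mean_fitness: float
    best_fitness: float
    best_chromosome: np.ndarray


@dataclass
class EvolutionTrace:
    """Per-generation fitness summaries and the best network found."""

    generations: list[GenerationStats]
    best_chromosome: np.ndarray
    best_fitness: float
    best_factors: np.ndarray
    best_hyper: dict[str, float | int]
    best_fold_result: FoldResult | None
    n_trainings: int
    n_unique_evaluated: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": [g.generation for g in self.generations],
                "mean_fitness": [round(g.mean_fitness, 2) for g in self.generations],
                "best_fitness": [round(g.best_fitness, 2) for g in self.generations],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "generations": self.to_dataframe().to_dict(orient="records"),
            "best_fitness": self.best_fitness,
            "best_chromosome": self.best_chromosome.astype(int).tolist(),
            "best_factors": self.best_factors.astype(int).tolist(),
            "best_hyper": self.best_hyper,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# operators


def roulette_select(
    fitnesses: np.ndarray, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Fitness-proportionate sampling of ``size`` indices (with replacement)."""
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("empty population")
    f = np.clip(f, 0.0, None)
    total = f.sum()
    p = np.full(f.size, 1.0 / f.size) if total <= 0 else f / total
    return rng.choice(f.size, size=size, replace=True, p=p)


def tournament_select(
    fitnesses: np.ndarray, rng: np.random.Generator, size: int, k: int
) -> np.ndarray:
    f = np.asarray(fitnesses, dtype=float)
    picks = rng.integers(0, f.size, size=(size, k))
    return picks[np.arange(size), np.argmax(f[picks], axis=1)]


def two_point_crossover(
    a: np.ndarray, b: np.ndarray, pc: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Swap the segment between two random cut points with probability pc."""
    a, b = a.copy(), b.copy()
    if rng.random() < pc:
        lo, hi = sorted(rng.choice(len(a) + 1, size=2, replace=False))
        a[lo:hi], b[lo:hi] = b[lo:hi].copy(), a[lo:hi].copy()
    return a, b


def mutate(bits: np.ndarray, pm: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability pm."""
    flips = rng.random(len(bits)) < pm
    out = bits.copy()
    out[flips] ^= 1
    return out


def election(
    parents: Sequence[np.ndarray],
    offspring: Sequence[np.ndarray],
    fitnesses: Sequence[float],
    mode: Literal["family", "offspring_parent"] = "family",
) -> tuple[np.ndarray, np.ndarray]:
    """Survival rule on one family of 2 parents + 2 offspring.

    ``family`` (default) keeps the two fittest of the four, so an
    offspring less fit than both parents never enters the next
    generation.  ``offspring_parent`` compares each offspring with the
    same-slot parent and keeps the fitter of each pair.
    """
    members = list(parents) + list(offspring)
    f = np.asarray(fitnesses, dtype=float)
    if len(members) != 4 or f.shape != (4,):
        raise ValueError("election expects 2 parents + 2 offspring with fitnesses")
    if mode == "family":
        # stable sort: ties favour parents (listed first)
        order = np.argsort(-f, kind="stable")[:2]
        return members[order[0]], members[order[1]]
    keep0 = members[2] if f[2] > f[0] else members[0]
    keep1 = members[3] if f[3] > f[1] else members[1]
    return keep0, keep1


def apply_penalty(
    fitnesses: np.ndarray, masks_sizes: np.ndarray, T: int | None
) -> np.ndarray:
    """Reassign oversized (or empty-mask) chromosomes half the average fitness.

    The average is taken over the current generation's unpenalized
    members; with every chromosome penalized the overall mean is used
    instead (with a warning).  ``T=None`` disables the size limit, but
    empty masks are always penalized.
    """
    f = np.asarray(fitnesses, dtype=float).copy()
    sizes = np.asarray(masks_sizes)
    bad = sizes == 0
    if T is not None:
        bad |= sizes > T
    if not bad.any():
        return f
    if bad.all():
        warnings.warn("every chromosome penalized; using overall mean", stacklevel=2)
        penalty = 0.5 * float(f.mean())
    else:
        penalty = 0.5 * float(f[~bad].mean())
    f[bad] = penalty
    return f


# ---------------------------------------------------------------------------
# evaluation with cache


class FitnessCache:
    """Raw 3-CV fitness per chromosome bit pattern; counts trainings."""

    def __init__(self) -> None:
        self._store: dict[bytes, tuple[float, int]] = {}
        self.n_trainings = 0

    def __len__(self) -> int:
        return len(self._store)

    def get(self, key: bytes):
        return self._store.get(key)

    def put(self, key: bytes, value: tuple[float, int]) -> None:
        self._store[key] = value


def evaluate_chromosome(
    bits: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    ga_config: GAConfig,
    cache: FitnessCache,
) -> tuple[float, int]:
    """Raw 3-CV fitness of one chromosome (cached by bit pattern).

    Returns (fitness %, mask size).  An empty feature mask is infeasible
    and scores 0 (the penalty step reassigns it).  The training seed
    derives from (global seed, bits), so the value is a pure function of
    the chromosome.
    """
    bits = np.asarray(bits, dtype=np.uint8)
    key = bits.tobytes()
    hit = cache.get(key)
    if hit is not None:
        return hit
    factors, hyper = decode(bits, ga_config.codec)
    if factors.size == 0:
        result = (0.0, 0)
        cache.put(key, result)
        return result
    cfg = NetworkConfig(
        n_inputs=factors.size,
        n_hidden=int(hyper["n_hidden"]),
        init_weight_range=float(hyper["init_weight_range"]),
        lr0=float(hyper["lr0"]),
        mc=float(hyper["mc"]),
        max_epochs=ga_config.max_epochs,
    )
    fr = cross_validate(
        X[:, factors],
        y,
        cfg,
        plan,
        derive_seed(ga_config.seed, key),
        keep_networks=False,
    )
    cache.n_trainings += len(plan.folds)
    result = (fitness(fr), int(factors.size))
    cache.put(key, result)
    return result


# ---------------------------------------------------------------------------
# the evolution loop


def evolve(
    data: Cohort | EncodedMatrix,
    ga_config: GAConfig,
    plan: CVPlan | None = None,
) -> EvolutionTrace:
    """Run the full GA: evaluate, penalize, select, cross over, mutate, elect.

    Elitism copies the best chromosome unchanged into each new
    generation, and together with the election operator makes the
    best-so-far fitness non-decreasing.  The reported optimum is the best
    feasible (unpenalized) chromosome ever evaluated.
    """
    mat = encode(data) if isinstance(data, Cohort) else data
    X, y = mat.X, mat.y
    codec = ga_config.codec
    if codec.n_factors != X.shape[1]:
        codec = replace(codec, n_factors=X.shape[1])
        ga_config = replace(ga_config, codec=codec)
    if plan is None:
        plan = make_3cv(X.shape[0], derive_seed(ga_config.seed, "cv"), y)
    rng = np.random.default_rng(derive_seed(ga_config.seed, "ga"))
    cache = FitnessCache()
    M = ga_config.population_size

    pop = [
        (rng.random(codec.length) < 0.5).astype(np.uint8) for _ in range(M)
    ]

    def feasible(size: int) -> bool:
        return size > 0 and (ga_config.T is None or size <= ga_config.T)

    best_bits: np.ndarray | None = None
    best_fit = -np.inf
    stats: list[GenerationStats] = []

    for gen in range(ga_config.n_generations):
        raw = np.empty(M)
        sizes = np.empty(M, dtype=int)
        for i, bits in enumerate(pop):
            raw[i], sizes[i] = evaluate_chromosome(
                bits, X, y, plan, ga_config, cache
            )
        adjusted = apply_penalty(raw, sizes, ga_config.T)
        for i in range(M):
            if feasible(sizes[i]) and raw[i] > best_fit:
                best_fit, best_bits = raw[i], pop[i].copy()
        stats.append(
            GenerationStats(
                generation=gen,
                mean_fitness=float(adjusted.mean()),
                best_fitness=float(best_fit),
                best_chromosome=best_bits.copy() if best_bits is not None else None,
            )
        )
        if gen == ga_config.n_generations - 1:
            break

        feas = np.array([feasible(s) for s in sizes])
        penalty_value = (
            0.5 * float(raw[feas].mean()) if feas.any() else 0.5 * float(raw.mean())
        )

        if ga_config.selection == "roulette":
            pool_idx = roulette_select(adjusted, rng, M)
        else:
            pool_idx = tournament_select(
                adjusted, rng, M, ga_config.tournament_size
            )
        next_pop: list[np.ndarray] = []
        for j in range(0, M, 2):
            p1, p2 = pop[pool_idx[j]], pop[pool_idx[j + 1]]
            o1, o2 = two_point_crossover(p1, p2, ga_config.pc, rng)
            o1 = mutate(o1, ga_config.pm, rng)
            o2 = mutate(o2, ga_config.pm, rng)
            fam = []
            for bits in (p1, p2, o1, o2):
                f_raw, size = evaluate_chromosome(
                    bits, X, y, plan, ga_config, cache
                )
                if feasible(size):
                    fam.append(f_raw)
                    if f_raw > best_fit:
                        best_fit, best_bits = f_raw, bits.copy()
                else:
                    fam.append(penalty_value)
            s1, s2 = election(
                (p1, p2), (o1, o2), fam, mode=ga_config.election_mode
            )
            next_pop.extend([s1, s2])
        # elitism: the best-ever feasible chromosome replaces the weakest slot
        if ga_config.n_elite > 0 and best_bits is not None:
            keys = {b.tobytes() for b in next_pop}
            if best_bits.tobytes() not in keys:
                fits = [
                    evaluate_chromosome(b, X, y, plan, ga_config, cache)[0]
                    for b in next_pop
                ]
                next_pop[int(np.argmin(fits))] = best_bits.copy()
        pop = next_pop

    if best_bits is None:
        warnings.warn("no feasible chromosome found; returning best penalized")
        idx = int(np.argmax(raw))
        best_bits, best_fit = pop[idx], float(raw[idx])
    factors, hyper = decode(best_bits, codec)
    fold_result = None
    if factors.size:
        cfg = NetworkConfig(
            n_inputs=factors.size,
            n_hidden=int(hyper["n_hidden"]),
            init_weight_range=float(hyper["init_weight_range"]),
            lr0=float(hyper["lr0"]),
            mc=float(hyper["mc"]),
            max_epochs=ga_config.max_epochs,
        )
        fold_result = cross_validate(
            X[:, factors],
            y,
            cfg,
            plan,
            derive_seed(ga_config.seed, best_bits.tobytes()),
        )
    return EvolutionTrace(
        generations=stats,
        best_chromosome=best_bits,
        best_fitness=float(best_fit),
        best_factors=factors,
        best_hyper=hyper,
        best_fold_result=fold_result,
        n_trainings=cache.n_trainings,
        n_unique_evaluated=len(cache),
        seed=ga_config.seed,
    )
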