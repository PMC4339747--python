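"""Clonal birth-death-mutation simulation of tumor progression.

Four models of tumor growth are implemented.  ``Bozic`` and ``exp`` have
density-independent rates and grow exponentially once drivers accumulate;
``McF_4`` and ``McF_6`` have a death rate log(1 + N/K) that rises with the
total population N, giving logistic-like dynamics.  Per-clone rates depend
on (j, p): the number of mutated drivers with all their graph dependencies
met (j) and unmet (p).  With s = 0.1 throughout:

=======  =======================  ==================  =====================
model    birth                    death               per-gene mutation
=======  =======================  ==================  =====================
Bozic    1                        (1-s)^j (1+sh)^p    1e-6
exp      max(0,(1+s)^j (1-sh)^p)  1                   birth * 1e-7
McF_*    (1+s)^j / (1+sh)^p       log(1 + N/K)        5e-7
=======  =======================  ==================  =====================

The deviation-from-monotonicity parameter sh is either 0 (a driver mutated
out of order behaves like a neutral passenger) or infinity (such a clone
has fitness zero and is never instantiated, enforcing monotonicity).
Passengers are strictly neutral and never contribute to j or p.

Two engines are provided: a clone-level tau-leap whose within-clone
birth-death updates use the exact binomial-negative-binomial transition of
the linear birth-death process (default; scales to large populations), and
an exact per-event Gillespie engine used as a correctness oracle at small
population caps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .graphs import ROOT, GenomeSpec, RestrictionGraph

ModelName = Literal["Bozic", "exp", "McF_4", "McF_6"]

_MODEL_MUTATION = {"Bozic": 1e-6, "exp": 1e-7, "McF_4": 5e-7, "McF_6": 5e-7}
_MCF_TARGET = {"McF_4": 4, "McF_6": 6}


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one tumor-progression model run.

    ``mutation_rate`` is per gene per unit time; for the exp model it is
    the scale multiplied by the clone birth rate.  ``pop_threshold`` is the
    cancer-reached size for Bozic/exp (1e9 at study scale; tests use much
    smaller caps), and McF models instead stop when the maximal j reaches
    their driver target.  ``init_size`` is the starting number of wild-type
    cells; the published value is not printed, 500 is this package's
    default.
    """

    model: ModelName
    sh: float = 0.0
    s: float = 0.1
    mutation_rate: float | None = None
    K: float = 2000.0
    pop_threshold: float = 1e9
    init_size: int = 500
    max_steps: int = 2_000_000

    def __post_init__(self) -> None:
        if self.model not in _MODEL_MUTATION:
            raise ValueError(f"unknown model {self.model!r}")
        if self.s <= 0 or self.K <= 0 or self.pop_threshold <= 0:
            raise ValueError("s, K and pop_threshold must be positive")
        if self.mutation_rate is None:
            object.__setattr__(
                self, "mutation_rate", _MODEL_MUTATION[self.model]
            )

    @property
    def driver_target(self) -> int | None:
        return _MCF_TARGET.get(self.model)


@dataclass
class Clone:
    genotype: frozenset[str]
    size: int
    birth_rate: float = 0.0
    death_rate: float = 0.0
    mutation_rate: float = 0.0


@dataclass
class Trajectory:
    """Recorded clone compositions of one simulated patient."""

    times: list[float]
    states: list[list[tuple[frozenset[str], int]]]
    t_first_driver: float | None
    t_end: float
    end_reason: Literal["cancer_reached", "extinct", "capped"]
    metadata: dict = field(default_factory=dict)

    def state_at(self, t: float) -> list[tuple[frozenset[str], int]]:
        """Clone composition at the recorded time closest at-or-before t."""
        if self.t_first_driver is None:
            raise ValueError("trajectory never acquired a driver")
        if t < self.t_first_driver or t > self.t_end:
            raise ValueError(
                f"t={t} outside sampling window "
                f"[{self.t_first_driver}, {self.t_end}]"
            )
        idx = int(np.searchsorted(np.asarray(self.times), t, side="right")) - 1
        idx = max(idx, 0)
        state = [(g, n) for g, n in self.states[idx] if n > 0]
        if not state:
            raise ValueError("empty population at requested time")
        return state


def state_at(traj: Trajectory, t: float) -> list[tuple[frozenset[str], int]]:
    return traj.state_at(t)


def clone_rates(
    genotype: frozenset[str] | Sequence[str],
    graph: RestrictionGraph,
    params: ModelParams,
    N: float = 0.0,
) -> tuple[float, float, float] | None:
    """(birth, death, per-gene mutation) for a clone, or None if nonviable.

    Nonviable means fitness zero under sh = infinity with any dependency
    unmet; such clones are never instantiated by the simulator.
    """
    drivers = set(graph.drivers)
    driver_part = frozenset(g for g in genotype if g in drivers)
    j, p = graph.count_driver_status(driver_part)
    s, sh = params.s, params.sh
    if math.isinf(sh) and p >= 1:
        return None
    if params.model == "Bozic":
        birth = 1.0
        death = (1 - s) ** j * (1 + sh) ** p
        mut = params.mutation_rate
    elif params.model == "exp":
        birth = max(0.0, (1 + s) ** j * (1 - sh) ** p)
        death = 1.0
        mut = birth * params.mutation_rate
    else:  # McF_4 / McF_6
        birth = (1 + s) ** j / (1 + sh) ** p
        death = math.log1p(N / params.K)
        mut = params.mutation_rate
    return birth, death, mut


def _bd_transition(n: int, b: float, d: float, dt: float, rng) -> int:
    """Exact linear birth-death transition over dt from n cells.

    Survivor lineages are Binomial(n, 1-alpha) and each survivor leaves a
    shifted-geometric family, so the total is survivors plus a negative
    binomial count (the binomial-negative-binomial kernel).
    """
    if n == 0:
        return 0
    if b == 0.0 and d == 0.0:
        return n
    if abs(b - d) < 1e-12:
        x = b * dt
        alpha = beta = x / (1 + x)
    else:
        w = math.exp((b - d) * dt)
        denom = b * w - d
        alpha = d * (w - 1) / denom
        beta = b * (w - 1) / denom
    survivors = rng.binomial(n, max(0.0, 1.0 - alpha))
    if survivors == 0:
        return 0
    if beta <= 0:
        return int(survivors)
    extra = rng.negative_binomial(survivors, 1.0 - beta)
    return int(survivors + extra)


def _first(genome: GenomeSpec, graph: RestrictionGraph, params: ModelParams):
    """Index maps shared by both engines, plus input validation."""
    genes = genome.genes
    driver_set = set(graph.drivers)
    if set(genome.driver_labels) != driver_set:
        raise ValueError("genome driver labels must match graph drivers")
    target = params.driver_target
    if target is not None and target > len(driver_set):
        raise ValueError(
            f"{params.model} needs >= {target} drivers; graph has "
            f"{len(driver_set)} (the end condition would be unreachable)"
        )
    return genes, driver_set


def simulate_patient(
    graph: RestrictionGraph,
    genome: GenomeSpec,
    params: ModelParams,
    rng: np.random.Generator,
    engine: Literal["bnb", "gillespie"] = "bnb",
    record: bool = True,
) -> Trajectory:
    """Simulate one patient from wild-type until cancer/extinction/cap."""
    if engine == "bnb":
        return _simulate_tau(graph, genome, params, rng, record)
    if engine == "gillespie":
        return _simulate_gillespie(graph, genome, params, rng, record)
    raise ValueError(f"unknown engine {engine!r}")


def _rates_cache(graph, params):
    cache: dict[frozenset, tuple | None] = {}

    def get(genotype: frozenset[str], N: float):
        if params.model.startswith("McF"):
            # death depends on N; cache only the genotype-dependent part
            key = genotype
            if key not in cache:
                cache[key] = clone_rates(genotype, graph, params, N=0.0)
            base = cache[key]
            if base is None:
                return None
            birth, _, mut = base
            return birth, math.log1p(N / params.K), mut
        if genotype not in cache:
            cache[genotype] = clone_rates(genotype, graph, params, N=0.0)
        return cache[genotype]

    return get


def _max_j(clones, graph, driver_set, cache={}):
    best = 0
    for g, n in clones.items():
        if n <= 0:
            continue
        key = (id(graph), g)
        if key not in cache:
            cache[key] = graph.count_driver_status(
                frozenset(x for x in g if x in driver_set)
            )[0]
        best = max(best, cache[key])
    return best


def _finish(times, states, clones, t, t_first, reason, params, record):
    comp = [(g, n) for g, n in clones.items() if n > 0]
    if record:
        times.append(t)
        states.append(comp)
    else:
        times, states = [t], [comp]
    return Trajectory(
        times=times,
        states=states,
        t_first_driver=t_first,
        t_end=t,
        end_reason=reason,
        metadata={"model": params.model, "sh": params.sh},
    )


def _simulate_tau(graph, genome, params, rng, record):
    genes, driver_set = _first(genome, graph, params)
    rates_of = _rates_cache(graph, params)
    wild = frozenset()
    clones: dict[frozenset, int] = {wild: params.init_size}
    t = 0.0
    t_first: float | None = None
    times: list[float] = [0.0]
    states: list[list[tuple[frozenset, int]]] = [[(wild, params.init_size)]]
    target = params.driver_target
    n_genes = genome.n_genes

    for _ in range(params.max_steps):
        N = sum(clones.values())
        if N == 0:
            return _finish(times, states, clones, t, t_first, "extinct", params, record)
        if target is None and N > params.pop_threshold:
            return _finish(
                times, states, clones, t, t_first, "cancer_reached", params, record
            )
        if target is not None and _max_j(clones, graph, driver_set) >= target:
            return _finish(
                times, states, clones, t, t_first, "cancer_reached", params, record
            )

        live = {g: n for g, n in clones.items() if n > 0}
        info = {g: rates_of(g, N) for g in live}
        # adaptive step: bounded relative population change and about one
        # mutation per leap
        max_growth = max(
            (abs(b - d) for b, d, _ in info.values()), default=0.0
        )
        mut_flux = sum(
            n * info[g][2] * (n_genes - len(g)) for g, n in live.items()
        )
        dt = min(
            0.25 / max_growth if max_growth > 0 else math.inf,
            1.0 / mut_flux if mut_flux > 0 else math.inf,
            50.0,
        )

        new_sizes: dict[frozenset, int] = {}
        mutated = False
        for g, n in live.items():
            b, d, u = info[g]
            n_new = _bd_transition(n, b, d, dt, rng)
            n_mid = 0.5 * (n + n_new)
            lam = u * (n_genes - len(g)) * n_mid * dt
            n_mut = rng.poisson(lam) if lam > 0 else 0
            n_mut = min(n_mut, n_new)
            for _m in range(n_mut):
                free = [x for x in genes if x not in g]
                gene = free[int(rng.integers(len(free)))]
                child = g | {gene}
                child_rates = rates_of(child, N)
                n_new -= 1
                mutated = True
                if child_rates is None:
                    continue  # monotonicity: fitness-zero clone never lives
                new_sizes[child] = new_sizes.get(child, 0) + 1
                if t_first is None and any(x in driver_set for x in child):
                    t_first = t + dt
            new_sizes[g] = new_sizes.get(g, 0) + n_new
        clones = {g: n for g, n in new_sizes.items() if n > 0}
        t += dt
        if record and mutated:
            times.append(t)
            states.append([(g, n) for g, n in clones.items()])
    return _finish(times, states, clones, t, t_first, "capped", params, record)


def _simulate_gillespie(graph, genome, params, rng, record):
    genes, driver_set = _first(genome, graph, params)
    rates_of = _rates_cache(graph, params)
    wild = frozenset()
    clones: dict[frozenset, int] = {wild: params.init_size}
    t = 0.0
    t_first: float | None = None
    times: list[float] = [0.0]
    states: list[list[tuple[frozenset, int]]] = [[(wild, params.init_size)]]
    target = params.driver_target
    n_genes = genome.n_genes

    for _ in range(params.max_steps):
        N = sum(clones.values())
        if N == 0:
            return _finish(times, states, clones, t, t_first, "extinct", params, record)
        if target is None and N > params.pop_threshold:
            return _finish(
                times, states, clones, t, t_first, "cancer_reached", params, record
            )
        if target is not None and _max_j(clones, graph, driver_set) >= target:
            return _finish(
                times, states, clones, t, t_first, "cancer_reached", params, record
            )
        live = [(g, n) for g, n in clones.items() if n > 0]
        events = []  # (rate, kind, clone)
        for g, n in live:
            b, d, u = rates_of(g, N)
            events.append((b * n, "birth", g))
            events.append((d * n, "death", g))
            events.append((u * (n_genes - len(g)) * n, "mut", g))
        total = sum(r for r, _, _ in events)
        if total <= 0:
            return _finish(times, states, clones, t, t_first, "capped", params, record)
        t += rng.exponential(1.0 / total)
        u01 = rng.random() * total
        acc = 0.0
        for rate, kind, g in events:
            acc += rate
            if u01 <= acc:
                break
        if kind == "birth":
            clones[g] += 1
        elif kind == "death":
            clones[g] -= 1
            if clones[g] == 0:
                del clones[g]
        else:
            free = [x for x in genes if x not in g]
            gene = free[int(rng.integers(len(free)))]
            child = g | {gene}
            clones[g] -= 1
            if clones[g] == 0:
                del clones[g]
            if rates_of(child, N) is not None:
                clones[child] = clones.get(child, 0) + 1
                if t_first is None and any(x in driver_set for x in child):
                    t_first = t
            if record:
                times.append(t)
                states.append([(gg, nn) for gg, nn in clones.items()])
    return _finish(times, states, clones, t, t_first, "capped", params, record)


def simulate_until_cancer(
    graph: RestrictionGraph,
    genome: GenomeSpec,
    params: ModelParams,
    rng: np.random.Generator,
    engine: Literal["bnb", "gillespie"] = "bnb",
    max_attempts: int = 1000,
    record: bool = True,
) -> Trajectory:
    """Resimulate with fresh randomness until a cancer-reached trajectory.

    Patients in the study are, by construction, individuals who developed
    cancer; extinct or capped runs are discarded and retried.  Requires a
    driver to have appeared (needed to define the sampling window).
    """
    for attempt in range(1, max_attempts + 1):
        traj = simulate_patient(graph, genome, params, rng, engine, record)
        if traj.end_reason == "cancer_reached" and traj.t_first_driver is not None:
            traj.metadata["attempts"] = attempt
            return traj
    raise RuntimeError(
        f"no cancer-reached trajectory in {max_attempts} attempts "
        f"(model={params.model}, sh={params.sh})"
    )
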