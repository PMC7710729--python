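"""Forward-in-time Wright-Fisher simulation of phased haplotype panels.

A single discrete-generation simulator serves both the neutral null
(for simulation-derived significance thresholds of the selection scan) and
planted selective sweeps from standing variation. The model is the textbook
diploid Wright-Fisher population with

* infinite-sites biallelic mutation at rate ``mu`` per bp per generation,
  placed at uniform integer positions (collisions with segregating sites are
  redrawn);
* per-meiosis recombination as a Poisson number of crossovers with mean
  ``rec * length``, at uniform positions;
* random union of gametes (selfing allowed), multinomial offspring numbers;
* optional population splits (a child population is founded by sampling
  founders from the parent with replacement) and symmetric per-generation
  migration;
* optional selection at a single site with genotype fitnesses
  ``1, 1+h*s, 1+s``.

All state lives in a haplotype matrix of 0/1 alleles over the currently
segregating sites; sites fixed or lost across the whole metapopulation are
pruned each generation. Every entry point is a pure function of its
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._kernels import apply_crossovers
from ..panel import HaplotypePanel

__all__ = [
    "DemographyConfig",
    "SweepConfig",
    "SweepResult",
    "simulate_panel",
    "simulate_sweep_panel",
    "simulate_replicate_panels",
]


@dataclass
class PopEpoch:
    """Diploid size of ``population`` from ``start_generation`` onward."""

    population: str
    size: int
    start_generation: int = 0


@dataclass
class Split:
    """Foundation of ``child`` from ``parent`` at ``generation`` (forward time)."""

    parent: str
    child: str
    generation: int


@dataclass
class DemographyConfig:
    """Demography for the forward simulator.

    ``epochs`` must contain, for every population, an entry giving its size;
    entries with later ``start_generation`` change the size at that time.
    Populations other than the ancestral one(s) must be introduced by a
    ``Split``. Time is forward: generation 0 is the first post-burn-in
    generation, sampling happens after ``generations`` generations.
    """

    epochs: list[PopEpoch]
    splits: list[Split] = field(default_factory=list)
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    mutation_rate: float = 1e-7
    recombination_rate: float = 1e-7
    sequence_length: int = 100_000
    samples: dict[str, int] = field(default_factory=dict)
    generations: int = 0
    burn_in: int | None = None  # default 8 x ancestral diploid size
    chrom: str = "1"

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("at least one population epoch required")
        for e in self.epochs:
            if e.size < 2:
                raise ValueError(f"population size must be >= 2 (got {e.size})")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.sequence_length <= 0:
            raise ValueError("sequence length must be > 0")
        if any(m < 0 for m in self.migration.values()):
            raise ValueError("migration rates must be >= 0")
        gens = [s.generation for s in self.splits]
        if sorted(gens) != gens or len(set(gens)) != len(gens):
            raise ValueError("split generations must be strictly increasing")
        children = {s.child for s in self.splits}
        ancestral = self.ancestral_populations()
        for s in self.splits:
            if s.parent not in ancestral and s.parent not in children:
                raise ValueError(f"split parent {s.parent!r} never exists")
        for s in self.splits:
            # parent must exist before the split happens
            parent_births = [t.generation for t in self.splits if t.child == s.parent]
            if parent_births and parent_births[0] >= s.generation:
                raise ValueError(
                    f"unreachable split order: {s.parent!r} is founded at generation "
                    f"{parent_births[0]} but splits off {s.child!r} at {s.generation}"
                )
        for pop in self.samples:
            if pop not in {e.population for e in self.epochs}:
                raise ValueError(f"sampled population {pop!r} has no epoch entry")

    def ancestral_populations(self) -> list[str]:
        children = {s.child for s in self.splits}
        return [p for p in dict.fromkeys(e.population for e in self.epochs) if p not in children]

    def size_at(self, population: str, generation: int) -> int:
        size = None
        for e in self.epochs:
            if e.population == population and e.start_generation <= generation:
                size = e.size
        if size is None:
            raise KeyError(f"no epoch covers {population!r} at generation {generation}")
        return size


@dataclass
class SweepConfig:
    """Positive selection on a standing variant.

    Genotype fitnesses are ``1 : 1+h*s : 1+s`` for ancestral homozygote :
    heterozygote : derived homozygote. Two origin modes for the standing
    variant:

    ``standing_instant``
        The derived allele is placed at frequency ``f0`` on randomly chosen
        haplotype backgrounds at ``start_generation`` and selection starts
        immediately (maximally soft; the analytic trajectory/fixation
        expectations condition on exactly ``f0``).
    ``standing_hard``
        As ``standing_instant`` but every initial copy is planted on one
        donor haplotype background, so the sweeping class is identical by
        descent from the start — the canonical hard-sweep signal a
        haplotype scan is calibrated to detect.
    ``single_mutation``
        One derived copy is injected at ``start_generation`` and drifts
        neutrally (re-injected on loss, i.e. conditioned on survival) until
        it reaches ``f0``; only then does selection switch on. This is the
        classic "previously neutrally segregating allele" scenario and
        leaves the single-origin haplotype structure a sweep scan keys on.
    """

    position: int
    s: float
    h: float = 0.5
    f0: float = 0.05
    population: str = ""
    start_generation: int = 0
    origin: str = "standing_instant"

    def __post_init__(self) -> None:
        if self.origin not in ("standing_instant", "standing_hard", "single_mutation"):
            raise ValueError(
                "origin must be 'standing_instant', 'standing_hard' or 'single_mutation'"
            )

    def validate(self, demography: DemographyConfig) -> None:
        if not (0.0 < self.f0 < 1.0):
            raise ValueError("f0 must be in (0, 1)")
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not (1 <= self.position <= demography.sequence_length):
            raise ValueError("selected position outside the simulated region")


@dataclass
class SweepResult:
    """Outcome of a sweep simulation: panel, final frequency, trajectory."""

    panel: HaplotypePanel
    outcome: str  # "segregating", "fixed" or "sweep_lost"
    final_frequency: float
    trajectory: np.ndarray


class _State:
    """Mutable simulator state: per-population haplotype blocks over shared sites."""

    def __init__(self, positions: np.ndarray, pops: dict[str, np.ndarray]):
        self.positions = positions  # sorted int64, 1-based
        self.pops = pops  # name -> (2N, S) uint8
        self.gen_count = 0  # fixed/lost columns are pruned every few generations

    def total_haplotypes(self) -> int:
        return sum(h.shape[0] for h in self.pops.values())


def _recombine(hap: np.ndarray, parents: np.ndarray, positions: np.ndarray,
               rec_mean: float, length: int, rng: np.random.Generator) -> np.ndarray:
    """Produce one gamete per entry of ``parents`` (diploid indices).

    Each gamete starts on one of its parent's two haplotypes (fair coin) and
    switches at each of a Poisson(``rec_mean``) number of uniform crossover
    positions; segments between sorted cuts alternate between the two
    parental haplotypes.
    """
    n = len(parents)
    start = rng.integers(0, 2, size=n)
    s = positions.size
    if rec_mean <= 0 or s == 0:
        return hap[2 * parents + start]
    out = hap[2 * parents + start]  # fancy indexing: already a copy
    n_cross = rng.poisson(rec_mean, size=n)
    total = int(n_cross.sum())
    if total:
        cuts = rng.uniform(0, length, size=total)
        rows = np.repeat(np.arange(n), n_cross)
        idx = np.searchsorted(positions, cuts)
        idx = idx[np.lexsort((idx, rows))]  # sort cut indices within each gamete
        apply_crossovers(hap, parents, start, n_cross, idx, out)
    return out


def _advance(state: _State, demography: DemographyConfig, generation: int,
             rng: np.random.Generator, sweep: SweepConfig | None,
             sweep_col: list[int | None], sweep_active: bool = True) -> None:
    """One Wright-Fisher generation over all populations."""
    length = demography.sequence_length
    rec_mean = demography.recombination_rate * length
    pop_names = list(state.pops)
    new_pops: dict[str, np.ndarray] = {}
    for name in pop_names:
        n_next = demography.size_at(name, generation)
        self_idx = pop_names.index(name)
        # migration: source population of each offspring
        incoming = [(j, demography.migration[(other, name)])
                    for j, other in enumerate(pop_names)
                    if other != name and demography.migration.get((other, name), 0.0) > 0]
        sources = None
        if incoming:
            for j, rate in incoming:
                migrant = rng.random(n_next) < rate
                if migrant.any():
                    if sources is None:
                        sources = np.full(n_next, self_idx)
                    sources[migrant] = j
        if sources is None:  # fast path: no migrant this generation
            groups = [(self_idx, np.arange(n_next))]
        else:
            groups = [(j, np.nonzero(sources == j)[0]) for j in range(len(pop_names))]
        gametes = []
        for j, take in groups:
            if take.size == 0:
                continue
            src = pop_names[j]
            hap = state.pops[src]
            n_src = hap.shape[0] // 2
            if (
                sweep is not None
                and sweep_active
                and src == sweep.population
                and sweep_col[0] is not None
                and generation >= sweep.start_generation
            ):
                g = hap[0::2, sweep_col[0]].astype(float) + hap[1::2, sweep_col[0]]
                w = 1.0 + sweep.h * sweep.s * (g == 1) + sweep.s * (g == 2)
                parents = rng.choice(n_src, size=(take.size, 2), p=w / w.sum())
            else:
                parents = rng.integers(0, n_src, size=(take.size, 2))
            g = _recombine(hap, parents.reshape(-1), state.positions,
                           rec_mean, length, rng)
            gametes.append((take, g))
        n_sites = state.positions.size
        if len(gametes) == 1 and gametes[0][0].size == n_next:
            child = gametes[0][1]
        else:
            child = np.empty((2 * n_next, n_sites), dtype=np.uint8)
            for take, g in gametes:
                rows = np.empty(2 * take.size, dtype=np.int64)
                rows[0::2] = 2 * take
                rows[1::2] = 2 * take + 1
                child[rows] = g
        new_pops[name] = child
    state.pops = new_pops

    # mutations: one new column per mutation, placed on a random haplotype
    mu_total = demography.mutation_rate * length
    if mu_total > 0:
        totals = {name: h.shape[0] for name, h in state.pops.items()}
        n_hap_all = sum(totals.values())
        n_mut = rng.poisson(mu_total * n_hap_all)
        if n_mut:
            # draw unique positions not colliding with segregating sites
            # (positions are kept sorted, so membership is a searchsorted)
            def _fresh(cand: np.ndarray) -> np.ndarray:
                cand = np.unique(cand)
                at = np.searchsorted(state.positions, cand)
                at = np.minimum(at, state.positions.size - 1) if state.positions.size else at
                taken = (state.positions[at] == cand) if state.positions.size else np.zeros(len(cand), bool)
                return cand[~taken]

            draw = _fresh(rng.integers(1, length + 1, size=n_mut))
            while draw.size < n_mut:
                extra = _fresh(rng.integers(1, length + 1, size=n_mut - draw.size))
                draw = np.unique(np.concatenate([draw, extra]))
            new_pos = draw[:n_mut]
            carriers = rng.integers(0, n_hap_all, size=n_mut)
            offsets = np.cumsum([0] + [totals[n] for n in state.pops])
            names = list(state.pops)
            # keep positions (and matrix columns) sorted: recombination relies on it
            sweep_pos = (int(state.positions[sweep_col[0]])
                         if sweep_col[0] is not None else None)
            all_pos = np.concatenate([state.positions, new_pos.astype(np.int64)])
            order = np.argsort(all_pos, kind="stable")
            new_states: dict[str, np.ndarray] = {}
            mut_idx = np.arange(n_mut)
            for w, name in enumerate(names):
                old = state.pops[name]
                grown = np.zeros((totals[name], old.shape[1] + n_mut), dtype=np.uint8)
                grown[:, :old.shape[1]] = old
                mine = (carriers >= offsets[w]) & (carriers < offsets[w + 1])
                grown[carriers[mine] - offsets[w], old.shape[1] + mut_idx[mine]] = 1
                new_states[name] = grown[:, order]
            state.positions = all_pos[order]
            state.pops = new_states
            if sweep_pos is not None:
                sweep_col[0] = int(np.searchsorted(state.positions, sweep_pos))

    state.gen_count += 1
    if state.gen_count % 4 == 0:
        _prune(state, sweep_col)


def _prune(state: _State, sweep_col: list[int | None]) -> None:
    """Drop sites fixed or lost across the metapopulation (keeping the sweep site)."""
    if state.positions.size == 0:
        return
    counts = sum(h.sum(axis=0, dtype=np.int64) for h in state.pops.values())
    total = state.total_haplotypes()
    keep = (counts > 0) & (counts < total)
    if sweep_col[0] is not None:
        keep[sweep_col[0]] = True
    if keep.all():
        return
    state.positions = state.positions[keep]
    state.pops = {n: h[:, keep] for n, h in state.pops.items()}
    if sweep_col[0] is not None:
        sweep_col[0] = int(keep[: sweep_col[0]].sum())


def demography_burn_in(demography: DemographyConfig) -> int:
    if demography.burn_in is not None:
        return demography.burn_in
    anc = demography.ancestral_populations()
    return 8 * max(demography.size_at(p, 0) for p in anc)


def _run(demography: DemographyConfig, rng: np.random.Generator,
         sweep: SweepConfig | None = None,
         trajectory: list[float] | None = None,
         stop_at_frequency: float | None = None,
         stop_when_lost: bool = False) -> tuple[_State, list[int | None]]:
    """Burn in, apply splits, run to the sampling generation."""
    burn = demography_burn_in(demography)
    anc = demography.ancestral_populations()
    pops = {name: np.zeros((2 * demography.size_at(name, 0), 0), dtype=np.uint8) for name in anc}
    state = _State(np.empty(0, dtype=np.int64), pops)
    sweep_col: list[int | None] = [None]
    for g in range(-burn, 0):
        _advance(state, demography, 0, rng, None, sweep_col)
    splits = {s.generation: s for s in demography.splits}
    select_active = True
    for g in range(demography.generations):
        if g in splits:
            s = splits[g]
            parent = state.pops[s.parent]
            n_child = demography.size_at(s.child, g)
            founders = rng.integers(0, parent.shape[0] // 2, size=n_child)
            rows = np.ravel(np.column_stack([2 * founders, 2 * founders + 1]))
            state.pops[s.child] = parent[rows].copy()
        if sweep is not None and g == sweep.start_generation:
            n_copies = None if sweep.origin == "standing_instant" else 1
            sweep_col[0] = _inject_standing_variant(state, demography, sweep, rng,
                                                    n_copies=n_copies)
            select_active = sweep.origin == "standing_instant"
        _advance(state, demography, g, rng, sweep, sweep_col,
                 sweep_active=select_active)
        if sweep is not None and sweep_col[0] is not None:
            hap = state.pops[sweep.population]
            freq = float(hap[:, sweep_col[0]].mean())
            if not select_active:
                if freq == 0.0:  # condition the neutral drift phase on survival
                    carrier = rng.integers(0, hap.shape[0])
                    hap[carrier, sweep_col[0]] = 1
                    freq = 1.0 / hap.shape[0]
                elif freq >= sweep.f0:
                    select_active = True
            if trajectory is not None:
                trajectory.append(freq)
            if select_active and stop_at_frequency is not None and freq >= stop_at_frequency:
                break
            if select_active and stop_when_lost and freq == 0.0:
                break
    return state, sweep_col


def _inject_standing_variant(state: _State, demography: DemographyConfig,
                             sweep: SweepConfig, rng: np.random.Generator,
                             n_copies: int | None = None) -> int:
    """Place the derived allele at the selected position (``f0`` of the
    haplotypes, or ``n_copies`` explicit copies)."""
    if sweep.position in state.positions:
        col = int(np.searchsorted(state.positions, sweep.position))
        for h in state.pops.values():
            h[:, col] = 0
    else:
        order = np.searchsorted(state.positions, sweep.position)
        state.positions = np.insert(state.positions, order, sweep.position)
        state.pops = {
            n: np.insert(h, order, 0, axis=1) for n, h in state.pops.items()
        }
        col = int(order)
    hap = state.pops[sweep.population]
    n_hap = hap.shape[0]
    if n_copies is None:
        n_copies = max(1, round(sweep.f0 * n_hap))
    carriers = rng.choice(n_hap, size=n_copies, replace=False)
    if sweep.origin == "standing_hard" and n_copies > 1:
        donor = hap[carriers[0]].copy()
        hap[carriers] = donor
    hap[carriers, col] = 1
    return col


def _sample_panel(state: _State, demography: DemographyConfig,
                  rng: np.random.Generator) -> HaplotypePanel:
    samples = demography.samples or {
        p: min(5, state.pops[p].shape[0] // 2) for p in state.pops
    }
    rows = []
    names: list[str] = []
    pops: list[str] = []
    for pop, n in samples.items():
        hap = state.pops[pop]
        chosen = rng.choice(hap.shape[0] // 2, size=n, replace=False)
        for k, c in enumerate(chosen):
            rows.append(hap[2 * c])
            rows.append(hap[2 * c + 1])
            names.append(f"{pop}_{k}")
            pops.append(pop)
    matrix = np.stack(rows) if rows else np.zeros((0, 0), dtype=np.int8)
    order = np.argsort(state.positions, kind="stable")
    matrix = matrix[:, order]
    positions = state.positions[order]
    segregating = (matrix.sum(axis=0) > 0) & (matrix.sum(axis=0) < matrix.shape[0])
    return HaplotypePanel(
        chrom=demography.chrom,
        positions=positions[segregating],
        haplotypes=matrix[:, segregating].astype(np.int8),
        samples=names,
        populations=pops,
    )


def simulate_panel(demography: DemographyConfig, seed: int) -> HaplotypePanel:
    """Simulate a neutral phased panel under ``demography``.

    Deterministic in ``(demography, seed)``; alleles are polarized 0=ancestral
    / 1=derived by construction (every derived allele descends from a single
    mutation event).
    """
    rng = np.random.default_rng(seed)
    state, _ = _run(demography, rng)
    return _sample_panel(state, demography, rng)


def simulate_sweep_panel(
    demography: DemographyConfig,
    sweep: SweepConfig,
    seed: int,
    min_final_frequency: float = 0.0,
    stop_at_frequency: float | None = None,
    stop_when_lost: bool = False,
    max_attempts: int = 1000,
) -> SweepResult:
    """Simulate a sweep from standing variation and sample a panel.

    The selected allele follows Wright-Fisher sampling with fitnesses
    ``1, 1+h*s, 1+s`` from the injection generation onward. Loss of the
    allele before sampling is reported as outcome ``"sweep_lost"``, not an
    exception. ``min_final_frequency`` > 0 makes the simulation retry with
    fresh randomness (same stream) until the population frequency reaches it.
    ``stop_at_frequency`` samples the panel as soon as the selected allele
    reaches that population frequency ("sampled near fixation") instead of
    running out the full number of generations.
    """
    sweep.validate(demography)
    if not sweep.population:
        raise ValueError("sweep population must be named")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        trajectory: list[float] = []
        state, sweep_col = _run(demography, rng, sweep=sweep, trajectory=trajectory,
                                stop_at_frequency=stop_at_frequency,
                                stop_when_lost=stop_when_lost)
        hap = state.pops[sweep.population]
        freq = float(hap[:, sweep_col[0]].mean()) if sweep_col[0] is not None else 0.0
        if freq >= min_final_frequency:
            break
    else:
        raise RuntimeError("sweep never reached min_final_frequency within max_attempts")
    if freq == 0.0:
        outcome = "sweep_lost"
    elif freq == 1.0:
        outcome = "fixed"
    else:
        outcome = "segregating"
    panel = _sample_panel(state, demography, rng)
    panel.metadata["sweep_position"] = sweep.position
    panel.metadata["sweep_final_frequency"] = freq
    return SweepResult(panel=panel, outcome=outcome, final_frequency=freq,
                       trajectory=np.asarray(trajectory))


def simulate_replicate_panels(
    demography: DemographyConfig,
    n_replicates: int,
    seed: int,
    spacing: int | None = None,
):
    """Yield ``n_replicates`` neutral panels from one long run.

    Burns in once, then samples a panel every ``spacing`` generations
    (default: twice the largest ancestral diploid size, enough for haplotype
    structure to decorrelate on the coalescent timescale). Far cheaper than
    independent burn-ins when thousands of replicates are needed for the
    neutral null; replicates are weakly correlated, which the two-seed
    agreement check of the null threshold is designed to absorb.
    """
    rng = np.random.default_rng(seed)
    if spacing is None:
        anc = demography.ancestral_populations()
        spacing = 2 * max(demography.size_at(p, 0) for p in anc)
    state, sweep_col = _run(demography, rng)
    for _ in range(n_replicates):
        yield _sample_panel(state, demography, rng)
        for g in range(spacing):
            _advance(state, demography, demography.generations, rng, None, sweep_col)


def pairwise_diversity(panel: HaplotypePanel) -> float:
    """Mean number of pairwise differences between haplotypes (sums over sites)."""
    h = panel.haplotypes.astype(np.float64)
    n = h.shape[0]
    if n < 2:
        return 0.0
    derived = h.sum(axis=0)
    return float(np.sum(derived * (n - derived)) / (n * (n - 1) / 2))


def demography_from_dict(data: dict) -> DemographyConfig:
    """Build a :class:`DemographyConfig` from a plain mapping (YAML layout)."""
    epochs = [PopEpoch(e["population"], int(e["size"]), int(e.get("start_generation", 0)))
              for e in data["epochs"]]
    splits = [Split(s["parent"], s["child"], int(s["generation"]))
              for s in data.get("splits", [])]
    migration = {
        (m["source"], m["dest"]): float(m["rate"]) for m in data.get("migration", [])
    }
    return DemographyConfig(
        epochs=epochs,
        splits=splits,
        migration=migration,
        mutation_rate=float(data.get("mutation_rate", 1e-7)),
        recombination_rate=float(data.get("recombination_rate", 1e-7)),
        sequence_length=int(data.get("sequence_length", 100_000)),
        samples={k: int(v) for k, v in data.get("samples", {}).items()},
        generations=int(data.get("generations", 0)),
        burn_in=None if data.get("burn_in") is None else int(data["burn_in"]),
        chrom=str(data.get("chrom", "1")),
    )


def load_demography_yaml(path) -> DemographyConfig:
    """Load a demography configuration from a YAML file."""
    import yaml

    with open(path) as fh:
        return demography_from_dict(yaml.safe_load(fh))


def example_demography() -> DemographyConfig:
    """The bundled three-population example demography (desk-scale)."""
    from importlib.resources import files

    return load_demography_yaml(files("sweepfunc.data").joinpath("example_demography.yaml"))


def simulate_sweep_replicates(
    demography: DemographyConfig,
    sweep: SweepConfig,
    n_replicates: int,
    seed: int,
    spacing: int | None = None,
    stop_at_frequency: float | None = None,
    min_final_frequency: float = 0.0,
    max_sweep_generations: int = 500,
):
    """Yield sweep panels sharing one neutral burn-in (power-analysis harness).

    A neutral base population is burned in once; for each replicate a copy of
    the current state receives the standing variant and evolves under
    selection until ``stop_at_frequency`` (or ``max_sweep_generations``),
    after which a panel is sampled. Between replicates the neutral base
    advances ``spacing`` generations. Replicates failing to reach
    ``min_final_frequency`` are retried on fresh neutral backgrounds, i.e.
    yields are conditioned on sweep success.
    """
    sweep.validate(demography)
    if not sweep.population:
        raise ValueError("sweep population must be named")
    rng = np.random.default_rng(seed)
    if spacing is None:
        anc = demography.ancestral_populations()
        spacing = 2 * max(demography.size_at(p, 0) for p in anc)
    base, base_col = _run(demography, rng)
    gen_final = demography.generations
    yielded = 0
    while yielded < n_replicates:
        state = _State(base.positions.copy(),
                       {k: v.copy() for k, v in base.pops.items()})
        state.gen_count = base.gen_count
        sweep_col: list[int | None] = [None]
        sweep_col[0] = _inject_standing_variant(
            state, demography, sweep, rng,
            n_copies=None if sweep.origin != "single_mutation" else 1)
        select_active = sweep.origin != "single_mutation"
        freq = 0.0
        for _ in range(max_sweep_generations):
            _advance(state, demography, gen_final, rng, sweep, sweep_col,
                     sweep_active=select_active)
            hap = state.pops[sweep.population]
            freq = float(hap[:, sweep_col[0]].mean())
            if not select_active:
                if freq == 0.0:
                    carrier = rng.integers(0, hap.shape[0])
                    hap[carrier, sweep_col[0]] = 1
                    freq = 1.0 / hap.shape[0]
                elif freq >= sweep.f0:
                    select_active = True
            elif freq == 0.0:
                break  # lost under selection: retry on a fresh background
            elif stop_at_frequency is not None and freq >= stop_at_frequency:
                break
        ok = freq >= min_final_frequency and freq > 0.0
        if ok:
            panel = _sample_panel(state, demography, rng)
            panel.metadata["sweep_position"] = sweep.position
            panel.metadata["sweep_final_frequency"] = freq
            yielded += 1
            yield SweepResult(panel=panel,
                              outcome="fixed" if freq == 1.0 else "segregating",
                              final_frequency=freq,
                              trajectory=np.empty(0))
        for _ in range(spacing):
            _advance(base, demography, gen_final, rng, None, base_col)
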