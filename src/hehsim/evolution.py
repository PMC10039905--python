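"""The generation loop: missegregation, selection, culling, stop detection.

Each generation every cell divides into two daughters (the population
transiently doubles).  Per chromosome, a missegregation event occurs with
probability ``m_misseg * N`` where ``N`` is the chromosome's copy number in
the mother — at most one event per chromosome per division.  The
missegregated copy (homologue chosen proportionally to its counts) ends up
+1 in a uniformly chosen daughter and -1 in the other, so per-chromosome
totals across the two daughters always sum to ``2 N``.  Daughters then
survive independently with probability equal to their clamped
survival/proliferation score; nullisomic cells die unconditionally.
Survivors are culled to ``pop_size`` by uniform subsampling, or topped up
with fresh founder draws from the initiation model when fewer remain.  The
run stops when the UPID frequency of the tracked chromosomes reaches
``upid_stop`` (default 2.5%) or after ``max_generations``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CellKaryotype, N_CHROM, SelectionConfig, population_scores, upid_frequency
from .initiation import InitiationModel, draw_founders

__all__ = [
    "GenerationRecord",
    "Population",
    "RunResult",
    "divide",
    "divide_population",
    "apply_tetraploid_loss",
    "survival_filter",
    "cull_and_replenish",
    "run_simulation",
    "trajectory_summary",
]


@dataclass(frozen=True)
class GenerationRecord:
    """Per-generation telemetry summary."""

    generation: int
    n_cells: int
    upid_frequency: float
    median_mcn: float
    mean_mcn: float
    mcn_hist: dict[int, int] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "generation": self.generation,
            "n_cells": self.n_cells,
            "upid_frequency": self.upid_frequency,
            "median_mcn": self.median_mcn,
            "mean_mcn": self.mean_mcn,
            "mcn_hist": {str(k): v for k, v in self.mcn_hist.items()},
        }


@dataclass
class Population:
    """A generation's cells as an ``(n, 23, 2)`` homologue-count matrix."""

    cells: np.ndarray
    generation: int = 0

    def __post_init__(self):
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 3 or self.cells.shape[1:] != (N_CHROM, 2):
            raise ValueError(f"expected (n, 23, 2), got {self.cells.shape}")

    @property
    def size(self) -> int:
        return self.cells.shape[0]

    def karyotypes(self) -> list[CellKaryotype]:
        return [CellKaryotype(c) for c in self.cells]

    def record(self, config: SelectionConfig, *, keep_hist: bool = True) -> GenerationRecord:
        mcns = self.cells.sum(axis=(1, 2))
        hist: dict[int, int] = {}
        if keep_hist:
            vals, counts = np.unique(mcns, return_counts=True)
            hist = {int(v): int(c) for v, c in zip(vals, counts)}
        return GenerationRecord(
            generation=self.generation,
            n_cells=self.size,
            upid_frequency=upid_frequency(
                self.cells, config.tracked_chromosomes,
                denominator=config.upid_denominator,
            ),
            median_mcn=float(np.median(mcns)),
            mean_mcn=float(mcns.mean()),
            mcn_hist=hist,
        )


@dataclass
class RunResult:
    """Outcome of one simulation run."""

    model: str
    stop_generation: int
    stop_reason: str  # "upid_threshold" | "max_generations"
    final_population: Population
    trajectory: list[GenerationRecord]
    seed: int

    def to_manifest(self) -> dict:
        return {
            "model": self.model,
            "stop_generation": self.stop_generation,
            "stop_reason": self.stop_reason,
            "seed": self.seed,
            "final_size": self.final_population.size,
            "trajectory": [r.to_dict() for r in self.trajectory],
        }


def divide_population(
    cells: np.ndarray, config: SelectionConfig, rng: np.random.Generator
) -> np.ndarray:
    """Divide every cell; returns the doubled pre-selection pool (2n, 23, 2)."""
    cells = np.asarray(cells)
    totals = cells.sum(axis=2)
    event = rng.random(totals.shape) < config.m_misseg * totals
    d1 = cells.copy()
    d2 = cells.copy()
    if event.any():
        i, c = np.nonzero(event)
        tot = totals[i, c]
        # homologue chosen proportionally to its copy count
        hom = (rng.random(i.size) * tot >= cells[i, c, 0]).astype(np.intp)
        gain_first = rng.random(i.size) < 0.5
        delta = np.where(gain_first, 1, -1).astype(cells.dtype)
        d1[i, c, hom] += delta
        d2[i, c, hom] -= delta
    return np.concatenate([d1, d2])


def divide(
    mother: CellKaryotype, config: SelectionConfig, rng: np.random.Generator
) -> tuple[CellKaryotype, CellKaryotype]:
    """Divide a single cell into its two daughters."""
    if mother.has_nullisomy():
        raise ValueError("cannot divide a nullisomic cell")
    pool = divide_population(mother.copies[None], config, rng)
    return CellKaryotype(pool[0]), CellKaryotype(pool[1])


def _apply_loss_batch(
    cells: np.ndarray, prob: float, rng: np.random.Generator
) -> np.ndarray:
    """Per chromosome, lose one copy (uniform among copies) with ``prob``."""
    cells = np.asarray(cells).copy()
    totals = cells.sum(axis=2)
    hit = (rng.random(totals.shape) < prob) & (totals > 0)
    if hit.any():
        i, c = np.nonzero(hit)
        tot = totals[i, c]
        hom = (rng.random(i.size) * tot >= cells[i, c, 0]).astype(np.intp)
        cells[i, c, hom] -= 1
    return cells


def apply_tetraploid_loss(
    cell: CellKaryotype | np.ndarray, config: SelectionConfig, rng: np.random.Generator
) -> CellKaryotype | np.ndarray:
    """Chromosome-loss step of the tetraploid/sequential model.

    Each chromosome independently loses one copy with probability
    ``tetraploid_loss_prob`` (default 35%) at division; the lost copy is
    uniform among the chromosome's copies.  A (1, 0) chromosome hit by a
    loss becomes nullisomic and the cell is subsequently excluded.
    """
    if isinstance(cell, CellKaryotype):
        return CellKaryotype(
            _apply_loss_batch(cell.copies[None], config.tetraploid_loss_prob, rng)[0]
        )
    return _apply_loss_batch(cell, config.tetraploid_loss_prob, rng)


def survival_filter(
    cells: np.ndarray,
    config: SelectionConfig,
    rng: np.random.Generator,
    *,
    apply_penalty: bool = True,
) -> np.ndarray:
    """Sample survivors: each cell lives with probability clamp(S, 0, 1).

    Nullisomic cells are removed unconditionally.
    """
    cells = np.asarray(cells)
    scores = np.clip(population_scores(cells, config, apply_penalty=apply_penalty), 0.0, 1.0)
    alive = rng.random(cells.shape[0]) < scores
    alive &= (cells.sum(axis=2) > 0).all(axis=1)
    return cells[alive]


def cull_and_replenish(
    cells: np.ndarray,
    founder_generator,
    config: SelectionConfig,
    rng: np.random.Generator,
    *,
    replenish_mode: str = "founders",
) -> np.ndarray:
    """Restore the population to ``pop_size`` cells.

    Above target: uniform subsample without replacement.  Below target:
    top up with fresh draws from ``founder_generator(k, rng)`` (default),
    or by resampling survivors with replacement (``replenish_mode=
    "resample"``); an empty population is always re-founded.
    """
    n = cells.shape[0]
    target = config.pop_size
    if n > target:
        return cells[rng.permutation(n)[:target]]
    if n < target:
        k = target - n
        if replenish_mode == "resample" and n > 0:
            extra = cells[rng.integers(0, n, size=k)]
        else:
            extra = founder_generator(k, rng)
        return np.concatenate([cells, extra]) if n else extra
    return cells


def run_simulation(
    model: str | InitiationModel,
    config: SelectionConfig = SelectionConfig(),
    seed: int | None = None,
    *,
    enforce_stop: bool = True,
    division_mode: str = "doubling",
    replenish_mode: str = "founders",
    keep_hist: bool = False,
) -> RunResult:
    """Run one seeded simulation of an initiation model under selection.

    Bit-reproducible given (model, config, seed): every generation draws
    from its own substream spawned from the master seed, so telemetry of
    early generations does not depend on how long the run lasts.

    For the tetraploid/sequential model the per-division 35% chromosome
    loss is applied to every daughter and the aneuploidy penalty is
    disabled (no initial tetraploid cell would survive it).

    Parameters
    ----------
    enforce_stop
        When False the UPID threshold is ignored and the run always lasts
        ``config.max_generations`` generations (used to study the long-run
        UPID plateau).
    """
    if isinstance(model, InitiationModel):
        name = model.name
        if seed is None:
            seed = model.rng_seed
    else:
        name = model
        if name not in ("diploid_sequential", "tetraploid_sequential",
                        "diploid_tripolar", "tetraploid_tripolar",
                        "mitotic_catastrophe"):
            raise ValueError(f"unknown model {name!r}")
        if seed is None:
            seed = 0
    if division_mode not in ("doubling", "replace"):
        raise ValueError("division_mode must be 'doubling' or 'replace'")

    master = np.random.SeedSequence(seed)
    founder_ss, loop_ss = master.spawn(2)
    rng0 = np.random.default_rng(founder_ss)

    def founders(k: int, rng: np.random.Generator) -> np.ndarray:
        return draw_founders(name, k, rng)

    is_tetra_seq = name == "tetraploid_sequential"
    apply_penalty = not is_tetra_seq

    pop = Population(founders(config.pop_size, rng0), generation=0)
    trajectory = [pop.record(config, keep_hist=keep_hist)]
    stop_reason = "max_generations"
    stop_generation = config.max_generations

    for gen in range(1, config.max_generations + 1):
        rng = np.random.default_rng(loop_ss.spawn(1)[0])
        pool = divide_population(pop.cells, config, rng)
        if division_mode == "replace":
            # keep one daughter per mother: the first half of the pool
            pool = pool[: pop.cells.shape[0]]
        if is_tetra_seq:
            pool = _apply_loss_batch(pool, config.tetraploid_loss_prob, rng)
        survivors = survival_filter(pool, config, rng, apply_penalty=apply_penalty)
        cells = cull_and_replenish(
            survivors, founders, config, rng, replenish_mode=replenish_mode
        )
        pop = Population(cells, generation=gen)
        rec = pop.record(config, keep_hist=keep_hist)
        trajectory.append(rec)
        if enforce_stop and rec.upid_frequency >= config.upid_stop:
            stop_reason = "upid_threshold"
            stop_generation = gen
            break

    return RunResult(
        model=name,
        stop_generation=stop_generation,
        stop_reason=stop_reason,
        final_population=pop,
        trajectory=trajectory,
        seed=seed,
    )


def trajectory_summary(results, *, frac: float = 0.3):
    """Smoothed median-MCN-versus-generation curve over replicate runs.

    Pools the per-generation median-MCN telemetry of all runs and fits a
    tricube-weighted local linear regression (LOESS) of median MCN on
    generation.  Returns a DataFrame with columns ``generation``,
    ``median_mcn`` (across-run median of per-run medians) and
    ``loess_mcn``.
    """
    import pandas as pd
    from statsmodels.nonparametric.smoothers_lowess import lowess

    results = list(results)
    if not results:
        raise ValueError("need at least one run with telemetry")
    rows = []
    for res in results:
        for rec in res.trajectory:
            rows.append((rec.generation, rec.median_mcn))
    df = pd.DataFrame(rows, columns=["generation", "median_mcn"])
    med = df.groupby("generation", as_index=False)["median_mcn"].median()
    if len(med) == 1:
        med["loess_mcn"] = med["median_mcn"]
        return med
    sm = lowess(med["median_mcn"], med["generation"], frac=frac, return_sorted=False)
    med["loess_mcn"] = sm
    return med
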