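"""Synthetic multi-set cohort simulator.

Cohorts are built from Gaussian cell populations: each group is a list
of samples drawn from a (possibly mixture of) multivariate normal
population(s) with diagonal covariance, optionally shifted per sample by
a random technical offset.  Three ready-made scenarios cover the
situations the preprocessing strategies are designed for:

* :func:`scenario_benchmark` — the two-group benchmark used throughout the
  package's tests: a control population with mean ``(0, -2)`` and
  within-sample sd ``(sigma, 4*sigma)`` versus a responder population
  with mean ``(0, 2)`` and the axis-swapped sd ``(4*sigma, sigma)``.
  The post-preprocessing statistics of this design are known in closed
  form (whole-set centered means (0, -2)/(0, 2); whole-set scaled sds
  (0.34, 1.37)/(1.37, 0.34); control-scaled responder sd (4, 0.25)),
  which makes it the reference cohort for validating the strategy
  algebra.
* :func:`scenario_unbalanced` — one sample with many times (default 50x)
  more cells than the rest, the stress test for pooled statistics.
* :func:`scenario_shifted_cohort` — large random per-sample fluorescence
  offsets in both groups plus a group effect expressed as responder
  variance inflation; the regime where per-sample centering combined
  with control-based scaling is the recoverable optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import MarkerPanel, MultiSet, SampleSet

__all__ = [
    "Population",
    "GroupSpec",
    "SimSpec",
    "simulate_multiset",
    "scenario_benchmark",
    "scenario_unbalanced",
    "scenario_shifted_cohort",
]


@dataclass(frozen=True)
class Population:
    """One Gaussian cell population: mixture weight, mean and sd per marker."""

    weight: float
    mean: tuple[float, ...]
    sd: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", tuple(float(v) for v in self.mean))
        object.__setattr__(self, "sd", tuple(float(v) for v in self.sd))
        if len(self.mean) != len(self.sd):
            raise ValueError("population mean and sd need equal length")
        if any(s <= 0 for s in self.sd):
            raise ValueError(f"population sds must be > 0, got {self.sd}")
        if self.weight <= 0:
            raise ValueError(f"population weight must be > 0, got {self.weight}")


@dataclass(frozen=True)
class GroupSpec:
    """One group: its id, number of samples, cells-per-sample rule, mixture.

    ``cells`` may be a fixed integer, a per-sample list, or a
    ``(low, high)`` tuple from which counts are drawn uniformly.
    """

    group_id: int
    n_samples: int
    cells: int | tuple[int, int] | list[int]
    populations: tuple[Population, ...]

    def __post_init__(self) -> None:
        if self.group_id < 0:
            raise ValueError("group_id must be >= 0")
        if self.n_samples < 1:
            raise ValueError("each group needs at least one sample")
        pops = tuple(self.populations)
        object.__setattr__(self, "populations", pops)
        total = sum(p.weight for p in pops)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population weights must sum to 1, got {total}")
        if isinstance(self.cells, int):
            if self.cells < 1:
                raise ValueError("cell count must be >= 1")
        elif isinstance(self.cells, tuple):
            lo, hi = self.cells
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid cell-count range {self.cells}")
        else:
            counts = list(self.cells)
            if len(counts) != self.n_samples:
                raise ValueError("per-sample cell list length must equal "
                                 "n_samples")
            if any(c < 1 for c in counts):
                raise ValueError("cell counts must be >= 1")
            object.__setattr__(self, "cells", counts)


@dataclass(frozen=True)
class SimSpec:
    """Full description of a synthetic cohort (reproducible from seed)."""

    n_markers: int
    groups: tuple[GroupSpec, ...]
    seed: int = 0
    between_sample_shift_sd: float | tuple[float, ...] = 0.0
    marker_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        for g in self.groups:
            for p in g.populations:
                if len(p.mean) != self.n_markers:
                    raise ValueError(
                        f"group {g.group_id}: population dimension "
                        f"{len(p.mean)} != n_markers {self.n_markers}"
                    )
        shift = self.between_sample_shift_sd
        if not np.isscalar(shift):
            shift = tuple(float(v) for v in shift)
            if len(shift) != self.n_markers:
                raise ValueError("between_sample_shift_sd length must equal "
                                 "n_markers")
            object.__setattr__(self, "between_sample_shift_sd", shift)
        elif shift < 0:
            raise ValueError("between_sample_shift_sd must be >= 0")
        if self.marker_names is not None:
            names = tuple(self.marker_names)
            if len(names) != self.n_markers:
                raise ValueError("marker_names length must equal n_markers")
            object.__setattr__(self, "marker_names", names)

    def resolve_cells(self) -> list[list[int]]:
        """Materialize per-sample cell counts (deterministic from seed)."""
        rng = np.random.default_rng(_derive_seed(self.seed, 1))
        out = []
        for g in self.groups:
            if isinstance(g.cells, int):
                out.append([g.cells] * g.n_samples)
            elif isinstance(g.cells, tuple):
                lo, hi = g.cells
                out.append(list(rng.integers(lo, hi + 1, size=g.n_samples)))
            else:
                out.append(list(g.cells))
        return out


def _derive_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0]
               % (2 ** 31))


def simulate_multiset(spec: SimSpec) -> MultiSet:
    """Draw a cohort: per sample, a technical offset plus mixture cells."""
    rng = np.random.default_rng(_derive_seed(spec.seed, 2))
    shift = np.broadcast_to(np.asarray(spec.between_sample_shift_sd,
                                       dtype=float), (spec.n_markers,))
    names = spec.marker_names or tuple(f"M{j + 1}" for j in range(spec.n_markers))
    panel = MarkerPanel(names)
    counts = spec.resolve_cells()
    samples = []
    for g, group_counts in zip(spec.groups, counts):
        prefix = "ctrl" if g.group_id == 0 else f"resp{g.group_id}"
        weights = np.array([p.weight for p in g.populations])
        for i, n_cells in enumerate(group_counts):
            offset = rng.normal(0.0, shift)
            pop_counts = rng.multinomial(n_cells, weights)
            blocks = []
            for p, n_pop in zip(g.populations, pop_counts):
                if n_pop == 0:
                    continue
                blocks.append(rng.normal(np.asarray(p.mean) + offset,
                                         np.asarray(p.sd),
                                         size=(n_pop, spec.n_markers)))
            samples.append(SampleSet(f"{prefix}_{i + 1}", g.group_id,
                                     np.vstack(blocks), validate=False))
    return MultiSet(panel, samples, meta={"seed": spec.seed})


def scenario_benchmark(sigma: float = 0.5, n_samples_per_group: int = 8,
                   cells_per_sample: int = 10_000, seed: int = 0,
                   mu: tuple[float, float] = (0.0, 0.0)) -> SimSpec:
    """Two-marker, two-group benchmark with axis-swapped dispersions.

    Controls: mean ``(mu1, mu2 - 2)``, sd ``(sigma, 4 sigma)``.
    Responders: mean ``(mu1, mu2 + 2)``, sd ``(4 sigma, sigma)``.
    The common offset ``mu`` is arbitrary: every post-preprocessing
    statistic of interest is invariant to it.
    """
    if sigma <= 0 or n_samples_per_group < 1 or cells_per_sample < 1:
        raise ValueError("sigma, n_samples_per_group and cells_per_sample "
                         "must be positive")
    mu1, mu2 = float(mu[0]), float(mu[1])
    control = GroupSpec(0, n_samples_per_group, cells_per_sample,
                        (Population(1.0, (mu1, mu2 - 2.0),
                                    (sigma, 4.0 * sigma)),))
    responder = GroupSpec(1, n_samples_per_group, cells_per_sample,
                          (Population(1.0, (mu1, mu2 + 2.0),
                                      (4.0 * sigma, sigma)),))
    return SimSpec(n_markers=2, groups=(control, responder), seed=seed)


def scenario_unbalanced(base: SimSpec, sample_index: int = 0,
                        factor: int = 50) -> SimSpec:
    """Multiply one sample's cell count by ``factor`` (default 50x).

    ``sample_index`` addresses samples in flat order (group order, then
    sample order within group).  Cell-count rules are materialized to
    explicit per-sample lists so only the chosen sample changes.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    counts = base.resolve_cells()
    flat = [(gi, si) for gi, g in enumerate(counts) for si in range(len(g))]
    if not 0 <= sample_index < len(flat):
        raise ValueError(f"sample_index {sample_index} out of range "
                         f"[0, {len(flat) - 1}]")
    gi, si = flat[sample_index]
    counts[gi][si] = int(counts[gi][si]) * int(factor)
    groups = tuple(
        replace(g, cells=[int(c) for c in group_counts])
        for g, group_counts in zip(base.groups, counts)
    )
    return replace(base, groups=groups)


def scenario_shifted_cohort(n_per_group: int = 8, cells: int = 500,
                            shift_sd: float = 2.0, effect: float = 2.0,
                            seed: int = 0) -> SimSpec:
    """Technical per-sample offsets in both groups plus a variance effect.

    Emulates a cohort where fluorescence baselines drift strongly from
    measurement to measurement (offset sd ``shift_sd`` per marker in
    *both* groups) while the biological group difference is an inflation
    of the responder within-sample sd by ``effect``.  Standard pooled
    preprocessing leaves the technical shifts in place; per-sample
    centering plus control-based scaling removes them and exposes the
    variance effect.
    """
    if n_per_group < 1 or cells < 1 or shift_sd < 0 or effect <= 0:
        raise ValueError("invalid shifted-cohort parameters")
    j = 2
    control = GroupSpec(0, n_per_group, cells,
                        (Population(1.0, (0.0,) * j, (1.0,) * j),))
    responder = GroupSpec(1, n_per_group, cells,
                          (Population(1.0, (0.0,) * j, (float(effect),) * j),))
    return SimSpec(n_markers=j, groups=(control, responder), seed=seed,
                   between_sample_shift_sd=float(shift_sd))
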