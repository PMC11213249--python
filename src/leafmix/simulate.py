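"""Synthetic data generation with planted ground truth.

Three generators cover every input the pipeline consumes:

* :func:`simulate_reference` — a labelled single-cell count matrix drawn from
  per-type expected profiles (negative-binomial counts, planted marker genes,
  optionally a pair of deliberately confusable types whose profiles are mixed
  before sampling so the ground truth stays well-defined);
* :func:`simulate_bulk_series` — bulk count series whose true cell-type
  fraction trajectories follow diurnal sinusoids, monotone developmental
  trends or constants, with replicate noise on the weight scale and Poisson
  count noise at a requested sequencing depth;
* :func:`simulate_network` — a directed TF->target edge list with per-gene
  functional-term annotations and planted term-pair enrichment.

All randomness flows from the explicit ``seed`` of each call; no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "ReferenceSimConfig",
    "SyntheticReference",
    "Sinusoid",
    "Monotone",
    "Constant",
    "SyntheticBulkSeries",
    "NetworkSimConfig",
    "SyntheticNetwork",
    "leaf_reference_config",
    "leaf_trajectories",
    "simulate_reference",
    "simulate_bulk_series",
    "simulate_network",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


# ---------------------------------------------------------------------------
# single-cell reference
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSimConfig:
    """Parameters of the synthetic labelled single-cell reference.

    ``confusable_pairs`` lists ``(a, b, w)`` type-index triples: type ``b``'s
    expected profile is replaced by ``(1 - w) * profile_b + w * profile_a``,
    planting a type that is hard to separate from its partner.
    """

    n_cell_types: int
    cells_per_type: tuple[int, ...]
    n_genes: int
    markers_per_type: int
    marker_fold_change: float = 4.0
    baseline_mean: float = 0.3
    dispersion: float = 0.4
    confusable_pairs: tuple[tuple[int, int, float], ...] = ()
    type_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_cell_types < 1:
            raise ConfigError("n_cell_types must be >= 1")
        if len(self.cells_per_type) != self.n_cell_types:
            raise ConfigError(
                "cells_per_type length must equal n_cell_types "
                f"({len(self.cells_per_type)} != {self.n_cell_types})"
            )
        if any(c < 1 for c in self.cells_per_type):
            raise ConfigError("cells_per_type entries must be >= 1")
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ConfigError("markers_per_type x n_cell_types exceeds n_genes")
        if self.marker_fold_change <= 0:
            raise ConfigError("marker_fold_change must be positive")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        for a, b, w in self.confusable_pairs:
            if not (0 <= w <= 1):
                raise ConfigError(f"confusable_pairs weight {w} outside [0, 1]")
            if not (0 <= a < self.n_cell_types and 0 <= b < self.n_cell_types):
                raise ConfigError("confusable_pairs type index out of range")
        if self.type_names is not None and len(self.type_names) != self.n_cell_types:
            raise ConfigError("type_names length must equal n_cell_types")


@dataclass
class SyntheticReference:
    counts: pd.DataFrame          # genes x cells, integer
    labels: pd.Series             # cell -> type name
    true_profiles: pd.DataFrame   # genes x types, expected counts per cell


LEAF_TYPES = (
    "mesophyll_1",
    "mesophyll_2",
    "mesophyll_3",
    "epidermis",
    "vascular",
    "bundle_sheath",
    "companion",
    "guard",
    "phloem_parenchyma",
    "hydathode",
)


def leaf_reference_config(seed: int = 0) -> ReferenceSimConfig:
    """Default 10-type leaf roster: three mesophyll groups plus epidermal,
    vascular and rare cell types, with a rare hydathode-like type whose
    profile is mixed with weight 0.8 toward mesophyll group 1 — the cluster
    pair that real leaf references struggle to separate."""
    return ReferenceSimConfig(
        n_cell_types=10,
        cells_per_type=(220,) * 9 + (60,),
        n_genes=3000,
        markers_per_type=25,
        marker_fold_change=4.0,
        baseline_mean=0.3,
        dispersion=0.4,
        confusable_pairs=((0, 9, 0.8),),   # hydathode pulled toward mesophyll_1
        type_names=LEAF_TYPES,
        seed=seed,
    )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size_param: float):
    """Negative binomial with mean ``mean`` and size (dispersion) ``size_param``;
    zero mean yields zero counts exactly."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_reference(config: ReferenceSimConfig) -> SyntheticReference:
    rng = np.random.default_rng(config.seed)
    T, G = config.n_cell_types, config.n_genes
    names = list(config.type_names or (f"type_{k}" for k in range(T)))

    profiles = np.full((G, T), config.baseline_mean, dtype=float)
    m = config.markers_per_type
    for k in range(T):
        profiles[k * m:(k + 1) * m, k] *= config.marker_fold_change
    for a, b, w in config.confusable_pairs:
        profiles[:, b] = (1.0 - w) * profiles[:, b] + w * profiles[:, a]

    genes = [f"G{i:05d}" for i in range(G)]
    cells, labels, blocks = [], [], []
    for k, n_cells in enumerate(config.cells_per_type):
        mean = np.broadcast_to(profiles[:, [k]], (G, n_cells))
        blocks.append(_nb_sample(rng, mean, config.dispersion))
        cells.extend(f"{names[k]}.c{i:04d}" for i in range(n_cells))
        labels.extend([names[k]] * n_cells)

    counts = pd.DataFrame(np.hstack(blocks), index=genes, columns=cells)
    return SyntheticReference(
        counts=counts,
        labels=pd.Series(labels, index=cells, name="cell_type"),
        true_profiles=pd.DataFrame(profiles, index=genes, columns=names),
    )


# ---------------------------------------------------------------------------
# bulk time series
# ---------------------------------------------------------------------------

@dataclass
class Sinusoid:
    """Diurnal weight trajectory: baseline + amplitude * cos(2*pi*(t - phase)/period).

    Peaks at ``t = phase_hours``; must remain >= 0 at every sampled time."""
    amplitude: float
    phase_hours: float
    baseline: float = 1.0
    period: float = 24.0

    def weight(self, t: float) -> float:
        return self.baseline + self.amplitude * math.cos(
            2.0 * math.pi * (t - self.phase_hours) / self.period
        )


@dataclass
class Monotone:
    """Developmental trend: linear interpolation of the weight from
    ``start_weight`` at the first sampled time to ``end_weight`` at the last."""
    start_weight: float
    end_weight: float

    def weight_at_fraction(self, frac: float) -> float:
        return self.start_weight + (self.end_weight - self.start_weight) * frac


@dataclass
class Constant:
    value: float

    def weight(self, t: float) -> float:
        return self.value


@dataclass
class SyntheticBulkSeries:
    counts: pd.DataFrame          # genes x samples
    metadata: pd.DataFrame        # sample -> time/age, replicate, traits
    true_fractions: pd.DataFrame  # samples x types, rows on the simplex


def _trajectory_weight(traj, t: float, frac: float) -> float:
    if isinstance(traj, Monotone):
        return traj.weight_at_fraction(frac)
    return traj.weight(t)


def leaf_trajectories(
    types, amplitude: float = 0.5, phases=None
) -> dict[str, Sinusoid]:
    """Convenience roster: one diurnal sinusoid per type with staggered phases."""
    types = list(types)
    if phases is None:
        phases = [24.0 * i / len(types) for i in range(len(types))]
    return {
        t: Sinusoid(amplitude=amplitude, phase_hours=ph, baseline=1.0)
        for t, ph in zip(types, phases)
    }


def simulate_bulk_series(
    reference_profiles: pd.DataFrame,
    trajectories: dict,
    timepoints,
    depth: int = 1_000_000,
    n_replicates: int = 4,
    replicate_noise_sd: float = 0.02,
    seed: int = 0,
    time_column: str = "time_hours",
    traits: bool = False,
) -> SyntheticBulkSeries:
    """Simulate a bulk count series from per-type expected profiles.

    At each timepoint the per-type weights from ``trajectories`` are
    normalized to fractions; each replicate perturbs the weights with
    Gaussian noise (sd ``replicate_noise_sd``), clamps at 0 and renormalizes,
    so true fractions stay on the simplex.  Expected bulk expression is the
    fraction-weighted profile mixture scaled to ``depth`` total counts, and
    observed counts are Poisson around it.  With ``traits=True`` the metadata
    gains pseudotime / biomass / leaf_area columns that increase monotonically
    with the time axis plus noise.
    """
    types = list(reference_profiles.columns)
    if set(trajectories) != set(types):
        raise ConfigError("trajectories must cover exactly the profile types")
    timepoints = list(timepoints)
    t0, t1 = min(timepoints), max(timepoints)
    span = (t1 - t0) or 1.0
    rng = np.random.default_rng(seed)
    P = reference_profiles.to_numpy(dtype=float)

    rows, samples, fracs = [], [], []
    count_cols = []
    for t in timepoints:
        w = np.array(
            [_trajectory_weight(trajectories[k], t, (t - t0) / span) for k in types]
        )
        if (w < 0).any():
            bad = types[int(np.argmin(w))]
            raise ConfigError(
                f"negative trajectory weight for type {bad!r} at time {t}"
            )
        for rep in range(n_replicates):
            wr = np.clip(w + rng.normal(0.0, replicate_noise_sd, len(types)), 0, None)
            if wr.sum() == 0:
                wr = w.copy()
            f = wr / wr.sum()
            expected = P @ f
            expected = expected * (depth / expected.sum())
            count_cols.append(rng.poisson(expected))
            sid = f"t{t:g}_r{rep + 1}"
            samples.append(sid)
            rows.append({time_column: t, "replicate": f"r{rep + 1}"})
            fracs.append(f)

    metadata = pd.DataFrame(rows, index=samples)
    if traits:
        ax = metadata[time_column].to_numpy(dtype=float)
        frac_ax = (ax - t0) / span
        metadata["pseudotime"] = frac_ax + rng.normal(0, 0.02, len(ax))
        metadata["biomass"] = 1.0 + 4.0 * frac_ax**2 + rng.normal(0, 0.05, len(ax))
        metadata["leaf_area"] = 1.0 + 3.0 * frac_ax**1.5 + rng.normal(0, 0.05, len(ax))

    counts = pd.DataFrame(
        np.column_stack(count_cols), index=reference_profiles.index, columns=samples
    )
    true_fractions = pd.DataFrame(np.vstack(fracs), index=samples, columns=types)
    return SyntheticBulkSeries(counts, metadata, true_fractions)


# ---------------------------------------------------------------------------
# annotated regulatory network
# ---------------------------------------------------------------------------

@dataclass
class NetworkSimConfig:
    """Parameters of the synthetic annotated TF->target network."""

    n_tfs: int
    n_targets: int
    n_edges: int
    n_terms: int
    annotation_prob: float
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_edges > self.n_tfs * self.n_targets:
            raise ConfigError("n_edges exceeds n_tfs x n_targets")
        if not (0 < self.annotation_prob < 1):
            raise ConfigError("annotation_prob must lie in (0, 1)")
        for a, b, f in self.planted_pairs:
            if f < 1:
                raise ConfigError(f"enrichment_factor {f} must be >= 1")


@dataclass
class SyntheticNetwork:
    edges: pd.DataFrame                 # source, target
    annotations: dict[str, list[str]]   # term -> genes
    planted_pairs: tuple[tuple[str, str, float], ...]


def simulate_network(config: NetworkSimConfig) -> SyntheticNetwork:
    """Draw ``n_edges`` distinct TF->target edges, uniform over the grid except
    that source-has-A -> target-has-B cells of each planted pair (A, B, f) are
    oversampled by factor f; each gene carries each term independently with
    ``annotation_prob``."""
    rng = np.random.default_rng(config.seed)
    tfs = [f"TF{i:04d}" for i in range(config.n_tfs)]
    targets = [f"TG{i:04d}" for i in range(config.n_targets)]
    genes = tfs + targets
    terms = [f"TERM{i:03d}" for i in range(config.n_terms)]

    has_term = {
        term: rng.random(len(genes)) < config.annotation_prob for term in terms
    }
    annotations = {
        term: [g for g, keep in zip(genes, mask) if keep]
        for term, mask in has_term.items()
    }

    n_tf, n_tg = config.n_tfs, config.n_targets
    weights = np.ones(n_tf * n_tg)
    for a, b, f in config.planted_pairs:
        if a not in has_term or b not in has_term:
            raise ConfigError(f"planted pair ({a}, {b}) names an unknown term")
        src_mask = has_term[a][:n_tf]
        tgt_mask = has_term[b][n_tf:]
        cell = np.outer(src_mask, tgt_mask).ravel()
        weights[cell] *= f
    prob = weights / weights.sum()
    if (prob * config.n_edges).max() > 1.0:
        raise ConfigError(
            "enrichment pushes a sampling probability above 1; lower "
            "enrichment_factor or n_edges"
        )
    chosen = rng.choice(n_tf * n_tg, size=config.n_edges, replace=False, p=prob)
    src = np.asarray(tfs)[chosen // n_tg]
    tgt = np.asarray(targets)[chosen % n_tg]
    edges = pd.DataFrame({"source": src, "target": tgt})
    return SyntheticNetwork(edges, annotations, tuple(config.planted_pairs))
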