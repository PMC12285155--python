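"""Synthetic multi-batch scRNA-seq generator with known ground truth.

Counts follow a gamma-Poisson (negative binomial) model: the expected
count of gene g in cell i is

    mu_ig = program[type(i)][g] * batch_factor[batch(i)][g] * library(i)

with cell-type expression programs built from a shared log-normal
baseline plus type-specific up-regulated marker genes, gene-wise
multiplicative log-normal batch factors (scale sigma_b per batch),
log-normal library-size variation, per-gene NB dispersion, and optional
uniform dropout zeroing. The composition table (cells per batch x type)
encodes dominant, minority and standalone structure, so sharing splits,
dominance and inclusion scenarios are known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fedbatch.data import ExpressionDataset, LayerTag

__all__ = ["SimulationConfig", "GroundTruth", "generate", "preset", "PRESETS"]


@dataclass
class SimulationConfig:
    """Everything the generator needs; deterministic given ``seed``.

    ``composition[batch][cell_type]`` is the number of cells to draw.
    ``batch_effect[batch]`` is the log-normal sigma of that batch's
    gene-wise multiplicative factor (0 = no technical shift).
    """

    n_genes: int = 300
    composition: dict = field(default_factory=dict)
    batch_effect: dict = field(default_factory=dict)
    n_markers_per_type: int = 30
    marker_fold: float = 6.0
    baseline_log_mean: float = 0.0
    baseline_log_sigma: float = 1.0
    library_size_sigma: float = 0.3
    dropout_rate: float = 0.1
    dispersion_range: tuple[float, float] = (0.1, 1.0)
    seed: int = 0

    def __post_init__(self):
        if not self.composition:
            raise ValueError("composition must name at least one (batch, type) count")
        for b, row in self.composition.items():
            for t, n in row.items():
                if int(n) != n or n < 0:
                    raise ValueError(f"composition[{b}][{t}] must be a nonnegative integer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        for b in self.composition:
            self.batch_effect.setdefault(b, 0.0)
            if self.batch_effect[b] < 0:
                raise ValueError("batch effect sigma must be >= 0")

    @property
    def batches(self) -> list[str]:
        return list(self.composition)

    @property
    def cell_types(self) -> list[str]:
        seen: list[str] = []
        for row in self.composition.values():
            for t in row:
                if t not in seen:
                    seen.append(t)
        return seen


@dataclass
class GroundTruth:
    type_labels: np.ndarray
    batch_labels: np.ndarray
    programs: dict  # type -> per-gene mean expression
    batch_factors: dict  # batch -> per-gene multiplicative factor
    library_sizes: np.ndarray
    marker_genes: dict  # type -> indices of up-regulated genes


def _build_programs(config: SimulationConfig, rng: np.random.Generator):
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sigma, config.n_genes)
    programs, markers = {}, {}
    gene_pool = rng.permutation(config.n_genes)
    k = config.n_markers_per_type
    for j, t in enumerate(config.cell_types):
        prog = baseline.copy()
        idx = gene_pool[(j * k) % config.n_genes : (j * k) % config.n_genes + k]
        prog[idx] = prog[idx] * config.marker_fold
        programs[t] = prog
        markers[t] = np.sort(idx)
    return programs, markers


def generate(config: SimulationConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset (raw counts) plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    programs, markers = _build_programs(config, rng)
    batch_factors = {
        b: (rng.lognormal(0.0, s, config.n_genes) if s > 0 else np.ones(config.n_genes))
        for b, s in config.batch_effect.items()
    }
    phi = np.exp(
        rng.uniform(
            np.log(config.dispersion_range[0]),
            np.log(config.dispersion_range[1]),
            config.n_genes,
        )
    )
    r = 1.0 / phi  # NB size: var = mu + phi * mu^2

    rows, tlab, blab = [], [], []
    libs = []
    for b in config.batches:
        for t, n in config.composition[b].items():
            if n == 0:
                continue
            lib = rng.lognormal(0.0, config.library_size_sigma, int(n))
            mu = programs[t][None, :] * batch_factors[b][None, :] * lib[:, None]
            lam = rng.gamma(shape=r[None, :], scale=mu / r[None, :])
            counts = rng.poisson(lam).astype(np.float64)
            if config.dropout_rate > 0:
                counts *= rng.random(counts.shape) >= config.dropout_rate
            rows.append(counts)
            tlab += [t] * int(n)
            blab += [b] * int(n)
            libs.append(lib)
    matrix = np.vstack(rows)
    n_cells = matrix.shape[0]
    ds = ExpressionDataset(
        matrix=matrix,
        batch_labels=np.asarray(blab, dtype=object),
        cell_type_labels=np.asarray(tlab, dtype=object),
        gene_ids=np.asarray([f"g{i:04d}" for i in range(config.n_genes)], dtype=object),
        cell_ids=np.asarray([f"cell{i:05d}" for i in range(n_cells)], dtype=object),
        layer_tag=LayerTag.raw_counts,
    )
    truth = GroundTruth(
        type_labels=np.asarray(tlab, dtype=object),
        batch_labels=np.asarray(blab, dtype=object),
        programs=programs,
        batch_factors=batch_factors,
        library_sizes=np.concatenate(libs),
        marker_genes=markers,
    )
    return ds, truth


def _compo(table: dict) -> dict:
    return {b: dict(row) for b, row in table.items()}


def preset(name: str, seed: int = 0) -> SimulationConfig:
    """Named study designs used throughout the tests and examples.

    - ``two_batch_shared``: 1,000 cells, 2 batches x 4 shared types, strong
      batch effect on one batch — the basic correction scenario.
    - ``five_batch_hp_like``: 5 batches with shared types whose dominant
      batches differ, echoing a multi-study pancreas-style design.
    - ``standalone_type``: one type confined to a single batch.
    - ``minority_types``: types below the minority threshold for the
      Combined/Dropped inclusion scenarios.
    - ``held_out``: five batches of which one ("B4") is excluded from
      training and arrives only at correction time.
    """
    if name == "two_batch_shared":
        return SimulationConfig(
            composition=_compo(
                {
                    "B0": {"alpha": 125, "beta": 125, "gamma": 125, "delta": 125},
                    "B1": {"alpha": 125, "beta": 125, "gamma": 125, "delta": 125},
                }
            ),
            batch_effect={"B0": 0.0, "B1": 0.8},
            seed=seed,
        )
    if name == "five_batch_hp_like":
        return SimulationConfig(
            composition=_compo(
                {
                    "B0": {"alpha": 120, "beta": 40, "gamma": 30, "delta": 20},
                    "B1": {"alpha": 40, "beta": 110, "gamma": 25, "delta": 25},
                    "B2": {"alpha": 30, "beta": 30, "gamma": 100, "delta": 20},
                    "B3": {"alpha": 25, "beta": 25, "gamma": 30, "delta": 90},
                    "B4": {"alpha": 30, "beta": 30, "gamma": 30, "delta": 30},
                }
            ),
            batch_effect={"B0": 0.0, "B1": 0.4, "B2": 0.5, "B3": 0.6, "B4": 0.7},
            seed=seed,
        )
    if name == "standalone_type":
        return SimulationConfig(
            composition=_compo(
                {
                    "B0": {"alpha": 150, "beta": 150, "solo": 80},
                    "B1": {"alpha": 150, "beta": 150},
                }
            ),
            batch_effect={"B0": 0.0, "B1": 0.5},
            seed=seed,
        )
    if name == "minority_types":
        return SimulationConfig(
            composition=_compo(
                {
                    "B0": {"alpha": 200, "beta": 150, "rare1": 5, "rare2": 4},
                    "B1": {"alpha": 180, "beta": 160, "rare1": 3, "rare2": 2},
                }
            ),
            batch_effect={"B0": 0.0, "B1": 0.5},
            seed=seed,
        )
    if name == "held_out":
        cfg = preset("five_batch_hp_like", seed=seed)
        cfg.composition["B4"] = {"alpha": 20, "beta": 20, "gamma": 20, "delta": 20}
        return cfg
    raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


PRESETS = {"two_batch_shared", "five_batch_hp_like", "standalone_type", "minority_types", "held_out"}

HELD_OUT_BATCH = "B4"
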