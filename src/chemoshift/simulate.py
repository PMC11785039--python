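"""Synthetic factorial expression experiments and tumor-growth datasets.

:func:`simulate_experiment` emulates the kind of study the pipeline analyses:
a 2 treatments x 2 phenotypes x r replicates microarray design on the log2
scale, a compendium of transcription-factor target sets, and one "active"
factor whose targets are induced by treatment but with the induction dampened
in the non-reference phenotype — the planted interaction the analysis must
recover.  Per-gene expression is generated directly from the factorial model
(x = mu + d*[treated] + c*[alt] + e*[treated & alt] + Gaussian noise), so the
generator's truth parameters are exactly the estimands of the fitting module.

:func:`simulate_growth` produces caliper series with log-normal noise around
exponential kinetics, with L = W = H chosen so the ellipsoid volume formula
reproduces the simulated volume exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleDesign,
    TumorSeries,
)

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_experiment", "simulate_growth"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic factorial expression experiment.

    Defaults emulate the deposited design the pipeline was built around:
    8 arrays (2 treatments x 2 phenotypes x 2 replicates), ~10,000 measured
    genes, a compendium of 50 TFs with 200 targets each, a 1.0 log2-unit
    treatment induction of the active TF's targets dampened by 0.6 log2 units
    in the non-reference phenotype, and 0.25 log2 units of replicate noise.
    """

    n_genes: int = 10_000
    n_tfs: int = 50
    targets_per_tf: int = 200
    overlap_fraction: float = 0.0
    reps_per_cell: int = 2
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    treatment_effect: float = 1.0  # d* on active-TF targets (log2)
    dampening: float = 0.6  # delta*: subtracted from d* in the alt phenotype
    effect_spread: float = 0.0  # per-target sd around the planted interaction
    background_effect_sd: float = 0.1  # small random d/c/e on background genes
    noise_sd: float = 0.25  # replicate noise sigma (log2)
    active_tf: str = "TF001"
    treatment_levels: tuple[str, str] = ("control", "irinotecan")
    phenotype_levels: tuple[str, str] = ("NT", "CSC")
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_tfs", "targets_per_tf", "reps_per_cell"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ConfigError("overlap_fraction must lie in [0, 1]")
        for name in ("baseline_sd", "background_effect_sd", "noise_sd", "effect_spread"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        n_shared = round(self.overlap_fraction * self.targets_per_tf)
        own = self.targets_per_tf - n_shared
        if own * self.n_tfs + n_shared > self.n_genes:
            raise ConfigError(
                "targets_per_tf x n_tfs exceeds n_genes at this overlap_fraction"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-gene parameters and the generating configuration."""

    params: pd.DataFrame = field(repr=False)  # gene-indexed mu, d, c, e, is_target
    active_tf: str = ""
    config: SimulationConfig = None  # type: ignore[assignment]


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _tf_names(n: int) -> list[str]:
    return [f"TF{i:03d}" for i in range(1, n + 1)]


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleDesign, GeneSetCollection, SyntheticTruth]:
    """Generate (matrix, design, TF target collection, truth) for one experiment.

    Identical seeds give bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    tf_names = _tf_names(config.n_tfs)
    if config.active_tf not in tf_names:
        raise ConfigError(f"active_tf {config.active_tf!r} not among generated TF names")

    # target assignment: an optional shared pool plus disjoint per-TF blocks
    n_shared = round(config.overlap_fraction * config.targets_per_tf)
    own = config.targets_per_tf - n_shared
    perm = rng.permutation(config.n_genes)
    shared = [genes[i] for i in perm[:n_shared]]
    sets = {}
    offset = n_shared
    for name in tf_names:
        block = [genes[i] for i in perm[offset : offset + own]]
        offset += own
        sets[name] = GeneSet(name, f"synthetic targets of {name}", frozenset(shared + block))
    collection = GeneSetCollection(sets)
    target_mask = np.zeros(config.n_genes, dtype=bool)
    active_members = collection[config.active_tf].members
    for i, g in enumerate(genes):
        if g in active_members:
            target_mask[i] = True

    # planted parameters
    mu = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    d = rng.normal(0.0, config.background_effect_sd, config.n_genes)
    c = rng.normal(0.0, config.background_effect_sd, config.n_genes)
    e = rng.normal(0.0, config.background_effect_sd, config.n_genes)
    d[target_mask] = config.treatment_effect
    planted_e = -config.dampening
    if config.effect_spread > 0:
        e[target_mask] = planted_e + rng.normal(
            0.0, config.effect_spread, int(target_mask.sum())
        )
    else:
        e[target_mask] = planted_e

    # samples: control first so default reference coding matches the truth
    t_ctrl, t_drug = config.treatment_levels
    p_ref, p_alt = config.phenotype_levels
    rows = []
    sample_ids = []
    for t in (t_ctrl, t_drug):
        for p in (p_ref, p_alt):
            for r in range(1, config.reps_per_cell + 1):
                sample_ids.append(f"{t}_{p}_r{r}")
                rows.append((t, p, r))
    design = SampleDesign(
        pd.DataFrame(rows, columns=["treatment", "phenotype", "replicate"],
                     index=pd.Index(sample_ids, name="sample")),
        treatment_levels=(t_ctrl, t_drug),
        phenotype_levels=(p_ref, p_alt),
    )
    treated, alt = design.indicator_arrays(sample_ids)
    signal = (
        mu[:, None]
        + np.outer(d, treated)
        + np.outer(c, alt)
        + np.outer(e, treated * alt)
    )
    noise = rng.normal(0.0, config.noise_sd, signal.shape) if config.noise_sd > 0 else 0.0
    matrix = ExpressionMatrix(
        pd.DataFrame(signal + noise, index=genes, columns=sample_ids)
    )
    truth = SyntheticTruth(
        params=pd.DataFrame(
            {"mu": mu, "d": d, "c": c, "e": e, "is_target": target_mask},
            index=pd.Index(genes, name="gene"),
        ),
        active_tf=config.active_tf,
        config=config,
    )
    return matrix, design, collection, truth


def simulate_growth(
    n_per_cell: int,
    rates: dict[tuple[str, str], float],
    v0: float,
    noise_sd: float,
    days: list[float] | np.ndarray,
    seed: int = 0,
) -> list[TumorSeries]:
    """Simulate caliper series for a 2x2 (vector x treatment) experiment.

    ``rates`` maps each (vector, treatment) cell to its per-day exponential
    rate k; volumes are V(t) = v0 * exp(k*t) * exp(N(0, noise_sd)), and the
    three caliper dimensions are set equal so the ellipsoid formula inverts
    exactly.
    """
    if v0 <= 0:
        raise ConfigError("v0 must be positive")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    days = np.asarray(days, dtype=float)
    series = []
    for (vector, treatment), k in rates.items():
        for i in range(1, n_per_cell + 1):
            log_v = np.log(v0) + k * days
            if noise_sd > 0:
                log_v = log_v + rng.normal(0.0, noise_sd, days.size)
            volumes = np.exp(log_v)
            dim = np.cbrt(6.0 * volumes / np.pi)  # L = W = H inverts V = LWH*pi/6
            series.append(
                TumorSeries(
                    tumor_id=f"{vector}_{treatment}_{i}",
                    vector=vector,
                    treatment=treatment,
                    days=tuple(days),
                    lengths=tuple(dim),
                    widths=tuple(dim),
                    heights=tuple(dim),
                )
            )
    return series
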