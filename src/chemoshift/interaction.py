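"""Per-gene factorial interaction model and responsive-gene selection.

The model for one gene's log2 level is

    x = mu + d * [treated] + c * [alt phenotype] + e * [treated & alt] + eps

under reference-level (treatment-contrast) coding: ``mu`` is the fitted level
in the (control, reference-phenotype) cell, ``d`` the treatment effect at the
reference phenotype, ``c`` the phenotype offset under control, and ``e`` the
interaction — the difference-of-differences quantifying how much the drug
response differs between the two phenotypes.  Genes are ranked on the raw
``e`` and the extreme tails (default 5% each side) form the "responsive" set
fed to enrichment.

The public surface follows the Model/Results convention: build an
:class:`InteractionModel` from an expression matrix and design, call
``fit()``, and query the returned :class:`InteractionResults`.  Thin
functional wrappers (:func:`fit_gene_model`, :func:`fit_all`,
:func:`rank_and_select`) expose the same operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyCellError, FractionError
from .io import ExpressionMatrix, SampleDesign

__all__ = [
    "InteractionFit",
    "ResponsiveSelection",
    "InteractionModel",
    "InteractionResults",
    "fit_gene_model",
    "fit_all",
    "rank_and_select",
]


@dataclass(frozen=True)
class InteractionFit:
    """OLS estimates for one gene under treatment-contrast coding."""

    gene: str
    mu: float
    d: float
    c: float
    e: float
    resid_sd: float
    n_obs: int


@dataclass(frozen=True)
class ResponsiveSelection:
    """Extreme-interaction gene tails.

    ``top_genes`` ordered by decreasing e (preferential drug response in the
    non-reference phenotype), ``bottom_genes`` by increasing e; the two tails
    are disjoint and their union is the responsive set.
    """

    fraction: float
    top_genes: tuple
    bottom_genes: tuple

    @property
    def responsive(self) -> frozenset:
        return frozenset(self.top_genes) | frozenset(self.bottom_genes)


class InteractionModel:
    """Gene-wise 2x2 factorial OLS model of a log2 expression matrix."""

    def __init__(self, matrix: ExpressionMatrix, design: SampleDesign):
        missing = set(matrix.sample_ids) - set(design.sample_ids)
        if missing:
            raise EmptyCellError(f"design lacks samples: {sorted(missing)}")
        self.matrix = matrix
        self.design = design
        treated, alt = design.indicator_arrays(matrix.sample_ids)
        for t_val in (0.0, 1.0):
            for p_val in (0.0, 1.0):
                if not np.any((treated == t_val) & (alt == p_val)):
                    t_lab = design.treatment_levels[int(t_val)]
                    p_lab = design.phenotype_levels[int(p_val)]
                    raise EmptyCellError(f"empty design cell ({t_lab!r}, {p_lab!r})")
        n = len(treated)
        self._X = np.column_stack([np.ones(n), treated, alt, treated * alt])

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, design: SampleDesign) -> "InteractionModel":
        return cls(ExpressionMatrix(values), design)

    def fit(self) -> "InteractionResults":
        """Solve the least-squares problem for every gene at once."""
        X = self._X
        Y = self.matrix.values.T  # samples x genes
        beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        rss = np.einsum("ij,ij->j", resid, resid)
        n = X.shape[0]
        dof = n - 4
        if dof > 0:
            resid_sd = np.sqrt(np.maximum(rss, 0.0) / dof)
        else:
            resid_sd = np.zeros(Y.shape[1])
        params = pd.DataFrame(
            beta.T, index=self.matrix.gene_ids, columns=["mu", "d", "c", "e"]
        )
        return InteractionResults(self, params, pd.Series(resid_sd, index=params.index), n)


class InteractionResults:
    """Fitted per-gene parameters with tail selection and a text summary."""

    def __init__(
        self,
        model: InteractionModel,
        params: pd.DataFrame,
        resid_sd: pd.Series,
        n_obs: int,
    ):
        self.model = model
        self.params = params
        self.resid_sd = resid_sd
        self.n_obs = n_obs

    def __iter__(self):
        for gene, row in self.params.iterrows():
            yield InteractionFit(
                gene=str(gene),
                mu=float(row["mu"]),
                d=float(row["d"]),
                c=float(row["c"]),
                e=float(row["e"]),
                resid_sd=float(self.resid_sd[gene]),
                n_obs=self.n_obs,
            )

    def to_frame(self) -> pd.DataFrame:
        df = self.params.copy()
        df["resid_sd"] = self.resid_sd
        df["n_obs"] = self.n_obs
        df.index.name = "gene"
        return df

    def select_responsive(self, fraction: float = 0.05) -> ResponsiveSelection:
        return rank_and_select(list(self), fraction=fraction)

    def summary(self) -> str:
        e = self.params["e"]
        lines = [
            "Factorial interaction model (treatment-contrast coding)",
            f"  genes: {len(self.params)}   samples: {self.n_obs}",
            f"  treatment levels: {self.model.design.treatment_levels}"
            f"   phenotype levels: {self.model.design.phenotype_levels}",
            f"  interaction e: mean={e.mean():.4g}  sd={e.std(ddof=1):.4g}"
            if len(e) > 1
            else f"  interaction e: {e.iloc[0]:.4g}",
            f"  median residual sd: {self.resid_sd.median():.4g}",
        ]
        return "\n".join(lines)


def fit_gene_model(
    values: Sequence[float] | pd.Series,
    design: SampleDesign,
    gene: str = "gene",
) -> InteractionFit:
    """Fit the factorial model to a single gene's per-sample log2 levels.

    ``values`` must align with ``design.sample_ids`` (or carry them as a
    pandas index).
    """
    if isinstance(values, pd.Series):
        sample_ids = list(values.index)
        data = pd.DataFrame([values.to_numpy(dtype=float)], index=[gene], columns=sample_ids)
    else:
        sample_ids = design.sample_ids
        data = pd.DataFrame(
            [np.asarray(values, dtype=float)], index=[gene], columns=sample_ids
        )
    results = InteractionModel(ExpressionMatrix(data), design).fit()
    return next(iter(results))


def fit_all(matrix: ExpressionMatrix, design: SampleDesign) -> list[InteractionFit]:
    """Fit every gene; one :class:`InteractionFit` per row, gene order preserved."""
    return list(InteractionModel(matrix, design).fit())


def rank_and_select(
    fits: Sequence[InteractionFit], fraction: float = 0.05
) -> ResponsiveSelection:
    """Take the k most extreme genes per tail of the interaction ranking.

    k = max(1, floor(fraction * G)).  Boundary ties are broken by gene
    identifier; the bottom tail is filled from genes not already in the top
    tail, keeping the tails disjoint even when e values are fully tied.
    """
    if not (0.0 < fraction < 0.5):
        raise FractionError(f"fraction must lie in (0, 0.5), got {fraction}")
    genes = [(f.e, f.gene) for f in fits]
    n = len(genes)
    k = max(1, int(np.floor(fraction * n)))
    if 2 * k > n:
        raise FractionError(f"tails of size {k} overlap in a {n}-gene ranking")
    top_sorted = sorted(genes, key=lambda eg: (-eg[0], eg[1]))
    top = [g for _, g in top_sorted[:k]]
    top_set = set(top)
    bottom_sorted = sorted(
        (eg for eg in genes if eg[1] not in top_set), key=lambda eg: (eg[0], eg[1])
    )
    bottom = [g for _, g in bottom_sorted[:k]]
    return ResponsiveSelection(fraction=fraction, top_genes=tuple(top), bottom_genes=tuple(bottom))
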