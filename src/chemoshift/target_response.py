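"""Aggregate drug response of TF targets vs non-targets.

For every gene the treated-minus-control difference of mean log2 levels
(the log2 fold-change) is computed separately in the reference and the
non-reference phenotype.  Genes are stratified into targets and non-targets of
the transcription factor under study, and the per-stratum averages of the two
fold-changes and of their per-gene difference (reference minus non-reference,
the "dampening") are reported with 95% t confidence intervals and a two-tailed
Welch t-test between strata.  On a balanced design the per-gene difference
equals minus the fitted interaction term, so this view and the factorial model
tell one consistent story.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import EmptyCellError
from .io import ExpressionMatrix, SampleDesign

__all__ = ["FoldChangeRecord", "TargetSummary", "fold_changes", "summarize_by_target"]


@dataclass(frozen=True)
class FoldChangeRecord:
    gene: str
    fc_ref: float  # log2 FC (treated - control) in the reference phenotype
    fc_alt: float  # same in the non-reference phenotype
    is_target: bool

    @property
    def delta(self) -> float:
        """Dampening of the drug response in the non-reference phenotype."""
        return self.fc_ref - self.fc_alt


@dataclass(frozen=True)
class TargetSummary:
    group: str  # "target" | "non-target"
    n: int
    mean_fc_ref: float
    mean_fc_alt: float
    mean_delta: float
    ci_fc_ref: tuple[float, float] | None
    ci_fc_alt: tuple[float, float] | None
    ci_delta: tuple[float, float] | None
    welch_t: float | None
    welch_df: float | None
    welch_p: float | None
    degenerate: bool = False  # too few genes or zero variance for t machinery


def fold_changes(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    targets: Iterable[str],
) -> list[FoldChangeRecord]:
    """Per-gene, per-phenotype log2 fold-changes with target membership."""
    cells = design.cells()
    t_ctrl, t_drug = design.treatment_levels
    p_ref, p_alt = design.phenotype_levels
    for key, samples in cells.items():
        if not samples:
            raise EmptyCellError(f"empty design cell {key!r}")
    df = matrix.data
    means = {key: df[samples].mean(axis=1) for key, samples in cells.items()}
    fc_ref = means[(t_drug, p_ref)] - means[(t_ctrl, p_ref)]
    fc_alt = means[(t_drug, p_alt)] - means[(t_ctrl, p_alt)]
    target_set = frozenset(targets)
    return [
        FoldChangeRecord(
            gene=str(g),
            fc_ref=float(fc_ref[g]),
            fc_alt=float(fc_alt[g]),
            is_target=g in target_set,
        )
        for g in df.index
    ]


def _ci(values: np.ndarray) -> tuple[float, float] | None:
    n = values.size
    if n < 2:
        return None
    sd = values.std(ddof=1)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    m = values.mean()
    return (float(m - half), float(m + half))


def _welch(x: np.ndarray, y: np.ndarray):
    """Two-tailed Welch t between two samples; returns (t, df, p) or Nones."""
    if x.size < 2 or y.size < 2:
        return None, None, None
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        return None, None, None  # infinite t: degenerate, flagged by caller
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def summarize_by_target(
    records: Sequence[FoldChangeRecord],
) -> tuple[TargetSummary, TargetSummary, float]:
    """Target and non-target summaries plus the delta-of-deltas.

    The headline number is ``delta_of_deltas`` = mean per-gene delta among
    targets minus the same among non-targets: how much more the drug response
    of the TF's targets is dampened in the non-reference phenotype than the
    transcriptome-wide background.  The Welch test compares the per-gene delta
    distributions of the two strata; per-phenotype Welch comparisons can be
    derived from the returned fold-change columns.
    """
    target_recs = [r for r in records if r.is_target]
    other_recs = [r for r in records if not r.is_target]
    if not target_recs or not other_recs:
        raise EmptyCellError("both target and non-target strata must be non-empty")

    def build(group: str, recs: list[FoldChangeRecord], other: list[FoldChangeRecord]):
        fc_ref = np.array([r.fc_ref for r in recs])
        fc_alt = np.array([r.fc_alt for r in recs])
        delta = fc_ref - fc_alt
        other_delta = np.array([r.fc_ref - r.fc_alt for r in other])
        t, df, p = _welch(delta, other_delta)
        degenerate = len(recs) < 2 or t is None
        return TargetSummary(
            group=group,
            n=len(recs),
            mean_fc_ref=float(fc_ref.mean()),
            mean_fc_alt=float(fc_alt.mean()),
            mean_delta=float(delta.mean()),
            ci_fc_ref=_ci(fc_ref),
            ci_fc_alt=_ci(fc_alt),
            ci_delta=_ci(delta),
            welch_t=t,
            welch_df=df,
            welch_p=p,
            degenerate=degenerate,
        )

    target_summary = build("target", target_recs, other_recs)
    other_summary = build("non-target", other_recs, target_recs)
    delta_of_deltas = target_summary.mean_delta - other_summary.mean_delta
    return target_summary, other_summary, float(delta_of_deltas)
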