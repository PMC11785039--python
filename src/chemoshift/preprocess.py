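"""Probe-level intensities -> gene-level, normalized, log2 matrix.

The flow mirrors an RMA-style pipeline minus background correction: quantile
normalization across arrays, log2 transform, then summarization of probes to
genes by the arithmetic mean, after discarding "promiscuous" probes that map
to more than one gene.  Each step also stands alone so a user who already has
a gene-level log2 matrix can skip the ones they do not need.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import EmptyResultError, NonPositiveValueError
from .io import ExpressionMatrix, ProbeMap

logger = logging.getLogger(__name__)

__all__ = ["quantile_normalize", "summarize_probes", "log2_transform", "preprocess_pipeline"]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common per-rank-mean distribution.

    The reference distribution is the mean of the sorted columns.  Tied values
    within a column receive the mean of the reference values over their tied
    rank range, so the operation is well defined and idempotent in the
    presence of ties.  A single-column matrix is returned unchanged.
    """
    df = matrix.data
    if df.size == 0:
        raise EmptyResultError("cannot quantile-normalize an empty matrix")
    if df.shape[1] == 1:
        return ExpressionMatrix(df.copy())
    values = df.to_numpy()
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        assigned = reference.copy()
        # average reference over runs of tied values
        start = 0
        for end in range(1, len(sorted_col) + 1):
            if end == len(sorted_col) or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    assigned[start:end] = reference[start:end].mean()
                start = end
        out[order, j] = assigned
    return ExpressionMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))


def summarize_probes(probe_matrix: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse a probes-x-samples matrix to genes by per-sample mean.

    Probes absent from the map are dropped (with a logged count); probes
    mapping to more than one gene are excluded before averaging; output gene
    rows are sorted lexicographically.
    """
    df = probe_matrix.data
    unmapped = [p for p in df.index if p not in probe_map]
    if unmapped:
        logger.info("dropping %d unmapped probe(s)", len(unmapped))
    promiscuous = probe_map.promiscuous()
    gene_rows: dict[str, list[np.ndarray]] = {}
    n_promiscuous = 0
    for probe in df.index:
        if probe not in probe_map:
            continue
        if probe in promiscuous:
            n_promiscuous += 1
            continue
        (gene,) = probe_map[probe]
        gene_rows.setdefault(gene, []).append(df.loc[probe].to_numpy())
    if n_promiscuous:
        logger.info("excluded %d promiscuous probe(s)", n_promiscuous)
    if not gene_rows:
        raise EmptyResultError("no probe survived mapping/promiscuity filtering")
    genes = sorted(gene_rows)
    values = np.vstack([np.mean(gene_rows[g], axis=0) for g in genes])
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=df.columns))


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise base-2 logarithm; every value must be strictly positive."""
    values = matrix.values
    if (values <= 0).any():
        g, s = np.argwhere(values <= 0)[0]
        raise NonPositiveValueError(
            f"non-positive value at gene {matrix.gene_ids[g]!r}, "
            f"sample {matrix.sample_ids[s]!r}"
        )
    return ExpressionMatrix(
        pd.DataFrame(np.log2(values), index=matrix.data.index, columns=matrix.data.columns)
    )


def preprocess_pipeline(
    matrix: ExpressionMatrix,
    probe_map: ProbeMap | None = None,
    skip_qn: bool = False,
    skip_log2: bool = False,
) -> ExpressionMatrix:
    """Quantile-normalize, log2-transform, then summarize probes to genes.

    When ``probe_map`` is None the input is taken to be gene-level already and
    summarization is skipped.  The default order (log2 before the probe mean)
    is the geometric-mean-style summarization of an RMA-like flow; callers who
    want means on the raw scale can summarize first and then transform using
    the standalone functions.
    """
    out = matrix
    if not skip_qn:
        out = quantile_normalize(out)
    if not skip_log2:
        out = log2_transform(out)
    if probe_map is not None:
        out = summarize_probes(out, probe_map)
    return out
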