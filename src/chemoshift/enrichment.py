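"""Gene-set enrichment of the responsive genes: Fisher tests, odds ratios,
multiple-testing correction and the volcano table.

Each gene set (a transcription factor's annotated targets, or a pathway's
member genes) is tested for over/under-representation among the responsive
genes with a two-tailed Fisher exact test on the 2x2 overlap table within a
gene universe.  Odds ratios use the cross-product, with the Haldane-Anscombe
half-count correction when a cell is zero so volcano coordinates stay finite.
Transcription factors are called significant at a fixed Bonferroni-style
cutoff (default p < 1e-5, conservative for a compendium of <2000 factors);
pathway collections get Benjamini-Hochberg q-values instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyUniverseError, SetNotRepresentedError
from .interaction import ResponsiveSelection
from .io import GeneSetCollection

__all__ = [
    "EnrichmentRecord",
    "odds_ratio_from_counts",
    "fisher_from_counts",
    "fisher_enrichment",
    "directional_enrichment",
    "enrich_collection",
    "rank_tfs",
    "bh_qvalues",
    "volcano_table",
    "volcano_plot",
]

MIN_REPRESENTED = 2  # sets with fewer genes in the universe are flagged, not tested


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-set 2x2 overlap counts and association statistics.

    a = responsive & set, b = responsive - set, c = set - responsive (within
    the universe), d = remainder of the universe.
    """

    set_name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    q_value: float | None = None
    or_top: float | None = None
    or_bottom: float | None = None
    significant: bool | None = None
    too_small: bool = False


def odds_ratio_from_counts(a: int, b: int, c: int, d: int) -> float:
    """Cross-product OR; Haldane-Anscombe half-count corrected on zero cells."""
    if min(a, b, c, d) == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return (a * d) / (b * c)


def fisher_from_counts(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """(odds_ratio, two-tailed Fisher exact p) for a 2x2 table.

    The p-value uses the probability-mass two-sided convention: the sum over
    all tables with the same margins whose point probability does not exceed
    the observed table's (up to a tiny relative slack for float ties).
    """
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds_ratio_from_counts(a, b, c, d), float(min(p, 1.0))


def _counts(responsive: frozenset, members: frozenset, universe: frozenset):
    a = len(responsive & members)
    b = len(responsive - members)
    c = len(members - responsive)
    d = len(universe) - a - b - c
    return a, b, c, d


def fisher_enrichment(
    responsive: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
    set_name: str = "set",
) -> EnrichmentRecord:
    """Test one gene set for enrichment among the responsive genes."""
    universe = frozenset(universe)
    if not universe:
        raise EmptyUniverseError("enrichment universe is empty")
    responsive = frozenset(responsive) & universe
    members = frozenset(gene_set) & universe
    if not members:
        raise SetNotRepresentedError(f"set not represented in universe: {set_name!r}")
    a, b, c, d = _counts(responsive, members, universe)
    odds_ratio, p = fisher_from_counts(a, b, c, d)
    return EnrichmentRecord(
        set_name=set_name,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=odds_ratio,
        p_value=p,
        too_small=len(members) < MIN_REPRESENTED,
    )


def directional_enrichment(
    selection: ResponsiveSelection,
    gene_set: Iterable[str],
    universe: Iterable[str],
) -> tuple[float, float, float]:
    """(or_all, or_top, or_bottom): overlap ORs for the union and each tail."""
    universe = frozenset(universe)
    if not universe:
        raise EmptyUniverseError("enrichment universe is empty")
    members = frozenset(gene_set) & universe
    if not members:
        raise SetNotRepresentedError("set not represented in universe")
    ors = []
    for subset in (selection.responsive, selection.top_genes, selection.bottom_genes):
        a, b, c, d = _counts(frozenset(subset) & universe, members, universe)
        ors.append(odds_ratio_from_counts(a, b, c, d))
    return tuple(ors)  # type: ignore[return-value]


def enrich_collection(
    selection: ResponsiveSelection,
    collection: GeneSetCollection,
    measured_genes: Iterable[str],
    universe_mode: str = "intersect",
) -> list[EnrichmentRecord]:
    """Run Fisher tests for every set of a collection against the selection.

    The universe defaults to measured genes that appear in at least one set of
    the collection (``"intersect"``); ``"measured"`` uses all measured genes.
    Sets with no member in the universe are skipped; sets with fewer than
    MIN_REPRESENTED members are emitted with the ``too_small`` flag and no
    significance call attached downstream.
    """
    measured = frozenset(measured_genes)
    if universe_mode == "intersect":
        universe = measured & collection.all_members()
    elif universe_mode == "measured":
        universe = measured
    else:
        raise ValueError(f"unknown universe_mode {universe_mode!r}")
    if not universe:
        raise EmptyUniverseError("enrichment universe is empty")
    records = []
    for gs in collection:
        if not (gs.members & universe):
            continue
        rec = fisher_enrichment(selection.responsive, gs.members, universe, gs.name)
        or_all, or_top, or_bottom = directional_enrichment(selection, gs.members, universe)
        records.append(replace(rec, or_top=or_top, or_bottom=or_bottom))
    return records


def rank_tfs(
    records: Sequence[EnrichmentRecord], alpha: float = 1e-5
) -> list[EnrichmentRecord]:
    """Sort ascending by p (ties by set name) and flag significance at p < alpha.

    The strict inequality implements the fixed conservative cutoff used for
    transcription-factor compendia; ``too_small`` records are never flagged.
    """
    ordered = sorted(records, key=lambda r: (r.p_value, r.set_name))
    return [
        replace(r, significant=bool(r.p_value < alpha) and not r.too_small)
        for r in ordered
    ]


def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """One row per set: log2 OR vs -log10 p (clipped at 300) and significance."""
    rows = []
    for r in records:
        neg_log10_p = 300.0 if r.p_value <= 0 else min(-math.log10(r.p_value), 300.0)
        rows.append(
            {
                "set_name": r.set_name,
                "log2_odds_ratio": math.log2(r.odds_ratio),
                "neg_log10_p": neg_log10_p,
                "significant": bool(r.significant) if r.significant is not None else False,
            }
        )
    return pd.DataFrame(rows, columns=["set_name", "log2_odds_ratio", "neg_log10_p", "significant"])


def volcano_plot(records: Sequence[EnrichmentRecord], path, alpha: float = 1e-5):
    """Scatter the volcano table to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = volcano_table(records)
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = np.where(table["significant"], "crimson", "grey")
    ax.scatter(table["log2_odds_ratio"], table["neg_log10_p"], c=colors, s=14, alpha=0.8)
    ax.axhline(-math.log10(alpha), ls="--", lw=0.8, color="black")
    ax.set_xlabel("log2 odds ratio (responsive vs set overlap)")
    ax.set_ylabel("-log10 Fisher p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
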