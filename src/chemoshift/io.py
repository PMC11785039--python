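"""Readers and writers for every on-disk artifact the pipeline touches.

Formats are deliberately plain: tab-separated text with a header for matrices,
sample sheets, probe maps, caliper measurements and result tables, and the
standard GMT dialect for gene-set collections.  Identifiers are case-sensitive
and whitespace-stripped; no symbol aliasing is attempted.  Missing ("NA"/empty)
expression cells are rejected rather than imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateGeneError,
    DuplicateSampleError,
    DuplicateSetNameError,
    FactorLevelError,
    MalformedGMTError,
    MeasurementError,
    NonNumericValueError,
    UnassignedSampleError,
    UnknownSampleError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleDesign",
    "ProbeMap",
    "GeneSet",
    "GeneSetCollection",
    "TumorSeries",
    "read_expression",
    "read_matrix",
    "read_sample_sheet",
    "read_probe_map",
    "read_gmt",
    "write_gmt",
    "write_results_table",
    "write_matrix",
    "read_tumor_measurements",
    "write_tumor_measurements",
]


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes (rows) x samples (columns) table of log2-scale intensities.

    Invariants enforced at construction: identifiers unique, every value
    finite, and the float matrix shape matches the identifier counts.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DuplicateGeneError(f"duplicate gene identifiers: {dupes[:5]}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise DuplicateSampleError(f"duplicate sample identifiers: {dupes[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise NonNumericValueError("expression matrix contains non-numeric cells")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))
            g, s = bad[0]
            raise NonNumericValueError(
                f"non-finite expression value at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )
        object.__setattr__(self, "data", df.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @classmethod
    def from_arrays(
        cls, gene_ids: Sequence[str], sample_ids: Sequence[str], values: np.ndarray
    ) -> "ExpressionMatrix":
        return cls(pd.DataFrame(values, index=list(gene_ids), columns=list(sample_ids)))


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample factor assignment for the 2x2 factorial design.

    ``table`` is indexed by sample id with columns ``treatment``, ``phenotype``
    and ``replicate``.  Each factor must carry exactly two levels; the first
    element of ``treatment_levels`` / ``phenotype_levels`` is the reference
    level (untreated control and the drug-sensitive reference phenotype in the
    study design this mirrors).  By default the reference is the level first
    encountered in the sheet.
    """

    table: pd.DataFrame
    treatment_levels: tuple[str, str] = field(default=())  # type: ignore[assignment]
    phenotype_levels: tuple[str, str] = field(default=())  # type: ignore[assignment]

    def __post_init__(self) -> None:
        tbl = self.table
        required = {"treatment", "phenotype", "replicate"}
        missing = required - set(tbl.columns)
        if missing:
            raise FactorLevelError(f"sample sheet missing columns: {sorted(missing)}")
        if tbl.index.has_duplicates:
            dupes = tbl.index[tbl.index.duplicated()].unique().tolist()
            raise DuplicateSampleError(f"duplicate samples in sheet: {dupes[:5]}")
        for factor, declared in (
            ("treatment", self.treatment_levels),
            ("phenotype", self.phenotype_levels),
        ):
            observed = list(dict.fromkeys(tbl[factor].astype(str)))
            if len(observed) != 2:
                raise FactorLevelError(
                    f"factor not two-level: {factor!r} has levels {observed}"
                )
            if declared:
                if set(declared) != set(observed):
                    raise FactorLevelError(
                        f"declared {factor} levels {declared} do not match "
                        f"observed {observed}"
                    )
                levels = tuple(declared)
            else:
                levels = tuple(observed)
            object.__setattr__(self, f"{factor}_levels", levels)
        reps = pd.to_numeric(tbl["replicate"], errors="coerce")
        if reps.isna().any() or (reps <= 0).any() or (reps != reps.round()).any():
            raise FactorLevelError("replicate indices must be positive integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def indicator_arrays(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """0/1 arrays (treated, alt-phenotype) aligned to ``sample_ids``."""
        sub = self.table.loc[list(sample_ids)]
        treated = (sub["treatment"].astype(str) == self.treatment_levels[1]).to_numpy()
        alt = (sub["phenotype"].astype(str) == self.phenotype_levels[1]).to_numpy()
        return treated.astype(float), alt.astype(float)

    def cells(self) -> dict[tuple[str, str], list[str]]:
        """Sample ids per (treatment, phenotype) cell."""
        out: dict[tuple[str, str], list[str]] = {
            (t, p): [] for t in self.treatment_levels for p in self.phenotype_levels
        }
        for sample, row in self.table.iterrows():
            out[(str(row["treatment"]), str(row["phenotype"]))].append(str(sample))
        return out


@dataclass(frozen=True)
class ProbeMap:
    """Mapping probe id -> set of gene identifiers it hybridises to."""

    mapping: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        for probe, genes in self.mapping.items():
            if not genes:
                raise MalformedGMTError(f"probe {probe!r} maps to no gene")

    def __getitem__(self, probe: str) -> frozenset:
        return self.mapping[probe]

    def __contains__(self, probe: str) -> bool:
        return probe in self.mapping

    def promiscuous(self) -> set:
        return {p for p, genes in self.mapping.items() if len(genes) > 1}


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered, uniquely named gene sets (GMT semantics)."""

    sets: Mapping[str, GeneSet]

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def all_members(self) -> set:
        out: set = set()
        for gs in self:
            out |= gs.members
        return out

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet]) -> "GeneSetCollection":
        mapping: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in mapping:
                raise DuplicateSetNameError(f"duplicate set name: {gs.name!r}")
            mapping[gs.name] = gs
        return cls(mapping)


@dataclass(frozen=True)
class TumorSeries:
    """Caliper measurement series for one tumor.

    ``days`` strictly increasing; L, W, H in mm, all non-negative.
    """

    tumor_id: str
    vector: str
    treatment: str
    days: tuple
    lengths: tuple
    widths: tuple
    heights: tuple

    def __post_init__(self) -> None:
        n = len(self.days)
        if not (len(self.lengths) == len(self.widths) == len(self.heights) == n):
            raise MeasurementError(f"tumor {self.tumor_id!r}: ragged measurement arrays")
        days = np.asarray(self.days, dtype=float)
        if n and (np.diff(days) <= 0).any():
            raise MeasurementError(f"tumor {self.tumor_id!r}: days not strictly increasing")
        if days.size and (days < 0).any():
            raise MeasurementError(f"tumor {self.tumor_id!r}: negative day")
        for name, dims in (("L", self.lengths), ("W", self.widths), ("H", self.heights)):
            if any(d < 0 for d in dims):
                raise MeasurementError(f"tumor {self.tumor_id!r}: negative {name}")

    def volumes(self) -> np.ndarray:
        """V = L*W*H*pi/6 at each timepoint (mm^3)."""
        L = np.asarray(self.lengths, dtype=float)
        W = np.asarray(self.widths, dtype=float)
        H = np.asarray(self.heights, dtype=float)
        return L * W * H * math.pi / 6.0


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (header = sample ids, first column = gene ids)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    try:
        numeric = raw.apply(pd.to_numeric, axis=0)
    except (ValueError, TypeError) as exc:
        raise NonNumericValueError(f"non-numeric cell in {path}: {exc}") from exc
    if numeric.isna().to_numpy().any():
        rows, cols = np.nonzero(numeric.isna().to_numpy())
        raise NonNumericValueError(
            f"missing/non-numeric cell at gene {numeric.index[rows[0]]!r}, "
            f"sample {numeric.columns[cols[0]]!r} in {path}"
        )
    return ExpressionMatrix(numeric)


def read_sample_sheet(
    path: str | Path,
    treatment_ref: str | None = None,
    phenotype_ref: str | None = None,
) -> SampleDesign:
    """Read a sample sheet TSV with columns sample, treatment, phenotype, replicate."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    sheet.columns = [c.strip() for c in sheet.columns]
    if "sample" not in sheet.columns:
        raise FactorLevelError(f"sample sheet {path} lacks a 'sample' column")
    sheet["sample"] = sheet["sample"].str.strip()
    sheet = sheet.set_index("sample")
    for col in ("treatment", "phenotype"):
        if col in sheet.columns:
            sheet[col] = sheet[col].str.strip()
    levels = {}
    for factor, ref in (("treatment", treatment_ref), ("phenotype", phenotype_ref)):
        if ref is None:
            levels[factor] = ()
            continue
        observed = list(dict.fromkeys(sheet[factor]))
        if ref not in observed:
            raise FactorLevelError(f"{factor} reference {ref!r} not among {observed}")
        other = [lev for lev in observed if lev != ref]
        levels[factor] = (ref, other[0]) if len(other) == 1 else ()
    return SampleDesign(
        sheet,
        treatment_levels=levels["treatment"],
        phenotype_levels=levels["phenotype"],
    )


def read_expression(
    matrix_path: str | Path,
    sample_sheet_path: str | Path,
    treatment_ref: str | None = None,
    phenotype_ref: str | None = None,
) -> tuple[ExpressionMatrix, SampleDesign]:
    """Read and cross-validate an expression matrix with its sample sheet.

    Column order of the matrix is preserved.  Every matrix sample must be
    assigned in the sheet and vice versa.
    """
    matrix = read_matrix(matrix_path)
    design = read_sample_sheet(sample_sheet_path, treatment_ref, phenotype_ref)
    matrix_samples = set(matrix.sample_ids)
    sheet_samples = set(design.sample_ids)
    unassigned = matrix_samples - sheet_samples
    if unassigned:
        raise UnassignedSampleError(f"unassigned sample(s): {sorted(unassigned)}")
    unknown = sheet_samples - matrix_samples
    if unknown:
        raise UnknownSampleError(f"sheet names unknown sample(s): {sorted(unknown)}")
    # reindex the sheet to matrix column order for downstream alignment
    design = SampleDesign(
        design.table.loc[matrix.sample_ids],
        treatment_levels=design.treatment_levels,
        phenotype_levels=design.phenotype_levels,
    )
    return matrix, design


def read_probe_map(path: str | Path) -> ProbeMap:
    """Read a 2-column TSV (probe, gene); repeated probe rows = multi-gene probes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    probe_col, gene_col = df.columns[:2]
    mapping: dict[str, set] = {}
    for probe, gene in zip(df[probe_col].str.strip(), df[gene_col].str.strip()):
        mapping.setdefault(probe, set()).add(gene)
    return ProbeMap({p: frozenset(g) for p, g in mapping.items()})


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated name, description, members."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise MalformedGMTError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3"
                )
            name, description = fields[0], fields[1]
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise MalformedGMTError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise DuplicateSetNameError(f"duplicate set name: {name!r}")
            sets[name] = GeneSet(name, description, members)
    return GeneSetCollection(sets)


def read_tumor_measurements(path: str | Path) -> list[TumorSeries]:
    """Read a caliper TSV (tumor_id, vector, treatment, day, L, W, H)."""
    df = pd.read_csv(path, sep="\t")
    required = ["tumor_id", "vector", "treatment", "day", "L", "W", "H"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MeasurementError(f"measurements file missing columns: {missing}")
    series = []
    for tumor_id, grp in df.groupby("tumor_id", sort=False):
        grp = grp.sort_values("day")
        vectors = grp["vector"].astype(str).unique()
        treatments = grp["treatment"].astype(str).unique()
        if len(vectors) > 1 or len(treatments) > 1:
            raise MeasurementError(f"tumor {tumor_id!r} has inconsistent group labels")
        series.append(
            TumorSeries(
                tumor_id=str(tumor_id),
                vector=vectors[0],
                treatment=treatments[0],
                days=tuple(grp["day"].astype(float)),
                lengths=tuple(grp["L"].astype(float)),
                widths=tuple(grp["W"].astype(float)),
                heights=tuple(grp["H"].astype(float)),
            )
        )
    return series


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # full round-trip precision


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)


def write_results_table(records, path: str | Path) -> None:
    """Write a sequence of records (dataclasses, dicts or a DataFrame) as TSV.

    Full floating precision, header row, deterministic (input) row order.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for rec in records:
            if hasattr(rec, "__dataclass_fields__"):
                rows.append({k: getattr(rec, k) for k in rec.__dataclass_fields__})
            else:
                rows.append(dict(rec))
        df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; members sorted for deterministic output."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def write_tumor_measurements(series: Iterable[TumorSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for day, L, W, H in zip(s.days, s.lengths, s.widths, s.heights):
            rows.append(
                {
                    "tumor_id": s.tumor_id,
                    "vector": s.vector,
                    "treatment": s.treatment,
                    "day": day,
                    "L": L,
                    "W": W,
                    "H": H,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
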