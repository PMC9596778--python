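"""Core domain containers shared across the pipeline.

Everything is a light dataclass around a pandas object so that the usual
DataFrame tooling (joins, groupby, to_csv) stays available, while construction
enforces the invariants the pipeline relies on: unique IDs, no missing values,
consistent dimensions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

ScaleTag = Literal["log2", "linear", "counts"]


def _check_unique(ids: Sequence[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} IDs: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with unique string IDs on both axes.

    ``data`` rows are genes, columns are samples.  Bulk arrays are expected on
    a log2 scale (``scale_tag='log2'``); raw single-cell matrices carry
    ``scale_tag='counts'``.  Missing values are rejected at construction:
    imputation is a caller decision, never a default.
    """

    data: pd.DataFrame
    scale_tag: ScaleTag = "log2"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric cells")
        if np.isnan(values).any():
            g, s = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                "missing value in expression matrix at "
                f"gene={self.data.index[g]!r}, sample={self.data.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in expression matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.scale_tag)


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes keyed by sample ID.

    ``time`` is nonnegative (units carried in ``time_unit``); ``event`` is 1
    when the endpoint (recurrence/death) was observed and 0 when censored.
    """

    data: pd.DataFrame  # index sample_id, columns: time, event
    time_unit: str = "months"

    def __post_init__(self) -> None:
        required = {"time", "event"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"survival table needs columns {sorted(required)}")
        _check_unique(self.data.index, "sample")
        t = self.data["time"].to_numpy(dtype=float)
        e = self.data["event"].to_numpy()
        if np.isnan(t).any() or (t < 0).any():
            raise ValueError("survival times must be finite and >= 0")
        if not np.isin(e, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        self.data = self.data.assign(time=t, event=e.astype(int))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(sample_ids)], self.time_unit)


@dataclass
class SignatureCollection:
    """Named gene sets (a GMT in memory). Within-set duplicates are collapsed."""

    gene_sets: dict[str, list[str]]
    source_tag: str = ""

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, genes in self.gene_sets.items():
            deduped = list(dict.fromkeys(genes))  # preserve order, drop dups
            if len(deduped) == 0:
                raise ValueError(f"signature {name!r} is empty")
            cleaned[name] = deduped
        self.gene_sets = cleaned

    @property
    def names(self) -> list[str]:
        return list(self.gene_sets)

    def __len__(self) -> int:
        return len(self.gene_sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.gene_sets[name]

    def overlap_report(self, expr: ExpressionMatrix) -> pd.DataFrame:
        """Per-signature overlap with an expression matrix's gene universe.

        Gene matching is exact-string and case-sensitive; this report is the
        always-emitted audit trail for that rule.
        """
        universe = set(expr.gene_ids)
        rows = []
        for name, genes in self.gene_sets.items():
            n_matched = sum(g in universe for g in genes)
            rows.append(
                {
                    "signature": name,
                    "n_genes": len(genes),
                    "n_matched": n_matched,
                    "frac_matched": n_matched / len(genes),
                }
            )
        return pd.DataFrame(rows).set_index("signature")


@dataclass
class CohortDataset:
    """One cohort: expression + survival + optional per-sample metadata."""

    name: str
    expression: ExpressionMatrix
    survival: SurvivalTable
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        expr_samples = set(self.expression.sample_ids)
        missing = [s for s in self.survival.sample_ids if s not in expr_samples]
        if missing:
            raise ValueError(
                f"cohort {self.name!r}: survival samples missing from "
                f"expression: {missing[:10]}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.expression.sample_ids)


@dataclass
class EnrichmentMatrix:
    """Signatures x samples enrichment scores.

    ``variant`` is ``raw_es`` straight from ssGSEA/GSVA, or ``nes`` after
    per-signature z-scaling across a cohort's samples (mean 0, sd 1 with
    ddof=1; constant rows become all-zero and are listed in
    ``degenerate_signatures``).
    """

    scores: pd.DataFrame  # index signatures, columns samples
    variant: Literal["raw_es", "nes"] = "raw_es"
    method: str = ""
    degenerate_signatures: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.scores.index, "signature")
        _check_unique(self.scores.columns, "sample")

    @property
    def signature_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class IRScoreTable:
    """Per-sample IRScore with high/low grouping and signature bookkeeping."""

    table: pd.DataFrame  # index sample_id, columns: irscore, group
    n_good: int
    n_bad: int
    threshold: float
    good_signatures: list[str] = field(default_factory=list)
    bad_signatures: list[str] = field(default_factory=list)

    @property
    def irscore(self) -> pd.Series:
        return self.table["irscore"]

    @property
    def group(self) -> pd.Series:
        return self.table["group"]
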