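"""Core domain types for quantitative MS differential expression.

The pipeline moves through three tabular stages:

``QuantTable``
    PSM- or peptide-level rows with raw reporter/LFQ intensities, one row
    per spectrum match (labelled data) or peptide (label-free), assigned to
    a protein and optionally to a TMT batch.

``ProteinMatrix``
    Proteins x samples matrix of log2 relative abundances, plus the
    per-protein quantification-depth covariate (PSM count for labelled
    data, peptide count for label-free).

``DesignSpec``
    Sample-to-group assignment, optional batch labels and reference
    channels, and the contrasts to test.

All containers are thin wrappers around pandas objects and validate their
invariants on construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QuantTable",
    "ProteinMatrix",
    "DesignSpec",
    "RunConfig",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a domain-type invariant is violated."""


@dataclass
class QuantTable:
    """PSM/peptide-level intensities.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per PSM/peptide. Must contain columns ``feature_id``,
        ``protein_id``, optionally ``batch``, plus one column per sample
        holding raw (linear-scale) intensities. Missing observations are
        NaN; raw zeros are treated as missing upstream (a zero reporter
        intensity means "not observed", not "abundance zero").
    sample_ids : list of str
        The intensity columns, in sample order.
    """

    data: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        for col in ("feature_id", "protein_id"):
            if col not in self.data.columns:
                raise ValidationError(f"QuantTable missing required column {col!r}")
        missing = [s for s in self.sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"QuantTable missing intensity columns: {missing}")
        if (self.data["protein_id"].astype(str).str.len() == 0).any():
            raise ValidationError("QuantTable has rows with empty protein_id")
        vals = self.data[self.sample_ids].to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("QuantTable intensities must be >= 0")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def has_batches(self) -> bool:
        return "batch" in self.data.columns

    def intensities(self) -> pd.DataFrame:
        """The raw intensity block (rows x samples), NaN = missing."""
        return self.data[self.sample_ids]


@dataclass
class ProteinMatrix:
    """Proteins x samples log2 relative abundances with a count covariate.

    ``values`` is indexed by protein id with one column per sample;
    ``count`` is the per-protein PSM (or peptide) count aligned to
    ``values.index``. The matrix is complete-case: no NaN is allowed, so a
    single residual degree of freedom applies to every protein.
    """

    values: pd.DataFrame
    count: pd.Series
    per_batch_count: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dups}")
        if not self.count.index.equals(self.values.index):
            self.count = self.count.reindex(self.values.index)
        if self.count.isna().any():
            raise ValidationError("count missing for some proteins")
        if (self.count < 1).any():
            bad = self.count.index[self.count < 1].tolist()
            raise ValidationError(f"count must be >= 1; offending proteins: {bad[:5]}")
        if self.values.isna().any().any():
            raise ValidationError("ProteinMatrix must be complete-case (no NaN)")
        self.count = self.count.astype(int)
        if self.per_batch_count is not None and not self.per_batch_count.index.equals(
            self.values.index
        ):
            self.per_batch_count = self.per_batch_count.reindex(self.values.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class DesignSpec:
    """Experimental design: sample grouping, batches, references, contrasts."""

    sample_to_group: dict[str, str]
    batches: dict[str, str] | None = None
    reference_samples: frozenset[str] = frozenset()
    contrasts: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reference_samples = frozenset(self.reference_samples)
        groups = set(self.sample_to_group.values())
        for g1, g2 in self.contrasts:
            if g1 not in groups or g2 not in groups:
                raise ValidationError(f"contrast ({g1}, {g2}) references unknown group")

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_group)

    def groups(self) -> dict[str, list[str]]:
        """Group label -> member samples, preserving sample order."""
        out: dict[str, list[str]] = {}
        for s, g in self.sample_to_group.items():
            out.setdefault(g, []).append(s)
        return out

    def group_sizes(self) -> dict[str, int]:
        return {g: len(m) for g, m in self.groups().items()}

    def validate_against(self, sample_ids: list[str]) -> None:
        missing = [s for s in sample_ids if s not in self.sample_to_group]
        if missing:
            raise ValidationError(f"samples not in design: {missing}")

    def references_by_batch(self) -> dict[str, list[str]]:
        """Reference samples per batch (single pseudo-batch if none given)."""
        out: dict[str, list[str]] = {}
        for s in self.reference_samples:
            b = (self.batches or {}).get(s, "")
            out.setdefault(b, []).append(s)
        for refs in out.values():
            refs.sort()
        return out

    @staticmethod
    def all_pairwise_contrasts(groups: list[str]) -> list[tuple[str, str]]:
        """Every unordered pair of group labels, lexicographic within pairs
        by input order (18 groups -> 153 contrasts)."""
        return list(itertools.combinations(groups, 2))


@dataclass
class RunConfig:
    """Hyperparameters of the variance-moderation pipeline.

    loess_span, loess_degree
        Local-regression window fraction and polynomial degree for the
        variance trend (defaults match the reference local-regression
        defaults: span 0.75, degree 2).
    d0_grid_step, d0_grid_max
        Grid for the prior-degrees-of-freedom search (step 0.1; the search
        returns +inf if still improving at the cap).
    count_metric
        How per-batch PSM counts are collapsed to one integer per protein
        for multi-batch data; the minimum is the recommended default.
    covariate_mode
        "count" fits the variance trend against log2 PSM/peptide count;
        "intensity" against mean log2 abundance (limma-trend style);
        "constant" uses a flat prior (classic moderated t).
    """

    loess_span: float = 0.75
    loess_degree: int = 2
    d0_grid_step: float = 0.1
    d0_grid_max: float = 500.0
    alpha: float = 0.01
    seed: int = 0
    count_metric: str = "min"
    covariate_mode: str = "count"

    _COUNT_METRICS = ("min", "mean", "median", "sum", "max")
    _COVARIATE_MODES = ("count", "intensity", "constant")

    def __post_init__(self) -> None:
        if not 0 < self.loess_span <= 1:
            raise ValidationError("loess_span must be in (0, 1]")
        if self.loess_degree not in (1, 2):
            raise ValidationError("loess_degree must be 1 or 2")
        if self.d0_grid_step <= 0 or self.d0_grid_max <= 0:
            raise ValidationError("d0 grid parameters must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.count_metric not in self._COUNT_METRICS:
            raise ValidationError(f"unknown count_metric {self.count_metric!r}")
        if self.covariate_mode not in self._COVARIATE_MODES:
            raise ValidationError(f"unknown covariate_mode {self.covariate_mode!r}")
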