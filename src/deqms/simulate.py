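"""Synthetic data generators and the null/spike-in benchmark experiments.

Three kinds of synthetic data are produced:

null simulation
    A proteins x samples matrix of i.i.d. Gaussian log2 ratios with mean
    zero, where proteins are partitioned into PSM-count groups and each
    group's variance follows a monotone-decreasing count-to-variance
    curve v(c) = v_inf + a * c**(-b). The default emulates a deep TMT
    experiment: 6000 proteins, 9 samples, 30 count groups (counts 1-30)
    of 200 proteins each. Null comparisons are obtained by splitting the
    samples into two disjoint triples.

spike-in benchmark
    A PSM/peptide-level quant table in which background proteins have
    equal expected abundance in both conditions and spike proteins are
    shifted by log2(ratio) in the second condition, with a long-tailed
    PSM-count distribution and per-observation lognormal noise. Because
    protein summaries are medians over c PSM rows, protein-level variance
    decreases with count, as in real data.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    DesignSpec,
    ProteinMatrix,
    QuantTable,
    RunConfig,
    ValidationError,
)
from .ebayes import spectra_count_ebayes
from .linear_models import fit_group_means, ordinary_t

__all__ = [
    "PowerLawVariance",
    "SimSpec",
    "simulate_null",
    "enumerate_null_splits",
    "null_fpr_experiment",
    "simulate_spikein",
    "simulate_multibatch",
    "default_null_spec",
]


@dataclass(frozen=True)
class PowerLawVariance:
    """Count-to-variance curve v(c) = v_inf + a * c**(-b).

    The defaults give per-protein log2-ratio variances from ~0.22 at one
    PSM down to ~0.03 at thirty, the order of magnitude seen in deep TMT
    cell-line data.
    """

    v_inf: float = 0.02
    a: float = 0.20
    b: float = 0.8

    def __call__(self, count: np.ndarray | int) -> np.ndarray:
        return self.v_inf + self.a * np.asarray(count, dtype=float) ** (-self.b)


@dataclass
class SimSpec:
    """Specification of a null simulation."""

    n_samples: int = 9
    count_groups: list[tuple[int, int]] = field(
        default_factory=lambda: [(c, 200) for c in range(1, 31)]
    )
    variance_fn: PowerLawVariance = field(default_factory=PowerLawVariance)
    seed: int = 0

    @property
    def n_proteins(self) -> int:
        return sum(n for _, n in self.count_groups)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("need at least 2 samples")
        if not self.count_groups:
            raise ValidationError("count_groups must be non-empty")
        for c, n in self.count_groups:
            if c < 1 or n < 1:
                raise ValidationError("counts and group sizes must be >= 1")
            if not self.variance_fn(c) > 0:
                raise ValidationError(f"variance_fn({c}) must be positive")


def default_null_spec(seed: int = 0, proteins_per_group: int = 200) -> SimSpec:
    """The standard null design: 9 samples, counts 1-30, equal groups."""
    return SimSpec(
        n_samples=9,
        count_groups=[(c, proteins_per_group) for c in range(1, 31)],
        seed=seed,
    )


def simulate_null(spec: SimSpec) -> tuple[ProteinMatrix, pd.DataFrame]:
    """Null matrix: i.i.d. Normal(0, v(count)) log2 ratios per protein.

    Returns the matrix plus a truth table (protein_id, is_de,
    true_log2fc, psm_count); every protein is null here.
    """
    rng = np.random.default_rng(spec.seed)
    counts = np.concatenate(
        [np.full(n, c, dtype=int) for c, n in spec.count_groups]
    )
    sds = np.sqrt(spec.variance_fn(counts))
    values = rng.standard_normal((counts.size, spec.n_samples)) * sds[:, None]
    protein_ids = [f"prot{i:05d}" for i in range(counts.size)]
    sample_ids = [f"s{j + 1}" for j in range(spec.n_samples)]
    matrix = ProteinMatrix(
        values=pd.DataFrame(values, index=protein_ids, columns=sample_ids),
        count=pd.Series(counts, index=protein_ids),
    )
    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "is_de": False,
            "true_log2fc": 0.0,
            "psm_count": counts,
        }
    ).set_index("protein_id")
    return matrix, truth


def enumerate_null_splits(
    sample_ids: list[str], group_size: int, all_pairs: bool = False
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Enumerate two-group null comparisons without repetition.

    Default convention: every combination of ``group_size`` samples forms
    the first group and the second group is the lexicographically
    smallest ``group_size``-subset of the remainder — for 9 samples in
    triples this yields C(9,3) = 84 comparisons. With ``all_pairs`` every
    unordered pair of disjoint subsets is returned instead.
    """
    if len(sample_ids) < 2 * group_size:
        raise ValidationError("not enough samples for two groups")
    splits = []
    if all_pairs:
        for a in itertools.combinations(sample_ids, group_size):
            rest = [s for s in sample_ids if s not in a]
            for b in itertools.combinations(rest, group_size):
                if a < b:
                    splits.append((a, b))
    else:
        for a in itertools.combinations(sample_ids, group_size):
            rest = [s for s in sample_ids if s not in a]
            splits.append((a, tuple(rest[:group_size])))
    return splits


def null_fpr_experiment(
    spec: SimSpec,
    config: RunConfig | None = None,
    alpha: float = 0.01,
    n_splits: int | None = None,
    group_size: int = 3,
) -> pd.DataFrame:
    """False-positive rates of the three methods over null splits.

    For every split (optionally only the first ``n_splits``) the ordinary
    t-test, the flat-prior moderated fit and the count-covariate
    moderated fit are run; the FPR is the fraction of (protein, split)
    tests with p < alpha, with the BH-adjusted fraction alongside.
    """
    config = config or RunConfig()
    matrix, _ = simulate_null(spec)
    splits = enumerate_null_splits(matrix.sample_ids, group_size)
    if n_splits is not None:
        splits = splits[:n_splits]

    methods = ["t_test", "constant", "count"]
    hits = {m: 0 for m in methods}
    hits_adj = {m: 0 for m in methods}
    n_tests = 0
    for a, b in splits:
        design = DesignSpec(
            sample_to_group={**{s: "A" for s in a}, **{s: "B" for s in b}}
        )
        sub = ProteinMatrix(
            values=matrix.values[list(a) + list(b)], count=matrix.count
        )
        base = fit_group_means(sub, design)
        _, p_ord = ordinary_t(base, ("A", "B"))
        from .ebayes import bh_adjust

        results = {"t_test": p_ord}
        for mode in ("constant", "count"):
            cfg = RunConfig(
                loess_span=config.loess_span,
                loess_degree=config.loess_degree,
                d0_grid_step=config.d0_grid_step,
                d0_grid_max=config.d0_grid_max,
                covariate_mode=mode,
            )
            fit = spectra_count_ebayes(sub, design, cfg, contrasts=[("A", "B")])
            results[mode] = fit.results[("A", "B")]["p_mod"].to_numpy()
        n_tests += sub.n_proteins
        for m in methods:
            hits[m] += int((results[m] < alpha).sum())
            hits_adj[m] += int((bh_adjust(results[m]) < alpha).sum())

    return pd.DataFrame(
        {
            "method": methods,
            "fpr": [hits[m] / n_tests for m in methods],
            "fpr_adjusted": [hits_adj[m] / n_tests for m in methods],
            "n_tests": n_tests,
            "alpha": alpha,
        }
    ).set_index("method")


def _truncated_geometric(
    rng: np.random.Generator, n: int, p: float = 0.25, high: int = 30
) -> np.ndarray:
    """Long-tailed PSM counts on 1..high (geometric, resampled into range)."""
    counts = rng.geometric(p, size=n)
    while (counts > high).any():
        redo = counts > high
        counts[redo] = rng.geometric(p, size=int(redo.sum()))
    return counts


def simulate_multibatch(
    n_proteins: int = 2000,
    n_batches: int = 3,
    n_groups: int = 3,
    variance_fn: PowerLawVariance | None = None,
    geometric_p: float = 0.25,
    max_count: int = 30,
    seed: int = 0,
) -> tuple[ProteinMatrix, DesignSpec]:
    """Null multi-batch matrix with heterogeneous per-batch PSM counts.

    Emulates a multi-TMT-set design in which each group's replicates sit
    in different batches: sample (b, g) belongs to group g and batch b,
    and protein i's value in batch b is Normal(0, v(c_ib)) with
    independent truncated-geometric counts c_ib per batch. The decay of
    v(c) is taken steeper here (b = 1.5) than in the single-batch null
    default, reflecting that per-batch protein summaries from very few
    PSMs are disproportionately noisy; the weakest batch then dominates
    the within-group variance of the combined profile.

    Returns the matrix (with ``per_batch_count``) and a design grouping
    samples across batches.
    """
    variance_fn = variance_fn or PowerLawVariance(v_inf=0.01, a=0.25, b=1.5)
    rng = np.random.default_rng(seed)
    cnt = np.minimum(rng.geometric(geometric_p, size=(n_proteins, n_batches)), max_count)
    v = variance_fn(cnt)
    sample_ids = [f"b{b + 1}.g{g + 1}" for b in range(n_batches) for g in range(n_groups)]
    vals = np.empty((n_proteins, n_batches * n_groups))
    for b in range(n_batches):
        for g in range(n_groups):
            vals[:, b * n_groups + g] = rng.standard_normal(n_proteins) * np.sqrt(
                v[:, b]
            )
    protein_ids = [f"prot{i:05d}" for i in range(n_proteins)]
    per_batch = pd.DataFrame(
        cnt, index=protein_ids, columns=[f"b{b + 1}" for b in range(n_batches)]
    )
    matrix = ProteinMatrix(
        values=pd.DataFrame(vals, index=protein_ids, columns=sample_ids),
        count=pd.Series(cnt.min(axis=1), index=protein_ids),
        per_batch_count=per_batch,
    )
    design = DesignSpec(
        sample_to_group={s: s.split(".")[1] for s in sample_ids},
        batches={s: s.split(".")[0] for s in sample_ids},
    )
    return matrix, design


def simulate_spikein(
    design: str = "labeled",
    n_background: int = 3000,
    n_spike: int = 600,
    ratio: float = 2.0,
    replicates: tuple[int, int] = (3, 3),
    psm_sd: float = 0.45,
    protein_sd: float = 0.12,
    seed: int = 0,
) -> tuple[QuantTable, pd.DataFrame, DesignSpec]:
    """Spike-in benchmark quant table with known ground truth.

    Background proteins have equal expected abundance in both conditions;
    spike proteins are multiplied by ``ratio`` in the second condition.
    Each protein gets a truncated-geometric number of PSM/peptide rows
    (1-30); each observation is abundance x row effect x lognormal noise
    (sd ``psm_sd`` on the log2 scale) plus a protein-level sample effect
    (sd ``protein_sd``), so summarized protein variance decreases with
    the number of rows. Returns the table, the truth table and a
    two-group design ("ctrl" vs "spike").

    ``design`` ("labeled" or "label-free") only labels the provenance of
    the count covariate (PSMs vs peptides); the generative model is
    shared.
    """
    if design not in ("labeled", "label-free"):
        raise ValidationError("design must be 'labeled' or 'label-free'")
    if ratio <= 0:
        raise ValidationError("ratio must be positive")
    if min(replicates) < 2:
        raise ValidationError("need >= 2 replicates per condition for inference")
    rng = np.random.default_rng(seed)
    n_prot = n_background + n_spike
    protein_ids = [f"bg{i:05d}" for i in range(n_background)] + [
        f"spike{i:05d}" for i in range(n_spike)
    ]
    is_de = np.array([False] * n_background + [True] * n_spike)
    counts = _truncated_geometric(rng, n_prot)
    base_abundance = 2.0 ** rng.normal(20.0, 1.5, size=n_prot)

    n1, n2 = replicates
    sample_ids = [f"ctrl{j + 1}" for j in range(n1)] + [
        f"spike{j + 1}" for j in range(n2)
    ]
    cond2 = np.array([0] * n1 + [1] * n2)
    log2fc = np.where(is_de, np.log2(ratio), 0.0)

    rows = []
    for i in range(n_prot):
        c = counts[i]
        row_eff = 2.0 ** rng.normal(0.0, 1.0, size=c)  # ionization efficiency
        prot_sample = rng.normal(0.0, protein_sd, size=len(sample_ids))
        shift = log2fc[i] * cond2 + prot_sample
        noise = rng.normal(0.0, psm_sd, size=(c, len(sample_ids)))
        inten = (
            base_abundance[i]
            * row_eff[:, None]
            * 2.0 ** (shift[None, :] + noise)
        )
        for r in range(c):
            rows.append(
                (f"{protein_ids[i]}.psm{r}", protein_ids[i], *inten[r])
            )
    data = pd.DataFrame(
        rows, columns=["feature_id", "protein_id", *sample_ids]
    )
    table = QuantTable(data=data, sample_ids=sample_ids)
    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "is_de": is_de,
            "true_log2fc": log2fc,
            "psm_count": counts,
        }
    ).set_index("protein_id")
    spec = DesignSpec(
        sample_to_group={
            **{s: "ctrl" for s in sample_ids[:n1]},
            **{s: "spike" for s in sample_ids[n1:]},
        },
        contrasts=[("spike", "ctrl")],
    )
    return table, truth, spec
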