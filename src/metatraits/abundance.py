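"""Normalization, aggregation, filtering and rarefaction of count tables.

Feature-by-sample count matrices (taxa, gene-catalog hits, viral contigs)
are normalized to RPKM or reads-per-base-per-million, rolled up into
functional categories through label maps (CAZy substrates, N-cycle
processes, heavy metals, drug classes), filtered by prevalence and mean
relative abundance, and rarefied for depth-comparable richness.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Features x samples counts with per-feature length/labels and sample totals.

    ``totals`` are total mapped reads per sample; they may exceed the column
    sums when the matrix holds only a subset of mapped features.
    """

    counts: pd.DataFrame
    lengths_bp: pd.Series
    labels: Mapping[str, Sequence[str]] = field(default_factory=dict)
    totals: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.lengths_bp.index.equals(self.counts.index):
            self.lengths_bp = self.lengths_bp.reindex(self.counts.index)
        if self.lengths_bp.isna().any() or (self.lengths_bp <= 0).any():
            raise ValueError("every feature needs a positive length")
        if self.totals is not None:
            colsums = self.counts.sum(axis=0)
            if ((self.totals.reindex(self.counts.columns) + 1e-9) < colsums).any():
                raise ValueError("sample totals below column sums")


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame
    tag: str  # RPKM | RPBPM | relative

    def __post_init__(self) -> None:
        if self.tag not in {"RPKM", "RPBPM", "relative"}:
            raise ValueError(f"unknown normalization tag {self.tag!r}")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("normalized values must be finite")


def _check_lengths_totals(counts, lengths_bp, totals):
    lengths = pd.Series(lengths_bp, dtype=float).reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("feature lengths must be positive for every feature")
    tot = pd.Series(totals, dtype=float).reindex(counts.columns)
    if tot.isna().any() or (tot <= 0).any():
        raise ValueError("per-sample totals must be positive for every sample")
    return lengths, tot


def rpkm(
    counts: pd.DataFrame,
    lengths_bp: pd.Series,
    totals: pd.Series,
) -> NormalizedMatrix:
    """Reads Per Kilobase per Million mapped reads.

    RPKM_fs = C_fs / ((L_f / 1000) * (N_s / 1e6)). ``totals`` must be the
    total mapped reads per sample, supplied explicitly; when every mapped
    read is in the catalog the conservation identity
    sum_f RPKM_fs * L_f/1000 = 1e6 holds per sample.
    """
    lengths, tot = _check_lengths_totals(counts, lengths_bp, totals)
    values = counts.div(lengths / 1000.0, axis=0).div(tot / 1e6, axis=1)
    return NormalizedMatrix(values, "RPKM")


def reads_per_base_per_million(
    counts: pd.DataFrame,
    lengths_bp: pd.Series,
    totals: pd.Series,
) -> NormalizedMatrix:
    """Reads per base per million: C / (L * N/1e6) — RPKM / 1000 elementwise."""
    lengths, tot = _check_lengths_totals(counts, lengths_bp, totals)
    values = counts.div(lengths, axis=0).div(tot / 1e6, axis=1)
    return NormalizedMatrix(values, "RPBPM")


def relative_abundance(counts: pd.DataFrame) -> NormalizedMatrix:
    """Column-wise relative abundance (each sample sums to 1)."""
    colsums = counts.sum(axis=0)
    if (colsums <= 0).any():
        raise ValueError("cannot normalize a sample with zero total")
    return NormalizedMatrix(counts.div(colsums, axis=1), "relative")


def aggregate_by_label(
    matrix: pd.DataFrame,
    label_map: Mapping[str, Sequence[str]],
    multilabel_policy: str = "duplicate",
) -> tuple[pd.DataFrame, dict]:
    """Roll feature rows up into category rows.

    ``label_map`` maps feature id -> its category labels. Under the default
    ``duplicate`` policy a multi-label feature contributes its full value to
    every label (the usual CAZy-substrate rollup); ``split`` divides the
    value evenly across labels. Unlabeled features are dropped and counted
    in the report.
    """
    if multilabel_policy not in {"duplicate", "split"}:
        raise ValueError(f"unknown multilabel policy {multilabel_policy!r}")
    if not label_map or all(len(v) == 0 for v in label_map.values()):
        raise ValueError("empty label map")
    categories: dict[str, np.ndarray] = {}
    dropped = []
    for feature in matrix.index:
        labels = list(label_map.get(feature, ()))
        if not labels:
            dropped.append(feature)
            continue
        share = 1.0 if multilabel_policy == "duplicate" else 1.0 / len(labels)
        row = matrix.loc[feature].to_numpy(dtype=float) * share
        for lab in labels:
            categories[lab] = categories.get(lab, np.zeros(matrix.shape[1])) + row
    if not categories:
        raise ValueError("no feature carries any label")
    agg = pd.DataFrame(categories, index=matrix.columns).T.sort_index()
    agg.index.name = "category"
    report = {"n_dropped_unlabeled": len(dropped), "dropped_features": dropped}
    return agg, report


def prevalence_abundance_filter(
    rel_matrix: pd.DataFrame,
    min_prevalence: float = 0.10,
    min_mean_abundance: float = 1e-5,
    rule: str = "and",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rare features from a relative-abundance matrix.

    Prevalence is the fraction of samples where the feature is present
    (> 0); abundance is the mean relative abundance across samples. Under
    the default ``and`` rule a feature is removed only when it fails BOTH
    thresholds; ``or`` removes it when it fails either.

    Returns the filtered matrix and a per-removed-feature report with the
    failing criteria.
    """
    if not (0 <= min_prevalence <= 1) or not (0 <= min_mean_abundance <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if rule not in {"and", "or"}:
        raise ValueError(f"unknown rule {rule!r}")
    prevalence = (rel_matrix > 0).mean(axis=1)
    mean_abund = rel_matrix.mean(axis=1)
    low_prev = prevalence < min_prevalence
    low_abund = mean_abund < min_mean_abundance
    remove = (low_prev & low_abund) if rule == "and" else (low_prev | low_abund)
    report = pd.DataFrame(
        {
            "prevalence": prevalence[remove],
            "mean_abundance": mean_abund[remove],
            "low_prevalence": low_prev[remove],
            "low_abundance": low_abund[remove],
        }
    )
    report.index.name = "feature_id"
    return rel_matrix.loc[~remove], report


def rarefy(
    counts_vector: np.ndarray | Sequence[int],
    depth: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    One multivariate-hypergeometric draw per call; averaging over draws is
    the caller's loop so seeds stay explicit.
    """
    counts = np.asarray(counts_vector, dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if depth < 0 or depth > total:
        raise ValueError(f"depth {depth} outside [0, total={total}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def expected_richness(counts_vector: np.ndarray | Sequence[int], depth: int) -> float:
    """Expected number of species seen in a without-replacement subsample.

    Hypergeometric closed form: E[S] = sum_i (1 - C(N - n_i, d) / C(N, d)).
    """
    counts = np.asarray(counts_vector, dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if depth < 0 or depth > total:
        raise ValueError(f"depth {depth} outside [0, total={total}]")
    present = counts[counts > 0]
    # P(species absent from the subsample) = hypergeom pmf at 0
    p_absent = np.array(
        [stats.hypergeom(M=total, n=int(n_i), N=depth).pmf(0) for n_i in present]
    )
    return float(np.sum(1.0 - p_absent))


def richness(counts_vector: np.ndarray | Sequence[float]) -> int:
    """Observed richness: number of strictly positive entries."""
    counts = np.asarray(counts_vector, dtype=float)
    return int(np.count_nonzero(counts > 0))
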