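"""Urban-vs-natural community comparison by permutation.

Bray-Curtis dissimilarities, PERMANOVA partitioning of squared distances
(Anderson's formulation), and a site-aware permutation test for scalar
traits. Because sites are nested within the urbanization factor, the
default permutation scheme exchanges whole sites between groups
(``site_exchange``): samples move with their site, which is the unit of
exchangeability when testing a group effect over nested sites. Free
permutation of samples is retained as an option. Assignments are
enumerated exhaustively whenever the number of distinct ones does not
exceed the requested permutation count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._util import substream


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape must match ids")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def reordered(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(tuple(ids), self.data[np.ix_(idx, idx)])


@dataclass(frozen=True)
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    scheme: str
    exhaustive: bool


def bray_curtis(abundance_matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns.

    BC(x, y) = sum|x - y| / sum(x + y), in [0, 1] for non-negative data.
    """
    values = abundance_matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = abundance_matrix.columns[values.sum(axis=0) == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero)}")
    dm = squareform(pdist(values.T, metric="braycurtis"))
    return DistanceMatrix(tuple(map(str, abundance_matrix.columns)), dm)


def _sums_of_squares(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """(SS_total, SS_within, SS_between) from squared distances and group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = float(d2[iu].sum()) / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += float(np.triu(sub, k=1).sum()) / idx.size
    return ss_total, ss_within, ss_total - ss_within


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, R^2) for a one-factor partition."""
    n = d2.shape[0]
    a = np.unique(labels).size
    ss_total, ss_within, ss_between = _sums_of_squares(d2, labels)
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def _site_assignments(site_groups: np.ndarray, n_perm: int, rng: np.random.Generator):
    """Distinct site-to-group label assignments: exhaustive or sampled.

    Returns (list of label arrays, exhaustive flag). Works for two groups,
    the nested urban/natural design this package targets.
    """
    groups = np.unique(site_groups)
    if groups.size != 2:
        raise ValueError("site-exchange permutation supports exactly two groups")
    n_sites = site_groups.size
    k = int(np.sum(site_groups == groups[0]))
    from math import comb

    n_distinct = comb(n_sites, k)
    if n_distinct <= n_perm:
        assignments = []
        for chosen in combinations(range(n_sites), k):
            labels = np.full(n_sites, groups[1], dtype=object)
            labels[list(chosen)] = groups[0]
            assignments.append(labels)
        return assignments, True
    return [rng.permutation(site_groups) for _ in range(n_perm)], False


def permanova(
    dist: DistanceMatrix,
    group_of_sample: pd.Series,
    site_of_sample: pd.Series | None = None,
    n_perm: int = 999,
    seed: int = 0,
    scheme: str = "site_exchange",
) -> PermanovaResult:
    """One-factor PERMANOVA with a site-aware permutation scheme.

    Sums of squares use squared distances; pseudo-F and R^2 follow the
    standard partition. Under ``site_exchange`` the null is built by
    reassigning group labels to whole sites (samples move with their
    site); under ``free`` sample labels are permuted freely. Sampled
    permutations use the "+1" convention p = (1 + #{F* >= F}) / (1 + n);
    exhaustive enumeration reports the exact p on its grid.
    """
    if scheme not in {"free", "site_exchange"}:
        raise ValueError(f"unknown scheme {scheme!r}")
    ids = sorted(dist.ids)  # permutation stream keyed to sorted ids
    dist = dist.reordered(ids)
    groups = group_of_sample.reindex(ids)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    labels = groups.to_numpy(dtype=object)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two groups")
    d2 = dist.data**2
    f_obs, r2 = _pseudo_f(d2, labels)
    rng = substream(seed, f"permanova/{scheme}")

    if scheme == "free":
        f_perm = [
            _pseudo_f(d2, rng.permutation(labels))[0] for _ in range(n_perm)
        ]
        exhaustive = False
        p = (1 + sum(f >= f_obs - 1e-12 for f in f_perm)) / (1 + n_perm)
        n_used = n_perm
    else:
        if site_of_sample is None:
            raise ValueError("site_exchange scheme needs site_of_sample")
        sites = site_of_sample.reindex(ids)
        site_ids = sorted(sites.unique())
        site_group = np.array(
            [groups[sites == s].iloc[0] for s in site_ids], dtype=object
        )
        for g in np.unique(site_group):
            if np.sum(site_group == g) < 2:
                raise ValueError(f"site_exchange needs >= 2 sites in group {g!r}")
        assignments, exhaustive = _site_assignments(site_group, n_perm, rng)
        site_index = {s: i for i, s in enumerate(site_ids)}
        sample_site_idx = np.array([site_index[s] for s in sites])
        f_perm = []
        for assignment in assignments:
            perm_labels = np.asarray(assignment, dtype=object)[sample_site_idx]
            f_perm.append(_pseudo_f(d2, perm_labels)[0])
        hits = sum(f >= f_obs - 1e-12 for f in f_perm)
        if exhaustive:
            p = hits / len(assignments)  # observed assignment is in the enumeration
            n_used = len(assignments)
        else:
            p = (1 + hits) / (1 + len(assignments))
            n_used = len(assignments)
    return PermanovaResult(float(r2), float(f_obs), float(p), n_used, scheme, exhaustive)


def site_permutation_test(
    values_per_sample: pd.Series,
    site_of_sample: pd.Series,
    group_of_site: pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
) -> dict:
    """Two-sided site-level permutation test for a per-sample scalar trait.

    The statistic is the difference of group means of site means (sites are
    the exchangeable units, standing in for a mixed model with site as a
    random effect). Group labels are permuted over sites, exhaustively when
    the number of distinct assignments does not exceed ``n_perm``.
    """
    sample_ids = sorted(values_per_sample.index)
    values = values_per_sample.reindex(sample_ids)
    sites = site_of_sample.reindex(sample_ids)
    site_means = values.groupby(sites).mean()
    site_ids = sorted(site_means.index)
    site_group = group_of_site.reindex(site_ids).to_numpy(dtype=object)
    if pd.isna(site_group).any():
        raise ValueError("every site needs a group label")
    group_names = sorted(pd.unique(site_group))
    if len(group_names) != 2:
        raise ValueError("site permutation test needs exactly two groups")
    for g in group_names:
        if np.sum(site_group == g) < 2:
            raise ValueError(f"need >= 2 sites in group {g!r}")
    means = site_means.reindex(site_ids).to_numpy(dtype=float)

    def stat(labels: np.ndarray) -> float:
        return float(
            means[labels == group_names[0]].mean() - means[labels == group_names[1]].mean()
        )

    obs = stat(site_group)
    rng = substream(seed, "site_permutation_test")
    assignments, exhaustive = _site_assignments(site_group, n_perm, rng)
    perm_stats = np.array([stat(np.asarray(a, dtype=object)) for a in assignments])
    hits = int(np.sum(np.abs(perm_stats) >= abs(obs) - 1e-12))
    if exhaustive:
        p = hits / len(assignments)
    else:
        p = (1 + hits) / (1 + len(assignments))
    return {
        "mean_difference": obs,
        "p_value": float(p),
        "n_permutations": len(assignments),
        "exhaustive": exhaustive,
        "groups": group_names,
    }
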