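"""Virus-host coupling statistics for soil viromes.

Per virus-host link: per-sample virus-host ratios (VHR), Pearson
correlations between virus and host abundance series, correlations between
VHR and host abundance, plus community-level summaries — the distribution
of pair correlations, virulent/temperate lifestyle abundance ratios per
group, and host-abundance versus viral-link-count profiles.

Positive abundance coupling (r near +1) is the signature of lysogenic
replication with the host (Piggyback-the-Winner); strong anti-coupling
(r near -1) indicates lytic predation. Correlations over constant series
are reported missing rather than zero so degenerate pairs cannot
masquerade as decoupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_SAMPLES = 5


@dataclass
class VirusHostPairStat:
    virus_id: str
    host_id: str
    vhr_by_sample: pd.Series  # NaN where the host is absent
    r_abund: float  # NaN = missing
    r_vhr_host: float  # NaN = missing
    n_used: int


def virus_host_ratio(v_rel: float, h_rel: float) -> float:
    """Per-sample VHR = virus/host relative abundance; NaN when the host is absent."""
    if v_rel < 0 or h_rel < 0:
        raise ValueError("abundances must be non-negative")
    if h_rel == 0:
        return float("nan")
    return float(v_rel) / float(h_rel)


def pair_abundance_correlation(
    v_series: np.ndarray,
    h_series: np.ndarray,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> float:
    """Pearson r between virus and host abundance over samples where both defined.

    Missing (NaN) when fewer than ``min_samples`` joint observations remain
    or either series is constant.
    """
    v = np.asarray(v_series, dtype=float)
    h = np.asarray(h_series, dtype=float)
    if v.shape != h.shape:
        raise ValueError(f"series lengths differ: {v.shape} vs {h.shape}")
    ok = np.isfinite(v) & np.isfinite(h)
    v, h = v[ok], h[ok]
    if v.size < min_samples:
        return float("nan")
    if np.ptp(v) == 0 or np.ptp(h) == 0:
        return float("nan")
    with warnings.catch_warnings():
        # exactly-coupled synthetic pairs trip scipy's near-constant heuristic
        warnings.simplefilter("ignore", stats.NearConstantInputWarning)
        return float(stats.pearsonr(v, h).statistic)


def compute_pair_stats(
    viral_abundance: pd.DataFrame,
    links: pd.DataFrame,
    host_abundance: pd.DataFrame,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> list[VirusHostPairStat]:
    """Per-link VHR series and correlations.

    ``links`` has columns ``votu_id`` and ``host_genome_id`` (rows with no
    host are skipped); abundance matrices are features x samples and must
    share their sample columns.
    """
    if not viral_abundance.columns.equals(host_abundance.columns):
        raise ValueError("viral and host abundance tables must share sample columns")
    out = []
    for _, row in links.iterrows():
        votu, host = row["votu_id"], row["host_genome_id"]
        if pd.isna(host) or host == "":
            continue
        if host not in host_abundance.index:
            raise ValueError(f"unresolvable host id {host!r} for {votu!r}")
        v = viral_abundance.loc[votu].astype(float)
        h = host_abundance.loc[host].astype(float)
        vhr = pd.Series(
            [virus_host_ratio(v[s], h[s]) for s in v.index], index=v.index, name=votu
        )
        r_ab = pair_abundance_correlation(v.to_numpy(), h.to_numpy(), min_samples)
        r_vh = vhr_host_correlation(vhr, h, min_samples)
        n_used = int(np.isfinite(v.to_numpy()).sum())
        out.append(VirusHostPairStat(str(votu), str(host), vhr, r_ab, r_vh, n_used))
    return out


def vhr_host_correlation(
    vhr_series: pd.Series,
    host_series: pd.Series,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> float:
    """Pearson r between per-sample VHR and host abundance.

    Exact proportional coupling (v = alpha h) makes VHR constant, so the
    correlation is reported missing in that degenerate case.
    """
    if not vhr_series.index.equals(host_series.index):
        raise ValueError("VHR and host series must be aligned by sample")
    return pair_abundance_correlation(
        vhr_series.to_numpy(), host_series.to_numpy(), min_samples
    )


def correlation_distribution(
    r_values: np.ndarray | list[float],
    bins: int = 40,
) -> dict:
    """Histogram and summary of pair correlation coefficients over [-1, 1].

    Summary reports skewness, the fraction of r in [0.5, 1] (strong
    positive coupling) and the fraction in [-0.25, 0.25] (near-decoupled);
    missing values are excluded and counted.
    """
    r = np.asarray(r_values, dtype=float)
    n_missing = int(np.sum(~np.isfinite(r)))
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("no non-missing correlation values")
    hist, edges = np.histogram(r, bins=bins, range=(-1.0, 1.0))
    return {
        "hist": hist,
        "bin_edges": edges,
        "n_used": int(r.size),
        "n_missing": n_missing,
        "skewness": (
            float(stats.skew(r)) if r.size > 2 and np.ptp(r) > 0 else float("nan")
        ),
        "frac_high_positive": float(np.mean((r >= 0.5) & (r <= 1.0))),
        "frac_near_zero": float(np.mean(np.abs(r) <= 0.25)),
        "median_r": float(np.median(r)),
    }


def lifestyle_ratio(
    viral_abundance: pd.DataFrame,
    lifestyles: pd.Series,
    sample_groups: pd.Series,
) -> dict[str, dict[str, float]]:
    """Virulent/temperate total-abundance ratio within each sample group.

    ``lifestyles`` maps votu_id -> temperate|virulent|unknown;
    ``sample_groups`` maps sample_id -> group. Unknown-lifestyle vOTUs are
    excluded and their count reported.
    """
    lifestyles = lifestyles.reindex(viral_abundance.index)
    if lifestyles.isna().any():
        raise ValueError("every vOTU needs a lifestyle entry")
    out: dict[str, dict[str, float]] = {}
    n_unknown = int((lifestyles == "unknown").sum())
    for group in pd.unique(sample_groups):
        samples = sample_groups.index[sample_groups == group]
        sub = viral_abundance[samples]
        vir = float(sub.loc[lifestyles == "virulent"].to_numpy().sum())
        temp = float(sub.loc[lifestyles == "temperate"].to_numpy().sum())
        if temp <= 0:
            raise ValueError(f"zero temperate abundance in group {group!r}")
        out[str(group)] = {
            "virulent_total": vir,
            "temperate_total": temp,
            "ratio": vir / temp,
            "n_unknown_excluded": n_unknown,
        }
    return out


def host_link_profile(
    host_abundance: pd.DataFrame,
    links: pd.DataFrame,
    viral_abundance: pd.DataFrame,
    presence_threshold: float = 0.0,
) -> pd.DataFrame:
    """Host abundance vs number of linked viruses present, per (host, sample).

    A linked virus counts as present when its abundance exceeds
    ``presence_threshold``. Points are classified into quadrants by median
    splits of both axes; soil virome profiles typically occupy three of
    them (low/low, low-abundance/high-links, high-abundance/low-links).
    """
    linked = pd.unique(links["host_genome_id"].dropna())
    missing = [h for h in linked if h not in host_abundance.index]
    if missing:
        raise ValueError(f"unresolvable host ids: {missing}")
    rows = []
    for host in host_abundance.index:  # hosts without links still profile as low-links
        votus = links.loc[links["host_genome_id"] == host, "votu_id"]
        vsub = viral_abundance.loc[viral_abundance.index.intersection(votus)]
        for sample in host_abundance.columns:
            n_links = int((vsub[sample] > presence_threshold).sum()) if len(vsub) else 0
            rows.append(
                {
                    "host_id": host,
                    "sample_id": sample,
                    "abundance": float(host_abundance.loc[host, sample]),
                    "n_viral_links_present": n_links,
                }
            )
    profile = pd.DataFrame(rows)
    med_a = profile["abundance"].median()
    med_l = profile["n_viral_links_present"].median()
    high_a = profile["abundance"] > med_a
    high_l = profile["n_viral_links_present"] > med_l
    profile["quadrant"] = np.select(
        [~high_a & ~high_l, ~high_a & high_l, high_a & ~high_l],
        ["low_abund_low_links", "low_abund_high_links", "high_abund_low_links"],
        default="high_abund_high_links",
    )
    return profile
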