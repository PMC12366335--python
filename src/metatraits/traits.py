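"""Metagenomics-informed life-history traits of a microbial community.

Per-sample estimators for the community trait profile:

* **AGS** — average genome size: total sequenced bases divided by genome
  equivalents, where genome equivalents are the mean coverage of 35
  universal single-copy gene families.
* **ACN** — average 16S rRNA copy number: 16S coverage over genome
  equivalents.
* **GC mean / variance** — moments of the per-read GC-fraction pool.
* **CUB** — codon usage bias: the inverse of the mean composition-corrected
  effective number of codons (ENC') over ribosomal protein genes.
* **Proportion of unannotated genes** and **SAP** (sugar-acid preference),
  computed from gene-catalog abundances and a pathway map.

ENC follows Wright's estimator on the 59 synonymous codons (18 amino-acid
families with degeneracies 2/3/4/6); ENC' replaces the within-family
homozygosity with a chi-square deviation from the codon usage expected
under a background nucleotide composition, and reduces exactly to ENC
when that background implies uniform expected usage.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._codons import (
    CODON_TO_FAMILY,
    DEGENERACY,
    SYNONYMOUS_CODONS,
    SYNONYMOUS_FAMILIES,
)

N_SCG_FAMILIES = 35

#: convention flags recorded in run metadata alongside any trait table
CONVENTIONS = {
    "gc_variance": "population (divide-by-N)",
    "read_gc_weighting": "equal per read (not length-weighted)",
    "enc_three_fold_family": "Ile",
    "enc_six_fold_families": "Leu/Ser/Arg kept 6-fold",
    "enc_min_family_count": 2,
    "enc_missing_f3": "imputed as mean of F2-bar and F4-bar",
    "enc_cap": [20.0, 61.0],
    "sap_default_weight": "1 / number of pathways containing the gene",
}

TRAIT_COLUMNS = [
    "ags_bp",
    "acn",
    "gc_mean",
    "gc_var",
    "cub",
    "p_unannotated",
    "sap_weighted",
    "sap_unweighted",
]

_BASES = ("A", "C", "G", "T")


class CodonCounts:
    """Counts of the 59 synonymous codons for one coding sequence.

    Met, Trp and stop codons do not enter ENC and are not stored.
    """

    def __init__(self, counts: Mapping[str, int] | pd.Series | np.ndarray):
        if isinstance(counts, np.ndarray):
            if counts.shape != (len(SYNONYMOUS_CODONS),):
                raise ValueError(
                    f"expected {len(SYNONYMOUS_CODONS)} codon counts, got shape {counts.shape}"
                )
            series = pd.Series(counts, index=list(SYNONYMOUS_CODONS))
        else:
            series = pd.Series(counts, dtype=float)
            series = series.reindex(list(SYNONYMOUS_CODONS), fill_value=0)
        values = series.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("codon counts must be finite and non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("codon counts must be integers")
        self.counts = pd.Series(np.round(values).astype(np.int64), index=list(SYNONYMOUS_CODONS))

    def family_counts(self, family: str) -> np.ndarray:
        return self.counts.loc[list(SYNONYMOUS_FAMILIES[family])].to_numpy()

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __eq__(self, other) -> bool:
        return isinstance(other, CodonCounts) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"CodonCounts(total={self.total})"


def codon_counts_from_sequence(seq: str) -> CodonCounts:
    """Count synonymous codons in an in-frame coding sequence.

    Raises if the length is not a multiple of 3 (trailing partial codons
    are rejected, not silently dropped).
    """
    seq = str(seq).upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"coding sequence length {len(seq)} is not divisible by 3")
    counts: dict[str, int] = {}
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in CODON_TO_FAMILY:
            counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(counts)


def codon_counts_from_fasta(path: Path | str) -> dict[str, CodonCounts]:
    """Read coding sequences from FASTA and count codons per record."""
    out: dict[str, CodonCounts] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = codon_counts_from_sequence(str(rec.seq))
    return out


# ---------------------------------------------------------------------------
# coverage-based estimators


def genome_equivalents(scg: np.ndarray | Sequence[float]) -> float:
    """Genome equivalents: the mean coverage of the 35 single-copy families."""
    scg = np.asarray(scg, dtype=float)
    if scg.shape != (N_SCG_FAMILIES,):
        raise ValueError(f"expected {N_SCG_FAMILIES} single-copy coverages, got {scg.shape}")
    if not np.all(np.isfinite(scg)) or np.any(scg < 0):
        raise ValueError("coverages must be finite and non-negative")
    if not np.any(scg > 0):
        raise ValueError("all single-copy coverages are zero; genome equivalents undefined")
    return float(scg.mean())


def average_genome_size(total_bases: float, geq: float) -> float:
    """AGS in bp: total sequenced bases divided by genome equivalents."""
    if geq <= 0:
        raise ValueError(f"genome equivalents must be positive, got {geq}")
    if total_bases < 0:
        raise ValueError("total_bases must be non-negative")
    return float(total_bases) / float(geq)


def average_16s_copy_number(ssu_coverage: float, geq: float) -> float:
    """ACN: 16S rRNA gene coverage divided by genome equivalents."""
    if geq <= 0:
        raise ValueError(f"genome equivalents must be positive, got {geq}")
    if ssu_coverage < 0:
        raise ValueError("ssu_coverage must be non-negative")
    return float(ssu_coverage) / float(geq)


def gc_statistics(read_gc: np.ndarray | Sequence[float]) -> tuple[float, float]:
    """Mean and population variance of per-read GC fractions."""
    gc = np.asarray(read_gc, dtype=float)
    if gc.size == 0:
        raise ValueError("empty GC vector")
    if np.any(gc < 0) or np.any(gc > 1) or not np.all(np.isfinite(gc)):
        raise ValueError("GC fractions must lie in [0, 1]")
    return float(gc.mean()), float(gc.var(ddof=0))


# ---------------------------------------------------------------------------
# effective number of codons


def _wright_f(counts: np.ndarray) -> tuple[int, float] | None:
    """Wright's homozygosity F-hat for one family; None when n < 2."""
    n = int(counts.sum())
    if n < 2:
        return None
    p = counts / n
    f = (n * float(np.sum(p**2)) - 1.0) / (n - 1)
    return n, f


def _expected_codon_freqs(family: str, background: np.ndarray) -> np.ndarray:
    """Within-family codon frequencies expected from a background base composition."""
    weights = []
    for codon in SYNONYMOUS_FAMILIES[family]:
        w = 1.0
        for base in codon:
            w *= background[_BASES.index(base)]
        weights.append(w)
    weights = np.asarray(weights)
    total = weights.sum()
    if total <= 0 or np.any(weights <= 0):
        raise ValueError(
            f"background composition gives zero expected frequency in family {family}"
        )
    return weights / total


def _chisq_f(counts: np.ndarray, expected: np.ndarray) -> tuple[int, float] | None:
    """Composition-corrected homozygosity F' = (chi2 + n - m) / (m (n - 1))."""
    n = int(counts.sum())
    if n < 2:
        return None
    m = counts.size
    p = counts / n
    chi2 = n * float(np.sum((p - expected) ** 2 / expected))
    f = (chi2 + n - m) / (m * (n - 1))
    return n, max(f, 0.0)


def _enc_from_family_fs(per_family: dict[str, float]) -> float:
    """Combine per-family homozygosities into ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6."""
    class_means: dict[int, float] = {}
    for k in (2, 3, 4, 6):
        fs = [f for aa, f in per_family.items() if DEGENERACY[aa] == k]
        if fs:
            class_means[k] = float(np.mean(fs))
    if not class_means:
        raise ValueError("no synonymous family has two or more codon observations")
    if 3 not in class_means:
        # Wright's convention: impute the single 3-fold class from its neighbours
        if 2 in class_means and 4 in class_means:
            class_means[3] = 0.5 * (class_means[2] + class_means[4])
    missing = [k for k in (2, 3, 4, 6) if k not in class_means]
    if missing:
        raise ValueError(f"no usable family in degeneracy class(es) {missing}")
    enc_value = 2.0
    for k, weight in ((2, 9.0), (3, 1.0), (4, 5.0), (6, 3.0)):
        fbar = class_means[k]
        enc_value += weight / fbar if fbar > 0 else np.inf
    return float(np.clip(enc_value, 20.0, 61.0))


def enc(codons: CodonCounts) -> float:
    """Wright's effective number of codons, capped to [20, 61].

    20 means a single codon per amino acid (maximal bias); 61 means
    uniform synonymous usage. Families with fewer than two observations
    are excluded from their degeneracy-class mean.
    """
    per_family: dict[str, float] = {}
    for aa in SYNONYMOUS_FAMILIES:
        res = _wright_f(codons.family_counts(aa).astype(float))
        if res is not None:
            per_family[aa] = res[1]
    return _enc_from_family_fs(per_family)


def enc_prime(codons: CodonCounts, background: np.ndarray | Sequence[float]) -> float:
    """Composition-corrected effective number of codons (ENC').

    ``background`` is the (A, C, G, T) nucleotide composition used to build
    the expected within-family codon frequencies. When the background implies
    uniform expected usage in every family, ENC' equals ENC exactly.
    """
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or np.any(background < 0):
        raise ValueError("background must be 4 non-negative frequencies (A, C, G, T)")
    if background.sum() <= 0:
        raise ValueError("background frequencies must not all be zero")
    background = background / background.sum()
    per_family: dict[str, float] = {}
    for aa in SYNONYMOUS_FAMILIES:
        expected = _expected_codon_freqs(aa, background)
        res = _chisq_f(codons.family_counts(aa).astype(float), expected)
        if res is not None:
            per_family[aa] = res[1]
    return _enc_from_family_fs(per_family)


def background_from_counts(genes: Sequence[CodonCounts]) -> np.ndarray:
    """Pooled (A, C, G, T) composition of the codons observed across genes."""
    base_counts = np.zeros(4)
    for gene in genes:
        for codon, count in gene.counts.items():
            for base in codon:
                base_counts[_BASES.index(base)] += count
    if base_counts.sum() == 0:
        raise ValueError("no codons observed")
    return base_counts / base_counts.sum()


def codon_usage_bias(
    genes: Sequence[CodonCounts],
    background: np.ndarray | Sequence[float] | None = None,
) -> float:
    """CUB = 1 / mean(ENC' over ribosomal protein genes); lies in [1/61, 1/20].

    When ``background`` is None it is estimated as the pooled nucleotide
    composition of the genes themselves, which is the composition the
    correction is meant to remove.
    """
    if len(genes) == 0:
        raise ValueError("empty gene list")
    if background is None:
        background = background_from_counts(genes)
    values = [enc_prime(g, background) for g in genes]
    return 1.0 / float(np.mean(values))


# ---------------------------------------------------------------------------
# annotation-derived traits


def proportion_unannotated(abund_unannotated: float, abund_annotated: float) -> float:
    """Fraction of gene abundance carried by unannotated genes, U / (U + A)."""
    if abund_unannotated < 0 or abund_annotated < 0:
        raise ValueError("abundances must be non-negative")
    total = abund_unannotated + abund_annotated
    if total == 0:
        raise ValueError("total gene abundance is zero")
    return float(abund_unannotated) / total


def sugar_acid_preference(
    gene_abundances: pd.Series,
    pathway_map: pd.DataFrame,
) -> tuple[float, float]:
    """Weighted and unweighted sugar/amino-acid decomposition abundance ratio.

    ``pathway_map`` has columns ``gene_id``, ``class`` (``sugar`` or ``acid``)
    and optionally ``weight``; a missing weight column defaults to
    1 / (number of pathway rows containing the gene), so genes shared by
    several pathways are not double-counted in the weighted ratio.

    Returns ``(sap_weighted, ratio_unweighted)``.
    """
    pm = pathway_map.copy()
    required = {"gene_id", "class"}
    if not required.issubset(pm.columns):
        raise ValueError(f"pathway map needs columns {sorted(required)}")
    bad = set(pm["class"]) - {"sugar", "acid"}
    if bad:
        raise ValueError(f"unknown pathway classes: {sorted(bad)}")
    if "weight" not in pm.columns:
        occurrences = pm.groupby("gene_id")["class"].transform("size")
        pm["weight"] = 1.0 / occurrences
    # one contribution per (gene, class)
    pm = pm.groupby(["gene_id", "class"], as_index=False)["weight"].mean()
    totals = {"sugar": 0.0, "acid": 0.0}
    weighted = {"sugar": 0.0, "acid": 0.0}
    for _, row in pm.iterrows():
        abund = float(gene_abundances.get(row["gene_id"], 0.0))
        totals[row["class"]] += abund
        weighted[row["class"]] += row["weight"] * abund
    if totals["acid"] <= 0 or weighted["acid"] <= 0:
        raise ValueError("zero acid-class abundance; SAP ratio undefined")
    if totals["sugar"] <= 0:
        raise ValueError("zero sugar-class abundance; SAP ratio undefined")
    return weighted["sugar"] / weighted["acid"], totals["sugar"] / totals["acid"]


# ---------------------------------------------------------------------------
# per-sample profile assembly


def _check_sample_sets(reference: list[str], name: str, other) -> None:
    mismatch_missing = sorted(set(reference) - set(other))
    mismatch_extra = sorted(set(other) - set(reference))
    if mismatch_missing or mismatch_extra:
        raise ValueError(
            f"sample sets inconsistent for {name}: "
            f"missing={mismatch_missing} extra={mismatch_extra}"
        )


def compute_trait_profiles(
    summaries: pd.DataFrame,
    read_gc: Mapping[str, np.ndarray] | None = None,
    codon_sets: Mapping[str, Sequence[CodonCounts]] | None = None,
    gene_counts: pd.DataFrame | None = None,
    gene_labels: Mapping[str, Sequence[str]] | None = None,
    pathway_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-sample trait table.

    ``summaries`` is indexed by sample id with columns ``scg_01``..``scg_35``,
    ``ssu_coverage`` and ``total_bases``. Optional inputs contribute their
    trait columns; traits whose inputs are absent are reported as NaN
    (flagged missing, never silently zero).
    """
    samples = list(summaries.index)
    scg_cols = [f"scg_{i:02d}" for i in range(1, N_SCG_FAMILIES + 1)]
    for col in scg_cols + ["ssu_coverage", "total_bases"]:
        if col not in summaries.columns:
            raise ValueError(f"summaries missing column {col}")
    if read_gc is not None:
        _check_sample_sets(samples, "read_gc", read_gc.keys())
    if codon_sets is not None:
        _check_sample_sets(samples, "codon_sets", codon_sets.keys())
    if gene_counts is not None:
        _check_sample_sets(samples, "gene_counts", gene_counts.columns)

    rows = []
    for sample in samples:
        row: dict[str, float] = {c: np.nan for c in TRAIT_COLUMNS}
        scg = summaries.loc[sample, scg_cols].to_numpy(dtype=float)
        geq = genome_equivalents(scg)
        row["ags_bp"] = average_genome_size(float(summaries.loc[sample, "total_bases"]), geq)
        row["acn"] = average_16s_copy_number(float(summaries.loc[sample, "ssu_coverage"]), geq)
        if read_gc is not None:
            row["gc_mean"], row["gc_var"] = gc_statistics(read_gc[sample])
        if codon_sets is not None:
            row["cub"] = codon_usage_bias(list(codon_sets[sample]))
        if gene_counts is not None and gene_labels is not None:
            counts = gene_counts[sample]
            annotated_mask = counts.index.map(lambda g: len(gene_labels.get(g, ())) > 0)
            abund_annot = float(counts[annotated_mask].sum())
            abund_unannot = float(counts[~annotated_mask].sum())
            row["p_unannotated"] = proportion_unannotated(abund_unannot, abund_annot)
            if pathway_map is not None:
                rel = counts / counts.sum()
                row["sap_weighted"], row["sap_unweighted"] = sugar_acid_preference(
                    rel, pathway_map
                )
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(samples, name="sample_id"))[TRAIT_COLUMNS]
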