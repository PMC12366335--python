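"""Synthetic soil-community generator with known ground truth.

Builds everything the downstream estimators consume — genome panels,
per-sample sequencing summaries, gene catalogs with count matrices,
ribosomal-protein codon tables, and virus-host abundance matrices with
lifestyle labels — from explicit distributional models, so parameter
recovery can be tested against the stored truth.

Every genome carries exactly one copy of each of 35 abstract universal
single-copy gene families (the defining property behind the genome-
equivalents estimator) plus ``rrn_copies`` copies of the 16S rRNA gene.
The noiseless sequencing contract is exact:

* each single-copy family coverage = kappa * sum_g a_g
* 16S coverage               = kappa * sum_g a_g * rrn_g
* total bases                = kappa * sum_g a_g * L_g

so AGS and ACN recover the abundance-weighted community means exactly.
Poisson noise, when enabled, perturbs coverages around those means.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._codons import SYNONYMOUS_CODONS, SYNONYMOUS_FAMILIES
from ._util import FLOAT_FMT, read_tsv, substream, write_tsv
from .abundance import CountMatrix
from .traits import N_SCG_FAMILIES, CodonCounts

GROUPS = ("urban", "natural")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GenomePanel:
    """Simulated genomes: id, length, GC fraction, rRNA operon copies."""

    genome_id: tuple[str, ...]
    length_bp: np.ndarray
    gc_fraction: np.ndarray
    rrn_copies: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.genome_id)
        if len(set(self.genome_id)) != n:
            raise ValueError("genome ids must be unique")
        for name in ("length_bp", "gc_fraction", "rrn_copies"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        if n and (self.length_bp <= 0).any():
            raise ValueError("genome lengths must be positive")
        if n and ((self.gc_fraction <= 0) | (self.gc_fraction >= 1)).any():
            raise ValueError("GC fractions must lie strictly in (0, 1)")
        if n and (self.rrn_copies < 1).any():
            raise ValueError("rrn_copies must be >= 1")

    def __len__(self) -> int:
        return len(self.genome_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genome_id": list(self.genome_id),
                "length_bp": self.length_bp,
                "gc_fraction": self.gc_fraction,
                "rrn_copies": self.rrn_copies,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomePanel":
        return cls(
            genome_id=tuple(df["genome_id"].astype(str)),
            length_bp=df["length_bp"].to_numpy(dtype=np.int64),
            gc_fraction=df["gc_fraction"].to_numpy(dtype=float),
            rrn_copies=df["rrn_copies"].to_numpy(dtype=np.int64),
        )


@dataclass(frozen=True)
class SampleDesign:
    """Sample -> site -> group (urban | natural) assignment."""

    frame: pd.DataFrame  # columns: sample_id, site_id, group

    def __post_init__(self) -> None:
        df = self.frame
        if df["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)}; expected {GROUPS}")
        per_site = df.groupby("site_id")["group"].nunique()
        if (per_site > 1).any():
            raise ValueError("all samples of one site must share one group")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def group_of_sample(self) -> pd.Series:
        return self.frame.set_index("sample_id")["group"]

    def site_of_sample(self) -> pd.Series:
        return self.frame.set_index("sample_id")["site_id"]

    def group_of_site(self) -> pd.Series:
        return self.frame.drop_duplicates("site_id").set_index("site_id")["group"]


@dataclass(frozen=True)
class AbundanceTruth:
    """Genome-copy abundances (genomes x samples) and derived true summaries."""

    abundance: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if (self.abundance.sum(axis=0) <= 0).any():
            raise ValueError("every sample needs at least one positive abundance")

    def true_ags(self, panel: GenomePanel) -> pd.Series:
        """Abundance-weighted mean genome size per sample."""
        a = self.abundance.to_numpy()
        return pd.Series(
            (a * panel.length_bp[:, None]).sum(axis=0) / a.sum(axis=0),
            index=self.abundance.columns,
        )

    def true_acn(self, panel: GenomePanel) -> pd.Series:
        """Abundance-weighted mean 16S copy number per sample."""
        a = self.abundance.to_numpy()
        return pd.Series(
            (a * panel.rrn_copies[:, None]).sum(axis=0) / a.sum(axis=0),
            index=self.abundance.columns,
        )


@dataclass(frozen=True)
class ReadSummary:
    """Per-sample sequencing digest consumed by the trait estimators."""

    sample_id: str
    scg_coverage: np.ndarray  # 35 single-copy family coverages
    ssu_coverage: float
    total_bases: float
    read_gc: np.ndarray

    def __post_init__(self) -> None:
        if self.scg_coverage.shape != (N_SCG_FAMILIES,):
            raise ValueError(f"expected {N_SCG_FAMILIES} single-copy coverages")


@dataclass(frozen=True)
class GeneCatalog:
    """Synthetic non-redundant gene catalog: lengths and category labels."""

    frame: pd.DataFrame  # columns: gene_id, length_bp, labels (';'-joined, '' = unannotated)

    def labels_of(self) -> dict[str, tuple[str, ...]]:
        out = {}
        for gid, lab in zip(self.frame["gene_id"], self.frame["labels"]):
            out[gid] = tuple(lab.split(";")) if lab else ()
        return out


@dataclass(frozen=True)
class ViralTruth:
    """vOTU metadata (lifestyle, host link, coupling) and abundance matrix."""

    meta: pd.DataFrame  # votu_id, lifestyle, host_genome_id, coupling
    abundance: pd.DataFrame  # votu x sample

    def __post_init__(self) -> None:
        bad = set(self.meta["lifestyle"]) - {"temperate", "virulent", "unknown"}
        if bad:
            raise ValueError(f"unknown lifestyles {sorted(bad)}")
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("viral abundances must be non-negative")


# ---------------------------------------------------------------------------
# generators


def generate_genomes(
    n: int,
    size_mu: float = float(np.log(4e6)),
    size_sigma: float = 0.35,
    gc_a: float = 30.0,
    gc_b: float = 20.0,
    rrn_max: int = 7,
    seed: int = 0,
) -> GenomePanel:
    """Draw a genome panel: lognormal sizes, beta GC, uniform-integer rRNA copies.

    Defaults reflect arid-soil bacteria: median genome ~4 Mb, GC centred
    near 0.60, and 1-7 rRNA operons spanning oligotroph-to-copiotroph
    growth strategies.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if size_sigma < 0 or gc_a <= 0 or gc_b <= 0 or rrn_max < 1:
        raise ValueError("invalid distribution parameters")
    rng = substream(seed, "genomes")
    lengths = np.maximum(np.round(rng.lognormal(size_mu, size_sigma, size=n)), 1).astype(np.int64)
    gc = rng.beta(gc_a, gc_b, size=n)
    gc = np.clip(gc, 1e-6, 1 - 1e-6)
    rrn = rng.integers(1, rrn_max + 1, size=n).astype(np.int64)
    ids = tuple(f"g{i:04d}" for i in range(n))
    return GenomePanel(ids, lengths, gc, rrn)


def make_design(
    n_samples: int = 18,
    n_sites: int = 6,
    seed: int = 0,
) -> SampleDesign:
    """Balanced urban/natural design: sites split evenly, samples split over sites."""
    if n_sites % 2 or n_samples % n_sites:
        raise ValueError("need an even number of sites and samples divisible by sites")
    per_site = n_samples // n_sites
    rows = []
    for s in range(n_sites):
        group = GROUPS[0] if s < n_sites // 2 else GROUPS[1]
        for r in range(per_site):
            rows.append(
                {
                    "sample_id": f"s{s * per_site + r:02d}",
                    "site_id": f"site{s:02d}",
                    "group": group,
                }
            )
    return SampleDesign(pd.DataFrame(rows))


def simulate_abundance(
    panel: GenomePanel,
    design: SampleDesign,
    base_sigma: float = 1.0,
    site_sigma: float = 0.3,
    sample_sigma: float = 0.2,
    group_effect: float = 0.8,
    affected_fraction: float = 0.5,
    seed: int = 0,
) -> AbundanceTruth:
    """Genome-copy abundances with site and urbanization structure.

    Log-abundances are a genome baseline (lognormal, sd ``base_sigma``)
    plus a site random effect (sd ``site_sigma``), a per-sample residual
    (sd ``sample_sigma``) and, for a random ``affected_fraction`` of
    genomes, a +-``group_effect``/2 urban-vs-natural shift — the structure
    the community-comparison tests are meant to detect.
    """
    rng = substream(seed, "abundance")
    n_g, samples = len(panel), design.sample_ids
    base = rng.normal(0.0, base_sigma, size=n_g)
    affected = rng.random(n_g) < affected_fraction
    direction = rng.choice([-1.0, 1.0], size=n_g)
    sites = sorted(design.frame["site_id"].unique())
    site_eff = {s: rng.normal(0.0, site_sigma, size=n_g) for s in sites}
    cols = {}
    site_of = design.site_of_sample()
    group_of = design.group_of_sample()
    for sample in samples:
        shift = np.where(
            affected,
            direction * (group_effect / 2) * (1 if group_of[sample] == "urban" else -1),
            0.0,
        )
        log_a = base + site_eff[site_of[sample]] + shift + rng.normal(0, sample_sigma, n_g)
        cols[sample] = np.exp(log_a)
    return AbundanceTruth(pd.DataFrame(cols, index=list(panel.genome_id)))


def simulate_read_summary(
    panel: GenomePanel,
    abundance: np.ndarray | Sequence[float],
    depth_factor: float = 20.0,
    noise: str = "none",
    n_reads: int = 2000,
    gc_jitter_sd: float = 0.05,
    seed: int = 0,
    sample_id: str = "sample",
) -> ReadSummary:
    """Sequencing digest of one sample under the coverage contract.

    ``noise='poisson'`` replaces each coverage by a Poisson draw around its
    noiseless mean; total bases and the GC read pool are unaffected.
    Per-read GC is the source genome's GC (genomes drawn with probability
    proportional to a_g * L_g) plus Gaussian jitter truncated to (0, 1).
    """
    a = np.asarray(abundance, dtype=float)
    if a.shape != (len(panel),):
        raise ValueError("abundance length must match the panel")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    if not np.any(a > 0):
        raise ValueError("all-zero abundance: sample contains no genomes")
    if depth_factor <= 0:
        raise ValueError("depth_factor must be positive")
    if noise not in {"none", "poisson"}:
        raise ValueError(f"unknown noise model {noise!r}")
    rng = substream(seed, f"read_summary/{sample_id}")
    total_copies = a.sum()
    scg_mean = depth_factor * total_copies
    ssu_mean = depth_factor * float(np.sum(a * panel.rrn_copies))
    total_bases = depth_factor * float(np.sum(a * panel.length_bp))
    if noise == "none":
        scg = np.full(N_SCG_FAMILIES, scg_mean)
        ssu = ssu_mean
    else:
        scg = rng.poisson(scg_mean, size=N_SCG_FAMILIES).astype(float)
        ssu = float(rng.poisson(ssu_mean))
    weights = a * panel.length_bp
    src = rng.choice(len(panel), size=n_reads, p=weights / weights.sum())
    loc = panel.gc_fraction[src]
    lo, hi = (0.0 - loc) / gc_jitter_sd, (1.0 - loc) / gc_jitter_sd
    read_gc = stats.truncnorm.rvs(lo, hi, loc=loc, scale=gc_jitter_sd, random_state=rng)
    return ReadSummary(sample_id, scg, ssu, total_bases, np.asarray(read_gc))


def summaries_to_table(summaries: Sequence[ReadSummary]) -> pd.DataFrame:
    """Stack per-sample digests into the trait module's summary table."""
    rows = {}
    for s in summaries:
        row = {f"scg_{i + 1:02d}": s.scg_coverage[i] for i in range(N_SCG_FAMILIES)}
        row["ssu_coverage"] = s.ssu_coverage
        row["total_bases"] = s.total_bases
        rows[s.sample_id] = row
    df = pd.DataFrame(rows).T
    df.index.name = "sample_id"
    return df


DEFAULT_LABEL_SCHEME = {
    "sugar_decomposition": 0.10,
    "acid_decomposition": 0.10,
    "carbon_cycling": 0.10,
    "nitrogen_cycling": 0.08,
    "metal_resistance": 0.04,
    "drug_resistance": 0.04,
}  # remaining 0.54 of genes unannotated, typical of soil catalogs


def simulate_gene_catalog(
    n_genes: int,
    n_samples: int = 1,
    sample_ids: Sequence[str] | None = None,
    label_scheme: Mapping[str, float] | None = None,
    length_mu: float = float(np.log(900.0)),
    length_sigma: float = 0.3,
    reads_per_sample: int = 200_000,
    abundance_mode: str = "lognormal",
    seed: int = 0,
) -> tuple[GeneCatalog, CountMatrix, pd.Series]:
    """Gene catalog plus a multinomial count matrix with retained truth.

    ``label_scheme`` maps category -> probability; the unassigned remainder
    is the unannotated fraction. Counts per sample are multinomial draws of
    ``reads_per_sample`` reads from the true relative abundances (equal or
    lognormal across genes, shared by all samples). Returns the catalog,
    the count matrix and the true relative-abundance vector.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    scheme = dict(DEFAULT_LABEL_SCHEME if label_scheme is None else label_scheme)
    probs = np.array(list(scheme.values()), dtype=float)
    if np.any(probs < 0):
        raise ValueError("label probabilities must be non-negative")
    if probs.sum() > 1 + 1e-12:
        raise ValueError("label probabilities must sum to at most 1")
    rng = substream(seed, "gene_catalog")
    lengths = np.maximum(np.round(rng.lognormal(length_mu, length_sigma, n_genes)), 30)
    lengths = (np.ceil(lengths / 3) * 3).astype(np.int64)  # in-frame lengths
    cats = list(scheme)
    full = np.concatenate([probs, [1 - probs.sum()]])
    assignment = rng.choice(len(cats) + 1, size=n_genes, p=full / full.sum())
    labels = ["" if k == len(cats) else cats[k] for k in assignment]
    gene_ids = [f"gene{i:06d}" for i in range(n_genes)]
    catalog = GeneCatalog(
        pd.DataFrame({"gene_id": gene_ids, "length_bp": lengths, "labels": labels})
    )
    if abundance_mode == "equal":
        true_rel = np.full(n_genes, 1.0 / n_genes)
    elif abundance_mode == "lognormal":
        raw = rng.lognormal(0.0, 1.0, n_genes)
        true_rel = raw / raw.sum()
    else:
        raise ValueError(f"unknown abundance mode {abundance_mode!r}")
    if sample_ids is None:
        sample_ids = [f"s{i:02d}" for i in range(n_samples)]
    counts = {
        sid: rng.multinomial(reads_per_sample, true_rel) for sid in sample_ids
    }
    counts_df = pd.DataFrame(counts, index=gene_ids)
    matrix = CountMatrix(
        counts=counts_df,
        lengths_bp=pd.Series(lengths, index=gene_ids),
        labels=catalog.labels_of(),
        totals=pd.Series(reads_per_sample, index=list(sample_ids), dtype=float),
    )
    return catalog, matrix, pd.Series(true_rel, index=gene_ids)


def pathway_map_from_catalog(catalog: GeneCatalog) -> pd.DataFrame:
    """Sugar/acid pathway map (gene_id, class, weight) from catalog labels."""
    rows = []
    for gid, labels in catalog.labels_of().items():
        for lab in labels:
            if lab == "sugar_decomposition":
                rows.append({"gene_id": gid, "class": "sugar", "weight": 1.0})
            elif lab == "acid_decomposition":
                rows.append({"gene_id": gid, "class": "acid", "weight": 1.0})
    return pd.DataFrame(rows, columns=["gene_id", "class", "weight"])


def simulate_codon_counts(
    bias: float,
    n_genes: int = 20,
    codons_per_gene: int = 200,
    seed: int = 0,
) -> list[CodonCounts]:
    """Ribosomal-protein codon tables with tunable synonymous bias.

    Amino acids are drawn uniformly over the 18 synonymous families; within
    a family the codon distribution interpolates between uniform (bias 0)
    and a point mass on one preferred codon (bias 1):
    p = (1 - b)/m + b * 1[preferred]. The preferred codon is the family's
    first in lexicographic order, giving a composition-neutral choice.
    """
    if not 0.0 <= bias <= 1.0:
        raise ValueError(f"bias must lie in [0, 1], got {bias}")
    if n_genes < 1 or codons_per_gene < 1:
        raise ValueError("n_genes and codons_per_gene must be >= 1")
    rng = substream(seed, "codon_counts")
    families = sorted(SYNONYMOUS_FAMILIES)
    genes = []
    for _ in range(n_genes):
        counts: dict[str, int] = {}
        fam_totals = rng.multinomial(codons_per_gene, np.full(len(families), 1 / len(families)))
        for fam, total in zip(families, fam_totals):
            codons = SYNONYMOUS_FAMILIES[fam]
            m = len(codons)
            p = np.full(m, (1.0 - bias) / m)
            p[0] += bias
            for codon, c in zip(codons, rng.multinomial(int(total), p)):
                if c:
                    counts[codon] = int(c)
        genes.append(CodonCounts(counts))
    return genes


def codon_counts_to_fasta(
    codon_sets: Mapping[str, Sequence[CodonCounts]],
    path: Path | str,
    seed: int = 0,
) -> None:
    """Write synthetic in-frame coding sequences realizing the codon counts.

    Each record is a shuffled concatenation of its codons; re-counting the
    FASTA reproduces the tables exactly.
    """
    rng = substream(seed, "codon_fasta")
    with open(path, "w") as fh:
        for sample in codon_sets:
            for i, gene in enumerate(codon_sets[sample]):
                codons = [
                    codon
                    for codon, count in gene.counts.items()
                    for _ in range(int(count))
                ]
                order = rng.permutation(len(codons))
                seq = "".join(codons[j] for j in order)
                fh.write(f">{sample}|rp{i:03d}\n{seq}\n")


def simulate_virus_host(
    panel: GenomePanel,
    truth: AbundanceTruth,
    n_viruses: int = 200,
    p_temperate: float = 0.65,
    coupling_model: str = "anti",
    p_decoupled: float = 0.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> ViralTruth:
    """Virus-host abundance matrix with lifestyle-dependent coupling.

    Temperate vOTUs track their host (lysogeny: v = alpha * h, positive
    coupling, the Piggyback-the-Winner regime). Virulent vOTUs are either
    linearly anti-coupled (lysis: v = c - beta * h with c chosen so v > 0,
    giving r = -1 noiselessly) or, with probability ``p_decoupled``,
    independent lognormal series (r ~ 0). Multiplicative Gaussian noise of
    sd ``noise_sd`` perturbs every entry; abundances are clipped at 0.
    """
    if not 0.0 <= p_temperate <= 1.0:
        raise ValueError("p_temperate must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if coupling_model not in {"anti", "decoupled"}:
        raise ValueError(f"unknown coupling model {coupling_model!r}")
    rng = substream(seed, "virus_host")
    samples = list(truth.abundance.columns)
    meta_rows, abund_rows = [], []
    for v in range(n_viruses):
        votu = f"votu{v:04d}"
        host_idx = int(rng.integers(0, len(panel)))
        host_id = panel.genome_id[host_idx]
        h = truth.abundance.loc[host_id].to_numpy(dtype=float)
        temperate = rng.random() < p_temperate
        if temperate:
            alpha = float(rng.lognormal(np.log(0.1), 0.5))
            base = alpha * h
            lifestyle, coupling = "temperate", alpha
        else:
            decoupled = coupling_model == "decoupled" or rng.random() < p_decoupled
            if decoupled:
                base = rng.lognormal(np.log(0.1 * h.mean() + 1e-12), 0.7, size=len(h))
                lifestyle, coupling = "virulent", 0.0
            else:
                beta = float(rng.lognormal(np.log(0.1), 0.5))
                c = beta * (h.max() + h.mean())
                base = np.maximum(0.0, c - beta * h)
                lifestyle, coupling = "virulent", -beta
        eps = rng.normal(0.0, noise_sd, size=len(h)) if noise_sd > 0 else 0.0
        abund = np.maximum(0.0, base * (1.0 + eps))
        meta_rows.append(
            {
                "votu_id": votu,
                "lifestyle": lifestyle,
                "host_genome_id": host_id,
                "coupling": coupling,
            }
        )
        abund_rows.append(pd.Series(abund, index=samples, name=votu))
    meta = pd.DataFrame(meta_rows, columns=["votu_id", "lifestyle", "host_genome_id", "coupling"])
    abundance = pd.DataFrame(abund_rows)
    abundance.index.name = "votu_id"
    return ViralTruth(meta, abundance)


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(
    outdir: Path | str,
    panel: GenomePanel,
    design: SampleDesign,
    truth: AbundanceTruth,
    summaries: Sequence[ReadSummary],
    catalog: GeneCatalog,
    gene_counts: CountMatrix,
    codon_sets: Mapping[str, Sequence[CodonCounts]],
    viral: ViralTruth,
    truth_params: Mapping | None = None,
    seed: int = 0,
) -> list[Path]:
    """Serialize the full fixture set as TSV/FASTA/JSON; returns written paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    def _w(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = out / name
        write_tsv(df, p, index=index)
        paths.append(p)

    _w("genomes.tsv", panel.to_frame())
    _w("design.tsv", design.frame)
    _w("abundance.tsv", truth.abundance, index=True)
    _w("read_summary.tsv", summaries_to_table(summaries), index=True)
    gc_long = pd.DataFrame(
        [(s.sample_id, g) for s in summaries for g in s.read_gc],
        columns=["sample_id", "gc"],
    )
    _w("read_gc.tsv", gc_long)
    _w("gene_catalog.tsv", catalog.frame)
    _w("gene_counts.tsv", gene_counts.counts, index=True)
    _w("pathway_map.tsv", pathway_map_from_catalog(catalog))
    fasta = out / "ribosomal_cds.fasta"
    codon_counts_to_fasta(codon_sets, fasta, seed=seed)
    paths.append(fasta)
    _w("viral_abundance.tsv", viral.abundance, index=True)
    _w("viral_meta.tsv", viral.meta)
    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "true_ags": {k: float(v) for k, v in truth.true_ags(panel).items()},
                "true_acn": {k: float(v) for k, v in truth.true_acn(panel).items()},
                "params": dict(truth_params or {}),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    paths.append(truth_path)
    return paths


def read_fixture(outdir: Path | str) -> dict:
    """Re-load a fixture directory into the in-memory objects."""
    out = Path(outdir)
    panel = GenomePanel.from_frame(read_tsv(out / "genomes.tsv"))
    design = SampleDesign(read_tsv(out / "design.tsv"))
    truth = AbundanceTruth(read_tsv(out / "abundance.tsv", index_col=0))
    summary_table = read_tsv(out / "read_summary.tsv", index_col=0)
    gc_long = read_tsv(out / "read_gc.tsv")
    read_gc = {
        str(sid): sub["gc"].to_numpy() for sid, sub in gc_long.groupby("sample_id", sort=False)
    }
    catalog = GeneCatalog(read_tsv(out / "gene_catalog.tsv").fillna({"labels": ""}))
    gene_counts = read_tsv(out / "gene_counts.tsv", index_col=0)
    pathway_map = read_tsv(out / "pathway_map.tsv")
    from .traits import codon_counts_from_fasta

    per_record = codon_counts_from_fasta(out / "ribosomal_cds.fasta")
    codon_sets: dict[str, list[CodonCounts]] = {}
    for rec_id, counts in per_record.items():
        sample = rec_id.split("|")[0]
        codon_sets.setdefault(sample, []).append(counts)
    viral = ViralTruth(
        read_tsv(out / "viral_meta.tsv"),
        read_tsv(out / "viral_abundance.tsv", index_col=0),
    )
    with open(out / "truth.json") as fh:
        truth_json = json.load(fh)
    return {
        "panel": panel,
        "design": design,
        "truth": truth,
        "summary_table": summary_table,
        "read_gc": read_gc,
        "catalog": catalog,
        "gene_counts": gene_counts,
        "pathway_map": pathway_map,
        "codon_sets": codon_sets,
        "viral": viral,
        "truth_json": truth_json,
    }
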