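"""End-to-end pipeline: seeded fixture -> traits -> tables -> virus-host -> comparison.

Every stage reads its inputs from the fixture/output directory and writes
TSV/JSON artifacts, so a piecewise run (stage by stage) and a monolithic
run produce identical files; a manifest with SHA-256 checksums makes
determinism verifiable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import comparison as cmp
from . import synthetic as syn
from . import traits as tr
from . import virushost as vh
from ._util import child_seed, sha256_of, write_tsv
from .config import RunConfig

log = logging.getLogger("metatraits")

STAGES = ("simulate", "traits", "abundance", "virus_host", "compare")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs missing upstream artifact: {path}"
        )
    return path


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


def stage_simulate(config: RunConfig) -> dict:
    """Generate the synthetic community and serialize the fixture set."""
    sim = config.simulate
    seed = config.seed
    panel = syn.generate_genomes(
        sim.n_genomes,
        size_mu=sim.size_mu,
        size_sigma=sim.size_sigma,
        gc_a=sim.gc_a,
        gc_b=sim.gc_b,
        rrn_max=sim.rrn_max,
        seed=seed,
    )
    design = syn.make_design(sim.n_samples, sim.n_sites)
    truth = syn.simulate_abundance(
        panel,
        design,
        base_sigma=sim.base_sigma,
        site_sigma=sim.site_sigma,
        sample_sigma=sim.sample_sigma,
        group_effect=sim.group_effect,
        affected_fraction=sim.affected_fraction,
        seed=seed,
    )
    summaries = [
        syn.simulate_read_summary(
            panel,
            truth.abundance[s].to_numpy(),
            depth_factor=sim.depth_factor,
            noise=sim.noise,
            n_reads=sim.n_reads,
            gc_jitter_sd=sim.gc_jitter_sd,
            seed=seed,
            sample_id=s,
        )
        for s in design.sample_ids
    ]
    catalog, gene_counts, _true_rel = syn.simulate_gene_catalog(
        sim.n_genes,
        sample_ids=design.sample_ids,
        reads_per_sample=sim.reads_per_sample,
        seed=seed,
    )
    codon_sets = {
        s: syn.simulate_codon_counts(
            sim.codon_bias,
            n_genes=sim.n_ribosomal_genes,
            codons_per_gene=sim.codons_per_gene,
            seed=child_seed(seed, f"codons/{s}"),
        )
        for s in design.sample_ids
    }
    viral = syn.simulate_virus_host(
        panel,
        truth,
        n_viruses=sim.n_votus,
        p_temperate=sim.p_temperate,
        coupling_model=sim.coupling_model,
        p_decoupled=sim.p_decoupled,
        noise_sd=sim.noise_sd,
        seed=seed,
    )
    fixture_dir = Path(config.outdir) / "fixture"
    paths = syn.write_fixture(
        fixture_dir,
        panel,
        design,
        truth,
        summaries,
        catalog,
        gene_counts,
        codon_sets,
        viral,
        truth_params={"seed": seed, **vars(sim)},
        seed=seed,
    )
    log.info("simulate: wrote %d fixture files to %s", len(paths), fixture_dir)
    return {"n_genomes": len(panel), "n_samples": len(design.sample_ids), "files": len(paths)}


def stage_traits(config: RunConfig) -> dict:
    """Compute the per-sample trait table from the fixture."""
    fixture_dir = _require(Path(config.outdir) / "fixture", "traits")
    fx = syn.read_fixture(fixture_dir)
    profiles = tr.compute_trait_profiles(
        fx["summary_table"],
        read_gc=fx["read_gc"],
        codon_sets=fx["codon_sets"],
        gene_counts=fx["gene_counts"],
        gene_labels=fx["catalog"].labels_of(),
        pathway_map=fx["pathway_map"],
    )
    outdir = Path(config.outdir) / "traits"
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(profiles, outdir / "trait_profiles.tsv", index=True)
    _write_json(tr.CONVENTIONS, outdir / "run_metadata.json")
    group = fx["design"].group_of_sample()
    group_means = profiles.groupby(group).mean()
    true_ags = pd.Series(fx["truth_json"]["true_ags"]).reindex(profiles.index)
    rel_err = ((profiles["ags_bp"] - true_ags).abs() / true_ags).max()
    log.info("traits: max AGS relative error vs truth = %.4f", rel_err)
    return {
        "group_means": {g: row.to_dict() for g, row in group_means.iterrows()},
        "ags_max_rel_error": float(rel_err),
    }


def stage_abundance(config: RunConfig) -> dict:
    """Normalize and aggregate gene counts; filter and rarefy the species table."""
    fixture_dir = _require(Path(config.outdir) / "fixture", "abundance")
    fx = syn.read_fixture(fixture_dir)
    ana = config.analysis
    outdir = Path(config.outdir) / "abundance"
    outdir.mkdir(parents=True, exist_ok=True)

    counts = fx["gene_counts"]
    lengths = fx["catalog"].frame.set_index("gene_id")["length_bp"]
    totals = counts.sum(axis=0).astype(float)
    norm = ab.rpkm(counts, lengths, totals)
    write_tsv(norm.values, outdir / "gene_rpkm.tsv", index=True)
    labels = fx["catalog"].labels_of()
    agg, agg_report = ab.aggregate_by_label(norm.values, labels)
    write_tsv(agg, outdir / "category_rpkm.tsv", index=True)

    species_rel = ab.relative_abundance(fx["truth"].abundance).values
    filtered, removal = ab.prevalence_abundance_filter(
        species_rel, ana.min_prevalence, ana.min_mean_abundance, rule=ana.filter_rule
    )
    write_tsv(filtered, outdir / "species_filtered.tsv", index=True)
    write_tsv(removal, outdir / "species_removed.tsv", index=True)

    gene_totals = counts.sum(axis=0)
    depth = int(ana.rarefaction_depth or gene_totals.min())
    rare_rows = {}
    for i, sample in enumerate(counts.columns):
        vec = counts[sample].to_numpy()
        sub = ab.rarefy(vec, depth, seed=child_seed(config.seed, f"rarefy/{sample}"))
        rare_rows[sample] = {
            "richness": ab.richness(vec),
            "rarefied_richness": ab.richness(sub),
            "expected_richness": ab.expected_richness(vec, depth),
        }
    richness_df = pd.DataFrame(rare_rows).T
    richness_df.index.name = "sample_id"
    write_tsv(richness_df, outdir / "gene_richness.tsv", index=True)
    log.info(
        "abundance: %d categories, %d species kept (%d removed), rarefaction depth %d",
        agg.shape[0], filtered.shape[0], removal.shape[0], depth,
    )
    return {
        "n_categories": int(agg.shape[0]),
        "n_unlabeled_dropped": agg_report["n_dropped_unlabeled"],
        "n_species_kept": int(filtered.shape[0]),
        "n_species_removed": int(removal.shape[0]),
        "rarefaction_depth": depth,
        "mean_rarefied_richness": float(richness_df["rarefied_richness"].mean()),
    }


def stage_virus_host(config: RunConfig) -> dict:
    """Pair statistics, correlation distributions and lifestyle ratios."""
    fixture_dir = _require(Path(config.outdir) / "fixture", "virus_host")
    fx = syn.read_fixture(fixture_dir)
    ana = config.analysis
    outdir = Path(config.outdir) / "virus_host"
    outdir.mkdir(parents=True, exist_ok=True)

    host_rel = ab.relative_abundance(fx["truth"].abundance).values
    viral_rel = ab.relative_abundance(fx["viral"].abundance).values
    links = fx["viral"].meta[["votu_id", "host_genome_id"]]
    group = fx["design"].group_of_sample()
    lifestyles = fx["viral"].meta.set_index("votu_id")["lifestyle"]

    rows = []
    dist_summaries = {}
    for grp in sorted(group.unique()):
        samples = group.index[group == grp]
        stats_g = vh.compute_pair_stats(
            viral_rel[samples], links, host_rel[samples], min_samples=ana.min_samples
        )
        for s in stats_g:
            rows.append(
                {
                    "group": grp,
                    "virus_id": s.virus_id,
                    "host_id": s.host_id,
                    "lifestyle": lifestyles.get(s.virus_id, "unknown"),
                    "r_abund": s.r_abund,
                    "r_vhr_host": s.r_vhr_host,
                    "n_used": s.n_used,
                }
            )
        dist = vh.correlation_distribution([s.r_abund for s in stats_g])
        hist_df = pd.DataFrame(
            {
                "bin_left": dist["bin_edges"][:-1],
                "bin_right": dist["bin_edges"][1:],
                "count": dist["hist"],
            }
        )
        write_tsv(hist_df, outdir / f"correlation_hist_{grp}.tsv")
        dist_summaries[grp] = {
            k: dist[k]
            for k in ("n_used", "n_missing", "skewness", "frac_high_positive",
                      "frac_near_zero", "median_r")
        }
    pair_df = pd.DataFrame(rows)
    write_tsv(pair_df, outdir / "pair_stats.tsv")

    ratios = vh.lifestyle_ratio(fx["viral"].abundance, lifestyles, group)
    _write_json(ratios, outdir / "lifestyle_ratio.json")

    profile = vh.host_link_profile(
        host_rel, links, viral_rel, presence_threshold=ana.presence_threshold
    )
    write_tsv(profile, outdir / "host_link_profile.tsv")
    quadrants = profile["quadrant"].value_counts().to_dict()
    log.info("virus_host: %d pairs, lifestyle ratios %s",
             len(pair_df), {g: r["ratio"] for g, r in ratios.items()})
    return {
        "correlation_summary": dist_summaries,
        "lifestyle_ratio": {g: r["ratio"] for g, r in ratios.items()},
        "quadrant_occupancy": {k: int(v) for k, v in quadrants.items()},
    }


def stage_compare(config: RunConfig) -> dict:
    """Bray-Curtis + PERMANOVA on the community; site permutation tests on traits."""
    fixture_dir = _require(Path(config.outdir) / "fixture", "compare")
    fx = syn.read_fixture(fixture_dir)
    ana = config.analysis
    outdir = Path(config.outdir) / "compare"
    outdir.mkdir(parents=True, exist_ok=True)

    species_rel = ab.relative_abundance(fx["truth"].abundance).values
    dist = cmp.bray_curtis(species_rel)
    design = fx["design"]
    result = cmp.permanova(
        dist,
        design.group_of_sample(),
        design.site_of_sample(),
        n_perm=ana.n_perm,
        seed=config.seed,
        scheme=ana.permanova_scheme,
    )
    perm_json = {
        "R2": result.r_squared,
        "F": result.pseudo_f,
        "p": result.p_value,
        "scheme": result.scheme,
        "n_perm": result.n_permutations,
        "exhaustive": result.exhaustive,
    }
    _write_json(perm_json, outdir / "permanova.json")

    trait_tests = {}
    trait_path = Path(config.outdir) / "traits" / "trait_profiles.tsv"
    if trait_path.exists():
        profiles = pd.read_csv(trait_path, sep="\t", index_col=0)
        for col in profiles.columns:
            series = profiles[col].dropna()
            if series.empty:
                continue
            trait_tests[col] = cmp.site_permutation_test(
                series,
                design.site_of_sample(),
                design.group_of_site(),
                n_perm=ana.n_perm,
                seed=child_seed(config.seed, f"trait_test/{col}"),
            )
        _write_json(trait_tests, outdir / "trait_tests.json")
    log.info("compare: PERMANOVA R2=%.3f p=%.4g (%s)",
             result.r_squared, result.p_value, result.scheme)
    return {"permanova": perm_json, "trait_tests": trait_tests}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "traits": stage_traits,
    "abundance": stage_abundance,
    "virus_host": stage_virus_host,
    "compare": stage_compare,
}


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in canonical order; write report + manifest."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    log.info("effective config:\n%s", config.to_yaml())
    # outdir is where, not what: leaving it out keeps equal-seed runs checksum-identical
    cfg_echo = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    results: dict = {"config": cfg_echo}
    for stage in STAGES:
        if stage in stages:
            log.info("running stage %s", stage)
            results[stage] = _STAGE_FUNCS[stage](config)
    write_report(results, Path(config.outdir))
    manifest = _build_manifest(Path(config.outdir))
    _write_json(manifest, Path(config.outdir) / "manifest.json")
    return results


def _build_manifest(outdir: Path) -> dict:
    """Relative path -> SHA-256 for every artifact (the manifest itself excluded)."""
    entries = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries[str(p.relative_to(outdir))] = sha256_of(p)
    return entries


def write_report(results: dict, outdir: Path) -> Path:
    """One JSON summary plus a short human-readable digest.

    Merges with any report already on disk so piecewise stage runs end with
    the same report a monolithic run writes.
    """
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    report: dict = {}
    if path.exists():
        with open(path) as fh:
            report = json.load(fh)
    report.update({k: v for k, v in results.items() if v})
    _write_json(report, path)
    lines = ["metatraits run summary", "======================"]
    if "traits" in report:
        for grp, means in sorted(report["traits"]["group_means"].items()):
            lines.append(f"trait means [{grp}]: " + ", ".join(
                f"{k}={v:.4g}" for k, v in sorted(means.items())))
    if "virus_host" in report:
        for grp, ratio in sorted(report["virus_host"]["lifestyle_ratio"].items()):
            lines.append(f"virulent/temperate ratio [{grp}]: {ratio:.3f}")
    if "compare" in report and report["compare"].get("permanova"):
        pj = report["compare"]["permanova"]
        lines.append(
            f"PERMANOVA ({pj['scheme']}): R2={pj['R2']:.3f} F={pj['F']:.3f} p={pj['p']:.4g}"
        )
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return path
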