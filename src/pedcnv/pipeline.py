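"""End-to-end pipeline: simulate (or load) -> filter -> de novo -> age ->
annotate -> stats, as one reproducible seeded run with a manifest.

A single global seed deterministically derives a per-stage seed by hashing
the stage name, so any stage can be re-run in isolation and reproduce the
full run's output bit for bit.  The manifest records the configuration
hash, the seed, per-stage record counts, and every output path; it contains
no timestamps, so identical runs produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import age_model, annotate_overlap, cnv_stats, filtering, io_formats, simgen, trio_denovo

logger = logging.getLogger("pedcnv")


@dataclass
class AgeConfig:
    n_reps: int = 10_000
    alpha: float = 0.01
    models: tuple[str, ...] = ("gaussian", "poisson")
    # When no reference count table is supplied, a strong-slope Poisson
    # reference (mean = reference_slope * age) is synthesized from the sire
    # ages, standing in for de novo SNV counts which do rise with age.
    reference_counts: dict[str, float] | None = None
    reference_slope: float = 1.5


@dataclass
class RunConfig:
    outdir: str = "pedcnv_run"
    seed: int = 0
    simulate: bool = True
    sim: simgen.SimConfig = field(default_factory=simgen.SimConfig)
    vcf: str | None = None  # used when simulate=False
    ped: str | None = None
    gtf: str | None = None
    filter_params: filtering.FilterParams = field(default_factory=filtering.FilterParams)
    denovo_policy: str = "strict"
    flank_bp: int = 10_000
    fdr: float = 0.01
    age: AgeConfig = field(default_factory=AgeConfig)
    annotate: bool = True
    # optional fixed gene gain/loss counts for the polymorphic-vs-fixed contrast
    fixed_gain_loss: tuple[int, int] | None = None  # (loss, gain)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "sim" in kwargs:
            sim = dict(kwargs["sim"])
            if "artifact_rates" in sim:
                sim["artifact_rates"] = simgen.ArtifactRates(**sim["artifact_rates"])
            kwargs["sim"] = simgen.SimConfig(**sim)
        if "filter_params" in kwargs:
            kwargs["filter_params"] = filtering.FilterParams(**kwargs["filter_params"])
        if "age" in kwargs:
            kwargs["age"] = AgeConfig(**kwargs["age"])
        if "fixed_gain_loss" in kwargs and kwargs["fixed_gain_loss"] is not None:
            kwargs["fixed_gain_loss"] = tuple(kwargs["fixed_gain_loss"])
        return cls(**kwargs)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived from the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return (and write) the manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    out = lambda name: os.path.join(config.outdir, name)  # noqa: E731
    stage = "validate"
    try:
        if not config.simulate:
            for label, path in (("vcf", config.vcf), ("ped", config.ped)):
                if path is None or not os.path.exists(path):
                    raise FileNotFoundError(f"{label} input missing: {path}")
            if config.annotate and (config.gtf is None or not os.path.exists(config.gtf)):
                raise FileNotFoundError(f"gtf input missing: {config.gtf}")

        # -- simulate or load ------------------------------------------------
        stage = "simulate" if config.simulate else "load"
        terms = None
        if config.simulate:
            sim_cfg = config.sim.with_seed(stage_seed(config.seed, "simulate"))
            sites, pedigree, truth = simgen.simulate_cohort(sim_cfg)
            model, terms = simgen.simulate_gene_models(sim_cfg)
            io_formats.write_sv_vcf(
                sites, out("cohort.vcf"), pedigree.samples, contigs=sim_cfg.chromosomes
            )
            io_formats.write_pedigree(pedigree, out("cohort.ped"))
            io_formats.write_gene_models(model, out("genes.gtf"))
            simgen.write_truth_table(truth, out("truth.tsv"))
            terms.to_csv(out("terms.tsv"), sep="\t", index=False)
            manifest["outputs"].update(
                vcf=out("cohort.vcf"), ped=out("cohort.ped"), gtf=out("genes.gtf"),
                truth=out("truth.tsv"), terms=out("terms.tsv"),
            )
            chrom_lengths = sim_cfg.chromosomes
        else:
            pedigree = io_formats.read_pedigree(config.ped)
            sites = io_formats.read_sv_vcf(config.vcf, cohort=pedigree.samples).sites
            model = (
                io_formats.read_gene_models(config.gtf)
                if config.annotate
                else io_formats.GeneModel.empty()
            )
            chrom_lengths = None
        ev, si = filtering.count_events_sites(sites)
        manifest["stages"][stage] = {"events": ev, "sites": si, "samples": len(pedigree.samples)}

        # -- filter ----------------------------------------------------------
        stage = "filter"
        filtered, report = filtering.apply_filter_cascade(
            sites, len(pedigree.samples), config.filter_params
        )
        report.to_frame().to_csv(out("filter_report.tsv"), sep="\t", index=False)
        io_formats.write_sv_vcf(
            filtered, out("filtered.vcf"), pedigree.samples, contigs=chrom_lengths
        )
        manifest["outputs"].update(
            filtered_vcf=out("filtered.vcf"), filter_report=out("filter_report.tsv")
        )
        manifest["stages"]["filter"] = {
            "events": report.output_events,
            "sites": report.output_sites,
            "conserved": report.is_conserved(),
        }

        # -- de novo ---------------------------------------------------------
        stage = "denovo"
        calls = trio_denovo.find_denovo(filtered, pedigree, policy=config.denovo_policy)
        counts = trio_denovo.per_trio_counts(calls, pedigree)
        rate = trio_denovo.estimate_rate(counts)
        with open(out("denovo.tsv"), "w") as fh:
            fh.write("site_id\ttrio_id\tproband\tsvtype\tpassed_f1_check\n")
            for c in calls:
                fh.write(
                    f"{c.site_id}\t{c.trio_id}\t{c.proband}\t{c.svtype.value}\t"
                    f"{int(c.passed_f1_check)}\n"
                )
        with open(out("rate.json"), "w") as fh:
            json.dump(
                dict(rate=rate.rate, ci_low=rate.ci_low, ci_high=rate.ci_high,
                     per_trio_counts=rate.per_trio_counts),
                fh, indent=2, sort_keys=True,
            )
        manifest["outputs"].update(denovo=out("denovo.tsv"), rate=out("rate.json"))
        manifest["stages"]["denovo"] = {
            "calls": len(calls),
            "rate": rate.rate,
            "ci": [rate.ci_low, rate.ci_high],
        }

        # -- age -------------------------------------------------------------
        stage = "age"
        trios = pedigree.trios
        ages = np.array([pedigree.paternal_age[t.trio_id] for t in trios])
        dn_counts = np.array([counts[t.trio_id] for t in trios], dtype=float)
        reg = age_model.fit_age_regression(ages, dn_counts)
        if config.age.reference_counts is not None:
            ref = np.array([config.age.reference_counts[t.trio_id] for t in trios])
        else:
            ref_rng = np.random.default_rng(stage_seed(config.seed, "age-reference"))
            ref = ref_rng.poisson(config.age.reference_slope * ages).astype(float)
        power = {}
        for m in config.age.models:
            p = age_model.run_power_simulation(
                ages, ref, model=m, n_reps=config.age.n_reps, alpha=config.age.alpha,
                seed=stage_seed(config.seed, f"power-{m}"),
            )
            power[m] = dict(
                n_significant_positive=p.n_significant_positive,
                n_reps=p.n_reps, power=p.power,
            )
        age_out = dict(
            slope=reg.slope, intercept=reg.intercept, r_squared=reg.r_squared,
            df_residual=reg.df_residual, p_value=reg.p_value, power=power,
        )
        with open(out("age.json"), "w") as fh:
            json.dump(age_out, fh, indent=2, sort_keys=True)
        manifest["outputs"]["age"] = out("age.json")
        manifest["stages"]["age"] = {
            "slope": reg.slope,
            "p_value": reg.p_value,
            "power": {m: power[m]["power"] for m in power},
        }

        # -- annotate --------------------------------------------------------
        stage = "annotate"
        summary = None
        if config.annotate:
            summary = annotate_overlap.summarize_overlaps(
                filtered, model, flank_bp=config.flank_bp, chrom_lengths=chrom_lengths
            )
            for name in ("region_centric", "cnv_centric", "per_cnv_averages"):
                summary.table(name).to_csv(out(f"{name}.tsv"), sep="\t", index=False)
                manifest["outputs"][name] = out(f"{name}.tsv")
            io_formats.write_bed(filtered, out("filtered.bed"))
            manifest["outputs"]["bed"] = out("filtered.bed")
            manifest["stages"]["annotate"] = {"overlap_records": len(summary.records)}

        # -- stats -----------------------------------------------------------
        stage = "stats"
        n_del, n_dup = cnv_stats.callset_del_dup_counts(filtered)
        stats_out: dict = {
            "n_del_sites": n_del,
            "n_dup_sites": n_dup,
            "del_dup_ratio": cnv_stats.del_dup_ratio(n_del, n_dup),
            "deletion_fraction": cnv_stats.deletion_fraction(filtered),
        }
        del_lengths = [s.length for s in filtered if s.svtype is io_formats.SVType.DEL]
        dup_lengths = [s.length for s in filtered if s.svtype is io_formats.SVType.DUP]
        if del_lengths and dup_lengths:
            ks = cnv_stats.ks_length_test(del_lengths, dup_lengths)
            stats_out["ks_del_vs_dup"] = dict(d=ks.d_statistic, p=ks.p_value)
        if summary is not None:
            exon_del = sum(summary.region_centric.get(("exon", "DEL", m), 0) for m in ("full", "partial"))
            exon_dup = sum(summary.region_centric.get(("exon", "DUP", m), 0) for m in ("full", "partial"))
            stats_out["exon_del_dup_ratio"] = cnv_stats.del_dup_ratio(exon_del, exon_dup)
            cnv_ex_del = sum(summary.cnv_centric.get(("exon", "DEL", m), 0) for m in ("full", "partial"))
            cnv_ex_dup = sum(summary.cnv_centric.get(("exon", "DUP", m), 0) for m in ("full", "partial"))
            if min(cnv_ex_del + cnv_ex_dup, n_del + n_dup) > 0 and cnv_ex_del + n_del > 0 and cnv_ex_dup + n_dup > 0:
                contrast = cnv_stats.yates_chi2([[cnv_ex_del, cnv_ex_dup], [n_del, n_dup]])
                stats_out["exon_vs_callset_chi2"] = dict(chi2=contrast.chi2, p=contrast.p_value)
            if terms is not None:
                universe = set(model.transcripts.transcript_id)
                overlapped = {
                    r.feature_id for r in summary.records if r.feature_class == "transcript"
                }
                enr = cnv_stats.fisher_enrichment(terms, overlapped, universe, fdr=config.fdr)
                enr.table.to_csv(out("enrichment.tsv"), sep="\t", index=False)
                manifest["outputs"]["enrichment"] = out("enrichment.tsv")
                stats_out["n_enriched_terms"] = int(enr.table.significant.sum())
        if config.fixed_gain_loss is not None:
            loss, gain = config.fixed_gain_loss
            pf = cnv_stats.polymorphic_vs_fixed(n_del, n_dup, loss, gain)
            stats_out["polymorphic_vs_fixed"] = dict(
                polymorphic_ratio=pf.polymorphic_ratio,
                fixed_ratio=pf.fixed_ratio,
                chi2=pf.contingency.chi2,
                p=pf.contingency.p_value,
            )
        stats_clean = {
            k: (str(v) if isinstance(v, float) and math.isinf(v) else v)
            for k, v in stats_out.items()
        }
        with open(out("stats.json"), "w") as fh:
            json.dump(stats_clean, fh, indent=2, sort_keys=True)
        manifest["outputs"]["stats"] = out("stats.json")
        manifest["stages"]["stats"] = {"keys": sorted(stats_out)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise StageError(stage, exc) from exc

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest"] = out("manifest.json")
    return manifest
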