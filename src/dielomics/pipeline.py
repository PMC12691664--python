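"""End-to-end pipeline driver: simulate -> preprocess -> diel statistics ->
co-expression network -> enrichment -> DGR diversity, with a reproducible
run manifest.

Every stochastic stage derives its seed from the single global seed keyed by
the stage name, so re-running with the same configuration and seed is
byte-identical, and adding or reordering stages does not silently shift the
streams of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpnet, diel_stats, dgr, enrichment, io, preprocess, simdata
from .errors import DielomicsError

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Paths (optional when simulating) and per-stage parameters."""

    # inputs; leave None with simulate=True to generate them
    counts: str | None = None
    meta: str | None = None
    gmt: str | None = None
    tr_fasta: str | None = None
    vr_bed: str | None = None
    pileup: str | None = None
    simulate: bool = True
    # simulation sizes (desk-scale end-to-end default)
    n_genes: int = 600
    # stage parameters
    threshold: float = 10.0
    alpha: float = 0.05
    powers: tuple[int, ...] = coexpnet.DEFAULT_SOFT_POWERS
    cut_height: float = 0.97
    min_size: int = 20
    mcc_threshold: float = 0.75
    min_depth: int = 10
    n_perm: int = 10000
    seed: int = 0
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DielomicsError(f"unknown config keys: {sorted(unknown)}")
        if "powers" in data:
            data["powers"] = tuple(data["powers"])
        return cls(**data)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed keyed by stage name (< 2^31)."""
    digest = hashlib.sha256(stage.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Execute every stage, wiring outputs to inputs; abort on stage error."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__, seed=config.seed,
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()})

    def write(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest.outputs[name] = _sha256(path)

    stage = "inputs"
    try:
        if config.simulate:
            sim_cfg = simdata.SimExprConfig(
                n_genes=config.n_genes, seed=stage_seed(config.seed, "simulate_expr"))
            X, truth = simdata.simulate_diel_counts(sim_cfg)
            write("counts.tsv", lambda p: io.write_counts_tsv(X, p, outdir / "meta.tsv"))
            manifest.outputs["meta.tsv"] = _sha256(outdir / "meta.tsv")
            truth.gene_class.to_frame().assign(module=truth.module_assignment).to_csv(
                outdir / "truth_genes.tsv", sep="\t")
            manifest.outputs["truth_genes.tsv"] = _sha256(outdir / "truth_genes.tsv")
            gene_sets = enrichment.GeneSetCollection(
                sets=simdata.simulate_gene_sets(
                    truth, seed=stage_seed(config.seed, "simulate_sets")))
            write("pathways.gmt", lambda p: io.write_gmt(gene_sets, p))
            dgr_cfg = simdata.DgrSimConfig(
                tr_sequence=simdata.random_tr_sequence(
                    seed=stage_seed(config.seed, "simulate_tr")),
                seed=stage_seed(config.seed, "simulate_dgr"))
            locus, pileup, dgr_truth = simdata.simulate_dgr_pileup(dgr_cfg)
            write("pileup.tsv", lambda p: io.write_pileup_tsv(pileup, p))
            write("locus.fasta", lambda p: io.write_locus(locus, p, outdir / "vr.bed"))
            manifest.outputs["vr.bed"] = _sha256(outdir / "vr.bed")
            dgr_truth.to_csv(outdir / "truth_dgr.tsv", sep="\t")
            manifest.outputs["truth_dgr.tsv"] = _sha256(outdir / "truth_dgr.tsv")
        else:
            X = io.read_counts_tsv(config.counts, config.meta)
            gene_sets = io.read_gmt(config.gmt) if config.gmt else None
            locus = (io.read_locus(config.tr_fasta, config.vr_bed)
                     if config.tr_fasta else None)
            pileup = io.read_pileup_tsv(config.pileup) if config.pileup else None

        stage = "preprocess"
        X_norm = preprocess.upper_quartile_normalize(X)
        filt = preprocess.filter_low_expression(X_norm, config.threshold)
        X_filt = filt.matrix
        Z = preprocess.zscore_by_gene(X_filt)
        write("normalized.tsv", lambda p: io.write_counts_tsv(X_norm, p))
        write("zscores.tsv", lambda p: io.write_counts_tsv(Z, p))
        write("filter_report.tsv", lambda p: Path(p).write_text(
            f"retained\t{filt.n_retained}\nremoved\t{filt.n_removed}\n"))
        qc = preprocess.sample_spearman(X_norm)
        write("sample_spearman.tsv", lambda p: qc.to_csv(p, sep="\t"))

        stage = "diel_stats"
        table, dend = diel_stats.diel_gene_table(X_filt, alpha=config.alpha)
        write("diel_genes.tsv", lambda p: table.to_csv(p, sep="\t"))
        if dend is not None:
            write("diel_dendrogram.nwk", lambda p: Path(p).write_text(
                dend.to_newick() + "\n"))

        stage = "coexpnet"
        C = coexpnet.pearson_matrix(Z)
        soft = coexpnet.pick_soft_threshold(C, config.powers)
        A = coexpnet.adjacency_from_correlation(C, soft.beta)
        tom = coexpnet.tom_from_adjacency(A)
        modules = coexpnet.build_modules(
            Z, tom, cut_height=config.cut_height, min_size=config.min_size)
        write("modules.tsv", lambda p: modules.assignment.rename("module")
              .to_csv(p, sep="\t"))
        if modules.eigengenes is not None:
            write("eigengenes.tsv", lambda p: modules.eigengenes.to_csv(p, sep="\t"))
            write("module_timepoints.tsv",
                  lambda p: modules.tp_correlation.to_csv(p, sep="\t", index=False))
        mcc_rows = []
        for m in modules.modules():
            genes = modules.genes_of(m)
            sub = C.loc[genes, genes]
            mcc = coexpnet.mcc_scores(sub, edge_threshold=config.mcc_threshold)
            for node, score in mcc.top(10).items():
                mcc_rows.append(f"{m}\t{node}\t{score}")
        write("mcc_top10.tsv", lambda p: Path(p).write_text(
            "module\tgene\tmcc\n" + "".join(r + "\n" for r in mcc_rows)))

        stage = "enrichment"
        if gene_sets is not None:
            universe = set(X_filt.gene_ids)
            anova_day = set(table.index[table["label"] == "day"])
            anova_night = set(table.index[table["label"] == "night"])
            consensus = diel_stats.consensus_gene_sets(
                anova_day, anova_night, modules.genes_by_timepoint(),
                simdata.DEFAULT_PHASES, Z)
            for name, genes in (("day", consensus.day), ("night", consensus.night)):
                result = enrichment.enrich_sets(genes & universe, universe, gene_sets)
                write(f"enrichment_{name}.tsv",
                      lambda p, r=result: r.to_csv(p, sep="\t", index=False))

        stage = "dgr_diversity"
        if locus is not None and pileup is not None:
            tr_iv = locus.tr_interval or (0, len(locus.tr_sequence))
            tr_prof = dgr.pi_profile(pileup, tr_iv, locus,
                                     min_depth=config.min_depth, region_name="TR")
            vr_profs = [
                dgr.pi_profile(pileup, (vr.start, vr.end), locus, vr_name=vr.name,
                               min_depth=config.min_depth)
                for vr in locus.vr_regions]
            summary = dgr.compare_vr_tr(
                tr_prof, vr_profs, n_perm=config.n_perm,
                seed=stage_seed(config.seed, "dgr_perm"))
            write("dgr_summary.tsv", lambda p: summary.to_csv(p, sep="\t", index=False))
            prof_table = pd.concat(
                [p_.table.assign(region=p_.region_name)
                 for p_ in [tr_prof, *vr_profs]])
            write("dgr_pi_profiles.tsv",
                  lambda p: prof_table.to_csv(p, sep="\t", index=False))
    except DielomicsError as exc:
        raise DielomicsError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
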