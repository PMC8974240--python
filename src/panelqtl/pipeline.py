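"""End-to-end pipeline orchestration and configuration.

``run_pipeline`` wires the stages together:
simulate (optional) -> phenotype summaries -> per-panel/per-trait GWAS ->
region calling & cross-panel merging -> co-location & pivot tables ->
gene annotation -> network learning.  All effective parameters and seeds are
logged; outputs are plain-text TSV/BED/JSON/DOT files under ``outdir``.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from panelqtl import bn as bn_mod
from panelqtl import gwas as gwas_mod
from panelqtl import io as io_mod
from panelqtl import phenostats as ph
from panelqtl import regions as reg
from panelqtl import simulate as sim

__all__ = ["PipelineConfig", "Thresholds", "run_pipeline", "standard_panels"]

logger = logging.getLogger("panelqtl")


@dataclass
class Thresholds:
    sig: float = 5.0
    extend: int = 200_000
    flank: int = 50_000
    merge_gap: int = 800_000
    coloc_gap: int = 500_000
    gene_window: int = 1_000_000
    min_snps: int = 2
    min_alt_carriers: int = 6

    def __post_init__(self) -> None:
        for name in ("extend", "flank", "merge_gap", "coloc_gap", "gene_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sig <= 0:
            raise ValueError("sig threshold must be > 0")


@dataclass
class PipelineConfig:
    outdir: str = "out"
    seed: int = 0
    genotypes: str | None = None      # .vcf or HapMap .txt/.hmp.txt
    phenotypes: str | None = None
    subpops: str | None = None
    annotations: str | None = None    # .gff3/.gff or gene-table .tsv
    simulate: dict | None = None      # PanelConfig overrides; presence enables simulation
    traits: list[str] | None = None
    log_traits: list[str] = field(default_factory=list)
    panels: list[dict] | None = None  # [{name, members|subpops, n_pcs}]
    thresholds: Thresholds = field(default_factory=Thresholds)
    bn: dict = field(default_factory=dict)   # BnConfig overrides + "stages"
    stat: str = "f"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        thr = raw.pop("thresholds", {})
        cfg = cls(**raw)
        if isinstance(thr, dict):
            cfg.thresholds = Thresholds(**thr)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def standard_panels(
    accessions: list[str],
    subpops: dict[str, str],
    pcs: dict[str, int] | None = None,
    min_size: int = 12,
) -> list[gwas_mod.PanelDef]:
    """Panels derived from subpopulation labels: the full collection, each
    sufficiently large pure subpopulation, and the two subspecies-style
    groupings (IND+AUS and TEJ+TRJ, each including their admixtures)."""
    pcs = dict(gwas_mod.DEFAULT_PANEL_PCS, **(pcs or {}))
    panels = [gwas_mod.PanelDef("All", list(accessions), pcs.get("All", 3))]

    def parents(label: str) -> set[str]:
        if label.startswith("ADM:"):
            return set(label[4:].split("/"))
        return {label}

    pure = sorted({s for s in subpops.values() if not s.startswith("ADM:")})
    for sp in pure:
        members = [a for a in accessions if subpops.get(a) == sp]
        if len(members) >= min_size:
            panels.append(gwas_mod.PanelDef(sp, members, pcs.get(sp, 0)))
    for name, group in (("INDAUS", {"IND", "AUS"}), ("JAP", {"TEJ", "TRJ"})):
        members = [a for a in accessions if parents(subpops.get(a, "")) <= group]
        if len(members) >= min_size:
            panels.append(gwas_mod.PanelDef(name, members, pcs.get(name, 0)))
    return panels


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the artifact directory.

    Raises ``RuntimeError`` naming the failing stage on any error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, outdir)
    logger.info("effective config: %s", config.to_dict())
    seed = config.seed

    genotypes, phenos, subpop_map = _stage("simulate_or_load")(_load_inputs)(config, outdir)

    traits = config.traits or list(dict.fromkeys(phenos["trait"]))
    tm = _stage("pheno")(_pheno_stage)(config, outdir, phenos, traits)

    assoc_by_trait = _stage("gwas")(_gwas_stage)(config, outdir, genotypes, subpop_map, tm)

    qtls_by_trait = _stage("regions")(_regions_stage)(config, outdir, assoc_by_trait)

    colocs = _stage("coloc")(_coloc_stage)(config, outdir, qtls_by_trait)

    _stage("pivot")(_pivot_stage)(config, outdir, qtls_by_trait, genotypes, tm)

    _stage("annotate")(_annotate_stage)(config, outdir, qtls_by_trait)

    _stage("bn")(_bn_stage)(config, outdir, tm)

    # combined report
    all_qtls = [q for qs in qtls_by_trait.values() for q in qs]
    io_mod.write_qtl_report(all_qtls, colocs, outdir / "qtl_report.tsv",
                            bed_path=outdir / "qtl_regions.bed", seed=seed)
    logger.info("pipeline complete: %s", outdir)
    return outdir


def _setup_logging(config: PipelineConfig, outdir: Path) -> None:
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    logger.handlers = []
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(outdir / "pipeline.log", mode="w")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        overrides = dict(config.simulate)
        n_qtl = overrides.pop("n_qtl_per_trait", 2)
        panel_cfg = sim.default_config(seed=config.seed, **overrides)
        genotypes = sim.simulate_genotypes(panel_cfg)
        truth = sim.default_truth(genotypes, seed=config.seed, n_qtl_per_trait=n_qtl)
        phenos = sim.simulate_traits(genotypes, truth, seed=config.seed)
        subpop_map = dict(zip(genotypes.accessions, genotypes.subpops))
        io_mod.write_hapmap(genotypes, outdir / "genotypes.hmp.txt", seed=config.seed)
        io_mod.write_vcf(genotypes, outdir / "genotypes.vcf", seed=config.seed)
        io_mod.write_phenotypes(phenos, outdir / "phenotypes.tsv", seed=config.seed)
        io_mod.write_subpops(subpop_map, outdir / "subpops.tsv")
        sim.write_truth(truth, outdir / "truth.json")
        return genotypes, phenos, subpop_map

    if not (config.genotypes and config.phenotypes):
        raise ValueError("config needs either a 'simulate' stanza or genotype+phenotype paths")
    gpath = str(config.genotypes)
    if gpath.endswith(".vcf"):
        genotypes = io_mod.read_vcf(gpath)
    else:
        genotypes = io_mod.read_hapmap(gpath)
    phenos = io_mod.read_phenotypes(config.phenotypes)
    subpop_map = io_mod.read_subpops(config.subpops) if config.subpops else {
        a: "NA" for a in genotypes.accessions
    }
    genotypes.subpops = [subpop_map.get(a, "NA") for a in genotypes.accessions]
    return genotypes, phenos, subpop_map


def _pheno_stage(config, outdir, phenos, traits):
    tm = ph.blup_matrix(phenos, traits=traits, log_traits=config.log_traits)
    io_mod.write_trait_matrix(tm, outdir / "trait_blups.tsv", seed=config.seed)
    r_mat, p_mat = ph.correlation_matrix(tm)
    r_mat.to_csv(outdir / "trait_correlations.tsv", sep="\t")
    p_mat.to_csv(outdir / "trait_correlation_p.tsv", sep="\t")
    return tm


def _gwas_stage(config, outdir, genotypes, subpop_map, tm):
    if config.panels:
        panels = []
        for p in config.panels:
            members = p.get("members")
            if members is None:
                wanted = set(p["subpops"])
                members = [a for a in genotypes.accessions if subpop_map.get(a) in wanted]
            panels.append(gwas_mod.PanelDef(p["name"], members, int(p.get("n_pcs", 0))))
    else:
        panels = standard_panels(genotypes.accessions, subpop_map)

    thr = config.thresholds
    assoc_by_trait: dict[str, dict[str, list[gwas_mod.AssocRecord]]] = {}
    all_records = []
    for panel in panels:
        Gp = gwas_mod.subset_panel(genotypes, panel, thr.min_alt_carriers)
        K = gwas_mod.centered_kinship(Gp)
        covs = gwas_mod.genotype_pca(Gp, panel.n_pcs)
        for trait in tm.traits:
            y = tm.values[trait].reindex(Gp.accessions).to_numpy()
            recs = gwas_mod.mlm_scan(Gp, y, K, covariates=covs, stat=config.stat,
                                     trait=trait, panel=panel.name)
            assoc_by_trait.setdefault(trait, {})[panel.name] = recs
            all_records.extend(recs)
            logger.info("gwas: panel=%s trait=%s snps=%d", panel.name, trait, len(recs))
    sig = [r for r in all_records if r.minus_log10_p > thr.sig]
    io_mod.write_assoc(sig, outdir / "assoc_significant.tsv", seed=config.seed)
    return assoc_by_trait


def _regions_stage(config, outdir, assoc_by_trait):
    thr = config.thresholds
    qtls_by_trait = {}
    for trait, by_panel in assoc_by_trait.items():
        clusters = []
        for panel_name, recs in sorted(by_panel.items()):
            cls = reg.call_clusters(recs, threshold=thr.sig, extend=thr.extend,
                                    flank=thr.flank, trait=trait, panel=panel_name)
            reg.apply_stringency(cls, min_snps=thr.min_snps,
                                 min_alt_carriers=thr.min_alt_carriers)
            clusters.extend(cls)
        qtls = reg.merge_panels(clusters, merge_gap=thr.merge_gap, flank=thr.flank)
        reg.assign_names(qtls, trait_symbol=trait)
        qtls_by_trait[trait] = qtls
        logger.info("regions: trait=%s clusters=%d qtls=%d", trait, len(clusters), len(qtls))
    return qtls_by_trait


def _coloc_stage(config, outdir, qtls_by_trait):
    pairs = []
    traits = sorted(qtls_by_trait)
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            pairs.extend(reg.coloc(qtls_by_trait[a], qtls_by_trait[b],
                                   end_gap=config.thresholds.coloc_gap))
    io_mod.write_coloc(pairs, outdir / "coloc_pairs.tsv", seed=config.seed)
    return pairs


def _pivot_stage(config, outdir, qtls_by_trait, genotypes, tm):
    frames = []
    for trait, qtls in sorted(qtls_by_trait.items()):
        for q in qtls:
            peak = q.peak
            try:
                genotypes.snp_index(peak.snp)
            except KeyError:
                continue
            table = reg.pivot_allele_effects(peak, genotypes, tm,
                                             [trait] + [t for t in tm.traits if t != trait])
            table = table.reset_index()
            table.insert(0, "qtl", q.name)
            table.insert(1, "peak_snp", peak.snp)
            frames.append(table)
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(outdir / "pivot_tables.tsv",
                                                    sep="\t", index=False)
    else:
        pd.DataFrame(columns=["qtl", "peak_snp", "trait", "mean_common", "mean_alt",
                              "diff", "sign", "estimable", "concordant"]).to_csv(
            outdir / "pivot_tables.tsv", sep="\t", index=False)


def _annotate_stage(config, outdir, qtls_by_trait):
    if not config.annotations:
        logger.warning("annotate: no annotation path configured; stage skipped")
        return
    path = str(config.annotations)
    genes = io_mod.read_gff3(path) if path.endswith((".gff", ".gff3")) \
        else io_mod.read_gene_table(path)
    all_qtls = [q for qs in qtls_by_trait.values() for q in qs]
    table = reg.genes_near(all_qtls, genes, window=config.thresholds.gene_window)
    table.to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False)


def _bn_stage(config, outdir, tm):
    opts = dict(config.bn)
    stages = opts.pop("stages", None)
    if stages is None:
        stages = _default_stages(tm.traits)
    bl = bn_mod.stage_blacklist({t: int(s) for t, s in stages.items() if t in tm.traits})
    cfg = bn_mod.BnConfig(seed=config.seed, **{
        k: v for k, v in opts.items()
        if k in ("alpha", "folds", "validation_size", "restarts")
    })
    if cfg.validation_size is not None:
        cfg.validation_size = min(cfg.validation_size, max(1, len(tm.values) // 3))
    dag, report = bn_mod.cv_learn(tm, config=cfg, blacklist=bl)
    io_mod.write_dag_tsv(dag, outdir / "trait_dag.tsv", seed=config.seed)
    io_mod.write_dag_dot(dag, outdir / "trait_dag.dot")
    io_mod.write_blacklist(bl, outdir / "bn_blacklist.tsv")
    report.to_csv(outdir / "bn_cv_report.tsv", sep="\t", index=False)
    return dag


_ELEMENT_TRAITS = {"Si", "As", "P", "S", "Ca", "Cu"}


def _default_stages(traits) -> dict[str, int]:
    """Development (0) -> element concentrations (1) -> disease severity (2)."""
    stages = {}
    for t in traits:
        base = t.rstrip("ntms")  # tolerate env-suffixed names like DHDnt / StHDms
        if t.startswith(("DHD", "PHT")):
            stages[t] = 0
        elif t in _ELEMENT_TRAITS or base in _ELEMENT_TRAITS:
            stages[t] = 1
        else:
            stages[t] = 2
    return stages
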