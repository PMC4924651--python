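"""End-to-end orchestration: config, stage execution, manifest.

The pipeline chains the analysis stages — (optional) simulate, expression
filter, fold-change ranking, cross-species concordance, GP time-shift
comparison, joint clustering, SNP/functional enrichment, co-localization,
lncRNA profiling — writing one TSV per stage plus a JSON run manifest
(config hash, seed, package version, per-stage row counts).  A single
global seed fans out to per-stage seeds by hashing the stage name, so
toggling one stage never perturbs another's randomness.  Any stage failure
halts the run with the stage name and cause.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from . import io as okio
from .coloc import circos_export, find_clusters, permutation_pvalues
from .de import (build_ranked_sets, call_de, cluster_profiles_kmeans,
                 concordant_pairs, correlate_ortholog_expression,
                 filter_expressed)
from .enrich import GeneSetSpec, enrich_gene_sets_vs_traits, hypergeom_enrich, link_snps_to_genes
from .gp import compare_orthologs, default_dt_grid
from .lncrna import (biotype_representation, de_lncrnas, lnc_expression_sets,
                     nearest_coding_gene, top_correlated_coding)
from .simulate import (simulate_de_tables, simulate_expression_matrix,
                       simulate_genome_annotation, simulate_ortholog_timecourse,
                       simulate_snp_catalog)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stage_seed"]

STAGE_ORDER = ["simulate", "filter", "rank", "concord", "gp", "cluster",
               "enrich", "coloc", "lncrna"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    expression_human: str | None = None
    expression_mouse: str | None = None
    de_human: str | None = None
    de_mouse: str | None = None
    orthologs: str | None = None
    annotation_human: str | None = None
    annotation_mouse: str | None = None
    snps: str | None = None
    term_map: str | None = None
    lnc_expression: str | None = None
    lnc_de: str | None = None


class StagesConfig(_Strict):
    simulate: bool = True
    filter: bool = True
    rank: bool = True
    concord: bool = True
    gp: bool = True
    cluster: bool = True
    enrich: bool = True
    coloc: bool = True
    lncrna: bool = True


class ParamsConfig(_Strict):
    """Numeric knobs; defaults follow the study's published cutoffs."""

    fdr: float = Field(0.05, gt=0, le=1)
    fc: float = Field(1.0, ge=0)
    fc_floor: float = Field(0.3, ge=0)
    fraction: float = Field(0.2, gt=0, le=1)
    k: int = Field(30, ge=2)
    cluster_restarts: int = Field(10, ge=1)
    window: int = Field(100_000, gt=0)
    snp_p: float = Field(1e-5, gt=0, lt=1)
    d: int = Field(3, ge=0)
    n_perm: int = Field(1000, ge=100)
    bf_threshold: float = Field(10.0, gt=0)
    dt_step: float = Field(2.0, gt=0, le=48)
    rpkm_coding: float = Field(3.0, gt=0)
    rpkm_lnc: float = Field(0.5, gt=0)
    min_replicates: int = Field(2, ge=1)
    gp_max_pairs: int | None = Field(12, ge=1)
    gp_restarts: int = Field(2, ge=1)
    lnc_top_n: int = Field(5, ge=1)


class SimulateConfig(_Strict):
    """Synthetic-cohort shape; defaults mirror the study design (10 time
    points, 3 replicates) at desk scale."""

    n_pairs: int = Field(60, gt=0)
    frac_shared: float = Field(0.5, ge=0, le=1)
    frac_shifted: float = Field(0.25, ge=0, le=1)
    shift_set: list[float] = [-12.0, -6.0, 6.0, 12.0]
    noise_sd: float = Field(0.2, ge=0)
    n_replicates: int = Field(3, ge=2)
    n_chromosomes: int = Field(3, gt=0)
    genes_per_chromosome: int = Field(150, gt=0)
    gene_length: int = Field(1000, gt=0)
    spacing: int = Field(50_000, gt=0)
    frac_coding: float = Field(0.70, gt=0, le=1)
    frac_lincrna: float = Field(0.12, ge=0, le=1)
    frac_antisense: float = Field(0.12, ge=0, le=1)
    frac_sense_intronic: float = Field(0.06, ge=0, le=1)
    n_de_pairs: int = Field(40, ge=0)
    snps_per_trait: int = Field(8, ge=0)
    background_snps: int = Field(40, ge=0)
    lnc_frac_silent: float = Field(0.15, ge=0, le=1)


class PipelineConfig(_Strict):
    seed: int = 0
    paths: PathsConfig = PathsConfig()
    stages: StagesConfig = StagesConfig()
    params: ParamsConfig = ParamsConfig()
    simulate: SimulateConfig = SimulateConfig()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: stable hash of the stage name mixed with the seed."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _write_gene_list(genes, path):
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def _read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# Simulate stage: manufacture a coherent input cohort


def _simulate_inputs(cfg: PipelineConfig, indir: Path) -> PathsConfig:
    sim = cfg.simulate
    seed = stage_seed(cfg.seed, "simulate")
    fractions = {
        "coding": sim.frac_coding,
        "lincRNA": sim.frac_lincrna,
        "antisense": sim.frac_antisense,
        "sense_intronic": sim.frac_sense_intronic,
    }
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"biotype fractions must sum to 1, got {total}")
    ann = simulate_genome_annotation(
        n_chromosomes=sim.n_chromosomes,
        genes_per_chromosome=sim.genes_per_chromosome,
        gene_length=sim.gene_length,
        spacing=sim.spacing,
        biotype_fractions=fractions,
        gene_prefix="hs",
        seed=seed,
    )
    coding_ids = ann.loc[ann["biotype"] == "coding", "gene_id"].tolist()
    lnc_ids = ann.loc[ann["biotype"] != "coding", "gene_id"].tolist()
    if sim.n_pairs > len(coding_ids):
        raise ValueError(
            f"n_pairs={sim.n_pairs} exceeds coding genes ({len(coding_ids)})"
        )

    human, mouse, ortho, truths = simulate_ortholog_timecourse(
        n_pairs=sim.n_pairs,
        frac_shared=sim.frac_shared,
        frac_shifted=sim.frac_shifted,
        shift_set=tuple(sim.shift_set),
        noise_sd=sim.noise_sd,
        n_replicates=sim.n_replicates,
        seed=seed + 1,
    )
    # relabel the pair genes onto annotated human coding genes (and mm_*
    # mouse counterparts) so every downstream join is coherent
    h_map = dict(zip(human.gene_ids, coding_ids[:sim.n_pairs]))
    m_map = {m: "mm_" + h_map[h][2:]
             for h, m in zip(human.gene_ids, mouse.gene_ids)}
    human.values.index = pd.Index([h_map[g] for g in human.gene_ids],
                                  name="gene_id")
    mouse.values.index = pd.Index([m_map[g] for g in mouse.gene_ids],
                                  name="gene_id")
    ortho = pd.DataFrame({
        "human_gene": [h_map[h] for h in ortho["human_gene"]],
        "mouse_gene": [m_map[m] for m in ortho["mouse_gene"]],
    })

    # planted DE: alternating up/down pairs, human hit at 72 h, mouse at
    # 48 h (different time points exercise the merged-set concordance)
    timepoints = human.timepoints
    n_de = min(sim.n_de_pairs, sim.n_pairs)
    planted_h: dict[float, list] = {72.0: [], 4.0: []}
    planted_m: dict[float, list] = {48.0: [], 4.0: []}
    rngfc = np.random.default_rng(seed + 2)
    for i in range(n_de):
        hgene = ortho["human_gene"].iloc[i]
        mgene = ortho["mouse_gene"].iloc[i]
        direction = "up" if i % 2 == 0 else "down"
        fc = 1.2 + 0.08 * i + rngfc.uniform(0, 0.04)
        planted_h[72.0].append((hgene, direction, fc))
        planted_m[48.0].append((mgene, direction, fc))
        if i % 5 == 0:  # a few early responders
            planted_h[4.0].append((hgene, direction, fc * 0.8))
            planted_m[4.0].append((mgene, direction, fc * 0.8))
    de_h = simulate_de_tables(
        n_genes=0, timepoints=timepoints, planted_top=planted_h,
        gene_ids=list(human.gene_ids), seed=seed + 3,
    )
    de_m = simulate_de_tables(
        n_genes=0, timepoints=timepoints, planted_top=planted_m,
        gene_ids=list(mouse.gene_ids), seed=seed + 4,
    )

    # SNP catalog: one trait planted on concordant-by-construction genes,
    # background SNPs diluting every trait
    traits = ["trait_planted", "trait_null_a", "trait_null_b"]
    target_genes = [ortho["human_gene"].iloc[i] for i in range(0, n_de, 2)][:5]
    snps = simulate_snp_catalog(
        annotation=ann, traits=traits,
        planted={"trait_planted": target_genes} if target_genes else {},
        snps_per_trait=sim.snps_per_trait,
        window=cfg.params.window,
        background_snps=sim.background_snps,
        seed=seed + 5,
    )

    # functional classes over human coding genes, round-robin
    classes = ["kinase", "cytokine", "transcription_regulator"]
    term_map = {c: set() for c in classes}
    for i, g in enumerate(coding_ids):
        term_map[classes[i % len(classes)]].add(g)

    # lncRNA cohort: expression with a silent fraction, DE skewed so that
    # antisense lncRNAs dominate the differential calls
    lnc_expr = simulate_expression_matrix(
        lnc_ids, species="human", n_replicates=sim.n_replicates,
        noise_sd=sim.noise_sd, baseline=4.0,
        frac_silent=sim.lnc_frac_silent, seed=seed + 6,
    )
    biotype = ann.set_index("gene_id")["biotype"]
    rng = np.random.default_rng(seed + 7)
    planted_lnc: dict[float, list] = {24.0: []}
    for g in lnc_ids:
        bt = biotype[g]
        p_de = {"antisense": 0.7, "sense_intronic": 0.6, "lincRNA": 0.08}[bt]
        if rng.random() < p_de:
            planted_lnc[24.0].append(
                (g, "up" if rng.random() < 0.5 else "down",
                 1.5 + rng.uniform(0, 1.5))
            )
    lnc_de = simulate_de_tables(
        n_genes=0, timepoints=timepoints, planted_top=planted_lnc,
        gene_ids=lnc_ids, seed=seed + 8,
    )

    paths = PathsConfig(
        expression_human=str(indir / "expression_human.tsv"),
        expression_mouse=str(indir / "expression_mouse.tsv"),
        de_human=str(indir / "de_human.tsv"),
        de_mouse=str(indir / "de_mouse.tsv"),
        orthologs=str(indir / "orthologs.tsv"),
        annotation_human=str(indir / "annotation_human.tsv"),
        snps=str(indir / "snps.tsv"),
        term_map=str(indir / "term_map.tsv"),
        lnc_expression=str(indir / "lnc_expression.tsv"),
        lnc_de=str(indir / "lnc_de.tsv"),
    )
    okio.write_expression_tsv(human, paths.expression_human)
    okio.write_expression_tsv(mouse, paths.expression_mouse)
    okio.write_de_table(de_h, paths.de_human)
    okio.write_de_table(de_m, paths.de_mouse)
    okio.write_ortholog_map(ortho, paths.orthologs)
    okio.write_annotation_tsv(ann, paths.annotation_human)
    okio.write_snp_table(snps, paths.snps)
    okio.write_term_map(term_map, paths.term_map)
    okio.write_expression_tsv(lnc_expr, paths.lnc_expression)
    okio.write_de_table(lnc_de, paths.lnc_de)
    truth_df = pd.DataFrame(
        [(t.pair_id, t.klass, t.true_shift_hours) for t in truths],
        columns=["pair_id", "class", "true_shift_hours"],
    )
    truth_df.to_csv(indir / "sim_truth.tsv", sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------


def _require(paths: PathsConfig, *names):
    missing = [n for n in names if getattr(paths, n) is None]
    if missing:
        raise ValueError(f"missing required input path(s): {missing}")
    for n in names:
        p = Path(getattr(paths, n))
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages; returns the manifest dict.

    Outputs go under ``outdir`` (one TSV per stage, inputs under
    ``outdir/inputs`` when simulating, manifest at ``outdir/manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict] = {}
    paths = config.paths
    P = config.params
    state: dict = {}

    def run_stage(name, fn):
        if not getattr(config.stages, name):
            return
        try:
            counts[name] = fn() or {}
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    # -- simulate ----------------------------------------------------------
    def do_simulate():
        nonlocal paths
        indir = outdir / "inputs"
        indir.mkdir(exist_ok=True)
        paths = _simulate_inputs(config, indir)
        return {"files": len([f for f in indir.iterdir()])}

    run_stage("simulate", do_simulate)

    # -- filter ------------------------------------------------------------
    def do_filter():
        _require(paths, "expression_human", "expression_mouse")
        mh = okio.read_expression_tsv(paths.expression_human, species="human")
        mm = okio.read_expression_tsv(paths.expression_mouse, species="mouse")
        state["matrix_h"], state["matrix_m"] = mh, mm
        eh = filter_expressed(mh, P.rpkm_coding, P.min_replicates)
        em = filter_expressed(mm, P.rpkm_coding, P.min_replicates)
        state["expressed_h"], state["expressed_m"] = eh, em
        _write_gene_list(eh, outdir / "expressed_human.txt")
        _write_gene_list(em, outdir / "expressed_mouse.txt")
        return {"expressed_human": len(eh), "expressed_mouse": len(em)}

    run_stage("filter", do_filter)

    # -- rank --------------------------------------------------------------
    def do_rank():
        _require(paths, "de_human", "de_mouse")
        de_h = okio.read_de_table(paths.de_human)
        de_m = okio.read_de_table(paths.de_mouse)
        if "expressed_h" in state:
            de_h = de_h[de_h["gene_id"].isin(state["expressed_h"])]
            de_m = de_m[de_m["gene_id"].isin(state["expressed_m"])]
        state["de_h"], state["de_m"] = de_h, de_m
        rh = build_ranked_sets(de_h, "human", P.fdr, P.fc_floor, P.fraction)
        rm = build_ranked_sets(de_m, "mouse", P.fdr, P.fc_floor, P.fraction)
        state["ranked_h"], state["ranked_m"] = rh, rm
        table = pd.concat([rh.to_frame(), rm.to_frame()], ignore_index=True)
        table.to_csv(outdir / "ranked_sets.tsv", sep="\t", index=False)
        return {"rows": len(table)}

    run_stage("rank", do_rank)

    # -- concord -----------------------------------------------------------
    def do_concord():
        _require(paths, "orthologs")
        ortho = okio.read_ortholog_map(paths.orthologs)
        state["ortho"] = ortho
        conc = concordant_pairs(state["ranked_h"], state["ranked_m"], ortho)
        state["concordant"] = conc
        conc.to_csv(outdir / "concordant_pairs.tsv", sep="\t", index=False)
        if "matrix_h" in state and len(conc):
            corr = correlate_ortholog_expression(
                state["matrix_h"], state["matrix_m"],
                conc.drop_duplicates(["human_gene", "mouse_gene"]),
            )
            corr.to_csv(outdir / "ortholog_correlation.tsv", sep="\t",
                        index=False)
        return {"pairs": len(conc)}

    run_stage("concord", do_concord)

    # -- gp ----------------------------------------------------------------
    def do_gp():
        _require(paths, "expression_human", "expression_mouse", "orthologs")
        mh = state.get("matrix_h") or okio.read_expression_tsv(
            paths.expression_human, species="human")
        mm = state.get("matrix_m") or okio.read_expression_tsv(
            paths.expression_mouse, species="mouse")
        ortho = state.get("ortho")
        if ortho is None:
            ortho = okio.read_ortholog_map(paths.orthologs)
        conc = state.get("concordant")
        if conc is not None and len(conc):
            keep = set(conc["human_gene"])
            ortho = ortho[ortho["human_gene"].isin(keep)]
        bf = compare_orthologs(
            mh, mm, ortho,
            dt_grid=default_dt_grid(P.dt_step),
            restarts=P.gp_restarts,
            seed=stage_seed(config.seed, "gp"),
            bf_threshold=P.bf_threshold,
            max_pairs=P.gp_max_pairs,
        )
        bf.to_csv(outdir / "bayes_factors.tsv", sep="\t", index=False)
        return {"pairs": len(bf),
                "shared_calls": int((bf["call"] == "shared").sum())}

    run_stage("gp", do_gp)

    # -- cluster -----------------------------------------------------------
    def do_cluster():
        de_genes_h = set(call_de(state["de_h"], P.fdr, P.fc)["gene_id"])
        de_genes_m = set(call_de(state["de_m"], P.fdr, P.fc)["gene_id"])
        assignments, co = cluster_profiles_kmeans(
            state["matrix_h"], state["matrix_m"],
            sorted(de_genes_h), sorted(de_genes_m), state["ortho"],
            k=P.k, restarts=P.cluster_restarts,
            seed=stage_seed(config.seed, "cluster"),
        )
        assignments.to_csv(outdir / "cluster_assignments.tsv", sep="\t",
                           index=False)
        co.to_csv(outdir / "co_clustered_pairs.tsv", sep="\t", index=False)
        return {"genes": len(assignments), "co_clustered_pairs": len(co)}

    run_stage("cluster", do_cluster)

    # -- enrich ------------------------------------------------------------
    def do_enrich():
        _require(paths, "snps", "annotation_human")
        snps = okio.read_snp_table(paths.snps)
        ann = okio.read_annotation(paths.annotation_human, format="tsv")
        trait_map = link_snps_to_genes(snps, ann, P.window, P.snp_p)
        ortho = state["ortho"]
        conc = state.get("concordant")
        common = frozenset(conc["human_gene"]) if conc is not None else frozenset()
        top_h = frozenset(state["ranked_h"].all_genes())
        top_m = frozenset(state["ranked_m"].all_genes())
        all_h = frozenset(state["de_h"]["gene_id"])
        ortho_h = frozenset(ortho["human_gene"])
        ortho_m = frozenset(ortho["mouse_gene"])
        sets = {
            "common": GeneSetSpec(common & ortho_h, ortho_h),
            "human_top20": GeneSetSpec(top_h & all_h, all_h),
            "mouse_top20": GeneSetSpec(top_m & ortho_m, ortho_m,
                                       map_to_human=True),
        }
        results = enrich_gene_sets_vs_traits(sets, trait_map, ortho)
        n_rows = 0
        for name, df in results.items():
            df.insert(0, "gene_set", name)
            n_rows += len(df)
        table = pd.concat(results.values(), ignore_index=True)
        table.to_csv(outdir / "trait_enrichment.tsv", sep="\t", index=False)
        out = {"trait_tests": n_rows}
        if paths.term_map:
            terms = okio.read_term_map(paths.term_map)
            func = hypergeom_enrich(set(top_h & all_h), terms, set(all_h))
            func.to_csv(outdir / "functional_enrichment.tsv", sep="\t",
                        index=False)
            out["functional_tests"] = len(func)
        return out

    run_stage("enrich", do_enrich)

    # -- coloc -------------------------------------------------------------
    def do_coloc():
        _require(paths, "annotation_human")
        ann = okio.read_annotation(paths.annotation_human, format="tsv")
        conc = state.get("concordant")
        query = set(conc["human_gene"]) if conc is not None else set()
        query &= set(ann["gene_id"])
        res = permutation_pvalues(
            query, ann, d=P.d, n_perm=P.n_perm,
            seed=stage_seed(config.seed, "coloc"),
        )
        res.cluster_table().to_csv(outdir / "colocalization.tsv", sep="\t",
                                   index=False)
        circos_export(res.clusters, ann).to_csv(
            outdir / "colocalization_circos.tsv", sep="\t", index=False)
        return {"clusters": res.global_count, "global_p": res.global_p}

    run_stage("coloc", do_coloc)

    # -- lncrna ------------------------------------------------------------
    def do_lncrna():
        _require(paths, "lnc_expression", "lnc_de", "annotation_human")
        lnc = okio.read_expression_tsv(paths.lnc_expression)
        ann = okio.read_annotation(paths.annotation_human, format="tsv")
        lnc_de_table = okio.read_de_table(paths.lnc_de)
        t0 = lnc.timepoints[0]
        pre = lnc.subset_times([t0])
        post = lnc.subset_times(lnc.timepoints[1:])
        before, after = lnc_expression_sets(pre, post, P.rpkm_lnc,
                                            P.min_replicates)
        de_set = de_lncrnas(lnc_de_table, after, P.fdr, P.fc)
        _write_gene_list(after, outdir / "lnc_expressed_after.txt")
        _write_gene_list(de_set, outdir / "lnc_de.txt")
        out = {"expressed_before": len(before), "expressed_after": len(after),
               "de_lncrnas": len(de_set)}
        if de_set:
            stats = biotype_representation(de_set, after, ann)
            pd.DataFrame([s.__dict__ for s in stats]).to_csv(
                outdir / "lnc_biotype_stats.tsv", sep="\t", index=False)
            nearest = []
            for g in sorted(de_set):
                hit = nearest_coding_gene(g, ann)
                if hit is not None:
                    nearest.append((g, hit[0], hit[1]))
            pd.DataFrame(nearest, columns=["lnc_gene", "coding_gene",
                                           "distance_bp"]).to_csv(
                outdir / "lnc_nearest_coding.tsv", sep="\t", index=False)
            if "matrix_h" in state and "de_h" in state:
                de_coding = set(call_de(state["de_h"], P.fdr, P.fc)["gene_id"])
                corr = top_correlated_coding(
                    lnc, state["matrix_h"], sorted(de_set),
                    sorted(de_coding), top_n=P.lnc_top_n)
                corr.to_csv(outdir / "lnc_coding_correlation.tsv", sep="\t",
                            index=False)
                out["correlation_rows"] = len(corr)
        return out

    run_stage("lncrna", do_lncrna)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages_run": [s for s in STAGE_ORDER if s in counts],
        "stage_counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
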