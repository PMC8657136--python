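"""End-to-end orchestration: simulate -> de -> cluster -> ebox -> sets -> gsea.

One :class:`RunConfig` (constructible from YAML) drives the whole run; every
stage can be toggled so real count tables can replace the simulator. The run
summary records per-stage counts, a checksum manifest of every written file,
the seed and the config echo, so reruns with an identical config are
verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from . import cluster as cluster_mod
from . import de as de_mod
from . import gsea as gsea_mod
from . import motif as motif_mod
from . import sets as sets_mod
from .synthetic import SimulationConfig, simulate

log = logging.getLogger("dosegrade")

DEFAULT_STAGES = ("simulate", "de", "cluster", "ebox", "sets", "gsea")


@dataclass
class RunConfig:
    """Thresholds, stage toggles and I/O paths for a pipeline run."""

    seed: int = 0
    outdir: str = "dosegrade_run"
    stages: dict = field(default_factory=lambda: {s: True for s in DEFAULT_STAGES})
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # inputs for real-data runs (used when the simulate stage is off)
    counts_path: str | None = None
    design_path: str | None = None
    genome_path: str | None = None
    genes_bed_path: str | None = None
    gmt_path: str | None = None
    external_list_path: str | None = None
    ortholog_map_path: str | None = None
    # thresholds
    cpm_min: float = 0.95
    cpm_min_samples: int = 3
    q_max: float = 0.01
    min_fold: float = 2.0
    k: int = 12
    ebox_window: int = 1000
    resample_B: int = 1000
    ora_fdr: float = 0.1
    gsea_padj: float = 0.05
    gsea_abs_nes: float = 1.7
    gsea_n_perm: int = 1000
    gsea_min_size: int = 5

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        stages = {s: True for s in DEFAULT_STAGES}
        stages.update(raw.pop("stages", {}))
        cfg = cls(simulation=sim, stages=stages,
                  **{k: v for k, v in raw.items()})
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: str, **kw) -> str:
    df.to_csv(path, sep="\t", float_format="%.6g", **kw)
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the summary.

    Any stage failure raises with the stage name; a partial manifest of the
    files written so far is attached to the exception.
    """
    import numpy as np

    os.makedirs(config.outdir, exist_ok=True)
    written: list[str] = []
    counts_summary: dict = {}
    stage = "setup"
    st = config.stages

    try:
        # ---------------- simulate / load ----------------
        stage = "synthetic_data"
        annotation = gene_sets = genome = None
        if st.get("simulate", True):
            sim_cfg = dataclasses.replace(config.simulation, rng_seed=config.seed)
            data = simulate(sim_cfg, with_genome=st.get("ebox", True),
                            with_sets=st.get("sets", True) or st.get("gsea", True))
            written += data.write(config.outdir)
            counts, design = data.counts, data.design
            annotation, genome = data.annotation, data.genome
            gene_sets = data.gene_sets
            lengths = (annotation.set_index("gene_id")["length_bp"]
                       if annotation is not None
                       else data.truth.set_index("gene_id")["length_bp"])
            counts_summary["n_genes_simulated"] = len(counts)
        else:
            if not config.counts_path or not config.design_path:
                raise FileNotFoundError(
                    "dose_response_de requires counts_path and design_path when "
                    "the simulate stage is disabled")
            counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
            design = pd.read_csv(config.design_path, sep="\t")
            if config.genes_bed_path:
                annotation = motif_mod.read_bed6(config.genes_bed_path)
                lengths = annotation.set_index("gene_id")["length_bp"]
            else:
                lengths = pd.Series(1000.0, index=counts.index)
            if config.gmt_path:
                gene_sets = sets_mod.read_gmt(config.gmt_path)
        counts_summary["n_samples"] = counts.shape[1]

        # ---------------- differential expression ----------------
        de_result = flags = None
        rpkm = None
        libsizes = counts.sum(axis=0)
        if st.get("de", True):
            stage = "dose_response_de"
            de_result = de_mod.run_de(
                counts, design, library_sizes=libsizes,
                min_cpm=config.cpm_min, min_samples=config.cpm_min_samples,
                q_max=config.q_max, min_fold=config.min_fold)
            res = de_result.results
            flags = res[["regulated_wt", "diff_t58a", "diff_t58i"]]
            written.append(_write(res, os.path.join(config.outdir, "de_results.tsv"),
                                  index_label="gene_id"))
            fitted = de_result.fitted_cpm.copy()
            fitted.columns = [f"{g}_d{int(d)}" for g, d in fitted.columns]
            written.append(_write(fitted,
                                  os.path.join(config.outdir, "fitted_means.tsv"),
                                  index_label="gene_id"))
            counts_summary.update({
                "n_genes_filtered": len(de_result.filtered_genes),
                "n_regulated_wt": int(res["regulated_wt"].sum()),
                "n_diff_t58a": int(res["diff_t58a"].sum()),
                "n_diff_t58i": int(res["diff_t58i"].sum()),
            })
            rpkm = de_mod.compute_rpkm(counts.loc[de_result.filtered_genes],
                                       lengths, libsizes)

        # ---------------- clustering ----------------
        assignments = None
        if st.get("cluster", True):
            stage = "cluster_profile"
            if de_result is None:
                raise RuntimeError("cluster_profile requires the de stage")
            selected = flags.index[flags.any(axis=1)]
            counts_summary["n_selected_union"] = len(selected)
            profiles = cluster_mod.build_profile_matrix(rpkm, design, selected)
            k = min(config.k, len(profiles))
            assignments, Z = cluster_mod.hierarchical_cluster(profiles, k=k)
            counts_summary["n_clusters"] = int(assignments.nunique())
            written.append(_write(assignments.to_frame(),
                                  os.path.join(config.outdir, "clusters.tsv"),
                                  index_label="gene_id"))
            newick = cluster_mod.dendrogram_newick(Z, profiles.index)
            nwk_path = os.path.join(config.outdir, "dendrogram.nwk")
            with open(nwk_path, "w") as fh:
                fh.write(newick + "\n")
            written.append(nwk_path)

        # ---------------- E-box proximity ----------------
        distances = None
        if st.get("ebox", True):
            stage = "motif_proximity"
            if genome is None:
                if not config.genome_path:
                    raise FileNotFoundError(
                        "motif_proximity requires a genome FASTA "
                        "(genome_path) when simulation is disabled")
                genome = motif_mod.load_fasta(config.genome_path)
            if annotation is None:
                raise FileNotFoundError(
                    "motif_proximity requires a gene annotation (genes_bed_path)")
            hits = motif_mod.scan_motif(genome)
            tss = motif_mod.annotation_to_tss(annotation)
            distances = motif_mod.gene_min_distance(hits, tss,
                                                    window=config.ebox_window)
            counts_summary["n_ebox_hits"] = len(hits)
            counts_summary["n_ebox_alignments"] = motif_mod.alignment_count(hits)
            written.append(_write(distances,
                                  os.path.join(config.outdir, "gene_distances.tsv"),
                                  index=False))
            bed_path = os.path.join(config.outdir, "eboxes.bed")
            motif_mod.write_bed6_hits(hits, bed_path)
            written.append(bed_path)

        # cluster characterization needs clustering (+ optionally distances)
        if assignments is not None and annotation is not None:
            stage = "cluster_profile"
            bg = de_result.filtered_genes.difference(
                flags.index[flags.any(axis=1)])
            if distances is None:
                distances = pd.DataFrame({"gene_id": [], "min_distance": [],
                                          "ebox_within_1kb": []})
            rng = np.random.default_rng(config.seed + 1)
            table = cluster_mod.build_cluster_table(
                assignments, rpkm, design, annotation, distances, bg,
                B=config.resample_B, rng=rng, ebox_window=config.ebox_window)
            written.append(_write(table,
                                  os.path.join(config.outdir, "cluster_table.tsv")))
            counts_summary["cluster_sizes"] = table["n_genes"].to_dict()

        # ---------------- set enrichment ----------------
        if st.get("sets", True):
            stage = "set_enrichment"
            if flags is None:
                raise RuntimeError("set_enrichment requires the de stage")
            venn = sets_mod.venn_decompose(flags)
            venn_df = pd.DataFrame(
                [(r, g) for r, gs in venn.items() for g in gs],
                columns=["region", "gene_id"])
            written.append(_write(venn_df,
                                  os.path.join(config.outdir, "venn_sets.tsv"),
                                  index=False))
            counts_summary["venn_sizes"] = {r: len(g) for r, g in venn.items()}
            universe = de_result.filtered_genes
            if assignments is not None:
                heat = sets_mod.sets_by_clusters_heatmap(venn, assignments)
                written.append(_write(heat,
                                      os.path.join(config.outdir,
                                                   "heatmap_matrix.tsv")))
            if gene_sets:
                query = flags.index[flags["regulated_wt"]]
                ora = sets_mod.ora_gmt(query, gene_sets, universe,
                                       fdr_max=config.ora_fdr)
                ora_out = ora.copy()
                written.append(_write(ora_out,
                                      os.path.join(config.outdir,
                                                   "ora_results.tsv")))
                counts_summary["n_ora_significant"] = int(
                    ora["significant"].fillna(False).sum())
            if config.external_list_path:
                ext = sets_mod.read_gene_list(config.external_list_path)
                omap = (pd.read_csv(config.ortholog_map_path, sep="\t")
                        if config.ortholog_map_path else None)
                flagged_any = flags.index[flags.any(axis=1)]
                res, report = sets_mod.external_overlap(
                    flagged_any, ext, universe, ortholog_map=omap)
                counts_summary["external_overlap"] = {
                    "n_overlap": res.n_overlap, "p": res.p, **report}

        # ---------------- sensitivity GSEA ----------------
        if st.get("gsea", True):
            stage = "sensitivity_gsea"
            if rpkm is None:
                raise RuntimeError("sensitivity_gsea requires the de stage")
            sens = gsea_mod.sensitivity_scores(rpkm, design)
            written.append(_write(sens,
                                  os.path.join(config.outdir, "sensitivity.tsv"),
                                  index_label="gene_id"))
            rnk = gsea_mod.rank_genes(sens["rank_metric"])
            rnk_path = os.path.join(config.outdir, "ranked_list.rnk")
            rnk.to_csv(rnk_path, sep="\t", header=False)
            written.append(rnk_path)
            if gene_sets:
                rng = np.random.default_rng(config.seed + 2)
                gres = gsea_mod.gsea_preranked(
                    sens["rank_metric"], gene_sets, n_perm=config.gsea_n_perm,
                    min_size=config.gsea_min_size, rng=rng)
                out = gres.copy()
                if len(out):
                    out["leading_edge"] = out["leading_edge"].map(",".join)
                written.append(_write(out,
                                      os.path.join(config.outdir,
                                                   "gsea_results.tsv")))
                enriched = gsea_mod.select_enriched(
                    gres, padj_max=config.gsea_padj,
                    abs_nes_min=config.gsea_abs_nes)
                counts_summary["n_gsea_significant"] = int(len(enriched))
                counts_summary["gsea_significant_sets"] = list(enriched.index)
    except Exception as exc:
        exc.stage = stage  # type: ignore[attr-defined]
        exc.partial_manifest = {p: _sha256(p) for p in written}  # type: ignore
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {os.path.basename(p): _sha256(p) for p in written}
    summary = {
        "version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "counts": counts_summary,
        "manifest": manifest,
    }
    summary_path = os.path.join(config.outdir, "run_summary.json")
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    log.info("pipeline complete: %d files, summary at %s", len(manifest),
             summary_path)
    return summary
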