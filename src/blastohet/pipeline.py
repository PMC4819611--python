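"""End-to-end orchestration with a single config and a run manifest.

Stage order: simulate/load -> QC (outliers dropped before normalization)
-> size factors + normalization + log transform -> batch adjustment ->
per-stage highly variable genes (plain and embryo-effect-adjusted) ->
intra/inter-embryo correlation comparison -> PCA on the union of
per-stage variable genes (batch-adjusted values) -> target-set
enrichment at the 4-cell stage -> co-expression clustering of the
variable target genes. Every intermediate is written to the output
directory; a manifest records the seed, a config hash, package versions
and the sha256 of each stage's outputs, so a re-run with one changed
parameter is detectable per stage. All randomness flows from the single
config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .batch import combat_adjust
from .enrichment import build_target_set, correlation_cluster, dendrogram_newick, enrichment_test
from .errors import BlastohetError, InsufficientDataError
from .heterogeneity import compare_intra_inter, pca_embedding
from .io import COMPLETE_EMBRYO_STAGES, CountMatrix, read_counts, write_counts
from .normalize import log_transform, normalize, size_factors
from .qc import compute_qc_metrics, flag_outliers
from .synthetic import GroundTruth, SyntheticConfig, generate_dataset
from .variability import call_hvg, intra_embryo_hvg

log = logging.getLogger("blastohet")


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults mirror the synthetic study."""

    out_dir: str = "blastohet_run"
    seed: int = 0
    # input: either a triplet of paths or a synthetic config
    matrix_path: str | None = None
    genes_path: str | None = None
    cells_path: str | None = None
    synthetic: SyntheticConfig | None = None
    # stage parameters
    size_factor_basis: str = "endogenous"
    qc_mad_k: float = 3.0
    drop_outliers: bool = True
    hvg_min_mean: float = 10.0
    hvg_fdr: float = 0.1
    heterogeneity_stages: tuple[int, ...] = COMPLETE_EMBRYO_STAGES
    batch_covariates: tuple[str, ...] = ("stage", "division_pattern")
    target_lists: tuple[str, ...] = ()  # paths, one gene id per line
    enrichment_min_support: int = 2
    enrichment_stage: int = 4
    cluster_min_size: int = 20
    pca_components: int = 2

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # run location is not an analysis parameter
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary report as a dict.

    Any stage error aborts with the stage name attached; intermediates
    already written stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    summary: dict = {}
    stage_name = "setup"

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {p.name: _sha256(p) for p in paths}

    try:
        # ---- input -----------------------------------------------------
        stage_name = "input"
        truth: GroundTruth | None = None
        if config.synthetic is not None:
            syn = replace(config.synthetic, seed=config.seed)
            matrix, truth = generate_dataset(syn)
            paths = write_counts(matrix, out / "counts")
            truth.save(out / "truth")
            record("input", list(paths.values()))
        elif config.matrix_path:
            matrix = read_counts(config.matrix_path, config.genes_path, config.cells_path)
        else:
            raise BlastohetError("config supplies neither input paths nor a synthetic config")
        log.info("input: %d genes x %d cells", matrix.n_genes, matrix.n_cells)

        # ---- QC --------------------------------------------------------
        stage_name = "qc"
        mapped = truth.mapped_read_totals if truth is not None else None
        qc = compute_qc_metrics(matrix, mapped)
        report = flag_outliers(qc, mad_k=config.qc_mad_k)
        qc.table.to_csv(out / "qc_metrics.tsv", sep="\t")
        (out / "flagged_cells.txt").write_text("\n".join(sorted(report.flagged)) + "\n")
        record("qc", [out / "qc_metrics.tsv", out / "flagged_cells.txt"])
        summary["n_cells_flagged"] = len(report.flagged)
        if config.drop_outliers and report.flagged:
            keep = ~matrix.cell_ids.isin(report.flagged)
            matrix = matrix.subset_cells(np.asarray(keep))
            log.info("qc: dropped %d outlier cells", len(report.flagged))

        # ---- normalization --------------------------------------------
        stage_name = "normalization"
        sf = size_factors(matrix, basis=config.size_factor_basis)
        sf_spike = None
        try:
            other = "spikein" if config.size_factor_basis == "endogenous" else "endogenous"
            sf_spike = size_factors(matrix, basis=other)
        except BlastohetError:
            pass
        nm = normalize(matrix, sf)
        lm = log_transform(nm)
        sf_tab = pd.DataFrame({config.size_factor_basis: sf.factors})
        if sf_spike is not None:
            sf_tab[sf_spike.basis] = sf_spike.factors
        sf_tab.to_csv(out / "size_factors.tsv", sep="\t")
        record("normalization", [out / "size_factors.tsv"])

        # ---- batch adjustment -----------------------------------------
        stage_name = "batch_adjust"
        n_batches = matrix.cells["batch"].nunique()
        adjusted_lm, batch_model = combat_adjust(
            lm,
            covariates=config.batch_covariates,
            min_mean_filter=config.hvg_min_mean,
        )
        _write_json(
            out / "batch_model.json",
            {
                "batches": batch_model.batches,
                "n_adjusted_genes": int(len(batch_model.adjusted_genes)),
                "n_passthrough_genes": int(len(batch_model.passthrough_genes)),
                "priors": batch_model.priors,
                "iterations": batch_model.n_iterations,
            },
        )
        record("batch_adjust", [out / "batch_model.json"])
        summary["n_batches"] = int(n_batches)
        # batch-adjusted values mapped back to the normalized-count scale;
        # gene-level analyses downstream of the adjustment run on these
        from .normalize import NormalizedMatrix

        adj_nm = NormalizedMatrix(
            values=np.maximum(10.0 ** adjusted_lm.values - 1.0, 0.0),
            genes=matrix.genes,
            cells=matrix.cells,
            basis=nm.basis,
            size_factors=sf.factors,
        )

        # ---- highly variable genes per stage --------------------------
        stage_name = "hvg"
        hvg_by_stage: dict[int, set] = {}
        hvg_rows = []
        for st in config.heterogeneity_stages:
            sel = (matrix.cells["stage"] == st).to_numpy()
            if sel.sum() < 3:
                log.warning("hvg: stage %d has <3 cells, skipped", st)
                continue
            nm_st = adj_nm.subset_cells(sel)
            lm_st = log_transform(nm_st)
            plain = call_hvg(nm_st, min_mean=config.hvg_min_mean, fdr=config.hvg_fdr)
            within, _ = intra_embryo_hvg(
                lm_st, min_mean=config.hvg_min_mean, fdr=config.hvg_fdr
            )
            hvg_by_stage[st] = within.variable_genes
            within.table.to_csv(out / f"hvg_stage{st}.tsv", sep="\t")
            hvg_rows.append(
                {
                    "stage": st,
                    "n_hvg_unadjusted": len(plain.variable_genes),
                    "n_hvg_embryo_adjusted": len(within.variable_genes),
                    "fit_a1": within.fit.a1,
                    "fit_a0": within.fit.a0,
                    "fit_method": within.fit.method,
                }
            )
        pd.DataFrame(hvg_rows).to_csv(out / "hvg_summary.tsv", sep="\t", index=False)
        record("hvg", [out / "hvg_summary.tsv"] + [out / f"hvg_stage{s}.tsv" for s in hvg_by_stage])
        summary["hvg_counts"] = {
            int(r["stage"]): int(r["n_hvg_embryo_adjusted"]) for r in hvg_rows
        }

        # ---- heterogeneity --------------------------------------------
        stage_name = "heterogeneity"
        het_rows = []
        pair_frames = []
        for st in config.heterogeneity_stages:
            try:
                comp = compare_intra_inter(nm, st, min_mean=config.hvg_min_mean)
            except InsufficientDataError as exc:
                log.warning("heterogeneity: stage %d skipped (%s)", st, exc)
                continue
            pairs = comp.pairs.assign(stage=st)
            pair_frames.append(pairs)
            het_rows.append(
                {
                    "stage": st,
                    "n_intra": comp.n_intra,
                    "n_inter": comp.n_inter,
                    "mean_intra_rho": float(np.mean(comp.intra_values)),
                    "mean_inter_rho": float(np.mean(comp.inter_values)),
                    "welch_t": comp.welch_t,
                    "welch_p": comp.welch_p,
                }
            )
        if pair_frames:
            pd.concat(pair_frames).to_csv(out / "correlations.tsv", sep="\t", index=False)
        pd.DataFrame(het_rows).to_csv(out / "welch.tsv", sep="\t", index=False)
        record("heterogeneity", [out / "welch.tsv"] + ([out / "correlations.tsv"] if pair_frames else []))
        summary["welch"] = {int(r["stage"]): {"t": r["welch_t"], "p": r["welch_p"]} for r in het_rows}
        summary["mean_rho"] = {
            int(r["stage"]): {"intra": r["mean_intra_rho"], "inter": r["mean_inter_rho"]}
            for r in het_rows
        }

        # ---- PCA on union of variable genes ---------------------------
        stage_name = "pca"
        union = sorted(set().union(*hvg_by_stage.values())) if hvg_by_stage else []
        if len(union) >= 2:
            emb = pca_embedding(adjusted_lm, union, n_components=config.pca_components)
            emb.coordinates.to_csv(out / "pca_coordinates.tsv", sep="\t")
            pd.DataFrame(
                {"variance_fraction": emb.variance_fractions},
                index=emb.coordinates.columns,
            ).to_csv(out / "pca_variance.tsv", sep="\t")
            emb.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
            record(
                "pca",
                [out / "pca_coordinates.tsv", out / "pca_variance.tsv", out / "pca_loadings.tsv"],
            )
            summary["pca_variance_fractions"] = [float(v) for v in emb.variance_fractions]

        # ---- enrichment ------------------------------------------------
        stage_name = "enrichment"
        if config.target_lists:
            lists = [
                [ln.strip() for ln in Path(p).read_text().splitlines() if ln.strip()]
                for p in config.target_lists
            ]
        elif truth is not None:
            lists = truth.target_gene_lists
        else:
            lists = []
        est = config.enrichment_stage
        if lists and est in hvg_by_stage:
            sel = (matrix.cells["stage"] == est).to_numpy()
            expressed = matrix.values[:, sel].sum(axis=1) > 0
            universe = set(matrix.gene_ids[expressed & matrix.endogenous_mask()])
            targets = build_target_set(
                lists, min_support=config.enrichment_min_support, universe=universe
            )
            enr = enrichment_test(hvg_by_stage[est], targets)
            _write_json(
                out / "enrichment.json",
                {
                    "stage": est,
                    "table": enr.table.tolist(),
                    "odds_ratio": enr.odds_ratio,
                    "p_value": enr.p_value,
                    "universe_size": enr.universe_size,
                    "n_targets": len(targets.genes),
                },
            )
            record("enrichment", [out / "enrichment.json"])
            summary["enrichment"] = {
                "stage": est,
                "odds_ratio": enr.odds_ratio,
                "p_value": enr.p_value,
            }

            # ---- clustering of variable target genes -------------------
            stage_name = "clustering"
            var_targets = sorted(hvg_by_stage[est] & targets.genes)
            if len(var_targets) >= 3:
                idx = matrix.gene_ids.get_indexer(var_targets)
                vals = adj_nm.values[np.ix_(idx, np.flatnonzero(sel))]
                assign = correlation_cluster(
                    vals, gene_ids=var_targets, min_cluster_size=config.cluster_min_size
                )
                assign.labels.rename("cluster").to_csv(out / "clusters.tsv", sep="\t")
                (out / "dendrogram.nwk").write_text(dendrogram_newick(assign) + "\n")
                record("clustering", [out / "clusters.tsv", out / "dendrogram.nwk"])
                summary["n_coexpression_clusters"] = assign.n_clusters
                summary["n_variable_targets"] = len(var_targets)

        stage_name = "report"
        _write_json(out / "summary.json", summary)
        _write_json(out / "manifest.json", manifest)
        return summary
    except BlastohetError as exc:
        _write_json(out / "manifest.json", manifest)
        raise BlastohetError(f"stage {stage_name!r} failed: {exc}") from exc
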