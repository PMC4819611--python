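"""Synthetic pre-implantation-embryo count data with full ground truth.

The generator emulates the structure of a Smart-Seq2-style single-cell
study of mouse cleavage stages: complete embryos at the 2-, 4- and 8-cell
stages (every sister blastomere captured) plus 16- and 32-cell embryos,
ERCC-like spike-ins added at fixed input amounts, per-cell capture/depth
scalings, per-embryo expression shifts, per-batch location/scale
distortions, a mitochondrial gene subset, and a planted set of genes with
excess biological variability.

Generative model for endogenous gene g in cell j of embryo k (batch b):

    count ~ Poisson( s_j * mu_g * theta_gj * 10**b_gk )

where ``s_j`` is a log-normal per-cell scaling (the true size factor),
``mu_g`` a log-normal baseline mean, ``theta_gj`` a unit-mean gamma
multiplier whose variance equals the planted excess squared CV for highly
variable genes (and which is identically 1 otherwise; the Poisson-gamma
mixture gives a negative-binomial marginal, matching the
CV²_total = CV²_tech + CV²_bio decomposition the downstream test assumes),
and ``b_gk ~ N(0, embryo_effect_sd)`` is a per-embryo additive shift on
the log10 scale, i.e. multiplicative on counts and exactly removable by a
linear model on log expression. Spike-in counts are Poisson(s_j * c_i)
with a fixed concentration ladder ``c_i`` and carry no biological, embryo
or batch term. Batch distortions are applied post hoc on the log10(x+1)
scale as per-batch, per-gene location/scale shifts around the gene mean,
then back-transformed and re-rounded to integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import COMPLETE_EMBRYO_STAGES, VALID_DIVISION_PATTERNS, VALID_STAGES, CountMatrix

#: embryos per stage in the emulated study design: 8 two-cell, 16 four-cell,
#: 4 eight-cell embryos plus 6 morulae and 6 blastocysts.
DEFAULT_EMBRYOS_PER_STAGE: dict[int, int] = {2: 8, 4: 16, 8: 4, 16: 6, 32: 6}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults define the standard simulated study: the stage design above,
    2000 endogenous genes, 50 spike-ins, 5% mitochondrial genes, gene
    means log-normal(meanlog 3.0, sdlog 1.3) so the median baseline is
    ~20 counts, per-cell scalings log-normal(0, 0.25), 10% of genes
    planted as highly variable with excess squared CV 0.5, per-embryo
    shifts of SD 0.1 on the log10 scale, and two collection batches with
    location shifts of SD 0.2 and gamma-distributed scale distortions of
    shape 6 (unit mean, typical distortions up to ~1.5x).
    """

    n_embryos_per_stage: Mapping[int, int] = None  # type: ignore[assignment]
    n_genes: int = 2000
    n_spikeins: int = 50
    frac_mito: float = 0.05
    baseline_mean_logdist: tuple[float, float] = (3.0, 1.3)
    capture_efficiency_dist: tuple[float, float] = (0.0, 0.25)
    hvg_fraction: float = 0.1
    hvg_bio_cv2: float = 0.5
    embryo_effect_sd: float = 0.1
    n_batches: int = 2
    batch_assignment: Mapping[str, str] | None = None
    batch_location_sd: float = 0.2
    batch_scale_shape: float = 6.0
    target_set_overlap: float = 0.4
    n_hvg_modules: int = 2
    hvg_module_fraction: float = 0.4
    mapped_frac_beta: tuple[float, float] = (40.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_embryos_per_stage is None:
            object.__setattr__(self, "n_embryos_per_stage", dict(DEFAULT_EMBRYOS_PER_STAGE))
        for stage, n in self.n_embryos_per_stage.items():
            if stage not in VALID_STAGES:
                raise ConfigurationError(f"invalid stage {stage}; expected one of {VALID_STAGES}")
            if n < 0:
                raise ConfigurationError(f"negative embryo count at stage {stage}")
        if self.n_genes < 1 or self.n_spikeins < 1:
            raise ConfigurationError("n_genes and n_spikeins must be >= 1")
        for name in ("frac_mito", "hvg_fraction", "target_set_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.hvg_bio_cv2 < 0 or self.embryo_effect_sd < 0 or self.batch_location_sd < 0:
            raise ConfigurationError("variability parameters must be non-negative")
        if self.capture_efficiency_dist[1] < 0:
            raise ConfigurationError("capture efficiency scale must be non-negative")
        if self.batch_scale_shape <= 0:
            raise ConfigurationError("batch_scale_shape must be positive")
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be >= 1")
        if self.n_hvg_modules < 0 or not 0.0 <= self.hvg_module_fraction <= 1.0:
            raise ConfigurationError("invalid co-expression module settings")


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery tests."""

    true_hvg_ids: set
    true_embryo_effects: pd.DataFrame  # embryo x gene, log10 shifts
    true_size_factors: pd.Series  # per cell, positive
    true_batch_params: dict  # batch -> {"location": Series, "scale": Series}
    target_gene_lists: list  # three gene-id lists
    true_module_labels: pd.Series  # per endogenous gene; 0 = no module
    mapped_read_totals: pd.Series  # per cell, incl. simulated unmapped remainder

    def save(self, out_prefix) -> None:
        """Write the ground truth as TSV/JSON text files."""
        import json
        from pathlib import Path

        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.true_embryo_effects.to_csv(f"{prefix}.embryo_effects.tsv", sep="\t")
        self.true_size_factors.rename("size_factor").to_csv(
            f"{prefix}.size_factors.tsv", sep="\t"
        )
        payload = {
            "true_hvg_ids": sorted(self.true_hvg_ids),
            "target_gene_lists": [sorted(lst) for lst in self.target_gene_lists],
            "true_batch_params": {
                b: {"location": p["location"].to_dict(), "scale": p["scale"].to_dict()}
                for b, p in self.true_batch_params.items()
            },
        }
        with open(f"{prefix}.truth.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _spikein_ladder(n_spikeins: int) -> np.ndarray:
    """Fixed spike-in input amounts: a geometric ladder spanning 1..10^4."""
    return np.geomspace(1.0, 1e4, n_spikeins)


def _build_cells(cfg: SyntheticConfig, rng: np.random.Generator):
    rows = []
    embryo_order = []
    for stage in sorted(cfg.n_embryos_per_stage):
        for e in range(cfg.n_embryos_per_stage[stage]):
            embryo = f"E{stage}c_{e + 1}"
            embryo_order.append(embryo)
            # division pattern is scored at the 2->4-cell transition; it is
            # metadata only (no expression effect planted by default)
            dp = (
                rng.choice(VALID_DIVISION_PATTERNS[:4])
                if stage in (4, 8)
                else "NA"
            )
            for j in range(stage):
                rows.append(
                    {
                        "cell_id": f"{embryo}_c{j + 1}",
                        "embryo": embryo,
                        "stage": stage,
                        "batch": "",
                        "division_pattern": dp,
                    }
                )
    cells = pd.DataFrame(rows).set_index("cell_id")
    if cfg.batch_assignment is not None:
        assign = dict(cfg.batch_assignment)
        missing = [e for e in embryo_order if e not in assign]
        if missing:
            raise ConfigurationError(f"batch_assignment missing embryos: {missing[:5]}")
    else:
        # alternate embryos within each stage across batches so that every
        # stage is represented in every batch (keeps stage and batch
        # unconfounded and leaves same-batch embryo pairs at each stage)
        assign = {}
        counters: dict[int, int] = {}
        for e in embryo_order:
            stage = int(cells.loc[cells["embryo"] == e, "stage"].iloc[0])
            i = counters.get(stage, 0)
            counters[stage] = i + 1
            assign[e] = f"batch{(i % cfg.n_batches) + 1}"
    cells["batch"] = cells["embryo"].map(assign)
    return cells, embryo_order


def generate_dataset(config: SyntheticConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw one synthetic dataset; deterministic for a fixed config seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cells, embryo_order = _build_cells(cfg, rng)
    n_cells = len(cells)
    if n_cells == 0:
        raise ConfigurationError("configuration yields zero cells")

    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    spike_ids = [f"ERCC-{i + 1:04d}" for i in range(cfg.n_spikeins)]
    n_mito = int(round(cfg.frac_mito * cfg.n_genes))
    mito_idx = rng.choice(cfg.n_genes, size=n_mito, replace=False)
    is_mito = np.zeros(cfg.n_genes, dtype=bool)
    is_mito[mito_idx] = True

    genes = pd.DataFrame(
        {
            "is_spikein": np.r_[np.zeros(cfg.n_genes, bool), np.ones(cfg.n_spikeins, bool)],
            "is_mito": np.r_[is_mito, np.zeros(cfg.n_spikeins, bool)],
        },
        index=pd.Index(gene_ids + spike_ids, name="gene_id"),
    )

    mu = rng.lognormal(*cfg.baseline_mean_logdist, size=cfg.n_genes)
    s = rng.lognormal(*cfg.capture_efficiency_dist, size=n_cells)

    n_hvg = int(round(cfg.hvg_fraction * cfg.n_genes))
    # plant excess variability only on expressed genes (baseline mean above
    # the downstream detection floor); ground truth on undetectable genes
    # would be meaningless for recovery benchmarks
    expressed = np.flatnonzero(mu > 10.0)
    if len(expressed) >= n_hvg:
        hvg_idx = rng.choice(expressed, size=n_hvg, replace=False)
    else:
        hvg_idx = np.argsort(mu)[::-1][:n_hvg]
    is_hvg = np.zeros(cfg.n_genes, dtype=bool)
    is_hvg[hvg_idx] = True

    # per-embryo per-gene log10 shifts
    b = np.zeros((len(embryo_order), cfg.n_genes))
    if cfg.embryo_effect_sd > 0:
        b = rng.normal(0.0, cfg.embryo_effect_sd, size=b.shape)
    embryo_index = {e: i for i, e in enumerate(embryo_order)}
    cell_embryo_row = np.array([embryo_index[e] for e in cells["embryo"]])

    # co-expression modules: a subset of the planted HVGs shares a
    # per-cell latent factor (log-normal multiplier, still unit mean and
    # excess squared CV hvg_bio_cv2); with exactly two modules the second
    # loads negatively on the same factor, giving one correlated and one
    # anti-correlated gene block as in a two-cluster co-expression map
    module_of = np.zeros(cfg.n_genes, dtype=int)  # 0 = no module
    n_module_genes = (
        int(round(cfg.hvg_module_fraction * n_hvg)) if cfg.n_hvg_modules else 0
    )
    if n_module_genes >= cfg.n_hvg_modules > 0:
        module_genes = rng.choice(hvg_idx, size=n_module_genes, replace=False)
        for mi, chunk in enumerate(np.array_split(module_genes, cfg.n_hvg_modules)):
            module_of[chunk] = mi + 1
        factors = rng.normal(size=(cfg.n_hvg_modules, n_cells))
        if cfg.n_hvg_modules == 2:
            factors[1] = -factors[0]

    rate = mu[:, None] * s[None, :]
    if cfg.hvg_bio_cv2 > 0 and n_hvg:
        shape = 1.0 / cfg.hvg_bio_cv2
        theta = rng.gamma(shape, 1.0 / shape, size=(n_hvg, n_cells))
        sigma = np.sqrt(np.log1p(cfg.hvg_bio_cv2))
        for pos, g in enumerate(hvg_idx):
            mi = module_of[g]
            if mi:
                theta[pos] = np.exp(sigma * factors[mi - 1] - 0.5 * sigma**2)
        rate[hvg_idx, :] = rate[hvg_idx, :] * theta
    rate = rate * 10.0 ** b[cell_embryo_row, :].T
    endo = rng.poisson(rate)

    c = _spikein_ladder(cfg.n_spikeins)
    spikes = rng.poisson(c[:, None] * s[None, :])

    values = np.vstack([endo, spikes]).astype(np.int64)

    # batch distortions on log10(x+1), per batch per endogenous gene, then
    # back-transformed and re-rounded (spike-ins untouched: fixed input)
    batches = sorted(cells["batch"].unique())
    batch_params: dict[str, dict[str, pd.Series]] = {}
    apply_batch = len(batches) > 1 and (cfg.batch_location_sd > 0 or cfg.batch_scale_shape < np.inf)
    if apply_batch:
        # distortions act on the depth-corrected log scale (counts divided
        # by the true per-cell scaling): the batch-adjustment model runs on
        # normalized log expression, so this is the scale on which the
        # planted location/scale shifts are well defined
        logv = np.log10(values[: cfg.n_genes] / s[None, :] + 1.0)
        # center distortions on gene x stage means so the location/scale
        # batch model with a stage covariate is correctly specified
        gene_means = np.empty_like(logv)
        stages_arr = cells["stage"].to_numpy()
        for st in np.unique(stages_arr):
            cols = stages_arr == st
            gene_means[:, cols] = logv[:, cols].mean(axis=1, keepdims=True)
        for bname in batches:
            loc = rng.normal(0.0, cfg.batch_location_sd, size=cfg.n_genes)
            if np.isfinite(cfg.batch_scale_shape):
                scale = rng.gamma(
                    cfg.batch_scale_shape, 1.0 / cfg.batch_scale_shape, size=cfg.n_genes
                )
            else:
                scale = np.ones(cfg.n_genes)
            batch_params[bname] = {
                "location": pd.Series(loc, index=gene_ids),
                "scale": pd.Series(scale, index=gene_ids),
            }
            cols = (cells["batch"] == bname).to_numpy()
            logv[:, cols] = (
                gene_means[:, cols]
                + (logv[:, cols] - gene_means[:, cols]) * scale[:, None]
                + loc[:, None]
            )
        back = np.round((10.0 ** logv - 1.0) * s[None, :])
        values[: cfg.n_genes] = np.maximum(back, 0.0).astype(np.int64)
    else:
        for bname in batches:
            batch_params[bname] = {
                "location": pd.Series(np.zeros(cfg.n_genes), index=gene_ids),
                "scale": pd.Series(np.ones(cfg.n_genes), index=gene_ids),
            }

    matrix = CountMatrix(values=values, genes=genes, cells=cells)

    truth = GroundTruth(
        true_hvg_ids={gene_ids[i] for i in hvg_idx},
        true_embryo_effects=pd.DataFrame(b, index=embryo_order, columns=gene_ids),
        true_size_factors=pd.Series(s, index=cells.index, name="size_factor"),
        true_batch_params=batch_params,
        target_gene_lists=_plant_target_lists(cfg, rng, gene_ids, hvg_idx, module_of),
        true_module_labels=pd.Series(module_of, index=gene_ids, name="module"),
        mapped_read_totals=_mapped_totals(cfg, rng, matrix),
    )
    return matrix, truth


def _plant_target_lists(cfg, rng, gene_ids, hvg_idx, module_of) -> list:
    """Three overlapping gene lists emulating published target catalogs.

    A core of "true targets" — ``target_set_overlap`` of the planted HVGs
    plus an equal number of non-HVG genes — appears in at least two of the
    three lists, so a two-of-three support rule recovers it. Each list
    additionally carries decoy genes unique to it.
    """
    n_genes = cfg.n_genes
    hvg_set = set(hvg_idx.tolist())
    n_core_hvg = int(round(cfg.target_set_overlap * len(hvg_idx)))
    # module genes enter the target core first: the correlated modules sit
    # inside the target set, as a co-expression map of variable targets
    # would show
    module_hvg = np.asarray(sorted(g for g in hvg_set if module_of[g]))
    other_hvg = np.asarray(sorted(g for g in hvg_set if not module_of[g]))
    if n_core_hvg <= len(module_hvg):
        core_hvg = rng.choice(module_hvg, size=n_core_hvg, replace=False)
    else:
        extra = rng.choice(
            other_hvg, size=min(n_core_hvg - len(module_hvg), len(other_hvg)), replace=False
        )
        core_hvg = np.r_[module_hvg, extra].astype(int)
    non_hvg = np.asarray(sorted(set(range(n_genes)) - hvg_set))
    n_core_other = min(len(non_hvg), n_core_hvg)
    core_other = rng.choice(non_hvg, size=n_core_other, replace=False)
    core = np.r_[core_hvg, core_other].astype(int)
    lists: list[set] = [set(), set(), set()]
    for g in core:
        # each core gene supported by 2 or 3 lists
        k = 2 + int(rng.random() < 0.5)
        for li in rng.choice(3, size=k, replace=False):
            lists[li].add(gene_ids[g])
    decoy_pool = np.asarray(sorted(set(range(n_genes)) - set(core.tolist())))
    n_decoy = max(1, n_genes // 50)
    for li in range(3):
        if len(decoy_pool):
            picks = rng.choice(decoy_pool, size=min(n_decoy, len(decoy_pool)), replace=False)
            lists[li].update(gene_ids[g] for g in picks)
    return [sorted(s) for s in lists]


def _mapped_totals(cfg, rng, matrix: CountMatrix) -> pd.Series:
    """Simulated per-cell total mapped reads incl. an unassigned remainder."""
    assigned = matrix.values.sum(axis=0).astype(float)
    frac = rng.beta(*cfg.mapped_frac_beta, size=matrix.n_cells)
    totals = np.round(assigned / np.clip(frac, 1e-6, 1.0))
    return pd.Series(totals, index=matrix.cell_ids, name="mapped_reads")


def generate_null_dataset(config: SyntheticConfig) -> tuple[CountMatrix, GroundTruth]:
    """Same study design with no planted structure.

    Forces ``hvg_fraction=0``, ``embryo_effect_sd=0`` and switches batch
    distortions off; every other setting (and the seed) is taken from
    ``config``.
    """
    from dataclasses import replace

    null_cfg = replace(
        config,
        hvg_fraction=0.0,
        embryo_effect_sd=0.0,
        batch_location_sd=0.0,
        batch_scale_shape=np.inf,
    )
    return generate_dataset(null_cfg)
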