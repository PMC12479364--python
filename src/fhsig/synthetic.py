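"""Synthetic bulk, single-cell and spatial experiments with planted truth.

The bulk generator emulates a sorted-population infection study: five
infection models x four CD4+ populations (IL-21+ T_FH, IL-21- T_FH, T_FR,
T_eff) x a few replicates, with negative-binomial counts around a log-linear
mean model.  Planted gene categories:

* ``core_up`` / ``core_down`` — shifted up/down in both T_FH subsets versus
  T_eff in *every* condition (the core follicular-helper program).
* ``tfr_shared`` — shifted up in T_FH *and* T_FR (follicular co-expression).
* ``specific:<condition>`` — shifted up in T_FH of that condition only
  (pathogen-specific program).
* ``null`` — no planted effect anywhere.

The analytic mean matrix is exposed on the truth object so the mean model
itself (mu ratios = 2**lfc exactly) can be checked independently of sampling
noise.  The single-cell generator plants cluster-specific signature activity
(cluster 0 expresses the core-up program, cluster k>0 the k-th pathogen
program) and the spatial generator places signature-positive cells inside
circular germinal-center-like regions on a grid.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .io import CountMatrix, SpatialDataset, write_counts, write_table

TFH_CELLTYPES = ("tfh_il21pos", "tfh_il21neg")

__all__ = [
    "SyntheticTruth",
    "generate_bulk_experiment",
    "generate_singlecell_experiment",
    "generate_spatial_experiment",
    "write_bulk_experiment",
]


@dataclasses.dataclass
class SyntheticTruth:
    """Planted gene categories and effect sizes — the oracle for recovery tests."""

    category: pd.Series  # gene -> core_up | core_down | tfr_shared | specific:<c> | null
    effect_lfc: float
    seed: int
    mu: pd.DataFrame | None = None  # analytic NB means, genes x samples (bulk)
    cell_clusters: pd.Series | None = None  # cell -> planted cluster (single cell)
    cluster_programs: dict[int, str] | None = None  # cluster -> planted category
    region_labels: pd.Series | None = None  # spot -> region (spatial)

    def genes_in(self, category: str) -> list[str]:
        return list(self.category.index[self.category == category])

    @property
    def core_up(self) -> list[str]:
        return self.genes_in("core_up")

    @property
    def core_down(self) -> list[str]:
        return self.genes_in("core_down")

    @property
    def tfr_shared(self) -> list[str]:
        return self.genes_in("tfr_shared")

    def specific(self, condition: str) -> list[str]:
        return self.genes_in(f"specific:{condition}")

    def expected_core(self) -> tuple[set[str], set[str]]:
        """Genes the core rule should recover, from the planted mean model.

        Up: genes with a positive T_FH-vs-T_eff shift in every condition —
        the ``core_up`` genes plus the ``tfr_shared`` genes (elevated in both
        follicular populations, hence also core by the rule, mirroring the
        T_FR-co-expressed core group).  Down: the ``core_down`` genes.
        """
        return set(self.core_up) | set(self.tfr_shared), set(self.core_down)

    def planted_lfc_tfh_vs_teff(self, condition: str) -> pd.Series:
        """Planted log2FC of the T_FH-vs-T_eff contrast within one condition."""
        lfc = pd.Series(0.0, index=self.category.index)
        lfc[self.category == "core_up"] = self.effect_lfc
        lfc[self.category == "core_down"] = -self.effect_lfc
        # tfr_shared genes are elevated in T_FH but not in T_eff
        lfc[self.category == "tfr_shared"] = self.effect_lfc
        lfc[self.category == f"specific:{condition}"] = self.effect_lfc
        return lfc


def _assign_categories(config: SimulationConfig) -> pd.Series:
    """Gene -> category map from a dedicated RNG stream.

    The stream depends only on (seed, design counts), so bulk, single-cell
    and spatial experiments generated from matching configs plant the same
    gene->category truth and bulk-derived signatures project onto them.
    """
    rng = np.random.default_rng([config.seed, 11])
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    cats = np.array(["null"] * config.n_genes, dtype=object)
    order = rng.permutation(config.n_genes)
    pos = 0
    for label, n in [
        ("core_up", config.n_core_up),
        ("core_down", config.n_core_down),
        ("tfr_shared", config.n_tfr_shared),
    ]:
        cats[order[pos : pos + n]] = label
        pos += n
    for cond in config.conditions:
        cats[order[pos : pos + config.n_specific_per_condition]] = f"specific:{cond}"
        pos += config.n_specific_per_condition
    return pd.Series(cats, index=genes, name="category")


def _celltype_shift(
    category: str, celltype: str, condition: str, lfc: float
) -> float:
    """Planted log2 shift of one gene in one (celltype, condition) group."""
    is_tfh = celltype in TFH_CELLTYPES
    if category == "core_up":
        return lfc if is_tfh else 0.0
    if category == "core_down":
        return -lfc if is_tfh else 0.0
    if category == "tfr_shared":
        return lfc if (is_tfh or celltype == "tfr") else 0.0
    if category.startswith("specific:"):
        return lfc if (is_tfh and category.split(":", 1)[1] == condition) else 0.0
    return 0.0


def _lognormal(
    rng: np.random.Generator, mean: float, cv: float, size: int
) -> np.ndarray:
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean mu, variance mu + dispersion*mu^2); Poisson when dispersion = 0."""
    if dispersion == 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate_bulk_experiment(
    config: SimulationConfig,
    counts_seed: int | None = None,
    force_small_library: bool = False,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate the sorted-population bulk experiment.

    ``counts_seed`` resamples the counts while keeping the planted truth and
    mean model fixed (held-out replicates for projection tests).  With
    ``force_small_library`` the last sample's library is scaled below one
    million reads to exercise the library-size filter.
    """
    truth_rng = np.random.default_rng([config.seed, 12])
    counts_rng = np.random.default_rng(
        [config.seed if counts_seed is None else counts_seed, 13]
    )

    category = _assign_categories(config)
    genes = category.index

    # baseline log2 relative expression; a fixed normalizer keeps planted
    # mu-ratios exactly 2**lfc between matched samples
    baseline = truth_rng.normal(4.0, 2.0, size=config.n_genes)
    norm_const = np.sum(2.0**baseline)

    rows = []
    for cond in config.conditions:
        for ct in config.celltypes:
            for rep in range(1, config.replicates_per_group + 1):
                rows.append((f"{cond}_{ct}_r{rep}", cond, ct, rep))
    meta = pd.DataFrame(
        rows, columns=["sample", "condition", "celltype", "replicate"]
    ).set_index("sample")

    lib = _lognormal(
        counts_rng, config.library_size_mean, config.library_size_cv, len(meta)
    )
    if force_small_library:
        lib[-1] = 9e5

    shift = np.empty((config.n_genes, len(meta)))
    cat_arr = category.to_numpy()
    for j, (cond, ct) in enumerate(zip(meta["condition"], meta["celltype"])):
        shift[:, j] = [
            _celltype_shift(c, ct, cond, config.effect_lfc) for c in cat_arr
        ]
    mu = (2.0 ** (baseline[:, None] + shift)) / norm_const * lib[None, :]

    counts = _nb_counts(counts_rng, mu, config.dispersion)
    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=meta.index), "genes_by_samples"
    )
    truth = SyntheticTruth(
        category=category,
        effect_lfc=config.effect_lfc,
        seed=config.seed,
        mu=pd.DataFrame(mu, index=genes, columns=meta.index),
    )
    return cm, meta, truth


# ---------------------------------------------------------------------------
# single cell


def _cluster_program_map(config: SimulationConfig) -> dict[int, str]:
    """Cluster 0 carries the core-up program; cluster k>0 the k-th pathogen program."""
    programs = {0: "core_up"}
    for k in range(1, config.n_clusters):
        cond = config.conditions[(k - 1) % len(config.conditions)]
        programs[k] = f"specific:{cond}"
    return programs


def generate_singlecell_experiment(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a tonsil-like single-cell dataset with planted clusters.

    Cells are Poisson around per-cell scaled cluster means.  A configurable
    fraction of genes is mitochondrial (``mt-`` prefix) and a configurable
    fraction of cells is given a high mitochondrial load to exercise QC.
    """
    rng = np.random.default_rng([config.seed, 17])
    category = _assign_categories(config)

    n_mito = int(round(config.mito_gene_fraction * config.n_genes))
    # mitochondrial identity goes to null genes so planted programs stay intact
    null_idx = np.flatnonzero((category == "null").to_numpy())
    if n_mito > len(null_idx):
        raise ConfigError("mito_gene_fraction leaves no room among null genes")
    mito_idx = null_idx[:n_mito]
    gene_names = category.index.to_numpy(dtype=object).copy()
    gene_names[mito_idx] = [f"mt-{g}" for g in gene_names[mito_idx]]
    category.index = pd.Index(gene_names)

    baseline = rng.normal(1.0, 1.5, size=config.n_genes)
    # mitochondrial transcripts are abundant but below the QC threshold
    baseline[mito_idx] += 3.0

    programs = _cluster_program_map(config)
    n_cells = config.n_cells_per_cluster * config.n_clusters
    clusters = np.repeat(np.arange(config.n_clusters), config.n_cells_per_cluster)
    donors = rng.integers(0, config.n_donors, size=n_cells)
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]

    lib = _lognormal(rng, config.cell_library_mean, 0.3, n_cells)
    high_mito = rng.random(n_cells) < config.high_mito_cell_fraction

    cat_arr = category.to_numpy()
    cluster_shift = np.zeros((config.n_clusters, config.n_genes))
    for k, prog in programs.items():
        cluster_shift[k, cat_arr == prog] = config.effect_lfc

    log2mu = baseline[None, :] + cluster_shift[clusters]
    rel = 2.0**log2mu
    mito_mask = np.zeros(config.n_genes, dtype=bool)
    mito_mask[mito_idx] = True
    # boost mito transcripts for damaged cells -> mito fraction past the QC cut
    rel[np.ix_(high_mito, mito_mask)] *= 50.0
    rel /= rel.sum(axis=1, keepdims=True)
    mu = rel * lib[:, None]

    counts = rng.poisson(mu)
    cm = CountMatrix(
        pd.DataFrame(counts, index=cell_ids, columns=category.index),
        "cells_by_genes",
    )
    cell_table = pd.DataFrame(
        {
            "donor": [f"donor{d + 1}" for d in donors],
            "true_cluster": clusters,
            "high_mito": high_mito,
        },
        index=pd.Index(cell_ids, name="cell"),
    )
    truth = SyntheticTruth(
        category=category,
        effect_lfc=config.effect_lfc,
        seed=config.seed,
        cell_clusters=pd.Series(clusters, index=cell_ids, name="cluster"),
        cluster_programs=programs,
    )
    return cm, cell_table, truth


# ---------------------------------------------------------------------------
# spatial


def generate_spatial_experiment(
    config: SimulationConfig,
) -> tuple[SpatialDataset, SyntheticTruth]:
    """Simulate a spatial grid with circular GC-like signature-positive regions.

    One cell per grid point (imaging-platform-like: cells are the units).
    Cells inside a region express the core-up program at ``effect_lfc``;
    cells outside are background.
    """
    rng = np.random.default_rng([config.seed, 19])
    category = _assign_categories(config)
    baseline = rng.normal(1.0, 1.5, size=config.n_genes)

    g = config.grid_size
    xs, ys = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    n_cells = len(coords)
    cell_ids = [f"spot{i:05d}" for i in range(n_cells)]

    region = np.array([""] * n_cells, dtype=object)
    if config.n_regions > 0:
        r = config.region_radius
        lo, hi = r, g - 1 - r
        if hi < lo:
            raise ConfigError("region_radius leaves no valid center on the grid")
        centers = rng.uniform(lo, hi, size=(config.n_regions, 2))
        for k, c in enumerate(centers):
            inside = np.linalg.norm(coords - c[None, :], axis=1) <= r
            region[inside] = f"gc_{k + 1}"

    in_region = region != ""
    cat_arr = category.to_numpy()
    shift = np.zeros((n_cells, config.n_genes))
    shift[np.ix_(in_region, cat_arr == "core_up")] = config.effect_lfc
    shift[np.ix_(in_region, cat_arr == "core_down")] = -config.effect_lfc

    lib = _lognormal(rng, config.cell_library_mean, 0.3, n_cells)
    rel = 2.0 ** (baseline[None, :] + shift)
    rel /= rel.sum(axis=1, keepdims=True)
    counts = rng.poisson(rel * lib[:, None])

    cm = CountMatrix(
        pd.DataFrame(counts, index=cell_ids, columns=category.index),
        "cells_by_genes",
    )
    coords_df = pd.DataFrame(coords, columns=["x", "y"], index=cell_ids)
    region_s = pd.Series(
        np.where(region == "", np.nan, region), index=cell_ids, name="region"
    )
    ds = SpatialDataset(counts=cm, coordinates=coords_df, region_labels=region_s)
    truth = SyntheticTruth(
        category=category,
        effect_lfc=config.effect_lfc,
        seed=config.seed,
        region_labels=region_s,
    )
    return ds, truth


# ---------------------------------------------------------------------------
# disk output


def write_bulk_experiment(
    config: SimulationConfig, out_dir: str | Path, format: str = "tsv"
) -> dict[str, Path]:
    """Generate and write counts, metadata and truth tables; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, meta, truth = generate_bulk_experiment(config)
    paths = {
        "counts": out / ("counts.mtx" if format == "mtx" else "counts.tsv"),
        "samples": out / "samples.tsv",
        "truth": out / "truth.tsv",
    }
    write_counts(counts, paths["counts"], format=format)
    write_table(meta, paths["samples"])
    write_table(truth.category.to_frame(), paths["truth"])
    return paths
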