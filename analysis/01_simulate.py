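"""Generate the synthetic study: bulk sorted-population infection experiment,
tonsil-like single-cell dataset, and spatial grid with GC-like regions.

Writes counts, metadata and planted-truth tables under results/simulated/.
"""

from pathlib import Path

from fhsig import synthetic
from fhsig.config import SimulationConfig
from fhsig.io import write_counts, write_table

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)

    paths = synthetic.write_bulk_experiment(cfg, OUT / "bulk")
    print(f"bulk: 5 infections x 4 populations x {cfg.replicates_per_group} reps, "
          f"{cfg.n_genes} genes -> {paths['counts']}")

    # same seed and design counts as the bulk run -> same planted gene->category
    # truth, so bulk-derived signatures project onto these datasets
    sc_cfg = cfg.replace(n_cells_per_cluster=200)
    cells, cell_meta, truth = synthetic.generate_singlecell_experiment(sc_cfg)
    sc_dir = OUT / "singlecell"
    sc_dir.mkdir(exist_ok=True)
    write_counts(cells, sc_dir / "counts.tsv")
    write_table(cell_meta, sc_dir / "cells.tsv")
    write_table(truth.category.to_frame(), sc_dir / "truth.tsv")
    print(f"single cell: {cells.shape[0]} cells x {cells.shape[1]} genes, "
          f"{sc_cfg.n_clusters} planted clusters -> {sc_dir}")

    sp_cfg = cfg.replace(grid_size=30, n_regions=3, region_radius=4.0)
    spatial, sp_truth = synthetic.generate_spatial_experiment(sp_cfg)
    spatial.write(OUT / "spatial")
    n_gc = spatial.region_labels.notna().sum()
    print(f"spatial: {spatial.counts.shape[0]} spots on a {sp_cfg.grid_size}x"
          f"{sp_cfg.grid_size} grid, {n_gc} spots inside GC-like regions -> {OUT / 'spatial'}")


if __name__ == "__main__":
    main()
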