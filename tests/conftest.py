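import numpy as np
import pytest

from epilandscape import synthdata, windows as win
from epilandscape.genome_model import CytosineRecord


def small_config(seed: int = 7) -> synthdata.SimConfig:
    """A fast ~200 kb simulation regime used across the suite."""
    return synthdata.SimConfig(
        seed=seed,
        chrom_sizes={"chrA": 120_000, "chrB": 80_000},
        n_genes=12,
        exons_per_gene=3,
        gene_length_range=(2000, 3000),
        te_families=[
            synthdata.TEFamilyConfig(
                "RLG", 6, (2000, 3000), 0.90, 0.85, 0.04, 30.0,
                spreading="linear_decay", spread_distance=1000,
            ),
            synthdata.TEFamilyConfig("RLC", 6, (2000, 3000), 0.90, 0.80, 0.04, 25.0),
            synthdata.TEFamilyConfig("DTA", 8, (600, 1200), 0.80, 0.60, 0.15, 3.0),
        ],
        genic_te_fraction=0.25,
        gap_range=(2000, 2600),
        n_high_chg_tss_genes=2,
        n_high_k9_tss_genes=2,
        n_high_both_tss_genes=1,
        expression=synthdata.ExpressionConfig(suppression_factor=0.0),
    )


@pytest.fixture(scope="session")
def sim_config():
    return small_config()


@pytest.fixture(scope="session")
def manifest(sim_config):
    return synthdata.simulate_genome(sim_config)


@pytest.fixture(scope="session")
def cytosines(manifest):
    return synthdata.simulate_methylome(manifest)


@pytest.fixture(scope="session")
def chip_reads(manifest):
    return synthdata.simulate_chip(manifest)


@pytest.fixture(scope="session")
def window_table(manifest, cytosines, chip_reads):
    table = win.tile_genome(manifest.chrom_sizes)
    win.weighted_methylation(cytosines, table)
    win.chip_window_counts(chip_reads, table)
    win.classify_window_location(
        table, manifest.genes + manifest.exons + manifest.tes
    )
    return table


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """Full simulated dataset written to disk once per session."""
    outdir = tmp_path_factory.mktemp("simdata")
    manifest = synthdata.simulate_all(small_config(seed=11), outdir)
    return outdir, manifest


def random_cytosines(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    n: int,
) -> list[CytosineRecord]:
    """Uniform random cytosine records for oracle comparisons."""
    chroms = list(chrom_sizes)
    records = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(chrom_sizes[chrom]))
        total = int(rng.integers(0, 30))
        meth = int(rng.integers(0, total + 1)) if total else 0
        records.append(
            CytosineRecord(
                chrom=chrom,
                pos=pos,
                strand="+" if rng.random() < 0.5 else "-",
                context=("CG", "CHG", "CHH")[int(rng.integers(3))],
                n_meth=meth,
                n_total=total,
                covered=total > 0,
            )
        )
    return records
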