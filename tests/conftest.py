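import numpy as np
import pandas as pd
import pytest

from popsweep.matrix import MISSING, VARIANT_COLUMNS, GenotypeMatrix
from popsweep.sim import SimConfig, SweepInterval, simulate_dataset


def make_matrix(
    dosages,
    positions=None,
    contig="chr1",
    ref="A",
    alt="G",
    populations=None,
    depth=100,
    mq=60.0,
    bq=35.0,
):
    """Hand-build a GenotypeMatrix from a dosage array (rows = samples)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_variants = dosages.shape
    if positions is None:
        positions = np.arange(1, n_variants + 1) * 100
    refs = [ref] * n_variants if isinstance(ref, str) else list(ref)
    alts = [alt] * n_variants if isinstance(alt, str) else list(alt)
    depths = [depth] * n_variants if np.isscalar(depth) else list(depth)
    mqs = [mq] * n_variants if np.isscalar(mq) else list(mq)
    bqs = [bq] * n_variants if np.isscalar(bq) else list(bq)
    samples = [f"s{i}" for i in range(n_samples)]
    if populations is None:
        populations = {s: "pop" for s in samples}
    elif isinstance(populations, list):
        populations = dict(zip(samples, populations))
    variants = pd.DataFrame(
        {
            "contig": contig,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "depth": depths,
            "mq": mqs,
            "base_qual": bqs,
        }
    )[VARIANT_COLUMNS]
    return GenotypeMatrix(
        samples=samples, dosages=dosages, variants=variants, populations=populations
    )


@pytest.fixture(scope="session")
def two_pop_dataset():
    """Two well-differentiated populations, 20+20 samples, ~660 SNPs."""
    cfg = SimConfig(
        contigs=[("chr1", 200_000)],
        pop_names=["a", "b"],
        samples_per_pop=[20, 20],
        f_per_pop=[0.2, 0.2],
        snp_density=1 / 300,
        missing_rate=0.02,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sweep_dataset():
    """Default three-population design with one planted sweep on 1 Mb."""
    cfg = SimConfig(
        contigs=[("chr1", 1_000_000)],
        seed=7,
        sweep_intervals=[
            SweepInterval("chr1", 400_000, 520_000, "target", 0.8, 0.2)
        ],
    )
    matrix, truth = simulate_dataset(cfg)
    return cfg, matrix, truth
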