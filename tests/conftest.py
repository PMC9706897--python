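import numpy as np
import pandas as pd
import pytest

import methylmark as mm


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-chromosome paired cohort with 12 planted ESCC regions."""
    scaffold = mm.generate_scaffold(2, 2000, mean_gap=25, seed=3)
    regions = mm.plant_dense_regions(scaffold, 12, sites_per_region=4,
                                     delta=40.0, seed=5)
    truth = mm.SimulationTruth(planted_regions=regions,
                               tumor_hypo_fraction=0.02, seed=11)
    matrix, meta, truth = mm.generate_paired_methylomes(scaffold, 9, truth)
    return {"scaffold": scaffold, "matrix": matrix, "meta": meta,
            "truth": truth}


@pytest.fixture(scope="session")
def small_dmcs(small_cohort):
    return mm.call_dmcs(small_cohort["matrix"], small_cohort["meta"])


def make_matrix(values, platform="wgbs", chrom="chr1", positions=None):
    """Build a MethylationMatrix from a 2-D array on one chromosome."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    positions = positions if positions is not None else np.arange(n) * 10
    manifest = pd.DataFrame({"chrom": [chrom] * n, "pos": positions})
    cols = [f"S{i + 1}" for i in range(values.shape[1])]
    return mm.MethylationMatrix(manifest=manifest,
                                values=pd.DataFrame(values, columns=cols),
                                platform=platform)


def paired_meta(n_pairs):
    rows = []
    for p in range(1, n_pairs + 1):
        rows.append({"sample_id": f"S{2 * p - 1}", "group": "normal",
                     "pair_id": f"P{p}"})
        rows.append({"sample_id": f"S{2 * p}", "group": "tumor",
                     "pair_id": f"P{p}"})
    return pd.DataFrame(rows)
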