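import numpy as np
import pandas as pd
import pytest

import lncprio
from lncprio import diffexp
from lncprio.simulate import GeneCatalog, SimulationTruth, simulate_counts


@pytest.fixture(scope="session")
def sim_sn():
    """Default single-region PD/control simulation (the package's study
    conditions at desk scale): 2,000 genes, 14 cases vs 9 controls."""
    cfg = lncprio.SimConfig(regions=("SN",))
    counts, catalog, samples, truth = lncprio.simulate_dataset(cfg, 0)
    return cfg, counts, catalog, samples, truth


@pytest.fixture(scope="session")
def de_sn(sim_sn):
    """Compensated NB differential expression on the default simulation."""
    _, counts, catalog, samples, _ = sim_sn
    cpm = lncprio.compute_cpm(counts)
    scores = lncprio.marker_scores(cpm, catalog.marker_sets())
    design = diffexp.build_design(samples, scores)
    disp = lncprio.estimate_dispersions(counts, design)
    return diffexp.test_differential_expression(counts, design, disp)


def flat_catalog(n_signal, signal_cpm, signal_disp, n_filler=200, filler_disp=0.05,
                 biotype="lncRNA", region="SN"):
    """Catalog of n_signal equal-expression genes plus filler genes that
    absorb the rest of the library (total baseline = 1e6 CPM)."""
    filler_cpm = (1e6 - n_signal * signal_cpm) / n_filler
    ids = [f"G{i:04d}" for i in range(n_signal)] + [f"F{i:04d}" for i in range(n_filler)]
    genes = pd.DataFrame(
        {
            "biotype": [biotype] * n_signal + ["PCG"] * n_filler,
            "specific_regions": "",
            "marker_of": "",
            "prc2_target": False,
            "dispersion": [signal_disp] * n_signal + [filler_disp] * n_filler,
            "beta_age": 0.0,
            "beta_sex": 0.0,
            "beta_rin": 0.0,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    base = pd.DataFrame(
        {region: [np.log2(signal_cpm)] * n_signal + [np.log2(filler_cpm)] * n_filler},
        index=genes.index,
    )
    return GeneCatalog(genes, base)


def flat_samples(n_cases, n_controls, region="SN", lib_size=2_000_000):
    rows = []
    for j in range(n_cases + n_controls):
        cond = "PD" if j < n_cases else "control"
        rows.append(
            dict(
                sample_id=f"S{j:03d}",
                region=region,
                condition=cond,
                age=70.0 + (j % 7),
                sex="M" if j % 2 else "F",
                RIN=7.0 + 0.1 * (j % 3),
                annotated_reads=lib_size,
                library_size=lib_size,
            )
        )
    return pd.DataFrame(rows)


def flat_truth(catalog, samples, lfc_by_gene=None, region="SN"):
    lfc = pd.Series(0.0, index=catalog.gene_ids)
    if lfc_by_gene is not None:
        for g, v in lfc_by_gene.items():
            lfc[g] = v
    return SimulationTruth(
        log2fc=pd.DataFrame({region: lfc}),
        celltype_multiplier=pd.DataFrame(
            1.0,
            index=pd.Index(samples["sample_id"], name="sample_id"),
            columns=["dopaminergic", "astrocyte", "microglia"],
        ),
    )
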