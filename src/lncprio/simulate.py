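"""Synthetic multi-region case/control RNA-seq cohorts with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a post-mortem Parkinson's disease brain cohort profiled in three
regions (substantia nigra SN, amygdala AM, middle temporal gyrus MTG):

* negative-binomial counts with biotype-dependent baseline expression and
  dispersion (lncRNAs lower expressed, more dispersed than protein-coding
  genes);
* region-specific expression, markedly more frequent among lncRNAs;
* planted per-region differential expression with covariate confounding
  (age, sex, RNA integrity) acting additively on log2 expression;
* a case-associated cell-type composition shift expressed as multiplicative
  changes of cell-type marker-gene sets (dopaminergic markers down in cases,
  glial markers up), which the DE stage is expected to compensate for;
* a PRC2-target gene set enriched for planted downregulation.

Everything is driven by a single integer seed; identical config + seed
reproduces every array bit-identically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .qc import CountMatrix, write_gmt

__all__ = [
    "SimConfig",
    "GeneCatalog",
    "SimulationTruth",
    "simulate_catalog",
    "simulate_cohort",
    "simulate_counts",
    "simulate_dataset",
    "write_dataset",
]

CELL_TYPES = ("dopaminergic", "astrocyte", "microglia")

#: log2-CPM assigned to a region-specific gene outside its regions; a small
#: floor rather than -inf so no count row is structurally all-zero.
OFF_REGION_LOG2CPM = np.log2(0.1)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the synthetic cohort.

    Defaults are calibrated to the qualitative class structure of a PD brain
    cohort: ~80% protein-coding genes, lncRNAs ~2.5 log2-CPM lower and with
    about double the biological dispersion, a ~6x higher region-specific
    fraction among lncRNAs, and a fourfold dopaminergic marker decline in
    cases. Ages/RIN emulate an elderly brain-bank cohort.
    """

    n_genes: int = 2000
    pcg_fraction: float = 0.8
    regions: tuple[str, ...] = ("SN", "AM", "MTG")
    n_cases: int = 14
    n_controls: int = 9
    lib_size_mean: float = 2.0e6
    lib_size_cv: float = 0.4
    base_logmean_pcg: tuple[float, float] = (4.0, 3.5)  # mean, sd of log2 CPM
    base_logmean_lnc: tuple[float, float] = (1.5, 3.5)
    dispersion_pcg: tuple[float, float] = (0.10, 0.5)  # log-normal median, sigma
    dispersion_lnc: tuple[float, float] = (0.20, 0.5)
    frac_region_specific_pcg: float = 0.05
    frac_region_specific_lnc: float = 0.30
    frac_de: float = 0.05
    lfc_sd_pcg: float = 1.0
    lfc_sd_lnc: float = 2.0
    age_effect_sd: float = 0.1   # log2 per SD of age, across genes
    sex_effect_sd: float = 0.1
    rin_effect_sd: float = 0.1
    celltype_shift: dict[str, float] = field(
        default_factory=lambda: {"dopaminergic": -2.0, "astrocyte": 0.5, "microglia": 0.5}
    )
    celltype_noise_sd: float = 0.75  # per-sample log2 composition noise
    marker_set_size: int = 20
    frac_prc2_targets: float = 0.10
    prc2_down_enrichment: float = 2.0
    age_mean_case: float = 75.0
    age_mean_control: float = 86.0
    age_sd: float = 6.0
    rin_mean: float = 7.4
    rin_sd: float = 0.7
    annot_rate_beta: tuple[float, float] = (8.5, 1.5)
    seed: int = 0

    def validate(self) -> None:
        props = {
            "pcg_fraction": self.pcg_fraction,
            "frac_region_specific_pcg": self.frac_region_specific_pcg,
            "frac_region_specific_lnc": self.frac_region_specific_lnc,
            "frac_de": self.frac_de,
            "frac_prc2_targets": self.frac_prc2_targets,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not 0.0 < self.pcg_fraction < 1.0:
            raise ValueError("pcg_fraction must lie strictly in (0, 1)")
        if self.n_genes < 10:
            raise ValueError("n_genes too small")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 cases and 2 controls per region")
        if self.dispersion_pcg[0] <= 0 or self.dispersion_lnc[0] <= 0:
            raise ValueError("dispersion medians must be positive")
        if len(self.regions) < 1:
            raise ValueError("at least one region required")
        if set(self.celltype_shift) - set(CELL_TYPES):
            raise ValueError(f"unknown cell types in celltype_shift: {self.celltype_shift}")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class GeneCatalog:
    """Per-gene attributes plus the baseline log2-CPM per region.

    ``genes`` is indexed by gene_id with columns biotype, specific_regions
    (comma-joined, empty = everywhere), marker_of, prc2_target, dispersion
    and the per-gene covariate coefficients (beta_age, beta_sex, beta_rin).
    ``baseline_log2cpm`` is gene x region.
    """

    genes: pd.DataFrame
    baseline_log2cpm: pd.DataFrame

    def __post_init__(self) -> None:
        if self.genes.index.duplicated().any():
            raise ValueError("duplicate gene_ids in catalog")
        if (self.genes["dispersion"] <= 0).any():
            raise ValueError("dispersions must be positive")
        markers = self.genes["marker_of"] != ""
        if (self.genes.loc[markers, "biotype"] != "PCG").any():
            raise ValueError("marker genes must be protein-coding")
        if (self.genes.loc[markers, "specific_regions"] != "").any():
            raise ValueError("marker genes must not be region-specific")

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    def marker_sets(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for ct in CELL_TYPES:
            members = list(self.genes.index[self.genes["marker_of"] == ct])
            if members:
                out[ct] = members
        return out

    def prc2_set(self) -> list[str]:
        return list(self.genes.index[self.genes["prc2_target"]])


@dataclass
class SimulationTruth:
    """Planted effects: per gene x region log2 fold change (0 = not DE) and
    per sample x cell-type expression multipliers."""

    log2fc: pd.DataFrame
    celltype_multiplier: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.celltype_multiplier.to_numpy() <= 0).any():
            raise ValueError("cell-type multipliers must be positive")

    @property
    def is_de(self) -> pd.DataFrame:
        return self.log2fc != 0.0


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

def simulate_catalog(config: SimConfig, seed: int | None = None) -> GeneCatalog:
    """Draw the gene universe: biotypes, baselines, dispersions, marker and
    PRC2 memberships, region-specificity."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_genes
    n_pcg = int(round(n * config.pcg_fraction))
    n_markers = config.marker_set_size * len(CELL_TYPES)
    if n_markers > n_pcg:
        raise ValueError(
            f"marker sets need {n_markers} protein-coding genes, only {n_pcg} available"
        )
    width = len(str(n))
    gene_ids = pd.Index([f"G{i:0{width}d}" for i in range(n)], name="gene_id")
    biotype = np.array(["PCG"] * n_pcg + ["lncRNA"] * (n - n_pcg))

    # marker genes: disjoint blocks of PCGs, never region-specific
    marker_of = np.array([""] * n, dtype=object)
    marker_idx = rng.choice(n_pcg, size=n_markers, replace=False)
    for k, ct in enumerate(CELL_TYPES):
        marker_of[marker_idx[k * config.marker_set_size:(k + 1) * config.marker_set_size]] = ct

    # region-specific genes, per-biotype fractions; markers excluded
    specific = np.array([""] * n, dtype=object)
    frac = np.where(biotype == "PCG", config.frac_region_specific_pcg,
                    config.frac_region_specific_lnc)
    is_specific = (rng.random(n) < frac) & (marker_of == "")
    if len(config.regions) >= 1:
        home = rng.choice(len(config.regions), size=n)
        specific[is_specific] = np.array(config.regions)[home[is_specific]]

    prc2 = rng.random(n) < config.frac_prc2_targets

    mean_pcg, sd_pcg = config.base_logmean_pcg
    mean_lnc, sd_lnc = config.base_logmean_lnc
    base = np.where(
        biotype == "PCG",
        rng.normal(mean_pcg, sd_pcg, size=n),
        rng.normal(mean_lnc, sd_lnc, size=n),
    )
    med = np.where(biotype == "PCG", config.dispersion_pcg[0], config.dispersion_lnc[0])
    sig = np.where(biotype == "PCG", config.dispersion_pcg[1], config.dispersion_lnc[1])
    dispersion = np.exp(np.log(med) + rng.normal(0.0, 1.0, size=n) * sig)

    beta_age = rng.normal(0.0, config.age_effect_sd, size=n) if config.age_effect_sd > 0 else np.zeros(n)
    beta_sex = rng.normal(0.0, config.sex_effect_sd, size=n) if config.sex_effect_sd > 0 else np.zeros(n)
    beta_rin = rng.normal(0.0, config.rin_effect_sd, size=n) if config.rin_effect_sd > 0 else np.zeros(n)

    genes = pd.DataFrame(
        {
            "biotype": biotype,
            "specific_regions": specific,
            "marker_of": marker_of,
            "prc2_target": prc2,
            "dispersion": dispersion,
            "beta_age": beta_age,
            "beta_sex": beta_sex,
            "beta_rin": beta_rin,
        },
        index=gene_ids,
    )
    baseline = pd.DataFrame(
        np.tile(base[:, None], (1, len(config.regions))),
        index=gene_ids,
        columns=list(config.regions),
    )
    # Off-region floor first, then renormalize the expressed entries per
    # region so each region's baseline CPM sums to 1e6: count column sums
    # then match library sizes and measured CPM matches the baseline.
    for j, r in enumerate(config.regions):
        off = (specific != "") & (specific != r)
        baseline.loc[off, r] = OFF_REGION_LOG2CPM
        lin = 2.0 ** baseline[r].to_numpy()
        s_floor = lin[off].sum()
        s_expr = lin[~off].sum()
        if s_expr <= 0 or s_floor >= 1e6:
            raise ValueError("degenerate baseline normalization")
        baseline.loc[~off, r] += np.log2((1e6 - s_floor) / s_expr)
    return GeneCatalog(genes=genes, baseline_log2cpm=baseline)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimConfig,
    seed: int | None = None,
    catalog: GeneCatalog | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw the sample table (per region: cases then controls) and the
    planted-effect truth tables.

    The truth needs gene identities (biotype-dependent fold-change scales,
    PRC2 targets); pass the catalog used for counts, otherwise one is
    regenerated from the same config and seed.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    if catalog is None:
        catalog = simulate_catalog(config, seed)
    rng = np.random.default_rng(seed + 1)

    rows = []
    for region in config.regions:
        for j in range(config.n_cases + config.n_controls):
            is_case = j < config.n_cases
            cond = "PD" if is_case else "control"
            age_mean = config.age_mean_case if is_case else config.age_mean_control
            age = float(np.clip(rng.normal(age_mean, config.age_sd), 40, 105))
            sex = "M" if rng.random() < 0.5 else "F"
            rin = float(np.clip(rng.normal(config.rin_mean, config.rin_sd), 1.0, 10.0))
            lib = rng.lognormal(
                np.log(config.lib_size_mean) - 0.5 * np.log1p(config.lib_size_cv**2),
                np.sqrt(np.log1p(config.lib_size_cv**2)),
            )
            lib = int(max(lib, 1000.0))
            annot_rate = rng.beta(*config.annot_rate_beta)
            rows.append(
                {
                    "sample_id": f"{region}_{cond}_{j:02d}",
                    "region": region,
                    "condition": cond,
                    "age": round(age, 1),
                    "sex": sex,
                    "RIN": round(rin, 2),
                    "annotated_reads": int(lib * annot_rate),
                    "library_size": lib,
                }
            )
    samples = pd.DataFrame(rows)

    # planted DE per gene x region; PRC2 targets get an elevated chance of
    # being planted *down* (relative risk = prc2_down_enrichment)
    genes = catalog.genes
    n = len(genes)
    lfc_sd = np.where(genes["biotype"] == "PCG", config.lfc_sd_pcg, config.lfc_sd_lnc)
    p_down = np.where(genes["prc2_target"],
                      config.prc2_down_enrichment * config.frac_de / 2.0,
                      config.frac_de / 2.0)
    p_up = np.full(n, config.frac_de / 2.0)
    log2fc = pd.DataFrame(0.0, index=genes.index, columns=list(config.regions))
    for region in config.regions:
        u = rng.random(n)
        down = u < p_down
        up = (u >= p_down) & (u < p_down + p_up)
        mag = np.abs(rng.normal(0.0, lfc_sd))
        mag = np.maximum(mag, 1e-6)  # keep is_de <=> lfc != 0 exact
        vals = np.zeros(n)
        vals[down] = -mag[down]
        vals[up] = mag[up]
        log2fc[region] = vals

    is_case_vec = (samples["condition"] == "PD").to_numpy()
    mult = {}
    for ct in CELL_TYPES:
        shift = config.celltype_shift.get(ct, 0.0)
        noise = (
            rng.normal(0.0, config.celltype_noise_sd, size=len(samples))
            if config.celltype_noise_sd > 0
            else np.zeros(len(samples))
        )
        mult[ct] = 2.0 ** (shift * is_case_vec + noise)
    celltype_multiplier = pd.DataFrame(mult, index=pd.Index(samples["sample_id"], name="sample_id"))
    return samples, SimulationTruth(log2fc=log2fc, celltype_multiplier=celltype_multiplier)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def simulate_counts(
    catalog: GeneCatalog,
    samples: pd.DataFrame,
    truth: SimulationTruth,
    seed: int,
) -> CountMatrix:
    """Draw NB counts. Per gene g and sample s:

    ``mu = lib_size_s * 2^(baseline[g, region_s] + case_s * log2fc[g, region_s]
    + beta_age_g * z(age_s) + beta_sex_g * sex_s + beta_rin_g * z(RIN_s)
    + log2 multiplier if g is a marker) / 1e6``

    then ``counts ~ NB(mean=mu, variance=mu + dispersion_g * mu^2)``; the
    Poisson limit is used for dispersions below 1e-8.
    """
    genes = catalog.genes
    if not truth.log2fc.index.equals(genes.index):
        raise ValueError("truth/catalog gene dimension mismatch")
    if set(truth.celltype_multiplier.index) != set(samples["sample_id"]):
        raise ValueError("truth/sample dimension mismatch")
    rng = np.random.default_rng(seed + 2)

    n_g, n_s = len(genes), len(samples)
    region = samples["region"].to_numpy()
    is_case = (samples["condition"] == "PD").to_numpy(dtype=float)

    def zscore(x):
        x = np.asarray(x, dtype=float)
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    z_age = zscore(samples["age"])
    z_rin = zscore(samples["RIN"])
    sex_ind = (samples["sex"] == "M").to_numpy(dtype=float) - 0.5

    log2cpm = catalog.baseline_log2cpm[region].to_numpy()  # gene x sample
    log2cpm = log2cpm + truth.log2fc[region].to_numpy() * is_case[None, :]
    log2cpm = log2cpm + np.outer(genes["beta_age"].to_numpy(), z_age)
    log2cpm = log2cpm + np.outer(genes["beta_sex"].to_numpy(), sex_ind)
    log2cpm = log2cpm + np.outer(genes["beta_rin"].to_numpy(), z_rin)

    mults = truth.celltype_multiplier.loc[samples["sample_id"]]
    for ct in CELL_TYPES:
        if ct in mults.columns:
            rows = (genes["marker_of"] == ct).to_numpy()
            if rows.any():
                log2cpm[rows, :] += np.log2(mults[ct].to_numpy())[None, :]

    lib = samples["library_size"].to_numpy(dtype=float)
    mu = np.clip(lib[None, :] * np.exp2(log2cpm) / 1e6, 1e-12, 1e12)

    alpha = genes["dispersion"].to_numpy()[:, None]
    counts = np.empty((n_g, n_s), dtype=np.int64)
    nb_rows = (alpha[:, 0] >= 1e-8)
    if nb_rows.any():
        size = 1.0 / alpha[nb_rows]
        p = size / (size + mu[nb_rows])
        counts[nb_rows] = rng.negative_binomial(size, p)
    if (~nb_rows).any():
        counts[~nb_rows] = rng.poisson(mu[~nb_rows])

    df = pd.DataFrame(counts, index=genes.index, columns=list(samples["sample_id"]))
    return CountMatrix(df, biotype=genes["biotype"].copy())


def simulate_dataset(
    config: SimConfig, seed: int | None = None
) -> tuple[CountMatrix, GeneCatalog, pd.DataFrame, SimulationTruth]:
    """Convenience wrapper: catalog + cohort + counts from one seed."""
    seed = config.seed if seed is None else seed
    catalog = simulate_catalog(config, seed)
    samples, truth = simulate_cohort(config, seed, catalog=catalog)
    counts = simulate_counts(catalog, samples, truth, seed)
    return counts, catalog, samples, truth


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_dataset(
    counts: CountMatrix,
    catalog: GeneCatalog,
    samples: pd.DataFrame,
    truth: SimulationTruth,
    out_dir,
) -> dict[str, str]:
    """Write the dataset as TSV/GMT files that round-trip through the qc
    readers. Returns a name -> path mapping."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    counts_df = counts.counts.copy()
    if counts.biotype is not None:
        counts_df.insert(0, "biotype", counts.biotype)
    paths["counts"] = os.path.join(out_dir, "counts.tsv")
    counts_df.to_csv(paths["counts"], sep="\t")

    paths["samples"] = os.path.join(out_dir, "samples.tsv")
    samples.to_csv(paths["samples"], sep="\t", index=False)

    paths["genes"] = os.path.join(out_dir, "genes.tsv")
    catalog.genes.to_csv(paths["genes"], sep="\t")

    paths["truth_log2fc"] = os.path.join(out_dir, "truth_log2fc.tsv")
    truth.log2fc.to_csv(paths["truth_log2fc"], sep="\t", float_format="%.6g")

    paths["truth_celltype"] = os.path.join(out_dir, "truth_celltype.tsv")
    truth.celltype_multiplier.to_csv(paths["truth_celltype"], sep="\t", float_format="%.6g")

    paths["markers"] = os.path.join(out_dir, "markers.gmt")
    write_gmt(catalog.marker_sets(), paths["markers"], description="cell_type_markers")

    paths["prc2"] = os.path.join(out_dir, "prc2.gmt")
    prc2 = catalog.prc2_set()
    write_gmt({"PRC2_targets": prc2} if prc2 else {}, paths["prc2"], description="prc2_targets")
    return paths
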