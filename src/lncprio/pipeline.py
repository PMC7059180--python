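"""End-to-end orchestration: QC -> per-region DE -> CCS/candidates -> class
statistics, driven by a single config and seed.

Every stochastic step derives its seed from the config seed, and all output
tables are written with a fixed float format, so an identical config + seed
reproduces the output bundle byte-identically.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import ccs as ccs_mod
from . import class_stats, diffexp, qc

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("lncprio")

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the cause."""


@dataclass
class PipelineConfig:
    counts: str
    metadata: str
    markers_gmt: str | None = None
    prc2_gmt: str | None = None
    homolog_map: str | None = None
    external_de: str | None = None
    out_dir: str = "lncprio_out"
    min_annotated_reads: int = 500_000
    min_rin: float = 6.5
    cpm_threshold: float = 1.0
    fdr_de: float = 0.05
    fdr_candidates: float = 0.1
    top_k: int = 15
    boot_level: float = 0.99
    n_boot: int = 10_000
    wad_delta: int = 10
    ccs_combine: str = "product"
    use_marker_compensation: bool = True
    extra_confounders: tuple[str, ...] = field(default_factory=tuple)
    primary_region: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "extra_confounders" in raw:
            raw["extra_confounders"] = tuple(raw["extra_confounders"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("min_annotated_reads", "cpm_threshold", "top_k", "n_boot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 < self.boot_level < 1:
            raise ValueError("boot_level must lie in (0, 1)")
        for name in ("counts", "metadata"):
            path = getattr(self, name)
            if path is None or not os.path.exists(path):
                raise ValueError(f"config path {name!r} does not exist: {path}")
        for name in ("markers_gmt", "prc2_gmt", "homolog_map", "external_de"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise ValueError(f"config path {name!r} does not exist: {path}")


def _write(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a dict of in-memory results and writes the
    TSV bundle plus a human-readable summary under ``config.out_dir``."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    results: dict = {"config": asdict(config)}
    summary_lines: list[str] = ["lncprio pipeline summary", "========================", ""]

    def stage(name):
        log.info("stage: %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    # ----- QC ------------------------------------------------------------
    with stage("qc"):
        counts = qc.read_counts(config.counts)
        meta = qc.read_metadata(config.metadata)
        counts, meta, exclusions = qc.filter_libraries(
            counts, meta, config.min_annotated_reads, config.min_rin
        )
        _write(exclusions, os.path.join(config.out_dir, "exclusions.tsv"), index=False)
        cpm = qc.compute_cpm(counts)
        regions = list(dict.fromkeys(meta["region"]))
        callsets = [
            qc.call_expressed(cpm, meta, r, config.cpm_threshold) for r in regions
        ]
        expressed_rows = []
        for cs in callsets:
            r_samples = meta.loc[meta["region"] == cs.region, "sample_id"]
            mean_cpm = cpm.cpm[list(r_samples)].mean(axis=1)
            expressed_rows.append(
                pd.DataFrame(
                    {
                        "region": cs.region,
                        "mean_cpm": mean_cpm,
                        "expressed": mean_cpm.index.isin(cs.expressed_genes),
                    }
                )
            )
        expressed = pd.concat(expressed_rows)
        _write(expressed, os.path.join(config.out_dir, "expressed.tsv"))
        specificity, venn = (None, None)
        if len(regions) >= 2:
            specificity, venn = qc.classify_specificity(callsets)
            _write(specificity, os.path.join(config.out_dir, "specificity.tsv"))
            _write(venn, os.path.join(config.out_dir, "venn.tsv"), index=False)
        results.update(
            counts=counts, meta=meta, cpm=cpm, exclusions=exclusions,
            callsets=callsets, specificity=specificity, venn=venn,
        )
        summary_lines.append(f"Libraries retained: {len(meta)} (excluded: {len(exclusions)})")
        for cs in callsets:
            summary_lines.append(
                f"Expressed genes in {cs.region} (mean CPM > {cs.threshold:g}): "
                f"{len(cs.expressed_genes)}"
            )
        if venn is not None:
            shared_all = venn.loc[venn["combination"] == ",".join(sorted(regions, key=regions.index)), "n_genes"]
            common = int(shared_all.iloc[0]) if len(shared_all) else 0
            summary_lines.append(f"Genes common to all regions: {common}")
        summary_lines.append("")

    primary = config.primary_region or regions[0]
    if primary not in regions:
        raise PipelineError(f"primary region {primary!r} not present in metadata")

    # ----- Differential expression per region ----------------------------
    de_by_region: dict[str, pd.DataFrame] = {}
    marker_sets = None
    with stage("diffexp"):
        if config.markers_gmt and config.use_marker_compensation:
            marker_sets = qc.read_gmt(config.markers_gmt)
        callset_by_region = {cs.region: cs for cs in callsets}
        for region in regions:
            r_meta = meta[meta["region"] == region].reset_index(drop=True)
            r_counts = counts.subset_samples(r_meta["sample_id"])
            r_cpm = qc.compute_cpm(r_counts)
            # test only the region's expressed genes (marker scores still use
            # the full matrix via r_cpm computed above)
            expressed_ids = [
                g for g in r_counts.gene_ids
                if g in callset_by_region[region].expressed_genes
            ]
            r_counts_expr = qc.CountMatrix(
                r_counts.counts.loc[expressed_ids], r_counts.biotype
            )
            scores = (
                diffexp.marker_scores(r_cpm, marker_sets) if marker_sets else None
            )
            design = diffexp.build_design(
                r_meta, scores, list(config.extra_confounders)
            )
            disp = diffexp.estimate_dispersions(r_counts_expr, design)
            de = diffexp.test_differential_expression(r_counts_expr, design, disp)
            de_by_region[region] = de
            _write(de, os.path.join(config.out_dir, f"de_{region}.tsv"))
            up = int(((de["q"] < config.fdr_de) & (de["log2fc"] > 0)).sum())
            down = int(((de["q"] < config.fdr_de) & (de["log2fc"] < 0)).sum())
            summary_lines.append(
                f"DE in {region} (FDR < {config.fdr_de:g}): {up + down} "
                f"({down} down, {up} up)"
            )
        summary_lines.append("")
        results["de"] = de_by_region

    # ----- CCS prioritization --------------------------------------------
    with stage("prioritize"):
        has_biotype = counts.biotype is not None
        ccs_by_region = {}
        for region, de in de_by_region.items():
            ccs_tab = ccs_mod.compute_ccs(
                de, biotype="lncRNA" if has_biotype else None,
                combine=config.ccs_combine,
            )
            ccs_by_region[region] = ccs_tab
            _write(ccs_tab, os.path.join(config.out_dir, f"ccs_{region}.tsv"))
        candidates, pool_size = ccs_mod.select_candidates(
            ccs_by_region[primary], config.fdr_candidates, config.top_k
        )
        _write(candidates, os.path.join(config.out_dir, "candidates.tsv"))
        wad = ccs_mod.screen_wad(ccs_by_region[primary], delta=config.wad_delta)
        _write(wad, os.path.join(config.out_dir, "wad_screen.tsv"))
        results.update(ccs=ccs_by_region, candidates=candidates,
                       candidate_pool_size=pool_size, wad_screen=wad)
        summary_lines.append(
            f"Candidate lncRNAs in {primary}: {len(candidates)} selected from a "
            f"pool of {pool_size} with q < {config.fdr_candidates:g}"
        )
        for gid in candidates.index:
            row = candidates.loc[gid]
            summary_lines.append(
                f"  {gid}  CCS={row['ccs']:.3g}  log2FC={row['log2fc']:+.3g}  "
                f"q={row['q']:.3g}"
            )
        try:
            diag = ccs_mod.ccs_diagnostics(ccs_by_region[primary])
            results["ccs_diagnostics"] = diag
            summary_lines.append(
                f"CCS diagnostics ({primary}): rho(CCS, -log10 p) = "
                f"{diag['neg_log10_p']['rho']:.3f}; rho(CCS, |log2FC|) = "
                f"{diag['abs_log2fc']['rho']:.3f}"
            )
        except ValueError as exc:
            summary_lines.append(f"CCS diagnostics skipped: {exc}")
        summary_lines.append("")

        if config.homolog_map and config.external_de:
            hmap = ccs_mod.read_homolog_map(config.homolog_map)
            ext = pd.read_csv(config.external_de, sep="\t", index_col=0)
            validation = ccs_mod.cross_model_validate(candidates, hmap, ext)
            _write(validation, os.path.join(config.out_dir, "validation.tsv"))
            results["validation"] = validation
            n_val = int((validation["status"] == "validated").sum())
            summary_lines.append(
                f"Cross-model validation: {n_val} of {len(validation)} candidates "
                f"validated (uncorrected p < 0.05, matching direction)"
            )
            summary_lines.append("")

    # ----- Class statistics ----------------------------------------------
    with stage("class_stats"):
        stats_rows = []
        if has_biotype:
            classes = counts.biotype
            r_meta = meta[meta["region"] == primary]
            r_cpm = qc.compute_cpm(counts.subset_samples(r_meta["sample_id"]))
            expr_primary = [
                g for g in r_cpm.gene_ids
                if g in callsets[regions.index(primary)].expressed_genes
            ]
            _, var_summary = class_stats.variability_by_class(
                r_cpm.cpm.loc[expr_primary], classes
            )
            stats_rows.append(
                {"statistic": "sd_log2cpm_contrast", "region": primary,
                 "estimate": var_summary["median_lncRNA"] - var_summary["median_PCG"],
                 "p": var_summary["p"], "lo": np.nan, "hi": np.nan,
                 "seed": np.nan}
            )
            summary_lines.append(
                f"Variability ({primary}): median SD lncRNA = "
                f"{var_summary['median_lncRNA']:.3f} vs PCG = "
                f"{var_summary['median_PCG']:.3f} (Mann-Whitney p = "
                f"{var_summary['p']:.3g})"
            )
            for i, subset in enumerate(("all", "cpm_gt_10", "p_lt_0.05")):
                try:
                    contrast = class_stats.lfc_class_contrast(
                        de_by_region[primary], classes, subset=subset,
                        n_boot=config.n_boot, level=config.boot_level,
                        seed=config.seed + 100 + i,
                    )
                except ValueError as exc:
                    summary_lines.append(f"|log2FC| contrast [{subset}] skipped: {exc}")
                    continue
                stats_rows.append(
                    {"statistic": contrast.statistic, "region": primary,
                     "estimate": contrast.difference, "p": np.nan,
                     "lo": contrast.ci[0], "hi": contrast.ci[1],
                     "seed": contrast.seed}
                )
                summary_lines.append(
                    f"|log2FC| contrast [{subset}]: lncRNA - PCG = "
                    f"{contrast.difference:+.3f} "
                    f"({contrast.level:.0%} CI {contrast.ci[0]:+.3f} to "
                    f"{contrast.ci[1]:+.3f})"
                )
            if specificity is not None:
                expressed_primary = {
                    g for g in callsets[regions.index(primary)].expressed_genes
                }
                spec_class = specificity["class"] == f"region-specific:{primary}"
                is_lnc = classes == "lncRNA"
                lnc_expr = [g for g in expressed_primary if is_lnc.get(g, False)]
                pcg_expr = [g for g in expressed_primary if not is_lnc.get(g, True)]
                k1 = int(spec_class.reindex(lnc_expr).sum())
                k2 = int(spec_class.reindex(pcg_expr).sum())
                if lnc_expr and pcg_expr:
                    enr = class_stats.enrichment_fold(k1, len(lnc_expr), k2, len(pcg_expr))
                    stats_rows.append(
                        {"statistic": f"{primary}_specific_enrichment_lnc_vs_pcg",
                         "region": primary, "estimate": enr.fold, "p": enr.p,
                         "lo": np.nan, "hi": np.nan, "seed": np.nan}
                    )
                    summary_lines.append(
                        f"{primary}-specific fraction: lncRNA {k1}/{len(lnc_expr)} vs "
                        f"PCG {k2}/{len(pcg_expr)}; fold = {enr.fold:.2f} "
                        f"(Fisher p = {enr.p:.3g})"
                    )
        if config.prc2_gmt:
            prc2_sets = qc.read_gmt(config.prc2_gmt)
            targets = set().union(*prc2_sets.values()) if prc2_sets else set()
            if targets & set(de_by_region[primary].index):
                prc2 = class_stats.prc2_target_analysis(de_by_region[primary], targets)
                results["prc2"] = prc2
                stats_rows.append(
                    {"statistic": "prc2_down_enrichment", "region": primary,
                     "estimate": prc2["down_enrichment"].fold,
                     "p": prc2["down_enrichment"].p, "lo": np.nan, "hi": np.nan,
                     "seed": np.nan}
                )
                summary_lines.append(
                    f"PRC2 targets: median q {prc2['median_q_targets']:.3g} vs "
                    f"others {prc2['median_q_others']:.3g} (Mann-Whitney p = "
                    f"{prc2['mannwhitney_p']:.3g}); downregulation enrichment = "
                    f"{prc2['down_enrichment'].fold:.2f} "
                    f"(Fisher p = {prc2['down_enrichment'].p:.3g})"
                )
        stats_table = pd.DataFrame(stats_rows)
        _write(stats_table, os.path.join(config.out_dir, "stats.tsv"), index=False)
        results["stats"] = stats_table

    summary_lines.append("")
    summary_lines.append(f"seed: {config.seed}")
    summary = "\n".join(summary_lines) + "\n"
    with open(os.path.join(config.out_dir, "summary.txt"), "w") as fh:
        fh.write(summary)
    results["summary"] = summary
    log.info("pipeline complete; outputs in %s", config.out_dir)
    return results
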