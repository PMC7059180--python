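"""Class-level and auxiliary statistics.

Covers the comparisons made between lncRNAs and protein-coding genes and
around the candidate transcripts: expression-variability contrast,
bootstrap |log2FC| class contrasts, exact 2x2 enrichment tests, PRC2-target
analyses, correlation utilities (including cross-region correlation over
matched donors), the brain-versus-periphery age-trend contrast, qPCR
delta-delta-Ct quantification, and relative-viability arithmetic.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from math import comb, inf

import numpy as np
import pandas as pd
from scipy import stats

from .qc import CpmMatrix

__all__ = [
    "ClassContrast",
    "CorrelationResult",
    "variability_by_class",
    "lfc_class_contrast",
    "fisher_exact",
    "enrichment_fold",
    "prc2_target_analysis",
    "correlation",
    "cross_region_correlation",
    "age_trend_contrast",
    "delta_delta_ct",
    "relative_change",
]


@dataclass
class CorrelationResult:
    method: str
    coefficient: float
    p: float
    n: int


@dataclass
class ClassContrast:
    """Bootstrap class contrast: group means of a statistic with percentile
    confidence intervals and the between-class difference."""

    statistic: str
    groups: dict[str, float]
    group_ci: dict[str, tuple[float, float]]
    difference: float
    ci: tuple[float, float]
    level: float
    n_resamples: int
    seed: int


# ---------------------------------------------------------------------------
# Variability and fold-change class contrasts
# ---------------------------------------------------------------------------

def variability_by_class(
    cpm: CpmMatrix, classes: pd.Series
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-gene SD of log2(CPM+1) across samples, contrasted between gene
    classes (Mann-Whitney U, two-sided).

    The log scale decouples the spread from raw abundance so the contrast
    reflects dispersion rather than expression level. Accepts a
    :class:`~lncprio.qc.CpmMatrix` or a plain gene x sample DataFrame (e.g.
    a subset restricted to expressed genes). Returns the per-gene SD table
    and a summary dict (medians per class, U, p).
    """
    cpm_df = cpm.cpm if hasattr(cpm, "cpm") else cpm
    if cpm_df.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = np.log2(cpm_df + 1.0).std(axis=1, ddof=1)
    cls = classes.reindex(sd.index)
    labels = [lab for lab in ("lncRNA", "PCG") if (cls == lab).sum() > 0]
    labels += sorted(set(cls.dropna().unique()) - set(labels))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 classes, got {labels}")
    groups = {lab: sd[cls == lab] for lab in labels}
    for lab, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 genes")
    u, p = stats.mannwhitneyu(groups[labels[0]], groups[labels[1]], alternative="two-sided")
    table = pd.DataFrame({"sd_log2cpm": sd, "class": cls})
    summary = {
        f"median_{labels[0]}": float(groups[labels[0]].median()),
        f"median_{labels[1]}": float(groups[labels[1]].median()),
        "U": float(u),
        "p": float(p),
    }
    return table, summary


_SUBSETS = ("all", "cpm_gt_10", "p_lt_0.05")


def lfc_class_contrast(
    de: pd.DataFrame,
    classes: pd.Series,
    subset: str = "all",
    n_boot: int = 10_000,
    level: float = 0.99,
    seed: int = 0,
) -> ClassContrast:
    """Mean |log2FC| per gene class with bootstrap percentile CIs.

    ``subset`` restricts the gene universe: all genes, highly expressed
    (mean CPM > 10), or nominally DE (p < 0.05). Genes are resampled with
    replacement within class; the difference is lncRNA minus PCG (first
    class minus second in label order).
    """
    if subset not in _SUBSETS:
        raise ValueError(f"subset must be one of {_SUBSETS}")
    df = de.copy()
    df["class"] = classes.reindex(df.index)
    if subset == "cpm_gt_10":
        df = df[df["mean_cpm"] > 10]
    elif subset == "p_lt_0.05":
        df = df[df["p"] < 0.05]
    labels = [lab for lab in ("lncRNA", "PCG") if (df["class"] == lab).any()]
    labels += sorted(set(df["class"].dropna().unique()) - set(labels))
    if len(labels) != 2 or any((df["class"] == lab).sum() == 0 for lab in labels):
        raise ValueError(f"both classes must be non-empty after subset {subset!r}")
    if n_boot < 2:
        warnings.warn("n_boot < 2: confidence interval degenerates to the point estimate")

    rng = np.random.default_rng(seed)
    boot_means = {}
    groups = {}
    for lab in labels:
        vals = np.abs(df.loc[df["class"] == lab, "log2fc"].to_numpy())
        groups[lab] = float(vals.mean())
        if n_boot < 2:
            boot_means[lab] = np.full(1, vals.mean())
        else:
            idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
            boot_means[lab] = vals[idx].mean(axis=1)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    group_ci = {
        lab: (float(np.quantile(bm, lo_q)), float(np.quantile(bm, hi_q)))
        for lab, bm in boot_means.items()
    }
    diff_draws = boot_means[labels[0]] - boot_means[labels[1]]
    difference = groups[labels[0]] - groups[labels[1]]
    ci = (float(np.quantile(diff_draws, lo_q)), float(np.quantile(diff_draws, hi_q)))
    if n_boot < 2:
        ci = (difference, difference)
        group_ci = {lab: (groups[lab], groups[lab]) for lab in labels}
    return ClassContrast(
        statistic=f"mean_abs_log2fc[{subset}]",
        groups=groups,
        group_ci=group_ci,
        difference=difference,
        ci=ci,
        level=level,
        n_resamples=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Exact 2x2 tests
# ---------------------------------------------------------------------------

def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table [[a, b], [c, d]].

    The two-sided p sums, over the hypergeometric support with the observed
    margins, the probabilities of all tables no more likely than the
    observed one (minimum-likelihood convention). Computed with exact
    integer arithmetic, so ties are exact rather than float-rounded.
    Returns (sample odds ratio a*d/(b*c), p).
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("contingency cells must be nonnegative")
    if any(int(x) != x for x in cells):
        raise ValueError("contingency cells must be integers")
    a, b, c, d = (int(x) for x in cells)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise ValueError("all margins must be positive")
    amin, amax = max(0, c1 - r2), min(r1, c1)
    numerators = [comb(r1, k) * comb(r2, c1 - k) for k in range(amin, amax + 1)]
    observed = numerators[a - amin]
    p = sum(v for v in numerators if v <= observed) / comb(n, c1)
    if b * c == 0:
        odds = inf if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return odds, min(p, 1.0)


@dataclass
class EnrichmentResult:
    fraction1: float
    fraction2: float
    fold: float
    p: float


def enrichment_fold(k1: int, n1: int, k2: int, n2: int) -> EnrichmentResult:
    """Fold enrichment of a property between two classes.

    fold = (k1/n1) / (k2/n2); the p-value is the two-sided Fisher exact
    test on [[k1, n1-k1], [k2, n2-k2]]. ``k2 = 0`` yields infinite fold
    (flagged via the value itself).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("class sizes must be positive")
    if k1 > n1 or k2 > n2 or k1 < 0 or k2 < 0:
        raise ValueError("k must lie in [0, n]")
    f1, f2 = k1 / n1, k2 / n2
    if k1 == 0 and k2 == 0:
        # property absent from both classes: no enrichment evidence either way
        return EnrichmentResult(fraction1=f1, fraction2=f2, fold=float("nan"), p=1.0)
    fold = inf if k2 == 0 else f1 / f2
    _, p = fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])
    return EnrichmentResult(fraction1=f1, fraction2=f2, fold=fold, p=p)


def prc2_target_analysis(
    de: pd.DataFrame,
    targets,
    q_threshold: float = 0.05,
) -> dict:
    """Are PRC2 targets more perturbed, and biased toward downregulation?

    Two readouts: a two-sided Mann-Whitney U comparing the FDR-adjusted
    q-values of target versus non-target genes (lower q among targets means
    stronger perturbation), and the fold enrichment of targets among
    significantly downregulated genes (log2FC < 0, q < threshold).
    """
    targets = set(targets)
    in_universe = de.index.isin(targets)
    if not in_universe.any():
        raise ValueError("PRC2 target set does not intersect the DE universe")
    if in_universe.all():
        raise ValueError("empty complement: every gene is a PRC2 target")
    q_t = de.loc[in_universe, "q"].to_numpy()
    q_o = de.loc[~in_universe, "q"].to_numpy()
    u, p_mw = stats.mannwhitneyu(q_t, q_o, alternative="two-sided")
    down_sig = (de["log2fc"] < 0) & (de["q"] < q_threshold)
    enr = enrichment_fold(
        int((down_sig & in_universe).sum()), int(in_universe.sum()),
        int((down_sig & ~in_universe).sum()), int((~in_universe).sum()),
    )
    return {
        "median_q_targets": float(np.median(q_t)),
        "median_q_others": float(np.median(q_o)),
        "mannwhitney_U": float(u),
        "mannwhitney_p": float(p_mw),
        "down_enrichment": enr,
    }


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def correlation(x, y, method: str = "spearman") -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant vector")
    if method == "spearman":
        coef, p = stats.spearmanr(x, y)
    elif method == "pearson":
        coef, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method=method, coefficient=float(coef), p=float(p), n=len(x))


def cross_region_correlation(
    expr_by_region: dict[str, pd.DataFrame],
    method: str = "spearman",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate each gene's expression across matched donors between every
    pair of regions.

    ``expr_by_region`` maps region label to a gene x donor table; donors are
    matched by column id (intersection across the pair). Returns a long
    table (gene, region_a, region_b, coefficient, p, n, significant);
    constant vectors are flagged with NaN coefficients.
    """
    regions = list(expr_by_region)
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    rows = []
    for i, ra in enumerate(regions):
        for rb in regions[i + 1:]:
            common = expr_by_region[ra].columns.intersection(expr_by_region[rb].columns)
            genes = expr_by_region[ra].index.intersection(expr_by_region[rb].index)
            for g in genes:
                xa = expr_by_region[ra].loc[g, common].to_numpy(dtype=float)
                xb = expr_by_region[rb].loc[g, common].to_numpy(dtype=float)
                if len(common) < 3 or np.ptp(xa) == 0 or np.ptp(xb) == 0:
                    rows.append((g, ra, rb, np.nan, np.nan, len(common), False))
                    continue
                res = correlation(xa, xb, method=method)
                rows.append((g, ra, rb, res.coefficient, res.p, res.n, res.p < alpha))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "region_a", "region_b", "coefficient", "p", "n", "significant"],
    )


# ---------------------------------------------------------------------------
# Age-trend contrast
# ---------------------------------------------------------------------------

_AGE_BIN = re.compile(r"^\s*(\d+)\s*[-–]\s*(\d+)\s*$")


def _age_to_numeric(ages) -> np.ndarray:
    """Accept numeric ages or range bins like '60-69' (mapped to midpoints)."""
    out = []
    for a in ages:
        if isinstance(a, str):
            m = _AGE_BIN.match(a)
            if not m:
                raise ValueError(f"cannot parse age value {a!r}")
            out.append((float(m.group(1)) + float(m.group(2))) / 2.0)
        else:
            out.append(float(a))
    return np.asarray(out)


def age_trend_contrast(
    tissue_tables: dict[str, tuple],
    tissue_class: dict[str, str],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Contrast per-tissue age correlations between tissue classes.

    ``tissue_tables`` maps tissue label to ``(ages, expression)`` paired
    vectors (ages may be numeric or binned strings); ``tissue_class`` maps
    each tissue to 'brain' or 'periphery'. Per tissue, the Pearson r of
    expression against age is computed (tissues with constant expression
    are flagged and excluded); the two sets of r values are then compared
    with Welch's two-sample t-test.
    """
    rows = []
    for tissue, (ages, expr) in tissue_tables.items():
        ages_num = _age_to_numeric(ages)
        expr = np.asarray(expr, dtype=float)
        if len(expr) < 4:
            raise ValueError(f"tissue {tissue!r} has fewer than 4 samples")
        cls = tissue_class[tissue]
        if np.ptp(expr) == 0 or np.ptp(ages_num) == 0:
            rows.append({"tissue": tissue, "class": cls, "r": np.nan,
                         "n_samples": len(expr), "excluded": True})
            continue
        r, _ = stats.pearsonr(ages_num, expr)
        rows.append({"tissue": tissue, "class": cls, "r": float(r),
                     "n_samples": len(expr), "excluded": False})
    summary_df = pd.DataFrame(rows)
    usable = summary_df[~summary_df["excluded"]]
    by_class = {c: usable.loc[usable["class"] == c, "r"].to_numpy()
                for c in sorted(usable["class"].unique())}
    if len(by_class) != 2 or any(len(v) < 2 for v in by_class.values()):
        raise ValueError("each tissue class needs at least 2 usable tissues")
    (c1, r1), (c2, r2) = by_class.items()
    t, p = stats.ttest_ind(r1, r2, equal_var=False)
    contrast = {
        f"mean_r_{c1}": float(np.mean(r1)),
        f"mean_r_{c2}": float(np.mean(r2)),
        "t": float(t),
        "p": float(p),
        f"n_{c1}": len(r1),
        f"n_{c2}": len(r2),
    }
    return summary_df, contrast


# ---------------------------------------------------------------------------
# qPCR and viability arithmetic
# ---------------------------------------------------------------------------

def delta_delta_ct(records: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Relative qPCR quantification by the delta-delta-Ct method.

    Per sample: dCt = Ct_target - Ct_housekeeping (mean of ct_hk1/ct_hk2
    when two housekeeping genes were run); ddCt references the *median* dCt
    of the reference group; relative expression = 2^(-ddCt), also reported
    as percent of the reference median.
    """
    required = {"sample_id", "group", "ct_target", "ct_hk1"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"qPCR records missing columns: {sorted(missing)}")
    hk_cols = [c for c in ("ct_hk1", "ct_hk2") if c in records.columns]
    hk = records[hk_cols].mean(axis=1)
    if records[hk_cols].isna().all(axis=1).any():
        raise ValueError("missing housekeeping Ct")
    for col in ("ct_target", *hk_cols):
        vals = records[col].dropna()
        if ((vals <= 0) | (vals >= 45)).any():
            raise ValueError(f"Ct values in {col} outside (0, 45)")
    dct = records["ct_target"] - hk
    ref = dct[records["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    ddct = dct - ref.median()
    rel = 2.0 ** (-ddct)
    out = records[["sample_id", "group"]].copy()
    out["dCt"] = dct
    out["ddCt"] = ddct
    out["relative_expression"] = rel
    out["pct_of_reference"] = 100.0 * rel
    return out


def relative_change(treated: float, control: float) -> float:
    """Percent decrease of ``treated`` relative to ``control``:
    100 * (control - treated) / control."""
    if control <= 0:
        raise ValueError("control must be positive")
    return 100.0 * (control - treated) / control
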