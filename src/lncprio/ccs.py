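"""Combined calculated score (CCS) prioritization and candidate validation.

The CCS merges two logarithmic quantities — average expression (CPM) and the
significance of disease-induced differential expression — so that transcripts
both reasonably abundant and reproducibly changed outrank transcripts that
are extreme on a single axis:

    CCS(g) = log2(1 + mean_cpm(g)) * (-log10 p(g))        (default, product)

An additive variant (sum of the two terms) is available behind
``combine="sum"``. The unadjusted p enters the score; the FDR-adjusted q is
applied separately as a candidate filter, never inside the score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_ccs",
    "ccs_diagnostics",
    "select_candidates",
    "screen_wad",
    "cross_model_validate",
    "read_homolog_map",
]

_MIN_P = 1e-300


def compute_ccs(
    de: pd.DataFrame,
    biotype: str | None = None,
    combine: str = "product",
) -> pd.DataFrame:
    """Score every gene of a DE table; optionally restrict to one biotype.

    Returns a table sorted by rank (1 = best) with columns ccs, rank,
    expr_term, sig_term plus the carried-over DE columns. Ties on CCS break
    by smaller p, then lexicographic gene_id.
    """
    if de.empty:
        raise ValueError("empty DE table")
    if combine not in ("product", "sum"):
        raise ValueError(f"unknown combine rule {combine!r}")
    df = de.copy()
    if biotype is not None:
        if "biotype" not in df.columns:
            raise ValueError("DE table has no biotype column to filter on")
        df = df[df["biotype"] == biotype]
        if df.empty:
            raise ValueError(f"no genes with biotype {biotype!r}")
    p = df["p"].to_numpy(dtype=float)
    if (p <= 0).any():
        warnings.warn("p-values of 0 clamped to smallest positive value")
        p = np.clip(p, _MIN_P, None)
    expr_term = np.log2(1.0 + df["mean_cpm"].to_numpy(dtype=float))
    sig_term = -np.log10(p)
    ccs = expr_term * sig_term if combine == "product" else expr_term + sig_term
    df = df.assign(ccs=ccs, expr_term=expr_term, sig_term=sig_term)
    order = np.lexsort(
        (df.index.to_numpy(), df["p"].to_numpy(), -df["ccs"].to_numpy())
    )
    df = df.iloc[order]
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def ccs_diagnostics(ccs_table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Spearman correlation of CCS with |log2FC| and with -log10 p.

    The score is expected to track significance more tightly than fold
    change (it contains -log10 p directly; fold change only through its
    association with p).
    """
    if len(ccs_table) < 10:
        raise ValueError("insufficient observations for CCS diagnostics")
    ccs = ccs_table["ccs"].to_numpy()
    abs_lfc = np.abs(ccs_table["log2fc"].to_numpy())
    nlp = -np.log10(np.clip(ccs_table["p"].to_numpy(), _MIN_P, None))
    out = {}
    for name, other in (("abs_log2fc", abs_lfc), ("neg_log10_p", nlp)):
        if np.ptp(ccs) == 0 or np.ptp(other) == 0:
            raise ValueError(f"constant input vector for {name}")
        rho, p = stats.spearmanr(ccs, other)
        out[name] = {"rho": float(rho), "p": float(p), "n": len(ccs)}
    return out


def select_candidates(
    ccs_table: pd.DataFrame,
    fdr_max: float = 0.1,
    top_k: int = 15,
) -> tuple[pd.DataFrame, int]:
    """Filter genes at q < ``fdr_max`` then keep the ``top_k`` by CCS rank.

    Returns (candidates, eligible_pool_size). An empty pool yields an empty
    frame with a warning rather than an error.
    """
    pool = ccs_table[ccs_table["q"] < fdr_max]
    if pool.empty:
        warnings.warn(f"no genes pass q < {fdr_max}; candidate list is empty")
        return pool.copy(), 0
    pool = pool.sort_values("rank", kind="mergesort")
    return pool.head(top_k).copy(), len(pool)


def screen_wad(
    ccs_table: pd.DataFrame,
    q_threshold: float = 0.05,
    delta: int = 10,
) -> pd.DataFrame:
    """Discovery screen: FDR-surviving genes whose CCS rank is materially
    better than their q rank.

    Reports genes with q < ``q_threshold`` whose CCS rank improves on their
    q rank by at least ``delta`` positions, sorted by CCS — the genes a pure
    FDR ordering would under-rank despite robust, well-expressed signal.
    """
    df = ccs_table.copy()
    order = np.lexsort((df.index.to_numpy(), df["p"].to_numpy(), df["q"].to_numpy()))
    q_rank = np.empty(len(df), dtype=int)
    q_rank[order] = np.arange(1, len(df) + 1)
    df["q_rank"] = q_rank
    hits = df[(df["q"] < q_threshold) & (df["q_rank"] - df["rank"] >= delta)]
    return hits.sort_values("rank", kind="mergesort").copy()


def read_homolog_map(path) -> pd.DataFrame:
    """Two-column TSV (source gene id, target gene id), header required;
    many-to-many allowed, duplicate pairs rejected."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError("homolog map must have exactly two columns")
    df.columns = ["gene_id_source", "gene_id_target"]
    if df.duplicated().any():
        raise ValueError("duplicate homolog pairs in map")
    return df


def cross_model_validate(
    candidates: pd.DataFrame,
    homolog_map: pd.DataFrame,
    external_de: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Check candidates in an external (e.g. cross-species) DE table.

    A candidate is ``validated`` when any mapped homolog is significant in
    the external table (p < alpha, deliberately uncorrected) with the same
    direction of change; ``no_homolog`` when absent from the map; otherwise
    ``not_validated``. The reported external p / direction refer to the
    best-supported homolog.
    """
    by_source = homolog_map.groupby("gene_id_source")["gene_id_target"].apply(list)
    rows = []
    for gene_id, row in candidates.iterrows():
        homologs = by_source.get(gene_id, [])
        if not homologs:
            rows.append(
                {"gene_id": gene_id, "status": "no_homolog", "homolog": "",
                 "external_p": np.nan, "direction_match": False}
            )
            continue
        present = [h for h in homologs if h in external_de.index]
        status, best_h, best_p, match = "not_validated", "", np.nan, False
        # prefer significant+matching homologs, then the smallest p overall
        ranked = sorted(
            present, key=lambda h: (float(external_de.loc[h, "p"]),)
        )
        for h in ranked:
            ext_p = float(external_de.loc[h, "p"])
            same_dir = np.sign(external_de.loc[h, "log2fc"]) == np.sign(row["log2fc"])
            if ext_p < alpha and same_dir:
                status, best_h, best_p, match = "validated", h, ext_p, True
                break
        if status != "validated" and ranked:
            best_h = ranked[0]
            best_p = float(external_de.loc[best_h, "p"])
            match = bool(
                np.sign(external_de.loc[best_h, "log2fc"]) == np.sign(row["log2fc"])
            )
        rows.append(
            {"gene_id": gene_id, "status": status, "homolog": best_h,
             "external_p": best_p, "direction_match": match}
        )
    return pd.DataFrame(rows).set_index("gene_id")
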