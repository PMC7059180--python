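"""Count/metadata ingestion, library QC filters, CPM, expressed-gene calls and
region-specificity classification.

The unit of expression throughout is CPM (counts per million): each library's
counts scaled by its column total. A gene is called *expressed* in a region
when its mean CPM across that region's retained samples exceeds a threshold
(default 1.0, strict ``>``). A gene expressed in exactly one region is
*region-specific*; in two or more, *shared*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "CpmMatrix",
    "ExpressionCallSet",
    "read_counts",
    "read_metadata",
    "read_gmt",
    "write_gmt",
    "validate_metadata",
    "filter_libraries",
    "compute_cpm",
    "call_expressed",
    "classify_specificity",
]

METADATA_COLUMNS = (
    "sample_id",
    "region",
    "condition",
    "age",
    "sex",
    "RIN",
    "annotated_reads",
    "library_size",
)


@dataclass
class CountMatrix:
    """Gene x sample matrix of nonnegative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by gene_id with sample_id columns; integer cells.
    biotype
        Optional per-gene biotype labels ("PCG" / "lncRNA"), aligned to
        ``counts.index``.
    """

    counts: pd.DataFrame
    biotype: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (values < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        if self.biotype is not None:
            self.biotype = self.biotype.reindex(self.counts.index)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.biotype)


@dataclass
class CpmMatrix:
    """Counts-per-million matrix; every column sums to 1e6."""

    cpm: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.cpm.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1e6, rtol=1e-6):
            raise ValueError("CPM columns must sum to 1e6")

    @property
    def gene_ids(self) -> pd.Index:
        return self.cpm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.cpm.columns


@dataclass
class ExpressionCallSet:
    """Expressed-gene call for one region.

    ``universe`` records the full gene set the call was made over so that
    specificity classification can verify consistency across regions.
    """

    region: str
    expressed_genes: frozenset
    threshold: float
    rule: str = "mean"
    universe: tuple = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_counts(path) -> CountMatrix:
    """Read a counts TSV (rows gene_id, columns samples, optional biotype
    column) into a :class:`CountMatrix`."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise ValueError(f"count matrix parse error in {path}: {exc}") from exc
    biotype = None
    if "biotype" in df.columns:
        biotype = df.pop("biotype")
    return CountMatrix(df, biotype=biotype)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns and c != "library_size"]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id: {dup!r}")
    rin = meta["RIN"].to_numpy(dtype=float)
    if ((rin < 1) | (rin > 10)).any():
        raise ValueError("RIN values must lie in [1, 10]")
    if "library_size" in meta.columns:
        if (meta["annotated_reads"] > meta["library_size"]).any():
            raise ValueError("annotated_reads exceeds library_size")
    return meta


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    return validate_metadata(meta)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: ``set_name<TAB>description<TAB>gene...`` per line.

    Returns an insertion-ordered mapping of set name to gene list. Empty
    member lists are preserved as empty sets.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs name and description")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# QC filters and normalization
# ---------------------------------------------------------------------------

def filter_libraries(
    counts: CountMatrix,
    meta: pd.DataFrame,
    min_annotated_reads: int = 500_000,
    min_rin: float = 6.5,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Drop libraries with too few annotated reads or low RNA integrity.

    A sample is retained when ``annotated_reads >= min_annotated_reads`` and
    ``RIN > min_rin`` (strictly above). Returns the filtered matrix, the
    matching metadata subset, and an exclusion log with one row per dropped
    sample and a semicolon-joined reason field.
    """
    meta = validate_metadata(meta)
    meta_ids = set(meta["sample_id"])
    uncovered = [s for s in counts.sample_ids if s not in meta_ids]
    if uncovered:
        raise ValueError(f"metadata does not cover samples: {uncovered[:5]}")
    meta = meta.set_index("sample_id", drop=False).loc[list(counts.sample_ids)]

    reasons = []
    for _, row in meta.iterrows():
        why = []
        if row["annotated_reads"] < min_annotated_reads:
            why.append("low_annotated_reads")
        if row["RIN"] <= min_rin:
            why.append("low_rin")
        reasons.append(";".join(why))
    meta = meta.assign(_exclude_reason=reasons)
    excluded = meta[meta["_exclude_reason"] != ""]
    retained = meta[meta["_exclude_reason"] == ""]
    if retained.empty:
        raise ValueError("all samples excluded by library filters")
    log = excluded[["sample_id", "region", "annotated_reads", "RIN"]].copy()
    log["reason"] = excluded["_exclude_reason"].to_numpy()
    kept = retained.drop(columns="_exclude_reason").reset_index(drop=True)
    return counts.subset_samples(kept["sample_id"]), kept, log.reset_index(drop=True)


def compute_cpm(counts: CountMatrix) -> CpmMatrix:
    """Library-size normalization: ``cpm = counts / column_sum * 1e6``."""
    colsums = counts.counts.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"zero-sum count column: {zero.index[0]!r}")
    return CpmMatrix(counts.counts / colsums * 1e6)


def call_expressed(
    cpm: CpmMatrix,
    meta: pd.DataFrame,
    region: str,
    threshold: float = 1.0,
) -> ExpressionCallSet:
    """Call genes expressed in ``region``: mean CPM across the region's
    samples strictly above ``threshold``."""
    samples = meta.loc[meta["region"] == region, "sample_id"]
    if samples.empty:
        raise ValueError(f"no samples for region {region!r}")
    mean_cpm = cpm.cpm[list(samples)].mean(axis=1)
    expressed = frozenset(mean_cpm.index[mean_cpm > threshold])
    return ExpressionCallSet(
        region=region,
        expressed_genes=expressed,
        threshold=threshold,
        rule="mean",
        universe=tuple(cpm.gene_ids),
    )


def classify_specificity(callsets: list[ExpressionCallSet]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every gene by the set of regions it is expressed in.

    Returns ``(specificity, venn)``: a per-gene table with columns
    ``regions_expressed`` (comma-joined) and ``class`` (``region-specific:R``,
    ``shared`` or ``not-expressed``), and a Venn-style table of counts per
    region combination.
    """
    if len(callsets) < 2:
        raise ValueError("specificity needs at least two regions")
    universe = callsets[0].universe
    for cs in callsets[1:]:
        if cs.universe != universe:
            raise ValueError("callsets have inconsistent gene universes")
    regions = [cs.region for cs in callsets]
    member = pd.DataFrame(
        {cs.region: [g in cs.expressed_genes for g in universe] for cs in callsets},
        index=pd.Index(universe, name="gene_id"),
    )
    n_regions = member.sum(axis=1)
    regions_expressed = member.apply(lambda r: ",".join(c for c in regions if r[c]), axis=1)
    cls = pd.Series("shared", index=member.index)
    cls[n_regions == 0] = "not-expressed"
    single = n_regions == 1
    cls[single] = "region-specific:" + regions_expressed[single]
    spec = pd.DataFrame({"regions_expressed": regions_expressed, "class": cls})

    combos = member.groupby(regions).size()
    venn = combos.reset_index(name="n_genes")
    venn["combination"] = [
        ",".join(c for c, flag in zip(regions, key) if flag) or "none"
        for key in (venn[regions].itertuples(index=False, name=None))
    ]
    venn = venn[["combination", "n_genes"]].sort_values("combination").reset_index(drop=True)
    return spec, venn
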