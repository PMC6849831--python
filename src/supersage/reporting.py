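"""Functional reporting over annotated, differentially expressed tags.

Annotation assignment itself (BLASTX, GO mapping) is an external,
database-dependent step; this module ingests its tabular output and
computes the summary views of a two-library tag study: Gene Ontology
category distributions, catalytic-activity breakdowns within a category,
top-hit species distributions, Venn partitions of functional groups by
expression direction (tags collapsed to genes), top-N tables, and the
bioassay-derived resistance-ratio / fiducial-limit utilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import percent
from .dge import DGERecord, dge_frame

REQUIRED_COLUMNS = ("tag_code", "protein_desc", "species", "evalue", "direction")
OPTIONAL_COLUMNS = ("contig_id", "go_categories", "functional_group",
                    "catalytic_activity", "gene_id")
DIRECTIONS = ("OE", "UE")


class AnnotationError(ValueError):
    pass


@dataclass
class VennPartition:
    """Gene-level partition of a functional group by expression direction."""

    n_oe_only: int
    n_ue_only: int
    n_shared: int
    n_unique_genes: int
    n_tags: int

    def __post_init__(self) -> None:
        assert self.n_unique_genes == self.n_oe_only + self.n_ue_only + self.n_shared


@dataclass
class BioassayResult:
    """An LC50 estimate with its 95% fiducial limits and probit slope."""

    lc50: float
    fl_low: float
    fl_high: float
    slope: float = float("nan")
    slope_se: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.fl_low <= self.lc50 <= self.fl_high):
            raise ValueError("fiducial limits must bracket the LC50")


def load_annotations(path: str | Path, on_invalid: str = "error") -> pd.DataFrame:
    """Load and validate a tag annotation table (TSV).

    Required columns: tag_code, protein_desc, species, evalue, direction.
    Rows with a negative E-value or a direction outside {OE, UE} are
    invalid; ``on_invalid='error'`` raises an :class:`AnnotationError`
    listing the offending line numbers, ``'skip'`` drops them.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing required column(s): {missing}")
    evalue = pd.to_numeric(df["evalue"], errors="coerce")
    bad = evalue.isna() | (evalue < 0) | ~df["direction"].isin(DIRECTIONS)
    if bad.any():
        # +2: 1-based line numbers counting the header
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        if on_invalid == "error":
            raise AnnotationError(f"{path}: invalid rows at lines {lines}")
        if on_invalid != "skip":
            raise ValueError(f"unknown on_invalid mode: {on_invalid!r}")
        df = df[~bad].reset_index(drop=True)
        evalue = evalue[~bad].reset_index(drop=True)
    df = df.copy()
    df["evalue"] = evalue.astype(float)
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def _gene_key(df: pd.DataFrame) -> pd.Series:
    """Gene identity used to collapse tags: gene_id, falling back to the
    protein description where gene_id is absent."""
    if "gene_id" in df.columns:
        gid = df["gene_id"].astype(str)
        return gid.where(gid != "", df["protein_desc"])
    return df["protein_desc"]


def category_distribution(records: pd.DataFrame,
                          denominator: str = "annotated") -> pd.DataFrame:
    """Counts and percentages per GO category.

    ``go_categories`` may hold several semicolon-separated categories per
    tag.  The percentage denominator is selectable: ``'annotated'`` (all
    records) or ``'go_assigned'`` (records with at least one category) --
    published category percentages are not always consistent about which
    of the two they use, so both are first-class.  Percentages are rounded
    half-even to two decimals.
    """
    cats = records["go_categories"].astype(str).str.split(";")
    exploded = (records.assign(_cat=cats).explode("_cat"))
    exploded["_cat"] = exploded["_cat"].str.strip()
    exploded = exploded[exploded["_cat"] != ""]
    if denominator == "annotated":
        denom = len(records)
    elif denominator == "go_assigned":
        denom = int((records["go_categories"].astype(str).str.strip() != "").sum())
    else:
        raise ValueError(f"unknown denominator: {denominator!r}")
    counts = exploded["_cat"].value_counts()
    return pd.DataFrame({
        "category": counts.index,
        "count": counts.to_numpy(),
        "percent": [percent(c, denom) for c in counts.to_numpy()],
    }).reset_index(drop=True)


def catalytic_breakdown(records: pd.DataFrame,
                        category: str = "metabolism") -> pd.DataFrame:
    """Catalytic-activity counts within one GO category.

    The denominator for the within-category percentages is the number of
    records assigned to the category.
    """
    in_cat = records["go_categories"].astype(str).str.split(";").apply(
        lambda cs: category in [c.strip() for c in cs])
    subset = records[in_cat]
    denom = len(subset)
    acts = subset["catalytic_activity"].astype(str).str.strip()
    counts = acts[acts != ""].value_counts()
    return pd.DataFrame({
        "catalytic_activity": counts.index,
        "count": counts.to_numpy(),
        "percent": [percent(c, denom, decimals=1) for c in counts.to_numpy()],
    }).reset_index(drop=True)


def venn_partition(records: pd.DataFrame,
                   group_prefix: str | None = None) -> VennPartition:
    """Partition a functional group's genes by expression direction.

    Tags are collapsed to genes (see :func:`_gene_key`); a gene whose tags
    appear only among OE records counts as OE-only, only among UE as
    UE-only, and in both directions as shared.  ``group_prefix`` filters
    on the ``functional_group`` column by prefix (e.g. ``'serine_protease'``
    covers both trypsin- and chymotrypsin-like subgroups); None uses all
    records.
    """
    df = records
    if group_prefix is not None:
        df = df[df["functional_group"].astype(str).str.startswith(group_prefix)]
    genes = _gene_key(df)
    directions = df["direction"]
    by_gene = pd.DataFrame({"gene": genes, "dir": directions}).groupby("gene")["dir"]
    dir_sets = by_gene.agg(lambda s: frozenset(s))
    n_oe = int((dir_sets == frozenset({"OE"})).sum())
    n_ue = int((dir_sets == frozenset({"UE"})).sum())
    n_shared = int((dir_sets == frozenset({"OE", "UE"})).sum())
    return VennPartition(n_oe, n_ue, n_shared, n_oe + n_ue + n_shared, len(df))


def species_distribution(records: pd.DataFrame) -> pd.DataFrame:
    """Top-hit species counts and percentages of annotated records,
    sorted descending."""
    counts = records["species"].value_counts()
    denom = len(records)
    return pd.DataFrame({
        "species": counts.index,
        "count": counts.to_numpy(),
        "percent": [percent(c, denom) for c in counts.to_numpy()],
    }).reset_index(drop=True)


def top_table(dge_records: Sequence[DGERecord] | pd.DataFrame,
              annotations: pd.DataFrame | None,
              n: int, direction: str) -> pd.DataFrame:
    """Top-N report table for one expression direction.

    OE tables rank by fold change descending and report FC; UE tables rank
    by log2(FC) ascending and report the log2 value.  Ties are broken by
    tag sequence lexicographically, making the ordering a total order.
    Annotations (optional) are joined on the 26-bp tag sequence via their
    ``tag_seq_26`` or ``tag_code`` column.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    df = dge_records if isinstance(dge_records, pd.DataFrame) else dge_frame(list(dge_records))
    df = df[df["class"] == direction].copy()
    if direction == "OE":
        df = df.sort_values(["FC", "tag_seq_26"], ascending=[False, True])
        value_col = "FC"
    else:
        df = df.sort_values(["log2FC", "tag_seq_26"], ascending=[True, True])
        value_col = "log2FC"
    df = df.head(n)
    out = df[["tag_seq_26", "tag_seq_22", "x", "y", value_col, "p"]].reset_index(drop=True)
    if annotations is not None and len(annotations):
        ann = annotations.copy()
        key = "tag_seq_26" if "tag_seq_26" in ann.columns else "tag_code"
        ann = ann.set_index(key)
        keep = [c for c in ("contig_id", "protein_desc", "species", "evalue")
                if c in ann.columns]
        out = out.join(ann[keep], on="tag_seq_26")
    return out


def resistance_ratio(lc50_resistant: float,
                     lc50_susceptible: float) -> tuple[float, int]:
    """Resistance ratio = LC50(resistant) / LC50(susceptible).

    Returns the raw ratio and its nearest-integer form (the convention for
    reporting whole-fold resistance levels).
    """
    if lc50_resistant <= 0 or lc50_susceptible <= 0:
        raise ValueError("LC50 values must be positive")
    ratio = lc50_resistant / lc50_susceptible
    return ratio, int(round(ratio))


def fl_overlap_significant(interval_a: tuple[float, float],
                           interval_b: tuple[float, float]) -> bool:
    """Significance by the fiducial-limit rule: two LC50s differ
    significantly (P < 0.05) iff their 95% fiducial intervals are disjoint.
    Touching intervals count as overlapping (conservative)."""
    for lo, hi in (interval_a, interval_b):
        if lo > hi:
            raise ValueError(f"malformed interval: ({lo}, {hi})")
    a_lo, a_hi = interval_a
    b_lo, b_hi = interval_b
    return a_hi < b_lo or b_hi < a_lo


def summary_text(dge_summary, stats=None, extra: dict | None = None) -> str:
    """Plain-text run summary used by the pipeline report stage."""
    lines = ["SuperSAGE run summary", "====================="]
    if stats is not None:
        lines.append(f"reads total:        {stats.reads_total}")
        for lab, n in stats.reads_per_index.items():
            lines.append(f"reads {lab}:         {n}")
        lines.append(f"reads unassigned:   {stats.reads_unassigned}")
        lines.append(f"tags kept:          {stats.tags_kept}")
        lines.append(f"unique tags:        {stats.unique_tags}")
        lines.append(f"singletons removed: {stats.singletons_removed}")
    lines.append(f"tags tested:        {dge_summary.n_total}")
    lines.append(f"overexpressed:      {dge_summary.n_oe}")
    lines.append(f"underexpressed:     {dge_summary.n_ue}")
    lines.append(f"percent DE:         {dge_summary.percent_de}")
    for key, value in (extra or {}).items():
        lines.append(f"{key}: {value}")
    return "\n".join(lines) + "\n"
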