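"""Differential expression of SAGE tag counts between two libraries.

The statistic is the exact Audic-Claverie model for comparing a tag's
counts x and y observed in libraries of total sizes N1 and N2.  Under the
null hypothesis of equal relative expression, the probability of observing
y copies in library 2 given x copies in library 1 is

    p(y|x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

a negative-binomial distribution over y.  Tail sums give a one-sided
probability; the two-sided P value reported here doubles the smaller tail
and caps at 1.  Terms are evaluated in log space via the log-gamma
function, so large counts and very unequal library sizes are safe.

Counts are put on a common scale with a normalization factor NF chosen
below the smaller library total: normalized value = (x / N) * NF.  Fold
change (library 1 over library 2) substitutes raw zero counts with 1
before normalizing, so tags absent from one library still get a finite
ratio.  Tags are classified overexpressed (OE) when FC >= fc_up and
P < alpha, underexpressed (UE) when FC <= fc_down and P < alpha, and not
significant (NS) otherwise; the fold-change boundaries are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._util import percent
from .extraction import TagCountTable


@dataclass
class ClassificationThresholds:
    fc_up: float = 2.5
    fc_down: float = 0.4
    alpha: float = 0.05

    def validate(self) -> None:
        if not (self.fc_down < 1.0 < self.fc_up):
            raise ValueError("need fc_down < 1 < fc_up")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class DGERecord:
    """One tag's counts, normalized values, fold change, P value and class."""

    tag: str
    x: int
    y: int
    x_eff: int
    y_eff: int
    norm1: float
    norm2: float
    fc: float
    log2_fc: float
    p: float
    label: str  # OE / UE / NS


@dataclass
class DGESummary:
    n_total: int
    n_oe: int
    n_ue: int
    percent_de: float


def choose_nf(n1: int, n2: int, override: float | None = None) -> float:
    """Normalization factor: the largest multiple of 1000 strictly below
    the smaller library total; a user override must not exceed that total.

    Note the edge case: totals that are exact multiples of 1000 step down
    one unit (e.g. min 5000 -> NF 4000), since NF must be *below* the total.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    smaller = min(n1, n2)
    if override is not None:
        if override > smaller:
            raise ValueError(
                f"NF override {override} exceeds the smaller library total {smaller}")
        if override <= 0:
            raise ValueError("NF must be positive")
        return float(override)
    nf = (smaller - 1) // 1000 * 1000
    if nf <= 0:
        raise ValueError(
            f"smaller library total {smaller} too small for the default NF rule; "
            "pass an explicit NF")
    return float(nf)


def normalize(x: float, total: int, nf: float) -> float:
    """Normalized tag value: (x / library total) * NF, real-valued."""
    if total <= 0:
        raise ValueError("library total must be positive")
    return x / total * nf


def audic_claverie_p(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie P value for counts x, y in libraries of
    sizes N1, N2.

    The lower tail is sum_{k=0..y} p(k|x), the upper tail
    1 - sum_{k=0..y-1} p(k|x); the reported P is twice the smaller tail,
    capped at 1.  Always in (0, 1].
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    log_r = np.log(n2) - np.log(n1)
    log1pr = np.logaddexp(0.0, log_r)  # log(1 + N2/N1)
    k = np.arange(y + 1)
    log_terms = (k * log_r + gammaln(x + k + 1) - gammaln(x + 1)
                 - gammaln(k + 1) - (x + k + 1) * log1pr)
    terms = np.exp(log_terms)
    t_low = float(terms.sum())
    t_high = 1.0 - (t_low - float(terms[-1]))
    if t_high < 1e-8:
        # the complement form cancels catastrophically for tiny upper
        # tails; sum the tail directly from k = y (geometric convergence,
        # term ratio -> r/(1+r) < 1)
        ratio = np.exp(log_r - log1pr)
        term = float(np.exp(log_terms[-1]))
        t_high = term
        kk = y
        while term > t_high * 1e-17:
            term *= ratio * (x + kk + 1) / (kk + 1)
            t_high += term
            kk += 1
    p = 2.0 * min(t_low, t_high)
    if p >= 1.0 - 1e-12:  # within round-off of the cap (e.g. exactly x == y)
        return 1.0
    return float(max(p, 5e-324))


def fold_change(x: int, y: int, n1: int, n2: int,
                nf: float) -> tuple[int, int, float, float, float, float]:
    """Normalized fold change with the zero-to-one substitution.

    Raw counts of 0 are set to 1 *before* normalization; returns
    ``(x_eff, y_eff, norm1, norm2, FC, log2FC)`` with FC = norm1/norm2.
    """
    x_eff = max(x, 1)
    y_eff = max(y, 1)
    norm1 = normalize(x_eff, n1, nf)
    norm2 = normalize(y_eff, n2, nf)
    fc = norm1 / norm2
    return x_eff, y_eff, norm1, norm2, fc, float(np.log2(fc))


def classify(fc: float, p: float,
             thresholds: ClassificationThresholds | None = None) -> str:
    """OE / UE / NS call; fold-change boundaries are inclusive."""
    t = thresholds or ClassificationThresholds()
    t.validate()
    if p < t.alpha:
        if fc >= t.fc_up:
            return "OE"
        if fc <= t.fc_down:
            return "UE"
    return "NS"


def summarize(n_total: int, n_oe: int, n_ue: int) -> DGESummary:
    """Summary with percent DE = 100*(OE+UE)/total to one decimal."""
    return DGESummary(n_total, n_oe, n_ue,
                      percent(n_oe + n_ue, n_total, decimals=1))


def run_dge(table: TagCountTable,
            thresholds: ClassificationThresholds | None = None,
            nf: float | None = None) -> tuple[list[DGERecord], DGESummary]:
    """Test every tag of a (singleton-free) count table.

    Library 1 is the table's first column.  Returns one record per tag and
    a summary with the OE/UE counts and the percent differentially
    expressed.
    """
    t = thresholds or ClassificationThresholds()
    t.validate()
    labels = table.lib_labels
    if len(labels) != 2:
        raise ValueError("differential expression requires exactly two libraries")
    if len(table.counts) == 0:
        return [], summarize(0, 0, 0)
    n1 = table.totals[labels[0]]
    n2 = table.totals[labels[1]]
    nf_val = choose_nf(n1, n2, override=nf)

    records: list[DGERecord] = []
    n_oe = n_ue = 0
    xs = table.counts[labels[0]].to_numpy()
    ys = table.counts[labels[1]].to_numpy()
    for tag, x, y in zip(table.counts.index, xs, ys):
        x = int(x)
        y = int(y)
        p = audic_claverie_p(x, y, n1, n2)
        x_eff, y_eff, norm1, norm2, fc, log2_fc = fold_change(x, y, n1, n2, nf_val)
        label = classify(fc, p, t)
        if label == "OE":
            n_oe += 1
        elif label == "UE":
            n_ue += 1
        records.append(DGERecord(tag, x, y, x_eff, y_eff, norm1, norm2,
                                 fc, log2_fc, p, label))
    return records, summarize(len(records), n_oe, n_ue)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted P values (optional, off by default in
    the pipeline; the primary analysis uses raw P < alpha)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def dge_frame(records: list[DGERecord]) -> pd.DataFrame:
    """Records as a table mirroring the per-tag report layout."""
    return pd.DataFrame({
        "tag_seq_26": [r.tag for r in records],
        "tag_seq_22": [r.tag[4:] for r in records],
        "x": [r.x for r in records],
        "y": [r.y for r in records],
        "norm1": [r.norm1 for r in records],
        "norm2": [r.norm2 for r in records],
        "FC": [r.fc for r in records],
        "log2FC": [r.log2_fc for r in records],
        "p": [r.p for r in records],
        "class": [r.label for r in records],
    })


def write_dge_results(records: list[DGERecord], path: str | Path) -> Path:
    path = Path(path)
    dge_frame(records).to_csv(path, sep="\t", index=False)
    return path


def fc_histogram(records: list[DGERecord],
                 bin_edges: dict[str, list[float]] | list[float],
                 ) -> pd.DataFrame:
    """Per-class fold-change histogram.

    ``bin_edges`` is either one ascending edge list used for every class or
    a mapping class -> edges.  Bins follow histogram convention: left-closed,
    right-open, except the last bin which is closed on both sides.  Fractions
    are relative to the number of records in the class and reported as NaN
    for an empty class (never 0/0 = 0).
    """
    if isinstance(bin_edges, dict):
        per_class = bin_edges
    else:
        per_class = {label: list(bin_edges) for label in ("OE", "UE")}
    rows = []
    for label, edges in per_class.items():
        edges = list(edges)
        if sorted(edges) != edges or len(edges) < 2:
            raise ValueError(f"bin edges for {label} must be ascending: {edges}")
        values = np.array([r.fc for r in records if r.label == label])
        hist, _ = np.histogram(values, bins=edges)
        n_class = len(values)
        for lo, hi, count in zip(edges[:-1], edges[1:], hist):
            rows.append({
                "class": label, "fc_low": lo, "fc_high": hi,
                "count": int(count),
                "fraction": (count / n_class) if n_class else np.nan,
            })
    return pd.DataFrame(rows)
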