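"""Demultiplexing, NlaIII-anchored tag extraction and quality filtering.

Reads are assigned to libraries by an exact match of their first four bases
against the library index map.  The candidate tag is the substring starting
at read position 5 (1-based) that begins with the anchoring-enzyme site
CATG and ends immediately before the first occurrence of the adapter-2
prefix.  Candidates then pass four filters, applied in a fixed order so
failure accounting is deterministic:

1. length   -- exactly 26 bp (EcoP15I length variants are discarded),
2. n_base   -- no undetermined bases,
3. homopolymer -- no single-base run longer than 10 bp,
4. low_quality -- fewer than 3 positions with Phred quality < 10.

Counting keeps per-library totals of all kept tags; tags seen exactly once
in the two libraries combined (singletons) are removed afterwards, without
recomputing the totals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import max_homopolymer_run, open_text

#: sentinel returned by :func:`demultiplex` for reads matching no index
UNASSIGNED = "UNASSIGNED"

#: rejection reasons from :func:`extract_tag`
NO_ANCHOR = "no_anchor"
NO_ADAPTER = "no_adapter"

#: failure reasons from :func:`quality_filter`, in the order they are tested
FILTER_REASONS = ("length", "n_base", "homopolymer", "low_quality")

_REASON_FIELD = {"length": "fail_length", "n_base": "fail_n",
                 "homopolymer": "fail_homopolymer", "low_quality": "fail_quality"}

_LOW_QUALITY_PHRED = 10   # positions strictly below this are "low quality"
_MAX_LOW_POSITIONS = 2    # more than this many low positions -> fail
_MAX_HOMOPOLYMER = 10     # runs strictly longer than this -> fail
TAG_LENGTH = 26


@dataclass
class TagCountTable:
    """Per-tag raw counts in each library plus the library totals.

    ``counts`` is indexed by the 26-bp tag sequence with one integer column
    per library label.  ``totals`` holds the per-library total number of
    kept tags, fixed at counting time; singleton removal does not change
    them (the statistics use pre-removal totals).
    """

    counts: pd.DataFrame
    totals: dict[str, int]

    @property
    def lib_labels(self) -> list[str]:
        return list(self.counts.columns)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class ExtractionStats:
    """Read-accounting ledger for one counting run."""

    reads_total: int = 0
    reads_per_index: dict[str, int] = field(default_factory=dict)
    reads_unassigned: int = 0
    fail_no_anchor: int = 0
    fail_no_adapter: int = 0
    fail_length: int = 0
    fail_n: int = 0
    fail_homopolymer: int = 0
    fail_quality: int = 0
    tags_kept: int = 0
    unique_tags: int = 0
    singletons_removed: int = 0

    @property
    def reads_assigned(self) -> int:
        return sum(self.reads_per_index.values())

    def check(self) -> None:
        """Assert the conservation identities of the ledger."""
        assert self.reads_total == self.reads_assigned + self.reads_unassigned
        assert self.reads_assigned == (
            self.tags_kept + self.fail_no_anchor + self.fail_no_adapter
            + self.fail_length + self.fail_n + self.fail_homopolymer
            + self.fail_quality)

    def to_frame(self) -> pd.DataFrame:
        rows = [("reads_total", self.reads_total)]
        rows += [(f"reads_index_{k}", v) for k, v in self.reads_per_index.items()]
        rows += [
            ("reads_unassigned", self.reads_unassigned),
            ("fail_no_anchor", self.fail_no_anchor),
            ("fail_no_adapter", self.fail_no_adapter),
            ("fail_length", self.fail_length),
            ("fail_n", self.fail_n),
            ("fail_homopolymer", self.fail_homopolymer),
            ("fail_quality", self.fail_quality),
            ("tags_kept", self.tags_kept),
            ("unique_tags", self.unique_tags),
            ("singletons_removed", self.singletons_removed),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def demultiplex(sequence: str, index_map: Mapping[str, str]) -> str:
    """Return the library label whose 4-bp index equals the read's first
    four bases, or :data:`UNASSIGNED`.  Matching is exact (0 mismatches)."""
    if len(sequence) < 4:
        return UNASSIGNED
    return index_map.get(sequence[:4], UNASSIGNED)


def extract_tag(sequence: str, qualities: str,
                adapter2_prefix: str) -> tuple[str, str] | str:
    """Extract the CATG-anchored candidate tag from a demultiplexed read.

    Returns ``(tag, quality_slice)`` on success, else the rejection reason
    :data:`NO_ANCHOR` (bases 5-8 are not CATG) or :data:`NO_ADAPTER`
    (the adapter-2 prefix never occurs after the anchor).
    """
    if sequence[4:8] != "CATG":
        return NO_ANCHOR
    end = sequence.find(adapter2_prefix, 4)
    if end < 0:
        return NO_ADAPTER
    return sequence[4:end], qualities[4:end]


def quality_filter(tag: str, qualities: str) -> str | None:
    """Apply the four tag filters; return None on PASS, else the first
    failing reason among :data:`FILTER_REASONS` (fixed order)."""
    if len(tag) != TAG_LENGTH:
        return "length"
    for base in tag:
        if base not in "ACGT":
            return "n_base"
    if max_homopolymer_run(tag) > _MAX_HOMOPOLYMER:
        return "homopolymer"
    n_low = sum(1 for q in qualities if ord(q) - 33 < _LOW_QUALITY_PHRED)
    if n_low > _MAX_LOW_POSITIONS:
        return "low_quality"
    return None


def count_tags(fastq_paths: Iterable[str | Path],
               index_map: Mapping[str, str],
               adapter2_prefix: str) -> tuple[TagCountTable, ExtractionStats]:
    """Build the per-library tag count table from FASTQ files.

    ``index_map`` maps each 4-bp index to its library label; the column
    order of the resulting table follows the mapping's insertion order.
    Library totals are the totals of kept (post-filter) tags.
    """
    for idx in index_map:
        if len(idx) != 4:
            raise ValueError(f"index {idx!r} is not 4 bp")
    labels = list(dict.fromkeys(index_map.values()))
    stats = ExtractionStats(reads_per_index={lab: 0 for lab in labels})
    counters: dict[str, Counter[str]] = {lab: Counter() for lab in labels}

    for path in fastq_paths:
        record_no = 0
        try:
            with open_text(path) as fh:
                for _title, seq, qual in FastqGeneralIterator(fh):
                    record_no += 1
                    stats.reads_total += 1
                    seq = seq.upper()
                    label = demultiplex(seq, index_map)
                    if label == UNASSIGNED:
                        stats.reads_unassigned += 1
                        continue
                    stats.reads_per_index[label] += 1
                    extracted = extract_tag(seq, qual, adapter2_prefix)
                    if extracted == NO_ANCHOR:
                        stats.fail_no_anchor += 1
                        continue
                    if extracted == NO_ADAPTER:
                        stats.fail_no_adapter += 1
                        continue
                    tag, tag_qual = extracted
                    reason = quality_filter(tag, tag_qual)
                    if reason is not None:
                        attr = _REASON_FIELD[reason]
                        setattr(stats, attr, getattr(stats, attr) + 1)
                        continue
                    counters[label][tag] += 1
                    stats.tags_kept += 1
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record ~{record_no + 1} in {path}: {exc}"
            ) from exc

    all_tags = sorted(set().union(*(c.keys() for c in counters.values())))
    counts = pd.DataFrame(
        {lab: [counters[lab].get(t, 0) for t in all_tags] for lab in labels},
        index=pd.Index(all_tags, name="tag"), dtype=int)
    totals = {lab: int(counts[lab].sum()) for lab in labels}
    stats.unique_tags = len(counts)
    stats.check()
    return TagCountTable(counts, totals), stats


def remove_singletons(table: TagCountTable) -> tuple[TagCountTable, int]:
    """Drop tags seen exactly once in the combined libraries.

    Library totals are intentionally left at their pre-removal values
    (the normalization and the significance test use totals of all kept
    tags).  Returns the filtered table and the number of tags removed.
    """
    if len(table.counts) == 0:
        return TagCountTable(table.counts.copy(), dict(table.totals)), 0
    combined = table.counts.sum(axis=1)
    keep = combined >= 2
    n_removed = int((~keep).sum())
    return TagCountTable(table.counts[keep].copy(), dict(table.totals)), n_removed


def write_tag_counts(table: TagCountTable, path: str | Path) -> Path:
    """Write ``tag_counts.tsv`` with the 26-bp and 22-bp display forms."""
    path = Path(path)
    out = table.counts.copy()
    out.insert(0, "tag_seq_22", [t[4:] for t in out.index])
    out.index.name = "tag_seq_26"
    with open(path, "w") as fh:
        fh.write("# totals: " + " ".join(
            f"{k}={v}" for k, v in table.totals.items()) + "\n")
        out.to_csv(fh, sep="\t")
    return path


def read_tag_counts(path: str | Path) -> TagCountTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# totals:"):
            raise ValueError(f"{path}: missing totals header line")
        totals = {}
        for item in header.split(":", 1)[1].split():
            k, v = item.split("=")
            totals[k] = int(v)
        df = pd.read_csv(fh, sep="\t", index_col="tag_seq_26")
    df = df.drop(columns=["tag_seq_22"])
    df.index.name = "tag"
    return TagCountTable(df[list(totals)].astype(int), totals)
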