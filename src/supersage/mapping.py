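"""Exact 26-mer mapping of tags onto reference contigs.

The acceptance rule for annotating a tag is a perfect 26-nt match, so the
reference is indexed as a hash of every 26-mer on both strands; partial or
mismatched placements are never reported ("no hit").  A hit is *canonical*
when it starts at the contig's 3'-most CATG that still has 22 bp of
non-poly-A sequence downstream -- the position SuperSAGE tags are expected
to derive from, since fragments are isolated from the NlaIII site closest
to the poly-A tail.  Minus-strand hits are always classified internal
(tags derive from the mRNA sense strand).

The module also provides an anchoring-enzyme motif scan used to compare
candidate 4-bp cutters (NlaIII/CATG, DpnII/GATC, BfaI/CTAG) across a
transcript set; all three default motifs are reverse-complement
palindromes, so overlapping occurrences are counted on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._util import reverse_complement

TAG_LENGTH = 26
DEFAULT_MOTIFS = ("CATG", "GATC", "CTAG")
DEFAULT_POLYA_MIN = 8  # trailing A-run length treated as a poly-A tract


@dataclass
class TagHit:
    tag: str
    contig_id: str
    start: int            # 0-based offset on the + strand
    strand: str           # '+' or '-'
    distance_to_3prime: int
    is_canonical: bool
    multiplicity: int


@dataclass
class VirtualTag:
    contig_id: str
    sequence: str         # up to 26 bp starting CATG
    truncated: bool       # fewer than 22 bp available downstream


@dataclass
class ReferenceIndex:
    contigs: dict[str, str]
    lookup: dict[str, list[tuple[str, int, str]]]
    canonical_start: dict[str, int]   # -1 when the contig has none
    polya_min: int = DEFAULT_POLYA_MIN


def _load_contigs(source: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(source, Mapping):
        return {str(k): str(v).upper() for k, v in source.items()}
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(source), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig id: {rec.id}")
        contigs[rec.id] = str(rec.seq).upper()
    return contigs


def _strip_polya(sequence: str, polya_min: int) -> str:
    """Sequence with its trailing poly-A run removed (if run >= polya_min)."""
    stripped = sequence.rstrip("A")
    if len(sequence) - len(stripped) >= polya_min:
        return stripped
    return sequence


def _canonical_start(sequence: str, polya_min: int) -> int:
    """Start of the 3'-most CATG with >= 22 bp downstream, poly-A excluded;
    -1 if there is none."""
    region = _strip_polya(sequence, polya_min)
    pos = region.rfind("CATG", 0, max(len(region) - TAG_LENGTH + 4, 0))
    # rfind end bound: CATG must start at <= len(region) - 26
    if pos >= 0 and pos + TAG_LENGTH <= len(region):
        return pos
    return -1


def build_index(source: str | Path | Mapping[str, str],
                polya_min: int = DEFAULT_POLYA_MIN) -> ReferenceIndex:
    """Index every 26-mer of both strands of the reference.

    26-mers containing N (or any non-ACGT base) are skipped.  Memory grows
    with twice the total reference length; intended for transcript-scale
    references.
    """
    contigs = _load_contigs(source)
    lookup: dict[str, list[tuple[str, int, str]]] = {}
    for cid, seq in contigs.items():
        for start in range(len(seq) - TAG_LENGTH + 1):
            kmer = seq[start:start + TAG_LENGTH]
            if any(b not in "ACGT" for b in kmer):
                continue
            lookup.setdefault(kmer, []).append((cid, start, "+"))
            rc = reverse_complement(kmer)
            lookup.setdefault(rc, []).append((cid, start, "-"))
    canonical = {cid: _canonical_start(seq, polya_min)
                 for cid, seq in contigs.items()}
    return ReferenceIndex(contigs, lookup, canonical, polya_min)


def map_tag(tag: str, index: ReferenceIndex) -> list[TagHit]:
    """All perfect full-length placements of ``tag``; empty list = no hit."""
    if len(tag) != TAG_LENGTH:
        raise ValueError(f"tag must be {TAG_LENGTH} bp, got {len(tag)}")
    placements = index.lookup.get(tag, [])
    hits = []
    for cid, start, strand in placements:
        contig_len = len(index.contigs[cid])
        hits.append(TagHit(
            tag=tag, contig_id=cid, start=start, strand=strand,
            distance_to_3prime=contig_len - (start + TAG_LENGTH),
            is_canonical=(strand == "+" and start == index.canonical_start[cid]),
            multiplicity=len(placements),
        ))
    return hits


def classify_hit_position(hit: TagHit, contig: str,
                          polya_min: int = DEFAULT_POLYA_MIN) -> str:
    """'canonical_3prime' iff the hit begins at the contig's 3'-most CATG
    with >= 22 bp downstream (poly-A excluded); minus-strand hits and all
    other placements are 'internal'."""
    if hit.strand != "+":
        return "internal"
    if hit.start == _canonical_start(contig, polya_min):
        return "canonical_3prime"
    return "internal"


def predict_virtual_tag(sequence: str, contig_id: str = "",
                        polya_min: int = DEFAULT_POLYA_MIN) -> VirtualTag | None:
    """Tag predicted in silico from a contig: the 3'-most CATG upstream of
    any trailing poly-A run plus up to 22 downstream non-poly-A bases.
    Returns None when the contig has no CATG outside the poly-A tract."""
    if not sequence:
        raise ValueError("contig sequence is empty")
    region = _strip_polya(sequence.upper(), polya_min)
    pos = region.rfind("CATG")
    if pos < 0:
        return None
    tag = region[pos:pos + TAG_LENGTH]
    return VirtualTag(contig_id, tag, truncated=len(tag) < TAG_LENGTH)


def _count_overlapping(sequence: str, motif: str) -> int:
    count = 0
    pos = sequence.find(motif)
    while pos >= 0:
        count += 1
        pos = sequence.find(motif, pos + 1)
    return count


def enzyme_site_scan(source: str | Path | Mapping[str, str] | Iterable,
                     motifs: Iterable[str] = DEFAULT_MOTIFS) -> pd.DataFrame:
    """Forward-strand motif frequencies over a contig set.

    Returns one row per motif with total occurrence count (overlapping),
    mean sites per contig and the fraction of contigs with at least one
    site (NaN for an empty contig set).
    """
    motifs = list(motifs)
    if any(not m for m in motifs):
        raise ValueError("empty motif")
    if isinstance(source, (str, Path, Mapping)):
        seqs = list(_load_contigs(source).values())
    else:
        seqs = [str(s).upper() for s in source]
    rows = []
    for motif in motifs:
        per_contig = np.array([_count_overlapping(s, motif) for s in seqs])
        rows.append({
            "motif": motif,
            "total_sites": int(per_contig.sum()) if len(seqs) else 0,
            "mean_sites_per_contig": float(per_contig.mean()) if len(seqs) else np.nan,
            "frac_contigs_with_site": float((per_contig > 0).mean()) if len(seqs) else np.nan,
        })
    return pd.DataFrame(rows)


def map_tags(tags: Iterable[str], index: ReferenceIndex) -> list[TagHit]:
    """Map many tags; tags without any perfect placement contribute no rows."""
    hits: list[TagHit] = []
    for tag in tags:
        hits.extend(map_tag(tag, index))
    return hits


def hits_frame(hits: list[TagHit]) -> pd.DataFrame:
    """Hits as a table; positions are reported 1-based for human readers."""
    return pd.DataFrame({
        "tag": [h.tag for h in hits],
        "contig": [h.contig_id for h in hits],
        "start_1based": [h.start + 1 for h in hits],
        "strand": [h.strand for h in hits],
        "canonical": [h.is_canonical for h in hits],
        "multiplicity": [h.multiplicity for h in hits],
        "distance_to_3prime": [h.distance_to_3prime for h in hits],
    })


def write_tag_hits(hits: list[TagHit], path: str | Path) -> Path:
    path = Path(path)
    hits_frame(hits).to_csv(path, sep="\t", index=False)
    return path
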