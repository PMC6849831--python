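"""Synthetic SuperSAGE data generator.

Emulates a two-library HT-SuperSAGE experiment: a transcriptome whose
transcripts end in a poly-A tract and (mostly) carry at least one NlaIII
site (CATG), per-transcript abundances with a designated differentially
expressed subset at a known fold change, and single-end reads laid out as

    4-bp library index + CATG-anchored tag (25-27 bp) + adapter-2 prefix,

padded or truncated to a fixed read length.  Tag-length variability mimics
the variable distance between the EcoP15I recognition and cleavage sites;
substitution errors, undetermined bases (N) and low-quality positions are
injected at configurable rates so every downstream extraction filter can
be exercised.

Every run is driven by a single numpy Generator seeded from the config, so
identical configurations produce byte-identical FASTA/FASTQ/TSV outputs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import max_homopolymer_run

log = logging.getLogger(__name__)

_BASES = np.array(["A", "C", "G", "T"])
# Constant used to extend reads past the adapter prefix up to read_len.
_ADAPTER_FILL = "TCGTATGCCGTCTTCTGCTTG"
_BASE_QUAL_CHAR = chr(33 + 35)   # Phred+33, Q35
_LOW_QUAL_CHAR = chr(33 + 2)     # Q2, well below the Q10 filter threshold


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig field is invalid; names the field."""


@dataclass
class SyntheticTranscript:
    id: str
    sequence: str            # A/C/G/T, ends in the configured poly-A tract
    has_nlaiii_site: bool    # at least one CATG upstream of the poly-A


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic transcriptome and reads.

    Defaults describe the emulated experiment: two libraries indexed GCCT
    (resistant) and GCAC (susceptible) with grossly unequal depths of about
    4:1, log-normal transcript abundances, 10% of transcripts differentially
    expressed at 8-fold, and mostly 26-bp tags with occasional 25/27-bp
    EcoP15I length variants.
    """

    n_transcripts: int = 20_000
    length_range: tuple[int, int] = (300, 1500)
    gc_fraction: float = 0.42
    polya_len: int = 18
    frac_with_site: float = 0.9
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 1.5
    de_fraction: float = 0.1
    de_fold: float = 8.0
    depth_lib1: int = 1_056_080
    depth_lib2: int = 268_172
    index_lib1: str = "GCCT"
    index_lib2: str = "GCAC"
    tag_len_probs: dict[int, float] = field(
        default_factory=lambda: {25: 0.15, 26: 0.70, 27: 0.15})
    substitution_error_rate: float = 0.001
    n_rate: float = 0.001
    low_quality_read_fraction: float = 0.02
    adapter2_prefix: str = "CTGCTGCGTA"
    read_len: int = 48
    seed: int = 2017

    def validate(self) -> None:
        def bad(name: str, why: str) -> ConfigurationError:
            return ConfigurationError(f"{name}: {why}")

        if self.n_transcripts < 1:
            raise bad("n_transcripts", "must be >= 1")
        lo, hi = self.length_range
        if lo < 30 or hi < lo:
            raise bad("length_range", "need 30 <= lo <= hi")
        for name in ("gc_fraction", "frac_with_site", "de_fraction",
                     "substitution_error_rate", "n_rate",
                     "low_quality_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise bad(name, "must be a proportion in [0, 1]")
        if self.polya_len < 1:
            raise bad("polya_len", "must be >= 1")
        if self.de_fold <= 1.0:
            raise bad("de_fold", "must be > 1")
        if self.depth_lib1 < 0 or self.depth_lib2 < 0:
            raise bad("depth_lib1/depth_lib2", "must be non-negative")
        for name in ("index_lib1", "index_lib2"):
            idx = getattr(self, name)
            if len(idx) != 4 or any(b not in "ACGT" for b in idx):
                raise bad(name, "must be a 4-bp ACGT string")
        if self.index_lib1 == self.index_lib2:
            raise bad("index_lib2", "library indexes must differ")
        if not self.tag_len_probs or abs(sum(self.tag_len_probs.values()) - 1.0) > 1e-9:
            raise bad("tag_len_probs", "probabilities must sum to 1")
        if any(t < 5 for t in self.tag_len_probs):
            raise bad("tag_len_probs", "tag lengths must be >= 5")
        if any(b not in "ACGT" for b in self.adapter2_prefix) or not self.adapter2_prefix:
            raise bad("adapter2_prefix", "must be a non-empty ACGT string")
        min_len = 4 + max(self.tag_len_probs) + len(self.adapter2_prefix)
        if self.read_len < min_len:
            raise bad("read_len", f"must be >= {min_len} to fit index+tag+adapter")


@dataclass
class SimulationResult:
    """Outputs of :func:`simulate_reads` plus bookkeeping oracles."""

    fastq_lib1: Path
    fastq_lib2: Path
    #: per-tag counts (columns lib1/lib2) of reads whose tag span is a clean,
    #: error-free 26-mer and that were not flagged low-quality -- with zero
    #: error rates this is exactly what a perfect extraction should recover.
    expected_counts: pd.DataFrame
    n_skipped_no_site: int


def _scrub_catg(core: np.ndarray) -> None:
    """Remove every CATG occurrence in-place (base array of single chars).

    Replacing the final G of an occurrence with T can never create a new
    CATG window, so one left-to-right pass converges.
    """
    s = "".join(core)
    pos = s.find("CATG")
    while pos >= 0:
        core[pos + 3] = "T"
        s = s[: pos + 3] + "T" + s[pos + 4:]
        pos = s.find("CATG", pos)


def generate_transcriptome(config: SimulationConfig) -> list[SyntheticTranscript]:
    """Generate ``n_transcripts`` random transcripts ending in poly-A.

    Exactly ``round(frac_with_site * n)`` transcripts carry a CATG site
    placed so that a full 26-bp tag (CATG + 22 bp) fits upstream of the
    poly-A tract; CATG occurrences are scrubbed from the remaining
    transcripts.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    n = config.n_transcripts
    n_site = int(round(config.frac_with_site * n))
    site_flags = np.zeros(n, dtype=bool)
    site_flags[rng.permutation(n)[:n_site]] = True

    lo, hi = config.length_range
    transcripts: list[SyntheticTranscript] = []
    polya = "A" * config.polya_len
    width = len(str(n - 1))
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        core = _BASES[rng.choice(4, size=length, p=probs)]
        _scrub_catg(core)
        # Keep the poly-A tract exactly the configured length: the core
        # must not end in A (and the patch must not create a CATG).
        if core[-1] == "A":
            choices = "CT" if "".join(core[-4:-1]) == "CAT" else "CGT"
            core[-1] = choices[rng.integers(len(choices))]
        if site_flags[i]:
            start = int(rng.integers(0, length - 26 + 1))
            core[start:start + 4] = list("CATG")
        seq = "".join(core) + polya
        transcripts.append(SyntheticTranscript(
            id=f"tx{str(i).zfill(width)}",
            sequence=seq,
            has_nlaiii_site=bool(site_flags[i]),
        ))
    return transcripts


def write_transcriptome(transcripts: Sequence[SyntheticTranscript],
                        path: str | Path) -> Path:
    """Write the transcriptome as single-line-per-record FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n{t.sequence}\n")
    return path


def _virtual_tag(sequence: str) -> str:
    """26-bp tag anchored at the 3'-most CATG, or "" if no site."""
    pos = sequence.rfind("CATG")
    if pos < 0:
        return ""
    return sequence[pos:pos + 26]


def assign_expression(transcripts: Sequence[SyntheticTranscript],
                      config: SimulationConfig) -> pd.DataFrame:
    """Draw abundances and designate the differentially expressed subset.

    Returns the ground-truth table indexed by transcript id with columns
    ``virtual_tag`` ("" when the transcript has no CATG site),
    ``abundance_1``, ``abundance_2`` and ``de_label`` in {OE, UE, NS}.
    Overexpressed transcripts get exactly ``de_fold`` times the base
    abundance in condition 1; underexpressed ones exactly ``1/de_fold``.
    Only site-bearing transcripts are eligible for the DE subset.
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n = len(transcripts)
    base = rng.lognormal(config.abundance_lognormal_mu,
                         config.abundance_lognormal_sigma, n)
    tagged = np.array([t.has_nlaiii_site for t in transcripts])
    n_de = int(round(config.de_fraction * n))
    if n_de > int(tagged.sum()):
        raise ValueError(
            f"de_fraction designates {n_de} DE transcripts but only "
            f"{int(tagged.sum())} carry an NlaIII site")
    de_idx = rng.permutation(np.flatnonzero(tagged))[:n_de]
    n_oe = n_de - n_de // 2  # any odd remainder goes to OE
    labels = np.array(["NS"] * n, dtype=object)
    labels[de_idx[:n_oe]] = "OE"
    labels[de_idx[n_oe:]] = "UE"

    ab1 = base.copy()
    ab1[labels == "OE"] *= config.de_fold
    ab1[labels == "UE"] /= config.de_fold
    truth = pd.DataFrame({
        "virtual_tag": [_virtual_tag(t.sequence) if t.has_nlaiii_site else ""
                        for t in transcripts],
        "abundance_1": ab1,
        "abundance_2": base,
        "de_label": labels,
    }, index=pd.Index([t.id for t in transcripts], name="transcript_id"))
    return truth


def simulate_reads(transcripts: Sequence[SyntheticTranscript],
                   truth: pd.DataFrame,
                   config: SimulationConfig,
                   out_lib1: str | Path,
                   out_lib2: str | Path) -> SimulationResult:
    """Sample reads from both libraries and write 4-line FASTQ files.

    Read counts per transcript are multinomial on the condition-specific
    abundances with totals ``depth_lib1``/``depth_lib2``.  Transcripts
    without a CATG site contribute no reads (logged).  Deterministic given
    ``config.seed``.
    """
    config.validate()
    ids = [t.id for t in transcripts]
    if list(truth.index) != ids:
        raise ValueError("ground truth is not aligned with the transcripts")
    rng = np.random.default_rng(config.seed + 2)

    eligible = [t for t in transcripts if t.has_nlaiii_site]
    n_skipped = len(transcripts) - len(eligible)
    if n_skipped:
        log.info("%d transcripts without an NlaIII site contribute no reads",
                 n_skipped)
    if not eligible:
        raise ValueError("no transcript carries an NlaIII site; nothing to sequence")

    tag_starts = np.array([t.sequence.rfind("CATG") for t in eligible])
    vtags = [t.sequence[s:s + 26] for t, s in zip(eligible, tag_starts)]
    tag_lens = np.array(sorted(config.tag_len_probs))
    tag_len_p = np.array([config.tag_len_probs[t] for t in tag_lens])
    elig_ids = [t.id for t in eligible]
    ab = truth.loc[elig_ids, ["abundance_1", "abundance_2"]].to_numpy()

    expected: Counter[tuple[str, int]] = Counter()
    adapter = config.adapter2_prefix
    fill = adapter + _ADAPTER_FILL * (1 + config.read_len // len(_ADAPTER_FILL))
    apply_errors = config.substitution_error_rate > 0 or config.n_rate > 0
    # an error anywhere in index+tag+adapter makes a read unrecoverable
    err_window = 4 + 26 + len(adapter)
    run_ok = np.array([max_homopolymer_run(v) <= 10 for v in vtags])
    paths = (Path(out_lib1), Path(out_lib2))
    depths = (config.depth_lib1, config.depth_lib2)
    indexes = (config.index_lib1, config.index_lib2)

    for lib, (path, depth, index) in enumerate(zip(paths, depths, indexes)):
        probs = ab[:, lib] / ab[:, lib].sum()
        counts = rng.multinomial(depth, probs)
        # a chance adapter occurrence inside index+tag truncates the
        # candidate; such reads are not recoverable as 26-bp tags
        extractable = run_ok & np.array(
            [(index + v + adapter).find(adapter, 4) == 30 for v in vtags])
        serial = 0
        with open(path, "w") as fh:
            for t, start, vtag, ok, c in zip(eligible, tag_starts, vtags,
                                             extractable, counts):
                if c == 0:
                    continue
                lens = rng.choice(tag_lens, size=c, p=tag_len_p)
                lowq = rng.random(c) < config.low_quality_read_fraction
                for tl, is_lowq in zip(lens, lowq):
                    tl = int(tl)
                    seq = (index + t.sequence[start:start + tl] + fill)[:config.read_len]
                    clean_tag = tl == 26 and not is_lowq and bool(ok)
                    if apply_errors:
                        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
                        sub = rng.random(config.read_len) < config.substitution_error_rate
                        if sub.any():
                            # substitute with a uniformly chosen *different* base
                            idx = np.searchsorted(_BASES, arr[sub])
                            shift = rng.integers(1, 4, int(sub.sum()))
                            arr[sub] = _BASES[(idx + shift) % 4]
                        nmask = rng.random(config.read_len) < config.n_rate
                        if nmask.any():
                            arr[nmask] = "N"
                        if (sub | nmask)[:err_window].any():
                            clean_tag = False
                        seq = "".join(arr)
                    qual = [_BASE_QUAL_CHAR] * config.read_len
                    if is_lowq:
                        for p in rng.choice(tl, size=3, replace=False):
                            qual[4 + int(p)] = _LOW_QUAL_CHAR
                    if clean_tag:
                        expected[(vtag, lib)] += 1
                    serial += 1
                    fh.write(f"@lib{lib + 1}:{t.id}:{serial}\n{seq}\n+\n"
                             f"{''.join(qual)}\n")

    tags = sorted({tag for tag, _ in expected})
    exp = pd.DataFrame(
        {"lib1": [expected.get((t, 0), 0) for t in tags],
         "lib2": [expected.get((t, 1), 0) for t in tags]},
        index=pd.Index(tags, name="tag"),
    )
    return SimulationResult(paths[0], paths[1], exp, n_skipped)


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    """Write the ground-truth table as TSV (lossless round trip)."""
    path = Path(path)
    truth.to_csv(path, sep="\t")
    return path


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", index_col="transcript_id",
                        keep_default_na=False, float_precision="round_trip",
                        dtype={"virtual_tag": str, "de_label": str})
    truth["abundance_1"] = truth["abundance_1"].astype(float)
    truth["abundance_2"] = truth["abundance_2"].astype(float)
    return truth


def config_from_mapping(mapping: Mapping) -> SimulationConfig:
    """Build a SimulationConfig from a plain mapping (e.g. parsed YAML)."""
    kwargs = dict(mapping)
    if "length_range" in kwargs:
        kwargs["length_range"] = tuple(kwargs["length_range"])
    if "tag_len_probs" in kwargs:
        kwargs["tag_len_probs"] = {int(k): float(v)
                                   for k, v in kwargs["tag_len_probs"].items()}
    unknown = set(kwargs) - set(SimulationConfig.__dataclass_fields__)
    if unknown:
        raise ConfigurationError(f"unknown simulation fields: {sorted(unknown)}")
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg
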