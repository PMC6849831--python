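# Methods

## The measurement model

A SuperSAGE library reduces each transcript to (ideally) one 26-bp tag.
The anchoring enzyme NlaIII cuts at CATG; because library construction
captures cDNA from its biotinylated 3′ end, the tag is anchored at the
CATG site **closest to the poly-A tail**. EcoP15I then cleaves at a
variable distance from its recognition site, so raw tags are 25–27 bp with
26 bp the dominant product. Each sequencing read therefore carries, in
order: a 4-bp library index, the CATG-anchored tag, and the start of the
adapter-2 sequence.

Tag counting converts the comparison of two libraries into a pair of
counts `(x, y)` per distinct 26-bp sequence, plus the two library totals
`(N1, N2)`. Everything downstream — normalization, fold change, the exact
test — operates on this table.

## Extraction filters

Reads are assigned by an **exact** match of the first four bases to a
library index; the variability of real index balancing is handled upstream
by the sequencer, and a 1-mismatch rescue would risk cross-talk between
4-bp indexes at Hamming distance 2, so no mismatch tolerance is offered.
The candidate tag runs from position 5 to the first occurrence of the
adapter-2 prefix; reads without the CATG anchor or without the adapter are
rejected and accounted separately.

Candidates then pass four filters in a **fixed order** so that the failure
ledger is deterministic: length (exactly 26 bp), undetermined bases (any
non-ACGT), homopolymers (any single-base run ≥ 11 bp), and low quality
(≥ 3 positions with Phred < 10). A tag seen exactly once in the combined
libraries (a *singleton*) is removed as probable sequencing error.

Two bookkeeping conventions matter and are deliberate:

* **Library totals `N1`, `N2` are the totals of kept tags before singleton
  removal.** The normalization factor convention (just below the smaller
  total) only reproduces published practice if totals are taken before the
  singleton cut, and the statistic should reflect the sequencing effort
  actually spent.
* **Singleton means combined count `x + y == 1`**, not per-library.

## The Audic–Claverie test

With `x` counts in a library of size `N1`, the posterior predictive
distribution of the count `y` in a second library of size `N2` under equal
relative expression is

    p(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

a negative binomial in `y`. The implementation evaluates terms in log
space through the log-gamma function. The two-sided P value doubles the
smaller of the two cumulative tails,

    T_low = Σ_{k≤y} p(k|x),   T_high = 1 − Σ_{k<y} p(k|x),
    P = min(1, 2·min(T_low, T_high)),

and is always in (0, 1]. Numerical choices:

* When the upper tail is below 1e-8 the complement form loses all
  precision to cancellation; the tail is then summed directly from `k = y`
  using the term recurrence (geometric convergence with ratio
  `→ (N2/N1)/(1+N2/N1)`), which keeps small P values accurate to full
  relative precision.
* A value within 1e-12 of 1 is reported as exactly 1. At `x = y` with
  equal totals the lower tail is exactly 1/2 (the negative-binomial median
  identity), so the doubled value is analytically 1; the clamp removes the
  ~1e-14 float residue.
* The test is validated against an exact rational-arithmetic summation of
  the closed form (`fractions.Fraction`) to < 1e-9 over the full grid
  x, y ≤ 50 at depth ratios 1:4, 1:1 and 4:1.

One property worth stating precisely: the two-sided P is **not** exactly
invariant under swapping `(x, N1)` with `(y, N2)`. The doubled-tail
construction includes the boundary term `p(y|x)` in both tails, so at equal
totals the swapped values agree only up to a factor of 2, and at unequal
totals the tails themselves are asymmetric (the exact oracle shows factors
up to ~5 at 4:1 depths). The significance decisions agree in the large
majority of cases; the test suite asserts the factor-2 bound at equal
totals rather than a false identity.

No multiple-testing correction is applied by default — single-library SAGE
practice tests at raw P < α — but Benjamini–Hochberg adjustment is
available (`supersage.dge.benjamini_hochberg`) for users who want it.

## Normalization and fold change

The normalization factor NF defaults to the largest multiple of 1000
strictly below the smaller library total (e.g. totals 1 056 080 / 268 172
give NF = 268 000); an override is accepted up to the smaller total. Note
the edge case: an exact-multiple total steps down (min 5000 → NF 4000).
Normalized values are `x/N × NF`, real-valued and never rounded.

Fold change substitutes **raw** zero counts with 1 before normalizing.
Applying the substitution at the raw-count level (rather than to the
normalized value) keeps the stated rule literal — it is the tag *count*
that is set to 1 — and makes FC reciprocal under swapping the libraries.
Classification uses inclusive boundaries: OE iff FC ≥ 2.5 and P < 0.05,
UE iff FC ≤ 0.4 and P < 0.05.

Report percentages use round-half-even at the printed precision. The
mapped-tag share is the one published figure conventionally produced by
truncation instead (419/1989 → 21.06 truncated vs 21.07 rounded), so the
percent helper offers both modes; nothing else uses truncation.

## Mapping

Because annotation requires a *perfect* 26-nt match, alignment reduces to
exact 26-mer lookup: the index hashes every 26-mer of both strands of the
reference (windows containing N are skipped). This replaces a short-read
BLASTN search exactly on the acceptance rule — gap costs and
low-complexity masking are irrelevant when only full-length identities
count. Memory grows with twice the reference length; transcript-scale
references (tens of Mb) are the intended regime.

A hit is **canonical** when it lies on the + strand and starts at the
contig's 3′-most CATG that still has 22 bp of non-poly-A sequence
downstream; all other placements, including every − strand hit, are
*internal* (tags derive from the mRNA sense strand, and real contigs have
unknown orientation, so both strands are searched but only the sense
placement can be canonical). Trailing runs of ≥ 8 A's are treated as the
poly-A tract (configurable). Ambiguous tags (multiple perfect placements)
are reported with all hits and a multiplicity flag, never discarded.

The virtual tag predicted from a contig takes the 3′-most CATG upstream of
the poly-A and up to 22 downstream bases, with a truncation flag when
fewer are available — truncated virtual tags cannot equal any observed
26-bp tag and are excluded from round-trip checks.

The enzyme-site scan counts overlapping motif occurrences on the forward
strand only; the three default motifs (CATG, GATC, CTAG) are their own
reverse complements, so forward counts cover both strands.

## The synthetic-data generator

The generator emulates the features the extraction filters exist to catch,
under a single seeded numpy Generator (identical configs give
byte-identical FASTA/FASTQ/TSV output):

| parameter | default | meaning |
|---|---|---|
| `n_transcripts` | 20 000 | transcriptome size |
| `length_range` | 300–1500 bp | uniform transcript core length |
| `gc_fraction` | 0.42 | per-base GC probability (insect-like) |
| `polya_len` | 18 bp | appended poly-A tract |
| `frac_with_site` | 0.9 | transcripts carrying a usable CATG |
| `abundance_lognormal_mu`, `sigma` | 0, 1.5 | heavy-tailed abundances |
| `de_fraction`, `de_fold` | 0.1, 8 | DE subset, exact multiplicative shift |
| `depth_lib1`, `depth_lib2` | 1 056 080 / 268 172 | the ~4:1 library imbalance |
| `index_lib1`, `index_lib2` | GCCT / GCAC | library indexes |
| `tag_len_probs` | 25:0.15, 26:0.70, 27:0.15 | EcoP15I length variability |
| `substitution_error_rate`, `n_rate` | 0.001 each | per-base errors |
| `low_quality_read_fraction` | 0.02 | reads given ≥3 sub-Q10 tag positions |
| `read_len` | 48 | fixed read length (pad/truncate) |

Site-bearing transcripts get exactly one CATG, planted where a full 26-bp
tag fits upstream of the poly-A; accidental CATGs are scrubbed (the
replacement of the final G with T provably cannot create a new site, so
one pass converges). This makes the designated tag both unique and
recoverable, which is what lets DE recovery be scored unambiguously.
Per-library read counts are multinomial over condition-specific
abundances; DE shifts are exact multiplications so the truth labels are
sharp. The OE/UE split of the DE subset is even, with any odd remainder
assigned to OE.

The simulator also returns an `expected_counts` table counting the reads
whose tag span is a clean, extractable 26-mer (correct length, no injected
error in the index/tag/adapter window, not flagged low-quality, no chance
adapter occurrence inside the tag, no homopolymer run > 10 in the true
tag). With all error rates at zero this is an **exact** oracle for the
extraction output — the suite asserts table equality, not approximate
agreement — and the tests confirm ≥ 99% of 8-fold DE tags with mean kept
count ≥ 20 per library are recovered with the correct direction at
2 × 10⁵ reads per library over 20 000 transcripts. Scale-downs of this
size were chosen to exercise every code path at comfortably interactive
runtimes; the statistics do not change character at full depth.

What the generator does **not** emulate: PCR duplicates, indel errors,
position-dependent quality decay, paired ends, polymorphism between
strains, and transcript isoforms sharing tags. Passing tests therefore
demonstrate correctness of the counting and testing machinery, not
robustness to every artifact of real sequencing chemistry.

Read orientation is a modeling choice: the layout of the sequenced strand
is not fixed by the library chemistry description alone, so the simulator
emits sense-strand tags and the mapper indexes both strands.

## Pipeline determinism

`run_pipeline` writes each stage's outputs and a `manifest.json` of
SHA-256 checksums. All randomness flows from the config seed, TSV/JSON
writers are deterministic, and reruns reproduce identical checksums — the
pipeline test asserts this end to end.

## Known limitations

* The exact-match mapper holds the full 26-mer hash in memory; genome-scale
  references would need a disk-backed or FM-index backend.
* One library per condition: the model cannot separate biological from
  technical variance (no dispersion estimation). This is inherent to the
  design the package implements, not an oversight.
* The Audic–Claverie P is anti-conservative in the presence of
  overdispersion; with replicates, a negative-binomial GLM framework is
  the right tool instead.
* `choose_nf` requires the smaller library total to exceed 1000; smaller
  toy tables must pass an explicit NF.
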