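# Methods

## The editing system being modelled

A prime editor built on nuclease wild-type SpCas9 fused to a reverse
transcriptase introduces, at each target site, a blunt double-strand break
(DSB) together with a 3'-extended single-strand DNA flap on the non-target
strand.  The flap sequence is programmed by the pegRNA's RT template; the
primer binding site (PBS) anneals to the broken non-target strand to prime
reverse transcription.  Two pegRNAs targeting opposite sides of a fragment
("PAMs pointing inward") yield two flaps whose 3' ends are mutually
reverse-complementary over a short programmed *edit*; annealing of the flaps
joins the retained fragments, producing large deletions (both cuts on one
chromosome) or translocations (cuts on two chromosomes).  Two pair classes
are modelled:

* **C1** — each flap carries the edit plus a homology arm (HA) identical to
  the retained sequence beyond the partner cut; homology-mediated joining
  collapses each HA onto its genomic copy, so the accurate product is
  `retained_a + edit + retained_b` with single HA copies.
* **C2** — flaps carry only the mutually reverse-complementary edit.

Sequenced outcomes fall into three classes plus unedited: *accurate edit*
(intended junction, no indel), *edit with indel* (edit present, indel in the
junction window — the canonical error being NHEJ ligation of the full flap
without HA collapse, leaving the junction flanked by duplicated HA copies),
and *pure indel* (no flap written; direct end joining with resection).
"Prime edits" denotes accurate + edit-with-indel.

## Geometry conventions

All coordinates are 0-based half-open on the + strand.  Protospacers are
20 nt with an NGG PAM; the DSB is modelled as blunt, 3 bp 5' of the PAM
(between protospacer positions 17 and 18).  SpCas9's occasional 1-nt 5'
overhang cleavage is not modelled; junction bookkeeping assumes blunt ends.
The 17-nt protospacer remnant on the PAM-distal side of each cut (the
"residue spacer") is annotated in every predicted allele, flanking the edit.

## pegRNA construction

`design_single` / `design_pair` emit spacer + scaffold + RT template + PBS
(5'→3', stored as DNA; U↔T is presentational).  The RT template is the
reverse complement of the desired flap; the PBS is the reverse complement of
the `pbs_len` nucleotides immediately 5' of the cut on the non-target
strand.  Defaults `pbs_len = 13`, `ha_len = 13` are typical mid-range
choices; `validate_plan` warns below an 8-nt HA (the shortest homology with
demonstrated intermolecular homology search) and outside a PBS window of
8–17 nt.  An EcoRV tag (`GATATC`, palindromic) can be appended to the flap
of homology-independent designs to make integration detectable by digestion;
combining it with an HA is rejected because the HA occupies the same
RT-template end.  Single-base conversions are expressed through an explicit
flap override rather than a separate edit type.

## Read classification

Each merged amplicon read is aligned to the wild-type reference(s) and to
the predicted accurate allele with the Needleman–Wunsch/Gotoh affine-gap
scheme (match +2, mismatch −4, gap open −12, extend −2; end gaps free).
The better-scoring reference decides the frame; indel operations are counted
inside a ±20-nt window around the cut(s) or edit junction (configurable).
Classes follow two booleans — edit found, indel in window.  Three deliberate
robustness rules:

* **Substitution tolerance.**  Substitutions never change a read's class;
  this makes classification stable under sequencing substitution error
  (≲1%) at the cost of treating a fully substituted edit as still present.
* **Edit integrity** is "no edit reference position deleted": the union of
  aligned blocks must cover the edit interval.  Insertions adjacent to the
  edit split alignment blocks without destroying the edit, and gap-placement
  ambiguity at the edit margin therefore cannot flip the call.  The exact
  edit string in the read is accepted as an alternative signal.
* **Tie-breaking.**  Equal scores against both references are resolved by
  presence of the exact edit string; a tie with an empty edit is discarded
  (counted and reported).

A gapless fast path classifies reads whose mismatch distance to a
same-length reference is provably below the cost of any gapped alternative;
within that budget it is mathematically identical to the full alignment and
exists only for speed.

Editing activity (prime edits + pure indels, percent of retained reads) is
flagged against a 0.2% threshold for on-target samples and 0.01% for
off-target samples.

## Efficiency formulas

Gel densitometry converts band greyscale to molar ratio by length
normalisation: `eff = 100·(Gd/Ld)/(Gd/Ld + Gu/Lu)`.  The formula is scale
invariant and monotone in each band; it is undefined when both greyscales
are zero and not clamped elsewhere.

Absolute qPCR fits `CT = slope·log10(copies) + intercept` per assay from a
serial tenfold dilution series (≥3 points enforced; the default simulated
series spans 2·10¹–10⁹ copies/µL) by ordinary least squares.  Replicate CTs
are arithmetic-averaged before inversion (standard practice; averaging CTs
rather than copies makes the estimate the geometric mean of replicate copy
numbers).  Efficiency is `100·copies(deleted junction)/copies(flanking)`;
values above 100% are flagged, not clamped, and CTs outside the fitted
dilution range are flagged as extrapolated.  The amplification efficiency of
an assay is `10^(−1/slope) − 1`.

## Synthetic data

The read simulator draws per-read class labels from a stated mixture
(multinomial; a fixed-count mode exists for exact tests), emits the matching
allele sequence, applies archetype indels and then sequencing error
(per-base substitutions, optional per-base indels), and writes FASTQ with
constant Q30 qualities plus a ground-truth table.  All generators are
deterministic under a fixed seed.

Indel archetypes: `ha_duplication` (the full flap ligated without HA
collapse — HA duplicated around the junction, C1 only), `blunt_join`
(resection flush against the edit) and `random_small` (geometric-size indel
near the junction, outside the edit).  Default weights 0.4/0.3/0.3 reflect
the qualitative observation that HA-flanked duplications dominate the
edit-with-indel class without asserting unreported frequencies.

Two generator rules remove label noise that would otherwise be a property of
the taxonomy rather than of the code.  First, candidate indel reads whose
length lands exactly on another reference class's length are redrawn: an
indel that restores the accurate-allele (or WT) length converts the
difference into a substitution-like patch, which substitution tolerance is
*required* to absorb.  Second, pure-indel reads at a junction-type no-flap
join carry deletions only: under affine scoring, random bases inserted at
such a junction always align as a degraded copy of the edit, so
insertion-bearing "pure indels" are not identifiable there even in
principle (at single-site cuts, where the no-flap join is the WT sequence,
insertions are generated as well).

The gel and qPCR generators invert their formulas exactly, with optional
Gaussian noise on greyscales or replicate CTs.

## What the synthetic data does and does not show

The simulator emulates outcome-class structure, junction indel archetypes
and uniform substitution error.  It does not model position-dependent
Illumina quality, PCR chimeras/duplicates, paired-end merging artefacts, or
large-scale coverage bias — so passing tests demonstrate correctness of
design arithmetic, classification logic and formula inversion, not
robustness to every failure mode of real amplicon data.  Problem sizes used
by the test suite and the acceptance script — toy loci of 190–600 nt,
10,000-read mixtures — were chosen as the smallest sizes at which the
stochastic checks (3 binomial standard errors) are meaningful.

## Known limitations and open choices

* **Single-base edits with adjacent indels are not identifiable.**  With a
  1-nt edit, "edit + small deletion" is rigorously closer to the wild type
  than to the edited allele under any sensible scoring, and such reads
  classify as pure indels.  The taxonomy is sharp for multi-base edits
  (paired designs use ≥6-nt junction edits, where all checks hold).
* The reciprocal (balanced) translocation product is always predicted and
  labelled separately, with a note that it is typically not recovered
  experimentally; prediction and observation are kept distinct.
* Barcode demultiplexing is exact-prefix by design; one mismatch discards
  the read.
* The classifier is quality-agnostic; no UMI handling or variant calling
  beyond the outcome taxonomy.
* Off-target site nomination is out of scope; only the threshold/comparison
  logic (`compare_editors`, 0.01% flagging) is provided.
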