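# Methods

This note records the models pamscape implements, the conventions and
defaults it fixes where the field (or the source assays) leave them open,
and what the synthetic-data generators do and do not establish.

## Coordinates, cut placement, topology

All intervals are 0-based, half-open, reported on the plus strand;
minus-strand features carry a strand flag (BED compatibility). On circular
records a feature may wrap the origin: `start` stays in `[0, L)` and `end`
may exceed `L`; positions reduce modulo `L`. Circular scanning works on an
extended copy of the sequence, keeping exactly the placements whose element
(protospacer + PAM) starts in the first copy — each physical placement is
reported once.

The blunt cut is placed `cut_offset = 3` nt 5' of the PAM on the site
strand. Double-strand-break tagging data place incorporation at the 3rd *or*
4th base upstream of the PAM for both FrCas9 and SpCas9; 3 is chosen to
match the SpCas9 convention and is a keyword argument everywhere it matters.

Sites overlapping an assembly N are dropped by default (`keep_n=True`
retains them, with N never satisfying a PAM code other than N). This choice
affects real-genome statistics; whether published genome-scale counts
included N-runs is generally unstated, so the flag exists.

## Palindromicity: two predicates

`PamMotif.is_palindromic` is the strict predicate — the motif's concrete
match set is closed under reverse complement. This is true of TA and GGCC
but **false of NNTA**: the reverse complement of the NNTA match set is
TANN-shaped. What the back-to-back geometry actually requires is the weaker
`palindromic_core()`: a literal TA whose flanking positions are all N, so
every genomic TA anchors one site per strand. `find_back_to_back_pairs`
demands the core predicate and reports, per shared TA, the divergent pair
with protospacer gap `2·core_offset + 2` (= 6 for NNTA). The pair count on
any record equals the number of flank-qualified plus-strand TA loci — a
property tested exhaustively.

## Landscape statistics

*Coverage* counts protospacer positions only (PAM bases excluded): "target
coverage" is read as editable sequence. The union is a boolean mask over
both strands, so overlapping sites never double-count.

*Spacing* anchors are cut positions for target sites and word start
positions for dinucleotides. Distances are consecutive differences of the
sorted anchors; circular records add the wrap-around gap, making the
distances sum to `L` and the mean exactly `L / n_anchors`. Coincident
anchors contribute zero distances. With both-strand counting, a palindromic
word (TA) contributes two coincident anchors per locus — one per
orientation — which is the convention under which each anchor corresponds
to one orientable PAM and the circular mean is `L / (2·#TA)`. These
conventions are switchable (`count_both_strands`); published distribution
figures rarely state theirs, so means computed here are calibrated against
closed forms (circle: exact; i.i.d. 1 Mb sequence: renewal expectation
`1/p = 16` bp for single-orientation TA) rather than against any published
genome scan. Medians are reported but are convention-sensitive and not
promised to match external figures. Multi-record inputs get per-record
summaries plus a length-weighted pooled mean; spacing never crosses record
boundaries.

## Depletion assay statistics

`PPDV(p)` is the selected-library frequency of PAM `p` divided by its
control-library frequency. With zero pseudocount (default) this is the raw
frequency ratio; a PAM absent from the control is flagged undefined rather
than raised. A positive pseudocount `c` is applied to **depth-matched
counts**, `(sel·ctl_total/sel_total + c) / (ctl + c)`: a naive count-space
pseudocount breaks the identity `PPDV ≡ 1` on proportional libraries
whenever the two libraries differ in sequencing depth, and that identity is
the contract the statistic must keep.

Depletion efficacy ranks ascend with PPDV (rank 1 = most depleted), ties
lexicographic. The top-depleted set takes `floor(q · n)` PAMs (the assay's
convention for the rounding is unstated; floor with lexicographic ties makes
the selection reproducible). The logo over that set reports the position
frequency matrix and `log2(freq / 0.25)` — enrichment over the uniform
expectation of a fully randomized library; whether published per-position
fold-changes were computed over the depleted subset or over all PAMs
weighted by depletion is unstated, so only this documented definition is
tested. The PAM wheel accumulates weight `1 − PPDV` (the "positively
depleted" PAMs, PPDV < 1) onto the trimer at PAM positions 2–4 and
normalizes to 1; no formula for wheel weights is published, so this linear
depletion weight is a package choice.

The sgRNA evenness index is `total_reads / (N · reads_i)`; the identity
`Σ 1/(N·index_i) = 1` holds algebraically and is property-tested. The
GUIDE-seq on:off ratio uses denominator `max(1, Σ off)` so perfectly
specific sites (zero off-target reads) remain finite and rankable.

## Base-editor scoping

Editing windows are 1-based protospacer positions counted from the
PAM-distal 5' end — the standard base-editor convention. Defaults:
FrCas9-BE4Gam C→T, window 6–10; FrCas9-ABE7.10 A→G, window 6–8; SpCas9
comparators BE4Gam 4–8 and ABE7.10 4–7 on a 20-nt spacer (canonical
literature windows, explicitly configurable because comparator windows used
in published scope counts are not stated).

Correction is evaluated on the **patient (alt-carrying) sequence**: the
editor must revert alt → ref, so sites are enumerated after substituting the
alt allele. A variant is correctable iff some site places it in the window
with site-strand alt equal to the substrate base and site-strand ref equal
to the product base (CBE fixes T>C via a plus-strand site and A>G via the
minus strand; ABE the complementary pairs). "Precise" requires ≥ 1
supporting site whose window carries no bystander — no other substrate base
on the site strand; PAM-disruption and codon effects are out of scope.
Published ClinVar scope *counts* are database-version-dependent and are
deliberately not reproduced; the scope-difference statistic `|A\B| / |A|` is
verified as arithmetic (235/260 = 90.38%, 1196/1297 = 92.21%).

`double_window` maps a back-to-back pair to its two genomic editing
windows; they are disjoint and symmetric about the 6-bp NNTANN core, and a
full-spacer window abuts the core on both sides — tested as geometry.

## Amplicon indel quantification

Reads are merged upstream (paired-end merging is out of scope) and globally
aligned with affine gaps (Gotoh; three matrices, rows vectorized, the
horizontal-gap state closed by a prefix running maximum). Scoring defaults
match +2 / mismatch −4 / gap open −8 / gap extend −1 (a length-k gap costs
open + k·extend); the heavy open penalty discourages spurious terminal gaps
on amplicons. Traceback tie-breaks are fixed — match > deletion > insertion
at equal score — so op lists are deterministic. Adjacent
insertion/deletion runs each pay their own open, matching exhaustive path
enumeration and Biopython's global affine aligner, which serve as
independent score oracles in the tests.

A read is edited iff an indel op overlaps the inclusive ±10 bp window
around the cut; deletions occupy their reference interval, insertions are
points at the reference offset they precede. Reads whose best alignment
exceeds 40% mismatches are discarded as unalignable and counted (read QC
beyond standard trimming is not specified by the assay; the threshold is
declared, not inferred). Rates: `raw = indel_reads / kept_reads`,
`corrected = max(0, raw − control_rate)`. Substitution errors cannot create
indel ops, so ≤ 1% substitution noise leaves calls unchanged (tested).
Per-base conversion tallies for base-editing efficiency are a documented
extension, not implemented.

## Synthetic data: what it emulates, what it does not

All generators take one integer seed, use a single local numpy Generator,
and are byte-identical under the same seed.

* `random_genome`: i.i.d. bases with `P(G)=P(C)=gc/2`. No repeats, no
  composition heterogeneity, no N-runs — a green landscape test establishes
  coordinate and counting correctness, not real-genome statistics.
* `simulate_depletion`: control is multinomial-uniform over all 4^k PAMs
  (self-calibrated by chi-square across seeds); selection reweights
  rule-matching PAMs by `retention` (default 0.1, i.e. 90% depletion of
  recognized PAMs; depth 10^6, k = 6 — the 4096-member randomized library
  of the source assay). No PCR bias or chimeras.
* `simulate_amplicon`: one indel per edited read, placed uniformly within
  ±3 bp of the cut (NHEJ outcomes cluster at the cut; break-tagging data
  localize incorporation to the 3rd/4th base upstream of the PAM), size from
  an NHEJ-like spectrum (mostly 1–4 bp deletions, occasional small
  insertions), then i.i.d. substitutions (default 0.5%, a typical
  post-merge Illumina error rate). Truth labels are emitted per read.
* `simulate_variants`: rejection-samples positions/alleles until an internal
  string-level brute-force checker — an independent code path from the
  scanner — confirms the requested category (correctable ± bystander,
  uncorrectable). Truth is therefore exact by construction and end-to-end
  recovery is tested with zero stochastic slack.

## Anti-repeat search

Ungapped, full-length sliding windows on both strands against the reverse
complement of the direct repeat; defaults 0.8 identity over ≥ 15 nt (the
protocol referenced for tracrRNA discovery publishes no parameters, so these
are declared package defaults). Overlapping hits merge to the
best-identity window; Ns never match. No gapped alignment and no
secondary-structure scoring.

## Known limitations

* Coverage/spacing equality with published genome scans is not asserted:
  those require the genome builds and an (unstated) strand/N-handling
  convention; the statistics are instead validated against exact closed
  forms and renewal expectations.
* The coverage monotonicity in spacer length holds on circular records
  only; on linear records longer spacers lose edge sites.
* The aligner is O(m·n) per read and pure numpy — ample for amplicons
  (~10^2 bp × 10^3 reads), not built for genome-scale alignment.
* sgRNA efficacy scoring, off-target search, thermodynamics, promoter
  discovery and cleavage-rate fitting are out of scope by design.
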