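# Methods

## The generative picture

A hard-stop modification on an RNA template interferes with reverse
transcription. Per cDNA synthesis event at a modified position, three
outcomes are modeled: termination (probability 1 − r), read-through with a
misincorporation (probability r·m), and silent read-through (r·(1 − m)).
With stoichiometry s (the fraction of molecules modified at the position),
reads that cover the position come from unmodified molecules (weight 1 − s)
and read-through events (weight s·r); of those, s·r·m carry a
misincorporation. The expected mismatch fraction among covering reads is
therefore

    rate(s, r, m) = s·r·m / (s·r + (1 − s))        (`expected_mismatch_rate`)

Truncated cDNAs never reach the position — they *reduce coverage* 5′ of the
stop and pile read 5′ ends at position +1, which is exactly the signal the
truncation analytics read out.

For m1A and SuperScript III-class enzymes, read-through is roughly 20–30%
and read-through events usually misincorporate, predominantly A→T with
minority A→G and A→C. The defaults (r = 0.25, m = 0.9, spectrum
0.8/0.1/0.1) encode that regime; all three are per-site configurable.

## The filter chain (`misinc.FilterConfig`)

| parameter | default | meaning and rationale |
|---|---|---|
| `min_combined_depth` | 500 reads | combined unique-read depth over all replicates; at 20% stoichiometry this guarantees ~100 synthesis events on modified templates, of which ~20 read through, so the signal is detectable |
| `min_rate` | 0.01 | combined misincorporation rate; 10× above the modeled sequencing error (0.001), 5× below the weakest planted signal (~5% at s = 0.2) |
| `min_replicate_fraction` | 0.5 | detection required in at least half of the replicates; random errors do not replicate across independent libraries |
| `per_replicate_min_depth` | 20 reads | a replicate "detects" a site only if it has meaningful coverage of its own; combined depth is the headline gate, this is a lower-stakes presence check |
| `per_replicate_min_rate` | 0.01 | same rate bar applied within each replicate |
| `min_heterogeneity` | 0.05 | high-confidence calls must show minority mismatch classes; editing and alleles are single-class |

The rate and depth thresholds are applied to replicate-combined counts; the
per-replicate gates are deliberately softer because per-replicate depth at
any one position is ~1/20 of the combined depth. Heterogeneity is defined as
the **minority-mismatch fraction**, 1 − modal/total over the three non-
reference bases (computed on combined mismatch counts). A stricter reading —
requiring all three alternative bases to be literally present — collapses to
a count threshold that becomes unreliable at shallow mismatch totals; the
fraction form subsumes it and is threshold-tunable. Ties for the modal base
are broken in fixed order A<C<G<T, which cannot change the result since only
the modal *count* enters.

Positions in the variant mask (genomic variants of the profiled individual,
dbSNP entries) are excluded before any filtering; positions whose reference
base is N are skipped. Raising any threshold can only shrink the output
(monotonicity), which the fuzz suite checks on random configuration pairs.

## Pileup conventions (`pileup.PileupConfig`)

Reads are collapsed to unique molecules first — by (sequence, start, strand,
UMI) when a UMI is present, by full placement plus base string otherwise,
keeping the first occurrence — then 10 aligned bases are clipped from each
read end (Illumina read ends are error-prone; a 50-mer contributes its
central 30 bases), then reads with more than one mismatch against the
reference are discarded, re-imposing the upstream aligner's mismatch ceiling
on any reads that arrive without it. N bases are ignored entirely; deletions
contribute no count at the deleted position; zero-depth columns are never
materialized. No base- or mapping-quality weighting is applied: the filter
chain's replication and heterogeneity requirements do the error suppression
that quality scores would otherwise approximate.

Strand handling: SAM stores every read's bases in forward reference
orientation, so pileup columns always count stored bases against the forward
reference (the behaviour of standard pileup engines). The `strand_aware`
flag governs where strand genuinely matters: duplicate-collapse keys, read
5′-end computation (start on +, end − 1 on −), and per-strand cluster
grouping.

## Read-through estimation

At a known full-stoichiometry site, the fraction of synthesis events that
traverse the stop is estimated as depth(site) divided by the **median depth
of the 20 positions immediately 3′** of it. The 3′ flank is used because
truncated cDNAs still cover it (their 5′ ends begin at site + 1), so flank
depth approximates total molecule flux while site depth counts only
read-through. Two practical caveats, both respected by
`experiments.readthrough_recovery`:

* the estimator should run on **unclipped** pileups — end-clipping hollows
  out the first `end_clip` flank positions covered only by truncated reads;
* the flank-ratio logic assumes column depth counts molecule passage, which
  holds when reads tile the fragments they come from. The validation
  experiment therefore uses fully sequenced fragments (fragment length =
  read length). With 50 nt reads off 250 nt inserts, reads sample only the
  termination end of each cDNA and the ratio understates read-through.

The estimate carries a small upward bias if very short truncated reads are
discarded (they carry the flank); the validation keeps reads ≥ 5 nt and
recovers a planted r = 0.15 to within ±0.05.

## miCLIP truncation analytics

**Termination profiles.** Read 5′ ends are counted at offsets 0..+4 from
each TSS (transcript orientation). A TSS enters the analysis only with ≥ 5
unique reads covering the TSS position in *both* the miCLIP and the matched
RNA-seq library, so that the contrast is never driven by coverage
differences. The aggregate is the per-offset mean of per-TSS fractions —
each TSS weighted equally — with the standard error of the mean across TSSs.
Pooling reads instead would let a handful of deep TSSs dominate.

**Clusters.** Same-strand overlapping unique reads merge transitively into
maximal intervals; the score is the maximum per-position stacked depth
(peak height, the natural reading of "stacked"), not the total read count,
and clusters below score 20 are dropped. Calling pools reads across
replicates by default.

**Metagene.** Each item (cluster or read) maps by its midpoint to a
region-relative coordinate — 30 bins each for 5′UTR, CDS and 3′UTR — and the
per-bin item fraction is divided by the RNA-seq read-midpoint fraction in
the same bin. Bins with zero RNA-seq density are reported as missing (NaN),
never infinite; an empty item set yields an all-zero profile. This is a
deliberately simple, fully documented normalization scheme: the operative
idea is the division by RNA-seq coverage, not any particular smoothing.

**TSS start-nucleotide enrichment.** A 2×2 table of {start nucleotide A vs
not} × {TSS overlapping a cluster vs not} over the full TSS catalog
(including unexpressed transcripts; configurable), tested with a two-sided
Fisher exact test. Degenerate margins (no clusters, or every TSS
overlapping) report the fractions with p = 1 and a warning rather than
failing.

## Site-list curation

External site lists are filtered in a fixed order: (1) records whose gene
identifier is missing or not in the supplied valid set; (2) records whose
nucleotide is not adenosine; (3) all but the first record per genomic
coordinate (transcript-isoform duplicates). Each record is tallied against
the first filter it fails, so the per-category counts depend on the order,
though the kept set does not when the defect classes are disjoint. The bundled
synthetic fixture (`make_curation_fixture`) is built with exactly disjoint
classes — 352 clean unique adenosine sites plus 3 invalid-gene, 37 non-A and
82 duplicate records, 474 in all — and a TSS structure of 19 annotated and
134 CAGE/m6Am positions with 13 in common, so the union is 140 and 212 sites
remain internal. TSS matching is exact by default; a tolerance window is
available because experimentally inferred start regions are not always
single-nucleotide.

## The simulator (`simulate.SimulationConfig`)

What it emulates: single-exon transcripts (one contig each, + strand, TSS at
position 0, CDS at 30–80% of the length); fragmentation in which the
5′-terminal fragment always starts at the TSS and appears with probability
fragment_length/transcript_length, other fragments starting uniformly;
cDNA synthesis 3′→5′ with per-site termination/read-through/misincorporation
as above; uniform per-base sequencing error applied independently to every
PCR copy; PCR duplication with shared 10 nt UMIs and fresh read identifiers;
heterozygous (50% alt) and homozygous SNPs; homogeneous per-molecule A→G
editing; and, in miCLIP mode, immunoprecipitation that keeps
crosslink-containing fragments (plus a 5% nonspecific background) with
terminations at TSS offsets 0/+1/+2/+3 under a configurable mixture
(defaults 0.35/0.40/0.08/0.05, remainder reading through to the cap). A
`crosslink_a_start_only` switch restricts crosslinking to adenosine-start
caps, modeling a cap-cross-reactive antibody for the enrichment experiment.
An optional `dimroth_loss` parameter attenuates effective stoichiometry to
model heat/base-driven m1A→m6A conversion during library preparation
(default 0).

Default study conditions: 20 replicates of 50 nt reads from ~250 nt
fragments; five planted sites per genome on adenosines with stoichiometry
drawn U(0.1, 0.5), r = 0.25, m = 0.9, spectrum 0.8/0.1/0.1 (A→T majority);
sequencing error 10⁻³; PCR duplication 0.2; two heterozygous SNPs, two
homozygous SNPs and two editing decoys (per-molecule rate 0.2). Special
positions are forced onto adenosines and separated by ≥ 50 nt — more than a
read span — so no single read can carry two planted mismatches and trip the
one-mismatch cap. The genome is one 800 nt transcript with 7,200 molecules
per replicate: sized so that the combined covering depth at every planted
site stays above 1,000 even for high-stoichiometry sites, whose truncations
both deplete their own coverage (factor s·r + 1 − s) and cast a coverage
shadow over sites within a fragment length 5′ of them. These are desk-scale
problem sizes chosen to make hundreds of full experiments cheap to rerun;
per-experiment overrides in `misincmap.experiments` change only geometry
(fragment length, duplication) for quantities that do not depend on it, never
the modification parameters.

Determinism: every stream comes from integer-seeded numpy Generators; each
replicate derives its generator from (seed, crc32(mode:replicate_id)), so a
fixed seed reproduces every read bit for bit across platforms and
simulations with different seeds are independent.

What it does **not** emulate — and what passing tests therefore do not show
about real data: spliced transcripts and multi-isoform loci, alignment and
mappability artifacts, indel errors, base-quality structure, non-uniform or
motif-dependent fragmentation, realistic expression distributions (abundance
is uniform unless overridden), sequence-context-dependent misincorporation
spectra, and correlated errors between PCR siblings that UMI collapsing
would miss. Recovery results bound what the filter chain does under the
stated generative model, not its false-positive rate on a real
transcriptome.

## Numerical and interface choices

* Coordinates are 0-based half-open everywhere internally; SAM/VCF are
  converted on read, written tables are 1-based. BED stays 0-based.
* `misincorporation_rate` and `heterogeneity_fraction` raise on zero depth /
  zero mismatches rather than returning a sentinel — callers must not query
  uncovered positions.
* Candidate sites are emitted sorted by (seq_id, position); cluster calling
  is input-order invariant.
* The Fisher test is delegated to scipy's exact implementation; the test
  suite verifies it against direct hypergeometric enumeration for every
  2×2 table with N ≤ 40.
* The curation fixture's duplicate records are appended after the clean
  records (shuffled among themselves), so "first per coordinate" always
  keeps the clean original.
* CLI exit codes: 0 on success, 2 on usage errors (including bare
  invocation), 1 on runtime errors; every subcommand writes a
  `<output>.manifest.json` with parameters, input MD5s and output counts.

## Known limitations

Heterogeneity cannot separate a hard stop from two co-located single-class
events (e.g. an unmasked SNP overlapping an edited position); the method
identifies misincorporation *positions*, not modification identity, which
requires orthogonal biochemistry. Sites within ~250 nt of a transcript 5′
end are hard to assess because truncation shadows and the 5′-fragment pileup
depress local coverage. The read-through estimator assumes the 3′ flank is
representative of molecule flux; strong coverage gradients (alternative
TSSs, degradation) bias it.
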