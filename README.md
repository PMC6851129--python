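# misincmap

Detection of hard-stop RNA modifications — N1-methyladenosine (m1A) and
similar nucleotides that arrest reverse transcription — from multi-replicate
aligned RNA-seq, by **misincorporation mapping**; plus miCLIP
truncation analytics, site-list curation, and a seeded read simulator so the
whole suite runs without any external sequencing data.

## The problem

A hard-stop modification such as m1A disrupts Watson–Crick pairing. When a
standard reverse transcriptase (e.g. SuperScript III) meets one, it usually
terminates; at low frequency it reads through and leaves a misincorporation in
the cDNA — for m1A mostly A→T, with minority A→G and A→C. These
misincorporations are direct, antibody-free evidence of a modified position,
but in any single library they are indistinguishable from sequencing error.
The method targets deep multi-replicate data (tens of independent libraries):
true modification signals replicate across libraries and scatter over all
three alternative bases; errors do neither, and genomic variants or A-to-I
editing produce a single pure mismatch class.

## The filter chain

For every unmasked position, with base counts summed over replicates:

1. **depth** — combined unique-read depth ≥ 500 (after UMI duplicate
   collapsing and clipping 10 bases from each read end);
2. **rate** — combined misincorporation rate
   `(depth − ref_count) / depth` ≥ 1%;
3. **replication** — independently detected (depth ≥ 20, rate ≥ 1%) in at
   least half of the replicates;
4. **variant mask** — positions with known genomic variants or dbSNP entries
   are never analyzed;
5. **heterogeneity** (high-confidence calls) — the minority-mismatch fraction
   `1 − modal_mismatch / total_mismatches` ≥ 5%, which rejects A→G editing
   and unannotated heterozygous alleles.

For a site of stoichiometry *s*, read-through probability *r*, and
misincorporation-given-read-through probability *m*, the expected mismatch
rate among reads covering the site (truncated cDNAs never reach it) is

    rate = s·r·m / (s·r + (1 − s))

so with *s* = 0.2, *r* = 0.25, *m* = 0.9 a site shows ≈ 5% mismatches —
comfortably above the 1% gate at depth 500. The read-through rate itself is
estimated at known full-stoichiometry sites as site depth over the median
depth of the 3′ flank.

The miCLIP side analyzes reverse-transcription *truncations* instead:
read 5′ ends at offsets 0..+4 from transcription-start sites (TSS),
stacked-read clusters (score = maximum stacked depth, kept at ≥ 20),
a metagene of cluster density normalized to RNA-seq coverage, and a Fisher
exact test for enrichment of adenosine-start TSSs among cluster-overlapping
TSSs — the signature of an antibody cross-reacting with the m7G-ppp-A cap.

## Worked example

```python
from misincmap import (SimulationConfig, VariantMask, build_pileup,
                       call_candidate_sites, simulate_experiment)

config = SimulationConfig(seed=1)   # 20 replicates, 5 planted m1A-like sites
refs, annotations, truth, reads_by_rep = simulate_experiment(config)
pileups = [build_pileup(rep_reads, refs) for rep_reads in reads_by_rep.values()]
mask = VariantMask({(s.seq_id, s.position) for s in truth.snps})
sites = call_candidate_sites(pileups, mask, refs)

print(f"{len(sites)} candidate sites "
      f"({sum(s.high_confidence for s in sites)} high-confidence)")
for site in sites:
    print(f"{site.seq_id}:{site.position + 1}  {site.ref_base}  "
          f"depth={site.combined_depth}  rate={site.combined_rate:.3f}  "
          f"reps={site.replicates_detected}/{site.n_replicates}  "
          f"het={site.heterogeneity:.2f}  high_conf={site.high_confidence}")
```

prints

```
7 candidate sites (5 high-confidence)
tx0000:76  A  depth=2703  rate=0.145  reps=20/20  het=0.17  high_conf=True
tx0000:138  A  depth=3945  rate=0.194  reps=20/20  het=0.00  high_conf=False
tx0000:446  A  depth=2336  rate=0.046  reps=18/20  het=0.25  high_conf=True
tx0000:497  A  depth=2499  rate=0.130  reps=20/20  het=0.24  high_conf=True
tx0000:574  A  depth=2291  rate=0.189  reps=20/20  het=0.00  high_conf=False
tx0000:707  A  depth=2298  rate=0.032  reps=16/20  het=0.15  high_conf=True
tx0000:758  A  depth=2499  rate=0.183  reps=20/20  het=0.21  high_conf=True
```

The five high-confidence calls are exactly the five planted modification
sites (positions 76, 446, 497, 707, 758, 1-based). The two rejected
candidates (138, 574) are the planted A→G editing decoys: they replicate and
exceed the rate gate, but every mismatch is A→G, so their heterogeneity is
~0 and they never reach high confidence. The planted SNPs were removed by the
variant mask before filtering.

## Command line

Every stage is also a `misincmap` subcommand operating on standard formats
(FASTA, SAM, VCF/BED, TSV), each writing a JSON manifest of its parameters
and input checksums:

```bash
misincmap simulate --mode rnaseq --seed 1 --outdir sim/
misincmap misinc-map --ref sim/reference.fasta --sam sim/rep01.sam ... \
    --mask snps.vcf --out sites.tsv --bed sites.bed
misincmap truncate --miclip mi.sam --rnaseq rna.sam --annot annot.tsv --out trunc.tsv
misincmap clusters --sam mi.sam --out clusters.bed
misincmap metagene --sam mi.sam --rnaseq rna.sam --annot annot.tsv --out meta.tsv
misincmap tss-enrich --sam mi.sam --annot annot.tsv --out enrich.tsv
misincmap curate --sites sites.tsv --genes genes.txt \
    --annotated-tss a.bed --cage-tss c.bed --out report.tsv
misincmap make-curation-fixture --outdir fixture/
```

## Layout

- `misincmap.core_io` — FASTA/SAM/VCF/BED/TSV readers and writers; 0-based
  half-open coordinates internally, 1-based in written tables.
- `misincmap.pileup` — UMI duplicate collapsing, end clipping, per-read
  mismatch cap, per-position base counts.
- `misincmap.misinc` — the filter chain, heterogeneity, read-through
  estimation.
- `misincmap.miclip` — termination profiles, cluster calling, metagene,
  TSS enrichment.
- `misincmap.curation` — site-list curation and TSS-overlap accounting.
- `misincmap.simulate` — the seeded generative model.
- `misincmap.experiments` — self-contained simulate→analyze validation runs.

See `docs/methods.md` for the model, its assumptions, and the reasoning
behind every default.
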