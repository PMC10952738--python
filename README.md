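# bolatype

High-throughput amplicon typing of the bovine MHC (**BoLA**) class I and
class II genes: from multiplexed MiSeq reads to per-animal allele calls,
cohort haplotype catalogues, and repertoire diversity analytics.

## The problem

The classical MHC molecules determine which peptides are presented to
T cells, so characterising their allelic repertoire in a cattle population
is foundational for immunology and vaccine design.  The bovine loci are
awkward to type: class I (BoLA-I) is polygenic with 1–4 genes expressed per
haplotype, and the class II DQ region carries one *or two* DQA/DQB gene
pairs per haplotype, all of them highly polymorphic in exon 2.  Sequencing
pooled exon-2 amplicons on a MiSeq resolves this, provided the
bioinformatics can (a) separate true alleles from PCR/sequencing artifacts
and (b) phase the called alleles into haplotypes without pedigrees, using
recurrent co-segregation across a cohort.

`bolatype` implements that platform end to end:

* **reads** — MID-tag demultiplexing, paired-end merging, Q28 screening,
  IUPAC primer trimming, 100 %-identity clustering, and the four artifact
  filters (ambiguous bases, ±9 bp length deviants, PCR chimaeras, 1 bp
  variants) followed by per-locus read-frequency thresholds
  (DQA 7 %, DQB 2 %, class I 0.2 %);
* **alleles / genotyping** — exact-match calling against IPD-style
  references; unmatched sequences classified by the ≤ 4 amino-acid rule
  into synonymous variants, new allelic-group members, or new groups, and
  named provisionally (`BoLA-DQA*024:AA`, `BoLA-DQB*zm1:01`);
* **haplotyping** — seed-and-subtract co-segregation inference with
  zygosity and ambiguity calls, DQ pairing by cohort-wide co-occurrence
  (orphan pairs when DQA fails to amplify), and primer-set concordance for
  the two redundant class I PCRs;
* **nomenclature** — DQ-pair tokens (`DQ30.1`), DR tokens (`DR23.1`),
  MHCII haplotype names (`DR23.1|DQ30.1`), class I `HP1.family.variant`
  names, all driven by a replayable JSON registry;
* **diversification** — association graphs of co-segregating elements at
  four genomic levels, with each association classified as one-to-one,
  index, mutation/gene-conversion (MU/GC) or recombination;
* **diversity** — Jaccard, Morisita-Horn, D90, Shannon, Simpson, Hill
  numbers, and bootstrap subsampling for cross-population comparison;
* **simulate** — fully specified synthetic cohorts (planted allele groups,
  geometric haplotype pools, diploid draws, artifact-bearing reads) with
  truth tables, so every stage is testable offline.

Two published haplotype catalogues (a Holstein-Friesian herd and a
three-breed Zambian cohort) ship as package fixtures and anchor the
validation suite.

## Worked example

Classify the DQA/DQB pairings of the bundled Holstein-Friesian catalogue
and summarise its MHCII diversity:

```python
from bolatype import fixtures as fx
from bolatype.diversification import build_graph, classify_edges, summarize
from bolatype.diversity import FrequencyProfile, entropy_suite

rows = fx.load_mhc2_table()
s = summarize(classify_edges(build_graph(rows, "hf", "pair")))
print(s.total, s.counts)

prof = FrequencyProfile("hf", {r.base_name: r.hf_n for r in fx.cohort_rows(rows, "hf")})
d = entropy_suite(prof)
print(d.richness, round(d.shannon, 3), round(d.simpson, 3), d.d90)
```

prints

```
20 {'one_to_one': 10, 'index': 4, 'mu_gc': 3, 'recombination': 3}
20 2.476 0.897 11
```

Read it as: the herd expresses 20 distinct complete DQA/DQB pairs; half of
them are exclusive one-to-one allele partnerships, while the rest fall into
four related groups whose non-index members look like products of
mutation/gene conversion (3) or recombination (3).  The 20 MHCII haplotypes
have Shannon entropy 2.48 nats and the 11 most frequent cover 90 % of the
652 haplotype observations (two per animal; homozygotes counted twice — the
most frequent haplotype, DR1.1|DQ1.1, accounts for 95/652 = 14.57 %).

The same analyses run from the command line:

```bash
bolatype simulate --seed 5 --cohort-size 8 --depth 200 --out sim/   # synthetic run + truth
bolatype type --merged-fastq DQA sim/DQA_merged.fastq \
              --reference DQA sim/reference_DQA.fasta ... --out typed/
bolatype haplotype --genotypes typed/genotypes.tsv --out haps/
bolatype analyze --cohort hf --out analysis/
```

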