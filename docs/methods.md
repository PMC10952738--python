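# Methods

`bolatype` re-implements a MiSeq-based platform for typing the expressed
classical MHC genes of cattle (BoLA): class I (1–4 co-expressed genes per
haplotype), DRB3 (one functional locus) and DQA/DQB (one or two co-expressed
gene pairs per haplotype).  The pipeline goes from multiplexed amplicon
reads to per-animal genotypes, from genotypes to cohort haplotype
catalogues, and from catalogues to diversification and diversity analytics.
This note records the model, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Amplicon model

Each locus is amplified from cDNA with primers in the conserved flanking
exons so that the entire polymorphic exon 2 is sequenced.  The default
geometries are:

| locus | amplicon | exon partition | frequency threshold |
|-------|----------|----------------|---------------------|
| DQA   | 324 bp   | 36 + 267 + 21  | 7 %  |
| DQB   | 320 bp   | 24 + 270 + 26  | 2 %  |
| DRB3  | 320 bp   | 24 + 270 + 26  | 2 %  |
| MHCI  | 414 bp   | two exons      | 0.2 % |

The DQA/DQB geometries and thresholds are the platform's published
operating points (the DQB amplicon is quoted as ~319 bp; the exon partition
sums to 320, which is what the package uses).  DRB3 has no restated
threshold on this platform; it defaults to the DQB value of 2 % and is
configurable.  The DRB3 and MHCI geometries are package defaults used by
the simulator and the length filter; real references override them.

An `AlleleRecord` stores the **primer-trimmed** amplicon region (the
"insert"), because that is what a merged, oriented, trimmed read yields and
what allele calling compares against.  The ±9 bp length filter is therefore
applied against the expected insert length.  Exon 2 is translated with the
standard code; an internal stop codon is an error unless the allele carries
the null flag (trailing `N`).

## Read pipeline

* **Demultiplexing** — exact match of both 5′ MID tags; near-miss tags are
  counted and dropped (no error correction: with 192 tag combinations a
  1-mismatch radius would risk cross-talk, the dominant failure mode the
  platform's contamination flag exists for).
* **Merging** — best-scoring ungapped 3′ overlap (score = matches −
  mismatches, mismatch fraction ≤ 0.25, minimum overlap 10 bp); overlap
  disagreements resolve to the higher-quality base call.  Pre-merged
  single-end FASTQ is accepted as an alternative entry point.
* **Quality screen** — mean Phred strictly above Q28, per read.  The
  original screen's granularity (per-base vs per-read) is unstated;
  mean-per-read is adopted.
* **Primer trimming** — both orientations tried; IUPAC-degenerate primer
  positions match their base set; up to 2 mismatches per primer.
* **Clustering and filters** — reads are clustered at 100 % identity and
  frequencies computed over *all* clustered reads of the sample-locus
  (removal does not re-normalise survivors; a switch enables
  re-normalisation).  Fates are assigned in a fixed order:
  1. ambiguous base calls (N);
  2. length more than ±9 bp from the expected insert;
  3. PCR chimaeras: the cluster equals `prefix(P1, i) + suffix(P2, i)` for
     an internal crossover of two distinct surviving clusters that each
     have strictly greater counts, and differs from both parents;
  4. 1 bp variants: unit edit distance 1 (substitution **or** single indel)
     from a surviving cluster of strictly greater count.  Removed variants
     are not added to their parent (a switch absorbs them instead);
  5. the per-locus frequency threshold.
  Cluster order (count descending, then sequence) makes the chain
  deterministic and idempotent; re-running on retained clusters changes
  nothing.  The chain is validated against a brute-force oracle that
  enumerates every parent pair and crossover position.

## Genotyping

Retained clusters that match a reference sequence exactly keep their
names.  Unmatched clusters are classified: identical exon-2 peptide →
synonymous variant; within 4 amino acid differences of the nearest
reference → new member of that allelic group; further → new allelic group.
The 4-aa rule is evaluated on exon 2 only (the polymorphic region the
groups are defined over), with unit-cost edit distance when peptide lengths
differ (gaps cost 1 each; the convention is configurable to
Hamming-only-with-error).  Null alleles stay in the database but are
excluded from peptide-distance searches.  Ties resolve to the
lexicographically smallest allele name.

Class I genotypes merge two redundant PCR reactions (For1/Rev2, For3/Rev1)
by allele-set union; per-set normalised frequencies are kept, and a set
with no amplicon is recorded as not-amplified rather than zero.  Quality
flags: `insufficient_data` below `min_reads` (default 200 per locus, at
which the 7 % DQA threshold still corresponds to ≥ 14 reads — the study
states no explicit cutoff) and `contamination_suspect` when a locus
exceeds diploid capacity (8 MHCI / 2 DRB3 / 4 DQA / 4 DQB alleles).

## Nomenclature

Novel alleles get alphabetic fields so they can never collide with
official numeric names: `group:AA` for new members, `group:protein:AA` for
synonymous variants, `cc<N>:01` (country-coded) for new groups.  DQ pairs
get `DQm.n` tokens (`m` = unique combination of DQA and DQB allelic
groups, `n` = allele-level variant within it); orphan pairs whose DQA
never amplified key on (unknown, DQB group), so two orphans with the same
DQB allele share a token.  DR tokens abbreviate DRB3 alleles (numeric
fields lose leading zeros, numeric synonym fields are dropped, alphabetic
provisional fields are kept: `020:01:AA` → `DR20.1.AA`).  MHCII haplotype
names concatenate the DR token and the DQ tokens; MHCI haplotypes are
`HP1.family.variant` with the family keyed by the allelic-group multiset.
Single-animal haplotypes carry the `un` (unconfirmed) prefix.

All naming flows through a `NameRegistry` that serialises to JSON and
replays byte-identically.  The registries shipped for the bundled tables
are primed from the printed name column (not re-derived), because the
historical numbering of families across earlier studies is not derivable
from a single catalogue; fresh cohorts start from empty registries and
issue numbers sequentially.  The bundled MHCII table contains one internal
naming conflict (`DQ53.1` printed for two pairs with different DQB
groups); priming is first-occurrence-wins on the family key while the
exact pair→token map keeps every printed row reproducible.

## Haplotype inference

No pedigree or statistical phasing: haplotypes are recurrent
co-segregation patterns.  Class bounds — MHCII: one DRB3 allele plus one
or two DQ pairs; MHCI: 1–4 alleles.  The fixed-point procedure visits
animals in (genotype size, id) order and, per animal: (1) accept an exact
partition of the called-allele sets into one or two catalogued haplotypes;
(2) else, if a catalogued haplotype is a proper subset and the remainder
is class-valid, catalogue the remainder (subtraction); (3) else, if the
genotype itself fits single-haplotype bounds, seed it.  Iterate to a fixed
point, then re-derive every animal against the finished catalogue: exactly
one decomposition → resolved (homozygous/heterozygous); several →
ambiguous (excluded from catalogue counts); none → unresolved, except that
genotypes beyond diploid capacity are tested for a unique three-haplotype
decomposition (blood-chimaeric twins, zygosity `multi`).  Processing
order, not input order, drives the loop, so the catalogue is invariant
under permutation of the input.

Decomposition-before-seeding (size order) is the package's resolution of
an ordering the original description leaves open; seeding every
single-consistent animal first would let a 4-allele MHCI heterozygote
masquerade as a homozygote.  Inference is checked against an exhaustive
oracle that enumerates all bipartitions of the allele multiset (≤ 12
elements per animal).

Counting: a haplotype is *confirmed* when observed in ≥ 2 resolved
animals; homozygotes count once toward confirmation but twice toward
observation totals (so 326 animals yield 652 haplotype observations and a
haplotype seen in 95 of them has frequency 14.57 %); `multi` animals
contribute one observation per haplotype.

DQ pairing (which DQA goes with which DQB) uses cohort-wide perfect
co-occurrence; DQB alleles with no matching DQA signature become orphan
pairs.  Two DQ pairs that always travel together (a duplicated haplotype
never broken up by recombination in the cohort) are genuinely
unidentifiable from presence data; the package pairs them lexicographically
and the simulator adopts the same convention.

## Association graphs

Four levels: DQA/DQB alleles within DQ pairs, paired DQ tokens within
duplicated haplotypes, DR↔DQ haplotypes, MHCI↔DR haplotypes.  Edge weight
is the summed observation count.  Orphan pairs are excluded at the pair
level.  Classification is descriptive (no parent/derived direction):
within each group of related edges, the most frequent is the *index*;
an edge whose every difference from the index stays within an allelic
group is a mutation/gene-conversion (MU/GC) proxy; an edge sharing an
element but crossing groups on the other side is a recombination proxy;
an edge related to nothing is one-to-one.  Groups are formed symmetrically
at the pair and duplicated-DQ levels (shared endpoint, or identical
group-signature on both sides); at the DR↔DQ and MHCI↔DR levels they are
rooted on the non-DR side — a DQ or MHCI haplotype recurring with several
DR elements forms a group, a DR allele recurring across haplotypes does
not by itself, since the DR locus is the anchor between the regions being
compared.  The group-signature rule (both sides in the same allelic
groups) is what lets pairs such as (012:05, 010:05) and (012:06, 010:01)
— same group combination, no shared allele — fall into one family, which
the token nomenclature (`DQ12.x`) also implies.

Both counting modes for DQ pairs are exposed: distinct `DQm.n` tokens or
distinct allele-level combinations, each with or without literature-
presumed (never-amplified) DQA partners.

## Diversity statistics

Jaccard (presence overlap), Morisita-Horn (frequency-weighted overlap,
`2Σp_iq_i / (Σp_i² + Σq_i²)`), D90 (fewest most-frequent haplotypes
covering 90 % of observations; ties broken by name), Shannon entropy
(natural log — no base is specified upstream), Simpson diversity
(`1 − Σp_i²`) and Hill numbers (`(Σp_i^α)^{1/(1−α)}`, with the α→1 limit
`exp(H)` and α=0 giving richness).  Observation profiles count two
observations per animal (homozygotes twice); site-level comparisons
exclude sites under 20 animals by default.  Bootstrap comparison draws
equal-sized animal subsamples (default 100 animals × 100 replicates)
without replacement (with replacement only when the population is smaller,
or on request) and reports mean cumulative-frequency curves, min–max
envelopes and the D90 distribution.  Implementations are direct closed
forms, cross-checked in the test suite against scikit-bio and brute-force
summation.

## Synthetic data

The simulator emulates the study conditions end to end: reference sets
with planted allelic-group structure (group members differ by 1–4 amino
acids in exon 2, groups are independent random codon sequences), a
haplotype pool with geometric rank-frequency decay (r = 0.75 — a long
descending tail like the observed haplotype spectra), diploid animals as
two independent draws from the pool (Hardy-Weinberg), and per-sample-locus
reads at fixed depth (default 1000) carrying substitution errors (default
0.1 %/base), single-crossover chimaeras between co-amplified alleles,
N injections and ±10–30 bp length artifacts at configurable rates.
Paired-end mode wraps each insert in realised primers and MID tags and
splits it into overlapping 250 bp mates.

Deliberate idealisations, and what they mean for the tests: pool
haplotypes are **allele-disjoint** by default, so co-segregation alone
identifies them — passing the recovery suites shows the inference machinery
is correct, not that real cohorts (where promiscuous alleles such as a
single DQA recurring across many haplotypes create genuine ambiguity) are
always resolvable; ambiguity handling is exercised by dedicated hand-built
cohorts instead.  Expression is uniform across a haplotype's alleles,
quality strings are flat, and there is no position-dependent MiSeq error
profile or chimera-abundance model.  Every generated dataset ships truth
tables, and all end-to-end tests compare pipeline output to planted truth,
never to other pipeline output.

## Problem sizes in the shipped suites

The validation suites run at desk scale by choice: 200 random ≤ 10-cluster
instances for the filter-vs-oracle check, a 200-animal cohort from 15
planted haplotypes for inference recovery, and end-to-end read-level
checks on cohorts of 5 (artifact-free, exact recovery) and 34 animals
(0.1 % error + 5 % chimeras at depth 1000, ≥ 99 % per-sample-locus allele
call accuracy, ≥ 100 sample-locus cells).

## Known limitations

* The per-animal replication suite (zygosity split, bootstrap D90 of the
  class I repertoire, MHCI–DR association counts) needs the study's
  per-animal supplementary tables, which are not redistributable inside
  the package; the corresponding test documents the expected file layout
  and fails until they are supplied.
* At the duplicated-DQ level the published grouping granularity is
  underdetermined; the symmetric shared-token rule reproduces the
  catalogue's duplicated-haplotype counts but can differ by one edge in
  the MU/GC-vs-recombination split.
* Chimera detection considers forward-orientation parents only, and
  1 bp-variant collapse is count-blind beyond the strictly-greater-parent
  rule — no abundance model (cf. denoising algorithms) is applied.
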