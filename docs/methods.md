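# Methods

## The problem this package models

A fully penetrant recessive coat-texture mutation segregates in an inbred
mouse stock.  The classic positional-candidate route to its molecular basis
has five computational stages, each implemented here as a standalone,
testable module:

1. **Testcross simulation** (`woolmap.genetics`) — an (A × N)F1 female,
   heterozygous for the mutation, is bred back to homozygous mutant males.
   Every N2 progeny's phenotype then reads out the allele the dam
   transmitted at the trait locus, and every marker genotype (H vs N) reads
   out the dam's allele at that marker.
2. **Recombinant-counting linkage mapping** (`woolmap.mapping`) — the trait
   is one more locus on the transmitted haplotype; flanking markers are the
   nearest loci showing at least one trait–marker recombinant per side.
3. **Two-stage refinement** — progeny recombinant inside the coarse
   interval (and only those) are typed at interval-internal SNPs; everyone
   else is implicitly parental across the interval.
4. **Candidate triage** (`woolmap.triage`) — published-evidence rules prune
   the interval gene list to primary candidates.
5. **Deletion detection and consequence prediction** (`woolmap.variants`,
   `woolmap.consequence`) — coisogenic wild-type and mutant sequences are
   compared, the single deletion is normalized and annotated against the
   gene models, and the mutant transcript, RT-PCR amplicons, protein and
   domain losses are predicted.

## Meiosis model

Crossovers follow the Haldane (no-interference) model: the crossover count
in an interval of genetic length *d* Morgans is Poisson(*d*), so the
dam-derived allele switches between adjacent loci with probability
r = (1 − e^(−2d))/2.  Only the dam's meiosis is simulated — the sire is
homozygous at every locus by design, so his gametes carry no information.
Interference is deliberately not modelled: the intervals of interest are
short (≤ a few cM), where interference changes double-crossover rates that
are already negligible, and the recombinant-counting estimator does not
depend on it.

Parameters that matter:

- `n` (progeny count): default study condition 1,679 — the replica family
  size.  SE of r̂ scales as 1/√n.
- `penetrance` ∈ (0, 1], default 1.0: probability a mutant-genotype animal
  shows the mutant phenotype.  The trait is treated as fully penetrant
  everywhere in the replica conditions.
- `genotyping_error` ≥ 0, default 0.0: per-call flip probability H↔N.
- `cm_per_mb`, default 0.5: the linear bp→cM conversion used when building
  maps, a typical mouse autosomal average.
- Seeds are explicit everywhere; no global random state is touched.

## Localization algorithm

For each progeny the markers concordant with the trait allele must form a
single contiguous block; the nearest discordant marker on each side of the
block becomes that progeny's flank candidate.  The reported proximal flank
is the candidate closest to the trait from below (maximum position), and
the count of recombinants attributed to a flank is the number of progeny
whose candidate it is.  Markers with zero trait recombinants therefore fall
inside the interval.  Progeny whose concordance pattern is non-contiguous
(or empty) would require two crossovers inside a single marker interval;
they are flagged as putative genotyping errors or penetrance failures,
retained in recombination-fraction estimates, but excluded from interval
bounds — no single trait position is consistent with them.  A
`drop_flagged` switch removes them entirely.  Refinement re-runs the same
algorithm on the union map; a guard clips the result to the previous
interval so refinement can never widen it.

The segregation check is the raw χ² goodness of fit to 1:1 with df = 1 and
no continuity correction — at n ≈ 1,700 the correction is immaterial.

## Deletion calling

Coisogenic strains differ at a single event by construction, so the caller
is alignment-free: longest common prefix P and suffix S bound every
placement of a deletion of length L = |wild| − |mutant|; placements form
the contiguous range [|mutant| − S, min(P, |mutant|)], the left-most is
reported (standard indel normalization), and the absorbed range is exposed
as `ambiguity_span`.  Anything violating the single-contiguous-deletion
model raises an error naming the first conflict position.  VCF output uses
the 1-based anchor-base convention.

Splice sites are defined structurally: acceptor = last 2 intronic nt + the
first exonic nt; donor = last exonic nt + first 2 intronic nt, both in
transcription orientation; losing any base of a site counts as loss.  No
motif scoring or branch-point modelling is attempted — the inference being
reproduced rests on physical removal of the acceptor.

## Consequence prediction

The skipping rule is purely structural and isolated in one function: an
exon that loses a splice site is dropped; a partially deleted exon with
intact sites keeps its remainder; intron-internal deletions change
nothing.  Donor loss triggers skipping symmetrically — the replica only
exercises acceptor loss, and the symmetric choice is the simplest rule
consistent with it.  Deleting the CDS start codon is outside the rule's
domain and raises an error.

Amplicon lengths are inclusive of both primer 3' ends (the size a gel
reports): first base of the forward site to last base of the reverse site
on the spliced transcript.  Translation uses the standard nuclear codon
table to the first stop (Biopython); proteins are compared by common
prefix, which is exact for single-junction events; a frameshift is
reported iff the count of removed coding nucleotides is not a multiple of
3 — an in-frame skip diverges in sequence but keeps frame.  Domain
retention is the fraction of a domain's aa span inside the common prefix.

## The replica locus fixture

The generator emits a 12-kb random-background sequence carrying two
engineered genes, chosen so every published computational anchor is
reproduced exactly:

- Gene B (Fam83g-like, + strand): exons 700/214/125/1000/700 nt, CDS of
  2,439 nt (812 codons + stop) starting 100 nt into exon 1.  600 + 214
  coding nt precede exon 3, so the codon for residue 272 (engineered as
  serine) spans the exon-2/3 junction and skipping the 125-nt exon 3
  shifts the frame by 2.  The shifted frame of exon 4 is engineered to
  carry no stop for 23 codons and TAA as the 24th, so the skipped product
  carries exactly 24 novel residues (divergence after codon 271, 295-aa
  product).  The nested primer pair (exon 1 offset 600, exon 4 offsets
  17–44) spans 484 bp on the wild-type spliced transcript and 359 bp after
  the skip — the difference is the skipped exon.
- Gene A (Slc5a10-like, + strand): thirteen 100-nt exons; its intron 10–11
  (7 kb) contains gene B's deleted region entirely, so the deletion is
  intronic for gene A and its splicing is untouched.
- The 955-bp deletion removes the last 830 nt of gene B's intron 2–3
  (including the exon-3 acceptor) plus all of exon 3.  Its boundaries are
  anchored so left alignment recovers the injected coordinates uniquely.

Engineering details: all introns get canonical GT..AG ends; internal stop
codons are destroyed by setting the codon's middle base to C (no stop
contains C, so the fix can never create one elsewhere); ORFs end in TAA.
Only the background bases depend on the seed, so every anchor above is
seed-invariant — a property the acceptance script relies on.

The replica backcross panel is deterministic: 1,679 progeny encoding the
published totals (840 mutant : 839 normal; 11 recombinants between the
proximal flank and the trait; 19 between the trait and the distal flank;
none between the trait and the cosegregating middle marker), with
plausible filler counts in the outer intervals.  The SNP typing preset
places two crossovers between SNP2 and the trait and one between the trait
and SNP6, refining the interval to SNP2–SNP6 (0.75 Mb).

## What the synthetic data does and does not show

Fixtures are uniform-random background with engineered constraints.  They
share none of the repeat structure, GC/codon bias, segmental duplications
or genotyping-artefact patterns of real mouse data, and marker
informativeness is perfect (every marker fully distinguishes the two
strains).  Passing tests therefore demonstrate the correctness of the
*algorithms* under the stated model — not robustness to real-genome
messiness such as ambiguous indel placement in long repeats, segregation
distortion, or partially informative markers.

## Numerical choices and problem sizes

Internal coordinates are 0-based half-open; GFF3 and VCF output are
1-based; report text is 1-based.  Simulation-based checks use: 100 panels
of n = 1,679 for interval containment; 20 pooled panels (~33,000 meioses)
for the Haldane consistency of r̂ (3-SE bands); 2,000 replicates for the
KS uniformity of null segregation p-values (α = 0.01); 1,000 random
injected deletions and 500 random CDSs for the comparator and translation
oracles.  These sizes give the property checks comfortable statistical
power while keeping the default suite fast.

## Known limitations

- Single-chromosome maps only; F2/intercross designs, sex linkage and
  quantitative traits are out of scope.
- The exon-skipping rule is binary; splice-strength changes, cryptic-site
  activation and NMD are not modelled.
- The deletion comparator handles exactly one contiguous deletion; any
  other difference is an error by contract, not a call.
- Frameshift-stop engineering in the generator supports only the 1-base
  codon-carry junction geometry; other phases raise a validation error.
- Haplotype-class output reflects the replica's encoded totals; published
  per-class counts were only ever available graphically.
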