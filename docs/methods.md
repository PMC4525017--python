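# Methods

This note records the models, parameter choices and numerical decisions
behind `c5nscreen`, and what the synthetic benchmarks do and do not show.

## The screening model

Producers of C5N-unit metabolites carry a cyclizing 5-aminolevulinate
synthase (cALAS) encoded by a *hemA* homolog inside the biosynthetic
cluster, next to an amide synthase (*ams*) and an aminolevulinate-CoA
ligase (*all*).  The package operationalises four observations:

1. two amino-acid stretches of ALAS are conserved enough to anchor
   degenerate PCR primers, giving a single product of invariable size
   from both classical and cyclizing *hemA* genes;
2. a small set of residues — Thr83→Ser (active site, mandatory),
   Ile149→Leu/Val, Asp231→Thr, Thr365→Ser in reference numbering —
   separates cALAS from classical ALAS;
3. the *ams–hemA–all* triad arrangement (head-to-tail vs divergent)
   tracks the metabolite class, as does the fragment's phylogenetic
   neighbourhood;
4. classical *hemA* genes acquired horizontally stand out by GC content,
   split at 62 % into a GC-rich and a GC-poor donor group.

## Degenerate primers and virtual PCR

The screening primers are modelled as IUPAC strings.  The forward primer
is printed in its source with an "S/R" at one position; the package reads
this as the union of the two base sets (IUPAC V, {A,C,G}), giving a
25-mer; `expand_two_variant` provides the alternative two-oligo reading.
A consequence of the single-oligo reading is that the primer is only in
frame with the conserved VWCS... motif for its first four codons, so the
synthetic templates embed the footprint as literal nucleotides and their
translation departs from the motif downstream of those codons.  This has
no effect on any downstream computation: the diagnostic positions lie
outside both footprints.

Matching semantics: a primer position is compatible with a template
position when the base sets intersect; template Ns match nothing
(conservative).  Defaults: `max_mismatches = 2`,
`require_3prime_exact = 3` (an exact 3′ end mimics the polymerase
extension requirement), size window 300–800 bp.  Product lengths include
both primer footprints, so the canonical band is
25 + 467 + 27 = 519 bp; a deficit of 20–120 bp is classed as the
off-target band.  These stringency values are package choices — the wet
assay's touchdown program has no in-silico equivalent — and all are
exposed in configuration.

## Reference, panel and verdict rule

Reference numbering for diagnostic residues differs between published
ALAS structure models, so the package ships its own 400-residue
**synthetic** reference protein (`data/calas_reference_synthetic.faa`;
the scaffold is a fixed random draw from a streptomycete-like amino-acid
composition with the footprint translations and cALAS residues
installed) and defines the panel in that reference's coordinates
(`data/panel.yaml`).  Both files can be swapped wholesale to use a real
reference and its numbering.

Alignment is global with free end gaps (so a 173-residue amplicon
translation maps onto the full-length reference), BLOSUM62, gap open 10
and extend 1, where a gap of length L costs 10 + (L−1).  Identity and
similarity are percentages over aligned (non-gap) columns; similarity
counts columns with a positive substitution score.  The homology
pre-filter keeps candidates with identity ≥ 40 % and similarity ≥ 60 %.

Verdict rule (exposed in config): **cALAS** iff position 83 is
cALAS-consistent and at least 2 of the remaining 3 core positions are;
**classical** iff position 83 is observed and every *observed* core
position is classical-consistent.  The "observed" qualifier matters for
amplicons: the 519 bp fragment covers reference positions ~70–242, so
position 365 is structurally unobservable there, and requiring all four
positions would make the classical verdict unreachable for exactly the
fragments the assay produces.  Unobserved positions never *support* a
verdict, they only stop blocking one.

## Triad typing and the GC/HGT rule

Triad typing works on annotation only (labels `ams`/`hemA`/`all`);
inferring labels from homology is out of scope.  `head_to_tail` requires
the three genes adjacent on one strand reading ams→hemA→all along that
strand; `divergent` requires the ams–all pair adjacent (ams first along
its strand) with hemA on the opposite strand upstream of the pair.
Adjacency means intergenic gaps ≤ 1000 nt (default; the source figures
show adjacency but quantify no gap).  Duplicate labels resolve by the
combination with the smallest genomic span; overlapping same-label
features are rejected.  Both rules are invariant under
reverse-complementing the contig.

GC is computed on the *hemA* CDS or amplicon (not the contig), Ns
excluded.  For non-cALAS verdicts, GC > 62 % → blue branch I, otherwise
blue branch II; equality is assigned to branch II so the rule is total
(the source partition ">62 / <62" leaves the boundary open).

## Branch placement

Full Bayesian phylogenetics is deliberately replaced by a desk-scale
procedure: k-nearest-neighbour majority vote (k = 3) on nucleotide
distance against a labelled panel, ties broken by smaller mean vote
distance then lexicographically, with support = fraction of B = 100
bootstrap column-resamples reproducing the point label.  Distances are
p-distance by default (JC69 optional; it is a monotone transform of p,
so rankings and hence assignments are identical).  Neighbor joining is
implemented in-package because the repair rule for negative branch
lengths is pinned down (clamp to zero, deficit moved to the sister edge,
preserving the joined pair's path length); the NJ tree is reporting
output only and never feeds the assignment.  Queries of non-panel length
are projected onto panel coordinates by global nucleotide alignment
(match +1, mismatch −1, gap −2, free ends).

## Fingerprints

Lane curves are linearly resampled to 256 samples and min-max scaled
(constant curves are flagged, not scaled; the proprietary normalization
of gel-analysis software is not reproducible from published
descriptions).  Similarity is Pearson r × 100 without clamping.
Grouping is agglomerative complete linkage on distance = 100 − s, cut at
distance 100 − limit (limit 70 % by default); with complete linkage this
cut *is* the guarantee that every within-group pair meets the limit, and
raising the limit only refines groups.  Dereplication keeps the
lexicographically smallest strain id per (group, habitat) cell.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not *hemA* biology:

* **Scaffold.**  Every non-negative gene class shares one fixed
  400-codon scaffold (the packaged reference), so alignments are trivial
  and position maps exact.  Class identity lives in the four diagnostic
  codons; branch identity lives in 60 reserved synonymous "barcode"
  codons inside the amplified region, chosen deterministically per
  branch label, so fragments cluster by branch while the protein is
  untouched.
* **GC3 control.**  Codons are sampled with a per-gene probability q of
  drawing a G/C third base, solved so the gene-wide mean GC3 lands on
  the configured target given all fixed codons (footprints, barcodes,
  single-codon amino acids); within the chosen third-base class the
  codon with extreme (max or min, following the target) GC at positions
  1–2 is preferred.  Measured over 100 genes the mean GC3 sits within
  0.5 points of targets 0.55 and 0.90.  Defaults: GC3 0.90 for
  streptomycete-like classes (gene GC ≈ 70 %), 0.45 for the low-GC
  class (≈ 49 %), placing the two classical classes firmly on either
  side of the 62 % split.  A steered variant maps a whole-fragment GC%
  target through a linear calibration (GC ≈ 41.6 + 30.6·u per unit of
  the steering parameter) for boundary studies.
* **Classes.**  cALAS purple/green/other (branches drawn from the
  matching producer sets), classical high/low-GC, an off-target class
  carrying both primer sites 30–90 nt (default 60) closer together, and
  negatives built on an independent random protein with neither site.
* **Mutation.**  Point mutations at the configured per-site rate spare
  the primer footprints and diagnostic codons, so truth labels stay
  valid at any rate; this is a stronger protection than the minimal
  3′-base requirement and reflects the assay's observed invariable band.
  Spacer variability is exposed (`spacing_jitter`) but defaults to 0.
* **Cohorts** round class fractions by largest remainder; the default
  mix (13 % PCR-positive, ~85 % of on-target positives cyclizing) echoes
  screening-scale proportions.
* **Fingerprints** are sums of 8–15 Gaussian peaks over 256 samples plus
  i.i.d. Gaussian noise, clipped at zero — no gel physics, no real BOX
  element positions.

Because real data have indels, annotation errors, uneven coverage and
non-scaffold diversity, passing these benchmarks shows the *pipeline
logic* is correct (rules, thresholds, determinism, recovery under
controlled noise), not that the classifier is calibrated for field data.

## Determinism and numerics

All randomness flows through `numpy.random.default_rng` seeded from the
config (sub-streams keyed by class, index or purpose), so identical
seeds give byte-identical outputs, including bootstrap supports.  JC69
errors at p ≥ 0.75; Pearson similarity errors on constant curves; GC
errors on empty/all-N input; merge and vote ties break by smallest
index / lexicographic order as documented above.

## Known limitations

* Single-oligo reading of the ambiguous forward-primer position (see
  above); the two-variant mode exists but is not the default.
* No melting-temperature or thermodynamic annealing model.
* No profile-HMM/PSSM classification; four residues only by default
  (extended panel positions are supported but ship empty).
* Triad detection trusts the annotation; impaired genes and PKS domain
  architecture are out of scope.
* Placement is nearest-neighbour, not model-based phylogenetics; the
  packaged panel is synthetic and labelled by construction.
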