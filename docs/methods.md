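# Methods

## The filtering model

`vcfsieve` treats causal-variant identification as sequential set algebra
over decomposed variant observations. A variant observation is the exact
tuple (chromosome, 1-based position, reference allele, one alternate
allele) plus a zygosity (heterozygous or homozygous-alternate).
Multi-allelic VCF records are decomposed into one observation per carried
alternate allele before anything else happens: a 1/2 genotype yields two
heterozygous observations, and those count as two *distinct* variants
everywhere downstream — in particular, a double-HET multi-allelic site
inside one unit is a legitimate compound heterozygote, since the two
alternate alleles are different alleles of the same locus.

Assumptions inherited from this design:

- **Diploid genotypes.** Haploid or polyploid GT fields are an error by
  default; a lenient mode maps "all present alleles are one alt" to
  homozygous-alternate and any other carriage to heterozygous. Partially
  missing diploid genotypes (`./1`) are conservatively heterozygous.
- **No normalisation.** Variants match only on the exact 4-tuple; indel
  left-alignment is an upstream concern and all inputs to one analysis
  must be normalised consistently. Chromosome names are opaque strings;
  an optional harmonisation mode adds or strips a `chr` prefix, because a
  silent `chr1`/`1` mismatch is the worst failure mode of set-based
  filtering.
- **No phase.** Compound heterozygosity means ≥ 2 distinct HET variants in
  one unit in one sample, regardless of phase; two variants truly in cis
  will qualify. No phasing input exists in this model.
- **Point anchoring.** A variant belongs to a unit when its POS lies in
  one of the unit's intervals. The span of a long deletion is ignored — a
  documented limitation for structural/indel variants, which are otherwise
  supported only insofar as they are representable as REF/ALT records.

## Penetrance and detectance

The case/control filters are parameterised by two fractions. With `n_s`
cases split into `n_c` sharing the common cause and `n_d` phenocopies, and
`c` controls split into `c_g` non-penetrant carriers and `c_c` genetically
healthy individuals:

- penetrance = `n_c / (n_c + c_g)` — probability of the phenotype given
  the causal genotype;
- detectance = `n_c / (n_c + n_d)` — probability of carrying the shared
  causal genotype given the phenotype.

Since only `n_s` and `c` are known a priori, the package enumerates the
feasible grids (`n_d` over `0..n_s−1`, `c_g` over `0..c`) for the user to
choose from. Chosen levels are lower limits and convert to the integer
retention thresholds `n_c = ceil(detectance·n_s)` and
`c_g = floor(n_c/penetrance − n_c)`, clamped to `[1, n_s]` and `[0, c]`.

**Rounding.** For levels picked off the enumerated grids, ceil for `n_c`
and floor for `c_g` is the unique rounding that keeps the guarantee
"every variant whose achieved levels are at least the requested levels is
retained"; achieved levels are reported back on the threshold object. A
snap tolerance of 1e-9 absorbs float noise so that on-grid fractions
round exactly; genuine off-grid inputs differ from grid points by far
more than that. Explicit integer overrides (`--min-cases`,
`--max-controls`) bypass the fraction machinery entirely; `--min-cases`
may exceed `n_s`, making the filter deliberately unsatisfiable.

## Control-filtering semantics

- **Dominant, both levels:** every control variant filters regardless of
  zygosity.
- **Recessive, nucleotide:** only homozygous control observations filter;
  a heterozygous control is a plausible unaffected carrier.
- **Recessive, unit:** two consecutive steps. First, case variants
  homozygous in controls are filtered. Second, for every control that is
  compound heterozygous within a unit, *all* of that control's variants in
  that unit become usable for filtering. The `c_g` allowance is counted
  per variant across controls (a variant survives while at most `c_g`
  controls filter it), while `n_c` is counted per unit (a unit is retained
  while at least `n_c` cases still qualify on the surviving variants).
  Where a control is compound heterozygous, each of its variants filters
  matching case variants independently; no joint pair-matching between the
  control's pair and a case's pair is required. This is the natural
  reading of "all compound heterozygous variants are used for filtering"
  and is the more conservative (stronger-filtering) choice.
- **Family (trio) mode:** retain variants heterozygous in the child and
  absent at any zygosity from every supplied parent. One family per
  invocation; unrelated controls must not be passed, since the filter
  would treat them as parents and remove variants on invalid assumptions.
  Running with one parent is allowed with a loud warning. A
  `family_recessive` convenience (child homozygous, both parents
  heterozygous) is provided as a clearly-labelled extension.

## Database filtering

With a MAF cutoff of 0, membership in the database is sufficient to
remove a variant. With a positive cutoff, only database variants whose
*folded* minor allele frequency (`min(af, 1−af)`) is at least the cutoff
are used — the rationale being that for rare traits the causal variant,
if present in a database at all, will be rare there, so it is the
known-common variants that are safe to remove. Database entries lacking a
frequency are, under a positive cutoff, conservatively *not* used for
filtering (`--treat-missing-af-as-common` inverts this). Matching requires
the full allele identity; `--match-position-only` relaxes it to
(chromosome, position). Database zygosity is ignored throughout.

## Synthetic cohorts

The generator produces the statistical structure the filters assume, not
realistic population genetics: no linkage disequilibrium, no relatedness
beyond the trio, no allele-frequency spectrum, no sequencing error. What
passing tests on these fixtures demonstrate is that the *filtering logic*
is correct under its stated assumptions — not that those assumptions hold
in any particular real dataset.

Design and defaults:

- Units are non-overlapping 1 kb intervals (20 by default) spread over
  three chromosomes; background variant positions are drawn uniformly
  without replacement across units, so no accidental multi-allelic
  collisions occur unless requested via the multi-allelic VCF dialect.
- The causal variant (or compound-het pair) is planted in one randomly
  chosen unit and carried by exactly `n_cases − n_d` cases and exactly
  `c_g` controls, with the model's zygosity (HET for dominant and
  compound-het, HOM for recessive). It is never placed in the database.
  Background variants never land inside the causal unit, so the truth
  record's carrier counts — and therefore recovery and
  tightened-threshold rejection — hold by construction rather than with
  high probability.
- Background carriage: each sample carries each background site with
  probability 0.3, heterozygous with probability 0.7 and
  homozygous-alternate otherwise. These defaults exercise both zygosity
  paths of every filter; all are configurable.
- Database sharing: each background variant enters the database VCF with
  probability 0.7 (`background_sharing`), with a uniform allele frequency
  in (0.01, 0.99) so MAF-cutoff behaviour can be exercised.
- Trio mode: the child carries the planted variant heterozygously plus
  all background sites; each background site is inherited (present in at
  least one parent; both when the child is homozygous) with probability
  `parental_sharing = 0.99`, reflecting that genuine de novo variants are
  a tiny fraction of a child's callset. Database membership and
  inheritance are drawn independently.

Identical configuration and seed give byte-identical fixture files.

## Numerical and I/O choices

- Reports are TSV with rows in natural chromosome order (`chr1 < chr2 <
  chr10`, lexicographic fallback for non-numeric names), position, ref,
  alt and unit as tie-breaks — a total order, so identical results are
  byte-identical files.
- The VCF FILTER and QUAL columns are ignored by default (permissive is
  the faithful default for a filtering tool fed pre-processed calls);
  `pass_only` and `min_qual` opt in to honouring them.
- Duplicate records for one sample at the same (chrom, pos, ref, alt):
  the last record wins.
- BED is read as 0-based half-open and converted to the 1-based inclusive
  internal convention; GTF coordinates are used as-is. Exon-level GTF
  units grouped by a gene attribute flatten into a per-gene exon union;
  transcript-aware exon structures are not modelled.
- Annotation sources (e.g. Ensembl vs RefSeq) are kept separate — one
  variant may be counted in one unit per source — with a merge report
  listing variants hit by multiple sources, since such hits often denote
  the same underlying gene.
- Unit lookup uses an interval tree (point query O(log n + hits));
  correctness is defined solely by agreement with an all-pairs
  point-in-interval oracle, which the test suite checks on random
  fixtures.

## Verification problem sizes

The test suite and `scripts/acceptance.py` verify the implementation
against independent nested-loop oracles on 500 randomized cohorts (up to
10 samples × 1,000 variants × 50 units, most smaller), sweep the full
penetrance/detectance grids up to 15 cases × 10 controls plus 10,000
random off-grid requests, run 50 simulated cohorts per inheritance-model ×
phenocopy × non-penetrant-carrier condition (650 recovery runs, 900
tightened-rejection runs), and measure the trio funnel on 20 trios of
10,000 background variants each. These sizes give exact (not sampled)
agreement checks at each fixture while keeping a full run around half a
minute on one core.

## Known limitations

- No X-linked, mitochondrial or imprinting-aware modes.
- No genotype-quality, depth or likelihood-aware filtering, and no
  statistical association testing — this is deterministic set algebra.
- Long indels/structural variants are anchored at POS only.
- Functional consequence prediction is out of scope; a consequence track
  can be applied only as a user-supplied custom annotation (keep-by-tag).
- Penetrance/detectance are sharp thresholds, not probabilistic models;
  very low settings filter little and the approach loses power for
  complex traits.
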