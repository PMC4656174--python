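# vcfsieve

Species-independent heuristic variant filtering for Mendelian trait studies.

Sequencing a handful of affected (case) and unaffected (control)
individuals yields tens of thousands of called variants per sample;
identifying the one (or few) causal variants is usually done by applying
heuristic filters sequentially. `vcfsieve` implements that funnel for any
diploid species, directly from standard VCF input:

- **database filtering** — remove variants already present in a dbSNP-like
  VCF, optionally only those at or above a minor-allele-frequency cutoff;
- **unit annotation** — assign variants to genes, exons or custom intervals
  from BED/GTF, and narrow candidate sets stepwise (genome → genes →
  exons → any custom track such as consequence tags);
- **four inheritance filters** — dominant and recessive models, each at
  the single-nucleotide level or at a user-chosen unit level (the unit
  level admits allelic heterogeneity, including compound heterozygosity);
- **reduced penetrance and detectance** — principled relaxation of the
  "all cases share it, no control carries it" assumption;
- **trio (family) mode** — de novo filtering of an affected child against
  its parents;
- **a synthetic cohort generator** — fully self-contained fixtures with a
  planted causal variant under any of the supported models, for testing
  and power exploration.

## The model

For `n_s` cases and `c` controls, let `n_c` be the cases sharing a common
genetic cause, `n_d = n_s − n_c` the phenocopies or cases with a different
cause, `c_g` the non-penetrant carrier controls and `c_c = c − c_g`:

```
penetrance = n_c / (n_c + c_g)        detectance = n_c / (n_c + n_d)
```

Only `n_s` and `c` are known a priori, so the feasible levels are
enumerated over `0 ≤ n_d < n_s` and `0 ≤ c_g ≤ c` and offered to the user.
A chosen (penetrance, detectance) pair is a lower limit; it rearranges to
integer retention thresholds

```
n_c = ceil(detectance · n_s)          c_g = floor(n_c / penetrance − n_c)
```

and a candidate is retained when it is present in **at least `n_c` cases**
and matched by **at most `c_g` controls**, where "present" and "matched"
depend on the filter:

| filter | a case supports when | a control filters when |
|---|---|---|
| dominant, nucleotide | carries the variant (any zygosity) | carries it (any zygosity) |
| recessive, nucleotide | homozygous for the variant | homozygous for it |
| dominant, unit | has ≥ 1 variant in the unit | carries the case variant |
| recessive, unit | has a homozygous variant or is compound heterozygous (≥ 2 distinct HETs) in the unit | is homozygous for the case variant, or is compound heterozygous in the unit and carries it |

At unit level, sharing is counted over *units* (different nucleotides in
different cases may implicate the same gene), while the `c_g` allowance is
counted per variant across controls. The trio filter retains variants that
are heterozygous in the child and absent from both parents.

## Worked example: a trio with a planted de novo variant

```
$ vcfsieve simulate --model denovo_trio --background 5000 --seed 42 --outdir demo
INFO simulated 3 sample(s), 5000 background variant(s), truth ['chr2:1774T>C'] in unit001

$ vcfsieve dbfilter --vcf demo/child.vcf --vcf demo/mother.vcf \
    --vcf demo/father.vcf --db demo/database.vcf --outdir demo/dbfiltered
INFO database: 3472 variant(s) from demo/database.vcf
INFO demo/child.vcf: 5001 -> 1529 observation(s) (69.4% removed)
INFO demo/mother.vcf: 3216 -> 992 observation(s) (69.2% removed)
INFO demo/father.vcf: 3283 -> 1000 observation(s) (69.5% removed)

$ vcfsieve family --child demo/dbfiltered/child.vcf \
    --mother demo/dbfiltered/mother.vcf --father demo/dbfiltered/father.vcf \
    --out demo/candidates.tsv
INFO child: 1529 -> 9 variant(s) (99.41% excluded); report: demo/candidates.tsv
```

Database filtering removed 69.4% of the child's 5001 variants (the
generator placed ~70% of background variation in the database); the family
filter then kept only variants heterozygous in the child and absent from
both parents, excluding 99.41% overall. The report lists, per retained
variant, the chromosome, position, alleles and the number of cases and
controls matching it:

```
chrom   pos     ref     alt     case_count      control_count
chr1    11112   G       T       1       0
...
chr2    1774    T       C       1       0      <- the planted variant
...
```

Nine candidates remain and the planted de novo variant (`chr2:1774 T>C`,
recorded in `demo/truth.json`) is among them. Every subcommand also writes
a machine-readable JSON run summary with before/after counts.

To see the feasible penetrance/detectance levels for a cohort:

```
$ vcfsieve levels --cases 3 --controls 2
detectance options for 3 case(s):
  n_d   n_c   detectance
  0     3     1.0000
  1     2     0.6667
  2     1     0.3333
penetrance options for n_c=3 sharing case(s), 2 control(s):
  c_g   penetrance
  0     1.0000
  1     0.7500
  2     0.6000
```

Case/control filtering works the same way through `vcfsieve dominant` and
`vcfsieve recessive` (`--level unit --bed genes.bed` for gene-level
compound-het analysis; `--penetrance/--detectance` or the explicit
`--min-cases/--max-controls` overrides).

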