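# paralogdeconv

Marker-based deconvolution of multi-copy gene expression from RNA-seq.

## The problem

Some genes exist as families of near-identical paralogs — the rat Y
chromosome, for example, carries at least eleven copies of the
sex-determining gene *Sry* that differ by only a handful of single-nucleotide
variants. Standard quantifiers cannot apportion reads among such copies, so
the usual approach is to map all of the family's reads against **one**
reference copy and let the copy-specific variants show up as mismatches in
the pileup. `paralogdeconv` implements that workflow end to end:

1. **Pileup** — tally aligned A/C/G/T bases at every position of the
   reference transcript from a SAM/BAM of family-mapped reads.
2. **Markers** — a user-supplied table of diagnostic positions mapping each
   base to the set of paralogs that carry it. The distinct paralog sets
   appearing as allele images form *attribution classes*: single copies
   where a base is unique to one paralog, or shared groups (an
   "other Sry3s"-style class) where reads cannot separate the members.
3. **Composition** — at each usable marker the allele fraction
   `f = count(allele) / depth` estimates its class's share of expression;
   per class, shares are the arithmetic mean of its marker allele fractions,
   renormalized to sum to 100%. Markers at sites with depth below a
   threshold (default 150) are excluded; a class left with no usable marker
   is reported *missing*, never silently zero.
4. **TPM partition** — the per-class percents split the total-gene TPM
   (from an external quantifier such as Salmon) into per-copy abundances:
   `TPM_c = percent_c / 100 × TPM_total`.

A non-negative least-squares fit over the same marker design matrix is
included as an independent cross-check of the averaging estimator, and a
synthetic-data module generates paralog families, truth-aligned reads with
known mixture proportions and substitution errors, and complete truth
ledgers, so the whole pipeline is testable without any download.

## Worked example

Simulate the standard fixture battery and deconvolve the 60/30/10 mixture
(three synthetic copies, ~500× depth, error-free reads, total TPM 20):

```sh
$ paralogdeconv simulate --preset fixtures --out fx --seed 1
$ paralogdeconv sample --alignments fx/mix_60_30_10/reads.truth.sam \
      --markers fx/mix_60_30_10/markers.tsv --total-tpm 20 --sample-id E13_demo
copy1   60.05   12.009
copy2   28.79   5.759
copy3   11.16   2.232
```

Columns are class, percent of family expression, and TPM. The true mixture
is 60/30/10 over a total TPM of 20 (i.e. 12/6/2); the small deviations are
the binomial sampling noise of ~500× marker depth. Batch runs take a YAML
manifest (`paralogdeconv run --config cfg.yaml --out out/`) and write
per-sample composition and partition TSVs plus a replicate-aggregated
timecourse table with means and n−1 standard deviations.

The marker table is plain TSV, one row per (position, base):

```
##reference=copy1
##length=600
##paralogs=copy1,copy2,copy3
position  in_coding  base  paralogs
30        0          A     copy1
30        0          C     copy2
...
```

For real data, transcribe the family's published diagnostic variants into
this format, align the family's reads against the reference copy, and pass
the per-sample total-gene TPM from your quantifier.

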