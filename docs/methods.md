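# Methods

## Model

A family of paralogous gene copies is quantified against a single reference
transcript (copy #1 of the family). Reads from every copy map to this one
reference; a copy-specific variant then appears as a non-reference base in
the pileup at its marker position. Let `d_i` be the depth at position `i`
and `n_i(b)` the count of aligned base `b` there. For a marker allele `b`
diagnostic of a set of copies `C`, the allele fraction

    f_i(b) = n_i(b) / d_i

is an unbiased estimate of the summed expression share of the copies in
`C`, under the assumptions that (a) reads are drawn from copies in
proportion to their transcript abundance, (b) alignment to the reference is
unaffected by which copy a read came from, and (c) sequencing errors are
rare and unbiased among bases.

**Attribution classes.** The distinct copy sets appearing as allele images
across all marker sites are the units the data can resolve: singleton
classes (one copy owns the base) and group classes (several copies share
it). Group classes are labeled `other <prefix>s` from the members' longest
common name prefix, so a family whose indistinguishable members are named
`Sry3`, `Sry3A`, `Sry3B` yields the label "other Sry3s". Every
(position, base) pair belongs to exactly one class; this partition is an
enforced invariant.

**Composition estimator.** For class `c` with usable diagnostic pairs
`M_c`, the raw mean is `m_c = mean_{(i,b) in M_c} f_i(b)`; reported
percents renormalize the raw means to 100 over classes with at least one
usable marker. When classes overlap (a group alongside a singleton member,
as in panels that mix family-level and member-level markers) the raw means
need not sum to 1; both the raw means and the renormalized percents are
retained in the output, and the overlap is reported rather than resolved —
there is no principled way to subtract member-specific signal from a
shared-allele marker without extra assumptions.

**Depth filter.** A marker site is usable iff its total site depth is at
least `min_depth` (default 150, kept at equality). The threshold is
site-level, not per-allele. Classes with no usable marker are *missing*
(`None`), distinct from an estimated 0% — important for very low-coverage
samples where a silent zero would be misleading.

**TPM partition.** Per-class TPM is `percent/100 × total TPM`, where total
TPM comes from an external whole-transcriptome quantifier. A naive
TPM-from-counts helper (`counts/effective length`, normalized to 1e6) is
provided only so synthetic end-to-end tests need no quantifier.

**NNLS cross-check.** `nnls_oracle` solves `min ||Ax − f||², x ≥ 0` with
one row per usable (position, base) pair and a one-hot class indicator
design, renormalized to 100. Because the class assignment partitions the
pairs, the least-squares solution equals the per-class mean whenever means
are non-negative; the value of the oracle is that it reaches the same
number through an entirely different numerical route (scipy's active-set
NNLS), so any disagreement beyond 1e-6 flags an implementation defect.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 150 reads | site depth below which a marker is excluded |
| `variable_positions` thresholds | 1 / 1 | depth and minor-count defining a "variable" site; no default claims to reproduce any particular published count, which depends on an unstated minor-allele criterion |
| base/mapping quality filters | off | raw extraction by default; thresholds available |
| deduplication | none | not part of the modeled extraction |
| reporting precision | 0.01 pp / 0.001 TPM | table rounding only; internal values are full precision |

Coordinates are 1-based and inclusive on the reference transcript
throughout; 0-based conversion happens only at the pysam boundary.

## Synthetic data: what it emulates and what it does not

The generator produces a reference transcript (configurable length and GC
content; defaults 600 bp, GC 0.5), `n` copies differing from the reference
only by substitutions at marker sites, and reads drawn from a configurable
mixture at uniform start positions with independent per-base substitution
errors (uniform over the three alternatives, default read length 50,
matching short paired-end RNA-seq reads; base qualities constant Q30).
Reads are *truth-aligned*: placed at their true start against the reference
with gapless CIGARs, so a copy-specific variant appears in the pileup as a
mismatch — exactly the estimator's input signal — without an aligner in the
loop. FASTQ is emitted for users who want to run a real aligner.

Marker design follows a feasibility rule: every site assigns a distinct
base to each *distinguishable unit* (each individually resolvable copy,
plus a shared group as one block), so the allele images at every site
partition the family into the same attribution classes and the averaging
estimator is consistent. At most four units can be separated per site
(four nucleotides); requesting more is an error. A `shared_group`
configuration reserves shared-only sites where the group is one block;
remaining sites separate the members, reproducing the group-vs-member
overlap of real panels.

Not emulated: alignment artifacts (mismapping, clipping near variants),
fragment-length distributions, PCR duplicates, strand bias,
quality-dependent errors, indels, splicing, and positional coverage bias
other than the deterministic ramp at transcript ends. Passing tests
therefore demonstrate correctness of the extraction and estimation
arithmetic under an idealized read model, not robustness to aligner
behavior on real libraries.

Fixture battery defaults (the study conditions the tests run under):
mixtures at 100/0, 60/30/10 and a 30/30/(20+10+10) shared-group setting;
marker depths ~500–1000×, matching the coverage regime where per-marker
binomial noise is a fraction of a percentage point; error rate 0 in
fixtures (exactness checks) and 0.005 in Monte-Carlo recovery runs
(typical Illumina substitution scale); 8 marker sites per family. The
recovery study uses 50 seeds; depth-scaling uses 100×/1000×/10000×. These
sizes make per-class recovery error measurably sub-1.5 pp while keeping
the whole suite under a minute of simulation time.

## Numerical choices and degenerate inputs

- Fractions at depth-0 positions are defined as 0 and flagged by the depth
  vector; 'N' bases are excluded from counts *and* depth so fractions over
  A/C/G/T sum to 1.
- Renormalization requires a positive sum of raw means; an all-zero signal
  (no marker allele observed at any usable site) raises an estimation
  error rather than returning an undefined composition.
- Zero usable markers raises `"no markers above depth threshold"`; a
  zero-read simulation yields valid empty outputs.
- Group labels that would collide (two groups sharing a name prefix) fall
  back to an explicit `group:<members>` label; class output order is
  sorted by label for determinism.
- Replicate aggregation uses the n−1 standard deviation, reported only for
  n ≥ 2; missing classes are excluded from that class's n rather than
  imputed as zero.
- Pooled mode merges pileups before estimation (weighting replicates by
  read count); per-sample mode estimates then averages. The two disagree
  on unbalanced replicates — both are provided because either convention
  is defensible for multi-pool designs, and the run report records which
  was used.

## Known limitations

- Hierarchically overlapping marker panels (group + member markers) are
  reported with their overlap, not reconciled; renormalized percents then
  include double-counted signal and should be read alongside the raw means.
- The depth filter uses total site depth; a site dominated by one allele
  can pass the filter while individual alleles have few supporting reads.
- Reads from a copy diverged enough to fail alignment against the
  reference would be invisible to the pileup; the simulator does not model
  this loss.
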