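# Methods

## Barcode extraction

Each amplicon read is inspected at fixed positions defined by a
`ReadLayout`: BC14 at `bc14_offset` (14 nt), an optional constant spacer,
and BC30 at `bc30_offset` (30 nt). The default layout is
`BC14 | TGGT | BC30` in a single 48-nt read. **This layout is an
assumption**: vendor amplicon designs place the two barcode halves at
kit-specific positions (and some kits read them in two separate reads),
so every field — offsets, spacer, minimum read length — is configurable,
and the defaults exist so that the simulator and extractor agree on a
concrete, documented geometry.

Matching is exact-only: a read counts for a clone iff the sliced BC14 and
BC30 are members of the whitelist sets (after uppercasing; `N` never
matches), the spacer matches exactly when configured, and the pair is
listed when an explicit pair whitelist is supplied. There is deliberately
no Hamming-distance rescue even though vendors sometimes allow it; with a
per-base error rate *e* the expected matched fraction is
`(1-e)^(44+|spacer|)`, which the test suite verifies against the simulator
(Monte-Carlo, 3-binomial-SD band).

Classification is exhaustive and mutually exclusive with precedence
`too_short` → `spacer_mismatch` → barcode membership
(`both_match`/`bc14_match_only`/`bc30_match_only`/`no_match`) →
`pair_invalid`; the QC bucket counts always sum to the total reads, which
is asserted as a property test. Clone identity defaults to the
concatenated BC14⊕BC30 pair (the two halves jointly identify a clone); a
`bc30_only` mode exists for kits where BC30 alone is clonal.

A clone is "unique" with ≥ 1 matched read by default; a `min_reads`
threshold is available everywhere but defaults to 1, since no threshold is
part of the stated counting procedure.

## Diversity statistics

With retained counts `c_i`, `p_i = c_i / Σc_j`:

- Shannon index `H = −Σ p_i log p_i` (natural log by default; the CLI
  offers log2),
- Shannon maximum `H_max = log S` with `S` the *observed* richness,
- evenness `J = H / H_max` (Pielou's J).

Interpreting the "Shannon maximum" as `log S` rather than
`log(whitelist size)` is a design choice: it is the standard evenness
denominator, and a whitelist-size denominator would make evenness values
incomparable between samples with different recovered richness. Because J
is a ratio of two logarithms in the same base, it is invariant to the base
— so published evenness values cannot distinguish the log-base convention,
and the base matters only for reported H. A `max_mode="whitelist"`
override is provided. Conventions for degenerate inputs: `S = 1 ⇒ H = 0,
J = 0` (avoids 0/0); a sample left empty after thresholding yields
all-zero statistics with a logged warning instead of an exception, so a
batch run survives a failed sample.

Implementation is a vectorized direct summation; tests pin it to an
independent per-term oracle at 1e−12 and cross-check against
scikit-bio's `shannon`/`pielou_e` on random tables.

## Retention analysis

Founder-vs-stage comparison operates on thresholded clone-key sets:
`retained_fraction = |F∩S| / |F|`, `richness_ratio = |S| / |F|`,
`jaccard = |F∩S| / |F∪S|`, plus `novel_in_stage = |S∖F|` and the evenness
change. Retained fraction and richness ratio are both reported because
they answer different questions (how many founders survived vs how
diverse the stage is relative to the founder) and coincide only when the
stage contains no novel barcodes. Novel-in-stage clones are never silently
dropped: the founder aliquot is itself an incomplete sample of the pool.

Group comparisons use the unpaired two-sided t-test (Welch by default,
pooled-variance optional) via `scipy.stats.ttest_ind`, with significance
stars at p < 0.05/0.01/0.001/0.0001. Two zero-variance groups with equal
means return t = 0, p = 1 by convention; with different means,
p = 0 and `±inf` (the permutation-test limit).

## The simulator

The generator emulates the stated experiment:

1. **Library** — `n_bc14 = 500` and `n_bc30 = 20,000` random distinct
   sequences (10 million possible pairs, the order of magnitude of a
   commercial barcoding library). Rejection sampling guarantees
   distinctness; requesting more than `4^L` sequences is an error.
2. **Transduction** — each of `n_founder_cells = 1,500,000` cells (one
   experimental group) is barcoded with probability
   `transduction_rate = 0.12`, the verified rate. `bernoulli_single`
   assigns one uniform random pair per barcoded cell; `poisson` draws
   integrations per cell from a zero-truncated Poisson with λ solved from
   `P(≥1) = rate`, keeps the first pair as clone identity, and tallies
   multi-integration cells. Unbarcoded cells are excluded — the model of
   puromycin selection. Rate 0 is allowed as a degenerate case (empty
   founder).
3. **Expansion and bottlenecks** — each stage grows clones by
   `2^doublings`, either exactly or with clone-specific Poisson noise
   (`growth_model="stochastic"`, mean `cells·2^d`; clones can go
   extinct), then draws the harvested cells without replacement
   (multivariate hypergeometric). One knob models sampling, death and
   non-differentiation jointly, since the experiment cannot separate
   them. The sequenced aliquot *is* the population carried forward — a
   simplification of passaging. Stage-plan templates mirror the two
   protocols' harvest numbers: `st` (HPC-first): 1.5 M of 3 M HPCs, 1.4 M
   precursors, 1 M final macrophages; `imac`: 1.5 M precursors, then 2 M
   of 4 M mature macrophages. `scale` (default 0.01 for pipeline runs)
   multiplies all cell numbers for desk-scale work; the whitelist is a
   library property and is not scaled.
4. **Sequencing** — per clone, reads ~ Poisson(`reads_per_cell = 10` ×
   cells); each read is the layout template with the clone's barcodes and
   i.i.d. per-base substitutions at `per_base_error = 0.001`
   (Illumina-typical). Read depth and error defaults are not stated in
   the source experiment and were chosen once as field-typical values.
   Quality strings are constant (`I`) because the counting procedure
   never uses qualities.

All randomness flows from one `numpy` `SeedSequence` with one child
stream per pipeline stage, so any stage is individually reproducible and
identical configs give byte-identical FASTQs, count tables and reports
(manifest timestamps excepted — they live only in `manifest.json`).

What a green desk-scale test establishes: the pipeline recovers planted
richness, survival fractions and evenness trends through the full
simulate → sequence → extract → analyze loop. What it does not: PCR
amplification bias, chimeric reads, index hopping, real error profiles
(indels, quality-correlated errors), or clone-level growth-rate
heterogeneity beyond Poisson noise — the simulator's bottlenecks are
neutral drift, with no selection on clone identity.

## Numerical and interface choices

- Count tables are TSV (`clone_id`, `bc14`, `bc30`, `read_count`), rows
  sorted by clone key, QC embedded as `#` header lines with a JSON
  payload; round-trip identity is tested. Bare TSVs with just
  `clone_id`/`read_count` (e.g. deposited count tables) load with
  zero-filled QC, so the pipeline can enter at either the FASTQ or the
  count-table stage.
- Rank-abundance ties are broken by clone-key lexicographic order for
  deterministic output.
- CLI exit codes: 0 success, 2 configuration error, 1 runtime failure;
  a failing pipeline names its stage and keeps partial outputs.

## Known limitations

- The default read layout is an assumption, not a vendor specification
  (see above); real data requires setting the layout flags to the actual
  amplicon design, including the case where BC14 and BC30 come from
  separate reads (run extraction per read with `bc30_only`/custom layouts
  and combine upstream).
- Barcode collisions (two founder cells drawing the same pair) are
  possible and uncorrected, exactly as in the real experiment; at default
  library size and desk scale they are negligible.
- No UMI handling, demultiplexing, paired-end merging, or
  error-correcting barcode assignment — perfect matching is the method.
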