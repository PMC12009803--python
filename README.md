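# clonetrace

Clonal barcode lineage tracing for hiPSC differentiation experiments:
quantify how much of a barcoded founder population survives the bottlenecks
of a differentiation protocol.

## The problem

To measure founder-population diversity during hiPSC→macrophage
differentiation, each founder cell is tagged with a heritable lentiviral
barcode (a 14-nt **BC14** plus a 30-nt **BC30**; the pair identifies a
clone). Amplicon sequencing of the barcode locus at each differentiation
stage then reveals which clones are still present and how skewed their
sizes have become. Differentiation protocols select and sample cells, so
clone diversity collapses — a *bottleneck* — which matters directly for
CRISPR screens performed in differentiated cells: a library transduced into
hiPSCs retains only a fraction of its diversity by the mature-macrophage
stage.

`clonetrace` implements the complete analysis:

- **Extraction** — reads are scanned at fixed, configurable positions for
  BC14 and BC30; only *perfect* matches against the expected whitelist
  count (no mismatch tolerance, no indel rescue, qualities ignored). Every
  read is classified into exactly one QC bucket, so the filter is auditable.
- **Diversity** — per sample with clone read-count proportions
  $p_i = c_i/N$: richness $S$, Shannon index $H=-\sum_i p_i\ln p_i$,
  Shannon maximum $H_{max}=\ln S$, and Pielou evenness $J=H/\ln S$
  ($J=1$: all clones equal; $J\to 0$: a few clones dominate).
- **Retention** — founder-vs-stage clone set comparison: retained fraction,
  richness ratio, Jaccard index, novel-in-stage clones, evenness change,
  plus an unpaired (Welch) t-test helper for group comparisons.
- **Simulation** — a generative model of the whole experiment
  (12% transduction of a 1.5-million-cell founder group, clonal expansion,
  stage-wise hypergeometric sampling along either differentiation protocol,
  Poisson read depth, per-base sequencing error) with planted ground truth,
  so the pipeline is testable end to end with no downloads.

## Worked example

Simulate the HPC-first protocol at 1% of the experimental cell numbers,
extract, and analyze, all in one reproducible run:

```sh
cat > demo.yaml <<EOF
seed: 7
scale: 0.01
protocol: st
growth_model: stochastic
EOF
clonetrace run --config demo.yaml --out demo
```

`demo/diversity.tsv`:

```text
label	richness_S	total_reads_N	shannon_H	shannon_max	evenness_J
hiPSC	1848	143364	7.450611	7.521859	0.990528
iHPC	1836	142295	7.382349	7.515345	0.982304
iMacPre	1807	133527	7.318102	7.499423	0.975822
iMacST	1713	94941	7.227542	7.446001	0.970661
```

`demo/retention.tsv`:

```text
stage	founder_richness	stage_richness	shared_clones	retained_fraction	novel_in_stage	jaccard	richness_ratio	evenness_delta
iHPC	1848	1836	1836	0.993506	0	0.993506	0.993506	-0.008224
iMacPre	1848	1807	1807	0.977814	0	0.977814	0.977814	-0.014706
iMacST	1848	1713	1713	0.926948	0	0.926948	0.926948	-0.019867
```

Reading this: the simulated founder aliquot contains 1,848 clones at
near-perfect evenness (J = 0.991). Each differentiation stage loses clones
(richness ratio falls to 0.927 by the final macrophage stage) and skews the
survivors' sizes (evenness drops at every stage) — the qualitative
signature of the real experiment, at desk scale. Against real data the same
numbers come from `clonetrace extract` + `clonetrace diversity` +
`clonetrace report` on your FASTQs and whitelist files; a count table looks
like:

```text
# sample_id=iMacST
# clone_key_mode=pair
# qc={"bc14_match_only": 2947, ..., "both_match": 94941, "total_reads": 99733}
clone_id	bc14	bc30	read_count
AAAAAAAGGCGTCCATGTTGGTTGAGGAGCTAATCTATTAGTAA	AAAAAAAGGCGTCC	ATGTTGGTTGAGGAGCTAATCTATTAGTAA	129
...
```

## CLI

| command | purpose |
|---|---|
| `clonetrace extract` | FASTQ(.gz) → perfect-match clone count table + QC JSON |
| `clonetrace diversity` | count table(s) → Shannon Index/Maximum/Evenness JSON/TSV |
| `clonetrace compare` | founder vs stage retention statistics |
| `clonetrace report` | multi-stage bottleneck report (JSON, TSV, optional plots) |
| `clonetrace simulate` | synthetic experiment → FASTQs, whitelists, ground truth |
| `clonetrace run` | simulate → extract → diversity → compare, one seeded run |

Exit codes: 0 success, 2 configuration error, 1 runtime failure. Every
command is a thin wrapper over the `clonetrace` Python API
(`extract_clone_counts`, `shannon_stats`, `retention`, `run_all`, …).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch: it simulates both
differentiation protocols at scale 0.01 under the given seed, runs
extraction, diversity and retention over the generated data, and writes the
results JSON. See `docs/methods.md` for the model, parameter defaults, and
known limitations.
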