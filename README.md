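# mirhost

Intronic microRNA target prediction from host-gene expression.

Roughly half of human miRNAs sit in the introns of protein-coding genes and
many are co-transcribed with their host, so the host mRNA's expression
profile can serve as a *surrogate* for the miRNA's (hard-to-measure)
expression. `mirhost` exploits this: given many independent gene-expression
studies, a table of miRNA → host-gene associations and a sequence-based
candidate list of miRNA → target predictions, it decides which candidate
interactions are functional (the target really is repressed when the
miRNA/host is up) and which host genes are trustworthy surrogates in the
first place. It is aimed at computational biologists who have bulk
expression compendia but no paired miRNA profiling.

## Model

For target gene *i* in dataset *k* with *S* samples, let

* **d**ᵢᵏ ∈ ℝˢ — the *down-regulation vector*: per-sample mean expression
  over all (filtered) genes minus the target's expression, on the linear
  intensity scale (repression is additive, so profiles are *not*
  log-transformed);
* **X**ᵏ ∈ ℝ^(S×Mᵢ) — one column per distinct host gene whose intronic
  miRNAs putatively target *i*, each column scaled to unit Euclidean norm.

The model is **d**ᵢᵏ = **X**ᵏ **w**ᵢᵏ + ε, ε ~ N(0, σ²I), so the OLS
solution ŵ = argmin‖**d** − **X w**‖₂ is the maximum-likelihood weight
vector (**ULM**, the unconstrained linear model). A positive weight means
the host's miRNA represses the target. Two companions are provided: **CLM**
(non-negative least squares, weights forced to pure repression) and **CORR**
(per-host Pearson correlation with **d**, a HOCTAR-style baseline).

Weights are L1-rescaled (w̃ = w / Σ|w|) and pooled across datasets. A null
distribution is built by permuting the assignment of host labels to host
expression profiles and refitting everything; each (host, target) pair is
then scored with two-sided Wilcoxon–Mann–Whitney rank-sum P-values of its
real (Pᵢⱼ) and permuted (Qᵢⱼ, a matched negative control) weight samples
against the pooled permutation null. Significant pairs (P ≤ 0.01 by default,
or a ROC-chosen cutoff using the Q values as negatives) whose mean weight
exceeds the null mean are *negative* (repressive) interactions. A host whose
significant interactions are mostly negative is called a **good surrogate**
for its intronic miRNAs; mostly non-negative, a **bad surrogate**
(its mRNA does not track the miRNA's activity — independent intronic
promoter, or the host is itself degraded by co-expressed miRNAs); no
significant interaction, **uninformative**.

## Worked example

Simulate a 50-dataset compendium with six hosts — four tightly coupled to
their intronic miRNA, one whose miRNA has an independent promoter, one whose
mRNA is degraded by a co-expressed miRNA — each miRNA repressing three
target genes (w\* = 1), then run the pipeline:

```sh
cat > sim.json <<'EOF'
{"n_datasets": 50, "n_samples": 30, "n_hosts": 6, "n_targets": 18,
 "regulators_per_target": 1, "n_decoys": 2, "w_range": [1.0, 1.0],
 "host_scenarios": ["coupled", "coupled", "coupled", "coupled",
                    "independent_promoter", "mirna_targeted_host"]}
EOF
mirhost simulate --config sim.json --seed 11 --out-dir demo
mirhost run-all --expression-dir demo/expression --host-map demo/host_map.tsv \
        --target-map demo/target_map.tsv --method ULM --seed 11 --out-dir out
```

which prints

```
wrote 50 dataset(s), 18 planted edge(s) to demo
ULM: 12 significant negative interaction(s) at cutoff 0.01, 4 good-surrogate host(s)
```

and writes `out/surrogacy_ulm.tsv`:

```
host    n_putative  n_significant  n_negative  mean_neglog_p  pct_negative  call
HOST01  9           3              3           11.3676        100           good_surrogate
HOST02  9           4              3           7.47541        75            good_surrogate
HOST03  10          4              3           8.39418        75            good_surrogate
HOST04  10          5              3           7.61232        60            good_surrogate
HOST05  7           0              0                                        uninformative
HOST06  9           6              0           7.3093         0             bad_surrogate
```

The four coupled hosts are recovered as good surrogates (their three planted
targets each appear among the significant negative interactions, e.g.
HOST01→TGT001 at P = 5.0 × 10⁻⁹ in `out/network_ulm.tsv`, fanned out per
miRNA). The independent-promoter host shows nothing significant —
its expression carries no information about its miRNA. The miRNA-targeted
host is confidently *bad*: its interactions are significant but
non-negative, because degradation by a co-expressed miRNA anti-correlates
its mRNA with the miRNA's activity. `out/scores_ulm.tsv` holds every pair's
Pᵢⱼ/Qᵢⱼ, mean weight, null mean and sign; `out/summary.json` records the
cutoff, pool size and counts.

The stages can also be run separately (`mirhost fit`, `mirhost score`,
`mirhost classify`), each consuming the previous stage's TSV.

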