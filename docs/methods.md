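# Methods

## Model and assumptions

The response for target gene *i* in dataset *k* is the down-regulation
vector d[s] = (mean over all genes of expression at sample s) − (expression
of *i* at s), computed on the **linear** intensity scale over the dataset's
filtered gene universe. Modeling repression as additive in expression units
is a deliberate assumption: the decrease in target mRNA is taken
proportional to miRNA abundance, so input matrices must not be
log-transformed (the readers perform no transform and cannot detect
pre-logged data).

Candidate regulators come from sequence-based miRNA → target predictions;
each miRNA is resolved to its host gene(s), and weights are assigned to
*hosts*, not miRNAs: a miRNA duplicated in several hosts contributes one
design column per host (each host may be a different-quality surrogate),
and several miRNAs sharing a host collapse to one column whose score is
later fanned back out to each miRNA. Host columns are ordered
lexicographically so weight vectors align across datasets.

With unit-norm host profiles and spherical Gaussian noise, the OLS solution
of d = Xw + ε is the maximum-likelihood estimate. No intercept is fitted —
d is already referenced to the per-sample universe mean; adding one would
change the model class. Per (target, dataset) fits are L1-rescaled
(w̃ = w/Σ|w|) to make weights commensurable across datasets of different
scale and quality.

Inference is nonparametric: host labels are permuted over the dataset's
host-profile pool (uniformly over non-identity permutations; the profile
multiset is preserved) and all designs refitted; every rescaled permuted
coefficient enters one pooled empirical null per method. P(pair) is the
two-sided WMW rank-sum p-value of the pair's cross-dataset real weights
against the pool, Q(pair) the same for the pair's permuted weights — a
matched negative control used both for ROC cutoff selection and as a
calibration check. The repression sign is the comparison of the pair's mean
rescaled weight with the pool mean. Surrogacy: a host with a strict
majority of negative significant interactions is a good surrogate; ties are
called bad (a good-surrogate call licenses downstream target claims, so the
tie-break is conservative); hosts with no significant interaction are
reported separately as uninformative rather than folded into either class.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| filter percentile | 0.10 | genes whose max absolute intensity falls strictly below this percentile of the per-gene-max distribution are dropped (low-value filter convention: linear interpolation between order statistics, ties kept) |
| cutoff | fixed 0.01 | default significance threshold on P; kept fixed for comparability. ROC mode instead picks the least stringent −log₁₀P threshold whose FPR on the Q controls meets a target specificity (default 1.0) |
| n_perms | 1 | permuted refits per dataset; one suffices for a usable pool at compendium scale, more smooths it |
| permute_scope | universe | host labels permuted across all design hosts present in the dataset; `design` restricts permutation to each design's own columns |

Numerical choices: singular X'X (collinear hosts, S < M) falls back to the
minimum-norm pseudo-inverse solution with a logged flag; all-zero weight
vectors are *degenerate* and excluded from both real samples and the pool
(recording them would spike the null at zero); WMW uses exact enumeration
when min(n, m) ≤ 8 with tie-free data, otherwise the normal approximation
with midranks and tie-corrected variance and no continuity correction (so
identical samples give p = 1); p-values are floored at 1e-300 so −log₁₀P
stays finite; the pair's own permuted weights are not removed from the pool
when computing Q — at compendium scale their self-contribution is
negligible. One seeded generator drives all randomness; permutation draws
are shared across methods so ULM/CLM/CORR comparisons are paired.

## Synthetic compendia

The generator emulates the study setting: many independent datasets, a few
host genes, targets repressed additively by the miRNA activities of their
(co-)regulating hosts, plus decoy hosts in each design and a large
background gene population on a positive baseline. Host activity profiles
are i.i.d. Gaussian per dataset and share a per-dataset factor giving
pairwise correlation `host_correlation` (default 0.5): hosts whose miRNAs
co-target a gene are typically co-expressed, often paralogous, families.
Three per-host scenarios set how the *emitted* host mRNA relates to the
miRNA activity that actually drives the targets:

* **coupled** — the host profile *is* the activity (good surrogate);
* **independent_promoter** — activity is a latent profile independent of
  the emitted host row (host uninformative);
* **mirna_targeted_host** — the host mRNA is degraded by a *co-expressed*
  miRNA (activity + independent noise, strength `degradation_strength` = 2),
  anti-correlating host and activity so that real interactions surface with
  negative weights — the bad-surrogate phenotype.

Defaults (50 datasets × 30 samples, 12 hosts, 20 targets with 3 regulators
at w\* ∈ [0.5, 2] and 3 decoys, noise σ = 0.5, baseline 10 ± 0.2, host
amplitude 8, 500 background genes) were chosen once as a realistic
mid-sized compendium; the host amplitude keeps host rows above the
low-value filter, and the background count keeps the hosts' contribution to
the per-sample universe mean small.

What the generator does **not** emulate: probe-level noise, batch effects,
cross-dataset heterogeneity of effect sizes (every dataset is statistically
identical), the order-of-magnitude baseline spread of real arrays (baseline
sd is kept small so the response is dominated by regulatory signal), or
positive-valued host intensities (host rows are emitted as centered
profiles; only their direction matters after unit-norm scaling). Passing
tests therefore demonstrate correctness and calibration of the procedure
under the model's own assumptions, not performance on real arrays. Two
consequences worth knowing: (i) because host rows are part of the gene
universe, the universe mean leaks a small positive, host-correlated
component into every down-regulation vector, so pooled null weights sit
slightly above zero at small gene counts — it cancels between real and
permuted fits, leaving calibration intact; (ii) with statistically
identical datasets the correlation baseline retains most of the linear
model's power, so the two methods' sensitivities are closer here than on
heterogeneous real compendia.

## Known limitations

* Hosts absent from a dataset (not measured, or removed by the low-value
  filter) are dropped from that dataset's designs only; a design whose
  hosts are all absent is skipped for that dataset.
* The GDS SOFT reader parses only the dataset-table section and a
  two-column probe map; multiple probes per symbol are collapsed by a
  user-chosen first/mean/max policy, since the right choice is
  platform-dependent.
* CORR correlates host profiles with d (not raw target expression) so that
  a positive value means repression for all three methods.
* No multiple-testing layer is applied on top of the P values; the cutoff
  is calibrated against the matched permuted controls instead.
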