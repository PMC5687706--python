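# Methods

`hicnets` analyzes the interaction network whose nodes are Hi-C *contact
domains* (Arrowhead-style calls; contiguous intervals with enriched internal
contacts) and whose edge weights are the average contact frequency between
two domains,

    I(a, b) = ( Σ_{i∈bins(a), j∈bins(b)} M[i, j] ) / (L_a · L_b),

with `M` the balanced (or otherwise normalized) binned contact matrix and
`L` the genomic lengths in bp, so `I` has units of intensity·bp⁻².  This
note records the model, the conventions and tie-breaks the implementation
commits to, what the synthetic generator does and does not emulate, and the
problem sizes the shipped tests and reproduction script use.

## Domain processing

* **Coordinates** are 0-based half-open (BED) everywhere.
* **Internal domains** — domains completely contained in another domain of
  the same chromosome — are removed before any network statistic, to avoid
  double counting of contacts.  Containment uses ≤ on both ends but
  excludes identical intervals; exact duplicates are collapsed to the first
  in sort order.  The filter is idempotent and order-independent (it is a
  single sweep over domains sorted by `(chrom, start, -end)`, so any
  container precedes its contents).
* **Bin membership** uses the bin-midpoint rule: a bin belongs to a domain
  iff its midpoint falls in the interval.  No prorating of partial bins; at
  10 kb bins against ≥50 kb domains the boundary effect is negligible and
  the rule is exactly invertible, which the generator's bin-matrix
  round-trip exploits.
* **Subcompartment labeling** supports two modes.  `single` (default):
  a domain is labeled only when every annotation interval it overlaps
  carries the same label.  `majority`: the label with the largest
  overlapped bp wins; exact ties leave the domain unassigned and are
  reported.  Annotation intervals overlapping with different labels are an
  input error, not a tie.

## Matrix balancing

`kr_balance` normalizes a raw cis matrix to the equal-row-sum fixed point
(row sums 1) with the symmetric diagonal iteration
`d ← d / sqrt(rowsum(D M D))`.  The fixed point — a positive diagonal
scaling making the matrix doubly stochastic up to scale — is what
Knight–Ruiz balancing produces; the solver here is the simple symmetric
Sinkhorn-type iteration, which suffices at the sizes this package targets.
All-zero rows are excluded before iterating and zeroed (and flagged) in the
output; there is no density-percentile mask by default.  Non-convergence
within `max_iter` raises, carrying the last residual.

## Tail-distribution fits

Intra-chromosomal intensities are heavy-tailed; inter-chromosomal ones
decay exponentially.  Two fitters share the `TailFitResult` container:

* **Power law** (`fit_power_law`): continuous maximum likelihood on the
  tail `x ≥ xmin`, `γ̂ = 1 + n / Σ ln(x_i/xmin)`.  Unless fixed by the
  caller, `xmin` is chosen among up to 100 quantile candidates (up to the
  95th percentile, tails of ≥50 points) to minimize the KS distance
  between the tail and the fitted model — the standard
  Clauset–Shalizi–Newman procedure.  The standard error of `γ̂` is
  `(γ̂−1)/√n_tail`.
* **Exponential** (`fit_exponential`): the tail starts at the sample median
  unless given.  The scale `I₀` is a nonlinear least-squares fit of the
  *bin-integrated* exponential model (free amplitude) to the tail density
  on 25 linear bins; integrating the model over each bin rather than
  evaluating it at bin centers removes the curvature bias that would
  otherwise shift `Î₀` at large n.  The closed-form MLE — the mean tail
  excess, exact by memorylessness — is reported alongside as `I0_mle`.

Both fits report an **R²** of the model log₁₀-density against the binned
empirical tail density (25 log bins for the power law, 25 linear bins for
the exponential; empty bins dropped).  Degenerate samples (constant, or
fewer than 50 positive values) return `converged=False`.

**Model comparison** (`compare_tail_models`) fits both families to the
same tail (start at the pooled median) and lets the higher R² win, with a
non-convergent fit losing automatically.  The two R² values are evaluated
on one *shared* log-binned density: with per-family binnings the
comparison at moderate n is decided by sparse-bin sampling noise rather
than by model shape (the linear binning of the exponential leaves many
one-count far-tail bins), and true-exponential samples were misclassified
several percent of the time.  On shared bins the per-bin noise is common
to both models and cancels from the comparison; 200 seeded samples
(n = 10⁴ per sample) classify without error.

**Rescaling collapse** scales each chromosome's intensity axis by its
median and the log-binned density by its value at the median, overlaying
distributions that differ only by scale.

## Connectivity

An edge exists iff `I > threshold` (strict, deterministic; ties are
measure-zero on continuous data).  The default threshold is a percentile
(25th, with 75th as a robustness check) of the *genome-wide pooled* trans
distribution, computed with the linear-interpolation percentile
convention.  The normalized degree divides by the count of *possible*
partners — `N−1` in cis (self excluded), the partner chromosome's domain
count in trans — so a complete graph gives exactly `n = 1`; dividing by
`N` instead is available via `include_self`.  `n_mean` averages over nodes
and, when aggregated, over chromosomes or pairs.

## Enrichment

For label pair `(i, j)`: `⟨H(i,j)⟩` is the unweighted mean of `I` over all
domain pairs carrying those labels (cis: distinct pairs on the same
chromosome; trans: all cross-chromosome pairs), `H₀` the unweighted mean
of `⟨H(i,j)⟩` over the `N_c` observed unordered label pairs (homotypic
included), and `H_ij = (⟨H(i,j)⟩ − H₀)/H₀`.  By construction `H` has
exactly zero mean over the stored pairs and is invariant under a global
intensity rescaling.  Label pairs with no observed domain pair are listed
as missing, not reported as zero; pair means are not weighted by domain
length (`I` is already length-normalized).  Top interactors are the top
`⌈fraction·N⌉` domains by mean interaction with their in-scope partners
(default 5%), ties at the cut broken by genomic coordinate and flagged.
Both the background-normalized and the raw-mean heatmaps are emitted for
the top-interactor subsets.

## Chromosome-pair structure and the DR score

* The **pair matrix** entry for chromosomes `(c₁, c₂)` is the summed trans
  `I` between their domains over `L_{c₁} · L_{c₂}`.  K-means (k-means++,
  best of 10 restarts) on its rows gives an RSS-vs-k curve; the elbow is
  the k maximizing the discrete second difference, and its value
  normalized by RSS(1) is the *elbow strength*.  Strength below 0.1
  (configurable) yields the verdict "no evident clusters" — the regime of
  a single global inter-chromosomal network.
* The **differential interaction score** of source domain k against a
  partner chromosome is `DR_k = (S_k − ⟨S⟩)/⟨S⟩` with `S_k` the row sum of
  the pair's domain interaction matrix and `⟨S⟩` the mean over k of `S_k`
  (this convention makes `mean(DR) = 0` exactly; "the average over the
  matrix" is the same number up to the constant partner count).  `σ` is
  the population standard deviation of DR.
* The **bootstrap null** permutes the positions of the matrix cells
  uniformly at random (cis variants permute the upper triangle and
  mirror), preserving the intensity multiset exactly; `σ_rand` and the
  null mean run length are means over 100 seeded replicates by default.
* **Sign runs**: maximal runs of constant DR sign in genomic order.  Exact
  zeros count as crossings and belong to no run, so `Σ runs + #zeros`
  equals the profile length; for i.i.d. signs with `P(+) = p` the mean run
  length tends to `1/(2p(1−p))`, which the tests verify.  The run-size
  histogram is summarized by a log-linear (exponential-decay) fit.

## The synthetic generator

`generate_genome` plants, at the domain level, the statistical structure
the pipeline is designed to detect.  Defaults (the study conditions):

| parameter | default | meaning |
|---|---|---|
| `n_chromosomes × domains_per_chromosome` | 5 × 200 | network size |
| `domain_length_median` | 185 kb | exponential length median (drawn lengths; floor 50 kb, 10 kb quantum) |
| `internal_fraction` | 0.35 | probability a domain spawns a strictly nested child |
| `gamma` | 2.0 | cis Pareto exponent |
| `cis_cutoff` | 10³ | upper truncation of the cis tail, in units of `cis_xmin` |
| `trans_I0` | 1.0 | trans exponential scale |
| `cis_trans_ratio` | 850 | target mean(cis)/mean(trans) |
| `homotypic_boost`, `a1_trans_boost`, `band_amplitude` | 1.0 (off) | planted-signal multipliers |
| `band_fraction`, `band_length` | 0.2, 5 | banded rows when `band_amplitude > 1` |
| `subcompartment_block_length` | 10 | domains per label block (labels are contiguous, as real subcompartments are) |

Design choices that matter:

* **Ratio calibration rescales the cis side.**  After drawing, all cis
  values are multiplied by one global factor so the realized mean ratio
  equals the target exactly.  Rescaling cis rather than trans leaves the
  trans exponential scale identifiable (the recovery tests fit `Î₀`
  against the planted value) and does not disturb `γ`, which is
  scale-free.
* **Truncated Pareto.**  A pure `γ = 2` Pareto has infinite variance, so
  label-pair mean enrichments are dominated by single extreme draws and no
  planted homotypic signal of realistic size is detectable.  Real
  intensity distributions follow the power law over a few decades, not to
  infinity; the generator truncates at `cis_cutoff · xmin` (three decades
  by default).  The truncation biases the untruncated-model MLE of `γ`
  upward by ≈0.008 at the default size, within the 3-standard-error
  recovery band (≈0.010); widen `cis_cutoff` if tighter exponent fidelity
  is needed at the cost of noisier enrichment means.
* **Signal multipliers default off.**  The base genome carries the pure
  power-law/exponential null distributions, so distributional parameters
  are exactly recoverable; enrichment, band and cluster signals are
  switched on explicitly by the scenario (tests use boosts of 2–3).
* **Lengths.**  The 185 kb median applies to the drawn top-level lengths;
  nested children are shorter, so the realized median over *all* domains
  is lower (≈130 kb) and over filtered domains slightly higher (≈190 kb).
  Real filtered domains are longer still (internal calls in published
  lists are not independent children of their parents); the generator
  makes no attempt to match that second-order feature.
* `generate_bin_matrix` spreads each pair's total intensity uniformly over
  its bin block, the exact inverse of `I(a, b)` under the midpoint rule,
  giving a lossless round-trip through the text-matrix I/O path.  Cis
  diagonal blocks are left at zero (self-interactions are excluded from
  every statistic).

What the generator does **not** emulate: polymer-physics contact decay
with genomic distance inside a chromosome, coverage bias (matrices are
born balanced; the balancing code is exercised on separate raw fixtures),
allele structure, unannotated gaps, and the B4 subcompartment.  Passing
tests therefore certify the statistical machinery — estimator
correctness, null-model identities, planted-signal detection — not the
biological conclusions on any real map.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; the pipeline derives all
randomness from one master seed, and reruns are byte-identical.  The test
suite and `scripts/acceptance.py` use genomes of 2–5 chromosomes × 30–200
domains, 20-seed recovery/discrimination sweeps, and 30–100 bootstrap
replicates; the full suite runs in a few seconds on one CPU.  Larger
genomes change only runtime, not any convention above.

## Known limitations

* The KS distance is reported but no p-value is simulated for the
  power-law fit, and no likelihood-ratio test between families is offered
  — model choice is by R², matching the analysis this package reproduces.
* `kr_balance` materializes the matrix densely; it targets per-chromosome
  matrices at domain-scale resolution, not genome-wide 1 kb maps.
* Real-data mode reads text sparse-triple/dense matrices (and BED lists);
  binary container formats are out of scope.
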