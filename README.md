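# hicnets

Network analysis of Hi-C contact domains: treats the contact domains called
on a chromosome (TAD-scale units, median ~200 kb) as the nodes of a weighted
interaction network and characterizes how those networks are organized
within and between chromosomes.

Given binned contact matrices, a domain list (BED), and a subcompartment
annotation (BED4 with labels A1, A2, B1, B2, B3, B4), or a synthetic genome
generated with the same statistical structure, the package computes:

* the **domain interaction statistic** `I(a,b) = Σ shared entries / (L_a·L_b)`
  on KR-balanced matrices, after removing *internal* domains (those
  completely contained in another) to avoid double counting;
* the **cis/trans contrast**: the ratio of mean in-cis to mean in-trans
  interaction (≈850 on real lymphoblastoid maps), thresholded
  **normalized degrees** `n_k`, and tail fits showing that intra-chromosomal
  intensities follow a power law `P(I) ≃ I^(−γ)` with `γ ≃ 2` (scale-free,
  hub-dominated) while inter-chromosomal intensities decay exponentially
  `P(I) ≃ exp(−I/I₀)` as in a random network — fitted by maximum likelihood
  with KS-selected `xmin`, compared by R² on a shared binned tail density;
* **subcompartment enrichment** `H_ij = (⟨H(i,j)⟩ − H₀)/H₀` over label
  pairs, compartment composition of all domains vs the top-5% interactors;
* **chromosome-pair structure**: the length-normalized pair matrix with a
  k-means RSS-elbow test for isolated chromosome clusters, and the
  **differential interaction score** `DR_k = (S_k − ⟨S⟩)/⟨S⟩` per domain
  against a partner chromosome, with a value-permuting bootstrap null for
  its standard deviation and the length of coherent-sign runs — the
  signature of banded, non-random trans contacts.

A first-class synthetic generator (`hicnets.synthetic`) plants all of these
features (exponential domain lengths, nested domains, truncated-Pareto cis /
exponential trans intensities, label blocks, homotypic and A1 boosts, trans
bands) so the entire pipeline is testable without downloads.

## Worked example

```python
from hicnets import *

spec = SyntheticGenomeSpec(n_chromosomes=3, domains_per_chromosome=80,
                           band_amplitude=2.0)   # plant trans bands
g = generate_genome(spec, seed=1)

print(cis_trans_ratio(g.cis_pool, g.trans_pool))  # 850.0  (calibrated)

pl = fit_power_law(g.cis_pool)
print(pl.gamma, pl.n_tail, pl.r_squared)          # 2.004  6023  0.983

thr = interaction_threshold(g.trans_pool, 25)     # noise threshold
print(mean_connectivity(g.cis.values(), thr))     # 1.000  -> complete cis nets
print(mean_connectivity(g.trans.values(), thr))   # 0.750  -> denser-than-random trans

net = g.trans[("chr1", "chr2")]
prof = dr_score(net)
null = dr_bootstrap(net, replicates=100, seed=0)
print(prof.sigma, null["sigma_rand"])             # 0.330  0.120
print(prof.mean_run, null["mean_run_rand"])       # 4.44   2.01
```

The cis pools recover the planted scale-free exponent (`γ ≈ 2`); every cis
network is complete above the 25th-percentile trans threshold while trans
networks keep 75% of possible edges, reproducing the strong-territory /
weak-intermingling contrast.  The planted bands make the DR score four
standard deviations wider than its shuffled null (σ 0.33 vs 0.12) with
coherent-sign stretches more than twice as long (4.4 vs 2.0 domains) —
trans contacts are not randomly placed.

The same analysis runs from the shell:

```sh
hicnet run-all --seed 1 --outdir out          # default synthetic genome
hicnet transnet --config analysis.yaml --pair chr1:chr2
```

writing per-stage TSV tables (`domains.tsv`, `tail_fits.tsv`,
`connectivity.tsv`, `enrichment_{cis,trans}.tsv`, `composition.tsv`,
`chrom_pairs.tsv`, `dr_profiles.tsv`), a `summary.json` of headline numbers
and a `manifest.json` of parameters.  Real inputs are configured with
`matrix_paths` / `domains_path` / `subcompartments_path` in the YAML config;
raw count matrices are KR-balanced on the fly (`matrices_raw: true`).

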