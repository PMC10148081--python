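# pccsort

Statistical-mechanics analysis of a D3-symmetric α₆β₆ multienzyme scaffold
from single-particle classification output:

- **`pccsort.symmetry`** — enumerates the 2⁶ = 64 binding-site occupancy
  configurations of the six α–β sites, partitions them into oligomeric
  isomers (orbits under the D3 point group: 16 isomers across 7 formulae
  α₀β₆…α₆β₆) and cross-checks the count via the orbit-counting theorem.
- **`pccsort.simulate`** — synthetic particle generator emulating
  symmetry-expanded focused-classification output: true occupancies from an
  independent-site or explicit-formula binding model, optional per-site
  misclassification, six `alpha_present`/`alpha_missing` records per particle.
- **`pccsort.sorting`** — the sorting method: count α-missing labels among a
  particle's six expanded copies, assign its oligomeric formula
  (n = 6 − k_missing), tally the formula distribution, and optionally
  deconvolve classification error through the binomial mixing matrix.
- **`pccsort.equilibrium`** — stepwise association attributes: count ratios
  r_n = N_{n+1}/N_n (the Kc·[α] product for α_nβ₆ + α ⇌ α_{n+1}β₆),
  exponential-decay fit on the log scale, and the identical-independent-site
  model r_n = ((6−n)/(n+1))·θ with a maximum-likelihood θ estimate and CI.
- **`pccsort.star` / `pccsort.cli`** — minimal STAR-dialect particle-table
  I/O and the command-line pipeline.

## CLI

```sh
# isomer census under a chosen point group
pccsort enumerate --group D3

# synthetic symmetry-expanded particle table + ground truth
pccsort simulate --n-particles 20000 --binding-prob 0.8 --seed 1 \
    --out particles.star --truth-out truth.tsv

# formula distribution (optionally deconvolving label noise)
pccsort sort particles.star --out dist.tsv [--correct --eps-fn 0.1]

# stepwise ratios, decay fit, independent-site estimate (+ optional figure)
pccsort equilibrium dist.tsv --out report.json --plot ratios.png
```

`pccsort simulate --config config.yaml` reads defaults from a YAML file
(see `pccsort.config.RunConfig`); explicit flags override. All outputs are
deterministic for a given seed and carry the run configuration as `#`
comments.

The particle table is a simplified STAR dialect: one `data_particles`
block with loop columns `_pccParticleId`, `_pccCopyIndex`,
`_pccClassLabel` (`present`/`missing`). Real symmetry-expanded tables can
be adapted by mapping each source particle (grouped by image name and
coordinates) to a `_pccParticleId` and each expansion copy to a
`_pccCopyIndex`.

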