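# pimotif

Maximum-entropy **pairwise interaction models (PIM)** of transcription
factor binding sites, with the full inference workflow around them:
iterative binding-site refinement on ChIP peak fragments, BIC-controlled
greedy coupling selection, PWM-mixture and nearest-neighbor baselines, and
an analysis toolkit (energy-landscape basins, direct/mutual information,
participation ratios, Hopfield spectral decomposition).

## The problem and the model

Position weight matrices (PWMs) assume each position of a binding site
contributes independently to binding. In vivo site collections frequently
violate that assumption: nucleotides at different positions co-vary, and
the PWM then misestimates the frequencies of the most common sites. The
PIM is the minimal extension that fixes this. It is the maximum-entropy
distribution over L-mers `s = (s_1 .. s_L)` that reproduces both the
single-nucleotide frequencies `f_i(a)` and the pairwise frequencies
`f_ij(a, b)` of a site sample:

```
P(s) = exp(-E(s)) / Z
E(s) = sum_i h_i(s_i) + sum_{(i,j) active} J_ij(s_i, s_j)
```

Lower energy means a more probable (better-bound) sequence. The fields
`h_i(a)` are per-position binding energies; the couplings `J_ij(a, b)` are
pairwise corrections; the PWM is the special case with all `J = 0`.
Everything is computed by exact enumeration of the sequence space (no
mean-field or pseudo-likelihood approximations); couplings are added
greedily — most-deviant pair first, by an exact binomial test — and the
Bayesian Information Criterion `BIC = -log L + (k/2) log N` decides when to
stop. A zero-sum (minimum-norm) gauge makes the parameters unique.

Intended users: regulatory genomics groups who have bound-fragment
sequences (ChIP peaks) and want a motif model that captures nucleotide
interdependencies, plus the diagnostics to interpret them.

## Worked example

Fit a PIM to 5,000 sites drawn from a sharp two-variant motif, then look at
its landscape and interactions:

```python
from pimotif import synth, inference as inf, information as info, landscape as ls

model = synth.demo_pim(12)                       # known two-basin generator
sites = synth.sample_sites(model, 5000, seed=1)  # exact draws
params, trace = inf.build_pim(sites)             # greedy BIC growth
print(trace.to_frame())
```

```
 step  pair_i  pair_j      nll      bic
    0      -1      -1 35922.02 36075.33
    1       6       7 32940.62 33132.25
    2       4      12 32930.24 33160.21
```

The first added coupling (positions 6–7, 1-based) drops the BIC by ~2,900
nats; later candidates no longer pay for their 9 parameters, so the
BIC-minimal model keeps exactly the one genuine interaction. Its energy
landscape has two basins, each holding about half the sites:

```python
for b in ls.find_basins(params, sites):
    print(b.sequence, round(b.energy, 2), round(b.weight, 3))
# ACGGATGGACCT -25.92 0.511
# ACGGACAGACCT -25.90 0.489
```

The interaction analysis confirms one strong, localized link
(normalized direct information 0.64 between the coupled positions;
participation ratio 0.015, i.e. the interaction weight concentrates on a
single pair out of 132), and the model-quality control shows the PIM fits
the sample as well as its finite size allows:

```python
mats = info.interaction_matrices(params)
print(mats.ndi[5, 6])                              # 0.642
d_pim = info.dkl_sample_to_model(sites, params)    # 1.126 bits
mean, sd = info.self_dkl(info.state_probabilities(params), N=5000,
                         reps=30, seed=2)          # 1.133 +/- 0.025 bits
```

`d_pim` within two standard deviations of the self-DKL means the residual
divergence is pure sampling noise — whereas the PWM fit of the same sample
leaves 1.99 bits, far outside that band.

The same workflow runs from the shell on FASTA fragments:

```sh
pimotif simulate --seed 3 --out sim/
pimotif refine --fasta sim/fragments.fa --matrix init.txt \
        --model pim --seed 5 --out refined/
pimotif info --model refined/model.json --out infodir/
```

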