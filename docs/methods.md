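# Methods

## The calling model

`amorthmm` calls 5-methylcytosine (5mC) at CpG sites from aligned
nanopore events. The underlying model is the classical per-k-mer
Gaussian-emission HMM: each 6-mer occupying the pore — over the expanded
alphabet {A, C, G, T, M}, with M marking 5mC and every non-terminal M
followed by G — has an independent current distribution N(mu, sigma^2).
A site is called by comparing, per read, the forward-algorithm
log-likelihood of the site's methylated 11-mer window path (its six
overlapping modified 6-mers) against the M→C substituted unmethylated
path, summing the log-likelihood ratio over reads, and calling
methylated when the sum is positive (symmetric prior; no per-read llr
magnitude filter). With aligned events the transition structure is
degenerate (stay and skip probabilities zero) and the forward recursion
reduces to a factorized sum; nonzero stay/skip probabilities are
supported and validated against exhaustive path enumeration.

Emission training is moment estimation: for every k-mer with at least
`min_events` events, mu is the sample mean and sigma^2 the
maximum-likelihood variance, floored at 1e-6 pA^2. Modified k-mers below
the support threshold fall back to a pooled default — the mixture
mean/variance over all learned modified k-mers. This default is the
plain HMM's only recourse for unseen modified k-mers and is exactly what
the amortizer replaces.

## Emission amortization

Every learned modified-k-mer row is a supervised pair (features ->
(mu, sigma^2)). Features are 141 bits: 30 position-by-letter one-hots,
105 adjacent-dinucleotide one-hots (21 CpG-valid ordered pairs — the 25
ordered pairs minus MA/MC/MT/MM, which the CpG constraint forbids — at
5 positions), and 6 per-position C-or-M indicators. Within each block
the layout is lexicographic under A<C<G<T<M and version-tagged in
serialized predictors.

The predictor is a feedforward network: `d` ReLU layers of width `h`
(grids d in {3..6}, h in {16,32,64,128}) plus a direct linear path from
the input to the two-unit output head (predicted mean and log-variance;
the exp parameterization guarantees positive variance). The loss is the
symmetrized KL divergence between target and predicted Gaussians, whose
closed form reduces to

    f = (s^2 + D^2) / (2 s_hat^2) + (s_hat^2 + D^2) / (2 s^2) - 1,

with D the mean difference — the log-sigma terms of the two directed
divergences cancel. Targets are standardized by the training means'
location and scale; the symmetrized KL is invariant under a common
affine map, so this is purely a conditioning choice.

Optimization is full-batch Adam with a cosine-annealed learning rate
(default 1e-2 annealed to zero over 1500 epochs) and decoupled weight
decay: strong (3.0) on the ReLU branch, light (1e-3) on the linear path,
with the branch's output layer initialized at zero. Pore-table means are
dominated by additive and adjacent-pair contributions that are exactly
linear in the feature encoding, so when only a few dozen training pairs
exist (highly incomplete panels) this regularization pulls the fit
toward the well-posed ridge-like linear solution; with thousands of
pairs the branch contributes freely. A constant learning rate or an
unregularized branch measurably underfits/overfits: on residual-free
synthetic tables the annealed, skip-connected fit reaches held-out
symmetrized KL ~1e-7, versus ~0.1 for the plain configuration.

Imputation replaces only rows with provenance `default` (and modified
k-mers absent altogether); learned rows are never overridden — the
override-everything variant is retained purely as an ablation, and the
evaluation shows it is consistently worse on seen k-mers. A combined
policy router is provided that sends a site to a "seen-k-mer" caller
when all six constituent modified k-mers were in training and to the
amortized HMM otherwise.

## Coherent panel selection

Simulating k-mer-incomplete training data must respect pore physics:
one methylated site yields all six of its overlapping modified 6-mers.
Selection is therefore posed over 11-mer windows as an ILP — maximize
the frequency-weighted count of fully included windows subject to a
budget B = floor(p |S| / 100) on unique k-mers, with the k-way AND
linearized as 0 <= -k y_i + sum_{s in V_i} x_s <= k-1. The backend is
HiGHS via `scipy.optimize.milp` (exact branch-and-bound); tests compare
objectives against exhaustive enumeration, never solver internals, and
any exact backend would do. A random-then-prune baseline (sample B
k-mers, keep windows that happen to be complete) quantifies what
incoherent selection loses: at p=10 it completes essentially no windows
while the ILP completes the budget's worth.

## The synthetic data generator

The generator emulates the statistical structure of bisulfite-labelled
nanopore training data; all defaults are in pA-like units chosen to
resemble published R9.4 CpG tables.

Ground-truth pore model: mean(s) = 90 + additive per-position letter
effects (s.d. 4 pA) + adjacent-pair effects (s.d. 0.4 pA) + i.i.d.
per-k-mer residual (s.d. 0.5 pA); per-k-mer event noise variance is
uniform on [1, 4] pA^2. M is a modified cytosine, not an independent
fifth letter: its effect equals the C effect plus a methylation shift
drawn per (pore position, preceding base) with s.d. 2.5 pA. Methylation
thus moves the current by ~1-2 pA against 1-2 pA event noise, while
letter swaps move it by several pA — the regime that makes 5mC calling
hard and imputation valuable. The construction keeps means exactly
linear in the 141 features when the residual is zero, so the residual
alone bounds achievable imputation accuracy. (An early design drew M
effects at full letter scale; that inverts the biology — any wide
"unknown" default then detects methylation by outlier-ness better than
imputation can.)

Reference: ~2100 CpG sites planted on a 42 kb sequence, windows
non-overlapping and the background CG-free, so sites are >6 bases apart
and every methylated site owns a valid single-M window. Site contexts
are drawn from 600 distinct 11-mer types in two frequency tiers — 5% of
types hold 45% of sites, the rest share the remainder with a floor of
at least one site per type (at this type count the CpG-constrained
k-mer universe holds ~1350 unique modified 6-mers, so the p=5 budget
buys ~70 of them, the scale of the real panels this protocol emulates).
Real methylomes observe each modified k-mer at many genomic sites; the
floor and the within-type stratification of the 50% methylation rate
reproduce that property at desk scale, and without them rare contexts
would be attested in only one state by chance, an artifact of small
references rather than a feature of the data. Methylation state is
site-level, shared by all reads.

Reads: 3150 fragments of 400 bases with uniform starts on the
circularized reference (~30x coverage; circularization avoids the
coverage ramp at linear ends, which would otherwise leave edge sites
under-supported in training folds). Each read emits one
Normal(mu_kmer, sigma_kmer^2) event per covered k-mer start; a
stay/skip event-sequence sampler exercises the forward algorithm's
non-degenerate regime. Per-read site labels reproduce the ground truth
(optionally corrupted at a configurable rate), and the confident-label
filter keeps sites covered by >= 5 reads with unanimous calls, marking
the remainder ambiguous and excluding them from training and
evaluation.

What the simulator does not model: raw squiggle, basecalling and
alignment errors, reverse-strand and hemimethylation, non-Gaussian
event noise, context-dependent coverage bias. Passing results
demonstrate the method's internal logic (selection coherence,
imputation benefit, generalization structure) under a faithful noise
model, not real-data accuracy levels.

## Evaluation protocol

Reads are split into folds (default 6; the synthetic study uses 2, each
held out once, with replication across 5 independent simulations);
sites therefore appear in training and test through disjoint reads. Per
completeness level p and fold: methylated-window frequencies from the
labelled training data weight the ILP; training events on unselected
modified k-mers are removed; emissions are trained; the amortizer is
fit on the learned modified rows and imputes the defaults; plain,
amortized and override-all tables are evaluated on the held-out fold
with no k-mer filtering. Class balancing and size normalization across
p are implemented and exposed behind config flags but default off: they
are accommodations for example-based discriminative callers, whereas
the HMM estimates per-k-mer moments that saturate at modest support and
is class-imbalance agnostic, so applying them would only thin rare
k-mer support without changing what is being measured.

Test sites split into the sensor subset (all six modified k-mers
learned — not merely selected — in training, so plain and amortized
tables provably agree there) and the k-mer subset; the latter splits at
the median novelty score (mean one-hot Hamming distance of the site's
11-mer to the unique learned training windows; ties go low). Two error
metrics are reported with explicit names, because "percent modified"
accuracy can be read either way: `read_error`, the fraction of per-read
calls disagreeing with the site label, and `site_error`, the mean
absolute difference between the called per-site methylated fraction and
the binary label. The headline per-site unit is `site_error`.

## Numerical and design notes

- Determinism: every stochastic component takes an explicit seed;
  sub-seeds derive from a master generator per simulation. HiGHS runs
  single-threaded on a fixed variable order. Identical configs produce
  byte-identical reports.
- `min_events` defaults to 5 for standalone training (conservative,
  guarding against spurious alignments in real data) and to 2 inside
  the synthetic protocol, where events are perfectly aligned and the
  rarest modified k-mer retains ~15 training events per fold.
- Degenerate inputs: empty event tables, absent classes, empty training
  window sets, non-positive variances and malformed windows raise
  informative errors rather than propagating NaNs; a variance floor
  keeps log-densities finite.
- Tie-breaks: equal-llr sites are called unmethylated (call = llr > 0);
  equal novelty scores fall to the low-novelty side; alternative ILP
  optima are accepted (tests compare objective values only).
- Known limitations: the k-mer universe of CG-free-flank windows
  saturates near 1600 modified 6-mers, capping the p=5 panel at ~70
  k-mers; novelty effects are correspondingly compressed relative to
  genome-scale data. The amortizer's advantage concentrates in the
  k-mer-generalization subset and grows as p falls, but its *relative*
  advantage over the pooled-default HMM on high- versus low-novelty
  sites is not guaranteed at very low p, where prediction error itself
  grows with novelty while the pooled default is novelty-blind.
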