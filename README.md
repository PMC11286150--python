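# amorthmm

Amortized-HMM calling of 5-methylcytosine (5mC) from nanopore current
signal, for the setting where labelled training data do not cover all
modified k-mer contexts.

## The problem

Nanopore methylation callers in the Nanopolish tradition model the
current of each 6-mer in the pore — over the alphabet {A, C, G, T, M},
M marking 5mC — with an independent Gaussian emission N(mu_s, sigma_s^2)
inside an HMM. Independence is fatal when training data are *k-mer
incomplete*: a modified 6-mer never observed in training has no learned
emission and falls back to an uninformative default, so calls at sites
containing it are near-useless. Complete training data are easy for
plain base calling but not for epigenetic marks, and will be harder
still for marks beyond CpG 5mC.

`amorthmm` implements the hybrid remedy: train the HMM as usual, then
fit a small feedforward network mapping a 141-bit k-mer encoding
(30 position-by-letter bits + 105 adjacent-dinucleotide bits + 6 C-or-M
indicator bits) to emission parameters, minimizing the symmetrized KL
divergence between predicted and learned Gaussians,

    f(P, P^) = D_KL(P || P^) + D_KL(P^ || P),

and use it to *impute only the missing rows* of the emission table —
learned rows are never overridden. Calling is unchanged: per read, the
forward log-likelihood of a site's methylated 11-mer window path minus
the unmethylated (M -> C) path, summed over reads; methylated iff the
sum is positive.

The package also provides:

- **Coherent k-mer panel selection.** Restricting training data to a
  budget B = floor(p |S| / 100) of unique modified k-mers must keep
  whole windows together (one methylated site physically yields all six
  of its overlapping 6-mers). Selection is an exact ILP — maximize
  frequency-weighted completed windows subject to the budget, with the
  six-way AND linearized as 0 <= -k y_i + sum_{s in V_i} x_s <= k-1 —
  plus a brute-force oracle and a random-then-prune baseline.
- **A synthetic data generator** reproducing the statistical structure
  of bisulfite-labelled nanopore training data (additive pore model
  with ~1-2 pA methylation shifts, recurring 11-mer context types,
  site-consistent methylation, ~30x reads, the >= 5-read unanimous
  confident-label filter).
- **The evaluation protocol**: read-level cross-validation folds,
  sweeps over completeness p, decomposition of test error into sensor
  (all modified k-mers seen in training) and k-mer-generalization
  subsets, and a further low/high novelty split by mean one-hot Hamming
  distance to the training windows.

See `docs/methods.md` for the full model description and design notes.

## Worked example

```python
from amorthmm import (
    generate_pore_model, generate_reference, simulate_events,
    per_read_site_calls, filter_confident_sites,
    build_selection_problem, solve_selection_ilp,
    restrict_training_events, train_emission_table,
    build_training_pairs, fit_amortizer, impute_emission_table,
    call_site, decompose_window,
)
import pandas as pd

model = generate_pore_model(seed=0)
ref = generate_reference(seed=1, length=42_000)
events = simulate_events(ref, model, n_reads=3_150, read_length=400, seed=2)
labels = filter_confident_sites(per_read_site_calls(ref, events))
meth = labels[labels.state == "methylated"]

# 5%-complete coherent panel from observed window frequencies
windows = pd.Series(
    [ref.site_windows[list(ref.cpg_sites).index(p)] for p in meth.position]
).value_counts()
sel = solve_selection_ilp(build_selection_problem(list(windows.items()), p=5))
print(len(sel.problem.universe), sel.problem.budget, len(sel.selected_kmers))
# 1319 65 65   <- universe of modified 6-mers, budget at p=5, panel size

restricted = restrict_training_events(events, sel.selected_kmers)
table = train_emission_table(restricted, min_events=2)
print(len(table.learned_modified_kmers()))
# 65            <- emissions learned only for the coherent panel

predictor = fit_amortizer(build_training_pairs(table))
full = impute_emission_table(table, predictor)
print(sum(full.provenance(s) == "imputed" for s in full.kmers()))
# 2239          <- every other single-M 6-mer imputed by the network

site = int(ref.cpg_sites[0])
window = ref.site_windows[0]
call = call_site(events, site, window, full.ensure_complete(
    [k.replace("M", "C") for k in decompose_window(window)]))
print(call.call, round(call.llr, 2), call.coverage)
# False -108.27 33  <- unmethylated site, summed llr, reads used
```

The printed numbers are from this exact script; the llr and panel
contents vary with the seeds.

The same pipeline is scriptable from the shell:

```
amorthmm simulate --seed 1 --out sim/
amorthmm select-kmers --windows windows.tsv --p 5 --out panel
amorthmm train-hmm --events sim/events.tsv --restrict panel.kmers.txt --out emissions.tsv
amorthmm train-amortizer --emissions emissions.tsv --out predictor.json
amorthmm impute --emissions emissions.tsv --model predictor.json --out imputed.tsv
amorthmm call --events sim/events.tsv --emissions imputed.tsv \
    --reference sim/reference.txt --sites sim/sites.bed --out calls
amorthmm evaluate --config run.yaml --out results/
```

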