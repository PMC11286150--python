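"""Coherent modified-k-mer panel selection.

Restricting training data to a budget of B unique modified k-mers must
respect the physics of sequencing: a methylated site contributes all k of
its overlapping modified k-mers or none of them. Selection therefore
happens at the 11-mer window level and is posed as an integer linear
program over binary k-mer indicators x_s and window indicators y_i:

    maximize    sum_i w_i * y_i
    subject to  sum_s x_s <= B
                0 <= -k*y_i + sum_{s in V_i} x_s <= k - 1   for every i,

where V_i is the set of constituent k-mers of window i and w_i are
user-supplied frequency weights summing to one. The double inequality is
the linearization of the k-way AND  y_i = AND_{s in V_i} x_s.

The exact solver is HiGHS via :func:`scipy.optimize.milp`. A brute-force
enumerator serves as an independent optimality oracle on small instances,
and a random-then-prune baseline shows what incoherent selection loses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .kmer_core import K_DEFAULT, MethylWindow, decompose_window

_WEIGHT_TOL = 1e-9


@dataclass
class SelectionProblem:
    """A budgeted coherent-selection instance.

    ``windows[i]`` has weight ``weights[i]`` and constituent k-mer set
    ``constituent_sets[i]``; ``universe`` is their union and ``budget`` the
    maximum number of unique k-mers that may be selected.
    """

    windows: list[str]
    weights: np.ndarray
    constituent_sets: list[frozenset[str]]
    universe: tuple[str, ...]
    budget: int
    k: int = K_DEFAULT

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.windows) != len(self.weights) or len(self.windows) != len(
            self.constituent_sets
        ):
            raise ValueError("windows, weights and constituent_sets must align")
        if abs(self.weights.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights sum to {self.weights.sum()}, expected 1")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        uni = set(self.universe)
        for V in self.constituent_sets:
            if not V <= uni:
                raise ValueError("constituent set escapes the universe")
            if len(V) > self.k:
                raise ValueError("constituent set larger than k")
        if self.budget < 0:
            raise ValueError("budget must be non-negative")
        if 0 < self.budget < self.k:
            warnings.warn(
                f"budget {self.budget} < k={self.k}: no window can be completed",
                stacklevel=2,
            )

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass
class SelectionResult:
    """Solution of a selection instance."""

    selected_kmers: set[str]
    selected_windows: list[str]
    objective: float
    solver_status: str
    problem: SelectionProblem = field(repr=False)

    @property
    def n_selected_windows(self) -> int:
        return len(self.selected_windows)


def compute_budget(p: float, universe_size: int) -> int:
    """The k-mer budget ``B = floor(p * |S| / 100)`` for completeness level p."""
    if not 0 < p <= 100:
        raise ValueError(f"p must be in (0, 100], got {p}")
    if universe_size < 0:
        raise ValueError("universe size must be non-negative")
    return math.floor(p * universe_size / 100.0)


def build_selection_problem(
    windows_with_counts: Sequence[tuple[MethylWindow | str, float]],
    p: float,
    uniform_weights: bool = False,
    k: int = K_DEFAULT,
) -> SelectionProblem:
    """Assemble a selection instance from observed window frequencies.

    Duplicate windows have their counts summed before normalization.
    Weights are the normalized counts (the observed frequency of each
    methylated 11-mer), or uniform over distinct windows when
    ``uniform_weights`` is set — the proxy for label-free settings.
    """
    counts: dict[str, float] = {}
    for w, c in windows_with_counts:
        if c < 0:
            raise ValueError("counts must be non-negative")
        seq = w.seq if isinstance(w, MethylWindow) else MethylWindow(w, k=k).seq
        counts[seq] = counts.get(seq, 0.0) + float(c)
    windows = sorted(counts)
    raw = np.array(
        [1.0 if uniform_weights else counts[w] for w in windows], dtype=float
    )
    if raw.sum() <= 0:
        raise ValueError("all window counts are zero")
    weights = raw / raw.sum()
    csets = [frozenset(decompose_window(w, k=k)) for w in windows]
    universe = tuple(sorted(set().union(*csets))) if csets else ()
    return SelectionProblem(
        windows=windows,
        weights=weights,
        constituent_sets=csets,
        universe=universe,
        budget=compute_budget(p, len(universe)),
        k=k,
    )


def _result_from_kmers(
    prob: SelectionProblem, kmers: set[str], status: str
) -> SelectionResult:
    selected = [
        w for w, V in zip(prob.windows, prob.constituent_sets) if V <= kmers
    ]
    mask = np.array([V <= kmers for V in prob.constituent_sets], dtype=bool)
    return SelectionResult(
        selected_kmers=set(kmers),
        selected_windows=selected,
        objective=float(prob.weights[mask].sum()),
        solver_status=status,
        problem=prob,
    )


def solve_selection_ilp(prob: SelectionProblem) -> SelectionResult:
    """Solve the coherent-selection ILP exactly.

    Variables are ordered ``[x_s for s in universe] + [y_i per window]``;
    HiGHS is run single-threaded with a fixed variable order, so the
    returned optimum is deterministic for a given instance.
    """
    nS, m = len(prob.universe), prob.n_windows
    if m == 0 or nS == 0:
        return _result_from_kmers(prob, set(), "optimal")
    kidx = {s: j for j, s in enumerate(prob.universe)}
    n = nS + m
    c = np.zeros(n)
    c[nS:] = -prob.weights  # milp minimizes

    constraints = []
    a_budget = np.zeros((1, n))
    a_budget[0, :nS] = 1.0
    constraints.append(LinearConstraint(a_budget, -np.inf, prob.budget))
    # coherence: 0 <= -k*y_i + sum_{s in V_i} x_s <= k-1
    a_coh = np.zeros((m, n))
    for i, V in enumerate(prob.constituent_sets):
        for s in V:
            a_coh[i, kidx[s]] = 1.0
        a_coh[i, nS + i] = -prob.k
    constraints.append(LinearConstraint(a_coh, 0.0, prob.k - 1.0))

    res = milp(
        c,
        constraints=constraints,
        integrality=np.ones(n),
        bounds=Bounds(0.0, 1.0),
    )
    if res.status != 0 or res.x is None:
        return SelectionResult(
            selected_kmers=set(),
            selected_windows=[],
            objective=float("nan"),
            solver_status=f"solver-failed({res.status}): {res.message}",
            problem=prob,
        )
    x = np.round(res.x[:nS]).astype(int)
    kmers = {s for s, xi in zip(prob.universe, x) if xi == 1}
    out = _result_from_kmers(prob, kmers, "optimal")
    # integer-arithmetic feasibility check of Eq. constraints
    assert len(out.selected_kmers) <= prob.budget
    return out


def brute_force_selection(
    prob: SelectionProblem, max_enumeration: int = 1 << 25
) -> SelectionResult:
    """Exhaustive optimality oracle for small instances.

    Any optimal selection's value is attained by a union of completed
    windows, so it suffices to enumerate window subsets whose constituent
    unions fit the budget. Refuses instances whose enumeration would
    exceed ``max_enumeration`` subsets.
    """
    m = prob.n_windows
    if 2**m > max_enumeration:
        raise ValueError(f"instance too large for brute force (m={m})")
    best_val, best_kmers = 0.0, set()
    for r in range(m + 1):
        for idx in combinations(range(m), r):
            union: set[str] = set()
            for i in idx:
                union |= prob.constituent_sets[i]
            if len(union) > prob.budget:
                continue
            val = float(prob.weights[list(idx)].sum()) if idx else 0.0
            if val > best_val:
                best_val, best_kmers = val, union
    return _result_from_kmers(prob, best_kmers, "optimal")


def random_prune_baseline(prob: SelectionProblem, seed: int) -> SelectionResult:
    """Incoherent baseline: B random k-mers, coherence enforced post hoc.

    Samples the budget's worth of k-mers uniformly without replacement,
    then keeps only windows all of whose constituents happened to be
    drawn. Far fewer windows survive than under coherent selection, which
    is precisely why selection is done at the window level.
    """
    rng = np.random.default_rng(seed)
    nS = len(prob.universe)
    take = min(prob.budget, nS)
    kmers = set(rng.choice(np.array(prob.universe, dtype=object), size=take, replace=False)) if take else set()
    return _result_from_kmers(prob, {str(s) for s in kmers}, "optimal")
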