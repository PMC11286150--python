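"""Desk-scale evaluation protocol for k-mer-incomplete training.

The protocol measures how methylation callers degrade as training data
cover fewer unique modified k-mers. For each completeness level p and
cross-validation fold (reads, not sites, are split into folds):

1. methylated 11-mer windows observed in the training folds, weighted by
   their frequencies, feed the coherent-selection ILP with budget
   B = floor(p |S| / 100);
2. training events on unselected modified k-mers are removed; the HMM is
   class-imbalance agnostic and estimates per-k-mer moments (which
   saturate at modest support), so class balancing and
   size-normalization across p — accommodations that example-based
   neural callers require — are off by default, though both operations
   are available behind config flags;
3. a plain HMM (pooled defaults for unseen modified k-mers), the
   amortized HMM (defaults imputed by the feedforward predictor) and the
   override-all ablation are trained and evaluated on the held-out fold
   with no k-mer filtering;
4. test sites are decomposed into the sensor subset (every constituent
   modified k-mer learned in training) and the k-mer subset (the rest),
   the latter further split at the median novelty score into low- and
   high-novelty sites.

Two error metrics are reported, because "per cent modified" accuracy can
be read per read or per site: ``read_error`` is the fraction of per-read
calls disagreeing with the site label, and ``site_error`` the mean
absolute difference between the per-site called methylation fraction and
the binary label.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import panel_design, signal_sim
from .emission_amortizer import (
    AmortizerConfig,
    build_training_pairs,
    fit_amortizer,
    impute_emission_table,
    override_all_emissions,
)
from .hmm_caller import (
    EmissionTable,
    restrict_training_events,
    train_emission_table,
)
from .kmer_core import (
    LETTERS,
    K_DEFAULT,
    MethylWindow,
    decompose_window,
    unmethylated_kmer,
)

_LETTER_CODE = {c: i for i, c in enumerate(LETTERS)}

METHODS = ("hmm", "amortized", "override")
SUBSETS = ("overall", "sensor", "kmer", "low_novelty", "high_novelty")


@dataclass
class ExperimentConfig:
    """Study conditions of a p-sweep.

    Defaults describe the desk-scale synthetic study: a 42 kb reference
    carrying ~2100 well-separated CpG sites drawn from 600 recurring
    11-mer context types in two frequency tiers (~1350 unique modified
    k-mers, so the p=5 budget buys ~65 of them — the scale of real CpG
    panels), ~30x read coverage, and a pore model whose means are
    dominated by additive per-position effects with ~1-2 pA methylation
    shifts (pA-like units). ``min_events`` is low because simulated
    events carry no alignment artifacts; the support threshold exists to
    reject unstable real-data estimates.
    """

    p_grid: tuple[float, ...] = (5.0, 10.0, 30.0, 100.0)
    n_folds: int = 6
    seeds: tuple[int, ...] = (0,)
    # simulator
    reference_length: int = 42_000
    cpg_density: float = 0.05
    methylated_fraction: float = 0.5
    n_window_types: int | None = 600
    head_fraction: float = 0.05
    head_share: float = 0.45
    stratify_methylation: bool = True
    n_reads: int = 3_150
    read_length: int = 400
    additive_effect_scale: float = 4.0
    pairwise_effect_scale: float = 0.4
    residual_scale: float = 0.5
    methylation_shift_scale: float = 2.5
    noise_var_range: tuple[float, float] = (1.0, 4.0)
    label_error_rate: float = 0.0
    min_label_coverage: int = 5
    # caller
    min_events: int = 2
    balance_training: bool = False
    normalize_size: bool = False
    # amortizer (frozen across p; tuned once on k-mer-complete tables)
    amortizer: AmortizerConfig = field(default_factory=AmortizerConfig)
    methods: tuple[str, ...] = METHODS
    novelty_threshold: float | None = None  # None -> median within subset

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        for p in self.p_grid:
            if not 0 < p <= 100:
                raise ValueError(f"p values must be in (0, 100], got {p}")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


# --- protocol operations --------------------------------------------------


def make_folds(read_ids: Sequence[int], n_folds: int, seed: int) -> dict[int, int]:
    """Read-level fold assignment: a near-equal random partition.

    Splitting reads (not sites) means every site appears in both training
    and test data, observed through disjoint reads — sensor noise is new
    in the test fold even for seen k-mers.
    """
    ids = list(read_ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} reads, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    out: dict[int, int] = {}
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        for i in chunk:
            out[ids[i]] = f
    return out


def balance_classes(sites: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Downsample the majority class of a labelled site table.

    ``sites`` must have a ``state`` column with both ``methylated`` and
    ``unmethylated`` present; the larger class is randomly downsampled
    without replacement to the size of the smaller. Applied to training
    folds only — evaluation keeps the natural class mix.
    """
    rng = np.random.default_rng(seed)
    groups = {s: df for s, df in sites.groupby("state")}
    for cls in ("methylated", "unmethylated"):
        if cls not in groups or groups[cls].empty:
            raise ValueError(f"class {cls!r} absent; cannot balance")
    n = min(len(groups["methylated"]), len(groups["unmethylated"]))
    parts = []
    for cls in ("methylated", "unmethylated"):
        df = groups[cls]
        idx = rng.choice(len(df), size=n, replace=False) if len(df) > n else np.arange(len(df))
        parts.append(df.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def normalize_training_size(
    training_sets: Mapping[float, pd.DataFrame],
    reference_p: float,
    seed: int,
    key_cols: tuple[str, ...] = ("site", "read_id"),
) -> dict[float, pd.DataFrame]:
    """Downsample every p's training set to the reference (smallest) p's size.

    Size is counted in unique ``key_cols`` examples (labelled site-read
    pairs); whole examples are kept or dropped. Raises if any set is
    smaller than the reference — examples cannot be upsampled.
    """
    if reference_p not in training_sets:
        raise ValueError(f"reference p={reference_p} not among training sets")

    def n_examples(df: pd.DataFrame) -> int:
        return len(df.drop_duplicates(list(key_cols))) if len(df) else 0

    target = n_examples(training_sets[reference_p])
    rng = np.random.default_rng(seed)
    out: dict[float, pd.DataFrame] = {}
    for p, df in training_sets.items():
        n = n_examples(df)
        if n < target:
            raise ValueError(
                f"training set for p={p} has {n} examples, fewer than the "
                f"reference {target}; cannot upsample"
            )
        if n == target:
            out[p] = df
            continue
        keys = df[list(key_cols)].drop_duplicates()
        keep = keys.iloc[np.sort(rng.choice(n, size=target, replace=False))]
        out[p] = df.merge(keep, on=list(key_cols))
    return out


def split_by_seen(
    site_windows: Sequence[MethylWindow | str], training_kmers: set[str]
) -> np.ndarray:
    """Sensor mask: True where all k constituent modified k-mers were trained.

    ``training_kmers`` should be the *learned* modified k-mers of the
    restricted training run, so sensor sites provably query identical
    emission rows under plain and amortized tables.
    """
    out = np.zeros(len(site_windows), dtype=bool)
    cache: dict[str, bool] = {}
    for i, w in enumerate(site_windows):
        seq = w.seq if isinstance(w, MethylWindow) else w
        if seq not in cache:
            cache[seq] = all(s in training_kmers for s in decompose_window(seq))
        out[i] = cache[seq]
    return out


def _encode(windows: Iterable[str]) -> np.ndarray:
    return np.array([[_LETTER_CODE[c] for c in w] for w in windows], dtype=np.uint8)


def novelty_scores(
    windows: Sequence[str], training_windows: Iterable[str]
) -> np.ndarray:
    """Mean one-hot Hamming distance of each window to unique training windows."""
    unique = sorted(set(training_windows))
    if not unique or not len(windows):
        raise ValueError("windows and training windows must be non-empty")
    A = _encode(windows)  # (n, 11)
    B = _encode(unique)  # (m, 11)
    mism = (A[:, None, :] != B[None, :, :]).sum(axis=2)  # (n, m)
    return 2.0 * mism.mean(axis=1)


def split_by_novelty(
    windows: Sequence[str],
    training_windows: Iterable[str],
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split k-mer-generalization sites at a novelty threshold.

    Returns ``(low_mask, high_mask, scores)``. The default threshold is
    the median score within the split population; ties go to the
    low-novelty side (``score <= threshold``), so an all-equal population
    is entirely low-novelty.
    """
    scores = novelty_scores(windows, training_windows)
    thr = float(np.median(scores)) if threshold is None else float(threshold)
    low = scores <= thr
    return low, ~low, scores


# --- vectorized two-hypothesis evaluation ---------------------------------


def _table_lookup(em: EmissionTable, kmers: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    mus = np.empty(len(kmers))
    vars_ = np.empty(len(kmers))
    cache: dict[str, tuple[float, float]] = {}
    for i, s in enumerate(kmers):
        if s not in cache:
            cache[s] = em.params(s)
        mus[i], vars_[i] = cache[s]
    return mus, vars_


def evaluate_table(
    events: pd.DataFrame,
    site_positions: np.ndarray,
    site_windows: Sequence[str],
    em: EmissionTable,
    k: int = K_DEFAULT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-read and per-site two-hypothesis calls, aligned-event regime.

    Equivalent to :func:`amorthmm.hmm_caller.call_site` with zero
    stay/skip probability at every site, but vectorized across the event
    table: each event at a window position contributes its methylated-
    minus-unmethylated log-density difference, and a read participates in
    a site iff it covers all k window positions.

    Returns ``(per_read, per_site)``: per-read rows
    ``(site, read_id, llr, call)`` and per-site rows
    ``(site, coverage, frac_methylated)``.
    """
    n = len(site_positions)
    if n == 0:
        raise ValueError("no sites to evaluate")
    pos_matrix = np.asarray(site_positions)[:, None] + np.arange(-k + 1, 1)[None, :]
    meth_kmers: list[str] = []
    cache: dict[str, list[str]] = {}
    for w in site_windows:
        if w not in cache:
            cache[w] = decompose_window(w)
        meth_kmers.extend(cache[w])
    unmeth_kmers = [unmethylated_kmer(s) for s in meth_kmers]
    m_mu, m_var = _table_lookup(em, meth_kmers)
    u_mu, u_var = _table_lookup(em, unmeth_kmers)

    L = int(events["position"].max()) + 1
    slot = np.full(max(L, pos_matrix.max() + 1), -1, dtype=np.int64)
    slot[pos_matrix.ravel()] = np.arange(n * k)
    ev_pos = events["position"].to_numpy()
    ev_slot = slot[ev_pos]
    sel = ev_slot >= 0
    ev_slot = ev_slot[sel]
    cur = events["current"].to_numpy()[sel]

    def logpdf(mu, var):
        return -0.5 * (np.log(2 * np.pi * var) + (cur - mu) ** 2 / var)

    llr_ev = logpdf(m_mu[ev_slot], m_var[ev_slot]) - logpdf(u_mu[ev_slot], u_var[ev_slot])
    df = pd.DataFrame(
        {
            "site": ev_slot // k,
            "read_id": events["read_id"].to_numpy()[sel],
            "llr": llr_ev,
        }
    )
    g = df.groupby(["site", "read_id"], sort=False).agg(
        llr=("llr", "sum"), n_pos=("llr", "size")
    )
    per_read = g[g["n_pos"] == k].reset_index()[["site", "read_id", "llr"]]
    per_read["call"] = per_read["llr"] > 0
    per_site = (
        per_read.groupby("site")
        .agg(coverage=("call", "size"), frac_methylated=("call", "mean"))
        .reset_index()
    )
    return per_read, per_site


def error_metrics(
    per_read: pd.DataFrame,
    per_site: pd.DataFrame,
    site_state: np.ndarray,
    site_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """read/site error of a call table, optionally restricted to a site subset."""
    mask = np.ones(len(site_state), dtype=bool) if site_mask is None else site_mask
    pr = per_read[mask[per_read["site"].to_numpy()]]
    ps = per_site[mask[per_site["site"].to_numpy()]]
    out = {"n_sites": float(len(ps)), "n_reads": float(len(pr))}
    if len(pr):
        truth = site_state[pr["site"].to_numpy()]
        out["read_error"] = float((pr["call"].to_numpy() != truth).mean())
    else:
        out["read_error"] = np.nan
    if len(ps):
        truth = site_state[ps["site"].to_numpy()].astype(float)
        out["site_error"] = float(
            np.abs(ps["frac_methylated"].to_numpy() - truth).mean()
        )
    else:
        out["site_error"] = np.nan
    return out


# --- the sweep ------------------------------------------------------------


def _labeled_slots(site_positions: np.ndarray, length: int, k: int) -> np.ndarray:
    """position -> labelled-site index map over window k-mer start positions."""
    slot = np.full(length, -1, dtype=np.int64)
    for i, c in enumerate(site_positions):
        slot[c - k + 1 : c + 1] = i
    return slot


def run_p_sweep(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run the full protocol; tidy report of errors per (p, seed, fold, method, subset).

    Test folds are evaluated k-mer complete (never filtered). Within a
    seed all methods and all p share the same simulated dataset and fold
    assignment, so differences are attributable to training-data
    completeness and calling policy alone.
    """
    log = logging.getLogger(__name__)
    rows: list[dict] = []
    k = K_DEFAULT
    for seed in cfg.seeds:
        t_seed = time.perf_counter()
        master = np.random.default_rng(seed)
        sub = master.integers(0, 2**31 - 1, size=6)
        model = signal_sim.generate_pore_model(
            seed=int(sub[0]),
            additive_effect_scale=cfg.additive_effect_scale,
            pairwise_effect_scale=cfg.pairwise_effect_scale,
            residual_scale=cfg.residual_scale,
            methylation_shift_scale=cfg.methylation_shift_scale,
            noise_var_range=cfg.noise_var_range,
        )
        ref = signal_sim.generate_reference(
            seed=int(sub[1]),
            length=cfg.reference_length,
            cpg_density=cfg.cpg_density,
            methylated_fraction=cfg.methylated_fraction,
            n_window_types=cfg.n_window_types,
            head_fraction=cfg.head_fraction,
            head_share=cfg.head_share,
            stratify_methylation=cfg.stratify_methylation,
        )
        events = signal_sim.simulate_events(
            ref, model, cfg.n_reads, cfg.read_length, seed=int(sub[2])
        )
        raw_calls = signal_sim.per_read_site_calls(
            ref, events, cfg.label_error_rate, seed=int(sub[3])
        )
        labels = signal_sim.filter_confident_sites(raw_calls, cfg.min_label_coverage)
        confident = labels[labels["state"] != "ambiguous"].reset_index(drop=True)
        if confident.empty:
            raise RuntimeError("no confident sites; increase coverage")
        site_pos = confident["position"].to_numpy()
        site_state = (confident["state"] == "methylated").to_numpy()
        win_by_pos = dict(zip(ref.cpg_sites.tolist(), ref.site_windows))
        site_windows = [win_by_pos[int(p)] for p in site_pos]
        needed = sorted(
            {s for w in set(site_windows) for s in decompose_window(w)}
            | {unmethylated_kmer(s) for w in set(site_windows) for s in decompose_window(w)}
        )
        slot_by_pos = _labeled_slots(site_pos, ref.length, k)
        # events in the window of ANY CpG site (ambiguous ones included)
        # are excluded from background training data
        site_region = _labeled_slots(ref.cpg_sites, ref.length, k) >= 0

        log.info(
            "seed %d: simulated %d events over %d confident sites in %.1fs",
            seed, len(events), len(site_pos), time.perf_counter() - t_seed,
        )
        folds = make_folds(range(cfg.n_reads), cfg.n_folds, int(sub[4]))
        fold_of = np.array([folds[i] for i in range(cfg.n_reads)])
        fold_rng = np.random.default_rng(int(sub[5]))

        for fold in range(cfg.n_folds):
            test_mask = fold_of[events["read_id"].to_numpy()] == fold
            train_ev = events[~test_mask]
            test_ev = events[test_mask]

            # window frequencies observed in the labelled training data
            meth_mask = site_state
            counts = pd.Series(
                [site_windows[i] for i in np.flatnonzero(meth_mask)]
            ).value_counts()
            wwc = list(counts.items())

            # build every p's labelled training set, then size-normalize
            labeled_sets: dict[float, pd.DataFrame] = {}
            ev_site = slot_by_pos[train_ev["position"].to_numpy()]
            for p in cfg.p_grid:
                prob = panel_design.build_selection_problem(wwc, p)
                sel = panel_design.solve_selection_ilp(prob)
                selected_windows = set(sel.selected_windows)
                kept_meth = np.array(
                    [
                        meth_mask[i] and site_windows[i] in selected_windows
                        for i in range(len(site_pos))
                    ]
                )
                if not kept_meth.any():
                    raise RuntimeError(
                        f"p={p}: no methylated site survives selection; "
                        "budget below one coherent window"
                    )
                if cfg.balance_training:
                    site_frame = pd.DataFrame(
                        {
                            "site": np.arange(len(site_pos)),
                            "state": np.where(
                                site_state, "methylated", "unmethylated"
                            ),
                        }
                    )
                    site_frame = site_frame[kept_meth | ~site_state]
                    balanced = balance_classes(
                        site_frame, seed=int(fold_rng.integers(2**31 - 1))
                    )
                    kept_sites = np.zeros(len(site_pos), dtype=bool)
                    kept_sites[balanced["site"].to_numpy()] = True
                else:
                    kept_sites = kept_meth | ~site_state

                lab = train_ev[(ev_site >= 0) & kept_sites[np.clip(ev_site, 0, None)]]
                lab = lab.assign(site=slot_by_pos[lab["position"].to_numpy()])
                lab = restrict_training_events(lab, sel.selected_kmers)
                labeled_sets[p] = lab

            if cfg.normalize_size:
                labeled_sets = normalize_training_size(
                    labeled_sets, min(cfg.p_grid), seed=int(fold_rng.integers(2**31 - 1))
                )

            bg_ev = train_ev[~site_region[train_ev["position"].to_numpy()]]
            for p in cfg.p_grid:
                t_p = time.perf_counter()
                train_events = pd.concat(
                    [bg_ev, labeled_sets[p].drop(columns="site")], ignore_index=True
                )
                table = train_emission_table(train_events, min_events=cfg.min_events)
                plain = table.ensure_complete(needed)
                pairs = build_training_pairs(table)
                acfg = replace(
                    cfg.amortizer, seed=int(fold_rng.integers(2**31 - 1))
                )
                predictor = fit_amortizer(pairs, acfg)
                tables = {"hmm": plain}
                if "amortized" in cfg.methods:
                    tables["amortized"] = impute_emission_table(
                        table, predictor
                    ).ensure_complete(needed)
                if "override" in cfg.methods:
                    tables["override"] = override_all_emissions(
                        table, predictor
                    ).ensure_complete(needed)

                learned = table.learned_modified_kmers()
                sensor = split_by_seen(site_windows, learned)
                masks: dict[str, np.ndarray | None] = {
                    "overall": None,
                    "sensor": sensor,
                    "kmer": ~sensor,
                }
                if (~sensor).any() and learned:
                    train_windows = {
                        site_windows[i]
                        for i in np.flatnonzero(site_state)
                        if all(s in learned for s in decompose_window(site_windows[i]))
                    }
                    if train_windows:
                        kmer_idx = np.flatnonzero(~sensor)
                        low, high, _ = split_by_novelty(
                            [site_windows[i] for i in kmer_idx],
                            train_windows,
                            cfg.novelty_threshold,
                        )
                        lo = np.zeros(len(site_pos), dtype=bool)
                        hi = np.zeros(len(site_pos), dtype=bool)
                        lo[kmer_idx[low]] = True
                        hi[kmer_idx[high]] = True
                        masks["low_novelty"] = lo
                        masks["high_novelty"] = hi

                log.info(
                    "seed %d fold %d p=%g: trained %d learned modified k-mers "
                    "in %.1fs", seed, fold, p, len(learned),
                    time.perf_counter() - t_p,
                )
                for method in cfg.methods:
                    per_read, per_site = evaluate_table(
                        test_ev, site_pos, site_windows, tables[method]
                    )
                    for subset, mask in masks.items():
                        m = error_metrics(per_read, per_site, site_state, mask)
                        for metric in ("read_error", "site_error"):
                            rows.append(
                                {
                                    "p": p,
                                    "seed": seed,
                                    "fold": fold,
                                    "method": method,
                                    "subset": subset,
                                    "metric": metric,
                                    "value": m[metric],
                                    "n": int(m["n_sites"]),
                                }
                            )
    return pd.DataFrame(rows)


def summarize_report(report: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- s.d. across folds and seeds per (p, method, subset, metric)."""
    return (
        report.groupby(["p", "method", "subset", "metric"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
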