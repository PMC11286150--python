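"""Gaussian-emission HMM methylation calling from aligned events.

Each (possibly modified) 6-mer state carries an independent Gaussian
emission over observed current. Training is moment estimation per k-mer
from labelled aligned events; k-mers with insufficient support fall back
to a pooled default distribution (and are exactly the rows the amortizer
later imputes). Site calling compares two hypotheses per read — the
methylated k-mer path of the site's 11-mer window versus its M->C
substituted unmethylated path — by forward-algorithm log-likelihood with
stay/step/skip transitions, and sums log-likelihood ratios over reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .kmer_core import decompose_window, is_modified, unmethylated_kmer, MethylWindow

#: Variance floor keeping log-densities finite for degenerate event lists.
VARIANCE_FLOOR = 1e-6

#: Default minimum event support for a learned emission row.
DEFAULT_MIN_EVENTS = 5

Provenance = str  # "learned" | "imputed" | "default"


class GaussianParams(NamedTuple):
    """Mean and (strictly positive) variance of a current distribution."""

    mu: float
    var: float


@dataclass
class TransitionParams:
    """Stay/step/skip probabilities of the event-to-state alignment.

    Aligned event tables have one event per position, i.e. the degenerate
    regime ``p_stay = p_skip = 0``; nonzero values model segmentation
    artifacts (split events and missed states).
    """

    p_stay: float = 0.0
    p_skip: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.p_stay <= 1 and 0 <= self.p_skip <= 1):
            raise ValueError("transition probabilities must be in [0, 1]")
        if self.p_step <= 0:
            raise ValueError("p_step = 1 - p_stay - p_skip must be positive")

    @property
    def p_step(self) -> float:
        return 1.0 - self.p_stay - self.p_skip


@dataclass
class SiteCall:
    """Two-hypothesis call at one CpG site.

    ``llr`` is the methylated-minus-unmethylated log-likelihood ratio
    summed over covering reads; the site is called methylated iff it is
    positive. ``read_llrs`` keeps the per-read components for frequency
    estimation.
    """

    position: int
    llr: float
    call: bool
    read_llrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.llr):
            raise ValueError("site llr must be finite")
        if self.call != (self.llr > 0):
            raise ValueError("call inconsistent with llr sign")

    @property
    def coverage(self) -> int:
        return len(self.read_llrs)

    @property
    def methylated_fraction(self) -> float:
        """Fraction of covering reads individually calling methylated."""
        if not self.read_llrs:
            return float(self.call)
        return float(np.mean([v > 0 for v in self.read_llrs.values()]))


class EmissionTable:
    """k-mer -> Gaussian emission parameters with provenance tracking."""

    def __init__(
        self,
        entries: Mapping[str, tuple[GaussianParams, Provenance]] | None = None,
        min_events: int = DEFAULT_MIN_EVENTS,
        default_params: GaussianParams | None = None,
    ):
        self._entries: dict[str, tuple[GaussianParams, Provenance]] = {}
        self.min_events = min_events
        self.default_params = default_params
        if entries:
            for kmer, (params, prov) in entries.items():
                self.set(kmer, params, prov)

    def set(self, kmer: str, params: GaussianParams, provenance: Provenance) -> None:
        params = GaussianParams(float(params[0]), float(params[1]))
        if params.var <= 0 or not all(map(math.isfinite, params)):
            raise ValueError(f"invalid emission parameters for {kmer}: {params}")
        if provenance not in ("learned", "imputed", "default"):
            raise ValueError(f"unknown provenance {provenance!r}")
        self._entries[kmer] = (params, provenance)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def params(self, kmer: str) -> GaussianParams:
        try:
            return self._entries[kmer][0]
        except KeyError:
            raise KeyError(
                f"no emission distribution for k-mer {kmer!r}; "
                "complete the table (ensure_complete) or impute first"
            ) from None

    def provenance(self, kmer: str) -> Provenance:
        return self._entries[kmer][1]

    def kmers(self) -> list[str]:
        return sorted(self._entries)

    def learned_modified_kmers(self) -> set[str]:
        """Modified k-mers whose parameters were estimated from events."""
        return {
            s
            for s, (_, prov) in self._entries.items()
            if prov == "learned" and is_modified(s)
        }

    def copy(self) -> "EmissionTable":
        return EmissionTable(
            dict(self._entries), self.min_events, self.default_params
        )

    def ensure_complete(self, kmers: Iterable[str]) -> "EmissionTable":
        """Copy with pooled-default rows added for any missing k-mer."""
        out = self.copy()
        for s in kmers:
            if s not in out:
                if self.default_params is None:
                    raise ValueError("no default parameters available")
                out.set(s, self.default_params, "default")
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self._entries.items())
        return pd.DataFrame(
            {
                "kmer": [s for s, _ in rows],
                "level_mean": [v[0].mu for _, v in rows],
                "level_var": [v[0].var for _, v in rows],
                "provenance": [v[1] for _, v in rows],
            }
        )


def _kmer_mask(events: pd.DataFrame, pred: Callable[[str], bool]) -> np.ndarray:
    """Vectorized per-event mask from a per-k-mer predicate."""
    col = events["kmer"]
    if isinstance(col.dtype, pd.CategoricalDtype):
        per_cat = np.array([pred(s) for s in col.cat.categories], dtype=bool)
        codes = col.cat.codes.to_numpy()
        out = np.zeros(len(col), dtype=bool)
        ok = codes >= 0
        out[ok] = per_cat[codes[ok]]
        return out
    return col.map(pred).to_numpy(dtype=bool)


def restrict_training_events(
    events: pd.DataFrame, allowed_kmers: set[str]
) -> pd.DataFrame:
    """Drop events on modified k-mers outside the selected panel.

    Events on unmodified k-mers pass through untouched; an M-containing
    event survives only if its k-mer is in ``allowed_kmers``. This is how
    k-mer-incomplete training data are realized: excluded modified k-mers
    must never receive learned emission parameters.
    """
    keep = _kmer_mask(
        events, lambda s: (not is_modified(s)) or s in allowed_kmers
    )
    return events[keep]


def train_emission_table(
    events: pd.DataFrame,
    min_events: int = DEFAULT_MIN_EVENTS,
    variance_floor: float = VARIANCE_FLOOR,
    n_iterations: int = 5,
) -> EmissionTable:
    """Estimate per-k-mer Gaussian emissions from aligned events.

    For every k-mer with at least ``min_events`` events: mu = sample mean,
    sigma^2 = maximum-likelihood sample variance floored at
    ``variance_floor`` (provenance ``learned``). Under-supported k-mers
    get the pooled default — the mixture mean/variance over all learned
    modified k-mers (falling back to all learned k-mers) — with
    provenance ``default``. ``n_iterations`` exists for interface parity
    with alternating alignment/update training; with fixed alignments
    every pass recomputes the same moments, so one pass is performed.
    """
    if events.empty:
        raise ValueError("cannot train an emission table from an empty event set")
    # Alternating alignment/update training degenerates to a single moment
    # pass when alignments are fixed, as they are for aligned event tables:
    # re-running the update on unchanged alignments is idempotent, so the
    # n_iterations knob (kept for interface parity with re-aligning
    # trainers) does not alter the result here.
    del n_iterations
    grouper = events.groupby("kmer", observed=True)
    stats = grouper["current"].agg(count="count", mean="mean")
    sq = events["current"] ** 2
    stats["m2"] = sq.groupby(events["kmer"], observed=True).mean()
    stats["var"] = np.maximum(stats["m2"] - stats["mean"] ** 2, variance_floor)
    learned = stats[stats["count"] >= min_events]

    table = EmissionTable(min_events=min_events)
    for kmer, row in learned.iterrows():
        table.set(str(kmer), GaussianParams(row["mean"], row["var"]), "learned")

    pool = learned[[is_modified(str(s)) for s in learned.index]]
    if pool.empty:
        pool = learned
    if pool.empty:
        raise ValueError(
            f"no k-mer reaches min_events={min_events}; lower the threshold"
        )
    pooled_mu = float(pool["mean"].mean())
    pooled_var = float(
        max(
            (pool["var"] + pool["mean"] ** 2).mean() - pooled_mu**2,
            variance_floor,
        )
    )
    table.default_params = GaussianParams(pooled_mu, pooled_var)
    for kmer in stats.index[stats["count"] < min_events]:
        table.set(str(kmer), table.default_params, "default")
    return table


# --- likelihoods ---------------------------------------------------------


def _log_normal_pdf(x: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)


def _path_params(
    kmer_path: Sequence[str], em: EmissionTable
) -> tuple[np.ndarray, np.ndarray]:
    mus, vars_ = [], []
    for s in kmer_path:
        p = em.params(s)  # raises KeyError naming the k-mer
        mus.append(p.mu)
        vars_.append(p.var)
    return np.array(mus), np.array(vars_)


def event_sequence_loglik(
    events: Sequence[float],
    kmer_path: Sequence[str],
    em: EmissionTable,
    tr: TransitionParams = TransitionParams(),
) -> float:
    """Forward-algorithm log-likelihood of currents given a k-mer path.

    Hidden states are positions along the path; each event is emitted from
    its state's Gaussian, and the state advances by 0 (stay), 1 (step) or
    2 (skip) between events. The walk starts on the first k-mer and must
    end on the last, so with ``p_stay = p_skip = 0`` the result is the
    factorized sum of per-event log-densities when lengths match, and
    ``-inf`` otherwise.
    """
    x = np.asarray(events, dtype=float)
    if x.size == 0 or len(kmer_path) == 0:
        raise ValueError("events and kmer_path must be non-empty")
    mus, vars_ = _path_params(kmer_path, em)
    N, T = len(kmer_path), x.size
    with np.errstate(divide="ignore"):
        log_tr = np.log([tr.p_stay, tr.p_step, tr.p_skip])
    emit = _log_normal_pdf(x[:, None], mus[None, :], vars_[None, :])  # (T, N)
    alpha = np.full(N, -np.inf)
    alpha[0] = emit[0, 0]
    for t in range(1, T):
        stay = alpha + log_tr[0]
        step = np.full(N, -np.inf)
        step[1:] = alpha[:-1] + log_tr[1]
        skip = np.full(N, -np.inf)
        if N > 2:
            skip[2:] = alpha[:-2] + log_tr[2]
        with np.errstate(invalid="ignore"):
            alpha = logsumexp(np.stack([stay, step, skip]), axis=0) + emit[t]
    return float(alpha[-1])


def enumerate_path_loglik(
    events: Sequence[float],
    kmer_path: Sequence[str],
    em: EmissionTable,
    tr: TransitionParams = TransitionParams(),
) -> float:
    """Exhaustive-alignment reference for :func:`event_sequence_loglik`.

    Sums the probability of every stay/step/skip state sequence that
    starts on the first k-mer and ends on the last (3^(T-1) paths); for
    validation on short instances only.
    """
    x = np.asarray(events, dtype=float)
    mus, vars_ = _path_params(kmer_path, em)
    N, T = len(kmer_path), x.size
    with np.errstate(divide="ignore"):
        log_tr = {0: np.log(tr.p_stay), 1: np.log(tr.p_step), 2: np.log(tr.p_skip)}
    terms: list[float] = []

    def recurse(t: int, j: int, acc: float) -> None:
        acc = acc + _log_normal_pdf(x[t], mus[j], vars_[j])
        if t == T - 1:
            if j == N - 1:
                terms.append(acc)
            return
        for inc in (0, 1, 2):
            if j + inc < N and np.isfinite(log_tr[inc]):
                recurse(t + 1, j + inc, acc + log_tr[inc])

    recurse(0, 0, 0.0)
    return float(logsumexp(terms)) if terms else -np.inf


def call_site(
    events_by_read: pd.DataFrame | Mapping[int, pd.DataFrame],
    site: int,
    window: MethylWindow | str,
    em: EmissionTable,
    tr: TransitionParams = TransitionParams(),
    k: int | None = None,
) -> SiteCall:
    """Call one CpG site from all reads covering its full window.

    For each read with events at every one of the k k-mer start positions
    ``site-k+1 .. site``, the per-read llr is the forward log-likelihood
    under the methylated path (the window's decomposition) minus that
    under the unmethylated path (M -> C). The site llr is the sum over
    reads; raises if no read covers the window.
    """
    if isinstance(window, str):
        window = MethylWindow(window)
    k = window.k if k is None else k
    meth_path = decompose_window(window)
    unmeth_path = [unmethylated_kmer(s) for s in meth_path]
    positions = range(site - k + 1, site + 1)

    if isinstance(events_by_read, pd.DataFrame):
        sub = events_by_read[events_by_read["position"].isin(list(positions))]
        groups: Iterable[tuple[int, pd.DataFrame]] = sub.groupby("read_id", observed=True)
    else:
        groups = events_by_read.items()

    read_llrs: dict[int, float] = {}
    for read_id, df in groups:
        df = df[df["position"].isin(list(positions))].sort_values("position")
        if df["position"].nunique() < k:
            continue  # read does not cover the full window
        currents = df["current"].to_numpy()
        llr = event_sequence_loglik(currents, meth_path, em, tr) - \
            event_sequence_loglik(currents, unmeth_path, em, tr)
        read_llrs[read_id] = float(llr)
    if not read_llrs:
        raise ValueError(f"no read covers the full window of site {site}")
    total = float(sum(read_llrs.values()))
    return SiteCall(position=site, llr=total, call=total > 0, read_llrs=read_llrs)


def methylation_frequency(calls: Iterable[SiteCall]) -> pd.Series:
    """Per-site fraction of reads individually calling methylated."""
    data = {c.position: c.methylated_fraction for c in calls}
    return pd.Series(data, name="methylated_fraction").sort_index()
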