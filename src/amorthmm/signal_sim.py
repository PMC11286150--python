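"""Synthetic nanopore current data with known methylation ground truth.

Real training data for 5mC callers consist of aligned event tables (one
mean current observation per read and reference position, labelled with
the 6-mer occupying the pore) together with bisulfite-derived per-site
methylation labels. This module generates data with the same statistical
structure:

* a ground-truth pore model whose per-k-mer current means decompose into
  additive per-position letter effects + adjacent-pair effects + an i.i.d.
  residual. The additive and pairwise terms are exactly linear in the
  141-bit k-mer featurization, so emission parameters are partially
  predictable from sequence — the property amortization exploits — while
  the residual bounds what any sequence-based predictor can achieve;
* a reference sequence in which CpG sites are planted far enough apart
  that each methylated site owns a single-M 11-mer window, and whose
  11-mer contexts are drawn from a limited, frequency-skewed vocabulary —
  mirroring real genomes, where a few thousand unique modified k-mers
  recur across millions of CpG sites;
* reads with uniform random starts (approximately Poisson site coverage)
  emitting one Gaussian event per covered position, with M substituted
  into k-mers overlapping methylated sites;
* the confident-label filter: a site is usable for training or evaluation
  only if covered by at least five reads, all agreeing on its state.

Currents are in pA-like units; positions are 0-based, forward strand only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kmer_core import DNA5, K_DEFAULT, Alphabet, MethylWindow, enumerate_kmers

#: Default confident-label coverage threshold.
MIN_LABEL_COVERAGE = 5

_ACGT = np.array(list("ACGT"))


@dataclass
class GroundTruthPoreModel:
    """Complete per-k-mer Gaussian current model (the simulator's truth)."""

    table: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for kmer, (_, var) in self.table.items():
            if var <= 0:
                raise ValueError(f"non-positive variance for {kmer}")

    def mean(self, kmer: str) -> float:
        return self.table[kmer][0]

    def var(self, kmer: str) -> float:
        return self.table[kmer][1]

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.table

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.table.items())
        return pd.DataFrame(
            {
                "kmer": [k for k, _ in rows],
                "level_mean": [v[0] for _, v in rows],
                "level_var": [v[1] for _, v in rows],
            }
        )


def generate_pore_model(
    seed: int,
    additive_effect_scale: float = 4.0,
    pairwise_effect_scale: float = 0.4,
    residual_scale: float = 0.5,
    noise_var_range: tuple[float, float] = (1.0, 6.25),
    methylation_shift_scale: float = 1.5,
    baseline: float = 90.0,
    methylation_effect_fraction: float = 1.0,
    alphabet: Alphabet = DNA5,
) -> GroundTruthPoreModel:
    """Draw a ground-truth pore model over all CpG-context k-mers.

    The unmodified backbone is additive + pairwise + residual:
    ``mean(s) = baseline + sum_i a[i, s_i] + sum_i b[i, s_i s_{i+1}] + eps_s``
    with ``a ~ N(0, additive_effect_scale^2)`` per (position, ACGT
    letter), ``b ~ N(0, pairwise_effect_scale^2)`` per (position, ordered
    ACGT pair) and ``eps_s ~ N(0, residual_scale^2)`` i.i.d. per k-mer.
    M is a modified cytosine, so its effect is anchored to C rather than
    drawn like a fifth independent letter: an M at position i contributes
    the C effect plus a context-dependent shift ``delta[i, prev] ~ N(0,
    methylation_shift_scale^2)`` indexed by pore position and the
    preceding base (pairwise terms reuse the C-pair effects), plus the
    k-mer's own residual. Methylation therefore perturbs the current by
    ~1-2 pA against a 1-2 pA event noise floor (variances are drawn
    uniformly from ``noise_var_range``; equal endpoints give a
    deterministic, learnable variance), while letter swaps move it by
    several pA — the regime of real 5mC pore tables.

    The construction keeps means exactly linear in the 141-bit
    featurization when ``residual_scale == 0`` (the M coefficients are
    simply C coefficients plus the shifts), which bounds achievable
    imputation accuracy by the residual alone.

    ``methylation_effect_fraction`` is the fraction of M-containing
    k-mers whose mean may differ from the unmethylated counterpart; the
    remainder are copied from the C-version (current-invisible
    methylation contexts). Defaults are pA-like: R9.4-style tables span
    roughly 60-130 pA.
    """
    scales = (
        additive_effect_scale,
        pairwise_effect_scale,
        residual_scale,
        methylation_shift_scale,
    )
    if min(scales) < 0:
        raise ValueError("effect scales must be non-negative")
    lo, hi = noise_var_range
    if lo <= 0 or hi < lo:
        raise ValueError("noise_var_range must be positive with lo <= hi")
    if not 0 <= methylation_effect_fraction <= 1:
        raise ValueError("methylation_effect_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k = alphabet.k
    acgt = ["A", "C", "G", "T"]
    additive = {
        (i, c): rng.normal(0.0, additive_effect_scale) if additive_effect_scale else 0.0
        for i in range(k)
        for c in acgt
    }
    pairwise = {
        (i, a + b): rng.normal(0.0, pairwise_effect_scale) if pairwise_effect_scale else 0.0
        for i in range(k - 1)
        for a in acgt
        for b in acgt
    }
    # 5mC shift per (pore position, preceding base); "^" marks M at the
    # first position, whose left neighbour lies outside the k-mer
    shift = {
        (i, prev): rng.normal(0.0, methylation_shift_scale) if methylation_shift_scale else 0.0
        for i in range(k)
        for prev in (acgt if i > 0 else ["^"])
    }
    kmers = sorted(enumerate_kmers(alphabet, cpg_only=True))
    table: dict[str, tuple[float, float]] = {}
    for kmer in kmers:
        c_version = kmer.replace("M", "C")
        mu = baseline
        mu += sum(additive[(i, c)] for i, c in enumerate(c_version))
        mu += sum(pairwise[(i, c_version[i : i + 2])] for i in range(k - 1))
        mu += sum(
            shift[(i, c_version[i - 1] if i > 0 else "^")]
            for i, c in enumerate(kmer)
            if c == "M"
        )
        mu += rng.normal(0.0, residual_scale) if residual_scale > 0 else 0.0
        var = float(rng.uniform(lo, hi))
        table[kmer] = (float(mu), var)
    if methylation_effect_fraction < 1.0:
        for kmer in kmers:
            if "M" in kmer and rng.random() > methylation_effect_fraction:
                c_version = kmer.replace("M", "C")
                if c_version in table:
                    table[kmer] = (table[c_version][0], table[kmer][1])
    return GroundTruthPoreModel(table)


@dataclass
class SyntheticReference:
    """A reference sequence with planted CpG sites of known state.

    ``cpg_sites[i]`` is the 0-based position of the C of the i-th CG
    dinucleotide; ``methylation_state[i]`` its (site-level, read-shared)
    state; ``site_windows[i]`` the methylated-form 11-mer context centred
    on the site (with M at the centre whether or not the site is actually
    methylated — it is the window of the methylated *hypothesis*).
    """

    seq: str
    cpg_sites: np.ndarray
    methylation_state: np.ndarray
    site_windows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cpg_sites = np.asarray(self.cpg_sites, dtype=np.int64)
        self.methylation_state = np.asarray(self.methylation_state, dtype=bool)
        for s in self.cpg_sites:
            if self.seq[s : s + 2] != "CG":
                raise ValueError(f"flagged site {s} is not a CG dinucleotide")
        if len(self.cpg_sites) != len(self.methylation_state):
            raise ValueError("site and state arrays must align")

    @property
    def length(self) -> int:
        return len(self.seq)

    def methylated_sequence(self) -> str:
        """Reference with M substituted at every methylated CpG's C."""
        chars = list(self.seq)
        for s in self.cpg_sites[self.methylation_state]:
            chars[s] = "M"
        return "".join(chars)


def _random_window_vocabulary(rng: np.random.Generator, n: int, k: int) -> list[str]:
    """Distinct methylated 11-mer contexts safe to embed in a CG-free background.

    Flanks avoid internal CG (no unplanned CpG sites), the left flank does
    not start with G (no CG across the upstream junction) and the right
    flank does not end with C (no CG across the downstream junction).
    """
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        left = "".join(rng.choice(_ACGT, size=k - 1))
        right = "".join(rng.choice(_ACGT, size=k - 2))
        w = left + "MG" + right
        if "CG" in left or "CG" in right or left[0] == "G" or right[-1] == "C":
            continue
        if w in seen:
            continue
        MethylWindow(w, k=k)  # asserts validity
        seen.add(w)
        out.append(w)
    return out


def generate_reference(
    seed: int,
    length: int,
    cpg_density: float = 0.05,
    methylated_fraction: float = 0.5,
    n_window_types: int | None = 600,
    head_fraction: float = 0.05,
    head_share: float = 0.45,
    stratify_methylation: bool = True,
    k: int = K_DEFAULT,
) -> SyntheticReference:
    """Generate a reference with well-separated CpG sites.

    ``round(length * cpg_density)`` CG dinucleotides are planted, each
    the centre of an 11-mer window drawn from a vocabulary of
    ``n_window_types`` distinct context types (``None`` draws a fresh
    context per site, all frequencies equal). Real methylomes observe a
    few thousand unique modified k-mers recurring across millions of
    sites with heavy-tailed frequencies; here that spectrum is
    approximated by two frequency tiers: a head of
    ``head_fraction * n_window_types`` common types sharing
    ``head_share`` of all sites, and a uniform tail holding the rest —
    so even the rarest context recurs at several sites, as every
    observed k-mer does in genome-scale data.

    Windows do not overlap and the background contains no CG, so
    consecutive CpG sites are always more than k bases apart and every
    methylated site owns a valid single-M window. Each site is
    methylated with probability ``methylated_fraction``; with
    ``stratify_methylation`` the fraction is applied within each context
    type (a balanced design guaranteeing that every type is attested in
    both states wherever counts permit), otherwise states are i.i.d.

    Raises ``ValueError`` when the requested density cannot satisfy the
    spacing constraint.
    """
    if not 0 <= cpg_density <= 1 or not 0 <= methylated_fraction <= 1:
        raise ValueError("cpg_density and methylated_fraction must be in [0, 1]")
    if not 0 < head_fraction <= 1 or not 0 <= head_share <= 1:
        raise ValueError("head_fraction in (0,1], head_share in [0,1] required")
    rng = np.random.default_rng(seed)
    wlen = 2 * k - 1
    n_sites = int(round(length * cpg_density))
    min_len = n_sites * wlen + (n_sites + 1)
    if length < min_len:
        raise ValueError(
            f"length {length} cannot host {n_sites} non-overlapping {wlen}-mer "
            f"windows with gaps (need >= {min_len}); lower cpg_density"
        )
    n_types = n_sites if n_window_types is None else int(n_window_types)
    if n_sites > 0 and n_types < 1:
        raise ValueError("n_window_types must be >= 1")
    if n_types > n_sites:
        n_types = max(n_sites, 1)
    vocab = _random_window_vocabulary(rng, n_types, k) if n_sites else []
    if n_sites:
        if n_window_types is None:
            counts = np.ones(n_types, dtype=int)
        else:
            n_head = max(1, int(round(head_fraction * n_types)))
            n_head = min(n_head, n_types)
            head_total = int(round(head_share * n_sites)) if n_head < n_types else n_sites
            head_total = max(head_total, n_head)
            # cap the vocabulary so every tail type receives >= 1 site
            n_types = min(n_types, n_head + max(n_sites - head_total, 0))
            vocab = vocab[:n_types]
            counts = np.zeros(n_types, dtype=int)
            counts[:n_head] = head_total // n_head
            counts[: head_total % n_head] += 1
            tail = n_types - n_head
            if tail:
                rest = n_sites - counts.sum()
                counts[n_head:] = rest // tail
                counts[n_head : n_head + rest % tail] += 1
            assert counts.min() >= 1 and counts.sum() == n_sites
        site_types = rng.permutation(np.repeat(np.arange(n_types), counts))
    else:
        site_types = np.array([], dtype=int)

    # distribute the non-window sequence into n_sites + 1 gaps of length >= 1
    slack = length - n_sites * wlen - (n_sites + 1)
    extra = rng.multinomial(slack, np.full(n_sites + 1, 1.0 / (n_sites + 1)))
    gaps = 1 + extra

    def bg(n: int, prev: str) -> str:
        chars = []
        for _ in range(n):
            opts = "ACT" if prev == "C" else "ACGT"
            prev = opts[rng.integers(len(opts))]
            chars.append(prev)
        return "".join(chars)

    pieces: list[str] = []
    cpg_sites: list[int] = []
    windows: list[str] = []
    pos = 0
    prev = ""
    for i in range(n_sites):
        g = bg(int(gaps[i]), prev)
        pieces.append(g)
        pos += len(g)
        w = vocab[site_types[i]]
        pieces.append(w.replace("M", "C"))
        windows.append(w)
        cpg_sites.append(pos + k - 1)
        pos += wlen
        prev = w[-1]
    pieces.append(bg(int(gaps[-1]), prev))
    seq = "".join(pieces)
    assert len(seq) == length
    if stratify_methylation and n_sites:
        state = np.zeros(n_sites, dtype=bool)
        for t in range(n_types):
            idx = np.flatnonzero(site_types == t)
            n_meth = int(np.floor(methylated_fraction * len(idx) + 0.5))
            state[rng.choice(idx, size=n_meth, replace=False)] = True
    else:
        state = rng.random(n_sites) < methylated_fraction
    ref = SyntheticReference(
        seq=seq,
        cpg_sites=np.array(cpg_sites, dtype=np.int64),
        methylation_state=state,
        site_windows=windows,
    )
    # paranoia: planted sites are the only CG dinucleotides
    assert seq.count("CG") == n_sites
    return ref


def simulate_events(
    ref: SyntheticReference,
    model: GroundTruthPoreModel,
    n_reads: int,
    read_length: int = 400,
    seed: int = 0,
    k: int = K_DEFAULT,
) -> pd.DataFrame:
    """Aligned event table: one Gaussian current per read and covered position.

    Reads are contiguous ``read_length``-base fragments with uniform
    random starts on a circularized reference (fragments may wrap; the
    few wrap-spanning k-mer positions are dropped), so per-site coverage
    is approximately Poisson with mean ``n_reads * read_length /
    len(ref)`` uniformly along the sequence, without the coverage ramp a
    linear fragment model produces at the ends. A read starting at ``a``
    emits events at k-mer start positions ``a .. a+read_length-k``; the
    k-mer is the methylated-reference substring (M substituted at
    methylated CpGs) and the current is drawn from the model's Gaussian
    for that k-mer.

    Returns a DataFrame with columns ``read_id, position, kmer, current``
    (``kmer`` categorical). Raises ``ValueError`` naming the k-mer if the
    reference induces one absent from the model.
    """
    L = ref.length
    if read_length < k or read_length > L:
        raise ValueError("read_length must be in [k, reference length]")
    rng = np.random.default_rng(seed)
    mseq = ref.methylated_sequence()
    kmer_by_pos = [mseq[i : i + k] for i in range(L - k + 1)]
    cats = sorted(set(kmer_by_pos))
    missing = [s for s in cats if s not in model]
    if missing:
        raise ValueError(f"k-mers missing from pore model: {missing[:5]} ...")
    cat_idx = {s: i for i, s in enumerate(cats)}
    code_by_pos = np.array([cat_idx[s] for s in kmer_by_pos], dtype=np.int32)
    mean_by_pos = np.array([model.mean(s) for s in kmer_by_pos])
    sd_by_pos = np.sqrt([model.var(s) for s in kmer_by_pos])

    nper = read_length - k + 1
    starts = rng.integers(0, L, size=n_reads)
    pos = (np.repeat(starts, nper) + np.tile(np.arange(nper), n_reads)) % L
    read_ids = np.repeat(np.arange(n_reads, dtype=np.int32), nper)
    keep = pos <= L - k  # k-mers spanning the circular junction are dropped
    pos, read_ids = pos[keep], read_ids[keep]
    currents = rng.normal(mean_by_pos[pos], sd_by_pos[pos])
    return pd.DataFrame(
        {
            "read_id": read_ids,
            "position": pos.astype(np.int32),
            "kmer": pd.Categorical.from_codes(code_by_pos[pos], categories=cats),
            "current": currents,
        }
    )


def sample_event_sequence(
    kmer_path: list[str],
    model: GroundTruthPoreModel,
    p_stay: float = 0.0,
    p_skip: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Currents from walking a k-mer path with stay/step/skip dynamics.

    Exercises the segmentation-noise regime of the forward algorithm: at
    each step the pore re-emits the same k-mer (stay), advances one
    (step), or advances two (skip). The walk starts at the first k-mer and
    ends once it has emitted from the last one.
    """
    rng = np.random.default_rng(seed)
    p_step = 1.0 - p_stay - p_skip
    if min(p_stay, p_skip) < 0 or p_step <= 0:
        raise ValueError("require p_stay, p_skip >= 0 and p_stay + p_skip < 1")
    out: list[float] = []
    j, N = 0, len(kmer_path)
    while True:
        out.append(rng.normal(model.mean(kmer_path[j]), np.sqrt(model.var(kmer_path[j]))))
        if j >= N - 1:
            break
        j = min(j + rng.choice([0, 1, 2], p=[p_stay, p_step, p_skip]), N - 1)
    return np.array(out)


def per_read_site_calls(
    ref: SyntheticReference,
    events: pd.DataFrame,
    error_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-read binary methylation calls at every covered CpG site.

    Emulates the per-read labelling that a ground-truth assay provides: a
    read calls a site iff it has an event at the site's position, the call
    being the true state flipped with probability ``error_rate``. Feed the
    result to :func:`filter_confident_sites`.
    """
    rng = np.random.default_rng(seed)
    at_sites = events[events["position"].isin(ref.cpg_sites)]
    state_by_pos = dict(zip(ref.cpg_sites.tolist(), ref.methylation_state.tolist()))
    truth = at_sites["position"].map(state_by_pos).to_numpy(dtype=bool)
    flip = rng.random(len(at_sites)) < error_rate
    return pd.DataFrame(
        {
            "position": at_sites["position"].to_numpy(),
            "read_id": at_sites["read_id"].to_numpy(),
            "call": truth ^ flip,
        }
    )


def filter_confident_sites(
    calls: pd.DataFrame, min_coverage: int = MIN_LABEL_COVERAGE
) -> pd.DataFrame:
    """Apply the confident-label filter to per-read site calls.

    A site gets a binary label only if it is covered by at least
    ``min_coverage`` reads and every read agrees; all other covered sites
    are marked ``ambiguous`` (to be excluded from training and
    evaluation). Returns columns ``position, coverage, state`` with state
    in {methylated, unmethylated, ambiguous}.
    """
    if calls.empty:
        return pd.DataFrame(columns=["position", "coverage", "state"])
    g = calls.groupby("position")["call"].agg(["count", "sum"])
    coverage = g["count"].to_numpy()
    n_meth = g["sum"].to_numpy()
    unanimous = (n_meth == 0) | (n_meth == coverage)
    confident = (coverage >= min_coverage) & unanimous
    state = np.where(
        confident, np.where(n_meth > 0, "methylated", "unmethylated"), "ambiguous"
    )
    return pd.DataFrame(
        {"position": g.index.to_numpy(), "coverage": coverage, "state": state}
    ).reset_index(drop=True)
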