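"""Modified k-mer domain model: alphabet, windows, featurization, novelty.

The methylation caller works over an expanded nucleotide alphabet
{A, C, G, T, M}, where M denotes 5-methylcytosine. Because mammalian 5mC
occurs in CpG context, every M that has a successor position must be
followed by G. A single methylated site, pulled through a pore reading k
bases at a time, gives rise to a (2k-1)-mer window centred on the M (an
11-mer for k=6), which decomposes into k overlapping modified k-mers — the
physical coherence constraint that drives panel selection.

Feature encoding of a 6-mer (141 bits):

* 30  = 6 positions x 5-letter one-hot,
* 105 = 5 adjacent positions x 21 CpG-valid ordered dinucleotides
        (the 25 ordered pairs minus MA, MC, MT, MM, which cannot occur
        when every non-terminal M is followed by G),
* 6   = per-position indicator of "C or M" (M is a modified cytosine, so
        the two letters are expected to perturb the current similarly).

Within each block the layout is lexicographic under A < C < G < T < M and
is stable across releases (the encoding is serialized with trained
predictors).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

#: Canonical letter order used by every one-hot block.
LETTERS: tuple[str, ...] = ("A", "C", "G", "T", "M")

#: Pore context length used throughout (R9.4-style 6-mer models).
K_DEFAULT: int = 6

#: Ordered dinucleotides that can occur in CpG-context sequence: all 25
#: ordered pairs except an M followed by anything but G.
DINUCLEOTIDES: tuple[str, ...] = tuple(
    a + b
    for a, b in itertools.product(LETTERS, repeat=2)
    if not (a == "M" and b != "G")
)

FEATURE_LENGTH: int = 5 * K_DEFAULT + len(DINUCLEOTIDES) * (K_DEFAULT - 1) + K_DEFAULT
assert len(DINUCLEOTIDES) == 21 and FEATURE_LENGTH == 141


@dataclass(frozen=True)
class Alphabet:
    """A symbol set for (modified) k-mers.

    Parameters
    ----------
    letters:
        Ordered symbols. Must contain the four nucleotides; ``M`` marks
        5-methylcytosine when present. Extra modification symbols (e.g. a
        hypothetical 5hmC letter) are allowed for counting exercises, but
        featurization and window semantics are defined for the canonical
        five-letter alphabet only.
    k:
        Pore context length, ``k >= 2`` for window semantics.
    """

    letters: tuple[str, ...] = LETTERS
    k: int = K_DEFAULT

    def __post_init__(self) -> None:
        letters = tuple(self.letters)
        object.__setattr__(self, "letters", letters)
        if len(set(letters)) != len(letters):
            raise ValueError("alphabet letters must be unique")
        if not {"A", "C", "G", "T"} <= set(letters):
            raise ValueError("alphabet must contain A, C, G, T")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")

    @property
    def window_length(self) -> int:
        return 2 * self.k - 1


#: The canonical 5mC alphabet.
DNA5 = Alphabet()


def _check_cpg_context(seq: str) -> bool:
    """True iff every M with a successor position is followed by G."""
    return all(b == "G" for a, b in zip(seq, seq[1:]) if a == "M")


def validate_kmer(seq: str, k: int = K_DEFAULT, alphabet: Alphabet = DNA5) -> str:
    """Validate a (possibly modified) k-mer, returning it unchanged.

    Raises ``ValueError`` on wrong length, foreign symbols, or an M not in
    CpG context.
    """
    if len(seq) != k:
        raise ValueError(f"k-mer {seq!r} has length {len(seq)}, expected {k}")
    if not set(seq) <= set(alphabet.letters):
        raise ValueError(f"k-mer {seq!r} contains symbols outside {alphabet.letters}")
    if not _check_cpg_context(seq):
        raise ValueError(f"k-mer {seq!r} violates the CpG context (M must precede G)")
    return seq


def is_modified(kmer: str) -> bool:
    """True iff the k-mer contains at least one M."""
    return "M" in kmer


def unmethylated_kmer(kmer: str) -> str:
    """The unmodified counterpart of a k-mer (every M replaced by C)."""
    return kmer.replace("M", "C")


@dataclass(frozen=True)
class MethylWindow:
    """A (2k-1)-mer centred on a single methylated CpG.

    The centre position carries the M, the next position the obligatory G,
    and no other M may appear: overlapping methylated CpGs would put a
    second modification inside the window, which is outside the
    single-modification setting this package models.
    """

    seq: str
    k: int = field(default=K_DEFAULT)

    def __post_init__(self) -> None:
        n = 2 * self.k - 1
        if len(self.seq) != n:
            raise ValueError(
                f"window {self.seq!r} has length {len(self.seq)}, expected {n}"
            )
        if not set(self.seq) <= set(LETTERS):
            raise ValueError(f"window {self.seq!r} contains invalid symbols")
        centre = self.k - 1
        if self.seq[centre] != "M":
            raise ValueError(f"window {self.seq!r} centre must be M")
        if self.seq[centre + 1] != "G":
            raise ValueError(f"window {self.seq!r} centre+1 must be G (CpG context)")
        if self.seq.count("M") != 1:
            raise ValueError(
                f"window {self.seq!r} contains a second M; overlapping methylated "
                "CpGs are not representable as a single window"
            )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.seq


def decompose_window(window: MethylWindow | str, k: int = K_DEFAULT) -> list[str]:
    """The k overlapping k-mers of a methyl window, in pore order.

    ``GATTTMGCAAC`` decomposes into GATTTM, ATTTMG, TTTMGC, TTMGCA,
    TMGCAA, MGCAAC. Each constituent contains the centre M, at position
    k-1-i for the i-th k-mer (0-based).
    """
    if isinstance(window, str):
        window = MethylWindow(window, k=k)
    k = window.k
    return [window.seq[i : i + k] for i in range(k)]


def enumerate_kmers(
    alphabet: Alphabet = DNA5, cpg_only: bool = False
) -> set[str]:
    """All k-mers over an alphabet, optionally restricted to CpG context.

    With ``cpg_only`` off this is the full ``|letters|^k`` census (4096 for
    {A,C,G,T}, 15625 for {A,C,G,T,M} at k=6). With it on, only strings in
    which every non-terminal M is followed by G are kept.
    """
    kmers = ("".join(t) for t in itertools.product(alphabet.letters, repeat=alphabet.k))
    if cpg_only:
        return {s for s in kmers if _check_cpg_context(s)}
    return set(kmers)


def single_m_kmers(k: int = K_DEFAULT) -> set[str]:
    """All CpG-context k-mers containing exactly one M.

    These are the modified k-mers that single-site methyl windows produce
    (2304 of them at k=6).
    """
    out: set[str] = set()
    acgt = ("A", "C", "G", "T")
    for pos in range(k):
        tail = 1 if pos < k - 1 else 0  # position after M is forced to G
        free = k - 1 - tail
        for combo in itertools.product(acgt, repeat=free):
            chars = list(combo[:pos]) + ["M"] + (["G"] if tail else [])
            chars += list(combo[pos:])
            out.add("".join(chars))
    return out


# --- featurization -------------------------------------------------------

_LETTER_INDEX = {c: i for i, c in enumerate(LETTERS)}
_DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}


def featurize_kmer(kmer: str, k: int = K_DEFAULT) -> np.ndarray:
    """Binary feature vector of a CpG-context 6-mer (length 141).

    Layout: ``[30 mononucleotide one-hot | 105 dinucleotide one-hot |
    6 C-or-M indicators]``. Deterministic and injective on valid inputs
    (the mono block alone determines the sequence).

    Raises ``ValueError`` for k != 6: the block sizes are specific to the
    6-mer pore context.
    """
    if k != K_DEFAULT:
        raise ValueError(f"featurization is defined for k=6 only, got k={k}")
    validate_kmer(kmer, k)
    v = np.zeros(FEATURE_LENGTH, dtype=np.uint8)
    for i, c in enumerate(kmer):
        v[5 * i + _LETTER_INDEX[c]] = 1
    off = 5 * k
    for i in range(k - 1):
        v[off + 21 * i + _DINUC_INDEX[kmer[i : i + 2]]] = 1
    off += 21 * (k - 1)
    for i, c in enumerate(kmer):
        if c in ("C", "M"):
            v[off + i] = 1
    return v


def featurize_kmers(kmers: Iterable[str]) -> np.ndarray:
    """Stacked feature matrix, one row per k-mer."""
    return np.stack([featurize_kmer(s) for s in kmers])


# --- novelty -------------------------------------------------------------


def onehot_hamming(a: MethylWindow | str, b: MethylWindow | str) -> int:
    """Hamming distance between per-position one-hot encodings of windows.

    Each substituted position flips two bits of the 5-symbol one-hot, so
    the distance equals twice the number of mismatched positions.
    """
    sa = a.seq if isinstance(a, MethylWindow) else a
    sb = b.seq if isinstance(b, MethylWindow) else b
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return 2 * sum(x != y for x, y in zip(sa, sb))


def novelty_score(
    window: MethylWindow | str, training: Iterable[MethylWindow | str]
) -> float:
    """Mean one-hot Hamming distance from a window to the unique training windows.

    Duplicated training entries are deduplicated before averaging, so the
    score depends on the set of distinct windows only. High scores mark
    windows far from everything the caller was trained on ("high novelty").
    """
    unique = {t.seq if isinstance(t, MethylWindow) else t for t in training}
    if not unique:
        raise ValueError("training window set is empty")
    w = window.seq if isinstance(window, MethylWindow) else window
    return float(np.mean([onehot_hamming(w, t) for t in sorted(unique)]))
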