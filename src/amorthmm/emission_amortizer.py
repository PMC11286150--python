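"""Amortized emission distributions: a feedforward net imputing HMM rows.

An independent-emission HMM cannot call modified k-mers absent from
training. The amortizer closes that gap: every *learned* modified-k-mer
emission row (mu, sigma^2) becomes a supervised example mapping the
k-mer's 141-bit featurization to its Gaussian parameters; a small
feedforward network fit to these pairs then predicts emission parameters
for the modified k-mers the HMM left at its pooled default. Learned rows
are never overridden — replacing them with predictions is strictly an
ablation (:func:`override_all_emissions`).

Because the regression targets are themselves distribution parameters,
training minimizes the symmetrized KL divergence between the target and
predicted Gaussians rather than a squared error on the raw parameters:

    f(P, P^) = D_KL(P || P^) + D_KL(P^ || P)
             = (s^2 + (m - m^)^2) / (2 s^^2)
             + (s^^2 + (m^ - m)^2) / (2 s^2) - 1,

the log-sigma terms of the two directed divergences cancelling. The net
is plain numpy (d fully connected ReLU layers of width h, linear head
predicting mean and log-variance, full-batch Adam); targets are
mean-standardized for conditioning, which leaves the loss unchanged
because the symmetrized KL is invariant under a common affine map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .hmm_caller import EmissionTable, GaussianParams
from .kmer_core import (
    FEATURE_LENGTH,
    MethylWindow,
    decompose_window,
    featurize_kmer,
    single_m_kmers,
)

#: Architecture grid searched when tuning on k-mer-complete data.
HIDDEN_DEPTHS = (3, 4, 5, 6)
HIDDEN_WIDTHS = (16, 32, 64, 128)

_LOGVAR_CLIP = 30.0  # pre-exp clamp in standardized space
_FEATURE_VERSION = "mono30-di21x5-cm6/v1"


def sym_kl(p: GaussianParams | tuple, q: GaussianParams | tuple) -> float:
    """Symmetrized KL divergence between two univariate Gaussians.

    Symmetric, non-negative, zero iff the parameters coincide; for equal
    unit variances it reduces to the squared mean difference.
    """
    mu1, var1 = p
    mu2, var2 = q
    return float(sym_kl_arrays(np.array([mu1]), np.array([var1]),
                               np.array([mu2]), np.array([var2]))[0])


def sym_kl_arrays(
    mu1: np.ndarray, var1: np.ndarray, mu2: np.ndarray, var2: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`sym_kl` over parameter arrays."""
    var1 = np.asarray(var1, dtype=float)
    var2 = np.asarray(var2, dtype=float)
    if np.any(var1 <= 0) or np.any(var2 <= 0):
        raise ValueError("variances must be strictly positive")
    d2 = (np.asarray(mu1, dtype=float) - np.asarray(mu2, dtype=float)) ** 2
    return (var1 + d2) / (2.0 * var2) + (var2 + d2) / (2.0 * var1) - 1.0


class TrainingPair(NamedTuple):
    """One supervised example: k-mer features -> learned emission row."""

    kmer: str
    features: np.ndarray
    target: GaussianParams


def build_training_pairs(em: EmissionTable) -> list[TrainingPair]:
    """Extract (features, emission parameters) pairs from a trained table.

    Only modified k-mers with provenance ``learned`` qualify: default and
    imputed rows carry no per-k-mer information, and unmodified k-mers are
    outside the imputation target set.
    """
    kmers = sorted(em.learned_modified_kmers())
    if not kmers:
        raise ValueError("emission table has no learned modified k-mer rows")
    return [TrainingPair(s, featurize_kmer(s), em.params(s)) for s in kmers]


@dataclass
class AmortizerConfig:
    """Hyperparameters of the emission predictor.

    ``d`` hidden layers of width ``h`` (restricted to the tuning grids)
    plus a direct linear path from the features to the output head; the
    ReLU branch's output layer starts at zero and all branch weights
    carry strong decoupled weight decay (``branch_weight_decay``) while
    the linear path decays only lightly (``skip_weight_decay``). Pore
    tables are dominated by additive and adjacent-pair contributions that
    are exactly linear in the feature encoding, so with the few dozen
    training pairs of a highly incomplete panel the regularization pulls
    the fit toward the well-posed linear solution, and the branch earns
    its keep only as data grows.

    Training is full-batch Adam for ``epochs`` epochs with a
    cosine-annealed learning rate starting at ``learning_rate``
    (annealing to zero; a constant rate leaves the fit visibly short of
    the optimum on exactly-linear targets), with a
    ``validation_fraction`` random holdout monitored during training.
    """

    d: int = 3
    h: int = 32
    learning_rate: float = 1e-2
    epochs: int = 1500
    seed: int = 0
    validation_fraction: float = 0.2
    cosine_decay: bool = True
    branch_weight_decay: float = 3.0
    skip_weight_decay: float = 1e-3

    def __post_init__(self) -> None:
        if self.d not in HIDDEN_DEPTHS:
            raise ValueError(f"d must be one of {HIDDEN_DEPTHS}, got {self.d}")
        if self.h not in HIDDEN_WIDTHS:
            raise ValueError(f"h must be one of {HIDDEN_WIDTHS}, got {self.h}")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs >= 1 and learning_rate > 0 required")
        if min(self.branch_weight_decay, self.skip_weight_decay) < 0:
            raise ValueError("weight decay must be non-negative")


@dataclass
class EmissionPredictor:
    """Trained feedforward map from k-mer features to Gaussian parameters.

    Outputs live in mean-standardized space internally
    (``mu_std``-scaled); ``predict`` de-standardizes, so predicted
    variances are always strictly positive by the exp parameterization.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    skip: np.ndarray
    mu_mean: float
    mu_std: float
    config: AmortizerConfig | None = None
    history: dict = field(default_factory=dict, repr=False)

    def _forward(self, X: np.ndarray) -> np.ndarray:
        X = X.astype(float)
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        return a @ self.weights[-1] + self.biases[-1] + X @ self.skip

    def predict_features(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        out = self._forward(np.atleast_2d(X))
        mu = out[:, 0] * self.mu_std + self.mu_mean
        var = np.exp(np.clip(out[:, 1], -_LOGVAR_CLIP, _LOGVAR_CLIP)) * self.mu_std**2
        return mu, var

    def predict_kmers(self, kmers: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        X = np.stack([featurize_kmer(s) for s in kmers])
        return self.predict_features(X)

    def predict(self, kmer: str) -> GaussianParams:
        mu, var = self.predict_kmers([kmer])
        return GaussianParams(float(mu[0]), float(var[0]))

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> dict:
        obj = {
            "feature_layout": _FEATURE_VERSION,
            "layer_sizes": [int(w.shape[0]) for w in self.weights]
            + [int(self.weights[-1].shape[1])],
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "skip": self.skip.tolist(),
            "mu_mean": self.mu_mean,
            "mu_std": self.mu_std,
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj))
        return obj

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "EmissionPredictor":
        obj = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        if obj.get("feature_layout") != _FEATURE_VERSION:
            raise ValueError(
                f"predictor was trained with feature layout "
                f"{obj.get('feature_layout')!r}, expected {_FEATURE_VERSION!r}"
            )
        return cls(
            weights=[np.asarray(w, dtype=float) for w in obj["weights"]],
            biases=[np.asarray(b, dtype=float) for b in obj["biases"]],
            skip=np.asarray(obj["skip"], dtype=float),
            mu_mean=float(obj["mu_mean"]),
            mu_std=float(obj["mu_std"]),
        )


def _mean_sym_kl_std(
    out: np.ndarray, mu_t: np.ndarray, var_t: np.ndarray
) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. network output in standardized space."""
    mu_hat = out[:, 0]
    s = np.clip(out[:, 1], -_LOGVAR_CLIP, _LOGVAR_CLIP)
    var_hat = np.exp(s)
    d = mu_t - mu_hat
    loss = np.mean(
        (var_t + d**2) / (2 * var_hat) + (var_hat + d**2) / (2 * var_t) - 1.0
    )
    n = out.shape[0]
    g = np.empty_like(out)
    g[:, 0] = -d * (1.0 / var_hat + 1.0 / var_t) / n
    g[:, 1] = (-(var_t + d**2) / (2 * var_hat) + var_hat / (2 * var_t)) / n
    g[:, 1] *= (out[:, 1] > -_LOGVAR_CLIP) & (out[:, 1] < _LOGVAR_CLIP)
    return float(loss), g


def fit_amortizer(
    pairs: Sequence[TrainingPair],
    cfg: AmortizerConfig = AmortizerConfig(),
) -> EmissionPredictor:
    """Fit the emission predictor by full-batch Adam on symmetrized KL.

    Deterministic given ``cfg.seed`` (initialization and the train /
    validation split both derive from it). Per-epoch training and
    validation losses are recorded in the returned predictor's
    ``history``; raises ``RuntimeError`` if the loss diverges.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two training pairs")
    rng = np.random.default_rng(cfg.seed)
    X = np.stack([p.features for p in pairs]).astype(float)
    mu = np.array([p.target.mu for p in pairs])
    var = np.array([p.target.var for p in pairs])
    if np.any(var <= 0):
        raise ValueError("target variances must be positive")

    mu_mean = float(mu.mean())
    mu_std = float(mu.std()) or 1.0
    mu_t = (mu - mu_mean) / mu_std
    var_t = var / mu_std**2

    n = len(pairs)
    idx = rng.permutation(n)
    n_val = min(max(int(round(cfg.validation_fraction * n)), 1), n - 1)
    val_idx, tr_idx = idx[:n_val], idx[n_val:]

    sizes = [X.shape[1]] + [cfg.h] * cfg.d + [2]
    Ws = [
        rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    Ws[-1][:] = 0.0  # branch starts silent; the linear path leads
    bs = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    skip = np.zeros((X.shape[1], 2))
    # start the log-variance head near the mean target log-variance
    bs[-1][1] = float(np.log(var_t.mean()))

    params = Ws + bs + [skip]
    decays = (
        [cfg.branch_weight_decay] * len(Ws) + [0.0] * len(bs) + [cfg.skip_weight_decay]
    )
    m_st = [np.zeros_like(p) for p in params]
    v_st = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8

    def forward(Xin: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = [Xin]
        for W, b in zip(Ws[:-1], bs[:-1]):
            acts.append(np.maximum(acts[-1] @ W + b, 0.0))
        return acts, acts[-1] @ Ws[-1] + bs[-1] + Xin @ skip

    Xtr, Xval = X[tr_idx], X[val_idx]
    hist_train, hist_val = [], []
    for epoch in range(1, cfg.epochs + 1):
        lr = cfg.learning_rate
        if cfg.cosine_decay:
            lr *= 0.5 * (1.0 + np.cos(np.pi * epoch / cfg.epochs))
        acts, out = forward(Xtr)
        loss, gout = _mean_sym_kl_std(out, mu_t[tr_idx], var_t[tr_idx])
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch} (loss={loss}); "
                f"lower the learning rate (current {cfg.learning_rate})"
            )
        # backward
        gWs = [np.zeros_like(w) for w in Ws]
        gbs = [np.zeros_like(b) for b in bs]
        gskip = Xtr.T @ gout
        delta = gout
        for li in range(len(Ws) - 1, -1, -1):
            gWs[li] = acts[li].T @ delta
            gbs[li] = delta.sum(axis=0)
            if li > 0:
                delta = (delta @ Ws[li].T) * (acts[li] > 0)
        # decoupled-weight-decay Adam update
        t = epoch
        for g, m, v, p, wd in zip(gWs + gbs + [gskip], m_st, v_st, params, decays):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
            if wd:
                p -= lr * wd * p
        hist_train.append(loss)
        _, val_out = forward(Xval)
        vloss, _ = _mean_sym_kl_std(val_out, mu_t[val_idx], var_t[val_idx])
        hist_val.append(vloss)

    return EmissionPredictor(
        weights=Ws,
        biases=bs,
        skip=skip,
        mu_mean=mu_mean,
        mu_std=mu_std,
        config=cfg,
        history={
            "train_loss": np.array(hist_train),
            "val_loss": np.array(hist_val),
        },
    )


def grid_search_amortizer(
    pairs: Sequence[TrainingPair],
    d_values: Sequence[int] = HIDDEN_DEPTHS,
    h_values: Sequence[int] = HIDDEN_WIDTHS,
    base: AmortizerConfig = AmortizerConfig(),
) -> tuple[AmortizerConfig, list[dict]]:
    """Grid search depth x width by final validation symmetrized KL.

    Meant to be run once on a k-mer-complete emission table with an 80/20
    random split; the winning configuration is then frozen for every
    completeness level. Returns the best config and the full result table.
    """
    from dataclasses import replace as _replace

    results = []
    for d in d_values:
        for h in h_values:
            pred = fit_amortizer(pairs, _replace(base, d=d, h=h))
            results.append(
                {"d": d, "h": h, "val_loss": float(pred.history["val_loss"][-1])}
            )
    best = min(results, key=lambda r: r["val_loss"])
    return _replace(base, d=best["d"], h=best["h"]), results


# --- imputation policies --------------------------------------------------


def impute_emission_table(
    em: EmissionTable,
    predictor: EmissionPredictor,
    kmers: Sequence[str] | None = None,
) -> EmissionTable:
    """Replace default modified-k-mer rows with predictor output.

    Learned rows are never touched; rows with provenance ``default`` (and
    modified k-mers missing entirely) are filled with predictions and
    marked ``imputed``. The result is complete over ``kmers`` (all
    single-M CpG-context 6-mers by default), which is what lets the
    amortized HMM call sites whose modified k-mers were never trained.
    """
    targets = sorted(single_m_kmers() if kmers is None else set(kmers))
    out = em.copy()
    todo = [
        s for s in targets if s not in out or out.provenance(s) != "learned"
    ]
    if todo:
        mu, var = predictor.predict_kmers(todo)
        for s, m, v in zip(todo, mu, var):
            out.set(s, GaussianParams(float(m), float(v)), "imputed")
    return out


def override_all_emissions(
    em: EmissionTable,
    predictor: EmissionPredictor,
    kmers: Sequence[str] | None = None,
) -> EmissionTable:
    """Ablation: predictor output for *every* modified k-mer row.

    Discards the learned rows in favour of predictions (all marked
    ``imputed``); kept as the baseline demonstrating why imputation-only
    is the right policy — memorized emission rows beat their predicted
    reconstructions on seen k-mers.
    """
    targets = set(single_m_kmers() if kmers is None else kmers)
    targets |= {s for s in em.kmers() if "M" in s}
    todo = sorted(targets)
    out = em.copy()
    mu, var = predictor.predict_kmers(todo)
    for s, m, v in zip(todo, mu, var):
        out.set(s, GaussianParams(float(m), float(v)), "imputed")
    return out


def combined_policy_call(
    seen_caller,
    unseen_caller,
    training_kmers: set[str],
    site_window: MethylWindow | str,
):
    """Route a site to the seen- or unseen-k-mer caller.

    A site counts as "seen" iff all k constituent modified k-mers of its
    window are in ``training_kmers``; such sites go to ``seen_caller``,
    the rest to ``unseen_caller``. Both callers are callables taking the
    window and returning a site call; the identities are injected, which
    is what lets a sensor-specialized caller handle in-training k-mers
    while the amortized HMM covers the rest.
    """
    constituents = decompose_window(site_window)
    caller = (
        seen_caller
        if all(s in training_kmers for s in constituents)
        else unseen_caller
    )
    return caller(site_window)
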