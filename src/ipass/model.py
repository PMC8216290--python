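"""The iPASS regression core.

An amber context is encoded as a 52-entry feature vector: 48 nucleotide
indicators (12 flanking positions x 4 bases), 3 stop-codon indicators
(UAA/UAG/UGA) and the G+C fraction of the 15 nt window.  Features are
standardized (center/scale from the training data) and a ridge
regression is fit in closed form,

    w = (X'X + k I)^-1 X'y

on the scaled design with the response centered by its mean (the mean
is restored at prediction time as the intercept, so scores live on the
normalized log2-fold-change scale of the training data).  The
regularization constant k defaults to 10^0.3 (~1.995) and can be
selected by leave-one-out cross-validation using the closed-form LOO
identity.  A decoy model — the same pipeline after permuting the
responses — serves as the negative control for predictive specificity,
and block-wise feature elimination ranks positional importance.

A score above 1.0 flags a context as permissive for ncAA incorporation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg

from ipass.contexts import RNA_BASES, STOP_CODONS, SequenceContext

#: flanking position labels in feature order: -6..-1 then +4..+9
POSITIONS: tuple[int, ...] = (-6, -5, -4, -3, -2, -1, 4, 5, 6, 7, 8, 9)
N_FEATURES = 52
GC_INDEX = 51
STOP_SLICE = slice(48, 51)

#: default regularization constant, 10^0.3
K_DEFAULT: float = 10.0**0.3
#: default LOO-CV grid: 10^p for p in -2..2, step 0.1
K_GRID_DEFAULT: tuple[float, ...] = tuple(10.0 ** np.arange(-2.0, 2.0001, 0.1))

SCORE_CUTOFF = 1.0

_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}


def feature_names() -> list[str]:
    """Column labels of the 52-entry feature layout."""
    names = [
        f"{'m' if p < 0 else 'p'}{abs(p)}_{b}" for p in POSITIONS for b in RNA_BASES
    ]
    names += [f"stop_{s}" for s in STOP_CODONS]
    names.append("gc")
    return names


def feature_blocks() -> dict[str, np.ndarray]:
    """Column-index blocks: one per flanking position, the stop, and GC."""
    blocks: dict[str, np.ndarray] = {}
    for i, p in enumerate(POSITIONS):
        label = f"{'m' if p < 0 else 'p'}{abs(p)}"
        blocks[label] = np.arange(4 * i, 4 * i + 4)
    blocks["stop"] = np.arange(48, 51)
    blocks["gc"] = np.array([GC_INDEX])
    return blocks


def encode_features(c: SequenceContext) -> np.ndarray:
    """Indicator-encode one context into the fixed 52-entry layout."""
    x = np.zeros(N_FEATURES)
    for i, base in enumerate(c.upstream + c.downstream):
        x[4 * i + _BASE_INDEX[base]] = 1.0
    x[48 + STOP_CODONS.index(c.stop)] = 1.0
    x[GC_INDEX] = c.gc
    return x


def encode_matrix(contexts: Sequence[SequenceContext]) -> np.ndarray:
    if len(contexts) == 0:
        raise ValueError("empty context list")
    return np.stack([encode_features(c) for c in contexts])


@dataclass(frozen=True)
class Scaler:
    """Per-column standardization statistics (mean, sample sd).

    Constant columns keep scale 1 and are flagged — with amber-only
    training data the three stop indicators are always constant.
    """

    center: np.ndarray
    scale: np.ndarray
    constant: np.ndarray  # boolean mask of constant columns

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.center) / self.scale

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, float) * self.scale + self.center


def fit_scaler(X: np.ndarray) -> Scaler:
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-d matrix with >= 2 rows")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    constant = scale == 0.0
    scale = np.where(constant, 1.0, scale)
    return Scaler(center=center, scale=scale, constant=constant)


def _augmented_solve(X: np.ndarray, y: np.ndarray, k: float) -> tuple[np.ndarray, float]:
    """Ridge with an unpenalized intercept, solved jointly.

    For a design with zero-mean columns this reduces exactly to the
    closed form w = (X'X + kI)^-1 X'y with intercept mean(y).
    """
    n, d = X.shape
    A = np.column_stack([np.ones(n), X])
    M = A.T @ A
    M[1:, 1:] += k * np.eye(d)
    beta = scipy.linalg.solve(M, A.T @ y, assume_a="pos")
    return beta[1:], float(beta[0])


def _dependent_columns(X: np.ndarray) -> list[int]:
    # pivoted QR: columns beyond the numerical rank are the dependents
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return sorted(int(j) for j in piv[rank:])


def fit_ridge(X_scaled: np.ndarray, y: np.ndarray, k: float) -> tuple[np.ndarray, float]:
    """Closed-form ridge fit on scaled features; returns (w, intercept).

    ``k = 0`` is allowed only on a full-rank design; otherwise the
    (0-based) dependent columns are named in the error.
    """
    X = np.asarray(X_scaled, float)
    y = np.asarray(y, float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in design or response")
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0 and np.linalg.matrix_rank(X) < X.shape[1]:
        dep = _dependent_columns(X)
        raise np.linalg.LinAlgError(
            f"k=0 with rank-deficient design; dependent columns: {dep}"
        )
    return _augmented_solve(X, y, k)


def _loo_residuals(X: np.ndarray, y: np.ndarray, k: float) -> np.ndarray:
    """Leave-one-out residuals via the hat-matrix identity e_i/(1-h_ii)."""
    n, d = X.shape
    A = np.column_stack([np.ones(n), X])
    M = A.T @ A
    M[1:, 1:] += k * np.eye(d)
    beta = scipy.linalg.solve(M, A.T @ y, assume_a="pos")
    # H = A M^-1 A'; only the diagonal is needed
    h = np.einsum("ij,ji->i", A, scipy.linalg.solve(M, A.T, assume_a="pos"))
    if np.any(h >= 1.0 - 1e-12):
        raise FloatingPointError("leverage >= 1: a point fully determines its own fit")
    resid = y - A @ beta
    return resid / (1.0 - h)


def loo_cv(
    X_scaled: np.ndarray,
    y: np.ndarray,
    k_grid: Sequence[float] = K_GRID_DEFAULT,
) -> tuple[float, dict]:
    """Select k by leave-one-out CV; returns (k*, diagnostics).

    Diagnostics carry both the mean and the sum of squared LOO
    residuals per candidate.  Ties are broken toward the larger
    (stronger) regularization.
    """
    X = np.asarray(X_scaled, float)
    y = np.asarray(y, float)
    if X.shape[0] < 3:
        raise ValueError("LOO-CV needs n >= 3")
    ks = sorted(float(k) for k in k_grid)
    mse, sse = [], []
    for k in ks:
        r = _loo_residuals(X, y, k)
        sse.append(float(np.sum(r**2)))
        mse.append(float(np.mean(r**2)))
    best = 0
    for i in range(1, len(ks)):
        if mse[i] <= mse[best]:
            best = i
    diagnostics = {"k_grid": ks, "loo_mse": mse, "loo_sse": sse}
    return ks[best], diagnostics


@dataclass
class IpassModel:
    """A fitted context-scoring model.

    ``w`` lives on the scaled feature space; ``intercept`` restores the
    training-response mean so scores are on the normalized-LFC scale.
    """

    scaler: Scaler
    w: np.ndarray
    intercept: float
    k: float
    diagnostics: dict = field(default_factory=dict)
    training_hash: str = ""

    def score_features(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self.intercept + self.scaler.transform(X) @ self.w

    def score(self, c: SequenceContext) -> float:
        return float(self.score_features(encode_features(c))[0])

    def score_many(self, contexts: Sequence[SequenceContext]) -> np.ndarray:
        return self.score_features(encode_matrix(contexts))

    def effective_linear_form(self) -> tuple[float, np.ndarray]:
        """Collapse scaling into raw-feature space: score = c0 + e . x.

        Returns (c0, e) with e of length 52 acting on *unscaled*
        features; used by the streaming logo scorer.
        """
        e = self.w / self.scaler.scale
        c0 = self.intercept - float(e @ self.scaler.center)
        return c0, e

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "ipass-model",
            "version": 1,
            "feature_names": feature_names(),
            "center": self.scaler.center.tolist(),
            "scale": self.scaler.scale.tolist(),
            "constant": self.scaler.constant.astype(bool).tolist(),
            "w": self.w.tolist(),
            "intercept": self.intercept,
            "k": self.k,
            "diagnostics": self.diagnostics,
            "training_hash": self.training_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IpassModel":
        if d.get("format") != "ipass-model":
            raise ValueError("not an iPASS model document")
        scaler = Scaler(
            center=np.asarray(d["center"], float),
            scale=np.asarray(d["scale"], float),
            constant=np.asarray(d["constant"], bool),
        )
        return cls(
            scaler=scaler,
            w=np.asarray(d["w"], float),
            intercept=float(d["intercept"]),
            k=float(d["k"]),
            diagnostics=d.get("diagnostics", {}),
            training_hash=d.get("training_hash", ""),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "IpassModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _hash_training(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(np.asarray(y, float)).tobytes())
    return h.hexdigest()[:16]


def train_model(
    contexts: Sequence[SequenceContext],
    y: Sequence[float],
    k: float | None = K_DEFAULT,
    k_grid: Sequence[float] | None = None,
) -> IpassModel:
    """Full training pipeline: encode, scale, (optionally) LOO-CV, fit.

    Pass ``k=None`` (or a ``k_grid``) to select the regularization
    constant by LOO-CV; otherwise the supplied constant is used.
    """
    X = encode_matrix(contexts)
    y = np.asarray(y, float)
    if len(y) != X.shape[0]:
        raise ValueError("contexts and responses differ in length")
    scaler = fit_scaler(X)
    Xs = scaler.transform(X)
    diagnostics: dict = {}
    if k is None or k_grid is not None:
        k, diagnostics = loo_cv(Xs, y, k_grid if k_grid is not None else K_GRID_DEFAULT)
    w, intercept = fit_ridge(Xs, y, k)
    return IpassModel(
        scaler=scaler,
        w=w,
        intercept=intercept,
        k=float(k),
        diagnostics=diagnostics,
        training_hash=_hash_training(X, y),
    )


def ipass_score(model: IpassModel, c: SequenceContext) -> float:
    """Score one context: intercept + w . scaled features."""
    return model.score(c)


def fit_decoy(
    contexts: Sequence[SequenceContext],
    y: Sequence[float],
    seed: int,
    k: float | None = K_DEFAULT,
    k_grid: Sequence[float] | None = None,
) -> IpassModel:
    """Negative-control model: permute responses, rerun the pipeline."""
    rng = np.random.default_rng(seed)
    y_perm = rng.permutation(np.asarray(y, float))
    return train_model(contexts, y_perm, k=k, k_grid=k_grid)


def feature_elimination(
    contexts: Sequence[SequenceContext],
    y: Sequence[float],
    k: float = K_DEFAULT,
) -> list[tuple[str, float]]:
    """Backward elimination of whole feature blocks.

    Each flanking position (its 4 indicators), and GC, is one removable
    block; the stop block always stays.  At every step the block with
    the minimum sum of squared coefficients is removed, the model
    refit, and the LOO mean-squared error of the reduced model
    recorded.  Returns the removal order with errors, length 13.
    """
    X_full = encode_matrix(contexts)
    y = np.asarray(y, float)
    blocks = feature_blocks()
    remaining = [name for name in blocks if name != "stop"]
    order: list[tuple[str, float]] = []
    while remaining:
        cols = np.concatenate([blocks[name] for name in remaining + ["stop"]])
        cols.sort()
        X = X_full[:, cols]
        scaler = fit_scaler(X)
        Xs = scaler.transform(X)
        w, _ = fit_ridge(Xs, y, k)
        col_pos = {c: i for i, c in enumerate(cols)}
        ssq = {
            name: float(sum(w[col_pos[c]] ** 2 for c in blocks[name]))
            for name in remaining
        }
        victim = min(remaining, key=lambda name: (ssq[name], name))
        remaining.remove(victim)
        kept = np.concatenate([blocks[name] for name in remaining + ["stop"]])
        kept.sort()
        Xr = X_full[:, kept]
        sc = fit_scaler(Xr)
        r = _loo_residuals(sc.transform(Xr), y, k)
        order.append((victim, float(np.mean(r**2))))
    return order


def classify_permissive(score: float, cutoff: float = SCORE_CUTOFF) -> str:
    """Binary call on a score: permissive iff strictly above the cutoff."""
    return "permissive" if score > cutoff else "non_permissive"
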