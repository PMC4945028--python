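"""k-mer and DNA-shape feature encoding with L2-regularized regression.

Aligned probe sequences are encoded as position-specific mononucleotide,
dinucleotide and trinucleotide indicators plus four DNA-shape features (minor
groove width, propeller twist, roll, helix twist) looked up from pentamer
context. Models are compared by 10-fold cross-validated R-squared, defined as
the squared Pearson correlation between predicted and held-out intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from xdense.genomic_io import ACGT, BASE_INDEX, ShapeTable

DEFAULT_LAMBDA_GRID = np.logspace(-4, 4, 17)


@dataclass(frozen=True)
class FeatureSpec:
    use_1mer: bool = True
    use_2mer: bool = False
    use_3mer: bool = False
    use_shape: bool = False
    shape_normalization: str = "z-score"  # or "none"

    def __post_init__(self):
        if not (self.use_1mer or self.use_2mer or self.use_3mer or self.use_shape):
            raise ValueError("at least one feature family must be enabled")
        if self.shape_normalization not in ("none", "z-score"):
            raise ValueError("shape_normalization must be 'none' or 'z-score'")

    @classmethod
    def parse(cls, text: str) -> "FeatureSpec":
        """Parse compact names like ``1mer+2mer+shape``."""
        parts = set(text.split("+"))
        unknown = parts - {"1mer", "2mer", "3mer", "shape"}
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        return cls(
            use_1mer="1mer" in parts,
            use_2mer="2mer" in parts,
            use_3mer="3mer" in parts,
            use_shape="shape" in parts,
        )


@dataclass
class RidgeModel:
    weights: np.ndarray
    intercept: float
    lam: float
    feature_names: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.intercept


@dataclass
class CVResult:
    per_fold_r2: np.ndarray
    fold_assignment_seed: int
    lambdas: np.ndarray

    @property
    def mean_r2(self) -> float:
        return float(self.per_fold_r2.mean())


def encode_features(
    aligned_seqs: Sequence[str],
    spec: FeatureSpec,
    shape_table: ShapeTable | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Encode an equal-length sequence block as a feature matrix.

    1mer: 4 indicators per position (4L columns); 2mer: 16 per adjacent pair;
    3mer: 64 per triple. Shape: 4 values per eligible position from the
    pentamer centered there (edge positions without pentamer context are
    dropped, giving 4(L-4) columns), optionally z-scored per feature.
    """
    if not aligned_seqs:
        raise ValueError("no sequences")
    L = len(aligned_seqs[0])
    seqs = [s.upper() for s in aligned_seqs]
    for s in seqs:
        if len(s) != L:
            raise ValueError("sequences must have equal lengths")
        if set(s) - set(ACGT):
            raise ValueError("sequences must be over ACGT for feature encoding")
    if spec.use_shape:
        if shape_table is None:
            raise ValueError("shape features requested but no shape table given")
        if L < 5:
            raise ValueError("shape features need L >= 5")
    n = len(seqs)
    blocks: list[np.ndarray] = []
    names: list[str] = []

    for k, enabled in ((1, spec.use_1mer), (2, spec.use_2mer), (3, spec.use_3mer)):
        if not enabled:
            continue
        kmers = ["".join(p) for p in product(ACGT, repeat=k)]
        index = {km: i for i, km in enumerate(kmers)}
        n_pos = L - k + 1
        block = np.zeros((n, n_pos * 4 ** k))
        for r, s in enumerate(seqs):
            for pos in range(n_pos):
                block[r, pos * 4 ** k + index[s[pos : pos + k]]] = 1.0
        blocks.append(block)
        names.extend(f"{k}mer_p{pos}_{km}" for pos in range(n_pos) for km in kmers)

    if spec.use_shape:
        shape_cols = ("MGW", "ProT", "Roll", "HelT")
        n_pos = L - 4
        block = np.zeros((n, n_pos * 4))
        for r, s in enumerate(seqs):
            for j, center in enumerate(range(2, L - 2)):
                vals = shape_table[s[center - 2 : center + 3]]
                block[r, j * 4 : j * 4 + 4] = vals
        if spec.shape_normalization == "z-score":
            mu = block.mean(axis=0)
            sd = block.std(axis=0)
            sd[sd == 0] = 1.0
            block = (block - mu) / sd
        blocks.append(block)
        names.extend(
            f"shape_p{center}_{c}" for center in range(2, L - 2) for c in shape_cols
        )

    return np.hstack(blocks), names


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float,
              feature_names: list[str] | None = None) -> RidgeModel:
    """Minimize ||y - Xw - w0||^2 + lam ||w||^2 with an unpenalized intercept.

    Solved deterministically by the normal equations on centered data; a
    degenerate design with lam = 0 raises a singularity error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y) or len(y) < 2:
        raise ValueError("need rows(X) == len(y) >= 2")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    A = Xc.T @ Xc + lam * np.eye(X.shape[1])
    try:
        c, low = scipy.linalg.cho_factor(A)
        w = scipy.linalg.cho_solve((c, low), Xc.T @ yc)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular normal equations (degenerate X with lambda = 0)"
        ) from e
    return RidgeModel(
        weights=w,
        intercept=float(y_mean - x_mean @ w),
        lam=lam,
        feature_names=feature_names or [],
    )


def _r2(pred: np.ndarray, obs: np.ndarray, mode: str = "pearson") -> float:
    if mode == "pearson":
        if np.std(pred) == 0 or np.std(obs) == 0:
            return 0.0
        return float(np.corrcoef(pred, obs)[0, 1] ** 2)
    if mode == "ss":
        ss_res = float(((obs - pred) ** 2).sum())
        ss_tot = float(((obs - obs.mean()) ** 2).sum())
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    raise ValueError(f"unknown r2 mode {mode!r}")


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[i::folds] for i in range(folds)]


def _select_lambda(X, y, grid, inner_folds: int = 5, seed: int = 0,
                   r2_mode: str = "pearson") -> float:
    # one Gram matrix per inner fold, re-solved across the whole grid
    folds = _fold_indices(len(y), inner_folds, seed)
    scores = np.zeros(len(grid))
    for test_idx in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        Xtr, ytr = X[mask], y[mask]
        x_mean, y_mean = Xtr.mean(axis=0), ytr.mean()
        Xc = Xtr - x_mean
        gram = Xc.T @ Xc
        xty = Xc.T @ (ytr - y_mean)
        Xte_c = X[test_idx] - x_mean
        for gi, lam in enumerate(grid):
            A = gram + lam * np.eye(gram.shape[0])
            c, low = scipy.linalg.cho_factor(A)
            w = scipy.linalg.cho_solve((c, low), xty)
            pred = Xte_c @ w + y_mean
            scores[gi] += _r2(pred, y[test_idx], r2_mode)
    return float(grid[int(np.argmax(scores))])


def crossval_r2(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    lam: float | None = None,
    seed: int = 0,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    r2_mode: str = "pearson",
) -> CVResult:
    """Cross-validated R-squared with seeded fold assignment.

    When ``lam`` is None, lambda is selected on each training split from the
    logarithmic grid by inner 5-fold cross-validation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError("need n >= folds")
    fold_idx = _fold_indices(n, folds, seed)
    r2s, lams = [], []
    for test_idx in fold_idx:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        lam_k = lam if lam is not None else _select_lambda(
            X[mask], y[mask], lambda_grid, seed=seed, r2_mode=r2_mode
        )
        model = fit_ridge(X[mask], y[mask], lam_k)
        r2s.append(_r2(model.predict(X[test_idx]), y[test_idx], r2_mode))
        lams.append(lam_k)
    return CVResult(np.array(r2s), seed, np.array(lams))


def compare_models(
    encodings: Sequence[tuple[str, FeatureSpec]],
    aligned_seqs: Sequence[str],
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    shape_table: ShapeTable | None = None,
    lam: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare feature encodings under a shared fold assignment.

    Returns (per-model table with mean and per-fold R-squared, pairwise table
    with paired t-test and Wilcoxon signed-rank p-values and relative gain in
    percent, computed as (R2_big - R2_small) / R2_small * 100 with "big" the
    higher-mean model of the pair).
    """
    results: dict[str, CVResult] = {}
    for name, spec in encodings:
        X, _ = encode_features(aligned_seqs, spec, shape_table)
        results[name] = crossval_r2(X, y, folds=folds, lam=lam, seed=seed)
    model_rows = [
        {
            "model": name,
            "mean_r2": res.mean_r2,
            "per_fold_r2": res.per_fold_r2.tolist(),
        }
        for name, res in results.items()
    ]
    pair_rows = []
    names = list(results)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = results[names[i]].per_fold_r2, results[names[j]].per_fold_r2
            diff = a - b
            if np.allclose(diff, 0):
                t_p, w_p = 1.0, 1.0
            else:
                t_p = float(scipy.stats.ttest_rel(a, b).pvalue)
                w_p = float(scipy.stats.wilcoxon(a, b).pvalue)
            small, big = sorted([a.mean(), b.mean()])
            gain = (big - small) / small * 100 if small > 0 else float("nan")
            pair_rows.append(
                {
                    "model_a": names[i],
                    "model_b": names[j],
                    "mean_diff": float(diff.mean()),
                    "paired_t_p": t_p,
                    "wilcoxon_p": w_p,
                    "relative_gain_pct": gain,
                }
            )
    return pd.DataFrame(model_rows), pd.DataFrame(pair_rows)
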