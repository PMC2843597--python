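"""Lasso/LARS prediction of binding divergence from word gain and loss.

The model relates the per-peak signed difference in DDW instance counts
between the two genomes to the normalized binding divergence of the peak:
each divergent word contributes a fixed amount, with multiple divergent
words adding independently.  The full lasso coefficient path is computed
with least angle regression; the regularization parameter is chosen by
5-fold cross-validated mean-squared prediction error.  Nucleotide-shuffled
words with unchanged base composition provide a negative control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import lars_path

from .ddw import revcomp

__all__ = [
    "FeatureTable",
    "LarsPath",
    "CVResult",
    "FittedDivergenceModel",
    "build_features",
    "fit_lars_lasso",
    "cv_select",
    "shuffled_control",
    "fit_divergence_model",
    "evaluate",
]


@dataclass
class FeatureTable:
    """Per-peak word gain/loss features and divergence response.

    ``X`` holds, per DDW, (instance count in the reference window) minus
    (instance count in the orthologous window); rows are the peaks with at
    least one instance of some DDW in either genome.
    """

    X: pd.DataFrame
    y: pd.Series
    counts_ref: pd.DataFrame = None
    counts_other: pd.DataFrame = None


def _count_in_text(text: str, word: str) -> int:
    """Occurrences of word or its reverse complement in uppercase text
    (overlapping occurrences counted; palindromes counted once)."""
    rc = revcomp(word)
    n = 0
    k = len(word)
    for off in range(len(text) - k + 1):
        sub = text[off : off + k]
        if not sub.isupper():
            continue
        if sub == word or (rc != word and sub == rc):
            n += 1
    return n


def build_features(
    ddws,
    matched_peaks,
    aln,
    ref_seqs: dict[str, str],
    other_seqs: dict[str, str],
) -> FeatureTable:
    """Count DDW instances in each peak's window and its orthologous
    projection, attach the peak's divergence response, and keep rows with
    at least one instance in either genome."""
    words = sorted(ddws)
    rows_ref, rows_other, resp, index = [], [], [], []
    for i, p in enumerate(matched_peaks):
        if p.status == "unalignable":
            continue
        s, e = p.window
        text_ref = ref_seqs[p.chrom][max(0, s) : e]
        texts_other = [
            other_seqs[c][s2:e2] for c, s2, e2 in p.ortholog_intervals
        ]
        cr = [_count_in_text(text_ref, w) for w in words]
        co = [
            sum(_count_in_text(t, w) for t in texts_other) for w in words
        ]
        if not any(cr) and not any(co):
            continue
        rows_ref.append(cr)
        rows_other.append(co)
        resp.append(p.strength - p.ortholog_strength)
        index.append(i)
    cr = pd.DataFrame(rows_ref, columns=words, index=index, dtype=int)
    co = pd.DataFrame(rows_other, columns=words, index=index, dtype=int)
    X = cr - co
    y = pd.Series(resp, index=index, name="divergence")
    return FeatureTable(X, y, cr, co)


@dataclass
class LarsPath:
    """Lasso coefficient path in standardized coordinates.

    ``betas`` are the breakpoints of the regularization parameter (sklearn
    convention: mean absolute covariance), decreasing; ``coefs`` has shape
    (n_features, n_breakpoints); coefficients are piecewise linear in beta
    between breakpoints and identically zero at the maximally penalized
    end.
    """

    betas: np.ndarray
    coefs: np.ndarray
    columns: list
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float

    def coefs_at(self, beta: float) -> np.ndarray:
        """Interpolated standardized coefficients at a penalty value."""
        b = self.betas
        if beta >= b[0]:
            return np.zeros(self.coefs.shape[0])
        if beta <= b[-1]:
            return self.coefs[:, -1].copy()
        # betas decrease; np.interp needs increasing x
        return np.array(
            [np.interp(beta, b[::-1], row[::-1]) for row in self.coefs]
        )

    def raw_coefs_at(self, beta: float) -> tuple[np.ndarray, float]:
        """Back-transformed coefficients and intercept on the raw scale."""
        c = self.coefs_at(beta) / self.x_std
        intercept = self.y_mean - float(c @ self.x_mean)
        return c, intercept


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    keep = std > 0
    return mean, std, keep


def fit_lars_lasso(X, y) -> LarsPath:
    """Full lasso path via LARS with the lasso modification.

    Columns are standardized internally (constant columns dropped with a
    warning); the response is centered and the intercept left unpenalized.
    """
    Xdf = pd.DataFrame(X)
    Xa = Xdf.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    mean, std, keep = _standardize(Xa)
    if not keep.all():
        dropped = [c for c, k in zip(Xdf.columns, keep) if not k]
        warnings.warn(f"dropping constant feature columns: {dropped}")
    cols = [c for c, k in zip(Xdf.columns, keep) if k]
    Xs = (Xa[:, keep] - mean[keep]) / std[keep]
    y_mean = float(ya.mean())
    betas, _, coefs = lars_path(Xs, ya - y_mean, method="lasso")
    return LarsPath(betas, coefs, cols, mean[keep], std[keep], y_mean)


@dataclass
class CVResult:
    """Cross-validated MSE curve over a common penalty grid."""

    betas: np.ndarray
    mse_mean: np.ndarray
    mse_sd: np.ndarray
    best_beta: float
    seed: int | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.betas, "mse": self.mse_mean, "sd": self.mse_sd}
        )


def cv_select(
    X,
    y,
    folds: int = 5,
    seed: int | None = 0,
    n_grid: int = 100,
    fold_ids=None,
) -> CVResult:
    """Choose the lasso penalty by k-fold cross-validated MSE.

    Folds are assigned by a seeded permutation (or given explicitly via
    `fold_ids`); each fold's path is evaluated on a common beta grid built
    from the full-data path breakpoints plus log-spaced fill-in points, and
    the beta minimizing the mean MSE is returned (ties break toward the
    sparser model).
    """
    Xdf = pd.DataFrame(X)
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    if n < folds:
        raise ValueError("need at least as many rows as folds")
    full = fit_lars_lasso(Xdf, ya)
    bmax = float(full.betas[0])
    bmin = max(float(full.betas[-1]), bmax * 1e-6, 1e-12)
    grid = np.unique(
        np.concatenate(
            [
                full.betas,
                np.geomspace(bmin, max(bmax, bmin * 10), n_grid),
                [0.0],
            ]
        )
    )[::-1]
    if fold_ids is None:
        rng = np.random.default_rng(seed)
        fold_ids = rng.permutation(n) % folds
    fold_ids = np.asarray(fold_ids)
    mses = np.full((folds, grid.size), np.nan)
    for f in range(folds):
        test = fold_ids == f
        path = fit_lars_lasso(Xdf[~test], ya[~test])
        Xt = Xdf[test].to_numpy(dtype=float)
        for j, b in enumerate(grid):
            coef, intercept = path.raw_coefs_at(b)
            coef_full = np.zeros(Xdf.shape[1])
            for c, v in zip(path.columns, coef):
                coef_full[Xdf.columns.get_loc(c)] = v
            pred = Xt @ coef_full + intercept
            mses[f, j] = float(np.mean((ya[test] - pred) ** 2))
    mean = mses.mean(axis=0)
    sd = mses.std(axis=0, ddof=1)
    # ties toward larger beta (sparser); grid is decreasing
    best = float(grid[int(np.argmin(mean))])
    return CVResult(grid, mean, sd, best, seed)


@dataclass
class FittedDivergenceModel:
    """DDW coefficients at the CV-chosen penalty, on the raw feature scale."""

    words: list
    coefficients: np.ndarray
    intercept: float
    beta: float
    train_r: float | None
    cv: CVResult = None

    def predict(self, X) -> np.ndarray:
        Xdf = pd.DataFrame(X)
        Xa = Xdf[self.words].to_numpy(dtype=float) if set(self.words) <= set(
            Xdf.columns
        ) else Xdf.to_numpy(dtype=float)
        return Xa @ self.coefficients + self.intercept


def evaluate(model: FittedDivergenceModel, X, y) -> float | None:
    """Pearson r between predicted and observed divergence; ``None`` when
    the prediction has zero variance (e.g. an empty model)."""
    pred = model.predict(X)
    ya = np.asarray(y, dtype=float)
    if np.std(pred) == 0 or np.std(ya) == 0:
        return None
    return float(np.corrcoef(pred, ya)[0, 1])


def fit_divergence_model(
    X, y, folds: int = 5, seed: int | None = 0
) -> FittedDivergenceModel:
    """CV-select the penalty, refit on all data, and report the training
    correlation between predicted and observed divergence."""
    cv = cv_select(X, y, folds=folds, seed=seed)
    path = fit_lars_lasso(X, y)
    coef, intercept = path.raw_coefs_at(cv.best_beta)
    model = FittedDivergenceModel(
        path.columns, coef, intercept, cv.best_beta, None, cv
    )
    model.train_r = evaluate(model, pd.DataFrame(X)[path.columns], y)
    return model


def shuffled_control(
    ddws, seed: int | None = 0, max_retries: int = 50
) -> list[str]:
    """Nucleotide-shuffle each word, preserving base composition.

    Shuffles colliding with the original word or with another word already
    in the output are re-drawn up to `max_retries` times, then kept (a
    homopolymer has only one arrangement).
    """
    rng = np.random.default_rng(seed)
    out: list[str] = []
    originals = set(ddws)
    for w in ddws:
        letters = list(w)
        shuf = w
        for _ in range(max_retries):
            rng.shuffle(letters)
            cand = "".join(letters)
            if cand != w and cand not in originals and cand not in out:
                shuf = cand
                break
        else:
            shuf = "".join(letters)
        out.append(shuf)
    return out
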