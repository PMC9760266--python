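"""Fisher-LDA miRNA panel construction by beam search under LOOCV.

Panels of 1..k_max probes are grown greedily with beam width 10: the ten
best single probes (by leave-one-out cross-validated Fisher LDA AUC) seed
the search; each retained (k-1)-probe candidate is extended by every
residual probe, duplicate probe sets are collapsed, and the ten best
k-probe candidates are retained.  The mean LOOCV AUC of the ten retained
candidates is tracked per panel size, and the working panel size is the
smallest one whose mean AUC is within epsilon of the maximum ("ceiling"
rule).

LOOCV fits the discriminant weights within a fixed probe set; the probe-set
selection itself sits outside the cross-validation loop (candidate sets are
ranked by their LOOCV AUC), so reported AUCs carry selection optimism —
this matches the procedure being reproduced and is flagged in the result
summary.

Scores are oriented so that higher values indicate the event class, and the
intercept centers each score at the midpoint of the projected class means.
Tie-breaking everywhere is lexicographic on the sorted probe-index tuple,
making the search deterministic and platform-stable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import auc as _auc
from .preprocess import ExpressionMatrix

__all__ = [
    "fit_fisher_lda",
    "loocv_scores",
    "loocv_auc",
    "choose_panel_size",
    "DiscriminantCandidate",
    "PanelSearch",
    "PanelSearchResult",
    "beam_search",
]

_RIDGE = 1e-8  # relative ridge on the pooled covariance, x trace/k


def _class_stats(X: np.ndarray, y: np.ndarray):
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    d0 = X[y == 0] - mu0
    d1 = X[y == 1] - mu1
    scatter = d0.T @ d0 + d1.T @ d1
    return mu0, mu1, scatter


def _regularize(cov: np.ndarray) -> np.ndarray:
    k = cov.shape[-1]
    tr = np.trace(cov, axis1=-2, axis2=-1)
    lam = _RIDGE * tr / k
    eye = np.eye(k)
    if cov.ndim == 3:
        return cov + lam[:, None, None] * eye
    return cov + lam * eye


def fit_fisher_lda(X, y, ridge: float = _RIDGE) -> tuple[np.ndarray, float]:
    """Fisher discriminant weights and midpoint intercept on full data.

    weights = pooled-within-covariance^-1 (mu_event - mu_nonevent); the
    intercept places the score zero at the midpoint of the projected class
    means; higher score = event-like.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both classes must be present")
    n = len(y)
    mu0, mu1, scatter = _class_stats(X, y)
    cov = scatter / (n - 2)
    k = X.shape[1]
    cov = cov + (ridge * np.trace(cov) / k) * np.eye(k)
    try:
        w = np.linalg.solve(cov, mu1 - mu0)
    except np.linalg.LinAlgError:
        w = np.linalg.pinv(cov) @ (mu1 - mu0)
    b = -0.5 * float(w @ (mu0 + mu1))
    return w, b


def loocv_scores(X, y) -> np.ndarray:
    """Out-of-fold Fisher LDA score for every sample (vectorized LOO).

    For each left-out sample the class means and pooled scatter are
    downdated in closed form and the discriminant refitted on the remaining
    n-1 samples; the left-out sample is scored against the refitted
    midpoint.  Requires >= 2 samples per class.
    """
    X = np.ascontiguousarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).astype(int)
    n, k = X.shape
    if n < 4:
        raise ValueError("LOOCV needs n >= 4")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples so every fold keeps both classes")

    mu0, mu1, scatter = _class_stats(X, y)
    mu = np.where(y[:, None] == 1, mu1, mu0)
    D = X - mu                           # deviation from own-class mean
    nc = counts[y].astype(float)         # size of own class
    alpha = nc / (nc - 1.0)

    # scatter after removing sample i: rank-one downdate
    A = scatter[None, :, :] - alpha[:, None, None] * D[:, :, None] * D[:, None, :]
    A /= (n - 3)
    A = _regularize(A)

    sign = np.where(y == 1, -1.0, 1.0)
    delta = (mu1 - mu0)[None, :] + sign[:, None] * D / (nc - 1.0)[:, None]
    msum = (mu0 + mu1)[None, :] - D / (nc - 1.0)[:, None]

    try:
        W = np.linalg.solve(A, delta[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        W = np.stack([np.linalg.lstsq(A[i], delta[i], rcond=None)[0] for i in range(n)])
    return np.einsum("ij,ij->i", W, X - 0.5 * msum)


def loocv_auc(X, y) -> tuple[np.ndarray, float]:
    """Pooled out-of-fold scores and their AUC against the labels."""
    scores = loocv_scores(X, y)
    return scores, _auc(scores, np.asarray(y).astype(int))


def choose_panel_size(mean_aucs: Sequence[float], epsilon: float = 0.002) -> int:
    """Smallest panel size whose mean AUC is within epsilon of the maximum."""
    arr = np.asarray(list(mean_aucs), dtype=float)
    if arr.size == 0:
        raise ValueError("mean_aucs is empty")
    best = arr.max()
    return int(np.flatnonzero(arr >= best - epsilon)[0]) + 1


@dataclass
class DiscriminantCandidate:
    """One probe panel with its LOOCV performance and full-data fit."""

    probes: tuple[str, ...]
    probe_idx: tuple[int, ...]
    weights: np.ndarray
    intercept: float
    loocv_scores: np.ndarray
    auc: float

    def to_dict(self) -> dict:
        return {"probes": list(self.probes), "auc": self.auc,
                "weights": [float(w) for w in self.weights],
                "intercept": float(self.intercept)}


@dataclass
class PanelSearchResult:
    """Beam-search output: per-size candidate lists and the chosen size.

    ``levels[k]`` (1-based keys) holds the retained candidates at panel size
    k, sorted by descending LOOCV AUC; ``mean_aucs[k-1]`` is the mean AUC of
    those candidates; ``k_star`` the ceiling panel size; ``final_models``
    the retained candidates at ``k_star``.
    """

    levels: dict[int, list[DiscriminantCandidate]]
    mean_aucs: list[float]
    k_star: int
    beam: int
    epsilon: float

    @property
    def final_models(self) -> list[DiscriminantCandidate]:
        return self.levels[self.k_star]

    def mean_auc_table(self) -> pd.DataFrame:
        return pd.DataFrame({"n_probes": range(1, len(self.mean_aucs) + 1),
                             "mean_loocv_auc": self.mean_aucs}).set_index("n_probes")

    def summary(self) -> str:
        lines = ["Panel search (Fisher LDA, LOOCV AUC; selection outside the CV loop "
                 "— AUCs carry selection optimism)",
                 f"beam width {self.beam}, ceiling epsilon {self.epsilon:g}",
                 f"chosen panel size k* = {self.k_star}", "",
                 "size  mean LOOCV AUC"]
        for k, a in enumerate(self.mean_aucs, start=1):
            mark = "  <- k*" if k == self.k_star else ""
            lines.append(f"{k:4d}  {a:.4f}{mark}")
        lines.append("")
        lines.append(f"top candidates at k* = {self.k_star}:")
        for cand in self.final_models:
            lines.append(f"  AUC {cand.auc:.4f}  {' + '.join(cand.probes)}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "beam": self.beam, "epsilon": self.epsilon, "k_star": self.k_star,
            "mean_aucs": self.mean_aucs,
            "levels": {str(k): [c.to_dict() for c in cands] for k, cands in self.levels.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


class PanelSearch:
    """Beam search over probes scored by LOOCV Fisher-LDA AUC.

    Accepts a normalized :class:`ExpressionMatrix` (probes x samples) or a
    plain samples x probes array with probe names, plus binary outcome
    labels aligned with the samples.  ``fit()`` runs the search and returns
    a :class:`PanelSearchResult`.
    """

    def __init__(self, expr, y, k_max: int = 10, beam: int = 10, epsilon: float = 0.002,
                 probe_names: Sequence[str] | None = None):
        if isinstance(expr, ExpressionMatrix):
            self.X = np.ascontiguousarray(expr.values.to_numpy(dtype=float).T)
            self.probe_names = list(expr.values.index)
        elif isinstance(expr, pd.DataFrame):  # probes x samples
            self.X = np.ascontiguousarray(expr.to_numpy(dtype=float).T)
            self.probe_names = list(expr.index)
        else:
            self.X = np.ascontiguousarray(np.asarray(expr, dtype=float))
            self.probe_names = list(probe_names) if probe_names is not None else \
                [f"probe_{j}" for j in range(self.X.shape[1])]
        self.y = np.asarray(y).astype(int)
        if self.X.shape[0] != len(self.y):
            raise ValueError("expression matrix and labels cover different samples")
        if self.X.shape[1] < 1:
            raise ValueError("no probes to search over")
        self.k_max = min(int(k_max), self.X.shape[1])
        self.beam = int(beam)
        self.epsilon = float(epsilon)

    def _evaluate(self, idx: tuple[int, ...]) -> tuple[np.ndarray, float] | None:
        sub = self.X[:, list(idx)]
        try:
            scores = loocv_scores(sub, self.y)
        except np.linalg.LinAlgError:
            return None
        if not np.isfinite(scores).all():
            return None
        return scores, _auc(scores, self.y)

    def fit(self) -> PanelSearchResult:
        n_probes = self.X.shape[1]
        usable = [j for j in range(n_probes) if self.X[:, j].std() > 0]
        if len(usable) < n_probes:
            warnings.warn(f"skipping {n_probes - len(usable)} zero-variance probes")
        if not usable:
            raise ValueError("all probes have zero variance")

        levels: dict[int, list[DiscriminantCandidate]] = {}
        mean_aucs: list[float] = []
        frontier: list[tuple[int, ...]] = [()]
        for k in range(1, self.k_max + 1):
            seen: dict[tuple[int, ...], tuple[np.ndarray, float]] = {}
            for parent in frontier:
                pset = set(parent)
                for j in usable:
                    if j in pset:
                        continue
                    idx = tuple(sorted(pset | {j}))
                    if idx in seen:
                        continue
                    out = self._evaluate(idx)
                    if out is not None:
                        seen[idx] = out
            if not seen:
                break
            ranked = sorted(seen.items(), key=lambda kv: (-kv[1][1], kv[0]))
            if self.beam > len(ranked):
                warnings.warn(f"beam {self.beam} exceeds {len(ranked)} candidates at size {k}; keeping all")
            kept = ranked[: self.beam]
            cands = []
            for idx, (scores, a) in kept:
                w, b = fit_fisher_lda(self.X[:, list(idx)], self.y)
                cands.append(DiscriminantCandidate(
                    probes=tuple(self.probe_names[j] for j in idx), probe_idx=idx,
                    weights=w, intercept=b, loocv_scores=scores, auc=a))
            levels[k] = cands
            mean_aucs.append(float(np.mean([c.auc for c in cands])))
            frontier = [c.probe_idx for c in cands]
            if all(len(idx) >= len(usable) for idx in frontier):
                break
        k_star = choose_panel_size(mean_aucs, self.epsilon)
        return PanelSearchResult(levels=levels, mean_aucs=mean_aucs, k_star=k_star,
                                 beam=self.beam, epsilon=self.epsilon)


def beam_search(expr, y, k_max: int = 10, beam: int = 10, epsilon: float = 0.002,
                probe_names: Sequence[str] | None = None) -> PanelSearchResult:
    """Functional wrapper around :class:`PanelSearch`."""
    return PanelSearch(expr, y, k_max=k_max, beam=beam, epsilon=epsilon,
                       probe_names=probe_names).fit()
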