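"""Item descriptives, polychoric correlations, and the redundancy screen.

Polychoric correlations are estimated by the standard two-step maximum
likelihood: item thresholds are fixed at inverse-normal quantiles of the
cumulative category proportions, then the latent correlation of each item
pair is found by maximizing the bivariate-normal likelihood of the observed
contingency table over rho alone.  Missing responses are handled by
pairwise deletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtri

from ._bvn import bvn_cdf
from .data import ResponseMatrix

#: truncation for infinite thresholds on the standard-normal scale
THRESHOLD_CLIP = 8.0
#: hard bounds for the latent correlation
RHO_BOUND = 0.999


def estimate_thresholds(counts: Sequence[float]) -> np.ndarray:
    """Thresholds Phi^-1(cumulative proportion) from category counts 1..K.

    Unobserved leading/trailing categories give cumulative proportions of 0
    or 1; those thresholds are truncated to +/-8 to keep likelihoods finite.
    """
    counts = np.asarray(counts, dtype=float)
    if np.sum(counts > 0) < 2:
        raise ValueError("need at least 2 observed categories")
    cum = np.cumsum(counts)[:-1] / counts.sum()
    with np.errstate(divide="ignore"):
        thr = ndtri(cum)
    thr = np.clip(thr, -THRESHOLD_CLIP, THRESHOLD_CLIP)
    return thr


def _cell_probs(thr_i: np.ndarray, thr_j: np.ndarray, rho: float) -> np.ndarray:
    gi = np.concatenate([[-9.0], thr_i, [9.0]])
    gj = np.concatenate([[-9.0], thr_j, [9.0]])
    C = bvn_cdf(gi[:, None], gj[None, :], rho)
    P = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
    return np.clip(P, 1e-300, None)


def _pair_loglik(rho: float, table: np.ndarray, thr_i, thr_j) -> float:
    return float(np.sum(table * np.log(_cell_probs(thr_i, thr_j, rho))))


def polychoric_pair(x_i, x_j, xtol: float = 1e-6):
    """Two-step ML polychoric correlation of two ordinal vectors.

    Returns ``(rho, se, n_eff)``.  ``se`` comes from the observed
    information (negative second derivative of the profile log-likelihood)
    at the optimum and is NaN when the estimate sits at the +/-0.999 clamp.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    keep = ~(np.isnan(x_i) | np.isnan(x_j))
    xi, xj = x_i[keep].astype(int), x_j[keep].astype(int)
    n_eff = int(keep.sum())
    if n_eff < 20:
        raise ValueError(f"effective n = {n_eff} < 20 after pairwise deletion")
    if n_eff < 50:
        warnings.warn(f"effective n = {n_eff} < 50; estimate will be noisy")
    ci = np.bincount(xi)[1:]
    cj = np.bincount(xj)[1:]
    if np.sum(ci > 0) < 2 or np.sum(cj > 0) < 2:
        raise ValueError("need >= 2 observed categories per item")
    thr_i = estimate_thresholds(ci)
    thr_j = estimate_thresholds(cj)
    Ki, Kj = ci.size, cj.size
    table = np.zeros((Ki, Kj))
    np.add.at(table, (xi - 1, xj - 1), 1.0)

    res = optimize.minimize_scalar(
        lambda r: -_pair_loglik(r, table, thr_i, thr_j),
        bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": xtol})
    rho = float(res.x)
    # boundary handling: the bounded optimizer never quite reaches the bound
    if rho > RHO_BOUND - 2e-3 and (_pair_loglik(RHO_BOUND, table, thr_i, thr_j)
                                   >= _pair_loglik(rho, table, thr_i, thr_j)):
        rho = RHO_BOUND
    if rho < -RHO_BOUND + 2e-3 and (_pair_loglik(-RHO_BOUND, table, thr_i, thr_j)
                                    >= _pair_loglik(rho, table, thr_i, thr_j)):
        rho = -RHO_BOUND
    if abs(rho) >= RHO_BOUND:
        warnings.warn("polychoric estimate clamped at boundary; SE undefined")
        return rho, float("nan"), n_eff
    h = 1e-4
    d2 = (_pair_loglik(rho + h, table, thr_i, thr_j)
          - 2.0 * _pair_loglik(rho, table, thr_i, thr_j)
          + _pair_loglik(rho - h, table, thr_i, thr_j)) / h**2
    se = float(1.0 / np.sqrt(-d2)) if d2 < 0 else float("nan")
    return rho, se, n_eff


@dataclass
class PolychoricMatrix:
    """Symmetric latent-correlation matrix with per-pair metadata."""

    rho: np.ndarray
    item_ids: List[str]
    thresholds: Dict[str, np.ndarray]
    se: np.ndarray
    n_eff: np.ndarray

    @property
    def p(self) -> int:
        return len(self.item_ids)

    def pair_index(self) -> List[tuple]:
        return list(combinations(range(self.p), 2))

    def offdiag_vector(self) -> np.ndarray:
        """Unique off-diagonal correlations in (i<j) lexicographic order."""
        return np.array([self.rho[i, j] for i, j in self.pair_index()])

    def submatrix(self, items: Sequence[str]) -> "PolychoricMatrix":
        items = [str(i) for i in items]
        idx = np.array([self.item_ids.index(i) for i in items])
        return PolychoricMatrix(self.rho[np.ix_(idx, idx)], items,
                                {i: self.thresholds[i] for i in items},
                                self.se[np.ix_(idx, idx)],
                                self.n_eff[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.item_ids, columns=self.item_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def polychoric_matrix(X: ResponseMatrix, xtol: float = 1e-6) -> PolychoricMatrix:
    """All p(p-1)/2 pairwise polychoric correlations with pairwise deletion.

    Pairs violating preconditions (e.g. a constant item) yield NaN entries
    with a warning; downstream consumers must reject or handle them.
    """
    p = X.p
    if p < 2:
        raise ValueError("need at least 2 items")
    rho = np.eye(p)
    se = np.full((p, p), np.nan)
    n_eff = np.zeros((p, p), dtype=float)
    for i, j in combinations(range(p), 2):
        try:
            r, s, ne = polychoric_pair(X.values[:, i], X.values[:, j], xtol=xtol)
        except ValueError as exc:
            warnings.warn(f"pair ({X.item_ids[i]}, {X.item_ids[j]}) failed: {exc}")
            r, s, ne = np.nan, np.nan, 0
        rho[i, j] = rho[j, i] = r
        se[i, j] = se[j, i] = s
        n_eff[i, j] = n_eff[j, i] = ne
    thresholds = {}
    for iid in X.item_ids:
        counts = X.category_counts(iid)
        try:
            thresholds[iid] = estimate_thresholds(counts)
        except ValueError:
            thresholds[iid] = np.full(X.n_categories - 1, np.nan)
    return PolychoricMatrix(rho, list(X.item_ids), thresholds, se, n_eff)


def bootstrap_polychoric(X: ResponseMatrix, n_boot: int = 200, seed: int = 0,
                         xtol: float = 1e-5) -> np.ndarray:
    """Person-bootstrap replicates of the off-diagonal polychoric vector.

    Returns a ``(n_boot, p(p-1)/2)`` array in the same pair order as
    :meth:`PolychoricMatrix.offdiag_vector`; used to estimate the
    asymptotic covariance of the correlations for DWLS fitting.
    """
    rng = np.random.default_rng(seed)
    pairs = list(combinations(range(X.p), 2))
    out = np.empty((n_boot, len(pairs)))
    for b in range(n_boot):
        idx = rng.integers(0, X.n, size=X.n)
        vals = X.values[idx]
        for m, (i, j) in enumerate(pairs):
            try:
                r, _, _ = polychoric_pair(vals[:, i], vals[:, j], xtol=xtol)
            except ValueError:
                r = np.nan
            out[b, m] = r
    return out


def item_descriptives(X: ResponseMatrix, R: Optional[PolychoricMatrix] = None,
                      cutoff: float = 0.7) -> pd.DataFrame:
    """Per-item N, mean, SD, skewness, count of inter-item polychoric
    correlations above ``cutoff`` and mean inter-item correlation (signed).

    Skewness is the adjusted Fisher-Pearson sample estimator; it is NaN
    (with a warning) for zero-variance items.
    """
    if X.p < 2:
        raise ValueError("need at least 2 items")
    if R is None:
        R = polychoric_matrix(X)
    rows = []
    offmask = ~np.eye(X.p, dtype=bool)
    for j, iid in enumerate(X.item_ids):
        x = X.values[:, j]
        x = x[~np.isnan(x)]
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        if sd == 0.0:
            warnings.warn(f"item {iid} has zero variance; skewness undefined")
            skew = float("nan")
        else:
            skew = float(stats.skew(x, bias=False))
        r_row = R.rho[j][offmask[j]]
        rows.append({
            "item": iid, "N": int(x.size), "mean": float(np.mean(x)),
            "sd": sd, "skew": skew,
            "n_r_gt_cutoff": int(np.nansum(r_row > cutoff)),
            "mean_r": float(np.nanmean(r_row)),
        })
    return pd.DataFrame(rows).set_index("item")


@dataclass
class RedundancyScreen:
    """Pairs exceeding the redundancy cutoff, plus per-item summaries."""

    pairs: pd.DataFrame          # item_a, item_b, r_poly, se, n_eff (sorted)
    item_counts: pd.Series       # N_{r>cutoff} per item
    item_mean_r: pd.Series       # signed mean inter-item correlation
    n_pairs_total: int
    cutoff: float

    @property
    def n_flagged(self) -> int:
        return len(self.pairs)

    @property
    def proportion_flagged(self) -> float:
        return self.n_flagged / self.n_pairs_total


def redundancy_screen(R: PolychoricMatrix, cutoff: float = 0.7) -> RedundancyScreen:
    """All item pairs with r_poly > cutoff, ranked by correlation."""
    recs = []
    counts = {i: 0 for i in R.item_ids}
    for i, j in R.pair_index():
        r = R.rho[i, j]
        if np.isnan(r):
            continue
        if r > cutoff:
            recs.append({"item_a": R.item_ids[i], "item_b": R.item_ids[j],
                         "r_poly": r, "se": R.se[i, j], "n_eff": R.n_eff[i, j]})
            counts[R.item_ids[i]] += 1
            counts[R.item_ids[j]] += 1
    pairs = pd.DataFrame(recs, columns=["item_a", "item_b", "r_poly", "se", "n_eff"])
    if len(pairs):
        pairs = pairs.sort_values("r_poly", ascending=False).reset_index(drop=True)
    offmask = ~np.eye(R.p, dtype=bool)
    mean_r = pd.Series({iid: float(np.nanmean(R.rho[j][offmask[j]]))
                        for j, iid in enumerate(R.item_ids)})
    return RedundancyScreen(pairs, pd.Series(counts), mean_r,
                            n_pairs_total=R.p * (R.p - 1) // 2, cutoff=cutoff)
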