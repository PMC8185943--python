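"""One-factor confirmatory factor analysis for ordinal items.

The model is a correlation-structure model: the p(p-1)/2 polychoric
correlations r are fitted by sigma_jk(lambda) = lambda_j lambda_k with the
factor variance fixed at 1.  Estimation is diagonally weighted least
squares (DWLS): minimize (r - sigma)' W^-1 (r - sigma) with W the diagonal
of the asymptotic covariance Gamma of the correlations.  The test
statistic is the mean-and-variance corrected (scaled-and-shifted) version
of n*F, moment-matched through trace formulas on U*Gamma so that it has
mean df and variance 2df under the fitted model.

Gamma is estimated by a nonparametric person bootstrap of the polychoric
vector, which keeps the machinery agnostic to how the correlations were
estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

from ._bvn import bvn_cdf
from .data import ResponseMatrix
from .polychoric import (PolychoricMatrix, bootstrap_polychoric,
                         polychoric_matrix)


class ConvergenceError(RuntimeError):
    def __init__(self, msg, last_iterate=None):
        super().__init__(msg)
        self.last_iterate = last_iterate


def model_df(p: int) -> int:
    """Degrees of freedom of the one-factor correlation-structure model."""
    if p < 3:
        raise ValueError("one-factor model unidentified for p < 3")
    return p * (p - 1) // 2 - p


def smooth_correlation(R: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Eigenvalue-smooth a non-PSD correlation matrix (floor, rescale)."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= floor:
        return R
    warnings.warn("polychoric matrix not positive definite; eigenvalue-smoothed")
    vals = np.maximum(vals, floor)
    S = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def _delta_matrix(lam: np.ndarray, pairs) -> np.ndarray:
    """Jacobian d sigma_e / d lambda, shape (n_pairs, p)."""
    m, p = len(pairs), lam.size
    D = np.zeros((m, p))
    for e, (i, j) in enumerate(pairs):
        D[e, i] = lam[j]
        D[e, j] = lam[i]
    return D


class OrdinalFactorModel:
    """One-factor DWLS model for a polychoric correlation matrix.

    Parameters
    ----------
    R : PolychoricMatrix
    nobs : int
        Number of persons behind ``R``.
    gamma : (m, m) array, optional
        Asymptotic covariance of sqrt(n) * r over the unique correlations.
        Required for the corrected test statistic and fit indices; built
        automatically by :meth:`from_data`.
    weights : (m,) array, optional
        Override of the DWLS weight diagonal (e.g. ones for unweighted
        least squares); defaults to ``diag(gamma)``.
    """

    def __init__(self, R: PolychoricMatrix, nobs: int,
                 gamma: Optional[np.ndarray] = None,
                 weights: Optional[np.ndarray] = None):
        self.R = R
        self.nobs = int(nobs)
        self.pairs = R.pair_index()
        self.r = R.offdiag_vector()
        if np.any(np.isnan(self.r)):
            raise ValueError("polychoric matrix contains failed (NaN) entries")
        # smoothing guards the optimizer against indefinite inputs
        Rs = smooth_correlation(R.rho)
        if not np.allclose(Rs, R.rho):
            self.r = np.array([Rs[i, j] for i, j in self.pairs])
        self.gamma = gamma
        if weights is not None:
            self.w = np.asarray(weights, dtype=float)
        elif gamma is not None:
            self.w = np.diag(gamma).copy()
        else:
            self.w = np.ones_like(self.r)
        if np.any(self.w <= 0):
            raise ValueError("non-positive DWLS weights")

    @classmethod
    def from_data(cls, X: ResponseMatrix, n_boot: int = 200, seed: int = 0,
                  R: Optional[PolychoricMatrix] = None,
                  boot_reps: Optional[np.ndarray] = None) -> "OrdinalFactorModel":
        """Estimate the polychoric matrix and bootstrap Gamma from raw data.

        ``boot_reps`` (replicate correlation vectors) may be passed to reuse
        a bootstrap computed on a superset of items.
        """
        if R is None:
            R = polychoric_matrix(X)
        if boot_reps is None:
            boot_reps = bootstrap_polychoric(X, n_boot=n_boot, seed=seed)
        reps = boot_reps[~np.any(np.isnan(boot_reps), axis=1)]
        if reps.shape[0] < max(20, boot_reps.shape[0] // 2):
            raise RuntimeError("too many failed bootstrap replicates for Gamma")
        gamma = np.cov(reps, rowvar=False) * X.n
        model = cls(R, X.n, gamma=gamma)
        model._boot_reps = boot_reps
        return model

    # -- estimation -------------------------------------------------------
    def _discrepancy(self, lam: np.ndarray):
        sig = np.array([lam[i] * lam[j] for i, j in self.pairs])
        e = self.r - sig
        F = float(np.sum(e * e / self.w))
        D = _delta_matrix(lam, self.pairs)
        grad = -2.0 * D.T @ (e / self.w)
        return F, grad

    def fit(self, start: Optional[np.ndarray] = None, maxiter: int = 500,
            ftol: float = 1e-8) -> "OrdinalFactorResults":
        p = self.R.p
        model_df(p)  # validates p >= 3
        if start is None:
            Rfull = self.R.rho.copy()
            np.fill_diagonal(Rfull, 1.0)
            vals, vecs = np.linalg.eigh(Rfull)
            v = vecs[:, -1] * np.sqrt(max(vals[-1], 1e-6))
            if v.sum() < 0:
                v = -v
            start = np.clip(v, -0.95, 0.95)
        res = optimize.minimize(
            self._discrepancy, start, jac=True, method="L-BFGS-B",
            bounds=[(-0.999, 0.999)] * p,
            options={"maxiter": maxiter, "ftol": ftol * 1e-4, "gtol": 1e-10})
        if not res.success and res.status != 1:  # 1 = maxiter
            raise ConvergenceError(f"DWLS fit failed: {res.message}",
                                   last_iterate=res.x)
        if res.status == 1:
            raise ConvergenceError("DWLS fit hit iteration cap",
                                   last_iterate=res.x)
        lam = res.x
        if np.any(np.abs(lam) > 0.9989):
            warnings.warn("Heywood case: loading clamped near |1|")
        return OrdinalFactorResults(self, lam, res.fun)


@dataclass
class OrdinalFactorResults:
    """Fitted one-factor DWLS solution."""

    model: OrdinalFactorModel
    loadings_: np.ndarray
    discrepancy: float

    def __post_init__(self):
        self.converged = True
        m = self.model
        self.df = model_df(m.R.p)
        self.nobs = m.nobs
        self.T_dwls = m.nobs * self.discrepancy
        self._corr = self._correction()
        if self._corr is not None:
            a, b = self._corr
            self.statistic = max((self.T_dwls - b) / a, 0.0)
            self.pvalue = float(stats.chi2.sf(self.statistic, self.df)) \
                if self.df > 0 else float("nan")
        else:
            self.statistic = self.T_dwls
            self.pvalue = float("nan")

    # -- parameter tables -------------------------------------------------
    @property
    def loadings(self) -> pd.Series:
        return pd.Series(self.loadings_, index=self.model.R.item_ids,
                         name="loading")

    @property
    def communalities(self) -> pd.Series:
        return pd.Series(self.loadings_**2, index=self.model.R.item_ids,
                         name="communality")

    @property
    def residual_variances(self) -> pd.Series:
        return (1.0 - self.communalities).rename("residual_variance")

    @property
    def fitted_correlations(self) -> np.ndarray:
        lam = self.loadings_
        return np.array([lam[i] * lam[j] for i, j in self.model.pairs])

    @property
    def residuals(self) -> np.ndarray:
        return self.model.r - self.fitted_correlations

    def loading_table(self) -> pd.DataFrame:
        return pd.DataFrame({"loading": self.loadings,
                             "communality": self.communalities,
                             "residual_variance": self.residual_variances})

    # -- scaled-shifted statistic -----------------------------------------
    def _residual_operator(self) -> np.ndarray:
        m = self.model
        D = _delta_matrix(self.loadings_, m.pairs)
        Winv = 1.0 / m.w
        A = D.T * Winv  # p x m
        H = A @ D
        U = np.diag(Winv) - A.T @ np.linalg.solve(H, A)
        return U

    def _correction(self):
        m = self.model
        if m.gamma is None or self.df <= 0:
            return None
        U = self._residual_operator()
        UG = U @ m.gamma
        c1 = float(np.trace(UG))
        c2 = float(np.trace(UG @ UG))
        if c2 <= 0:
            return None
        a = np.sqrt(c2 / self.df)
        b = c1 - a * self.df
        return a, b

    # -- fit indices ------------------------------------------------------
    def _baseline(self):
        """Independence baseline fitted with the same estimator."""
        m = self.model
        F_b = float(np.sum(m.r**2 / m.w))
        T_b = m.nobs * F_b
        df_b = len(m.r)
        if m.gamma is not None:
            UG = (m.gamma.T / m.w).T  # W^-1 Gamma
            c1 = float(np.trace(UG))
            c2 = float(np.trace(UG @ UG))
            a = np.sqrt(c2 / df_b)
            b = c1 - a * df_b
            T_b = max((T_b - b) / a, 0.0)
        return T_b, df_b

    def fit_indices(self, alpha: float = 0.10) -> pd.Series:
        """CFI, TLI, RMSEA with 90% CI, SRMR, CRMR, WRMR."""
        n, df, T = self.nobs, self.df, self.statistic
        T_b, df_b = self._baseline()
        num = max(T - df, 0.0)
        den = max(T_b - df_b, 1e-12)
        cfi = min(1.0 - num / den, 1.0)
        if T_b > df_b and df > 0:
            tli = ((T_b / df_b) - (T / df)) / ((T_b / df_b) - 1.0)
            tli = min(tli, 1.0)
        else:
            tli = float("nan")
        rmsea = np.sqrt(num / (df * n)) if df > 0 else float("nan")
        lo, hi = _rmsea_ci(T, df, n, alpha)
        e = self.residuals
        srmr = float(np.sqrt(np.mean(e**2)))
        wrmr = float("nan")
        if self.model.gamma is not None:
            v = np.diag(self.model.gamma) / n
            wrmr = float(np.sqrt(np.sum(e**2 / v) / e.size))
        return pd.Series({"CFI": cfi, "TLI": tli, "RMSEA": rmsea,
                          "RMSEA_lo": lo, "RMSEA_hi": hi,
                          "SRMR": srmr, "CRMR": srmr, "WRMR": wrmr})

    # -- misspecification analysis ----------------------------------------
    def modification_indices(self, epc_cutoff: float = 0.1,
                             alpha: float = 0.05) -> pd.DataFrame:
        """Score-test MI, EPC and power for freeing each residual correlation.

        The MI is the 1-df score statistic in the DWLS metric for adding a
        residual correlation between a pair; EPC is the predicted value of
        that correlation; power is the probability of detecting |EPC| = 0.1
        at level ``alpha`` given the observed information (Saris-style
        decision table).  A pair is flagged when |EPC| >= ``epc_cutoff``.
        """
        m = self.model
        D = _delta_matrix(self.loadings_, m.pairs)
        Winv = 1.0 / m.w
        A = D.T * Winv
        Hinv = np.linalg.inv(A @ D)
        e = self.residuals
        crit = stats.chi2.ppf(1.0 - alpha, 1)
        rows = []
        for k, (i, j) in enumerate(m.pairs):
            q = A[:, k]
            h = Winv[k] - q @ Hinv @ q
            if h <= 1e-12:
                rows.append({"item_a": m.R.item_ids[i], "item_b": m.R.item_ids[j],
                             "mi": 0.0, "epc": 0.0, "power": float("nan"),
                             "flag": False})
                continue
            score = e[k] * Winv[k]
            epc = score / h
            mi = self.nobs * score * epc
            ncp = mi * (epc_cutoff / epc) ** 2 if epc != 0 else float("inf")
            power = float(stats.ncx2.sf(crit, 1, ncp))
            rows.append({"item_a": m.R.item_ids[i], "item_b": m.R.item_ids[j],
                         "mi": float(mi), "epc": float(epc), "power": power,
                         "flag": bool(abs(epc) >= epc_cutoff)})
        return (pd.DataFrame(rows)
                .sort_values("mi", ascending=False)
                .reset_index(drop=True))

    def summary(self) -> str:
        lines = ["One-factor ordinal CFA (DWLS, mean-and-variance corrected)",
                 f"  n = {self.nobs}, items = {self.model.R.p}",
                 f"  T = {self.statistic:.3f}, df = {self.df}, "
                 f"p = {self.pvalue:.4g}", ""]
        lines.append(self.loading_table().round(3).to_string())
        try:
            lines += ["", self.fit_indices().round(3).to_string()]
        except Exception:
            pass
        return "\n".join(lines)


def _rmsea_ci(T: float, df: int, n: int, alpha: float = 0.10):
    """Noncentral-chi-square inversion for the RMSEA confidence interval."""
    if df <= 0 or not np.isfinite(T):
        return float("nan"), float("nan")

    def solve(q):
        # find ncp with P(chi2_df(ncp) <= T) = q
        if stats.chi2.cdf(T, df) < q:
            return 0.0
        f = lambda nc: stats.ncx2.cdf(T, df, nc) - q
        hi = max(T * 2, 10.0)
        while f(hi) > 0:
            hi *= 2
            if hi > 1e7:
                return float("nan")
        return optimize.brentq(f, 1e-12, hi)

    lo = solve(1.0 - alpha / 2.0)
    hi = solve(alpha / 2.0)
    c = df * n
    return (np.sqrt(lo / c) if np.isfinite(lo) else lo,
            np.sqrt(hi / c) if np.isfinite(hi) else hi)


# -- Green-Yang categorical omega -----------------------------------------

def _ordinal_cov(tau_j: np.ndarray, tau_k: np.ndarray, rho: float) -> float:
    """Cov(X_j, X_k) of integer-scored ordinal variables with underlying
    bivariate-normal correlation ``rho`` and thresholds tau."""
    if rho >= 1.0:
        raise ValueError("rho must be < 1 for the bivariate kernel")
    P2 = bvn_cdf(tau_j[:, None], tau_k[None, :], rho)
    P1 = np.outer(ndtr(tau_j), ndtr(tau_k))
    return float(np.sum(P2 - P1))


def _ordinal_var(tau: np.ndarray) -> float:
    """Var(X) for integer scores 1..K with normal thresholds tau."""
    cum = np.concatenate([[0.0], ndtr(tau), [1.0]])
    probs = np.diff(cum)
    k = np.arange(1, probs.size + 1)
    mu = np.sum(k * probs)
    return float(np.sum(k * k * probs) - mu * mu)


@dataclass
class ReliabilityResult:
    omega: float
    ci: tuple
    n_boot: int

    def __repr__(self):
        lo, hi = self.ci
        return (f"ReliabilityResult(omega={self.omega:.3f}, "
                f"95% CI [{lo:.3f}, {hi:.3f}], n_boot={self.n_boot})")


def omega_from_params(loadings: np.ndarray, thresholds: Sequence[np.ndarray]) -> float:
    """Green-Yang categorical omega from loadings and item thresholds.

    Ratio of the model-implied true-score variance of the unit-weighted sum
    score to the total sum-score variance, both reconstructed from
    bivariate-normal category probabilities.
    """
    lam = np.asarray(loadings, dtype=float)
    taus = [np.asarray(t, dtype=float) for t in thresholds]
    p = lam.size
    num = 0.0
    den = 0.0
    for j in range(p):
        num += _ordinal_cov(taus[j], taus[j], min(lam[j] ** 2, 0.999))
        den += _ordinal_var(taus[j])
    for j in range(p):
        for k in range(j + 1, p):
            c = _ordinal_cov(taus[j], taus[k], np.clip(lam[j] * lam[k], -0.999, 0.999))
            num += 2.0 * c
            den += 2.0 * c
    return float(num / den)


def omega_categorical(results: OrdinalFactorResults, X: ResponseMatrix,
                      n_boot: int = 1000, seed: int = 0,
                      n_jack_groups: int = 20) -> ReliabilityResult:
    """Omega with a bias-corrected and accelerated bootstrap CI.

    Each resample redraws persons, re-estimates thresholds and polychoric
    correlations, refits the one-factor model (weights held at the original
    DWLS diagonal) and recomputes omega.  Acceleration uses a grouped
    (delete-block) jackknife.
    """
    ids = results.model.R.item_ids
    taus = [results.model.R.thresholds[i] for i in ids]
    omega_hat = omega_from_params(results.loadings_, taus)

    def refit_omega(Xs: ResponseMatrix) -> float:
        Rb = polychoric_matrix(Xs.select_items(ids), xtol=1e-5)
        mb = OrdinalFactorModel(Rb, Xs.n, weights=results.model.w)
        rb = mb.fit(start=results.loadings_.copy())
        return omega_from_params(rb.loadings_, [Rb.thresholds[i] for i in ids])

    rng = np.random.default_rng(seed)
    boots, failures = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, X.n, size=X.n)
        try:
            boots.append(refit_omega(X.select_persons(idx)))
        except Exception:
            failures += 1
    if failures > 0.1 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap resamples failed")
    boots = np.asarray(boots)

    # BCa: bias correction from the bootstrap distribution, acceleration
    # from a grouped jackknife
    eps = 1.0 / (2.0 * boots.size)
    prop = np.clip(np.mean(boots < omega_hat), eps, 1 - eps)
    z0 = ndtri(prop)
    groups = np.array_split(rng.permutation(X.n), n_jack_groups)
    jack = []
    for g in groups:
        mask = np.ones(X.n, dtype=bool)
        mask[g] = False
        try:
            jack.append(refit_omega(X.select_persons(mask)))
        except Exception:
            pass
    jack = np.asarray(jack)
    if jack.size >= 3:
        d = jack.mean() - jack
        denom = 6.0 * (np.sum(d * d) ** 1.5)
        a = float(np.sum(d**3) / denom) if denom > 0 else 0.0
    else:
        a = 0.0

    def bca_q(alpha):
        z = ndtri(alpha)
        adj = ndtr(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        return float(np.quantile(boots, adj))

    return ReliabilityResult(omega_hat, (bca_q(0.025), bca_q(0.975)),
                             int(boots.size))
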