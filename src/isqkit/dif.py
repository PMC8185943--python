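"""Differential item functioning via iterative Wald tests on a
multiple-group graded response model, plus group construction and the
demographic regression on latent scores.

The procedure is anchor-based and two-stage: every item is first tested
with all other items as anchors (the focal group's latent mean and
variance re-estimated each time); items flagged after
Benjamini-Hochberg FDR correction are then removed from the anchor set
and all items are re-tested against the purified anchors.  Omnibus Wald
statistics test an item's slope and thresholds jointly between groups,
with the parameter covariance taken from the empirical cross-product
information of the multigroup model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ResponseMatrix
from .grm import (ConvergenceError, GradedResponseModel, GRMResults,
                  _item_tables, _mstep_objective, _pack, _unpack,
                  default_quadrature)
from .simulate import ItemParams

# -- group construction -----------------------------------------------------


@dataclass
class GroupSpec:
    variable: str
    rule: str
    group_names: Tuple[str, str]
    labels: pd.Series          # per-person group label; NaN = excluded
    n_excluded: int = 0

    def counts(self) -> pd.Series:
        return self.labels.value_counts()


def make_groups(covariates: pd.DataFrame, variable: str,
                cutpoint: Optional[float] = None,
                mapping: Optional[dict] = None) -> GroupSpec:
    """Dichotomize a covariate into reference/focal groups.

    Numeric variables use ``cutpoint`` with boundary values assigned to the
    "<=" group.  Categorical variables with more than two levels require an
    explicit ``mapping`` from level to group label (levels mapped to None
    are excluded).
    """
    if variable not in covariates.columns:
        raise ValueError(f"covariate {variable!r} not present")
    col = covariates[variable]
    present = col.notna()
    if present.mean() < 0.9:
        raise ValueError(f"covariate {variable!r} present for "
                         f"{present.mean():.0%} of persons (< 90%)")
    if present.mean() < 1.0:
        warnings.warn(f"{(~present).sum()} persons excluded: missing {variable}")
    if cutpoint is not None:
        lo, hi = f"{variable}<={cutpoint:g}", f"{variable}>{cutpoint:g}"
        labels = pd.Series(np.where(col <= cutpoint, lo, hi), index=col.index,
                           dtype=object)
        rule = f"{variable} > {cutpoint:g} vs <= {cutpoint:g}"
        names = (lo, hi)
    else:
        levels = sorted(col.dropna().unique().tolist())
        if mapping is None:
            if len(levels) != 2:
                raise ValueError(
                    f"{variable!r} has {len(levels)} levels; provide a mapping")
            mapping = {levels[0]: str(levels[0]), levels[1]: str(levels[1])}
        labels = col.map(mapping).astype(object)
        names = tuple(sorted(set(v for v in mapping.values() if v is not None)))
        if len(names) != 2:
            raise ValueError("mapping must produce exactly 2 groups")
        rule = f"{variable} mapped to {names}"
    labels[~present] = np.nan
    counts = labels.value_counts()
    for g in names:
        n = int(counts.get(g, 0))
        if n < 10:
            raise ValueError(f"group {g!r} has only {n} members")
        if n < 50:
            warnings.warn(f"group {g!r} has only {n} members")
    return GroupSpec(variable, rule, names, labels,
                     n_excluded=int((labels.isna()).sum()))


# -- multiple-group GRM -----------------------------------------------------


class MultigroupGRMModel:
    """Two-group GRM with shared item parameters except a released set.

    The reference group's latent trait is fixed to N(0, 1); the focal
    group's mean and variance are free.  Estimation reuses the single-group
    Bock-Aitkin machinery with group-specific quadrature weights.
    """

    def __init__(self, X: ResponseMatrix, group_labels: Sequence,
                 reference: Optional[str] = None, n_quad: int = 61,
                 quad_bound: float = 6.0):
        labels = np.asarray(pd.Series(group_labels, dtype=object))
        keep = pd.notna(labels)
        if not keep.all():
            X = X.select_persons(np.where(keep)[0])
            labels = labels[keep]
        names = list(pd.unique(labels))
        if len(names) != 2:
            raise ValueError(f"need exactly 2 groups, got {names}")
        if reference is not None:
            names = [reference] + [g for g in names if g != reference]
        self.group_names = names
        self.X = X
        self.labels = labels
        self.nodes, base_w = default_quadrature(n_quad, quad_bound)
        self.masks = {g: labels == g for g in names}
        for g, m in self.masks.items():
            if m.sum() < 1:
                raise ValueError(f"group {g} is empty")
        self.codes = np.where(np.isnan(X.values), 0, X.values - 1).astype(int)
        self.obs = ~np.isnan(X.values)

    def _group_weights(self, mu: float, sigma: float) -> np.ndarray:
        w = np.exp(-0.5 * ((self.nodes - mu) / sigma) ** 2)
        return w / w.sum()

    def fit(self, free_items: Set[str] = frozenset(),
            start: Optional[dict] = None, tol: float = 1e-4,
            maxiter: int = 500) -> "MultigroupGRMResults":
        X, nodes = self.X, self.nodes
        p, K = X.p, X.n_categories
        ref, focal = self.group_names
        free = {str(i) for i in free_items}
        unknown = free - set(X.item_ids)
        if unknown:
            raise ValueError(f"free_items not in data: {unknown}")

        if start is not None:
            params = {iid: {g: ItemParams(iid, prm[g].slope,
                                          prm[g].thresholds.copy())
                            for g in self.group_names}
                      for iid, prm in start["items"].items()}
            mu_f, sig_f = start["focal_mean"], start["focal_sd"]
        else:
            sg = GradedResponseModel(X, n_quad=nodes.size,
                                     quad_bound=float(nodes.max()))
            init = sg._start_values()
            params = {it.item_id: {g: ItemParams(it.item_id, it.slope,
                                                 it.thresholds.copy())
                                   for g in self.group_names}
                      for it in init}
            mu_f, sig_f = 0.0, 1.0

        zs = {iid: {g: _pack(params[iid][g].slope, params[iid][g].thresholds)
                    for g in self.group_names} for iid in X.item_ids}
        bounds0 = [(np.log(0.01), np.log(50.0)), (-12.0, 12.0)]
        from .grm import _LOG_GAP_MAX, _LOG_GAP_MIN
        nb = bounds0 + [(_LOG_GAP_MIN, _LOG_GAP_MAX)] * (K - 2)

        last_ll = -np.inf
        ll_trace = []
        for it_num in range(maxiter):
            gw = {ref: self._group_weights(0.0, 1.0),
                  focal: self._group_weights(mu_f, sig_f)}
            # E-step
            acc = np.empty((X.n, nodes.size))
            for g in self.group_names:
                acc[self.masks[g]] = np.log(gw[g])[None, :]
            for j, iid in enumerate(X.item_ids):
                for g in self.group_names:
                    m = self.masks[g]
                    it = params[iid][g]
                    _, P = _item_tables(it.slope, it.thresholds, nodes)
                    logP = np.log(P)
                    contrib = logP[:, self.codes[m, j]].T
                    acc[m] += np.where(self.obs[m][:, [j]], contrib, 0.0)
            from scipy.special import logsumexp
            ll_i = logsumexp(acc, axis=1)
            ll = float(ll_i.sum())
            ll_trace.append(ll)
            if ll < last_ll - 1e-6 * abs(last_ll):
                raise ConvergenceError("EM log-likelihood decreased", ll_trace)
            post = np.exp(acc - ll_i[:, None])

            max_delta = 0.0
            # latent update for the focal group
            pf = post[self.masks[focal]]
            Eth = pf @ nodes
            Eth2 = pf @ nodes**2
            mu_new = float(Eth.mean())
            sig_new = float(np.sqrt(max(Eth2.mean() - mu_new**2, 1e-4)))
            max_delta = max(abs(mu_new - mu_f), abs(sig_new - sig_f))
            mu_f, sig_f = mu_new, sig_new

            # M-step for items
            for j, iid in enumerate(X.item_ids):
                tables = {}
                for g in self.group_names:
                    m = self.masks[g] & self.obs[:, j]
                    r = np.zeros((nodes.size, K))
                    pm = post[m]
                    cj = self.codes[m, j]
                    for k in range(K):
                        sel = cj == k
                        if sel.any():
                            r[:, k] = pm[sel].sum(axis=0)
                    tables[g] = r
                if iid in free:
                    for g in self.group_names:
                        from scipy import optimize
                        tg = tables[g] / max(tables[g].sum(), 1e-300)
                        res = optimize.minimize(
                            _mstep_objective, zs[iid][g], args=(tg, nodes),
                            jac=True, method="L-BFGS-B", bounds=nb,
                            options={"maxiter": 50})
                        a_new, b_new = _unpack(res.x)
                        old = np.concatenate([[params[iid][g].slope],
                                              params[iid][g].thresholds])
                        new = np.concatenate([[a_new], b_new])
                        max_delta = max(max_delta, float(np.max(np.abs(new - old))))
                        params[iid][g] = ItemParams(iid, a_new, b_new)
                        zs[iid][g] = res.x
                else:
                    from scipy import optimize
                    pooled = tables[ref] + tables[focal]
                    pooled = pooled / max(pooled.sum(), 1e-300)
                    res = optimize.minimize(
                        _mstep_objective, zs[iid][ref], args=(pooled, nodes),
                        jac=True, method="L-BFGS-B", bounds=nb,
                        options={"maxiter": 50})
                    a_new, b_new = _unpack(res.x)
                    old = np.concatenate([[params[iid][ref].slope],
                                          params[iid][ref].thresholds])
                    new = np.concatenate([[a_new], b_new])
                    max_delta = max(max_delta, float(np.max(np.abs(new - old))))
                    for g in self.group_names:
                        params[iid][g] = ItemParams(iid, a_new, b_new)
                        zs[iid][g] = res.x
            if it_num > 0 and (max_delta < tol
                               or abs(ll - last_ll) < 1e-7 * (1 + abs(ll) * 1e-4)):
                return MultigroupGRMResults(self, params, free, mu_f, sig_f,
                                            ll, it_num + 1, ll_trace)
            last_ll = ll
        raise ConvergenceError(f"multigroup EM did not converge in {maxiter} "
                               "iterations", ll_trace)


@dataclass
class MultigroupGRMResults:
    model: MultigroupGRMModel
    params: Dict[str, Dict[str, ItemParams]]
    free_items: Set[str]
    focal_mean: float
    focal_sd: float
    loglik: float
    n_iter: int
    ll_trace: List[float] = field(repr=False, default_factory=list)

    def start_dict(self) -> dict:
        return {"items": self.params, "focal_mean": self.focal_mean,
                "focal_sd": self.focal_sd}

    # -- empirical information over the full parameter vector --------------
    def _score_columns(self):
        """Per-person score matrix over (item blocks, focal mean/sd)."""
        mdl = self.model
        X, nodes = mdl.X, mdl.nodes
        ref, focal = mdl.group_names
        gw = {ref: mdl._group_weights(0.0, 1.0),
              focal: mdl._group_weights(self.focal_mean, self.focal_sd)}
        acc = np.empty((X.n, nodes.size))
        for g in mdl.group_names:
            acc[mdl.masks[g]] = np.log(gw[g])[None, :]
        tabs = {}
        for j, iid in enumerate(X.item_ids):
            for g in mdl.group_names:
                m = mdl.masks[g]
                it = self.params[iid][g]
                _, P = _item_tables(it.slope, it.thresholds, nodes)
                tabs[(iid, g)] = P
                logP = np.log(P)
                contrib = logP[:, mdl.codes[m, j]].T
                acc[m] += np.where(mdl.obs[m][:, [j]], contrib, 0.0)
        from scipy.special import logsumexp
        post = np.exp(acc - logsumexp(acc, axis=1)[:, None])

        cols, names = [], []
        K = X.n_categories
        for j, iid in enumerate(X.item_ids):
            blocks = ([("shared", None)] if iid not in self.free_items
                      else [(g, g) for g in mdl.group_names])
            for tag, g_only in blocks:
                sc = np.zeros((X.n, K))  # a + thresholds columns, K = 1+(K-1)
                for g in mdl.group_names:
                    if g_only is not None and g != g_only:
                        continue
                    it = self.params[iid][g]
                    P = tabs[(iid, g)]
                    pstar = 1.0 / (1.0 + np.exp(
                        -it.slope * (nodes[:, None] - it.thresholds)))
                    s = pstar * (1.0 - pstar)
                    tmb = nodes[:, None] - it.thresholds[None, :]
                    dPda = np.zeros_like(P)
                    dPda[:, :-1] += s * tmb
                    dPda[:, 1:] -= s * tmb
                    dlda = dPda / P
                    m = mdl.masks[g] & mdl.obs[:, j]
                    cj = mdl.codes[:, j]
                    sc[m, 0] += np.sum(post[m] * dlda[:, cj[m]].T, axis=1)
                    for mth in range(K - 1):
                        dPdb = np.zeros_like(P)
                        dPdb[:, mth] += -it.slope * s[:, mth]
                        dPdb[:, mth + 1] += it.slope * s[:, mth]
                        dldb = dPdb / P
                        sc[m, 1 + mth] += np.sum(post[m] * dldb[:, cj[m]].T,
                                                 axis=1)
                cols.append(sc)
                names += [f"{iid}:{tag}:a"] + \
                         [f"{iid}:{tag}:b{k+1}" for k in range(K - 1)]
        # focal latent scores
        mu, sig = self.focal_mean, self.focal_sd
        gmu = (nodes - mu) / sig**2
        gsig = -1.0 / sig + (nodes - mu) ** 2 / sig**3
        mfoc = mdl.masks[focal]
        wf = gw[focal]
        sc_lat = np.zeros((X.n, 2))
        sc_lat[mfoc, 0] = post[mfoc] @ gmu - wf @ gmu
        sc_lat[mfoc, 1] = post[mfoc] @ gsig - wf @ gsig
        cols.append(sc_lat)
        names += ["focal:mean", "focal:sd"]
        return np.hstack(cols), names

    def wald_test(self, item_id: str):
        """Omnibus Wald chi-square for group differences in one released
        item's slope and thresholds, with its per-parameter follow-ups."""
        item_id = str(item_id)
        if item_id not in self.free_items:
            raise ValueError(f"{item_id} was not released in this fit")
        S, names = self._score_columns()
        info = S.T @ S
        cov = np.linalg.pinv(info)
        ref, focal = self.model.group_names
        i1 = [k for k, nm in enumerate(names) if nm.startswith(f"{item_id}:{ref}:")]
        i2 = [k for k, nm in enumerate(names) if nm.startswith(f"{item_id}:{focal}:")]
        p1 = self.params[item_id][ref]
        p2 = self.params[item_id][focal]
        d = np.concatenate([[p1.slope - p2.slope], p1.thresholds - p2.thresholds])
        V = (cov[np.ix_(i1, i1)] + cov[np.ix_(i2, i2)]
             - cov[np.ix_(i1, i2)] - cov[np.ix_(i2, i1)])
        try:
            stat = float(d @ np.linalg.solve(V, d))
        except np.linalg.LinAlgError:
            stat = float(d @ np.linalg.pinv(V) @ d)
        df = d.size
        pval = float(stats.chi2.sf(stat, df))
        se = np.sqrt(np.maximum(np.diag(V), 1e-300))
        z = d / se
        follow = pd.DataFrame({
            "parameter": ["slope"] + [f"b{k+1}" for k in range(d.size - 1)],
            "difference": d, "se": se, "z": z,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        })
        return stat, df, pval, follow


# -- iterative Wald DIF procedure -------------------------------------------


@dataclass
class DifResult:
    table: pd.DataFrame            # item, wald, df, p, p_fdr, flagged, stage
    anchors: List[str]
    focal_mean: float
    focal_sd: float
    followups: Dict[str, pd.DataFrame]
    group_spec: Optional[GroupSpec] = None

    @property
    def flagged(self) -> List[str]:
        return list(self.table.loc[self.table.flagged, "item"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def iterative_wald_dif(X: ResponseMatrix, group_labels: Sequence,
                       reference: Optional[str] = None, alpha: float = 0.05,
                       n_stages: int = 2, n_quad: int = 61,
                       em_tol: float = 1e-4,
                       group_spec: Optional[GroupSpec] = None) -> DifResult:
    """Two-stage (configurable) iterative Wald DIF scan over all items.

    Stage 1 tests each item with all other items as anchors; items flagged
    at BH-FDR ``alpha`` lose anchor status and every item is re-tested
    against the purified anchors in the next stage.
    """
    if X.p < 4:
        raise ValueError("need >= 4 items so that anchors exist")
    mdl = MultigroupGRMModel(X, group_labels, reference=reference,
                             n_quad=n_quad)
    base = mdl.fit(free_items=set(), tol=em_tol)
    flagged: Set[str] = set()
    table = None
    followups: Dict[str, pd.DataFrame] = {}
    last_fit = base
    for stage in range(1, n_stages + 1):
        rows = []
        for iid in X.item_ids:
            release = (flagged | {iid}) if stage > 1 else {iid}
            fit = mdl.fit(free_items=release, start=base.start_dict(),
                          tol=em_tol)
            stat, df, pval, follow = fit.wald_test(iid)
            rows.append({"item": iid, "wald": stat, "df": df, "p": pval,
                         "stage": stage})
            followups[iid] = follow
            last_fit = fit
        table = pd.DataFrame(rows)
        rej, p_fdr, _, _ = multipletests(table["p"], alpha=alpha,
                                         method="fdr_bh")
        table["p_fdr"] = p_fdr
        table["flagged"] = rej
        new_flagged = set(table.loc[table.flagged, "item"])
        if len(new_flagged) == X.p:
            raise RuntimeError("all items flagged; no anchors remain")
        if new_flagged == flagged and stage > 1:
            break
        flagged = new_flagged
    anchors = [i for i in X.item_ids if i not in flagged]
    followups = {i: followups[i] for i in flagged} if flagged else {}
    return DifResult(table, anchors, last_fit.focal_mean, last_fit.focal_sd,
                     followups, group_spec)


# -- demographic regression -------------------------------------------------


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    rsquared: float
    beta_f_minus_m: float
    n_used: int
    n_excluded: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse,
                             "p": self.pvalues})


def regress_scores(scores: pd.DataFrame, covariates: pd.DataFrame,
                   sex_levels: Tuple[str, str] = ("M", "F")) -> RegressionResult:
    """OLS of the latent trait score on age, sex, and age x sex.

    Persons outside the binary ``sex_levels`` or with missing data are
    excluded listwise (counts reported).  Age is centred at the sample mean
    so that ``beta_f_minus_m`` — the sex main-effect contrast (second level
    minus first) — refers to a person of average age despite the
    interaction term.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({
        "theta": np.asarray(scores["theta"], dtype=float),
        "age": np.asarray(covariates["age"], dtype=float),
        "sex": np.asarray(covariates["sex"], dtype=object),
    })
    n_total = len(df)
    df = df[df.sex.isin(sex_levels)].dropna()
    n_used = len(df)
    if n_used < 10:
        raise ValueError("too few complete cases for regression")
    if np.var(df.theta.to_numpy()) < 1e-12:
        raise ValueError("degenerate (constant) scores")
    female = (df.sex == sex_levels[1]).astype(float)
    age_c = df.age.to_numpy() - df.age.to_numpy().mean()
    Xd = pd.DataFrame({"age": age_c, "sex_F": female.to_numpy()})
    Xd["age_x_sex"] = Xd.age * Xd.sex_F
    Xd = sm.add_constant(Xd)
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(df.theta.to_numpy(), Xd).fit()
    return RegressionResult(fit.params, fit.bse, fit.pvalues,
                            float(fit.rsquared), float(fit.params["sex_F"]),
                            n_used, n_total - n_used)
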