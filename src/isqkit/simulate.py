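"""Synthetic ordinal questionnaire data with known graded-response structure.

The generator emulates the structure the downstream pipeline assumes and is
the source of every test fixture in the package: a unidimensional latent
trait, logistic graded-response items, optional "doublet" item pairs that
share variance beyond the common trait (content redundancy), optional
group differences in item parameters (DIF), two-cohort sampling, and a
small completely-at-random missingness rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import ResponseMatrix

#: residual SD of the standard logistic, used for the slope <-> loading map
LOGISTIC_SD = np.pi / np.sqrt(3.0)


@dataclass
class ItemParams:
    """Graded-response item: discrimination ``slope`` (logistic metric) and
    ordered category thresholds ``thresholds`` (length K-1, trait units)."""

    item_id: str
    slope: float
    thresholds: np.ndarray
    n_categories: int = field(init=False)

    def __post_init__(self):
        self.thresholds = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        if not np.isfinite(self.slope) or self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        if self.thresholds.size < 1 or np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        self.n_categories = self.thresholds.size + 1

    @property
    def loading(self) -> float:
        """Standardized loading implied by the slope: a / sqrt(a^2 + pi^2/3)."""
        return slope_to_loading(self.slope)

    def to_dict(self) -> dict:
        return {"item_id": self.item_id, "slope": float(self.slope),
                "thresholds": [float(t) for t in self.thresholds]}

    @classmethod
    def from_dict(cls, d: dict) -> "ItemParams":
        return cls(d["item_id"], d["slope"], np.asarray(d["thresholds"]))


def slope_to_loading(a) -> float:
    a = np.asarray(a, dtype=float)
    return a / np.sqrt(a * a + LOGISTIC_SD**2)


def loading_to_slope(lam) -> float:
    lam = np.asarray(lam, dtype=float)
    return lam * LOGISTIC_SD / np.sqrt(1.0 - lam * lam)


def grm_category_probs(theta, item: ItemParams) -> np.ndarray:
    """P(X = k | theta) for k = 1..K under the logistic graded response model.

    ``theta`` may be scalar or an array; the category axis is last.
    P*(X >= k) = logistic(a (theta - b_{k-1})), P*(X >= 1) = 1.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    z = item.slope * (theta[..., None] - item.thresholds)  # (..., K-1)
    pstar = 1.0 / (1.0 + np.exp(-z))
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    cum = np.concatenate([ones, pstar, zeros], axis=-1)  # P*(X>=k), k=1..K+1
    return -np.diff(cum, axis=-1)


@dataclass
class DifEffect:
    """A group-specific shift on one item parameter.

    ``parameter`` is ``"slope"`` (delta added to a_j), ``"thresholds"``
    (delta added to every b_jk) or ``"threshold<k>"`` (single threshold).
    """

    item_id: str
    parameter: str
    delta: float
    group: Optional[str] = None  # defaults to the last (focal) group


@dataclass
class SimConfig:
    items: List[ItemParams]
    n_per_group: Dict[str, int]
    group_theta_means: Optional[Dict[str, float]] = None
    doublets: List[Tuple[Tuple[str, str], float]] = field(default_factory=list)
    dif_spec: List[DifEffect] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0
    covariate_overrides: Optional[Dict[str, dict]] = None

    def __post_init__(self):
        if not self.items:
            raise ValueError("no items")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        seen: set = set()
        for (a, b), gamma in self.doublets:
            if not 0.0 < gamma < 1.0:
                raise ValueError("doublet loading must be in (0, 1)")
            if a == b or a in seen or b in seen:
                raise ValueError("doublet pairs must be disjoint")
            if a not in ids or b not in ids:
                raise ValueError(f"doublet refers to unknown item ({a}, {b})")
            seen |= {a, b}
        for d in self.dif_spec:
            if d.item_id not in ids:
                raise ValueError(f"dif_spec refers to unknown item {d.item_id}")

    @property
    def groups(self) -> List[str]:
        return list(self.n_per_group)


def default_items(p: int = 20, n_categories: int = 7, seed: int = 12345,
                  slope_range: Tuple[float, float] = (1.0, 2.5),
                  min_gap: float = 0.3) -> List[ItemParams]:
    """Ground-truth item bank: slopes uniform on ``slope_range``; thresholds
    from sorted standard-normal draws pushed apart to at least ``min_gap``
    and recentred on their pre-spacing mean."""
    rng = np.random.default_rng(seed)
    items = []
    for j in range(p):
        a = rng.uniform(*slope_range)
        t = np.sort(rng.normal(0.0, 1.0, size=n_categories - 1))
        centre = t.mean()
        for k in range(1, t.size):
            t[k] = max(t[k], t[k - 1] + min_gap)
        t = t - t.mean() + centre
        items.append(ItemParams(f"item{j + 1}", a, t))
    return items


def study_like_config(seed: int = 12345, missing_rate: float = 4e-5,
                      doublet_loading: float = 0.5) -> SimConfig:
    """Default study conditions: adult (n=495) and adolescent (n=187)
    cohorts, 20 seven-category items, six redundant doublet pairs
    (12 doublet memberships), ~0.004% missing responses.

    Item slopes are set from the published 20-item standardized loadings
    (strong general factor, loadings 0.61-0.89) so the simulated
    polychoric matrix reproduces the scale's redundancy regime; thresholds
    follow the generator's default spacing rule.
    """
    from .isq import ISQ20_LOADINGS

    base = default_items(20, 7, seed=seed)
    items = [ItemParams(it.item_id,
                        float(loading_to_slope(ISQ20_LOADINGS[it.item_id])),
                        it.thresholds) for it in base]
    pairs = [("item5", "item13"), ("item3", "item11"), ("item10", "item14"),
             ("item19", "item20"), ("item1", "item17"), ("item12", "item16")]
    return SimConfig(
        items=items,
        n_per_group={"adult": 495, "adolescent": 187},
        group_theta_means={"adult": 0.0, "adolescent": 0.0},
        doublets=[(pr, doublet_loading) for pr in pairs],
        missing_rate=missing_rate,
        seed=seed,
    )


# Annual-household-income bracket midpoints (USD) and sampling weights for
# the synthetic covariate table.
_INCOME_MID = np.array([10_000, 28_000, 43_000, 58_000, 73_000,
                        90_500, 115_500, 145_500, 180_000], dtype=float)
_INCOME_W = np.array([156, 103, 89, 57, 70, 53, 55, 30, 29], dtype=float)


def _draw_covariates(rng, group: str, n: int) -> pd.DataFrame:
    if group.lower().startswith("adol"):
        age = np.clip(rng.normal(15.4, 1.4, n), 13.0, 17.9)
    elif group.lower().startswith("adult"):
        age = np.clip(rng.normal(37.2, 13.3, n), 18.0, 78.0)
    else:
        age = np.clip(rng.normal(35.0, 12.0, n), 18.0, 80.0)
    sex = rng.choice(["M", "F"], size=n, p=[0.516, 0.484])
    gender = np.where(rng.random(n) < 0.96,
                      np.where(sex == "M", "cis_male", "cis_female"),
                      rng.choice(["trans_male", "trans_female", "nonbinary"], size=n))
    income = rng.choice(_INCOME_MID, size=n, p=_INCOME_W / _INCOME_W.sum())
    return pd.DataFrame({"age": age, "sex": sex, "gender": gender,
                         "income": income, "cohort": group})


def _conditional_coefs(item: ItemParams, gamma: float):
    """Slope on the trait, slope on the doublet factor, and thresholds of the
    conditional logistic model, with the doublet factor carrying standardized
    loading ``gamma`` and the common loading rescaled to lam*sqrt(1-gamma^2)
    so the item's standardized underlying-variable scale is preserved."""
    a, b = item.slope, item.thresholds
    s = np.sqrt(a * a + LOGISTIC_SD**2)
    lam = a / s
    tau = a * b / s  # thresholds on the unit underlying scale
    lam_c = lam * np.sqrt(1.0 - gamma**2)
    resid_sd = np.sqrt(1.0 - lam_c**2 - gamma**2)
    c = resid_sd / LOGISTIC_SD
    return lam_c / c, gamma / c, tau / c


def _sample_item(rng, item: ItemParams, lin: np.ndarray, thr: np.ndarray) -> np.ndarray:
    """Sample categories from cumulative logistic probs at linear predictor
    ``lin`` against thresholds ``thr`` (both already on the logistic scale)."""
    pstar = 1.0 / (1.0 + np.exp(-(lin[:, None] - thr[None, :])))  # P(X>=k+1)
    u = rng.random(lin.shape[0])[:, None]
    return 1 + (u < pstar).sum(axis=1)


def simulate_responses(config: SimConfig):
    """Draw a ResponseMatrix and a full ground-truth record.

    Returns ``(X, truth)`` where ``truth`` holds the generating item
    parameters, the per-person latent traits, doublet/DIF structure and the
    seed — everything a recovery test needs.
    """
    rng = np.random.default_rng(config.seed)
    ids = [it.item_id for it in config.items]
    means = config.group_theta_means or {}
    doublet_of = {}
    for di, ((ia, ib), gamma) in enumerate(config.doublets):
        doublet_of[ia] = (di, gamma)
        doublet_of[ib] = (di, gamma)

    frames, thetas, groups_col = [], [], []
    blocks = []
    for g, n in config.n_per_group.items():
        theta = rng.normal(means.get(g, 0.0), 1.0, size=n)
        u = rng.normal(0.0, 1.0, size=(n, max(len(config.doublets), 1)))
        vals = np.empty((n, len(ids)), dtype=float)
        for j, item in enumerate(config.items):
            a, b = item.slope, item.thresholds.copy()
            for d in config.dif_spec:
                focal = d.group if d.group is not None else config.groups[-1]
                if d.item_id == item.item_id and g == focal:
                    if d.parameter == "slope":
                        a = a + d.delta
                    elif d.parameter == "thresholds":
                        b = b + d.delta
                    elif d.parameter.startswith("threshold"):
                        b[int(d.parameter[len("threshold"):]) - 1] += d.delta
                    else:
                        raise ValueError(f"unknown DIF parameter {d.parameter}")
            eff = ItemParams(item.item_id, a, b)
            if item.item_id in doublet_of:
                di, gamma = doublet_of[item.item_id]
                A, D, T = _conditional_coefs(eff, gamma)
                lin = A * theta + D * u[:, di]
            else:
                lin, T = eff.slope * theta, eff.slope * eff.thresholds
            vals[:, j] = _sample_item(rng, eff, lin, T)
        frames.append(vals)
        thetas.append(theta)
        groups_col.extend([g] * n)
        blocks.append(_draw_covariates(rng, g, n))

    values = np.vstack(frames)
    theta = np.concatenate(thetas)
    cov = pd.concat(blocks, ignore_index=True)
    if config.covariate_overrides:
        for g, over in config.covariate_overrides.items():
            mask = np.asarray(groups_col) == g
            for col, val in over.items():
                cov.loc[mask, col] = val
    if config.missing_rate > 0:
        miss = rng.random(values.shape) < config.missing_rate
        values[miss] = np.nan

    K = config.items[0].n_categories
    X = ResponseMatrix(values, ids, covariates=cov, n_categories=K)
    truth = {
        "items": [it.to_dict() for it in config.items],
        "loadings": {it.item_id: float(it.loading) for it in config.items},
        "doublets": [{"pair": list(pr), "loading": g} for pr, g in config.doublets],
        "dif": [{"item_id": d.item_id, "parameter": d.parameter,
                 "delta": d.delta, "group": d.group or config.groups[-1]}
                for d in config.dif_spec],
        "group_theta_means": {g: float(means.get(g, 0.0)) for g in config.groups},
        "theta": theta,
        "group": np.asarray(groups_col),
        "seed": config.seed,
    }
    return X, truth


def write_simulation(X: ResponseMatrix, truth: dict, prefix) -> None:
    """Write responses.csv, covariates.csv and ground_truth.json."""
    from pathlib import Path

    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    X.to_csv(prefix / "responses.csv", prefix / "covariates.csv")
    record = {k: v for k, v in truth.items() if k not in ("theta", "group")}
    record["theta"] = [float(t) for t in truth["theta"]]
    record["group"] = [str(g) for g in truth["group"]]
    with open(prefix / "ground_truth.json", "w") as fh:
        json.dump(record, fh, indent=1)
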