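"""Core data container for person-by-item ordinal response matrices."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class ResponseMatrix:
    """n persons x p items of ordinal responses coded 1..K, NaN = missing.

    Parameters
    ----------
    values : (n, p) float array
        Integer categories 1..K stored as floats so that NaN can mark
        missing responses.
    item_ids : sequence of str
        Column labels, one per item.
    person_ids : sequence, optional
        Row labels; defaults to 0..n-1.
    covariates : DataFrame, optional
        Per-person covariates (age, sex, gender, income, cohort, ...),
        indexed like ``person_ids``.
    n_categories : int, optional
        K. Inferred from the data maximum when omitted.
    """

    values: np.ndarray
    item_ids: Sequence[str]
    person_ids: Optional[Sequence] = None
    covariates: Optional[pd.DataFrame] = None
    n_categories: Optional[int] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n == 0 or p == 0:
            raise ValueError("empty response matrix")
        if len(self.item_ids) != p:
            raise ValueError("item_ids length does not match columns")
        self.item_ids = list(map(str, self.item_ids))
        if self.person_ids is None:
            self.person_ids = list(range(n))
        else:
            self.person_ids = list(self.person_ids)
            if len(self.person_ids) != n:
                raise ValueError("person_ids length does not match rows")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and (np.any(obs < 1) or np.any(obs != np.round(obs))):
            raise ValueError("responses must be integer categories >= 1")
        if self.n_categories is None:
            self.n_categories = int(obs.max()) if obs.size else 2
        elif obs.size and obs.max() > self.n_categories:
            raise ValueError("observed category exceeds n_categories")

    # -- basic properties -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, item) -> np.ndarray:
        return self.values[:, self.item_ids.index(str(item))]

    def category_counts(self, item) -> np.ndarray:
        """Observed counts of categories 1..K for one item."""
        x = self.column(item)
        x = x[~np.isnan(x)].astype(int)
        return np.bincount(x, minlength=self.n_categories + 1)[1:]

    # -- subsetting -------------------------------------------------------
    def select_items(self, items: Sequence) -> "ResponseMatrix":
        items = [str(i) for i in items]
        idx = [self.item_ids.index(i) for i in items]
        return ResponseMatrix(self.values[:, idx], items, self.person_ids,
                              self.covariates, self.n_categories)

    def select_persons(self, mask_or_idx) -> "ResponseMatrix":
        arr = np.asarray(mask_or_idx)
        vals = self.values[arr]
        pids = list(np.asarray(self.person_ids, dtype=object)[arr])
        cov = self.covariates.iloc[arr] if self.covariates is not None else None
        return ResponseMatrix(vals, self.item_ids, pids, cov, self.n_categories)

    # -- I/O --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.person_ids, name="person_id"),
                            columns=self.item_ids)

    def to_csv(self, path, covariates_path=None) -> None:
        """Write responses (empty cell = missing) and, optionally, covariates."""
        df = self.to_frame()
        df.to_csv(path, float_format="%.0f")
        if covariates_path is not None and self.covariates is not None:
            self.covariates.to_csv(covariates_path)

    @classmethod
    def from_csv(cls, path, covariates_path=None, n_categories=None) -> "ResponseMatrix":
        df = pd.read_csv(path, index_col=0)
        cov = None
        if covariates_path is not None and Path(covariates_path).exists():
            cov = pd.read_csv(covariates_path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns),
                   list(df.index), cov, n_categories)
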