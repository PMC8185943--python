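"""Criterion-driven item elimination and response-category collapsing.

The reduction loop removes items until (a) no polychoric correlation
between two retained items exceeds the cutoff and (b) the misspecification
analysis flags no retained pair with |EPC| at or above its cutoff.  Every
removal is logged with its reason and supporting statistics so the run can
be audited, and the retained set is re-checked against both criteria
before the trace is returned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .cfa import OrdinalFactorModel
from .data import ResponseMatrix
from .polychoric import (PolychoricMatrix, bootstrap_polychoric,
                         polychoric_matrix, redundancy_screen)
from .simulate import ItemParams, grm_category_probs


class ReductionError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace


@dataclass
class ReductionConfig:
    corr_cutoff: float = 0.7
    epc_cutoff: float = 0.1
    generality: Dict[str, float] = field(default_factory=dict)
    max_iterations: int = 50
    batch_mode: bool = False          # remove all high-count items in one block
    batch_count_threshold: int = 5    # count that defines "many" correlations
    n_boot: int = 200                 # bootstrap reps behind the CFA weights
    seed: int = 0

    def __post_init__(self):
        if self.corr_cutoff <= 0 or self.epc_cutoff <= 0:
            raise ValueError("cutoffs must be positive")

    def more_general(self, a: str, b: str) -> str:
        ga, gb = self.generality.get(a), self.generality.get(b)
        if ga is None or gb is None or ga == gb:
            raise ReductionError(
                f"generality ranking does not adjudicate pair ({a}, {b})")
        return a if ga > gb else b


@dataclass
class RemovalEvent:
    item: str
    iteration: int
    reason: str                       # high-correlation-count |
    stats: dict = field(default_factory=dict)  # pairwise-redundancy | misspecification-flag

    def to_dict(self) -> dict:
        return {"item": self.item, "iteration": self.iteration,
                "reason": self.reason, "stats": self.stats}


@dataclass
class ReductionTrace:
    events: List[RemovalEvent]
    retained: List[str]
    original: List[str]

    @property
    def removed(self) -> List[str]:
        return [e.item for e in self.events]

    def to_dict(self) -> dict:
        return {"events": [e.to_dict() for e in self.events],
                "retained": self.retained, "original": self.original}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _screen_counts(R: PolychoricMatrix, cutoff: float):
    scr = redundancy_screen(R, cutoff)
    return scr, scr.item_counts, scr.item_mean_r


def reduce_items(X: ResponseMatrix, R: Optional[PolychoricMatrix] = None,
                 config: Optional[ReductionConfig] = None,
                 boot_reps: Optional[np.ndarray] = None) -> ReductionTrace:
    """Iteratively eliminate redundant items until both criteria hold.

    Per outer iteration: (1) items with two or more supra-cutoff
    correlations are removed one at a time, highest count first (ties
    broken by higher mean correlation, then lower generality), re-screening
    after each removal; in ``batch_mode`` all items above
    ``batch_count_threshold`` counts go in one block first; (2) each
    remaining isolated supra-cutoff pair loses its less-general member;
    (3) the one-factor CFA is refit on the survivors and the less-general
    member of the top-MI pair with |EPC| >= cutoff is removed.  The loop
    repeats until neither screen flags anything.
    """
    config = config or ReductionConfig()
    if R is None:
        R = polychoric_matrix(X)
    if boot_reps is None:
        boot_reps = bootstrap_polychoric(X, n_boot=config.n_boot,
                                         seed=config.seed)
    full_pairs = {(R.item_ids[i], R.item_ids[j]): m
                  for m, (i, j) in enumerate(R.pair_index())}

    def sub_boot(items: Sequence[str]) -> np.ndarray:
        cols = []
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                key = (items[a], items[b])
                cols.append(full_pairs.get(key, full_pairs.get(key[::-1])))
        return boot_reps[:, cols]

    items = list(R.item_ids)
    events: List[RemovalEvent] = []
    did_batch = False

    def remove(item, iteration, reason, stats):
        items.remove(item)
        events.append(RemovalEvent(item, iteration, reason, stats))

    for iteration in range(1, config.max_iterations + 1):
        changed = False
        # -- step 1: high-correlation-count offenders ----------------------
        while True:
            Rs = R.submatrix(items)
            scr, counts, mean_r = _screen_counts(Rs, config.corr_cutoff)
            if config.batch_mode and not did_batch:
                did_batch = True
                block = counts[counts > config.batch_count_threshold]
                for item in list(block.index):
                    remove(item, iteration, "high-correlation-count",
                           {"n_r_gt_cutoff": int(counts[item]),
                            "mean_r": float(mean_r[item]), "batch": True})
                    changed = True
                if len(block):
                    continue
            if counts.max() < 2:
                break
            top = counts[counts == counts.max()].index
            if len(top) > 1:
                sub = mean_r[top]
                top = sub[sub == sub.max()].index
            if len(top) > 1:
                gen = {i: config.generality.get(i) for i in top}
                if any(v is None for v in gen.values()):
                    raise ReductionError(
                        f"generality needed to break tie among {list(top)}",
                        ReductionTrace(events, items, list(R.item_ids)))
                top = [min(gen, key=gen.get)]
            item = top[0]
            remove(item, iteration, "high-correlation-count",
                   {"n_r_gt_cutoff": int(counts[item]),
                    "mean_r": float(mean_r[item])})
            changed = True
        # -- step 2: isolated supra-cutoff pairs ---------------------------
        while True:
            Rs = R.submatrix(items)
            scr, _, _ = _screen_counts(Rs, config.corr_cutoff)
            if not len(scr.pairs):
                break
            row = scr.pairs.iloc[0]
            keep = config.more_general(row.item_a, row.item_b)
            drop = row.item_b if keep == row.item_a else row.item_a
            remove(drop, iteration, "pairwise-redundancy",
                   {"pair": [row.item_a, row.item_b],
                    "r_poly": float(row.r_poly), "kept": keep})
            changed = True
        # -- step 3: misspecification flags --------------------------------
        while True:
            Rs = R.submatrix(items)
            model = OrdinalFactorModel.from_data(
                X.select_items(items), R=Rs, boot_reps=sub_boot(items))
            res = model.fit()
            mi = res.modification_indices(epc_cutoff=config.epc_cutoff)
            flagged = mi[mi.flag]
            if not len(flagged):
                break
            row = flagged.iloc[0]  # largest MI among flagged
            keep = config.more_general(row.item_a, row.item_b)
            drop = row.item_b if keep == row.item_a else row.item_a
            remove(drop, iteration, "misspecification-flag",
                   {"pair": [row.item_a, row.item_b], "mi": float(row.mi),
                    "epc": float(row.epc), "kept": keep})
            changed = True
        if not changed:
            break
    else:
        raise ReductionError("criteria unreachable before iteration cap",
                             ReductionTrace(events, items, list(R.item_ids)))

    # post-condition audit
    Rs = R.submatrix(items)
    scr, _, _ = _screen_counts(Rs, config.corr_cutoff)
    assert not len(scr.pairs), "retained set still has supra-cutoff pairs"
    model = OrdinalFactorModel.from_data(X.select_items(items), R=Rs,
                                         boot_reps=sub_boot(items))
    mi = model.fit().modification_indices(epc_cutoff=config.epc_cutoff)
    assert not mi.flag.any(), "retained set still has EPC flags"
    return ReductionTrace(events, items, list(R.item_ids))


# -- response-category collapsing -------------------------------------------

@dataclass
class CollapseMap:
    """Surjective nondecreasing map from old categories to new ones."""

    mapping: Dict[int, int]

    def __post_init__(self):
        self.mapping = {int(k): int(v) for k, v in self.mapping.items()}
        ks = sorted(self.mapping)
        if ks != list(range(1, len(ks) + 1)):
            raise ValueError("map domain must be 1..K_old")
        vs = [self.mapping[k] for k in ks]
        if any(b - a not in (0, 1) for a, b in zip(vs, vs[1:])) or vs[0] != 1:
            raise ValueError("map must be nondecreasing and onto 1..K_new")

    @property
    def k_old(self) -> int:
        return len(self.mapping)

    @property
    def k_new(self) -> int:
        return max(self.mapping.values())

    def apply(self, values: np.ndarray) -> np.ndarray:
        out = np.full_like(values, np.nan, dtype=float)
        for old, new in self.mapping.items():
            out[values == old] = new
        bad = ~np.isnan(values) & np.isnan(out)
        if bad.any():
            raise ValueError("responses outside the collapse-map domain")
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({str(k): v for k, v in self.mapping.items()}, fh)

    @classmethod
    def from_json(cls, path) -> "CollapseMap":
        with open(path) as fh:
            return cls({int(k): v for k, v in json.load(fh).items()})

    @classmethod
    def identity(cls, k: int) -> "CollapseMap":
        return cls({i: i for i in range(1, k + 1)})


def apply_collapse(X: ResponseMatrix, cmap: CollapseMap) -> ResponseMatrix:
    """Recode every non-missing response through the collapse map."""
    obs = X.values[~np.isnan(X.values)]
    if obs.size and obs.max() > cmap.k_old:
        raise ValueError("response exceeds collapse-map domain")
    return ResponseMatrix(cmap.apply(X.values), X.item_ids, X.person_ids,
                          X.covariates, cmap.k_new)


def detect_collapsible_categories(item_params: Sequence[ItemParams],
                                  grid: Optional[np.ndarray] = None) -> Dict[str, list]:
    """Categories whose characteristic curve is nowhere the most probable.

    Evaluated pointwise on a dense trait grid (at least 81 points spanning
    [-4, 4]); returns a per-item sorted list of such categories.
    """
    if grid is None:
        grid = np.linspace(-4.0, 4.0, 161)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 81:
        raise ValueError("grid too coarse: need >= 81 points")
    if grid.min() > -4.0 or grid.max() < 4.0:
        raise ValueError("grid must span at least [-4, 4]")
    out = {}
    for it in item_params:
        P = grm_category_probs(grid, it)
        winners = set(np.argmax(P, axis=1) + 1)
        out[it.item_id] = sorted(set(range(1, it.n_categories + 1)) - winners)
    return out


def derive_collapse_map(item_params: Sequence[ItemParams],
                        grid: Optional[np.ndarray] = None,
                        min_item_fraction: float = 0.5) -> CollapseMap:
    """One shared collapse map for the scale.

    An interior category is marked collapsible when it is never the most
    probable response for at least ``min_item_fraction`` of the items.
    Adjacent collapsible categories are merged pairwise (2/3-style); no new
    category absorbs more than two original ones, a trailing unpaired
    category stays separate, and the extreme categories are never merged.
    """
    K = item_params[0].n_categories
    colls = detect_collapsible_categories(item_params, grid)
    counts = {k: 0 for k in range(2, K)}
    for cats in colls.values():
        for k in cats:
            if 2 <= k <= K - 1:
                counts[k] += 1
    flagged = sorted(k for k, c in counts.items()
                     if c >= min_item_fraction * len(item_params))
    # pair up adjacent flagged categories, left to right
    merges: List[tuple] = []
    used: set = set()
    i = 0
    while i < len(flagged) - 1:
        if flagged[i + 1] == flagged[i] + 1:
            merges.append((flagged[i], flagged[i + 1]))
            used |= {flagged[i], flagged[i + 1]}
            i += 2
        else:
            i += 1
    # a lone flagged category joins its weaker interior neighbour (the one
    # whose characteristic curve peaks lower, averaged over items)
    if grid is None:
        grid = np.linspace(-4.0, 4.0, 161)
    peak = np.zeros(K + 1)
    for it in item_params:
        peak[1:] += grm_category_probs(np.asarray(grid), it).max(axis=0)
    for k in flagged:
        if k in used:
            continue
        cands = [m for m in (k - 1, k + 1)
                 if 2 <= m <= K - 1 and m not in used]
        if not cands:
            continue
        mate = min(cands, key=lambda m: peak[m])
        merges.append((min(k, mate), max(k, mate)))
        used |= {k, mate}
    mapping = {}
    new = 0
    merged_into = {b: a for a, b in merges}
    for old in range(1, K + 1):
        if old in merged_into:
            mapping[old] = mapping[merged_into[old]]
        else:
            new += 1
            mapping[old] = new
    return CollapseMap(mapping)
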