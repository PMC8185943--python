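"""Score-calculator: convert response patterns into calibrated latent
trait estimates (EAP), posterior SDs, person reliabilities and T-scores.

Replicates the computation of the online scoring tool: 7-point responses
are first passed through the calibration's collapse map, then scored with
the calibrated item parameters; T = 50 + 10 * theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .data import ResponseMatrix
from .grm import GRMResults, load_calibration
from .reduction import CollapseMap, apply_collapse


@dataclass
class ScoreTable:
    """Per-person scores plus a report of rejected input rows."""

    table: pd.DataFrame
    scale_used: int
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def score_responses(calibration: Union[str, dict, GRMResults],
                    responses: Union[str, ResponseMatrix],
                    scale: Optional[int] = None) -> ScoreTable:
    """Score a response table against a calibration artifact.

    ``scale`` is 5 or 7 (default: inferred from the calibration's item
    parameters when omitted); 7-point input requires the calibration to
    carry a collapse map.  Response columns must match the calibration
    item ids exactly; rows containing out-of-range values are rejected
    individually and reported.
    """
    if isinstance(calibration, GRMResults):
        results = calibration
        cmap_dict = getattr(calibration, "collapse_map", None)
    else:
        results = load_calibration(calibration)
        cmap_dict = results.collapse_map
    if isinstance(responses, (str,)) or hasattr(responses, "__fspath__"):
        X = ResponseMatrix.from_csv(responses)
    else:
        X = responses

    want = list(results.item_ids)
    have = list(X.item_ids)
    missing = [i for i in want if i not in have]
    extra = [i for i in have if i not in want]
    if missing:
        raise ValueError(f"response columns missing items {missing}"
                         + (f"; unknown columns {extra}" if extra else ""))
    X = X.select_items(want)

    K_cal = results.item_params[0].n_categories
    if scale is None:
        scale = K_cal
    if scale not in (5, 7) and scale != K_cal:
        raise ValueError(f"scale must be the calibrated {K_cal} or 7")

    obs = X.values
    bad_rows = np.zeros(X.n, dtype=bool)
    with np.errstate(invalid="ignore"):
        bad_rows |= np.any((obs < 1) | (obs > scale), axis=1) & ~np.all(
            np.isnan(obs), axis=1)
        bad_rows |= np.any((obs > scale), axis=1)
    rejected = pd.DataFrame({
        "person_id": np.asarray(X.person_ids, dtype=object)[bad_rows],
        "reason": f"response outside 1..{scale}",
    })
    if bad_rows.any():
        X = X.select_persons(~bad_rows)

    if scale != K_cal:
        if cmap_dict is None:
            raise ValueError(f"calibration has no collapse map; cannot score "
                             f"{scale}-point input against {K_cal} categories")
        cmap = CollapseMap({int(k): v for k, v in cmap_dict.items()})
        if cmap.k_old != scale or cmap.k_new != K_cal:
            raise ValueError("collapse map does not bridge the given scales")
        X = apply_collapse(
            ResponseMatrix(X.values, X.item_ids, X.person_ids,
                           X.covariates, scale), cmap)

    tbl = results.eap_scores(X)
    tbl["scale_used"] = scale
    return ScoreTable(tbl, scale, rejected)
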