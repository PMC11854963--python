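"""Stepwise multiple linear regression of mitigation on meteorology.

The response is the hourly PM2.5 delta (road − park); candidate
predictors are the meteorological variables of both sensors
(temperature, humidity, pressure) plus wind direction and speed, all on
their natural scales.  Selection is bidirectional stepwise from the
full model: at each step the single add or drop move that most reduces
the information criterion is taken, ties broken toward the smaller
model.  The fit is run both on the full hourly dataset and on the
24-row hour-of-day-averaged dataset, where averaging removes most of
the observation noise.

Wind direction enters as a linear degree value despite being circular;
a sine/cosine encoding is available but off by default so that the
reported coefficient is a single number per predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from parkdelta.errors import InsufficientDataError

CANDIDATE_PREDICTORS = [
    "T_park", "H_park", "P_park",
    "T_road", "H_road", "P_road",
    "WD", "WS",
]

_SOURCE_COLUMNS = {
    "T_park": "park_temperature",
    "H_park": "park_rh",
    "P_park": "park_pressure",
    "T_road": "road_temperature",
    "H_road": "road_rh",
    "P_road": "road_pressure",
    "WD": "wd",
    "WS": "ws",
}

#: criterion differences below this are ties (resolved toward fewer terms)
_TIE_TOL = 1e-8


@dataclass
class RegressionResult:
    dataset: str                      # "full" or "hour-by-hour"
    terms: list = field(default_factory=list)
    coefficients: dict = field(default_factory=dict)
    intercept: float = 0.0
    r_squared: float = 0.0
    n_observations: int = 0
    criterion: str = "aic"
    criterion_value: float = np.nan
    trace: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": "intercept", "coefficient": self.intercept}]
        rows += [{"term": t, "coefficient": self.coefficients[t]} for t in self.terms]
        return pd.DataFrame(rows)


def build_design(
    joined: pd.DataFrame,
    response_col: str = "delta_pm25",
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Response and candidate-predictor table from wind-attached paired hours.

    Rows missing the response or any predictor are dropped (the count is
    returned).  Raises :class:`InsufficientDataError` when fewer rows
    remain than candidate predictors + 2.
    """
    cols = {"y": joined[response_col]}
    for name, src in _SOURCE_COLUMNS.items():
        if src not in joined.columns:
            raise InsufficientDataError(f"design is missing source column {src!r}")
        cols[name] = joined[src]
    df = pd.DataFrame(cols)
    n_in = len(df)
    df = df.dropna()
    n_dropped = n_in - len(df)
    if len(df) < len(CANDIDATE_PREDICTORS) + 2:
        raise InsufficientDataError(
            f"{len(df)} complete rows is too few for {len(CANDIDATE_PREDICTORS)} predictors"
        )
    return df["y"], df[CANDIDATE_PREDICTORS], n_dropped


def collapse_hour_of_day(joined: pd.DataFrame, hour_col: str = "hour_start") -> pd.DataFrame:
    """Average every numeric variable by clock hour (≤ 24 rows).

    The collapsed table feeds the same design builder as the full data;
    ``hour_start`` is replaced by a representative hour label.
    """
    hours = pd.to_datetime(joined[hour_col]).dt.hour
    numeric = joined.select_dtypes(include=[np.number])
    collapsed = numeric.groupby(hours).mean().rename_axis("hour").reset_index()
    collapsed[hour_col] = pd.to_datetime("2000-01-01") + pd.to_timedelta(
        collapsed["hour"], unit="h"
    )
    return collapsed.drop(columns="hour")


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Drop columns that are perfectly collinear with earlier ones."""
    dropped = []
    keep: list[str] = []
    mat = np.column_stack([np.ones(len(X))])
    for col in X.columns:
        cand = np.column_stack([mat, X[col].to_numpy()])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(mat):
            keep.append(col)
            mat = cand
        else:
            dropped.append(col)
    return X[keep], dropped


def _fit(y: np.ndarray, X: pd.DataFrame, terms: tuple, criterion: str):
    """OLS on the selected terms; returns (criterion value, fitted model)."""
    design = sm.add_constant(X[list(terms)], has_constant="add")
    model = sm.OLS(np.asarray(y, dtype=float), np.asarray(design, dtype=float)).fit()
    n = len(design)
    k = design.shape[1]
    ssr = float(model.ssr)
    if ssr <= max(1e-12, 1e-14 * n):
        # perfect fit: the likelihood diverges, any model containing the
        # true terms ties at -inf and the tie rule shrinks to the smallest
        return -np.inf, model
    value = model.aic if criterion == "aic" else model.bic
    return float(value), model


def _better(cand: float, cur: float) -> bool:
    """Strict criterion improvement (both -inf is not an improvement)."""
    if np.isneginf(cand) and np.isneginf(cur):
        return False
    return cand < cur - _TIE_TOL


def _tied(cand: float, cur: float) -> bool:
    if np.isneginf(cand) and np.isneginf(cur):
        return True
    return abs(cand - cur) <= _TIE_TOL


def stepwise_mlr(
    y,
    X: pd.DataFrame,
    *,
    criterion: str = "aic",
    direction: str = "both",
    dataset: str = "full",
) -> RegressionResult:
    """Bidirectional stepwise model selection by information criterion.

    Starts from the full candidate model (``direction="both"`` or
    ``"backward"``) or the intercept-only model (``"forward"``) and
    repeatedly applies the single add/drop move that most reduces the
    criterion until no move improves it; a tie is resolved toward the
    smaller model.  Coefficients are the ordinary least-squares fit of
    the selected terms.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    if direction not in ("both", "forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    y = np.asarray(y, dtype=float)
    X, collinear = _drop_collinear(X)
    if collinear:
        import warnings

        warnings.warn(
            f"dropping perfectly collinear predictors before selection: {collinear}"
        )
    candidates = list(X.columns)
    current: tuple = () if direction == "forward" else tuple(candidates)
    allow_add = direction in ("both", "forward")
    allow_drop = direction in ("both", "backward")

    cur_val, cur_model = _fit(y, X, current, criterion)
    trace = [("start", current, cur_val)]
    while True:
        moves = []
        if allow_drop:
            for t in current:
                moves.append(("drop", tuple(u for u in current if u != t)))
        if allow_add:
            for t in candidates:
                if t not in current:
                    moves.append(("add", current + (t,)))
        best = None
        for kind, terms in moves:
            val, model = _fit(y, X, terms, criterion)
            if best is None:
                best = (val, kind, terms, model)
                continue
            bval, bkind, bterms, _ = best
            if _better(val, bval) or (
                _tied(val, bval) and len(terms) < len(bterms)
            ):
                best = (val, kind, terms, model)
        if best is None:
            break
        bval, bkind, bterms, bmodel = best
        take = _better(bval, cur_val) or (
            _tied(bval, cur_val) and len(bterms) < len(current)
        )
        if not take:
            break
        current, cur_val, cur_model = bterms, bval, bmodel
        trace.append((bkind, current, cur_val))

    params = np.asarray(cur_model.params, dtype=float)
    coefs = dict(zip(current, params[1:]))
    return RegressionResult(
        dataset=dataset,
        terms=list(current),
        coefficients=coefs,
        intercept=float(params[0]),
        r_squared=float(cur_model.rsquared) if len(current) else 0.0,
        n_observations=len(y),
        criterion=criterion,
        criterion_value=cur_val,
        trace=trace,
    )
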