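"""Polarization index and temporal consistency statistics.

The polarization index of a group is the normalized variance of the
individual action probabilities,

    F = Var(p) / (p_bar * (1 - p_bar)),

with population (divide-by-n) variance, in analogy with Wright's
fixation index: F = 0 when all group members share the same p, F = 1
when every p is 0 or 1 but both values occur.  F is undefined when
p_bar is 0 or 1 (returned as NaN, never silently coerced to 0).

Behavioural consistency over time is the product-moment correlation of
individual logit(p) values at two time points, as a function of the
lag, pooled over individuals, replicate groups and window start times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit

from netgames.engine import Trajectory

#: probabilities are clamped to [EPS, 1-EPS] before taking logits
LOGIT_EPS = 1e-6


def polarization_index(p_values: np.ndarray) -> float:
    """Polarization index F = Var(p) / (p_bar (1 - p_bar)) of one group.

    Uses the population variance, which keeps F within [0, 1] (the
    two-individual boundary case p = (0, 1) gives exactly 1).  Returns
    NaN when the mean probability is 0 or 1 (index undefined).

    Parameters
    ----------
    p_values : array-like
        Action probabilities of the group members (length >= 2, each
        in [0, 1]).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need a 1-d vector of at least 2 probabilities")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("probabilities must lie in [0, 1]")
    pbar = p.mean()
    denom = pbar * (1.0 - pbar)
    if denom == 0.0:
        return float("nan")
    return float(np.var(p) / denom)


def mean_polarization(groups: Iterable[np.ndarray]) -> tuple[float, int]:
    """Average F over groups, skipping groups where F is undefined.

    Returns ``(mean_F, n_excluded)`` where ``n_excluded`` counts the
    groups with undefined index.  Raises if every group is undefined.
    """
    values = [polarization_index(g) for g in groups]
    arr = np.asarray(values, dtype=float)
    defined = arr[~np.isnan(arr)]
    if defined.size == 0:
        raise ValueError("polarization index undefined for every group")
    return float(defined.mean()), int(np.isnan(arr).sum())


def polarization_series(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Group-mean polarization index over recorded rounds.

    All trajectories must share one recording grid.  Returns a frame
    with columns ``round``, ``mean_F`` and ``n_groups`` (the number of
    groups with a defined index at that round).
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    rounds = trajectories[0].rounds
    for t in trajectories[1:]:
        if not np.array_equal(t.rounds, rounds):
            raise ValueError("trajectories have different recording grids")
    # per-group, per-round F in one vectorized pass
    stack = np.stack([t.p for t in trajectories])  # (G, R, N)
    pbar = stack.mean(axis=2)
    denom = pbar * (1.0 - pbar)
    var = stack.var(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0.0, var / denom, np.nan)
    n_groups = (~np.isnan(f)).sum(axis=0)
    mean_f = np.where(
        n_groups > 0, np.nansum(f, axis=0) / np.maximum(n_groups, 1), np.nan
    )
    return pd.DataFrame(
        {"round": rounds.astype(np.int64), "mean_F": mean_f, "n_groups": n_groups}
    )


@dataclass
class AutocorrelationCurve:
    """Lagged autocorrelation of logit(p), pooled over individuals,
    groups and window start times.

    ``correlation[j]`` estimates the product-moment correlation between
    logit(p) at times t and t + ``lags[j]`` inside the analysis window
    ``window = (start_round, end_round)``; NaN where undefined (zero
    variance).  ``n_pairs[j]`` counts the pooled (series x start-time)
    pairs behind each estimate and ``n_groups`` the groups pooled.
    """

    lags: np.ndarray
    correlation: np.ndarray
    n_pairs: np.ndarray
    window: tuple[int, int]
    n_groups: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag": self.lags, "correlation": self.correlation, "n_pairs": self.n_pairs}
        )


def logit_autocorrelation(
    trajectories: Sequence[Trajectory],
    window: tuple[int, int] = (4000, 5000),
    lags: Sequence[int] | None = None,
) -> AutocorrelationCurve:
    """Temporal consistency: correlation of logit(p) at lag ``l``.

    For each lag, all pairs (logit p at round t, logit p at round
    t + l) with both rounds inside ``window`` are pooled over every
    individual of every group and every admissible start time t, and a
    single Pearson correlation is computed.  Probabilities are clamped
    to [1e-6, 1 - 1e-6] before the logit so extreme preferences stay
    finite.

    The window bounds are in rounds and must lie on the trajectories'
    recording grid; lags are likewise in rounds and must be multiples
    of the recording interval.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    rounds = trajectories[0].rounds
    for t in trajectories[1:]:
        if not np.array_equal(t.rounds, rounds):
            raise ValueError("trajectories have different recording grids")
    start, end = window
    sel = (rounds >= start) & (rounds <= end)
    if sel.sum() < 2:
        raise ValueError(f"window {window} covers fewer than 2 recorded rounds")
    win_rounds = rounds[sel]
    steps = np.diff(win_rounds)
    if len(set(steps.tolist())) != 1:
        raise ValueError("recording grid is not uniform inside the window")
    dt = int(steps[0])
    if lags is None:
        lags = [int(l) for l in win_rounds - win_rounds[0]]
    # logit series: rows = individual series pooled over groups
    x = np.concatenate([t.p[sel].T for t in trajectories], axis=0)
    x = logit(np.clip(x, LOGIT_EPS, 1.0 - LOGIT_EPS))
    n_win = x.shape[1]
    out = np.empty(len(lags))
    n_pairs = np.zeros(len(lags), dtype=np.int64)
    for j, lag in enumerate(lags):
        if lag < 0 or lag % dt != 0:
            raise ValueError(f"lag {lag} not a non-negative multiple of the grid step {dt}")
        shift = lag // dt
        if shift >= n_win:
            raise ValueError(f"lag {lag} does not fit in window {window}")
        a = x[:, : n_win - shift].ravel()
        b = x[:, shift:].ravel()
        n_pairs[j] = a.size
        sa, sb = a.std(), b.std()
        if sa == 0.0 or sb == 0.0:
            # zero pooled variance (all behaviour identical): undefined
            out[j] = float("nan")
        else:
            out[j] = float(np.corrcoef(a, b)[0, 1])
    return AutocorrelationCurve(
        lags=np.asarray(lags, dtype=np.int64),
        correlation=out,
        n_pairs=n_pairs,
        window=(int(start), int(end)),
        n_groups=len(trajectories),
    )
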