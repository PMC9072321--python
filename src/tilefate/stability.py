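"""Half-life estimation from transcription-shutoff time courses.

After actinomycin D blocks transcription, each tile's level decays roughly
exponentially; on a log2 scale the decay is linear in time. Levels are first
normalized to exogenous spike-in RNA (which absorbs extraction and depth
differences between timepoints), then expressed relative to the t=0 sample,
and an ordinary least-squares line of log2(level / level at t=0) on time is
fitted per tile. The half-life follows from the regression coefficients as

    t_1/2 = (log_b(0.5) - intercept) / slope        (b = 2 by default)

which, with the default t=0 normalization, is the time at which the fitted
line reaches 50% of the initial level. A non-negative slope means no
measurable decay and the half-life is reported as undefined (NaN), not an
error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DecayFit:
    tile_id: str
    intercept: float  # log-base units at t=0
    slope: float      # log-base units per hour
    r_squared: float
    n_timepoints: int

    @property
    def half_life(self) -> float:
        return half_life(self)


def spike_normalize(counts: pd.DataFrame, spike_ids: list[str]) -> pd.DataFrame:
    """Divide every tile count by the summed spike-in counts of its sample.

    Multiple spike species (e.g. two input concentrations at a 10:1 ratio)
    are summed before division. Spike rows are removed from the output.
    """
    missing = [s for s in spike_ids if s not in counts.index]
    if missing:
        raise ValueError(f"spike id(s) not in matrix: {missing}")
    spike_tot = counts.loc[spike_ids].sum(axis=0)
    zero = spike_tot[spike_tot <= 0]
    if len(zero):
        raise ValueError(f"zero spike-in total in sample(s): {list(zero.index)}")
    return counts.drop(index=spike_ids) / spike_tot


def fit_decay(
    timepoints,
    levels,
    base: float = 2.0,
    t0_normalize: bool = True,
    tile_id: str = "",
) -> DecayFit | None:
    """OLS fit of log_base(level) (relative to t=0 by default) against time.

    Nonpositive levels are dropped with a warning; if fewer than two distinct
    timepoints remain the fit is absent (None).
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(levels, dtype=float)
    if t.shape != y.shape:
        raise ValueError("timepoints and levels differ in length")
    keep = y > 0
    if not keep.all():
        warnings.warn(
            f"tile {tile_id or '?'}: dropped {int((~keep).sum())} nonpositive level(s)",
            stacklevel=2,
        )
    t, y = t[keep], y[keep]
    if len(np.unique(t)) < 2:
        return None
    if t0_normalize:
        at0 = y[t == t.min()] if 0.0 not in t else y[t == 0.0]
        y = y / at0.mean()
    ly = np.log(y) / np.log(base)
    slope, intercept = np.polyfit(t, ly, 1)
    resid = ly - (intercept + slope * t)
    sst = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    return DecayFit(tile_id, float(intercept), float(slope),
                    min(max(r2, 0.0), 1.0), int(len(np.unique(t))))


def half_life(fit: DecayFit | None, base: float = 2.0) -> float:
    """(log_base(0.5) - intercept) / slope, in hours; NaN when undefined."""
    if fit is None or fit.slope >= 0:
        return math.nan
    hl = (math.log(0.5, base) - fit.intercept) / fit.slope
    return hl if hl > 0 else math.nan


def fit_all(
    levels: pd.DataFrame,
    timepoint_of: dict[str, float],
    base: float = 2.0,
    t0_normalize: bool = True,
) -> pd.DataFrame:
    """Fit every tile of a (spike-normalized) level matrix.

    *timepoint_of* maps sample column -> hours; replicate samples at the same
    timepoint simply contribute multiple points to the regression. Returns a
    per-tile table of intercept, slope, r^2 and half-life.
    """
    unknown = [c for c in levels.columns if c not in timepoint_of]
    if unknown:
        raise ValueError(f"samples without a timepoint: {unknown}")
    t = np.array([timepoint_of[c] for c in levels.columns], dtype=float)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tid, row in levels.iterrows():
            fit = fit_decay(t, row.to_numpy(), base=base,
                            t0_normalize=t0_normalize, tile_id=str(tid))
            if fit is None:
                rows.append((tid, np.nan, np.nan, np.nan, 0, np.nan))
            else:
                rows.append((tid, fit.intercept, fit.slope, fit.r_squared,
                             fit.n_timepoints, half_life(fit, base=base)))
    out = pd.DataFrame(
        rows,
        columns=["tile_id", "intercept", "slope", "r_squared",
                 "n_timepoints", "half_life_h"],
    ).set_index("tile_id")
    return out
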