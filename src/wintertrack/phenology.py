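"""Winter-window delimitation from colony-attendance (immersion) records.

Crested penguins moult ashore for weeks in autumn, spend the entire winter
at sea, and come ashore again in spring — so daily wet/dry fractions from
the tags show a dry block, a long wet block, and a terminal dry block.
Departure is the first day of sustained wetness after the moult haul-out;
return is the first day of the terminal sustained dry run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class PhenologyError(RuntimeError):
    pass


@dataclass(frozen=True)
class WinterWindow:
    departure: pd.Timestamp
    return_date: pd.Timestamp

    def __post_init__(self):
        if self.return_date < self.departure:
            raise PhenologyError("return date precedes departure")

    @property
    def duration_days(self) -> int:
        return winter_duration(self.departure, self.return_date)


def winter_duration(departure, return_date) -> int:
    """Exact calendar-day difference between departure and return."""
    dep = pd.Timestamp(departure).normalize()
    ret = pd.Timestamp(return_date).normalize()
    days = (ret - dep).days
    if days < 0:
        raise PhenologyError("return date precedes departure")
    return int(days)


def _runs(mask: np.ndarray):
    """(start, stop, value) runs of a boolean series; stop exclusive."""
    out = []
    i = 0
    while i < len(mask):
        j = i
        while j < len(mask) and mask[j] == mask[i]:
            j += 1
        out.append((i, j, bool(mask[i])))
        i = j
    return out


def detect_winter_window(series: pd.DataFrame, dry_threshold: float = 0.5,
                         min_run_days: int = 5) -> WinterWindow:
    """Delimit the winter window from daily wet fractions.

    ``series`` needs columns ``date`` and ``wet_fraction`` in [0, 1].  A day
    is ashore (dry) when its wet fraction is below ``dry_threshold``.  The
    window requires an initial ashore run and a terminal ashore run, each of
    at least ``min_run_days`` days, separated by a sustained wet run.
    """
    df = series.sort_values("date").reset_index(drop=True)
    wf = df["wet_fraction"].to_numpy(dtype=float)
    if ((wf < 0) | (wf > 1)).any():
        raise PhenologyError("wet fractions must lie in [0, 1]")
    ashore = wf < dry_threshold
    runs = [(a, b, v) for a, b, v in _runs(ashore) if b - a >= min_run_days]
    dry_runs = [(a, b) for a, b, v in runs if v]
    wet_runs = [(a, b) for a, b, v in runs if not v]
    if not dry_runs or not wet_runs:
        raise PhenologyError(
            "no qualifying ashore/at-sea runs: "
            f"{ashore.sum()} ashore days of {len(ashore)} "
            f"(threshold {dry_threshold}, min run {min_run_days})")
    # departure: first sustained wet run that follows a sustained dry run
    dep_idx = None
    for wa, wb in wet_runs:
        if any(db <= wa for da, db in dry_runs):
            dep_idx = wa
            break
    # return: first sustained dry run after the departure
    ret_idx = None
    if dep_idx is not None:
        for da, db in dry_runs:
            if da >= dep_idx:
                ret_idx = da
                break
    if dep_idx is None or ret_idx is None:
        raise PhenologyError(
            "could not find moult haul-out followed by winter and return "
            f"(dry runs at {dry_runs}, wet runs at {wet_runs})")
    return WinterWindow(pd.Timestamp(df["date"].iloc[dep_idx]),
                        pd.Timestamp(df["date"].iloc[ret_idx]))
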