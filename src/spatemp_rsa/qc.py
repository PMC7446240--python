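"""Quality-control metrics for volume time series."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["dvars", "dvars_by_condition"]


def dvars(series: np.ndarray) -> np.ndarray:
    """Frame-to-frame RMS signal change (DVARS).

    For each frame ``i >= 1`` the value is the square root of the spatial
    mean, over features, of the squared intensity difference to the
    previous frame — a motion/quality index for fMRI time series.

    Parameters
    ----------
    series
        ``(n_features, n_frames)`` intensity matrix.

    Returns
    -------
    ndarray of length ``n_frames - 1``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be (n_features, n_frames)")
    if x.shape[1] < 2:
        raise ValueError("DVARS requires at least 2 frames")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    diff = np.diff(x, axis=1)
    return np.sqrt(np.mean(diff**2, axis=0))


def dvars_by_condition(
    series: np.ndarray, events: pd.DataFrame, tr_s: float
) -> pd.DataFrame:
    """Descriptive DVARS statistics grouped by movement condition.

    Each frame transition is attributed to the condition whose event
    interval contains it; transitions outside every event are dropped.
    """
    d = dvars(series)
    frame_times = (np.arange(len(d)) + 1) * tr_s  # time of the later frame
    rows = []
    for _, ev in events.iterrows():
        m = (frame_times >= ev["onset_s"]) & (frame_times < ev["onset_s"] + ev["duration_s"])
        for val in d[m]:
            rows.append({"condition": ev["condition"], "dvars": val})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["condition", "mean", "std", "max", "n"])
    g = df.groupby("condition")["dvars"]
    return pd.DataFrame(
        {"mean": g.mean(), "std": g.std(), "max": g.max(), "n": g.count()}
    ).reset_index()
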