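"""Behavioural task bookkeeping: block/run durations and trial counts.

The motor task presents 26 hand movements in blocks; each block cues a
single movement and contains a fixed number of paced movement trials.
These helpers recompute session arithmetic (block durations, run
durations, per-condition repeat counts, GLM regressor counts) from the
component durations so that generators and analyses share one source of
truth.
"""

from __future__ import annotations

__all__ = [
    "MOVEMENT_S",
    "fmri_block_s",
    "meg_block_s",
    "behavioral_block_s",
    "behavioral_run_s",
    "repeats_per_condition",
    "min_trials_after_rejection",
    "n_glm_regressors",
]

#: Duration of the expanding/contracting movement cue, seconds.
MOVEMENT_S = 1.6


def fmri_block_s(
    n_trials: int = 5,
    instruction_s: float = 3.0,
    video_s: float = 3.0,
    cue_s: float = 1.0,
    movement_s: float = MOVEMENT_S,
    rest_s: float = 0.4,
) -> float:
    """Duration of one fMRI movement block (default 17 s).

    3 s "Prepare to Move" + 3 s instructional video + 1 s "Move" cue,
    followed by five 1.6 s movement trials each with a 0.4 s rest.
    """
    return instruction_s + video_s + cue_s + n_trials * (movement_s + rest_s)


def meg_block_s(
    n_trials: int = 5,
    fixation_s: float = 2.0,
    video_s: float = 3.0,
    cue_s: float = 1.0,
    movement_s: float = MOVEMENT_S,
    rest_s: float = 0.8,
) -> float:
    """Duration of one MEG movement block (default 18 s).

    2 s fixation cross + 3 s instructional video + 1 s "Prepare to Move"
    cue, followed by five 1.6 s movement trials each with a 0.8 s rest.
    """
    return fixation_s + video_s + cue_s + n_trials * (movement_s + rest_s)


def behavioral_block_s(
    n_trials: int = 8,
    video_s: float = 3.0,
    prep_s: float = 1.0,
    movement_s: float = MOVEMENT_S,
    rest_s: float = 0.8,
) -> float:
    """Duration of one behavioural-session movement block (default 23.2 s)."""
    return video_s + prep_s + n_trials * (movement_s + rest_s)


def behavioral_run_s(n_conditions: int = 26, **block_kwargs) -> float:
    """Duration of one behavioural task run, excluding self-paced breaks.

    With 26 movement blocks of 23.2 s this is 603.2 s (10 min 3.2 s).
    The per-block arithmetic is authoritative; multiplying across runs
    does not reproduce the quoted 5-run session total, which is
    internally inconsistent with the per-run figure.
    """
    return n_conditions * behavioral_block_s(**block_kwargs)


def repeats_per_condition(n_runs: int = 10, trials_per_block: int = 5) -> int:
    """Total repeats of one movement pooled across task runs (default 50)."""
    if n_runs < 1 or trials_per_block < 1:
        raise ValueError("need at least one run and one trial per block")
    return n_runs * trials_per_block


def min_trials_after_rejection(n_repeats: int = 50, rejection_cap: int = 10) -> int:
    """Guaranteed minimum trial count after artifact rejection (default 40).

    Visual artifact rejection removes at most ``rejection_cap`` trials per
    condition, so at least ``n_repeats - rejection_cap`` remain.
    """
    if rejection_cap < 0 or rejection_cap >= n_repeats:
        raise ValueError("rejection cap must lie in [0, n_repeats)")
    return n_repeats - rejection_cap


def n_glm_regressors(n_conditions: int = 26, temporal_derivative: bool = True) -> int:
    """Number of condition regressors in the first-level GLM (default 52).

    Each condition contributes a boxcar-convolved-HRF regressor and,
    optionally, its temporal derivative.  The intercept is not counted.
    """
    if n_conditions < 1:
        raise ValueError("need at least one condition")
    return n_conditions * (2 if temporal_derivative else 1)
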