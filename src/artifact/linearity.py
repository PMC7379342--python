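"""Linearity assessment: scaling and additivity of artifact amplitudes.

The whole artifact-prediction approach rests on the stimulation current and
the recorded artifact being linearly related (passive capacitive/inductive
coupling).  This module implements the two standard checks: *scaling* --
peak-to-peak artifact amplitude versus input current amplitude should fall
on a line through the origin -- and *additivity* -- the composite artifact
of concurrently delivered currents should equal the sum of the single-input
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.stats

from .signals import FilterBank, MultichannelSignal
from .wiener import predict_artifacts

__all__ = ["AmplitudePairs", "peak_to_peak", "linearity_r2", "additivity_check"]


@dataclass
class AmplitudePairs:
    """Paired amplitudes for a scaling fit.

    ``x`` is the input current peak-to-peak (uA) or the predicted-artifact
    peak-to-peak (uV); ``y`` the recorded-artifact peak-to-peak (uV).
    """

    x: np.ndarray
    y: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size < 2:
            raise ValueError("need at least 2 amplitude pairs")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("amplitudes must be finite")


def peak_to_peak(
    signal: MultichannelSignal,
    event_times: Sequence[float],
    window: float = 0.5e-3,
    pre_offset: float = 0.0,
    channel: int = 0,
) -> np.ndarray:
    """Per-event peak-to-peak amplitude (max - min) in a post-event window.

    The window starts at ``event_time - pre_offset`` and spans ``window``
    seconds (alignment at the event onset by default).
    """
    fs = signal.fs
    K = signal.n_samples
    n_win = max(round(window * fs), 1)
    out = np.empty(len(event_times))
    for i, t in enumerate(event_times):
        k0 = round((t - pre_offset) * fs)
        k1 = k0 + n_win
        if k0 < 0 or k1 > K:
            raise ValueError(f"window for event at {t} s falls outside the record")
        seg = signal.samples[k0:k1, channel]
        out[i] = seg.max() - seg.min()
    return out


def linearity_r2(pairs: AmplitudePairs) -> dict[str, float]:
    """Ordinary least-squares scaling fit; r^2 is the squared Pearson r.

    Raw (unlogged) amplitudes are fitted, matching how scaling plots are
    normally drawn.
    """
    if pairs.x.size < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.var(pairs.x) == 0:
        raise ValueError("degenerate fit: x has zero variance")
    res = scipy.stats.linregress(pairs.x, pairs.y)
    return {
        "r2": float(res.rvalue**2),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
    }


def additivity_check(
    single_inputs: Sequence[MultichannelSignal],
    system: FilterBank | Callable[[MultichannelSignal], MultichannelSignal],
) -> float:
    """Max relative deviation between response(sum) and sum(responses).

    ``single_inputs`` are stimulus programs (same shape/fs) that are summed
    sample-wise to form the composite drive; ``system`` is either a known
    coupling filter bank or any callable mapping stimulus to response (e.g.
    one with an injected static nonlinearity).  Returns
    ``max|r(sum) - sum(r_i)| / max|sum(r_i)|`` (0 for all-zero inputs).
    """
    if len(single_inputs) < 2:
        raise ValueError("need at least 2 single-input programs")
    if isinstance(system, FilterBank):
        bank = system
        respond = lambda s: predict_artifacts(s, bank)  # noqa: E731
    else:
        respond = system
    ref = single_inputs[0]
    total = np.zeros_like(ref.samples)
    sum_resp = None
    for s in single_inputs:
        if s.samples.shape != ref.samples.shape or s.fs != ref.fs:
            raise ValueError("single-input programs must share shape and fs")
        total += s.samples
        r = respond(s).samples
        sum_resp = r.copy() if sum_resp is None else sum_resp + r
    combined = respond(ref.with_samples(total)).samples
    denom = np.abs(sum_resp).max()
    if denom == 0:
        return 0.0
    return float(np.abs(combined - sum_resp).max() / denom)
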