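"""Containers for time-aligned multichannel signals and FIR filter banks.

A recording session pairs N stimulation-current channels (microamps) with M
extracellular recording channels (microvolts) sampled on a shared clock.
:class:`MultichannelSignal` holds either side as a ``(K, C)`` float64 matrix.
:class:`FilterBank` holds the N x M bank of length-L impulse responses
``h[n, m]`` (units uV/uA) that map each stimulation channel onto the artifact
it produces on each recording channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Units understood by the containers.
MICROAMP = "microamp"
MICROVOLT = "microvolt"
DIMENSIONLESS = "dimensionless"
VALID_UNITS = frozenset({MICROAMP, MICROVOLT, DIMENSIONLESS})


class UnitsError(ValueError):
    """Operands carry physically inconsistent units."""


class AlignmentError(ValueError):
    """Signals do not share a sampling clock (fs) or record length."""


class InsufficientDataError(ValueError):
    """Record too short for the requested estimation."""


def _check_units(units: str) -> str:
    if units not in VALID_UNITS:
        raise UnitsError(f"unknown units {units!r}; expected one of {sorted(VALID_UNITS)}")
    return units


@dataclass
class MultichannelSignal:
    """Time samples x channels matrix with sampling rate and physical units.

    Parameters
    ----------
    samples : ndarray, shape (K, C) or (K,)
        Sample matrix; a 1-D array is promoted to a single channel.
        Stored as float64.
    fs : float
        Sampling rate in Hz, > 0.
    units : str
        One of ``microamp`` (stimulation currents), ``microvolt``
        (recordings) or ``dimensionless``.
    channel_ids : sequence of str, optional
        Channel labels; defaults to ``ch0 .. ch{C-1}``.
    """

    samples: np.ndarray
    fs: float
    units: str = DIMENSIONLESS
    channel_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2:
            raise ValueError(f"samples must be 1-D or 2-D, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"need at least one sample and one channel, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples contain non-finite values")
        self.samples = arr
        self.fs = float(self.fs)
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        _check_units(self.units)
        if self.channel_ids is None:
            self.channel_ids = tuple(f"ch{i}" for i in range(arr.shape[1]))
        else:
            self.channel_ids = tuple(str(c) for c in self.channel_ids)
            if len(self.channel_ids) != arr.shape[1]:
                raise ValueError("channel_ids length does not match channel count")

    # -- convenience -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def segment(self, start: int, stop: int) -> "MultichannelSignal":
        """Return samples ``start:stop`` as a new signal (sample indices)."""
        if not 0 <= start < stop <= self.n_samples:
            raise ValueError(f"invalid segment [{start}, {stop}) for K={self.n_samples}")
        return replace(self, samples=self.samples[start:stop].copy())

    def with_samples(self, samples: np.ndarray) -> "MultichannelSignal":
        """New signal sharing fs/units/labels but with different samples."""
        return replace(self, samples=samples)


def require_alignment(a: MultichannelSignal, b: MultichannelSignal) -> None:
    """Raise :class:`AlignmentError` unless a and b share fs and K."""
    if a.fs != b.fs:
        raise AlignmentError(f"sampling rates differ: {a.fs} vs {b.fs} Hz")
    if a.n_samples != b.n_samples:
        raise AlignmentError(f"record lengths differ: {a.n_samples} vs {b.n_samples} samples")


@dataclass
class FilterBank:
    """N x M bank of length-L FIR impulse responses, units uV/uA.

    ``taps[n, m, i]`` is the i-th coefficient of the impulse response from
    stimulation channel n to recording channel m.  The coefficient at index
    ``lag0`` multiplies the zero-lag input sample, so ``lag0 = 0`` is a
    purely causal filter and a positive ``lag0`` allows an acausal lead that
    absorbs recording-chain delays.
    """

    taps: np.ndarray  # (N, M, L)
    lag0: int = 0
    fs: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.taps, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"taps must have shape (N, M, L), got {arr.shape}")
        if arr.shape[2] < 1:
            raise ValueError("need at least one tap (L >= 1)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("taps contain non-finite values")
        self.taps = arr
        self.lag0 = int(self.lag0)
        if not 0 <= self.lag0 < arr.shape[2]:
            raise ValueError(f"lag0 must satisfy 0 <= lag0 < L, got {self.lag0} with L={arr.shape[2]}")
        self.fs = float(self.fs)
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")

    @property
    def n_inputs(self) -> int:
        return self.taps.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.taps.shape[1]

    @property
    def n_taps(self) -> int:
        return self.taps.shape[2]

    @property
    def lags(self) -> np.ndarray:
        """Actual lags (in samples) of each tap: ``arange(L) - lag0``."""
        return np.arange(self.n_taps) - self.lag0
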