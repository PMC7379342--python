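"""MIMO Wiener artifact-prediction filters via the Wiener-Hopf equations.

The recorded artifact on channel m is modelled as the sum of the stimulation
currents convolved with per-pair FIR impulse responses,

    y_m[k] = sum_n (x_n * h_nm)[k],

and the minimum mean-squared-error filter bank solves the normal equations
``Cxx h = Ryx`` where ``Cxx`` is the blockwise lagged covariance of the
stimulation channels and ``Ryx`` stacks the input-output cross-correlations.
Estimation, prediction (convolution) and subtraction are exposed both as
functions operating on :class:`~artifact.signals.MultichannelSignal` and as
the sklearn-style :class:`WienerArtifactFilter` estimator.

Conventions (documented, configurable):

* lag layout is channel-major: row ``n*L + i`` of the stacked system is tap
  ``i`` of input ``n``; tap ``i`` multiplies ``x[k - (i - lag0)]``;
* correlations are *biased* (divide by K) by default, which keeps ``Cxx``
  positive semidefinite; signals are zero-padded outside ``[0, K-1]``
  (a small-K edge bias);
* ``Cxx`` equals exactly ``Z^T Z / K`` for the K-row lagged design matrix Z
  (computed via FFT correlations plus edge corrections, never materialising
  Z); the familiar Toeplitz-block form is its large-K limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.signal
from sklearn.base import BaseEstimator, RegressorMixin

from .signals import (
    DIMENSIONLESS,
    MICROAMP,
    MICROVOLT,
    AlignmentError,
    FilterBank,
    InsufficientDataError,
    MultichannelSignal,
    UnitsError,
    require_alignment,
)

__all__ = [
    "WienerConfig",
    "CorrelationSet",
    "RankDeficiencyError",
    "build_normal_equations",
    "solve_wiener",
    "predict_artifacts",
    "clean",
    "fit_and_clean",
    "FitResult",
    "template_baseline",
    "make_split",
    "WienerArtifactFilter",
]


class RankDeficiencyError(np.linalg.LinAlgError):
    """Cxx is singular, ridge is zero and no fallback is permitted."""


@dataclass
class WienerConfig:
    """Estimation settings for the Wiener filter bank.

    Parameters
    ----------
    L : int
        Taps per input channel (filter order); default 40.
    lag0 : int
        Acausal offset: tap ``lag0`` is the zero-lag coefficient. 0 means a
        purely causal filter (the physical coupling is causal; a small
        positive value absorbs recording-chain group delay).
    ridge : float
        Nonnegative diagonal loading added to Cxx before solving.
    normalization : {"biased", "unbiased"}
        Biased divides correlation sums by K and guarantees a positive
        semidefinite Cxx; unbiased rescales each entry by ``K/(K-|dlag|)``
        and is intended for diagnostics only.
    fallback : bool
        If True (default), a singular Cxx with ridge=0 triggers an automatic
        diagonal-loading retry (``1e-8 * trace/NL``) with a warning and, if
        still singular, a least-squares pseudo-solve.  If False, a
        :class:`RankDeficiencyError` is raised instead.
    """

    L: int = 40
    lag0: int = 0
    ridge: float = 0.0
    normalization: str = "biased"
    fallback: bool = True

    def __post_init__(self) -> None:
        self.L = int(self.L)
        if self.L < 1:
            raise ValueError("L must be >= 1")
        self.lag0 = int(self.lag0)
        if not 0 <= self.lag0 < self.L:
            raise ValueError("lag0 must satisfy 0 <= lag0 < L")
        self.ridge = float(self.ridge)
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")
        if self.normalization not in ("biased", "unbiased"):
            raise ValueError("normalization must be 'biased' or 'unbiased'")


@dataclass
class CorrelationSet:
    """Normal-equation blocks: Cxx (NL x NL) and Ryx (NL x M).

    Rows are channel-major: input-0 lags ``0..L-1``, input-1 lags ``0..L-1``,
    and so on.  ``n_samples`` is the total number of design rows that entered
    the sums (used to undo the biased normalisation when accumulating).
    """

    cxx: np.ndarray
    ryx: np.ndarray
    n_inputs: int
    n_outputs: int
    L: int
    lag0: int
    fs: float
    n_samples: int
    layout: str = field(default="channel-major")

    def __post_init__(self) -> None:
        nl = self.n_inputs * self.L
        if self.cxx.shape != (nl, nl):
            raise ValueError(f"cxx shape {self.cxx.shape} inconsistent with N*L={nl}")
        if self.ryx.shape != (nl, self.n_outputs):
            raise ValueError(f"ryx shape {self.ryx.shape} inconsistent with (N*L, M)")
        scale = max(np.abs(self.cxx).max(), np.finfo(float).tiny)
        if np.abs(self.cxx - self.cxx.T).max() > 1e-10 * scale:
            raise ValueError("cxx is not symmetric to relative tolerance 1e-10")


def _check_stim_rec_units(X: MultichannelSignal, Y: MultichannelSignal) -> None:
    # dimensionless is accepted anywhere; crossed uA/uV slots are refused
    if X.units == MICROVOLT:
        raise UnitsError("stimulation input carries microvolt units")
    if Y.units == MICROAMP:
        raise UnitsError("recording input carries microamp units")


def _edge_rows(x: np.ndarray, lags: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Rows of the lagged design matrix at (out-of-record) times ``ks``."""
    K, N = x.shape
    L = lags.size
    Z = np.zeros((ks.size, N * L))
    for r, k in enumerate(ks):
        idx = k - lags  # source sample feeding each tap
        valid = (idx >= 0) & (idx < K)
        if not np.any(valid):
            continue
        for n in range(N):
            Z[r, n * L + np.nonzero(valid)[0]] = x[idx[valid], n]
    return Z


def _design_sums(x: np.ndarray, y: np.ndarray, L: int, lag0: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact Z^T Z and Z^T Y for the K-row lagged design matrix Z.

    Z[k, n*L+i] = x_n[k - (i - lag0)] for k = 0..K-1, zero outside the
    record.  Computed from full zero-padded cross-correlations; rows of the
    infinite design at k < 0 and k >= K (at most lag0 and L-1-lag0 rows) are
    subtracted as explicit Gram corrections.
    """
    K, N = x.shape
    lags = np.arange(L) - lag0
    NL = N * L

    ztz = np.empty((NL, NL))
    for n in range(N):
        for l in range(n, N):
            # r[d] = sum_j x_n[j] x_l[j - d]; correlate gives r at index d+K-1
            r = scipy.signal.correlate(x[:, n], x[:, l], mode="full", method="auto")
            # block(i, j) of the *full* (all-k) sum is r[j - i]
            col = r[K - 1 - np.arange(L)]  # r[-i], i = 0..L-1
            row = r[K - 1 + np.arange(L)]  # r[+j], j = 0..L-1
            block = scipy.linalg.toeplitz(col, row)
            ztz[n * L:(n + 1) * L, l * L:(l + 1) * L] = block
            if l != n:
                ztz[l * L:(l + 1) * L, n * L:(n + 1) * L] = block.T

    # remove contributions from design rows outside [0, K-1]
    head_ks = np.arange(-lag0, 0)
    tail_ks = np.arange(K, K + max(0, L - 1 - lag0))
    for ks in (head_ks, tail_ks):
        if ks.size:
            Z = _edge_rows(x, lags, ks)
            ztz -= Z.T @ Z

    zty = np.empty((NL, y.shape[1]))
    for m in range(y.shape[1]):
        for n in range(N):
            # y is zero outside [0, K-1], so no edge correction is needed
            r = scipy.signal.correlate(y[:, m], x[:, n], mode="full", method="auto")
            zty[n * L:(n + 1) * L, m] = r[lags + K - 1]
    return ztz, zty


def build_normal_equations(
    X: MultichannelSignal,
    Y: MultichannelSignal,
    cfg: WienerConfig,
    segments: Sequence[tuple[int, int]] | None = None,
) -> CorrelationSet:
    """Estimate Cxx and Ryx from paired stimulation/recording records.

    Parameters
    ----------
    X, Y : MultichannelSignal
        Stimulation currents (K x N, uA) and recordings (K x M, uV) on a
        shared clock.
    cfg : WienerConfig
    segments : sequence of (start, stop), optional
        Restrict estimation to these sample ranges (e.g. training trials).
        Each segment is treated as an independent record with zero padding
        at its own boundaries; sums are pooled and normalised by the total
        segment length.

    Raises
    ------
    AlignmentError
        fs or K mismatch between X and Y.
    InsufficientDataError
        Fewer training samples than filter taps.
    """
    require_alignment(X, Y)
    _check_stim_rec_units(X, Y)
    K = X.n_samples
    if segments is None:
        segments = [(0, K)]
    segments = [(int(a), int(b)) for a, b in segments]
    total = 0
    for a, b in segments:
        if not 0 <= a < b <= K:
            raise ValueError(f"invalid segment ({a}, {b}) for K={K}")
        if b - a < cfg.L:
            raise InsufficientDataError(
                f"segment ({a}, {b}) shorter than L={cfg.L} taps"
            )
        total += b - a
    if total < cfg.L:
        raise InsufficientDataError(
            f"{total} training samples < L={cfg.L} taps; cannot estimate"
        )

    NL = X.n_channels * cfg.L
    ztz = np.zeros((NL, NL))
    zty = np.zeros((NL, Y.n_channels))
    for a, b in segments:
        s_ztz, s_zty = _design_sums(X.samples[a:b], Y.samples[a:b], cfg.L, cfg.lag0)
        ztz += s_ztz
        zty += s_zty

    if cfg.normalization == "unbiased":
        lags = np.arange(cfg.L) - cfg.lag0
        dl = np.abs(lags[:, None] - lags[None, :])
        denom = np.maximum(total - np.tile(dl, (X.n_channels, X.n_channels)), 1)
        cxx = ztz / denom
        ryx = zty / np.maximum(total - np.abs(np.tile(lags, X.n_channels))[:, None], 1)
    else:
        cxx = ztz / total
        ryx = zty / total
    cxx = 0.5 * (cxx + cxx.T)  # enforce exact symmetry against FFT round-off
    return CorrelationSet(
        cxx=cxx, ryx=ryx, n_inputs=X.n_channels, n_outputs=Y.n_channels,
        L=cfg.L, lag0=cfg.lag0, fs=X.fs, n_samples=total,
    )


def _name_deficient_channels(cxx: np.ndarray, N: int, L: int) -> list[int]:
    w, v = scipy.linalg.eigh(cxx)
    null = v[:, np.abs(w) <= max(1e-12 * np.abs(w).max(), np.finfo(float).tiny)]
    if null.size == 0:
        null = v[:, [0]]
    energy = (null ** 2).reshape(N, L, -1).sum(axis=(1, 2))
    return [int(n) for n in np.nonzero(energy > 0.1 * energy.max())[0]]


def solve_wiener(corr: CorrelationSet, cfg: WienerConfig) -> FilterBank:
    """Solve ``(Cxx + ridge I) h = Ryx`` for the full filter bank.

    All M output columns reuse a single symmetric positive-definite
    factorization, so per-output and joint solves are identical to machine
    precision.  See :class:`WienerConfig` for the singular-Cxx fallback.
    """
    NL = corr.cxx.shape[0]
    A = corr.cxx
    if cfg.ridge > 0:
        A = A + cfg.ridge * np.eye(NL)

    w = None
    try:
        cho = scipy.linalg.cho_factor(A)
        w = scipy.linalg.cho_solve(cho, corr.ryx)
    except np.linalg.LinAlgError:
        pass
    if w is None:
        if not cfg.fallback:
            bad = _name_deficient_channels(corr.cxx, corr.n_inputs, corr.L)
            raise RankDeficiencyError(
                "Cxx is rank deficient with ridge=0 and fallback disabled; "
                f"offending input channels: {bad}"
            )
        auto = 1e-8 * np.trace(corr.cxx) / NL
        warnings.warn(
            f"Cxx not positive definite; retrying with ridge={auto:.3e}",
            RuntimeWarning,
            stacklevel=2,
        )
        try:
            cho = scipy.linalg.cho_factor(A + auto * np.eye(NL))
            w = scipy.linalg.cho_solve(cho, corr.ryx)
        except np.linalg.LinAlgError:
            w, *_ = scipy.linalg.lstsq(A, corr.ryx)

    taps = w.reshape(corr.n_inputs, corr.L, corr.n_outputs).transpose(0, 2, 1)
    return FilterBank(taps=taps, lag0=corr.lag0, fs=corr.fs)


def predict_artifacts(X: MultichannelSignal, H: FilterBank) -> MultichannelSignal:
    """Predict artifacts by convolving the stimulation currents with H.

    Output channel m is ``sum_n (x_n * h_nm)`` with zero-padded edges and the
    bank's ``lag0`` honoured; output length equals the input length.
    """
    if X.fs != H.fs:
        raise AlignmentError(f"stimulus fs {X.fs} != filter fs {H.fs}")
    if X.n_channels != H.n_inputs:
        raise ValueError(
            f"stimulus has {X.n_channels} channels but filter bank expects {H.n_inputs}"
        )
    K = X.n_samples
    out = np.zeros((K, H.n_outputs))
    for n in range(H.n_inputs):
        xn = X.samples[:, n]
        if not np.any(xn):
            continue
        for m in range(H.n_outputs):
            full = scipy.signal.fftconvolve(xn, H.taps[n, m])
            out[:, m] += full[H.lag0:H.lag0 + K]
    units = MICROVOLT if X.units == MICROAMP else DIMENSIONLESS
    return MultichannelSignal(out, fs=X.fs, units=units)


def clean(Y: MultichannelSignal, Yhat: MultichannelSignal) -> MultichannelSignal:
    """Subtract the predicted artifact: ``Y - Yhat`` elementwise."""
    require_alignment(Y, Yhat)
    if Y.n_channels != Yhat.n_channels:
        raise AlignmentError("channel counts differ")
    if Y.units != Yhat.units and DIMENSIONLESS not in (Y.units, Yhat.units):
        raise UnitsError(f"cannot subtract {Yhat.units} from {Y.units}")
    return Y.with_samples(Y.samples - Yhat.samples)


def make_split(
    kind: str | None, n_samples: int, trial_len: int | None = None
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Standard train/test partitions as lists of (start, stop) segments.

    ``none`` trains on everything, ``halves`` trains on the first half, and
    ``even-odd`` alternates trials of ``trial_len`` samples (even-indexed
    trials train).
    """
    if kind in (None, "none"):
        return [(0, n_samples)], []
    if kind == "halves":
        half = n_samples // 2
        return [(0, half)], [(half, n_samples)]
    if kind == "even-odd":
        if not trial_len or trial_len < 1:
            raise ValueError("even-odd split requires a positive trial_len")
        train, test = [], []
        for i, a in enumerate(range(0, n_samples, trial_len)):
            seg = (a, min(a + trial_len, n_samples))
            (train if i % 2 == 0 else test).append(seg)
        return train, test
    raise ValueError(f"unknown split kind {kind!r}")


@dataclass
class FitResult:
    """Output of :func:`fit_and_clean`.

    ``cross_validated`` flags whether any held-out samples exist, i.e.
    whether metrics computed on ``test_segments`` are cross-validated.
    """

    filters: FilterBank
    cleaned: MultichannelSignal
    predicted: MultichannelSignal
    train_segments: list[tuple[int, int]]
    test_segments: list[tuple[int, int]]
    cross_validated: bool


def fit_and_clean(
    X: MultichannelSignal,
    Y: MultichannelSignal,
    cfg: WienerConfig,
    split: str | tuple[list[tuple[int, int]], list[tuple[int, int]]] | None = None,
    trial_len: int | None = None,
) -> FitResult:
    """Estimate filters on the training partition, then clean everything.

    ``split`` is either a named policy (``none``, ``halves``, ``even-odd``;
    the latter needs ``trial_len``) or an explicit
    ``(train_segments, test_segments)`` pair.  Filters are estimated from
    the training segments only; the artifact prediction and subtraction are
    applied to the full record so both partitions come back cleaned.
    """
    if isinstance(split, tuple):
        train, test = [list(map(tuple, s)) for s in split]
    else:
        train, test = make_split(split, X.n_samples, trial_len)
    if not train:
        raise ValueError("empty training partition")
    corr = build_normal_equations(X, Y, cfg, segments=train)
    H = solve_wiener(corr, cfg)
    Yhat = predict_artifacts(X, H)
    return FitResult(
        filters=H,
        cleaned=clean(Y, Yhat),
        predicted=Yhat,
        train_segments=train,
        test_segments=test,
        cross_validated=bool(test),
    )


def template_baseline(
    aligned_trials: Sequence[MultichannelSignal],
    holdout_index: int,
    mode: str = "single",
    template_index: int | None = None,
) -> MultichannelSignal:
    """Trial-template control: the linearity-free artifact estimate.

    With repeated identical stimulation, one trial (or the mean of the
    non-holdout trials) can serve directly as the artifact template to
    subtract from the held-out trial.  This is the classic control that
    needs no linearity assumption, at the cost of carrying one (or 1/(T-1))
    extra unit of trial noise into the residual.
    """
    T = len(aligned_trials)
    if T < 2:
        raise ValueError("template baseline needs at least 2 trials")
    if not 0 <= holdout_index < T:
        raise ValueError("holdout_index out of range")
    ref = aligned_trials[holdout_index]
    for t in aligned_trials:
        require_alignment(ref, t)
    if mode == "single":
        if template_index is None:
            template_index = 0 if holdout_index != 0 else 1
        if template_index == holdout_index:
            raise ValueError("template trial must differ from the holdout trial")
        return aligned_trials[template_index]
    if mode == "mean":
        others = [t.samples for i, t in enumerate(aligned_trials) if i != holdout_index]
        return ref.with_samples(np.mean(others, axis=0))
    raise ValueError(f"unknown mode {mode!r}")


class WienerArtifactFilter(RegressorMixin, BaseEstimator):
    """sklearn-style estimator for MIMO stimulation-artifact prediction.

    ``fit(X, y)`` takes the stimulation currents ``X`` of shape (K, N) and
    the recordings ``y`` of shape (K, M) (or (K,)), solves the Wiener-Hopf
    normal equations, and stores the filter bank; ``predict(X)`` returns the
    predicted artifact and ``clean(X, y)`` the artifact-subtracted
    recording.  Composes with sklearn model selection; ``score`` is the R^2
    of the artifact prediction.

    Parameters
    ----------
    n_taps : int, default 40
        FIR length per stimulation channel.
    lag0 : int, default 0
        Acausal tap offset (0 = purely causal).
    ridge : float, default 0.0
        Diagonal loading of Cxx.
    normalization : {"biased", "unbiased"}
    fallback : bool
        Automatic regularised retry on a singular Cxx (see
        :class:`WienerConfig`).
    fs : float, default 1.0
        Sampling rate attached to the fitted :class:`FilterBank`.

    Attributes
    ----------
    filter_bank_ : FilterBank
        Estimated impulse responses, shape (N, M, n_taps).
    coef_ : ndarray
        Alias of ``filter_bank_.taps``.
    correlations_ : CorrelationSet
        The normal-equation blocks used for the solve.
    """

    def __init__(
        self,
        n_taps: int = 40,
        lag0: int = 0,
        ridge: float = 0.0,
        normalization: str = "biased",
        fallback: bool = True,
        fs: float = 1.0,
    ) -> None:
        self.n_taps = n_taps
        self.lag0 = lag0
        self.ridge = ridge
        self.normalization = normalization
        self.fallback = fallback
        self.fs = fs

    def _config(self) -> WienerConfig:
        return WienerConfig(
            L=self.n_taps,
            lag0=self.lag0,
            ridge=self.ridge,
            normalization=self.normalization,
            fallback=self.fallback,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "WienerArtifactFilter":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        self._y_ndim = y.ndim
        Xs = MultichannelSignal(X, fs=self.fs)
        Ys = MultichannelSignal(y, fs=self.fs)
        cfg = self._config()
        self.correlations_ = build_normal_equations(Xs, Ys, cfg)
        self.filter_bank_ = solve_wiener(self.correlations_, cfg)
        self.coef_ = self.filter_bank_.taps
        self.n_features_in_ = Xs.n_channels
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "filter_bank_"):
            raise AttributeError("estimator is not fitted; call fit first")
        Xs = MultichannelSignal(np.asarray(X, dtype=np.float64), fs=self.fs)
        out = predict_artifacts(Xs, self.filter_bank_).samples
        return out[:, 0] if self._y_ndim == 1 else out

    def clean(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Return ``y`` with the predicted artifact subtracted."""
        return np.asarray(y, dtype=np.float64) - self.predict(X)
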