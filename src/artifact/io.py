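"""File containers, run configuration and the end-to-end pipeline.

Signals travel as HDF5 (a dataset of shape K x C with ``fs``, ``units`` and
``channel_ids`` attributes; the canonical container uses datasets ``/stim``
and ``/rec``) or, for small fixtures, as CSV with one time column plus one
column per channel.  Filter banks are an HDF5 dataset of shape N x M x L
with ``lag0``, ``fs`` and ``units`` attributes.  Channel indexing is 0-based
everywhere; samples are float64.

:func:`run_pipeline` ties the modules together for a synthetic benchmark
run: generate the stimulation program and ground-truth coupling, simulate
trials, fit and clean, evaluate spectra/ARR and linearity, and write the
filters, cleaned traces and a JSON report carrying a provenance block
(config hash, package versions, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import pandas as pd
import pydantic
import yaml

from . import bench, linearity, spectral, stimgen, wiener
from .signals import DIMENSIONLESS, VALID_UNITS, FilterBank, MultichannelSignal

__all__ = [
    "read_signals",
    "write_signals",
    "read_filterbank",
    "write_filterbank",
    "RunConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# signal containers


def write_signals(signal: MultichannelSignal, path: str | Path, name: str = "signal") -> None:
    """Write a signal to HDF5 (or CSV when the suffix is .csv)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.DataFrame(signal.samples, columns=list(signal.channel_ids))
        df.insert(0, "time_s", signal.times)
        df.attrs["units"] = signal.units
        df.to_csv(path, index=False)
        return
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        d = f.create_dataset(name, data=signal.samples)
        d.attrs["fs"] = signal.fs
        d.attrs["units"] = signal.units
        d.attrs["channel_ids"] = list(signal.channel_ids)


def read_signals(
    path: str | Path, name: str | None = None, units: str | None = None
) -> MultichannelSignal:
    """Read a signal from HDF5 or CSV.

    For HDF5, ``name`` selects the dataset; when omitted, ``signal``,
    ``stim`` or ``rec`` is tried in that order.  CSV carries no units
    metadata, so ``units`` may be supplied (default dimensionless); the
    sampling rate is inferred from the time column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such signal file: {path}")
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("CSV needs a time column plus at least one channel")
        t = df.iloc[:, 0].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size < 2 or np.any(dt <= 0):
            raise ValueError("time column must be strictly increasing")
        fs = 1.0 / float(np.median(dt))
        return MultichannelSignal(
            df.iloc[:, 1:].to_numpy(dtype=float), fs=fs,
            units=units or DIMENSIONLESS, channel_ids=tuple(df.columns[1:]),
        )
    with h5py.File(path, "r") as f:
        if name is None:
            for cand in ("signal", "stim", "rec"):
                if cand in f:
                    name = cand
                    break
            else:
                raise KeyError(f"no signal dataset found in {path}")
        d = f[name]
        for attr in ("fs", "units"):
            if attr not in d.attrs:
                raise KeyError(f"dataset {name!r} missing required attribute {attr!r}")
        file_units = d.attrs["units"]
        file_units = file_units.decode() if isinstance(file_units, bytes) else str(file_units)
        if units is not None and units != file_units:
            raise ValueError(f"file stores {file_units}, expected {units}")
        ids = d.attrs.get("channel_ids")
        ids = tuple(c.decode() if isinstance(c, bytes) else str(c) for c in ids) if ids is not None else None
        return MultichannelSignal(d[()], fs=float(d.attrs["fs"]), units=file_units, channel_ids=ids)


def write_filterbank(bank: FilterBank, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("taps", data=bank.taps)
        d.attrs["lag0"] = bank.lag0
        d.attrs["fs"] = bank.fs
        d.attrs["units"] = "microvolt_per_microamp"
        d.attrs["lag_layout"] = "channel-major"


def read_filterbank(path: str | Path) -> FilterBank:
    with h5py.File(path, "r") as f:
        d = f["taps"]
        return FilterBank(taps=d[()], lag0=int(d.attrs["lag0"]), fs=float(d.attrs["fs"]))


# ---------------------------------------------------------------------------
# run configuration (schema-validated; unknown keys rejected)


class _Strict(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    kind: Literal["rqp", "poisson", "monophasic", "ci"] = "rqp"
    fs: float = 12000.0
    duration_s: float = 10.0
    n_channels: int = 16
    n_active: int = 4
    amplitude_uA: float = 10.0
    rate_hz: float = 16.0
    dynamic: bool = False


class WienerSection(_Strict):
    taps: int = 40
    lag0: int = 0
    ridge: float = 0.0
    normalization: Literal["biased", "unbiased"] = "biased"


class WelchSection(_Strict):
    segment_len: int = 256
    kaiser_beta: float = 5.0
    overlap_fraction: float = 0.5


class BenchSection(_Strict):
    n_rec_channels: int = 4
    coupling: Literal["delta_gain", "rc_decay", "random_fir", "mixed"] = "rc_decay"
    coupling_taps: int = 24
    noise_sigma_uv: float = 1.0
    artifact_to_neural_db: float = 20.0
    n_trials: int = 2


class RunConfig(_Strict):
    """Validated configuration for an end-to-end synthetic pipeline run."""

    protocol: ProtocolConfig = ProtocolConfig()
    wiener: WienerSection = WienerSection()
    welch: WelchSection = WelchSection()
    bench: BenchSection = BenchSection()
    band_hz: tuple[float, float] = (300.0, 6000.0)
    split: Literal["none", "halves", "even-odd"] = "halves"
    seed: int = 0
    outdir: str = "artifact_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            payload = yaml.safe_load(f) or {}
        return cls.model_validate(payload)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _make_stim(p: ProtocolConfig, seed: int) -> stimgen.StimProgram:
    if p.kind == "rqp":
        return stimgen.rqp_sequence(
            n_channels=p.n_channels, n_active=p.n_active, duration=p.duration_s,
            amplitude=p.amplitude_uA, dynamic=p.dynamic, fs=p.fs, seed=seed,
        )
    if p.kind == "poisson":
        return stimgen.poisson_train(
            rate=p.rate_hz, duration=p.duration_s, amplitude=p.amplitude_uA,
            fs=p.fs, seed=seed,
        )
    if p.kind == "monophasic":
        return stimgen.monophasic_protocol(fs=p.fs, seed=seed)
    return stimgen.ci_pulse_train(duration=p.duration_s, fs=p.fs, amplitude=p.amplitude_uA)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full synthetic pipeline and write artifacts to ``cfg.outdir``.

    Deterministic given the config (which includes the seed).  Returns the
    report payload that is also written to ``report.json``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stim = _make_stim(cfg.protocol, cfg.seed)
    model = bench.CouplingModel(kind=cfg.bench.coupling, seed=cfg.seed)
    h_true = bench.make_coupling_filters(
        stim.signal.n_channels, cfg.bench.n_rec_channels,
        cfg.bench.coupling_taps, model, fs=stim.signal.fs,
    )
    ds = bench.simulate_recording(
        stim, h_true, neural=bench.NeuralModel(),
        noise_sigma_uv=cfg.bench.noise_sigma_uv, n_trials=cfg.bench.n_trials,
        seed=cfg.seed, artifact_to_neural_db=cfg.bench.artifact_to_neural_db,
    )

    wcfg = wiener.WienerConfig(
        L=cfg.wiener.taps, lag0=cfg.wiener.lag0, ridge=cfg.wiener.ridge,
        normalization=cfg.wiener.normalization,
    )
    fit = wiener.fit_and_clean(stim.signal, ds.composite[0], wcfg, split=cfg.split)
    fit2_pred = wiener.predict_artifacts(stim.signal, fit.filters)
    cleaned2 = wiener.clean(ds.composite[1], fit2_pred)

    welch_cfg = spectral.WelchConfig(
        segment_len=cfg.welch.segment_len, kaiser_beta=cfg.welch.kaiser_beta,
        overlap_fraction=cfg.welch.overlap_fraction,
    )
    pre_pair = spectral.TrialPair(ds.composite[0], ds.composite[1])
    post_pair = spectral.TrialPair(fit.cleaned, cleaned2)
    arr_curve = spectral.arr(pre_pair, post_pair, welch_cfg, floor=1e-30)
    snr_pre = spectral.snr_shuffled(pre_pair, welch_cfg)
    snr_post = spectral.snr_shuffled(post_pair, welch_cfg)

    events = [e for e in stim.events if e.channel == 0]
    lin = None
    if len(events) >= 3:
        p2p_in = np.array([abs(e.amplitude) for e in events])
        p2p_art = linearity.peak_to_peak(
            ds.artifact, [e.time for e in events], window=1e-3
        )
        if np.var(p2p_in) > 0:
            lin = linearity.linearity_r2(linearity.AmplitudePairs(p2p_in, p2p_art))

    write_filterbank(fit.filters, outdir / "filters.h5")
    write_signals(stim.signal, outdir / "data.h5", name="stim")
    write_signals(ds.composite[0], outdir / "data.h5", name="rec")
    write_signals(fit.cleaned, outdir / "cleaned.h5", name="rec")

    band = cfg.band_hz
    report = {
        "provenance": {
            "config_hash": cfg.digest(),
            "seed": cfg.seed,
            "versions": _versions(),
        },
        "config": cfg.model_dump(),
        "cross_validated": fit.cross_validated,
        "arr_band_db": _as_jsonable(spectral.band_average(arr_curve, *band)),
        "snr_pre_band_db": _as_jsonable(spectral.band_average(snr_pre, *band)),
        "snr_post_band_db": _as_jsonable(spectral.band_average(snr_post, *band)),
        "linearity": lin,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _as_jsonable(v):
    if isinstance(v, np.ndarray):
        return [float(x) for x in v]
    return float(v)


def _versions() -> dict[str, str]:
    import scipy

    from . import __version__

    return {"artifact": __version__, "numpy": np.__version__, "scipy": scipy.__version__}
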