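"""Stimulation-current program generators.

Every program is returned as a :class:`StimProgram`: the sampled current
waveform (microamps) plus the event list (time, channel, amplitude, label)
that generated it.  Waveforms are built by placing a unit pulse kernel at
each event sample and scaling by the event amplitude, so reconstructing the
waveform from the events reproduces it exactly.

Programs provided:

* :func:`monophasic_protocol` -- slow sub/supra-threshold cathodic pulses at
  six amplitudes in pseudo-random order (nerve-trunk protocol);
* :func:`ci_pulse_train` -- bilateral cochlear-implant style trains of
  anode-leading triphasic pulses at 300 pps with an interaural time
  difference (ITD) and optional Hanning amplitude envelope;
* :func:`poisson_train` -- Poisson-timed biphasic pulses (midbrain protocol);
* :func:`rqp_sequence` -- random quad-pulse trains: 4 of 16 channels fire
  concurrently every 40 ms, amplitudes fixed or log-stepped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signals import MICROAMP, MultichannelSignal

__all__ = [
    "PulseShape",
    "StimEvent",
    "StimProgram",
    "monophasic_protocol",
    "ci_pulse_train",
    "poisson_train",
    "rqp_sequence",
    "count_rqp_conditions",
]


@dataclass
class PulseShape:
    """Unit-amplitude stimulus pulse kernel.

    kinds
    -----
    ``monophasic_cathodic``
        A single negative phase of ``phase_duration`` seconds.
    ``biphasic``
        Charge-balanced pair of equal phases (+1 then -1), total duration
        ``2 * phase_duration``; ``anode_leading=False`` flips polarity.
    ``triphasic_ci``
        Three equal phases (+1, 0, -1), the cochlear-implant duty cycle.

    Sample sums of the biphasic/triphasic kernels are exactly zero (charge
    balance) because the phases are realised with identical sample counts.
    """

    kind: str = "biphasic"
    phase_duration: float = 82e-6
    anode_leading: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("monophasic_cathodic", "biphasic", "triphasic_ci"):
            raise ValueError(f"unknown pulse kind {self.kind!r}")
        if self.phase_duration <= 0:
            raise ValueError("phase_duration must be > 0")

    def waveform(self, fs: float) -> np.ndarray:
        """Sampled unit kernel at rate ``fs``; raises if fs is too low."""
        n = round(self.phase_duration * fs)
        if n < 1:
            raise ValueError(
                f"fs={fs} Hz too low to represent a {self.phase_duration * 1e6:.1f} us phase"
            )
        sign = 1.0 if self.anode_leading else -1.0
        if self.kind == "monophasic_cathodic":
            return -np.ones(n)
        if self.kind == "biphasic":
            return sign * np.concatenate([np.ones(n), -np.ones(n)])
        return sign * np.concatenate([np.ones(n), np.zeros(n), -np.ones(n)])


@dataclass
class StimEvent:
    """One pulse: onset time (s), channel index, amplitude (uA), label."""

    time: float
    channel: int
    amplitude: float
    label: str = ""


@dataclass
class StimProgram:
    """A realized stimulation program: waveform + event metadata."""

    signal: MultichannelSignal
    events: list[StimEvent]
    pulse: PulseShape
    seed: int | None = None
    protocol: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def event_rate(self) -> float:
        """Events per second over the program duration."""
        return self.n_events / self.signal.duration

    def amplitude_histogram(self) -> dict[float, int]:
        hist: dict[float, int] = {}
        for e in self.events:
            hist[e.amplitude] = hist.get(e.amplitude, 0) + 1
        return hist

    def reconstruct(self) -> np.ndarray:
        """Rebuild the waveform from the event list (must equal ``signal``)."""
        return _render(
            self.events, self.pulse, self.signal.fs,
            self.signal.n_samples, self.signal.n_channels,
        )


def _render(
    events: Sequence[StimEvent], pulse: PulseShape, fs: float, n_samples: int, n_channels: int
) -> np.ndarray:
    kernel = pulse.waveform(fs)
    out = np.zeros((n_samples, n_channels))
    for e in events:
        k0 = round(e.time * fs)
        k1 = min(k0 + kernel.size, n_samples)
        if k0 < 0 or k0 >= n_samples:
            raise ValueError(f"event at {e.time} s falls outside the record")
        out[k0:k1, e.channel] += e.amplitude * kernel[: k1 - k0]
    return out


def _program(
    events: list[StimEvent], pulse: PulseShape, fs: float, n_samples: int,
    n_channels: int, seed: int | None, protocol: dict,
) -> StimProgram:
    samples = _render(events, pulse, fs, n_samples, n_channels)
    sig = MultichannelSignal(samples, fs=fs, units=MICROAMP)
    return StimProgram(signal=sig, events=events, pulse=pulse, seed=seed, protocol=protocol)


def monophasic_protocol(
    amplitudes: Sequence[float] = (10, 20, 40, 80, 160, 320),
    reps: int = 10,
    rate: float = 0.5,
    width: float = 0.2e-3,
    fs: float = 25000.0,
    seed: int | None = 0,
) -> StimProgram:
    """Sub/supra-threshold cathodic pulse protocol, single channel.

    Defaults give a 120-s program: 6 amplitudes x 10 repeats at 0.5 Hz with
    0.2-ms cathodic (negative) pulses, amplitude order pseudo-random by
    ``seed``.  Event amplitudes are stored as positive magnitudes; the
    cathodic kernel carries the negative polarity.
    """
    pulse = PulseShape(kind="monophasic_cathodic", phase_duration=width)
    pulse.waveform(fs)  # validate fs before building anything
    rng = np.random.default_rng(seed)
    amps = np.repeat(np.asarray(amplitudes, dtype=float), reps)
    order = rng.permutation(amps.size)
    n_pulses = amps.size
    duration = max(n_pulses / rate, 1.0 / fs)
    events = [
        StimEvent(time=i / rate, channel=0, amplitude=float(amps[order[i]]),
                  label=f"{amps[order[i]]:g}uA")
        for i in range(n_pulses)
    ]
    return _program(
        events, pulse, fs, round(duration * fs), 1, seed,
        {"protocol": "monophasic", "rate_hz": rate, "reps": reps,
         "amplitudes_uA": list(map(float, amplitudes))},
    )


def ci_pulse_train(
    rate: float = 300.0,
    duration: float = 0.2,
    itd_us: float = 0.0,
    fs: float = 24414.0,
    hanning: bool = False,
    amplitude: float = 100.0,
    phase_duration: float = 40.96e-6,
) -> StimProgram:
    """Bilateral cochlear-implant pulse train (channels: 0 = left, 1 = right).

    Anode-leading triphasic pulses (equal +/0/- phases, 40.96 us each at the
    stimulator's native 24414 Hz, i.e. one sample per phase) at ``rate``
    pulses per second for ``duration`` seconds.  The right-channel train is
    the left train delayed by ``round(itd_us * fs)`` samples -- the ITD grid
    is realised as integer sample shifts.  ``hanning=True`` applies a
    raised-cosine amplitude envelope across the pulses of the train.
    """
    pulse = PulseShape(kind="triphasic_ci", phase_duration=phase_duration, anode_leading=True)
    kernel = pulse.waveform(fs)
    shift = round(itd_us * 1e-6 * fs)
    if abs(itd_us) * 1e-6 >= duration:
        raise ValueError("ITD exceeds the train duration")
    n_pulses = round(rate * duration)
    env = np.hanning(n_pulses) if hanning and n_pulses > 1 else np.ones(max(n_pulses, 0))
    times = np.arange(n_pulses) / rate
    right_offset = shift / fs
    events: list[StimEvent] = []
    for i, t in enumerate(times):
        a = float(amplitude * env[i])
        events.append(StimEvent(t, 0, a, label=f"itd={itd_us:g}us"))
        events.append(StimEvent(t + right_offset, 1, a, label=f"itd={itd_us:g}us"))
    # cover the shifted train and the pulse tail
    n_samples = round(duration * fs) + abs(shift) + kernel.size
    if events and min(e.time for e in events) < 0:
        # negative ITD leads the right channel; shift everything to t >= 0
        t0 = -min(e.time for e in events)
        events = [StimEvent(e.time + t0, e.channel, e.amplitude, e.label) for e in events]
    return _program(
        events, pulse, fs, n_samples, 2, None,
        {"protocol": "ci", "rate_pps": rate, "duration_s": duration,
         "itd_us": itd_us, "hanning": hanning, "amplitude_uA": amplitude},
    )


def poisson_train(
    rate: float = 16.0,
    duration: float = 86.0,
    amplitude: float = 40.0,
    pulse_duration: float = 164e-6,
    fs: float = 12000.0,
    seed: int | None = 0,
) -> StimProgram:
    """Poisson-timed biphasic pulse sequence, single channel.

    Inter-event intervals are exponential with mean ``1/rate``; each event is
    a charge-balanced biphasic pulse (``pulse_duration`` total, equal
    phases).  ``rate=0`` yields an empty program.
    """
    pulse = PulseShape(kind="biphasic", phase_duration=pulse_duration / 2)
    pulse.waveform(fs)
    rng = np.random.default_rng(seed)
    times: list[float] = []
    if rate > 0:
        t = rng.exponential(1.0 / rate)
        while t < duration:
            times.append(t)
            t += rng.exponential(1.0 / rate)
    events = [StimEvent(t, 0, amplitude, label="poisson") for t in times]
    return _program(
        events, pulse, fs, round(duration * fs), 1, seed,
        {"protocol": "poisson", "rate_hz": rate, "duration_s": duration,
         "amplitude_uA": amplitude},
    )


def rqp_sequence(
    n_channels: int = 16,
    n_active: int = 4,
    interval: float = 0.040,
    duration: float = 86.0,
    amplitude: float = 10.0,
    dynamic: bool = False,
    amp_range: tuple[float, float] = (0.1, 10.0),
    n_amp_steps: int = 11,
    pulse_duration: float = 164e-6,
    fs: float = 12000.0,
    seed: int | None = 0,
) -> StimProgram:
    """Random quad-pulse (RQP) program.

    Every ``interval`` (default 40 ms) exactly ``n_active`` distinct channels
    of ``n_channels`` fire a biphasic pulse concurrently -- 4 of 16 every
    40 ms yields an average rate of 100 pulses/s.  With ``dynamic=True``
    each pulse amplitude is drawn from a logarithmic grid of
    ``n_amp_steps`` levels spanning ``amp_range`` (defaults: 0.1-10 uA,
    11 steps, consecutive levels a factor 10^0.2 apart).
    """
    if not 1 <= n_active <= n_channels:
        raise ValueError("need 1 <= n_active <= n_channels")
    pulse = PulseShape(kind="biphasic", phase_duration=pulse_duration / 2)
    pulse.waveform(fs)
    rng = np.random.default_rng(seed)
    levels = np.logspace(np.log10(amp_range[0]), np.log10(amp_range[1]), n_amp_steps)
    n_intervals = round(duration / interval)
    events: list[StimEvent] = []
    for i in range(n_intervals):
        t = i * interval
        chans = rng.choice(n_channels, size=n_active, replace=False)
        for c in np.sort(chans):
            a = float(rng.choice(levels)) if dynamic else float(amplitude)
            events.append(StimEvent(t, int(c), a, label="rqp"))
    return _program(
        events, pulse, fs, round(duration * fs), n_channels, seed,
        {"protocol": "rqp", "n_channels": n_channels, "n_active": n_active,
         "interval_s": interval, "duration_s": duration, "dynamic": dynamic},
    )


def count_rqp_conditions(
    n_channels: int, n_active: int, n_amplitudes: int
) -> dict[str, int]:
    """Size of the RQP condition space.

    ``n_combinations = C(n_channels, n_active)`` channel subsets; each
    subset at each amplitude produces a distinct composite artifact, so
    ``n_unique_artifacts = n_combinations * n_amplitudes`` (e.g. C(16, 4) =
    1820 and 1820 x 6 = 10920).
    """
    n_comb = math.comb(n_channels, n_active)
    return {"n_combinations": n_comb, "n_unique_artifacts": n_comb * n_amplitudes}
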