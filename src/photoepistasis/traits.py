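"""Quantitative traits of the single-photon response.

From an ensemble of quantum-bump trials we extract:

* **reliability** R — probability that one photon elicits a detectable bump
  (peak open-channel count reaching the detection threshold);
* **amplitude** A — peak of the trial-averaged response (channels), the
  analogue of the recorded flash-response peak current;
* **duration** T — full width at half maximum of the trial-averaged response
  (ms);
* **latency** — mean first threshold-crossing time over successful trials;
* **composite** — product of two sigmoids rewarding high amplitude and short
  duration, a dimensionless performance trait in [0, 1].

Amplitude and duration are computed on the trial-averaged trace by default
(failures included, as in a flash average over many microvilli); a per-trial
averaging variant is available via ``per_trial=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .simulate import QBEnsemble, QBTrace

__all__ = [
    "TraitDefinition",
    "TraitValue",
    "detect_qb",
    "trait_reliability",
    "mean_response",
    "trait_amplitude",
    "trait_duration",
    "trait_latency",
    "trait_composite",
    "compute_trait",
    "anchor_composite",
]

TRAIT_NAMES = ("reliability", "amplitude", "duration", "latency", "composite")


@dataclass(frozen=True)
class TraitDefinition:
    """Which trait to compute and with what constants.

    ``theta`` is the bump-detection threshold in open channels.  The
    composite trait needs reference amplitude/duration anchors ``a0, t0``
    with sigmoid widths ``da, dt`` (set them from the reference genotype with
    :func:`anchor_composite`).
    """

    name: str = "composite"
    theta: float = 2.0
    a0: float | None = None
    da: float | None = None
    t0: float | None = None
    dt: float | None = None
    per_trial: bool = False

    def __post_init__(self) -> None:
        if self.name not in TRAIT_NAMES:
            raise ValueError(f"unknown trait {self.name!r}; expected one of {TRAIT_NAMES}")
        if self.theta < 1:
            raise ValueError("detection threshold theta must be >= 1 channel")
        for label in ("a0", "da", "t0", "dt"):
            v = getattr(self, label)
            if v is not None and v <= 0:
                raise ValueError(f"composite constant {label} must be positive")


@dataclass(frozen=True)
class TraitValue:
    name: str
    value: float
    stderr: float
    n_trials: int


def detect_qb(trace: QBTrace | np.ndarray, theta: float) -> tuple[bool, float | None]:
    """Per-trial bump detection: did the open-channel count reach theta, and when.

    Returns ``(success, latency_ms)``; latency is the first grid time at
    which the count reaches the threshold, ``None`` on failure.
    """
    if theta < 1:
        raise ValueError("theta must be >= 1")
    if isinstance(trace, QBTrace):
        counts, times = trace.open_channels, trace.time_ms
    else:
        counts = np.asarray(trace)
        times = np.arange(counts.shape[-1], dtype=float)
    if counts.size == 0:
        raise ValueError("empty trace")
    hits = counts >= theta
    if not hits.any():
        return False, None
    return True, float(times[int(np.argmax(hits))])


def _success_latency(ensemble: QBEnsemble, theta: float) -> tuple[np.ndarray, np.ndarray]:
    hits = ensemble.open_channels >= theta
    success = hits.any(axis=1)
    first = np.argmax(hits, axis=1)
    latencies = ensemble.time_ms[first]
    return success, latencies[success]


def trait_reliability(ensemble: QBEnsemble, theta: float = 2.0) -> TraitValue:
    """Fraction of trials with a detectable bump; binomial standard error."""
    success, _ = _success_latency(ensemble, theta)
    n = ensemble.n_trials
    p = success.mean()
    return TraitValue("reliability", float(p), float(np.sqrt(p * (1 - p) / n)), n)


def trait_latency(ensemble: QBEnsemble, theta: float = 2.0) -> TraitValue:
    """Mean first-crossing time over successful trials (NaN if none succeed)."""
    _, lat = _success_latency(ensemble, theta)
    if lat.size == 0:
        return TraitValue("latency", float("nan"), float("nan"), ensemble.n_trials)
    sd = lat.std(ddof=1) if lat.size > 1 else 0.0
    return TraitValue("latency", float(lat.mean()), float(sd / np.sqrt(lat.size)),
                      ensemble.n_trials)


def mean_response(ensemble: QBEnsemble) -> np.ndarray:
    """Pointwise trial average of the open-channel traces, failures included."""
    return ensemble.open_channels.mean(axis=0)


def _fwhm(avg: np.ndarray, times: np.ndarray) -> float:
    """Full width at half maximum with linear interpolation at the crossings."""
    peak = avg.max()
    if peak <= 0:
        return 0.0
    half = 0.5 * peak
    above = avg >= half
    i_first = int(np.argmax(above))
    i_last = len(avg) - 1 - int(np.argmax(above[::-1]))
    # rising edge
    if i_first == 0:
        t_rise = times[0]
    else:
        y0, y1 = avg[i_first - 1], avg[i_first]
        t_rise = times[i_first - 1] + (half - y0) / (y1 - y0) * (times[i_first] - times[i_first - 1])
    # falling edge
    if i_last == len(avg) - 1:
        t_fall = times[-1]
    else:
        y0, y1 = avg[i_last], avg[i_last + 1]
        t_fall = times[i_last] + (y0 - half) / (y0 - y1) * (times[i_last + 1] - times[i_last])
    return float(t_fall - t_rise)


def trait_amplitude(avg: np.ndarray, times: np.ndarray | None = None) -> float:
    """Peak of the averaged response, in channels (0 for a flat-zero average)."""
    avg = np.asarray(avg, dtype=float)
    if np.any(avg < 0):
        raise ValueError("averaged response must be non-negative")
    return float(avg.max()) if avg.size else 0.0


def trait_duration(avg: np.ndarray, times: np.ndarray) -> float:
    """FWHM of the averaged response in ms (0 for a flat-zero average)."""
    avg = np.asarray(avg, dtype=float)
    if np.any(avg < 0):
        raise ValueError("averaged response must be non-negative")
    return _fwhm(avg, np.asarray(times, dtype=float))


def _logistic(x: float, x0: float, dx: float) -> float:
    return 1.0 / (1.0 + np.exp(-(x - x0) / dx))


def trait_composite(a: float, t: float, a0: float, da: float, t0: float, dt: float) -> float:
    """Sigmoid performance trait: rises with amplitude, falls with duration.

    ``logistic(A; a0, da) * (1 - logistic(T; t0, dt))``; equals 0.25 when the
    response sits exactly at the anchors.
    """
    if min(da, dt) <= 0:
        raise ValueError("sigmoid widths must be positive")
    return float(_logistic(a, a0, da) * (1.0 - _logistic(t, t0, dt)))


def anchor_composite(definition: TraitDefinition, reference_ensemble: QBEnsemble,
                     rel_width: float = 0.2) -> TraitDefinition:
    """Fill the composite anchors from a reference-genotype ensemble.

    Sets ``a0, t0`` to the reference amplitude and duration and the widths to
    ``rel_width`` times the anchors, making the composite 0.25 at reference.
    """
    avg = mean_response(reference_ensemble)
    a0 = trait_amplitude(avg)
    t0 = trait_duration(avg, reference_ensemble.time_ms)
    if a0 <= 0 or t0 <= 0:
        raise ValueError("reference ensemble has no detectable average response")
    return replace(definition, a0=a0, da=rel_width * a0, t0=t0, dt=rel_width * t0)


def _per_trial_amp_dur(ensemble: QBEnsemble) -> tuple[float, float]:
    amps = ensemble.open_channels.max(axis=1).astype(float)
    durs = np.array([
        _fwhm(ensemble.open_channels[i].astype(float), ensemble.time_ms)
        for i in range(ensemble.n_trials)
    ])
    return float(amps.mean()), float(durs.mean())


def compute_trait(ensemble: QBEnsemble, definition: TraitDefinition) -> TraitValue:
    """Evaluate the trait named in ``definition`` on an ensemble."""
    name = definition.name
    if name == "reliability":
        return trait_reliability(ensemble, definition.theta)
    if name == "latency":
        return trait_latency(ensemble, definition.theta)
    if definition.per_trial:
        a, t = _per_trial_amp_dur(ensemble)
    else:
        avg = mean_response(ensemble)
        a = trait_amplitude(avg)
        t = trait_duration(avg, ensemble.time_ms)
    if name == "amplitude":
        return TraitValue("amplitude", a, _mean_peak_stderr(ensemble), ensemble.n_trials)
    if name == "duration":
        return TraitValue("duration", t, float("nan"), ensemble.n_trials)
    if None in (definition.a0, definition.da, definition.t0, definition.dt):
        raise ValueError(
            "composite trait needs a0/da/t0/dt anchors; use anchor_composite()"
        )
    value = trait_composite(a, t, definition.a0, definition.da, definition.t0, definition.dt)
    return TraitValue("composite", value, float("nan"), ensemble.n_trials)


def _mean_peak_stderr(ensemble: QBEnsemble) -> float:
    # spread of the peak of the mean across trials, crude delta estimate
    peak_idx = int(np.argmax(mean_response(ensemble)))
    col = ensemble.open_channels[:, peak_idx].astype(float)
    return float(col.std(ddof=1) / np.sqrt(ensemble.n_trials)) if ensemble.n_trials > 1 else 0.0
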