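"""Spike detection, action-potential metrics and firing-pattern classification.

Traces are classified per stimulus into ``phasic``, ``tonic``, ``silent`` or
one of the artifact categories (``spontaneous``, ``post-stimulus-firing``,
``incomplete-repolarization``); an ordered amplitude sweep then maps each
neuronal genotype onto a phenotype (``phasic``, ``tonic``,
``phasic-to-tonic``, ``tonic-to-phasic`` or ``other``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SpikeTrain",
    "SpikeMetrics",
    "ClassificationRules",
    "TRACE_CLASSES",
    "PHENOTYPES",
    "detect_spikes",
    "spike_metrics",
    "classify_trace",
    "classify_genotype",
    "fi_slope",
]

TRACE_CLASSES = (
    "phasic",
    "tonic",
    "silent",
    "spontaneous",
    "post-stimulus-firing",
    "incomplete-repolarization",
)

PHENOTYPES = ("phasic", "tonic", "phasic-to-tonic", "tonic-to-phasic", "other")

ARTIFACT_CLASSES = ("spontaneous", "post-stimulus-firing", "incomplete-repolarization")


@dataclass(frozen=True)
class SpikeTrain:
    """Upward threshold-crossing times (ms) within one voltage trace."""

    times: np.ndarray
    threshold: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
            raise ValueError("spike times must be strictly increasing 1-D")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SpikeMetrics:
    """Per-trace action-potential summary.

    ``frequency`` is spike count over the stimulus window (Hz); AP shape
    metrics are NaN when the trace has no spikes.
    """

    frequency: float
    n_spikes: int
    ap_peak: float = float("nan")
    max_hyperpolarization: float = float("nan")
    fwhm: float = float("nan")


@dataclass(frozen=True)
class ClassificationRules:
    """Operational thresholds for the firing-pattern taxonomy.

    The tonic rule (last spike within the final ``tonic_tail_fraction`` of
    the stimulus and at least ``tonic_min_spikes`` spikes) and the artifact
    windows are this package's operational definitions; they are exposed so
    the sensitivity of population statistics to the rule can be studied.
    """

    tonic_tail_fraction: float = 0.2
    tonic_min_spikes: int = 3
    post_stim_margin: float = 20.0  # ms after stimulus offset
    repol_window: float = 50.0  # ms at trace end
    repol_excess: float = 10.0  # mV above pre-stimulus baseline


def detect_spikes(
    t: np.ndarray,
    vm: np.ndarray,
    threshold: float = -10.0,
    min_separation: float = 1.0,
) -> SpikeTrain:
    """Upward crossings of ``threshold``; crossings closer than
    ``min_separation`` ms are merged into the first."""
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if t.shape != vm.shape:
        raise ValueError("time and voltage series must have equal length")
    above = vm >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = t[idx]
    if times.size and min_separation > 0:
        keep = [0]
        for i in range(1, times.size):
            if times[i] - times[keep[-1]] >= min_separation:
                keep.append(i)
        times = times[keep]
    return SpikeTrain(times=times, threshold=threshold)


def spike_metrics(t, vm, train: SpikeTrain, stim_onset: float, stim_duration: float) -> SpikeMetrics:
    """AP metrics over the stimulus window.

    Frequency = spikes during the stimulus / stimulus duration.  AP peak is
    the maximum vm per spike; max hyperpolarization is the most negative vm
    between/after spikes during the stimulus; FWHM is measured on the first
    spike at half of (peak - preceding trough).
    """
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    stim_end = stim_onset + stim_duration
    in_stim = train.times[(train.times >= stim_onset) & (train.times <= stim_end)]
    freq = in_stim.size / (stim_duration * 1e-3)
    if in_stim.size == 0:
        return SpikeMetrics(frequency=0.0, n_spikes=0)

    # segment boundaries: spike onsets, stimulus end
    bounds = np.concatenate([in_stim, [stim_end]])
    peaks = []
    for i, ts in enumerate(in_stim):
        seg = (t >= ts) & (t < bounds[i + 1])
        peaks.append(vm[seg].max())
    ap_peak = float(np.max(peaks))
    # hyperpolarization: after the first spike, within the stimulus
    after = (t >= in_stim[0]) & (t <= stim_end)
    max_hyp = float(vm[after].min())
    fwhm = _fwhm_first_spike(t, vm, in_stim[0], bounds[1], stim_onset)
    return SpikeMetrics(
        frequency=freq,
        n_spikes=int(in_stim.size),
        ap_peak=ap_peak,
        max_hyperpolarization=max_hyp,
        fwhm=fwhm,
    )


def _fwhm_first_spike(t, vm, t_spike, t_next, stim_onset) -> float:
    """Width (ms) at half of (peak - preceding trough) around one spike."""
    pre = (t >= stim_onset) & (t <= t_spike)
    trough = vm[pre].min() if np.any(pre) else vm.min()
    seg = (t >= stim_onset) & (t <= t_next)
    ts, vs = t[seg], vm[seg]
    ipk = int(np.argmax(vs))
    half = trough + 0.5 * (vs[ipk] - trough)
    # walk left and right from the peak to the half-height crossings
    left = ipk
    while left > 0 and vs[left] > half:
        left -= 1
    right = ipk
    while right < vs.size - 1 and vs[right] > half:
        right += 1
    t_left = np.interp(half, [vs[left], vs[left + 1]], [ts[left], ts[left + 1]]) if vs[left] <= half else ts[left]
    t_right = (
        np.interp(half, [vs[right], vs[right - 1]], [ts[right], ts[right - 1]]) if vs[right] <= half else ts[right]
    )
    return float(t_right - t_left)


def classify_trace(
    t,
    vm,
    train: SpikeTrain,
    stim_onset: float,
    stim_duration: float,
    rules: ClassificationRules = ClassificationRules(),
) -> str:
    """Assign exactly one firing class to a trace.

    Precedence: spontaneous (any spike before stimulus onset) >
    post-stimulus-firing (any spike after offset + margin) >
    incomplete-repolarization (mean vm over the final window exceeds the
    pre-stimulus baseline by more than ``repol_excess``) > tonic (last spike
    in the final tail fraction of the stimulus and enough spikes) > phasic
    (any spike) > silent.
    """
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    stim_end = stim_onset + stim_duration
    times = train.times
    if np.any(times < stim_onset):
        return "spontaneous"
    if np.any(times > stim_end + rules.post_stim_margin):
        return "post-stimulus-firing"
    pre = (t >= max(0.0, stim_onset - 50.0)) & (t < stim_onset)
    baseline = vm[pre].mean() if np.any(pre) else vm[0]
    tail = t >= t[-1] - rules.repol_window
    if vm[tail].mean() > baseline + rules.repol_excess:
        return "incomplete-repolarization"
    in_stim = times[(times >= stim_onset) & (times <= stim_end)]
    if in_stim.size == 0:
        return "silent"
    tail_start = stim_end - rules.tonic_tail_fraction * stim_duration
    if in_stim[-1] >= tail_start and in_stim.size >= rules.tonic_min_spikes:
        return "tonic"
    return "phasic"


def classify_genotype(classes: Sequence[str]) -> str:
    """Phenotype of an ordered (low-to-high amplitude) stimulus sweep.

    Any artifact class maps the sweep to ``other``; otherwise the phenotype
    is phasic/tonic if all spiking traces agree, phasic-to-tonic for an
    upward transition, tonic-to-phasic for the reverse, and ``other`` for
    all-silent or non-monotone patterns.
    """
    for c in classes:
        if c not in TRACE_CLASSES:
            raise ValueError(f"unknown trace class {c!r}")
    if any(c in ARTIFACT_CLASSES for c in classes):
        return "other"
    spiking = [c for c in classes if c in ("phasic", "tonic")]
    if not spiking:
        return "other"
    if all(c == "phasic" for c in spiking):
        return "phasic"
    if all(c == "tonic" for c in spiking):
        return "tonic"
    first_tonic = spiking.index("tonic")
    if all(c == "tonic" for c in spiking[first_tonic:]):
        return "phasic-to-tonic"
    first_phasic = spiking.index("phasic")
    if spiking[0] == "tonic" and all(c == "phasic" for c in spiking[first_phasic:]):
        return "tonic-to-phasic"
    return "other"


def fi_slope(amplitudes, frequencies):
    """Ordinary-least-squares slope (Hz/nA) of an f-I relationship.

    Returns NaN when fewer than two points are available.
    """
    a = np.asarray(amplitudes, dtype=float)
    f = np.asarray(frequencies, dtype=float)
    if a.size != f.size:
        raise ValueError("amplitudes and frequencies must have equal length")
    if a.size < 2 or np.allclose(a, a[0]):
        return float("nan")
    return float(stats.linregress(a, f).slope)
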