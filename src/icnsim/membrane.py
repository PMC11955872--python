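"""Single-compartment parallel-conductance membrane models under current clamp.

A :class:`NeuronModel` combines a cylindrical soma, a passive leak and the
channel set of one neuronal genotype (with the published conductance
densities) into the current-balance equation

    Cm dv/dt = -(i_leak + sum_k i_k) + I_stim / A

integrated at a fixed 25 us step.  The module also measures the passive
properties used to screen models: resting membrane potential, input
impedance and rheobase, and can solve for the leak reversal that balances
the membrane at a target RMP.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _engine
from . import channels as ch
from .spikes import detect_spikes

__all__ = [
    "Morphology",
    "PassiveLeak",
    "ConductanceSet",
    "SimulationConfig",
    "StimulusProtocol",
    "VoltageTrace",
    "NeuronModel",
    "SpontaneousActivityError",
    "SimulationBlowupError",
    "ModelRejectedError",
    "build_model",
    "simulate",
    "measure_rmp",
    "measure_rin",
    "find_rheobase",
    "tune_epas",
    "tune_leak",
    "channel_slope_conductance",
    "steady_state_current",
    "K_CHANNELS",
]

# Potassium channel genes that satisfy the excitability guard.
K_CHANNELS = ("Kcna1+ab1", "Kcna1", "Kcnc1", "Kcnj3")


class SpontaneousActivityError(RuntimeError):
    """The model fires (or oscillates) without a stimulus."""


class SimulationBlowupError(RuntimeError):
    """|vm| exceeded the blow-up bound during integration."""


class ModelRejectedError(RuntimeError):
    """A screening constraint (e.g. the E_pas band) cannot be satisfied."""


@dataclass(frozen=True)
class Morphology:
    """Cylindrical soma; area is the lateral surface (end caps excluded)."""

    length_um: float = 21.0
    diameter_um: float = 21.0
    cm_uf_per_cm2: float = 1.0
    ra_ohm_cm: float = 35.4
    nseg: int = 1

    @property
    def area_um2(self) -> float:
        return math.pi * self.diameter_um * self.length_um

    @property
    def area_cm2(self) -> float:
        return self.area_um2 * 1e-8


@dataclass(frozen=True)
class PassiveLeak:
    g_pas: float  # S/cm2
    e_pas: float  # mV, physiological band [-80, -50]

    def __post_init__(self):
        if self.g_pas <= 0:
            raise ValueError("g_pas must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    dt_us: float = 25.0
    total_ms: float = 1000.0
    v_init: float = -61.0
    spike_threshold: float = -10.0
    temperature_c: float = 35.0
    e_na: float = 50.0
    e_k: float = -77.0
    e_h: float = -45.0

    def __post_init__(self):
        if self.dt_us <= 0:
            raise ValueError("dt must be positive")

    @property
    def dt_ms(self) -> float:
        return self.dt_us * 1e-3

    @property
    def reversals(self) -> dict:
        return {"ENa": self.e_na, "EK": self.e_k, "EHcn": self.e_h}


@dataclass(frozen=True)
class StimulusProtocol:
    """Square current-clamp pulse: onset delay, duration (ms), amplitude (nA)."""

    delay_ms: float = 100.0
    duration_ms: float = 800.0
    amplitude_na: float = 0.1

    def __post_init__(self):
        if self.delay_ms < 0 or self.duration_ms <= 0:
            raise ValueError("protocol timing must be non-negative / positive")

    @property
    def offset_ms(self) -> float:
        return self.delay_ms + self.duration_ms


# Published conductance densities (S/cm2) of the reference parameter set;
# phi is the Kv3.1 fast/slow fractional amplitude.
_DEFAULT_GBARS = {
    "Scn1a": 0.075,
    "Hcn1": 0.003,
    "Hcn2": 0.009,
    "Hcn3": 0.01,
    "Hcn4": 0.0035,
    "Kcna1+ab1": 0.018,
    "Kcnc1": 0.018,
    "Kcnj3": 3.5e-3,
    "Cacna1a": 5e-5,
    "Cacna1b": 1e-4,
    "Cacna1c": 0.006,
    "Cacna1d": 4.5e-4,
    "Cacna1g": 3e-4,
    "Cacna1i": 6e-4,
}


@dataclass(frozen=True)
class ConductanceSet:
    """Maximal conductance density per channel gene + the Kv3.1 mix fraction.

    The beta1-less delayed rectifier ('Kcna1') reuses the 'Kcna1+ab1'
    density unless set explicitly.
    """

    gbars: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_GBARS))
    phi_kcnc1: float = 0.2

    def __post_init__(self):
        for gene, g in self.gbars.items():
            if g < 0:
                raise ValueError(f"negative conductance for {gene}")
        if not (0.0 <= self.phi_kcnc1 <= 1.0):
            raise ValueError("phi_kcnc1 must lie in [0, 1]")

    def for_gene(self, gene: str) -> float:
        if gene in self.gbars:
            return float(self.gbars[gene])
        if gene == "Kcna1" and "Kcna1+ab1" in self.gbars:
            return float(self.gbars["Kcna1+ab1"])
        raise KeyError(f"no conductance for gene {gene!r}")

    def scaled(self, gene: str, factor: float) -> "ConductanceSet":
        new = dict(self.gbars)
        new[gene] = self.for_gene(gene) * factor
        return replace(self, gbars=new)


@dataclass(frozen=True)
class VoltageTrace:
    """Current-clamp response: time (ms), vm (mV), injected current (nA)."""

    t: np.ndarray
    vm: np.ndarray
    i_stim: np.ndarray
    protocol: StimulusProtocol
    dt_ms: float
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ms": self.t, "vm_mV": self.vm, "i_stim_nA": self.i_stim})


@dataclass
class NeuronModel:
    """A genotype's channel set on the default soma with a passive leak."""

    channel_genes: tuple
    conductances: ConductanceSet
    morphology: Morphology
    leak: PassiveLeak
    config: SimulationConfig
    env: ch.IonEnvironment = field(default_factory=ch.IonEnvironment)
    label: str = ""
    channel_overrides: dict = field(default_factory=dict)
    _compiled: "_engine.CompiledMembrane | None" = field(default=None, repr=False, compare=False)

    @property
    def excitable(self) -> bool:
        return "Scn1a" in self.channel_genes and any(k in self.channel_genes for k in K_CHANNELS)

    def channel_spec(self, gene: str) -> ch.ChannelSpec:
        return self.channel_overrides.get(gene) or ch.get_channel(gene)

    def compiled(self) -> "_engine.CompiledMembrane":
        if self._compiled is None:
            gbars = {g: self.conductances.for_gene(g) for g in self.channel_genes}
            self._compiled = _engine.compile_membrane(
                self.channel_genes,
                gbars,
                self.conductances.phi_kcnc1,
                self.leak.g_pas,
                self.leak.e_pas,
                self.morphology.cm_uf_per_cm2,
                self.morphology.area_cm2,
                self.config.reversals,
                self.env,
                specs=self.channel_overrides or None,
            )
        return self._compiled

    def _replaced(self, **kw) -> "NeuronModel":
        fields_ = dict(
            channel_genes=self.channel_genes,
            conductances=self.conductances,
            morphology=self.morphology,
            leak=self.leak,
            config=self.config,
            env=self.env,
            label=self.label,
            channel_overrides=self.channel_overrides,
        )
        fields_.update(kw)
        return NeuronModel(**fields_)

    def with_leak(self, leak: PassiveLeak) -> "NeuronModel":
        return self._replaced(leak=leak)

    def with_conductances(self, conductances: ConductanceSet) -> "NeuronModel":
        return self._replaced(conductances=conductances)


def _default_leak(morphology: Morphology, rin_mohm: float = 300.0, e_pas: float = -61.0) -> PassiveLeak:
    # Leak density giving the requested leak-only input impedance.  The
    # default sits at the upper end of the physiological 40-300 MOhm band:
    # the channel set itself contributes ~50 MOhm of resting conductance in
    # the full genotype, so a heavier leak would push the assembled model's
    # input impedance below the band.
    g = 1.0 / (rin_mohm * 1e6 * morphology.area_cm2)
    return PassiveLeak(g_pas=g, e_pas=e_pas)


def build_model(
    genotype,
    conductances: ConductanceSet | None = None,
    morphology: Morphology | None = None,
    leak: PassiveLeak | None = None,
    config: SimulationConfig | None = None,
    env: ch.IonEnvironment | None = None,
    label: str = "",
    channel_overrides: Mapping[str, ch.ChannelSpec] | None = None,
) -> NeuronModel:
    """Assemble a parallel-conductance model for one neuronal genotype.

    ``genotype`` may be an iterable of channel gene names or any object with
    a ``channels`` attribute (e.g. :class:`icnsim.transcriptome.Genotype`).
    Channels absent from the genotype contribute nothing.  A genotype
    without Scn1a or without any K+ channel is assembled but a warning is
    issued, since it cannot be excitable.
    """
    genes = tuple(getattr(genotype, "channels", genotype))
    lbl = label or getattr(genotype, "label", "")
    reg = ch.registry()
    for g in genes:
        if g not in reg and g not in (channel_overrides or {}):
            raise KeyError(f"unknown channel gene {g!r} in genotype")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate channel genes in genotype")
    morphology = morphology or Morphology()
    config = config or SimulationConfig()
    conductances = conductances or ConductanceSet()
    leak = leak or _default_leak(morphology)
    env = env or ch.IonEnvironment(temperature=273.15 + config.temperature_c)
    model = NeuronModel(
        channel_genes=genes,
        conductances=conductances,
        morphology=morphology,
        leak=leak,
        config=config,
        env=env,
        label=lbl,
        channel_overrides=dict(channel_overrides or {}),
    )
    if genes and not model.excitable:
        warnings.warn(f"genotype {lbl or genes} lacks Na+ and/or K+ channels; it cannot spike", stacklevel=2)
    return model


def simulate(
    model: NeuronModel,
    protocol: StimulusProtocol,
    config: SimulationConfig | None = None,
    record_full: bool = True,
) -> VoltageTrace:
    """Integrate the model under one current-clamp pulse.

    Deterministic: identical inputs give bit-identical traces.  Raises
    :class:`SimulationBlowupError` if |vm| exceeds 200 mV.
    """
    cfg = config or model.config
    if protocol.offset_ms > cfg.total_ms:
        raise ValueError("protocol extends beyond the simulation window")
    dt = cfg.dt_ms
    n_steps = int(round(cfg.total_ms / dt))
    # per-step stimulus density (mA/cm2); step i covers (t_i, t_{i+1}]
    t_mid = (np.arange(n_steps) + 0.5) * dt
    on = (t_mid >= protocol.delay_ms) & (t_mid < protocol.offset_ms)
    amp_density = protocol.amplitude_na * 1e-6 / model.morphology.area_cm2
    i_density = np.where(on, amp_density, 0.0)

    cm = model.compiled() if cfg is model.config else _recompile(model, cfg)
    v_out, gates, status = _engine.integrate(cm, cfg.v_init, dt, i_density)
    t = np.arange(n_steps + 1) * dt
    if status != 0:
        raise SimulationBlowupError(
            f"|vm| exceeded {_engine.V_BLOWUP} mV (genotype {model.label or model.channel_genes}, "
            f"amp {protocol.amplitude_na} nA, dt {cfg.dt_us} us)"
        )
    i_stim = np.where((t >= protocol.delay_ms) & (t < protocol.offset_ms), protocol.amplitude_na, 0.0)
    return VoltageTrace(
        t=t,
        vm=v_out,
        i_stim=i_stim,
        protocol=protocol,
        dt_ms=dt,
        meta={"scheme": _engine.SCHEME, "label": model.label, "dt_us": cfg.dt_us},
    )


def _recompile(model: NeuronModel, cfg: SimulationConfig):
    gbars = {g: model.conductances.for_gene(g) for g in model.channel_genes}
    return _engine.compile_membrane(
        model.channel_genes,
        gbars,
        model.conductances.phi_kcnc1,
        model.leak.g_pas,
        model.leak.e_pas,
        model.morphology.cm_uf_per_cm2,
        model.morphology.area_cm2,
        cfg.reversals,
        model.env,
        specs=model.channel_overrides or None,
    )


def measure_rmp(model: NeuronModel, settle_time_ms: float = 1000.0) -> float:
    """Resting potential: mean vm over the final 10% of a stimulus-free run.

    Raises :class:`SpontaneousActivityError` if the model spikes or if the
    tail oscillates by more than 1 mV (no settled rest exists).
    """
    cfg = replace(model.config, total_ms=settle_time_ms)
    trace = simulate(model, StimulusProtocol(delay_ms=0.0, duration_ms=settle_time_ms, amplitude_na=0.0), cfg)
    tail = trace.vm[int(0.9 * trace.vm.size):]
    if np.any(trace.vm >= model.config.spike_threshold):
        raise SpontaneousActivityError(f"model {model.label} fires without stimulus")
    if tail.max() - tail.min() > 1.0:
        raise SpontaneousActivityError(f"model {model.label} does not settle (oscillation > 1 mV)")
    return float(tail.mean())


def measure_rin(model: NeuronModel, test_amplitude_na: float = -0.01) -> float:
    """Input impedance (MOhm) from a small hyperpolarizing test pulse."""
    cfg = replace(model.config, total_ms=1000.0)
    proto = StimulusProtocol(delay_ms=300.0, duration_ms=600.0, amplitude_na=test_amplitude_na)
    trace = simulate(model, proto, cfg)
    train = detect_spikes(trace.t, trace.vm, model.config.spike_threshold)
    # a rebound (anode-break) spike after pulse release does not invalidate
    # the steady-state deflection; only spikes up to the offset do
    if np.any(train.times <= proto.offset_ms):
        raise SpontaneousActivityError("model spikes during the Rin test pulse")
    pre = (trace.t >= proto.delay_ms - 100.0) & (trace.t < proto.delay_ms)
    during = (trace.t >= proto.offset_ms - 60.0) & (trace.t < proto.offset_ms)
    dv = trace.vm[during].mean() - trace.vm[pre].mean()
    return float(dv / test_amplitude_na)  # mV/nA == MOhm


def _spikes_during(model, amp, protocol, cfg) -> int:
    proto = replace(protocol, amplitude_na=amp)
    trace = simulate(model, proto, cfg)
    train = detect_spikes(trace.t, trace.vm, model.config.spike_threshold)
    times = train.times
    return int(np.sum((times >= proto.delay_ms) & (times <= proto.offset_ms)))


def find_rheobase(
    model: NeuronModel,
    search_range: tuple = (0.0, 0.5),
    resolution_na: float = 0.001,
    protocol: StimulusProtocol | None = None,
) -> float | None:
    """Minimum pulse amplitude (nA) eliciting >= 1 spike, by bisection.

    Returns ``None`` if the upper search bound never spikes.  Raises
    :class:`SpontaneousActivityError` if the model spikes at 0 nA.
    """
    lo, hi = search_range
    if not (hi > lo >= 0.0) or resolution_na <= 0:
        raise ValueError("search range must be ordered and resolution positive")
    protocol = protocol or StimulusProtocol(amplitude_na=hi)
    cfg = model.config
    if _spikes_during(model, 0.0, protocol, cfg) > 0:
        raise SpontaneousActivityError("model spikes at 0 nA; rheobase undefined")
    if _spikes_during(model, hi, protocol, cfg) == 0:
        return None
    if lo > 0 and _spikes_during(model, lo, protocol, cfg) > 0:
        return lo
    while hi - lo > resolution_na:
        mid = 0.5 * (lo + hi)
        if _spikes_during(model, mid, protocol, cfg) > 0:
            hi = mid
        else:
            lo = mid
    return float(hi)


def steady_state_current(model: NeuronModel, vm: float) -> float:
    """Total membrane current density (mA/cm2) with gates at steady state.

    Positive is outward; includes the leak.
    """
    total = model.leak.g_pas * (vm - model.leak.e_pas)
    rev = model.config.reversals
    for gene in model.channel_genes:
        spec = model.channel_spec(gene)
        gates = {g.name: float(np.asarray(ch.steady_state(spec, g, vm))) for g in spec.gates}
        phi = model.conductances.phi_kcnc1 if spec.phi_mix is not None else None
        total += ch.channel_current(
            spec, gates, vm, model.conductances.for_gene(gene), rev, model.env, phi=phi
        )
    return float(total)


def tune_epas(
    model: NeuronModel,
    target_rmp: float = -61.0,
    band: tuple = (-80.0, -50.0),
) -> PassiveLeak:
    """Solve the leak reversal that balances the membrane at ``target_rmp``.

    At steady state ``sum_k i_k(v) + g_pas (v - E_pas) = 0``, so
    ``E_pas = v + sum_k i_k(v) / g_pas``.  Raises
    :class:`ModelRejectedError` when the solution leaves the physiological
    band (this mirrors the rejection step of the conductance screen).
    """
    i_ch = steady_state_current(model, target_rmp) - model.leak.g_pas * (target_rmp - model.leak.e_pas)
    e_pas = target_rmp + i_ch / model.leak.g_pas
    if not (band[0] <= e_pas <= band[1]):
        raise ModelRejectedError(
            f"required E_pas {e_pas:.2f} mV outside the physiological band {band} "
            f"(genotype {model.label or model.channel_genes})"
        )
    return PassiveLeak(g_pas=model.leak.g_pas, e_pas=float(e_pas))


def channel_slope_conductance(model: NeuronModel, vm: float, dv: float = 0.5) -> float:
    """Steady-state slope conductance (S/cm2) of the channel set at ``vm``."""
    g_pas = model.leak.g_pas
    i_hi = steady_state_current(model, vm + dv) - g_pas * (vm + dv - model.leak.e_pas)
    i_lo = steady_state_current(model, vm - dv) - g_pas * (vm - dv - model.leak.e_pas)
    return (i_hi - i_lo) / (2 * dv)


def tune_leak(
    model: NeuronModel,
    target_rmp: float = -61.0,
    target_rin_mohm: float = 100.0,
    band: tuple = (-80.0, -50.0),
    band_margin: float = 2.0,
) -> PassiveLeak:
    """Choose a genotype-specific leak that satisfies the passive constraints.

    The leak density is the largest of (a) what the target input impedance
    requires after subtracting the channels' own resting slope conductance,
    (b) what keeping E_pas inside the physiological band requires to balance
    the net channel current at the target RMP, and (c) a floor equal to a
    300 MOhm leak-only impedance.  E_pas is then solved exactly as in
    :func:`tune_epas`.  Raises :class:`ModelRejectedError` if no in-band
    solution exists.
    """
    area = model.morphology.area_cm2
    g_floor = 1.0 / (300.0e6 * area)
    g_ch = channel_slope_conductance(model, target_rmp)
    g_rin = 1.0 / (target_rin_mohm * 1e6 * area) - max(g_ch, 0.0)
    i_ch = steady_state_current(model, target_rmp) - model.leak.g_pas * (target_rmp - model.leak.e_pas)
    lo, hi = band[0] + band_margin, band[1] - band_margin
    if i_ch > 0:  # net outward: E_pas must sit above the target RMP
        g_band = i_ch / (hi - target_rmp) if hi > target_rmp else float("inf")
    elif i_ch < 0:
        g_band = -i_ch / (target_rmp - lo) if target_rmp > lo else float("inf")
    else:
        g_band = 0.0
    g_pas = max(g_floor, g_rin, g_band)
    if not np.isfinite(g_pas):
        raise ModelRejectedError(f"no in-band leak solution for genotype {model.label or model.channel_genes}")
    e_pas = target_rmp + i_ch / g_pas
    if not (band[0] <= e_pas <= band[1]):
        raise ModelRejectedError(
            f"required E_pas {e_pas:.2f} mV outside the physiological band {band} "
            f"(genotype {model.label or model.channel_genes})"
        )
    return PassiveLeak(g_pas=float(g_pas), e_pas=float(e_pas))
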