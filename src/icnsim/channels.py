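"""Hodgkin-Huxley kinetics for the 14 ion channels expressed by RAGP neurons.

Each channel model is stored as *data*: a :class:`ChannelSpec` holding one
:class:`GateSpec` per gating variable, where every steady-state, time-constant
and rate expression is a named functional form plus a parameter dict.  The
registry (:func:`registry`, :func:`get_channel`) covers the sodium channel
Nav1.1 (*Scn1a*), the four HCN isoforms, the potassium channels Kv1.1
(*Kcna1*, with or without the fast-inactivating *Kcnab1* beta1 subunit),
Kv3.1 (*Kcnc1*) and Kir3.1/GIRK-1 (*Kcnj3*), and six voltage-gated calcium
channels (*Cacna1a/b/c/d/g/i*).  Ohmic channels carry a reversal-potential
key (ENa, EK, EHcn); calcium channels use the Goldman-Hodgkin-Katz (GHK)
constant-field flux with fixed intra-/extracellular Ca2+.

Voltages are in mV, time constants in ms, rates in 1/ms, conductance
densities in S/cm2 and currents in mA/cm2.  For GHK channels the nominal
``gbar`` is a lumped permeability scale chosen so that ``gbar * gates * Phi``
has current-density units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GENES",
    "TRANSCRIPTS",
    "KCNJ3_SCALE",
    "GateSpec",
    "ChannelSpec",
    "IonEnvironment",
    "efun",
    "ghk_flux",
    "rate_with_limit",
    "eval_rate",
    "steady_state",
    "time_constant",
    "channel_current",
    "iv_curves",
    "registry",
    "get_channel",
]

# Transcripts assayed by the HT-qPCR panel (15) and the channel genes they
# collapse to (14) once Kcna1/Kcnab1 are merged into a single conductance.
TRANSCRIPTS: tuple[str, ...] = (
    "Scn1a",
    "Hcn1",
    "Hcn2",
    "Hcn3",
    "Hcn4",
    "Kcna1",
    "Kcnab1",
    "Kcnc1",
    "Kcnj3",
    "Cacna1a",
    "Cacna1b",
    "Cacna1c",
    "Cacna1d",
    "Cacna1g",
    "Cacna1i",
)

GENES: tuple[str, ...] = (
    "Scn1a",
    "Hcn1",
    "Hcn2",
    "Hcn3",
    "Hcn4",
    "Kcna1+ab1",
    "Kcnc1",
    "Kcnj3",
    "Cacna1a",
    "Cacna1b",
    "Cacna1c",
    "Cacna1d",
    "Cacna1g",
    "Cacna1i",
)

# Fixed multiplier on the Kcnj3 conductance (source-model normalisation
# constant, kept verbatim; its reciprocal also scales tau_n).
KCNJ3_SCALE = 2.716898432

# Voltage tolerance (mV) inside which removable 0/0 singularities of the
# linoid rate family are replaced by their analytic limit.
SINGULARITY_TOL = 1e-4


@dataclass(frozen=True)
class IonEnvironment:
    """Fixed ionic conditions for the GHK calcium flux.

    Concentrations are held constant throughout a simulation (50 nM
    intracellular, 2 mM extracellular Ca2+ by default; 35 C).
    """

    ca_in: float = 5e-5  # mM
    ca_out: float = 2.0  # mM
    z_ca: int = 2
    temperature: float = 308.15  # K
    faraday: float = 96485.33212  # C/mol
    gas_constant: float = 8.314462618  # J/(mol K)

    def __post_init__(self) -> None:
        if self.ca_in <= 0 or self.ca_out <= 0:
            raise ValueError("ionic concentrations must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")


@dataclass(frozen=True)
class GateSpec:
    """One gating variable: its exponent and the printed rate laws.

    ``rate_form`` is one of ``alpha-beta`` (x_inf = a/(a+b),
    tau = tau_scale/(a+b)), ``inf-tau`` (explicit x_inf and tau expressions)
    or ``piecewise-inf-tau`` (tau switches functional form at a break
    voltage).  ``inf`` / ``tau`` / ``alpha`` / ``beta`` are (form, params)
    pairs understood by :func:`eval_rate`, :func:`_eval_inf` and
    :func:`_eval_tau`.
    """

    name: str
    exponent: int
    rate_form: str
    alpha: tuple | None = None
    beta: tuple | None = None
    inf: tuple | None = None
    tau: tuple | None = None
    tau_scale: float = 1.0
    tau_rates: tuple = ()  # inf-tau gates whose tau = 1 / sum(rates)

    def __post_init__(self) -> None:
        if self.exponent < 1:
            raise ValueError("gate exponent must be >= 1")
        if self.rate_form not in ("alpha-beta", "inf-tau", "piecewise-inf-tau"):
            raise ValueError(f"unknown rate_form {self.rate_form!r}")


@dataclass(frozen=True)
class ChannelSpec:
    """A channel's gating structure and current law.

    ``components`` lists additive conductance terms as
    ``(multiplier, ((gate_name, exponent), ...))``; the open-channel
    conductance is ``gbar * sum(mult * prod(gate**exp))``.  Most channels
    have a single component; Kv3.1 mixes a fast n^2 and a slow p process
    with fractional amplitude phi, and Kir3.1 carries the fixed multiplier
    2.716898432.  ``current_law`` is ``ohmic`` (needs ``reversal``, one of
    ENa/EK/EHcn) or ``ghk`` (no reversal; Ca2+ constant-field flux).
    """

    gene: str
    protein: str
    gates: tuple[GateSpec, ...]
    current_law: str
    reversal: str | None = None
    components: tuple | None = None
    phi_mix: float | None = None  # Kcnc1 fractional amplitude placeholder

    def __post_init__(self) -> None:
        if self.current_law == "ohmic":
            if self.reversal not in ("ENa", "EK", "EHcn"):
                raise ValueError(f"{self.gene}: ohmic channel needs one reversal key")
        elif self.current_law == "ghk":
            if self.reversal is not None:
                raise ValueError(f"{self.gene}: ghk channel must not set a reversal")
        else:
            raise ValueError(f"unknown current_law {self.current_law!r}")
        if self.phi_mix is not None and not (0.0 <= self.phi_mix <= 1.0):
            raise ValueError("phi mix fraction must lie in [0, 1]")

    def gate(self, name: str) -> GateSpec:
        for g in self.gates:
            if g.name == name:
                return g
        raise KeyError(f"channel {self.gene} has no gate {name!r}")

    def conductance_components(self, phi: float | None = None):
        """Resolved additive components ``(multiplier, ((gate, exp), ...))``."""
        if self.components is not None:
            return self.components
        if self.phi_mix is not None or phi is not None:
            f = self.phi_mix if phi is None else phi
            if not (0.0 <= f <= 1.0):
                raise ValueError("phi mix fraction must lie in [0, 1]")
            return ((f, (("n", 2),)), (1.0 - f, (("p", 1),)))
        return ((1.0, tuple((g.name, g.exponent) for g in self.gates)),)

    def to_dict(self) -> dict:
        """Serialise the kinetics to plain data (one block per gene)."""

        def law(pair):
            return None if pair is None else {"form": pair[0], **pair[1]}

        return {
            "gene": self.gene,
            "protein": self.protein,
            "current_law": self.current_law,
            "reversal": self.reversal,
            "phi_mix": self.phi_mix,
            "components": self.components,
            "gates": [
                {
                    "name": g.name,
                    "exponent": g.exponent,
                    "rate_form": g.rate_form,
                    "alpha": law(g.alpha),
                    "beta": law(g.beta),
                    "inf": law(g.inf),
                    "tau": law(g.tau),
                    "tau_scale": g.tau_scale,
                    "tau_rates": [law(r) for r in g.tau_rates],
                }
                for g in self.gates
            ],
        }


# ---------------------------------------------------------------------------
# Elementary evaluators
# ---------------------------------------------------------------------------

def efun(x):
    """x / (exp(x) - 1) with the removable singularity at 0 filled.

    Returns ``1 - x/2`` for ``|x| < 1e-4`` (first-order expansion), the exact
    expression otherwise; continuous across the branch point and guarded
    against overflow for large negative ``x``.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)  # dummy away from 0; branch discarded below
    with np.errstate(over="ignore"):
        exact = xs / np.expm1(np.clip(xs, -700, 700))
    out = np.where(small, 1.0 - x / 2.0, exact)
    return out if out.ndim else float(out)


def ghk_flux(vm, env: IonEnvironment = IonEnvironment()):
    """Goldman-Hodgkin-Katz constant-field flux for Ca2+ at potential ``vm``.

    Implements ``1e-3 * z * F * ([Ca]_i * f(-u) - [Ca]_o * f(u))`` with
    ``u = 1e-3 * z * F * vm / (R * T)`` and ``f`` = :func:`efun`.  Negative
    values are inward current; the zero crossing sits at the Ca2+ Nernst
    potential.  Multiplied by a permeability scale and the open-gate product
    this yields a current density in mA/cm2.
    """
    vm = np.asarray(vm, dtype=float)
    zF = env.z_ca * env.faraday
    u = 1e-3 * vm * zF / (env.gas_constant * env.temperature)
    out = 1e-3 * zF * (env.ca_in * efun(-u) - env.ca_out * efun(u))
    return out if np.ndim(out) else float(out)


def rate_with_limit(a: float, vhalf: float, k: float, vm, tol: float = SINGULARITY_TOL):
    """Linoid rate ``a*(vm-vhalf) / (1 - exp(-(vm-vhalf)/k))`` (1/ms).

    The printed expression is 0/0 at ``vm = vhalf``; within ``tol`` mV of it
    the analytic (L'Hopital) limit ``a*k`` is returned instead.  ``a`` and
    ``k`` may be negative, which covers every x/(1-exp) variant in the
    channel table.
    """
    vm = np.asarray(vm, dtype=float)
    x = vm - vhalf
    sing = np.abs(x) < tol
    xs = np.where(sing, 1.0, x)  # dummy away from 0 to avoid warnings
    with np.errstate(over="ignore"):
        exact = a * xs / (-np.expm1(np.clip(-xs / k, -700, 700)))
    out = np.where(sing, a * k, exact)
    return out if out.ndim else float(out)


def _eval_form(form: str, p: Mapping[str, float], vm):
    vm = np.asarray(vm, dtype=float)
    if form == "linoid":
        return rate_with_limit(p["a"], p["vhalf"], p["k"], vm)
    if form == "exp":
        return p["a"] * np.exp((vm - p["vhalf"]) / p["k"])
    if form == "sigmoid_rate":
        return p["a"] / (1.0 + np.exp((vm - p["vhalf"]) / p["k"]))
    raise ValueError(f"unknown rate form {form!r}")


def eval_rate(law: tuple, vm):
    """Evaluate an (alpha/beta) rate law ``(form, params)`` at ``vm`` (1/ms)."""
    form, params = law
    return _eval_form(form, params, vm)


def _eval_inf(law: tuple, vm):
    form, p = law
    vm = np.asarray(vm, dtype=float)
    if form == "sigmoid":
        # 1 / (1 + exp((vm - vhalf)/k)); signed k encodes the direction.
        return 1.0 / (1.0 + np.exp((vm - p["vhalf"]) / p["k"]))
    if form == "powered_sigmoid":
        # c1 / (1 + exp((vm - vhalf)/k))**power + c0   (Kcna1 x gate)
        base = (1.0 + np.exp((vm - p["vhalf"]) / p["k"])) ** p["power"]
        return p["c1"] / base + p["c0"]
    raise ValueError(f"unknown steady-state form {form!r}")


def _eval_tau(law: tuple, vm):
    form, p = law
    vm = np.asarray(vm, dtype=float)
    if form == "const":
        return np.full_like(vm, p["value"]) if vm.ndim else p["value"]
    if form == "bi_exp":
        # amp / (c1*exp((vm-vhalf)/k1) + c2*exp(-(vm-vhalf)/k2)) + base
        x = vm - p["vhalf"]
        return p["amp"] / (p["c1"] * np.exp(x / p["k1"]) + p["c2"] * np.exp(-x / p["k2"])) + p["base"]
    if form == "offset_exp":
        # a + b*exp((vm - vhalf)/k)
        return p["a"] + p["b"] * np.exp((vm - p["vhalf"]) / p["k"])
    if form == "sum_exp_inv":
        # (base + amp/(exp((vm-v1)/k1) + exp((vm-v2)/k2))) / div
        s = np.exp((vm - p["v1"]) / p["k1"]) + np.exp((vm - p["v2"]) / p["k2"])
        return (p["base"] + p["amp"] / s) / p["div"]
    if form == "piecewise":
        # ordered (upper_break, sub-law) branches; last branch has break=None
        out = np.empty_like(vm, dtype=float) if vm.ndim else None
        remaining = np.ones_like(vm, dtype=bool) if vm.ndim else None
        if vm.ndim:
            for brk, sub in p["branches"]:
                mask = remaining & ((vm < brk) if brk is not None else True)
                if np.any(mask):
                    out[mask] = np.asarray(_eval_tau(sub, vm[mask]))
                remaining &= ~mask
            return out
        for brk, sub in p["branches"]:
            if brk is None or vm < brk:
                return _eval_tau(sub, vm)
        raise AssertionError("piecewise tau has no terminal branch")
    raise ValueError(f"unknown tau form {form!r}")


# ---------------------------------------------------------------------------
# Gate-level API
# ---------------------------------------------------------------------------

def steady_state(channel: ChannelSpec, gate: GateSpec | str, vm):
    """Steady-state activation x_inf(vm) of one gate, in [0, 1]."""
    g = channel.gate(gate) if isinstance(gate, str) else gate
    if g.rate_form == "alpha-beta":
        a = eval_rate(g.alpha, vm)
        b = eval_rate(g.beta, vm)
        return a / (a + b)
    return _eval_inf(g.inf, vm)


def time_constant(channel: ChannelSpec, gate: GateSpec | str, vm):
    """Relaxation time constant tau_x(vm) of one gate, in ms (always > 0)."""
    g = channel.gate(gate) if isinstance(gate, str) else gate
    if g.rate_form == "alpha-beta":
        tau = g.tau_scale / (eval_rate(g.alpha, vm) + eval_rate(g.beta, vm))
    elif g.tau_rates:
        total = sum(eval_rate(r, vm) for r in g.tau_rates)
        tau = g.tau_scale / total
    else:
        tau = _eval_tau(g.tau, vm)
    bad = np.asarray(tau) <= 0
    if np.any(bad):
        vbad = np.asarray(vm, dtype=float)[bad] if np.ndim(vm) else vm
        raise ValueError(
            f"non-positive time constant for {channel.gene}/{g.name} at vm={vbad}"
        )
    return tau


def channel_current(
    channel: ChannelSpec,
    gate_values: Mapping[str, float],
    vm,
    gbar: float,
    reversal_potentials: Mapping[str, float] | None = None,
    env: IonEnvironment = IonEnvironment(),
    phi: float | None = None,
):
    """Instantaneous current density (mA/cm2) for given gate states.

    Ohmic: ``gbar * sum_components * (vm - E)``; GHK: ``gbar *
    sum_components * Phi_Ca(vm)``.  A Kv1.1 spec without the beta1 subunit
    simply has no ``x`` gate, which is equivalent to clamping x at 1.
    """
    for name, val in gate_values.items():
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"gate value {name}={val} outside [0, 1]")
    open_frac = 0.0
    for mult, terms in channel.conductance_components(phi=phi):
        prod = mult
        for gname, expo in terms:
            prod *= gate_values[gname] ** expo
        open_frac += prod
    if channel.current_law == "ohmic":
        if reversal_potentials is None or channel.reversal not in reversal_potentials:
            raise KeyError(f"missing reversal potential {channel.reversal} for {channel.gene}")
        return gbar * open_frac * (np.asarray(vm, dtype=float) - reversal_potentials[channel.reversal])
    return gbar * open_frac * ghk_flux(vm, env)


def iv_curves(channel: ChannelSpec, vm_grid) -> "pd.DataFrame":
    """Steady-state activation/inactivation table over ``vm_grid``.

    Columns follow the convention of voltage-clamp curve comparisons:
    ``act_<gate>`` for activation gates (x_inf increasing with vm) and
    ``inact_<gate>`` for inactivation gates; single-gate channels (e.g. the
    HCN family) yield one activation column only.
    """
    import pandas as pd

    vm = np.asarray(vm_grid, dtype=float)
    if vm.ndim != 1 or np.any(np.diff(vm) <= 0):
        raise ValueError("vm_grid must be strictly increasing 1-D")
    data = {"vm_mV": vm}
    for g in channel.gates:
        x = np.asarray(steady_state(channel, g, vm))
        # a single-gate channel's only curve is its activation curve (the HCN
        # family activates on hyperpolarization, so the slope alone is not
        # decisive); in multi-gate channels the falling curves inactivate
        kind = "act" if (len(channel.gates) == 1 or x[-1] >= x[0]) else "inact"
        data[f"{kind}_{g.name}"] = x
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# The registry (kinetics transcribed from the source channel models)
# ---------------------------------------------------------------------------

def _sigmoid(vhalf, k):
    return ("sigmoid", {"vhalf": vhalf, "k": k})


def _linoid(a, vhalf, k):
    return ("linoid", {"a": a, "vhalf": vhalf, "k": k})


def _exp(a, vhalf, k):
    return ("exp", {"a": a, "vhalf": vhalf, "k": k})


def _sigrate(a, vhalf, k):
    return ("sigmoid_rate", {"a": a, "vhalf": vhalf, "k": k})


def _const(value):
    return ("const", {"value": value})


def _build_registry() -> dict[str, ChannelSpec]:
    reg: dict[str, ChannelSpec] = {}

    # --- Nav1.1 (Scn1a): i = gbar * m^3 * h * (vm - ENa)
    reg["Scn1a"] = ChannelSpec(
        gene="Scn1a",
        protein="Nav1.1",
        current_law="ohmic",
        reversal="ENa",
        gates=(
            GateSpec(
                name="m",
                exponent=3,
                rate_form="alpha-beta",
                alpha=_linoid(0.182, -35.0, 9.0),
                # beta_m = 0.124*(-(vm+35)) / (1 - exp((vm+35)/9))
                beta=_linoid(-0.124, -35.0, -9.0),
            ),
            GateSpec(
                name="h",
                exponent=1,
                rate_form="inf-tau",
                inf=_sigmoid(-65.0, 6.2),
                # tau_h = 1 / (r1 + r2), two linoid rates (singularities at
                # -50 and -75.000123 mV)
                tau_rates=(
                    _linoid(0.024, -50.0, 5.0),
                    _linoid(-0.0091, -75.000123, -5.0),
                ),
            ),
        ),
    )

    # --- HCN1-4: i = gbar * m * (vm - EHcn); fixed tau, sigmoid activation
    for iso, vhalf, k, tau in (
        (1, -94.0, 8.1, 30.0),
        (2, -99.0, 6.2, 184.0),
        (3, -96.0, 8.6, 265.0),
        (4, -100.0, 9.6, 461.0),
    ):
        reg[f"Hcn{iso}"] = ChannelSpec(
            gene=f"Hcn{iso}",
            protein=f"HCN{iso}",
            current_law="ohmic",
            reversal="EHcn",
            gates=(
                GateSpec(
                    name="m",
                    exponent=1,
                    rate_form="inf-tau",
                    inf=_sigmoid(vhalf, k),
                    tau=_const(tau),
                ),
            ),
        )

    # --- Kv1.1 (Kcna1 + Kcnab1): i = gbar * n^4 * x * (vm - EK)
    kcna1_n = GateSpec(
        name="n",
        exponent=4,
        rate_form="alpha-beta",
        alpha=_exp(0.12889, -45.0, 33.90877),
        beta=_exp(0.12889, -45.0, -12.42101),
        tau_scale=1.0 / 4.171167511,  # tau_n = 1/(4.171167511*(an+bn))
    )
    kcna1_x = GateSpec(
        name="x",
        exponent=1,
        rate_form="inf-tau",
        inf=("powered_sigmoid", {"c1": 0.95, "vhalf": -59.0, "k": 3.0, "power": 0.5, "c0": 0.05}),
        tau=(
            "bi_exp",
            {"amp": 500.0, "vhalf": -28.0, "c1": 14.0, "k1": 20.0, "c2": 29.0, "k2": 10.0, "base": 6.0},
        ),
    )
    reg["Kcna1+ab1"] = ChannelSpec(
        gene="Kcna1+ab1",
        protein="Kv1.1 (+beta1)",
        current_law="ohmic",
        reversal="EK",
        gates=(kcna1_n, kcna1_x),
    )
    # Without the beta1 subunit the delayed rectifier does not inactivate:
    # same n gate, no x gate (x == 1).
    reg["Kcna1"] = ChannelSpec(
        gene="Kcna1",
        protein="Kv1.1",
        current_law="ohmic",
        reversal="EK",
        gates=(kcna1_n,),
    )

    # --- Kv3.1 (Kcnc1): g = gbar*(phi*n^2 + (1-phi)*p); i = g*(vm - EK)
    reg["Kcnc1"] = ChannelSpec(
        gene="Kcnc1",
        protein="Kv3.1",
        current_law="ohmic",
        reversal="EK",
        phi_mix=0.2,
        gates=(
            GateSpec(
                name="n",
                exponent=2,
                rate_form="inf-tau",
                inf=_sigmoid(-15.0, -5.0),
                tau=(
                    "bi_exp",
                    {"amp": 100.0, "vhalf": -60.0, "c1": 11.0, "k1": 24.0, "c2": 21.0, "k2": 23.0, "base": 0.7},
                ),
            ),
            GateSpec(
                name="p",
                exponent=1,
                rate_form="inf-tau",
                inf=_sigmoid(-23.0, -6.0),
                tau=(
                    "bi_exp",
                    {"amp": 100.0, "vhalf": -60.0, "c1": 4.0, "k1": 32.0, "c2": 5.0, "k2": 22.0, "base": 5.0},
                ),
            ),
        ),
    )

    # --- Kir3.1 / GIRK-1 (Kcnj3): g = gbar * 2.716898432 * n
    reg["Kcnj3"] = ChannelSpec(
        gene="Kcnj3",
        protein="Kir3.1 (GIRK-1)",
        current_law="ohmic",
        reversal="EK",
        components=((KCNJ3_SCALE, (("n", 1),)),),
        gates=(
            GateSpec(
                name="n",
                exponent=1,
                rate_form="alpha-beta",
                alpha=_linoid(0.001, -30.0, 9.0),
                # beta_n = -0.001*(vm+30) / (1 - exp((vm+30)/9))
                beta=_linoid(-0.001, -30.0, -9.0),
                tau_scale=1.0 / KCNJ3_SCALE,  # tau_n = (1/2.716898432)/(an+bn)
            ),
        ),
    )

    # --- Cav2.1 (Cacna1a, P/Q): i = gbar * m * Phi_Ca
    reg["Cacna1a"] = ChannelSpec(
        gene="Cacna1a",
        protein="Cav2.1 (P/Q)",
        current_law="ghk",
        gates=(
            GateSpec(
                name="m",
                exponent=1,
                rate_form="alpha-beta",
                alpha=_sigrate(8.5, 8.0, -12.5),
                beta=_sigrate(35.0, -74.0, 14.5),
            ),
        ),
    )

    # --- Cav2.2 (Cacna1b, N): i = gbar * m^2 * h * Phi_Ca
    reg["Cacna1b"] = ChannelSpec(
        gene="Cacna1b",
        protein="Cav2.2 (N)",
        current_law="ghk",
        gates=(
            GateSpec(
                name="m",
                exponent=2,
                rate_form="alpha-beta",
                alpha=_linoid(0.1, 20.0, 10.0),
                beta=_exp(0.4, -25.0, -18.0),
            ),
            GateSpec(
                name="h",
                exponent=1,
                rate_form="alpha-beta",
                alpha=_exp(0.01, -50.0, -10.0),
                beta=_sigrate(0.1, -17.0, -17.0),
            ),
        ),
    )

    # --- Cav1.2 (Cacna1c, L): i = gbar * m^2 * h * Phi_Ca
    reg["Cacna1c"] = ChannelSpec(
        gene="Cacna1c",
        protein="Cav1.2 (L)",
        current_law="ghk",
        gates=(
            GateSpec(name="m", exponent=2, rate_form="inf-tau", inf=_sigmoid(-30.0, -6.0), tau=_const(10.0)),
            GateSpec(name="h", exponent=1, rate_form="inf-tau", inf=_sigmoid(-80.0, 6.4), tau=_const(59.0)),
        ),
    )

    # --- Cav1.3 (Cacna1d, L): explicit m_inf/h_inf; tau_m from rates / 3
    reg["Cacna1d"] = ChannelSpec(
        gene="Cacna1d",
        protein="Cav1.3 (L)",
        current_law="ghk",
        gates=(
            GateSpec(
                name="m",
                exponent=2,
                rate_form="inf-tau",
                inf=_sigmoid(-33.0, -6.7),
                # alpha_m = 0.0398*(vm+8.124)/(exp((vm+8.124)/9.005)-1)
                # == linoid with a=-0.0398, k=-9.005 (limit 0.0398*9.005)
                tau_rates=(
                    _linoid(-0.0398, -8.124, -9.005),
                    _exp(0.99, 0.0, 31.4),
                ),
                tau_scale=1.0 / 3.0,  # tau_m = 1/(3*(am+bm))
            ),
            GateSpec(
                name="h",
                exponent=1,
                rate_form="inf-tau",
                inf=_sigmoid(-13.4, 11.9),
                tau=_const(44.3 / 3.0),
            ),
        ),
    )

    # --- Cav3.1 (Cacna1g, T): i = gbar * m * h * Phi_Ca; piecewise tau_m
    reg["Cacna1g"] = ChannelSpec(
        gene="Cacna1g",
        protein="Cav3.1 (T)",
        current_law="ghk",
        gates=(
            GateSpec(
                name="m",
                exponent=1,
                rate_form="piecewise-inf-tau",
                inf=_sigmoid(-42.921064, -5.163208),
                tau=(
                    "piecewise",
                    {
                        "branches": (
                            (-10.0, ("offset_exp", {"a": -0.855809, "b": 1.493527, "vhalf": 0.0, "k": -27.414182})),
                            (None, _const(1.0)),
                        )
                    },
                ),
            ),
            GateSpec(
                name="h",
                exponent=1,
                rate_form="inf-tau",
                inf=_sigmoid(-72.907420, 4.575763),
                tau=("offset_exp", {"a": 9.987873, "b": 0.002883, "vhalf": 0.0, "k": -5.598574}),
            ),
        ),
    )

    # --- Cav3.3 (Cacna1i, T): i = gbar * m^2 * h * Phi_Ca; divisors are
    # Q10-style factors applied to the whole bracketed expressions.
    reg["Cacna1i"] = ChannelSpec(
        gene="Cacna1i",
        protein="Cav3.3 (T)",
        current_law="ghk",
        gates=(
            GateSpec(
                name="m",
                exponent=2,
                rate_form="inf-tau",
                inf=_sigmoid(-59.0, -6.2),
                tau=(
                    "sum_exp_inv",
                    {"base": 0.612, "amp": 1.0, "v1": -134.0, "k1": -16.7, "v2": -18.8, "k2": 18.2, "div": 6.898648307},
                ),
            ),
            GateSpec(
                name="h",
                exponent=1,
                rate_form="piecewise-inf-tau",
                inf=_sigmoid(-83.0, 4.0),
                tau=(
                    "piecewise",
                    {
                        "branches": (
                            (-82.0, ("offset_exp", {"a": 0.0, "b": 1.0 / 3.737192819, "vhalf": -469.0, "k": 66.6})),
                            (None, ("offset_exp", {"a": 28.0 / 3.737192819, "b": 1.0 / 3.737192819, "vhalf": -24.0, "k": -10.5})),
                        )
                    },
                ),
            ),
        ),
    )

    return reg


_REGISTRY = _build_registry()


def registry() -> dict[str, ChannelSpec]:
    """All channel specs keyed by gene (includes the beta1-less 'Kcna1')."""
    return dict(_REGISTRY)


def get_channel(gene: str) -> ChannelSpec:
    try:
        return _REGISTRY[gene]
    except KeyError:
        raise KeyError(f"unknown channel gene {gene!r}") from None


def registry_to_dict() -> dict:
    """Whole registry as plain serialisable data (kinetics as config)."""
    return {gene: spec.to_dict() for gene, spec in _REGISTRY.items()}


def scale_inf_slope(spec: ChannelSpec, gate_name: str, factor: float) -> ChannelSpec:
    """Channel spec with one gate's steady-state slope constant scaled.

    Only defined for sigmoid-form steady states (e.g. the Nav1.1 h gate,
    whose slope constant is 6.2 mV); a larger slope factor makes the curve
    shallower.  Used for kinetic-uncertainty perturbation studies.
    """
    if factor <= 0:
        raise ValueError("slope factor must be positive")
    gates = []
    found = False
    for g in spec.gates:
        if g.name == gate_name:
            if g.inf is None or g.inf[0] != "sigmoid":
                raise ValueError(f"gate {gate_name!r} of {spec.gene} has no sigmoid steady state")
            form, params = g.inf
            g = replace(g, inf=(form, {**params, "k": params["k"] * factor}))
            found = True
        gates.append(g)
    if not found:
        raise KeyError(f"channel {spec.gene} has no gate {gate_name!r}")
    return replace(spec, gates=tuple(gates))
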