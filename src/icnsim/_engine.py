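"""Fixed-step integration kernel for single-compartment conductance models.

The membrane equation is integrated with the staggered scheme used by
fixed-step compartmental simulators: gating variables advance by exponential
Euler (exact for the linear gate ODE at frozen vm), then the membrane
potential advances by a trapezoidal (Crank-Nicolson) step in which ohmic
conductances are treated implicitly and the (small) GHK calcium currents
explicitly.  The implicit voltage update keeps the scheme stable at the
25 us default step even during the sodium-driven upstroke, when the
instantaneous membrane time constant drops below the step size, and is
second-order accurate on the passive response.

Gate steady states, time constants and the GHK flux are tabulated on a fine
voltage grid (0.02 mV) and linearly interpolated inside the numba kernel;
tables are built from the analytic expressions in :mod:`icnsim.channels`,
which fill removable singularities with their limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import channels as ch

V_TABLE_MIN = -150.0
V_TABLE_MAX = 100.0
V_TABLE_STEP = 0.02
V_BLOWUP = 200.0  # |vm| beyond this aborts the run

SCHEME = "exponential-Euler gates + Crank-Nicolson vm"


@dataclass
class CompiledMembrane:
    """Flat-array form of a neuron model, ready for the kernel."""

    gate_labels: list  # (gene, gate name) per gate row
    inf_tab: np.ndarray  # (n_gates, nv)
    tau_tab: np.ndarray  # (n_gates, nv)
    ghk_tab: np.ndarray  # (nv,)
    ghk_slope_tab: np.ndarray  # (nv,) dPhi/dv, for the linearized implicit step
    comp_g: np.ndarray  # effective conductance per additive component
    comp_law: np.ndarray  # 0 = ohmic, 1 = ghk
    comp_E: np.ndarray  # reversal (mV), 0 for ghk rows
    term_gate: np.ndarray  # flattened (gate index, exponent) terms
    term_exp: np.ndarray
    comp_off: np.ndarray  # component -> term slice offsets
    g_pas: float
    e_pas: float
    cm_mf: float  # membrane capacitance in mF/cm2
    area_cm2: float

    def steady_gates(self, vm: float) -> np.ndarray:
        x = np.clip((vm - V_TABLE_MIN) / V_TABLE_STEP, 0, self.inf_tab.shape[1] - 1.001)
        i0 = int(x)
        frac = x - i0
        return self.inf_tab[:, i0] * (1 - frac) + self.inf_tab[:, i0 + 1] * frac


def compile_membrane(
    channel_genes,
    gbars,
    phi_kcnc1: float,
    g_pas: float,
    e_pas: float,
    cm_uf: float,
    area_cm2: float,
    reversals: dict,
    env: ch.IonEnvironment,
    specs: dict | None = None,
) -> CompiledMembrane:
    """Tabulate kinetics and flatten the channel set into kernel arrays.

    ``specs`` optionally overrides registry entries (gene -> ChannelSpec),
    e.g. for kinetic-parameter perturbation studies.
    """
    vgrid = np.arange(V_TABLE_MIN, V_TABLE_MAX + V_TABLE_STEP / 2, V_TABLE_STEP)
    gate_labels: list = []
    inf_rows: list = []
    tau_rows: list = []
    comp_g: list = []
    comp_law: list = []
    comp_E: list = []
    term_gate: list = []
    term_exp: list = []
    comp_off = [0]

    for gene in channel_genes:
        spec = specs[gene] if specs and gene in specs else ch.get_channel(gene)
        gbar = gbars[gene]
        if gbar < 0:
            raise ValueError(f"negative conductance for {gene}")
        gate_index = {}
        for g in spec.gates:
            gate_index[g.name] = len(gate_labels)
            gate_labels.append((gene, g.name))
            inf_rows.append(np.asarray(ch.steady_state(spec, g, vgrid)))
            tau_rows.append(np.asarray(ch.time_constant(spec, g, vgrid)))
        phi = phi_kcnc1 if spec.phi_mix is not None else None
        for mult, terms in spec.conductance_components(phi=phi):
            comp_g.append(gbar * mult)
            comp_law.append(0 if spec.current_law == "ohmic" else 1)
            comp_E.append(reversals[spec.reversal] if spec.current_law == "ohmic" else 0.0)
            for gname, expo in terms:
                term_gate.append(gate_index[gname])
                term_exp.append(int(expo))
            comp_off.append(len(term_gate))

    n_gates = len(gate_labels)
    nv = vgrid.size
    ghk_tab = np.asarray(ch.ghk_flux(vgrid, env), dtype=np.float64)
    return CompiledMembrane(
        gate_labels=gate_labels,
        inf_tab=np.asarray(inf_rows, dtype=np.float64).reshape(n_gates, nv),
        tau_tab=np.asarray(tau_rows, dtype=np.float64).reshape(n_gates, nv),
        ghk_tab=ghk_tab,
        ghk_slope_tab=np.gradient(ghk_tab, V_TABLE_STEP),
        comp_g=np.asarray(comp_g, dtype=np.float64),
        comp_law=np.asarray(comp_law, dtype=np.int64),
        comp_E=np.asarray(comp_E, dtype=np.float64),
        term_gate=np.asarray(term_gate, dtype=np.int64),
        term_exp=np.asarray(term_exp, dtype=np.int64),
        comp_off=np.asarray(comp_off, dtype=np.int64),
        g_pas=float(g_pas),
        e_pas=float(e_pas),
        cm_mf=float(cm_uf) * 1e-3,
        area_cm2=float(area_cm2),
    )


@njit(cache=True)
def _kernel(
    v0,
    n_steps,
    dt,
    inf_tab,
    tau_tab,
    ghk_tab,
    ghk_slope_tab,
    comp_g,
    comp_law,
    comp_E,
    term_gate,
    term_exp,
    comp_off,
    g_pas,
    e_pas,
    cm_mf,
    i_stim,  # per-step injected current density, mA/cm2
    gates0,
    v_min,
    inv_dv,
):
    n_gates = inf_tab.shape[0]
    nv = inf_tab.shape[1]
    gates = gates0.copy()
    v = v0
    v_out = np.empty(n_steps + 1)
    v_out[0] = v
    status = 0
    c = cm_mf / dt
    for step in range(n_steps):
        # gates live on the half-shifted grid: advancing them with rates at
        # v(t) places them at t + dt/2, the midpoint of the voltage step
        x = (v - v_min) * inv_dv
        if x < 0.0:
            x = 0.0
        elif x > nv - 1.001:
            x = nv - 1.001
        i0 = int(x)
        frac = x - i0
        for gi in range(n_gates):
            inf = inf_tab[gi, i0] * (1.0 - frac) + inf_tab[gi, i0 + 1] * frac
            tau = tau_tab[gi, i0] * (1.0 - frac) + tau_tab[gi, i0 + 1] * frac
            xg = inf + (gates[gi] - inf) * np.exp(-dt / tau)
            if xg < 0.0:
                xg = 0.0
            elif xg > 1.0:
                xg = 1.0
            gates[gi] = xg
        g_sum = g_pas
        ge_sum = g_pas * e_pas
        i_expl = 0.0
        gb = 0.0  # linearized GHK slope conductance
        phi = ghk_tab[i0] * (1.0 - frac) + ghk_tab[i0 + 1] * frac
        dphi = ghk_slope_tab[i0] * (1.0 - frac) + ghk_slope_tab[i0 + 1] * frac
        for ci in range(comp_g.size):
            g = comp_g[ci]
            for ti in range(comp_off[ci], comp_off[ci + 1]):
                gv = gates[term_gate[ti]]
                for _ in range(term_exp[ti]):
                    g *= gv
            if comp_law[ci] == 0:
                g_sum += g
                ge_sum += g * comp_E[ci]
            else:
                i_expl += g * phi
                gb += g * dphi
        v = ((c - 0.5 * g_sum + 0.5 * gb) * v + ge_sum - i_expl + i_stim[step]) / (
            c + 0.5 * g_sum + 0.5 * gb
        )
        v_out[step + 1] = v
        if v > V_BLOWUP or v < -V_BLOWUP:
            status = 1
            for k in range(step + 2, n_steps + 1):
                v_out[k] = v
            break
    return v_out, gates, status


def integrate(
    cm: CompiledMembrane,
    v0: float,
    dt_ms: float,
    i_stim_density: np.ndarray,
    gates0: np.ndarray | None = None,
):
    """Run the kernel; returns (vm series incl. t=0, final gates, status)."""
    if gates0 is None:
        gates0 = cm.steady_gates(v0)
    return _kernel(
        float(v0),
        i_stim_density.size,
        float(dt_ms),
        cm.inf_tab,
        cm.tau_tab,
        cm.ghk_tab,
        cm.ghk_slope_tab,
        cm.comp_g,
        cm.comp_law,
        cm.comp_E,
        cm.term_gate,
        cm.term_exp,
        cm.comp_off,
        cm.g_pas,
        cm.e_pas,
        cm.cm_mf,
        np.asarray(i_stim_density, dtype=np.float64),
        np.asarray(gates0, dtype=np.float64),
        V_TABLE_MIN,
        1.0 / V_TABLE_STEP,
    )
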