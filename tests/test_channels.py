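"""Ion-channel kinetics: golden values, singularities, GHK flux, invariants."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from icnsim import channels as ch

VM_GRID = np.linspace(-120.0, 60.0, 1801)


# ---------------------------------------------------------------------------
# efun and GHK flux
# ---------------------------------------------------------------------------

def test_efun_reference_values():
    assert ch.efun(0.0) == 1.0
    assert ch.efun(1.0) == pytest.approx(1.0 / (math.e - 1.0), rel=1e-12)
    # continuity across the series/exact branch point
    assert abs(ch.efun(1e-4) - ch.efun(1.0001e-4)) < 1e-8
    assert abs(ch.efun(-1e-4) - ch.efun(-1.0001e-4)) < 1e-8


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.floats(min_value=-500.0, max_value=500.0))
def test_efun_positive_and_matches_exact_form(x):
    val = ch.efun(x)
    assert np.isfinite(val) and val > 0
    if abs(x) > 1e-3:  # away from the guarded region, match the raw formula
        assert val == pytest.approx(x / (math.exp(x) - 1.0), rel=1e-12)


def test_ghk_zero_crossing_at_nernst():
    env = ch.IonEnvironment()
    nernst = (
        1e3
        * env.gas_constant
        * env.temperature
        / (env.z_ca * env.faraday)
        * math.log(env.ca_out / env.ca_in)
    )
    crossing = brentq(lambda v: ch.ghk_flux(v, env), 100.0, 200.0)
    assert nernst == pytest.approx(140.7, abs=0.1)
    assert abs(crossing - nernst) < 0.5


def test_ghk_inward_at_rest_and_monotone():
    env = ch.IonEnvironment()
    assert ch.ghk_flux(0.0, env) < 0  # [Ca]i << [Ca]o: inward at 0 mV
    vals = ch.ghk_flux(np.linspace(-100.0, 200.0, 601), env)
    assert np.all(np.diff(vals) > 0)


def test_ghk_matches_unexpanded_constant_field_form():
    env = ch.IonEnvironment()
    vm = np.linspace(-100.0, 100.0, 201)
    vm = vm[np.abs(vm) > 1.0]  # stay away from the removable singularity
    u = 1e-3 * vm * env.z_ca * env.faraday / (env.gas_constant * env.temperature)
    brute = 1e-3 * env.z_ca * env.faraday * u * (env.ca_in - env.ca_out * np.exp(-u)) / (1.0 - np.exp(-u))
    assert np.allclose(ch.ghk_flux(vm, env), brute, rtol=1e-6)


# ---------------------------------------------------------------------------
# Removable singularities
# ---------------------------------------------------------------------------

def test_scn1a_alpha_m_limit():
    scn = ch.get_channel("Scn1a")
    assert ch.eval_rate(scn.gate("m").alpha, -35.0) == pytest.approx(0.182 * 9.0, rel=1e-12)


def test_kcnj3_steady_state_at_singularity():
    kj = ch.get_channel("Kcnj3")
    assert ch.steady_state(kj, "n", -30.0) == pytest.approx(0.5, abs=1e-12)
    assert ch.eval_rate(kj.gate("n").alpha, -30.0) == pytest.approx(0.009, rel=1e-12)


@pytest.mark.parametrize(
    "gene,gate,law,v_sing",
    [
        ("Scn1a", "m", "alpha", -35.0),
        ("Scn1a", "m", "beta", -35.0),
        ("Cacna1b", "m", "alpha", 20.0),
        ("Kcnj3", "n", "alpha", -30.0),
        ("Kcnj3", "n", "beta", -30.0),
    ],
)
def test_rate_continuity_across_singular_voltage(gene, gate, law, v_sing):
    g = ch.get_channel(gene).gate(gate)
    rate = getattr(g, law)
    at = ch.eval_rate(rate, v_sing)
    for eps in (1e-6, -1e-6):
        assert abs(ch.eval_rate(rate, v_sing + eps) - at) < 1e-6


def test_cacna1d_tau_rate_limit():
    # alpha_m = 0.0398*(vm+8.124)/(exp((vm+8.124)/9.005)-1) -> 0.0398*9.005
    g = ch.get_channel("Cacna1d").gate("m")
    lim = ch.eval_rate(g.tau_rates[0], -8.124)
    assert lim == pytest.approx(0.0398 * 9.005, rel=1e-12)
    assert abs(ch.eval_rate(g.tau_rates[0], -8.124 + 1e-6) - lim) < 1e-6


# ---------------------------------------------------------------------------
# Steady states and time constants (golden values)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("iso,vhalf", [(1, -94.0), (2, -99.0), (3, -96.0), (4, -100.0)])
def test_hcn_midpoints(iso, vhalf):
    spec = ch.get_channel(f"Hcn{iso}")
    assert ch.steady_state(spec, "m", vhalf) == pytest.approx(0.5, abs=1e-9)


@pytest.mark.parametrize("iso,tau", [(1, 30.0), (2, 184.0), (3, 265.0), (4, 461.0)])
def test_hcn_fixed_time_constants(iso, tau):
    spec = ch.get_channel(f"Hcn{iso}")
    for vm in (-120.0, -61.0, 0.0):
        assert ch.time_constant(spec, "m", vm) == tau


def test_scn1a_h_midpoint():
    assert ch.steady_state(ch.get_channel("Scn1a"), "h", -65.0) == pytest.approx(0.5, abs=1e-12)


def test_kcna1_x_asymptote():
    # x_inf = 0.95/(1+exp((vm+59)/3))**0.5 + 0.05 -> 0.05 as vm -> +inf
    assert ch.steady_state(ch.get_channel("Kcna1+ab1"), "x", 300.0) == pytest.approx(0.05, abs=1e-9)


def test_cacna1d_h_tau():
    assert ch.time_constant(ch.get_channel("Cacna1d"), "h", -50.0) == pytest.approx(44.3 / 3.0, rel=1e-12)


def test_cacna1g_piecewise_tau_m():
    spec = ch.get_channel("Cacna1g")
    assert ch.time_constant(spec, "m", -10.0) == 1.0  # right branch at the break
    assert ch.time_constant(spec, "m", 20.0) == 1.0
    left = -0.855809 + 1.493527 * math.exp(10.001 / 27.414182)
    assert ch.time_constant(spec, "m", -10.001) == pytest.approx(left, rel=1e-9)


def test_cacna1i_piecewise_tau_h_branches():
    spec = ch.get_channel("Cacna1i")
    lo = math.exp((-90.0 + 469.0) / 66.6) / 3.737192819
    hi = (28.0 + math.exp(-(-60.0 + 24.0) / 10.5)) / 3.737192819
    assert ch.time_constant(spec, "h", -90.0) == pytest.approx(lo, rel=1e-9)
    assert ch.time_constant(spec, "h", -60.0) == pytest.approx(hi, rel=1e-9)


# ---------------------------------------------------------------------------
# Alpha/beta consistency against independently coded printed expressions
# ---------------------------------------------------------------------------

def _scn1a_m_rates(v):
    a = 0.182 * (v + 35.0) / (1.0 - np.exp(-(v + 35.0) / 9.0))
    b = 0.124 * (-v - 35.0) / (1.0 - np.exp((v + 35.0) / 9.0))
    return a, b


def _kcna1_n_rates(v):
    a = 0.12889 * np.exp(-(v + 45.0) / -33.90877)
    b = 0.12889 * np.exp(-(v + 45.0) / 12.42101)
    return a, b


def _cacna1a_m_rates(v):
    a = 8.5 / (1.0 + np.exp((v - 8.0) / -12.5))
    b = 35.0 / (1.0 + np.exp((v + 74.0) / 14.5))
    return a, b


def _cacna1b_m_rates(v):
    a = 0.1 * (v - 20.0) / (1.0 - np.exp(-(v - 20.0) / 10.0))
    b = 0.4 * np.exp(-(v + 25.0) / 18.0)
    return a, b


def _cacna1b_h_rates(v):
    a = 0.01 * np.exp(-(v + 50.0) / 10.0)
    b = 0.1 / (1.0 + np.exp(-(v + 17.0) / 17.0))
    return a, b


@pytest.mark.parametrize(
    "gene,gate,rates,tau_scale",
    [
        ("Scn1a", "m", _scn1a_m_rates, 1.0),
        ("Kcna1+ab1", "n", _kcna1_n_rates, 1.0 / 4.171167511),
        ("Cacna1a", "m", _cacna1a_m_rates, 1.0),
        ("Cacna1b", "m", _cacna1b_m_rates, 1.0),
        ("Cacna1b", "h", _cacna1b_h_rates, 1.0),
    ],
)
def test_alpha_beta_gates_match_printed_expressions(gene, gate, rates, tau_scale):
    spec = ch.get_channel(gene)
    vm = np.array([-80.0, -61.0, -50.0, -20.0, 0.0, 30.0])  # away from singularities
    a, b = rates(vm)
    assert np.allclose(ch.steady_state(spec, gate, vm), a / (a + b), rtol=0, atol=1e-12)
    assert np.allclose(ch.time_constant(spec, gate, vm), tau_scale / (a + b), rtol=1e-12)


# ---------------------------------------------------------------------------
# Global invariants and current law
# ---------------------------------------------------------------------------

def test_all_gates_bounded_and_tau_positive():
    for gene, spec in ch.registry().items():
        for gate in spec.gates:
            inf = np.asarray(ch.steady_state(spec, gate, VM_GRID))
            tau = np.asarray(ch.time_constant(spec, gate, VM_GRID))
            assert inf.min() >= -1e-12 and inf.max() <= 1.0 + 1e-12, (gene, gate.name)
            assert tau.min() > 0.0, (gene, gate.name)


def test_channel_current_zero_cases():
    scn = ch.get_channel("Scn1a")
    rev = {"ENa": 50.0, "EK": -77.0, "EHcn": -45.0}
    assert ch.channel_current(scn, {"m": 0.0, "h": 0.0}, -61.0, 0.075, rev) == 0.0
    assert ch.channel_current(scn, {"m": 0.7, "h": 0.3}, 50.0, 0.075, rev) == 0.0  # vm == ENa


def test_channel_current_hcn_worked_example():
    hcn1 = ch.get_channel("Hcn1")
    i = ch.channel_current(hcn1, {"m": 1.0}, -55.0, 0.003, {"EHcn": -45.0})
    assert i == pytest.approx(0.003 * (-10.0), rel=1e-12)


def test_channel_current_linear_in_gbar():
    kc = ch.get_channel("Kcnc1")
    rev = {"EK": -77.0}
    gates = {"n": 0.4, "p": 0.6}
    i1 = ch.channel_current(kc, gates, -30.0, 0.018, rev, phi=0.2)
    i3 = ch.channel_current(kc, gates, -30.0, 3 * 0.018, rev, phi=0.2)
    assert i3 == pytest.approx(3 * i1, rel=1e-12)


def test_kcna1_without_beta1_equals_x_clamped_at_one():
    merged = ch.get_channel("Kcna1+ab1")
    bare = ch.get_channel("Kcna1")
    rev = {"EK": -77.0}
    i_merged = ch.channel_current(merged, {"n": 0.5, "x": 1.0}, -40.0, 0.018, rev)
    i_bare = ch.channel_current(bare, {"n": 0.5}, -40.0, 0.018, rev)
    assert i_bare == pytest.approx(i_merged, rel=1e-12)


def test_missing_reversal_potential_raises():
    with pytest.raises(KeyError):
        ch.channel_current(ch.get_channel("Scn1a"), {"m": 0.1, "h": 0.5}, -61.0, 0.075, {"EK": -77.0})


def test_gate_values_outside_unit_interval_rejected():
    with pytest.raises(ValueError):
        ch.channel_current(ch.get_channel("Hcn1"), {"m": 1.2}, -61.0, 0.003, {"EHcn": -45.0})


def test_ghk_channel_current_sign_at_rest():
    cav = ch.get_channel("Cacna1b")
    i = ch.channel_current(cav, {"m": 0.5, "h": 0.5}, -20.0, 1e-4)
    assert i < 0  # calcium current is inward below the Ca nernst potential


# ---------------------------------------------------------------------------
# IV curves
# ---------------------------------------------------------------------------

def test_iv_curves_scn1a_monotone_and_window():
    df = ch.iv_curves(ch.get_channel("Scn1a"), np.linspace(-120.0, 40.0, 801))
    m, h = df["act_m"].to_numpy(), df["inact_h"].to_numpy()
    assert np.all(np.diff(m) >= 0)
    assert np.all(np.diff(h) <= 0)
    window = m**3 * h
    v_at_max = df["vm_mV"].to_numpy()[np.argmax(window)]
    assert -60.0 <= v_at_max <= -20.0


def test_iv_curves_hcn_single_activation_column():
    df = ch.iv_curves(ch.get_channel("Hcn1"), np.linspace(-140.0, 0.0, 141))
    assert list(df.columns) == ["vm_mV", "act_m"]


def test_iv_curves_requires_ordered_grid():
    with pytest.raises(ValueError):
        ch.iv_curves(ch.get_channel("Hcn1"), np.array([0.0, -10.0, 10.0]))


# ---------------------------------------------------------------------------
# Registry structure and serialization
# ---------------------------------------------------------------------------

def test_registry_covers_all_channel_genes():
    reg = ch.registry()
    for gene in ch.GENES:
        assert gene in reg
    assert "Kcna1" in reg  # beta1-less variant
    assert len(ch.TRANSCRIPTS) == 15 and len(ch.GENES) == 14


def test_ohmic_channels_reference_exactly_one_reversal():
    for spec in ch.registry().values():
        if spec.current_law == "ohmic":
            assert spec.reversal in ("ENa", "EK", "EHcn")
        else:
            assert spec.reversal is None


def test_registry_serializes_to_json():
    blob = json.dumps(ch.registry_to_dict(), default=list)
    data = json.loads(blob)
    assert data["Scn1a"]["current_law"] == "ohmic"
    assert data["Cacna1g"]["current_law"] == "ghk"
    assert {g["name"] for g in data["Kcna1+ab1"]["gates"]} == {"n", "x"}


def test_scale_inf_slope():
    scn = ch.get_channel("Scn1a")
    shallow = ch.scale_inf_slope(scn, "h", 1.2)
    assert shallow.gate("h").inf[1]["k"] == pytest.approx(6.2 * 1.2)
    # midpoint is unchanged, the curve is just shallower
    assert ch.steady_state(shallow, "h", -65.0) == pytest.approx(0.5, abs=1e-12)
    with pytest.raises(KeyError):
        ch.scale_inf_slope(scn, "q", 1.2)
    with pytest.raises(ValueError):
        ch.scale_inf_slope(scn, "m", 1.2)  # alpha-beta gate has no sigmoid inf
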