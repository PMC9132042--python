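"""Astrocyte membrane electrics: Kir4.1, leak, Nernst and resting potential.

The inwardly rectifying Kir4.1 current density (mA cm^-2, inward negative) is

    I_Kir = G_Kir * c([K]o) * (V - NK*E_K - V_A1) / (1 + exp((V - NK*E_K - V_A2)/V_A3))

with the Nernst potential E_K = s * ln([K]o/[K]i) and a concentration factor
c([K]o) whose published form is ambiguous; the default dialect uses
sqrt([K]o / K_ref) (the square-root conductance scaling typical of Kir4.1),
with linear and constant dialects selectable.  A small ohmic leak
I_pas = G_pas (V - E_pas) stabilises the resting potential near E_pas.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MembraneParams",
    "nernst_potential",
    "kir_current_density",
    "leak_current_density",
    "resting_potential",
    "voltage_step_response",
]


@dataclass(frozen=True)
class MembraneParams:
    g_kir: float = 0.1        # mS cm^-2
    v_a1: float = -14.83      # mV
    v_a2: float = -105.82     # mV
    v_a3: float = 19.23       # mV
    nk: float = 0.81          # Nernst scaling of the Kir equilibrium
    g_pas: float = 0.001      # mS cm^-2
    e_pas: float = -85.0      # mV
    c_m: float = 1.0          # uF cm^-2
    nernst_slope: float = 26.7  # mV (= 53.4 / 2, the transporter convention)
    k_ref: float = 3.0        # mM, reference [K]o of the Kir concentration factor
    kir_k_factor: str = "sqrt"  # "sqrt" | "linear" | "none"

    def __post_init__(self) -> None:
        if self.g_kir < 0 or self.g_pas < 0:
            raise ValueError("conductances must be >= 0")
        if self.v_a3 == 0:
            raise ValueError("v_a3 must be nonzero")
        if self.c_m <= 0 or self.nernst_slope <= 0 or self.k_ref <= 0:
            raise ValueError("c_m, nernst_slope and k_ref must be > 0")
        if self.kir_k_factor not in ("sqrt", "linear", "none"):
            raise ValueError(f"unknown kir_k_factor {self.kir_k_factor!r}")

    def replace(self, **kw) -> "MembraneParams":
        return replace(self, **kw)


def nernst_potential(k_out, k_in, slope: float = 26.7):
    """E_K = slope * ln([K]o / [K]i), mV."""
    k_out = np.asarray(k_out, dtype=float)
    k_in = np.asarray(k_in, dtype=float)
    if np.any(k_out <= 0) or np.any(k_in <= 0):
        raise ValueError("concentrations must be > 0")
    return slope * np.log(k_out / k_in)


def _k_factor(k_out, p: MembraneParams):
    if p.kir_k_factor == "sqrt":
        return np.sqrt(np.asarray(k_out, dtype=float) / p.k_ref)
    if p.kir_k_factor == "linear":
        return np.asarray(k_out, dtype=float) / p.k_ref
    return np.ones_like(np.asarray(k_out, dtype=float))


def kir_current_density(V, k_out, k_in, params: MembraneParams | None = None):
    """Kir4.1 current density, mA cm^-2 (inward negative)."""
    p = params if params is not None else MembraneParams()
    e_k = nernst_potential(k_out, k_in, p.nernst_slope)
    x = V - p.nk * e_k
    num = p.g_kir * _k_factor(k_out, p) * (x - p.v_a1)
    den = 1.0 + np.exp((x - p.v_a2) / p.v_a3)
    return num / den * 1e-3  # mS cm^-2 * mV = uA cm^-2 -> mA cm^-2


def leak_current_density(V, params: MembraneParams | None = None):
    p = params if params is not None else MembraneParams()
    return p.g_pas * (V - p.e_pas) * 1e-3


def total_current_density(V, k_out, k_in, params: MembraneParams | None = None):
    return kir_current_density(V, k_out, k_in, params) + leak_current_density(V, params)


def resting_potential(
    k_out: float,
    k_in: float = 120.0,
    params: MembraneParams | None = None,
    extra_current=None,
    bracket=(-150.0, 0.0),
) -> float:
    """Zero of the total membrane current over the physiological bracket, mV.

    ``extra_current(V) -> mA cm^-2`` may add e.g. the transporter current.
    """
    p = params if params is not None else MembraneParams()
    if p.g_kir == 0 and extra_current is None:
        return p.e_pas

    def f(V):
        tot = total_current_density(V, k_out, k_in, p)
        if extra_current is not None:
            tot += extra_current(V)
        return tot

    lo, hi = bracket
    if f(lo) * f(hi) > 0:
        raise RuntimeError("no bracketed zero-current voltage; check parameters")
    V = brentq(f, lo, hi, xtol=1e-12)
    assert abs(f(V)) < 1e-12 + 1e-9 * abs(f(lo))
    return V


def voltage_step_response(
    k_out_schedule,
    params: MembraneParams | None = None,
    dt: float = 0.1,
    T: float = 2000.0,
    k_in: float = 120.0,
    v0: float | None = None,
):
    """Single-compartment voltage relaxation under a [K]o schedule.

    Integrates C_m dV/dt = -(I_Kir + I_pas) by semi-implicit Euler (the ohmic
    leak implicit, Kir explicit).  ``k_out_schedule`` maps t (ms) to [K]o (mM).

    Returns (times_ms, V_mV).
    """
    p = params if params is not None else MembraneParams()
    if v0 is None:
        v0 = resting_potential(k_out_schedule(0.0), k_in, p)
    n = int(round(T / dt))
    t = np.arange(n + 1) * dt
    V = np.empty(n + 1)
    V[0] = v0
    # unit bookkeeping: densities cancel, so work per unit area.
    # C_m [uF/cm^2] dV/dt [mV/ms] = -I [mA/cm^2] * 1e3
    for i in range(n):
        ko = k_out_schedule(t[i + 1])
        i_kir = kir_current_density(V[i], ko, k_in, p)
        rhs = V[i] - dt * 1e3 / p.c_m * (i_kir - p.g_pas * p.e_pas * 1e-3)
        V[i + 1] = rhs / (1.0 + dt * 1e3 / p.c_m * p.g_pas * 1e-3)
        if not -150.0 <= V[i + 1] <= 50.0:
            raise FloatingPointError("voltage left the physiological range")
    return t, V
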