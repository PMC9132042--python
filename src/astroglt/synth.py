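"""Seeded generator of synthetic astrocyte recordings with known ground truth.

Each synthetic recording is the sum of two inward components plus Gaussian
noise: a fast transporter current (difference-of-exponentials kernel,
tau_decay ~ 5.75 ms for a single stimulus) and a slow K+ current (tau_decay
hundreds of ms).  Train protocols (5 stimuli at 50 Hz) apply per-stimulus
facilitation factors and tau_decay multipliers (use-dependent prolongation,
up to ~4x for the last response, mirroring the 23.65/5.75 ms ratio observed
experimentally).  Every random draw flows from the config seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .traceio import Trace

__all__ = ["SynthConfig", "make_kernel", "kernel_peak_time", "synth_trace",
           "synth_experiment"]

TRAIN_FACILITATION = (1.0, 1.4, 1.8, 2.1, 2.3)
TRAIN_TAU_MULT = (1.0, 1.5, 2.2, 3.0, 4.1)  # last ~ 23.65 / 5.75


@dataclass(frozen=True)
class SynthConfig:
    glut_tau_rise: float = 1.0
    glut_tau_decay: float = 5.75
    glut_peak: float = 10.0        # pA, magnitude of the inward peak
    ik_tau_rise: float = 10.0
    ik_tau_decay: float = 300.0
    ik_peak: float = 20.0
    protocol: str = "single"       # "single" | "train"
    n_stims: int = 5
    train_hz: float = 50.0
    glut_facilitation: tuple = TRAIN_FACILITATION
    ik_facilitation: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    glut_tau_mult: tuple = TRAIN_TAU_MULT
    noise_sd: float = 1.0          # pA
    dt: float = 0.1                # ms (10 kHz)
    t_pre: float = 50.0
    t_post: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.glut_tau_decay <= 0 or self.ik_tau_decay <= 0 or self.dt <= 0:
            raise ValueError("tau values and dt must be > 0")
        if any(f <= 0 for f in self.glut_facilitation + self.glut_tau_mult):
            raise ValueError("facilitation factors and tau multipliers must be > 0")
        if self.protocol not in ("single", "train"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def replace(self, **kw) -> "SynthConfig":
        return replace(self, **kw)

    def stim_times(self, t0: float = 0.0):
        if self.protocol == "single":
            return (t0 + self.t_pre,)
        isi = 1000.0 / self.train_hz
        return tuple(t0 + self.t_pre + i * isi for i in range(self.n_stims))


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Extremum time of the difference-of-exponentials kernel (ms)."""
    return math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)


def make_kernel(tau_rise: float, tau_decay: float, peak: float,
                dt: float = 0.1, t_len: float | None = None) -> Trace:
    """Inward unit response: normalised difference of exponentials.

    k(t) = -peak * (exp(-t/tau_decay) - exp(-t/tau_rise)) / norm, so the
    extremum magnitude equals ``peak`` (at the closed-form time t*).
    """
    if not tau_decay > tau_rise > 0:
        raise ValueError("need tau_decay > tau_rise > 0")
    if t_len is None:
        t_len = 8.0 * tau_decay
    t = np.arange(0.0, t_len, dt)
    shape = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    tstar = kernel_peak_time(tau_rise, tau_decay)
    norm = math.exp(-tstar / tau_decay) - math.exp(-tstar / tau_rise)
    return Trace(t0=0.0, dt=dt, samples=-peak * shape / norm, unit="pA",
                 label=f"kernel tau={tau_decay}")


def _add_kernel(samples, t, onset, tau_rise, tau_decay, peak):
    m = t >= onset
    tt = t[m] - onset
    shape = np.exp(-tt / tau_decay) - np.exp(-tt / tau_rise)
    tstar = kernel_peak_time(tau_rise, tau_decay)
    norm = math.exp(-tstar / tau_decay) - math.exp(-tstar / tau_rise)
    samples[m] += -peak * shape / norm


def synth_trace(config: SynthConfig):
    """Combined noisy trace plus noise-free ground-truth components.

    Returns (combined, components) where components is a dict with keys
    ``glut``, ``ik`` (noise-free Traces); combined = glut + ik + noise.
    """
    cfg = config
    stims = cfg.stim_times()
    t_len = cfg.t_pre + (stims[-1] - stims[0]) + cfg.t_post
    n = int(round(t_len / cfg.dt)) + 1
    t = np.arange(n) * cfg.dt
    glut = np.zeros(n)
    ik = np.zeros(n)
    for i, st in enumerate(stims):
        fg = cfg.glut_facilitation[i] if cfg.protocol == "train" else 1.0
        fk = cfg.ik_facilitation[i] if cfg.protocol == "train" else 1.0
        tm = cfg.glut_tau_mult[i] if cfg.protocol == "train" else 1.0
        _add_kernel(glut, t, st, cfg.glut_tau_rise, cfg.glut_tau_decay * tm,
                    cfg.glut_peak * fg)
        _add_kernel(ik, t, st, cfg.ik_tau_rise, cfg.ik_tau_decay,
                    cfg.ik_peak * fk)
    rng = np.random.default_rng(cfg.seed)
    noise = rng.normal(scale=cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
    mk = lambda s, lbl: Trace(t0=0.0, dt=cfg.dt, samples=s, unit="pA",
                              stim_times=stims, label=lbl)
    combined = mk(glut + ik + noise, f"synthetic:{cfg.protocol}")
    return combined, {"glut": mk(glut, "glut"), "ik": mk(ik, "ik")}


def synth_experiment(config: SynthConfig, n_cells: int, seed: int | None = None,
                     out_dir=None):
    """Batch of paired (combined, K-only template) recordings with a manifest.

    Per cell the K+ component is rescaled by a lognormal per-cell factor and
    returned noise-corrupted as the blocker (transporter-free) template,
    emulating the combined + DL-TBOA recording pairs.  If ``out_dir`` is
    given, traces and the JSON manifest are written there.

    Returns (cells, manifest); cells is a list of dicts with keys
    ``combined``, ``template``, ``truth``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    master = np.random.default_rng(seed if seed is not None else config.seed)
    cells = []
    manifest = {"n_cells": n_cells, "config": {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(config).items()}, "cells": []}
    for c in range(n_cells):
        cell_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(cell_seed)
        ik_scale = float(np.exp(rng.normal(0.0, 0.2)))
        cfg = config.replace(seed=cell_seed)
        combined, comps = synth_trace(cfg)
        # blocker trace: same K+ kernel scaled per cell, its own noise
        tmpl_noise = rng.normal(scale=cfg.noise_sd, size=len(comps["ik"].samples)) \
            if cfg.noise_sd > 0 else 0.0
        template = comps["ik"].replace(
            samples=comps["ik"].samples / ik_scale + tmpl_noise,
            label=f"cell{c}|ik_template")
        truth = dict(cell=c, seed=cell_seed, ik_scale=ik_scale,
                     glut_tau_decay=cfg.glut_tau_decay,
                     glut_peak=cfg.glut_peak, noise_sd=cfg.noise_sd)
        cells.append(dict(combined=combined, template=template, truth=truth))
        manifest["cells"].append(truth)
    if out_dir is not None:
        from .traceio import write_trace

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for c, cell in enumerate(cells):
            write_trace(cell["combined"], out / f"cell{c:03d}_combined.csv")
            write_trace(cell["template"], out / f"cell{c:03d}_template.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return cells, manifest
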