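"""Patch-clamp IV-curve analysis: membrane properties, kinetics, classification.

Works on voltage-step recordings (50 ms steps, −170 … +60 mV in 10 mV
increments, holding −70 or −20 mV).  Derives membrane resistance R_m (MΩ),
capacitance C_m (pF), reversal potential V_rev (mV), the specific outward
conductance (0 vs −20 mV steps read 40 ms after pulse onset, nS/pF), the
specific inward conductance (−120 vs −100 mV steps read 10 ms after onset,
nS/pF), exponential activation / inactivation time constants, and a
four-group current-type classification with the 0.5 nS/pF strong/moderate
inward threshold.

Unit conventions: voltages mV, currents pA, resistances MΩ, capacitances pF,
conductances nS, times ms.  Note mV/MΩ = nA = 1000 pA and nS·mV = pA.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class StepProtocol:
    """Voltage-step protocol: holding potential plus a ladder of steps."""

    holding: float = -70.0
    step_levels: tuple[float, ...] = tuple(float(v) for v in range(-170, 70, 10))
    step_duration: float = 50.0   # ms
    sample_interval: float = 0.02  # ms (50 kHz)

    def __post_init__(self) -> None:
        levels = np.asarray(self.step_levels)
        if len(levels) < 1 or np.any(np.diff(levels) <= 0):
            raise ValueError("step levels must be strictly increasing")
        if self.step_duration <= 0 or self.sample_interval <= 0:
            raise ValueError("durations must be positive")

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms from step onset (inclusive of 0)."""
        n = int(round(self.step_duration / self.sample_interval)) + 1
        return np.arange(n) * self.sample_interval


@dataclass
class IVRecording:
    """Current traces for one cell: one row of ``traces`` per step level (pA)."""

    protocol: StepProtocol
    traces: np.ndarray  # (n_steps, n_samples)
    cell_id: str = "cell"
    clone_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.shape != (len(self.protocol.step_levels),
                                 len(self.protocol.times)):
            raise ValueError("trace array does not match protocol")

    def trace(self, level: float) -> np.ndarray:
        levels = np.asarray(self.protocol.step_levels)
        idx = np.flatnonzero(np.isclose(levels, level))
        if idx.size == 0:
            raise KeyError(f"no step at {level} mV")
        return self.traces[idx[0]]


@dataclass
class MembraneProperties:
    R_m: Optional[float] = None        # MΩ
    C_m: Optional[float] = None        # pF
    V_rev: Optional[float] = None      # mV (None when IV does not cross zero)
    G_out_spec: Optional[float] = None  # nS/pF
    G_in_spec: Optional[float] = None   # nS/pF
    current_class: Optional[str] = None


@dataclass
class KineticsFit:
    """One exponential fit: time constant (ms) plus diagnostics."""

    voltage: float
    tau: Optional[float]
    amplitude: Optional[float]
    residual_norm: Optional[float]
    ok: bool
    note: str = ""


CURRENT_CLASSES = ("small", "moderate_inward_only", "strong_inward_only",
                   "inward_and_outward")


# ---------------------------------------------------------------------------
# trace persistence (long CSV: cell_id, holding_mV, step_mV, t_ms, I_pA)

def write_traces(recordings: dict[float, list[IVRecording]],
                 path: str | Path) -> Path:
    """Write recordings keyed by holding potential to one long-format CSV."""
    frames = []
    for holding, recs in recordings.items():
        for rec in recs:
            t = rec.protocol.times
            for lvl, tr in zip(rec.protocol.step_levels, rec.traces):
                frames.append(pd.DataFrame({
                    "cell_id": rec.cell_id, "holding_mV": holding,
                    "step_mV": lvl, "t_ms": t, "I_pA": tr}))
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.10g")
    return path


def read_traces(path: str | Path) -> dict[float, list[IVRecording]]:
    df = pd.read_csv(path)
    out: dict[float, list[IVRecording]] = {}
    for (holding, cell_id), g in df.groupby(["holding_mV", "cell_id"], sort=True):
        levels = np.sort(g["step_mV"].unique())
        t = np.sort(g["t_ms"].unique())
        proto = StepProtocol(holding=float(holding),
                             step_levels=tuple(float(v) for v in levels),
                             step_duration=float(t[-1]),
                             sample_interval=float(t[1] - t[0]))
        traces = np.empty((len(levels), len(t)))
        for i, lvl in enumerate(levels):
            gi = g[g["step_mV"] == lvl].sort_values("t_ms")
            traces[i] = gi["I_pA"].to_numpy()
        out.setdefault(float(holding), []).append(
            IVRecording(protocol=proto, traces=traces, cell_id=str(cell_id)))
    return out


# ---------------------------------------------------------------------------
# IV-curve construction and membrane properties

def build_iv_curve(rec: IVRecording, latency: float | None = None,
                   window: tuple[float, float] | None = None) -> np.ndarray:
    """IV points (V, I): current read at ``latency`` ms (3-sample median) or
    averaged over ``window``; default = steady state, mean over the final 5 ms.
    """
    t = rec.protocol.times
    if latency is not None:
        if not (0 <= latency <= rec.protocol.step_duration):
            raise ValueError(f"latency {latency} ms outside the step")
        i = int(np.argmin(np.abs(t - latency)))
        lo, hi = max(i - 1, 0), min(i + 2, len(t))
        current = np.median(rec.traces[:, lo:hi], axis=1)
    else:
        if window is None:
            window = (rec.protocol.step_duration - 5.0,
                      rec.protocol.step_duration)
        sel = (t >= window[0]) & (t <= window[1])
        if not sel.any():
            raise ValueError("window outside the trace")
        current = rec.traces[:, sel].mean(axis=1)
    return np.column_stack([rec.protocol.step_levels, current])


def membrane_resistance(iv: np.ndarray, holding: float = -20.0,
                        half_width: float = 20.0) -> float:
    """Inverse slope (MΩ) of the least-squares IV line within ±20 mV of holding."""
    V, I = iv[:, 0], iv[:, 1]
    sel = (V >= holding - half_width) & (V <= holding + half_width)
    if sel.sum() < 3:
        raise ValueError("need at least 3 IV points near holding")
    slope, _ = np.polyfit(V[sel], I[sel], 1)  # pA/mV = nS
    if slope <= 0:
        raise ValueError("non-positive IV slope; resistance undefined")
    return 1000.0 / slope  # nS -> MΩ


def _estimate_transient_tau(t: np.ndarray, dI: np.ndarray) -> float:
    """Rough τ of the fast capacitive decay: log-linear fit over the leading
    samples before |dI| falls below 30 % of its peak (the fast transient
    dominates there even when slow channel relaxations overlap)."""
    peak = abs(dI[0])
    sel = np.abs(dI) > 0.3 * peak
    stop = np.argmin(sel) if not sel.all() else len(sel)
    stop = int(np.clip(stop, 3, 12))
    y = np.log(np.abs(dI[:stop]) + 1e-300)
    slope, _ = np.polyfit(t[:stop], y, 1)
    if slope >= 0:
        raise ValueError("transient does not decay")
    return -1.0 / slope


def membrane_capacitance(rec: IVRecording, step_level: float | None = None) -> float:
    """C_m (pF) from the capacitive charging transient of a small step.

    Q = ∫(I(t) − I_ss) dt (trapezoidal) over the first 5·τ̂ of the step, with
    τ̂ estimated from the transient's own decay, a correction for the
    truncated exponential tail, and a fitted constant-plus-linear baseline
    that absorbs slowly relaxing channel currents; C_m = Q/ΔV.  Default
    step: −10 mV from holding.
    """
    holding = rec.protocol.holding
    if step_level is None:
        step_level = holding - 10.0
    dV = step_level - holding
    if dV == 0:
        raise ValueError("ΔV = 0: no charging transient")
    t = rec.protocol.times
    dt = rec.protocol.sample_interval
    tr = rec.trace(step_level)
    i_ss = tr[t >= rec.protocol.step_duration - 5.0].mean()
    dI = tr - i_ss
    tau_rough = _estimate_transient_tau(t, dI)
    t_fit = min(max(12.0 * tau_rough, 25.0 * dt), rec.protocol.step_duration / 2)
    sel = t <= t_fit
    model = lambda tt, a, tau, b, c: a * np.exp(-tt / tau) + b + c * tt
    try:
        popt, _ = curve_fit(model, t[sel], dI[sel],
                            p0=(dI[0], tau_rough, 0.0, 0.0),
                            bounds=([-np.inf, dt / 10, -np.inf, -np.inf],
                                    [np.inf, t_fit, np.inf, np.inf]),
                            maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"capacitive transient fit failed: {exc}") from exc
    a, tau, b, c = popt
    win = t <= 5.0 * tau
    corrected = dI[win] - (b + c * t[win])
    q = np.trapezoid(corrected, t[win])        # pA·ms = fC
    q /= 1.0 - np.exp(-t[win][-1] / tau)       # tail correction
    c_m = q / dV                               # fC/mV = pF
    if c_m <= 0:
        raise ValueError("non-positive capacitance estimate")
    return float(c_m)


def reversal_potential(iv: np.ndarray, holding: float = -70.0) -> Optional[float]:
    """Zero-current crossing (mV) by linear interpolation; nearest to holding
    when several; None when the IV does not bracket zero."""
    V, I = iv[:, 0], iv[:, 1]
    crossings = []
    for k in range(len(V) - 1):
        if I[k] == 0:
            crossings.append(float(V[k]))
        elif I[k] * I[k + 1] < 0:
            crossings.append(float(V[k] - I[k] * (V[k + 1] - V[k]) / (I[k + 1] - I[k])))
    if I[-1] == 0:
        crossings.append(float(V[-1]))
    if not crossings:
        return None
    return min(crossings, key=lambda v: abs(v - holding))


def _current_at(rec: IVRecording, level: float, latency: float) -> float:
    t = rec.protocol.times
    i = int(np.argmin(np.abs(t - latency)))
    lo, hi = max(i - 1, 0), min(i + 2, len(t))
    return float(np.median(rec.trace(level)[lo:hi]))


def specific_outward_conductance(rec: IVRecording, c_m: float,
                                 latency: float = 40.0) -> float:
    """[I(0 mV) − I(−20 mV)] / 20 mV / C_m at 40 ms after pulse onset (nS/pF),
    floored at 0.  Expects a recording from holding −70 mV."""
    if c_m <= 0:
        raise ValueError("C_m must be positive")
    dI = _current_at(rec, 0.0, latency) - _current_at(rec, -20.0, latency)
    return max(dI / 20.0 / c_m, 0.0)


def specific_inward_conductance(rec: IVRecording, c_m: float,
                                latency: float = 10.0) -> float:
    """[I(−120 mV) − I(−100 mV)] / (−20 mV) / C_m at 10 ms after onset (nS/pF),
    floored at 0 (positive for inward rectification).  Expects holding −20 mV."""
    if c_m <= 0:
        raise ValueError("C_m must be positive")
    dI = _current_at(rec, -120.0, latency) - _current_at(rec, -100.0, latency)
    return max(dI / -20.0 / c_m, 0.0)


def classify_cell(g_out_spec: float, g_in_spec: float,
                  theta_out: float = 0.1, theta_in: float = 0.1,
                  strong_threshold: float = 0.5) -> str:
    """Four-group current-type classification.

    Outward current present iff G_out_spec ≥ θ_out, inward present iff
    G_in_spec ≥ θ_in.  Neither → ``small``; both → ``inward_and_outward``;
    inward only → split at the 0.5 nS/pF threshold (≥ 0.5 → strong).
    """
    outward = g_out_spec >= theta_out
    inward = g_in_spec >= theta_in
    if outward:
        # outward-present cells go to the outward group; an outward-only cell
        # (not observed in practice) has no class of its own
        return "inward_and_outward"
    if not inward:
        return "small"
    return "strong_inward_only" if g_in_spec >= strong_threshold else "moderate_inward_only"


def extract_membrane_properties(rec_minus70: IVRecording,
                                rec_minus20: IVRecording,
                                theta_out: float = 0.1, theta_in: float = 0.1,
                                strong_threshold: float = 0.5) -> MembraneProperties:
    """Full per-cell property extraction from the paired-holding recordings."""
    iv20 = build_iv_curve(rec_minus20)
    iv70 = build_iv_curve(rec_minus70)
    r_m = membrane_resistance(iv20, holding=-20.0)
    c_m = membrane_capacitance(rec_minus20)
    v_rev = reversal_potential(iv70, holding=-70.0)
    g_out = specific_outward_conductance(rec_minus70, c_m)
    g_in = specific_inward_conductance(rec_minus20, c_m)
    cls = classify_cell(g_out, g_in, theta_out, theta_in, strong_threshold)
    return MembraneProperties(R_m=r_m, C_m=c_m, V_rev=v_rev,
                              G_out_spec=g_out, G_in_spec=g_in,
                              current_class=cls)


# ---------------------------------------------------------------------------
# current kinetics

def _fit_exponential(t: np.ndarray, y: np.ndarray, rising: bool,
                     voltage: float) -> KineticsFit:
    span = y.max() - y.min()
    if span == 0 or not np.isfinite(span):
        return KineticsFit(voltage, None, None, None, False, "flat trace")
    tau0 = max(t[-1] / 5.0, t[1] - t[0])
    if rising:
        model = lambda tt, a, tau, b: a * (1.0 - np.exp(-tt / tau)) + b
        p0 = (y[-1] - y[0], tau0, y[0])
    else:
        model = lambda tt, a, tau, b: a * np.exp(-tt / tau) + b
        p0 = (y[0] - y[-1], tau0, y[-1])
    try:
        popt, _ = curve_fit(model, t, y, p0=p0,
                            bounds=([-np.inf, t[1] - t[0], -np.inf],
                                    [np.inf, 10 * t[-1], np.inf]),
                            maxfev=5000)
    except (RuntimeError, ValueError):
        return KineticsFit(voltage, None, None, None, False, "fit failed")
    a, tau, b = popt
    resid = float(np.linalg.norm(y - model(t, *popt)))
    if abs(a) < 0.02 * max(abs(span), 1e-12) or abs(a) < 1e-9:
        return KineticsFit(voltage, None, None, resid, False,
                           "no resolvable exponential component")
    if rising and a <= 0:
        return KineticsFit(voltage, float(tau), float(a), resid, False,
                           "amplitude sign inconsistent with activation")
    if not rising and a >= 0 and y[0] < y[-1]:
        return KineticsFit(voltage, float(tau), float(a), resid, False,
                           "trace does not decay")
    return KineticsFit(voltage, float(tau), float(a), resid, True)


def _post_transient(rec: IVRecording, level: float,
                    skip_ms: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    t = rec.protocol.times
    sel = t >= skip_ms
    return t[sel] - skip_ms, rec.trace(level)[sel]


def fit_activation_tau(rec: IVRecording, voltage: float,
                       skip_ms: float = 2.0) -> KineticsFit:
    """τ of delayed outward-current activation at one depolarizing step:
    least-squares fit of I = A(1 − exp(−t/τ)) + B after the capacitive
    transient.  Non-convergence is flagged in the result, never raised."""
    t, y = _post_transient(rec, voltage, skip_ms)
    fit = _fit_exponential(t, y, rising=True, voltage=voltage)
    return fit


def fit_inactivation_tau(rec: IVRecording, voltage: float,
                         skip_ms: float = 2.0) -> KineticsFit:
    """τ of inward-current inactivation at one hyperpolarizing step
    (V ≤ −110 mV): fit of I = A·exp(−t/τ) + B after the transient."""
    t, y = _post_transient(rec, voltage, skip_ms)
    # inactivation is a decay of current *magnitude*; a trace whose magnitude
    # grows (e.g. an activating outward current) is flagged, not fitted
    m0 = float(np.median(np.abs(y[:5])))
    m1 = float(np.median(np.abs(y[-5:])))
    if m0 <= m1:
        return KineticsFit(voltage, None, None, None, False,
                           "current magnitude does not decay")
    # inward current relaxes toward less negative values: fit on -I so the
    # exponential amplitude is positive-decaying
    return _fit_exponential(t, -y, rising=False, voltage=voltage)


def kinetics_profile(rec: IVRecording, voltages: list[float],
                     kind: str = "activation") -> list[KineticsFit]:
    fitter = fit_activation_tau if kind == "activation" else fit_inactivation_tau
    return [fitter(rec, v) for v in voltages]
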