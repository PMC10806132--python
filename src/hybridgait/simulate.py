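"""Closed-loop gait simulation of the hybrid orthosis + FES system.

A 1-DOF torque-balance ankle plant is walked through synthetic treadmill
gait while the full control stack runs in the loop: foot-switch contact
detection and gait-phase tracking, speed-adaptive reference lookups,
stimulated-EMG synthesis and artifact-removal filtering, volitional torque
estimation, coordination, and the admittance + PD orthosis controller.

Two controller modes mirror the experimental conditions:

* **PF** — orthosis and FES assist without considering volition: the
  volitional-torque path is disabled (``r_v`` forced to 0) and the FES
  amplitudes follow the reference-torque profile.
* **PFV** — the volitional torque estimated from the filtered EMG offsets
  the FES demand and lowers the rendered stiffness (assist-as-needed).

Sign conventions: the *ankle angle* is dorsiflexion-positive; *torques*
are reported plantar-flexion-positive (muscle convention).  The bridge
between the two frames is the single constant ``TORQUE_TO_ANGLE_SIGN``:
angular acceleration is ``TORQUE_TO_ANGLE_SIGN * tau / I``.  Powers and
energies are computed in the angle-consistent frame, so positive power is
work done in the direction of motion regardless of convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import coordination as coord
from .cnn import CnnTorqueRegressor
from .filters import (
    CASCADE_GAIN,
    FilterConfig,
    carrier_window,
    comb_filter,
    volitional_torque,
)
from .gait import ColdStartError, ContactDetector, FsrFrame, GaitPhaseTracker
from .linkage import ImpedanceSetpoint, PDGains, desired_angle_step, pd_control
from .reference import (
    EnvelopeModel,
    ReferenceTable,
    _raised_cosine,
    default_envelope_model,
    default_reference_table,
    emg_envelope,
)
from .synth import (
    TORQUE_GAIN_NM,
    EmgSynthesisParams,
    bandlimited_noise,
    gen_fsr_traces,
    mwave_template,
)

__all__ = [
    "PlantParams",
    "SimResult",
    "simulate_gait",
    "joint_power",
    "cycle_energy",
    "compare_modes",
    "TORQUE_TO_ANGLE_SIGN",
    "CADENCE_SLOPE",
]

# plantar-flexion-positive torque -> dorsiflexion-positive angular acceleration
TORQUE_TO_ANGLE_SIGN = -1.0
# cycle duration model T = CADENCE_SLOPE / speed (1.44 s cycle at 3 km/h)
CADENCE_SLOPE = 4.32


@dataclass(frozen=True)
class PlantParams:
    """Synthetic human-ankle plant.

    FES recruitment is linear above the onset amplitude
    (``tau = gain * max(0, A - onset)``); the wearer's volitional torque is
    ``participation_alpha`` times the reference-torque profile plus
    band-limited noise, and its EMG correlate drives the stimulated-EMG
    synthesis so the estimation chain sees realistic inputs.
    """

    I_ankle: float = 0.05  # kg m^2, foot + orthosis
    passive_k: float = 3.0  # Nm/rad
    passive_c: float = 0.4  # Nm s/rad
    fes_gain_TA: float = 0.8  # Nm/mA above onset
    fes_gain_Sol: float = 0.8
    onset_TA: float = 10.0  # mA
    onset_Sol: float = 10.0
    participation_alpha: float = 0.5
    ground_peak_nm: float = 20.0  # dorsiflexing stance bump amplitude
    ground_window: tuple[float, float] = (10.0, 55.0)  # % cycle
    vol_noise_nm: float = 0.8  # band-limited volitional torque noise (at alpha=1)
    # wearer tracking impedance: a participating wearer also corrects the
    # joint toward their intended trajectory (stretch reflexes and
    # short-latency voluntary corrections); scaled by participation_alpha
    # and counted as volitional torque
    vol_track_k: float = 60.0  # Nm/rad
    vol_track_c: float = 1.0  # Nm s/rad
    foot_mass: float = 1.2  # kg
    com_distance: float = 0.08  # m
    fsr_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.I_ankle <= 0:
            raise ValueError("I_ankle must be positive")
        if min(self.fes_gain_TA, self.fes_gain_Sol) < 0:
            raise ValueError("FES gains must be nonnegative")
        if not 0.0 <= self.participation_alpha <= 1.0:
            raise ValueError("participation_alpha must be in [0, 1]")


@dataclass
class SimResult:
    """Synchronized simulation series and per-cycle energy aggregates.

    Torque series are plantar-flexion-positive; ``energy_*`` are net works
    per cycle in the angle-consistent frame (they satisfy
    ``energy_total = energy_pafo + energy_fes + energy_vol``) and
    ``consumption_*`` are the corresponding absolute-work integrals, the
    energy-consumption measure used for mode comparisons.
    """

    mode: str
    speed_kmh: float
    alpha: float
    seed: int
    dt: float
    t: np.ndarray = field(repr=False, default=None)
    phase: np.ndarray = field(repr=False, default=None)  # estimated, %
    phase_true: np.ndarray = field(repr=False, default=None)
    theta: np.ndarray = field(repr=False, default=None)  # rad
    theta_d: np.ndarray = field(repr=False, default=None)
    tau_pafo: np.ndarray = field(repr=False, default=None)
    tau_fes: np.ndarray = field(repr=False, default=None)
    tau_vol: np.ndarray = field(repr=False, default=None)
    tau_vol_mech: np.ndarray = field(repr=False, default=None)
    tau_vol_est: np.ndarray = field(repr=False, default=None)
    A_TA: np.ndarray = field(repr=False, default=None)
    A_Sol: np.ndarray = field(repr=False, default=None)
    r_v: np.ndarray = field(repr=False, default=None)
    k_d: np.ndarray = field(repr=False, default=None)
    cycle_bounds: list[tuple[int, int]] = field(default_factory=list)
    energy_pafo: np.ndarray = None
    energy_fes: np.ndarray = None
    energy_vol: np.ndarray = None
    energy_total: np.ndarray = None
    consumption_pafo: np.ndarray = None
    consumption_fes: np.ndarray = None

    @property
    def theta_dot(self) -> np.ndarray:
        return np.gradient(self.theta, self.dt)

    def device_consumption(self) -> float:
        """Mean per-cycle orthosis + FES energy consumption (J)."""
        return float(np.mean(self.consumption_pafo + self.consumption_fes))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "phase": self.phase,
                "theta_deg": np.rad2deg(self.theta),
                "theta_d_deg": np.rad2deg(self.theta_d),
                "tau_pafo": self.tau_pafo,
                "tau_fes": self.tau_fes,
                "tau_vol": self.tau_vol,
                "tau_vol_est": self.tau_vol_est,
                "A_TA": self.A_TA,
                "A_Sol": self.A_Sol,
                "r_v": self.r_v,
                "k_d": self.k_d,
            }
        )


def joint_power(tau: np.ndarray, theta_dot: np.ndarray) -> np.ndarray:
    """Instantaneous joint power, the elementwise torque-velocity product."""
    tau = np.asarray(tau, dtype=float)
    theta_dot = np.asarray(theta_dot, dtype=float)
    if tau.shape != theta_dot.shape:
        raise ValueError("series must be aligned")
    return tau * theta_dot


def cycle_energy(
    power: np.ndarray, cycle_bounds: list[tuple[int, int]], dt: float
) -> np.ndarray:
    """Trapezoidal time-integral of power over each cycle (J per cycle)."""
    power = np.asarray(power, dtype=float)
    out = []
    for start, stop in cycle_bounds:
        if not 0 <= start < stop <= len(power):
            raise ValueError("cycle boundaries outside series")
        out.append(np.trapezoid(power[start:stop], dx=dt))
    return np.asarray(out)


class _ChannelFilterState:
    """Streaming blanking + comb + envelope state for one EMG channel."""

    def __init__(self, cfg: FilterConfig, pulse_rate_hz: float):
        self.cfg = cfg
        self.prev_segment: np.ndarray | None = None
        self.envelope = 0.0
        # one-pole smoother at the low-pass cutoff, sampled at the pulse rate
        self.smooth_a = 1.0 - np.exp(
            -2.0 * np.pi * cfg.lowpass_cutoff_hz / pulse_rate_hz
        )

    def update(self, segment: np.ndarray) -> float:
        """Consume one inter-pulse segment (already blanked); returns the
        current volitional RMS-envelope estimate."""
        if self.prev_segment is not None:
            y = comb_filter(segment, self.prev_segment)
            raw = float(np.mean(np.abs(y))) * CASCADE_GAIN
            self.envelope += self.smooth_a * (raw - self.envelope)
        self.prev_segment = segment
        return self.envelope


def _linear_torque(env_ta: float, env_sol: float) -> float:
    """The recruitment-map torque the synthetic datasets are built on."""
    return TORQUE_GAIN_NM * (env_sol - env_ta)


def simulate_gait(
    mode: str,
    n_cycles: int,
    speed_kmh: float,
    plant: PlantParams,
    calib: coord.SubjectCalibration | None = None,
    dt: float = 1e-3,
    *,
    torque_model: CnnTorqueRegressor | None = None,
    gains: PDGains | None = None,
    reference_table: ReferenceTable | None = None,
    envelope_ta: EnvelopeModel | None = None,
    envelope_sol: EnvelopeModel | None = None,
    filter_cfg: FilterConfig | None = None,
    fes_rate_hz: float = 40.0,
    k_min: float = coord.K_MIN_DEFAULT,
    k_max: float = coord.K_MAX_DEFAULT,
    zeta: float = coord.ZETA_DEFAULT,
    damping_mode: str = "critical",
) -> SimResult:
    """Run one closed-loop gait experiment.

    ``torque_model`` is the trained EMG-torque regressor used both for the
    reference torque (from the reference EMG envelopes) and, in PFV mode,
    for the volitional torque estimated from the filtered EMG; when None,
    the analytic recruitment map the synthetic data are generated from is
    used directly, which is exact and fast.  The first cycle is treated as
    cold start and excluded from the per-cycle aggregates.
    """
    if mode not in ("PF", "PFV"):
        raise ValueError("mode must be 'PF' or 'PFV'")
    if n_cycles < 2:
        raise ValueError("need n_cycles >= 2 (first cycle is cold start)")
    if not 1.0 <= speed_kmh <= 5.0:
        raise ValueError("speed must be in [1, 5] km/h")
    calib = calib or coord.SubjectCalibration()
    gains = gains or PDGains(I=plant.I_ankle)
    table = reference_table or default_reference_table()
    env_ta_model = envelope_ta or default_envelope_model("TA")
    env_sol_model = envelope_sol or default_envelope_model("soleus")
    filter_cfg = filter_cfg or FilterConfig()

    T = CADENCE_SLOPE / speed_kmh
    n = int(round(n_cycles * T / dt))
    rate = 1.0 / dt
    rng = np.random.default_rng(plant.seed)

    # --- synthetic foot switches with ground-truth phase
    fsr = gen_fsr_traces(
        speed_kmh, n_cycles, noise=plant.fsr_noise, seed=plant.seed, rate=rate,
        cadence_slope=CADENCE_SLOPE,
    )
    n = len(fsr["t"])
    phase_true = fsr["phase"]
    calib_span = slice(0, min(int(T / dt), n))
    frames = np.column_stack(
        [fsr[c] for c in ("heel_medial", "heel_lateral", "toe_medial", "toe_lateral")]
    )
    detector = ContactDetector.from_calibration(frames[calib_span])
    tracker = GaitPhaseTracker()

    # --- reference grids at the commanded treadmill speed
    phase_grid = table.phase_grid
    env_ta_grid = np.asarray(emg_envelope(env_ta_model, speed_kmh, phase_grid % 100.0))
    env_sol_grid = np.asarray(
        emg_envelope(env_sol_model, speed_kmh, phase_grid % 100.0)
    )
    if torque_model is not None:
        carrier = carrier_window(torque_model.window_len)
        windows = (
            env_ta_grid[:, None, None] * carrier[0][None, None, :],
            env_sol_grid[:, None, None] * carrier[1][None, None, :],
        )
        batch = np.concatenate(windows, axis=1)
        tau_ref_grid = torque_model.predict(batch)
    else:
        tau_ref_grid = _linear_torque(env_ta_grid, env_sol_grid)
    k_ref_max = table.k_ref_max

    # --- volitional activity: the wearer reproduces an alpha-scaled version
    # of the healthy pattern.  Two consistent faces of the same effort:
    # the *EMG-visible* volitional torque on the isometric-equivalent scale
    # of the torque model (what the estimation chain should recover, and
    # what the coordinator compares against the reference torque), and the
    # *mechanical* feedforward torque on the dynamically consistent scale
    # of the reference trajectory table.
    alpha = plant.participation_alpha
    if alpha > 0:
        slow = bandlimited_noise(n, rate, rng, band=(0.3, 3.0))
        vol_noise = alpha * plant.vol_noise_nm * slow
    else:
        vol_noise = np.zeros(n)
    tau_vol_emg = alpha * np.interp(phase_true, phase_grid, tau_ref_grid) + vol_noise
    tau_vol_ff = alpha * np.interp(phase_true, phase_grid, table.tau_ref) + vol_noise
    theta_intent = np.interp(phase_true, phase_grid, table.theta_ref)

    # --- EMG carriers and M-wave template for the estimation chain
    emg_params = EmgSynthesisParams(seed=plant.seed)
    carriers = np.vstack(
        [bandlimited_noise(n, rate, rng), bandlimited_noise(n, rate, rng)]
    )
    floor = 0.01 * np.vstack(
        [bandlimited_noise(n, rate, rng), bandlimited_noise(n, rate, rng)]
    )
    emg = floor.copy()  # volitional modulation filled in step by step
    template = mwave_template(emg_params)
    pulse_period = int(round(rate / fes_rate_hz))
    blank_len = int(round(filter_cfg.blanking_ms * 1e-3 * rate))
    chan_state = [
        _ChannelFilterState(filter_cfg, fes_rate_hz),
        _ChannelFilterState(filter_cfg, fes_rate_hz),
    ]

    # --- ground reaction torque profile (dorsiflexing bump in stance)
    g_lo, g_hi = plant.ground_window
    g_center, g_half = 0.5 * (g_lo + g_hi), 0.5 * (g_hi - g_lo)
    ground_ang = plant.ground_peak_nm * _raised_cosine(phase_true, g_center, g_half)

    # --- state
    theta = float(table.theta_ref[0])
    theta_dot = 0.0
    theta_d = theta
    theta_d_dot = 0.0
    tau_v_hat = 0.0
    heel_prev = False
    mwave_drive = [0.0, 0.0]  # current per-channel M-wave scale (mV)

    out = {
        k: np.zeros(n)
        for k in (
            "phase theta theta_d tau_pafo tau_fes tau_vol tau_vol_mech "
            "tau_vol_est A_TA A_Sol r_v k_d".split()
        )
    }

    for i in range(n):
        t = i * dt
        # -- gait events
        heel, _toe = detector.update(
            FsrFrame(t, frames[i, 0], frames[i, 1], frames[i, 2], frames[i, 3])
        )
        if heel and not heel_prev:
            tracker.record_heel_strike(t)
        heel_prev = heel
        try:
            phase = tracker.phase(t)
        except ColdStartError:
            # hold reference playback at the nominal cadence until the
            # second heel strike defines a cycle
            phase = float(np.mod(100.0 * t / T, 100.0))

        # -- per-pulse stimulation + volitional estimation (PFV)
        if mode == "PFV" and i % pulse_period == 0 and i > 0:
            seg_lo = i - pulse_period + blank_len
            seg_hi = i
            for c in range(2):
                seg = emg[c, seg_lo:seg_hi].copy()
                # the M-wave outlasting the blanking window contaminates
                # the first part of the segment
                tail = template[min(blank_len, len(template)) :]
                m = min(len(tail), len(seg))
                seg[:m] += mwave_drive[c] * tail[:m]
                chan_state[c].update(seg)
            if i >= 2 * pulse_period:
                if torque_model is not None:
                    tau_v_hat = volitional_torque(
                        chan_state[0].envelope, chan_state[1].envelope, torque_model
                    ).tau
                else:
                    tau_v_hat = _linear_torque(
                        chan_state[0].envelope, chan_state[1].envelope
                    )

        # -- coordination
        tau_ref = float(np.interp(phase, phase_grid, tau_ref_grid))
        k_ref = float(np.interp(phase, phase_grid, table.k_ref))
        tau_v_ctrl = tau_v_hat if mode == "PFV" else 0.0
        co = coord.coordinate(
            tau_ref, tau_v_ctrl, k_ref, k_ref_max, calib,
            k_min=k_min, k_max=k_max, zeta=zeta,
            damping_mode=damping_mode, inertia=gains.I,
        )

        # -- update M-wave drive from the commanded amplitudes
        mwave_drive[0] = (
            max(co.A_TA - plant.onset_TA, 0.0) * emg_params.mwave_mv_per_ma
        )
        mwave_drive[1] = (
            max(co.A_Sol - plant.onset_Sol, 0.0) * emg_params.mwave_mv_per_ma
        )

        # -- torques (plantar-flexion-positive)
        tau_fes = plant.fes_gain_Sol * max(
            co.A_Sol - plant.onset_Sol, 0.0
        ) - plant.fes_gain_TA * max(co.A_TA - plant.onset_TA, 0.0)
        # mechanical wearer torque: feedforward intent plus tracking
        # corrections toward the intended trajectory
        tau_vol_mech = float(
            tau_vol_ff[i]
            + alpha
            * (
                plant.vol_track_k * (theta - theta_intent[i])
                + plant.vol_track_c * theta_dot
            )
        )
        tau_vol = float(tau_vol_emg[i])  # EMG-visible volitional torque
        emg[0, i] += max(-tau_vol, 0.0) / TORQUE_GAIN_NM * carriers[0, i]
        emg[1, i] += max(tau_vol, 0.0) / TORQUE_GAIN_NM * carriers[1, i]

        # angle-consistent frame for the dynamics
        s = TORQUE_TO_ANGLE_SIGN
        theta_ref = float(np.interp(phase, phase_grid, table.theta_ref))
        # the admittance sees the wearer's push against the cuff; the
        # ground reaction passes through the foot plate, not the load cell
        tau_ext_ang = s * tau_vol_mech

        setp = ImpedanceSetpoint(theta_ref=theta_ref, k_d=co.k_d, c_d=co.c_d)
        theta_d, theta_d_dot = desired_angle_step(
            theta_d, theta_d_dot, setp, tau_ext_ang, gains, dt
        )
        u = pd_control(theta - theta_d, theta_dot - theta_d_dot, gains)
        tau_pafo_ang = -u
        tau_passive_ang = -plant.passive_k * theta - plant.passive_c * theta_dot
        acc = (
            tau_pafo_ang
            + s * tau_fes
            + s * tau_vol_mech
            + tau_passive_ang
            + ground_ang[i]
        ) / plant.I_ankle
        theta_dot += dt * acc
        theta += dt * theta_dot
        if not np.isfinite(theta) or abs(theta) > 10.0:
            raise FloatingPointError("plant integration diverged")

        out["phase"][i] = phase
        out["theta"][i] = theta
        out["theta_d"][i] = theta_d
        out["tau_pafo"][i] = s * tau_pafo_ang  # report in muscle convention
        out["tau_fes"][i] = tau_fes
        out["tau_vol"][i] = tau_vol
        out["tau_vol_mech"][i] = tau_vol_mech
        out["tau_vol_est"][i] = tau_v_ctrl
        out["A_TA"][i] = co.A_TA
        out["A_Sol"][i] = co.A_Sol
        out["r_v"][i] = co.r_v
        out["k_d"][i] = co.k_d

    # --- per-cycle aggregates (first cycle discarded as cold start)
    strikes = np.asarray(tracker.strikes)
    idx = np.clip((strikes / dt).round().astype(int), 0, n - 1)
    # cycle boundaries: strike-to-strike, the trace end closing the last
    # cycle; the segment before the second strike is the cold start
    edges = list(idx[1:]) + [n]
    bounds = [
        (edges[j], edges[j + 1])
        for j in range(len(edges) - 1)
        if edges[j + 1] > edges[j]
    ]
    theta_dot_series = np.gradient(out["theta"], dt)
    s = TORQUE_TO_ANGLE_SIGN
    p_pafo = joint_power(s * out["tau_pafo"], theta_dot_series)
    p_fes = joint_power(s * out["tau_fes"], theta_dot_series)
    p_vol = joint_power(s * out["tau_vol"], theta_dot_series)

    result = SimResult(
        mode=mode, speed_kmh=speed_kmh, alpha=alpha, seed=plant.seed, dt=dt,
        t=fsr["t"], phase=out["phase"], phase_true=phase_true,
        theta=out["theta"], theta_d=out["theta_d"],
        tau_pafo=out["tau_pafo"], tau_fes=out["tau_fes"], tau_vol=out["tau_vol"],
        tau_vol_mech=out["tau_vol_mech"],
        tau_vol_est=out["tau_vol_est"], A_TA=out["A_TA"], A_Sol=out["A_Sol"],
        r_v=out["r_v"], k_d=out["k_d"], cycle_bounds=bounds,
    )
    result.energy_pafo = cycle_energy(p_pafo, bounds, dt)
    result.energy_fes = cycle_energy(p_fes, bounds, dt)
    result.energy_vol = cycle_energy(p_vol, bounds, dt)
    result.energy_total = (
        result.energy_pafo + result.energy_fes + result.energy_vol
    )
    result.consumption_pafo = cycle_energy(np.abs(p_pafo), bounds, dt)
    result.consumption_fes = cycle_energy(np.abs(p_fes), bounds, dt)
    return result


def compare_modes(
    results_pf: "SimResult | list[SimResult]",
    results_pfv: "SimResult | list[SimResult]",
) -> dict:
    """Per-source energy summary and paired test across matched runs.

    Both inputs must come from matched seeds and speeds.  Returns means and
    standard deviations of the per-cycle energy consumption by source and
    a paired two-sided t-test on the per-run device (orthosis + FES)
    consumption; identical inputs give difference 0 and p = 1.
    """
    pf = [results_pf] if isinstance(results_pf, SimResult) else list(results_pf)
    pfv = [results_pfv] if isinstance(results_pfv, SimResult) else list(results_pfv)
    if len(pf) != len(pfv):
        raise ValueError("need matched PF/PFV run lists")
    for a, b in zip(pf, pfv, strict=True):
        if a.seed != b.seed or a.speed_kmh != b.speed_kmh:
            raise ValueError("PF/PFV runs must be matched in seed and speed")

    def _agg(runs, attr):
        vals = [float(np.mean(getattr(r, attr))) for r in runs]
        return {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}

    dev_pf = np.array([r.device_consumption() for r in pf])
    dev_pfv = np.array([r.device_consumption() for r in pfv])
    diff = dev_pfv - dev_pf
    if np.allclose(diff, 0.0):
        p_value = 1.0
    elif len(diff) < 2:
        p_value = float("nan")
    else:
        p_value = float(stats.ttest_rel(dev_pfv, dev_pf).pvalue)
    return {
        "n_runs": len(pf),
        "device_consumption_pf": {"mean": float(dev_pf.mean()), "sd": float(dev_pf.std())},
        "device_consumption_pfv": {"mean": float(dev_pfv.mean()), "sd": float(dev_pfv.std())},
        "consumption_pafo_pf": _agg(pf, "consumption_pafo"),
        "consumption_pafo_pfv": _agg(pfv, "consumption_pafo"),
        "consumption_fes_pf": _agg(pf, "consumption_fes"),
        "consumption_fes_pfv": _agg(pfv, "consumption_fes"),
        "energy_total_pf": _agg(pf, "energy_total"),
        "energy_total_pfv": _agg(pfv, "energy_total"),
        "energy_vol_pfv": _agg(pfv, "energy_vol"),
        "paired_p_value": p_value,
    }
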