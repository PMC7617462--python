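"""Synthetic EEG/EMG cohort generator.

Emulates a posture-holding / perturbation-resisting manipulandum task:
each participant performs blocks of trials with phases Ready -> Steady ->
Go (reach) -> Relax under three force conditions (F0 no perturbation,
F1 weak, F2 strong pulsed perturbation).  Five channels are produced --
one cortical source ("CTX") and four bipolar forearm EMGs -- containing
a 1/f background, a narrow-band beta carrier with transient cortical
beta bursts, a gamma component, and condition-dependent burst-locked
phase coupling between the cortical beta phase and each EMG's beta
component.

The coupling mechanism is a shared beta carrier plus von-Mises phase
jitter: within cortical bursts in condition F0 the cortex->EMG phase
offset is drawn with concentration kappa > 0, so the expected
within-burst phase-locking value has the closed form I1(kappa)/I0(kappa)
(the von-Mises resultant), which parameter-recovery tests exploit.
Everything is deterministic given a seed, and every injected burst is
returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import i0e, i1e

__all__ = [
    "TaskConfig",
    "CouplingSpec",
    "TrialSchedule",
    "GroundTruth",
    "Recording",
    "generate_schedule",
    "generate_kinematics",
    "generate_signals",
    "generate_participant",
    "vonmises_plv",
    "fast_task_config",
    "fast_coupling_spec",
    "CHANNEL_ROLES",
]

CHANNEL_ROLES = ("CTX", "FLX1", "FLX2", "EXT1", "EXT2")
EMG_ROLES = CHANNEL_ROLES[1:]


class ConfigurationError(ValueError):
    """Raised when a task or coupling configuration is inconsistent."""


class GenerationError(RuntimeError):
    """Raised when signals cannot be generated under the requested spec."""


@dataclass(frozen=True)
class TaskConfig:
    """Task paradigm layout.

    Defaults mirror the full experiment: 10 blocks of 36 trials, 12
    trials per force condition per block, 2 s Ready, 4-5 s (uniform)
    Steady, a cued reach, 4-5 s Relax, sampled at 2048 Hz with pulsed
    perturbations every 100 ms in F1/F2.
    """

    n_blocks: int = 10
    trials_per_block: int = 36
    conditions: tuple[str, ...] = ("F0", "F1", "F2")
    trials_per_condition_per_block: int = 12
    ready_s: float = 2.0
    steady_s: tuple[float, float] = (4.0, 5.0)
    relax_s: tuple[float, float] = (4.0, 5.0)
    reach_latency_s: float = 0.25
    reach_move_s: float = 0.7
    return_s: float = 0.6
    fs: float = 2048.0
    perturbation_period_s: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_block != self.trials_per_condition_per_block * len(self.conditions):
            raise ConfigurationError(
                "trials_per_block must equal trials_per_condition_per_block x n_conditions "
                f"({self.trials_per_block} != {self.trials_per_condition_per_block} x {len(self.conditions)})"
            )
        for name in ("ready_s", "reach_latency_s", "reach_move_s", "return_s", "fs", "perturbation_period_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("steady_s", "relax_s"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"{name} must be a positive, ordered interval")
        # analysis runs up to 100 Hz; demand comfortable sampling headroom
        if self.fs < 4 * 100:
            raise ConfigurationError("fs must be at least 4x the highest analysed frequency (100 Hz)")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class CouplingSpec:
    """Signal-content parameters of the generator.

    Burst rates / durations / counts loosely follow the real cohort
    (about 0.41 bursts/s and 231 ms mean duration in F0, slightly fewer
    and shorter under perturbation).  ``kappa_burst`` controls the
    burst-locked cortex->EMG phase coupling per condition: positive in
    F0 only by default, so burst-aligned PLV rises above the no-burst
    level during static posture holding and nowhere else.
    """

    burst_rate: dict = field(default_factory=lambda: {"F0": 0.41, "F1": 0.30, "F2": 0.31})
    burst_duration_median_s: dict = field(default_factory=lambda: {"F0": 0.20, "F1": 0.175, "F2": 0.18})
    burst_duration_sigma: float = 0.4
    burst_duration_range_s: tuple[float, float] = (0.05, 0.6)
    burst_gain: dict = field(default_factory=lambda: {"F0": 3.0, "F1": 2.7, "F2": 2.8})
    kappa_burst: dict = field(default_factory=lambda: {"F0": 8.0, "F1": 0.0, "F2": 0.0})
    kappa_background: float = 0.0
    emg_gain: dict = field(default_factory=lambda: {"F0": 1.0, "F1": 2.0, "F2": 3.0})
    line_noise_amp: float = 0.1
    noise_exponent: float = 1.0
    pink_amp: float = 1.0
    beta_freq_hz: float = 22.0
    beta_linewidth_hz: float = 3.0
    beta_amp: float = 1.0
    beta_am_sigma: float = 0.5
    beta_am_bandwidth_hz: float = 0.7
    gamma_freq_hz: float = 70.0
    gamma_linewidth_hz: float = 8.0
    gamma_amp: float = 0.3
    emg_noise_amp: float = 1.0
    emg_beta_amp: float = 0.5
    emg_band_hz: tuple[float, float] = (20.0, 450.0)
    burst_ramp_s: float = 0.02
    # kinematics (metres)
    hold_wobble_m: float = 0.0015
    pulse_disp_m: dict = field(default_factory=lambda: {"F0": 0.0, "F1": 0.004, "F2": 0.008})
    reach_distance_m: float = 0.12
    kin_fs: float = 1000.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.kappa_burst.values()) or self.kappa_background < 0:
            raise ConfigurationError("kappa must be >= 0")
        if any(v <= 0 for v in self.emg_gain.values()):
            raise ConfigurationError("emg gains must be > 0")
        lo, hi = self.burst_duration_range_s
        if not (0 < lo < hi):
            raise ConfigurationError("burst duration range must be positive and ordered")


@dataclass
class TrialSchedule:
    """Per-trial layout; times in seconds relative to the trial's block start."""

    trials: pd.DataFrame  # trial, block, condition, direction, t_ready, t_steady, t_go, t_target, t_relax, t_end

    def block(self, b: int) -> pd.DataFrame:
        return self.trials[self.trials["block"] == b]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class GroundTruth:
    """Everything injected: burst intervals, per-sample coupling state, target PLV."""

    bursts: pd.DataFrame  # block, condition, trial, onset_s, offset_s, gain
    coupling_kappa: dict  # block -> per-sample kappa array (cortex->EMG coupling state)
    target_plv: dict  # condition -> I1(kappa)/I0(kappa) within bursts


@dataclass
class Recording:
    """One block of multichannel data."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    roles: tuple[str, ...]
    events: pd.DataFrame  # trial rows of this block
    block: int

    def channel(self, role: str) -> np.ndarray:
        return self.data[self.roles.index(role)]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def vonmises_plv(kappa: float) -> float:
    """Expected resultant length of a von-Mises sample: I1(kappa)/I0(kappa)."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    return float(i1e(kappa) / i0e(kappa))  # scaled Bessels: stable for large kappa


def fast_task_config(**overrides) -> TaskConfig:
    """Small preset for tests and demos: fs=512, 2 short blocks."""
    base = dict(
        n_blocks=2,
        trials_per_block=9,
        trials_per_condition_per_block=3,
        ready_s=0.8,
        steady_s=(3.6, 4.2),
        relax_s=(0.8, 1.2),
        reach_latency_s=0.25,
        reach_move_s=0.6,
        return_s=0.4,
        fs=512.0,
    )
    base.update(overrides)
    return TaskConfig(**base)


def fast_coupling_spec(**overrides) -> CouplingSpec:
    """Coupling preset matched to the fast task config (denser bursts)."""
    base = dict(
        burst_rate={"F0": 0.5, "F1": 0.38, "F2": 0.38},
        line_noise_amp=0.0,
        emg_band_hz=(20.0, 230.0),
    )
    base.update(overrides)
    return CouplingSpec(**base)


# ---------------------------------------------------------------------------
# schedule


def generate_schedule(cfg: TaskConfig, seed: int | None = None) -> TrialSchedule:
    """Randomise condition order (balanced within block) and phase onsets.

    Reach directions alternate within each block's per-condition trials so
    they are balanced overall.
    """
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    rows = []
    trial_idx = 0
    for b in range(cfg.n_blocks):
        conds = np.repeat(cfg.conditions, cfg.trials_per_condition_per_block)
        rng.shuffle(conds)
        # balanced directions per condition within the block
        dir_pools = {
            c: rng.permutation(
                ["left", "right"] * ((cfg.trials_per_condition_per_block + 1) // 2)
            )[: cfg.trials_per_condition_per_block].tolist()
            for c in cfg.conditions
        }
        t = 0.0
        for c in conds:
            steady = rng.uniform(*cfg.steady_s)
            relax = rng.uniform(*cfg.relax_s)
            t_ready = t
            t_steady = t_ready + cfg.ready_s
            t_go = t_steady + steady
            t_target = t_go + cfg.reach_latency_s + cfg.reach_move_s
            t_relax = t_target + cfg.return_s
            t_end = t_relax + relax
            rows.append(
                dict(
                    trial=trial_idx,
                    block=b,
                    condition=c,
                    direction=dir_pools[c].pop(),
                    t_ready=t_ready,
                    t_steady=t_steady,
                    t_go=t_go,
                    t_target=t_target,
                    t_relax=t_relax,
                    t_end=t_end,
                )
            )
            trial_idx += 1
            t = t_end
    return TrialSchedule(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# kinematics


def _minimum_jerk(s: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile on s in [0, 1]."""
    s = np.clip(s, 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def minimum_jerk_fraction_time(fraction: float) -> float:
    """Normalised time at which the minimum-jerk profile covers `fraction` of the distance."""
    grid = np.linspace(0, 1, 200001)
    return float(grid[np.searchsorted(_minimum_jerk(grid), fraction)])


def _pulse_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random pulse angles whose quadrant never repeats more than twice in a row."""
    quads = np.empty(n, dtype=int)
    run = 0
    for i in range(n):
        while True:
            q = rng.integers(0, 4)
            if i >= 1 and q == quads[i - 1]:
                if run >= 2:
                    continue
                run += 1
            else:
                run = 1
            quads[i] = q
            break
    return quads * (np.pi / 2) + rng.uniform(0, np.pi / 2, size=n)


def generate_kinematics(
    schedule: TrialSchedule, cfg: TaskConfig, spec: CouplingSpec, seed: int = 0
) -> pd.DataFrame:
    """Manipulandum x/y position and velocity traces, 1 kHz by default.

    Steady phase: small hold wobble around the centre plus, in F1/F2,
    a damped displacement response to each perturbation pulse (one per
    ``perturbation_period_s``, amplitude scaled by force level), giving
    the pulse-train structure at 1/period in the velocity spectrum.
    Reach phase: minimum-jerk profile toward the cued direction.
    """
    rng = np.random.default_rng(seed)
    fs = spec.kin_fs
    dt = 1.0 / fs
    out = []
    for row in schedule.trials.itertuples():
        n = int(round((row.t_end - row.t_ready) * fs))
        t = np.arange(n) * dt  # trial-local time
        x = np.zeros(n)
        y = np.zeros(n)
        # hold wobble: smoothed Gaussian walk, present throughout pre-reach
        wob = rng.standard_normal((2, n))
        win = max(int(0.15 * fs), 1)
        kern = np.hanning(win)
        kern /= kern.sum()
        wob = np.stack([np.convolve(w, kern, mode="same") for w in wob])
        wob *= spec.hold_wobble_m / max(np.sqrt(np.mean(wob**2)), 1e-12)
        x += wob[0]
        y += wob[1]

        steady0 = row.t_steady - row.t_ready
        go = row.t_go - row.t_ready
        amp = spec.pulse_disp_m.get(row.condition, 0.0)
        if amp > 0:
            pulses = np.arange(steady0, go, cfg.perturbation_period_s)
            angles = _pulse_directions(len(pulses), rng)
            tau = 0.05  # damped response time constant (s); long enough that
            # successive 100 ms pulses overlap and the speed trace oscillates
            # at the pulse rate rather than at its first harmonic
            kern_t = np.arange(0, 6 * tau, dt)
            resp = (kern_t / tau) * np.exp(1 - kern_t / tau)
            for tp, ang in zip(pulses, angles):
                i0_ = int(round(tp * fs))
                sl = slice(i0_, min(i0_ + len(resp), n))
                seg = resp[: sl.stop - sl.start] * amp
                x[sl] += seg * np.cos(ang)
                y[sl] += seg * np.sin(ang)

        # reach: latency then minimum jerk to target, then return
        lat = go + cfg.reach_latency_s
        sgn = 1.0 if row.direction == "right" else -1.0
        s = (t - lat) / cfg.reach_move_s
        reach = _minimum_jerk(s) * spec.reach_distance_m * sgn
        ret_start = lat + cfg.reach_move_s
        s_ret = (t - ret_start) / cfg.return_s
        reach -= _minimum_jerk(s_ret) * spec.reach_distance_m * sgn
        x += reach

        vx = np.gradient(x, dt)
        vy = np.gradient(y, dt)
        phase = np.full(n, "ready", dtype=object)
        phase[t >= steady0] = "steady"
        phase[t >= go] = "reach"
        phase[t >= (row.t_relax - row.t_ready)] = "relax"
        out.append(
            pd.DataFrame(
                dict(
                    trial=row.trial,
                    block=row.block,
                    condition=row.condition,
                    t=t + row.t_ready,
                    x=x,
                    y=y,
                    vx=vx,
                    vy=vy,
                    speed=np.hypot(vx, vy),
                    phase=phase,
                )
            )
        )
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# signals


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent Gaussian noise, unit variance."""
    freqs = np.fft.rfftfreq(n)
    spec_amp = np.ones_like(freqs)
    nz = freqs > 0
    spec_amp[nz] = freqs[nz] ** (-exponent / 2)
    spec_amp[0] = 0.0
    coef = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) * spec_amp
    x = np.fft.irfft(coef, n=n)
    return x / x.std()


def _carrier_phase(n: int, fs: float, f0: float, linewidth: float, rng: np.random.Generator) -> np.ndarray:
    """Phase of a narrow-band carrier: linear phase plus a Wiener process
    whose diffusion gives a Lorentzian linewidth of about `linewidth` Hz."""
    step_sd = np.sqrt(2 * np.pi * linewidth / fs)
    return 2 * np.pi * f0 * np.arange(n) / fs + np.cumsum(rng.standard_normal(n) * step_sd)


def _smooth_mask(mask: np.ndarray, fs: float, ramp_s: float) -> np.ndarray:
    if ramp_s <= 0:
        return mask.astype(float)
    win = max(int(round(ramp_s * fs)), 1)
    kern = np.hanning(2 * win + 1)
    kern /= kern.sum()
    return np.convolve(mask.astype(float), kern, mode="same")


def _place_bursts(
    events: pd.DataFrame, spec: CouplingSpec, rng: np.random.Generator
) -> list[tuple[float, float, str, int, float]]:
    """Poisson burst placement within Steady phases; overlapping draws are
    re-drawn a bounded number of times, then dropped."""
    placed: list[tuple[float, float, str, int, float]] = []
    for row in events.itertuples():
        cond = row.condition
        rate = spec.burst_rate[cond]
        t0, t1 = row.t_steady, row.t_go
        n_ev = rng.poisson(rate * (t1 - t0))
        lo, hi = spec.burst_duration_range_s
        mu = np.log(spec.burst_duration_median_s[cond])
        intervals: list[tuple[float, float]] = []
        for _ in range(n_ev):
            for _attempt in range(20):
                dur = float(np.clip(np.exp(rng.normal(mu, spec.burst_duration_sigma)), lo, hi))
                if dur >= t1 - t0:
                    continue
                onset = rng.uniform(t0, t1 - dur)
                if all(onset >= b or onset + dur <= a for a, b in intervals):
                    intervals.append((onset, onset + dur))
                    break
        for a, b in sorted(intervals):
            placed.append((a, b, cond, row.trial, spec.burst_gain[cond]))
    return placed


def _burst_offsets(
    n: int,
    fs: float,
    bursts: list,
    spec: "CouplingSpec",
    cond_steady: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-burst constant von-Mises phase offsets for one EMG channel.

    Each coupled burst is one communication event: the EMG's beta phase
    locks to the cortical carrier at a fixed offset drawn with the
    condition's concentration kappa, so the expected resultant across
    bursts is I1(kappa)/I0(kappa).  Zero elsewhere (unused: uncoupled
    segments run an independent oscillator).
    """
    theta = np.zeros(n)
    for a, b, cond, _trial, _g in bursts:
        k = spec.kappa_burst.get(cond, 0.0)
        if k <= 0:
            continue
        draw = rng.vonmises(0.0, k)
        theta[int(round(a * fs)) : int(round(b * fs))] = draw
    return theta


def generate_signals(
    schedule: TrialSchedule, cfg: TaskConfig, spec: CouplingSpec, seed: int = 0
) -> tuple[list[Recording], GroundTruth]:
    """Generate one participant's blocks of 5-channel data plus ground truth.

    Cortex = 1/f background + beta carrier (envelope raised by
    ``burst_gain`` inside injected bursts) + gamma carrier + optional
    50 Hz line noise.  Each EMG = condition-scaled broadband noise +
    a beta component sharing the cortical carrier phase with von-Mises
    jitter (concentration kappa depends on condition and in-burst state).
    """
    rng = np.random.default_rng(seed)
    fs = cfg.fs
    recordings: list[Recording] = []
    burst_rows = []
    kappa_state: dict[int, np.ndarray] = {}

    for b in range(cfg.n_blocks):
        events = schedule.block(b)
        n = int(round(events["t_end"].max() * fs))
        t = np.arange(n) / fs

        # condition per sample (empty string outside steady phases)
        cond_steady = np.full(n, "", dtype=object)
        for row in events.itertuples():
            i0_, i1_ = int(row.t_steady * fs), int(row.t_go * fs)
            cond_steady[i0_:i1_] = row.condition

        for cond in cfg.conditions:
            if spec.burst_rate[cond] * spec.burst_duration_median_s[cond] > 0.9:
                raise GenerationError(
                    f"burst rate for {cond} cannot be placed disjointly "
                    "(requested occupancy > 90% of Steady time)"
                )
        bursts = _place_bursts(events, spec, rng)
        # occupancy guard: percentile-based detection needs headroom
        occ = sum(b2 - a2 for a2, b2, *_ in bursts) / max(events["t_go"].sub(events["t_steady"]).sum(), 1e-9)
        if occ > 0.9:
            raise GenerationError("requested burst rate leaves no sub-threshold time")

        gain = np.ones(n)
        in_burst = np.zeros(n, dtype=bool)
        for a, b2, cond, trial, g in bursts:
            i0_, i1_ = int(round(a * fs)), int(round(b2 * fs))
            gain[i0_:i1_] = g
            in_burst[i0_:i1_] = True
            burst_rows.append(
                dict(block=b, condition=cond, trial=trial, onset_s=a, offset_s=b2, gain=g)
            )
        # slow lognormal amplitude modulation of the baseline carrier: real
        # beta amplitude waxes and wanes, which keeps detected bursts ~2 SD
        # events (not artifact-scale outliers) and creates sub-median dips
        if spec.beta_am_sigma > 0:
            sos_am = sps.butter(2, spec.beta_am_bandwidth_hz, btype="lowpass", fs=fs, output="sos")
            am = sps.sosfiltfilt(sos_am, rng.standard_normal(n))
            am = np.exp(spec.beta_am_sigma * am / max(am.std(), 1e-12))
        else:
            am = 1.0
        env = spec.beta_amp * (am + _smooth_mask(gain - 1.0, fs, spec.burst_ramp_s))

        phi_beta = _carrier_phase(n, fs, spec.beta_freq_hz, spec.beta_linewidth_hz, rng)
        phi_gamma = _carrier_phase(n, fs, spec.gamma_freq_hz, spec.gamma_linewidth_hz, rng)
        line = spec.line_noise_amp * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))

        ctx = (
            spec.pink_amp * _pink_noise(n, spec.noise_exponent, rng)
            + env * np.cos(phi_beta)
            + spec.gamma_amp * np.cos(phi_gamma)
            + line
        )

        # per-sample cortex->EMG coupling concentration
        kappa = np.full(n, spec.kappa_background)
        for cond in cfg.conditions:
            m = in_burst & (cond_steady == cond)
            kappa[m] = spec.kappa_burst[cond]
        kappa_state[b] = kappa

        # per-sample EMG gain from the condition of the ongoing steady phase
        g_emg = np.ones(n)
        for cond in cfg.conditions:
            g_emg[cond_steady == cond] = spec.emg_gain[cond]
        g_emg = _smooth_mask(g_emg - 1.0, fs, 0.05) + 1.0

        hi_edge = min(spec.emg_band_hz[1], 0.45 * fs)
        sos = sps.butter(4, [spec.emg_band_hz[0], hi_edge], btype="bandpass", fs=fs, output="sos")

        # coupling weight: 1 inside coupled (kappa>0) bursts, 0 elsewhere.
        # Outside coupled intervals each EMG runs its own beta oscillator,
        # so the cross-channel phase difference drifts and the no-burst PLV
        # sits at the null level; inside, the EMG beta phase tracks the
        # cortical carrier with von-Mises jitter of concentration kappa.
        w = _smooth_mask(kappa > 0, fs, 0.03)
        data = np.empty((len(CHANNEL_ROLES), n))
        data[0] = ctx
        for j in range(len(EMG_ROLES)):
            theta = _burst_offsets(n, fs, bursts, spec, cond_steady, rng)
            phi_own = _carrier_phase(n, fs, spec.beta_freq_hz, spec.beta_linewidth_hz, rng)
            z = (1.0 - w) * np.exp(1j * phi_own) + w * np.exp(1j * (phi_beta + theta))
            noise = sps.sosfiltfilt(sos, rng.standard_normal(n))
            noise /= max(noise.std(), 1e-12)
            emg = g_emg * (
                spec.emg_noise_amp * noise + spec.emg_beta_amp * z.real
            )
            data[1 + j] = emg + line
        recordings.append(
            Recording(data=data, fs=fs, roles=CHANNEL_ROLES, events=events.reset_index(drop=True), block=b)
        )

    gt = GroundTruth(
        bursts=pd.DataFrame(
            burst_rows, columns=["block", "condition", "trial", "onset_s", "offset_s", "gain"]
        ),
        coupling_kappa=kappa_state,
        target_plv={c: vonmises_plv(spec.kappa_burst[c]) for c in cfg.conditions},
    )
    return recordings, gt


def generate_participant(
    cfg: TaskConfig, spec: CouplingSpec, seed: int
) -> tuple[TrialSchedule, list[Recording], GroundTruth]:
    """Schedule + signals for one participant, all derived from one seed."""
    ss = np.random.SeedSequence(seed)
    s_sched, s_sig = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    schedule = generate_schedule(cfg, seed=s_sched)
    recs, gt = generate_signals(schedule, cfg, spec, seed=s_sig)
    return schedule, recs, gt
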