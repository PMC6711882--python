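"""Synthetic probe-scheduled EEG sessions with known mind-wandering structure.

The generator emulates the experience-sampling design the analysis assumes:
blocks of SART (go/no-go, 135 trials/block) or visual search (140
trials/block) trials, 54 thought probes per task separated by 7-24 trials,
and a latent attentional state (on-task vs mind-wandering) that is constant
over the six trials preceding each probe and is reported through a 6-option
probe response (1-2 on-task, 3/5 mind-wandering, 4/6 neither).

Each epoch is a sum of

* Mexican-hat shaped ERP components (P1, N1, P3) whose per-trial amplitude is
  drawn around a state-dependent mean with latency jitter — during
  mind-wandering all three are attenuated (perceptual/cognitive decoupling);
* an alpha oscillation whose amplitude is larger during mind-wandering, and a
  theta oscillation whose phase difference across the parietal-occipital
  A19-A10 pair follows a circular diffusion with a von Mises stationary law —
  concentration kappa is larger (tighter coupling) during mind-wandering;
* 1/f pink background noise.

All randomness flows from explicit seeds; a given (parameters, seed) pair is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CHANNELS, EpochSet, default_time_axis
from .sterp import mexican_hat

__all__ = [
    "ON_TASK", "MIND_WANDERING", "TaskDesign", "build_design", "ProbeEvent",
    "GenParams", "ErpComponent", "BehaviorParams", "simulate_states",
    "synthesize_epochs", "simulate_behavior", "simulate_session", "pink_noise",
]

ON_TASK = "on_task"
MIND_WANDERING = "mind_wandering"

TRIALS_PER_BLOCK = {"SART": 135, "VS": 140}

#: probe responses by meaning: 1 concentrated, 2 evaluating the task
#: (on-task); 3 personal matters, 5 daydreaming (mind-wandering);
#: 4 external distraction, 6 blank (excluded)
ON_TASK_RESPONSES = (1, 2)
MW_RESPONSES = (3, 5)
EXCLUDED_RESPONSES = (4, 6)

#: number of pre-probe trials that inherit the probe's reported state
PROBE_WINDOW = 6


# ---------------------------------------------------------------------------
# task design / probe schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskDesign:
    """Session layout for one task: blocks, trials, and the probe schedule."""

    task: str
    n_blocks: int
    trials_per_block: int
    probe_gaps: tuple[int, int]
    n_probes: int
    fs: float
    epoch_window: tuple[float, float]          # (pre_ms, post_ms)
    probe_positions: tuple[int, ...] = ()      # trial index preceding each probe

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def validate(self) -> list[str]:
        """Return invariant violations (empty list means valid)."""
        v = []
        if self.task not in TRIALS_PER_BLOCK:
            v.append(f"unknown task {self.task!r}")
        elif self.trials_per_block != TRIALS_PER_BLOCK[self.task]:
            v.append(f"{self.task} must have {TRIALS_PER_BLOCK[self.task]} "
                     f"trials per block, got {self.trials_per_block}")
        if not (7 <= self.probe_gaps[0] <= self.probe_gaps[1] <= 24):
            v.append(f"probe gaps {self.probe_gaps} outside [7, 24]")
        if abs(self.epoch_window[0] + self.epoch_window[1] - 1600.0) > 1e-9:
            v.append("epoch length must be 1600 ms")
        pos = np.asarray(self.probe_positions)
        if pos.size:
            if pos.size != self.n_probes:
                v.append("probe count mismatch")
            gaps = np.diff(np.concatenate([[-1], pos]))
            if np.any(gaps < 7):
                v.append("probe positions closer than 7 trials")
            if pos[-1] >= self.n_trials:
                v.append("probe position beyond session")
        return v


def build_design(task: str, *, n_blocks: int = 12,
                 probe_gaps: tuple[int, int] = (7, 24), n_probes: int = 54,
                 fs: float = 256.0, epoch_window: tuple[float, float] = (400.0, 1200.0),
                 seed: int | np.random.Generator = 0) -> TaskDesign:
    """Build a task design with a randomized, feasible probe schedule.

    Gaps between consecutive probes (and before the first probe) are drawn
    uniformly from ``probe_gaps``, constrained so the remaining probes always
    fit in the session; an infeasible configuration raises.
    """
    if task not in TRIALS_PER_BLOCK:
        raise ValueError(f"unknown task {task!r}; expected one of {list(TRIALS_PER_BLOCK)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g_lo, g_hi = probe_gaps
    n_trials = n_blocks * TRIALS_PER_BLOCK[task]
    if n_probes * g_lo > n_trials:
        raise ValueError(f"{n_probes} probes with min gap {g_lo} do not fit "
                         f"in {n_trials} trials")
    positions = []
    prev = -1
    for k in range(n_probes):
        remaining = n_probes - k - 1
        hi = min(g_hi, n_trials - 1 - prev - remaining * g_lo)
        if hi < g_lo:
            raise ValueError("probe schedule infeasible")
        gap = int(rng.integers(g_lo, hi + 1))
        prev += gap
        positions.append(prev)
    return TaskDesign(task=task, n_blocks=n_blocks,
                      trials_per_block=TRIALS_PER_BLOCK[task],
                      probe_gaps=probe_gaps, n_probes=n_probes, fs=fs,
                      epoch_window=epoch_window, probe_positions=tuple(positions))


@dataclass(frozen=True)
class ProbeEvent:
    """One thought probe: its index, the trial it follows, and the response."""

    probe_index: int
    trial_index: int          # trial immediately preceding the probe screen
    response: int             # 1..6
    state: str = ""           # generator ground truth (convenience)

    def __post_init__(self):
        if self.response not in range(1, 7):
            raise ValueError(f"probe response {self.response} outside 1..6")


# ---------------------------------------------------------------------------
# generative parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErpComponent:
    """Template parameters for one embedded ERP component."""

    name: str
    channels: tuple[str, ...]
    latency_ms: float
    latency_jitter_sd_ms: float
    scale_ms: float
    amp: dict            # state -> mean amplitude, microvolts (signed)
    amp_sd: float        # trial-to-trial amplitude sd


def _default_components() -> tuple[ErpComponent, ...]:
    return (
        ErpComponent("P1", ("A10", "B7"), 120.0, 15.0, 100.0,
                     {ON_TASK: 3.0, MIND_WANDERING: 2.4}, 1.0),
        ErpComponent("N1", ("A10", "B7"), 200.0, 15.0, 120.0,
                     {ON_TASK: -3.0, MIND_WANDERING: -2.4}, 1.0),
        ErpComponent("P3", ("A19",), 450.0, 20.0, 400.0,
                     {ON_TASK: 5.0, MIND_WANDERING: 4.0}, 1.5),
    )


@dataclass(frozen=True)
class GenParams:
    """Generator parameters; defaults encode the emulated state effects.

    Mind-wandering trials have attenuated P1/N1/P3, elevated alpha power, and
    tighter theta phase coupling on the A19-A10 pair; theta amplitude itself
    carries no state effect. ``mw_rate`` is the probability that a probe finds
    the subject mind-wandering; ``leak_prob`` the probability that a report
    falls into the excluded categories (external distraction / blank).
    """

    mw_rate: float = 0.38
    leak_prob: float = 0.16
    components: tuple[ErpComponent, ...] = field(default_factory=_default_components)
    alpha_freq_hz: float = 10.25
    alpha_amp: dict = field(default_factory=lambda: {ON_TASK: 1.5, MIND_WANDERING: 2.1})
    alpha_cv: float = 0.3
    alpha_weights: dict = field(default_factory=lambda: {
        "A10": 1.0, "B7": 1.0, "A19": 0.8, "C21": 0.5})
    theta_freq_hz: float = 6.0
    theta_amp: dict = field(default_factory=lambda: {ON_TASK: 2.2, MIND_WANDERING: 2.2})
    theta_cv: float = 0.3
    theta_weights: dict = field(default_factory=lambda: {
        "A10": 0.8, "B7": 0.8, "A19": 1.0, "C21": 1.0})
    #: coupled pair -> state -> von Mises concentration of the phase offset
    theta_coupling_kappa: dict = field(default_factory=lambda: {
        ("A19", "A10"): {ON_TASK: 0.3, MIND_WANDERING: 3.0}})
    coupling_sigma: float = 2.0    # phase-diffusion noise, rad / sqrt(s)
    freq_jitter_sd_hz: float = 0.3
    noise_sd: float = 2.0          # pink background, microvolts
    pink_exponent: float = 1.0
    artifact_prob: float = 0.05

    def validate(self) -> list[str]:
        v = []
        if not 0.0 <= self.mw_rate <= 1.0:
            v.append(f"mw_rate {self.mw_rate} outside [0, 1]")
        if not 0.0 <= self.leak_prob <= 1.0:
            v.append(f"leak_prob {self.leak_prob} outside [0, 1]")
        for c in self.components:
            if c.latency_jitter_sd_ms < 0 or c.amp_sd < 0 or c.scale_ms <= 0:
                v.append(f"component {c.name}: negative spread or scale")
        for d in (self.alpha_amp, self.theta_amp):
            if any(a < 0 for a in d.values()):
                v.append("oscillation amplitude < 0")
        for pair, kk in self.theta_coupling_kappa.items():
            if any(k < 0 for k in kk.values()):
                v.append(f"kappa < 0 for pair {pair}")
        if self.noise_sd < 0:
            v.append("noise_sd < 0")
        for name in ("mw_rate", "noise_sd", "coupling_sigma"):
            if not np.isfinite(getattr(self, name)):
                v.append(f"{name} not finite")
        return v


@dataclass(frozen=True)
class BehaviorParams:
    """State-conditional accuracy and response-time model."""

    accuracy: dict = field(default_factory=lambda: {ON_TASK: 0.96, MIND_WANDERING: 0.94})
    rt_mean_ms: dict = field(default_factory=lambda: {ON_TASK: 654.0, MIND_WANDERING: 687.0})
    rt_sd_ms: dict = field(default_factory=lambda: {ON_TASK: 120.0, MIND_WANDERING: 130.0})

    def validate(self) -> list[str]:
        return [f"accuracy {p} outside [0, 1]" for p in self.accuracy.values()
                if not 0.0 <= p <= 1.0]


# ---------------------------------------------------------------------------
# latent states and probe responses
# ---------------------------------------------------------------------------

def simulate_states(design: TaskDesign, gen: GenParams,
                    seed: int | np.random.Generator = 0):
    """Draw the latent attentional state sequence and probe responses.

    Each probe's state is Bernoulli(``mw_rate``); the six trials preceding the
    probe share it (attentional states persist over multiple trials). Trials
    outside probe windows carry an independent latent filler state. Responses
    are drawn from the state's response set, except with probability
    ``leak_prob`` the report falls in the excluded categories {4, 6}.

    Returns ``(states, probes)``: a length-``n_trials`` array of state strings
    and a list of :class:`ProbeEvent`.
    """
    bad = design.validate() + gen.validate()
    if bad:
        raise ValueError("; ".join(bad))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = design.n_trials
    # filler states for trials not governed by a probe
    states = np.where(rng.random(n) < gen.mw_rate, MIND_WANDERING, ON_TASK)
    states = states.astype(object)
    probes = []
    for k, pos in enumerate(design.probe_positions):
        mw = rng.random() < gen.mw_rate
        state = MIND_WANDERING if mw else ON_TASK
        lo = max(0, pos - PROBE_WINDOW + 1)
        states[lo:pos + 1] = state
        if rng.random() < gen.leak_prob:
            resp = int(rng.choice(EXCLUDED_RESPONSES))
        else:
            resp = int(rng.choice(MW_RESPONSES if mw else ON_TASK_RESPONSES))
        probes.append(ProbeEvent(probe_index=k, trial_index=pos,
                                 response=resp, state=state))
    return states, probes


# ---------------------------------------------------------------------------
# epoch synthesis
# ---------------------------------------------------------------------------

def pink_noise(shape: tuple[int, ...], exponent: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise along the last axis, standardized to ``sd``."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    if sd == 0.0:
        return np.zeros(shape)
    if exponent == 0.0:
        return white * sd
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n=n, axis=-1)
    x_sd = x.std(axis=-1, keepdims=True)
    x_sd[x_sd == 0] = 1.0
    return x / x_sd * sd


def _phase_offset(n_trials: int, n_samples: int, kappa: np.ndarray, sigma: float,
                  fs: float, rng: np.random.Generator) -> np.ndarray:
    """Circular-diffusion phase offsets with von Mises(0, kappa) marginal.

    Euler-Maruyama integration of ``dD = -lambda sin(D) dt + sigma dW`` with
    ``lambda = kappa sigma^2 / 2``, whose stationary density is von
    Mises(0, kappa). For very concentrated coupling the drift rate is capped
    at ``0.4 fs`` for stability and the noise rescaled to keep the same
    stationary variance. ``kappa`` is per-trial.
    """
    dt = 1.0 / fs
    kappa = np.asarray(kappa, dtype=float)
    lam = kappa * sigma ** 2 / 2.0
    sig = np.full_like(lam, sigma)
    cap = 0.4 * fs
    hot = lam > cap
    lam[hot] = cap
    sig[hot] = np.sqrt(2.0 * cap / kappa[hot])
    out = np.empty((n_trials, n_samples))
    init = np.where(kappa > 0, rng.vonmises(0.0, np.maximum(kappa, 1e-12)),
                    rng.uniform(-np.pi, np.pi, n_trials))
    out[:, 0] = init
    steps = rng.standard_normal((n_trials, n_samples - 1)) * (sig * np.sqrt(dt))[:, None]
    for i in range(1, n_samples):
        out[:, i] = out[:, i - 1] - lam * np.sin(out[:, i - 1]) * dt + steps[:, i - 1]
    return out


def _trial_amplitudes(mean: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Per-trial amplitudes around state means, clipped to the mean's sign."""
    draw = rng.normal(mean, sd)
    return np.where(mean >= 0, np.clip(draw, 0.0, None), np.clip(draw, None, 0.0))


def synthesize_epochs(states: np.ndarray, design: TaskDesign, gen: GenParams,
                      seed: int | np.random.Generator = 0,
                      trial_indices: np.ndarray | None = None) -> EpochSet:
    """Render epochs for (a subset of) trials from their latent states.

    Each epoch is ERP templates + state-dependent alpha and theta oscillations
    + pink noise on the four analysis channels. ``trial_indices`` restricts
    synthesis to the given global trial indices (the trial table keeps the
    global ``trial_id``). Reproducibility is defined for a fixed
    (states, trial subset, seed) triple.
    """
    bad = gen.validate()
    if bad:
        raise ValueError("; ".join(bad))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.asarray(states, dtype=object)
    if trial_indices is None:
        trial_indices = np.arange(states.size)
    trial_indices = np.asarray(trial_indices, dtype=int)
    st = states[trial_indices]
    n = trial_indices.size
    time_ms = default_time_axis(design.fs, *design.epoch_window)
    t_s = time_ms / 1000.0
    nchan = len(CHANNELS)
    nsamp = time_ms.size
    data = np.zeros((n, nchan, nsamp))
    chan_idx = {c: i for i, c in enumerate(CHANNELS)}

    # --- ERP templates --------------------------------------------------
    for comp in gen.components:
        mean = np.array([comp.amp[s] for s in st])
        amps = _trial_amplitudes(mean, comp.amp_sd, rng)
        lats = comp.latency_ms + rng.normal(0.0, comp.latency_jitter_sd_ms, n)
        wave = amps[:, None] * mexican_hat(
            (time_ms[None, :] - lats[:, None]) / comp.scale_ms)
        for ch in comp.channels:
            data[:, chan_idx[ch], :] += wave

    # --- alpha: independent oscillators per channel ----------------------
    a_mean = np.array([gen.alpha_amp[s] for s in st])
    for ch in CHANNELS:
        a = np.clip(rng.normal(a_mean, gen.alpha_cv * np.maximum(a_mean, 1e-12)), 0, None)
        f = gen.alpha_freq_hz + rng.normal(0.0, gen.freq_jitter_sd_hz, n)
        phi = rng.uniform(0.0, 2 * np.pi, n)
        data[:, chan_idx[ch], :] += (gen.alpha_weights.get(ch, 1.0) * a[:, None]
                                     * np.cos(2 * np.pi * f[:, None] * t_s[None, :]
                                              + phi[:, None]))

    # --- theta: common oscillator on coupled pairs, independent elsewhere
    th_mean = np.array([gen.theta_amp[s] for s in st])
    coupled = {}
    for (ref, dep), kk in gen.theta_coupling_kappa.items():
        if dep in coupled:
            raise ValueError(f"channel {dep} coupled twice")
        coupled[dep] = (ref, np.array([kk[s] for s in st]))
    ref_phase = {}
    for ch in CHANNELS:
        if ch in coupled:
            continue
        f = gen.theta_freq_hz + rng.normal(0.0, gen.freq_jitter_sd_hz, n)
        phi = rng.uniform(0.0, 2 * np.pi, n)
        phase = 2 * np.pi * f[:, None] * t_s[None, :] + phi[:, None]
        ref_phase[ch] = phase
        a = np.clip(rng.normal(th_mean, gen.theta_cv * np.maximum(th_mean, 1e-12)), 0, None)
        data[:, chan_idx[ch], :] += (gen.theta_weights.get(ch, 1.0)
                                     * a[:, None] * np.cos(phase))
    for dep, (ref, kappa) in coupled.items():
        if ref not in ref_phase:
            raise ValueError(f"coupling reference {ref} is itself coupled")
        offset = _phase_offset(n, nsamp, kappa, gen.coupling_sigma, design.fs, rng)
        a = np.clip(rng.normal(th_mean, gen.theta_cv * np.maximum(th_mean, 1e-12)), 0, None)
        data[:, chan_idx[dep], :] += (gen.theta_weights.get(dep, 1.0)
                                      * a[:, None] * np.cos(ref_phase[ref] + offset))

    # --- background noise -------------------------------------------------
    if gen.noise_sd > 0:
        data += pink_noise((n, nchan, nsamp), gen.pink_exponent, gen.noise_sd, rng)

    trials = pd.DataFrame({"trial_id": trial_indices, "state": st})
    return EpochSet(data.astype(np.float32), list(CHANNELS), design.fs, time_ms, trials)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(states: np.ndarray, behav: BehaviorParams,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Per-trial correctness and response time conditional on latent state.

    RTs exist only for correct trials (NaN otherwise); each state draws from
    its own normal RT distribution, truncated at 100 ms.
    """
    bad = behav.validate()
    if bad:
        raise ValueError("; ".join(bad))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.asarray(states, dtype=object)
    n = states.size
    acc = np.array([behav.accuracy[s] for s in states])
    correct = rng.random(n) < acc
    mu = np.array([behav.rt_mean_ms[s] for s in states])
    sd = np.array([behav.rt_sd_ms[s] for s in states])
    rt = np.maximum(rng.normal(mu, sd), 100.0)
    rt[~correct] = np.nan
    return pd.DataFrame({"correct": correct, "rt_ms": rt})


# ---------------------------------------------------------------------------
# whole-session convenience
# ---------------------------------------------------------------------------

def simulate_session(task: str, gen: GenParams | None = None, *, seed: int = 0,
                     behav: BehaviorParams | None = None,
                     design_kwargs: dict | None = None,
                     epochs_for: str = "all"):
    """Simulate one subject's session on one task, end to end.

    ``epochs_for`` is ``"all"`` (render every trial) or ``"labeled"`` (render
    only the six-trial pre-probe windows, which is all the analysis consumes).
    Returns ``(epochs, probes, design)``; the epoch trial table carries block,
    stimulus metadata, latent state, artifact flags and behavior.
    """
    gen = gen or GenParams()
    behav = behav or BehaviorParams()
    if epochs_for not in ("all", "labeled"):
        raise ValueError("epochs_for must be 'all' or 'labeled'")
    ss = np.random.SeedSequence(seed)
    r_design, r_states, r_epochs, r_behav, r_meta = [
        np.random.default_rng(c) for c in ss.spawn(5)]
    design = build_design(task, seed=r_design, **(design_kwargs or {}))
    states, probes = simulate_states(design, gen, r_states)
    if epochs_for == "labeled":
        idx = np.unique(np.concatenate([
            np.arange(max(0, p.trial_index - PROBE_WINDOW + 1), p.trial_index + 1)
            for p in probes]))
    else:
        idx = np.arange(design.n_trials)
    epochs = synthesize_epochs(states, design, gen, r_epochs, trial_indices=idx)
    behavior = simulate_behavior(states, behav, r_behav)

    # trial metadata: block structure, stimulus type (carried as metadata
    # only: SART go/no-go 89%/11%, probe trials always no-go; VS
    # target-present/absent 50/50), artifact flags
    n = design.n_trials
    meta = pd.DataFrame({
        "trial_id": np.arange(n),
        "task": task,
        "block": np.arange(n) // design.trials_per_block,
        "state": states,
        "artifact": r_meta.random(n) < gen.artifact_prob,
    })
    if task == "SART":
        stim = np.where(r_meta.random(n) < 0.11, "nogo", "go")
        stim[list(design.probe_positions)] = "nogo"
    else:
        stim = np.where(r_meta.random(n) < 0.5, "present", "absent")
    meta["stimulus"] = stim
    meta = meta.join(behavior)
    probe_of = np.full(n, -1)
    for p in probes:
        lo = max(0, p.trial_index - PROBE_WINDOW + 1)
        probe_of[lo:p.trial_index + 1] = p.probe_index
    meta["probe_index"] = probe_of

    epochs.trials = meta.iloc[idx].reset_index(drop=True)
    return epochs, probes, design
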