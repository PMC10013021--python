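"""Synthetic cardiorespiratory sleep data.

Generates ground-truth hypnograms (first-order Markov stage dynamics),
error-injected "model" hypnograms (per-epoch stage substitution through a
configurable confusion distribution), stage-conditioned respiratory-effort
belt traces, and stage-conditioned R-peak trains with LF/HF heart-rate
oscillations.  Every generator is a pure function of (config, seed), so
the whole downstream analysis is testable without recordings or trained
sleep stagers.

The respiratory waveform is a raised-cosine inspiration followed by an
exponential-decay expiration: asymmetric, one dominant inspiratory peak
per cycle, which keeps peak detection and the amplitude-change features
non-degenerate (a pure sinusoid would make them trivial).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, STAGES, EPOCH_LEN_S, Hypnogram, RPeakSeries, RespSignal

__all__ = [
    "StageResp",
    "StageRR",
    "ModelError",
    "SimConfig",
    "simulate_hypnogram",
    "derive_model_hypnogram",
    "simulate_resp",
    "simulate_rpeaks",
    "scenario",
    "stationary_distribution",
    "SCENARIO_NAMES",
]


@dataclass
class StageResp:
    """Per-stage breathing parameters.

    rate_mean : breaths/min; rate_cv and amp_cv are unitless coefficients
    of variation of breath-to-breath period and amplitude.
    """

    rate_mean: float
    rate_cv: float = 0.05
    amp_cv: float = 0.1

    def validate(self) -> None:
        if self.rate_mean <= 0:
            raise ValueError("rate_mean must be positive")
        if self.rate_cv < 0 or self.amp_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")


@dataclass
class StageRR:
    """Per-stage heart-rhythm parameters (mean RR in ms, target RMSSD in
    ms, and LF/HF spectral power ratio of the RR modulation)."""

    rr_mean_ms: float
    rmssd_ms: float = 30.0
    lf_hf_ratio: float = 1.5

    def validate(self) -> None:
        if not 300.0 <= self.rr_mean_ms <= 2000.0:
            raise ValueError("rr_mean_ms must lie in [300, 2000] ms")
        if self.rmssd_ms < 0:
            raise ValueError("rmssd_ms must be >= 0")
        if self.lf_hf_ratio < 0:
            raise ValueError("lf_hf_ratio must be >= 0")


@dataclass
class ModelError:
    """Epoch-substitution error model for a derived stager.

    With probability ``substitution_rate`` an epoch's true stage is
    replaced by a draw from ``confusion_bias[true_stage]`` (a probability
    distribution over stages; self-maps are allowed and count as no
    change).  Errors are epoch-independent.
    """

    substitution_rate: float
    confusion_bias: dict[str, dict[str, float]]

    def validate(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must lie in [0, 1]")
        for stage in STAGES:
            dist = self.confusion_bias.get(stage)
            if dist is None:
                raise ValueError(f"confusion_bias missing stage {stage}")
            tot = sum(dist.values())
            if not math.isclose(tot, 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"confusion_bias[{stage}] sums to {tot}, expected 1"
                )
            if any(p < 0 for p in dist.values()):
                raise ValueError("confusion probabilities must be >= 0")
            bad = set(dist) - set(STAGES)
            if bad:
                raise ValueError(f"confusion targets not stages: {bad}")


@dataclass
class SimConfig:
    """Full simulation configuration for one synthetic recording."""

    duration_h: float
    transition_matrix: np.ndarray
    stage_resp: dict[str, StageResp]
    stage_rr: dict[str, StageRR]
    model_error: ModelError
    epoch_len_s: float = EPOCH_LEN_S
    clock_start: pd.Timestamp = pd.Timestamp("2000-01-01 20:00:00")
    seed: int = 0
    resp_noise_sd: float = 0.05
    resp_fs: float = 10.0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.clock_start = pd.Timestamp(self.clock_start)

    def validate(self) -> None:
        if self.duration_h * 3600.0 < self.epoch_len_s:
            raise ValueError("duration must cover at least one epoch")
        P = self.transition_matrix
        if P.shape != (5, 5):
            raise ValueError("transition_matrix must be 5x5 over (W,N1,N2,N3,R)")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition_matrix rows must be stochastic")
        for s in STAGES:
            if s not in self.stage_resp:
                raise ValueError(f"stage_resp missing stage {s}")
            self.stage_resp[s].validate()
            if s not in self.stage_rr:
                raise ValueError(f"stage_rr missing stage {s}")
            self.stage_rr[s].validate()
        self.model_error.validate()

    @property
    def n_epochs(self) -> int:
        return int(self.duration_h * 3600.0 // self.epoch_len_s)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix by
    eigen-decomposition (left eigenvector of eigenvalue 1)."""
    P = np.asarray(P, dtype=float)
    w, v = np.linalg.eig(P.T)
    k = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_hypnogram(
    cfg: SimConfig, seed: int | None = None, initial_stage: str | None = None
) -> Hypnogram:
    """Simulate a ground-truth hypnogram as a first-order Markov chain.

    The initial stage is drawn from the chain's stationary distribution
    unless ``initial_stage`` is given.  Deterministic under a fixed seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    P = cfg.transition_matrix
    n = cfg.n_epochs
    cum = np.cumsum(P, axis=1)
    if initial_stage is None:
        state = int(rng.choice(5, p=stationary_distribution(P)))
    else:
        state = STAGES.index(initial_stage)
    states = np.empty(n, dtype=np.int64)
    u = rng.random(n)
    for i in range(n):
        states[i] = state
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, 4)
    stages = np.array([STAGES[s] for s in states], dtype=object)
    return Hypnogram(
        start=cfg.clock_start, stages=stages, epoch_len_s=cfg.epoch_len_s,
        source="truth",
    )


def derive_model_hypnogram(
    truth: Hypnogram,
    model_error: ModelError,
    seed: int,
    source: str = "model",
) -> Hypnogram:
    """Inject epoch-independent substitution errors into a truth hypnogram.

    Stands in for an imperfect automatic sleep stager: each epoch is,
    with probability ``substitution_rate``, re-drawn from the per-stage
    confusion distribution, else copied verbatim.
    """
    model_error.validate()
    if MISSING in truth.stages:
        raise ValueError("truth hypnogram must not contain MISSING epochs")
    rng = np.random.default_rng(seed)
    out = truth.stages.copy()
    hit = rng.random(truth.n_epochs) < model_error.substitution_rate
    for i in np.nonzero(hit)[0]:
        dist = model_error.confusion_bias[truth.stages[i]]
        targets = list(dist.keys())
        probs = np.array([dist[t] for t in targets])
        out[i] = targets[int(rng.choice(len(targets), p=probs / probs.sum()))]
    return Hypnogram(
        start=truth.start, stages=out, epoch_len_s=truth.epoch_len_s,
        source=source,
    )


def _breath_waveform(n: int, n_insp: int, amp: float) -> np.ndarray:
    """One breath cycle: raised-cosine inspiration over ``n_insp`` samples
    reaching ``amp``, then exponential decay back toward baseline."""
    y = np.empty(n)
    if n_insp < 1:
        n_insp = 1
    u = np.arange(n_insp) / n_insp
    y[:n_insp] = amp * 0.5 * (1.0 - np.cos(np.pi * u))
    n_exp = n - n_insp
    if n_exp > 0:
        tau = max(n_exp / 3.0, 1.0)
        y[n_insp:] = amp * np.exp(-np.arange(n_exp) / tau)
    return y


def simulate_resp(
    hyp: Hypnogram,
    stage_resp: dict[str, StageResp],
    fs: float = 10.0,
    seed: int = 0,
    noise_sd: float = 0.05,
    return_peaks: bool = False,
) -> RespSignal | tuple[RespSignal, np.ndarray]:
    """Synthesize a respiratory-effort belt trace following a hypnogram.

    Breath periods are drawn per breath with mean 60/rate_mean(stage) s
    and coefficient of variation rate_cv(stage); amplitudes with mean 1
    and CV amp_cv(stage).  Gaussian sensor noise of standard deviation
    ``noise_sd`` is added.  With ``return_peaks`` the true inspiratory
    peak times (s) are also returned for detector validation.
    """
    if fs < 4.0:
        raise ValueError("fs must be >= 4 Hz")
    for s, p in stage_resp.items():
        p.validate()
        if 60.0 / p.rate_mean < 2.0 / fs:
            raise ValueError(
                f"stage {s}: breath period shorter than 2 samples at fs={fs}"
            )
    rng = np.random.default_rng(seed)
    total_s = hyp.duration_s
    n_total = int(round(total_s * fs))
    x = np.zeros(n_total)
    true_peaks: list[float] = []
    t = 0.0
    while t < total_s:
        stage = hyp.stage_at(t)
        if stage == MISSING:
            t += hyp.epoch_len_s  # no breathing synthesized for gaps
            continue
        p = stage_resp[stage]
        mu = 60.0 / p.rate_mean
        period = rng.normal(mu, p.rate_cv * mu) if p.rate_cv > 0 else mu
        period = float(np.clip(period, max(1.0, 2.0 / fs), 15.0))
        amp = rng.normal(1.0, p.amp_cv) if p.amp_cv > 0 else 1.0
        amp = max(amp, 0.1)
        i0 = int(round(t * fs))
        n = int(round(period * fs))
        n = min(n, n_total - i0)
        if n <= 0:
            break
        # inspiratory time is kept near-constant (expiration absorbs the
        # period variability, as in real breathing); this also keeps the
        # inspiratory-peak times faithful to the drawn breath periods
        t_insp = min(1.5, 0.5 * period)
        n_insp = max(int(round(t_insp * fs)), 1)
        x[i0 : i0 + n] += _breath_waveform(n, min(n_insp, n), amp)
        true_peaks.append(t + min(n_insp, n) / fs)
        t += period
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n_total)
    sig = RespSignal(samples=x, fs=fs, t0=hyp.start)
    if return_peaks:
        return sig, np.asarray(true_peaks)
    return sig


def simulate_rpeaks(
    hyp: Hypnogram,
    stage_rr: dict[str, StageRR],
    seed: int = 0,
    lf_freq_hz: float = 0.095,
    hf_freq_hz: float = 0.25,
) -> RPeakSeries:
    """Synthesize an R-peak train with stage-conditioned mean RR, RMSSD
    and LF/HF oscillatory structure.

    RR intervals are the stage mean plus two sinusoidal modulations (one
    in the LF band at ``lf_freq_hz``, one in the HF band at
    ``hf_freq_hz``, variance split per lf_hf_ratio) plus white jitter.
    The white-noise level is solved analytically per stage so that the
    RMSSD of the generated intervals matches the configured target: for
    a sinusoid of amplitude A at frequency f sampled every T seconds the
    successive-difference mean square is 2 A^2 sin^2(pi f T), and for
    white noise of SD s it is 2 s^2.
    """
    for p in stage_rr.values():
        p.validate()
    rng = np.random.default_rng(seed)
    phi_lf = rng.uniform(0, 2 * np.pi)
    phi_hf = rng.uniform(0, 2 * np.pi)
    total_s = hyp.duration_s
    # Pre-solve amplitudes per stage.
    params: dict[str, tuple[float, float, float, float]] = {}
    for s, p in stage_rr.items():
        T = p.rr_mean_ms / 1000.0
        rho = p.lf_hf_ratio
        v_osc = 0.25 * p.rmssd_ms**2  # oscillation variance budget, ms^2
        a_hf = math.sqrt(2.0 * v_osc / (1.0 + rho))
        a_lf = math.sqrt(2.0 * v_osc * rho / (1.0 + rho))
        contrib = 2.0 * a_lf**2 * math.sin(math.pi * lf_freq_hz * T) ** 2
        contrib += 2.0 * a_hf**2 * math.sin(math.pi * hf_freq_hz * T) ** 2
        resid = p.rmssd_ms**2 - contrib
        sd_w = math.sqrt(max(resid, 0.0) / 2.0)
        params[s] = (p.rr_mean_ms, a_lf, a_hf, sd_w)
    times: list[float] = []
    t = 0.0
    while t < total_s:
        stage = hyp.stage_at(t)
        if stage == MISSING:
            t += hyp.epoch_len_s
            continue
        rr_mean, a_lf, a_hf, sd_w = params[stage]
        rr = (
            rr_mean
            + a_lf * math.sin(2 * np.pi * lf_freq_hz * t + phi_lf)
            + a_hf * math.sin(2 * np.pi * hf_freq_hz * t + phi_hf)
            + (rng.normal(0.0, sd_w) if sd_w > 0 else 0.0)
        )
        rr = float(np.clip(rr, 300.0, 2000.0))
        t += rr / 1000.0
        if t <= total_s:
            times.append(t)
    return RPeakSeries(peak_times=np.asarray(times), t0=hyp.start)


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

SCENARIO_NAMES = ("icu-like", "lab-nosdb", "lab-sdb")

# Stage-relative breathing-rate multipliers (wake slightly faster, deep
# NREM slowest, REM irregular and near wake); rescaled per scenario so
# that the stationary-weighted mean rate hits the scenario target.
_RATE_SHAPE = {"W": 1.06, "N1": 1.01, "N2": 0.98, "N3": 0.93, "R": 1.03}


def _sticky_matrix(self_p: dict[str, float], towards: dict[str, dict[str, float]]) -> np.ndarray:
    P = np.zeros((5, 5))
    for i, s in enumerate(STAGES):
        P[i, i] = self_p[s]
        rest = 1.0 - self_p[s]
        dist = towards[s]
        z = sum(dist.values())
        for tgt, w in dist.items():
            P[i, STAGES.index(tgt)] = rest * w / z
    return P


def _adjacent_confusion(adjacent_w: float = 0.8, rem_w: float = 0.2) -> dict[str, dict[str, float]]:
    """Default confusion: mass on ordinally adjacent NREM stages plus a
    smaller REM/wake component, so substitution produces both concordant
    (within one stage) and discordant disagreements."""
    return {
        "W": {"N1": 0.5 * adjacent_w, "N2": 0.5 * adjacent_w, "R": rem_w},
        "N1": {"W": 0.4 * adjacent_w, "N2": 0.4 * adjacent_w, "N3": 0.2 * adjacent_w, "R": rem_w},
        "N2": {"N1": 0.5 * adjacent_w, "N3": 0.3 * adjacent_w, "W": 0.2 * adjacent_w, "R": rem_w},
        "N3": {"N2": 0.6 * adjacent_w, "N1": 0.3 * adjacent_w, "W": 0.1 * adjacent_w, "R": rem_w},
        "R": {"N1": 0.3, "N2": 0.3, "W": 0.4},
    }


def _make_stage_resp(target_rate: float, rate_cv: float, amp_cv: float,
                     P: np.ndarray) -> dict[str, StageResp]:
    """Per-stage breathing params rescaled so the stationary-weighted
    mean rate equals ``target_rate`` breaths/min exactly."""
    pi = stationary_distribution(P)
    raw = np.array([_RATE_SHAPE[s] for s in STAGES])
    scale = target_rate / float(pi @ raw)
    return {
        s: StageResp(rate_mean=float(_RATE_SHAPE[s] * scale),
                     rate_cv=rate_cv, amp_cv=amp_cv)
        for s in STAGES
    }


def scenario(name: str, duration_h: float = 24.0, seed: int = 0) -> SimConfig:
    """Fully-populated simulation presets.

    - ``icu-like``: fast breathing (stationary mean 17.4 breaths/min),
      fragmented stage dynamics, depressed HRV, high stager error.
    - ``lab-nosdb``: slow regular breathing (14 breaths/min),
      consolidated sleep, low stager error.
    - ``lab-sdb``: sleep-disordered-breathing-like lab patient: 15.5
      breaths/min with high breath-to-breath variability, fragmented
      sleep, intermediate stager error.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    if name == "icu-like":
        P = _sticky_matrix(
            {"W": 0.85, "N1": 0.70, "N2": 0.75, "N3": 0.70, "R": 0.70},
            {
                "W": {"N1": 0.7, "N2": 0.2, "R": 0.1},
                "N1": {"W": 0.5, "N2": 0.4, "R": 0.1},
                "N2": {"N1": 0.5, "W": 0.3, "N3": 0.15, "R": 0.05},
                "N3": {"N2": 0.7, "N1": 0.2, "W": 0.1},
                "R": {"W": 0.5, "N1": 0.4, "N2": 0.1},
            },
        )
        stage_resp = _make_stage_resp(17.4, rate_cv=0.12, amp_cv=0.25, P=P)
        stage_rr = {
            "W": StageRR(780.0, 18.0, 2.5),
            "N1": StageRR(820.0, 16.0, 2.0),
            "N2": StageRR(850.0, 15.0, 1.5),
            "N3": StageRR(880.0, 12.0, 0.8),
            "R": StageRR(800.0, 20.0, 2.5),
        }
        err = ModelError(0.35, _adjacent_confusion())
    elif name == "lab-nosdb":
        P = _sticky_matrix(
            {"W": 0.90, "N1": 0.75, "N2": 0.92, "N3": 0.90, "R": 0.90},
            {
                "W": {"N1": 0.8, "N2": 0.2},
                "N1": {"N2": 0.6, "W": 0.3, "R": 0.1},
                "N2": {"N3": 0.4, "N1": 0.3, "W": 0.2, "R": 0.1},
                "N3": {"N2": 0.8, "N1": 0.1, "W": 0.1},
                "R": {"N1": 0.4, "N2": 0.3, "W": 0.3},
            },
        )
        stage_resp = _make_stage_resp(14.0, rate_cv=0.05, amp_cv=0.10, P=P)
        stage_rr = {
            "W": StageRR(900.0, 35.0, 2.5),
            "N1": StageRR(950.0, 32.0, 2.0),
            "N2": StageRR(1000.0, 30.0, 1.2),
            "N3": StageRR(1050.0, 25.0, 0.6),
            "R": StageRR(920.0, 40.0, 2.5),
        }
        err = ModelError(0.12, _adjacent_confusion())
    else:  # lab-sdb
        P = _sticky_matrix(
            {"W": 0.88, "N1": 0.70, "N2": 0.85, "N3": 0.85, "R": 0.85},
            {
                "W": {"N1": 0.8, "N2": 0.2},
                "N1": {"N2": 0.5, "W": 0.4, "R": 0.1},
                "N2": {"N1": 0.4, "W": 0.3, "N3": 0.2, "R": 0.1},
                "N3": {"N2": 0.8, "N1": 0.1, "W": 0.1},
                "R": {"N1": 0.4, "W": 0.4, "N2": 0.2},
            },
        )
        stage_resp = _make_stage_resp(15.5, rate_cv=0.25, amp_cv=0.35, P=P)
        stage_rr = {
            "W": StageRR(880.0, 30.0, 2.8),
            "N1": StageRR(920.0, 28.0, 2.2),
            "N2": StageRR(960.0, 26.0, 1.5),
            "N3": StageRR(1000.0, 22.0, 0.8),
            "R": StageRR(900.0, 34.0, 2.8),
        }
        err = ModelError(0.20, _adjacent_confusion())
    cfg = SimConfig(
        duration_h=duration_h,
        transition_matrix=P,
        stage_resp=stage_resp,
        stage_rr=stage_rr,
        model_error=err,
        seed=seed,
    )
    cfg.validate()
    return cfg
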