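"""Seeded generators for all three data modalities with retained ground truth.

The glomerular generator emulates the in vivo protocol: 20 s trials
(4 s baseline, 1 s stimulus, 15 s post-stimulus), three trials per
stimulus, a deodorized-air blank, sparse tuning across an odorant
panel, and an ascending concentration ladder (0.5/1/5/10 % v/v).
Fluorescence transients are difference-of-exponentials kernels riding
on a constant baseline with Gaussian noise; response amplitude follows
a population Hill curve times a per-glomerulus lognormal gain, and
latency shortens by a fixed decrement per ladder step.  Two presets
bracket the concentration-coding regimes of interest:

* ``mature_like``   — steep Hill curve saturating by the 1 % step, so
  amplitudes differ between 0.5 % and 1 % but are flat above;
* ``immature_like`` — shallow graded curve, so amplitudes keep rising
  across every ascending pair.

A hard fluorescence ceiling (optional) simulates indicator saturation
as a clip, producing the rapid-onset plateau signature the QC module
screens for.

EPSC sweeps are alpha-function inward currents with per-trial Gaussian
onset jitter and baseline noise; behavior tables follow a geometric
sniffing-habituation decay with an additive dishabituation jump on each
odorant change.

Every generator consumes a single ``numpy.random.default_rng(seed)``
stream in a fixed documented order, so identical configs and seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epsc import SweepSet
from .model import RoiDataset, SchedulePanel, StimulusSchedule, TrialTrace, ValidationError

DEFAULT_ODORANT_PANEL = (
    "ethyl_butyrate", "hexanal", "2-hexanone", "propionic_acid",
    "isoamyl_acetate", "methyl_salicylate", "acetophenone",
)
DEFAULT_LADDER = (0.005, 0.01, 0.05, 0.10)


def hill_amplitude(concentration, a_max_pct: float, ec50: float, hill_n: float):
    """Population concentration-response curve A(c) = A_max c^n / (c^n + EC50^n)."""
    c = np.asarray(concentration, dtype=float)
    return a_max_pct * c ** hill_n / (c ** hill_n + ec50 ** hill_n)


def doexp_kernel(t, rise_tau_s: float, decay_tau_s: float):
    """Difference-of-exponentials transient normalized to peak 1; 0 for t < 0."""
    if rise_tau_s >= decay_tau_s:
        raise ValidationError("rise tau must be < decay tau")
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, np.exp(-t / decay_tau_s) - np.exp(-t / rise_tau_s), 0.0)
    t_peak = (
        np.log(decay_tau_s / rise_tau_s) / (1 / rise_tau_s - 1 / decay_tau_s)
    )
    peak = np.exp(-t_peak / decay_tau_s) - np.exp(-t_peak / rise_tau_s)
    return k / peak


@dataclass
class GlomGenConfig:
    """Parameters of the glomerular calcium-imaging simulation."""

    n_mice: int = 1
    n_glomeruli_per_mouse: int = 20
    odorant_panel: tuple[str, ...] = DEFAULT_ODORANT_PANEL
    concentration_ladder: tuple[float, ...] = DEFAULT_LADDER
    tuning_sparsity: float = 0.25       # P(odorant drives a given glomerulus)
    a_max_pct: float = 300.0            # Hill plateau, % ΔF/F
    ec50: float = 0.007
    hill_n: float = 4.0
    gain_sigma: float = 0.4             # lognormal per-glomerulus gain spread
    base_latency_s: float = 0.8
    latency_step_s: float = 0.1         # decrement per ascending ladder step
    rise_tau_s: float = 0.2             # GCaMP6s-like slow kernel
    decay_tau_s: float = 1.0
    baseline_f0: float = 100.0
    noise_sd: float = 2.0               # a.u. per sample per trial
    mechanosensory_blank_amp_pct: float = 2.0
    ceiling: float | None = None        # hard fluorescence clip (indicator saturation)
    onset_s: float = 4.0
    stimulus_duration_s: float = 1.0
    trial_length_s: float = 20.0
    sampling_rate_hz: float = 15.0
    trials_per_stimulus: int = 3
    include_blank: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        ladder = self.concentration_ladder
        if len(ladder) >= 2 and not (min(ladder) <= self.ec50 <= max(ladder) * 2):
            raise ValidationError("EC50 must lie within (twice) the ladder span")
        if self.rise_tau_s >= self.decay_tau_s:
            raise ValidationError("rise tau must be < decay tau")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @classmethod
    def preset(cls, name: str, **overrides) -> "GlomGenConfig":
        """Named parameter sets for the two concentration-coding regimes."""
        if name == "mature_like":
            base = cls(ec50=0.007, hill_n=4.0)
        elif name == "immature_like":
            base = cls(ec50=0.05, hill_n=1.0)
        else:
            raise ValidationError(f"unknown preset {name!r}")
        return replace(base, **overrides)


@dataclass
class GlomSimulation:
    """Generated datasets (one per mouse) plus the ground truth behind them."""

    datasets: list[RoiDataset]
    schedule: SchedulePanel
    ground_truth: pd.DataFrame
    config: GlomGenConfig


def _glom_schedule(cfg: GlomGenConfig) -> SchedulePanel:
    entries: dict[str, StimulusSchedule] = {}
    for odorant in cfg.odorant_panel:
        for conc in cfg.concentration_ladder:
            label = f"{odorant}_{conc:g}"
            entries[label] = StimulusSchedule(
                stimulus_label=label, odorant=odorant, concentration=conc,
                is_blank=False, onset_s=cfg.onset_s, duration_s=cfg.stimulus_duration_s,
                trial_length_s=cfg.trial_length_s, sampling_rate_hz=cfg.sampling_rate_hz,
            )
    if cfg.include_blank:
        entries["blank"] = StimulusSchedule(
            stimulus_label="blank", odorant="blank", concentration=0.0,
            is_blank=True, onset_s=cfg.onset_s, duration_s=cfg.stimulus_duration_s,
            trial_length_s=cfg.trial_length_s, sampling_rate_hz=cfg.sampling_rate_hz,
        )
    return SchedulePanel(entries)


def generate_glom_dataset(cfg: GlomGenConfig) -> GlomSimulation:
    """Simulate glomerular trial traces with known amplitudes, latencies and tuning.

    RNG consumption order (fixed): per mouse → per glomerulus (tuning
    mask, then gain) → per stimulus → per trial noise.  Traces are
    F0 + F0·(A/100)·K(t − onset − latency) + N(0, noise_sd), clipped at
    the ceiling when one is set.
    """
    rng = np.random.default_rng(cfg.seed)
    schedule = _glom_schedule(cfg)
    n_samples = schedule[next(iter(schedule.entries))].n_samples
    t = np.arange(n_samples) / cfg.sampling_rate_hz
    ladder_index = {c: i for i, c in enumerate(cfg.concentration_ladder)}

    datasets, truth_rows = [], []
    for m in range(cfg.n_mice):
        mouse_id = f"m{m + 1}"
        traces: list[TrialTrace] = []
        for g in range(cfg.n_glomeruli_per_mouse):
            roi_id = f"{mouse_id}_g{g + 1:03d}"
            tuned = rng.random(len(cfg.odorant_panel)) < cfg.tuning_sparsity
            gain = float(rng.lognormal(0.0, cfg.gain_sigma))
            for entry in schedule:
                if entry.is_blank:
                    amp_pct = cfg.mechanosensory_blank_amp_pct
                    latency = cfg.base_latency_s
                else:
                    odor_idx = cfg.odorant_panel.index(entry.odorant)
                    step = ladder_index[entry.concentration]
                    if tuned[odor_idx]:
                        amp_pct = float(
                            hill_amplitude(entry.concentration, cfg.a_max_pct,
                                           cfg.ec50, cfg.hill_n) * gain
                        )
                    else:
                        amp_pct = 0.0
                    latency = cfg.base_latency_s - cfg.latency_step_s * step
                    truth_rows.append({
                        "mouse_id": mouse_id, "roi_id": roi_id,
                        "odorant": entry.odorant, "concentration": entry.concentration,
                        "stimulus_label": entry.stimulus_label,
                        "true_amplitude_pct": amp_pct,
                        "true_latency_s": latency,
                        "true_responder": amp_pct > 0,
                    })
                k = doexp_kernel(t - entry.onset_s - latency,
                                 cfg.rise_tau_s, cfg.decay_tau_s)
                # renormalize to the sampled peak so the configured amplitude
                # is exactly the peak of the discretized trace
                if k.max() > 0:
                    k = k / k.max()
                signal = cfg.baseline_f0 * (1.0 + amp_pct / 100.0 * k)
                for trial in range(1, cfg.trials_per_stimulus + 1):
                    samples = signal + (
                        rng.normal(0.0, cfg.noise_sd, n_samples)
                        if cfg.noise_sd > 0 else 0.0
                    )
                    if cfg.ceiling is not None:
                        samples = np.minimum(samples, cfg.ceiling)
                    traces.append(TrialTrace(roi_id, entry.stimulus_label,
                                             trial, samples, entry))
        datasets.append(RoiDataset(traces=traces, schedule=schedule, mouse_id=mouse_id))
    return GlomSimulation(datasets, schedule, pd.DataFrame(truth_rows), cfg)


# ---------------------------------------------------------------------------
# EPSC sweeps

@dataclass
class EpscGenConfig:
    """Parameters of the light-evoked EPSC simulation (10 kHz voltage clamp)."""

    n_cells: int = 1
    conditions: tuple[tuple[float, float], ...] = ((1.0, 100.0),)  # (duration ms, intensity %)
    amplitude_range_pA: tuple[float, float] = (-200.0, -10.0)
    onset_range_s: tuple[float, float] = (0.0005, 0.003)
    jitter_range_s: tuple[float, float] = (0.00005, 0.0005)
    noise_range_pA: tuple[float, float] = (2.0, 10.0)
    alpha_tau_s: float = 0.0015
    n_sweeps: int = 10
    sampling_rate_hz: float = 10_000.0
    light_onset_s: float = 0.4
    sweep_length_s: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_range_pA[0] > self.amplitude_range_pA[1]:
            raise ValidationError("amplitude range must be (low, high)")
        if self.amplitude_range_pA[1] > 0:
            raise ValidationError("EPSC amplitudes must be <= 0 (inward)")
        for name in ("onset_range_s", "jitter_range_s", "noise_range_pA"):
            lo, hi = getattr(self, name)
            if lo < 0 or lo > hi:
                raise ValidationError(f"invalid {name}")


def alpha_epsc(t, amplitude_pA: float, onset_s: float, tau_s: float):
    """Alpha-function EPSC: peak = amplitude (negative) at onset + tau."""
    x = (np.asarray(t, dtype=float) - onset_s) / tau_s
    return np.where(x >= 0, amplitude_pA * x * np.exp(1.0 - x), 0.0)


def generate_epsc_dataset(cfg: EpscGenConfig) -> tuple[list[SweepSet], pd.DataFrame]:
    """Simulate per-cell sweep sets with known amplitude, onset and jitter.

    RNG order: per cell (amplitude, onset, jitter σ, noise RMS) → per
    condition → per sweep (onset offset, then sample noise).  Amplitude
    scales with light intensity so power curves are monotone.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.sweep_length_s * cfg.sampling_rate_hz))
    t = np.arange(n) / cfg.sampling_rate_hz
    sets, truth = [], []
    for c in range(cfg.n_cells):
        cell_id = f"c{c + 1:03d}"
        amp = float(rng.uniform(*cfg.amplitude_range_pA))
        onset = float(rng.uniform(*cfg.onset_range_s))
        sigma = float(rng.uniform(*cfg.jitter_range_s))
        noise = float(rng.uniform(*cfg.noise_range_pA))
        for duration_ms, intensity in cfg.conditions:
            label = f"{duration_ms:g}ms_{intensity:g}pct"
            cond_amp = amp * intensity / 100.0
            sweeps = []
            for _ in range(cfg.n_sweeps):
                trial_onset = onset + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
                trial_onset = max(trial_onset, 1e-4)
                trace = alpha_epsc(t, cond_amp, cfg.light_onset_s + trial_onset,
                                   cfg.alpha_tau_s)
                # renormalize so the configured amplitude is exactly the
                # sampled peak of each sweep
                if trace.min() < 0:
                    trace = trace * (cond_amp / trace.min())
                if noise > 0:
                    trace = trace + rng.normal(0.0, noise, n)
                sweeps.append(trace)
            sets.append(SweepSet(
                cell_id=cell_id, condition_label=label, time_s=t,
                sweeps=np.array(sweeps), light_onset_s=cfg.light_onset_s,
                light_duration_ms=duration_ms, light_intensity_pct=intensity,
            ))
            truth.append({
                "cell_id": cell_id, "condition_label": label,
                "true_amplitude_pA": cond_amp, "true_onset_s": onset,
                "true_jitter_s": sigma, "noise_rms_pA": noise,
            })
    return sets, pd.DataFrame(truth)


def sweep_sets_to_table(sets: list[SweepSet]) -> pd.DataFrame:
    """Long-format sweeps.csv dialect for a list of sweep sets."""
    frames = []
    for ss in sets:
        n_sweeps, n_samples = ss.sweeps.shape
        frames.append(pd.DataFrame({
            "cell_id": np.repeat(ss.cell_id, n_sweeps * n_samples),
            "condition_label": np.repeat(ss.condition_label, n_sweeps * n_samples),
            "sweep_index": np.repeat(np.arange(1, n_sweeps + 1), n_samples),
            "time_s": np.tile(ss.time_s, n_sweeps),
            "current_pA": ss.sweeps.ravel(),
            "light_onset_s": ss.light_onset_s,
            "light_duration_ms": ss.light_duration_ms,
            "light_intensity_pct": ss.light_intensity_pct,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Behavior

@dataclass
class BehaviorGroupConfig:
    """Ground-truth behavioral parameters for one treatment group.

    Sniffing follows a geometric within-odorant decay: trial k of an
    odorant draws around t·ρ^(k−1), where t starts at ``t1_s`` and each
    odorant change resets it to (previous last trial) + ``dishab_jump_s``.
    Hence the expected habituation difference is t·(1−ρ) and the expected
    dishabituation difference is exactly the jump J.
    """

    name: str
    n_subjects: int = 12
    t1_s: float = 10.0                 # first-trial sniffing, s
    rho: float = 0.5                   # within-odorant decay factor
    # stationary default t1·(1−ρ²): every odorant then starts at t1, so the
    # expected habituation difference is t1·(1−ρ) for each odorant
    dishab_jump_s: float = 7.5         # novel-odor sniffing jump J, s
    pref_ratio: float = 3.0            # odor:MO sniffing ratio in the two-choice assay
    mo_sniff_s: float = 10.0
    buried_latency_scale_s: float = 100.0
    buried_fail_prob: float = 0.0
    noise_sd_s: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValidationError("rho must lie in (0, 1)")
        if self.pref_ratio <= 0 or self.t1_s <= 0:
            raise ValidationError("t1_s and pref_ratio must be > 0")


def generate_behavior_dataset(
    groups: list[BehaviorGroupConfig],
    seed: int = 0,
    odorant_order: tuple[str, ...] = ("water", "almond", "mint", "vanilla"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate all three assays for each subject of each group.

    RNG order: per group → per subject → (habituation grid, two-choice
    pair, buried-food latency).  Sniff times are max(0, model + noise).
    """
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for grp in groups:
        for s in range(grp.n_subjects):
            subject = f"{grp.name}_s{s + 1:02d}"
            base = {"subject_id": subject, "group": grp.name}
            t_start = grp.t1_s
            for odorant in odorant_order:
                for trial in range(1, 4):
                    mean = t_start * grp.rho ** (trial - 1)
                    value = max(0.0, mean + (rng.normal(0.0, grp.noise_sd_s)
                                             if grp.noise_sd_s > 0 else 0.0))
                    rows.append({**base, "assay": "habituation", "trial_index": trial,
                                 "odorant": odorant, "value_s": value})
                t_start = t_start * grp.rho ** 2 + grp.dishab_jump_s

            mo = max(0.0, grp.mo_sniff_s + (rng.normal(0.0, grp.noise_sd_s)
                                            if grp.noise_sd_s > 0 else 0.0))
            odor = max(0.0, grp.pref_ratio * grp.mo_sniff_s
                       + (rng.normal(0.0, grp.noise_sd_s) if grp.noise_sd_s > 0 else 0.0))
            rows.append({**base, "assay": "two_choice", "trial_index": 1,
                         "odorant": "odor", "value_s": odor})
            rows.append({**base, "assay": "two_choice", "trial_index": 1,
                         "odorant": "mineral_oil", "value_s": mo})

            if grp.buried_fail_prob > 0 and rng.random() < grp.buried_fail_prob:
                latency = 601.0
            else:
                latency = float(rng.exponential(grp.buried_latency_scale_s)) + 1.0
            digging = max(0.0, 30.0 + (rng.normal(0.0, 5.0) if grp.noise_sd_s > 0 else 0.0))
            rows.append({**base, "assay": "buried_food", "trial_index": 1,
                         "odorant": "latency", "value_s": latency})
            rows.append({**base, "assay": "buried_food", "trial_index": 1,
                         "odorant": "digging", "value_s": digging})

            # expected first-trial sniffing per odorant from the jump recursion
            t_seq = [grp.t1_s]
            for _ in odorant_order[1:]:
                t_seq.append(t_seq[-1] * grp.rho ** 2 + grp.dishab_jump_s)
            truth.append({
                "subject_id": subject, "group": grp.name,
                "true_habituation_s": float(np.mean(t_seq)) * (1.0 - grp.rho),
                "true_dishabituation_s": grp.dishab_jump_s,
                "true_ratio": grp.pref_ratio / (1.0 + grp.pref_ratio),
                "true_detects": grp.pref_ratio / (1.0 + grp.pref_ratio) >= 0.75,
            })
    cols = ["assay", "subject_id", "group", "trial_index", "odorant", "value_s"]
    return pd.DataFrame(rows)[cols], pd.DataFrame(truth)
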