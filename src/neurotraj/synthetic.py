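"""Synthetic multimodal cohorts with planted class and condition effects.

The generator emulates the structure of the live-interaction study —
24 condition blocks per subject, EEG at 256 Hz, fNIRS HbDiff and facial
action units at 8.13 Hz — with a forward model whose knobs plant the effects
the analysis is meant to recover:

* EEG: band-limited oscillations (delta/theta/alpha sinusoids with random
  phases) plus Gaussian noise plus a smooth event-locked transient (Gaussian
  bump, ~0.5 s wide) at each of the four task-switch times.  Patients
  (FEP-like subjects) get larger transients; direct gaze and negative
  valence multiply the transient amplitude.
* fNIRS: a canonical double-gamma HRF convolved with a boxcar over the gaze
  segments, mixed with the low-passed EEG amplitude envelope resampled to
  the fNIRS clock (cross-modal coupling), plus noise.
* faceAU: smoothed nonnegative activations elevated during movie segments,
  plus noise.

Synthetic GAF decreases — and PANSS-positive increases — linearly in the
subject's realized transient amplitude, with Gaussian jitter, so severity
regression from classifier probabilities has a planted target.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gamma as gamma_dist

from .data_model import (
    CONDITIONS,
    DEFAULT_N_AU,
    EEG_CHANNELS,
    EEG_RATE,
    FNIRS_CHANNELS,
    FNIRS_RATE,
    Group,
    Modality,
    ModalityBlock,
    ParadigmTimeline,
    SessionRecord,
    build_timeline,
    read_session,
    samples_per_block,
    write_session,
)

__all__ = [
    "SimulationConfig",
    "generate_session",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
    "double_gamma_hrf",
    "segment_boxcar",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic forward model.

    Defaults reproduce the study conditions: 19 control-like (TD) and 14
    patient-like (FEP) subjects, native sampling rates and channel counts,
    and group/condition effects in the directions the analysis is designed
    to detect (larger switch transients in FEP, amplified under direct gaze
    and negative valence).
    """

    n_td: int = 19
    n_fep: int = 14
    seed: int = 0
    #: baseline oscillation amplitudes per EEG band (roughly 1/f ordering)
    eeg_band_power: dict[str, float] = field(
        default_factory=lambda: {"delta": 1.0, "theta": 0.8, "alpha": 0.6}
    )
    #: group-specific amplitude of switch-locked transients
    switch_transient_amp: dict[str, float] = field(
        default_factory=lambda: {"TD": 1.0, "FEP": 2.5}
    )
    gaze_effect: float = 1.3  # multiplier in direct-gaze blocks
    valence_effect: float = 1.3  # multiplier in negative-valence blocks
    coupling_strength: float = 0.4  # EEG envelope -> fNIRS mixing, in [0, 1]
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"eeg": 0.5, "fnirs": 0.3, "faceau": 0.2}
    )
    #: slope linking a subject's realized transient amplitude to GAF/PANSS
    severity_link: float = 1.0
    #: sd of per-subject multiplicative amplitude jitter (log scale)
    amp_jitter_sd: float = 0.15
    #: sd of per-subject per-channel gain idiosyncrasy (identity signal that
    #: makes random block splits optimistic relative to LOSO)
    subject_gain_sd: float = 0.15
    n_au: int = DEFAULT_N_AU
    transient_width_s: float = 0.2  # Gaussian-bump sigma (~0.5 s FWHM)

    def validate(self) -> None:
        if self.n_td < 0 or self.n_fep < 0:
            raise ValueError("subject counts must be >= 0")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        for name, val in {**self.eeg_band_power, **self.switch_transient_amp}.items():
            if val < 0:
                raise ValueError(f"amplitude '{name}' must be >= 0")
        for name, val in self.noise_sd.items():
            if val < 0:
                raise ValueError(f"noise_sd '{name}' must be >= 0")


BAND_EDGES = {"delta": (0.5, 3.0), "theta": (4.0, 7.0), "alpha": (8.0, 13.0)}


def double_gamma_hrf(rate: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak ~6 s, undershoot
    ~16 s, undershoot ratio 1/6), sampled at ``rate`` Hz, peak normalized to 1."""
    t = np.arange(0.0, duration, 1.0 / rate)
    h = gamma_dist.pdf(t, 7.0) - gamma_dist.pdf(t, 17.0) / 6.0
    return h / h.max()


def segment_boxcar(
    timeline: ParadigmTimeline, rate: float, segments: str = "gaze"
) -> np.ndarray:
    """Indicator over the named within-block segments at the given rate."""
    n = samples_per_block(rate)
    t = np.arange(n) / rate
    box = np.zeros(n)
    spans = (
        timeline.gaze_segments if segments == "gaze" else timeline.movie_segments
    )
    for a, b in spans:
        box[(t >= a) & (t < b)] = 1.0
    return box


def _switch_bumps(timeline: ParadigmTimeline, rate: float, sigma_s: float) -> np.ndarray:
    n = samples_per_block(rate)
    t = np.arange(n) / rate
    bump = np.zeros(n)
    for ts in timeline.switch_times:
        bump += np.exp(-0.5 * ((t - ts) / sigma_s) ** 2)
    return bump


def _subject_rng(master_seed: int, subject_id: str) -> np.random.Generator:
    # per-subject stream: deterministic, platform independent
    return np.random.default_rng([master_seed, zlib.crc32(subject_id.encode())])


def generate_session(
    group: Group | str,
    subject_id: str,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> SessionRecord:
    """Simulate one subject's full session (24 blocks x 3 modalities)."""
    config = config or SimulationConfig()
    config.validate()
    group = Group(group)
    rng = _subject_rng(config.seed if seed is None else seed, subject_id)
    timeline = build_timeline()

    # subject-level draws
    amp_subj = config.switch_transient_amp[group.value] * float(
        np.exp(rng.normal(0.0, config.amp_jitter_sd))
    )
    eeg_gain = np.clip(rng.normal(1.0, config.subject_gain_sd, EEG_CHANNELS), 0.2, None)
    eeg_loading = rng.uniform(0.5, 1.5, EEG_CHANNELS)
    fnirs_loading = rng.uniform(0.5, 1.5, FNIRS_CHANNELS)
    au_loading = rng.uniform(0.5, 1.5, config.n_au)

    n_eeg = samples_per_block(EEG_RATE)
    n_fast = samples_per_block(FNIRS_RATE)
    t_eeg = np.arange(n_eeg) / EEG_RATE
    bump_eeg = _switch_bumps(timeline, EEG_RATE, config.transient_width_s)
    hrf = double_gamma_hrf(FNIRS_RATE)
    gaze_box = segment_boxcar(timeline, FNIRS_RATE, "gaze")
    movie_box = segment_boxcar(timeline, FNIRS_RATE, "movie")
    hemo = np.convolve(gaze_box, hrf)[:n_fast]

    record = SessionRecord(subject_id=subject_id, group=group)
    blocks: dict[Modality, list[ModalityBlock]] = {m: [] for m in Modality}

    for idx in range(24):
        valence, gaze = CONDITIONS[idx % 4]
        amp_eff = (
            amp_subj
            * (config.gaze_effect if gaze.value == "direct" else 1.0)
            * (config.valence_effect if valence.value == "negative" else 1.0)
        )

        # --- EEG: oscillation mixture + switch transients + noise
        clean = np.zeros((n_eeg, EEG_CHANNELS))
        for band, power in config.eeg_band_power.items():
            lo, hi = BAND_EDGES[band]
            freqs = rng.uniform(lo, hi, EEG_CHANNELS)
            phases = rng.uniform(0.0, 2 * np.pi, EEG_CHANNELS)
            clean += power * np.sin(2 * np.pi * freqs * t_eeg[:, None] + phases)
        clean *= eeg_gain
        transient = amp_eff * bump_eeg[:, None] * eeg_loading
        eeg = clean + transient + rng.normal(0.0, config.noise_sd["eeg"], clean.shape)

        # --- fNIRS: HRF response to gaze + coupled EEG envelope + noise
        envelope = gaussian_filter1d(np.abs(clean + transient).mean(axis=1), EEG_RATE * 0.5)
        env_fast = np.interp(
            np.arange(n_fast) / FNIRS_RATE, t_eeg, envelope
        )
        env_fast = env_fast - env_fast.mean()
        drive = (1.0 - config.coupling_strength) * amp_eff * hemo + (
            config.coupling_strength * env_fast
        )
        fnirs = fnirs_loading * drive[:, None] + rng.normal(
            0.0, config.noise_sd["fnirs"], (n_fast, FNIRS_CHANNELS)
        )

        # --- faceAU: activation during movie segments, smoothed, rectified
        act = 0.5 + amp_eff * movie_box * (
            config.valence_effect if valence.value == "negative" else 1.0
        )
        au = au_loading * act[:, None] + rng.normal(
            0.0, config.noise_sd["faceau"], (n_fast, config.n_au)
        )
        au = np.clip(gaussian_filter1d(au, 2.0, axis=0), 0.0, None)

        for mod, data, rate in (
            (Modality.EEG, eeg, EEG_RATE),
            (Modality.FNIRS, fnirs, FNIRS_RATE),
            (Modality.FACEAU, au, FNIRS_RATE),
        ):
            blocks[mod].append(
                ModalityBlock(
                    modality=mod,
                    data=data,
                    sampling_rate=rate,
                    valence=valence,
                    gaze=gaze,
                    subject_id=subject_id,
                    block_index=idx,
                )
            )

    record.blocks = blocks
    # clinical scores: planted linear link to the realized transient amplitude
    if group is Group.FEP:
        record.gaf = float(
            np.clip(85.0 - 18.0 * config.severity_link * amp_subj + rng.normal(0, 3.0), 1, 100)
        )
        record.panss_pos = float(
            np.clip(7.0 + 6.0 * config.severity_link * amp_subj + rng.normal(0, 1.5), 7, 49)
        )
        record.panss_neg = float(
            np.clip(10.0 + 0.5 * amp_subj + rng.normal(0, 3.0), 7, 49)
        )
    record.validate()
    return record


def generate_cohort(config: SimulationConfig | None = None) -> list[SessionRecord]:
    """Simulate a full cohort (defaults: 19 TD-like + 14 FEP-like subjects)."""
    config = config or SimulationConfig()
    config.validate()
    sessions = []
    for i in range(config.n_td):
        sessions.append(generate_session(Group.TD, f"td_{i:02d}", config))
    for i in range(config.n_fep):
        sessions.append(generate_session(Group.FEP, f"fep_{i:02d}", config))
    return sessions


def write_cohort(sessions: list[SessionRecord], out_dir: str | Path) -> Path:
    """Write one HDF5 container per subject plus a cohort manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sessions:
        write_session(s, out_dir / f"{s.subject_id}.h5")
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group.value,
                "gaf": s.gaf,
                "panss_pos": s.panss_pos,
                "panss_neg": s.panss_neg,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(in_dir: str | Path) -> list[SessionRecord]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    return [read_session(in_dir / f"{sid}.h5") for sid in manifest["subject_id"]]
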