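"""Synthetic multichannel sEMG cohorts emulating a passive-stretch
spasticity protocol.

The generator reproduces the recording timeline of a clinical
spasticity examination: 2 min of rest, then three loops of three
consecutive 30-s passive flexion-extension cycles (each cycle holding
three ~10-s movements) separated by 30-s breaks, then 2 min of rest —
roughly 7 minutes per trial at 1,024 Hz.

The signal model is amplitude-modulated band-limited Gaussian noise
rather than a motor-unit simulation.  Three properties of real spastic
sEMG are planted so the analysis pipeline has genuine structure to
recover:

* grade-monotone amplitude — movement-epoch bursts are scaled by a
  strictly increasing gain per MAS grade (stronger stretch reflexes in
  more spastic muscle), with log-normal between-patient variability,
  per-channel gain jitter and per-epoch jitter providing realistic
  within-grade spread;
* grade-decreasing spectral content — the burst band's upper edge moves
  down with grade, so MPF and MF correlate negatively with MAS;
* 50 Hz powerline contamination plus a white baseline noise floor
  everywhere, which the preprocessing stage must remove.

Channels share a patient's reflex intensity but carry independent
multiplicative jitter, so fusing them averages out channel noise — the
effect the correlation-weighted fusion stage exists to exploit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .recording import (
    CHANNELS,
    GRADE_LABELS,
    EMGRecording,
    MASGrade,
    write_manifest,
    write_recording,
)


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.  Durations are in seconds, amplitudes in
    millivolts; defaults mirror the clinical protocol (2-min rests,
    3 loops x 3 x 30-s cycles, 30-s breaks, ~10-s movements) and a cohort
    of 8 patients per grade x 2 trials."""

    rate: float = 1024.0
    n_patients_per_grade: int = 8
    trials_per_patient: int = 2
    rest_duration: float = 120.0
    cycle_duration: float = 30.0
    cycles_per_loop: int = 3
    loops: int = 3
    break_duration: float = 30.0
    movement_duration: float = 10.0
    baseline_sigma: float = 0.01
    burst_gain_per_grade: tuple[float, ...] = (0.05, 0.07, 0.10, 0.14, 0.20)
    burst_band: tuple[float, float] = (30.0, 250.0)
    spectral_shift_per_grade: float = 15.0
    powerline_freq: float = 50.0
    powerline_amp: float = 0.02
    channel_gain_jitter: float = 0.10
    patient_sigma: float = 0.25
    epoch_jitter: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.rate <= 0:
            raise ConfigurationError("rate must be positive")
        n_epochs = self.cycle_duration / self.movement_duration
        if abs(n_epochs - round(n_epochs)) > 1e-9 or round(n_epochs) < 1:
            raise ConfigurationError(
                "cycle_duration must be a whole multiple of movement_duration"
            )
        for name in ("rest_duration", "cycle_duration", "break_duration",
                     "movement_duration"):
            samples = getattr(self, name) * self.rate
            if abs(samples - round(samples)) > 1e-6:
                raise ConfigurationError(
                    f"{name} does not map to a whole number of samples at "
                    f"rate {self.rate}"
                )
        gains = self.burst_gain_per_grade
        if len(gains) != len(GRADE_LABELS):
            raise ConfigurationError(
                f"burst_gain_per_grade needs {len(GRADE_LABELS)} entries"
            )
        if any(b <= a for a, b in zip(gains, gains[1:])):
            raise ConfigurationError(
                "burst_gain_per_grade must be strictly increasing with grade"
            )
        low, high = self.burst_band
        top_shift = 2 * self.spectral_shift_per_grade * (len(GRADE_LABELS) - 1)
        if not (0 < low < high - top_shift):
            raise ConfigurationError(
                "burst_band too narrow for the per-grade spectral shift"
            )
        if high >= self.rate / 2:
            raise ConfigurationError("burst_band upper edge must be below Nyquist")
        if self.loops < 1 or self.cycles_per_loop < 1:
            raise ConfigurationError("loops and cycles_per_loop must be >= 1")

    def grade_band(self, ordinal: int) -> tuple[float, float]:
        """Burst band for a grade: the upper edge drops by twice the
        centre shift per grade step, so the band centre moves down by
        ``spectral_shift_per_grade`` Hz per step."""
        low, high = self.burst_band
        return low, high - 2 * self.spectral_shift_per_grade * ordinal

    @property
    def loop_samples(self) -> int:
        return int(round(self.cycles_per_loop * self.cycle_duration * self.rate))

    @property
    def active_span_samples(self) -> int:
        """Active span: all loops plus the breaks between them."""
        return self.loops * self.loop_samples + (self.loops - 1) * int(
            round(self.break_duration * self.rate)
        )

    @property
    def total_samples(self) -> int:
        return 2 * int(round(self.rest_duration * self.rate)) + self.active_span_samples

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class SynthCohort:
    """Generated recordings with their active spans and provenance."""

    recordings: list[EMGRecording]
    spans: list[tuple[int, int]]
    config: SynthConfig

    def manifest_rows(self, paths: list[str] | None = None) -> list[dict]:
        rows = []
        for i, (rec, span) in enumerate(zip(self.recordings, self.spans)):
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "trial_index": rec.trial_index,
                    "path": paths[i] if paths else f"{rec.subject_id}_t{rec.trial_index}.csv",
                    "mas_label": rec.grade.label,
                    "span_start": span[0],
                    "span_end": span[1],
                }
            )
        return rows


def _bandlimited_noise(
    rng: np.random.Generator, n: int, rate: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band``."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, white)
    r = np.sqrt(np.mean(x**2))
    return x / r if r > 0 else x


def generate_recording(
    grade: MASGrade | str,
    config: SynthConfig,
    seed: int,
    subject_id: str = "synthetic",
    trial_index: int = 1,
    patient_factor: float | None = None,
) -> tuple[EMGRecording, tuple[int, int]]:
    """Generate one trial's 3-channel recording; returns the recording
    and the half-open active-span sample interval.

    ``patient_factor`` carries a patient's reflex-intensity multiplier
    across that patient's trials; when omitted it is drawn log-normally
    (sigma = ``config.patient_sigma``) from the seed.
    """
    config.validate()
    if not isinstance(grade, MASGrade):
        grade = MASGrade(str(grade))
    rng = np.random.default_rng(seed)
    if patient_factor is None:
        patient_factor = float(np.exp(rng.normal(0.0, config.patient_sigma)))

    rate = config.rate
    n_total = config.total_samples
    rest_n = int(round(config.rest_duration * rate))
    break_n = int(round(config.break_duration * rate))
    epoch_n = int(round(config.movement_duration * rate))
    epochs_per_cycle = int(round(config.cycle_duration / config.movement_duration))
    g = grade.ordinal
    band = config.grade_band(g)
    gain = config.burst_gain_per_grade[g] * patient_factor

    signal = np.empty((len(CHANNELS), n_total))
    taper = sps.windows.tukey(epoch_n, alpha=0.25) if epoch_n >= 8 else np.ones(epoch_n)
    span_start = rest_n
    span_end = rest_n + config.active_span_samples
    for ci in range(len(CHANNELS)):
        x = (
            rng.standard_normal(n_total) * config.baseline_sigma
            if config.baseline_sigma > 0
            else np.zeros(n_total)
        )
        channel_gain = gain * (1.0 + config.channel_gain_jitter * rng.standard_normal())
        channel_gain = max(channel_gain, 0.0)
        pos = span_start
        for loop in range(config.loops):
            for _cycle in range(config.cycles_per_loop):
                for _epoch in range(epochs_per_cycle):
                    if channel_gain > 0:
                        amp = channel_gain * max(
                            1.0 + config.epoch_jitter * rng.standard_normal(), 0.05
                        )
                        burst = _bandlimited_noise(rng, epoch_n, rate, band)
                        x[pos : pos + epoch_n] += amp * taper * burst
                    pos += epoch_n
            if loop < config.loops - 1:
                pos += break_n
        if config.powerline_amp > 0:
            t = np.arange(n_total) / rate
            phase = rng.uniform(0, 2 * np.pi)
            x += config.powerline_amp * np.sin(
                2 * np.pi * config.powerline_freq * t + phase
            )
        signal[ci] = x

    rec = EMGRecording(
        subject_id=subject_id,
        trial_index=trial_index,
        rate=rate,
        signal=signal,
        grade=grade,
    )
    return rec, (span_start, span_end)


def iter_cohort(
    config: SynthConfig,
) -> Iterator[tuple[EMGRecording, tuple[int, int]]]:
    """Lazily generate a balanced cohort: for each grade,
    ``n_patients_per_grade`` patients x ``trials_per_patient`` trials.

    Per-recording seeds are derived deterministically from
    ``config.seed``, and a patient's reflex-intensity factor is shared
    across that patient's trials.
    """
    config.validate()
    root = np.random.default_rng(config.seed)
    for g, label in enumerate(GRADE_LABELS):
        for p in range(config.n_patients_per_grade):
            patient_rng = np.random.default_rng(root.integers(2**31))
            patient_factor = float(
                np.exp(patient_rng.normal(0.0, config.patient_sigma))
            )
            subject = f"G{label.replace('+', 'p')}P{p:02d}"
            for t in range(1, config.trials_per_patient + 1):
                rec_seed = int(patient_rng.integers(2**31))
                yield generate_recording(
                    label,
                    config,
                    seed=rec_seed,
                    subject_id=subject,
                    trial_index=t,
                    patient_factor=patient_factor,
                )


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Materialize the full cohort in memory (see :func:`iter_cohort`
    for the streaming variant used by the pipeline)."""
    recs, spans = [], []
    for rec, span in iter_cohort(config):
        recs.append(rec)
        spans.append(span)
    return SynthCohort(recordings=recs, spans=spans, config=config)


def write_cohort(cohort: SynthCohort, out_dir: str | Path) -> Path:
    """Write every recording as CSV plus a manifest and provenance file;
    returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in cohort.recordings:
        name = f"{rec.subject_id}_t{rec.trial_index}.csv"
        write_recording(rec, out / name)
        paths.append(name)
    manifest_path = out / "manifest.csv"
    write_manifest(cohort.manifest_rows(paths), manifest_path)
    provenance = {
        "config": dataclasses.asdict(cohort.config),
        "config_hash": cohort.config.config_hash(),
        "seed": cohort.config.seed,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=list))
    return manifest_path
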