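"""Synthetic two-class pulse cohorts with known ground truth.

Two levels of realism are generated:

* amplitude level — per-subject 3×5 amplitude matrices drawn around
  class-conditional mean surfaces, with a block latent-factor noise
  structure (groups of H_ij cells sharing one factor each, mirroring the
  empirical grouping of the pulse amplitudes: a Cheok-heavy block, a
  light-pressure block spanning Gwan and Cheok, per-position heavy-pressure
  blocks, and a Chon-light block);

* waveform level — a raw pressure signal per (position, step): a periodic
  beat template (two asymmetric Gaussian lobes, systolic peak + dicrotic
  wave) scaled to a known foot-to-peak amplitude, plus sinusoidal baseline
  wander (breathing) and sparse motion spikes, all recorded in ground-truth
  metadata.

The excess class has its mean surface scaled up relative to the deficient
class — a forceful pulse is large over the range of hold-down pressures —
and, per subject, one randomly chosen palpation position further boosted
(the pulse is markedly strong at its optimal depth), so class separation
concentrates in pulse-pressure-like summaries, with the over-position
maximum carrying information complementary to the over-position average.
Everything is reproducible: one root seed, per-subject streams derived by
a counter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import H_COLUMNS, N_POSITIONS, N_STEPS, AmplitudeMatrix
from .metrics import DEFICIENT, EXCESS
from .waveform import PulseRecord


@dataclass(frozen=True)
class PressureProtocol:
    """Hold-down pressure staircase: five increasing steps, held constant."""

    step_means: tuple = (37.0, 73.0, 109.0, 143.0, 184.0)   # mmHg
    step_sds: tuple = (4.0, 5.0, 5.0, 7.0, 7.0)             # mmHg
    hold_seconds: float = 5.0

    def __post_init__(self) -> None:
        m = np.asarray(self.step_means, dtype=float)
        s = np.asarray(self.step_sds, dtype=float)
        if m.size != N_STEPS or s.size != N_STEPS:
            raise ValueError("protocol needs exactly 5 pressure steps")
        if not np.all(np.diff(m) > 0):
            raise ValueError("step means must be strictly increasing")
        if np.any(m <= 0) or np.any(s <= 0) or self.hold_seconds <= 0:
            raise ValueError("pressures and hold duration must be positive")


@dataclass(frozen=True)
class FactorBlock:
    """Cells (1-based (position, step) pairs) sharing one latent factor."""

    name: str
    cells: tuple
    loading: float


#: latent blocks mirroring the empirical five-factor grouping of H_ij
DEFAULT_BLOCKS = (
    FactorBlock("cheok_heavy", ((3, 3), (3, 4), (3, 5)), 0.85),
    FactorBlock("light_pressure", ((2, 1), (2, 2), (3, 1), (3, 2)), 0.75),
    FactorBlock("chon_heavy", ((1, 3), (1, 4), (1, 5)), 0.80),
    FactorBlock("gwan_heavy", ((2, 3), (2, 4), (2, 5)), 0.80),
    FactorBlock("chon_light", ((1, 1), (1, 2)), 0.85),
)

#: deficient-class mean amplitude surface (arb): the optimal depth is
#: shallow at Chon, intermediate at Gwan, deep at Cheok
DEFAULT_DEFICIENT_PROFILE = np.array([
    [10.0, 12.0, 9.0, 6.0, 4.0],
    [9.0, 12.0, 12.0, 9.0, 6.0],
    [6.0, 9.0, 12.0, 13.0, 10.0],
])
#: excess = mildly scaled-up deficient surface (forceful over all pressures) …
DEFAULT_EXCESS_SCALE = 1.05
#: … plus a focal boost of one randomly chosen position's row per excess
#: subject: a forceful pulse is markedly strong at its optimal depth, which
#: shows in PP^max beyond what <PP> already captures
DEFAULT_FOCAL_TILT = 0.6
#: within-class amplitude noise SD (arb); the default separation/noise pair is
#: calibrated so a single-cut classifier on <PP> reaches ~75% LOOCV accuracy
DEFAULT_NOISE_SD = 4.5


@dataclass(frozen=True)
class CohortSpec:
    """Amplitude-level cohort description with a block factor structure."""

    n_subjects: int = 70
    prevalence_excess: float = 44.0 / 70.0
    deficient_profile: np.ndarray = field(
        default_factory=lambda: DEFAULT_DEFICIENT_PROFILE.copy())
    excess_profile: np.ndarray | None = None     # default: scale × deficient
    excess_scale: float = DEFAULT_EXCESS_SCALE
    focal_tilt: float = DEFAULT_FOCAL_TILT
    blocks: tuple = DEFAULT_BLOCKS
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_excess < 1:
            raise ValueError("prevalence_excess must lie strictly in (0, 1)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        dp = np.asarray(self.deficient_profile, dtype=float)
        if dp.shape != (N_POSITIONS, N_STEPS) or (dp < 0).any():
            raise ValueError("deficient profile must be a non-negative 3x5 surface")
        object.__setattr__(self, "deficient_profile", dp)
        ep = (np.asarray(self.excess_profile, dtype=float)
              if self.excess_profile is not None else self.excess_scale * dp)
        if ep.shape != (N_POSITIONS, N_STEPS) or (ep < 0).any():
            raise ValueError("excess profile must be a non-negative 3x5 surface")
        object.__setattr__(self, "excess_profile", ep)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.focal_tilt < 0:
            raise ValueError("focal_tilt must be non-negative")
        self._validate_blocks()

    def _validate_blocks(self) -> None:
        seen: dict[tuple, str] = {}
        for blk in self.blocks:
            if not 0 <= blk.loading < 1:
                raise ValueError(
                    f"block {blk.name!r}: loading {blk.loading} makes the implied "
                    "15x15 correlation matrix non-positive-definite "
                    "(|loading| must be < 1)")
            for cell in blk.cells:
                i, j = cell
                if not (1 <= i <= N_POSITIONS and 1 <= j <= N_STEPS):
                    raise ValueError(f"block {blk.name!r}: cell {cell} out of range")
                if cell in seen:
                    raise ValueError(
                        f"blocks {seen[cell]!r} and {blk.name!r} overlap at cell "
                        f"{cell}: overlapping blocks make the correlation "
                        "specification non-positive-definite here")
                seen[cell] = blk.name
        R = self.implied_correlation()
        eigmin = float(np.linalg.eigvalsh(R).min())
        if eigmin <= 0:
            raise ValueError(
                f"implied correlation matrix is non-positive-definite "
                f"(min eigenvalue {eigmin:.3g}); check block loadings")

    def implied_correlation(self) -> np.ndarray:
        """The 15×15 noise correlation matrix the block structure implies
        (within-block correlation loading², zero between blocks)."""
        R = np.eye(N_POSITIONS * N_STEPS)
        flat = {(i, j): (i - 1) * N_STEPS + (j - 1)
                for i in range(1, N_POSITIONS + 1) for j in range(1, N_STEPS + 1)}
        for blk in self.blocks:
            idx = [flat[c] for c in blk.cells]
            for a in idx:
                for b in idx:
                    if a != b:
                        R[a, b] = blk.loading ** 2
        return R


def _subject_rng(seed: int, counter: int) -> np.random.Generator:
    return np.random.default_rng([seed, counter])


def simulate_amplitude_cohort(spec: CohortSpec) -> tuple[list[str], list[AmplitudeMatrix]]:
    """Draw a labelled cohort of 3×5 amplitude matrices.

    Class labels are assigned by quota (round(n·prevalence) excess) and
    shuffled under the root seed; each subject's noise comes from its own
    counter-derived stream, so subsetting a cohort is reproducible.
    Amplitudes are truncated at zero (additive Gaussian noise otherwise).
    """
    n = spec.n_subjects
    n_excess = int(round(n * spec.prevalence_excess))
    n_excess = min(max(n_excess, 1), n - 1) if n >= 2 else n_excess
    labels = np.array([EXCESS] * n_excess + [DEFICIENT] * (n - n_excess))
    _subject_rng(spec.seed, 2 ** 20).shuffle(labels)

    flat_block: dict[tuple, tuple[int, float]] = {}
    for b_idx, blk in enumerate(spec.blocks):
        for cell in blk.cells:
            flat_block[cell] = (b_idx, blk.loading)

    matrices = []
    for s_idx in range(n):
        rng = _subject_rng(spec.seed, s_idx)
        factors = rng.standard_normal(len(spec.blocks))
        eps = rng.standard_normal((N_POSITIONS, N_STEPS))
        noise = np.empty((N_POSITIONS, N_STEPS))
        for i in range(1, N_POSITIONS + 1):
            for j in range(1, N_STEPS + 1):
                if (i, j) in flat_block:
                    b_idx, lam = flat_block[(i, j)]
                    noise[i - 1, j - 1] = (lam * factors[b_idx]
                                           + np.sqrt(1 - lam ** 2) * eps[i - 1, j - 1])
                else:
                    noise[i - 1, j - 1] = eps[i - 1, j - 1]
        if labels[s_idx] == EXCESS:
            profile = spec.excess_profile.copy()
            if spec.focal_tilt > 0:
                # forceful at the subject's optimal position: one row boosted
                profile[rng.integers(N_POSITIONS)] *= 1.0 + spec.focal_tilt
        else:
            profile = spec.deficient_profile
        H = np.maximum(profile + spec.noise_sd * noise, 0.0)
        matrices.append(AmplitudeMatrix(H, subject_id=f"S{s_idx:04d}"))
    return list(labels), matrices


@dataclass(frozen=True)
class WaveformSpec:
    """Raw-signal realism knobs for one simulated record."""

    sampling_rate: float = 200.0        # Hz
    heart_rate: float = 70.0            # beats/min
    peak_time: float = 0.30             # systolic peak position, beat fraction
    rise_width: float = 0.10            # left lobe width, beat fraction
    fall_width: float = 0.18            # right lobe width, beat fraction
    dicrotic_time: float = 0.62         # dicrotic wave position, beat fraction
    dicrotic_width: float = 0.10
    dicrotic_height: float = 0.22       # relative to systolic peak
    baseline_wander_amp: float = 2.0    # arb
    baseline_wander_freq: float = 0.25  # Hz (breathing)
    spike_rate: float = 1.0             # expected motion artifacts per record
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 100:
            raise ValueError("sampling_rate must be at least 100 Hz")
        if not 30 < self.heart_rate < 200:
            raise ValueError("heart_rate must lie in (30, 200) bpm")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be non-negative")


def _beat_template(phase: np.ndarray, spec: WaveformSpec) -> np.ndarray:
    """Two-lobe beat shape on phase ∈ [0, 1), normalized to [0, 1]."""
    def raw(p):
        width = np.where(p < spec.peak_time, spec.rise_width, spec.fall_width)
        main = np.exp(-0.5 * ((p - spec.peak_time) / width) ** 2)
        dic = spec.dicrotic_height * np.exp(
            -0.5 * ((p - spec.dicrotic_time) / spec.dicrotic_width) ** 2)
        return main + dic

    dense = raw(np.linspace(0.0, 1.0, 2001))
    lo, hi = dense.min(), dense.max()
    return (raw(np.asarray(phase)) - lo) / (hi - lo)


def simulate_pulse_record(spec: WaveformSpec, protocol: PressureProtocol,
                          true_amplitude: float, position: int = 1,
                          step: int = 1, rng: np.random.Generator | None = None
                          ) -> PulseRecord:
    """One raw record: beat train of known amplitude + wander + spikes.

    With zero wander and zero spikes the beat foot-to-peak excursion equals
    ``true_amplitude`` up to interpolation error.  Ground truth (amplitude,
    spike sample indices, wander parameters) is stored in ``meta``.
    """
    if true_amplitude < 0:
        raise ValueError("true_amplitude must be non-negative")
    samples_per_beat = spec.sampling_rate * 60.0 / spec.heart_rate
    if samples_per_beat < 20:
        raise ValueError(
            f"sampling too coarse: {samples_per_beat:.1f} samples/beat < 20")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = int(round(protocol.hold_seconds * spec.sampling_rate))
    t = np.arange(n) / spec.sampling_rate
    phase = (t * spec.heart_rate / 60.0) % 1.0
    signal = true_amplitude * _beat_template(phase, spec)
    wander_phase = rng.uniform(0, 2 * np.pi)
    signal = signal + spec.baseline_wander_amp * np.sin(
        2 * np.pi * spec.baseline_wander_freq * t + wander_phase)
    n_spikes = rng.poisson(spec.spike_rate)
    spike_idx = np.sort(rng.choice(n, size=min(n_spikes, n), replace=False)) \
        if n_spikes else np.empty(0, dtype=int)
    for idx in spike_idx:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        signal[idx] += sign * rng.uniform(4.0, 8.0) * max(true_amplitude, 1.0)
    applied = float(protocol.step_means[step - 1])
    meta = {
        "true_amplitude": float(true_amplitude),
        "n_spikes": int(spike_idx.size),
        "spike_indices": [int(i) for i in spike_idx],
        "wander_amp": spec.baseline_wander_amp,
        "wander_freq": spec.baseline_wander_freq,
    }
    return PulseRecord(time=t, signal=signal, position=position, step=step,
                       applied_pressure=applied, meta=meta)


def simulate_subject_records(cohort_spec: CohortSpec, wf_spec: WaveformSpec,
                             protocol: PressureProtocol, subject_index: int,
                             matrix: AmplitudeMatrix) -> list[PulseRecord]:
    """The 15 raw records of one subject, cell amplitudes from its H matrix."""
    rng = _subject_rng(cohort_spec.seed, 2 ** 21 + subject_index)
    records = []
    for i in range(1, N_POSITIONS + 1):
        for j in range(1, N_STEPS + 1):
            records.append(simulate_pulse_record(
                wf_spec, protocol, float(matrix.H[i - 1, j - 1]),
                position=i, step=j, rng=rng))
    return records


# ---------------------------------------------------------------------------
# CSV interfaces

def write_cohort_csv(labels, matrices, path) -> None:
    """Amplitude cohort schema: subject_id,label,H11..H35 (position-major)."""
    rows = [{"subject_id": m.subject_id, "label": lab,
             **{c: v for c, v in zip(H_COLUMNS, m.H.ravel())}}
            for lab, m in zip(labels, matrices)]
    pd.DataFrame(rows, columns=["subject_id", "label", *H_COLUMNS]).to_csv(
        path, index=False)


def read_cohort_csv(path) -> tuple[list[str], list[AmplitudeMatrix]]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in ("subject_id", "label", *H_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    matrices = [AmplitudeMatrix(
        np.asarray(row[list(H_COLUMNS)], dtype=float).reshape(N_POSITIONS, N_STEPS),
        subject_id=str(row["subject_id"])) for _, row in df.iterrows()]
    return [str(v) for v in df["label"]], matrices


def write_waveform_csv(record: PulseRecord, directory, subject_id: str) -> Path:
    """One CSV per (subject, position, step): columns time_s,signal_arb."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"subj{subject_id}_pos{record.position}_step{record.step}.csv"
    pd.DataFrame({"time_s": record.time, "signal_arb": record.signal}).to_csv(
        path, index=False)
    return path


def read_waveform_csv(path, position: int | None = None, step: int | None = None,
                      applied_pressure: float = float("nan")) -> PulseRecord:
    """Read a waveform CSV; position/step default to the filename pattern."""
    path = Path(path)
    if position is None or step is None:
        import re
        m = re.search(r"pos(\d+)_step(\d+)", path.stem)
        if not m:
            raise ValueError(f"cannot infer (position, step) from {path.name}")
        position, step = int(m.group(1)), int(m.group(2))
    df = pd.read_csv(path)
    return PulseRecord(time=df["time_s"].to_numpy(float),
                       signal=df["signal_arb"].to_numpy(float),
                       position=position, step=step,
                       applied_pressure=applied_pressure)
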