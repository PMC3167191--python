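"""Preprocessing of raw radial-pulse records into pulse amplitudes.

A record is one uniformly sampled pressure signal, held for a few seconds at
one palpation position and one hold-down pressure step.  The chain is:

1. despike — samples whose first difference is an outlier (in robust-SD
   units of the record's first differences) are replaced by the nearest
   unflagged neighbour value;
2. remove_baseline — a least-squares 5th-order polynomial over the full
   record is subtracted, then a natural cubic spline through the beat-foot
   anchors of the residual, pinning the beat feet to zero;
3. segment_periods — beats are delimited foot-to-foot around detected
   systolic peaks (refractory window caps the admissible heart rate), each
   beat resampled to a common length, and ensemble-averaged;
4. pulse_amplitude — H = max − min of the ensemble-mean beat.

Repeating the chain over the 15 (position, step) records of a subject
assembles the 3×5 amplitude matrix H_ij.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .features import N_POSITIONS, N_STEPS, AmplitudeMatrix

#: beats are resampled to this many samples before ensemble averaging
BEAT_RESAMPLE_LENGTH = 100
#: minimum spacing between detected systolic peaks (s); caps HR at 200 bpm
REFRACTORY_SECONDS = 0.3
DEFAULT_SPIKE_K = 6.0


@dataclass(frozen=True)
class PulseRecord:
    """One uniformly sampled pulse waveform at (position i, pressure step j)."""

    time: np.ndarray          # seconds, uniform grid from 0
    signal: np.ndarray        # pressure amplitude (arb)
    position: int             # 1=Chon, 2=Gwan, 3=Cheok
    step: int                 # 1 (lightest) .. 5 (heaviest)
    applied_pressure: float   # mmHg
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or t.shape != s.shape or t.size < 2:
            raise ValueError("time and signal must be equal-length 1-D arrays")
        dt = np.diff(t)
        if not np.all(dt > 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(s)):
            raise ValueError("signal contains non-finite samples")
        if not 1 <= self.position <= N_POSITIONS:
            raise ValueError(f"position must be 1..{N_POSITIONS}")
        if not 1 <= self.step <= N_STEPS:
            raise ValueError(f"step must be 1..{N_STEPS}")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)

    @property
    def fs(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class BeatEnsemble:
    """Equal-length resampled single beats and their pointwise mean."""

    beats: np.ndarray        # (n_beats, BEAT_RESAMPLE_LENGTH)
    mean_beat: np.ndarray

    def __post_init__(self) -> None:
        b = np.atleast_2d(np.asarray(self.beats, dtype=float))
        if b.shape[0] < 1:
            raise ValueError("ensemble needs at least one beat")
        object.__setattr__(self, "beats", b)
        object.__setattr__(self, "mean_beat", np.asarray(self.mean_beat, dtype=float))
        if self.mean_beat.shape != (b.shape[1],):
            raise ValueError("mean_beat length must match beat length")

    @property
    def n_beats(self) -> int:
        return self.beats.shape[0]

    @classmethod
    def from_beats(cls, beats) -> "BeatEnsemble":
        b = np.atleast_2d(np.asarray(beats, dtype=float))
        return cls(beats=b, mean_beat=b.mean(axis=0))


def despike(record: PulseRecord, k: float = DEFAULT_SPIKE_K) -> PulseRecord:
    """Replace abrupt-variation samples by their nearest unflagged neighbour.

    A sample is flagged when the first difference into it exceeds ``k``
    robust SDs (median absolute deviation / 0.6745) of the record's first
    differences.  Rejects records with more than half their samples flagged.
    """
    if k <= 0:
        raise ValueError("spike threshold k must be positive")
    x = record.signal.copy()
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = mad / 0.6745
    if sigma == 0:
        sigma = np.std(d) or np.finfo(float).tiny
    big = np.abs(d) > k * sigma
    # a jump into sample i+1 flags sample i+1
    flagged = np.zeros(x.size, dtype=bool)
    flagged[1:] = big
    # isolated spike: jump up into it and jump down out of it — the sample
    # after the spike is flagged by the return jump; unflag it when it agrees
    # with the pre-spike level so only the spike itself is replaced
    for i in np.nonzero(flagged)[0]:
        if 0 < i < x.size - 1 and flagged[i] and i + 1 < x.size and flagged[i + 1]:
            if abs(x[i + 1] - x[i - 1]) <= k * sigma:
                flagged[i + 1] = False
    n_flagged = int(flagged.sum())
    if n_flagged > 0.5 * x.size:
        raise ValueError(
            f"record unusable: {n_flagged}/{x.size} samples flagged as spikes")
    if n_flagged:
        good = np.nonzero(~flagged)[0]
        bad = np.nonzero(flagged)[0]
        nearest = good[np.abs(good[None, :] - bad[:, None]).argmin(axis=1)]
        x[bad] = x[nearest]
    meta = dict(record.meta)
    meta["despiked"] = True
    meta["n_flagged"] = n_flagged
    return replace(record, signal=x, meta=meta)


def _foot_anchors(x: np.ndarray, fs: float) -> np.ndarray:
    """Indices of beat feet: local minima between successive systolic peaks,
    plus edge minima before the first / after the last peak when those
    regions are long enough to contain a genuine foot."""
    distance = max(int(REFRACTORY_SECONDS * fs), 1)
    prominence = 0.25 * (np.percentile(x, 95) - np.percentile(x, 5))
    peaks, _ = find_peaks(x, distance=distance, prominence=prominence)
    if peaks.size < 2:
        return np.empty(0, dtype=int)
    feet = [int(np.argmin(x[a:b])) + a for a, b in zip(peaks[:-1], peaks[1:])]
    period = float(np.median(np.diff(peaks)))
    if peaks[0] >= 0.25 * period:
        feet.insert(0, int(np.argmin(x[:peaks[0]])))
    tail_start = peaks[-1]
    if (x.size - 1 - tail_start) >= 0.25 * period:
        feet.append(int(np.argmin(x[tail_start:])) + tail_start)
    return np.asarray(sorted(set(feet)), dtype=int)


def remove_baseline(record: PulseRecord) -> PulseRecord:
    """Polynomial-plus-spline baseline correction pinning beat feet to zero.

    A 5th-order polynomial trend is estimated on the beat-foot anchor values
    (the degree drops when few anchors are available) and subtracted; a
    natural cubic spline through the residual anchors removes what the
    polynomial missed, leaving every anchored foot exactly at zero.  Because
    both stages are fitted to the foot values only, a record whose feet
    already sit at zero passes through unchanged — the correction is
    idempotent — and the beat shape between feet is never absorbed into the
    baseline estimate.

    With fewer than 4 anchors (e.g. no discernible beats) the anchored
    stages are replaced by a full-record least-squares polynomial with a
    warning, and ``meta['spline_skipped']`` is set.
    """
    t, x = record.time, record.signal
    meta = dict(record.meta)
    feet = _foot_anchors(x, record.fs)
    if feet.size >= 4:
        deg = min(5, feet.size - 2)
        trend = np.polynomial.Polynomial.fit(t[feet], x[feet], deg=deg)
        resid = x - trend(t)
        spline = CubicSpline(t[feet], resid[feet], bc_type="natural")
        resid = resid - spline(t)
        meta["spline_skipped"] = False
    else:
        warnings.warn("fewer than 4 beat-foot anchors: spline stage skipped, "
                      "polynomial-only baseline correction")
        trend = np.polynomial.Polynomial.fit(t, x, deg=5)  # scaled domain
        resid = x - trend(t)
        meta["spline_skipped"] = True
    meta["baseline_removed"] = True
    meta["n_anchors"] = int(feet.size)
    return replace(record, signal=resid, meta=meta)


def segment_periods(record: PulseRecord) -> BeatEnsemble:
    """Delimit beats foot-to-foot, resample each to a common length, average."""
    x, fs = record.signal, record.fs
    distance = max(int(REFRACTORY_SECONDS * fs), 1)
    prominence = 0.25 * (np.percentile(x, 95) - np.percentile(x, 5))
    peaks, _ = find_peaks(x, distance=distance, prominence=prominence)
    if peaks.size == 0:
        raise ValueError("no pulse peaks detected: cannot segment periods")
    feet = _foot_anchors(x, fs)
    if feet.size >= 2:
        segments = [(a, b) for a, b in zip(feet[:-1], feet[1:]) if b - a >= 4]
        if len(segments) >= 2:
            # drop fragments (e.g. a sliver before the first full beat)
            med = float(np.median([b - a for a, b in segments]))
            segments = [(a, b) for a, b in segments if (b - a) >= 0.7 * med]
    else:
        segments = [(0, x.size - 1)]       # single usable beat: whole record
    if not segments:
        segments = [(0, x.size - 1)]
    beats = []
    grid = np.linspace(0.0, 1.0, BEAT_RESAMPLE_LENGTH)
    for a, b in segments:
        seg = x[a:b + 1]
        beats.append(np.interp(grid, np.linspace(0.0, 1.0, seg.size), seg))
    beats = np.vstack(beats)
    if beats.shape[0] > 1:
        # align systolic peaks before averaging so that slightly truncated
        # boundary beats do not smear the ensemble peak; the circular shift
        # only wraps flat foot-region samples
        peak_idx = beats.argmax(axis=1)
        target = int(np.median(peak_idx))
        beats = np.vstack([np.roll(row, target - idx)
                           for row, idx in zip(beats, peak_idx)])
    return BeatEnsemble.from_beats(beats)


def pulse_amplitude(ensemble: BeatEnsemble) -> float:
    """Pulse amplitude H = max − min of the ensemble-mean beat (arb, ≥ 0)."""
    mb = ensemble.mean_beat
    return float(mb.max() - mb.min())


def process_record(record: PulseRecord, k: float = DEFAULT_SPIKE_K) -> float:
    """Full chain despike → baseline → segmentation → amplitude."""
    return pulse_amplitude(segment_periods(remove_baseline(despike(record, k=k))))


def extract_amplitude_matrix(records, subject_id: str = "anon",
                             k: float = DEFAULT_SPIKE_K) -> AmplitudeMatrix:
    """Assemble the 3×5 H_ij matrix from one subject's 15 records.

    Records are keyed by (position, step); duplicates or missing cells are
    an error (cells are never imputed), and any record failing the chain
    rejects the whole subject with the offending cell listed.
    """
    by_cell: dict[tuple[int, int], PulseRecord] = {}
    for rec in records:
        key = (rec.position, rec.step)
        if key in by_cell:
            raise ValueError(f"duplicate record for cell (position, step) = {key}")
        by_cell[key] = rec
    expected = {(i, j) for i in range(1, N_POSITIONS + 1)
                for j in range(1, N_STEPS + 1)}
    missing = sorted(expected - set(by_cell))
    if missing:
        raise ValueError(f"missing records for cells: {missing}")
    H = np.zeros((N_POSITIONS, N_STEPS))
    failures = []
    for (i, j), rec in by_cell.items():
        try:
            H[i - 1, j - 1] = process_record(rec, k=k)
        except ValueError as err:
            failures.append(((i, j), str(err)))
    if failures:
        cells = [c for c, _ in failures]
        raise ValueError(f"subject {subject_id!r} rejected; failing cells "
                         f"{cells}: {failures[0][1]}")
    return AmplitudeMatrix(H, subject_id=subject_id)
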