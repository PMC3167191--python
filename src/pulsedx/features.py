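"""Pulse quantities derived from the 3×5 amplitude matrix.

For each subject the device yields the pulse amplitude H_ij at palpation
position i (1 = Chon, 2 = Gwan, 3 = Cheok) and hold-down pressure step j
(1 = lightest … 5 = heaviest).  Per position:

    PP_i  = max_j H_ij     (pulse pressure — proxy for systolic−diastolic)
    MPA_i = mean_j H_ij    (mean pulse amplitude)

and over the three positions the aggregates ⟨PP⟩, PP^max, ⟨MPA⟩, MPA^max.
The max and mean are exact; device discretisation is the only reason the
field literature writes them with "≈".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import CLASSES

N_POSITIONS = 3
N_STEPS = 5
POSITION_NAMES = ("Chon", "Gwan", "Cheok")

#: H-matrix column names in the cohort CSV schema, position-major.
H_COLUMNS = tuple(f"H{i}{j}" for i in range(1, N_POSITIONS + 1) for j in range(1, N_STEPS + 1))
SUMMARY_COLUMNS = (
    "PP1", "PP2", "PP3", "MPA1", "MPA2", "MPA3",
    "PP_avg", "PP_max", "MPA_avg", "MPA_max",
)
FEATURE_COLUMNS = H_COLUMNS + SUMMARY_COLUMNS


@dataclass(frozen=True)
class AmplitudeMatrix:
    """Per-subject pulse-amplitude surface H_ij, 3 positions × 5 steps (arb)."""

    H: np.ndarray
    subject_id: str = "anon"

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float)
        if H.shape != (N_POSITIONS, N_STEPS):
            raise ValueError(f"amplitude matrix must be 3x5, got {H.shape}")
        if not np.all(np.isfinite(H)):
            raise ValueError("amplitude matrix contains non-finite entries")
        if (H < 0).any():
            raise ValueError("pulse amplitudes must be non-negative")
        object.__setattr__(self, "H", H)


@dataclass(frozen=True)
class PulseSummary:
    """The per-position and over-position pulse quantities of one subject."""

    PP: np.ndarray      # per-position pulse pressure, length 3
    MPA: np.ndarray     # per-position mean pulse amplitude, length 3
    PP_avg: float
    PP_max: float
    MPA_avg: float
    MPA_max: float

    def as_dict(self) -> dict[str, float]:
        d = {f"PP{i+1}": float(self.PP[i]) for i in range(N_POSITIONS)}
        d.update({f"MPA{i+1}": float(self.MPA[i]) for i in range(N_POSITIONS)})
        d.update(PP_avg=self.PP_avg, PP_max=self.PP_max,
                 MPA_avg=self.MPA_avg, MPA_max=self.MPA_max)
        return d


def summarize(matrix: AmplitudeMatrix) -> PulseSummary:
    """Compute PP_i, MPA_i and their over-position average/maximum."""
    H = matrix.H
    PP = H.max(axis=1)
    MPA = H.mean(axis=1)
    return PulseSummary(
        PP=PP, MPA=MPA,
        PP_avg=float(PP.mean()), PP_max=float(PP.max()),
        MPA_avg=float(MPA.mean()), MPA_max=float(MPA.max()),
    )


def standardize(values) -> np.ndarray:
    """z-scores over a cohort: mean 0, sample SD 1 (n−1 denominator).

    Raises on fewer than two values or zero variance.  Affine transforms
    a·x+b (a>0) of the input leave the output unchanged.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize needs a 1-D cohort of at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize")
    return (x - x.mean()) / sd


def feature_table(matrices, labels) -> pd.DataFrame:
    """Assemble the per-subject analysis table for a cohort.

    One row per subject: subject_id, label, H11..H35, then the ten summary
    columns (PP1..3, MPA1..3, PP_avg, PP_max, MPA_avg, MPA_max).
    """
    matrices = list(matrices)
    labels = list(labels)
    if len(matrices) != len(labels):
        raise ValueError("matrices and labels differ in length")
    for lab in labels:
        if lab not in CLASSES:
            raise ValueError(f"unknown label {lab!r}")
    ids = [m.subject_id for m in matrices]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    rows = []
    for m, lab in zip(matrices, labels):
        row: dict[str, object] = {"subject_id": m.subject_id, "label": lab}
        row.update({c: v for c, v in zip(H_COLUMNS, m.H.ravel())})
        row.update(summarize(m).as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "label", *FEATURE_COLUMNS])


def table_to_matrices(df: pd.DataFrame) -> tuple[list[AmplitudeMatrix], list[str]]:
    """Inverse of :func:`feature_table` for the H columns."""
    matrices = [
        AmplitudeMatrix(np.asarray(row[list(H_COLUMNS)], dtype=float).reshape(3, 5),
                        subject_id=str(row["subject_id"]))
        for _, row in df.iterrows()
    ]
    return matrices, [str(v) for v in df["label"]]


def write_feature_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in ("subject_id", "label", *H_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV missing columns: {missing}")
    return df


def plot_amplitude_curves(matrix: AmplitudeMatrix, pressures=None, ax=None):
    """Diagnostic H-versus-applied-pressure plot, one curve per position."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(pressures, dtype=float) if pressures is not None else np.arange(1, N_STEPS + 1)
    for i, name in enumerate(POSITION_NAMES):
        ax.plot(x, matrix.H[i], marker="o", label=name)
    ax.set_xlabel("applied pressure (mmHg)" if pressures is not None else "pressure step")
    ax.set_ylabel("pulse amplitude H (arb)")
    ax.set_title(f"subject {matrix.subject_id}")
    ax.legend()
    return ax
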