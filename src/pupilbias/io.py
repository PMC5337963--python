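"""Trial-table and eye-recording I/O.

The package's tabular currency is a plain :class:`pandas.DataFrame` with one
row per trial ("trial table") and a light :class:`EyeRecording` container for
continuous eye-tracker data (pupil area plus gaze, uniformly sampled, with an
event list marking trial landmarks and artifacts).

Trial tables are stored as comma-separated UTF-8 CSV with a canonical column
order and '.' decimals; eye recordings as two TSV files (samples and events).
All times are seconds from block start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical trial-table column order.
TRIAL_COLUMNS = [
    "session", "block", "trial",
    "stim_category", "coherence_diff",
    "evidence", "evidence_strength",
    "choice", "correct", "rt",
    "pupil_baseline", "pupil_response",
    "t_ref_on", "t_test_on", "t_test_off", "t_response", "t_feedback",
]

#: Columns that may be empty (NaN) before pupil preprocessing has run.
OPTIONAL_COLUMNS = {"pupil_baseline", "pupil_response"}

#: Recognized event kinds in an eye recording.
EVENT_KINDS = {
    "ref_on", "test_on", "test_off", "response", "feedback",
    "blink_start", "blink_end", "saccade_start", "saccade_end",
    "block_start",
}

#: Maximum allowed response time (observers had 3 s to respond).
RT_MAX = 3.0

_TIME_TOL = 1e-6


class SchemaError(ValueError):
    """A required column is missing or has the wrong dtype."""


class ValidationError(ValueError):
    """A row violates a trial-table invariant."""


def validate_trial_table(df: pd.DataFrame) -> None:
    """Validate trial-table invariants, raising on the first violation.

    Checks domain constraints (binary codes, positive RT), the consistency
    invariants ``correct == (choice == stim_category)`` and
    ``evidence_strength == |evidence|``, and the within-trial event ordering
    ref_on < test_on < test_off <= response < feedback with
    ``rt == t_response - t_test_off`` and ``0 < rt <= 3``.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        return

    def _bad(mask: np.ndarray, msg: str) -> None:
        mask = np.asarray(mask)
        if mask.any():
            idx = int(np.flatnonzero(mask)[0])
            raise ValidationError(f"row {df.index[idx]}: {msg}")

    _bad(df["session"].to_numpy() < 1, "session must be >= 1")
    _bad(df["block"].to_numpy() < 1, "block must be >= 1")
    _bad(df["trial"].to_numpy() < 0, "trial must be >= 0")
    _bad(~df["stim_category"].isin([-1, 1]).to_numpy(),
         "stim_category must be +1 or -1")
    _bad(~df["choice"].isin([-1, 1]).to_numpy(), "choice must be +1 or -1")
    _bad(~df["correct"].isin([0, 1]).to_numpy(), "correct must be 0 or 1")
    _bad(df["correct"].to_numpy()
         != (df["choice"].to_numpy() == df["stim_category"].to_numpy()),
         "correct must equal (choice == stim_category)")
    _bad(~np.isclose(df["evidence_strength"].to_numpy(),
                     np.abs(df["evidence"].to_numpy()), atol=1e-9),
         "evidence_strength must equal |evidence|")

    t = {c: df[c].to_numpy(float) for c in
         ("t_ref_on", "t_test_on", "t_test_off", "t_response", "t_feedback")}
    _bad(t["t_ref_on"] >= t["t_test_on"] - _TIME_TOL,
         "t_ref_on must precede t_test_on")
    _bad(t["t_test_on"] >= t["t_test_off"] - _TIME_TOL,
         "t_test_on must precede t_test_off")
    _bad(t["t_test_off"] > t["t_response"] + _TIME_TOL,
         "t_test_off must not exceed t_response")
    _bad(t["t_response"] >= t["t_feedback"] - _TIME_TOL,
         "t_response must precede t_feedback")

    rt = df["rt"].to_numpy(float)
    _bad(~np.isclose(rt, t["t_response"] - t["t_test_off"], atol=1e-6),
         "rt must equal t_response - t_test_off")
    _bad((rt <= 0) | (rt > RT_MAX + _TIME_TOL),
         f"rt must lie in (0, {RT_MAX}]")


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV, sorted by (session, block, trial)."""
    df = pd.read_csv(path, float_precision="round_trip")
    validate_trial_table(df)
    df = df.sort_values(["session", "block", "trial"], kind="stable")
    return df.reset_index(drop=True)[TRIAL_COLUMNS]


def write_trial_table(df: pd.DataFrame, path) -> None:
    """Write a validated trial table as CSV in canonical column order."""
    validate_trial_table(df)
    df[TRIAL_COLUMNS].to_csv(path, index=False, float_format="%.17g")


@dataclass
class EyeRecording:
    """Continuous eye-tracker recording: uniformly sampled samples + events.

    Attributes
    ----------
    time, pupil, gaze_x, gaze_y : ndarray
        Uniformly sampled at ``rate`` Hz; pupil in arbitrary tracker units.
    rate : float
        Sampling rate in Hz.
    events : DataFrame with columns (t, kind, label)
        Time-ordered markers; ``kind`` in :data:`EVENT_KINDS`.
    interp_mask : ndarray of bool, optional
        Per-sample flag marking interpolated (artifactual) samples; filled
        in by preprocessing.
    """

    time: np.ndarray
    pupil: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    rate: float
    events: pd.DataFrame
    interp_mask: np.ndarray | None = field(default=None)

    def __post_init__(self):
        n = len(self.time)
        for name in ("pupil", "gaze_x", "gaze_y"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from time")
        if self.interp_mask is None:
            self.interp_mask = np.zeros(n, dtype=bool)

    def events_of_kind(self, kind: str) -> np.ndarray:
        return self.events.loc[self.events["kind"] == kind, "t"].to_numpy(float)

    def copy(self) -> "EyeRecording":
        return EyeRecording(
            self.time.copy(), self.pupil.copy(), self.gaze_x.copy(),
            self.gaze_y.copy(), self.rate, self.events.copy(),
            self.interp_mask.copy(),
        )


def read_eye_recording(samples_path, events_path) -> EyeRecording:
    """Read TSV samples (t, pupil, gx, gy) and events (t, kind, label).

    The sampling rate is inferred from the sample times; non-uniform sampling
    or out-of-order events raise ``ValueError`` naming the first bad entry.
    """
    samples = pd.read_csv(samples_path, sep="\t")
    events = pd.read_csv(events_path, sep="\t", keep_default_na=False)
    for col in ("t", "pupil", "gx", "gy"):
        if col not in samples.columns:
            raise SchemaError(f"samples file missing column {col!r}")
    for col in ("t", "kind", "label"):
        if col not in events.columns:
            raise SchemaError(f"events file missing column {col!r}")

    t = samples["t"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("need at least two samples to infer a rate")
    dt = np.diff(t)
    step = np.median(dt)
    bad = np.flatnonzero(np.abs(dt - step) > 0.01 * step)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"non-uniform sampling: interval {dt[i]:.6f}s between samples "
            f"{i} and {i + 1} (expected {step:.6f}s)")

    et = events["t"].to_numpy(float)
    if np.any(np.diff(et) < 0):
        i = int(np.flatnonzero(np.diff(et) < 0)[0])
        raise ValueError(f"events out of order at row {i + 1}")
    unknown = set(events["kind"]) - EVENT_KINDS
    if unknown:
        raise ValueError(f"unknown event kind(s): {sorted(unknown)}")

    return EyeRecording(
        time=t,
        pupil=samples["pupil"].to_numpy(float),
        gaze_x=samples["gx"].to_numpy(float),
        gaze_y=samples["gy"].to_numpy(float),
        rate=1.0 / step,
        events=events[["t", "kind", "label"]].copy(),
    )


def write_eye_recording(rec: EyeRecording, samples_path, events_path) -> None:
    """Write an eye recording as two TSV files (inverse of the reader)."""
    pd.DataFrame({
        "t": rec.time, "pupil": rec.pupil,
        "gx": rec.gaze_x, "gy": rec.gaze_y,
    }).to_csv(samples_path, sep="\t", index=False, float_format="%.17g")
    rec.events.to_csv(events_path, sep="\t", index=False, float_format="%.17g")
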