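"""Landmark-based registration accuracy.

Registration error for a landmark is the 3D Euclidean distance (mm)
between the transformed CBCT landmark and its CT counterpart — the target
registration error (TRE).  Summaries report median, range, mean, SD and
the fractions of landmarks with error strictly below 3, 5 and 10 mm,
plus the empirical cumulative error curve and per-case means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transforms import apply_transform

__all__ = [
    "Landmark",
    "ErrorSummary",
    "read_landmarks",
    "write_landmarks",
    "landmark_errors",
    "summarize_errors",
    "cumulative_curve",
    "per_case_mean",
]


@dataclass(frozen=True)
class Landmark:
    label: str
    position: np.ndarray  # (3,) mm
    volume_role: str = ""  # "ct" or "cbct"

    def __post_init__(self):
        if not self.label:
            raise ValueError("landmark label must be non-empty")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"landmark {self.label!r} needs a finite 3D position")
        object.__setattr__(self, "position", pos)


def read_landmarks(path) -> dict:
    """Read `label x y z` lines (mm, physical space); `#` starts a comment."""
    landmarks: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'label x y z', got {raw!r}")
            label = parts[0]
            if label in landmarks:
                raise ValueError(f"{path}:{lineno}: duplicate label {label!r}")
            landmarks[label] = np.asarray([float(v) for v in parts[1:]])
    return landmarks


def write_landmarks(landmarks: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("# label x y z (mm)\n")
        for label in sorted(landmarks):
            x, y, z = np.asarray(landmarks[label], dtype=float)
            fh.write(f"{label} {x:.9g} {y:.9g} {z:.9g}\n")


def _as_dict(landmarks) -> dict:
    if isinstance(landmarks, dict):
        return {k: np.asarray(v, dtype=float) for k, v in landmarks.items()}
    return {lm.label: np.asarray(lm.position, dtype=float) for lm in landmarks}


def landmark_errors(landmarks_cbct, landmarks_ct, transform) -> dict:
    """Per-label 3D distance (mm) between transform(CBCT landmark) and the CT
    landmark.  Landmarks are keyed by label, so file ordering is irrelevant.

    Raises ``ValueError`` listing unmatched labels if the two label sets
    differ.
    """
    lc = _as_dict(landmarks_cbct)
    lt = _as_dict(landmarks_ct)
    only_cbct = sorted(set(lc) - set(lt))
    only_ct = sorted(set(lt) - set(lc))
    if only_cbct or only_ct:
        raise ValueError(
            f"landmark label mismatch: only in CBCT {only_cbct}, only in CT {only_ct}"
        )
    labels = sorted(lc)
    moved = apply_transform(transform, np.array([lc[k] for k in labels]))
    ref = np.array([lt[k] for k in labels])
    dist = np.linalg.norm(moved - ref, axis=1)
    return dict(zip(labels, dist))


@dataclass(frozen=True)
class ErrorSummary:
    errors: np.ndarray  # mm
    median: float
    min: float
    max: float
    mean: float
    sd: float
    fraction_below_3mm: float
    fraction_below_5mm: float
    fraction_below_10mm: float

    def to_dict(self) -> dict:
        return {
            "n": int(len(self.errors)),
            "median_mm": self.median,
            "min_mm": self.min,
            "max_mm": self.max,
            "mean_mm": self.mean,
            "sd_mm": self.sd,
            "fraction_below_3mm": self.fraction_below_3mm,
            "fraction_below_5mm": self.fraction_below_5mm,
            "fraction_below_10mm": self.fraction_below_10mm,
        }


def summarize_errors(errors) -> ErrorSummary:
    """Median (midpoint convention for even counts), range, mean/SD, and the
    strict `< 3 / < 5 / < 10 mm` fractions."""
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise ValueError("cannot summarize an empty error list")
    frac = lambda t: float(np.mean(errors < t))  # noqa: E731  strict <
    return ErrorSummary(
        errors=errors,
        median=float(np.median(errors)),
        min=float(errors.min()),
        max=float(errors.max()),
        mean=float(errors.mean()),
        sd=float(errors.std(ddof=1)) if errors.size > 1 else 0.0,
        fraction_below_3mm=frac(3.0),
        fraction_below_5mm=frac(5.0),
        fraction_below_10mm=frac(10.0),
    )


def cumulative_curve(errors):
    """Empirical CDF of the errors: (sorted unique thresholds, cumulative
    fractions).  Right-continuous; the last fraction is 1.0."""
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise ValueError("cannot build a cumulative curve from no errors")
    thresholds, counts = np.unique(errors, return_counts=True)
    fractions = np.cumsum(counts) / errors.size
    return thresholds, fractions


def per_case_mean(errors_by_case: dict) -> dict:
    """Arithmetic mean error per case (patient)."""
    out = {}
    for case, errs in errors_by_case.items():
        errs = np.asarray(list(errs), dtype=float)
        if errs.size == 0:
            raise ValueError(f"case {case!r} has no errors")
        out[case] = float(errs.mean())
    return out
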