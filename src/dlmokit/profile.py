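"""Melatonin profile container, parsing, midnight unwrapping and validation.

A profile is a short evening time series of melatonin concentrations
(pg/mL) sampled at clock times. All internal computation runs on an
*unwrapped* decimal-hour axis: when sampling crosses midnight, times after
the crossing gain 24 h so the axis stays strictly increasing.

Inclusion rules: a profile enters the analysis only if it has at least
three samples and rises strictly above the ascending threshold (default
2.3 pg/mL). Trailing samples that fall back below the threshold after the
last above-threshold sample are trimmed before fitting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DuplicateTimeError,
    ImplausibleSpanError,
    InputFormatError,
)

DEFAULT_THRESHOLD = 2.3  # pg/mL, ascending level of the hockey-stick method

_HHMM = re.compile(r"^(\d{1,2}):(\d{2})$")


@dataclass(frozen=True)
class MelatoninProfile:
    """Timestamped melatonin concentration series on an unwrapped hour axis.

    Attributes
    ----------
    id : str
        Label for the profile (participant/visit).
    times : np.ndarray
        Decimal hours, strictly increasing, finite.
    concentrations : np.ndarray
        pg/mL, finite and non-negative, same length as ``times``.
    clock_labels : tuple of str or None
        Original "HH:MM" strings when the input carried clock times.
    """

    id: str
    times: np.ndarray
    concentrations: np.ndarray
    clock_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or len(t) != len(c):
            raise InputFormatError("times and concentrations must be 1-D and equal length")
        if len(t) < 1:
            raise InputFormatError("profile must contain at least one sample")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(c)):
            raise InputFormatError("times and concentrations must be finite")
        if np.any(c < 0):
            raise InputFormatError("negative concentrations are not allowed")
        if np.any(np.diff(t) == 0):
            raise DuplicateTimeError(f"duplicate timestamps in profile {self.id!r}")
        if np.any(np.diff(t) < 0):
            raise InputFormatError(
                f"times must be strictly increasing in profile {self.id!r} "
                "(unwrap clock times first)"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "melatonin": self.concentrations})


@dataclass
class ValidationReport:
    """Outcome of profile validation and terminal trimming.

    ``status`` is one of ``ok``, ``no_dynamic_part`` (no sample strictly
    above the threshold), ``insufficient_points`` (fewer than three samples
    before or after trimming).
    """

    status: str
    trimmed_profile: MelatoninProfile
    n_trimmed_terminal: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def parse_time(value) -> tuple[float, str | None]:
    """Parse a single "HH:MM" or decimal-hour value → (hours, clock label)."""
    if isinstance(value, str):
        m = _HHMM.match(value.strip())
        if m:
            hh, mm = int(m.group(1)), int(m.group(2))
            if hh >= 24 or mm >= 60:
                raise InputFormatError(f"invalid clock time {value!r}")
            return hh + mm / 60.0, f"{hh:02d}:{mm:02d}"
        try:
            return float(value), None
        except ValueError as exc:
            raise InputFormatError(f"unparseable time {value!r}") from exc
    try:
        return float(value), None
    except (TypeError, ValueError) as exc:
        raise InputFormatError(f"unparseable time {value!r}") from exc


def parse_profile(raw_table, id: str = "profile") -> MelatoninProfile:
    """Build a profile from rows of (time-text, concentration).

    Times may be 24-h "HH:MM" strings or decimal hours; decimal input is
    passed through unchanged. Raises :class:`InputFormatError` naming the
    offending row, and :class:`DuplicateTimeError` on repeated timestamps.
    """
    times, concs, labels = [], [], []
    any_clock = False
    for i, row in enumerate(raw_table):
        t_raw, c_raw = row[0], row[1]
        try:
            t, label = parse_time(t_raw)
        except InputFormatError as exc:
            raise InputFormatError(f"row {i}: {exc}") from exc
        try:
            c = float(c_raw)
        except (TypeError, ValueError) as exc:
            raise InputFormatError(f"row {i}: unparseable concentration {c_raw!r}") from exc
        if not np.isfinite(c) or c < 0:
            raise InputFormatError(f"row {i}: concentration must be finite and >= 0, got {c}")
        times.append(t)
        concs.append(c)
        labels.append(label)
        any_clock = any_clock or label is not None
    if len(set(times)) != len(times):
        raise DuplicateTimeError(f"duplicate timestamps in profile {id!r}")
    prof = MelatoninProfile.__new__(MelatoninProfile)
    object.__setattr__(prof, "id", id)
    object.__setattr__(prof, "times", np.asarray(times, dtype=float))
    object.__setattr__(prof, "concentrations", np.asarray(concs, dtype=float))
    object.__setattr__(prof, "clock_labels", tuple(labels) if any_clock else None)
    # order preserved; strict monotonicity is established by unwrap_times
    if np.any(np.asarray(concs) < 0):
        raise InputFormatError("negative concentrations are not allowed")
    return prof


def unwrap_times(profile: MelatoninProfile) -> MelatoninProfile:
    """Unwrap a clock-time axis across midnight onto a monotone axis.

    Whenever ``times[i+1] <= times[i]`` (one midnight crossing per step),
    24 h is added to all subsequent samples. A span above 36 h after
    unwrapping is rejected as implausible for a single evening.
    """
    t = np.asarray(profile.times, dtype=float).copy()
    for i in range(1, len(t)):
        if t[i] <= t[i - 1]:
            if t[i] == t[i - 1]:
                raise DuplicateTimeError(f"duplicate timestamps in profile {profile.id!r}")
            t[i:] += 24.0
            if t[i] <= t[i - 1]:
                raise DuplicateTimeError(
                    f"non-monotone times in profile {profile.id!r} after unwrap"
                )
    if len(t) > 1 and (t[-1] - t[0]) > 36.0:
        raise ImplausibleSpanError(
            f"profile {profile.id!r} spans {t[-1] - t[0]:.1f} h after unwrap (> 36 h)"
        )
    prof = MelatoninProfile.__new__(MelatoninProfile)
    object.__setattr__(prof, "id", profile.id)
    object.__setattr__(prof, "times", t)
    object.__setattr__(prof, "concentrations", np.asarray(profile.concentrations, float))
    object.__setattr__(prof, "clock_labels", profile.clock_labels)
    MelatoninProfile.__post_init__(prof)
    return prof


def validate_and_trim(
    profile: MelatoninProfile, threshold: float = DEFAULT_THRESHOLD
) -> ValidationReport:
    """Apply the inclusion rules and trim trailing sub-threshold samples.

    A concentration exactly equal to the threshold does NOT count as a rise
    (strict ``>``). Trimming removes the maximal run of trailing points with
    concentration strictly below the threshold that follows the last
    above-threshold point; it is idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    c = profile.concentrations
    if len(profile) <= 2:
        return ValidationReport(
            status="insufficient_points",
            trimmed_profile=profile,
            warnings=["insufficient number of data points"],
        )
    above = c > threshold
    if not above.any():
        return ValidationReport(
            status="no_dynamic_part",
            trimmed_profile=profile,
            warnings=["no dynamic part"],
        )
    last_above = int(np.flatnonzero(above)[-1])
    end = len(c)
    while end - 1 > last_above and c[end - 1] < threshold:
        end -= 1
    n_trimmed = len(c) - end
    trimmed = profile
    warnings: list[str] = []
    if n_trimmed:
        trimmed = MelatoninProfile(
            id=profile.id,
            times=profile.times[:end],
            concentrations=c[:end],
            clock_labels=profile.clock_labels[:end] if profile.clock_labels else None,
        )
        warnings.append(f"{n_trimmed} trailing sub-threshold point(s) excluded")
    if len(trimmed) <= 2:
        return ValidationReport(
            status="insufficient_points",
            trimmed_profile=trimmed,
            n_trimmed_terminal=n_trimmed,
            warnings=warnings + ["insufficient number of data points"],
        )
    return ValidationReport(
        status="ok",
        trimmed_profile=trimmed,
        n_trimmed_terminal=n_trimmed,
        warnings=warnings,
    )


def hours_to_clock(hours: float) -> str:
    """Decimal hours → "HH:MM" mod 24, rounded to the nearest minute."""
    minutes = int(round((hours % 24.0) * 60.0)) % (24 * 60)
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def read_profiles_csv(path) -> list[MelatoninProfile]:
    """Read profiles from CSV with header ``time,melatonin`` (optional
    leading ``id`` column for long format). Clock times are unwrapped."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "time" not in cols or "melatonin" not in cols:
        raise InputFormatError(f"{path}: expected columns time,melatonin (optional id)")
    out = []
    if "id" in cols:
        for pid, grp in df.groupby("id", sort=True):
            rows = list(zip(grp["time"], grp["melatonin"]))
            out.append(unwrap_times(parse_profile(rows, id=str(pid))))
    else:
        rows = list(zip(df["time"], df["melatonin"]))
        out.append(unwrap_times(parse_profile(rows, id="profile")))
    return out


def write_profile_csv(profile: MelatoninProfile, path) -> None:
    profile.to_frame().to_csv(path, index=False)
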