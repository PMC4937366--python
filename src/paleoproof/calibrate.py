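"""Single-date radiocarbon calibration with highest-density intervals.

A radiocarbon determination (age BP with 1-sigma error) is mapped through
a calibration curve mu(t), sigma_curve(t) defined on a calendar-age grid.
The likelihood of calendar age t is

    L(t) proportional to exp(-(age - mu(t))^2 / (2 (sigma^2 + sigma_curve(t)^2)))

which, normalised over the grid, is the calibrated-age distribution.
Highest-posterior-density (HPD) regions at 68.2% and 95.4% are extracted
by accumulating grid points in order of descending density; multi-modal
distributions legitimately yield several disjoint intervals per level.
Interval bounds are rounded outward (older bound up, younger bound down)
to a conventional multiple of 10 years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RadiocarbonDate:
    lab_code: str
    age_bp: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.age_bp <= 0:
            raise ValueError("age_bp must be > 0")


@dataclass
class CalibrationCurve:
    cal_bp: np.ndarray  # strictly increasing
    c14_age: np.ndarray
    curve_sigma: np.ndarray
    name: str = "curve"

    def __post_init__(self):
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_age = np.asarray(self.c14_age, dtype=float)
        self.curve_sigma = np.asarray(self.curve_sigma, dtype=float)
        if len(self.cal_bp) == 0:
            raise CurveParseError("empty curve")
        if not np.all(np.diff(self.cal_bp) > 0):
            raise CurveParseError("cal_bp grid must be strictly increasing")
        if not np.all(self.curve_sigma > 0):
            raise CurveParseError("curve_sigma must be positive")


class CurveParseError(ValueError):
    pass


class CurveRangeError(ValueError):
    pass


@dataclass
class CalResult:
    lab_code: str
    grid: np.ndarray  # calendar ages, cal BP
    posterior: np.ndarray  # sums to 1
    intervals: dict[float, list[tuple[int, int]]]  # level -> [(older, younger)]

    def hpd(self, level: float) -> list[tuple[int, int]]:
        return self.intervals[level]


def read_curve(path, name: str | None = None) -> CalibrationCurve:
    """Parse an IntCal-dialect ``.14c`` file.

    Comment lines start with '#'; data lines are comma-separated
    "CAL BP, 14C age, Error, Delta14C, Sigma" — only the first three
    fields are used.  The grid is sorted ascending in cal BP.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 3:
                raise CurveParseError(f"line {lineno}: expected >= 3 comma-separated fields")
            try:
                cal, age, err = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise CurveParseError(f"line {lineno}: non-numeric field") from exc
            rows.append((cal, age, err))
    if not rows:
        raise CurveParseError("empty curve")
    rows.sort(key=lambda r: r[0])
    cal, age, err = map(np.array, zip(*rows))
    if np.any(np.diff(cal) == 0):
        raise CurveParseError("duplicate cal BP grid points")
    return CalibrationCurve(cal, age, err, name=name or str(path))


def identity_curve(
    span: tuple[float, float] = (0.0, 50000.0),
    step: float = 5.0,
    curve_sigma: float = 1e-3,
) -> CalibrationCurve:
    """mu(t) = t with constant (tiny) curve error — the closed-form testbed."""
    grid = np.arange(span[0], span[1] + step, step)
    return CalibrationCurve(
        grid, grid.copy(), np.full_like(grid, curve_sigma), name="identity"
    )


def _round_outward(older: float, younger: float, rounding: int) -> tuple[int, int]:
    if rounding <= 1:
        return int(round(older)), int(round(younger))
    return (
        int(np.ceil(older / rounding) * rounding),
        int(np.floor(younger / rounding) * rounding),
    )


def calibrate(
    date: RadiocarbonDate,
    curve: CalibrationCurve,
    interval_levels: tuple[float, ...] = (0.682, 0.954),
    grid_step: float = 5.0,
    rounding: int = 10,
) -> CalResult:
    """Calibrate one radiocarbon date against ``curve``.

    The curve is linearly interpolated onto a calendar grid at
    ``grid_step`` years; HPD intervals are reported as (older_bound,
    younger_bound) in cal BP, rounded outward to ``rounding`` years.
    """
    lo_mu, hi_mu = float(curve.c14_age.min()), float(curve.c14_age.max())
    if not (lo_mu - 4 * date.sigma <= date.age_bp <= hi_mu + 4 * date.sigma):
        raise CurveRangeError(
            f"{date.age_bp} BP outside curve 14C range [{lo_mu}, {hi_mu}]"
        )
    grid = np.arange(curve.cal_bp[0], curve.cal_bp[-1] + grid_step, grid_step)
    mu = np.interp(grid, curve.cal_bp, curve.c14_age)
    sig = np.interp(grid, curve.cal_bp, curve.curve_sigma)
    var = date.sigma**2 + sig**2
    loglik = -((date.age_bp - mu) ** 2) / (2 * var) - 0.5 * np.log(var)
    loglik -= loglik.max()
    post = np.exp(loglik)
    total = post.sum()
    if total == 0:
        raise CurveRangeError("posterior vanishes everywhere on the grid")
    post /= total

    intervals: dict[float, list[tuple[int, int]]] = {}
    order = np.argsort(post)[::-1]
    for level in interval_levels:
        cum = np.cumsum(post[order])
        k = int(np.searchsorted(cum, level)) + 1
        included = np.zeros(len(grid), dtype=bool)
        included[order[:k]] = True
        # contiguous runs of included grid points -> intervals
        runs = []
        start = None
        for i, inc in enumerate(included):
            if inc and start is None:
                start = i
            elif not inc and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(grid) - 1))
        ivals = []
        for a, b in runs:
            older, younger = float(grid[b]), float(grid[a])  # grid ascends in cal BP
            ivals.append(_round_outward(older, younger, rounding))
        ivals.sort(reverse=True)
        intervals[level] = ivals
    return CalResult(date.lab_code, grid, post, intervals)
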