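"""Radioluminescence time-series reduction and linearity handling.

Reduces 200 Hz RL traces to background-corrected integrated signals,
fits through-origin dose-response slopes, computes linearity indices
relative to a calibration dose, and fits/applies polynomial linearity
correction factors (LCF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ConfigurationError, DomainError

__all__ = [
    "RLTrace",
    "DoseResponseSet",
    "SlopeFit",
    "LinearityCorrection",
    "PUBLISHED_LCF_COEFFS",
    "integrate_trace",
    "fit_dose_response",
    "linearity_index",
    "fit_lcf",
    "apply_lcf",
    "published_lcf",
]

DEFAULT_SAMPLE_RATE = 200.0
DEFAULT_BACKGROUND_SAMPLES = 25


@dataclass
class RLTrace:
    """A sampled RL count trace with irradiation window and backgrounds.

    ``window`` is the half-open sample-index interval [start, stop) of the
    irradiation; ``pre_background`` and ``post_background`` are index
    intervals of at least 25 samples each, disjoint from the window.
    """

    counts: np.ndarray
    window: tuple[int, int]
    pre_background: tuple[int, int]
    post_background: tuple[int, int]
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.counts)
        for name, (a, b) in (
            ("window", self.window),
            ("pre_background", self.pre_background),
            ("post_background", self.post_background),
        ):
            if not (0 <= a < b <= n):
                raise ConfigurationError(f"{name} interval {a, b} outside trace of {n}")
        w = self.window
        for name, seg in (
            ("pre_background", self.pre_background),
            ("post_background", self.post_background),
        ):
            if seg[1] > w[0] and seg[0] < w[1]:
                raise ConfigurationError(f"{name} overlaps the irradiation window")
        if np.any(self.counts < 0):
            raise ConfigurationError("counts must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.counts)) / self.sample_rate

    def to_csv(self, path, sidecar=None) -> None:
        import pandas as pd
        import yaml

        pd.DataFrame({"time_s": self.times, "counts": self.counts}).to_csv(
            path, index=False
        )
        sidecar = sidecar or str(path) + ".yaml"
        meta = {
            "sample_rate_hz": float(self.sample_rate),
            "window": list(self.window),
            "pre_background": list(self.pre_background),
            "post_background": list(self.post_background),
        }
        with open(sidecar, "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def from_csv(cls, path, sidecar=None) -> "RLTrace":
        import pandas as pd
        import yaml

        df = pd.read_csv(path)
        sidecar = sidecar or str(path) + ".yaml"
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        return cls(
            counts=df["counts"].to_numpy(float),
            window=tuple(meta["window"]),
            pre_background=tuple(meta["pre_background"]),
            post_background=tuple(meta["post_background"]),
            sample_rate=float(meta["sample_rate_hz"]),
        )


def integrate_trace(
    trace: RLTrace, n_background: int = DEFAULT_BACKGROUND_SAMPLES
) -> float:
    """Background-corrected integrated signal.

    Sums the counts over the irradiation window and subtracts the window
    length times the mean of ``n_background`` samples taken immediately
    before and immediately after the window (2 x 25 = 50 by default).
    The result may be negative for noise-only traces.
    """
    pre = trace.counts[trace.pre_background[0] : trace.pre_background[1]]
    post = trace.counts[trace.post_background[0] : trace.post_background[1]]
    if len(pre) < n_background or len(post) < n_background:
        raise ConfigurationError(
            f"background segments must hold >= {n_background} samples "
            f"(got {len(pre)} pre, {len(post)} post)"
        )
    bkg = np.concatenate((pre[-n_background:], post[:n_background])).mean()
    a, b = trace.window
    return float(trace.counts[a:b].sum() - (b - a) * bkg)


@dataclass
class DoseResponseSet:
    """(dose, integrated signal) points for one probe and beam."""

    doses: np.ndarray
    delta_rl: np.ndarray
    probe: str = ""
    beam: str = ""
    d0: float = 1.0

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.delta_rl = np.asarray(self.delta_rl, dtype=float)
        if self.doses.shape != self.delta_rl.shape:
            raise ConfigurationError("doses and delta_rl lengths differ")
        if len(self.doses) < 2:
            raise ConfigurationError("need at least 2 dose points")
        if np.any(self.doses < 0):
            raise ConfigurationError("doses must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "dose_gy": self.doses,
                "delta_rl": self.delta_rl,
                "probe": self.probe,
                "beam": self.beam,
            }
        )


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    stderr: float
    n_points: int


def fit_dose_response(dose_set: DoseResponseSet) -> SlopeFit:
    """Through-origin least-squares slope s = sum(D*y) / sum(D^2)."""
    d, y = dose_set.doses, dose_set.delta_rl
    ssd = float(np.sum(d * d))
    if ssd == 0.0:
        raise DomainError("all doses are zero; slope is undefined")
    s = float(np.sum(d * y)) / ssd
    resid = y - s * d
    dof = max(len(d) - 1, 1)
    stderr = float(np.sqrt(np.sum(resid**2) / dof / ssd))
    return SlopeFit(slope=s, stderr=stderr, n_points=len(d))


def linearity_index(dose_set: DoseResponseSet, d0: float | None = None) -> np.ndarray:
    """Per-point sensitivity normalized to the calibration dose.

    index_i = (y_i / D_i) / (y(D0) / D0); the sensitivity at D0 is taken
    from the exact point when measured, otherwise linearly interpolated
    between the bracketing doses.
    """
    d0 = dose_set.d0 if d0 is None else d0
    d, y = dose_set.doses, dose_set.delta_rl
    if np.any(d <= 0):
        raise DomainError("linearity index requires strictly positive doses")
    sens = y / d
    order = np.argsort(d)
    ds, ss = d[order], sens[order]
    exact = np.isclose(ds, d0, rtol=1e-9, atol=1e-12)
    if exact.any():
        s0 = float(ss[exact][0])
    elif ds[0] < d0 < ds[-1]:
        s0 = float(np.interp(d0, ds, ss))
    else:
        raise CalibrationError(
            f"calibration dose {d0} Gy outside measured range "
            f"[{ds[0]}, {ds[-1]}] Gy; cannot normalize"
        )
    if s0 == 0:
        raise CalibrationError("zero sensitivity at the calibration dose")
    return sens / s0


@dataclass
class LinearityCorrection:
    """Polynomial linearity correction factor LCF(D) in dose D (Gy).

    ``coefficients`` are in descending powers (numpy polyval order);
    degree must be 3 or 4.  ``validity`` is the dose interval over which
    the polynomial evaluates within (0, 10].
    """

    probe: str
    beam: str
    coefficients: np.ndarray
    validity: tuple[float, float]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.degree not in (3, 4):
            raise ConfigurationError(f"LCF degree must be 3 or 4, got {self.degree}")
        lo, hi = self.validity
        if not lo < hi:
            raise ConfigurationError("empty validity range")

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, dose):
        return np.polyval(self.coefficients, dose)

    def rounded_coefficients(self, ndigits: int = 2) -> np.ndarray:
        """Coefficients at the 2-decimal reporting precision."""
        return np.round(self.coefficients, ndigits)


def _validity_window(
    coeffs: np.ndarray, lo: float, hi: float, anchor: float
) -> tuple[float, float]:
    """Largest contiguous sub-interval of [lo, hi] where the polynomial is
    in (0, 10], preferring the window containing ``anchor``."""
    grid = np.linspace(lo, hi, 2001)
    ok = (np.polyval(coeffs, grid) > 0) & (np.polyval(coeffs, grid) <= 10)
    if not ok.any():
        raise ConfigurationError("polynomial never evaluates within (0, 10]")
    # contiguous runs of ok
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    runs = list(zip(edges[::2], edges[1::2] - 1))
    containing = [r for r in runs if grid[r[0]] <= anchor <= grid[r[1]]]
    run = containing[0] if containing else max(runs, key=lambda r: r[1] - r[0])
    return float(grid[run[0]]), float(grid[run[1]])


def fit_lcf(
    doses,
    indices,
    degree: int,
    probe: str = "",
    beam: str = "",
) -> LinearityCorrection:
    """Least-squares polynomial fit of the linearity index versus dose."""
    doses = np.asarray(doses, dtype=float)
    indices = np.asarray(indices, dtype=float)
    if degree not in (3, 4):
        raise ConfigurationError("LCF degree must be 3 or 4")
    if len(np.unique(doses)) < degree + 1:
        raise ConfigurationError(
            f"need >= {degree + 1} distinct doses for a degree-{degree} fit"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coeffs = np.polyfit(doses, indices, degree)
    validity = _validity_window(coeffs, doses.min(), doses.max(), anchor=1.0)
    return LinearityCorrection(probe, beam, coeffs, validity)


def apply_lcf(value: float, correction: LinearityCorrection, dose: float) -> float:
    """Divide out the supralinear over-response at ``dose``.

    Refuses extrapolation outside the correction's validity range.
    """
    lo, hi = correction.validity
    if not lo <= dose <= hi:
        raise DomainError(
            f"dose {dose} Gy outside LCF validity range [{lo:.3g}, {hi:.3g}] Gy"
        )
    return value / float(correction(dose))


#: Published LCF polynomial coefficients (descending powers of dose in Gy).
#: The single-crystal helium correction is quartic; all others are cubic.
PUBLISHED_LCF_COEFFS: dict[tuple[str, str], list[float]] = {
    ("single_crystal", "He150"): [8.11, -24.38, 27.46, -13.66, 3.53],
    ("grain_38um", "He150"): [0.82, -1.83, -1.36, 0.66],
    ("single_crystal", "C400"): [-0.03, 0.12, -0.03, 0.99],
    ("grain_38um", "C400"): [-0.02, 0.09, -0.07, 1.01],
    ("single_crystal", "C290"): [-0.06, 0.18, -0.02, 0.99],
    ("grain_38um", "C290"): [-0.05, 0.19, -0.17, 1.03],
}


def published_lcf(probe: str, beam: str, dose_range=(0.01, 10.0)) -> LinearityCorrection:
    """Published LCF for (probe, beam) with a computed validity range.

    The helium polynomials misbehave outside a narrow dose window when the
    dose is read in Gy; the validity range is clamped to where the
    polynomial stays within (0, 10].
    """
    key = (probe, beam)
    if key not in PUBLISHED_LCF_COEFFS:
        known = sorted(PUBLISHED_LCF_COEFFS)
        raise KeyError(f"no published LCF for {key}; available: {known}")
    coeffs = np.asarray(PUBLISHED_LCF_COEFFS[key], dtype=float)
    validity = _validity_window(coeffs, *dose_range, anchor=1.0)
    return LinearityCorrection(probe, beam, coeffs, validity)
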