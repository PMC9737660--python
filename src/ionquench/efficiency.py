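"""Relative luminescence efficiency versus LET.

Computes the efficiency of a charged-particle beam relative to the Co-60
reference calibration, assembles efficiency-vs-LET curves along Bragg
curves, and fits the exponential decay-to-plateau efficiency model
mu(L) = y0 + A exp(-L / tau).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .beam_model import DepthDoseCurve, SpeciesDepthProfile, fluence_weighted_let
from .constants import MEV_CM_PER_KEV_UM
from .errors import AlignmentError, DomainError, FittingError

__all__ = [
    "CalibrationConstant",
    "EfficiencyCurve",
    "ExponentialFit",
    "relative_efficiency",
    "build_efficiency_curve",
    "fit_mu_exponential",
]

SENSITIVITY_DRIFT_TOL = 0.03


@dataclass
class CalibrationConstant:
    """Co-60 calibration constant C = RL_Co / D_Co for one probe.

    Pre- and post-campaign values are averaged; a drift above 3% triggers
    a sensitivity-change warning.
    """

    probe: str
    c_pre: float
    c_post: float | None = None

    def __post_init__(self) -> None:
        if self.c_pre <= 0 or (self.c_post is not None and self.c_post <= 0):
            raise DomainError("calibration constants must be positive")
        if self.c_post is not None:
            drift = abs(self.c_pre - self.c_post) / self.c
            if drift > SENSITIVITY_DRIFT_TOL:
                warnings.warn(
                    f"probe {self.probe!r}: pre/post calibration differ by "
                    f"{100 * drift:.1f}% (> {100 * SENSITIVITY_DRIFT_TOL:.0f}%); "
                    "possible sensitivity change",
                    stacklevel=2,
                )

    @property
    def c(self) -> float:
        """Averaged counts per Gy."""
        if self.c_post is None:
            return self.c_pre
        return 0.5 * (self.c_pre + self.c_post)


def relative_efficiency(rl_hcp: float, d_hcp: float, cal: CalibrationConstant) -> float:
    """Light-per-dose relative to the Co-60 reference: (RL/D) / C."""
    if rl_hcp <= 0 or d_hcp <= 0:
        raise DomainError("RL signal and dose must be positive")
    return (rl_hcp / d_hcp) / cal.c


@dataclass(frozen=True)
class ExponentialFit:
    """Parameters of mu(L) = y0 + A exp(-L / tau), with fit quality."""

    y0: float
    amplitude: float
    tau: float
    r_squared: float

    def __call__(self, let_kev_um):
        return self.y0 + self.amplitude * np.exp(-np.asarray(let_kev_um) / self.tau)


@dataclass
class EfficiencyCurve:
    """(mu, LET) points along one or more Bragg curves."""

    mu: np.ndarray
    let_kev_um: np.ndarray
    depth_mm: np.ndarray
    beam: np.ndarray  # per-point beam label
    fit: ExponentialFit | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.let_kev_um = np.asarray(self.let_kev_um, dtype=float)
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.beam = np.asarray(self.beam)
        if not (len(self.mu) == len(self.let_kev_um) == len(self.depth_mm)):
            raise ValueError("point arrays must have equal length")
        if np.any(self.mu <= 0) or np.any(self.let_kev_um <= 0):
            raise ValueError("mu and LET must be positive")

    def __len__(self) -> int:
        return len(self.mu)

    @staticmethod
    def concatenate(curves: list["EfficiencyCurve"]) -> "EfficiencyCurve":
        return EfficiencyCurve(
            np.concatenate([c.mu for c in curves]),
            np.concatenate([c.let_kev_um for c in curves]),
            np.concatenate([c.depth_mm for c in curves]),
            np.concatenate([c.beam for c in curves]),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "beam": self.beam,
                "depth_mm": self.depth_mm,
                "let_kev_um": self.let_kev_um,
                "mu": self.mu,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_efficiency_curve(
    measurements,
    reference: DepthDoseCurve,
    cal: CalibrationConstant,
    profile: SpeciesDepthProfile,
    let_axis: str = "weighted",
    beam: str = "",
) -> EfficiencyCurve:
    """One (mu, LET) point per measured depth along a Bragg curve.

    ``measurements`` is a sequence of (depth_mm, delta_rl) pairs;
    ``reference`` must carry absolute dose (Gy) at those depths.  The LET
    axis is the fluence-weighted LET over all species by default
    (``let_axis="weighted"``); ``"primary"`` uses the primary species'
    LET only.  Only the weighted axis collapses beams of different energy
    onto a single curve.
    """
    if let_axis not in ("weighted", "primary"):
        raise ValueError("let_axis must be 'weighted' or 'primary'")
    depths, mus, lets = [], [], []
    for depth, delta_rl in measurements:
        try:
            dose = reference.at(depth)
        except DomainError as exc:
            raise AlignmentError(f"no reference dose at depth {depth} mm") from exc
        if dose <= 0:
            raise AlignmentError(f"non-positive reference dose at depth {depth} mm")
        mus.append(relative_efficiency(delta_rl, dose, cal))
        if let_axis == "weighted":
            lets.append(fluence_weighted_let(profile, depth))
        else:
            frac, let = profile.at_depth(depth)
            lets.append(let[0] / MEV_CM_PER_KEV_UM)  # primary is column 0
        depths.append(depth)
    return EfficiencyCurve(
        np.array(mus),
        np.array(lets),
        np.array(depths),
        np.array([beam] * len(depths)),
    )


def fit_mu_exponential(
    curve: EfficiencyCurve, max_restarts: int = 6
) -> ExponentialFit:
    """Fit mu(L) = y0 + A exp(-L / tau) by least squares.

    Requires at least 4 points over a nondegenerate LET range.  Restarts
    from several tau scales before giving up; attaches the result to
    ``curve.fit`` and returns it.
    """
    L, mu = curve.let_kev_um, curve.mu
    if len(L) < 4:
        raise FittingError("need at least 4 points to fit the exponential model")
    span = float(L.max() - L.min())
    if span <= 0:
        raise FittingError("degenerate LET range")
    y0_0 = max(float(mu.min()), 1e-9)
    a_0 = max(float(mu.max() - mu.min()), 1e-9)
    last_err: Exception | None = None
    for tau_0 in np.geomspace(span / 30, 3 * span, max_restarts):
        try:
            popt, _ = curve_fit(
                lambda x, y0, a, tau: y0 + a * np.exp(-x / tau),
                L,
                mu,
                p0=(y0_0, a_0, tau_0),
                bounds=((0.0, 0.0, 1e-12), (np.inf, np.inf, np.inf)),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        fit = ExponentialFit(*popt, r_squared=_r_squared(mu, _model(L, popt)))
        curve.fit = fit
        return fit
    raise FittingError(
        f"exponential fit failed after {max_restarts} restarts: {last_err}"
    )


def _model(L, popt):
    y0, a, tau = popt
    return y0 + a * np.exp(-L / tau)


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
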