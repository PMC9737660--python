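"""Voxelized Birks quenching model and fluence-weighted correction.

The core method: per-voxel Birks light emission, per-species and
fluence-weighted quenching correction factors eta, nonlinear (kB, RL0)
fitting with frozen-fragment constraints, finite-probe volume averaging,
and corrected-dose reconstruction with difference metrics.

Unit convention: kB is stored in ug MeV^-1 cm^-2 (the published unit) and
divided by the density of water (1e6 ug/cm^3) before multiplying LET in
MeV/cm, so the Birks product kB*LET is dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .beam_model import DepthDoseCurve, SpeciesDepthProfile
from .constants import RHO_WATER_UG_CM3
from .errors import (
    CalibrationError,
    ConfigurationError,
    DomainError,
    FittingError,
    IonquenchError,
)

__all__ = [
    "BirksParams",
    "ProbeSpec",
    "PROBE_PRESETS",
    "NormalizedRL",
    "BirksFit",
    "CorrectionResult",
    "birks_rl",
    "eta_single",
    "eta_combined",
    "eta_profile",
    "normalized_rl_curve",
    "model_normalized_rl",
    "fit_birks",
    "volume_average",
    "correct_curve",
    "UNPARAMETERIZED_DEFAULT",
]


@dataclass(frozen=True)
class BirksParams:
    """Per-species Birks constant and luminescence scaling.

    ``kb_ug_per_mev_cm2`` is the published mass-unit Birks constant;
    ``kb_cm_per_mev`` is the density-scaled value actually multiplied
    by LET (MeV/cm).  ``let_range_mev_cm`` is the validity range of the
    fitted parameters.
    """

    species: str
    kb_ug_per_mev_cm2: float
    rl0: float
    let_range_mev_cm: tuple[float, float] = (0.0, np.inf)
    kb_stderr: float | None = None
    rl0_stderr: float | None = None

    def __post_init__(self) -> None:
        if self.kb_ug_per_mev_cm2 < 0:
            raise ValueError("kB must be non-negative")
        if self.rl0 <= 0:
            raise ValueError("RL0 must be positive")
        lo, hi = self.let_range_mev_cm
        if not lo < hi:
            raise ValueError("empty LET validity range")

    @property
    def kb_cm_per_mev(self) -> float:
        return self.kb_ug_per_mev_cm2 / RHO_WATER_UG_CM3

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "kb_ug_per_mev_cm2": self.kb_ug_per_mev_cm2,
            "rl0": self.rl0,
            "let_range_mev_cm": list(self.let_range_mev_cm),
            "stderr": {"kb": self.kb_stderr, "rl0": self.rl0_stderr},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BirksParams":
        stderr = d.get("stderr") or {}
        return cls(
            species=d["species"],
            kb_ug_per_mev_cm2=d["kb_ug_per_mev_cm2"],
            rl0=d["rl0"],
            let_range_mev_cm=tuple(d.get("let_range_mev_cm", (0.0, np.inf))),
            kb_stderr=stderr.get("kb"),
            rl0_stderr=stderr.get("rl0"),
        )


#: Contribution of species without fitted parameters (trace fragments):
#: unquenched, unit scaling.
UNPARAMETERIZED_DEFAULT = BirksParams("default", 0.0, 1.0)


@dataclass(frozen=True)
class ProbeSpec:
    """Geometry of an optical-fibre probe's active volume."""

    probe_type: str
    active_length_mm: float
    grain_size_um: float | None = None

    def __post_init__(self) -> None:
        if self.probe_type not in ("single_crystal", "grain_38um", "grain_4um"):
            raise ValueError(f"unknown probe type {self.probe_type!r}")
        if self.active_length_mm <= 0:
            raise ValueError("active length must be positive")


PROBE_PRESETS: dict[str, ProbeSpec] = {
    "single_crystal": ProbeSpec("single_crystal", 1.0, None),
    "grain_38um": ProbeSpec("grain_38um", 0.2, 38.0),
    "grain_4um": ProbeSpec("grain_4um", 0.2, 4.0),
}


# --------------------------------------------------------------------------
# Birks model and correction factors
# --------------------------------------------------------------------------


def birks_rl(let_mev_cm, fluence, params: BirksParams):
    """Voxel light output RL_v = (RL0 * LET / (1 + kB * LET)) * fluence."""
    let = np.asarray(let_mev_cm, dtype=float)
    if np.any(let <= 0):
        raise DomainError("LET must be positive")
    phi = np.asarray(fluence, dtype=float)
    if np.any(phi < 0):
        raise DomainError("fluence must be non-negative")
    out = params.rl0 * let / (1.0 + params.kb_cm_per_mev * let) * phi
    return out if out.ndim else float(out)


def eta_single(let_mev_cm, params: BirksParams):
    """Per-species correction factor (1 + kB * LET) / RL0."""
    let = np.asarray(let_mev_cm, dtype=float)
    out = (1.0 + params.kb_cm_per_mev * let) / params.rl0
    return out if out.ndim else float(out)


def _resolve_params(
    species: list[str],
    fractions: np.ndarray,
    params: Mapping[str, BirksParams],
    default: BirksParams | None,
) -> list[BirksParams]:
    occupied = np.asarray(fractions).reshape(-1, len(species)).max(axis=0) > 0
    missing = [
        sp for sp, occ in zip(species, occupied) if occ and sp not in params
    ]
    if missing and default is None:
        raise ConfigurationError(
            f"no Birks parameters for species with nonzero fluence: {missing}"
        )
    return [params.get(sp, default) for sp in species]


def eta_combined(
    species: list[str],
    fractions,
    lets_mev_cm,
    params: Mapping[str, BirksParams],
    default: BirksParams | None = UNPARAMETERIZED_DEFAULT,
):
    """Fluence-weighted correction factor at one depth (or many).

    eta = sum_i f_i * (1 + kB_i * LET_i) / RL0_i over the species present.
    ``fractions`` and ``lets_mev_cm`` may be 1-D (one depth) or 2-D
    (n_depths, n_species).  Species carrying fluence but lacking an entry
    in ``params`` fall back to ``default``; pass ``default=None`` to make
    that a configuration error.
    """
    f = np.atleast_2d(np.asarray(fractions, dtype=float))
    let = np.atleast_2d(np.asarray(lets_mev_cm, dtype=float))
    if f.shape != let.shape or f.shape[1] != len(species):
        raise ConfigurationError("fractions/LET shapes do not match species list")
    sums = f.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ConfigurationError("fluence fractions must sum to 1 at each depth")
    plist = _resolve_params(species, f, params, default)
    eta = np.zeros(f.shape[0])
    for j, p in enumerate(plist):
        col = f[:, j]
        term = np.zeros_like(eta)
        occ = col > 0
        term[occ] = col[occ] * (1.0 + p.kb_cm_per_mev * let[occ, j]) / p.rl0
        eta += term
    return eta if np.asarray(fractions).ndim == 2 else float(eta[0])


def eta_profile(
    profile: SpeciesDepthProfile,
    params: Mapping[str, BirksParams],
    default: BirksParams | None = UNPARAMETERIZED_DEFAULT,
) -> np.ndarray:
    """eta at every depth bin of a profile."""
    return eta_combined(
        profile.species,
        profile.fluence_fraction,
        profile.let_mev_cm,
        params,
        default,
    )


# --------------------------------------------------------------------------
# normalized RL curves
# --------------------------------------------------------------------------


@dataclass
class NormalizedRL:
    """Measured RL rescaled to the peak-to-plateau representation.

    ``values[i]`` is the apparent (quenched) dose at ``depths[i]``,
    normalized to the reference entrance dose; the entrance value equals
    the entrance relative efficiency by construction.  ``ref_norm`` is the
    reference curve normalized to its entrance, aligned to ``depths``.
    """

    depths: np.ndarray
    values: np.ndarray
    ref_norm: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.ref_norm = np.asarray(self.ref_norm, dtype=float)
        if not (len(self.depths) == len(self.values) == len(self.ref_norm)):
            raise ValueError("arrays must have equal length")


def normalized_rl_curve(
    mu_entrance: float,
    measured,
    reference: DepthDoseCurve,
) -> NormalizedRL:
    """Convert integrated signals along a Bragg curve to normalized RL.

    ``measured`` is a sequence of (depth_mm, delta_rl); a point in the
    entrance bin of the reference grid must be present.  Each signal is
    scaled by the entrance calibration so that the entrance value is
    ``mu_entrance`` and deeper values read mu(d) * D(d) / D_entrance.
    """
    measured = sorted(measured, key=lambda p: p[0])
    depths = np.array([p[0] for p in measured], dtype=float)
    signals = np.array([p[1] for p in measured], dtype=float)
    entrance_mask = np.array(
        [reference.grid.locate(d) == 0 for d in depths], dtype=bool
    )
    if not entrance_mask.any():
        raise CalibrationError(
            "no measurement in the entrance bin; cannot anchor the curve"
        )
    entrance_signal = float(signals[entrance_mask][0])
    if entrance_signal <= 0:
        raise CalibrationError("non-positive entrance signal")
    values = signals * (mu_entrance / entrance_signal)
    refn = reference.normalized()
    ref_at = np.array([refn.at(d) for d in depths])
    return NormalizedRL(depths, values, ref_at)


def model_normalized_rl(
    depths,
    profile: SpeciesDepthProfile,
    params: Mapping[str, BirksParams],
    reference: DepthDoseCurve,
    default: BirksParams | None = UNPARAMETERIZED_DEFAULT,
) -> np.ndarray:
    """Forward model of the normalized RL: D_norm(d) / eta(d).

    This is the voxelized Birks forward model the fitting inverts: the
    reference-normalized dose attenuated by the fluence-weighted quenching
    factor.
    """
    refn = reference.normalized()
    out = np.empty(len(depths))
    for i, d in enumerate(np.asarray(depths, dtype=float)):
        frac, let = profile.at_depth(d)
        eta = eta_combined(profile.species, frac, let, params, default)
        out[i] = refn.at(d) / eta
    return out


# --------------------------------------------------------------------------
# parameter fitting
# --------------------------------------------------------------------------


@dataclass
class BirksFit:
    """Result of a (kB, RL0) fit for one species."""

    fitted: BirksParams
    params: dict[str, BirksParams]  # fitted + frozen, by species
    r_squared: float
    n_points: int
    residual_norm: float


def fit_birks(
    normalized_rl: NormalizedRL,
    profile: SpeciesDepthProfile,
    let_range_mev_cm: tuple[float, float],
    frozen: Mapping[str, BirksParams],
    fit_species: str | None = None,
    reference: DepthDoseCurve | None = None,
    default: BirksParams | None = UNPARAMETERIZED_DEFAULT,
    n_starts: int = 5,
) -> BirksFit:
    """Fit (kB, RL0) of the primary species with fragments frozen.

    Depth points are selected by the primary LET lying inside
    ``let_range_mev_cm`` (the validity range of the resulting parameters);
    the forward model is the fluence-weighted Birks model with the frozen
    fragment parameters fixed.  Trust-region least squares with multiple
    kB starts (log-spaced) and kB >= 0, RL0 > 0 bounds.
    """
    fit_species = fit_species or profile.species[0]
    if fit_species in frozen:
        raise ConfigurationError(f"cannot fit frozen species {fit_species!r}")

    depths = normalized_rl.depths
    primary_let = np.array(
        [profile.at_depth(d)[1][profile.species_index(fit_species)] for d in depths]
    )
    lo, hi = let_range_mev_cm
    sel = (primary_let >= lo) & (primary_let <= hi)
    if sel.sum() < 4:
        raise ConfigurationError(
            f"only {int(sel.sum())} depth points with primary LET in "
            f"[{lo}, {hi}] MeV/cm; need >= 4"
        )
    # every other occupied species must be frozen or defaulted
    occupied = {
        sp
        for d in depths[sel]
        for sp, f in zip(profile.species, profile.at_depth(d)[0])
        if f > 0 and sp != fit_species
    }
    missing = sorted(occupied - set(frozen))
    if missing and default is None:
        raise ConfigurationError(f"frozen set missing required fragments: {missing}")

    d_sel = depths[sel]
    y = normalized_rl.values[sel]
    refn = normalized_rl.ref_norm[sel]
    frac = np.stack([profile.at_depth(d)[0] for d in d_sel])
    lets = np.stack([profile.at_depth(d)[1] for d in d_sel])
    j_fit = profile.species_index(fit_species)

    frozen_eta = np.zeros(len(d_sel))
    for j, sp in enumerate(profile.species):
        if j == j_fit:
            continue
        p = frozen.get(sp, default)
        col = frac[:, j]
        occ = col > 0
        frozen_eta[occ] += col[occ] * (1.0 + p.kb_cm_per_mev * lets[occ, j]) / p.rl0

    f_fit = frac[:, j_fit]
    l_fit = lets[:, j_fit]

    def residuals(x):
        kb, rl0 = x
        eta = frozen_eta + f_fit * (1.0 + kb * l_fit) / rl0
        return refn / eta - y

    best = None
    rl0_guess = max(float(y[np.argmin(l_fit)]), 0.1)
    for kb0 in np.geomspace(1e-6, 1e-1, n_starts):
        try:
            res = least_squares(
                residuals,
                x0=(kb0, rl0_guess),
                bounds=((0.0, 1e-9), (np.inf, np.inf)),
                method="trf",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:  # noqa: BLE001 - collect and retry other starts
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        diag = None if best is None else best.message
        raise FittingError(f"Birks fit did not converge (multi-start): {diag}")

    kb_cm, rl0 = best.x
    resid = best.fun
    dof = max(len(resid) - 2, 1)
    s2 = float(resid @ resid) / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        kb_err, rl0_err = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        kb_err = rl0_err = float("nan")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0

    fitted = BirksParams(
        species=fit_species,
        kb_ug_per_mev_cm2=kb_cm * RHO_WATER_UG_CM3,
        rl0=float(rl0),
        let_range_mev_cm=let_range_mev_cm,
        kb_stderr=float(kb_err) * RHO_WATER_UG_CM3,
        rl0_stderr=float(rl0_err),
    )
    out_params = dict(frozen)
    out_params[fit_species] = fitted
    return BirksFit(
        fitted=fitted,
        params=out_params,
        r_squared=r2,
        n_points=int(sel.sum()),
        residual_norm=float(np.sqrt(resid @ resid)),
    )


# --------------------------------------------------------------------------
# finite-probe volume averaging
# --------------------------------------------------------------------------


def _boxcar(values: np.ndarray, window_bins: int) -> np.ndarray:
    kernel = np.ones(window_bins)
    norm = np.convolve(np.ones_like(values), kernel, mode="same")
    return np.convolve(values, kernel, mode="same") / norm


def volume_average(obj, probe: ProbeSpec):
    """Boxcar-average a curve or profile over the probe's active length.

    The moving-average window equals the probe length along the beam,
    renormalized at the edges.  A window at or below one bin returns the
    input unchanged with a warning.
    """
    if isinstance(obj, DepthDoseCurve):
        grid = obj.grid
    elif isinstance(obj, SpeciesDepthProfile):
        grid = obj.grid
    else:
        raise TypeError("expected DepthDoseCurve or SpeciesDepthProfile")
    if grid.bin_width > probe.active_length_mm:
        raise ConfigurationError(
            "grid spacing exceeds the probe active length; refine the grid"
        )
    window = int(round(probe.active_length_mm / grid.bin_width))
    if window <= 1:
        warnings.warn(
            "averaging window is a single bin; returning input unchanged",
            stacklevel=2,
        )
        return obj
    if isinstance(obj, DepthDoseCurve):
        return DepthDoseCurve(grid, _boxcar(obj.dose, window), obj.source)
    let = np.column_stack(
        [_boxcar(obj.let_mev_cm[:, j], window) for j in range(len(obj.species))]
    )
    frac = np.column_stack(
        [_boxcar(obj.fluence_fraction[:, j], window) for j in range(len(obj.species))]
    )
    frac = frac / frac.sum(axis=1)[:, None]
    fluence = (
        _boxcar(obj.absolute_fluence, window)
        if obj.absolute_fluence is not None
        else None
    )
    return SpeciesDepthProfile(grid, list(obj.species), frac, let, fluence)


# --------------------------------------------------------------------------
# corrected curves and metrics
# --------------------------------------------------------------------------

FALLOFF_DOSE_FRACTION = 0.8  # distal boundary: 80% of peak dose
PLATEAU_DEPTH_FRACTION = 0.9  # plateau: depths below 90% of the peak depth


@dataclass
class CorrectionResult:
    """Quenching-corrected depth dose with difference-vs-reference metrics."""

    depths: np.ndarray
    eta: np.ndarray
    corrected: np.ndarray
    uncorrected: np.ndarray
    reference_norm: np.ndarray
    diff_pct_corrected: np.ndarray
    diff_pct_uncorrected: np.ndarray
    falloff_flag: np.ndarray
    metrics: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "depth_mm": self.depths,
                "eta": self.eta,
                "dose_corrected": self.corrected,
                "dose_uncorrected": self.uncorrected,
                "ref_dose": self.reference_norm,
                "diff_pct_corrected": self.diff_pct_corrected,
                "diff_pct_uncorrected": self.diff_pct_uncorrected,
                "falloff": self.falloff_flag,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def correct_curve(
    measured: NormalizedRL,
    profile: SpeciesDepthProfile,
    params: Mapping[str, BirksParams],
    reference: DepthDoseCurve,
    default: BirksParams | None = UNPARAMETERIZED_DEFAULT,
) -> CorrectionResult:
    """Apply the fluence-weighted quenching correction to a measured curve.

    corrected(d) = eta(d) * measured(d) / eta(entrance), renormalized so
    the corrected entrance equals the reference entrance.  Per-depth
    percent differences versus the reference are reported for both the
    corrected and uncorrected curves, along with summary metrics at the
    peak, in the plateau, and in the (flagged) falloff region beyond the
    80% distal dose depth.
    """
    depths = measured.depths
    frac = np.stack([profile.at_depth(d)[0] for d in depths])
    lets = np.stack([profile.at_depth(d)[1] for d in depths])
    eta = eta_combined(profile.species, frac, lets, params, default)
    if not np.all(np.isfinite(eta)):
        bad = depths[~np.isfinite(eta)][0]
        raise IonquenchError(f"non-finite correction factor at depth {bad} mm")

    refn = reference.normalized()
    ref_at = np.array([refn.at(d) for d in depths])
    corrected = eta * measured.values / eta[0]
    corrected = corrected / corrected[0]  # anchor entrance to the reference
    uncorrected = measured.values / measured.values[0]

    with np.errstate(divide="ignore", invalid="ignore"):
        diff_c = 100.0 * (corrected - ref_at) / ref_at
        diff_u = 100.0 * (uncorrected - ref_at) / ref_at
    diff_c[ref_at <= 0] = np.nan
    diff_u[ref_at <= 0] = np.nan

    i_peak = int(np.argmax(ref_at))
    peak_depth = float(depths[i_peak])
    peak_dose = float(ref_at[i_peak])
    beyond = np.arange(len(depths)) > i_peak
    below80 = beyond & (ref_at < FALLOFF_DOSE_FRACTION * peak_dose)
    d80 = float(depths[below80][0]) if below80.any() else float(depths[-1])
    falloff = depths > d80
    plateau = depths <= PLATEAU_DEPTH_FRACTION * peak_depth

    def _maxabs(arr, mask):
        vals = arr[mask]
        vals = vals[np.isfinite(vals)]
        return float(np.max(np.abs(vals))) if len(vals) else float("nan")

    metrics = {
        "peak_depth_mm": peak_depth,
        "falloff_boundary_mm": d80,
        "diff_at_peak_pct_corrected": float(diff_c[i_peak]),
        "diff_at_peak_pct_uncorrected": float(diff_u[i_peak]),
        "max_plateau_pct_corrected": _maxabs(diff_c, plateau),
        "max_plateau_pct_uncorrected": _maxabs(diff_u, plateau),
        "max_falloff_pct_corrected": _maxabs(diff_c, falloff),
        "max_falloff_pct_uncorrected": _maxabs(diff_u, falloff),
    }
    return CorrectionResult(
        depths=depths,
        eta=eta,
        corrected=corrected,
        uncorrected=uncorrected,
        reference_norm=ref_at,
        diff_pct_corrected=diff_c,
        diff_pct_uncorrected=diff_u,
        falloff_flag=falloff,
        metrics=metrics,
    )
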