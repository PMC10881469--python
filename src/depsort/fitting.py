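"""Fitting single-shell DEP spectra to extract cell electric parameters.

Given a relative-force spectrum (proportional to Re[K(f)]), the fitter
estimates the three cell parameters accessible from a DEP spectrum —
membrane relative permittivity, membrane conductivity and cytoplasm
conductivity — together with the unknown instrument proportionality
scale, by bounded nonlinear least squares:

    min_theta,scale  sum_i ( relative_force_i - scale * Re[K(f_i; theta)] )^2

The cell radius, membrane thickness, cytoplasm permittivity and the
buffer properties are held fixed (radius comes from the per-group cell
size measurement, not the fit).  Conductivities are optimized on a log10
scale, since they span decades.  A seeded multi-start (default 5
restarts) guards against local minima.  Crossover frequencies are then
computed from the fitted parameters on the instrument range
(10 kHz - 50 MHz).

Quality control mirrors instrument-analysis practice: an iterative
MAD-based outlier rule drops gross single-point artifacts before the
final fit, and spectra whose final R^2 falls below a threshold are
rejected as a whole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import (
    DielectricMedium,
    DomainError,
    FrequencyGrid,
    ShelledParticle,
    crossover_frequencies,
    re_cm_spectrum,
)
from .synthetic import DepSpectrum

_MIN_POINTS = 6  # 4 free parameters + 2


@dataclass(frozen=True)
class FitConfig:
    """Fixed quantities, free-parameter bounds/guesses and QC settings.

    Bounds are (low, high); initial guesses default to the geometric
    mid-bound.  ``outlier_k`` multiplies the MAD-scaled residual spread
    (1.4826 * median |residual|); points beyond it are dropped, up to
    ``max_outlier_fraction`` of the spectrum.
    """

    radius: float = 9e-6
    membrane_thickness: float = 5e-9
    int_rel_permittivity: float = 60.0
    medium: DielectricMedium = field(default_factory=lambda: DielectricMedium(80.0, 0.04))
    mem_rel_permittivity_bounds: tuple[float, float] = (1.0, 30.0)
    mem_conductivity_bounds: tuple[float, float] = (1e-9, 1e-4)
    int_conductivity_bounds: tuple[float, float] = (0.01, 2.0)
    scale_bounds: tuple[float, float] = (1e-3, 1e3)
    r2_threshold: float = 0.85
    outlier_k: float = 3.0
    max_outlier_fraction: float = 0.2
    n_starts: int = 5
    seed: int = 0
    log_freq_weighting: bool = False
    co_range: tuple[float, float] = (1e4, 5e7)

    def __post_init__(self) -> None:
        for lo, hi in (
            self.mem_rel_permittivity_bounds,
            self.mem_conductivity_bounds,
            self.int_conductivity_bounds,
            self.scale_bounds,
        ):
            if not (0 < lo < hi):
                raise DomainError("bounds must satisfy 0 < low < high")
        if not (0 < self.r2_threshold < 1):
            raise DomainError("r2_threshold must be in (0, 1)")
        if self.outlier_k <= 0:
            raise DomainError("outlier_k must be > 0")

    def with_radius(self, radius: float) -> "FitConfig":
        return replace(self, radius=radius)

    def particle(self, mem_rel_permittivity, mem_conductivity, int_conductivity) -> ShelledParticle:
        return ShelledParticle(
            radius=self.radius,
            membrane_thickness=self.membrane_thickness,
            mem_rel_permittivity=mem_rel_permittivity,
            mem_conductivity=mem_conductivity,
            int_rel_permittivity=self.int_rel_permittivity,
            int_conductivity=int_conductivity,
        )


@dataclass(frozen=True)
class FitResult:
    """Extracted electric parameters and diagnostics for one spectrum."""

    mem_rel_permittivity: float
    mem_conductivity: float
    int_conductivity: float
    scale: float
    r_squared: float
    co_first: float | None
    co_second: float | None
    n_points_used: int
    rejected: bool = False
    reject_reason: str = ""
    group: str = ""
    replicate: int = 0
    well_id: str = ""

    #: parameter fields summarized by :func:`summarize_group`
    PARAMS = (
        "mem_rel_permittivity",
        "mem_conductivity",
        "int_conductivity",
        "scale",
        "co_first",
        "co_second",
    )


def _model_matrix(cfg: FitConfig, grid: FrequencyGrid):
    """Residual function over x = (eps_mem, log10 s_mem, log10 s_int, scale)."""

    weights = None
    if cfg.log_freq_weighting:
        # weight each point by the log-frequency interval it represents
        lf = np.log10(grid.frequencies)
        w = np.gradient(lf)
        weights = np.sqrt(w / w.mean())

    def model(x: np.ndarray) -> np.ndarray:
        p = cfg.particle(x[0], 10.0 ** x[1], 10.0 ** x[2])
        return x[3] * re_cm_spectrum(p, cfg.medium, grid)

    return model, weights


def _bounds_arrays(cfg: FitConfig):
    lo = np.array(
        [
            cfg.mem_rel_permittivity_bounds[0],
            math.log10(cfg.mem_conductivity_bounds[0]),
            math.log10(cfg.int_conductivity_bounds[0]),
            cfg.scale_bounds[0],
        ]
    )
    hi = np.array(
        [
            cfg.mem_rel_permittivity_bounds[1],
            math.log10(cfg.mem_conductivity_bounds[1]),
            math.log10(cfg.int_conductivity_bounds[1]),
            cfg.scale_bounds[1],
        ]
    )
    return lo, hi


def _starts(cfg: FitConfig, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """First start at the (geometric) mid-bounds, the rest seeded uniform draws."""
    mid = np.empty(4)
    mid[0] = math.sqrt(lo[0] * hi[0])
    mid[1] = 0.5 * (lo[1] + hi[1])
    mid[2] = 0.5 * (lo[2] + hi[2])
    mid[3] = math.sqrt(lo[3] * hi[3])
    starts = [mid]
    rng = np.random.default_rng(cfg.seed)
    for _ in range(max(0, cfg.n_starts - 1)):
        x = rng.uniform(lo, hi)
        x[3] = 10.0 ** rng.uniform(math.log10(lo[3]), math.log10(hi[3]))
        starts.append(x)
    return np.array(starts)


def _rejected(cfg: FitConfig, s: DepSpectrum, reason: str, n_used: int) -> FitResult:
    return FitResult(
        mem_rel_permittivity=math.nan,
        mem_conductivity=math.nan,
        int_conductivity=math.nan,
        scale=math.nan,
        r_squared=0.0,
        co_first=None,
        co_second=None,
        n_points_used=n_used,
        rejected=True,
        reject_reason=reason,
        group=s.group,
        replicate=s.replicate,
        well_id=s.well_id,
    )


def fit_spectrum(s: DepSpectrum, cfg: FitConfig) -> FitResult:
    """Fit the single-shell model to one spectrum.

    Raises on fewer than 6 points (4 free parameters + 2); returns a
    result flagged ``rejected`` for degenerate spectra (e.g. all zeros,
    scale unidentifiable) or optimizer non-convergence.
    """
    if len(s) < _MIN_POINTS:
        raise DomainError(f"need >= {_MIN_POINTS} frequency points, got {len(s)}")

    y = s.relative_force
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0.0 or not np.any(np.abs(y) > 0):
        return _rejected(cfg, s, "degenerate spectrum (no variation; scale unidentifiable)", len(s))

    model, weights = _model_matrix(cfg, s.grid)
    lo, hi = _bounds_arrays(cfg)

    def residuals(x):
        r = y - model(x)
        return r * weights if weights is not None else r

    best = None
    for x0 in _starts(cfg, lo, hi):
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return _rejected(cfg, s, "optimizer did not converge", len(s))

    x = best.x
    ss_res = float(np.sum((y - model(x)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    p = cfg.particle(x[0], 10.0 ** x[1], 10.0 ** x[2])
    roots = crossover_frequencies(p, cfg.medium, *cfg.co_range)
    return FitResult(
        mem_rel_permittivity=float(x[0]),
        mem_conductivity=float(10.0 ** x[1]),
        int_conductivity=float(10.0 ** x[2]),
        scale=float(x[3]),
        r_squared=r2,
        co_first=roots[0] if len(roots) > 0 else None,
        co_second=roots[1] if len(roots) > 1 else None,
        n_points_used=len(s),
        group=s.group,
        replicate=s.replicate,
        well_id=s.well_id,
    )


def remove_outliers(s: DepSpectrum, cfg: FitConfig) -> tuple[DepSpectrum, list[int]]:
    """Iteratively drop gross single-point artifacts from a spectrum.

    Fit, compute residuals, drop points with |residual| beyond
    ``outlier_k * 1.4826 * median|residual|``, refit; stops at a fixed
    point or when dropping more would exceed ``max_outlier_fraction`` of
    the original length.  Returns the cleaned spectrum and the removed
    indices (into the original grid).
    """
    if len(s) < _MIN_POINTS:
        raise DomainError(f"need >= {_MIN_POINTS} frequency points, got {len(s)}")
    n0 = len(s)
    max_removed = int(math.floor(cfg.max_outlier_fraction * n0))
    keep = np.arange(n0)
    current = s
    while True:
        fit = fit_spectrum(current, cfg)
        if fit.rejected:
            break
        p = cfg.particle(fit.mem_rel_permittivity, fit.mem_conductivity, fit.int_conductivity)
        resid = current.relative_force - fit.scale * re_cm_spectrum(p, cfg.medium, current.grid)
        mad_scale = 1.4826 * float(np.median(np.abs(resid)))
        # a near-perfect fit leaves only float noise; nothing to remove
        if mad_scale <= 1e-10 * float(np.max(np.abs(current.relative_force))):
            break
        bad = np.abs(resid) > cfg.outlier_k * mad_scale
        if not np.any(bad):
            break
        # drop worst offenders first, respecting the global cap
        order = np.argsort(-np.abs(resid))
        to_drop = [i for i in order if bad[i]]
        budget = max_removed - (n0 - len(keep))
        to_drop = to_drop[: max(0, budget)]
        if not to_drop or len(current) - len(to_drop) < _MIN_POINTS:
            break
        mask = np.ones(len(current), dtype=bool)
        mask[to_drop] = False
        keep = keep[mask]
        current = DepSpectrum(
            grid=FrequencyGrid(current.grid.frequencies[mask]),
            relative_force=current.relative_force[mask],
            buffer_conductivity=current.buffer_conductivity,
            buffer_rel_permittivity=current.buffer_rel_permittivity,
            radius=current.radius,
            group=current.group,
            replicate=current.replicate,
            well_id=current.well_id,
            seed=current.seed,
        )
    removed = sorted(set(range(n0)) - set(keep.tolist()))
    return current, removed


def fit_spectrum_qc(s: DepSpectrum, cfg: FitConfig, use_radius_metadata: bool = True) -> FitResult:
    """Outlier removal + fit + R^2 gating for one spectrum (pipeline entry point)."""
    if use_radius_metadata and s.radius > cfg.membrane_thickness:
        cfg = cfg.with_radius(s.radius)
    cleaned, _removed = remove_outliers(s, cfg)
    result = fit_spectrum(cleaned, cfg)
    if not result.rejected and result.r_squared < cfg.r2_threshold:
        result = replace(
            result,
            rejected=True,
            reject_reason=f"R^2 {result.r_squared:.4f} below threshold {cfg.r2_threshold}",
        )
    return result


def gate_by_r2(results: list[FitResult], threshold: float) -> tuple[list[FitResult], list[FitResult]]:
    """Partition results into (accepted, rejected) by R^2 >= threshold.

    Results already flagged ``rejected`` go to the rejected side
    regardless of their R^2.  Counts are conserved.
    """
    accepted = [r for r in results if not r.rejected and r.r_squared >= threshold]
    rejected = [r for r in results if r.rejected or r.r_squared < threshold]
    return accepted, rejected


def summarize_group(results: list[FitResult]) -> pd.DataFrame:
    """Per-parameter mean, sample SD and n over accepted results.

    Rows are the fitted parameters plus the crossover frequencies; a CO
    absent from a fit is excluded from that row's n.  Raises on an empty
    accepted set.
    """
    accepted = [r for r in results if not r.rejected]
    if not accepted:
        raise DomainError("no accepted fits to summarize")
    rows = {}
    for name in FitResult.PARAMS:
        vals = np.array(
            [getattr(r, name) for r in accepted if getattr(r, name) is not None], dtype=float
        )
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            rows[name] = (math.nan, math.nan, 0)
        else:
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            rows[name] = (float(vals.mean()), sd, int(vals.size))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["mean", "sd", "n"])


FITS_COLUMNS = [
    "group",
    "replicate",
    "well_id",
    "mem_rel_permittivity",
    "mem_conductivity_S_per_m",
    "int_conductivity_S_per_m",
    "scale",
    "r_squared",
    "co_first_hz",
    "co_second_hz",
    "n_points_used",
    "rejected",
    "reject_reason",
]


def fits_to_frame(results: list[FitResult]) -> pd.DataFrame:
    """One row per spectrum, rejected rows flagged rather than dropped."""
    rows = []
    for r in results:
        rows.append(
            {
                "group": r.group,
                "replicate": r.replicate,
                "well_id": r.well_id,
                "mem_rel_permittivity": r.mem_rel_permittivity,
                "mem_conductivity_S_per_m": r.mem_conductivity,
                "int_conductivity_S_per_m": r.int_conductivity,
                "scale": r.scale,
                "r_squared": r.r_squared,
                "co_first_hz": r.co_first if r.co_first is not None else math.nan,
                "co_second_hz": r.co_second if r.co_second is not None else math.nan,
                "n_points_used": r.n_points_used,
                "rejected": r.rejected,
                "reject_reason": r.reject_reason,
            }
        )
    return pd.DataFrame(rows, columns=FITS_COLUMNS)


def write_fits(results: list[FitResult], path) -> None:
    fits_to_frame(results).to_csv(path, index=False)
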