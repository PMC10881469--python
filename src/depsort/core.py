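"""Single-shell dielectrophoresis (DEP) physics.

A biological cell in a non-uniform AC field experiences the time-averaged
DEP force

    F_DEP = 2 pi r^3 eps0 eps_med Re[K(f)] grad|E|^2

where ``K(f)`` is the Clausius–Mossotti (CM) factor, the complex contrast
between the effective particle permittivity and that of the suspending
medium::

    K = (eps_p* - eps_med*) / (eps_p* + 2 eps_med*)

Each material is described by a complex permittivity
``eps* = eps0*eps_r - j*sigma/(2 pi f)``.  The cell is idealized as a
conductive homogeneous sphere (cytoplasm) covered by a thin, poorly
conducting shell (plasma membrane): the "single-shell" model.  The
frequencies at which ``Re[K(f)] = 0`` are the crossover (CO) frequencies;
the first CO is controlled mainly by the membrane capacitance and the
medium conductivity, the second by the cytoplasm.

All user-facing permittivities are RELATIVE (dimensionless); the complex
arithmetic internally multiplies by ``EPS0`` so that K is dimensionless
either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

#: Vacuum permittivity, F/m (CODATA 2018).
EPS0 = 8.8541878128e-12

_DEGENERATE_TOL = 1e-300


class DomainError(ValueError):
    """Raised when a physical precondition is violated."""


class DegenerateInputError(ValueError):
    """Raised when an input makes the model singular (e.g. CM denominator ~ 0)."""


@dataclass(frozen=True)
class DielectricMedium:
    """Suspending buffer: relative permittivity and conductivity (S/m)."""

    rel_permittivity: float
    conductivity: float

    def __post_init__(self) -> None:
        if not self.rel_permittivity > 0:
            raise DomainError("medium rel_permittivity must be > 0")
        if self.conductivity < 0:
            raise DomainError("medium conductivity must be >= 0")


@dataclass(frozen=True)
class ShelledParticle:
    """One cell in the single-shell model.

    Parameters
    ----------
    radius : float
        Outer cell radius, m.
    membrane_thickness : float
        Shell thickness d, m (typically ~5 nm for a plasma membrane).
    mem_rel_permittivity, mem_conductivity : float
        Membrane relative permittivity (dimensionless) and conductivity (S/m).
    int_rel_permittivity, int_conductivity : float
        Cytoplasm relative permittivity and conductivity.
    """

    radius: float
    membrane_thickness: float
    mem_rel_permittivity: float
    mem_conductivity: float
    int_rel_permittivity: float
    int_conductivity: float

    def __post_init__(self) -> None:
        if self.membrane_thickness < 0:
            raise DomainError("membrane_thickness must be >= 0")
        if not self.radius > self.membrane_thickness:
            raise DomainError("radius must exceed membrane_thickness (shell model singular)")
        if self.mem_rel_permittivity <= 0 or self.int_rel_permittivity <= 0:
            raise DomainError("relative permittivities must be > 0")
        if self.mem_conductivity < 0 or self.int_conductivity < 0:
            raise DomainError("conductivities must be >= 0")


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of AC frequencies, Hz, all > 0."""

    frequencies: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise DomainError("frequency grid must be a non-empty 1-D sequence")
        if not np.all(f > 0):
            raise DomainError("all frequencies must be > 0")
        if not np.all(np.diff(f) > 0):
            raise DomainError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    def __len__(self) -> int:
        return len(self.frequencies)


def _check_frequency(f) -> np.ndarray:
    fa = np.asarray(f, dtype=float)
    if not np.all(fa > 0):
        raise DomainError("frequency must be > 0")
    return fa


def complex_permittivity(rel_permittivity: float, conductivity: float, f):
    """Complex absolute permittivity eps* = eps0*eps_r - j*sigma/(2 pi f), F/m.

    ``f`` may be a scalar or array of frequencies in Hz (all > 0).
    """
    fa = _check_frequency(f)
    return EPS0 * rel_permittivity - 1j * conductivity / (2.0 * math.pi * fa)


def equivalent_particle_permittivity(p: ShelledParticle, f):
    """Effective complex permittivity of a shelled sphere (single-shell model).

    With ``a = (r/(r-d))^3`` and the core/shell contrast
    ``k = (eps_int* - eps_mem*)/(eps_int* + 2 eps_mem*)``::

        eps_p* = eps_mem* (a + 2k) / (a - k)

    A zero-thickness shell collapses exactly to the interior permittivity.
    """
    eps_int = complex_permittivity(p.int_rel_permittivity, p.int_conductivity, f)
    if p.membrane_thickness == 0.0:
        return eps_int
    eps_mem = complex_permittivity(p.mem_rel_permittivity, p.mem_conductivity, f)
    a = (p.radius / (p.radius - p.membrane_thickness)) ** 3
    k = (eps_int - eps_mem) / (eps_int + 2.0 * eps_mem)
    return eps_mem * (a + 2.0 * k) / (a - k)


def clausius_mossotti(p: ShelledParticle, m: DielectricMedium, f):
    """Complex Clausius–Mossotti factor K(f) = (eps_p*-eps_med*)/(eps_p*+2 eps_med*).

    For physical inputs Re[K] lies in [-0.5, 1.0].
    """
    eps_p = equivalent_particle_permittivity(p, f)
    eps_med = complex_permittivity(m.rel_permittivity, m.conductivity, f)
    den = eps_p + 2.0 * eps_med
    if np.any(np.abs(den) < _DEGENERATE_TOL):
        raise DegenerateInputError("CM denominator vanishes for the given inputs")
    return (eps_p - eps_med) / den


def re_cm_spectrum(p: ShelledParticle, m: DielectricMedium, grid: FrequencyGrid) -> np.ndarray:
    """Re[K(f)] evaluated on a frequency grid — the model DEP spectrum."""
    return np.real(clausius_mossotti(p, m, grid.frequencies))


def dep_force_magnitude(p: ShelledParticle, m: DielectricMedium, f, grad_e2) -> float:
    """Time-averaged DEP force, N: 2 pi r^3 eps0 eps_med Re[K] * grad|E|^2.

    ``grad_e2`` is the magnitude of the gradient of the squared field
    intensity, V^2/m^3; the sign of the result follows Re[K].
    """
    re_k = np.real(clausius_mossotti(p, m, f))
    return 2.0 * math.pi * p.radius**3 * EPS0 * m.rel_permittivity * re_k * grad_e2


def crossover_frequencies(
    p: ShelledParticle,
    m: DielectricMedium,
    f_min: float = 1e4,
    f_max: float = 5e7,
    points_per_decade: int = 2000,
) -> list[float]:
    """All roots of Re[K(f)] = 0 in [f_min, f_max], ascending (possibly empty).

    Sign-change bracketing on a dense logarithmic scan, then Brent
    refinement to 1e-9 relative tolerance in frequency.  The default search
    range is the 3DEP instrument range, 10 kHz - 50 MHz.  Roots closer than
    1e-6 relative are deduplicated.
    """
    if not (0 < f_min < f_max):
        raise DomainError("require 0 < f_min < f_max")
    n = max(8, int(points_per_decade * math.log10(f_max / f_min)) + 1)
    freqs = np.geomspace(f_min, f_max, n)
    vals = np.real(clausius_mossotti(p, m, freqs))

    roots: list[float] = []
    exact = np.flatnonzero(vals == 0.0)
    roots.extend(freqs[exact].tolist())
    sign = np.sign(vals)
    # brackets where consecutive nonzero values differ in sign
    idx = np.flatnonzero((sign[:-1] * sign[1:]) < 0)
    for i in idx:
        g = lambda f: float(np.real(clausius_mossotti(p, m, f)))
        root = brentq(g, freqs[i], freqs[i + 1], xtol=1e-300, rtol=1e-12)
        roots.append(float(root))

    roots.sort()
    deduped: list[float] = []
    for r in roots:
        if not deduped or abs(r - deduped[-1]) > 1e-6 * deduped[-1]:
            deduped.append(r)
    return deduped


def first_crossover(
    p: ShelledParticle, m: DielectricMedium, f_min: float = 1e4, f_max: float = 5e7
) -> float | None:
    """First (lowest) crossover frequency in range, or None."""
    roots = crossover_frequencies(p, m, f_min, f_max)
    return roots[0] if roots else None
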