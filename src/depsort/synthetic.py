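"""Synthetic 3DEP-style DEP spectra and cell populations.

The 3DEP well-plate instrument reports, per frequency, a dimensionless
"relative DEP force" that is directly proportional to Re[K(f)].  This
module emulates that output so the whole analysis chain can be exercised
without instrument data: a population model with between-cell variability
in radius, membrane permittivity/conductivity and cytoplasm conductivity;
a per-spectrum proportionality scale; and additive Gaussian measurement
noise on the relative force.

The default acquisition grid is 20 log-spaced frequencies from 10 kHz to
40 MHz; the default replicate structure is 24 spectra per group.

The bundled fixture populations (:func:`msc_like_population`,
:func:`differentiated_like_population`) are synthetic stand-ins chosen
within literature ranges for mammalian cells (membrane relative
permittivity ~6-9, membrane conductivity ~1e-6 S/m, cytoplasm
conductivity a few tenths of S/m); they are NOT measured values.  The
differentiated-like population has the lower membrane permittivity and
hence the higher first crossover frequency — the direction of change seen
when mesenchymal stem cells start to differentiate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DielectricMedium,
    DomainError,
    FrequencyGrid,
    ShelledParticle,
    re_cm_spectrum,
)

#: CSV dialect: required columns, in canonical order.
SPECTRA_COLUMNS = [
    "frequency_hz",
    "relative_force",
    "group",
    "replicate",
    "well_id",
    "buffer_conductivity_S_per_m",
    "buffer_rel_permittivity",
    "radius_m",
    "seed",
]

_MAX_REDRAWS = 100


def default_frequency_grid() -> FrequencyGrid:
    """20 log-spaced frequencies, 10 kHz to 40 MHz inclusive (3DEP acquisition grid)."""
    return FrequencyGrid(np.geomspace(1e4, 4e7, 20))


@dataclass(frozen=True)
class PopulationModel:
    """Mean/SD description of one cell population for the single-shell model.

    Varying parameters (mean, sd): radius (m), membrane relative
    permittivity, membrane conductivity (S/m), cytoplasm conductivity
    (S/m).  Fixed across the population: membrane thickness (m) and
    cytoplasm relative permittivity.  ``distribution`` is "uniform"
    (default; parameters drawn uniformly on [mean-sd, mean+sd]) or
    "normal".
    """

    label: str
    radius_mean: float
    radius_sd: float
    mem_rel_permittivity_mean: float
    mem_rel_permittivity_sd: float
    mem_conductivity_mean: float
    mem_conductivity_sd: float
    int_conductivity_mean: float
    int_conductivity_sd: float
    membrane_thickness: float = 5e-9
    int_rel_permittivity: float = 60.0
    distribution: str = "uniform"

    def __post_init__(self) -> None:
        self.mean_particle()  # validates means against ShelledParticle invariants
        for sd in (
            self.radius_sd,
            self.mem_rel_permittivity_sd,
            self.mem_conductivity_sd,
            self.int_conductivity_sd,
        ):
            if sd < 0:
                raise DomainError("population SDs must be >= 0")
        if self.distribution not in ("uniform", "normal"):
            raise DomainError("distribution must be 'uniform' or 'normal'")

    def mean_particle(self) -> ShelledParticle:
        """The population-mean cell."""
        return ShelledParticle(
            radius=self.radius_mean,
            membrane_thickness=self.membrane_thickness,
            mem_rel_permittivity=self.mem_rel_permittivity_mean,
            mem_conductivity=self.mem_conductivity_mean,
            int_rel_permittivity=self.int_rel_permittivity,
            int_conductivity=self.int_conductivity_mean,
        )


def msc_like_population(label: str = "MSC") -> PopulationModel:
    """Synthetic undifferentiated-MSC-like fixture population (stand-in values)."""
    return PopulationModel(
        label=label,
        radius_mean=9e-6,
        radius_sd=0.5e-6,
        mem_rel_permittivity_mean=9.0,
        mem_rel_permittivity_sd=0.3,
        mem_conductivity_mean=1e-6,
        mem_conductivity_sd=0.1e-6,
        int_conductivity_mean=0.4,
        int_conductivity_sd=0.02,
    )


def differentiated_like_population(label: str = "diff_w1") -> PopulationModel:
    """Synthetic early-differentiated fixture population: same size as the
    MSC-like population but lower membrane permittivity/conductivity and
    cytoplasm conductivity, hence a higher first crossover frequency."""
    return PopulationModel(
        label=label,
        radius_mean=9e-6,
        radius_sd=0.5e-6,
        mem_rel_permittivity_mean=6.0,
        mem_rel_permittivity_sd=0.3,
        mem_conductivity_mean=0.5e-6,
        mem_conductivity_sd=0.1e-6,
        int_conductivity_mean=0.3,
        int_conductivity_sd=0.02,
    )


def dep_buffer(conductivity: float = 0.04, rel_permittivity: float = 80.0) -> DielectricMedium:
    """Sucrose-based DEP buffer; the working conductivities are 0.04 and 0.128 S/m."""
    return DielectricMedium(rel_permittivity=rel_permittivity, conductivity=conductivity)


def _draw(rng: np.random.Generator, mean: float, sd: float, distribution: str) -> float:
    if sd == 0.0:
        return mean
    if distribution == "uniform":
        return rng.uniform(mean - sd, mean + sd)
    return rng.normal(mean, sd)


def sample_population(model: PopulationModel, n: int, seed: int) -> list[ShelledParticle]:
    """Draw ``n`` cells with parameters varied independently around the means.

    Uniform draws on [mean-sd, mean+sd] by default ("randomly attributed
    parameters ranging within the standard deviation"); draws violating the
    particle invariants are redrawn a bounded number of times.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    particles: list[ShelledParticle] = []
    for _ in range(n):
        for attempt in range(_MAX_REDRAWS):
            try:
                particles.append(
                    ShelledParticle(
                        radius=_draw(rng, model.radius_mean, model.radius_sd, model.distribution),
                        membrane_thickness=model.membrane_thickness,
                        mem_rel_permittivity=_draw(
                            rng,
                            model.mem_rel_permittivity_mean,
                            model.mem_rel_permittivity_sd,
                            model.distribution,
                        ),
                        mem_conductivity=_draw(
                            rng,
                            model.mem_conductivity_mean,
                            model.mem_conductivity_sd,
                            model.distribution,
                        ),
                        int_rel_permittivity=model.int_rel_permittivity,
                        int_conductivity=_draw(
                            rng,
                            model.int_conductivity_mean,
                            model.int_conductivity_sd,
                            model.distribution,
                        ),
                    )
                )
                break
            except DomainError:
                continue
        else:
            raise DomainError(
                f"could not draw a valid particle from population {model.label!r} "
                f"after {_MAX_REDRAWS} attempts"
            )
    return particles


@dataclass(frozen=True)
class DepSpectrum:
    """One measured or synthetic DEP spectrum.

    ``relative_force`` is the dimensionless instrument readout,
    proportional to Re[K(f)] through an unknown per-spectrum scale.
    """

    grid: FrequencyGrid
    relative_force: np.ndarray = field(repr=False)
    buffer_conductivity: float = 0.04
    buffer_rel_permittivity: float = 80.0
    radius: float = 9e-6
    group: str = ""
    replicate: int = 0
    well_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        rf = np.asarray(self.relative_force, dtype=float)
        if rf.shape != self.grid.frequencies.shape:
            raise DomainError("relative_force length must equal grid length")
        if not np.all(np.isfinite(rf)):
            raise DomainError("relative_force must be finite")
        object.__setattr__(self, "relative_force", rf)

    def __len__(self) -> int:
        return len(self.grid)


def generate_spectrum(
    p: ShelledParticle,
    m: DielectricMedium,
    grid: FrequencyGrid,
    scale: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    group: str = "",
    replicate: int = 0,
    well_id: str = "",
) -> DepSpectrum:
    """relative_force[i] = scale * Re[K(f_i)] + N(0, noise_sd), seeded."""
    if scale <= 0:
        raise DomainError("scale must be > 0")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    values = scale * re_cm_spectrum(p, m, grid)
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(grid))
    return DepSpectrum(
        grid=grid,
        relative_force=values,
        buffer_conductivity=m.conductivity,
        buffer_rel_permittivity=m.rel_permittivity,
        radius=p.radius,
        group=group,
        replicate=replicate,
        well_id=well_id,
        seed=seed,
    )


def generate_group_spectra(
    model: PopulationModel,
    m: DielectricMedium,
    n_replicates: int = 24,
    grid: FrequencyGrid | None = None,
    scale: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[DepSpectrum]:
    """One spectrum per replicate, each from a freshly drawn cell of ``model``.

    The reported per-spectrum radius is the drawn cell's radius, mirroring
    the per-group cell-size measurement that accompanies 3DEP runs.
    """
    grid = grid if grid is not None else default_frequency_grid()
    particles = sample_population(model, n_replicates, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    spectra = []
    for i, particle in enumerate(particles):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spectra.append(
            generate_spectrum(
                particle,
                m,
                grid,
                scale=scale,
                noise_sd=noise_sd,
                seed=sub_seed,
                group=model.label,
                replicate=i,
                well_id=f"{model.label}_{i:03d}",
            )
        )
    return spectra


def spectra_to_frame(spectra: list[DepSpectrum]) -> pd.DataFrame:
    """Long-format table, one row per (spectrum, frequency)."""
    frames = []
    for s in spectra:
        frames.append(
            pd.DataFrame(
                {
                    "frequency_hz": s.grid.frequencies,
                    "relative_force": s.relative_force,
                    "group": s.group,
                    "replicate": s.replicate,
                    "well_id": s.well_id,
                    "buffer_conductivity_S_per_m": s.buffer_conductivity,
                    "buffer_rel_permittivity": s.buffer_rel_permittivity,
                    "radius_m": s.radius,
                    "seed": s.seed,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=SPECTRA_COLUMNS)
    return pd.concat(frames, ignore_index=True)[SPECTRA_COLUMNS]


def frame_to_spectra(df: pd.DataFrame) -> list[DepSpectrum]:
    """Inverse of :func:`spectra_to_frame`; spectra ordered by first appearance."""
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spectra table missing column(s): {', '.join(missing)}")
    spectra = []
    for well_id, sub in df.groupby("well_id", sort=False):
        sub = sub.sort_values("frequency_hz")
        first = sub.iloc[0]
        spectra.append(
            DepSpectrum(
                grid=FrequencyGrid(sub["frequency_hz"].to_numpy()),
                relative_force=sub["relative_force"].to_numpy(),
                buffer_conductivity=float(first["buffer_conductivity_S_per_m"]),
                buffer_rel_permittivity=float(first["buffer_rel_permittivity"]),
                radius=float(first["radius_m"]),
                group=str(first["group"]),
                replicate=int(first["replicate"]),
                well_id=str(well_id),
                seed=int(first["seed"]),
            )
        )
    return spectra


def write_spectra(spectra: list[DepSpectrum], path) -> None:
    """Write spectra to CSV (UTF-8, header mandatory, full float precision)."""
    spectra_to_frame(spectra).to_csv(path, index=False, float_format="%.17g")


def read_spectra(path) -> list[DepSpectrum]:
    """Read a spectra CSV written by :func:`write_spectra`.

    Raises ``ValueError`` naming the offending column or row on malformed
    input; an header-only file reads back as an empty list.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed spectra CSV {path}: {exc}") from exc
    if df.empty:
        missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"spectra table missing column(s): {', '.join(missing)}")
        return []
    for col in ("frequency_hz", "relative_force", "radius_m"):
        if col in df.columns and not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(f"non-numeric value in column {col!r} at row {bad}")
    return frame_to_spectra(df)
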