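# Methods

## Single-shell model and conventions

A cell is modelled as a homogeneous conductive sphere (cytoplasm) covered
by a thin, poorly conducting shell (plasma membrane). Each phase x
(membrane, interior, medium) carries a complex permittivity
ε_x* = ε₀ε_x − j σ_x/(2πf). The shelled sphere collapses to an effective
particle permittivity via the standard mixing rule with
a = (r/(r−d))³; the Clausius–Mossotti factor K(f) then contrasts particle
and medium, and the DEP force is 2π r³ ε₀ ε_med Re[K] ∇|E|².

Conventions and numerical choices:

- User-facing permittivities are **relative**; every internal complex
  arithmetic multiplies by ε₀ = 8.8541878128e−12 F/m. K is dimensionless
  either way; this matches standard practice.
- A zero-thickness shell returns the interior permittivity exactly
  (algebraic limit handled explicitly, so d = 0 is a valid input).
- Crossover frequencies: dense logarithmic scan (2000 points/decade) for
  sign changes, Brent refinement to 1e−12 relative in frequency (so the
  residual |Re K| at a reported root is far below the 1e−9 certificate),
  deduplication of roots closer than 1e−6 relative, ascending order. The
  default search window is the instrument range 10 kHz–50 MHz.
- Defaults for quantities the spectrum does not constrain: membrane
  thickness d = 5 nm, cytoplasm relative permittivity 60, buffer relative
  permittivity 80. All are configurable; none is fitted.

## Synthetic spectra generator

The generator emulates a 3DEP-style well-plate readout: 20 log-spaced
frequencies from 10 kHz to 40 MHz, a per-spectrum "relative DEP force"
equal to scale · Re[K(f)] plus additive homoscedastic Gaussian noise
(default SD 0.05 of the dimensionless force). Between-cell variability is
uniform on [mean − SD, mean + SD] for radius, membrane permittivity,
membrane conductivity and cytoplasm conductivity (a Gaussian option
exists); the uniform choice reads the idea of parameters "ranging within"
one SD literally and guarantees bounded, always-physical draws. Default
replicate structure: 24 spectra per group.

Fixture populations (synthetic stand-ins chosen inside literature ranges
for mammalian cells — membrane relative permittivity ≈ 6–9, membrane
conductivity ≈ 0.5–5 × 10⁻⁶ S/m, cytoplasm conductivity a few tenths of
S/m):

| population           | r (µm)  | ε_mem | σ_mem (S/m) | σ_int (S/m) |
|----------------------|---------|-------|-------------|-------------|
| MSC-like             | 9 ± 0.5 | 9 ± 0.3 | 1e−6 ± 1e−7 | 0.40 ± 0.02 |
| differentiated-like  | 9 ± 0.5 | 6 ± 0.3 | 5e−7 ± 1e−7 | 0.30 ± 0.02 |

Equal mean radius is deliberate: it isolates the membrane-permittivity
difference as the separating mechanism, mirroring the first week of
differentiation when cell size has not yet changed. The SDs are a design
choice (measured per-week SDs are not available to this package); they
are modest enough that the two populations' Re[K] distributions do not
overlap at the operating frequency.

What the generator does **not** emulate: electrode polarization at low
frequency, frequency-dependent intrinsic permittivities, per-well scale
drift, image-analysis artifacts of the real instrument, and hierarchical
donor-to-donor variability. Passing tests therefore demonstrate the
correctness and self-consistency of the analysis chain, not robustness
against every artifact of real 3DEP data.

## Spectrum fitting

Bounded trust-region least squares (scipy `least_squares`, trf) over four
free parameters: membrane relative permittivity (bounds [1, 30]),
membrane conductivity ([1e−9, 1e−4] S/m) and cytoplasm conductivity
([0.01, 2] S/m) — both conductivities on a log₁₀ internal scale since
they span decades — plus the instrument scale ([1e−3, 1e3]). Radius,
membrane thickness, interior permittivity and the buffer are fixed
(radius from the spectrum's metadata, i.e. the per-group cell-size
measurement). The first start sits at the (geometric) mid-bounds; four
further seeded random restarts guard against local minima. Residuals are
unweighted across frequency by default (log-frequency weighting is a
config flag).

Quality control: an iterative outlier pass drops points whose absolute
residual exceeds k · 1.4826 · median|residual| (k = 3), at most 20% of
the spectrum, stopping at a fixed point; a near-perfect fit (residual
spread below 1e−10 of the data scale) short-circuits the pass so float
noise is never "removed". Whole spectra are rejected when the final R²
falls below 0.85, when the data carry no variation (scale
unidentifiable), or when the optimizer fails. Rejected spectra are
flagged with a reason, never silently dropped.

These QC constants are explicit stand-ins: the upstream analysis software
this mirrors does not publish its threshold, outlier rule or optimizer
settings.

## Group statistics

One-way ANOVA via the classical between/within sums-of-squares
decomposition (implemented directly — the decomposition is also the
degenerate-input check), p-values from the F survival function. Pairwise
comparisons by Tukey's HSD (scipy `tukey_hsd`, Tukey–Kramer for unequal
n). Star convention with strict inequalities: p < 0.001 → ***,
p < 0.01 → **, p < 0.05 → *, otherwise "ns" (so p = 0.05 exactly is
"ns"). Each fitted parameter is its own comparison family; no correction
is applied across parameters.

## 2D sorter simulation

Geometry (x along the flow, y across; left wall at y = 0):

- Channel 5 mm × 500 µm.
- Neutral electrode: a 50 µm-wide strip running obliquely from the right
  wall at x = 0.5 mm down to y = 0.1·w at x = 4.5 mm. The strip stops
  short of the left wall deliberately: the wall is no-slip, so a cell
  delivered exactly to y = 0 would sit in stagnant fluid and never exit;
  terminating at 0.1·w releases escorted cells into moving fluid.
- Phase electrode: a comb of 50 µm-wide fingers rising from the left
  wall, tips tracking the diagonal at a constant 50 µm gap, pitch
  ≈ 100 µm. The pitch matters: a coarse comb makes the |E|² crest a
  string of isolated maxima at the finger tips, which pin positive-DEP
  cells in place (axial DEP wells deeper than the Stokes drag); a pitch
  comparable to the gap smooths the crest so captured cells slide along
  it. Fingers shorter than 20 µm are omitted, which ends the comb before
  the diagonal reaches the wall region.
- Cells enter at x = 0 uniformly within y ∈ [0.70, 0.95]·w (the
  sheath-flow junction of a real device is abstracted into this entry
  band), and the outlet fork is abstracted into a lateral split at
  y = 0.4·w: left outlet below, right outlet above.

Fields: the RMS potential solves ∇²V = 0 with V = V_rms (default 10 V) on
phase electrodes, V = 0 on neutral, zero-flux mirror conditions on the
outer boundary; 5-point finite differences on a uniform grid (default 64
nodes across the width, matching axial spacing), direct sparse solve,
discrete-residual check. |E|² and ∇|E|² by central differences (one-sided
at boundaries). Flow is the fully developed parabolic profile
u(y) = 1.5 ū (1 − (2(y − w/2)/w)²), lateral component zero — a defensible
reduction for a straight channel (a Stokes-solver hook can replace it).

Transport is inertialess: particle velocity = fluid velocity + μ ∇|E|²,
with DEP mobility μ = r² ε₀ ε_med Re[K]/(3η) from the Stokes balance
(η = 1.0e−3 Pa·s). Explicit integration with a global adaptive step
capped at half a grid cell per step; bilinear field interpolation;
lateral wall contacts clamp and are logged; cells exceeding the time cap
(5 channel transits) are reported as outcome "none", never silently
dropped.

Operating point: the field frequency is the first crossover of the
population with the **higher** first CO (the differentiated-like one);
the contract verifies that the other population's Re[K] is positive
there, and the error message suggests swapping roles if not. Choosing
the lower-CO population instead would put the other population in
negative DEP, which the diagonal-plow geometry also moves left — the
chosen convention keeps "no force → right outlet, positive DEP → left
outlet" unambiguous.

The default mean flow speed (15 mm/s) sits in the middle of the window
set by the capture physics: a cell is escorted by the oblique crest only
while its transverse DEP drift exceeds the crest's lateral sweep speed
(slope × local axial flow). The speed must be high enough that
near-crossover cells (|Re K| ≲ 0.06 across the fixture populations'
parameter spread) fall below that threshold and pass straight through,
and low enough that the positive-DEP population (Re K ≈ 0.24) stays
above it; 14–18 mm/s satisfies both with margin for the default device
and voltage.

Fidelity losses of the 2D abstraction, in decreasing order of importance:
no channel-height dimension (every cell is assumed to travel within reach
of the floor electrodes, which overestimates yield rather than purity),
no meshed inlet junction or outlet fork, no AC electro-osmotic or
electrothermal flow, no particle–particle interactions, no electrode
polarization.

## Problem sizes

Defaults throughout are desk-scale: 24 spectra/group for the pipeline,
200 cells/population for the sorter run (400 traced particles on a
631 × 64 field grid), 50 zero-noise + 100 noisy fits in the recovery
experiments, 10⁴-draw sweeps for the Clausius–Mossotti bound and
10⁵-point scans for root-finder verification. A full pipeline run
completes in well under a minute on one core.

## Known limitations

- Membrane conductivity is weakly identified from a noisy 20-point
  spectrum (its influence concentrates below the first crossover); its
  noisy-recovery error is accordingly larger than the membrane
  permittivity's. This mirrors the practical situation in DEP
  spectroscopy.
- The second crossover of the fixture populations lies above the
  instrument range in the 0.04 S/m buffer, so `co_second` is reported as
  absent there; fits against wider synthetic grids recover it.
- The uniform ±1 SD population model cannot represent heavy-tailed or
  correlated parameter variation (e.g. radius–membrane-area coupling).
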