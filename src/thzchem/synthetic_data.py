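"""Synthetic THz absorbance spectra of ternary analyte mixtures.

The generator stands in for an instrument dataset: 80 mixture compositions of
caffeine / quinic acid / nicotinic acid (60 laid out systematically on the
edges and medians of the ternary diagram, 20 drawn at random from the simplex
interior), six replicate spectra each, 480 spectra total on the 540-point
acquisition grid.

The spectral model per replicate r of composition y is

    a_r(w) = t_r * [ sum_c y_c s_c(w)
                     + beta * sum_{c<c'} y_c y_c' g_{cc'}(w) ]
             + xi_r * Q_ext(w) + water(w) + eps_r(w)

with s_c Lorentzian-sum pure-component spectra, g a smooth pairwise cross-term
(the controllable departure from Beer-Lambert linearity, strength beta),
xi_r * Q_ext an additive Mie-scattering baseline with per-replicate coefficient,
sharp positive water-vapor line artifacts, i.i.d. Gaussian noise eps_r, and a
per-replicate thickness jitter t_r multiplying the chemical signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mie_baseline import (
    DEFAULT_WATER_LINES_THZ,
    MieParams,
    mie_extinction_efficiency,
)
from .spectra_io import (
    Composition,
    FrequencyGrid,
    SampleRecord,
    SpectraDataset,
    Spectrum,
    default_grid,
)

__all__ = [
    "ComponentLibrary",
    "SimulationConfig",
    "DEFAULT_LIBRARY",
    "design_compositions",
    "simulate_dataset",
]

COMPONENTS = ("caffeine", "quinic_acid", "nicotinic_acid")


@dataclass(frozen=True)
class ComponentLibrary:
    """Lorentzian peak lists plus a broadband slope per component.

    ``peaks[name]`` is a tuple of (center THz, half-width THz, amplitude a.u.)
    triples; ``slopes[name]`` a broadband linear-in-frequency coefficient.
    The default peak positions sit in the literature-reported ranges for the
    three compounds (distinct features mostly between 0.5 and 3.0 THz, the
    most discriminating ones in 2.0-3.0 THz); they are documented constants of
    this generator, not claims about the real crystals.
    """

    peaks: dict = field(default_factory=lambda: dict(_DEFAULT_PEAKS))
    slopes: dict = field(default_factory=lambda: dict(_DEFAULT_SLOPES))

    def __post_init__(self):
        if set(self.peaks) != set(COMPONENTS) or set(self.slopes) != set(COMPONENTS):
            raise ValueError(f"library must define exactly components {COMPONENTS}")
        seen = []
        for name in COMPONENTS:
            plist = tuple(tuple(p) for p in self.peaks[name])
            if not plist:
                raise ValueError(f"{name}: empty peak list")
            for c, w, amp in plist:
                if not (0.3 < c <= 3.0):
                    raise ValueError(f"{name}: peak center {c} outside (0.3, 3.0]")
                if w <= 0 or amp < 0:
                    raise ValueError(f"{name}: invalid width/amplitude ({w}, {amp})")
            if plist in seen:
                raise ValueError("two components share an identical peak list")
            seen.append(plist)

    def pure_spectrum(self, name: str, grid: FrequencyGrid) -> np.ndarray:
        """Noiseless pure-component absorbance on the grid."""
        f = grid.frequencies
        out = self.slopes[name] * f
        for center, hwhm, amp in self.peaks[name]:
            out = out + amp * hwhm**2 / ((f - center) ** 2 + hwhm**2)
        return out


# documented generator constants: 4-5 Lorentzians per compound, the sharpest
# and most distinguishing ones placed in the 2.0-3.0 THz window
_DEFAULT_PEAKS = {
    "caffeine": (
        (0.77, 0.06, 0.25),
        (1.25, 0.08, 0.30),
        (1.60, 0.09, 0.25),
        (2.12, 0.07, 0.55),
        (2.68, 0.08, 0.45),
    ),
    "quinic_acid": (
        (1.02, 0.07, 0.30),
        (1.45, 0.08, 0.35),
        (1.85, 0.08, 0.30),
        (2.40, 0.07, 0.60),
        (2.92, 0.08, 0.40),
    ),
    "nicotinic_acid": (
        (0.88, 0.07, 0.20),
        (1.38, 0.09, 0.25),
        (1.95, 0.07, 0.40),
        (2.25, 0.06, 0.45),
        (2.80, 0.07, 0.55),
    ),
}
_DEFAULT_SLOPES = {"caffeine": 0.08, "quinic_acid": 0.10, "nicotinic_acid": 0.06}

DEFAULT_LIBRARY = ComponentLibrary()


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the stated measurement world.

    Defaults reproduce the experimental design: 10 points per edge/median of
    the ternary diagram (60 systematic compositions), 20 random interior
    compositions, 6 replicates, for 480 spectra.  ``noise_sd`` is the
    replicate-level Gaussian noise (a.u.); ``baseline_xi_range`` the uniform
    draw interval of the per-replicate Mie baseline coefficient;
    ``thickness_jitter`` the relative s.d. of the multiplicative pellet
    thickness factor (pellets vary ~0.85-0.95 mm, about 5% relative);
    ``nonlinearity_strength`` scales the pairwise Beer-Lambert departure
    (0 = exactly linear mixing).
    """

    n_edge_points: int = 10
    n_random: int = 20
    replicates: int = 6
    noise_sd: float = 0.01
    baseline_xi_range: tuple = (0.05, 0.15)
    thickness_jitter: float = 0.05
    nonlinearity_strength: float = 0.0
    water_lines: tuple = DEFAULT_WATER_LINES_THZ
    water_amplitude: float = 0.02
    water_halfwidth: float = 0.006
    seed: int = 0

    def __post_init__(self):
        if self.n_edge_points < 1 or self.replicates < 1:
            raise ValueError("counts must be >= 1")
        if self.n_random < 0:
            raise ValueError("n_random must be >= 0")
        if self.noise_sd < 0 or self.nonlinearity_strength < 0:
            raise ValueError("noise_sd and nonlinearity_strength must be >= 0")
        lo, hi = self.baseline_xi_range
        if lo < 0 or hi < lo:
            raise ValueError("baseline_xi_range must satisfy 0 <= min <= max")


_VERTICES = np.eye(3)


def design_compositions(config: SimulationConfig) -> list[tuple[Composition, str]]:
    """Mixture design: systematic edge + median points plus random interior points.

    Systematic set (with the default ``n_edge_points = 10``):

    * each of the 3 edges carries ``n`` points at parameter t = k/n,
      k = 0..n-1 — half-open, so cycling the edges visits each vertex exactly
      once (30 unitary/binary compositions);
    * each of the 3 medians (vertex to opposite-edge midpoint) carries ``n``
      strictly interior points at t = k/(n+1), k = 1..n (30 ternary
      compositions; the centroid at t = 2/3 is skipped by construction).

    The random set is ``n_random`` points drawn uniformly on the open simplex
    interior with the config seed.  Returns (composition, tag) pairs, tag in
    {"systematic", "random"}; raises if any two points collide.
    """
    if config.n_edge_points < 2:
        raise ValueError("n_edge_points must be >= 2")
    n = config.n_edge_points
    points: list[np.ndarray] = []
    # edges, half-open: A->B, B->C, C->A
    for i in range(3):
        a, b = _VERTICES[i], _VERTICES[(i + 1) % 3]
        for k in range(n):
            t = k / n
            points.append((1 - t) * a + t * b)
    # medians: vertex -> midpoint of opposite edge, endpoints excluded
    for i in range(3):
        a = _VERTICES[i]
        mid = (_VERTICES[(i + 1) % 3] + _VERTICES[(i + 2) % 3]) / 2
        for k in range(1, n + 1):
            t = k / (n + 1)
            points.append((1 - t) * a + t * mid)
    tags = ["systematic"] * len(points)

    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_random):
        while True:
            y = rng.dirichlet(np.ones(3))
            if np.all(y > 1e-6):
                break
        points.append(y)
        tags.append("random")

    arr = np.vstack(points)
    collisions = []
    for i in range(len(arr)):
        for j in range(i + 1, len(arr)):
            if np.allclose(arr[i], arr[j], atol=1e-12):
                collisions.append((i, j))
    if collisions:
        raise ValueError(f"duplicate design points at index pairs {collisions}")

    return [
        (Composition(*np.round(p, 15)), tag) for p, tag in zip(arr, tags)
    ]


def _cross_term_spectra(library: ComponentLibrary, grid: FrequencyGrid) -> dict:
    """Smooth pairwise cross-term spectra g_{cc'}, derived from the library.

    Each g is the mean of the two pure-component spectra, so the cross term
    redistributes intensity among the *existing* absorption bands (the way
    intermolecular interaction perturbs oscillator strengths) instead of
    creating new, linearly independent bands.  This matters: a cross term
    outside the span of the pure spectra would leave the composition linearly
    recoverable from the mixture spectrum, and no linearity probe could detect
    the departure from Beer-Lambert mixing.  With g in the span, the
    spectrum -> composition inverse is genuinely nonlinear.
    """
    pures = {c: library.pure_spectrum(c, grid) for c in COMPONENTS}
    out = {}
    for i, ci in enumerate(COMPONENTS):
        for cj in COMPONENTS[i + 1:]:
            out[(ci, cj)] = 0.5 * (pures[ci] + pures[cj])
    return out


def _water_artifacts(config: SimulationConfig, grid: FrequencyGrid) -> np.ndarray:
    f = grid.frequencies
    out = np.zeros_like(f)
    for line in config.water_lines:
        out += config.water_amplitude * config.water_halfwidth**2 / (
            (f - line) ** 2 + config.water_halfwidth**2
        )
    return out


def simulate_dataset(
    library: ComponentLibrary = DEFAULT_LIBRARY,
    compositions: list | None = None,
    config: SimulationConfig = SimulationConfig(),
    grid: FrequencyGrid | None = None,
    mie_params: MieParams = MieParams(),
    return_manifest: bool = False,
):
    """Simulate replicate absorbance spectra for a list of compositions.

    ``compositions`` may be (Composition, tag) pairs from
    :func:`design_compositions` or bare Compositions; None regenerates the
    default design.  Same config seed, bit-identical dataset.  Negative
    absorbance after assembly is clipped at zero with a warning reporting the
    affected point count.

    With ``return_manifest=True`` returns ``(dataset, manifest)`` where the
    manifest records, per record in order, the drawn baseline coefficient
    ``xi`` and thickness factor — the generator's ground truth.
    """
    if grid is None:
        grid = default_grid()
    if compositions is None:
        compositions = design_compositions(config)
    comps = [c[0] if isinstance(c, tuple) else c for c in compositions]

    rng = np.random.default_rng(config.seed + 1)
    pures = np.vstack([library.pure_spectrum(c, grid) for c in COMPONENTS])
    cross = _cross_term_spectra(library, grid)
    water = _water_artifacts(config, grid)
    lo, hi = config.baseline_xi_range
    stochastic_baseline = hi > 0
    qext = mie_extinction_efficiency(mie_params, grid) if stochastic_baseline else None

    records: list[SampleRecord] = []
    xi_drawn: list[float] = []
    thickness_drawn: list[float] = []
    n_clipped = 0
    for idx, comp in enumerate(comps):
        y = comp.as_array()
        chem = y @ pures
        if config.nonlinearity_strength > 0:
            for i, ci in enumerate(COMPONENTS):
                for j in range(i + 1, 3):
                    cj = COMPONENTS[j]
                    chem = chem + (
                        config.nonlinearity_strength * y[i] * y[j] * cross[(ci, cj)]
                    )
        for rep in range(1, config.replicates + 1):
            thickness = (
                1.0 + config.thickness_jitter * rng.standard_normal()
                if config.thickness_jitter > 0 else 1.0
            )
            a = thickness * chem + water
            xi_r = rng.uniform(lo, hi) if stochastic_baseline else 0.0
            if stochastic_baseline:
                a = a + xi_r * qext
            xi_drawn.append(xi_r)
            thickness_drawn.append(thickness)
            if config.noise_sd > 0:
                a = a + config.noise_sd * rng.standard_normal(len(grid))
            neg = a < 0
            if neg.any():
                n_clipped += int(neg.sum())
                a = np.clip(a, 0.0, None)
            records.append(
                SampleRecord(
                    sample_id=f"S{idx:03d}",
                    composition=comp,
                    replicate_index=rep,
                    spectrum=Spectrum(grid=grid, absorbance=a),
                )
            )
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} negative absorbance values to 0")
    dataset = SpectraDataset(records=records, grid=grid)
    if return_manifest:
        manifest = {
            "seed": config.seed,
            "xi": np.array(xi_drawn),
            "thickness": np.array(thickness_drawn),
            "n_clipped": n_clipped,
        }
        return dataset, manifest
    return dataset
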