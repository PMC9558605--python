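"""Mie-scattering baseline removal for powder-pellet THz absorbance spectra.

Pellets pressed from analyte + HDPE binder scatter the THz beam off binder
grains.  For grain sizes comparable to the wavelength this scattering follows
the Mie solution for a homogeneous sphere, and the apparent absorbance gains a
smooth, rising baseline proportional to the extinction efficiency Q_ext(f).
This module computes Q_ext on a frequency grid and removes the baseline
xi * Q_ext(f), with the scalar xi chosen so that the baseline touches the
spectrum's troughs without ever exceeding them on a valid frequency set
(water-vapor lines and the noisy low-frequency band are excluded).

The fit is a one-variable linear program:

    minimize over xi >= 0:
        sum_{w in Omega} [a(w) - xi Q(w)]  +  M sum_{w in Omega} max(0, xi Q(w) - a(w))

For M large the solution is the closed form xi* = max(0, min_{Omega} a/Q).
Both routes are implemented and must agree; the LP (HiGHS) is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .spectra_io import FrequencyGrid, SpectraDataset, Spectrum

__all__ = [
    "MieParams",
    "ValidMask",
    "BaselineFit",
    "SPEED_OF_LIGHT_UM_THZ",
    "DEFAULT_WATER_LINES_THZ",
    "mie_extinction_efficiency",
    "valid_frequency_mask",
    "fit_baseline_coefficient",
    "remove_baseline",
]

#: c in micrometre * THz units (so x = 2 pi r f n_med / c with r in um, f in THz)
SPEED_OF_LIGHT_UM_THZ = 299.792458

#: strong atmospheric water-vapor lines inside the acquisition band, THz.
#: Residual absorption at these frequencies survives nitrogen purging as sharp
#: positive artifacts, so they are excluded from baseline fitting by default.
DEFAULT_WATER_LINES_THZ = (0.557, 0.752, 0.988, 1.097, 1.163, 1.207, 1.411,
                           1.603, 1.669, 1.717, 1.762, 1.919, 2.040, 2.164,
                           2.264, 2.344, 2.464, 2.640, 2.773, 2.884)

#: default LP penalty weight keeping the baseline below the troughs
DEFAULT_PENALTY_M = 1e9


@dataclass(frozen=True)
class MieParams:
    """Optical inputs of the scattering sphere model.

    ``particle_radius`` in micrometres; ``refractive_index`` is the (possibly
    complex) index of the binder grains; ``medium_index`` that of the
    surrounding medium.  Defaults describe HDPE powder at a typical grain
    scale; neither is a measured property of any particular batch, so both are
    meant to be overridden from config.
    """

    particle_radius: float = 30.0
    refractive_index: complex = 1.54 + 0.0j
    medium_index: float = 1.0

    def __post_init__(self):
        if self.particle_radius <= 0:
            raise ValueError("particle_radius must be positive")
        if complex(self.refractive_index).real <= 0:
            raise ValueError("refractive index real part must be positive")
        if self.medium_index <= 0:
            raise ValueError("medium_index must be positive")


def _mie_qext_single(m: complex, x: float) -> float:
    """Q_ext of a homogeneous sphere, Bohren–Huffman log-derivative recursion."""
    if x == 0:
        return 0.0
    nmax = int(np.ceil(x + 4 * x ** (1 / 3) + 2))
    mx = m * x
    # downward recurrence for the logarithmic derivative D_n(mx)
    nstart = nmax + 15
    d = np.zeros(nstart + 1, dtype=complex)
    for n in range(nstart, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    qext = 0.0
    # Riccati-Bessel psi_n(x), chi_n(x) by upward recurrence
    psi0, psi1 = np.cos(x), np.sin(x)
    chi0, chi1 = -np.sin(x), np.cos(x)
    xi1 = complex(psi1, -chi1)
    for n in range(1, nmax + 1):
        psi = (2 * n - 1) / x * psi1 - psi0
        chi = (2 * n - 1) / x * chi1 - chi0
        xi = complex(psi, -chi)
        dn = d[n]
        a_n = ((dn / m + n / x) * psi - psi1) / ((dn / m + n / x) * xi - xi1)
        b_n = ((dn * m + n / x) * psi - psi1) / ((dn * m + n / x) * xi - xi1)
        if not (np.isfinite(a_n) and np.isfinite(b_n)):
            raise FloatingPointError("Mie recurrence did not converge")
        qext += (2 * n + 1) * (a_n + b_n).real
        psi0, psi1 = psi1, psi
        chi0, chi1 = chi1, chi
        xi1 = xi
    return 2.0 / x ** 2 * qext


def size_parameter(params: MieParams, freqs_thz: np.ndarray) -> np.ndarray:
    """x = 2 pi r f n_medium / c for frequencies in THz, radius in um."""
    return (
        2.0 * np.pi * params.particle_radius * np.asarray(freqs_thz)
        * params.medium_index / SPEED_OF_LIGHT_UM_THZ
    )


def mie_extinction_efficiency(params: MieParams, grid: FrequencyGrid) -> np.ndarray:
    """Extinction efficiency Q_ext at every grid frequency.

    The relative refractive index is ``refractive_index / medium_index``; the
    series is truncated at N = ceil(x + 4 x^(1/3) + 2).

    Raises
    ------
    ValueError
        If any grid frequency is non-positive.
    FloatingPointError
        If the recurrence overflows (error names the frequency).
    """
    freqs = grid.frequencies
    if np.any(freqs <= 0):
        raise ValueError("grid frequencies must be positive for Mie evaluation")
    m_rel = complex(params.refractive_index) / params.medium_index
    xs = size_parameter(params, freqs)
    out = np.empty_like(xs)
    for i, (f, x) in enumerate(zip(freqs, xs)):
        try:
            out[i] = _mie_qext_single(m_rel, float(x))
        except FloatingPointError as exc:
            raise FloatingPointError(f"Mie series failed at {f:.3f} THz") from exc
    if np.any(~np.isfinite(out)) or np.any(out < -1e-12):
        bad = freqs[np.flatnonzero(~np.isfinite(out) | (out < -1e-12))[0]]
        raise FloatingPointError(f"non-physical Q_ext at {bad:.3f} THz")
    return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class ValidMask:
    """Boolean mask of grid points retained for baseline fitting (the set Omega)."""

    mask: np.ndarray
    water_lines: tuple = DEFAULT_WATER_LINES_THZ
    exclusion_halfwidth: float = 0.025
    low_cut: tuple = (0.3, 0.55)

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if not m.any():
            raise ValueError("valid frequency set is empty")


def valid_frequency_mask(
    grid: FrequencyGrid,
    water_lines=DEFAULT_WATER_LINES_THZ,
    halfwidth: float = 0.025,
    low_cut: tuple = (0.3, 0.55),
) -> ValidMask:
    """Grid points valid for baseline fitting.

    A point is valid iff its frequency exceeds ``low_cut[1]`` (the 0.3-0.55 THz
    band carries negative absorbance residues from noise) and lies outside
    every closed interval [line - halfwidth, line + halfwidth] around a
    water-vapor line.  Band edges landing exactly on grid points are excluded.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be nonnegative")
    freqs = grid.frequencies
    mask = freqs > low_cut[1]
    for line in water_lines:
        mask &= ~((freqs >= line - halfwidth) & (freqs <= line + halfwidth))
    return ValidMask(
        mask=mask,
        water_lines=tuple(water_lines),
        exclusion_halfwidth=halfwidth,
        low_cut=tuple(low_cut),
    )


@dataclass(frozen=True)
class BaselineFit:
    """Result of one baseline fit: the coefficient and its provenance."""

    xi: float
    mode: str
    penalty_M: float
    qext: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _xi_closed_form(a: np.ndarray, q: np.ndarray) -> float:
    pos = q > 0
    if not pos.any():
        raise ValueError("Q_ext is zero everywhere on the valid set")
    return float(max(0.0, np.min(a[pos] / q[pos])))


def _xi_penalty(a: np.ndarray, q: np.ndarray, penalty_M: float) -> float:
    # variables (xi, t_1..t_k): minimize -xi*sum(q) + M*sum(t)
    # s.t. t_i >= xi*q_i - a_i, t_i >= 0, xi >= 0  (sum(a) constant, dropped)
    pos = q > 0
    if not pos.any():
        raise ValueError("Q_ext is zero everywhere on the valid set")
    a, q = a[pos], q[pos]
    k = q.size
    c = np.concatenate([[-q.sum()], np.full(k, penalty_M)])
    # xi*q_i - t_i <= a_i
    A_ub = np.hstack([q[:, None], -np.eye(k)])
    res = linprog(c, A_ub=A_ub, b_ub=a, bounds=[(0, None)] * (k + 1), method="highs")
    if not res.success:
        raise RuntimeError(f"baseline LP failed: {res.message}")
    return float(res.x[0])


def fit_baseline_coefficient(
    spectrum: Spectrum,
    qext: np.ndarray,
    mask: ValidMask,
    penalty_M: float = DEFAULT_PENALTY_M,
    method: str = "penalty",
) -> float:
    """Fit the scalar xi so xi*Q_ext sits at the spectrum's troughs on Omega.

    ``method='penalty'`` solves the LP with penalty weight ``penalty_M``;
    ``method='closed_form'`` uses the exact large-M limit
    xi* = max(0, min_{Omega, Q>0} a/Q).  A spectrum dipping below zero on
    Omega yields xi = 0 with a warning (a negative scattering baseline is
    unphysical).
    """
    a = spectrum.absorbance[mask.mask]
    q = np.asarray(qext, dtype=float)[mask.mask]
    if not np.all(np.isfinite(a)):
        raise ValueError("spectrum has non-finite values on the valid set")
    xi_cf = _xi_closed_form(a, q)
    if xi_cf == 0.0 and np.min(a[q > 0]) < 0:
        warnings.warn("spectrum dips below zero on the valid set; xi clipped to 0")
        return 0.0
    if method == "closed_form":
        return xi_cf
    if method == "penalty":
        return _xi_penalty(a, q, penalty_M)
    raise ValueError(f"unknown method {method!r}")


def remove_baseline(
    dataset_train: SpectraDataset,
    dataset_apply: SpectraDataset | None,
    params: MieParams,
    mask: ValidMask,
    mode: str = "multifactor",
    penalty_M: float = DEFAULT_PENALTY_M,
    method: str = "penalty",
    qext: np.ndarray | None = None,
):
    """Remove xi*Q_ext from every spectrum of the train and apply sets.

    Modes
    -----
    ``multifactor``
        Each spectrum gets its own xi; the baseline is subtracted on all grid
        points (not just Omega).
    ``single_factor``
        One shared xi — the minimum of the per-spectrum fits over the
        *training* set — is applied to every spectrum, including the apply set.
    ``multifactor_concat``
        As multifactor; the per-spectrum xi values are additionally meant for
        later concatenation as an extra feature after dimensionality reduction.

    Returns ``(corrected_train, corrected_apply, fit)`` where ``fit`` maps
    ``'train'``/``'apply'`` to the xi array actually subtracted, in record
    order; ``corrected_apply`` is None when ``dataset_apply`` is None.
    """
    if mode not in ("multifactor", "single_factor", "multifactor_concat"):
        raise ValueError(f"unknown baseline mode {mode!r}")
    if dataset_apply is not None and dataset_apply.grid != dataset_train.grid:
        raise ValueError("apply-set grid differs from training grid")
    if qext is None:
        qext = mie_extinction_efficiency(params, dataset_train.grid)

    def fit_all(ds: SpectraDataset) -> np.ndarray:
        return np.array([
            fit_baseline_coefficient(r.spectrum, qext, mask, penalty_M, method)
            for r in ds.records
        ])

    xi_train = fit_all(dataset_train)
    xi_apply = fit_all(dataset_apply) if dataset_apply is not None else None

    if mode == "single_factor":
        xi_shared = float(xi_train.min())
        xi_train = np.full(len(dataset_train), xi_shared)
        if xi_apply is not None:
            xi_apply = np.full(len(dataset_apply), xi_shared)

    corrected_train = dataset_train.with_absorbance(
        dataset_train.absorbance_matrix() - xi_train[:, None] * qext[None, :]
    )
    corrected_apply = None
    if dataset_apply is not None:
        corrected_apply = dataset_apply.with_absorbance(
            dataset_apply.absorbance_matrix() - xi_apply[:, None] * qext[None, :]
        )
    fit = {"train": xi_train, "apply": xi_apply, "qext": qext, "mode": mode}
    return corrected_train, corrected_apply, fit
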