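"""Single-shell EXAFS forward model, Fourier filtering and cumulant fitting.

The oscillatory fine structure above an absorption edge is modelled for one
coordination shell with the standard cumulant expansion:

    χ(k) = S0² · CN · F(k') / (k' R²) · exp(−2 k'² σ²) · exp(−2R/λ(k'))
           · sin(2 k' R + φ(k') − (4/3) C3 k'³)

with k' = sqrt(k² − 0.2625 · ΔE0) (0.2625 Å⁻²/eV = 2 m_e/ħ²), F and φ
interpolated from a backscattering table, σ² the Debye–Waller-type second
cumulant (Å²) and C3 the third cumulant (Å³) carrying the shell's asymmetry.
The mean-free-path factor is applied only when the table provides λ(k).

S0² and CN are exactly degenerate (χ is linear in their product), so fits fix
S0² (default 1.0) and let CN absorb the amplitude.

Fitting minimises the k³-weighted residual with a local least-squares solver
started from the best point of a coarse (R, ΔE0) grid — the 2kR phase makes
the problem multimodal in those two parameters.  The goodness of fit is the
residual factor Rf = Σ(k³χ_data − k³χ_fit)² / Σ(k³χ_data)² × 100 (%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.fft import dst, idst
from scipy.optimize import least_squares

__all__ = [
    "ScatteringTable",
    "EXAFSSpectrum",
    "ChiParameters",
    "EXAFSFitResult",
    "FitError",
    "read_scattering_table",
    "write_scattering_table",
    "read_spectrum",
    "write_spectrum",
    "chi_model",
    "fourier_filter",
    "fit_single_shell",
    "rf_residual",
]

K_PER_EV = 0.2625  # Å⁻² per eV: 2 m_e / ħ²


@dataclass(frozen=True)
class ScatteringTable:
    """Backscattering amplitude/phase (and optional mean free path) vs k."""

    k: np.ndarray  # Å⁻¹, strictly increasing, ≥ 0
    amplitude: np.ndarray  # Å
    phase: np.ndarray  # rad (total phase shift)
    mean_free_path: np.ndarray | None = None  # Å

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=float)
        amp = np.asarray(self.amplitude, dtype=float)
        ph = np.asarray(self.phase, dtype=float)
        if k.ndim != 1 or np.any(np.diff(k) <= 0) or k[0] < 0:
            raise ValueError("k grid must be 1-D, non-negative and strictly increasing")
        if amp.shape != k.shape or ph.shape != k.shape:
            raise ValueError("amplitude and phase must match the k grid")
        if np.any(amp < 0):
            raise ValueError("scattering amplitude must be non-negative")
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "amplitude", amp)
        object.__setattr__(self, "phase", ph)
        if self.mean_free_path is not None:
            lam = np.asarray(self.mean_free_path, dtype=float)
            if lam.shape != k.shape:
                raise ValueError("mean_free_path must match the k grid")
            object.__setattr__(self, "mean_free_path", lam)

    def amplitude_at(self, k: np.ndarray) -> np.ndarray:
        return np.interp(k, self.k, self.amplitude)

    def phase_at(self, k: np.ndarray) -> np.ndarray:
        return np.interp(k, self.k, self.phase)

    def mean_free_path_at(self, k: np.ndarray) -> np.ndarray | None:
        if self.mean_free_path is None:
            return None
        return np.interp(k, self.k, self.mean_free_path)


def read_scattering_table(path: str | Path) -> ScatteringTable:
    """Read a whitespace-separated k / F / φ [/ λ] table; '#' comments."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 3:
        raise ValueError(f"{Path(path).name}: need at least 3 columns (k, F, phase)")
    lam = data[:, 3] if data.shape[1] >= 4 else None
    return ScatteringTable(data[:, 0], data[:, 1], data[:, 2], lam)


def write_scattering_table(table: ScatteringTable, path: str | Path) -> None:
    cols = [table.k, table.amplitude, table.phase]
    header = "k_invA amplitude_A phase_rad"
    if table.mean_free_path is not None:
        cols.append(table.mean_free_path)
        header += " lambda_A"
    np.savetxt(path, np.column_stack(cols), header=header, fmt="%.10g")


@dataclass(frozen=True)
class EXAFSSpectrum:
    """χ(k) on an increasing k grid; ``k_weight`` records the display weight."""

    k: np.ndarray  # Å⁻¹
    chi: np.ndarray
    k_weight: int = 3

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=float)
        chi = np.asarray(self.chi, dtype=float)
        if np.any(np.diff(k) <= 0):
            raise ValueError("k grid must be strictly increasing")
        if not (np.all(np.isfinite(k)) and np.all(np.isfinite(chi))):
            raise ValueError("spectrum values must be finite")
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "chi", chi)

    def windowed(self, k_min: float, k_max: float) -> "EXAFSSpectrum":
        m = (self.k >= k_min - 1e-12) & (self.k <= k_max + 1e-12)
        return EXAFSSpectrum(self.k[m], self.chi[m], self.k_weight)


def read_spectrum(path: str | Path, k_weight: int = 3) -> EXAFSSpectrum:
    data = np.loadtxt(path, comments="#", ndmin=2)
    return EXAFSSpectrum(data[:, 0], data[:, 1], k_weight)


def write_spectrum(spectrum: EXAFSSpectrum, path: str | Path) -> None:
    np.savetxt(
        path,
        np.column_stack([spectrum.k, spectrum.chi]),
        header="k_invA chi",
        fmt="%.10g",
    )


@dataclass(frozen=True)
class ChiParameters:
    """Cumulant-expansion parameters of one shell."""

    cn: float
    r: float  # Å
    sigma2: float  # Å²
    c3: float = 0.0  # Å³
    delta_e0: float = 0.0  # eV
    s02: float = 1.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("shell distance R must be positive")


def chi_model(
    params: ChiParameters, table: ScatteringTable, k_grid: np.ndarray
) -> EXAFSSpectrum:
    """Single-shell cumulant-expansion χ(k) on ``k_grid``.

    The threshold shift enters through k' = sqrt(k² − 0.2625·ΔE0); grid
    points where k'² ≤ 0 are dropped from the returned spectrum.
    """
    k = np.asarray(k_grid, dtype=float)
    k2p = k**2 - K_PER_EV * params.delta_e0
    keep = k2p > 0
    k = k[keep]
    kp = np.sqrt(k2p[keep])
    amp = table.amplitude_at(kp)
    phase = table.phase_at(kp)
    chi = (
        params.s02
        * params.cn
        * amp
        / (kp * params.r**2)
        * np.exp(-2.0 * kp**2 * params.sigma2)
        * np.sin(2.0 * kp * params.r + phase - 4.0 / 3.0 * params.c3 * kp**3)
    )
    lam = table.mean_free_path_at(kp)
    if lam is not None:
        chi = chi * np.exp(-2.0 * params.r / lam)
    return EXAFSSpectrum(k, chi)


# ---------------------------------------------------------------------------
# Fourier filtering
# ---------------------------------------------------------------------------

def _taper_window(k: np.ndarray, k_min: float, k_max: float, window_fn: str, taper_frac: float) -> np.ndarray:
    """Tukey-style taper over [k_min, k_max], zero outside."""
    w = np.zeros_like(k)
    inside = (k >= k_min) & (k <= k_max)
    if window_fn == "rect":
        w[inside] = 1.0
        return w
    if window_fn != "hanning":
        raise ValueError(f"unknown window_fn {window_fn!r}")
    width = k_max - k_min
    ramp = taper_frac * width
    x = k[inside]
    wi = np.ones(x.size)
    lo = x < k_min + ramp
    hi = x > k_max - ramp
    if ramp > 0:
        wi[lo] = 0.5 * (1 - np.cos(np.pi * (x[lo] - k_min) / ramp))
        wi[hi] = 0.5 * (1 - np.cos(np.pi * (k_max - x[hi]) / ramp))
    w[inside] = wi
    return w


def fourier_filter(
    spectrum: EXAFSSpectrum,
    k_window: tuple[float, float],
    r_window: tuple[float, float],
    window_fn: str = "hanning",
    taper_frac: float = 0.1,
    n_fft: int = 4096,
) -> EXAFSSpectrum:
    """Fourier-filter k³χ through an R-space window and back-transform.

    The spectrum (uniform k grid required) is tapered over ``k_window``,
    embedded in a zero-padded grid starting at k = 0, transformed with kernel
    exp(2ikr), components with conjugate distance outside ``r_window`` are
    zeroed, and the result is transformed back.  The taper is divided back
    out (window compensation) and the curve is returned over the original
    ``k_window``; bins where the taper is ~0 (the very window edges) are
    returned as zero.

    With ``window_fn="rect"`` and a k_window spanning the whole input grid
    the operation is a pure FFT-bin projection (applying it twice is exactly
    applying it once).
    """
    k = spectrum.k
    dk = np.diff(k)
    if dk.size == 0:
        raise ValueError("spectrum too short to filter")
    if np.max(np.abs(dk - dk[0])) > 1e-9:
        raise ValueError("fourier_filter requires a uniform k grid; resample first")
    dk = float(dk[0])
    k_min, k_max = k_window
    r_min, r_max = r_window
    if not 0 <= r_min < r_max:
        raise ValueError("invalid r_window")
    w = _taper_window(k, k_min, k_max, window_fn, taper_frac)
    weighted = w * k**3 * spectrum.chi

    n0 = int(round(k[0] / dk))
    if abs(n0 * dk - k[0]) > 1e-9:
        raise ValueError("k grid must be commensurate with its own spacing from k=0")
    n_used = k.size if n0 >= 1 else k.size - 1
    if n_fft - 1 < max(n0 - 1, 0) + n_used:
        raise ValueError("n_fft too small for the padded grid")
    if r_max > np.pi / (2.0 * dk):
        raise ValueError(
            f"r_window upper edge {r_max:g} Å exceeds the transform range "
            f"{np.pi / (2.0 * dk):g} Å"
        )
    # k³χ is odd in k, so the transform pair sin(2 k_n r_j) (DST-I on the
    # grid k_n = n·dk, r_j = π·j / (2·n_fft·dk)) is the natural basis;
    # zeroing coefficients outside the r window is an exact orthogonal
    # projection in that basis.
    full = np.zeros(n_fft - 1)  # index n-1 holds k = n·dk, n = 1..n_fft-1
    lo = n0 - 1 if n0 >= 1 else 0
    full[lo : lo + k.size] = weighted if n0 >= 1 else weighted[1:]
    coeff = dst(full, type=1)
    r_grid = np.pi * np.arange(1, n_fft) / (2.0 * n_fft * dk)
    coeff[(r_grid < r_min) | (r_grid > r_max)] = 0.0
    back = idst(coeff, type=1)
    filtered_weighted = back[lo : lo + k.size] if n0 >= 1 else np.concatenate([[0.0], back[: k.size - 1]])

    chi_f = np.zeros(k.size)
    ok = (w > 1e-8) & (k > 1e-12)
    chi_f[ok] = filtered_weighted[ok] / (w[ok] * k[ok] ** 3)
    return EXAFSSpectrum(k, chi_f, spectrum.k_weight).windowed(k_min, k_max)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EXAFSFitResult:
    """Converged single-shell fit with covariance-based uncertainties."""

    params: ChiParameters
    uncertainties: dict[str, float]
    rf: float  # %
    k_range: tuple[float, float]
    k_weight: int
    n_points: int
    fit_c3: bool

    # convenience accessors mirroring the reported table fields
    @property
    def cn(self) -> float:
        return self.params.cn

    @property
    def r(self) -> float:
        return self.params.r

    @property
    def sigma2(self) -> float:
        return self.params.sigma2

    @property
    def c3(self) -> float:
        return self.params.c3

    @property
    def delta_e0(self) -> float:
        return self.params.delta_e0

    def to_json(self) -> str:
        return json.dumps(
            {
                "k_range_invA": list(self.k_range),
                "k_weight": self.k_weight,
                "cn": self.params.cn,
                "r_angstrom": self.params.r,
                "delta_e0_eV": self.params.delta_e0,
                "sigma2_angstrom2": self.params.sigma2,
                "c3_angstrom3": self.params.c3,
                "s02": self.params.s02,
                "rf_percent": self.rf,
                "uncertainties": self.uncertainties,
                "n_points": self.n_points,
                "fit_c3": self.fit_c3,
            },
            indent=2,
            sort_keys=True,
        )


class FitError(RuntimeError):
    """Optimizer failed to converge; carries the best parameters seen."""

    def __init__(self, message: str, best: ChiParameters | None = None) -> None:
        super().__init__(message)
        self.best = best


def rf_residual(
    chi_data: np.ndarray,
    chi_fit: np.ndarray,
    k: np.ndarray | None = None,
    k_weight: int = 3,
) -> float:
    """Residual factor Rf = Σ(w·(data − fit))² / Σ(w·data)² × 100 (%).

    Weights are k**k_weight; pass ``k=None`` for unit weights.
    """
    d = np.asarray(chi_data, dtype=float)
    f = np.asarray(chi_fit, dtype=float)
    w = np.ones_like(d) if k is None else np.asarray(k, dtype=float) ** k_weight
    denom = np.sum((w * d) ** 2)
    if denom == 0:
        raise ValueError("Rf undefined for identically zero data")
    return float(np.sum((w * (d - f)) ** 2) / denom * 100.0)


_BOUNDS = {
    "cn": (0.05, 50.0),
    "r": (1.0, 6.0),
    "sigma2": (0.0, 1.0),
    "c3": (-0.05, 0.05),
    "delta_e0": (-15.0, 15.0),
}
_SCALES = {"cn": 5.0, "r": 0.05, "sigma2": 0.005, "c3": 5e-4, "delta_e0": 2.0}


def fit_single_shell(
    spectrum: EXAFSSpectrum,
    table: ScatteringTable,
    k_range: tuple[float, float],
    fixed: dict[str, float] | None = None,
    init: ChiParameters | None = None,
    fit_c3: bool = True,
    k_weight: int = 3,
) -> EXAFSFitResult:
    """Fit (CN, R, σ², C3, ΔE0) to k³-weighted χ(k) over ``k_range``.

    ``fixed`` freezes parameters by name (S0² is always fixed; default 1.0).
    The local optimizer starts from the best point of a coarse grid over
    R = init.r ± 0.3 Å and ΔE0 ∈ [−10, 10] eV, with CN solved linearly at
    each grid point, which steps over the 2kR-phase local minima.  Parameter
    uncertainties are 1σ from the covariance at the optimum with the noise
    variance estimated from the residuals.
    """
    fixed = dict(fixed or {})
    s02 = float(fixed.pop("s02", 1.0))
    if init is None:
        init = ChiParameters(cn=8.0, r=2.8, sigma2=0.01, c3=0.0, delta_e0=0.0, s02=s02)
    else:
        init = replace(init, s02=s02)
    data = spectrum.windowed(*k_range)
    if data.k.size < 8:
        raise ValueError("fewer than 8 data points in k_range")
    kmin_allowed = np.sqrt(K_PER_EV * _BOUNDS["delta_e0"][1])
    if data.k[0] <= kmin_allowed:
        raise ValueError(
            f"k_range must start above {kmin_allowed:.2f} Å⁻¹ so the ΔE0 remap "
            "stays real over its search bounds"
        )
    w = data.k**k_weight
    target = w * data.chi

    names = ["cn", "r", "sigma2"] + (["c3"] if fit_c3 else []) + ["delta_e0"]
    free = [n for n in names if n not in fixed]
    base = {
        "cn": init.cn,
        "r": init.r,
        "sigma2": init.sigma2,
        "c3": init.c3,
        "delta_e0": init.delta_e0,
    }
    base.update(fixed)
    if not fit_c3 and "c3" not in fixed:
        fixed["c3"] = init.c3

    def build(theta: np.ndarray) -> ChiParameters:
        p = dict(base)
        for name, val in zip(free, theta):
            p[name] = float(val)
        return ChiParameters(s02=s02, **p)

    def residual(theta: np.ndarray) -> np.ndarray:
        model = chi_model(build(theta), table, data.k)
        if model.k.size != data.k.size:
            return np.full(data.k.size, 1e3)
        return w * model.chi - target

    # --- coarse (R, ΔE0) grid with linear CN solve ----------------------
    best = None
    r_grid = init.r + np.arange(-0.3, 0.301, 0.05)
    e_grid = np.arange(-10.0, 10.01, 2.5) if "delta_e0" not in fixed else [base["delta_e0"]]
    r_grid = r_grid[r_grid > 0.5] if "r" not in fixed else [base["r"]]
    for r0 in r_grid:
        for e0 in e_grid:
            p = dict(base)
            p["r"], p["delta_e0"] = float(r0), float(e0)
            p["cn"] = 1.0
            unit = chi_model(ChiParameters(s02=s02, **p), table, data.k)
            if unit.k.size != data.k.size:
                continue
            a = w * unit.chi
            denom = a @ a
            if denom <= 0:
                continue
            cn0 = float(np.clip((a @ target) / denom, *_BOUNDS["cn"]))
            p["cn"] = cn0 if "cn" not in fixed else base["cn"]
            ssr = float(np.sum((cn0 * a - target) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, p)
    if best is None:
        raise FitError("no feasible starting point found on the coarse grid")
    start = best[1]
    x0 = np.array([start[n] for n in free])
    lb = np.array([_BOUNDS[n][0] for n in free])
    ub = np.array([_BOUNDS[n][1] for n in free])
    x0 = np.clip(x0, lb, ub)
    res = least_squares(
        residual,
        x0,
        bounds=(lb, ub),
        x_scale=np.array([_SCALES[n] for n in free]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=5000,
    )
    if res.status <= 0:
        raise FitError(
            f"single-shell fit did not converge: {res.message}", best=build(res.x)
        )
    params = build(res.x)
    model = chi_model(params, table, data.k)
    rf = rf_residual(data.chi, model.chi, data.k, k_weight)

    # covariance at optimum; noise scale from the residuals
    dof = max(data.k.size - len(free), 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.pinv(jtj)
        sigmas = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        sigmas = np.full(len(free), np.nan)
    uncertainties = {n: float(s) for n, s in zip(free, sigmas)}
    return EXAFSFitResult(
        params=params,
        uncertainties=uncertainties,
        rf=rf,
        k_range=(float(k_range[0]), float(k_range[1])),
        k_weight=k_weight,
        n_points=int(data.k.size),
        fit_c3=fit_c3,
    )
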