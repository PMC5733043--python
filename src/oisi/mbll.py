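"""Modified Beer-Lambert decomposition with a scattering pseudo-chromophore.

The relative intensity change of cortical tissue (the optical intrinsic
signal, OIS) is modeled as a linear mixture of absorption changes of oxy- and
deoxyhemoglobin and a light-scattering pseudo-chromophore S::

    OIS_lambda(t) = (dHbO(t) * eps_HbO(lambda)
                     + dHbR(t) * eps_HbR(lambda)
                     + mu_s'(lambda) * dS(t)) * 2 * d_IV

where ``OIS`` is the attenuation change (positive = darker in reflectance),
``eps`` are band-averaged extinction coefficients (mm^-1 uM^-1), ``mu_s'`` is
the reduced scattering coefficient (mm^-1), and the effective photon path is
taken as twice the cortical layer-4 depth ``d_IV`` (mm) — the light travels to
the active layer and back.  ``dS`` is dimensionless.

Given traces in >= 3 spectral bands the system is inverted per timepoint
(exact 3x3 solve, least squares when overdetermined).  The inversion is
exposed both as plain functions and as the scikit-learn style estimator
:class:`MBLLDecomposer` (fit -> coefficient matrix, transform -> chromophores,
inverse_transform -> forward projection).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import TimeCourse

__all__ = [
    "SpectrumCurve",
    "SpectralBand",
    "MBLLModel",
    "ChromophoreTimecourses",
    "band_average_extinction",
    "assemble_system",
    "forward_project",
    "decompose",
    "MBLLDecomposer",
    "DEFAULT_BANDS",
    "default_bands",
]

CHROMOPHORES = ("hbo", "hbr", "s")

#: canonical unit strings carried by spectra; mismatches are errors
EXTINCTION_UNITS = "1/(mm*uM)"
SCATTERING_UNITS = "1/mm"
EMISSION_UNITS = "arbitrary"


@dataclass
class SpectrumCurve:
    """A sampled spectral curve: LED emission, extinction, or mu_s'(lambda)."""

    wavelength_nm: np.ndarray
    value: np.ndarray
    units: str = EMISSION_UNITS
    name: str = ""

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.shape != self.value.shape:
            raise ValueError("wavelength and value must be equal-length 1-D arrays")
        if self.wavelength_nm.size > 1 and np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(self.wavelength_nm)) and np.all(np.isfinite(self.value))):
            raise ValueError("spectrum contains non-finite entries")

    @classmethod
    def from_csv(cls, path: str | Path, name: str = "") -> "SpectrumCurve":
        """Read a two-column CSV ``wavelength_nm,value`` with a ``# units:`` header."""
        path = Path(path)
        units = EMISSION_UNITS
        wl, val = [], []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "units:" in line:
                    units = line.split("units:", 1)[1].strip()
                continue
            if line.lower().startswith("wavelength"):
                continue
            a, b = line.split(",")[:2]
            wl.append(float(a))
            val.append(float(b))
        return cls(np.array(wl), np.array(val), units=units, name=name or path.stem)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        lines = [f"# units: {self.units}", "wavelength_nm,value"]
        lines += [f"{w:.6g},{v:.10g}" for w, v in zip(self.wavelength_nm, self.value)]
        path.write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class SpectralBand:
    """One illumination band with its band-averaged optical coefficients.

    ``eps_hbo``/``eps_hbr`` in mm^-1 uM^-1, ``mu_s_prime`` in mm^-1.
    """

    name: str
    eps_hbo: float
    eps_hbr: float
    mu_s_prime: float

    def __post_init__(self) -> None:
        for fname in ("eps_hbo", "eps_hbr", "mu_s_prime"):
            v = getattr(self, fname)
            if not np.isfinite(v):
                raise ValueError(f"{self.name}: {fname} must be finite")
        if self.eps_hbo < 0 or self.eps_hbr < 0:
            raise ValueError(f"{self.name}: extinction coefficients must be >= 0")
        if self.mu_s_prime < 0:
            raise ValueError(f"{self.name}: mu_s_prime must be >= 0")


# Representative band-averaged coefficients for the three default diodes.
# Hemoglobin values follow the standard rat/human hemoglobin extinction
# compilations (Zijlstra-style spectra) converted to mm^-1 uM^-1 (base 10);
# mu_s' follows the weakly wavelength-dependent cortical values reported in
# the tissue-optics literature.  These are editable defaults, not measured
# constants of any particular rig.
DEFAULT_BANDS: dict[str, SpectralBand] = {
    "GREEN": SpectralBand("GREEN", eps_hbo=3.10e-3, eps_hbr=3.05e-3, mu_s_prime=2.0),
    "RED": SpectralBand("RED", eps_hbo=1.51e-4, eps_hbr=1.47e-3, mu_s_prime=1.8),
    "IR": SpectralBand("IR", eps_hbo=7.1e-5, eps_hbr=1.08e-4, mu_s_prime=1.5),
}


def default_bands(names: Sequence[str] = ("GREEN", "RED", "IR")) -> list[SpectralBand]:
    return [DEFAULT_BANDS[n] for n in names]


def band_average_extinction(emission: SpectrumCurve, extinction: SpectrumCurve) -> float:
    """Emission-weighted mean of an extinction (or mu_s') curve.

    eps_bar = integral(L(lambda) eps(lambda) dlambda) / integral(L dlambda)
    by trapezoidal quadrature on the union grid with linear interpolation.
    A single-sample emission degenerates to point evaluation eps(lambda0).
    """
    if np.any(emission.value < 0):
        raise ValueError("emission spectrum must be non-negative")
    lo, hi = emission.wavelength_nm[0], emission.wavelength_nm[-1]
    if lo < extinction.wavelength_nm[0] - 1e-9 or hi > extinction.wavelength_nm[-1] + 1e-9:
        raise ValueError(
            "emission support "
            f"[{lo}, {hi}] nm lies outside the extinction grid "
            f"[{extinction.wavelength_nm[0]}, {extinction.wavelength_nm[-1]}] nm"
        )
    if emission.wavelength_nm.size == 1:
        return float(np.interp(lo, extinction.wavelength_nm, extinction.value))
    grid = np.union1d(emission.wavelength_nm, extinction.wavelength_nm)
    grid = grid[(grid >= lo) & (grid <= hi)]
    L = np.interp(grid, emission.wavelength_nm, emission.value)
    eps = np.interp(grid, extinction.wavelength_nm, extinction.value)
    denom = np.trapezoid(L, grid)
    if denom <= 0:
        raise ValueError("emission spectrum integrates to zero")
    return float(np.trapezoid(L * eps, grid) / denom)


@dataclass
class MBLLModel:
    """Assembled linear system mapping chromophore changes to attenuation.

    ``matrix`` is (n_bands, n_chromophores) with columns ordered as
    ``chromophores`` (subset of ("hbo", "hbr", "s")) and rows ordered as
    ``bands``; every entry already includes the 2*d_IV pathlength factor.
    """

    d_iv: float
    bands: list[SpectralBand]
    chromophores: tuple[str, ...] = CHROMOPHORES
    matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.d_iv) or self.d_iv <= 0:
            raise ValueError(f"d_iv must be finite and > 0, got {self.d_iv}")
        unknown = set(self.chromophores) - set(CHROMOPHORES)
        if unknown:
            raise ValueError(f"unknown chromophores {sorted(unknown)}")
        if len(self.chromophores) == 3 and len(self.bands) < 3:
            raise ValueError(
                "full 3-chromophore decomposition requires >= 3 bands, "
                f"got {len(self.bands)}"
            )
        if len(self.bands) < len(self.chromophores):
            raise ValueError("need at least as many bands as chromophores")
        cols = {"hbo": lambda b: b.eps_hbo, "hbr": lambda b: b.eps_hbr, "s": lambda b: b.mu_s_prime}
        self.matrix = self.pathlength * np.array(
            [[cols[c](b) for c in self.chromophores] for b in self.bands]
        )

    @property
    def pathlength(self) -> float:
        """Effective photon path: exactly twice the layer-4 depth (mm)."""
        return 2.0 * self.d_iv

    @property
    def band_names(self) -> list[str]:
        return [b.name for b in self.bands]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "d_iv_mm": self.d_iv,
            "pathlength_mm": self.pathlength,
            "chromophores": list(self.chromophores),
            "bands": [
                {
                    "name": b.name,
                    "eps_hbo": b.eps_hbo,
                    "eps_hbr": b.eps_hbr,
                    "mu_s_prime": b.mu_s_prime,
                }
                for b in self.bands
            ],
            "matrix": self.matrix.tolist(),
            "condition_number": self.condition_number,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class ChromophoreTimecourses:
    """Per-timepoint chromophore changes; HbT is dHbO + dHbR by construction."""

    t: np.ndarray
    d_hbo: np.ndarray
    d_hbr: np.ndarray
    d_s: np.ndarray
    stim_onset_s: float = 0.0
    residual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("d_hbo", "d_hbr", "d_s"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"{name} length {arr.shape} != t length {self.t.shape}")
            setattr(self, name, arr)

    @property
    def hbt(self) -> np.ndarray:
        return self.d_hbo + self.d_hbr

    def as_array(self) -> np.ndarray:
        """(n_times, 3) columns (dHbO, dHbR, dS)."""
        return np.column_stack([self.d_hbo, self.d_hbr, self.d_s])


class MBLLDecomposer(BaseEstimator, TransformerMixin):
    """Scikit-learn style spectral unmixer for multiband attenuation traces.

    Parameters
    ----------
    bands:
        Spectral bands (``SpectralBand``) whose order defines the column
        order of ``X`` in :meth:`transform`.
    d_iv:
        Cortical layer-4 depth in mm; the effective path is ``2 * d_iv``.
    chromophores:
        Which components to solve for; subset of ``("hbo", "hbr", "s")``.
    max_condition:
        Refuse to invert systems whose coefficient-matrix condition number
        exceeds this bound.

    After :meth:`fit`, ``matrix_`` holds the (n_bands, n_chromophores)
    coefficient matrix and ``condition_number_`` its conditioning.
    ``transform`` maps attenuation traces (n_times, n_bands) to chromophore
    traces (n_times, n_chromophores); ``inverse_transform`` is the exact
    forward projection.
    """

    def __init__(
        self,
        bands: Sequence[SpectralBand] = (),
        d_iv: float = 0.35,
        chromophores: tuple[str, ...] = CHROMOPHORES,
        max_condition: float = 1e8,
    ) -> None:
        self.bands = bands
        self.d_iv = d_iv
        self.chromophores = chromophores
        self.max_condition = max_condition

    def fit(self, X=None, y=None) -> "MBLLDecomposer":
        model = MBLLModel(
            d_iv=self.d_iv, bands=list(self.bands), chromophores=tuple(self.chromophores)
        )
        self.model_ = model
        self.matrix_ = model.matrix
        self.condition_number_ = model.condition_number
        self.n_features_in_ = len(model.bands)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "matrix_"):
            raise AttributeError("MBLLDecomposer is not fitted; call fit() first")

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Invert attenuation traces into chromophore traces.

        ``X``: (n_times, n_bands) attenuation (positive = darker in
        reflectance), band columns in ``self.bands`` order.
        """
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.matrix_.shape[0]:
            raise ValueError(
                f"X must be (n_times, {self.matrix_.shape[0]}), got {X.shape}"
            )
        if self.condition_number_ > self.max_condition:
            raise ValueError(
                f"coefficient matrix condition number {self.condition_number_:.3g} "
                f"exceeds {self.max_condition:.3g}; refusing to invert "
                f"(bands: {[b.name for b in self.bands]})"
            )
        M = self.matrix_
        if M.shape[0] == M.shape[1]:
            C = np.linalg.solve(M, X.T).T
        else:
            C, *_ = np.linalg.lstsq(M, X.T, rcond=None)
            C = C.T
        return C

    def inverse_transform(self, C: np.ndarray) -> np.ndarray:
        """Forward projection: chromophore traces -> per-band attenuation."""
        self._check_fitted()
        C = np.asarray(C, dtype=float)
        return C @ self.matrix_.T

    def residuals(self, X: np.ndarray, C: np.ndarray) -> np.ndarray:
        """Per-timepoint 2-norm of X - forward(C); informative when n_bands > n_chromophores."""
        self._check_fitted()
        return np.linalg.norm(np.asarray(X) - self.inverse_transform(C), axis=1)


def assemble_system(
    bands: Sequence[SpectralBand],
    d_iv: float,
    chromophores: tuple[str, ...] = CHROMOPHORES,
) -> MBLLModel:
    """Build the per-band coefficient matrix [eps_HbO, eps_HbR, mu_s'] * 2*d_IV."""
    return MBLLModel(d_iv=d_iv, bands=list(bands), chromophores=chromophores)


def forward_project(
    chromophores: ChromophoreTimecourses,
    bands: Sequence[SpectralBand],
    d_iv: float,
) -> dict[str, np.ndarray]:
    """Exact linear forward model: per-band attenuation traces, no noise.

    Returns ``{band name: trace}`` where positive values mean increased
    attenuation (darkening in reflectance imaging).  Any number of bands is
    allowed — the >= 3 band requirement applies only to inversion.
    """
    if not np.isfinite(d_iv) or d_iv <= 0:
        raise ValueError(f"d_iv must be finite and > 0, got {d_iv}")
    M = 2.0 * d_iv * np.array([[b.eps_hbo, b.eps_hbr, b.mu_s_prime] for b in bands])
    A = chromophores.as_array() @ M.T
    return {b.name: A[:, k] for k, b in enumerate(bands)}


def _attenuation_sign(mode: str, polarity: str) -> float:
    # raw reflectance traces are relative intensity (darkening negative);
    # attenuation is their negation.  The activation-positive convention
    # already flipped reflectance, and transmission brightening carries the
    # attenuation sign directly in either polarity.
    if mode == "reflectance" and polarity == "raw":
        return -1.0
    return 1.0


def decompose(
    ois_by_band: Mapping[str, TimeCourse] | Sequence[TimeCourse],
    model: MBLLModel,
    max_condition: float = 1e8,
) -> ChromophoreTimecourses:
    """Invert multiband OIS time courses into chromophore time courses.

    Each trace's ``mode``/``polarity`` metadata determines its sign relative
    to attenuation, so reflectance and transmission recordings of the same
    response decompose identically.
    """
    if isinstance(ois_by_band, Mapping):
        traces = [ois_by_band[b.name] for b in model.bands]
    else:
        by_name = {tc.band: tc for tc in ois_by_band}
        traces = [by_name[b.name] for b in model.bands]
    t0 = traces[0].t
    for tc in traces[1:]:
        if tc.t.shape != t0.shape or not np.allclose(tc.t, t0, atol=1e-9):
            raise ValueError("band traces do not share one time grid")
    X = np.column_stack(
        [_attenuation_sign(tc.mode, tc.polarity) * tc.y for tc in traces]
    )
    est = MBLLDecomposer(
        bands=model.bands,
        d_iv=model.d_iv,
        chromophores=model.chromophores,
        max_condition=max_condition,
    ).fit()
    C = est.transform(X)
    full = {c: C[:, k] for k, c in enumerate(model.chromophores)}
    z = np.zeros_like(t0)
    res = est.residuals(X, C) if len(model.bands) > len(model.chromophores) else None
    return ChromophoreTimecourses(
        t=t0,
        d_hbo=full.get("hbo", z.copy()),
        d_hbr=full.get("hbr", z.copy()),
        d_s=full.get("s", z.copy()),
        stim_onset_s=traces[0].stim_onset_s,
        residual=res,
    )
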