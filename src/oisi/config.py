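"""Run configuration: YAML schema, validation-as-data, band resolution."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .core import Protocol
from .mbll import DEFAULT_BANDS, SpectralBand, SpectrumCurve, band_average_extinction
from .simulate import ADULT, NEONATAL, ResponseParams, SceneParams

__all__ = ["RunConfig", "load_config", "validate_config", "resolve_bands", "resolve_response", "resolve_scene"]

_PRESETS = {"neonatal": NEONATAL, "adult": ADULT}


@dataclass
class RunConfig:
    """Everything one pipeline run needs; see ``validate_config`` for the rules."""

    out_dir: str = "ois_run"
    seed: int = 0
    input_dir: str | None = None  # read recorded/simulated stacks instead of simulating
    scene: dict = field(default_factory=dict)  # SceneParams overrides
    response: str | dict = "neonatal"  # preset name or ResponseParams fields
    mode: str = "reflectance"
    bands: list = field(default_factory=lambda: ["GREEN", "RED", "IR"])
    d_iv: float = 0.35
    chromophores: tuple = ("hbo", "hbr", "s")
    sigma_px: float = 2.0
    alpha_window: str = "full"
    illumination_correction: bool = True
    threshold_frac: float = 0.5
    smooth_window_s: float = 3.0
    save_raw: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**dict(d))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chromophores"] = list(self.chromophores)
        return d


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def resolve_response(config: RunConfig) -> ResponseParams:
    if isinstance(config.response, str):
        try:
            return _PRESETS[config.response]
        except KeyError:
            raise ValueError(
                f"unknown response preset {config.response!r}; "
                f"choose from {sorted(_PRESETS)} or give explicit fields"
            ) from None
    return ResponseParams(**dict(config.response))


def resolve_scene(config: RunConfig) -> SceneParams:
    d = dict(config.scene)
    if "protocol" in d:
        d["protocol"] = Protocol.from_dict(d["protocol"])
    if "blob_center" in d:
        d["blob_center"] = tuple(d["blob_center"])
    d.setdefault("seed", config.seed)
    return SceneParams(**d)


def _band_from_spec(spec: Any) -> SpectralBand:
    """A band is a known name, explicit coefficients, or spectra CSV paths."""
    if isinstance(spec, str):
        if spec not in DEFAULT_BANDS:
            raise ValueError(f"unknown band name {spec!r}; known: {sorted(DEFAULT_BANDS)}")
        return DEFAULT_BANDS[spec]
    spec = dict(spec)
    name = spec.get("name")
    if not name:
        raise ValueError("band entry missing 'name'")
    coeff_keys = {"eps_hbo", "eps_hbr", "mu_s_prime"}
    if coeff_keys <= set(spec):
        return SpectralBand(
            name=name,
            eps_hbo=float(spec["eps_hbo"]),
            eps_hbr=float(spec["eps_hbr"]),
            mu_s_prime=float(spec["mu_s_prime"]),
        )
    spectra_keys = {"emission_csv", "extinction_hbo_csv", "extinction_hbr_csv"}
    if spectra_keys <= set(spec):
        emission = SpectrumCurve.from_csv(spec["emission_csv"], name=name)
        eps_hbo = band_average_extinction(emission, SpectrumCurve.from_csv(spec["extinction_hbo_csv"]))
        eps_hbr = band_average_extinction(emission, SpectrumCurve.from_csv(spec["extinction_hbr_csv"]))
        if "mu_s_prime_csv" in spec:
            mu = band_average_extinction(emission, SpectrumCurve.from_csv(spec["mu_s_prime_csv"]))
        else:
            mu = float(spec.get("mu_s_prime", 0.0))
        return SpectralBand(name=name, eps_hbo=eps_hbo, eps_hbr=eps_hbr, mu_s_prime=mu)
    raise ValueError(
        f"band {name!r} needs either coefficients {sorted(coeff_keys)} or "
        f"spectra {sorted(spectra_keys)}"
    )


def resolve_bands(config: RunConfig) -> list[SpectralBand]:
    return [_band_from_spec(s) for s in config.bands]


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    if config.d_iv is None or not (config.d_iv > 0):
        problems.append(f"d_iv: must be > 0 (got {config.d_iv!r})")
    if config.mode not in ("reflectance", "transmission"):
        problems.append(f"mode: must be 'reflectance' or 'transmission' (got {config.mode!r})")
    if not (0 < config.threshold_frac < 1):
        problems.append(f"threshold_frac: must be in (0, 1) (got {config.threshold_frac!r})")
    if config.sigma_px <= 0:
        problems.append(f"sigma_px: must be > 0 (got {config.sigma_px!r})")
    if config.alpha_window not in ("full", "baseline"):
        problems.append(f"alpha_window: must be 'full' or 'baseline' (got {config.alpha_window!r})")
    try:
        bands = resolve_bands(config)
    except (ValueError, OSError) as e:
        problems.append(f"bands: {e}")
        bands = []
    if bands and len(bands) < len(config.chromophores):
        problems.append(
            f"bands: {len(config.chromophores)}-chromophore decomposition requires "
            f">= {len(config.chromophores)} bands, got {len(bands)}"
        )
    if config.input_dir is not None:
        p = Path(config.input_dir)
        if not (p / "metadata.json").exists():
            problems.append(f"input_dir: {p}/metadata.json not found")
    else:
        try:
            resolve_response(config)
        except (ValueError, TypeError) as e:
            problems.append(f"response: {e}")
        try:
            resolve_scene(config)
        except (ValueError, TypeError) as e:
            problems.append(f"scene: {e}")
    return problems
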