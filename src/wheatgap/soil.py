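"""Soil water as a cascade of 5-cm layers.

Each layer holds up to its available water capacity (AWC); infiltration
fills layers top-down and overflow past the bottom layer is drainage.
Daily root extraction from layer *i* is limited to
``(R_u / 100) * (lambda_i / mean(lambda)) * available_i`` — the cultivar
trait ``R_u`` is the percentage of currently extractable root-zone
water usable per day, and the extraction-efficiency profile ``lambda``
declines linearly with depth (0.10 at the surface to 0.04 at the
bottom), weighting uptake toward shallow layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernel import soil_step

__all__ = ["SoilProfile", "rothamsted_210", "lincoln_270", "named_profile",
           "soil_water_step", "read_soil", "write_soil"]

LAYER_CM = 5.0
LAMBDA_TOP = 0.10
LAMBDA_BOTTOM = 0.04


@dataclass
class SoilProfile:
    name: str
    awc_per_layer: np.ndarray  # mm per 5-cm layer
    lambda_profile: np.ndarray  # extraction efficiency per layer
    water: np.ndarray  # current plant-available water per layer, mm

    def __post_init__(self):
        self.awc_per_layer = np.asarray(self.awc_per_layer, dtype=float)
        self.lambda_profile = np.asarray(self.lambda_profile, dtype=float)
        self.water = np.asarray(self.water, dtype=float)
        if not (len(self.awc_per_layer) == len(self.lambda_profile) == len(self.water)):
            raise ValueError("layer arrays must have equal length")
        if np.any(self.water < -1e-12) or np.any(self.water > self.awc_per_layer + 1e-9):
            raise ValueError("layer water content outside [0, awc]")

    @property
    def n_layers(self) -> int:
        return len(self.awc_per_layer)

    @property
    def total_awc(self) -> float:
        return float(self.awc_per_layer.sum())

    @property
    def depth_cm(self) -> float:
        return self.n_layers * LAYER_CM

    @property
    def lambda_rel(self) -> np.ndarray:
        """Extraction efficiency relative to the profile mean."""
        return self.lambda_profile / self.lambda_profile.mean()

    def copy_full(self) -> "SoilProfile":
        """A copy of this profile at field capacity."""
        return SoilProfile(
            self.name,
            self.awc_per_layer.copy(),
            self.lambda_profile.copy(),
            self.awc_per_layer.copy(),
        )


def _uniform_profile(name: str, total_awc: float, n_layers: int) -> SoilProfile:
    awc = np.full(n_layers, total_awc / n_layers)
    lam = np.linspace(LAMBDA_TOP, LAMBDA_BOTTOM, n_layers)
    return SoilProfile(name, awc, lam, awc.copy())


def rothamsted_210() -> SoilProfile:
    """UK profile: 210 mm AWC over 28 x 5-cm layers (140 cm)."""
    return _uniform_profile("rothamsted_210", 210.0, 28)


def lincoln_270() -> SoilProfile:
    """NZ profile: 270 mm AWC over 36 x 5-cm layers (180 cm)."""
    return _uniform_profile("lincoln_270", 270.0, 36)


_NAMED = {"rothamsted_210": rothamsted_210, "lincoln_270": lincoln_270}


def named_profile(name: str) -> SoilProfile:
    try:
        return _NAMED[name]()
    except KeyError:
        raise KeyError(f"unknown soil profile {name!r}; have {sorted(_NAMED)}")


def soil_water_step(
    profile: SoilProfile,
    precip: float,
    transp_demand: float,
    R_u: float,
    root_depth_cm: float,
    evap_demand: float = 0.0,
):
    """One day of the soil water cascade (in place).

    Order of operations: infiltration (top-down cascade, overflow is
    drainage), soil evaporation from the top two layers, then root
    extraction limited per layer by ``R_u`` and the lambda profile.

    Returns ``(transpiration, drainage, evaporation)`` in mm; the water
    balance ``precip - (d_storage + drainage + transpiration +
    evaporation)`` closes to machine precision.
    """
    if precip < 0 or transp_demand < 0 or evap_demand < 0:
        raise ValueError("precip, transpiration demand and evap demand must be >= 0")
    if R_u <= 0:
        raise ValueError("R_u must be positive")
    n_rooted = int(min(profile.n_layers, max(0.0, root_depth_cm) / LAYER_CM))
    transp, drainage, evap = soil_step(
        profile.water,
        profile.awc_per_layer,
        profile.lambda_rel,
        float(precip),
        float(evap_demand),
        float(transp_demand),
        float(R_u),
        n_rooted,
    )
    return float(transp), float(drainage), float(evap)


def write_soil(profile: SoilProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"name = {profile.name}\n")
        fh.write(f"total_awc_mm = {profile.total_awc:g}\n")
        fh.write(f"n_layers = {profile.n_layers}\n")


def read_soil(path) -> SoilProfile:
    """Read a soil config: name, total AWC (mm) and layer count."""
    kw: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kw[key.strip()] = val.strip()
    try:
        return _uniform_profile(
            kw.get("name", "custom"), float(kw["total_awc_mm"]), int(kw["n_layers"])
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing soil key {exc}") from exc
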