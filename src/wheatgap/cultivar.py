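"""Cultivar trait parameterisation.

Seven optimizable traits describe a winter wheat cultivar:

==========  =============================================  ==============
symbol      meaning                                        units
==========  =============================================  ==============
``P_h``     phyllochron                                    degC day/leaf
``P_p``     daylength response (extra leaves per hour of   leaf/h
            daylength shortfall)
``G_f``     grain-filling duration                         degC day
``A_max``   potential flag-leaf area                       m2 leaf/m2 soil
``S_G``     stay-green factor (delays senescence)          --
``R_u``     rate of root water uptake                      % per day
``W_ss``    max acceleration of senescence under drought   --
==========  =============================================  ==============

``TRAIT_BOUNDS`` holds the observed genetic-variation ranges used to
constrain ideotype optimisation; the reference cultivar Claire sits
inside them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["CultivarParams", "CLAIRE", "TRAIT_BOUNDS", "TRAIT_NAMES",
           "read_cultivar", "write_cultivar"]

TRAIT_NAMES = ("P_h", "P_p", "G_f", "A_max", "S_G", "R_u", "W_ss")

#: observed genetic-variation ranges used in ideotype optimisation
TRAIT_BOUNDS: dict[str, tuple[float, float]] = {
    "P_h": (80.0, 140.0),
    "P_p": (0.065, 0.900),
    "G_f": (500.0, 900.0),
    "A_max": (0.005, 0.01),
    "S_G": (0.00, 1.50),
    "R_u": (1.0, 5.0),
    "W_ss": (1.0, 1.7),
}


@dataclass(frozen=True)
class CultivarParams:
    P_h: float = 110.0
    P_p: float = 0.565
    G_f: float = 650.0
    A_max: float = 0.007
    S_G: float = 0.5
    R_u: float = 3.0
    W_ss: float = 1.27
    name: str = "unnamed"

    def __post_init__(self):
        for t in TRAIT_NAMES:
            if getattr(self, t) <= 0 and t != "S_G":
                raise ValueError(f"trait {t} must be positive")
        if self.S_G < 0:
            raise ValueError("S_G must be >= 0")

    def as_vector(self, names=TRAIT_NAMES):
        return [getattr(self, n) for n in names]

    def within_bounds(self, names=TRAIT_NAMES) -> bool:
        return all(
            TRAIT_BOUNDS[n][0] - 1e-12 <= getattr(self, n) <= TRAIT_BOUNDS[n][1] + 1e-12
            for n in names
        )

    def replace(self, **kw) -> "CultivarParams":
        return replace(self, **kw)


#: locally adapted reference winter wheat cultivar
CLAIRE = CultivarParams(
    P_h=110.0, P_p=0.565, G_f=650.0, A_max=0.007, S_G=0.5, R_u=3.0, W_ss=1.27,
    name="Claire",
)


def write_cultivar(cv: CultivarParams, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"name = {cv.name}\n")
        for t in TRAIT_NAMES:
            fh.write(f"{t} = {getattr(cv, t)!r}\n")


def read_cultivar(path) -> CultivarParams:
    """Read a key=value cultivar file (the seven traits plus a name)."""
    kw: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key == "name":
                kw["name"] = val
            elif key in TRAIT_NAMES:
                kw[key] = float(val)
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    return CultivarParams(**kw)
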