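"""Shared constants and run configuration.

The solvent panel, element alphabet and adduct table are process-wide
conventions: every module that mentions a solvent or an element refers to
the ordered sequences defined here, so that fingerprint vectors, formula
encodings and CSV columns line up across stages.
"""

from __future__ import annotations

import logging
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator

log = logging.getLogger("turbofp")

#: The ten organic solvents of the shake-flask partition panel, in the
#: fixed order used for fingerprint vectors and CSV columns.
DEFAULT_SOLVENTS: tuple[str, ...] = (
    "octanol",
    "butyl_acetate",
    "chloroform",
    "cyclohexane",
    "dichloromethane",
    "hexane",
    "octane",
    "oleyl_alcohol",
    "toluene",
    "undecane",
)

#: Ordered element alphabet for fixed-length molecular-formula encodings.
ELEMENT_ALPHABET: tuple[str, ...] = ("C", "H", "N", "O", "S", "P", "F", "Cl", "Br", "I")

#: Monoisotopic masses (Da) of the alphabet elements.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
}

#: Mass of a proton (Da); the adduct mass for [M+H]+ / [M-H]-.
PROTON_MASS: float = 1.007276

#: Neutral-mass correction per ionization mode: observed m/z plus this
#: offset gives the neutral monoisotopic mass.
ADDUCT_OFFSET: dict[str, float] = {
    "positive": -PROTON_MASS,  # [M+H]+  -> subtract a proton
    "negative": +PROTON_MASS,  # [M-H]-  -> add a proton back
    "neutral": 0.0,
}

#: Phase volumes (V_W, V_S) in mL per replicate experiment: the OECD
#: shake-flask design runs solvent:water ratios 1:1, 2:1 and 0.5:1.
DEFAULT_VOLUMES: dict[int, tuple[float, float]] = {
    1: (1.0, 1.0),
    2: (1.0, 2.0),
    3: (1.0, 0.5),
}

#: Mass-matching tolerance (ppm) per instrument platform.
PPM_TOL: dict[str, float] = {"qtof": 10.0, "orbitrap": 5.0}

#: Blank-filter ratio: a feature is real if its reference area is at least
#: this multiple of the mean blank area.
BLANK_RATIO: float = 1.3


class RunConfig(BaseModel):
    """Validated configuration for a pipeline run."""

    solvents: tuple[str, ...] = DEFAULT_SOLVENTS
    platform: Literal["qtof", "orbitrap"] = "qtof"
    ionization: Literal["positive", "negative", "neutral"] = "positive"
    ppm_tol: Optional[float] = Field(default=None, gt=0)
    blank_ratio: float = Field(default=BLANK_RATIO, ge=1.0)
    volume_correction: bool = True
    volumes: dict[int, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_VOLUMES)
    )
    impute_iters: int = Field(default=100, ge=1)
    seed: int = 0
    epochs: int = Field(default=200, ge=1)
    dropout_rate: float = Field(default=0.2, ge=0.0, lt=1.0)

    @field_validator("solvents")
    @classmethod
    def _nonempty_panel(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if len(v) < 2:
            raise ValueError("solvent panel needs at least 2 solvents")
        if len(set(v)) != len(v):
            raise ValueError("solvent panel has duplicates")
        return v

    @property
    def effective_ppm_tol(self) -> float:
        return self.ppm_tol if self.ppm_tol is not None else PPM_TOL[self.platform]


def formula_mass(formula: dict[str, int]) -> float:
    """Monoisotopic mass (Da) of an element-count map."""
    unknown = set(formula) - set(ELEMENT_ALPHABET)
    if unknown:
        raise ValueError(f"elements outside the supported alphabet: {sorted(unknown)}")
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.items())


def setup_logging(level: int = logging.INFO) -> None:
    """Route structured logs to stderr (data goes to files only)."""
    h = logging.StreamHandler()
    h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [h]
    log.setLevel(level)
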