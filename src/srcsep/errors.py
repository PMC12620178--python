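"""The three ways the pipeline corrupts its R2 input.

1. **Global scaling** — multiply the baseline (dictionary-fit) R2 map by
   a factor between 0.75 and 1.25 in 1 % steps, skipping 1.00: fifty
   altered maps carrying -25 % .. +25 % errors.
2. **Exponential-fit substitution** — replace the dictionary fit by the
   naive two-point exponential fit, whose stimulated-echo blindness
   underestimates R2 with a B1-dependent spatial pattern.
3. **R2*-based approximation** — discard the R2 measurement entirely and
   set R2 = 0.48 R2*, equivalently R2' = 0.52 R2* (no clipping can
   trigger downstream since R2* - 0.48 R2* = 0.52 R2* >= 0).

Alterations always apply to fitted baseline maps, not to ground truth:
they emulate analysis mistakes, not physics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ScalarVolume
from .relaxometry import fit_r2_exponential
from .sequences import TSEParams

R2STAR_TO_R2_COEFF = 0.48  # R2 = 0.48 R2*  <=>  R2' = 0.52 R2*


class ErrorModelError(ValueError):
    pass


@dataclass
class ErrorSpec:
    """One R2 corruption: its family and, for scaling, the factor."""

    kind: str                      # global_scale | exponential_fit | r2star_based
    factor: float | None = None    # global_scale only

    def __post_init__(self) -> None:
        if self.kind not in ("global_scale", "exponential_fit", "r2star_based"):
            raise ErrorModelError(f"unknown error kind {self.kind!r}")
        if self.kind == "global_scale":
            if self.factor is None or not (0.75 <= self.factor <= 1.25):
                raise ErrorModelError("global_scale factor must be in [0.75, 1.25]")

    @property
    def label(self) -> str:
        if self.kind == "global_scale":
            return f"scale_{self.factor:.2f}"
        return self.kind


def scale_r2_map(r2: ScalarVolume, factor: float) -> ScalarVolume:
    """Voxelwise R2 x factor (unit preserved); linear in the factor."""
    if factor <= 0:
        raise ErrorModelError("factor must be positive")
    return r2.with_data(r2.data * factor)


def enumerate_error_series() -> list[float]:
    """The fifty global scaling factors: 0.75 .. 1.25 step 0.01, no 1.00.

    The identity factor is excluded so the count of *altered* maps is 50.
    """
    factors = np.round(0.75 + 0.01 * np.arange(51), 10)
    return [float(f) for f in factors if abs(f - 1.0) > 1e-9]


def r2_from_r2star(r2star: ScalarVolume) -> ScalarVolume:
    """R2*-based approximation: R2 = 0.48 R2* voxelwise.

    Downstream R2' becomes exactly 0.52 R2*, so R2 + R2' = R2* holds
    identically.
    """
    if r2star.unit != "Hz":
        raise ErrorModelError("r2star must be in Hz")
    return r2star.with_data(R2STAR_TO_R2_COEFF * r2star.data)


def exponential_substitute(
    echo1: ScalarVolume, echo2: ScalarVolume, params: TSEParams
) -> ScalarVolume:
    """R2 by naive exponential fitting of the TSE pair.

    Pure delegation to the relaxometry fit; exists so the sweep driver
    treats all three alteration families through one interface.
    """
    return fit_r2_exponential(echo1, echo2, params)
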