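"""Isotropic incompressible hyperelastic models in uniaxial tension.

Four models are supported: Neo-Hookean, Yeoh (two active coefficients),
and the 3- and 5-parameter Mooney-Rivlin forms.  All stresses are nominal
(force over undeformed cross-section, N/mm^2 == MPa) and all formulas are
evaluated exactly in the algebraic form used throughout the package, with
the stretch ratio ``lambda = l / l0 = strain + 1`` as the kinematic input.

Uniaxial stress expressions (lam == stretch ratio):

* ``NEO_HOOKEAN``:  sigma = 2 C1 (lam - lam^-2)
* ``YEOH``:         sigma = 2 (lam - lam^-2) (C1 + 2 C2 (lam^2 + 2/lam - 3))
* ``MR3``:          sigma = 2 C1 (lam - 1/lam) + 2 C2 (1 - lam^-3)
  + 6 C3 (lam^2 - lam - 1 + lam^-2 + lam^-3 - lam^-4)
* ``MR5``:          the MR3 expression plus
  4 C4 lam (1 - lam^-3)(lam^2 + 2/lam - 3) + 4 C5 (2 lam + lam^-2 - 3)(1 - lam^-3)

Note the first Mooney-Rivlin term is ``lam - 1/lam`` (not ``lam - lam^-2``),
so the Mooney-Rivlin family deliberately does *not* reduce to the
Neo-Hookean expression at C2 = C3 = 0; each formula is kept verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "Model",
    "CoefficientSet",
    "StabilityCondition",
    "StabilityReport",
    "uniaxial_stress",
    "strain_energy",
    "linear_part",
    "stability_check",
]


class Model(str, Enum):
    """Identifier of a hyperelastic model and its coefficient count."""

    NEO_HOOKEAN = "NEO_HOOKEAN"
    YEOH = "YEOH"
    MR3 = "MR3"
    MR5 = "MR5"

    @property
    def n_coeffs(self) -> int:
        return _N_COEFFS[self]


_N_COEFFS = {Model.NEO_HOOKEAN: 1, Model.YEOH: 2, Model.MR3: 3, Model.MR5: 5}


@dataclass(frozen=True)
class CoefficientSet:
    """A model identifier plus its material coefficients C1..Cn in MPa."""

    model: Model
    coefficients: tuple[float, ...]

    def __post_init__(self):
        coeffs = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        if len(coeffs) != self.model.n_coeffs:
            raise ValidationError(
                f"{self.model.value} needs {self.model.n_coeffs} coefficients, "
                f"got {len(coeffs)}",
                fields=["coefficients"],
            )
        if not all(np.isfinite(coeffs)):
            raise ValidationError("coefficients must be finite", fields=["coefficients"])

    def __getitem__(self, i: int) -> float:
        return self.coefficients[i]

    def to_json(self) -> str:
        return json.dumps(
            {"model": self.model.value, "coefficients_MPa": list(self.coefficients)}
        )

    @classmethod
    def from_json(cls, text: str) -> "CoefficientSet":
        obj = json.loads(text)
        return cls(Model(obj["model"]), tuple(obj["coefficients_MPa"]))


def _as_valid_stretch(stretch) -> np.ndarray:
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0.0):
        raise DomainError("stretch ratio must be > 0")
    return lam


def _maybe_scalar(value: np.ndarray, template) -> float | np.ndarray:
    if np.isscalar(template) or np.ndim(template) == 0:
        return float(value)
    return value


def uniaxial_stress(coeffs: CoefficientSet, stretch) -> float | np.ndarray:
    """Nominal uniaxial stress [MPa] at the given stretch ratio(s).

    Vectorized over arrays; raises :class:`DomainError` for non-positive
    stretch.  Every model yields exactly zero stress at ``lam == 1``.
    """
    lam = _as_valid_stretch(stretch)
    c = coeffs.coefficients
    m = coeffs.model
    if m is Model.NEO_HOOKEAN:
        sig = 2.0 * c[0] * (lam - lam**-2)
    elif m is Model.YEOH:
        sig = 2.0 * (lam - lam**-2) * (c[0] + 2.0 * c[1] * (lam**2 + 2.0 / lam - 3.0))
    else:
        sig = (
            2.0 * c[0] * (lam - 1.0 / lam)
            + 2.0 * c[1] * (1.0 - lam**-3)
            + 6.0 * c[2] * (lam**2 - lam - 1.0 + lam**-2 + lam**-3 - lam**-4)
        )
        if m is Model.MR5:
            sig = sig + 4.0 * c[3] * lam * (1.0 - lam**-3) * (lam**2 + 2.0 / lam - 3.0)
            sig = sig + 4.0 * c[4] * (2.0 * lam + lam**-2 - 3.0) * (1.0 - lam**-3)
    return _maybe_scalar(sig, stretch)


def strain_energy(coeffs: CoefficientSet, stretch) -> float | np.ndarray:
    """Strain energy density W [MPa] under incompressible uniaxial kinematics.

    Uses the invariant substitutions I1 = lam^2 + 2/lam and
    I2 = 2 lam + lam^-2 (J = 1, volumetric terms dropped).
    """
    lam = _as_valid_stretch(stretch)
    i1 = lam**2 + 2.0 / lam - 3.0
    i2 = 2.0 * lam + lam**-2 - 3.0
    c = coeffs.coefficients
    m = coeffs.model
    if m is Model.NEO_HOOKEAN:
        w = c[0] * i1
    elif m is Model.YEOH:
        # third-order term of the Yeoh series is fixed at zero
        w = c[0] * i1 + c[1] * i1**2
    else:
        w = c[0] * i1 + c[1] * i2 + c[2] * i1 * i2
        if m is Model.MR5:
            w = w + c[3] * i1**2 + c[4] * i2**2
    return _maybe_scalar(w, stretch)


def linear_part(coeffs: CoefficientSet) -> float:
    """Coefficient of the linear (small-strain) part of the elastic energy.

    C1 for Neo-Hookean and Yeoh; C1 - 3 C3 for MR3;
    C1 - 3 C3 - 6 C4 + 4 C5 for MR5.
    """
    c = coeffs.coefficients
    m = coeffs.model
    if m in (Model.NEO_HOOKEAN, Model.YEOH):
        return c[0]
    if m is Model.MR3:
        return c[0] - 3.0 * c[2]
    return c[0] - 3.0 * c[2] - 6.0 * c[3] + 4.0 * c[4]


@dataclass(frozen=True)
class StabilityCondition:
    label: str
    margin: float  # value of the condition expression, pass when >= -tolerance
    passed: bool


@dataclass(frozen=True)
class StabilityReport:
    model: Model
    conditions: tuple[StabilityCondition, ...]
    overall: bool
    note: str = ""


#: (label, linear-form row) pairs; each condition reads row . C >= 0.
#: The MR5 condition "C5 < 0" is encoded as -C5 with a strict-side note in
#: :func:`stability_check`.
STABILITY_ROWS: dict[Model, list[tuple[str, tuple[float, ...]]]] = {
    Model.NEO_HOOKEAN: [],
    Model.YEOH: [],
    Model.MR3: [
        ("C1+C2>=0", (1.0, 1.0, 0.0)),
        ("C3>=0", (0.0, 0.0, 1.0)),
    ],
    Model.MR5: [
        ("C1+C2>=0", (1.0, 1.0, 0.0, 0.0, 0.0)),
        ("C4>=0", (0.0, 0.0, 0.0, 1.0, 0.0)),
        ("C5<0", (0.0, 0.0, 0.0, 0.0, -1.0)),
        ("C3+C4+C5>=0", (0.0, 0.0, 1.0, 1.0, 1.0)),
    ],
}


def stability_check(coeffs: CoefficientSet, tolerance: float = 1e-5) -> StabilityReport:
    """Evaluate the material-stability sign conditions on the coefficients.

    MR3: C1+C2 >= 0 and C3 >= 0.  MR5: C1+C2 >= 0, C4 >= 0, C5 < 0 and
    C3+C4+C5 >= 0.  Neo-Hookean and Yeoh have no stated conditions and pass
    vacuously.  ``tolerance`` (MPa) absorbs rounding of published
    coefficients: a condition ``expr >= 0`` passes when ``expr >= -tolerance``
    and ``C5 < 0`` passes when ``C5 < +tolerance``.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0", fields=["tolerance"])
    rows = STABILITY_ROWS[coeffs.model]
    c = np.asarray(coeffs.coefficients)
    conditions = []
    for label, row in rows:
        margin = float(np.dot(row, c))
        conditions.append(StabilityCondition(label, margin, margin >= -tolerance))
    note = "" if rows else "no stability conditions stated for this model"
    overall = all(cond.passed for cond in conditions)
    return StabilityReport(coeffs.model, tuple(conditions), overall, note)
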