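"""Synthetic tensile-test data with the statistical structure the analysis
pipeline assumes: multi-stage loading with preconditioning repeats, a
model-governed elastic response up to an optional plateau, additive
Gaussian stress noise, and cohorts whose ultimate stresses differ between
ruptured and unruptured groups.

Everything is seeded and bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constitutive import CoefficientSet, Model, uniaxial_stress
from .errors import ValidationError
from .io_tensile import RawTest, SpecimenMeta, Status, TensileCurve
from . import tables

__all__ = [
    "GeneratorConfig",
    "generate_curve",
    "generate_specimen_series",
    "generate_cohort",
    "paper_like_cohort",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic tensile-test generator."""

    coefficients: CoefficientSet
    lambda_max: float
    n_points: int = 200
    noise_sd: float = 0.0  # MPa, additive Gaussian on stress
    plateau_at: float | None = None  # stretch at which the plateau begins
    plateau_slope: float = 0.0  # MPa per unit stretch beyond the plateau
    stages: int = 1
    preconditioning_cycles: int = 0  # repeats before the kept cycle, per stage
    softening: float = 0.2  # first-cycle stress inflation fraction
    softening_decay: float = 0.5  # geometric decay of inflation per cycle
    seed: int = 0
    specimen_id: str = "SYN"
    status: Status = Status.NOT_APPLICABLE
    thickness_mm: float = 0.1
    width_mm: float = 2.0
    gauge_length_mm: float = 10.0

    def validate(self) -> None:
        bad = []
        if not self.lambda_max > 1:
            bad.append("lambda_max")
        if self.n_points < 2:
            bad.append("n_points")
        if self.noise_sd < 0:
            bad.append("noise_sd")
        if self.plateau_at is not None and not 1.0 < self.plateau_at:
            bad.append("plateau_at")
        if self.stages < 1:
            bad.append("stages")
        if not 0 <= self.preconditioning_cycles <= 5:
            bad.append("preconditioning_cycles")
        if self.softening < 0:
            bad.append("softening")
        if not 0 < self.softening_decay <= 1:
            bad.append("softening_decay")
        if self.thickness_mm <= 0:
            bad.append("thickness_mm")
        if self.width_mm <= 0:
            bad.append("width_mm")
        if self.gauge_length_mm <= 0:
            bad.append("gauge_length_mm")
        if bad:
            raise ValidationError("invalid generator config", fields=bad)

    def meta(self) -> SpecimenMeta:
        return SpecimenMeta(
            id=self.specimen_id,
            status=self.status,
            thickness_mm=self.thickness_mm,
            width_mm=self.width_mm,
            gauge_length_mm=self.gauge_length_mm,
        )


def _clean_stress(config: GeneratorConfig, lam: np.ndarray) -> np.ndarray:
    """Noise-free stress: model response spliced continuously into a linear
    plateau tail beyond ``plateau_at``."""
    sig = np.asarray(uniaxial_stress(config.coefficients, lam), dtype=float)
    if config.plateau_at is not None and config.plateau_at < config.lambda_max:
        lam_c = config.plateau_at
        sig_c = float(uniaxial_stress(config.coefficients, lam_c))
        past = lam > lam_c
        sig[past] = sig_c + config.plateau_slope * (lam[past] - lam_c)
    return sig


def generate_curve(config: GeneratorConfig) -> TensileCurve:
    """One stress-stretch curve on a uniform stretch grid [1, lambda_max]."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lam = np.linspace(1.0, config.lambda_max, config.n_points)
    sig = _clean_stress(config, lam)
    if config.noise_sd > 0:
        sig = _add_noise(sig, rng, config.noise_sd)
    return TensileCurve(lam, sig, specimen_id=config.specimen_id, stage=0)


def _add_noise(clean: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """Additive Gaussian noise, floored so it never drives the signal below
    zero (or below the noise-free value where that is already negative)."""
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.size)
    return np.maximum(noisy, np.minimum(clean, 0.0))


def _softening_factor(config: GeneratorConfig, cycle: int, n_cycles: int) -> float:
    # last cycle is the designated "true" response, factor exactly 1
    if cycle == n_cycles - 1:
        return 1.0
    return 1.0 + config.softening * config.softening_decay**cycle


def generate_specimen_series(config: GeneratorConfig) -> RawTest:
    """Force/displacement rows for a programmed multi-stage experiment.

    Stage k (k = 1..stages) ramps to the target stretch
    ``1 + (lambda_max - 1) k / stages``; each stage consists of
    ``preconditioning_cycles`` softened repeats followed by one kept cycle
    at the true response.  The clamps return to the origin between cycles
    (each cycle restarts at zero displacement), and the stage column holds
    the programmed stage index.  Inverse of the stress/stretch conversion
    up to rounding.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    s0 = config.thickness_mm * config.width_mm
    l0 = config.gauge_length_mm
    n_cycles = config.preconditioning_cycles + 1
    force, disp, stage = [], [], []
    for k in range(1, config.stages + 1):
        target = 1.0 + (config.lambda_max - 1.0) * k / config.stages
        lam = np.linspace(1.0, target, config.n_points)
        base = _clean_stress(config, lam)
        for j in range(n_cycles):
            sig = base * _softening_factor(config, j, n_cycles)
            if config.noise_sd > 0:
                sig = _add_noise(sig, rng, config.noise_sd)
            force.append(sig * s0)
            disp.append((lam - 1.0) * l0)
            stage.append(np.full(lam.size, k - 1, dtype=int))
    return RawTest(
        force_N=np.concatenate(force),
        displacement_mm=np.concatenate(disp),
        stage=np.concatenate(stage),
        meta=config.meta(),
    )


def _group_medians(
    stress_ratio: float, median_unruptured: float = 1.2
) -> tuple[float, float]:
    """(ruptured, unruptured) log-normal medians of ultimate stress [MPa]."""
    return median_unruptured / stress_ratio, median_unruptured


def generate_cohort(
    n_ruptured: int,
    n_unruptured: int,
    stress_ratio: float,
    seed: int,
    *,
    median_unruptured: float = 1.2,
    sigma_log: float = 0.25,
    noise_sd: float = 0.0,
    n_points: int = 120,
    rupture_stretch: tuple[float, float] = (1.8, 2.2),
) -> list[tuple[SpecimenMeta, RawTest]]:
    """Seeded cohort of ruptured and unruptured synthetic specimens.

    Per-specimen ultimate stresses are drawn from log-normal distributions
    whose medians differ by ``stress_ratio`` (unruptured over ruptured);
    each specimen's series is built so the record ends at rupture, i.e. at
    its drawn ultimate stress.
    """
    if n_ruptured < 1 or n_unruptured < 1:
        raise ValidationError("group sizes must be >= 1",
                              fields=["n_ruptured", "n_unruptured"])
    if not stress_ratio > 0:
        raise ValidationError("stress_ratio must be > 0", fields=["stress_ratio"])
    rng = np.random.default_rng(seed)
    m_ruptured, m_unruptured = _group_medians(stress_ratio, median_unruptured)
    plan = [(Status.RUPTURED, m_ruptured, f"SR{i + 1}") for i in range(n_ruptured)]
    plan += [(Status.UNRUPTURED, m_unruptured, f"SU{i + 1}") for i in range(n_unruptured)]
    out = []
    for status, median, specimen_id in plan:
        sigma_ult = median * float(rng.lognormal(0.0, sigma_log))
        lam_r = float(rng.uniform(*rupture_stretch))
        # Neo-Hookean response scaled to reach sigma_ult exactly at lam_r
        c1 = sigma_ult / (2.0 * (lam_r - lam_r**-2))
        config = GeneratorConfig(
            coefficients=CoefficientSet(Model.NEO_HOOKEAN, (c1,)),
            lambda_max=lam_r,
            n_points=n_points,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            specimen_id=specimen_id,
            status=status,
        )
        raw = generate_specimen_series(config)
        meta = SpecimenMeta(
            id=specimen_id,
            status=status,
            thickness_mm=config.thickness_mm,
            width_mm=config.width_mm,
            gauge_length_mm=config.gauge_length_mm,
            ultimate_strain=lam_r - 1.0,
            ultimate_stress_MPa=sigma_ult,
        )
        out.append((meta, raw))
    return out


def paper_like_cohort(
    seed: int = 0,
    model: Model = Model.MR5,
    noise_sd: float = 0.0,
    stages: int = 2,
    preconditioning_cycles: int = 2,
    n_points: int = 120,
) -> list[tuple[SpecimenMeta, RawTest]]:
    """Eight-specimen fixture cohort built from the packaged reference tables.

    Each aneurysm specimen uses its published geometry and rupture status,
    its published coefficients of ``model``, and its published maximum
    valid stretch as the final elongation target.
    """
    rng = np.random.default_rng(seed)
    out = []
    for specimen_id in tables.aneurysm_ids():
        ref_meta = tables.specimen_metadata(specimen_id)
        config = GeneratorConfig(
            coefficients=tables.reference_coefficients(specimen_id, model),
            lambda_max=tables.reference_window(specimen_id, model),
            n_points=n_points,
            noise_sd=noise_sd,
            stages=stages,
            preconditioning_cycles=preconditioning_cycles,
            seed=int(rng.integers(0, 2**31 - 1)),
            specimen_id=specimen_id,
            status=ref_meta.status,
            thickness_mm=ref_meta.thickness_mm,
            width_mm=ref_meta.width_mm,
            gauge_length_mm=tables.DEFAULT_GAUGE_LENGTH_MM,
        )
        raw = generate_specimen_series(config)
        # generated forces assume S0 = thickness * width; keep meta consistent
        meta = replace(
            ref_meta,
            cross_section_area_mm2=ref_meta.thickness_mm * ref_meta.width_mm,
            gauge_length_mm=tables.DEFAULT_GAUGE_LENGTH_MM,
        )
        out.append((meta, raw))
    return out
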