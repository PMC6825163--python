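"""Reading and preprocessing of uniaxial tensile-machine records.

The raw record of one specimen is a sequence of (force [N], crosshead
displacement [mm]) rows, optionally annotated with a programmed stage
index.  Preprocessing proceeds as::

    load_raw_csv -> segment_stages -> split_cycles -> to_curve
                 -> drop_preconditioning -> truncate_at_plateau

yielding stress-stretch curves (nominal stress sigma = F / S0 [MPa],
stretch lambda = 1 + displacement / l0) truncated before the plastic
plateau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyCurveError, FormatError, ParseError, ValidationError

__all__ = [
    "Status",
    "ColumnMap",
    "SpecimenMeta",
    "RawTest",
    "TensileCurve",
    "load_raw_csv",
    "load_metadata_csv",
    "to_curve",
    "segment_stages",
    "split_cycles",
    "drop_preconditioning",
    "truncate_at_plateau",
    "curves_to_frame",
]

log = logging.getLogger(__name__)


class Status(str, Enum):
    RUPTURED = "ruptured"
    UNRUPTURED = "unruptured"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ColumnMap:
    """Configurable header names of the raw CSV dialect."""

    force: str = "force_N"
    displacement: str = "displacement_mm"
    stage: str = "stage"


@dataclass(frozen=True)
class SpecimenMeta:
    """Specimen identity, geometry and (optional) ultimate point.

    ``cross_section_area_mm2`` defaults to thickness * width when omitted.
    """

    id: str
    status: Status
    thickness_mm: float
    width_mm: float
    gauge_length_mm: float
    cross_section_area_mm2: float | None = None
    ultimate_strain: float | None = None
    ultimate_stress_MPa: float | None = None

    def __post_init__(self):
        bad = [
            name
            for name, value in [
                ("thickness_mm", self.thickness_mm),
                ("width_mm", self.width_mm),
                ("gauge_length_mm", self.gauge_length_mm),
            ]
            if not value > 0
        ]
        if self.cross_section_area_mm2 is None:
            object.__setattr__(
                self, "cross_section_area_mm2", self.thickness_mm * self.width_mm
            )
        if not self.cross_section_area_mm2 > 0:
            bad.append("cross_section_area_mm2")
        if bad:
            raise ValidationError("specimen geometry must be positive", fields=bad)
        if not isinstance(self.status, Status):
            object.__setattr__(self, "status", Status(self.status))


def _placeholder_meta(specimen_id: str) -> SpecimenMeta:
    # unit geometry: stress equals force and stretch equals 1 + displacement
    return SpecimenMeta(
        id=specimen_id,
        status=Status.NOT_APPLICABLE,
        thickness_mm=1.0,
        width_mm=1.0,
        gauge_length_mm=1.0,
    )


@dataclass(frozen=True)
class RawTest:
    """One specimen's machine record, in file order."""

    force_N: np.ndarray
    displacement_mm: np.ndarray
    meta: SpecimenMeta
    stage: np.ndarray | None = None

    def __post_init__(self):
        force = np.asarray(self.force_N, dtype=float)
        disp = np.asarray(self.displacement_mm, dtype=float)
        object.__setattr__(self, "force_N", force)
        object.__setattr__(self, "displacement_mm", disp)
        if force.size == 0 or disp.size == 0:
            raise ValidationError("raw record must be non-empty", fields=["rows"])
        if force.shape != disp.shape:
            raise ValidationError("column length mismatch", fields=["rows"])
        if not np.all(np.isfinite(disp)):
            raise ValidationError("displacement must be finite", fields=["displacement_mm"])
        if self.stage is not None:
            stage = np.asarray(self.stage, dtype=int)
            object.__setattr__(self, "stage", stage)
            if stage.shape != force.shape:
                raise ValidationError("stage length mismatch", fields=["stage"])
            if np.any(stage < 0) or np.any(np.diff(stage) < 0):
                raise ValidationError(
                    "stage indices must be non-negative and non-decreasing",
                    fields=["stage"],
                )

    def __len__(self) -> int:
        return int(self.force_N.size)


@dataclass(frozen=True)
class TensileCurve:
    """Paired stretch/stress arrays for one loading stage after preprocessing."""

    stretch: np.ndarray
    stress_MPa: np.ndarray
    specimen_id: str = ""
    stage: int = 0

    def __post_init__(self):
        lam = np.asarray(self.stretch, dtype=float)
        sig = np.asarray(self.stress_MPa, dtype=float)
        object.__setattr__(self, "stretch", lam)
        object.__setattr__(self, "stress_MPa", sig)
        if lam.size != sig.size or lam.size < 2:
            raise ValidationError(
                "curve needs equal-length arrays of at least 2 points", fields=["stretch"]
            )
        if np.any(lam < 1.0):
            raise ValidationError("stretch must be >= 1", fields=["stretch"])
        if np.any(np.diff(lam) <= 0):
            raise ValidationError("stretch must be strictly increasing", fields=["stretch"])
        if not np.all(np.isfinite(sig)):
            raise ValidationError("stress must be finite", fields=["stress_MPa"])

    def __len__(self) -> int:
        return int(self.stretch.size)

    def prefix(self, n: int) -> "TensileCurve":
        return replace(self, stretch=self.stretch[:n], stress_MPa=self.stress_MPa[:n])


def load_raw_csv(
    path: str | Path,
    meta: SpecimenMeta | None = None,
    columns: ColumnMap = ColumnMap(),
) -> RawTest:
    """Read a raw machine CSV into a :class:`RawTest`.

    The file must contain the force and displacement columns of ``columns``;
    the stage column is optional.  A missing column raises
    :class:`FormatError` naming it; a non-numeric cell raises
    :class:`ParseError` citing the file line (header = line 1).
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    for required in (columns.force, columns.displacement):
        if required not in frame.columns:
            raise FormatError(f"{path.name}: missing required column {required!r}")
    has_stage = columns.stage in frame.columns
    parsed = {}
    wanted = [columns.force, columns.displacement] + ([columns.stage] if has_stage else [])
    for name in wanted:
        values = pd.to_numeric(frame[name], errors="coerce")
        bad = values.index[values.isna() & frame[name].notna()]
        if len(bad) > 0:
            # +2: one for the header line, one for 0-based indexing
            raise ParseError(
                f"{path.name}: non-numeric value {frame[name][bad[0]]!r} "
                f"in column {name!r}",
                line=int(bad[0]) + 2,
            )
        if values.isna().any():
            raise ParseError(
                f"{path.name}: empty cell in column {name!r}",
                line=int(values.index[values.isna()][0]) + 2,
            )
        parsed[name] = values.to_numpy(dtype=float)
    if meta is None:
        meta = _placeholder_meta(path.stem)
    return RawTest(
        force_N=parsed[columns.force],
        displacement_mm=parsed[columns.displacement],
        stage=parsed[columns.stage].astype(int) if has_stage else None,
        meta=meta,
    )


_META_COLUMNS = ["id", "status", "thickness_mm", "width_mm", "area_mm2", "gauge_length_mm"]


def load_metadata_csv(path: str | Path) -> dict[str, SpecimenMeta]:
    """Read the sidecar specimen-metadata CSV into a dict keyed by id.

    Optional columns ``ultimate_strain`` and ``ultimate_stress_MPa`` are
    carried through when present.
    """
    path = Path(path)
    frame = pd.read_csv(path, skipinitialspace=True)
    for required in _META_COLUMNS:
        if required not in frame.columns:
            raise FormatError(f"{path.name}: missing required column {required!r}")
    out = {}
    for _, row in frame.iterrows():
        area = row["area_mm2"]
        out[str(row["id"])] = SpecimenMeta(
            id=str(row["id"]),
            status=Status(str(row["status"])),
            thickness_mm=float(row["thickness_mm"]),
            width_mm=float(row["width_mm"]),
            cross_section_area_mm2=None if pd.isna(area) else float(area),
            gauge_length_mm=float(row["gauge_length_mm"]),
            ultimate_strain=_optional(row, "ultimate_strain"),
            ultimate_stress_MPa=_optional(row, "ultimate_stress_MPa"),
        )
    return out


def _optional(row, name):
    if name in row.index and not pd.isna(row[name]):
        return float(row[name])
    return None


def to_curve(raw: RawTest, stage: int | None = None) -> TensileCurve:
    """Convert a raw record to a stress-stretch curve.

    sigma_i = F_i / S0 (N/mm^2 == MPa), lambda_i = 1 + d_i / l0.  Rows with
    lambda < 1 (slack take-up) are dropped and counted in the log; the
    output is sorted by lambda with duplicate lambdas collapsed by
    averaging their stresses.
    """
    s0 = raw.meta.cross_section_area_mm2
    l0 = raw.meta.gauge_length_mm
    lam = 1.0 + raw.displacement_mm / l0
    sig = raw.force_N / s0
    keep = lam >= 1.0
    n_dropped = int(np.count_nonzero(~keep))
    if n_dropped:
        log.info("%s: dropped %d rows with lambda < 1", raw.meta.id, n_dropped)
    lam, sig = lam[keep], sig[keep]
    if lam.size == 0:
        raise EmptyCurveError(f"{raw.meta.id}: all rows dropped (lambda < 1)")
    uniq, inverse = np.unique(lam, return_inverse=True)
    mean_sig = np.bincount(inverse, weights=sig) / np.bincount(inverse)
    if uniq.size < 2:
        raise EmptyCurveError(f"{raw.meta.id}: fewer than 2 distinct stretch values")
    if stage is None:
        stage = int(raw.stage[0]) if raw.stage is not None else 0
    return TensileCurve(uniq, mean_sig, specimen_id=raw.meta.id, stage=stage)


def _split_on_returns(displacement: np.ndarray, return_fraction: float) -> list[int]:
    """Start indices of segments; a new segment begins where displacement
    returns below ``return_fraction`` of the running maximum of the current
    segment (and actually decreases)."""
    starts = [0]
    cur_max = displacement[0]
    for i in range(1, displacement.size):
        d = displacement[i]
        if cur_max > 0 and d < return_fraction * cur_max and d < displacement[i - 1]:
            starts.append(i)
            cur_max = d
        else:
            cur_max = max(cur_max, d)
    return starts


def _slice_raw(raw: RawTest, start: int, stop: int) -> RawTest:
    return RawTest(
        force_N=raw.force_N[start:stop],
        displacement_mm=raw.displacement_mm[start:stop],
        stage=None if raw.stage is None else raw.stage[start:stop],
        meta=raw.meta,
    )


def segment_stages(raw: RawTest, return_fraction: float = 0.02) -> list[RawTest]:
    """Split a record into programmed loading stages.

    Splits on the stage column when present; otherwise starts a new stage
    wherever displacement returns below ``return_fraction`` of the
    preceding stage maximum.  Every row lands in exactly one stage.
    """
    if raw.stage is not None:
        boundaries = np.flatnonzero(np.diff(raw.stage) != 0) + 1
        starts = [0] + boundaries.tolist()
    else:
        starts = _split_on_returns(raw.displacement_mm, return_fraction)
    stops = starts[1:] + [len(raw)]
    return [_slice_raw(raw, a, b) for a, b in zip(starts, stops)]


def split_cycles(raw: RawTest, return_fraction: float = 0.02) -> list[RawTest]:
    """Split one stage into its loading cycles by displacement returns,
    ignoring the stage column."""
    starts = _split_on_returns(raw.displacement_mm, return_fraction)
    stops = starts[1:] + [len(raw)]
    return [_slice_raw(raw, a, b) for a, b in zip(starts, stops)]


def drop_preconditioning(
    curves: list[TensileCurve], n_cycles: int = 2, target_rtol: float = 0.05
) -> list[TensileCurve]:
    """Discard preconditioning cycles within each programmed elongation step.

    Consecutive curves whose elongation targets (max stretch - 1) agree
    within ``target_rtol`` relative are treated as repeats of the same
    step; the first ``min(n_cycles, available - 1)`` of each step are
    dropped, so the last cycle of every step is always kept.
    """
    if n_cycles < 0:
        raise ValidationError("n_cycles must be >= 0", fields=["n_cycles"])
    if not curves:
        return []
    groups: list[list[TensileCurve]] = [[curves[0]]]
    for curve in curves[1:]:
        target = curve.stretch.max() - 1.0
        ref = groups[-1][0].stretch.max() - 1.0
        if abs(target - ref) <= target_rtol * max(ref, 1e-12):
            groups[-1].append(curve)
        else:
            groups.append([curve])
    kept: list[TensileCurve] = []
    for group in groups:
        kept.extend(group[min(n_cycles, len(group) - 1):])
    return kept


def _window_slopes(lam: np.ndarray, sig: np.ndarray, half: int) -> np.ndarray:
    """Least-squares slope of sigma(lambda) over a window centered at each
    point (clipped at the ends)."""
    n = lam.size
    slopes = np.empty(n)
    for i in range(n):
        a, b = max(0, i - half), min(n, i + half + 1)
        x, y = lam[a:b], sig[a:b]
        dx = x - x.mean()
        denom = np.dot(dx, dx)
        slopes[i] = np.dot(dx, y - y.mean()) / denom if denom > 0 else 0.0
    return slopes


def truncate_at_plateau(
    curve: TensileCurve, slope_fraction: float = 0.1, window: int = 5
) -> TensileCurve:
    """Cut the curve before the plastic plateau.

    Scans the centered moving-window slope d(sigma)/d(lambda); the first
    point where the slope drops below ``slope_fraction`` times the maximum
    slope seen so far flags the plateau, and the curve is truncated at the
    left edge of that window (the plateau onset).  Returns the curve
    unchanged when no such point exists.  The result is always a non-empty
    prefix of the input.
    """
    n = len(curve)
    if n < 2 * window:
        raise ValidationError(
            f"curve too short for plateau detection: {n} < {2 * window}",
            fields=["curve"],
        )
    half = window // 2
    slopes = _window_slopes(curve.stretch, curve.stress_MPa, half)
    max_so_far = -np.inf
    for i in range(n):
        max_so_far = max(max_so_far, slopes[i])
        # a plateau is only meaningful after a rising phase
        if max_so_far > 0 and slopes[i] < slope_fraction * max_so_far:
            end = max(i - half, 1)  # keep at least 2 points
            return curve.prefix(end + 1)
    return curve


def curves_to_frame(curves: list[TensileCurve]) -> pd.DataFrame:
    """Tidy frame (specimen_id, stage, lambda, stress_MPa) for CSV export."""
    parts = [
        pd.DataFrame(
            {
                "specimen_id": c.specimen_id,
                "stage": c.stage,
                "lambda": c.stretch,
                "stress_MPa": c.stress_MPa,
            }
        )
        for c in curves
    ]
    return pd.concat(parts, ignore_index=True)
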