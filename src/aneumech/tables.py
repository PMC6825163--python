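"""Packaged reference values: specimen geometry/ultimates, published model
coefficients per specimen, and per-model maximum valid stretch windows.

Loaded once from ``data/printed_tables.json`` and exposed as plain Python
structures keyed by specimen id.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .constitutive import CoefficientSet, Model
from .io_tensile import SpecimenMeta, Status

__all__ = [
    "specimen_metadata",
    "reference_coefficients",
    "reference_window",
    "specimen_ids",
    "aneurysm_ids",
    "ultimates_by_group",
]

#: Gauge length [mm] used when building metadata records from the reference
#: tables (the published tables do not report one).
DEFAULT_GAUGE_LENGTH_MM = 10.0


@lru_cache(maxsize=1)
def _raw() -> dict:
    text = resources.files("aneumech.data").joinpath("printed_tables.json").read_text()
    return json.loads(text)


def specimen_ids() -> list[str]:
    """All specimen ids, in table order (includes the healthy-artery pair)."""
    return [row["id"] for row in _raw()["specimens"]]


def aneurysm_ids() -> list[str]:
    """Ids of the eight aneurysm specimens (with fitted coefficients)."""
    return list(_raw()["coefficients_MPa"].keys())


def specimen_metadata(specimen_id: str) -> SpecimenMeta:
    for row in _raw()["specimens"]:
        if row["id"] == specimen_id:
            return SpecimenMeta(
                id=row["id"],
                status=Status(row["status"]),
                thickness_mm=row["thickness_mm"],
                width_mm=row["width_mm"],
                cross_section_area_mm2=row["area_mm2"],
                gauge_length_mm=DEFAULT_GAUGE_LENGTH_MM,
                ultimate_strain=row["ultimate_strain"],
                ultimate_stress_MPa=row["ultimate_stress_MPa"],
            )
    raise KeyError(f"unknown specimen id {specimen_id!r}")


def reference_coefficients(specimen_id: str, model: Model) -> CoefficientSet:
    """Published coefficients [MPa] of ``model`` for one specimen."""
    table = _raw()["coefficients_MPa"]
    if specimen_id not in table:
        raise KeyError(f"no published coefficients for specimen {specimen_id!r}")
    return CoefficientSet(model, tuple(table[specimen_id][model.value]))


def reference_window(specimen_id: str, model: Model) -> float:
    """Published maximum valid stretch of ``model`` for one specimen."""
    table = _raw()["max_valid_stretch"]
    if specimen_id not in table:
        raise KeyError(f"no published stretch window for specimen {specimen_id!r}")
    return float(table[specimen_id][model.value])


def ultimates_by_group(field: str = "ultimate_stress_MPa") -> dict[str, list[float]]:
    """Ultimate stress or strain values split by rupture status.

    ``field`` is ``"ultimate_stress_MPa"`` or ``"ultimate_strain"``; the
    healthy-artery specimens (status ``not_applicable``) are excluded.
    """
    if field not in ("ultimate_stress_MPa", "ultimate_strain"):
        raise KeyError(f"unknown field {field!r}")
    out: dict[str, list[float]] = {"ruptured": [], "unruptured": []}
    for row in _raw()["specimens"]:
        if row["status"] in out:
            out[row["status"]].append(float(row[field]))
    return out
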