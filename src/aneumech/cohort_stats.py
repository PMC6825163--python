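"""Ultimate-point extraction and the exact Mann-Whitney rank test.

Cohort sizes in this problem are tiny (3 vs 5), so the test is computed by
complete enumeration of all C(n1+n2, n1) group assignments of the observed
ranks — no normal approximation.  Ties are handled with mid-ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError
from .io_tensile import TensileCurve

__all__ = ["UltimatePoint", "MWTestResult", "extract_ultimates", "mann_whitney_exact"]


@dataclass(frozen=True)
class UltimatePoint:
    specimen_id: str
    ultimate_strain: float
    ultimate_stress_MPa: float


@dataclass(frozen=True)
class MWTestResult:
    U: float  # rank statistic of the first group; half-integer under ties
    p_value: float
    alternative: str  # two_sided | greater | less
    method: str = "exact"
    n1: int = 0
    n2: int = 0


def extract_ultimates(curve: TensileCurve) -> UltimatePoint:
    """Ultimate stress (max over the curve) and strain (at the last point).

    Expects the untruncated curve, i.e. the record up to specimen rupture.
    """
    return UltimatePoint(
        specimen_id=curve.specimen_id,
        ultimate_strain=float(curve.stretch[-1] - 1.0),
        ultimate_stress_MPa=float(curve.stress_MPa.max()),
    )


_ALTERNATIVES = ("two_sided", "greater", "less")


def mann_whitney_exact(group_a, group_b, alternative: str = "two_sided") -> MWTestResult:
    """Exact Mann-Whitney U test by complete enumeration.

    ``U`` is the statistic of ``group_a`` (rank-sum form).  The two-sided
    p-value is the null probability of ``|U - n1 n2 / 2|`` at least as
    large as observed; one-sided alternatives use the corresponding tail
    (``greater``: group_a tends to exceed group_b).  Group sizes up to 12
    are supported (enumeration regime).
    """
    if alternative not in _ALTERNATIVES:
        raise ValidationError(
            f"alternative must be one of {_ALTERNATIVES}", fields=["alternative"]
        )
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty", fields=["group_a", "group_b"])
    if n1 > 12 or n2 > 12:
        raise ValidationError("exact enumeration supports group sizes <= 12",
                              fields=["group_a", "group_b"])
    n = n1 + n2
    ranks = rankdata(np.concatenate([a, b]))  # mid-ranks under ties
    offset = n1 * (n1 + 1) / 2.0
    u_obs = float(ranks[:n1].sum() - offset)
    mu = n1 * n2 / 2.0
    eps = 1e-9

    count = 0
    if alternative == "two_sided":
        dev_obs = abs(u_obs - mu)
        for idx in combinations(range(n), n1):
            u = ranks[list(idx)].sum() - offset
            if abs(u - mu) >= dev_obs - eps:
                count += 1
    elif alternative == "greater":
        for idx in combinations(range(n), n1):
            if ranks[list(idx)].sum() - offset >= u_obs - eps:
                count += 1
    else:
        for idx in combinations(range(n), n1):
            if ranks[list(idx)].sum() - offset <= u_obs + eps:
                count += 1
    p = count / comb(n, n1)
    return MWTestResult(
        U=u_obs, p_value=p, alternative=alternative, method="exact", n1=n1, n2=n2
    )
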