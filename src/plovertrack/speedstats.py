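"""Apparent-speed filtering and ground-speed ~ wind-support regressions.

Because the transmitter duty cycle (10 h on / 48 h off) hides short
stopovers, segments with apparent ground speed below 20 km/h are excluded
from flight-speed analyses: a slow apparent speed over a long gap is more
likely an undetected stop than sustained slow flight. The boundary is kept
(speeds below the threshold are excluded, exactly 20.0 km/h is retained).

Each migration period (northward, post-breeding, southward) is modelled
separately with simple ordinary least squares: ground speed (km/h) on wind
support at one pressure level, intercept included, standard error and
two-sided p from the t distribution with n - 2 degrees of freedom and
R-squared equal to the squared Pearson correlation. Wind support enters in
m/s by default; a unit flag converts it to km/h. No multiple-testing
correction is applied across the period x level models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateFitError
from .geodesy import Segment
from .segmentation import Phase, PhaseKind, phase_of
from .windfield import LEVELS, LEVEL_NAMES, SupportRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_SPEED_KMH = 20.0
#: a period is modelled only when it has at least this many segments
DEFAULT_MIN_PERIOD_N = 5

MS_TO_KMH = 3.6


def filter_speed(segments: Sequence[Segment], min_speed: float = DEFAULT_MIN_SPEED_KMH) -> list[Segment]:
    """Drop segments with apparent ground speed below ``min_speed`` km/h."""
    kept = [s for s in segments if s.ground_speed_kmh >= min_speed]
    if len(kept) != len(segments):
        logger.info(
            "filter_speed: excluded %d of %d segments below %.1f km/h",
            len(segments) - len(kept), len(segments), min_speed,
        )
    return kept


@dataclass
class PeriodDataset:
    """Flight segments of one migration period with per-level support."""

    period: PhaseKind
    #: rows of (ground_speed_kmh, {level: support_ms})
    records: list[tuple[float, dict[int, float]]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.records)

    def xy(self, level: int, support_units: str = "m/s") -> tuple[np.ndarray, np.ndarray]:
        x = np.array([r[1][level] for r in self.records], dtype=float)
        y = np.array([r[0] for r in self.records], dtype=float)
        if support_units == "km/h":
            x = x * MS_TO_KMH
        return x, y


def build_period_datasets(
    records: Sequence[SupportRecord],
    phases: Sequence[Phase],
    min_speed: float = DEFAULT_MIN_SPEED_KMH,
) -> dict[PhaseKind, PeriodDataset]:
    """Group annotated flight segments into migration-period datasets.

    A segment belongs to the period containing its mid-time; wintering and
    breeding segments are not flight data and are dropped, as are segments
    below the apparent-speed threshold.
    """
    wanted = (PhaseKind.NORTHWARD, PhaseKind.POST_BREEDING, PhaseKind.SOUTHWARD)
    by_segment: dict[int, tuple[Segment, dict[int, float]]] = {}
    for r in records:
        entry = by_segment.setdefault(id(r.segment), (r.segment, {}))
        entry[1][r.level] = r.support
    out = {k: PeriodDataset(k) for k in wanted}
    for seg, supports in by_segment.values():
        if seg.ground_speed_kmh < min_speed:
            continue
        kind = phase_of(list(phases), seg.mid_time)
        if kind in wanted:
            out[kind].records.append((seg.ground_speed_kmh, supports))
    return out


@dataclass(frozen=True)
class OLSResult:
    """Simple-regression summary for one period x pressure level."""

    coefficient: float
    se: float
    p: float
    r2: float
    n: int
    intercept: float

    def ci95(self) -> tuple[float, float]:
        from scipy import stats

        t = stats.t.ppf(0.975, self.n - 2)
        return self.coefficient - t * self.se, self.coefficient + t * self.se


def ols_fit(x: Sequence[float], y: Sequence[float]) -> OLSResult:
    """OLS of y on x with intercept; errors from the t(n-2) distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise DegenerateFitError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("explanatory variable is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return OLSResult(
        coefficient=float(model.params[1]),
        se=float(model.bse[1]),
        p=float(model.pvalues[1]),
        r2=float(model.rsquared),
        n=int(x.size),
        intercept=float(model.params[0]),
    )


def period_models(
    datasets: Mapping[PhaseKind, PeriodDataset],
    levels: Iterable[int] = LEVELS,
    support_units: str = "m/s",
    min_period_n: int = DEFAULT_MIN_PERIOD_N,
) -> pd.DataFrame:
    """Fit ground speed ~ support per period and level.

    Periods with fewer than ``min_period_n`` segments are skipped with a log
    message (mirroring the post-breeding exclusion for small samples).
    Returns a tidy frame: period, level, coefficient, se, p, r2, n.
    """
    rows = []
    for kind, ds in datasets.items():
        if ds.n < min_period_n:
            logger.info(
                "period_models: %s skipped (n=%d < %d)", kind.value, ds.n, min_period_n
            )
            continue
        for level in levels:
            x, y = ds.xy(level, support_units)
            res = ols_fit(x, y)
            rows.append(
                {
                    "period": kind.value,
                    "level": level,
                    "level_name": LEVEL_NAMES.get(level, str(level)),
                    "coefficient": res.coefficient,
                    "se": res.se,
                    "p": res.p,
                    "r2": res.r2,
                    "n": res.n,
                }
            )
    return pd.DataFrame(
        rows, columns=["period", "level", "level_name", "coefficient", "se", "p", "r2", "n"]
    )
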