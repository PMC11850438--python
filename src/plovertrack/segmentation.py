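"""Stopover detection, stay durations and migration-phase classification.

A stopover is a period in which the bird remains within a bounded area
(default 150 km, roughly the pooled Argos error plus local foraging range)
for more than a minimum duration (default 2 days), preceded and followed by
directional movements larger than that radius. With a transmitter duty
cycle of 10 h on / 48 h off, stays shorter than the off period cannot be
resolved, so durations are span-based: the gap between two on-windows
counts toward a stay when its bounding fixes sit inside the same cluster.

The detection algorithm is greedy and sequential: a candidate cluster opens
at the current fix and absorbs subsequent fixes while each lies within
``radius_km`` of the running mean-coordinate centroid; the cluster closes
at the first fix that falls outside. Closed clusters are accepted as
stopovers when their first-to-last fix span exceeds ``min_days``;
consecutive accepted clusters closer than ``radius_km`` are merged. The
procedure is deterministic and idempotent.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import DomainError
from .geodesy import great_circle_km, initial_bearing
from .trackio import Fix, Track

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_KM = 150.0
DEFAULT_MIN_DAYS = 2.0
#: minimum residence (days) for a stay to qualify as a breeding attempt
DEFAULT_BREEDING_MIN_DAYS = 46.0


@dataclass
class Stopover:
    """A detected stationary cluster."""

    arrival: pd.Timestamp
    departure: pd.Timestamp
    centroid_lat: float
    centroid_lon: float
    n_fixes: int
    label: str = ""

    @property
    def duration_days(self) -> int:
        return duration_days(self.arrival, self.departure)

    @property
    def span_days(self) -> float:
        return (self.departure - self.arrival).total_seconds() / 86400.0


class PhaseKind(str, Enum):
    WINTERING = "WINTERING"
    NORTHWARD = "NORTHWARD"
    BREEDING = "BREEDING"
    POST_BREEDING = "POST_BREEDING"
    SOUTHWARD = "SOUTHWARD"


@dataclass
class Phase:
    kind: PhaseKind
    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def duration_days(self) -> int:
        return duration_days(self.start, self.end)


def duration_days(arrival, departure) -> int:
    """Whole-day calendar difference, departure date minus arrival date."""
    a = arrival.date() if isinstance(arrival, (pd.Timestamp, dt.datetime)) else arrival
    d = departure.date() if isinstance(departure, (pd.Timestamp, dt.datetime)) else departure
    days = (d - a).days
    if days < 0:
        raise DomainError("departure precedes arrival")
    return days


def _cluster_fixes(fixes: list[Fix], radius_km: float) -> list[list[Fix]]:
    """Greedy sequential clustering around a running mean centroid."""
    clusters: list[list[Fix]] = []
    i, n = 0, len(fixes)
    while i < n:
        members = [fixes[i]]
        clat, clon = fixes[i].lat, fixes[i].lon
        j = i + 1
        while j < n and great_circle_km(clat, clon, fixes[j].lat, fixes[j].lon) <= radius_km:
            members.append(fixes[j])
            clat = float(np.mean([m.lat for m in members]))
            clon = float(np.mean([m.lon for m in members]))
            j += 1
        clusters.append(members)
        i = j
    return clusters


def _to_stopover(members: list[Fix]) -> Stopover:
    return Stopover(
        arrival=members[0].timestamp,
        departure=members[-1].timestamp,
        centroid_lat=float(np.mean([m.lat for m in members])),
        centroid_lon=float(np.mean([m.lon for m in members])),
        n_fixes=len(members),
    )


def detect_stopovers(
    track: Track,
    radius_km: float = DEFAULT_RADIUS_KM,
    min_days: float = DEFAULT_MIN_DAYS,
) -> list[Stopover]:
    """Detect stationary clusters occupied for more than ``min_days``.

    The track should already be filtered to stationary-quality classes.
    Returns stopovers ordered by arrival; may be empty.
    """
    if len(track) < 2:
        return []
    clusters = _cluster_fixes(track.fixes, radius_km)
    accepted = [
        m
        for m in clusters
        if (m[-1].timestamp - m[0].timestamp).total_seconds() / 86400.0 > min_days
    ]
    # merge consecutive accepted clusters not separated by a directional
    # movement larger than the clustering radius
    merged: list[list[Fix]] = []
    for m in accepted:
        if merged:
            prev = _to_stopover(merged[-1])
            cur = _to_stopover(m)
            if (
                great_circle_km(
                    prev.centroid_lat, prev.centroid_lon, cur.centroid_lat, cur.centroid_lon
                )
                <= radius_km
            ):
                merged[-1] = merged[-1] + m
                continue
        merged.append(m)
    return [_to_stopover(m) for m in merged]


def _is_southward(bearing: float, halfwidth_deg: float) -> bool:
    return abs(((bearing - 180.0) + 180.0) % 360.0 - 180.0) <= halfwidth_deg


def assign_phases(
    stopovers: list[Stopover],
    track: Track,
    breeding_min_days: float = DEFAULT_BREEDING_MIN_DAYS,
    southward_halfwidth_deg: float = 45.0,
    southward_onset: pd.Timestamp | None = None,
) -> list[Phase]:
    """Split a full migration cycle into contiguous phases.

    The stationary period with duration above ``breeding_min_days`` (the
    time needed for a successful breeding attempt) and the highest latitude
    is labelled BREEDING. NORTHWARD runs from the wintering departure to
    the breeding arrival; POST_BREEDING from the breeding departure to the
    onset of sustained southward movement; SOUTHWARD from that onset to the
    wintering arrival. The onset is the departure of the first post-breeding
    site whose leg to the next site heads within ``southward_halfwidth_deg``
    of due south, overridable with an explicit ``southward_onset`` time.

    First/last clusters containing the track endpoints are treated as the
    wintering site (they contribute WINTERING phases, not stopovers).
    """
    if not stopovers:
        logger.warning("assign_phases: no stopovers; no phases derivable")
        return []

    sites = list(stopovers)
    phases: list[Phase] = []

    origin = sites[0] if sites[0].arrival <= track.start else None
    terminal = sites[-1] if len(sites) > 1 and sites[-1].departure >= track.end else None
    depart = origin.departure if origin is not None else track.start
    arrive = terminal.arrival if terminal is not None else track.end
    migratory = [s for s in sites if s is not origin and s is not terminal]

    breeders = [s for s in migratory if s.duration_days > breeding_min_days]
    if not breeders:
        logger.warning(
            "assign_phases: no stay exceeds %.0f days; BREEDING phase not assigned",
            breeding_min_days,
        )
        if origin is not None:
            phases.append(Phase(PhaseKind.WINTERING, origin.arrival, depart))
        phases.append(Phase(PhaseKind.NORTHWARD, depart, arrive))
        return phases

    breeding = max(breeders, key=lambda s: s.centroid_lat)
    post = [s for s in migratory if s.arrival > breeding.departure]

    if southward_onset is None:
        southward_onset = post[-1].departure if post else breeding.departure
        chain = [breeding] + post
        for cur, nxt in zip(chain, chain[1:] + [None]):
            if nxt is not None:
                to = (nxt.centroid_lat, nxt.centroid_lon)
            elif terminal is not None:
                to = (terminal.centroid_lat, terminal.centroid_lon)
            else:
                to = (track.fixes[-1].lat, track.fixes[-1].lon)
            if (cur.centroid_lat, cur.centroid_lon) == to:
                continue
            brg = initial_bearing(cur.centroid_lat, cur.centroid_lon, to[0], to[1])
            if _is_southward(brg, southward_halfwidth_deg):
                southward_onset = cur.departure
                break

    if origin is not None:
        phases.append(Phase(PhaseKind.WINTERING, origin.arrival, depart))
    phases.append(Phase(PhaseKind.NORTHWARD, depart, breeding.arrival))
    phases.append(Phase(PhaseKind.BREEDING, breeding.arrival, breeding.departure))
    phases.append(Phase(PhaseKind.POST_BREEDING, breeding.departure, southward_onset))
    phases.append(Phase(PhaseKind.SOUTHWARD, southward_onset, arrive))
    if terminal is not None:
        phases.append(Phase(PhaseKind.WINTERING, arrive, terminal.departure))
    return phases


def phase_of(phases: list[Phase], when: pd.Timestamp) -> PhaseKind | None:
    """Phase containing a time instant (phases are contiguous, end-exclusive)."""
    for i, p in enumerate(phases):
        if p.start <= when < p.end or (i == len(phases) - 1 and when == p.end):
            return p.kind
    return None


_TABLE_COLUMNS = [
    "arrival_date",
    "departure_date",
    "migration_status",
    "duration_days",
    "lat",
    "lon",
]


def stopover_table(stopovers: list[Stopover], phases: list[Phase]) -> pd.DataFrame:
    """Tabulate stopovers in timetable order with their migration status.

    Wintering endpoint clusters become 'Departed' / 'Arrived' rows carrying
    only the relevant date; migratory stopovers are labelled 'NW Stopover',
    'Breeding' or 'SW Stopover' according to the phase they fall in.
    """
    rows = []
    wintering = [p for p in phases if p.kind is PhaseKind.WINTERING]
    breeding = next((p for p in phases if p.kind is PhaseKind.BREEDING), None)
    for s in stopovers:
        if wintering and s.departure <= wintering[0].end:
            rows.append(
                {
                    "arrival_date": None,
                    "departure_date": s.departure.date(),
                    "migration_status": "Departed",
                    "duration_days": None,
                    "lat": round(s.centroid_lat, 2),
                    "lon": round(s.centroid_lon, 2),
                }
            )
            continue
        if len(wintering) > 1 and s.arrival >= wintering[-1].start:
            rows.append(
                {
                    "arrival_date": s.arrival.date(),
                    "departure_date": None,
                    "migration_status": "Arrived",
                    "duration_days": None,
                    "lat": round(s.centroid_lat, 2),
                    "lon": round(s.centroid_lon, 2),
                }
            )
            continue
        if breeding is not None and s.arrival >= breeding.start and s.departure <= breeding.end:
            status = "Breeding"
        elif breeding is not None and s.arrival >= breeding.end:
            status = "SW Stopover"
        else:
            status = "NW Stopover"
        rows.append(
            {
                "arrival_date": s.arrival.date(),
                "departure_date": s.departure.date(),
                "migration_status": status,
                "duration_days": s.duration_days,
                "lat": round(s.centroid_lat, 2),
                "lon": round(s.centroid_lon, 2),
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
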