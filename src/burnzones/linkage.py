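"""Cross-source entity resolution for wildfire incident records.

Matches records across the three incident flavors with a three-part rule —
county overlap, ignition dates within a configurable window, and a
Jaro-Winkler name distance cap — then merges connected components of the
match graph into canonical fires with precedence-based conflict resolution
(the California annual-report flavor wins on harm counts and dates).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from .records import (
    SOURCE_ORDER,
    CanonicalFire,
    EventCluster,
    MatchEvidence,
    SourceEventRecord,
    UNRESOLVED,
)

# ---------------------------------------------------------------------------
# string distance
# ---------------------------------------------------------------------------


def jaro_similarity(a: str, b: str) -> float:
    """Plain Jaro similarity.

    Matching window is ``floor(max(|a|,|b|)/2) - 1``; transpositions are
    half the number of out-of-order matched characters.
    """
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    a_matched = [False] * la
    b_matched = [False] * lb
    m = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not b_matched[j] and b[j] == ca:
                a_matched[i] = b_matched[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    a_common = [a[i] for i in range(la) if a_matched[i]]
    b_common = [b[j] for j in range(lb) if b_matched[j]]
    half_transpositions = sum(ca != cb for ca, cb in zip(a_common, b_common))
    t = half_transpositions / 2
    return (m / la + m / lb + (m - t) / m) / 3


def jw_distance(a: str, b: str, prefix_factor: float = 0.1) -> float:
    """Jaro-Winkler distance: 1 - (jaro + l * p * (1 - jaro)).

    ``l`` is the common-prefix length capped at 4; the prefix boost is
    applied unconditionally (no boost threshold), matching the common
    default of the R ``stringdist`` routine. Two empty strings are distance
    0 by convention.
    """
    if a == b:
        return 0.0
    jaro = jaro_similarity(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix == 4:
            break
        prefix += 1
    return 1.0 - (jaro + prefix * prefix_factor * (1.0 - jaro))


# ---------------------------------------------------------------------------
# pair matching and clustering
# ---------------------------------------------------------------------------


@dataclass
class MatchConfig:
    jw_max: float = 0.25
    prefix_factor: float = 0.1
    date_window_days: int = 30
    waive_missing_dates: bool = True
    block_by_state: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.jw_max <= 1.0:
            raise ValueError("jw_max must be in [0, 1]")
        if self.date_window_days < 0:
            raise ValueError("date_window_days must be >= 0")


def name_distance(
    names1: Sequence[str], names2: Sequence[str], prefix_factor: float = 0.1
) -> float:
    """Minimum Jaro-Winkler distance over all name-pair combinations."""
    return min(
        jw_distance(n1, n2, prefix_factor) for n1 in names1 for n2 in names2
    )


def _resolved_counties(rec: SourceEventRecord) -> set[tuple[str, str]]:
    return {(s, c) for s, c in rec.counties if c != UNRESOLVED}


def pair_match(
    e1: SourceEventRecord,
    e2: SourceEventRecord,
    cfg: Optional[MatchConfig] = None,
) -> tuple[bool, MatchEvidence]:
    """Do two cleaned records describe the same fire?

    True iff their resolved county sets intersect, their match dates are
    within the window (or one side lacks a date and waiving is enabled),
    and the minimum name distance is at or below the cap.
    """
    cfg = cfg or MatchConfig()
    shared = tuple(sorted(_resolved_counties(e1) & _resolved_counties(e2)))
    dist = name_distance([e1.clean_name], [e2.clean_name], cfg.prefix_factor)

    d1, d2 = e1.match_date(), e2.match_date()
    gap: Optional[int] = None
    waived = False
    if d1 is not None and d2 is not None:
        gap = abs((d1 - d2).days)
        date_ok = gap <= cfg.date_window_days
    else:
        waived = cfg.waive_missing_dates
        date_ok = waived

    ok = bool(shared) and date_ok and dist <= cfg.jw_max
    return ok, MatchEvidence(
        name_distance=dist,
        date_gap_days=gap,
        shared_counties=shared,
        date_waived=waived,
    )


def _blocks(
    records: Sequence[SourceEventRecord], cfg: MatchConfig
) -> dict[str, list[int]]:
    if not cfg.block_by_state:
        return {"": list(range(len(records)))}
    blocks: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        states = rec.states or ("",)
        for state in states:  # multi-state records appear in every block
            blocks.setdefault(state, []).append(i)
    return blocks


def cluster_events(
    tables: Iterable[Sequence[SourceEventRecord]],
    cfg: Optional[MatchConfig] = None,
) -> list[EventCluster]:
    """Connected components of the pair-match graph over all records.

    Candidate pairs are generated within state blocks; the output is a
    deterministic partition of every input record (singletons included),
    invariant to input row order.
    """
    cfg = cfg or MatchConfig()
    records = [r for table in tables for r in table]
    records.sort(key=lambda r: r.key)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(records)))
    edge_evidence: dict[tuple[int, int], MatchEvidence] = {}
    for block in _blocks(records, cfg).values():
        for a_pos, i in enumerate(block):
            for j in block[a_pos + 1 :]:
                if (i, j) in edge_evidence:
                    continue
                ok, evidence = pair_match(records[i], records[j], cfg)
                if ok:
                    graph.add_edge(i, j)
                    edge_evidence[(i, j)] = evidence

    clusters = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        edges = tuple(
            (records[i].key, records[j].key, edge_evidence[(i, j)])
            for (i, j) in sorted(edge_evidence)
            if i in component and j in component
        )
        clusters.append(
            EventCluster(
                members=tuple(records[i].key for i in members), edges=edges
            )
        )
    clusters.sort(key=lambda c: c.members[0])
    return clusters


# ---------------------------------------------------------------------------
# conflict resolution
# ---------------------------------------------------------------------------


@dataclass
class ResolveConfig:
    """Precedence and complex-aggregation knobs.

    ``complex_mode`` controls how multiple distinct member fires reported by
    one source combine: "sum" (default) or "max". Across sources, the
    precedence source wins outright and other sources are reduced by max,
    so a member appearing in several sources is never double-counted.
    """

    precedence_source: str = "redbooks"
    complex_mode: str = "sum"


_COUNT_FIELDS = (
    "civilian_fatalities",
    "total_fatalities",
    "destroyed_structures",
    "damaged_structures",
    "combined_damaged_destroyed",
)
_DESCRIPTIVE_FIELDS = (
    "threatened_structures",
    "injuries",
    "evacuated",
    "estimated_cost",
)


def _per_source_total(
    members: Sequence[SourceEventRecord], source: str, attr: str, mode: str
):
    values = [
        getattr(r, attr)
        for r in members
        if r.source == source and getattr(r, attr) is not None
    ]
    if not values:
        return None
    return sum(values) if mode == "sum" else max(values)


def _resolve_count(
    members: Sequence[SourceEventRecord], attr: str, cfg: ResolveConfig
):
    preferred = _per_source_total(
        members, cfg.precedence_source, attr, cfg.complex_mode
    )
    if preferred is not None:
        return preferred
    others = [
        total
        for source in sorted({r.source for r in members}, key=lambda s: SOURCE_ORDER.get(s, 9))
        if source != cfg.precedence_source
        and (total := _per_source_total(members, source, attr, cfg.complex_mode))
        is not None
    ]
    return max(others) if others else None


def resolve_cluster(
    cluster: EventCluster,
    records_by_key: dict[tuple[str, str], SourceEventRecord],
    fire_id: str,
    cfg: Optional[ResolveConfig] = None,
) -> CanonicalFire:
    """Merge one cluster into a canonical fire.

    Harm counts: the precedence source's total wins when present, otherwise
    the maximum across the other sources' totals. Ignition date: precedence
    source when present, else earliest across members; containment: latest.
    FMAG is true if any member came from the FMAG flavor. All names and all
    state-county combinations are retained. Resolution is a pure function of
    the stored members, so canonical fields are re-derivable.
    """
    cfg = cfg or ResolveConfig()
    members = [records_by_key[k] for k in cluster.members]
    if not members:
        raise ValueError("empty cluster")

    names = tuple(sorted({r.clean_name for r in members if r.clean_name}))
    counties = tuple(
        sorted({pair for r in members for pair in r.counties})
    )

    pref = [r for r in members if r.source == cfg.precedence_source]
    pref_ignitions = [r.ignition_date for r in pref if r.ignition_date]
    all_ignitions = [r.ignition_date for r in members if r.ignition_date]
    ignition = (
        min(pref_ignitions) if pref_ignitions
        else (min(all_ignitions) if all_ignitions else None)
    )
    pref_containments = [r.containment_date for r in pref if r.containment_date]
    all_containments = [r.containment_date for r in members if r.containment_date]
    containment = (
        max(pref_containments) if pref_containments
        else (max(all_containments) if all_containments else None)
    )
    if ignition is not None and containment is not None:
        containment = max(containment, ignition)

    counts = {
        attr: _resolve_count(members, attr, cfg) for attr in _COUNT_FIELDS
    }
    descriptives = {}
    for attr in _DESCRIPTIVE_FIELDS:
        values = [getattr(r, attr) for r in members if getattr(r, attr) is not None]
        descriptives[attr] = max(values) if values else None

    fmag_members = [r for r in members if r.source == "fmag"]
    declaration_dates = [
        r.fmag_declaration_date for r in fmag_members if r.fmag_declaration_date
    ]

    origins = [
        r.origin
        for r in sorted(members, key=lambda r: (SOURCE_ORDER.get(r.source, 9), r.key))
        if r.origin is not None
    ]

    pref_areas = [r.area_acres for r in pref if r.area_acres is not None]
    all_areas = [r.area_acres for r in members if r.area_acres is not None]
    if cfg.complex_mode == "sum" and len({r.source_id for r in pref}) > 1:
        area = sum(pref_areas) if pref_areas else None
    else:
        area = (
            max(pref_areas) if pref_areas
            else (max(all_areas) if all_areas else None)
        )

    years = [r.year for r in members if r.year is not None]

    return CanonicalFire(
        fire_id=fire_id,
        names=names,
        counties=counties,
        ignition_date=ignition,
        containment_date=containment,
        year=ignition.year if ignition else (min(years) if years else None),
        fmag=bool(fmag_members),
        fmag_declaration_date=min(declaration_dates) if declaration_dates else None,
        origin=origins[0] if origins else None,
        area_acres=area,
        shared_ids=tuple(
            sorted({r.shared_id for r in members if r.shared_id})
        ),
        members=cluster.members,
        **counts,
        **descriptives,
    )


def resolve_all(
    clusters: Sequence[EventCluster],
    records: Sequence[SourceEventRecord],
    cfg: Optional[ResolveConfig] = None,
) -> list[CanonicalFire]:
    by_key = {r.key: r for r in records}
    return [
        resolve_cluster(cluster, by_key, f"F{i:06d}", cfg)
        for i, cluster in enumerate(clusters)
    ]
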