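"""Greedy sort-based consensus alignment.

The alignment loop works on a mass-sorted string list.  Contiguous runs of
records within a doubled mass tolerance of the run's minimum form
M-clusters; each M-cluster is copied to a retention-time-sorted list whose
maximal runs within a doubled RT tolerance form R-clusters.  An R-cluster
becomes a consensus when, after per-map collision resolution against the
midrange centre, its membership has exactly the size currently targeted by
the coverage-maximization loop (full map coverage first, then one less,
down to singletons).  Accepted members are whitened out of the string list;
rejected features stay in the pool and are rescanned on the next pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

from .core import (
    Consensus,
    ContractError,
    Dataset,
    IntegrityError,
    ResolutionSet,
)
from .dav import (
    StringList,
    decode,
    encode,
    from_features,
    infer_layout,
    sort_strings,
    whiten,
)


@dataclass(frozen=True)
class MCluster:
    """Contiguous run ``[start, stop)`` of mass-sorted records."""

    start: int
    stop: int
    min_mass: float
    max_mass: float


@dataclass(frozen=True)
class RCluster:
    """Contiguous run ``[start, stop)`` of an rt-sorted per-cluster list."""

    start: int
    stop: int
    min_rt: float
    max_rt: float


@dataclass(frozen=True)
class PassLog:
    stage: int
    pass_index: int
    n_clusters: int
    n_accepted: int


@dataclass
class AlignmentResult:
    """All consensuses (singletons included) plus the per-size count vector."""

    consensuses: list[Consensus]
    n_maps: int
    passes: list[PassLog] = field(default_factory=list)

    @property
    def c(self) -> list[int]:
        counts = [0] * self.n_maps
        for cons in self.consensuses:
            counts[cons.size - 1] += 1
        return counts

    @property
    def n_features(self) -> int:
        return sum(c.size for c in self.consensuses)

    def validate(self, dataset: Dataset, res: ResolutionSet) -> None:
        """Assert conservation, collision-freedom and the resolution condition."""
        seen: set[int] = set()
        by_uid = dataset.by_uid
        for cons in self.consensuses:
            maps = set()
            for uid in cons.members:
                if uid in seen:
                    raise IntegrityError(f"feature {uid} duplicated across consensuses")
                seen.add(uid)
                f = by_uid[uid]
                if f.map_index in maps:
                    raise IntegrityError(
                        f"consensus contains two features from map {f.map_index}"
                    )
                maps.add(f.map_index)
                if not res.rt_close(f.rt, cons.centre_rt) or not res.mass_close(
                    f.mz, cons.centre_mz
                ):
                    raise IntegrityError(
                        f"feature {uid} violates the resolution condition"
                    )
        if seen != set(by_uid):
            raise IntegrityError("alignment omits features")


class _Member(NamedTuple):
    uid: int
    rt: float
    mz: float
    map_index: int
    s_pos: int  # position in the S list at scan time


def _leading_values(sl: StringList) -> list[float]:
    key = "mz" if sl.leading == "mass" else "rt"
    return [decode(r, leading=sl.leading)[key] for r in sl.records[: sl.n_active()]]


def scan_m_clusters(sorted_s: StringList, res: ResolutionSet) -> list[MCluster]:
    """Greedy maximal mass runs over the un-whitened prefix of a sorted S list.

    Each cluster extends while the candidate mass stays within twice the
    mass tolerance (evaluated at the candidate mass; see
    ``ResolutionSet.in_mass_window``) of the cluster's minimum; the record
    after the cluster starts the next one, giving a disjoint cover.
    """
    if sorted_s.leading != "mass":
        raise ContractError("scan_m_clusters requires a mass-leading list")
    masses = _leading_values(sorted_s)
    if any(masses[i] > masses[i + 1] for i in range(len(masses) - 1)):
        raise ContractError("S list is not sorted by mass")
    return [
        MCluster(start, stop, masses[start], masses[stop - 1])
        for start, stop in _greedy_runs(masses, res.in_mass_window)
    ]


def scan_r_clusters(sorted_r: StringList, res: ResolutionSet) -> list[RCluster]:
    """Greedy maximal rt runs (doubled RT tolerance) over a sorted R list."""
    if sorted_r.leading != "rt":
        raise ContractError("scan_r_clusters requires an rt-leading list")
    rts = _leading_values(sorted_r)
    if any(rts[i] > rts[i + 1] for i in range(len(rts) - 1)):
        raise ContractError("R list is not sorted by retention time")
    return [
        RCluster(start, stop, rts[start], rts[stop - 1])
        for start, stop in _greedy_runs(rts, res.in_rt_window)
    ]


def _greedy_runs(values: list[float], in_window) -> list[tuple[int, int]]:
    runs = []
    i = 0
    n = len(values)
    while i < n:
        j = i
        while j + 1 < n and in_window(values[j + 1], values[i]):
            j += 1
        runs.append((i, j + 1))
        i = j + 1
    return runs


def build_r_list(sorted_s: StringList, cluster: MCluster) -> StringList:
    """Copy an M-cluster into an rt-leading list with an origin column.

    The origin field of each record holds its absolute position in the S
    list, so identities survive re-sorting by retention time.
    """
    if cluster.stop <= cluster.start:
        raise ContractError("empty M-cluster")
    origin_width = max(1, len(str(len(sorted_s.records) - 1)))
    records = []
    for p in range(cluster.start, cluster.stop):
        d = decode(sorted_s.records[p], leading="mass")
        records.append(
            _r_record(d, sorted_s, origin=p, origin_width=origin_width)
        )
    return StringList(
        records=tuple(records), leading="rt", layouts=sorted_s.layouts, uids=None
    )


def _r_record(d: dict, sl: StringList, origin: int, origin_width: int) -> str:
    from .core import Feature

    f = Feature(
        uid=0,
        rt=d["rt"],
        mz=d["mz"],
        map_index=d["map_index"],
        intensity=d["intensity"],
    )
    return encode(f, sl.layouts, leading="rt", origin=origin, origin_width=origin_width)


def consensus_centre(members: Sequence) -> tuple[float, float]:
    """Midrange centre: midpoint of (min, max) retention time and mass."""
    if not members:
        raise ContractError("cannot centre an empty member set")
    rts = [m.rt for m in members]
    mzs = [m.mz for m in members]
    return (min(rts) + max(rts)) / 2.0, (min(mzs) + max(mzs)) / 2.0


def _normalized_distance(m, centre_rt: float, centre_mz: float, res: ResolutionSet) -> float:
    dr = (m.rt - centre_rt) / res.delta_r
    dm = (m.mz - centre_mz) / res.delta_m(centre_mz)
    return math.hypot(dr, dm)


def _refine(members: list[_Member], res: ResolutionSet) -> tuple[list[_Member], tuple[float, float]]:
    """Iterate collision resolution + resolution filtering to a fixed point.

    Per map, the feature closest (normalized distance) to the current
    midrange centre is retained; retained members must satisfy the
    resolution condition against that centre.  Membership only shrinks, so
    the loop terminates in at most ``len(members)`` rounds.
    """
    current = list(members)
    while True:
        centre_rt, centre_mz = consensus_centre(current)
        best: dict[int, tuple[float, int, _Member]] = {}
        for rank, m in enumerate(current):
            d = _normalized_distance(m, centre_rt, centre_mz, res)
            key = (d, rank)
            if m.map_index not in best or key < best[m.map_index][:2]:
                best[m.map_index] = (d, rank, m)
        kept = [m for (_, _, m) in sorted(best.values(), key=lambda t: t[1])]
        kept = [
            m
            for m in kept
            if res.rt_close(m.rt, centre_rt) and res.mass_close(m.mz, centre_mz)
        ]
        if kept == current or not kept:
            return kept, (centre_rt, centre_mz)
        current = kept


def form_consensus(
    members: Sequence[_Member], target_size: int, res: ResolutionSet
) -> tuple[Consensus, list[int]] | None:
    """Attempt a size-``target_size`` consensus from an R-cluster's members.

    Returns ``(consensus, s_positions_of_accepted_members)`` on acceptance,
    ``None`` on rejection (rejected features stay in the pool for later
    passes).
    """
    if not 1 <= target_size:
        raise ContractError("target size must be >= 1")
    refined, _ = _refine(list(members), res)
    if len(refined) != target_size:
        return None
    centre_rt, centre_mz = consensus_centre(refined)
    cons = Consensus(
        centre_rt=centre_rt,
        centre_mz=centre_mz,
        members=frozenset(m.uid for m in refined),
    )
    return cons, [m.s_pos for m in refined]


def _cluster_members(sorted_s: StringList, sorted_r: StringList, rc: RCluster) -> list[_Member]:
    members = []
    for p in range(rc.start, rc.stop):
        d = decode(sorted_r.records[p], leading="rt")
        origin = d["origin"]
        members.append(
            _Member(
                uid=sorted_s.uids[origin],
                rt=d["rt"],
                mz=d["mz"],
                map_index=d["map_index"],
                s_pos=origin,
            )
        )
    return members


def align(dataset: Dataset, res: ResolutionSet, layouts=None) -> AlignmentResult:
    """Run the full alignment loop over a dataset.

    For target size n = K down to 2: repeatedly sort the string list
    (whitened records sink to the bottom), scan M-clusters, scan R-clusters
    within each, attempt size-n consensuses and whiten accepted members,
    until a pass accepts nothing.  Every feature still unaligned at the end
    becomes a singleton consensus.  Deterministic: no randomness anywhere.
    """
    result = AlignmentResult(consensuses=[], n_maps=max(dataset.n_maps, 1))
    if dataset.n_features == 0:
        result.n_maps = dataset.n_maps
        return result
    if layouts is None:
        layouts = infer_layout(dataset)
    s_list = from_features(dataset.features, layouts, leading="mass")
    for stage in range(dataset.n_maps, 1, -1):
        pass_index = 0
        while True:
            s_list = sort_strings(s_list)
            mclusters = scan_m_clusters(s_list, res)
            accepted: list[tuple[Consensus, list[int]]] = []
            for mc in mclusters:
                if mc.stop - mc.start < stage:
                    continue  # too few features to reach the target size
                r_list = sort_strings(build_r_list(s_list, mc))
                for rc in scan_r_clusters(r_list, res):
                    if rc.stop - rc.start < stage:
                        continue
                    outcome = form_consensus(
                        _cluster_members(s_list, r_list, rc), stage, res
                    )
                    if outcome is not None:
                        accepted.append(outcome)
            pass_index += 1
            result.passes.append(
                PassLog(stage, pass_index, len(mclusters), len(accepted))
            )
            if not accepted:
                break
            positions = []
            for cons, s_positions in accepted:
                result.consensuses.append(cons)
                positions.extend(s_positions)
            s_list = whiten(s_list, positions)
    # Singleton stage: every remaining feature is its own consensus.
    s_list = sort_strings(s_list)
    for p in range(s_list.n_active()):
        d = decode(s_list.records[p], leading="mass")
        result.consensuses.append(
            Consensus(
                centre_rt=d["rt"],
                centre_mz=d["mz"],
                members=frozenset({s_list.uids[p]}),
            )
        )
    result.validate(dataset, res)
    return result
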