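"""Domain types, tolerance model and feature-table I/O.

A *feature* is one detected LC-MS peak: retention time (minutes), mass
(Daltons), the index of the map (spectrum) it was detected in, and its
intensity.  A *consensus* is a predicted metabolite: a collision-free group
of features drawn from distinct maps that all fall within the retention-time
and mass tolerances of a common centre.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd


class FormatError(ValueError):
    """Input file does not have the expected columns/layout."""


class ValidationError(ValueError):
    """A value violates a domain invariant (e.g. non-positive mass)."""


class IntegrityError(ValueError):
    """An internal consistency contract is broken (duplication/omission)."""


class ContractError(ValueError):
    """A function precondition is violated by the caller."""


class ConfigurationError(ValueError):
    """Invalid run configuration."""


#: Relative slack applied to tolerance comparisons to absorb float rounding
#: in midrange arithmetic.  Far below any physically meaningful scale.
REL_EPS = 1e-9


@dataclass(frozen=True)
class Feature:
    """One detected peak.

    Attributes
    ----------
    uid : int
        Stable identity, assigned at load time, unique within a dataset.
    rt : float
        Retention time in minutes, > 0.
    mz : float
        Mass in Daltons, > 0.
    map_index : int
        1-based spectrum identifier.
    intensity : float
        Non-negative abundance.
    """

    uid: int
    rt: float
    mz: float
    map_index: int
    intensity: float

    def __post_init__(self) -> None:
        if not self.rt > 0:
            raise ValidationError(f"feature {self.uid}: rt must be > 0, got {self.rt}")
        if not self.mz > 0:
            raise ValidationError(f"feature {self.uid}: mz must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise ValidationError(
                f"feature {self.uid}: intensity must be >= 0, got {self.intensity}"
            )
        if self.map_index < 1:
            raise ValidationError(
                f"feature {self.uid}: map_index must be >= 1, got {self.map_index}"
            )


@dataclass(frozen=True)
class ResolutionSet:
    """Retention-time and mass tolerances.

    The RT tolerance ``delta_r`` is a constant (minutes).  The mass
    tolerance is proportional to the mass in ``ppm`` mode
    (``eps_ppm * m * 1e-6``), or a constant number of Daltons in
    ``fixed_da`` mode.
    """

    delta_r: float = 0.3
    eps_ppm: float = 10.0
    mode: str = "ppm"
    delta_m_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("ppm", "fixed_da"):
            raise ConfigurationError(f"unknown mass tolerance mode {self.mode!r}")
        if not self.delta_r > 0:
            raise ConfigurationError("delta_r must be > 0")
        if self.mode == "ppm" and not self.eps_ppm > 0:
            raise ConfigurationError("eps_ppm must be > 0 in ppm mode")
        if self.mode == "fixed_da" and (
            self.delta_m_fixed is None or not self.delta_m_fixed > 0
        ):
            raise ConfigurationError("delta_m_fixed must be > 0 in fixed_da mode")

    def delta_m(self, m: float) -> float:
        """Mass tolerance (Daltons) at mass ``m``."""
        if not m > 0:
            raise ValidationError(f"mass must be > 0, got {m}")
        if self.mode == "ppm":
            return self.eps_ppm * m * 1e-6
        return float(self.delta_m_fixed)  # fixed_da

    # -- tolerance comparisons (with float-rounding slack) ----------------

    def rt_close(self, rt: float, centre_rt: float) -> bool:
        d = self.delta_r
        return abs(rt - centre_rt) <= d * (1.0 + REL_EPS)

    def mass_close(self, mz: float, centre_mz: float) -> bool:
        d = self.delta_m(centre_mz)
        return abs(mz - centre_mz) <= d * (1.0 + REL_EPS)

    def in_mass_window(self, mz: float, window_min: float) -> bool:
        """Doubled-tolerance greedy-scan window anchored at the cluster minimum.

        The tolerance is evaluated at the candidate mass (the larger one):
        in ppm mode this over-covers slightly, which is required for a
        consensus whose members sit exactly on the tolerance boundary never
        to be split by a scan window (tolerance at the cluster minimum
        would under-cover by ~ppm of the tolerance itself).
        """
        d = self.delta_m(mz)
        return mz - window_min <= 2.0 * d * (1.0 + REL_EPS)

    def in_rt_window(self, rt: float, window_min: float) -> bool:
        return rt - window_min <= 2.0 * self.delta_r * (1.0 + REL_EPS)


def delta_m(res: ResolutionSet, m: float) -> float:
    """Mass tolerance in Daltons at mass ``m`` under resolution set ``res``."""
    return res.delta_m(m)


@dataclass
class Dataset:
    """A collection of features over ``n_maps`` spectra."""

    features: list[Feature]
    n_maps: int
    _by_uid: dict[int, Feature] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_maps < 0:
            raise ValidationError("n_maps must be >= 0")
        for f in self.features:
            if f.map_index > self.n_maps:
                raise ValidationError(
                    f"feature {f.uid}: map_index {f.map_index} exceeds n_maps {self.n_maps}"
                )
        uids = [f.uid for f in self.features]
        if len(set(uids)) != len(uids):
            raise ValidationError("feature uids are not unique")
        self._by_uid = {f.uid: f for f in self.features}

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def by_uid(self) -> dict[int, Feature]:
        return self._by_uid

    def counts_per_map(self) -> dict[int, int]:
        counts = {m: 0 for m in range(1, self.n_maps + 1)}
        for f in self.features:
            counts[f.map_index] += 1
        return counts


@dataclass(frozen=True)
class Consensus:
    """A predicted metabolite: centre coordinates plus member feature uids."""

    centre_rt: float
    centre_mz: float
    members: frozenset[int]

    @property
    def size(self) -> int:
        return len(self.members)


REQUIRED_COLUMNS = ("map", "rt", "mz", "intensity")


def read_features(path: str | os.PathLike, dialect: str = "tsv") -> Dataset:
    """Read a feature table (columns: map, rt, mz, intensity) into a Dataset.

    uids are assigned in file order starting at 0; the number of maps is
    inferred as the maximum map index present.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    features = []
    for uid, row in enumerate(df.itertuples(index=False)):
        try:
            features.append(
                Feature(
                    uid=uid,
                    rt=float(row.rt),
                    mz=float(row.mz),
                    map_index=int(row.map),
                    intensity=float(row.intensity),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, data row {uid + 1}: {exc}") from exc
    n_maps = max((f.map_index for f in features), default=0)
    return Dataset(features=features, n_maps=n_maps)


def write_features(dataset: Dataset, path: str | os.PathLike) -> None:
    """Write a Dataset back to a TSV feature table (uid order)."""
    df = pd.DataFrame(
        {
            "map": [f.map_index for f in dataset.features],
            "rt": [repr(f.rt) for f in dataset.features],
            "mz": [repr(f.mz) for f in dataset.features],
            "intensity": [repr(f.intensity) for f in dataset.features],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def assignments_path(path: str | os.PathLike) -> str:
    """Companion long-format path for a wide alignment table."""
    base, ext = os.path.splitext(os.fspath(path))
    return f"{base}_assignments{ext or '.tsv'}"


def check_partition(consensuses: Sequence[Consensus], dataset: Dataset) -> None:
    """Verify the consensuses partition the dataset's features exactly."""
    seen: dict[int, int] = {}
    for cid, cons in enumerate(consensuses):
        for uid in cons.members:
            if uid in seen:
                raise IntegrityError(
                    f"feature {uid} appears in consensuses {seen[uid]} and {cid}"
                )
            seen[uid] = cid
    all_uids = set(dataset.by_uid)
    missing = all_uids - set(seen)
    extra = set(seen) - all_uids
    if missing:
        raise IntegrityError(f"{len(missing)} feature(s) omitted from the alignment")
    if extra:
        raise IntegrityError(f"unknown feature uid(s) in alignment: {sorted(extra)[:5]}")


def write_alignment(
    consensuses: Sequence[Consensus],
    dataset: Dataset,
    path: str | os.PathLike,
) -> tuple[str, str]:
    """Write the wide intensity matrix plus the long uid->consensus table.

    The wide table has one row per consensus (id, centre_rt, centre_mz,
    size, then one intensity column per map; empty cell where the map is
    not covered).  Returns ``(wide_path, long_path)``.
    """
    check_partition(consensuses, dataset)
    by_uid = dataset.by_uid
    rows = []
    long_rows = []
    for cid, cons in enumerate(consensuses):
        row: dict[str, object] = {
            "consensus_id": cid,
            "centre_rt": cons.centre_rt,
            "centre_mz": cons.centre_mz,
            "size": cons.size,
        }
        for uid in sorted(cons.members):
            f = by_uid[uid]
            row[f"map_{f.map_index}"] = f.intensity
            long_rows.append({"uid": uid, "consensus_id": cid})
        rows.append(row)
    cols = ["consensus_id", "centre_rt", "centre_mz", "size"] + [
        f"map_{m}" for m in range(1, dataset.n_maps + 1)
    ]
    wide = pd.DataFrame(rows, columns=cols)
    wide.to_csv(path, sep="\t", index=False)
    long_path = assignments_path(path)
    pd.DataFrame(long_rows, columns=["uid", "consensus_id"]).sort_values("uid").to_csv(
        long_path, sep="\t", index=False
    )
    return os.fspath(path), long_path


def read_alignment(
    wide_path: str | os.PathLike, long_path: str | os.PathLike | None = None
) -> tuple[list[Consensus], int]:
    """Rebuild consensuses from the wide + long alignment tables.

    Returns the consensus list (indexed by consensus_id) and the number of
    map columns found in the wide table.
    """
    if long_path is None:
        long_path = assignments_path(wide_path)
    wide = pd.read_csv(wide_path, sep="\t")
    long = pd.read_csv(long_path, sep="\t")
    members: dict[int, set[int]] = {}
    for row in long.itertuples(index=False):
        members.setdefault(int(row.consensus_id), set()).add(int(row.uid))
    consensuses = []
    for row in wide.itertuples(index=False):
        cid = int(row.consensus_id)
        mem = frozenset(members.get(cid, set()))
        if len(mem) != int(row.size):
            raise IntegrityError(
                f"consensus {cid}: size column {row.size} != {len(mem)} assigned uids"
            )
        consensuses.append(
            Consensus(
                centre_rt=float(row.centre_rt),
                centre_mz=float(row.centre_mz),
                members=mem,
            )
        )
    n_maps = sum(1 for c in wide.columns if c.startswith("map_"))
    return consensuses, n_maps
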