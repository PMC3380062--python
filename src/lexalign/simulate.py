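"""Ground-truthed simulators for two-map and multi-map benchmark data.

Planted "true simulated metabolites" (TSMs) get centres drawn uniformly
over rt [1, 27] minutes and mass [1, 500] Daltons.  Each feature of a TSM
adds uniform noise bounded by ``noise * tolerance`` in both dimensions, so
at noise <= 1 every feature satisfies the resolution condition against its
TSM.  Centres are rejection-sampled to keep every pair of TSMs separated by
more than four mass tolerances, which makes the planted truth exactly
recoverable by the greedy aligner (no two TSMs can merge, and no foreign
feature can fall inside another TSM's scan window).
"""

from __future__ import annotations

import os
from bisect import bisect_left, insort
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfigurationError, Dataset, Feature, ResolutionSet

RT_RANGE = (1.0, 27.0)
MASS_RANGE = (1.0, 500.0)
SEPARATION_FACTOR = 4.0
_MAX_TRIES = 10_000


@dataclass(frozen=True)
class TSM:
    """A planted ground-truth metabolite."""

    tsm_id: int
    rt: float
    mz: float
    member_uids: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.member_uids)

    @property
    def category(self) -> str:
        return "aligned" if self.size >= 2 else "non-aligned"


@dataclass
class SimTruth:
    """Planted TSMs plus the feature -> TSM mapping."""

    tsms: list[TSM]
    n_maps: int

    @property
    def feature_to_tsm(self) -> dict[int, int]:
        return {uid: t.tsm_id for t in self.tsms for uid in t.member_uids}

    @property
    def aligned(self) -> list[TSM]:
        return [t for t in self.tsms if t.size >= 2]

    @property
    def nonaligned(self) -> list[TSM]:
        return [t for t in self.tsms if t.size == 1]

    def t_vector(self, n_maps: int | None = None) -> list[int]:
        """Per-size TSM counts t_1..t_K."""
        k = n_maps or self.n_maps
        t = [0] * k
        for tsm in self.tsms:
            t[tsm.size - 1] += 1
        return t


@dataclass(frozen=True)
class SimConfig:
    """Two-map benchmark configuration."""

    n_aligned: int
    n_nonaligned: int
    noise: float
    seed: int
    res: ResolutionSet = ResolutionSet()
    n_maps: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise <= 1.0:
            raise ConfigurationError(f"noise must be in [0, 1], got {self.noise}")
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")
        if self.n_maps != 2:
            raise ConfigurationError("the two-map generator requires n_maps = 2")
        if self.n_aligned < 0 or self.n_nonaligned < 0:
            raise ConfigurationError("TSM counts must be non-negative")


def _sample_centres(n: int, rng: np.random.Generator, res: ResolutionSet):
    """Rejection-sample TSM centres with pairwise mass separation > 4 tolerances."""
    rts = rng.uniform(*RT_RANGE, size=n)
    masses: list[float] = []
    for _ in range(n):
        for _attempt in range(_MAX_TRIES):
            m = float(rng.uniform(*MASS_RANGE))
            i = bisect_left(masses, m)
            ok = True
            for nbr in masses[max(0, i - 1): i + 1]:
                gap = abs(m - nbr)
                if gap <= SEPARATION_FACTOR * res.delta_m(max(m, nbr)):
                    ok = False
                    break
            if ok:
                insort(masses, m)
                break
        else:
            raise ConfigurationError(
                "could not place TSM centres with the required mass separation"
            )
    order = rng.permutation(n)
    masses_arr = np.asarray(masses)[order]
    return rts, masses_arr


def _noised(value: float, bound: float, rng: np.random.Generator) -> float:
    if bound == 0.0:
        return value
    return value + float(rng.uniform(-bound, bound))


def _make_feature(
    uid: int,
    tsm_rt: float,
    tsm_mz: float,
    map_index: int,
    noise: float,
    res: ResolutionSet,
    rng: np.random.Generator,
) -> Feature:
    rt = _noised(tsm_rt, noise * res.delta_r, rng)
    mz = _noised(tsm_mz, noise * res.delta_m(tsm_mz), rng)
    intensity = float(rng.lognormal(mean=10.0, sigma=1.0))
    return Feature(uid=uid, rt=rt, mz=mz, map_index=map_index, intensity=intensity)


def generate_toy_a(cfg: SimConfig) -> tuple[Dataset, SimTruth]:
    """Two-map benchmark with aligned (size-2) and non-aligned (size-1) TSMs.

    An aligned TSM contributes one independently noised feature to each of
    the two maps; a non-aligned TSM contributes a single feature to a
    uniformly chosen map.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_aligned + cfg.n_nonaligned
    rts, mzs = _sample_centres(n_total, rng, cfg.res)
    sizes = [2] * cfg.n_aligned + [1] * cfg.n_nonaligned
    features: list[Feature] = []
    tsms: list[TSM] = []
    uid = 0
    for tsm_id, (trt, tmz, size) in enumerate(zip(rts, mzs, sizes)):
        if size == 2:
            maps = [int(m) for m in rng.permutation([1, 2])]
        else:
            maps = [int(rng.integers(1, 3))]
        uids = []
        for m in maps:
            features.append(
                _make_feature(uid, float(trt), float(tmz), m, cfg.noise, cfg.res, rng)
            )
            uids.append(uid)
            uid += 1
        tsms.append(TSM(tsm_id=tsm_id, rt=float(trt), mz=float(tmz), member_uids=tuple(uids)))
    return Dataset(features=features, n_maps=2), SimTruth(tsms=tsms, n_maps=2)


def generate_toy_b(
    n_maps: int = 10,
    n_per_size: int | list[int] = 10,
    noise: float = 0.0,
    res: ResolutionSet = ResolutionSet(),
    seed: int = 0,
) -> tuple[Dataset, SimTruth]:
    """Multi-map benchmark: planted TSMs of every size 1..n_maps.

    A TSM of size s contributes s independently noised features placed in s
    distinct, uniformly chosen maps.  Returns the dataset and the truth
    (whose ``t_vector`` gives the planted per-size counts).
    """
    if not 0.0 <= noise <= 1.0:
        raise ConfigurationError(f"noise must be in [0, 1], got {noise}")
    if isinstance(n_per_size, int):
        per_size = [n_per_size] * n_maps
    else:
        per_size = list(n_per_size)
        if len(per_size) != n_maps:
            raise ConfigurationError("n_per_size must have one count per size 1..n_maps")
    rng = np.random.default_rng(seed)
    n_total = sum(per_size)
    rts, mzs = _sample_centres(n_total, rng, res)
    sizes = [s for s, count in enumerate(per_size, start=1) for _ in range(count)]
    features: list[Feature] = []
    tsms: list[TSM] = []
    uid = 0
    for tsm_id, (trt, tmz, size) in enumerate(zip(rts, mzs, sizes)):
        maps = [int(m) + 1 for m in rng.choice(n_maps, size=size, replace=False)]
        uids = []
        for m in maps:
            features.append(
                _make_feature(uid, float(trt), float(tmz), m, noise, res, rng)
            )
            uids.append(uid)
            uid += 1
        tsms.append(TSM(tsm_id=tsm_id, rt=float(trt), mz=float(tmz), member_uids=tuple(uids)))
    return Dataset(features=features, n_maps=n_maps), SimTruth(tsms=tsms, n_maps=n_maps)


def write_truth(truth: SimTruth, path: str | os.PathLike) -> None:
    rows = [
        {
            "tsm_id": t.tsm_id,
            "size": t.size,
            "category": t.category,
            "true_rt": repr(t.rt),
            "true_mz": repr(t.mz),
            "members": ";".join(str(u) for u in t.member_uids),
        }
        for t in truth.tsms
    ]
    pd.DataFrame(
        rows, columns=["tsm_id", "size", "category", "true_rt", "true_mz", "members"]
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | os.PathLike, n_maps: int | None = None) -> SimTruth:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    tsms = [
        TSM(
            tsm_id=int(row.tsm_id),
            rt=float(row.true_rt),
            mz=float(row.true_mz),
            member_uids=tuple(int(u) for u in str(row.members).split(";")),
        )
        for row in df.itertuples(index=False)
    ]
    if n_maps is None:
        n_maps = max((t.size for t in tsms), default=0)
    return SimTruth(tsms=tsms, n_maps=n_maps)
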