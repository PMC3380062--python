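import itertools
import math
import time

import numpy as np
import pytest

from lexalign.aligner import (
    align,
    build_r_list,
    consensus_centre,
    form_consensus,
    scan_m_clusters,
    scan_r_clusters,
    _Member,
)
from lexalign.core import ContractError, Dataset, ResolutionSet
from lexalign.dav import decode, from_features, infer_layout, sort_strings
from lexalign.evaluate import sensitivity, specificity
from lexalign.simulate import SimConfig, generate_toy_a, generate_toy_b

from conftest import make_dataset, make_features

WORKED_MASSES = [130.033, 130.034, 130.035, 130.409, 130.410, 130.411]


def _sorted_mass_list(rows):
    ds = make_dataset(rows)
    return sort_strings(from_features(ds.features, infer_layout(ds))), ds


# -- independent brute-force gap oracle (plain arithmetic, no string path) --


def gap_oracle(sorted_values, window_of_candidate):
    """Left-to-right scanner: a run ends when the next value exceeds
    run_min + window(candidate)."""
    runs = []
    i = 0
    while i < len(sorted_values):
        j = i
        while (
            j + 1 < len(sorted_values)
            and sorted_values[j + 1] - sorted_values[i]
            <= window_of_candidate(sorted_values[j + 1])
        ):
            j += 1
        runs.append((i, j + 1))
        i = j + 1
    return runs


class TestScanMClusters:
    def test_worked_example_two_clusters(self, fixed_res):
        sl, _ = _sorted_mass_list([(1.0, mz, 1, 10.0) for mz in WORKED_MASSES])
        clusters = scan_m_clusters(sl, fixed_res)
        assert len(clusters) == 2
        assert (clusters[0].start, clusters[0].stop) == (0, 3)
        assert (clusters[1].start, clusters[1].stop) == (3, 6)
        assert clusters[0].max_mass == 130.035
        assert clusters[1].min_mass == 130.409

    def test_single_feature(self, res):
        sl, _ = _sorted_mass_list([(1.0, 100.0, 1, 10.0)])
        clusters = scan_m_clusters(sl, res)
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].stop) == (0, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed, res):
        rng = np.random.default_rng(seed)
        masses = np.round(np.sort(rng.uniform(100.0, 100.02, size=50)), 6)
        sl, _ = _sorted_mass_list([(1.0, mz, 1, 10.0) for mz in masses])
        got = [(c.start, c.stop) for c in scan_m_clusters(sl, res)]
        expected = gap_oracle(list(masses), lambda m: 2 * res.delta_m(m))
        assert got == expected

    def test_unsorted_input_is_contract_error(self, res):
        ds = make_dataset([(1.0, 200.0, 1, 10.0), (1.0, 100.0, 1, 10.0)])
        sl = from_features(ds.features, infer_layout(ds))  # deliberately unsorted
        with pytest.raises(ContractError):
            scan_m_clusters(sl, res)


class TestBuildRList:
    def _cluster(self, rows, res):
        sl, ds = _sorted_mass_list(rows)
        mc = scan_m_clusters(sl, res)[0]
        return sl, mc

    def test_origins_point_into_s(self, fixed_res):
        rows = [(3.0, 130.034, 1, 10.0), (1.0, 130.0341, 2, 20.0), (2.0, 130.0342, 1, 30.0)]
        sl, mc = self._cluster(rows, fixed_res)
        rl = build_r_list(sl, mc)
        assert len(rl) == 3
        origins = [decode(r, leading="rt")["origin"] for r in rl.records]
        assert origins == [0, 1, 2]

    def test_origin_survives_sorting(self, fixed_res):
        rows = [(3.0, 130.034, 1, 10.0), (1.0, 130.0341, 2, 20.0), (2.0, 130.0342, 1, 30.0)]
        sl, mc = self._cluster(rows, fixed_res)
        rl = sort_strings(build_r_list(sl, mc))
        for rec in rl.records:
            d = decode(rec, leading="rt")
            s = decode(sl.records[d["origin"]])
            assert s["rt"] == d["rt"] and s["mz"] == d["mz"]

    def test_membership_roundtrip(self, fixed_res):
        rows = [(3.0, 130.034, 1, 10.0), (1.0, 130.0341, 2, 20.0), (2.0, 130.0342, 1, 30.0)]
        sl, mc = self._cluster(rows, fixed_res)
        rl = sort_strings(build_r_list(sl, mc))
        uids = {sl.uids[decode(r, leading="rt")["origin"]] for r in rl.records}
        assert uids == {sl.uids[p] for p in range(mc.start, mc.stop)}


class TestScanRClusters:
    def _r_list(self, rts, res):
        rows = [(rt, 100.0, 1, 10.0) for rt in rts]
        sl, _ = _sorted_mass_list(rows)
        mc = scan_m_clusters(sl, res)[0]
        return sort_strings(build_r_list(sl, mc))

    def test_doubled_window_split(self, res):
        rl = self._r_list([10.0, 10.3, 10.6, 12.0], res)
        clusters = scan_r_clusters(rl, res)
        assert [(c.start, c.stop) for c in clusters] == [(0, 3), (3, 4)]
        # the 0.6 span equals the doubled tolerance, hence stays together
        assert clusters[0].max_rt - clusters[0].min_rt == pytest.approx(0.6)

    def test_single_member(self, res):
        assert len(scan_r_clusters(self._r_list([5.0], res), res)) == 1

    def test_all_within_window_single_cluster(self, res):
        rl = self._r_list([10.0, 10.1, 10.25, 10.55], res)
        assert len(scan_r_clusters(rl, res)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed, res):
        rng = np.random.default_rng(100 + seed)
        rts = np.round(np.sort(rng.uniform(5.0, 10.0, size=40)), 6)
        rl = self._r_list(list(rts), res)
        got = [(c.start, c.stop) for c in scan_r_clusters(rl, res)]
        assert got == gap_oracle(list(rts), lambda _: 2 * res.delta_r)


class TestConsensusCentre:
    def test_first_worked_cluster(self):
        members = [_Member(i, 1.0, mz, i + 1, 0) for i, mz in enumerate([130.033, 130.034, 130.035])]
        assert consensus_centre(members)[1] == pytest.approx(130.034)

    def test_second_worked_cluster(self):
        members = [_Member(i, 1.0, mz, i + 1, 0) for i, mz in enumerate([130.409, 130.411, 130.410])]
        assert consensus_centre(members)[1] == pytest.approx(130.410)

    def test_single_member_is_own_centre(self):
        m = _Member(0, 3.3, 250.1, 1, 0)
        assert consensus_centre([m]) == (3.3, 250.1)


def _exhaustive_best_subset(members, res):
    """Oracle: largest collision-free subset consistent with its own midrange
    centre; ties broken by smallest summed normalized distance."""
    best = None
    for k in range(len(members), 0, -1):
        for subset in itertools.combinations(members, k):
            maps = [m.map_index for m in subset]
            if len(set(maps)) != len(maps):
                continue
            crt = (min(m.rt for m in subset) + max(m.rt for m in subset)) / 2
            cmz = (min(m.mz for m in subset) + max(m.mz for m in subset)) / 2
            if any(
                abs(m.rt - crt) > res.delta_r or abs(m.mz - cmz) > res.delta_m(cmz)
                for m in subset
            ):
                continue
            dist = sum(
                math.hypot((m.rt - crt) / res.delta_r, (m.mz - cmz) / res.delta_m(cmz))
                for m in subset
            )
            if best is None or dist < best[0]:
                best = (dist, frozenset(m.uid for m in subset))
        if best is not None:
            return best[1]
    return None


class TestFormConsensus:
    def test_one_feature_per_map_accepted(self, res):
        members = [
            _Member(0, 10.0, 100.0, 1, 0),
            _Member(1, 10.1, 100.0005, 2, 1),
            _Member(2, 10.2, 100.001, 3, 2),
        ]
        outcome = form_consensus(members, 3, res)
        assert outcome is not None
        cons, positions = outcome
        assert cons.members == {0, 1, 2}
        assert sorted(positions) == [0, 1, 2]
        assert cons.centre_rt == pytest.approx(10.1)

    @pytest.mark.parametrize("seed", range(10))
    def test_collision_resolution_matches_exhaustive_oracle(self, seed, res):
        # planted consensus of one feature per map plus one same-map intruder
        # sitting strictly farther out in both dimensions than its rival
        rng = np.random.default_rng(seed)
        crt, cmz = rng.uniform(5, 20), rng.uniform(50, 400)
        dm = res.delta_m(cmz)
        members = []
        for i, m in enumerate([1, 2, 3]):
            members.append(
                _Member(
                    i,
                    crt + rng.uniform(-0.3, 0.3) * res.delta_r,
                    cmz + rng.uniform(-0.3, 0.3) * dm,
                    m,
                    i,
                )
            )
        intruder_map = int(rng.integers(1, 4))
        sr = rng.choice([-1.0, 1.0])
        sm = rng.choice([-1.0, 1.0])
        members.append(
            _Member(
                3,
                crt + sr * rng.uniform(0.8, 0.95) * res.delta_r,
                cmz + sm * rng.uniform(0.8, 0.95) * dm,
                intruder_map,
                3,
            )
        )
        outcome = form_consensus(members, 3, res)
        assert outcome is not None
        assert outcome[0].members == _exhaustive_best_subset(members, res)
        assert 3 not in outcome[0].members  # the intruder is returned to the pool

    def test_rejection_when_size_misses_target(self, res):
        members = [_Member(0, 10.0, 100.0, 1, 0), _Member(1, 10.1, 100.0005, 2, 1)]
        assert form_consensus(members, 3, res) is None

    def test_out_of_resolution_members_excluded(self, res):
        # artificial over-wide member list: the mass extremes violate the
        # resolution condition against the midrange centre and are filtered
        # out before the acceptance test
        members = [
            _Member(0, 10.0, 100.0, 1, 0),
            _Member(1, 10.02, 100.001, 2, 1),
            _Member(2, 10.05, 100.003, 3, 2),
        ]
        outcome = form_consensus(members, 1, res)
        assert outcome is not None
        assert outcome[0].members == {1}
        assert form_consensus(members, 3, res) is None


# -- exhaustive whole-alignment oracle -------------------------------------


def _oracle_align(dataset, res, max_component=10):
    """Enumerate all collision-free partitions satisfying the resolution
    condition within each block, maximizing coverage lexicographically
    (count of size-K blocks first, then size K-1, ...)."""
    feats = dataset.features
    n = len(feats)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            a, b = feats[i], feats[j]
            if abs(a.rt - b.rt) <= 2 * res.delta_r and abs(a.mz - b.mz) <= 2 * res.delta_m(
                max(a.mz, b.mz)
            ):
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(feats[i])
    K = dataset.n_maps

    def valid_block(block):
        maps = [f.map_index for f in block]
        if len(set(maps)) != len(maps):
            return False
        crt = (min(f.rt for f in block) + max(f.rt for f in block)) / 2
        cmz = (min(f.mz for f in block) + max(f.mz for f in block)) / 2
        return all(
            abs(f.rt - crt) <= res.delta_r and abs(f.mz - cmz) <= res.delta_m(cmz)
            for f in block
        )

    def partitions(block):
        if not block:
            yield []
            return
        first, rest = block[0], block[1:]
        for r in range(len(rest) + 1):
            for combo in itertools.combinations(rest, r):
                cand = [first, *combo]
                if not valid_block(cand):
                    continue
                remaining = [f for f in rest if f not in combo]
                for sub in partitions(remaining):
                    yield [cand] + sub

    def score(partition):
        c = [0] * K
        for block in partition:
            c[len(block) - 1] += 1
        return tuple(c[::-1])

    blocks = []
    for comp in comps.values():
        assert len(comp) <= max_component, "oracle component too large"
        best = max(partitions(comp), key=score)
        blocks.extend(best)
    return {frozenset(f.uid for f in block) for block in blocks}


class TestAlign:
    def test_empty_dataset(self, res):
        result = align(Dataset(features=[], n_maps=0), res)
        assert result.consensuses == []

    def test_toy_a_zero_noise_exact_recovery(self, res):
        cfg = SimConfig(n_aligned=40, n_nonaligned=40, noise=0.0, seed=7, res=res)
        ds, truth = generate_toy_a(cfg)
        result = align(ds, res)
        assert sensitivity(result, truth) == 100.0
        assert specificity(result, truth) == 100.0
        got = {c.members for c in result.consensuses}
        assert got == {frozenset(t.member_uids) for t in truth.tsms}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle_random_sparse(self, seed):
        res = ResolutionSet()
        rng = np.random.default_rng(200 + seed)
        n = 30
        rows = [
            (
                float(np.round(rng.uniform(1, 27), 6)),
                float(np.round(rng.uniform(1, 500), 6)),
                int(rng.integers(1, 5)),
                float(np.round(rng.uniform(1, 100), 3)),
            )
            for _ in range(n)
        ]
        ds = make_dataset(rows, n_maps=4)
        result = align(ds, res)
        assert {c.members for c in result.consensuses} == _oracle_align(ds, res)

    @pytest.mark.parametrize("seed,noise", [(0, 0.0), (1, 0.5), (2, 1.0)])
    def test_matches_exhaustive_oracle_planted(self, seed, noise, res):
        ds, truth = generate_toy_b(
            n_maps=4, n_per_size=[3, 2, 2, 1], noise=noise, res=res, seed=seed
        )
        result = align(ds, res)
        oracle = _oracle_align(ds, res)
        assert {c.members for c in result.consensuses} == oracle
        assert oracle == {frozenset(t.member_uids) for t in truth.tsms}

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_and_collision_freedom_on_dense_data(self, seed, res):
        # deliberately overlapping features to force collisions
        rng = np.random.default_rng(300 + seed)
        rows = [
            (
                float(rng.uniform(10.0, 10.5)),
                float(rng.uniform(100.0, 100.003)),
                int(rng.integers(1, 4)),
                1.0,
            )
            for _ in range(25)
        ]
        ds = make_dataset(rows, n_maps=3)
        result = align(ds, res)
        result.validate(ds, res)  # raises on duplication/omission/collision
        assert sum((i + 1) * ci for i, ci in enumerate(result.c)) == ds.n_features

    def test_degenerate_identical_features(self, res):
        rows = [(5.0, 100.0, m, 1.0) for m in [1, 1, 2, 2, 3, 3, 3]]
        ds = make_dataset(rows, n_maps=3)
        result = align(ds, res)
        result.validate(ds, res)
        # one consensus per collision group: bounded by the deepest map multiplicity
        assert len(result.consensuses) == 3
        assert result.c == [1, 0, 2]

    def test_remark2_boundary_consensus_not_split(self, res):
        # planted consensus with members exactly on the tolerance boundary
        centre_rt, centre_mz = 10.1, 100.0
        dm = res.delta_m(centre_mz)
        rows = [
            (centre_rt - 0.3, centre_mz - dm, 1, 1.0),
            (centre_rt + 0.3, centre_mz + dm, 2, 1.0),
            (centre_rt, centre_mz, 3, 1.0),
            (centre_rt - 0.1, centre_mz + 0.5 * dm, 4, 1.0),
            # distant bystanders
            (20.0, 300.0, 1, 1.0),
            (3.0, 50.0, 2, 1.0),
        ]
        ds = make_dataset(rows, n_maps=4)
        sl = sort_strings(from_features(ds.features, infer_layout(ds)))
        clusters = scan_m_clusters(sl, res)
        planted = {0, 1, 2, 3}
        containing = [
            c
            for c in clusters
            if planted <= {sl.uids[p] for p in range(c.start, c.stop)}
        ]
        assert len(containing) == 1  # no M-cluster boundary separates the members
        result = align(ds, res)
        assert frozenset(planted) in {c.members for c in result.consensuses}

    def test_deterministic_reruns(self, res):
        cfg = SimConfig(n_aligned=30, n_nonaligned=30, noise=0.8, seed=11, res=res)
        ds, _ = generate_toy_a(cfg)
        r1, r2 = align(ds, res), align(ds, res)
        assert [c.members for c in r1.consensuses] == [c.members for c in r2.consensuses]
        assert [(c.centre_rt, c.centre_mz) for c in r1.consensuses] == [
            (c.centre_rt, c.centre_mz) for c in r2.consensuses
        ]

    def test_remark3_subquadratic_scaling_soft(self, res, capsys):
        """Runtime scaling log (soft check: printed, not hard-asserted)."""
        times = {}
        for n_pairs in (1250, 5000):
            cfg = SimConfig(
                n_aligned=n_pairs, n_nonaligned=n_pairs // 2, noise=0.5, seed=5, res=res
            )
            ds, _ = generate_toy_a(cfg)
            t0 = time.perf_counter()
            align(ds, res)
            times[ds.n_features] = time.perf_counter() - t0
        (n1, t1), (n2, t2) = sorted(times.items())
        ratio = t2 / max(t1, 1e-9)
        quadratic_ratio = (n2 / n1) ** 2
        with capsys.disabled():
            print(
                f"\n[remark3] N={n1}: {t1:.3f}s, N={n2}: {t2:.3f}s, "
                f"ratio {ratio:.1f} (quadratic would be {quadratic_ratio:.1f})"
            )
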