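import math

import numpy as np
import pytest
from scipy.spatial.distance import directed_hausdorff
from scipy.spatial.transform import Rotation

from trajsim import (
    StructureEnsemble,
    Trajectory,
    compare,
    ddm,
    discrete_frechet,
    dtw,
    hausdorff,
    kld,
    lcss,
    pair_distributions,
    wasserstein,
    weak_frechet,
)
from trajsim.measures import MEASURE_NAMES
from trajsim.oracles import oracle_coupling_search, weak_frechet_oracle

from conftest import random_pair, random_trajectory


def T(*pts):
    return Trajectory(np.array(pts, dtype=float))


# ---------------------------------------------------------------------------
# Worked toy examples with hand-checkable optima


class TestToyExamples:
    def test_hausdorff_single_pair(self):
        assert hausdorff(T((0, 0, 0)), T((3, 4, 0))).value == pytest.approx(5.0)

    def test_hausdorff_asymmetric_point_sets(self):
        p = T((0, 0, 0), (1, 0, 0), (2, 0, 0))
        q = T((0, 1, 0), (2, 1, 0))
        assert hausdorff(p, q).value == pytest.approx(math.sqrt(2))

    def test_frechet_parallel_segments(self):
        p, q = T((0, 0, 0), (1, 0, 0)), T((0, 1, 0), (1, 1, 0))
        assert discrete_frechet(p, q).value == pytest.approx(1.0)
        assert weak_frechet(p, q).value == pytest.approx(1.0)

    def test_frechet_forced_detour(self):
        p = T((0, 0, 0), (2, 0, 0))
        q = T((0, 0, 0), (1, 3, 0), (2, 0, 0))
        assert discrete_frechet(p, q).value == pytest.approx(math.sqrt(10))

    def test_weak_frechet_forgives_zigzag(self):
        p = T((0, 0, 0), (2, 0, 0), (0, 0, 0), (2, 0, 0))
        q = T((0, 1, 0), (2, 1, 0))
        assert weak_frechet(p, q).value == pytest.approx(1.0)
        assert discrete_frechet(p, q).value == pytest.approx(math.sqrt(5))

    def test_dtw_parallel_segments_and_fan_out(self):
        assert dtw(T((0, 0, 0), (1, 0, 0)), T((0, 1, 0), (1, 1, 0))).value == pytest.approx(2.0)
        assert dtw(T((0, 0, 0)), T((0, 0, 0), (3, 4, 0))).value == pytest.approx(5.0)

    def test_lcss_single_outlier(self):
        p = T((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0))
        q = T((0, 0, 0), (5, 0, 0), (2, 0, 0), (3, 0, 0))
        res = lcss(p, q, epsilon=0.5)
        assert res.raw == 3
        assert res.value == pytest.approx(0.25)

    def test_wasserstein_shifted_samples(self):
        p, q = T((0, 0, 0), (1, 0, 0)), T((1, 0, 0), (2, 0, 0))
        assert wasserstein(p, q).value == pytest.approx(1.0)

    def test_wasserstein_translated_delta(self):
        assert wasserstein(T((0, 0, 0)), T((5, 0, 0))).value == pytest.approx(5.0)

    def test_kld_two_bin_example(self):
        from trajsim import DimensionDistributions

        edges = np.tile([0.0, 0.5, 1.0], (3, 1))
        even = np.array([[0.5, 0.5]] * 3)
        skew = np.array([[0.25, 0.75], [0.5, 0.5], [0.5, 0.5]])
        dp = DimensionDistributions(np.zeros((4, 3)), edges, even)
        dq = DimensionDistributions(np.zeros((4, 3)), edges, skew)
        expect = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)  # ≈ 0.14384 nats
        assert kld(dp, dq, pseudocount=1e-15).value == pytest.approx(expect, abs=1e-6)

    def test_ddm_two_static_sites(self):
        a = StructureEnsemble(np.tile([[0, 0, 0], [1, 0, 0]], (3, 1, 1)).astype(float))
        b = StructureEnsemble(np.tile([[0, 0, 0], [3, 0, 0]], (3, 1, 1)).astype(float))
        res = ddm(a, b)
        np.testing.assert_allclose(res.diff_matrix, [[0, -2], [-2, 0]])
        np.testing.assert_allclose(res.per_site, [1.0, 1.0])
        signed = ddm(a, b, signed=True)
        np.testing.assert_allclose(signed.per_site, [-1.0, -1.0])


# ---------------------------------------------------------------------------
# Shared invariants


def _identity_value(name, p):
    if name == "ddm":
        ens = StructureEnsemble(p.coords[None, :, :])
        return compare(ens, ens, "ddm").value
    if name == "lcss":
        return compare(p, p, name, epsilon=0.5).value
    return compare(p, p, name).value


class TestInvariants:
    @pytest.mark.parametrize("name", MEASURE_NAMES)
    def test_identity_gives_zero(self, name, rng):
        p = random_trajectory(rng, 12)
        assert _identity_value(name, p) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("name", ["hd", "dfd", "dwfd", "dtw", "wd"])
    def test_symmetry(self, name, rng):
        p, q = random_trajectory(rng, 9), random_trajectory(rng, 13)
        assert compare(p, q, name).value == pytest.approx(compare(q, p, name).value, rel=1e-12)

    def test_lcss_symmetry(self, rng):
        p, q = random_trajectory(rng, 9), random_trajectory(rng, 13)
        assert lcss(p, q, epsilon=1.0).raw == lcss(q, p, epsilon=1.0).raw

    def test_kld_asymmetric_unless_symmetrized(self, rng):
        p = random_trajectory(rng, 60)
        q = Trajectory(rng.normal(size=(60, 3)) * 2 + 1)
        dp, dq = pair_distributions(p, q, bins=12)
        fwd, bwd = kld(dp, dq).value, kld(dq, dp).value
        assert fwd != pytest.approx(bwd, rel=1e-6)
        sym_pq = kld(dp, dq, symmetrize=True).value
        sym_qp = kld(dq, dp, symmetrize=True).value
        assert sym_pq == pytest.approx(fwd + bwd)
        assert sym_pq == pytest.approx(sym_qp)

    @pytest.mark.parametrize("seed", range(40))
    def test_ordering_chain(self, seed):
        p, q = random_pair(seed, max_len=20)
        wf = weak_frechet(p, q).value
        df = discrete_frechet(p, q).value
        assert wf <= df + 1e-9
        assert hausdorff(p, q).value <= df + 1e-9
        assert df <= dtw(p, q).value + 1e-9

    def test_kld_non_negative(self, rng):
        for _ in range(10):
            p = random_trajectory(rng, 30)
            q = Trajectory(rng.normal(size=(25, 3)) + rng.normal())
            assert kld(p, q, bins=15).value >= 0

    def test_hausdorff_matches_scipy(self, rng):
        p, q = random_trajectory(rng, 25), random_trajectory(rng, 18)
        expect = max(
            directed_hausdorff(p.coords, q.coords)[0],
            directed_hausdorff(q.coords, p.coords)[0],
        )
        assert hausdorff(p, q).value == pytest.approx(expect, rel=1e-12)


class TestOrderDependence:
    """Table-1 attribute: which measures see the trajectory as an ordered sequence."""

    @staticmethod
    def _permuted(p, rng):
        return p.permuted(rng.permutation(len(p)))

    @pytest.mark.parametrize("name", ["hd", "wd", "kld"])
    def test_order_independent_measures(self, name, rng):
        p, q = random_trajectory(rng, 15), random_trajectory(rng, 11)
        base = compare(p, q, name, bins=8).value if name == "kld" else compare(p, q, name).value
        for _ in range(5):
            pp, qq = self._permuted(p, rng), self._permuted(q, rng)
            v = compare(pp, qq, name, bins=8).value if name == "kld" else compare(pp, qq, name).value
            assert v == pytest.approx(base, rel=1e-9, abs=1e-12)

    def test_ddm_order_independent_in_time(self, rng):
        # DDM averages over frames: permuting the frame order changes nothing
        a = StructureEnsemble(rng.normal(size=(6, 5, 3)))
        b = StructureEnsemble(rng.normal(size=(6, 5, 3)))
        perm = rng.permutation(6)
        shuffled = StructureEnsemble(a.coords[perm])
        np.testing.assert_allclose(ddm(a, b).per_site, ddm(shuffled, b).per_site, atol=1e-12)

    @pytest.mark.parametrize("name", ["dfd", "dtw", "lcss"])
    def test_order_dependent_measures_have_counterexample(self, name):
        # reversing one straight-line trajectory changes every order-dependent measure
        p = T((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0))
        q = T((3, 0.1, 0), (2, 0.1, 0), (1, 0.1, 0), (0, 0.1, 0))
        kw = {"epsilon": 0.5} if name == "lcss" else {}
        straight = compare(p, q.permuted([3, 2, 1, 0]), name, **kw).value
        reversed_ = compare(p, q, name, **kw).value
        assert straight != pytest.approx(reversed_)


class TestRigidMotionAndScaling:
    @pytest.mark.parametrize("name", ["hd", "dfd", "dwfd", "dtw", "lcss"])
    def test_common_rigid_motion_leaves_value_unchanged(self, name, rng):
        p, q = random_trajectory(rng, 10), random_trajectory(rng, 14)
        rot = Rotation.random(random_state=7).as_matrix()
        shift = rng.normal(size=3) * 10
        pm = Trajectory(p.coords @ rot.T + shift)
        qm = Trajectory(q.coords @ rot.T + shift)
        kw = {"epsilon": 0.8} if name == "lcss" else {}
        assert compare(pm, qm, name, **kw).value == pytest.approx(
            compare(p, q, name, **kw).value, abs=1e-9
        )

    def test_ddm_rigid_motion_invariance_per_frame(self, rng):
        a = StructureEnsemble(rng.normal(size=(4, 6, 3)))
        moved = a.coords.copy()
        for t in range(4):
            moved[t] = moved[t] @ Rotation.random(random_state=t).as_matrix().T + t
        np.testing.assert_allclose(
            ddm(a, StructureEnsemble(moved)).per_site, 0.0, atol=1e-9
        )

    @pytest.mark.parametrize("name", ["hd", "dfd", "dwfd", "dtw", "wd"])
    def test_uniform_scaling_scales_value(self, name, rng):
        p, q = random_trajectory(rng, 8), random_trajectory(rng, 11)
        s = 3.7
        base = compare(p, q, name).value
        scaled = compare(Trajectory(p.coords * s), Trajectory(q.coords * s), name).value
        assert scaled == pytest.approx(s * base, rel=1e-9)


class TestLCSSBehaviour:
    def test_identity_full_match(self, rng):
        p = random_trajectory(rng, 9)
        res = lcss(p, p, epsilon=1e-9)
        assert res.raw == 9 and res.value == 0.0

    def test_threshold_floor_and_ceiling(self, rng):
        p, q = random_trajectory(rng, 8), Trajectory(rng.normal(size=(6, 3)) + 100)
        far = lcss(p, q, epsilon=0.5)
        assert far.raw == 0 and far.value == 1.0
        near = lcss(p, q, epsilon=1e6)
        assert near.raw == 6 and near.value == 0.0

    def test_delta_restricts_matches(self):
        p = T((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0))
        q = T((3, 0, 0), (0, 0, 0), (1, 0, 0), (2, 0, 0))
        assert lcss(p, q, epsilon=0.1).raw == 3
        assert lcss(p, q, epsilon=0.1, delta=0).raw == 0

    def test_contiguous_variant_is_a_lower_bound(self, rng):
        for seed in range(10):
            p, q = random_pair(seed, max_len=10)
            sub = lcss(p, q, epsilon=1.0).raw
            run = lcss(p, q, epsilon=1.0, contiguous=True).raw
            assert run <= sub

    def test_epsilon_must_be_positive(self, rng):
        p = random_trajectory(rng, 3)
        with pytest.raises(ValueError, match="epsilon"):
            lcss(p, p, epsilon=0.0)


class TestCouplings:
    def test_frechet_witness_achieves_value(self, rng):
        p, q = random_trajectory(rng, 7), random_trajectory(rng, 9)
        res = discrete_frechet(p, q, return_coupling=True)
        assert res.coupling.is_monotone(7, 9)
        d = np.linalg.norm(p.coords[:, None] - q.coords[None], axis=2)
        assert max(d[i, j] for i, j in res.coupling.pairs) == pytest.approx(res.value)

    def test_dtw_witness_achieves_value(self, rng):
        p, q = random_trajectory(rng, 6), random_trajectory(rng, 8)
        res = dtw(p, q, return_coupling=True)
        assert res.coupling.is_monotone(6, 8)
        d = np.linalg.norm(p.coords[:, None] - q.coords[None], axis=2)
        assert sum(d[i, j] for i, j in res.coupling.pairs) == pytest.approx(res.value)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_dp_equals_exhaustive_enumeration(self, seed):
        p, q = random_pair(seed, max_len=6)
        assert discrete_frechet(p, q).value == pytest.approx(
            oracle_coupling_search(p, q, "max"), abs=1e-12
        )
        assert dtw(p, q).value == pytest.approx(
            oracle_coupling_search(p, q, "sum"), abs=1e-12
        )
        eps = 0.5 + (seed % 5) * 0.4
        assert lcss(p, q, epsilon=eps).raw == oracle_coupling_search(
            p, q, "lcss", {"epsilon": eps}
        )

    @pytest.mark.parametrize("seed", range(30))
    def test_weak_frechet_equals_reachability_oracle(self, seed):
        p, q = random_pair(seed, max_len=12)
        assert weak_frechet(p, q).value == pytest.approx(
            weak_frechet_oracle(p, q), abs=1e-12
        )

    def test_oracle_size_guard(self, rng):
        big = random_trajectory(rng, 9)
        with pytest.raises(ValueError, match="length"):
            oracle_coupling_search(big, big, "max")


class TestErrors:
    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hausdorff(np.empty((0, 3)), np.zeros((1, 3)))

    def test_kld_mismatched_edges(self, rng):
        p, q = random_trajectory(rng, 10), random_trajectory(rng, 10)
        dp, _ = pair_distributions(p, q, bins=5)
        _, dq = pair_distributions(p, Trajectory(q.coords * 2), bins=5)
        with pytest.raises(ValueError, match="bin edges"):
            kld(dp, dq)

    def test_ddm_site_mismatch(self, rng):
        a = StructureEnsemble(rng.normal(size=(2, 4, 3)))
        b = StructureEnsemble(rng.normal(size=(2, 5, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            ddm(a, b)

    def test_unknown_measure(self, rng):
        p = random_trajectory(rng, 3)
        with pytest.raises(ValueError, match="unknown measure"):
            compare(p, p, "euclid")
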