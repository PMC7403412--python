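import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spermqpi.types import WrappedPhase
from spermqpi.unwrap import (
    compute_residues,
    integrate,
    place_branch_cuts,
    unwrap_goldstein,
    wrap,
)

TWO_PI = 2 * np.pi


def wrapped_of(values):
    return WrappedPhase(values=wrap(values), pixel_pitch=0.108)


def brute_force_residues(w: np.ndarray):
    """Independent oracle: explicit loop integral over every 2x2 loop."""
    out = {}
    for i in range(w.shape[0] - 1):
        for j in range(w.shape[1] - 1):
            loop = [w[i, j], w[i, j + 1], w[i + 1, j + 1], w[i + 1, j], w[i, j]]
            s = 0.0
            for a, b in zip(loop[:-1], loop[1:]):
                d = (b - a + np.pi) % TWO_PI - np.pi
                if d == -np.pi:
                    d = np.pi
                s += d
            q = int(round(s / TWO_PI))
            if q:
                out[(i, j)] = q
    return out


def itoh_unwrap(w: np.ndarray) -> np.ndarray:
    """1-D sequential unwrapping, rows then columns — exact without residues."""
    first_col = np.unwrap(w[:, 0])
    rows = np.unwrap(w, axis=1)
    return rows - rows[:, :1] + first_col[:, None]


def smooth_field(seed, n=64, amp=6.0):
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.standard_normal((n, n)), 4.0)
    return amp * f / np.abs(f).max()


def vortex(n=64, yc=31.7, xc=32.3, sign=1):
    y, x = np.mgrid[0:n, 0:n].astype(float)
    return sign * np.arctan2(y - yc, x - xc)


class TestResidues:
    def test_smooth_ramp_has_no_residues(self):
        y, x = np.mgrid[0:64, 0:64].astype(float)
        res = compute_residues(wrapped_of(0.1 * x + 0.05 * y))
        assert len(res) == 0

    def test_single_vortex_carries_unit_charge(self):
        res = compute_residues(wrapped_of(vortex()))
        assert len(res) == 1
        assert res.charges[0] == 1
        # the loop whose 2x2 pixel block contains the vortex center (31.7, 32.3)
        assert tuple(res.positions[0]) == (31, 32)

    def test_vortex_antivortex_pair_is_neutral(self):
        phi = vortex(yc=20.5, xc=20.5) + vortex(yc=43.5, xc=43.5, sign=-1)
        res = compute_residues(wrapped_of(phi))
        assert len(res) == 2
        assert res.total_charge == 0
        assert set(res.charges.tolist()) == {-1, 1}

    @pytest.mark.parametrize("seed", range(10))
    def test_charges_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = wrap(rng.uniform(-4, 4, (24, 24)))
        res = compute_residues(wrapped_of(w))
        oracle = brute_force_residues(wrap(w))
        got = {tuple(p): int(c) for p, c in zip(res.positions, res.charges)}
        assert got == oracle
        assert np.all(np.isin(res.charges, (-1, 1)))


class TestBranchCuts:
    def test_empty_residues_empty_cuts(self):
        res = compute_residues(wrapped_of(np.zeros((32, 32))))
        cuts = place_branch_cuts(res)
        assert cuts.cut_length == 0 and not cuts.segments

    def test_lone_residue_grounds_to_nearest_border(self):
        phi = vortex(n=64, yc=10.2, xc=32.3)  # nearest border: top
        res = compute_residues(wrapped_of(phi))
        assert len(res) == 1
        cuts = place_branch_cuts(res)
        assert len(cuts.segments) == 1
        (r0, c0), (r1, c1) = cuts.segments[0]
        assert r1 == 0 and c1 == c0  # straight up
        assert cuts.cut_length == r0 + 1

    def test_adjacent_pair_joined_by_single_segment(self):
        phi = vortex(n=64, yc=30.5, xc=30.5) + vortex(n=64, yc=30.5, xc=34.5, sign=-1)
        res = compute_residues(wrapped_of(phi))
        assert len(res) == 2 and res.total_charge == 0
        cuts = place_branch_cuts(res)
        assert len(cuts.segments) == 1
        ends = {cuts.segments[0][0], cuts.segments[0][1]}
        assert ends == {tuple(p) for p in res.positions}


class TestIntegrate:
    def test_residue_free_ramp_exact(self):
        y, x = np.mgrid[0:64, 0:64].astype(float)
        true = 0.3 * x + 0.17 * y
        w = wrapped_of(true)
        out, conf = integrate(w, None, (0, 0))
        assert conf.all()
        d = out.values - true
        assert np.ptp(d) < 1e-9  # equal up to a constant

    def test_congruence_modulo_two_pi(self):
        rng = np.random.default_rng(3)
        w = wrapped_of(rng.uniform(-3, 3, (32, 32)))
        res = compute_residues(w)
        cuts = place_branch_cuts(res)
        sr, sc = 0, 0
        while cuts.mask[sr, sc]:
            sc += 1
        out, _ = integrate(w, cuts, (sr, sc))
        k = (out.values - w.values) / TWO_PI
        assert np.abs(k - np.rint(k)).max() < 1e-9

    def test_seed_on_cut_rejected(self):
        phi = vortex(n=32, yc=4.5, xc=15.5)
        w = wrapped_of(phi)
        cuts = place_branch_cuts(compute_residues(w))
        r, c = np.argwhere(cuts.mask)[0]
        with pytest.raises(ValueError, match="seed"):
            integrate(w, cuts, (int(r), int(c)))

    @pytest.mark.parametrize("seed", range(5))
    def test_goldstein_equals_itoh_on_residue_free_fields(self, seed):
        phi = smooth_field(seed)
        w = wrapped_of(phi)
        assert len(compute_residues(w)) == 0
        gold, _ = unwrap_goldstein(w)
        itoh = itoh_unwrap(w.values)
        d = gold.values - itoh
        assert np.ptp(d) < 1e-9
        piston = d.mean() / TWO_PI
        assert abs(piston - round(piston)) < 1e-9

    def test_path_independence_from_random_seeds(self):
        phi = smooth_field(11)
        w = wrapped_of(phi)
        rng = np.random.default_rng(0)
        ref, _ = integrate(w, None, (0, 0))
        for _ in range(10):
            r = int(rng.integers(0, 64))
            c = int(rng.integers(0, 64))
            out, _ = integrate(w, None, (r, c))
            d = out.values - ref.values
            assert np.ptp(d) < 1e-9


class TestGoldstein:
    def test_all_zero_input(self):
        out, rep = unwrap_goldstein(wrapped_of(np.zeros((32, 32))))
        assert not out.values.any()
        assert rep.residue_count == 0 and rep.cut_length == 0
        assert rep.low_confidence_fraction == 0.0

    def test_pure_noise_reports_dense_residues(self):
        rng = np.random.default_rng(21)
        w = wrapped_of(rng.uniform(-np.pi + 1e-9, np.pi, (64, 64)))
        out, rep = unwrap_goldstein(w)
        assert rep.residue_count > 0
        # dense residues: well above 1 per kilopixel
        assert rep.residue_count / (64 * 64 / 1000) > 10

    def test_recovers_smooth_field_exceeding_2pi_range(self):
        phi = smooth_field(5, amp=9.0)
        out, rep = unwrap_goldstein(wrapped_of(phi))
        d = out.values - phi
        assert np.ptp(d) < 1e-9

    def test_reproducible(self):
        phi = smooth_field(7) + vortex(yc=20.4, xc=40.6)
        w = wrapped_of(phi)
        a, ra = unwrap_goldstein(w)
        b, rb = unwrap_goldstein(w)
        assert np.array_equal(a.values, b.values)
        assert ra == rb


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_wrap_into_half_open_interval(seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-50, 50, 100)
    w = wrap(x)
    assert np.all(w > -np.pi) and np.all(w <= np.pi)
    k = (x - w) / TWO_PI
    assert np.abs(k - np.rint(k)).max() < 1e-6


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_residue_charges_always_unit(seed):
    rng = np.random.default_rng(seed)
    w = wrapped_of(rng.uniform(-6, 6, (16, 16)))
    res = compute_residues(w)
    if len(res):
        assert np.all(np.isin(res.charges, (-1, 1)))
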