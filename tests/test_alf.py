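"""Bias family, profile estimation, and the adaptive flattening loop."""

import numpy as np
import pytest

from mslambda import (
    KB,
    AlchemicalTopology,
    BiasParameters,
    FlatteningPhase,
    FlatteningSchedule,
    LambdaState,
    LambdaTrajectory,
    SamplerSettings,
    Site,
    ValidationError,
    alf_flatten,
    bias_energy,
    estimate_profile,
    quadrature_dg,
    update_bias,
)
from mslambda.schemes import MutationSpec, build_scheme

from conftest import random_lambda

kT = KB * 298.0


def brute_force_bias(lam, bias):
    """Independent nested-loop evaluation of V_bias."""
    topo = bias.topology
    v = 0.0
    for s in range(topo.n_sites):
        for i in range(topo.sites[s].n):
            v -= bias.linear[topo.coord_index(s, i)] * lam[topo.coord_index(s, i)]
            for j in range(topo.sites[s].n):
                if i != j:
                    a, b = topo.coord_index(s, i), topo.coord_index(s, j)
                    v += bias.intra_quad[a, b] * lam[a] * lam[b]
    seen = set()
    for s, t in topo.pairing.items():
        if (t, s) in seen:
            continue
        seen.add((s, t))
        for i in range(topo.sites[s].n):
            for j in range(topo.sites[t].n):
                a, b = topo.coord_index(s, i), topo.coord_index(t, j)
                v -= bias.inter_coupling[a, b] * lam[a] * lam[b]
    return v


def paired_topology():
    build = build_scheme(MutationSpec("GGTCAA", ("GATCAA",), scheme="two_lambda"))
    return build.topology


class TestBiasEnergy:
    def test_null_bias_is_zero(self, one_site_topology):
        bias = BiasParameters.zeros(one_site_topology)
        for x in (0.0, 0.3, 1.0):
            lam = LambdaState(one_site_topology, np.array([x, 1 - x]))
            assert bias_energy(lam, bias) == 0.0

    def test_vertex_reduction_with_coupling(self):
        topo = paired_topology()
        n = topo.n_coords
        psi = np.zeros((n, n))
        a, b = topo.coord_index(0, 1), topo.coord_index(1, 1)
        psi[a, b] = psi[b, a] = 1.4
        linear = np.arange(n, dtype=float) * 0.1
        bias = BiasParameters(topo, linear=linear, inter_coupling=psi)
        lam = LambdaState(topo, topo.vertex_lambda((1, 1)))
        expected = -linear[a] - linear[b] - 1.4
        assert bias_energy(lam, bias) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(3000 + seed)
        topo = paired_topology()
        n = topo.n_coords
        intra = np.zeros((n, n))
        for s in range(topo.n_sites):
            sl = topo.site_slice(s)
            block = rng.normal(0, 1, (2, 2))
            block = block + block.T
            np.fill_diagonal(block, 0.0)
            intra[sl, sl] = block
        psi = np.zeros((n, n))
        for pos in range(topo.n_sites // 2):
            a = topo.coord_index(2 * pos, 1)
            b = topo.coord_index(2 * pos + 1, 1)
            psi[a, b] = psi[b, a] = rng.normal()
        bias = BiasParameters(topo, linear=rng.normal(0, 1, n), intra_quad=intra, inter_coupling=psi)
        for _ in range(12):
            lam = random_lambda(topo, rng)
            got = bias_energy(LambdaState(topo, lam), bias)
            assert got == pytest.approx(brute_force_bias(lam, bias), abs=1e-10)

    def test_psi_on_unpaired_sites_rejected(self):
        topo = AlchemicalTopology([Site("a", ("A", "C")), Site("b", ("G", "T"))])
        psi = np.zeros((4, 4))
        psi[1, 3] = psi[3, 1] = 1.0
        with pytest.raises(ValidationError):
            BiasParameters(topo, inter_coupling=psi)

    def test_psi_reference_rows_must_vanish(self):
        topo = paired_topology()
        psi = np.zeros((topo.n_coords, topo.n_coords))
        a = topo.coord_index(0, 0)  # reference substituent
        b = topo.coord_index(1, 1)
        psi[a, b] = psi[b, a] = 1.0
        with pytest.raises(ValidationError):
            BiasParameters(topo, inter_coupling=psi)

    def test_intra_quad_diagonal_must_vanish(self, one_site_topology):
        m = np.eye(2)
        with pytest.raises(ValidationError):
            BiasParameters(one_site_topology, intra_quad=m)


def synthetic_trajectory(topology, lam_values, counts, settings=None):
    """Trajectory whose λ₁ takes each value the given number of times."""
    frames = []
    for v, c in zip(lam_values, counts):
        frames.extend([[v, 1 - v]] * c)
    frames = np.array(frames)
    return LambdaTrajectory(
        topology=topology,
        frames=frames,
        steps=np.arange(1, len(frames) + 1),
        settings=settings,
    )


class TestEstimateProfile:
    def test_uniform_frames_give_flat_values(self, one_site_topology):
        rng = np.random.default_rng(0)
        centers = np.linspace(0.02, 0.98, 25)
        traj = synthetic_trajectory(one_site_topology, centers, [4] * 25)
        prof = estimate_profile(traj, BiasParameters.zeros(one_site_topology), rng=rng)
        assert np.allclose(prof.values[0], 0.0, atol=1e-12)
        assert not prof.degenerate

    def test_two_bin_closed_form(self, one_site_topology):
        rng = np.random.default_rng(0)
        traj = synthetic_trajectory(one_site_topology, [0.02, 0.98], [100, 10])
        prof = estimate_profile(traj, BiasParameters.zeros(one_site_topology), rng=rng)
        occ = ~prof.empty[0]
        vals = prof.values[0][occ]
        assert vals.max() - vals.min() == pytest.approx(kT * np.log(10), abs=1e-10)

    def test_constant_frames_zero_bootstrap_se(self, one_site_topology):
        rng = np.random.default_rng(0)
        traj = synthetic_trajectory(one_site_topology, [0.5], [200])
        prof = estimate_profile(traj, BiasParameters.zeros(one_site_topology), rng=rng)
        occ = ~prof.empty[0]
        assert prof.degenerate
        assert np.allclose(prof.se[0][occ], 0.0)

    def test_empty_bins_flagged_not_imputed(self, one_site_topology):
        rng = np.random.default_rng(0)
        traj = synthetic_trajectory(one_site_topology, [0.02, 0.98], [50, 50])
        prof = estimate_profile(traj, BiasParameters.zeros(one_site_topology), rng=rng)
        assert prof.empty[0][12]
        assert np.isnan(prof.values[0][12])

    def test_linear_bias_is_subtracted(self, one_site_topology):
        rng = np.random.default_rng(0)
        traj = synthetic_trajectory(one_site_topology, [0.02, 0.98], [100, 100])
        bias = BiasParameters(one_site_topology, linear=np.array([0.0, 1.0]))
        prof = estimate_profile(traj, bias, rng=rng)
        occ = ~prof.empty[1]
        vals = prof.values[1][occ]
        # equal sampled populations under b₂ = 1 mean the unbiased landscape
        # rises by b₂·Δλ across the λ₂ coordinate (bin centers 0.02 → 0.98)
        assert vals[-1] - vals[0] == pytest.approx(0.96, abs=1e-9)


class TestUpdateBias:
    def test_measure_distributed_frames_are_a_fixed_point(self, one_site_topology):
        """Frames drawn from the transform's own geometric measure leave the
        bias (statistically) unchanged."""
        rng = np.random.default_rng(7)
        k, alpha = 0.3, 5.5
        d = rng.normal(0.0, np.sqrt(2 * kT / k), size=20_000)
        lam1 = 1.0 / (1.0 + np.exp(-alpha * d))
        frames = np.column_stack([lam1, 1 - lam1])
        traj = LambdaTrajectory(
            topology=one_site_topology, frames=frames,
            steps=np.arange(1, len(frames) + 1),
        )
        bias = BiasParameters.zeros(one_site_topology)
        prof = estimate_profile(traj, bias, rng=rng)
        new = update_bias(prof, bias, damping=1.0)
        assert np.max(np.abs(new.linear)) < 0.1
        assert np.max(np.abs(new.intra_quad)) < 0.2

    def test_endpoint_difference_drives_linear_update(self, one_site_topology):
        rng = np.random.default_rng(0)
        n_lo, n_hi = 2000, 68  # kT ln(2000/68) ≈ 2 kcal/mol
        traj = synthetic_trajectory(one_site_topology, [0.01, 0.99], [n_lo, n_hi])
        bias = BiasParameters.zeros(one_site_topology)
        prof = estimate_profile(traj, bias, rng=rng)
        new = update_bias(prof, bias, damping=1.0, cap=5.0)
        # λ₁ = 0.99 is the rare well, so substituent 1 is the disfavored one
        expected = kT * np.log(n_lo / n_hi)
        assert new.linear[0] == pytest.approx(expected, abs=1e-9)
        assert new.linear[1] == pytest.approx(-expected, abs=1e-9)

    def test_increment_is_clipped_at_cap(self, one_site_topology):
        rng = np.random.default_rng(0)
        traj = synthetic_trajectory(one_site_topology, [0.01, 0.99], [2000, 68])
        bias = BiasParameters.zeros(one_site_topology)
        prof = estimate_profile(traj, bias, rng=rng)
        new = update_bias(prof, bias, damping=1.0, cap=1.5)
        assert new.linear[0] == pytest.approx(1.5, abs=1e-12)

    def test_unobservable_wells_leave_bias_unchanged(self, one_site_topology):
        rng = np.random.default_rng(0)
        traj = synthetic_trajectory(one_site_topology, [0.5], [100])
        bias = BiasParameters(one_site_topology, linear=np.array([0.4, -0.4]))
        prof = estimate_profile(traj, bias, rng=rng)
        new = update_bias(prof, bias)
        assert new.no_update
        assert np.array_equal(new.linear, bias.linear)

    def test_input_bias_not_modified(self, one_site_topology):
        rng = np.random.default_rng(0)
        traj = synthetic_trajectory(one_site_topology, [0.01, 0.99], [500, 100])
        bias = BiasParameters.zeros(one_site_topology)
        prof = estimate_profile(traj, bias, rng=rng)
        update_bias(prof, bias)
        assert np.array_equal(bias.linear, np.zeros(2))

    def test_damping_must_be_in_unit_interval(self, one_site_topology):
        rng = np.random.default_rng(0)
        traj = synthetic_trajectory(one_site_topology, [0.01, 0.99], [100, 100])
        bias = BiasParameters.zeros(one_site_topology)
        prof = estimate_profile(traj, bias, rng=rng)
        with pytest.raises(ValidationError):
            update_bias(prof, bias, damping=0.0)


class TestAlfFlatten:
    def test_symmetric_system_keeps_small_bias(self, symmetric_pair, quick_settings):
        bias, log = alf_flatten(
            symmetric_pair.topology, symmetric_pair.bound,
            FlatteningSchedule.quick(), quick_settings, seed=5,
        )
        final = log[-1].profile
        se_end = np.sqrt(np.nansum(final.se[:, [0, -1]] ** 2, axis=1))
        assert np.all(np.abs(bias.linear) < np.maximum(3 * se_end, 0.6))

    def test_gap_recovery_against_quadrature(self, gapped_pair, quick_settings):
        diffs = []
        for seed in (1, 2, 3):
            bias, _ = alf_flatten(
                gapped_pair.topology, gapped_pair.bound,
                FlatteningSchedule.quick(), quick_settings, seed=seed,
            )
            diffs.append(bias.linear[1] - bias.linear[0])
        oracle = quadrature_dg(gapped_pair.bound, gapped_pair.topology)["GATCAA"]
        assert abs(np.median(diffs) - oracle) < 0.3

    def test_flattening_balances_endstate_populations(self, gapped_pair, quick_settings):
        from mslambda import assign_endstates, run_trajectory

        bias, _ = alf_flatten(
            gapped_pair.topology, gapped_pair.bound,
            FlatteningSchedule.quick(), quick_settings, seed=11,
        )
        settings = quick_settings.with_(n_steps=200_000, seed=404)
        traj = run_trajectory(gapped_pair.topology, gapped_pair.bound, bias, settings)
        ser = assign_endstates(traj)
        counts = {}
        for lab in ser.labels:
            if lab is not None:
                counts[lab] = counts.get(lab, 0) + 1
        ratio = counts["GGTCAA"] / counts["GATCAA"]
        assert 0.5 < ratio < 2.0

    def test_imbalance_shrinks_over_iterations(self, gapped_pair, quick_settings):
        _, log = alf_flatten(
            gapped_pair.topology, gapped_pair.bound,
            FlatteningSchedule.quick(), quick_settings, seed=2,
        )
        first = [e.imbalance for e in log[:3] if np.isfinite(e.imbalance)]
        last = [e.imbalance for e in log[-3:] if np.isfinite(e.imbalance)]
        assert np.median(np.abs(last)) < np.median(np.abs(first))

    def test_reproducible_from_seed(self, gapped_pair, quick_settings):
        sched = FlatteningSchedule(
            (FlatteningPhase(2, 2000), FlatteningPhase(1, 5000, production=True))
        )
        a, _ = alf_flatten(gapped_pair.topology, gapped_pair.bound, sched, quick_settings, seed=3)
        b, _ = alf_flatten(gapped_pair.topology, gapped_pair.bound, sched, quick_settings, seed=3)
        assert np.array_equal(a.linear, b.linear)
        assert np.array_equal(a.intra_quad, b.intra_quad)

    def test_schedule_requires_production_phase(self):
        with pytest.raises(ValidationError):
            FlatteningSchedule((FlatteningPhase(2, 1000),))

    def test_idempotent_at_convergence(self, gapped_pair, quick_settings):
        sched = FlatteningSchedule.quick()
        bias, _ = alf_flatten(
            gapped_pair.topology, gapped_pair.bound, sched, quick_settings, seed=6
        )
        restart = FlatteningSchedule((FlatteningPhase(2, 20_000, production=True),))
        bias2, _ = alf_flatten(
            gapped_pair.topology, gapped_pair.bound, restart, quick_settings,
            seed=7, initial_bias=bias, reset=False,
        )
        # continuing from a converged bias should only move coefficients
        # within the per-run estimation noise
        assert abs(
            (bias2.linear[1] - bias2.linear[0]) - (bias.linear[1] - bias.linear[0])
        ) < 0.5
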