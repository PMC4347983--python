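import numpy as np
import pytest

from kinteam.chemistry import ChemicalState
from kinteam.engine import (
    SimulationConfig,
    init_state,
    run_ensemble,
    run_transport,
    step,
)

UNBIND_KINDS = ("unbind_D0", "unbind_D1", "unbind_eq")


def mean_bound_number(result) -> float:
    """Time-averaged number of bound motors from the event log."""
    bound = {0}
    t_prev = 0.0
    integral = 0.0
    for t, i, kind, _ in result.events:
        integral += len(bound) * (t - t_prev)
        t_prev = t
        if kind == "rebind":
            bound.add(i)
        elif kind in UNBIND_KINDS:
            bound.discard(i)
    return integral / t_prev if t_prev > 0 else 1.0


class TestInitState:
    def test_single_motor(self):
        s = init_state(SimulationConfig(n_kinesins=1, seed=0))
        assert sum(m.bound for m in s.motors) == 1

    def test_team_starts_with_one_bound(self):
        s = init_state(SimulationConfig(n_kinesins=3, seed=0))
        assert sum(m.bound for m in s.motors) == 1
        assert s.motors[0].bound and s.motors[0].site == 0
        assert s.motors[0].state is ChemicalState.K_MT
        assert all(m.state is ChemicalState.UNBOUND for m in s.motors[1:])

    def test_cargo_starts_at_equilibrium(self, mech):
        s = init_state(SimulationConfig(n_kinesins=1, F_L=3.0, seed=0))
        assert s.x_c == pytest.approx(-mech.L_c - 3.0 / mech.K_e)

    @pytest.mark.parametrize("n", [0, 6])
    def test_team_size_bounds_enforced(self, n):
        with pytest.raises(ValueError):
            SimulationConfig(n_kinesins=n)

    def test_large_team_override(self):
        cfg = SimulationConfig(n_kinesins=7, allow_large_teams=True)
        assert len(init_state(cfg).motors) == 7

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=1e-2, dt_rebind=1e-3)


class TestDeterminism:
    def test_identical_seeds_identical_logs(self):
        cfg = lambda: SimulationConfig(n_kinesins=2, F_L=4.0, seed=99, dt=1e-3)
        r1 = run_transport(cfg())
        r2 = run_transport(cfg())
        assert r1.events == r2.events
        assert r1.run_length == r2.run_length

    def test_different_seeds_differ(self):
        r1 = run_transport(SimulationConfig(n_kinesins=1, seed=1, dt=1e-3))
        r2 = run_transport(SimulationConfig(n_kinesins=1, seed=2, dt=1e-3))
        assert r1.events != r2.events


class TestStepping:
    def test_step_advances_time(self):
        s = init_state(SimulationConfig(n_kinesins=1, seed=0))
        t0 = s.t
        step(s)
        assert s.t == pytest.approx(t0 + s.config.dt)

    def test_anchor_moves_in_8nm_quanta(self):
        r = run_transport(SimulationConfig(n_kinesins=2, F_L=2.0, seed=5, dt=1e-3))
        # reconstruct every anchor trajectory from the event log
        pos = {0: 0.0}
        for t, i, kind, val in r.events:
            if kind == "rebind":
                pos[i] = val * 8.0
            elif kind == "step":
                assert val in (1, -1)
                pos[i] += val * 8.0
                assert pos[i] % 8.0 == 0.0

    def test_zero_atp_never_steps(self):
        cfg = SimulationConfig(n_kinesins=1, ATP_conc=0.0, seed=3, dt=1e-3, t_max=5.0)
        r = run_transport(cfg)
        assert not any(e[2] == "step" for e in r.events)
        assert abs(r.run_length) < 1e-6
        assert r.terminated_by in ("all-unbound", "t_max")
        if r.terminated_by == "all-unbound":
            assert r.events[-1][2] == "unbind_D0"


class TestRunTransport:
    def test_termination_accounting(self):
        r = run_transport(SimulationConfig(n_kinesins=1, seed=8, dt=1e-3))
        assert r.terminated_by == "all-unbound"
        assert r.mean_velocity == pytest.approx(r.run_length / r.duration)
        unbinds = [e for e in r.events if e[2] in UNBIND_KINDS]
        assert len(unbinds) == 1
        assert r.duration == pytest.approx(unbinds[-1][0])

    def test_t_max_cap(self):
        cfg = SimulationConfig(n_kinesins=1, ATP_conc=0.0, seed=1, dt=1e-3, t_max=0.05)
        r = run_transport(cfg)
        assert r.terminated_by in ("t_max", "all-unbound")

    def test_super_stall_runs_backward(self):
        rls = []
        for c in np.random.SeedSequence(17).spawn(25):
            r = run_transport(
                SimulationConfig(n_kinesins=1, F_L=12.0, seed=0, dt=1e-3, t_max=120),
                seed_seq=c,
            )
            rls.append(r.run_length)
        assert np.mean(rls) < 0.0


class TestEnsemble:
    def test_summary_matches_replicates(self):
        cfg = SimulationConfig(n_kinesins=1, seed=31, dt=1e-3)
        results, summary = run_ensemble(cfg, n_reps=12)
        assert summary.n_reps == 12
        assert summary.mean_run_length == pytest.approx(
            np.mean([r.run_length for r in results])
        )
        assert summary.mean_velocity == pytest.approx(
            np.mean([r.mean_velocity for r in results])
        )

    def test_default_replicate_count_is_200(self):
        import inspect

        assert inspect.signature(run_ensemble).parameters["n_reps"].default == 200

    def test_replicates_are_independent(self):
        cfg = SimulationConfig(n_kinesins=1, seed=31, dt=1e-3)
        results, _ = run_ensemble(cfg, n_reps=4)
        lengths = [r.run_length for r in results]
        assert len(set(lengths)) > 1


class TestTeamCooperation:
    def test_two_motors_outrun_one(self):
        means = {}
        for n in (1, 2):
            cfg = SimulationConfig(n_kinesins=n, F_L=0.0, seed=41, dt=1e-3, t_max=120)
            _, s = run_ensemble(cfg, n_reps=40)
            means[n] = (s.mean_run_length, s.se_run_length)
        assert means[2][0] - means[1][0] > 2 * (means[2][1] + means[1][1])

    def test_high_load_anchor_keeps_team_engaged(self):
        """Time-averaged bound number is higher at 12 pN than at 4 pN (HLB)."""
        avg = {}
        for F_L, seed in ((4.0, 51), (12.0, 52)):
            vals = []
            for c in np.random.SeedSequence(seed).spawn(25):
                cfg = SimulationConfig(n_kinesins=2, F_L=F_L, seed=0, dt=1e-3, t_max=60)
                vals.append(mean_bound_number(run_transport(cfg, seed_seq=c)))
            avg[F_L] = np.mean(vals)
        assert avg[12.0] > avg[4.0]
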