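"""Hopping engine: adiabatization, integrators, hops, decoherence."""
import numpy as np
import pytest

from nonrad import models, tsh, units


def make_frame(energies, sigma, vel=1.0, time=0.0, ekin=None):
    """Synthetic 1-DoF frame with scalar coupling sigma = vel * d01."""
    return tsh.AdiabaticFrame(
        R=np.zeros(1),
        vel=np.array([vel]),
        energies=np.asarray(energies, dtype=float),
        grads=np.zeros((2, 1)),
        nacv=np.array([sigma / vel]),
        U=np.eye(2),
        kinetic_energy=0.5 * vel**2 if ekin is None else ekin,
        time=time,
    )


# ----------------------------------------------------------------------
# adiabatize
# ----------------------------------------------------------------------

def test_adiabatize_uncoupled_has_zero_nacv():
    m = models.build_uncoupled_harmonic()
    for x in (-1.0, 0.3, 2.0):
        f = tsh.adiabatize(m, np.array([x]))
        assert f.nacv[0] == pytest.approx(0.0, abs=1e-14)
        assert f.energies[1] >= f.energies[0]


def test_adiabatize_gap_at_crossing_is_twice_coupling(tully_model):
    f = tsh.adiabatize(tully_model, np.array([0.0]))
    assert f.gap == pytest.approx(2 * 0.005)


def test_nacv_matches_eigenvector_finite_difference(tully_model):
    """d01 = <u0 | du1/dx> by central differences of the eigenvectors
    (phase-aligned), within 1e-5."""
    rng = np.random.default_rng(1)
    h = 1e-6
    for _ in range(25):
        x = rng.uniform(-3, 3)
        f = tsh.adiabatize(tully_model, np.array([x]))
        fp = tsh.adiabatize(tully_model, np.array([x + h]), prev=f)
        fm = tsh.adiabatize(tully_model, np.array([x - h]), prev=f)
        du1 = (fp.U[:, 1] - fm.U[:, 1]) / (2 * h)
        d_fd = float(f.U[:, 0] @ du1)
        assert f.nacv[0] == pytest.approx(d_fd, abs=1e-5)


def test_adiabatize_phase_continuity(tully_model):
    xs = np.linspace(-3, 3, 400)
    prev = None
    for x in xs:
        f = tsh.adiabatize(tully_model, np.array([x]), prev=prev)
        if prev is not None:
            assert f.U[:, 0] @ prev.U[:, 0] >= 0
            assert f.U[:, 1] @ prev.U[:, 1] >= 0
        prev = f


# ----------------------------------------------------------------------
# nuclear propagation
# ----------------------------------------------------------------------

def test_free_particle_advances_linearly():
    m = models.build_uncoupled_harmonic(omega=1e-12)  # effectively flat
    cfg = tsh.IntegratorConfig(dt_fs=0.5)
    frame = tsh.adiabatize(m, np.array([0.0]), vel=np.array([0.01]))
    state = tsh.ElectronicState(c=np.array([1.0 + 0j, 0.0]), active=0)
    new = tsh.propagate_nuclei(m, frame, state, cfg)
    assert new.R[0] == pytest.approx(0.01 * cfg.dt, rel=1e-10)


def test_harmonic_energy_drift_and_closed_form():
    """250 fs of velocity Verlet on a soft harmonic surface at a 0.5 fs
    step: energy drift < 1e-6 hartree, position tracks the closed form."""
    m = models.build_uncoupled_harmonic()
    cfg = tsh.IntegratorConfig(dt_fs=0.5, t_max_fs=250.0, stop_on_decay_gap=False)
    v0 = np.sqrt(2 * 1e-3 / 2000.0)  # ~1 mHa of vibrational energy
    traj = tsh.run_trajectory(m, np.array([0.0]), np.array([v0]), cfg, initial_state=0, seed=1)
    e = traj.metadata["total_energy"]
    assert np.abs(e - e[0]).max() < 1e-6
    omega = 3e-3
    x_exact = v0 / omega * np.sin(omega * traj.times)
    amp = v0 / omega
    assert np.abs(traj.positions[:, 0] - x_exact).max() < 0.01 * amp


def test_stiff_constraint_freezes_coordinate(carbonyl_model):
    cfg = tsh.IntegratorConfig(dt_fs=0.1, t_max_fs=50.0)
    con = tsh.ConstraintSpec(coordinate=0, k=1e6)
    pos, vel = models.sample_ground_state(carbonyl_model, 1, seed=2)
    traj = tsh.run_trajectory(carbonyl_model, pos[0], vel[0], cfg, [con], seed=3)
    r = traj.positions[:, 0] * units.BOHR_TO_ANGSTROM
    assert np.var(r) < 1e-6  # A^2


def test_constraint_validation():
    with pytest.raises(ValueError):
        tsh.ConstraintSpec(coordinate=0, k=-1.0)


# ----------------------------------------------------------------------
# electronic propagation
# ----------------------------------------------------------------------

def test_decoupled_coefficients_keep_populations_and_relative_phase():
    e0, e1 = -0.05, 0.07
    cfg = tsh.IntegratorConfig(dt_fs=0.5, n_substeps_electronic=20)
    dt = cfg.dt
    c = np.array([np.sqrt(0.3), np.sqrt(0.7) + 0j])
    state = tsh.ElectronicState(c=c.copy(), active=1)
    n_steps = 40
    for k in range(n_steps):
        prev = make_frame([e0, e1], sigma=0.0, time=k * dt)
        cur = make_frame([e0, e1], sigma=0.0, time=(k + 1) * dt)
        state, p, _ = tsh.propagate_coefficients(state, (prev, cur), cfg)
        assert p == 0.0
    np.testing.assert_allclose(np.abs(state.c), np.abs(c), atol=1e-10)
    # relative phase advances as exp(-i (E1 - E0) t) (global phase is gauge)
    t = n_steps * dt
    rel = (state.c[1] / state.c[0]) / (c[1] / c[0])
    # phase accurate to the integrator order: O((omega h)^5) per substep
    assert rel == pytest.approx(np.exp(-1j * (e1 - e0) * t), abs=2e-5)


def test_rabi_oscillation_matches_closed_form():
    """Degenerate two-level system with constant coupling sigma:
    populations oscillate as cos^2(sigma t), i.e. at frequency 2 sigma."""
    sigma = 0.01
    cfg = tsh.IntegratorConfig(dt_fs=0.5, n_substeps_electronic=20)
    dt = cfg.dt
    state = tsh.ElectronicState(c=np.array([1.0 + 0j, 0.0]), active=0)
    t_final = 10 * np.pi / sigma  # ten population periods
    n_steps = int(t_final / dt)
    worst = 0.0
    for k in range(n_steps):
        prev = make_frame([0.0, 0.0], sigma=sigma, time=k * dt)
        cur = make_frame([0.0, 0.0], sigma=sigma, time=(k + 1) * dt)
        state, _, _ = tsh.propagate_coefficients(state, (prev, cur), cfg)
        expected = np.cos(sigma * (k + 1) * dt) ** 2
        worst = max(worst, abs(abs(state.c[0]) ** 2 - expected))
    assert worst < 1e-4


def test_time_reversal_recovers_coefficients():
    """Reversing velocities and conjugating the amplitudes retraces the
    electronic propagation (unitarity/symmetry)."""
    rng = np.random.default_rng(8)
    cfg = tsh.IntegratorConfig(dt_fs=0.5, n_substeps_electronic=20)
    dt = cfg.dt
    e_series = 0.05 * rng.standard_normal(30)
    s_series = 0.02 * rng.standard_normal(30)
    c0 = np.array([np.sqrt(0.6), np.sqrt(0.4) * np.exp(0.3j)])
    state = tsh.ElectronicState(c=c0.copy(), active=1)
    frames = [make_frame([-e, e], sigma=s, time=k * dt)
              for k, (e, s) in enumerate(zip(e_series, s_series))]
    for k in range(len(frames) - 1):
        state, _, _ = tsh.propagate_coefficients(state, (frames[k], frames[k + 1]), cfg)
    state = tsh.ElectronicState(c=np.conj(state.c), active=1)
    rev = [make_frame([-e, e], sigma=-s, time=k * dt)
           for k, (e, s) in enumerate(zip(e_series[::-1], s_series[::-1]))]
    for k in range(len(rev) - 1):
        state, _, _ = tsh.propagate_coefficients(state, (rev[k], rev[k + 1]), cfg)
    np.testing.assert_allclose(np.conj(state.c), c0, atol=1e-6)


def test_hop_probability_integrand_value():
    """Direct rectangle-rule evaluation of the hop-probability integrand:
    |c_i| = sqrt(0.8), |c_j| = sqrt(0.2), |sigma| = 0.01, dt = 20.67 a.u.
    gives P = 2 sqrt(0.16) * 0.01 * 20.67 / 0.8."""
    ci, cj = np.sqrt(0.8), np.sqrt(0.2)
    p = tsh.fs_probability_increment(ci, cj, -0.01, 20.67)
    assert p == pytest.approx(2 * np.sqrt(0.16) * 0.01 * 20.67 / 0.8, rel=1e-12)
    # opposite coupling sign gives an (unphysical) negative flux
    assert tsh.fs_probability_increment(ci, cj, +0.01, 20.67) < 0
    # zero target amplitude or tiny active population -> 0
    assert tsh.fs_probability_increment(ci, 0.0, 0.01, 20.67) == 0.0
    assert tsh.fs_probability_increment(1e-9, cj, 0.01, 20.67) == 0.0


def test_hop_probability_zero_for_zero_coupling():
    cfg = tsh.IntegratorConfig()
    state = tsh.ElectronicState(c=np.array([np.sqrt(0.5), np.sqrt(0.5) + 0j]), active=1)
    prev = make_frame([0.0, 0.1], sigma=0.0)
    cur = make_frame([0.0, 0.1], sigma=0.0, time=cfg.dt)
    p = tsh.hop_probability(state, (prev, cur), cfg)
    assert p[0] == 0.0 and p[1] == 0.0


# ----------------------------------------------------------------------
# hops and decoherence
# ----------------------------------------------------------------------

def test_attempt_hop_rejection_branch():
    cfg = tsh.IntegratorConfig(forbid_recrossing=False)
    frame = make_frame([0.0, 0.05], sigma=0.01, vel=1.0)
    state = tsh.ElectronicState(c=np.array([0.6 + 0j, 0.8]), active=1)
    new, rec = tsh.attempt_hop(0.3, 0.9, frame, state, np.array([2000.0]), cfg)
    assert new.active == 1 and rec is None


def test_downward_hop_conserves_total_energy(tully_model):
    cfg = tsh.IntegratorConfig(forbid_recrossing=False)
    frame = tsh.adiabatize(tully_model, np.array([0.1]), vel=np.array([0.01]))
    state = tsh.ElectronicState(c=np.array([0.6 + 0j, 0.8]), active=1)
    before = frame.energies[1] + frame.kinetic_energy
    new, rec = tsh.attempt_hop(0.9, 0.1, frame, state, tully_model.masses, cfg)
    assert new.active == 0 and rec == {"frustrated": False, "from": 1, "to": 0}
    after = frame.energies[0] + frame.kinetic_energy
    assert after == pytest.approx(before, abs=1e-8)


def test_frustrated_upward_hop_leaves_state_and_velocity():
    cfg = tsh.IntegratorConfig(forbid_recrossing=False)
    # tiny kinetic energy, large gap -> energetically forbidden
    frame = make_frame([0.0, 0.5], sigma=0.01, vel=1e-4, ekin=0.5 * 2000 * 1e-8)
    v_before = frame.vel.copy()
    state = tsh.ElectronicState(c=np.array([0.8 + 0j, 0.6]), active=0)
    new, rec = tsh.attempt_hop(0.99, 0.0, frame, state, np.array([2000.0]), cfg)
    assert new.active == 0
    assert rec["frustrated"]
    np.testing.assert_array_equal(frame.vel, v_before)


def test_recrossing_forbidden_from_ground_state():
    cfg = tsh.IntegratorConfig(forbid_recrossing=True)
    frame = make_frame([0.0, 0.01], sigma=0.05, vel=1.0)
    state = tsh.ElectronicState(c=np.array([0.6 + 0j, 0.8]), active=0)
    new, rec = tsh.attempt_hop(0.99, 0.0, frame, state, np.array([2000.0]), cfg)
    assert new.active == 0 and rec is None


def test_decoherence_time_closed_form():
    """tau = (1/|dE|)(1 + C/E_kin) = 30 a.u. for dE = 0.1, C = 0.1,
    E_kin = 0.05; inactive amplitude damps by exp(-dt/tau)."""
    params = tsh.DecoherenceParams(C=0.1)
    frame = make_frame([0.0, 0.1], sigma=0.0, ekin=0.05)
    c = np.array([np.sqrt(0.3), np.sqrt(0.7) + 0j])
    state = tsh.ElectronicState(c=c.copy(), active=1)
    dt = 3.0
    new = tsh.apply_decoherence(state, frame, params, dt)
    tau = 30.0
    expected_p0 = 0.3 * np.exp(-2 * dt / tau)
    assert abs(new.c[0]) ** 2 == pytest.approx(expected_p0, rel=1e-12)
    assert abs(new.c[0]) ** 2 + abs(new.c[1]) ** 2 == pytest.approx(1.0, abs=1e-12)


def test_decoherence_vanishes_at_degeneracy():
    params = tsh.DecoherenceParams(C=0.1)
    frame = make_frame([0.0, 1e-9], sigma=0.0, ekin=0.05)
    c = np.array([np.sqrt(0.3), np.sqrt(0.7) + 0j])
    state = tsh.ElectronicState(c=c.copy(), active=1)
    new = tsh.apply_decoherence(state, frame, params, 20.0)
    assert abs(new.c[0]) ** 2 == pytest.approx(0.3, rel=1e-6)


def test_decoherence_disabled_is_identity():
    params = tsh.DecoherenceParams(C=0.1, enabled=False)
    frame = make_frame([0.0, 0.1], sigma=0.0, ekin=0.05)
    c = np.array([np.sqrt(0.3), np.sqrt(0.7) + 0j])
    state = tsh.ElectronicState(c=c.copy(), active=1)
    new = tsh.apply_decoherence(state, frame, params, 20.0)
    np.testing.assert_array_equal(new.c, c)


# ----------------------------------------------------------------------
# trajectory drivers
# ----------------------------------------------------------------------

def test_uncoupled_model_never_decays():
    m = models.build_uncoupled_harmonic(gap=0.5)
    cfg = tsh.IntegratorConfig(dt_fs=0.5, t_max_fs=50.0)
    traj = tsh.run_trajectory(m, np.array([0.1]), np.array([0.0]), cfg, seed=4)
    assert not traj.decayed
    assert traj.active[-1] == 1
    assert traj.times_fs[-1] == pytest.approx(50.0, abs=0.5)


def test_same_seed_reproduces_trajectory(carbonyl_model):
    cfg = tsh.IntegratorConfig(t_max_fs=60.0, seed=5)
    pos, vel = models.sample_ground_state(carbonyl_model, 1, seed=6)
    a = tsh.run_trajectory(carbonyl_model, pos[0], vel[0], cfg)
    b = tsh.run_trajectory(carbonyl_model, pos[0], vel[0], cfg)
    assert a.hops == b.hops
    np.testing.assert_array_equal(a.positions, b.positions)
    np.testing.assert_array_equal(a.coeffs, b.coeffs)


def test_trajectory_consistency_and_gap_stop(carbonyl_model):
    cfg = tsh.IntegratorConfig(seed=7)
    pos, vel = models.sample_ground_state(carbonyl_model, 4, seed=8)
    for k in range(4):
        t = tsh.run_trajectory(carbonyl_model, pos[k], vel[k], cfg, seed=100 + k)
        t.validate()
        if t.decayed:
            # stopped at the crossing: final frame on the ground state
            # within the gap criterion
            assert t.active[-1] == 0
            assert t.gap_ev[-1] < cfg.gap_stop_ev or t.n_frames - 1 == 500


def test_unitarity_on_scattering_run(tully_model):
    """Norm drift before renormalization stays below 1e-8 per step."""
    au = units.AU_TIME_TO_FS
    cfg = tsh.IntegratorConfig(
        dt_fs=2.0 * au, n_substeps_electronic=6, t_max_fs=3000 * au,
        stop_on_decay_gap=False, forbid_recrossing=False, exit_abs_position=14.0,
    )
    traj = tsh.run_trajectory(
        tully_model, np.array([-8.0]), np.array([0.01]), cfg, initial_state=0, seed=9
    )
    assert traj.metadata["max_norm_drift"] < 1e-8
    assert traj.metadata["norm_warnings"] == 0


def test_swarm_determinism_and_constraint_noop(carbonyl_model):
    cfg = tsh.IntegratorConfig(t_max_fs=40.0, seed=10)
    pos, vel = models.sample_ground_state(carbonyl_model, 3, seed=11)
    a = tsh.run_swarm(carbonyl_model, (pos, vel), cfg)
    b = tsh.run_swarm(carbonyl_model, (pos, vel), cfg, constraints=[])
    for ta, tb in zip(a, b):
        np.testing.assert_array_equal(ta.positions, tb.positions)
        assert ta.hops == tb.hops


def test_swarm_decay_fraction_regression():
    """Frozen regression value for the weak-lock swarm (200 seeds): the
    decay fraction stays inside a 95% binomial band around 0.73."""
    m = models.build_carbonyl_lock_model(models.CarbonylLockParams(k_lock=0.02))
    pos, vel = models.sample_ground_state(m, 200, seed=77)
    swarm = tsh.run_swarm(m, (pos, vel), tsh.IntegratorConfig(seed=909))
    frac = sum(t.decayed for t in swarm) / len(swarm)
    ref = 0.73
    band = 1.96 * np.sqrt(ref * (1 - ref) / 200)
    assert abs(frac - ref) <= band
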