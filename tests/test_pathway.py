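"""Relaxation-coordinate estimator: gap swap, pooling, recovery, bounds."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_toy_trajectory
from nonrad import mockdimer as md, pathway as pw
from nonrad.geometry import CoordinateDefinition, Structure
from nonrad.trajectory import Trajectory


def test_gap_swap_sign_series():
    gaps = np.linspace(4.0, 1.0, 100)
    traj = make_toy_trajectory(gaps, crossing=50)
    d = pw.reconstruct_diabatic_gap(traj)
    np.testing.assert_allclose(d[:50], gaps[:50])
    np.testing.assert_allclose(d[50:], -gaps[50:])
    signs = np.sign(-d)
    assert np.all(signs[:50] == -1) and np.all(signs[50:] == 1)


def test_gap_without_crossing_stays_adiabatic():
    gaps = np.full(30, 2.5)
    traj = make_toy_trajectory(gaps)
    d = pw.reconstruct_diabatic_gap(traj)
    assert np.all(d > 0)
    np.testing.assert_allclose(d, gaps)


def test_crossing_frame_assigned_to_swapped_side():
    traj = make_toy_trajectory([3.0, 1.0, 0.05, 1.0], crossing=2)
    d = pw.reconstruct_diabatic_gap(traj)
    assert d[2] < 0  # the exact-crossing frame is on the post-crossing side


def test_pool_requires_decaying_trajectories():
    traj = make_toy_trajectory(np.full(20, 2.0))
    with pytest.raises(ValueError, match="admitted"):
        pw.pool_ensemble([traj], pw.PathwayConfig())
    ens = pw.pool_ensemble([traj], pw.PathwayConfig(include_nondecaying=True))
    assert ens.n_frames == 20


def test_pool_static_trajectory_has_zero_fluctuations():
    traj = make_toy_trajectory(np.full(25, 2.0), values=np.full(25, 1.3))
    ens = pw.pool_ensemble([traj], pw.PathwayConfig(include_nondecaying=True))
    assert np.abs(ens.fluctuations).max() == pytest.approx(0.0, abs=1e-12)
    assert np.abs(ens.fluctuations.mean(axis=0)).max() < 1e-10


def test_provenance_covers_every_frame_once():
    trajs = md.generate_mock_dimer_trajectories(md.MockDimerSpec(seed=8, n_frames=60), 4)
    ens = pw.pool_ensemble(trajs)
    assert sum(n for _, n in ens.provenance) == ens.n_frames
    assert [i for i, _ in ens.provenance] == [0, 1, 2, 3]


def test_alignment_noop_for_drift_free_frames():
    """With no global rotation planted, aligned and unaligned vectors agree
    (alignment corrections are second order in the displacements)."""
    trajs = md.generate_mock_dimer_trajectories(md.MockDimerSpec(seed=10), 20)
    on = pw.relaxation_vector(pw.pool_ensemble(trajs, pw.PathwayConfig(align=True)))
    off = pw.relaxation_vector(pw.pool_ensemble(trajs, pw.PathwayConfig(align=False)),
                               pw.PathwayConfig(align=False))
    assert on.cosine_to(off.c) > 1 - 1e-8
    xy = np.ones(36, bool); xy[2::3] = False  # see CLI test: z is frozen
    assert np.abs(on.c[xy] - off.c[xy]).max() < 1e-5


def test_constant_coordinate_component_is_zero():
    rng = np.random.default_rng(0)
    n = 400
    f = rng.normal(0, 0.1, (n, 6))
    f[:, 2] = 0.0
    gaps = np.abs(rng.normal(1.0, 0.3, n))
    ens = pw.PooledEnsemble(
        fluctuations=f - f.mean(axis=0), deltaE_D=gaps, means=f.mean(axis=0),
        provenance=[(0, n)],
    )
    vec = pw.relaxation_vector(ens)
    assert vec.c[2] == 0.0


@settings(deadline=None, max_examples=100, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_components_bounded_by_one(seed):
    """Every component is a weight-normalized correlation: |c_i| <= 1
    (Cauchy-Schwarz), on arbitrary random ensembles."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 200))
    k = int(rng.integers(1, 8))
    f = rng.normal(0, rng.uniform(0.01, 10.0), (n, k))
    f -= f.mean(axis=0)
    gaps = rng.normal(0, 3.0, n)  # signed, arbitrary
    ens = pw.PooledEnsemble(fluctuations=f, deltaE_D=gaps, means=np.zeros(k),
                            provenance=[(0, n)])
    vec = pw.relaxation_vector(ens)
    assert np.all(np.abs(vec.c) <= 1.0 + 1e-12)


def test_planted_mode_recovery_and_sign():
    """The estimator recovers the planted Cartesian decay direction with
    positive orientation (excited -> ground configurations)."""
    spec = md.MockDimerSpec(seed=10)
    trajs = md.generate_mock_dimer_trajectories(spec, 25)
    vec = pw.relaxation_vector(pw.pool_ensemble(trajs))
    cos = vec.cosine_to(md.planted_direction(spec))
    assert cos >= 0.9  # signed cosine: orientation matters


def test_alpha_stability():
    """Doubling the Arrhenius width changes the recovered direction by
    less than 0.05 in cosine."""
    spec = md.MockDimerSpec(seed=11)
    trajs = md.generate_mock_dimer_trajectories(spec, 25)
    truth = md.planted_direction(spec)
    cfg1 = pw.PathwayConfig(alpha=100.0)
    cfg2 = pw.PathwayConfig(alpha=200.0)
    c1 = pw.relaxation_vector(pw.pool_ensemble(trajs, cfg1), cfg1).cosine_to(truth)
    c2 = pw.relaxation_vector(pw.pool_ensemble(trajs, cfg2), cfg2).cosine_to(truth)
    assert abs(c1 - c2) < 0.05


def test_projection_on_parallel_and_orthogonal_coordinates():
    ref = Structure(["C", "O", "N", "H"],
                    np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]]))
    d01 = CoordinateDefinition("distance", (0, 1), "par")
    d23 = CoordinateDefinition("distance", (2, 3), "other")
    from nonrad.geometry import coordinate_gradient

    g = coordinate_gradient(d01, ref).ravel()
    vec = pw.RelaxationVector(c=g / np.linalg.norm(g), config=pw.PathwayConfig())
    out = pw.project_vector(vec, [d01, d23], ref)
    assert out["projection"]["par"] == pytest.approx(1.0)
    assert abs(out["projection"]["other"]) < 1e-10
    assert out["share"]["par"] == pytest.approx(1.0)


def test_projection_ranks_planted_mode_first():
    spec = md.MockDimerSpec(seed=12)
    trajs = md.generate_mock_dimer_trajectories(spec, 25)
    vec = pw.relaxation_vector(pw.pool_ensemble(trajs))
    ref = md.reference_structure()
    out = pw.project_vector(vec, [md.CO_A, md.CO_B, md.AMIDE_PLANE_B, md.PT_AB], ref)
    shares = out["share"]
    assert shares["CO_A"] > max(v for k, v in shares.items() if k != "CO_A")


def test_projection_dimension_mismatch():
    ref = Structure(["C", "O"], np.array([[0, 0, 0], [1.5, 0, 0]]))
    vec = pw.RelaxationVector(c=np.zeros(9), config=pw.PathwayConfig())
    with pytest.raises(ValueError, match="components"):
        pw.project_vector(vec, [CoordinateDefinition("distance", (0, 1))], ref)


def test_config_validation():
    with pytest.raises(ValueError):
        pw.PathwayConfig(alpha=0.0)
    with pytest.raises(ValueError):
        pw.PathwayConfig(temperature=-1.0)
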