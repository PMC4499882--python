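import numpy as np
import pytest

from geltrax.materials import lame_from_engineering


@pytest.fixture(scope="session")
def material():
    """Default gel: E = 500 Pa, nu = 0.2 (mu = 208.33 Pa, lam = 138.89 Pa)."""
    return lame_from_engineering(500.0, 0.2)


@pytest.fixture(scope="session")
def small_cavity_solution(material):
    """Coarse FEM solve of the pressurised-cavity problem, shared by the
    cheaper solver checks (subdivision-1 icosphere, 6 radial layers)."""
    from geltrax.fem import solve_displacement_bvp
    from geltrax.mesh import SphereShape, TissueSurface, build_gel_mesh
    from geltrax.synthetic import cavity_displacement_field

    a, p = 50.0, 100.0
    surf = TissueSurface.sphere(a, subdivisions=1)
    mesh = build_gel_mesh(surf, SphereShape(400.0), n_layers=6, order=2)
    sol = solve_displacement_bvp(
        mesh, material, lambda pts: cavity_displacement_field(material, a, p, pts))
    return {"a": a, "p": p, "mesh": mesh, "solution": sol}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
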