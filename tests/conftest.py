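import math

import numpy as np
import pytest

from rvatlas.mesh import CorrespondedMesh, N_CIRC, N_RINGS
from rvatlas.synthetic import generate_template


@pytest.fixture(scope="session")
def template():
    return generate_template()


def ring_solid(z_profile, r_profile, crescent: float = 0.0) -> CorrespondedMesh:
    """Closed ring-parameterized solid (endo only) from analytic profiles.

    ``z_profile``/``r_profile`` map a parameter in [0, 1] to height and
    ring radius; crescent adds the limacon septal dimple.
    """
    t = np.linspace(0.0, 1.0, N_RINGS)
    z = np.asarray([z_profile(s) for s in t])
    r = np.asarray([r_profile(s) for s in t])
    phi = 2 * np.pi * np.arange(N_CIRC) / N_CIRC
    a = 1.0 - crescent * np.cos(phi)
    v = np.empty((N_RINGS, N_CIRC, 3))
    v[..., 0] = r[:, None] * a[None, :] * np.cos(phi)[None, :]
    v[..., 1] = r[:, None] * a[None, :] * np.sin(phi)[None, :]
    v[..., 2] = z[:, None]
    return CorrespondedMesh(endo=v.reshape(-1, 3), epi=None,
                            septal_mask=np.zeros(N_RINGS * N_CIRC, bool),
                            landmark=np.array([r.max() + 5.0, 0.0, z.min()]))


def ring_sphere(radius: float, center_z: float = 0.0, eps: float = 0.995) -> CorrespondedMesh:
    """Near-complete sphere as a ring solid (poles closed by the end caps)."""
    return ring_solid(
        lambda s: center_z + radius * math.cos(math.pi * (1 - s * eps - (1 - eps) / 2)),
        lambda s: radius * math.sin(math.pi * (1 - s * eps - (1 - eps) / 2)) + 1e-9,
    )


def ring_cylinder(radius: float, height: float) -> CorrespondedMesh:
    return ring_solid(lambda s: s * height, lambda s: radius)


def ring_ellipsoid(a: float, b_axis: float) -> CorrespondedMesh:
    """Prolate spheroid with equatorial radius ``a`` and polar semi-axis ``b``."""
    eps = 0.995
    ang = lambda s: math.pi * (1 - s * eps - (1 - eps) / 2)
    return ring_solid(lambda s: b_axis * math.cos(ang(s)),
                      lambda s: a * math.sin(ang(s)) + 1e-9)


def concentric_sphere_mesh(r_in: float, r_out: float) -> CorrespondedMesh:
    inner = ring_sphere(r_in)
    outer = ring_sphere(r_out)
    return CorrespondedMesh(endo=inner.endo, epi=outer.endo,
                            septal_mask=np.ones(N_RINGS * N_CIRC, bool),
                            landmark=np.array([r_out + 5.0, 0.0, -r_out]))
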