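"""Isotropic linear-elastic material parameters.

Collagen gels are modelled as isotropic Hookean solids, T = 2 mu eps +
lam tr(eps) I, with the Lame pair (mu, lam) derived from the engineering
constants (E, nu). The Poisson ratio defaults to 0.2 throughout the
package; the Young's modulus of a given gel is an input parameter.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic elastic constants.

    Attributes
    ----------
    E : float
        Young's modulus in Pa. Must be positive.
    nu : float
        Poisson ratio, ``0 <= nu < 0.5``. The incompressible limit is not
        supported by the displacement formulation used here.
    mu : float
        Shear modulus (first Lame parameter of the pair), Pa.
    lam : float
        Second Lame parameter, Pa.
    """

    E: float
    nu: float
    mu: float
    lam: float


def lame_from_engineering(E: float, nu: float = 0.2) -> ElasticMaterial:
    """Convert engineering constants to a full :class:`ElasticMaterial`.

    mu = E / (2 (1 + nu)),  lam = E nu / ((1 + nu)(1 - 2 nu)).

    Raises
    ------
    ValueError
        If ``E <= 0`` or ``nu`` lies outside ``[0, 0.5)``.
    """
    if E <= 0:
        raise ValueError(f"Young's modulus must be positive, got E={E}")
    if not (0.0 <= nu < 0.5):
        raise ValueError(
            f"Poisson ratio must satisfy 0 <= nu < 0.5, got nu={nu}"
        )
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return ElasticMaterial(E=E, nu=nu, mu=mu, lam=lam)
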