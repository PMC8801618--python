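"""Optical tissue properties and the coefficients derived from them.

Holds the per-tissue optical parameter tables (absorption ``mu_a``, scattering
``mu_s``, anisotropy ``g``, refractive index ``n``), the diffusion coefficient
D = 1/(3(mu_a + (1-g) mu_s)), the SP3 moment absorption coefficients
mu_ai = mu_a + mu_s (1 - g^i), the refractive-mismatch boundary factor A_n of
the diffusion Robin condition, and the 2x2 SP3 boundary coefficient table
xi_st.  The xi table is derived from the P3 Marshak conditions with Fresnel
reflection moments evaluated by fixed-order Gauss-Legendre quadrature; the
matched-boundary (n = 1) limit reduces to the closed forms
xi = [[1/2, -1/8], [-1/8, 7/24]].

Also provides the rule deciding which transport approximation a tissue gets:
tissues whose reduced scattering dominates absorption
(mu_s (1 - g) >= ratio * mu_a, default ratio 10) are diffusive enough for the
diffusion equation (region 1); the rest are assigned SP3 (region 2).  For the
mouse-organ table shipped as ``digimouse_610_630`` this assigns adipose,
stomach and kidneys to region 1 and heart, liver and lungs to region 2 at both
wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalProperties",
    "DerivedCoefficients",
    "diffusion_coefficient",
    "sp3_moment_coefficients",
    "boundary_coefficients",
    "effective_attenuation",
    "region_rule",
    "digimouse_610_630",
    "load_tissue_table",
    "XI_VACUUM",
    "DEFAULT_REFRACTIVE_INDEX",
]

#: standard soft-tissue refractive index, used when a table omits ``n``
DEFAULT_REFRACTIVE_INDEX = 1.37

#: matched-boundary SP3 coefficient table (vacuum Marshak values)
XI_VACUUM = np.array([[0.5, -0.125], [-0.125, 7.0 / 24.0]])


@dataclass(frozen=True)
class OpticalProperties:
    """Optical parameters of one tissue at one wavelength.

    mu_a, mu_s in mm^-1; g dimensionless in [0, 1); refractive_index >= 1.
    """

    mu_a: float
    mu_s: float
    g: float
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX

    def __post_init__(self):
        if self.mu_a < 0:
            raise ValueError("mu_a must be non-negative")
        if self.mu_s <= 0:
            raise ValueError("mu_s must be positive")
        if not 0.0 <= self.g < 1.0:
            raise ValueError("g must be in [0, 1)")
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_s_reduced(self) -> float:
        return (1.0 - self.g) * self.mu_s

    @property
    def transport_length(self) -> float:
        """1/(mu_a + (1-g) mu_s), the direction-randomisation scale in mm."""
        return 1.0 / (self.mu_a + self.mu_s_reduced)


@dataclass(frozen=True)
class DerivedCoefficients:
    """All model coefficients derived from one tissue's optical properties."""

    D: float
    mu_a1: float
    mu_a2: float
    mu_a3: float
    A_n: float
    xi: np.ndarray


def diffusion_coefficient(props: OpticalProperties) -> float:
    """Optical diffusion coefficient D = 1/(3 (mu_a + (1-g) mu_s)), in mm."""
    denom = props.mu_a + props.mu_s_reduced
    if denom <= 0.0:
        raise ValueError("mu_a + (1-g) mu_s must be positive")
    return 1.0 / (3.0 * denom)


def sp3_moment_coefficients(props: OpticalProperties) -> tuple[float, float, float]:
    """SP3 moment absorption coefficients mu_ai = mu_a + mu_s (1 - g^i)."""
    return tuple(props.mu_a + props.mu_s * (1.0 - props.g ** i) for i in (1, 2, 3))


def effective_attenuation(props: OpticalProperties) -> float:
    """mu_eff = sqrt(mu_a / D), the diffusion decay constant in mm^-1."""
    return float(np.sqrt(props.mu_a / diffusion_coefficient(props)))


def derive(props: OpticalProperties, quad_order: int = 64) -> DerivedCoefficients:
    m1, m2, m3 = sp3_moment_coefficients(props)
    A_n, xi = boundary_coefficients(props.refractive_index, quad_order=quad_order)
    return DerivedCoefficients(D=diffusion_coefficient(props), mu_a1=m1,
                               mu_a2=m2, mu_a3=m3, A_n=A_n, xi=xi)


# ---------------------------------------------------------------------------
# boundary coefficients
# ---------------------------------------------------------------------------

def fresnel_reflectance(cos_i, n_rel):
    """Unpolarized Fresnel reflectance for internal incidence.

    ``cos_i`` is the cosine of the angle to the boundary normal on the tissue
    side, ``n_rel = n_tissue / n_outside >= 1``.  Total internal reflection
    beyond the critical angle.
    """
    cos_i = np.clip(np.asarray(cos_i, dtype=np.float64), 0.0, 1.0)
    sin_i = np.sqrt(1.0 - cos_i ** 2)
    sin_t = n_rel * sin_i
    tir = sin_t >= 1.0
    sin_t = np.where(tir, 0.0, sin_t)
    cos_t = np.sqrt(1.0 - sin_t ** 2)
    # n1 = n_rel (inside), n2 = 1 (outside)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (cos_i - n_rel * cos_t) / (cos_i + n_rel * cos_t)
    r = 0.5 * (rs ** 2 + rp ** 2)
    return np.where(tir, 1.0, r)


def _legendre(k, x):
    if k == 0:
        return np.ones_like(x)
    if k == 1:
        return x
    if k == 2:
        return 0.5 * (3 * x ** 2 - 1)
    if k == 3:
        return 0.5 * (5 * x ** 3 - 3 * x)
    raise ValueError(k)


def boundary_coefficients(refractive_index: float,
                          quad_order: int = 64) -> tuple[float, np.ndarray]:
    """Diffusion mismatch factor A_n and the 2x2 SP3 boundary table xi_st.

    A_n follows the standard partial-current construction: with the Fresnel
    reflection moments R_phi = int 2 mu R(mu) dmu and R_j = int 3 mu^2 R(mu)
    dmu, R_eff = (R_phi + R_j)/(2 - R_phi + R_j) and
    A_n = (1 + R_eff)/(1 - R_eff); a matched boundary gives A_n = 1.

    xi_st comes from the two odd-order (l = 1, 3) Marshak conditions applied to
    the P3 angular flux with partial Fresnel reflection: writing the composite
    moments' normal derivatives as u1 = (1/(3 mu_a1)) dphi1/dn and
    u2 = (1/(7 mu_a3)) dphi2/dn, the conditions are solved for
    (u1, u2) = -xi (phi1, phi2).  All angular integrals use fixed-order
    Gauss-Legendre quadrature, so refreshing the table for another reflection
    model only means swapping the reflectance function.
    """
    if refractive_index < 1.0:
        raise ValueError("refractive index must be >= 1")
    x, w = np.polynomial.legendre.leggauss(quad_order)
    # panels split at the total-internal-reflection kink; above it the
    # transmitted cosine behaves like sqrt(mu - mu_c), so that panel uses the
    # substitution mu = mu_c + (1 - mu_c) t^2 to restore smoothness
    mu_c = np.sqrt(max(0.0, 1.0 - 1.0 / refractive_index ** 2))
    t01 = 0.5 * (x + 1.0)
    w01 = 0.5 * w
    if 0.0 < mu_c < 1.0:
        mu_lo = mu_c * t01
        w_lo = mu_c * w01
        mu_hi = mu_c + (1.0 - mu_c) * t01 ** 2
        w_hi = 2.0 * (1.0 - mu_c) * t01 * w01
        mu = np.concatenate([mu_lo, mu_hi])
        wm = np.concatenate([w_lo, w_hi])
    else:
        mu, wm = t01, w01
    R = fresnel_reflectance(mu, refractive_index)

    R_phi = float(np.sum(2.0 * mu * R * wm))
    R_j = float(np.sum(3.0 * mu ** 2 * R * wm))
    R_eff = (R_phi + R_j) / (2.0 - R_phi + R_j)
    A_n = (1.0 + R_eff) / (1.0 - R_eff)

    # c[l][k] = (2k+1) [ int_{-1}^{0} P_l P_k dmu - int_0^1 R P_l(-mu) P_k dmu ]
    coeffs = {}
    for el in (1, 3):
        row = []
        for k in range(4):
            inc = np.sum(_legendre(el, -mu) * _legendre(k, -mu) * wm)
            ref = np.sum(R * _legendre(el, -mu) * _legendre(k, mu) * wm)
            row.append((2 * k + 1) * (inc - ref))
        coeffs[el] = row
    # moments in terms of composites: m0 = phi1 - (2/3) phi2, m2 = phi2 / 3,
    # m1 = -u1, m3 = -u2
    A = np.empty((2, 2))
    B = np.empty((2, 2))
    for i, el in enumerate((1, 3)):
        c0, c1, c2, c3 = coeffs[el]
        A[i, 0] = c0
        A[i, 1] = -2.0 / 3.0 * c0 + c2 / 3.0
        B[i, 0] = c1
        B[i, 1] = c3
    xi = -np.linalg.solve(B, A)
    return A_n, xi


# ---------------------------------------------------------------------------
# region rule and tissue tables
# ---------------------------------------------------------------------------

def region_rule(tissue_table: dict[str, OpticalProperties],
                override: dict[str, int] | None = None,
                ratio: float = 10.0) -> dict[str, int]:
    """Tissue→region map: diffusion (1) where scattering dominates, SP3 (2) else.

    A tissue is diffusive enough for the diffusion equation when its reduced
    scattering exceeds ``ratio`` times its absorption; otherwise the
    higher-order SP3 model is required.  An explicit ``override`` map is
    returned verbatim.
    """
    if not tissue_table:
        raise ValueError("empty tissue table")
    if override is not None:
        return dict(override)
    return {
        name: 1 if props.mu_s_reduced >= ratio * props.mu_a else 2
        for name, props in tissue_table.items()
    }


def digimouse_610_630(wavelength: int = 610,
                      refractive_index: float = DEFAULT_REFRACTIVE_INDEX
                      ) -> dict[str, OpticalProperties]:
    """Mouse-organ optical parameters at 610 or 630 nm.

    Absorption/scattering/anisotropy per organ for the six-organ mouse torso
    model; the refractive index is not part of the published table and defaults
    to the standard soft-tissue value.
    """
    tables = {
        610: {
            "adipose": (0.0127, 21.1547, 0.94),
            "heart": (0.2015, 7.3484, 0.85),
            "stomach": (0.0384, 19.6728, 0.92),
            "liver": (1.2086, 7.4826, 0.90),
            "kidneys": (0.2258, 18.5421, 0.86),
            "lungs": (0.6687, 38.0785, 0.94),
        },
        630: {
            "adipose": (0.0069, 20.7961, 0.94),
            "heart": (0.1085, 7.0171, 0.85),
            "stomach": (0.0207, 19.0667, 0.92),
            "liver": (0.6505, 7.2334, 0.90),
            "kidneys": (0.1216, 17.6605, 0.86),
            "lungs": (0.3622, 37.4330, 0.94),
        },
    }
    if wavelength not in tables:
        raise ValueError("tabulated wavelengths are 610 and 630 nm")
    return {
        name: OpticalProperties(mu_a, mu_s, g, refractive_index)
        for name, (mu_a, mu_s, g) in tables[wavelength].items()
    }


def load_tissue_table(path) -> dict[int | str, dict[str, OpticalProperties]]:
    """Load a per-tissue, per-wavelength optical table from YAML.

    Expected layout::

        liver:
          610: {mu_a: 1.2086, mu_s: 7.4826, g: 0.90, n: 1.37}
          630: {mu_a: 0.6505, mu_s: 7.2334, g: 0.90}
    """
    import yaml

    with open(path) as f:
        raw = yaml.safe_load(f)
    out: dict = {}
    for tissue, by_wl in raw.items():
        out[tissue] = {}
        for wl, rec in by_wl.items():
            out[tissue][int(wl)] = OpticalProperties(
                mu_a=float(rec["mu_a"]), mu_s=float(rec["mu_s"]),
                g=float(rec["g"]),
                refractive_index=float(rec.get("n", DEFAULT_REFRACTIVE_INDEX)),
            )
    return out
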