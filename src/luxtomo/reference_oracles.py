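"""Independent ground-truth generators for validating the transport solvers.

Two oracles, both independent of the finite-element machinery:

* the infinite-medium diffusion Green's function
  Phi(r) = exp(-mu_eff r) / (4 pi D r), the closed-form fluence of an
  isotropic unit point source in a homogeneous medium, and
* a weight-based Monte Carlo photon random walk (exponential free paths with
  mu_t = mu_a + mu_s, Henyey-Greenstein scattering, absorption by weight
  attenuation with Russian roulette, Fresnel partial reflection at a
  refractive boundary) on analytic geometries — sphere, slab or infinite
  medium — with binned boundary exitance and a radial interior fluence tally.

The Monte Carlo geometry is analytic rather than mesh-conforming on purpose:
sharing nothing with the FEM mesh strengthens it as an oracle.  The weight
bookkeeping is exact: absorbed + exited + roulette-terminated (net) weight
equals the launched weight to rounding error, which the tests assert at 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optical_props import OpticalProperties, fresnel_reflectance

__all__ = ["MCConfig", "MCResult", "de_greens_function", "mc_simulate"]


def de_greens_function(props: OpticalProperties, r) -> np.ndarray:
    """Infinite-medium diffusion fluence of a unit isotropic point source.

    Phi(r) = exp(-mu_eff r) / (4 pi D r), D = 1/(3 (mu_a + (1-g) mu_s)),
    mu_eff = sqrt(mu_a / D).  ``r`` in mm, strictly positive.
    """
    r = np.asarray(r, dtype=np.float64)
    if (r <= 0).any():
        raise ValueError("r must be positive")
    D = 1.0 / (3.0 * (props.mu_a + (1.0 - props.g) * props.mu_s))
    mu_eff = np.sqrt(props.mu_a / D)
    return np.exp(-mu_eff * r) / (4.0 * np.pi * D * r)


@dataclass
class MCConfig:
    """Monte Carlo run configuration (seed mandatory for reproducibility)."""

    n_photons: int
    seed: int
    props: OpticalProperties
    geometry: dict = field(default_factory=lambda: {"type": "infinite"})
    source_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source_type: str = "isotropic"  # or "pencil" along +z
    n_cos_bins: int = 10
    n_phi_bins: int = 10
    radial_bin_width: float = 0.25
    radial_max: float = 20.0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    max_steps: int = 20000
    batch_size: int = 250_000

    def __post_init__(self):
        if self.n_photons <= 0:
            raise ValueError("photon count must be positive")


@dataclass
class MCResult:
    """Normalized per launched photon; energy terms are raw weights."""

    exitance: np.ndarray          # (n_cos_bins, n_phi_bins) power / mm^2 (sphere)
    exitance_se: np.ndarray
    bin_area: np.ndarray
    fluence_r: np.ndarray         # radial interior fluence (absorption estimator)
    r_centers: np.ndarray
    absorbed: float
    exited: float
    terminated: float
    launched: float
    transmitted: float = 0.0      # slab only
    reflected_back: float = 0.0   # slab only

    @property
    def energy_residual(self) -> float:
        return abs(self.launched - (self.absorbed + self.exited +
                                    self.terminated)) / self.launched


def _hg_scatter(d, g, rng):
    n = d.shape[0]
    u = rng.random(n)
    if g == 0.0:
        ct = 2.0 * u - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        np.clip(ct, -1.0, 1.0, out=ct)
    st = np.sqrt(1.0 - ct * ct)
    psi = 2.0 * np.pi * rng.random(n)
    cp, sp_ = np.cos(psi), np.sin(psi)
    dz = d[:, 2]
    near_pole = np.abs(dz) > 0.99999
    denom = np.sqrt(np.maximum(1.0 - dz * dz, 1e-30))
    ux = st * (d[:, 0] * dz * cp - d[:, 1] * sp_) / denom + d[:, 0] * ct
    uy = st * (d[:, 1] * dz * cp + d[:, 0] * sp_) / denom + d[:, 1] * ct
    uz = -st * cp * denom + dz * ct
    out = np.column_stack([ux, uy, uz])
    if near_pole.any():
        sgn = np.sign(dz[near_pole])
        out[near_pole, 0] = st[near_pole] * cp[near_pole]
        out[near_pole, 1] = st[near_pole] * sp_[near_pole]
        out[near_pole, 2] = sgn * ct[near_pole]
    norm = np.linalg.norm(out, axis=1, keepdims=True)
    return out / norm


def mc_simulate(config: MCConfig) -> MCResult:
    """Run the photon-weight random walk; fixed seed gives bit-identical output."""
    rng = np.random.default_rng(config.seed)
    pr = config.props
    mu_t = pr.mu_a + pr.mu_s
    albedo_loss = pr.mu_a / mu_t
    geo = config.geometry.get("type", "infinite")
    R = float(config.geometry.get("radius", 0.0))
    L = float(config.geometry.get("thickness", 0.0))
    n_rel = pr.refractive_index
    src = np.asarray(config.source_position, dtype=np.float64)

    nr = int(np.ceil(config.radial_max / config.radial_bin_width))
    fluence_acc = np.zeros(nr)
    exit_w = np.zeros((config.n_cos_bins, config.n_phi_bins))
    exit_w2 = np.zeros_like(exit_w)
    absorbed = exited = terminated = 0.0
    transmitted = reflected_back = 0.0

    remaining = config.n_photons
    while remaining > 0:
        nb = min(remaining, config.batch_size)
        remaining -= nb
        pos = np.tile(src, (nb, 1))
        if config.source_type == "isotropic":
            ct = 2.0 * rng.random(nb) - 1.0
            phi = 2.0 * np.pi * rng.random(nb)
            st = np.sqrt(1.0 - ct * ct)
            d = np.column_stack([st * np.cos(phi), st * np.sin(phi), ct])
        else:
            d = np.tile([0.0, 0.0, 1.0], (nb, 1))
        w = np.ones(nb)

        for _ in range(config.max_steps):
            n_act = w.shape[0]
            if n_act == 0:
                break
            s = -np.log(rng.random(n_act)) / mu_t

            if geo == "sphere":
                b = np.einsum("ij,ij->i", pos, d)
                c = np.einsum("ij,ij->i", pos, pos) - R * R
                disc = np.sqrt(np.maximum(b * b - c, 0.0))
                t_b = -b + disc
                cross = s >= t_b
            elif geo == "slab":
                dz = d[:, 2]
                t_b = np.full(n_act, np.inf)
                fwd = dz > 1e-12
                bwd = dz < -1e-12
                t_b[fwd] = (L - pos[fwd, 2]) / dz[fwd]
                t_b[bwd] = -pos[bwd, 2] / dz[bwd]
                cross = s >= t_b
            else:
                cross = np.zeros(n_act, dtype=bool)

            if cross.any():
                pc = pos[cross] + t_b[cross, None] * d[cross]
                if geo == "sphere":
                    nrm = pc / np.linalg.norm(pc, axis=1, keepdims=True)
                else:
                    nrm = np.zeros_like(pc)
                    nrm[:, 2] = np.where(d[cross, 2] > 0, 1.0, -1.0)
                cos_i = np.abs(np.einsum("ij,ij->i", d[cross], nrm))
                refl = fresnel_reflectance(cos_i, n_rel) if n_rel > 1.0 else \
                    np.zeros(int(cross.sum()))
                ew = w[cross] * (1.0 - refl)
                exited += float(ew.sum())
                if geo == "sphere":
                    ctb = np.clip(pc[:, 2] / R, -1.0, 1.0)
                    pb = np.mod(np.arctan2(pc[:, 1], pc[:, 0]), 2 * np.pi)
                    i = np.minimum(((ctb + 1.0) / 2.0 * config.n_cos_bins).astype(int),
                                   config.n_cos_bins - 1)
                    j = np.minimum((pb / (2 * np.pi) * config.n_phi_bins).astype(int),
                                   config.n_phi_bins - 1)
                    np.add.at(exit_w, (i, j), ew)
                    np.add.at(exit_w2, (i, j), ew * ew)
                else:
                    up = nrm[:, 2] > 0
                    transmitted += float(ew[up].sum())
                    reflected_back += float(ew[~up].sum())
                w_rem = w[cross] - ew
                # reflected fraction continues from the boundary
                pos[cross] = pc * (1.0 - 1e-12) if geo == "sphere" else pc
                d[cross] -= 2.0 * np.einsum("ij,ij->i", d[cross], nrm)[:, None] * nrm
                w[cross] = w_rem

            walk = ~cross
            if walk.any():
                pos[walk] += s[walk, None] * d[walk]
                dw = w[walk] * albedo_loss
                absorbed += float(dw.sum())
                rr = np.linalg.norm(pos[walk] - src, axis=1)
                ridx = np.minimum((rr / config.radial_bin_width).astype(int), nr - 1)
                np.add.at(fluence_acc, ridx, dw)
                w[walk] = w[walk] - dw
                d[walk] = _hg_scatter(d[walk], pr.g, rng)

            # Russian roulette with exact weight bookkeeping
            low = w < config.roulette_threshold
            if low.any():
                u = rng.random(int(low.sum()))
                survive = u < config.roulette_survival
                idx = np.nonzero(low)[0]
                kill = idx[~survive]
                keep = idx[survive]
                terminated += float(w[kill].sum())
                boosted = w[keep] / config.roulette_survival
                terminated -= float((boosted - w[keep]).sum())
                w[keep] = boosted
                w[kill] = 0.0
            alive = w > 0.0
            pos, d, w = pos[alive], d[alive], w[alive]
        # photons still alive at the step cap are terminated outright
        terminated += float(w.sum())

    N = float(config.n_photons)
    dcos = 2.0 / config.n_cos_bins
    dphi = 2.0 * np.pi / config.n_phi_bins
    bin_area = np.full_like(exit_w, R * R * dcos * dphi) if geo == "sphere" else \
        np.ones_like(exit_w)
    exitance = exit_w / (bin_area * N)
    exitance_se = np.sqrt(exit_w2) / (bin_area * N)
    edges = config.radial_bin_width * np.arange(nr + 1)
    vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    fluence = fluence_acc / (pr.mu_a * vol * N) if pr.mu_a > 0 else \
        np.zeros(nr)
    return MCResult(
        exitance=exitance, exitance_se=exitance_se, bin_area=bin_area,
        fluence_r=fluence, r_centers=0.5 * (edges[1:] + edges[:-1]),
        absorbed=absorbed, exited=exited, terminated=terminated, launched=N,
        transmitted=transmitted / N, reflected_back=reflected_back / N)
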