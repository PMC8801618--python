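"""End-to-end orchestration: phantom → transport model → measurement →
sensitivity → reconstruction → metrics.

The transport model is selectable: ``de`` and ``sp3`` assemble the pure model
on the whole mesh; ``mrhm`` regroups the mesh by region label, assembles the
diffusion system on region 1 and the SP3 system on region 2, and couples them
at the interface duplicates.  Boundary terms (A_n, xi) are evaluated from the
refractive index of each boundary face's owning tet.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass

import numpy as np

from . import __version__
from .fem_assembly import AssembledSystem, assemble_de, assemble_sp3, props_per_tet
from .forward_solver import (FactorizedSystem, SurfaceMeasurement,
                             build_sensitivity, select_fov_nodes, solve_forward,
                             stack_multispectral, surface_fluence)
from .hybrid_coupling import (HybridSystem, build_hybrid_system,
                              couple_interface_nodes, merge_source_weights)
from .inverse_recon import evaluate_reconstruction, reconstruct
from .mesh_core import RegroupedMesh, TetMesh, classify_regions, regroup_mesh
from .optical_props import OpticalProperties, boundary_coefficients

__all__ = ["TransportModel", "build_transport_system", "forward_surface",
           "run_pipeline", "default_tau"]

MODELS = ("de", "sp3", "mrhm")


def _face_terms(mesh: TetMesh, props: list[OpticalProperties]):
    """Per-boundary-face A_n and xi from the owning tet's refractive index."""
    if mesh.boundary_faces is None or not len(mesh.boundary_faces):
        return np.zeros(0), np.zeros((0, 2, 2))
    n_idx = np.array([props[t].refractive_index for t in mesh.boundary_owner])
    An = np.empty(len(n_idx))
    xi = np.empty((len(n_idx), 2, 2))
    for n_val in np.unique(n_idx):
        a, x = boundary_coefficients(float(n_val))
        sel = n_idx == n_val
        An[sel] = a
        xi[sel] = x
    return An, xi


@dataclass
class TransportModel:
    """An assembled forward model bound to its source mesh."""

    mesh: TetMesh
    system: AssembledSystem | HybridSystem
    model: str
    regrouped: RegroupedMesh | None = None
    _factorization: FactorizedSystem | None = None

    @property
    def factorization(self) -> FactorizedSystem:
        if self._factorization is None:
            self._factorization = FactorizedSystem(self.system.M)
        return self._factorization

    def rhs(self, S: np.ndarray) -> np.ndarray:
        if isinstance(self.system, HybridSystem):
            return merge_source_weights(self.system, S)
        return self.system.rhs(S)

    def solve(self, S: np.ndarray) -> np.ndarray:
        return solve_forward(self.system, self.rhs(S),
                             factorization=self.factorization)

    def surface(self, x: np.ndarray, measurable=None,
                wavelength: float = 0.0) -> SurfaceMeasurement:
        return surface_fluence(self.system, x, self.mesh.boundary_nodes(),
                               measurable=measurable, wavelength=wavelength)

    def sensitivity(self, measurable=None, wavelength: float = 0.0):
        sel = self.mesh.boundary_nodes() if measurable is None else measurable
        return build_sensitivity(self.system, sel, wavelength=wavelength,
                                 factorization=self.factorization)


def build_transport_system(mesh: TetMesh, tissue_table: dict,
                           model: str = "mrhm",
                           region_map: dict | None = None,
                           include_m12_volume: bool = True) -> TransportModel:
    """Assemble the selected forward model on a tissue-labelled mesh."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if model == "de":
        props = props_per_tet(mesh, tissue_table)
        An, _ = _face_terms(mesh, props)
        return TransportModel(mesh, assemble_de(mesh, props, A_n=An), model)
    if model == "sp3":
        props = props_per_tet(mesh, tissue_table)
        _, xi = _face_terms(mesh, props)
        sys_ = assemble_sp3(mesh, props, xi=xi,
                            include_m12_volume=include_m12_volume)
        return TransportModel(mesh, sys_, model)
    if region_map is not None:
        mesh = classify_regions(mesh, region_map)
    if mesh.region is None:
        raise ValueError("mrhm needs region labels (pass region_map or classify)")
    rg = regroup_mesh(mesh)
    de_sys = None
    sp3_sys = None
    if rg.t1:
        props1 = props_per_tet(rg.mesh1, tissue_table)
        An, _ = _face_terms(rg.mesh1, props1)
        de_sys = assemble_de(rg.mesh1, props1, A_n=An)
    if rg.t2:
        props2 = props_per_tet(rg.mesh2, tissue_table)
        _, xi = _face_terms(rg.mesh2, props2)
        sp3_sys = assemble_sp3(rg.mesh2, props2, xi=xi,
                               include_m12_volume=include_m12_volume)
    hybrid = couple_interface_nodes(build_hybrid_system(rg, de_sys, sp3_sys))
    return TransportModel(mesh, hybrid, model, regrouped=rg)


def forward_surface(mesh: TetMesh, tissue_table: dict, S: np.ndarray,
                    model: str = "mrhm", region_map: dict | None = None,
                    measurable=None, wavelength: float = 0.0
                    ) -> tuple[SurfaceMeasurement, np.ndarray, TransportModel]:
    """One-call forward run: assemble, solve, measure surface fluence."""
    tm = build_transport_system(mesh, tissue_table, model, region_map)
    x = tm.solve(S)
    return tm.surface(x, measurable=measurable, wavelength=wavelength), x, tm


def default_tau(A, phi_m, fraction: float = 1e-3) -> float:
    """Regularization weight heuristic: a fixed fraction of ||A^T phi||_inf
    (the threshold above which the all-zero solution stops being stationary)."""
    A = getattr(A, "A", A)
    return float(fraction * np.abs(A.T @ np.asarray(phi_m)).max())


def run_pipeline(config: dict, outdir=None) -> dict:
    """Run the numerical-simulation workflow described by a config mapping.

    Stages: phantom construction, forward solve per wavelength, measurement,
    sensitivity, reconstruction (single- or multi-wavelength), metrics.
    Returns the metrics report; artifacts are written under ``outdir`` when
    given, along with a provenance log (config hash, seeds, versions).
    """
    from . import optical_props as op
    from . import phantom_factory as pf

    t_start = time.time()
    stage = "config"
    try:
        model = config.get("model", "mrhm")
        wavelengths = list(config.get("wavelengths", [610]))
        if model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if not wavelengths:
            raise ValueError("at least one wavelength required")
        seed = int(config.get("seed", 0))
        noise = float(config.get("noise", 0.0))
        mesh_path = config.get("mesh")
        if mesh_path is not None:
            import os
            if not os.path.exists(mesh_path):
                raise FileNotFoundError(mesh_path)

        stage = "phantom"
        h_fwd = float(config.get("forward_element_size", 1.0))
        h_rec = float(config.get("recon_element_size", 1.25))
        fine, S_true, info = pf.mouse_torso_phantom(h_fwd)
        coarse, _, _ = pf.mouse_torso_phantom(h_rec)
        region_map = config.get("region_map", pf.MOUSE_REGION_RULE)

        rng = np.random.default_rng(seed)
        measurements, sens = [], []
        coarse_bn = coarse.boundary_nodes()
        stride = int(config.get("measurable_stride", 1))
        measurable = coarse_bn[::stride]
        from scipy.spatial import cKDTree

        for wl in wavelengths:
            stage = f"forward-{wl}"
            table = op.digimouse_610_630(int(wl))
            meas_f, _, _ = forward_surface(fine, table, S_true, model=model,
                                           region_map=region_map, wavelength=wl)
            tree = cKDTree(fine.nodes[meas_f.node_indices])
            _, nearest = tree.query(coarse.nodes[measurable])
            vals = meas_f.values[nearest]
            if noise > 0:
                vals = np.clip(vals * (1.0 + noise * rng.standard_normal(vals.shape)),
                               0.0, None)
            measurements.append(SurfaceMeasurement(wl, measurable, vals,
                                                   provenance="solver"))
            stage = f"sensitivity-{wl}"
            tm_c = build_transport_system(coarse, table, model, region_map)
            sens.append(tm_c.sensitivity(measurable, wavelength=wl))

        stage = "reconstruct"
        A, phi = stack_multispectral(sens[::-1], measurements[::-1])
        normalize = bool(config.get("column_normalize", True))
        Aeff = A.A
        if normalize:
            scale = np.linalg.norm(Aeff, axis=0)
            scale[scale == 0] = 1.0
            tau = config.get("tau") or default_tau(Aeff / scale, phi)
        else:
            tau = config.get("tau") or default_tau(Aeff, phi)
        res = reconstruct(A, phi, tau=float(tau),
                          norm=config.get("solver_norm", "l1"),
                          column_normalize=normalize)

        stage = "metrics"
        src = info["sources"][0]
        true_region = np.nonzero(
            ((coarse.nodes - np.asarray(src["center"])) ** 2).sum(1)
            <= src["radius"] ** 2)[0]
        report = evaluate_reconstruction(res.S, coarse.nodes, src["center"],
                                         true_region,
                                         threshold=config.get("threshold", 0.3))
        out = report.to_dict()
        out.update({"tau": res.tau, "iterations": res.iterations,
                    "converged": res.converged, "model": model,
                    "wavelengths": wavelengths})
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "metrics.json"), "w") as f:
            json.dump(out, f, indent=2)
        np.savetxt(os.path.join(outdir, "reconstruction.csv"),
                   np.column_stack([coarse.nodes, res.S]), delimiter=",",
                   header="x,y,z,S", comments="")
        prov = {
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
            "config": config, "seed": seed, "version": __version__,
            "elapsed_s": time.time() - t_start,
        }
        with open(os.path.join(outdir, "provenance.json"), "w") as f:
            json.dump(prov, f, indent=2, default=str)
    return out
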