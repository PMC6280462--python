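"""Linear-elastic FEM on tetrahedral meshes with Dirichlet surface BCs.

Four-node (constant-strain) tetrahedra, isotropic homogeneous material,
no body forces.  The displacement of every surface node is prescribed
(sampled from the initial registration's displacement field), so the
reduced system is symmetric positive definite and has no rigid-body modes.
A useful consequence of pure-Dirichlet loading with a uniform material is
that Young's modulus cancels exactly: the interior solution depends only
on the Poisson ratio, which is why registration accuracy is insensitive to
the absolute organ stiffness.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import TetMesh, tet_volumes

__all__ = [
    "ElasticMaterial",
    "ElasticModel",
    "NodalSolution",
    "AssembledSystem",
    "assemble",
    "solve",
    "scale_invariance_check",
]

# default soft-tissue constants for solid organs (prostate-like)
DEFAULT_E_MPA = 0.27
DEFAULT_NU = 0.40

_DIRECT_SOLVER_MAX_UNKNOWNS = 200_000


@dataclasses.dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic linear-elastic constants.

    E in MPa, Poisson ratio dimensionless (0 <= nu < 0.5).  Units are
    self-consistent because only displacements are consumed downstream.
    """

    E: float = DEFAULT_E_MPA
    nu: float = DEFAULT_NU

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if not (0 <= self.nu < 0.5):
            raise ValueError(f"Poisson ratio must be in [0, 0.5), got {self.nu}")

    @property
    def lam(self) -> float:
        """First Lame parameter lambda = E*nu / ((1+nu)(1-2nu))."""
        return self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))

    @property
    def mu(self) -> float:
        """Shear modulus mu = E / (2(1+nu))."""
        return self.E / (2 * (1 + self.nu))


@dataclasses.dataclass
class ElasticModel:
    """Mesh + uniform material + Dirichlet map (node id -> displacement, mm)."""

    mesh: TetMesh
    material: ElasticMaterial
    dirichlet: dict[int, np.ndarray]

    def __post_init__(self):
        missing = set(self.mesh.surface_node_ids.tolist()) - set(self.dirichlet)
        if missing:
            raise ValueError(
                f"{len(missing)} surface nodes lack a Dirichlet displacement")
        for nid, u in self.dirichlet.items():
            u = np.asarray(u, dtype=float)
            if u.shape != (3,) or not np.all(np.isfinite(u)):
                raise ValueError(f"invalid prescribed displacement at node {nid}")
            self.dirichlet[nid] = u


@dataclasses.dataclass
class NodalSolution:
    """Nodal displacements (mm) with solver diagnostics."""

    displacements: np.ndarray        # (nn, 3)
    residual: float                  # relative residual of the reduced solve
    tet_jacobians: np.ndarray        # per-tet det(F), F = I + grad(u)

    @property
    def min_jacobian(self) -> float:
        return float(self.tet_jacobians.min()) if len(self.tet_jacobians) else 1.0


@dataclasses.dataclass
class AssembledSystem:
    """Reduced linear system after Dirichlet elimination.

    ``K_ff`` acts on the free DOFs; the boundary contribution is moved to
    the right-hand side as ``-K_fc @ u_c``.  The factorization of ``K_ff``
    is cached so repeated solves (one per deformation stage) reuse it.
    """

    K_ff: sp.csr_matrix
    K_fc: sp.csr_matrix
    free_dofs: np.ndarray
    fixed_dofs: np.ndarray
    n_dofs: int
    _lu: object = None

    def rhs(self, u_fixed: np.ndarray) -> np.ndarray:
        return -self.K_fc @ u_fixed

    def solve_free(self, u_fixed: np.ndarray, tol: float = 1e-10):
        """Solve for the free DOFs; returns (u_free, relative_residual)."""
        if self.K_ff.shape[0] == 0:
            return np.zeros(0), 0.0
        b = self.rhs(u_fixed)
        bnorm = np.linalg.norm(b)
        if bnorm == 0:
            return np.zeros(self.K_ff.shape[0]), 0.0
        if self.K_ff.shape[0] <= _DIRECT_SOLVER_MAX_UNKNOWNS:
            if self._lu is None:
                self._lu = spla.splu(self.K_ff.tocsc())
            x = self._lu.solve(b)
        else:
            M = sp.diags(1.0 / self.K_ff.diagonal())
            x, info = spla.cg(self.K_ff, b, rtol=tol, maxiter=20_000, M=M)
            if info != 0:
                raise RuntimeError(f"conjugate-gradient solver failed (info={info})")
        res = np.linalg.norm(self.K_ff @ x - b) / bnorm
        return x, res


def _element_stiffness(nodes: np.ndarray, tets: np.ndarray,
                       material: ElasticMaterial) -> np.ndarray:
    """Element stiffness matrices K_e = V * B^T D B for all tets, (nt,12,12)."""
    p = nodes[tets]                       # (nt, 4, 3)
    vol = tet_volumes(nodes, tets)
    if np.any(vol <= 0):
        raise ValueError("mesh contains inverted or degenerate elements")

    # gradients of the four linear shape functions: rows of inv([[1,x,y,z]...])
    ones = np.ones((len(tets), 4, 1))
    M = np.concatenate([ones, p], axis=2)  # (nt, 4, 4)
    Minv = np.linalg.inv(M)
    grads = Minv[:, 1:4, :].transpose(0, 2, 1)  # (nt, 4, 3): grad N_a

    nt = len(tets)
    B = np.zeros((nt, 6, 12))
    gx, gy, gz = grads[..., 0], grads[..., 1], grads[..., 2]
    for a in range(4):
        c = 3 * a
        B[:, 0, c + 0] = gx[:, a]
        B[:, 1, c + 1] = gy[:, a]
        B[:, 2, c + 2] = gz[:, a]
        B[:, 3, c + 0] = gy[:, a]; B[:, 3, c + 1] = gx[:, a]
        B[:, 4, c + 1] = gz[:, a]; B[:, 4, c + 2] = gy[:, a]
        B[:, 5, c + 0] = gz[:, a]; B[:, 5, c + 2] = gx[:, a]

    lam, mu = material.lam, material.mu
    D = np.array([
        [lam + 2 * mu, lam, lam, 0, 0, 0],
        [lam, lam + 2 * mu, lam, 0, 0, 0],
        [lam, lam, lam + 2 * mu, 0, 0, 0],
        [0, 0, 0, mu, 0, 0],
        [0, 0, 0, 0, mu, 0],
        [0, 0, 0, 0, 0, mu],
    ])
    Ke = np.einsum("eia,ij,ejb->eab", B, D, B, optimize=True)
    return Ke * vol[:, None, None]


def global_stiffness(mesh: TetMesh, material: ElasticMaterial) -> sp.csr_matrix:
    """Assembled global stiffness matrix (3*nn x 3*nn, CSR)."""
    Ke = _element_stiffness(mesh.nodes, mesh.tets, material)
    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes))
    return K.tocsr()


def assemble(model: ElasticModel) -> AssembledSystem:
    """Assemble and reduce the system by Dirichlet elimination."""
    K = global_stiffness(model.mesh, model.material)
    n_dofs = 3 * model.mesh.n_nodes
    fixed_nodes = np.array(sorted(model.dirichlet), dtype=np.int64)
    fixed_dofs = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    free_mask = np.ones(n_dofs, dtype=bool)
    free_mask[fixed_dofs] = False
    free_dofs = np.nonzero(free_mask)[0]
    K_ff = K[free_dofs][:, free_dofs].tocsr()
    K_fc = K[free_dofs][:, fixed_dofs].tocsr()
    return AssembledSystem(K_ff, K_fc, free_dofs, fixed_dofs, n_dofs)


def solve(model: ElasticModel, system: AssembledSystem | None = None,
          tol: float = 1e-10) -> NodalSolution:
    """Solve for interior node displacements under the prescribed surface BCs.

    Prescribed nodes carry their boundary values exactly (elimination, not
    penalty).  Per-tet deformation Jacobians det(I + grad u) are reported;
    any non-positive value indicates locally folded (non-physical) output.
    """
    if system is None:
        system = assemble(model)
    fixed_nodes = system.fixed_dofs[::3] // 3
    u_fixed = np.concatenate([model.dirichlet[int(n)] for n in fixed_nodes])
    u_free, res = system.solve_free(u_fixed, tol=tol)
    u = np.zeros(system.n_dofs)
    u[system.fixed_dofs] = u_fixed
    u[system.free_dofs] = u_free
    u = u.reshape(-1, 3)
    jac = deformation_jacobians(model.mesh, u)
    return NodalSolution(u, res, jac)


def deformation_jacobians(mesh: TetMesh, nodal_u: np.ndarray) -> np.ndarray:
    """det(I + grad u) per tetrahedron (constant within each linear element)."""
    p = mesh.nodes[mesh.tets]
    ones = np.ones((mesh.n_tets, 4, 1))
    Minv = np.linalg.inv(np.concatenate([ones, p], axis=2))
    grads = Minv[:, 1:4, :].transpose(0, 2, 1)       # (nt, 4, 3)
    ue = nodal_u[mesh.tets]                          # (nt, 4, 3)
    G = np.einsum("eai,eaj->eij", ue, grads)         # du_i/dx_j
    F = np.eye(3)[None] + G
    return np.linalg.det(F)


def scale_invariance_check(model: ElasticModel,
                           factors=(0.1, 1.0, 10.0)) -> dict:
    """Quantify how scaling E (and perturbing nu) changes the solution.

    Under full-surface Dirichlet BCs with a uniform material the stiffness
    matrix is linear in E on both sides of the reduced system, so E cancels
    and the solutions should agree to solver precision.  Poisson-ratio
    changes do alter the interior field; the report carries that sensitivity
    without judging it.
    """
    base = solve(model)
    report = {"E_factors": list(factors), "E_max_rel_diff": 0.0,
              "nu_sensitivity": {}}
    scale = max(np.abs(base.displacements).max(), 1e-30)
    for f in factors:
        mat = ElasticMaterial(model.material.E * f, model.material.nu)
        sol = solve(ElasticModel(model.mesh, mat, model.dirichlet))
        d = np.abs(sol.displacements - base.displacements).max() / scale
        report["E_max_rel_diff"] = max(report["E_max_rel_diff"], float(d))
    for nu in (0.35, 0.45):
        if nu == model.material.nu:
            continue
        mat = ElasticMaterial(model.material.E, nu)
        sol = solve(ElasticModel(model.mesh, mat, model.dirichlet))
        d = np.abs(sol.displacements - base.displacements).max()
        report["nu_sensitivity"][nu] = float(d)
    return report
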