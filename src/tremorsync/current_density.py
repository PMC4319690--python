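"""Quasi-static current-density modelling on voxel phantoms.

At transcranial-stimulation frequencies the tissue volume conductor is
quasi-static: the electric potential obeys the conductivity-weighted
Laplace equation ``div(sigma grad phi) = 0`` with the stimulating
electrode held at +1 V and the return electrode at -1 V, from which the
electric field ``E = -grad phi`` and current density ``J = sigma E``
follow; ``|J|`` is the scalar field-strength map, rescaled afterwards so
the electrodes inject a nominal 1 mA.

The solver is finite-volume on the voxel grid: each voxel is a control
volume, face fluxes use the harmonic mean of the adjoining conductivities
(exact for layered media, flux-continuous at tissue interfaces), and the
resulting symmetric positive-definite system is solved by Jacobi-
preconditioned conjugate gradients from a zero initial guess. Air is
carried as a true (very low) conductivity rather than an excluded domain,
so no boundary needs special casing; one or two voxels of air padding make
the exterior effectively insulating. The alternating stimulation current
simply scales this steady-state map up and down in time, so a single
solution characterizes the whole cycle.

Phantoms are synthetic concentric-ellipsoid heads (scalp, skull, CSF, gray
and white matter at standard isotropic conductivities), optionally fused
to a neck-and-shoulders block of tissue-average conductivity — a stand-in
geometry; no real-MRI segmentation is attempted.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg

from .io_core import DegenerateInputError, SolverError, ValidationError

__all__ = [
    "AIR", "SKIN", "BONE", "CSF", "GRAY", "WHITE", "SALINE", "AVERAGE",
    "ELECTRODE",
    "DEFAULT_CONDUCTIVITY",
    "TISSUE_NAMES",
    "VoxelHeadModel",
    "ElectrodeSpec",
    "FieldSolution",
    "build_phantom",
    "attach_electrode",
    "solve_laplace",
    "scale_to_current",
    "roi_mean_density",
    "montage_contrast",
    "region_outflux",
    "export_nifti",
]

AIR, SKIN, BONE, CSF, GRAY, WHITE, SALINE, AVERAGE, ELECTRODE = range(9)

#: Isotropic conductivities in S/m. Tissue values follow the standard
#: literature set used for tES head models; "average" covers remaining soft
#: tissue (muscle/fat); the electrode layer is conductive rubber.
DEFAULT_CONDUCTIVITY: dict[int, float] = {
    AIR: 0.0001,
    SKIN: 0.43,
    BONE: 0.0064,
    CSF: 1.79,
    GRAY: 0.33,
    WHITE: 0.142,
    SALINE: 0.367,
    AVERAGE: 0.08,
    ELECTRODE: 1.0,
}

TISSUE_NAMES: dict[int, str] = {
    AIR: "air", SKIN: "skin", BONE: "bone", CSF: "csf", GRAY: "gray",
    WHITE: "white", SALINE: "saline", AVERAGE: "average",
    ELECTRODE: "electrode",
}

_NAME_TO_LABEL = {v: k for k, v in TISSUE_NAMES.items()}

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclasses.dataclass
class VoxelHeadModel:
    """Labelled voxel grid with a label -> conductivity lookup."""

    labels: np.ndarray
    voxel_size_mm: float
    conductivity: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITY)
    )
    tissue_names: Mapping[int, str] = dataclasses.field(
        default_factory=lambda: dict(TISSUE_NAMES)
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3-D grid")
        if self.voxel_size_mm <= 0:
            raise ValidationError("voxel_size_mm must be positive")
        self.validate()

    def validate(self) -> None:
        present = np.unique(self.labels)
        for lab in present:
            if int(lab) not in self.conductivity:
                raise ValidationError(f"label {lab} has no conductivity")
            if self.conductivity[int(lab)] <= 0:
                raise ValidationError(f"conductivity of label {lab} must be > 0")

    def conductivity_volume(self) -> np.ndarray:
        sigma = np.zeros(self.labels.shape)
        for lab, s in self.conductivity.items():
            sigma[self.labels == lab] = s
        return sigma

    def boundary_is_air(self) -> bool:
        lab = self.labels
        faces = [lab[0], lab[-1], lab[:, 0], lab[:, -1],
                 lab[:, :, 0], lab[:, :, -1]]
        return all(np.all(f == AIR) for f in faces)


@dataclasses.dataclass
class ElectrodeSpec:
    """Dirichlet electrode pad: voxel indices held at a fixed potential."""

    pad_voxels: np.ndarray  # (k, 3) integer voxel indices
    role: str  # "source" | "return"
    potential: float
    saline_thickness_mm: float = 2.0

    def __post_init__(self) -> None:
        self.pad_voxels = np.atleast_2d(np.asarray(self.pad_voxels, dtype=int))
        if self.pad_voxels.shape[1] != 3 or self.pad_voxels.shape[0] == 0:
            raise ValidationError("pad_voxels must be a nonempty (k, 3) index array")
        if self.role not in ("source", "return"):
            raise ValidationError(f"role must be source|return, got {self.role!r}")

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.pad_voxels.T)] = True
        return m


@dataclasses.dataclass
class FieldSolution:
    """Potential, fields and injected current of one montage solve."""

    phi: np.ndarray            # volts
    efield: np.ndarray         # (3, nx, ny, nz), V/m
    current: np.ndarray        # (3, nx, ny, nz), A/m^2
    jmag: np.ndarray           # |J|, A/m^2
    injected_current: float    # amperes
    sigma: np.ndarray          # S/m, the conductivity grid used
    voxel_size_mm: float


def _resolve_label(tissue: int | str) -> int:
    if isinstance(tissue, str):
        try:
            return _NAME_TO_LABEL[tissue]
        except KeyError as exc:
            raise ValidationError(f"unknown tissue {tissue!r}") from exc
    return int(tissue)


def build_phantom(
    layers: Sequence[tuple[int | str, float | Sequence[float]]],
    voxel_size_mm: float = 2.0,
    pad_voxels: int = 2,
    shoulders: bool | dict = False,
) -> VoxelHeadModel:
    """Concentric-ellipsoid head phantom, optionally fused to shoulders.

    ``layers`` runs outermost first, e.g.
    ``[("skin", (88, 104, 90)), ("bone", (82, 98, 84)), ...]``; scalar
    semi-axes give spheres. Each layer must fit strictly inside the one
    before it. ``shoulders`` adds a block of tissue-average conductivity
    below the head (dict keys ``height_mm`` and ``halfwidth_mm`` override
    the defaults).
    """
    if not layers:
        raise ValidationError("need at least one layer")
    parsed: list[tuple[int, np.ndarray]] = []
    for tissue, semi in layers:
        semi_arr = np.asarray(
            [semi] * 3 if np.isscalar(semi) else semi, dtype=float
        )
        if semi_arr.shape != (3,) or np.any(semi_arr <= 0):
            raise ValidationError(f"bad semi-axes {semi} for layer {tissue}")
        parsed.append((_resolve_label(tissue), semi_arr))
    for (_, outer), (_, inner) in zip(parsed, parsed[1:]):
        if np.any(inner >= outer):
            raise ValidationError(
                "layers out of order: each inner layer must be strictly "
                "smaller than the one enclosing it"
            )

    h = float(voxel_size_mm)
    outer_semi = parsed[0][1]
    sh_cfg = {"height_mm": 60.0, "halfwidth_mm": 1.6 * outer_semi.max()}
    if isinstance(shoulders, dict):
        sh_cfg.update(shoulders)
        shoulders = True
    extra_z = sh_cfg["height_mm"] if shoulders else 0.0
    half_xy = outer_semi[:2].max()
    if shoulders:
        half_xy = max(half_xy, sh_cfg["halfwidth_mm"])

    nx = int(np.ceil(2 * half_xy / h)) + 2 * pad_voxels
    ny = nx
    nz = int(np.ceil((2 * outer_semi[2] + extra_z) / h)) + 2 * pad_voxels
    labels = np.full((nx, ny, nz), AIR, dtype=np.int16)

    # voxel-center coordinates with the head center at the origin
    cx = (nx - 1) / 2.0 * h
    cy = (ny - 1) / 2.0 * h
    cz_head = (nz - 1) / 2.0 * h + extra_z / 2.0
    x = np.arange(nx) * h - cx
    y = np.arange(ny) * h - cy
    z = np.arange(nz) * h - cz_head
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    if shoulders:
        top = -0.5 * outer_semi[2]  # fuse into the lower head
        block = (
            (np.abs(X) <= sh_cfg["halfwidth_mm"])
            & (np.abs(Y) <= outer_semi[1])
            & (Z <= top)
            & (Z >= top - sh_cfg["height_mm"])
        )
        labels[block] = AVERAGE

    for lab, semi in parsed:
        inside = (X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2 <= 1.0
        labels[inside] = lab

    model = VoxelHeadModel(labels=labels, voxel_size_mm=h)
    if not model.boundary_is_air():
        raise ValidationError("phantom must keep at least one air voxel on all faces")
    return model


def attach_electrode(
    model: VoxelHeadModel,
    center_mm: Sequence[float],
    size_mm: tuple[float, float] = (50.0, 70.0),
    direction: str = "+z",
    role: str = "source",
    potential: float = 1.0,
    saline_thickness_mm: float = 2.0,
) -> ElectrodeSpec:
    """Attach a rectangular pad electrode to the phantom surface (in place).

    A saline layer of ``saline_thickness_mm`` is inserted between the skin
    surface and a one-voxel electrode layer covering the pad footprint.
    ``direction`` names the outward surface normal (``"+z"`` attaches from
    above); ``center_mm`` is the footprint center in voxel-grid
    coordinates (voxel centers at ``(i + 0.5) * h``). The pad follows the
    surface curvature column by column.
    """
    if len(direction) != 2 or direction[0] not in "+-" or direction[1] not in _AXES:
        raise ValidationError(f"direction must be like '+z', got {direction!r}")
    ax = _AXES[direction[1]]
    sign = 1 if direction[0] == "+" else -1
    h = model.voxel_size_mm
    labels = model.labels
    shape = labels.shape
    n_sal = max(1, int(round(saline_thickness_mm / h)))

    u_ax, v_ax = [a for a in range(3) if a != ax]
    center_vox = [int(round(c / h - 0.5)) for c in center_mm]
    nu = max(1, int(round(size_mm[0] / h)))
    nv = max(1, int(round(size_mm[1] / h)))
    u0 = center_vox[u_ax] - nu // 2
    v0 = center_vox[v_ax] - nv // 2

    # scan order runs from the outer boundary inward along -sign*axis
    depth = shape[ax]
    scan = range(depth - 1, -1, -1) if sign > 0 else range(depth)

    pad: list[tuple[int, int, int]] = []
    center_found = False
    for iu in range(u0, u0 + nu):
        for iv in range(v0, v0 + nv):
            if not (0 <= iu < shape[u_ax] and 0 <= iv < shape[v_ax]):
                continue
            idx = [0, 0, 0]
            idx[u_ax], idx[v_ax] = iu, iv
            surf = None
            for k in scan:
                idx[ax] = k
                lab = labels[tuple(idx)]
                if lab != AIR:
                    surf = k
                    break
            if surf is None:
                continue
            idx[ax] = surf
            if labels[tuple(idx)] in (SALINE, ELECTRODE):
                raise ValidationError("pad overlaps an existing electrode")
            outermost = surf + sign * (n_sal + 1)
            if not 0 <= outermost < depth:
                raise ValidationError("not enough air padding to place the electrode")
            for j in range(1, n_sal + 1):
                idx[ax] = surf + sign * j
                labels[tuple(idx)] = SALINE
            idx[ax] = outermost
            labels[tuple(idx)] = ELECTRODE
            pad.append(tuple(idx))
            if iu == center_vox[u_ax] and iv == center_vox[v_ax]:
                center_found = True
    if not pad or not center_found:
        raise ValidationError("pad center is not over the phantom surface")
    return ElectrodeSpec(
        pad_voxels=np.array(pad, dtype=int),
        role=role,
        potential=float(potential),
        saline_thickness_mm=float(saline_thickness_mm),
    )


def _face_conductance(sigma: np.ndarray, axis: int, h_m: float):
    """Harmonic-mean conductance (siemens) of the faces along ``axis``."""
    sl1 = [slice(None)] * 3
    sl2 = [slice(None)] * 3
    sl1[axis] = slice(None, -1)
    sl2[axis] = slice(1, None)
    s1, s2 = sigma[tuple(sl1)], sigma[tuple(sl2)]
    # conductance = sigma_face * area / spacing = sigma_face * h
    return 2.0 * s1 * s2 / (s1 + s2) * h_m, tuple(sl1), tuple(sl2)


def solve_laplace(
    model: VoxelHeadModel,
    electrodes: Sequence[ElectrodeSpec],
    tol: float = 1e-8,
    max_iter: int = 20000,
) -> FieldSolution:
    """Solve ``div(sigma grad phi) = 0`` with Dirichlet electrode pads.

    Finite-volume 7-point stencil with harmonic-mean face conductivities;
    the SPD system over the non-electrode voxels is solved by Jacobi-
    preconditioned conjugate gradients to relative residual ``tol``. The
    electric field is obtained by central differences, ``J = sigma E``,
    and the injected current is the net flux out of the source pad.
    """
    roles = sorted(e.role for e in electrodes)
    if roles != ["return", "source"]:
        raise ValidationError(
            f"need exactly one source and one return electrode, got {roles}"
        )
    h_m = model.voxel_size_mm * 1e-3
    sigma = model.conductivity_volume()
    shape = sigma.shape

    dir_mask = np.zeros(shape, dtype=bool)
    dir_val = np.zeros(shape)
    for e in electrodes:
        m = e.mask(shape)
        if np.any(dir_mask & m):
            raise ValidationError("source and return pads overlap")
        dir_mask |= m
        dir_val[m] = e.potential

    free = ~dir_mask
    n_free = int(free.sum())
    idx = -np.ones(shape, dtype=np.int64)
    idx[free] = np.arange(n_free)

    diag = np.zeros(shape)
    b_grid = np.zeros(shape)
    rows, cols, vals = [], [], []
    for axis in range(3):
        g, sl1, sl2 = _face_conductance(sigma, axis, h_m)
        diag[sl1] += g
        diag[sl2] += g
        f1, f2 = free[sl1], free[sl2]
        both = f1 & f2
        rows.append(idx[sl1][both])
        cols.append(idx[sl2][both])
        vals.append(-g[both])
        # flux from Dirichlet neighbours enters the right-hand side
        d2 = f1 & ~f2
        b_grid[sl1][...] = b_grid[sl1] + np.where(d2, g * dir_val[sl2], 0.0)
        d1 = ~f1 & f2
        b_grid[sl2][...] = b_grid[sl2] + np.where(d1, g * dir_val[sl1], 0.0)

    rows = np.concatenate(rows + [idx[free]])
    cols = np.concatenate(cols + [idx[free]])
    vals = np.concatenate(vals + [diag[free]])
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(n_free, n_free))
    A = (A + A.T.tocoo().tocsr() - sparse.diags(diag[free])).tocsr()
    b = b_grid[free]

    inv_diag = 1.0 / diag[free]
    M = LinearOperator((n_free, n_free), matvec=lambda v: inv_diag * v)
    x, info = cg(A, b, rtol=tol, atol=0.0, maxiter=max_iter, M=M)
    if info != 0:
        residual = np.linalg.norm(b - A @ x) / max(np.linalg.norm(b), 1e-300)
        raise SolverError(
            f"CG failed to converge in {max_iter} iterations "
            f"(relative residual {residual:.3e})"
        )

    phi = dir_val.copy()
    phi[free] = x

    grads = np.gradient(phi, h_m)
    efield = -np.stack(grads)
    current = sigma[None] * efield
    jmag = np.sqrt((current**2).sum(axis=0))

    source = next(e for e in electrodes if e.role == "source")
    injected = region_outflux(phi, sigma, h_m, source.mask(shape))
    return FieldSolution(
        phi=phi, efield=efield, current=current, jmag=jmag,
        injected_current=float(injected), sigma=sigma,
        voxel_size_mm=model.voxel_size_mm,
    )


def region_outflux(
    phi: np.ndarray, sigma: np.ndarray, h_m: float, mask: np.ndarray
) -> float:
    """Net current (A) flowing out of the voxel region ``mask``.

    Uses the same harmonic-mean face conductances as the solver, so for
    any closed region containing no electrode the discrete conservation
    law makes this vanish to solver tolerance.
    """
    if not np.any(mask):
        raise ValidationError("empty region mask")
    flux = 0.0
    for axis in range(3):
        g, sl1, sl2 = _face_conductance(sigma, axis, h_m)
        m1, m2 = mask[sl1], mask[sl2]
        out = m1 & ~m2
        flux += float((g[out] * (phi[sl1][out] - phi[sl2][out])).sum())
        inward = ~m1 & m2
        flux += float((g[inward] * (phi[sl2][inward] - phi[sl1][inward])).sum())
    return flux


def scale_to_current(sol: FieldSolution, target: float = 1e-3) -> FieldSolution:
    """Rescale a solution so the injected current equals ``target`` amperes.

    The Laplace problem is linear, so potential, fields and current all
    scale by ``target / injected_current``.
    """
    if sol.injected_current <= 0:
        raise DegenerateInputError("injected current must be positive to rescale")
    k = target / sol.injected_current
    return FieldSolution(
        phi=sol.phi * k,
        efield=sol.efield * k,
        current=sol.current * k,
        jmag=sol.jmag * k,
        injected_current=float(target),
        sigma=sol.sigma,
        voxel_size_mm=sol.voxel_size_mm,
    )


def roi_mean_density(sol: FieldSolution, mask: np.ndarray) -> float:
    """Arithmetic mean of |J| (A/m^2) over a voxel region of interest."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != sol.jmag.shape:
        raise ValidationError("mask shape does not match the solution grid")
    if not np.any(mask):
        raise ValidationError("empty ROI mask")
    return float(sol.jmag[mask].mean())


def montage_contrast(
    sol_a: FieldSolution, sol_b: FieldSolution, mask: np.ndarray
) -> float:
    """Relative ROI difference ``100 (mean_A - mean_B) / mean_B`` in percent."""
    if sol_a.jmag.shape != sol_b.jmag.shape:
        raise ValidationError("solutions live on different grids")
    mean_b = roi_mean_density(sol_b, mask)
    if mean_b == 0:
        raise DegenerateInputError("reference montage ROI mean is zero")
    return 100.0 * (roi_mean_density(sol_a, mask) - mean_b) / mean_b


def export_nifti(volume: np.ndarray, voxel_size_mm: float, path) -> None:
    """Write a scalar voxel volume as NIfTI with an isotropic affine."""
    import nibabel as nib

    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))
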