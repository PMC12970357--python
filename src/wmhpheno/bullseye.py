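"""Bullseye mapping: harmonic depth field, layer binning, regional volumetry.

The white-matter domain is assigned a scalar depth in [0, 1] by solving the
Laplace equation with Dirichlet conditions 0 on the inner (ventricular)
boundary and 1 on the outer (cortical) boundary, then binned into equal
depth layers. Lesion voxels are tallied per (lobe, layer) cell using true
voxel dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .regions import LOBES, N_LAYERS, N_LOBES, REGION_COLUMNS

__all__ = [
    "LabelVolume",
    "DepthField",
    "RegionalWMHVector",
    "solve_laplace_depth",
    "bin_layers",
    "regional_volumes",
    "load_label_volume",
    "save_label_volume",
    "save_depth_field",
]


@dataclass
class LabelVolume:
    """Integer label grid with physical voxel dimensions."""

    grid: np.ndarray
    voxel_dims: tuple[float, ...]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)
        if any(v <= 0 for v in self.voxel_dims):
            raise ValueError(f"voxel_dims must be > 0, got {self.voxel_dims}")
        if len(self.voxel_dims) != self.grid.ndim:
            raise ValueError(
                f"voxel_dims length {len(self.voxel_dims)} != grid ndim "
                f"{self.grid.ndim}")
        if self.affine is None:
            aff = np.eye(4)
            for i, v in enumerate(self.voxel_dims[:3]):
                aff[i, i] = v
            self.affine = aff

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_dims))

    def as_bool(self) -> np.ndarray:
        vals = np.unique(self.grid)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask is not {{0,1}}-valued (labels {vals[:5]})")
        return self.grid.astype(bool)


@dataclass
class DepthField:
    """Normalised harmonic depth on the white-matter domain (NaN outside)."""

    values: np.ndarray
    domain: np.ndarray
    voxel_dims: tuple[float, ...]
    iterations: int = 0
    residual: float = np.inf
    converged: bool = False
    n_filled: int = 0  # voxels filled by nearest-neighbour (isolated islands)

    def __post_init__(self) -> None:
        inside = self.values[self.domain]
        if inside.size and (np.nanmin(inside) < -1e-9
                            or np.nanmax(inside) > 1 + 1e-9):
            raise ValueError("depth values outside [0,1] on the domain")


def _neighbour_sums(values: np.ndarray, valid: np.ndarray,
                    weights: tuple[float, ...]):
    """Weighted sums of valid face-neighbour values and of their weights."""
    num = np.zeros_like(values)
    den = np.zeros_like(values)
    for ax, w in enumerate(weights):
        for shift in (1, -1):
            v = np.roll(values, shift, axis=ax)
            ok = np.roll(valid, shift, axis=ax)
            # rolled-in border slabs are invalid
            sl = [slice(None)] * values.ndim
            sl[ax] = 0 if shift == 1 else -1
            ok = ok.copy()
            ok[tuple(sl)] = False
            num += w * np.where(ok, v, 0.0)
            den += w * ok
    return num, den


def solve_laplace_depth(wm: LabelVolume, inner: LabelVolume, outer: LabelVolume,
                        tol: float = 1e-6, max_iter: int = 50_000,
                        method: str = "sor", omega: float | None = None,
                        init: float = 0.5) -> DepthField:
    """Solve the discrete Laplace equation for normalised depth.

    Dirichlet values: 0 on ``inner``, 1 on ``outer``; unknowns are the
    ``wm`` voxels (boundary labels take precedence where masks overlap the
    domain). The stencil uses face neighbours weighted by 1/h^2 per axis, so
    anisotropic voxels are handled in physical space. Voxels unreachable
    from both boundaries are filled from their nearest solved/boundary
    neighbour and counted in ``n_filled``.

    ``method`` is ``"sor"`` (red-black successive over-relaxation, the
    default) or ``"direct"`` (sparse solve of the same fixed point).
    Non-convergence at ``max_iter`` warns and flags the field, it is not
    fatal.
    """
    wm_mask = wm.as_bool()
    inner_mask = inner.as_bool()
    outer_mask = outer.as_bool()
    if not (wm_mask.shape == inner_mask.shape == outer_mask.shape):
        raise ValueError("wm, inner and outer grids must share one shape")
    if (inner_mask & outer_mask).any():
        raise ValueError("inner and outer boundaries overlap")
    unknown = wm_mask & ~inner_mask & ~outer_mask
    if not unknown.any():
        raise ValueError("white-matter domain is empty")

    weights = tuple(1.0 / h**2 for h in wm.voxel_dims)
    values = np.zeros(wm_mask.shape, dtype=float)
    values[unknown] = init
    values[inner_mask] = 0.0
    values[outer_mask] = 1.0
    valid = unknown | inner_mask | outer_mask

    iterations = 0
    residual = np.inf
    converged = False

    if np.isinf(tol):
        converged = True
        residual = 0.0
    elif method == "direct":
        values = _solve_direct(values, unknown, valid, weights)
        num, den = _neighbour_sums(values, valid, weights)
        upd = np.zeros_like(values)
        ok = unknown & (den > 0)
        upd[ok] = num[ok] / den[ok] - values[ok]
        residual = float(np.abs(upd).max()) if ok.any() else 0.0
        converged = True
        iterations = 1
    elif method == "sor":
        if omega is None:
            n = max(values.shape)
            omega = 2.0 / (1.0 + np.sin(np.pi / (n + 1)))
        idx = np.indices(values.shape).sum(axis=0)
        colors = [unknown & (idx % 2 == 0), unknown & (idx % 2 == 1)]
        for iterations in range(1, max_iter + 1):
            residual = 0.0
            for color in colors:
                num, den = _neighbour_sums(values, valid, weights)
                ok = color & (den > 0)
                upd = num[ok] / den[ok] - values[ok]
                values[ok] += omega * upd
                if upd.size:
                    residual = max(residual, float(np.abs(upd).max()))
            if residual < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"Laplace solve did not converge in {max_iter} iterations "
                f"(residual {residual:.3g})", RuntimeWarning)
    else:
        raise ValueError(f"unknown method {method!r}")

    values = np.clip(values, 0.0, 1.0)

    # fill voxels with no path to either boundary from nearest assigned voxel
    n_filled = 0
    reachable = _boundary_reachable(unknown, inner_mask | outer_mask)
    isolated = unknown & ~reachable
    if isolated.any():
        n_filled = int(isolated.sum())
        assigned = valid & ~isolated
        _, ind = ndimage.distance_transform_edt(
            ~assigned, sampling=wm.voxel_dims, return_indices=True)
        values[isolated] = values[tuple(i[isolated] for i in ind)]

    out = np.full(values.shape, np.nan)
    out[unknown] = values[unknown]
    return DepthField(values=out, domain=unknown, voxel_dims=wm.voxel_dims,
                      iterations=iterations, residual=residual,
                      converged=converged, n_filled=n_filled)


def _boundary_reachable(unknown: np.ndarray, boundary: np.ndarray) -> np.ndarray:
    """Unknown voxels whose face-connected component touches a boundary."""
    struct = ndimage.generate_binary_structure(unknown.ndim, 1)
    lab, nlab = ndimage.label(unknown, structure=struct)
    if nlab == 0:
        return np.zeros_like(unknown)
    grown = ndimage.binary_dilation(boundary, structure=struct)
    touching = np.unique(lab[grown & unknown])
    return np.isin(lab, touching[touching > 0])


def _solve_direct(values, unknown, valid, weights):
    from scipy.sparse import coo_matrix
    from scipy.sparse.linalg import spsolve

    shape = values.shape
    n_unk = int(unknown.sum())
    index = -np.ones(shape, dtype=np.int64)
    index[unknown] = np.arange(n_unk)
    rows, cols, data = [], [], []
    rhs = np.zeros(n_unk)
    diag = np.zeros(n_unk)
    coords = np.argwhere(unknown)
    for ax, w in enumerate(weights):
        for shift in (1, -1):
            nb = coords.copy()
            nb[:, ax] += shift
            inb = (nb[:, ax] >= 0) & (nb[:, ax] < shape[ax])
            src = index[tuple(coords[inb].T)]
            nb_t = tuple(nb[inb].T)
            is_valid = valid[nb_t]
            diag_add = np.zeros(len(src))
            diag_add[is_valid] = w
            np.add.at(diag, src, diag_add)
            nb_unknown = unknown[nb_t]
            rows.extend(src[nb_unknown])
            cols.extend(index[tuple(nb[inb][nb_unknown].T)])
            data.extend([-w] * int(nb_unknown.sum()))
            fixed = is_valid & ~nb_unknown
            np.add.at(rhs, src[fixed], w * values[tuple(nb[inb][fixed].T)])
    solvable = diag > 0
    rows.extend(np.arange(n_unk))
    cols.extend(np.arange(n_unk))
    data.extend(np.where(solvable, diag, 1.0))
    A = coo_matrix((data, (rows, cols)), shape=(n_unk, n_unk)).tocsr()
    rhs[~solvable] = values[unknown][~solvable]  # keep init for isolated voxels
    sol = spsolve(A, rhs)
    out = values.copy()
    out[unknown] = sol
    return out


def bin_layers(depth: DepthField, n_layers: int = N_LAYERS) -> LabelVolume:
    """Bin depth into equal layers 1..n (periventricular to juxtacortical).

    Bins are half-open, upper-inclusive: layer l covers ((l-1)/n, l/n],
    with depth 0 in layer 1.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    layers = np.zeros(depth.values.shape, dtype=np.int16)
    vals = depth.values[depth.domain]
    lab = np.ceil(vals * n_layers).astype(np.int16)
    lab[lab < 1] = 1
    lab[lab > n_layers] = n_layers
    layers[depth.domain] = lab
    return LabelVolume(grid=layers, voxel_dims=depth.voxel_dims)


@dataclass
class RegionalWMHVector:
    """36 regional lesion volumes (mm^3) keyed by (lobe, layer)."""

    volumes: np.ndarray  # ordered as regions.REGION_COLUMNS
    unassigned_mm3: float = 0.0

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.shape != (len(REGION_COLUMNS),):
            raise ValueError(
                f"expected {len(REGION_COLUMNS)} volumes, got "
                f"{self.volumes.shape}")
        if (self.volumes < 0).any() or self.unassigned_mm3 < 0:
            raise ValueError("volumes must be >= 0")

    @property
    def total_mm3(self) -> float:
        return float(self.volumes.sum())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(REGION_COLUMNS, map(float, self.volumes)))


def regional_volumes(wmh: LabelVolume, lobes: LabelVolume, layers: LabelVolume,
                     voxel_dims: tuple[float, ...] | None = None
                     ) -> RegionalWMHVector:
    """Tally lesion volume per (lobe, layer) cell using true voxel volume.

    Lesion voxels outside lobe/layer coverage are reported in the
    ``unassigned_mm3`` remainder rather than dropped, so
    ``total + unassigned`` always equals lesion voxel count x voxel volume.
    """
    for name, vol in (("lobes", lobes), ("layers", layers)):
        if vol.grid.shape != wmh.grid.shape:
            raise ValueError(
                f"shape mismatch between wmh {wmh.grid.shape} and {name} "
                f"{vol.grid.shape}")
    dims = tuple(voxel_dims) if voxel_dims is not None else wmh.voxel_dims
    voxel_vol = float(np.prod(dims))

    mask = wmh.as_bool()
    lobe = lobes.grid[mask].astype(np.int64)
    layer = layers.grid[mask].astype(np.int64)
    covered = (lobe >= 1) & (lobe <= N_LOBES) & (layer >= 1) & (layer <= N_LAYERS)
    cell = (lobe[covered] - 1) * N_LAYERS + (layer[covered] - 1)
    counts = np.bincount(cell, minlength=len(REGION_COLUMNS))
    unassigned = float((~covered).sum()) * voxel_vol
    return RegionalWMHVector(volumes=counts * voxel_vol,
                             unassigned_mm3=unassigned)


# ---------------------------------------------------------------------------
# NIfTI I/O (2D grids are promoted to singleton third axes)


def _promote(grid: np.ndarray, voxel_dims):
    if grid.ndim == 2:
        return grid[:, :, None], (*voxel_dims, 1.0)
    return grid, voxel_dims


def save_label_volume(vol: LabelVolume, path) -> None:
    import nibabel as nib

    grid, dims = _promote(vol.grid, vol.voxel_dims)
    aff = np.diag((*dims[:3], 1.0))
    nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.int16), aff), str(path))


def save_depth_field(depth: DepthField, path) -> None:
    import nibabel as nib

    grid, dims = _promote(np.nan_to_num(depth.values, nan=-1.0),
                          depth.voxel_dims)
    aff = np.diag((*dims[:3], 1.0))
    nib.save(nib.Nifti1Image(grid.astype(np.float32), aff), str(path))


def load_label_volume(path) -> LabelVolume:
    import nibabel as nib

    img = nib.load(str(path))
    grid = np.asarray(img.dataobj)
    dims = tuple(float(z) for z in img.header.get_zooms()[:grid.ndim])
    if grid.ndim == 3 and grid.shape[2] == 1:
        grid = grid[:, :, 0]
        dims = dims[:2]
    return LabelVolume(grid=grid.astype(np.int32), voxel_dims=dims,
                       affine=np.asarray(img.affine))
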