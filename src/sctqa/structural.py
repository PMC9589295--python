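"""Structural descriptions for organ-driven registration.

Each organ contributes a scalar field encoding where its surface is and how
deep a voxel sits inside it: a signed Euclidean distance map for blob-like
structures, a Laplace field normalised to [0, 1] for the rectum (distance to
the central path) and the prostate (distance to the barycenter).  The fields
are rescaled to disjoint intensity bands, summed, and alpha-blended with the
intensity-normalised MRI into one merged structural description that drives
the Demons stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .core import Geometry, StructureError, StructureSet, VolumeGrid

#: disjoint intensity bands: organ o contributes values in (0, band[o]],
#: and the bands are combined so each organ's vicinity keeps its own level
DEFAULT_BANDS = {
    "body": 0.2,
    "bones": 0.4,
    "rectum": 0.6,
    "prostate": 0.8,
    "bladder": 1.0,
}

ORGAN_FIELD_KIND = {
    "bladder": "distance",
    "rectum": "tubular",
    "prostate": "radial",
    "bones": "distance",
    "body": "distance",
}


def distance_map(mask: np.ndarray, geometry: Geometry) -> VolumeGrid:
    """Signed Euclidean distance in mm: negative inside, positive outside.

    Outside voxels measure the distance to the nearest mask voxel centre,
    inside voxels the (negated) distance to the nearest background voxel
    centre; surface voxels are therefore within one voxel of zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise StructureError("empty mask")
    sampling = geometry.spacing
    d_out = ndimage.distance_transform_edt(~mask, sampling=sampling)
    d_in = ndimage.distance_transform_edt(mask, sampling=sampling)
    signed = np.where(mask, -d_in, d_out)
    return VolumeGrid(signed, geometry.spacing, geometry.origin, "unitless")


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    return mask & ~eroded


def _solve_laplace(mask: np.ndarray, sink: np.ndarray, geometry: Geometry
                   ) -> np.ndarray:
    """Discrete harmonic field inside ``mask``: 1 on the surface, 0 on the
    sink, solved exactly with a sparse direct solve (6-neighbour Laplacian
    weighted by 1/h^2 per axis)."""
    surface = _surface_voxels(mask)
    out = np.ones(mask.shape)
    out[mask] = 1.0
    out[sink] = 0.0
    fixed = surface | sink | ~mask
    unknown = mask & ~fixed
    n = int(unknown.sum())
    if n == 0:
        return out
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[unknown] = np.arange(n)
    h2 = [1.0 / s**2 for s in geometry.spacing]
    rows, cols, vals = [], [], []
    b = np.zeros(n)
    diag = np.zeros(n)
    ij = np.argwhere(unknown)
    for axis in range(3):
        for step in (-1, 1):
            nb = ij.copy()
            nb[:, axis] += step
            # neighbours outside the array cannot occur: unknown voxels are
            # interior to the mask, whose surface layer is fixed
            nb_flat = tuple(nb.T)
            w = h2[axis]
            diag += w
            nb_idx = idx[nb_flat]
            free = nb_idx >= 0
            rows.append(idx[tuple(ij[free].T)])
            cols.append(nb_idx[free])
            vals.append(np.full(free.sum(), -w))
            fixed_nb = ~free
            if fixed_nb.any():
                b_add = w * out[tuple(nb[fixed_nb].T)]
                np.add.at(b, idx[tuple(ij[fixed_nb].T)], b_add)
    A = sparse.coo_matrix(
        (np.concatenate(vals + [diag]),
         (np.concatenate(rows + [np.arange(n)]),
          np.concatenate(cols + [np.arange(n)]))),
        shape=(n, n),
    ).tocsr()
    u = spsolve(A, b)
    out[unknown] = np.clip(u, 0.0, 1.0)
    return out


def _require_connected(mask: np.ndarray) -> None:
    _, n = ndimage.label(mask)
    if n != 1:
        raise StructureError(f"mask must be one connected component, got {n}")


def _snap_to_mask(point_vox: np.ndarray, mask: np.ndarray) -> tuple:
    p = tuple(int(round(c)) for c in point_vox)
    p = tuple(np.clip(p, 0, np.asarray(mask.shape) - 1))
    if mask[p]:
        return p
    candidates = np.argwhere(mask)
    d2 = ((candidates - np.asarray(p)) ** 2).sum(axis=1)
    return tuple(candidates[int(np.argmin(d2))])


def laplace_field_tubular(mask: np.ndarray, geometry: Geometry) -> VolumeGrid:
    """Laplace field of a tube: 0 on the central path, 1 on the wall.

    The central path is the chain of slice-wise in-plane centroids along the
    tube (z) axis, snapped into the mask where the centroid falls outside
    (curved tubes).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise StructureError("empty mask")
    _require_connected(mask)
    sink = np.zeros(mask.shape, dtype=bool)
    for k in range(mask.shape[2]):
        sl = mask[:, :, k]
        if not sl.any():
            continue
        com = ndimage.center_of_mass(sl)
        i, j = _snap_to_mask(np.asarray(com), sl)
        sink[i, j, k] = True
    out = _solve_laplace(mask, sink, geometry)
    return VolumeGrid(out, geometry.spacing, geometry.origin, "unitless")


def laplace_field_radial(mask: np.ndarray, geometry: Geometry) -> VolumeGrid:
    """Laplace field of a blob: 0 at the barycenter voxel, 1 at the surface."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise StructureError("empty mask")
    _require_connected(mask)
    com = np.asarray(ndimage.center_of_mass(mask))
    sink = np.zeros(mask.shape, dtype=bool)
    sink[_snap_to_mask(com, mask)] = True
    out = _solve_laplace(mask, sink, geometry)
    return VolumeGrid(out, geometry.spacing, geometry.origin, "unitless")


def organ_field(mask: np.ndarray, geometry: Geometry, kind: str = "distance",
                d_max_mm: float = 20.0) -> VolumeGrid:
    """Organ scalar field in [0, 1], continuous across the surface (0.5).

    Outside: 0.5 + 0.5 * clip(d / d_max); inside: either the mirrored
    distance ramp (``distance``) or half the Laplace field (``tubular`` /
    ``radial``), which is likewise 0.5 at the surface and 0 at the sink.
    """
    d = distance_map(mask, geometry).values
    ramp = 0.5 + 0.5 * np.clip(d / d_max_mm, -1.0, 1.0)
    if kind == "distance":
        values = ramp
    elif kind in ("tubular", "radial"):
        solver = laplace_field_tubular if kind == "tubular" else laplace_field_radial
        lap = solver(mask, geometry).values
        values = np.where(np.asarray(mask, bool), 0.5 * lap, ramp)
    else:
        raise ValueError(f"unknown field kind {kind!r}")
    return VolumeGrid(values, geometry.spacing, geometry.origin, "unitless")


@dataclass
class StructuralDescription:
    geometry: Geometry
    organ_fields: dict = dfield(default_factory=dict)   # organ -> VolumeGrid [0,1]
    contributions: dict = dfield(default_factory=dict)  # band-rescaled fields
    mri_norm: VolumeGrid | None = None
    organ_merged: VolumeGrid | None = None              # global organ SD
    merged: VolumeGrid | None = None                    # blended with MRI


def build_sd(mri: VolumeGrid, structures: StructureSet, w_sd: float = 0.5,
             bands: dict | None = None, d_max_mm: float = 20.0
             ) -> StructuralDescription:
    """Structural description: per-organ fields, a global organ SD, and the
    MRI-blended merged image.

    Two views of each organ are produced.  ``organ_fields`` are the per-organ
    stage channels (distance ramp / Laplace interior, [0, 1]).  For the
    global description, each organ contributes a localized bump — its band
    amplitude inside the organ, fading to zero ``d_max_mm`` outside — and
    the bumps combine by maximum, so every organ's vicinity keeps a distinct
    intensity level and the field is flat far from all structures (which
    keeps the global Demons stage from chasing structure that is not there).
    """
    bands = bands or DEFAULT_BANDS
    structures.require(*bands.keys())
    geo = structures.geometry
    sd = StructuralDescription(geometry=geo)
    acc = np.zeros(geo.shape)
    for organ, amplitude in bands.items():
        f = organ_field(structures[organ], geo,
                        kind=ORGAN_FIELD_KIND.get(organ, "distance"),
                        d_max_mm=d_max_mm)
        sd.organ_fields[organ] = f
        d = distance_map(structures[organ], geo).values
        bump = amplitude * np.clip(1.0 - np.maximum(d, 0.0) / d_max_mm, 0.0, 1.0)
        sd.contributions[organ] = VolumeGrid(bump, geo.spacing, geo.origin,
                                             "unitless")
        acc = np.maximum(acc, bump)
    sd.organ_merged = VolumeGrid(acc, geo.spacing, geo.origin, "unitless")
    body = structures["body"]
    scale = np.percentile(mri.values[body], 99) if body.any() else mri.values.max()
    mri_norm = np.clip(mri.values / max(scale, 1e-9), 0.0, 1.0)
    sd.mri_norm = VolumeGrid(mri_norm, geo.spacing, geo.origin, "unitless")
    merged = (1.0 - w_sd) * mri_norm + w_sd * acc
    sd.merged = VolumeGrid(merged, geo.spacing, geo.origin, "unitless")
    return sd


def select_template(cohort, organs=("bladder", "rectum", "prostate")) -> str:
    """Patient whose organ volumes are jointly closest to the cohort medians.

    Score = sum over organs of |v - median(v)| / median(v); ties break to the
    lowest patient id.
    """
    if len(cohort) < 3:
        raise StructureError("template selection needs at least 3 patients")
    vols = {}
    for case in cohort:
        case.structures.require(*organs)
        vols[case.id] = np.array(
            [case.structures.volume_cm3(o) for o in organs])
    med = np.median(np.stack(list(vols.values())), axis=0)
    scores = {cid: float(np.sum(np.abs(v - med) / np.maximum(med, 1e-12)))
              for cid, v in vols.items()}
    best = min(scores)  # lowest id first for ties
    for cid in sorted(scores):
        if scores[cid] < scores[best] - 1e-15:
            best = cid
    return best
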