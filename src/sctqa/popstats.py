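"""Voxel-wise population statistics in the common coordinate system.

Given per-voxel aligned stacks of reference and synthetic volumes, computes
mean error maps across the cohort (vMAE, vME, vMAPE), the coefficient of
variation of the absolute error (RSD_AE, an uncertainty map), and a
studentized paired permutation test per voxel: the null of equal reference
and synthetic values is simulated by randomly swapping each patient's pair,
which is equivalent to flipping the sign of the paired difference.  Voxels
with p below alpha form the error subregions (ESRs).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .core import Geometry, VolumeGrid


class CohortError(ValueError):
    pass


@dataclass
class CohortStack:
    """p aligned patient volumes in the CCS plus the analysis mask
    (template body contour); statistics are computed only inside it."""

    volumes: np.ndarray            # (p, nx, ny, nz)
    geometry: Geometry
    patient_ids: tuple
    analysis_mask: np.ndarray
    unit: str = "unitless"

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=np.float64)
        if self.volumes.ndim != 4:
            raise CohortError("stack must be (patients, nx, ny, nz)")
        if self.volumes.shape[0] < 2:
            raise CohortError("need at least 2 patients")
        if self.volumes.shape[1:] != self.geometry.shape:
            raise CohortError("stack shape does not match geometry")
        if len(self.patient_ids) != self.volumes.shape[0]:
            raise CohortError("one patient id per volume required")
        self.analysis_mask = np.asarray(self.analysis_mask, dtype=bool)

    @property
    def p(self) -> int:
        return self.volumes.shape[0]

    @classmethod
    def from_volumes(cls, vols: "list[VolumeGrid]", ids, analysis_mask):
        geo = vols[0].geometry
        for v in vols[1:]:
            vols[0].check_compatible(v)
        return cls(np.stack([v.values for v in vols]), geo, tuple(ids),
                   analysis_mask, vols[0].unit)


def _check_paired(ref: CohortStack, pred: CohortStack) -> None:
    if ref.patient_ids != pred.patient_ids:
        raise CohortError(f"mismatched patient ids: {ref.patient_ids} "
                          f"vs {pred.patient_ids}")
    if not ref.geometry.compatible(pred.geometry):
        raise CohortError("stacks must share geometry")


@dataclass
class VoxelStatMaps:
    vmae: VolumeGrid
    vme: VolumeGrid
    vmape: VolumeGrid        # NaN where no patient had a valid reference
    rsd_ae: VolumeGrid       # NaN where vMAE ~ 0 (undefined)
    vmape_count: np.ndarray  # valid patients per voxel for vMAPE


def voxelwise_maps(ref: CohortStack, pred: CohortStack,
                   eps: float | None = None) -> VoxelStatMaps:
    """vMAE/vME/vMAPE/RSD_AE maps across the cohort, inside the analysis
    mask (NaN outside)."""
    _check_paired(ref, pred)
    if eps is None:
        eps = {"HU": 1.0, "Gy": 0.01}.get(ref.unit, 1e-6)
    mask = ref.analysis_mask
    d = ref.volumes - pred.volumes
    ad = np.abs(d)
    vmae = ad.mean(axis=0)
    vme = d.mean(axis=0)

    valid = np.abs(ref.volumes) >= eps
    n_valid = valid.sum(axis=0)
    ape = np.where(valid, ad / np.maximum(np.abs(ref.volumes), eps), 0.0)
    with np.errstate(invalid="ignore"):
        vmape = np.where(n_valid > 0, ape.sum(axis=0) / n_valid, np.nan)

    # RSD_AE = sqrt(mean((AE - vMAE)^2)) / vMAE, the coefficient of variation
    rsd = np.sqrt(((ad - vmae) ** 2).mean(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rsd_ae = np.where(vmae >= eps, rsd / vmae, np.nan)

    def volgrid(v):
        out = np.where(mask, v, np.nan)
        return VolumeGrid(out, ref.geometry.spacing, ref.geometry.origin,
                          "unitless")

    maps = VoxelStatMaps(
        vmae=volgrid(vmae), vme=volgrid(vme), vmape=volgrid(vmape),
        rsd_ae=volgrid(rsd_ae), vmape_count=np.where(mask, n_valid, 0),
    )
    maps.vmae.unit = ref.unit
    maps.vme.unit = ref.unit
    return maps


@dataclass
class PValueVolume:
    pvalues: VolumeGrid
    n_permutations: int
    seed: int
    alpha: float
    analysis_mask: np.ndarray = dfield(default=None)


def _studentized(mean: np.ndarray, sumsq: np.ndarray, p: int) -> np.ndarray:
    """T = mean / (sd / sqrt(p)) with sample sd; +/-inf when sd == 0 and the
    mean is nonzero, 0 when all differences vanish."""
    var = (sumsq - p * mean**2) / (p - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / p)
        t = np.where((var == 0) & (mean != 0), np.inf * np.sign(mean), t)
        t = np.where((var == 0) & (mean == 0), 0.0, t)
    return t


def paired_permutation_test(ref: CohortStack, pred: CohortStack,
                            n_perm: int = 10000, alpha: float = 0.05,
                            seed: int = 0,
                            chunk_voxels: int = 20000) -> PValueVolume:
    """Voxel-wise studentized sign-flip test of ref == pred.

    The observed statistic is T = mean(D) / (sd(D)/sqrt(p)) with D_j the
    paired difference of patient j.  The null swaps each pair independently
    (negates D_j); the same n_perm flip vectors, drawn from ``seed``, are
    reused across voxels.  Two-sided p-value with the add-one estimator,
    p = (1 + #{|T*| >= |T|}) / (n_perm + 1), so p >= 1/(n_perm+1) > 0.
    All-zero-difference voxels carry no evidence and get p = 1.
    """
    _check_paired(ref, pred)
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable p-values")
    p = ref.p
    mask = ref.analysis_mask
    d_all = (ref.volumes - pred.volumes)[:, mask]  # (p, n_voxels)
    n_vox = d_all.shape[1]

    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, p)).astype(np.float64) * 2.0 - 1.0

    pv = np.empty(n_vox)
    for lo in range(0, n_vox, chunk_voxels):
        d = d_all[:, lo:lo + chunk_voxels]
        sumsq = (d**2).sum(axis=0)
        t_obs = _studentized(d.mean(axis=0), sumsq, p)
        means = (signs @ d) / p                     # (n_perm, chunk)
        t_perm = _studentized(means, sumsq[None, :], p)
        with np.errstate(invalid="ignore"):
            count = (np.abs(t_perm) >= np.abs(t_obs)[None, :]).sum(axis=0)
        pv[lo:lo + chunk_voxels] = (1.0 + count) / (n_perm + 1.0)
        # degenerate all-zero voxels: no evidence against the null
        pv[lo:lo + chunk_voxels][(sumsq == 0)] = 1.0

    out = np.ones(ref.geometry.shape)
    out[mask] = pv
    vol = VolumeGrid(out, ref.geometry.spacing, ref.geometry.origin,
                     "probability")
    return PValueVolume(pvalues=vol, n_permutations=n_perm, seed=seed,
                        alpha=alpha, analysis_mask=mask)


def esr_mask(pvals: PValueVolume, alpha: float | None = None) -> np.ndarray:
    """Error subregions: voxels with p strictly below alpha, inside the
    analysis mask."""
    alpha = pvals.alpha if alpha is None else alpha
    m = pvals.pvalues.values < alpha
    if pvals.analysis_mask is not None:
        m &= pvals.analysis_mask
    return m
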