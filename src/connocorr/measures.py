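"""Per-session regional measures: ROI means, ReHo (Kendall's W), confound
regression, and global-mean scaling.

These operate on post-preprocessing imagery: a 3-D measure volume (gray
matter volume map, PET uptake map, ReHo map) or a 4-D resting-state series,
together with a label atlas on the same grid. Spatial preprocessing
(realignment, normalization, smoothing) is out of scope here; inputs are
assumed already in a common space. ``compute_reho`` accepts pre-smoothed
series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "LabelVolume",
    "RehoMap",
    "extract_roi_means",
    "friston24",
    "build_confound_matrix",
    "regress_confounds",
    "compute_reho",
    "kendalls_w",
    "scale_global",
    "NEIGHBORHOOD_OFFSETS",
]


# ---------------------------------------------------------------------------
# Containers and I/O
# ---------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """3-D integer label atlas (0 = background) with affine and a label table."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got {self.data.ndim}-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must hold integer labels")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if 0 in self.labels:
            raise ValueError("label 0 is reserved for background")
        if not self.labels:
            present = np.unique(self.data)
            self.labels = {int(v): f"ROI_{int(v)}" for v in present if v != 0}

    @property
    def roi_names(self) -> list[str]:
        return [self.labels[k] for k in sorted(self.labels)]

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path, labels: dict[int, str] | None = None) -> "LabelVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj).astype(int), img.affine, labels or {})


@dataclass
class RehoMap:
    """Voxel-wise Kendall's W map with the per-voxel neighborhood size used.

    Values lie in [0, 1]; voxels where concordance is undefined (all neighbor
    series constant, or fewer than two in-mask neighbors) are NaN and excluded
    from ``defined``.
    """

    data: np.ndarray
    k_map: np.ndarray
    mask: np.ndarray
    neighborhood: int

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.data)

    def to_nifti(self, path, affine=None) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32),
                                 np.eye(4) if affine is None else affine), str(path))


# ---------------------------------------------------------------------------
# ROI means and global scaling
# ---------------------------------------------------------------------------

def extract_roi_means(volume: np.ndarray, labels: LabelVolume) -> pd.Series:
    """Average voxel values within each atlas label.

    Returns a Series indexed by ROI name. ROIs without any voxel in the
    volume are NaN (flagged missing), never silently zero.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape != labels.data.shape:
        raise ValueError(
            f"volume grid {volume.shape} does not match label grid "
            f"{labels.data.shape}")
    out = {}
    for lab in sorted(labels.labels):
        sel = labels.data == lab
        out[labels.labels[lab]] = volume[sel].mean() if sel.any() else np.nan
    return pd.Series(out, dtype=float)


def scale_global(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Divide a measure volume by its mean within a mask (PET-style scaling).

    The output's mean within the mask is exactly 1; the operation is invariant
    to any positive rescaling of the input.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume.shape}")
    m = volume[mask].mean() if mask.any() else 0.0
    if not m > 0:
        raise ValueError(f"mask mean must be positive, got {m}")
    return volume / m


# ---------------------------------------------------------------------------
# Confound regression
# ---------------------------------------------------------------------------

def friston24(motion_params: np.ndarray) -> np.ndarray:
    """Friston 24-parameter expansion of 6 rigid-body motion series.

    Columns are [M, M(t-1), M^2, M(t-1)^2]; the one-lag block is zero-padded
    at the first timepoint.
    """
    M = np.asarray(motion_params, dtype=float)
    if M.ndim != 2 or M.shape[1] != 6:
        raise ValueError(f"motion parameters must be t x 6, got {M.shape}")
    if M.shape[0] < 2:
        raise ValueError("need at least 2 timepoints for the lagged expansion")
    lag = np.vstack([np.zeros((1, 6)), M[:-1]])
    return np.hstack([M, lag, M ** 2, lag ** 2])


def build_confound_matrix(motion_params: np.ndarray,
                          nuisance_signals: np.ndarray | None = None,
                          n_components: int = 5) -> np.ndarray:
    """Assemble the t x 30 confound design: Friston-24 motion regressors,
    the first ``n_components`` principal components of white-matter/CSF
    signals, and an intercept."""
    F = friston24(motion_params)
    cols = [F]
    if nuisance_signals is not None:
        S = np.asarray(nuisance_signals, dtype=float)
        if S.shape[0] != F.shape[0]:
            raise ValueError(
                f"nuisance signals have {S.shape[0]} timepoints, motion has "
                f"{F.shape[0]}")
        S = S - S.mean(axis=0)
        U, s, _ = np.linalg.svd(S, full_matrices=False)
        k = min(n_components, (s > 1e-12 * s.max()).sum() if s.size else 0)
        cols.append(U[:, :k] * s[:k])
    cols.append(np.ones((F.shape[0], 1)))
    return np.hstack(cols)


def _prune_collinear(C: np.ndarray, tol: float = 1e-10) -> tuple[np.ndarray, list[int]]:
    """Drop linearly dependent columns (rank-revealing pivoted QR)."""
    _, R, piv = scipy.linalg.qr(C, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    rank = int((d > tol * max(d[0], 1e-300)).sum()) if d.size else 0
    keep = sorted(piv[:rank])
    dropped = sorted(set(range(C.shape[1])) - set(keep))
    return C[:, keep], dropped


def regress_confounds(ts: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualize a time series array against a confound design.

    ``ts`` has time as its last axis (ROI x t matrix or x,y,z,t volume);
    ``confounds`` is t x q. Residuals are the least-squares projection
    complement, orthogonal to every (retained) confound column. Collinear
    confound columns are pruned and logged rather than failing.
    """
    ts = np.asarray(ts, dtype=float)
    C = np.asarray(confounds, dtype=float)
    if C.ndim != 2:
        raise ValueError("confounds must be a 2-D t x q matrix")
    t = ts.shape[-1]
    if C.shape[0] != t:
        raise ValueError(
            f"confounds have {C.shape[0]} rows but the series has {t} timepoints")
    Ck, dropped = _prune_collinear(C)
    if dropped:
        logger.info("regress_confounds: pruned collinear confound columns %s",
                    dropped)
    Y = ts.reshape(-1, t).T                      # t x voxels
    beta, *_ = np.linalg.lstsq(Ck, Y, rcond=None)
    resid = Y - Ck @ beta
    return resid.T.reshape(ts.shape)


# ---------------------------------------------------------------------------
# Regional homogeneity (Kendall's coefficient of concordance)
# ---------------------------------------------------------------------------

def _offsets(neighborhood: int) -> np.ndarray:
    """Voxel offsets for the 7 (faces), 19 (faces+edges) or 27 (cube)
    neighborhood, center included."""
    if neighborhood not in (7, 19, 27):
        raise ValueError(f"neighborhood must be one of 7, 19, 27, got {neighborhood}")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if neighborhood == 7 and order > 1:
                    continue
                if neighborhood == 19 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.array(offs)


NEIGHBORHOOD_OFFSETS = {k: _offsets(k) for k in (7, 19, 27)}


def _tie_term(series: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups of one series (Kendall's correction)."""
    _, counts = np.unique(series, return_counts=True)
    counts = counts[counts > 1]
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kendalls_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance for K series over n timepoints.

    W = 12 * sum_t (R_t - Rbar)^2 / (K^2 (n^3 - n) - K * sum T), where R_t is
    the across-series rank sum at timepoint t and sum T the standard tie
    correction. W is 1 for identical rank orderings and (with ties handled by
    mid-ranks) 0 for perfectly discordant pairs. Returns NaN when every series
    is constant (concordance undefined).
    """
    S = np.asarray(series, dtype=float)
    if S.ndim != 2:
        raise ValueError("series must be K x n")
    K, n = S.shape
    if n < 2 or K < 2:
        raise ValueError(f"need K >= 2 series of n >= 2 timepoints, got {S.shape}")
    ranks = rankdata(S, axis=1)
    R = ranks.sum(axis=0)
    ss = float(((R - R.mean()) ** 2).sum())
    tie = sum(_tie_term(S[i]) for i in range(K))
    denom = K * K * (n ** 3 - n) - K * tie
    if denom <= 0:
        return np.nan
    return 12.0 * ss / denom


def compute_reho(ts: np.ndarray, neighborhood: int = 27,
                 mask: np.ndarray | None = None,
                 scale_by_mean: bool = False) -> RehoMap:
    """Voxel-wise ReHo map: Kendall's W of each voxel's series with its
    neighbors.

    At mask edges the neighborhood shrinks to the available in-mask voxels
    (the per-voxel K actually used is returned in ``k_map``). Voxels whose
    entire neighborhood is constant are flagged NaN. ``scale_by_mean``
    optionally divides the map by its in-mask mean afterwards (whether the
    original pipeline standardized ReHo maps before ROI averaging is not
    documented; default off).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 4:
        raise ValueError(f"expected a 4-D (x, y, z, t) array, got {ts.ndim}-D")
    nx, ny, nz, n = ts.shape
    if n < 2:
        raise ValueError("need at least 2 timepoints for concordance")
    if mask is None:
        mask = np.ones((nx, ny, nz), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (nx, ny, nz):
        raise ValueError(f"mask shape {mask.shape} != grid {(nx, ny, nz)}")

    if neighborhood not in NEIGHBORHOOD_OFFSETS:
        raise ValueError(
            f"neighborhood must be one of 7, 19, 27, got {neighborhood}")
    ranks = rankdata(ts, axis=-1)
    ties = np.zeros((nx, ny, nz))
    for idx in np.argwhere(mask):
        ties[tuple(idx)] = _tie_term(ts[tuple(idx)])
    offs = NEIGHBORHOOD_OFFSETS[neighborhood]

    W = np.full((nx, ny, nz), np.nan)
    Kmap = np.zeros((nx, ny, nz), dtype=int)
    n3n = float(n ** 3 - n)
    for idx in np.argwhere(mask):
        x, y, z = idx
        pts = idx + offs
        ok = np.all((pts >= 0) & (pts < (nx, ny, nz)), axis=1)
        pts = pts[ok]
        pts = pts[mask[pts[:, 0], pts[:, 1], pts[:, 2]]]
        K = len(pts)
        Kmap[x, y, z] = K
        if K < 2:
            continue
        nr = ranks[pts[:, 0], pts[:, 1], pts[:, 2]]       # K x n
        R = nr.sum(axis=0)
        ss = float(((R - R.mean()) ** 2).sum())
        tie = float(ties[pts[:, 0], pts[:, 1], pts[:, 2]].sum())
        denom = K * K * n3n - K * tie
        if denom > 0:
            W[x, y, z] = 12.0 * ss / denom
    if scale_by_mean:
        m = np.nanmean(W[mask])
        if m > 0:
            W = W / m
    return RehoMap(W, Kmap, mask, neighborhood)
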