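"""nT2*w tissue-iron quantification from echo-planar volume series.

The normalized T2*-weighted measure is computed by z-scoring every retained
volume over a coverage mask (voxels non-zero in all volumes), censoring
volumes with framewise displacement above 0.3 mm, taking the voxelwise
median across retained volumes, and averaging within bilateral basal-ganglia
regions.  Lower nT2*w means more tissue iron; values are never sign-flipped
in storage — the reversed axis is a display convention only.

A simplified location-scale batch harmonizer (empirical shrinkage of
per-batch offsets and scales toward their across-region means, with
covariates preserved) stands in for full empirical-Bayes harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd

FD_THRESHOLD_MM = 0.3

PRIMARY_ROIS = ("caudate", "putamen", "globus_pallidus", "nucleus_accumbens")
PUTAMEN_SUBDIVISIONS = (
    "putamen_anterior_dorsal", "putamen_anterior_ventral",
    "putamen_posterior_dorsal", "putamen_posterior_ventral",
)


@dataclass
class VolumeSeries:
    """A 4D intensity series with motion trace and batch metadata."""

    intensities: np.ndarray          # (x, y, z, t)
    fd: np.ndarray                   # per-volume framewise displacement, mm
    session: Optional[str] = None
    batch: Optional[str] = None
    coverage_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, float)
        self.fd = np.asarray(self.fd, float)
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be 4D (x, y, z, t)")
        if len(self.fd) != self.intensities.shape[3]:
            raise ValueError("fd length must equal the number of volumes")
        if self.coverage_mask is None:
            self.coverage_mask = np.all(self.intensities != 0, axis=3)
        if not self.coverage_mask.any():
            raise ValueError("coverage mask is empty")


def censor_volumes(series: VolumeSeries, threshold: float = FD_THRESHOLD_MM) -> np.ndarray:
    """Keep-mask over volumes: keep iff FD <= threshold (strict exclusion above)."""
    keep = series.fd <= threshold
    if not keep.any():
        raise ValueError(
            f"all {len(keep)} volumes exceed FD threshold {threshold} mm"
        )
    return keep


def compute_nt2w_map(series: VolumeSeries, keep: Optional[np.ndarray] = None) -> np.ndarray:
    """Voxelwise median of per-volume z-scored intensities over the mask.

    Each retained volume is normalized by the mean and SD of its intensities
    within the coverage mask; the per-voxel median over retained volumes is
    returned with NaN outside the mask.
    """
    if keep is None:
        keep = censor_volumes(series)
    keep = np.asarray(keep, bool)
    mask = series.coverage_mask
    vols = series.intensities[..., keep]
    z = np.empty_like(vols)
    for t in range(vols.shape[3]):
        v = vols[..., t]
        mu = v[mask].mean()
        sd = v[mask].std()
        if sd == 0:
            raise ValueError(f"volume {np.flatnonzero(keep)[t]} has zero variance within the mask")
        z[..., t] = (v - mu) / sd
    out = np.median(z, axis=3)
    out[~mask] = np.nan
    return out


def extract_roi(
    nt2w_map: np.ndarray,
    atlas: np.ndarray,
    region_labels: Dict[str, Sequence[int]],
    session: Optional[str] = None,
    batch: Optional[str] = None,
) -> pd.DataFrame:
    """Per-region mean nT2*w, pooling all listed labels (both hemispheres).

    ``region_labels`` maps region name -> integer atlas labels belonging to
    it (e.g. left and right hemisphere labels).
    """
    atlas = np.asarray(atlas)
    if atlas.shape != nt2w_map.shape:
        raise ValueError("atlas grid does not match the nT2*w map grid")
    rows = []
    for region, labels in region_labels.items():
        sel = np.isin(atlas, np.asarray(labels))
        if not sel.any():
            raise ValueError(f"region {region!r}: no voxels carry labels {labels}")
        vals = nt2w_map[sel]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"region {region!r} lies entirely outside the coverage mask")
        rows.append({"region": region, "nt2w": float(vals.mean()),
                     "n_voxels": int(sel.sum()), "session": session, "batch": batch})
    return pd.DataFrame(rows)


def harmonize_batches(
    measures: pd.DataFrame,
    batch_col: str = "batch",
    value_col: str = "nt2w",
    region_col: str = "region",
    covariates: Sequence[str] = (),
    min_batch_n: int = 5,
    shrink_n0: float = 10.0,
) -> pd.DataFrame:
    """Location-scale batch harmonization with across-region shrinkage.

    Per region: a linear model with covariates plus batch offsets is fit;
    batch offsets are removed and batch residual scales equalized to the
    pooled scale.  Batch parameters are shrunk toward their across-region
    means with weight n_b / (n_b + shrink_n0); batches with fewer than
    ``min_batch_n`` observations are adjusted without shrinkage support
    (warning).  Covariate relationships pass through untouched.
    """
    df = measures.copy()
    batches = sorted(df[batch_col].unique())
    if len(batches) < 2:
        raise ValueError("need at least 2 batches to harmonize")
    regions = sorted(df[region_col].unique())
    # first pass: per-region, per-batch location/scale estimates
    est: Dict[Tuple[str, str], Tuple[float, float, int]] = {}
    resid_store: Dict[str, np.ndarray] = {}
    fitted_store: Dict[str, np.ndarray] = {}
    for region in regions:
        sub = df[df[region_col] == region]
        y = sub[value_col].to_numpy(float)
        Xc = [np.ones(len(sub))]
        for c in covariates:
            Xc.append(sub[c].to_numpy(float))
        X = np.column_stack(Xc)
        # batch dummies (reference coding on the first batch)
        B = np.column_stack([(sub[batch_col] == b).to_numpy(float) for b in batches[1:]])
        full = np.column_stack([X, B])
        coef, *_ = np.linalg.lstsq(full, y, rcond=None)
        cov_part = X @ coef[: X.shape[1]]
        gamma = {batches[0]: 0.0}
        for i, b in enumerate(batches[1:]):
            gamma[b] = float(coef[X.shape[1] + i])
        resid = y - cov_part - np.array([gamma[b] for b in sub[batch_col]])
        pooled_sd = resid.std(ddof=1)
        for b in batches:
            m = (sub[batch_col] == b).to_numpy()
            nb = int(m.sum())
            sd_b = resid[m].std(ddof=1) if nb > 1 else pooled_sd
            est[(region, b)] = (gamma[b], sd_b / pooled_sd if pooled_sd > 0 else 1.0, nb)
        resid_store[region] = resid
        fitted_store[region] = cov_part

    # second pass: shrink batch parameters across regions and adjust
    adj = pd.Series(index=df.index, dtype=float)
    for region in regions:
        sub_mask = df[region_col] == region
        sub = df[sub_mask]
        y = sub[value_col].to_numpy(float)
        cov_part = fitted_store[region]
        out = np.empty(len(sub))
        for b in batches:
            g_rb, d_rb, nb = est[(region, b)]
            g_bar = float(np.mean([est[(r, b)][0] for r in regions]))
            d_bar = float(np.mean([est[(r, b)][1] for r in regions]))
            if nb < min_batch_n:
                warnings.warn(
                    f"batch {b!r} has only {nb} observations in region {region!r};"
                    " applying unshrunk adjustment"
                )
                w = 1.0
            else:
                w = nb / (nb + shrink_n0)
            g_star = w * g_rb + (1.0 - w) * g_bar
            d_star = max(w * d_rb + (1.0 - w) * d_bar, 1e-8)
            m = (sub[batch_col] == b).to_numpy()
            out[m] = cov_part[m] + (y[m] - cov_part[m] - g_star) / d_star
        adj[sub_mask] = out
    result = df.copy()
    result[value_col] = adj
    return result


# ---------------------------------------------------------------------------
# optional NIfTI I/O


def load_nifti_series(path: str, fd_path: str, session=None, batch=None) -> VolumeSeries:
    """Read a 4D NIfTI plus a one-column FD text file."""
    import nibabel as nib

    img = nib.load(path)
    fd = np.loadtxt(fd_path, ndmin=1)
    return VolumeSeries(np.asarray(img.dataobj, float), fd, session=session, batch=batch)


def save_nifti_map(nt2w_map: np.ndarray, path: str, affine: Optional[np.ndarray] = None) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.nan_to_num(nt2w_map), affine if affine is not None else np.eye(4)), path)
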