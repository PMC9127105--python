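"""Full-reference image-quality metrics (NRMSE, SSIM/MSSIM) and studies.

NRMSE is the root mean squared difference normalized by the reference
intensity range.  SSIM follows the standard definition with an isotropic
Gaussian weighting window of SD 1.5 and a dynamic range of 255 on inputs
rescaled by the affine map that sends the reference min/max to [0, 255]
(stabilization constants K1 = 0.01, K2 = 0.03).  MSSIM is the mean of the
local SSIM map, optionally restricted to a region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["MetricReport", "nrmse", "mssim", "run_snr_motion_study"]


@dataclass
class MetricReport:
    nrmse: float
    mssim: float
    ssim_map: np.ndarray
    metadata: dict = field(default_factory=dict)


def nrmse(reference: np.ndarray, test: np.ndarray) -> float:
    """Root mean squared error normalized by the reference intensity range."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("reference and test shapes differ")
    rng = reference.max() - reference.min()
    if rng == 0:
        raise ValueError("reference image has zero intensity range")
    return float(np.sqrt(np.mean((test - reference) ** 2)) / rng)


def _normalize_pair(reference: np.ndarray, test: np.ndarray):
    """Affine map sending the reference min/max to [0, 255], applied to both.

    A degenerate (constant) reference is shifted only, so that
    near-identical pairs keep SSIM ~ 1 (continuity).
    """
    lo, hi = reference.min(), reference.max()
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    return (reference - lo) * scale, (test - lo) * scale


def mssim(reference: np.ndarray, test: np.ndarray,
          mask: np.ndarray | None = None) -> MetricReport:
    """Local SSIM map and its mean between two same-shape images/volumes."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("reference and test shapes differ")
    ref_n, test_n = _normalize_pair(reference, test)
    kwargs = dict(gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
                  data_range=255.0, K1=0.01, K2=0.03, full=True)
    # volumetric SSIM needs >= 11 voxels per axis (the Gaussian window);
    # thin multi-slice stacks are scored slice-wise along their thinnest axis
    if reference.ndim == 3 and min(reference.shape) < 11:
        ax = int(np.argmin(reference.shape))
        maps = [structural_similarity(r, t, **kwargs)[1]
                for r, t in zip(np.moveaxis(ref_n, ax, 0),
                                np.moveaxis(test_n, ax, 0))]
        ssim_map = np.moveaxis(np.stack(maps), 0, ax)
        mean_val = float(ssim_map.mean())
    else:
        mean_val, ssim_map = structural_similarity(ref_n, test_n, **kwargs)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != reference.shape:
            raise ValueError("mask shape differs from image shape")
        mean_val = float(ssim_map[mask].mean()) if mask.any() else float("nan")
    try:
        err = nrmse(reference, test)
    except ValueError:      # degenerate (constant) reference
        err = float("nan")
    return MetricReport(nrmse=err, mssim=float(mean_val),
                        ssim_map=ssim_map,
                        metadata={"normalization": "reference-minmax-255",
                                  "masked": mask is not None})


def run_snr_motion_study(phantom, seq, sd_list, motion_levels,
                         n_realizations: int = 6, seed: int | None = 0,
                         props=None):
    """NRMSE/MSSIM grid over (noise SD x motion level x realization).

    Every cell simulates a full series and scores it against the noiseless,
    motion-free simulation of the identical geometry.  Returns a pandas
    DataFrame with one row per cell.
    """
    import pandas as pd

    from .acquisition import simulate_series
    from dataclasses import replace

    if not sd_list or not motion_levels:
        raise ValueError("sd_list and motion_levels must be non-empty")
    ref_seq = replace(seq, noise_sd=0.0)
    reference = simulate_series(phantom, ref_seq, motion_level="none",
                                seed=0, props=props).images
    ss = np.random.SeedSequence(seed if seed is not None else None)
    children = iter(ss.spawn(len(sd_list) * len(motion_levels) * n_realizations))
    rows = []
    for sd in sd_list:
        for level in motion_levels:
            for r in range(n_realizations):
                child_seed = int(next(children).generate_state(1)[0] % (2 ** 31))
                sim = simulate_series(phantom, replace(seq, noise_sd=sd),
                                      motion_level=level, seed=child_seed,
                                      props=props)
                rep = mssim(reference, sim.images)
                rows.append({"noise_sd": sd, "motion_level": level,
                             "realization": r, "seed": child_seed,
                             "nrmse": rep.nrmse, "mssim": rep.mssim})
    return pd.DataFrame(rows)
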