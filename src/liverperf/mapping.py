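"""Voxel-wise perfusion mapping, difference maps and ROI statistics.

Applies either estimator to every masked voxel of a 4D dynamic volume:
signal intensity -> concentration (SPGR inversion with baseline M0) ->
(AF, DV, MTT) estimate, producing 3D parameter maps, a goodness-of-match
map (best inner product, dictionary method only) and a validity mask.
Voxels where SPGR inversion fails at any frame, or whose concentration
curve has zero norm (no enhancement), are flagged invalid rather than
interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import AcquisitionParams, concentration_from_signal
from .inputs import InputFunctions
from .dictionary import DictionaryMatcher
from .fitting import CurveFitEstimator, FitConfig

__all__ = [
    "DynamicVolume",
    "PerfusionMaps",
    "map_volume",
    "map_volume_by_class",
    "difference_map",
    "roi_compare",
    "save_maps",
    "load_maps",
]

PROPERTIES = ("af", "dv", "mtt")


@dataclass
class DynamicVolume:
    """4D dynamic signal volume (x, y, z, t) with geometry and frame times."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    frame_times: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic volume must be 4D (x, y, z, t)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("dynamic volume contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.size != self.data.shape[3]:
                raise ValueError("frame_times length must equal the number of frames")


@dataclass
class PerfusionMaps:
    """Voxel-wise perfusion property maps plus goodness and validity."""

    af: np.ndarray
    dv: np.ndarray
    mtt: np.ndarray
    score: np.ndarray  # best inner product (NaN for the fitting method)
    valid: np.ndarray  # bool
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    method: str = ""

    def __getitem__(self, prop: str) -> np.ndarray:
        return getattr(self, prop)


def map_volume(
    vol: DynamicVolume,
    mask: np.ndarray,
    inputs: InputFunctions,
    acq: AcquisitionParams | None = None,
    method: str = "dictionary",
    matcher: DictionaryMatcher | None = None,
    fit_config: FitConfig | None = None,
    labels=None,
) -> PerfusionMaps:
    """Estimate perfusion properties for every masked voxel.

    ``mask`` is an integer label volume with the spatial shape of ``vol``;
    voxels with label > 0 (or whose label is in ``labels`` if given) are
    processed.  ``acq.t10_ms`` should be the tissue T1 appropriate for the
    masked tissue class.  Deterministic; estimator choice changes only the
    map values, never geometry or mask handling.
    """
    if acq is None:
        acq = AcquisitionParams()
    mask = np.asarray(mask)
    if mask.shape != vol.data.shape[:3]:
        raise ValueError("mask shape must match the volume's spatial shape")
    sel = np.isin(mask, np.asarray(labels)) if labels is not None else mask > 0
    if not np.any(sel):
        raise ValueError("mask selects no voxels")

    signals = vol.data[sel]  # (m, t)
    conc, frame_valid = concentration_from_signal(signals, acq)
    voxel_ok = frame_valid.all(axis=1)
    conc_safe = np.where(np.isfinite(conc), conc, 0.0)
    norms = np.linalg.norm(conc_safe, axis=1)
    # flat / non-enhancing voxels carry no kinetic information
    voxel_ok &= (norms > 0) & (np.ptp(signals, axis=1) > 0)

    shape = vol.data.shape[:3]
    out = {p: np.full(shape, np.nan) for p in PROPERTIES}
    score = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    if np.any(voxel_ok):
        curves = conc_safe[voxel_ok]
        if method == "dictionary":
            if matcher is None:
                matcher = DictionaryMatcher(inputs=inputs)
            if not hasattr(matcher, "dictionary_"):
                matcher.fit()
            res = matcher.match(curves)
            est = res[["af", "dv", "mtt"]].to_numpy(float)
            sc = res["inner_product"].to_numpy(float)
            ok = res["valid"].to_numpy(bool)
        elif method == "fit":
            fitter = CurveFitEstimator(inputs=inputs, config=fit_config).fit()
            est = fitter.predict(curves)
            sc = np.full(curves.shape[0], np.nan)
            ok = np.ones(curves.shape[0], dtype=bool)
        else:
            raise ValueError("method must be 'dictionary' or 'fit'")

        vox_idx = np.flatnonzero(sel.ravel())[voxel_ok]
        coords = np.unravel_index(vox_idx, shape)
        for j, p in enumerate(PROPERTIES):
            out[p][coords] = np.where(ok, est[:, j], np.nan)
        score[coords] = sc
        valid[coords] = ok

    return PerfusionMaps(
        af=out["af"], dv=out["dv"], mtt=out["mtt"],
        score=score, valid=valid, affine=vol.affine.copy(), method=method,
    )


def map_volume_by_class(
    vol: DynamicVolume,
    mask: np.ndarray,
    inputs: InputFunctions,
    t10_by_label: dict[int, float],
    method: str = "dictionary",
    acq: AcquisitionParams | None = None,
    matcher: DictionaryMatcher | None = None,
    fit_config: FitConfig | None = None,
) -> PerfusionMaps:
    """Map each tissue class with its own baseline T1 and merge the results.

    ``t10_by_label`` assigns a pre-contrast T1 (ms) to each mask label to be
    mapped (e.g. healthy liver 800 ms, cirrhotic liver 950 ms); labels not
    listed are left invalid.  A prebuilt ``matcher`` is reused across classes.
    """
    if acq is None:
        acq = AcquisitionParams()
    if method == "dictionary" and matcher is None:
        matcher = DictionaryMatcher(inputs=inputs).fit()
    merged = None
    for label, t10 in t10_by_label.items():
        part = map_volume(
            vol, mask, inputs, acq.with_t10(t10), method=method,
            matcher=matcher, fit_config=fit_config, labels=[label],
        )
        if merged is None:
            merged = part
        else:
            sel = part.valid
            for p in PROPERTIES:
                merged[p][sel] = part[p][sel]
            merged.score[sel] = part.score[sel]
            merged.valid |= sel
    return merged


def difference_map(maps_a: PerfusionMaps, maps_b: PerfusionMaps) -> dict[str, np.ndarray]:
    """Per-property difference volumes a - b, NaN where either map is invalid."""
    if maps_a.af.shape != maps_b.af.shape:
        raise ValueError("maps have different geometry")
    if not np.allclose(maps_a.affine, maps_b.affine):
        raise ValueError("maps have different affines")
    both = maps_a.valid & maps_b.valid
    return {
        p: np.where(both, maps_a[p] - maps_b[p], np.nan) for p in PROPERTIES
    }


def _two_sample_t(x: np.ndarray, y: np.ndarray, equal_var: bool) -> tuple[float, float]:
    """Two-tailed two-sample t-test, defined for degenerate samples.

    If both samples have zero variance the statistic is taken as 0 (p = 1)
    when the means agree and +/-inf (p = 0) when they differ.
    """
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        return (0.0, 1.0) if np.mean(x) == np.mean(y) else (np.inf, 0.0)
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def roi_compare(
    maps_a: PerfusionMaps,
    maps_b: PerfusionMaps,
    roi_labels: np.ndarray,
    roi_names: dict | None = None,
    equal_var: bool = True,
    min_voxels: int = 2,
) -> pd.DataFrame:
    """Per-ROI summary statistics and method comparison.

    For every ROI label > 0: the mean and SD of each property over each
    method's valid voxels, and a two-tailed two-sample t-test between the
    two methods' voxel value sets (Student's by default, Welch's with
    ``equal_var=False``).  ROIs with fewer than ``min_voxels`` valid voxels
    in either map are skipped with a warning.
    """
    roi_labels = np.asarray(roi_labels)
    if roi_labels.shape != maps_a.af.shape:
        raise ValueError("ROI label volume must match map geometry")
    rows = []
    for label in np.unique(roi_labels[roi_labels > 0]):
        in_roi = roi_labels == label
        sel_a = in_roi & maps_a.valid
        sel_b = in_roi & maps_b.valid
        if sel_a.sum() < min_voxels or sel_b.sum() < min_voxels:
            warnings.warn(f"ROI {label}: fewer than {min_voxels} valid voxels; skipped")
            continue
        name = roi_names.get(int(label), str(label)) if roi_names else str(label)
        for p in PROPERTIES:
            a_vals = maps_a[p][sel_a]
            b_vals = maps_b[p][sel_b]
            t, pval = _two_sample_t(a_vals, b_vals, equal_var)
            rows.append(
                {
                    "roi": int(label),
                    "roi_name": name,
                    "property": p,
                    "mean_a": float(np.mean(a_vals)),
                    "sd_a": float(np.std(a_vals, ddof=1)),
                    "mean_b": float(np.mean(b_vals)),
                    "sd_b": float(np.std(b_vals, ddof=1)),
                    "n_a": int(sel_a.sum()),
                    "n_b": int(sel_b.sum()),
                    "t_stat": t,
                    "p_value": pval,
                }
            )
    return pd.DataFrame(rows)


def save_maps(maps: PerfusionMaps, out_dir, prefix: str = "") -> None:
    """Write each map as a NIfTI volume (af, dv, mtt, score, valid)."""
    import pathlib

    import nibabel as nib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("af", "dv", "mtt", "score"):
        nib.save(nib.Nifti1Image(maps[name].astype(np.float64), maps.affine),
                 out / f"{prefix}{name}.nii.gz")
    nib.save(nib.Nifti1Image(maps.valid.astype(np.uint8), maps.affine),
             out / f"{prefix}valid.nii.gz")


def load_maps(map_dir, prefix: str = "", method: str = "") -> PerfusionMaps:
    """Load maps written by :func:`save_maps`."""
    import pathlib

    import nibabel as nib

    d = pathlib.Path(map_dir)
    arrays = {}
    for name in ("af", "dv", "mtt", "score", "valid"):
        img = nib.load(d / f"{prefix}{name}.nii.gz")
        arrays[name] = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
    return PerfusionMaps(
        af=arrays["af"], dv=arrays["dv"], mtt=arrays["mtt"], score=arrays["score"],
        valid=arrays["valid"] > 0.5, affine=affine, method=method,
    )
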