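"""Per-nucleus Top2 localization quantification from 3-D stacks.

The measurement chain mirrors how focal vs. diffuse nuclear topoisomerase II
signal is scored in fixed-cell spinning-disk data:

1. resample the anisotropic stack to isotropic voxels (trilinear);
2. denoise the DAPI channel (Gaussian blur, sigma = 2 px) and segment nuclei by
   four-level Multi-Otsu thresholding, keeping the brightest classes;
3. drop connected components outside a physical volume window (debris,
   aggregates);
4. expand each nuclear mask by a fixed radius (default 5 px = 325 nm at 65 nm
   voxels) so the mask encloses the Top2 signal hugging the nuclear periphery;
5. inside each expanded mask compute the mean fluorescence intensity (MFI, a
   proxy for abundance), the population SD, and the coefficient of variation
   CV = SD / MFI (a proxy for how focal the distribution is: diffuse signal
   gives CV near 0, chromatin-bound foci drive CV up).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .stacks import ImageStack3D

__all__ = [
    "NucleusMask",
    "NucleusMeasurement",
    "resample_isotropic",
    "multi_otsu_thresholds",
    "segment_nuclei",
    "expand_labels_euclidean",
    "expand_masks",
    "measure_nucleus_signal",
    "quantify_stack",
]

# 26-connectivity: bright blobs should not split along axis artifacts
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class NucleusMask:
    """One segmented nucleus: core voxel set, physical descriptors, and the
    expanded voxel set once :func:`expand_masks` has run.

    Voxel coordinate arrays have shape (n, 3) in (z, y, x) index order.
    """

    label: int
    core_voxels: np.ndarray
    volume_um3: float
    centroid_um: tuple[float, float, float]
    expanded_voxels: np.ndarray | None = None

    @property
    def n_core(self) -> int:
        return len(self.core_voxels)


@dataclass
class NucleusMeasurement:
    label: int
    mfi: float
    sd: float
    cv: float | None  # None when MFI == 0 (undefined)


def resample_isotropic(stack: ImageStack3D, target_nm: float) -> ImageStack3D:
    """Resample every channel onto an isotropic grid of ``target_nm`` spacing.

    Output voxel ``j`` along an axis sits at physical position ``j * target``;
    the number of output voxels is ``floor((n - 1) * spacing / target) + 1``,
    which preserves the physical extent to within one voxel.  Intensities are
    trilinear-interpolated.  A target coarser than every input axis loses
    information and triggers a warning rather than an error.
    """
    if target_nm <= 0:
        raise ValueError("target spacing must be positive")
    if target_nm > max(stack.spacing_nm):
        warnings.warn(
            f"target {target_nm} nm is coarser than all input axes {stack.spacing_nm}; "
            "resampling loses information",
            stacklevel=2,
        )
    shape = stack.shape
    new_shape = tuple(
        int(np.floor((n - 1) * s / target_nm)) + 1 for n, s in zip(shape, stack.spacing_nm)
    )
    # coordinate of output voxel j in input index units: j * target / spacing
    grids = [
        np.arange(m, dtype=np.float64) * (target_nm / s)
        for m, s in zip(new_shape, stack.spacing_nm)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    coords = np.stack([c.ravel() for c in coords])
    channels = {}
    for name, vol in stack.channels.items():
        out = ndimage.map_coordinates(
            np.asarray(vol, dtype=np.float64), coords, order=1, mode="nearest"
        )
        channels[name] = out.reshape(new_shape)
    return ImageStack3D(
        channels=channels,
        spacing_nm=(target_nm,) * 3,
        meta=dict(stack.meta, resampled_from=stack.spacing_nm),
    )


def multi_otsu_thresholds(
    counts: np.ndarray,
    bin_values: np.ndarray | None = None,
    n_classes: int = 4,
) -> np.ndarray:
    """Multi-Otsu thresholds of an intensity histogram.

    Finds the ``n_classes - 1`` split points maximizing the between-class
    variance (equivalently minimizing the weighted within-class variance) by
    exhaustive search over all threshold tuples, vectorized over prefix sums.
    Ties are broken toward the lexicographically smallest tuple.  The returned
    thresholds are bin values: class ``k`` comprises bins with value >=
    threshold ``k-1`` and < threshold ``k``.

    Parameters
    ----------
    counts
        Histogram counts per bin (any nonnegative scale; the criterion is
        count-scale-free).
    bin_values
        Value of each bin (defaults to ``arange(len(counts))``).
    n_classes
        Number of intensity classes; ``n_classes - 1`` thresholds returned.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("histogram must be a nonempty 1-D array")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if bin_values is None:
        bin_values = np.arange(counts.size, dtype=np.float64)
    bin_values = np.asarray(bin_values, dtype=np.float64)
    occupied = np.flatnonzero(counts > 0)
    if occupied.size < n_classes:
        raise ValueError(
            f"histogram has {occupied.size} occupied bins; need >= {n_classes} "
            "distinct intensity values"
        )
    nbins = counts.size
    k = n_classes - 1
    # prefix sums: W(a, b) = cw[b] - cw[a], S(a, b) = cs[b] - cs[a]
    cw = np.concatenate([[0.0], np.cumsum(counts)])
    cs = np.concatenate([[0.0], np.cumsum(counts * bin_values)])

    combos = np.array(
        list(itertools.combinations(range(1, nbins), k)), dtype=np.intp
    )  # lexicographic order; argmax keeps the first (smallest) maximizer
    bounds = np.concatenate(
        [np.zeros((len(combos), 1), dtype=np.intp), combos,
         np.full((len(combos), 1), nbins, dtype=np.intp)],
        axis=1,
    )
    w = cw[bounds[:, 1:]] - cw[bounds[:, :-1]]
    s = cs[bounds[:, 1:]] - cs[bounds[:, :-1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(w > 0, s * s / np.where(w > 0, w, 1.0), 0.0)
    objective = term.sum(axis=1)
    best = combos[int(np.argmax(objective))]
    return bin_values[best]


def _classify_by_thresholds(values: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Class index per voxel: value >= thresholds[j] puts it past class j."""
    return np.searchsorted(np.asarray(thresholds), values, side="right")


def segment_nuclei(
    stack: ImageStack3D,
    dapi_channel: str = "DAPI",
    sigma_px: float = 2.0,
    n_classes: int = 4,
    foreground_classes: int = 2,
    volume_bounds_um3: tuple[float, float] = (0.5, 15.0),
    hist_bins: int = 128,
) -> tuple[np.ndarray, list[NucleusMask]]:
    """Segment nuclei from the DAPI channel of an isotropic stack.

    Gaussian blur (sigma in isotropic pixels) -> Multi-Otsu over a histogram of
    the blurred intensities -> foreground = the ``foreground_classes``
    brightest classes -> 26-connected components -> physical volume filter.
    Returns the label volume and the surviving masks (empty foreground gives an
    empty list, not an error).
    """
    if not stack.is_isotropic:
        raise ValueError("segment_nuclei requires an isotropic stack; resample first")
    dapi = stack.channel(dapi_channel)
    blurred = ndimage.gaussian_filter(np.asarray(dapi, dtype=np.float64), sigma=sigma_px)
    lo, hi = float(blurred.min()), float(blurred.max())
    if hi <= lo:  # constant image: no foreground
        return np.zeros(stack.shape, dtype=np.int32), []
    counts, edges = np.histogram(blurred, bins=hist_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < n_classes:
        return np.zeros(stack.shape, dtype=np.int32), []
    thr = multi_otsu_thresholds(counts, centers, n_classes=n_classes)
    fg_cut = thr[n_classes - 1 - foreground_classes]
    foreground = blurred >= fg_cut
    labels, n = ndimage.label(foreground, structure=_STRUCT_26)
    if n == 0:
        return labels.astype(np.int32), []
    voxel_um3 = stack.voxel_volume_um3
    masks: list[NucleusMask] = []
    keep = np.zeros(n + 1, dtype=bool)
    relabel = np.zeros(n + 1, dtype=np.int32)
    next_id = 1
    spacing_um = np.array(stack.spacing_nm) * 1e-3
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        vol = len(vox) * voxel_um3
        if not (volume_bounds_um3[0] <= vol <= volume_bounds_um3[1]):
            continue
        keep[lab] = True
        relabel[lab] = next_id
        centroid = tuple(vox.mean(axis=0) * spacing_um)
        masks.append(
            NucleusMask(label=next_id, core_voxels=vox, volume_um3=vol, centroid_um=centroid)
        )
        next_id += 1
    out_labels = relabel[labels]
    return out_labels, masks


def expand_labels_euclidean(labels: np.ndarray, radius: float) -> np.ndarray:
    """Grow every label outward by a Euclidean radius (in voxels).

    A background voxel joins the label whose nearest core voxel is closest,
    provided that distance is <= ``radius``; voxels equidistant between labels
    go to the lower label id.  Expansion never overwrites a core voxel and is
    clipped at the grid bounds.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    labels = np.asarray(labels)
    out = labels.copy()
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if radius == 0 or ids.size == 0:
        return out
    best_dist = np.full(labels.shape, np.inf)
    best_label = np.zeros(labels.shape, dtype=labels.dtype)
    for lab in ids:  # increasing order: strict '<' keeps the lower id on ties
        dist = ndimage.distance_transform_edt(labels != lab)
        closer = dist < best_dist
        best_dist[closer] = dist[closer]
        best_label[closer] = lab
    grow = (labels == 0) & (best_dist <= radius)
    out[grow] = best_label[grow]
    return out


def expand_masks(
    masks: list[NucleusMask], shape: tuple[int, int, int], radius_px: float = 5.0
) -> list[NucleusMask]:
    """Fill each mask's expanded voxel set by nearest-label Euclidean growth.

    The default 5 px corresponds to 325 nm on the 65 nm isotropic grid, sized
    to capture perinuclear Top2 signal just outside the DAPI core.
    """
    labels = np.zeros(shape, dtype=np.int32)
    for m in masks:
        labels[tuple(m.core_voxels.T)] = m.label
    expanded = expand_labels_euclidean(labels, radius_px)
    for m in masks:
        m.expanded_voxels = np.argwhere(expanded == m.label)
    return masks


def measure_nucleus_signal(mask: NucleusMask, channel: np.ndarray) -> NucleusMeasurement:
    """MFI, population SD, and CV = SD/MFI of a channel over the expanded mask."""
    vox = mask.expanded_voxels if mask.expanded_voxels is not None else mask.core_voxels
    if vox is None or len(vox) == 0:
        raise ValueError(f"mask {mask.label} has an empty voxel set")
    vals = np.asarray(channel)[tuple(np.asarray(vox).T)]
    mfi = float(vals.mean())
    sd = float(vals.std(ddof=0))  # population SD: descriptive per-mask statistic
    if mfi == 0:
        warnings.warn(f"mask {mask.label}: MFI is 0, CV undefined", stacklevel=2)
        cv = None
    else:
        cv = sd / mfi
    return NucleusMeasurement(label=mask.label, mfi=mfi, sd=sd, cv=cv)


def quantify_stack(
    stack: ImageStack3D,
    dapi_channel: str = "DAPI",
    signal_channel: str = "Top2",
    target_nm: float = 65.0,
    sigma_px: float = 2.0,
    n_classes: int = 4,
    foreground_classes: int = 2,
    volume_bounds_um3: tuple[float, float] = (0.5, 15.0),
    expand_radius_px: float = 5.0,
) -> pd.DataFrame:
    """Full chain: resample -> segment -> volume-filter -> expand -> measure.

    Returns one row per surviving nucleus:
    ``label, cz, cy, cx, volume_um3, MFI, SD, CV`` (centroid in µm).
    """
    if not stack.is_isotropic:
        stack = resample_isotropic(stack, target_nm)
    _, masks = segment_nuclei(
        stack,
        dapi_channel=dapi_channel,
        sigma_px=sigma_px,
        n_classes=n_classes,
        foreground_classes=foreground_classes,
        volume_bounds_um3=volume_bounds_um3,
    )
    expand_masks(masks, stack.shape, radius_px=expand_radius_px)
    signal = stack.channel(signal_channel)
    rows = []
    for m in masks:
        meas = measure_nucleus_signal(m, signal)
        rows.append(
            {
                "label": m.label,
                "cz": m.centroid_um[0],
                "cy": m.centroid_um[1],
                "cx": m.centroid_um[2],
                "volume_um3": m.volume_um3,
                "MFI": meas.mfi,
                "SD": meas.sd,
                "CV": np.nan if meas.cv is None else meas.cv,
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "cz", "cy", "cx", "volume_um3", "MFI", "SD", "CV"]
    )
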