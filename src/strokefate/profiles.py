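"""Relative regional perfusion indices and voxel-class fractions.

Two complementary summaries of each perfusion map (CBF, CBV, MTT) per ROI:

* the relative regional (rr) index — the ROI mean expressed as a percentage
  of the mean over the mirrored contralateral homologue — a single number
  robust to bolus-injection variability;
* a heterogeneity profile — every voxel is repercentaged to the
  contralateral hemisphere median and binned as hypo- (< 85%), normo-
  (85-115%) or hyperperfused (> 115%), the class fractions summing to one
  per ROI.  For MTT the classification is reversed: short transit (< 85%)
  means hyperperfusion and long transit (> 115%) hypoperfusion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .image import VolumeImage

__all__ = [
    "rr_index",
    "repercentage",
    "bin_voxels",
    "class_fractions",
    "profile_table",
    "CLASS_HYPO",
    "CLASS_NORMO",
    "CLASS_HYPER",
]

CLASS_HYPO, CLASS_NORMO, CLASS_HYPER = -1, 0, 1

#: Normal band in percent of the contralateral median.
NORMO_BAND = (85.0, 115.0)


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, VolumeImage) else np.asarray(x)


def rr_index(map_img, roi: np.ndarray, homologue: np.ndarray) -> float:
    """ROI mean as a percentage of the contralateral homologue mean."""
    data = _data(map_img)
    roi = np.asarray(roi, dtype=bool)
    hom = np.asarray(homologue, dtype=bool)
    if not roi.any() or not hom.any():
        raise ValueError("ROI and homologue masks must be non-empty")
    hom_mean = data[hom].mean()
    if hom_mean == 0:
        raise ValueError("homologue mean is zero; rr index undefined")
    return float(100.0 * data[roi].mean() / hom_mean)


def repercentage(map_img, homologue_median: float):
    """Voxelwise repercentaging to an internal control value.

    Each voxel is expressed as a percentage of the contralateral median, the
    internal control that removes between-subject bolus variability.
    """
    if homologue_median <= 0:
        raise ValueError("control median must be positive")
    data = _data(map_img)
    pct = 100.0 * data / homologue_median
    if isinstance(map_img, VolumeImage):
        return map_img.copy_with(pct, map_img.name + "_pct")
    return pct


def bin_voxels(
    pct_map,
    parameter: str,
    band: tuple[float, float] = NORMO_BAND,
) -> np.ndarray:
    """Classify repercentaged voxels as hypo- / normo- / hyperperfused.

    For CBF and CBV, values strictly above the upper band edge are
    hyperperfused and values strictly below the lower edge hypoperfused;
    values at exactly 85% or 115% are normoperfused.  For MTT the mapping is
    reversed (short transit = hyperperfusion).
    """
    parameter = parameter.lower()
    if parameter not in ("cbf", "cbv", "mtt"):
        raise ValueError("parameter must be one of cbf, cbv, mtt")
    pct = _data(pct_map)
    lo, hi = band
    out = np.full(pct.shape, CLASS_NORMO, dtype=np.int8)
    if parameter == "mtt":
        out[pct > hi] = CLASS_HYPO
        out[pct < lo] = CLASS_HYPER
    else:
        out[pct > hi] = CLASS_HYPER
        out[pct < lo] = CLASS_HYPO
    return out


def class_fractions(class_map: np.ndarray, roi: np.ndarray) -> tuple[float, float, float]:
    """(f_hypo, f_normo, f_hyper) over an ROI; the triple sums to exactly 1."""
    roi = np.asarray(roi, dtype=bool)
    n = int(roi.sum())
    if n == 0:
        raise ValueError("ROI is empty")
    classes = np.asarray(class_map)[roi]
    n_hypo = int((classes == CLASS_HYPO).sum())
    n_hyper = int((classes == CLASS_HYPER).sum())
    f_hypo, f_normo = _exact_partition(n_hypo / n, (n - n_hypo - n_hyper) / n,
                                       n_hyper / n)
    return (f_hypo, f_normo, n_hyper / n)


def _exact_partition(a: float, b: float, c: float) -> tuple[float, float]:
    """Adjust (a, b) by a few ulps so that (a + b) + c == 1.0 exactly.

    The counts behind the fractions partition the ROI exactly but the
    divisions round, leaving the float sum an ulp off roughly 3% of the
    time.  A small search over ulp-neighbourhoods of the two fractions
    restores exactness; single-ulp steps in both operands are enough to
    escape round-to-even ties.  Values move by at most ~4 ulps.
    """
    if (a + b) + c == 1.0:
        return a, b
    a0, b0 = a, b
    for db in range(-3, 4):
        b = b0
        for _ in range(abs(db)):
            b = float(np.nextafter(b, np.inf if db > 0 else -np.inf))
        for da in range(-4, 5):
            a = a0
            for _ in range(abs(da)):
                a = float(np.nextafter(a, np.inf if da > 0 else -np.inf))
            if (a + b) + c == 1.0:
                return a, b
    return a0, b0  # give up; callers treat exactness as best-effort


def profile_table(
    perfusion_maps: dict[str, "VolumeImage | np.ndarray"],
    rois: dict[str, np.ndarray],
    homologues: dict[str, np.ndarray],
    contralateral_mask: np.ndarray,
    subject: str = "",
    timepoint: str = "",
) -> pd.DataFrame:
    """Long-format perfusion profile for one subject and timepoint.

    One row per (ROI, hemisphere, parameter) with the rr index (ipsilateral
    rows only) and the hypo/normo/hyper class fractions.  The repercentaging
    control is the median over the contralateral hemisphere (non-zero
    voxels, i.e. inside the perfusion mask).
    """
    rows = []
    contra = np.asarray(contralateral_mask, dtype=bool)
    for param, img in perfusion_maps.items():
        data = _data(img)
        ctrl_vals = data[contra & (data > 0)]
        if ctrl_vals.size == 0:
            raise ValueError("no usable contralateral voxels for repercentaging")
        ctrl_median = float(np.median(ctrl_vals))
        pct = repercentage(data, ctrl_median)
        classes = bin_voxels(pct, param)
        for roi_name, roi in rois.items():
            hom = homologues[roi_name]
            if not roi.any() or not hom.any():
                continue
            rr = rr_index(data, roi, hom)
            for hemi, mask in (("ipsilateral", roi), ("contralateral", hom)):
                f_hypo, f_normo, f_hyper = class_fractions(classes, mask)
                rows.append(
                    {
                        "subject": subject,
                        "timepoint": timepoint,
                        "roi": roi_name,
                        "hemisphere": hemi,
                        "parameter": param,
                        "rr_index": rr if hemi == "ipsilateral" else 100.0,
                        "f_hypo": f_hypo,
                        "f_normo": f_normo,
                        "f_hyper": f_hyper,
                    }
                )
    return pd.DataFrame(rows)
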