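"""DSC-MRI perfusion quantification by oscillation-index regularized oSVD.

The signal drop during bolus passage is converted to a relaxation-rate
proportional concentration, C(t) = -ln(S(t)/S0)/TE.  An arterial reference
curve is extracted from the contralateral hemisphere by a deterministic
ranking of candidate voxel curves (tall, early, narrow).  Tissue curves are
then deconvolved against the arterial curve with the block-circulant SVD
method: the convolution matrix of a circularly embedded AIF is diagonalized
by the DFT, so its singular values are the DFT magnitudes and truncated-SVD
deconvolution reduces to masked spectral division.  For each voxel the
truncation threshold is chosen adaptively as the weakest regularization
whose reconstructed residue function has an oscillation index

    OI = (1/L) * (1/max r) * sum_k |r(k) - 2 r(k+1) + r(k+2)|

not exceeding the configured limit (0.17 by default); if no candidate
satisfies the limit the strongest regularization on the ladder is used.
CBF is the peak of the recovered residue function, CBV the trapezoidal
integral of the (non-negative) concentration curve through the truncation
frame, and MTT = CBV/CBF by the central volume theorem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .image import DscSeries, VolumeImage

__all__ = [
    "ConcentrationSeries",
    "Aif",
    "PerfusionMaps",
    "signal_to_concentration",
    "extract_aif",
    "oscillation_index",
    "osvd_deconvolve",
    "compute_cbv",
    "compute_mtt",
    "deconvolve_perfusion",
]

#: Default singular-value cutoff ladder, as fractions of the largest
#: singular value, ordered from weakest to strongest regularization.
DEFAULT_CUTOFFS: tuple[float, ...] = (
    0.0, 0.02, 0.04, 0.06, 0.08, 0.10, 0.13, 0.17, 0.22, 0.30, 0.40, 0.50,
)

#: Default baseline window as 1-based inclusive frame ordinals: skips the
#: initial approach to steady state and ends before the bolus injection.
DEFAULT_BASELINE_ORDINALS: tuple[int, int] = (20, 170)


@dataclass
class ConcentrationSeries:
    """Voxelwise contrast-agent concentration curves (dR2*-proportional)."""

    values: np.ndarray  # (nx, ny, nz, nt)
    frame_interval_s: float
    baseline_window: tuple[int, int]  # 0-based inclusive frame range
    bolus_frame: int
    truncation_frame: int
    valid: np.ndarray  # (nx, ny, nz) voxels with usable baseline
    masked_frames: np.ndarray  # (nx, ny, nz, nt) frames with S <= 0
    voxel_size: tuple[float, float, float] = (0.3, 0.3, 1.2)

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]


@dataclass
class Aif:
    """Arterial reference curve and the voxels that produced it."""

    curve: np.ndarray
    source_voxels: np.ndarray  # (k, 3) voxel indices
    peak_frame: int


@dataclass
class PerfusionMaps:
    """CBF, CBV (relative units) and MTT (s) maps with deconvolution audit."""

    cbf: VolumeImage
    cbv: VolumeImage
    mtt: VolumeImage
    oscillation_index_used: np.ndarray
    cutoff_used: np.ndarray


def signal_to_concentration(
    series: DscSeries,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_ORDINALS,
) -> ConcentrationSeries:
    """Convert DSC signal to concentration: C(t) = -ln(S(t)/S0)/TE.

    ``baseline_window`` is given as 1-based inclusive frame ordinals (the
    convention of acquisition protocols); S0 is the mean signal over that
    window.  Voxels with S0 <= 0 are marked invalid; individual frames with
    S <= 0 are recorded in ``masked_frames`` and set to zero concentration.
    """
    lo, hi = baseline_window
    if lo < 1 or hi < lo:
        raise ValueError("empty or invalid baseline window")
    b0, b1 = lo - 1, hi - 1  # to 0-based inclusive
    if b1 >= series.bolus_frame:
        raise ValueError("baseline window must precede the bolus-arrival frame")
    sig = np.asarray(series.data, dtype=np.float64)
    s0 = sig[..., b0 : b1 + 1].mean(axis=-1)
    valid = s0 > 0
    te_s = series.te_ms / 1000.0
    safe_s0 = np.where(valid, s0, 1.0)
    ratio = sig / safe_s0[..., None]
    bad = ratio <= 0
    conc = np.zeros_like(sig)
    good = ~bad & valid[..., None]
    conc[good] = -np.log(ratio[good]) / te_s
    return ConcentrationSeries(
        values=conc,
        frame_interval_s=series.frame_interval_s,
        baseline_window=(b0, b1),
        bolus_frame=series.bolus_frame,
        truncation_frame=series.truncation_frame,
        valid=valid,
        masked_frames=bad,
        voxel_size=series.voxel_size,
    )


def _curve_features(curves: np.ndarray, dt: float):
    """Peak height, arrival frame and first-moment width per curve."""
    pos = np.clip(curves, 0.0, None)
    peak = pos.max(axis=1)
    peak_frame = pos.argmax(axis=1)
    above = pos > 0.1 * peak[:, None]
    arrival = np.where(above.any(axis=1), above.argmax(axis=1), curves.shape[1])
    t = np.arange(curves.shape[1]) * dt
    mass = pos.sum(axis=1)
    safe = np.where(mass > 0, mass, 1.0)
    mu = (pos * t).sum(axis=1) / safe
    width = np.sqrt(np.clip((pos * (t - mu[:, None]) ** 2).sum(axis=1) / safe, 0, None))
    return peak, peak_frame, arrival, width


def extract_aif(
    conc: ConcentrationSeries,
    contralateral_mask: np.ndarray,
    k: int = 10,
) -> Aif:
    """Deterministic arterial-curve extraction from the contralateral hemisphere.

    Candidate voxels are ranked by the sum of three ranks — tallest peak,
    earliest arrival, narrowest first-moment width — and the top ``k``
    curves are averaged.  Ties resolve by voxel order, so the selection is
    reproducible.
    """
    mask = np.asarray(contralateral_mask, dtype=bool) & conc.valid
    idx = np.argwhere(mask)
    if len(idx) == 0:
        raise ValueError("contralateral mask is empty")
    curves = conc.values[mask]
    peak, peak_frame, arrival, width = _curve_features(curves, conc.frame_interval_s)
    usable = (peak > 0) & (peak_frame > conc.bolus_frame)
    # Curves with any non-positive signal frame are unreliable (air or
    # near-zero baseline); they produce spurious concentration spikes.
    usable &= ~conc.masked_frames[mask].any(axis=1)
    if not usable.any():
        raise ValueError("no contralateral voxel has a post-bolus concentration peak")
    order = np.arange(len(curves))
    rank_peak = np.empty(len(curves))
    rank_peak[np.lexsort((order, -peak))] = np.arange(len(curves))
    rank_arr = np.empty(len(curves))
    rank_arr[np.lexsort((order, arrival))] = np.arange(len(curves))
    rank_wid = np.empty(len(curves))
    rank_wid[np.lexsort((order, width))] = np.arange(len(curves))
    total = rank_peak + rank_arr + rank_wid
    total[~usable] = np.inf
    k_eff = min(k, int(usable.sum()))
    sel = np.lexsort((order, total))[:k_eff]
    aif_curve = np.clip(curves[sel].mean(axis=0), 0.0, None)
    return Aif(
        curve=aif_curve,
        source_voxels=idx[sel],
        peak_frame=int(aif_curve.argmax()),
    )


def oscillation_index(residues: np.ndarray, L: int) -> np.ndarray:
    """Oscillation index of residue functions (rows), over the first L samples."""
    r = residues[:, :L]
    rmax = r.max(axis=1)
    d2 = np.abs(r[:, :-2] - 2.0 * r[:, 1:-1] + r[:, 2:]).sum(axis=1)
    out = np.zeros(len(r))
    nz = rmax > 1e-300
    out[nz] = d2[nz] / (L * rmax[nz])
    return out


def osvd_deconvolve(
    tissue_conc,
    aif,
    oi_threshold: float = 0.17,
    dt: float | None = None,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    oi_fn: Callable[[np.ndarray, int], np.ndarray] | None = None,
    peak_window: int | None = None,
):
    """Block-circulant (oSVD) deconvolution with adaptive OI regularization.

    Parameters
    ----------
    tissue_conc : ConcentrationSeries or ndarray (n_voxels, L)
        Tissue concentration curves.  A ConcentrationSeries is windowed to
        frames [0, truncation_frame] and flattened over valid voxels.
    aif : Aif or ndarray
        Arterial input curve on the same frame grid (windowed identically).
    oi_threshold : float
        Oscillation-index limit for the residue function (0.17 default).
    dt : float
        Frame interval in seconds; taken from the series when available.
    cutoffs : sequence of float
        Singular-value cutoff ladder as fractions of the largest singular
        value, weakest regularization first.
    oi_fn : callable, optional
        Replacement oscillation-index function ``f(residues, L) -> array``.
    peak_window : int, optional
        Number of leading residue lags searched for the flow-scaled peak
        (physically, tissue cannot lead the arterial input by more than the
        post-bolus window).  Defaults to all L lags.

    Returns
    -------
    cbf : ndarray (n_voxels,)
        Peak of the recovered residue function (flow-scaled).
    residues : ndarray (n_voxels, L)
        Recovered residue functions for audit.
    oi_used : ndarray (n_voxels,)
    cutoff_used : ndarray (n_voxels,)
    """
    if isinstance(tissue_conc, ConcentrationSeries):
        if dt is None:
            dt = tissue_conc.frame_interval_s
        L = tissue_conc.truncation_frame + 1
        if peak_window is None:
            peak_window = L - tissue_conc.bolus_frame
        curves = tissue_conc.values[..., :L].reshape(-1, L)
    else:
        curves = np.atleast_2d(np.asarray(tissue_conc, dtype=np.float64))
        L = curves.shape[1]
    if dt is None:
        raise ValueError("dt is required when passing raw curves")
    aif_curve = np.asarray(aif.curve if isinstance(aif, Aif) else aif, dtype=np.float64)
    aif_curve = aif_curve[:L]
    if np.trapezoid(aif_curve, dx=dt) <= 0:
        raise ValueError("AIF integral must be positive")
    oi_fn = oi_fn or oscillation_index

    n = 2 * L  # circular embedding with zero padding to avoid wrap-around
    lam = np.fft.rfft(aif_curve, n) * dt  # circulant eigenvalues
    sigma = np.abs(lam)
    smax = sigma.max()

    chat = np.fft.rfft(curves, n, axis=1)
    nvox = curves.shape[0]
    cbf = np.zeros(nvox)
    residues = np.zeros((nvox, L))
    oi_used = np.zeros(nvox)
    cutoff_used = np.full(nvox, np.nan)

    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(sigma > 0, 1.0 / lam, 0.0)

    pending = np.ones(nvox, dtype=bool)
    flat = np.abs(curves).max(axis=1) == 0
    pending[flat] = False  # zero curves: CBF = 0, flat residue, by contract
    cutoff_used[flat] = cutoffs[0]

    for i, frac in enumerate(cutoffs):
        if not pending.any():
            break
        keep = sigma >= frac * smax
        if not keep.any():
            continue
        r = np.fft.irfft(chat[pending] * (inv * keep), n, axis=1)[:, :L]
        oi = oi_fn(r, L)
        last = i == len(cutoffs) - 1
        accept = (oi <= oi_threshold) | last
        if accept.any():
            rows = np.flatnonzero(pending)[accept]
            residues[rows] = r[accept]
            oi_used[rows] = oi[accept]
            cutoff_used[rows] = frac
            pw = L if peak_window is None else max(int(peak_window), 1)
            cbf[rows] = np.clip(r[accept][:, :pw].max(axis=1), 0.0, None)
            pending[rows] = False
    return cbf, residues, oi_used, cutoff_used


def compute_cbv(
    conc,
    truncation_index: int | None = None,
    dt: float | None = None,
    aif: "Aif | np.ndarray | None" = None,
    clip_negative: bool = True,
):
    """CBV by trapezoidal integration of the concentration curve.

    Integration runs from the first frame through the truncation frame;
    frames beyond it have no effect on the result.  ``truncation_index`` is
    a 1-based frame ordinal (protocol convention); when ``conc`` is a
    ConcentrationSeries it defaults to the series' stored truncation frame.
    Negative concentration excursions are clipped to zero before
    integration.  If an AIF is supplied the integral is normalized by the
    AIF integral over the same window, yielding CBV in the units of the
    forward model.
    """
    if isinstance(conc, ConcentrationSeries):
        dt = conc.frame_interval_s
        trunc = conc.truncation_frame if truncation_index is None else truncation_index - 1
        if trunc <= conc.baseline_window[1]:
            raise ValueError("truncation frame must lie beyond the baseline window")
        values = conc.values
    else:
        if dt is None or truncation_index is None:
            raise ValueError("dt and truncation_index are required for raw arrays")
        values = np.asarray(conc, dtype=np.float64)
        trunc = truncation_index - 1
    if trunc >= values.shape[-1]:
        raise ValueError("truncation frame beyond the end of the series")
    window = values[..., : trunc + 1]
    if clip_negative:
        window = np.clip(window, 0.0, None)
    cbv = np.trapezoid(window, dx=dt, axis=-1)
    if aif is not None:
        aif_curve = np.asarray(aif.curve if isinstance(aif, Aif) else aif)
        denom = np.trapezoid(np.clip(aif_curve[: trunc + 1], 0, None), dx=dt)
        if denom <= 0:
            raise ValueError("AIF integral must be positive")
        cbv = cbv / denom
    return cbv


def compute_mtt(cbv, cbf, eps: float = 1e-12):
    """MTT = CBV/CBF where CBF > eps; masked (zero) elsewhere.

    Accepts arrays or VolumeImages; returns the same kind.
    """
    cbv_arr = cbv.data if isinstance(cbv, VolumeImage) else np.asarray(cbv)
    cbf_arr = cbf.data if isinstance(cbf, VolumeImage) else np.asarray(cbf)
    if cbv_arr.shape != cbf_arr.shape:
        raise ValueError("CBV and CBF grids do not match")
    mtt = np.zeros_like(cbv_arr, dtype=np.float64)
    ok = cbf_arr > eps
    mtt[ok] = cbv_arr[ok] / cbf_arr[ok]
    if isinstance(cbv, VolumeImage):
        return cbv.copy_with(mtt, "mtt")
    return mtt


def deconvolve_perfusion(
    conc: ConcentrationSeries,
    aif: Aif,
    oi_threshold: float = 0.17,
    mask: np.ndarray | None = None,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> PerfusionMaps:
    """Full perfusion-map computation for one concentration series.

    Deconvolves every voxel in ``mask`` (default: all valid voxels), then
    derives CBV (AIF-normalized) and MTT = CBV/CBF.
    """
    shape = conc.values.shape[:3]
    mask = conc.valid if mask is None else (np.asarray(mask, dtype=bool) & conc.valid)
    L = conc.truncation_frame + 1
    curves = conc.values[mask][:, :L]
    cbf_v, _, oi_v, cut_v = osvd_deconvolve(
        curves, aif.curve[:L], oi_threshold, dt=conc.frame_interval_s, cutoffs=cutoffs
    )
    cbf = np.zeros(shape)
    cbf[mask] = cbf_v
    oi_map = np.zeros(shape)
    oi_map[mask] = oi_v
    cut_map = np.full(shape, np.nan)
    cut_map[mask] = cut_v
    cbv_full = compute_cbv(conc, aif=aif)
    cbv = np.where(mask, cbv_full, 0.0)
    mtt = compute_mtt(cbv, cbf)
    vi = lambda a, nm: VolumeImage(a, conc.voxel_size, nm)
    return PerfusionMaps(
        cbf=vi(cbf, "cbf"),
        cbv=vi(cbv, "cbv"),
        mtt=vi(mtt, "mtt"),
        oscillation_index_used=oi_map,
        cutoff_used=cut_map,
    )
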