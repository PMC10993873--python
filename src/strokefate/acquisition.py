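"""Forward simulation of the MRI acquisitions.

Three acquisitions are emulated per imaging session:

* diffusion-weighted spin-echo EPI at b = 0 and b = 1454 s/mm^2 with the
  diffusion gradient along each cardinal direction,
* multi-echo T2-weighted imaging at TE = 30/50/80/190 ms,
* a dynamic susceptibility contrast (DSC) gradient-echo EPI series at
  TR/TE = 164/13 ms with the contrast bolus arriving at the 180th image.

The DSC forward model is the standard indicator-dilution convolution: the
tissue concentration is C(t) = CBF * (AIF (*) R)(t) with a residue function
R from a configurable family, discretized on the frame grid.  The discrete
residue is normalized so that dt * sum(R) = MTT exactly, which makes the
central-volume convention integral C = CBV * integral AIF hold to machine
precision.  Signal follows the T2* relation S(t) = S0 * exp(-TE * C(t)) with
a unit susceptibility proportionality constant; all downstream perfusion
quantities are contralateral-relative, so the constant cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import DscSeries, VolumeImage
from .phantom import LABELS, Phantom

__all__ = [
    "AcquisitionConfig",
    "AifSpec",
    "gamma_variate_aif",
    "residue_function",
    "forward_concentration",
    "simulate_dwi",
    "simulate_multiecho",
    "simulate_dsc",
]


@dataclass
class AcquisitionConfig:
    """Sequence parameters and noise model for the simulated acquisitions."""

    b_values: tuple[float, float] = (0.0, 1454.0)  # s/mm^2
    echo_times: tuple[float, ...] = (30.0, 50.0, 80.0, 190.0)  # ms
    dsc_tr: float = 164.0  # ms
    dsc_te: float = 13.0  # ms
    bolus_image_index: int = 180  # 1-based frame ordinal
    truncation_index: int = 400  # 1-based frame ordinal
    n_frames: int = 450
    s0: float = 1000.0
    noise_sd: float = 20.0
    #: DSC frames use larger voxels (64 x 64 EPI, 1.2 mm slices) than the
    #: diffusion/T2 scans, hence a better baseline SNR.
    dsc_noise_sd: float = 10.0
    noise_model: str = "gaussian"  # or "rician"
    anisotropy: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (1 <= self.bolus_image_index < self.truncation_index <= self.n_frames):
            raise ValueError(
                "require 1 <= bolus_image_index < truncation_index <= n_frames"
            )
        if self.dsc_tr <= 0 or self.dsc_te <= 0 or any(t <= 0 for t in self.echo_times):
            raise ValueError("all times must be strictly positive")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")

    @property
    def frame_interval_s(self) -> float:
        return self.dsc_tr / 1000.0

    @property
    def bolus_frame(self) -> int:
        """0-based index of the bolus-arrival frame."""
        return self.bolus_image_index - 1

    @property
    def truncation_frame(self) -> int:
        """0-based index of the last integrated frame."""
        return self.truncation_index - 1


@dataclass
class AifSpec:
    """Gamma-variate arterial input: C_a(t) = A * (t - t0)^alpha * exp(-(t - t0)/beta)."""

    alpha: float = 3.0
    beta_s: float = 1.5
    amplitude: float = 8.0

    def __post_init__(self) -> None:
        if self.beta_s <= 0 or self.alpha <= 0 or self.amplitude <= 0:
            raise ValueError("gamma-variate parameters must be positive")


def gamma_variate_aif(
    n_frames: int, dt: float, t0_frame: int, spec: AifSpec | None = None
) -> np.ndarray:
    """Sample a gamma-variate bolus curve on the frame grid (zero before t0)."""
    spec = spec or AifSpec()
    t = np.arange(n_frames) * dt
    tau = t - t0_frame * dt
    curve = np.zeros(n_frames)
    pos = tau > 0
    curve[pos] = spec.amplitude * tau[pos] ** spec.alpha * np.exp(-tau[pos] / spec.beta_s)
    return curve


def residue_function(
    mtt: float, dt: float, n: int, family: str = "exponential"
) -> np.ndarray:
    """Discrete residue function scaled so dt * sum(R) = MTT exactly."""
    if mtt <= 0:
        raise ValueError("MTT must be positive")
    t = np.arange(n) * dt
    if family == "exponential":
        r = np.exp(-t / mtt)
    elif family == "boxcar":
        r = (t < mtt).astype(float)
        if not r.any():
            r[0] = 1.0
    else:
        raise ValueError(f"unknown residue family: {family!r}")
    # Trapezoid-rule normalization: the CBV stage integrates concentration
    # curves by the trapezoid rule, so matching that quadrature here makes
    # integral C = CBV * integral AIF hold while leaving the residue peak
    # within O((dt/MTT)^2) of 1.
    return r * (mtt / np.trapezoid(r, dx=dt))


def forward_concentration(
    cbf: np.ndarray,
    mtt: np.ndarray,
    aif_curve: np.ndarray,
    dt: float,
    residue_family: str = "exponential",
) -> np.ndarray:
    """Noiseless tissue concentration curves C = CBF * dt * conv(AIF, R).

    ``cbf`` and ``mtt`` are flat arrays over voxels; returns an array of
    shape (n_voxels, n_frames).  Voxels sharing (CBF, MTT) are computed once.
    """
    cbf = np.asarray(cbf, dtype=np.float64).ravel()
    mtt = np.asarray(mtt, dtype=np.float64).ravel()
    n = len(aif_curve)
    out = np.zeros((cbf.size, n))
    active = cbf > 0
    if np.any(active & (mtt <= 0)):
        raise ValueError("MTT <= 0 in a perfused voxel")
    pairs, inv = np.unique(
        np.column_stack([cbf[active], mtt[active]]), axis=0, return_inverse=True
    )
    curves = np.empty((len(pairs), n))
    for i, (f, m) in enumerate(pairs):
        r = residue_function(m, dt, n, residue_family)
        curves[i] = f * dt * np.convolve(aif_curve, r)[:n]
    out[active] = curves[inv]
    return out


def _add_noise(
    signal: np.ndarray, config: AcquisitionConfig, rng, sd: float | None = None
) -> np.ndarray:
    sd = config.noise_sd if sd is None else sd
    if sd == 0:
        return signal
    if config.noise_model == "gaussian":
        return signal + rng.normal(0.0, sd, signal.shape)
    re = signal + rng.normal(0.0, sd, signal.shape)
    im = rng.normal(0.0, sd, signal.shape)
    return np.sqrt(re**2 + im**2)


def simulate_dwi(
    phantom: Phantom,
    config: AcquisitionConfig,
    timepoint: str = "occlusion",
    rng=None,
) -> dict[str, VolumeImage]:
    """Simulate b = 0 and per-direction diffusion-weighted volumes.

    Noiseless signal obeys S(b) = S0 * exp(-b * ADC) per gradient direction;
    the truth is isotropic unless ``config.anisotropy`` scales the ADC seen
    along x, y or z.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    adc = phantom.truth(timepoint)["adc"]
    s0 = np.where(phantom.brain_mask, config.s0, 0.0)
    b_high = max(config.b_values)
    out: dict[str, VolumeImage] = {
        "b0": VolumeImage(
            _add_noise(s0.copy(), config, rng), phantom.voxel_size, "b0"
        )
    }
    for axis, factor in zip("xyz", config.anisotropy):
        sig = s0 * np.exp(-b_high * adc * factor)
        out[f"dwi_{axis}"] = VolumeImage(
            _add_noise(sig, config, rng), phantom.voxel_size, f"dwi_{axis}"
        )
    return out


def simulate_multiecho(
    phantom: Phantom,
    config: AcquisitionConfig,
    timepoint: str = "day4",
    rng=None,
) -> dict[float, VolumeImage]:
    """Simulate one T2-weighted volume per echo time: S(TE) = S0 * exp(-TE/T2)."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    t2 = phantom.truth(timepoint)["t2"]
    s0 = np.where(phantom.brain_mask, config.s0, 0.0)
    out: dict[float, VolumeImage] = {}
    with np.errstate(divide="ignore"):
        rate = np.where(t2 > 0, 1.0 / t2, 0.0)  # flat decay where T2 is 0/inf
    for te in config.echo_times:
        sig = s0 * np.exp(-te * rate)
        out[te] = VolumeImage(
            _add_noise(sig, config, rng), phantom.voxel_size, f"te{te:g}"
        )
    return out


def simulate_dsc(
    phantom: Phantom,
    config: AcquisitionConfig,
    aif_spec: AifSpec | None = None,
    residue_family: str = "exponential",
    timepoint: str = "post_0.5h",
    rng=None,
    return_concentration: bool = False,
):
    """Simulate the 4D DSC bolus-tracking series.

    Frames before the bolus-arrival index are baseline S0 (plus noise); from
    the bolus on, each voxel follows the convolution forward model with its
    ground-truth CBF and MTT.  Set ``return_concentration`` to also obtain
    the planted noiseless concentration array for round-trip oracles.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    truth = phantom.truth(timepoint)
    cbf, mtt = truth["cbf"], truth["mtt"]
    tissue = phantom.brain_mask
    if np.any(tissue & (cbf > 0) & (mtt <= 0)):
        raise ValueError("MTT <= 0 in a perfused tissue voxel")
    dt = config.frame_interval_s
    aif_curve = gamma_variate_aif(config.n_frames, dt, config.bolus_frame, aif_spec)
    conc = forward_concentration(
        cbf.ravel(), mtt.ravel(), aif_curve, dt, residue_family
    ).reshape(phantom.shape + (config.n_frames,))
    s0 = np.where(tissue, config.s0, 0.0)
    te_s = config.dsc_te / 1000.0
    signal = s0[..., None] * np.exp(-te_s * conc)
    signal = _add_noise(signal, config, rng, sd=config.dsc_noise_sd)
    series = DscSeries.from_ordinals(
        signal,
        bolus_image_ordinal=config.bolus_image_index,
        truncation_ordinal=config.truncation_index,
        tr_ms=config.dsc_tr,
        te_ms=config.dsc_te,
        voxel_size=phantom.voxel_size,
    )
    if return_concentration:
        return series, conc
    return series
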