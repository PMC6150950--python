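"""Closed-form beamformer images from exact model covariances.

In the infinite-data limit the sensor covariance of the boxcar two-source
simulation has the exact form

    C = υ² I + Σ_i  δ_i σ_i²  l_i l_iᵀ,

where l_i is source i's lead field, σ_i² its moment variance while active
(mean² + across-trial SD² for the truncated-normal per-trial amplitude
model), δ_i the duty cycle (fraction of the covariance window during which
the source is active) and υ² the per-sample sensor noise variance.  Feeding
these exact covariances through the very same weights/pseudo-z code used for
simulated data yields the analytical image a simulation converges to as the
trial count grows — the reference against which finite-data images are
judged.

Only methods 1 (full-window covariance) and 3 (per-source segmented
covariances) have analytic counterparts here; the duty cycle of a segmented
half-window is twice the full-window value for the default paradigm (2 s of
activity in 10 s rather than 20 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beamformer import CovarianceMatrix, CovarianceWindow, SourceImage, method_profiles
from .geometry import NAM, HeadModel, SensorArray

__all__ = [
    "ExactCovarianceSpec",
    "exact_covariance",
    "analytic_method_covariances",
    "analytic_profile",
    "woodbury_inverse",
]


@dataclass(frozen=True)
class ExactCovarianceSpec:
    """Model covariance parameters for one covariance window.

    ``source_variances`` are within-active-window moment variances in nAm²;
    ``duty_cycles`` the active fraction of the window per source;
    ``noise_variance`` the per-sample sensor noise variance in T².
    """

    lead_fields: tuple[np.ndarray, ...]  # T per A·m, one per source
    source_variances: tuple[float, ...]  # (nAm)²
    duty_cycles: tuple[float, ...]
    noise_variance: float  # T²

    def __post_init__(self) -> None:
        k = len(self.lead_fields)
        if len(self.source_variances) != k or len(self.duty_cycles) != k:
            raise ValueError("one variance and one duty cycle per source required")
        if any(not 0.0 <= d <= 1.0 for d in self.duty_cycles):
            raise ValueError("duty cycles must lie in [0, 1]")
        if any(v < 0 for v in self.source_variances):
            raise ValueError("source variances must be non-negative")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be non-negative")
        object.__setattr__(
            self, "lead_fields", tuple(np.asarray(l, dtype=float) for l in self.lead_fields)
        )


def trial_amplitude_variance(amplitude_mean: float, amplitude_sd: float) -> float:
    """E[s²] (nAm²) of the per-trial strength model s ~ N(mean, sd)."""
    return amplitude_mean**2 + amplitude_sd**2


def exact_covariance(
    spec: ExactCovarianceSpec, window: CovarianceWindow | None = None
) -> CovarianceMatrix:
    """C = υ²I + Σ δ_i σ_i² l_i l_iᵀ as an (infinite-sample) covariance."""
    n = spec.lead_fields[0].shape[0] if spec.lead_fields else 0
    if n == 0:
        raise ValueError("at least one lead field required to size the covariance")
    m = spec.noise_variance * np.eye(n)
    for l, var, duty in zip(spec.lead_fields, spec.source_variances, spec.duty_cycles):
        m = m + (duty * var * NAM**2) * np.outer(l, l)
    return CovarianceMatrix(matrix=m, n_samples=np.inf, window=window, n_raw=None)


def woodbury_inverse(spec: ExactCovarianceSpec) -> np.ndarray:
    """C⁻¹ via the rank-recursive (Sherman–Morrison) identity.

    An independent route to the inverse used to cross-check the direct
    solves in the imaging code.
    """
    if spec.noise_variance <= 0:
        raise ValueError("rank-recursive inverse needs positive noise variance")
    n = spec.lead_fields[0].shape[0]
    inv = np.eye(n) / spec.noise_variance
    for l, var, duty in zip(spec.lead_fields, spec.source_variances, spec.duty_cycles):
        s = duty * var * NAM**2
        if s == 0:
            continue
        u = inv @ l
        inv = inv - np.outer(u, u) * (s / (1.0 + s * float(l @ u)))
    return inv


def analytic_method_covariances(
    lead_fields,
    source_variances,
    duty_cycles,
    noise_variance: float,
    segment_duty_factor: float = 2.0,
) -> dict:
    """Exact {full, w1, w2} covariances for the two-source paradigm.

    The full-window covariance contains both sources at their full-trial duty
    cycles; each half-window covariance contains only its own source at
    ``segment_duty_factor`` times that duty (a source active 2 s out of a
    20 s trial is active 2 s out of its 10 s half-trial).
    """
    lead_fields = tuple(np.asarray(l, dtype=float) for l in lead_fields)
    if len(lead_fields) != 2:
        raise ValueError("the two-source construction needs exactly two lead fields")
    nv = noise_variance
    if nv <= 0:
        # zero-noise images diverge at the sources; guard with a tiny floor
        nv = 1e-12 * max(float(np.max(l @ l)) for l in lead_fields) * NAM**2
    full = ExactCovarianceSpec(lead_fields, tuple(source_variances), tuple(duty_cycles), nv)
    segs = [
        ExactCovarianceSpec(
            (lead_fields[i],),
            (source_variances[i],),
            (min(duty_cycles[i] * segment_duty_factor, 1.0),),
            nv,
        )
        for i in range(2)
    ]
    return {
        "full": exact_covariance(full),
        "w1": exact_covariance(segs[0]),
        "w2": exact_covariance(segs[1]),
        "noise_variance": nv,
    }


def analytic_profile(
    lead_field_fn_inputs: dict,
    method: int,
    scan_points: np.ndarray,
    head: HeadModel,
    sensors: SensorArray,
    orientations="optimal",
    statistic: str = "pseudo_z",
) -> list[SourceImage]:
    """Infinite-data pseudo-z image(s) along a scan line for method 1 or 3.

    ``lead_field_fn_inputs`` carries ``lead_fields`` (two source lead
    fields), ``source_variances`` (nAm²), ``duty_cycles`` (full-window) and
    ``noise_variance`` (T²).  The same scanning code as for simulated
    covariances is used, so simulated profiles converge to these curves as
    trials grow.
    """
    if method not in (1, 3):
        raise ValueError("analytic images are defined for methods 1 and 3 only")
    covs = analytic_method_covariances(
        lead_field_fn_inputs["lead_fields"],
        lead_field_fn_inputs["source_variances"],
        lead_field_fn_inputs["duty_cycles"],
        lead_field_fn_inputs["noise_variance"],
        lead_field_fn_inputs.get("segment_duty_factor", 2.0),
    )
    nv = covs.pop("noise_variance")
    images = method_profiles(
        covs, scan_points, head, sensors, method, nv, orientations=orientations,
        statistic=statistic,
    )
    for img in images:
        img.meta["analytic"] = True
    return images
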