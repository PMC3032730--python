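"""Reconvolved multi-exponential decay model and derived lifetime quantities.

A fluorescence decay recorded through an instrument with a non-negligible
response is modelled as a linear combination of *unit-area* basis decays
(kernels).  Instead of a scattered-light instrument response, the kernels
are built from the measured decay of a reference dye with a known
mono-exponential lifetime ``tau_ref`` (delta-function iterative
reconvolution).  For a component lifetime ``tau`` the kernel is

    phi(t)  propto  ref(t) + (1/tau_ref - 1/tau) * (ref * exp(-t/tau))(t)

where ``*`` is convolution on the micro-time grid.  Using the reference in
place of the raw response automatically corrects the wavelength dependence
of the response shape, because reference and probe are measured through the
same detection band.

Amplitude conventions
---------------------
``alpha_j`` are expected photon counts per component (they sum to the pixel
photon number).  Two normalizations are used downstream:

* normalized amplitudes ``a_j = alpha_j / sum_k |alpha_k|`` — intensity
  fractions of unit-area kernels; weighting lifetimes by ``a`` gives the
  intensity-averaged ("average") lifetime;
* pre-exponential fractions ``p_j ∝ alpha_j / tau_j`` (again normalized by
  the absolute sum) — molecule fractions; weighting by ``p`` gives the
  amplitude-averaged ("mean") lifetime.

Absolute-value normalization keeps the fractions meaningful when a rising
(negative-amplitude) component is present, e.g. acceptor emission fed by
energy transfer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import h5py
import numpy as np

from .io import TimeAxis

__all__ = [
    "ReferenceDecay",
    "ComponentSpec",
    "Kernels",
    "PixelAmplitudes",
    "DomainError",
    "ModelValidityError",
    "build_kernels",
    "expected_counts",
    "normalized_amplitudes",
    "pre_exponential_fractions",
    "amplitude_fractions_from_preexp",
    "average_lifetime",
    "mean_lifetime",
]

MAX_COMPONENTS = 4


class DomainError(ValueError):
    """Parameter outside its physical domain."""


class ModelValidityError(ValueError):
    """Amplitude combination producing a negative expected count."""


@dataclass
class ReferenceDecay:
    """Measured (or synthesized) decay of the mono-exponential reference dye."""

    histogram: np.ndarray
    tau_ref: float  # picoseconds
    time_axis: TimeAxis

    def __post_init__(self) -> None:
        self.histogram = np.asarray(self.histogram, dtype=float)
        if self.histogram.ndim != 1:
            raise DomainError("reference histogram must be 1-D")
        if len(self.histogram) != self.time_axis.n_channels:
            raise DomainError("reference histogram / time axis length mismatch")
        if (self.histogram < 0).any():
            raise DomainError("reference histogram has negative entries")
        if self.histogram.sum() <= 0:
            raise DomainError("reference histogram is empty")
        if not self.tau_ref > 0:
            raise DomainError("tau_ref must be positive")


@dataclass(frozen=True)
class ComponentSpec:
    """One exponential component of a decay model.

    ``tau`` is the lifetime in picoseconds (``None`` = to be fitted, start
    from a default grid).  ``link_key`` names a lifetime shared across
    channels; components with equal keys are fitted as a single parameter.
    ``sign`` is ``"positive"`` for ordinary emission or ``"free"`` for
    components allowed to carry a negative amplitude (rising edge).
    """

    tau: float | None = None
    link_key: str | None = None
    sign: str = "positive"

    def __post_init__(self) -> None:
        if self.tau is not None and not self.tau > 0:
            raise DomainError("component lifetime must be positive")
        if self.sign not in ("positive", "free"):
            raise DomainError(f"unknown sign {self.sign!r}")


@dataclass
class Kernels:
    """Unit-area reconvolved basis decays, one row per component."""

    phi: np.ndarray  # (n_components, n_time_channels)
    time_axis: TimeAxis
    taus: np.ndarray  # picoseconds
    tau_ref: float

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.taus = np.asarray(self.taus, dtype=float)
        if self.phi.ndim != 2:
            raise DomainError("phi must be 2-D")
        if not np.isfinite(self.phi).all():
            raise DomainError("non-finite kernel values")

    @property
    def n_components(self) -> int:
        return self.phi.shape[0]

    def save_hdf5(self, path, group: str = "kernels") -> None:
        with h5py.File(path, "a") as h5:
            if group in h5:
                del h5[group]
            g = h5.create_group(group)
            g.create_dataset("phi", data=self.phi)
            g.create_dataset("taus_ps", data=self.taus)
            g.attrs["tau_ref_ps"] = self.tau_ref
            g.attrs["n_channels"] = self.time_axis.n_channels
            g.attrs["channel_width_ps"] = self.time_axis.channel_width
            g.attrs["origin_ps"] = self.time_axis.origin

    @classmethod
    def load_hdf5(cls, path, group: str = "kernels") -> "Kernels":
        with h5py.File(path, "r") as h5:
            g = h5[group]
            axis = TimeAxis(
                int(g.attrs["n_channels"]),
                float(g.attrs["channel_width_ps"]),
                float(g.attrs["origin_ps"]),
            )
            return cls(
                np.asarray(g["phi"]),
                axis,
                np.asarray(g["taus_ps"]),
                float(g.attrs["tau_ref_ps"]),
            )


@dataclass
class PixelAmplitudes:
    """Fitted per-pixel amplitudes (expected photons per component)."""

    alpha: np.ndarray
    taus: np.ndarray
    n_photons: float
    deviance: float | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.taus = np.asarray(self.taus, dtype=float)

    @property
    def normalized(self) -> np.ndarray:
        """Normalized (intensity-fraction) amplitudes ``a_j``."""
        return normalized_amplitudes(self.alpha)

    @property
    def preexp(self) -> np.ndarray:
        """Normalized pre-exponential (molecule) fractions ``p_j``."""
        return pre_exponential_fractions(self.alpha, self.taus)

    @property
    def tau_av(self) -> float:
        return average_lifetime(self.normalized, self.taus)

    @property
    def tau_mean(self) -> float:
        return mean_lifetime(self.preexp, self.taus)


# ---------------------------------------------------------------------------
# Kernel construction
# ---------------------------------------------------------------------------

def _component_taus(components) -> np.ndarray:
    taus = []
    for c in components:
        if isinstance(c, ComponentSpec):
            if c.tau is None:
                raise DomainError("ComponentSpec without a lifetime")
            taus.append(c.tau)
        else:
            taus.append(float(c))
    arr = np.asarray(taus, dtype=float)
    if arr.size < 1 or arr.size > MAX_COMPONENTS:
        raise DomainError(
            f"number of components must be 1..{MAX_COMPONENTS}, got {arr.size}"
        )
    if (arr <= 0).any():
        raise DomainError("lifetimes must be positive")
    return arr


def _reference_convolution(ref: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Channel-integrated convolution of the reference with ``exp(-t/tau)``.

    The reference histogram is treated as a piecewise-constant photon
    density (``ref[l]/dt`` on channel ``l``); the double integral of
    ``rho(s) * exp(-(t-s)/tau)`` over source channel ``l`` and target
    channel ``i`` then has a closed form, so no quadrature error enters
    beyond the piecewise-constant assumption:

        C[i] = ref[i] * (tau*dt - tau^2*(1-g)) / dt
             + tau^2 * (1-g)^2 / dt * sum_{l<i} ref[l] * g^(i-l-1)

    with ``g = exp(-dt/tau)``.
    """
    n = len(ref)
    g = np.exp(-dt / tau)
    same = tau * dt - tau * tau * (1.0 - g)
    cross = tau * tau * (1.0 - g) ** 2
    geom = g ** np.arange(n, dtype=float)
    # S[i] = sum_{l <= i-1} ref[l] * g^(i-1-l)
    full = np.convolve(ref, geom)[:n]
    shifted = np.concatenate(([0.0], full[:-1]))
    return (ref * same + cross * shifted) / dt


def build_kernels(
    ref: ReferenceDecay,
    components: Sequence[ComponentSpec] | Sequence[float] | np.ndarray,
) -> Kernels:
    """Build unit-area decay kernels for the given component lifetimes.

    Each kernel is ``ref`` convolved with ``delta(t) + (1/tau_ref - 1/tau) *
    exp(-t/tau)``, evaluated channel-by-channel on the reference's time axis
    and normalized to unit sum.  When ``tau == tau_ref`` the correction term
    vanishes and the kernel is the normalized reference itself.
    """
    taus = _component_taus(components)
    dt = ref.time_axis.channel_width
    hist = ref.histogram
    phi = np.empty((taus.size, len(hist)))
    for j, tau in enumerate(taus):
        coeff = 1.0 / ref.tau_ref - 1.0 / tau
        raw = hist + coeff * _reference_convolution(hist, tau, dt)
        total = raw.sum()
        if total <= 0:
            raise DomainError(f"kernel for tau={tau} ps has non-positive area")
        phi[j] = raw / total
    return Kernels(phi, ref.time_axis, taus, ref.tau_ref)


# ---------------------------------------------------------------------------
# Model evaluation and amplitude algebra
# ---------------------------------------------------------------------------

def expected_counts(
    kernels: Kernels, alpha: Sequence[float] | np.ndarray, validate: bool = True
) -> np.ndarray:
    """Expected histogram ``m_i = sum_j alpha_j * phi_{j,i}``.

    Photons are conserved: ``sum_i m_i == sum_j alpha_j``.  When a signed
    amplitude combination drives any expected count negative the model is
    unphysical and a :class:`ModelValidityError` is raised.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (kernels.n_components,):
        raise DomainError(
            f"expected {kernels.n_components} amplitudes, got {alpha.shape}"
        )
    m = alpha @ kernels.phi
    if validate:
        scale = np.abs(m).max() if m.size else 0.0
        if scale > 0 and m.min() < -1e-9 * scale:
            raise ModelValidityError(
                "amplitude combination yields negative expected counts "
                f"(min {m.min():.3g})"
            )
        np.clip(m, 0.0, None, out=m)
    return m


def normalized_amplitudes(alpha) -> np.ndarray:
    """``a_j = alpha_j / sum_k |alpha_k|`` (signed fractions, |a| sums to 1)."""
    alpha = np.asarray(alpha, dtype=float)
    total = np.abs(alpha).sum()
    if total <= 0:
        raise DomainError("all-zero amplitudes cannot be normalized")
    return alpha / total


def pre_exponential_fractions(alpha, taus) -> np.ndarray:
    """``p_j ∝ alpha_j / tau_j`` normalized so that ``sum |p_j| = 1``."""
    alpha = np.asarray(alpha, dtype=float)
    taus = np.asarray(taus, dtype=float)
    if (taus <= 0).any():
        raise DomainError("lifetimes must be positive")
    q = alpha / taus
    total = np.abs(q).sum()
    if total <= 0:
        raise DomainError("all-zero amplitudes cannot be normalized")
    return q / total


def amplitude_fractions_from_preexp(p, taus) -> np.ndarray:
    """Inverse of :func:`pre_exponential_fractions` on normalized fractions."""
    p = np.asarray(p, dtype=float)
    taus = np.asarray(taus, dtype=float)
    if (taus <= 0).any():
        raise DomainError("lifetimes must be positive")
    return normalized_amplitudes(p * taus)


def average_lifetime(a, taus) -> float:
    """Intensity-averaged lifetime ``sum a_j tau_j / sum a_j``.

    ``a`` are intensity fractions of unit-area kernels.  Returns NaN when the
    fractions sum to zero (undefined average).
    """
    a = np.asarray(a, dtype=float)
    taus = np.asarray(taus, dtype=float)
    denom = a.sum()
    if denom == 0:
        return float("nan")
    return float((a * taus).sum() / denom)


def mean_lifetime(p, taus) -> float:
    """Amplitude-averaged (mean) lifetime ``sum p_j tau_j / sum p_j``.

    ``p`` are normalized pre-exponential fractions; this is the quantity of
    interest for energy-transfer efficiencies because it weights each
    molecular species equally rather than by emitted intensity.
    """
    p = np.asarray(p, dtype=float)
    taus = np.asarray(taus, dtype=float)
    denom = p.sum()
    if denom == 0:
        return float("nan")
    return float((p * taus).sum() / denom)
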