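"""Three-stage global analysis of multi-channel FLIM images.

The estimation strategy separates what is spatially invariant from what is
not:

1. **Segmentation** — pixels are sorted into background and bright
   connected regions (:mod:`mpflim.segmentation`).
2. **Lifetimes** — within each region the decays are summed into a single
   high-count trace per channel and the component lifetimes are estimated
   by weighted least squares, optionally *linking* a lifetime across
   channels (e.g. a transfer component appearing in donor and acceptor
   channels must share one value).
3. **Amplitudes** — with lifetimes frozen, the per-component amplitudes are
   estimated pixel by pixel by minimizing the multinomial deviance

       D = 2 * sum_i n_i * ln(n_i / m_i),

   the exact (fixed-N) Poisson/multinomial likelihood-ratio statistic,
   under the constraint that the amplitudes sum to the pixel photon number.
   For fixed kernels the problem is convex, so the per-pixel estimate is
   unique; a projected Newton iteration solves all pixels of a region in a
   vectorized sweep.

At the photon counts typical of minimally invasive imaging (tens to
hundreds of photons per pixel) the deviance-based stage-3 estimator is what
keeps the per-pixel amplitude maps unbiased and CRLB-efficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .decay_model import (
    ComponentSpec,
    Kernels,
    PixelAmplitudes,
    ReferenceDecay,
    average_lifetime,
    build_kernels,
    mean_lifetime,
    normalized_amplitudes,
    pre_exponential_fractions,
)
from .io import DecayCube
from .segmentation import SegmentMap, intensity_image, segment

__all__ = [
    "ModelSpec",
    "LifetimeFitResult",
    "LifetimeMaps",
    "GlobalFitResult",
    "PipelineConfig",
    "FitError",
    "InfiniteDevianceError",
    "deviance",
    "sum_decays",
    "fit_lifetimes",
    "fit_pixel_amplitudes",
    "fit_amplitudes_batch",
    "run_pipeline",
]

TAU_BOUNDS_PS = (10.0, 20000.0)


class FitError(RuntimeError):
    """Estimation failed in a way the caller must handle."""


class InfiniteDevianceError(FitError):
    """Observed photons in a channel where the model predicts zero."""


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Decay model of every acquisition channel.

    ``channels`` maps channel name to its list of components.  Components
    sharing a ``link_key`` are fitted with a single lifetime across
    channels; unlinked components get an implicit per-channel key.
    """

    channels: Mapping[str, Sequence[ComponentSpec]]

    def __post_init__(self) -> None:
        for name, comps in self.channels.items():
            if not 1 <= len(comps) <= 4:
                raise ValueError(
                    f"channel {name}: 1..4 components required, got {len(comps)}"
                )

    def resolved_keys(self) -> dict[str, list[str]]:
        """Per-channel list of lifetime parameter keys."""
        out: dict[str, list[str]] = {}
        for name, comps in self.channels.items():
            out[name] = [
                c.link_key if c.link_key else f"{name}:{i}"
                for i, c in enumerate(comps)
            ]
        return out

    def unique_keys(self) -> list[str]:
        seen: list[str] = []
        for keys in self.resolved_keys().values():
            for k in keys:
                if k not in seen:
                    seen.append(k)
        return seen

    def initial_taus(self) -> dict[str, float]:
        """Starting lifetime per key: declared value or a log-spaced default."""
        inits: dict[str, float] = {}
        keys = self.unique_keys()
        declared: dict[str, float] = {}
        for name, comps in self.channels.items():
            for key, c in zip(self.resolved_keys()[name], comps):
                if c.tau is not None and key not in declared:
                    declared[key] = float(c.tau)
        missing = [k for k in keys if k not in declared]
        if missing:
            # log-spaced over 0.1-5 ns
            grid = np.geomspace(100.0, 5000.0, num=max(len(missing), 2))
            for k, tau in zip(missing, grid):
                declared[k] = float(tau)
        for k in keys:
            inits[k] = declared[k]
        return inits

    def signs(self, channel: str) -> np.ndarray:
        return np.array(
            [c.sign == "free" for c in self.channels[channel]], dtype=bool
        )


# ---------------------------------------------------------------------------
# Deviance
# ---------------------------------------------------------------------------

def deviance(n: np.ndarray, m: np.ndarray, rel_tol: float = 1e-6) -> float:
    """Multinomial deviance ``D = 2 sum n ln(n/m)`` with ``0 ln 0 = 0``.

    Requires photon conservation (``sum m == sum n``) within ``rel_tol``;
    under that constraint D coincides with the Poisson deviance
    ``2 sum [n ln(n/m) - (n - m)]`` and is >= 0 with equality iff n == m on
    its support.
    """
    n = np.asarray(n, dtype=float)
    m = np.asarray(m, dtype=float)
    sn, sm = n.sum(), m.sum()
    if sn > 0 and abs(sm - sn) > rel_tol * sn:
        raise ValueError(
            f"deviance requires sum(m) == sum(n); got {sm:.6g} vs {sn:.6g}"
        )
    pos = n > 0
    if (m[pos] <= 0).any():
        raise InfiniteDevianceError(
            "model predicts zero counts where photons were observed"
        )
    return float(2.0 * np.sum(n[pos] * np.log(n[pos] / m[pos])))


# ---------------------------------------------------------------------------
# Stage 2: region-summed decays and lifetime estimation
# ---------------------------------------------------------------------------

def sum_decays(
    cube: DecayCube, segment_map: SegmentMap, label: int
) -> dict[str, np.ndarray]:
    """Channel-wise sum of the decay histograms over one region."""
    mask = segment_map.region_mask(label)
    if not mask.any():
        raise FitError(f"region {label} is empty")
    return {
        ch.name: cube.counts[i][mask].sum(axis=0).astype(float)
        for i, ch in enumerate(cube.channels)
    }


@dataclass
class LifetimeFitResult:
    """Shared lifetimes with amplitudes of the region-summed traces."""

    taus: dict[str, float]  # key -> picoseconds
    taus_ci68: dict[str, tuple[float, float]]
    channel_taus: dict[str, np.ndarray]
    channel_amplitudes: dict[str, np.ndarray]
    chi2: float
    red_chi2: float
    converged: bool
    n_eval: int


def _weights(n: np.ndarray, m: np.ndarray | None, weighting: str) -> np.ndarray:
    if weighting == "neyman":
        return np.maximum(n, 1.0)
    if weighting == "pearson":
        if m is None:
            return np.maximum(n, 1.0)
        return np.maximum(m, 1e-3)
    raise ValueError(f"unknown weighting {weighting!r}")


def fit_lifetimes(
    decays: Mapping[str, np.ndarray],
    model: ModelSpec,
    references: ReferenceDecay | Mapping[str, ReferenceDecay],
    weighting: str = "pearson",
    n_starts: int = 1,
    compute_ci: bool = True,
    bounds_ps: tuple[float, float] = TAU_BOUNDS_PS,
) -> LifetimeFitResult:
    """Estimate linked lifetimes from region-summed decay traces.

    Minimizes the weighted least-squares objective
    ``sum_i (n_i - m_i)^2 / w_i`` jointly over all channels, with lifetimes
    shared through the model's link keys and channel amplitudes eliminated
    analytically at every step (amplitudes enter linearly for fixed
    lifetimes).  Default weights are iterated Pearson (``w = m`` from a
    Neyman pre-fit), which avoids the downward lifetime bias Neyman weights
    (``w = max(n, 1)``) develop in low-count tail channels; plain Neyman
    remains available via ``weighting="neyman"``.  68 % confidence
    intervals are obtained by profiling the objective to a unit increase.
    """
    names = [n for n in model.channels if n in decays]
    if not names:
        raise FitError("no channel of the model is present in the data")
    refs = (
        {n: references for n in names}
        if isinstance(references, ReferenceDecay)
        else dict(references)
    )
    keys = model.unique_keys()
    resolved = model.resolved_keys()
    inits = model.initial_taus()
    lo, hi = np.log(bounds_ps[0]), np.log(bounds_ps[1])

    traces = {n: np.asarray(decays[n], dtype=float) for n in names}
    base_w = {n: _weights(traces[n], None, weighting) for n in names}

    def channel_fit(x: np.ndarray, name: str):
        taus = np.exp(x)
        tau_ch = np.array([taus[keys.index(k)] for k in resolved[name]])
        kern = build_kernels(refs[name], tau_ch)
        design = kern.phi.T
        w = base_w[name]
        if weighting == "pearson":
            # one reweighting pass with the current model
            amp, *_ = np.linalg.lstsq(
                design / np.sqrt(w)[:, None], traces[name] / np.sqrt(w), rcond=None
            )
            w = _weights(traces[name], design @ amp, weighting)
        sw = np.sqrt(w)
        amp, *_ = np.linalg.lstsq(
            design / sw[:, None], traces[name] / sw, rcond=None
        )
        resid = (traces[name] - design @ amp) / sw
        return amp, resid, tau_ch

    def residuals(x: np.ndarray) -> np.ndarray:
        return np.concatenate([channel_fit(x, n)[1] for n in names])

    x0 = np.log([inits[k] for k in keys])
    starts = [np.clip(x0, lo, hi)]
    rngf = 1.5
    for s in range(1, n_starts):
        fac = rngf ** (s if s % 2 else -s)
        starts.append(np.clip(x0 + np.log(fac), lo, hi))

    best = None
    n_eval = 0
    for xs in starts:
        res = optimize.least_squares(
            residuals,
            xs,
            bounds=(lo, hi),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=500 * (len(keys) + 1),
        )
        n_eval += res.nfev
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None
    converged = best.status > 0
    if not converged:
        warnings.warn("lifetime fit hit the iteration limit; returning best-so-far")
    x_hat = best.x
    at_bound = (np.abs(x_hat - lo) < 1e-6) | (np.abs(x_hat - hi) < 1e-6)
    if at_bound.any():
        bad = [keys[i] for i in np.flatnonzero(at_bound)]
        warnings.warn(f"lifetime(s) {bad} collapsed to a bound")

    chi2 = float(2.0 * best.cost)
    n_data = sum(len(traces[n]) for n in names)
    n_par = len(keys) + sum(len(model.channels[n]) for n in names)
    red_chi2 = chi2 / max(n_data - n_par, 1)

    channel_amp: dict[str, np.ndarray] = {}
    channel_taus: dict[str, np.ndarray] = {}
    for n in names:
        amp, _, tau_ch = channel_fit(x_hat, n)
        channel_amp[n] = amp
        channel_taus[n] = tau_ch

    taus = {k: float(np.exp(x_hat[i])) for i, k in enumerate(keys)}
    cis: dict[str, tuple[float, float]] = {}
    if compute_ci:
        cis = {
            k: _profile_ci(residuals, x_hat, i, chi2, (lo, hi))
            for i, k in enumerate(keys)
        }
    return LifetimeFitResult(
        taus=taus,
        taus_ci68=cis,
        channel_taus=channel_taus,
        channel_amplitudes=channel_amp,
        chi2=chi2,
        red_chi2=red_chi2,
        converged=converged,
        n_eval=n_eval,
    )


def _profile_ci(
    residuals, x_hat: np.ndarray, index: int, chi2_min: float, bounds
) -> tuple[float, float]:
    """68% interval of one log-lifetime by chi-square profiling (delta = 1)."""
    lo, hi = bounds
    free = [i for i in range(len(x_hat)) if i != index]

    def prof(xu: float) -> float:
        if not free:
            r = residuals(np.array([xu]))
            return float(r @ r) * 2.0
        def inner(xf):
            x = x_hat.copy()
            x[index] = xu
            x[free] = xf
            return residuals(x)
        res = optimize.least_squares(
            inner, x_hat[free], bounds=(lo, hi), method="trf",
            xtol=1e-10, ftol=1e-10, max_nfev=200,
        )
        return float(2.0 * res.cost)

    target = chi2_min + 1.0

    def crossing(direction: int) -> float:
        step = 0.005 * direction
        prev = x_hat[index]
        for _ in range(60):
            cand = np.clip(prev + step, lo, hi)
            if prof(cand) >= target or cand in (lo, hi):
                if prof(cand) < target:
                    return float(np.exp(cand))  # bound reached first
                sol = optimize.brentq(
                    lambda xu: prof(xu) - target, min(prev, cand), max(prev, cand),
                    xtol=1e-6,
                )
                return float(np.exp(sol))
            prev = cand
            step *= 1.6
        return float(np.exp(prev))

    return (crossing(-1), crossing(+1))


# ---------------------------------------------------------------------------
# Stage 3: per-pixel amplitudes by multinomial-deviance MLE
# ---------------------------------------------------------------------------

def fit_amplitudes_batch(
    counts: np.ndarray,
    kernels: Kernels,
    signs: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    tol: float = 1e-11,
    max_iter: int = 200,
    chunk: int = 4096,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-pixel amplitude MLE with lifetimes fixed.

    Parameters
    ----------
    counts : (P, T) array
        One decay histogram per pixel.
    kernels : Kernels
        Unit-area basis decays (J components).
    signs : (J,) bool array
        True where a component may carry a negative amplitude (rising
        edge); positive components are bound at zero.

    Returns
    -------
    alpha : (P, J) amplitudes with ``alpha.sum(1) == counts.sum(1)`` exactly
    dev : (P,) multinomial deviance at the optimum
    fitted : (P,) bool, False where the pixel had no photons

    Notes
    -----
    The deviance is convex in the amplitudes for fixed kernels, so the
    projected-Newton iteration used here converges to the unique optimum
    from any feasible start.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be (pixels, time channels)")
    phi = kernels.phi
    J, T = phi.shape
    if counts.shape[1] != T:
        raise ValueError("counts/kernels time-channel mismatch")
    if signs is None:
        signs = np.zeros(J, dtype=bool)
    signs = np.asarray(signs, dtype=bool)

    support = phi.sum(axis=0) > 0
    if (counts[:, ~support] > 0).any():
        raise InfiniteDevianceError(
            "photons observed in time channels where all kernels vanish"
        )

    P = counts.shape[0]
    N = counts.sum(axis=1)
    fitted = N > 0
    alpha = np.zeros((P, J))
    dev = np.zeros(P)

    if J == 1:
        # closed form: the single amplitude is the photon count
        alpha[fitted, 0] = N[fitted]
        for p in np.flatnonzero(fitted):
            dev[p] = deviance(counts[p], N[p] * phi[0])
        return alpha, dev, fitted

    # eliminate one positive component to absorb the sum constraint
    positive = np.flatnonzero(~signs)
    if positive.size == 0:
        raise FitError("at least one component must have positive sign")
    e = int(positive[-1])
    rest = [j for j in range(J) if j != e]
    A = phi[rest] - phi[e]  # (M, T)
    M = len(rest)
    lower_bounded = np.array([not signs[j] for j in rest])

    idx_all = np.flatnonzero(fitted)
    beta_rest = np.empty((P, M))

    for start in range(0, idx_all.size, chunk):
        sel = idx_all[start : start + chunk]
        c = counts[sel]
        if beta0 is not None:
            th = np.tile(np.asarray(beta0, dtype=float)[rest], (sel.size, 1))
        else:
            th = np.full((sel.size, M), 1.0 / J)
        th = _newton_chunk(c, phi[e], A, th, lower_bounded, tol, max_iter)
        beta_rest[sel] = th

    for p in idx_all:
        th = beta_rest[p]
        beta = np.empty(J)
        beta[rest] = th
        beta[e] = 1.0 - th.sum()
        alpha[p] = N[p] * beta
        m = np.clip(alpha[p] @ phi, 0.0, None)
        dev[p] = deviance(counts[p], m)
    return alpha, dev, fitted


def _nll(c: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-pixel negative log-likelihood; +inf when infeasible."""
    out = np.full(c.shape[0], np.inf)
    ok = np.all((p > 0) | (c <= 0), axis=1) & np.all(p >= -1e-14, axis=1)
    if ok.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.where(p[ok] > 0, np.log(np.maximum(p[ok], 1e-300)), 0.0)
        out[ok] = -(c[ok] * lp).sum(axis=1)
    return out


def _newton_chunk(
    c: np.ndarray,
    base: np.ndarray,
    A: np.ndarray,
    th: np.ndarray,
    lower_bounded: np.ndarray,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Projected Newton on theta for one chunk of pixels (all vectorized)."""
    Pn, M = th.shape
    N = c.sum(axis=1)
    active_ix = np.arange(Pn)
    for _ in range(max_iter):
        if active_ix.size == 0:
            break
        t = th[active_ix]
        cc = c[active_ix]
        p = t @ A + base  # (p_act, T)
        f0 = _nll(cc, p)
        # zero-count channels contribute nothing to gradient or Hessian;
        # masking them also guards against underflowing kernel tails
        pc = np.clip(p, 1e-150, None)
        has = cc > 0
        r = np.where(has, cc / pc, 0.0)
        g = -(r @ A.T)  # (p_act, M)
        r2 = np.where(has, cc / (pc * pc), 0.0)
        H = np.einsum("pi,ji,ki->pjk", r2, A, A)
        # freeze positive components at the lower bound pushing outward
        frozen = lower_bounded[None, :] & (t <= 1e-14) & (g > 0)
        g_eff = np.where(frozen, 0.0, g)
        Hm = H.copy()
        for j in range(M):
            row = frozen[:, j]
            if row.any():
                Hm[row, j, :] = 0.0
                Hm[row, :, j] = 0.0
                Hm[row, j, j] = 1.0
        # ridge for numerical safety
        diag = np.einsum("pjj->pj", Hm)
        diag += 1e-12 * np.maximum(diag.max(axis=1, keepdims=True), 1.0)
        try:
            d = np.linalg.solve(Hm, -g_eff[..., None])[..., 0]
        except np.linalg.LinAlgError:
            d = -g_eff / np.maximum(diag, 1e-30)
        d[frozen] = 0.0

        gnorm = np.abs(g_eff).max(axis=1)
        moving = gnorm > tol * np.maximum(N[active_ix], 1.0)
        if not moving.any():
            active_ix = active_ix[moving]
            continue

        # maximum feasible step: theta_j >= 0 (positive comps), beta_e >= 0
        smax = np.full(active_ix.size, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            for j in range(M):
                if lower_bounded[j]:
                    neg = d[:, j] < 0
                    lim = np.where(neg, t[:, j] / np.maximum(-d[:, j], 1e-300), np.inf)
                    smax = np.minimum(smax, np.where(neg, 0.999 * lim, smax))
            de = -d.sum(axis=1)
            be = 1.0 - t.sum(axis=1)
            neg = de < 0
            lim = np.where(neg, be / np.maximum(-de, 1e-300), np.inf)
            smax = np.minimum(smax, np.where(neg, 0.999 * lim, smax))
        s = np.minimum(1.0, smax)

        # backtracking on the (convex) objective
        accepted = np.zeros(active_ix.size, dtype=bool)
        t_new = t.copy()
        for _bt in range(50):
            trial = ~accepted & moving & (s > 1e-16)
            if not trial.any():
                break
            cand = t[trial] + s[trial, None] * d[trial]
            if lower_bounded.any():
                cand[:, lower_bounded] = np.clip(cand[:, lower_bounded], 0.0, None)
            f1 = _nll(c[active_ix[trial]], cand @ A + base)
            good = f1 <= f0[trial] + 1e-12 * np.abs(f0[trial])
            ti = np.flatnonzero(trial)
            t_new[ti[good]] = cand[good]
            accepted[ti[good]] = True
            s[ti[~good]] *= 0.5
        th[active_ix] = t_new
        # drop pixels that stalled or converged
        step = np.abs(t_new - t).max(axis=1)
        keep = moving & accepted & (step > 1e-14)
        active_ix = active_ix[keep]
    return th


def fit_pixel_amplitudes(
    counts: np.ndarray,
    kernels: Kernels,
    signs: np.ndarray | Sequence[bool] | None = None,
    min_photons: float = 1.0,
) -> PixelAmplitudes:
    """Amplitude MLE of a single pixel histogram (lifetimes fixed).

    The estimate minimizes the multinomial deviance subject to the
    amplitudes summing to the pixel photon number, with non-negativity on
    ordinary components and sign freedom on designated rise components.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < min_photons:
        raise FitError(
            f"pixel has {n} photons, below the floor of {min_photons}"
        )
    alpha, dev, fitted = fit_amplitudes_batch(
        counts[None, :], kernels, None if signs is None else np.asarray(signs)
    )
    return PixelAmplitudes(
        alpha=alpha[0], taus=kernels.taus, n_photons=float(n), deviance=float(dev[0])
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class LifetimeMaps:
    """Per-channel parameter maps; NaN outside the fitted foreground."""

    taus: np.ndarray  # (J,) picoseconds used for this channel
    amplitude_fractions: np.ndarray  # (J, H, W) signed a_j
    preexp_fractions: np.ndarray  # (J, H, W) signed p_j
    tau_av: np.ndarray  # (H, W) ps
    tau_mean: np.ndarray  # (H, W) ps
    n_photons: np.ndarray  # (H, W)
    deviance: np.ndarray  # (H, W)


@dataclass
class GlobalFitResult:
    """Everything the three-stage analysis produces."""

    segment_map: SegmentMap
    region_fits: dict[int, LifetimeFitResult]
    maps: dict[str, LifetimeMaps]
    model: ModelSpec


@dataclass
class PipelineConfig:
    model: ModelSpec
    references: ReferenceDecay | Mapping[str, ReferenceDecay]
    threshold: float = 30.0
    connectivity: int = 8
    min_photons_pixel: float = 1.0
    weighting: str = "pearson"
    n_starts: int = 1
    compute_ci: bool = False
    roi_mask: np.ndarray | None = None
    #: skip stage 2 and evaluate per-pixel amplitudes at the lifetimes
    #: declared in the model (for calibration scenes or re-mapping with
    #: lifetimes from a previous, larger fit)
    fix_lifetimes: bool = False


def _fixed_lifetime_result(model: ModelSpec) -> LifetimeFitResult:
    """Stage-2 result built directly from declared lifetimes."""
    resolved = model.resolved_keys()
    taus: dict[str, float] = {}
    channel_taus: dict[str, np.ndarray] = {}
    for name, comps in model.channels.items():
        vals = []
        for key, c in zip(resolved[name], comps):
            if c.tau is None:
                raise FitError(
                    "fix_lifetimes requires every component to declare tau"
                )
            taus.setdefault(key, float(c.tau))
            vals.append(taus[key])
        channel_taus[name] = np.asarray(vals)
    return LifetimeFitResult(
        taus=taus,
        taus_ci68={},
        channel_taus=channel_taus,
        channel_amplitudes={},
        chi2=float("nan"),
        red_chi2=float("nan"),
        converged=True,
        n_eval=0,
    )


def run_pipeline(cube: DecayCube, config: PipelineConfig) -> GlobalFitResult:
    """Segment, fit shared lifetimes per region, then per-pixel amplitudes.

    Returns lifetime maps (amplitude and molecule fractions, average and
    mean lifetime, photon number, deviance) for every channel declared in
    the model, defined on foreground pixels and NaN elsewhere.
    """
    intensity = intensity_image(cube)
    if config.roi_mask is not None:
        seg = SegmentMap(
            np.where(config.roi_mask, 1, 0).astype(int),
            threshold=config.threshold,
            connectivity=config.connectivity,
        )
    else:
        seg = segment(intensity, config.threshold, config.connectivity)

    h, w = cube.shape
    names = [n for n in config.model.channels]
    maps: dict[str, LifetimeMaps] = {}
    sizes = {
        n: len(config.model.channels[n]) for n in names
    }
    store = {
        n: LifetimeMaps(
            taus=np.full(sizes[n], np.nan),
            amplitude_fractions=np.full((sizes[n], h, w), np.nan),
            preexp_fractions=np.full((sizes[n], h, w), np.nan),
            tau_av=np.full((h, w), np.nan),
            tau_mean=np.full((h, w), np.nan),
            n_photons=np.full((h, w), np.nan),
            deviance=np.full((h, w), np.nan),
        )
        for n in names
    }
    refs = config.references
    if isinstance(refs, ReferenceDecay):
        refs = {n: refs for n in names}

    region_fits: dict[int, LifetimeFitResult] = {}
    for label in range(1, seg.n_regions + 1):
        summed = sum_decays(cube, seg, label)
        if config.fix_lifetimes:
            fit = _fixed_lifetime_result(config.model)
            # region-level amplitudes from the summed (high-count) traces
            for n in names:
                kern = build_kernels(refs[n], fit.channel_taus[n])
                alpha_r, _, _ = fit_amplitudes_batch(
                    summed[n][None, :], kern, config.model.signs(n)
                )
                fit.channel_amplitudes[n] = alpha_r[0]
        else:
            fit = fit_lifetimes(
                {n: summed[n] for n in names},
                config.model,
                refs,
                weighting=config.weighting,
                n_starts=config.n_starts,
                compute_ci=config.compute_ci,
            )
        region_fits[label] = fit
        mask = seg.region_mask(label)
        yy, xx = np.nonzero(mask)
        for n in names:
            kern = build_kernels(refs[n], fit.channel_taus[n])
            pix_counts = cube.channel_counts(n)[mask]
            alpha, dev, fitted_mask = fit_amplitudes_batch(
                pix_counts, kern, config.model.signs(n)
            )
            npho = pix_counts.sum(axis=1)
            ok = fitted_mask & (npho >= config.min_photons_pixel)
            lm = store[n]
            lm.taus = fit.channel_taus[n]
            for p in np.flatnonzero(ok):
                a = normalized_amplitudes(alpha[p])
                pe = pre_exponential_fractions(alpha[p], kern.taus)
                lm.amplitude_fractions[:, yy[p], xx[p]] = a
                lm.preexp_fractions[:, yy[p], xx[p]] = pe
                lm.tau_av[yy[p], xx[p]] = average_lifetime(a, kern.taus)
                lm.tau_mean[yy[p], xx[p]] = mean_lifetime(pe, kern.taus)
            lm.n_photons[yy, xx] = npho
            lm.deviance[yy[ok], xx[ok]] = dev[ok]
    for n in names:
        maps[n] = store[n]
    return GlobalFitResult(seg, region_fits, maps, config.model)
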