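"""Dwell-time extraction and exponential-mixture kinetics for smFRET traces.

A surface-immobilized DNA molecule reports factor binding as intervals of
acceptor signal in a two-channel (donor/acceptor) fluorescence trace.
Bound dwell durations are modeled as draws from a one- or two-component
exponential mixture; lifetimes and amplitudes are estimated by maximum
likelihood (closed form for one component, expectation-maximization for
two), with right-censored dwells (trace end / donor bleach) entering the
likelihood through survival terms and left truncation at the camera frame
time handled by a conditional likelihood.  FRET-efficiency distributions
during bound intervals are summarized by Gaussian mixture components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

logger = logging.getLogger("taumap")

#: Relative lifetime separation below which a two-component fit is
#: reported as an effective single exponential.
COLLAPSE_TOL = 1e-3


@dataclass(frozen=True)
class DwellRecord:
    """One bound dwell: duration in seconds, construct label, censor flag.

    ``component`` carries the generating mixture component for synthetic
    dwells (ground truth); it is None for extracted dwells.
    """

    duration: float
    construct: str = ""
    censored: bool = False
    component: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.duration) or self.duration < 0:
            raise ValueError("dwell duration must be finite and >= 0")


@dataclass
class Trace:
    """Two-channel fluorescence trace with optional ground-truth annotations."""

    frame_time: float
    donor: np.ndarray
    acceptor: np.ndarray
    bound_intervals: list[tuple[int, int]] = field(default_factory=list)
    bleach_frame: int | None = None

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor channels must have equal length")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")

    def __len__(self) -> int:
        return len(self.donor)


@dataclass
class ExpMixtureFit:
    """Maximum-likelihood exponential mixture fit."""

    k: int
    lifetimes: tuple[float, ...]      # ascending for k=2
    weights: tuple[float, ...]
    log_likelihood: float
    n: int
    converged: bool
    truncation: float | None = None
    bootstrap_sd: dict[str, float] | None = None

    @property
    def bic(self) -> float:
        n_params = 1 if self.k == 1 else 3
        return -2.0 * self.log_likelihood + n_params * np.log(self.n)


@dataclass
class ModelSelection:
    k: int
    fits: dict[int, ExpMixtureFit]
    delta_bic: float   # BIC(k=1) - BIC(k=2); positive favors k=2


@dataclass
class MedianEstimate:
    median: float
    ci_low: float
    ci_high: float
    bootstrap_sd: float
    n: int


@dataclass
class FretComponentFit:
    n_components: int
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    log_likelihood: float
    converged: bool

    @property
    def bic(self) -> float:
        return float(self._bic)

    _bic: float = 0.0


@dataclass
class ThresholdRule:
    """Dwell segmentation rule: moving-average smoothing + baseline threshold.

    The noise standard deviation is estimated from median absolute
    successive differences of the raw signal (level-structure agnostic).
    The unbound baseline is the mean of the lowest signal cluster: all
    smoothed values within 5 noise sd of the 1st percentile — robust to
    traces that are bound most of the time, where a plain low-quantile
    baseline would land inside the bound population.  The dwell threshold
    is baseline + ``k_sigma`` noise sd.
    """

    window: int = 1          # moving-average window, frames
    k_sigma: float = 4.0


def _robust_noise_sd(signal: np.ndarray) -> float:
    """Noise sd from successive differences: 1.4826 * MAD(diff) / sqrt(2)."""
    if len(signal) < 2:
        return 0.0
    return float(1.4826 * np.median(np.abs(np.diff(signal))) / np.sqrt(2.0))


# ---------------------------------------------------------------------------
# trace processing
# ---------------------------------------------------------------------------

def detect_bleach_step(trace: Trace, rule: ThresholdRule | None = None) -> tuple[int | None, bool]:
    """Locate a single-step donor bleach in the total (donor+acceptor) signal.

    Returns (bleach_frame, is_single_step).  The candidate step is the
    largest frame-to-frame drop of the smoothed total intensity; it
    qualifies as a single bleach step when the signal after the step
    stays near the post-bleach baseline (no re-brightening).
    """
    rule = rule or ThresholdRule()
    total = trace.donor + trace.acceptor
    w = max(1, rule.window)
    sm = np.convolve(total, np.ones(w) / w, mode="same")
    if len(sm) < 3:
        return None, False
    steps = sm[:-1] - sm[1:]
    i = int(np.argmax(steps))
    drop = steps[i]
    post = sm[i + 1:]
    noise = float(np.std(post)) if len(post) > 1 else 0.0
    if drop <= 4 * max(noise, 1e-12):
        return None, False   # no step distinguishable from noise
    single = bool(np.all(post < sm[i] - 0.5 * drop))
    return i + 1, single


def extract_dwells(
    trace: Trace,
    rule: ThresholdRule | None = None,
    construct: str = "",
) -> list[DwellRecord]:
    """Segment bound dwells from the acceptor channel of one trace.

    The acceptor signal is smoothed with a moving average and thresholded
    at the unbound baseline level plus ``k_sigma`` noise standard
    deviations (see :class:`ThresholdRule`).  Contiguous above-threshold
    runs become
    dwells of duration run-length x frame time; a run touching the trace
    end or the bleach frame is right-censored.  An all-flat trace yields
    zero dwells.
    """
    rule = rule or ThresholdRule()
    end = trace.bleach_frame if trace.bleach_frame is not None else len(trace)
    end = min(end, len(trace))
    signal = trace.acceptor[:end]
    if len(signal) == 0:
        return []
    w = max(1, rule.window)
    sm = np.convolve(signal, np.ones(w) / w, mode="same")
    if sm.max() - sm.min() < 1e-12:
        return []  # all-flat trace
    sd_u = _robust_noise_sd(signal) / np.sqrt(w)  # smoothing averages w frames
    anchor = float(np.quantile(sm, 0.01))
    base_vals = sm[sm <= anchor + 5.0 * sd_u]
    baseline = float(base_vals.mean())
    threshold = baseline + rule.k_sigma * sd_u
    above = sm > threshold
    dwells: list[DwellRecord] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            censored = j >= end or (trace.bleach_frame is not None and j >= trace.bleach_frame)
            dwells.append(DwellRecord(
                duration=(j - i) * trace.frame_time,
                construct=construct,
                censored=bool(censored),
            ))
            i = j
        else:
            i += 1
    return dwells


def extract_all_dwells(
    traces: list[Trace],
    rule: ThresholdRule | None = None,
    construct: str = "",
    require_single_bleach: bool = False,
) -> tuple[list[DwellRecord], int]:
    """Extract dwells from many traces; returns (dwells, n_rejected).

    With ``require_single_bleach`` traces whose donor channel lacks a
    detectable single bleach step are rejected and counted.
    """
    dwells: list[DwellRecord] = []
    n_rejected = 0
    for t in traces:
        if require_single_bleach:
            _, single = detect_bleach_step(t, rule)
            if not single:
                n_rejected += 1
                continue
        dwells.extend(extract_dwells(t, rule, construct))
    if n_rejected:
        logger.info("extract_all_dwells: rejected %d traces without a single bleach step",
                    n_rejected)
    return dwells, n_rejected


# ---------------------------------------------------------------------------
# exponential mixture MLE
# ---------------------------------------------------------------------------

def _prepare_durations(
    dwells: list[DwellRecord], truncation: float | None
) -> tuple[np.ndarray, np.ndarray]:
    d = np.array([r.duration for r in dwells], dtype=float)
    c = np.array([r.censored for r in dwells], dtype=bool)
    if truncation is not None:
        if np.any(d < truncation - 1e-12):
            raise ValueError("dwell shorter than the stated truncation time")
        d = d - truncation  # memorylessness: conditional law of T - t0 | T >= t0
        d = np.maximum(d, 0.0)
    return d, c


def _exp_loglik_k1(x: np.ndarray, c: np.ndarray, tau: float) -> float:
    # uncensored: log f = -log tau - x/tau ; censored: log S = -x/tau
    return float(-np.sum(~c) * np.log(tau) - np.sum(x) / tau)


def _em_k2(
    x: np.ndarray,
    c: np.ndarray,
    tau_init: tuple[float, float],
    w_init: tuple[float, float],
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """EM for a two-component exponential mixture with right censoring.

    E-step responsibilities use the density for uncensored dwells and the
    survival function for censored ones; the M-step imputes a censored
    dwell's residual lifetime as the current component mean (standard
    complete-data EM for censored exponentials).  The observed-data
    log-likelihood is non-decreasing per iteration (asserted).
    """
    tau = np.array(tau_init, dtype=float)
    w = np.array(w_init, dtype=float)
    n = len(x)
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        # E-step
        log_dens = np.empty((n, 2))
        for j in range(2):
            log_dens[:, j] = -x / tau[j]
            log_dens[~c, j] -= np.log(tau[j])
        log_num = log_dens + np.log(w)
        m = log_num.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_num - m).sum(axis=1))
        r = np.exp(log_num - log_norm[:, None])
        ll = float(np.sum(log_norm))
        assert ll >= prev_ll - 1e-8 * max(1.0, abs(prev_ll)), "EM log-likelihood decreased"
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            prev_ll = ll
            converged = True
            break
        prev_ll = ll
        # M-step
        nk = r.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        for j in range(2):
            complete = x + np.where(c, tau[j], 0.0)  # E[T | T > x] = x + tau
            tau[j] = float(np.sum(r[:, j] * complete) / nk[j])
            tau[j] = max(tau[j], 1e-12)
    order = np.argsort(tau)
    return tau[order], w[order], prev_ll, converged


def fit_exp_mixture(
    dwells: list[DwellRecord],
    k: int,
    truncation: float | None = None,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-10,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> ExpMixtureFit:
    """Maximum-likelihood fit of a k-component exponential mixture to dwells.

    ``k=1`` is closed form: the lifetime equals the total observed time
    divided by the number of uncensored dwells (the truncation-corrected
    mean when ``truncation`` is set, by memorylessness).  ``k=2`` runs EM
    from ``n_restarts`` deterministic quantile-based initializations and
    keeps the best log-likelihood.  Censored dwells contribute survival
    terms.  Weights refer to the observed (post-truncation) dwell
    population.  A two-component fit whose lifetimes collapse within
    ``COLLAPSE_TOL`` relative separation is reported as effective k=1.
    Optional percentile bootstrap gives per-parameter standard deviations.
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    n_unc = sum(not r.censored for r in dwells)
    if n_unc < 10:
        raise ValueError(f"need >= 10 uncensored dwells, got {n_unc}")
    x, c = _prepare_durations(dwells, truncation)
    n = len(x)

    if k == 1:
        tau = float(np.sum(x) / n_unc)
        tau = max(tau, 1e-12)
        ll = _exp_loglik_k1(x, c, tau)
        fit = ExpMixtureFit(
            k=1, lifetimes=(tau,), weights=(1.0,), log_likelihood=ll,
            n=n, converged=True, truncation=truncation,
        )
    else:
        xs = x[~c] if np.any(~c) else x
        best: tuple[np.ndarray, np.ndarray, float, bool] | None = None
        for r_i in range(n_restarts):
            ql = 0.05 + 0.4 * r_i / max(1, n_restarts - 1)   # 0.05 .. 0.45
            qh = 0.55 + 0.4 * r_i / max(1, n_restarts - 1)   # 0.55 .. 0.95
            t1 = max(float(np.quantile(xs, ql)) / np.log(2.0), 1e-6)
            t2 = max(float(np.quantile(xs, qh)) / np.log(2.0), t1 * 1.5)
            res = _em_k2(x, c, (t1, t2), (0.5, 0.5), max_iter, tol)
            if best is None or res[2] > best[2]:
                best = res
        tau, w, ll, converged = best
        if not converged:
            logger.warning("fit_exp_mixture: EM did not converge; best-so-far reported")
        if abs(tau[1] - tau[0]) / tau[1] < COLLAPSE_TOL:
            logger.info("fit_exp_mixture: components collapsed; effective k=1")
            return fit_exp_mixture(
                dwells, k=1, truncation=truncation,
                n_bootstrap=n_bootstrap, seed=seed,
            )
        fit = ExpMixtureFit(
            k=2, lifetimes=(float(tau[0]), float(tau[1])),
            weights=(float(w[0]), float(w[1])), log_likelihood=ll,
            n=n, converged=converged, truncation=truncation,
        )

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        samples: dict[str, list[float]] = {}
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(dwells), size=len(dwells))
            resampled = [dwells[i] for i in idx]
            if sum(not r.censored for r in resampled) < 10:
                continue
            try:
                b = fit_exp_mixture(
                    resampled, k=fit.k, truncation=truncation,
                    n_restarts=3, max_iter=max_iter, tol=tol,
                )
            except ValueError:
                continue
            if b.k != fit.k:
                continue
            for j, t in enumerate(b.lifetimes):
                samples.setdefault(f"lifetime_{j}", []).append(t)
            for j, wj in enumerate(b.weights):
                samples.setdefault(f"weight_{j}", []).append(wj)
        fit.bootstrap_sd = {
            key: float(np.std(vals)) for key, vals in samples.items() if len(vals) > 1
        }
    return fit


def model_select(
    dwells: list[DwellRecord],
    truncation: float | None = None,
) -> ModelSelection:
    """Choose between single- and double-exponential fits by BIC."""
    fit1 = fit_exp_mixture(dwells, k=1, truncation=truncation)
    fit2 = fit_exp_mixture(dwells, k=2, truncation=truncation)
    if fit2.k == 1:      # collapsed: only the single-exponential model remains
        return ModelSelection(k=1, fits={1: fit1, 2: fit2}, delta_bic=0.0)
    delta = fit1.bic - fit2.bic
    return ModelSelection(k=2 if delta > 0 else 1, fits={1: fit1, 2: fit2},
                          delta_bic=float(delta))


def median_lifetime(
    dwells: list[DwellRecord],
    n_bootstrap: int = 1000,
    seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> MedianEstimate:
    """Sample median of uncensored dwells with a percentile bootstrap interval."""
    durations = np.array([r.duration for r in dwells if not r.censored])
    if len(durations) == 0:
        raise ValueError("median_lifetime needs at least one uncensored dwell")
    med = float(np.median(durations))
    rng = np.random.default_rng(seed)
    n = len(durations)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):  # loop keeps memory O(n) for large samples
        boots[b] = np.median(durations[rng.integers(0, n, size=n)])
    lo, hi = np.percentile(boots, ci)
    return MedianEstimate(
        median=med, ci_low=float(lo), ci_high=float(hi),
        bootstrap_sd=float(np.std(boots)), n=len(durations),
    )


# ---------------------------------------------------------------------------
# FRET efficiency
# ---------------------------------------------------------------------------

def compute_fret(
    donor: np.ndarray,
    acceptor: np.ndarray,
    bg_donor: float = 0.0,
    bg_acceptor: float = 0.0,
    crosstalk: float = 0.0,
    gamma: float = 1.0,
) -> np.ndarray:
    """Per-frame FRET efficiency with background/crosstalk/gamma corrections.

    E = (A - bg_A - x (D - bg_D)) / (gamma (D - bg_D) + (A - bg_A - x (D - bg_D)))

    With the neutral defaults this reduces to A / (A + D).  Frames with
    zero corrected total intensity get a NaN sentinel.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError("channels must have equal length")
    d = donor - bg_donor
    a = acceptor - bg_acceptor - crosstalk * d
    denom = gamma * d + a
    with np.errstate(divide="ignore", invalid="ignore"):
        e = a / denom
    return np.where(denom == 0.0, np.nan, e)


def fit_gaussian_components(
    efficiencies: np.ndarray,
    n_components: int,
    seed: int = 0,
    n_init: int = 5,
) -> FretComponentFit:
    """ML Gaussian mixture fit to a FRET-efficiency distribution.

    Values outside [0, 1] are clipped with a warning; NaNs are dropped.
    Components are reported sorted by mean.
    """
    e = np.asarray(efficiencies, dtype=float)
    e = e[np.isfinite(e)]
    if len(e) < 20:
        raise ValueError("need at least 20 efficiency values")
    if np.any(e < 0.0) or np.any(e > 1.0):
        warnings.warn("FRET efficiencies outside [0, 1] were clipped", stacklevel=2)
        e = np.clip(e, 0.0, 1.0)
    gm = GaussianMixture(
        n_components=n_components, covariance_type="full",
        n_init=n_init, random_state=seed,
    )
    gm.fit(e.reshape(-1, 1))
    if not gm.converged_:
        logger.warning("fit_gaussian_components: EM did not converge")
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    fit = FretComponentFit(
        n_components=n_components,
        means=tuple(float(m) for m in means[order]),
        sds=tuple(float(s) for s in sds[order]),
        weights=tuple(float(w) for w in weights[order]),
        log_likelihood=float(gm.score(e.reshape(-1, 1)) * len(e)),
        converged=bool(gm.converged_),
    )
    fit._bic = float(gm.bic(e.reshape(-1, 1)))
    return fit
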