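"""Mixture composition from classifier scores.

Scoring a mixed sample with a binary classifier yields a bimodal histogram
of positive-class probabilities.  The naive estimate — the fraction of
events above 0.5 — is biased whenever the two peaks drift away from 0 and 1
(e.g. under train/test voltage mismatch).  The chain implemented here:

1. fit a two-component Gaussian mixture to the scores (EM);
2. place the decision boundary at the intersection of the two weighted
   component densities (or, alternatively, at the minimum of the mixture
   density between the means);
3. recompute the event-class ratio as the fraction of scores beyond the
   boundary (or as the high-score component weight);
4. convert the *event* ratio into a *molecular* ratio by weighting with
   the inverse per-class capture rates measured on pure reference runs:
   ``p = (r/lam_pos) / (r/lam_pos + (1-r)/lam_neg)``.

Step 4 undoes the capture bias: a class captured twice as often contributes
twice as many events per molecule, so its event share overstates its molar
share.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = [
    "BimodalFit",
    "MixtureEstimate",
    "RateEstimate",
    "score_histogram",
    "fit_two_gaussians",
    "find_boundary",
    "corrected_event_ratio",
    "frequency_correction",
    "estimate_capture_rate",
    "estimate_mixture",
    "write_mixture_json",
    "write_histogram_tsv",
    "read_histogram_tsv",
]


@dataclass
class BimodalFit:
    """Two-component Gaussian mixture on the score axis (mu1 < mu2)."""

    w1: float
    w2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    converged: bool
    log_likelihood: float
    unimodal: bool = False  # set when one component collapses (weight < 0.01)

    def pdf(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.w1 * norm.pdf(x, self.mu1, self.sigma1) + self.w2 * norm.pdf(
            x, self.mu2, self.sigma2
        )


def score_histogram(scores: Sequence[float], n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of scores on uniform bins over [0, 1]: (edges, counts)."""
    s = np.asarray(scores, dtype=float)
    if s.size and (s.min() < 0 or s.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    counts, edges = np.histogram(s, bins=n_bins, range=(0.0, 1.0))
    return edges, counts


def fit_two_gaussians(
    scores: Sequence[float],
    *,
    min_n: int = 50,
    max_iter: int = 500,
    tol: float = 1e-8,
    sigma_floor: float = 0.02,
) -> BimodalFit:
    """EM fit of a two-Gaussian mixture to raw scores.

    Initialization: means 0.25/0.75, equal weights, sd 0.1.  Components are
    relabeled so mu1 < mu2.  If a component's weight collapses below 0.01
    the fit is flagged ``unimodal`` and downstream boundary optimization
    falls back to 0.5.

    ``sigma_floor`` regularizes the classic EM singularity: confident
    classifiers emit many *exactly* identical scores (0 or 1), and an
    unfloored component collapses onto that point mass instead of covering
    its peak.  The default keeps components no narrower than roughly half a
    histogram bin, the finest structure the score-histogram method resolves.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} scores to fit (got {x.size})")
    mu = np.array([0.25, 0.75])
    sigma = np.array([0.1, 0.1])
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        dens = w[None, :] * norm.pdf(x[:, None], mu[None, :], sigma[None, :])
        total = dens.sum(axis=1)
        total = np.maximum(total, 1e-300)
        resp = dens / total[:, None]
        ll = float(np.log(total).sum())
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.maximum(np.sqrt(var), sigma_floor)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    order = np.argsort(mu)
    w, mu, sigma = w[order], mu[order], sigma[order]
    return BimodalFit(
        w1=float(w[0]),
        w2=float(w[1]),
        mu1=float(mu[0]),
        mu2=float(mu[1]),
        sigma1=float(sigma[0]),
        sigma2=float(sigma[1]),
        converged=converged,
        log_likelihood=float(ll),
        unimodal=bool(min(w) < 0.01),
    )


def _density_minimum(fit: BimodalFit) -> float:
    res = minimize_scalar(
        lambda x: fit.pdf(x), bounds=(fit.mu1, fit.mu2), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def find_boundary(fit: BimodalFit, rule: str = "intersection", spike_sigma: float = 0.01) -> float:
    """Optimized decision boundary between the two score peaks.

    ``intersection`` (default): the x in (mu1, mu2) where the weighted
    component densities are equal — a quadratic in x, solved in closed
    form.  ``density_min``: the minimum of the mixture density between the
    means.  If the fit is degenerate (unimodal flag) the boundary falls
    back to 0.5; if the intersection has no root between the means the
    density-minimum rule is used with a warning.  The result is clipped to
    [0, 1].

    A component narrower than ``spike_sigma`` means EM collapsed onto a
    point mass of identical scores (confident classifiers emit exact 0/1
    probabilities); the crossing with such a spike hugs the peak instead of
    the valley, so the density-minimum rule is used instead, with a warning.
    """
    if rule not in ("intersection", "density_min"):
        raise ValueError(f"unknown boundary rule {rule!r}")
    if fit.unimodal:
        return 0.5
    if rule == "density_min":
        return float(np.clip(_density_minimum(fit), 0.0, 1.0))
    if min(fit.sigma1, fit.sigma2) < spike_sigma:
        warnings.warn(
            "a mixture component collapsed to spike width; using the "
            "density-minimum boundary instead of the intersection",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.clip(_density_minimum(fit), 0.0, 1.0))

    s1sq, s2sq = fit.sigma1**2, fit.sigma2**2
    k = 2.0 * s1sq * s2sq * np.log((fit.w1 * fit.sigma2) / (fit.w2 * fit.sigma1))
    a = s2sq - s1sq
    b = -2.0 * (fit.mu1 * s2sq - fit.mu2 * s1sq)
    c = s2sq * fit.mu1**2 - s1sq * fit.mu2**2 - k
    if abs(a) < 1e-14:  # equal variances: linear equation
        roots = [-c / b] if b != 0 else []
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            roots = []
        else:
            sq = np.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if fit.mu1 < r < fit.mu2]
    if not inside:
        warnings.warn(
            "no density intersection between the component means; "
            "falling back to the density-minimum rule",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.clip(_density_minimum(fit), 0.0, 1.0))
    # if both quadratic roots fall between the means, take the one in the
    # density valley (lower mixture density)
    best = min(inside, key=lambda r: float(fit.pdf(r)))
    return float(np.clip(best, 0.0, 1.0))


def corrected_event_ratio(
    scores: Sequence[float],
    fit: BimodalFit,
    boundary: float,
    rule: str = "exceedance",
) -> float:
    """Event-class ratio after boundary optimization.

    ``exceedance``: fraction of scores above the boundary (default —
    operates on the actual events, robust to tail misfit).
    ``peak_area``: weight of the high-score mixture component.
    """
    if rule == "exceedance":
        s = np.asarray(scores, dtype=float)
        return float(np.mean(s > boundary))
    if rule == "peak_area":
        return float(fit.w2)
    raise ValueError(f"unknown ratio rule {rule!r}")


def frequency_correction(event_ratio: float, rate_pos: float, rate_neg: float) -> float:
    """Convert an event-count ratio into a molecular fraction.

    Each positive-class molecule produces events at ``rate_pos`` (per unit
    concentration), so inverse-rate weighting recovers the molar share:
    ``p = (r/rate_pos) / (r/rate_pos + (1-r)/rate_neg)``.  Monotone in
    ``r``; equals ``r`` when the rates are equal; preserves 0 and 1.
    """
    if rate_pos <= 0 or rate_neg <= 0:
        raise ValueError("capture rates must be positive")
    r = float(event_ratio)
    if not 0.0 <= r <= 1.0:
        raise ValueError("event ratio must lie in [0, 1]")
    a = r / rate_pos
    b = (1.0 - r) / rate_neg
    if a + b == 0:
        return 0.0
    return a / (a + b)


@dataclass
class RateEstimate:
    """Capture rate with Poisson standard error (rule-of-three bound at 0 counts)."""

    rate: float  # events / s
    se: float
    n_events: int
    duration_s: float
    upper95: float | None = None  # only for zero counts


def estimate_capture_rate(events, total_duration_s: float) -> RateEstimate:
    """count / duration with SE = sqrt(count)/duration.

    ``events`` may be a count or a sequence of events.  Zero events yield
    rate 0 with the rule-of-three 95% upper bound 3/T.
    """
    if total_duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(events) if np.isscalar(events) else len(events)
    if n == 0:
        return RateEstimate(0.0, 0.0, 0, total_duration_s, upper95=3.0 / total_duration_s)
    return RateEstimate(n / total_duration_s, np.sqrt(n) / total_duration_s, n, total_duration_s)


@dataclass
class MixtureEstimate:
    """All stages of the mixture quantification chain."""

    raw_ratio_at_half: float
    boundary: float
    corrected_event_ratio: float
    capture_rate_pos: float
    capture_rate_neg: float
    molecular_ratio: float
    boundary_rule: str
    ratio_rule: str
    fit: BimodalFit | None = None
    n_events: int = 0
    scores: np.ndarray | None = None  # retained for histogram export; not serialized


def estimate_mixture(
    scores: Sequence[float],
    rate_pos: float,
    rate_neg: float,
    *,
    boundary_rule: str = "intersection",
    ratio_rule: str = "exceedance",
    min_n: int = 50,
) -> MixtureEstimate:
    """Run the full score-based composition chain on mixed-sample scores."""
    s = np.asarray(scores, dtype=float)
    raw = float(np.mean(s > 0.5))
    fit = fit_two_gaussians(s, min_n=min_n)
    boundary = find_boundary(fit, rule=boundary_rule)
    r = corrected_event_ratio(s, fit, boundary, rule=ratio_rule)
    p = frequency_correction(r, rate_pos, rate_neg)
    return MixtureEstimate(
        raw_ratio_at_half=raw,
        boundary=boundary,
        corrected_event_ratio=r,
        capture_rate_pos=float(rate_pos),
        capture_rate_neg=float(rate_neg),
        molecular_ratio=p,
        boundary_rule=boundary_rule,
        ratio_rule=ratio_rule,
        fit=fit,
        n_events=int(s.size),
        scores=s,
    )


def write_histogram_tsv(
    edges: np.ndarray, counts: np.ndarray, path: str | Path
) -> Path:
    """Score histogram as TSV: bin_left, bin_right, count."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("bin_left\tbin_right\tcount\n")
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            fh.write(f"{lo:.6g}\t{hi:.6g}\t{int(c)}\n")
    return path


def read_histogram_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    data = np.atleast_2d(data)
    edges = np.concatenate([data[:, 0], data[-1:, 1]])
    return edges, data[:, 2].astype(int)


def write_mixture_json(estimate: MixtureEstimate, path: str | Path, extra: dict | None = None) -> Path:
    path = Path(path)
    payload = asdict(estimate)
    payload.pop("scores", None)
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=1, default=float))
    return path
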