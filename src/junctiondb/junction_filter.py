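"""Read-count thresholding and replicate-consistency filtering.

A two-component Gaussian mixture fitted to log2(count+1)-transformed
minimum-replicate skipped-junction counts separates lowly from highly
expressed junctions; the threshold theta is the smallest integer count
whose posterior probability of belonging to the high component reaches
the requested cutoff (default 0.95). Events are then kept iff their
min-replicate SJC passes theta and their replicate-consistency p-value
does not flag them as significantly differential (default p <= 0.01
excluded; missing p passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .rmats_io import ReplicateCounts, SpliceEvent, min_skipped_count

__all__ = [
    "CountThreshold",
    "MixtureConvergenceError",
    "fit_count_mixture",
    "manual_threshold",
    "posterior_high",
    "filter_events",
    "RejectedEvent",
    "REASON_LOW_COUNT",
    "REASON_INCONSISTENT",
]

FIT_SCALE = "log2(count+1)"
REASON_LOW_COUNT = "low_count"
REASON_INCONSISTENT = "inconsistent"

MIN_FIT_VALUES = 50
_EM_TOL = 1e-6
_EM_MAX_ITER = 1000


@dataclass(frozen=True)
class CountThreshold:
    theta: int
    component_means: tuple[float, float]  # (low, high), log2(count+1) scale
    component_sds: tuple[float, float]
    component_weights: tuple[float, float]
    posterior_cutoff: float = 0.95
    n_events_fit: int = 0
    degenerate: bool = False
    source: str = "fitted"  # "fitted" | "manual"
    scale: str = FIT_SCALE

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if self.source == "fitted" and not self.degenerate:
            if abs(sum(self.component_weights) - 1.0) > 1e-9:
                raise ValueError("component weights must sum to 1")
            if any(s <= 0 for s in self.component_sds):
                raise ValueError("component sds must be positive")

    def report(self) -> str:
        """Flat key-value text block describing the threshold."""
        lines = [
            f"theta\t{self.theta}",
            f"source\t{self.source}",
            f"scale\t{self.scale}",
            f"posterior_cutoff\t{self.posterior_cutoff}",
            f"mean_low\t{self.component_means[0]:.6g}",
            f"mean_high\t{self.component_means[1]:.6g}",
            f"sd_low\t{self.component_sds[0]:.6g}",
            f"sd_high\t{self.component_sds[1]:.6g}",
            f"weight_low\t{self.component_weights[0]:.6g}",
            f"weight_high\t{self.component_weights[1]:.6g}",
            f"n_events_fit\t{self.n_events_fit}",
            f"degenerate\t{self.degenerate}",
        ]
        return "\n".join(lines) + "\n"


class MixtureConvergenceError(RuntimeError):
    """EM failed to converge; carries the partial fit."""

    def __init__(self, message: str, partial: Optional[CountThreshold] = None):
        super().__init__(message)
        self.partial = partial


def manual_threshold(theta: int, posterior_cutoff: float = 0.95) -> CountThreshold:
    """A user-supplied threshold that bypasses mixture fitting entirely."""
    return CountThreshold(
        theta=int(theta),
        component_means=(float("nan"), float("nan")),
        component_sds=(float("nan"), float("nan")),
        component_weights=(float("nan"), float("nan")),
        posterior_cutoff=posterior_cutoff,
        n_events_fit=0,
        degenerate=False,
        source="manual",
    )


def posterior_high(
    count: float,
    means: Sequence[float],
    sds: Sequence[float],
    weights: Sequence[float],
) -> float:
    """Posterior probability that log2(count+1) came from the high component.

    ``means``/``sds``/``weights`` are ordered (low, high) on the transformed
    scale.
    """
    y = np.log2(count + 1.0)
    d_low = weights[0] * norm.pdf(y, means[0], sds[0])
    d_high = weights[1] * norm.pdf(y, means[1], sds[1])
    total = d_low + d_high
    if total == 0.0:
        # far in a tail where both densities underflow: assign by proximity
        return 1.0 if abs(y - means[1]) / sds[1] < abs(y - means[0]) / sds[0] else 0.0
    return float(d_high / total)


def scan_theta(
    means: Sequence[float],
    sds: Sequence[float],
    weights: Sequence[float],
    posterior_cutoff: float,
    max_count: int,
) -> Optional[int]:
    """Smallest integer count with high-component posterior >= cutoff."""
    for c in range(0, max_count + 1):
        if posterior_high(c, means, sds, weights) >= posterior_cutoff:
            return c
    return None


def fit_count_mixture(
    min_sjc_values: Iterable[int],
    posterior_cutoff: float = 0.95,
    seed: int = 0,
) -> CountThreshold:
    """Fit the two-component mixture and derive the count threshold.

    Initialization is a deterministic tertile split (lower/upper third
    means and variances), so identical inputs give identical fits
    regardless of ``seed``; the seed only guards sklearn internals.
    """
    values = np.asarray(list(min_sjc_values), dtype=float)
    if values.size < MIN_FIT_VALUES:
        raise ValueError(
            f"need at least {MIN_FIT_VALUES} count values to fit the mixture "
            f"(got {values.size}); supply a manual threshold instead"
        )
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    if not (0.0 < posterior_cutoff < 1.0):
        raise ValueError("posterior_cutoff must be in (0, 1)")

    y = np.log2(values + 1.0)
    if np.ptp(y) < 1e-12:
        return CountThreshold(
            theta=0,
            component_means=(float(y[0]), float(y[0])),
            component_sds=(0.0, 0.0),
            component_weights=(0.5, 0.5),
            posterior_cutoff=posterior_cutoff,
            n_events_fit=int(values.size),
            degenerate=True,
        )

    y_sorted = np.sort(y)
    third = max(1, y_sorted.size // 3)
    lo, hi = y_sorted[:third], y_sorted[-third:]
    means_init = np.array([[lo.mean()], [hi.mean()]])
    var_floor = 1e-4
    precisions_init = np.array(
        [[[1.0 / max(lo.var(), var_floor)]], [[1.0 / max(hi.var(), var_floor)]]]
    )
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=_EM_TOL,
        max_iter=_EM_MAX_ITER,
        n_init=1,
        weights_init=np.array([0.5, 0.5]),
        means_init=means_init,
        precisions_init=precisions_init,
        reg_covar=1e-8,
        random_state=seed,
    )
    gm.fit(y.reshape(-1, 1))

    order = np.argsort(gm.means_.ravel())
    means = tuple(float(m) for m in gm.means_.ravel()[order])
    sds = tuple(float(np.sqrt(gm.covariances_.ravel()[i])) for i in order)
    weights_arr = gm.weights_.ravel()[order]
    weights = tuple(float(w / weights_arr.sum()) for w in weights_arr)

    degenerate = abs(means[1] - means[0]) < 1e-6 or min(sds) <= 0
    partial = CountThreshold(
        theta=0,
        component_means=means,
        component_sds=sds,
        component_weights=weights,
        posterior_cutoff=posterior_cutoff,
        n_events_fit=int(values.size),
        degenerate=True,
    )
    if not gm.converged_:
        raise MixtureConvergenceError(
            f"EM did not converge within {_EM_MAX_ITER} iterations", partial=partial
        )
    if degenerate:
        return partial

    max_scan = int(values.max()) * 4 + 1000
    theta = scan_theta(means, sds, weights, posterior_cutoff, max_scan)
    if theta is None:
        return partial
    return replace(partial, theta=theta, degenerate=False)


@dataclass(frozen=True)
class RejectedEvent:
    event: SpliceEvent
    counts: ReplicateCounts
    reason: str


def filter_events(
    events: Sequence[tuple[SpliceEvent, ReplicateCounts]],
    threshold: CountThreshold,
    p_cutoff: float = 0.01,
) -> tuple[list[tuple[SpliceEvent, ReplicateCounts]], list[RejectedEvent]]:
    """Partition events into kept vs rejected-with-reason.

    Keep iff min-replicate SJC >= theta AND (p missing OR p > p_cutoff).
    The low-count test is applied first, so an event failing both carries
    the ``low_count`` reason.
    """
    if not (0.0 < p_cutoff <= 1.0):
        raise ValueError("p_cutoff must be in (0, 1]")
    kept: list[tuple[SpliceEvent, ReplicateCounts]] = []
    rejected: list[RejectedEvent] = []
    for event, counts in events:
        if min_skipped_count(counts) < threshold.theta:
            rejected.append(RejectedEvent(event, counts, REASON_LOW_COUNT))
        elif counts.p_value is not None and counts.p_value <= p_cutoff:
            rejected.append(RejectedEvent(event, counts, REASON_INCONSISTENT))
        else:
            kept.append((event, counts))
    return kept, rejected
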