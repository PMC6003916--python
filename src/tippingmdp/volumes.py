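"""Parameter-space volume of the eight paradigm categories.

Sampling the unit hypercube of (delta, rho, gamma, r_l/r_h, r_min/r_h)
uniformly — by a regular grid including the endpoints, or by Monte Carlo —
and classifying *both* the risky and the cautious policy at every point
yields the fraction of parameter space occupied by each of the eight
(optimal, sustainable, safe) combinations.

Each policy carries half the weight of a point, so the total mass over the
eight categories is one.  Under this weighting the four safe categories
hold exactly the cautious-policy mass and the four unsafe ones the
risky-policy mass, and the safe-and-sustainable ("safe and just") mass has
the closed form 0.5 * P(r_l >= r_min) = 1/4 under uniform sampling — a
sharp calibration point for the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .paradigms import ALL_LABELS, ParadigmLabel, classify_many

__all__ = ["SamplingSpec", "VolumeReport", "category_volumes", "rank_categories"]

_N_PARAMS = 5


@dataclass(frozen=True)
class SamplingSpec:
    """How to sample the unit parameter hypercube.

    mode : "grid" (n points per axis, endpoints included) or "monte_carlo"
        (n uniform draws in total; seed mandatory).
    """

    mode: str
    n: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("grid", "monte_carlo"):
            raise ValueError(f"mode must be 'grid' or 'monte_carlo', got {self.mode!r}")
        if self.mode == "grid" and self.n < 2:
            raise ValueError("grid mode needs n >= 2 points per axis")
        if self.mode == "monte_carlo":
            if self.n < 1:
                raise ValueError("monte_carlo mode needs n >= 1 draws")
            if self.seed is None:
                raise ValueError("monte_carlo mode requires a seed")


@dataclass(frozen=True)
class VolumeReport:
    """Estimated parameter-space fraction per paradigm category.

    ``fractions`` maps each of the eight labels to its mass (summing to one);
    ``standard_error`` carries per-category Monte-Carlo standard errors
    (zeros in grid mode, where the estimate is deterministic).
    """

    fractions: dict[ParadigmLabel, float]
    n_points: int
    spec: SamplingSpec
    standard_error: dict[ParadigmLabel, float] = field(default_factory=dict)

    def fraction(self, code: str) -> float:
        return self.fractions[ParadigmLabel.from_code(code)]

    def to_dict(self) -> dict:
        return {
            "fractions": {lab.code: self.fractions[lab] for lab in ALL_LABELS},
            "standard_error": {lab.code: self.standard_error.get(lab, 0.0)
                               for lab in ALL_LABELS},
            "n_points": self.n_points,
            "spec": {"mode": self.spec.mode, "n": self.spec.n,
                     "seed": self.spec.seed},
        }


def _label_counts(delta, rho, gamma, r_l, r_min) -> np.ndarray:
    """Per-category point counts; each point counted once per policy."""
    labels = classify_many(delta, rho, gamma, r_l, r_min)
    counts = np.zeros(8, dtype=np.int64)
    for policy in ("risky", "cautious"):
        opt, sus, safe = labels[policy]
        idx = opt.astype(np.int64) * 4 + sus.astype(np.int64) * 2 + safe.astype(np.int64)
        counts += np.bincount(idx.ravel(), minlength=8)
    return counts


def category_volumes(spec: SamplingSpec) -> VolumeReport:
    """Estimate the volume fraction of each paradigm category.

    Every sampled 5-tuple (with r_h fixed to 1 so the sampled rewards are
    the ratios r_l/r_h and r_min/r_h) is classified under both policies;
    each policy contributes weight 1/2 per point.  Grid mode iterates the
    first axis in chunks so memory stays modest even at high resolution.
    """
    counts = np.zeros(8, dtype=np.int64)
    if spec.mode == "grid":
        axis = np.linspace(0.0, 1.0, spec.n)
        rho, gamma, r_l, r_min = np.meshgrid(axis, axis, axis, axis,
                                             indexing="ij", sparse=True)
        for d in axis:
            counts += _label_counts(d, rho, gamma, r_l, r_min)
        n_points = spec.n ** _N_PARAMS
        se = {lab: 0.0 for lab in ALL_LABELS}
    else:
        rng = np.random.default_rng(spec.seed)
        n_points = spec.n
        chunk = 1_000_000
        for start in range(0, n_points, chunk):
            m = min(chunk, n_points - start)
            u = rng.random((_N_PARAMS, m))
            counts += _label_counts(*u)
        se = None

    fractions_arr = counts / (2.0 * n_points)
    fractions = {lab: float(fractions_arr[lab.index]) for lab in ALL_LABELS}
    if se is None:
        # per-point contribution to a category is 0 or 1/2, so
        # Var = E[X^2] - p^2 = p/2 - p^2
        se = {lab: float(np.sqrt(max(p / 2.0 - p * p, 0.0) / n_points))
              for lab, p in fractions.items()}
    return VolumeReport(fractions=fractions, n_points=n_points, spec=spec,
                        standard_error=se)


def rank_categories(report: VolumeReport) -> list[tuple[ParadigmLabel, float]]:
    """Categories sorted by descending mass; ties broken by label code."""
    return sorted(report.fractions.items(),
                  key=lambda item: (-item[1], item[0].code))
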