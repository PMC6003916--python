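"""Real-world tipping-element case studies: climate, fisheries, farming.

Transition probabilities per yearly time step are obtained from typical
residence timescales through the geometric-distribution relation
``<N> = (1 - p)/p``, i.e. ``p = 1/(<N> + 1)``: a system that stays in a
state for an average of 50 years transitions with probability ~0.02 per
year.  With delta and rho pinned down (or bracketed) this way, the
remaining parameters (gamma, r_l/r_h, r_min/r_h) are uncertain; sampling
them uniformly from a plausibility box and classifying both policies at
each draw gives the probability of the system falling in each paradigm
regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .paradigms import ALL_LABELS, ParadigmLabel, classify_many

__all__ = [
    "timescale_to_probability",
    "probability_to_timescale",
    "UncertaintyBox",
    "CaseStudy",
    "CASE_STUDIES",
    "RegimeProbabilities",
    "regime_probabilities",
]


def timescale_to_probability(mean_residence_years: float) -> float:
    """Transition probability per yearly step from a mean residence time.

    Residence in a state is geometrically distributed, with mean
    ``<N> = (1 - p)/p`` steps; inverting gives ``p = 1/(<N> + 1)``.
    ``<N> = 0`` means the system transitions every step (p = 1).
    """
    if mean_residence_years < 0:
        raise ValueError("mean residence time must be non-negative")
    return 1.0 / (mean_residence_years + 1.0)


def probability_to_timescale(p: float) -> float:
    """Inverse of :func:`timescale_to_probability`: ``<N> = (1 - p)/p``."""
    if not 0.0 < p <= 1.0:
        raise ValueError("probability must lie in (0, 1]")
    return (1.0 - p) / p


def _as_range(x) -> tuple[float, float]:
    if np.isscalar(x):
        return (float(x), float(x))
    lo, hi = (float(v) for v in x)
    if lo > hi:
        raise ValueError(f"range lower bound exceeds upper: {x!r}")
    return (lo, hi)


@dataclass(frozen=True)
class UncertaintyBox:
    """Uniform-sampling ranges for the non-timescale parameters.

    Defaults reflect a moderately farsighted decision maker
    (gamma in [0.95, 0.99]) with broad uncertainty about the reward ratio
    (r_l/r_h in [0.3, 0.7]) and the normative threshold
    (r_min/r_h in [0.1, 0.5]).  delta/rho ranges, when given, override the
    case study's timescale-derived values.
    """

    gamma: tuple[float, float] = (0.95, 0.99)
    r_l: tuple[float, float] = (0.3, 0.7)
    r_min: tuple[float, float] = (0.1, 0.5)
    delta: tuple[float, float] | None = None
    rho: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("gamma", "r_l", "r_min", "delta", "rho"):
            rng = getattr(self, name)
            if rng is None:
                continue
            lo, hi = rng
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} range must satisfy 0 <= lo <= hi <= 1, "
                                 f"got {rng!r}")


@dataclass(frozen=True)
class CaseStudy:
    """A named tipping element with collapse/recovery residence timescales.

    Timescales may be single values or (lo, hi) ranges in years; ranges are
    carried into the derived transition probabilities as intervals sampled
    uniformly on the probability scale.
    """

    name: str
    collapse_timescale_years: float | tuple[float, float]
    recovery_timescale_years: float | tuple[float, float]

    @property
    def delta_range(self) -> tuple[float, float]:
        lo, hi = _as_range(self.collapse_timescale_years)
        # longer residence -> smaller probability
        return (timescale_to_probability(hi), timescale_to_probability(lo))

    @property
    def rho_range(self) -> tuple[float, float]:
        lo, hi = _as_range(self.recovery_timescale_years)
        return (timescale_to_probability(hi), timescale_to_probability(lo))


#: Presets built from the typical residence timescales of each system.
#: Climate: collapse triggered within 30-50 years under business-as-usual
#: forcing; recovery is multi-millennial (encoded as 5000 years, i.e. rho
#: close to zero).  Fisheries: stock collapse within ~20 years, recovery
#: ~50 years.  Farming (land degradation): collapse ~100 years, soil
#: recovery ~300 years.
CASE_STUDIES: dict[str, CaseStudy] = {
    "climate": CaseStudy("climate", (30.0, 50.0), 5000.0),
    "fisheries": CaseStudy("fisheries", 20.0, 50.0),
    "farming": CaseStudy("farming", 100.0, 300.0),
}


@dataclass(frozen=True)
class RegimeProbabilities:
    """Per-policy, per-label regime probabilities under parameter uncertainty."""

    case: str
    probabilities: dict[str, dict[ParadigmLabel, float]]
    standard_errors: dict[str, dict[ParadigmLabel, float]]
    n: int
    seed: int
    box: UncertaintyBox = field(default=UncertaintyBox())

    def probability(self, policy: str, code: str) -> float:
        return self.probabilities[policy][ParadigmLabel.from_code(code)]

    def modal_label(self, policy: str) -> ParadigmLabel:
        probs = self.probabilities[policy]
        return max(sorted(probs, key=lambda lab: lab.code), key=probs.get)

    def to_dict(self) -> dict:
        return {
            "case": self.case,
            "n": self.n,
            "seed": self.seed,
            "box": {
                "gamma": list(self.box.gamma),
                "r_l": list(self.box.r_l),
                "r_min": list(self.box.r_min),
                "delta": list(self.box.delta) if self.box.delta else None,
                "rho": list(self.box.rho) if self.box.rho else None,
            },
            "probabilities": {
                pol: {lab.code: p[lab] for lab in ALL_LABELS}
                for pol, p in self.probabilities.items()
            },
            "standard_errors": {
                pol: {lab.code: s[lab] for lab in ALL_LABELS}
                for pol, s in self.standard_errors.items()
            },
        }


def _uniform(rng: np.random.Generator, bounds: tuple[float, float], n: int):
    lo, hi = bounds
    if lo == hi:
        return np.full(n, lo)
    return rng.uniform(lo, hi, n)


def regime_probabilities(case: CaseStudy, box: UncertaintyBox | None = None,
                         n: int = 100_000, seed: int | None = None
                         ) -> RegimeProbabilities:
    """Monte-Carlo regime-membership probabilities for a case study.

    Draws (gamma, r_l/r_h, r_min/r_h) — and delta, rho where the case or
    box gives ranges — uniformly and independently, classifies both
    policies at every draw, and returns per-label probabilities with
    binomial standard errors.  A seed is mandatory for reproducibility.
    """
    box = box or UncertaintyBox()
    if seed is None:
        raise ValueError("a seed is required for the Monte-Carlo sampling")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    delta = _uniform(rng, box.delta or case.delta_range, n)
    rho = _uniform(rng, box.rho or case.rho_range, n)
    gamma = _uniform(rng, box.gamma, n)
    r_l = _uniform(rng, box.r_l, n)
    r_min = _uniform(rng, box.r_min, n)

    labels = classify_many(delta, rho, gamma, r_l, r_min)
    probabilities: dict[str, dict[ParadigmLabel, float]] = {}
    standard_errors: dict[str, dict[ParadigmLabel, float]] = {}
    for policy in ("risky", "cautious"):
        opt, sus, safe = labels[policy]
        idx = opt.astype(np.int64) * 4 + sus.astype(np.int64) * 2 + safe.astype(np.int64)
        counts = np.bincount(idx, minlength=8)
        p = counts / n
        probabilities[policy] = {lab: float(p[lab.index]) for lab in ALL_LABELS}
        standard_errors[policy] = {
            lab: float(np.sqrt(p[lab.index] * (1.0 - p[lab.index]) / n))
            for lab in ALL_LABELS
        }
    return RegimeProbabilities(case=case.name, probabilities=probabilities,
                               standard_errors=standard_errors, n=n, seed=seed,
                               box=box)
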