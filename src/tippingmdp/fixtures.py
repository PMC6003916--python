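"""Witness parameter points and figure settings used across tests and docs.

The eight paradigm categories are all realizable: for each (optimal,
sustainable, safe) combination there is a (policy, parameter) witness —
cautious witnesses cover the four safe categories, risky witnesses the four
unsafe ones.  Two complete sets are shipped, one at gamma < 1 and one at
the undiscounted limit gamma = 1, since the classification survives
absolute farsightedness.
"""

from __future__ import annotations

import json
from pathlib import Path

from .casestudies import CASE_STUDIES, UncertaintyBox
from .mdp import TippingModel

__all__ = [
    "WITNESS_POINTS",
    "WITNESS_POINTS_GAMMA1",
    "SWEEP_SETTINGS",
    "witness_models",
    "make_fixtures",
]

# (expected label code, policy name, parameters); r_h = 1 throughout.
WITNESS_POINTS: tuple[tuple[str, str, dict], ...] = (
    ("OSF", "cautious", dict(delta=0.5, rho=0.2, gamma=0.9, r_l=0.5, r_min=0.3)),
    ("OsF", "cautious", dict(delta=0.5, rho=0.2, gamma=0.9, r_l=0.5, r_min=0.7)),
    ("oSF", "cautious", dict(delta=0.05, rho=0.2, gamma=0.9, r_l=0.5, r_min=0.3)),
    ("osF", "cautious", dict(delta=0.05, rho=0.2, gamma=0.9, r_l=0.5, r_min=0.7)),
    ("OSf", "risky", dict(delta=0.05, rho=0.3, gamma=0.99, r_l=0.5, r_min=0.1)),
    ("Osf", "risky", dict(delta=0.05, rho=0.2, gamma=0.9, r_l=0.5, r_min=0.7)),
    ("oSf", "risky", dict(delta=0.3, rho=0.5, gamma=0.99, r_l=0.9, r_min=0.1)),
    ("osf", "risky", dict(delta=0.5, rho=0.2, gamma=0.9, r_l=0.5, r_min=0.3)),
)

WITNESS_POINTS_GAMMA1: tuple[tuple[str, str, dict], ...] = (
    ("OSF", "cautious", dict(delta=0.5, rho=0.2, gamma=1.0, r_l=0.5, r_min=0.3)),
    ("OsF", "cautious", dict(delta=0.5, rho=0.2, gamma=1.0, r_l=0.5, r_min=0.7)),
    ("oSF", "cautious", dict(delta=0.05, rho=0.5, gamma=1.0, r_l=0.5, r_min=0.3)),
    ("osF", "cautious", dict(delta=0.05, rho=0.5, gamma=1.0, r_l=0.5, r_min=0.7)),
    ("OSf", "risky", dict(delta=0.05, rho=0.5, gamma=1.0, r_l=0.5, r_min=0.3)),
    ("Osf", "risky", dict(delta=0.05, rho=0.5, gamma=1.0, r_l=0.5, r_min=0.9)),
    ("oSf", "risky", dict(delta=0.5, rho=0.2, gamma=1.0, r_l=0.5, r_min=0.1)),
    ("osf", "risky", dict(delta=0.5, rho=0.2, gamma=1.0, r_l=0.5, r_min=0.3)),
)

#: Fixed parameters behind the standard two-axis (delta x gamma) region
#: sweeps: the baseline setting admits a safe-and-just region (r_min <= r_l),
#: the high-threshold variant does not (r_min > r_l).
SWEEP_SETTINGS: dict[str, dict] = {
    "baseline": dict(rho=0.2, r_l=0.5, r_min=0.3),
    "high_threshold": dict(rho=0.2, r_l=0.5, r_min=0.7),
}


def witness_models(gamma1: bool = False):
    """Yield (expected code, policy name, TippingModel) witness triples."""
    points = WITNESS_POINTS_GAMMA1 if gamma1 else WITNESS_POINTS
    for code, policy, params in points:
        yield code, policy, TippingModel(**params)


def make_fixtures(out_dir: str | Path) -> list[Path]:
    """Write all fixture collections as JSON files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    box = UncertaintyBox()
    payloads = {
        "witness_points.json": {
            "description": "one (policy, parameters) witness per paradigm label",
            "gamma_lt_1": [
                {"label": c, "policy": p, "params": d} for c, p, d in WITNESS_POINTS
            ],
            "gamma_eq_1": [
                {"label": c, "policy": p, "params": d}
                for c, p, d in WITNESS_POINTS_GAMMA1
            ],
        },
        "sweep_settings.json": SWEEP_SETTINGS,
        "case_presets.json": {
            name: {
                "collapse_timescale_years": cs.collapse_timescale_years,
                "recovery_timescale_years": cs.recovery_timescale_years,
                "delta_range": list(cs.delta_range),
                "rho_range": list(cs.rho_range),
                "default_box": {"gamma": list(box.gamma),
                                "r_l": list(box.r_l),
                                "r_min": list(box.r_min)},
            }
            for name, cs in CASE_STUDIES.items()
        },
    }
    paths = []
    for fname, payload in payloads.items():
        path = out / fname
        path.write_text(json.dumps(payload, indent=2) + "\n")
        paths.append(path)
    return paths
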