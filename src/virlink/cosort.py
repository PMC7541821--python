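"""Droplet co-sorting expectation model.

During fluorescence-activated cell sorting, a free viral particle can be
deposited in the same drop as the target cell.  With no discrimination
against virions, the number of co-sorted viruses per drop is Poisson with

    lambda = virus_concentration [viruses/pL] * drop_sample_volume [pL]

Surface seawater typically carries 1e7–1e8 viruses/mL (0.01–0.1 per pL);
with ~21–28 pL of sample per drop this puts the expectation between about
one virus per five sorted cells and two viruses per sorted cell — the
baseline against which observed per-SAG virus prevalence is judged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SortingParameters",
    "per_ml_to_per_pl",
    "expected_cosorts",
    "prob_at_least_one",
    "cosort_bounds",
]

PL_PER_ML = 1e9  # 1 mL = 1e-3 L = 1e9 pL; 1e7/mL <-> 0.01/pL


@dataclass(frozen=True)
class SortingParameters:
    drop_sample_volume: float  # pL
    virus_concentration: float  # viruses per pL
    instrument: str = ""

    def __post_init__(self) -> None:
        if self.drop_sample_volume <= 0:
            raise ValueError("drop sample volume must be positive")
        if self.virus_concentration < 0:
            raise ValueError("virus concentration must be non-negative")


def per_ml_to_per_pl(concentration_per_ml: float) -> float:
    """Convert viruses/mL to viruses/pL (1 mL = 1e9 pL)."""
    if concentration_per_ml < 0:
        raise ValueError("concentration must be non-negative")
    return concentration_per_ml / PL_PER_ML


def expected_cosorts(p: SortingParameters) -> float:
    """Expected number of co-sorted free viral particles per drop."""
    return p.virus_concentration * p.drop_sample_volume


def prob_at_least_one(lam: float) -> float:
    """Poisson probability of at least one co-sorted virus, 1 - exp(-lambda)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return 1.0 - math.exp(-lam)


def cosort_bounds(volumes, conc_range, observed_prevalence=None) -> list[dict]:
    """Expectation table over (volume, concentration) corners.

    ``conc_range`` is (low, high) in viruses/pL.  When per-SAG virus
    prevalences (fractions in [0,1], keyed by label) are supplied, each is
    flagged if it exceeds the highest P(>=1 co-sort) in the table — i.e.
    cannot be explained by co-sorting alone.
    """
    low, high = conc_range
    if low > high:
        raise ValueError("conc_range must satisfy low <= high")
    rows = []
    for v in volumes:
        for conc in (low, high):
            lam = expected_cosorts(SortingParameters(v, conc))
            rows.append({
                "drop_sample_volume_pl": v,
                "virus_concentration_per_pl": conc,
                "lambda": lam,
                "p_at_least_one": prob_at_least_one(lam),
            })
    if observed_prevalence:
        p_max = max((r["p_at_least_one"] for r in rows), default=0.0)
        for label, prev in observed_prevalence.items():
            rows.append({
                "observed": label,
                "prevalence": prev,
                "exceeds_cosort_bound": bool(prev > p_max),
            })
    return rows
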