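"""Percentile reference ranges and the >=60% outlier call.

A reference range is the central 95% band of a trait in matched control
animals of one sex: the 2.5th and 97.5th percentiles, computed by linear
interpolation between order statistics (the "type 7" convention; the
convention is configurable because the band edges shift slightly with it).
Being percentile-based, the method makes no distributional assumption and is
invariant under monotone transforms of the trait.

A mutant cohort is called abnormal when at least ``threshold_fraction``
(default 60%) of the animals lie strictly beyond the *same* side of the
band.  The two directions are assessed separately: 3 animals above plus 2
below out of 7 is normal.

Reference-interval practice requires a large control sample; a warning flag
is set below 120 control values.

:func:`rr_false_positive_rate` gives the chance of a spurious abnormal call
when the mutants are in truth draws from the control distribution (the band
itself assumed estimated perfectly).  Two computations are provided:

* ``method="exact"`` — exact enumeration over the (below, inside, above)
  trinomial outcome space with 2.5% mass per tail: the true false-positive
  rate of the one-sided call implemented here (~3.9e-7 for 7 animals at the
  60% rule).
* ``method="binomial"`` — the upper tail of B(N, 0.05): the common
  back-of-envelope figure that counts animals outside either end without
  requiring them on the same side (~6e-6 for 7 animals).  It overstates the
  directional rate roughly 15-fold but is the number usually quoted.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, comb

import numpy as np
from scipy import stats

from .data import TraitDataset, WILDTYPE
from .errors import InsufficientDataError, ValidationError

MIN_CONTROLS_RECOMMENDED = 120

ABNORMAL_HIGH = "abnormal_high"
ABNORMAL_LOW = "abnormal_low"
NORMAL = "normal"


@dataclass
class ReferenceRange:
    """Central 95% percentile band of one trait in controls of one sex."""

    trait_name: str
    sex: str
    lower: float
    upper: float
    n_controls: int
    tail_prob: float = 0.05
    percentile_method: str = "linear"

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValidationError("reference range lower bound exceeds upper bound")

    @property
    def low_n_warning(self) -> bool:
        """True when fewer controls than reference-interval practice recommends."""
        return self.n_controls < MIN_CONTROLS_RECOMMENDED


@dataclass
class RRCall:
    """Outcome of the >=60% rule for one mutant cohort against one range."""

    n_mutants: int
    n_above: int
    n_below: int
    threshold_fraction: float

    def __post_init__(self):
        if self.n_above + self.n_below > self.n_mutants:
            raise ValidationError("more outliers than mutants")

    @property
    def fraction_outside_one_sided(self) -> float:
        return max(self.n_above, self.n_below) / self.n_mutants

    @property
    def call(self) -> str:
        if self.n_above / self.n_mutants >= self.threshold_fraction:
            return ABNORMAL_HIGH
        if self.n_below / self.n_mutants >= self.threshold_fraction:
            return ABNORMAL_LOW
        return NORMAL


def build_reference(
    controls: TraitDataset | np.ndarray, sex: str | None = None,
    tail_prob: float = 0.05, percentile_method: str = "linear",
    trait_name: str = "",
) -> ReferenceRange:
    """Build the percentile band from wildtype animals of one sex.

    ``controls`` may be a TraitDataset (restricted internally to wildtype
    records of ``sex``) or a plain array of control values.
    """
    if isinstance(controls, TraitDataset):
        values = controls.values(genotype=WILDTYPE, sex=sex)
        trait_name = controls.trait_name
    else:
        values = np.asarray(controls, dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            f"reference range needs >= 2 control values, got {values.size}"
        )
    lo, hi = np.quantile(values, [tail_prob / 2.0, 1.0 - tail_prob / 2.0],
                         method=percentile_method)
    return ReferenceRange(
        trait_name=trait_name, sex=sex or "", lower=float(lo), upper=float(hi),
        n_controls=int(values.size), tail_prob=tail_prob,
        percentile_method=percentile_method,
    )


def call_reference_range(
    rr: ReferenceRange, mutants: np.ndarray, threshold_fraction: float = 0.60,
) -> RRCall:
    """Apply the >=threshold one-sided outlier rule to mutant values.

    "Outside" is strict inequality — values equal to a band edge count as
    inside.
    """
    values = np.asarray(mutants, dtype=float)
    if values.size == 0:
        raise InsufficientDataError("no mutant values to call")
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValidationError("threshold_fraction must lie in (0, 1]")
    return RRCall(
        n_mutants=int(values.size),
        n_above=int(np.sum(values > rr.upper)),
        n_below=int(np.sum(values < rr.lower)),
        threshold_fraction=threshold_fraction,
    )


def _k_min(n: int, threshold_fraction: float) -> int:
    """Smallest count k with k/n >= threshold_fraction."""
    k = ceil(n * threshold_fraction - 1e-9)
    return max(k, 1)


def rr_false_positive_rate(
    n_mutants: int, threshold_fraction: float = 0.60, tail_prob: float = 0.05,
    method: str = "exact",
) -> float:
    """Chance of a spurious abnormal call for null mutants (perfect band).

    ``method="exact"`` enumerates the trinomial (below, inside, above)
    outcome space with ``tail_prob/2`` mass per tail and returns the
    probability that either direction alone reaches the threshold — the
    actual rate of :func:`call_reference_range`.  ``method="binomial"``
    returns the B(n, tail_prob) upper tail (animals outside either end,
    direction ignored), the simpler figure usually quoted.
    """
    if n_mutants < 1:
        raise ValidationError("n_mutants must be >= 1")
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValidationError("threshold_fraction must lie in (0, 1]")
    if not 0.0 < tail_prob < 1.0:
        raise ValidationError("tail_prob must lie in (0, 1)")
    n, k = n_mutants, _k_min(n_mutants, threshold_fraction)
    if method == "binomial":
        return float(stats.binom.sf(k - 1, n, tail_prob))
    if method != "exact":
        raise ValidationError(f"unknown method {method!r}")
    pt = tail_prob / 2.0
    total = 0.0
    for a in range(n + 1):          # animals above
        for b in range(n - a + 1):  # animals below
            if a >= k or b >= k:
                total += (comb(n, a) * comb(n - a, b)
                          * pt ** (a + b) * (1.0 - 2.0 * pt) ** (n - a - b))
    return float(total)


def either_sex(p: float) -> float:
    """Chance that at least one of two independent per-sex calls triggers."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("probability must lie in [0, 1]")
    return 1.0 - (1.0 - p) ** 2
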