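"""Concentration and genome-integrity estimators for duplex droplet dPCR.

A duplex droplet dPCR reaction partitions template DNA into ~20,000
nanolitre-scale droplets and scores each droplet on two fluorescence
channels, one per target (a 5' target such as the CMV enhancer and a 3'
target such as the polyA signal).  The instrument reports four category
counts per well: double-positive, target-1-only, target-2-only, and
negative droplets.  This module turns those counts into

* template concentration via the standard Poisson occupancy correction
  ``lambda = -ln(negative fraction)``,
* genome-integrity estimates (the percentage of template molecules that
  carry *both* targets) under four models:

  - ``simple``: double positives over total positives,
  - ``linkage_avg``: linked-template concentration over the mean of the
    two single-target concentrations,
  - ``linkage_comp``: linkage compensated for unequal target
    concentrations,
  - ``poisson_multinomial``: the mixture model in which the number of
    molecules per droplet is Poisson(lambda) and each molecule is
    independently one of three species (5'-only, 3'-only, intact).  The
    single-positive droplet fractions determine the species
    probabilities through a degree-``k_max`` polynomial, solved by
    bracketed bisection; integrity is ``(1 - p_t1_only - p_t2_only) * 100``.

All estimators are pure functions of the four category counts; none of
them clamps its output (negative estimates, or estimates slightly above
100%, are reported as-is so that downstream averaging stays unbiased).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import stats

__all__ = [
    "DEFAULT_DROPLET_VOLUME_NL",
    "DEFAULT_K_MAX",
    "DropletCounts",
    "ConcentrationEstimate",
    "SpeciesProbabilities",
    "IntegrityResult",
    "SaturationError",
    "InfeasibleFractionError",
    "lambda_from_negative_fraction",
    "lambda_to_copies_per_ul",
    "copies_per_ul_to_lambda",
    "concentration_from_counts",
    "target_lambdas",
    "linkage_concentration",
    "integrity_simple",
    "integrity_linkage_avg",
    "integrity_linkage_comp",
    "single_positive_fraction",
    "solve_single_positive_probability",
    "closed_form_single_positive_probability",
    "integrity_poisson_multinomial",
    "expected_category_probabilities",
]

#: Average droplet volume of the Bio-Rad QX200 system, in nanolitres.
DEFAULT_DROPLET_VOLUME_NL = 0.85

#: Truncation depth of the single-positive polynomial.  At the top of the
#: instrument's dynamic range (5000 copies/uL, i.e. 4.25 copies/droplet)
#: the probability of a droplet holding more than 20 molecules is ~5.4e-9,
#: so terms beyond k=20 are numerically irrelevant.
DEFAULT_K_MAX = 20

_NL_TO_UL = 1e-3


class SaturationError(ValueError):
    """No negative droplets on a required channel: concentration is above
    the dynamic range and the Poisson correction is undefined."""


class InfeasibleFractionError(ValueError):
    """A single-positive fraction exceeds what any species distribution
    could produce at the given lambda."""


@dataclass(frozen=True)
class DropletCounts:
    """Four-category droplet tally for one well.

    Instrument data are non-negative integers; real-valued "expected
    counts" (category probabilities times total droplets) are also
    accepted, which is how the estimators are checked against the exact
    generative model.
    """

    n_double: float
    n_t1_only: float
    n_t2_only: float
    n_negative: float

    def __post_init__(self) -> None:
        for name in ("n_double", "n_t1_only", "n_t2_only", "n_negative"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")
        if self.d_total <= 0:
            raise ValueError("d_total must be positive")

    @property
    def d_total(self) -> float:
        """Total accepted droplets (sum of the four categories)."""
        return self.n_double + self.n_t1_only + self.n_t2_only + self.n_negative

    @property
    def n_positive(self) -> float:
        return self.n_double + self.n_t1_only + self.n_t2_only

    def scaled(self, factor: float) -> "DropletCounts":
        return DropletCounts(
            self.n_double * factor,
            self.n_t1_only * factor,
            self.n_t2_only * factor,
            self.n_negative * factor,
        )


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Template concentration on both the per-droplet and the
    instrument (copies/uL) scale."""

    lambda_per_droplet: float
    copies_per_ul: float
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL


@dataclass(frozen=True)
class SpeciesProbabilities:
    """Species distribution of template molecules: 5'-only, 3'-only, and
    intact (both targets).

    As generative parameters the three components are probabilities
    (``validate_generative``).  As *estimates* the components may fall
    slightly outside [0, 1]; they are carried unclamped and flagged via
    :attr:`out_of_range`.
    """

    p_t1_only: float
    p_t2_only: float

    @property
    def p_full(self) -> float:
        return 1.0 - self.p_t1_only - self.p_t2_only

    @property
    def out_of_range(self) -> bool:
        return not (
            0.0 <= self.p_t1_only <= 1.0
            and 0.0 <= self.p_t2_only <= 1.0
            and 0.0 <= self.p_full <= 1.0
        )

    def validate_generative(self) -> "SpeciesProbabilities":
        if self.out_of_range:
            raise ValueError(
                f"not a valid species distribution: p_t1_only={self.p_t1_only}, "
                f"p_t2_only={self.p_t2_only}, p_full={self.p_full}"
            )
        return self


@dataclass(frozen=True)
class IntegrityResult:
    """One model's integrity estimate plus its intermediates.

    ``integrity_percent`` is never clamped: negative values and values
    above 100 are legitimate finite-count outcomes.  When ``is_na`` is
    true the estimate is NaN and ``na_reason`` says why.
    """

    method: str
    integrity_percent: float
    lambda_total: float = math.nan
    lambda_t1: float = math.nan
    lambda_t2: float = math.nan
    linkage_copies_per_ul: float = math.nan
    species: Optional[SpeciesProbabilities] = None
    is_na: bool = False
    na_reason: Optional[str] = None

    @staticmethod
    def na(method: str, reason: str, **kw) -> "IntegrityResult":
        return IntegrityResult(
            method=method, integrity_percent=math.nan, is_na=True, na_reason=reason, **kw
        )


# ---------------------------------------------------------------------------
# Concentration (Poisson occupancy correction)
# ---------------------------------------------------------------------------

def lambda_from_negative_fraction(counts: DropletCounts) -> float:
    """Mean template molecules per droplet from the double-negative fraction.

    The negative fraction estimates ``exp(-lambda)``, so
    ``lambda = -ln(n_negative / d_total)``.

    Raises
    ------
    SaturationError
        If no droplet is negative (concentration above the dynamic range).
    """
    if counts.n_negative == 0:
        raise SaturationError("all droplets positive; concentration above dynamic range")
    return -math.log(counts.n_negative / counts.d_total)


def lambda_to_copies_per_ul(lam: float, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL) -> float:
    """Convert copies/droplet to copies/uL given the droplet volume in nL."""
    if droplet_volume_nl <= 0:
        raise ValueError("droplet volume must be positive")
    return lam / (droplet_volume_nl * _NL_TO_UL)


def copies_per_ul_to_lambda(copies_per_ul: float, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL) -> float:
    if droplet_volume_nl <= 0:
        raise ValueError("droplet volume must be positive")
    return copies_per_ul * droplet_volume_nl * _NL_TO_UL


def concentration_from_counts(
    counts: DropletCounts, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
) -> ConcentrationEstimate:
    """Template concentration of a well on both scales."""
    lam = lambda_from_negative_fraction(counts)
    return ConcentrationEstimate(
        lambda_per_droplet=lam,
        copies_per_ul=lambda_to_copies_per_ul(lam, droplet_volume_nl),
        droplet_volume_nl=droplet_volume_nl,
    )


def target_lambdas(counts: DropletCounts) -> tuple[float, float, float]:
    """Per-droplet concentrations ``(lambda_t1, lambda_t2, lambda_total)``.

    On channel i the negatives are the droplets lacking target i, so the
    Poisson correction applies channel-wise:
    ``lambda_t1 = -ln((n_negative + n_t2_only)/d_total)`` and symmetrically
    for the other channel.
    """
    neg1 = counts.n_negative + counts.n_t2_only
    neg2 = counts.n_negative + counts.n_t1_only
    if neg1 == 0:
        raise SaturationError("all droplets positive on channel 1 (target 1)")
    if neg2 == 0:
        raise SaturationError("all droplets positive on channel 2 (target 2)")
    lam_total = lambda_from_negative_fraction(counts)
    lam1 = -math.log(neg1 / counts.d_total)
    lam2 = -math.log(neg2 / counts.d_total)
    return lam1, lam2, lam_total


def linkage_concentration(
    counts: DropletCounts, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
) -> float:
    """Linked-template concentration in copies/uL.

    Linkage is the concentration of templates carrying both targets: the
    double positives in excess of chance co-localization.  Under the
    Poisson partition model the molecular species decompose as
    ``lambda_linked = lambda_t1 + lambda_t2 - lambda_total``.  The value
    may be <= 0 when double positives are at or below the chance
    expectation; it is never clamped.
    """
    lam1, lam2, lam_total = target_lambdas(counts)
    return lambda_to_copies_per_ul(lam1 + lam2 - lam_total, droplet_volume_nl)


# ---------------------------------------------------------------------------
# Integrity models
# ---------------------------------------------------------------------------

def integrity_simple(counts: DropletCounts, use_concentration: bool = False) -> IntegrityResult:
    """Integrity as double positives over total positives.

    The droplet-number form is the default.  ``use_concentration=True``
    Poisson-corrects each positive category separately
    (``-ln(1 - n_cat/d_total)``) and takes the same ratio on the
    concentration scale.
    """
    method = "simple"
    if counts.n_positive == 0:
        return IntegrityResult.na(method, "no positive droplets", lambda_total=0.0)
    if use_concentration:
        d = counts.d_total
        def cat_lambda(n: float) -> float:
            if n >= d:
                raise SaturationError("category occupies all droplets")
            return -math.log1p(-n / d)
        c_double = cat_lambda(counts.n_double)
        c_pos = (
            c_double + cat_lambda(counts.n_t1_only) + cat_lambda(counts.n_t2_only)
        )
        value = 100.0 * c_double / c_pos
    else:
        value = 100.0 * counts.n_double / counts.n_positive
    lam_total = (
        lambda_from_negative_fraction(counts) if counts.n_negative > 0 else math.nan
    )
    return IntegrityResult(method=method, integrity_percent=value, lambda_total=lam_total)


def _linkage_result(
    counts: DropletCounts, method: str, droplet_volume_nl: float
) -> tuple[float, float, float, float] | IntegrityResult:
    lam1, lam2, lam_total = target_lambdas(counts)
    if lam1 == 0 and lam2 == 0:
        return IntegrityResult.na(
            method, "no amplification", lambda_total=lam_total, lambda_t1=0.0, lambda_t2=0.0
        )
    linked = lam1 + lam2 - lam_total
    return lam1, lam2, lam_total, linked


def integrity_linkage_avg(
    counts: DropletCounts, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
) -> IntegrityResult:
    """Integrity as linkage over the average of the two target
    concentrations.  The ratio is scale invariant, so it is computed on
    the per-droplet scale."""
    method = "linkage_avg"
    out = _linkage_result(counts, method, droplet_volume_nl)
    if isinstance(out, IntegrityResult):
        return out
    lam1, lam2, lam_total, linked = out
    value = 100.0 * linked / ((lam1 + lam2) / 2.0)
    return IntegrityResult(
        method=method,
        integrity_percent=value,
        lambda_total=lam_total,
        lambda_t1=lam1,
        lambda_t2=lam2,
        linkage_copies_per_ul=lambda_to_copies_per_ul(linked, droplet_volume_nl),
    )


def integrity_linkage_comp(
    counts: DropletCounts, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
) -> IntegrityResult:
    """Integrity as ``(linkage + |c1 - c2|) / max(c1, c2)``: the
    compensated linkage model for unequal target concentrations.

    Known pathology (reported, not "fixed"): a sample whose molecules
    all carry only one target still scores 100%.
    """
    method = "linkage_comp"
    out = _linkage_result(counts, method, droplet_volume_nl)
    if isinstance(out, IntegrityResult):
        return out
    lam1, lam2, lam_total, linked = out
    value = 100.0 * (linked + abs(lam1 - lam2)) / max(lam1, lam2)
    return IntegrityResult(
        method=method,
        integrity_percent=value,
        lambda_total=lam_total,
        lambda_t1=lam1,
        lambda_t2=lam2,
        linkage_copies_per_ul=lambda_to_copies_per_ul(linked, droplet_volume_nl),
    )


# ---------------------------------------------------------------------------
# Poisson-multinomial model
# ---------------------------------------------------------------------------

def _poisson_coeffs(lam: float, k_max: int) -> np.ndarray:
    """Polynomial coefficients [0, Pois(1;lam), ..., Pois(k_max;lam)]."""
    k = np.arange(0, k_max + 1)
    c = stats.poisson.pmf(k, lam)
    c[0] = 0.0
    return c


def single_positive_fraction(
    lam: float, p: float, k_max: int = DEFAULT_K_MAX
) -> float:
    """Expected single-positive droplet fraction for species probability p.

    The truncated forward map ``sum_{k=1..k_max} Pois(k; lam) p^k``: the
    probability that a droplet contains at least one molecule and all of
    its molecules belong to the one species with probability ``p``.
    """
    return float(npoly.polyval(p, _poisson_coeffs(lam, k_max)))


def closed_form_single_positive_probability(s: float, lam: float) -> float:
    """Untruncated inverse of the single-positive fraction.

    Summing the full series gives
    ``s = exp(-lam (1 - p)) - exp(-lam)``, hence
    ``p = 1 + ln(s + exp(-lam)) / lam``.  Kept as an independent oracle
    for the polynomial solver.
    """
    return 1.0 + math.log(s + math.exp(-lam)) / lam


def solve_single_positive_probability(
    s: float,
    lam: float,
    k_max: int = DEFAULT_K_MAX,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> float:
    """Solve the degree-``k_max`` polynomial for the species probability.

    Finds the unique root p in [0, 1] of
    ``f(p) = sum_{k=1..k_max} Pois(k; lam) p^k - s`` by bracketed
    bisection.  All coefficients are non-negative, so f is strictly
    increasing on [0, 1] and the root is unique.

    Parameters
    ----------
    s : observed single-positive droplet fraction, ``0 <= s < 1 - exp(-lam)``.
    lam : mean molecules per droplet, > 0 (0 allowed only with s = 0).
    """
    if s < 0:
        raise InfeasibleFractionError(f"single-positive fraction {s} < 0")
    if s == 0:
        return 0.0
    if lam <= 0:
        raise InfeasibleFractionError(
            f"single-positive fraction {s} > 0 is impossible at lambda = {lam}"
        )
    # s equal to the positive fraction corresponds exactly to p = 1
    # (every molecule is of this one species); beyond it is infeasible.
    # A few ulps of slack absorb roundoff in exactly-at-the-bound inputs.
    bound = 1.0 - math.exp(-lam)
    if s > bound:
        if s - bound <= 1e-12 * max(1.0, s):
            return 1.0
        raise InfeasibleFractionError(
            f"single-positive fraction {s} exceeds the positive fraction "
            f"{bound:.6g} at lambda = {lam}"
        )
    coeffs = _poisson_coeffs(lam, k_max)
    if float(npoly.polyval(1.0, coeffs)) <= s:
        # s sits in the O(1e-9) truncation gap just below the positive
        # fraction; the truncated polynomial's root is effectively 1.
        return 1.0
    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if float(npoly.polyval(mid, coeffs)) < s:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


_NA_RULES = ("strict", "relaxed")


def integrity_poisson_multinomial(
    counts: DropletCounts,
    k_max: int = DEFAULT_K_MAX,
    na_rule: str = "strict",
    tol: float = 1e-12,
) -> IntegrityResult:
    """Poisson-multinomial integrity estimate.

    Estimates lambda from the negative fraction, solves the truncated
    polynomial for each single-positive species probability, and returns
    ``integrity = (1 - p_t1_only - p_t2_only) * 100`` (unclamped).

    ``na_rule="strict"`` (default, mirroring the published analysis app)
    returns NA unless all four category counts are nonzero;
    ``"relaxed"`` requires only negatives, so a perfectly intact sample
    (zero single positives on both channels) evaluates to exactly 100%.
    """
    method = "poisson_multinomial"
    if na_rule not in _NA_RULES:
        raise ValueError(f"na_rule must be one of {_NA_RULES}, got {na_rule!r}")
    if na_rule == "strict":
        for name in ("n_double", "n_t1_only", "n_t2_only", "n_negative"):
            if getattr(counts, name) == 0:
                return IntegrityResult.na(method, f"zero-count category: {name}")
    elif counts.n_negative == 0:
        return IntegrityResult.na(method, "zero-count category: n_negative")

    lam = lambda_from_negative_fraction(counts)
    if lam == 0.0:
        # no positives at all: integrity undefined
        return IntegrityResult.na(method, "no positive droplets", lambda_total=0.0)
    d = counts.d_total
    p1 = solve_single_positive_probability(counts.n_t1_only / d, lam, k_max, tol)
    p2 = solve_single_positive_probability(counts.n_t2_only / d, lam, k_max, tol)
    species = SpeciesProbabilities(p_t1_only=p1, p_t2_only=p2)

    try:
        lam1, lam2, _ = target_lambdas(counts)
    except SaturationError:
        lam1 = lam2 = math.nan
    return IntegrityResult(
        method=method,
        integrity_percent=species.p_full * 100.0,
        lambda_total=lam,
        lambda_t1=lam1,
        lambda_t2=lam2,
        species=species,
    )


def expected_category_probabilities(
    lam: float, species: SpeciesProbabilities
) -> np.ndarray:
    """Exact droplet-category probabilities ``(double, t1_only, t2_only,
    negative)`` under the generative model.

    A droplet is target-1-only when it holds at least one molecule and
    every molecule is of the 5'-only species; summing the Poisson series
    gives ``exp(-lam (1 - p_t1_only)) - exp(-lam)``, and symmetrically
    for the other channel.  The double-positive probability is the
    complement.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    species.validate_generative()
    p_neg = math.exp(-lam)
    p_t1 = math.exp(-lam * (1.0 - species.p_t1_only)) - p_neg
    p_t2 = math.exp(-lam * (1.0 - species.p_t2_only)) - p_neg
    p_double = 1.0 - p_neg - p_t1 - p_t2
    return np.array([p_double, p_t1, p_t2, p_neg])
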