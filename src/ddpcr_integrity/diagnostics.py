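"""Analytic self-checks of the model's numerical premises.

Three closed-form facts anchor the estimator's working range on the
QX200 instrument, plus a sweep verifying that the degree-20 truncated
polynomial solver agrees with the untruncated closed form everywhere in
that range:

1. the 5000 copies/uL upper limit of the dynamic range equals 4.25
   copies/droplet at the 0.85 nL droplet volume;
2. at 4.25 copies/droplet, the Poisson probability of a droplet holding
   more than 20 molecules is ~5.4e-9 (so truncating at k=20 is safe);
3. at 150 copies/uL (lambda = 0.1275) a positive droplet contains
   exactly one template with probability ~0.94 (the dilute regime in
   which the naive double-positive percentage is trustworthy).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .models import (
    DEFAULT_DROPLET_VOLUME_NL,
    DEFAULT_K_MAX,
    closed_form_single_positive_probability,
    copies_per_ul_to_lambda,
    solve_single_positive_probability,
)

__all__ = [
    "dynamic_range_copies_per_droplet",
    "tail_probability_beyond_kmax",
    "single_template_conditional_probability",
    "truncation_error_sweep",
    "selfcheck",
]


def dynamic_range_copies_per_droplet(
    copies_per_ul: float = 5000.0,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> float:
    """Copies/droplet at the instrument's dynamic-range ceiling."""
    return copies_per_ul_to_lambda(copies_per_ul, droplet_volume_nl)


def tail_probability_beyond_kmax(
    lam: float = 4.25, k_max: int = DEFAULT_K_MAX
) -> float:
    """P(K > k_max) for K ~ Poisson(lam)."""
    return float(stats.poisson.sf(k_max, lam))


def single_template_conditional_probability(
    copies_per_ul: float = 150.0,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> float:
    """P(exactly one template | at least one template) for a droplet.

    Equals ``lam * exp(-lam) / (1 - exp(-lam)) = lam / (exp(lam) - 1)``.
    """
    lam = copies_per_ul_to_lambda(copies_per_ul, droplet_volume_nl)
    return lam / math.expm1(lam)


def truncation_error_sweep(
    lam_grid=None,
    s_fractions=(0.05, 0.1, 0.25, 0.5, 0.75, 0.9, 0.99),
    k_max: int = DEFAULT_K_MAX,
) -> float:
    """Max |p_truncated - p_closed_form| over a (lambda, s) grid.

    ``s_fractions`` are fractions of each lambda's feasible range
    (0, 1 - exp(-lambda)).
    """
    if lam_grid is None:
        lam_grid = np.linspace(0.01, 4.25, 40)
    worst = 0.0
    for lam in lam_grid:
        s_max = 1.0 - math.exp(-lam)
        for f in s_fractions:
            s = f * s_max
            p_trunc = solve_single_positive_probability(s, lam, k_max=k_max)
            p_exact = closed_form_single_positive_probability(s, lam)
            worst = max(worst, abs(p_trunc - p_exact))
    return worst


def selfcheck() -> dict:
    """Run all analytic checks; each entry reports the computed value
    and whether it meets its tolerance."""
    conv = dynamic_range_copies_per_droplet()
    tail = tail_probability_beyond_kmax()
    single = single_template_conditional_probability()
    sweep = truncation_error_sweep()
    report = {
        "dynamic_range_copies_per_droplet": {
            "value": float(conv),
            "ok": bool(abs(conv - 4.25) < 1e-12),
        },
        "tail_probability_beyond_k20": {
            "value": float(tail),
            "ok": bool(abs(tail / 5.4e-9 - 1.0) < 0.05),  # 2 significant figures
        },
        "single_template_conditional_probability": {
            "value": float(single),
            "ok": bool(round(single, 2) == 0.94),
        },
        "max_truncation_error": {
            "value": float(sweep),
            "ok": bool(sweep < 1e-6),
        },
    }
    report["all_ok"] = all(v["ok"] for v in report.values() if isinstance(v, dict))
    return report
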