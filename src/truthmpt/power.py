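"""A-priori power analysis for parameter restrictions in MPT models.

The noncentrality parameter of the Delta G^2 test is obtained by the
expected-frequency method: generate the exact expected category counts
under the alternative-hypothesis parameter values, fit the restricted
(null) model to those noise-free data, and read off the resulting G^2
discrepancy.  Because expected counts scale linearly with the number of
participants, so does the noncentrality, and power at any sample size
follows from the noncentral chi-square distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy import optimize, stats

from .estimation import FrequencyTable, compile_model, fit
from .model_spec import ConstraintSet, ModelSpec, ParameterVector, category_probabilities
from .synthetic_data import DesignSpec

__all__ = [
    "PowerSpec",
    "PowerResult",
    "expected_table",
    "noncentrality",
    "power_at",
    "solve_noncentrality",
    "min_sample_size",
]


@dataclass
class PowerSpec:
    """Inputs of an a-priori power analysis for a parameter restriction."""

    model: ModelSpec
    params: ParameterVector  # generating values under H1
    restriction: ConstraintSet  # extra constraints defining H0
    design: DesignSpec
    alpha: float = 0.05
    target_power: float = 0.95
    effect_floor: float = 0.0  # minimum parameter difference of interest

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError("target_power must be in (0,1)")
        if self.effect_floor < 0:
            raise ValueError("effect floor must be >= 0")

    @property
    def df(self) -> int:
        general = compile_model(self.model).n_free
        restricted = compile_model(self.model, self.restriction).n_free
        return general - restricted


@dataclass
class PowerResult:
    """Noncentrality, power curve, and minimum sample size."""

    spec: PowerSpec
    df: int
    lambda_per_participant: float
    reference_n: int
    lambda_at_reference: float
    min_n: int | None = None
    power_curve: dict[int, float] = field(default_factory=dict)


def expected_table(
    model: ModelSpec,
    params: ParameterVector,
    design: DesignSpec,
    n_total: float | None = None,
) -> FrequencyTable:
    """Noise-free expected frequencies ``row total x category probability``.

    When ``n_total`` is given, group sizes are rescaled to that total
    keeping the design's allocation ratio (counts may be non-integral).
    """
    probs = category_probabilities(model, params)
    scale = 1.0 if n_total is None else n_total / design.n_total
    rows = []
    for group, cond, items in design.condition_items():
        n_g = design.groups[group].n_participants * scale
        tree_id = cond if group == "" else f"{cond}_{group}"
        tree = model.tree(tree_id)
        for cat, p in zip(tree.categories, probs[tree_id]):
            rows.append(
                {
                    "group": group,
                    "item_condition": cond,
                    "response": cat,
                    "count": n_g * items * p,
                }
            )
    import pandas as pd

    return FrequencyTable(pd.DataFrame(rows))


def noncentrality(spec: PowerSpec, n_participants: float | None = None) -> float:
    """Noncentrality of the restriction test at ``n_participants`` total.

    Fits the H0-restricted model to the expected frequencies generated
    under the H1 parameter values; the misfit G^2 is the noncentrality.
    Warns when the generating values already satisfy the restriction.
    """
    n_total = spec.design.n_total if n_participants is None else n_participants
    table = expected_table(spec.model, spec.params, spec.design, n_total)
    restricted = fit(
        spec.model,
        table,
        constraints=spec.restriction,
        starts=5,
        seed=0,
        tol=1e-14,
    )
    lam = max(restricted.g_squared, 0.0)
    if lam < 1e-8:
        warnings.warn(
            "generating parameters satisfy the tested restriction "
            f"(lambda = {lam:.3g}); the test has no power beyond alpha",
            RuntimeWarning,
        )
    return lam


def power_at(lam: float, df: int, alpha: float = 0.05) -> float:
    """Rejection probability of the chi-square test at noncentrality ``lam``."""
    if lam < 0:
        raise ValueError("noncentrality must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    if lam == 0:
        return float(alpha)
    crit = stats.chi2.ppf(1.0 - alpha, df)
    return float(stats.ncx2.sf(crit, df, lam))


def solve_noncentrality(df: int, alpha: float, power: float) -> float:
    """Noncentrality at which the test attains ``power`` (inverse of power_at)."""
    if not alpha < power < 1.0:
        raise ValueError("power must be in (alpha, 1)")
    hi = 1.0
    while power_at(hi, df, alpha) < power:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - defensive
            raise RuntimeError("failed to bracket noncentrality")
    return float(
        optimize.brentq(lambda l: power_at(l, df, alpha) - power, 0.0, hi, xtol=1e-10)
    )


def min_sample_size(
    spec: PowerSpec,
    max_n: int = 10_000_000,
) -> PowerResult:
    """Smallest total N reaching the target power for the restriction test.

    Uses the linearity lambda(N) = N * lambda(1) and monotonicity of power
    in lambda; group allocation is held at the design ratio.
    """
    df = spec.df
    if df < 1:
        raise ValueError("restriction removes no free parameters")
    ref_n = spec.design.n_total
    lam_ref = noncentrality(spec, ref_n)
    lam1 = lam_ref / ref_n
    result = PowerResult(
        spec=spec,
        df=df,
        lambda_per_participant=lam1,
        reference_n=ref_n,
        lambda_at_reference=lam_ref,
    )
    if lam1 <= 0:
        raise ValueError(
            "noncentrality is zero: the effect is not detectable at any N"
        )
    if spec.target_power <= spec.alpha:
        result.min_n = 1
        result.power_curve[1] = power_at(lam1, df, spec.alpha)
        return result
    lo, hi = 1, 1
    while power_at(hi * lam1, df, spec.alpha) < spec.target_power:
        lo, hi = hi, hi * 2
        if hi > max_n:
            raise ValueError(f"target power not reachable below N = {max_n}")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at(mid * lam1, df, spec.alpha) >= spec.target_power:
            hi = mid
        else:
            lo = mid + 1
    result.min_n = lo
    for n in sorted({1, ref_n, lo}):
        result.power_curve[n] = power_at(n * lam1, df, spec.alpha)
    return result
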