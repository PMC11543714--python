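"""Nested-model inference: likelihood-ratio (Delta G^2) tests.

Two nested MPT models are compared by the difference of their G^2
statistics, referred to a central chi-square with df equal to the number
of free parameters removed by the restriction.  The module also runs the
preregistered restriction ladder of the base-rate study (item-memory
restrictions, the feedback-memory test separating the Cartesian from the
Spinozan and expectation-violation accounts, and three guessing
restrictions) and the guessing-bias tests of ``a_true``/``g_true``
against .50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy import stats

from .estimation import FitResult, FrequencyTable, fit
from .model_spec import GROUPS, ConstraintSet, ModelSpec

__all__ = [
    "TestResult",
    "LadderReport",
    "delta_g_squared",
    "ladder_steps",
    "run_restriction_ladder",
    "test_guessing_bias",
]

_NEG_TOL = 1e-4


@dataclass
class TestResult:
    """A single Delta G^2 comparison of nested fits."""

    description: str
    delta_g_squared: float
    df: int
    p_value: float
    general_fit: FitResult
    restricted_fit: FitResult
    direction: str | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def row(self) -> dict:
        return {
            "test": self.description,
            "delta_g_squared": self.delta_g_squared,
            "df": self.df,
            "p_value": self.p_value,
        }


def delta_g_squared(general: FitResult, restricted: FitResult,
                    description: str = "") -> TestResult:
    """Likelihood-ratio test of ``restricted`` against nesting ``general``.

    Requires the restricted model's constraints to imply the general
    model's.  A Delta G^2 in [-1e-4, 0) is clamped to zero; anything more
    negative indicates a convergence or nesting failure and raises.
    """
    params = general.model.parameters
    if restricted.model.parameters != params:
        raise ValueError("models are not defined over the same parameters")
    if not restricted.constraints.implies(general.constraints, params):
        raise ValueError("restricted model does not nest the general model")
    df = general.n_free - restricted.n_free
    if df <= 0:
        raise ValueError("restriction removes no free parameters")
    delta = restricted.g_squared - general.g_squared
    if delta < -_NEG_TOL:
        raise RuntimeError(
            f"restricted fit beats general fit (Delta G^2 = {delta:.3g}); "
            "likely non-convergence of the general fit"
        )
    delta = max(delta, 0.0)
    return TestResult(
        description=description,
        delta_g_squared=delta,
        df=df,
        p_value=float(stats.chi2.sf(delta, df)),
        general_fit=general,
        restricted_fit=restricted,
    )


def ladder_steps(groups=GROUPS) -> list[tuple[str, ConstraintSet]]:
    """The preregistered restriction sequence for the two-group model.

    Steps (tested in order, each against the currently retained model):
    item memory equal across groups; item memory equal for "true" and
    "false" claims within groups; feedback memory equal for "true" and
    "false" within groups; equal "old"-guessing across groups; a- and
    g-family guessing equated within groups; feedback-presence guessing
    equal across groups.
    """
    g1, g2 = groups
    return [
        (
            "D equal across groups",
            ConstraintSet(
                [(f"D_{c}_{g1}", f"D_{c}_{g2}") for c in ("true", "false", "unchecked")]
            ),
        ),
        (
            "D_true = D_false within groups",
            ConstraintSet([(f"D_true_{g}", f"D_false_{g}") for g in groups]),
        ),
        (
            "d_true = d_false within groups",
            ConstraintSet([(f"d_true_{g}", f"d_false_{g}") for g in groups]),
        ),
        (
            "b equal across groups",
            ConstraintSet([(f"b_{g1}", f"b_{g2}")]),
        ),
        (
            "a_fb = g_fb and a_true = g_true within groups",
            ConstraintSet(
                [(f"a_fb_{g}", f"g_fb_{g}") for g in groups]
                + [(f"a_true_{g}", f"g_true_{g}") for g in groups]
            ),
        ),
        (
            "a_fb and g_fb equal across groups",
            ConstraintSet([(f"a_fb_{g1}", f"a_fb_{g2}"), (f"g_fb_{g1}", f"g_fb_{g2}")]),
        ),
    ]


@dataclass
class LadderReport:
    """Outcome of the preregistered restriction ladder."""

    base_fit: FitResult
    steps: list[TestResult]
    adopted: list[bool]
    alpha: float
    base_fit_adequate: bool
    retained_description: str = "base model"
    warnings: list[str] = field(default_factory=list)

    def table(self):
        import pandas as pd

        rows = []
        for t, a in zip(self.steps, self.adopted):
            rows.append({**t.row(), "adopted": a})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "base_fit": {
                "g_squared": self.base_fit.g_squared,
                "df": self.base_fit.df,
                "p_value": self.base_fit.p_value,
            },
            "base_fit_adequate": self.base_fit_adequate,
            "steps": [
                {**t.row(), "adopted": a}
                for t, a in zip(self.steps, self.adopted)
            ],
            "retained": self.retained_description,
            "warnings": list(self.warnings),
        }


def run_restriction_ladder(
    model: ModelSpec,
    data: FrequencyTable,
    alpha: float = 0.05,
    starts: int = 20,
    seed: int | None = None,
    groups=GROUPS,
) -> LadderReport:
    """Run the preregistered restriction ladder on a two-group dataset.

    Each restriction is refit from scratch with the full multistart
    protocol and tested against the currently retained model; it is
    adopted iff ``p >= alpha``, otherwise the previous model is kept.
    """
    report_warnings: list[str] = []
    base = fit(model, data, starts=starts, seed=seed)
    adequate = not (base.df > 0 and base.p_value < alpha)
    if not adequate:
        msg = (
            f"base model misfits the data (G^2({base.df}) = "
            f"{base.g_squared:.2f}, p = {base.p_value:.3f}); ladder run anyway"
        )
        report_warnings.append(msg)
        warnings.warn(msg, RuntimeWarning)

    retained = base
    retained_extra = ConstraintSet()
    retained_desc = "base model"
    results: list[TestResult] = []
    adopted: list[bool] = []
    for i, (name, step_cs) in enumerate(ladder_steps(groups)):
        trial_cs = retained_extra.merged(step_cs)
        restricted = fit(
            model,
            data,
            constraints=trial_cs,
            starts=starts,
            seed=None if seed is None else seed + i + 1,
        )
        test = delta_g_squared(retained, restricted, description=name)
        results.append(test)
        take = test.p_value >= alpha
        adopted.append(take)
        if take:
            retained = restricted
            retained_extra = trial_cs
            retained_desc = f"{retained_desc} + {name}"
    return LadderReport(
        base_fit=base,
        steps=results,
        adopted=adopted,
        alpha=alpha,
        base_fit_adequate=adequate,
        retained_description=retained_desc,
        warnings=report_warnings,
    )


def test_guessing_bias(
    model: ModelSpec,
    data: FrequencyTable,
    param: str,
    group: str | None = None,
    null: float = 0.50,
    starts: int = 20,
    seed: int | None = None,
    general: FitResult | None = None,
) -> TestResult:
    """One-df test of a guessing parameter against a point null (.50).

    ``param`` may be a bare family name (``a_true``/``g_true``) combined
    with ``group``, or a full suffixed name.  The reported ``direction``
    ("above"/"below") comes from the unconstrained estimate.
    """
    full = param if group is None else f"{param}_{group}"
    if full not in model.parameters:
        raise KeyError(f"parameter {full!r} not in model")
    if general is None:
        general = fit(model, data, starts=starts, seed=seed)
    restricted = fit(
        model,
        data,
        constraints=ConstraintSet(fixed={full: null}),
        starts=starts,
        seed=None if seed is None else seed + 1,
    )
    result = delta_g_squared(
        general, restricted, description=f"{full} = {null:g}"
    )
    estimate = general.estimates[full]
    result.direction = "above" if estimate > null else "below"
    return result
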