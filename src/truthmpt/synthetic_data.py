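"""Simulation of the two-group base-rate feedback-memory design.

Generates response frequencies (and optionally trial-level records) with
exactly the statistical structure the measurement model assumes: every
participant responds to old items carrying majority/minority/no veracity
feedback plus new items, and responses are multinomial draws from the
processing-tree category probabilities.  Includes generating regimes for
the three competing theoretical accounts (Cartesian, Spinozan,
expectation-violation) and a parameter-recovery driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .estimation import FrequencyTable, compile_model, fit
from .model_spec import (
    GROUPS,
    ConstraintSet,
    ModelSpec,
    ParameterVector,
    build_three_sources_model,
    category_probabilities,
)

__all__ = [
    "GroupDesign",
    "DesignSpec",
    "AccountSpec",
    "default_design",
    "account_parameters",
    "simulate",
    "parameter_recovery",
    "RecoveryReport",
]

ACCOUNTS = ("cartesian", "spinozan", "expectation_violation")


@dataclass(frozen=True)
class GroupDesign:
    """Per-group design: sample size and items per condition.

    The standard layout assigns 36 old items to the group's majority
    feedback type, 12 to the minority type, 12 unchecked, and 30 new test
    items.  ``items`` overrides the layout with an explicit
    condition -> items-per-participant mapping (used for toy models).
    """

    n_participants: float
    majority: str = "true"
    items_majority: int = 36
    items_minority: int = 12
    items_unchecked: int = 12
    items_new: int = 30
    items: Mapping[str, int] | None = None

    def items_per_condition(self) -> dict[str, int]:
        if self.items is not None:
            return dict(self.items)
        if self.majority not in ("true", "false"):
            raise ValueError("majority feedback must be 'true' or 'false'")
        minority = "false" if self.majority == "true" else "true"
        return {
            f"old_{self.majority}": self.items_majority,
            f"old_{minority}": self.items_minority,
            "old_unchecked": self.items_unchecked,
            "new": self.items_new,
        }


@dataclass(frozen=True)
class DesignSpec:
    """The full between/within design driving simulation and power."""

    groups: Mapping[str, GroupDesign]

    @property
    def n_total(self) -> float:
        return sum(g.n_participants for g in self.groups.values())

    def condition_items(self) -> Iterator[tuple[str, str, int]]:
        for group, gd in self.groups.items():
            for cond, items in gd.items_per_condition().items():
                yield group, cond, items

    def row_totals(self) -> dict[tuple[str, str], float]:
        return {
            (g, c): self.groups[g].n_participants * items
            for g, c, items in self.condition_items()
        }


def default_design(n_htb: int = 103, n_hfb: int = 105) -> DesignSpec:
    """The study design: HTB majority-"true", HFB majority-"false"."""
    return DesignSpec(
        {
            "HTB": GroupDesign(n_htb, majority="true"),
            "HFB": GroupDesign(n_hfb, majority="false"),
        }
    )


@dataclass(frozen=True)
class AccountSpec:
    """Generating regime for one of the three theoretical accounts.

    Base levels sit near the magnitudes observed in the study: item memory
    ``D = .55``, feedback memory ``d = .60``, old-guessing ``b = .27``,
    feedback-presence guessing ``a_fb = .66`` / ``g_fb = .77``, and a
    "true"-guessing bias of .70 in the majority-"true" group versus .30 in
    the majority-"false" group.  The accounts differ only in the pattern
    they impose on the feedback-memory parameters: the Cartesian account
    tags truth and falsity alike (``d_true = d_false``), the Spinozan
    account tags only falsity (``d_true = 0``), and the
    expectation-violation account tags whatever feedback is unexpected,
    i.e. ``d`` is larger for each group's minority feedback type.
    """

    account: str
    D: float = 0.55
    d: float = 0.60
    d_unchecked: float = 0.30
    b: float = 0.27
    a_fb: float = 0.66
    g_fb: float = 0.77
    true_bias_majority_true: float = 0.70
    true_bias_majority_false: float = 0.30
    delta: float = 0.15
    spinozan_d_unchecked: float = 0.0

    def __post_init__(self) -> None:
        if self.account not in ACCOUNTS:
            raise ValueError(f"unknown account {self.account!r}; one of {ACCOUNTS}")


def account_parameters(
    spec: AccountSpec,
    design: DesignSpec | None = None,
) -> ParameterVector:
    """Full two-group base-model parameter vector for an account."""
    design = design or default_design()
    values: dict[str, float] = {}
    for group, gd in design.groups.items():
        sfx = f"_{group}"
        bias = (
            spec.true_bias_majority_true
            if gd.majority == "true"
            else spec.true_bias_majority_false
        )
        if spec.account == "cartesian":
            d_true, d_false, d_unch = spec.d, spec.d, spec.d_unchecked
        elif spec.account == "spinozan":
            d_true, d_false, d_unch = 0.0, spec.d, spec.spinozan_d_unchecked
        else:  # expectation_violation: minority feedback is tagged better
            if gd.majority == "true":
                d_true, d_false = spec.d - spec.delta, spec.d
            else:
                d_true, d_false = spec.d, spec.d - spec.delta
            d_unch = spec.d_unchecked
        values.update(
            {
                f"D_true{sfx}": spec.D,
                f"D_false{sfx}": spec.D,
                f"D_unchecked{sfx}": spec.D,
                f"D_new{sfx}": spec.D,
                f"d_true{sfx}": d_true,
                f"d_false{sfx}": d_false,
                f"d_unchecked{sfx}": d_unch,
                f"b{sfx}": spec.b,
                f"a_fb{sfx}": spec.a_fb,
                f"a_true{sfx}": bias,
                f"g_fb{sfx}": spec.g_fb,
                f"g_true{sfx}": bias,
            }
        )
    return ParameterVector(values)


def _model_for(design: DesignSpec, model: ModelSpec | None) -> ModelSpec:
    if model is not None:
        return model
    labels = tuple(design.groups)
    if set(labels) == set(GROUPS):
        return build_three_sources_model(True)
    if labels == ("",):
        return build_three_sources_model(False)
    return build_three_sources_model(True, groups=labels)


def _logit_jitter(values: dict[str, float], sd: float, rng) -> dict[str, float]:
    out = {}
    for k, v in values.items():
        v = min(max(v, 1e-9), 1 - 1e-9)
        z = np.log(v / (1 - v)) + rng.normal(0.0, sd)
        out[k] = 1.0 / (1.0 + np.exp(-z))
    return out


def simulate(
    design: DesignSpec,
    params: ParameterVector | Mapping[str, float],
    seed: int | None = None,
    model: ModelSpec | None = None,
    trial_level: bool = False,
    heterogeneity_sd: float = 0.0,
) -> FrequencyTable | tuple[FrequencyTable, pd.DataFrame]:
    """Sample a response-frequency table from the processing-tree model.

    Counts for each (group, condition) row are multinomial with total
    ``n_participants x items``.  With ``trial_level=True`` the function
    samples participant by participant and also returns the long-form
    trial records whose aggregation equals the returned table.
    ``heterogeneity_sd`` > 0 adds per-participant logit-normal jitter to
    all parameters (off by default: the measurement model itself assumes
    homogeneous participants).
    """
    model = _model_for(design, model)
    rng = np.random.default_rng(seed)
    values = model.expand_parameters(params)
    if not trial_level and heterogeneity_sd == 0.0:
        probs = category_probabilities(model, params)
        rows = []
        for group, cond, items in design.condition_items():
            tree_id = cond if group == "" else f"{cond}_{group}"
            total = round(design.groups[group].n_participants * items)
            counts = rng.multinomial(total, probs[tree_id])
            tree = model.tree(tree_id)
            rows.extend(
                {
                    "group": group,
                    "item_condition": cond,
                    "response": cat,
                    "count": int(n),
                }
                for cat, n in zip(tree.categories, counts)
            )
        return FrequencyTable(pd.DataFrame(rows))

    records = []
    for group, gd in design.groups.items():
        n_part = round(gd.n_participants)
        for i in range(n_part):
            pid = f"{group}_{i + 1:03d}" if group else f"p{i + 1:03d}"
            pvals = (
                _logit_jitter(values, heterogeneity_sd, rng)
                if heterogeneity_sd > 0
                else values
            )
            for cond, items in gd.items_per_condition().items():
                tree_id = cond if group == "" else f"{cond}_{group}"
                tree = model.tree(tree_id)
                p = tree.category_probabilities(pvals)
                counts = rng.multinomial(items, p)
                for cat, n in zip(tree.categories, counts):
                    records.extend(
                        {
                            "participant": pid,
                            "group": group,
                            "item_condition": cond,
                            "response": cat,
                        }
                        for _ in range(int(n))
                    )
    trials = pd.DataFrame(records)
    agg = trials.groupby(
        ["group", "item_condition", "response"], as_index=False
    ).size().rename(columns={"size": "count"})
    table = FrequencyTable(agg)
    return table, trials


@dataclass
class RecoveryReport:
    """Aggregate outcome of a simulate-and-refit study."""

    frame: pd.DataFrame  # per free parameter: truth, mean, bias, rmse, coverage
    n_reps: int
    n_failures: int
    design: DesignSpec

    @property
    def max_abs_bias(self) -> float:
        return float(self.frame["bias"].abs().max())

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "n_failures": self.n_failures,
            "parameters": self.frame.to_dict(orient="records"),
        }


def parameter_recovery(
    design: DesignSpec,
    params: ParameterVector | Mapping[str, float],
    n_reps: int,
    seed: int | None = None,
    model: ModelSpec | None = None,
    starts: int = 2,
    constraints: ConstraintSet | None = None,
) -> RecoveryReport:
    """Simulate-and-refit study: bias, RMSE, and 95% CI coverage.

    Each replicate draws a fresh dataset from ``params`` under ``design``
    and refits the model; failures (exceptions) are counted, not raised.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    model = _model_for(design, model)
    compiled = compile_model(model, constraints)
    truth_full = model.expand_parameters(params, constraints)
    truth = np.array([truth_full[name] for name in compiled.free_names])

    rng = np.random.default_rng(seed)
    estimates = []
    covered = []
    failures = 0
    for _ in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        table = simulate(design, params, seed=rep_seed, model=model)
        try:
            res = fit(
                model,
                table,
                constraints=constraints,
                starts=starts,
                seed=rep_seed,
                compiled=compiled,
            )
        except Exception:
            failures += 1
            continue
        estimates.append(res.free_estimates)
        covered.append(
            [
                res.ci95[name][0] <= t <= res.ci95[name][1]
                for name, t in zip(compiled.free_names, truth)
            ]
        )
    est = np.array(estimates)
    cov = np.array(covered, dtype=float)
    frame = pd.DataFrame(
        {
            "parameter": compiled.free_names,
            "truth": truth,
            "mean_estimate": est.mean(axis=0),
            "bias": est.mean(axis=0) - truth,
            "rmse": np.sqrt(((est - truth) ** 2).mean(axis=0)),
            "coverage": cov.mean(axis=0),
        }
    )
    return RecoveryReport(
        frame=frame, n_reps=n_reps, n_failures=failures, design=design
    )
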