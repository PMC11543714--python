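"""Maximum-likelihood estimation for MPT models.

Fitting follows the classic expectation-maximization scheme for binary MPT
models: the E-step distributes each observed category count over the
branches ending in that category in proportion to their current branch
probabilities, and the M-step re-estimates every free parameter as its
expected success ratio.  EM respects the [0,1] parameter space natively and
increases the likelihood monotonically; a bounded quasi-Newton polish step
(L-BFGS-B with analytic gradients) sharpens the final optimum.

Goodness of fit is the likelihood-ratio statistic
``G^2 = 2 * sum n * ln(n / e)`` with ``0 * ln 0 = 0``, referred to a
chi-square distribution with ``df = (free category proportions) - (free
parameters)``.  Standard errors come from the expected Fisher information
evaluated at the estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model_spec import (
    ConstraintSet,
    ModelSpec,
    ParameterVector,
)

__all__ = [
    "FrequencyTable",
    "FitResult",
    "IdentifiabilityResult",
    "CompiledModel",
    "compile_model",
    "fit",
    "g_squared",
    "confidence_intervals",
    "check_identifiability",
]

_EPS = 1e-6  # parameter clamp during optimization
_BOUNDARY_TOL = 1e-4


class FrequencyTable:
    """Observed response counts per (group, item condition, response).

    Counts are stored long-form.  ``group`` may be the empty string for
    single-group models; tree ids are ``condition`` or ``condition_group``,
    matching :func:`truthmpt.model_spec.build_three_sources_model`.
    Non-integral counts are accepted (expected-frequency tables used by the
    power module are real-valued); the simulator always produces integers.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"group", "item_condition", "response", "count"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"frequency table missing columns {sorted(missing)}")
        frame = frame.copy()
        frame["group"] = frame["group"].fillna("").astype(str)
        if (frame["count"] < 0).any():
            raise ValueError("negative counts in frequency table")
        self.frame = (
            frame.groupby(["group", "item_condition", "response"], as_index=False)[
                "count"
            ].sum()
        )

    @classmethod
    def from_counts(
        cls, counts: Mapping[tuple[str, str, str], float]
    ) -> "FrequencyTable":
        rows = [
            {"group": g, "item_condition": c, "response": r, "count": n}
            for (g, c, r), n in counts.items()
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path) -> "FrequencyTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def is_integral(self) -> bool:
        return bool(np.allclose(self.frame["count"] % 1.0, 0.0))

    def tree_id(self, group: str, condition: str) -> str:
        return condition if group == "" else f"{condition}_{group}"

    def row_totals(self) -> dict[tuple[str, str], float]:
        g = self.frame.groupby(["group", "item_condition"])["count"].sum()
        return {k: float(v) for k, v in g.items()}

    def counts_for(self, model: ModelSpec) -> np.ndarray:
        """Counts aligned to the model's (tree, category) cell order."""
        lookup = {
            (r.group, r.item_condition, r.response): r.count
            for r in self.frame.itertuples()
        }
        by_tree: dict[str, dict[str, float]] = {}
        for (g, c, r), n in lookup.items():
            by_tree.setdefault(self.tree_id(g, c), {})[r] = n
        out = []
        for t in model.trees:
            cells = by_tree.get(t.tree_id, {})
            unknown = set(cells) - set(t.categories)
            if unknown:
                raise ValueError(
                    f"responses {sorted(unknown)} not among categories of "
                    f"tree {t.tree_id!r}"
                )
            out.extend(cells.get(cat, 0.0) for cat in t.categories)
        return np.asarray(out, dtype=float)


@dataclass
class CompiledModel:
    """Matrix form of an MPT model for fast repeated evaluation.

    Branch probabilities are ``const * prod theta^A * (1-theta)^B`` over
    the free parameters; ``const`` absorbs factors whose parameter is fixed
    by a constraint.
    """

    model: ModelSpec
    constraints: ConstraintSet
    free_names: tuple[str, ...]
    A: np.ndarray  # (n_branches, n_free) direct-factor exponents
    B: np.ndarray  # (n_branches, n_free) complement-factor exponents
    const: np.ndarray  # (n_branches,)
    branch_cell: np.ndarray  # global cell index per branch
    cell_tree: np.ndarray  # tree index per cell
    n_cells: int
    tree_cells: list[tuple[str, slice]]

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def cell_probabilities(self, theta: np.ndarray) -> np.ndarray:
        bp = self.branch_probabilities(theta)
        p = np.zeros(self.n_cells)
        np.add.at(p, self.branch_cell, bp)
        return p

    def branch_probabilities(self, theta: np.ndarray) -> np.ndarray:
        if self.n_free == 0:
            return self.const.copy()
        th = np.clip(theta, 1e-300, 1.0)
        om = np.clip(1.0 - theta, 1e-300, 1.0)
        return self.const * np.exp(self.A @ np.log(th) + self.B @ np.log(om))

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        """d cell_prob / d theta, shape (n_cells, n_free)."""
        bp = self.branch_probabilities(theta)
        th = np.clip(theta, _EPS, 1.0 - _EPS)
        w = self.A / th - self.B / (1.0 - th)  # (n_branches, n_free)
        J = np.zeros((self.n_cells, self.n_free))
        np.add.at(J, self.branch_cell, bp[:, None] * w)
        return J


def compile_model(
    model: ModelSpec, extra_constraints: ConstraintSet | None = None
) -> CompiledModel:
    cs = model.constraints.merged(extra_constraints)
    rep, fix = cs.resolve(model.parameters)
    free_names = tuple(model.free_parameters(extra_constraints))
    free_index = {p: i for i, p in enumerate(free_names)}

    rows_A, rows_B, const, branch_cell = [], [], [], []
    cell_tree: list[int] = []
    tree_cells: list[tuple[str, slice]] = []
    offset = 0
    for ti, tree in enumerate(model.trees):
        cat_index = {c: offset + i for i, c in enumerate(tree.categories)}
        tree_cells.append((tree.tree_id, slice(offset, offset + len(tree.categories))))
        cell_tree.extend([ti] * len(tree.categories))
        offset += len(tree.categories)
        for b in tree.branches:
            a = np.zeros(len(free_names))
            bb = np.zeros(len(free_names))
            c = 1.0
            for name, direct in b.factors:
                r = rep[name]
                if r in fix:
                    v = fix[r]
                    c *= v if direct else 1.0 - v
                elif direct:
                    a[free_index[r]] += 1
                else:
                    bb[free_index[r]] += 1
            rows_A.append(a)
            rows_B.append(bb)
            const.append(c)
            branch_cell.append(cat_index[b.category])
    return CompiledModel(
        model=model,
        constraints=cs,
        free_names=free_names,
        A=np.array(rows_A),
        B=np.array(rows_B),
        const=np.array(const),
        branch_cell=np.array(branch_cell, dtype=int),
        cell_tree=np.array(cell_tree, dtype=int),
        n_cells=offset,
        tree_cells=tree_cells,
    )


def g_squared(counts: np.ndarray, expected: np.ndarray) -> float:
    """Likelihood-ratio statistic ``2 sum n ln(n/e)`` with ``0 ln 0 = 0``."""
    counts = np.asarray(counts, dtype=float)
    expected = np.asarray(expected, dtype=float)
    mask = counts > 0
    if np.any(expected[mask] <= 0):
        return float("inf")
    return float(2.0 * np.sum(counts[mask] * np.log(counts[mask] / expected[mask])))


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    model: ModelSpec
    constraints: ConstraintSet
    free_names: tuple[str, ...]
    free_estimates: np.ndarray
    estimates: ParameterVector
    log_likelihood: float
    g_squared: float
    df: int
    p_value: float
    std_errors: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    n_starts: int
    starts_agree: bool
    iterations: int
    converged: bool
    boundary: tuple[str, ...] = ()
    information_singular: bool = False
    counts: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.free_names:
            lo, hi = self.ci95[name]
            rows.append(
                {
                    "parameter": name,
                    "estimate": float(
                        self.free_estimates[self.free_names.index(name)]
                    ),
                    "se": self.std_errors[name],
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "boundary": name in self.boundary,
                }
            )
        return pd.DataFrame(rows)


def _loglik(compiled: CompiledModel, counts: np.ndarray, theta: np.ndarray) -> float:
    p = compiled.cell_probabilities(theta)
    mask = counts > 0
    if np.any(p[mask] <= 0):
        return -np.inf
    return float(np.sum(counts[mask] * np.log(p[mask])))


def _em(
    compiled: CompiledModel,
    counts: np.ndarray,
    theta0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    track: list[float] | None = None,
) -> tuple[np.ndarray, float, int, bool]:
    theta = np.clip(theta0, _EPS, 1.0 - _EPS)
    ll = _loglik(compiled, counts, theta)
    if track is not None:
        track.append(ll)
    for it in range(1, max_iter + 1):
        bp = compiled.branch_probabilities(theta)
        p = np.zeros(compiled.n_cells)
        np.add.at(p, compiled.branch_cell, bp)
        ratio = np.divide(counts, p, out=np.zeros_like(p), where=p > 0)
        m = bp * ratio[compiled.branch_cell]  # expected branch counts
        S = compiled.A.T @ m
        F = compiled.B.T @ m
        denom = S + F
        new = np.where(denom > 0, S / np.maximum(denom, 1e-300), theta)
        theta = np.clip(new, _EPS, 1.0 - _EPS)
        new_ll = _loglik(compiled, counts, theta)
        if track is not None:
            track.append(new_ll)
        if abs(new_ll - ll) <= tol * (abs(ll) + 1e-12):
            return theta, new_ll, it, True
        ll = new_ll
    return theta, ll, max_iter, False


def _heuristic_start(compiled: CompiledModel, counts: np.ndarray) -> np.ndarray:
    """Moment-style start for the three-sources model; 0.5 elsewhere.

    Uses observed response rates: the "new"-response rate in the new tree
    and the old trees pins D and b, the feedback-response split among
    false alarms pins g_fb/g_true.  Falls back to 0.5 per parameter when
    the model is not the three-sources layout.
    """
    theta = np.full(compiled.n_free, 0.5)
    model = compiled.model
    by_tree: dict[str, np.ndarray] = {}
    for tree_id, sl in compiled.tree_cells:
        n = counts[sl]
        tot = n.sum()
        if tot > 0:
            by_tree[tree_id] = n / tot
    idx = {p: i for i, p in enumerate(compiled.free_names)}

    def setp(name: str, value: float) -> None:
        if name in idx and np.isfinite(value):
            theta[idx[name]] = float(np.clip(value, 0.05, 0.95))

    suffixes = sorted(
        {tid.removeprefix("new") for tid in by_tree if tid.startswith("new")}
    )
    for sfx in suffixes:
        new_p = by_tree.get("new" + sfx)
        unch_p = by_tree.get("old_unchecked" + sfx)
        if new_p is None:
            continue
        resp = {c: new_p[i] for i, c in enumerate(model.tree("new" + sfx).categories)}
        fb = resp.get("true", 0) + resp.get("false", 0)
        old_guess = fb + resp.get("unchecked", 0) - (
            unch_p[3] if unch_p is not None else 0.0
        )
        setp("g_fb" + sfx, fb / max(fb + resp.get("unchecked", 0), 1e-9))
        setp("g_true" + sfx, resp.get("true", 0) / max(fb, 1e-9))
        if unch_p is not None:
            # with D_new = D_unchecked: P(new|new) - P(new|unchecked) = D
            D_u = resp.get("new", 0) - unch_p[3]
            setp("D_unchecked" + sfx, D_u)
            D_u = float(np.clip(D_u, 0.05, 0.95))
            b = 1.0 - unch_p[3] / max(1.0 - D_u, 1e-9)
            setp("b" + sfx, b)
            b = float(np.clip(b, 0.05, 0.95))
            for short in ("true", "false"):
                tp = by_tree.get(f"old_{short}" + sfx)
                if tp is None:
                    continue
                D_c = 1.0 - tp[3] / max(1.0 - b, 1e-9)
                setp(f"D_{short}" + sfx, D_c)
                D_c = float(np.clip(D_c, 0.05, 0.95))
                correct = tp[0] if short == "true" else tp[1]
                base = resp.get(short, 0)
                setp(f"d_{short}" + sfx, (correct - base) / max(D_c, 1e-9))
            if "d_unchecked" + sfx in idx:
                setp("d_unchecked" + sfx,
                     (unch_p[2] - resp.get("unchecked", 0)) / max(D_u, 1e-9))
        setp("a_fb" + sfx, theta[idx["g_fb" + sfx]] if "g_fb" + sfx in idx else 0.5)
        setp("a_true" + sfx,
             theta[idx["g_true" + sfx]] if "g_true" + sfx in idx else 0.5)
    return theta


def fit(
    model: ModelSpec,
    data: FrequencyTable | np.ndarray,
    constraints: ConstraintSet | None = None,
    starts: int = 20,
    seed: int | None = None,
    polish: bool = True,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    compiled: CompiledModel | None = None,
) -> FitResult:
    """Fit ``model`` to ``data`` by maximum likelihood.

    Runs EM from ``starts`` random interior initializations plus one
    moment-style heuristic start, keeps the best optimum, and (by default)
    polishes it with bounded L-BFGS-B.  ``data`` may be a
    :class:`FrequencyTable` or a pre-aligned cell-count vector.
    """
    if starts < 1:
        raise ValueError("starts must be >= 1")
    if compiled is None:
        compiled = compile_model(model, constraints)
    counts = data.counts_for(model) if isinstance(data, FrequencyTable) else (
        np.asarray(data, dtype=float)
    )
    if counts.shape != (compiled.n_cells,):
        raise ValueError(
            f"count vector has {counts.shape} cells, model has {compiled.n_cells}"
        )
    totals = np.zeros(compiled.cell_tree.max() + 1)
    np.add.at(totals, compiled.cell_tree, counts)
    if np.any(totals <= 0):
        empty = [model.trees[i].tree_id for i in np.nonzero(totals <= 0)[0]]
        raise ValueError(f"zero total count for tree(s) {empty}")

    rng = np.random.default_rng(seed)
    inits = [_heuristic_start(compiled, counts)]
    inits.extend(
        rng.uniform(0.05, 0.95, size=compiled.n_free) for _ in range(starts)
    )

    results = []
    converged_any = compiled.n_free == 0
    total_iter = 0
    if compiled.n_free == 0:
        theta_best = np.empty(0)
        ll_best = _loglik(compiled, counts, theta_best)
    else:
        for theta0 in inits:
            theta, ll, iters, conv = _em(compiled, counts, theta0, tol, max_iter)
            results.append((ll, theta, conv))
            total_iter += iters
            converged_any = converged_any or conv
        results.sort(key=lambda r: -r[0])
        ll_best, theta_best, _ = results[0]

        # flat-likelihood symptom: near-tied optima with diverging estimates
        near = [th for ll, th, _ in results if ll >= ll_best - 1e-4]
        spread = max(
            (float(np.max(np.abs(th - theta_best))) for th in near), default=0.0
        )

        if polish:
            def objective(th: np.ndarray) -> tuple[float, np.ndarray]:
                p = compiled.cell_probabilities(th)
                mask = counts > 0
                nll = -float(np.sum(counts[mask] * np.log(np.maximum(p[mask], 1e-300))))
                grad_p = np.zeros_like(p)
                grad_p[mask] = -counts[mask] / np.maximum(p[mask], 1e-300)
                return nll, compiled.jacobian(th).T @ grad_p

            res = optimize.minimize(
                objective,
                theta_best,
                jac=True,
                method="L-BFGS-B",
                bounds=[(_EPS, 1.0 - _EPS)] * compiled.n_free,
                options={"ftol": 1e-15, "gtol": 1e-10, "maxiter": 1000},
            )
            if np.isfinite(res.fun) and -res.fun > ll_best:
                ll_best, theta_best = -float(res.fun), np.asarray(res.x)
    if not converged_any:
        warnings.warn(
            "EM did not meet the convergence tolerance from any start",
            RuntimeWarning,
        )

    expected = totals[compiled.cell_tree] * compiled.cell_probabilities(theta_best)
    g2 = g_squared(counts, expected)
    df = model.n_free_category_proportions - compiled.n_free
    p_value = float(stats.chi2.sf(g2, df)) if df > 0 else float("nan")

    se, ci, singular = _wald_intervals(compiled, counts, totals, theta_best)
    boundary = tuple(
        name
        for name, v in zip(compiled.free_names, theta_best)
        if v <= _EPS + _BOUNDARY_TOL or v >= 1.0 - _EPS - _BOUNDARY_TOL
    )
    full = model.expand_parameters(
        dict(zip(compiled.free_names, theta_best)), constraints
    )
    return FitResult(
        model=model,
        constraints=compiled.constraints,
        free_names=compiled.free_names,
        free_estimates=theta_best,
        estimates=ParameterVector(full),
        log_likelihood=ll_best,
        g_squared=g2,
        df=df,
        p_value=p_value,
        std_errors=se,
        ci95=ci,
        n_starts=starts + 1,
        starts_agree=(compiled.n_free == 0 or spread <= 0.01),
        iterations=total_iter,
        converged=converged_any,
        boundary=boundary,
        information_singular=singular,
        counts=counts,
    )


def _wald_intervals(
    compiled: CompiledModel,
    counts: np.ndarray,
    totals: np.ndarray,
    theta: np.ndarray,
    level: float = 0.95,
) -> tuple[dict[str, float], dict[str, tuple[float, float]], bool]:
    if compiled.n_free == 0:
        return {}, {}, False
    J = compiled.jacobian(theta)
    p = np.maximum(compiled.cell_probabilities(theta), 1e-12)
    w = totals[compiled.cell_tree] / p
    info = J.T @ (w[:, None] * J)
    singular = False
    try:
        cov = np.linalg.inv(info)
        if np.any(np.diag(cov) < 0) or not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        singular = True
        cov = np.full((compiled.n_free, compiled.n_free), np.nan)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = {
        name: float(np.sqrt(cov[i, i])) if np.isfinite(cov[i, i]) else float("nan")
        for i, name in enumerate(compiled.free_names)
    }
    ci = {}
    for i, name in enumerate(compiled.free_names):
        s = se[name]
        if np.isfinite(s):
            ci[name] = (
                float(max(0.0, theta[i] - z * s)),
                float(min(1.0, theta[i] + z * s)),
            )
        else:
            ci[name] = (float("nan"), float("nan"))
    return se, ci, singular


def confidence_intervals(
    fit_result: FitResult, level: float = 0.95
) -> dict[str, tuple[float, float]]:
    """Wald intervals ``estimate +/- z*SE``, truncated to [0, 1]."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = {}
    for i, name in enumerate(fit_result.free_names):
        s = fit_result.std_errors[name]
        th = fit_result.free_estimates[i]
        if np.isfinite(s):
            out[name] = (float(max(0.0, th - z * s)), float(min(1.0, th + z * s)))
        else:
            out[name] = (float("nan"), float("nan"))
    return out


@dataclass
class IdentifiabilityResult:
    rank: int
    n_free: int
    deficient: bool
    points_checked: int
    #: largest (over points) minimum singular value of the Jacobian; values
    #: near zero signal practical non-identifiability even at full rank
    min_singular_value: float = float("nan")


def check_identifiability(
    model: ModelSpec,
    constraints: ConstraintSet | None = None,
    n_points: int = 10,
    seed: int | None = 0,
) -> IdentifiabilityResult:
    """Local identifiability via the numerical Jacobian rank.

    Evaluates the Jacobian of all category probabilities with respect to
    the free parameters at ``n_points`` random interior points and takes
    the maximum rank; the model is flagged deficient when that rank stays
    below the free-parameter count.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    compiled = compile_model(model, constraints)
    if compiled.n_free == 0:
        return IdentifiabilityResult(0, 0, False, n_points, float("inf"))
    rng = np.random.default_rng(seed)
    best = 0
    best_min_sv = 0.0
    for _ in range(n_points):
        theta = rng.uniform(0.1, 0.9, size=compiled.n_free)
        J = compiled.jacobian(theta)
        sv = np.linalg.svd(J, compute_uv=False)
        tol = sv[0] * max(J.shape) * np.finfo(float).eps
        best = max(best, int(np.sum(sv > tol)))
        best_min_sv = max(best_min_sv, float(sv[-1]))
    return IdentifiabilityResult(
        rank=best,
        n_free=compiled.n_free,
        deficient=best < compiled.n_free,
        points_checked=n_points,
        min_singular_value=best_min_sv,
    )
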