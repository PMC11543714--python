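"""Multinomial processing tree (MPT) model structures.

An MPT model expresses the probability of each discrete response category as
a sum of branch probabilities, where each branch is a product of latent
process probabilities ``theta`` or their complements ``1 - theta``.  This
module provides the generic containers (trees, branches, parameter vectors,
equality/fixed-value constraints), the two-high-threshold three-sources
model used to measure memory for "true"/"false" veracity feedback, and
read/write support for the classic ``.eqn`` model-file dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RESPONSES",
    "CONDITIONS",
    "GROUPS",
    "BranchTerm",
    "TreeSpec",
    "ConstraintSet",
    "ParameterVector",
    "ModelSpec",
    "build_three_sources_model",
    "category_probabilities",
    "read_eqn",
    "write_eqn",
]

#: Response alternatives in the feedback memory test.
RESPONSES = ("true", "false", "unchecked", "new")
#: Item conditions (= processing trees) of the design.
CONDITIONS = ("old_true", "old_false", "old_unchecked", "new")
#: Base-rate groups: high-"true" and high-"false" base rate.
GROUPS = ("HTB", "HFB")


@dataclass(frozen=True)
class BranchTerm:
    """One branch of a processing tree.

    ``factors`` is an ordered tuple of ``(parameter_name, direct)`` pairs;
    ``direct=True`` contributes ``theta``, ``direct=False`` contributes
    ``1 - theta``.  The branch terminates in a single response ``category``.
    """

    factors: tuple[tuple[str, bool], ...]
    category: str

    def probability(self, values: Mapping[str, float]) -> float:
        p = 1.0
        for name, direct in self.factors:
            v = values[name]
            p *= v if direct else 1.0 - v
        return p

    def expression(self) -> str:
        if not self.factors:
            return "1"
        return "*".join(
            name if direct else f"(1-{name})" for name, direct in self.factors
        )


@dataclass(frozen=True)
class TreeSpec:
    """A processing tree: one item condition with its response categories."""

    tree_id: str
    categories: tuple[str, ...]
    branches: tuple[BranchTerm, ...]

    def __post_init__(self) -> None:
        if not self.branches:
            raise ValueError(f"tree {self.tree_id!r} has no branches")
        extra = {b.category for b in self.branches} - set(self.categories)
        if extra:
            raise ValueError(
                f"tree {self.tree_id!r}: branches reference undeclared "
                f"categories {sorted(extra)}"
            )

    @property
    def parameters(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for b in self.branches:
            for name, _ in b.factors:
                seen.setdefault(name)
        return tuple(seen)

    def category_probabilities(self, values: Mapping[str, float]) -> np.ndarray:
        out = np.zeros(len(self.categories))
        index = {c: i for i, c in enumerate(self.categories)}
        for b in self.branches:
            out[index[b.category]] += b.probability(values)
        return out


class ConstraintSet:
    """Equality constraints (``a = b``) and fixed values (``a = c``).

    Constraints are resolved by union--find into equivalence classes; each
    class is either *free* (represented by one canonical parameter) or
    *fixed* to a constant.  Inconsistent constant assignments raise.
    """

    def __init__(
        self,
        equalities: Iterable[tuple[str, str]] = (),
        fixed: Mapping[str, float] | None = None,
    ) -> None:
        self.equalities: list[tuple[str, str]] = [tuple(e) for e in equalities]
        self.fixed: dict[str, float] = dict(fixed or {})
        for name, value in self.fixed.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"fixed value for {name!r} outside [0,1]: {value}")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ConstraintSet(equalities={self.equalities!r}, fixed={self.fixed!r})"

    def copy(self) -> "ConstraintSet":
        return ConstraintSet(self.equalities, self.fixed)

    def merged(self, other: "ConstraintSet | None") -> "ConstraintSet":
        if other is None:
            return self.copy()
        return ConstraintSet(
            self.equalities + other.equalities, {**self.fixed, **other.fixed}
        )

    def resolve(
        self, parameters: Sequence[str]
    ) -> tuple[dict[str, str], dict[str, float]]:
        """Return ``(representative, fixed_value)`` maps over ``parameters``.

        ``representative[p]`` is the canonical member (first in declaration
        order) of p's equality class; ``fixed_value[rep]`` is set when the
        class is pinned to a constant.
        """
        order = {p: i for i, p in enumerate(parameters)}
        parent: dict[str, str] = {p: p for p in parameters}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in self.equalities:
            for name in (a, b):
                if name not in parent:
                    raise KeyError(f"constraint references unknown parameter {name!r}")
            ra, rb = find(a), find(b)
            if ra != rb:
                # keep the earliest-declared name as the representative
                keep, drop = (ra, rb) if order[ra] <= order[rb] else (rb, ra)
                parent[drop] = keep
        fixed_value: dict[str, float] = {}
        for name, value in self.fixed.items():
            if name not in parent:
                raise KeyError(f"fixed constraint on unknown parameter {name!r}")
            rep = find(name)
            if rep in fixed_value and abs(fixed_value[rep] - value) > 1e-12:
                raise ValueError(
                    f"inconsistent constants for parameter class of {rep!r}: "
                    f"{fixed_value[rep]} vs {value}"
                )
            fixed_value[rep] = value
        representative = {p: find(p) for p in parameters}
        return representative, fixed_value

    def implies(self, other: "ConstraintSet", parameters: Sequence[str]) -> bool:
        """True if every constraint in ``other`` is implied by ``self``."""
        rep, fix = self.resolve(parameters)
        for a, b in other.equalities:
            if rep.get(a) != rep.get(b):
                return False
        for name, value in other.fixed.items():
            r = rep.get(name)
            if r not in fix or abs(fix[r] - value) > 1e-12:
                return False
        return True


@dataclass
class ParameterVector:
    """Named latent probabilities, all in [0, 1]."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"parameter {name!r} outside [0,1]: {v}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def updated(self, **changes: float) -> "ParameterVector":
        return ParameterVector({**self.values, **changes})

    def items(self):
        return self.values.items()


@dataclass
class ModelSpec:
    """A complete MPT model: trees plus parameter constraints."""

    trees: tuple[TreeSpec, ...]
    constraints: ConstraintSet = field(default_factory=ConstraintSet)

    @property
    def parameters(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.trees:
            for p in t.parameters:
                seen.setdefault(p)
        return tuple(seen)

    def tree(self, tree_id: str) -> TreeSpec:
        for t in self.trees:
            if t.tree_id == tree_id:
                return t
        raise KeyError(f"no tree {tree_id!r} in model")

    @property
    def tree_ids(self) -> tuple[str, ...]:
        return tuple(t.tree_id for t in self.trees)

    def free_parameters(
        self, extra_constraints: ConstraintSet | None = None
    ) -> tuple[str, ...]:
        cs = self.constraints.merged(extra_constraints)
        rep, fix = cs.resolve(self.parameters)
        out: dict[str, None] = {}
        for p in self.parameters:
            r = rep[p]
            if r not in fix:
                out.setdefault(r)
        return tuple(out)

    @property
    def n_free_parameters(self) -> int:
        return len(self.free_parameters())

    @property
    def n_free_category_proportions(self) -> int:
        """Independent category proportions: sum over trees of (K_t - 1)."""
        return sum(len(t.categories) - 1 for t in self.trees)

    @property
    def df(self) -> int:
        """Goodness-of-fit degrees of freedom."""
        return self.n_free_category_proportions - self.n_free_parameters

    def expand_parameters(self, params: ParameterVector | Mapping[str, float],
                          extra_constraints: ConstraintSet | None = None
                          ) -> dict[str, float]:
        """Map a (possibly partial) parameter vector to all tree parameters.

        Each free equality class must receive exactly one value (any member
        name may carry it; values supplied for several tied members must
        agree).  Fixed classes take their constant regardless of input.
        """
        if isinstance(params, ParameterVector):
            given = params.values
        else:
            given = dict(params)
        unknown = set(given) - set(self.parameters)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        for name, v in given.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"parameter {name!r} outside [0,1]: {v}")
        cs = self.constraints.merged(extra_constraints)
        rep, fix = cs.resolve(self.parameters)
        class_value: dict[str, float] = dict(fix)
        for name, v in given.items():
            r = rep[name]
            if r in fix:
                continue  # fixed wins; a consistent value is simply ignored
            if r in class_value and abs(class_value[r] - v) > 1e-9:
                raise ValueError(
                    f"conflicting values for tied parameters in class of {r!r}"
                )
            class_value.setdefault(r, v)
        missing = [p for p in self.free_parameters(extra_constraints)
                   if p not in class_value]
        if missing:
            raise KeyError(f"no value supplied for free parameter(s): {missing}")
        return {p: class_value[rep[p]] for p in self.parameters}


def category_probabilities(
    model: ModelSpec,
    params: ParameterVector | Mapping[str, float],
    extra_constraints: ConstraintSet | None = None,
) -> dict[str, np.ndarray]:
    """Per-tree response-category probabilities under ``params``.

    Constraints of the model (plus any ``extra_constraints``) are applied
    before evaluation; each returned vector sums to 1.
    """
    values = model.expand_parameters(params, extra_constraints)
    return {t.tree_id: t.category_probabilities(values) for t in model.trees}


# ---------------------------------------------------------------------------
# The two-high-threshold three-sources model
# ---------------------------------------------------------------------------

def _group_trees(suffix: str) -> list[TreeSpec]:
    """Trees for one base-rate group; ``suffix`` like '_HTB' or ''."""

    def P(name: str) -> tuple[str, bool]:
        return (name + suffix, True)

    def C(name: str) -> tuple[str, bool]:
        return (name + suffix, False)

    def guess_after_recognition(cat_prefix: list[tuple[str, bool]]):
        # recognized old, feedback not remembered: a-family guessing
        return [
            BranchTerm((*cat_prefix, P("a_fb"), P("a_true")), "true"),
            BranchTerm((*cat_prefix, P("a_fb"), C("a_true")), "false"),
            BranchTerm((*cat_prefix, C("a_fb")), "unchecked"),
        ]

    def guess_after_old_guess(prefix: list[tuple[str, bool]]):
        # unrecognized item: guess "old" (b), then g-family guessing
        return [
            BranchTerm((*prefix, P("b"), P("g_fb"), P("g_true")), "true"),
            BranchTerm((*prefix, P("b"), P("g_fb"), C("g_true")), "false"),
            BranchTerm((*prefix, P("b"), C("g_fb")), "unchecked"),
            BranchTerm((*prefix, C("b")), "new"),
        ]

    trees = []
    for cond, source in (("old_true", "true"), ("old_false", "false"),
                         ("old_unchecked", "unchecked")):
        short = cond.removeprefix("old_")
        D, d = f"D_{short}", f"d_{short}"
        branches = [
            BranchTerm((P(D), P(d)), source),
            *guess_after_recognition([P(D), C(d)]),
            *guess_after_old_guess([C(D)]),
        ]
        trees.append(
            TreeSpec(cond + suffix, RESPONSES, tuple(branches))
        )
    new_branches = [
        BranchTerm((P("D_new"),), "new"),
        *guess_after_old_guess([C("D_new")]),
    ]
    trees.append(TreeSpec("new" + suffix, RESPONSES, tuple(new_branches)))
    return trees


def build_three_sources_model(
    two_group: bool = True,
    identifiable: bool = True,
    groups: Sequence[str] = GROUPS,
) -> ModelSpec:
    """Two-high-threshold three-sources model for veracity-feedback memory.

    Four trees per group (old "true", old "false", old "unchecked", new),
    four response categories each.  Per group the parameters are item
    memory ``D_true, D_false, D_unchecked, D_new``, feedback memory
    ``d_true, d_false, d_unchecked``, and guessing ``b`` (guess "old"),
    ``a_fb``/``a_true`` (feedback guessing after recognition) and
    ``g_fb``/``g_true`` (feedback guessing after an "old" guess).

    With ``identifiable=True`` the base-model constraint ``D_new =
    D_unchecked`` is applied, leaving 11 free parameters per group.  The
    two-group variant suffixes every parameter and tree id with the group
    label; there are no cross-group constraints in the base model.
    """
    if two_group:
        trees: list[TreeSpec] = []
        eq: list[tuple[str, str]] = []
        for g in groups:
            sfx = f"_{g}"
            trees.extend(_group_trees(sfx))
            if identifiable:
                eq.append((f"D_unchecked{sfx}", f"D_new{sfx}"))
        return ModelSpec(tuple(trees), ConstraintSet(eq))
    trees = _group_trees("")
    eq = [("D_unchecked", "D_new")] if identifiable else []
    return ModelSpec(tuple(trees), ConstraintSet(eq))


# ---------------------------------------------------------------------------
# .eqn model files
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"^(?:(?P<direct>[A-Za-z_][\w.]*)|\(1-(?P<comp>[A-Za-z_][\w.]*)\))$")


def write_eqn(model: ModelSpec, path) -> None:
    """Write the model's trees in the classic ``.eqn`` dialect.

    First line: number of branch lines; then one line per branch,
    ``tree category expression`` with ``*``-separated factors and
    complements written ``(1-name)``.  Equality/fixed constraints are not
    part of the format and are not stored.
    """
    lines = []
    for t in model.trees:
        for b in t.branches:
            lines.append(f"{t.tree_id} {b.category} {b.expression()}")
    with open(path, "w") as fh:
        fh.write(f"{len(lines)}\n")
        fh.write("\n".join(lines) + "\n")


def read_eqn(path) -> ModelSpec:
    """Read a model in the classic ``.eqn`` dialect.

    Accepts an optional leading line with the branch count, blank lines and
    ``#`` comments.  Categories are collected per tree in order of first
    appearance; no constraints are read (the format has none).
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    rows: list[tuple[str, str, str]] = []
    declared_count: int | None = None
    for lineno, line in enumerate(raw, 1):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        if declared_count is None and not rows and re.fullmatch(r"\d+", text):
            declared_count = int(text)
            continue
        parts = text.split(None, 2)
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: malformed line {line!r}")
        rows.append((parts[0], parts[1], parts[2]))
    if not rows:
        raise ValueError(f"{path}: no branch lines found")
    if declared_count is not None and declared_count != len(rows):
        raise ValueError(
            f"{path}: header declares {declared_count} lines, found {len(rows)}"
        )
    tree_cats: dict[str, dict[str, None]] = {}
    tree_branches: dict[str, list[BranchTerm]] = {}
    for tree_id, cat, expr in rows:
        factors = []
        for tok in expr.replace(" ", "").split("*"):
            m = _TOKEN.match(tok)
            if not m:
                raise ValueError(f"{path}: bad factor {tok!r} in tree {tree_id!r}")
            if m.group("direct"):
                factors.append((m.group("direct"), True))
            else:
                factors.append((m.group("comp"), False))
        tree_cats.setdefault(tree_id, {}).setdefault(cat)
        tree_branches.setdefault(tree_id, []).append(
            BranchTerm(tuple(factors), cat)
        )
    trees = tuple(
        TreeSpec(tid, tuple(tree_cats[tid]), tuple(tree_branches[tid]))
        for tid in tree_branches
    )
    return ModelSpec(trees)
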