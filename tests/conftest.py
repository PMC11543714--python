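import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from truthmpt import (
    AccountSpec,
    BranchTerm,
    ModelSpec,
    ParameterVector,
    TreeSpec,
    account_parameters,
    build_three_sources_model,
    default_design,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def two_group_model():
    return build_three_sources_model(two_group=True)


@pytest.fixture(scope="session")
def one_group_model():
    return build_three_sources_model(two_group=False)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def cartesian_params(design):
    return account_parameters(AccountSpec("cartesian"), design)


@pytest.fixture(scope="session")
def paperlike_params():
    """Generating values at the study's reported estimate magnitudes.

    All parameters differ between groups and between feedback types, so
    every restriction of the ladder is genuinely false except the
    near-equality of d_true and d_false.
    """
    vals = {}
    table1 = {
        "HTB": dict(D_true=0.53, D_false=0.64, D_unchecked=0.52,
                    d_true=0.62, d_false=0.66, d_unchecked=0.26),
        "HFB": dict(D_true=0.55, D_false=0.47, D_unchecked=0.46,
                    d_true=0.61, d_false=0.57, d_unchecked=0.36),
    }
    table2 = {
        "HTB": dict(b=0.25, a_fb=0.57, g_fb=0.76, a_true=0.66, g_true=0.73),
        "HFB": dict(b=0.29, a_fb=0.75, g_fb=0.77, a_true=0.26, g_true=0.28),
    }
    for g in ("HTB", "HFB"):
        for name, v in {**table1[g], **table2[g]}.items():
            vals[f"{name}_{g}"] = v
        vals[f"D_new_{g}"] = table1[g]["D_unchecked"]
    return ParameterVector(vals)


@pytest.fixture(scope="session")
def coin_model():
    """One tree, two branches: p -> heads, (1-p) -> tails."""
    return ModelSpec(
        (
            TreeSpec(
                "coin",
                ("heads", "tails"),
                (
                    BranchTerm((("p", True),), "heads"),
                    BranchTerm((("p", False),), "tails"),
                ),
            ),
        )
    )


@pytest.fixture(scope="session")
def two_param_model():
    """Two trees sharing p: used for grid-search and EM-agreement checks."""
    return ModelSpec(
        (
            TreeSpec(
                "t1",
                ("a", "b"),
                (
                    BranchTerm((("p", True),), "a"),
                    BranchTerm((("p", False),), "b"),
                ),
            ),
            TreeSpec(
                "t2",
                ("a", "b", "c"),
                (
                    BranchTerm((("p", True), ("q", True)), "a"),
                    BranchTerm((("p", True), ("q", False)), "b"),
                    BranchTerm((("p", False),), "c"),
                ),
            ),
        )
    )


def random_full_params(model, rng) -> dict:
    free = model.free_parameters()
    return {name: float(v) for name, v in
            zip(free, rng.uniform(0.0, 1.0, len(free)))}
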