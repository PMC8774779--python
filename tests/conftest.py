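import numpy as np
import pytest
from hypothesis import settings

from cbrmatch import AttributeSchema, Case, CaseBase

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_vdm_base():
    """Six-case all-discrete base whose conditional probabilities are exact
    by enumeration: attribute value 'a' splits 1:1 over pos/neg, value 'b'
    is purely pos (with alpha=0)."""
    schema = [AttributeSchema(name="attr", kind="discrete", domain=("a", "b"))]
    cases = [
        Case(case_id="c1", x=["a"], y="pos"),
        Case(case_id="c2", x=["a"], y="neg"),
        Case(case_id="c3", x=["a"], y="pos"),
        Case(case_id="c4", x=["a"], y="neg"),
        Case(case_id="c5", x=["b"], y="pos"),
        Case(case_id="c6", x=["b"], y="pos"),
    ]
    return CaseBase(schema=schema, class_values=("neg", "pos"), cases=cases)


@pytest.fixture
def mixed_base():
    """Small mixed-type base with a missing value and two classes."""
    schema = [
        AttributeSchema(name="sex", kind="discrete", domain=("f", "m")),
        AttributeSchema(name="glucose", kind="continuous"),
    ]
    cases = [
        Case(case_id=f"c{i}", x=[sex, val], y=y)
        for i, (sex, val, y) in enumerate(
            [("f", 0.1, "A"), ("m", 0.9, "B"), ("f", 0.5, "A"),
             ("m", None, "B"), ("f", 0.3, "A")]
        )
    ]
    return CaseBase(schema=schema, class_values=("A", "B"), cases=cases)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
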