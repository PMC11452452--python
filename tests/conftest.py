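import pytest

from netdiv import DiversityTable, example1_fixture

#: the 15 known nonempty-subset rPSD values of the four-leaf galled tree
EXAMPLE1_TABLE = {
    frozenset({"x1"}): 5,
    frozenset({"x2"}): 6,
    frozenset({"x3"}): 5,
    frozenset({"x4"}): 4,
    frozenset({"x1", "x2"}): 8,
    frozenset({"x1", "x3"}): 9,
    frozenset({"x1", "x4"}): 9,
    frozenset({"x2", "x3"}): 8,
    frozenset({"x2", "x4"}): 10,
    frozenset({"x3", "x4"}): 9,
    frozenset({"x1", "x2", "x3"}): 10,
    frozenset({"x1", "x2", "x4"}): 12,
    frozenset({"x1", "x3", "x4"}): 13,
    frozenset({"x2", "x3", "x4"}): 12,
    frozenset({"x1", "x2", "x3", "x4"}): 14,
}


@pytest.fixture(scope="session")
def example1():
    return example1_fixture()


@pytest.fixture(scope="session")
def example1_table(example1):
    return DiversityTable(example1)
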