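import textwrap

import numpy as np
import pandas as pd
import pytest

from coevo import go_eval, simulate, treeio
from coevo.profiles import ProfileMatrix

TOY_OBO = textwrap.dedent("""\
    format-version: 1.2
    ontology: toy

    [Term]
    id: GO:0000001
    name: biological process root
    namespace: biological_process

    [Term]
    id: GO:0000002
    name: parent process
    namespace: biological_process
    is_a: GO:0000001 ! biological process root

    [Term]
    id: GO:0000003
    name: child process a
    namespace: biological_process
    is_a: GO:0000002 ! parent process

    [Term]
    id: GO:0000004
    name: child process b
    namespace: biological_process
    is_a: GO:0000002 ! parent process

    [Term]
    id: GO:0000005
    name: component-linked process
    namespace: biological_process
    relationship: part_of GO:0000002 ! parent process

    [Term]
    id: GO:0000006
    name: gone
    namespace: biological_process
    is_obsolete: true

    [Term]
    id: GO:0000007
    name: molecular widget
    namespace: molecular_function
    """)


@pytest.fixture(scope="session")
def toy_obo_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("go") / "toy.obo"
    path.write_text(TOY_OBO)
    return str(path)


@pytest.fixture(scope="session")
def toy_dag(toy_obo_path):
    return go_eval.parse_obo(toy_obo_path)


@pytest.fixture(scope="session")
def tree74():
    """A 74-tip birth-death tree shared by the heavier statistical tests."""
    return simulate.simulate_tree(n_tips=74, seed=1)


@pytest.fixture
def quartet():
    return treeio.read_newick("((A:0.3,B:0.7):0.4,(C:1.1,D:0.2):0.6);")


@pytest.fixture
def small_profiles():
    data = pd.DataFrame(
        {
            "g1": [1, 1, 0, 0],
            "g2": [1, 1, 0, 0],  # duplicate of g1
            "g3": [0, 1, 1, 0],
            "g4": [1, 0, 0, 1],
        },
        index=["G1", "G2", "G3", "G4"],
        dtype=np.int8,
    )
    return ProfileMatrix(data=data)
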