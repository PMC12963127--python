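import pytest

import arbornet as an
from arbornet import genfix


@pytest.fixture
def cat5():
    """The 5-leaf caterpillar with cherries {1,2} and {4,5}."""
    return an.read_newick("((1,2),3,(4,5));")


@pytest.fixture
def fig_aug():
    """The caterpillar with the interior vertex adjacent to leaf 3 marked AUG."""
    return an.read_augmented_newick("((1,2),3,(4,5))AUG;")


@pytest.fixture
def worked_system():
    """The 5-taxon system on {a,b,c,d,z}: the caterpillar with cherries
    {a,b} and {c,d}, z in the middle, and the middle vertex marked AUG."""
    t = an.read_augmented_newick("((a,b),z,(c,d))AUG;")
    return an.induced_eqts(t)


@pytest.fixture
def net9():
    return genfix.net9()
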