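import pytest

from superrec.model import Gene, Synteny
from superrec.trees import parse_newick


def make_synteny(sid: str, species: str, families) -> Synteny:
    """A synteny with one auto-named gene per family."""
    return Synteny(
        sid, species, tuple(Gene(f"{f}.{sid}", f, species) for f in families)
    )


@pytest.fixture
def species_ab():
    return parse_newick("(A,B);")


@pytest.fixture
def species_abc():
    return parse_newick("((spA,spB),spC);")


@pytest.fixture
def fig_style_instance(species_ab):
    """Two genomes, three families (a, b, c) grouped into two syntenies
    per genome; the kind of overlapping-synteny input the method is
    built for."""
    syntenies = [
        make_synteny("A1", "A", "abc"),
        make_synteny("A2", "A", "bc"),
        make_synteny("B1", "B", "abc"),
        make_synteny("B2", "B", "c"),
    ]
    gene_trees = [
        parse_newick("(a.A1,a.B1);"),
        parse_newick("((b.A1,b.B1),b.A2);"),
        parse_newick("((c.A1,c.B1),(c.A2,c.B2));"),
    ]
    return species_ab, gene_trees, syntenies
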