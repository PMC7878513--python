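import pytest

from beecaste.overlap import TermSet


@pytest.fixture
def shared_universe_sets():
    """Two TermSets over one shared universe, for closed-form null oracles."""
    def make(n_universe: int, n_a: int, n_b: int, n_common: int = 0):
        universe = {f"term {i:04d}" for i in range(n_universe)}
        ordered = sorted(universe)
        a_terms = set(ordered[:n_a])
        b_terms = set(ordered[:n_common] + ordered[n_a:n_a + n_b - n_common])
        ts_a = TermSet("A", "all", a_terms, universe)
        ts_b = TermSet("B", "all", b_terms, universe)
        return ts_a, ts_b
    return make


@pytest.fixture
def tiny_obo(tmp_path):
    """Minimal OBO file: root <- A <- B chain plus an obsolete stanza."""
    text = """format-version: 1.2

[Term]
id: T:0000001
name: root process
namespace: biological_process

[Term]
id: T:0000002
name: mid process
namespace: biological_process
is_a: T:0000001 ! root process

[Term]
id: T:0000003
name: leaf process
namespace: biological_process
is_a: T:0000002 ! mid process

[Term]
id: T:0000009
name: gone process
namespace: biological_process
is_obsolete: true
"""
    path = tmp_path / "mini.obo"
    path.write_text(text)
    return path
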