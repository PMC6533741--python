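import numpy as np
import pytest

from cleftminer import SyntheticSpec, build_target_map


@pytest.fixture
def tiny_target_map():
    """Three miRNAs over a five-gene universe."""
    pairs = {
        ("miR-a", "G1"), ("miR-a", "G2"), ("miR-a", "G3"),
        ("miR-b", "G2"), ("miR-b", "G4"),
        ("miR-c", "G5"),
    }
    return build_target_map(pairs)


@pytest.fixture
def null_spec():
    """Small null (no planted structure) synthetic spec."""
    return SyntheticSpec(
        seed=0,
        n_genes_universe=400,
        n_foreground=40,
        n_mirnas=12,
        target_size_range=(10, 25),
        planted_mirnas=0,
        n_trios=60,
        n_snps=12,
    )


def write_interactions(path, rows):
    """Write an interaction TSV from (source, mirna, gene, validated) tuples."""
    lines = ["source\tmirna\tgene\tvalidated"]
    lines += [f"{s}\t{m}\t{g}\t{str(v).lower()}" for s, m, g, v in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
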