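import pytest

from plastopart.core_io import GeneFeature, Interval, PlastomeRecord
from plastopart.gene_status import build_reference_panel
from plastopart.quadripartite import detect_quadripartite
from plastopart.synthetic_data import SynthSpec, build_plastome


@pytest.fixture(scope="session")
def type_a():
    """A default Type A synthetic plastome with its truth table."""
    return build_plastome(SynthSpec.type_a(11))


@pytest.fixture(scope="session")
def type_a_map(type_a):
    rec, _ = type_a
    return detect_quadripartite(rec)


@pytest.fixture(scope="session")
def intact_panel(type_a):
    """Reference panel built from an all-intact genome."""
    rec, _ = type_a
    return build_reference_panel([rec])


def make_single_gene_record(rec_id: str, cds: str, strand: str = "+", pad: int = 400):
    """A minimal circular record: one CDS embedded in fixed AT background."""
    import zlib

    import numpy as np

    from plastopart.core_io import reverse_complement

    rng = np.random.default_rng(zlib.crc32(rec_id.encode()) % (2**31))
    bg = "".join(rng.choice(list("ACGT"), size=2 * pad, p=[0.31, 0.19, 0.19, 0.31]))
    text = cds if strand == "+" else reverse_complement(cds)
    seq = bg[:pad] + text + bg[pad:]
    feat = GeneFeature("geneX", "CDS", strand, [Interval(pad + 1, pad + len(cds))])
    return PlastomeRecord(rec_id, seq, True, [feat])
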