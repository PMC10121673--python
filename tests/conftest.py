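import numpy as np
import pandas as pd
import pytest

from scarsig.refit import SignatureCatalog
from scarsig.synthetic import SimulationConfig, synthetic_catalog


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_catalog(rng):
    """Five synthetic signatures over the 96 SBS channels."""
    return synthetic_catalog(5, rng=rng)


@pytest.fixture
def two_sig_catalog():
    """Analytic 2-signature, 3-channel catalog for hand-checkable refits."""
    profiles = pd.DataFrame(
        [[0.5, 0.5, 0.0], [0.0, 0.5, 0.5]],
        index=["SigA", "SigB"], columns=["c1", "c2", "c3"],
    )
    return SignatureCatalog(profiles=profiles)


@pytest.fixture
def default_cfg():
    return SimulationConfig(seed=0)


def write_vcf(path, rows, contig="chr1", length=10_000, extra_header=""):
    """Minimal VCF writer for fixtures; rows are (pos, ref, alt, filter, info)."""
    header = (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={contig},length={length}>\n"
        '##FILTER=<ID=lowqual,Description="Low quality">\n'
        '##INFO=<ID=NONSYN,Number=0,Type=Flag,Description="Coding">\n'
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n'
        + extra_header +
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for pos, ref, alt, filt, info in rows:
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t{info}\n")
    return path
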