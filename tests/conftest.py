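import numpy as np
import pytest

from tfbs_indel_scan import (
    GenomicInterval, GenotypeMatrix, IndelVariant, TfbsPeak, worked_fixture,
)


@pytest.fixture(scope="session")
def worked():
    """In-memory deterministic worked-example cohort."""
    return worked_fixture()


@pytest.fixture(scope="session")
def worked_paths(tmp_path_factory):
    """The same cohort written as a file bundle."""
    return worked_fixture(tmp_path_factory.mktemp("worked"))


def make_indel(chrom="chr1", first_base=100, length=1, kind="DEL", vid=None):
    """Indel whose first affected base (0-based) is ``first_base``."""
    seq = "A" * length
    if kind == "DEL":
        ref, alt = "C" + seq, "C"
    else:
        ref, alt = "C", "C" + seq
    return IndelVariant(chrom, first_base, ref, alt, vid)


def make_matrix(variants, n_samples=4, pop="AFR", dosage=None):
    samples = [f"s{i}" for i in range(n_samples)]
    if dosage is None:
        dosage = np.zeros((len(variants), n_samples), dtype=np.int8)
    return GenotypeMatrix(variants, samples, dosage, {s: pop for s in samples})


def make_peak(chrom="chr1", start=100, end=120, tf="CTCF"):
    return TfbsPeak(GenomicInterval(chrom, start, end), tf)
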