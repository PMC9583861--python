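import numpy as np
import pandas as pd
import pytest

from isomirnet.catalog import HairpinRecord, MatureAnnotation, build_isomir


@pytest.fixture(scope="session")
def plus_hairpin():
    # 40-nt toy hairpin on the + strand; mature occupies local 5..26
    seq = "GGGCUAGCUUAUCAGACUGAUGUUGACUGUUGAAUCUCAU"
    hp = HairpinRecord(
        hairpin_id="toy-mir-1", sequence=seq, chrom="chr1",
        start=1001, end=1000 + len(seq), strand="+",
    )
    mature = MatureAnnotation(mature_id="toy-miR-1-5p", hairpin_id="toy-mir-1", start=5, end=26)
    return hp, mature


@pytest.fixture(scope="session")
def minus_hairpin():
    # same idea on the - strand: the sequence is the RNA 5'->3', so its
    # first base sits at the *highest* genomic coordinate
    seq = "AAUACUGCCGGGUAAUGAUGGAGGCCCCUGUAGAACCGAA"
    hp = HairpinRecord(
        hairpin_id="toy-mir-2", sequence=seq, chrom="chr2",
        start=5001, end=5000 + len(seq), strand="-",
    )
    mature = MatureAnnotation(mature_id="toy-miR-2-3p", hairpin_id="toy-mir-2", start=5, end=26)
    return hp, mature


@pytest.fixture(scope="session")
def toy_isomirs(plus_hairpin):
    hp, mature = plus_hairpin
    return {s: build_isomir(hp, mature, s) for s in (-1, 0, 1, 2)}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_counts():
    return pd.DataFrame(
        {
            "S1": [100, 80, 12, 0, 3],
            "S2": [120, 70, 15, 0, 2],
            "S3": [90, 95, 9, 0, 4],
        },
        index=["iso-a", "iso-b", "iso-c", "iso-d", "iso-e"],
    )
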