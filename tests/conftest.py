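import datetime as dt

import pytest

from bloomclone.genotype_core import LocusGenotype, MatingType, StrainRecord


def make_strains(genotypes, date=dt.date(2020, 1, 1), loci=None, mts=None):
    """Build StrainRecords from lists of per-locus (a, b) pairs (None = missing)."""
    n_loci = len(genotypes[0])
    loci = loci or [f"L{j + 1}" for j in range(n_loci)]
    mts = mts or [MatingType.UNKNOWN] * len(genotypes)
    out = []
    for i, (pairs, mt) in enumerate(zip(genotypes, mts)):
        genotype = tuple(
            LocusGenotype(loci[j], pair) for j, pair in enumerate(pairs)
        )
        out.append(StrainRecord(f"s{i + 1}", date, genotype, mt))
    return out


@pytest.fixture
def associated_toy():
    """4 strains, 2 loci, two perfectly associated genotype groups of 2.

    K multiset {0,0,2,2,2,2}; d_1 = d_2 = 2/3; Vd = 8/9; Ve = 4/9; ia_s = 1.
    """
    return make_strains(
        [
            [(100, 102), (200, 204)],
            [(100, 102), (200, 204)],
            [(110, 112), (210, 214)],
            [(110, 112), (210, 214)],
        ]
    )


@pytest.fixture
def genotype_csv(tmp_path):
    path = tmp_path / "genotypes.csv"
    path.write_text(
        "strain_id,date,mt,PNm1.a1,PNm1.a2,PNm3.a1,PNm3.a2\n"
        "sA,2013-08-20,MT+,100,104,200,200\n"
        "sB,2013-08-20,MT-,100,104,200,200\n"
        "sC,2013-09-01,,102,104,0,0\n"
    )
    return path
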