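import gzip
import shutil

import numpy as np
import pytest

from snpkinpca import (
    MISSING,
    PopulationModel,
    SiteRecord,
    make_toy_vcf,
    simulate_structured_vcf,
    site_stats,
)

TOY_SAMPLES = ["s1", "s2", "s3", "s4"]

TOY_RECORDS = [
    {"chrom": "1", "pos": 100, "ref": "A", "alt": "C",
     "gts": ["0/0", "0/1", "1/1", "0/0"]},
    {"chrom": "1", "pos": 200, "ref": "G", "alt": "T",
     "gts": ["0|1", "./.", "0/0", "1/1"]},
    {"chrom": "1", "pos": 300, "ref": "T", "alt": "A",
     "gts": ["0/0", "0/0", "0/1", "0/1"]},
]


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    make_toy_vcf(TOY_SAMPLES, TOY_RECORDS, str(path))
    return str(path)


@pytest.fixture
def toy_vcf_gz(toy_vcf, tmp_path):
    gz = tmp_path / "toy.vcf.gz"
    with open(toy_vcf, "rb") as src, gzip.open(gz, "wb") as dst:
        shutil.copyfileobj(src, dst)
    return str(gz)


@pytest.fixture(scope="session")
def sim_world(tmp_path_factory):
    """The standard synthetic world: 4 pops x 50 samples, 2000 SNPs, F=0.2."""
    d = tmp_path_factory.mktemp("sim")
    model = PopulationModel()
    vcf, truth = simulate_structured_vcf(model, str(d / "sim.vcf"))
    return model, vcf, truth


def record_from_dosages(dosages, pos=1, ref="A", alt="C"):
    """Build a biallelic SiteRecord directly from a dosage vector."""
    d = np.asarray(dosages, dtype=np.int8)
    called = d[d != MISSING]
    n_alt = int(called.sum())
    n_ref = 2 * called.size - n_alt
    site_class = "BIALLELIC_SNP" if (n_alt > 0 and n_ref > 0) else "MONOMORPHIC"
    return SiteRecord(chrom="1", pos=pos, ref=ref, alts=(alt,), dosages=d,
                      site_class=site_class)


def stream_dosage_matrix(G):
    """Yield (SiteRecord, SiteStats) for each polymorphic row of a
    sites-x-samples matrix with np.nan for missing."""
    for s, row in enumerate(np.asarray(G, dtype=float)):
        d = np.where(np.isnan(row), MISSING, row).astype(np.int8)
        rec = record_from_dosages(d, pos=s + 1)
        if rec.site_class != "BIALLELIC_SNP":
            continue
        yield rec, site_stats(rec)
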