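import numpy as np
import pytest

from canidkit.cohort import CohortGenotypes, SampleRecord, SiteRecord


def make_cohort(dosage, categories=None, breeds=None, positions=None, chrom="chr1",
                region="autosome", sexes=None, **layers):
    """Small hand-built cohort from a dosage matrix (rows = samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    categories = categories or ["breed"] * n
    samples = []
    for i in range(n):
        cat = categories[i]
        breed = None
        if cat == "breed":
            breed = (breeds[i] if breeds else f"B{i}")
        samples.append(
            SampleRecord(f"s{i}", cat, breed_label=breed,
                         sex=(sexes[i] if sexes else "F"))
        )
    positions = positions if positions is not None else [(j + 1) * 100 for j in range(m)]
    regions = [region] * m if isinstance(region, str) else region
    sites = [
        SiteRecord(chrom, int(positions[j]), "A", "G", regions[j]) for j in range(m)
    ]
    return CohortGenotypes(samples, sites, dosage, **layers)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
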