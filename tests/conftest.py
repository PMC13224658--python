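import numpy as np

from pollenscape.genotypes import GenotypeSet, Locus, Role, SampleRecord


def make_sample(sid, role, alleles, patch="P1", cluster=None, mother=None, coords=None):
    return SampleRecord(
        sample_id=sid,
        role=role,
        patch_id=patch,
        cluster_id=cluster,
        mother_id=mother,
        coords=coords,
        alleles=alleles,
    )


def random_genotype_set(rng, n_samples, panel=None, n_alleles=4, n_loci=2, missing_rate=0.0):
    """Small random genotype set; low allele count forces repeated MLGs."""
    if panel is None:
        panel = [
            Locus(f"L{i+1}", frozenset(range(100 * (i + 1), 100 * (i + 1) + n_alleles)))
            for i in range(n_loci)
        ]
    samples = []
    for i in range(n_samples):
        alleles = {}
        for locus in panel:
            codes = sorted(locus.allele_set)
            pair = [int(rng.choice(codes)), int(rng.choice(codes))]
            if rng.random() < missing_rate:
                pair = [0, 0]
            alleles[locus.name] = tuple(pair)
        samples.append(
            make_sample(f"S{i:03d}", Role.DONOR, alleles, cluster=f"C{i % 7}")
        )
    return GenotypeSet(panel, samples)
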