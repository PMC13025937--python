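import numpy as np
import pandas as pd
import pytest

from sweetbsa.simulate import Qtl, SimConfig


def make_table(chrom, pos, ad_high, ad_low, ad_p1=None, ad_p2=None,
               impact=None, variant_class=None):
    """Build a minimal allele-depth table from per-locus tuples."""
    n = len(pos)
    ad_p1 = ad_p1 if ad_p1 is not None else [(10, 0)] * n
    ad_p2 = ad_p2 if ad_p2 is not None else [(0, 10)] * n
    impact = impact if impact is not None else ["MODIFIER"] * n
    variant_class = variant_class if variant_class is not None else ["SNP"] * n
    return pd.DataFrame({
        "chrom": chrom if not isinstance(chrom, str) else [chrom] * n,
        "pos": pos,
        "ref": ["A"] * n, "alt": ["G"] * n,
        "p1_ref": [a[0] for a in ad_p1], "p1_alt": [a[1] for a in ad_p1],
        "p2_ref": [a[0] for a in ad_p2], "p2_alt": [a[1] for a in ad_p2],
        "high_ref": [a[0] for a in ad_high], "high_alt": [a[1] for a in ad_high],
        "low_ref": [a[0] for a in ad_low], "low_alt": [a[1] for a in ad_low],
        "variant_class": variant_class, "impact": impact,
    })


@pytest.fixture
def tiny_sim_config():
    """A fast, small simulated experiment with one strong QTL."""
    return SimConfig(n_lines=60, n_bulk=10, n_chromosomes=2,
                     chrom_length_bp=10_000_000, n_snps=120, n_background=400,
                     qtl_list=(Qtl("chr1", 5_000_000, 28.0, "P2"),),
                     baseline=-0.21, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
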