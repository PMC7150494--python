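import numpy as np
import pytest

from aasig.refit import MergeMap
from aasig.reference import synthetic_signature_matrix
from aasig.variants import VariantRecord


@pytest.fixture(scope="session")
def signatures():
    """The package's synthetic 30-signature reference matrix (fixed seed)."""
    return synthetic_signature_matrix()


@pytest.fixture(scope="session")
def merge_map(signatures):
    return MergeMap.default(signatures.names)


def make_record(**overrides) -> VariantRecord:
    """A variant record comfortably passing every filter; override to taste."""
    defaults = dict(
        chrom="chr1",
        pos=1000,
        ref="C",
        alt="T",
        dist_to_end_median=40.0,
        dist_to_end_mad=10.0,
        frac_low_mapq=0.0,
        mapq_median_varreads=60.0,
        baseq_median_varreads=35.0,
        strand_frac_varreads=0.4,
        strand_frac_allreads=0.45,
        repeat_len_adjacent=2,
        nearby_variant_max=0,
        allele_freq=0.5,
        pop_freqs={},
    )
    defaults.update(overrides)
    return VariantRecord(**defaults)


def mixture_weights(aa_weight: float) -> dict[str, float]:
    """AA weight on signature 22; remainder split over the clock-like pair."""
    rest = (1.0 - aa_weight) / 2.0
    return {"Signature 22": aa_weight, "Signature 1": rest, "Signature 5": rest}
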