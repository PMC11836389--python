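import pandas as pd
import pytest

from notet import MethylomeSimSpec, synth_oxrrbs


@pytest.fixture(scope="session")
def null_methylome():
    """Small synthetic oxRRBS dataset with no planted effects."""
    return synth_oxrrbs(MethylomeSimSpec(n_sites=300, seed=11))


@pytest.fixture(scope="session")
def planted_methylome():
    """Synthetic oxRRBS dataset with hyper- and hypo-5mC effects planted."""
    return synth_oxrrbs(
        MethylomeSimSpec(
            n_sites=400,
            seed=12,
            effect_fraction_hyper=0.10,
            effect_fraction_hypo=0.05,
        )
    )


@pytest.fixture()
def tiny_counts():
    """Hand-written 2-condition, 2-replicate count table for one CpG."""
    rows = []
    for cond, betas in (("control", [0.20, 0.22]), ("treated", [0.50, 0.52])):
        for rep, b in enumerate(betas, 1):
            rows.append(("chr1", 100, ".", cond, rep, "BS", int(b * 100), 100))
            rows.append(("chr1", 100, ".", cond, rep, "oxBS", int(b * 100), 100))
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "condition", "replicate",
                 "assay", "meth", "total"],
    )
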