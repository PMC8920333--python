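import pandas as pd
import pytest

from editome.simulate import SimConfig, generate_catalogs, generate_cohort
from editome.types import SiteObservation


def obs_list(frame: pd.DataFrame) -> list:
    return [
        SiteObservation(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref_base=str(r.ref),
            alt_base=str(r.alt),
            sample_id=str(r.sample),
            edited_reads=int(r.edited_reads),
            total_reads=int(r.total_reads),
        )
        for r in frame.itertuples(index=False)
    ]


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=7,
        n_genes=60,
        sites_per_gene=4,
        n_case=12,
        n_ctrl=5,
        snp_fraction=0.15,
        planted_specific=(("G0002", 3.0), ("G0011", 3.0)),
        planted_target="G0005",
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_catalogs(small_config, small_cohort):
    return generate_catalogs(small_config, small_cohort.truth)


@pytest.fixture(scope="session")
def small_records(small_cohort) -> list:
    return [r for recs in small_cohort.variants.values() for r in recs]


@pytest.fixture(scope="session")
def small_observations(small_cohort) -> list:
    return obs_list(small_cohort.observations)
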