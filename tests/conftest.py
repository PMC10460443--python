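import numpy as np
import pandas as pd
import pytest

import sigcrypt as sc


@pytest.fixture(scope="session")
def sbs96():
    return sc.get_schema("SBS96")


@pytest.fixture(scope="session")
def id83():
    return sc.get_schema("ID83")


@pytest.fixture(scope="session")
def separated_sigs(sbs96):
    """Ten well-separated synthetic SBS-like reference signatures."""
    return sc.make_reference_signatures("SBS96", 10, separation=0.5, seed=11)


@pytest.fixture()
def toy_catalog(sbs96):
    """Two-group catalog drawn from one shared 4-signature mixture."""
    sigs = sc.make_reference_signatures("SBS96", 4, seed=42)
    mixture = sc.GeneratingMixture.null(sigs)
    design = sc.CohortDesign(
        mice_per_group=2, clones_per_mouse=2, mutations_per_clone=2000, seed=1
    )
    catalog, truth = sc.simulate_cohort(design, mixture)
    return catalog, truth, sigs


def make_catalog(counts: dict[str, list[int]], schema_name: str,
                 group_of: dict[str, str] | None = None) -> sc.MutationCatalog:
    """Small helper: dense per-sample channel count lists -> catalog."""
    schema = sc.get_schema(schema_name)
    df = pd.DataFrame(counts, index=list(schema.labels))
    return sc.MutationCatalog(df, schema, group_of or {})


def sparse_catalog(channel_counts: dict[str, dict[str, int]], schema_name: str,
                   group_of: dict[str, str] | None = None) -> sc.MutationCatalog:
    """Catalog from {sample: {channel_label: count}}."""
    schema = sc.get_schema(schema_name)
    df = pd.DataFrame(0, index=list(schema.labels),
                      columns=list(channel_counts))
    for sample, counts in channel_counts.items():
        for label, n in counts.items():
            df.loc[label, sample] = n
    return sc.MutationCatalog(df, schema, group_of or {})
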