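import pandas as pd
import pytest

from emvarkit import callers, quantify, synthdata


def run_mpra_pipeline(params: synthdata.SimParams, n_elements: int):
    """Simulate and run the full count -> activity -> calling pipeline."""
    manifest = synthdata.simulate_manifest(params, n_elements=n_elements)
    counts, truth = synthdata.simulate_mpra_counts(manifest, params)
    filtered = quantify.filter_low_barcodes(counts)
    act = quantify.quantile_normalize(quantify.activity_table(filtered))
    des = params.replicate_design()
    enh = callers.call_enhancers(act, manifest, des)
    emv = callers.call_emvars(act, enh, manifest, des)
    return manifest, counts, truth, act, enh, emv


@pytest.fixture(scope="session")
def small_manifest() -> pd.DataFrame:
    params = synthdata.SimParams(seed=11, barcodes_per_allele=18)
    return synthdata.simulate_manifest(params, n_elements=5)
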