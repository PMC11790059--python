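from __future__ import annotations

import numpy as np
import pytest

from somaticvote.search import run_search, select_tradeoff
from somaticvote.simulate import DESIGNED_F1_TOLERANCE, designed_scenario
from somaticvote.variants import VariantClass

SCENARIO_SEED = 0


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scenario():
    """The seeded designed study shared across end-to-end tests."""
    return designed_scenario(SCENARIO_SEED)


@pytest.fixture(scope="session")
def scenario_snv_search(scenario):
    """Exhaustive SNV-arm search over the designed scenario (computed once)."""
    results = run_search(
        scenario.callsets_for_class(VariantClass.SNV),
        scenario.truths_for_class(VariantClass.SNV),
        None,
        scenario.caller_meta,
    )
    report = select_tradeoff(results, f1_tolerance=DESIGNED_F1_TOLERANCE)
    return results, report


@pytest.fixture(scope="session")
def scenario_dir(scenario, tmp_path_factory):
    """The designed scenario written to disk (VCFs, BEDs, manifest)."""
    outdir = tmp_path_factory.mktemp("scenario")
    manifest_path = scenario.write(outdir)
    return outdir, manifest_path
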