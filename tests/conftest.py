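import pandas as pd
import pytest

import kawcycle as kc


@pytest.fixture(scope="session")
def registry():
    return kc.load_registry()


@pytest.fixture(scope="session")
def measured_values():
    return kc.load_measured_values()


@pytest.fixture(scope="session")
def droplet_pairs():
    return kc.load_droplet_pairs()


@pytest.fixture(scope="session")
def pipeline_results(registry, measured_values):
    """Full pipeline over the published table: per-compound final values."""
    khxdair = kc.backcompute_khxdair(measured_values)
    results, report = kc.run_pipeline(
        kc.StudyBundle(
            registry=registry, values=measured_values, khxdair=khxdair
        )
    )
    assert not report.skipped
    return results


@pytest.fixture(scope="session")
def final_values(pipeline_results):
    """Long-form (compound, quantity, log_k) table of final values."""
    return pd.concat(
        [
            pd.DataFrame(
                {
                    "compound": pipeline_results["compound"],
                    "quantity": "hxd/w",
                    "log_k": pipeline_results["log_khxdw"],
                }
            ),
            pd.DataFrame(
                {
                    "compound": pipeline_results["compound"],
                    "quantity": "aw",
                    "log_k": pipeline_results["log_kaw"],
                }
            ),
        ],
        ignore_index=True,
    )
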