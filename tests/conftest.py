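import numpy as np
import pandas as pd
import pytest

from phagestress import pipeline
from phagestress.synthetic_data import make_fixture_bundle

FIXTURE_SEED = 20220223


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The packaged synthetic dataset: every stage exercised once."""
    out = tmp_path_factory.mktemp("fixture")
    return make_fixture_bundle(FIXTURE_SEED, out)


@pytest.fixture(scope="session")
def fixture_run(fixture_bundle, tmp_path_factory):
    """Full pipeline results on the fixture bundle."""
    out = tmp_path_factory.mktemp("results")
    cfg = pipeline.RunConfig(
        plaque_counts=str(fixture_bundle["plaque_counts"]),
        layout=str(fixture_bundle["layout"]),
        measurements=str(fixture_bundle["measurements"]),
        out_dir=str(out))
    return cfg, pipeline.run_pipeline(cfg)


def random_plaque_table(rng: np.random.Generator, n_samples: int = 3,
                        n_plates: int = 2) -> pd.DataFrame:
    """A small well-formed plaque-count table with random contents."""
    rows = []
    for i in range(n_samples):
        for d in range(n_plates):
            rows.append({
                "sample_id": f"s{i}",
                "stressor": rng.choice(["heat", "urea", "saline", "none"]),
                "level": float(rng.integers(0, 80)),
                "duration_min": float(rng.integers(0, 90)),
                "stock_id": rng.choice(["A", "B", "stock-é"]),
                "dilution_exponent": int(rng.integers(0, 8)),
                "volume_ml": 0.1,
                "plaques": int(rng.integers(0, 400)),
            })
    return pd.DataFrame(rows)
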