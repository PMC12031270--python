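import dataclasses

import numpy as np
import pytest

from pearbrowning.classify import SliceRecord
from pearbrowning.pipeline import PipelineConfig, fit_slices, load_metadata
from pearbrowning.synthetic import GeneratorConfig, generate_dataset, generate_shape_trajectories


def records_from_truth(truth) -> list[SliceRecord]:
    """Slice records carrying the generator's *true* shape factors."""
    return [
        SliceRecord(r.slice_id, r.group, r.time_min, r.beta_bi_true, r.beta_yi_true)
        for r in truth.itertuples()
    ]


@pytest.fixture(scope="session")
def default_truth():
    """Truth table under the default study design (216 slices, seed 11)."""
    return generate_shape_trajectories(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def default_records(default_truth):
    return records_from_truth(default_truth)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full default synthetic dataset pushed through the image pipeline.

    Expensive (216 rendered images, 432 Weibull fits) and therefore shared:
    returns (truth table, fitted slice records).
    """
    root = tmp_path_factory.mktemp("dataset")
    cfg = GeneratorConfig(seed=11)
    ds = generate_dataset(cfg, root)
    meta = load_metadata(root)
    records, _ = fit_slices(meta, root, PipelineConfig())
    return ds.truth, records


def chance_records(seed: int, n: int = 100) -> list[SliceRecord]:
    """Two classes with identical feature distributions (no real signal)."""
    rng = np.random.default_rng(seed)
    recs = []
    for cls in ("A", "B"):
        for i, (v, w) in enumerate(zip(rng.normal(2.0, 0.5, n), rng.normal(1.5, 0.4, n))):
            recs.append(
                SliceRecord(f"{cls}{i}", cls, 0.0, max(0.05, v), max(0.05, w))
            )
    return recs


def replace(obj, **kw):
    return dataclasses.replace(obj, **kw)
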