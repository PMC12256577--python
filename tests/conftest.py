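"""Shared fixtures.

The desk-scale denoising experiment (simulate -> train -> evaluate at
64x64 / 200 pairs) is expensive, so it runs once per session and is
shared by every test that needs a trained model.
"""

import numpy as np
import pytest

from petcycle.evaluation import evaluate_model
from petcycle.phantom import generate_dataset
from petcycle.presets import (DESK, desk_scale_phantom_spec,
                              desk_scale_train_config)
from petcycle.training import fit


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """Full desk-scale pipeline: dataset, training run, test-split report."""
    root = tmp_path_factory.mktemp("desk")
    spec = desk_scale_phantom_spec()
    manifest = generate_dataset(spec, n_phantoms=DESK.n_phantoms,
                                slices_per_phantom=DESK.slices_per_phantom,
                                out_dir=root / "data", seed=11)
    cfg = desk_scale_train_config(seed=7)
    summary = fit(cfg, manifest, root / "run")
    report = evaluate_model(root / "run" / "best.npz", manifest,
                            split="test", reference="truth")
    return {"manifest": manifest, "run_dir": root / "run",
            "summary": summary, "report": report, "config": cfg}
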