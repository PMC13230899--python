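"""Run the five-stage pipeline (simulate -> extract -> train -> correct ->
evaluate) from a single config, with on-disk artifacts and resume support.

Equivalent to `snvpurify run --config ... --out ...` on the command line.
"""

import tempfile
from pathlib import Path

from snvpurify.config import validate_config
from snvpurify.pipeline import run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg, errors = validate_config({
        "seed": 11,
        "output_root": str(Path(tmp) / "run"),
        "simulation": {"n_samples": 80, "true_count_range": [200, 800]},
        "model": {"d_model": 16, "n_heads": 2, "n_blocks": 1},
        "train": {"max_epochs": 20, "patience": 20, "batch_size": 16},
        "evaluate": {"figures": False},
    })
    assert not errors, errors
    manifest = run_pipeline(cfg)
    print("artifacts written:")
    for key in ("simulated", "features", "checkpoint", "corrected"):
        print(f"  {key:12s} {manifest[key]}")
    print(f"  evaluation   {manifest['evaluation']['per_bin']}")
    print(f"\nheld-out samples: {len(manifest['holdout_ids'])} "
          "(evaluation tables are computed on these only)")
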