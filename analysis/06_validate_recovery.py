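#!/usr/bin/env python
"""Score the run against the generator's truth tables: cleavage-site
recall/precision (exact and +-20 nt), PAS-class accuracy, feature
accuracy, and the internal-priming decoy removal rate.
"""

import argparse
from pathlib import Path

from pasite.pipeline import validate_run_dir, write_validation


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=Path, default=Path("results/synthetic_run"))
    args = ap.parse_args()

    metrics = validate_run_dir(args.dir)
    write_validation(metrics, args.dir / "validation.json")
    for key in ("n_truth_sites", "n_clusters", "recall_exact",
                "precision_exact", "recall_within_20", "precision_within_20",
                "pas_accuracy", "feature_accuracy", "n_decoy_reads",
                "decoy_removal_rate"):
        v = metrics[key]
        print(f"{key}: {v:.4f}" if isinstance(v, float) else f"{key}: {v}")


if __name__ == "__main__":
    main()
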