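#!/usr/bin/env python
"""Generate the study's synthetic inputs: a tumour/germline variant pair with
planted filter failures, a per-base depth track, a two-timepoint clone
scenario, and the reconstructed 40-patient outcome table.

Writes everything under results/simulated/ for the downstream scripts.
"""

import json
from pathlib import Path

from neoexome import io_formats as io
from neoexome.clinical import write_outcomes
from neoexome.refdata import synthetic_signature_catalog
from neoexome.synthetic import (
    CohortSpec,
    SimulationConfig,
    generate_cohort,
    generate_depth_track,
    generate_pair,
    generate_timepoint_pair,
)

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"

CONFIG = SimulationConfig(
    seed=SEED,
    n_snvs=400,
    n_indels=60,
    signature_weights={"Signature 1": 0.6, "Signature 3": 0.4},
    clone_vafs_diagnostic=[0.45, 0.15],
    clone_vafs_residual=[0.40, 0.25],
    clone_map_residual=[0, None],
    planted_failures={"tumour_depth": 5, "vaf": 5, "call_quality": 3,
                      "indel_interior_support": 3, "repeat_adjacency": 2},
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = synthetic_signature_catalog()
    io.write_signature_matrix(matrix, OUT / "signature_matrix.csv")

    tumour, germ, truth = generate_pair(CONFIG, matrix)
    io.write_variants(tumour, OUT / "tumour_variants.tsv")
    io.write_variants(germ, OUT / "germline_variants.tsv")
    (OUT / "ground_truth.json").write_text(json.dumps(
        {"fates": {u: list(v) for u, v in truth.fates.items()},
         "signatures": truth.signatures}, indent=2))

    track = generate_depth_track(200_000, 0.9, seed=SEED)
    io.write_depth_track(track, OUT / "depth_track.bed")

    diag, resid, clone_truth = generate_timepoint_pair(CONFIG, matrix)
    io.write_variants(diag, OUT / "diagnostic_variants.tsv")
    io.write_variants(resid, OUT / "residual_variants.tsv")
    (OUT / "clone_truth.json").write_text(json.dumps(clone_truth.clone_fates, indent=2))

    cohort = generate_cohort(CohortSpec(seed=SEED))
    write_outcomes(cohort, OUT / "outcomes.csv")

    n_fail = sum(1 for fate, _ in truth.fates.values() if fate == "fail")
    print(f"wrote {len(tumour)} tumour records ({n_fail} planted filter failures), "
          f"{len(germ)} germline records")
    print(f"depth track: {track.length} bp, clone scenario: "
          f"{len(diag)} diagnostic / {len(resid)} residual variants, "
          f"cohort: {len(cohort)} patients")


if __name__ == "__main__":
    main()
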