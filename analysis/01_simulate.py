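"""Generate the synthetic study that stands in for the raw MS data.

Writes a complete input directory under results/inputs: a two-strain
replicate time-course peptide table (3 and 4 timepoints, 4 replicates
each), a 27-species tree with orthogroup presence/absence traits
(planted coevolving pairs), a small GO DAG with gene annotations and a
DOOR-style operon table, plus the planted ground truth.
"""

import json
from dataclasses import asdict
from pathlib import Path

from pufgba.evidence import write_synthetic_inputs
from pufgba.simulate import SimStudyConfig, SimTraitConfig

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    indir = ROOT / "results" / "inputs"
    study_cfg = SimStudyConfig(seed=SEED)
    trait_cfg = SimTraitConfig(seed=SEED)
    study_truth, trait_truth = write_synthetic_inputs(
        indir, study_cfg, trait_cfg, seed=SEED)

    truth = {
        "true_de": study_truth.true_de,
        "true_clusters": study_truth.true_clusters,
        "true_dependent_pairs": sorted(map(list, trait_truth.true_dependent_pairs)),
        "lod_threshold_per_sample": study_truth.lod_threshold_per_sample,
    }
    (indir / "truth.json").write_text(json.dumps(truth, indent=1))
    (indir / "config.json").write_text(json.dumps(
        {"study": asdict(study_cfg), "traits": asdict(trait_cfg)}, indent=1))

    print(f"wrote synthetic inputs to {indir}")
    print(f"  {study_cfg.n_proteins} proteins ({study_cfg.n_puf} PUFs), "
          f"{len(study_truth.true_de)} planted DE proteins")
    print(f"  {len(trait_truth.true_dependent_pairs)} planted coevolving "
          f"orthogroup pairs on a 27-species tree")


if __name__ == "__main__":
    main()
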