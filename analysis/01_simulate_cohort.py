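"""Simulate the reference serum/tissue methylation cohort and summarize it.

Generates the default study scenario (50 meningioma + 50 non-meningioma
serum samples, paired and tissue-only meningioma series, nontumor brain
controls; planted diagnostic/prognostic/cluster probe sets; immune
mixtures; recurrence outcomes) and writes a cohort overview to results/.
The full beta matrix is large and is re-derived deterministically by every
later driver, so only the summary is persisted.
"""

import json
import os

from melb.synthetic_data import SimulationConfig, simulate_cohort, config_to_dict

SEED = 11
OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    cfg = SimulationConfig(seed=SEED)
    beta, sheet, gt = simulate_cohort(cfg)
    os.makedirs(OUT, exist_ok=True)

    counts = (sheet.table.groupby(["specimen", "group", "outcome"])
              .size().rename("n").reset_index())
    counts.to_csv(os.path.join(OUT, "01_cohort_summary.tsv"), sep="\t",
                  index=False)
    summary = {
        "config": config_to_dict(cfg),
        "n_probes": beta.shape[0],
        "n_samples": beta.shape[1],
        "planted": {
            "diagnostic_probes": len(gt.diagnostic_probes),
            "prognostic_probes": len(gt.prognostic_probes),
            "cluster_probes_per_cluster": {str(k): len(v) for k, v in
                                           gt.cluster_probes.items()},
            "immune_probes": len(gt.immune_probes),
        },
        "outcomes_tissue_mng": sheet.rows(specimen="tissue", group="MNG")
        ["outcome"].value_counts().to_dict(),
    }
    with open(os.path.join(OUT, "01_cohort_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)

    print(f"cohort: {beta.shape[0]} probes x {beta.shape[1]} samples")
    print(counts.to_string(index=False))
    print("tissue MNG outcomes:", summary["outcomes_tissue_mng"])


if __name__ == "__main__":
    main()
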