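"""Simulate the whole-cell recording population used by the downstream analyses.

Builds the full study design — 12 visually tuned (γd-like) and 11 olfactory
(α/β-like) Kenyon cells, each tested with 2 light and 5 odor stimuli, 6
trials per cell-stimulus pair — and reports what was generated: pair counts
per cell type and modality and ground-truth event totals.  A two-cell
example dataset is persisted for the classification driver; the full
population is regenerated from the same seed wherever it is needed, so
nothing large has to live on disk.
"""

import argparse
from pathlib import Path

import pandas as pd

from kcmod import generate_population, study_design, write_dataset

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    profiles, stimuli = study_design()
    dataset = generate_population(profiles, stimuli, n_trials=6, seed=args.seed)

    rows = []
    for (cell, stim), trials in sorted(dataset.pairs().items()):
        t0 = trials[0]
        rows.append(
            {
                "cell_id": cell,
                "cell_type": t0.cell_type,
                "stimulus_id": stim,
                "modality": t0.modality,
                "n_trials": len(trials),
                "true_spikes_total": sum(len(t.true_spike_times_s) for t in trials),
                "true_epsp_mv": t0.true_event_peaks_mv[0],
                "true_ipsp_mv": t0.true_event_peaks_mv[1],
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "01_population_summary.csv", index=False)

    by = summary.groupby(["cell_type", "modality"]).size().unstack()
    print(f"simulated {len(dataset)} trials across {dataset.n_pairs} cell-stimulus pairs")
    print("pairs per cell type and modality:")
    print(by.to_string())
    print(
        "ground-truth spikes: %d total (%d in light pairs, %d in odor pairs)"
        % (
            summary.true_spikes_total.sum(),
            summary.loc[summary.modality == "light", "true_spikes_total"].sum(),
            summary.loc[summary.modality == "odor", "true_spikes_total"].sum(),
        )
    )

    example = type(dataset)(
        [t for t in dataset.trials if t.cell_id in ("gd_00", "ab_00")]
    )
    write_dataset(example, RESULTS / "example_dataset", fmt="hdf5")
    print(f"persisted {len(example)} example trials to {RESULTS/'example_dataset'}")


if __name__ == "__main__":
    main()
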