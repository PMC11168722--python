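"""Generate the packaged two-condition synthetic study.

Builds the rich-club connectome, the 116-parcel label table, and the
two-condition BOLD ensemble (20 subjects x 2 conditions x 350 TRs at TR = 2 s;
rest-like G = 0.04, meditation-like G = 0.09), and writes everything under
results/data/ with a manifest. Ground truth (G per condition, node
frequencies) is fully determined by the scenario seeds, so every later stage
can be checked against it.
"""

from pathlib import Path

from pmspace import io as pio
from pmspace.synthetic import (
    default_scenario,
    make_parcel_labels,
    make_structural_connectivity,
    make_two_condition_dataset,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    scenario = default_scenario()
    OUT.mkdir(parents=True, exist_ok=True)
    sc = make_structural_connectivity(scenario.n_parcels, seed=scenario.sc_seed)
    pio.write_matrix_tsv(OUT / "sc.tsv", sc)
    labels = make_parcel_labels()
    pio.write_labels(OUT / "labels.csv", labels)
    dataset = make_two_condition_dataset(scenario, sc)
    files = [str(pio.write_bold(OUT / "bold", ts)) for ts in dataset.values()]
    pio.write_manifest(
        OUT / "synth_manifest.json",
        {
            "scenario": {
                "n_parcels": scenario.n_parcels,
                "n_subjects": scenario.n_subjects,
                "n_timepoints": scenario.n_timepoints,
                "tr": scenario.tr,
                "sc_seed": scenario.sc_seed,
                "sim_seed": scenario.sim_seed,
                "g_true_by_condition": dict(scenario.g_true_by_condition),
            },
            "files": files,
        },
    )
    print(f"wrote {len(files)} BOLD series ({scenario.n_parcels} parcels x "
          f"{scenario.n_timepoints} TRs), sc.tsv and labels.csv under {OUT}")
    print(f"ground truth: G = {dict(scenario.g_true_by_condition)}")


if __name__ == "__main__":
    main()
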