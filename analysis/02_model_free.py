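"""Model-free stage: LEiDA substates and per-condition PMS with statistics.

Loads the generated study from results/data/, runs the chain
filter -> Hilbert phase -> phase coherence -> leading eigenvector -> K-means
(k = 2..4 at desk scale) -> PMS -> permutation contrast with FDR, selects k,
and writes centroids, assignments, PMS tables and test results under
results/model_free/.
"""

from pathlib import Path

from pmspace import io as pio
from pmspace.pipeline import RunConfig, run_model_free

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    manifest = pio.read_manifest(ROOT / "data" / "synth_manifest.json")
    tr = manifest["scenario"]["tr"]
    dataset = pio.read_bold_glob(str(ROOT / "data" / "bold" / "bold_*.tsv"), tr)
    config = RunConfig.desk()
    result = run_model_free(dataset, config, outdir=ROOT / "model_free")
    print(f"pooled {result.n_eigenvectors_pooled} leading eigenvectors")
    print(f"selected k = {result.chosen_k}")
    for cond, pms in result.pms_by_k[result.chosen_k].items():
        print(f"  PMS[{cond}] = {pms.probabilities.round(4)}")
    test = result.tests_by_k[result.chosen_k]
    print(f"  FDR-corrected p per substate: {test.p_fdr.round(4)}")


if __name__ == "__main__":
    main()
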