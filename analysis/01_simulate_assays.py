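"""Generate synthetic datasets for all four bioassays.

One dataset per assay (Microtox, Artemia, Daphnia, Lemna), each with a
known true EC50 and the replicate design of its protocol, written as tidy
CSVs plus JSON truth sidecars under results/simulated/.  These are the
inputs of the downstream fitting and classification steps.
"""

from pathlib import Path

from uvtox.synthetic import SyntheticTruth, simulate, write_synthetic_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"

# one representative truth per assay; EC50s span the acute band
TRUTHS = [
    SyntheticTruth(true_ec50=4.5, assay="microtox", seed=101,
                   compound_code="SYN-MTX"),
    SyntheticTruth(true_ec50=5.3, assay="artemia", seed=102,
                   compound_code="SYN-ART"),
    SyntheticTruth(true_ec50=2.7, assay="daphnia", seed=103,
                   compound_code="SYN-DAP"),
    SyntheticTruth(true_ec50=3.0, assay="lemna", seed=104,
                   compound_code="SYN-LEM"),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for truth in TRUTHS:
        series = simulate(truth)
        write_synthetic_dataset(series, truth,
                                OUT / f"{truth.assay}.csv",
                                OUT / f"{truth.assay}_truth.json")
        n_obs = sum(len(s.observations) for s in series)
        print(f"{truth.assay:9s} true EC50 {truth.true_ec50:5.2f} mg/L  "
              f"{len(series)} series, {n_obs} observations -> "
              f"{OUT / (truth.assay + '.csv')}")


if __name__ == "__main__":
    main()
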