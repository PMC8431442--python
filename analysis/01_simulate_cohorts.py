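"""Generate the synthetic training and test cohorts used by the downstream
analyses.

Training cohort: 30 PDAC / 18 CP specimens; test cohort: 27 PDAC / 15 CP —
the sizes of the study the pipeline targets.  Each cohort carries a planted
diagnostic miRNA pair (up in PDAC / up in CP), a planted metastasis pair
inside PDAC, log-normal CA19-9, and exponential overall survival tied to
the metastasis ratio.  Outputs: counts TSV, metadata CSV (with a
train/test split column) and the planted-truth JSON under results/data/.
"""

from pathlib import Path

import pandas as pd

from evmir import SimConfig, io, normalize, simulate

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def build_cohort(cfg: SimConfig, prefix: str, split: str):
    cohort = simulate.simulate_cohort(cfg)
    norm = normalize.normalize_counts(cohort.counts)
    pdac = cohort.samples.index[cohort.samples["diagnosis"] == "PDAC"]
    met_marker = (norm.values.loc["miR-335-5p"] / norm.values.loc["miR-340-5p"])[pdac]
    cohort.samples = simulate.simulate_survival(cohort.samples, met_marker, cfg)
    cohort.counts.columns = [f"{prefix}{c}" for c in cohort.counts.columns]
    cohort.samples.index = [f"{prefix}{c}" for c in cohort.samples.index]
    cohort.samples["split"] = split
    return cohort


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    train = build_cohort(SimConfig(n_pdac=30, n_cp=18, seed=SEED), "TR-", "train")
    test = build_cohort(SimConfig(n_pdac=27, n_cp=15, seed=SEED + 1), "TE-", "test")
    counts = pd.concat([train.counts, test.counts], axis=1)
    samples = pd.concat([train.samples, test.samples])
    io.write_counts(counts, OUT / "counts.tsv")
    io.write_metadata(samples, OUT / "metadata.csv")
    io.write_truth({"train": train.truth, "test": test.truth}, OUT / "truth.json")
    n_ev = int(samples["os_event"].fillna(False).sum())
    print(f"wrote {counts.shape[0]} miRNAs x {counts.shape[1]} specimens "
          f"({len(train.samples)} train + {len(test.samples)} test) to {OUT}")
    print(f"PDAC specimens with survival: "
          f"{samples['os_days'].notna().sum()} ({n_ev} deaths observed)")


if __name__ == "__main__":
    main()
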