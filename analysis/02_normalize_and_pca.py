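"""Normalize the simulated cohorts and inspect the specimen structure by PCA.

Per cohort: housekeeping selection (>= 1 read in all specimens), 75th-
percentile size factors, normalized expression; then per-miRNA max-scaling
and PCA of the specimens.  Writes normalized matrices and PC coordinates
under results/.
"""

from pathlib import Path

import pandas as pd

from evmir import io, normalize

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = io.read_counts(ROOT / "data" / "counts.tsv")
    samples = io.read_metadata(ROOT / "data" / "metadata.csv", counts)
    out = ROOT / "normalized"
    out.mkdir(parents=True, exist_ok=True)
    for split in ("train", "test"):
        ids = samples.index[samples["split"] == split]
        nm = normalize.normalize_counts(counts[ids])
        nm.values.to_csv(out / f"normalized_{split}.tsv", sep="\t",
                         index_label="mirna_id")
        scaled, dropped = normalize.max_scale(nm.values)
        res = normalize.pca(scaled, n_components=5)
        coords = res.coordinates.assign(diagnosis=samples.loc[ids, "diagnosis"])
        coords.to_csv(out / f"pca_{split}.tsv", sep="\t", index_label="specimen_id")
        pc1, pc2 = res.variance_fractions[:2]
        print(f"[{split}] housekeeping: {len(nm.housekeeping_ids)} miRNAs; "
              f"size factors {nm.size_factors.min():.0f}-{nm.size_factors.max():.0f}; "
              f"{dropped} all-zero rows dropped before PCA")
        print(f"[{split}] PC1/PC2 variance fractions: {pc1:.1%} / {pc2:.1%}")
        # how well do the first two PCs separate the diagnosis groups?
        sep = coords.groupby("diagnosis")[["PC1", "PC2"]].mean()
        print(f"[{split}] group mean PC coordinates:\n{sep.round(2)}")


if __name__ == "__main__":
    main()
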