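"""Bayesian-network cause/consequence analysis.

Median-discretizes the most abundant training-cohort miRNAs, appends the
cancer / pancreatitis / metastasis indicator nodes, learns a DAG by
BIC-scored tabu search, and extracts the cause/consequence neighborhood of
the cancer node.  The planted diagnostic miRNAs should attach to the
pathology nodes.
"""

from pathlib import Path

from evmir import PipelineConfig, io, run_pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = io.read_counts(ROOT / "data" / "counts.tsv")
    samples = io.read_metadata(ROOT / "data" / "metadata.csv", counts)
    report = run_pipeline(PipelineConfig(output_dir=str(ROOT / "pipeline")),
                          counts=counts, samples=samples)
    dag = report.bn_dag
    causes, consequences, sub = report.cancer_neighborhood
    print(f"learned network: {len(dag.nodes)} nodes, {len(dag.edges)} edges, "
          f"BIC {dag.score:.1f}")
    print(f"causes of cancer:       {sorted(causes)}")
    print(f"consequences of cancer: {sorted(consequences)}")
    print(f"cancer subnetwork edges: {sorted(sub.edges)}")
    planted = {"miR-95-3p", "miR-26b-5p"}
    linked = planted & (causes | consequences)
    print(f"planted diagnostic miRNAs adjacent to the cancer node: {sorted(linked)}")


if __name__ == "__main__":
    main()
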