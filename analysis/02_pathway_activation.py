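#!/usr/bin/env python
"""Score pathway activation for every sample of the simulated aging study.

Reads the expression matrices and annotations written by
01_simulate_aging_study.py through the same file-based route real data
would take, computes per-sample PAS against each dataset's reference
(Young samples for the aging datasets, matched healthy controls for the
progeria datasets; the Young group itself is scored unfiltered), and
writes the PAS matrix plus differential tables under results/aging4/.
"""

import json
from pathlib import Path

import pandas as pd

from pasdrift import (
    assemble_groups,
    compute_pas_matrix,
    load_pathway_collection,
    read_annotations,
    read_expression_matrix,
)
from pasdrift.pipeline import write_pas_outputs

IN = Path("results/aging4/inputs")
OUT = Path("results/aging4")


def main() -> None:
    truth = json.loads((IN / "ground_truth.json").read_text())
    matrices = {
        p.stem: read_expression_matrix(p, dataset_id=p.stem)
        for p in sorted(IN.glob("*.tsv"))
        if p.stem not in ("annotations", "pathways")
    }
    annotations = read_annotations(IN / "annotations.tsv")
    collection = load_pathway_collection(IN / "pathways.tsv")
    groups = assemble_groups(annotations, matrices)
    pas = compute_pas_matrix(
        matrices, groups, collection, truth["reference"], mode="filtered"
    )
    write_pas_outputs(pas, OUT)

    print(f"PAS matrix: {pas.values.shape[0]} pathways x {pas.values.shape[1]} samples")
    print("group means of |PAS| (activation magnitude per group):")
    by_group = pas.values.T.abs().groupby(pas.sample_groups).mean().mean(axis=1)
    print(by_group.round(2).to_string())
    n_btif = {
        f"{d.dataset_id}/{d.group}": int(d.table["btif"].sum())
        for d in pas.differentials
        if d.mode == "filtered"
    }
    print(f"gated (significant) genes per dataset/group comparison: {n_btif}")


if __name__ == "__main__":
    main()
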