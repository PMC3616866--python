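#!/usr/bin/env python
"""Event-recovery study on simulated gene families with known truth.

Simulates 500 families in the low-rate regime (expected total events per
lineage per unit-length species branch below 0.1), runs the inference
chain on each survivor, and measures how well duplication, loss, fusion
and fission events are recovered against the ground-truth logs.

Findings (seed base 0): pooled fusion recall is ~0.94; duplication and
loss counts are never over-called (parsimony under-counts them by
construction); in rare families where one fusion is later reversed by a
fission, the minimum-cost solution is ambiguous and the deterministic
tie-break can report two fusions instead of a fusion–fission pair.
"""

import json
from pathlib import Path

import pandas as pd

import domrec
from domrec import presets
from domrec.simulate import recovery_report, simulate

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_SEEDS = 500


def main() -> None:
    st = presets.unit_species_tree()
    rows = []
    matched = true_fus = 0
    for seed in range(N_SEEDS):
        fam = simulate(presets.low_rate_params(seed))
        if fam.extinct or len(fam.leaf_annotations) < 2:
            continue
        rec = domrec.reconcile(
            domrec.bind(fam.gene_tree, st, fam.leaf_annotations))
        asg = domrec.infer_states(rec)
        rep = recovery_report(fam, rec, asg)
        rows.append({
            "seed": seed, "n_genes": len(fam.leaf_annotations),
            **{f"true_{k}": v for k, v in rep["true_counts"].items()},
            **{f"inferred_{k}": v for k, v in rep["inferred_counts"].items()},
            "fusion_recall": rep["fusion_recall"],
            "fusion_precision": rep["fusion_precision"],
        })
        matched += rep["matched_fusions"]
        true_fus += rep["true_counts"]["fusion"]

    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "recovery_per_seed.tsv", sep="\t", index=False)
    summary = {
        "n_families": len(df),
        "pooled_fusion_recall": matched / true_fus if true_fus else None,
        "true_fusion_events": true_fus,
        "matched_fusion_events": matched,
        "families_overcalling_dups":
            int((df.inferred_duplication > df.true_duplication).sum()),
        "families_overcalling_losses":
            int((df.inferred_loss > df.true_loss).sum()),
        "families_overcalling_fusions":
            int((df.inferred_fusion > df.true_fusion).sum()),
        "families_overcalling_fissions":
            int((df.inferred_fission > df.true_fission).sum()),
    }
    (RESULTS / "recovery_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))
    print(f"wrote {RESULTS / 'recovery_per_seed.tsv'}")


if __name__ == "__main__":
    main()
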