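#!/usr/bin/env python
"""Overall-gait-behavior phenotyping: k-means on the seven z-scored metrics.

At each speed condition (every participant's slowest and fastest belt speed),
selects the number of clusters with the silhouette method, clusters, and
quantifies the structure: within/between sums of squares, random-forest
permutation importance of each metric, PCA projection for visualization, the
cross-condition composition (who switches cluster when walking fast), and
Mann-Whitney contrasts of Fugl-Meyer scores and gait speeds between the
stroke participants of the two clusters.

Writes results/cluster_<condition>_{labels,centroids,importance,pca}.csv and
results/cluster_report.json.  Requires the outputs of 01_simulate_cohort.py.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from hemigait import clusterpipe as cp
from hemigait import markerio, pipeline

SEED = 20233
OUT = Path("results")


def main() -> None:
    table = pd.read_csv(OUT / "metrics.csv")
    metas = markerio.read_metadata(OUT / "participants.csv")
    report: dict = {"conditions": {}}
    results = {}

    for cond in ("self_selected", "fast"):
        wide = pipeline.condition_table(table, cond)
        res = cp.cluster_condition(wide, cond, seed=SEED, n_trees=500)
        results[cond] = res
        stem = OUT / f"cluster_{cond}"
        res.label_of().to_csv(f"{stem}_labels.csv")
        pd.DataFrame(res.centroids, columns=list(cp.METRIC_COLUMNS)).to_csv(
            f"{stem}_centroids.csv", index_label="cluster"
        )
        res.importance.to_csv(f"{stem}_importance.csv")
        pd.DataFrame(res.pca_scores, index=res.participant_ids,
                     columns=["PC1", "PC2"]).to_csv(f"{stem}_pca.csv")

        comp = (
            wide.loc[res.participant_ids, "group"]
            .groupby(res.label_of()).value_counts().to_dict()
        )
        report["conditions"][cond] = {
            "chosen_k": res.chosen_k,
            "silhouette_by_k": res.silhouette_by_k,
            "wss_per_cluster": res.wss_per_cluster.tolist(),
            "bss": res.bss,
            "composition": {f"cluster{c}_{g}": int(n) for (c, g), n in comp.items()},
            "importance_ranking": list(res.importance.index),
        }
        print(f"{cond}: k={res.chosen_k}, BSS={res.bss:.1f}, "
              f"WSS={res.wss_per_cluster.round(1).tolist()}, "
              f"top metric: {res.importance.index[0]}")

    comparison = cp.compare_conditions(results["self_selected"], results["fast"])
    report["n_switchers"] = comparison["n_switchers"]
    report["switchers"] = comparison["switchers"]
    report["bss_change"] = comparison["bss_change"]
    print(f"Cluster switchers at fast speed: {comparison['n_switchers']} "
          f"({', '.join(comparison['switchers']) or 'none'}); "
          f"BSS change {comparison['bss_change']:+.1f}")

    for variable in ("le_fugl_meyer", "speed"):
        try:
            contrast = cp.clinical_contrast(results["self_selected"].label_of(), metas, variable)
        except cp.ClusterError as exc:
            report[f"{variable}_contrast"] = str(exc)
            continue
        report[f"{variable}_contrast"] = contrast
        print(f"Mann-Whitney {variable} between stroke subgroups: "
              f"U={contrast['U']:.0f}, p={contrast['p']:.4f} "
              f"(medians {contrast['medians']}, n={contrast['n']})")

    (OUT / "cluster_report.json").write_text(json.dumps(report, indent=1, default=str))
    print(f"Wrote {OUT / 'cluster_report.json'}")


if __name__ == "__main__":
    sys.exit(main())
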