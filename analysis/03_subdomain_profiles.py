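#!/usr/bin/env python
"""Sub-domain sensitivity analysis: re-derive sub-groups within each of the
psychosocial, spinal-tissue and nervous-system domains separately (using
the screening survivors of the primary analysis), then combine each case's
per-domain labels into one overall profile, mirroring how a clinician
would read contributions per domain.  Writes results/subdomain/."""

import argparse
from pathlib import Path

import pandas as pd

from painstrat import (
    PipelineConfig,
    collinearity_filter,
    combine_subdomain_labels,
    group_t_tests,
    load_feature_table,
)
from painstrat.pipeline import run_subdomain

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    args = ap.parse_args()

    cohort = ROOT / "results" / "cohort"
    table = load_feature_table(cohort / "cohort.csv", cohort / "metadata.csv")
    out = ROOT / "results" / "subdomain"
    out.mkdir(parents=True, exist_ok=True)

    cfg = PipelineConfig(seed=args.seed)
    scr = group_t_tests(table, alpha=cfg.alpha)
    collinearity_filter(table, scr, r_threshold=cfg.r_threshold)
    survivors = scr.selected
    print(f"screening survivors: {survivors}")

    labels = {}
    for dom in ("psychosocial", "spinal", "nervous"):
        res = run_subdomain(table, cfg, dom, survivors)
        if res.skipped:
            print(f"{dom}: skipped — {res.reason}")
            labels[dom] = pd.Series("normal", index=table.cases().data.index)
            continue
        print(f"{dom}: {res.model.k} clusters on {res.validity.selected_features}, "
              f"sizes {res.model.cluster_sizes}, "
              f"silhouette {res.model.silhouette_index:.2f}")
        res.labels.to_csv(out / f"labels_{dom}.csv")
        labels[dom] = res.labels

    profiles = combine_subdomain_labels(labels)
    frame = pd.DataFrame([p.__dict__ for p in profiles])
    frame.to_csv(out / "combined_profiles.csv", index=False)
    census = frame["domains_contributing"].map(
        lambda d: " + ".join(d) if d else "none"
    ).value_counts()
    print("domain-contribution census:")
    for combo, n in census.items():
        print(f"  {combo}: {n} ({100 * n / len(frame):.0f}%)")
    print(f"artifacts in {out}")


if __name__ == "__main__":
    main()
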