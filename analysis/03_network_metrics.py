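#!/usr/bin/env python
"""Summarise network- and cohort-level metrics of the profiled run.

Reads results/run/ and reports: reaction presence differences between
groups, strong flux-species correlations, independent sulfur species by
group and degrader status, and the ordination separation of the
contribution profiles.
"""

from pathlib import Path

import pandas as pd

RUN = Path("results/run")


def main():
    sulfur = pd.read_csv(RUN / "metrics/sulfur_counts.tsv", sep="\t", index_col=0)
    print("independent sulfur species by group and glycan-degrader status:")
    print(
        sulfur.groupby(["group", "has_glycan_degrader"])[
            "n_independent_sulfur"
        ].agg(["count", "mean"])
    )

    strong = pd.read_csv(RUN / "metrics/strong_correlations.tsv", sep="\t")
    print(f"\n{len(strong)} strong (|rho| > 0.75) metabolite-species pairs; "
          f"{strong.metabolite_id.nunique()} metabolites involved")
    print(strong.sort_values("rho", ascending=False).head(8).to_string(index=False))

    presence = pd.read_csv(RUN / "metrics/reaction_presence.tsv", sep="\t",
                           index_col=0)
    counts = pd.read_csv(RUN / "metrics/secreted_counts.tsv", sep="\t",
                         index_col=0)
    groups = counts["group"]
    frac = presence.groupby(groups).mean()
    spread = (frac.loc["healthy"] - frac.loc["IBD_dysbiotic"]).abs()
    print("\nreactions with the largest presence gap (healthy vs dysbiotic):")
    print(spread.sort_values(ascending=False).head(8).to_string())

    coords = pd.read_csv(RUN / "metrics/pcoa_coordinates.tsv", sep="\t",
                         index_col=0)
    coords["group"] = groups
    print("\ncontribution-profile ordination centroids (first two axes):")
    print(coords.groupby("group")[["axis1", "axis2"]].mean())


if __name__ == "__main__":
    main()
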