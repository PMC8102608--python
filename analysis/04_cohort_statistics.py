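#!/usr/bin/env python
"""Report the cohort statistics of the profiled run.

Reads results/run/stats/ and prints the group screens, the
secretion-diversity regression, the sulfur classification AUC, the
glycan-degrader mediation analysis, the random-forest stratification and
the metabolomic direction agreement.
"""

import json
from pathlib import Path

import pandas as pd

RUN = Path("results/run")


def main():
    report = json.loads((RUN / "stats/report.json").read_text())
    print("secretion-flux screens (Wilcoxon + BH, q < 0.05):")
    print(f"  IBD vs healthy: {report['n_significant_ibd_vs_healthy']} metabolites")
    print(f"  dysbiotic vs non-dysbiotic: "
          f"{report['n_significant_dys_vs_nondys']} metabolites")
    print(f"  independent binary secretions tested (Fisher): "
          f"{report['n_independent_secretions_tested']}, "
          f"{report['n_fisher_significant']} significant")

    reg = report["regression"]
    print("\nsecretion diversity ~ group + f(number of strains):")
    print(f"  chosen FP1 power {reg['chosen_power']} "
          f"(deviance test vs linear p = {reg['form_p']:.3g})")
    print(f"  dysbiosis effect b = {reg['b']:.2f}, "
          f"95% CI ({reg['ci'][0]:.2f}; {reg['ci'][1]:.2f}), "
          f"t({reg['df_resid']}) = {reg['t']:.2f}, p = {reg['p']:.3g}")

    print(f"\nsulfur species count classifies healthy vs dysbiotic: "
          f"AUC = {report['sulfur_auc_healthy_vs_dysbiotic']:.3f}")
    med = report["mediation"]
    print(f"glycan-degrader mediation of the sulfur-diversity effect: "
          f"{100 * med['proportion_mediated']:.1f}% "
          f"(95% CI {100 * med['proportion_ci'][0]:.1f}%–"
          f"{100 * med['proportion_ci'][1]:.1f}%), "
          f"Sobel z = {med['z']:.2f}, p = {med['p']:.3g}, "
          f"{med['n_bootstrap']} bootstrap replications")

    print(f"\nrandom forest (dysbiotic vs non-dysbiotic) OOB error: "
          f"{report['rf_oob_error']:.4f}")
    rf = pd.read_csv(RUN / "stats/rf_top_features.tsv", sep="\t", index_col=0)
    print("top discriminating secreted metabolites (mean decrease accuracy):")
    print(rf.head(6).to_string())

    if "direction_agreement" in report:
        ag = report["direction_agreement"]
        print(f"\nagreement with the (synthetic) metabolomic reference: "
              f"{ag['n_agree']} of {ag['n_agree'] + ag['n_disagree']} "
              f"({ag['percent']:.1f}%), "
              f"binomial p = {ag['binomial_p']:.3g} "
              f"(Fisher variant p = {ag['fisher_p']:.3g}; "
              f"reported: {ag['reported']})")


if __name__ == "__main__":
    main()
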