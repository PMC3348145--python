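#!/usr/bin/env python
"""Integrate the morphometric and expression dimensions of the cohort.

Reuses the 253-sample feature cohort from the survival driver (regenerated
deterministically if absent), generates the matched expression matrix on the
same samples and response labels, and then (a) tests each signature gene for
differential expression between the feature-split groups (p<0.01) and
(b) maps all highly correlated feature-gene pairs (p<0.005, signed).

Writes results/feature_split_genes.csv and results/feature_gene_pairs.csv.
"""

import argparse
import importlib.util
import sys
from pathlib import Path

from ovmorph import integration as integ
from ovmorph import signature as sig
from ovmorph import survival as surv
from ovmorph import synthetic as syn
from ovmorph.io import read_clinical, read_feature_matrix

_spec = importlib.util.spec_from_file_location(
    "survival_driver", Path(__file__).parent / "04_survival_stratification.py")
_driver = importlib.util.module_from_spec(_spec)
sys.modules["survival_driver"] = _driver
_spec.loader.exec_module(_driver)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    cohort = args.out / "cohort"
    if not (cohort / "features.csv").exists():
        _driver.build_cohort(args.seed, cohort)
    features = read_feature_matrix(cohort / "features.csv")
    labels = read_clinical(cohort / "clinical.tsv")["response"]

    matrix, _, truth = syn.generate_expression_dataset(
        n_genes=1000, labels=labels, seed=args.seed + 7)

    entries = sig.select_morph_features(features, labels, fdr_max=0.02)
    top = entries[0].feature_id
    groups = surv.median_split(features, top)

    gene_entries = sig.select_genes(matrix, labels, 1.5, 0.05)
    signature_genes = [e.feature_id for e in gene_entries]
    split_genes = integ.supervised_gene_analysis(
        matrix, groups, p_max=0.01, genes=signature_genes)
    lower = (split_genes["direction"] == "lower").sum()
    print(f"{len(split_genes)} of {len(signature_genes)} signature genes differ "
          f"between the {top} groups (p<0.01); {lower} lower in the low group")
    split_genes.to_csv(args.out / "feature_split_genes.csv", index=False)

    selected = [e.feature_id for e in entries]
    pairs = integ.feature_gene_correlation(
        features[selected], matrix.loc[signature_genes], p_max=0.005)
    n_pos = (pairs["sign"] == "positive").sum()
    print(f"{len(pairs)} correlated feature-gene pairs at p<0.005 "
          f"({n_pos} positive, {len(pairs) - n_pos} negative)")
    planted = truth.informative_gene_ids
    in_planted = pairs["gene"].isin(planted).mean() if len(pairs) else 0.0
    print(f"{100 * in_planted:.0f}% of correlated pairs involve planted "
          f"signature genes")
    pairs.round(6).to_csv(args.out / "feature_gene_pairs.csv", index=False)


if __name__ == "__main__":
    main()
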