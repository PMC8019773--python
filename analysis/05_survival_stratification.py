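#!/usr/bin/env python
"""Kaplan-Meier stratification: actual versus GA-KPLS-predicted risk groups.

Holds out a stratified 20% test set, GA-tunes and fits KPLS on the remaining
80%, predicts the test patients' risk group, and compares the KM curves (and
log-rank tests) of the actual and the predicted grouping. A good classifier
makes the two panels nearly interchangeable.

Run 01 and 02 first.
"""

import json
from pathlib import Path

import numpy as np

from hfpef_risk.config import GAConfig, KernelConfig
from hfpef_risk.evaluation import confusion_metrics, split_indices
from hfpef_risk.ga import optimize_sigma
from hfpef_risk.io import read_expression_matrix, read_phenotypes, align_samples
from hfpef_risk.kpls import predict_features, train_kpls
from hfpef_risk.preprocessing import log2_standardize
from hfpef_risk.survival import km_summary

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260930


def main() -> None:
    X = read_expression_matrix(ROOT / "cohort" / "expression.tsv")
    pheno = read_phenotypes(ROOT / "cohort" / "phenotypes.csv")
    X, pheno = align_samples(X, pheno)
    Xs = log2_standardize(X, already_log=True)
    y = pheno["outcome"].to_numpy()
    kept = [line.split("\t")[1] for line in
            (ROOT / "screened_genes.tsv").read_text().splitlines()[1:]]
    A = Xs.loc[kept].to_numpy().T

    rng = np.random.default_rng(SEED)
    tr, te = split_indices(len(y), 0.8, rng, y=y)
    gcfg = GAConfig(population_size=10, n_generations=10, patience=5,
                    cv_folds=3, seed=SEED)
    ga = optimize_sigma(A[tr], y[tr], KernelConfig(), gcfg)
    model = train_kpls(A[tr], y[tr],
                       KernelConfig(sigma=ga.best_sigma, n_components=3))
    scores, labels = predict_features(model, A[te])
    mcc = confusion_metrics(y[te], labels, scores).mcc

    test_pheno = pheno.iloc[te].copy()
    actual = km_summary(test_pheno, "outcome")
    out = {"actual": actual, "test_mcc": mcc,
           "sigma": ga.best_sigma, "train_size": len(tr), "test_size": len(te)}
    print(f"split: {len(tr)} train / {len(te)} test; GA sigma = {ga.best_sigma:.4g}")
    print(f"test MCC = {mcc:.3f}")
    print(f"log-rank on actual outcome groups:    p = {actual['logrank_p']:.3g}")
    if len(np.unique(labels)) == 2:
        test_pheno["predicted"] = labels
        predicted = km_summary(test_pheno, "predicted")
        out["predicted"] = predicted
        print(f"log-rank on predicted risk groups:    p = {predicted['logrank_p']:.3g}")
        agree = (actual["logrank_p"] < 0.05) == (predicted["logrank_p"] < 0.05)
        print("significance verdicts agree" if agree else "verdicts differ")
    (ROOT / "km_logrank.json").write_text(json.dumps(out, indent=2))
    print(f"curves -> {ROOT / 'km_logrank.json'}")


if __name__ == "__main__":
    main()
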