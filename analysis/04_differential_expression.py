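#!/usr/bin/env python
"""SAM differential expression between outcome groups on the screened genes.

Moderated d statistics with the variance-stabilizing fudge factor s0 and
permutation-FDR q-values; genes called at q < 0.05, with direction relative
to the good-outcome (control) group. Reports the call counts, the up:down
split, and recovery of the planted DE genes.

Run 01 and 02 first.
"""

import json
from pathlib import Path

from hfpef_risk.io import read_expression_matrix, read_phenotypes, align_samples
from hfpef_risk.preprocessing import log2_standardize
from hfpef_risk.sam import sam_qvalues

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260930


def main() -> None:
    X = read_expression_matrix(ROOT / "cohort" / "expression.tsv")
    pheno = read_phenotypes(ROOT / "cohort" / "phenotypes.csv")
    X, pheno = align_samples(X, pheno)
    truth = json.loads((ROOT / "cohort" / "truth.json").read_text())
    Xs = log2_standardize(X, already_log=True)

    kept = [line.split("\t")[1] for line in
            (ROOT / "screened_genes.tsv").read_text().splitlines()[1:]]
    res = sam_qvalues(Xs.loc[kept], pheno["outcome"].to_numpy(),
                      n_perm=1000, seed=SEED, threshold=0.05)
    res.table.to_csv(ROOT / "deg.tsv", sep="\t", float_format="%.6g")

    counts = res.counts()
    planted = set(truth["de_genes"])
    called = set(res.called.index)
    print(f"screened genes tested: {len(kept)}; s0 = {res.s0:.4g}; "
          f"{res.n_permutations} permutations")
    print(f"DEGs at q<0.05: {counts['n_deg']} "
          f"({counts['n_up']} up, {counts['n_down']} down)")
    print(f"planted DE genes recovered: {len(called & planted)}/"
          f"{len(planted & set(kept))} of those screened in")
    print(f"table -> {ROOT / 'deg.tsv'}")


if __name__ == "__main__":
    main()
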