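"""End-to-end orchestration: simulate/load -> screen -> benchmark -> DEG -> KM.

Every stage draws its randomness from a child generator spawned from the
master seed and the stage name, so a fixed seed reproduces every output file
byte-identically and any stage can be rerun alone. All resolved parameters
are written to the run log, making a run reconstructible from its log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from hfpef_risk import io as hio
from hfpef_risk.config import GAConfig, KernelConfig, PipelineConfig, stage_rng
from hfpef_risk.evaluation import dunnett_compare, repeated_evaluation, confusion_metrics, split_indices
from hfpef_risk.ga import optimize_sigma
from hfpef_risk.kpls import predict_features, train_kpls
from hfpef_risk.preprocessing import log2_standardize, marginal_t, sis_dimension, sis_screen
from hfpef_risk.sam import sam_qvalues
from hfpef_risk.simulate import generate_cohort
from hfpef_risk.survival import km_summary

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def _load_inputs(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict | None, bool]:
    if cfg.expression_path and cfg.phenotype_path:
        X = hio.read_expression_matrix(cfg.expression_path)
        pheno = hio.read_phenotypes(cfg.phenotype_path)
        X, pheno = hio.align_samples(X, pheno)
        raw = bool(cfg.raw_input) if cfg.raw_input is not None else False
        return X, pheno, None, raw
    if cfg.synth is None:
        raise ValueError("stage inputs: no input paths and synthesis disabled")
    synth = cfg.synth
    synth.seed = int(stage_rng(cfg.seed, "simulate").integers(0, 2**31))
    X, pheno, truth = generate_cohort(synth)
    raw = synth.raw_intensities if cfg.raw_input is None else bool(cfg.raw_input)
    return X, pheno, truth, raw


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and write the result bundle under ``cfg.out_dir``.

    Returns a dict of the main in-memory results (paths, summary frame, DEG
    counts, log-rank p-values).
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    try:
        X, pheno, truth, raw = _load_inputs(cfg)
        stage = "preprocessing"
        Xs = log2_standardize(X, already_log=not raw)
        y = pheno["outcome"].to_numpy()

        stage = "screening"
        n = Xs.shape[1]
        d = sis_dimension(n, cfg.screen, n_genes=Xs.shape[0])
        A = Xs.to_numpy().T  # samples x genes
        idx = sis_screen(A, y, d, cfg.screen)
        screen_df = pd.DataFrame(
            {
                "rank": np.arange(1, len(idx) + 1),
                "gene_id": Xs.index.to_numpy()[idx],
                "abs_t": np.abs(marginal_t(A, y))[idx],
            }
        )
        screen_df.to_csv(out / "screened_genes.tsv", sep="\t", index=False,
                         float_format=FLOAT_FMT)
        X_screened = A[:, idx]

        stage = "evaluation"
        table = repeated_evaluation(X_screened, y, list(cfg.models), cfg)
        summary = table.summary()
        summary.to_csv(out / "metrics_summary.csv", float_format=FLOAT_FMT)
        auc = table.auc_matrix()
        auc.to_csv(out / "auc_per_repeat.csv", float_format=FLOAT_FMT)
        comparison = None
        if "ga_kpls" in cfg.models and len(cfg.models) >= 2 and cfg.n_repeats >= 3:
            comparison = dunnett_compare(
                auc, control="ga_kpls",
                seed=int(stage_rng(cfg.seed, "dunnett").integers(0, 2**31)),
            )
            (out / "model_comparison.json").write_text(json.dumps(comparison, indent=2))

        stage = "differential_expression"
        sam = sam_qvalues(
            Xs.iloc[idx], y, n_perm=cfg.n_permutations,
            seed=int(stage_rng(cfg.seed, "sam").integers(0, 2**31)),
            threshold=cfg.q_threshold,
        )
        sam.table.to_csv(out / "deg.tsv", sep="\t", float_format=FLOAT_FMT)

        stage = "survival"
        km_rng = stage_rng(cfg.seed, "km")
        tr, te = split_indices(len(y), cfg.train_fraction, km_rng, y=y,
                               stratify=cfg.stratify)
        gcfg = GAConfig(**{**vars(cfg.ga), "seed": int(km_rng.integers(0, 2**31))})
        ga_res = optimize_sigma(X_screened[tr], y[tr], cfg.kernel, gcfg)
        kcfg = KernelConfig(sigma=ga_res.best_sigma,
                            n_components=cfg.kernel.n_components,
                            threshold=cfg.kernel.threshold)
        model = train_kpls(X_screened[tr], y[tr], kcfg)
        scores, labels = predict_features(model, X_screened[te])
        test_pheno = pheno.iloc[te].copy()
        km_actual = km_summary(test_pheno, "outcome")
        test_pheno["predicted"] = labels
        km_block = {"actual": km_actual, "test_mcc": confusion_metrics(
            y[te], labels, scores).mcc}
        if len(np.unique(labels)) == 2:
            km_block["predicted"] = km_summary(test_pheno, "predicted")
        (out / "km_logrank.json").write_text(json.dumps(km_block, indent=2))

        stage = "logging"
        log = {
            "seed": cfg.seed,
            "resolved_config": cfg.to_dict(),
            "n_samples": int(n),
            "n_genes": int(Xs.shape[0]),
            "screen_dimension": int(d),
            "deg_counts": sam.counts(),
            "sam_s0": sam.s0,
            "truth": truth,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "out_dir": str(out),
        "summary": summary,
        "auc_matrix": auc,
        "comparison": comparison,
        "deg_counts": sam.counts(),
        "km": km_block,
        "truth": truth,
    }
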