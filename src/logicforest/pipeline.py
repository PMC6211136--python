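"""Config-driven end-to-end runner.

QC -> encoding -> one Logic Forest per requested genetic model ->
prime-implicant importance aggregation -> permutation p-values for the
top-ranked implicants -> univariate logistic confirmation, with every
stochastic stage seeded deterministically from one master seed and all
artifacts written as TSV/JSON under the output directory.

No encoding is selected automatically: each requested model is fitted and
reported, ranked by OOB misclassification, and the choice among them is
left to the analyst.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .data_model import assemble_dataset, read_genotypes, read_phenotypes
from .confirmation import confirm_prime_implicants, confirmation_frame
from .logic_forest import (
    aggregate,
    fit_forest,
    oob_misclassification,
    oob_vote_shares,
    records_to_frame,
    roc_auc,
)
from .logic_tree import AnnealingSchedule
from .permutation import permutation_pvalues
from .qc import apply_qc

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genotypes: str = ""
    genotype_format: str = "tsv"
    phenotypes: str = ""
    out_dir: str = "lf_run"
    hwe_p_min: float = 0.001
    maf_min: float = 0.05
    max_missing: float = 0.0
    encodings: tuple[str, ...] = ("recessive", "dominant", "genotypic")
    exposures: list[str] | None = None
    B: int = 200
    max_leaves: int = 8
    n_iter: int = 25_000
    n_perm: int = 500
    perm_n_iter: int = 600
    top_k: int = 10
    importance: str = "vi1"
    seed: int = 0
    skip_qc: bool = False

    def __post_init__(self):
        if not self.encodings:
            raise ValueError("at least one encoding must be selected")
        for e in self.encodings:
            if e not in ("recessive", "dominant", "genotypic"):
                raise ValueError(f"unknown encoding {e!r}")
        if not (0 <= self.maf_min <= 0.5) or not (0 <= self.hwe_p_min <= 1):
            raise ValueError("QC thresholds out of range")


def _stage_seed(master: int, label: str) -> int:
    """Deterministic child seed (< 2^31) for a named stage."""
    import hashlib

    h = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a manifest of artifact paths and metrics."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"config": asdict(config), "version": __version__, "stages": {}}

    stage = "read"
    try:
        gm = read_genotypes(config.genotypes, config.genotype_format)
        ph = read_phenotypes(config.phenotypes)

        if not config.skip_qc:
            stage = "qc"
            controls = [s for s, st in zip(ph.subject_ids, ph.status) if st == 0]
            gm, qc_report = apply_qc(
                gm, controls,
                hwe_p_min=config.hwe_p_min, maf_min=config.maf_min,
                max_missing=config.max_missing,
            )
            qc_path = out / "qc_report.tsv"
            qc_report.to_tsv(qc_path)
            manifest["stages"]["qc"] = {
                "retained_snps": len(qc_report.retained_snps),
                "report": str(qc_path),
            }

        encoding_summaries = {}
        for enc in config.encodings:
            stage = f"fit[{enc}]"
            enc_dir = out / enc
            enc_dir.mkdir(exist_ok=True)
            W = assemble_dataset(gm, ph, scheme=enc, predictors=config.exposures)
            rng = np.random.default_rng(_stage_seed(config.seed, f"fit:{enc}"))
            schedule = AnnealingSchedule(n_iter=config.n_iter)
            model = fit_forest(W, B=config.B, max_leaves=config.max_leaves,
                               schedule=schedule, rng=rng)
            model.save(enc_dir / "model.json")

            mc = oob_misclassification(model, W)
            shares = oob_vote_shares(model, W)
            fpr, tpr, auc_val = roc_auc(shares, W.y)
            np.savetxt(enc_dir / "roc_curve.tsv",
                       np.column_stack([fpr, tpr]), delimiter="\t",
                       header="fpr\ttpr", comments="")

            stage = f"aggregate[{enc}]"
            agg_rng = np.random.default_rng(_stage_seed(config.seed, f"agg:{enc}"))
            pi_records, pred_records = aggregate(model, W, rng=agg_rng)

            stage = f"permtest[{enc}]"
            top = pi_records[: config.top_k]
            if config.n_perm > 0 and top:
                perm_rng = np.random.default_rng(_stage_seed(config.seed, f"perm:{enc}"))
                res = permutation_pvalues(
                    W, model, [r.prime_implicant for r in top],
                    n_perm=config.n_perm, B=config.B,
                    importance=config.importance, rng=perm_rng,
                    schedule=AnnealingSchedule.fast(config.perm_n_iter),
                    max_leaves=config.max_leaves,
                )
                for r in top:
                    r.perm_p = res.p_value(r.prime_implicant)
                    r.perm_p_display = res.p_display(r.prime_implicant)

            pi_frame = records_to_frame(pi_records, W.descriptors)
            pred_frame = records_to_frame(pred_records, W.descriptors)
            pi_frame.to_csv(enc_dir / "prime_implicants.tsv", sep="\t", index=False)
            pred_frame.to_csv(enc_dir / "predictors.tsv", sep="\t", index=False)
            # frequency-vs-normalised-importance scatter data
            pi_frame[["tree_count", "normalized_vi1", "prime_implicant"]].to_csv(
                enc_dir / "pi_scatter.tsv", sep="\t", index=False)
            pred_frame[["tree_count", "normalized_vi1", "prime_implicant"]].to_csv(
                enc_dir / "predictor_scatter.tsv", sep="\t", index=False)

            stage = f"confirm[{enc}]"
            conf = confirm_prime_implicants(W, [r.prime_implicant for r in top])
            confirmation_frame(conf).to_csv(enc_dir / "confirmation.tsv", sep="\t",
                                            index=False, float_format="%.6g")
            # a raw-permutation-p note: no multiplicity adjustment is applied
            (enc_dir / "NOTES.txt").write_text(
                "Permutation p-values are raw (unadjusted for multiple testing).\n"
            )

            encoding_summaries[enc] = {
                "n": W.n, "p": W.p, "B": model.B,
                "oob_misclassification": mc, "auc": auc_val,
                "n_unique_prime_implicants": len(pi_records),
                "dir": str(enc_dir),
            }

        manifest["stages"]["models"] = encoding_summaries
        manifest["ranking_by_oob_error"] = sorted(
            encoding_summaries, key=lambda e: encoding_summaries[e]["oob_misclassification"]
        )
        manifest["elapsed_s"] = round(time.time() - t0, 2)
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise
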