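"""Marker-level quality control.

Filters mirror standard case-control practice: Hardy-Weinberg equilibrium
tested in controls only (genotyping artefacts inflate heterozygote deficit
in the combined sample when the marker is truly associated), minor-allele
frequency and missingness computed over all subjects, and optional
restriction to gene regions with a flank.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GenotypeMatrix

logger = logging.getLogger(__name__)


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(n major-hom, n het, n minor-hom) from a 0/1/2 dosage vector (NaN ignored)."""
    d = np.asarray(dosages, dtype=float)
    return (
        int(np.nansum(d == 0.0)),
        int(np.nansum(d == 1.0)),
        int(np.nansum(d == 2.0)),
    )


def hwe_test(counts: tuple[int, int, int], method: str = "chisq") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    ``counts`` is (n_AA, n_Aa, n_aa).  The default is the 1-df chi-square
    goodness-of-fit test against expected counts under the allele frequency
    estimated from the sample, without continuity correction.  ``exact``
    uses the conditional exact test (enumeration over heterozygote counts
    given the allele counts).  A monomorphic marker returns p = 1.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        logger.debug("monomorphic marker (allele counts %d/%d): HWE p set to 1", n_a, n_b)
        return 1.0
    if method == "chisq":
        p = n_a / (2 * n)
        exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        obs = np.array([n_aa, n_ab, n_bb], dtype=float)
        stat = float(((obs - exp) ** 2 / exp).sum())
        return float(stats.chi2.sf(stat, df=1))
    if method == "exact":
        return _hwe_exact(n_aa, n_ab, n_bb)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional HWE test (sum of probabilities <= observed).

    Enumerates all heterozygote counts compatible with the observed allele
    counts; the probability of each configuration follows the conditional
    distribution of heterozygotes given allele counts under random mating.
    """
    n = n_aa + n_ab + n_bb
    n_rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    hets = range(n_rare % 2, n_rare + 1, 2)
    logprobs = {}
    for h in hets:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        lp = (
            math.lgamma(n + 1)
            - math.lgamma(rare_hom + 1)
            - math.lgamma(common_hom + 1)
            - math.lgamma(h + 1)
            + h * math.log(2)
            + math.lgamma(n_rare + 1)
            + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )
        logprobs[h] = lp
    m = max(logprobs.values())
    total = sum(math.exp(lp - m) for lp in logprobs.values())
    probs = {h: math.exp(lp - m) / total for h, lp in logprobs.items()}
    p_obs = probs[n_ab]
    return float(min(1.0, sum(p for p in probs.values() if p <= p_obs + 1e-12)))


def maf(counts: tuple[int, int, int]) -> float:
    """Minor-allele frequency from genotype counts: min(f, 1-f) of the counted allele."""
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("total genotype count must be positive")
    f = (2 * n_bb + n_ab) / (2 * n)
    return float(min(f, 1.0 - f))


@dataclass
class QCReport:
    """Per-SNP QC metrics and filter outcomes."""

    table: pd.DataFrame  # snp_id, maf, hwe_p, missing_fraction, fail_reasons, retained
    thresholds: dict = field(default_factory=dict)

    @property
    def retained_snps(self) -> list[str]:
        return self.table.loc[self.table["retained"], "snp_id"].tolist()

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def apply_qc(
    gm: GenotypeMatrix,
    controls: list[str],
    hwe_p_min: float = 0.001,
    maf_min: float = 0.05,
    max_missing: float = 0.0,
    hwe_method: str = "chisq",
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers by HWE (in controls), MAF, and missingness (in all subjects).

    A marker is retained iff it passes every enabled filter.  Raises if no
    marker survives, with the report attached to the exception.
    """
    control_set = set(controls)
    ctrl_rows = [i for i, s in enumerate(gm.subject_ids) if s in control_set]
    if hwe_p_min is not None and not ctrl_rows:
        raise ValueError("HWE filter enabled but the control subset is empty")

    recs = []
    for j, snp in enumerate(gm.snp_ids):
        col = gm.dosage[:, j]
        miss_frac = float(np.isnan(col).mean())
        all_counts = genotype_counts(col)
        snp_maf = maf(all_counts) if sum(all_counts) else 0.0
        hwe_p = hwe_test(genotype_counts(col[ctrl_rows]), method=hwe_method) if ctrl_rows else np.nan
        reasons = []
        if hwe_p_min is not None and hwe_p < hwe_p_min:
            reasons.append("hwe")
        if maf_min is not None and snp_maf < maf_min:
            reasons.append("maf")
        if max_missing is not None and miss_frac > max_missing:
            reasons.append("missing")
        recs.append(
            dict(snp_id=snp, maf=snp_maf, hwe_p=hwe_p, missing_fraction=miss_frac,
                 fail_reasons=",".join(reasons), retained=not reasons)
        )
    report = QCReport(
        pd.DataFrame.from_records(recs),
        thresholds=dict(hwe_p_min=hwe_p_min, maf_min=maf_min, max_missing=max_missing,
                        hwe_method=hwe_method),
    )
    keep = report.retained_snps
    if not keep:
        err = ValueError("no SNPs survive QC")
        err.report = report  # type: ignore[attr-defined]
        raise err
    logger.info("QC retained %d of %d SNPs", len(keep), gm.n_snps)
    return gm.subset_snps(keep), report


def read_gene_intervals(path: str, format: str = "bed") -> list[tuple[str, int, int]]:
    """Read gene intervals; BED (0-based half-open) is converted to 1-based closed."""
    out = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split()
            chrom, a, b = parts[0], int(parts[1]), int(parts[2])
            if format == "bed":
                out.append((chrom, a + 1, b))
            elif format == "tsv1":
                out.append((chrom, a, b))
            else:
                raise ValueError(f"unknown interval format {format!r}")
    logger.info("read %d gene intervals from %s (%s convention)", len(out), path, format)
    return out


def select_region(
    gm: GenotypeMatrix,
    gene_intervals: list[tuple[str, int, int]],
    flank: int = 5000,
) -> GenotypeMatrix:
    """Retain SNPs within ``flank`` bp of any gene interval (1-based, closed, inclusive)."""
    if not gm.positions:
        raise ValueError("genotype matrix carries no positions; cannot select regions")
    keep = []
    for snp in gm.snp_ids:
        if snp not in gm.positions:
            raise ValueError(f"no position recorded for SNP {snp}")
        chrom, pos = gm.positions[snp]
        for c, start, end in gene_intervals:
            if str(c) == str(chrom) and start - flank <= pos <= end + flank:
                keep.append(snp)
                break
    return gm.subset_snps(keep)
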