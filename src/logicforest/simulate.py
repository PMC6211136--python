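"""Synthetic case-control studies with planted Boolean G x E structure.

The generator emulates the shape of a candidate-gene case-control study:
a couple of hundred subjects, ~150 SNPs drawn from Hardy-Weinberg genotype
probabilities at realistic minor-allele frequencies, binary smoke-exposure
and sex variables at stated prevalences, and an outcome drawn from a
logistic model whose linear predictor contains indicator terms for planted
Boolean conjunctions over the *encoded* predictors.  Every pipeline stage
is therefore testable without any external download, and recovery of the
planted prime implicants can be scored against the returned manifest.

Defaults mirror the target study's dimensions: n = 204 subjects, 148 SNPs,
four smoke-exposure variables plus sex (p = 153 predictors under the
recessive encoding), exposure prevalences near the observed cohort values
(childhood passive smoke 0.34), case prevalence near 0.49, and a single
planted G x E term — childhood passive smoke AND at least one copy of the
major allele of the first SNP — at odds ratio 2.3, matching the magnitude
of the interaction odds ratios the method is designed to detect.  The
planted SNP's MAF defaults to 0.45 so that the recessive genotype
(frequency MAF^2 ~= 0.2) is common enough for the conjunction to be
distinguishable from the bare exposure main effect at moderate n.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import (
    Dataset,
    GenotypeMatrix,
    PhenotypeTable,
    assemble_dataset,
)
from .logic_tree import Literal, PrimeImplicant

DEFAULT_EXPOSURE_PREVALENCES = {
    # pooled cohort rates: psc 69/204, psa 38/204, ever 48/204, current 30/204,
    # female 175/204
    "psc": 0.34,
    "psa": 0.186,
    "ever_smoker": 0.235,
    "current_smoker": 0.147,
    "female": 0.858,
}


@dataclass
class TruthTerm:
    """A planted conjunction over encoded predictor names with a log-odds effect."""

    literals: tuple[tuple[str, bool], ...]  # (column name, complemented)
    log_odds: float

    def __post_init__(self):
        if not math.isfinite(self.log_odds):
            raise ValueError("planted effect must be finite")

    def indicator(self, X: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(X), dtype=bool)
        for name, comp in self.literals:
            if name not in X.columns:
                raise KeyError(f"truth term references unknown column {name!r}")
            col = X[name].to_numpy(dtype=bool)
            out &= ~col if comp else col
        return out

    def prime_implicant(self, names: list[str]) -> PrimeImplicant:
        return PrimeImplicant(
            tuple(Literal(names.index(n), comp) for n, comp in self.literals)
        )


def default_truth(effect_or: float = 2.3) -> list[TruthTerm]:
    """The standard planted G x E term: psc AND >=1 major-allele copy of snp001."""
    return [TruthTerm((("psc", False), ("snp001_R", True)), math.log(effect_or))]


@dataclass
class SimulationConfig:
    n_subjects: int = 204
    n_snps: int = 148
    snp_mafs: list[float] | None = None        # explicit per-SNP MAFs, or None
    maf_range: tuple[float, float] = (0.1, 0.5)
    planted_snp_maf: float = 0.45              # MAF of the first SNP when truth is planted
    ld_block_spec: list[tuple[int, float]] = field(default_factory=list)
    exposure_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPOSURE_PREVALENCES)
    )
    truth: list[TruthTerm] | None = None       # None -> default_truth()
    baseline_log_odds: float = -0.26           # tuned so case prevalence ~= 0.49
    encoding: str = "recessive"
    seed: int = 0

    def __post_init__(self):
        if self.snp_mafs is not None:
            if any(not (0 < m <= 0.5) for m in self.snp_mafs):
                raise ValueError("MAFs must lie in (0, 0.5]")
        if any(not (0 < v < 1) for v in self.exposure_prevalences.values()):
            raise ValueError("exposure prevalences must lie in (0, 1)")
        if self.truth is None:
            self.truth = default_truth()
        for term in self.truth:
            if not math.isfinite(term.log_odds):
                raise ValueError("planted effects must be finite")

    # flat key=value (JSON-encoded values) round-trip -----------------------

    def to_file(self, path: str) -> None:
        d = asdict(self)
        d["truth"] = [
            {"literals": [list(l) for l in t.literals], "log_odds": t.log_odds}
            for t in self.truth
        ]
        with open(path, "w") as fh:
            for k, v in d.items():
                fh.write(f"{k} = {json.dumps(v)}\n")

    @classmethod
    def from_file(cls, path: str) -> "SimulationConfig":
        d = {}
        with open(path) as fh:
            for ln in fh:
                if not ln.strip() or ln.lstrip().startswith("#"):
                    continue
                k, _, v = ln.partition("=")
                d[k.strip()] = json.loads(v.strip())
        if d.get("truth") is not None:
            d["truth"] = [
                TruthTerm(tuple((n, bool(c)) for n, c in t["literals"]), t["log_odds"])
                for t in d["truth"]
            ]
        if d.get("ld_block_spec"):
            d["ld_block_spec"] = [tuple(b) for b in d["ld_block_spec"]]
        if d.get("maf_range"):
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


def _resolve_mafs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.snp_mafs is not None:
        if len(config.snp_mafs) != config.n_snps:
            raise ValueError("snp_mafs length must equal n_snps")
        return np.asarray(config.snp_mafs, dtype=float)
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_snps)
    if config.truth:
        mafs[0] = config.planted_snp_maf
    return mafs


def generate_genotypes(config: SimulationConfig, rng: np.random.Generator) -> GenotypeMatrix:
    """HWE genotypes at each SNP's MAF; optional LD blocks via latent Gaussians.

    Independent SNPs are drawn from genotype probabilities
    ((1-q)^2, 2q(1-q), q^2) at MAF q.  When ``ld_block_spec`` is given,
    leading SNPs are grouped into blocks whose two latent haplotype
    Gaussian vectors share an equicorrelation, and alleles are obtained by
    thresholding at the MAF quantile — each SNP stays in HWE marginally
    while genotypes within a block are positively correlated.
    """
    n, m = config.n_subjects, config.n_snps
    mafs = _resolve_mafs(config, rng)
    dosage = np.empty((n, m), dtype=float)

    blocks: list[tuple[int, int, float]] = []  # (start, size, rho)
    start = 0
    for size, rho in config.ld_block_spec:
        if start + size > m:
            raise ValueError("ld_block_spec exceeds the number of SNPs")
        blocks.append((start, size, float(rho)))
        start += size
    in_block = np.zeros(m, dtype=bool)
    for s, size, _ in blocks:
        in_block[s:s + size] = True

    free = np.flatnonzero(~in_block)
    if free.size:
        u = rng.random((n, free.size, 2))
        alleles = u < mafs[free][None, :, None]
        dosage[:, free] = alleles.sum(axis=2)

    for s, size, rho in blocks:
        cov = np.full((size, size), rho) + (1 - rho) * np.eye(size)
        chol = np.linalg.cholesky(cov)
        thr = norm.ppf(mafs[s:s + size])
        for hap in range(2):
            z = rng.standard_normal((n, size)) @ chol.T
            if hap == 0:
                dos = (z < thr).astype(float)
            else:
                dos += (z < thr)
        dosage[:, s:s + size] = dos

    snp_ids = [f"snp{j + 1:03d}" for j in range(m)]
    positions = {sid: ("1", 10_000 + 5_000 * j) for j, sid in enumerate(snp_ids)}
    return GenotypeMatrix([f"S{i + 1:04d}" for i in range(n)], snp_ids, dosage,
                          positions=positions)


def generate_exposures(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    cols = {
        name: (rng.random(config.n_subjects) < prev).astype(float)
        for name, prev in config.exposure_prevalences.items()
    }
    return pd.DataFrame(cols)


def generate_outcome(
    X_encoded: pd.DataFrame,
    truth: list[TruthTerm],
    baseline_log_odds: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli outcome from logistic(baseline + sum effect * I[term true])."""
    eta = np.full(len(X_encoded), float(baseline_log_odds))
    for term in truth:
        eta += term.log_odds * term.indicator(X_encoded)
    prob = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(X_encoded)) < prob).astype(np.uint8)


def make_study(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PhenotypeTable, dict]:
    """Full study bundle: genotypes, phenotypes, and a ground-truth manifest.

    The manifest records the planted prime implicants (as literal lists
    over encoded predictor names), the effects, the baseline, and the seed,
    so downstream recovery can be scored without re-deriving anything.
    """
    rng = np.random.default_rng(config.seed)
    gm = generate_genotypes(config, rng)
    expo = generate_exposures(config, rng)

    # encode to evaluate planted terms on the same columns the analysis sees
    ph_tmp = PhenotypeTable(list(gm.subject_ids), np.zeros(config.n_subjects), expo.copy())
    W_tmp = assemble_dataset(gm, ph_tmp, scheme=config.encoding)
    Xdf = pd.DataFrame(W_tmp.X, columns=W_tmp.predictor_names)
    y = generate_outcome(Xdf, config.truth, config.baseline_log_odds, rng)

    ph = PhenotypeTable(list(gm.subject_ids), y.astype(float), expo)
    manifest = {
        "seed": config.seed,
        "encoding": config.encoding,
        "baseline_log_odds": config.baseline_log_odds,
        "n_subjects": config.n_subjects,
        "n_snps": config.n_snps,
        "planted_terms": [
            {"literals": [list(l) for l in t.literals], "log_odds": t.log_odds,
             "odds_ratio": math.exp(t.log_odds)}
            for t in config.truth
        ],
    }
    return gm, ph, manifest


def planted_prime_implicants(manifest: dict, W: Dataset) -> list[PrimeImplicant]:
    """Resolve the manifest's planted terms into PIs over a dataset's columns."""
    names = W.predictor_names
    out = []
    for t in manifest["planted_terms"]:
        out.append(
            PrimeImplicant(
                tuple(Literal(names.index(n), bool(c)) for n, c in t["literals"])
            )
        )
    return out
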