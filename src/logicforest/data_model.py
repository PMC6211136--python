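"""Genotype/phenotype containers, file readers, and SNP binary encodings.

The analysis operates on a dataset ``W = {X, y}`` where ``X`` is an n x p
matrix of binary predictors and ``y`` a binary case/control outcome.  SNP
minor-allele dosages (0/1/2) are turned into binary predictors under one of
three genetic models:

* **recessive** — 1 iff the subject carries two copies of the minor allele;
* **dominant** — 1 iff the subject carries at least one copy;
* **genotypic** — two indicators (exactly one copy; exactly two copies),
  with zero copies as the reference category.

The complement of a recessive predictor is the indicator of carrying at
least one copy of the major allele, and renderings follow that convention so
interaction terms read the way an epidemiologist would phrase them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing dosage inside float arrays
MISSING = np.nan

VALID_SCHEMES = ("recessive", "dominant", "genotypic")


class ParseError(ValueError):
    """Raised when an input file does not conform to its dialect."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix.

    ``dosage`` is a float array with entries in {0, 1, 2} or NaN for
    missing.  ``allele_labels`` maps snp_id -> (minor, major) when known;
    ``positions`` maps snp_id -> (chromosome, 1-based position).
    """

    subject_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray
    allele_labels: dict[str, tuple[str, str]] = field(default_factory=dict)
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject_ids in genotype matrix")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp_ids in genotype matrix")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"dosage value {self.dosage[tuple(bad)]!r} for subject "
                f"{self.subject_ids[bad[0]]!r}, SNP {self.snp_ids[bad[1]]!r} "
                "is not 0/1/2/missing"
            )
        for snp, (chrom, pos) in self.positions.items():
            if int(pos) < 1:
                raise ValueError(f"position {pos} for {snp} is not a positive 1-based coordinate")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset_snps(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in keep]
        return GenotypeMatrix(
            subject_ids=list(self.subject_ids),
            snp_ids=list(keep),
            dosage=self.dosage[:, idx].copy(),
            allele_labels={s: self.allele_labels[s] for s in keep if s in self.allele_labels},
            positions={s: self.positions[s] for s in keep if s in self.positions},
        )

    def subset_subjects(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.subject_ids.index(s) for s in keep]
        return GenotypeMatrix(
            subject_ids=list(keep),
            snp_ids=list(self.snp_ids),
            dosage=self.dosage[idx, :].copy(),
            allele_labels=dict(self.allele_labels),
            positions=dict(self.positions),
        )


@dataclass
class PhenotypeTable:
    """Case/control status plus named binary exposure columns."""

    subject_ids: list[str]
    status: np.ndarray  # 0/1, never missing
    exposures: pd.DataFrame  # 0/1/NaN, indexed like subject_ids

    def __post_init__(self) -> None:
        if len(set(self.subject_ids)) != len(self.subject_ids):
            dup = pd.Series(self.subject_ids)
            name = dup[dup.duplicated()].iloc[0]
            raise ValueError(f"duplicate subject_id {name!r} in phenotype table")
        self.status = np.asarray(self.status, dtype=float)
        if np.isnan(self.status).any() or not np.isin(self.status, (0.0, 1.0)).all():
            raise ValueError("status must be 0/1 and never missing for retained subjects")
        self.status = self.status.astype(np.uint8)


@dataclass(frozen=True)
class PredictorDescriptor:
    """Metadata for one binary column of X.

    ``literal_rendering`` is (text when true, text when complemented).
    """

    name: str
    origin: str  # snp | exposure | demographic
    source_snp: str | None
    encoding: str  # recessive | dominant | genotypic_1 | genotypic_2 | raw_binary
    literal_rendering: tuple[str, str]

    def render(self, complemented: bool = False) -> str:
        return self.literal_rendering[1 if complemented else 0]


@dataclass
class Dataset:
    """The analysis dataset W = {X, y}: complete-case binary predictors."""

    X: np.ndarray  # n x p uint8
    y: np.ndarray  # n uint8
    descriptors: list[PredictorDescriptor]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(np.asarray(self.X), dtype=np.uint8)
        self.y = np.asarray(self.y, dtype=np.uint8)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X rows must align with y")
        if self.X.shape[1] != len(self.descriptors):
            raise ValueError("one descriptor per predictor column required")
        if not np.isin(self.X, (0, 1)).all() or not np.isin(self.y, (0, 1)).all():
            raise ValueError("Dataset must be fully binary with no missing values")
        if not self.subject_ids:
            self.subject_ids = [str(i) for i in range(self.X.shape[0])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def predictor_names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def column(self, name: str) -> int:
        try:
            return self.predictor_names.index(name)
        except ValueError:
            raise KeyError(f"no predictor named {name!r}") from None


# ---------------------------------------------------------------------------
# readers / writers


def _parse_dosage_token(tok: str, line_no: int, path: str) -> float:
    if tok in ("NA", "", "."):
        return MISSING
    try:
        v = float(tok)
    except ValueError:
        raise ParseError(f"{path}:{line_no}: dosage value {tok!r} is not numeric or NA") from None
    if v not in (0.0, 1.0, 2.0):
        raise ParseError(f"{path}:{line_no}: dosage value {tok!r} outside {{0,1,2}}")
    return v


def _read_genotypes_tsv(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}:1: empty file")
    header = lines[0].split("\t")
    if header[0] != "subject_id":
        raise ParseError(f"{path}:1: first column must be 'subject_id', got {header[0]!r}")
    snp_ids = header[1:]
    subject_ids, rows = [], []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ParseError(f"{path}:{i}: expected {len(header)} fields, got {len(parts)}")
        subject_ids.append(parts[0])
        rows.append([_parse_dosage_token(t, i, path) for t in parts[1:]])
    return GenotypeMatrix(subject_ids, snp_ids, np.array(rows, dtype=float))


def _read_genotypes_plink_raw(path: str) -> GenotypeMatrix:
    meta_cols = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}:1: empty file")
    header = lines[0].split()
    if tuple(header[:6]) != meta_cols:
        raise ParseError(f"{path}:1: header must start with {' '.join(meta_cols)}")
    snp_ids = header[6:]
    subject_ids, rows = [], []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        if len(parts) != len(header):
            raise ParseError(f"{path}:{i}: expected {len(header)} fields, got {len(parts)}")
        subject_ids.append(parts[1])
        rows.append([_parse_dosage_token(t, i, path) for t in parts[6:]])
    labels = {}
    clean_ids = []
    for s in snp_ids:
        # PLINK .raw names columns SNP_<counted allele>; the counted allele is
        # the minor allele under default --recode A behaviour
        if "_" in s and len(s.rsplit("_", 1)[1]) >= 1:
            base, allele = s.rsplit("_", 1)
            clean_ids.append(base)
            labels[base] = (allele, "?")
        else:
            clean_ids.append(s)
    return GenotypeMatrix(subject_ids, clean_ids, np.array(rows, dtype=float), allele_labels=labels)


def _read_genotypes_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    subject_ids = list(vcf.samples)
    snp_ids: list[str] = []
    cols: list[np.ndarray] = []
    labels: dict[str, tuple[str, str]] = {}
    positions: dict[str, tuple[str, int]] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            raise ParseError(
                f"{path}: multi-allelic site {var.CHROM}:{var.POS} "
                f"(REF={var.REF}, ALT={','.join(var.ALT)}) is not supported"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        alt_dose = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, MISSING)))
        called = ~np.isnan(alt_dose)
        alt_freq = alt_dose[called].sum() / (2.0 * called.sum()) if called.any() else 0.0
        if alt_freq > 0.5:
            dose = 2.0 - alt_dose  # minor allele is REF
            minor, major = var.REF, var.ALT[0]
        else:
            dose = alt_dose  # ties orient toward ALT
            minor, major = var.ALT[0], var.REF
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snp_ids.append(name)
        cols.append(dose)
        labels[name] = (minor, major)
        positions[name] = (str(var.CHROM), int(var.POS))
    if not snp_ids:
        raise ParseError(f"{path}: no variant records found")
    return GenotypeMatrix(
        subject_ids, snp_ids, np.column_stack(cols), allele_labels=labels, positions=positions
    )


def read_genotypes(path: str, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``tsv``, ``plink_raw`` or ``vcf``.

    Dosages always count copies of the minor allele.  For VCF input the
    minor allele is determined from the sample allele frequencies in the
    file, ties broken toward the ALT allele.
    """
    readers = {"tsv": _read_genotypes_tsv, "plink_raw": _read_genotypes_plink_raw,
               "vcf": _read_genotypes_vcf}
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}; expected one of {sorted(readers)}")
    return readers[format](str(path))


def write_genotypes_tsv(gm: GenotypeMatrix, path: str) -> None:
    """Write the tab-separated dialect (missing rendered as NA); round-trips."""
    with open(path, "w") as fh:
        fh.write("subject_id\t" + "\t".join(gm.snp_ids) + "\n")
        for i, sid in enumerate(gm.subject_ids):
            vals = ["NA" if np.isnan(v) else str(int(v)) for v in gm.dosage[i]]
            fh.write(sid + "\t" + "\t".join(vals) + "\n")


def read_phenotypes(path: str) -> PhenotypeTable:
    """Read the phenotype TSV: subject_id, status, then 0/1/NA exposure columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "subject_id" not in df.columns:
        raise ParseError(f"{path}: missing 'subject_id' column")
    if "status" not in df.columns:
        raise ParseError(f"{path}: missing 'status' column")
    subject_ids = df["subject_id"].astype(str).tolist()
    raw_status = df["status"].astype(str)
    is_na = raw_status.isin(("NA", "nan", ""))
    status = pd.to_numeric(df["status"].where(~is_na), errors="coerce")
    invalid = ~is_na & (status.isna() | ~status.isin((0, 1)))
    if invalid.any():
        i = int(np.argmax(invalid.to_numpy()))
        raise ParseError(
            f"{path}: status value {df['status'].iloc[i]!r} for subject "
            f"{subject_ids[i]!r} is not in {{0,1,NA}}"
        )
    if is_na.any():
        logger.info("%s: dropped %d subjects with missing status", path, int(is_na.sum()))
        keep = (~is_na).to_numpy()
        df = df[keep].reset_index(drop=True)
        subject_ids = [s for s, k in zip(subject_ids, keep) if k]
        status = status[keep].reset_index(drop=True)
    expo_cols = [c for c in df.columns if c not in ("subject_id", "status")]
    exposures = pd.DataFrame(index=range(len(df)))
    for c in expo_cols:
        vals = pd.to_numeric(df[c].replace("NA", np.nan), errors="coerce")
        nonbinary = vals.notna() & ~vals.isin((0, 1))
        if nonbinary.any():
            logger.warning(
                "%s: %d non-0/1 entries in exposure %r set to missing",
                path, int(nonbinary.sum()), c,
            )
            vals[nonbinary] = np.nan
        exposures[c] = vals
    return PhenotypeTable(subject_ids, status.to_numpy(), exposures)


def write_phenotypes_tsv(ph: PhenotypeTable, path: str) -> None:
    with open(path, "w") as fh:
        cols = list(ph.exposures.columns)
        fh.write("subject_id\tstatus" + ("\t" + "\t".join(cols) if cols else "") + "\n")
        for i, sid in enumerate(ph.subject_ids):
            vals = [
                "NA" if np.isnan(ph.exposures[c].iloc[i]) else str(int(ph.exposures[c].iloc[i]))
                for c in cols
            ]
            fh.write(f"{sid}\t{int(ph.status[i])}" + ("\t" + "\t".join(vals) if vals else "") + "\n")


# ---------------------------------------------------------------------------
# encodings


def _snp_renderings(snp: str, encoding: str) -> tuple[str, str]:
    if encoding == "recessive":
        return (
            f"2 copies of the minor allele of {snp}",
            f">=1 copy of the major allele of {snp}",
        )
    if encoding == "dominant":
        return (
            f">=1 copy of the minor allele of {snp}",
            f"0 copies of the minor allele of {snp}",
        )
    if encoding == "genotypic_1":
        return (
            f"1 copy of the minor allele of {snp}",
            f"0 or 2 copies of the minor allele of {snp}",
        )
    if encoding == "genotypic_2":
        return (
            f"2 copies of the minor allele of {snp}",
            f"0 or 1 copies of the minor allele of {snp}",
        )
    raise ValueError(f"unknown encoding {encoding!r}")


def encode_snp(
    dosages: np.ndarray, scheme: str, snp_id: str = "snp"
) -> list[tuple[np.ndarray, PredictorDescriptor]]:
    """Encode one SNP's dosage vector under a genetic model.

    Returns one (column, descriptor) pair for recessive/dominant, two for
    the genotypic model.  Missing dosages propagate as NaN so the subject
    can be dropped at assembly.
    """
    if scheme not in VALID_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {VALID_SCHEMES}")
    d = np.asarray(dosages, dtype=float)
    ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
    if not ok.all():
        raise ValueError(f"dosages for {snp_id} contain values outside {{0,1,2,NA}}")
    miss = np.isnan(d)

    def col(indicator: np.ndarray) -> np.ndarray:
        out = indicator.astype(float)
        out[miss] = MISSING
        return out

    if scheme == "recessive":
        desc = PredictorDescriptor(
            f"{snp_id}_R", "snp", snp_id, "recessive", _snp_renderings(snp_id, "recessive")
        )
        return [(col(d == 2.0), desc)]
    if scheme == "dominant":
        desc = PredictorDescriptor(
            f"{snp_id}_D", "snp", snp_id, "dominant", _snp_renderings(snp_id, "dominant")
        )
        return [(col(d >= 1.0), desc)]
    d1 = PredictorDescriptor(
        f"{snp_id}_G1", "snp", snp_id, "genotypic_1", _snp_renderings(snp_id, "genotypic_1")
    )
    d2 = PredictorDescriptor(
        f"{snp_id}_G2", "snp", snp_id, "genotypic_2", _snp_renderings(snp_id, "genotypic_2")
    )
    return [(col(d == 1.0), d1), (col(d == 2.0), d2)]


DEMOGRAPHIC_NAMES = frozenset({"female", "male", "sex", "gender"})


def assemble_dataset(
    gm: GenotypeMatrix,
    ph: PhenotypeTable,
    scheme: str = "recessive",
    predictors: list[str] | None = None,
) -> Dataset:
    """Join genotypes and phenotypes into the complete-case dataset W.

    Subjects missing any genotype or any selected exposure are dropped
    (listwise deletion); the count of dropped subjects is logged.
    """
    if predictors is None:
        predictors = list(ph.exposures.columns)
    for c in predictors:
        if c not in ph.exposures.columns:
            raise KeyError(f"exposure column {c!r} not present in phenotype table")
    common = [s for s in gm.subject_ids if s in set(ph.subject_ids)]
    if not common:
        raise ValueError("no overlapping subject ids between genotypes and phenotypes")

    g_idx = {s: i for i, s in enumerate(gm.subject_ids)}
    p_idx = {s: i for i, s in enumerate(ph.subject_ids)}
    expo = ph.exposures[predictors].to_numpy(dtype=float) if predictors else np.empty((len(ph.subject_ids), 0))

    kept, rows_g, rows_e, ys = [], [], [], []
    for s in common:
        gv = gm.dosage[g_idx[s]]
        ev = expo[p_idx[s]]
        if np.isnan(gv).any() or np.isnan(ev).any():
            continue
        kept.append(s)
        rows_g.append(gv)
        rows_e.append(ev)
        ys.append(ph.status[p_idx[s]])
    dropped = len(common) - len(kept)
    if dropped:
        logger.info("assemble_dataset: dropped %d of %d overlapping subjects with missing data",
                    dropped, len(common))
    if not kept:
        raise ValueError("no subjects remain after listwise deletion of missing data")

    G = np.array(rows_g, dtype=float)
    E = np.array(rows_e, dtype=float)
    cols: list[np.ndarray] = []
    descs: list[PredictorDescriptor] = []
    for j, snp in enumerate(gm.snp_ids):
        for colv, desc in encode_snp(G[:, j], scheme, snp):
            cols.append(colv)
            descs.append(desc)
    for k, name in enumerate(predictors):
        origin = "demographic" if name.lower() in DEMOGRAPHIC_NAMES else "exposure"
        descs.append(
            PredictorDescriptor(name, origin, None, "raw_binary", (name, f"not {name}"))
        )
        cols.append(E[:, k])

    X = np.column_stack(cols) if cols else np.empty((len(kept), 0))
    for j, desc in enumerate(descs):
        colj = X[:, j]
        if colj.min() == colj.max():
            logger.warning("predictor %r is constant (all %d); retained", desc.name, int(colj[0]))
    return Dataset(X.astype(np.uint8), np.array(ys, dtype=np.uint8), descs, kept)
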