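"""Genotype/phenotype I/O, marker quality control, and the genomic relationship matrix.

Genotypes are biallelic SNP dosages coded 0/1/2 (ALT-allele counts) with
missing entries allowed.  The kinship kernel is the VanRaden linear kernel
``G = W W' / (2 * sum_k p_k (1 - p_k))`` on column-centered dosages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "-9", "-9.0", ".", "na"}


class InputError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class MarkerMatrix:
    """Lines-by-markers dosage matrix with a missingness mask.

    Attributes
    ----------
    line_ids : list of str
        Unique line identifiers, one per row.
    marker_ids : list of str
        Unique marker identifiers, one per column.
    dosages : ndarray of float, shape (n_lines, n_markers)
        Allele counts; entries where ``missing`` is True are undefined.
    missing : ndarray of bool, shape (n_lines, n_markers)
        True where the call is missing.
    """

    line_ids: list
    marker_ids: list
    dosages: np.ndarray
    missing: np.ndarray = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.missing is None:
            self.missing = np.isnan(self.dosages)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, p = self.dosages.shape
        if len(self.line_ids) != n or len(self.marker_ids) != p:
            raise InputError("id lists inconsistent with dosage dimensions")
        if len(set(self.line_ids)) != n:
            raise InputError("duplicate line ids")
        if len(set(self.marker_ids)) != p:
            raise InputError("duplicate marker ids")
        if self.missing.shape != self.dosages.shape:
            raise InputError("mask shape mismatch")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def validate_dosage_codes(self) -> None:
        """Check every non-missing entry is in {0, 1, 2}; name the offender."""
        obs = ~self.missing
        bad = obs & ~np.isin(self.dosages, (0.0, 1.0, 2.0))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise InputError(
                f"non-{{0,1,2}} dosage {self.dosages[i, j]!r} at line "
                f"{self.line_ids[i]!r}, marker {self.marker_ids[j]!r}"
            )


@dataclass
class PhenotypeTable:
    """Continuous trait values per line, with optional check-line flags."""

    line_ids: list
    values: np.ndarray
    trait_name: str = "trait"
    check_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.line_ids)) != len(self.line_ids):
            raise InputError("duplicate line ids in phenotype table")
        if len(self.line_ids) != self.values.shape[0]:
            raise InputError("phenotype values inconsistent with line ids")
        unknown = set(self.check_ids) - set(self.line_ids)
        if unknown:
            raise InputError(f"check ids not in line ids: {sorted(unknown)}")

    @property
    def check_values(self) -> np.ndarray:
        idx = {l: k for k, l in enumerate(self.line_ids)}
        return self.values[[idx[c] for c in self.check_ids]]


@dataclass
class KinshipMatrix:
    """Symmetric PSD relationship matrix over a set of lines."""

    line_ids: list
    G: np.ndarray

    SYM_TOL = 1e-10
    PSD_TOL = 1e-8

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        n = len(self.line_ids)
        if self.G.shape != (n, n):
            raise InputError("G dimensions do not match line ids")
        if np.abs(self.G - self.G.T).max() > self.SYM_TOL:
            raise InputError("G is not symmetric within tolerance")

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.G)[0])

    def subset(self, ids) -> "KinshipMatrix":
        idx = {l: k for k, l in enumerate(self.line_ids)}
        sel = np.array([idx[i] for i in ids])
        return KinshipMatrix(list(ids), self.G[np.ix_(sel, sel)])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.G, index=self.line_ids, columns=self.line_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(i) for i in df.index], df.to_numpy(dtype=float))


@dataclass
class MarkerQCReport:
    n_markers_in: int
    n_markers_out: int
    removed_maf: int
    removed_missing: int
    removed_het: int
    maf_min: float
    max_missing: float
    max_het: float
    het_filter_applied: bool = True

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# readers


def read_marker_matrix(path, format: str = "delimited") -> MarkerMatrix:
    """Read a dosage matrix from a delimited table or a VCF.

    Delimited dialect: lines in rows, first column line ids, header row of
    marker ids; missing coded as NA / empty / -9.  VCF: biallelic SNPs are
    converted to ALT-allele dosage; multi-allelic sites are skipped with a
    warning.
    """
    if format == "delimited":
        return _read_delimited(path)
    if format == "vcf":
        return _read_vcf(path)
    raise InputError(f"unknown genotype format {format!r}")


def _read_delimited(path) -> MarkerMatrix:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                         keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read genotype file {path}: {exc}") from exc
    line_ids = [str(i) for i in df.index]
    marker_ids = [str(c) for c in df.columns]
    if len(set(line_ids)) != len(line_ids):
        dup = next(i for i in line_ids if line_ids.count(i) > 1)
        raise InputError(f"duplicate line id {dup!r} in {path}")
    # transposed-input heuristic: ids that all look like typical marker names
    # while columns look like line names is not detectable in general; we
    # reject only the unambiguous case where a header cell reappears as a row id
    raw = df.to_numpy()
    n, p = raw.shape
    dosages = np.zeros((n, p), dtype=float)
    missing = np.zeros((n, p), dtype=bool)
    for j in range(p):
        col = raw[:, j]
        for i in range(n):
            tok = col[i].strip()
            if tok in _MISSING_TOKENS:
                missing[i, j] = True
            else:
                try:
                    dosages[i, j] = float(tok)
                except ValueError:
                    raise InputError(
                        f"unparseable dosage {tok!r} at line {line_ids[i]!r}, "
                        f"marker {marker_ids[j]!r}"
                    ) from None
    M = MarkerMatrix(line_ids, marker_ids, dosages, missing)
    M.validate_dosage_codes()
    return M


def _read_vcf(path) -> MarkerMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids, cols, masks = [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gts = np.asarray(var.genotype.array())[:, :2]
        miss = (gts < 0).any(axis=1)
        dose = np.where(miss, 0, (gts > 0).sum(axis=1)).astype(float)
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        cols.append(dose)
        masks.append(miss)
    vcf.close()
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multi-allelic site(s) in {path}")
        logger.warning("skipped %d multi-allelic sites in %s", n_skipped, path)
    if not cols:
        raise InputError(f"no biallelic SNPs found in {path}")
    return MarkerMatrix(
        line_ids, marker_ids, np.column_stack(cols), np.column_stack(masks)
    )


def read_phenotype_table(path, trait: str = None, check_ids=None) -> PhenotypeTable:
    """Read a phenotype table: first column line ids, one column per trait."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if trait is None:
        trait = df.columns[0]
    if trait not in df.columns:
        raise InputError(f"trait {trait!r} not found; have {list(df.columns)}")
    line_ids = [str(i) for i in df.index]
    return PhenotypeTable(
        line_ids,
        df[trait].to_numpy(dtype=float),
        trait_name=trait,
        check_ids=list(check_ids or []),
    )


# ---------------------------------------------------------------------------
# QC, imputation, kinship


def marker_stats(M: MarkerMatrix):
    """Per-marker (maf, missing_fraction, het_fraction) over non-missing calls."""
    obs = ~M.missing
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, M.dosages, 0.0).sum(axis=0) / (2.0 * n_obs)
        het = (obs & (M.dosages == 1.0)).sum(axis=0) / n_obs
    maf = np.minimum(p, 1.0 - p)
    miss_frac = 1.0 - n_obs / M.n_lines
    return maf, miss_frac, het


def filter_markers(
    M: MarkerMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.50,
    max_het: float = 0.05,
) -> tuple:
    """Retain markers with MAF >= maf_min, missing fraction < max_missing and
    heterozygosity fraction < max_het.

    The heterozygosity filter is skipped (with a warning) when the matrix
    contains non-integer dosages, i.e. has already been imputed.
    """
    for t in (maf_min, max_missing, max_het):
        if not 0.0 <= t <= 1.0:
            raise InputError(f"threshold {t} outside [0, 1]")
    maf, miss_frac, het = marker_stats(M)

    obs = ~M.missing
    integral = np.all(M.dosages[obs] == np.round(M.dosages[obs]))
    apply_het = bool(integral)
    if not apply_het:
        warnings.warn(
            "non-integer dosages detected (already imputed?); "
            "heterozygosity filter skipped"
        )

    ok_maf = maf >= maf_min
    ok_miss = miss_frac < max_missing
    ok_het = het < max_het if apply_het else np.ones(M.n_markers, dtype=bool)
    # fully-missing markers have undefined maf/het; drop them via missingness
    ok_maf &= ~np.isnan(maf)
    keep = ok_maf & ok_miss & ok_het
    if not keep.any():
        raise InputError(
            "all markers removed by QC; relax maf_min/max_missing/max_het"
        )
    report = MarkerQCReport(
        n_markers_in=M.n_markers,
        n_markers_out=int(keep.sum()),
        removed_maf=int((~ok_maf).sum()),
        removed_missing=int((~ok_miss).sum()),
        removed_het=int((~ok_het).sum()),
        maf_min=maf_min,
        max_missing=max_missing,
        max_het=max_het,
        het_filter_applied=apply_het,
    )
    out = MarkerMatrix(
        list(M.line_ids),
        [m for m, k in zip(M.marker_ids, keep) if k],
        M.dosages[:, keep].copy(),
        M.missing[:, keep].copy(),
    )
    return out, report


def impute_missing_mean(M: MarkerMatrix) -> MarkerMatrix:
    """Replace each missing cell with its marker's non-missing mean."""
    if not M.missing.any():
        return MarkerMatrix(
            list(M.line_ids), list(M.marker_ids), M.dosages.copy(),
            M.missing.copy(),
        )
    obs = ~M.missing
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.argmax(n_obs == 0))
        raise InputError(
            f"marker {M.marker_ids[j]!r} is fully missing; filter first"
        )
    col_mean = np.where(obs, M.dosages, 0.0).sum(axis=0) / n_obs
    dosages = np.where(M.missing, col_mean[np.newaxis, :], M.dosages)
    return MarkerMatrix(
        list(M.line_ids), list(M.marker_ids), dosages,
        np.zeros_like(M.missing),
    )


def compute_grm(M: MarkerMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from a complete dosage matrix.

    With per-marker allele frequency ``p_k = mean(dosage_k) / 2`` and
    ``W = dosages - 2 p_k``, returns ``G = W W' / (2 sum_k p_k (1 - p_k))``.
    """
    if M.missing.any():
        raise InputError("compute_grm requires a complete matrix; impute first")
    if M.n_markers < 1:
        raise InputError("no markers")
    p = M.dosages.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise InputError("all markers monomorphic: VanRaden denominator is zero")
    W = M.dosages - 2.0 * p
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)  # enforce exact symmetry against fp round-off
    return KinshipMatrix(list(M.line_ids), G)


def align_data(M: MarkerMatrix, P: PhenotypeTable) -> tuple:
    """Restrict both objects to the common line ids, in marker-matrix order."""
    common = set(M.line_ids) & set(P.line_ids)
    if not common:
        raise InputError("genotype and phenotype line ids are disjoint")
    keep_ids = [l for l in M.line_ids if l in common]
    dropped_g = [l for l in M.line_ids if l not in common]
    dropped_p = [l for l in P.line_ids if l not in common]
    if dropped_g or dropped_p:
        logger.info(
            "align_data dropped %d genotyped-only and %d phenotyped-only lines",
            len(dropped_g), len(dropped_p),
        )
    gsel = [M.line_ids.index(l) for l in keep_ids]
    M2 = MarkerMatrix(
        keep_ids, list(M.marker_ids), M.dosages[gsel], M.missing[gsel]
    )
    pidx = {l: k for k, l in enumerate(P.line_ids)}
    psel = [pidx[l] for l in keep_ids]
    P2 = PhenotypeTable(
        keep_ids,
        P.values[psel],
        trait_name=P.trait_name,
        check_ids=[c for c in P.check_ids if c in common],
    )
    return M2, P2
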