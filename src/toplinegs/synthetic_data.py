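"""Synthetic genotype/phenotype generator with known ground truth.

Emulates GBS-style dosage data: biallelic markers with configurable allele
frequencies, an additive polygenic trait with a target narrow-sense
heritability, optional check lines replicated near a high quantile, and a
recorded truth object for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_kinship import MarkerMatrix, PhenotypeTable
from .thresholding import ThresholdSpec, resolve_threshold


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    n_lines: int = 500
    n_markers: int = 1000
    maf_range: tuple = (0.05, 0.5)
    n_qtl: int = None  # default: min(100, n_markers // 5), at least 1
    h2: float = 0.5
    inbreeding: float = 0.95
    n_checks: int = 0
    missing_rate: float = 0.0
    tau: float = 0.8
    intercept: float = 10.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationError("maf_range must be within (0, 0.5]")
        if not 0.0 <= self.h2 <= 1.0:
            raise SimulationError("h2 must be in [0, 1]")
        if self.n_qtl is None:
            self.n_qtl = max(1, min(100, self.n_markers // 5))
        if self.n_qtl > self.n_markers:
            raise SimulationError("n_qtl exceeds n_markers")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.inbreeding <= 1.0:
            raise SimulationError("inbreeding must be in [0, 1]")
        if self.h2 == 1.0 and self.n_qtl == 0:
            raise SimulationError("h2 = 1 requires at least one causal marker")

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["maf_range"] = list(self.maf_range)
        return d


@dataclass
class SyntheticTruth:
    causal_marker_ids: list
    effects: np.ndarray
    g_true: np.ndarray
    realized_h2: float
    top_line_ids: list
    threshold_value: float
    tau: float

    def as_dict(self) -> dict:
        return {
            "causal_marker_ids": list(self.causal_marker_ids),
            "effects": [float(b) for b in self.effects],
            "g_true": [float(g) for g in self.g_true],
            "realized_h2": self.realized_h2,
            "top_line_ids": list(self.top_line_ids),
            "threshold_value": self.threshold_value,
            "tau": self.tau,
        }


def simulate_genotypes(cfg: SimConfig) -> MarkerMatrix:
    """Dosages with per-marker allele frequency p ~ Uniform(maf_range),
    missing cells masked independently at ``missing_rate``.

    Calls follow the inbred-line genotype model: with probability
    ``inbreeding`` a call is homozygous (2 with prob p, else 0), otherwise
    Binomial(2, p).  The default high inbreeding emulates GBS data from
    elite inbred material, whose heterozygosity stays under typical QC
    limits; set ``inbreeding=0`` for Hardy-Weinberg sampling.
    """
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_markers)
    shape = (cfg.n_lines, cfg.n_markers)
    hwe = rng.binomial(2, p, size=shape).astype(float)
    if cfg.inbreeding > 0:
        homo = 2.0 * rng.binomial(1, p, size=shape)
        ibd = rng.uniform(size=shape) < cfg.inbreeding
        dosages = np.where(ibd, homo, hwe)
    else:
        dosages = hwe
    missing = (
        rng.uniform(size=dosages.shape) < cfg.missing_rate
        if cfg.missing_rate > 0
        else np.zeros(dosages.shape, dtype=bool)
    )
    line_ids = [f"L{i:04d}" for i in range(cfg.n_lines)]
    marker_ids = [f"M{j:05d}" for j in range(cfg.n_markers)]
    return MarkerMatrix(line_ids, marker_ids, dosages, missing)


def simulate_phenotypes(M: MarkerMatrix, cfg: SimConfig):
    """Additive polygenic trait on a complete dosage matrix.

    ``n_qtl`` causal markers get Normal effects; the centered genetic score
    plus Normal noise scaled to the target h2 gives the phenotype (intercept
    10 by default so quantile thresholds stay positive).  Checks, when
    requested, are extra replicated lines placed near the tau quantile.
    """
    if M.missing.any():
        raise SimulationError("simulate_phenotypes requires a complete matrix")
    rng = np.random.default_rng(cfg.seed + 1)
    n = M.n_lines
    if cfg.n_qtl > 0 and cfg.h2 > 0:
        causal_idx = np.sort(rng.choice(M.n_markers, size=cfg.n_qtl, replace=False))
        effects = rng.standard_normal(cfg.n_qtl)
        score = M.dosages[:, causal_idx] @ effects
        g_true = score - score.mean()
    else:
        causal_idx = np.array([], dtype=int)
        effects = np.array([])
        g_true = np.zeros(n)
    var_g = float(np.var(g_true))
    if cfg.h2 > 0 and var_g > 0:
        var_e = var_g * (1.0 - cfg.h2) / cfg.h2 if cfg.h2 < 1 else 0.0
    else:
        g_true = np.zeros(n)
        var_g, var_e = 0.0, 1.0
    resid = np.sqrt(var_e) * rng.standard_normal(n) if var_e > 0 else np.zeros(n)
    values = cfg.intercept + g_true + resid
    realized_h2 = var_g / (var_g + np.var(resid)) if (var_g + np.var(resid)) > 0 else 0.0

    line_ids = list(M.line_ids)
    check_ids = []
    if cfg.n_checks > 0:
        # checks replicate performance near the tau quantile of the trait
        anchor = float(np.quantile(values, cfg.tau, method="linear"))
        noise = 0.05 * max(np.std(values), 1e-6)
        check_vals = anchor + noise * rng.standard_normal(cfg.n_checks)
        check_ids = [f"CHK{i:02d}" for i in range(cfg.n_checks)]
        line_ids = line_ids + check_ids
        values = np.concatenate([values, check_vals])

    pheno = PhenotypeTable(line_ids, values, trait_name="trait",
                           check_ids=check_ids)
    thr = resolve_threshold(
        values[: n], ThresholdSpec(kind="quantile", tau=cfg.tau)
    )
    top = [l for l, v in zip(M.line_ids, values[:n]) if v >= thr.value]
    truth = SyntheticTruth(
        causal_marker_ids=[M.marker_ids[j] for j in causal_idx],
        effects=effects,
        g_true=g_true,
        realized_h2=float(realized_h2),
        top_line_ids=top,
        threshold_value=thr.value,
        tau=cfg.tau,
    )
    return pheno, truth


@dataclass
class BenchmarkBundle:
    genotypes: MarkerMatrix
    phenotypes: PhenotypeTable
    truth: SyntheticTruth
    config: SimConfig
    paths: dict = field(default_factory=dict)


def make_benchmark(cfg: SimConfig, out_dir=None) -> BenchmarkBundle:
    """Generate a genotype/phenotype/truth bundle; optionally write it out in
    the standard delimited formats plus a truth/config JSON."""
    from .io_kinship import impute_missing_mean

    M = simulate_genotypes(cfg)
    complete = impute_missing_mean(M) if M.missing.any() else M
    pheno, truth = simulate_phenotypes(complete, cfg)

    paths = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        geno_df = pd.DataFrame(
            np.where(M.missing, np.nan, M.dosages),
            index=M.line_ids, columns=M.marker_ids,
        )
        paths["genotypes"] = out / "genotypes.csv"
        geno_df.to_csv(paths["genotypes"], na_rep="NA", float_format="%g")
        paths["phenotypes"] = out / "phenotypes.csv"
        pd.DataFrame(
            {"trait": pheno.values}, index=pheno.line_ids
        ).rename_axis("line_id").to_csv(paths["phenotypes"], float_format="%.10g")
        paths["truth"] = out / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(
                {"config": cfg.as_dict(), "truth": truth.as_dict(),
                 "check_ids": pheno.check_ids},
                fh, indent=1,
            )
        paths = {k: str(v) for k, v in paths.items()}
    return BenchmarkBundle(M, pheno, truth, cfg, paths)
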