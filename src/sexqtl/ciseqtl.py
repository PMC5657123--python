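"""Additive cis-eQTL scan with sex as covariate.

For each seed SNP, probes on the same chromosome within a closed +/-1 Mb
window of the SNP position (probe start coordinate) are tested with
ordinary least squares of z-scored expression on
``(intercept, dosage, sex)`` — the standard additive eQTL model with a
sex covariate. The two-sided t-test p-value on the dosage coefficient is
adjusted by Benjamini-Hochberg FDR, pooled over all tests in the scan.
Trans associations are not considered.

A pair is testable only when the dosage is polymorphic among
pairwise-complete samples and each genotype class present has at least
``min_genotype_count`` samples (default 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import ExpressionMatrix, GenotypeMatrix, norm_chrom

WINDOW_BASES = 1_000_000
MIN_GENOTYPE_COUNT = 3
FDR_THRESHOLD = 0.05


@dataclass
class CisWindow:
    """Probes within ``window`` bases of one seed SNP, same chromosome."""

    snp: str
    chromosome: str
    position: int
    probe_ids: list[str] = field(default_factory=list)
    window: int = WINDOW_BASES


@dataclass
class CisPairResult:
    """One SNP-probe additive test (fdr filled in by the scan)."""

    snp: str
    probe: str
    gene: str
    beta: float = np.nan
    se: float = np.nan
    t: float = np.nan
    p: float = np.nan
    fdr: float = np.nan
    n_used: int = 0
    direction_vs_risk: str = ""
    testable: bool = True
    reason: str = ""


def build_cis_windows(genotypes: GenotypeMatrix, seed_snps: list[str],
                      probe_annotation: pd.DataFrame,
                      window: int = WINDOW_BASES) -> list[CisWindow]:
    """Closed-interval windows: |probe_start - snp_pos| <= window, same chrom."""
    windows = []
    probe_chrom = probe_annotation["chromosome"].map(norm_chrom)
    probe_start = probe_annotation["start"].astype(float)
    for snp in seed_snps:
        if snp not in genotypes.snp_annotation.index:
            raise KeyError(f"seed SNP {snp} not in genotype annotation")
        row = genotypes.snp_annotation.loc[snp]
        pos = row["position"]
        if pd.isna(pos) or pd.isna(row["chromosome"]):
            raise ValueError(f"seed SNP {snp} lacks coordinates")
        chrom = norm_chrom(row["chromosome"])
        in_window = (probe_chrom == chrom) & \
            ((probe_start - float(pos)).abs() <= window)
        windows.append(CisWindow(
            snp=snp, chromosome=chrom, position=int(pos),
            probe_ids=list(probe_annotation.index[in_window]), window=window,
        ))
    return windows


def ols_fit(X: np.ndarray, y: np.ndarray):
    """OLS via the normal equations; returns (beta, se, t, p, dof).

    Raises ``numpy.linalg.LinAlgError`` on a rank-deficient design.
    """
    n, k = X.shape
    if n <= k:
        raise np.linalg.LinAlgError("fewer observations than parameters + 1")
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < k:
        raise np.linalg.LinAlgError("collinear design")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, p, dof


def _usable_mask(*arrays: np.ndarray) -> np.ndarray:
    mask = np.ones(arrays[0].shape, dtype=bool)
    for a in arrays:
        mask &= np.isfinite(a)
    return mask


def genotype_class_ok(dosage: np.ndarray, min_count: int) -> tuple[bool, str]:
    classes, counts = np.unique(dosage, return_counts=True)
    if classes.size < 2:
        return False, "monomorphic dosage"
    if (counts < min_count).any():
        small = classes[counts < min_count].astype(int).tolist()
        return False, f"genotype class(es) {small} below min count {min_count}"
    return True, ""


def fit_additive_model(dosage, expression_row, sex,
                       min_genotype_count: int = MIN_GENOTYPE_COUNT,
                       snp: str = "", probe: str = "", gene: str = ""
                       ) -> CisPairResult:
    """OLS of one expression row on (intercept, dosage, sex).

    Missing dosages are handled pairwise-complete: samples missing this
    SNP are dropped for this test only.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(expression_row, dtype=float)
    s = np.asarray(sex, dtype=float)
    mask = _usable_mask(d, y, s)
    d, y, s = d[mask], y[mask], s[mask]
    n = d.size

    res = CisPairResult(snp=snp, probe=probe, gene=gene, n_used=int(n))
    ok, why = genotype_class_ok(d, min_genotype_count)
    if not ok:
        res.testable, res.reason = False, why
        return res
    if n < 5:  # 3 parameters + 2
        res.testable, res.reason = False, f"only {n} usable samples"
        return res
    X = np.column_stack([np.ones(n), d, s])
    try:
        beta, se, t, p, _ = ols_fit(X, y)
    except np.linalg.LinAlgError as exc:
        res.testable, res.reason = False, str(exc)
        return res
    res.beta, res.se, res.t, res.p = (float(beta[1]), float(se[1]),
                                      float(t[1]), float(p[1]))
    res.direction_vs_risk = "increased" if res.beta >= 0 else "decreased"
    return res


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def run_cis_scan(genotypes: GenotypeMatrix, expression: ExpressionMatrix,
                 windows: list[CisWindow], sex: pd.Series,
                 min_genotype_count: int = MIN_GENOTYPE_COUNT,
                 fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Additive scan over all (seed SNP, in-window probe) pairs.

    Returns one row per testable pair with BH FDR computed jointly over
    the whole scan; ``df.attrs`` records the number of untestable pairs
    and tested probes per SNP.
    """
    if not expression.normalized:
        raise ValueError("expression must be z-scored before the cis scan")
    sex = sex.reindex(expression.sample_ids)
    if sex.isna().any():
        raise ValueError("sex vector does not cover all expression samples")

    rows: list[CisPairResult] = []
    untestable = 0
    probes_per_snp: dict[str, int] = {}
    for w in windows:
        dosage = genotypes.dosage(w.snp).reindex(expression.sample_ids)
        probes_per_snp[w.snp] = len(w.probe_ids)
        for probe in w.probe_ids:
            if probe not in expression.values.index:
                continue
            gene = str(expression.probe_annotation.loc[probe, "gene"])
            res = fit_additive_model(
                dosage.to_numpy(), expression.values.loc[probe].to_numpy(),
                sex.to_numpy(), min_genotype_count=min_genotype_count,
                snp=w.snp, probe=probe, gene=gene)
            if res.testable:
                rows.append(res)
            else:
                untestable += 1

    df = pd.DataFrame(
        [(r.snp, r.probe, r.gene, r.beta, r.se, r.t, r.p, r.n_used,
          r.direction_vs_risk) for r in rows],
        columns=["snp", "probe", "gene", "beta", "se", "t", "p", "n_used",
                 "direction_vs_risk"],
    )
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["fdr"] < fdr_threshold
    else:
        df["fdr"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    df.attrs["n_untestable"] = untestable
    df.attrs["probes_per_snp"] = probes_per_snp
    return df
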