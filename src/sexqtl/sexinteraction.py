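"""SNP-by-sex interaction tests with a genotype-permutation FDR.

The model, fitted per (SNP, probe) pair on z-scored expression, is

    expression ~ intercept + dosage + sex + dosage * sex

with dosage the 0/1/2 risk-allele count and sex coded 0 (male) / 1
(female). ``beta_int``, the coefficient on ``dosage * sex``, measures how
the per-allele expression effect differs in females relative to males.

Significance of the interaction is assessed against a permutation null:
the genotype vector of each SNP is shuffled across samples (sex and
expression stay fixed, so the sex-expression relationship is preserved)
and the interaction |t| recomputed; one shuffle per SNP per permutation is
shared by all probes of that SNP, preserving cross-probe correlation.
Permuting genotype only destroys both the SNP main effect and the
interaction; the null is therefore conservative for pairs with strong
main effects.

The permutation FDR follows the SAMseq construction: at each observed
threshold c,

    FDR(c) = pi0 * median_b #{|t*_b| >= c} / max(1, #{|t_obs| >= c})

clipped to [0, 1] and made monotone non-increasing in c, with pi0
estimated by the Storey-Tibshirani quantile method at lambda = 0.5 on the
per-pair permutation p-values. Permutation p-values use the add-one
estimator ``(1 + #{|t*| >= |t_obs|}) / (1 + n_perm)``.

The module also provides per-sex stratified fits (for inspecting
opposite-direction effects) and composite-LD r^2 between dosage vectors
(for proxy-SNP confirmation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ciseqtl import (CisWindow, MIN_GENOTYPE_COUNT, genotype_class_ok,
                      ols_fit)
from .genio import ExpressionMatrix, GenotypeMatrix

N_PERM_DEFAULT = 10_000
MIN_N_PERM = 100
ALPHA = 0.05
PI0_LAMBDA = 0.5


@dataclass
class InteractionResult:
    """One SNP-probe interaction fit (permutation fields filled by the scan)."""

    snp: str
    probe: str
    gene: str
    beta_int: float = np.nan
    se_int: float = np.nan
    t_int: float = np.nan
    p_intercept: float = np.nan
    p_snp: float = np.nan
    p_sex: float = np.nan
    p_int: float = np.nan
    perm_p: float = np.nan
    perm_fdr: float = np.nan
    n_used: int = 0
    testable: bool = True
    reason: str = ""


@dataclass
class PermutationNull:
    """Permuted interaction |t*| statistics, aligned with ``pairs``.

    ``abs_t`` has shape (n_perm, n_pairs); within one permutation every
    probe of a given SNP shares that SNP's genotype shuffle.
    """

    pairs: list[tuple[str, str]]
    abs_t: np.ndarray
    n_perm: int
    seed: int


@dataclass
class StratumFit:
    """Per-sex genotype effect from a within-stratum OLS."""

    sex: str
    beta: float = np.nan
    se: float = np.nan
    p: float = np.nan
    n: int = 0
    ok: bool = True
    reason: str = ""


@dataclass
class LdResult:
    """Composite LD between two dosage vectors."""

    snp_a: str
    snp_b: str
    r2: float
    n_used: int


def fit_interaction_model(dosage, sex, expression_row,
                          min_genotype_count: int = MIN_GENOTYPE_COUNT,
                          snp: str = "", probe: str = "", gene: str = ""
                          ) -> InteractionResult:
    """OLS on (intercept, dosage, sex, dosage*sex) with per-term p-values."""
    d = np.asarray(dosage, dtype=float)
    s = np.asarray(sex, dtype=float)
    y = np.asarray(expression_row, dtype=float)
    mask = np.isfinite(d) & np.isfinite(s) & np.isfinite(y)
    d, s, y = d[mask], s[mask], y[mask]
    n = d.size

    res = InteractionResult(snp=snp, probe=probe, gene=gene, n_used=int(n))
    if np.unique(s).size < 2:
        res.testable, res.reason = False, "single-sex input"
        return res
    ok, why = genotype_class_ok(d, min_genotype_count)
    if not ok:
        res.testable, res.reason = False, why
        return res
    if n < 6:  # 4 parameters + 2
        res.testable, res.reason = False, f"only {n} usable samples"
        return res
    X = np.column_stack([np.ones(n), d, s, d * s])
    try:
        beta, se, t, p, _ = ols_fit(X, y)
    except np.linalg.LinAlgError as exc:
        res.testable, res.reason = False, str(exc)
        return res
    res.beta_int, res.se_int, res.t_int = float(beta[3]), float(se[3]), float(t[3])
    res.p_intercept, res.p_snp, res.p_sex, res.p_int = (
        float(p[0]), float(p[1]), float(p[2]), float(p[3]))
    return res


def _batched_interaction_abs_t(G: np.ndarray, s: np.ndarray,
                               E: np.ndarray) -> np.ndarray:
    """|t| of the interaction coefficient for every (permutation, probe).

    ``G`` is (n_perm, n) permuted dosages, ``s`` the 0/1 sex vector, ``E``
    (n_probes, n) expression. Exploits that the design differs between
    permutations only through the dosage column: X'X and X'Y reduce to a
    handful of cross-sums, solved as batched 4x4 systems.
    """
    n = s.size
    n_perm, m = G.shape[0], E.shape[0]
    ssum = float(s.sum())           # sum s = sum s^2 (s is 0/1)
    a = float(G[0].sum())           # permutation-invariant
    q = float((G[0] ** 2).sum())
    c = G @ s                       # sum g*s per permutation
    dd = (G ** 2) @ s               # sum g^2*s per permutation

    A = np.empty((n_perm, 4, 4))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = a
    A[:, 0, 2] = A[:, 2, 0] = ssum
    A[:, 0, 3] = A[:, 3, 0] = c
    A[:, 1, 1] = q
    A[:, 1, 2] = A[:, 2, 1] = c
    A[:, 1, 3] = A[:, 3, 1] = dd
    A[:, 2, 2] = ssum
    A[:, 2, 3] = A[:, 3, 2] = c
    A[:, 3, 3] = dd

    se_y = E.sum(axis=1)                    # (m,)
    sse_y = E @ s                           # (m,)
    gy = G @ E.T                            # (n_perm, m)
    gsy = G @ (E * s).T                     # (n_perm, m)

    B = np.empty((n_perm, 4, m))
    B[:, 0, :] = se_y
    B[:, 1, :] = gy
    B[:, 2, :] = sse_y
    B[:, 3, :] = gsy

    try:
        beta = np.linalg.solve(A, B)
        Ainv33 = np.linalg.inv(A)[:, 3, 3]
    except np.linalg.LinAlgError:
        # rare degenerate shuffle (e.g. one sex monomorphic); fall back row-wise
        beta = np.full((n_perm, 4, m), np.nan)
        Ainv33 = np.full(n_perm, np.nan)
        for b in range(n_perm):
            try:
                beta[b] = np.linalg.solve(A[b], B[b])
                Ainv33[b] = np.linalg.inv(A[b])[3, 3]
            except np.linalg.LinAlgError:
                pass

    yy = (E ** 2).sum(axis=1)
    rss = np.maximum(yy[None, :] - np.einsum("bkm,bkm->bm", beta, B), 0.0)
    sigma2 = rss / (n - 4)
    var_int = sigma2 * Ainv33[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        abs_t = np.abs(beta[:, 3, :]) / np.sqrt(var_int)
    return np.nan_to_num(abs_t, nan=0.0, posinf=0.0)


def build_permutation_null(dosages: pd.DataFrame, sex: pd.Series,
                           expression: ExpressionMatrix | pd.DataFrame,
                           n_perm: int = N_PERM_DEFAULT, seed: int = 0,
                           pairs: list[tuple[str, str]] | None = None
                           ) -> PermutationNull:
    """Genotype-shuffle null of interaction |t*| for each (SNP, probe) pair.

    ``dosages`` is samples x SNPs (NaN = missing; samples missing a SNP are
    dropped for all of that SNP's pairs). Expression must be complete. One
    shared shuffle per SNP per permutation covers all its probes.
    """
    if n_perm < MIN_N_PERM:
        raise ValueError(
            f"n_perm={n_perm} too small for FDR resolution (min {MIN_N_PERM})")
    values = expression.values if isinstance(expression, ExpressionMatrix) \
        else expression
    if pairs is None:
        pairs = [(snp, probe) for snp in dosages.columns
                 for probe in values.index]
    by_snp: dict[str, list[str]] = {}
    for snp, probe in pairs:
        by_snp.setdefault(snp, []).append(probe)

    rng = np.random.default_rng(seed)
    sex_arr = sex.reindex(dosages.index).to_numpy(dtype=float)
    col_of_pair: dict[tuple[str, str], int] = {}
    stats_cols: list[np.ndarray] = []
    for snp in by_snp:
        g = dosages[snp].to_numpy(dtype=float)
        mask = np.isfinite(g)
        gm, sm = g[mask], sex_arr[mask]
        E = values.loc[by_snp[snp]].to_numpy(dtype=float)[:, mask]
        G = rng.permuted(np.broadcast_to(gm, (n_perm, gm.size)).copy(), axis=1)
        abs_t = _batched_interaction_abs_t(G, sm, E)
        for j, probe in enumerate(by_snp[snp]):
            col_of_pair[(snp, probe)] = len(stats_cols)
            stats_cols.append(abs_t[:, j])

    ordered = np.column_stack([stats_cols[col_of_pair[p]] for p in pairs])
    return PermutationNull(pairs=list(pairs), abs_t=ordered, n_perm=n_perm,
                           seed=seed)


def permutation_pvalues(observed_abs_t, null: PermutationNull) -> np.ndarray:
    """Add-one permutation p per pair: (1 + #{|t*| >= |t|}) / (1 + n_perm)."""
    obs = np.asarray(observed_abs_t, dtype=float)
    if obs.size != len(null.pairs):
        raise ValueError("observed statistics not aligned with null pairs")
    exceed = (null.abs_t >= obs[None, :]).sum(axis=0)
    return (1.0 + exceed) / (1.0 + null.n_perm)


def estimate_pi0(perm_p: np.ndarray, lambda_: float = PI0_LAMBDA) -> float:
    """Storey-Tibshirani quantile estimate of the null proportion."""
    m = perm_p.size
    if m == 0:
        raise ValueError("no p-values for pi0 estimation")
    pi0 = (perm_p > lambda_).sum() / ((1.0 - lambda_) * m)
    return float(min(1.0, max(pi0, 1.0 / m)))


def permutation_fdr(observed_abs_t, null: PermutationNull,
                    lambda_: float = PI0_LAMBDA) -> np.ndarray:
    """SAMseq-style permutation FDR per pair, in input pair order.

    At each observed threshold c, the numerator is the median over
    permutations of the pooled count of permuted statistics >= c, scaled
    by pi0; the denominator is the observed count >= c. Estimates are
    clipped to [0, 1] and made monotone non-increasing in c.
    """
    obs = np.asarray(observed_abs_t, dtype=float)
    if obs.size == 0:
        raise ValueError("empty observed statistic set")
    if obs.size != len(null.pairs):
        raise ValueError("observed statistics not aligned with null pairs")
    m = obs.size
    pi0 = estimate_pi0(permutation_pvalues(obs, null), lambda_)

    obs_sorted = np.sort(obs)
    # permuted tail counts pooled over pairs, per permutation, per threshold
    null_sorted = np.sort(null.abs_t, axis=1)
    counts = np.empty((null.n_perm, m))
    for b in range(null.n_perm):
        counts[b] = m - np.searchsorted(null_sorted[b], obs, side="left")
    med_null = np.median(counts, axis=0)
    n_obs_ge = obs.size - np.searchsorted(obs_sorted, obs, side="left")

    raw = np.clip(pi0 * med_null / np.maximum(1, n_obs_ge), 0.0, 1.0)

    # enforce monotone non-increasing FDR in c: in descending-c order each
    # estimate is the min of itself and everything less significant
    order = np.argsort(-obs, kind="mergesort")
    raw_desc = raw[order]
    mono_desc = np.minimum.accumulate(raw_desc[::-1])[::-1]
    fdr = np.empty(m)
    fdr[order] = mono_desc
    return fdr


def stratified_fit(dosage, expression_row, sex,
                   min_genotype_count: int = MIN_GENOTYPE_COUNT
                   ) -> dict[str, StratumFit]:
    """Separate OLS of expression on (intercept, dosage) within each sex."""
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(expression_row, dtype=float)
    s = np.asarray(sex, dtype=float)
    mask = np.isfinite(d) & np.isfinite(y) & np.isfinite(s)
    out: dict[str, StratumFit] = {}
    for label, code in (("male", 0), ("female", 1)):
        sel = mask & (s == code)
        fit = StratumFit(sex=label, n=int(sel.sum()))
        if fit.n == 0:
            fit.ok, fit.reason = False, "no samples in stratum"
            out[label] = fit
            continue
        ds, ys = d[sel], y[sel]
        ok, why = genotype_class_ok(ds, min_genotype_count)
        if not ok or fit.n < 4:
            fit.ok = False
            fit.reason = why if not ok else f"only {fit.n} samples"
            out[label] = fit
            continue
        X = np.column_stack([np.ones(fit.n), ds])
        try:
            beta, se, _, p, _ = ols_fit(X, ys)
        except np.linalg.LinAlgError as exc:
            fit.ok, fit.reason = False, str(exc)
            out[label] = fit
            continue
        fit.beta, fit.se, fit.p = float(beta[1]), float(se[1]), float(p[1])
        out[label] = fit
    return out


def compute_r2(dosage_a, dosage_b, snp_a: str = "A", snp_b: str = "B"
               ) -> LdResult:
    """Composite LD: squared Pearson correlation of additive dosages."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError("r^2 undefined for monomorphic dosage")
    r = np.corrcoef(a, b)[0, 1]
    return LdResult(snp_a=snp_a, snp_b=snp_b, r2=float(np.clip(r * r, 0.0, 1.0)),
                    n_used=int(a.size))


def run_interaction_scan(genotypes: GenotypeMatrix,
                         expression: ExpressionMatrix,
                         windows: list[CisWindow], sex: pd.Series,
                         n_perm: int = N_PERM_DEFAULT, seed: int = 0,
                         min_genotype_count: int = MIN_GENOTYPE_COUNT,
                         alpha: float = ALPHA) -> pd.DataFrame:
    """Interaction scan over all (seed SNP, in-window probe) pairs.

    Fits the interaction model per pair, builds one shared permutation
    null (one genotype shuffle per SNP per permutation), and computes
    permutation p-values and SAMseq-style permutation FDR over one family
    spanning the entire scan. Pairs are flagged significant when both
    perm_p and perm_fdr fall below ``alpha``.
    """
    if not expression.normalized:
        raise ValueError("expression must be z-scored before the interaction scan")
    sex = sex.reindex(expression.sample_ids)
    if sex.isna().any():
        raise ValueError("sex vector does not cover all expression samples")

    fits: list[InteractionResult] = []
    untestable = 0
    for w in windows:
        dosage = genotypes.dosage(w.snp).reindex(expression.sample_ids)
        for probe in w.probe_ids:
            if probe not in expression.values.index:
                continue
            gene = str(expression.probe_annotation.loc[probe, "gene"])
            res = fit_interaction_model(
                dosage.to_numpy(), sex.to_numpy(),
                expression.values.loc[probe].to_numpy(),
                min_genotype_count=min_genotype_count,
                snp=w.snp, probe=probe, gene=gene)
            if res.testable:
                fits.append(res)
            else:
                untestable += 1

    columns = ["snp", "probe", "gene", "p_intercept", "p_snp", "p_sex",
               "p_int", "beta_int", "se_int", "t_int", "perm_p", "perm_fdr",
               "n_used", "significant"]
    if not fits:
        df = pd.DataFrame(columns=columns)
        df.attrs["n_untestable"] = untestable
        return df

    pairs = [(r.snp, r.probe) for r in fits]
    snps = list(dict.fromkeys(snp for snp, _ in pairs))
    dosage_frame = genotypes.dosage_frame(snps).reindex(expression.sample_ids)
    null = build_permutation_null(dosage_frame, sex, expression,
                                  n_perm=n_perm, seed=seed, pairs=pairs)
    obs = np.array([abs(r.t_int) for r in fits])
    perm_p = permutation_pvalues(obs, null)
    perm_fdr = permutation_fdr(obs, null)
    for r, pp, pf in zip(fits, perm_p, perm_fdr):
        r.perm_p, r.perm_fdr = float(pp), float(pf)

    df = pd.DataFrame(
        [(r.snp, r.probe, r.gene, r.p_intercept, r.p_snp, r.p_sex, r.p_int,
          r.beta_int, r.se_int, r.t_int, r.perm_p, r.perm_fdr, r.n_used,
          (r.perm_p < alpha) and (r.perm_fdr < alpha)) for r in fits],
        columns=columns)
    df.attrs["n_untestable"] = untestable
    return df
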