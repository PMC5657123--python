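"""Dual sex inference: X-heterozygosity F statistic and Y-probe clustering.

Sex is inferred twice, independently, and then reconciled:

1. From genotypes, via the X-chromosome inbreeding coefficient
   ``F = 1 - O_het / E_het`` per sample. Males (one X) show no X
   heterozygosity when hemizygotes are array-coded as homozygotes, so
   F ~ 1; females under HWE have F ~ 0. Thresholds follow the common
   genotype-QC defaults: F > 0.8 -> male, F < 0.2 -> female.
2. From expression, by selecting Y-chromosome probes whose cross-sample
   coefficient of variation is high (above the 25th percentile of Y-probe
   CVs) and 2-means clustering samples on their mean Y expression; the
   cluster with the higher centroid is called male.

Samples where the two calls disagree, or either is ambiguous, are left
unresolved and reported; the pipeline excludes them by default.
Pseudoautosomal X SNPs must be excluded from the X-SNP list upstream —
they are heterozygous in males and bias F downward.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genio import ExpressionMatrix, GenotypeMatrix, MISSING_CALL, norm_chrom

MALE_F_THRESHOLD = 0.8
FEMALE_F_THRESHOLD = 0.2
MIN_X_SNPS = 20


def x_snp_ids(genotypes: GenotypeMatrix) -> list[str]:
    """SNPs annotated on the X chromosome (labels 'X' or '23')."""
    chroms = genotypes.snp_annotation["chromosome"].map(norm_chrom).str.upper()
    return list(genotypes.snp_annotation.index[chroms.isin(["X", "23"])])


def y_probe_ids(expression: ExpressionMatrix) -> list[str]:
    """Probes annotated on the Y chromosome."""
    chroms = expression.probe_annotation["chromosome"].map(norm_chrom).str.upper()
    return list(expression.probe_annotation.index[chroms == "Y"])


def impute_sex_from_x(genotypes: GenotypeMatrix,
                      x_snps: list[str] | None = None,
                      female_mask: pd.Series | None = None,
                      male_threshold: float = MALE_F_THRESHOLD,
                      female_threshold: float = FEMALE_F_THRESHOLD,
                      min_snps: int = MIN_X_SNPS) -> pd.DataFrame:
    """Per-sample X inbreeding coefficient and the sex call derived from it.

    ``E_het`` sums ``2 p (1-p)`` over the sample's non-missing X SNPs, with
    allele frequencies ``p`` estimated from female samples when a
    ``female_mask`` is supplied, otherwise from all samples. Samples with
    fewer than ``min_snps`` informative X SNPs are flagged unresolvable.

    Returns a DataFrame indexed by sample with columns ``f_stat``,
    ``n_x_snps``, ``sex_from_x`` in {male, female, ambiguous, unresolvable}.
    """
    if x_snps is None:
        x_snps = x_snp_ids(genotypes)
    if not x_snps:
        raise ValueError("no X-chromosome SNPs available")

    calls = genotypes.calls[list(x_snps)]
    ref = calls.loc[female_mask.index[female_mask.astype(bool)]] \
        if female_mask is not None else calls

    # per-SNP frequency of an arbitrary reference allele; 2p(1-p) is symmetric
    exp_het = {}
    for snp in x_snps:
        col = ref[snp]
        counts: dict[str, int] = {}
        for call in col:
            if call == MISSING_CALL:
                continue
            for letter in call:
                counts[letter] = counts.get(letter, 0) + 1
        total = sum(counts.values())
        p = (min(counts.values()) / total) if total and len(counts) > 1 else 0.0
        exp_het[snp] = 2.0 * p * (1.0 - p)

    records = []
    for sample in genotypes.sample_ids:
        row = calls.loc[sample]
        nonmissing = row[row != MISSING_CALL]
        n = len(nonmissing)
        o_het = sum(1 for c in nonmissing if c[0] != c[1])
        e_het = sum(exp_het[snp] for snp in nonmissing.index)
        if n < min_snps or e_het <= 0:
            records.append((sample, np.nan, n, "unresolvable"))
            continue
        f = 1.0 - o_het / e_het
        if f > male_threshold:
            call = "male"
        elif f < female_threshold:
            call = "female"
        else:
            call = "ambiguous"
        records.append((sample, f, n, call))
    return pd.DataFrame(
        records, columns=["sample_id", "f_stat", "n_x_snps", "sex_from_x"],
    ).set_index("sample_id")


def _two_means_1d(x: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 1-D 2-means: centroids initialized at min and max.

    Returns 0/1 labels where 1 is the higher-centroid cluster.
    """
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("cannot cluster: all values identical")
    centers = np.array([lo, hi])
    labels = np.zeros(x.shape, dtype=int)
    for _ in range(max_iter):
        new_labels = (np.abs(x - centers[1]) < np.abs(x - centers[0])).astype(int)
        for k in (0, 1):
            if (new_labels == k).any():
                centers[k] = x[new_labels == k].mean()
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    if centers[1] < centers[0]:
        labels = 1 - labels
    return labels


def classify_sex_from_y(expression: ExpressionMatrix,
                        y_probes: list[str] | None = None,
                        cv_quantile: float = 0.25) -> pd.Series:
    """Sex call per sample from Y-probe expression clustering.

    Y probes with a cross-sample coefficient of variation above the
    ``cv_quantile`` quantile of Y-probe CVs are retained; samples are
    2-means clustered on their mean retained-Y expression and the cluster
    with the higher centroid is called male.
    """
    if y_probes is None:
        y_probes = y_probe_ids(expression)
    if not y_probes:
        raise ValueError("no Y-chromosome probes available")
    vals = expression.values.loc[list(y_probes)].to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if np.all(sd == 0):
        raise ValueError("no informative Y probes (all zero variance)")
    mean = vals.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), np.inf)
    keep = cv > np.quantile(cv, cv_quantile)
    if not keep.any():
        keep = cv >= np.quantile(cv, cv_quantile)
    score = vals[keep].mean(axis=0)
    labels = _two_means_1d(score)
    calls = np.where(labels == 1, "male", "female")
    return pd.Series(calls, index=expression.sample_ids, name="sex_from_y")


def reconcile_sex(from_x: pd.DataFrame, from_y: pd.Series) -> pd.DataFrame:
    """Combine the two calls into a final sex, listing discordant samples.

    Returns a DataFrame (one row per sample) with ``f_stat``, ``sex_from_x``,
    ``sex_from_y``, ``final_sex`` ('male'/'female'/'unresolved') and
    ``discordant``. A final sex is set only when both calls agree and
    neither is ambiguous/unresolvable.
    """
    if set(from_x.index) != set(from_y.index):
        raise ValueError("X-based and Y-based call sets cover different samples")
    out = from_x.copy()
    out["sex_from_y"] = from_y.reindex(out.index)
    agree = (out["sex_from_x"] == out["sex_from_y"]) & \
        out["sex_from_x"].isin(["male", "female"])
    out["final_sex"] = np.where(agree, out["sex_from_x"], "unresolved")
    out["discordant"] = ~agree
    return out


def sex_to_numeric(report: pd.DataFrame) -> pd.Series:
    """0/1 (male/female) sex for resolved samples, dropping unresolved ones."""
    resolved = report[report["final_sex"].isin(["male", "female"])]
    return (resolved["final_sex"] == "female").astype(int).rename("sex")
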