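"""Plain-text I/O for genotype, expression, and result tables.

All tables are tab-separated with a header row. Genomic positions are
1-based throughout (dbSNP / array-annotation convention).

Formats
-------
genotype TSV
    Rows = samples, columns = SNPs. Cells are unphased allele-pair codes
    such as ``"AG"`` (``"GA"`` is equivalent); ``"00"`` marks a missing
    call.
SNP annotation TSV
    Columns ``rsid``, ``chromosome``, ``position``, ``alleles`` (slash
    separated, e.g. ``"G/T"``), ``risk_allele``.
expression TSV
    Rows = probes, columns = samples, log2 intensities (or z-scores once
    normalized).
probe annotation TSV
    Columns ``probe_id``, ``gene``, ``chromosome``, ``start``.

Binary array formats (IDAT, PLINK bed, VCF) are deliberately out of scope;
they can be adapted to these TSVs upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING_CALL = "00"

#: canonical column order for result tables (extra columns are appended)
RESULT_COLUMNS = [
    "snp", "probe", "gene",
    "beta", "se", "t", "p", "fdr",
    "p_intercept", "p_snp", "p_sex", "p_int", "beta_int",
    "perm_p", "perm_fdr",
    "n_used", "direction_vs_risk", "significant",
]

#: float format that round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17g"


def norm_chrom(chrom) -> str:
    """Normalize a chromosome label ('chr2', 2, '2' -> '2')."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-pair genotype calls plus per-SNP annotation.

    ``calls`` is a DataFrame indexed by sample ID with one column per SNP;
    ``snp_annotation`` is indexed by rsID with columns ``chromosome``,
    ``position``, ``alleles``, ``risk_allele`` and (after reading or
    simulation) ``maf``.
    """

    calls: pd.DataFrame
    snp_annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.calls.index.duplicated().any():
            dups = self.calls.index[self.calls.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if self.calls.columns.duplicated().any():
            dups = self.calls.columns[self.calls.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate SNP IDs: {dups}")
        missing = [s for s in self.calls.columns if s not in self.snp_annotation.index]
        if missing:
            raise ValueError(f"SNPs without annotation: {missing}")
        # keep annotation in matrix column order
        self.snp_annotation = self.snp_annotation.loc[list(self.calls.columns)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.columns)

    def dosage(self, snp_id: str) -> pd.Series:
        """Additive risk-allele dosage for one SNP (float, NaN = missing)."""
        return encode_additive(self, snp_id)

    def dosage_frame(self, snp_ids=None) -> pd.DataFrame:
        """Dosages for several SNPs as a samples x SNPs float frame."""
        ids = list(snp_ids) if snp_ids is not None else self.snp_ids
        return pd.DataFrame({s: encode_additive(self, s) for s in ids})


@dataclass
class ExpressionMatrix:
    """Probes x samples expression values plus per-probe annotation.

    ``values`` is indexed by probe ID with one column per sample;
    ``probe_annotation`` is indexed by probe ID with columns ``gene``,
    ``chromosome``, ``start``. ``normalized`` records whether the rows have
    been z-scored (mean 0, population SD 1 per probe).
    """

    values: pd.DataFrame
    probe_annotation: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe IDs: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        missing = [p for p in self.values.index if p not in self.probe_annotation.index]
        if missing:
            raise ValueError(f"probes without annotation: {missing}")
        self.probe_annotation = self.probe_annotation.loc[list(self.values.index)]
        if self.normalized:
            mu = self.values.to_numpy().mean(axis=1)
            sd = self.values.to_numpy().std(axis=1)
            if not (np.all(np.abs(mu) < 1e-8) and np.all(np.abs(sd - 1) < 1e-8)):
                raise ValueError("normalized flag set but rows are not z-scored")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _allele_counts(calls: pd.Series) -> dict[str, int]:
    counts: dict[str, int] = {}
    for call in calls:
        if call == MISSING_CALL:
            continue
        for letter in call:
            counts[letter] = counts.get(letter, 0) + 1
    return counts


def compute_maf(calls: pd.Series) -> float:
    """Minor allele frequency from non-missing allele-pair calls (NaN if none)."""
    counts = _allele_counts(calls)
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    if len(counts) == 1:
        return 0.0
    return min(counts.values()) / total


def read_genotypes(genotype_path, annotation_path) -> GenotypeMatrix:
    """Read a genotype TSV and its SNP annotation TSV.

    Validates every call against the annotated allele pair, recomputes MAF
    from the non-missing calls into ``snp_annotation['maf']``, and flags
    SNPs whose MAF is undefined (all calls missing) in
    ``snp_annotation['maf_undefined']``.
    """
    calls = pd.read_csv(genotype_path, sep="\t", index_col=0, dtype=str)
    calls.index = calls.index.astype(str)
    calls.index.name = None
    calls.columns.name = None
    annot = pd.read_csv(annotation_path, sep="\t", dtype={"rsid": str})
    annot = annot.set_index("rsid")
    gm = GenotypeMatrix(calls=calls, snp_annotation=annot)

    mafs = []
    undefined = []
    for snp in gm.snp_ids:
        alleles = set(str(gm.snp_annotation.loc[snp, "alleles"]).split("/"))
        col = gm.calls[snp]
        for sample, call in col.items():
            if call == MISSING_CALL:
                continue
            if len(call) != 2 or not set(call) <= alleles:
                raise ValueError(
                    f"invalid call '{call}' for SNP {snp} (alleles "
                    f"{'/'.join(sorted(alleles))}) in sample {sample}"
                )
        maf = compute_maf(col)
        mafs.append(maf)
        undefined.append(not np.isfinite(maf))
    gm.snp_annotation["maf"] = mafs
    gm.snp_annotation["maf_undefined"] = undefined
    return gm


def write_genotypes(gm: GenotypeMatrix, genotype_path, annotation_path) -> None:
    gm.calls.to_csv(genotype_path, sep="\t", index_label="sample_id")
    annot = gm.snp_annotation.drop(columns=["maf_undefined"], errors="ignore")
    annot.to_csv(annotation_path, sep="\t", index_label="rsid",
                 float_format=_FLOAT_FMT)


def read_expression(expression_path, annotation_path,
                    normalized: bool = False) -> ExpressionMatrix:
    values = pd.read_csv(expression_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns.name = None
    annot = pd.read_csv(annotation_path, sep="\t", dtype={"probe_id": str})
    annot = annot.set_index("probe_id")
    return ExpressionMatrix(values=values, probe_annotation=annot,
                            normalized=normalized)


def write_expression(em: ExpressionMatrix, expression_path, annotation_path) -> None:
    em.values.to_csv(expression_path, sep="\t", index_label="probe_id",
                     float_format=_FLOAT_FMT)
    em.probe_annotation.to_csv(annotation_path, sep="\t",
                               index_label="probe_id", float_format=_FLOAT_FMT)


def encode_additive(genotypes: GenotypeMatrix, snp_id: str) -> pd.Series:
    """Additive coding: number of risk-allele copies (0/1/2, NaN = missing)."""
    if snp_id not in genotypes.snp_annotation.index:
        raise KeyError(f"unknown SNP {snp_id}")
    risk = genotypes.snp_annotation.loc[snp_id, "risk_allele"]
    if not isinstance(risk, str) or risk == "" or pd.isna(risk):
        raise ValueError(f"no risk allele annotated for SNP {snp_id}")
    calls = genotypes.calls[snp_id]
    out = pd.Series(
        [np.nan if c == MISSING_CALL else float(c.count(risk)) for c in calls],
        index=calls.index, dtype=float, name=snp_id,
    )
    return out


def _sort_key_column(df: pd.DataFrame) -> str | None:
    if "p" in df.columns:
        return "p"
    if "p_int" in df.columns:
        return "p_int"
    return None


def write_results(results: pd.DataFrame, path) -> None:
    """Write a result table with fixed column order and deterministic rows.

    Rows sort by ascending p (``p`` if present, else ``p_int``), ties broken
    by snp then probe lexicographically. Floats are written with enough
    digits to round-trip exactly.
    """
    if results is None:
        raise ValueError("results table is None")
    df = results.copy()
    ordered = [c for c in RESULT_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    df = df[ordered]
    if len(df):
        key = _sort_key_column(df)
        by = ([key] if key else []) + [c for c in ("snp", "probe") if c in df.columns]
        if by:
            df = df.sort_values(by=by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
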