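"""End-to-end pipeline: ingest -> sex inference -> filter/normalize ->
additive cis scan -> interaction scan -> reports.

Stage order is fixed (detection filtering before normalization before any
modeling) and every output is deterministic given the configured seed.
On a stage failure, partially written outputs are removed and a
:class:`PipelineError` naming the stage is raised.

Outputs written to the configured directory:

* ``cis_results.tsv`` — additive scan, one row per testable pair, BH FDR.
* ``interaction_results.tsv`` — interaction scan with permutation p/FDR.
* ``filter_report.tsv`` — detection cutoff and per-probe outcome.
* ``sex_report.tsv`` — both sex calls, F statistics, and reconciliation.
* ``run.log`` — parameter echo, library versions, per-stage counts
  (including probes analyzed per SNP).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from . import ciseqtl, exprfilter, genio, sexcheck, sexinteraction, synthdata


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one full analysis run (YAML-loadable)."""

    genotypes: str
    snp_annotation: str
    expression: str
    probe_annotation: str
    out_dir: str
    seed_snps: list[str] | None = None
    window: int = ciseqtl.WINDOW_BASES
    cis_fdr: float = ciseqtl.FDR_THRESHOLD
    interaction_alpha: float = sexinteraction.ALPHA
    n_perm: int = sexinteraction.N_PERM_DEFAULT
    min_genotype_count: int = ciseqtl.MIN_GENOTYPE_COUNT
    seed: int = 0

    def validate(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        for name in ("cis_fdr", "interaction_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"invalid run config in {path}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _check_sample_alignment(gm: genio.GenotypeMatrix,
                            em: genio.ExpressionMatrix) -> list[str]:
    g, e = set(gm.sample_ids), set(em.sample_ids)
    if g != e:
        only_g = sorted(g - e)
        only_e = sorted(e - g)
        raise ValueError(
            "genotype/expression sample-ID mismatch: "
            f"genotype-only={only_g}, expression-only={only_e}")
    return gm.sample_ids


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    log(f"sexqtl {__version__} (numpy {np.__version__}, "
        f"pandas {pd.__version__}, scipy {scipy.__version__})")
    log("parameters: " + ", ".join(
        f"{k}={v}" for k, v in vars(config).items()))

    stage = "ingest"
    try:
        gm = genio.read_genotypes(config.genotypes, config.snp_annotation)
        em = genio.read_expression(config.expression, config.probe_annotation)
        order = _check_sample_alignment(gm, em)
        em.values = em.values[order]
        log(f"ingest: {len(order)} samples, {len(gm.snp_ids)} SNPs, "
            f"{len(em.probe_ids)} probes")

        stage = "sex inference"
        from_x = sexcheck.impute_sex_from_x(gm)
        from_y = sexcheck.classify_sex_from_y(em)
        report = sexcheck.reconcile_sex(from_x, from_y)
        sex = sexcheck.sex_to_numeric(report)
        n_unresolved = int((report["final_sex"] == "unresolved").sum())
        log(f"sex inference: {int((sex == 0).sum())} male, "
            f"{int((sex == 1).sum())} female, {n_unresolved} unresolved "
            "(excluded)")
        sex_path = out / "sex_report.tsv"
        report.to_csv(sex_path, sep="\t", index_label="sample_id",
                      float_format="%.17g")
        written.append(sex_path)
        keep = list(sex.index)
        gm = genio.GenotypeMatrix(calls=gm.calls.loc[keep],
                                  snp_annotation=gm.snp_annotation)
        em = genio.ExpressionMatrix(values=em.values[keep],
                                    probe_annotation=em.probe_annotation)

        stage = "expression filtering"
        y_probes = sexcheck.y_probe_ids(em)
        cutoff_probe, cutoff = exprfilter.derive_expression_cutoff(
            em, y_probes, sex)
        cutoff_gene = str(em.probe_annotation.loc[cutoff_probe, "gene"])
        filtered, freport = exprfilter.filter_probes(
            em, cutoff, cutoff_gene=cutoff_gene, cutoff_probe=cutoff_probe)
        log(f"filtering: cutoff {cutoff:.4f} (probe {cutoff_probe}, gene "
            f"{cutoff_gene}); kept {freport.n_probes_kept}/"
            f"{freport.n_probes_in} probes")
        filt_path = out / "filter_report.tsv"
        freport.to_tsv(filt_path)
        written.append(filt_path)

        stage = "normalization"
        norm = exprfilter.zscore_normalize(filtered)

        stage = "cis scan"
        if config.seed_snps is not None:
            seeds = list(config.seed_snps)
        else:
            chroms = gm.snp_annotation["chromosome"].map(genio.norm_chrom)
            seeds = list(gm.snp_annotation.index[~chroms.str.upper()
                                                 .isin(["X", "Y", "23", "24"])])
        windows = ciseqtl.build_cis_windows(gm, seeds, norm.probe_annotation,
                                            window=config.window)
        cis = ciseqtl.run_cis_scan(gm, norm, windows, sex,
                                   min_genotype_count=config.min_genotype_count,
                                   fdr_threshold=config.cis_fdr)
        for snp, k in cis.attrs.get("probes_per_snp", {}).items():
            log(f"cis scan: {snp}: {k} probes in window")
        log(f"cis scan: {len(cis)} pairs tested, "
            f"{cis.attrs.get('n_untestable', 0)} untestable")
        cis_path = out / "cis_results.tsv"
        genio.write_results(cis, cis_path)
        written.append(cis_path)

        stage = "interaction scan"
        inter = sexinteraction.run_interaction_scan(
            gm, norm, windows, sex, n_perm=config.n_perm, seed=config.seed,
            min_genotype_count=config.min_genotype_count,
            alpha=config.interaction_alpha)
        log(f"interaction scan: {len(inter)} pairs tested, "
            f"{inter.attrs.get('n_untestable', 0)} untestable, "
            f"{config.n_perm} permutations")
        inter_path = out / "interaction_results.tsv"
        genio.write_results(inter, inter_path)
        written.append(inter_path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def make_fixture(synth_config, out_dir) -> dict[str, Path]:
    """Write a simulated cohort as the four pipeline input TSVs.

    ``synth_config`` may be a :class:`~sexqtl.synthdata.SynthConfig` or a
    path to its YAML form. Also writes ``truth.tsv`` (planted per-pair
    effects) and ``sex_truth.tsv`` (simulated sex). Identical configs,
    including the seed, produce byte-identical files.
    """
    if not isinstance(synth_config, synthdata.SynthConfig):
        synth_config = synthdata.SynthConfig.from_yaml(synth_config)
    synth_config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gm, em, sex = synthdata.simulate_cohort(synth_config)

    paths = {
        "genotypes": out / "genotypes.tsv",
        "snp_annotation": out / "snp_annotation.tsv",
        "expression": out / "expression.tsv",
        "probe_annotation": out / "probe_annotation.tsv",
        "truth": out / "truth.tsv",
        "sex_truth": out / "sex_truth.tsv",
    }
    genio.write_genotypes(gm, paths["genotypes"], paths["snp_annotation"])
    genio.write_expression(em, paths["expression"], paths["probe_annotation"])
    truth = pd.DataFrame(
        [(snp, probe, b[0], b[1], b[2])
         for (snp, probe), b in synth_config.effect_map.items()],
        columns=["snp", "probe", "beta_snp", "beta_sex", "beta_int"])
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.17g")
    sex.to_frame().to_csv(paths["sex_truth"], sep="\t",
                          index_label="sample_id")
    return paths
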