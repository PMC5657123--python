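"""Synthetic cohort generator for sex-aware cis-eQTL analysis.

Emulates the statistical structure of a genotyped microarray B-cell cohort:

* autosomal SNPs drawn under Hardy-Weinberg equilibrium at a stated MAF,
  allele-pair coded with the risk allele as the minor allele;
* X-chromosome SNPs that are HWE in females and hemizygous in males
  (the single male allele written as a homozygote, as genotyping arrays
  report it) — the signal the X-heterozygosity F statistic relies on;
* per-probe log2 expression following the linear interaction model
  ``expr = b0 + beta_snp*dosage + beta_sex*sex + beta_int*dosage*sex + noise``
  with effects expressed in expression-SD units so that planted
  coefficients are directly comparable to estimates on z-scored data;
* Y-chromosome marker probes expressed high in males and at background in
  females, separated by several noise SDs, which anchors both Y-based sex
  classification and the detection cutoff.

Defaults mirror the study conditions the analysis assumes: 125 males and
162 females, unit noise SD, and a handful of seed SNPs with coordinates
that make closed +/-1 Mb window tests possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genio import ExpressionMatrix, GenotypeMatrix

# sex coding used everywhere downstream: 0 = male, 1 = female
MALE, FEMALE = 0, 1

#: Y non-recombining-region gene symbols used to label synthetic Y probes
Y_MARKER_GENES = ["EIF1AY", "RPS4Y1", "DDX3Y", "KDM5D", "UTY", "USP9Y",
                  "NLGN4Y", "ZFY"]


@dataclass(frozen=True)
class SnpSpec:
    """One simulated SNP: coordinates, allele pair, and population MAF.

    ``risk_allele`` is the minor allele; ``other_allele`` the major one.
    """

    rsid: str
    chromosome: str
    position: int
    risk_allele: str
    other_allele: str
    maf: float


@dataclass(frozen=True)
class ProbeSpec:
    """One simulated expression probe with its gene label and start coordinate."""

    probe_id: str
    gene: str
    chromosome: str
    start: int


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Effects in ``effect_map`` are keyed by ``(rsid, probe_id)`` and give
    ``(beta_snp, beta_sex, beta_int)`` in expression-SD units. ``noise_sd``
    is the per-probe residual SD on the log2 scale. ``y_separation_sd``
    is the male-minus-female Y-probe mean difference in units of
    ``noise_sd`` (must exceed 4 for unambiguous Y-based sex calls).
    """

    n_male: int = 125
    n_female: int = 162
    snp_specs: list[SnpSpec] = field(default_factory=list)
    probe_specs: list[ProbeSpec] = field(default_factory=list)
    effect_map: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=dict)
    noise_sd: float = 1.0
    baseline: float = 8.0
    n_y_probes: int = 6
    n_x_snps: int = 1000
    y_background: float = 5.0
    y_separation_sd: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_male + self.n_female < 2:
            raise ValueError("need at least 2 samples")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.y_separation_sd <= 4:
            raise ValueError("y_separation_sd must exceed 4 noise SDs")
        for s in self.snp_specs:
            if not 0.0 <= s.maf <= 0.5:
                raise ValueError(f"MAF outside [0, 0.5] for {s.rsid}: {s.maf}")
            if s.risk_allele == s.other_allele:
                raise ValueError(f"identical alleles for {s.rsid}")
        snp_ids = {s.rsid for s in self.snp_specs}
        probe_ids = {p.probe_id for p in self.probe_specs}
        for snp, probe in self.effect_map:
            if snp not in snp_ids:
                raise ValueError(f"effect_map references unknown SNP {snp}")
            if probe not in probe_ids:
                raise ValueError(f"effect_map references unknown probe {probe}")

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        snps = [SnpSpec(rsid=str(s["rsid"]), chromosome=str(s["chromosome"]),
                        position=int(s["position"]),
                        risk_allele=str(s["risk_allele"]),
                        other_allele=str(s["other_allele"]), maf=float(s["maf"]))
                for s in d.get("snps", [])]
        probes = [ProbeSpec(probe_id=str(p["probe_id"]), gene=str(p["gene"]),
                            chromosome=str(p["chromosome"]), start=int(p["start"]))
                  for p in d.get("probes", [])]
        effects = {}
        for e in d.get("effects", []):
            effects[(str(e["snp"]), str(e["probe"]))] = (
                float(e.get("beta_snp", 0.0)),
                float(e.get("beta_sex", 0.0)),
                float(e.get("beta_int", 0.0)),
            )
        kwargs = {k: d[k] for k in
                  ("n_male", "n_female", "noise_sd", "baseline", "n_y_probes",
                   "n_x_snps", "y_background", "y_separation_sd", "seed")
                  if k in d}
        cfg = cls(snp_specs=snps, probe_specs=probes, effect_map=effects, **kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"invalid synthetic-cohort config in {path}")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {
            "n_male": self.n_male, "n_female": self.n_female,
            "noise_sd": self.noise_sd, "baseline": self.baseline,
            "n_y_probes": self.n_y_probes, "n_x_snps": self.n_x_snps,
            "y_background": self.y_background,
            "y_separation_sd": self.y_separation_sd, "seed": self.seed,
            "snps": [vars(s) | {} for s in self.snp_specs],
            "probes": [vars(p) | {} for p in self.probe_specs],
            "effects": [
                {"snp": k[0], "probe": k[1], "beta_snp": v[0],
                 "beta_sex": v[1], "beta_int": v[2]}
                for k, v in self.effect_map.items()
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_config(seed: int = 0) -> SynthConfig:
    """Study-scale default cohort: two seed SNPs, planted additive and
    interaction effects, plus null probes in and outside their windows."""
    snps = [
        SnpSpec("rs7574865", "2", 191_611_003, "T", "G", 0.22),
        SnpSpec("rs4637409", "4", 102_751_076, "A", "G", 0.33),
    ]
    probes = [
        # window of rs7574865 (chr2): planted additive eQTL + nulls
        ProbeSpec("ILMN_2000001", "INPP1", "2", 190_896_000),
        ProbeSpec("ILMN_2000002", "MYO1B", "2", 192_100_000),
        ProbeSpec("ILMN_2000003", "NULL2A", "2", 191_200_000),
        ProbeSpec("ILMN_2000004", "NULL2B", "2", 192_400_000),
        # window of rs4637409 (chr4): planted interaction + nulls
        ProbeSpec("ILMN_4000001", "SLC39A8", "4", 103_172_000),
        ProbeSpec("ILMN_4000002", "NULL4A", "4", 102_300_000),
        ProbeSpec("ILMN_4000003", "NULL4B", "4", 103_500_000),
        # outside any window
        ProbeSpec("ILMN_9000001", "FAR9A", "9", 10_000_000),
        ProbeSpec("ILMN_9000002", "FAR9B", "9", 50_000_000),
    ]
    effects = {
        ("rs7574865", "ILMN_2000001"): (0.40, 0.0, 0.0),
        ("rs4637409", "ILMN_4000001"): (0.10, 0.30, 0.66),
    }
    cfg = SynthConfig(snp_specs=snps, probe_specs=probes, effect_map=effects,
                      seed=seed)
    cfg.validate()
    return cfg


def sample_ids(config: SynthConfig) -> list[str]:
    n = config.n_male + config.n_female
    return [f"S{i + 1:04d}" for i in range(n)]


def sex_vector(config: SynthConfig) -> pd.Series:
    """True sex per sample (0 = male, 1 = female); males listed first."""
    sex = np.concatenate([
        np.zeros(config.n_male, dtype=int),
        np.ones(config.n_female, dtype=int),
    ])
    return pd.Series(sex, index=sample_ids(config), name="sex")


def _calls_from_dosage(dosage: np.ndarray, risk: str, other: str) -> np.ndarray:
    het = "".join(sorted((other, risk)))
    codes = np.array([other * 2, het, risk * 2])
    return codes[dosage]


def simulate_genotypes(config: SynthConfig,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw genotypes under HWE, plus an X-chromosome sex-marker block.

    Autosomal SNPs: risk(=minor)-allele dosage ~ Binomial(2, MAF) per sample.
    X SNPs: females Binomial(2, p); males carry a single allele written as a
    homozygote, so male X-heterozygosity is exactly zero.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sex = sex_vector(config).to_numpy()
    ids = sample_ids(config)
    n = len(ids)

    columns: dict[str, np.ndarray] = {}
    annot_rows = []
    for spec in config.snp_specs:
        if norm_upper(spec.chromosome) in ("X", "23"):
            dosage = _draw_x_dosage(rng, sex, spec.maf)
        else:
            dosage = rng.binomial(2, spec.maf, size=n)
        columns[spec.rsid] = _calls_from_dosage(dosage, spec.risk_allele,
                                                spec.other_allele)
        annot_rows.append((spec.rsid, spec.chromosome, spec.position,
                           "/".join(sorted((spec.other_allele, spec.risk_allele))),
                           spec.risk_allele, spec.maf))

    allele_pairs = [("A", "G"), ("C", "T")]
    for i in range(config.n_x_snps):
        rsid = f"rsX{i + 1:04d}"
        p = float(rng.uniform(0.15, 0.45))
        minor, major = allele_pairs[i % 2]
        dosage = _draw_x_dosage(rng, sex, p)
        columns[rsid] = _calls_from_dosage(dosage, minor, major)
        annot_rows.append((rsid, "X", 1_000_000 + i * 150_000,
                           "/".join(sorted((major, minor))), minor, p))

    calls = pd.DataFrame(columns, index=ids)
    annot = pd.DataFrame(
        annot_rows,
        columns=["rsid", "chromosome", "position", "alleles", "risk_allele",
                 "maf"],
    ).set_index("rsid")
    annot["chromosome"] = annot["chromosome"].astype(str)
    return GenotypeMatrix(calls=calls, snp_annotation=annot)


def _draw_x_dosage(rng: np.random.Generator, sex: np.ndarray,
                   p: float) -> np.ndarray:
    dosage = np.empty(sex.shape, dtype=int)
    male = sex == MALE
    dosage[male] = 2 * rng.binomial(1, p, size=male.sum())
    dosage[~male] = rng.binomial(2, p, size=(~male).sum())
    return dosage


def norm_upper(chrom) -> str:
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


def simulate_expression(genotypes: GenotypeMatrix, sex: pd.Series,
                        config: SynthConfig,
                        rng: np.random.Generator | None = None
                        ) -> ExpressionMatrix:
    """Simulate log2 expression from the linear interaction model.

    Autosomal probes: ``baseline + noise_sd*(b_snp*d + b_sex*s + b_int*d*s)
    + N(0, noise_sd^2)``. Y-marker probes: males at
    ``y_background + y_separation_sd*noise_sd``, females at ``y_background``,
    both with residual SD ``noise_sd``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if list(sex.index) != genotypes.sample_ids:
        raise ValueError("sex vector not aligned to genotype samples")
    s = sex.to_numpy().astype(float)
    n = len(s)
    sd = config.noise_sd

    effects_by_probe: dict[str, list[tuple[str, tuple[float, float, float]]]] = {}
    for (snp, probe), betas in config.effect_map.items():
        effects_by_probe.setdefault(probe, []).append((snp, betas))

    rows = {}
    annot_rows = []
    for spec in config.probe_specs:
        e = np.full(n, config.baseline, dtype=float)
        for snp, (b_snp, b_sex, b_int) in effects_by_probe.get(spec.probe_id, []):
            d = genotypes.dosage(snp).to_numpy()
            e += sd * (b_snp * d + b_sex * s + b_int * d * s)
        e += rng.normal(0.0, sd, size=n)
        rows[spec.probe_id] = e
        annot_rows.append((spec.probe_id, spec.gene, spec.chromosome, spec.start))

    high = config.y_background + config.y_separation_sd * sd
    for i in range(config.n_y_probes):
        probe_id = f"ILMN_Y{i + 1:05d}"
        mean = np.where(s == MALE, high, config.y_background)
        rows[probe_id] = mean + rng.normal(0.0, sd, size=n)
        annot_rows.append((probe_id, Y_MARKER_GENES[i % len(Y_MARKER_GENES)],
                           "Y", 2_700_000 + i * 100_000))

    values = pd.DataFrame(rows, index=genotypes.sample_ids).T
    annot = pd.DataFrame(
        annot_rows, columns=["probe_id", "gene", "chromosome", "start"],
    ).set_index("probe_id")
    annot["chromosome"] = annot["chromosome"].astype(str)
    return ExpressionMatrix(values=values, probe_annotation=annot,
                            normalized=False)


def simulate_cohort(config: SynthConfig
                    ) -> tuple[GenotypeMatrix, ExpressionMatrix, pd.Series]:
    """Genotypes, expression, and true sex for one seeded cohort."""
    genotypes = simulate_genotypes(config)
    sex = sex_vector(config)
    expression = simulate_expression(genotypes, sex, config)
    return genotypes, expression, sex


def simulate_proxy(genotypes: GenotypeMatrix, snp_id: str, proxy_id: str,
                   flip: bool = True) -> GenotypeMatrix:
    """Append a perfect-LD (r^2 = 1) proxy of ``snp_id``.

    With ``flip`` the proxy carries the allele labels swapped
    (dosage -> 2 - dosage), mimicking a proxy tagged by the opposite
    allele; r^2 is unaffected.
    """
    if proxy_id in genotypes.calls.columns:
        raise ValueError(f"proxy id {proxy_id} already present")
    row = genotypes.snp_annotation.loc[snp_id]
    alleles = str(row["alleles"]).split("/")
    risk = str(row["risk_allele"])
    other = alleles[0] if alleles[1] == risk else alleles[1]
    dosage = genotypes.dosage(snp_id).to_numpy()
    if flip:
        dosage = 2.0 - dosage
    calls = genotypes.calls.copy()
    coded = np.where(np.isfinite(dosage),
                     _calls_from_dosage(np.nan_to_num(dosage).astype(int),
                                        risk, other), "00")
    calls[proxy_id] = coded
    annot = genotypes.snp_annotation.copy()
    annot.loc[proxy_id] = row
    annot.loc[proxy_id, "position"] = int(row["position"]) + 1_000
    return GenotypeMatrix(calls=calls, snp_annotation=annot)
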