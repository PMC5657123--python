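"""Detection filtering and z-score normalization of log2 expression.

The detection threshold is anchored on Y-chromosome genes: in females, Y
non-recombining-region genes are not expressed, so their apparent signal
is pure array background. Among the Y probes with the highest
male-to-female mean expression ratio (top half by default), the probe with
the highest mean log2 value in females defines the expression cutoff.
Probes where at least ``max_below_frac`` (default 20%) of samples fall
below that cutoff are treated as undetected and removed, and the surviving
probes are z-scored per probe across all retained samples (both sexes
pooled) before any modeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import ExpressionMatrix

MAX_BELOW_FRAC = 0.20
TOP_RATIO_FRACTION = 0.5


@dataclass
class FilterReport:
    """Outcome of detection filtering.

    ``per_probe`` has one row per input probe with its fraction of samples
    below the cutoff and whether it was kept.
    """

    cutoff_gene: str
    cutoff_probe: str
    cutoff_value: float
    n_probes_in: int
    n_probes_kept: int
    n_probes_dropped: int
    per_probe: pd.DataFrame

    def to_tsv(self, path) -> None:
        df = self.per_probe.copy()
        df.insert(0, "cutoff_value", self.cutoff_value)
        df.insert(0, "cutoff_probe", self.cutoff_probe)
        df.insert(0, "cutoff_gene", self.cutoff_gene)
        df.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def derive_expression_cutoff(expression: ExpressionMatrix,
                             y_probes: list[str], sex: pd.Series,
                             top_ratio_fraction: float = TOP_RATIO_FRACTION
                             ) -> tuple[str, float]:
    """Choose the detection cutoff from Y-gene expression.

    Candidates are ranked by male-to-female mean expression ratio and the
    top ``top_ratio_fraction`` retained; among those the probe with the
    highest female mean log2 value is chosen and its female mean returned
    as the cutoff. Returns ``(probe_id, cutoff_value)``.
    """
    if not y_probes:
        raise ValueError("no candidate Y probes for cutoff derivation")
    sex = sex.reindex(expression.sample_ids)
    if sex.isna().any():
        raise ValueError("sex vector does not cover all expression samples")
    male = sex.to_numpy() == 0
    female = sex.to_numpy() == 1
    if not male.any() or not female.any():
        raise ValueError("both sexes required to derive the expression cutoff")

    vals = expression.values.loc[list(y_probes)].to_numpy(dtype=float)
    male_mean = vals[:, male].mean(axis=1)
    female_mean = vals[:, female].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(female_mean != 0, male_mean / female_mean, np.inf)

    # tie-inclusive "top fraction": keep ratios at or above the
    # lower-interpolated (1 - fraction) quantile, so a 2-candidate set at
    # the default 0.5 retains both
    threshold = np.quantile(ratio, 1.0 - top_ratio_fraction, method="lower")
    kept = np.flatnonzero(ratio >= threshold)
    best = kept[np.argmax(female_mean[kept])]
    return y_probes[int(best)], float(female_mean[best])


def filter_probes(expression: ExpressionMatrix, cutoff_value: float,
                  max_below_frac: float = MAX_BELOW_FRAC,
                  cutoff_gene: str = "", cutoff_probe: str = ""
                  ) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop probes with >= ``max_below_frac`` of samples below the cutoff.

    The boundary is inclusive: a probe with exactly 20% of samples below
    the cutoff is excluded. Input must be on the unnormalized log2 scale;
    retained probe order is preserved.
    """
    if not np.isfinite(cutoff_value):
        raise ValueError("cutoff_value must be finite")
    if expression.normalized:
        raise ValueError("filter_probes expects unnormalized log2 expression")
    vals = expression.values.to_numpy(dtype=float)
    frac_below = (vals < cutoff_value).mean(axis=1)
    keep = frac_below < max_below_frac

    per_probe = pd.DataFrame({
        "fraction_below": frac_below,
        "kept": keep,
    }, index=expression.values.index)
    filtered = ExpressionMatrix(
        values=expression.values.loc[keep].copy(),
        probe_annotation=expression.probe_annotation.loc[keep].copy(),
        normalized=False,
    )
    report = FilterReport(
        cutoff_gene=cutoff_gene, cutoff_probe=cutoff_probe,
        cutoff_value=float(cutoff_value),
        n_probes_in=len(keep), n_probes_kept=int(keep.sum()),
        n_probes_dropped=int((~keep).sum()), per_probe=per_probe,
    )
    return filtered, report


def zscore_normalize(expression: ExpressionMatrix) -> ExpressionMatrix:
    """Per-probe z-scores across samples (population SD, divisor n).

    Idempotent to numerical tolerance; raises on any zero-variance probe —
    such probes must be filtered out first.
    """
    vals = expression.values.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [expression.probe_ids[i] for i in zero[:5]]
        raise ValueError(f"zero-variance probe(s) cannot be z-scored: {names}")
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(
        values=pd.DataFrame(z, index=expression.values.index,
                            columns=expression.values.columns),
        probe_annotation=expression.probe_annotation.copy(),
        normalized=True,
    )
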