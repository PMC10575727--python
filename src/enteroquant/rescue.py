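"""Rescue-gene filtering of differential-expression contrasts and qPCR.

Given per-gene differential-expression (DE) results for a disease
baseline contrast (disease vs healthy) and a treatment contrast
(disease+drug vs disease), a *rescue gene* is one that is significantly
altered at baseline and significantly shifted in the **opposite**
direction by the drug — e.g. downregulated in disease, upregulated by
treatment. The filter consumes standard DE tables (gene, log2 fold
change, FDR-adjusted p, base mean); fitting the DE model itself is the
job of an established engine upstream.

Also implements relative qPCR quantification by the 2^−ΔΔCt method
against a housekeeping gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DeContrastTable",
    "RescueGeneSet",
    "QpcrPlate",
    "opposite_direction_filter",
    "prioritize",
    "delta_delta_ct",
]

DE_COLUMNS = ["gene", "log2fc", "padj", "basemean"]


@dataclass
class DeContrastTable:
    """Per-gene DE results for one named contrast.

    ``table`` must have columns gene, log2fc, padj, basemean with unique
    gene ids, padj in [0, 1] and basemean ≥ 0.
    """

    name: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"DE table {self.name!r} missing columns {missing}")
        t = self.table
        if t["gene"].duplicated().any():
            raise ValueError(f"duplicate gene ids in contrast {self.name!r}")
        padj = t["padj"].dropna()
        if ((padj < 0) | (padj > 1)).any():
            raise ValueError("padj values must lie in [0, 1]")
        if (t["basemean"].dropna() < 0).any():
            raise ValueError("basemean must be non-negative")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RescueGeneSet:
    """Genes passing the opposite-direction filter, with both contrasts' stats.

    ``table`` columns: gene, baseline_log2fc, baseline_padj,
    treatment_log2fc, treatment_padj, basemean, direction — where
    direction is ``"down_up"`` (down in disease, up with drug) or
    ``"up_down"``.
    """

    table: pd.DataFrame
    fdr_cutoff: float
    baseline_contrast: str = ""
    treatment_contrast: str = ""
    thresholds: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


@dataclass
class QpcrPlate:
    """Long-format qPCR quantification cycles.

    ``table`` columns: sample, gene, cq — one row per replicate well.
    """

    table: pd.DataFrame
    housekeeping: str = "GAPDH"

    def __post_init__(self) -> None:
        missing = [c for c in ("sample", "gene", "cq") if c not in self.table.columns]
        if missing:
            raise ValueError(f"qPCR table missing columns {missing}")
        if (self.table["cq"] <= 0).any():
            raise ValueError("Cq values must be positive")


def opposite_direction_filter(
    baseline: DeContrastTable,
    treatment: DeContrastTable,
    fdr_cutoff: float = 0.05,
) -> RescueGeneSet:
    """Select genes significantly reversed by treatment.

    A gene passes when its FDR-adjusted p is below ``fdr_cutoff`` in
    *both* contrasts and its log2 fold changes have strictly opposite
    signs (a zero fold change in either contrast excludes the gene, as
    does absence from either table or a missing padj).
    """
    if len(baseline) == 0 or len(treatment) == 0:
        raise ValueError("empty DE table(s)")
    merged = baseline.table.merge(
        treatment.table, on="gene", suffixes=("_base", "_treat"), how="inner"
    )
    if merged.empty:
        raise ValueError("the two contrasts share no gene ids")
    sig = (merged["padj_base"] < fdr_cutoff) & (merged["padj_treat"] < fdr_cutoff)
    opposite = merged["log2fc_base"] * merged["log2fc_treat"] < 0
    hits = merged[sig.fillna(False) & opposite.fillna(False)].copy()
    out = pd.DataFrame(
        {
            "gene": hits["gene"],
            "baseline_log2fc": hits["log2fc_base"],
            "baseline_padj": hits["padj_base"],
            "treatment_log2fc": hits["log2fc_treat"],
            "treatment_padj": hits["padj_treat"],
            "basemean": hits["basemean_treat"],
            "direction": np.where(
                hits["log2fc_base"] < 0, "down_up", "up_down"
            ),
        }
    ).reset_index(drop=True)
    return RescueGeneSet(
        table=out,
        fdr_cutoff=fdr_cutoff,
        baseline_contrast=baseline.name,
        treatment_contrast=treatment.name,
    )


def prioritize(
    filtered: RescueGeneSet,
    min_abs_log2fc: float = 1.0,
    max_fdr: float = 0.05,
    min_basemean: float = 10.0,
) -> RescueGeneSet:
    """Threshold and rank rescue genes.

    Thresholds apply to the treatment contrast (|log2FC| and FDR) and to
    the base mean expression; survivors are ranked by descending
    |treatment log2FC|, ties broken by ascending treatment FDR, then
    gene id.
    """
    for name, v in (("min_abs_log2fc", min_abs_log2fc), ("max_fdr", max_fdr),
                    ("min_basemean", min_basemean)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    t = filtered.table
    keep = (
        (t["treatment_log2fc"].abs() >= min_abs_log2fc)
        & (t["treatment_padj"] < max_fdr)
        & (t["basemean"] >= min_basemean)
    )
    ranked = t[keep].copy()
    ranked["_abs"] = ranked["treatment_log2fc"].abs()
    ranked = ranked.sort_values(
        ["_abs", "treatment_padj", "gene"], ascending=[False, True, True]
    ).drop(columns="_abs").reset_index(drop=True)
    return RescueGeneSet(
        table=ranked,
        fdr_cutoff=filtered.fdr_cutoff,
        baseline_contrast=filtered.baseline_contrast,
        treatment_contrast=filtered.treatment_contrast,
        thresholds={
            "min_abs_log2fc": min_abs_log2fc,
            "max_fdr": max_fdr,
            "min_basemean": min_basemean,
        },
    )


def delta_delta_ct(plate: QpcrPlate, reference_sample: str) -> pd.DataFrame:
    """Relative expression by the 2^−ΔΔCt method.

    Per sample and target gene: ΔCt = mean target Cq − mean housekeeping
    Cq; ΔΔCt = ΔCt(sample) − ΔCt(reference); fold change = 2^−ΔΔCt.
    Returns a tidy frame with columns sample, gene, delta_ct,
    delta_delta_ct, fold_change (housekeeping gene excluded).
    """
    t = plate.table
    samples = t["sample"].unique()
    if reference_sample not in samples:
        raise ValueError(f"reference sample {reference_sample!r} not in plate")
    hk = t[t["gene"] == plate.housekeeping].groupby("sample")["cq"].mean()
    missing_hk = [s for s in samples if s not in hk.index]
    if missing_hk:
        raise ValueError(
            f"housekeeping gene {plate.housekeeping!r} missing for samples {missing_hk}"
        )
    targets = t[t["gene"] != plate.housekeeping]
    mean_cq = targets.groupby(["sample", "gene"])["cq"].mean().reset_index()
    mean_cq["delta_ct"] = mean_cq["cq"] - mean_cq["sample"].map(hk)
    ref = mean_cq[mean_cq["sample"] == reference_sample].set_index("gene")["delta_ct"]
    mean_cq["delta_delta_ct"] = mean_cq["delta_ct"] - mean_cq["gene"].map(ref)
    mean_cq["fold_change"] = 2.0 ** (-mean_cq["delta_delta_ct"])
    return mean_cq[["sample", "gene", "delta_ct", "delta_delta_ct", "fold_change"]]
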