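"""Weighted LDL-c gene score (wGS) computation.

wGS of a sample over a panel P is the burden sum Σ_{i∈P} c_i·β_i, where c_i
is the effect-allele dosage and β_i the signed per-allele weight in mmol/L.
Two conventions for APOE are supported:

* ``two-snp-additive`` (default) — rs429358 and rs7412 enter the sum like
  any other SNP with their own signed betas;
* ``diplotype-table`` — the rs429358/rs7412 pair is replaced by a single
  configured contribution for the inferred ε-diplotype (E2/E2 … E4/E4).

Missing-data policy: ``exclude-sample`` (default) flags a sample with any
missing panel dosage as incomplete and leaves its score undefined;
``renormalize`` rescales the partial sum by panel size / SNPs used.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    APOE_RSIDS,
    ConfigError,
    GenotypeMatrix,
    ScorePanel,
    ScoreResult,
    WeightTable,
)

MISSING_POLICIES = ("exclude-sample", "renormalize")


def apoe_diplotype(rs429358_dosage: float, rs7412_dosage: float) -> str:
    """Map the two-site APOE genotype to an ε-diplotype.

    ``rs429358_dosage`` counts the ε4-defining C allele and
    ``rs7412_dosage`` the ε2-defining T allele.  Haplotypes carrying both
    defining alleles (ε1) are assumed absent: the double heterozygote is
    phased as E2/E4, and genotype pairs only explicable by an ε1 haplotype
    return ``indeterminate``, as does a missing dosage at either site.
    """
    if math.isnan(rs429358_dosage) or math.isnan(rs7412_dosage):
        return "indeterminate"
    d4, d2 = int(rs429358_dosage), int(rs7412_dosage)
    if d4 not in (0, 1, 2) or d2 not in (0, 1, 2):
        raise ConfigError(f"dosages must be 0/1/2, got ({rs429358_dosage}, {rs7412_dosage})")
    table = {
        (0, 0): "E3/E3",
        (1, 0): "E3/E4",
        (2, 0): "E4/E4",
        (0, 1): "E2/E3",
        (0, 2): "E2/E2",
        (1, 1): "E2/E4",
    }
    return table.get((d4, d2), "indeterminate")


def _check_panel(genotypes: GenotypeMatrix, weights: WeightTable, panel: ScorePanel) -> None:
    for rsid in panel.members:
        if rsid not in weights:
            raise ConfigError(f"panel {panel.name}: {rsid} absent from weight table")
        if rsid not in genotypes.rsids:
            raise ConfigError(f"panel {panel.name}: {rsid} absent from genotype matrix")
    if panel.apoe_mode == "diplotype-table":
        if weights.apoe_diplotype_weights is None:
            raise ConfigError(
                "diplotype-table mode requires apoe_diplotype_weights in the weight table"
            )
        if not all(r in panel.members for r in APOE_RSIDS):
            raise ConfigError(
                f"panel {panel.name}: diplotype-table mode needs both APOE SNPs"
            )


def compute_wgs(
    genotypes: GenotypeMatrix,
    weights: WeightTable,
    panel: ScorePanel,
    missing_policy: str = "exclude-sample",
) -> list[ScoreResult]:
    """Compute per-sample weighted gene scores for one panel."""
    if missing_policy not in MISSING_POLICIES:
        raise ConfigError(f"unknown missing policy {missing_policy!r}")
    _check_panel(genotypes, weights, panel)

    if panel.apoe_mode == "two-snp-additive":
        additive = list(panel.members)
    else:
        additive = [r for r in panel.members if r not in APOE_RSIDS]

    dosage = np.column_stack([genotypes.column(r) for r in additive]) \
        if additive else np.empty((genotypes.n_samples, 0))
    betas = weights.betas(additive)
    observed = np.isfinite(dosage)
    partial = np.where(observed, dosage, 0.0) @ betas
    n_used = observed.sum(axis=1)

    apoe_contrib = np.zeros(genotypes.n_samples)
    apoe_used = np.zeros(genotypes.n_samples, dtype=int)
    if panel.apoe_mode == "diplotype-table":
        d4 = genotypes.column(APOE_RSIDS[0])
        d2 = genotypes.column(APOE_RSIDS[1])
        dip_w = weights.apoe_diplotype_weights
        for i in range(genotypes.n_samples):
            dip = apoe_diplotype(d4[i], d2[i])
            if dip == "indeterminate":
                continue  # both APOE sites counted as missing for this sample
            apoe_contrib[i] = dip_w[dip]
            apoe_used[i] = 2

    total_used = n_used + apoe_used
    raw = partial + apoe_contrib
    size = panel.size
    results = []
    for i, sid in enumerate(genotypes.sample_ids):
        used = int(total_used[i])
        complete = used == size
        if complete:
            wgs = float(raw[i])
        elif missing_policy == "exclude-sample":
            wgs = math.nan
        else:  # renormalize
            wgs = float(raw[i] * size / used) if used > 0 else math.nan
        results.append(
            ScoreResult(sample_id=sid, panel_name=panel.name, wgs=wgs,
                        n_snps_used=used, complete=complete)
        )
    return results


def score_bounds(weights: WeightTable, panel: ScorePanel) -> tuple[float, float]:
    """Analytic [min, max] of the wGS over a panel (two-SNP-additive mode)."""
    betas = weights.betas(panel.members)
    return float(np.minimum(0.0, 2 * betas).sum()), float(np.maximum(0.0, 2 * betas).sum())


def score_difference(
    panel_a: ScorePanel,
    panel_b: ScorePanel,
    scores_a: Sequence[ScoreResult],
    scores_b: Sequence[ScoreResult],
) -> pd.Series:
    """Per-sample wGS(panel_a) − wGS(panel_b) for nested panels.

    Requires panel_b ⊆ panel_a and matching APOE modes; only samples
    complete under both panels are returned.  By linearity the result
    equals the score over the set-difference SNPs.
    """
    if not set(panel_b.members) <= set(panel_a.members):
        raise ConfigError(
            f"panel {panel_b.name} is not nested in {panel_a.name}"
        )
    if panel_a.apoe_mode != panel_b.apoe_mode:
        raise ConfigError("panels differ in APOE mode")
    a = {r.sample_id: r for r in scores_a if r.complete}
    b = {r.sample_id: r for r in scores_b if r.complete}
    common = [sid for sid in a if sid in b]
    return pd.Series(
        {sid: a[sid].wgs - b[sid].wgs for sid in common}, name="score_difference"
    )
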