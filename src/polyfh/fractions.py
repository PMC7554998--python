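"""Combined monogenic + polygenic genetic-assignment estimation, and the
end-to-end simulated pipeline.

The headline estimator: if M% of clinically diagnosed FH patients carry a
monogenic mutation and r% of the mutation-negative remainder sit above the
polygenic cutoff, then

    combined% = M + (100 − M) · r / 100

patients have an identifiable genetic (monogenic or polygenic) cause.
Percentages are carried at full precision and rounded only for reporting.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify, defaults, stats
from .io import write_report
from .model import (
    CohortTable,
    ConfigError,
    FractionEstimate,
    GenotypeMatrix,
    InsufficientDataError,
    ParameterError,
    ScorePanel,
    WeightTable,
    scores_to_frame,
    standard_panel,
)
from .score import compute_wgs
from .simulate import SimulationConfig, StudyData, simulate_study

STRATA = ("all", "definite", "probable", "probable+definite")


def monogenic_pct(cohort: CohortTable, stratum: str = "all") -> float:
    """Percentage of FH patients in a DLCN stratum carrying a monogenic mutation.

    EUR controls are never part of the denominator.
    """
    mask = cohort.stratum_mask(stratum)
    total = int(mask.sum())
    if total == 0:
        raise InsufficientDataError(f"stratum {stratum!r} is empty")
    positives = int((cohort.df.loc[mask, "group"] == "FH_Mpos").sum())
    return 100.0 * positives / total


def combined_assignment(m: float, r: float) -> float:
    """Combined genetic-assignment percentage M + (100 − M)·r/100."""
    if not (0.0 <= m <= 100.0) or not (0.0 <= r <= 100.0):
        raise ParameterError(f"percentages must lie in [0, 100], got M={m}, r={r}")
    return m + (100.0 - m) * r / 100.0


def estimate_fractions(
    cohort: CohortTable,
    mneg_scores: Mapping[str, float],
    threshold: float,
    strata: Sequence[str] = STRATA,
    strict: bool = True,
) -> list[FractionEstimate]:
    """Per-stratum combined estimates.

    ``mneg_scores`` maps mutation-negative sample ids to their wGS; samples
    with a missing score are excluded from the polygenic-rate denominator.
    """
    estimates = []
    df = cohort.df
    for stratum in strata:
        mask = cohort.stratum_mask(stratum)
        m = monogenic_pct(cohort, stratum)
        ids = df.loc[mask & (df["group"] == "FH_Mneg").to_numpy(), "sample_id"]
        vals = np.array([mneg_scores[s] for s in ids if s in mneg_scores])
        _, prop = classify.proportion_above(vals, threshold, strict)
        r = 100.0 * prop
        estimates.append(
            FractionEstimate(
                stratum=stratum,
                monogenic_pct=m,
                polygenic_rate=r,
                combined_pct=combined_assignment(m, r),
            )
        )
    return estimates


# ---------------------------------------------------------------------------
# pipeline


def _config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _round(x: float | None, nd: int = 6) -> float | None:
    return None if x is None else round(float(x), nd)


def run_pipeline(
    config: SimulationConfig | None = None,
    weights: WeightTable | None = None,
    out_dir: str | os.PathLike | None = None,
    refine: bool = True,
    missing_policy: str = "exclude-sample",
    cutoffs: Sequence[str] = ("p75", "p90", "p95", "youden"),
    study: StudyData | None = None,
) -> dict[str, Any]:
    """Run the full analysis on a simulated (or supplied) study.

    Stages: simulate → score (wGS11/wGS8/wGS6) → HWE + per-SNP association →
    stepwise refinement → group comparisons → cutoffs → fraction estimates →
    report.  Deterministic for a fixed config: two runs write byte-identical
    reports.
    """
    config = config or SimulationConfig.default()
    weights = weights or defaults.default_weights()
    if study is None:
        study = simulate_study(config, weights)
    genotypes, cohort = study.genotypes, study.cohort
    df = cohort.df

    panels = {name: standard_panel(name) for name in ("wGS11", "wGS8", "wGS6")}
    score_frames: dict[str, pd.DataFrame] = {}
    for name, panel in panels.items():
        score_frames[name] = scores_to_frame(
            compute_wgs(genotypes, weights, panel, missing_policy)
        )

    group_of = dict(zip(df["sample_id"], df["group"]))
    gene_of = dict(zip(df["sample_id"], df["mutation_gene"]))

    def scores_by_group(frame: pd.DataFrame) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {}
        for sid, wgs in zip(frame["sample_id"], frame["wgs"]):
            out.setdefault(group_of[sid], []).append(wgs)
            if gene_of[sid] in ("LDLR", "APOB"):
                out.setdefault(f"FH_Mpos-{gene_of[sid]}", []).append(wgs)
        return {g: np.asarray(v) for g, v in out.items()}

    # HWE per SNP per group
    hwe_section: dict[str, Any] = {}
    for group in ("EUR", "FH_Mneg", "FH_Mpos"):
        members = [s for s in df.loc[df["group"] == group, "sample_id"]]
        if not members:
            continue
        mask = df["group"].to_numpy() == group
        sub = genotypes.subset_samples(mask)
        hwe_section[group] = {}
        for rsid in genotypes.rsids:
            res = stats.hwe_test(sub.genotype_counts(rsid), rsid=rsid, group=group)
            hwe_section[group][rsid] = {
                "chi2": _round(res.chi2),
                "p_value": _round(res.p_value),
                "counts": list(res.genotype_counts),
                "method": res.method,
            }

    # per-SNP allele-frequency tests, EUR vs FH_Mneg
    eur_mask = df["group"].to_numpy() == "EUR"
    mneg_mask = df["group"].to_numpy() == "FH_Mneg"
    freq_tests: dict[str, Any] = {}
    for rsid in genotypes.rsids:
        col = genotypes.column(rsid)
        res = stats.allele_freq_test(
            stats.allele_counts(col[mneg_mask]), stats.allele_counts(col[eur_mask])
        )
        freq_tests[rsid] = {
            "chi2": _round(res.chi2),
            "p_value": _round(res.p_value),
            "method": res.method,
        }

    association: dict[str, Any] = {"per_snp": freq_tests}
    refined_panel = panels["wGS8"]
    if refine:
        cc_mask = eur_mask | mneg_mask
        labels = mneg_mask[cc_mask].astype(int)
        sub = genotypes.subset_samples(cc_mask)
        sw = stats.stepwise_logistic(sub, labels)
        association["stepwise"] = {
            "criterion": sw.criterion,
            "separation": sw.separation,
            "selected": [
                {
                    "rsid": r.rsid,
                    "odds_ratio": _round(r.odds_ratio),
                    "ci95": [_round(r.ci95[0]), _round(r.ci95[1])],
                    "p_value": _round(r.p_value),
                    "note": r.note,
                }
                for r in sw.selected
            ],
        }

    # group score comparisons, Table-3 style layout
    table3_pairs = [
        ("FH_Mneg", "FH_Mpos"),
        ("FH_Mneg", "FH_Mpos-LDLR"),
        ("FH_Mneg", "FH_Mpos-APOB"),
        ("FH_Mneg", "EUR"),
        ("FH_Mpos", "EUR"),
        ("FH_Mpos-LDLR", "FH_Mpos-APOB"),
        ("FH_Mpos-LDLR", "EUR"),
        ("FH_Mpos-APOB", "EUR"),
    ]
    comparison: dict[str, Any] = {}
    for name, frame in score_frames.items():
        by_group = scores_by_group(frame)
        pairs = [(a, b) for a, b in table3_pairs if a in by_group and b in by_group]
        rep = stats.group_compare(by_group, pairs=pairs)
        comparison[name] = {
            "groups": ["FH_Mneg", "FH_Mpos", "FH_Mpos-LDLR", "FH_Mpos-APOB", "EUR"],
            "moments": {
                g: {k: v if k in ("n", "normal") else _round(v)
                    for k, v in m.items()}
                for g, m in rep.moments.items()
            },
            "omnibus": {"test": rep.omnibus_test, "p_value": _round(rep.omnibus_p)},
            "pairwise": {
                f"{t.group_a}|{t.group_b}": {
                    "test": t.test,
                    "p_value": _round(t.p_value),
                }
                for t in rep.pairwise
            },
        }

    # cutoffs
    suite_scores = {
        name: {
            g: v
            for g, v in scores_by_group(frame).items()
            if g in ("EUR", "FH_Mneg", "FH_Mpos")
        }
        for name, frame in score_frames.items()
    }
    reports = classify.panel_cutoff_suite(suite_scores, cutoffs=cutoffs)
    cutoff_section = {
        f"{r.panel_name}|{r.cutoff_type}": {
            "threshold": _round(r.threshold),
            "sens": _round(r.sens),
            "spec": _round(r.spec),
            "youden_j": _round(r.youden_j),
            "n_above": r.n_above,
            "n_total": r.n_total,
            "proportion_above": {g: _round(p) for g, p in r.proportion_above.items()},
        }
        for r in reports
    }

    # fraction estimates from the wGS8 top-quartile rule
    wgs8 = score_frames[refined_panel.name]
    mneg_scores = {
        sid: w
        for sid, w in zip(wgs8["sample_id"], wgs8["wgs"])
        if group_of[sid] == "FH_Mneg"
    }
    p75 = classify.percentile_cutoff(
        [w for sid, w in zip(wgs8["sample_id"], wgs8["wgs"]) if group_of[sid] == "EUR"],
        75.0,
    )
    estimates = estimate_fractions(cohort, mneg_scores, p75)
    fractions_section = {
        "rule": {"panel": refined_panel.name, "cutoff": "p75", "threshold": _round(p75)},
        "denominator_note": "mutation-negative patients with missing scores excluded",
        "estimates": [
            {
                "stratum": e.stratum,
                "monogenic_pct": round(e.monogenic_pct, 1),
                "polygenic_rate": round(e.polygenic_rate, 1),
                "combined_pct": round(e.combined_pct, 1),
            }
            for e in estimates
        ],
    }

    results = {
        "meta": {
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "mode": config.mode,
            "missing_policy": missing_policy,
            "n_per_group": config.n_per_group,
        },
        "panels": {
            name: {"members": list(p.members), "apoe_mode": p.apoe_mode}
            for name, p in panels.items()
        },
        "scores": {
            name: {
                "n_complete": int(frame["complete"].sum()),
                "n_total": int(len(frame)),
            }
            for name, frame in score_frames.items()
        },
        "hwe": hwe_section,
        "association": association,
        "group_comparison": comparison,
        "cutoffs": cutoff_section,
        "fractions": fractions_section,
    }
    if out_dir is not None:
        write_report(results, out_dir)
    return results
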