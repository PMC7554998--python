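"""Synthetic cohort generator.

Generates the three study groups the analysis assumes:

* ``EUR`` — population controls in Hardy-Weinberg equilibrium (HWE) at
  configured effect-allele frequencies;
* ``FH_Mneg`` — clinically diagnosed FH patients without a monogenic
  mutation, enriched for LDL-c-raising alleles either directly
  (``frequency-shift`` mode: HWE draws at shifted group frequencies) or
  endogenously (``liability-threshold`` mode: draws at control frequencies
  followed by selection of the upper tail of a latent LDL-c liability);
* ``FH_Mpos`` — monogenic carriers with an LDLR/APOB mutation label and a
  milder polygenic enrichment.

DLCN clinical components are drawn independently per component from the
configured group margins (no dependence structure — a documented
simplification), and the DLCN point total is drawn within the band of a
diagnostic class sampled from the configured class proportions, so score
and class are consistent by construction.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import defaults
from .io import write_cohort_tsv, write_genotypes_tsv
from .model import (
    CohortTable,
    ConfigError,
    DLCN_COMPONENTS,
    GenotypeMatrix,
    ParameterError,
    WeightTable,
)

_CLASS_SCORE_BANDS = {"<3": (0, 2), "possible": (3, 5), "probable": (6, 8),
                      "definite": (9, 14)}


@dataclass
class SimulationConfig:
    """Full parameterisation of the synthetic study."""

    n_per_group: dict[str, int]
    freq_table: dict[str, dict[str, float]]
    mode: str = "frequency-shift"
    liability: dict[str, Any] = field(default_factory=dict)
    monogenic_split: dict[str, float] = field(default_factory=lambda: {"LDLR": 0.924, "APOB": 0.076})
    dlcn_margins: dict[str, dict[str, float]] = field(default_factory=dict)
    ldl_category_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    dlcn_class_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    age: dict[str, dict[str, float]] = field(default_factory=dict)
    sex_male_prob: dict[str, float] = field(default_factory=dict)
    missing_rate: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("frequency-shift", "liability-threshold"):
            raise ConfigError(f"unknown simulation mode {self.mode!r}")
        for g, n in self.n_per_group.items():
            if n < 0:
                raise ConfigError(f"negative group size for {g}")
        for g, freqs in self.freq_table.items():
            for rsid, p in freqs.items():
                if not (0.0 < p < 1.0):
                    raise ParameterError(
                        f"frequency for {rsid} in {g} must lie in (0,1), got {p}"
                    )
        split_total = sum(self.monogenic_split.values())
        if abs(split_total - 1.0) > 1e-9:
            raise ConfigError(f"monogenic split sums to {split_total}, not 1")

    @classmethod
    def default(cls, seed: int | None = None) -> "SimulationConfig":
        cfg = cls.from_dict(defaults.default_sim_dict())
        if seed is not None:
            cfg.seed = seed
        return cfg

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "SimulationConfig":
        doc = {k: v for k, v in doc.items() if k != "description"}
        return cls(**doc)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_per_group": self.n_per_group,
            "freq_table": self.freq_table,
            "mode": self.mode,
            "liability": self.liability,
            "monogenic_split": self.monogenic_split,
            "dlcn_margins": self.dlcn_margins,
            "ldl_category_probs": self.ldl_category_probs,
            "dlcn_class_probs": self.dlcn_class_probs,
            "age": self.age,
            "sex_male_prob": self.sex_male_prob,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes_hwe(
    n: int,
    freqs: Mapping[str, float],
    seed: int | np.random.Generator,
    sample_prefix: str = "S",
) -> GenotypeMatrix:
    """Draw ``n`` samples in HWE: dosage ~ Binomial(2, p) independently per SNP."""
    if n < 0:
        raise ParameterError(f"n must be >= 0, got {n}")
    for rsid, p in freqs.items():
        if not (0.0 < p < 1.0):
            raise ParameterError(f"frequency for {rsid} must lie in (0,1), got {p}")
    rng = _as_rng(seed)
    rsids = list(freqs)
    dosage = np.column_stack(
        [rng.binomial(2, freqs[r], size=n).astype(float) for r in rsids]
    ) if n else np.empty((0, len(rsids)))
    ids = [f"{sample_prefix}{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(ids, rsids, dosage)


def _inject_missing(dosage: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return dosage
    mask = rng.random(dosage.shape) < rate
    out = dosage.copy()
    out[mask] = math.nan
    return out


def _draw_categorical(rng, probs: Mapping[str, float], n: int) -> np.ndarray:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(keys, dtype=object), size=n, p=p)


def _liability_select(
    n: int,
    freqs: Mapping[str, float],
    weights: WeightTable,
    residual_sd: float,
    quantile: float,
    rng: np.random.Generator,
    sample_prefix: str,
) -> GenotypeMatrix:
    """Draw at control frequencies, keep the top ``quantile`` tail of a latent
    LDL-c liability = Σ c_i β_i + Normal(0, residual_sd)."""
    if not (0.0 < quantile <= 1.0):
        raise ConfigError(f"selection quantile must lie in (0, 1], got {quantile}")
    pool_n = max(n, int(math.ceil(n / quantile)))
    pool = simulate_genotypes_hwe(pool_n, freqs, rng, sample_prefix="tmp")
    betas = weights.betas(pool.rsids)
    latent = pool.dosage @ betas + rng.normal(0.0, residual_sd, size=pool_n)
    keep = np.argsort(latent)[-n:] if n else np.array([], dtype=int)
    keep.sort()
    ids = [f"{sample_prefix}{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(ids, pool.rsids, pool.dosage[keep])


def simulate_case_group(
    n: int,
    config: SimulationConfig,
    group: str,
    weights: WeightTable,
    seed: int | np.random.Generator,
    sample_prefix: str | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate one FH patient group: genotypes plus cohort metadata rows."""
    if group not in ("FH_Mneg", "FH_Mpos"):
        raise ConfigError(f"case group must be FH_Mneg or FH_Mpos, got {group!r}")
    rng = _as_rng(seed)
    prefix = sample_prefix or ("MNEG" if group == "FH_Mneg" else "MPOS")

    if config.mode == "frequency-shift":
        genotypes = simulate_genotypes_hwe(
            n, config.freq_table[group], rng, sample_prefix=prefix
        )
    else:
        lia = config.liability
        if weights is None:
            raise ConfigError("liability-threshold mode requires a weight table")
        residual_sd = lia.get("residual_sd")
        if residual_sd is None:
            raise ConfigError("liability-threshold mode requires residual_sd")
        quantile = lia.get("selection_quantile", {}).get(group)
        if quantile is None:
            raise ConfigError(f"no selection quantile configured for {group}")
        genotypes = _liability_select(
            n, config.freq_table["EUR"], weights, residual_sd, quantile, rng, prefix
        )

    rate = config.missing_rate.get(group, 0.0)
    genotypes = GenotypeMatrix(
        genotypes.sample_ids, genotypes.rsids,
        _inject_missing(genotypes.dosage, rate, rng),
    )

    rows: dict[str, Any] = {"sample_id": list(genotypes.sample_ids), "group": group}
    if group == "FH_Mpos":
        k = int(round(n * config.monogenic_split.get("LDLR", 1.0)))
        genes = np.array(["LDLR"] * k + ["APOB"] * (n - k), dtype=object)
        rows["mutation_gene"] = rng.permutation(genes)
    else:
        rows["mutation_gene"] = np.array(["none"] * n, dtype=object)
    margins = config.dlcn_margins.get(group, {})
    for comp in DLCN_COMPONENTS:
        p = margins.get(comp, 0.0)
        rows[f"dlcn_{comp}"] = (rng.random(n) < p).astype(int)
    cat_probs = config.ldl_category_probs.get(group)
    if cat_probs:
        rows["ldl_category"] = _draw_categorical(rng, cat_probs, n).astype(int)
    else:
        rows["ldl_category"] = np.full(n, 3, dtype=int)
    cls_probs = config.dlcn_class_probs.get(group)
    if cls_probs:
        classes = _draw_categorical(rng, cls_probs, n)
    else:
        classes = np.array(["probable"] * n, dtype=object)
    lo = np.array([_CLASS_SCORE_BANDS[c][0] for c in classes])
    hi = np.array([_CLASS_SCORE_BANDS[c][1] for c in classes])
    rows["dlcn_score"] = rng.integers(lo, hi + 1) if n else np.array([], dtype=int)
    age_cfg = config.age.get(group, {"mean": 45.0, "sd": 13.0})
    rows["age"] = np.clip(
        np.round(rng.normal(age_cfg["mean"], age_cfg["sd"], size=n), 1), 18.0, 90.0
    )
    p_male = config.sex_male_prob.get(group, 0.5)
    rows["sex"] = np.where(rng.random(n) < p_male, "M", "F")
    return genotypes, pd.DataFrame(rows)


@dataclass
class StudyData:
    genotypes: GenotypeMatrix
    cohort: CohortTable


def simulate_study(
    config: SimulationConfig,
    weights: WeightTable | None = None,
    out_dir: str | os.PathLike | None = None,
) -> StudyData:
    """Compose the three study groups; optionally write TSVs re-readable by the IO layer."""
    if weights is None:
        weights = defaults.default_weights()
    ss = np.random.SeedSequence(config.seed)
    rng_eur, rng_mneg, rng_mpos = (np.random.default_rng(s) for s in ss.spawn(3))

    n_eur = config.n_per_group.get("EUR", 0)
    eur = simulate_genotypes_hwe(
        n_eur, config.freq_table["EUR"], rng_eur, sample_prefix="EUR"
    )
    eur = GenotypeMatrix(
        eur.sample_ids, eur.rsids,
        _inject_missing(eur.dosage, config.missing_rate.get("EUR", 0.0), rng_eur),
    )
    eur_rows = pd.DataFrame(
        {
            "sample_id": pd.array(list(eur.sample_ids), dtype=object),
            "group": pd.array(["EUR"] * n_eur, dtype=object),
            "mutation_gene": pd.array(["none"] * n_eur, dtype=object),
            **{f"dlcn_{c}": pd.array([pd.NA] * n_eur, dtype="Int64")
               for c in DLCN_COMPONENTS},
            "ldl_category": pd.array([pd.NA] * n_eur, dtype="Int64"),
            "dlcn_score": pd.array([pd.NA] * n_eur, dtype="Int64"),
            "age": pd.array([pd.NA] * n_eur, dtype="Float64"),
            "sex": pd.array([pd.NA] * n_eur, dtype=object),
        }
    )
    mneg, mneg_rows = simulate_case_group(
        config.n_per_group.get("FH_Mneg", 0), config, "FH_Mneg", weights, rng_mneg
    )
    mpos, mpos_rows = simulate_case_group(
        config.n_per_group.get("FH_Mpos", 0), config, "FH_Mpos", weights, rng_mpos
    )
    genotypes = GenotypeMatrix.concat([eur, mneg, mpos])
    nullable = {
        **{f"dlcn_{c}": "Int64" for c in DLCN_COMPONENTS},
        "ldl_category": "Int64",
        "dlcn_score": "Int64",
        "age": "Float64",
    }
    frames = [f.astype(nullable) for f in (eur_rows, mneg_rows, mpos_rows)]
    cohort = CohortTable(pd.concat(frames, ignore_index=True))
    study = StudyData(genotypes=genotypes, cohort=cohort)
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        try:
            os.makedirs(out_dir, exist_ok=True)
            write_genotypes_tsv(genotypes, os.path.join(out_dir, "genotypes.tsv"))
            write_cohort_tsv(cohort, os.path.join(out_dir, "cohort.tsv"))
            with open(os.path.join(out_dir, "sim_config.json"), "w") as fh:
                json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
        except OSError as exc:
            raise ConfigError(f"cannot write study files under {out_dir}: {exc}") from exc
    return study
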