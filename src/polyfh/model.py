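"""Core data types for the polygenic familial-hypercholesterolemia (FH) pipeline.

The pipeline works on a fixed small panel of LDL-cholesterol-raising SNPs.
Every genotype is stored as an *effect-allele dosage*: the number of copies
(0, 1 or 2) of the LDL-c-raising allele declared in the weight table.  A
weighted gene score (wGS) for a sample is the dosage-weighted sum of the
per-allele effect sizes over a named panel of SNPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("EUR", "FH_Mneg", "FH_Mpos")
MUTATION_GENES = ("none", "LDLR", "APOB")
APOE_DIPLOTYPES = ("E2/E2", "E2/E3", "E2/E4", "E3/E3", "E3/E4", "E4/E4")
APOE_RSIDS = ("rs429358", "rs7412")
DLCN_COMPONENTS = ("1a", "1b", "2a", "2b", "3a", "3b", "4a", "4b")
DLCN_CLASSES = ("<3", "possible", "probable", "definite")
PANEL_MODES = ("two-snp-additive", "diplotype-table")

#: Canonical panel memberships.  The 11-SNP panel is the genotyped assay;
#: the 8-SNP panel keeps the SNPs independently associated with FH plus
#: rs429358 (needed to resolve APOE E2/E3/E4); the 6-SNP panel is the
#: published six-SNP refinement.  wGS6 ⊂ wGS8 ⊂ wGS11.
WGS11_MEMBERS = (
    "rs2479409", "rs629301", "rs1367117", "rs4299376", "rs1564348",
    "rs1800562", "rs3757354", "rs8017377", "rs6511720", "rs429358", "rs7412",
)
WGS8_MEMBERS = (
    "rs2479409", "rs629301", "rs1367117", "rs4299376", "rs3757354",
    "rs6511720", "rs429358", "rs7412",
)
WGS6_MEMBERS = (
    "rs629301", "rs1367117", "rs4299376", "rs6511720", "rs429358", "rs7412",
)

_BASES = frozenset("ACGT")


class PolyFHError(Exception):
    """Base class for pipeline errors."""


class FormatError(PolyFHError):
    """Malformed or inconsistent input file."""


class UnknownSnpError(FormatError):
    """A SNP identifier is not present in the weight table."""


class AlleleMismatchError(FormatError):
    """Observed alleles are incompatible with the weight-table orientation."""


class ConfigError(PolyFHError):
    """Invalid configuration (panel, simulation or model settings)."""


class ParameterError(PolyFHError):
    """Numeric parameter outside its valid domain."""


class InsufficientDataError(PolyFHError):
    """Not enough observations for the requested operation."""


@dataclass(frozen=True)
class SnpDefinition:
    """One panel SNP: identity, orientation and per-allele weight.

    ``effect_allele`` is the counted (LDL-c-raising, by convention) allele;
    ``beta`` is the signed per-allele effect in mmol/L, so a SNP whose
    counted allele lowers LDL-c (e.g. the ε2-defining rs7412-T) carries a
    negative beta.  ``ref_freq`` is an optional effect-allele frequency used
    as the simulator default.
    """

    rsid: str
    gene_label: str
    effect_allele: str
    other_allele: str
    beta: float
    ref_freq: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _BASES or self.other_allele not in _BASES:
            raise FormatError(
                f"{self.rsid}: alleles must be single bases, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise FormatError(f"{self.rsid}: effect and other allele identical")
        if not math.isfinite(self.beta):
            raise FormatError(f"{self.rsid}: beta must be finite")
        if self.ref_freq is not None and not (0.0 <= self.ref_freq <= 1.0):
            raise FormatError(f"{self.rsid}: ref_freq {self.ref_freq} outside [0, 1]")


@dataclass
class WeightTable:
    """The SNP weight configuration: definitions plus optional APOE diplotype weights."""

    snps: list[SnpDefinition]
    apoe_diplotype_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        rsids = [s.rsid for s in self.snps]
        dupes = {r for r in rsids if rsids.count(r) > 1}
        if dupes:
            raise FormatError(f"duplicate rsid(s) in weight table: {sorted(dupes)}")
        if self.apoe_diplotype_weights is not None:
            missing = set(APOE_DIPLOTYPES) - set(self.apoe_diplotype_weights)
            if missing:
                raise FormatError(
                    f"apoe_diplotype_weights incomplete, missing {sorted(missing)}"
                )
        self._by_rsid = {s.rsid: s for s in self.snps}

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.snps)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._by_rsid

    def __getitem__(self, rsid: str) -> SnpDefinition:
        try:
            return self._by_rsid[rsid]
        except KeyError:
            raise UnknownSnpError(f"rsid {rsid!r} not in weight table") from None

    def __len__(self) -> int:
        return len(self.snps)

    def betas(self, members: Sequence[str]) -> np.ndarray:
        return np.array([self[r].beta for r in members], dtype=float)


@dataclass(frozen=True)
class ScorePanel:
    """A named subset of the weight table over which a wGS is computed."""

    name: str
    members: tuple[str, ...]
    apoe_mode: str = "two-snp-additive"

    def __post_init__(self) -> None:
        if self.apoe_mode not in PANEL_MODES:
            raise ConfigError(f"unknown apoe_mode {self.apoe_mode!r}")
        if len(set(self.members)) != len(self.members):
            raise ConfigError(f"panel {self.name}: duplicate members")
        # APOE ε-genotypes need both defining sites: never one without the other.
        has = [r for r in APOE_RSIDS if r in self.members]
        if len(has) == 1:
            raise ConfigError(
                f"panel {self.name}: {has[0]} present without its APOE partner"
            )

    @property
    def size(self) -> int:
        return len(self.members)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.members


def standard_panel(name: str, apoe_mode: str = "two-snp-additive") -> ScorePanel:
    """Return one of the canonical panels wGS11, wGS8 or wGS6."""
    members = {"wGS11": WGS11_MEMBERS, "wGS8": WGS8_MEMBERS, "wGS6": WGS6_MEMBERS}
    if name not in members:
        raise ConfigError(f"unknown standard panel {name!r}; use wGS11/wGS8/wGS6")
    return ScorePanel(name=name, members=members[name], apoe_mode=apoe_mode)


class GenotypeMatrix:
    """Samples × SNPs effect-allele dosages; NaN encodes a missing genotype."""

    def __init__(
        self,
        sample_ids: Sequence[str],
        rsids: Sequence[str],
        dosage: np.ndarray,
    ) -> None:
        sample_ids = tuple(str(s) for s in sample_ids)
        rsids = tuple(str(r) for r in rsids)
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(sample_ids), len(rsids)):
            raise FormatError(
                f"dosage shape {dosage.shape} != ({len(sample_ids)}, {len(rsids)})"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError("duplicate sample identifiers")
        if len(set(rsids)) != len(rsids):
            raise FormatError("duplicate SNP identifiers")
        finite = dosage[np.isfinite(dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(finite[~np.isin(finite, (0.0, 1.0, 2.0))]))
            raise FormatError(f"dosages must be 0/1/2 or missing, got {bad}")
        self.sample_ids = sample_ids
        self.rsids = rsids
        self.dosage = dosage
        self._col = {r: j for j, r in enumerate(rsids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.rsids)

    def column(self, rsid: str) -> np.ndarray:
        if rsid not in self._col:
            raise UnknownSnpError(f"rsid {rsid!r} not in genotype matrix")
        return self.dosage[:, self._col[rsid]]

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        ids = tuple(np.asarray(self.sample_ids, dtype=object)[mask])
        return GenotypeMatrix(ids, self.rsids, self.dosage[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=list(self.sample_ids),
                            columns=list(self.rsids))

    def genotype_counts(self, rsid: str) -> tuple[int, int, int]:
        """(n0, n1, n2) non-missing dosage counts for one SNP."""
        col = self.column(rsid)
        col = col[np.isfinite(col)]
        return (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))

    @staticmethod
    def concat(parts: Sequence["GenotypeMatrix"]) -> "GenotypeMatrix":
        if not parts:
            raise FormatError("nothing to concatenate")
        rsids = parts[0].rsids
        for p in parts[1:]:
            if p.rsids != rsids:
                raise FormatError("SNP columns differ between parts")
        ids = [s for p in parts for s in p.sample_ids]
        dosage = np.vstack([p.dosage for p in parts]) if ids else \
            np.empty((0, len(rsids)))
        return GenotypeMatrix(ids, rsids, dosage)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.rsids == other.rsids
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )


def dlcn_class_from_score(score: float) -> str:
    """Map a DLCN point total to its diagnostic class."""
    if score < 0:
        raise ParameterError(f"DLCN score must be non-negative, got {score}")
    if score < 3:
        return "<3"
    if score <= 5:
        return "possible"
    if score <= 8:
        return "probable"
    return "definite"


#: cohort-metadata columns in file order
COHORT_COLUMNS = (
    ["sample_id", "group", "mutation_gene"]
    + [f"dlcn_{c}" for c in DLCN_COMPONENTS]
    + ["ldl_category", "dlcn_score", "age", "sex"]
)


class CohortTable:
    """Per-sample group labels, mutation status and DLCN phenotype fields.

    EUR control rows carry NA in the patient-only fields (DLCN components,
    LDL-c category, DLCN score).  ``dlcn_class`` is derived from
    ``dlcn_score`` so the two can never disagree.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"cohort table missing columns {missing}")
        df = df[list(COHORT_COLUMNS)].copy()
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in cohort table")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise FormatError(f"unknown group labels {sorted(bad_group)}")
        bad_gene = set(df["mutation_gene"]) - set(MUTATION_GENES)
        if bad_gene:
            raise FormatError(f"unknown mutation genes {sorted(bad_gene)}")
        pos = df["group"] == "FH_Mpos"
        if (df.loc[pos, "mutation_gene"] == "none").any():
            raise FormatError("FH_Mpos sample with mutation_gene 'none'")
        if (df.loc[~pos, "mutation_gene"] != "none").any():
            raise FormatError("mutation_gene set on a non-FH_Mpos sample")
        cat = df["ldl_category"].dropna()
        if cat.size and not cat.isin([1, 2, 3, 4, 5]).all():
            raise FormatError("ldl_category outside 1..5")
        df["dlcn_class"] = df["dlcn_score"].map(
            lambda s: dlcn_class_from_score(s) if pd.notna(s) else pd.NA
        )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def group_mask(self, group: str) -> np.ndarray:
        return (self.df["group"] == group).to_numpy()

    def stratum_mask(self, stratum: str) -> np.ndarray:
        """Boolean mask over FH patients for a DLCN stratum.

        ``all`` keeps every FH patient; ``definite`` keeps DLCN > 8,
        ``probable`` DLCN 6-8, ``probable+definite`` DLCN >= 6.  EUR
        controls are always excluded.
        """
        fh = self.df["group"].isin(["FH_Mneg", "FH_Mpos"]).to_numpy()
        cls = self.df["dlcn_class"]
        if stratum == "all":
            sel = np.ones(len(self.df), dtype=bool)
        elif stratum == "definite":
            sel = (cls == "definite").to_numpy()
        elif stratum == "probable":
            sel = (cls == "probable").to_numpy()
        elif stratum == "probable+definite":
            sel = cls.isin(["probable", "definite"]).to_numpy()
        else:
            raise ConfigError(f"unknown stratum {stratum!r}")
        return fh & sel


@dataclass(frozen=True)
class ScoreResult:
    """Weighted gene score of one sample under one panel."""

    sample_id: str
    panel_name: str
    wgs: float            # NaN when the sample was excluded for missingness
    n_snps_used: int
    complete: bool


def scores_to_frame(results: Sequence[ScoreResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "panel": [r.panel_name for r in results],
            "wgs": [r.wgs for r in results],
            "n_snps_used": [r.n_snps_used for r in results],
            "complete": [r.complete for r in results],
        }
    )


@dataclass
class RocCurve:
    """Empirical ROC of case vs control scores (classification rule: score > t)."""

    thresholds: np.ndarray   # ascending; midpoints between distinct scores ± sentinels
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    n_case: int
    n_control: int
    degenerate: bool = False
    panel_name: str | None = None
    # raw scores retained for the correlated-AUC (DeLong) comparison
    case_scores: np.ndarray | None = None
    control_scores: np.ndarray | None = None


@dataclass
class CutoffReport:
    """One classification threshold and its operating characteristics."""

    panel_name: str
    cutoff_type: str                     # p75 | p90 | p95 | youden
    threshold: float
    n_above: dict[str, int] = field(default_factory=dict)
    n_total: dict[str, int] = field(default_factory=dict)
    proportion_above: dict[str, float] = field(default_factory=dict)
    sens: float | None = None
    spec: float | None = None
    youden_j: float | None = None


@dataclass(frozen=True)
class AssocResult:
    """Per-SNP association under the additive model: OR per effect-allele copy."""

    rsid: str
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    model: str = "additive"
    note: str = ""


@dataclass(frozen=True)
class HweResult:
    """Hardy-Weinberg goodness-of-fit result for one SNP in one group."""

    rsid: str | None
    group: str | None
    chi2: float
    p_value: float
    genotype_counts: tuple[int, int, int]
    method: str = "chi2"        # chi2 | exact


@dataclass(frozen=True)
class FractionEstimate:
    """Combined monogenic + polygenic genetic-assignment estimate for a stratum.

    ``combined_pct`` = M + (100 − M) · r / 100, where M is the monogenic
    percentage of the stratum and r the percentage of mutation-negative
    patients above the polygenic cutoff.
    """

    stratum: str
    monogenic_pct: float
    polygenic_rate: float
    combined_pct: float
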