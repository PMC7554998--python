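"""Readers and writers for the pipeline's file formats.

Formats handled:

* weight config — JSON (``{"snps": [...], "apoe_diplotype_weights": {...}}``)
  or TSV with columns ``rsid gene effect_allele other_allele beta [ref_freq]``;
* dosage TSV — header ``sample_id<TAB>rsid1<TAB>...``, cells are effect-allele
  dosages ``0/1/2``, allele pairs such as ``AG`` (flipped to effect-allele
  orientation via the weight table), or ``.`` for missing;
* minimal VCF v4.x — matched to panel SNPs by ID; ``CHROM``/``POS`` ignored;
* cohort metadata TSV;
* the machine-readable JSON report plus a human-readable score-matrix table.

Orientation policy: dosages always count the effect allele declared in the
weight table.  An allele that is neither the effect nor the other allele of
its SNP is a data error — ambiguous strand flips are rejected, never guessed.
"""

from __future__ import annotations

import json
import math
import os
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AlleleMismatchError,
    COHORT_COLUMNS,
    CohortTable,
    FormatError,
    GenotypeMatrix,
    SnpDefinition,
    UnknownSnpError,
    WeightTable,
)

MISSING_TOKEN = "."

_WEIGHT_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta")


def _snp_from_record(rec: Mapping[str, Any]) -> SnpDefinition:
    for col in _WEIGHT_COLUMNS:
        if col not in rec or rec[col] is None or (
            isinstance(rec[col], float) and math.isnan(rec[col])
        ):
            raise FormatError(f"weight record missing required field {col!r}: {rec}")
    try:
        beta = float(rec["beta"])
    except (TypeError, ValueError):
        raise FormatError(f"non-numeric beta for {rec.get('rsid')}: {rec['beta']!r}")
    ref_freq = rec.get("ref_freq")
    if ref_freq is not None and not (isinstance(ref_freq, float) and math.isnan(ref_freq)):
        ref_freq = float(ref_freq)
    else:
        ref_freq = None
    return SnpDefinition(
        rsid=str(rec["rsid"]),
        gene_label=str(rec.get("gene", rec.get("gene_label", ""))),
        effect_allele=str(rec["effect_allele"]).upper(),
        other_allele=str(rec["other_allele"]).upper(),
        beta=beta,
        ref_freq=ref_freq,
    )


def read_weights(path: str | os.PathLike, format: str | None = None) -> WeightTable:
    """Read a weight table from JSON or TSV.

    ``format`` is inferred from the file extension when omitted.
    """
    path = os.fspath(path)
    if format is None:
        format = "json" if path.endswith(".json") else "tsv"
    if format == "json":
        with open(path) as fh:
            doc = json.load(fh)
        if "snps" not in doc:
            raise FormatError(f"{path}: JSON weight file must contain a 'snps' list")
        snps = [_snp_from_record(rec) for rec in doc["snps"]]
        apoe = doc.get("apoe_diplotype_weights")
        if apoe is not None:
            apoe = {k: float(v) for k, v in apoe.items()}
        return WeightTable(snps=snps, apoe_diplotype_weights=apoe)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"rsid": str})
        missing = [c for c in _WEIGHT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: weight TSV missing columns {missing}")
        snps = [_snp_from_record(rec) for rec in df.to_dict("records")]
        return WeightTable(snps=snps)
    raise FormatError(f"unknown weight format {format!r}")


def write_weights(weights: WeightTable, path: str | os.PathLike) -> None:
    doc: dict[str, Any] = {
        "snps": [
            {
                "rsid": s.rsid,
                "gene": s.gene_label,
                "effect_allele": s.effect_allele,
                "other_allele": s.other_allele,
                "beta": s.beta,
                "ref_freq": s.ref_freq,
            }
            for s in weights.snps
        ]
    }
    if weights.apoe_diplotype_weights is not None:
        doc["apoe_diplotype_weights"] = weights.apoe_diplotype_weights
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _cell_to_dosage(cell: str, snp: SnpDefinition, where: str) -> float:
    cell = cell.strip()
    if cell == MISSING_TOKEN or cell == "":
        return math.nan
    if cell in ("0", "1", "2"):
        return float(cell)
    if len(cell) == 2 and all(ch.isalpha() for ch in cell):
        dosage = 0.0
        for allele in cell.upper():
            if allele == snp.effect_allele:
                dosage += 1.0
            elif allele != snp.other_allele:
                raise AlleleMismatchError(
                    f"{where}: allele {allele!r} not in "
                    f"{{{snp.effect_allele},{snp.other_allele}}} for {snp.rsid}"
                )
        return dosage
    raise FormatError(f"{where}: cannot parse genotype cell {cell!r}")


def _dosage_to_cell(value: float) -> str:
    if math.isnan(value):
        return MISSING_TOKEN
    return str(int(value))


def read_genotypes_tsv(path: str | os.PathLike, weights: WeightTable) -> GenotypeMatrix:
    """Read a dosage TSV, flipping allele-pair cells to effect-allele dosage."""
    path = os.fspath(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id'")
    rsids = list(df.columns[1:])
    for rsid in rsids:
        if rsid not in weights:
            raise UnknownSnpError(f"{path}: column {rsid!r} not in weight table")
    dosage = np.empty((len(df), len(rsids)))
    for j, rsid in enumerate(rsids):
        snp = weights[rsid]
        col = df[rsid].tolist()
        for i, cell in enumerate(col):
            dosage[i, j] = _cell_to_dosage(
                cell, snp, f"{path} row {i + 2} ({df.iloc[i, 0]})"
            )
    return GenotypeMatrix(df["sample_id"].tolist(), rsids, dosage)


def write_genotypes_tsv(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(matrix.rsids) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            cells = [_dosage_to_cell(v) for v in matrix.dosage[i]]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_genotypes_vcf(path: str | os.PathLike, weights: WeightTable) -> GenotypeMatrix:
    """Read panel SNP dosages from a VCF.

    Records are matched to the weight table by ID (rsid); records whose ID is
    not a panel SNP are ignored.  REF/ALT must equal the SNP's
    {effect, other} allele set — anything else (including a strand flip) is
    an :class:`AlleleMismatchError`.  Multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    columns: list[str] = []
    dosage_cols: list[np.ndarray] = []
    for variant in vcf:
        rsid = variant.ID
        if rsid is None or rsid not in weights:
            continue
        if rsid in columns:
            raise FormatError(f"{path}: duplicate record for {rsid}")
        if len(variant.ALT) != 1:
            raise FormatError(f"{path}: {rsid} is not biallelic (ALT={variant.ALT})")
        snp = weights[rsid]
        ref, alt = variant.REF.upper(), variant.ALT[0].upper()
        if {ref, alt} != {snp.effect_allele, snp.other_allele}:
            raise AlleleMismatchError(
                f"{path}: {rsid} REF/ALT {ref}/{alt} incompatible with "
                f"weight-table alleles {snp.effect_allele}/{snp.other_allele}"
            )
        effect_index = 0 if ref == snp.effect_allele else 1
        col = np.empty(len(samples))
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                col[i] = math.nan
            else:
                col[i] = sum(1.0 for a in alleles if a == effect_index)
        columns.append(rsid)
        dosage_cols.append(col)
    if not columns:
        raise FormatError(f"{path}: no panel SNPs found by ID")
    dosage = np.column_stack(dosage_cols)
    return GenotypeMatrix(samples, columns, dosage)


def read_cohort_tsv(path: str | os.PathLike) -> CohortTable:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "group": str, "mutation_gene": str, "sex": str},
        na_values=[MISSING_TOKEN],
    )
    return CohortTable(df)


def write_cohort_tsv(cohort: CohortTable, path: str | os.PathLike) -> None:
    df = cohort.df[list(COHORT_COLUMNS)].astype(object)
    int_like = ["ldl_category", "dlcn_score"] + [
        c for c in COHORT_COLUMNS if c.startswith("dlcn_") and c != "dlcn_score"
    ]
    for col in int_like:
        df[col] = df[col].map(lambda v: MISSING_TOKEN if pd.isna(v) else str(int(v)))
    df["age"] = df["age"].map(lambda v: MISSING_TOKEN if pd.isna(v) else f"{v:.1f}")
    df = df.where(df.notna(), MISSING_TOKEN)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# report writing

REPORT_SECTIONS = (
    "meta",
    "panels",
    "scores",
    "hwe",
    "association",
    "group_comparison",
    "cutoffs",
    "fractions",
)


def _jsonable(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays and NaN for strict JSON."""
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not math.isfinite(v) else v
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(results: Mapping[str, Any], out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the JSON summary and a text score-comparison table.

    ``results`` maps section names (:data:`REPORT_SECTIONS`) to their
    content; sections that were not computed are written as
    ``{"absent": true}`` so a partial run is explicit, never silent.
    Returns the paths written.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    doc = {}
    for section in REPORT_SECTIONS:
        if section in results and results[section] is not None:
            doc[section] = _jsonable(results[section])
        else:
            doc[section] = {"absent": True}
    json_path = os.path.join(out_dir, "report.json")
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    txt_path = os.path.join(out_dir, "report.txt")
    with open(txt_path, "w") as fh:
        fh.write(_format_text_report(doc))
    return {"json": json_path, "txt": txt_path}


def _format_text_report(doc: Mapping[str, Any]) -> str:
    """Human-readable matrix of group score means (SD) and pairwise p-values."""
    lines = ["polyfh report", "=" * 60]
    gc = doc.get("group_comparison", {})
    if gc.get("absent"):
        lines.append("group comparison: absent")
    else:
        for panel, block in sorted(gc.items()):
            groups = block.get("groups", [])
            lines.append("")
            lines.append(panel)
            header = "\t".join([""] + groups)
            lines.append(header)
            moments = block.get("moments", {})
            pairwise = {tuple(k.split("|")): v for k, v in block.get("pairwise", {}).items()}
            for i, gi in enumerate(groups):
                row = [gi]
                for j, gj in enumerate(groups):
                    if j > i:
                        row.append("-")
                    elif i == j:
                        m = moments.get(gi, {})
                        mean, sd = m.get("mean"), m.get("sd")
                        row.append(
                            f"{mean:.3f} ({sd:.2f})" if mean is not None else "NA"
                        )
                    else:
                        p = pairwise.get((gi, gj), pairwise.get((gj, gi), {}))
                        pv = p.get("p_value") if isinstance(p, Mapping) else None
                        row.append(f"p={pv:.2g}" if pv is not None else "-")
                lines.append("\t".join(row))
    fr = doc.get("fractions", {})
    lines.append("")
    if fr.get("absent"):
        lines.append("fractions: absent")
    else:
        lines.append("combined genetic assignment (monogenic + polygenic)")
        for est in fr.get("estimates", []):
            lines.append(
                f"  {est['stratum']}: monogenic {est['monogenic_pct']:.1f}% + "
                f"polygenic rate {est['polygenic_rate']:.1f}% -> "
                f"combined {est['combined_pct']:.1f}%"
            )
    lines.append("")
    return "\n".join(lines)
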