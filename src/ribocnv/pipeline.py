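"""Configuration-driven pipeline tracks binding the stages together.

Three tracks mirror the analysis workflow: ``run_mapping_track`` (FASTQ ->
survey-style copy-number table), ``run_qpcr_track`` (plate TSV -> per-2C
quantification table) and ``run_stats`` (cohort TSV -> lineage summaries,
foreign fractions, ANOVA and pairwise reports).  Every output TSV carries
a provenance comment (config hash + seed) and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import qpcr as qp
from . import stats as st
from .mapping import MappingParams, ReadMappingModel
from .reference import read_unit
from .simulate import DEFAULT_INSERT_LENGTHS, ReadSet

logger = logging.getLogger("ribocnv")


class ConfigError(ValueError):
    """A problem with the pipeline configuration (missing/invalid field)."""


class DataError(ValueError):
    """A problem with the input data files."""


@dataclasses.dataclass
class PipelineConfig:
    """Declarative pipeline configuration (usually loaded from YAML)."""

    raw: dict
    base_dir: Path = Path(".")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        path = Path(path)
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        return cls(raw=raw, base_dir=path.parent)

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def output_dir(self) -> Path:
        out = self.base_dir / self.raw.get("output_dir", "ribocnv_out")
        out.mkdir(parents=True, exist_ok=True)
        return out

    def section(self, name: str) -> dict:
        sec = self.raw.get(name)
        if sec is None:
            raise ConfigError(f"missing config section: {name!r}")
        return sec

    def path(self, value: str) -> Path:
        p = self.base_dir / value
        if not p.exists():
            raise ConfigError(f"configured path does not exist: {p}")
        return p

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.raw, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ribocnv provenance: config_sha256={config.digest()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)
    logger.info("wrote %s (%d rows)", path, len(df))


def run_mapping_track(config: PipelineConfig) -> pd.DataFrame:
    """Map each configured FASTQ against the repeat-unit reference.

    Emits one row per sample: read counts, genome proportion (%), genome
    space (Mb and Kb) and copy number per 2C rounded to the nearest 10.
    """
    sec = config.section("mapping")
    ref_sec = config.section("reference")
    for field in ("fasta", "annotation"):
        if field not in ref_sec:
            raise ConfigError(f"reference section missing field {field!r}")
    unit = read_unit(config.path(ref_sec["fasta"]), config.path(ref_sec["annotation"]))
    params = MappingParams(
        k=int(sec.get("k", 20)),
        min_identity=float(sec.get("min_identity", 0.90)),
        min_match_length=int(sec.get("min_match_length", 50)),
    )
    coverage = sec.get("target_coverage", 1.0)
    samples = sec.get("samples") or []
    if not samples:
        raise ConfigError("mapping section has no samples")
    logger.info(
        "mapping track: unit=%s U=%d k=%d min_identity=%.2f seed=%d",
        unit.species, unit.unit_length, params.k, params.min_identity, config.seed,
    )
    rows = []
    for sample in samples:
        for field in ("name", "fastq", "two_c_pg"):
            if field not in sample:
                raise ConfigError(f"mapping sample missing field {field!r}")
        try:
            reads = ReadSet.from_fastq(config.path(sample["fastq"]))
        except ValueError as exc:
            raise DataError(str(exc)) from exc
        model = ReadMappingModel(reads, unit, float(sample["two_c_pg"]), params)
        result = model.fit(target_coverage=coverage, seed=config.seed)
        if result.mapping.m_mapped_reads == 0:
            warnings.warn(f"sample {sample['name']}: zero mapped reads", stacklevel=2)
        rows.append(result.to_row(sample["name"]))
    table = pd.DataFrame(rows)
    _write_tsv(table, config.output_dir / "mapping_track.tsv", config)
    return table


def _load_plates(path: Path) -> pd.DataFrame:
    plates = pd.read_csv(path, sep="\t", comment="#", na_values=["n.d.", ""], keep_default_na=False)
    required = {"assay", "sample", "role", "cq"}
    missing = required - set(plates.columns)
    if missing:
        raise DataError(f"plate TSV missing columns: {sorted(missing)}")
    return plates


def run_qpcr_track(config: PipelineConfig) -> pd.DataFrame:
    """Standard-curve calibration and absolute quantification per assay.

    The plate TSV is tidy: (assay, sample, role, copies, template_ng,
    replicate, cq) with role in {standard, sample}.  Output is one row per
    sample x assay with copies per 2C; "n.d." marks below-detection results.
    """
    sec = config.section("qpcr")
    plates = _load_plates(config.path(sec.get("plates") or _missing("qpcr.plates")))
    meta = {s["name"]: float(s["two_c_pg"]) for s in sec.get("samples", [])}
    template_ng = float(sec.get("template_ng", 1.0))
    curves = {}
    for assay, grp in plates[plates["role"] == "standard"].groupby("assay"):
        pts = grp.rename(columns={"copies": "true_copies"})[["true_copies", "cq"]]
        curves[assay] = qp.fit_standard_curve(pts, assay=assay)
        logger.info("standard curve %s: slope=%.4f E=%.4f R2=%.5f",
                    assay, curves[assay].slope_a, curves[assay].efficiency_e, curves[assay].r_squared)
    rows = []
    sample_wells = plates[plates["role"] == "sample"]
    for (sample, assay), grp in sample_wells.groupby(["sample", "assay"]):
        if assay not in curves:
            raise DataError(f"no standard series for assay {assay!r}")
        tng = float(grp["template_ng"].iloc[0]) if "template_ng" in grp and grp["template_ng"].notna().all() else template_ng
        quant = qp.quantify_absolute(grp["cq"].to_numpy(float), curves[assay], tng, sample=str(sample))
        if sample in meta:
            quant = qp.quant_to_2c(quant, meta[sample])
        rows.append(
            {
                "sample": sample,
                "assay": assay,
                "copies_per_ng": quant.copies_per_ng_template,
                "copies_per_2c": "n.d." if quant.not_detected else quant.copies_per_2c,
                "sd_per_2c": quant.sd_per_2c,
                "two_c_pg": meta.get(sample, np.nan),
            }
        )
    # assays with a curve but no wells for a sample are reported as n.d.
    for sample in sorted(meta):
        seen = {r["assay"] for r in rows if r["sample"] == sample}
        for assay in sorted(set(curves) - seen):
            rows.append(
                {"sample": sample, "assay": assay, "copies_per_ng": np.nan,
                 "copies_per_2c": "n.d.", "sd_per_2c": np.nan, "two_c_pg": meta[sample]}
            )
    table = pd.DataFrame(rows).sort_values(["sample", "assay"], ignore_index=True)
    _write_tsv(table, config.output_dir / "qpcr_track.tsv", config)
    return table


def _missing(field: str):
    raise ConfigError(f"missing config field: {field!r}")


def run_stats(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Cohort statistics: lineage summaries, fractions, ANOVA, pairwise."""
    sec = config.section("stats")
    cohort_path = config.path(sec.get("cohort") or _missing("stats.cohort"))
    try:
        cohort = pd.read_csv(cohort_path, sep="\t", comment="#", na_values=["n.d.", ""], keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed cohort TSV {cohort_path}: {exc}") from exc
    if "native_cn" not in cohort.columns:
        raise DataError("cohort TSV lacks a native_cn column")
    level = sec.get("level", "taxon-means")
    outputs: dict[str, pd.DataFrame] = {}

    outputs["lineage_summary"] = st.lineage_summary(cohort, level=level)
    fold_all = st.fold_variation(cohort["native_cn"].dropna())
    outputs["fold_variation"] = pd.DataFrame(
        [{"scope": "all_taxa", "fold_variation": round(fold_all, 1), "fold_variation_raw": fold_all}]
    )
    ribotypes = [
        r for r in ("panicum", "paspalum", "setaria", "euclasta") if f"{r}_cn" in cohort.columns
    ]
    if ribotypes and cohort[[f"{r}_cn" for r in ribotypes]].notna().any().any():
        outputs["foreign_fractions"] = st.foreign_fraction_summary(
            cohort, ribotypes, denominator=sec.get("fraction_denominator", "native")
        )
    else:
        logger.info("no foreign ribotype detections; fraction summary omitted")

    groups, labels = [], []
    for clade, grp in cohort.dropna(subset=["native_cn"]).groupby("clade"):
        groups.append(grp["native_cn"].to_numpy(float))
        labels.append(str(clade))
    report_rows = []
    if len(groups) >= 2:
        f, p = st.one_way_anova(groups)
        report_rows.append({"test": "native_cn ~ clade (one-way ANOVA)", "statistic": f, "p_value": p})
        outputs["pairwise_p"] = st.pairwise_comparisons_mc(
            groups, n_draws=int(sec.get("mc_draws", 100_000)), seed=config.seed, labels=labels
        ).reset_index(names="lineage")
    if "x_col" in sec and "y_col" in sec:
        sub = cohort.dropna(subset=[sec["x_col"], sec["y_col"]])
        reg = st.ols_regression(sub[sec["x_col"]], sub[sec["y_col"]])
        report_rows.append(
            {"test": f"{sec['y_col']} ~ {sec['x_col']} (OLS, adjusted R2={reg.adjusted_r_squared:.3f})",
             "statistic": reg.slope, "p_value": reg.p_value}
        )
    if report_rows:
        outputs["inference_report"] = pd.DataFrame(report_rows)

    for name, df in outputs.items():
        _write_tsv(df, config.output_dir / f"{name}.tsv", config)
    return outputs
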