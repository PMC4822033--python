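"""Empirical somatic-variant filtering for paired tumour/normal exomes.

Reads variant tables (VCF 4.2 or flat TSV) and applies the empirical somatic
filter battery, each rule recorded as an independent audit flag per tumour
sample:

    R1_depth        normal depth < min_normal_depth OR tumour depth < min_tumour_depth
    R2_normal_vaf   normal VAF >= max_normal_vaf
    R3_min_alt      tumour alt reads < min_alt_reads
    R4_min_vaf      tumour VAF <= min_tumour_vaf (FF) / <= FFPE threshold
    R5_popfreq      population germline frequency >= max_population_freq
    R6_pon          present in local constitutional ("panel of normals") data
    R7_mappability  segmental-duplication region or mappability < min_mappability

A variant passes for a tumour sample iff no flag is raised.  Because the goal
is pre/post comparison, the paired relaxation requires both samples to be
clean on R1, R2, R5, R6 and R7, but only ONE of the pair to be clean on the
evidence-strength rules R3 and R4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterParams",
    "RULES",
    "read_variants",
    "apply_somatic_filters",
    "apply_pair_relaxation",
]

RULES = ("R1_depth", "R2_normal_vaf", "R3_min_alt", "R4_min_vaf",
         "R5_popfreq", "R6_pon", "R7_mappability")

#: rules evaluated on site/normal-level evidence, required clean in both samples
SITE_RULES = ("R1_depth", "R2_normal_vaf", "R5_popfreq", "R6_pon", "R7_mappability")
#: evidence-strength rules relaxed to "at least one sample clean"
RELAXED_RULES = ("R3_min_alt", "R4_min_vaf")

TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "context96",
    "normal_depth", "normal_alt", "pre_depth", "pre_alt",
    "post_depth", "post_alt",
]
OPTIONAL_COLUMNS = {
    "population_frequency": 0.0,
    "panel_of_normals_hit": False,
    "segdup_region": False,
    "mappability": 1.0,
    "total_cn": 2.0,
}


@dataclass
class FilterParams:
    min_normal_depth: int = 10
    min_tumour_depth: int = 8
    max_normal_vaf: float = 0.03
    min_alt_reads: int = 4
    min_tumour_vaf_ff: float = 0.02
    min_tumour_vaf_ffpe: float = 0.05
    max_population_freq: float = 0.01
    min_mappability: float = 0.8

    def __post_init__(self):
        if self.min_normal_depth < 0 or self.min_tumour_depth < 0 or self.min_alt_reads < 0:
            raise ValueError("read-count thresholds must be nonnegative")
        for v in (self.max_normal_vaf, self.min_tumour_vaf_ff, self.min_tumour_vaf_ffpe,
                  self.max_population_freq, self.min_mappability):
            if not 0 <= v <= 1:
                raise ValueError("proportion thresholds must be in [0, 1]")

    def min_tumour_vaf(self, preservation: str) -> float:
        if preservation == "ff":
            return self.min_tumour_vaf_ff
        if preservation == "ffpe":
            return self.min_tumour_vaf_ffpe
        raise ValueError(f"unknown preservation {preservation!r}; expected 'ff' or 'ffpe'")


def _compute_vafs(df: pd.DataFrame) -> pd.DataFrame:
    for s in ("normal", "pre", "post"):
        depth = df[f"{s}_depth"].to_numpy(dtype=float)
        alt = df[f"{s}_alt"].to_numpy(dtype=float)
        if (alt > depth).any() or (alt < 0).any():
            raise ValueError(f"{s}: alt counts must satisfy 0 <= alt <= depth")
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        df[f"{s}_vaf"] = vaf
    return df


def read_variants(path, format: str = "tsv") -> pd.DataFrame:
    """Read a paired-sample variant table into the flat schema.

    TSV: one row per (site, alt allele) with the columns in ``TSV_COLUMNS``
    (missing optional annotation columns are filled with neutral defaults).
    VCF 4.2: requires per-sample DP and AD FORMAT fields for samples named
    NORMAL, PRE and POST; multi-allelic rows are split per ALT allele.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = [c for c in TSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"TSV is missing required columns: {missing}")
    elif format == "vcf":
        df = _read_vcf(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    for col, default in OPTIONAL_COLUMNS.items():
        if col not in df.columns:
            df[col] = default
    if len(df) and (df["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    return _compute_vafs(df)


def _read_vcf(path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = {name.lower(): i for i, name in enumerate(vcf.samples)}
    for want in ("normal", "pre", "post"):
        if want not in samples:
            raise ValueError(f"VCF must contain a sample named {want.upper()}")
    rows = []
    for var in vcf:
        dp = var.format("DP")
        ad = var.format("AD")
        if dp is None or ad is None:
            raise ValueError(f"missing DP/AD FORMAT fields at {var.CHROM}:{var.POS}")
        info = dict(var.INFO)
        for ai, alt in enumerate(var.ALT):
            row = {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": alt,
                "gene": info.get("GENE", "."),
                "context96": info.get("CTX96", -1),
                "population_frequency": float(info.get("POPFREQ", 0.0)),
                "panel_of_normals_hit": bool(info.get("PON", False)),
                "segdup_region": bool(info.get("SEGDUP", False)),
                "mappability": float(info.get("MAPQ96", info.get("MAPPABILITY", 1.0))),
                "total_cn": float(info.get("TCN", 2.0)),
            }
            for sname, si in samples.items():
                row[f"{sname}_depth"] = int(dp[si][0] if np.ndim(dp[si]) else dp[si])
                row[f"{sname}_alt"] = int(ad[si][ai + 1])
            rows.append(row)
    df = pd.DataFrame(rows, columns=TSV_COLUMNS + list(OPTIONAL_COLUMNS))
    return df


def apply_somatic_filters(variants: pd.DataFrame, params: FilterParams | None = None,
                          preservation: str = "ff") -> pd.DataFrame:
    """Evaluate every filter rule independently per tumour sample.

    Adds boolean columns ``{pre,post}_{rule}`` (True = rule raised = fail) and
    ``{pre,post}_pass``.  Pure: same input always yields the same flags, and
    re-applying to an already-flagged table recomputes identical flags.
    """
    params = params or FilterParams()
    vaf_floor = params.min_tumour_vaf(preservation)
    df = variants.copy()
    if "normal_vaf" not in df.columns:
        df = _compute_vafs(df)

    popfreq = df["population_frequency"].fillna(0.0)
    site_r2 = df["normal_vaf"] >= params.max_normal_vaf
    site_r5 = popfreq >= params.max_population_freq
    site_r6 = df["panel_of_normals_hit"].astype(bool)
    site_r7 = df["segdup_region"].astype(bool) | (df["mappability"] < params.min_mappability)

    for s in ("pre", "post"):
        df[f"{s}_R1_depth"] = (df["normal_depth"] < params.min_normal_depth) | (
            df[f"{s}_depth"] < params.min_tumour_depth
        )
        df[f"{s}_R2_normal_vaf"] = site_r2
        df[f"{s}_R3_min_alt"] = df[f"{s}_alt"] < params.min_alt_reads
        df[f"{s}_R4_min_vaf"] = df[f"{s}_vaf"] <= vaf_floor
        df[f"{s}_R5_popfreq"] = site_r5
        df[f"{s}_R6_pon"] = site_r6
        df[f"{s}_R7_mappability"] = site_r7
        df[f"{s}_pass"] = ~np.logical_or.reduce([df[f"{s}_{r}"].to_numpy() for r in RULES])
    return df


def apply_pair_relaxation(flagged: pd.DataFrame) -> pd.DataFrame:
    """Retain variants for the pair under the paired-sample relaxation.

    Retained iff both samples are clean on the site-level rules (R1, R2, R5,
    R6, R7) and at least one of pre/post is clean on both R3 and R4.  The
    retained set is therefore a superset of {both samples pass everything}.
    """
    need = [f"{s}_{r}" for s in ("pre", "post") for r in RULES]
    missing = [c for c in need if c not in flagged.columns]
    if missing:
        raise ValueError("run apply_somatic_filters first; missing flag columns")
    df = flagged.copy()
    site_clean = ~np.logical_or.reduce(
        [df[f"{s}_{r}"].to_numpy() for s in ("pre", "post") for r in SITE_RULES]
    )
    pre_evidence = ~(df["pre_R3_min_alt"] | df["pre_R4_min_vaf"])
    post_evidence = ~(df["post_R3_min_alt"] | df["post_R4_min_vaf"])
    df["retained"] = site_clean & (pre_evidence | post_evidence).to_numpy()
    return df
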