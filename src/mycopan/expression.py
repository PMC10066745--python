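"""Symbiosis differential expression and pangenome-class summaries.

Raw read counts (ectomycorrhizal root tips, "ECM", versus free-living
mycelium, "FLM") are normalized with median-of-ratios size factors and tested
gene-by-gene with a negative-binomial Wald test using a method-of-moments
dispersion estimate.  A gene is called up-regulated when log2FC > 1 with
BH-adjusted p < 0.05 (down-regulated symmetrically).  Calls are then
tabulated by pangenome partition (core / accessory / specific), lifted to
orthogroup regulation sets across species, and summarized for SSP genes.

The test is a deliberately transparent re-implementation of the DESeq2-style
workflow without dispersion shrinkage: the thresholds, not the estimator,
are the quantities reused downstream.  A loader for externally produced DE
tables is provided for real-data parity.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class DEConfig:
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    dispersion_floor: float = 1e-8
    pseudocount: float = 1.0


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    The per-gene reference is the geometric mean over samples, computed over
    genes with no zero count; each sample's size factor is the median of
    count/reference over those genes (median taken on the log scale, the
    DESeq2 convention, which matters only when the gene count is even).
    Raises if no gene is zero-free.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples to normalize")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "every gene has a zero count; median-of-ratios undefined "
            "(consider a pseudo-reference fallback)"
        )
    log_counts = np.log(counts.loc[positive].to_numpy(float))
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_counts - log_geomean, axis=0))
    size_factors = pd.Series(factors, index=counts.columns, name="size_factor")
    return size_factors, counts / size_factors


def test_de(
    counts: pd.DataFrame,
    conditions: pd.Series | Mapping[str, str],
    cfg: DEConfig | None = None,
) -> pd.DataFrame:
    """Per-gene negative-binomial Wald test of ECM versus FLM.

    Returns a DataFrame (gene_id, base_mean, log2fc, p_value, fdr, call)
    where log2fc is the pseudo-counted ratio of normalized condition means
    (ECM over FLM) and call in {up, down, ns}.  Genes with zero counts in
    every sample are excluded from testing and reported as ns with NaN p.
    """
    cfg = cfg or DEConfig()
    cond = pd.Series(conditions)
    cond = cond.reindex(counts.columns)
    if cond.isna().any():
        raise ValueError("every sample needs a condition label")
    levels = sorted(cond.unique())
    if set(levels) != {"ECM", "FLM"}:
        raise ValueError(f"conditions must be ECM/FLM, got {levels}")
    for lvl in levels:
        if (cond == lvl).sum() < 2:
            raise ValueError(f"condition {lvl} has fewer than 2 replicates")

    size_factors, normalized = normalize_counts(counts)
    ecm = normalized.loc[:, cond == "ECM"].to_numpy(float)
    flm = normalized.loc[:, cond == "FLM"].to_numpy(float)
    n_ecm, n_flm = ecm.shape[1], flm.shape[1]

    mu_ecm = ecm.mean(axis=1)
    mu_flm = flm.mean(axis=1)
    base_mean = normalized.mean(axis=1).to_numpy(float)
    log2fc = np.log2((mu_ecm + cfg.pseudocount) / (mu_flm + cfg.pseudocount))

    # method-of-moments NB dispersion pooled across conditions:
    # var = mu + alpha * mu^2  =>  alpha = (var - mu) / mu^2
    var_ecm = ecm.var(axis=1, ddof=1)
    var_flm = flm.var(axis=1, ddof=1)
    pooled_var = ((n_ecm - 1) * var_ecm + (n_flm - 1) * var_flm) / (
        n_ecm + n_flm - 2
    )
    pooled_mu = (mu_ecm * n_ecm + mu_flm * n_flm) / (n_ecm + n_flm)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mu) / pooled_mu**2
    alpha = np.where(np.isfinite(alpha), alpha, cfg.dispersion_floor)
    alpha = np.maximum(alpha, cfg.dispersion_floor)

    # Wald statistic on the log2 ratio; delta method on each condition mean
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log2_ecm = (mu_ecm + alpha * mu_ecm**2) / (
            n_ecm * (mu_ecm + cfg.pseudocount) ** 2 * np.log(2.0) ** 2
        )
        var_log2_flm = (mu_flm + alpha * mu_flm**2) / (
            n_flm * (mu_flm + cfg.pseudocount) ** 2 * np.log(2.0) ** 2
        )
    se = np.sqrt(var_log2_ecm + var_log2_flm)

    testable = base_mean > 0
    z = np.full(len(counts), np.nan)
    np.divide(log2fc, se, out=z, where=(se > 0) & testable)
    # t reference with the pooled residual df guards small replicate numbers
    df = n_ecm + n_flm - 2
    p = np.full(len(counts), np.nan)
    p[testable] = 2.0 * stats.t.sf(np.abs(z[testable]), df)
    # a gene identical in both conditions with zero variance: no evidence
    p[testable & (se == 0)] = 1.0

    fdr = np.full(len(counts), np.nan)
    if testable.any():
        fdr[testable] = multipletests(p[testable], method="fdr_bh")[1]

    call = np.full(len(counts), "ns", dtype=object)
    up = testable & (log2fc > cfg.lfc_threshold) & (fdr < cfg.fdr_threshold)
    down = testable & (log2fc < -cfg.lfc_threshold) & (fdr < cfg.fdr_threshold)
    call[up] = "up"
    call[down] = "down"

    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean": base_mean,
            "log2fc": np.where(testable, log2fc, 0.0),
            "p_value": p,
            "fdr": fdr,
            "call": call,
        }
    ).reset_index(drop=True)


def load_de_table(path) -> pd.DataFrame:
    """Load an externally produced DE table (gene_id, log2fc, fdr [, p_value]).

    Calls are (re)derived with the standard thresholds so that external
    DESeq2 output can flow through the same downstream summaries.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "fdr"}
    if not required <= set(df.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    call = np.full(len(df), "ns", dtype=object)
    call[(df.log2fc > 1) & (df.fdr < 0.05)] = "up"
    call[(df.log2fc < -1) & (df.fdr < 0.05)] = "down"
    df["call"] = call
    return df


def summarize_by_partition(
    de_results: pd.DataFrame,
    partition_by_gene: Mapping[str, str],
    genome_total_genes: int | None = None,
) -> pd.DataFrame:
    """Per-direction DEG counts by pangenome partition (one row per direction).

    Columns: direction, total, core, accessory, specific, percent_specific
    (one decimal, round half up).  When the genome-wide gene total is given,
    a genome row with its percent-specific is appended for context.
    """
    parts = pd.Series(partition_by_gene)
    rows = []
    for direction in ("up", "down"):
        sub = de_results.loc[de_results.call == direction, "gene_id"]
        labels = parts.reindex(sub)
        counts = labels.value_counts()
        total = int(len(sub))
        spec = int(counts.get("specific", 0))
        percent = _round_half_up(100.0 * spec / total, 1) if total else 0.0
        rows.append(
            {
                "direction": direction,
                "total": total,
                "core": int(counts.get("core", 0)),
                "accessory": int(counts.get("accessory", 0)),
                "specific": spec,
                "percent_specific": percent,
                "defined": total > 0,
            }
        )
    if genome_total_genes is not None:
        genome_spec = int((parts == "specific").sum())
        rows.append(
            {
                "direction": "genome",
                "total": genome_total_genes,
                "core": int((parts == "core").sum()),
                "accessory": int((parts == "accessory").sum()),
                "specific": genome_spec,
                "percent_specific": _round_half_up(
                    100.0 * genome_spec / genome_total_genes, 1
                )
                if genome_total_genes
                else 0.0,
                "defined": genome_total_genes > 0,
            }
        )
    return pd.DataFrame(rows)


def orthogroup_regulation(
    de_by_species: Mapping[str, pd.DataFrame],
    orthogroups: pd.DataFrame,
) -> dict[str, dict[str, set[str]]]:
    """Orthogroups containing >= 1 regulated gene, per species and direction.

    ``orthogroups`` is the long table (og_id, species_id, gene_id).  An
    orthogroup may appear in both the up and the down set of a species when
    it has members regulated in both directions.
    """
    out: dict[str, dict[str, set[str]]] = {}
    for sp, de in de_by_species.items():
        member_og = orthogroups.loc[
            orthogroups.species_id == sp, ["og_id", "gene_id"]
        ].set_index("gene_id")["og_id"]
        sets = {}
        for direction in ("up", "down"):
            genes = de.loc[de.call == direction, "gene_id"]
            sets[direction] = set(member_og.reindex(genes).dropna())
        out[sp] = sets
    return out


def upset_counts(sets_by_species: Mapping[str, set]) -> dict[frozenset, int]:
    """Exclusive intersection counts over every non-empty species subset.

    Each element is counted once, in the subset of exactly the species whose
    sets contain it, so the counts sum to the size of the union.
    """
    names = sorted(sets_by_species)
    counts: dict[frozenset, int] = {
        frozenset(sub): 0
        for r in range(1, len(names) + 1)
        for sub in combinations(names, r)
    }
    union = set().union(*sets_by_species.values()) if names else set()
    for element in union:
        membership = frozenset(n for n in names if element in sets_by_species[n])
        counts[membership] += 1
    return counts


def ssp_regulation_table(
    de_results: pd.DataFrame,
    class_by_gene: Mapping[str, str],
    partition_by_gene: Mapping[str, str],
    normalized: pd.DataFrame,
    conditions: pd.Series | Mapping[str, str],
    expression_floor: float = 5.0,
) -> pd.DataFrame:
    """Expressed and differentially expressed SSPs by pangenome partition.

    A gene is "expressed" when its normalized mean count reaches
    ``expression_floor`` in at least one condition.  Percent-specific values
    are rounded to the nearest integer (half up), matching the reporting
    convention of SSP tables.  Rows: expressed / up / down.
    """
    classes = pd.Series(class_by_gene)
    # SSP by the disjoint rule OR SSP-sized secreted enzymes are NOT included:
    # the SSP table follows the disjoint classification
    ssp_genes = set(classes.index[classes == "SSP"])
    cond = pd.Series(conditions).reindex(normalized.columns)
    parts = pd.Series(partition_by_gene)

    in_table = [g for g in normalized.index if g in ssp_genes]
    sub_norm = normalized.loc[in_table]
    expressed_mask = pd.Series(False, index=sub_norm.index)
    for level in cond.dropna().unique():
        expressed_mask |= sub_norm.loc[:, cond == level].mean(axis=1) >= expression_floor
    expressed = set(expressed_mask.index[expressed_mask])

    de_idx = de_results.set_index("gene_id")
    rows = []
    for label, genes in (
        ("expressed", expressed),
        ("up", {g for g in in_table if g in de_idx.index and de_idx.at[g, "call"] == "up"}),
        ("down", {g for g in in_table if g in de_idx.index and de_idx.at[g, "call"] == "down"}),
    ):
        labels = parts.reindex(sorted(genes))
        counts = labels.value_counts()
        total = len(genes)
        spec = int(counts.get("specific", 0))
        rows.append(
            {
                "category": label,
                "n_ssp": total,
                "core": int(counts.get("core", 0)),
                "accessory": int(counts.get("accessory", 0)),
                "specific": spec,
                "percent_specific": int(_round_half_up(100.0 * spec / total, 0))
                if total
                else 0,
            }
        )
    return pd.DataFrame(rows)
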