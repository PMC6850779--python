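"""Pooled CRISPR screen scoring: per-gene sgRNA enrichment with
permutation significance and FDR hit calling.

The enrichment statistic is the mean, over a gene's guides, of each
guide's sorted/unsorted normalized-abundance ratio.  Significance comes
from a permutation null that reassigns guide ratios to genes while
preserving each gene's guide count, with Benjamini-Hochberg FDR across
targeting genes; guides labeled with the reserved ``non-targeting``
pseudo-gene are scored but excluded from the BH family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NONTARGETING_GENE",
    "LibrarySummary",
    "assemble_library",
    "coverage_fold",
    "normalize_counts",
    "gene_enrichment_scores",
    "permutation_significance",
    "call_hits",
]

NONTARGETING_GENE = "non-targeting"

DEFAULT_PSEUDOCOUNT_RPM = 0.5


@dataclass
class LibrarySummary:
    manifest: pd.DataFrame  # guide_id, gene, is_control, is_nontargeting
    n_guides: int
    n_genes: int
    guides_per_gene: tuple[int, int]  # (min, max) over targeting genes


def assemble_library(
    targeting: list[tuple[str, str]],
    nontargeting: list[str] | None = None,
    controls: list[str] | None = None,
) -> LibrarySummary:
    """Join targeting guides, non-targeting controls and control genes.

    ``targeting`` is (guide_id, gene) pairs; ``controls`` marks genes that
    are positive controls (their guides are part of ``targeting``).
    Non-targeting guides are filed under the reserved pseudo-gene and do
    not count toward the gene total.
    """
    nontargeting = nontargeting or []
    controls = set(controls or [])
    rows = [
        {"guide_id": g, "gene": gene, "is_control": gene in controls,
         "is_nontargeting": False}
        for g, gene in targeting
    ]
    rows += [
        {"guide_id": g, "gene": NONTARGETING_GENE, "is_control": False,
         "is_nontargeting": True}
        for g in nontargeting
    ]
    manifest = pd.DataFrame(rows, columns=["guide_id", "gene", "is_control",
                                           "is_nontargeting"])
    dupes = manifest["guide_id"][manifest["guide_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate guide ids: {sorted(set(dupes))[:5]} ...")
    per_gene = manifest.loc[~manifest["is_nontargeting"]].groupby("gene").size()
    return LibrarySummary(
        manifest=manifest,
        n_guides=len(manifest),
        n_genes=int(per_gene.size),
        guides_per_gene=(int(per_gene.min()), int(per_gene.max())) if len(per_gene) else (0, 0),
    )


def coverage_fold(n_cells: int, library_size: int) -> float:
    """Cells per guide in the library (screen coverage)."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return n_cells / library_size


def _validate_table(table: pd.DataFrame) -> None:
    required = {"guide_id", "gene", "count_unsorted", "count_sorted"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if table["guide_id"].duplicated().any():
        raise ValueError("guide ids must be unique")
    if (table[["count_unsorted", "count_sorted"]] < 0).any().any():
        raise ValueError("counts must be nonnegative")


def normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Add reads-per-million columns for both populations."""
    _validate_table(table)
    out = table.copy()
    for pop in ("unsorted", "sorted"):
        total = out[f"count_{pop}"].sum()
        if total <= 0:
            raise ValueError(f"{pop} population has zero total reads")
        out[f"rpm_{pop}"] = out[f"count_{pop}"] * 1e6 / total
    return out


def gene_enrichment_scores(
    table: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT_RPM,
) -> pd.DataFrame:
    """Per-gene mean guide ratio (sorted over unsorted, RPM scale).

    Each guide's ratio is ``(rpm_sorted + c) / (rpm_unsorted + c)`` with
    pseudocount ``c`` guarding zero counts; the gene score is the
    arithmetic mean of its guides' ratios, reported with its log2 and a
    direction (enriched / depleted).
    """
    if "rpm_unsorted" not in table.columns:
        table = normalize_counts(table)
    ratios = (table["rpm_sorted"] + pseudocount) / (table["rpm_unsorted"] + pseudocount)
    work = table.assign(ratio=ratios)
    grouped = work.groupby("gene", sort=True)["ratio"].agg(["size", "mean"])
    result = pd.DataFrame(
        {
            "gene": grouped.index,
            "n_guides": grouped["size"].to_numpy(),
            "mean_ratio": grouped["mean"].to_numpy(),
        }
    ).reset_index(drop=True)
    result["log2_enrichment"] = np.log2(result["mean_ratio"])
    result["direction"] = np.where(result["log2_enrichment"] >= 0, "enriched", "depleted")
    return result


def permutation_significance(
    table: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT_RPM,
    chunk: int = 500,
) -> pd.DataFrame:
    """Permutation p-values and BH FDR for the gene enrichment scores.

    The null reassigns the observed guide ratios to genes at random,
    preserving each gene's guide count.  The two-sided empirical p-value
    for a gene is ``(1 + #{|null log2| >= |observed log2|}) / (n_perm + 1)``.
    BH is applied across targeting genes only; the non-targeting
    pseudo-gene keeps its p-value but gets no FDR.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if scores is None:
        scores = gene_enrichment_scores(table, pseudocount)
    if "rpm_unsorted" not in table.columns:
        table = normalize_counts(table)
    ratios = (
        (table["rpm_sorted"] + pseudocount) / (table["rpm_unsorted"] + pseudocount)
    ).to_numpy()

    # lay genes out contiguously so a shuffled ratio vector reduces per gene
    order = np.argsort(table["gene"].to_numpy(), kind="stable")
    genes_sorted = table["gene"].to_numpy()[order]
    boundaries = np.flatnonzero(np.r_[True, genes_sorted[1:] != genes_sorted[:-1]])
    gene_names = genes_sorted[boundaries]
    sizes = np.diff(np.r_[boundaries, len(genes_sorted)])

    obs = scores.set_index("gene").loc[gene_names]
    obs_abs_log2 = np.abs(obs["log2_enrichment"].to_numpy())

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(gene_names), dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perm = rng.permuted(np.broadcast_to(ratios, (b, len(ratios))).copy(), axis=1)
        null_means = np.add.reduceat(perm, boundaries, axis=1) / sizes
        null_abs_log2 = np.abs(np.log2(null_means))
        exceed += (null_abs_log2 >= obs_abs_log2).sum(axis=0)
        done += b

    p_perm = (1.0 + exceed) / (n_perm + 1.0)
    result = obs.reset_index()
    result["p_perm"] = p_perm

    targeting = result["gene"] != NONTARGETING_GENE
    fdr = np.full(len(result), np.nan)
    if targeting.any():
        fdr[targeting.to_numpy()] = multipletests(
            p_perm[targeting.to_numpy()], method="fdr_bh"
        )[1]
    result["fdr"] = fdr
    return result[["gene", "n_guides", "mean_ratio", "log2_enrichment",
                   "direction", "p_perm", "fdr"]]


def call_hits(results: pd.DataFrame, fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Genes at or below the FDR threshold, most significant first."""
    if "fdr" not in results.columns:
        raise ValueError("run permutation_significance first (no fdr column)")
    hits = results[results["fdr"] <= fdr_threshold].copy()
    return hits.sort_values(["fdr", "p_perm", "gene"]).reset_index(drop=True)
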