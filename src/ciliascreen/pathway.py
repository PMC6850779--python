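"""Pathway roll-up of screen results with an expression filter.

Genes with zero RPKM in both RNAseq replicates are dropped before
grouping; hits within each curated pathway are split into positive and
negative regulators according to the declared screen design (in a
bottom-tail sort under high ligand, guides *enriched* in the sorted bin
mark lost positive regulators).
"""

from __future__ import annotations

import logging

import pandas as pd

__all__ = ["filter_expressed", "pathway_summary", "load_annotations"]

logger = logging.getLogger(__name__)

# enrichment direction -> regulator class, per screen design
DESIGN_DIRECTION = {
    "bottom_high_ligand": {"enriched": "positive_regulator", "depleted": "negative_regulator"},
    "top_low_ligand": {"enriched": "negative_regulator", "depleted": "positive_regulator"},
}


def load_annotations(path) -> pd.DataFrame:
    """Read a two-column (pathway, gene) TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = {"pathway", "gene"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def filter_expressed(genes, expression: pd.DataFrame) -> list[str]:
    """Keep genes with RPKM > 0 in at least one RNAseq replicate.

    Genes absent from the expression table are treated as unexpressed
    (and logged), matching the rule that a gene with RPKM 0 in both
    replicates is excluded.
    """
    required = {"gene", "rpkm_rep1", "rpkm_rep2"}
    missing = required - set(expression.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    expr = expression.set_index("gene")
    kept = []
    for gene in genes:
        if gene not in expr.index:
            logger.info("gene %s missing from expression table; treated as unexpressed", gene)
            continue
        row = expr.loc[gene]
        if row["rpkm_rep1"] > 0 or row["rpkm_rep2"] > 0:
            kept.append(gene)
    return kept


def pathway_summary(
    annotations: pd.DataFrame,
    results: pd.DataFrame,
    expression: pd.DataFrame,
    fdr_threshold: float = 0.1,
    design: str = "bottom_high_ligand",
) -> pd.DataFrame:
    """Per-pathway hit table over expressed, screened genes.

    Returns one row per pathway with expressed-gene and hit counts, the
    hits split into positive/negative regulators, and member genes
    ordered by FDR.  Pathways whose genes are all unexpressed are
    dropped; annotated genes absent from the screen results are logged
    and skipped.
    """
    if design not in DESIGN_DIRECTION:
        raise ValueError(f"unknown screen design {design!r}")
    if "fdr" not in results.columns:
        raise ValueError("results lack an fdr column")
    direction_map = DESIGN_DIRECTION[design]
    scored = results.set_index("gene")

    rows = []
    for pathway, members in annotations.groupby("pathway", sort=True):
        genes = list(dict.fromkeys(members["gene"]))
        unknown = [g for g in genes if g not in scored.index]
        for g in unknown:
            logger.info("pathway %s: gene %s not in screen results; skipped", pathway, g)
        genes = [g for g in genes if g in scored.index]
        expressed = filter_expressed(genes, expression)
        if not expressed:
            continue
        sub = scored.loc[expressed].sort_values("fdr")
        hits = sub[sub["fdr"] <= fdr_threshold]
        regulator = hits["direction"].map(direction_map)
        rows.append(
            {
                "pathway": pathway,
                "n_genes_expressed": len(expressed),
                "n_hits": len(hits),
                "positive_regulators": ",".join(
                    hits.index[regulator == "positive_regulator"]
                ),
                "negative_regulators": ",".join(
                    hits.index[regulator == "negative_regulator"]
                ),
                "genes_by_fdr": ",".join(sub.index),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pathway", "n_genes_expressed", "n_hits",
                 "positive_regulators", "negative_regulators", "genes_by_fdr"],
    )
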