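"""Bookkeeping layer: candidate regions from association results, genes in
regions, and deleterious-variant / candidate-region overlap summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .selection import genes_overlapping


def variants_in_genes(variants: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    """Boolean mask: variant position falls inside a gene body (inclusive)."""
    mask = np.zeros(len(variants), dtype=bool)
    pos = variants["pos"].to_numpy()
    chroms = variants["chrom"].to_numpy()
    for t in genes.itertuples(index=False):
        mask |= (chroms == t.chrom) & (pos >= t.start) & (pos <= t.end)
    return mask


def define_candidate_regions(
    assoc: pd.DataFrame,
    threshold: float,
    flank_bp: int = 50_000,
    trait: str = "trait",
    p_column: str = "p_wald",
) -> pd.DataFrame:
    """Clump significant variants into candidate regions.

    Variants with p <= ``threshold`` are flanked by ``flank_bp`` on each
    side (clipped at 1) and overlapping windows merge; the lead variant of
    a clump is its smallest p. Merging is idempotent. Returns columns
    ``trait, chrom, start, end, lead_id, lead_pos, lead_p``.
    """
    cols = ["trait", "chrom", "start", "end", "lead_id", "lead_pos", "lead_p"]
    sig = assoc[assoc[p_column] <= threshold].sort_values(["chrom", "pos"])
    if sig.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        cur = None
        for t in grp.itertuples(index=False):
            lo = max(int(t.pos) - flank_bp, 1)
            hi = int(t.pos) + flank_bp
            p = getattr(t, p_column)
            if cur is None:
                cur = [chrom, lo, hi, t.id, int(t.pos), p]
            elif lo <= cur[2]:
                cur[2] = max(cur[2], hi)
                if p < cur[5]:
                    cur[3], cur[4], cur[5] = t.id, int(t.pos), p
            else:
                rows.append(cur)
                cur = [chrom, lo, hi, t.id, int(t.pos), p]
        rows.append(cur)
    out = pd.DataFrame(rows, columns=cols[1:])
    out.insert(0, "trait", trait)
    return out


def genes_in_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> dict[str, set]:
    """Per-trait candidate gene sets (>= 1 bp overlap, deduplicated)."""
    out: dict[str, set] = {}
    if regions.empty:
        return out
    for trait, grp in regions.groupby("trait", sort=False):
        out[trait] = genes_overlapping(grp[["chrom", "start", "end"]], genes)
    return out


def deleterious_overlap(
    variants: pd.DataFrame,
    deleterious: np.ndarray,
    regions: pd.DataFrame,
    genes: pd.DataFrame,
) -> dict:
    """Counts of deleterious variants in candidate regions and gene bodies.

    Returns per-trait and per-chromosome counts, the pooled (trait-unioned)
    totals, and SV-class variants overlapping candidate genes. All interval
    checks are 1-based inclusive.
    """
    pos = variants["pos"].to_numpy()
    chroms = variants["chrom"].to_numpy()
    vclass = variants["vclass"].to_numpy()
    dele = np.asarray(deleterious, dtype=bool)
    gene_sets = genes_in_regions(regions, genes)

    def in_intervals(df: pd.DataFrame, start_col="start", end_col="end") -> np.ndarray:
        m = np.zeros(len(variants), dtype=bool)
        for t in df.itertuples(index=False):
            m |= ((chroms == t.chrom)
                  & (pos >= getattr(t, start_col)) & (pos <= getattr(t, end_col)))
        return m

    per_trait = {}
    union_region = np.zeros(len(variants), dtype=bool)
    union_gene = np.zeros(len(variants), dtype=bool)
    for trait, grp in (regions.groupby("trait", sort=False) if not regions.empty else []):
        in_reg = in_intervals(grp)
        gset = gene_sets.get(trait, set())
        gsub = genes[genes["gene_id"].isin(gset)]
        in_gene = in_intervals(gsub) if not gsub.empty else np.zeros(len(variants), bool)
        union_region |= in_reg
        union_gene |= in_gene
        per_trait[trait] = {
            "n_candidate_genes": len(gset),
            "n_deleterious_in_regions": int((dele & in_reg).sum()),
            "n_deleterious_in_gene_bodies": int((dele & in_gene).sum()),
            "n_sv_in_gene_bodies": int(((vclass == "SV") & in_gene).sum()),
        }
    per_chrom = (
        pd.Series(chroms[dele & union_region]).value_counts().to_dict()
        if union_region.any() else {}
    )
    all_genes = set().union(*gene_sets.values()) if gene_sets else set()
    return {
        "per_trait": per_trait,
        "per_chromosome_deleterious_in_regions": per_chrom,
        "total_deleterious_in_regions": int((dele & union_region).sum()),
        "total_deleterious_in_gene_bodies": int((dele & union_gene).sum()),
        "n_candidate_genes_union": len(all_genes),
        "n_sv_in_candidate_genes": int(((vclass == "SV") & union_gene).sum()),
    }
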