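"""Readers, writers and site/genotype filtering for the standard formats.

VCF in/out (biallelic GT + GQ), GFF3 gene models, BED3 export, and the TSV
tables used across the pipeline (population map, phenotypes, SIFT
annotations, gene-family presence/absence matrix). All table readers and
writers round-trip.
"""

from __future__ import annotations

import logging



import numpy as np
import pandas as pd

from .core import (
    MISSING,
    ConfigError,
    FilterConfig,
    GenotypeMatrix,
    ParseError,
    VARIANT_COLUMNS,
    validate_population_map,
    variant_class,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, gq_mask: int | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are skipped (count logged). Genotypes with
    GQ < ``gq_mask`` are set missing. Phased and unphased genotypes are
    treated identically; half calls (``./1``) are missing. Variant class is
    assigned from allele lengths (> 50 bp on either allele -> SV).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib reports its own context
        raise ParseError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    rows, gcols, gqcols = [], [], []
    n_multi = 0
    has_gq = True
    try:
        for rec in vcf:
            if len(rec.ALT) != 1:
                n_multi += 1
                continue
            alleles = np.array(rec.genotypes, dtype=object)
            codes = np.empty(len(samples), dtype=np.int8)
            for i, gt in enumerate(rec.genotypes):
                a = gt[:-1]  # last element is the phase flag
                if len(a) < 2 or any(x is None or x < 0 for x in a):
                    codes[i] = MISSING
                else:
                    codes[i] = int(a[0] > 0) + int(a[1] > 0)
            gq = rec.gt_quals if has_gq else None
            if gq is None or (np.asarray(gq) < 0).all():
                has_gq = has_gq and gq is not None
            rows.append(
                (rec.CHROM, rec.POS, rec.ID or f"{rec.CHROM}_{rec.POS}",
                 rec.REF, rec.ALT[0], variant_class(rec.REF, rec.ALT[0]))
            )
            gcols.append(codes)
            if gq is not None:
                gqcols.append(np.asarray(gq, dtype=np.float32))
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"malformed VCF record in {path!r}: {exc}") from exc
    if n_multi:
        log.info("read_vcf: skipped %d multiallelic records", n_multi)
    if not rows:
        raise ParseError(f"no biallelic records in {path!r}")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    G = np.vstack(gcols).T  # samples x variants
    GQ = np.vstack(gqcols).T if len(gqcols) == len(rows) else None
    if gq_mask is not None and GQ is not None:
        G = np.where((GQ >= 0) & (GQ < gq_mask), MISSING, G).astype(np.int8)
    return GenotypeMatrix(samples=samples, variants=variants, G=G, GQ=GQ)


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as a minimal VCF v4.2 (GT:GQ)."""
    chroms = g.variants["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=milletpop\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        has_gq = g.GQ is not None
        fmt = "GT:GQ" if has_gq else "GT"
        for j, v in enumerate(g.variants.itertuples(index=False)):
            fields = [v.chrom, str(v.pos), str(v.id), v.ref, v.alt, ".", "PASS", ".", fmt]
            for i in range(g.n_samples):
                s = gt_str[int(g.G[i, j])]
                if has_gq:
                    s += f":{int(g.GQ[i, j])}"
                fields.append(s)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Filtering (VCFtools semantics)
# ---------------------------------------------------------------------------

def filter_variants(g: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Apply site filters, VCFtools semantics.

    Retains sites with call rate >= ``cfg.max_missing_rate`` (``--max-missing``
    is a keep threshold) and minor-allele frequency >= ``cfg.min_maf``
    computed on called alleles only. If ``cfg.min_gq`` > 0 and the matrix
    carries GQ, genotypes below the threshold are masked to missing first,
    so both criteria see the post-mask call set. Returns a new matrix.
    """
    if not isinstance(cfg, FilterConfig):
        raise ConfigError("cfg must be a FilterConfig")
    G = g.G
    if cfg.min_gq > 0 and g.GQ is not None:
        G = np.where((g.GQ >= 0) & (g.GQ < cfg.min_gq), MISSING, G).astype(np.int8)
    masked = GenotypeMatrix(g.samples, g.variants.copy(), G.copy(),
                            None if g.GQ is None else g.GQ.copy())
    called = masked.called()
    call_rate = called.mean(axis=0)
    ac, an = masked.alt_allele_stats()
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(an > 0, ac / np.maximum(an, 1), 0.0)
    maf = np.minimum(af, 1.0 - af)
    keep = (call_rate >= cfg.max_missing_rate) & (an > 0) & (maf >= cfg.min_maf)
    log.info("filter_variants: retained %d of %d sites", int(keep.sum()), g.n_variants)
    return masked.take_variants(keep)


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

def read_gff_genes(path: str) -> pd.DataFrame:
    """Extract gene features from a GFF3 file.

    Returns a DataFrame with columns ``gene_id, chrom, start, end, strand``
    (1-based inclusive coordinates). Duplicate gene ids are an error.
    """
    import gffutils

    try:
        db = gffutils.create_db(path, ":memory:", force=True,
                                merge_strategy="create_unique", keep_order=True)
    except Exception as exc:
        raise ParseError(f"cannot parse GFF3 {path!r}: {exc}") from exc
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gid, feat.seqid, feat.start, feat.end, feat.strand))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if genes.empty:
        raise ParseError(f"no gene features in {path!r}")
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        raise ParseError(f"duplicated gene ids in {path!r}: {dups[:5]}")
    if (genes["start"] > genes["end"]).any():
        raise ParseError(f"gene with start > end in {path!r}")
    return genes.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_gff_genes(genes: pd.DataFrame, path: str) -> None:
    """Write gene models as a minimal GFF3 (inverse of :func:`read_gff_genes`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in genes.itertuples(index=False):
            fh.write(f"{t.chrom}\tmilletpop\tgene\t{t.start}\t{t.end}\t.\t"
                     f"{t.strand}\t.\tID={t.gene_id}\n")


def write_bed(regions: pd.DataFrame, path: str) -> None:
    """Write 1-based inclusive regions (chrom, start, end[, name]) as BED3/4."""
    with open(path, "w") as fh:
        for t in regions.itertuples(index=False):
            line = f"{t.chrom}\t{int(t.start) - 1}\t{int(t.end)}"
            if hasattr(t, "name") and t.name is not None:
                line += f"\t{t.name}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_population_map(path: str) -> pd.Series:
    """Read a two-column TSV (sample, group) into a Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"population map {path!r} needs columns (sample, group)")
    df.columns = ["sample", "group"] + list(df.columns[2:])
    if df["sample"].duplicated().any():
        raise ParseError(f"duplicated sample ids in {path!r}")
    pops = df.set_index("sample")["group"]
    unknown = set(pops.unique()) - {"wild", "cultivated", "outgroup"}
    if unknown:
        raise ParseError(f"unknown group labels in {path!r}: {sorted(unknown)}")
    return pops


def write_population_map(pops: pd.Series, path: str) -> None:
    pops.rename("group").rename_axis("sample").reset_index().to_csv(
        path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read a sample x trait TSV; first column is the sample id."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ParseError(f"empty phenotype table {path!r}")
    sample_col = df.columns[0]
    if df[sample_col].duplicated().any():
        raise ParseError(f"duplicated sample ids in {path!r}")
    return df.set_index(sample_col).rename_axis("sample")


def write_phenotypes(phen: pd.DataFrame, path: str) -> None:
    phen.rename_axis("sample").reset_index().to_csv(path, sep="\t", index=False)


def read_annotations(path: str) -> pd.DataFrame:
    """Read a per-variant annotation TSV (chrom, pos, ref, alt, sift_score[, ...])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "sift_score"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"annotation table {path!r} missing columns {sorted(missing)}")
    return df


def write_annotations(ann: pd.DataFrame, path: str) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_pam(path: str) -> pd.DataFrame:
    """Read a gene-family presence/absence matrix TSV.

    First column is the family id; remaining columns are genomes with 0/1
    entries. An empty file or non-binary entries are errors.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"empty presence/absence matrix {path!r}") from exc
    if df.empty or df.shape[1] < 2:
        raise ParseError(f"presence/absence matrix {path!r} is empty")
    fam_col = df.columns[0]
    if df[fam_col].duplicated().any():
        raise ParseError(f"duplicated family ids in {path!r}")
    pam = df.set_index(fam_col).rename_axis("family_id")
    vals = pam.to_numpy()
    if not np.isin(vals, [0, 1]).all():
        raise ParseError(f"non-binary entries in {path!r}")
    return pam.astype(np.int8)


def write_pam(pam: pd.DataFrame, path: str) -> None:
    pam.rename_axis("family_id").reset_index().to_csv(path, sep="\t", index=False)
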