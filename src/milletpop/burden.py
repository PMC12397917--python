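"""Deleterious-burden analysis: outgroup polarization, SIFT-based
classification, per-individual burdens under three dominance models, and
wild-vs-cultivated group comparison.

The additive burden of an individual is het + 2*hom-derived over the chosen
site set; heterozygous and homozygous models count the carrier classes
separately. Burdens are reported both raw and per called site, since groups
can differ in missingness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, ConfigError, GenotypeMatrix, group_samples

log = logging.getLogger(__name__)

MODELS = ("het", "hom", "additive")


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

def polarize(
    g: GenotypeMatrix,
    pops: pd.Series,
    min_outgroup_calls: int = 1,
    tol: float = 0.0,
) -> pd.Series:
    """Infer the ancestral allele of each site from the outgroup.

    The ancestral allele is the one at frequency >= 1 - ``tol`` among called
    outgroup alleles; sites with fewer than ``min_outgroup_calls`` called
    outgroup genotypes, or too polymorphic an outgroup, are 'unpolarized'.

    Returns a Series aligned with ``g.variants`` with values in
    {'ref', 'alt', 'unpolarized'}.
    """
    out_samples = group_samples(pops, "outgroup")
    out_samples = [s for s in out_samples if s in g.samples]
    if not out_samples:
        raise ValueError("no outgroup samples in the population map")
    sub = g.take_samples(out_samples)
    called = sub.called()
    n_called = called.sum(axis=0)
    ac, an = sub.alt_allele_stats()
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
    anc = np.full(g.n_variants, "unpolarized", dtype=object)
    ok = n_called >= max(min_outgroup_calls, 1)
    anc[ok & (alt_freq <= tol)] = "ref"
    anc[ok & (alt_freq >= 1.0 - tol)] = "alt"
    return pd.Series(anc, name="ancestral")


def classify_deleterious(
    ann: pd.DataFrame,
    threshold: float = 0.05,
) -> pd.Series:
    """Flag deleterious variants: SIFT score strictly below ``threshold``,
    site polarized, and the derived allele is the substituting (ALT) allele.

    ``ann`` must carry ``sift_score`` and ``ancestral`` columns. Missing
    scores are never deleterious (tallied in the log).
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigError("threshold must be in (0, 1]")
    score = pd.to_numeric(ann["sift_score"], errors="coerce")
    n_unscored = int(score.isna().sum())
    if n_unscored:
        log.info("classify_deleterious: %d sites without a SIFT score", n_unscored)
    valid = score.notna() & (score >= 0) & (score <= 1)
    if (score.notna() & ~valid).any():
        raise ValueError("SIFT scores must be in [0, 1]")
    # derived = ALT only where the ancestral allele is REF
    flags = valid & (score < threshold) & (ann["ancestral"] == "ref")
    return flags.rename("deleterious")


# ---------------------------------------------------------------------------
# Burden
# ---------------------------------------------------------------------------

def derived_dosage(g: GenotypeMatrix, ancestral: pd.Series) -> np.ndarray:
    """Genotype codes recoded to count derived alleles.

    Sites where the ancestral allele is ALT have codes swapped (0 <-> 2);
    unpolarized sites are set entirely missing.
    """
    G = g.G.astype(np.int8).copy()
    anc = np.asarray(ancestral)
    flip = anc == "alt"
    called = G != MISSING
    G[:, flip] = np.where(called[:, flip], 2 - G[:, flip], MISSING)
    G[:, anc == "unpolarized"] = MISSING
    return G


def burden_per_individual(
    g: GenotypeMatrix,
    ann: pd.DataFrame,
    site_set: str = "deleterious_snp",
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample burden counts over a chosen site set.

    ``site_set`` is one of ``deleterious_snp`` (polarized deleterious SNPs),
    ``all_sv`` (all polarized SVs) or ``genic_sv`` (polarized SVs overlapping
    a gene model, requires ``genes``). Returns a DataFrame indexed by sample
    with raw counts (n_het, n_hom, additive), n_called, and per-called-site
    rates.
    """
    vclass = g.variants["vclass"].to_numpy()
    anc = np.asarray(ann["ancestral"])
    polarized = anc != "unpolarized"
    if site_set == "deleterious_snp":
        mask = polarized & np.asarray(ann["deleterious"], dtype=bool) & (vclass == "SNP")
    elif site_set == "all_sv":
        mask = polarized & (vclass == "SV")
    elif site_set == "genic_sv":
        if genes is None:
            raise ValueError("genic_sv requires gene models")
        from .annotate import variants_in_genes
        genic = variants_in_genes(g.variants, genes)
        mask = polarized & (vclass == "SV") & genic
    else:
        raise ConfigError(f"unknown site set {site_set!r}")
    if not mask.any():
        raise ValueError(f"site set {site_set!r} is empty")

    D = derived_dosage(g, ann["ancestral"])[:, mask]
    called = D != MISSING
    n_het = (D == 1).sum(axis=1)
    n_hom = (D == 2).sum(axis=1)
    n_called = called.sum(axis=1)
    out = pd.DataFrame({
        "n_het": n_het,
        "n_hom": n_hom,
        "additive": n_het + 2 * n_hom,
        "n_called": n_called,
    }, index=pd.Index(g.samples, name="sample"))
    with np.errstate(invalid="ignore", divide="ignore"):
        for m in MODELS:
            col = {"het": "n_het", "hom": "n_hom", "additive": "additive"}[m]
            out[f"rate_{m}"] = np.where(n_called > 0, out[col] / n_called, np.nan)
    return out


@dataclass
class GroupComparison:
    model: str
    mean_wild: float
    mean_cultivated: float
    reduction_percent: float | None
    ci_low: float | None
    ci_high: float | None
    p_ranksum: float
    n_wild: int
    n_cultivated: int


def compare_groups(
    b: pd.DataFrame,
    pops: pd.Series,
    model: str = "additive",
    rate: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> GroupComparison:
    """Wild vs cultivated burden comparison for one dominance model.

    Reports group means, the percent reduction in cultivars
    100*(mean_wild - mean_cult)/mean_wild, a bootstrap CI for it, and a
    two-sided Wilcoxon rank-sum p-value. ``rate=True`` compares per-called-
    site rates instead of raw counts.
    """
    if model not in MODELS:
        raise ConfigError(f"model must be one of {MODELS}")
    col = f"rate_{model}" if rate else {"het": "n_het", "hom": "n_hom",
                                        "additive": "additive"}[model]
    wild = b.loc[[s for s in b.index if pops.get(s) == "wild"], col].to_numpy(float)
    cult = b.loc[[s for s in b.index if pops.get(s) == "cultivated"], col].to_numpy(float)
    if len(wild) < 2 or len(cult) < 2:
        raise ValueError("both groups need >= 2 samples")
    mw, mc = wild.mean(), cult.mean()
    stat = stats.ranksums(wild, cult)
    if mw == 0:
        return GroupComparison(model, mw, mc, None, None, None,
                               float(stat.pvalue), len(wild), len(cult))
    red = 100.0 * (mw - mc) / mw
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bw = rng.choice(wild, size=len(wild), replace=True).mean()
        bc = rng.choice(cult, size=len(cult), replace=True).mean()
        boots[i] = 100.0 * (bw - bc) / bw if bw != 0 else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return GroupComparison(model, float(mw), float(mc), float(red),
                           float(lo), float(hi), float(stat.pvalue),
                           len(wild), len(cult))


def sv_sharing(g: GenotypeMatrix, pops: pd.Series) -> dict:
    """Counts of SVs segregating in both groups / only wild / only cultivated.

    An SV 'occurs' in a group if at least one called genotype carries at
    least one ALT allele.
    """
    sv_idx = np.flatnonzero(g.variants["vclass"].to_numpy() == "SV")
    if sv_idx.size == 0:
        raise ValueError("no SV-class sites")
    sub = g.take_variants(sv_idx)
    wild = sub.take_samples([s for s in sub.samples if pops.get(s) == "wild"])
    cult = sub.take_samples([s for s in sub.samples if pops.get(s) == "cultivated"])
    in_w = ((wild.G == 1) | (wild.G == 2)).any(axis=0)
    in_c = ((cult.G == 1) | (cult.G == 2)).any(axis=0)
    return {
        "shared": int((in_w & in_c).sum()),
        "wild_only": int((in_w & ~in_c).sum()),
        "cultivated_only": int((~in_w & in_c).sum()),
    }
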