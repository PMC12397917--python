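"""Selection scans: windowed Hudson FST, the population branch statistic
(PBS) with empirical p-values, and a composite likelihood ratio (CLR) sweep
scan of the SweepFinder family, plus candidate-region intersection.

PBS for the focal (cultivated) branch is (T_cw + T_co - T_wo)/2 with
T = -log(1 - FST), so allele-frequency change specific to the cultivated
lineage accumulates on its branch. The CLR scan compares the composite
likelihood of local site frequency spectra under a hitchhiking model (each
lineage escapes a sweep at distance d with probability 1 - exp(-alpha*d))
against the genome-wide background spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import ConfigError, GenotypeMatrix, group_samples

FST_EPS = 1e-6


# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------

def hudson_fst_components(
    ac1: np.ndarray, an1: np.ndarray, ac2: np.ndarray, an2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson estimator components.

    N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1), D = p1(1-p2)+p2(1-p1)
    with p the alt/derived frequency and n the called allele numbers.
    Sites with n < 2 alleles in either population get NaN components and
    are excluded from window sums.
    """
    ac1, an1, ac2, an2 = (np.asarray(a, dtype=float) for a in (ac1, an1, ac2, an2))
    ok = (an1 >= 2) & (an2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = ac1 / an1
        p2 = ac2 / an2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (an1 - 1) - p2 * (1 - p2) / (an2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    return num, den


def hudson_fst(
    ac1: np.ndarray, an1: np.ndarray, ac2: np.ndarray, an2: np.ndarray
) -> float:
    """Windowed Hudson FST: ratio of averaged components (sum N / sum D)."""
    num, den = hudson_fst_components(ac1, an1, ac2, an2)
    sn, sd = np.nansum(num), np.nansum(den)
    return float(sn / sd) if sd != 0 else np.nan


def allele_counts(g: GenotypeMatrix, pops: pd.Series, group: str) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele count, called allele number) per site for one group."""
    names = [s for s in g.samples if pops.get(s) == group]
    if not names:
        raise ValueError(f"no samples in group {group!r}")
    return g.take_samples(names).alt_allele_stats()


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    """SNP-count window: ``snps_per_window`` SNPs, start every ``step_snps``.

    The upstream convention of window 100 / step 101 yields non-overlapping
    windows that skip one SNP between consecutive windows; both knobs are
    free here.
    """

    snps_per_window: int = 100
    step_snps: int = 101

    def __post_init__(self) -> None:
        if self.snps_per_window < 1 or self.step_snps < 1:
            raise ConfigError("window and step must be >= 1")


def make_windows(variants: pd.DataFrame, spec: WindowSpec) -> list[np.ndarray]:
    """Per-chromosome windows of variant indices (into ``variants``).

    Windows contain exactly ``snps_per_window`` consecutive variants starting
    at per-chromosome offsets 0, step, 2*step, ...; trailing partial windows
    are dropped. ``variants`` must be sorted by (chrom, pos).
    """
    out: list[np.ndarray] = []
    for _, idx in variants.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        n = idx.size
        for start in range(0, n - spec.snps_per_window + 1, spec.step_snps):
            out.append(idx[start:start + spec.snps_per_window])
    return out


# ---------------------------------------------------------------------------
# PBS
# ---------------------------------------------------------------------------

def branch_length(fst: float) -> float:
    """T = -log(1 - FST), with FST clamped into [0, 1 - 1e-6] first."""
    f = min(max(float(fst), 0.0), 1.0 - FST_EPS)
    return -np.log(1.0 - f)


def pbs(fst_cw: float, fst_co: float, fst_wo: float) -> float:
    """PBS of the cultivated branch from the three pairwise window FSTs."""
    t_cw, t_co, t_wo = (branch_length(f) for f in (fst_cw, fst_co, fst_wo))
    return (t_cw + t_co - t_wo) / 2.0


def pbs_scan(
    g: GenotypeMatrix,
    pops: pd.Series,
    spec: WindowSpec = WindowSpec(),
) -> pd.DataFrame:
    """Windowed FST triplets and cultivated-branch PBS with empirical p.

    Returns one row per window: chrom, start, end (bp span of included
    SNPs), n_snps, fst_cw, fst_co, fst_wo, pbs, p_emp.
    """
    ac_c, an_c = allele_counts(g, pops, "cultivated")
    ac_w, an_w = allele_counts(g, pops, "wild")
    ac_o, an_o = allele_counts(g, pops, "outgroup")
    ncw, dcw = hudson_fst_components(ac_c, an_c, ac_w, an_w)
    nco, dco = hudson_fst_components(ac_c, an_c, ac_o, an_o)
    nwo, dwo = hudson_fst_components(ac_w, an_w, ac_o, an_o)
    windows = make_windows(g.variants, spec)
    rows = []
    chroms = g.variants["chrom"].to_numpy()
    positions = g.variants["pos"].to_numpy()
    for w in windows:
        def ratio(num, den):
            sn, sd = np.nansum(num[w]), np.nansum(den[w])
            return sn / sd if sd != 0 else np.nan
        f_cw, f_co, f_wo = ratio(ncw, dcw), ratio(nco, dco), ratio(nwo, dwo)
        rows.append((chroms[w[0]], positions[w[0]], positions[w[-1]], w.size,
                     f_cw, f_co, f_wo, pbs(f_cw, f_co, f_wo)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                     "fst_cw", "fst_co", "fst_wo", "pbs"])
    df["p_emp"] = empirical_p(df["pbs"].to_numpy())
    return df


def empirical_p(values: np.ndarray) -> np.ndarray:
    """Add-one right-tail rank p: p_w = (1 + #{j != w : v_j >= v_w}) / (n + 1)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    sv = np.sort(v)
    ge_others = n - np.searchsorted(sv, v, side="left") - 1
    return (1.0 + ge_others) / (n + 1.0)


def significant_windows(
    df: pd.DataFrame, p_cut: float = 0.05, top_frac: float = 0.10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(p <= 0.05 windows, smallest-10%-p windows)."""
    sig = df[df["p_emp"] <= p_cut]
    k = max(int(np.floor(top_frac * len(df))), 1)
    top = df.nsmallest(k, "p_emp", keep="first")
    return sig, top


def permutation_p(
    g: GenotypeMatrix,
    pops: pd.Series,
    spec: WindowSpec,
    n_perm: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Label-permutation null for window PBS (wild/cultivated labels shuffled)."""
    rng = np.random.default_rng(seed)
    obs = pbs_scan(g, pops, spec)["pbs"].to_numpy()
    focal = [s for s in pops.index if pops[s] in ("wild", "cultivated")]
    labels = pops.loc[focal].to_numpy().copy()
    exceed = np.zeros(obs.size)
    for _ in range(n_perm):
        rng.shuffle(labels)
        perm = pops.copy()
        perm.loc[focal] = labels
        null = pbs_scan(g, perm, spec)["pbs"].to_numpy()
        exceed += null >= obs
    return (1.0 + exceed) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# CLR sweep scan (SweepFinder-family model)
# ---------------------------------------------------------------------------

def background_sfs(derived_counts: np.ndarray, n: int, pseudocount: float = 0.5) -> np.ndarray:
    """Background probability of derived count j in {0..n} over all polarized
    sites genome-wide (invariant classes included: the dearth of polymorphism
    around a sweep is part of its footprint), with a small pseudocount so no
    class has probability zero."""
    counts = np.bincount(derived_counts, minlength=n + 1).astype(float)
    counts += pseudocount
    return counts / counts.sum()


class SweepModel:
    """Single-sweep hitchhiking likelihood for fixed sample size n.

    Conditional on a pre-sweep derived count j ~ background, each of the n
    sampled lineages independently escapes the sweep with probability
    p_e = 1 - exp(-alpha d). The hitchhiking lineage is derived with
    probability j/n; non-escaping lineages all carry its allele, escaping
    lineages resample the pre-sweep frequency binomially. The support is the
    full spectrum 0..n, so sites driven to fixation (or extinction) by the
    sweep contribute likelihood.
    """

    def __init__(self, pi: np.ndarray, n: int):
        if len(pi) != n + 1:
            raise ValueError("background spectrum must have length n + 1")
        self.n = n
        self.pi = np.asarray(pi, dtype=float)
        self._build_tables()

    def _build_tables(self) -> None:
        from scipy.stats import binom as binom_dist

        n = self.n
        j = np.arange(0, n + 1)  # pre-sweep derived counts
        fj = j / n
        # B[e, j, k] = P(Binom(e, j/n) = k); binom.pmf handles fj in {0, 1}
        B = np.zeros((n + 1, n + 1, n + 1))
        k = np.arange(n + 1)
        for ei in range(n + 1):
            B[ei] = binom_dist.pmf(k[None, :], ei, fj[:, None])
        # T0[e, k]: hitchhiker ancestral; T1[e, k']: hitchhiker derived, and
        # the final count is k' + (n - e) non-escaping derived lineages.
        w0 = self.pi * (1 - fj)
        w1 = self.pi * fj
        self.T0 = np.einsum("j,ejk->ek", w0, B)
        self.T1 = np.einsum("j,ejk->ek", w1, B)
        T = np.zeros((n + 1, n + 1))
        for ei in range(n + 1):
            T[ei] += self.T0[ei]
            shift = n - ei
            T[ei, shift:] += self.T1[ei, : n + 1 - shift]
        self.T = T

    def escape_weights(self, p_e: np.ndarray) -> np.ndarray:
        """Binomial(n, p_e) pmf over the number of escaping lineages."""
        n = self.n
        e = np.arange(n + 1)
        p = np.clip(np.asarray(p_e, dtype=float)[..., None], 1e-300, 1.0)
        logC = gammaln(n + 1) - gammaln(e + 1) - gammaln(n - e + 1)
        with np.errstate(divide="ignore"):
            lw = logC + e * np.log(p) + (n - e) * np.log1p(-np.clip(p, 0, 1 - 1e-16))
        w = np.exp(lw)
        w /= w.sum(axis=-1, keepdims=True)
        return w

    def site_log_prob(self, k: np.ndarray, p_e: np.ndarray) -> np.ndarray:
        """log P(post-sweep derived count k | escape prob p_e)."""
        W = self.escape_weights(p_e)  # sites x (n+1)
        num = np.einsum("se,se->s", W, self.T[:, k].T)
        with np.errstate(divide="ignore"):
            return np.log(num)

    def background_log_prob(self, k: np.ndarray) -> np.ndarray:
        return np.log(self.pi[np.asarray(k)])


@dataclass
class ClrPoint:
    chrom: str
    position: int
    alpha_hat: float
    clr: float


def clr_scan(
    g: GenotypeMatrix,
    pops: pd.Series,
    target: str = "cultivated",
    ancestral: pd.Series | None = None,
    grid_bp: int = 1000,
    n_alpha: int = 50,
    max_sites: int = 200,
    n_haplotypes: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """CLR sweep scan over a position grid in the target population.

    Sites must be polarized (``ancestral`` in {'ref','alt'}; unpolarized
    sites are dropped, and an all-unpolarized input is an error). The
    likelihood needs a constant sample size: derived counts are subsampled
    without replacement (hypergeometric, seeded) to ``n_haplotypes`` called
    haplotypes, by default the 10th percentile of per-site call counts;
    sites with fewer calls are dropped. At each grid point the sweep
    intensity alpha is maximized over ``n_alpha`` log-spaced values; the CLR
    is clamped at 0, which makes the background model the null boundary of
    the family.
    """
    names = group_samples(pops, target)
    names = [s for s in names if s in g.samples]
    sub = g.take_samples(names)
    if ancestral is None:
        raise ValueError("clr_scan requires polarized sites: run polarize() first")
    anc = np.asarray(ancestral)
    polarized = anc != "unpolarized"
    if not polarized.any():
        raise ValueError("no polarized sites: run polarize() first")
    sub = sub.take_variants(polarized)
    anc = anc[polarized]
    called = sub.called()
    an = 2 * called.sum(axis=0)
    alt_count = np.where(called, sub.G, 0).sum(axis=0)
    derived_full = np.where(anc == "alt", an - alt_count, alt_count)
    if n_haplotypes is None:
        n = int(np.percentile(an[an > 0], 10))
        n = max(n, 4)
    else:
        n = int(n_haplotypes)
    keep = an >= n
    if not keep.any():
        raise ValueError("no polarized sites with enough called haplotypes")
    rng = np.random.default_rng(seed)
    derived = rng.hypergeometric(derived_full[keep],
                                 an[keep] - derived_full[keep], n)
    variants = sub.variants.loc[keep].reset_index(drop=True)
    return _clr_scan_counts(variants, derived, n, grid_bp, n_alpha, max_sites)


def _derived_counts(dos_alt: np.ndarray, anc: np.ndarray) -> np.ndarray:
    """Per-site derived allele counts from ALT dosages and ancestral labels
    (fully-called matrices)."""
    n_hap = 2 * dos_alt.shape[0]
    alt_count = dos_alt.sum(axis=0)
    return np.where(anc == "alt", n_hap - alt_count, alt_count)


def _clr_scan_counts(
    variants: pd.DataFrame,
    derived: np.ndarray,
    n: int,
    grid_bp: int,
    n_alpha: int,
    max_sites: int,
) -> pd.DataFrame:
    if len(variants) == 0:
        raise ValueError("no polarized fully-called sites for the CLR scan")
    pi = background_sfs(derived, n)
    model = SweepModel(pi, n)
    rows = []
    for chrom, idx in variants.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        pos = variants["pos"].to_numpy()[idx]
        k = derived[idx]
        lo, hi = pos.min(), pos.max()
        grid = np.arange(lo, hi + 1, grid_bp)
        span = max(hi - lo, 1)
        spacing = max(np.median(np.diff(np.sort(pos))) if pos.size > 1 else 1.0, 1.0)
        alphas = np.logspace(np.log10(0.01 / span), np.log10(100.0 / spacing), n_alpha)
        l0 = model.background_log_prob(k)
        for x in grid:
            d = np.abs(pos - x)
            if d.size > max_sites:
                nearest = np.argpartition(d, max_sites)[:max_sites]
            else:
                nearest = np.arange(d.size)
            dd, kk = d[nearest], k[nearest]
            l0s = l0[nearest].sum()
            best, best_a = -np.inf, 0.0
            for a in alphas:
                p_e = 1.0 - np.exp(-a * dd)
                ll = model.site_log_prob(kk, p_e).sum()
                if ll > best:
                    best, best_a = ll, a
            lam = best - l0s
            clr = 2.0 * max(lam, 0.0)
            rows.append((chrom, int(x), best_a if lam > 0 else 0.0, clr))
    return pd.DataFrame(rows, columns=["chrom", "position", "alpha_hat", "clr"])


def select_regions_clr(
    points: pd.DataFrame,
    rule: str = "top_fraction",
    fraction: float = 0.10,
    min_clr: float = 200.0,
    merge_gap_bp: int = 0,
) -> pd.DataFrame:
    """Candidate regions from CLR grid points.

    ``top_fraction`` keeps the top ``fraction`` of points by CLR (stable
    position tie-break); ``min_clr`` keeps points with CLR >= cutoff.
    Adjacent selected points (gap <= grid spacing + ``merge_gap_bp``) merge
    into regions.
    """
    if rule == "top_fraction":
        k = max(int(np.floor(fraction * len(points))), 1)
        order = np.lexsort((points["position"].to_numpy(),
                            -points["clr"].to_numpy()))
        sel = points.iloc[order[:k]]
    elif rule == "min_clr":
        sel = points[points["clr"] >= min_clr]
    else:
        raise ConfigError(f"unknown rule {rule!r}")
    if sel.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    regions = []
    for chrom, grp in sel.groupby("chrom", sort=False):
        ps = np.sort(grp["position"].to_numpy())
        all_pos = np.sort(points.loc[points["chrom"] == chrom, "position"].to_numpy())
        spacing = int(np.min(np.diff(all_pos))) if all_pos.size > 1 else 1
        start = prev = ps[0]
        for p in ps[1:]:
            if p - prev <= spacing + merge_gap_bp:
                prev = p
            else:
                regions.append((chrom, int(start), int(prev)))
                start = prev = p
        regions.append((chrom, int(start), int(prev)))
    return pd.DataFrame(regions, columns=["chrom", "start", "end"])


def windows_to_regions(windows: pd.DataFrame, merge_gap_bp: int = 0) -> pd.DataFrame:
    """Merge selected windows (chrom, start, end) into maximal regions."""
    if windows.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    regions = []
    for chrom, grp in windows.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
        start = prev_end = None
        for t in grp.itertuples(index=False):
            if start is None:
                start, prev_end = t.start, t.end
            elif t.start <= prev_end + 1 + merge_gap_bp:
                prev_end = max(prev_end, t.end)
            else:
                regions.append((chrom, int(start), int(prev_end)))
                start, prev_end = t.start, t.end
        regions.append((chrom, int(start), int(prev_end)))
    return pd.DataFrame(regions, columns=["chrom", "start", "end"])


def genes_overlapping(regions: pd.DataFrame, genes: pd.DataFrame) -> set:
    """Gene ids whose [start, end] overlaps any region by >= 1 bp."""
    hits = set()
    if regions.empty:
        return hits
    for chrom, grp in regions.groupby("chrom", sort=False):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        rs = grp["start"].to_numpy()
        re = grp["end"].to_numpy()
        for t in gsub.itertuples(index=False):
            if ((t.start <= re) & (t.end >= rs)).any():
                hits.add(t.gene_id)
    return hits


def intersect_candidates(
    pbs_regions: pd.DataFrame,
    clr_regions: pd.DataFrame,
    genes: pd.DataFrame,
) -> dict:
    """PBS-only / CLR-only / shared candidate gene sets."""
    pbs_genes = genes_overlapping(pbs_regions, genes)
    clr_genes = genes_overlapping(clr_regions, genes)
    return {
        "pbs_only": pbs_genes - clr_genes,
        "clr_only": clr_genes - pbs_genes,
        "shared": pbs_genes & clr_genes,
        "pbs_all": pbs_genes,
        "clr_all": clr_genes,
    }
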