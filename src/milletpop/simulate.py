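"""Forward-in-time synthetic cohorts with the structure the analyses assume.

A discrete-generation Wright-Fisher model on unlinked sites generates a wild
population, a bottlenecked cultivated derivative, and a diverged outgroup for
polarization. Deleterious sites evolve under selection against the derived
allele (fitnesses 1, 1-hs, 1-s for 0/1/2 derived copies); optional selective
sweeps in the cultivated population leave a spatial hitchhiking footprint
for the sweep scan. Polygenic phenotypes with chosen heritabilities and
genetic correlations, and a two-clade gene-family gain/loss process, cover
the quantitative-genetics and pangenome stages.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .core import MISSING, ConfigError, GenotypeMatrix, VARIANT_COLUMNS

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass
class DemographyConfig:
    """Demography and mutation/selection parameters of the synthetic cohort.

    Sizes are diploid population sizes. ``split_gen`` / ``outgroup_gen`` are
    generations before present; the cultivated population splits from the
    wild lineage ``split_gen`` generations ago with size ``N_cult``, the
    outgroup diverges ``outgroup_gen`` generations ago. Per-site mutation
    rates are desk-scale (orders of magnitude above per-bp rates) so a few
    thousand simulated sites segregate; see docs/methods.md.
    """

    N_wild: int = 500
    N_cult: int = 100
    N_out: int = 500
    split_gen: int = 60
    outgroup_gen: int = 300
    mu_snp: float = 1e-5
    mu_sv: float = 2e-6
    L: int = 3000
    prop_deleterious: float = 0.2
    prop_sv: float = 0.15
    s: float = 0.05
    h: float = 0.1
    seed: int = 0
    burnin_gen: int = 200  # ancestral equilibration after the SFS draw
    init: str = "stationary"  # or "monomorphic"
    n_wild_samples: int = 35
    n_cult_samples: int = 60
    n_out_samples: int = 6
    n_chrom: int = 2
    spacing_bp: int = 500
    missing_rate: float = 0.02
    hitch_alpha: float = 2e-5  # per-bp escape intensity; footprint ~ tens of kb

    def __post_init__(self) -> None:
        if min(self.N_wild, self.N_cult, self.N_out) < 2:
            raise ConfigError("population sizes must be >= 2")
        if not 0.0 <= self.prop_deleterious <= 1.0:
            raise ConfigError("prop_deleterious must be in [0, 1]")
        if not 0.0 <= self.h <= 1.0:
            raise ConfigError("dominance h must be in [0, 1]")
        if self.s < 0:
            raise ConfigError("selection coefficient s must be >= 0")
        if self.outgroup_gen < self.split_gen:
            raise ConfigError("outgroup_gen must be >= split_gen")


@dataclass
class SweepConfig:
    """A beneficial allele sweeping in the cultivated population."""

    locus_pos: int
    s_beneficial: float = 0.3
    start_gen: int | None = None  # default: at the domestication split
    target_pop: str = "cultivated"
    chrom_index: int = 0

    def __post_init__(self) -> None:
        if self.s_beneficial <= 0:
            raise ConfigError("s_beneficial must be > 0")
        if self.target_pop != "cultivated":
            raise ConfigError("only cultivated-population sweeps are modelled")


@dataclass
class TraitArchitecture:
    """Polygenic architecture for one or more traits.

    ``h2`` is the narrow-sense heritability per trait; ``r_g`` the genetic
    correlation matrix (scalar shorthand allowed for two traits). Effects
    are drawn from a multivariate normal over traits so shared causal sites
    induce the requested correlations; trait variance is scaled to meet h2.
    """

    n_causal: int = 100
    h2: tuple[float, ...] = (0.5,)
    r_g: np.ndarray | float | None = None
    rho_e: float = 0.0
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        t = len(self.h2)
        if self.r_g is None:
            R = np.eye(t)
        elif np.isscalar(self.r_g):
            if t != 2:
                raise ConfigError("scalar r_g only valid for two traits")
            R = np.array([[1.0, float(self.r_g)], [float(self.r_g), 1.0]])
        else:
            R = np.asarray(self.r_g, dtype=float)
        if R.shape != (t, t):
            raise ConfigError("r_g matrix shape must match number of traits")
        if not np.allclose(R, R.T):
            raise ConfigError("r_g matrix must be symmetric")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ConfigError("r_g matrix must be positive semidefinite")
        for v in self.h2:
            if not 0.0 <= v <= 1.0:
                raise ConfigError("h2 must be in [0, 1]")
        return R


# ---------------------------------------------------------------------------
# Wright-Fisher machinery
# ---------------------------------------------------------------------------

def selection_update(q: np.ndarray, s: float, h: float) -> np.ndarray:
    """Deterministic one-generation change in derived-allele frequency under
    selection against the derived allele (fitnesses 1, 1-hs, 1-s)."""
    p = 1.0 - q
    wbar = p * p + 2 * p * q * (1 - h * s) + q * q * (1 - s)
    with np.errstate(invalid="ignore", divide="ignore"):
        qn = (q * q * (1 - s) + p * q * (1 - h * s)) / wbar
    return np.where(wbar > 0, qn, 0.0)


def wright_fisher_freqs(
    q0: np.ndarray,
    N: int,
    generations: int,
    rng: np.random.Generator,
    s: float | np.ndarray = 0.0,
    h: float = 0.5,
    mu: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Evolve derived-allele frequencies for ``generations`` WF generations.

    Per generation: deterministic selection, one-way mutation influx
    ``q += mu (1-q)``, then binomial resampling of 2N gametes. ``s`` and
    ``mu`` may be per-site arrays.
    """
    q = np.asarray(q0, dtype=float).copy()
    s = np.broadcast_to(np.asarray(s, dtype=float), q.shape)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), q.shape)
    sel = s.max() > 0 if s.size else False
    for _ in range(generations):
        qs = selection_update(q, s, h) if sel else q
        qm = qs + mu * (1.0 - qs)
        q = rng.binomial(2 * N, np.clip(qm, 0.0, 1.0)) / (2.0 * N)
    return q


def sweep_trajectory(
    N: int,
    s_beneficial: float,
    generations: int,
    rng: np.random.Generator,
    max_retries: int = 200,
    min_final_freq: float = 0.95,
) -> tuple[np.ndarray, bool]:
    """WF trajectory of a beneficial allele conditioned on (near-)fixation.

    Starts one copy at frequency 1/(2N); the stochastic trajectory is
    re-drawn until the final frequency reaches ``min_final_freq`` or the
    retry cap is hit, after which a deterministic logistic trajectory is
    used. Returns (trajectory of length generations+1, used_logistic flag).
    """
    q0 = 1.0 / (2 * N)
    for _ in range(max_retries):
        q = q0
        traj = [q]
        for _ in range(generations):
            # beneficial allele: selection *for* the derived allele, h = 1/2
            p = 1.0 - q
            wbar = 1.0 + 2 * p * q * (s_beneficial / 2) + q * q * s_beneficial
            q = (q * q * (1 + s_beneficial) + p * q * (1 + s_beneficial / 2)) / wbar
            q = rng.binomial(2 * N, min(q, 1.0)) / (2.0 * N)
            traj.append(q)
            if q == 0.0:
                break
        if traj[-1] >= min_final_freq and len(traj) == generations + 1:
            return np.array(traj), False
    # deterministic logistic fallback, guaranteed reproducible
    t = np.arange(generations + 1, dtype=float)
    x0 = q0 / (1 - q0)
    q = x0 * np.exp(s_beneficial * t) / (1 + x0 * (np.exp(s_beneficial * t) - 1))
    if q[-1] < min_final_freq:
        raise ConfigError(
            "sweep allele cannot approach fixation within split_gen generations; "
            "increase s_beneficial or split_gen"
        )
    return q, True


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _draw_alleles(rng: np.random.Generator, vclass: np.ndarray) -> tuple[list, list]:
    refs, alts = [], []
    for vc in vclass:
        if vc == "SNP":
            r, a = rng.choice(4, size=2, replace=False)
            refs.append(_BASES[r])
            alts.append(_BASES[a])
        else:
            base = _BASES[rng.integers(4)]
            ins_len = int(rng.integers(51, 151))
            seq = "".join(rng.choice(_BASES, size=ins_len))
            if rng.random() < 0.5:  # insertion
                refs.append(base)
                alts.append(base + seq)
            else:  # deletion
                refs.append(base + seq)
                alts.append(base)
    return refs, alts


def simulate_cohort(
    d: DemographyConfig,
    sweeps: list[SweepConfig] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.Series, dict]:
    """Simulate the full cohort.

    Returns ``(genotypes, annotations, population map, truth)``. Genotype
    codes count ALT alleles; the derived allele coincides with ALT at sites
    where ``truth['ancestral'] == 'ref'`` and with REF otherwise (50/50),
    so the polarization stage has real work to do. The annotation table
    carries SIFT-like scores: Uniform(0, 0.05) at deleterious sites,
    Uniform(0.05, 1) elsewhere.
    """
    sweeps = sweeps or []
    rng = np.random.default_rng(d.seed)
    L = d.L
    n_per_chrom = np.full(d.n_chrom, L // d.n_chrom)
    n_per_chrom[: L % d.n_chrom] += 1
    chrom = np.concatenate(
        [np.full(n, i) for i, n in enumerate(n_per_chrom)])
    pos = np.concatenate(
        [1 + np.arange(n, dtype=np.int64) * d.spacing_bp for n in n_per_chrom])

    vclass = np.where(rng.random(L) < d.prop_sv, "SV", "SNP")
    is_sv = vclass == "SV"
    deleterious = rng.random(L) < d.prop_deleterious
    s_site = np.where(deleterious, d.s, 0.0)
    mu_site = np.where(is_sv, d.mu_sv, d.mu_snp)

    # ancestral standing variation: neutral-SFS draw (density ~ 1/q, i.e.
    # log-uniform) followed by a short selective equilibration, or a
    # monomorphic start when mutation alone is meant to supply variation
    if d.init == "stationary":
        qmin = 1.0 / (2 * d.N_wild)
        q = qmin * (0.95 / qmin) ** rng.random(L)
    elif d.init == "monomorphic":
        q = np.zeros(L)
    else:
        raise ConfigError(f"unknown init {d.init!r}")
    q = wright_fisher_freqs(q, d.N_wild, d.burnin_gen, rng, s=s_site, h=d.h, mu=mu_site)

    # outgroup branch
    q_out = wright_fisher_freqs(q, d.N_out, d.outgroup_gen, rng,
                                s=s_site, h=d.h, mu=mu_site)
    # main lineage to the domestication split
    q_main = wright_fisher_freqs(q, d.N_wild, d.outgroup_gen - d.split_gen, rng,
                                 s=s_site, h=d.h, mu=mu_site)
    q_pre = q_main.copy()  # frequencies at the split (pre-sweep state)
    q_wild = wright_fisher_freqs(q_main, d.N_wild, d.split_gen, rng,
                                 s=s_site, h=d.h, mu=mu_site)
    q_cult = wright_fisher_freqs(q_main, d.N_cult, d.split_gen, rng,
                                 s=s_site, h=d.h, mu=mu_site)

    # sweeps: trajectory + hitchhiking footprint on cultivated haplotypes
    sweep_truth = []
    hitch = np.zeros(L)  # per-site escape probability complement applicability
    p_escape = np.ones(L)
    for sw in sweeps:
        gen = d.split_gen if sw.start_gen is None else sw.start_gen
        if not 0 < gen <= d.split_gen:
            raise ConfigError("sweep start_gen must be in (0, split_gen]")
        traj, logistic = sweep_trajectory(d.N_cult, sw.s_beneficial, gen, rng)
        on_chrom = chrom == sw.chrom_index
        dist = np.abs(pos - sw.locus_pos)
        pe = 1.0 - np.exp(-d.hitch_alpha * dist)
        p_escape = np.where(on_chrom, np.minimum(p_escape, pe), p_escape)
        sweep_truth.append({
            "chrom_index": sw.chrom_index,
            "locus_pos": int(sw.locus_pos),
            "s_beneficial": sw.s_beneficial,
            "start_gen": int(gen),
            "final_freq": float(traj[-1]),
            "logistic_fallback": bool(logistic),
        })
    swept = p_escape < 1.0

    # sample genotypes (HWE draws from final frequencies)
    def hwe_genotypes(qv: np.ndarray, n: int) -> np.ndarray:
        return rng.binomial(2, np.clip(qv, 0, 1), size=(n, L)).astype(np.int8)

    G_wild = hwe_genotypes(q_wild, d.n_wild_samples)
    G_out = hwe_genotypes(q_out, d.n_out_samples)

    n_hap = 2 * d.n_cult_samples
    hap = (rng.random((n_hap, L)) < q_cult).astype(np.int8)
    if sweeps and swept.any():
        # the CLR scan's generative model: at swept sites a non-escaping
        # lineage carries the hitchhiker's allele (drawn from the frequency
        # at sweep onset); an escaping lineage keeps sampling the drifted
        # present-day cultivated frequency, like the rest of the genome.
        idx = np.flatnonzero(swept)
        b = (rng.random(idx.size) < q_pre[idx]).astype(np.int8)  # hitchhiker allele
        esc = rng.random((n_hap, idx.size)) < p_escape[idx]
        bg_draw = (rng.random((n_hap, idx.size)) < q_cult[idx]).astype(np.int8)
        hap[:, idx] = np.where(esc, bg_draw, b[None, :])
    G_cult = (hap[0::2] + hap[1::2]).astype(np.int8)

    G_derived = np.vstack([G_wild, G_cult, G_out])
    samples = (
        [f"wild_{i:03d}" for i in range(d.n_wild_samples)]
        + [f"cult_{i:03d}" for i in range(d.n_cult_samples)]
        + [f"out_{i:03d}" for i in range(d.n_out_samples)]
    )
    pops = pd.Series(
        ["wild"] * d.n_wild_samples + ["cultivated"] * d.n_cult_samples
        + ["outgroup"] * d.n_out_samples,
        index=samples, name="group",
    )

    # REF/ALT assignment: ancestral allele is REF for half the sites
    anc_is_ref = rng.random(L) < 0.5
    G_alt = np.where(anc_is_ref[None, :], G_derived, 2 - G_derived).astype(np.int8)

    # missingness + genotype qualities
    GQ = rng.integers(5, 100, size=G_alt.shape).astype(np.float32)
    miss = rng.random(G_alt.shape) < d.missing_rate
    G_alt = np.where(miss, MISSING, G_alt).astype(np.int8)

    refs, alts = _draw_alleles(rng, vclass)
    chrom_names = np.array([f"chr{i + 1}" for i in range(d.n_chrom)])
    variants = pd.DataFrame({
        "chrom": chrom_names[chrom],
        "pos": pos,
        "id": [f"var{i:06d}" for i in range(L)],
        "ref": refs,
        "alt": alts,
        "vclass": vclass,
    })[VARIANT_COLUMNS]

    g = GenotypeMatrix(samples=samples, variants=variants, G=G_alt, GQ=GQ)

    sift = np.where(
        deleterious,
        rng.uniform(0.0, 0.05, size=L),
        rng.uniform(0.05, 1.0, size=L),
    )
    ann = variants[["chrom", "pos", "ref", "alt"]].copy()
    ann["sift_score"] = sift

    truth = {
        "config": asdict(d),
        "ancestral": np.where(anc_is_ref, "ref", "alt").tolist(),
        "deleterious": deleterious.tolist(),
        "vclass": vclass.tolist(),
        "q_wild": q_wild.tolist(),
        "q_cult": q_cult.tolist(),
        "q_out": q_out.tolist(),
        "sweeps": sweep_truth,
    }
    return g, ann, pops, truth


def simulate_related_panel(
    n_samples: int,
    n_variants: int,
    n_founders: int = 30,
    seed: int = 0,
) -> GenotypeMatrix:
    """A diversity panel with genuine relatedness structure.

    Individuals draw their two haplotypes from a small founder-haplotype
    pool, emulating the shared ancestry of a crop accession panel; the
    resulting kinship matrix has the off-diagonal variance that variance-
    component estimation (h2, r_g) relies on.
    """
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.1, 0.9, n_variants)
    H = (rng.random((n_founders, n_variants)) < f).astype(np.int8)
    idx = rng.integers(0, n_founders, size=(n_samples, 2))
    G = (H[idx[:, 0]] + H[idx[:, 1]]).astype(np.int8)
    refs, alts = _draw_alleles(rng, np.full(n_variants, "SNP"))
    variants = pd.DataFrame({
        "chrom": "chr1",
        "pos": 1 + np.arange(n_variants, dtype=np.int64) * 100,
        "id": [f"pv{i:06d}" for i in range(n_variants)],
        "ref": refs,
        "alt": alts,
        "vclass": "SNP",
    })[VARIANT_COLUMNS]
    samples = [f"acc_{i:03d}" for i in range(n_samples)]
    return GenotypeMatrix(samples=samples, variants=variants, G=G)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    g: GenotypeMatrix,
    arch: TraitArchitecture,
    trait_names: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Polygenic phenotypes y_t = sum_j beta_tj x_j + e_t.

    A shared causal-site set with effects drawn from a multivariate normal
    across traits induces the requested genetic correlations; residuals are
    independent across traits unless ``arch.rho_e`` is set. Genotypes are
    mean-imputed and standardized before effects are applied, matching the
    standardized-kinship association model downstream.
    """
    R = arch.correlation_matrix()
    t = len(arch.h2)
    if arch.n_causal > g.n_variants:
        raise ConfigError("n_causal exceeds number of variants")
    rng = np.random.default_rng(arch.seed)
    X = g.G.astype(float)
    X[X == MISSING] = np.nan
    f = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), f[None, :], X)
    sd = X.std(axis=0)
    poly = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, poly] = (X[:, poly] - X[:, poly].mean(axis=0)) / sd[poly]

    causal = rng.choice(np.flatnonzero(poly), size=min(arch.n_causal, poly.sum()),
                        replace=False)
    Lc = np.linalg.cholesky(R + 1e-10 * np.eye(t))
    beta = rng.standard_normal((causal.size, t)) @ Lc.T

    gv = Xs[:, causal] @ beta  # n x t genetic values
    gv_sd = gv.std(axis=0)
    n = g.n_samples
    E = np.zeros((n, t))
    if t == 2 and arch.rho_e != 0.0:
        Re = np.array([[1.0, arch.rho_e], [arch.rho_e, 1.0]])
        E = rng.standard_normal((n, t)) @ np.linalg.cholesky(Re).T
    else:
        E = rng.standard_normal((n, t))

    Y = np.zeros((n, t))
    realized_h2 = []
    for k in range(t):
        h2 = arch.h2[k]
        gk = gv[:, k] / gv_sd[k] * np.sqrt(h2) if gv_sd[k] > 0 else np.zeros(n)
        if h2 >= 1.0:
            yk = gk
        elif h2 <= 0.0:
            gk = np.zeros(n)
            yk = E[:, k]
        else:
            yk = gk + E[:, k] * np.sqrt(1.0 - h2)
        Y[:, k] = yk
        vg = gk.var()
        vy = yk.var()
        realized_h2.append(float(vg / vy) if vy > 0 else 0.0)

    names = trait_names or [f"trait{k + 1}" for k in range(t)]
    phen = pd.DataFrame(Y, index=pd.Index(g.samples, name="sample"), columns=names)
    gcorr = np.corrcoef(gv.T) if t > 1 and gv_sd.min() > 0 else np.eye(t)
    truth = {
        "causal_indices": causal.tolist(),
        "beta": beta.tolist(),
        "realized_h2": realized_h2,
        "realized_r_g": gcorr.tolist(),
        "h2_target": list(arch.h2),
    }
    return phen, truth


# ---------------------------------------------------------------------------
# Gene-family presence/absence
# ---------------------------------------------------------------------------

def simulate_pam(
    n_families: int,
    n_wild: int,
    n_cult: int,
    loss_rate: float = 0.05,
    gain_cult_rate: float = 0.1,
    gain_wild_rate: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Two-clade star-tree gene-family gain/loss process.

    Each family is either ancestral (present at the root, then lost
    independently on each terminal branch with ``loss_rate``) or a
    clade-restricted gain (present only within one clade, carried by each
    member genome with probability 0.9). Families absent everywhere are
    resampled so the emitted matrix has no empty rows.
    """
    for r in (loss_rate, gain_cult_rate, gain_wild_rate):
        if not 0.0 <= r <= 1.0:
            raise ConfigError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genomes = [f"wild_g{i:02d}" for i in range(n_wild)] + \
              [f"cult_g{i:02d}" for i in range(n_cult)]
    clades = pd.Series(["wild"] * n_wild + ["cultivated"] * n_cult,
                       index=genomes, name="clade")
    N = n_wild + n_cult
    M = np.zeros((n_families, N), dtype=np.int8)
    classes = []
    u = rng.random(n_families)
    p_gain = gain_cult_rate + gain_wild_rate
    for i in range(n_families):
        while True:
            if u[i] < gain_cult_rate:
                cls = "gained_cultivated"
                row = np.zeros(N, dtype=np.int8)
                row[n_wild:] = rng.random(n_cult) < 0.9
            elif u[i] < p_gain:
                cls = "gained_wild"
                row = np.zeros(N, dtype=np.int8)
                row[:n_wild] = rng.random(n_wild) < 0.9
            else:
                cls = "ancestral"
                row = (rng.random(N) >= loss_rate).astype(np.int8)
            if row.any():
                break
        M[i] = row
        classes.append(cls)
    pam = pd.DataFrame(M, columns=genomes,
                       index=pd.Index([f"fam{i:05d}" for i in range(n_families)],
                                      name="family_id"))
    truth = {"classes": classes, "clades": clades.to_dict()}
    return pam, truth
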