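"""Gene-family classification, pan/core accumulation curves, and
clade-conditional gain/loss calls from a presence/absence matrix (PAM).

Occupancy bands generalize the usual 26-genome convention: with N genomes,
core = N, soft-core = N-2..N-1, dispensable = 2..N-3, private = 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ConfigError


def classify_families(pam: pd.DataFrame) -> pd.DataFrame:
    """Assign each family to {core, softcore, dispensable, private} by occupancy.

    Parameters
    ----------
    pam : DataFrame, families x genomes, binary.

    Returns a DataFrame indexed by family with columns ``occupancy`` and
    ``category``. Families present in no genome are an error.
    """
    M = pam.to_numpy()
    if not np.isin(M, [0, 1]).all():
        raise ValueError("presence/absence matrix must be binary")
    N = pam.shape[1]
    if N < 4:
        raise ConfigError("need at least 4 genomes for distinct occupancy bands")
    occ = M.sum(axis=1)
    if (occ == 0).any():
        bad = pam.index[occ == 0].tolist()
        raise ValueError(f"families present in no genome: {bad[:5]}")
    category = np.select(
        [occ == N, occ >= N - 2, occ >= 2],
        ["core", "softcore", "dispensable"],
        default="private",
    )
    return pd.DataFrame({"occupancy": occ, "category": category}, index=pam.index)


def classification_summary(classes: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per category (core first)."""
    order = ["core", "softcore", "dispensable", "private"]
    counts = classes["category"].value_counts().reindex(order, fill_value=0)
    return pd.DataFrame({
        "count": counts,
        "percent": 100.0 * counts / len(classes),
    })


def pan_core_curve(pam: pd.DataFrame, n_perm: int = 100, seed: int = 0) -> pd.DataFrame:
    """Pan/core gene-family accumulation curves over genome-order permutations.

    For each random permutation of genome order, the cumulative union (pan)
    and intersection (core) family counts at each k are recorded; means and
    standard deviations over permutations are returned, indexed by k.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    M = pam.to_numpy(dtype=bool)
    n_fam, N = M.shape
    rng = np.random.default_rng(seed)
    pan = np.empty((n_perm, N), dtype=np.int64)
    core = np.empty((n_perm, N), dtype=np.int64)
    for p in range(n_perm):
        order = rng.permutation(N)
        cum_any = np.logical_or.accumulate(M[:, order], axis=1)
        cum_all = np.logical_and.accumulate(M[:, order], axis=1)
        pan[p] = cum_any.sum(axis=0)
        core[p] = cum_all.sum(axis=0)
    return pd.DataFrame({
        "k": np.arange(1, N + 1),
        "pan_mean": pan.mean(axis=0),
        "pan_sd": pan.std(axis=0, ddof=0),
        "core_mean": core.mean(axis=0),
        "core_sd": core.std(axis=0, ddof=0),
    }).set_index("k")


def gain_loss(
    pam: pd.DataFrame,
    clades: pd.Series,
    min_frac: float | None = None,
) -> tuple[set, set, set]:
    """Classify families as gained / lost during domestication.

    Default rule: *gained* families are present in at least one cultivated
    genome (or >= ``min_frac`` of them if given) and absent from every wild
    genome; *lost* is the mirror image; *shared* families occur in at least
    one genome of each clade.
    """
    unknown = set(clades.unique()) - {"wild", "cultivated"}
    if unknown:
        raise ValueError(f"unknown clade labels: {sorted(unknown)}")
    absent = [g for g in pam.columns if g not in clades.index]
    if absent:
        raise ValueError(f"genomes missing from clade map: {absent[:5]}")
    wild_cols = [g for g in pam.columns if clades[g] == "wild"]
    cult_cols = [g for g in pam.columns if clades[g] == "cultivated"]
    if not wild_cols or not cult_cols:
        raise ValueError("both clades must be non-empty")
    W = pam[wild_cols].to_numpy(dtype=bool)
    C = pam[cult_cols].to_numpy(dtype=bool)
    w_occ, c_occ = W.sum(axis=1), C.sum(axis=1)
    if min_frac is None:
        min_c, min_w = 1, 1
    else:
        min_c = int(np.ceil(min_frac * len(cult_cols)))
        min_w = int(np.ceil(min_frac * len(wild_cols)))
    gained = set(pam.index[(c_occ >= max(min_c, 1)) & (w_occ == 0)])
    lost = set(pam.index[(w_occ >= max(min_w, 1)) & (c_occ == 0)])
    shared = set(pam.index[(w_occ >= 1) & (c_occ >= 1)])
    return gained, lost, shared
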