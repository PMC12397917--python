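"""Core in-memory containers shared across the pipeline.

Coordinate convention: all positions are 1-based inclusive (VCF/GFF native);
BED export subtracts 1 from start. Genotypes count copies of a designated
allele (ALT on ingest, derived after polarization) with ``MISSING`` (-1) as
the sentinel for uncalled or half-called genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: sentinel genotype code for missing / half calls
MISSING: int = -1

#: alleles longer than this (ref or alt) make a variant an SV
SV_LENGTH_THRESHOLD: int = 50

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "vclass"]

GROUPS = ("wild", "cultivated", "outgroup")


class MilletpopError(Exception):
    """Base class for pipeline errors."""


class ConfigError(MilletpopError):
    """A configuration value is out of its allowed range."""


class ParseError(MilletpopError):
    """An input file could not be parsed."""


def variant_class(ref: str, alt: str) -> str:
    """SV if either allele exceeds 50 bp, else SNP."""
    return "SV" if max(len(ref), len(alt)) > SV_LENGTH_THRESHOLD else "SNP"


@dataclass
class GenotypeMatrix:
    """Samples x biallelic variants genotype matrix.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``G``).
    variants : pandas.DataFrame
        One row per variant with columns ``chrom, pos, id, ref, alt, vclass``,
        sorted by (chrom, pos) on ingest.
    G : numpy.ndarray, shape (n_samples, n_variants), dtype int8
        Codes in {0, 1, 2, MISSING} counting copies of the ALT allele.
    GQ : numpy.ndarray or None
        Optional per-genotype qualities, same shape as ``G``.
    """

    samples: list[str]
    variants: pd.DataFrame
    G: np.ndarray
    GQ: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"G shape {self.G.shape} inconsistent with {len(self.samples)} "
                f"samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.G, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype codes outside {{0,1,2,missing}}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample ids")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes."""
        return self.G != MISSING

    def take_variants(self, idx) -> "GenotypeMatrix":
        """New matrix restricted to the given variant indices (order kept)."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            G=self.G[:, idx].copy(),
            GQ=None if self.GQ is None else self.GQ[:, idx].copy(),
        )

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        """New matrix restricted to the given samples, in the given order."""
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in names if s not in pos]
        if missing:
            raise KeyError(f"unknown samples: {missing[:5]}")
        idx = np.array([pos[s] for s in names])
        return GenotypeMatrix(
            samples=list(names),
            variants=self.variants.copy(),
            G=self.G[idx, :].copy(),
            GQ=None if self.GQ is None else self.GQ[idx, :].copy(),
        )

    def alt_allele_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant (alt allele count, called allele number)."""
        called = self.called()
        ac = np.where(called, self.G, 0).sum(axis=0)
        an = 2 * called.sum(axis=0)
        return ac.astype(np.int64), an.astype(np.int64)


def validate_population_map(pops: pd.Series, samples: list[str]) -> pd.Series:
    """Check a sample -> {wild, cultivated, outgroup} mapping covers ``samples``.

    Returns the mapping restricted to ``samples`` in sample order.
    """
    unknown = set(pops.unique()) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown population labels: {sorted(unknown)}")
    absent = [s for s in samples if s not in pops.index]
    if absent:
        raise ValueError(f"samples missing from population map: {absent[:5]}")
    if pops.index.duplicated().any():
        raise ValueError("duplicated sample ids in population map")
    return pops.loc[samples]


def group_samples(pops: pd.Series, group: str) -> list[str]:
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    return list(pops.index[pops == group])


@dataclass(frozen=True)
class FilterConfig:
    """Site/genotype filters in VCFtools semantics.

    ``max_missing_rate`` is a *keep* threshold on call rate (VCFtools
    ``--max-missing``): sites with call rate >= value are retained.
    """

    max_missing_rate: float = 0.8
    min_gq: int = 10
    min_maf: float = 0.05
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ConfigError("max_missing_rate must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ConfigError("min_maf must be in [0, 0.5]")
        if self.min_gq < 0:
            raise ConfigError("min_gq must be >= 0")


# VCFtools parameter sets from the upstream study: SNPs and SVs are filtered
# with different stringency.
SNP_FILTER = FilterConfig(max_missing_rate=0.8, min_gq=10, min_maf=0.05)
SV_FILTER = FilterConfig(max_missing_rate=0.7, min_gq=20, min_maf=0.01)
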