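"""Locus filtering, Weir-Cockerham F_ST and PCoA ordination.

The pairwise F_ST estimator is Weir & Cockerham's (1984) theta: per locus
the among-population (a), among-individual-within-population (b) and
within-individual (c) variance components are computed from sample allele
frequencies and observed heterozygosity, and the multi-locus estimate is
the ratio of sums  sum(a) / sum(a + b + c)  over loci informative in both
colonies. Small negative estimates are legitimate for this estimator and
are reported as computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .distmat import DistanceMatrix
from .geno import MISSING, GenotypeMatrix

__all__ = [
    "LocusFilterReport", "filter_loci",
    "FstResult", "pairwise_fst", "weir_cockerham_components",
    "allele_sharing_distance", "PcoaResult", "pcoa",
]


# ------------------------------------------------------------- filtering

@dataclass
class LocusFilterReport:
    n_loci_in: int
    n_loci_out: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_loci_out + sum(self.removed_by_rule.values()) != self.n_loci_in:
            raise ValueError("filter report does not account for every locus")


def _alt_freq(calls: np.ndarray) -> np.ndarray:
    """Per-locus alternate allele frequency over non-missing calls (nan if none)."""
    ok = calls != MISSING
    with np.errstate(invalid="ignore"):
        return np.where(ok, calls, 0).sum(axis=0) / (2.0 * ok.sum(axis=0))


def filter_loci(g: GenotypeMatrix, maf_min: float = 0.0,
                call_rate_min: float = 0.0, drop_monomorphic: bool = True
                ) -> tuple[GenotypeMatrix, LocusFilterReport]:
    """Remove loci by call rate, then minor-allele frequency, then monomorphism.

    The rules are applied in that fixed order, so each removed locus is
    attributed to exactly one rule.
    """
    for name, t in (("maf_min", maf_min), ("call_rate_min", call_rate_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    ok = g.calls != MISSING
    call_rate = ok.mean(axis=0)
    p = _alt_freq(g.calls)
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)

    removed = {"call_rate": 0, "maf": 0, "monomorphic": 0}
    keep = np.ones(g.n_loci, dtype=bool)

    fail_cr = call_rate < call_rate_min
    removed["call_rate"] = int(fail_cr.sum())
    keep &= ~fail_cr

    fail_maf = keep & (maf < maf_min)
    removed["maf"] = int(fail_maf.sum())
    keep &= ~fail_maf

    if drop_monomorphic:
        fail_mono = keep & (maf == 0.0)
        removed["monomorphic"] = int(fail_mono.sum())
        keep &= ~fail_mono

    if not keep.any():
        raise ValueError("filtering removed every locus")
    report = LocusFilterReport(g.n_loci, int(keep.sum()), removed)
    return g.subset_loci(keep), report


# ----------------------------------------------------------------- F_ST

def weir_cockerham_components(calls_1: np.ndarray, calls_2: np.ndarray
                              ) -> np.ndarray:
    """Per-locus Weir-Cockerham variance components for two populations.

    ``calls_*`` are individuals x loci alt-allele counts with MISSING for
    no-calls. Returns an array of shape (n_loci, 3) with columns (a, b, c);
    loci lacking data in either population (or with fewer than 3 genotypes
    overall) are NaN.
    """
    comps = np.full((calls_1.shape[1], 3), np.nan)
    ok1, ok2 = calls_1 != MISSING, calls_2 != MISSING
    n1 = ok1.sum(axis=0).astype(float)
    n2 = ok2.sum(axis=0).astype(float)
    usable = (n1 >= 1) & (n2 >= 1) & (n1 + n2 > 2)
    if not usable.any():
        return comps

    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(ok1, calls_1, 0).sum(axis=0) / (2 * n1)
        p2 = np.where(ok2, calls_2, 0).sum(axis=0) / (2 * n2)
        h1 = np.where(ok1, calls_1 == 1, 0).sum(axis=0) / n1
        h2 = np.where(ok2, calls_2 == 1, 0).sum(axis=0) / n2

    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
    c = h_bar / 2

    comps[usable, 0] = a[usable]
    comps[usable, 1] = b[usable]
    comps[usable, 2] = c[usable]
    return comps


@dataclass
class FstResult:
    matrix: DistanceMatrix
    per_locus_components: dict[tuple[str, str], np.ndarray]


def pairwise_fst(g: GenotypeMatrix) -> FstResult:
    """Multi-locus Weir-Cockerham theta for every colony pair.

    The multi-locus estimate is the ratio of sums sum(a)/sum(a+b+c); loci
    with no data in either member of a pair are excluded locus-wise, never
    silently dropped globally.
    """
    colonies = g.colonies
    if len(colonies) < 2:
        raise ValueError("need >= 2 colonies")
    for c in colonies:
        if g.colony_mask(c).sum() < 2:
            raise ValueError(f"colony {c!r} has fewer than 2 genotyped individuals")
    k = len(colonies)
    theta = np.zeros((k, k))
    comps: dict[tuple[str, str], np.ndarray] = {}
    for i in range(k):
        for j in range(i + 1, k):
            abc = weir_cockerham_components(
                g.calls[g.colony_mask(colonies[i])],
                g.calls[g.colony_mask(colonies[j])],
            )
            ok = ~np.isnan(abc[:, 0])
            if not ok.any():
                raise ValueError(
                    f"no shared genotyped loci for pair ({colonies[i]}, {colonies[j]})"
                )
            denom = abc[ok].sum()
            t = abc[ok, 0].sum() / denom if denom != 0 else 0.0
            theta[i, j] = theta[j, i] = t
            comps[(colonies[i], colonies[j])] = abc
    return FstResult(DistanceMatrix(colonies, theta, "fst", allow_negative=True),
                     comps)


# ------------------------------------------------ individual distances / PCoA

def allele_sharing_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """1 - mean proportion of shared alleles between individual pairs.

    Per locus the shared-allele proportion is 1 - |g_i - g_j| / 2; loci
    missing in either individual are excluded pairwise.
    """
    calls = g.calls.astype(float)
    calls[g.calls == MISSING] = np.nan
    n = g.n_individuals
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(calls[i + 1:] - calls[i]) / 2.0
        d[i, i + 1:] = np.nanmean(diff, axis=1)
    d = d + d.T
    return DistanceMatrix(g.individual_ids, d, "allele_sharing")


@dataclass
class PcoaResult:
    coordinates: np.ndarray        # individuals x axes
    eigenvalues: np.ndarray        # kept (positive) eigenvalues, non-increasing
    proportion_explained: np.ndarray
    sample_ids: list[str]
    n_negative_eigenvalues: int = 0

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Principal coordinates analysis (classical metric scaling).

    Gower double-centring of -d^2/2 followed by eigendecomposition;
    coordinates are eigenvectors scaled by sqrt(eigenvalue). Axes with
    negative eigenvalues (non-Euclidean distances) are dropped and counted.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(_SkbioDM(d.values, ids=d.labels), method="eigh",
                          inplace=False)
    eig = res.eigvals.to_numpy()
    tol = max(abs(eig).max(), 1.0) * 1e-12
    pos = eig > tol
    n_neg = int((eig < -tol).sum())
    coords = res.samples.to_numpy()[:, pos]
    eig_pos = eig[pos]
    prop = res.proportion_explained.to_numpy()[pos]
    if n_axes is not None:
        if n_axes > pos.sum():
            warnings.warn(
                f"requested {n_axes} axes but only {int(pos.sum())} positive "
                "eigenvalues; truncating", stacklevel=2)
            n_axes = int(pos.sum())
        coords, eig_pos, prop = coords[:, :n_axes], eig_pos[:n_axes], prop[:n_axes]
    coords = coords - coords.mean(axis=0, keepdims=True)
    return PcoaResult(coords, eig_pos, prop, list(d.labels), n_neg)
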