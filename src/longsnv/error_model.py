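"""Beta-binomial background-error model.

Sequencing and mapping errors in droplet scRNA-seq pileups are overdispersed:
the per-site error rate P is itself a random variable. We model nonreference
allele counts at homozygous-reference sites as

    K | P ~ Binomial(n, P),    P ~ Beta(alpha, beta),

i.e. K ~ BetaBinomial(n, alpha, beta). The one-sided tail probability
P(K >= k) is the p-value used by every noise, germline, panel-of-normals,
single-cell-genotyping, and scWGS-support decision in this package.

Two parameter sets are maintained, mirroring the two tests applied to a
candidate locus: a *primary* set for the candidate allele itself and an
*other-allele* set for the residual noise test that ignores reads carrying
the candidate allele. The shipped long-read defaults are
(0.21, 104.95) and (0.25, 162.04) respectively, corresponding to mean error
rates of ~0.20% and ~0.15%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import yaml
from scipy import optimize
from scipy.stats import betabinom

logger = logging.getLogger("longsnv")

__all__ = [
    "BetaParams",
    "SiteObservation",
    "DEFAULT_LR_PRIMARY",
    "DEFAULT_LR_OTHER",
    "betabinom_tail",
    "is_significant",
    "fit_background",
    "training_sites_from_pseudobulk",
]


@dataclass(frozen=True)
class BetaParams:
    """Parameters of the background-error beta distribution.

    Attributes
    ----------
    alpha, beta
        Shape parameters of the Beta prior on the per-site error rate.
        Both must be strictly positive.
    n_sites_fit
        Number of homozygous-reference sites used in the fit (0 for
        shipped defaults).
    source
        ``"fit"`` for data-derived parameters, ``"default_LR"`` for the
        shipped long-read defaults.
    """

    alpha: float
    beta: float
    n_sites_fit: int = 0
    source: str = "fit"

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"alpha and beta must be positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean_error_rate(self) -> float:
        """Expected error rate alpha / (alpha + beta)."""
        return self.alpha / (self.alpha + self.beta)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "alpha": float(self.alpha),
                    "beta": float(self.beta),
                    "n_sites_fit": int(self.n_sites_fit),
                    "source": self.source,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "BetaParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(d["alpha"], d["beta"], d.get("n_sites_fit", 0), d.get("source", "fit"))


class SiteObservation(NamedTuple):
    """Nonreference count and depth at one homozygous-reference site."""

    nonref_count: int
    depth: int


#: Shipped long-read defaults for the primary (candidate-allele) test.
DEFAULT_LR_PRIMARY = BetaParams(0.21, 104.95, n_sites_fit=0, source="default_LR")
#: Shipped long-read defaults for the other-allele (residual-noise) test.
DEFAULT_LR_OTHER = BetaParams(0.25, 162.04, n_sites_fit=0, source="default_LR")


def betabinom_tail(k, n, params: BetaParams):
    """One-sided upper-tail p-value P(K >= k) under BetaBinomial(n, alpha, beta).

    Vectorized over ``k`` and ``n``. ``betabinom_tail(0, n) == 1`` exactly and
    the tail is monotone non-increasing in ``k`` at fixed ``n``.

    Raises
    ------
    ValueError
        If ``k < 0``, ``n < 0`` or ``k > n`` anywhere.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(n < 0):
        raise ValueError("depth n must be non-negative")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("nonreference count k must satisfy 0 <= k <= n")
    # P(K >= k) = sf(k - 1); sf(-1) = 1 covers the k = 0 case.
    out = betabinom.sf(k - 1, n, params.alpha, params.beta)
    if out.ndim == 0:
        return float(out)
    return out


def is_significant(k, n, params: BetaParams, alpha_level: float):
    """True iff the tail p-value is strictly below ``alpha_level``."""
    return betabinom_tail(k, n, params) < alpha_level


def _neg_log_likelihood(log_ab: np.ndarray, k: np.ndarray, n: np.ndarray,
                        w: np.ndarray) -> float:
    a, b = np.exp(log_ab)
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        return np.inf
    with np.errstate(all="ignore"):
        ll = betabinom.logpmf(k, n, a, b)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return float(-np.sum(w * ll))


def _method_of_moments(k: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Moment start values; falls back to a weakly informative start."""
    m = k.sum() / n.sum()
    m = min(max(m, 1e-6), 1 - 1e-6)
    p = k / n
    v = p.var()
    # Remove the average binomial sampling component of the variance.
    v_beta = v - m * (1 - m) * np.mean(1.0 / n)
    if v_beta <= 0:
        # Nearly binomial: start from a concentrated beta.
        s = 1000.0
    else:
        rho = v_beta / (m * (1 - m))
        rho = min(max(rho, 1e-6), 1 - 1e-6)
        s = (1 - rho) / rho
    return max(m * s, 1e-3), max((1 - m) * s, 1e-2)


def fit_background(sites: Sequence[SiteObservation] | np.ndarray,
                   min_sites: int = 1000) -> BetaParams:
    """Fit (alpha, beta) by maximum likelihood from homozygous-reference sites.

    Parameters
    ----------
    sites
        Sequence of ``(nonref_count, depth)`` pairs (or an (m, 2) array).
        At least ``min_sites`` observations with depth >= 1 are required;
        practical fits use hundreds of thousands of sites.

    Returns
    -------
    BetaParams
        Maximum-likelihood estimate, initialized by method of moments.
        If every nonreference count is zero the fit is degenerate and the
        shipped long-read defaults are returned with a warning.

    Notes
    -----
    The optimizer works on (log alpha, log beta) with Nelder-Mead, which is
    robust for the flat, banana-shaped likelihood typical of low error rates.
    Identical (k, n) pairs are collapsed to weighted unique rows, so the cost
    is independent of the number of sites once the table is aggregated.
    """
    arr = np.asarray([(s[0], s[1]) for s in sites] if not isinstance(sites, np.ndarray)
                     else sites, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("sites must be a sequence of (nonref_count, depth) pairs")
    k_all, n_all = arr[:, 0], arr[:, 1]
    keep = n_all >= 1
    k_all, n_all = k_all[keep], n_all[keep]
    if np.any(k_all > n_all) or np.any(k_all < 0):
        raise ValueError("nonref_count must satisfy 0 <= nonref_count <= depth")
    if len(k_all) < min_sites:
        raise ValueError(
            f"only {len(k_all)} usable sites (< {min_sites}); too few to fit a "
            "background model — use the shipped defaults "
            "(DEFAULT_LR_PRIMARY / DEFAULT_LR_OTHER) instead"
        )
    if k_all.max() == 0:
        warnings.warn(
            "all nonreference counts are zero: degenerate fit, returning "
            "shipped long-read defaults",
            RuntimeWarning,
            stacklevel=2,
        )
        return BetaParams(DEFAULT_LR_PRIMARY.alpha, DEFAULT_LR_PRIMARY.beta,
                          n_sites_fit=len(k_all), source="default_LR")

    pairs, w = np.unique(np.stack([k_all, n_all], axis=1), axis=0, return_counts=True)
    ku, nu = pairs[:, 0], pairs[:, 1]
    a0, b0 = _method_of_moments(k_all, n_all)
    res = optimize.minimize(
        _neg_log_likelihood,
        x0=np.log([a0, b0]),
        args=(ku, nu, w.astype(float)),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000},
    )
    a, b = np.exp(res.x)
    return BetaParams(float(a), float(b), n_sites_fit=int(len(k_all)), source="fit")


def training_sites_from_pseudobulk(pb_counts, max_vaf: float = 0.05,
                                   min_depth: int = 10,
                                   max_sites: int = 500_000,
                                   seed: int = 0) -> np.ndarray:
    """Select homozygous-reference training sites from pseudo-bulk counts.

    A site qualifies if its pooled nonreference fraction is below ``max_vaf``
    and its pooled depth is at least ``min_depth``; qualifying sites are
    subsampled to ``max_sites`` with a fixed seed. Returns an (m, 2) array of
    (nonref_count, depth) rows suitable for :func:`fit_background`.

    ``pb_counts`` is the per-locus count frame of a
    :class:`~longsnv.io_counts.PseudoBulk` (columns A, C, G, T, other, depth;
    index carrying the reference base as its ``ref`` level).
    """
    ref = pb_counts.index.get_level_values("ref")
    base_cols = np.stack([pb_counts[b].to_numpy() for b in "ACGT"], axis=1)
    ref_idx = np.searchsorted(np.array(list("ACGT")), np.asarray(ref))
    ref_counts = base_cols[np.arange(len(pb_counts)), ref_idx]
    depth = pb_counts["depth"].to_numpy()
    nonref = depth - ref_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, nonref / np.maximum(depth, 1), 0.0)
    keep = (depth >= min_depth) & (vaf < max_vaf)
    out = np.stack([nonref[keep], depth[keep]], axis=1).astype(np.int64)
    if len(out) > max_sites:
        rng = np.random.default_rng(seed)
        out = out[rng.choice(len(out), size=max_sites, replace=False)]
    return out
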