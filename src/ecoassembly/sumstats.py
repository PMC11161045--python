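"""Fixed-order summary statistics over the three biodiversity data axes.

Each simulated (or empirical-style) community is reduced to one feature
vector spanning species abundances (SAD), per-species genetic diversity
(pi), and species trait values: richness, the first four moments of each
axis, Hill numbers of orders 1-4 per axis, Spearman rank correlations
between axes, and the divergence of the local trait distribution from the
metacommunity reference.  Missing axes produce NaN sentinels in exactly
their columns — never silently dropped — so downstream axis masks can
reconstruct which data were available.

Conventions (fixed, config-switchable where noted): SAD moments are taken
on log abundances; trait and genetic moments are species-weighted (one
point per species); genetic Hill numbers treat the per-species pi values,
normalized to proportions, as the "abundances" of diversity; trait Hill
numbers are Chiu-Chao attribute (functional) diversities with pairwise
trait distances normalized by the abundance-weighted mean distance Q.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ecoassembly.metacommunity import Metacommunity

__all__ = [
    "SENTINEL",
    "FEATURE_COLUMNS",
    "AXIS_COLUMNS",
    "hill_abundance",
    "hill_genetic",
    "hill_trait",
    "axis_moments",
    "spearman_cross",
    "trait_divergence",
    "summarize",
]

#: Not-available marker for masked or undefined features.
SENTINEL = np.nan

HILL_ORDERS = (1, 2, 3, 4)

_MOMENTS = ("mean", "sd", "skew", "kurt")

#: Canonical column order of the summary-statistic vector.
FEATURE_COLUMNS = (
    ["S", "lam"]
    + [f"abund_{m}" for m in _MOMENTS]
    + [f"pi_{m}" for m in _MOMENTS]
    + [f"trait_{m}" for m in _MOMENTS]
    + [f"hill_abund_q{q}" for q in HILL_ORDERS]
    + [f"hill_pi_q{q}" for q in HILL_ORDERS]
    + [f"hill_trait_q{q}" for q in HILL_ORDERS]
    + ["rho_abund_pi", "rho_abund_trait", "rho_pi_trait"]
    + ["trait_dmean", "trait_dsd"]
)

#: Which columns depend on which data axis (used by axis masks).  "S" and
#: "lam" are axis-independent: a species list exists whenever any axis does,
#: and lam is simulation metadata.
AXIS_COLUMNS = {
    "abundance": [f"abund_{m}" for m in _MOMENTS]
    + [f"hill_abund_q{q}" for q in HILL_ORDERS],
    "genetic": [f"pi_{m}" for m in _MOMENTS] + [f"hill_pi_q{q}" for q in HILL_ORDERS],
    "trait": [f"trait_{m}" for m in _MOMENTS]
    + [f"hill_trait_q{q}" for q in HILL_ORDERS]
    + ["trait_dmean", "trait_dsd"],
}
_CROSS_COLUMNS = {
    "rho_abund_pi": ("abundance", "genetic"),
    "rho_abund_trait": ("abundance", "trait"),
    "rho_pi_trait": ("genetic", "trait"),
}


def _hill_from_proportions(p: np.ndarray, q: float) -> float:
    p = p[p > 0]
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def hill_abundance(counts, q: float) -> float:
    """Hill number of order q of a species abundance vector (>= 1)."""
    if q < 0:
        raise ValueError(f"Hill order q must be >= 0, got {q}")
    counts = np.asarray(counts, float)
    if counts.size == 0 or np.any(counts <= 0):
        raise ValueError("counts must be nonempty and positive")
    return _hill_from_proportions(counts / counts.sum(), q)


def hill_genetic(pi_values, q: float) -> float:
    """Hill number of the per-species pi values, normalized to proportions.

    An all-zero pi vector (no diversity anywhere) is undefined and returns
    the NaN sentinel with a warning.
    """
    if q < 0:
        raise ValueError(f"Hill order q must be >= 0, got {q}")
    pi = np.asarray(pi_values, float)
    if pi.size == 0 or np.any(pi < 0):
        raise ValueError("pi values must be nonempty and nonnegative")
    total = pi.sum()
    if total == 0:
        warnings.warn("all-zero pi vector: genetic Hill number undefined",
                      RuntimeWarning, stacklevel=2)
        return SENTINEL
    return _hill_from_proportions(pi / total, q)


def hill_trait(traits, abundances, q: float) -> float:
    """Attribute-diversity (functional) Hill number of the trait axis.

    Chiu-Chao construction: with p the abundance proportions and d_ij the
    pairwise trait distances normalized by Q = sum_ij d_ij p_i p_j,

        qFD = ( sum_ij (d_ij / Q) (p_i p_j)^q )^(1 / (2 (1 - q)))

    with the usual exponential limit at q = 1.  Invariant to rescaling all
    distances; reduces to the abundance Hill number for equally abundant,
    equally spaced species.  Fewer than two species, or all traits equal
    (Q = 0), return the NaN sentinel.
    """
    if q < 0:
        raise ValueError(f"Hill order q must be >= 0, got {q}")
    z = np.asarray(traits, float)
    n = np.asarray(abundances, float)
    if z.size < 2:
        return SENTINEL
    p = n / n.sum()
    d = np.abs(z[:, None] - z[None, :])
    Q = float(np.sum(d * p[:, None] * p[None, :]))
    if Q == 0.0:
        warnings.warn("all trait values identical: trait Hill number undefined",
                      RuntimeWarning, stacklevel=2)
        return SENTINEL
    pp = p[:, None] * p[None, :]
    w = d / Q
    if q == 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(pp > 0, w * pp * np.log(pp), 0.0)
        return float(np.exp(-0.5 * term.sum()))
    return float(np.sum(w * pp**q) ** (1.0 / (2.0 * (1.0 - q))))


def axis_moments(values) -> tuple[float, float, float, float]:
    """(mean, SD, skewness, excess kurtosis) of one axis' values.

    Sample SD uses ddof=1.  Skewness needs at least 3 points and kurtosis
    at least 4; a constant vector has undefined shape moments.  Undefined
    entries carry the NaN sentinel.
    """
    x = np.asarray(values, float)
    if x.size == 0:
        return (SENTINEL, SENTINEL, SENTINEL, SENTINEL)
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else SENTINEL
    degenerate = sd == 0.0 or not np.isfinite(sd)
    skew = (
        float(stats.skew(x)) if x.size >= 3 and not degenerate else SENTINEL
    )
    kurt = (
        float(stats.kurtosis(x)) if x.size >= 4 and not degenerate else SENTINEL
    )
    return (mean, sd, skew, kurt)


def spearman_cross(axis_a, axis_b) -> float:
    """Spearman rank correlation between two axes' per-species values."""
    a = np.asarray(axis_a, float)
    b = np.asarray(axis_b, float)
    if a.shape != b.shape:
        raise ValueError("axes must be indexed by the same species set")
    if a.size < 3:
        return SENTINEL
    if np.all(a == a[0]) or np.all(b == b[0]):
        return SENTINEL  # rank correlation undefined for a constant axis
    return float(stats.spearmanr(a, b).statistic)


def trait_divergence(
    local_traits, local_abundances, meta: Metacommunity
) -> tuple[float, float]:
    """(local - metacommunity) trait mean and SD, abundance-weighted.

    Both sides are individual-level: the local mean/SD weight each species
    by its abundance, matching the abundance-weighted metacommunity
    reference values.
    """
    z = np.asarray(local_traits, float)
    n = np.asarray(local_abundances, float)
    p = n / n.sum()
    mean = float(np.sum(p * z))
    sd = float(np.sqrt(np.sum(p * (z - mean) ** 2)))
    return (mean - meta.meta_trait_mean, sd - meta.meta_trait_sd)


def summarize(
    community,
    pi_table: pd.DataFrame | None,
    meta: Metacommunity | None,
    lam: float | None = None,
    mask: set[str] | None = None,
) -> pd.Series:
    """Assemble the full fixed-order summary-statistic vector.

    ``mask``, if given, is the set of *available* axes (subset of
    {"abundance", "genetic", "trait"}); columns of unavailable axes (and
    cross-correlations touching them) are set to the NaN sentinel.  Passing
    ``pi_table=None`` masks the genetic axis; ``meta=None`` masks the
    trait-divergence reference columns.
    """
    from ecoassembly.assembly import LocalCommunity  # cycle guard

    assert isinstance(community, LocalCommunity)
    available = {"abundance", "trait"}
    if pi_table is not None and len(pi_table):
        available.add("genetic")
    if mask is not None:
        available &= set(mask)

    counts = community.abundance.astype(float)
    traits = community.trait
    out = pd.Series(SENTINEL, index=FEATURE_COLUMNS, dtype=float)
    out["S"] = community.richness
    out["lam"] = lam if lam is not None else SENTINEL

    if "abundance" in available:
        mom = axis_moments(np.log(counts))
        for name, v in zip(_MOMENTS, mom):
            out[f"abund_{name}"] = v
        for q in HILL_ORDERS:
            out[f"hill_abund_q{q}"] = hill_abundance(counts, q)

    pi_aligned = None
    if "genetic" in available:
        merged = pd.DataFrame(
            {"species_id": community.species_uid}
        ).merge(pi_table, on="species_id", how="left")
        pi_aligned = merged["pi"].to_numpy(float)
        if np.any(~np.isfinite(pi_aligned)):
            raise ValueError("pi_table is missing species present in the community")
        mom = axis_moments(pi_aligned)
        for name, v in zip(_MOMENTS, mom):
            out[f"pi_{name}"] = v
        if pi_aligned.sum() > 0:
            for q in HILL_ORDERS:
                out[f"hill_pi_q{q}"] = hill_genetic(pi_aligned, q)

    if "trait" in available:
        mom = axis_moments(traits)
        for name, v in zip(_MOMENTS, mom):
            out[f"trait_{name}"] = v
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for q in HILL_ORDERS:
                out[f"hill_trait_q{q}"] = hill_trait(traits, counts, q)
        if meta is not None:
            dmean, dsd = trait_divergence(traits, counts, meta)
            out["trait_dmean"] = dmean
            out["trait_dsd"] = dsd

    axis_values = {
        "abundance": counts,
        "genetic": pi_aligned,
        "trait": traits,
    }
    for col, (ax_a, ax_b) in _CROSS_COLUMNS.items():
        if ax_a in available and ax_b in available:
            out[col] = spearman_cross(axis_values[ax_a], axis_values[ax_b])

    return out
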