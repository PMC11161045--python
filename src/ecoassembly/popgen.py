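"""Per-species genetic diversity from abundance-constrained coalescents.

After a forward community simulation, each extant species' recorded
abundance trajectory defines a piecewise-constant effective population size
Ne(t) = alpha * n(t) looking backward in time; lineages older than the
species' (re-)colonization of the local community coalesce in a large
panmictic source pool.  A haploid single-locus Hudson coalescent with
infinite-sites mutation then yields per-species nucleotide diversity (pi)
and the number of segregating sites.  Defaults emulate a short mtDNA
barcode locus (COI-like, 570 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ecoassembly import _kernels
from ecoassembly.assembly import SimulationParams, Trajectory

__all__ = [
    "PopgenConfig",
    "DemographicHistory",
    "GeneticSample",
    "build_history",
    "simulate_pi",
    "community_pi_vector",
    "export_haplotypes_fasta",
]


@dataclass(frozen=True)
class PopgenConfig:
    """Sampling and mutation settings for the coalescent layer.

    ``mu_per_site`` is per generation; ``source_pool_size`` is the haploid
    effective size of the panmictic pool that absorbs lineages older than
    the local colonization.
    """

    n_haplotypes: int = 10
    locus_length_bp: int = 570
    mu_per_site: float = 1e-7
    source_pool_size: float = 1e5

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise ValueError("n_haplotypes must be >= 2")
        if self.locus_length_bp < 1:
            raise ValueError("locus_length_bp must be >= 1")
        if self.mu_per_site < 0:
            raise ValueError("mu_per_site must be >= 0")
        if self.source_pool_size < 1:
            raise ValueError("source_pool_size must be >= 1")


@dataclass
class DemographicHistory:
    """Backward-time piecewise-constant Ne for one species.

    ``sizes[k]`` holds for ``durations[k]`` generations, counted backward
    from the end of the forward simulation; the final epoch is the source
    pool with infinite duration.
    """

    species_id: int
    colonization_generation: float
    sizes: np.ndarray  # haploid Ne per epoch, oldest last
    durations: np.ndarray  # generations; last entry is inf
    source_pool_size: float

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, float)
        self.durations = np.asarray(self.durations, float)
        if np.any(self.sizes < 1.0):
            raise ValueError("all Ne values must be >= 1")
        if np.any(self.durations[:-1] <= 0):
            raise ValueError("epoch durations must be strictly positive")

    @property
    def n_epochs(self) -> int:
        return len(self.sizes)


@dataclass
class GeneticSample:
    """Simulated genetic summary for one species' local population."""

    species_id: int
    n_haplotypes: int
    locus_length_bp: int
    segregating_sites: int
    pi: float  # mean pairwise difference per site
    tmrca: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.segregating_sites == 0 and self.pi != 0.0:
            raise ValueError("pi must be 0 when there are no segregating sites")


def build_history(
    trajectory: Trajectory,
    slot: int,
    alpha: float,
    source_pool_size: float = 1e5,
) -> DemographicHistory:
    """Backward piecewise-constant Ne from a species' abundance column.

    ``slot`` indexes the trajectory's species columns.  The abundance rows
    from the species' colonization generation to the end are scaled by
    ``alpha``, reversed into backward time, and consecutive equal sizes are
    merged; times older than colonization map to the source pool.
    """
    ab = trajectory.abundance[:, slot]
    if ab[-1] <= 0:
        raise ValueError(f"species slot {slot} is not extant at simulation end")
    gens = trajectory.generation
    colgen = float(trajectory.colonization_gen[slot])
    rows = np.flatnonzero(gens >= colgen)
    if rows.size == 0:  # colonized within the final recording interval
        rows = np.array([len(gens) - 1])
    ab = ab[rows].astype(float)
    gens = gens[rows]
    # a zero inside the residency window can only come from trajectory
    # thinning that skipped an extinction/recolonization; treat as size 1
    ab = np.maximum(ab, 1.0)

    # backward in time: last interval first.  Each interval between recorded
    # boundaries carries the abundance at its older boundary, so a change
    # recorded at generation g puts the size step exactly at g; the final
    # recorded abundance describes the sampling instant itself.
    sizes_bw = np.maximum(alpha * ab[-2::-1], 1.0)
    widths = np.diff(gens)[::-1]  # duration of each step between boundaries
    if widths.size == 0:
        sizes = [max(alpha * ab[0], 1.0)]
        durations = [max(gens[-1] - colgen, 1e-9)]
    else:
        sizes = [sizes_bw[0]]
        durations = [widths[0]]
        for k in range(1, len(widths)):
            if sizes_bw[k] == sizes[-1]:
                durations[-1] += widths[k]
            else:
                sizes.append(sizes_bw[k])
                durations.append(widths[k])
        # the stub from the first recorded boundary back to colonization
        stub = gens[0] - colgen
        if stub > 0:
            if sizes_bw[-1] == sizes[-1]:
                durations[-1] += stub
            else:
                sizes.append(sizes_bw[-1])
                durations.append(stub)
    sizes.append(float(source_pool_size))
    durations.append(np.inf)
    return DemographicHistory(
        species_id=int(trajectory.species_uid[slot]),
        colonization_generation=colgen,
        sizes=np.array(sizes),
        durations=np.array(durations),
        source_pool_size=float(source_pool_size),
    )


def simulate_pi(
    history: DemographicHistory,
    n_haplotypes: int = 10,
    mu_per_site: float = 1e-7,
    locus_length_bp: int = 570,
    seed: int = 0,
) -> GeneticSample:
    """Single-population Hudson coalescent under ``history``.

    Haploid, no recombination, infinite sites: mutations fall on branches
    at rate ``mu_per_site * locus_length_bp`` per generation, and pi is the
    mean pairwise difference averaged over haplotype pairs, per site.
    """
    if mu_per_site < 0:
        raise ValueError("mu_per_site must be >= 0")
    if n_haplotypes < 2:
        raise ValueError("n_haplotypes must be >= 2")
    mu_total = mu_per_site * locus_length_bp
    pi_locus, seg, tmrca = _kernels.coalesce_pi(
        history.sizes,
        history.durations,
        n_haplotypes,
        mu_total,
        int(seed) % (2**31 - 1),
    )
    return GeneticSample(
        species_id=history.species_id,
        n_haplotypes=n_haplotypes,
        locus_length_bp=locus_length_bp,
        segregating_sites=int(seg),
        pi=float(pi_locus) / locus_length_bp,
        tmrca=float(tmrca),
    )


def community_pi_vector(
    trajectory: Trajectory,
    params: SimulationParams,
    config: PopgenConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One genetic sample per extant species; deterministic under ``seed``.

    Sample size per species is ``min(n_haplotypes, abundance)`` with a
    floor of 2 (a species is never sampled deeper than its census size,
    but pi needs at least one pair).  Returns a table with columns
    species_id, abundance, pi, segregating_sites, n_haplotypes.
    """
    if config is None:
        config = PopgenConfig()
    slots = trajectory.extant_slots()
    final_ab = trajectory.abundance[-1]
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(slots))
    records = []
    for s, sub in zip(slots, child_seeds):
        hist = build_history(
            trajectory, int(s), params.alpha, config.source_pool_size
        )
        n = max(2, min(config.n_haplotypes, int(final_ab[s])))
        g = simulate_pi(
            hist,
            n_haplotypes=n,
            mu_per_site=config.mu_per_site,
            locus_length_bp=config.locus_length_bp,
            seed=int(sub),
        )
        records.append(
            {
                "species_id": g.species_id,
                "abundance": int(final_ab[s]),
                "pi": g.pi,
                "segregating_sites": g.segregating_sites,
                "n_haplotypes": g.n_haplotypes,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["species_id", "abundance", "pi", "segregating_sites", "n_haplotypes"],
    )


def export_haplotypes_fasta(
    history: DemographicHistory,
    path,
    n_haplotypes: int = 10,
    mu_per_site: float = 1e-7,
    locus_length_bp: int = 570,
    seed: int = 0,
) -> int:
    """Write a synthetic haplotype alignment for visual inspection.

    Re-simulates a coalescent tree in plain Python, assigns each infinite-
    sites mutation a distinct locus position, and writes two-allele (A/T)
    sequences.  Returns the number of segregating sites written.
    """
    rng = np.random.default_rng(seed)
    n = n_haplotypes
    sizes, durations = history.sizes, history.durations
    act = list(range(n))
    parent = {}
    t_node = {i: 0.0 for i in range(n)}
    nxt = n
    t, ep = 0.0, 0
    ep_end = durations[0]
    while len(act) > 1:
        k = len(act)
        w = rng.exponential(sizes[ep] / (k * (k - 1) / 2))
        if t + w > ep_end and ep < len(sizes) - 1:
            t = ep_end
            ep += 1
            ep_end += durations[ep]
            continue
        t += w
        i, j = rng.choice(k, size=2, replace=False)
        a, b = act[int(i)], act[int(j)]
        t_node[nxt] = t
        parent[a] = nxt
        parent[b] = nxt
        act = [x for x in act if x not in (a, b)] + [nxt]
        nxt += 1

    # leaves under each node
    leaves_under: dict[int, set[int]] = {i: {i} for i in range(n)}
    for node in sorted(parent):
        leaves_under.setdefault(parent[node], set()).update(leaves_under[node])

    seqs = np.full((n, locus_length_bp), "A", dtype="U1")
    site = 0
    for node, par in parent.items():
        bl = t_node[par] - t_node[node]
        muts = rng.poisson(mu_per_site * locus_length_bp * bl)
        for _ in range(int(muts)):
            if site >= locus_length_bp:
                break
            for leaf in leaves_under[node]:
                seqs[leaf, site] = "T"
            site += 1
    with open(path, "w") as fh:
        for i in range(n):
            fh.write(f">sp{history.species_id}_hap{i}\n")
            fh.write("".join(seqs[i]) + "\n")
    return site
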