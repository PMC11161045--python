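"""Forward-time zero-sum (Moran) community assembly under five death models.

At each event exactly one individual dies — chosen from the model's
normalized death-rate vector — and is replaced either by an immigrant from
the metacommunity (probability ``m``) or by the offspring of a uniformly
chosen surviving local individual, which speciates by point mutation with
probability ``nu``.  Selection acts on death only.

Death rates (before normalization), for individual ``i`` with trait ``z_i``:

- neutral:      constant (probability of death 1/J exactly)
- filtering:    q = 1 - exp(-s_E (z_i - z_E)^2)      (penalises distance
                from the environmental optimum z_E)
- mean:         q = exp(-s_E (z_i - zbar)^2)         (penalises proximity
                to the community mean trait zbar)
- pairwise:     q = sum_{j != i} exp(-s_E (z_i - z_j)^2)
- beta:         q = sum_{j != i} beta_ij exp(-s_E (z_i - z_j)^2), with
                beta_ij = beta_intra for conspecific pairs and beta_inter
                otherwise.  beta with beta_intra = beta_inter = 1 is exactly
                the pairwise model.

Because all conspecifics share one trait value, the pairwise/beta sums
collapse to species-level aggregates (see :func:`aggregated_pairwise_rates`),
which is what makes the simulation O(S) per event instead of O(J^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ecoassembly import _kernels
from ecoassembly.metacommunity import Metacommunity, sample_immigrant

__all__ = [
    "MODELS",
    "SimulationParams",
    "LocalCommunity",
    "Trajectory",
    "death_weights",
    "aggregated_pairwise_rates",
    "step",
    "compute_lambda",
    "run",
]

MODELS = ("neutral", "filtering", "mean", "pairwise", "beta")
_MODEL_CODE = {
    "neutral": _kernels.NEUTRAL,
    "filtering": _kernels.FILTERING,
    "mean": _kernels.MEAN,
    "pairwise": _kernels.PAIRWISE,
    "beta": _kernels.BETA,
}


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one local-community simulation.

    ``z_E=None`` resolves to the metacommunity trait mean at run time;
    ``sigma_sp=None`` (speciation trait step SD) resolves to 10% of the
    metacommunity trait SD.  The run stops when Lambda (the fraction of
    individuals descending from lineages that colonized after the start)
    reaches ``lambda_target``, or after ``max_generations`` generations,
    whichever comes first; ``lambda_target=None`` disables the Lambda rule.
    One generation = J death-birth events.
    """

    J: int = 1000
    m: float = 5e-3
    nu: float = 0.0
    s_E: float = 0.1
    z_E: float | None = None
    beta_intra: float = 1.0
    beta_inter: float = 1.0
    model: str = "neutral"
    alpha: float = 1000.0
    lambda_target: float | None = 1.0
    max_generations: int = 3000
    snapshot_every: int = 1
    sigma_sp: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 2:
            raise ValueError(f"J must be >= 2, got {self.J}")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m must be in [0, 1], got {self.m}")
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError(f"nu must be in [0, 1], got {self.nu}")
        if self.s_E < 0.0:
            raise ValueError(f"s_E must be >= 0, got {self.s_E}")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.beta_intra <= 0 or self.beta_inter <= 0:
            raise ValueError("beta_intra and beta_inter must be positive")
        if self.model == "beta" and self.beta_intra < self.beta_inter:
            raise ValueError(
                "beta model requires beta_intra >= beta_inter "
                "(the beta_intra << beta_inter regime is out of scope)"
            )
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.lambda_target is not None and not 0.0 < self.lambda_target <= 1.0:
            raise ValueError("lambda_target must be in (0, 1]")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.snapshot_every < 1:
            raise ValueError("snapshot_every must be >= 1")


@dataclass
class LocalCommunity:
    """State of the local community: J individuals with species identities.

    ``species_of`` maps each individual to a row of the per-species arrays
    (``species_uid``, ``trait``, ``meta_index``, ``colonization_gen``).
    All conspecific individuals share one trait value.  ``colonist_flag``
    marks individuals descending from a lineage that arrived (immigration
    or in-situ speciation) after the simulation started.
    """

    species_of: np.ndarray  # (J,) int, index into per-species arrays
    species_uid: np.ndarray  # (S,) unique ids, stable within a run
    trait: np.ndarray  # (S,) trait value per species
    colonist_flag: np.ndarray  # (J,) bool
    meta_index: np.ndarray  # (S,) metacommunity species index, -1 if neoendemic
    colonization_gen: np.ndarray  # (S,) generation of current residency start
    generation: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = self.abundance
        if counts.sum() != self.J:
            raise ValueError("total abundance must equal J (zero-sum)")
        if np.any(counts == 0):
            raise ValueError("per-species arrays must list extant species only")
        if len(self.trait) != len(self.species_uid):
            raise ValueError("every species needs a trait value")

    @property
    def J(self) -> int:
        return len(self.species_of)

    @property
    def richness(self) -> int:
        return len(self.species_uid)

    @property
    def abundance(self) -> np.ndarray:
        return np.bincount(self.species_of, minlength=len(self.species_uid))

    @property
    def individual_traits(self) -> np.ndarray:
        return self.trait[self.species_of]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "individual_id": np.arange(self.J),
                "species_id": self.species_uid[self.species_of],
                "trait": self.individual_traits,
                "colonist_flag": self.colonist_flag,
            }
        )


@dataclass
class Trajectory:
    """Per-generation record of one run.

    Rows are generation boundaries (row 0 = initial state).  ``abundance``
    columns are aligned with the per-species metadata arrays (``species_uid``
    etc.); a column only describes its final occupant from that occupant's
    ``colonization_gen`` onward (storage slots are recycled after
    extinctions).  Consumers that reconstruct demographic histories must
    therefore cut each column at the species' colonization generation, which
    is what :func:`ecoassembly.popgen.build_history` does.
    """

    generation: np.ndarray  # (G,) float
    abundance: np.ndarray  # (G, n_slots) int
    lam: np.ndarray  # (G,) Lambda at each boundary
    richness: np.ndarray  # (G,) int
    trait_mean: np.ndarray  # (G,) community mean trait
    species_uid: np.ndarray  # (n_slots,)
    species_trait: np.ndarray  # (n_slots,)
    species_meta: np.ndarray  # (n_slots,)
    colonization_gen: np.ndarray  # (n_slots,)
    truncated: bool
    params: SimulationParams
    final: LocalCommunity = field(repr=False)

    @property
    def n_snapshots(self) -> int:
        return len(self.generation)

    @property
    def final_lambda(self) -> float:
        return float(self.lam[-1])

    def extant_slots(self) -> np.ndarray:
        return np.flatnonzero(self.abundance[-1] > 0)

    def to_long_frame(self):
        """Long-format (generation, species_id, abundance) table."""
        import pandas as pd

        gens, slots = np.nonzero(self.abundance)
        return pd.DataFrame(
            {
                "generation": self.generation[gens],
                "species_id": self.species_uid[slots],
                "abundance": self.abundance[gens, slots],
            }
        )


def _resolve(params: SimulationParams, meta: Metacommunity) -> SimulationParams:
    """Fill in metacommunity-derived defaults (z_E, sigma_sp)."""
    z_E = params.z_E if params.z_E is not None else meta.meta_trait_mean
    sigma = (
        params.sigma_sp
        if params.sigma_sp is not None
        else 0.1 * meta.meta_trait_sd
    )
    return replace(params, z_E=float(z_E), sigma_sp=float(sigma))


def aggregated_pairwise_rates(
    abundance: np.ndarray,
    trait: np.ndarray,
    s_E: float,
    beta_intra: float = 1.0,
    beta_inter: float = 1.0,
) -> np.ndarray:
    """Species-level pairwise/beta death rates, O(S^2) instead of O(J^2).

    For species ``a`` with abundance ``n_a`` every member shares the rate

        q(a) = beta_intra (n_a - 1)
             + beta_inter sum_{b != a} n_b exp(-s_E (z_a - z_b)^2)

    which, with ``beta_intra = beta_inter = 1``, equals the per-individual
    pairwise sum for any member of ``a`` (conspecifics contribute exp(0)).
    """
    n = np.asarray(abundance, float)
    if np.any(n <= 0):
        raise ValueError("abundances must be positive")
    z = np.asarray(trait, float)
    x = -s_E * (z[:, None] - z[None, :]) ** 2
    K = np.where(x < _kernels._EXP_CLAMP, 0.0, np.exp(np.maximum(x, _kernels._EXP_CLAMP)))
    K[K < _kernels._TINY] = 0.0
    hetero = K @ n - n  # subtract own-species block (K diagonal is 1)
    return beta_inter * hetero + beta_intra * (n - 1.0)


def death_weights(community: LocalCommunity, params: SimulationParams) -> np.ndarray:
    """Normalized per-individual death probabilities for the chosen model.

    Returns a length-J vector summing to 1.  A degenerate all-zero rate
    vector (e.g. filtering with every individual exactly at the optimum)
    falls back to the uniform vector with a warning, which is the
    s_E -> 0 consistent completion of the normalization.
    """
    J = community.J
    model = params.model
    if model == "neutral":
        return np.full(J, 1.0 / J)

    z_ind = community.individual_traits
    if model == "filtering":
        if params.z_E is None:
            raise ValueError("filtering model needs a resolved z_E")
        x = -params.s_E * (z_ind - params.z_E) ** 2
        q = 1.0 - np.exp(np.maximum(x, _kernels._EXP_CLAMP))
    elif model == "mean":
        zbar = z_ind.mean()
        x = -params.s_E * (z_ind - zbar) ** 2
        q = np.exp(np.maximum(x, _kernels._EXP_CLAMP))
        q[q < _kernels._TINY] = 0.0
    else:  # pairwise / beta
        bi = params.beta_intra if model == "beta" else 1.0
        be = params.beta_inter if model == "beta" else 1.0
        q_sp = aggregated_pairwise_rates(
            community.abundance, community.trait, params.s_E, bi, be
        )
        q = q_sp[community.species_of]

    total = q.sum()
    if total <= 0.0:
        warnings.warn(
            f"all-zero {model} death rates; falling back to uniform 1/J",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full(J, 1.0 / J)
    return q / total


def compute_lambda(community: LocalCommunity) -> float:
    """Fraction of individuals descending from post-start colonists."""
    return float(np.count_nonzero(community.colonist_flag)) / community.J


def step(
    community: LocalCommunity,
    params: SimulationParams,
    meta: Metacommunity,
    rng: np.random.Generator,
) -> LocalCommunity:
    """One death-birth event (reference implementation, mutates a copy).

    This is the readable single-step semantics used by the unit tests and
    small experiments; :func:`run` executes the same dynamics through the
    compiled event loop.
    """
    params = _resolve(params, meta)
    weights = death_weights(community, params)
    J = community.J
    victim = int(rng.choice(J, p=weights))

    species_of = community.species_of.copy()
    colonist = community.colonist_flag.copy()
    uids = community.species_uid
    traits = community.trait
    metas = community.meta_index
    colgen = community.colonization_gen
    gen_time = community.generation

    def _add_species(trait_val, meta_idx, flag):
        nonlocal species_of, colonist, uids, traits, metas, colgen
        uids = np.append(uids, uids.max() + 1 if len(uids) else 0)
        traits = np.append(traits, trait_val)
        metas = np.append(metas, meta_idx)
        colgen = np.append(colgen, gen_time)
        species_of[victim] = len(uids) - 1
        colonist[victim] = flag

    if rng.random() < params.m:
        msp = sample_immigrant(meta, rng)
        existing = np.flatnonzero(metas == msp)
        if existing.size:
            species_of[victim] = existing[0]
            colonist[victim] = True
        else:
            _add_species(meta.trait[msp], msp, True)
    else:
        parent = int(rng.integers(J))
        while parent == victim:
            parent = int(rng.integers(J))
        if params.nu > 0 and rng.random() < params.nu:
            _add_species(
                traits[species_of[parent]] + rng.normal(0.0, params.sigma_sp),
                -1,
                True,
            )
        else:
            species_of[victim] = species_of[parent]
            colonist[victim] = colonist[parent]

    # drop species that lost their last individual, reindexing survivors
    counts = np.bincount(species_of, minlength=len(uids))
    keep = np.flatnonzero(counts > 0)
    remap = np.full(len(uids), -1)
    remap[keep] = np.arange(len(keep))
    return LocalCommunity(
        species_of=remap[species_of],
        species_uid=uids[keep],
        trait=traits[keep],
        colonist_flag=colonist,
        meta_index=metas[keep],
        colonization_gen=colgen[keep],
        generation=gen_time + 1.0 / J,
    )


def initialize(params: SimulationParams, meta: Metacommunity, rng: np.random.Generator) -> LocalCommunity:
    """All-founder start: one species drawn abundance-weighted from the pool."""
    msp = sample_immigrant(meta, rng)
    return LocalCommunity(
        species_of=np.zeros(params.J, int),
        species_uid=np.array([0]),
        trait=np.array([meta.trait[msp]]),
        colonist_flag=np.zeros(params.J, bool),
        meta_index=np.array([msp]),
        colonization_gen=np.array([0.0]),
    )


def run(
    params: SimulationParams,
    meta: Metacommunity,
    seed: int | None = None,
) -> Trajectory:
    """Run the compiled event loop to the stopping rule.

    The community starts as J copies of a single founder species drawn
    abundance-weighted from the metacommunity.  Returns the trajectory
    (snapshots every ``snapshot_every`` generations, always including the
    final state) with the final community attached; if ``lambda_target``
    was not reached within ``max_generations`` the trajectory is flagged
    ``truncated`` rather than raising.
    """
    params = _resolve(params, meta)
    if seed is None:
        seed = params.seed
    seed = int(seed) % (2**31 - 1)

    meta_cum = np.cumsum(meta.rel_abundance)
    lam_target = -1.0 if params.lambda_target is None else params.lambda_target
    (
        gens_done,
        truncated,
        hist_ab,
        hist_lam,
        hist_S,
        hist_zbar,
        slot_trait,
        slot_colgen,
        slot_meta,
        slot_uid,
        sp_of,
        colonist,
        n_of,
    ) = _kernels.run_assembly(
        _MODEL_CODE[params.model],
        params.J,
        params.m,
        params.nu,
        params.s_E,
        params.z_E,
        params.beta_intra if params.model == "beta" else 1.0,
        params.beta_inter if params.model == "beta" else 1.0,
        meta_cum,
        np.asarray(meta.trait, float),
        params.sigma_sp,
        lam_target,
        params.max_generations,
        seed,
    )

    rows = np.arange(gens_done + 1)
    if params.snapshot_every > 1:
        keep = rows[:: params.snapshot_every]
        if keep[-1] != gens_done:
            keep = np.append(keep, gens_done)
        rows = keep

    # columns ever used (uid assigned)
    used = np.flatnonzero(slot_uid >= 0)

    extant_slots = np.flatnonzero(n_of[used] > 0)
    slot_to_row = np.full(len(slot_uid), -1)
    slot_to_row[used[extant_slots]] = np.arange(len(extant_slots))
    final = LocalCommunity(
        species_of=slot_to_row[sp_of],
        species_uid=slot_uid[used][extant_slots],
        trait=slot_trait[used][extant_slots],
        colonist_flag=colonist,
        meta_index=slot_meta[used][extant_slots],
        colonization_gen=slot_colgen[used][extant_slots],
        generation=float(gens_done),
    )

    return Trajectory(
        generation=rows.astype(float),
        abundance=hist_ab[rows][:, used],
        lam=hist_lam[rows],
        richness=hist_S[rows],
        trait_mean=hist_zbar[rows],
        species_uid=slot_uid[used],
        species_trait=slot_trait[used],
        species_meta=slot_meta[used],
        colonization_gen=slot_colgen[used],
        truncated=bool(truncated),
        params=params,
        final=final,
    )
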