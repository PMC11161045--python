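"""Fixed regional species pool supplying immigrants and reference traits.

The metacommunity is treated as infinitely large and static on the timescale
of local community assembly: a list of species with log-series relative
abundances and one trait value per species.  Traits are simulated either by
Brownian motion along a Yule (pure-birth) tree over the species — giving
phylogenetically correlated traits, the default — or as iid normal draws.
"""

from __future__ import annotations

import hashlib
import io
import random as _random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetacommunitySpec",
    "Metacommunity",
    "generate_metacommunity",
    "sample_immigrant",
]

TRAIT_MODELS = ("brownian_on_tree", "iid_normal")


@dataclass(frozen=True)
class MetacommunitySpec:
    """Parameters of the regional pool generator.

    Parameters
    ----------
    n_species
        Number of species in the regional pool (at least 2).
    sad_shape
        Log-series parameter in (0, 1); values near 1 give long-tailed
        regional abundance distributions.
    trait_model
        ``"brownian_on_tree"`` (Brownian motion along a Yule tree) or
        ``"iid_normal"``.
    trait_rate
        Variance scale of the trait process (Brownian rate per unit branch
        length, or the iid normal variance).
    seed
        Seed for the generator.
    """

    n_species: int
    sad_shape: float = 0.98
    trait_model: str = "brownian_on_tree"
    trait_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError(f"n_species must be >= 2, got {self.n_species}")
        if not 0.0 < self.sad_shape < 1.0:
            raise ValueError(f"sad_shape must be in (0, 1), got {self.sad_shape}")
        if self.trait_model not in TRAIT_MODELS:
            raise ValueError(
                f"trait_model must be one of {TRAIT_MODELS}, got {self.trait_model!r}"
            )
        if self.trait_rate <= 0:
            raise ValueError(f"trait_rate must be positive, got {self.trait_rate}")


@dataclass(frozen=True)
class Metacommunity:
    """Immutable regional species pool.

    ``rel_abundance`` is a strictly positive probability vector; ``trait``
    holds one value per species.  ``meta_trait_mean``/``meta_trait_sd`` are
    abundance-weighted (individual-level) moments used as the reference for
    local trait-divergence statistics.
    """

    species_ids: np.ndarray
    rel_abundance: np.ndarray
    trait: np.ndarray
    meta_trait_mean: float
    meta_trait_sd: float
    newick: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in ("species_ids", "rel_abundance", "trait"):
            arr = np.asarray(getattr(self, name))
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        if len(self.trait) != len(self.species_ids):
            raise ValueError("trait vector length must equal species count")
        if np.any(self.rel_abundance <= 0):
            raise ValueError("rel_abundance entries must be strictly positive")
        if abs(float(self.rel_abundance.sum()) - 1.0) > 1e-12:
            raise ValueError("rel_abundance must sum to 1 within 1e-12")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def content_hash(self) -> str:
        """SHA256 over the pool contents; used to assert fixedness."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.species_ids).tobytes())
        h.update(np.ascontiguousarray(self.rel_abundance).tobytes())
        h.update(np.ascontiguousarray(self.trait).tobytes())
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": self.species_ids,
                "rel_abundance": self.rel_abundance,
                "trait": self.trait,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Metacommunity":
        rel = df["rel_abundance"].to_numpy(float)
        trait = df["trait"].to_numpy(float)
        mean = float(np.sum(rel * trait))
        sd = float(np.sqrt(np.sum(rel * (trait - mean) ** 2)))
        return cls(
            species_ids=df["species_id"].to_numpy(),
            rel_abundance=rel,
            trait=trait,
            meta_trait_mean=mean,
            meta_trait_sd=sd,
        )


def _yule_brownian_traits(
    n_species: int, trait_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, str]:
    """Brownian trait values at the tips of a simulated Yule tree.

    Returns traits ordered by taxon index T1..Tn together with the newick
    string of the tree used.
    """
    # dendropy draws from Python's random module; bridge our numpy seed.
    from dendropy.simulate import treesim

    pyrng = _random.Random(int(rng.integers(0, 2**31 - 1)))
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=pyrng,
    )
    values: dict = {}
    tip_values = np.empty(n_species)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = 0.0
        else:
            edge = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(
                0.0, np.sqrt(trait_rate * edge)
            )
        if node.is_leaf():
            # taxa are labelled T1..Tn by dendropy
            idx = int(node.taxon.label[1:]) - 1
            tip_values[idx] = values[node]
    buf = io.StringIO()
    tree.write(file=buf, schema="newick")
    return tip_values, buf.getvalue().strip()


def generate_metacommunity(spec: MetacommunitySpec) -> Metacommunity:
    """Build the fixed regional pool from its generator spec.

    Relative abundances are a normalized log-series sample; traits come from
    the configured trait model.  The pool-level trait mean and SD are
    abundance-weighted, i.e. they describe a randomly sampled *individual*
    from the pool, which is what the local community actually samples.
    """
    rng = np.random.default_rng(spec.seed)
    counts = stats.logser.rvs(spec.sad_shape, size=spec.n_species, random_state=rng)
    rel = counts / counts.sum()

    newick: str | None = None
    if spec.trait_model == "iid_normal":
        trait = rng.normal(0.0, np.sqrt(spec.trait_rate), spec.n_species)
    else:
        trait, newick = _yule_brownian_traits(spec.n_species, spec.trait_rate, rng)

    mean = float(np.sum(rel * trait))
    sd = float(np.sqrt(np.sum(rel * (trait - mean) ** 2)))
    return Metacommunity(
        species_ids=np.arange(spec.n_species),
        rel_abundance=np.asarray(rel, float),
        trait=np.asarray(trait, float),
        meta_trait_mean=mean,
        meta_trait_sd=sd,
        newick=newick,
    )


def sample_immigrant(meta: Metacommunity, rng: np.random.Generator) -> int:
    """Draw one immigrant species index, proportional to regional abundance."""
    u = rng.random()
    return int(np.searchsorted(np.cumsum(meta.rel_abundance), u, side="right"))
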