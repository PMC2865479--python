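"""Generators for every input the pipeline needs.

The original study system is a songbird clade scored for male and female
ornament elaboration on a 23-species rooted speciational phylogeny.
That topology and score table are not bundled here, so this module
produces stand-ins: Yule-topology speciational trees, pseudo-observed
score tables simulated under a chosen constraint model calibrated to a
target cross-sex correlation, and latent-factor measurement matrices
whose correlation-matrix PCA retains a known number of components.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .phylo import Phylogeny
from .simulate import (ModelName, _as_model, TipPhenotypes,
                       calibrate_pull_constant, simulate_tip_matrix)

# Observed cross-sex correlation regimes emulated by default: carotenoid
# coloration r = 0.893, melanin r = 0.560, total coloration r = 0.848,
# each over N = 23 species.
DEFAULT_TARGET_R = {"carotenoid": 0.893, "melanin": 0.560, "total": 0.848}
DEFAULT_N_SPECIES = 23


@dataclass
class SyntheticStudySpec:
    """Parameters of one pseudo-observed dataset."""

    n_species: int = DEFAULT_N_SPECIES
    model: ModelName = ModelName.CONSTRAINT_ON_FEMALES
    target_r: float = DEFAULT_TARGET_R["carotenoid"]
    seed: int = 0

    def __post_init__(self):
        self.model = _as_model(self.model)
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if not 0.0 < self.target_r <= 1.0:
            raise ValueError("target_r must be in (0, 1]")


def gen_yule_tree(n_tips: int, seed: int = 0) -> Phylogeny:
    """Random speciational tree grown by uniform tip splitting.

    Starting from a two-tip tree, a uniformly chosen extant tip splits
    into two daughters until ``n_tips`` is reached (the Yule pure-birth
    topology process); branch lengths are then set to 1 throughout.
    Tips are labelled sp01, sp02, ... in traversal order.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    tips = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        tips.append(child)
    while len(tips) < n_tips:
        idx = int(rng.integers(len(tips)))
        node = tips.pop(idx)
        for _ in range(2):
            tips.append(node.new_child())
    width = max(2, len(str(n_tips)))
    namespace = tree.taxon_namespace
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            counter += 1
            taxon = namespace.new_taxon(f"sp{counter:0{width}d}")
            node.taxon = taxon
        node.edge.length = 1.0
    tree.seed_node.edge.length = None
    return Phylogeny(tree).as_speciational()


def gen_study_dataset(tree: Phylogeny, spec: SyntheticStudySpec
                      ) -> TipPhenotypes:
    """Pseudo-observed score table under the spec's constraint model.

    The pull constant is calibrated to the spec's target correlation,
    then one simulation provides the score table.  Every species
    satisfies female <= male by the simulator's invariant.
    """
    tree = tree if tree.is_speciational else tree.as_speciational()
    c = calibrate_pull_constant(
        tree, spec.model, spec.target_r, seed=spec.seed
    )
    rng = np.random.default_rng(spec.seed + 1)
    male, female = simulate_tip_matrix(tree, spec.model, c, 1, rng=rng)
    return TipPhenotypes(
        species=tree.tip_labels, male=male[0], female=female[0]
    )


def gen_measurement_matrix(n_species: int, n_traits: int,
                           n_factors: int = 1, loading: float = 0.8,
                           noise_sd: float = 0.6,
                           seed: int = 0) -> pd.DataFrame:
    """Latent-factor species x trait measurement matrix.

    Each trait loads on exactly one of ``n_factors`` latent factors
    (assigned round-robin) with the given loading; independent
    Normal(0, noise_sd) noise is added.  With loading 0.8 and noise SD
    0.6 the broken-stick criterion typically recovers ``n_factors``.
    """
    if not (1 <= n_factors < n_traits < n_species):
        raise ValueError(
            "need 1 <= n_factors < n_traits < n_species, got "
            f"({n_factors}, {n_traits}, {n_species})"
        )
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_species, n_factors))
    pattern = np.zeros((n_factors, n_traits))
    for j in range(n_traits):
        pattern[j % n_factors, j] = loading
    noise = (rng.standard_normal((n_species, n_traits)) * noise_sd
             if noise_sd > 0 else 0.0)
    values = factors @ pattern + noise
    width = max(2, len(str(n_species)))
    df = pd.DataFrame(
        values, columns=[f"trait{j + 1:02d}" for j in range(n_traits)]
    )
    df.insert(0, "species",
              [f"sp{i + 1:0{width}d}" for i in range(n_species)])
    return df
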