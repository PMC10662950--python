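"""Two-species single-cell count simulator with planted homologous cell types.

The generator emulates the statistical structure a cross-species progenitor
comparison relies on: two datasets sharing a set of orthologous genes,
several shared cell types each carrying a disjoint block of type-specific
marker genes with a stated fold effect, a species-level multiplicative
expression shift on a fraction of genes, one rare shared type (standing in
for a scarce progenitor subtype such as truncated radial glia), and
negative-binomial UMI counts with lognormal library sizes.

The negative binomial is parameterized mean/dispersion with
``variance = mu + dispersion * mu**2``; per cell the expected count of a
gene is ``library_size x relative_expression`` where the relative-expression
vector (baseline x marker effect x species shift) is renormalized to sum to
one before sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment

from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "simulate_two_species",
    "make_fixture",
    "evaluate_against_truth",
    "FIXTURE_REGISTRY",
    "RARE_TYPE",
]

#: Name of the planted rare shared type (always the last type).
RARE_TYPE = "rare"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for :func:`simulate_two_species`.

    Defaults are the conditions the downstream recovery checks run under:
    six shared types at 200 cells/type/species over 1500 genes, 5 % of the
    ortholog genes marking each type at a natural-log effect of 1.0, and a
    negative-binomial dispersion of 0.1.  One of the six types is rare,
    holding ~5 % of each dataset instead of a full 200-cell allotment.
    """

    n_types: int = 6
    cells_per_type_per_species: int = 200
    n_genes: int = 1500
    frac_marker_per_type: float = 0.05
    marker_log_effect: float = 1.0
    rare_type_frac: float = 0.05
    species_shift_frac: float = 0.10
    species_shift_log_effect: float = 0.5
    dispersion: float = 0.1
    libsize_log_mean: float = 8.5
    libsize_log_sd: float = 0.3
    frac_nonortholog: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "frac_marker_per_type",
            "rare_type_frac",
            "species_shift_frac",
            "frac_nonortholog",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if self.n_types < 2:
            raise ValueError(f"n_types must be >= 2; got {self.n_types}")
        if self.cells_per_type_per_species < 1:
            raise ValueError("cells_per_type_per_species must be >= 1")
        if self.n_genes < 10:
            raise ValueError(f"n_genes must be >= 10; got {self.n_genes}")
        if self.marker_log_effect < 0:
            raise ValueError("marker_log_effect must be >= 0")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0; got {self.dispersion}")
        if self.frac_marker_per_type * self.n_types >= 1.0:
            raise ValueError(
                "total marker fraction frac_marker_per_type * n_types must be < 1"
            )


@dataclass
class PlantedTruth:
    """Ground truth of a simulated pair of datasets.

    ``labels_a``/``labels_b`` map cell id -> true type name; ``markers`` maps
    type -> tuple of marker gene names (disjoint across types); ``homology``
    is the bijection between species-A and species-B type names;
    ``species_shift`` maps shifted shared genes to their signed natural-log
    effect (applied to species B).
    """

    labels_a: pd.Series
    labels_b: pd.Series
    markers: dict[str, tuple[str, ...]]
    homology: dict[str, str]
    species_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.homology.values())) != len(self.homology):
            raise ValueError("homology map must be a bijection")
        seen: set[str] = set()
        for t, genes in self.markers.items():
            g = set(genes)
            if g & seen:
                raise ValueError(f"marker sets must be disjoint; overlap at type {t}")
            seen |= g


def _type_names(n_types: int) -> list[str]:
    return [f"type{i}" for i in range(n_types - 1)] + [RARE_TYPE]


def _cells_per_type(config: SimulationConfig) -> list[int]:
    per = config.cells_per_type_per_species
    n_major = (config.n_types - 1) * per
    n_rare = max(3, round(config.rare_type_frac / (1 - config.rare_type_frac) * n_major))
    return [per] * (config.n_types - 1) + [n_rare]


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    # NB(mean mu, var mu + phi mu^2): shape n = 1/phi, p = n / (n + mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_two_species(
    config: SimulationConfig | None = None,
) -> tuple[CountMatrix, CountMatrix, PlantedTruth]:
    """Simulate a pair of species datasets with planted homologous types.

    Returns ``(counts_a, counts_b, truth)``.  Gene name spaces of the two
    datasets overlap on exactly ``round(n_genes * (1 - frac_nonortholog))``
    shared (ortholog) genes; each species additionally carries private genes
    under species-specific names.  Same config (same seed) gives
    byte-identical outputs.
    """
    config = config or SimulationConfig()
    config.validate()

    n_shared = round(config.n_genes * (1 - config.frac_nonortholog))
    n_private = config.n_genes - n_shared
    n_markers = round(config.frac_marker_per_type * config.n_genes)
    if n_markers * config.n_types > n_shared:
        raise ValueError(
            "marker genes must fit inside the shared ortholog space: "
            f"{n_markers} markers x {config.n_types} types > {n_shared} shared genes"
        )

    # One RNG stream per concern, split in a fixed documented key order:
    # 0 shared structure, 1 species A sampling, 2 species B sampling.
    ss = np.random.SeedSequence(config.seed)
    rng_shared, rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(3))

    shared_genes = [f"G{i:05d}" for i in range(n_shared)]
    private_a = [f"PA{i:05d}" for i in range(n_private)]
    private_b = [f"PB{i:05d}" for i in range(n_private)]

    types = _type_names(config.n_types)
    # Marker blocks: disjoint, drawn from the shared genes.
    marker_pool = rng_shared.permutation(n_shared)
    markers: dict[str, tuple[str, ...]] = {}
    for k, t in enumerate(types):
        idx = marker_pool[k * n_markers : (k + 1) * n_markers]
        markers[t] = tuple(shared_genes[i] for i in sorted(idx))

    # Species-level multiplicative shift on a fraction of shared genes, random sign.
    n_shift = round(config.species_shift_frac * n_shared)
    shift_idx = np.sort(rng_shared.permutation(n_shared)[:n_shift])
    shift_sign = rng_shared.choice([-1.0, 1.0], size=n_shift)
    species_shift = {
        shared_genes[i]: float(s * config.species_shift_log_effect)
        for i, s in zip(shift_idx, shift_sign)
    }

    # Baselines: shared genes share one baseline across species; private genes
    # get fresh baselines per species.
    base_shared = rng_shared.lognormal(mean=0.0, sigma=1.0, size=n_shared)
    base_priv_a = rng_shared.lognormal(mean=0.0, sigma=1.0, size=n_private)
    base_priv_b = rng_shared.lognormal(mean=0.0, sigma=1.0, size=n_private)

    cells_per_type = _cells_per_type(config)
    marker_index = {t: np.array([shared_genes.index(g) for g in markers[t]]) for t in types}

    def build(species: str, rng: np.random.Generator, base_priv, private_names,
              apply_shift: bool):
        gene_ids = shared_genes + private_names
        base = np.concatenate([base_shared, base_priv])
        shift_mult = np.ones(len(gene_ids))
        if apply_shift:
            shift_mult[shift_idx] = np.exp(shift_sign * config.species_shift_log_effect)
        profiles = {}
        for t in types:
            rel = base * shift_mult
            rel = rel.copy()
            rel[marker_index[t]] *= np.exp(config.marker_log_effect)
            profiles[t] = rel / rel.sum()
        blocks, labels, cell_ids = [], [], []
        offset = 0
        for t, n_cells in zip(types, cells_per_type):
            lib = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, n_cells)
            lib = np.maximum(lib, 100.0)  # truncate: no degenerate empty cells
            mu = lib[:, None] * profiles[t][None, :]
            blocks.append(_sample_counts(rng, mu, config.dispersion))
            labels += [t] * n_cells
            cell_ids += [f"{species}_{offset + i:05d}" for i in range(n_cells)]
            offset += n_cells
        X = sp.csr_matrix(np.vstack(blocks).astype(np.int64))
        meta = pd.DataFrame(
            {"species": species, "true_type": labels}, index=pd.Index(cell_ids)
        )
        counts = CountMatrix(X, pd.Index(cell_ids), pd.Index(gene_ids), cell_meta=meta)
        return counts, pd.Series(labels, index=pd.Index(cell_ids), name="true_type")

    counts_a, labels_a = build("A", rng_a, base_priv_a, private_a, apply_shift=False)
    counts_b, labels_b = build("B", rng_b, base_priv_b, private_b, apply_shift=True)

    truth = PlantedTruth(
        labels_a=labels_a,
        labels_b=labels_b,
        markers=markers,
        homology={t: t for t in types},
        species_shift=species_shift,
    )
    return counts_a, counts_b, truth


# ---------------------------------------------------------------------------
# Tiny deterministic fixtures for exact tests
# ---------------------------------------------------------------------------


def _fixture_norm4x3() -> CountMatrix:
    # 4 cells x 3 genes, per-cell totals 10, 10, 10, 20.
    X = np.array(
        [
            [1, 2, 7],
            [0, 5, 5],
            [3, 3, 4],
            [10, 4, 6],
        ]
    )
    return CountMatrix(
        sp.csr_matrix(X),
        pd.Index([f"c{i}" for i in range(4)]),
        pd.Index(["gA", "gB", "gC"]),
    )


def _fixture_separable6v6() -> CountMatrix:
    # 12 cells; gene SEP has count 1 in exactly the 6 cells of cluster X.
    sep = np.array([1] * 6 + [0] * 6)
    bg1 = np.ones(12, dtype=int)
    bg2 = np.array([2, 1, 2, 1, 2, 1, 1, 2, 1, 2, 1, 2])
    X = np.column_stack([sep, bg1, bg2])
    meta = pd.DataFrame(
        {"cluster": ["X"] * 6 + ["Y"] * 6},
        index=pd.Index([f"c{i:02d}" for i in range(12)]),
    )
    return CountMatrix(
        sp.csr_matrix(X),
        meta.index,
        pd.Index(["SEP", "BG1", "BG2"]),
        cell_meta=meta,
    )


def _fixture_genescore_toy() -> pd.DataFrame:
    # Rows chosen so genescore = avg_logFC * pct1 / max(pct2, 0.001) is an
    # exact rational: 0.5*0.8/0.2 = 2, 1.0*0.5/0.001 = 500, 0.3*0.3/0.3 = 0.3.
    return pd.DataFrame(
        {
            "cluster": ["K", "K", "K"],
            "gene": ["g1", "g2", "g3"],
            "avg_logFC": [0.5, 1.0, 0.3],
            "pct1": [0.8, 0.5, 0.3],
            "pct2": [0.2, 0.0, 0.3],
            "p_value": [0.001, 0.0005, 0.01],
            "p_adjusted": [0.003, 0.0015, 0.03],
        }
    )


FIXTURE_REGISTRY = {
    "norm4x3": _fixture_norm4x3,
    "separable6v6": _fixture_separable6v6,
    "genescore_toy": _fixture_genescore_toy,
}


def make_fixture(name: str):
    """Return a small deterministic object from the fixture registry."""
    try:
        return FIXTURE_REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; registry: {sorted(FIXTURE_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Evaluation against planted truth
# ---------------------------------------------------------------------------


def evaluate_against_truth(
    predicted_labels: pd.Series, truth_labels: pd.Series
) -> dict:
    """Precision/recall per planted type plus best-bijective accuracy.

    ``predicted_labels`` maps cell id -> predicted cluster (any hashable);
    ``truth_labels`` maps cell id -> planted type.  Overall accuracy is
    computed under the best bijective matching of predicted clusters to
    planted types (Hungarian assignment on the contingency table); per-type
    precision/recall use the matched predicted cluster for that type.
    """
    predicted_labels = pd.Series(predicted_labels)
    truth_labels = pd.Series(truth_labels)
    common = predicted_labels.index.intersection(truth_labels.index)
    if len(common) == 0:
        raise ValueError("predicted and truth label cell-id sets are disjoint")
    pred = predicted_labels.loc[common]
    true = truth_labels.loc[common]
    tab = pd.crosstab(true, pred)  # types x clusters
    cost = -tab.to_numpy()
    rows, cols = linear_sum_assignment(cost)
    matched = {tab.index[r]: tab.columns[c] for r, c in zip(rows, cols)}
    n_correct = sum(tab.iat[r, c] for r, c in zip(rows, cols))
    per_type = {}
    for t in tab.index:
        if t in matched:
            c = matched[t]
            tp = tab.loc[t, c]
            precision = tp / tab[c].sum() if tab[c].sum() else 0.0
            recall = tp / tab.loc[t].sum()
        else:
            precision = recall = 0.0
        per_type[t] = {"precision": float(precision), "recall": float(recall)}
    return {
        "accuracy": float(n_correct / len(common)),
        "per_type": per_type,
        "matching": matched,
        "n_cells": int(len(common)),
    }
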