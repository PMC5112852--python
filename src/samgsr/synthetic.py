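"""Synthetic two-class expression data with gene-set-structured signal.

Generates genes x samples matrices of correlated Gaussian log2-scale noise
with additive mean shifts on designated marker genes in the diseased class,
together with a gene-set collection of declared overlap structure and the
ground-truth marker list. Within-set correlation rho comes from a shared
standard-normal set-level factor,

    value = sigma * (sqrt(rho) * factor + sqrt(1 - rho) * idiosyncratic)
            + delta * 1[diseased & marker],

which preserves unit marginal variance before the sigma scaling. A gene
belonging to several sets takes the factor of the first set that contains
it; genes in no set are purely idiosyncratic.

The named presets in :func:`overlap_scenarios` probe the structural failure
mode of set-guided selection: markers that sit in few (or no) gene sets
cannot be found no matter how strong their signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_genesets import CONTROL, DISEASED, ExpressionDataset, GeneSetCollection


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to draw one dataset + collection + truth."""

    n_per_class: tuple[int, int] = (30, 30)     # (diseased, control)
    n_genes: int = 1000
    sets: dict[str, list[str]] = field(default_factory=dict)
    marker_shift: dict[str, float] = field(default_factory=dict)  # gene -> delta (log2 units)
    within_set_correlation: float = 0.2
    noise_sd: float = 1.0
    seed: int = 0

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]


def simulate(config: SimulationConfig):
    """Draw (ExpressionDataset, GeneSetCollection, marker gene list).

    Deterministic given ``config.seed``. Raises if a marker or set member
    falls outside the gene universe or rho is outside [0, 1).
    """
    rho = config.within_set_correlation
    if not 0.0 <= rho < 1.0:
        raise ValueError("within_set_correlation must lie in [0, 1)")
    if config.noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    n_d, n_c = config.n_per_class
    if n_d < 2 or n_c < 2:
        raise ValueError("need >= 2 samples per class")

    genes = config.gene_ids()
    universe = set(genes)
    for name, members in config.sets.items():
        outside = [g for g in members if g not in universe]
        if outside:
            raise ValueError(f"set {name!r} members outside universe: {outside[:5]}")
    bad_markers = [g for g in config.marker_shift if g not in universe]
    if bad_markers:
        raise ValueError(f"markers outside universe: {bad_markers[:5]}")

    n = n_d + n_c
    rng = np.random.default_rng(config.seed)

    # factor index per gene: first containing set, -1 for set-free genes
    factor_of_gene = np.full(len(genes), -1, dtype=int)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for set_idx, members in enumerate(config.sets.values()):
        for g in members:
            i = gene_pos[g]
            if factor_of_gene[i] < 0:
                factor_of_gene[i] = set_idx

    factors = rng.standard_normal((max(len(config.sets), 1), n))
    idio = rng.standard_normal((len(genes), n))
    values = np.sqrt(1.0 - rho) * idio
    in_set = factor_of_gene >= 0
    values[in_set] += np.sqrt(rho) * factors[factor_of_gene[in_set]]
    values[~in_set] += (1.0 - np.sqrt(1.0 - rho)) * idio[~in_set]  # unit variance everywhere
    values *= config.noise_sd

    diseased_cols = np.arange(n) < n_d
    for g, delta in config.marker_shift.items():
        values[gene_pos[g], diseased_cols] += delta

    sample_ids = [f"d{i + 1:03d}" for i in range(n_d)] + \
                 [f"c{i + 1:03d}" for i in range(n_c)]
    labels = pd.Series(
        [DISEASED] * n_d + [CONTROL] * n_c, index=sample_ids, name="label"
    )
    ds = ExpressionDataset(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                     columns=sample_ids),
        labels,
    )
    coll = GeneSetCollection(
        sets={k: list(v) for k, v in config.sets.items()},
        descriptions={k: "synthetic" for k in config.sets},
        source="synthetic",
    )
    return ds, coll, sorted(config.marker_shift)


# ---------------------------------------------------------------------------
# structured configs


def _block_sets(genes: list[str], markers: list[str], n_marker_sets: int,
                n_background_sets: int, set_size: int,
                include_markers: bool) -> dict[str, list[str]]:
    """Marker sets share all markers; background sets are disjoint filler."""
    filler = [g for g in genes if g not in set(markers)]
    sets: dict[str, list[str]] = {}
    pos = 0
    n_fill = set_size - (len(markers) if include_markers else 0)
    for s in range(n_marker_sets):
        members = (list(markers) if include_markers else []) + filler[pos:pos + n_fill]
        pos += n_fill
        sets[f"S{s + 1:02d}"] = members
    for s in range(n_background_sets):
        sets[f"N{s + 1:02d}"] = filler[pos:pos + set_size]
        pos += set_size
    if pos > len(filler):
        raise ValueError("gene universe too small for the requested sets")
    return sets


def shared_marker_config(*, n_markers: int = 5, n_marker_sets: int = 3,
                         n_background_sets: int = 7, set_size: int = 10,
                         shift: float = 2.0, n_per_class: tuple[int, int] = (30, 30),
                         n_genes: int = 1000, rho: float = 0.2,
                         noise_sd: float = 1.0, seed: int = 0,
                         markers_in_sets: bool = True) -> SimulationConfig:
    """Markers shared by several gene sets, on a background of null sets.

    The default shape — 5 markers shifted by 2 noise SDs, present in 3 sets
    of 10 genes, with 7 pure-noise background sets and n = 30 + 30 — is the
    package's reference scenario for ground-truth recovery.
    """
    width = max(4, len(str(n_genes)))
    genes = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    markers = genes[:n_markers]
    sets = _block_sets(genes, markers, n_marker_sets, n_background_sets,
                       set_size, include_markers=markers_in_sets)
    delta = shift * noise_sd
    return SimulationConfig(
        n_per_class=n_per_class, n_genes=n_genes, sets=sets,
        marker_shift={g: delta for g in markers} if delta != 0 else {},
        within_set_correlation=rho, noise_sd=noise_sd, seed=seed,
    )


def overlap_scenarios(seed: int = 0) -> dict[str, SimulationConfig]:
    """Named presets spanning the set-membership gradient of the markers.

    ``markers-in-many-sets`` / ``markers-in-one-set`` vary how many sets
    carry the markers; ``markers-in-no-set`` keeps the differential signal
    but removes the markers from every set (set-guided selection is then
    structurally blind to them); ``pure-null`` has no signal at all.
    """
    common = dict(n_markers=5, set_size=10, shift=2.0, seed=seed)
    return {
        "markers-in-many-sets": shared_marker_config(
            n_marker_sets=5, n_background_sets=5, **common),
        "markers-in-one-set": shared_marker_config(
            n_marker_sets=1, n_background_sets=9, **common),
        "markers-in-no-set": shared_marker_config(
            n_marker_sets=3, n_background_sets=7, markers_in_sets=False,
            **common),
        "pure-null": shared_marker_config(
            n_marker_sets=3, n_background_sets=7, shift=0.0, seed=seed,
            n_markers=5, set_size=10),
    }
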