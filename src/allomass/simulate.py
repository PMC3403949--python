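"""Synthetic measurement tables and tree+trait sets.

The generators emulate the statistical structure the analyses assume: a
log10-linear relation between combined stylopodial circumference and
body mass with slope near 2.78, intercept near -1.16 and R^2 near
0.986 over a log10 circumference span of about 1.3-3.2 (the empirical
all-data values for extant quadrupeds), clade structure, optional
planted outliers, and Brownian-motion traits evolved on pure-birth
trees.  Log-predictor values are drawn uniformly over the span so that
var(x) — and hence slope recovery — is stable across replicates.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .core_data import COLUMNS, MeasurementTable, derive_variables

__all__ = [
    "SimulationConfig",
    "DEFAULT_CLADES",
    "simulate_allometric_table",
    "simulate_pure_birth_tree",
    "simulate_tree_and_traits",
    "inject_outliers",
]

#: clade composition loosely matching the extant sample (fractions of n)
DEFAULT_CLADES: dict[str, float] = {
    "Ungulata": 41 / 247,
    "Carnivora": 48 / 247,
    "Marsupialia": 14 / 247,
    "Euarchonta": 15 / 247,
    "Glires": 66 / 247,
    "other": 16 / 247,
    "Reptilia": 47 / 247,
}


@dataclass
class SimulationConfig:
    """Parameters of the bivariate allometric generator.

    ``slope``/``intercept``/``target_R2`` default to the all-data
    circumference-mass values; ``x_range`` is the log10 mm span of the
    combined circumference.  Exactly one of ``sigma`` (residual SD in
    log10 units) and ``target_R2`` may be set; with ``target_R2`` the
    residual SD is solved from sigma^2 = (1-R^2)/R^2 * slope^2 * var(x)
    for x uniform on the range.
    """

    n: int = 247
    slope: float = 2.78
    intercept: float = -1.16
    sigma: float | None = None
    target_R2: float | None = 0.986
    x_range: tuple[float, float] = (1.3, 3.2)
    clades: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLADES))
    seed: int = 0
    length_slope: float = 1.03  # log C on log L slope for generated lengths
    length_sigma: float = 0.06

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n >= 3 required")
        if self.sigma is not None and self.target_R2 is not None:
            raise ValueError("set either sigma or target_R2, not both")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma >= 0 required")
        if not self.x_range[0] < self.x_range[1]:
            raise ValueError("x_range must be (lo, hi) with lo < hi")
        total = sum(self.clades.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"clade proportions sum to {total}, not 1")

    @property
    def resolved_sigma(self) -> float:
        if self.sigma is not None:
            return self.sigma
        r2 = self.target_R2
        var_x = (self.x_range[1] - self.x_range[0]) ** 2 / 12.0
        return math.sqrt((1 - r2) / r2 * self.slope**2 * var_x)


def simulate_allometric_table(config: SimulationConfig) -> MeasurementTable:
    """Draw a measurement table from the log-linear allometric model.

    log10 C_H+F ~ Uniform(x_range); log10 BM = slope*x + intercept + N(0,
    sigma); the humeral share of the combined circumference is Beta
    distributed around 0.48; stylopodial lengths are generated from each
    circumference through an approximately isometric log-linear relation
    so that length-based and multiple-predictor analyses have realistic
    structure.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    x = rng.uniform(*config.x_range, size=n)
    sigma = config.resolved_sigma
    log_bm = config.slope * x + config.intercept + rng.normal(0.0, sigma, size=n)
    chf = 10.0**x
    share = rng.beta(48.0, 52.0, size=n)  # humeral share, mean 0.48
    c_h = share * chf
    c_f = (1.0 - share) * chf
    # invert log C = length_slope * log L + b with b chosen near the
    # empirical femoral value, plus independent noise on the length
    b_len = -0.60
    log_l_f = (np.log10(c_f) - b_len) / config.length_slope + rng.normal(
        0.0, config.length_sigma, size=n
    )
    log_l_h = (np.log10(c_h) - b_len) / config.length_slope + rng.normal(
        0.0, config.length_sigma, size=n
    )
    labels = list(config.clades)
    clade = rng.choice(labels, size=n, p=[config.clades[c] for c in labels])
    df = pd.DataFrame(
        {
            "species": [f"sim_sp{i:04d}" for i in range(n)],
            "class": np.where(clade == "Reptilia", "Reptilia", "Mammalia"),
            "clade": clade,
            "lifestyle": "terrestrial",
            "body_mass_g": 10.0**log_bm,
            "humerus_length_mm": 10.0**log_l_h,
            "humerus_circ_mm": c_h,
            "femur_length_mm": 10.0**log_l_f,
            "femur_circ_mm": c_f,
            "source": "simulated",
        },
        columns=COLUMNS,
    )
    table = MeasurementTable(df, provenance=f"simulate_allometric_table(seed={config.seed})")
    return derive_variables(table)


def simulate_pure_birth_tree(
    n_tips: int, birth_rate: float = 0.1, seed: int = 0
) -> dendropy.Tree:
    """Simulate a Yule (pure-birth) tree with ``n_tips`` extant tips.

    Speciation events occur at rate ``birth_rate`` per lineage per Myr;
    after the n-th lineage appears the tree is extended by one further
    exponential waiting time so every pendant edge has positive length.
    """
    if n_tips < 3:
        raise ValueError("n_tips >= 3 required")
    if birth_rate <= 0:
        raise ValueError("birth_rate > 0 required")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    t = 0.0
    root_children = [tree.seed_node.new_child(), tree.seed_node.new_child()]
    birth_time = {id(nd): 0.0 for nd in root_children}
    active = list(root_children)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(len(active))
        parent = active.pop(idx)
        parent.edge.length = t - birth_time[id(parent)]
        kids = [parent.new_child(), parent.new_child()]
        for kd in kids:
            birth_time[id(kd)] = t
        active.extend(kids)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for i, nd in enumerate(active):
        nd.edge.length = t - birth_time[id(nd)]
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(f"t{i + 1}")
    tree.seed_node.edge.length = None
    return tree


def _simulate_bm(
    tree: dendropy.Tree, sigma: float, rng: np.random.Generator
) -> dict[str, float]:
    """Brownian motion along the tree, root value 0, rate sigma^2/Myr."""
    value = {id(tree.seed_node): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        step = rng.normal(0.0, sigma * math.sqrt(node.edge.length))
        value[id(node)] = value[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = value[id(node)]
    return out


def simulate_tree_and_traits(
    n_tips: int,
    birth_rate: float = 0.1,
    slope: float = 2.78,
    sigma_x: float = 0.2,
    sigma_resid: float = 0.05,
    seed: int = 0,
) -> tuple[dendropy.Tree, dict[str, dict[str, float]]]:
    """Pure-birth tree with correlated Brownian tip traits.

    x evolves by Brownian motion with rate ``sigma_x**2``; y = slope*x
    plus an independent Brownian residual with rate ``sigma_resid**2``.
    Returns the tree and ``{"x": tip_map, "y": tip_map}``.
    """
    if sigma_x <= 0 or sigma_resid < 0:
        raise ValueError("rates must be positive (sigma_resid may be 0)")
    rng = np.random.default_rng(seed)
    tree = simulate_pure_birth_tree(n_tips, birth_rate, seed=int(rng.integers(2**31)))
    x = _simulate_bm(tree, sigma_x, rng)
    resid = (
        _simulate_bm(tree, sigma_resid, rng)
        if sigma_resid > 0
        else {k: 0.0 for k in x}
    )
    y = {tip: slope * x[tip] + resid[tip] for tip in x}
    return tree, {"x": x, "y": y}


def inject_outliers(
    table: MeasurementTable, k: int, magnitude: float, seed: int = 0
) -> tuple[MeasurementTable, list[str]]:
    """Multiply the body mass of ``k`` randomly chosen species by ``magnitude``.

    Returns the modified table and the list of altered species.
    ``magnitude`` must be positive and different from 1 (a silent no-op
    would defeat outlier-detection tests).
    """
    if k >= len(table):
        raise ValueError("k must be smaller than the table size")
    if magnitude <= 0 or magnitude == 1:
        raise ValueError("magnitude must be > 0 and != 1")
    df = table.df.copy()
    if k > 0:
        rng = np.random.default_rng(seed)
        rows = rng.choice(len(df), size=k, replace=False)
        df.loc[rows, "body_mass_g"] *= magnitude
        chosen = list(df.loc[rows, "species"])
    else:
        chosen = []
    out = MeasurementTable(df, provenance=table.provenance + f" +outliers(k={k})")
    if "log_body_mass_g" in df.columns:
        out = derive_variables(out)
    return out, chosen
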