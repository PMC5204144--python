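"""Generators for phylogenies, trait evolution and multi-census stem data.

The generator mirrors the statistical structure the analysis assumes so
every stage can be tested against known truth:

* pure-birth (Yule) ultrametric phylogenies with genera at the tips;
* Brownian-motion trait evolution (optionally lambda-transformed, or
  tip-shuffled to destroy signal), with species-level draws around each
  genus value to exercise the intrageneric-SE machinery;
* stem-level censuses at irregular intervals: genus-specific growth with
  log-normal stem heterogeneity and multiplicative plot offsets, additive
  diameter measurement noise, exponential survival with a size effect on
  the log hazard, occasional POM changes, a palm fraction, and a census
  floor of 10 cm diameter.

Every simulated dataset carries a truth table holding both the generating
parameters and the realized per-genus values, so recovery tests never
hard-code expected numbers. All outputs are reproducible from (config,
seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from scipy.stats import lognorm

from .census_io import CENSUS_COLUMNS, PLOT_COLUMNS, WD_COLUMNS
from .phylo_signal import PhyloCovariance, phylo_vcv, _lambda_transform

__all__ = [
    "SimConfig",
    "TraitSim",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_traits",
    "simulate_bm_matrix",
    "genus_params_from_tree",
    "simulate_census",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic forest-census generator.

    Defaults emulate the lowland Amazon plot-network setting: mostly 1-ha
    plots, ~4.4-yr mean census intervals, stem diameters >= 10 cm, genus
    mean diameter growth around 0.26 cm yr^-1, mortality around 1 % yr^-1,
    genus wood densities centred on 0.61 g cm^-3, and a small palm fraction.
    """

    n_genera: int = 100
    species_per_genus_mean: float = 3.0  # 1 + Poisson(mean - 1)
    n_plots: int = 10
    plot_area: float = 1.0  # ha
    n_censuses: int = 3
    census_interval_mean: float = 4.4  # yr
    census_interval_sd: float = 1.0  # yr (irregular intervals)
    first_census_year: float = 2000.0
    census_dates: list | None = None  # explicit per-plot dates override
    stems_per_genus: int = 150
    birth_rate: float = 1.0  # Yule speciation rate (tree sim)
    trait_model: str = "bm"  # bm | lambda | shuffled
    trait_sigma2: float = 1.0
    trait_lambda: float = 1.0
    growth_mean_base: float = 0.26  # cm yr^-1, genus-level geometric centre
    growth_genus_lnsd: float = 0.5  # spread of genus means (log scale)
    growth_stem_lnsd: float = 0.5  # stem heterogeneity around genus mean (log scale)
    plot_offset_sd: float = 0.2  # plot random intercept sd (log scale)
    measurement_noise_sd: float = 0.1  # cm, additive on observed diameter
    mortality_alpha_mean: float = -4.5  # ln hazard at z = 0 (~1.1 % yr^-1)
    mortality_alpha_sd: float = 0.5  # spread of genus log hazards
    mortality_beta: float = -0.2  # shared slope on standardized ln initial diameter
    pom_change_prob: float = 0.02  # per surviving census
    pom_shrink: float = 0.05  # relative diameter drop at the raised POM
    palm_fraction: float = 0.05
    non_tape_fraction: float = 0.001
    wd_mean: float = 0.61  # g cm^-3
    wd_genus_sd: float = 0.12
    wd_species_sd: float = 0.05  # intrageneric spread
    d0_median: float = 15.0  # cm, log-normal initial diameters truncated at 10
    d0_lnsd: float = 0.45
    e_range: tuple = (-0.1, 0.2)
    precip_range: tuple = (1400.0, 3500.0)
    elev_range: tuple = (0.0, 400.0)
    plot_center: tuple = (-3.1, -60.0)  # lat, lon
    plot_scatter_deg: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trait_sigma2", "growth_mean_base", "census_interval_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("pom_change_prob", "palm_fraction", "non_tape_fraction"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.trait_model not in ("bm", "lambda", "shuffled"):
            raise ValueError("trait_model must be bm | lambda | shuffled")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("e_range", "precip_range", "elev_range", "plot_center"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree with tips G0001, G0002, ...

    Starts from two lineages at the root; with k lineages the next split
    arrives after Exp(k * birth_rate) and hits a uniformly chosen lineage.
    After the n-th tip appears the tree grows for one further Exp(n * rate)
    interval so terminal branches are strictly positive.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    t = 0.0
    start: dict = {}
    active: list = []
    for _ in range(2):
        child = dendropy.Node()
        tree.seed_node.add_child(child)
        start[child] = 0.0
        active.append(child)

    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        nd = active.pop(rng.integers(k))
        nd.edge.length = t - start[nd]
        for _ in range(2):
            child = dendropy.Node()
            nd.add_child(child)
            start[child] = t
            active.append(child)

    t_end = t + rng.exponential(1.0 / (n_tips * birth_rate))
    for nd in active:
        nd.edge.length = t_end - start[nd]

    width = max(4, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tns.new_taxon(label=f"G{i:0{width}d}")
    return tree


# ---------------------------------------------------------------------------
# trait evolution
# ---------------------------------------------------------------------------


def simulate_bm_matrix(
    tree: dendropy.Tree, n_traits: int, sigma2: float = 1.0, seed: int = 0
) -> tuple[list[str], np.ndarray]:
    """``n_traits`` independent BM traits on ``tree``; root value 0.

    Returns (tip labels in leaf-traversal order, tips x traits array).
    Increments along each branch are Normal(0, sigma2 * branch length);
    sigma2 = 0 degenerates to the root value at every tip.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    vals: dict = {tree.seed_node: np.zeros(n_traits)}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        el = nd.edge.length
        vals[nd] = vals[nd.parent_node] + rng.normal(0.0, np.sqrt(sigma2 * el), n_traits)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    X = np.vstack([vals[lf] for lf in leaves])
    return labels, X


@dataclass
class TraitSim:
    genus_values: pd.Series  # tip label -> trait value
    species_values: pd.DataFrame | None  # genus, species, value
    model: str
    seed: int


def simulate_traits(
    tree: dendropy.Tree,
    model: str = "bm",
    sigma2: float = 1.0,
    lam: float = 1.0,
    seed: int = 0,
    species_per_genus_mean: float | None = None,
    intrageneric_sd: float = 0.0,
) -> TraitSim:
    """One trait evolved on ``tree`` under bm | lambda | shuffled.

    ``lambda`` draws from the multivariate normal on the lambda-transformed
    covariance; ``shuffled`` evolves under BM and then permutes tip values
    (destroying signal while keeping the marginal distribution). Optional
    species-level draws are Normal(genus value, intrageneric_sd^2), with a
    1 + Poisson species count per genus.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    if model == "bm" or model == "shuffled":
        labels, X = simulate_bm_matrix(tree, 1, sigma2, seed=rng.integers(2**31))
        x = X[:, 0]
        if model == "shuffled":
            x = x[rng.permutation(len(x))]
    elif model == "lambda":
        C = phylo_vcv(tree)
        labels = list(C.labels)
        Clam = _lambda_transform(C.matrix, lam)
        L = np.linalg.cholesky(sigma2 * Clam)
        x = L @ rng.standard_normal(len(labels))
    else:
        raise ValueError("model must be bm | lambda | shuffled")
    genus_values = pd.Series(x, index=labels, name="trait")

    species_values = None
    if species_per_genus_mean is not None:
        rows = []
        for g in labels:
            k = 1 + rng.poisson(max(species_per_genus_mean - 1.0, 0.0))
            draws = rng.normal(genus_values[g], intrageneric_sd, k)
            rows += [{"genus": g, "species": f"{g} sp{j + 1}", "value": v}
                     for j, v in enumerate(draws)]
        species_values = pd.DataFrame(rows)
    return TraitSim(genus_values, species_values, model, seed)


# ---------------------------------------------------------------------------
# census simulation
# ---------------------------------------------------------------------------


def genus_params_from_tree(
    tree: dendropy.Tree, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Phylogenetically structured generator parameters per genus.

    Three independent traits evolve on the tree under ``config.trait_model``
    and are mapped to: genus mean growth (log-normal around
    ``growth_mean_base``), genus log mortality hazard, and genus wood
    density (clipped to the plausible 0.15-1.21 g cm^-3 span).
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed).spawn(3)
    draws = []
    for sub in ss:
        ts = simulate_traits(
            tree, model=config.trait_model, sigma2=config.trait_sigma2,
            lam=config.trait_lambda, seed=int(sub.generate_state(1)[0] % 2**31),
        )
        x = ts.genus_values
        sd = x.std(ddof=1)
        draws.append((x - x.mean()) / (sd if sd > 0 else 1.0))
    z_growth, z_mort, z_wd = draws
    return pd.DataFrame({
        "growth_mean": config.growth_mean_base * np.exp(config.growth_genus_lnsd * z_growth),
        "mort_alpha": config.mortality_alpha_mean + config.mortality_alpha_sd * z_mort,
        "wd": np.clip(config.wd_mean + config.wd_genus_sd * z_wd, 0.15, 1.21),
    })


@dataclass
class SimulatedDataset:
    census: pd.DataFrame  # census_io dialect
    plots: pd.DataFrame
    wood_density: pd.DataFrame
    truth_genus: pd.DataFrame
    truth_plot: pd.DataFrame
    truth_stem: pd.DataFrame
    config: SimConfig
    seed: int

    def write(self, out_dir) -> dict:
        """Write the CSVs census_io reads, plus truth tables and config."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "census": out / "census.csv",
            "plots": out / "plots.csv",
            "wood_density": out / "wood_density.csv",
            "truth_genus": out / "truth_genus.csv",
            "truth_plot": out / "truth_plot.csv",
            "truth_stem": out / "truth_stem.csv",
            "config": out / "sim_config.yaml",
        }
        self.census.to_csv(paths["census"], index=False)
        self.plots.to_csv(paths["plots"], index=False)
        self.wood_density.to_csv(paths["wood_density"], index=False)
        self.truth_genus.to_csv(paths["truth_genus"], index=True)
        self.truth_plot.to_csv(paths["truth_plot"], index=True)
        self.truth_stem.to_csv(paths["truth_stem"], index=False)
        self.config.to_yaml(paths["config"])
        return paths


def _census_dates(config: SimConfig, rng) -> np.ndarray:
    """(n_plots, n_censuses) census dates; irregular but >= 0.5 yr apart."""
    if config.census_dates is not None:
        dates = np.asarray(config.census_dates, dtype=float)
        if dates.ndim == 1:
            dates = np.tile(dates, (config.n_plots, 1))
        if np.any(np.diff(dates, axis=1) <= 0):
            raise ValueError("census_dates must be strictly increasing per plot")
        return dates
    t0 = config.first_census_year + rng.uniform(0.0, 1.0, config.n_plots)
    gaps = np.maximum(
        rng.normal(config.census_interval_mean, config.census_interval_sd,
                   (config.n_plots, config.n_censuses - 1)),
        0.5,
    )
    return np.column_stack([t0, t0[:, None] + np.cumsum(gaps, axis=1)])


def simulate_census(
    config: SimConfig,
    genus_params: pd.DataFrame,
    seed: int | None = None,
) -> SimulatedDataset:
    """Generate a multi-census stem table from per-genus parameters.

    ``genus_params`` must be indexed by genus with columns ``growth_mean``
    (cm yr^-1), ``mort_alpha`` (ln hazard at z = 0) and ``wd`` (g cm^-3) —
    typically from :func:`genus_params_from_tree`.
    """
    req = {"growth_mean", "mort_alpha", "wd"}
    if not req.issubset(genus_params.columns):
        raise ValueError(f"genus_params needs columns {sorted(req)}")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    genera = list(genus_params.index)
    n_gen = len(genera)
    n = n_gen * config.stems_per_genus
    gidx = np.repeat(np.arange(n_gen), config.stems_per_genus)
    pidx = rng.integers(config.n_plots, size=n)
    palm = rng.random(n) < config.palm_fraction
    non_tape = rng.random(n) < config.non_tape_fraction

    n_species = 1 + rng.poisson(max(config.species_per_genus_mean - 1.0, 0.0), n_gen)
    sp_of_stem = rng.integers(n_species[gidx]) + 1

    # truncated log-normal initial diameters (floor at the 10 cm census limit)
    dist = lognorm(s=config.d0_lnsd, scale=config.d0_median)
    p10 = dist.cdf(10.0)
    d0 = dist.ppf(rng.uniform(p10, 1.0, n))

    lnd0 = np.log(d0)
    sdz = lnd0.std(ddof=1)
    z = (lnd0 - lnd0.mean()) / (sdz if sdz > 0 else 1.0)
    alpha = genus_params["mort_alpha"].to_numpy()[gidx]
    hazard = np.exp(alpha + config.mortality_beta * z)

    plot_offsets = rng.normal(0.0, config.plot_offset_sd, config.n_plots)
    g_true = (
        genus_params["growth_mean"].to_numpy()[gidx]
        * np.exp(rng.normal(0.0, config.growth_stem_lnsd, n))
        * np.exp(plot_offsets[pidx])
    )

    dates = _census_dates(config, rng)
    n_cen = dates.shape[1]
    stem_dates = dates[pidx]  # (n, n_censuses)
    true_d = d0[:, None] + g_true[:, None] * (stem_dates - stem_dates[:, [0]])

    alive = np.ones((n, n_cen), dtype=bool)
    for j in range(1, n_cen):
        dt = stem_dates[:, j] - stem_dates[:, j - 1]
        surv_p = np.exp(-hazard * dt)
        alive[:, j] = alive[:, j - 1] & (rng.random(n) < surv_p)

    stem_ids = np.array([f"S{i + 1:06d}" for i in range(n)])
    genus_of = np.array(genera, dtype=object)[gidx]
    species_of = np.array(
        [f"{g} sp{k}" for g, k in zip(genus_of, sp_of_stem)], dtype=object
    )

    rows: list[list] = []
    shrink = np.ones(n)
    prev_alive = np.ones(n, dtype=bool)
    pom0 = 1.3
    pom_h = np.full(n, pom0)
    noise = lambda size: rng.normal(0.0, config.measurement_noise_sd, size)
    for j in range(n_cen):
        obs_d = np.maximum(true_d[:, j] * shrink + noise(n), 0.1)
        if j == 0:
            change = np.zeros(n, dtype=bool)
        else:
            change = alive[:, j] & (rng.random(n) < config.pom_change_prob)
        new_shrink = np.where(change, shrink * (1.0 - config.pom_shrink), shrink)
        new_d = np.maximum(true_d[:, j] * new_shrink + noise(n), 0.1)
        for i in np.flatnonzero(prev_alive):
            if alive[i, j]:
                rows.append([
                    stem_ids[i], f"P{pidx[i] + 1:03d}", genus_of[i], species_of[i],
                    "palm" if palm[i] else "tree",
                    round(stem_dates[i, j], 6),
                    round(obs_d[i], 6),
                    round(pom_h[i] + (0.5 if change[i] else 0.0), 2),
                    True, not non_tape[i],
                    round(new_d[i], 6) if change[i] else "",
                ])
            else:
                rows.append([
                    stem_ids[i], f"P{pidx[i] + 1:03d}", genus_of[i], species_of[i],
                    "palm" if palm[i] else "tree",
                    round(stem_dates[i, j], 6), "", round(pom_h[i], 2),
                    False, True, "",
                ])
        pom_h = np.where(change, pom_h + 0.5, pom_h)
        shrink = new_shrink
        prev_alive = alive[:, j]

    census = pd.DataFrame(rows, columns=CENSUS_COLUMNS)

    lat0, lon0 = config.plot_center
    plots = pd.DataFrame({
        "plot_id": [f"P{i + 1:03d}" for i in range(config.n_plots)],
        "latitude": np.round(lat0 + rng.uniform(-1, 1, config.n_plots) * config.plot_scatter_deg, 4),
        "longitude": np.round(lon0 + rng.uniform(-1, 1, config.n_plots) * config.plot_scatter_deg, 4),
        "elevation": np.round(rng.uniform(*config.elev_range, config.n_plots), 1),
        "annual_precip": np.round(rng.uniform(*config.precip_range, config.n_plots), 0),
        "E": np.round(rng.uniform(*config.e_range, config.n_plots), 4),
        "area": config.plot_area,
    }, columns=PLOT_COLUMNS)

    wd_rows = []
    for g_i, g in enumerate(genera):
        for k in range(1, n_species[g_i] + 1):
            wd_val = np.clip(
                genus_params.loc[g, "wd"] + rng.normal(0.0, config.wd_species_sd),
                0.1, 1.4,
            )
            wd_rows.append({"taxon": f"{g} sp{k}", "wd": round(float(wd_val), 4)})
    wood_density = pd.DataFrame(wd_rows, columns=WD_COLUMNS)

    # realized truth: what a perfect estimator would recover
    max_true_size = np.where(
        alive[:, 0], np.max(np.where(alive, true_d, -np.inf), axis=1), d0
    )
    tg = pd.DataFrame(index=pd.Index(genera, name="genus"))
    tg["growth_mean_config"] = genus_params["growth_mean"]
    tg["mort_alpha_config"] = genus_params["mort_alpha"]
    tg["wd_config"] = genus_params["wd"]
    per = pd.DataFrame({
        "genus": genus_of, "g_true": g_true, "hazard": hazard, "max_size": max_true_size,
    })
    agg = per.groupby("genus").agg(
        growth_mean_true=("g_true", "mean"),
        hazard_mean_true=("hazard", "mean"),
        size95_true=("max_size", lambda v: float(np.quantile(v, 0.95))),
        n_stems=("g_true", "size"),
    )
    tg = tg.join(agg)
    tg["mortality_true_pct"] = 100.0 * tg["hazard_mean_true"]

    truth_plot = pd.DataFrame({
        "plot_id": plots["plot_id"],
        "log_growth_offset": plot_offsets,
    }).set_index("plot_id")

    truth_stem = pd.DataFrame({
        "stem_id": stem_ids, "genus": genus_of, "plot_id": [f"P{i + 1:03d}" for i in pidx],
        "palm": palm, "d0": d0, "g_true": g_true, "hazard": hazard,
        "survived_last": alive[:, -1],
    })

    return SimulatedDataset(
        census=census, plots=plots, wood_density=wood_density,
        truth_genus=tg, truth_plot=truth_plot, truth_stem=truth_stem,
        config=config, seed=seed,
    )
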