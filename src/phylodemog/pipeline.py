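"""End-to-end pipeline stages: simulate, traits, signal, ppca.

Each stage reads/writes plain CSV (plus a Newick tree and a JSON manifest)
in a single output directory, so stages can be run separately or chained
with ``all``. The manifest records package and library versions, the seed,
a hash of the resolved configuration and the counts behind every filter,
making every number in the result tables traceable to a stage, seed and
config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import census_io
from .allometry import AllometryParams, DEFAULT_PARAMS
from . import demographic_traits as dt
from .phylo_signal import pagel_lambda, permutation_test, phylo_vcv
from .phylo_pca import ppca, standardize_traits
from .synthetic_data import SimConfig, genus_params_from_tree, simulate_census, simulate_tree

__all__ = ["RunConfig", "run_simulate", "run_traits", "run_signal", "run_ppca", "run_all",
           "haversine_km"]

CORE_PPCA_TRAITS = ("wd", "max_d", "maxgr_d", "mortality")


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run."""

    out_dir: str = "results"
    census_path: str | None = None
    plot_path: str | None = None
    wd_path: str | None = None
    newick_path: str | None = None
    precip_min: float = 1300.0
    elev_max: float = 500.0
    min_monitoring_years: float = 2.0
    min_stems_size_growth: int = 20
    min_stems_mortality: int = 100
    min_stems_species_value: int = 20  # species-level values feeding the SEs
    n_perm: int = 1000
    taxon_level: str = "genus"  # genus | species
    spatial_subset: tuple | None = None  # (lat, lon, radius_km)
    complete_traits_only: bool = False
    adjust_metrics: tuple = ("d",)  # size scales that get the plot adjustment
    ppca_traits: tuple = CORE_PPCA_TRAITS
    seed: int = 0
    allometry: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        if self.min_stems_size_growth < 1 or self.min_stems_mortality < 1:
            raise ValueError("thresholds must be >= 1")
        if self.taxon_level not in ("genus", "species"):
            raise ValueError("taxon_level must be genus|species")
        if self.spatial_subset is not None:
            lat, lon, radius = (float(v) for v in self.spatial_subset)
            if radius <= 0:
                raise ValueError("spatial subset radius must be > 0")
            self.spatial_subset = (lat, lon, radius)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("spatial_subset", "adjust_metrics", "ppca_traits"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def allometry_params(self) -> AllometryParams:
        return dataclasses.replace(DEFAULT_PARAMS, **self.allometry) if self.allometry else DEFAULT_PARAMS

    def paths(self) -> dict:
        out = Path(self.out_dir)
        return {
            "census": Path(self.census_path) if self.census_path else out / "census.csv",
            "plots": Path(self.plot_path) if self.plot_path else out / "plots.csv",
            "wd": Path(self.wd_path) if self.wd_path else out / "wood_density.csv",
            "tree": Path(self.newick_path) if self.newick_path else out / "tree.nwk",
        }


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (mean Earth radius 6371 km)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 6371.0 * 2 * np.arcsin(np.sqrt(a))


def _update_manifest(out_dir: Path, stage: str, payload: dict) -> None:
    import dendropy
    import scipy
    import statsmodels

    from . import __version__

    path = out_dir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest.setdefault("versions", {
        "phylodemog": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "dendropy": dendropy.__version__,
    })
    manifest[stage] = payload
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def run_simulate(config: RunConfig) -> dict:
    """Generate a synthetic tree + census dataset into the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = SimConfig(**{**config.simulate, "seed": config.seed})
    ss = np.random.SeedSequence(config.seed).spawn(3)
    tree = simulate_tree(sim.n_genera, sim.birth_rate, seed=int(ss[0].generate_state(1)[0] % 2**31))
    params = genus_params_from_tree(tree, sim, seed=int(ss[1].generate_state(1)[0] % 2**31))
    ds = simulate_census(sim, params, seed=int(ss[2].generate_state(1)[0] % 2**31))
    ds.write(out)
    tree.write(path=str(out / "tree.nwk"), schema="newick", suppress_rooting=True)
    _update_manifest(out, "simulate", {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_genera": sim.n_genera,
        "n_plots": sim.n_plots,
        "n_stems": int(ds.truth_stem.shape[0]),
        "n_census_rows": int(ds.census.shape[0]),
    })
    return {"tree": out / "tree.nwk", "census": out / "census.csv"}


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def _relabel_species(stems):
    """Species-level sensitivity mode: group by binomial instead of genus."""
    out = []
    for s in stems:
        if not s.species:
            continue
        out.append(census_io.StemRecord(
            stem_id=s.stem_id, plot_id=s.plot_id, genus=s.species,
            species=s.species, growth_form=s.growth_form,
            observations=s.observations,
        ))
    return out


def _species_trait_values(summaries, min_n, trait_kind):
    """Species-level trait values per genus (feed intrageneric SEs)."""
    by_sp: dict = {}
    for s in summaries:
        if s.species:
            by_sp.setdefault((s.genus, s.species), []).append(s)
    out: dict[str, list[float]] = {}
    for (genus, _sp), group in by_sp.items():
        if len(group) < min_n:
            continue
        vals = trait_kind(group)
        if vals is not None:
            out.setdefault(genus, []).append(vals)
    return out


def run_traits(config: RunConfig) -> pd.DataFrame:
    """Compute the genus x trait table (values, SEs, plot-adjusted variants)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = config.paths()
    stems, plots, wd_map, tree = census_io.read_inputs(
        paths["census"], paths["plots"], paths["wd"], paths["tree"]
    )
    n_input_stems, n_input_plots = len(stems), len(plots)

    if config.spatial_subset is not None:
        lat0, lon0, radius = config.spatial_subset
        keep = {p.plot_id for p in plots.values()
                if haversine_km(lat0, lon0, p.latitude, p.longitude) <= radius}
        plots = {pid: p for pid, p in plots.items() if pid in keep}
        if not plots:
            raise ValueError("spatial subset excludes every plot")
        stems = [s for s in stems if s.plot_id in keep]

    fr = census_io.apply_selection_filters(
        stems, plots,
        census_io.FilterConfig(config.precip_min, config.elev_max, config.min_monitoring_years),
    )
    stems = fr.stems
    if config.taxon_level == "species":
        wd_by_taxon_genus = {s.stem_id: s.genus for s in stems}
        stems = _relabel_species(stems)
    census_io.write_exclusion_log(fr.log, out / "exclusions.csv")

    params = config.allometry_params()
    genera = sorted({s.genus for s in stems})

    # wood density per genus (and per stem for the biomass allometry)
    if config.taxon_level == "species":
        wd_ests, wd_omitted = [], []
        for g in genera:
            hit = wd_map.get(g)
            if hit is None:
                parts = g.split(" ", 1)
                hit_g = dt.assign_wood_density(parts[0], g, wd_map)
                hit = hit_g[0] if hit_g else None
            if hit is None:
                wd_omitted.append(g)
            else:
                wd_ests.append(dt.GenusTraitEstimate(g, "wd", float(hit), None, 0, 1))
    else:
        wd_ests, wd_omitted = dt.genus_wood_density(wd_map, genera)
    genus_wd = {e.genus: e.value for e in wd_ests}
    wd_fallback = float(np.mean(list(wd_map.values())))

    summaries = []
    n_wd_fallback = 0
    for s in stems:
        if config.taxon_level == "species":
            hit = dt.assign_wood_density(wd_by_taxon_genus[s.stem_id], s.species, wd_map)
        else:
            hit = dt.assign_wood_density(s.genus, s.species, wd_map)
        if hit is None:
            wd_stem, n_wd_fallback = wd_fallback, n_wd_fallback + 1
        else:
            wd_stem = hit[0]
        e_plot = fr.plots[s.plot_id].E
        summaries.append(dt.stem_growth_summary(s, wd_stem, e_plot, params))

    demog = fr.demography_plot_ids
    growth_pool = [s for s in summaries if s.plot_id in demog]
    kept_growth, excluded_growth = dt.apply_growth_exclusions(growth_pool)
    excl_df = pd.DataFrame(
        [{"kind": "stem_growth", "id": s.stem_id, "reason": s.exclusion_reason}
         for s in excluded_growth], columns=["kind", "id", "reason"],
    )
    pd.concat([fr.log, excl_df]).to_csv(out / "exclusions.csv", index=False)

    min_n = config.min_stems_size_growth
    estimates: list[dt.GenusTraitEstimate] = list(wd_ests)
    for metric in dt.SIZE_METRICS:
        ests, _ = dt.genus_potential_size(summaries, metric, min_n, genus_wd)
        estimates += ests
    growth_ests, _ = dt.genus_growth_traits(kept_growth, min_n)
    estimates += growth_ests

    mrec = dt.mortality_records(stems, demog)
    mort_fit = None
    if not mrec.empty and (mrec.groupby("genus").size() >= config.min_stems_mortality).any():
        mort_fit = dt.fit_genus_mortality(mrec, config.min_stems_mortality)
        estimates += mort_fit.estimates

    # --- intrageneric SEs from species-level values ------------------------
    sp_min = config.min_stems_species_value
    sp_vals: dict[str, dict[str, list[float]]] = {}
    sp_vals["max_d"] = _species_trait_values(
        summaries, sp_min, lambda g: dt.quantile95([s.max_size_d for s in g]))
    sp_vals["max_ba"] = _species_trait_values(
        summaries, sp_min, lambda g: dt.quantile95([s.max_size_ba for s in g]))
    sp_vals["max_agb"] = _species_trait_values(
        summaries, sp_min, lambda g: dt.quantile95([s.max_size_agb for s in g]))
    for metric in dt.SIZE_METRICS:
        sp_vals[f"meangr_{metric}"] = _species_trait_values(
            kept_growth, sp_min,
            lambda g, m=metric: float(np.mean([getattr(s, f"mean_growth_{m}") for s in g
                                               if s.has_growth])) if any(s.has_growth for s in g) else None)
        sp_vals[f"maxgr_{metric}"] = _species_trait_values(
            kept_growth, sp_min,
            lambda g, m=metric: dt.quantile95([getattr(s, f"max_growth_{m}") for s in g
                                               if s.has_growth]) if any(s.has_growth for s in g) else None)
    if not mrec.empty:
        sp_mort: dict[str, list[float]] = {}
        for (genus, _sp), grp in mrec.groupby(["genus", "species"]):
            if len(grp) >= sp_min:
                sbar = grp["survived"].mean()
                rate = 0.0 if sbar >= 1.0 else 100.0 * (-np.log(sbar) / grp["t"].mean())
                sp_mort.setdefault(genus, []).append(rate)
        sp_vals["mortality"] = sp_mort

    wd_species: dict[str, list[float]] = {}
    for g in genera:
        vals = [w for t, w in wd_map.items() if " " in t and t.split(" ", 1)[0] == g]
        if vals:
            wd_species[g] = vals
    sp_vals["wd"] = wd_species

    ses: dict[str, dict[str, float]] = {}
    for trait, mapping in sp_vals.items():
        try:
            ses[trait] = dt.intrageneric_se(mapping)
        except ValueError:
            ses[trait] = {}
    for est in estimates:
        base = est.trait_name.replace("xwd", "")
        table = ses.get(est.trait_name) or ses.get(base) or {}
        if est.se is None and est.genus in table:
            est.se = table[est.genus]
    # genera absent even from the imputation pool get the trait's mean imputed SE
    for est in estimates:
        if est.se is None:
            pool = ses.get(est.trait_name.replace("xwd", ""), {})
            if pool:
                est.se = float(np.mean(list(pool.values())))

    # --- plot adjustment ---------------------------------------------------
    adj_rows = []
    adj_summary = []
    for metric in config.adjust_metrics:
        emitted = {e.genus for e in estimates if e.trait_name == f"max_{metric}"}
        pool = [s for s in summaries if s.genus in emitted and getattr(s, f"max_size_{metric}") > 0]
        if pool and len({s.plot_id for s in pool}) >= 2:
            res = dt.plot_adjusted_traits(
                [getattr(s, f"max_size_{metric}") for s in pool],
                [s.genus for s in pool], [s.plot_id for s in pool], kind="quantile",
            )
            adj_rows += [{"genus": g, "trait_name": f"max_{metric}", "value": v}
                         for g, v in res.adjusted.items() if g in emitted]
            adj_summary.append({"trait_name": f"max_{metric}",
                                "kendall_tau": res.kendall_tau, "kendall_p": res.kendall_p})
        for kind, prefix, attr in (
            ("quantile", "maxgr", "max_growth"), ("mean", "meangr", "mean_growth"),
        ):
            emitted = {e.genus for e in estimates if e.trait_name == f"{prefix}_{metric}"}
            pool = [s for s in kept_growth if s.genus in emitted and s.has_growth
                    and getattr(s, f"{attr}_{metric}") > 0]
            if pool and len({s.plot_id for s in pool}) >= 2:
                res = dt.plot_adjusted_traits(
                    [getattr(s, f"{attr}_{metric}") for s in pool],
                    [s.genus for s in pool], [s.plot_id for s in pool], kind=kind,
                )
                adj_rows += [{"genus": g, "trait_name": f"{prefix}_{metric}", "value": v}
                             for g, v in res.adjusted.items() if g in emitted]
                adj_summary.append({"trait_name": f"{prefix}_{metric}",
                                    "kendall_tau": res.kendall_tau, "kendall_p": res.kendall_p})

    long = pd.DataFrame([
        {"genus": e.genus, "trait_name": e.trait_name, "value": e.value,
         "se": e.se, "n_stems": e.n_stems, "n_species": e.n_species}
        for e in estimates
    ])
    if long.duplicated(["genus", "trait_name"]).any():
        raise RuntimeError("duplicate genus x trait rows")
    census_io.write_trait_table(long, out / "traits.csv")
    pd.DataFrame(adj_rows, columns=["genus", "trait_name", "value"]).to_csv(
        out / "traits_adjusted.csv", index=False)
    pd.DataFrame(adj_summary, columns=["trait_name", "kendall_tau", "kendall_p"]).to_csv(
        out / "adjustment_summary.csv", index=False)

    # Table-1-style per-trait summary
    summary_rows = []
    units = {"wd": "g cm-3", "max_d": "cm", "max_ba": "m2", "max_agb": "kg",
             "max_dxwd": "", "max_baxwd": "", "maxgr_d": "cm yr-1",
             "maxgr_ba": "m2 yr-1", "maxgr_agb": "kg yr-1", "meangr_d": "cm yr-1",
             "meangr_ba": "m2 yr-1", "meangr_agb": "kg yr-1", "mortality": "% yr-1"}
    for trait, grp in long.groupby("trait_name"):
        summary_rows.append({
            "trait": trait, "units": units.get(trait, ""),
            "n_ind": int(grp["n_stems"].sum()), "n_genera": len(grp),
            "n_species": int(grp["n_species"].sum()),
            "min": grp["value"].min(), "max": grp["value"].max(),
            "mean": grp["value"].mean(),
            "fold_range": (dt.fold_range(grp["value"]) if (grp["value"] > 0).all() else np.nan),
        })
    pd.DataFrame(summary_rows).to_csv(out / "trait_summary.csv", index=False)

    reason_counts = fr.log["reason"].value_counts().to_dict() if len(fr.log) else {}
    _update_manifest(out, "traits", {
        "seed": config.seed, "config_hash": config.config_hash(),
        "n_stems_input": n_input_stems, "n_plots_input": n_input_plots,
        "n_stems_kept": len(stems), "n_plots_kept": len(fr.plots),
        "n_plots_demography": len(demog),
        "n_growth_stems_kept": len(kept_growth),
        "n_growth_stems_excluded": len(excluded_growth),
        "n_wd_fallback_stems": n_wd_fallback,
        "wd_unmatched_genera": len(wd_omitted),
        "mortality_beta": (mort_fit.beta if mort_fit else None),
        "mortality_plot_random_effects": False,
        "exclusion_reasons": {str(k): int(v) for k, v in reason_counts.items()},
        "taxon_level": config.taxon_level,
        "spatial_subset": list(config.spatial_subset) if config.spatial_subset else None,
    })
    return long


# ---------------------------------------------------------------------------
# signal
# ---------------------------------------------------------------------------


def _signal_rows(name, x, se, C, n_perm, rng, adjusted):
    rows = []
    labels = [g for g in C.labels if g in x.index and np.isfinite(x[g])]
    if len(labels) < 4:
        return rows
    sub = C.subset(labels)
    xv = x.reindex(labels)
    if xv.std(ddof=0) == 0:
        return rows
    sev = None
    if se is not None:
        sev = se.reindex(labels).fillna(0.0)

    base = {"trait": name, "adjusted": adjusted, "n_tips": len(labels)}
    seed1 = int(rng.integers(2**31))
    r = permutation_test(xv.to_numpy(), None, sub, n_perm=n_perm, seed=seed1)
    rows.append({**base, "statistic": "K", "se_used": False, "estimate": r.estimate,
                 "sigma2": r.sigma2, "perm_lo": r.perm_quantiles[0],
                 "perm_hi": r.perm_quantiles[1], "significant": r.significant,
                 "log_likelihood": None, "lrt_p": None, "seed": r.seed})
    if sev is not None and (sev > 0).any():
        seed2 = int(rng.integers(2**31))
        try:
            r = permutation_test(xv.to_numpy(), sev.to_numpy(), sub, n_perm=n_perm, seed=seed2)
            rows.append({**base, "statistic": "K", "se_used": True, "estimate": r.estimate,
                         "sigma2": r.sigma2, "perm_lo": r.perm_quantiles[0],
                         "perm_hi": r.perm_quantiles[1], "significant": r.significant,
                         "log_likelihood": r.log_likelihood, "lrt_p": None, "seed": r.seed})
        except RuntimeError:
            # intrageneric SEs swamp the among-genus variance: no resolvable
            # error-aware K for this trait — recorded, not fatal
            rows.append({**base, "statistic": "K", "se_used": True, "estimate": np.nan,
                         "sigma2": np.nan, "perm_lo": None, "perm_hi": None,
                         "significant": None, "log_likelihood": None, "lrt_p": None,
                         "seed": seed2})
    r = pagel_lambda(xv.to_numpy(), sub)
    rows.append({**base, "statistic": "lambda", "se_used": False, "estimate": r.estimate,
                 "sigma2": r.sigma2, "perm_lo": None, "perm_hi": None,
                 "significant": bool(r.lrt_pvalue < 0.05), "log_likelihood": r.log_likelihood,
                 "lrt_p": r.lrt_pvalue, "seed": None})
    if sev is not None and (sev > 0).any():
        try:
            r = pagel_lambda(xv.to_numpy(), sub, se=sev.to_numpy())
            rows.append({**base, "statistic": "lambda", "se_used": True,
                         "estimate": r.estimate, "sigma2": r.sigma2, "perm_lo": None,
                         "perm_hi": None, "significant": bool(r.lrt_pvalue < 0.05),
                         "log_likelihood": r.log_likelihood, "lrt_p": r.lrt_pvalue,
                         "seed": None})
        except RuntimeError:
            rows.append({**base, "statistic": "lambda", "se_used": True,
                         "estimate": np.nan, "sigma2": np.nan, "perm_lo": None,
                         "perm_hi": None, "significant": None, "log_likelihood": None,
                         "lrt_p": None, "seed": None})
    return rows


def run_signal(config: RunConfig) -> pd.DataFrame:
    """Blomberg's K (plain/error-aware, with tip-randomization significance)
    and Pagel's lambda for every trait in the trait table."""
    out = Path(config.out_dir)
    traits_path = out / "traits.csv"
    if not traits_path.exists():
        raise FileNotFoundError("traits.csv not found: run the 'traits' stage first")
    long = pd.read_csv(traits_path)
    tree = census_io.read_tree(config.paths()["tree"])
    C = phylo_vcv(tree)
    rng = np.random.default_rng(config.seed)

    wide = long.pivot(index="genus", columns="trait_name", values="value")
    if config.complete_traits_only:
        core = [t for t in config.ppca_traits if t in wide.columns]
        keep = wide[core].dropna().index
        long = long[long["genus"].isin(keep)]

    rows = []
    for trait, grp in long.groupby("trait_name"):
        x = grp.set_index("genus")["value"]
        se = grp.set_index("genus")["se"]
        rows += _signal_rows(trait, x, se, C, config.n_perm, rng, adjusted=False)

    adj_path = out / "traits_adjusted.csv"
    if adj_path.exists():
        adj = pd.read_csv(adj_path)
        for trait, grp in adj.groupby("trait_name"):
            x = grp.set_index("genus")["value"]
            se = long[long["trait_name"] == trait].set_index("genus")["se"]
            rows += _signal_rows(trait, x, se, C, config.n_perm, rng, adjusted=True)

    result = pd.DataFrame(rows)
    result.to_csv(out / "signal.csv", index=False)
    _update_manifest(out, "signal", {
        "seed": config.seed, "config_hash": config.config_hash(),
        "n_perm": config.n_perm, "n_rows": len(result),
        "n_tree_tips": C.n,
        "complete_traits_only": config.complete_traits_only,
    })
    return result


# ---------------------------------------------------------------------------
# ppca
# ---------------------------------------------------------------------------


def run_ppca(config: RunConfig) -> pd.DataFrame:
    """Phylogenetic PCA of the core trait matrix; K of the leading axes."""
    out = Path(config.out_dir)
    traits_path = out / "traits.csv"
    if not traits_path.exists():
        raise FileNotFoundError("traits.csv not found: run the 'traits' stage first")
    long = pd.read_csv(traits_path)
    tree = census_io.read_tree(config.paths()["tree"])
    C = phylo_vcv(tree)

    wide = long.pivot(index="genus", columns="trait_name", values="value")
    core = [t for t in config.ppca_traits if t in wide.columns]
    X = wide[core].dropna()
    X = X.loc[[g for g in X.index if g in C.labels]]
    if X.shape[0] < len(core) + 2:
        raise ValueError(
            f"too few complete-trait genera ({X.shape[0]}) for PPCA on {core}"
        )
    Z = standardize_traits(X)
    res = ppca(Z, C)

    res.loadings.to_csv(out / "ppca_loadings.csv", index_label="trait")
    res.scores.to_csv(out / "ppca_scores.csv", index_label="genus")
    axes = pd.DataFrame({
        "axis": res.loadings.columns,
        "eigenvalue": res.eigenvalues,
        "proportion_variance": res.proportion_variance,
        "percent_variance": 100.0 * res.proportion_variance,
    })
    axes.to_csv(out / "ppca_axes.csv", index=False)

    # phylogenetic signal of the first two axes (no natural intrageneric SE)
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for axis in res.scores.columns[: min(2, res.scores.shape[1])]:
        rows += _signal_rows(f"PPCA_{axis}", res.scores[axis], None, C,
                             config.n_perm, rng, adjusted=False)
    sig = pd.DataFrame(rows)
    sig_path = out / "signal.csv"
    if sig_path.exists() and len(sig):
        prev = pd.read_csv(sig_path)
        prev = prev[~prev["trait"].astype(str).str.startswith("PPCA_")]
        pd.concat([prev, sig], ignore_index=True).to_csv(sig_path, index=False)
    elif len(sig):
        sig.to_csv(sig_path, index=False)

    _update_manifest(out, "ppca", {
        "seed": config.seed, "config_hash": config.config_hash(),
        "n_genera": res.n_genera, "traits_used": list(res.traits_used),
        "percent_variance": [float(f"{v:.4f}") for v in 100.0 * res.proportion_variance],
        "percent_first_two": float(100.0 * res.proportion_variance[:2].sum()),
    })
    return axes


def run_all(config: RunConfig) -> None:
    """Chain traits -> signal -> ppca on existing inputs."""
    run_traits(config)
    run_signal(config)
    run_ppca(config)
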