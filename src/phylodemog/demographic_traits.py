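"""Genus-level life-history traits from stem-level census series.

From repeated diameter measurements this module derives, per genus:

* potential size — the 95th percentile of the per-stem maximum size
  distribution (diameter, basal area, biomass), for genera with >= 20 stems;
* growth — the arithmetic mean (over stems) of mean annual stem growth and
  the 95th percentile of maximum stem growth, on the same three size scales;
* mortality — the stem-averaged hazard from an exponential survival model
  with a genus intercept and a shared size effect, for genera with >= 100
  stems;
* wood density — the mean of species-level densities.

Growth excludes stems with negative mean growth, any census interval above
8 cm yr^-1, palms (no secondary growth), and stems with any non-tape
measurement; palms stay in the size/biomass traits through a palm-specific
allometry. When a tree's point of measurement (POM) moved, the census where
it moved uses the arithmetic mean of the diameters at the old and new POM.

Intrageneric standard errors are the standard error of the mean of
species-level trait values; genera with fewer than two species inherit the
mean SE of the multi-species genera. A linear mixed model on the log scale
(genus fixed effects, plot random intercepts) separates genus trait values
from systematic plot-to-plot differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import kendalltau

from .allometry import AllometryParams, DEFAULT_PARAMS, basal_area, palm_agb, tree_agb
from .census_io import StemRecord

__all__ = [
    "StemGrowthSummary",
    "GenusTraitEstimate",
    "MortalityFit",
    "AdjustedTraits",
    "effective_diameter_series",
    "stem_growth_summary",
    "apply_growth_exclusions",
    "genus_potential_size",
    "genus_growth_traits",
    "mortality_records",
    "fit_genus_mortality",
    "plot_adjusted_traits",
    "intrageneric_se",
    "assign_wood_density",
    "genus_wood_density",
    "fold_range",
    "quantile95",
]

SIZE_METRICS = ("d", "ba", "agb")


def quantile95(values) -> float:
    """95th percentile with linear interpolation at h = (n-1)p + 1."""
    return float(np.quantile(np.asarray(values, dtype=float), 0.95))


@dataclass
class StemGrowthSummary:
    """Per-stem growth and maximum-size summary across censuses."""

    stem_id: str
    genus: str
    species: str | None
    plot_id: str
    growth_form: str
    all_tape: bool
    max_size_d: float  # cm
    max_size_ba: float  # m^2
    max_size_agb: float  # kg
    mean_growth_d: float | None = None  # cm yr^-1; None for single-census stems
    max_growth_d: float | None = None
    mean_growth_ba: float | None = None  # m^2 yr^-1
    max_growth_ba: float | None = None
    mean_growth_agb: float | None = None  # kg yr^-1
    max_growth_agb: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def has_growth(self) -> bool:
        return self.mean_growth_d is not None


@dataclass
class GenusTraitEstimate:
    """One genus x one trait: value, intrageneric SE, sample sizes."""

    genus: str
    trait_name: str
    value: float
    se: float | None
    n_stems: int
    n_species: int
    flags: dict = field(default_factory=dict)


def effective_diameter_series(stem: StemRecord) -> list[tuple[float, float]]:
    """Ordered (date, diameter) pairs for growth computation.

    At a POM-change census the effective diameter is the arithmetic mean of
    the old-POM and new-POM diameters; other censuses pass through. Only
    alive observations enter the series.
    """
    alive = stem.alive_observations
    if not alive:
        raise ValueError(f"stem {stem.stem_id}: no alive observation")
    out: list[tuple[float, float]] = []
    prev_pom = None
    for o in alive:
        if o.new_pom_diameter is not None:
            d = 0.5 * (o.diameter + o.new_pom_diameter)
        else:
            if prev_pom is not None and o.pom_height != prev_pom:
                raise ValueError(
                    f"stem {stem.stem_id}: POM change at {o.date} without new_pom_diameter"
                )
            d = o.diameter
        out.append((o.date, d))
        prev_pom = o.pom_height
    return out


def stem_growth_summary(
    stem: StemRecord,
    wd: float,
    e: float,
    params: AllometryParams = DEFAULT_PARAMS,
) -> StemGrowthSummary:
    """Summarize one stem: interval growth rates and maximum sizes.

    Growth on each size scale is computed by converting every effective
    diameter first (same allometry, constant wd and E) and then differencing
    across census intervals; annualized rate = delta / interval years.
    """
    series = effective_diameter_series(stem)
    dates = np.array([t for t, _ in series])
    d = np.array([x for _, x in series])
    ba = basal_area(d)
    if stem.growth_form == "palm":
        agb = palm_agb(d, params)
    else:
        agb = tree_agb(d, wd, e, params)
    agb = np.atleast_1d(agb)
    ba = np.atleast_1d(ba)

    summary = StemGrowthSummary(
        stem_id=stem.stem_id,
        genus=stem.genus,
        species=stem.species,
        plot_id=stem.plot_id,
        growth_form=stem.growth_form,
        all_tape=all(o.method_tape for o in stem.alive_observations),
        max_size_d=float(d.max()),
        max_size_ba=float(ba.max()),
        max_size_agb=float(agb.max()),
    )
    if len(series) < 2:
        return summary

    dt = np.diff(dates)
    if np.any(dt <= 0):
        raise ValueError(f"stem {stem.stem_id}: zero-length census interval")
    for name, vals in (("d", d), ("ba", ba), ("agb", agb)):
        rates = np.diff(vals) / dt
        setattr(summary, f"mean_growth_{name}", float(rates.mean()))
        setattr(summary, f"max_growth_{name}", float(rates.max()))
    return summary


def apply_growth_exclusions(
    summaries: list[StemGrowthSummary],
    max_interval_growth: float = 8.0,  # cm yr^-1 (the 80 mm yr^-1 rule)
) -> tuple[list[StemGrowthSummary], list[StemGrowthSummary]]:
    """Partition stems into growth-qualifying and growth-excluded.

    Exclusion reasons (applied in order): palm, negative (mean diameter
    growth < 0), implausible (any interval above ``max_interval_growth``),
    not_tape. Excluded stems remain usable for size traits.
    """
    kept: list[StemGrowthSummary] = []
    excluded: list[StemGrowthSummary] = []
    for s in summaries:
        reason = None
        if s.growth_form == "palm":
            reason = "palm"
        elif not s.has_growth:
            reason = "single_census"
        elif s.mean_growth_d < 0:
            reason = "negative"
        elif s.max_growth_d > max_interval_growth:
            reason = "implausible"
        elif not s.all_tape:
            reason = "not_tape"
        if reason is None:
            kept.append(s)
        else:
            s.excluded = True
            s.exclusion_reason = reason
            excluded.append(s)
    return kept, excluded


def _group_by_genus(summaries: list[StemGrowthSummary]) -> dict[str, list[StemGrowthSummary]]:
    out: dict[str, list[StemGrowthSummary]] = {}
    for s in summaries:
        out.setdefault(s.genus, []).append(s)
    return out


def _n_species(group: list[StemGrowthSummary]) -> int:
    return len({s.species for s in group if s.species})


def genus_potential_size(
    summaries: list[StemGrowthSummary],
    metric: str,
    min_n: int = 20,
    genus_wd: dict[str, float] | None = None,
) -> tuple[list[GenusTraitEstimate], list[str]]:
    """Potential size per genus: 95th percentile of per-stem maximum sizes.

    ``metric`` is one of d|ba|agb. With ``genus_wd`` supplied, also emits
    the size x wood-density product traits (d and ba metrics only).
    Genera under ``min_n`` stems are omitted and returned in the log.
    """
    if metric not in SIZE_METRICS:
        raise ValueError(f"metric must be one of {SIZE_METRICS}")
    estimates: list[GenusTraitEstimate] = []
    omitted: list[str] = []
    for genus, group in sorted(_group_by_genus(summaries).items()):
        if len(group) < min_n:
            omitted.append(genus)
            continue
        vals = [getattr(s, f"max_size_{metric}") for s in group]
        est = GenusTraitEstimate(
            genus=genus,
            trait_name=f"max_{metric}",
            value=quantile95(vals),
            se=None,
            n_stems=len(group),
            n_species=_n_species(group),
        )
        estimates.append(est)
        if genus_wd is not None and metric in ("d", "ba") and genus in genus_wd:
            estimates.append(
                GenusTraitEstimate(
                    genus=genus,
                    trait_name=f"max_{metric}xwd",
                    value=est.value * genus_wd[genus],
                    se=None,
                    n_stems=len(group),
                    n_species=est.n_species,
                )
            )
    return estimates, omitted


def genus_growth_traits(
    summaries: list[StemGrowthSummary], min_n: int = 20
) -> tuple[list[GenusTraitEstimate], list[str]]:
    """Mean and maximum growth per genus on all three size scales.

    The genus mean-growth trait is the arithmetic mean over stems of the
    stem mean growth; the maximum-growth trait is the 95th percentile over
    stems of the stem maximum growth. Only growth-qualifying stems (after
    :func:`apply_growth_exclusions`) should be passed in; the >= ``min_n``
    threshold applies after those exclusions.
    """
    estimates: list[GenusTraitEstimate] = []
    omitted: list[str] = []
    with_growth = [s for s in summaries if s.has_growth]
    for genus, group in sorted(_group_by_genus(with_growth).items()):
        if len(group) < min_n:
            omitted.append(genus)
            continue
        nsp = _n_species(group)
        for metric in SIZE_METRICS:
            mean_vals = [getattr(s, f"mean_growth_{metric}") for s in group]
            max_vals = [getattr(s, f"max_growth_{metric}") for s in group]
            estimates.append(
                GenusTraitEstimate(
                    genus=genus, trait_name=f"meangr_{metric}",
                    value=float(np.mean(mean_vals)), se=None,
                    n_stems=len(group), n_species=nsp,
                )
            )
            estimates.append(
                GenusTraitEstimate(
                    genus=genus, trait_name=f"maxgr_{metric}",
                    value=quantile95(max_vals), se=None,
                    n_stems=len(group), n_species=nsp,
                )
            )
    return estimates, omitted


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------


def mortality_records(
    stems: list[StemRecord], demography_plot_ids: set[str] | None = None
) -> pd.DataFrame:
    """Per-stem survival records for the mortality model.

    Monitoring time runs from a stem's first to last census; ``survived``
    is its status at the last census; size is the diameter at the first
    (alive) record. Stems with a single census carry no information and are
    dropped.
    """
    rows = []
    for s in stems:
        if demography_plot_ids is not None and s.plot_id not in demography_plot_ids:
            continue
        if len(s.observations) < 2:
            continue
        first, last = s.observations[0], s.observations[-1]
        if not first.alive:
            continue
        rows.append({
            "stem_id": s.stem_id,
            "genus": s.genus,
            "species": s.species,
            "t": last.date - first.date,
            "survived": bool(last.alive),
            "d0": first.diameter,
        })
    return pd.DataFrame(rows, columns=["stem_id", "genus", "species", "t", "survived", "d0"])


@dataclass
class MortalityFit:
    estimates: list[GenusTraitEstimate]  # % yr^-1 per genus
    beta: float  # shared size-effect slope on standardized ln d0
    alphas: pd.Series  # genus log-hazard intercepts
    log_likelihood: float
    converged: bool
    n_stems_fit: int
    zero_death_genera: list[str]
    diagnostics: dict = field(default_factory=dict)


def _mortality_nll_grad(theta, t, surv, z, gidx, n_genera, fix_beta):
    alpha = theta[:n_genera]
    beta = fix_beta if fix_beta is not None else theta[n_genera]
    u = t * np.exp(alpha[gidx] + beta * z)
    emu = np.exp(-u)
    # survive: -ln P = u ; die: -ln(1 - e^-u)
    with np.errstate(divide="ignore"):
        die_term = -np.log(-np.expm1(-u))
    nll = np.sum(np.where(surv, u, die_term))
    w = np.where(surv, 1.0, -emu / (1.0 - emu))
    wu = w * u
    grad_alpha = np.bincount(gidx, weights=wu, minlength=n_genera)
    if fix_beta is None:
        return nll, np.concatenate([grad_alpha, [np.sum(wu * z)]])
    return nll, grad_alpha


def fit_genus_mortality(
    records: pd.DataFrame,
    min_n: int = 100,
    fix_beta: float | None = None,
    compute_se: bool = False,
) -> MortalityFit:
    """Exponential-survival mortality rates per genus.

    The survival probability of stem i over its monitoring period t_i is
    exp(-m_i t_i), with log hazard ln m_i = alpha_g + beta * z_i where z_i
    is the standardized log initial diameter and beta is shared across
    genera (jointly fitted by ML). The reported genus rate is 100x the mean
    fitted hazard over the genus's stems (% yr^-1). Genera with zero deaths
    sit on the likelihood boundary and are reported as 0 with a flag.
    """
    req = {"genus", "t", "survived", "d0"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    counts = records.groupby("genus").size()
    qualifying = counts[counts >= min_n].index
    rec = records[records["genus"].isin(qualifying)].reset_index(drop=True)
    if rec.empty:
        raise ValueError(f"no genus reaches the mortality threshold of {min_n} stems")
    if (rec["t"] <= 0).any():
        raise ValueError("non-positive monitoring time")

    lnd = np.log(rec["d0"].to_numpy(dtype=float))
    sd = lnd.std(ddof=1)
    z_all = (lnd - lnd.mean()) / (sd if sd > 0 else 1.0)
    rec = rec.assign(z=z_all)

    deaths = rec.groupby("genus")["survived"].apply(lambda s: (~s).sum())
    zero_death = sorted(deaths[deaths == 0].index)
    fit_rec = rec[~rec["genus"].isin(zero_death)].reset_index(drop=True)

    estimates: list[GenusTraitEstimate] = []
    alphas = {}
    beta_hat = fix_beta if fix_beta is not None else 0.0
    ll = 0.0
    converged = True
    diagnostics: dict = {}

    if not fit_rec.empty:
        genera = sorted(fit_rec["genus"].unique())
        gmap = {g: i for i, g in enumerate(genera)}
        gidx = fit_rec["genus"].map(gmap).to_numpy()
        t = fit_rec["t"].to_numpy(dtype=float)
        surv = fit_rec["survived"].to_numpy(dtype=bool)
        z = fit_rec["z"].to_numpy(dtype=float)
        G = len(genera)

        # moment start: per-genus equal-time closed form
        a0 = np.empty(G)
        for g, i in gmap.items():
            sub = fit_rec[fit_rec["genus"] == g]
            sbar = max(sub["survived"].mean(), 1e-3)
            a0[i] = np.log(max(-np.log(sbar) / sub["t"].mean(), 1e-6))
        theta0 = a0 if fix_beta is not None else np.concatenate([a0, [0.0]])

        res = minimize(
            _mortality_nll_grad, theta0, args=(t, surv, z, gidx, G, fix_beta),
            jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if not res.success:
            raise RuntimeError(
                f"mortality ML failed to converge: {res.message}; "
                f"n={len(fit_rec)}, G={G}, final |grad|={np.abs(res.jac).max():.3g}"
            )
        alpha_hat = res.x[:G]
        beta_hat = float(fix_beta if fix_beta is not None else res.x[G])
        ll = -float(res.fun)
        alphas = dict(zip(genera, alpha_hat))
        diagnostics["n_iterations"] = res.nit

        if compute_se:
            # observed information by central differences of the analytic gradient
            k = len(res.x)
            H = np.empty((k, k))
            h = 1e-5
            for j in range(k):
                tp = res.x.copy(); tp[j] += h
                tm = res.x.copy(); tm[j] -= h
                gp = _mortality_nll_grad(tp, t, surv, z, gidx, G, fix_beta)[1]
                gm = _mortality_nll_grad(tm, t, surv, z, gidx, G, fix_beta)[1]
                H[:, j] = (gp - gm) / (2 * h)
            H = 0.5 * (H + H.T)
            diagnostics["param_cov"] = np.linalg.inv(H)
            diagnostics["param_names"] = genera + ([] if fix_beta is not None else ["beta"])

        for g in genera:
            sub = rec[rec["genus"] == g]
            m_i = np.exp(alphas[g] + beta_hat * sub["z"].to_numpy())
            estimates.append(
                GenusTraitEstimate(
                    genus=g, trait_name="mortality",
                    value=100.0 * float(m_i.mean()), se=None,
                    n_stems=len(sub),
                    n_species=sub["species"].nunique() if "species" in sub else 0,
                )
            )

    for g in zero_death:
        sub = rec[rec["genus"] == g]
        estimates.append(
            GenusTraitEstimate(
                genus=g, trait_name="mortality", value=0.0, se=None,
                n_stems=len(sub),
                n_species=sub["species"].nunique() if "species" in sub else 0,
                flags={"boundary": True},
            )
        )

    estimates.sort(key=lambda e: e.genus)
    return MortalityFit(
        estimates=estimates,
        beta=beta_hat,
        alphas=pd.Series(alphas, dtype=float).sort_index(),
        log_likelihood=ll,
        converged=converged,
        n_stems_fit=len(fit_rec),
        zero_death_genera=zero_death,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# plot adjustment (mixed model)
# ---------------------------------------------------------------------------


@dataclass
class AdjustedTraits:
    adjusted: pd.Series  # genus -> adjusted value (average-plot scale)
    unadjusted: pd.Series
    kendall_tau: float | None
    kendall_p: float | None
    plot_offsets: pd.Series  # BLUP random intercepts per plot (log scale)
    adjusted_is_unadjusted: bool = False  # singular-fit fallback


def plot_adjusted_traits(
    values,
    genus_ids,
    plot_ids,
    kind: str = "mean",
    q: float = 0.95,
) -> AdjustedTraits:
    """Genus trait values adjusted for systematic among-plot variation.

    Fits ``log(value) ~ genus (fixed) + plot (random intercept)`` by ML.
    For ``kind='mean'`` the adjusted genus value is the back-transformed
    genus effect (the expected value at an average plot); for
    ``kind='quantile'`` the BLUP plot offsets are subtracted from the log
    stem values and the genus quantile is then taken on the back-transformed
    values. Unadjusted values are the plain genus aggregate of the raw
    stem values. With a single plot the model is unidentifiable and the
    unadjusted values are returned with a warning.
    """
    import statsmodels.api as sm

    if kind not in ("mean", "quantile"):
        raise ValueError("kind must be 'mean' or 'quantile'")
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "genus": list(genus_ids),
        "plot": list(plot_ids),
    })
    if (df["value"] <= 0).any():
        raise ValueError("log-scale plot adjustment requires positive stem values")

    def aggregate(col: str) -> pd.Series:
        g = df.groupby("genus")[col]
        return g.mean() if kind == "mean" else g.quantile(0.95) if q == 0.95 else g.quantile(q)

    unadjusted = aggregate("value")

    n_plots = df["plot"].nunique()
    if n_plots < 2:
        warnings.warn("single plot: plot adjustment is unidentifiable; returning unadjusted values")
        zero = pd.Series(0.0, index=sorted(df["plot"].unique()))
        return AdjustedTraits(unadjusted.copy(), unadjusted, None, None, zero, True)

    df["logv"] = np.log(df["value"])
    exog = pd.get_dummies(df["genus"], dtype=float)
    genus_names = list(exog.columns)
    model = sm.MixedLM(df["logv"], exog, groups=df["plot"])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=False)
        offsets = pd.Series(
            {pid: float(re.iloc[0]) for pid, re in fit.random_effects.items()}
        ).sort_index()
    except (np.linalg.LinAlgError, ValueError):
        # plot variance on the boundary (or singular design): no detectable
        # plot effect, so the adjusted values equal the unadjusted ones
        warnings.warn("plot random-effect fit singular; returning unadjusted values")
        zero = pd.Series(0.0, index=sorted(df["plot"].unique()))
        return AdjustedTraits(unadjusted.copy(), unadjusted, None, None, zero, True)

    if kind == "mean":
        adjusted = pd.Series(
            np.exp(fit.params[genus_names].to_numpy(dtype=float)), index=genus_names
        ).sort_index()
    else:
        df["adj_value"] = np.exp(df["logv"] - offsets.reindex(df["plot"]).to_numpy())
        adjusted = df.groupby("genus")["adj_value"].quantile(q).sort_index()

    common = adjusted.index.intersection(unadjusted.index)
    if len(common) >= 3:
        tau, pval = kendalltau(adjusted[common], unadjusted[common])
        tau, pval = float(tau), float(pval)
    else:
        tau = pval = None
    return AdjustedTraits(adjusted, unadjusted, tau, pval, offsets)


# ---------------------------------------------------------------------------
# intrageneric SE and wood density
# ---------------------------------------------------------------------------


def intrageneric_se(species_values: dict[str, list[float]]) -> dict[str, float]:
    """Standard error of each genus trait from its species-level values.

    SE = sd(species values)/sqrt(k) for genera with k >= 2 species; genera
    with fewer species receive the mean SE of the multi-species genera.
    """
    direct: dict[str, float] = {}
    needs_imputing: list[str] = []
    for genus, vals in species_values.items():
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        if len(vals) >= 2:
            direct[genus] = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
        else:
            needs_imputing.append(genus)
    if not direct:
        raise ValueError(
            "no genus has >= 2 species-level values: intrageneric SE cannot be imputed"
        )
    fill = float(np.mean(list(direct.values())))
    out = dict(direct)
    for genus in needs_imputing:
        out[genus] = fill
    return out


def _species_densities(wd_map: dict[str, float], genus: str) -> list[float]:
    vals = [wd for taxon, wd in wd_map.items()
            if " " in taxon and taxon.split(" ", 1)[0] == genus]
    if not vals and genus in wd_map:
        vals = [wd_map[genus]]
    return vals


def assign_wood_density(
    genus: str, species: str | None, wd_map: dict[str, float]
) -> tuple[float, str] | None:
    """Wood density for one stem: exact species match first, else genus mean.

    Returns (density, 'species'|'genus') or None when the genus is absent.
    """
    if species:
        key = species if " " in species else f"{genus} {species}"
        if key in wd_map:
            return wd_map[key], "species"
    vals = _species_densities(wd_map, genus)
    if not vals:
        return None
    return float(np.mean(vals)), "genus"


def genus_wood_density(
    wd_map: dict[str, float], genera
) -> tuple[list[GenusTraitEstimate], list[str]]:
    """Genus wood density: mean over matched species-level densities.

    SEs come from :func:`intrageneric_se` over the same species values.
    Unmatched genera are omitted and returned in the log.
    """
    per_genus: dict[str, list[float]] = {}
    omitted: list[str] = []
    for genus in genera:
        vals = _species_densities(wd_map, genus)
        if vals:
            per_genus[genus] = vals
        else:
            omitted.append(genus)
    if not per_genus:
        return [], omitted
    try:
        ses = intrageneric_se(per_genus)
    except ValueError:
        ses = {g: None for g in per_genus}
    estimates = [
        GenusTraitEstimate(
            genus=g, trait_name="wd", value=float(np.mean(vals)),
            se=ses.get(g), n_stems=0, n_species=len(vals),
        )
        for g, vals in sorted(per_genus.items())
    ]
    return estimates, sorted(omitted)


def fold_range(values) -> float:
    """Max/min ratio of a positive trait vector (the 'n-fold variation' summary)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.any(v <= 0):
        raise ValueError("fold range needs a non-empty, strictly positive vector")
    return float(v.max() / v.min())
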