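"""Assemblage metrics: biomass density, contamination indices, Kempton's Q.

Per sampling unit *s* and species *j*, biomass density is B_j = W_j / A
(summed weight over sampled area, g m^-2).  Splitting species into native
and non-native classes gives richnesses R_n, R_nn and summed densities
B_n, B_nn, from which five contamination indices are formed:

    CI_r  = R_nn / (R_nn + R_n)                  richness proportion
    CI_b  = B_nn / (B_nn + B_n)                  biomass proportion
    CI_e  = R_nn*B_nn / (R_nn*B_nn + R_n*B_n)    "ecosystem" product form
    CI_a  = (CI_b + CI_r) / 2                    additive mean
    CI_sq = sqrt(CI_b * CI_r)                    multiplicative (geometric)

Each is a proportion in [0, 1]; an index whose denominator is zero is
*undefined* (NaN) and is excluded from group means rather than coerced to
0 or 1.  The multiplicative index defaults to the geometric mean; the plain
product is available via ``ci_sq_form="product"``.

Kempton's interquartile diversity for one assemblage with per-species
biomasses B is Q = (R/2) / ln(B_4/B_2) where B_4 and B_2 are the 75th and
25th percentiles (linear interpolation between order statistics) of the
biomass distribution; the campaign-level statistic is the mean of defined
per-locality Q values.  Q is high when the assemblage is both rich and even,
and is invariant to rescaling all biomasses by a common factor.

Species of unclassified origin are retained in tables but enter neither
richness nor biomass totals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SurveyTable, require_valid

# ---------------------------------------------------------------------------
# per-unit summaries


@dataclass(frozen=True)
class AssemblageSummary:
    """Richness and biomass density of one sampling unit, split by origin."""

    unit_id: str
    r_n: int
    r_nn: int
    b_n: float
    b_nn: float


@dataclass(frozen=True)
class ContaminationProfile:
    """The five contamination indices for one unit or aggregate (NaN = undefined)."""

    ci_r: float
    ci_b: float
    ci_e: float
    ci_a: float
    ci_sq: float


@dataclass(frozen=True)
class KemptonResult:
    q: float
    k: int
    n_skipped: int


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


def biomass_density(total_weight_g: float, area_m2: float) -> float:
    """Biomass per area, g m^-2.  Area must be strictly positive."""
    if not area_m2 > 0:
        raise ValueError(f"area_m2 must be > 0, got {area_m2}")
    if total_weight_g < 0:
        raise ValueError("total_weight_g must be >= 0")
    return total_weight_g / area_m2


def summarize_units(survey: SurveyTable) -> pd.DataFrame:
    """Per-unit assemblage summaries for every sampling unit.

    Returns one row per unit with columns ``unit_id, locality, habitat, gear,
    campaign_date, season, area_m2, r_n, r_nn, b_n, b_nn``.  Richness counts
    species with at least one individual; biomass sums per-species densities;
    unclassified species are ignored.  Units without catches appear with
    zeros.
    """
    require_valid(survey)
    origin = survey.registry.set_index("species_id")["origin"]
    c = survey.catches.merge(
        survey.units[["unit_id", "area_m2"]], on="unit_id", how="left"
    )
    c["origin"] = c["species_id"].map(origin)
    c = c[c["origin"].isin(["native", "non_native"]) & (c["n_individuals"] > 0)]
    c["b"] = c["total_weight_g"] / c["area_m2"]
    g = c.groupby(["unit_id", "origin"]).agg(r=("species_id", "nunique"), b=("b", "sum"))
    wide = g.unstack("origin").reindex(survey.units["unit_id"])
    out = survey.units.copy()
    for col, src in (
        ("r_n", ("r", "native")),
        ("r_nn", ("r", "non_native")),
        ("b_n", ("b", "native")),
        ("b_nn", ("b", "non_native")),
    ):
        out[col] = wide[src].values if src in wide.columns else 0.0
    out[["r_n", "r_nn", "b_n", "b_nn"]] = out[["r_n", "r_nn", "b_n", "b_nn"]].fillna(0)
    out[["r_n", "r_nn"]] = out[["r_n", "r_nn"]].astype(int)
    return out.reset_index(drop=True)


def summarize_unit(survey: SurveyTable, unit_id: str) -> AssemblageSummary:
    """Assemblage summary of a single sampling unit."""
    table = summarize_units(survey)
    row = table[table["unit_id"] == unit_id]
    if len(row) == 0:
        raise KeyError(f"unknown unit_id {unit_id!r}")
    r = row.iloc[0]
    return AssemblageSummary(unit_id=unit_id, r_n=int(r.r_n), r_nn=int(r.r_nn), b_n=float(r.b_n), b_nn=float(r.b_nn))


# ---------------------------------------------------------------------------
# contamination indices


def ci_additive(ci_b: float, ci_r: float) -> float:
    """Additive index: arithmetic mean of the biomass and richness indices."""
    return (ci_b + ci_r) / 2.0


def ci_multiplicative(ci_b: float, ci_r: float, form: str = "geometric") -> float:
    """Multiplicative index: geometric mean (default) or plain product."""
    if form == "geometric":
        return math.sqrt(ci_b * ci_r)
    if form == "product":
        return ci_b * ci_r
    raise ValueError(f"unknown ci_sq_form {form!r}")


def contamination_indices(
    summary: AssemblageSummary, ci_sq_form: str = "geometric"
) -> ContaminationProfile:
    """The five contamination indices of one assemblage summary.

    Any index whose denominator vanishes (no species at all, or zero total
    biomass) is NaN; the derived CI_a and CI_sq are defined exactly when both
    CI_b and CI_r are.
    """
    r_tot = summary.r_nn + summary.r_n
    b_tot = summary.b_nn + summary.b_n
    e_tot = summary.r_nn * summary.b_nn + summary.r_n * summary.b_n
    ci_r = summary.r_nn / r_tot if r_tot > 0 else math.nan
    ci_b = summary.b_nn / b_tot if b_tot > 0 else math.nan
    ci_e = summary.r_nn * summary.b_nn / e_tot if e_tot > 0 else math.nan
    if math.isnan(ci_r) or math.isnan(ci_b):
        ci_a = ci_sq = math.nan
    else:
        ci_a = ci_additive(ci_b, ci_r)
        ci_sq = ci_multiplicative(ci_b, ci_r, ci_sq_form)
    return ContaminationProfile(ci_r=ci_r, ci_b=ci_b, ci_e=ci_e, ci_a=ci_a, ci_sq=ci_sq)


# ---------------------------------------------------------------------------
# Spearman rho with exact small-sample p


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho(x, y, exact_max_n: int = 8) -> SpearmanResult:
    """Tie-corrected Spearman correlation with a two-sided p-value.

    The statistic is the Pearson correlation of mid-ranks.  For n <= 8 the
    p-value is exact, by enumerating all permutations of one margin (valid
    under ties); for larger n the usual t approximation with n-2 degrees of
    freedom is used.  A constant margin leaves rho undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = _midranks(x), _midranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return SpearmanResult(rho=math.nan, p=math.nan, n=n)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        obs = abs(float(rxc @ ryc))
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = abs(float(rxc @ ryc[list(perm)]))
            if stat >= obs - 1e-12 * denom:
                count += 1
            total += 1
        p = count / total
    else:
        r2 = min(rho * rho, 1.0)
        if r2 >= 1.0:
            p = 0.0
        else:
            t = abs(rho) * math.sqrt((n - 2) / (1.0 - r2))
            p = 2.0 * stats.t.sf(t, df=n - 2)
    return SpearmanResult(rho=rho, p=min(p, 1.0), n=n)


# ---------------------------------------------------------------------------
# Kempton's Q


def kempton_q(species_biomasses) -> float:
    """Kempton's interquartile diversity of one assemblage.

    ``species_biomasses`` is the vector of per-species biomasses (all > 0).
    Returns NaN when the quartiles coincide (for example, all biomasses
    equal), in which case the log-ratio denominator vanishes.
    """
    b = np.asarray(species_biomasses, dtype=float)
    if b.size == 0:
        return math.nan
    if np.any(b <= 0):
        raise ValueError("species biomasses must be > 0")
    b4 = float(np.percentile(b, 75))  # linear interpolation between order stats
    b2 = float(np.percentile(b, 25))
    if not b4 > b2:
        return math.nan
    return (b.size / 2.0) / math.log(b4 / b2)


def kempton_q_campaign(per_locality_biomasses) -> KemptonResult:
    """Mean of defined per-locality Q values for one campaign and origin class.

    ``per_locality_biomasses`` is an iterable of per-species biomass vectors,
    one per locality.  Localities whose Q is undefined are skipped and
    counted in ``n_skipped``.
    """
    qs = []
    skipped = 0
    for b in per_locality_biomasses:
        q = kempton_q(b)
        if math.isnan(q):
            skipped += 1
        else:
            qs.append(q)
    if not qs:
        return KemptonResult(q=math.nan, k=0, n_skipped=skipped)
    return KemptonResult(q=float(np.mean(qs)), k=len(qs), n_skipped=skipped)


# ---------------------------------------------------------------------------
# aggregation


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report-table convention)."""
    if isinstance(x, float) and math.isnan(x):
        return x
    scale = 10**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def _campaign_key(units: pd.DataFrame) -> pd.Series:
    d = pd.to_datetime(units["campaign_date"])
    return d.dt.year.astype(str) + units["season"]


def _per_unit_profiles(per_unit: pd.DataFrame, ci_sq_form: str) -> pd.DataFrame:
    out = per_unit.copy()
    cis = [
        contamination_indices(
            AssemblageSummary("", int(r.r_n), int(r.r_nn), float(r.b_n), float(r.b_nn)),
            ci_sq_form=ci_sq_form,
        )
        for r in out.itertuples()
    ]
    out["CIr"] = [c.ci_r for c in cis]
    out["CIb"] = [c.ci_b for c in cis]
    out["CIe"] = [c.ci_e for c in cis]
    out["CIa"] = [c.ci_a for c in cis]
    out["CIsq"] = [c.ci_sq for c in cis]
    return out


def _species_biomass_vectors(survey: SurveyTable, pool_gears: bool = True) -> pd.DataFrame:
    """Per (campaign, locality, origin, species) biomass density, gears pooled.

    Biomass per species is the summed weight over the summed sampled area of
    the contributing units within locality x campaign.
    """
    units = survey.units.copy()
    units["campaign"] = _campaign_key(units)
    origin = survey.registry.set_index("species_id")["origin"]
    c = survey.catches[survey.catches["n_individuals"] > 0].merge(
        units[["unit_id", "locality", "campaign", "gear", "area_m2"]], on="unit_id"
    )
    c["origin"] = c["species_id"].map(origin)
    c = c[c["origin"].isin(["native", "non_native"])]
    keys = ["campaign", "locality", "origin"] + ([] if pool_gears else ["gear"])
    g = (
        c.groupby(keys + ["species_id"])
        .agg(w=("total_weight_g", "sum"))
        .reset_index()
    )
    area = (
        c.drop_duplicates("unit_id")
        .groupby(keys)
        .agg(area=("area_m2", "sum"))
        .reset_index()
    )
    g = g.merge(area, on=keys)
    g["b"] = g["w"] / g["area"]
    return g


def kempton_q_series(survey: SurveyTable, pool_gears: bool = True) -> pd.DataFrame:
    """Per-campaign, per-origin Kempton Q (mean over localities with defined Q)."""
    vec = _species_biomass_vectors(survey, pool_gears=pool_gears)
    rows = []
    for (campaign, origin), grp in vec.groupby(["campaign", "origin"]):
        per_loc = [g["b"].to_numpy() for _, g in grp.groupby("locality")]
        res = kempton_q_campaign(per_loc)
        rows.append(
            {"campaign": campaign, "origin": origin, "Q": res.q, "k": res.k, "n_skipped": res.n_skipped}
        )
    return pd.DataFrame(rows).sort_values(["campaign", "origin"]).reset_index(drop=True)


CI_COLS = ["CIe", "CIb", "CIa", "CIsq", "CIr"]


def unit_profile_table(survey: SurveyTable, ci_sq_form: str = "geometric") -> pd.DataFrame:
    """Per-unit assemblage summaries with the five CI columns attached."""
    per_unit = summarize_units(survey)
    per_unit["campaign"] = _campaign_key(per_unit)
    return _per_unit_profiles(per_unit, ci_sq_form)


def aggregate_series(
    survey: SurveyTable,
    group_by: str = "locality",
    ci_sq_form: str = "geometric",
    pool_gears_for_q: bool = True,
) -> pd.DataFrame:
    """Grouped metric series over sampling units.

    ``group_by`` is ``"locality"`` (temporal averaging: units of all campaigns
    pooled per locality x gear) or ``"campaign"`` (spatial averaging: units of
    all localities pooled per campaign x gear).  Each group yields, per origin
    class, mean +- sd of unit biomass density and richness; the contamination
    index block (computed per unit, then averaged over units with the index
    defined, sd only for n >= 2); the Spearman correlation between unit
    biomass and richness across the group's units; and, for campaign grouping,
    Kempton's Q (gears pooled by default).
    """
    require_valid(survey)
    per_unit = summarize_units(survey)
    per_unit["campaign"] = _campaign_key(per_unit)
    per_unit = _per_unit_profiles(per_unit, ci_sq_form)
    key = "locality" if group_by == "locality" else "campaign"
    if group_by not in ("locality", "campaign"):
        raise ValueError("group_by must be 'locality' or 'campaign'")

    q_table = None
    if group_by == "campaign":
        q = kempton_q_series(survey, pool_gears=pool_gears_for_q)
        q_table = q.set_index(["campaign", "origin"])["Q"]

    rows = []
    for (gkey, gear), grp in per_unit.groupby([key, "gear"]):
        ci_stats = {}
        for col in CI_COLS:
            vals = grp[col].dropna()
            ci_stats[col] = float(vals.mean()) if len(vals) else math.nan
            ci_stats["median_" + col] = float(vals.median()) if len(vals) else math.nan
            ci_stats["sd_" + col] = float(vals.std(ddof=1)) if len(vals) >= 2 else math.nan
        for origin, (rcol, bcol) in (("native", ("r_n", "b_n")), ("non_native", ("r_nn", "b_nn"))):
            n = len(grp)
            b = grp[bcol].astype(float)
            r = grp[rcol].astype(float)
            if n >= 3 and b.nunique() > 1 and r.nunique() > 1:
                sp = spearman_rho(b.to_numpy(), r.to_numpy())
                rho, rho_p = sp.rho, sp.p
            else:
                rho = rho_p = math.nan
            row = {
                "locality": gkey if key == "locality" else "",
                "campaign": gkey if key == "campaign" else "",
                "gear": gear,
                "origin": origin,
                "n_units": n,
                "mean_biomass": float(b.mean()),
                "sd_biomass": float(b.std(ddof=1)) if n >= 2 else math.nan,
                "mean_richness": float(r.mean()),
                "sd_richness": float(r.std(ddof=1)) if n >= 2 else math.nan,
                **{c: ci_stats[c] for c in CI_COLS},
                **{"sd_" + c: ci_stats["sd_" + c] for c in CI_COLS},
                **{"median_" + c: ci_stats["median_" + c] for c in CI_COLS},
                "rho": rho,
                "rho_p": rho_p,
                "Q": float(q_table.get((gkey, origin), math.nan)) if q_table is not None else math.nan,
            }
            rows.append(row)
    cols = (
        ["locality", "campaign", "gear", "origin", "n_units", "mean_biomass", "sd_biomass", "mean_richness", "sd_richness"]
        + CI_COLS
        + ["sd_" + c for c in CI_COLS]
        + ["median_" + c for c in CI_COLS]
        + ["rho", "rho_p", "Q"]
    )
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["locality", "campaign", "gear", "origin"]
    ).reset_index(drop=True)
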