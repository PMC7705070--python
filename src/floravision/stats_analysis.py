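"""Mixed-model inference on perceived floral color variation.

The central question is whether perceived intrapopulation color
variation depends on the interaction between the viewer's visual system
(bee vs bird) and the plant's pollination system (Bee vs Bird).  The
response — fraction discriminable (or saturation) — is modeled with a
linear mixed-effects model fit by maximum likelihood:

    response ~ visual_system * pollination_system
               + (1 | species) + (1 | population nested in species)

Terms are tested with likelihood-ratio chi-square tests between nested
ML fits (df = difference in fixed-effect parameters); main effects are
tested against the additive model (type-II style).  Planned cell-mean
contrasts compare pollination systems within each visual system; their
t ratios use residual degrees of freedom n_obs - rank(X) (the
denominator-df method is a documented package choice, reported in the
output).  Fractions are analyzed untransformed on [0, 1] by default,
with an optional logit transform.

Robustness regroupings fold species with mixed pollination systems into
the pure classes; a cross-space regression of bird-perceived on
bee-perceived variation compares candidate models by AICc,

    AICc = -2 loglik + 2k + 2k(k + 1)/(n - k - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .colorspaces import color_point
from .spectra_io import SpectralDataset
from .visual_systems import Illuminant, ViewerPhenotype, quantum_catches

__all__ = [
    "VariationModelResult",
    "variation_table",
    "saturation_table",
    "fit_variation_model",
    "fit_saturation_model",
    "regroup_mixed_systems",
    "regress_across_spaces",
    "simulate_variation_table",
    "aicc",
    "REGROUPING_SCHEMES",
]

_RESPONSE = "response"


def _logit(p: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    q = np.clip(p, eps, 1 - eps)
    return np.log(q / (1 - q))


@dataclass
class VariationModelResult:
    """Fitted mixed-model summary for a variation (or saturation) table."""

    response: str
    grouping_scheme: str
    fixed_effects: pd.Series
    lrt: pd.DataFrame  # term, chi2, df, p
    contrasts: pd.DataFrame  # within, comparison, estimate, se, t_ratio, df, p
    cell_means: pd.DataFrame  # visual_system, pollination_system, estimate, se
    loglik: float
    aicc: float
    n_obs: int
    df_method: str = "residual"

    def lrt_for(self, term: str) -> pd.Series:
        row = self.lrt[self.lrt["term"] == term]
        if row.empty:
            raise KeyError(f"no LRT for term {term!r}")
        return row.iloc[0]

    def contrast_for(self, within: str) -> pd.Series:
        row = self.contrasts[self.contrasts["within"] == within]
        if row.empty:
            raise KeyError(f"no contrast within {within!r}")
        return row.iloc[0]


# ---------------------------------------------------------------------------
# Table construction

def variation_table(pop_table: pd.DataFrame, bird_viewer: str = "bird_VS") -> pd.DataFrame:
    """Reshape a population fraction table into the analysis layout.

    Keeps the bee viewer and one bird viewer, mapping viewer labels to
    the two-level ``visual_system`` factor.  One row per population per
    visual system.
    """
    keep = pop_table[pop_table["viewer"].isin(["bee", bird_viewer])].copy()
    if keep["viewer"].nunique() != 2:
        raise ValueError(f"table must contain viewers 'bee' and {bird_viewer!r}")
    keep["visual_system"] = np.where(keep["viewer"] == "bee", "bee", "bird")
    out = keep[
        [
            "population_id",
            "species_code",
            "pollination_system",
            "visual_system",
            "fraction_discriminable",
        ]
    ].reset_index(drop=True)
    return out


def saturation_table(
    ds: SpectralDataset,
    viewers: list[ViewerPhenotype],
    ill: Illuminant,
    level: str = "population",
) -> pd.DataFrame:
    """Per-flower or population-mean saturation for each viewer.

    Bee saturation is the hexagon origin distance (spectral purity);
    bird saturation is the RNL distance from the adaptation background.
    ``level='population'`` (default) averages flowers within each
    population, the default unit of analysis for the saturation model.
    """
    if level not in ("population", "flower"):
        raise ValueError("level must be 'population' or 'flower'")
    rows = []
    for pop_id, flowers in ds.populations().items():
        species, system = ds.population_info(pop_id)
        for v in viewers:
            for fid in flowers:
                q = quantum_catches(ds.spectra[fid], v, ill)
                rows.append(
                    {
                        "flower_id": fid,
                        "population_id": pop_id,
                        "species_code": species,
                        "pollination_system": system,
                        "visual_system": "bee" if v.model == "hexagon" else "bird",
                        "viewer": v.label,
                        "saturation": color_point(q, v).saturation,
                    }
                )
    table = pd.DataFrame(rows)
    if level == "flower":
        return table
    return (
        table.groupby(
            ["population_id", "species_code", "pollination_system", "visual_system", "viewer"],
            as_index=False,
        )["saturation"].mean()
    )


# ---------------------------------------------------------------------------
# Mixed model machinery

def _fit_lmm(data: pd.DataFrame, fixed: str):
    model = smf.mixedlm(
        f"{_RESPONSE} ~ {fixed}",
        data,
        groups="species_code",
        re_formula="1",
        vc_formula={"population": "0 + C(population_id)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("lbfgs", "cg", "powell"):
            try:
                res = model.fit(reml=False, method=method, maxiter=500, disp=False)
            except Exception:
                continue
            if np.isfinite(res.llf):
                return res
    raise RuntimeError("mixed model failed to converge with all optimizers")


def _cell_row(exog_names: list[str], vs: str, ps: str) -> np.ndarray:
    """Design row of a (visual_system, pollination_system) cell.

    Reconstructs patsy treatment coding from the exogenous-variable
    names, e.g. ``C(visual_system)[T.bird]:C(pollination_system)[T.Bird]``.
    """
    values = {"visual_system": vs, "pollination_system": ps}
    row = np.zeros(len(exog_names))
    for i, name in enumerate(exog_names):
        if name == "Intercept":
            row[i] = 1.0
            continue
        active = 1.0
        for factor in name.split(":"):
            var = factor[factor.index("(") + 1 : factor.index(")")]
            level = factor[factor.index("[T.") + 3 : -1]
            if values[var] != level:
                active = 0.0
                break
        row[i] = active
    return row


def _check_cells(data: pd.DataFrame) -> None:
    counts = data.groupby(["visual_system", "pollination_system"]).size()
    all_cells = [
        (vs, ps)
        for vs in sorted(data["visual_system"].unique())
        for ps in sorted(data["pollination_system"].unique())
    ]
    for cell in all_cells:
        if counts.get(cell, 0) < 2:
            raise ValueError(f"unreplicated design cell {cell}: cannot fit the interaction model")


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _fit_factorial_lmm(
    data: pd.DataFrame, response: str, grouping_scheme: str, logit: bool
) -> VariationModelResult:
    required = {"species_code", "population_id", "visual_system", "pollination_system", response}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    d = data.copy()
    d[_RESPONSE] = _logit(d[response].to_numpy(float)) if logit else d[response].astype(float)
    _check_cells(d)

    full = _fit_lmm(d, "C(visual_system) * C(pollination_system)")
    additive = _fit_lmm(d, "C(visual_system) + C(pollination_system)")
    vs_only = _fit_lmm(d, "C(visual_system)")
    ps_only = _fit_lmm(d, "C(pollination_system)")

    def _lrt(big, small, term):
        chi2 = max(0.0, 2.0 * (big.llf - small.llf))
        df = len(big.fe_params) - len(small.fe_params)
        return {"term": term, "chi2": chi2, "df": df, "p": float(sps.chi2.sf(chi2, df))}

    lrt = pd.DataFrame(
        [
            _lrt(full, additive, "visual_system:pollination_system"),
            _lrt(additive, ps_only, "visual_system"),
            _lrt(additive, vs_only, "pollination_system"),
        ]
    )

    # cell means and planned contrasts from the full model
    names = list(full.fe_params.index)
    beta = full.fe_params.to_numpy()
    cov = np.asarray(full.cov_params())[: len(names), : len(names)]
    n_obs = len(d)
    df_resid = n_obs - len(names)

    cells = []
    for vs in sorted(d["visual_system"].unique()):
        for ps in sorted(d["pollination_system"].unique()):
            L = _cell_row(names, vs, ps)
            cells.append(
                {
                    "visual_system": vs,
                    "pollination_system": ps,
                    "estimate": float(L @ beta),
                    "se": float(np.sqrt(L @ cov @ L)),
                }
            )
    cell_means = pd.DataFrame(cells)

    contrasts = []
    ps_levels = sorted(d["pollination_system"].unique())
    for vs in sorted(d["visual_system"].unique()):
        La = _cell_row(names, vs, ps_levels[0])
        Lb = _cell_row(names, vs, ps_levels[1])
        L = La - Lb
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        t = est / se
        contrasts.append(
            {
                "within": vs,
                "comparison": f"{ps_levels[0]} - {ps_levels[1]}",
                "estimate": est,
                "se": se,
                "t_ratio": t,
                "df": df_resid,
                "p": float(2 * sps.t.sf(abs(t), df_resid)),
            }
        )

    # parameters: fixed effects + species variance + population vc + residual
    k = len(names) + 3
    return VariationModelResult(
        response=response,
        grouping_scheme=grouping_scheme,
        fixed_effects=full.fe_params,
        lrt=lrt,
        contrasts=pd.DataFrame(contrasts),
        cell_means=cell_means,
        loglik=float(full.llf),
        aicc=aicc(float(full.llf), k, n_obs),
        n_obs=n_obs,
    )


def fit_variation_model(
    table: pd.DataFrame, grouping_scheme: str = "main", logit: bool = False
) -> VariationModelResult:
    """Fit the viewer x pollination-system mixed model to fraction discriminable."""
    return _fit_factorial_lmm(table, "fraction_discriminable", grouping_scheme, logit)


def fit_saturation_model(table: pd.DataFrame, standardize: bool = True) -> VariationModelResult:
    """Same factorial mixed model with saturation as the response.

    Saturation is measured in hexagon units for the bee and JND units
    for the birds; by default it is z-standardized within each visual
    system so the two scales are comparable and the bird-space spread
    does not dominate the shared residual variance.  Pass
    ``standardize=False`` to analyze raw saturations.
    """
    d = table.copy()
    if standardize:
        grp = d.groupby("visual_system")["saturation"]
        d["saturation"] = (d["saturation"] - grp.transform("mean")) / grp.transform("std")
    return _fit_factorial_lmm(d, "saturation", "main", logit=False)


# ---------------------------------------------------------------------------
# Robustness regroupings

#: scheme -> (mixed systems folded into a pure class, systems dropped)
REGROUPING_SCHEMES: dict[str, dict[str, str]] = {
    "main": {},
    "BeeBird->Bee": {"Bee/Bird": "Bee"},
    "BeeBird->Bird": {"Bee/Bird": "Bird"},
    "mixed->Bee": {"Bee/Fly": "Bee", "Bee/Hawkmoth": "Bee"},
}


def regroup_mixed_systems(table: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Fold mixed pollination systems into pure classes per a named scheme.

    ``main`` keeps only pure Bee and Bird species; the other schemes fold
    the named mixed systems in and drop the remaining mixed species.  A
    table with no mixed-system species passes through unchanged (apart
    from the main filter, which is then the identity).
    """
    if scheme not in REGROUPING_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; known: {sorted(REGROUPING_SCHEMES)}")
    mapping = REGROUPING_SCHEMES[scheme]
    out = table.copy()
    out["pollination_system"] = out["pollination_system"].replace(mapping)
    return out[out["pollination_system"].isin(["Bee", "Bird"])].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cross-space regression

def regress_across_spaces(table: pd.DataFrame) -> pd.DataFrame:
    """Regress bird-perceived on bee-perceived variation across populations.

    Three nested OLS candidates are compared by AICc: slope only, plus
    pollination system, plus its interaction with bee-perceived
    variation.  Returns one row per candidate with AICc, adjusted R^2
    and slope p-value; the lowest-AICc model is flagged ``best``.
    """
    wide = table.pivot_table(
        index=["population_id", "species_code", "pollination_system"],
        columns="visual_system",
        values="fraction_discriminable",
    ).reset_index()
    if "bee" not in wide.columns or "bird" not in wide.columns:
        raise ValueError("table must contain both visual systems")
    if wide[["bee", "bird"]].isna().any().any():
        bad = wide.loc[wide[["bee", "bird"]].isna().any(axis=1), "population_id"].tolist()
        raise ValueError(f"unpaired populations (missing one viewer): {bad}")

    candidates = {
        "slope_only": "bird ~ bee",
        "plus_pollination": "bird ~ bee + C(pollination_system)",
        "plus_interaction": "bird ~ bee * C(pollination_system)",
    }
    n = len(wide)
    rows = []
    for label, formula in candidates.items():
        res = smf.ols(formula, data=wide).fit()
        k = int(res.df_model) + 2  # coefficients incl. intercept + sigma
        rows.append(
            {
                "model": label,
                "formula": formula,
                "k": k,
                "aicc": aicc(float(res.llf), k, n),
                "adj_r2": float(res.rsquared_adj),
                "slope": float(res.params["bee"]),
                "slope_p": float(res.pvalues["bee"]),
            }
        )
    out = pd.DataFrame(rows)
    out["best"] = out["aicc"] == out["aicc"].min()
    return out


# ---------------------------------------------------------------------------
# Table-level simulation (for calibration and power checks)

def simulate_variation_table(
    rng: np.random.Generator,
    n_species: dict[str, int] = {"Bee": 24, "Bird": 7},
    populations_per_species: int = 2,
    cell_means: dict[tuple[str, str], float] | None = None,
    species_sd: float = 0.08,
    population_sd: float = 0.05,
    residual_sd: float = 0.05,
) -> pd.DataFrame:
    """Draw a variation table directly from the mixed-model data-generating process.

    Used for calibration (type-I error) and power studies of the
    inference machinery without simulating spectra: response =
    cell mean + species effect + population effect + residual, with the
    population effect shared between the two viewer rows of a
    population.  Under ``cell_means=None`` all cells share one mean
    (a null table).
    """
    cell_means = cell_means or {}
    rows = []
    sp_idx = 0
    for system, n_sp in sorted(n_species.items()):
        for _ in range(n_sp):
            sp_idx += 1
            species = f"sp{sp_idx:02d}"
            sp_eff = rng.normal(0, species_sd)
            for p in range(1, populations_per_species + 1):
                pop = f"{species}_p{p}"
                pop_eff = rng.normal(0, population_sd)
                for vs in ("bee", "bird"):
                    mu = 0.3 + cell_means.get((vs, system), 0.0)
                    rows.append(
                        {
                            "population_id": pop,
                            "species_code": species,
                            "pollination_system": system,
                            "visual_system": vs,
                            "fraction_discriminable": mu
                            + sp_eff
                            + pop_eff
                            + rng.normal(0, residual_sd),
                        }
                    )
    return pd.DataFrame(rows)
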