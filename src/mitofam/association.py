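"""Association layer: exposures, matched and unmatched models, meta-analysis,
population-attributable risk, severity score.

Exposure construction follows the family-comparator rule: a child *carries*
a predicted-pathogenic heteroplasmy only if its fraction exceeds the
matched comparator's (the sibling in quartets, the mother in dyads), so a
shared inherited variant counts toward whichever family member it is
enriched in.  The matched design is analyzed by conditional logistic
regression stratified on family; unrelated children by ordinary logistic
regression with sex and lineage covariates.  Cohort effects are combined by
inverse-variance fixed-effect meta-analysis with Cochran's Q / I^2
heterogeneity, and translated into a population-attributable risk
proportion with a family-bootstrap CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.discrete.conditional_models import ConditionalLogit

Z975 = 1.959964


@dataclass
class StratumEffect:
    label: str
    or_point: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (0 < self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError(f"inconsistent CI for stratum {self.label!r}")


@dataclass
class MetaResult:
    or_combined: float
    ci_low: float
    ci_high: float
    z_p: float
    q_stat: float
    q_p: float
    i2: float


def build_exposures(calls: pd.DataFrame, content: pd.DataFrame,
                    sample_sheet: pd.DataFrame, design: str = "quartet",
                    min_vaf: float = 0.015) -> pd.DataFrame:
    """Per-child exposure record from annotated calls, content, pedigree.

    ``calls`` needs sample_id / pos / alt / vaf / pp (and optionally
    category, consequence, origin); ``content`` needs sample_id / mtCNz /
    tertile.  carry_pp uses the design's comparator rule; heteroplasmy
    counts are tallied overall, coding, OXPHOS, tRNA and by VAF stratum.
    Missing parental ages are imputed with the group mean.  A quartet
    child without a sibling gets an indeterminate (NA) carry_pp.
    """
    sheet = sample_sheet.set_index("sample_id")
    children = sample_sheet[
        sample_sheet.role.str.startswith("child")
        | sample_sheet.role.isin(["proband", "sibling"])].copy()
    vaf_lookup = calls.groupby(["sample_id", "pos", "alt"]).vaf.max()
    calls_by_sample = dict(tuple(calls.groupby("sample_id")))

    sibling_of = {}
    if design == "quartet":
        for fid, grp in children.groupby("family_id"):
            ids = list(grp.sample_id)
            for sid in ids:
                others = [s for s in ids if s != sid]
                sibling_of[sid] = others[0] if others else None

    rows = []
    for ch in children.itertuples():
        mine = calls_by_sample.get(ch.sample_id, calls.iloc[[]])
        mine = mine[mine.vaf >= min_vaf]
        comparator = (sibling_of.get(ch.sample_id) if design == "quartet"
                      else sheet.loc[ch.sample_id].get("mother_id"))
        carry = pd.NA
        if comparator is not None:
            carry = False
            for e in mine[mine.pp.fillna(False)].itertuples():
                other = vaf_lookup.get((comparator, e.pos, e.alt), 0.0)
                if e.vaf > other:
                    carry = True
                    break
        n_all = len(mine)
        cat = mine.category if "category" in mine else pd.Series(dtype=object)
        cons = (mine.consequence if "consequence" in mine
                else pd.Series(dtype=object))
        rows.append({
            "sample_id": ch.sample_id, "family_id": ch.family_id,
            "carry_pp": carry,
            "n_het": n_all,
            "n_coding": int((cons == "nonsynonymous").sum()
                            + (cons == "synonymous").sum()),
            "n_oxphos": int((cat == "OXPHOS").sum()),
            "n_trna": int((cat == "tRNA").sum()),
            "n_vaf5": int((mine.vaf >= 0.05).sum()),
            "n_vaf20": int((mine.vaf >= 0.20).sum()),
        })
    out = pd.DataFrame(rows)
    merged = out.merge(content[["sample_id", "mtCNz", "tertile"]],
                       on="sample_id", how="left")
    keep = [c for c in ("sample_id", "role", "male", "age", "affected",
                        "maternal_age_birth", "paternal_age_birth",
                        "lineage") if c in sample_sheet.columns]
    merged = merged.merge(sample_sheet[["sample_id", *keep[1:]]],
                          on="sample_id", how="left")
    for col in ("maternal_age_birth", "paternal_age_birth", "age"):
        if col in merged and merged[col].isna().any():
            merged[col] = merged[col].fillna(merged[col].mean())
    return merged


def conditional_logistic(data: pd.DataFrame, exposure_cols,
                         outcome_col: str = "affected",
                         group_col: str = "family_id") -> pd.DataFrame:
    """Matched (within-family) conditional logistic regression.

    For a single binary exposure in 1:1 matched pairs this equals the
    discordant-pair ratio.  Returns one row per exposure with OR, 95% CI
    and p.  Raises when no family is outcome-discordant.
    """
    if isinstance(exposure_cols, str):
        exposure_cols = [exposure_cols]
    df = data.dropna(subset=[*exposure_cols, outcome_col]).copy()
    disc = df.groupby(group_col)[outcome_col].nunique()
    if not (disc > 1).any():
        raise ValueError("no outcome-discordant family")
    y = df[outcome_col].astype(int).to_numpy()
    X = df[exposure_cols].astype(float)
    fit = ConditionalLogit(y, X, groups=df[group_col].to_numpy()).fit(disp=0)
    ci = fit.conf_int()
    return pd.DataFrame({
        "term": exposure_cols,
        "or": np.exp(fit.params.to_numpy()),
        "ci_low": np.exp(ci.iloc[:, 0].to_numpy()),
        "ci_high": np.exp(ci.iloc[:, 1].to_numpy()),
        "p": fit.pvalues.to_numpy(),
    })


def logistic_model(data: pd.DataFrame, exposure_cols,
                   outcome_col: str = "affected",
                   covariate_cols=()) -> pd.DataFrame:
    """Unmatched ML logistic regression (dyad-design template).

    Returns per-term OR with 95% CI and p; categorical covariates are
    dummy-coded.  Separation leaves the affected term flagged via an
    infinite CI rather than raising.
    """
    if isinstance(exposure_cols, str):
        exposure_cols = [exposure_cols]
    cols = [*exposure_cols, *covariate_cols]
    df = data.dropna(subset=[*cols, outcome_col]).copy()
    y = df[outcome_col].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("constant outcome")
    X = pd.get_dummies(df[cols], drop_first=True, dtype=float)
    X = sm.add_constant(X.astype(float))
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    ci = fit.conf_int()
    out = pd.DataFrame({
        "term": X.columns,
        "or": np.exp(fit.params.to_numpy()),
        "ci_low": np.exp(ci.iloc[:, 0].to_numpy()),
        "ci_high": np.exp(ci.iloc[:, 1].to_numpy()),
        "p": fit.pvalues.to_numpy(),
    })
    out.attrs["llf"] = float(fit.llf)
    out.attrs["df_model"] = int(fit.df_model)
    return out[out.term != "const"].reset_index(drop=True)


def likelihood_ratio_test(data: pd.DataFrame, outcome_col: str,
                          full_cols, reduced_cols) -> dict:
    """LRT between nested logistic models (e.g. with/without mtCNz and the
    content x exposure interaction)."""
    full = logistic_model(data, full_cols, outcome_col)
    red = logistic_model(data, reduced_cols, outcome_col)
    lr = 2 * (full.attrs["llf"] - red.attrs["llf"])
    df = full.attrs["df_model"] - red.attrs["df_model"]
    if df <= 0:
        raise ValueError("models are not strictly nested")
    return {"lr": float(lr), "df": int(df),
            "p": float(stats.chi2.sf(max(lr, 0.0), df))}


def fixed_effect_meta(strata: list[StratumEffect]) -> MetaResult:
    """Inverse-variance fixed-effect combination of odds ratios.

    Per-stratum log-OR standard errors are back-calculated from the 95%
    CI assuming symmetric Wald intervals on the log scale:
    SE = (ln hi - ln lo) / (2 * 1.959964).  Cochran's Q is referred to
    chi-squared with k-1 df; I^2 = max(0, (Q - (k-1)) / Q).
    """
    if not strata:
        raise ValueError("need at least one stratum")
    logs = np.array([np.log(s.or_point) for s in strata])
    ses = np.array([(np.log(s.ci_high) - np.log(s.ci_low)) / (2 * Z975)
                    for s in strata])
    if np.any(ses <= 0):
        bad = strata[int(np.argmin(ses))].label
        raise ValueError(f"degenerate CI in stratum {bad!r}")
    w = 1.0 / ses**2
    combined = float(np.sum(w * logs) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (logs - combined) ** 2))
    k = len(strata)
    q_p = float(stats.chi2.sf(q, k - 1)) if k > 1 else 1.0
    i2 = float(max(0.0, (q - (k - 1)) / q)) if q > 0 else 0.0
    z = combined / se
    return MetaResult(
        or_combined=float(np.exp(combined)),
        ci_low=float(np.exp(combined - Z975 * se)),
        ci_high=float(np.exp(combined + Z975 * se)),
        z_p=float(2 * stats.norm.sf(abs(z))),
        q_stat=q, q_p=q_p, i2=i2)


def par(prevalence_in_controls: float, or_combined: float) -> float:
    """Population-attributable risk proportion.

    PAR = p0 (OR - 1) / (1 + p0 (OR - 1)) with p0 the family-adjusted
    exposure prevalence among controls.
    """
    if not 0 <= prevalence_in_controls <= 1:
        raise ValueError("prevalence must be in [0,1]")
    if or_combined <= 0:
        raise ValueError("OR must be positive")
    x = prevalence_in_controls * (or_combined - 1.0)
    return x / (1.0 + x)


def family_adjusted_prevalence(exposed_flags, B: int = 1000,
                               seed: int = 0) -> tuple[float, float]:
    """Comparator-rule exposure prevalence with a family-bootstrap SEM.

    ``exposed_flags``: one flag per matched unit (family/dyad).  Returns
    ``(prevalence, bootstrap SEM)``; SEM is 0 when the flags are constant.
    """
    x = np.asarray(pd.Series(exposed_flags).dropna(), dtype=float)
    if x.size == 0:
        raise ValueError("no exposure flags")
    x = np.sort(x)  # the bootstrap depends only on the multiset of flags
    rng = np.random.default_rng(seed)
    boots = rng.choice(x, size=(B, x.size), replace=True).mean(axis=1)
    return float(x.mean()), float(boots.std())


def par_bootstrap(exposures: pd.DataFrame, B: int = 1000, seed: int = 0,
                  outcome_col: str = "affected",
                  exposure_col: str = "carry_pp",
                  group_col: str = "family_id") -> dict:
    """PAR with a percentile CI from bootstrap resamples of families.

    Each resample redraws families with replacement, recomputes the
    control-group exposure prevalence and the matched OR (discordant-pair
    ratio), and re-evaluates the PAR formula.
    """
    df = exposures.dropna(subset=[exposure_col, outcome_col])
    fams = df[group_col].unique()
    rng = np.random.default_rng(seed)

    def compute(frame):
        controls = frame[frame[outcome_col] == 0]
        p0 = float(controls[exposure_col].astype(float).mean())
        wide = frame.pivot_table(index=group_col, columns=outcome_col,
                                 values=exposure_col, aggfunc="max")
        if wide.shape[1] < 2:
            return np.nan
        a = int(((wide[1] == 1) & (wide[0] == 0)).sum())
        b = int(((wide[1] == 0) & (wide[0] == 1)).sum())
        if a == 0 or b == 0:
            return np.nan
        return par(p0, a / b)

    point = compute(df)
    grouped = dict(tuple(df.groupby(group_col)))
    draws = []
    for _ in range(B):
        pick = rng.choice(fams, size=fams.size, replace=True)
        frames = []
        for i, f in enumerate(pick):
            g = grouped[f].copy()
            g[group_col] = f"{f}#{i}"
            frames.append(g)
        draws.append(compute(pd.concat(frames, ignore_index=True)))
    draws = np.asarray([d for d in draws if np.isfinite(d)])
    lo, hi = (np.percentile(draws, [2.5, 97.5]) if draws.size
              else (np.nan, np.nan))
    return {"par": point, "ci_low": float(lo), "ci_high": float(hi),
            "n_boot_valid": int(draws.size)}


def severity_score(nv_iq, v_iq, vabs, ados_cs) -> pd.Series:
    """0-4 phenotype severity: (NV-IQ < 70) + (V-IQ < 70) + (VABS in the
    bottom quartile) + (negated ADOS calibrated severity in the bottom
    quartile).  Quartile cutoffs are computed over the analyzed cohort;
    a missing component makes the score indeterminate (NA).
    """
    nv = pd.Series(nv_iq, dtype=float)
    v = pd.Series(v_iq, dtype=float)
    vb = pd.Series(vabs, dtype=float)
    ac = pd.Series(ados_cs, dtype=float)
    vabs_q = np.nanquantile(vb.to_numpy(), 0.25)
    ados_q = np.nanquantile((-ac).to_numpy(), 0.25)
    score = ((nv < 70).astype(float) + (v < 70).astype(float)
             + (vb <= vabs_q).astype(float) + ((-ac) <= ados_q).astype(float))
    score[nv.isna() | v.isna() | vb.isna() | ac.isna()] = np.nan
    return score
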