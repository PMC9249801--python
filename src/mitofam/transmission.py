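"""Heteroplasmy origin, germline purifying selection, maternal-age effects.

Origin classification: a child heteroplasmy shared (per the exact-binomial
sharing test) with any member of the same maternal lineage is *inherited*;
otherwise, at VAF >= 1.5%, it is *de novo*.  Maternal heteroplasmies are
*transmitted* or *untransmitted* by the same sharing test against each
child, with depth-insufficient queries left indeterminate.

Selection tests: (1) a one-sample t test of whether the mean pathogenicity
z of an observed heteroplasmy set deviates from the universe median (z = 0);
(2) a composition-matched resampling test drawing, from the change universe,
sets that match the observed counts within each (gene category x
transition/transversion) stratum — the "P for selection".  The
transmission readout fits logit(transmitted) ~ z + category + maternal VAF
+ sex and reports the per-SD odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .calling import sharing_test


@dataclass
class SelectionTestResult:
    label: str
    n: int
    mean_z: float
    t_p: float | None = None
    boot_p: float | None = None
    resamples: int = 0
    composition: dict = field(default_factory=dict)
    tail: str = "lower"


def classify_origin(child_calls: pd.DataFrame,
                    lineage_pileups: dict[str, pd.DataFrame],
                    error_rate: float = 1e-3,
                    min_vaf_de_novo: float = 0.015) -> pd.DataFrame:
    """Assign inherited / de novo / unknown origin to child calls.

    ``lineage_pileups`` maps maternal-lineage sample ids (the mother and,
    in quartets, the other child) to their pileup tables.  A call shared
    with any lineage member is inherited — including "secondary"
    heteroplasmies where the relative sits below the primary-calling VAF
    floor but passes the sharing test.  With no lineage data every call is
    ``unknown``.  Untransmitted maternal heteroplasmies are enumerated
    separately by :func:`transmission_table`.
    """
    out = child_calls.copy()
    if not lineage_pileups:
        out["origin"] = "unknown"
        out["shared_with"] = None
        return out

    indexed = {sid: p.set_index("pos") for sid, p in lineage_pileups.items()}

    def alt_depth(sid, pos, alt):
        try:
            row = indexed[sid].loc[pos]
        except KeyError:
            return 0, 0
        cnt = int(row[f"{alt}_fwd"]) + int(row[f"{alt}_rev"])
        tot = int(sum(row[f"{b}_{s}"] for b in "ACGT" for s in ("fwd", "rev")))
        return cnt, tot

    origins, shared_with = [], []
    for call in out.itertuples():
        share, indet = None, False
        for sid in indexed:
            k, n = alt_depth(sid, call.pos, call.alt)
            verdict = sharing_test(k, n, error_rate=error_rate)
            if verdict == "shared":
                share = sid
                break
            indet |= verdict == "indeterminate"
        if share is not None:
            origins.append("inherited")
        elif indet:
            origins.append("unknown")
        elif call.vaf >= min_vaf_de_novo:
            origins.append("de_novo")
        else:
            origins.append("unknown")
        shared_with.append(share)
    out["origin"] = origins
    out["shared_with"] = shared_with
    return out


def transmission_table(maternal_calls: pd.DataFrame,
                       child_pileup: pd.DataFrame,
                       child_id: str,
                       error_rate: float = 1e-3) -> pd.DataFrame:
    """Per maternal heteroplasmy: transmitted / untransmitted / indeterminate
    for one child, with the child VAF and the increased-fraction flag."""
    indexed = child_pileup.set_index("pos")
    rows = []
    for call in maternal_calls.itertuples():
        try:
            prow = indexed.loc[call.pos]
            k = int(prow[f"{call.alt}_fwd"]) + int(prow[f"{call.alt}_rev"])
            n = int(sum(prow[f"{b}_{s}"] for b in "ACGT"
                        for s in ("fwd", "rev")))
        except KeyError:
            k, n = 0, 0
        verdict = sharing_test(k, n, error_rate=error_rate)
        child_vaf = k / n if n else 0.0
        rows.append({
            "child_id": child_id, "pos": call.pos, "ref": call.ref,
            "alt": call.alt, "maternal_vaf": call.vaf,
            "child_vaf": child_vaf,
            "transmitted": {"shared": True, "not_shared": False,
                            "indeterminate": None}[verdict],
            "increased": child_vaf > call.vaf,
        })
    return pd.DataFrame(rows)


def selection_t_test(z_values) -> tuple[float, float]:
    """One-sample t test of mean pathogenicity z against 0 (two-sided).

    Returns ``(mean_z, p)``.  Requires n >= 2 and non-constant z.
    """
    z = np.asarray(z_values, dtype=float)
    z = z[~np.isnan(z)]
    if z.size < 2:
        raise ValueError("need at least 2 z values")
    if np.ptp(z) == 0:
        raise ValueError("constant z values: t test undefined")
    t = stats.ttest_1samp(z, 0.0)
    return float(z.mean()), float(t.pvalue)


def _stratum_key(category, transition):
    return f"{category}:{'Ts' if transition else 'Tv'}"


def selection_bootstrap(observed: pd.DataFrame, universe: pd.DataFrame,
                        B: int = 100_000, seed: int = 0,
                        tail: str = "lower") -> SelectionTestResult:
    """Composition-matched resampling test of purifying selection.

    Each of the B resamples draws, without replacement within each
    (category x Ts/Tv) stratum of the change universe, exactly the number
    of observed heteroplasmies in that stratum, and records the mean z.
    The lower-tail probability ``(1 + #{mean_resample <= mean_obs}) /
    (B + 1)`` is the "P for selection" (purifying); ``tail="two-sided"``
    doubles the smaller tail.  Deterministic under ``seed``.
    """
    if tail not in ("lower", "upper", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    obs = observed.dropna(subset=["z"])
    comp = obs.groupby([obs.category, obs.is_transition]).size()
    if comp.empty:
        raise ValueError("no scored heteroplasmies in observed set")
    rng = np.random.default_rng(seed)
    totals = np.zeros(B)
    n_total = 0
    composition = {}
    for (cat, is_ts), c in comp.items():
        stratum = universe[(universe.category == cat)
                           & (universe.is_transition == is_ts)]
        composition[_stratum_key(cat, is_ts)] = int(c)
        s = len(stratum)
        if s < c:
            raise ValueError(
                f"universe stratum {_stratum_key(cat, is_ts)} has {s} "
                f"entries, {c} requested")
        zs = stratum.z.to_numpy()
        n_total += c
        if B * s <= 5_000_000:
            # vectorized draw-without-replacement via random-key selection
            keys = rng.random((B, s))
            idx = np.argpartition(keys, c - 1, axis=1)[:, :c]
            totals += zs[idx].sum(axis=1)
        else:
            for b in range(B):
                totals[b] += zs[rng.choice(s, c, replace=False)].sum()
    means = totals / n_total
    mean_obs = float(obs.z.mean())
    lower = (1 + int(np.sum(means <= mean_obs))) / (B + 1)
    upper = (1 + int(np.sum(means >= mean_obs))) / (B + 1)
    if tail == "lower":
        p = lower
    elif tail == "upper":
        p = upper
    else:
        p = min(1.0, 2 * min(lower, upper))
    return SelectionTestResult(label=tail, n=int(n_total), mean_z=mean_obs,
                               boot_p=float(p), resamples=B,
                               composition=composition, tail=tail)


def transmission_model(records: pd.DataFrame) -> dict:
    """Per-SD transmission odds ratio of pathogenicity z.

    Fits logit(transmitted) ~ z + RNA-or-OXPHOS + maternal VAF + sex by
    maximum likelihood on rows with a determinate transmitted flag and a
    z score.  Returns the OR per SD of z with 95% CI; separation is
    flagged and the CI reported as unbounded.
    """
    df = records.dropna(subset=["transmitted", "z"]).copy()
    y = df.transmitted.astype(int).to_numpy()
    if y.sum() < 10 or (1 - y).sum() < 10:
        raise ValueError("need >= 10 transmitted and >= 10 untransmitted")
    X = pd.DataFrame({"z": df.z.to_numpy()})
    if "category" in df:
        X["is_rna"] = (df.category == "tRNA").astype(float).to_numpy()
    if "maternal_vaf" in df:
        X["maternal_vaf"] = df.maternal_vaf.to_numpy()
    if "male" in df:
        X["male"] = df.male.astype(float).to_numpy()
    # constant covariates (e.g. single-category sets) would make the
    # design singular
    X = X.loc[:, X.nunique() > 1]
    X = sm.add_constant(X)
    try:
        fit = sm.Logit(y, X).fit(disp=0)
        b, se = fit.params["z"], fit.bse["z"]
        separated = not np.isfinite(se) or se > 50
    except Exception:  # perfect separation
        return {"or_per_sd": np.nan, "ci_low": 0.0, "ci_high": np.inf,
                "p": np.nan, "separated": True, "n": len(df)}
    return {
        "or_per_sd": float(np.exp(b)),
        "ci_low": float(np.exp(b - 1.959964 * se)) if not separated else 0.0,
        "ci_high": float(np.exp(b + 1.959964 * se)) if not separated
        else np.inf,
        "p": float(fit.pvalues["z"]),
        "separated": bool(separated),
        "n": int(len(df)),
    }


def maternal_age_trend(counts: pd.DataFrame) -> dict:
    """Linear regression of de novo counts on maternal age at childbirth.

    ``counts`` columns: ``n_de_novo``, ``maternal_age``, optional ``group``
    (case/control) for a group x age interaction test of slope
    heterogeneity, optional ``paternal_age`` covariate.  Returns slope,
    CI, p, and (when grouped) the interaction slope difference and its p.
    """
    df = counts.dropna(subset=["n_de_novo", "maternal_age"])
    if len(df) < 10:
        raise ValueError("need at least 10 children")
    if np.ptp(df.maternal_age.to_numpy(dtype=float)) == 0:
        raise ValueError("constant maternal age")
    X = pd.DataFrame({"maternal_age": df.maternal_age.to_numpy(dtype=float)})
    if "paternal_age" in df.columns and df.paternal_age.notna().all():
        X["paternal_age"] = df.paternal_age.to_numpy(dtype=float)
    has_group = "group" in df.columns and df.group.nunique() == 2
    if has_group:
        g = (df.group == sorted(df.group.unique())[1]).astype(float)
        X["group"] = g.to_numpy()
        X["group_x_age"] = (g * df.maternal_age).to_numpy()
    fit = sm.OLS(df.n_de_novo.to_numpy(dtype=float),
                 sm.add_constant(X)).fit()
    out = {
        "slope": float(fit.params["maternal_age"]),
        "ci_low": float(fit.conf_int().loc["maternal_age", 0]),
        "ci_high": float(fit.conf_int().loc["maternal_age", 1]),
        "p": float(fit.pvalues["maternal_age"]),
        "n": int(len(df)),
    }
    if has_group:
        out["slope_difference"] = float(fit.params["group_x_age"])
        out["interaction_p"] = float(fit.pvalues["group_x_age"])
    return out


def mutation_rate(total_de_novo: int, n_children: int, callable_sites: int,
                  detectable_fraction: float = 1.0) -> float:
    """Per-site per-generation mtDNA mutation rate.

    ``rate = total / (n_children * callable_sites) / detectable_fraction``;
    the detectability correction defaults to 1 (off) and is an explicit
    user input — with it set to the true detection probability the
    estimator recovers the underlying rate.
    """
    if n_children <= 0:
        raise ValueError("need at least one child")
    if callable_sites <= 0:
        raise ValueError("callable_sites must be positive")
    if not 0 < detectable_fraction <= 1:
        raise ValueError("detectable_fraction must be in (0,1]")
    return total_de_novo / (n_children * callable_sites) / detectable_fraction
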