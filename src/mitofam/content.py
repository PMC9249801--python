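"""mtDNA content estimation and mtCNz standardization.

Content is the number of mtDNA copies per diploid nuclear genome, estimated
either from WGS depth ratios (mt depth over autosomal window coverage,
times two) or from barcode-consensus read counts on mt vs single-copy
nuclear capture targets.  Child content is then standardized to mtCNz — the
standardized residual from regressing content on age (or gestational age)
and the parental mean (or maternal) content — and cut into tertiles over
the pooled child cohort.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def content_from_depth(window_depths: pd.DataFrame, mt_depth: float,
                       min_covered: float = 0.8) -> float:
    """mtDNA content from WGS depth ratios.

    ``window_depths`` rows: ``chrom``, ``mean_depth``, ``frac_covered``
    (sliding windows, typically 100-kb at 50-kb step).  Per autosome,
    coverage is the mean over windows with more than ``min_covered`` of
    sites covered; content is two times the mean over autosomes of
    mt_depth / autosome coverage.  Autosomes with no usable window are
    excluded with a warning; if all are excluded an error is raised.
    """
    ratios = []
    for chrom, grp in window_depths.groupby("chrom", sort=False):
        usable = grp[grp.frac_covered > min_covered]
        if len(usable) == 0 or usable.mean_depth.mean() <= 0:
            warnings.warn(f"chromosome {chrom} has no usable window; excluded")
            continue
        ratios.append(mt_depth / usable.mean_depth.mean())
    if not ratios:
        raise ValueError("no autosome with a usable window")
    return 2.0 * float(np.mean(ratios))


def content_from_consensus(mt_counts, nuclear_counts,
                           usable_mt_probes=None) -> float:
    """mtDNA content from consensus-read counts on capture targets.

    ``mt_counts``: consensus reads per mt probe target; ``nuclear_counts``:
    consensus reads per single-copy nuclear target; ``usable_mt_probes``:
    boolean mask excluding probes whose arms overlap batch polymorphisms
    (minor allele in >= 0.2% of samples).  The estimate is the mean per-
    target mt read count over usable probes divided by the mean nuclear
    per-target count, times two for diploidy.
    """
    mt = np.asarray(mt_counts, dtype=float)
    nuc = np.asarray(nuclear_counts, dtype=float)
    if usable_mt_probes is not None:
        mt = mt[np.asarray(usable_mt_probes, dtype=bool)]
    if mt.size == 0:
        raise ValueError("no usable mt probe")
    if nuc.size == 0 or nuc.sum() <= 0:
        raise ValueError("zero nuclear consensus reads")
    return 2.0 * float(mt.mean() / nuc.mean())


def probe_usability(minor_allele_samples, n_samples: int,
                    max_freq: float = 0.002) -> np.ndarray:
    """Probe mask: a probe is disqualified when a polymorphism in its arm
    region has the minor allele in more than ``max_freq`` of batch samples."""
    counts = np.asarray(minor_allele_samples, dtype=float)
    return counts / float(n_samples) < max_freq


def standardize_mtcnz(children: pd.DataFrame,
                      content_col: str = "raw_content",
                      age_col: str = "age",
                      parental_col: str = "parental_content") -> pd.Series:
    """mtCNz: standardized residuals of child content on age and parental
    content.

    Missing ages are imputed with the cohort mean age before fitting.
    Constant covariates are dropped with a warning.  On the fitted set the
    residuals have mean 0 and standard deviation 1 exactly.
    """
    df = children.copy()
    if len(df) < 3:
        raise ValueError("need at least 3 children to standardize")
    y = df[content_col].to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    for c in (age_col, parental_col):
        if c not in df.columns:
            continue
        x = df[c].to_numpy(dtype=float)
        if np.isnan(x).any():
            x = np.where(np.isnan(x), np.nanmean(x), x)
        if np.nanstd(x) == 0:
            warnings.warn(f"constant covariate {c!r} dropped")
            continue
        cols.append(x)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = resid.std()  # ddof=0 so the standardized set has sd exactly 1
    if sd == 0:
        raise ValueError("degenerate content: zero residual variance")
    return pd.Series(resid / sd, index=df.index, name="mtCNz")


def assign_tertiles(mtcnz) -> pd.Series:
    """Empirical tertiles (T1 low / T2 / T3 high) of pooled child mtCNz.

    Cuts at the 1/3 and 2/3 quantiles; ties are broken by stable input
    order.  Degenerate all-equal inputs are flagged with a warning and
    split by stable order.
    """
    x = pd.Series(mtcnz)
    if len(x) < 3:
        raise ValueError("need at least 3 values for tertiles")
    q1, q2 = np.quantile(x.to_numpy(dtype=float), [1 / 3, 2 / 3])
    if q1 == q2:
        warnings.warn("degenerate mtCNz distribution; tertiles by stable order")
        thirds = np.array_split(np.arange(len(x)), 3)
        lab = np.empty(len(x), dtype=object)
        for name, idx in zip(("T1", "T2", "T3"), thirds):
            lab[idx] = name
        return pd.Series(lab, index=x.index, name="tertile")
    # stable order within ties: rank by (value, original position)
    order = np.lexsort((np.arange(len(x)), x.to_numpy(dtype=float)))
    lab = np.empty(len(x), dtype=object)
    n = len(x)
    cut1, cut2 = n // 3 + (n % 3 > 0), 2 * (n // 3) + (n % 3 > 1) + (n % 3 > 0)
    lab[order[:cut1]] = "T1"
    lab[order[cut1:cut2]] = "T2"
    lab[order[cut2:]] = "T3"
    return pd.Series(lab, index=x.index, name="tertile")


def content_records(children: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Convenience: raw content -> mtCNz -> tertile table per child."""
    out = children.copy()
    out["mtCNz"] = standardize_mtcnz(children, **kwargs)
    out["tertile"] = assign_tertiles(out["mtCNz"])
    return out
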