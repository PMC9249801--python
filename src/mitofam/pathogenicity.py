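"""Predicted-pathogenic classification and pathogenicity z-scores.

Two tasks:

* **PP flag** — a variant is predicted pathogenic when (1) the applicable
  in-silico predictors all exceed their thresholds (nonsynonymous OXPHOS
  changes: CADD-Phred > 15 AND PolyPhen-2 possibly/probably damaging AND
  MutPred > 0.6; tRNA changes: MitoTIP raw > 12.66), or (2) the variant is a
  confirmed mitochondrial-disorder mutation not marked benign in ClinVar;
  and in either route (3) its maximum population frequency is <= 0.05%.

* **Pathogenicity z** — rank-based inverse-normal transform of the raw
  predictor score (CADD-like for OXPHOS, MitoTIP-like for tRNA) across the
  complete universe of possible nucleotide changes in that gene category,
  so z represents the pathogenicity *rank* of a change among all changes.

rRNA and D-loop variants receive no z and can be PP only via the confirmed
route; predictors do not exist for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

CADD_MIN = 15.0
MUTPRED_MIN = 0.6
MITOTIP_MIN = 12.66
MAX_POP_FREQ = 0.0005
DAMAGING_POLYPHEN = frozenset({"possibly", "probably"})


@dataclass
class PPThresholds:
    cadd: float = CADD_MIN
    mutpred: float = MUTPRED_MIN
    mitotip: float = MITOTIP_MIN
    max_freq: float = MAX_POP_FREQ


def classify_pp(cadd_phred=None, polyphen_cat=None, mutpred=None,
                mitotip_raw=None, md_confirmed: bool = False,
                clinvar_benign: bool = False, pop_freq_max: float = 0.0,
                consequence: str = "nonsynonymous", category: str = "OXPHOS",
                thresholds: PPThresholds | None = None) -> bool | None:
    """Predicted-pathogenic flag for one variant.

    ``consequence``/``category`` select the applicable predictor set.
    Returns True/False, or None (indeterminate) when a required predictor
    is missing and the confirmed-mutation route does not apply.
    """
    th = thresholds if thresholds is not None else PPThresholds()

    freq_ok = pop_freq_max is not None and pop_freq_max <= th.max_freq
    confirmed = bool(md_confirmed) and not bool(clinvar_benign)
    if confirmed:
        return freq_ok

    if category == "OXPHOS" and consequence == "nonsynonymous":
        needed = (cadd_phred, polyphen_cat, mutpred)
        if any(v is None or (isinstance(v, float) and np.isnan(v))
               for v in needed):
            return None
        predicted = (cadd_phred > th.cadd
                     and str(polyphen_cat) in DAMAGING_POLYPHEN
                     and mutpred > th.mutpred)
    elif category == "tRNA":
        if mitotip_raw is None or (isinstance(mitotip_raw, float)
                                   and np.isnan(mitotip_raw)):
            return None
        predicted = mitotip_raw > th.mitotip
    else:
        # rRNA / D-loop / synonymous: no applicable predictor route
        predicted = False
    return bool(predicted and freq_ok)


def classify_pp_frame(scores: pd.DataFrame,
                      thresholds: PPThresholds | None = None) -> pd.Series:
    """Vector form of :func:`classify_pp` over a score table.

    Expected columns: ``cadd_phred, polyphen_cat, mutpred, mitotip_raw,
    md_confirmed, clinvar_benign, pop_freq_max, consequence, category``.
    Returns a nullable-boolean Series aligned to ``scores``.
    """
    out = []
    for r in scores.itertuples():
        out.append(classify_pp(
            cadd_phred=getattr(r, "cadd_phred", None),
            polyphen_cat=getattr(r, "polyphen_cat", None),
            mutpred=getattr(r, "mutpred", None),
            mitotip_raw=getattr(r, "mitotip_raw", None),
            md_confirmed=bool(getattr(r, "md_confirmed", False)),
            clinvar_benign=bool(getattr(r, "clinvar_benign", False)),
            pop_freq_max=getattr(r, "pop_freq_max", 0.0),
            consequence=getattr(r, "consequence", "nonsynonymous"),
            category=getattr(r, "category", "OXPHOS"),
            thresholds=thresholds))
    return pd.Series(out, index=scores.index, dtype="boolean")


def pathogenicity_z(raw_scores) -> np.ndarray:
    """Rank-based inverse-normal transform over a complete change universe.

    z_i = Phi^{-1}((r_i - 0.5) / m) with r_i the ascending rank (mean rank
    for ties) among the m universe entries.  Mean ~ 0 by construction; z is
    invariant to strictly monotone transformations of the raw score.
    """
    x = np.asarray(raw_scores, dtype=float)
    m = x.size
    if m < 2:
        raise ValueError("universe must contain at least 2 entries")
    if np.isnan(x).any():
        raise ValueError("raw scores must be complete over the universe")
    ranks = rankdata(x, method="average")
    return ndtri((ranks - 0.5) / m)


def attach_z(universe: pd.DataFrame, scores: pd.DataFrame,
             score_col: str) -> pd.DataFrame:
    """Merge raw scores onto a change universe and add the z column.

    ``universe`` rows (pos, ref, alt) must be fully covered by ``scores``;
    the transform is computed over the complete universe so z means rank
    among *all possible* changes of the category, not among observed ones.
    """
    merged = universe.merge(scores[["pos", "ref", "alt", score_col]],
                            on=["pos", "ref", "alt"], how="left",
                            validate="one_to_one")
    if merged[score_col].isna().any():
        n = int(merged[score_col].isna().sum())
        raise ValueError(f"{n} universe entries missing {score_col} scores")
    merged["z"] = pathogenicity_z(merged[score_col].to_numpy())
    return merged


def read_score_table(path) -> pd.DataFrame:
    """Read a variant pathogenicity/frequency score table (TSV)."""
    df = pd.read_csv(path, sep="\t")
    required = {"pos", "ref", "alt"}
    if missing := required - set(df.columns):
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    return df
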