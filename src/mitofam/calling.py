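"""Heteroplasmy calling from ultradeep per-site pileups.

The caller consumes strand-split allele-count pileups (one row per rCRS
position) and applies the filter cascade used for ultradeep mtDNA data:

* site quality  — depth of unique/consensus reads > 500 with > 70% of bases
  at BAQ >= 30, outside low-complexity regions;
* allele support — minor-allele count >= 5, BAQ-based log-likelihood quality
  score > 5, minor-allele fraction >= 1.5% (the NUMT defense);
* strand concordance — non-zero minor allele on both strands and Fisher's
  exact P >= 1e-4 between strands;
* for barcode-consensus data, two additional screens comparing VAF between
  consensus reads built from multiple vs single read pairs.

Also here: the exact-binomial sharing test used to rescue low-fraction
"secondary" heteroplasmies across relatives, the detection-power calculus,
Bayesian consensus-read construction, and per-sample QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import MaskedRegions, BASES

PILEUP_COUNT_COLS = [f"{b}_{s}" for b in BASES for s in ("fwd", "rev")]


def phred_to_error(q) -> np.ndarray | float:
    """Phred quality -> error probability, e = 10^(-Q/10)."""
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


@dataclass
class CallThresholds:
    """Filter thresholds; defaults are the ultradeep-pipeline values."""

    min_depth: int = 500          # strictly greater than
    min_frac_baq30: float = 0.70  # strictly greater than
    min_minor: int = 5            # at least
    min_llq: float = 5.0          # strictly greater than
    min_vaf: float = 0.015        # at least
    strand_p: float = 1e-4        # pass if P >= this
    vi_fold: float = 5.0          # consensus filter vi: VAF decrease < 5-fold
    vii_fail_frac: float = 0.5    # consensus filter vii: >50% of variants fail vi


def llq_score(minor_count: int, depth: int, baq_errors) -> float:
    """BAQ-based log-likelihood quality score for a candidate minor allele.

    log10 likelihood ratio between "heteroplasmy at the MLE fraction
    p = k/n" and "sequencing errors only".  Under the heteroplasmy model a
    minor-allele base with error probability e contributes
    ``p(1-e) + (1-p) e/3`` and a major base ``(1-p)(1-e) + p e/3``; under
    the error-only model the same bases contribute ``e/3`` and ``1-e``.
    ``baq_errors`` is either a scalar error probability applied to every
    base or a pair ``(e_minor, e_major)``.

    The score is >= 0 (the MLE model dominates the null) and is monotone
    non-decreasing in ``minor_count`` at fixed depth and qualities.
    """
    k, n = int(minor_count), int(depth)
    if not 0 <= k <= n:
        raise ValueError(f"minor count {k} outside [0, depth={n}]")
    e = np.broadcast_to(np.asarray(baq_errors, dtype=float), (2,)) \
        if np.ndim(baq_errors) else np.array([baq_errors, baq_errors], float)
    e_minor, e_major = float(e[0]), float(e[-1])
    for ei in (e_minor, e_major):
        if not 0.0 < ei < 1.0:
            raise ValueError(f"error probability {ei} outside (0,1)")
    if k == 0:
        return 0.0
    p = k / n
    l_alt = k * np.log10(p * (1 - e_minor) + (1 - p) * e_minor / 3.0) \
        + (n - k) * np.log10((1 - p) * (1 - e_major) + p * e_major / 3.0)
    l_null = k * np.log10(e_minor / 3.0) + (n - k) * np.log10(1 - e_major)
    # when k/n sits below the error expectation the error-only model is
    # itself the MLE (p = 0), so the ratio is floored at equality
    return float(max(l_alt - l_null, 0.0))


def strand_concordance(fwd_alt: int, fwd_ref: int, rev_alt: int, rev_ref: int):
    """Two-sided Fisher exact probability that strand VAFs are comparable.

    Returns ``(p, passes)``: the exact conditional (hypergeometric)
    two-sided probability for the 2x2 table, and the filter decision
    ``p >= 1e-4 and alt > 0 on both strands``.  An all-zero table is
    defined as pass with P = 1.
    """
    table = np.array([[fwd_alt, fwd_ref], [rev_alt, rev_ref]], dtype=int)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        return 1.0, True
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    passes = (p >= 1e-4) and fwd_alt > 0 and rev_alt > 0
    return p, passes


def sharing_test(alt_count: int, depth: int, error_rate: float = 1e-3,
                 min_fraction: float = 0.002, tail_p: float = 1e-3,
                 min_depth: int = 500):
    """Is a known variant detectably present in another sample?

    Shared iff the variant-allele fraction is >= ``min_fraction`` among
    > ``min_depth`` unique reads and the upper-tail binomial probability of
    seeing that many error bases, P(X >= k | n, error_rate), is < ``tail_p``.
    Returns ``"shared"``, ``"not_shared"``, or ``"indeterminate"`` when the
    depth requirement is not met (distinct from not-shared).
    """
    if depth <= min_depth:
        return "indeterminate"
    if alt_count / depth < min_fraction:
        return "not_shared"
    tail = stats.binom.sf(alt_count - 1, depth, error_rate)
    return "shared" if tail < tail_p else "not_shared"


def detection_power(depth: int, error_rate: float, vaf: float,
                    alpha: float) -> float:
    """Exact-binomial power to discriminate a heteroplasmy from errors.

    Critical count k* is the smallest k with P(Binom(n, e) >= k) <= alpha;
    power is P(Binom(n, p) >= k*).  No normal approximation.  When
    ``vaf <= error_rate`` the returned value is the achieved size of the
    test at p = vaf (at most alpha), not an error.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if not 0 < error_rate < 1 or not 0 < vaf < 1:
        raise ValueError("rates must be in (0,1)")
    n = int(depth)
    # isf gives the largest k with sf(k) > alpha; critical count is k+1,
    # where sf is evaluated at k-1 for P(X >= k).
    k_star = int(stats.binom.isf(alpha, n, error_rate)) + 1
    while k_star > 0 and stats.binom.sf(k_star - 2, n, error_rate) <= alpha:
        k_star -= 1
    return float(stats.binom.sf(k_star - 1, n, vaf))


def _major_minor(counts: np.ndarray):
    """Per-site major and minor allele indices from a (S, 4) count matrix."""
    order = np.argsort(counts, axis=1, kind="stable")
    return order[:, -1], order[:, -2]


def call_heteroplasmies(pileup: pd.DataFrame,
                        masks: MaskedRegions | None = None,
                        thresholds: CallThresholds | None = None,
                        sample_id: str | None = None) -> pd.DataFrame:
    """Call heteroplasmies from a per-site pileup table.

    ``pileup`` columns: ``pos``, ``ref``, the eight strand-split counts
    (``A_fwd`` ... ``T_rev``), per-allele mean BAQ (``baq_A`` ... ``baq_T``)
    and ``frac_baq30``.  Rows must be position-sorted and unique.  Returns
    a DataFrame of passing calls with VAF, minor count, depth, llq and
    strand-test P; minor fraction is <= 0.5 by construction.
    """
    masks = masks if masks is not None else MaskedRegions()
    th = thresholds if thresholds is not None else CallThresholds()
    pos = pileup["pos"].to_numpy()
    if len(pos) and (np.any(np.diff(pos) <= 0)):
        raise ValueError("pileup positions must be sorted and unique")

    fwd = np.column_stack([pileup[f"{b}_fwd"].to_numpy() for b in BASES])
    rev = np.column_stack([pileup[f"{b}_rev"].to_numpy() for b in BASES])
    counts = fwd + rev
    depth = counts.sum(axis=1)
    maj_i, min_i = _major_minor(counts)
    rows_idx = np.arange(len(pileup))
    minor_count = counts[rows_idx, min_i]
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, minor_count / np.maximum(depth, 1), 0.0)

    site_ok = (depth > th.min_depth) \
        & (pileup["frac_baq30"].to_numpy() > th.min_frac_baq30) \
        & ~masks.contains(pos)
    cand = site_ok & (minor_count >= th.min_minor) & (vaf >= th.min_vaf)

    records = []
    base_arr = np.array(BASES)
    ref_arr = pileup["ref"].to_numpy()
    baq = np.column_stack([pileup[f"baq_{b}"].to_numpy() for b in BASES])
    for i in np.flatnonzero(cand):
        bi, bj = int(min_i[i]), int(maj_i[i])
        e_minor = float(phred_to_error(baq[i, bi]))
        e_major = float(phred_to_error(baq[i, bj]))
        llq = llq_score(int(minor_count[i]), int(depth[i]), (e_minor, e_major))
        if llq <= th.min_llq:
            continue
        p_strand, strand_ok = strand_concordance(
            int(fwd[i, bi]), int(fwd[i, bj]), int(rev[i, bi]), int(rev[i, bj]))
        if p_strand < th.strand_p or not strand_ok:
            continue
        records.append({
            "sample_id": sample_id,
            "pos": int(pos[i]),
            "ref": ref_arr[i],
            "major": base_arr[bj],
            "alt": base_arr[bi],
            "vaf": float(vaf[i]),
            "minor_count": int(minor_count[i]),
            "depth": int(depth[i]),
            "llq": float(llq),
            "strand_p": float(p_strand),
            "secondary": False,
        })
    cols = ["sample_id", "pos", "ref", "major", "alt", "vaf", "minor_count",
            "depth", "llq", "strand_p", "secondary"]
    return pd.DataFrame(records, columns=cols)


def major_allele_array(pileup: pd.DataFrame) -> np.ndarray:
    """Per-site major allele (for lineage-concordance QC)."""
    counts = sum(
        np.column_stack([pileup[f"{b}_{s}"].to_numpy() for b in BASES])
        for s in ("fwd", "rev"))
    return np.array(BASES)[np.argmax(counts, axis=1)]


def build_consensus(read_families: pd.DataFrame) -> pd.DataFrame:
    """Merge barcode-grouped reads into consensus base calls.

    ``read_families`` rows: ``barcode``, ``pos``, ``base``, ``qual``
    (one row per read base).  Per barcode per site a posterior over the
    four bases is computed with a uniform prior and per-read error
    likelihoods from Phred qualities (correct base with probability 1-e,
    each other base e/3); consensus base is the MAP, consensus quality the
    Phred of the posterior error.  Posterior ties emit ``N`` (excluded from
    downstream counting); single-member families pass through unchanged.

    Returns rows: ``barcode, pos, base, qual, n_members``.
    """
    if len(read_families) == 0:
        raise ValueError("empty read-family table")
    out = []
    for (barcode, pos), grp in read_families.groupby(["barcode", "pos"],
                                                    sort=True):
        bases = grp["base"].to_numpy()
        quals = grp["qual"].to_numpy(dtype=float)
        n = len(grp)
        if n == 1:
            out.append((barcode, pos, bases[0], float(quals[0]), 1))
            continue
        logpost = np.zeros(4)
        errs = phred_to_error(quals)
        for b, e in zip(bases, errs):
            like = np.full(4, e / 3.0)
            like[BASES.index(b)] = 1.0 - e
            logpost += np.log(like)
        logpost -= logpost.max()
        post = np.exp(logpost)
        post /= post.sum()
        best = np.flatnonzero(np.isclose(post, post.max(), rtol=1e-12))
        if len(best) > 1:
            out.append((barcode, pos, "N", 0.0, n))
            continue
        p_err = max(1.0 - post[best[0]], 1e-30)
        out.append((barcode, pos, BASES[best[0]],
                    float(-10.0 * np.log10(p_err)), n))
    return pd.DataFrame(out, columns=["barcode", "pos", "base", "qual",
                                      "n_members"])


def consensus_filters(calls: pd.DataFrame, pileup_single: pd.DataFrame,
                      pileup_multi: pd.DataFrame,
                      thresholds: CallThresholds | None = None) -> pd.DataFrame:
    """Apply consensus-specific filters vi and vii to called heteroplasmies.

    Filter vi: per call, VAF among consensus reads from multiple read pairs
    must be comparable to VAF among single-read-pair consensus reads
    (Fisher exact P >= 1e-4 and VAF decrease < 5-fold).  Filter vii: sites
    where more than half of the batch's variants fail vi are flagged
    low-quality and every call there is removed.  Returns the surviving
    calls with ``pass_vi`` annotation.
    """
    th = thresholds if thresholds is not None else CallThresholds()
    if pileup_single is None or pileup_multi is None:
        raise ValueError("consensus-source calls need single- and "
                         "multi-member pileups")
    single = pileup_single.set_index("pos")
    multi = pileup_multi.set_index("pos")

    def class_counts(frame, pos, allele):
        row = frame.loc[pos]
        alt = sum(int(row[f"{allele}_{s}"]) for s in ("fwd", "rev"))
        tot = sum(int(row[f"{b}_{s}"]) for b in BASES for s in ("fwd", "rev"))
        return alt, tot

    pass_vi = []
    for call in calls.itertuples():
        alt_s, tot_s = class_counts(single, call.pos, call.alt)
        alt_m, tot_m = class_counts(multi, call.pos, call.alt)
        vaf_s = alt_s / tot_s if tot_s else 0.0
        vaf_m = alt_m / tot_m if tot_m else 0.0
        p = float(stats.fisher_exact(
            [[alt_m, tot_m - alt_m], [alt_s, tot_s - alt_s]])[1])
        fold_ok = vaf_m > 0 and (vaf_s / vaf_m) < th.vi_fold
        pass_vi.append(p >= th.strand_p and fold_ok)
    out = calls.copy()
    out["pass_vi"] = pass_vi

    fail_frac = out.groupby("pos")["pass_vi"].apply(lambda s: (~s).mean())
    bad_sites = set(fail_frac[fail_frac > th.vii_fail_frac].index)
    out["pass_vii"] = ~out["pos"].isin(bad_sites)
    return out[out.pass_vi & out.pass_vii].drop(columns=["pass_vii"])


def sample_qc(calls_by_sample: dict[str, pd.DataFrame],
              sample_sheet: pd.DataFrame,
              major_alleles: dict[str, np.ndarray] | None = None,
              de_novo_counts: dict[str, int] | None = None,
              median_depth: dict[str, float] | None = None,
              max_de_novo: int = 15, min_mismatches: int = 5,
              min_median_depth: float = 500.0) -> pd.DataFrame:
    """Per-sample/family exclusion report (report-only, never mutates calls).

    Flags: children with excessive (> 15) de novo heteroplasmies; mother-child
    pairs whose major-allele sequences differ at >= 5 sites (mislabeling
    proxy for haplogroup discordance); samples with median mtDNA coverage
    below 500X.
    """
    rows = []
    sheet = sample_sheet.set_index("sample_id")
    for sid in sheet.index:
        reasons = []
        if de_novo_counts and de_novo_counts.get(sid, 0) > max_de_novo:
            reasons.append("excess_de_novo")
        if median_depth and median_depth.get(sid, np.inf) < min_median_depth:
            reasons.append("low_coverage")
        mother = sheet.loc[sid].get("mother_id")
        if (major_alleles is not None and isinstance(mother, str)
                and mother in major_alleles and sid in major_alleles):
            mism = int(np.sum(major_alleles[sid] != major_alleles[mother]))
            if mism >= min_mismatches:
                reasons.append(f"lineage_discordant:{mism}")
        rows.append({"sample_id": sid,
                     "family_id": sheet.loc[sid].get("family_id"),
                     "flagged": bool(reasons),
                     "reasons": ";".join(reasons)})
    return pd.DataFrame(rows)
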