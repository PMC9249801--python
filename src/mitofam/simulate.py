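"""Synthetic family data with the statistical structure the analysis assumes.

The generator emulates the study designs the pipeline is built for — family
quartets (mother, father, proband, sibling) and mother-child dyads — and the
data-generating mechanisms the analysis is meant to recover:

* maternal transmission of heteroplasmies through a single-generation
  germline bottleneck (binomial resampling of ``bottleneck_n`` segregating
  units), with purifying selection expressed as a per-SD-of-pathogenicity
  transmission odds ratio;
* Poisson de novo mutation whose mean rises with maternal age at childbirth
  and whose pathogenicity distribution shifts upward with maternal age;
* ultradeep pileups with a ~0.02%-per-base error floor, Phred-distributed
  base qualities and ~50/50 strand split;
* mtDNA content with an additive-genetic decomposition (h^2 ~ 0.65,
  parent-child r ~ h^2/2) and a negative age trend;
* disease liability in which carrying a predicted-pathogenic heteroplasmy
  raises risk (OR ~ 1.5), more so in the low-content tertile.

Every stage writes truth tables so downstream estimates can be checked
against what was simulated.  Output is fully deterministic under a seed,
with independent streams per family: growing ``n_families`` never perturbs
earlier families.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import reference as ref
from .pathogenicity import classify_pp_frame, pathogenicity_z

# spawn-key namespaces for independent deterministic streams
_KEY_SCORES = 0
_KEY_FAMILY = 1
_KEY_PILEUP = 2
_KEY_PHENO = 3


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    n_families: int = 200
    design: str = "quartet"          # "quartet" or "dyad"
    seed: int = 0

    # sequencing
    depth_mean: float = 2000.0
    depth_sd: float = 300.0
    error_floor: float = 2e-4        # per-base variant-allele rate
    baq_phred_mean: float = 33.0
    baq_phred_sd: float = 2.0
    frac_baq30_mean: float = 0.92    # site-level fraction of bases BAQ>=30
    strand_bias: float = 0.0         # error-allele strand asymmetry knob

    # germline transmission
    bottleneck_n: int = 32
    selection_or_per_sd: float = 0.64
    transmission_base_logit: float = 0.6
    transmission_vaf_coef: float = 2.5

    # de novo mutation
    mu: float = 2e-5                 # detectable de novo per site per generation
    maternal_age_slope: float = 0.015  # extra expected count per year over age 30
    de_novo_z_age_shift: float = 0.02  # z location shift per year of maternal age

    # heteroplasmy load
    mother_het_mean: float = 1.2     # Poisson count of maternal heteroplasmies
    lineage_homoplasmy_mean: float = 10.0

    # mtDNA content
    content_mean: float = 150.0
    content_sd: float = 35.0
    content_h2: float = 0.65
    content_parent_child_r: float = 0.325  # h^2/2 under pure additivity
    content_age_slope: float = -1.0        # copies per year, negative

    # disease liability
    pp_asd_or: float = 1.5
    pp_lowcn_interaction_or: float = 1.4
    cn_asd_or: float = 0.85          # per SD of mtCNz
    base_prevalence: float = 0.2     # dyad design only
    proband_male_frac: float = 0.8

    def __post_init__(self):
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.design not in ("quartet", "dyad"):
            raise ValueError(f"unknown design {self.design!r}")
        if not 0 <= self.content_h2 <= 1:
            raise ValueError("content_h2 must be in [0,1]")
        if self.bottleneck_n < 1:
            raise ValueError("bottleneck_n must be >= 1")
        for name in ("error_floor", "frac_baq30_mean"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _rng(cfg: SimulationConfig, *spawn_key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed,
                                                        spawn_key=spawn_key))


# ---------------------------------------------------------------------------
# change universe and synthetic pathogenicity scores


_CODON_AA = {}


def _annotated_oxphos_universe() -> pd.DataFrame:
    """OXPHOS change universe with coding effect, computed once per session."""
    global _OXPHOS_ANNOT
    try:
        return _OXPHOS_ANNOT
    except NameError:
        pass
    from Bio.Seq import Seq
    if not _CODON_AA:
        for i, b1 in enumerate("ACGT"):
            for b2 in "ACGT":
                for b3 in "ACGT":
                    c = b1 + b2 + b3
                    _CODON_AA[c] = str(Seq(c).translate(table=2))
    uni = ref.default_universe("OXPHOS")
    genome = ref.load_reference()
    genes = ref.gene_table()
    ox = genes[genes.category == "OXPHOS"]
    effect = np.array(["other"] * len(uni), dtype=object)
    seq = genome.sequence
    rc = {"A": "T", "T": "A", "C": "G", "G": "C"}
    pos_arr = uni.pos.to_numpy()
    alt_arr = uni.alt.to_numpy()
    for g in ox.itertuples():
        in_gene = (pos_arr >= g.start) & (pos_arr <= g.end)
        for i in np.flatnonzero(in_gene):
            p, alt = int(pos_arr[i]), alt_arr[i]
            if g.strand >= 0:
                off = p - g.start
                cstart = g.start + 3 * (off // 3)
                codon = seq[cstart - 1:cstart + 2]
                if len(codon) < 3:
                    continue
                mut = list(codon)
                mut[off % 3] = alt
            else:
                off = g.end - p
                cstart = g.end - 3 * (off // 3)
                if cstart - 3 < 0:
                    continue
                codon = "".join(rc[b] for b in seq[cstart - 1:cstart - 4:-1])
                mut = list(codon)
                mut[off % 3] = rc[alt]
            # first gene membership wins for overlap regions (documented)
            if effect[i] == "other":
                effect[i] = ("synonymous"
                             if _CODON_AA[codon] == _CODON_AA["".join(mut)]
                             else "nonsynonymous")
    uni = uni.copy()
    uni["consequence"] = effect
    _OXPHOS_ANNOT = uni
    return uni


def simulate_score_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Synthetic predictor/frequency table over the OXPHOS+tRNA universes.

    A latent pathogenicity variable drives correlated CADD-like,
    PolyPhen-2-like, MutPred-like (OXPHOS) and MitoTIP-like (tRNA) scores
    with realistic marginals; population frequency is concentrated on
    low-pathogenicity changes.  PP flags and rank-based z-scores are
    attached with the same rules the pipeline applies to user tables.
    """
    rng = _rng(cfg, _KEY_SCORES)
    ox = _annotated_oxphos_universe()
    tr = ref.default_universe("tRNA")
    tr["consequence"] = "tRNA"
    uni = pd.concat([ox, tr], ignore_index=True)
    m = len(uni)

    latent = rng.normal(size=m)

    def noisy(w=0.8):
        return w * latent + np.sqrt(1 - w * w) * rng.normal(size=m)

    uni["cadd_raw"] = noisy(0.95)          # raw score driving the z ranks
    uni["cadd_phred"] = np.round(10 + 5 * noisy(), 2)
    pp2 = noisy()
    uni["polyphen_cat"] = np.select([pp2 > 1.5, pp2 > 0.8],
                                    ["probably", "possibly"], "benign")
    uni["mutpred"] = np.round(
        1 / (1 + np.exp(-1.7 * noisy())), 3)
    uni["mitotip_raw"] = np.round(10 + 2.5 * noisy(0.95), 2)

    # confirmed-mutation and benign flags, rare
    uni["md_confirmed"] = rng.random(m) < np.where(latent > 1.5, 0.02, 0.0005)
    uni["clinvar_benign"] = rng.random(m) < np.where(latent < 0, 0.03, 0.002)

    # population frequency: mostly absent; carriers skew benign
    w = np.exp(-latent)
    carrier = rng.random(m) < 0.15 * w / w.mean()
    freq = np.zeros(m)
    freq[carrier] = 10 ** rng.uniform(-4, -0.3, carrier.sum())
    uni["pop_freq_max"] = freq

    is_ox = (uni.category == "OXPHOS").to_numpy()
    uni.loc[is_ox, "mitotip_raw"] = np.nan
    uni.loc[~is_ox, ["cadd_phred", "mutpred"]] = np.nan
    uni.loc[~is_ox, "polyphen_cat"] = "NA"

    uni["pp"] = classify_pp_frame(uni).fillna(False).to_numpy(dtype=bool)
    z = np.full(m, np.nan)
    z[is_ox] = pathogenicity_z(uni.loc[is_ox, "cadd_raw"].to_numpy())
    z[~is_ox] = pathogenicity_z(uni.loc[~is_ox, "mitotip_raw"].to_numpy())
    uni["z"] = z
    return uni


# ---------------------------------------------------------------------------
# transmission and de novo mutation


def transmit_heteroplasmy(maternal_vaf: float, pathogenicity_z: float,
                          cfg: SimulationConfig,
                          rng: np.random.Generator) -> float:
    """Child true VAF for one maternal heteroplasmy (0 if lost, 1 if fixed).

    The child allele count is a binomial draw of ``bottleneck_n`` germline
    units at the maternal VAF.  Without selection
    (``selection_or_per_sd == 1``) transmission is exactly bottleneck
    survival (count >= 1).  With selection, the transmitted indicator is
    drawn from the logistic model
    ``logit P = a + c * maternal_vaf + log(selection_or_per_sd) * z``
    so the per-SD transmission odds ratio equals the configured value by
    construction, and the bottleneck then supplies the child VAF
    conditional on transmission.
    """
    if not 0 < maternal_vaf < 1:
        raise ValueError(f"maternal VAF {maternal_vaf} outside (0,1)")
    n = cfg.bottleneck_n
    k = rng.binomial(n, maternal_vaf)
    if cfg.selection_or_per_sd == 1.0:
        return k / n
    z = 0.0 if np.isnan(pathogenicity_z) else float(pathogenicity_z)
    p_trans = expit(cfg.transmission_base_logit
                    + cfg.transmission_vaf_coef * maternal_vaf
                    + np.log(cfg.selection_or_per_sd) * z)
    if rng.random() >= p_trans:
        return 0.0
    while k == 0:  # condition the bottleneck draw on survival
        k = rng.binomial(n, maternal_vaf)
    return k / n


def _tilted_draw(rng, z_universe: np.ndarray, n: int, theta: float):
    """Sample n universe indices with probability ~ exp(theta * z).

    Gumbel-max trick; with z ~ N(0,1) over the universe this shifts the
    sampled z distribution to approximately N(theta, 1).  theta = 0 is a
    uniform draw.
    """
    if n == 0:
        return np.array([], dtype=int)
    g = rng.gumbel(size=(n, z_universe.size))
    return np.argmax(theta * np.where(np.isnan(z_universe), 0.0, z_universe)
                     + g, axis=1)


def simulate_de_novo(maternal_age: float, cfg: SimulationConfig,
                     rng: np.random.Generator,
                     universe: pd.DataFrame) -> pd.DataFrame:
    """De novo heteroplasmies for one child.

    Count ~ Poisson with mean ``mu * n_sites + maternal_age_slope *
    (age - 30)``; entries drawn from the unmasked change universe with an
    exponential tilt that shifts the mean pathogenicity z by
    ``de_novo_z_age_shift`` per year of maternal age; VAF log-uniform on
    [1.5%, 30%].
    """
    if not 10 <= maternal_age <= 60:
        raise ValueError(f"implausible maternal age {maternal_age}")
    pool = universe[~universe.masked]
    lam = cfg.mu * pool.pos.nunique() \
        + cfg.maternal_age_slope * (maternal_age - 30.0)
    if lam < 0:
        raise ValueError(f"negative de novo mean {lam:.3f}")
    count = rng.poisson(lam)
    theta = cfg.de_novo_z_age_shift * (maternal_age - 30.0)
    idx = _tilted_draw(rng, pool.z.to_numpy(), count, theta)
    out = pool.iloc[idx][["pos", "ref", "alt", "category", "consequence",
                          "is_transition", "z", "pp"]].copy()
    out["true_vaf"] = 10 ** rng.uniform(np.log10(0.015), np.log10(0.30),
                                        count)
    out["origin"] = "de_novo"
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# content, phenotype


def simulate_content(n_families: int, cfg: SimulationConfig,
                     rng: np.random.Generator,
                     child_ages: np.ndarray | None = None,
                     n_children: int = 2) -> pd.DataFrame:
    """Latent and raw mtDNA content for parents and children.

    Additive decomposition on the standardized scale: parental additive
    values A ~ N(0, h^2); child A = midparent A + segregation N(0, h^2/2);
    a shared family-environment term supplies any requested parent-child
    correlation beyond h^2/2; residual environment tops variance to 1.
    Raw content adds a linear negative age trend.
    """
    h2 = cfg.content_h2
    c2 = max(0.0, cfg.content_parent_child_r - h2 / 2.0)
    e2 = max(1.0 - h2 - c2, 1e-12)
    F = n_families
    a_m = rng.normal(0, np.sqrt(h2), F)
    a_f = rng.normal(0, np.sqrt(h2), F)
    fam_env = rng.normal(0, np.sqrt(c2), F) if c2 > 0 else np.zeros(F)
    rows = []
    parent_ages = rng.uniform(30, 55, (F, 2))
    if child_ages is None:
        child_ages = rng.integers(4, 19, (F, n_children)).astype(float)
    for i in range(F):
        for role, a, age in (("mother", a_m[i], parent_ages[i, 0]),
                             ("father", a_f[i], parent_ages[i, 1])):
            lat = a + fam_env[i] + rng.normal(0, np.sqrt(e2))
            rows.append((i, role, age, lat))
        for j in range(n_children):
            a_c = (a_m[i] + a_f[i]) / 2 + rng.normal(0, np.sqrt(h2 / 2))
            lat = a_c + fam_env[i] + rng.normal(0, np.sqrt(e2))
            rows.append((i, f"child{j}", child_ages[i, j], lat))
    df = pd.DataFrame(rows, columns=["family", "role", "age", "latent"])
    df["raw_content"] = np.maximum(
        cfg.content_mean + cfg.content_sd * df.latent
        + cfg.content_age_slope * (df.age - df.age.mean()), 5.0)
    return df


def simulate_phenotype(exposures: pd.DataFrame,
                       cfg: SimulationConfig,
                       rng: np.random.Generator) -> pd.Series:
    """Disease labels from child exposures.

    Quartet design: within each family the case child is drawn with
    probability softmax of the linear predictor over the two children —
    the exact conditional-logistic generating process, so Eq.-1-style
    refits are correctly specified.  Dyad design: independent Bernoulli
    from a logistic model with the configured baseline prevalence.

    ``exposures`` columns: family, carry_pp (bool), mtcnz, low_tertile
    (bool), male (bool).
    """
    eta = (np.log(cfg.pp_asd_or) * exposures.carry_pp.to_numpy(dtype=float)
           + np.log(cfg.pp_lowcn_interaction_or)
           * (exposures.carry_pp & exposures.low_tertile).to_numpy(dtype=float)
           + np.log(cfg.cn_asd_or) * exposures.mtcnz.to_numpy(dtype=float))
    if cfg.design == "quartet":
        status = np.zeros(len(exposures), dtype=int)
        for _, idx in exposures.groupby("family").indices.items():
            w = np.exp(eta[idx] - eta[idx].max())
            case = idx[rng.choice(len(idx), p=w / w.sum())]
            status[case] = 1
        return pd.Series(status, index=exposures.index, name="affected")
    p = expit(logit(cfg.base_prevalence) + eta
              + 0.4 * exposures.male.to_numpy(dtype=float))
    return pd.Series((rng.random(len(exposures)) < p).astype(int),
                     index=exposures.index, name="affected")


# ---------------------------------------------------------------------------
# whole-study orchestration


@dataclass
class SimulatedStudy:
    """A simulated cohort: sample sheet, truth tables, scores, config."""

    config: SimulationConfig
    sample_sheet: pd.DataFrame
    truth_het: pd.DataFrame
    truth_homoplasmy: pd.DataFrame
    truth_content: pd.DataFrame
    score_table: pd.DataFrame

    def truth_for(self, sample_id: str) -> pd.DataFrame:
        t = self.truth_het[self.truth_het.sample_id == sample_id]
        return t[t.true_vaf > 0]

    def homoplasmies_for(self, sample_id: str) -> pd.DataFrame:
        return self.truth_homoplasmy[
            self.truth_homoplasmy.sample_id == sample_id]


def _family_members(design: str):
    if design == "quartet":
        return ("mother", "father", "child0", "child1")
    return ("mother", "child0")


def simulate_families(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate a full synthetic cohort with truth tables for every stage."""
    scores = simulate_score_table(cfg)
    pool = scores[~scores.masked].reset_index(drop=True)
    genome = ref.load_reference()
    unmasked_sites = np.flatnonzero(
        ~ref.MaskedRegions().contains(np.arange(1, genome.length + 1))) + 1

    sheet_rows, het_rows, homo_rows, content_rows = [], [], [], []
    members = _family_members(cfg.design)
    n_children = members.count("child0") + members.count("child1")
    n_children = sum(1 for m in members if m.startswith("child"))

    for fam in range(cfg.n_families):
        rng = _rng(cfg, _KEY_FAMILY, fam)
        fid = f"F{fam:05d}"
        sids = {m: f"{fid}_{m}" for m in members}

        child_ages = rng.integers(4, 19, n_children).astype(float)
        if cfg.design == "dyad":
            child_ages[:] = 0.0  # cord blood at birth
        maternal_age_birth = np.clip(rng.normal(30, 5, n_children), 16, 50)
        paternal_age_birth = np.clip(
            maternal_age_birth + rng.normal(2, 3, n_children), 16, 65)

        # lineage homoplasmies: maternal set shared with children; paternal own
        for parent in ("mother", "father"):
            if parent not in members:
                continue
            n_homo = rng.poisson(cfg.lineage_homoplasmy_mean)
            hpos = rng.choice(unmasked_sites, size=n_homo, replace=False)
            carriers = [parent] if parent == "father" else \
                [parent] + [m for m in members if m.startswith("child")]
            for p in np.sort(hpos):
                refb = genome.base(int(p))
                alt = rng.choice([b for b in "ACGT" if b != refb])
                for m in carriers:
                    homo_rows.append((fid, sids[m], int(p), refb, alt))

        # parental heteroplasmies
        parent_hets = {}
        for parent in ("mother", "father"):
            if parent not in members:
                continue
            n_het = rng.poisson(cfg.mother_het_mean)
            idx = rng.choice(len(pool), size=n_het, replace=False)
            ent = pool.iloc[idx].copy()
            ent["true_vaf"] = 10 ** rng.uniform(np.log10(0.02),
                                                np.log10(0.50), n_het)
            parent_hets[parent] = ent
            for e in ent.itertuples():
                het_rows.append((fid, sids[parent], e.pos, e.ref, e.alt,
                                 e.category, e.consequence, e.is_transition,
                                 e.z, bool(e.pp), float(e.true_vaf),
                                 "inherited", np.nan))

        # children: maternal transmissions + de novo
        mother_ent = parent_hets.get("mother",
                                     pool.iloc[[]].assign(true_vaf=[]))
        for j in range(n_children):
            child = f"child{j}"
            for e in mother_ent.itertuples():
                cvaf = transmit_heteroplasmy(float(e.true_vaf), e.z, cfg, rng)
                het_rows.append((fid, sids[child], e.pos, e.ref, e.alt,
                                 e.category, e.consequence, e.is_transition,
                                 e.z, bool(e.pp), float(cvaf), "inherited",
                                 float(e.true_vaf)))
            dn = simulate_de_novo(float(maternal_age_birth[j]), cfg, rng, pool)
            for e in dn.itertuples():
                het_rows.append((fid, sids[child], e.pos, e.ref, e.alt,
                                 e.category, e.consequence, e.is_transition,
                                 e.z, bool(e.pp), float(e.true_vaf),
                                 "de_novo", 0.0))

        # mtDNA content for the family (one family per call keeps streams local)
        fam_content = simulate_content(
            1, cfg, rng, child_ages=child_ages[None, :],
            n_children=n_children)
        for r in fam_content.itertuples():
            if r.role in members:
                content_rows.append((fid, sids[r.role], r.role, r.age,
                                     r.latent, r.raw_content))

        ages = dict(zip(members, [None] * len(members)))
        for r in fam_content.itertuples():
            ages[r.role] = r.age
        for j, m in enumerate(members):
            is_child = m.startswith("child")
            cj = int(m[-1]) if is_child else None
            sheet_rows.append({
                "sample_id": sids[m], "family_id": fid, "role": m,
                "mother_id": sids["mother"] if is_child else None,
                "father_id": sids.get("father") if is_child else None,
                "age": ages[m],
                "maternal_age_birth":
                    float(maternal_age_birth[cj]) if is_child else np.nan,
                "paternal_age_birth":
                    float(paternal_age_birth[cj]) if is_child else np.nan,
                "male": None,  # filled after phenotype assignment
                "lineage": f"L{fam % 12:02d}",
            })

    sheet = pd.DataFrame(sheet_rows)
    het = pd.DataFrame(het_rows, columns=[
        "family_id", "sample_id", "pos", "ref", "alt", "category",
        "consequence", "is_transition", "z", "pp", "true_vaf", "origin",
        "maternal_vaf"])
    homo = pd.DataFrame(homo_rows, columns=["family_id", "sample_id", "pos",
                                            "ref", "alt"])
    content = pd.DataFrame(content_rows, columns=[
        "family_id", "sample_id", "role", "age", "latent", "raw_content"])

    # --- phenotype layer (children only) ---
    child_mask = sheet.role.str.startswith("child")
    children = sheet[child_mask].copy()
    lat = content.set_index("sample_id").latent
    children["mtcnz"] = children.sample_id.map(lat)
    q1, q2 = np.quantile(children.mtcnz, [1 / 3, 2 / 3])
    children["low_tertile"] = children.mtcnz <= q1

    children["carry_pp"] = _truth_carry_pp(het, sheet, cfg.design)\
        .reindex(children.sample_id).to_numpy()
    children["family"] = children.family_id

    prng = _rng(cfg, _KEY_PHENO)
    # sex before phenotype for the dyad model; reassigned by status in quartets
    children["male"] = prng.random(len(children)) < 0.5
    children["affected"] = simulate_phenotype(children, cfg, prng).to_numpy()
    if cfg.design == "quartet":
        aff = children.affected.to_numpy(dtype=bool)
        male = np.where(aff, prng.random(len(children)) < cfg.proband_male_frac,
                        prng.random(len(children)) < 0.5)
        children["male"] = male

    sheet = sheet.merge(
        children[["sample_id", "carry_pp", "mtcnz", "low_tertile",
                  "affected"]], on="sample_id", how="left")
    sheet["male"] = sheet.sample_id.map(
        children.set_index("sample_id").male)
    parent_mask = ~sheet.role.str.startswith("child")
    sheet.loc[parent_mask, "male"] = sheet.loc[parent_mask, "role"] == "father"
    if cfg.design == "quartet":
        role_map = {}
        for r in children.itertuples():
            role_map[r.sample_id] = "proband" if r.affected else "sibling"
        sheet["status_role"] = sheet.role.map(
            lambda m: None).astype(object)
        sheet.loc[child_mask, "status_role"] = [
            role_map[s] for s in sheet.loc[child_mask, "sample_id"]]
    return SimulatedStudy(cfg, sheet, het, homo, content, scores)


def _truth_carry_pp(het: pd.DataFrame, sheet: pd.DataFrame,
                    design: str) -> pd.Series:
    """Comparator-rule exposure truth: a child carries a PP heteroplasmy if
    its VAF exceeds the sibling's (quartet) or the mother's (dyad) at that
    site."""
    children = sheet[sheet.role.str.startswith("child")]
    vaf = het.groupby(["sample_id", "pos", "alt"]).true_vaf.max()
    carry = {}
    for ch in children.itertuples():
        mine = het[(het.sample_id == ch.sample_id) & het.pp
                   & (het.true_vaf >= 0.015)]
        if design == "quartet":
            other_role = "child1" if ch.role == "child0" else "child0"
            comparator = f"{ch.family_id}_{other_role}"
        else:
            comparator = ch.mother_id
        flag = False
        for e in mine.itertuples():
            other = vaf.get((comparator, e.pos, e.alt), 0.0)
            if e.true_vaf > other:
                flag = True
                break
        carry[ch.sample_id] = flag
    return pd.Series(carry, name="carry_pp")


# ---------------------------------------------------------------------------
# pileups


def simulate_pileup(study: SimulatedStudy, sample_id: str) -> pd.DataFrame:
    """Ultradeep per-site pileup for one sample.

    Depth is negative-binomial (Poisson if ``depth_sd^2 <= depth_mean``)
    around ``depth_mean``, split ~50/50 by strand; the sample's true
    variants are sampled binomially at their true VAF; error alleles are
    spread over the three non-reference bases at ``error_floor`` total;
    per-allele mean BAQ and the site-level fraction of BAQ>=30 bases are
    Phred-realistic.  Allele counts sum to depth per strand.
    """
    cfg = study.config
    sheet = study.sample_sheet.set_index("sample_id")
    fam = int(sheet.loc[sample_id, "family_id"][1:])
    member = sheet.loc[sample_id, "role"]
    midx = _family_members(cfg.design).index(member)
    rng = _rng(cfg, _KEY_PILEUP, fam, midx)

    genome = ref.load_reference()
    S = genome.length
    raw = np.frombuffer(genome.sequence.encode(), np.uint8)
    seq = raw.view("S1").astype("U1")
    base_idx = {b: i for i, b in enumerate("ACGT")}
    lut = np.zeros(128, dtype=np.int64)
    for b, i in base_idx.items():
        lut[ord(b)] = i
    ref_i = lut[raw]

    # per-site alt allele and true VAF (variants + homoplasmies)
    vaf = np.zeros(S)
    alt_i = (ref_i + 1) % 4  # default error sink, overwritten at truth sites
    for t in study.truth_for(sample_id).itertuples():
        vaf[t.pos - 1] = min(t.true_vaf, 1.0)
        alt_i[t.pos - 1] = base_idx[t.alt]
    for t in study.homoplasmies_for(sample_id).itertuples():
        vaf[t.pos - 1] = 1.0
        alt_i[t.pos - 1] = base_idx[t.alt]

    mean, sd = cfg.depth_mean, cfg.depth_sd
    if sd * sd > mean:
        r = mean * mean / (sd * sd - mean)
        depth = rng.negative_binomial(r, r / (r + mean), S)
    else:
        depth = rng.poisson(mean, S)
    depth_fwd = rng.binomial(depth, 0.5)
    depth_rev = depth - depth_fwd

    e = cfg.error_floor
    counts = np.zeros((S, 4, 2), dtype=np.int64)
    for s, (dstr, ebias) in enumerate(
            (("fwd", 1 + cfg.strand_bias), ("rev", 1 - cfg.strand_bias))):
        n = depth_fwd if s == 0 else depth_rev
        es = min(e * ebias, 0.9)
        probs = np.full((S, 4), es / 3.0)
        rows = np.arange(S)
        probs[rows, ref_i] = 0.0
        probs[rows, alt_i] += vaf * (1 - 4 * es / 3)
        probs[rows, ref_i] = 1.0 - probs.sum(axis=1)
        counts[:, :, s] = rng.multinomial(n, probs)

    data = {"pos": np.arange(1, S + 1), "ref": seq}
    for i, b in enumerate("ACGT"):
        data[f"{b}_fwd"] = counts[:, i, 0]
        data[f"{b}_rev"] = counts[:, i, 1]
    for b in "ACGT":
        data[f"baq_{b}"] = np.round(
            rng.normal(cfg.baq_phred_mean, cfg.baq_phred_sd, S), 1)
    data["frac_baq30"] = np.clip(
        rng.normal(cfg.frac_baq30_mean, 0.02, S), 0, 1)
    df = pd.DataFrame(data)
    df["source"] = "wgs"
    return df
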