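"""Synthetic twin-cohort generator with known genetic/environmental structure.

Everything downstream (phenotype scoring, EWAS, meta-analysis, twin and
sex-limitation models, discordant-pair analysis, meQTL integration) is
exercised against cohorts produced here, where the generating A/C/D/E
variance fractions, phenotype linkage modes and covariate effects are known.

The generative model per CpG is Gaussian on the beta-value scale:

    m = baseline + total_sd * (sqrt(a2)*G + sqrt(c2)*C + sqrt(d2)*D
                               + sqrt(e2)*E) + linkage + covariate terms

with G shared within a pair at correlation 1 (MZ) / 0.5 (DZ), D at
1 / 0.25, C at 1 / 1 and E independent, then clamped to [0.001, 0.999].
Gaussian-on-beta generation (rather than a logistic latent) preserves the
exact twin-correlation algebra r_MZ = a2 + c2 + d2, r_DZ = a2/2 + c2 + d2/4
that the variance-component tests rely on; capping total_sd at 0.2 keeps
clamping negligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "TwinCohort",
    "CpgSpec",
    "MethylationMatrix",
    "GroundTruth",
    "SnpConfig",
    "ClampWarning",
    "generate_cohort",
    "generate_methylation",
    "generate_questionnaires",
    "generate_meqtl_table",
    "make_cpg_specs",
]

SMOKING_LEVELS = ("never", "current", "former")
CELL_TYPES = ("cd4t", "cd8t", "nk", "bcell", "mono", "gran")
CELL_COLUMNS = tuple(f"cell_{c}" for c in CELL_TYPES)
# rough whole-blood composition used as the Dirichlet mean
_CELL_ALPHA = np.array([0.16, 0.10, 0.06, 0.06, 0.08, 0.54]) * 60.0

PLATFORMS = ("P450K", "PEPIC")
LINKAGE_MODES = ("null", "causal_individual", "family_confounded", "genetic_confounded")

SAMPLE_SHEET_COLUMNS = (
    "individual_id", "family_id", "twin_order", "sex", "zygosity", "cohort",
    "platform", "age_at_sampling", "smoking", "alcohol_g_day",
    *CELL_COLUMNS, "chip_date", "array_row",
)


class ClampWarning(UserWarning):
    """Raised when clamping to the valid beta range affects >1% of values."""


@dataclass
class CohortConfig:
    """Cohort composition and covariate distributions.

    Defaults emulate a two-wave Finnish-style twin sample: two birth cohorts
    ("FT12"-like, younger, with pubertal-development questionnaires at ages
    12 and 14; "FT16"-like, older, pubertal-age only), blood sampled in early
    adulthood on two overlapping methylation platforms. The MZ:DZ ratio and
    the opposite-sex share of DZ pairs are not published for the analysed
    subsample; 1/3 MZ and half of DZ opposite-sex are exposed defaults.
    """

    n_families: int = 400
    mz_fraction: float = 1.0 / 3.0
    os_dz_fraction: float = 0.5          # share of DZ pairs that are opposite-sex
    female_fraction: float = 0.546
    singleton_fraction: float = 0.05     # families contributing a single twin
    cohort_younger_fraction: float = 0.6  # share assigned to the FT12-like cohort
    platform_450k_fraction: float = 0.6
    n_chip_dates: int = 6
    smoking_probs: tuple[float, float, float] = (0.55, 0.30, 0.15)
    alcohol_mean_g_day: float = 11.2
    # latent pubertal-timing phenotype: ACE fractions and female mean shift
    phenotype_a2: float = 0.5
    phenotype_c2: float = 0.2
    phenotype_female_shift: float = 1.0
    rg_os: float = 0.5                   # cross-sex genetic correlation, in [0, 0.5]

    def validate(self) -> None:
        if self.n_families < 2:
            raise ValueError("n_families must be >= 2")
        for name in ("mz_fraction", "os_dz_fraction", "female_fraction",
                     "singleton_fraction", "cohort_younger_fraction",
                     "platform_450k_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.smoking_probs) - 1.0) > 1e-9 or min(self.smoking_probs) < 0:
            raise ValueError("smoking_probs must be nonnegative and sum to 1")
        if not 0.0 <= self.rg_os <= 0.5:
            raise ValueError(f"rg_os must be in [0, 0.5], got {self.rg_os}")
        p_e2 = 1.0 - self.phenotype_a2 - self.phenotype_c2
        if self.phenotype_a2 < 0 or self.phenotype_c2 < 0 or p_e2 < -1e-9:
            raise ValueError("phenotype_a2 + phenotype_c2 must be in [0, 1]")


@dataclass
class TwinCohort:
    """Individuals grouped into twin families.

    ``samples`` has one row per individual (columns ``SAMPLE_SHEET_COLUMNS``
    plus latent ground-truth columns ``latent_g``, ``latent_c``, ``latent_e``
    and ``phenotype``, the standardized pubertal-timing liability).
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        sizes = self.samples.groupby("family_id").size()
        if not sizes.isin([1, 2]).all():
            raise ValueError("every family must have 1 or 2 members")

    @property
    def pairs(self) -> pd.DataFrame:
        """Index of complete families: one row per 2-member family."""
        s = self.samples.sort_values(["family_id", "twin_order"])
        counts = s.groupby("family_id")["individual_id"].transform("size")
        full = s[counts == 2]
        t1 = full[full.twin_order == 1].set_index("family_id")
        t2 = full[full.twin_order == 2].set_index("family_id")
        out = pd.DataFrame({
            "family_id": t1.index,
            "id1": t1.individual_id.values, "id2": t2.individual_id.values,
            "zygosity": t1.zygosity.values, "cohort": t1.cohort.values,
            "platform": t1.platform.values,
            "sex1": t1.sex.values, "sex2": t2.sex.values,
        }).reset_index(drop=True)
        return out

    @property
    def n(self) -> int:
        return len(self.samples)

    def write_sample_sheet(self, path) -> None:
        self.samples[list(SAMPLE_SHEET_COLUMNS)].to_csv(path, sep="\t", index=False)


def _require_frac(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def generate_cohort(config: CohortConfig, seed: int) -> TwinCohort:
    """Generate a seeded twin cohort. Deterministic given (config, seed)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1776]))
    nf = config.n_families

    is_mz = rng.random(nf) < config.mz_fraction
    is_os = (~is_mz) & (rng.random(nf) < config.os_dz_fraction)
    singleton = rng.random(nf) < config.singleton_fraction
    cohort = np.where(rng.random(nf) < config.cohort_younger_fraction, "FT12", "FT16")
    platform = np.where(rng.random(nf) < config.platform_450k_fraction,
                        "P450K", "PEPIC")
    chip_date = rng.integers(0, config.n_chip_dates, nf)

    # sexes: MZ pairs share sex; same-sex DZ share; opposite-sex DZ differ
    sex1 = np.where(rng.random(nf) < config.female_fraction, "F", "M")
    sex2 = np.where(is_os, np.where(sex1 == "F", "M", "F"), sex1)

    # latent pubertal-timing phenotype with ACE familial structure
    a2, c2 = config.phenotype_a2, config.phenotype_c2
    e2 = max(0.0, 1.0 - a2 - c2)
    g_shared = rng.standard_normal(nf)
    g_ind = rng.standard_normal(nf)
    c_shared = rng.standard_normal(nf)
    e1 = rng.standard_normal(nf)
    e2dev = rng.standard_normal(nf)
    rg = np.where(is_mz, 1.0, np.where(is_os, config.rg_os, 0.5))
    g1 = g_shared
    g2 = rg * g_shared + np.sqrt(1.0 - rg ** 2) * g_ind

    def phenotype(g, e, sexes):
        lat = np.sqrt(a2) * g + np.sqrt(c2) * c_shared + np.sqrt(e2) * e
        return lat + config.phenotype_female_shift * (sexes == "F")

    rows = []
    age_params = {"FT12": (22.7, 1.7), "FT16": (28.1, 4.3)}
    for order, (g, e, sexes) in enumerate(
            [(g1, e1, sex1), (g2, e2dev, sex2)], start=1):
        ph = phenotype(g, e, sexes)
        mu, sd = np.vectorize(lambda c: age_params[c][0])(cohort), \
            np.vectorize(lambda c: age_params[c][1])(cohort)
        age = np.clip(rng.normal(mu, sd), 18.0, 45.0)
        smoking = rng.choice(SMOKING_LEVELS, size=nf, p=config.smoking_probs)
        alcohol = rng.gamma(1.2, config.alcohol_mean_g_day / 1.2, nf)
        cells = rng.dirichlet(_CELL_ALPHA, nf)
        df = pd.DataFrame({
            "individual_id": [f"F{f:05d}_{order}" for f in range(nf)],
            "family_id": [f"F{f:05d}" for f in range(nf)],
            "twin_order": order,
            "sex": sexes,
            "zygosity": np.where(is_mz, "MZ", "DZ"),
            "cohort": cohort,
            "platform": platform,
            "age_at_sampling": np.round(age, 2),
            "smoking": smoking,
            "alcohol_g_day": np.round(alcohol, 3),
            "chip_date": [f"chip{d:02d}" for d in chip_date],
            "array_row": rng.integers(1, 9, nf),
            "latent_g": g, "latent_c": c_shared, "latent_e": e,
            "phenotype": ph,
        })
        for k, col in enumerate(CELL_COLUMNS):
            df[col] = cells[:, k]
        rows.append(df)
    rows[1] = rows[1][~singleton]
    samples = (pd.concat(rows, ignore_index=True)
               .sort_values(["family_id", "twin_order"])
               .reset_index(drop=True))
    return TwinCohort(samples=samples)


# ---------------------------------------------------------------------------
# per-CpG methylation

@dataclass
class CpgSpec:
    """Generating parameters for one CpG site."""

    cpg_id: str
    baseline_mean: float
    a2: float
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 0.0
    total_sd: float = 0.05
    linkage_mode: str = "null"
    linkage_beta: float = 0.0
    sex_mean_shift: float = 0.0
    age_beta: float = 0.0
    panel: str = "both"

    def validate(self) -> None:
        if not 0.0 < self.baseline_mean < 1.0:
            raise ValueError(f"{self.cpg_id}: baseline_mean must be in (0,1)")
        fr = np.array([self.a2, self.c2, self.d2, self.e2])
        if (fr < -1e-12).any():
            raise ValueError(f"{self.cpg_id}: variance fractions must be nonnegative")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.cpg_id}: a2+c2+d2+e2 must sum to 1")
        if self.c2 > 0 and self.d2 > 0:
            raise ValueError(f"{self.cpg_id}: C and D cannot both be nonzero "
                             "(classical twin design identifies at most one)")
        if not 0.0 < self.total_sd <= 0.2:
            raise ValueError(f"{self.cpg_id}: total_sd must be in (0, 0.2]")
        if self.linkage_mode not in LINKAGE_MODES:
            raise ValueError(f"{self.cpg_id}: unknown linkage_mode "
                             f"{self.linkage_mode!r}")
        if self.panel not in (*PLATFORMS, "both"):
            raise ValueError(f"{self.cpg_id}: unknown panel {self.panel!r}")


@dataclass
class MethylationMatrix:
    """CpG x sample beta values with platform panel membership."""

    values: pd.DataFrame          # index: cpg_id, columns: individual_id
    panel: pd.Series              # cpg_id -> P450K | PEPIC | both

    def for_platform(self, cohort: TwinCohort, platform: str) -> pd.DataFrame:
        """Beta values observed on one platform: its samples x its panel."""
        if platform not in PLATFORMS:
            raise ValueError(f"unknown platform {platform!r}")
        cpgs = self.panel[(self.panel == platform) | (self.panel == "both")].index
        ids = cohort.samples.loc[cohort.samples.platform == platform,
                                 "individual_id"]
        return self.values.loc[cpgs, list(ids)]

    def write_tsv(self, values_path, panel_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="cpg_id")
        self.panel.rename("panel").to_csv(panel_path, sep="\t",
                                          index_label="cpg_id")


@dataclass
class GroundTruth:
    """Per-CpG generating parameters; reproducible from (config, seed)."""

    specs: pd.DataFrame           # one row per CpgSpec
    clamp_fraction: pd.Series     # cpg_id -> fraction of values clamped

    def write_tsv(self, path) -> None:
        out = self.specs.copy()
        out["clamp_fraction"] = self.clamp_fraction.values
        out.to_csv(path, sep="\t", index=False)


def _familial_normal(rng: np.random.Generator, samples: pd.DataFrame,
                     r_mz: float, r_dz: float) -> np.ndarray:
    """Standard-normal deviates with within-pair correlation r by zygosity."""
    fam_codes, fam_index = pd.factorize(samples.family_id)
    nf = len(fam_index)
    z_fam = rng.standard_normal(nf)
    z_ind = rng.standard_normal(len(samples))
    r = np.where(samples.zygosity.values == "MZ", r_mz, r_dz)
    first = samples.twin_order.values == 1
    out = np.where(first, z_fam[fam_codes],
                   r * z_fam[fam_codes] + np.sqrt(1.0 - r ** 2) * z_ind)
    return out


def generate_methylation(cohort: TwinCohort, specs, truth_out: bool = False,
                         seed: int = 0):
    """Generate the CpG x sample beta matrix (optionally with ground truth).

    The RNG is split per CpG from a single seed sequence, so extending the
    spec list never perturbs the values generated for earlier CpGs.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("specs must be nonempty")
    if cohort.n == 0:
        raise ValueError("cohort must be nonempty")
    for s in specs:
        s.validate()
    samples = cohort.samples
    children = np.random.SeedSequence([int(seed), 0x2A11]).spawn(len(specs))
    is_f = (samples.sex.values == "F").astype(float)
    age_c = samples.age_at_sampling.values - samples.age_at_sampling.mean()
    rows = np.empty((len(specs), len(samples)))
    clamp_frac = np.empty(len(specs))
    for j, (spec, ss) in enumerate(zip(specs, children)):
        rng = np.random.default_rng(ss)
        g = _familial_normal(rng, samples, 1.0, 0.5)
        c = _familial_normal(rng, samples, 1.0, 1.0)
        d = _familial_normal(rng, samples, 1.0, 0.25)
        e = rng.standard_normal(len(samples))
        m = spec.baseline_mean + spec.total_sd * (
            np.sqrt(spec.a2) * g + np.sqrt(spec.c2) * c
            + np.sqrt(spec.d2) * d + np.sqrt(spec.e2) * e)
        if spec.linkage_mode == "causal_individual":
            m = m + spec.linkage_beta * samples.phenotype.values
        elif spec.linkage_mode == "family_confounded":
            m = m + spec.linkage_beta * samples.latent_c.values
        elif spec.linkage_mode == "genetic_confounded":
            m = m + spec.linkage_beta * samples.latent_g.values
        m = m + spec.sex_mean_shift * is_f + spec.age_beta * age_c
        clamped = (m < 0.001) | (m > 0.999)
        clamp_frac[j] = clamped.mean()
        rows[j] = np.clip(m, 0.001, 0.999)
    if (clamp_frac > 0.01).any():
        worst = specs[int(np.argmax(clamp_frac))].cpg_id
        warnings.warn(
            f"clamping affected >1% of values for some CpGs (worst: {worst}, "
            f"{clamp_frac.max():.1%})", ClampWarning)
    values = pd.DataFrame(rows, index=[s.cpg_id for s in specs],
                          columns=samples.individual_id.values)
    panel = pd.Series({s.cpg_id: s.panel for s in specs})
    mat = MethylationMatrix(values=values, panel=panel)
    if truth_out:
        truth = GroundTruth(
            specs=pd.DataFrame([vars(s) for s in specs]),
            clamp_fraction=pd.Series(clamp_frac, index=values.index))
        return mat, truth
    return mat


def make_cpg_specs(n_null: int, n_causal: int = 0, causal_beta: float = 0.01,
                   a2: float | None = None, c2: float = 0.05,
                   total_sd: float = 0.05, baseline: float = 0.5,
                   seed: int = 0) -> list[CpgSpec]:
    """Convenience spec builder: null CpGs plus individually causal spikes.

    With ``a2 = None`` each CpG draws its heritability uniformly from
    [0.2, 0.8], emulating the wide per-CpG heritability range of blood
    methylation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5BEC]))
    specs = []
    for i in range(n_null + n_causal):
        mode = "causal_individual" if i < n_causal else "null"
        beta = causal_beta if i < n_causal else 0.0
        a2_i = float(rng.uniform(0.2, 0.8)) if a2 is None else a2
        e2_i = 1.0 - a2_i - c2
        specs.append(CpgSpec(
            cpg_id=f"cg{i:07d}",
            baseline_mean=float(np.clip(rng.normal(baseline, 0.1), 0.1, 0.9)),
            a2=a2_i, c2=c2, e2=e2_i, total_sd=total_sd,
            linkage_mode=mode, linkage_beta=beta))
    return specs


# ---------------------------------------------------------------------------
# questionnaires

def generate_questionnaires(cohort: TwinCohort, seed: int = 0,
                            female_shift: float = 1.0):
    """Ordinal puberty items at two waves plus censored pubertal-age reports.

    Item codes are threshold cuts of a noisy copy of the latent timing
    phenotype, so a higher liability yields more advanced codes. Menarche is
    binary {1, 4} and facial hair {1, 2, 3} at both waves; the other four
    items run 1-3 at wave 12 and 1-4 at wave 14. Pubertal-age reports are
    right-censored at the report age ("not_yet").

    Returns (pds_items, pa_reports) DataFrames. PDS items are produced only
    for the younger cohort, emulating the wave structure of the study sample.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9D5]))
    s = cohort.samples
    young = s[s.cohort == "FT12"]
    t = young.phenotype.values

    def ordinal(latent, cuts):
        return 1 + np.searchsorted(cuts, latent).astype(int)

    items = []
    for wave, base, n_levels in ((12, -0.4, 3), (14, 1.2, 4)):
        dev = base + t  # development level at the wave
        cuts3, cuts4 = np.array([0.0, 1.1]), np.array([0.0, 0.9, 1.9])
        cuts = cuts3 if n_levels == 3 else cuts4
        noise = lambda: rng.normal(0, 0.7, len(young))  # noqa: E731
        rec = pd.DataFrame({
            "individual_id": young.individual_id.values,
            "sex": young.sex.values,
            "wave": wave,
            "growth_spurt": ordinal(dev + noise(), cuts),
            "body_hair": ordinal(dev + noise(), cuts),
            "skin_changes": ordinal(dev + noise(), cuts),
            "breast_or_voice": ordinal(dev + noise(), cuts),
        })
        mf = np.where(
            young.sex.values == "F",
            np.where(dev + noise() > 0.8, 4, 1),          # menarche {1,4}
            ordinal(dev + noise(), cuts3))                 # facial hair 1-3
        rec["menarche_or_facial_hair"] = mf
        items.append(rec)
    pds_items = pd.concat(items, ignore_index=True)

    # pubertal age, censored at the report age
    report_age = np.where(s.cohort.values == "FT12", 17.6, 16.2)
    # sex-free liability: the phenotype column already carries the female
    # shift (pass the generating CohortConfig.phenotype_female_shift here)
    liability = s.phenotype.values - (s.sex.values == "F") * female_shift
    event = (13.9 - 1.15 * (s.sex.values == "F")
             - 0.9 * liability + rng.normal(0, 0.5, cohort.n))
    event = np.clip(event, 8.5, None)
    not_yet = event >= report_age
    pa_reports = pd.DataFrame({
        "individual_id": s.individual_id.values,
        "sex": s.sex.values,
        "report_age": np.round(report_age, 2),
        "event_age": np.where(not_yet, np.nan, np.round(event, 2)),
        "not_yet": not_yet,
    })
    return pds_items, pa_reports


# ---------------------------------------------------------------------------
# meQTL table

@dataclass
class SnpConfig:
    """Layout of the synthetic meQTL association table.

    ``causal`` maps cpg_id -> number of causal variants; every CpG in the
    table is tested against ``n_snps_per_cpg`` SNPs in total. Effects are in
    residual-SD units per effect allele.
    """

    n_snps_per_cpg: int = 50
    causal: dict = field(default_factory=dict)
    effect_size: float = 0.5
    maf_range: tuple[float, float] = (0.1, 0.5)

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range must lie in (0, 1), got {self.maf_range}")
        if self.n_snps_per_cpg < 1:
            raise ValueError("n_snps_per_cpg must be >= 1")


def _family_genotypes(rng, pairs: pd.DataFrame, maf: float) -> dict:
    """Per-individual allele counts; MZ identical, DZ by parental transmission."""
    nf = len(pairs)
    mom = rng.random((nf, 2)) < maf
    dad = rng.random((nf, 2)) < maf
    pick = rng.integers(0, 2, (nf, 4))  # transmissions for twin1, twin2
    g1 = (mom[np.arange(nf), pick[:, 0]].astype(int)
          + dad[np.arange(nf), pick[:, 1]].astype(int))
    g2_dz = (mom[np.arange(nf), pick[:, 2]].astype(int)
             + dad[np.arange(nf), pick[:, 3]].astype(int))
    mz = pairs.zygosity.values == "MZ"
    g2 = np.where(mz, g1, g2_dz)
    out = {}
    for i, row in enumerate(pairs.itertuples()):
        out[row.id1] = g1[i]
        out[row.id2] = g2[i]
    return out


def generate_meqtl_table(cohort: TwinCohort, specs, snp_config: SnpConfig,
                         seed: int = 0) -> pd.DataFrame:
    """Synthetic SNP-CpG association table emulating a consortium export.

    For each CpG a methylation-like trait is drawn as the sum of its
    configured causal SNP effects plus unit noise; every SNP assigned to the
    CpG is then tested by OLS in one twin per family (avoiding familial
    pseudo-replication), yielding rows (snp_id, chrom, pos, cpg_id,
    cis_trans, p, beta). Genotypes respect twin sharing: MZ cotwins carry
    identical genotypes, DZ cotwins draw independent parental transmissions.
    """
    from scipy import stats

    snp_config.validate()
    specs = list(specs)
    pairs = cohort.pairs
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD0C]))
    # association sample: first twin of every family (complete or not)
    first = cohort.samples[cohort.samples.twin_order == 1]
    test_ids = list(first.individual_id)
    n = len(test_ids)
    records = []
    for spec in specs:
        k = snp_config.n_snps_per_cpg
        n_causal = int(snp_config.causal.get(spec.cpg_id, 0))
        if n_causal > k:
            raise ValueError(f"{spec.cpg_id}: more causal SNPs than SNPs")
        genos = np.empty((n, k))
        mafs = rng.uniform(*snp_config.maf_range, k)
        for j in range(k):
            gmap = _family_genotypes(rng, pairs, mafs[j])
            # singletons (twin_order==1 without a pair row) draw HWE genotypes
            genos[:, j] = [
                gmap.get(i, (rng.random() < mafs[j]) + (rng.random() < mafs[j]))
                for i in test_ids]
        y = rng.standard_normal(n)
        for j in range(n_causal):
            sd = max(genos[:, j].std(), 1e-9)
            y = y + snp_config.effect_size * (genos[:, j] - genos[:, j].mean()) / sd
        # per-SNP OLS slope tests via the correlation identity
        gc = genos - genos.mean(axis=0)
        gss = (gc ** 2).sum(axis=0)
        yc = y - y.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = gc.T @ yc / gss
            r = gc.T @ yc / np.sqrt(gss * (yc ** 2).sum())
            r = np.clip(r, -0.999999, 0.999999)
            tstat = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
        p = np.where(np.isfinite(p), p, 1.0)
        for j in range(k):
            records.append({
                "snp_id": f"rs_{spec.cpg_id}_{j:04d}",
                "chrom": int(rng.integers(1, 23)),
                "pos": int(rng.integers(1, 2 ** 27)),
                "cpg_id": spec.cpg_id,
                "cis_trans": "cis" if (j < n_causal or rng.random() < 0.8)
                             else "trans",
                "p": float(max(p[j], 5e-324)),
                "beta": float(slope[j]) if np.isfinite(slope[j]) else 0.0,
            })
    return pd.DataFrame.from_records(records)
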