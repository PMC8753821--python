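"""Synthetic genotype + QST cohort generation.

Emulates a recall-by-genotype sampling frame over five biallelic SNPs in a
nociceptor channel gene: Hardy-Weinberg genotypes at the stated minor-allele
frequencies, two pairs of loci in linkage disequilibrium (one moderate, one
complete), imputation-certainty eligibility screening, recall of major-allele
homozygotes as controls and minor-allele homozygotes as the sequential test
groups, telephone-screen exclusions, and quantitative-sensory-testing
phenotypes around a heat-pain-threshold endpoint distributed N(42, 2.5^2)
degrees C with configurable group effects.

The generator exists so every stage of the design engine can be exercised end
to end with no access to the underlying cohort; it makes no attempt to model
genome-wide structure, realistic QST covariance beyond a single shared
factor, or the physiology of sensitization beyond a mean shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InfeasibleLDError,
    InsufficientPoolError,
    InvalidParameterError,
)

__all__ = [
    "SNPSpec",
    "LDPair",
    "TRPA1_SNPS",
    "TRPA1_LD_PAIRS",
    "DEFAULT_EXCLUSION_PREVALENCES",
    "haplotype_freqs",
    "sample_genotypes",
    "recall_sample",
    "generate_qst",
    "screen_exclusions",
    "synthesize_cohort",
    "write_vcf",
]


@dataclass(frozen=True)
class SNPSpec:
    """A biallelic locus: rsid, minor-allele frequency, allele-group index.

    ``group`` is the sequential test group the minor-allele homozygotes feed
    (1-3); every SNP also contributes to the control definition (controls are
    major-homozygous at all loci).
    """

    rsid: str
    maf: float
    group: int
    major_allele: str = "N"
    minor_allele: str = "n"

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise InvalidParameterError(
                f"{self.rsid}: maf must be in (0, 0.5], got {self.maf}"
            )


@dataclass(frozen=True)
class LDPair:
    """Pairwise linkage constraint between two loci.

    ``sign`` is the phase convention: +1 associates the two minor alleles on
    the same haplotype, -1 puts them in repulsion.
    """

    snp_a: str
    snp_b: str
    r2: float
    sign: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.r2 <= 1:
            raise InvalidParameterError(f"r2 must be in [0, 1], got {self.r2}")
        if self.sign not in (-1, 1):
            raise InvalidParameterError("sign must be +1 or -1")


#: The five-SNP recall panel: allele-group 1 is the common-variant group,
#: groups 2 and 3 are each defined by a pair of linked loci.
TRPA1_SNPS: tuple[SNPSpec, ...] = (
    SNPSpec("rs7819749", 0.40, 1, "G", "T"),
    SNPSpec("rs920829", 0.10, 2, "C", "T"),
    SNPSpec("rs959976", 0.16, 2, "T", "C"),
    SNPSpec("rs16937976", 0.15, 3, "C", "G"),
    SNPSpec("rs13268757", 0.15, 3, "G", "A"),
)

TRPA1_LD_PAIRS: tuple[LDPair, ...] = (
    LDPair("rs920829", "rs959976", 0.51),
    LDPair("rs16937976", "rs13268757", 1.0),
)

#: Telephone-screen exclusion criteria with default population prevalences
#: (plausible rates for a healthy young-adult cohort; each criterion is an
#: independent Bernoulli flag).
DEFAULT_EXCLUSION_PREVALENCES: dict[str, float] = {
    "neurological_disorder": 0.02,
    "regular_analgesics": 0.05,
    "recent_analgesics": 0.10,
    "pregnancy": 0.02,
    "pain_condition": 0.05,
    "severe_anxiety_depression": 0.05,
    "allergy": 0.02,
    "recreational_drugs": 0.05,
}

#: Secondary QST endpoints: (mean, SD) on their native scales. Values are
#: round numbers in the range reported for healthy-adult normative QST data;
#: only the heat pain threshold enters the design mathematics.
DEFAULT_QST_ENDPOINTS: dict[str, tuple[float, float]] = {
    "cdt": (30.0, 1.5),   # cool detection threshold, deg C
    "wdt": (34.5, 1.5),   # warm detection threshold, deg C
    "cpt": (10.0, 8.0),   # cold pain threshold, deg C
    "mdt": (4.0, 2.0),    # mechanical detection threshold, mN
    "mpt": (64.0, 30.0),  # mechanical pain threshold, mN
    "ppt": (350.0, 120.0),  # pressure pain threshold, kPa
}


def haplotype_freqs(
    maf_a: float, maf_b: float, r2: float, sign: int = 1
) -> np.ndarray:
    """Two-locus haplotype frequencies implied by MAFs and r-squared.

    Returns frequencies in order (minor-minor, minor-major, major-minor,
    major-major). The disequilibrium coefficient is
    ``D = sign * sqrt(r2 * pa*(1-pa) * pb*(1-pb))``.

    Raises
    ------
    InfeasibleLDError
        If any implied frequency falls outside [0, 1]; the message names the
        largest feasible r-squared (the Frechet bound) for the pair.
    """
    for name, p in (("maf_a", maf_a), ("maf_b", maf_b)):
        if not 0 < p <= 0.5:
            raise InvalidParameterError(f"{name} must be in (0, 0.5], got {p}")
    if not 0 <= r2 <= 1:
        raise InvalidParameterError(f"r2 must be in [0, 1], got {r2}")
    if sign not in (-1, 1):
        raise InvalidParameterError("sign must be +1 or -1")
    d_coef = sign * np.sqrt(r2 * maf_a * (1 - maf_a) * maf_b * (1 - maf_b))
    freqs = np.array(
        [
            maf_a * maf_b + d_coef,
            maf_a * (1 - maf_b) - d_coef,
            (1 - maf_a) * maf_b - d_coef,
            (1 - maf_a) * (1 - maf_b) + d_coef,
        ]
    )
    if np.any(freqs < -1e-12) or np.any(freqs > 1 + 1e-12):
        if sign > 0:
            d_max = min(maf_a * (1 - maf_b), maf_b * (1 - maf_a))
        else:
            d_max = min(maf_a * maf_b, (1 - maf_a) * (1 - maf_b))
        r2_max = d_max**2 / (maf_a * (1 - maf_a) * maf_b * (1 - maf_b))
        raise InfeasibleLDError(
            f"r2 = {r2} infeasible for MAFs ({maf_a}, {maf_b}); the Frechet "
            f"bound allows r2 <= {r2_max:.4f}"
        )
    freqs = np.clip(freqs, 0.0, 1.0)
    return freqs / freqs.sum()


def _certainty(
    rng: np.random.Generator, size: tuple[int, ...], scale: float
) -> np.ndarray:
    """Imputation-certainty draws: 1 minus an exponential tail, capped at 1."""
    return np.clip(1.0 - rng.exponential(scale, size=size), 0.0, 1.0)


def sample_genotypes(
    n: int,
    snp_specs: Sequence[SNPSpec] = TRPA1_SNPS,
    ld_pairs: Sequence[LDPair] = TRPA1_LD_PAIRS,
    seed: int | np.random.Generator = 0,
    certainty_scale: float = 0.002,
) -> pd.DataFrame:
    """Hardy-Weinberg genotypes (minor-allele dosages) for ``n`` individuals.

    Loci in an LD pair are generated by drawing two haplotypes per individual
    from :func:`haplotype_freqs`; unpaired loci are independent
    Binomial(2, maf) dosages. Each genotype carries an imputation certainty
    ``imputation_prob_<rsid>`` drawn from a high-certainty distribution
    (default: about 0.7% of calls fall below the 0.99 eligibility bar).
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    by_rsid = {s.rsid: s for s in snp_specs}
    paired: set[str] = set()
    data: dict[str, np.ndarray] = {}
    for pair in ld_pairs:
        a, b = by_rsid[pair.snp_a], by_rsid[pair.snp_b]
        freqs = haplotype_freqs(a.maf, b.maf, pair.r2, pair.sign)
        # haplotype index -> (carries minor at a, carries minor at b)
        minor_a = np.array([1, 1, 0, 0])
        minor_b = np.array([1, 0, 1, 0])
        haps = rng.choice(4, size=(n, 2), p=freqs)
        data[a.rsid] = minor_a[haps].sum(axis=1)
        data[b.rsid] = minor_b[haps].sum(axis=1)
        paired |= {a.rsid, b.rsid}
    for spec in snp_specs:
        if spec.rsid not in paired:
            data[spec.rsid] = rng.binomial(2, spec.maf, size=n)
    df = pd.DataFrame(
        {f"dosage_{s.rsid}": data[s.rsid] for s in snp_specs},
        index=pd.RangeIndex(n),
    )
    for spec in snp_specs:
        df[f"imputation_prob_{spec.rsid}"] = _certainty(
            rng, (n,), certainty_scale
        )
    df.insert(0, "participant_id", [f"P{i:07d}" for i in range(n)])
    return df


def _eligible_mask(
    genotypes: pd.DataFrame,
    snp_specs: Sequence[SNPSpec],
    threshold: float = 0.99,
) -> np.ndarray:
    cols = [f"imputation_prob_{s.rsid}" for s in snp_specs]
    return (genotypes[cols] > threshold).all(axis=1).to_numpy()


def recall_sample(
    genotypes: pd.DataFrame,
    group_sizes: Mapping[str, int],
    seed: int | np.random.Generator = 0,
    snp_specs: Sequence[SNPSpec] = TRPA1_SNPS,
    certainty_threshold: float = 0.99,
) -> pd.DataFrame:
    """Select recall groups from a genotyped pool.

    Eligibility requires imputation certainty above ``certainty_threshold``
    at every locus. Controls are major-allele homozygotes (dosage 0) at all
    loci; test group k requires minor-allele homozygosity (dosage 2) at every
    locus assigned to group k, leaving the other loci unconstrained.
    Selection within each pool is uniform without replacement.

    ``group_sizes`` maps 'control' / 'group1' / 'group2' / 'group3' to the
    requested counts. Returns the genotype rows of the recalled participants
    with ``recall_group`` and ``eligible`` columns added.

    Raises
    ------
    InsufficientPoolError
        If a pool is smaller than its request; the message reports the pool
        size and the analytically expected yield.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    eligible = _eligible_mask(genotypes, snp_specs, certainty_threshold)
    dosage_cols = [f"dosage_{s.rsid}" for s in snp_specs]
    dosages = genotypes[dosage_cols].to_numpy()

    pools: dict[str, np.ndarray] = {
        "control": eligible & (dosages == 0).all(axis=1)
    }
    groups = sorted({s.group for s in snp_specs})
    for g in groups:
        idx = [i for i, s in enumerate(snp_specs) if s.group == g]
        pools[f"group{g}"] = eligible & (dosages[:, idx] == 2).all(axis=1)

    expected = _expected_pool_fractions(snp_specs)
    taken: list[pd.DataFrame] = []
    used = np.zeros(len(genotypes), dtype=bool)
    for name, size in group_sizes.items():
        if name not in pools:
            raise InvalidParameterError(f"unknown recall group {name!r}")
        avail = np.flatnonzero(pools[name] & ~used)
        if avail.size < size:
            raise InsufficientPoolError(
                f"{name}: requested {size} but only {avail.size} eligible "
                f"{name} homozygotes in a pool of {len(genotypes)} (expected "
                f"yield ~ {expected[name] * len(genotypes):.1f})"
            )
        chosen = rng.choice(avail, size=size, replace=False)
        used[chosen] = True
        block = genotypes.iloc[np.sort(chosen)].copy()
        block["recall_group"] = name
        taken.append(block)
    out = pd.concat(taken, ignore_index=True)
    out["eligible"] = True
    return out


def _expected_pool_fractions(
    snp_specs: Sequence[SNPSpec],
    ld_pairs: Sequence[LDPair] = TRPA1_LD_PAIRS,
) -> dict[str, float]:
    """Analytic Hardy-Weinberg expectations for each recall pool.

    Control expectation treats loci as independent (an understatement when
    loci are in coupling LD, so it is a conservative yield figure); group
    expectations use the minor-minor haplotype frequency for linked pairs.
    """
    by_rsid = {s.rsid: s for s in snp_specs}
    out = {"control": float(np.prod([(1 - s.maf) ** 2 for s in snp_specs]))}
    pair_of = {p.snp_a: p for p in ld_pairs} | {p.snp_b: p for p in ld_pairs}
    for g in sorted({s.group for s in snp_specs}):
        members = [s for s in snp_specs if s.group == g]
        if len(members) == 1:
            out[f"group{g}"] = members[0].maf ** 2
        else:
            pair = pair_of.get(members[0].rsid)
            if pair is not None:
                a, b = by_rsid[pair.snp_a], by_rsid[pair.snp_b]
                h_mm = haplotype_freqs(a.maf, b.maf, pair.r2, pair.sign)[0]
                out[f"group{g}"] = float(h_mm**2)
            else:
                out[f"group{g}"] = float(
                    np.prod([s.maf**2 for s in members])
                )
    return out


@dataclass(frozen=True)
class QstNoiseConfig:
    """Phenotype-model parameters.

    ``hpt_mean``/``hpt_sd`` set the baseline heat-pain-threshold
    distribution; ``sensitization_shift`` is the mean change after topical
    sensitization (negative: hyperalgesia); ``baseline_post_corr`` is the
    within-subject correlation between baseline and post-sensitization HPT
    (both margins keep SD ``hpt_sd``); ``factor_loading`` is the shared
    loading of the secondary endpoints on one subject-level factor.
    """

    hpt_mean: float = 42.0
    hpt_sd: float = 2.5
    sensitization_shift: float = -3.0
    baseline_post_corr: float = 0.7
    factor_loading: float = 0.4
    endpoints: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_QST_ENDPOINTS)
    )
    censor_at_50c: bool = False


def generate_qst(
    cohort: pd.DataFrame,
    effect_map: Mapping[str, float] | None = None,
    noise: QstNoiseConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Attach QST phenotypes to a labelled recall cohort.

    ``effect_map`` gives each recall group's mean shift (degrees C, additive)
    of the post-sensitization heat pain threshold relative to control; groups
    not listed get 0. Baseline HPT is N(hpt_mean, hpt_sd^2); the
    post-sensitization value shares the subject effect with correlation
    ``baseline_post_corr`` and keeps the same SD, so a two-group comparison
    of the post endpoint sees exactly the configured effect against SD
    ``hpt_sd``. Secondary endpoints load on a single common subject factor;
    the sensitization pain rating is an integer 0-10.
    """
    if "recall_group" not in cohort.columns:
        raise InvalidParameterError("cohort must carry a recall_group column")
    noise = noise or QstNoiseConfig()
    effect_map = dict(effect_map or {})
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = len(cohort)
    rho = noise.baseline_post_corr
    u = rng.normal(0.0, 1.0, n)  # subject effect, shared across time points
    e = rng.normal(0.0, 1.0, n)
    shift = (
        cohort["recall_group"].map(lambda g: effect_map.get(g, 0.0)).to_numpy()
    )
    out = cohort.copy()
    out["hpt_baseline"] = noise.hpt_mean + noise.hpt_sd * u
    out["hpt_post"] = (
        noise.hpt_mean
        + noise.sensitization_shift
        + shift
        + noise.hpt_sd * (rho * u + np.sqrt(1 - rho**2) * e)
    )
    if noise.censor_at_50c:
        out["hpt_baseline"] = out["hpt_baseline"].clip(upper=50.0)
        out["hpt_post"] = out["hpt_post"].clip(upper=50.0)
    lam = noise.factor_loading
    f = rng.normal(0.0, 1.0, n)
    for name, (mean, sd) in noise.endpoints.items():
        eps = rng.normal(0.0, 1.0, n)
        vals = mean + sd * (lam * f + np.sqrt(1 - lam**2) * eps)
        out[f"{name}_baseline"] = vals
        out[f"{name}_post"] = vals + sd * 0.3 * rng.normal(0.0, 1.0, n)
    out["cinnamaldehyde_pain"] = np.clip(
        np.rint(rng.normal(5.0, 2.0, n)), 0, 10
    ).astype(int)
    return out


def screen_exclusions(
    records: pd.DataFrame,
    prevalences: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply independent Bernoulli telephone-screen exclusions.

    Returns the retained records and a per-criterion count of exclusion
    flags (a record can trip several criteria; it is dropped if it trips
    any).
    """
    prevalences = dict(
        DEFAULT_EXCLUSION_PREVALENCES if prevalences is None else prevalences
    )
    for name, p in prevalences.items():
        if not 0 <= p <= 1:
            raise InvalidParameterError(f"{name}: prevalence must be in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = len(records)
    flags = pd.DataFrame(
        {
            f"excl_{name}": rng.random(n) < p
            for name, p in prevalences.items()
        },
        index=records.index,
    )
    keep = ~flags.any(axis=1)
    counts = flags.sum(axis=0)
    counts.index = [c.removeprefix("excl_") for c in counts.index]
    return records.loc[keep].copy(), counts


def synthesize_cohort(
    pool_size: int = 200_000,
    group_sizes: Mapping[str, int] | None = None,
    effect_map: Mapping[str, float] | None = None,
    noise: QstNoiseConfig | None = None,
    prevalences: Mapping[str, float] | None = None,
    seed: int = 0,
    snp_specs: Sequence[SNPSpec] = TRPA1_SNPS,
    ld_pairs: Sequence[LDPair] = TRPA1_LD_PAIRS,
) -> pd.DataFrame:
    """End-to-end cohort: genotype pool -> recall -> screening -> QST.

    The default pool of 200,000 comfortably yields the default request of 50
    controls and 15 per test group (the rarest pool, the moderately linked
    pair's double homozygotes, runs at about 0.9% of the genotyped sample).
    Screening is applied *before* group selection so the requested group
    sizes are the sizes that reach testing.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    group_sizes = dict(
        group_sizes or {"control": 50, "group1": 15, "group2": 15, "group3": 15}
    )
    genotypes = sample_genotypes(pool_size, snp_specs, ld_pairs, rng)
    screened, _ = screen_exclusions(genotypes, prevalences, rng)
    cohort = recall_sample(screened, group_sizes, rng, snp_specs)
    return generate_qst(cohort, effect_map, noise, rng)


def write_vcf(
    genotypes: pd.DataFrame,
    path: str | Path,
    snp_specs: Sequence[SNPSpec] = TRPA1_SNPS,
) -> None:
    """Write the five-SNP genotypes as a minimal VCFv4.2 text file.

    Sites are unphased diploid GT calls with the rsid as ID; placeholder
    chromosome/position coordinates are used (the panel is defined by rsid,
    not by build coordinates, in this synthetic setting).
    """
    path = Path(path)
    samples = genotypes["participant_id"].tolist()
    lines = [
        "##fileformat=VCFv4.2",
        "##source=rbgdesign-synthetic-cohort",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    for pos, spec in enumerate(snp_specs, start=1):
        dosages = genotypes[f"dosage_{spec.rsid}"].to_numpy()
        calls = "\t".join(gt_code[int(d)] for d in dosages)
        lines.append(
            f"8\t{pos * 1000}\t{spec.rsid}\t{spec.major_allele}\t"
            f"{spec.minor_allele}\t.\tPASS\t.\tGT\t{calls}"
        )
    path.write_text("\n".join(lines) + "\n")
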