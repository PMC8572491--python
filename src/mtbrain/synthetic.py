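"""Seedable synthetic cohorts with the statistical structure of an aged-brain
mtDNA study.

Every downstream stage of the pipeline (coverage-based copy-number
estimation, heteroplasmy calling, deconvolution, proteomic scoring, the
association stack) can be exercised on the output of this module without any
external data.  The generator emulates:

* cohort marginals of an aged autopsy series (age ~ 89 +/- 7 years, ten
  correlated neuropathologies with realistic stage prevalences, cognition);
* a latent mitochondrial DNA copy number depending linearly on tau burden
  and neuronal proportion, with optional APOE-e4 (mediated + direct) and
  SNP-dosage paths;
* heteroplasmic mtDNA mutations accumulating at ~1.6 %/year, concentrated
  in the D-loop, with allele fractions in the detectable 3-90 % band, plus
  planted homoplasmies, NUMT-like artifacts and low-level contamination;
* per-base WGS coverage over toy contigs (2 x 10 kb autosomes, 16,569 bp
  MT) such that the coverage-ratio estimator recovers the latent copy
  number;
* marker-structured bulk expression mixtures of five brain cell types and
  mitochondrial-marker protein profiles.

All outputs are deterministic given a `numpy.random.Generator`; truth tables
for every planted quantity are emitted alongside the observable data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .heteroplasmy import ALLELE_COLUMNS, BASES, CONTROL_REGION, MT_LENGTH

__all__ = [
    "GenerativeParams",
    "REGIONS",
    "generate_cohort",
    "generate_coverage",
    "generate_pileup",
    "make_shifted_pileup",
    "draw_heteroplasmy_counts",
    "generate_expression",
    "generate_proteomics",
    "mediation_scenario",
    "snp_scenario",
    "burden_scenario",
    "reference_base",
]

# Region presets: (n, age mean, age SD, censored ages, burden mean, male frac)
REGIONS: Mapping[str, tuple] = {
    "DLPFC": (454, 89.3, 6.6, False, 2.7, 0.348),
    "PCC": (66, 89.1, 5.6, False, 2.7, 0.318),
    "CB": (242, 88.0, 6.7, False, 1.0, 0.293),
    "TCX": (262, 82.0, 8.0, True, 2.6, 0.45),
    "FP": (337, 84.0, 8.0, True, 2.8, 0.40),
}

# Ordinal stage prevalences (cortical defaults): TDP-43, Lewy bodies, CAA,
# atherosclerosis, arteriolosclerosis each staged 0..3; then binary gross
# infarcts, microinfarcts, hippocampal sclerosis.
STAGE_PREVALENCES: Mapping[str, Sequence[float]] = {
    "tdp43": (0.486, 0.180, 0.230, 0.104),
    "lewy": (0.773, 0.016, 0.073, 0.138),
    "caa": (0.207, 0.429, 0.247, 0.117),
    "atherosclerosis": (0.186, 0.469, 0.272, 0.073),
    "arteriolosclerosis": (0.300, 0.347, 0.260, 0.093),
}
BINARY_PREVALENCES: Mapping[str, float] = {
    "gross_infarcts": 0.377,
    "microinfarcts": 0.291,
    "hippocampal_sclerosis": 0.087,
}

#: order of the latent Gaussian-copula dimensions behind the pathologies
_COPULA_VARS = (
    "amyloid", "tau", "tdp43", "lewy", "caa",
    "atherosclerosis", "arteriolosclerosis",
    "gross_infarcts", "microinfarcts", "hippocampal_sclerosis",
)


def _default_pathology_corr() -> np.ndarray:
    k = len(_COPULA_VARS)
    R = np.full((k, k), 0.10)
    np.fill_diagonal(R, 1.0)
    idx = {v: i for i, v in enumerate(_COPULA_VARS)}
    for a, b, r in [
        ("amyloid", "tau", 0.55),
        ("amyloid", "caa", 0.35),
        ("tau", "tdp43", 0.25),
        ("tdp43", "hippocampal_sclerosis", 0.35),
        ("atherosclerosis", "arteriolosclerosis", 0.30),
        ("gross_infarcts", "microinfarcts", 0.25),
    ]:
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return R


@dataclass
class GenerativeParams:
    """All knobs of the synthetic cohort; defaults emulate the DLPFC series."""

    region: str = "DLPFC"
    n: int = 454
    age_mean: float = 89.3
    age_sd: float = 6.6
    age_censored: bool = False  # emit 5-year stratum midpoints, open top > 95
    male_fraction: float = 0.348
    education_mean: float = 16.0
    education_sd: float = 3.5

    # pathology marginals (sqrt-%-area scale chosen to match the target
    # mean/SD of 4.6 (4.4) for amyloid and 7.4 (8.1) for tau on the raw scale)
    amyloid_sqrt_mean: float = 1.841
    amyloid_sqrt_sd: float = 1.101
    tau_sqrt_mean: float = 2.166
    tau_sqrt_sd: float = 1.646
    pathology_corr: np.ndarray = field(default_factory=_default_pathology_corr)

    # effect sizes on the standardized latent log-mtDNAcn (SD units)
    tau_effect: float = -0.30
    neuron_effect: float = 0.30
    snp_effect: float = 0.0
    apoe_a: float = 0.5        # e4 dosage -> AD-pathology latent, per dosage
    apoe_b: float = -0.32      # AD-pathology latent -> mtDNAcn, per SD
    apoe_c_prime: float = -0.204  # direct e4 -> mtDNAcn, per dosage
    apoe_dosage_probs: tuple[float, float, float] = (335 / 454, 112 / 454, 7 / 454)
    snp_allele_freq: float = 0.20
    mtdnacn_noise_sd: float = 0.85

    # raw copy-number scale (copies per diploid genome, log-normal)
    mtdnacn_baseline: float = 2000.0
    mtdnacn_log_sd: float = 0.25

    # cognition latent
    cognition_tau_effect: float = -0.40
    cognition_mtdnacn_effect: float = 0.20
    cognition_noise_sd: float = 0.80

    # heteroplasmy burden: count ~ Poisson(burden_mean * exp(age_rate*(age - age_mean)))
    burden_mean: float = 2.7
    age_rate: float = math.log(1.016)
    dloop_weight: float = 0.6
    af_alpha: float = 1.2
    af_beta: float = 8.0
    min_af: float = 0.03
    max_af: float = 0.90
    indel_fraction: float = 0.15
    n_homoplasmies: int = 2
    n_numt_artifacts: int = 1
    contamination: float = 0.0

    # coverage
    cov_nuc_target: float = 30.0
    coverage_noise: float = 1.0   # 0 disables sampling noise entirely
    coverage_dispersion: float = 100.0  # negative-binomial size parameter
    autosome_sizes: tuple[int, ...] = (10_000, 10_000)
    mask_fraction: float = 0.10

    @classmethod
    def for_region(cls, region: str, **overrides) -> "GenerativeParams":
        n, am, asd, cens, burden, male = REGIONS[region]
        base = cls(
            region=region, n=n, age_mean=am, age_sd=asd, age_censored=cens,
            burden_mean=burden, male_fraction=male,
        )
        return replace(base, **overrides) if overrides else base

    def validate(self) -> None:
        R = np.asarray(self.pathology_corr, dtype=float)
        if R.shape != (len(_COPULA_VARS),) * 2:
            raise ValueError(f"pathology_corr must be {len(_COPULA_VARS)}x{len(_COPULA_VARS)}")
        if not np.allclose(R, R.T):
            raise ValueError("pathology_corr must be symmetric")
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-10:
            raise ValueError(
                f"pathology_corr is not positive semi-definite (min eigenvalue {eig.min():.3g})"
            )
        for name in ("age_sd", "mtdnacn_noise_sd", "burden_mean", "cov_nuc_target"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.dloop_weight <= 1:
            raise ValueError("dloop_weight must be in [0, 1]")


def _censor_ages(ages: np.ndarray) -> np.ndarray:
    """Five-year stratum midpoints with an open top interval above 95."""
    out = np.where(ages > 95.0, 97.5, (np.floor(ages / 5.0) * 5.0) + 2.5)
    return out


def _stage_from_z(z: np.ndarray, prevalences: Sequence[float]) -> np.ndarray:
    """Threshold a standard-normal latent into ordinal stages with given prevalences."""
    from scipy.stats import norm

    cuts = norm.ppf(np.cumsum(prevalences)[:-1])
    return np.digitize(z, cuts).astype(int)


def generate_cohort(params: GenerativeParams, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one cohort table with correlated pathologies and latent outcomes.

    The returned frame carries the observable phenotypes plus the planted
    truths (``mtdnacn_true``, ``neuronal_proportion_true``) used by recovery
    tests.  Rounded/typed columns make equal-seed runs byte-identical.
    """
    params.validate()
    n = params.n

    age = rng.normal(params.age_mean, params.age_sd, n)
    age = np.clip(age, 60.0, 105.0)
    if params.age_censored:
        age = _censor_ages(age)
    sex_male = (rng.random(n) < params.male_fraction).astype(int)
    education = np.clip(rng.normal(params.education_mean, params.education_sd, n), 5, 30)

    L = np.linalg.cholesky(
        np.asarray(params.pathology_corr, float) + 1e-12 * np.eye(len(_COPULA_VARS))
    )
    Z = rng.standard_normal((n, len(_COPULA_VARS))) @ L.T
    zc = {v: Z[:, i] for i, v in enumerate(_COPULA_VARS)}

    apoe = rng.choice(3, size=n, p=np.asarray(params.apoe_dosage_probs) / sum(params.apoe_dosage_probs))
    snp = rng.binomial(2, params.snp_allele_freq, n)

    # APOE raises the AD-pathology latents (path a), centered on the mean dosage
    d_c = apoe - apoe.mean()
    z_amyloid = zc["amyloid"] + params.apoe_a * d_c
    z_tau = zc["tau"] + params.apoe_a * d_c

    amyloid_sqrt = np.clip(params.amyloid_sqrt_mean + params.amyloid_sqrt_sd * z_amyloid, 0, None)
    tau_sqrt = np.clip(params.tau_sqrt_mean + params.tau_sqrt_sd * z_tau, 0, None)
    gpath_latent = (z_amyloid + z_tau) / np.sqrt(2.0)
    gpath = gpath_latent + 0.3 * rng.standard_normal(n)

    stages = {k: _stage_from_z(zc[k], p) for k, p in STAGE_PREVALENCES.items()}
    binaries = {
        k: _stage_from_z(zc[k], (1 - p, p)) for k, p in BINARY_PREVALENCES.items()
    }

    neuron = np.clip(0.40 - 0.04 * z_tau + 0.04 * rng.standard_normal(n), 0.05, 0.85)
    z_neuron = _zscore(neuron)

    z_mt = (
        params.tau_effect * z_tau
        + params.neuron_effect * z_neuron
        + params.apoe_b * gpath_latent
        + params.apoe_c_prime * d_c
        + params.snp_effect * (snp - snp.mean())
        + params.mtdnacn_noise_sd * rng.standard_normal(n)
    )
    mtdnacn_true = params.mtdnacn_baseline * np.exp(params.mtdnacn_log_sd * z_mt)

    cognition = (
        params.cognition_tau_effect * z_tau
        + params.cognition_mtdnacn_effect * z_mt
        - 0.15 * zc["lewy"]
        - 0.10 * binaries["gross_infarcts"]
        - 0.10 * binaries["hippocampal_sclerosis"]
        + params.cognition_noise_sd * rng.standard_normal(n)
    )

    if params.region == "DLPFC":
        batch = np.where(rng.random(n) < 367 / 454, "DLPFC-kit1", "DLPFC-kit2")
    else:
        batch = np.full(n, f"{params.region}-kit1")

    df = pd.DataFrame(
        {
            "sample_id": [f"{params.region}_{i:04d}" for i in range(n)],
            "region": params.region,
            "age": np.round(age, 2),
            "sex_male": sex_male,
            "education": np.round(education, 1),
            "batch": batch,
            "amyloid_sqrt": np.round(amyloid_sqrt, 4),
            "tau_sqrt": np.round(tau_sqrt, 4),
            "global_ad_path": np.round(gpath, 4),
            "tdp43_stage": stages["tdp43"],
            "lewy_stage": stages["lewy"],
            "caa_stage": stages["caa"],
            "atherosclerosis_stage": stages["atherosclerosis"],
            "arteriolosclerosis_stage": stages["arteriolosclerosis"],
            "gross_infarcts": binaries["gross_infarcts"],
            "microinfarcts": binaries["microinfarcts"],
            "hippocampal_sclerosis": binaries["hippocampal_sclerosis"],
            "cognition": np.round(cognition, 4),
            "neuronal_proportion_true": np.round(neuron, 4),
            "apoe4_dosage": apoe,
            "snp_dosage": snp,
            "mtdnacn_true": np.round(mtdnacn_true, 3),
        }
    )
    return df


# ---------------------------------------------------------------------------
# coverage


def generate_mask(params: GenerativeParams, rng: np.random.Generator) -> pd.DataFrame:
    """Ambiguity mask: random 500-bp autosomal windows, ~mask_fraction of bases."""
    rows = []
    for ci, size in enumerate(params.autosome_sizes, start=1):
        for start in range(0, size, 500):
            if rng.random() < params.mask_fraction:
                rows.append({"contig": f"chr{ci}", "start": start, "end": min(start + 500, size)})
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def _runlength(depths: np.ndarray, contig: str) -> pd.DataFrame:
    change = np.flatnonzero(np.diff(depths)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(depths)]))
    return pd.DataFrame(
        {"contig": contig, "start": starts, "end": ends, "depth": depths[starts]}
    )


def _depth_array(mean: float, length: int, params: GenerativeParams, rng: np.random.Generator) -> np.ndarray:
    if params.coverage_noise == 0:
        return np.full(length, int(round(mean)), dtype=np.int64)
    size = params.coverage_dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p, length).astype(np.int64)


def generate_coverage(
    cohort: pd.DataFrame,
    params: GenerativeParams,
    rng: np.random.Generator,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-sample bedGraph-style coverage tracks plus the shared ambiguity mask.

    MT depth targets ``mtdnacn_true * cov_nuc / 2`` so that the coverage-ratio
    estimator inverts exactly in the noiseless case.
    """
    mask = generate_mask(params, rng)
    tracks: dict[str, pd.DataFrame] = {}
    for _, row in cohort.iterrows():
        pieces = []
        for ci, size in enumerate(params.autosome_sizes, start=1):
            d = _depth_array(params.cov_nuc_target, size, params, rng)
            pieces.append(_runlength(d, f"chr{ci}"))
        mt_mean = row["mtdnacn_true"] * params.cov_nuc_target / 2.0
        pieces.append(_runlength(_depth_array(mt_mean, MT_LENGTH, params, rng), "MT"))
        tracks[row["sample_id"]] = pd.concat(pieces, ignore_index=True)
    return tracks, mask


# ---------------------------------------------------------------------------
# heteroplasmy pileups

_REF_RNG = np.random.default_rng(16569)
REFERENCE = np.array(BASES)[_REF_RNG.integers(0, 4, MT_LENGTH)]


def reference_base(position: int) -> str:
    """Deterministic pseudo-reference base at a 1-based position."""
    return str(REFERENCE[position - 1])


def draw_heteroplasmy_counts(
    ages: np.ndarray, params: GenerativeParams, rng: np.random.Generator
) -> np.ndarray:
    """Poisson burden with multiplicative per-year age effect.

    mean(age) = burden_mean * exp(age_rate * (age - age_mean)), i.e. the
    configured mean burden holds at the cohort's mean age and grows by
    100*(exp(age_rate)-1) percent per year.
    """
    lam = params.burden_mean * np.exp(params.age_rate * (np.asarray(ages) - params.age_mean))
    return rng.poisson(lam)


_CR_POSITIONS = np.concatenate(
    [np.arange(lo, hi + 1) for lo, hi in CONTROL_REGION]
)
_NON_CR_POSITIONS = np.setdiff1d(np.arange(1, MT_LENGTH + 1), _CR_POSITIONS)


def _draw_positions(k: int, params: GenerativeParams, rng: np.random.Generator) -> np.ndarray:
    """k distinct positions, mass `dloop_weight` on the control region."""
    chosen: set[int] = set()
    while len(chosen) < k:
        if rng.random() < params.dloop_weight:
            p = int(rng.choice(_CR_POSITIONS))
        else:
            p = int(rng.choice(_NON_CR_POSITIONS))
        chosen.add(p)
    return np.array(sorted(chosen))


def _draw_af(params: GenerativeParams, rng: np.random.Generator) -> float:
    for _ in range(1000):
        af = rng.beta(params.af_alpha, params.af_beta)
        if params.min_af < af < params.max_af:
            return float(af)
    return float(np.clip(rng.beta(params.af_alpha, params.af_beta), params.min_af + 1e-3, params.max_af - 1e-3))


def _alt_allele(ref: str, indel: bool, rng: np.random.Generator) -> str:
    if indel:
        return "ins" if rng.random() < 0.5 else "del"
    choices = [b for b in BASES if b != ref]
    return choices[int(rng.integers(0, 3))]


def generate_pileup(
    cohort: pd.DataFrame,
    params: GenerativeParams,
    rng: np.random.Generator,
    mt_depths: Mapping[str, float] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-sample 16,569-row allele-count matrices plus the planted truth table.

    Planted per sample: Poisson(age-dependent) heteroplasmies with Beta allele
    fractions concentrated in the D-loop, ``n_homoplasmies`` near-fixed
    variants, ``n_numt_artifacts`` variants whose alternative support scales
    with *nuclear* depth, and (when ``contamination > 0``) low-fraction
    contaminant variants.  Alternative counts are Binomial(depth, AF).
    """
    counts_truth: list[dict] = []
    pileups: dict[str, pd.DataFrame] = {}
    burdens = draw_heteroplasmy_counts(cohort["age"].to_numpy(), params, rng)
    allele_index = {a: j for j, a in enumerate(ALLELE_COLUMNS)}
    ref_idx = np.array([allele_index[b] for b in REFERENCE])

    for (_, row), k_het in zip(cohort.iterrows(), burdens):
        sid = row["sample_id"]
        if mt_depths is not None:
            mt_depth = float(mt_depths[sid])
        else:
            mt_depth = row["mtdnacn_true"] * params.cov_nuc_target / 2.0
        depth = (
            np.full(MT_LENGTH, int(round(mt_depth)), dtype=np.int64)
            if params.coverage_noise == 0
            else rng.poisson(mt_depth, MT_LENGTH).astype(np.int64)
        )
        mat = np.zeros((MT_LENGTH, len(ALLELE_COLUMNS)), dtype=np.int64)
        mat[np.arange(MT_LENGTH), ref_idx] = depth

        def plant(pos: int, af: float, kind: str, alt: str | None = None) -> None:
            i = pos - 1
            ref = REFERENCE[i]
            if alt is None:
                alt = _alt_allele(ref, rng.random() < params.indel_fraction, rng)
            d = depth[i]
            alt_n = int(rng.binomial(d, af)) if 0 < af < 1 else int(round(d * af))
            alt_n = min(alt_n, d)
            j = ALLELE_COLUMNS.index(alt)
            mat[i, j] += alt_n
            mat[i, ref_idx[i]] -= alt_n
            counts_truth.append(
                {"sample_id": sid, "pos": pos, "ref": ref, "alt": alt,
                 "af_true": af, "kind": kind}
            )

        n_extra = params.n_homoplasmies + params.n_numt_artifacts
        n_contam = 3 if params.contamination > 0 else 0
        all_pos = _draw_positions(k_het + n_extra + n_contam, params, rng)
        rng.shuffle(all_pos)
        pos_iter = iter(int(p) for p in all_pos)

        for _ in range(int(k_het)):
            plant(next(pos_iter), _draw_af(params, rng), "heteroplasmy")
        for _ in range(params.n_homoplasmies):
            plant(next(pos_iter), 0.995, "homoplasmy")
        for _ in range(params.n_numt_artifacts):
            pos = next(pos_iter)
            i = pos - 1
            # NUMT: alternative reads scale with nuclear depth, not MT depth
            alt_n = int(rng.poisson(1.5 * params.cov_nuc_target))
            alt_n = min(alt_n, int(depth[i]))
            ref = REFERENCE[i]
            alt = _alt_allele(ref, False, rng)
            j = ALLELE_COLUMNS.index(alt)
            mat[i, j] += alt_n
            mat[i, ref_idx[i]] -= alt_n
            counts_truth.append(
                {"sample_id": sid, "pos": pos, "ref": ref, "alt": alt,
                 "af_true": alt_n / max(depth[i], 1), "kind": "numt"}
            )
        for _ in range(n_contam):
            af = float(rng.uniform(0.003, max(params.contamination * 0.9, 0.004)))
            plant(next(pos_iter), af, "contamination")

        pdf = pd.DataFrame(mat, columns=list(ALLELE_COLUMNS))
        pdf.insert(0, "ref", REFERENCE)
        pdf.insert(0, "pos", np.arange(1, MT_LENGTH + 1))
        pileups[sid] = pdf

    truth = pd.DataFrame(
        counts_truth, columns=["sample_id", "pos", "ref", "alt", "af_true", "kind"]
    )
    return pileups, truth


def make_shifted_pileup(pileup: pd.DataFrame, shift: int, length: int = MT_LENGTH) -> pd.DataFrame:
    """Re-index a pileup onto a reference rotated by ``shift`` base pairs.

    Original position p lands at shifted coordinate ((p - shift - 1) mod L) + 1,
    the inverse of `heteroplasmy.shifted_to_original`.
    """
    pos = pileup["pos"].to_numpy()
    new_pos = (pos - shift - 1) % length + 1
    out = pileup.copy()
    out["pos"] = new_pos
    return out.sort_values("pos", ignore_index=True)


# ---------------------------------------------------------------------------
# expression

MARKER_COUNTS: Mapping[str, int] = {
    "astrocyte": 87, "endothelial": 88, "microglia": 59, "neuron": 90,
    "oligodendrocyte": 86,
}
_GLIA = ("astrocyte", "endothelial", "microglia", "oligodendrocyte")
_GLIA_ALPHA = (5.0, 1.5, 1.5, 5.0)


def generate_expression(
    cohort: pd.DataFrame,
    rng: np.random.Generator,
    noise_sd: float = 0.30,
    n_background: int = 100,
    marker_counts: Mapping[str, int] = MARKER_COUNTS,
) -> tuple[pd.DataFrame, dict[str, list[str]], pd.DataFrame]:
    """CPM-scale bulk expression from proportion-weighted cell-type signatures.

    Marker genes are exclusive to their type: expression of marker g of type t
    in sample i is proportion[i, t] * signature[g] * exp(noise).  Neuronal
    proportions come from the cohort's planted truth; the glial remainder is
    split by a per-sample Dirichlet draw.  Returns (matrix, marker lists,
    true proportions).
    """
    n = len(cohort)
    neuron = cohort["neuronal_proportion_true"].to_numpy()
    glia = rng.dirichlet(_GLIA_ALPHA, n) * (1.0 - neuron)[:, None]
    props = pd.DataFrame(
        {"neuron": neuron, **{ct: glia[:, i] for i, ct in enumerate(_GLIA)}},
        index=cohort["sample_id"],
    )

    markers: dict[str, list[str]] = {}
    cols: dict[str, np.ndarray] = {}
    for ct, k in marker_counts.items():
        sig = np.exp(rng.normal(np.log(50.0), 0.5, k))
        names = [f"{ct[:3].upper()}{j:03d}" for j in range(k)]
        markers[ct] = names
        base = props[ct].to_numpy()[:, None] * sig[None, :]
        noise = np.exp(noise_sd * rng.standard_normal((n, k))) if noise_sd > 0 else 1.0
        for name, col in zip(names, (base * noise).T):
            cols[name] = col
    bg_sig = np.exp(rng.normal(np.log(20.0), 0.8, n_background))
    for j in range(n_background):
        noise = np.exp(noise_sd * rng.standard_normal(n)) if noise_sd > 0 else 1.0
        cols[f"BG{j:03d}"] = bg_sig[j] * noise
    expr = pd.DataFrame(cols, index=cohort["sample_id"]).round(4)
    return expr, markers, props


# ---------------------------------------------------------------------------
# proteomics

_N_PER_COMPLEX = 8


def generate_proteomics(
    cohort: pd.DataFrame,
    rng: np.random.Generator,
    noise_sd: float = 0.30,
    content_np_effect: float = 0.5,
    mtdnacn_me_effect: float = 0.15,
    complex_idiosyncrasy: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Standardized protein abundances driven by a latent mitochondrial content.

    The content latent loads on the part of neuronal proportion orthogonal to
    the copy-number latent, so content and mtDNAcn are decoupled (population
    correlation ~0) while both stay positively correlated with neuronal
    proportion; the mtDNA-encoded protein latent receives a weak copy-number
    loading.  Returns (matrix, membership annotation, per-sample latent truths).
    """
    n = len(cohort)
    z_np = _zscore(cohort["neuronal_proportion_true"].to_numpy())
    z_mt = _zscore(np.log(cohort["mtdnacn_true"].to_numpy()))
    z_np_perp = _zscore(z_np - (z_np @ z_mt / (z_mt @ z_mt)) * z_mt)
    resid = math.sqrt(max(1.0 - content_np_effect**2, 0.0))
    content = content_np_effect * z_np_perp + resid * rng.standard_normal(n)

    from .proteomics import COMPLEX_NAMES, CONTENT_MARKERS, MTDNA_ENCODED

    cols: dict[str, np.ndarray] = {}
    membership: list[dict] = []

    def emit(name: str, latent: np.ndarray, group: str, role: str = "subunit") -> None:
        x = latent + (noise_sd * rng.standard_normal(n) if noise_sd > 0 else 0.0)
        cols[name] = x
        membership.append({"protein": name, "group": group, "role": role})

    for p in CONTENT_MARKERS:
        emit(p, content, "content", "marker")
    for cname in COMPLEX_NAMES:
        cl = content + complex_idiosyncrasy * rng.standard_normal(n)
        for j in range(_N_PER_COMPLEX):
            emit(f"{cname.upper()}_P{j:02d}", cl, cname,
                 "assembly_factor" if j >= _N_PER_COMPLEX - 2 else "subunit")
    me_latent = 0.8 * content + mtdnacn_me_effect * z_mt
    for p in MTDNA_ENCODED:
        emit(p, me_latent, "mtdna_encoded")
    for j in range(20):  # unrelated background proteome
        emit(f"NONMITO{j:03d}", np.zeros(n), "background")

    matrix = pd.DataFrame(cols, index=cohort["sample_id"])
    sd = matrix.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    matrix = ((matrix - matrix.mean(axis=0)) / sd).round(6)
    truths = pd.DataFrame(
        {"content_true": content, "mtdna_encoded_true": me_latent},
        index=cohort["sample_id"],
    )
    return matrix, pd.DataFrame(membership), truths


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# focused scenarios for the inference stack


def mediation_scenario(
    rng: np.random.Generator,
    n: int = 454,
    proportion_mediated: float = 0.44,
    total_effect: float = -0.364,
    a: float = 0.5,
    dosage_probs: Sequence[float] = (335 / 454, 112 / 454, 7 / 454),
    mediator_noise_sd: float = 1.0,
    outcome_noise_sd: float = 0.9,
) -> pd.DataFrame:
    """Linear-Gaussian mediation triplet with a prescribed indirect/total ratio.

    Path b is solved from a and the requested proportion: with indirect a*b
    and direct c' = (1 - prop) * total, prop = a*b / (a*b + c') holds exactly
    in the generating model.
    """
    ab = proportion_mediated * total_effect
    c_prime = (1.0 - proportion_mediated) * total_effect
    b = ab / a
    dosage = rng.choice(3, size=n, p=np.asarray(dosage_probs) / sum(dosage_probs))
    mediator = a * dosage + mediator_noise_sd * rng.standard_normal(n)
    outcome = b * mediator + c_prime * dosage + outcome_noise_sd * rng.standard_normal(n)
    return pd.DataFrame({"dosage": dosage, "pathology": mediator, "mtdnacn": outcome})


def snp_scenario(
    rng: np.random.Generator,
    effect: float = 0.23,
    allele_freq: float = 0.20,
    ns: Mapping[str, int] = {"DLPFC": 454, "CB": 242, "TCX": 262, "FP": 337},
) -> dict[str, pd.DataFrame]:
    """Four region cohorts with a planted additive SNP effect on z-scaled mtDNAcn.

    The residual SD is shrunk so the outcome's marginal variance is ~1, making
    the planted coefficient directly interpretable in SD units per dosage.
    """
    var_d = 2 * allele_freq * (1 - allele_freq)
    resid_sd = math.sqrt(max(1.0 - effect**2 * var_d, 0.1))
    out = {}
    for region, n in ns.items():
        dosage = rng.binomial(2, allele_freq, n)
        age = rng.normal(85.0, 7.0, n)
        sex = rng.binomial(1, 0.35, n)
        y = effect * dosage + resid_sd * rng.standard_normal(n)
        out[region] = pd.DataFrame(
            {"mtdnacn": y, "snp_dosage": dosage, "age": age, "sex_male": sex}
        )
    return out


def burden_scenario(
    rng: np.random.Generator,
    n: int = 454,
    age_mean: float = 89.3,
    age_sd: float = 6.6,
    burden_mean: float = 2.7,
    age_rate: float = math.log(1.016),
) -> pd.DataFrame:
    """Ages plus Poisson heteroplasmy counts with a multiplicative age effect."""
    params = GenerativeParams(
        n=n, age_mean=age_mean, age_sd=age_sd,
        burden_mean=burden_mean, age_rate=age_rate,
    )
    age = rng.normal(age_mean, age_sd, n)
    counts = draw_heteroplasmy_counts(age, params, rng)
    return pd.DataFrame({"age": age, "heteroplasmy_count": counts})
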