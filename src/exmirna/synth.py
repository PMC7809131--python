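"""Synthetic cohorts and CT panels with known ground truth.

The generator emulates a two-group prenatal-alcohol-exposure infant cohort
(default 37 exposed / 31 control, two timepoints) assayed on a 752-miRNA
qPCR panel of which ~148 are reliably detected.  A latent 3-factor
structure drives a subset of "responsive" miRNAs; exposure shifts those
miRNAs with configurable standardized effect sizes, smoking is generated
as a correlated covariate, and growth/cognition outcomes follow a linear
structural model (outcome = c'·exposure + b·factor + noise with
factor = a·exposure + noise, all paths standardized).  Ground truth is
exported so recovery tests can compare estimates against it.

Three independent RNG streams (subjects, panel, hemolysis) are derived
from the configured seed, so adding one block never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .corrnet import MiRNALocus
from .qc import CtPanel

#: assay detection ceiling: latent CT above this is a non-detect
CT_CEILING = 37.0

_BLOCK_SUBJECTS = 101
_BLOCK_PANEL = 202
_BLOCK_HEMOLYSIS = 303
_BLOCK_LOCI = 404

TIMEPOINTS = ("T2wk", "T6.5mo")


def _default_effects() -> list[float]:
    # exposure effects spanning the observed small-to-large range
    return list(np.round(np.linspace(0.4, 0.9, 18), 3))


def _default_loadings() -> list[float]:
    return [0.5] * 18


def _default_factor_cov() -> list[list[float]]:
    return [[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]]


def _default_allocation() -> list[int]:
    return [8, 5, 5]


@dataclass
class PathCoefficients:
    """Standardized structural paths: exposure→factor (a), factor→outcome
    (b), exposure→outcome direct (c')."""

    a: float = 0.4
    b: float = -0.4
    c_prime: float = -0.4


@dataclass
class CohortConfig:
    n_control: int = 31
    n_exposed: int = 37
    n_mirnas_total: int = 752
    n_expressed: int = 148
    n_responsive: int = 18
    factor_allocation: list[int] = field(default_factory=_default_allocation)
    factor_loadings: list[float] = field(default_factory=_default_loadings)
    factor_covariances: list[list[float]] = field(default_factory=_default_factor_cov)
    exposure_effect_d: list[float] = field(default_factory=_default_effects)
    smoking_exposure_corr: float = 0.25
    nondetect_rate: float = 0.05
    paths: PathCoefficients = field(default_factory=PathCoefficients)
    mediating_factor: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_exposed < 2:
            raise ValueError("group sizes must be ≥ 2")
        if not 0.0 <= self.nondetect_rate <= 1.0:
            raise ValueError("nondetect_rate must be a probability")
        if not -1.0 <= self.smoking_exposure_corr <= 1.0:
            raise ValueError("smoking_exposure_corr must lie in [-1, 1]")
        if len(self.factor_loadings) != self.n_responsive:
            raise ValueError("one factor loading per responsive miRNA required")
        if len(self.exposure_effect_d) != self.n_responsive:
            raise ValueError("one effect size per responsive miRNA required")
        if sum(self.factor_allocation) != self.n_responsive:
            raise ValueError("factor allocation must partition the responsive set")
        phi = np.asarray(self.factor_covariances, dtype=float)
        if phi.shape[0] != phi.shape[1] or not np.allclose(phi, phi.T):
            raise ValueError("factor covariance must be symmetric")
        try:
            np.linalg.cholesky(phi)
        except np.linalg.LinAlgError as exc:
            raise ValueError("factor covariance must be positive definite") from exc
        if any(abs(l) >= 1 for l in self.factor_loadings):
            raise ValueError("standardized loadings must satisfy |λ| < 1")

    @property
    def n_factors(self) -> int:
        return len(self.factor_allocation)

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_exposed

    def factor_of_item(self, j: int) -> int:
        """Factor index of the j-th responsive miRNA under the allocation."""
        return int(np.repeat(np.arange(self.n_factors), self.factor_allocation)[j])

    def mirna_ids(self) -> list[str]:
        return [f"MIMAT{9000000 + i:07d}" for i in range(self.n_mirnas_total)]

    def expressed_ids(self) -> list[str]:
        return self.mirna_ids()[: self.n_expressed]

    def responsive_ids(self) -> list[str]:
        return self.mirna_ids()[: self.n_responsive]


@dataclass
class SubjectRecord:
    subject_id: str
    group: str                    # control / exposed
    sex: str                      # F / M
    timepoint: str                # T2wk / T6.5mo
    aa_per_day: float
    cigarettes_per_day: float
    weight_z: float
    length_z: float
    hc_z: float
    ftii_novelty: float
    factor_scores: tuple[float, ...] = ()

    @property
    def sample_id(self) -> str:
        return f"{self.subject_id}_{self.timepoint}"


@dataclass
class GroundTruth:
    latent_factor_scores: dict        # timepoint -> {subject_id: [f1..fk]}
    loadings: list[float]
    paths: PathCoefficients
    responsive_ids: list[str]
    factor_assignment: dict           # responsive mimat -> factor index
    effect_sizes: list[float]


def _rng(config: CohortConfig, block: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=[config.seed, block, extra])
    )


def generate_cohort(config: CohortConfig) -> tuple[list[SubjectRecord], GroundTruth]:
    """Draw subjects, latent factor scores, covariates, and outcomes.

    Outcomes obey the linear mediation structure on standardized scales:
    growth z-scores and novelty preference are linear in the standardized
    exposure indicator and the mediating factor, each with unit marginal
    variance, so OLS on z-scored variables recovers (a, b, c') without
    rescaling.
    """
    rng = _rng(config, _BLOCK_SUBJECTS)
    n = config.n_subjects
    group01 = np.array([0] * config.n_control + [1] * config.n_exposed)
    subject_ids = [f"S{i:03d}" for i in range(n)]
    sex = rng.choice(["F", "M"], size=n)

    p = config.n_exposed / n
    x_std = (group01 - p) / np.sqrt(p * (1 - p))

    # exposure level: controls near zero oz AA/day, exposed strictly positive
    aa = np.where(
        group01 == 1,
        np.maximum(rng.gamma(shape=2.5, scale=0.28, size=n), 0.05),
        np.abs(rng.normal(0.0, 0.004, size=n)),
    )

    # smoking as zero-inflated Poisson, more prevalent among exposed
    base_prev = 0.55
    prev = np.clip(base_prev + config.smoking_exposure_corr * group01, 0.0, 1.0)
    smoker = rng.random(n) < prev
    cigs = np.where(smoker, rng.poisson(6.0, size=n), 0).astype(float)

    a, b, c = config.paths.a, config.paths.b, config.paths.c_prime
    if abs(a) >= 1:
        raise ValueError("|a| must be < 1 for a standardized factor")
    phi = np.asarray(config.factor_covariances, dtype=float)
    k = config.n_factors
    chol = np.linalg.cholesky(phi)

    factor_scores: dict[str, np.ndarray] = {}
    for tp in TIMEPOINTS:
        u = rng.standard_normal((n, k)) @ chol.T
        # within-group variance (1−a²)·Φ_jj = 1−a², group difference a·Δx_std
        f = np.sqrt(1 - a**2) * u + a * x_std[:, None]
        factor_scores[tp] = f

    # outcomes from the T2wk mediating factor (measured once per infant)
    fm = factor_scores[TIMEPOINTS[0]][:, config.mediating_factor]
    resid_var = 1.0 - c**2 - b**2 - 2 * a * b * c
    if resid_var <= 0:
        raise ValueError("path coefficients imply non-positive outcome variance")
    outcomes = {}
    for name in ("weight_z", "length_z", "hc_z", "ftii"):
        e = rng.normal(0.0, np.sqrt(resid_var), size=n)
        outcomes[name] = c * x_std + b * fm + e
    ftii = np.clip(60.0 + 6.0 * outcomes["ftii"], 0.0, 100.0)

    records = []
    for tp in TIMEPOINTS:
        for i in range(n):
            records.append(
                SubjectRecord(
                    subject_id=subject_ids[i],
                    group="exposed" if group01[i] else "control",
                    sex=str(sex[i]),
                    timepoint=tp,
                    aa_per_day=float(aa[i]),
                    cigarettes_per_day=float(cigs[i]),
                    weight_z=float(outcomes["weight_z"][i]),
                    length_z=float(outcomes["length_z"][i]),
                    hc_z=float(outcomes["hc_z"][i]),
                    ftii_novelty=float(ftii[i]),
                    factor_scores=tuple(factor_scores[tp][i]),
                )
            )
    truth = GroundTruth(
        latent_factor_scores={
            tp: {subject_ids[i]: list(map(float, factor_scores[tp][i])) for i in range(n)}
            for tp in TIMEPOINTS
        },
        loadings=list(config.factor_loadings),
        paths=config.paths,
        responsive_ids=config.responsive_ids(),
        factor_assignment={
            mid: config.factor_of_item(j)
            for j, mid in enumerate(config.responsive_ids())
        },
        effect_sizes=list(config.exposure_effect_d),
    )
    return records, truth


def _panel_assay_params(config: CohortConfig, rng: np.random.Generator):
    """Assay-level parameters shared across panels of one cohort."""
    n_exp = config.n_expressed
    baseline = rng.uniform(18.0, 28.0, size=n_exp)
    sd = rng.uniform(0.8, 2.0, size=n_exp)
    n_non = config.n_mirnas_total - n_exp
    detect_prob = rng.uniform(0.0, 0.15, size=n_non)
    return baseline, sd, detect_prob


def _normalized_within_sd(config: CohortConfig, sd: np.ndarray) -> np.ndarray:
    """Within-group SD of the responsive miRNAs on the normalized ΔCT scale.

    Global-mean normalization subtracts the per-sample average CT over the
    expressed set, which both adds the variance of that average and removes
    covariance shared with it (the factor structure couples responsive
    assays to the average).  The exact within-group covariance of the
    expressed CTs is analytic, so the normalized-scale SD is too.
    """
    a = config.paths.a
    lam = np.asarray(config.factor_loadings)
    phi = np.asarray(config.factor_covariances, dtype=float)
    n_exp, n_resp = config.n_expressed, config.n_responsive
    qs = np.array([config.factor_of_item(j) for j in range(n_resp)])
    C = np.diag(sd[:n_exp] ** 2)
    sl = sd[:n_resp] * lam
    C[:n_resp, :n_resp] += (1 - a**2) * np.outer(sl, sl) * phi[np.ix_(qs, qs)]
    # the outer product put sd²λ²(1−a²) on the diagonal; the base diagonal
    # should read sd²(λ²(1−a²) + 1 − λ²), so remove the surplus sd²λ²
    C[np.arange(n_resp), np.arange(n_resp)] -= sl**2
    v_norm = (
        np.diag(C) - (2.0 / n_exp) * C.sum(axis=1) + C.sum() / n_exp**2
    )
    return np.sqrt(v_norm[:n_resp])


def _exposure_shifts(config: CohortConfig, sd: np.ndarray, delta_f: float) -> np.ndarray:
    """Per-assay exposure shifts on the CT scale.

    Global-mean normalization subtracts the average effect across the
    expressed set, so shifts are solved such that the post-normalization
    standardized group difference of each responsive miRNA equals its
    configured d exactly in expectation (negative CT shift = upregulation).
    """
    a = config.paths.a
    lam = np.asarray(config.factor_loadings)
    d = np.asarray(config.exposure_effect_d)
    s_within = _normalized_within_sd(config, sd)
    target = -d * s_within                     # desired normalized ΔCT difference
    n_exp, n_resp = config.n_expressed, config.n_responsive
    total = target.sum() * n_exp / (n_exp - n_resp)
    raw = target + total / n_exp               # required raw CT group difference
    # the factor term already contributes −sd·λ·Δf to the raw difference
    factor_part = -sd[:n_resp] * lam * delta_f
    return raw - factor_part


def generate_ct_panel(
    subjects: list[SubjectRecord],
    config: CohortConfig,
    failed_panel_samples: tuple[str, ...] = (),
) -> CtPanel:
    """Simulate the 752-assay CT matrix for one timepoint's samples.

    Responsive miRNAs follow CT = baseline − sd·(λ·factor + √(1−λ²)·noise)
    plus a solved exposure shift; other expressed miRNAs are pure noise
    around their baselines.  Non-detects arise from the CT-37 detection
    ceiling or random dropout at ``nondetect_rate``; non-expressed assays
    detect with probability < 0.2.  Samples listed in
    ``failed_panel_samples`` have their panel-I half marked structurally
    missing (failed amplification criteria), not imputable.
    """
    if not subjects:
        raise ValueError("subjects must be nonempty")
    tps = {s.timepoint for s in subjects}
    if len(tps) != 1:
        raise ValueError("one panel per timepoint; pass records of a single timepoint")
    tp = tps.pop()
    rng = _rng(config, _BLOCK_PANEL, TIMEPOINTS.index(tp))

    ids = config.mirna_ids()
    n_exp, n_resp = config.n_expressed, config.n_responsive
    baseline, sd, detect_prob = _panel_assay_params(config, _rng(config, _BLOCK_PANEL))

    n = len(subjects)
    group01 = np.array([1 if s.group == "exposed" else 0 for s in subjects])
    p = group01.mean()
    delta_f = config.paths.a / np.sqrt(p * (1 - p)) if 0 < p < 1 else 0.0
    shifts = _exposure_shifts(config, sd, delta_f)

    F = np.array([s.factor_scores for s in subjects])  # n × k
    lam = np.asarray(config.factor_loadings)
    item_factor = np.array([config.factor_of_item(j) for j in range(n_resp)])

    ct = np.empty((config.n_mirnas_total, n))
    noise = rng.standard_normal((n_exp, n))
    for j in range(n_exp):
        if j < n_resp:
            f = F[:, item_factor[j]]
            latent = lam[j] * f + np.sqrt(1 - lam[j] ** 2) * noise[j]
            ct[j] = baseline[j] - sd[j] * latent + shifts[j] * group01
        else:
            ct[j] = baseline[j] + sd[j] * noise[j]

    detected = np.zeros((config.n_mirnas_total, n), dtype=bool)
    detected[:n_exp] = ct[:n_exp] <= CT_CEILING
    if config.nondetect_rate > 0:
        dropout = rng.random((n_exp, n)) < config.nondetect_rate
        detected[:n_exp] &= ~dropout

    non_detected = rng.random((config.n_mirnas_total - n_exp, n)) < detect_prob[:, None]
    detected[n_exp:] = non_detected
    ct[n_exp:] = rng.uniform(33.0, CT_CEILING, size=(config.n_mirnas_total - n_exp, n))

    samples = [s.sample_id for s in subjects]
    ct_df = pd.DataFrame(np.where(detected, ct, np.nan), index=ids, columns=samples)
    det_df = pd.DataFrame(detected, index=ids, columns=samples)
    panel_ok = pd.DataFrame(True, index=ids, columns=samples)
    half = config.n_mirnas_total // 2
    for s in failed_panel_samples:
        if s in panel_ok.columns:
            panel_ok.loc[ids[:half], s] = False
            ct_df.loc[ids[:half], s] = np.nan
            det_df.loc[ids[:half], s] = False

    hemo = generate_hemolysis_metrics(subjects, 0.0, config)
    return CtPanel(
        ct=ct_df,
        detected=det_df,
        panel_ok=panel_ok,
        a414=hemo["a414"],
        ct_mir23a=hemo["ct_mir23a"],
        ct_mir451a=hemo["ct_mir451a"],
        slc4a1_detected=hemo["slc4a1_detected"],
    )


def generate_hemolysis_metrics(
    subjects: list[SubjectRecord],
    contamination_fraction: float,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Per-sample hemolysis metrics with a controlled contamination rate.

    Exactly round(fraction · n) samples exceed both QC thresholds
    (A414 > 0.3 and ΔCT(miR-23a − miR-451a) > 7); all others stay safely
    below both.
    """
    if not 0.0 <= contamination_fraction <= 1.0:
        raise ValueError("contamination_fraction must lie in [0, 1]")
    seed_cfg = config if config is not None else CohortConfig()
    rng = _rng(seed_cfg, _BLOCK_HEMOLYSIS)
    n = len(subjects)
    k = int(round(contamination_fraction * n))
    flagged = np.zeros(n, dtype=bool)
    if k:
        flagged[rng.choice(n, size=k, replace=False)] = True

    a414 = np.where(flagged, rng.uniform(0.35, 0.8, n), rng.uniform(0.05, 0.25, n))
    ct23 = rng.normal(26.0, 1.0, n)
    delta = np.where(
        flagged,
        rng.uniform(7.5, 12.0, n),
        np.clip(rng.normal(2.0, 1.5, n), None, 6.5),
    )
    out = pd.DataFrame(
        {
            "a414": a414,
            "ct_mir23a": ct23,
            "ct_mir451a": ct23 - delta,
            "slc4a1_detected": False,
        },
        index=[s.sample_id for s in subjects],
    )
    return out


def generate_loci(config: CohortConfig) -> list[MiRNALocus]:
    """Synthetic genomic coordinates for the expressed miRNAs.

    Loci are spread over chromosomes 1–22/X; a few miRNAs get a duplicated
    locus on a second chromosome and a few are placed within 10 kb of a
    neighbor to exercise the cluster rule.
    """
    rng = _rng(config, _BLOCK_LOCI)
    chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
    loci: list[MiRNALocus] = []
    ids = config.expressed_ids()
    prev_pos: dict[str, int] = {}
    for i, mid in enumerate(ids):
        chrom = chroms[rng.integers(0, len(chroms))]
        if i % 11 == 10 and chrom in prev_pos:
            start = prev_pos[chrom] + int(rng.integers(200, 8000))  # in-cluster
        else:
            start = int(rng.integers(1_000_00, 200_000_000))
        end = start + int(rng.integers(18, 25))
        loci.append(MiRNALocus(mid, f"syn-miR-{i}", chrom, start, end, "+", 0))
        prev_pos[chrom] = end
        if i % 17 == 16:  # chromosomal duplication on another chromosome
            other = chroms[(chroms.index(chrom) + 5) % len(chroms)]
            s2 = int(rng.integers(1_000_00, 200_000_000))
            loci.append(MiRNALocus(mid, f"syn-miR-{i}", other, s2, s2 + 21, "+", 1))
    return loci


# ---------------------------------------------------------------------------
# File export

def write_ct_tsv(panel: CtPanel, path) -> None:
    panel.ct.to_csv(path, sep="\t", index_label="mimat_id", float_format="%.6g")


def write_metadata_csv(records: list[SubjectRecord], path) -> None:
    df = pd.DataFrame([asdict(r) | {"sample_id": r.sample_id} for r in records])
    df = df.drop(columns=["factor_scores"]).set_index("sample_id")
    df.to_csv(path)


def read_metadata_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = asdict(truth)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
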