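"""Synthetic longitudinal methylation cohort with known ground truth.

The generator emulates the structure the validation pipeline needs: a
two-generation cohort (mothers sampled during pregnancy and ~21 years later
at midlife; their children at birth, childhood and adolescence), beta-value
methylation matrices over a nested coefficient family's CpGs plus background
probes, per-time-point covariates, and alcohol phenotypes (intake in g/day,
AUDIT 0-40) with realistic zero-inflated, right-skewed intake.

Latent model (all drivers jointly Gaussian before transformation):

* ``g_i`` — stable per-person component (abstract genotype / fixed
  environment), shared across all of an individual's time points; child g
  correlates with mother g.
* ``u_i`` — long-run drinking propensity.  In ``genetic_stable`` mode u is
  partly determined by g (the confounding structure under test).
* occasion draws ``z = rho*u + sqrt(1-rho^2)*eps`` — one per unit of
  drinking history; the most recent draw sets concurrent intake via a
  quantile map onto a zero-inflated lognormal calibrated to the configured
  drinker-category mixture.

Methylation at score CpGs is simulated on the logit scale,

    logit(beta_ij) = logit(mu_j) + lambda*w_j*D_i(t) + covariate terms + e_ij

then inverse-transformed (no boundary pile-up, clipping fraction is zero by
construction).  The alcohol driver ``D`` depends on the effect mode:
concurrent standardized log intake (``exposure_concurrent``), the
standardized mean over the drinking history (``exposure_cumulative``), the
stable component g (``genetic_stable``), nothing (``null``), or concurrent
intake plus a smoking term with smoking correlated to drinking
(``smoking_confounded``).

Effect sizes are specified as target R-squared values and solved internally:
``lambda`` is chosen so the calibration set's score carries the requested
signal fraction through the per-CpG linearization factor d_j = mu_j(1-mu_j),
and the AUDIT noise parameter is solved so the latent score-AUDIT R-squared
hits its target at the calibration time point.  Infeasible targets raise
with the feasible bound.  All ground truth (latents, solved constants,
implied R-squared values) is retained on the returned cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import MethylationMatrix
from .phenotypes import HEAVY_THRESHOLD, LIGHT_UPPER, build_phenotype_table
from .scoring import CoefficientFamily, default_family

__all__ = [
    "TimePointSpec",
    "SimulationConfig",
    "SimulatedCohort",
    "aries_timepoints",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

logger = logging.getLogger(__name__)

MODES = ("exposure_concurrent", "exposure_cumulative", "genetic_stable", "smoking_confounded", "null")

WBC_CELLS = ("gran", "cd4t", "cd8t", "bcell", "mono", "nk")
WBC_ALPHA = np.array([60.0, 15.0, 8.0, 6.0, 7.0, 4.0])


@dataclass(frozen=True)
class TimePointSpec:
    """One blood-collection wave for one generation."""

    name: str
    generation: str  # "mother" | "child"
    mean_age: float
    sd_age: float
    drinking: bool  # participants consume alcohol at this wave
    history_length: int  # independent exposure draws averaged in cumulative mode
    adjustment: str  # standard adjustment-set name for residualization
    birth: bool = False  # birth-style covariates (gestational age, birthweight)
    smoking_rate: float = 0.2


def aries_timepoints() -> tuple[TimePointSpec, ...]:
    """Default two-generation layout: mothers at pregnancy (~29y, low/no
    drinking) and midlife (~21 years later, ~30 years of drinking history);
    children at birth, childhood (~7y) and adolescence (~17y, ~2 years of
    drinking history)."""
    return (
        TimePointSpec("pregnancy", "mother", 29.1, 4.2, False, 0, "pregnancy", smoking_rate=0.15),
        TimePointSpec("midlife", "mother", 50.2, 4.2, True, 30, "midlife", smoking_rate=0.2),
        TimePointSpec("birth", "child", 0.0, 0.0, False, 0, "birth", birth=True, smoking_rate=0.0),
        TimePointSpec("childhood", "child", 7.4, 0.1, False, 0, "childhood", smoking_rate=0.0),
        TimePointSpec("adolescence", "child", 17.4, 0.9, True, 2, "adolescence", smoking_rate=0.3),
    )


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults mirror the study conditions
    the pipeline is validated under (1018 mother-child pairs, ~5% never
    drinkers, ~1.5% heavy, midlife AUDIT mean ~8)."""

    n_pairs: int = 1018
    mode: str = "exposure_concurrent"
    time_points: tuple[TimePointSpec, ...] = field(default_factory=aries_timepoints)
    seed: int = 0

    # targets (fractions of variance, latent scale)
    target_r2_intake: float = 0.08  # score vs log intake (concurrent mode) or vs driver (cumulative)
    target_r2_audit: float = 0.025
    stable_score_fraction: float = 0.85  # genetic mode: score reliability across time

    # latent correlation structure
    propensity_corr: float = 0.5  # corr(one occasion draw, long-run propensity u)
    genetic_propensity_corr: float = 0.5  # genetic mode: corr(g, u)
    mother_child_g_corr: float = 0.5
    audit_mix: tuple[float, float] = (0.8, 0.2)  # weights of (u, concurrent z) in the AUDIT driver
    audit_mean: float = 8.5
    audit_sd: float = 4.0
    calibration_time: str = "midlife"

    # drinker-category mixture (marginal over the cohort)
    category_mix: dict = field(
        default_factory=lambda: {"non": 0.05, "light": 0.71, "at_risk": 0.225, "heavy": 0.015}
    )

    # methylation layer
    n_background_cpgs: int = 56
    baseline_beta_range: tuple[float, float] = (0.2, 0.8)
    noise_logit_sd_range: tuple[float, float] = (0.15, 0.35)
    covariate_effect_scales: dict = field(
        default_factory=lambda: {
            "age": 0.003, "sex": 0.05, "bmi": 0.008, "wbc": 0.4,
            "smoking": 0.05, "gestational_age": 0.02, "birthweight": 1e-4,
        }
    )
    smoking_confound_scale: float = 0.5  # extra score-CpG smoking effect, smoking_confounded mode
    exposure_decay_half_life: float | None = None  # optional decay of past draws (cumulative mode)

    family: CoefficientFamily | None = None

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"category mixture must sum to 1, got {total}")
        for name in ("target_r2_intake", "target_r2_audit", "stable_score_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.audit_sd <= 0:
            raise ValueError("audit_sd must be > 0")
        lo, hi = self.noise_logit_sd_range
        if lo <= 0 or hi < lo:
            raise ValueError("noise_logit_sd_range must be positive and ordered")


@dataclass
class SimulatedCohort:
    """Generated data plus the ground truth it was built from."""

    methylation: dict[str, MethylationMatrix]
    covariates: dict[str, pd.DataFrame]
    phenotypes: dict[str, pd.DataFrame]
    ground_truth: dict
    config: SimulationConfig

    @property
    def time_points(self) -> list[str]:
        return list(self.methylation)


# ---------------------------------------------------------------------------
# intake quantile map


def _calibrate_intake_lognormal(mix: dict, female_frac: float) -> tuple[float, float]:
    """Solve lognormal (mu, sigma) so the sex-averaged drinker-category
    fractions match the configured mixture under the sex-specific g/day
    thresholds."""
    p_non = mix["non"]
    light_c = mix["light"] / (1 - p_non)
    heavy_c = mix["heavy"] / (1 - p_non)

    def eqs(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        p_light = p_heavy = 0.0
        for sex, frac in (("female", female_frac), ("male", 1 - female_frac)):
            if frac == 0:
                continue
            p_light += frac * stats.norm.cdf((np.log(LIGHT_UPPER[sex]) - mu) / sigma)
            p_heavy += frac * stats.norm.sf((np.log(HEAVY_THRESHOLD[sex]) - mu) / sigma)
        return [p_light - light_c, p_heavy - heavy_c]

    sol, info, ier, msg = optimize.fsolve(eqs, x0=[2.3, np.log(0.5)], full_output=True)
    if ier != 1:
        raise RuntimeError(f"intake-mixture calibration failed: {msg}")
    return float(sol[0]), float(np.exp(sol[1]))


def _intake_from_latent(z: np.ndarray, p_non: float, mu: float, sigma: float) -> np.ndarray:
    """Quantile-map standard-normal occasion latents onto the zero-inflated
    lognormal intake scale (g/day)."""
    u = stats.norm.cdf(z)
    intake = np.zeros_like(z)
    drink = u >= p_non
    q = (u[drink] - p_non) / (1 - p_non)
    q = np.clip(q, 1e-12, 1 - 1e-12)
    intake[drink] = np.exp(mu + sigma * stats.norm.ppf(q))
    return intake


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _history_moments(rho: float, m: int, half_life: float | None) -> tuple[float, float, float]:
    """sd of the (possibly decay-weighted) history mean C, and its covariances
    with the propensity u and the most recent occasion draw z."""
    if half_life is not None:
        w = 0.5 ** (np.arange(m - 1, -1, -1, dtype=float) / half_life)
    else:
        w = np.ones(m)
    w = w / w.sum()
    var_c = rho**2 + (1 - rho**2) * float((w**2).sum())
    cov_cu = rho
    cov_cz = rho**2 + (1 - rho**2) * float(w[-1])
    return float(np.sqrt(var_c)), cov_cu, cov_cz


def _analytic_audit_corr(config: "SimulationConfig", tp: "TimePointSpec",
                         ln_params: tuple[float, float], kappa: float) -> float:
    """corr(D, M) between the methylation driver at ``tp`` and the AUDIT
    driver M = w_u*u + w_z*z, computed on the latent scale.

    Deterministic given the config: the concurrent mode's nonlinear
    z -> log(intake+1) map is integrated by Gauss-Hermite quadrature; the
    cumulative and genetic modes are closed-form in the jointly normal
    latents.
    """
    w_u, w_z = config.audit_mix
    rho = config.propensity_corr
    sd_m = float(np.sqrt(w_u**2 + w_z**2 + 2 * w_u * w_z * rho))
    if sd_m == 0:
        return 0.0
    mode = config.mode
    if mode == "genetic_stable":
        # D = g; cov(g,u) = kappa, cov(g,z) = kappa*rho
        return (w_u * kappa + w_z * kappa * rho) / sd_m
    if mode == "exposure_cumulative":
        m = max(int(tp.history_length), 1)
        sd_c, cov_cu, cov_cz = _history_moments(rho, m, config.exposure_decay_half_life)
        return (w_u * cov_cu + w_z * cov_cz) / (sd_c * sd_m)
    # concurrent modes: D = standardized T(z), T = log1p(quantile-mapped intake)
    nodes, wts = np.polynomial.hermite_e.hermegauss(201)
    wts = wts / wts.sum()  # standard-normal expectation weights
    mu_ln, sigma_ln = ln_params
    t = np.log1p(_intake_from_latent(nodes, config.category_mix["non"], mu_ln, sigma_ln))
    e_t = float(wts @ t)
    var_t = float(wts @ (t - e_t) ** 2)
    cov_tz = float(wts @ (t * nodes))  # E[T z] - E[T]E[z], E[z]=0
    if var_t == 0:
        return 0.0
    # cov(T, M) = cov(T, z) * (w_u * rho + w_z)  since E[u|z] = rho z
    return cov_tz * (w_u * rho + w_z) / (np.sqrt(var_t) * sd_m)


# ---------------------------------------------------------------------------
# generator


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a fully reproducible two-generation cohort.

    Returns matrices, covariates and phenotypes per time point plus a
    ``ground_truth`` dict holding the latent components and every solved
    calibration constant.
    """
    rng = np.random.default_rng(config.seed)
    fam = config.family if config.family is not None else default_family()
    largest = fam.largest
    score_cpgs = largest.cpgs
    weights = np.array([largest.weights[c] for c in score_cpgs])
    n_score = len(score_cpgs)
    bg_cpgs = [f"bg{j:05d}" for j in range(config.n_background_cpgs)]
    all_cpgs = score_cpgs + bg_cpgs
    n_cpg = len(all_cpgs)

    # --- per-CpG parameters ------------------------------------------------
    lo_b, hi_b = config.baseline_beta_range
    mu_beta = rng.uniform(lo_b, hi_b, n_cpg)
    base_logit = special.logit(mu_beta)
    d = mu_beta * (1 - mu_beta)  # local slope of the inverse-logit
    lo_s, hi_s = config.noise_logit_sd_range
    sigma = rng.uniform(lo_s, hi_s, n_cpg)
    scales = config.covariate_effect_scales
    gamma = {
        "age": rng.normal(0, scales["age"], n_cpg),
        "sex": rng.normal(0, scales["sex"], n_cpg),
        "bmi": rng.normal(0, scales["bmi"], n_cpg),
        "smoking": rng.normal(0, scales["smoking"], n_cpg),
        "gestational_age": rng.normal(0, scales["gestational_age"], n_cpg),
        "birthweight": rng.normal(0, scales["birthweight"], n_cpg),
    }
    gamma_wbc = rng.normal(0, scales["wbc"], (len(WBC_CELLS), n_cpg))
    # background probes carry a small stable-person loading for realism
    bg_stable = np.concatenate([np.zeros(n_score), rng.normal(0, 0.1, len(bg_cpgs))])

    # --- solve lambda from the target signal fraction ----------------------
    wd = weights**2 * d[:n_score]
    B_cd = float(wd.sum())  # score signal per unit of driver
    v_noise = float((weights**2 * sigma[:n_score] ** 2 * d[:n_score] ** 2).sum())
    if config.mode == "null":
        lam, psi = 0.0, 0.0
    else:
        psi = (
            config.stable_score_fraction
            if config.mode == "genetic_stable"
            else config.target_r2_intake
        )
        lam = float(np.sqrt(psi * v_noise / (1 - psi)) / B_cd)

    # --- latent person-level components ------------------------------------
    n = config.n_pairs
    g_mother = rng.normal(0, 1, n)
    rg = config.mother_child_g_corr
    g_child = rg * g_mother + np.sqrt(1 - rg**2) * rng.normal(0, 1, n)
    g = {"mother": g_mother, "child": g_child}
    kappa = config.genetic_propensity_corr if config.mode == "genetic_stable" else 0.0
    u = {
        gen: kappa * g[gen] + np.sqrt(1 - kappa**2) * rng.normal(0, 1, n)
        for gen in ("mother", "child")
    }
    ids = {
        "mother": pd.Index([f"M{i:05d}" for i in range(n)], name="sample_id"),
        "child": pd.Index([f"C{i:05d}" for i in range(n)], name="sample_id"),
    }
    sex = {"mother": np.zeros(n, dtype=int), "child": rng.integers(0, 2, n)}  # 1 = male

    female_frac = {gen: float((sex[gen] == 0).mean()) for gen in sex}
    ln_params = {
        gen: _calibrate_intake_lognormal(config.category_mix, female_frac[gen]) for gen in sex
    }

    rho = config.propensity_corr
    p_non = config.category_mix["non"]

    # first pass: exposure latents and intake per drinking time point
    z_conc: dict[str, np.ndarray] = {}
    D: dict[str, np.ndarray] = {}
    intake: dict[str, np.ndarray] = {}
    for tp in config.time_points:
        gen = tp.generation
        if not tp.drinking:
            intake[tp.name] = np.zeros(n)
            D[tp.name] = g[gen] if config.mode == "genetic_stable" else np.zeros(n)
            if config.mode == "genetic_stable":
                D[tp.name] = _standardize(D[tp.name])
            continue
        m = max(int(tp.history_length), 1)
        eps = rng.normal(0, 1, (n, m))
        draws = rho * u[gen][:, None] + np.sqrt(1 - rho**2) * eps
        z = draws[:, -1]  # most recent occasion sets concurrent intake
        z_conc[tp.name] = z
        mu_ln, sd_ln = ln_params[gen]
        intake[tp.name] = _intake_from_latent(z, p_non, mu_ln, sd_ln)
        if config.mode in ("exposure_concurrent", "smoking_confounded", "null"):
            D[tp.name] = _standardize(np.log1p(intake[tp.name]))
        elif config.mode == "exposure_cumulative":
            if config.exposure_decay_half_life is not None:
                ages = np.arange(m - 1, -1, -1, dtype=float)  # draws ago
                w_decay = 0.5 ** (ages / config.exposure_decay_half_life)
                hist = (draws * w_decay).sum(axis=1) / w_decay.sum()
            else:
                hist = draws.mean(axis=1)
            D[tp.name] = _standardize(hist)
        else:  # genetic_stable
            D[tp.name] = _standardize(g[gen])

    # --- AUDIT noise solved from its target at the calibration time --------
    w_u, w_z = config.audit_mix
    M: dict[str, np.ndarray] = {}
    for tp in config.time_points:
        if tp.drinking:
            M[tp.name] = _standardize(w_u * u[tp.generation] + w_z * z_conc[tp.name])
    cal = config.calibration_time
    if cal not in M:
        drinking_names = [t.name for t in config.time_points if t.drinking]
        if not drinking_names:
            cal = None
        else:
            cal = drinking_names[-1]
    if config.mode == "null" or cal is None:
        theta = np.sqrt(0.5)
        corr_dm = 0.0
    else:
        cal_tp = next(t for t in config.time_points if t.name == cal)
        corr_dm = _analytic_audit_corr(config, cal_tp, ln_params[cal_tp.generation], kappa)
        bound = psi * corr_dm**2
        if config.target_r2_audit >= bound:
            raise ValueError(
                f"target_r2_audit={config.target_r2_audit} infeasible in mode "
                f"'{config.mode}': the feasible bound given the intake/driver "
                f"signal is {bound:.4f} (= signal fraction {psi:.3f} x "
                f"corr(driver, AUDIT driver)^2 {corr_dm ** 2:.3f})"
            )
        theta = float(np.sqrt(config.target_r2_audit / bound))

    # --- smoking ------------------------------------------------------------
    smoking: dict[str, np.ndarray] = {}
    for tp in config.time_points:
        gen = tp.generation
        if tp.smoking_rate <= 0:
            smoking[tp.name] = np.zeros(n, dtype=int)
        elif config.mode == "smoking_confounded" and tp.drinking:
            logit_p = special.logit(tp.smoking_rate) + 1.0 * u[gen]
            smoking[tp.name] = (rng.uniform(size=n) < special.expit(logit_p)).astype(int)
        else:
            smoking[tp.name] = (rng.uniform(size=n) < tp.smoking_rate).astype(int)

    # --- assemble per-time-point tables ------------------------------------
    methylation: dict[str, MethylationMatrix] = {}
    covariates: dict[str, pd.DataFrame] = {}
    phenotypes: dict[str, pd.DataFrame] = {}
    tp_truth: dict[str, dict] = {}

    for tp in config.time_points:
        gen = tp.generation
        idx = ids[gen]
        cov = pd.DataFrame(index=idx)
        if tp.birth:
            cov["gestational_age"] = np.round(rng.normal(39.5, 1.5, n), 1)
            cov["birthweight"] = np.round(rng.normal(3450, 480, n), 0)
            cov["sex"] = sex[gen]
        else:
            cov["age"] = np.round(rng.normal(tp.mean_age, max(tp.sd_age, 1e-6), n), 1)
            cov["sex"] = sex[gen]
            bmi_mean = {"childhood": 16.5, "adolescence": 22.0}.get(tp.name, 25.0)
            bmi_sd = {"childhood": 2.0, "adolescence": 3.5}.get(tp.name, 4.0)
            cov["bmi"] = np.round(rng.normal(bmi_mean, bmi_sd, n), 1)
        wbc = rng.dirichlet(WBC_ALPHA, size=n)
        for k, cell in enumerate(WBC_CELLS):
            cov[f"wbc_{cell}"] = wbc[:, k]
        if tp.smoking_rate > 0:
            cov["smoking"] = smoking[tp.name]

        # methylation on the logit scale
        x = np.tile(base_logit, (n, 1))
        x[:, :n_score] += lam * np.outer(D[tp.name], weights)
        x += np.outer(g[gen], bg_stable)  # small stable-person loading on background probes
        if "age" in cov:
            x += np.outer(cov["age"] - cov["age"].mean(), gamma["age"])
        x += np.outer(cov["sex"] - 0.5, gamma["sex"])
        if "bmi" in cov:
            x += np.outer(cov["bmi"] - cov["bmi"].mean(), gamma["bmi"])
        if tp.birth:
            x += np.outer(cov["gestational_age"] - 39.5, gamma["gestational_age"])
            x += np.outer(cov["birthweight"] - 3450.0, gamma["birthweight"])
        for k in range(len(WBC_CELLS)):
            x += np.outer(wbc[:, k] - WBC_ALPHA[k] / WBC_ALPHA.sum(), gamma_wbc[k])
        if "smoking" in cov:
            x += np.outer(cov["smoking"] - cov["smoking"].mean(), gamma["smoking"])
            if config.mode == "smoking_confounded" and tp.drinking:
                x[:, :n_score] += config.smoking_confound_scale * lam * np.outer(
                    cov["smoking"] - cov["smoking"].mean(), weights
                )
        x += rng.normal(0, 1, (n, n_cpg)) * sigma
        betas = special.expit(x)
        methylation[tp.name] = MethylationMatrix(
            pd.DataFrame(betas, index=idx, columns=all_cpgs), time_point=tp.name
        )

        # phenotypes
        raw = pd.DataFrame(index=idx)
        raw["sex"] = np.where(sex[gen] == 1, "male", "female")
        raw["intake_gday"] = intake[tp.name]
        if tp.drinking:
            e_a = rng.normal(0, 1, n)
            latent = config.audit_mean + config.audit_sd * (
                theta * M[tp.name] + np.sqrt(1 - theta**2) * e_a
            )
            audit = np.clip(np.round(latent), 0, 40).astype(int)
            audit[intake[tp.name] == 0] = 0  # self-reported non-drinkers score 0
            raw["audit"] = audit
        phenotypes[tp.name] = build_phenotype_table(raw)
        covariates[tp.name] = cov

        exp_r2_intake = (
            psi * float(np.corrcoef(D[tp.name], np.log1p(intake[tp.name]))[0, 1]) ** 2
            if tp.drinking and lam > 0 and np.log1p(intake[tp.name]).std() > 0
            else 0.0
        )
        exp_r2_audit = (
            psi * float(np.corrcoef(D[tp.name], M[tp.name])[0, 1]) ** 2 * theta**2
            if tp.drinking and lam > 0
            else 0.0
        )
        mix_achieved = (
            phenotypes[tp.name]["category"].value_counts(normalize=True).to_dict()
            if tp.drinking
            else {}
        )
        tp_truth[tp.name] = {
            "drinking": tp.drinking,
            "expected_latent_r2_intake": exp_r2_intake,
            "expected_latent_r2_audit": exp_r2_audit,
            "achieved_category_mix": mix_achieved,
            "clipping_fraction": 0.0,  # inverse-logit never leaves (0, 1)
        }

    latents = {
        gen: pd.DataFrame({"g": g[gen], "u": u[gen]}, index=ids[gen]) for gen in ("mother", "child")
    }
    ground_truth = {
        "lambda": lam,
        "theta": float(theta),
        "signal_fraction": float(psi),
        "corr_driver_audit_driver": corr_dm,
        "calibration_time": cal,
        "score_signal_per_driver_sd": lam * B_cd,
        "score_noise_var": v_noise,
        "intake_lognormal": {gen: ln_params[gen] for gen in ln_params},
        "time_points": tp_truth,
        "latents": latents,
    }
    return SimulatedCohort(methylation, covariates, phenotypes, ground_truth, config)


# ---------------------------------------------------------------------------
# persistence


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> list[Path]:
    """Write every matrix/table plus the ground-truth sidecars as TSV.

    Round-trips losslessly through :func:`read_cohort` (floats are written
    at full shortest-repr precision)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t")
        written.append(p)

    for tp_name, meth in cohort.methylation.items():
        emit(meth.values, f"meth_{tp_name}.tsv")
        emit(cohort.covariates[tp_name], f"covar_{tp_name}.tsv")
        emit(cohort.phenotypes[tp_name], f"pheno_{tp_name}.tsv")
    for gen, lat in cohort.ground_truth["latents"].items():
        emit(lat, f"latents_{gen}.tsv")
    meta = {k: v for k, v in cohort.ground_truth.items() if k != "latents"}
    p = outdir / "ground_truth.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    written.append(p)
    return written


def read_cohort(indir: str | Path) -> dict[str, dict[str, pd.DataFrame]]:
    """Read back the TSV tables written by :func:`write_cohort`."""
    indir = Path(indir)
    out: dict[str, dict[str, pd.DataFrame]] = {"methylation": {}, "covariates": {}, "phenotypes": {}}
    kinds = {"meth": "methylation", "covar": "covariates", "pheno": "phenotypes"}
    for p in sorted(indir.glob("*.tsv")):
        stem = p.stem
        for prefix, kind in kinds.items():
            if stem.startswith(prefix + "_"):
                tp = stem[len(prefix) + 1 :]
                out[kind][tp] = pd.read_csv(p, sep="\t", index_col=0)
    return out
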