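"""End-to-end orchestration: simulate/load -> residualize -> score -> evaluate
-> longitudinal, emitting the report tables.

The report bundle mirrors the shape of the analyses the pipeline validates:

* a variance-explained table (rows: outcome x time point; columns: one per
  coefficient set; both R2 and adjusted R2 as percent),
* an AUC table (binary drinker-category and high-AUDIT contrasts per set),
* a refit-comparison table quantifying in-sample overfitting of
  re-estimated CpG coefficients against the fixed-coefficient score,
* longitudinal earlier-vs-concurrent tables, and
* sensitivity variants (non-drinkers excluded; smoking-adjusted
  residualization).

Everything is deterministic given the config seed; a manifest records sample
flow and skipped contrasts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import MethylationMatrix, ScoreVector
from .evaluation import refit_comparison, roc_auc, variance_explained
from .longitudinal import birth_maternal_extension, early_vs_concurrent, results_table
from .residualize import STANDARD_SETS, AdjustmentSet, residualize_matrix
from .scoring import CoefficientFamily, compute_score, default_family, load_coefficients
from .synthetic import SimulatedCohort, SimulationConfig, TimePointSpec, simulate_cohort

__all__ = [
    "PipelineState",
    "RunConfig",
    "build_state",
    "state_from_cohort",
    "r2_table",
    "auc_table",
    "refit_table",
    "run_sensitivity",
    "run_validation",
    "CONTRASTS",
]

logger = logging.getLogger(__name__)

#: contrast name -> (positive categories, negative categories) on drinker
#: category, or the special AUDIT dichotomy.
CONTRASTS = {
    "heavy_vs_non": (("heavy",), ("non",)),
    "heavy_vs_light": (("heavy",), ("light",)),
    "at_risk_vs_light_non": (("at_risk",), ("light", "non")),
    "audit_high": "audit_high",
}


@dataclass
class PipelineState:
    """All per-time-point inputs plus residualization/score caches."""

    family: CoefficientFamily
    methylation: dict[str, MethylationMatrix]
    covariates: dict[str, pd.DataFrame]
    phenotypes: dict[str, pd.DataFrame]
    adjustments: dict[str, AdjustmentSet]
    residuals: dict[str, MethylationMatrix] = field(default_factory=dict)
    scores: dict[str, dict[str, ScoreVector]] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def residualized(self, tp: str) -> MethylationMatrix:
        if tp not in self.residuals:
            self.residuals[tp] = residualize_matrix(
                self.methylation[tp], self.covariates[tp], self.adjustments[tp]
            )
        return self.residuals[tp]

    def score(self, tp: str, set_name: str, missing_policy: str = "error") -> ScoreVector:
        cache = self.scores.setdefault(tp, {})
        if set_name not in cache:
            cache[set_name] = compute_score(
                self.residualized(tp), self.family[set_name], missing_policy
            )
        return cache[set_name]

    def subset(self, tp: str, sample_ids: pd.Index) -> "PipelineState":
        """A fresh state with time point ``tp`` restricted to ``sample_ids``
        (caches discarded so residualization reruns on the subset)."""
        meth = dict(self.methylation)
        cov = dict(self.covariates)
        phen = dict(self.phenotypes)
        m = self.methylation[tp]
        meth[tp] = MethylationMatrix(
            m.values.loc[sample_ids], time_point=m.time_point, residualized=m.residualized
        )
        cov[tp] = self.covariates[tp].loc[sample_ids]
        phen[tp] = self.phenotypes[tp].loc[sample_ids]
        return PipelineState(self.family, meth, cov, phen, dict(self.adjustments))


def state_from_cohort(
    cohort: SimulatedCohort, family: CoefficientFamily | None = None
) -> PipelineState:
    fam = family or (cohort.config.family if cohort.config.family is not None else default_family())
    adjustments = {
        tp.name: STANDARD_SETS[tp.adjustment] for tp in cohort.config.time_points
    }
    return PipelineState(
        fam, dict(cohort.methylation), dict(cohort.covariates), dict(cohort.phenotypes), adjustments
    )


def build_state(
    meth_files: dict[str, str | Path],
    covar_files: dict[str, str | Path],
    pheno_files: dict[str, str | Path],
    adjustments: dict[str, str],
    coefficients: str | Path | None = None,
) -> PipelineState:
    """Assemble a state from on-disk TSV tables keyed by time point."""
    fam = load_coefficients(coefficients) if coefficients else default_family()
    meth = {
        tp: MethylationMatrix(pd.read_csv(p, sep="\t", index_col=0), time_point=tp)
        for tp, p in meth_files.items()
    }
    cov = {tp: pd.read_csv(p, sep="\t", index_col=0) for tp, p in covar_files.items()}
    phen = {tp: pd.read_csv(p, sep="\t", index_col=0) for tp, p in pheno_files.items()}
    adj = {tp: STANDARD_SETS[name] for tp, name in adjustments.items()}
    return PipelineState(fam, meth, cov, phen, adj)


# ---------------------------------------------------------------------------
# report tables


def r2_table(
    state: PipelineState,
    time_points: list[str],
    outcomes: tuple[str, ...] = ("log_intake", "audit"),
) -> pd.DataFrame:
    """Tidy variance-explained table: one row per (time point, outcome, set)
    with R2 and adjusted R2 as percent."""
    rows = []
    for tp in time_points:
        phen = state.phenotypes[tp]
        for outcome in outcomes:
            if outcome not in phen.columns:
                continue
            y = phen[outcome].dropna().astype(float)
            for cs in state.family:
                sv = state.score(tp, cs.name)
                res = variance_explained(sv, y)
                rows.append(
                    {
                        "time_point": tp,
                        "outcome": outcome,
                        "set": cs.name,
                        "n_cpgs": cs.n_cpgs,
                        "n": res.n,
                        "r2_pct": round(res.r2 * 100, 2),
                        "adj_r2_pct": round(res.adj_r2 * 100, 2),
                    }
                )
    return pd.DataFrame(rows)


def pivot_r2(table: pd.DataFrame, value: str = "adj_r2_pct") -> pd.DataFrame:
    """Report layout: rows outcome x time point, one column per set size."""
    return table.pivot_table(
        index=["time_point", "outcome", "n"], columns="n_cpgs", values=value
    )


def auc_table(
    state: PipelineState,
    time_points: list[str],
    contrasts: tuple[str, ...] = ("heavy_vs_non", "heavy_vs_light", "audit_high"),
) -> pd.DataFrame:
    """AUC per (time point, contrast, set); contrasts with an empty class are
    skipped with a logged warning and recorded in the manifest."""
    rows = []
    skipped = state.manifest.setdefault("skipped_contrasts", [])
    for tp in time_points:
        phen = state.phenotypes[tp]
        for name in contrasts:
            spec = CONTRASTS[name]
            if spec == "audit_high":
                if "audit_high" not in phen.columns:
                    continue
                mask = phen["audit_high"].notna()
                labels = phen.loc[mask, "audit_high"].astype(bool)
            else:
                pos, neg = spec
                cat = phen["category"].astype(str)
                mask = cat.isin(pos + neg)
                labels = cat[mask].isin(pos)
            if labels.sum() == 0 or (~labels).sum() == 0:
                logger.warning("contrast '%s' at '%s' skipped: a class is empty", name, tp)
                skipped.append({"time_point": tp, "contrast": name, "reason": "empty class"})
                continue
            for cs in state.family:
                sv = state.score(tp, cs.name)
                roc = roc_auc(sv.scores.loc[labels.index], labels, contrast=f"{tp}:{name}")
                rows.append(
                    {
                        "time_point": tp,
                        "contrast": name,
                        "set": cs.name,
                        "n_cpgs": cs.n_cpgs,
                        "n_pos": roc.n_pos,
                        "n_neg": roc.n_neg,
                        "auc": round(roc.auc, 3),
                    }
                )
    return pd.DataFrame(rows)


def refit_table(
    state: PipelineState, time_points: list[str], outcome: str = "log_intake"
) -> pd.DataFrame:
    """In-sample overfitting comparison per set: adjusted R2 of the
    fixed-coefficient score versus CpG coefficients re-estimated in this very
    sample (alongside age/sex/BMI), plus the covariates-only baseline."""
    rows = []
    for tp in time_points:
        phen = state.phenotypes[tp]
        if outcome not in phen.columns:
            continue
        y = phen[outcome].dropna().astype(float)
        resid = state.residualized(tp)
        covars = state.covariates[tp]
        for cs in state.family:
            try:
                cov_fit, full_fit = refit_comparison(resid, covars, y, cpgs=cs.cpgs)
            except ValueError as err:
                logger.warning("refit for set '%s' at '%s' skipped: %s", cs.name, tp, err)
                continue
            fixed = variance_explained(state.score(tp, cs.name), y)
            rows.append(
                {
                    "time_point": tp,
                    "outcome": outcome,
                    "set": cs.name,
                    "n_cpgs": cs.n_cpgs,
                    "n": full_fit.n,
                    "covars_adj_r2_pct": round(cov_fit.adj_r2 * 100, 2),
                    "refit_r2_pct": round(full_fit.r2 * 100, 2),
                    "refit_adj_r2_pct": round(full_fit.adj_r2 * 100, 2),
                    "fixed_r2_pct": round(fixed.r2 * 100, 2),
                    "fixed_adj_r2_pct": round(fixed.adj_r2 * 100, 2),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensitivity reruns


def run_sensitivity(state: PipelineState, mode: str, time_points: list[str] | None = None) -> dict:
    """Re-execute residualize -> score -> evaluate under a sensitivity mode.

    ``exclude_nondrinkers`` drops self-reported non-drinkers per time point
    before re-residualizing; ``adjust_smoking`` switches to the "+smoking"
    adjustment-set variants where defined.  Returns the same table schema as
    the primary run, flagged with the mode.
    """
    tps = time_points or [tp for tp, p in state.phenotypes.items() if "log_intake" in p.columns]
    work = state
    if mode == "exclude_nondrinkers":
        for tp in tps:
            keep = work.phenotypes[tp].index[work.phenotypes[tp]["intake_gday"] > 0]
            dropped = len(work.phenotypes[tp]) - len(keep)
            if dropped:
                logger.info("sensitivity '%s': dropping %d non-drinker(s) at '%s'", mode, dropped, tp)
            work = work.subset(tp, keep)
    elif mode == "adjust_smoking":
        adj = {}
        for tp, aset in state.adjustments.items():
            smoking_variant = next(
                (
                    s
                    for n, s in STANDARD_SETS.items()
                    if n.startswith(aset.name + "+") and "smok" in n
                ),
                None,
            )
            if smoking_variant is not None and "smoking" in state.covariates[tp].columns:
                adj[tp] = smoking_variant
            else:
                adj[tp] = aset
        work = PipelineState(
            state.family,
            dict(state.methylation),
            dict(state.covariates),
            dict(state.phenotypes),
            adj,
        )
    else:
        raise ValueError(f"unknown sensitivity mode: {mode!r}")

    tables = {
        "r2": r2_table(work, tps),
        "auc": auc_table(work, tps),
    }
    for t in tables.values():
        if len(t):
            t.insert(0, "mode", mode)
    return tables


# ---------------------------------------------------------------------------
# run config and top-level driver


@dataclass
class RunConfig:
    """Single-file description of a full validation run."""

    out_dir: str = "methalc_run"
    seed: int = 0
    simulate: dict | None = None  # SimulationConfig overrides; None -> load inputs
    inputs: dict | None = None  # {meth: {tp: path}, covars: {...}, phenos: {...}, adjustments: {...}}
    coefficients: str | None = None
    cross_sectional: list[str] = field(default_factory=lambda: ["midlife", "adolescence"])
    outcomes: tuple[str, ...] = ("log_intake", "audit")
    contrasts: tuple[str, ...] = ("heavy_vs_non", "heavy_vs_light", "audit_high")
    sensitivity: tuple[str, ...] = ("exclude_nondrinkers", "adjust_smoking")
    longitudinal: list[dict] = field(
        default_factory=lambda: [
            {"outcome_time": "midlife", "early_time": "pregnancy"},
            {"outcome_time": "adolescence", "early_time": "childhood"},
            {"outcome_time": "adolescence", "early_time": "birth"},
        ]
    )
    maternal_extension: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cross_sectional", "longitudinal"):
            if key in raw and raw[key] is not None:
                raw[key] = list(raw[key])
        for key in ("outcomes", "contrasts", "sensitivity"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _simulation_config(run: RunConfig) -> SimulationConfig:
    overrides = dict(run.simulate or {})
    if "time_points" in overrides:
        overrides["time_points"] = tuple(
            TimePointSpec(**tp) if isinstance(tp, dict) else tp for tp in overrides["time_points"]
        )
    overrides.setdefault("seed", run.seed)
    return SimulationConfig(**overrides)


def run_validation(run: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns the in-memory tables; writes TSVs plus ``manifest.json`` under
    ``run.out_dir``.  All outputs are computed before anything is written, so
    a stage failure leaves no partial bundle behind.
    """
    if run.simulate is None and run.inputs is None:
        raise ValueError("config must provide either a 'simulate' block or 'inputs' paths")

    if run.simulate is not None:
        sim_cfg = _simulation_config(run)
        cohort = simulate_cohort(sim_cfg)
        fam = load_coefficients(run.coefficients) if run.coefficients else None
        state = state_from_cohort(cohort, fam)
        sample_flow = {tp: int(m.n_samples) for tp, m in cohort.methylation.items()}
    else:
        state = build_state(
            run.inputs["meth"],
            run.inputs["covars"],
            run.inputs["phenos"],
            run.inputs.get("adjustments", {}),
            run.coefficients,
        )
        sample_flow = {tp: int(m.n_samples) for tp, m in state.methylation.items()}

    tps = [tp for tp in run.cross_sectional if tp in state.methylation]
    tables: dict[str, pd.DataFrame] = {}
    tables["r2"] = r2_table(state, tps, run.outcomes)
    tables["auc"] = auc_table(state, tps, run.contrasts)
    tables["refit"] = refit_table(state, tps)

    for mode in run.sensitivity:
        sens = run_sensitivity(state, mode, tps)
        tables[f"r2_{mode}"] = sens["r2"]
        tables[f"auc_{mode}"] = sens["auc"]

    longit_frames = []
    paired_ns = {}
    largest = state.family.largest.name
    for design in run.longitudinal:
        out_tp, early_tp = design["outcome_time"], design["early_time"]
        if out_tp not in state.methylation or early_tp not in state.methylation:
            continue
        audit = state.phenotypes[out_tp]["audit"].dropna().astype(float)
        fits = early_vs_concurrent(
            audit,
            state.score(early_tp, largest),
            state.score(out_tp, largest),
            early_name=early_tp,
            concurrent_name=out_tp,
        )
        frame = results_table(fits, dependent=f"AUDIT at {out_tp}")
        longit_frames.append(frame)
        paired_ns[f"{early_tp}->{out_tp}"] = int(fits[early_tp].n)
    if longit_frames:
        tables["longitudinal"] = pd.concat(longit_frames, ignore_index=True)

    if (
        run.maternal_extension
        and {"birth", "pregnancy", "adolescence"} <= set(state.methylation)
    ):
        audit = state.phenotypes["adolescence"]["audit"].dropna().astype(float)
        preg = state.score("pregnancy", largest)
        # re-key maternal scores by offspring id (M#### -> C####): family pairing
        maternal = ScoreVector(
            pd.Series(
                preg.scores.to_numpy(),
                index=pd.Index([i.replace("M", "C", 1) for i in preg.sample_ids]),
            ),
            preg.set_name,
            preg.coverage,
            preg.time_point,
        )
        fits = birth_maternal_extension(
            audit, state.score("birth", largest), maternal, state.score("adolescence", largest)
        )
        tables["maternal_extension"] = results_table(fits, dependent="AUDIT at adolescence")

    manifest = {
        "package_version": __version__,
        "seed": run.seed,
        "config": dataclasses.asdict(run),
        "sample_flow": sample_flow,
        "paired_n": paired_ns,
        "skipped_contrasts": state.manifest.get("skipped_contrasts", []),
    }

    outdir = Path(run.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return tables
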