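"""Synthetic patient cohorts and the end-to-end prediction pipeline.

Two generative modes, each honest to a different stage of the analysis:

* ``generate_cohort_conditional`` draws the pCR label first and then every
  covariate from its class-conditional distribution — the structure a
  two-group comparison table describes (categorical conditionals, group
  means/SDs with an exchangeable correlation among related features).
  Feature vectors can alternatively be derived per patient from a simulated
  voxel sample run through the histogram stage ("voxel" mode), which makes
  every percentile feature internally consistent by construction.
* ``generate_cohort_logistic`` draws covariates marginally and the outcome
  from a logistic model with user-specified true coefficients — the mode for
  parameter-recovery and model-selection experiments.

``run_full_pipeline`` chains the whole statistical analysis on a cohort
table: categorical tests, feature comparisons, univariate screen, forward
stepwise multivariate logistic fit, ROC per predictor and for the combined
model, and DeLong comparisons of the combined model against each single
predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import stats as cs
from .histogram import compute_features

__all__ = [
    "CohortSpec",
    "default_cohort_spec",
    "generate_cohort_conditional",
    "generate_cohort_logistic",
    "run_full_pipeline",
    "CATEGORICAL_LEVELS",
]

#: Allowed levels per categorical column of a cohort table (reference first).
CATEGORICAL_LEVELS = {
    "er": ("negative", "positive"),
    "pr": ("negative", "positive"),
    "her2": ("negative", "positive"),
    "ki67": ("low", "high"),
    "menopause": ("premenopausal", "postmenopausal"),
    "grade": ("hg1-2", "hg3"),
    "node": ("negative", "positive"),
    "subtype": ("luminal_a", "luminal_b", "her2_enriched", "tn"),
    "response": ("non_pcr", "pcr"),
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``categorical_cond`` maps column -> {"pcr": p_or_probs, "non_pcr": ...}
    where a float is the probability of the non-reference level of a binary
    factor and a sequence is a multinomial over CATEGORICAL_LEVELS order.
    ``features`` maps column -> (mean_pcr, sd_pcr, mean_non_pcr, sd_non_pcr).
    ``rho`` is the exchangeable correlation among features within each block
    (blocks = common column prefix before the last underscore group, e.g. all
    ``mtr_*`` features form one block).  ``true_beta`` holds the generative
    log-odds for the logistic-outcome mode (key "intercept" plus one key per
    covariate column; binary factors count their non-reference level as 1).
    """

    n_patients: int = 108
    prevalence: float = 43.0 / 108.0
    categorical_cond: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    rho: float = 0.8
    true_beta: dict = field(default_factory=dict)
    feature_mode: str = "gaussian"   # "gaussian" | "voxel"
    voxels_per_patient: int = 400

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not -0.99 <= self.rho < 1.0:
            raise ValueError("rho must be in [-0.99, 1)")
        for col, cond in self.categorical_cond.items():
            for cls in ("pcr", "non_pcr"):
                p = cond[cls]
                arr = np.atleast_1d(np.asarray(p, dtype=float))
                if np.any(arr < 0) or np.any(arr > 1):
                    raise ValueError(f"probabilities for {col}/{cls} outside [0,1]")
        for col, (m1, s1, m0, s0) in self.features.items():
            if s1 <= 0 or s0 <= 0:
                raise ValueError(f"SDs for feature {col} must be > 0")
        if self.feature_mode not in ("gaussian", "voxel"):
            raise ValueError("feature_mode must be 'gaussian' or 'voxel'")


def default_cohort_spec(**overrides) -> CohortSpec:
    """Stock spec: a 108-patient two-arm cohort with the class-conditional
    categorical frequencies and group feature means/SDs of a typical breast
    NAC response study (43 pCR / 65 non-pCR).

    Features whose study summary is median (IQR) are approximated as normal
    with mean = median and sd = IQR / 1.349.
    """
    categorical = {
        "er": {"pcr": 11 / 43, "non_pcr": 43 / 65},
        "pr": {"pcr": 10 / 43, "non_pcr": 34 / 65},
        "her2": {"pcr": 26 / 43, "non_pcr": 14 / 65},
        "ki67": {"pcr": 42 / 43, "non_pcr": 54 / 65},
        "menopause": {"pcr": 23 / 43, "non_pcr": 32 / 65},
        "grade": {"pcr": 12 / 43, "non_pcr": 20 / 65},
        "node": {"pcr": 26 / 43, "non_pcr": 40 / 65},
        "subtype": {
            "pcr": (1 / 43, 11 / 43, 18 / 43, 13 / 43),
            "non_pcr": (3 / 65, 40 / 65, 5 / 65, 17 / 65),
        },
    }
    features = {
        "mtr_p5": (0.83, 2.22, -0.54, 2.62),
        "mtr_p10": (1.29, 2.05, 0.06, 2.23),
        "mtr_p15": (1.59, 1.94, 0.44, 2.03),
        "mtr_p25": (2.00, 1.80, 0.93, 1.89),
        "mtr_p50": (2.63, 1.63, 1.74, 1.77),
        "mtr_p75": (3.20, 1.55, 2.44, 1.78),
        "mtr_p85": (3.50, 1.56, 2.81, 1.84),
        "mtr_mean": (2.55, 1.69, 1.64, 1.82),
        "mtr_rms": (3.02, 1.17, 2.57, 1.15),
        "mtr_iqr": (1.04, 0.75 / 1.349, 1.35, 0.95 / 1.349),
        "adc_p1": (-0.15, 0.63 / 1.349, -0.36, 0.65 / 1.349),
        "adc_p10": (0.13, 0.76 / 1.349, 0.26, 0.74 / 1.349),
    }
    spec = CohortSpec(categorical_cond=categorical, features=features)
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# Generation helpers
# ---------------------------------------------------------------------------

def _feature_blocks(names: Sequence[str]) -> list:
    """Group feature columns by prefix (text before the first underscore)."""
    blocks: dict = {}
    for name in names:
        blocks.setdefault(name.split("_", 1)[0], []).append(name)
    return list(blocks.values())


def _exchangeable_normal(rng, n: int, k: int, rho: float) -> np.ndarray:
    """n draws of a k-variate standard normal with exchangeable correlation."""
    if k == 1 or rho == 0.0:
        return rng.standard_normal((n, k))
    shared = rng.standard_normal((n, 1))
    indiv = rng.standard_normal((n, k))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indiv


def _draw_categorical(rng, col: str, p, n: int) -> np.ndarray:
    levels = CATEGORICAL_LEVELS[col]
    arr = np.atleast_1d(np.asarray(p, dtype=float))
    if arr.size == 1:  # binary: p = P(non-reference level)
        draws = rng.random(n) < arr[0]
        return np.where(draws, levels[1], levels[0])
    probs = arr / arr.sum()
    idx = rng.choice(len(levels), size=n, p=probs)
    return np.asarray(levels, dtype=object)[idx]


def _voxel_features(rng, mean: float, sd: float, n_vox: int) -> dict:
    """One patient's feature vector from an explicit voxel sample.

    Voxels ~ N(mean, sd_vox) with a 0-20% colder subpopulation emulating
    residual unexcluded low-signal tissue; features then come from the
    histogram stage, so percentile order and the IQR identity hold exactly.
    """
    frac = rng.uniform(0.0, 0.2)
    n_cold = int(round(frac * n_vox))
    sd_vox = max(sd, 0.2)
    main = rng.normal(mean, sd_vox, n_vox - n_cold)
    cold = rng.normal(mean - 2.0 * sd_vox, 0.5 * sd_vox, n_cold)
    f = compute_features(np.concatenate([main, cold]))
    return f.as_dict()


def generate_cohort_conditional(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Draw labels first, then covariates conditional on the label."""
    rng = np.random.default_rng(seed)
    n = spec.n_patients
    label = rng.random(n) < spec.prevalence   # True = pCR
    df = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "response": np.where(label, "pcr", "non_pcr"),
    })
    for col, cond in spec.categorical_cond.items():
        vals = np.empty(n, dtype=object)
        for cls, m in (("pcr", label), ("non_pcr", ~label)):
            if m.any():
                vals[m] = _draw_categorical(rng, col, cond[cls], int(m.sum()))
        df[col] = vals
    feat_names = list(spec.features)
    if spec.feature_mode == "gaussian" and feat_names:
        z = np.empty((n, len(feat_names)))
        for block in _feature_blocks(feat_names):
            cols = [feat_names.index(b) for b in block]
            z[:, cols] = _exchangeable_normal(rng, n, len(block), spec.rho)
        for j, name in enumerate(feat_names):
            m1, s1, m0, s0 = spec.features[name]
            mu = np.where(label, m1, m0)
            sig = np.where(label, s1, s0)
            df[name] = mu + sig * z[:, j]
    elif spec.feature_mode == "voxel" and feat_names:
        rows = []
        for i in range(n):
            # class-conditional voxel distribution anchored on the mean feature
            key = "mtr_mean" if "mtr_mean" in spec.features else feat_names[0]
            m1, s1, m0, s0 = spec.features[key]
            mu, sig = (m1, s1) if label[i] else (m0, s0)
            patient_mu = rng.normal(mu, sig)
            rows.append(_voxel_features(rng, patient_mu, sig, spec.voxels_per_patient))
        fdf = pd.DataFrame(rows, index=df.index)
        keep = {
            "mtr_p5": "p5", "mtr_p10": "p10", "mtr_p15": "p15",
            "mtr_p25": "p25", "mtr_p50": "p50", "mtr_p75": "p75",
            "mtr_p85": "p85", "mtr_mean": "mean", "mtr_rms": "rms",
            "mtr_iqr": "iqr",
        }
        for out_col, feat in keep.items():
            df[out_col] = fdf[feat].to_numpy()
    return df


def generate_cohort_logistic(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Draw covariates marginally, then the outcome from the logistic model.

    Binary categoricals use the prevalence-weighted marginal of their
    class-conditional probabilities; features use the pooled mean and SD.
    ``spec.true_beta`` supplies the intercept and per-column log-odds (for a
    binary factor, the effect of its non-reference level).
    """
    if not spec.true_beta:
        raise ValueError("true_beta must be set for the logistic-outcome mode")
    if not all(np.isfinite(v) for v in spec.true_beta.values()):
        raise ValueError("true_beta values must be finite")
    rng = np.random.default_rng(seed)
    n = spec.n_patients
    w = spec.prevalence
    df = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})
    eta = np.full(n, float(spec.true_beta.get("intercept", 0.0)))
    for col, cond in spec.categorical_cond.items():
        p1 = np.atleast_1d(np.asarray(cond["pcr"], dtype=float))
        p0 = np.atleast_1d(np.asarray(cond["non_pcr"], dtype=float))
        marg = w * p1 + (1 - w) * p0
        df[col] = _draw_categorical(rng, col, marg if marg.size > 1 else marg[0], n)
        if col in spec.true_beta:
            ref = CATEGORICAL_LEVELS[col][0]
            eta = eta + spec.true_beta[col] * (df[col].to_numpy() != ref)
    for name, (m1, s1, m0, s0) in spec.features.items():
        mu = w * m1 + (1 - w) * m0
        sd = float(np.sqrt(w * s1**2 + (1 - w) * s0**2 + w * (1 - w) * (m1 - m0) ** 2))
        df[name] = rng.normal(mu, sd, n)
        if name in spec.true_beta:
            eta = eta + spec.true_beta[name] * df[name].to_numpy()
    df["response"] = np.where(rng.random(n) < expit(eta), "pcr", "non_pcr")
    return df


# ---------------------------------------------------------------------------
# Full statistical pipeline
# ---------------------------------------------------------------------------

def _binary_indicator(df: pd.DataFrame, col: str) -> np.ndarray:
    ref = CATEGORICAL_LEVELS[col][0]
    return (df[col].to_numpy() != ref).astype(float)


def run_full_pipeline(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    alpha_normality: float = 0.05,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    mc_reps: int = 20000,
    mc_seed: int = 0,
) -> dict:
    """Run the complete statistical analysis on a cohort table.

    Returns a dict of pandas DataFrames — ``categorical`` (per-factor test),
    ``features`` (per-feature group comparison), ``univariate`` (logistic
    screen of significant variables), ``multivariate`` (stepwise model
    terms), ``roc`` (per independent predictor + combined model),
    ``delong`` (combined vs each single predictor) — plus ``model`` (the
    fitted LogisticModel), ``n_tests`` (count of hypothesis tests run, since
    no multiplicity adjustment is applied) and ``warnings``.
    """
    if "response" not in cohort.columns:
        raise ValueError("cohort must contain a 'response' column")
    y = (cohort["response"].to_numpy() == "pcr").astype(float)
    if np.unique(y).size < 2:
        raise ValueError("cohort contains a single outcome class")
    notes: list = []
    if min(int(y.sum()), int((1 - y).sum())) < 20:
        notes.append("fewer than 20 patients in one class: model fit is fragile")

    cat_cols = [c for c in cohort.columns
                if c in CATEGORICAL_LEVELS and c != "response"]
    feat_cols = [c for c in cohort.columns
                 if c not in CATEGORICAL_LEVELS and c != "patient_id"
                 and pd.api.types.is_numeric_dtype(cohort[c])]
    n_tests = 0

    # -- categorical tests (Table-1-shaped) ---------------------------------
    cat_rows = []
    for col in cat_cols:
        levels = CATEGORICAL_LEVELS[col]
        counts = np.array([
            [int(np.sum((cohort[col] == lv) & (y == 1))),
             int(np.sum((cohort[col] == lv) & (y == 0)))]
            for lv in levels
        ])
        present = counts.sum(axis=1) > 0
        counts_p = counts[present]
        if counts_p.shape[0] < 2:
            continue
        n_tests += 1
        if counts_p.shape[0] == 2:
            t = cs.ContingencyTable2x2(*counts_p.ravel())
            try:
                res = cs.chi_square_2x2(t)
            except ValueError:
                cat_rows.append({"variable": col, "test": "none",
                                 "statistic": np.nan, "p": np.nan})
                continue
            if res.fisher_recommended:
                p = cs.fisher_exact_2x2(t)
                cat_rows.append({"variable": col, "test": "fisher",
                                 "statistic": np.nan, "p": p})
            else:
                cat_rows.append({
                    "variable": col,
                    "test": "chi2_yates" if res.correction_applied else "chi2",
                    "statistic": res.statistic, "p": res.p_value,
                })
        else:
            p, _ = cs.fisher_rxc_montecarlo(counts_p, reps=mc_reps, seed=mc_seed)
            cat_rows.append({"variable": col, "test": "fisher_mc",
                             "statistic": np.nan, "p": p})
    categorical = pd.DataFrame(cat_rows)

    # -- feature comparisons (Table-2-shaped) -------------------------------
    feat_rows = []
    for col in feat_cols:
        vals = cohort[col].to_numpy(dtype=float)
        res = cs.compare_groups(vals, y, alpha_normality=alpha_normality)
        n_tests += 1
        # summaries follow np.unique(label) order: 0.0 (non_pcr) first
        feat_rows.append({
            "feature": col, "test": res.test_used,
            "statistic": res.statistic, "p": res.p_value,
            "mean_non_pcr": res.summaries[0]["mean"],
            "mean_pcr": res.summaries[1]["mean"],
        })
    features = pd.DataFrame(feat_rows)

    # -- univariate logistic screen (Table-4-shaped, left half) -------------
    sig_cat = [r["variable"] for r in cat_rows
               if np.isfinite(r["p"]) and r["p"] < alpha
               and len(CATEGORICAL_LEVELS[r["variable"]]) == 2]
    sig_feat = [r["feature"] for r in feat_rows if r["p"] < alpha]
    uni_rows, candidates = [], {}
    for col in sig_cat + sig_feat:
        x = (_binary_indicator(cohort, col) if col in CATEGORICAL_LEVELS
             else cohort[col].to_numpy(dtype=float))
        n_tests += 1
        try:
            model = cs.univariate_logistic(x, y, name=col)
        except cs.SeparationError:
            notes.append(f"univariate fit for {col} did not converge (separation)")
            continue
        t = model.term(col)
        uni_rows.append({
            "variable": col, "beta": t.beta, "se": t.se, "z": t.z,
            "wald_chi2": t.wald_chi2, "p": t.p, "or": t.odds_ratio,
            "ci_low": t.ci_low, "ci_high": t.ci_high,
        })
        if t.p < alpha:
            candidates[col] = x
    univariate = pd.DataFrame(uni_rows)

    # -- stepwise multivariate model ----------------------------------------
    if candidates:
        import warnings as _w
        with _w.catch_warnings(record=True) as wl:
            _w.simplefilter("always")
            model = cs.stepwise_logistic(candidates, y,
                                         p_enter=p_enter, p_remove=p_remove)
        notes.extend(str(w.message) for w in wl)
    else:
        notes.append("no univariate candidate was significant; no model fitted")
        model = None
    multi_rows = []
    if model is not None:
        for t in model.terms:
            multi_rows.append({
                "variable": t.name, "beta": t.beta, "se": t.se, "z": t.z,
                "wald_chi2": t.wald_chi2, "p": t.p, "or": t.odds_ratio,
                "ci_low": t.ci_low, "ci_high": t.ci_high,
            })
    multivariate = pd.DataFrame(multi_rows)

    # -- ROC + DeLong (Tables 3/5-shaped) -----------------------------------
    roc_rows, delong_rows = [], []
    if model is not None and model.terms:
        X = np.column_stack([candidates[nm] for nm in model.term_names])
        combined = model.linear_predictor(X)
        scored = [(nm, candidates[nm]) for nm in model.term_names]
        scored.append(("combined_model", combined))
        for nm, s in scored:
            r = cs.roc_analysis(s, y)
            n_tests += 1
            roc_rows.append({
                "predictor": nm, "auc": r.auc, "se": r.se_delong,
                "ci_low": r.ci95[0], "ci_high": r.ci95[1],
                "cutoff": r.cutoff, "orientation": r.orientation,
                "sensitivity": r.sensitivity, "specificity": r.specificity,
                "accuracy": r.accuracy,
            })
        for nm in model.term_names:
            z, p = cs.delong_test(combined, candidates[nm], y)
            n_tests += 1
            delong_rows.append({"comparison": f"combined_vs_{nm}",
                                "z": z, "p": p})
    return {
        "categorical": categorical,
        "features": features,
        "univariate": univariate,
        "multivariate": multivariate,
        "roc": pd.DataFrame(roc_rows),
        "delong": pd.DataFrame(delong_rows),
        "model": model,
        "n_tests": n_tests,
        "warnings": tuple(notes),
    }
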