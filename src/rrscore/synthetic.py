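"""Synthetic longitudinal cohort generator with known latent ground truth.

Emulates a biennial aging-cohort visit table (one row per subject-visit,
static and time-varying predictors, raw gait and cognitive test results,
configurable missingness) generated from a known instance of the
reduced-rank model itself:

    theta = X_enc @ A_true          (latent composite score per visit)
    T     = theta @ B_true.T + E    (13 latent outcome targets, higher = worse)

The raw clinical columns are then obtained by inverting the outcome
derivation formulas, so that running the preprocessing stage on a
noise-free cohort recovers ``theta @ B_true.T`` exactly.  This makes
parameter recovery and pipeline behavior testable without any real data.

One subtlety of raw-data consistency: the two walking-dual conditions
(walk-while-subtracting, walk-while-box-checking) share the single
max-walk speed, so their four composites carry only three raw degrees of
freedom.  The generator therefore sets the ``cost_walk_box`` row of
``B_true`` (and its noise column) to the implied combination of the other
three, exactly as any cohort derived from raw measurements would.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .monotonic import cmo
from .preprocessing import (
    GAIT_PAIRS,
    OUTCOME_NAMES,
    OUTCOME_ORIENTATION,
    RAW_COGNITIVE_COLUMNS,
    RAW_GAIT_COLUMNS,
    TMT_A_CAP,
    TMT_B_CAP,
)

__all__ = [
    "PredictorSpec",
    "SimConfig",
    "TruthRecord",
    "GenerationError",
    "default_predictor_specs",
    "generate_cohort",
    "inject_missingness",
    "write_cohort",
    "encode_truth_design",
]


class GenerationError(RuntimeError):
    """Raised when raw-score inversion stays infeasible after bounded retries."""


@dataclass
class PredictorSpec:
    """Sampling recipe for one predictor.

    kind is one of ``continuous | binary | ordinal``; ordinals carry
    ``n_levels`` (categories ``0..n_levels-1``).  ``distribution_params``
    parameterizes the marginal: ``{"dist": "normal", "mean", "sd"}``,
    ``{"dist": "lognormal", "mean_log", "sd_log"}``, ``{"dist":
    "bernoulli", "p"}`` or ``{"dist": "categorical", "weights"}``.
    Continuous specs may add ``drift_per_visit`` (age advances 2 per
    biennial visit) and ``min`` (clip floor, e.g. pack-years at 0).
    """

    name: str
    kind: str
    n_levels: int | None = None
    time_varying: bool = False
    distribution_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "ordinal"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.kind == "ordinal":
            if self.n_levels is None or self.n_levels < 2:
                raise ValueError(f"ordinal predictor {self.name!r} needs n_levels >= 2")
        elif self.n_levels is not None:
            raise ValueError("n_levels only applies to ordinal predictors")


def default_predictor_specs() -> list[PredictorSpec]:
    """The default predictor roster of an older-adult observational cohort.

    Demographics and lifestyle (sex, education, age, BMI, skeletal muscle
    index, pack-years, physical-activity and alcohol-frequency ratings
    0-4), hypertension, serum neurofilament light chain (right-skewed),
    family history of PD/dementia, and genetic dose variables (GBA
    severity group, SNCA risk alleles, ApoE4 count, MAPT haplotype), all
    modeled as ordinals.
    """
    return [
        PredictorSpec("sex", "binary", distribution_params={"dist": "bernoulli", "p": 0.55}),
        PredictorSpec("education_years", "continuous",
                      distribution_params={"dist": "normal", "mean": 14.0, "sd": 3.0}),
        PredictorSpec("age", "continuous", time_varying=True,
                      distribution_params={"dist": "normal", "mean": 64.0, "sd": 7.0,
                                           "drift_per_visit": 2.0}),
        PredictorSpec("bmi", "continuous", time_varying=True,
                      distribution_params={"dist": "normal", "mean": 26.0, "sd": 4.0,
                                           "min": 15.0}),
        PredictorSpec("smi", "continuous", time_varying=True,
                      distribution_params={"dist": "normal", "mean": 9.5, "sd": 1.3,
                                           "min": 4.0}),
        PredictorSpec("pack_years", "continuous",
                      distribution_params={"dist": "normal", "mean": 8.0, "sd": 10.0,
                                           "min": 0.0}),
        PredictorSpec("nfl", "continuous", time_varying=True,
                      distribution_params={"dist": "lognormal", "mean_log": 3.1,
                                           "sd_log": 0.45}),
        PredictorSpec("hypertension", "binary",
                      distribution_params={"dist": "bernoulli", "p": 0.35}),
        PredictorSpec("relatives_pd_dementia", "ordinal", n_levels=3,
                      distribution_params={"dist": "categorical",
                                           "weights": [0.65, 0.25, 0.10]}),
        PredictorSpec("physical_activity", "ordinal", n_levels=5, time_varying=True,
                      distribution_params={"dist": "categorical",
                                           "weights": [0.15, 0.20, 0.25, 0.25, 0.15]}),
        PredictorSpec("alcohol_frequency", "ordinal", n_levels=5, time_varying=True,
                      distribution_params={"dist": "categorical",
                                           "weights": [0.25, 0.25, 0.20, 0.18, 0.12]}),
        PredictorSpec("gba_group", "ordinal", n_levels=3,
                      distribution_params={"dist": "categorical",
                                           "weights": [0.95, 0.037, 0.013]}),
        PredictorSpec("snca_risk_alleles", "ordinal", n_levels=3,
                      distribution_params={"dist": "categorical",
                                           "weights": [0.45, 0.42, 0.13]}),
        PredictorSpec("apoe4_count", "ordinal", n_levels=3,
                      distribution_params={"dist": "categorical",
                                           "weights": [0.72, 0.25, 0.03]}),
        PredictorSpec("mapt_haplotype", "ordinal", n_levels=3,
                      distribution_params={"dist": "categorical",
                                           "weights": [0.60, 0.33, 0.07]}),
    ]


@dataclass
class SimConfig:
    """Ground-truth generating conditions for one synthetic cohort."""

    n_subjects: int
    max_visits: int = 4
    predictor_specs: list[PredictorSpec] = field(default_factory=default_predictor_specs)
    true_rank: int = 1
    sparsity_fraction: float = 0.5
    effect_scale: float = 1.0
    noise_sd: float = 0.5
    missing_rate_predictors: float = 0.0
    missing_rate_outcomes: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.max_visits < 1:
            raise ValueError("max_visits must be >= 1")
        for rate in (self.sparsity_fraction, self.missing_rate_predictors,
                     self.missing_rate_outcomes, self.dropout_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        m = len(self.predictor_specs)
        if not 1 <= self.true_rank <= min(len(OUTCOME_NAMES), m):
            raise ValueError("true_rank must satisfy 1 <= k <= min(n_outcomes, n_predictors)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class TruthRecord:
    """The generating parameter values behind one synthetic cohort."""

    A_true: np.ndarray                      # m x k loadings (sparse)
    B_true: np.ndarray                      # n x k positive output mapping
    zeta_true: dict[str, np.ndarray]        # ordinal predictor -> simplex
    sigma_true: float
    theta_true: np.ndarray                  # j x k latent scores (emitted rows)
    offsets: dict[str, float]               # clinical-scale mean per outcome
    scales: dict[str, float]                # clinical-scale SD factor per outcome
    predictor_names: list[str]
    outcome_names: list[str]

    def targets_from_theta(self) -> np.ndarray:
        """Noise-free latent outcome targets ``theta @ B_true.T``."""
        return self.theta_true @ self.B_true.T

    def to_json(self, path) -> None:
        payload = {
            "A_true": self.A_true.tolist(),
            "B_true": self.B_true.tolist(),
            "zeta_true": {k: v.tolist() for k, v in self.zeta_true.items()},
            "sigma_true": self.sigma_true,
            "theta_true": self.theta_true.tolist(),
            "offsets": self.offsets,
            "scales": self.scales,
            "predictor_names": self.predictor_names,
            "outcome_names": self.outcome_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            A_true=np.asarray(payload["A_true"], dtype=float),
            B_true=np.asarray(payload["B_true"], dtype=float),
            zeta_true={k: np.asarray(v, dtype=float)
                       for k, v in payload["zeta_true"].items()},
            sigma_true=float(payload["sigma_true"]),
            theta_true=np.asarray(payload["theta_true"], dtype=float),
            offsets=payload["offsets"],
            scales=payload["scales"],
            predictor_names=payload["predictor_names"],
            outcome_names=payload["outcome_names"],
        )


# plausible clinical-scale means and SDs per outcome (higher-is-better raw
# scale for speeds/counts); walk-linked composites share one scale factor so
# the raw-score inversion stays exact (see module docstring)
_CLINICAL_MEAN = {
    "overall_walk_subtract": 3.55, "overall_subtract_walk": 0.75,
    "overall_walk_box": 3.65, "overall_box_walk": 1.75,
    "cost_walk_subtract": -0.45, "cost_subtract_walk": -0.15,
    "cost_walk_box": -0.35, "cost_box_walk": -0.25,
    "cerad_total": 90.0, "wordlist_learning": 21.0, "wordlist_recall": 7.0,
    "tmt_sum": 130.0, "tmt_diff": 55.0,
}
# SDs kept small enough relative to the distance of the implied raw speeds
# and TMT times from their physical bounds that the inversion is feasible
# for essentially every row (retries handle the tails when noise_sd > 0)
_CLINICAL_SD = {
    "overall_walk_subtract": 0.25, "overall_subtract_walk": 0.07,
    "overall_walk_box": 0.25, "overall_box_walk": 0.12,
    "cost_walk_subtract": 0.25, "cost_subtract_walk": 0.05,
    "cost_walk_box": 0.25, "cost_box_walk": 0.12,
    "cerad_total": 6.0, "wordlist_learning": 3.5, "wordlist_recall": 1.6,
    "tmt_sum": 12.0, "tmt_diff": 8.0,
}
# means must be raw-consistent: cost_walk_box = cost_walk_subtract +
# overall_walk_box - overall_walk_subtract
assert abs(_CLINICAL_MEAN["cost_walk_box"]
           - (_CLINICAL_MEAN["cost_walk_subtract"]
              + _CLINICAL_MEAN["overall_walk_box"]
              - _CLINICAL_MEAN["overall_walk_subtract"])) < 1e-12

_WALK_LINKED = ["overall_walk_subtract", "cost_walk_subtract",
                "overall_walk_box", "cost_walk_box"]
_IMPLIED = "cost_walk_box"
_MAX_RETRIES = 100


def _draw_raw_predictor(spec: PredictorSpec, size: int, rng, visit: int = 0):
    p = spec.distribution_params
    dist = p.get("dist")
    if dist == "normal":
        x = rng.normal(p["mean"] + p.get("drift_per_visit", 0.0) * visit, p["sd"], size)
        if "min" in p:
            x = np.maximum(x, p["min"])
        return x
    if dist == "lognormal":
        return rng.lognormal(p["mean_log"], p["sd_log"], size)
    if dist == "bernoulli":
        return rng.binomial(1, p["p"], size).astype(float)
    if dist == "categorical":
        w = np.asarray(p["weights"], dtype=float)
        return rng.choice(len(w), size=size, p=w / w.sum()).astype(float)
    raise ValueError(f"unknown distribution {dist!r} for predictor {spec.name!r}")


def _draw_predictor_table(config: SimConfig, rng) -> pd.DataFrame:
    """Raw predictor values, statics drawn once per subject."""
    n_visits = np.full(config.n_subjects, config.max_visits)
    if config.dropout_rate > 0:
        # geometric attrition: survive each follow-up visit independently
        for s in range(config.n_subjects):
            nv = 1
            while nv < config.max_visits and rng.random() > config.dropout_rate:
                nv += 1
            n_visits[s] = nv
    subj = np.repeat(np.arange(config.n_subjects), n_visits)
    visit = np.concatenate([np.arange(nv) for nv in n_visits])
    table = pd.DataFrame({"subject_id": subj, "visit_index": visit})
    j = len(table)
    for spec in config.predictor_specs:
        if spec.time_varying:
            if spec.name == "age" or "drift_per_visit" in spec.distribution_params:
                base = _draw_raw_predictor(spec, config.n_subjects, rng)[subj]
                drift = spec.distribution_params.get("drift_per_visit", 0.0)
                table[spec.name] = base + drift * visit
            else:
                table[spec.name] = _draw_raw_predictor(spec, j, rng)
        else:
            table[spec.name] = _draw_raw_predictor(spec, config.n_subjects, rng)[subj]
    return table


def encode_truth_design(table: pd.DataFrame, specs: list[PredictorSpec],
                        zeta_true: dict[str, np.ndarray]) -> np.ndarray:
    """Encode raw predictors the way the generative model sees them.

    Continuous columns are standardized against the realized cohort
    (empirical mean/SD), binaries stay 0/1, ordinals go through the
    cumulative monotonic transform with the true spacings.
    """
    cols = []
    for spec in specs:
        x = table[spec.name].to_numpy(dtype=float)
        if spec.kind == "continuous":
            sd = x.std(ddof=0)
            cols.append((x - x.mean()) / (sd if sd > 0 else 1.0))
        elif spec.kind == "binary":
            cols.append(x)
        else:
            cols.append(cmo(x.astype(int), zeta_true[spec.name]))
    return np.column_stack(cols)


def _draw_truth(config: SimConfig, rng) -> tuple[np.ndarray, np.ndarray, dict]:
    m, k, n = len(config.predictor_specs), config.true_rank, len(OUTCOME_NAMES)
    n_zero = int(round(config.sparsity_fraction * m * k))
    A = np.zeros((m, k))
    flat = rng.permutation(m * k)
    nonzero_idx = flat[n_zero:]
    signs = rng.choice([-1.0, 1.0], size=nonzero_idx.size)
    mags = config.effect_scale * rng.uniform(0.5, 1.5, size=nonzero_idx.size)
    A.flat[nonzero_idx] = signs * mags

    names = OUTCOME_NAMES
    implied_row = names.index(_IMPLIED)
    for _ in range(_MAX_RETRIES):
        B = np.exp(rng.normal(0.0, 0.25, size=(n, k)))
        # raw consistency: the implied composite's loading is determined
        B[implied_row] = (B[names.index("cost_walk_subtract")]
                          + B[names.index("overall_walk_box")]
                          - B[names.index("overall_walk_subtract")])
        if np.all(B[implied_row] > 0):
            break
    else:  # pragma: no cover - lognormal(0, .25) makes this astronomically rare
        raise GenerationError("could not draw a positive raw-consistent B_true")

    zeta_true = {
        spec.name: rng.dirichlet(np.ones(spec.n_levels - 1))
        for spec in config.predictor_specs if spec.kind == "ordinal"
    }
    return A, B, zeta_true


def _draw_noise(config: SimConfig, rng, j: int) -> np.ndarray:
    """Outcome-target noise; the implied column is the linear combination."""
    names = OUTCOME_NAMES
    E = rng.normal(0.0, config.noise_sd, size=(j, len(names)))
    E[:, names.index(_IMPLIED)] = (E[:, names.index("cost_walk_subtract")]
                                   + E[:, names.index("overall_walk_box")]
                                   - E[:, names.index("overall_walk_subtract")])
    return E


def _target_scales(noisy: np.ndarray) -> dict[str, float]:
    """Map latent targets onto clinical scales; walk-linked share a factor."""
    scales = {}
    sds = noisy.std(axis=0, ddof=0)
    for i, name in enumerate(OUTCOME_NAMES):
        scales[name] = _CLINICAL_SD[name] / sds[i] if sds[i] > 1e-9 else 1.0
    shared = scales["overall_walk_subtract"]
    for name in _WALK_LINKED:
        scales[name] = shared
    return scales


def _invert_outcomes(raw_derived: pd.DataFrame, rng, config: SimConfig,
                     targets: np.ndarray, scales: dict[str, float]) -> pd.DataFrame:
    """Solve raw clinical columns from clinical-scale derived outcomes.

    ``raw_derived`` holds the 13 derived outcomes on the clinical scale;
    rows violating physical feasibility (negative speeds, TMT caps) get
    their free noise resampled, bounded times.
    """
    j = len(raw_derived)
    out = pd.DataFrame(index=raw_derived.index)

    def gait_cols(frame):
        cols = {}
        for cond, (dual_col, single_col) in GAIT_PAIRS.items():
            o = frame[f"overall_{cond}"]
            c = frame[f"cost_{cond}"]
            cols[dual_col] = (o + c) / 2.0
            cols[single_col] = (o - c) / 2.0
        return cols

    cols = gait_cols(raw_derived)
    # the two walk pairs share the single max-walk column; by construction of
    # the implied target they agree, keep one
    tmt_a = (raw_derived["tmt_sum"] - raw_derived["tmt_diff"]) / 2.0
    tmt_b = (raw_derived["tmt_sum"] + raw_derived["tmt_diff"]) / 2.0

    feasible = np.ones(j, dtype=bool)
    for col in cols.values():
        feasible &= col.to_numpy() >= 0.0
    feasible &= (tmt_a.to_numpy() >= 0.0) & (tmt_a.to_numpy() <= TMT_A_CAP)
    feasible &= (tmt_b.to_numpy() >= 0.0) & (tmt_b.to_numpy() <= TMT_B_CAP)

    bad = np.flatnonzero(~feasible)
    names = OUTCOME_NAMES
    for row in bad:
        ok = False
        for _ in range(_MAX_RETRIES):
            e = _draw_noise(config, rng, 1)[0]
            vals = {}
            for i, name in enumerate(names):
                flip = OUTCOME_ORIENTATION[name]
                vals[name] = _CLINICAL_MEAN[name] + flip * scales[name] * (targets[row, i] + e[i])
            ta = (vals["tmt_sum"] - vals["tmt_diff"]) / 2.0
            tb = (vals["tmt_sum"] + vals["tmt_diff"]) / 2.0
            good = 0.0 <= ta <= TMT_A_CAP and 0.0 <= tb <= TMT_B_CAP
            for cond in GAIT_PAIRS:
                o, c = vals[f"overall_{cond}"], vals[f"cost_{cond}"]
                good &= (o + c) >= 0.0 and (o - c) >= 0.0
            if good:
                for name in names:
                    raw_derived.iloc[row, raw_derived.columns.get_loc(name)] = vals[name]
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"raw-score inversion infeasible for row {row} after {_MAX_RETRIES} retries; "
                "reduce noise_sd or effect_scale"
            )
    if bad.size:
        cols = gait_cols(raw_derived)
        tmt_a = (raw_derived["tmt_sum"] - raw_derived["tmt_diff"]) / 2.0
        tmt_b = (raw_derived["tmt_sum"] + raw_derived["tmt_diff"]) / 2.0

    for col_name, series in cols.items():
        out[col_name] = series
    out["tmt_a"] = tmt_a
    out["tmt_b"] = tmt_b
    for name in ("cerad_total", "wordlist_learning", "wordlist_recall"):
        out[name] = raw_derived[name]
    # habitual walk: measured but not part of any composite
    out["gait_single_walk_habitual"] = np.maximum(
        rng.normal(1.3, 0.2, size=j), 0.1)
    return out


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate a visit table plus the ground truth that produced it.

    Fully reproducible from ``config.seed``.  Missingness is injected last
    (see :func:`inject_missingness`), so a config with zero rates yields a
    complete table.
    """
    rng = np.random.default_rng(config.seed)
    table = _draw_predictor_table(config, rng)
    A, B, zeta_true = _draw_truth(config, rng)
    X = encode_truth_design(table, config.predictor_specs, zeta_true)
    theta = X @ A
    targets = theta @ B.T
    noise = _draw_noise(config, rng, len(table))
    noisy = targets + noise
    scales = _target_scales(noisy)

    derived = pd.DataFrame(index=table.index)
    for i, name in enumerate(OUTCOME_NAMES):
        flip = OUTCOME_ORIENTATION[name]
        derived[name] = _CLINICAL_MEAN[name] + flip * scales[name] * noisy[:, i]
    raw = _invert_outcomes(derived, rng, config, targets, scales)

    clinical_order = RAW_GAIT_COLUMNS + RAW_COGNITIVE_COLUMNS
    table = pd.concat([table, raw[clinical_order]], axis=1)
    truth = TruthRecord(
        A_true=A, B_true=B, zeta_true=zeta_true, sigma_true=config.noise_sd,
        theta_true=theta, offsets=dict(_CLINICAL_MEAN), scales=scales,
        predictor_names=[s.name for s in config.predictor_specs],
        outcome_names=list(OUTCOME_NAMES),
    )
    table = inject_missingness(table, config, rng=rng)
    if len(table) != len(theta):  # subjects dropped by the missingness guarantee
        truth.theta_true = theta[table.index.to_numpy()]
        table = table.reset_index(drop=True)
    return table, truth


def inject_missingness(table: pd.DataFrame, config: SimConfig,
                       rng=None) -> pd.DataFrame:
    """Mask predictor and raw-outcome cells independently at the configured rates.

    Every retained subject keeps at least one observed value per predictor
    (so downstream fill-imputation eligibility is exercised, not vacuous);
    when a subject's cells for some predictor are all masked, one is
    unmasked at random.  Subjects for which the guarantee cannot hold are
    dropped.
    """
    if not 0.0 <= config.missing_rate_predictors <= 1.0:
        raise ValueError("missing_rate_predictors must lie in [0, 1]")
    if not 0.0 <= config.missing_rate_outcomes <= 1.0:
        raise ValueError("missing_rate_outcomes must lie in [0, 1]")
    if config.missing_rate_predictors == 0.0 and config.missing_rate_outcomes == 0.0:
        return table
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    masked = table.copy()
    pred_cols = [s.name for s in config.predictor_specs]
    out_cols = RAW_GAIT_COLUMNS + RAW_COGNITIVE_COLUMNS

    drop_subjects: list = []
    if config.missing_rate_predictors > 0:
        for col in pred_cols:
            hit = rng.random(len(masked)) < config.missing_rate_predictors
            masked.loc[masked.index[hit], col] = np.nan
        for subject, grp in masked.groupby("subject_id", sort=False):
            for col in pred_cols:
                if grp[col].notna().any():
                    continue
                # unmask one randomly chosen visit that had an original value
                candidates = grp.index[table.loc[grp.index, col].notna()]
                if len(candidates) == 0:
                    drop_subjects.append(subject)
                    break
                pick = rng.choice(candidates)
                masked.loc[pick, col] = table.loc[pick, col]
    if config.missing_rate_outcomes > 0:
        for col in out_cols:
            hit = rng.random(len(masked)) < config.missing_rate_outcomes
            masked.loc[masked.index[hit], col] = np.nan
    if drop_subjects:
        warnings.warn(
            f"dropped {len(drop_subjects)} subject(s) that could not retain one "
            "value per predictor"
        )
        masked = masked[~masked["subject_id"].isin(drop_subjects)]
    return masked


def write_cohort(table: pd.DataFrame, truth: TruthRecord, csv_path, truth_path) -> None:
    """Write the visit table as tidy CSV (empty cells = missing) and the truth as JSON."""
    table.to_csv(csv_path, index=False)
    truth.to_json(truth_path)
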