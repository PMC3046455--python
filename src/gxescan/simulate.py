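"""Multi-study case-control cohort simulator.

Generates subject-level data with the statistical structure the scan
assumes: per-study populations of women with reproductive history and BMI,
genotypes drawn under Hardy-Weinberg equilibrium at configured risk-allele
frequencies, and disease status assigned by a multiplicative logistic model

    logit P(case) = study intercept
                  + sum_snp    log(OR_g) * dosage
                  + sum_factor log(OR_e) * coded factor value
                  + sum        log(OR_ge) * dosage * coded factor value

used generatively.  Case-control ascertainment is emulated by rejection:
population records are drawn, disease status sampled from the logistic
probability, and cases/controls accumulated until the per-study targets are
met.  Study intercepts are auto-calibrated so expected prevalence sits at a
configurable target inside a plausibility band, keeping rejection cheap.

Randomness contract: a single master seed spawns per-study, per-field
substreams (keyed by CRC-32 of the study label and field name), so adding a
study or a field never perturbs existing studies' draws, and a fixed seed
fixes the cohort byte-for-byte.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .catalog import SnpCatalog, SnpDef, default_catalog
from .cohort import BASE_COLUMNS
from .errors import ConfigError, GenerationError
from .factors import DEFAULT_FACTORS

#: population distribution defaults; every entry can be overridden per config
DEFAULT_FACTOR_PARAMS: dict[str, float] = {
    "age_mean": 56.0, "age_sd": 11.0, "age_min": 25.0, "age_max": 90.0,
    # age at menarche: 9 + Binomial(9, 4/9) -> support 9..18, mean 13
    "menarche_min": 9.0, "menarche_n": 9.0, "menarche_p": 4.0 / 9.0,
    "parous_p": 0.85,
    # age at first birth: rounded Normal(25, 4.5) clipped to [14, 45] and < age
    "afb_mean": 25.0, "afb_sd": 4.5, "afb_min": 14.0, "afb_max": 45.0,
    # live births among parous: 1 + Poisson(lambda), lambda by age-at-first-
    # birth band (<=19, 20-24, 25-29, >=30): earlier first birth, more births
    "births_lambda_le19": 1.6, "births_lambda_20_24": 1.3,
    "births_lambda_25_29": 0.9, "births_lambda_ge30": 0.6,
    "births_max": 12.0,
    # BMI: log-normal, median ~25.2 kg/m^2, rounded to 1 decimal
    "bmi_log_mean": math.log(25.2), "bmi_log_sd": 0.15,
    # centering constants for parous-only *main* effects: keeps the
    # ever-birth coefficient interpretable as the marginal parous contrast
    # (interaction terms always use raw factor values, as the fitted
    # models do)
    "center_n_births": 2.0, "center_age_first_birth": 25.0,
}

_FACTOR_OR_KEYS = ("menarche", "ever_birth", "n_births", "age_first_birth",
                   "bmi_lt55", "bmi_ge55", "age")


@dataclass(frozen=True)
class StudyArm:
    label: str
    n_cases: int
    n_controls: int
    population_based: bool = False

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigError(f"study {self.label}: arm sizes must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Full generative model for a multi-study case-control cohort."""

    studies: tuple[StudyArm, ...]
    catalog: SnpCatalog
    factor_params: dict[str, float] = field(default_factory=dict)
    main_effect_ors: dict[str, float] = field(default_factory=dict)
    interaction_ors: dict[tuple[str, str], float] = field(default_factory=dict)
    missingness: dict[str, float] = field(default_factory=dict)
    p_er_pos: float = 0.75
    p_pr_pos: float = 0.70
    er_dosage_ors: dict[str, float] = field(default_factory=dict)
    prevalence_target: float = 0.125
    prevalence_band: tuple[float, float] = (0.05, 0.20)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.studies:
            raise ConfigError("at least one study is required")
        labels = [s.label for s in self.studies]
        if len(set(labels)) != len(labels):
            raise ConfigError("study labels must be unique")
        for key in self.factor_params:
            if key not in DEFAULT_FACTOR_PARAMS:
                raise ConfigError(f"unknown factor_params key {key!r}")
        for key, or_ in self.main_effect_ors.items():
            if key not in _FACTOR_OR_KEYS:
                raise ConfigError(f"unknown main-effect factor {key!r}")
            if not or_ > 0:
                raise ConfigError(f"main effect OR for {key!r} must be > 0")
        for (snp_name, factor_name), or_ in self.interaction_ors.items():
            self.catalog.by_name(snp_name)
            if factor_name not in DEFAULT_FACTORS:
                raise ConfigError(f"unknown interaction factor {factor_name!r}")
            if not or_ > 0:
                raise ConfigError(
                    f"interaction OR for ({snp_name}, {factor_name}) must be > 0"
                )
        for key, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"missingness rate for {key!r} outside [0, 1]")
        for p in (self.p_er_pos, self.p_pr_pos):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("subtype probabilities must be in [0, 1]")
        lo, hi = self.prevalence_band
        if not 0.0 < lo < hi < 1.0:
            raise ConfigError("prevalence band must satisfy 0 < lo < hi < 1")
        if not lo <= self.prevalence_target <= hi:
            raise ConfigError(
                f"prevalence target {self.prevalence_target} outside band "
                f"[{lo}, {hi}]"
            )

    def param(self, key: str) -> float:
        return float(self.factor_params.get(key, DEFAULT_FACTOR_PARAMS[key]))

    # -- serialisation ----------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        if "studies" not in data:
            raise ConfigError("config missing required field 'studies'")
        if "catalog" not in data:
            raise ConfigError("config missing required field 'catalog'")
        studies = tuple(
            StudyArm(label=s["label"], n_cases=int(s["n_cases"]),
                     n_controls=int(s["n_controls"]),
                     population_based=bool(s.get("population_based", False)))
            for s in data["studies"]
        )
        cat_spec = data["catalog"]
        if cat_spec == "default":
            catalog = default_catalog()
        else:
            catalog = SnpCatalog.from_records(cat_spec)
        if "snp_ors" in data:
            by_name = dict(data["snp_ors"])
            snps = []
            for s in catalog:
                or_ = float(by_name.pop(s.name, s.per_allele_or))
                snps.append(SnpDef(s.name, s.alleles, s.risk_allele,
                                   s.risk_allele_freq, s.gene_label, or_))
            if by_name:
                raise ConfigError(f"snp_ors refers to unknown SNPs: {sorted(by_name)}")
            catalog = SnpCatalog(snps)
        interactions = {
            (i["snp"], i["factor"]): float(i["or"])
            for i in data.get("interaction_ors", [])
        }
        subtype = data.get("subtype", {})
        return cls(
            studies=studies,
            catalog=catalog,
            factor_params={k: float(v)
                           for k, v in data.get("factor_params", {}).items()},
            main_effect_ors={k: float(v)
                             for k, v in data.get("main_effect_ors", {}).items()},
            interaction_ors=interactions,
            missingness={k: float(v)
                         for k, v in data.get("missingness", {}).items()},
            p_er_pos=float(subtype.get("p_er_pos", 0.75)),
            p_pr_pos=float(subtype.get("p_pr_pos", 0.70)),
            er_dosage_ors={k: float(v)
                           for k, v in subtype.get("er_dosage_ors", {}).items()},
            prevalence_target=float(data.get("prevalence_target", 0.125)),
            prevalence_band=tuple(data.get("prevalence_band", (0.05, 0.20))),
            seed=data.get("seed"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_sim_config() -> SimConfig:
    """The packaged 21-study consortium-like demo configuration."""
    text = resources.files("gxescan.data").joinpath(
        "demo_consortium_config.json").read_text()
    return SimConfig.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# random substreams

def _stream(seed: int, study: str, fieldname: str) -> np.random.Generator:
    key = [int(seed), zlib.crc32(study.encode()), zlib.crc32(fieldname.encode())]
    return np.random.default_rng(np.random.SeedSequence(key))


def draw_genotypes(freq: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Dosages 0/1/2 under Hardy-Weinberg: P = ((1-q)^2, 2q(1-q), q^2)."""
    if not 0.0 <= freq <= 1.0:
        raise ConfigError(f"allele frequency {freq} outside [0, 1]")
    return rng.binomial(2, freq, size=n).astype(np.int64)


# ---------------------------------------------------------------------------
# the generative linear predictor

def _eta_no_intercept(cov: dict[str, np.ndarray], config: SimConfig) -> np.ndarray:
    """Linear predictor minus the study intercept, on complete covariates."""
    n = len(cov["age"])
    eta = np.zeros(n)
    for snp in config.catalog:
        b = math.log(snp.per_allele_or)
        if b != 0.0:
            eta += b * cov[f"dosage:{snp.name}"]

    parous = cov["parous"].astype(float)
    age = cov["age"].astype(float)
    lt55 = (age < 55.0).astype(float)

    def factor_value(name: str, centered: bool) -> np.ndarray:
        if name == "menarche":
            return cov["menarche_age"].astype(float)
        if name == "ever_birth":
            return parous
        if name == "n_births":
            c = config.param("center_n_births") if centered else 0.0
            return np.where(parous == 1.0, cov["n_live_births"] - c, 0.0)
        if name == "age_first_birth":
            c = config.param("center_age_first_birth") if centered else 0.0
            return np.where(parous == 1.0, cov["age_first_birth"] - c, 0.0)
        if name == "bmi_lt55":
            return cov["bmi"] * lt55
        if name == "bmi_ge55":
            return cov["bmi"] * (1.0 - lt55)
        if name == "age":
            return age - 50.0
        raise ConfigError(f"unknown factor {name!r}")

    # main effects of parous-only factors are centered at a typical parous
    # woman, so the ever-birth coefficient stays a marginal parous contrast;
    # interaction products use raw values, matching the analysis models
    for name, or_ in config.main_effect_ors.items():
        b = math.log(or_)
        if b != 0.0:
            eta += b * factor_value(name, centered=True)
    for (snp_name, factor_name), or_ in config.interaction_ors.items():
        b = math.log(or_)
        if b != 0.0:
            eta += b * cov[f"dosage:{snp_name}"] * factor_value(
                factor_name, centered=False)
    return eta


def disease_logit(records: pd.DataFrame, config: SimConfig,
                  study_intercepts: dict[str, float]) -> np.ndarray:
    """Generative log-odds of disease for complete-covariate records.

    ``records`` uses the cohort column schema with dosage columns named by
    rsID.  Raises :class:`ConfigError` for an unknown study label.
    """
    for label in records["study"].unique():
        if label not in study_intercepts:
            raise ConfigError(f"no intercept for unknown study {label!r}")
    cov = {
        "age": records["age"].to_numpy(dtype=float),
        "menarche_age": records["menarche_age"].to_numpy(dtype=float),
        "parous": records["parous"].to_numpy(dtype=float),
        "n_live_births": records["n_live_births"].to_numpy(dtype=float, na_value=0.0),
        "age_first_birth": records["age_first_birth"].to_numpy(dtype=float,
                                                               na_value=0.0),
        "bmi": records["bmi"].to_numpy(dtype=float),
    }
    for snp in config.catalog:
        cov[f"dosage:{snp.name}"] = records[snp.rsid].to_numpy(dtype=float)
    intercept = records["study"].map(study_intercepts).to_numpy(dtype=float)
    return intercept + _eta_no_intercept(cov, config)


# ---------------------------------------------------------------------------
# population draws

def _draw_covariates(config: SimConfig, n: int,
                     gens: dict[str, np.random.Generator]) -> dict[str, np.ndarray]:
    p = config.param
    age = np.clip(np.rint(gens["age"].normal(p("age_mean"), p("age_sd"), n)),
                  p("age_min"), p("age_max"))
    menarche = p("menarche_min") + gens["menarche"].binomial(
        int(p("menarche_n")), p("menarche_p"), n)
    parous = (gens["parous"].random(n) < p("parous_p")).astype(float)

    afb = np.clip(np.rint(gens["afb"].normal(p("afb_mean"), p("afb_sd"), n)),
                  p("afb_min"), p("afb_max"))
    afb = np.minimum(afb, age - 1.0)
    lam = np.select(
        [afb <= 19, afb <= 24, afb <= 29],
        [p("births_lambda_le19"), p("births_lambda_20_24"),
         p("births_lambda_25_29")],
        default=p("births_lambda_ge30"),
    )
    births = np.minimum(1.0 + gens["births"].poisson(lam), p("births_max"))
    # parity fields are structurally absent for nulliparous women
    afb = np.where(parous == 1.0, afb, np.nan)
    births = np.where(parous == 1.0, births, np.nan)

    bmi = np.round(gens["bmi"].lognormal(p("bmi_log_mean"), p("bmi_log_sd"), n), 1)

    cov = {"age": age, "menarche_age": menarche.astype(float), "parous": parous,
           "age_first_birth": afb, "n_live_births": births, "bmi": bmi}
    for snp in config.catalog:
        cov[f"dosage:{snp.name}"] = draw_genotypes(
            snp.risk_allele_freq, n, gens[f"geno:{snp.name}"]).astype(float)
    return cov


def _complete(cov: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Zero-fill structural NaNs for linear-predictor evaluation."""
    out = dict(cov)
    out["n_live_births"] = np.nan_to_num(cov["n_live_births"])
    out["age_first_birth"] = np.nan_to_num(cov["age_first_birth"])
    return out


def _calibrate_intercept(config: SimConfig, study: str, seed: int) -> float:
    """Solve for the study intercept putting expected prevalence on target."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(study.encode()),
                                zlib.crc32(b"calibration")]))
    gens = {k: rng for k in ("age", "menarche", "parous", "afb", "births", "bmi")}
    gens.update({f"geno:{s.name}": rng for s in config.catalog})
    cov = _draw_covariates(config, 4000, gens)
    eta = _eta_no_intercept(_complete(cov), config)
    target = config.prevalence_target

    def gap(c: float) -> float:
        return float(np.mean(expit(c + eta))) - target

    try:
        return brentq(gap, -40.0, 40.0, xtol=1e-10)
    except ValueError as exc:  # pragma: no cover - requires absurd config
        raise GenerationError(
            f"study {study}: cannot calibrate intercept to prevalence {target}"
        ) from exc


# ---------------------------------------------------------------------------
# case-control sampling

_MAX_BATCHES = 200

_FIELDS = ("age", "menarche", "parous", "afb", "births", "bmi")


def _sample_study(config: SimConfig, study: StudyArm, seed: int) -> pd.DataFrame:
    gens = {f: _stream(seed, study.label, f) for f in _FIELDS}
    for snp in config.catalog:
        gens[f"geno:{snp.name}"] = _stream(seed, study.label, f"geno:{snp.name}")
    disease = _stream(seed, study.label, "disease")

    intercept = _calibrate_intercept(config, study.label, seed)
    prev = config.prevalence_target
    batch = int(min(max(1.3 * max(study.n_cases / prev,
                                  study.n_controls / (1.0 - prev)), 2000), 500_000))

    need_cases, need_controls = study.n_cases, study.n_controls
    case_rows: list[dict[str, np.ndarray]] = []
    control_rows: list[dict[str, np.ndarray]] = []
    for _ in range(_MAX_BATCHES):
        if need_cases == 0 and need_controls == 0:
            break
        cov = _draw_covariates(config, batch, gens)
        eta = intercept + _eta_no_intercept(_complete(cov), config)
        is_case = disease.random(batch) < expit(eta)
        take_case = np.flatnonzero(is_case)[:need_cases]
        take_ctrl = np.flatnonzero(~is_case)[:need_controls]
        if take_case.size:
            case_rows.append({k: v[take_case] for k, v in cov.items()})
            need_cases -= take_case.size
        if take_ctrl.size:
            control_rows.append({k: v[take_ctrl] for k, v in cov.items()})
            need_controls -= take_ctrl.size
        batch = min(batch, 100_000)
    else:
        raise GenerationError(
            f"study {study.label}: could not reach targets "
            f"({need_cases} cases / {need_controls} controls short) within the "
            f"attempt budget"
        )

    def stack(rows: list[dict[str, np.ndarray]], is_case_val: int) -> pd.DataFrame:
        merged = {k: np.concatenate([r[k] for r in rows]) for k in rows[0]}
        n = len(merged["age"])
        out = pd.DataFrame({
            "study": np.repeat(study.label, n),
            "is_case": np.repeat(is_case_val, n),
            "age": merged["age"].astype(np.int64),
            "menarche_age": merged["menarche_age"],
            "parous": merged["parous"],
            "n_live_births": merged["n_live_births"],
            "age_first_birth": merged["age_first_birth"],
            "bmi": merged["bmi"],
        })
        for snp in config.catalog:
            out[snp.rsid] = merged[f"dosage:{snp.name}"]
        return out

    df = pd.concat([stack(case_rows, 1), stack(control_rows, 0)],
                   ignore_index=True)

    # ER/PR subtype for cases only
    subtype = _stream(seed, study.label, "subtype")
    er = np.full(len(df), None, dtype=object)
    pr = np.full(len(df), None, dtype=object)
    cases = df["is_case"].to_numpy() == 1
    n_cases = int(cases.sum())
    er_logit = logit(config.p_er_pos) * np.ones(n_cases)
    for snp_name, or_ in config.er_dosage_ors.items():
        snp = config.catalog.by_name(snp_name)
        er_logit = er_logit + math.log(or_) * df.loc[cases, snp.rsid].to_numpy()
    er[cases] = np.where(subtype.random(n_cases) < expit(er_logit),
                         "positive", "negative")
    pr[cases] = np.where(subtype.random(n_cases) < config.p_pr_pos,
                         "positive", "negative")
    df["er"] = er
    df["pr"] = pr

    # observational missingness (structural parity NaNs already in place)
    miss = _stream(seed, study.label, "missing")
    col_rates = [("menarche_age", config.missingness.get("menarche_age", 0.0)),
                 ("parous", config.missingness.get("parous", 0.0)),
                 ("n_live_births", config.missingness.get("n_live_births", 0.0)),
                 ("age_first_birth", config.missingness.get("age_first_birth", 0.0)),
                 ("bmi", config.missingness.get("bmi", 0.0))]
    dosage_rate = config.missingness.get("dosage", 0.0)
    col_rates += [(snp.rsid, dosage_rate) for snp in config.catalog]
    for col, rate in col_rates:
        if rate > 0.0:
            drop = miss.random(len(df)) < rate
            df.loc[drop, col] = np.nan
    # a missing parous flag hides the dependent parity fields too
    hidden = df["parous"].isna()
    df.loc[hidden, ["n_live_births", "age_first_birth"]] = np.nan

    for col in ("menarche_age", "parous", "n_live_births", "age_first_birth"):
        df[col] = df[col].astype(float).round().astype("Int64")
    for snp in config.catalog:
        df[snp.rsid] = df[snp.rsid].astype(float).round().astype("Int64")
    return df


def sample_case_control(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a full multi-study case-control cohort.

    The seed (argument, falling back to ``config.seed``) fully determines
    the output.  Within each study, cases precede controls in draw order.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ConfigError("a seed is required (argument or config.seed)")
    frames = [_sample_study(config, study, int(seed)) for study in config.studies]
    df = pd.concat(frames, ignore_index=True)
    cols = list(BASE_COLUMNS) + [snp.rsid for snp in config.catalog]
    return df[cols]


def study_intercepts(config: SimConfig, seed: int) -> dict[str, float]:
    """The calibrated per-study intercepts implied by a config and seed."""
    return {s.label: _calibrate_intercept(config, s.label, int(seed))
            for s in config.studies}
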