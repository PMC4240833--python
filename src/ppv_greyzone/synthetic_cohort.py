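"""Synthetic ICU cohorts with the statistical structure of the pooled
fluid-challenge population.

The generator emulates a 556-patient mixed-ICU cohort: ~48% fluid
responders, group-specific marker distributions (PPV 15 +/- 9 vs 9 +/- 7
%, CVP 9 +/- 5 vs 11 +/- 4 mmHg, baseline stroke volume 60 +/- 21 vs 74
+/- 27 ml, and the ventilator variables), per-variable missingness
matching the published available-n, and a nine-centre mixture. Each
continuous marker is drawn from a lower-truncated normal whose TRUNCATED
mean and SD equal the configured values (underlying parameters are
solved by moment matching), so the published group summaries are
reproduced exactly in expectation despite physiologic truncation at 0.

ΔSV is drawn from invented label-consistent mixtures (the source tables
report only the responder dichotomy): responders from N(25, 10) restricted
to >= 15%, non-responders from N(5, 6) restricted to < 15%; stroke volume
after the challenge is set accordingly, so re-deriving the responder
label from stroke volumes reproduces the drawn label exactly.

Variables are sampled independently within outcome group (the published
summaries carry no covariance information); an optional Gaussian-copula
hook makes this limitation explicit and extensible. Every column draws
from its own seeded substream keyed by (seed, column name), so adding a
variable does not perturb existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from . import cohort_model
from .cohort_model import Cohort, build_cohort
from scipy.stats import rankdata

__all__ = [
    "GeneratorConfig",
    "CohortSummary",
    "default_config",
    "generate_cohort",
    "summarize",
    "expected_binormal_auc",
    "truncated_normal_params",
    "truncated_marker_oracle",
]


@dataclass
class GroupDist:
    """Target (mean, sd) per outcome group for one marker, with an optional
    lower truncation bound interpreted on the truncated distribution."""

    responder: tuple[float, float]
    nonresponder: tuple[float, float]
    lower: Optional[float] = None


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n: int = 556
    prevalence: float = 0.48
    markers: dict = field(default_factory=dict)
    # ΔSV mixtures as PARENT normal parameters, truncated to the label side
    delta_sv_responder: tuple[float, float] = (25.0, 10.0)
    delta_sv_nonresponder: tuple[float, float] = (5.0, 6.0)
    missingness: dict = field(default_factory=dict)
    centres: list = field(default_factory=list)  # (label, weight)
    female_fraction: float = 197 / 556
    vasopressor_rate: float = 249 / 556
    integer_markers: tuple = ("ppv", "cvp")
    copula_corr: Optional[np.ndarray] = None  # optional across-marker correlation
    copula_markers: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n < 1:
            raise ValueError("n must be positive")
        for name, dist in self.markers.items():
            for mu, sd in (dist.responder, dist.nonresponder):
                if sd <= 0:
                    raise ValueError(f"non-positive scale for marker {name}")
                if dist.lower is not None and mu <= dist.lower:
                    raise ValueError(f"mean below truncation bound for {name}")
        for name, rate in self.missingness.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missingness rate for {name} outside [0, 1]")
        if self.centres:
            w = sum(w for _, w in self.centres)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"centre weights sum to {w}, not 1")
        if self.copula_corr is not None:
            c = np.asarray(self.copula_corr, float)
            if c.shape != (len(self.copula_markers),) * 2:
                raise ValueError("copula_corr shape must match copula_markers")
            np.linalg.cholesky(c)  # must be positive definite

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["markers"] = {k: asdict(v) for k, v in self.markers.items()}
        if d["copula_corr"] is not None:
            d["copula_corr"] = np.asarray(d["copula_corr"]).tolist()
        d["integer_markers"] = list(d["integer_markers"])
        d["copula_markers"] = list(d["copula_markers"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["markers"] = {
            k: GroupDist(
                responder=tuple(v["responder"]),
                nonresponder=tuple(v["nonresponder"]),
                lower=v.get("lower"),
            )
            for k, v in d.get("markers", {}).items()
        }
        for key in ("integer_markers", "copula_markers"):
            if key in d:
                d[key] = tuple(d[key])
        d["centres"] = [tuple(c) for c in d.get("centres", [])]
        if d.get("copula_corr") is not None:
            d["copula_corr"] = np.asarray(d["copula_corr"], float)
        return cls(**d)


#: n = 556 study population; per-variable missing counts out of 556 are
#: back-calculated from the published available-n per variable.
_TABLE_MARKERS = {
    "age": GroupDist((58, 18), (56, 17), lower=18),
    "height": GroupDist((169, 9), (169, 9), lower=120),
    "weight": GroupDist((72, 15), (75, 17), lower=30),
    "ppv": GroupDist((15, 9), (9, 7), lower=0),
    "cvp": GroupDist((9, 5), (11, 4), lower=0),
    "sv_pre": GroupDist((60, 21), (74, 27), lower=10),
    "hr": GroupDist((91, 24), (88, 25), lower=30),
    "map": GroupDist((73, 15), (75, 16), lower=30),
    "rr": GroupDist((19, 6), (19, 6), lower=6),
    "vt_per_ibw": GroupDist((7.4, 2.3), (7.6, 2.6), lower=2),
    "peep": GroupDist((6, 5), (7, 5), lower=0),
    "pplat": GroupDist((19.3, 5.5), (20.7, 5.8), lower=5),
    "pf_ratio": GroupDist((185, 107), (182, 103), lower=40),
}

_MISSINGNESS = {
    "cvp": 150 / 556,
    "pf_ratio": 306 / 556,
    "pplat": 126 / 556,
    "rr": 63 / 556,
    "vt": 37 / 556,
    "peep": 36 / 556,
}

#: Nine-centre mixture; the three smallest centres fall under the
#: pooling rule (fewer than 70 patients at n = 556).
_CENTRES = [
    ("Nimes", 0.20),
    ("Tours", 0.18),
    ("Bordeaux", 0.15),
    ("Orleans", 0.14),
    ("Strasbourg", 0.13),
    ("Nantes", 0.13),
    ("Amiens", 0.03),
    ("Lyon", 0.02),
    ("Paris", 0.02),
]


def default_config() -> GeneratorConfig:
    """The study conditions: n = 556, prevalence 0.48, published group
    moments, published per-variable missingness, nine-centre mixture."""
    return GeneratorConfig(
        markers={k: GroupDist(v.responder, v.nonresponder, v.lower) for k, v in _TABLE_MARKERS.items()},
        missingness=dict(_MISSINGNESS),
        centres=list(_CENTRES),
    )


# ---------------------------------------------------------------------------
# truncated-normal machinery

@lru_cache(maxsize=256)
def truncated_normal_params(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Underlying (mu, sigma) of a lower-truncated normal whose truncated
    mean and SD equal the targets.

    Solved numerically; requires sd < mean - lower (the one-sided
    truncated family cannot exceed unit coefficient of variation above
    the bound). When the bound is > 6 target-SDs below the mean the
    truncation is negligible and the targets are returned unchanged.
    """
    if (mean - lower) / sd > 6.0:
        return mean, sd
    if sd >= mean - lower:
        raise ValueError(
            f"unattainable truncated moments: sd {sd} >= mean - lower {mean - lower}"
        )

    def moments(params):
        mu, log_sig = params
        sig = np.exp(log_sig)
        a = (lower - mu) / sig
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sig, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(moments, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"moment matching failed for ({mean}, {sd}, {lower}): {sol.message}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float, lower: Optional[float]) -> np.ndarray:
    """Inverse-CDF sampling of the moment-matched truncated normal."""
    if lower is None:
        return stats.norm.ppf(u, loc=mean, scale=sd)
    mu, sig = truncated_normal_params(mean, sd, lower)
    a = (lower - mu) / sig
    return stats.truncnorm.ppf(u, a, np.inf, loc=mu, scale=sig)


def expected_binormal_auc(mu1: float, sd1: float, mu0: float, sd0: float) -> float:
    """Closed-form AUC of an untruncated binormal marker: Phi(d / sqrt(s1^2+s0^2))."""
    if sd1 <= 0 or sd0 <= 0:
        raise ValueError("scales must be positive")
    return float(stats.norm.cdf((mu1 - mu0) / np.hypot(sd1, sd0)))


def truncated_marker_oracle(
    config: GeneratorConfig, marker: str, n_draws: int = 10**6, seed: int = 12345
):
    """Monte-Carlo oracle for one marker's group distributions.

    Returns (auc, (q10_responders, q90_nonresponders)) computed from
    large independent draws of the configured truncated normals: the
    truncation-adjusted expected AUC and the analytic 10%-tolerance zone
    (rule-out bound = responders' 10th percentile, rule-in bound =
    non-responders' 90th percentile) for a higher-predicts-responder
    marker. Used only as an independent check of the generator.
    """
    dist = config.markers[marker]
    rng = np.random.default_rng(seed)
    x1 = _truncnorm_ppf(rng.random(n_draws), *dist.responder, dist.lower)
    x0 = _truncnorm_ppf(rng.random(n_draws), *dist.nonresponder, dist.lower)
    if marker in config.integer_markers:
        x1, x0 = np.round(x1), np.round(x0)
    r = rankdata(np.concatenate([x1, x0]))
    auc = (r[:n_draws].sum() - n_draws * (n_draws + 1) / 2) / (n_draws * n_draws)
    zone = (float(np.quantile(x1, 0.10)), float(np.quantile(x0, 0.90)))
    return float(auc), zone


# ---------------------------------------------------------------------------
# generation

def _col_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def generate_cohort(config: Optional[GeneratorConfig] = None) -> Cohort:
    """Draw one synthetic cohort; deterministic under ``config.seed``."""
    config = config or default_config()
    config.validate()
    n = config.n
    seed = config.seed

    responder = _col_rng(seed, "responder").random(n) < config.prevalence
    sex = np.where(_col_rng(seed, "sex").random(n) < config.female_fraction, "F", "M")
    if config.centres:
        labels = [c for c, _ in config.centres]
        weights = [w for _, w in config.centres]
        centre = _col_rng(seed, "centre").choice(labels, size=n, p=weights)
    else:
        centre = np.full(n, "synthetic")

    # uniform draws per marker; optionally correlated through a Gaussian copula
    uniforms: dict[str, np.ndarray] = {}
    if config.copula_corr is not None:
        chol = np.linalg.cholesky(np.asarray(config.copula_corr, float))
        z = _col_rng(seed, "copula").standard_normal((len(config.copula_markers), n))
        u = stats.norm.cdf(chol @ z)
        uniforms.update(dict(zip(config.copula_markers, u)))
    for name in config.markers:
        if name not in uniforms:
            uniforms[name] = _col_rng(seed, name).random(n)

    cols: dict[str, np.ndarray] = {}
    for name, dist in config.markers.items():
        if name == "pplat":
            continue  # handled conditionally on PEEP below
        x = np.empty(n)
        u = uniforms[name]
        x[responder] = _truncnorm_ppf(u[responder], *dist.responder, dist.lower)
        x[~responder] = _truncnorm_ppf(u[~responder], *dist.nonresponder, dist.lower)
        if name in config.integer_markers:
            x = np.round(x)
        cols[name] = x

    # plateau pressure: configured distribution truncated below at each
    # patient's own PEEP (physical constraint pplat >= peep)
    if "pplat" in config.markers:
        dist = config.markers["pplat"]
        u = uniforms["pplat"]
        floor = np.maximum(cols["peep"], dist.lower if dist.lower is not None else -np.inf)
        pplat = np.empty(n)
        for grp, params in ((responder, dist.responder), (~responder, dist.nonresponder)):
            mu, sig = truncated_normal_params(*params, dist.lower)
            a = (floor[grp] - mu) / sig
            pplat[grp] = stats.truncnorm.ppf(u[grp], a, np.inf, loc=mu, scale=sig)
        cols["pplat"] = pplat

    # ΔSV consistent with the drawn label (parent normals, one-sided cut at 15%)
    t = cohort_model.RESPONDER_THRESHOLD_PCT
    u = _col_rng(seed, "delta_sv").random(n)
    delta = np.empty(n)
    mu, sd = config.delta_sv_responder
    delta[responder] = stats.truncnorm.ppf(u[responder], (t - mu) / sd, np.inf, loc=mu, scale=sd)
    mu, sd = config.delta_sv_nonresponder
    delta[~responder] = stats.truncnorm.ppf(u[~responder], -np.inf, (t - mu) / sd, loc=mu, scale=sd)

    sv_pre = cols["sv_pre"]
    sv_post = sv_pre * (1.0 + delta / 100.0)
    # guard against float round-trip flipping the label at the 15% boundary
    rederived = 100.0 * (sv_post - sv_pre) / sv_pre >= t - cohort_model._BOUNDARY_EPS
    flip = rederived != responder
    if flip.any():
        sv_post[flip] = np.where(
            responder[flip], sv_pre[flip] * (1 + t / 100), sv_pre[flip] * (1 + (t - 0.01) / 100)
        )

    ibw = np.where(sex == "M", 50.0, 45.5) + 0.91 * (cols["height"] - 152.4)
    vt = cols["vt_per_ibw"] * ibw
    vaso = _col_rng(seed, "vasopressor").random(n) < config.vasopressor_rate

    df = pd.DataFrame(
        {
            "patient_id": [f"synth-{i:04d}" for i in range(n)],
            "centre": centre,
            "age": cols["age"],
            "sex": sex,
            "height_cm": cols["height"],
            "weight_kg": cols["weight"],
            "ppv_pct": cols["ppv"],
            "pp_max_mmhg": np.nan,
            "pp_min_mmhg": np.nan,
            "cvp_mmhg": cols["cvp"],
            "sv_pre_ml": sv_pre,
            "sv_post_ml": sv_post,
            "hr_bpm": cols["hr"],
            "map_mmhg": cols["map"],
            "rr_cpm": cols["rr"],
            "vt_ml": vt,
            "peep_cmh2o": cols["peep"],
            "pplat_cmh2o": cols["pplat"],
            "pf_ratio": cols["pf_ratio"],
            "ppv_method": "synthetic",
            "vasopressor": vaso,
            "arrhythmia": False,
            "spontaneous_breathing": False,
            "suspected_iap": False,
            "poor_echogenicity": False,
        }
    )

    col_map = {
        "cvp": "cvp_mmhg",
        "pf_ratio": "pf_ratio",
        "pplat": "pplat_cmh2o",
        "rr": "rr_cpm",
        "vt": "vt_ml",
        "peep": "peep_cmh2o",
        "ppv": "ppv_pct",
    }
    for name, rate in config.missingness.items():
        if rate == 0:
            continue
        mask = _col_rng(seed, f"missing:{name}").random(n) < rate
        df.loc[mask, col_map.get(name, name)] = np.nan

    return build_cohort(df)


# ---------------------------------------------------------------------------
# summaries

@dataclass
class CohortSummary:
    """Per-group mean/SD/available-n table plus the responder fraction."""

    table: pd.DataFrame
    n: int
    n_responders: int
    responder_fraction: float


_SUMMARY_VARS = [
    "age",
    "height_cm",
    "weight_kg",
    "ibw_kg",
    "hr_bpm",
    "map_mmhg",
    "rr_cpm",
    "vt_per_ibw",
    "peep_cmh2o",
    "pplat_cmh2o",
    "driving_pressure",
    "cst_rs",
    "hr_rr",
    "pf_ratio",
    "cvp_mmhg",
    "sv_pre_ml",
    "ppv_pct",
]


def summarize(cohort: Cohort, variables: Optional[list[str]] = None) -> CohortSummary:
    """Group summary in the style of a baseline-characteristics table."""
    df = cohort.df
    variables = variables or [v for v in _SUMMARY_VARS if v in df.columns]
    labelled = df[df["responder"].notna()]
    resp = labelled[labelled["responder"].astype(bool)]
    nonresp = labelled[~labelled["responder"].astype(bool)]
    rows = []
    for var in variables:
        rows.append(
            {
                "variable": var,
                "responder_mean": resp[var].mean(),
                "responder_sd": resp[var].std(),
                "responder_n": int(resp[var].notna().sum()),
                "nonresponder_mean": nonresp[var].mean(),
                "nonresponder_sd": nonresp[var].std(),
                "nonresponder_n": int(nonresp[var].notna().sum()),
            }
        )
    n_resp = len(resp)
    return CohortSummary(
        table=pd.DataFrame(rows),
        n=len(df),
        n_responders=n_resp,
        responder_fraction=n_resp / len(labelled) if len(labelled) else float("nan"),
    )
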