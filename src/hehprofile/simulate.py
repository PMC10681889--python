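"""Synthetic HeH cohort generation.

Patient-level data behind published HeH risk validations are not public, so
this module generates cohorts with the statistical structure the classifier
and the survival validation assume:

* ISCN karyotype strings with modal number 51–67 and non-random chromosome
  gains (weighted toward X, 4, 6, 10, 14, 17, 18 and 21, with 21 allowed
  twice), whose 5/17/18/20 trisomy pattern realises a requested risk class;
* a configurable rate of classification ambiguity (``+mar`` substitution and
  ``inc`` truncation) plus contaminant records (Ph-positive, masked doubled
  hypodiploidy, non-HeH);
* clinical covariates (age band, sex, white-cell count, end-of-induction MRD)
  with marginals matching a large multi-trial HeH cohort;
* three time-to-event endpoints (relapse, any event, death) under exact
  proportional hazards: exponential (optionally Weibull) event times whose
  good-risk 5-year cumulative risk and poor-risk hazard ratio are
  configuration parameters, censored by uniform trial entry over a 4-year
  accrual window with a 10-year administrative horizon (median follow-up
  8 years).

Everything is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import PROFILE_CHROMOSOMES, RiskRule
from .iscn import CHROMOSOMES

__all__ = [
    "CohortConfig",
    "generate_karyotype",
    "simulate_endpoints",
    "generate_cohort",
    "write_cohort",
    "ENDPOINTS",
]

ENDPOINTS: tuple[str, ...] = ("relapse", "event", "death")

#: Marginal gain weights for HeH karyotype synthesis, excluding the four
#: profile chromosomes (those are forced by the requested risk class).
#: Weighted toward the classic HeH gains; "21b" is the second copy of +21.
DEFAULT_GAIN_WEIGHTS: dict[str, float] = {
    "21": 0.99, "X": 0.85, "14": 0.80, "6": 0.78, "4": 0.70, "10": 0.55,
    "21b": 0.50, "8": 0.30, "2": 0.10, "3": 0.10, "9": 0.08, "11": 0.06,
    "12": 0.06, "13": 0.05, "16": 0.05, "22": 0.10, "1": 0.04, "7": 0.04,
    "15": 0.04, "19": 0.04,
}

_ISCN_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}


def _default_group_mix() -> dict[str, float]:
    return {
        "GR": 0.64,
        "PR": 0.22,
        "not_heh": 0.10,
        "ph_positive": 0.02,
        "masked_doubled": 0.02,
    }


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults emulate the published multi-trial HeH validation cohort: a
    74/26 GR/PR split among HeH cases, ~27% of karyotypes carrying ``+mar``
    or ``inc`` ambiguity, 5-year good-risk cumulative risks of 6% (relapse),
    9% (any event) and 5% (death), and poor-risk hazard ratios of 3.52,
    2.80 and 3.21 respectively; MRD is independent of risk group unless
    ``mrd_group_shift`` (a log10 location shift in the PR arm) is set.
    """

    n: int = 1169
    seed: int = 0
    group_mix: dict = field(default_factory=_default_group_mix)
    mar_rate: float = 0.17
    inc_rate: float = 0.12
    gain_weights: dict = field(default_factory=lambda: dict(DEFAULT_GAIN_WEIGHTS))
    hr: dict = field(
        default_factory=lambda: {"relapse": 3.52, "event": 2.80, "death": 3.21}
    )
    baseline_5yr_risk: dict = field(
        default_factory=lambda: {"relapse": 0.06, "event": 0.09, "death": 0.05}
    )
    horizon_years: float = 10.0
    accrual_years: float = 4.0
    weibull_shape: float = 1.0
    # covariate marginals (age bands 1-9 / 10-14 / 15-24 / 25+)
    age_band_probs: tuple = (0.78, 0.09, 0.09, 0.04)
    sex_male_prob: float = 0.53
    wcc_band_probs: tuple = (0.91, 0.06, 0.03)
    mrd_log10_mean: float = -4.71
    mrd_log10_sd: float = 1.36
    mrd_group_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size n must be positive")
        total = sum(self.group_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group_mix must sum to 1 (got {total})")
        for r in (self.mar_rate, self.inc_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("ambiguity rates must lie in [0, 1]")
        if any(h <= 0 for h in self.hr.values()):
            raise ValueError("hazard ratios must be positive")
        for ep, risk in self.baseline_5yr_risk.items():
            if not 0.0 < risk < 1.0:
                raise ValueError(
                    f"baseline 5-year risk for {ep!r} must lie in (0, 1), got {risk}"
                )


_AGE_BANDS = (("1-9", 1.0, 10.0), ("10-14", 10.0, 15.0),
              ("15-24", 15.0, 25.0), ("25+", 25.0, 60.0))
_WCC_BANDS = (("0-49", 0.5, 50.0), ("50-99", 50.0, 100.0), ("100+", 100.0, 300.0))

_MODAL_CHOICES = np.arange(51, 61)
_MODAL_WEIGHTS = np.array([4, 6, 8, 10, 10, 9, 7, 4, 2, 1], dtype=float)
_MODAL_WEIGHTS /= _MODAL_WEIGHTS.sum()

_DEFAULT_RULE = RiskRule.default()


def _profile_combo(rule: RiskRule, target: str, rng: np.random.Generator) -> dict[str, bool]:
    combos = [bits for bits, cls in rule.table.items() if cls == target]
    g5, g17, g18, g20 = combos[rng.integers(len(combos))]
    return {"5": g5, "17": g17, "18": g18, "20": g20}


def generate_karyotype(
    cfg: CohortConfig,
    rng: np.random.Generator,
    target: str,
    sex: str = "XX",
    rule: RiskRule | None = None,
    max_tries: int = 50,
) -> str:
    """Generate one ISCN karyotype string realising ``target``.

    ``target`` is one of ``GR`` / ``PR`` (HeH with the requested decision-table
    class), ``not_heh``, ``ph_positive`` or ``masked_doubled``.  For HeH
    targets the string classifies to the definite target class, softened to
    the provisional class when ``+mar``/``inc`` ambiguity is injected (the
    baseline resolution preserves the intended polarity by construction).
    """
    rule = rule or _DEFAULT_RULE
    if target == "not_heh":
        templates = (f"46,{sex}[20]", f"47,{sex},+21[20]", f"48,{sex},+X,+21[20]")
        return templates[rng.integers(len(templates))]
    if target == "masked_doubled":
        k = int(rng.integers(5, 8))
        autos = sorted(
            rng.choice(np.arange(1, 23), size=k, replace=False).tolist()
        )
        gains = ",".join(f"+{a},+{a}" for a in autos)
        return f"{46 + 2 * k},{sex},{gains}[20]"

    pattern_class = "GR" if target in ("GR", "ph_positive") else "PR"
    for _ in range(max_tries):
        combo = _profile_combo(rule, pattern_class, rng)
        forced = [c for c in PROFILE_CHROMOSOMES if combo[c]]
        modal = int(rng.choice(_MODAL_CHOICES, p=_MODAL_WEIGHTS))
        n_extra = modal - 46 - len(forced)
        if n_extra < 1:
            continue
        pool = list(cfg.gain_weights)
        if n_extra > len(pool):
            continue
        w = np.array([cfg.gain_weights[c] for c in pool], dtype=float)
        picked = rng.choice(len(pool), size=n_extra, replace=False, p=w / w.sum())
        extras = [pool[i].rstrip("b") for i in picked]
        gains = sorted(forced + extras, key=lambda c: _ISCN_ORDER[c])
        tokens = [f"+{c}" for c in gains]

        if target == "ph_positive":
            tokens = ["t(9;22)(q34;q11)"] + tokens
        else:
            non_profile = [i for i, c in enumerate(gains) if c not in PROFILE_CHROMOSOMES]
            suffix = ""
            add_mar = False
            if non_profile and rng.random() < cfg.mar_rate:
                j = non_profile.pop(rng.integers(len(non_profile)))
                del tokens[j]
                non_profile = [i - 1 if i > j else i for i in non_profile]
                add_mar = True  # +mar written last, per convention
            if non_profile and rng.random() < cfg.inc_rate:
                idx = non_profile[rng.integers(len(non_profile))]
                del tokens[idx]
                suffix = ",inc"
            if add_mar:
                tokens.append("+mar")
            return f"{modal},{sex}," + ",".join(tokens) + suffix + "[20]"
        return f"{modal},{sex}," + ",".join(tokens) + "[20]"
    raise RuntimeError(
        f"could not generate a karyotype for target {target!r} "
        f"after {max_tries} attempts"
    )


def simulate_endpoints(
    cfg: CohortConfig, groups: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate the three endpoints for an array of merged-group labels.

    Event times follow a Weibull proportional-hazards model (shape 1 =
    exponential) with the good-risk 5-year cumulative risk and the PR/GR
    hazard ratio taken from the configuration; one shared trial-entry time
    per patient yields administrative censoring uniform on
    [horizon − accrual, horizon] years.
    """
    groups = np.asarray(groups)
    n = len(groups)
    k = cfg.weibull_shape
    entry = rng.uniform(0.0, cfg.accrual_years, size=n)
    censor = cfg.horizon_years - entry
    out = {}
    is_pr = groups == "PR"
    for ep in ENDPOINTS:
        risk = cfg.baseline_5yr_risk[ep]
        lam = -np.log1p(-risk) / 5.0**k
        mult = np.where(is_pr, cfg.hr[ep], 1.0)
        u = rng.uniform(size=n)
        t = (-np.log(u) / (lam * mult)) ** (1.0 / k)
        out[f"{ep}_time"] = np.minimum(t, censor)
        out[f"{ep}_ind"] = (t <= censor).astype(int)
    return pd.DataFrame(out)


def generate_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Generate a full synthetic cohort as a DataFrame.

    Columns: ``id``, ``karyotype``, the latent ``intended_group`` (kept for
    test oracles; stripped from the main CSV by :func:`write_cohort`),
    covariates, and time/indicator pairs for relapse, event and death.
    Deterministic under a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = list(cfg.group_mix)
    probs = np.array([cfg.group_mix[k] for k in labels], dtype=float)
    intended = rng.choice(labels, size=cfg.n, p=probs / probs.sum())

    sex = np.where(rng.uniform(size=cfg.n) < cfg.sex_male_prob, "XY", "XX")
    karyotypes = [
        generate_karyotype(cfg, rng, target=t, sex=s)
        for t, s in zip(intended, sex)
    ]

    band_idx = rng.choice(len(_AGE_BANDS), size=cfg.n, p=np.array(cfg.age_band_probs))
    age = np.array(
        [rng.uniform(_AGE_BANDS[i][1], _AGE_BANDS[i][2]) for i in band_idx]
    ).round(1)
    wcc_idx = rng.choice(len(_WCC_BANDS), size=cfg.n, p=np.array(cfg.wcc_band_probs))
    wcc = np.array(
        [rng.uniform(_WCC_BANDS[i][1], _WCC_BANDS[i][2]) for i in wcc_idx]
    ).round(1)

    hazard_group = np.where(intended == "PR", "PR", "GR")
    shift = np.where(intended == "PR", cfg.mrd_group_shift, 0.0)
    log_mrd = rng.normal(cfg.mrd_log10_mean + shift, cfg.mrd_log10_sd, size=cfg.n)
    mrd = np.minimum(10.0**log_mrd, 0.5)

    df = pd.DataFrame(
        {
            "id": [f"P{i + 1:05d}" for i in range(cfg.n)],
            "karyotype": karyotypes,
            "intended_group": intended,
            "age_years": age,
            "sex": np.where(sex == "XY", "Male", "Female"),
            "wcc": wcc,
            "mrd": mrd,
        }
    )
    df = pd.concat([df, simulate_endpoints(cfg, hazard_group, rng)], axis=1)
    return df


def write_cohort(
    df: pd.DataFrame,
    path: str | Path,
    header_lines: list[str] | None = None,
) -> Path:
    """Write the cohort CSV, placing the latent labels in a sidecar file.

    The main CSV omits ``intended_group`` so validation cannot silently use
    the generator's truth; labels go to ``<stem>.labels.csv``.  Optional
    ``header_lines`` are written as ``#``-prefixed comments.
    """
    path = Path(path)
    visible = df.drop(columns=["intended_group"], errors="ignore")
    _write_csv(visible, path, header_lines)
    if "intended_group" in df.columns:
        sidecar = path.with_name(path.stem + ".labels.csv")
        _write_csv(df[["id", "intended_group"]], sidecar, header_lines)
    return path


def _write_csv(df: pd.DataFrame, path: Path, header_lines: list[str] | None) -> None:
    with open(path, "w", newline="") as f:
        for line in header_lines or []:
            f.write(f"# {line}\n")
        df.to_csv(f, index=False)
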