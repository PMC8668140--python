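"""Synthetic per-subject data with known ("planted") structure.

The study's per-animal raw data are unpublished, so every pipeline stage
is exercised on synthetic cohorts whose generative truth is known:

* **Fos counts** — per condition, n subjects are drawn from a
  multivariate Gaussian over the 11 regions whose marginal means/SDs are
  calibrated to the published group means (+/- SEM) for that condition
  and sex, and whose correlation matrix carries user-planted region-pair
  correlations (identity elsewhere), repaired to the nearest positive
  definite correlation matrix. Draws are left-censored at 0 (counts
  cannot be negative); the censoring fraction is reported because it
  biases low-mean regions (e.g. SON) upward.
* **Drinking** — day-1 intake from sex-specific per-kg baselines
  (females drink more per kg); day-2 intake equals day-1 times a
  dose-dependent expected D2/D1 suppression (non-increasing in LiCl
  dose) times multiplicative noise.
* **USVs** — a two-part model per channel: a subject-level emitter
  probability (many animals do not vocalize at all) and, for emitters,
  overdispersed per-minute negative-binomial call counts with
  condition- and sex-specific rates.
* **Nausea** — each 15-s block score is an ordinal cut of a latent
  normal whose mean increases with LiCl dose.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import BLOCKS_PER_EPOCH, SESSION_EPOCHS
from .io import FosCountTable
from .registries import ConditionRegistry, RegionRegistry, SEXES

__all__ = [
    "FOS_CALIBRATION",
    "CALIBRATION_N",
    "calibration_means",
    "calibration_sds",
    "make_correlation_target",
    "SyntheticFosConfig",
    "simulate_fos",
    "SyntheticBehaviorConfig",
    "simulate_behavior",
    "InfeasibleTargetWarning",
]

# ---------------------------------------------------------------------------
# calibration fixture: published per-group Fos means +/- SEM
# (mean Fos+ cells per image), by region x condition x sex.

_CAL_ROWS = {
    #          AN            AB            AL            COT           BOT           BLT
    #        F      M      F      M      F      M      F      M      F      M      F      M
    "vmPFC": [(244, 37), (229, 72), (244, 20), (239, 33), (266, 41), (272, 51),
              (246, 37), (241, 32), (268, 52), (212, 31), (249, 44), (221, 43)],
    "aIC":   [(183, 32), (187, 40), (198, 20), (215, 22), (212, 50), (206, 27),
              (232, 32), (193, 14), (223, 31), (176, 26), (227, 21), (174, 24)],
    "gIC5/6": [(100, 38), (87, 44), (197, 29), (178, 77), (206, 44), (206, 70),
               (81, 45), (86, 26), (162, 53), (145, 23), (144, 55), (99, 72)],
    "gIC4":  [(134, 66), (85, 28), (262, 23), (253, 82), (255, 23), (267, 89),
              (148, 82), (98, 64), (225, 69), (184, 27), (121, 45), (79, 43)],
    "NAcC":  [(91, 30), (98, 35), (133, 7), (98, 20), (100, 62), (109, 29),
              (110, 1), (76, 18), (123, 26), (99, 34), (101, 21), (64, 29)],
    "NAcS":  [(117, 39), (123, 36), (125, 19), (107, 33), (171, 78), (141, 68),
              (120, 26), (90, 17), (153, 38), (113, 41), (124, 52), (118, 52)],
    "SON":   [(7, 5), (14, 8), (11, 9), (10, 12), (112, 34), (112, 3),
              (10, 10), (2, 1), (21, 6), (27, 27), (5, 2), (45, 70)],
    "BLA":   [(34, 8), (32, 8), (56, 16), (53, 8), (67, 25), (58, 15),
              (52, 19), (24, 5), (61, 10), (42, 3), (52, 6), (41, 15)],
    "CeA":   [(44, 22), (42, 26), (133, 40), (108, 33), (191, 73), (199, 58),
              (30, 7), (42, 60), (142, 19), (115, 60), (62, 48), (48, 28)],
    "PVN":   [(113, 51), (103, 26), (122, 51), (143, 29), (230, 102), (226, 96),
              (95, 36), (107, 28), (91, 20), (74, 45), (141, 39), (134, 70)],
    "VTA":   [(63, 17), (50, 13), (84, 30), (92, 16), (93, 29), (52, 15),
              (63, 22), (69, 15), (118, 22), (66, 30), (83, 13), (51, 9)],
}

_CAL_ORDER = [(c, s) for c in ("AN", "AB", "AL", "COT", "BOT", "BLT") for s in SEXES]

#: (region, condition, sex) -> (mean, sem)
FOS_CALIBRATION: Mapping[tuple[str, str, str], tuple[float, float]] = {
    (region, cond, sex): cells[k]
    for region, cells in _CAL_ROWS.items()
    for k, (cond, sex) in enumerate(_CAL_ORDER)
}

#: Per-region group sizes used to turn SEM into SD (SD = SEM * sqrt(n)).
#: The published per-group n is only given as figure-legend ranges; these
#: are the range midpoints (rounded), with 4 where no range is stated.
CALIBRATION_N: Mapping[str, int] = {
    "vmPFC": 4, "aIC": 4, "gIC5/6": 6, "gIC4": 4, "NAcC": 4, "NAcS": 4,
    "SON": 4, "BLA": 4, "CeA": 6, "PVN": 6, "VTA": 4,
}


def calibration_means(condition: str, sex: str, regions: Sequence[str]) -> np.ndarray:
    return np.array([FOS_CALIBRATION[(r, condition, sex)][0] for r in regions], dtype=float)


def calibration_sds(condition: str, sex: str, regions: Sequence[str]) -> np.ndarray:
    return np.array(
        [
            FOS_CALIBRATION[(r, condition, sex)][1] * np.sqrt(CALIBRATION_N[r])
            for r in regions
        ],
        dtype=float,
    )


# ---------------------------------------------------------------------------
# correlation targets

MIN_EIGENVALUE = 1e-8


class InfeasibleTargetWarning(UserWarning):
    """PD repair moved a planted correlation by more than the tolerance."""


def make_correlation_target(
    regions: Sequence[str],
    planted_edges: Sequence[tuple[str, str, float]],
    min_eig: float = MIN_EIGENVALUE,
    warn_tol: float = 0.05,
) -> tuple[np.ndarray, dict]:
    """Unit-diagonal correlation matrix with planted entries, repaired to PD.

    Starts from the identity, sets each planted (a, b, r), then — if the
    matrix is not positive definite — clips eigenvalues at ``min_eig`` and
    rescales to unit diagonal, iterating until PD. Returns the matrix and
    a report of achieved values and deviations; a deviation larger than
    ``warn_tol`` raises :class:`InfeasibleTargetWarning`.
    """
    regions = list(regions)
    k = len(regions)
    target = np.eye(k)
    for a, b, r in planted_edges:
        if not -1 < r < 1:
            raise ValueError(f"planted correlation must be in (-1, 1), got {r}")
        i, j = regions.index(a), regions.index(b)
        if i == j:
            raise ValueError(f"cannot plant a self-edge on {a}")
        target[i, j] = target[j, i] = r

    mat = target.copy()
    for _ in range(200):
        w, v = np.linalg.eigh(mat)
        if w.min() >= min_eig:
            break
        w = np.clip(w, min_eig, None)
        mat = (v * w) @ v.T
        d = np.sqrt(np.diag(mat))
        mat = mat / np.outer(d, d)
        np.fill_diagonal(mat, 1.0)
        mat = (mat + mat.T) / 2.0
    else:
        raise RuntimeError("positive-definite repair did not converge")

    deviations = {}
    for a, b, r in planted_edges:
        i, j = regions.index(a), regions.index(b)
        deviations[(a, b)] = float(mat[i, j] - r)
    max_dev = max((abs(d) for d in deviations.values()), default=0.0)
    if max_dev > warn_tol:
        warnings.warn(
            f"planted correlations infeasible as a set; largest repair shift {max_dev:.3f}",
            InfeasibleTargetWarning,
        )
    report = {
        "planted": [(a, b, float(r)) for a, b, r in planted_edges],
        "achieved": {f"{a}|{b}": float(mat[regions.index(a), regions.index(b)]) for a, b, _ in planted_edges},
        "deviations": {f"{a}|{b}": d for (a, b), d in deviations.items()},
        "max_deviation": max_dev,
        "min_eigenvalue": float(np.linalg.eigvalsh(mat).min()),
    }
    return mat, report


# ---------------------------------------------------------------------------
# Fos cohorts


@dataclass
class SyntheticFosConfig:
    """Configuration of the synthetic Fos cohort.

    ``planted_edges`` maps condition -> list of (region_a, region_b, r).
    ``n_per_condition`` is the number of subjects per condition (sexes
    alternate F, M, F, M ... so groups are balanced); 8 by default, i.e.
    4 per sex, consistent with the published per-sex group sizes of 3-9.
    ``means``/``sds`` override the calibration defaults per
    (condition, sex) with arrays in region order.
    """

    regions: tuple[str, ...] = field(default_factory=lambda: RegionRegistry().regions)
    conditions: tuple[str, ...] = field(
        default_factory=lambda: ConditionRegistry().conditions
    )
    planted_edges: Mapping[str, Sequence[tuple[str, str, float]]] = field(default_factory=dict)
    n_per_condition: int | Mapping[str, int] = 8
    means: Mapping[tuple[str, str], np.ndarray] | None = None
    sds: Mapping[tuple[str, str], np.ndarray] | None = None
    sex_shift: float = 0.0  # additive F-minus-M mean shift, in SD units
    seed: int = 0

    def n_for(self, condition: str) -> int:
        if isinstance(self.n_per_condition, Mapping):
            return int(self.n_per_condition[condition])
        return int(self.n_per_condition)

    def mean_vector(self, condition: str, sex: str) -> np.ndarray:
        if self.means is not None:
            return np.asarray(self.means[(condition, sex)], dtype=float)
        return calibration_means(condition, sex, self.regions)

    def sd_vector(self, condition: str, sex: str) -> np.ndarray:
        if self.sds is not None:
            return np.asarray(self.sds[(condition, sex)], dtype=float)
        return calibration_sds(condition, sex, self.regions)


def simulate_fos(config: SyntheticFosConfig) -> tuple[FosCountTable, dict]:
    """Draw a per-subject Fos count table plus ground-truth metadata.

    Returns ``(table, truth)`` where ``truth`` records, per condition, the
    repaired target correlation matrix, planted-edge report, and the
    fraction of draws left-censored at 0.
    """
    rng = np.random.default_rng(config.seed)
    regions = list(config.regions)
    k = len(regions)
    rows = []
    truth: dict = {"seed": int(config.seed), "conditions": {}}
    for cond in config.conditions:
        n = config.n_for(cond)
        if n < 3:
            raise ValueError(f"need n >= 3 per condition, got {n} for {cond}")
        corr, report = make_correlation_target(regions, config.planted_edges.get(cond, ()))
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((n, k)) @ chol.T
        sexes = [SEXES[i % 2] for i in range(n)]
        mu = np.stack([config.mean_vector(cond, s) for s in sexes])
        sd = np.stack([config.sd_vector(cond, s) for s in sexes])
        if config.sex_shift:
            shift = np.array([1.0 if s == "F" else 0.0 for s in sexes])[:, None]
            mu = mu + config.sex_shift * sd * shift
        x = mu + sd * z
        censored = x < 0
        x = np.where(censored, 0.0, x)
        for i in range(n):
            sid = f"{cond}{i + 1:02d}"
            for j, region in enumerate(regions):
                rows.append(
                    {
                        "subject_id": sid,
                        "sex": sexes[i],
                        "condition": cond,
                        "region": region,
                        "fos_count": float(x[i, j]),
                    }
                )
        truth["conditions"][cond] = {
            "n": n,
            "target_correlation": corr.tolist(),
            "planted": report,
            "censored_fraction": {
                region: float(censored[:, j].mean()) for j, region in enumerate(regions)
            },
        }
    table = FosCountTable(pd.DataFrame(rows))
    return table, truth


# ---------------------------------------------------------------------------
# behavioral cohorts

#: expected D2/D1 by LiCl dose (mg/kg); non-increasing in dose.
DEFAULT_DOSE_SUPPRESSION: Mapping[float, float] = {0.0: 1.0, 19.0: 0.6, 38.0: 0.35, 80.0: 0.15}

#: subject-level probability of emitting on each channel, per (condition, sex):
#: anticipation of the reward drives 55 kHz calls (highest in BOT), pairing
#: with LiCl recruits 22 kHz warning calls, more so in females.
DEFAULT_P_EMIT_55: Mapping[tuple[str, str], float] = {
    ("COT", "F"): 0.30, ("COT", "M"): 0.15,
    ("BOT", "F"): 0.45, ("BOT", "M"): 0.55,
    ("BLT", "F"): 0.40, ("BLT", "M"): 0.35,
}
DEFAULT_P_EMIT_22: Mapping[tuple[str, str], float] = {
    ("COT", "F"): 0.25, ("COT", "M"): 0.05,
    ("BOT", "F"): 0.20, ("BOT", "M"): 0.10,
    ("BLT", "F"): 0.55, ("BLT", "M"): 0.25,
}


@dataclass
class SyntheticBehaviorConfig:
    """Configuration of the synthetic behavioral cohorts.

    Drinking: per-kg day-1 baselines (females higher), body weights by
    sex, a dose -> expected-D2/D1 map, and log-normal ratio noise.
    USVs: emitter probabilities per condition/sex/channel and
    negative-binomial per-minute call counts for emitters.
    Nausea: latent-normal dose effect cut into ordinal 0-3 block scores.
    """

    # drinking arm: subjects per dose group (half F, half M)
    doses: tuple[float, ...] = (0.0, 19.0, 38.0, 80.0)
    n_per_dose: int = 12
    conditioning_dose: float = 38.0
    baseline_intake_per_kg: Mapping[str, float] = field(
        default_factory=lambda: {"F": 40.0, "M": 30.0}
    )
    intake_per_kg_sd: float = 8.0
    body_weight_mean: Mapping[str, float] = field(
        default_factory=lambda: {"F": 250.0, "M": 350.0}
    )
    body_weight_sd: float = 20.0
    dose_suppression: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_SUPPRESSION)
    )
    ratio_noise_sd: float = 0.25  # SD of log-ratio noise
    p_high_e2: float = 0.5  # estrous split among females

    # USV arm: subjects per task condition (half F, half M)
    usv_conditions: tuple[str, ...] = ("COT", "BOT", "BLT")
    n_per_usv_condition: int = 12
    p_emit_55: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_P_EMIT_55)
    )
    p_emit_22: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_P_EMIT_22)
    )
    rate_55: float = 15.0  # mean calls/min for a 55 kHz emitter
    rate_22: float = 3.0  # mean calls/min for a 22 kHz emitter
    nb_dispersion: float = 2.0  # NB shape; smaller = more overdispersed

    # nausea latent model: P(score >= s) = P(latent > cut_s)
    nausea_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"pica": -1.2, "LOB": -1.5, "ptosis": -1.0}
    )
    nausea_dose_slope: float = 0.03  # latent-mean units per mg/kg
    nausea_cuts: tuple[float, float, float] = (0.0, 1.0, 2.0)

    seed: int = 0

    def __post_init__(self) -> None:
        sup = [self.dose_suppression[d] for d in sorted(self.dose_suppression)]
        if any(b > a for a, b in zip(sup, sup[1:])):
            raise ValueError("expected D2/D1 must be non-increasing in dose")
        if any(v < 0 for v in (self.rate_55, self.rate_22)):
            raise ValueError("USV rates must be non-negative")


def _nb_counts(rng: np.random.Generator, mean: float, shape: float, size: int) -> np.ndarray:
    """Negative-binomial counts with the given mean and shape (gamma-Poisson)."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    lam = rng.gamma(shape, mean / shape, size=size)
    return rng.poisson(lam)


def simulate_behavior(
    config: SyntheticBehaviorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (drinking, usv, nausea) tables in the pipeline's CSV schemas."""
    rng = np.random.default_rng(config.seed)

    # drinking + nausea share the dose-response roster
    drink_rows, nausea_rows = [], []
    for dose in config.doses:
        condition = "BOT" if dose == 0 else "BLT"
        for i in range(config.n_per_dose):
            sex = SEXES[i % 2]
            sid = f"D{int(dose):02d}_{i + 1:02d}"
            bw = max(150.0, rng.normal(config.body_weight_mean[sex], config.body_weight_sd))
            per_kg = max(2.0, rng.normal(config.baseline_intake_per_kg[sex], config.intake_per_kg_sd))
            d1 = per_kg * bw / 1000.0
            expected_ratio = config.dose_suppression[float(dose)]
            d2 = d1 * expected_ratio * rng.lognormal(0.0, config.ratio_noise_sd)
            estrous = "NA" if sex == "M" else ("high_E2" if rng.random() < config.p_high_e2 else "low_E2")
            drink_rows.append(
                {
                    "subject_id": sid,
                    "sex": sex,
                    "condition": condition,
                    "body_weight": round(bw, 1),
                    "intake_d1": round(d1, 2),
                    "intake_d2": round(d2, 2),
                    "licl_dose": float(dose),
                    "estrous_state": estrous,
                }
            )
            for behavior, base in config.nausea_baseline.items():
                latent_mean = base + config.nausea_dose_slope * float(dose)
                latent = rng.normal(latent_mean, 1.0, size=SESSION_EPOCHS * BLOCKS_PER_EPOCH)
                scores = np.sum(latent[:, None] > np.asarray(config.nausea_cuts)[None, :], axis=1)
                for epoch in range(SESSION_EPOCHS):
                    for block in range(BLOCKS_PER_EPOCH):
                        nausea_rows.append(
                            {
                                "subject_id": sid,
                                "behavior": behavior,
                                "epoch_index": epoch,
                                "block_index": block,
                                "score": int(scores[epoch * BLOCKS_PER_EPOCH + block]),
                            }
                        )

    usv_rows = []
    for cond in config.usv_conditions:
        for i in range(config.n_per_usv_condition):
            sex = SEXES[i % 2]
            sid = f"U{cond}_{i + 1:02d}"
            emits55 = rng.random() < config.p_emit_55[(cond, sex)]
            emits22 = rng.random() < config.p_emit_22[(cond, sex)]
            c55 = _nb_counts(rng, config.rate_55 if emits55 else 0.0, config.nb_dispersion, 10)
            c22 = _nb_counts(rng, config.rate_22 if emits22 else 0.0, config.nb_dispersion, 10)
            row = {"subject_id": sid, "sex": sex, "condition": cond}
            row.update({f"khz55_min_{m + 1}": int(c55[m]) for m in range(10)})
            row.update({f"khz22_min_{m + 1}": int(c22[m]) for m in range(10)})
            usv_rows.append(row)

    drinking = pd.DataFrame(drink_rows)
    usv = pd.DataFrame(usv_rows)
    nausea = pd.DataFrame(nausea_rows)
    return drinking, usv, nausea
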