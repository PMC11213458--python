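"""Synthetic correlated cohort of ham-quality measurements.

No public dataset exists for the joint distribution of bioimpedance Py,
ultimate pH, CIELAB color and visual DES scores in defective ham, so this
module generates one with a controlled correlation structure:

* A latent Gaussian vector holds the continuous quality variables
  (``py_ad``, ``py_sm``, ``ph_u``, ``l_star``, ``a_star``, ``b_star``)
  plus a latent defect *severity* factor.  Pairwise structure is a
  single-factor model (each variable loads on severity) blended with
  explicit residual correlations for pairs the factor alone cannot hit.
* Each observer's integer DES score (0-3) is the shared severity plus
  per-observer Gaussian noise, cut at fixed quantile thresholds; joint
  (training) samples take the consensus score from severity alone, so
  both observers agree by construction.
* Marginals are location/scale transforms of the latent normals with
  truncation by rejection resampling (no point masses at the bounds).

Thresholding and truncation attenuate correlations, so latent parameters
are *calibrated* by a simulate-measure-adjust fixed-point loop against the
requested observed-scale targets (:func:`calibrate_latent`).  The default
targets are literature-reported values: Py(AD)-DES -0.461,
pH_u-DES -0.44, a*-DES 0.21, Py-pH_u 0.29, Py-b* -0.27, Py(AD)-Py(SM)
0.80 and inter-observer 0.62.

Spectra consistent with each record's Py can be attached
(:func:`generate_spectra_for_record`), closing the loop back to the
Cole-fitting stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import scoring
from .cole import ColeParameters, ImpedanceSpectrum, evaluate_cole, default_frequency_grid
from .errors import CalibrationError, ConfigError, InputError
from .stats import QualityRecord

CONTINUOUS_VARS = ("py_ad", "py_sm", "ph_u", "l_star", "a_star", "b_star")
_SEV = "sev"


def _pair(a: str, b: str) -> tuple:
    return tuple(sorted((a, b)))


#: Observed-scale correlation targets used by default (literature values).
DEFAULT_TARGET_CORR = {
    _pair("py_ad", "des_avg"): -0.461,
    _pair("ph_u", "des_avg"): -0.44,
    _pair("a_star", "des_avg"): 0.21,
    _pair("py_ad", "ph_u"): 0.29,
    _pair("py_ad", "b_star"): -0.27,
    _pair("py_ad", "py_sm"): 0.80,
    _pair("des_obs1", "des_obs2"): 0.62,
}


@dataclass(frozen=True)
class Marginal:
    """Mean/SD and open truncation bounds for one continuous variable."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (self.sd > 0 and self.lower < self.mean < self.upper):
            raise ConfigError(f"invalid marginal {self}")


#: Plausible per-variable marginals (invented defaults: no published
#: descriptive table backs them).  SM Py sits ~8 units above AD, mirroring the
#: lower-shifted AD distribution.
DEFAULT_MARGINALS = {
    "py_ad": Marginal(45.0, 15.0, 0.0, 100.0),
    "py_sm": Marginal(53.0, 15.0, 0.0, 100.0),
    "ph_u": Marginal(5.6, 0.15, 4.5, 7.5),
    "l_star": Marginal(50.0, 4.0, 20.0, 80.0),
    "a_star": Marginal(8.0, 2.0, 0.0, 20.0),
    "b_star": Marginal(4.0, 1.5, -2.0, 12.0),
}

#: Marginal probabilities of observer scores 0..3 (heterogeneous, all
#: four ranks well represented).
DEFAULT_SCORE_PROBS = (0.35, 0.30, 0.20, 0.15)


@dataclass
class CohortConfig:
    """Generator configuration.

    ``target_corr`` maps sorted variable-name pairs to desired
    observed-scale Pearson correlations; ``latent`` holds the calibrated
    latent-scale parameters (loadings on severity, residual correlations,
    observer weight) and is filled in by :func:`calibrate_latent`.
    ``joint_fraction`` is the share of samples scored jointly by both
    observers (training samples), 25/136 by default.
    """

    n_animals: int = 136
    seed: int = 0
    target_corr: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_CORR))
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    score_probs: tuple = DEFAULT_SCORE_PROBS
    joint_fraction: float = 25.0 / 136.0
    latent: dict | None = None
    calibration_seed: int = 20211
    pilot_n: int = 50_000

    def __post_init__(self):
        if self.n_animals < 4:
            raise ConfigError(f"n_animals must be >= 4, got {self.n_animals}")
        self.target_corr = {_pair(*k): float(v) for k, v in self.target_corr.items()}
        for pair, v in self.target_corr.items():
            if not (-1.0 < v < 1.0):
                raise ConfigError(f"target correlation {pair} = {v} outside (-1, 1)")
        probs = np.asarray(self.score_probs, dtype=float)
        if len(probs) != 4 or np.any(probs <= 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("score_probs must be 4 positive values summing to 1")
        if not (0.0 <= self.joint_fraction < 1.0):
            raise ConfigError(f"joint_fraction must be in [0, 1), got {self.joint_fraction}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["target_corr"] = {"|".join(k): v for k, v in self.target_corr.items()}
        d["marginals"] = {k: dataclasses.asdict(m) if isinstance(m, Marginal) else m
                          for k, m in self.marginals.items()}
        if self.latent is not None:
            d["latent"] = _latent_as_json(self.latent)
        d["score_probs"] = list(self.score_probs)
        return d


@dataclass
class SyntheticCohort:
    """A generated cohort: records, optional spectra, and provenance."""

    records: list
    spectra: list | None = None
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        from .stats import records_to_frame

        return records_to_frame(self.records)


# ---------------------------------------------------------------------------
# Latent machinery


def _score_cutpoints(score_probs) -> np.ndarray:
    cum = np.cumsum(np.asarray(score_probs, dtype=float))[:-1]
    return sps.norm.ppf(cum)


def _init_latent(cfg: CohortConfig) -> dict:
    loadings = {v: 0.0 for v in CONTINUOUS_VARS}
    residuals = {}
    w_obs = 0.0
    for pair, target in cfg.target_corr.items():
        if pair == _pair("des_obs1", "des_obs2"):
            w_obs = float(np.sqrt(min(abs(target), 0.95)))
        elif "des_avg" in pair:
            var = pair[0] if pair[1] == "des_avg" else pair[1]
            if var not in CONTINUOUS_VARS:
                raise ConfigError(f"unknown variable in target pair {pair}")
            loadings[var] = target
        else:
            if not set(pair).issubset(CONTINUOUS_VARS):
                raise ConfigError(f"unknown variable in target pair {pair}")
            residuals[pair] = target  # refined after loadings are known
    # SM mirrors AD on the severity factor (same tissue property)
    if loadings["py_sm"] == 0.0 and loadings["py_ad"] != 0.0:
        loadings["py_sm"] = loadings["py_ad"]
    for pair in residuals:
        lam = loadings[pair[0]] * loadings[pair[1]]
        residuals[pair] = cfg.target_corr[pair] - lam
    return {"loadings": loadings, "residuals": residuals, "w_obs": w_obs}


def _latent_matrix(latent: dict) -> np.ndarray:
    """Latent correlation matrix over CONTINUOUS_VARS + severity.

    Entries are factor-implied (loading products) plus residuals; mildly
    indefinite matrices are repaired by eigenvalue clipping, strongly
    indefinite ones raise :class:`ConfigError`.
    """
    names = CONTINUOUS_VARS + (_SEV,)
    k = len(names)
    lam = dict(latent["loadings"], **{_SEV: 1.0})
    res = latent["residuals"]
    C = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            v = lam[a] * lam[b] + res.get(_pair(a, b), 0.0)
            C[i, j] = C[j, i] = float(np.clip(v, -0.99, 0.99))
    eigval, eigvec = np.linalg.eigh(C)
    if eigval.min() < -0.05:
        bad = sorted(res, key=lambda p: -abs(res[p]))[:3]
        raise ConfigError(
            f"latent correlation structure is not positive definite "
            f"(min eigenvalue {eigval.min():.3f}); offending pairs likely among {bad}"
        )
    if eigval.min() < 1e-8:
        eigval = np.clip(eigval, 1e-8, None)
        C = eigvec @ np.diag(eigval) @ eigvec.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    return C


def _simulate_latent(cfg: CohortConfig, latent: dict, n: int, rng) -> pd.DataFrame:
    """Draw n rows: continuous variables (truncated by resampling),
    observer scores, consensus score and latent severity."""
    C = _latent_matrix(latent)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    w = float(latent["w_obs"])
    w_noise = float(np.sqrt(max(0.0, 1.0 - w * w)))
    cut = _score_cutpoints(cfg.score_probs)

    k = len(CONTINUOUS_VARS)
    kept = []
    total = 0
    for _ in range(200):
        m = max(256, int((n - total) * 1.3) + 32)
        z = rng.standard_normal((m, k + 1)) @ L.T
        eps = rng.standard_normal((m, 2))
        ok = np.ones(m, dtype=bool)
        for i, v in enumerate(CONTINUOUS_VARS):
            marg = cfg.marginals[v]
            x = marg.mean + marg.sd * z[:, i]
            ok &= (x > marg.lower) & (x < marg.upper)
        block = np.column_stack([z[ok], eps[ok]])
        kept.append(block)
        total += block.shape[0]
        if total >= n:
            break
    else:
        raise ConfigError(
            "truncation bounds reject nearly all draws; loosen the marginals"
        )
    data = np.vstack(kept)[:n]
    z = data[:, : k + 1]
    eps = data[:, k + 1 :]
    sev = z[:, k]

    cols = {}
    for i, v in enumerate(CONTINUOUS_VARS):
        marg = cfg.marginals[v]
        cols[v] = marg.mean + marg.sd * z[:, i]
    z1 = w * sev + w_noise * eps[:, 0]
    z2 = w * sev + w_noise * eps[:, 1]
    cols["des_obs1"] = np.searchsorted(cut, z1, side="right")
    cols["des_obs2"] = np.searchsorted(cut, z2, side="right")
    cols["consensus"] = np.searchsorted(cut, sev, side="right")
    cols["sev"] = sev
    return pd.DataFrame(cols)


def _measure(cfg: CohortConfig, df: pd.DataFrame) -> dict:
    """Observed-scale sample correlations for every target pair."""
    des_avg = (df["des_obs1"].to_numpy() + df["des_obs2"].to_numpy()) / 2.0
    out = {}
    for pair in cfg.target_corr:
        if pair == _pair("des_obs1", "des_obs2"):
            x, y = df["des_obs1"].to_numpy(), df["des_obs2"].to_numpy()
        elif "des_avg" in pair:
            var = pair[0] if pair[1] == "des_avg" else pair[1]
            x, y = df[var].to_numpy(), des_avg
        else:
            x, y = df[pair[0]].to_numpy(), df[pair[1]].to_numpy()
        out[pair] = float(np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1])
    return out


def calibrate_latent(
    config: CohortConfig,
    tolerance: float = 0.0075,
    max_iter: int = 40,
) -> tuple[CohortConfig, dict]:
    """Calibrate latent parameters so observed-scale statistics hit targets.

    Simulate-measure-adjust fixed point: each iteration simulates a pilot
    cohort (``config.pilot_n`` rows, fixed calibration seed so the same
    normal draws are reused and the iteration is a smooth fixed-point
    map), measures every target pair on the observed scale, and shifts
    the responsible latent parameter by the residual.  Loadings answer
    for variable-DES pairs, the observer weight for the inter-observer
    pair, pair residual correlations for continuous-continuous pairs.

    Returns ``(calibrated_config, report)`` where the report lists
    targets, achieved values and iterations.  Raises
    :class:`CalibrationError` when ``max_iter`` is exhausted or the
    implied latent structure is infeasible.
    """
    cfg = dataclasses.replace(config)
    latent = _init_latent(cfg)
    pilot_cfg = dataclasses.replace(cfg, joint_fraction=0.0)
    measured: dict = {}
    # Clamped or non-responsive parameters (e.g. observer weight at 0, where
    # scores carry no severity signal) can leave a residual error that no
    # update removes; accept such a stagnant state only when the error is
    # below the Monte-Carlo resolution of the pilot sample.
    stall_tol = max(tolerance, 4.0 / np.sqrt(cfg.pilot_n))
    best_err = np.inf
    stagnant = 0
    for iteration in range(1, max_iter + 1):
        rng = np.random.default_rng(cfg.calibration_seed)
        try:
            df = _simulate_latent(pilot_cfg, latent, cfg.pilot_n, rng)
        except ConfigError as exc:
            raise CalibrationError(
                f"latent structure became infeasible during calibration: {exc}",
                achieved=_report_values(cfg, measured),
            ) from exc
        measured = _measure(cfg, df)
        errs = {p: cfg.target_corr[p] - measured[p] for p in cfg.target_corr}
        max_err = max(abs(e) for e in errs.values()) if errs else 0.0
        if max_err < best_err - tolerance / 10.0:
            best_err = max_err
            stagnant = 0
        else:
            stagnant += 1
        stalled = stagnant >= 5
        if max_err <= tolerance or (stalled and max_err <= stall_tol):
            out = dataclasses.replace(cfg, latent=latent)
            return out, {
                "iterations": iteration,
                "tolerance": tolerance,
                "achieved": _report_values(cfg, measured),
                "latent": _latent_as_json(latent),
            }
        if stalled:
            raise CalibrationError(
                f"calibration stalled with residual error {max_err:.3f} "
                f"(targets likely infeasible under the latent structure)",
                achieved=_report_values(cfg, measured),
            )
        for pair, err in errs.items():
            if pair == _pair("des_obs1", "des_obs2"):
                w2 = float(np.clip(latent["w_obs"] ** 2 + err, 0.0, 0.97))
                latent["w_obs"] = float(np.sqrt(w2))
            elif "des_avg" in pair:
                var = pair[0] if pair[1] == "des_avg" else pair[1]
                latent["loadings"][var] = float(
                    np.clip(latent["loadings"][var] + err, -0.97, 0.97)
                )
            else:
                latent["residuals"][pair] = float(
                    np.clip(latent["residuals"].get(pair, 0.0) + err, -1.9, 1.9)
                )
        # keep the SM loading tied to AD when SM has no DES target of its own
        if _pair("py_sm", "des_avg") not in cfg.target_corr:
            latent["loadings"]["py_sm"] = latent["loadings"]["py_ad"]
    raise CalibrationError(
        f"calibration did not reach tolerance {tolerance} in {max_iter} iterations",
        achieved=_report_values(cfg, measured),
    )


def _report_values(cfg, measured):
    return {
        "|".join(p): {"target": cfg.target_corr[p], "achieved": measured.get(p)}
        for p in cfg.target_corr
    }


def _latent_as_json(latent):
    return {
        "loadings": dict(latent["loadings"]),
        "residuals": {"|".join(k): v for k, v in latent["residuals"].items()},
        "w_obs": latent["w_obs"],
    }


# ---------------------------------------------------------------------------
# Cohort generation


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort of :class:`QualityRecord` from a (calibrated) config.

    Calibrates first when ``config.latent`` is missing.  Deterministic
    given ``config.seed``.  The first ``round(joint_fraction * n)``
    samples are joint-scored training samples (both observers carry the
    consensus score).
    """
    report = None
    if config.latent is None:
        config, report = calibrate_latent(config)
    rng = np.random.default_rng(config.seed)
    df = _simulate_latent(config, config.latent, config.n_animals, rng)
    n_joint = int(round(config.joint_fraction * config.n_animals))

    records = []
    width = len(str(config.n_animals))
    for i in range(config.n_animals):
        joint = i < n_joint
        if joint:
            s1 = s2 = int(df["consensus"].iloc[i])
        else:
            s1 = int(df["des_obs1"].iloc[i])
            s2 = int(df["des_obs2"].iloc[i])
        avg = scoring.average_scores(s1, s2)
        records.append(
            QualityRecord(
                sample_id=f"S{i + 1:0{width}d}",
                py_ad=float(df["py_ad"].iloc[i]),
                py_sm=float(df["py_sm"].iloc[i]),
                ph_u=float(df["ph_u"].iloc[i]),
                l_star=float(df["l_star"].iloc[i]),
                a_star=float(df["a_star"].iloc[i]),
                b_star=float(df["b_star"].iloc[i]),
                des_obs1=s1,
                des_obs2=s2,
                des_avg=avg,
                des_rank=scoring.rank_from_average(avg),
                joint=joint,
            )
        )
    provenance = {"config": config.to_dict(), "seed": config.seed}
    if report is not None:
        provenance["calibration"] = report
    return SyntheticCohort(records=records, provenance=provenance)


# ---------------------------------------------------------------------------
# Spectra consistent with a record's Py


def generate_spectra_for_record(
    record,
    noise_level: float = 0.01,
    seed: int = 0,
    *,
    r0_range: tuple = (150.0, 450.0),
    fc_range: tuple = (2e3, 8e4),
    alpha_range: tuple = (0.6, 0.9),
    n_replicates: int = 2,
    frequencies: np.ndarray | None = None,
) -> list[ImpedanceSpectrum]:
    """Emit replicate impedance spectra whose Cole parameters match the
    record's Py for each measured muscle.

    R0 is drawn uniformly from ``r0_range``, the characteristic frequency
    log-uniformly from ``fc_range`` (inside the measured band), alpha
    uniformly from ``alpha_range``; Rinf follows from Py.  Proportional
    complex Gaussian noise of ``noise_level`` (fraction of |Z|, per point
    and per component) is added.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if frequencies is None:
        frequencies = default_frequency_grid()
    py_by_muscle = {"AD": record.py_ad}
    if getattr(record, "py_sm", None) is not None:
        py_by_muscle["SM"] = record.py_sm
    spectra = []
    for muscle, py in py_by_muscle.items():
        if not (0.0 < py < 100.0):
            raise InputError(f"Py must be in (0, 100) to synthesize a spectrum, got {py}")
        r0 = rng.uniform(*r0_range)
        fc = np.exp(rng.uniform(np.log(fc_range[0]), np.log(fc_range[1])))
        alpha = rng.uniform(*alpha_range)
        params = ColeParameters(
            r0=r0,
            rinf=r0 * (1.0 - py / 100.0),
            tau=1.0 / (2.0 * np.pi * fc),
            alpha=alpha,
        )
        clean = evaluate_cole(params, frequencies)
        for rep in range(1, n_replicates + 1):
            scale = noise_level * np.abs(clean)
            noisy = clean + scale * (
                rng.standard_normal(len(clean)) + 1j * rng.standard_normal(len(clean))
            )
            spectra.append(
                ImpedanceSpectrum(
                    sample_id=record.sample_id,
                    muscle=muscle,
                    replicate=rep,
                    frequencies=frequencies.copy(),
                    impedance=noisy,
                )
            )
    return spectra


def attach_spectra(
    cohort: SyntheticCohort, noise_level: float = 0.01, seed: int = 0, **kwargs
) -> SyntheticCohort:
    """Generate spectra for every record in a cohort (deterministic per seed)."""
    spectra = []
    for i, rec in enumerate(cohort.records):
        sub_seed = (seed * 100_003 + i) % (2**31 - 1)
        spectra.extend(
            generate_spectra_for_record(rec, noise_level=noise_level, seed=sub_seed, **kwargs)
        )
    cohort.spectra = spectra
    return cohort
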