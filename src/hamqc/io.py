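"""CSV / JSON / YAML readers and writers binding the pipeline stages.

All tabular interchange is plain CSV (UTF-8, mandatory header); models,
fit results and calibration reports are JSON; pipeline configuration may
be given as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cole import ColeFitResult, ImpedanceSpectrum
from .cohort import CohortConfig, Marginal
from .errors import InputError
from .scoring import DesRank, ObserverScores
from .stats import QualityRecord, RegressionModel, Term

SPECTRA_COLUMNS = ["sample_id", "muscle", "replicate", "frequency_hz", "z_real_ohm", "z_imag_ohm"]
FITS_COLUMNS = [
    "sample_id", "muscle", "replicate", "r0_ohm", "rinf_ohm", "tau_s", "alpha",
    "py", "fc_hz", "residual_norm", "converged",
]
RECORDS_COLUMNS = [
    "sample_id", "py_ad", "py_sm", "ph_u", "l_star", "a_star", "b_star",
    "des_obs1", "des_obs2", "des_avg", "des_rank", "joint",
]
SCORES_COLUMNS = ["sample_id", "observer_id", "score", "joint"]


def _read_csv(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise InputError(f"cannot parse CSV {path}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s): {missing}")
    return df


# ---------------------------------------------------------------------------
# Spectra


def write_spectra_csv(spectra, path) -> None:
    """Long-format spectrum CSV: one row per frequency point."""
    rows = []
    for s in spectra:
        for f, z in zip(s.frequencies, s.impedance):
            rows.append((s.sample_id, s.muscle, s.replicate, f, z.real, z.imag))
    pd.DataFrame(rows, columns=SPECTRA_COLUMNS).to_csv(path, index=False)


def read_spectra_csv(path) -> list:
    """Read spectra grouped by (sample_id, muscle, replicate), frequency-sorted."""
    df = _read_csv(path, SPECTRA_COLUMNS)
    spectra = []
    for (sid, muscle, rep), grp in df.groupby(
        ["sample_id", "muscle", "replicate"], sort=True
    ):
        grp = grp.sort_values("frequency_hz")
        try:
            spectra.append(
                ImpedanceSpectrum(
                    sample_id=str(sid),
                    muscle=str(muscle),
                    replicate=int(rep),
                    frequencies=grp["frequency_hz"].to_numpy(dtype=float),
                    impedance=grp["z_real_ohm"].to_numpy(dtype=float)
                    + 1j * grp["z_imag_ohm"].to_numpy(dtype=float),
                )
            )
        except InputError as exc:
            first_row = int(grp.index.min()) + 2  # 1-based, plus header
            raise InputError(
                f"{path} near line {first_row} ({sid}/{muscle}/rep{rep}): {exc}"
            ) from exc
    return spectra


def write_fits_csv(rows, path) -> None:
    """Fit output CSV; ``rows`` are dicts with the FITS_COLUMNS keys."""
    pd.DataFrame(rows, columns=FITS_COLUMNS).to_csv(path, index=False)


def write_aggregates_csv(aggregates, path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "muscle": a.muscle,
                "py": a.py,
                "n_replicates": a.n_replicates,
                "spread": a.spread,
                "flagged": a.flagged,
            }
            for a in aggregates
        ]
    ).to_csv(path, index=False)


def fit_result_to_json(result: ColeFitResult) -> str:
    return json.dumps(result.to_dict(), indent=2)


# ---------------------------------------------------------------------------
# Scores and quality records


def write_scores_csv(scores, path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.observer_id, s.score, s.joint) for s in scores],
        columns=SCORES_COLUMNS,
    ).to_csv(path, index=False)


def read_scores_csv(path) -> list:
    df = _read_csv(path, SCORES_COLUMNS)
    return [
        ObserverScores(
            sample_id=str(r.sample_id),
            observer_id=str(r.observer_id),
            score=int(r.score),
            joint=bool(r.joint),
        )
        for r in df.itertuples()
    ]


def write_records_csv(records_or_frame, path) -> None:
    from .stats import records_to_frame

    df = records_to_frame(records_or_frame)
    df.to_csv(path, index=False, columns=[c for c in RECORDS_COLUMNS if c in df.columns])


def read_records_csv(path) -> list:
    df = _read_csv(path, [c for c in RECORDS_COLUMNS if c != "py_sm"])
    records = []
    for r in df.itertuples():
        py_sm = getattr(r, "py_sm", None)
        if py_sm is not None and pd.isna(py_sm):
            py_sm = None
        records.append(
            QualityRecord(
                sample_id=str(r.sample_id),
                py_ad=float(r.py_ad),
                py_sm=float(py_sm) if py_sm is not None else None,
                ph_u=float(r.ph_u),
                l_star=float(r.l_star),
                a_star=float(r.a_star),
                b_star=float(r.b_star),
                des_obs1=int(r.des_obs1),
                des_obs2=int(r.des_obs2),
                des_avg=float(r.des_avg),
                des_rank=DesRank[str(r.des_rank)],
                joint=bool(r.joint),
            )
        )
    return records


def write_correlations_csv(results, path) -> None:
    pd.DataFrame(
        [
            {
                "var_x": c.var_x,
                "var_y": c.var_y,
                "r": c.r,
                "p_value": c.p_value,
                "n": c.n,
                "r_squared_pct": c.r_squared_pct,
            }
            for c in results
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Models


def model_to_dict(model: RegressionModel) -> dict:
    return {
        "response": model.response,
        "terms": [{"kind": t.kind, "vars": list(t.vars)} for t in model.terms],
        "coefficients": [float(c) for c in model.coefficients],
        "n": model.n,
        "r_multiple": model.r_multiple,
        "prediction_error_rmse": model.prediction_error,
        "prediction_error_mae": model.mae,
        "p_values": [float(p) for p in model.p_values] if model.p_values is not None else None,
        "skipped_terms": list(model.skipped_terms),
    }


def write_model_json(model: RegressionModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2))


def read_model_json(path) -> RegressionModel:
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    d = json.loads(path.read_text())
    return RegressionModel(
        response=d["response"],
        terms=[Term(t["kind"], tuple(t["vars"])) for t in d["terms"]],
        coefficients=np.asarray(d["coefficients"], dtype=float),
        n=int(d["n"]),
        r_multiple=d.get("r_multiple"),
        prediction_error=d.get("prediction_error_rmse"),
        mae=d.get("prediction_error_mae"),
        p_values=np.asarray(d["p_values"], dtype=float) if d.get("p_values") else None,
        skipped_terms=d.get("skipped_terms", []),
    )


# ---------------------------------------------------------------------------
# Configuration


def load_cohort_config(path, **overrides) -> CohortConfig:
    """Build a :class:`CohortConfig` from a YAML/JSON file plus overrides.

    ``target_corr`` keys use ``"var_a|var_b"`` strings; ``marginals``
    entries are ``{mean, sd, lower, upper}`` mappings.
    """
    raw = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise InputError(f"config file not found: {p}")
        raw = yaml.safe_load(p.read_text()) or {}
        if not isinstance(raw, dict):
            raise InputError(f"config file {p} must contain a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    kwargs = {}
    for key in ("n_animals", "seed", "joint_fraction", "calibration_seed", "pilot_n"):
        if key in raw:
            kwargs[key] = raw[key]
    if "score_probs" in raw:
        kwargs["score_probs"] = tuple(raw["score_probs"])
    if "target_corr" in raw:
        kwargs["target_corr"] = {
            tuple(k.split("|")): float(v) for k, v in raw["target_corr"].items()
        }
    if "marginals" in raw:
        kwargs["marginals"] = {
            name: Marginal(**spec) if isinstance(spec, dict) else spec
            for name, spec in raw["marginals"].items()
        }
    try:
        return CohortConfig(**kwargs)
    except TypeError as exc:
        raise InputError(f"bad configuration: {exc}") from exc
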