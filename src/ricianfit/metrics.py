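"""Accuracy/precision/error summaries for simulated parameter estimates.

Per ground-truth parameter combination, the error (estimate minus truth) of
each parameter is reduced to

* bias   — mean signed error (accuracy; lower magnitude is better),
* std    — population standard deviation of the error (precision),
* rmse   — root mean squared error (total error),
* median / iqr — robust counterparts.

Population (ddof=0) standard deviations are used so the decomposition
rmse^2 = bias^2 + std^2 holds exactly on every emitted table; the identity is
asserted at construction time. Quartiles use linear interpolation (NumPy's
default, type 7).

``boxplot_summary`` produces five-number summaries whose whiskers extend to
the most extreme point within 1.5*IQR *of the median* (the convention used in
the study's error boxplots); the standard Tukey rule (whiskers from the
quartiles) is available behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ivim import PARAM_NAMES

__all__ = [
    "error_table",
    "metrics_by_combination",
    "marginal_summary",
    "boxplot_summary",
]

_IDENTITY_TOL = 1e-9


def error_table(estimates: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Signed and relative per-voxel errors for each parameter.

    Rows must be aligned (voxel j of ``estimates`` corresponds to voxel j of
    ``truth``). Output columns: err_<p> = estimate - truth and
    rel_<p> = err_<p> / truth per parameter, plus truth columns and combo_id
    when present.
    """
    if len(estimates) != len(truth):
        raise ValueError(
            f"misaligned tables: {len(estimates)} estimates vs {len(truth)} truths"
        )
    out = {}
    for name in PARAM_NAMES:
        est = np.asarray(estimates[name], dtype=float)
        tru = np.asarray(truth[name], dtype=float)
        out[f"err_{name}"] = est - tru
        out[f"rel_{name}"] = (est - tru) / tru
        out[f"true_{name}"] = tru
    table = pd.DataFrame(out)
    if "combo_id" in truth.columns:
        table["combo_id"] = truth["combo_id"].to_numpy()
    return table


def _assert_rmse_identity(table: pd.DataFrame) -> None:
    lhs = table["rmse"] ** 2
    rhs = table["bias"] ** 2 + table["std"] ** 2
    scale = np.maximum(lhs.to_numpy(), 1.0)
    if np.any(np.abs(lhs.to_numpy() - rhs.to_numpy()) > _IDENTITY_TOL * scale):
        raise AssertionError("rmse^2 != bias^2 + std^2 — population-statistics bug")


def metrics_by_combination(errors: pd.DataFrame,
                           min_n: int = 2) -> pd.DataFrame:
    """Groupwise bias/std/rmse/median/iqr per (parameter, combination).

    ``errors`` is an :func:`error_table` output carrying a ``combo_id``
    column. Combinations with fewer than ``min_n`` instantiations are flagged
    in the ``underpowered`` column (std is undefined at n=1).
    """
    if "combo_id" not in errors.columns:
        raise ValueError("errors table must carry a combo_id column")
    records = []
    grouped = errors.groupby("combo_id", sort=True)
    for combo, g in grouped:
        n = len(g)
        for name in PARAM_NAMES:
            e = g[f"err_{name}"].to_numpy()
            bias = float(e.mean())
            std = float(e.std(ddof=0))
            q1, q3 = np.percentile(e, [25, 75])
            records.append({
                "parameter": name,
                "combo_id": combo,
                f"true_value": float(g[f"true_{name}"].iloc[0]),
                "bias": bias,
                "std": std,
                "rmse": float(np.sqrt(np.mean(e * e))),
                "median_error": float(np.median(e)),
                "iqr": float(q3 - q1),
                "mean_rel_error": float(g[f"rel_{name}"].mean()),
                "n": n,
                "underpowered": n < min_n,
            })
    table = pd.DataFrame.from_records(records)
    _assert_rmse_identity(table)
    return table


def marginal_summary(metrics: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Reduce combination-level metrics to one row per ground-truth level.

    For each unique true value of ``parameter``, the mean and standard
    deviation of each metric across the other parameters' combinations — the
    reduction used to visualise bias/std/RMSE profiles against one parameter.
    """
    sub = metrics[metrics["parameter"] == parameter]
    if sub.empty:
        raise ValueError(f"no rows for parameter {parameter!r}")
    rows = []
    for value, g in sub.groupby("true_value", sort=True):
        row = {"parameter": parameter, "true_value": value, "n_combos": len(g)}
        for m in ("bias", "std", "rmse", "median_error", "iqr", "mean_rel_error"):
            row[f"{m}_mean"] = float(g[m].mean())
            row[f"{m}_sd"] = float(g[m].std(ddof=0))
        rows.append(row)
    return pd.DataFrame(rows)


def _five_numbers(e: np.ndarray, whiskers_from: str) -> dict:
    med = float(np.median(e))
    q1, q3 = (float(q) for q in np.percentile(e, [25, 75]))
    iqr = q3 - q1
    if whiskers_from == "median":
        lo_lim, hi_lim = med - 1.5 * iqr, med + 1.5 * iqr
    elif whiskers_from == "quartiles":
        lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    else:
        raise ValueError("whiskers_from must be 'median' or 'quartiles'")
    inside = e[(e >= lo_lim) & (e <= hi_lim)]
    src = inside if inside.size else np.array([med])
    return {"median": med, "q1": q1, "q3": q3,
            "whisker_low": float(src.min()), "whisker_high": float(src.max())}


def boxplot_summary(errors: pd.DataFrame, snr_labels,
                    whiskers_from: str = "median") -> pd.DataFrame:
    """Per-SNR five-number summaries of the error distributions.

    ``errors`` maps SNR label -> error_table, or is a single table paired with
    one label. Whiskers extend to the most extreme data point within 1.5*IQR
    of the median by default; pass ``whiskers_from='quartiles'`` for the
    standard Tukey convention.
    """
    if isinstance(errors, pd.DataFrame):
        errors = {snr_labels if np.isscalar(snr_labels) else snr_labels[0]: errors}
        snr_labels = list(errors)
    rows = []
    for label in snr_labels:
        table = errors[label]
        if not len(table):
            raise ValueError(f"empty error group for SNR label {label!r}")
        for name in PARAM_NAMES:
            e = table[f"err_{name}"].to_numpy()
            rows.append({"snr": label, "parameter": name, "n": e.size,
                         **_five_numbers(e, whiskers_from)})
    return pd.DataFrame(rows)
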