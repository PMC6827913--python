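"""Signal-detection analysis of single-interval forced-choice edge trials.

Observers classify each briefly presented edge as "shadow" or "other".
Because single-interval tasks are susceptible to response bias, raw
percent correct is converted into the bias-free sensitivity measure

    d' = z(pH) - z(pFA)

where a Hit is an "other" response to a material edge, a False Alarm an
"other" response to a shadow, and z is the standard-normal quantile.
Response bias is summarized by the equal-variance criterion

    c = -(z(pH) + z(pFA)) / 2

(c > 0: conservative toward responding "shadow").

Rates of exactly 0 or 1 make z infinite; whenever that would happen in a
cell, the log-linear correction is applied (add 0.5 to each count and 1
to each denominator) and flagged in the output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "TRIAL_COLUMNS",
    "TrialParseError",
    "read_trials",
    "corrected_rates",
    "rates",
    "dprime",
    "bias",
    "summarize_observers",
    "aggregate_group",
]

TRIAL_COLUMNS = ["observer_id", "block", "condition", "size_class", "true_category", "response"]

_CONDITIONS = {"col", "lum"}
_SIZES = {"small", "medium", "large"}
_CATEGORIES = {"shadow", "other"}


class TrialParseError(ValueError):
    """Raised for malformed trial tables (missing columns, bad enum values)."""


def _canon(series: pd.Series, allowed: set[str], column: str, title: bool = False) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    bad = ~s.isin(allowed)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise TrialParseError(
            f"invalid value {series[bad.idxmax()]!r} in column {column!r} (line {line})"
        )
    return s.str.capitalize() if title else s


def read_trials(path_or_buffer) -> pd.DataFrame:
    """Read and validate a trial-level CSV.

    Required columns: observer_id, block, condition (Col/Lum), size_class
    (small/medium/large), true_category (shadow/other), response
    (shadow/other).  Values are case-folded; anything outside the
    enumerations raises :class:`TrialParseError` with a line number.
    """
    df = pd.read_csv(path_or_buffer)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"missing required columns: {missing}")
    df = df[TRIAL_COLUMNS].copy()
    df["condition"] = _canon(df["condition"], _CONDITIONS, "condition", title=True)
    df["size_class"] = _canon(df["size_class"], _SIZES, "size_class")
    df["true_category"] = _canon(df["true_category"], _CATEGORIES, "true_category")
    df["response"] = _canon(df["response"], _CATEGORIES, "response")
    return df


def corrected_rates(
    hits: int, n_material: int, false_alarms: int, n_shadow: int
) -> tuple[float, float, bool]:
    """(pH, pFA, corrected) with the log-linear extreme-rate correction.

    If either raw rate would be 0 or 1, 0.5 is added to *each* count and 1
    to *each* denominator, keeping both rates strictly inside (0, 1).
    """
    if n_material < 1 or n_shadow < 1:
        raise ValueError("each cell needs at least one trial of each category")
    ph = hits / n_material
    pfa = false_alarms / n_shadow
    if ph in (0.0, 1.0) or pfa in (0.0, 1.0):
        return (hits + 0.5) / (n_material + 1), (false_alarms + 0.5) / (n_shadow + 1), True
    return ph, pfa, False


def rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Hit/false-alarm summary per (observer, condition, size_class) cell.

    A Hit is an "other" response to a material ("other") edge; a False
    Alarm an "other" response to a shadow.  Cells missing either true
    category raise ``ValueError``.
    """
    rows = []
    for (obs, cond, size), cell in trials.groupby(
        ["observer_id", "condition", "size_class"], sort=True
    ):
        material = cell[cell["true_category"] == "other"]
        shadow = cell[cell["true_category"] == "shadow"]
        if len(material) == 0 or len(shadow) == 0:
            raise ValueError(
                f"cell ({obs}, {cond}, {size}) lacks trials of one true category"
            )
        hits = int((material["response"] == "other").sum())
        fas = int((shadow["response"] == "other").sum())
        ph, pfa, corrected = corrected_rates(hits, len(material), fas, len(shadow))
        rows.append(
            {
                "observer_id": obs, "condition": cond, "size_class": size,
                "n_material": len(material), "n_shadow": len(shadow),
                "hits": hits, "false_alarms": fas,
                "pH": ph, "pFA": pfa, "correction_applied": corrected,
            }
        )
    return pd.DataFrame(rows)


def dprime(ph: float, pfa: float) -> float:
    """Sensitivity ``d' = z(pH) - z(pFA)``; rates must lie strictly in (0, 1)."""
    ph, pfa = np.asarray(ph, dtype=float), np.asarray(pfa, dtype=float)
    if np.any((ph <= 0) | (ph >= 1) | (pfa <= 0) | (pfa >= 1)):
        raise ValueError("rates must be in (0, 1); apply the correction upstream")
    return norm.ppf(ph) - norm.ppf(pfa)


def bias(ph: float, pfa: float) -> float:
    """Equal-variance SDT criterion ``c = -(z(pH) + z(pFA))/2``."""
    ph, pfa = np.asarray(ph, dtype=float), np.asarray(pfa, dtype=float)
    if np.any((ph <= 0) | (ph >= 1) | (pfa <= 0) | (pfa >= 1)):
        raise ValueError("rates must be in (0, 1); apply the correction upstream")
    return -0.5 * (norm.ppf(ph) + norm.ppf(pfa))


def summarize_observers(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-(observer, condition, size) d' and bias table."""
    r = rates(trials)
    r["dprime"] = dprime(r["pH"].to_numpy(), r["pFA"].to_numpy())
    r["bias"] = bias(r["pH"].to_numpy(), r["pFA"].to_numpy())
    return r


def aggregate_group(
    per_observer: pd.DataFrame, n_boot: int = 2000, seed: int | None = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Across-observer mean +/- SEM of d' per (condition, size_class).

    Returns ``(group, paired)``: the group table (mean_dprime, sem, n) and a
    per-size table of the paired Col - Lum d' difference across observers
    with a percentile-bootstrap confidence interval (resampling observers).
    SEM is NaN when only one observer is present.
    """
    group = (
        per_observer.groupby(["condition", "size_class"], sort=True)["dprime"]
        .agg(mean_dprime="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n="size")
        .reset_index()
    )

    wide = per_observer.pivot_table(
        index="observer_id", columns=["condition", "size_class"], values="dprime"
    )
    rng = np.random.default_rng(seed)
    paired_rows = []
    for size in sorted(per_observer["size_class"].unique()):
        if ("Col", size) not in wide.columns or ("Lum", size) not in wide.columns:
            continue
        diff = (wide[("Col", size)] - wide[("Lum", size)]).dropna().to_numpy()
        if len(diff) >= 2:
            idx = rng.integers(0, len(diff), size=(n_boot, len(diff)))
            boot = diff[idx].mean(axis=1)
            lo, hi = np.percentile(boot, [2.5, 97.5])
        else:
            lo = hi = np.nan
        paired_rows.append(
            {
                "size_class": size, "mean_diff": diff.mean() if len(diff) else np.nan,
                "ci_lo": lo, "ci_hi": hi, "n_observers": len(diff),
            }
        )
    return group, pd.DataFrame(paired_rows)
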